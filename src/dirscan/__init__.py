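"""Detection, clustering and structural annotation of DIRS1-like retrotransposons."""

__version__ = "0.1.0"

from .config import Config  # noqa: F401


def __getattr__(name):
    # lazy re-exports so `import dirscan` stays light (numba compiles on use)
    import importlib

    entry_points = {
        "run_pipeline": "pipeline",
        "scan_domain": "profiles",
        "build_profile": "profiles",
        "calibrate_profile": "profiles",
        "mcl_cluster": "clustering",
        "pairwise_nt_similarity": "clustering",
        "classify_superfamily": "clustering",
        "annotate_element": "annotate",
        "nj_tree": "phylo",
        "jtt_gamma_distance": "phylo",
        "bootstrap_support": "phylo",
        "make_element": "synth",
        "plant_elements": "synth",
        "demo_genome": "synth",
    }
    if name in entry_points:
        mod = importlib.import_module(f".{entry_points[name]}", __name__)
        return getattr(mod, name)
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")
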