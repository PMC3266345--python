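# Methods

This note records the models, statistical procedures and design choices
behind `dirscan`, in the order the pipeline applies them.

## Profile search

Each domain profile is a position × amino-acid log-odds matrix in bits.
Columns of the seed alignment with more than 50% gaps are dropped; observed
column frequencies receive background-proportional pseudocounts with total
prior weight 1, i.e. p̂ₐ = (cₐ + πₐ)/(n + 1) against a standard background
composition π. Proportional (rather than uniform add-one) pseudocounts are
used because with few sequences a uniform pseudocount lets rare unseen
residues (W, C) outscore the residues actually observed, inverting the
column consensus. The ambiguity residue X scores 0 everywhere; the stop
symbol scores −10 bits, which prevents local alignments from crossing
in-frame stop codons. Gap penalties are 11 bits to open, 1 bit to extend —
conventional protein-search defaults, exposed in `Config`.

All searches run through one affine-gap Smith–Waterman kernel (numba-JIT,
linear memory) that propagates alignment origins through the recurrence, so
hit spans are recovered without a traceback matrix. Multiple hits per
sequence are obtained maximal-first: report the optimum, mask its subject
span, re-run until the score threshold is passed. The kernel is exhaustive —
no seeding heuristic — and the test suite pins it against an independent
full-matrix implementation with explicit traceback.

**E-values.** E = K·m·n·exp(−λS), with m the profile length and n the
nucleotide length of the searched region. (λ, K) are fitted per profile by
the method of moments on maximal local scores against 300 null sequences of
400 aa each. The null is the *translation of shuffled random nucleotide
sequence*, not clean random protein: translated genomic frames are
interrupted by stop codons roughly every 21 residues, and with the −10-bit
stop score this segmentation lowers attainable null scores several-fold at
the far tail. Calibrating against clean amino-acid strings made the
E ≤ 0.01 threshold ~5× conservative in measured false-positive rate;
against the translated null the measured rate is within sampling error of
nominal (4–7 events per 500 two-kb scans, expectation 5). Because a
six-frame scan of n nt covers ≈ 2n residues, the stored K absorbs a factor
2 so that n can be given in nucleotides. Calibration is deterministic given
its seed; the packaged profiles use fixed per-domain seeds.

Hits of the same domain on the same strand closer than 300 nt are merged
(union interval, best E-value kept) to absorb frameshift-split matches in
degenerate copies.

## Detection pipeline

Six steps: (1) RT search over the whole sequence; (2) one window per RT
anchor, ±5 kb, clipped at sequence ends (all described elements are under
~6.3 kb, so a 10-kb window always contains the full element); (3, 4) YR and
MT searches restricted to the window, E-values computed with n = window
length; (5) architecture check; (6) window merging and copy counting.

The architecture check first takes the best-scoring hit per domain on each
strand that carries all three domains (anchor strand first) and requires
YR < RT < MT along the element's own 5'→3' direction. If that fails *and*
some domain has several occurrences on the strand, any one-hit-per-domain
selection satisfying the order rescues the window: a nested or
tandem-rearranged locus should not be discarded merely because the
best-scoring hits belong to different inserted copies. Windows failing with
a single occurrence per domain are genuine order violations (Ngaro-like
architectures). Windows are merged when they share a hit (same domain,
interval and strand) — mere window overlap is not enough, to avoid chaining
unrelated neighbours — and a merged locus with ≥ 2 occurrences of any
domain becomes one copy with `complex_flag` set. A marginal spurious
duplicate hit can therefore occasionally flag an ordinary copy as complex;
the copy *count* is unaffected.

Per-element rough boundaries for annotation are the outermost domain hit
± 2500 nt (configurable): the margin must exceed the distance from the YR
domain hit back to the left terminus, which the ~1.6–2 kb GAG region can
push well past 1.5 kb.

## Family clustering and superfamily labels

RT fragments are compared all-vs-all with the same kernel under
megablast-like scoring (match +1, mismatch −2, gap open 5, extend 2);
E-values come from a seeded empirical Gumbel calibration at bucketed
lengths. Edges with E ≤ 0.01 get weight min(200, −log₁₀E). The Markov
Cluster algorithm is implemented directly: self-loops at the maximum
incident weight, column normalization, then alternating expansion (matrix
squaring) and inflation (entrywise power 1.2, renormalize) to a 1e−6
fixed point (≤ 200 iterations, convergence error otherwise). Clusters are
read from attractor systems; nodes supported by several systems go to the
one with the largest mass, ties to the lexicographically first — the
partition is invariant to node input order.

Superfamily labels use a translated six-frame × six-frame comparison
(BLOSUM62, gaps 11/1, empirical calibration): DIRS iff the best DIRS-reference
E-value is below 1e−20 *and* at least 10 orders of magnitude better than the
best PAT-reference E-value; PAT by the mirrored rule; otherwise uncertain.
The "10 orders" reading is multiplicative — an arithmetic difference of
1e−10 would be vacuous for E-values far below 1e−10.

## Repeat annotation

The annotator relies on the structural identities of the element model:

* conserved ITR: maximal *exact* reverse-complement run between the 5' and
  3' terminal windows;
* left ICR: exact reverse complement of the element prefix
  (lE + divergent ITR + outer part of the conserved ITR);
* right ICR: exact reverse complement of the element suffix (inner part of
  the conserved ITR + divergent ITR + rE);
* the two ICRs overlap on the 2–3 bp circular junction, and the ICR block
  abuts one terminus (the right one for a forward-oriented copy, the left
  one for a reverse-complement copy — accepting either makes annotation
  orientation-agnostic, and reverse-complement equivariance is tested).

Because the internal complementary regions can fall *inside* the 3'
terminal search window, the longest exact match between the windows is not
always the conserved ITR (it is the prefix↔lICR match whenever the lICR is
longer). The annotator therefore enumerates maximal exact matches as
conserved-ITR candidates, longest first, and accepts the first whose full
derived geometry is self-consistent (each ICR reaching into but not beyond
the conserved block, ICR block abutting a terminus). A tolerant local
alignment (match +1, mismatch −1, min length 20, identity ≥ 60%) gates the
whole procedure so unrelated sequence fails fast.

The divergent/extension split scans outward from the conserved block for
the outermost complementary column between the two termini: divergent
columns retain partial complementarity (50–85% in the observed elements),
extensions have none. ORF overlap is operationalized as two stop-to-stop
reading frames ≥ 600 nt in *different* frames overlapping by ≥ 50 nt
("long" is never quantified in the literature; both thresholds are
configuration). Diagnostic motifs are read at the profile positions of
Y[LI]DD (RT) and HSTR (YR), located in the profile consensus and mapped
through a traceback alignment of the hit region; variants are reported
verbatim. All failures degrade to "nd" fields, never abort.

## Phylogeny

Pairwise distances are ML estimates under the JTT empirical rate matrix
(published exchangeabilities and frequencies embedded as constants;
Q = S·diag(π) normalized to one expected substitution per site per unit
time) with discrete-gamma rate variation: 4 equal-probability categories at
quantile-midpoint rates, shape α configurable (default 1.0 — the original
analysis never reports its fitted shape). Columns with a gap or unknown in
either sequence are deleted pairwise; the likelihood is maximized over
t ∈ [1e−6, 10] by bounded scalar optimization. Neighbor joining follows
Saitou–Nei with deterministic lexicographic tie-breaking; a negative branch
length is clamped to zero with the excess moved to its sister edge.
Bootstrap resamples alignment columns, rebuilds the tree per replicate and
reports bipartition frequencies on the full-data tree. Correctness anchors:
NJ must exactly invert additive matrices; the distance estimator must
recover a simulated t = 0.5 within 0.05 on average (the simulator is an
independent forward implementation of the same model).

## Synthetic data

The generator emits every repeat relation *literally* (the ICRs are
computed reverse complements of the termini, the conserved ITR is an exact
reverse-complement pair, terminal trinucleotides are the reverse complement
of the junction), then fills the interior with back-translated domain
cassettes (uniform synonymous codon choice) at blueprint-specified
amino-acid identities to the profile consensi, separated by random stuffers
that carry stop codons in all three frames every ~90 nt. Default blueprint
draws sample repeat lengths uniformly within the observed per-element
ranges (divergent ITR 8–30, conserved 40–200, rE 9–60, ICRs ≥ 24 with sum
85–130, total size 3974–6283 nt) and NTT-style termini; the benchmark
genome is 2 Mb at GC 0.42 with 10 intact elements in 3 families, 3
Ngaro-order decoys (YR+RT, no MT), 2 MT-less frameshifted relics and one
nested pair.

Ground truth at single-base resolution requires that planted boundaries be
the *unique* maximal ones, so the generator disambiguates actively: the
divergent column adjacent to the conserved block is forced to mismatch
(otherwise the conserved run would extend), the outermost divergent column
is forced to match (anchoring the divergent/extension split), extension
columns never complement the opposite terminus, and the single bases
flanking each repeat (in stuffers and genomic flanks) are chosen so no
exact match extends past its planted end. Every element is round-tripped
through the annotation module before release and re-drawn from a derived
random stream in the rare cases where residual coincidences remain
(long chance matches inside the divergent part). ORF-overlap plantings use
a dedicated dual-frame stop-free segment rather than recoding a domain
cassette.

What the generator does *not* emulate: codon-usage bias, indel evolution in
the background, more than one level of nesting, segmental duplications and
low-complexity/repetitive background. Passing the closure tests therefore
demonstrates correctness of the algorithms on the stated element model, not
screening performance on real genomes, whose backgrounds are richer in
repeat-like noise.

## Numerical and procedural choices

* Internal coordinates 0-based half-open; GFF3 written 1-based inclusive.
* IUPAC ambiguity codes other than N become N at load time and act as
  neutral (score 0) in nucleotide scoring, X in translation.
* Orientation of a copy is defined by its RT strand; minus-strand copies
  are reverse-complemented before annotation.
* Benchmark sizes (2-Mb genome, 300-kb demo preset, 20 annotation
  blueprints, 25 additivity trees, 50 distance pairs, 500 calibration
  scans) are the package's standard desk-scale study conditions.
* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; generators are pure functions of (parameters, seed).

## Known limitations

* Relic and fragmented copies missing any of the three domains are outside
  the detector's scope by design.
* The empirical Gumbel calibration assumes a uniform-composition background;
  strongly skewed GC or low-complexity regions shift the realized
  false-positive rate.
* The packaged seed alignments and DIRS/PAT reference sets are synthetic
  stand-ins with the documented lengths and motifs, not curated biological
  alignments; profiles built from them are suitable for the synthetic
  benchmark and for testing, not for screening real assemblies.
* The per-element table transcription carries one internal inconsistency of
  its source (a 3793-nt element below the prose minimum of 3974 nt); the
  summaries report the table as printed.
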