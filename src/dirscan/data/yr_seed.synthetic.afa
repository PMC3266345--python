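>yr_seed_0
PISIVRPISHCNIEVDSTDKLWEHVINYLGQLWAGTSDPYYGDSIHTAICHNLAVFSDLF
GRVWKFFKGPIDNQWIWKCHLNMLMVMQQLPKCDSRIGIACDEPKKQIWPGCWFFDIAGT
QQAYPPSAETEYSHESEMRGHSTRPLCHVKGTMLKKSRRQCYCETTATNQLPSAQHQAWK
MSIGWQMPDEMYQGKIHFRCHMWVILWDTHQPRNQDWMNGTPTHKCLAHSNDFPNELEKH
STGKPHTAMGIIAGEQVMQCNPSVVAYSGSIQFAGGLDHLWG
>yr_seed_1
ITSDPRPISHCNIEVDSTWKLWEHVINYLGAACAGTSDPEITDSIITAVCHNLAVFSDLF
GRVWKFFKGPIDNHIRWKCFWNMLMVMQQLPKCKSREGIACDAPWKRIWPGNWPFDIAGH
QQPYPYSAEREYSHESEDRGHSTRPLCHVKGTMLKKSRRQCYTQWTATNQNPWAQHWAWK
MSIMFQMPDEMYQIPIHFRCHMWVILWDTVQFRNQDRMNGTPTAKCLAHSNDFYNELEKH
STGIPHTAMGIIWGMQRMACNPSVVAYSGSIQQAMGLDHVHG
>yr_seed_2
PISIVRPISHCNIEVLSTWKLWSHVINYLGQACAGTSDPEIFDSIHTAIGHNSSVFSDHF
GRVWKFFKGHIGNHWRWKCHPNMEMVMLQLPKCDSGELIACDAPWLRIWPGCPFFDIAGH
QQAYPYSAEEEYSHESEMRGHSTRPLCHVKGTMTKKSRRQCYTQTTGMNQNPWIQHQAWK
MSIMIVMPDEMYAIKIHFRCHMWVILWDTVQFRNQDWMNGTSKAKCGAHSNDFYNELEKH
YTGIPHTAMGIIPGMQRNQCNPSVVAYSGSIQFAGGLDHLWG
>yr_seed_3
WISIVRPISHCNIEVDSTWKSREHVINYLGQACAGTSSPEIGDSIHTAICHNLAVFSDWF
GKVWKFFKGPIDNHWRWKAHLNELMVMQQLPKPDWRQGIACDAPWKRRWMGCWFMDFAGH
PQIYPYSAETEYSHESEMRGHSTRPLCHVKGTMLKCSRRQLYTQTTATNQNPWANHQAWK
MSIMIQMPDEMYQITIHDRCHMWVILWDTVQFRNQDTINGTPTAKCLAHSNDFYNELEKH
STGIPHTAMDIIPGCCRMQCNPSVVAYPGSIQFAGGLDHLWG
>yr_seed_4
PISIVRPISHCNIMVKSTWKLWEHVQNYLGQACAGTSDPEIGDSIHYAICHNLAVFSDLF
GRVEKFFKGPIDLHWRWKCHLNMLMVMQQLANCDYCEGIACDAPSKRIWPGCWFFDIAGH
QQAYPYQAETEYSHDSEMRGHSTRPLCQVGPTMLKKSRRQCYTQTTMTNQNPWAQHQAKK
MMIMIQMPVEHYQIKIHFRCRMWVILWDTVQFPNQDWMNRTPTAKCLAHSNDFYNELEKH
STGIPHTFMKIIPGMQRMQCNPSVVAYSISIQLAGGLDHLWG
>yr_seed_5
PISIVRPISHCNIEEDSTWKLWEHVINYLGQACAGTSDPEIGDSIHNAICHNLAVFSDLF
GRVWKFFKDPIDNHWRWKCHLEMLMVMQQAPKCDSREGIACDAPWWRIWPGCWMFDDAGH
QQAYPYSAETNAATYHEMRGHSTRPLCHVKGTMLKKSRRQCYTQATRTPQNPWNQHQAWK
MSSMIQFPDEMYAIKIDFPCHMWVILWDTVQFRNQTGMNGTPTAKRLAHSNDFYNELEKH
STEHPHTAMGIIPGMQRMQCNPSVVAYSGSIQFAGGLDHLWG
>yr_seed_6
PISIVRPISHCNIECDSTWKLWEIVINYLDQASAGTSDPEIIDSAHTKICHYLAVFSDLF
GRVWKFFKGPIDNHWRDKCHLNMLMVMQQLKKCDSREGICCDAPWKRIWPGCWFFDIKPH
QQAYPYSAETEYSHESEMRGHSTRPLCHVKGTMLKKSRRQCYTQTKATNQNPWAQHQAWK
MSDMIQMPDERYQIKIHFQGHMWFILWDTVQFREQDWMNGMPTAKILAHSLDFRPELEKH
STGIPHTAMGIIPGMQRMQCNPSVVAYPGAIQFKGGLDHLWG
>yr_seed_7
PISIVRCISHCNIMVDSTWKLWEHVINYLGQACAGTSDPEIGDSIGTAICHNLAVFSDLF
GCVWKRFMGPIDNHWRWKCHLNMLVFMQQLPKCDSREGIACDAPWKRIWPGCWFFDIALH
QRAYPYCAETEYSYESEKNGHSTRPLCHHKGTMKKKSRVQCHTQTTATNQNPWAQHQAWK
MSIMIQMPDEMYQIKIHFRCHMWVILWDTVQFRNQDWMRGTYTAKCLKHSNDRYNNLEKH
SYGIPHHMMGIIPGMQRMQCNPSVVAYSGFIQFAGGLDHLWH
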