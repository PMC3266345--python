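>rt_seed_0
WPTARESVECKDLPCCQEDEYDRYLSIGDLYFGIGNHKQFQGRYYSDDQVCICHNYLDDY
KIIIIIDAPIGDQCAGYKSRDFWTIFYKCMSTVIYSIQIKFPKTRKPDKERYRQNKSN
>rt_seed_1
WPTAMESVEDKFLPCCQESEYDTYLSIGDLYFGINWHCQFQGGYYSKDQVCICHNYLDDY
KIIIIINAPIGDQCAEKKSRDFWTIFYKAMTTVIYSIQIKTPKDIKPDTEHQRQNKMY
>rt_seed_2
WPTAMQSVECKGLPCCQEDEYDTYLSIGDLYFGIGWHCQFQGRVYSKYIVCICHNYLDDY
KIIIIIKAPQGDTCAGYKSRDFWTIFYKCMTTVIYSIQIKFKKDMVPHKERQRQNKMM
>rt_seed_3
WPTAMESVECKFLPCCQYDHNDTYLSEGDRYFGIGWMCIFQGRYYSKDQFCICHRYLDDG
KIIIIIDAPIGDQCAGYKSRDFWTIFYKCMTTVIYSIQIKFPKDMKPDKEMQRQNKML
>rt_seed_4
WPTAMESVECKALPCCQEDEYDTYLSIGDLYFGIGSHCCYQGRGYSKDQVCIPHNYLDDY
KIIIIIILPIGDHVAGYKSRWFWTIFYKCMTTIIYSIQIKFPKDMKPDKERQRQNKMY
>rt_seed_5
WPTAMNSVECKFLPYAQEDEYDTYLWIGDLYFGIGQHCQFQGRYHSKDQYCICHNYLDDY
KIIIIIDAPIGDQCAGYKSRQIWTIWYKCMTTVIYSIQIKFPKDMKFDKERQRQLKMY
>rt_seed_6
WATAMESVECKFLPCCQWDEYDTYLSIGDLTFIIGWHCKFQGRYYSEDHVQICHNYLDDY
KIIIIIDIPIGDQCAGGKSRDFWTIFFKCMTTVIYSIQIIFPKDMKPDKERQRQNKMY
>rt_seed_7
WPTAIEVVECKFLPCCQEDEYDTYLSIQDLYFQIGWHCQFQGRYYSKDQVCICHNYLDDY
KGIIIIDAPIGDQKAGYKDRDGWTIFYKCMTTVPYSIQIKWPKDMKPDKERSRQNKMC
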