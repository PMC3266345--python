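>dirs_ref_0_synthetic
CCCATCAGCATAGTGGACTTCATCAGTCACTGCAACATTGAAGTTGATTCCACGTGGAAA
CTATGGGAGCACGTTATCAACTATCTTGGACAGGCCTGCGCCGGAACGAGCGACCCGGAG
ATAGGCGACTCTATTCACACAGCGATATGTCATAATTTAGCCGTTTTTTATGATTGGTTC
GGCATGGTCTGGAAATTTTTCAAGGGACCGATCGATAACCACTGGAGGTGGAAGTGCCAT
TGGAATATGCTTATGGTTATGCAGCAACTACCAAAATGCGATTCTCGTGAAGGTATAGCT
TGTGACGCCCCGTGGAAACGCATTTGGCCTGGTTGCTGGTTCTTCGACCCAGCTGGACAC
CAGCAGGCTTATCCTTACAGCGCCGAGACAGAATACAGCTCAGAGAGTGAGATGCGGGGG
CATTCTACACGTCCTCTTTGCCACGTCAAAGGAACTATGTTAAAAAAAAGCCGCCGTCAG
TGTTATACTCAGACTACTGCCACCAACCAGAATCCGTGGGCCCAGCATCAAGCGTGGAAG
ATGTCGATCATGATTCAGATGCCAGATGAAATGTATCAAATTAAAATACACTTCCGCTGC
CATATGTGGGTCATCTTGTGGGATACGGTGCAATTCAGGAACCAAGATTGGATGAATGGC
ACTCCGACGGCCAAGTGCTTAGCGCATTCTAATGATTTCTACAACGAGCTGGAGAAACAT
AGCACTGGTATCCCACATACAGCGATGGGAATCATCCCAGGAATGCAGCGTATGCAATGT
AATCCTAGCGTGGTGGCGTATTCTGGGTCGATTAGTTTCGCGGGAGGCTTGGACCACAAA
TGGGGCAGACGGATCTTGTCTGCCAGTAATCGCTGGTGGCCGACCGCTATGGAGTCCGAG
GAGTGCAAATTCTTACCATGCTGTCAAATGGACGAGTACGATACCTATCTCTCAATTAAC
GATCTCTATTTTGGTATCGGCTGGCACTGTCAATTCCAAGGCCGGTATTATTCTAAGGAT
CAGGTCTGTATTTGTCACAATTATCTGGATGATTACAAAATTATTATCATAATAGATGCA
CCGATCGGGGACGATTGCGCCGGATACAAGAGCCGCGACTTCTGGACAATATTCTATAAA
TGCATGACCACCGTCATCTACAGCATCCAAATTAAGTTTCCTAAGGATATGAAACCCGAC
AAAGAAAGACAGCGCCAAAACAAAATGTACGCATGCTACGCTTAACCTGATGGACAGCAC
CGCGAAAACGGCGGGCTAGTGCAGAGTTCGTTGAGGTTCCATCCAAATCTTTACGGGCGT
TGGTTTATCGATATGCGTGAGGTCTACATAGCGGATAATATGTGGATGAAGACAAATGAC
CACTATCAGAGGTTCTGTCCCACAGGACTGATCCGTTGCATGGCTGATTGGGTTGAAGAA
CGCATATCAATGCATAAGCATAATTGTTGGATAGACTGTAACGTCGAAGCTCGCGACCCG
TTCCATTTGCACGAACATTCCAACTCAGAGTATTACATGGTGGTGTGGCTCACTGAGTCA
TGTTTTCCT
>dirs_ref_1_synthetic
CCCATTTCCATCGTGCGACCCATTTCGCATTGCAATATCGAAGTGCTCTCTACGTGGAAG
TTGTGGGTGCACGTCATTAATTATTTAGGTCAAGCGTGTGCAGGGACTAGCGATCCTGAA
ATAGGGGACTCCATACACACAGCAATTGTCCATAATCTCGCCGTCTTTTCAGACTGGTTT
GGGAGGGTATGGAAGTTTTTTAAAGGCCCAATCGATAATCATTGGAGGTGGAAATGTCAT
TGGAACGAACTGATGGTCATGCAGCAGCTTCCCAAATGCGATAGTAGATGGGGGATCGCT
TGTGACGCCCCCTGGAAGCGGATTTGGCCGGGATGCTGGTTCTTCGATATTGCCGGCCAT
CAGCAAGCCTACCCCTATAGCGCAGAGACTGAATATTCTCACGAAAGTGAAATGAGAGGG
CACAGCACAAGGCCACTTTGTCATGTGAAAGGGACAATGTTAAAGAAAAGCCGCCGGCAA
TGTTACGATCAAACAACCGCTACGAATCAGAATCCGTGGGCTCAGCATCAGGCTTGGAAG
ATGAGTATCATGATTCAAATGCCCGATGAGATGTACCAGATTAAAATACATTTCAGATGT
CACATGTGGGTGATACTTTGGGATACTGTTCAGTTCCGAAATCAAGACTGGATGAACGGG
ACGCCAACTGCTAAGTGCCTTGCACATAGTAATGATTTTTACAACGAACTTGAGAAGAGC
TCTACCGGCATCCCCCATACCTGGATGGGCATTATACCTGGAATGCAACGCATGCAGTGC
AACCCAAGTGTCGTAGCGTACTCTGGCAGTATCCAATTTGCAGGAGGATTGGATCACCTC
TGGGGACCCATCAAATTGCATGCAATTCGGGTCATGTGGCCAACCGCCATGGAGTCCGTA
GAATGCAAGTTTTTGCCCTGTGACCAGGAGGACGAATATGATACCTACCTATCGATAGGA
GATCTCTACTTTGGAATTGGATGGCATTGCCAATTCCAAGGTCGCGAGTACTCCAAGGAC
CAGGTTTGCATCTGCCATAATTACCTTGATGACTATAAGATAATCATAATTATAGATGCG
CCGATCGGTGATCATTGTGCTGGCTATAAGTCAAGGGACTTTTGGACTATTTTTTACCTC
TGTATGACTACTGTGATTTACTCGATACAGATAAAGTTCCCGAAGGACATGAAGCCCGAT
AAGGAAAGACAACGACAAAACAAGATGTACAGTCGTTTTGACGGCCACGGCGGTAGACTT
GGATGTAATGGCGGGCTAGTCCAATCCTCCTTAAGATTTCATCCTAACCTTTATGGCCGG
TGGTTCATTGATATGCGCGAGGTATACATAGCCGACAACATGTGGATGAAAACCAATGAC
CATTATCAAAGGTTTTGTCCAACGGGGCTAATCTGTTGCATGAACGACTGGGTCGAAGAG
CGAATATCGATGCACATTCACAACTGTTGGATAGACTGTAATGTCGAGGCCCGGAATCCC
TTCCACCTCCACGAACACTCGAACAGTGAGTACTATATGAGGCGTAAGGTGCGGCAGCGT
TGTCAAGTC
>dirs_ref_2_synthetic
CCGATTTCGATCGTACGTCCAATATCACATTGCAACATAGAGGTAGATTCGACATGGAAG
CTATGGGAGCACGTAATTAATTATCTGGGCCAAGCTTGTGCGGGCACGTCGGATATGGAA
ATTGGTGATAGTATTCACACGGCTATCTGCCATAATCTTGCCGTGTTTTCTGATTGGGAT
GGACGTGTCTGGAAATTCTTCAAGGGCCCGATAGACAACCATTGGAGGTGGAAATGCCAC
TGGAATATGCTAATGGTAATGCAGCAACTCCCCAAGTGTGATTCCCGAGAGGGCATTGCT
TGTGACGCGCCCTGGAAGCGCATTTGGCCAGGCTGTTGGTTTTTTGACATCGCGGGTCAC
ATTCAGGCATATCCATATTCTGCCGAGACGGAGTACTTTCATGAGAGTGAGATGCGTGGA
CATTCTACGCGACCGCTCTGTCATGTAAAAGGGACTATGCTCAAAACTTCACGAAGGCAA
TGTTACACTCAGACTACGGCTACAAATCAGAATCCGTGGGCTCAACATCAAGCGTGGAAG
ATGAGCATTATGATACAAATGCCTGATGAGATGTATCAGATTAAAATACATTTCCCTTGC
CACATGTGGAAGATATTATGGGATACAGTCCAGTTCAGAAACCAGGATTGGATGAATGGT
ACCCCGACAGCAAAATGTCTTGCACATTCGAATGATTTTTACAATGAACTGGAGAAACAC
AGCACAGGCATTCCACACACCGCAATGGGTATCATTCCTGGTATGCAAAGGATGCAATAT
AACCCGAGTGTTGTGGCATATAGCGGTAGTATACAATTCGCCGGTGGGTTGGATCATCTC
TGGGGCTAAGTCCCATAAATCGGTACGCAAAATAAATGGCCTACTGCTATGGAATCTGTA
GAGTGCAAGTTTTTAACATGCTGCCAGGGGGACGAGTACGACACCTATCTCTCTATAGGG
GATCTATATTTCGGCATCGGATGGCATTGTCAGTTCCAGGGGCGGTACTACTCAAAGGAT
CAGGTGTGCATATGTCACAACTATCTGGACGACTACAAGATCATTATAATTATCGACGCG
CCCATAGGGGATCAATGCGCGGGGTACAAATCTAGAGACTTTTGGACCATCTTCTACAAG
TGTATGATGACGGTTATATATTCGATACAAATTAAGTTCCCGAAGGACATGAAGCCCGAT
AAGGAACGGCAGGAGCAAAACAAAATGTATCCATCACTTTGGGTTCGACGACTGCGTCTA
GGCGAGAACGGAGGGCTCGTCCAATCTAGCCTCAGATTCAATCCGAATCTGTATGGCCGT
TGGTTCATAGACATGCGAGAAGTCTATATAGCTGATAACATGTGGATGAAGACCAATGAC
CACTATCAGCGGTTTTGTCCAACTGGCCTCATCCGATGCATGGCTGACTGGGTTGAAGAG
CGGATTTCTATGCACATACACAACTGTTGGATTGATTGTAATGTCGAAGAGCGGAATCCT
TTTCATCTCCATGAACATTCTAATTATGAGTATTACATGAGTGCTACGTCAGCCGTCCAC
GAGTTTAAC
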