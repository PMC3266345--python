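>pat_ref_0_synthetic
ATGATACGCATAGTAGCCCCTATTGATCACGACAACATCGAGGTCACAACAAACGACGCA
CGTGAGATACATACTGCATACTATCCAGGAGAAGCTTGCATGAATACATCCGACCCGTTC
ATTGGATGGTCAATTTTCGACATAATTTCGCACTGTCTCATGGTATTCGAAACCCCCTTC
GGCTTAATCTGGAAATTCTTTAAGCCACCCATCGACTGGCATTGGAGGTGGCGATGCATG
GCGGACGACCTAATGTATATGACAAGTCCTGGCAAGCAAAAATCCAGAGAGGGGATATCG
TGCGATGCCCCTTGGAAACGTATCTGGCCGGGGACGTGGTTCTTTGTCATTGCCGGGAAA
GAACAGGCGTGGCCCCGAAGTGCGGAATGTGAGTATCATCACGAGTCAGAGTGGTATGGC
CATTCGCACAGACCGTGCTGTTTCGTAACTGGGACCATGGAAAAACAATCCCTCCGTATG
TGTGGGACACAGAACACCGCGAAGTTTAAGAATGTGATGCGCCAGCATCATATTTGGTTT
AATGGGATAATGCATATGAGGCCGGATGAGTGCATTGCGTTCATGATACATTTCCCGTGC
CACATGTGGGTGATACTACGCGACACCGTGCAGGGTCGGTTGATGTGCTGGATGAATTGG
ACTCGGTCTAAGCCATGCCTACTGCACGTCTTCGTCGTACAGCTCGAGGGTTATATGTCA
AGTAGGATAGAGCCTTGGACTGCTTGTGGTGACATCTGGGGTGCATGGAGGATGCAGTGT
TACGATTCGGTTGTAGCGTTTTGGTGGTATATGCAGTTCTTTGGCTGGCGACGGCAAAAG
TGGAATGTGAGGATAACACCACCCTCGATCGTTAATTGGCCTGACGCCGAGGAAGGAGTT
GAAGTAATGTTTCTGCCATGTTGTCAGGAATACGAGGGCGATATAGATCTAAGTGGCATA
GACTGTTACTTCGTGATTGTCTGGGCCTGCACGTTCCAAGGGCGTCACTACTCGGCACCT
GGTTGCTGTATCTGTCATGCCTATTGTGACGAGTATAAAATTATAATCATAATCGACGAT
TGCATATTTTTCTATGATGCAGGGATCAAGTCATTCGATCGCTGTACTATCTGTTATCTG
TATCAAACTACCGTCTCCGGTACCCATCAGAGTTGGTTCTTAGGTGATATGCAGCCGGAT
AAGGAAATCGGGGATCAACGCAGTATGTGCCCTCGCCCGGCGAGGCGGTAAATGAGAAAT
GGTGAAAATGGTGGAATCGTACAGAAAGTACAGCGACTCCATATGATCCTCTACGACCGG
ATTTTTTCCCATGTACGAGAGGTAGCGCAATGGATGTCAGAAGTAATGCATACTAATAAT
CACTATACTCCGTTTTGTCCCACTGGCTTACAACACTGTGCTTATGATTGGGTATCCGAG
CGTCGGTCCAATGACCAGCACCTATGCTGGATATGTAAGAACGTACTAGCACGCAATCCT
GATCAATTGCGTATGGGTAGTGCGCAAATGTACTACCTAAATTAGGCTGAGAATTTTTTC
GTGGGCGTA
>pat_ref_1_synthetic
ATGATTAGGATAGTCTCACCAATCGATCACGATAATATAGAGGTAACTACAAATGACGCC
AGAGAGATTCACACAGCGTATGACCCCGGAGAAGCGTGTATGAACACGAGCGATCCCGAA
ATAGGGGACAGCATTTTCGACATTATTAGCCATTGCCTGATGGTGTTTGAAACCCCTTTC
GGTCTCATTTGGAAATTTTTTAAACCGCCTATCGATTGGCATTGGAGATGGAGGTGCATG
GCGGACGACCTCATGTATATGACGTCTCTGGGTAAACAGAAGAGCCGGGAGGGCATTAGC
TGCGATGCCCCTTGGAAACGGATATGGCCGGGCACGTGGTTTTTTGTGATTGCCGGAAAA
GAACAGGCCTGGCCTCGGTCTGCCGAGTGTGAATACCATCATGAAAGTGAGTGGTATGGC
CATAGTCACAGACCATGCTGCTTTGTAACTGGTACGATGGAAAAACAGAAATTACGCATG
TGTGGATTCCAAAATACAGCGAAATTTAAAAACGTTATGCGTCAGCACCACATTTGGTTT
AATGGGATTATGATTATGCGCCCTGATGAGTGCATCGCCTTTATGATTCACTTCCCGATT
CACATGTGGGTTATACTGCGCGATACTGTGCAGGGCCGTCTAATGTGCTGGATGAATTGG
ACGAGATCCAAACCCTGCTTGCTCCACGTTTTTGCGTTTCAGCTAGAGGGCTTAATGTCG
TCCAGAATAGAGCCCCAAACGGCATGCGGTGATATTTGGGGCGCTTGGTTATGCCAGTGC
TATGATTCGGTAGTTGCTTTTTCTTGGTACATGCAATTCTTCGGCTGGCGACGACAGAAA
TGGAACACTGTGACAAGCAAACTTCGAACGCCAAGCTGGCCTGACGCGGAGGAAGGTGTG
GAAGTGATGTTCTTACCCTGCTGTCAGGAACCAGAGGGGGACATACCATTATCTGTAATC
GATTGCTACTTCGTGATCGTTTGGGCATGCACATTCCAAGAACGTCATTACTCGGCACCG
GGGTGCTGCATCTGTCACGCTTACTGCGATGAGTACAAGATAATTATCATAATAGACGAT
TGTATTTTCTTCTACGATGCAGTAATTAAGTCTTTCGATAGATGTACGATTTGTTACCTT
TACCAAACGTGGGTGTCGGGACCACACCAGTCATGGTTTTTAGGCGATATGCAGATAGAT
AAGGAGATAGGCGATCAACGCTCAATGTGTGTGTTGTTTCATAAATGTACAAGATCGGTC
GGCGAAAATGGCGGAATTGTGCAGAAAGTCCAGAGATTCAAAATGATCCTATACGACCGT
ATTTTTAGTCACGTCAGGGAGGTAGCCCAGTGGATGTCCGAAGTAATGCATACCAACAAT
CATTACACACCGTTCTGCCCTACTGGCTTACAGCACTGTGCGTATGATTGGGTATCGGAG
CGCATCAGCAATGACCAGCATCTCTGGTGGATCGATAAAAATGTGCTAGCTCGCAACCCC
GATCAGCTTAGGATGGGGTCCAATCAGATGTATTATTTGCGTACTCATTCAGTGTAGTGG
ATACGTTGC
>pat_ref_2_synthetic
ATGATTCGTATAGTGCTACCTATCGACCATGATAATATAGAGGTTACGACAAACGATGCC
CGAGAAATCCATACTGCATACTATCCCGGAGAGGCCTGTATGAATAGCTCTGACCCTGAA
ATTGGCGATTCGATCTTCGATATCATCAGCCATTGCCTAATGGTGTTTGAGACGCCCTTC
GGGTTGATATGGAAGTTTTTCAAACCGCCCATAGATGCACACTGGCGATGGCGGTGCATG
GCAGACGATTTAATGTACATGACTTCTTTAGGGAAACAAAAGAGTCGCGAAGGTATATCG
TGCGATGCCCCATGGAAACGCATCTGGCCTGGTACGTGGTTTTTTGTGATCGCGGGCAAG
GAGCAGGCATGGCCTCGGTCGGCTGAGTGTGAATATCACCATGAATGCGAGTGGTACGGC
CACAGTCACCGTCCATGTTGTTTCGTCACCGGGACTATGGAAAAACAATCTCTATTTATG
TGCGGAACCCAAAATACGGCCAAGTTTAAGAATGTGATGCGGCAGCACCACATTTGGTTT
AACGGAATTATGATCATGAGGCCAGACGAGGACATCGCGTTTATGATTCACTTTCCCTGC
CACATGTGGGTAATTCTACGGGACACTGTACAGGGGCGATTAATGTGTTGGATGAATTGG
ACACGGAGCAAGCCCTGTCTTCTACATGTTTTTGTATTTCAGCTGGAGGGATACTGTAGT
AGTAGAATTGAGCCACAGACAGCGTGCGGTGATATCTGGGGTGCTTGGCGCTGGCAATGT
TATGACTCCGTAGTGGCCTTTAGTTGGTACATGCAGTTCTTCGGGTGGAGGCGTCAAAAG
TGGAACGTTCCTTACCCTAGAACAGTTAAGCGGGTGTGGCCAGATGCAGAAGAGGGGGTT
GAGGTAATGTTTCTTCCGTGCTGCCAAGAGCCTGAGGGGGACATACCGCTGTCGGTTGAG
GATTGCTACTTCGTAATAGTATGGGCTTGTACCTTCCAAGGACGGCATTATTCAGCACCG
GGGTGCTGTATTTGCCATGCGTACTGCGATGAATATAGCATAATAATAATTATAGACGTT
TGTATCTTCTTCTACGACGCTGGTATTAAGTCTTTTGATTTTTGTACAATTTGTTACCTG
TACCAAACGACTGTTTCGGGACCTCATCAATCATGGTTCCTTGGGGATATGCAGCCAGAT
AAAGAGATTGGCGATCAAAGGAGTATGTGCGGTTTCGCGACGATGGAATCTCCGGTTTTG
GGGGAAAACGGCGGCATTGTCCAGAAAGTACAACGGTTACACATGATTTTATATGACCGT
ATTTTTTCCCATGTGCGAGAGGTGGCACAGTGGATGAGCGAAGTCATGCACACCAACAAT
CACTACACGCCTTTTTGCCCCACCGGACTCCAGATGTGTGCTTGTGACTGGGTGTCTGAG
AGAATCTCCAATGATCAACACCTCTGTTGGATTGACAAGAACGTCTTGGCGCGTAACCCG
GACCAGCTCCGCATGGGGTCCAACAACATGTATTACTTACAATTGTCTAGTCCGGGGTCG
CCCAATCGC
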