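>AfuSINE3-1a origin=5S_rRNA chr=1
TAGGCTCCAACCAAGCACATACGACCATAGGGTGTGGAAAACAGGGCTTCCCGTCCGCTC
AACCGTACTTAAGCCAGGTGTAGAATGTGGTCAATCCATAGAAAGCCCTTTTGCCTCCAA
AGCAGCGGCGGGATGCTTTTCGTATGAGTGCTGGTGATGTGGGTGAGAACTCCAGGGGGC
CCCATCACCCCTGGTGATGATGGCTCTAGGGGTTTGATGAAGGCTAACTTAACAGCTGAC
TGCAGAAGAAAACAGTGATTCAGCTGCTTTTAATAGGCTC
>AfuSINE3-3a origin=5S_rRNA chr=3
AGCTTGAAAACAAGCACATACGACCATAGGGTGTGGAAAACAGGGCTTCCCGTCCGCTCA
GCCGTACTTAAGCCACATGTATCAACGTGGTCGGAAGTTATATGCGCCCTTAATGGCCTG
CTGCTTTACGGGTGAGAGACGCTAAACCATAGGGTGAGTGTGGGTGAGTGAAGGTGAGCT
GAGTGATGCTATCCAACGCCATGGGTGAGCAAGGGTGATCAGTGGGTGACAGTGTGATTC
TATAATGACTAGACTCCGTCTATCGCTAGCTTAAA
>AfuSINE3-3c origin=5S_rRNA chr=3
ATTCAGTTATCTTTCTCCCAGCACATACGACCATAGGGTGTGGAAAACAGGGCTTCCCGT
CCGCTCAGCCGTACTTAAGCCACACGTAGAACGTGGTCAATCCCTAGAAAGCCTTTTTGC
TTCTAAAGCAGCGGCGTAATTCTTTTAGTATGAGTGCTGGTGATACGGGTGAGGACCCCG
TCACCCCTGGTGATGATGGCTTACTGGTGGTGACGAGGGCTCCAGGGGGGTGACGAAGGC
GTACTCAGAAGTCAACCACAGAAGATACAGTGATTGAGCTACTTTTAATGGGCTCTGCGC
CCCGCAGAAGTAATGCACTTGATTATTCCTGAGTCCATACAGT
>AfuSINE3-4a origin=5S_rRNA chr=4
CGTCAGATTGCACAATGACCATAGGGTGTGGAAAACAGGGCTTCCTGTCCGCTCAGCCGT
ATTCAAACCAGTATTATTAATTTGGTCGGAAGTTATATGCGTCCCTAAAGGCCTGCCGCT
CTACGGATGAGAGACACTGAACCATAGGGTGAGTGTGGTGAGTGAAGGTGAGCAGAACGA
TGCTATCTATTGAATTATTCACATCGGCGATCCGTAGAACAGGTTGGTCCCACGTCCTGG
ACACGCCCATACTCCGTCA
>AfuSINE3-5c origin=5S_rRNA chr=5
AGCTTCTATATGAATTTCTTGCACGAATATCCTAGCACATACGACCATAGGGTGTGGAAA
ACAGGGCCTCCTGGCTGCTCGGCCATACTTAAGCCAGTATTATTAATATAGTCAAAAGTT
ATATGCACCCTTAAAGGCCTGCTACTTTACAGATAAGAGATACTAAACCATAGGGTGAGT
ATAGGTGAGTAAAGGTGAGCTAAGTAATGCTATCTAACAGCATACTTGAGCATGGTGATT
AGTAGATAACAGAGTGATTCTATCATGACTAGACTCCTCTATCACTAGCTTCAATAT
>AfuSINE2-1a origin=tRNA/Arg chr=1
AAGTGTACATAGAGCCGGTAGCGGTAGCGTAGTGGTAAGCGCTCCGAGGCAGCCTCTAGA
GAAGTAGGATTGGTGACCCTGCTTTTTTGGAGGTTATGGGTTCGATTCCCGTCGCTGGCA
CAACATTTACCACCACAATGGAAGATCACTTCCCACAATGGTATCAAGGCCACTCCCTTA
TCGCAAGGTGGTGGGGAAGTTGGAACAATCACAGGCCTGTAAGGCGAGGCTCTAAATTCG
CCCTCATGTAATGGAACAAAATGTAACTAGACACACAAGGATTAGCTATAGTCGATACCT
GCATATCGCCCAAGGCGAGGGGTCAGCGTATGAGTACTACTACTACTACTACTACTAAGT
GTACATAGAG
>AfuSINE2-3a origin=tRNA/Ser chr=3
AGGGAGTTTGATATCCCATTTTGGAGGGACTGGCCGGCTCTGGGGTCGGTCGTTAAGGCG
CTCCGCCATTCATCTGCAGGTTGGATAACAGCCGGGCAATTTTCGTGACTGAAAATCCCA
TCCATCTGAAACTCTTGTGAGTATGTTGAAAGCCGACTTTTCAAGACGCCAATCTCAGGG
CCATCCGCAGCTGAAAGATAACTCTCGAAGCAATGCCGGCACTGTAGAAAGCAGCAACGG
AGAAGAGGCGATTGTTGGTGTCCGGCCAACTTGACATAACGATCGAATAGATCGAACATT
CGTTGCGAGGTTTCGACGGCCAGATCAATCATATCGGCACTGGGAGACCGACAGTGGCGG
ACAAGTGCGAGAATCACAAAGACGGCTGTTAGATGCAAGGTAAGAAGAGGCGGCGTAGTA
GAGTCGGACCTGGGATTTGAGTATTGTGCTAGAAGAATCGCCTGTTGTTCCTGGATCTGG
AGCAGGAGGGAGT
>AfuSINE2-4a origin=tRNA/Ser chr=4
ATGTACATCAGGTGTATGCGGCCTGGGCAGAAATATGATGGGTAGATATCAAGATATCGT
AAGTATTCCAGCTCCTCCACTGATTGACGATCCTTTTGTTATCTTGAGCCAAGGAATTTG
GTGCCTTTGGGCCTGAGGTTCCAGATCCTCCCCCACATCCGCGAACCTCATTTCGTGGTT
AAGGACAACATTAAATAACCGTGAATTTACTCCGTAGTGTCTCGACCCTTTGGGGGGTGA
TCTTGTAAAGATTAGGAAAGAATGAGAGAAATAAATCACAGATTTTTTTTTTTTTTTTTT
CGTAAGAAAGAAAAGGCAACTCCCTCGTCACAGCAGGATTTATGTACAT
>AfuSINE2-7a origin=tRNA/Gly chr=7
TCAAAACGCTGGAACTGGGTTTATTTCCATTTGGCGGAATGGAAAGGTTCGAAACAGCCC
TGGAGGTGTTCGAATAGTAGAGTATGGTCAGCTTCGCTTCCTGCTCGTGTGACTATGATG
TAAAGATGTTGGGTTATTTTATTTCAATCAATCAGTGGGCCGCATTCTATTCTTACAAGT
CCCTTCAATGGCAATCATGGATATCAGATGGAGAGATTTGCGATGCTTCTGTGTCTCTAA
TAATAAGCAGTCTTCAGATGAGTGGAGGCGGCAGAGAAGGGGAGCAATGGGGACCAATGG
GGAGCAATGGGGAGTAATAAGGAGCAACAAGGATGAAGAGGATTGGTGTGACGACCCCTG
CATACAACACTTGTAGGAAACGACATCTTATCAATCTCAAA
>AfuSINE2-5d origin=tRNA/Ser chr=5
TTTTTAGTTGCTACGTAGGCTTAATGGAAGGAACATGTTCGAGGATGGTCGGAAAATCGC
TGGAGGTGTTCAATCCCCGAGGTACGTCATCTGGAACTGAATCAAACCTCTCCACTCGAG
GGAGAGCTGAGAGTATTAGGTGGTTTTCGTACTTATATCCAAGGCTCATTATCACGAATG
CCGTACAAACAAACACAATCGAGATACTCCATACTTGAATTATTTTCAGT
>AfuSINE2-3c origin=tRNA/Ala chr=3
TGTGATGCCTTTCCACACTGCATGGTTGTCTCGGCACAGATGGCAAAGCCGTTCCTGGCA
ACAGTTAATTGTTCAGTTCAAATCTGTTAAAACGGGGTCGTACTTACCATAGACTGTCGT
CGAGCATCTGCCGCAGCTCTAGCCAAAAGACCCAGTGATTTCTGCCTATGAATGACAGGT
CAGCTTTGTGGGGGCTTTGCA
>AfuSINE2-4c origin=tRNA/Thr chr=4
CTTGGAGATTACATACGTATCCTGCAATGGGCAGAATCAACAACGTGTACATTTTACGCG
TAAATGGATCGATTCCATATGTACCACTCTCTAAGCCAACGCAACCATGAAAGGGTGAGA
AGACCCTGACGGCCACCGAAACACTTACCAACCAGTTCTTGGTTGTGAACATAGTATGGA
TAATTTGGTAGCTATAGTTGATTTGAATAATGGTGCTGTCGCACCTCGCAATGTCTTTTT
AGCATCTTGGAGA
>AfuSINE2-7e origin=tRNA/Met chr=7
AATTACTTATATAGCAGAGTGGTAGAGTCATAGGCTTCATATTTTTACAGCAATGGAGAT
GAGATAAGGATTCGATTTCTATATATTTTAGTACTAGATAATATTAACTTTAAGGGAAGC
TATAGGATTTTCCCCTAATT
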