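>trnA
ACAGTTCGACTCAGATTCTGTTCTTACCAATCTTACAGTATCATTGCGTATAGAACGTAATTTAG
>trnC
TGTATCAAATCTTATAATAGCACATGCAAAGTATTTTTCCGTCATTGAATCATCTCTCTTCATAAATATCC
>trnD
ACTAACTTTGCAGTTAATGTTCTTGCAACACATATATACGCTTTATCTCAAAAATGTTGATTAACT
>trnE
ATACCAGACAGAATACGTTTTTATGTCCCAAGACTATATTTGGAGTTATTTTACTCTATGCACAGAACA
>trnF
CAGAGTCCCACTTTATATAACTAGACAGGGATATACAAAAGATGTAATTTATAATGTCGCTGCGTAATTGT
>trnG
TAGAATGTGGACCAATAAGTTGCAAAACCGTCGATTATGAAGTTTCTGCATTTACAAAATATGTAAAAAG
>trnH
GTTTTAGAACCCTGTACAGAATAATGGAGAAAAAAACCCTGAGTATCCCTTGATATGAATTTGATAGC
>trnI
TATATTTGCCGGAATAGAAATATTAAATCTGGTCTATTTATAACAGCGTGTTTTAATTTTATTGGCTAA
>trnK
TCTTAAATACTCCAGACGCTATGGTCCAATTAAGGTCTAGCAACAATAGTACTACAGTTTCAGTT
>trnL1
TTTAGACAAAATTGTTGATCACCAAATTATTTATAATTACTAGATGAGTCCTATATACATCATGAAGAGC
>trnL2
AGGTATACCGAGTATTGTGAAATTATGCGTGTGACAAGTACTAAAAGGCTATTTTGTGTTTTTAGTGTCG
>trnM
AAGAAGTATTATTACGTTTACTATTGGTCTTAATGTGTAAATAACAGTCCCGTTAGCACAATAAAATT
>trnN
TTTAAGATAAATTTTGTTATGACTATATATCACATATACAAACCTAGTATGATTAATTGACAGCACA
>trnP
TGGCAATGAGATGACCTTTAAATACACGACTTAAGACAACTAGGAAGGCCCCATTTTAAAAAGCTGTGAAT
>trnQ
CTTAAAGACAGATACTGATGAAATTATCTGATCAATTTATAAAAAGACTATTTATCAATTTCGCATTTG
>trnR
GTAGAATTTTTTATGAAAAATTTTAAGATATGCCAAAGTGCGACATATCTTTAGATACCTAACTC
>trnS1
ACGAATGGCTATACCTTCATGGTATATTGTCTCTTAATCTGATCTGTAATGATATGCTTATAATGCGC
>trnS2
CGCTTGATTTGTAGTTGTCACTCTTTTTATATTGTTTTATATTTAGGTCTCTATTCTAACGTTATATT
>trnT
TAATTTTATGAATTTTTATCACATGCTTAAGTCTATAGTGGTGGTTGATTATCATATTGCTTAATTTTCAAG
>trnV
AAATCTATATCGAGTTAATCTTAATGATTTTAGATTTTTTCAAATTCTATTACTAATCTTATGGATTAACT
>trnW
GAAGTGAATTTATTCGTTCCTGCATGAAAAACTAAAAAAATATATAAAATTTCTTTAATGCTGGT
>trnY
GCGGTTTTATAATTAAATAAAAACAAAAGTTCTTTTTAGGCTACCTTACTTTGACAAGTCTTCCGTT
>rrnS
TGATTTAAAACCTACAAGAGTACTATATGACTATCCTATCTAATTCATCAAGTTATAAATTTAGTCAGAA
CATACTAATATCAGGTCTGAATAACATTGCAACATATAGAGAATCTAACGTTAAATTAAACCTATATTGC
AAGCTATCAAAACATAATCATAATAATTAGTAATTATACCACCAAATTAAAACAACAGAGCAGGTTTCGT
TGATCAGTTGAACTACAGCATACTAACAGGTGCACCAATATTATCTGAATAATATTACTAAAATTAGCTT
TATACTTTGAACTATCCCTTAGAATAACTGAATAAAGTTAGTAGACATTATTCATTGATTCAGTGTATTG
TATAAATGTCCTAAATATGTAAAGATGAATCTAAATCAGAAAGGCTTCTAAACTAGATCTACGATTAATC
CCGCAAGGATTCGTTTAATAAAGAAAGACAGATATGATATGAATAACACTGGTAGAAATACAGAAATCTA
AATAACAAATTTAACAGCTTAGTTAGACACAATACTAAGATATGTTATACCGTCGGATACGTTTAAATGA
ATCTCGTTAAAGGAAGTTTTACTTTACTACCAGTATTCATACTTTAGGTATAGCTTTTTGCATAGAACTA
GCGCCATAGATTAAGCTACAAAATATACTCCACCTCTCATATCGAATTGACAAAGCAGACAAAATTACAT
AGGGATTTTAACTTCATATA
>rrnL
AAGATTTTGTCCCTTGGTATTGTTATTATAAAATCTCTATAGATATTAATTGCAATTTATTTCATTTTCG
AACTAAGTTTGATCAGGGTAGTATTACTACTACATTATTAAAGATGCTGCGTTAAATCACGTAAATTCAA
CGGACTACTTGGTACATCCGCAATATGGTAATAGGCTAATTTTAAACGATAGTCCTGTTGACTGAAAGTT
ATAGTTAGCCGATAATAATAATGTTTTCAGTAATTAGGTGCTACGTTCTCGTCGTATAATAAATTTTTAA
ATATAAGGCGTAAGAGAGAAAGACATTATCGACTTAACGGGCTTCTCTTAAATCGTGTCTATACTACGCC
TTATTGTTTTAATTATGATTTAATATCTAGAAATAGACTATAGTAATTAAGGTATAGAAGATTATTTTTG
CTTGATCAAACAGTCATTCTTACACAATAATACTTTTTTTCAAGTCTGTATATTATAATACTTCGTACTT
ATATAACAAATATATTGATTTAGTTCGACTTATTATAGAATACGACGGTAAAACCATAGCTTGGTTGGTA
ACAATATATAAGACTGCGTTAGTAAAATACTGTAAAAAATAAGTATAAAAGAAAACCCATCTCATAGATA
GTTTAATAATTGTCTAATATATATTATCACTCACAACAATCACCGAATTTTTGAGTAATCAATTTTGTAT
TACAGCACAATATAATTCTAAAAGTTGTGTAGAGGCTTCAACATCGAGAAAAAAGTAAGCTGGTAGTGGT
ACTGCCCTTATAGAATGAGTTATACGCATCTTCTATATGGAAAACACAGGTATGTAGTTAAATGGTTTGC
GAAGGGCATCGAATCTTATCTTTTAATATATAAAATTATAGAGAGTAATTTACTGTTAAATTTTAATTAT
TTCTGAACATAATCGACGAGGATGGATATATGATTGCACGTAAAAAAGACAGATATTACAATAATGTTAT
CTGAAAAAGACCAGCTTCTAATACTAAAAAAGAGAATAAAAGATCAGTCAGCATTATCAAATACTTACAA
CCGTTATATTAAGAATTAATACATATATTTATTAATGAATCCCGACCTTA
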