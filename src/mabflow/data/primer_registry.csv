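name,pcr_stage,chain,direction,allele_keys,sequence
PCR1_H_mix_F,PCR1,Heavy,forward,,ATTTGCTGCTTAGTGGACGCGA
PCR1_H_mix_R,PCR1,Heavy,reverse,,GGATCTATGGCAGCCGTATGCG
PCR1_K_mix_F,PCR1,Kappa,forward,,AGGTAACCTTTCGATCCGTTTT
PCR1_K_mix_R,PCR1,Kappa,reverse,,CCAGTTGGCCTGCCTCTGTAGT
PCR1_L_mix_F,PCR1,Lambda,forward,,CATGGTGTAAAGTCAAATACTG
PCR1_L_mix_R,PCR1,Lambda,reverse,,GGCCTATATCGAGGCTAACCTG
PCR2_H_mix_F,PCR2,Heavy,forward,,GAGGACTCGAACACACTGGCGT
PCR2_H_mix_R,PCR2,Heavy,reverse,,CGACCTCTCGGTAGGTGTGCTT
PCR2_K_mix_F,PCR2,Kappa,forward,,GTGGACGCCCAGCTCATTCTCT
PCR2_K_mix_R,PCR2,Kappa,reverse,,AATGGGCGATGCAGTGACACCA
PCR2_L_mix_F,PCR2,Lambda,forward,,GTGAATCTTTAGAATCGATCCC
PCR2_L_mix_R,PCR2,Lambda,reverse,,TTGCTGGGTTGGGCATAGTGTT
P3_HV1-2_F,PCR3,Heavy,forward,IGHV1-2,TCGCGCTACCGGCTGTCGAAAT
P3_HV1-8_F,PCR3,Heavy,forward,IGHV1-8,AAGTGAATGACGGCTGGGAGCT
P3_HV1-18_F,PCR3,Heavy,forward,IGHV1-18,ATCTCCGCCCTATCACTCCAGG
P3_HV1-24_F,PCR3,Heavy,forward,IGHV1-24,TGGTCGATCCGAGAGTCTCCCG
P3_HV1-46_F,PCR3,Heavy,forward,IGHV1-46,TTATTGTGCGGTTAACAAGCGG
P3_HV1-69_F,PCR3,Heavy,forward,IGHV1-69,AAGCTGAATGAGGAGCTTAATG
P3_HV2-5_F,PCR3,Heavy,forward,IGHV2-5,CTCGACTGTCTCCACGGTCGTA
P3_HV2-26_F,PCR3,Heavy,forward,IGHV2-26,TAAGACACGGAGCTTTAGACGT
P3_HV3-7_F,PCR3,Heavy,forward,IGHV3-7,TTGGATTGAACTTAGGGCGCGA
P3_HV3-9_F,PCR3,Heavy,forward,IGHV3-9,TCGCATTGACATAGCAAGGATG
P3_HV3-11_F,PCR3,Heavy,forward,IGHV3-11,AACTAATGGGCCAGGCTTAGCT
P3_HV3-15_F,PCR3,Heavy,forward,IGHV3-15,AACACGCAAGATTTTCACAAAT
P3_HV3-21_F,PCR3,Heavy,forward,IGHV3-21,TTGAGTCGCGCCGAATATCCTG
P3_HV3-23_F,PCR3,Heavy,forward,IGHV3-23,CGTAGCGGTGCAATGCGGATTC
P3_HV3-30_F,PCR3,Heavy,forward,IGHV3-30,GCTCTGACTTCGGTATTTGTTC
P3_HV3-33_F,PCR3,Heavy,forward,IGHV3-33,TTGATAGCGTACGAAAGAAATC
P3_HV3-48_F,PCR3,Heavy,forward,IGHV3-48,TTGCCGGGCATGGAGAGCCCCG
P3_HV3-53_F,PCR3,Heavy,forward,IGHV3-53,CCTAGTACGCGTAGCGATCCCC
P3_HV4-4_F,PCR3,Heavy,forward,IGHV4-4,CTGTGCAGCAGTACATGATACT
P3_HV4-34_F,PCR3,Heavy,forward,IGHV4-34,TGTGAGGAATAACGACGCGATA
P3_HV4-39_F,PCR3,Heavy,forward,IGHV4-39,CCAGTGGGGGTCGACCTCATGG
P3_HV4-59_F,PCR3,Heavy,forward,IGHV4-59,AGCGGTAGGAACGTGACTTCCG
P3_IGHJ1_R,PCR3,Heavy,reverse,IGHJ1,AACAAATGACAGCCGCATTGCA
P3_IGHJ2_R,PCR3,Heavy,reverse,IGHJ2,CGTTGTAGGGCTTCCCATCCTC
P3_IGHJ3_R,PCR3,Heavy,reverse,IGHJ3,AGCCCAGCGGGGCTAGTTGAAT
P3_IGHJ4_R,PCR3,Heavy,reverse,IGHJ4,ATATCCCTATCACCACACCGTT
P3_IGHJ5_R,PCR3,Heavy,reverse,IGHJ5,AAACAGAAGCTCTGTTACGTTC
P3_IGHJ6_R,PCR3,Heavy,reverse,IGHJ6,CCGGCATATATGTGTTGAATAT
P3_KV1-5_F,PCR3,Kappa,forward,IGKV1-5,ACCAAAGACTTCTTGGAGTGAT
P3_KV1-9_F,PCR3,Kappa,forward,IGKV1-9,ACGTGAACTTAGGCTAAGTGGA
P3_KV1-12_F,PCR3,Kappa,forward,IGKV1-12,GACGGGAGGTTGGTAAGCTCCT
P3_KV1-16_F,PCR3,Kappa,forward,IGKV1-16,GCGGCATGTATAGTAACGCTGA
P3_KV1-27_F,PCR3,Kappa,forward,IGKV1-27,TTGCGAAATAACAGGTTTTGAA
P3_KV1-33_F,PCR3,Kappa,forward,IGKV1-33,GATTACGAGCGGGGACATTCCA
P3_KV1-39_F,PCR3,Kappa,forward,IGKV1-39,CCGATAGTATTACTACCAAGTT
P3_KV2-28_F,PCR3,Kappa,forward,IGKV2-28,ATCTCGACAATGAGGATAGAAG
P3_KV2-30_F,PCR3,Kappa,forward,IGKV2-30,GGTGTAAAGTCCCTCCCCTCCC
P3_KV3-11_F,PCR3,Kappa,forward,IGKV3-11,GGCTCCGCTAAGACTATTGAGC
P3_KV3-15_F,PCR3,Kappa,forward,IGKV3-15,TCCAATATCTCCTAGTATAACT
P3_KV3-20_F,PCR3,Kappa,forward,IGKV3-20,CACCTACTGCTGTCGGCGCGGA
P3_KV4-1_F,PCR3,Kappa,forward,IGKV4-1,CGAGTGTGACTACAGTCCACCA
P3_KV5-2_F,PCR3,Kappa,forward,IGKV5-2,CTACTTCGTAATGTAAGACGAC
P3_KV6-21_F,PCR3,Kappa,forward,IGKV6-21,GTCGCATTCGTTTGGGAACTAA
P3_IGKJ1_R,PCR3,Kappa,reverse,IGKJ1,GCGCGTCTCGAAGCAGAATGCA
P3_IGKJ2_R,PCR3,Kappa,reverse,IGKJ2,TACAGCGTGTCTGACTAATCGG
P3_IGKJ3_R,PCR3,Kappa,reverse,IGKJ3,AGCAGAGGCTTTAGTCGGTTTC
P3_IGKJ4_R,PCR3,Kappa,reverse,IGKJ4,CCGGTCGACAGAGAGAAATACG
P3_IGKJ5_R,PCR3,Kappa,reverse,IGKJ5,TGTATCAATGAAGAGGCGACCG
P3_LV1-40_F,PCR3,Lambda,forward,IGLV1-40,TGCATGAATCAAAGGAATTTAC
P3_LV1-44_F,PCR3,Lambda,forward,IGLV1-44,CGCGATGTATTTCATTGTGGCC
P3_LV1-47_F,PCR3,Lambda,forward,IGLV1-47,ATCATTCTATTATTACGCACGA
P3_LV1-51_F,PCR3,Lambda,forward,IGLV1-51,TCGGATATCCCCAGACAGCAGG
P3_LV2-8_F,PCR3,Lambda,forward,IGLV2-8,CCACCGGTCATTGAGGGATGTG
P3_LV2-11_F,PCR3,Lambda,forward,IGLV2-11,ATAGTGCATTGGATCTACGGGA
P3_LV2-14_F,PCR3,Lambda,forward,IGLV2-14,CCTCGCGGCCCGGACATCTTGC
P3_LV2-23_F,PCR3,Lambda,forward,IGLV2-23,GACTGATCTTTCACGGGATATT
P3_LV3-1_F,PCR3,Lambda,forward,IGLV3-1,AGTCCTAAACGACGGACATACG
P3_LV3-19_F,PCR3,Lambda,forward,IGLV3-19,AGTGTCCACCGGTACGACGCGG
P3_LV3-21_F,PCR3,Lambda,forward,IGLV3-21,AGGTGCCAATCATACGTACAGT
P3_LV3-25_F,PCR3,Lambda,forward,IGLV3-25,TCACTACTGTCGCCGGGATTTA
P3_LV4-69_F,PCR3,Lambda,forward,IGLV4-69,CTCCGGAGGTTTCTTTTCGTTT
P3_LV6-57_F,PCR3,Lambda,forward,IGLV6-57,CAGGTCGAAATAGGAAGGATCT
P3_IGLJ1_R,PCR3,Lambda,reverse,IGLJ1,GTCGGGGAGCCAGCGTCCTAGT
P3_IGLJ2_R,PCR3,Lambda,reverse,IGLJ2,TCATGTACTTATCTTTACCTAC
P3_IGLJ3_R,PCR3,Lambda,reverse,IGLJ3,AGCAATCACGAAGAAAAACAAC
P3_IGLJ4_R,PCR3,Lambda,reverse,IGLJ4,TGGCAATTAAAGAAGGCACCAT
P3_IGLJ5_R,PCR3,Lambda,reverse,IGLJ5,CTTGGCTGGGACTGCATTTCTG
P3_IGLJ6_R,PCR3,Lambda,reverse,IGLJ6,AGGTCCCTATAGTCAGCGTGTG
P3_IGLJ7_R,PCR3,Lambda,reverse,IGLJ7,GTTTGCCTAAGACTTGCTGACA
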