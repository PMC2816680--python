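sequence	delta_g
ACGUUGUAUACGACGGCGGCGCAGGGGAUU	-5.50
UCGCUUCUGCCCUAAAAACUCUGGUAACCU	-1.50
CAUCCCCAGCAUGGGAUCACCCUGCAAACG	-7.60
UCCUGGUAACUAGGACCCCCCGGCGUUAUG	-5.50
AGCAAUCCGCCUCUCUACAUAAUUCAGACA	-0.20
GCGGUCAUCCUCAAGCCCGAUGCCCGAAAC	-6.80
CGGAAGUCUGGACAGCGAGAAUUGUAGGCU	-3.80
CGGUGUCGAACUCUGCUGUUCAACAAUUGA	-5.90
ACGAUAUCAGGUCCACGCAGUCCCUCCUUU	-0.50
ACUGGCGUGGAGUAAAUGCCACCCUCGCAG	-7.40
ACGACGGAUCACCUUUUGACGAUCGCGGAG	-6.00
GCAGGCUCAGAGGUCAUCUGCCUGCGCAUG	-12.70
AAAAAAAAAAAAAAAAAAAAAAAAAAAAAA	0.00
GGGGGGAAAAACCCCCC	-11.90
GCGCGCGCAAAAGCGCGCGC	-16.70
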