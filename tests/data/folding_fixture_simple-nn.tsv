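sequence	delta_g
ACGUUGUAUACGACGGCGGCGCAGGGGAUU	-7.00
UCGCUUCUGCCCUAAAAACUCUGGUAACCU	-1.80
CAUCCCCAGCAUGGGAUCACCCUGCAAACG	-6.40
UCCUGGUAACUAGGACCCCCCGGCGUUAUG	-6.10
AGCAAUCCGCCUCUCUACAUAAUUCAGACA	-0.80
GCGGUCAUCCUCAAGCCCGAUGCCCGAAAC	-5.50
CGGAAGUCUGGACAGCGAGAAUUGUAGGCU	-7.50
CGGUGUCGAACUCUGCUGUUCAACAAUUGA	-4.40
ACGAUAUCAGGUCCACGCAGUCCCUCCUUU	-2.10
ACUGGCGUGGAGUAAAUGCCACCCUCGCAG	-7.70
ACGACGGAUCACCUUUUGACGAUCGCGGAG	-3.30
GCAGGCUCAGAGGUCAUCUGCCUGCGCAUG	-12.30
AAAAAAAAAAAAAAAAAAAAAAAAAAAAAA	0.00
GGGGGGAAAAACCCCCC	-13.10
GCGCGCGCAAAAGCGCGCGC	-20.40
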