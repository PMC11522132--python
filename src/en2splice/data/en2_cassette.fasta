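>En2_splice_acceptor_full length=158
gtcccaggtcccgaaaaccaaagaagaagaaccctaacaaagaggacaagcggcctcgca
cagccttcactgctgagcagctccagaggctcaaggctgagtttcagaccaacaggtacc
tgacagagcagcggcgccagagtctggcacaggagctc
>En2_retained_insert length=115 note=prefix ending at the ag of the cryptic aggt donor
gtcccaggtcccgaaaaccaaagaagaagaaccctaacaaagaggacaagcggcctcgca
cagccttcactgctgagcagctccagaggctcaaggctgagtttcagaccaacag
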