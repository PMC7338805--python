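# aligned canonical splice-site examples used to estimate the default PWM
# donor: exon -3..-1 | intron +1..+6 ; acceptor: intron -20..-1 | exon +1..+3
CGTTTTCTAACATTCCGCAGTTT
CCTCTTTGTGTATGCCTCAGGAT
TTTTTCAAGTTATGTCCCAGTTA
TCTATTTGCCTATCTTCCAGGCC
ATCGCTTTCGAGTTTCTCAGGTT
ACGTCACTTACTGTATATAGAAC
TCCTTCCCAACGACGTATAGAGA
TTCTAGTCTTTTTTCGCGAGGTA
CCCACTCCCTCCACTTTTAGAAG
TATTTTATTCTTTTTTGCAGTCC
TTTCTATCGATGTTCTAAAGGGT
GTTTCTTCCCCTCTCAAAAGGTT
GCTCGTTATTCCCCTTATAGCGT
TTTCTTTCCTTCTCTCTCAGGAC
TCGCCCGCTCTTCACCCCAGGAA
TTTCTCATCTCTATGTCCAGAGC
CCCGGCTCACCTTGTCACAGCAA
TAGACCAGCTTCGATTCTAGCCG
CACTGACTTGCTTCGATCAGTCA
CTTCCTTTATCTCCTACCAGGAA
TGCGTTGTCCATGTTCTCAGACC
ACATATCACTGTTTCCCTAGAGG
CTATTGGTTTTCCTTCCTAGGAT
TTTTTTTTTCTCCCAGGCAGGGG
TTCTCGTTCCTCCATCTCAGGTG
TTATCCCCTTTTCACCCCAGACA
TTTCTCTTTTATCCCTACAGGAG
CGATACCTTTGCTTATACAGGAG
GCTTATCTTCACTTCCCCAGCTG
CTTCTTCCTCTCTTAGTCAGGCC
CACATCTTTTTTCTTATTAGGGC
ATCCCATAGTGTACTTGCAGACT
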