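# aligned canonical splice-site examples used to estimate the default PWM
# donor: exon -3..-1 | intron +1..+6 ; acceptor: intron -20..-1 | exon +1..+3
GAGGTACGG
GTGGTTAGG
CAAGTGTGT
CAGGTGTTC
AGGGTAAGT
GAGGTGAAC
CAGGTGAGT
TAGGTACGG
CTGGTAAGC
AAGGTGACA
CAGGTAGGG
AAGGTAAGT
CAGGTGAGG
ACGGTATGA
AATGTCAGT
AGAGTAAGG
CGGGTATGT
AAGGTGAGT
CAGGTAAGT
TCGGTAAGA
GCGGTAGAT
ACTGTAAGT
CAGGTAAGC
TAGGTAAGT
GTGGTGAGA
GAGGTAAGT
CACGTAAGT
CTGGTGAGC
AGGGTGGGG
ATGGTAAGT
AAAGTAATA
CAGGTGAGT
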