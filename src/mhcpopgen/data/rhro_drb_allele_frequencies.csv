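# Published DRB allele frequencies for three golden snub-nosed monkey
# populations (Foping FP, Ningshan NS, Zhouzhi ZZ) at the two co-amplified
# DRB loci, with the number of genotyped individuals per population x locus.
population,locus,allele,frequency,n_individuals
FP,DRB1,Rhro-DRB*03,0.625,32
FP,DRB1,Rhro-DRB*06,0.031,32
FP,DRB1,Rhro-DRB*09,0.031,32
FP,DRB1,Rhro-DRB*14,0.125,32
FP,DRB1,Rhro-DRB*17,0.125,32
FP,DRB1,Rhro-DRB*41,0.063,32
NS,DRB1,Rhro-DRB*02,0.042,36
NS,DRB1,Rhro-DRB*03,0.583,36
NS,DRB1,Rhro-DRB*06,0.083,36
NS,DRB1,Rhro-DRB*09,0.083,36
NS,DRB1,Rhro-DRB*14,0.083,36
NS,DRB1,Rhro-DRB*17,0.083,36
NS,DRB1,Rhro-DRB*23,0.042,36
ZZ,DRB1,Rhro-DRB*02,0.074,54
ZZ,DRB1,Rhro-DRB*03,0.370,54
ZZ,DRB1,Rhro-DRB*09,0.213,54
ZZ,DRB1,Rhro-DRB*14,0.259,54
ZZ,DRB1,Rhro-DRB*17,0.046,54
ZZ,DRB1,Rhro-DRB*38,0.019,54
ZZ,DRB1,Rhro-DRB*39,0.009,54
ZZ,DRB1,Rhro-DRB*42,0.009,54
FP,DRB2,Rhro-DRB*04,0.667,30
FP,DRB2,Rhro-DRB*05,0.067,30
FP,DRB2,Rhro-DRB*08,0.133,30
FP,DRB2,Rhro-DRB*16,0.133,30
NS,DRB2,Rhro-DRB*04,0.583,36
NS,DRB2,Rhro-DRB*05,0.125,36
NS,DRB2,Rhro-DRB*08,0.042,36
NS,DRB2,Rhro-DRB*16,0.125,36
NS,DRB2,Rhro-DRB*18,0.083,36
NS,DRB2,Rhro-DRB*26,0.042,36
ZZ,DRB2,Rhro-DRB*04,0.519,53
ZZ,DRB2,Rhro-DRB*05,0.075,53
ZZ,DRB2,Rhro-DRB*07,0.038,53
ZZ,DRB2,Rhro-DRB*08,0.292,53
ZZ,DRB2,Rhro-DRB*16,0.066,53
ZZ,DRB2,Rhro-DRB*40,0.009,53
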