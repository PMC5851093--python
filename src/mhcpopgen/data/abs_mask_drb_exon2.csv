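# Default antigen-binding-site (ABS) mask for the 81-codon DRB exon-2 core.
# Codon index is 1-based over the in-frame alignment; alignment codon i
# corresponds to DR beta-chain residue i+5 (codon 1 = residue 6). The 18 ABS
# codons are the human DR beta peptide-contact residues 9, 11, 13, 28, 30,
# 32, 37, 38, 47, 56, 57, 60, 61, 67, 70, 71, 74, 78.
codon_index,class,beta_residue
1,non-ABS,6
2,non-ABS,7
3,non-ABS,8
4,ABS,9
5,non-ABS,10
6,ABS,11
7,non-ABS,12
8,ABS,13
9,non-ABS,14
10,non-ABS,15
11,non-ABS,16
12,non-ABS,17
13,non-ABS,18
14,non-ABS,19
15,non-ABS,20
16,non-ABS,21
17,non-ABS,22
18,non-ABS,23
19,non-ABS,24
20,non-ABS,25
21,non-ABS,26
22,non-ABS,27
23,ABS,28
24,non-ABS,29
25,ABS,30
26,non-ABS,31
27,ABS,32
28,non-ABS,33
29,non-ABS,34
30,non-ABS,35
31,non-ABS,36
32,ABS,37
33,ABS,38
34,non-ABS,39
35,non-ABS,40
36,non-ABS,41
37,non-ABS,42
38,non-ABS,43
39,non-ABS,44
40,non-ABS,45
41,non-ABS,46
42,ABS,47
43,non-ABS,48
44,non-ABS,49
45,non-ABS,50
46,non-ABS,51
47,non-ABS,52
48,non-ABS,53
49,non-ABS,54
50,non-ABS,55
51,ABS,56
52,ABS,57
53,non-ABS,58
54,non-ABS,59
55,ABS,60
56,ABS,61
57,non-ABS,62
58,non-ABS,63
59,non-ABS,64
60,non-ABS,65
61,non-ABS,66
62,ABS,67
63,non-ABS,68
64,non-ABS,69
65,ABS,70
66,ABS,71
67,non-ABS,72
68,non-ABS,73
69,ABS,74
70,non-ABS,75
71,non-ABS,76
72,non-ABS,77
73,ABS,78
74,non-ABS,79
75,non-ABS,80
76,non-ABS,81
77,non-ABS,82
78,non-ABS,83
79,non-ABS,84
80,non-ABS,85
81,non-ABS,86
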