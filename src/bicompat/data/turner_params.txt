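# Nearest-neighbor loop energy parameters (kcal/mol, 37 C)
# Grammar: '[section]' headers; '#' comments; whitespace-separated columns.
# Pairs are written 5'-to-3': 'XY' is the pair (X_i, Y_j) with i < j.

[constants]
kt 0.61633
param_version 1
ml_closing 3.4
ml_branch 0.4
ml_unpaired 0.1
interior_asymmetry 0.6
interior_asymmetry_max 3.0
long_loop_coef 1.07858   # 1.75*kt, ln-extrapolation beyond size 30

[stack]
# outer_pair inner_pair dG : pair (i,j) stacked over (i+1, j-1)
AU AU -0.93
AU CG -2.24
AU GC -2.08
AU GU -0.55
AU UA -1.10
AU UG -1.36
CG AU -2.11
CG CG -3.26
CG GC -2.36
CG GU -1.41
CG UA -2.08
CG UG -2.11
GC AU -2.35
GC CG -3.42
GC GC -3.26
GC GU -1.53
GC UA -2.24
GC UG -2.51
GU AU -1.27
GU CG -2.51
GU GC -2.11
GU GU -0.50
GU UA -1.36
GU UG 1.29
UA AU -1.33
UA CG -2.35
UA GC -2.11
UA GU -1.00
UA UA -0.93
UA UG -1.27
UG AU -1.00
UG CG -1.53
UG GC -1.41
UG GU 0.30
UG UA -0.55
UG UG -0.50

[hairpin_initiation]
# size dG (sizes 0-2 are formally closed hairpins, heavily penalized)
0 50.00
1 50.00
2 50.00
3 5.40
4 5.60
5 5.70
6 5.40
7 6.00
8 5.50
9 6.40
10 6.50
11 6.60
12 6.70
13 6.80
14 6.90
15 7.00
16 7.10
17 7.10
18 7.20
19 7.20
20 7.30
21 7.30
22 7.40
23 7.40
24 7.50
25 7.50
26 7.50
27 7.60
28 7.60
29 7.70
30 7.70

[bulge_initiation]
1 3.80
2 2.80
3 3.20
4 3.60
5 4.00
6 4.40
7 4.60
8 4.70
9 4.80
10 4.90
11 5.00
12 5.10
13 5.20
14 5.30
15 5.40
16 5.40
17 5.50
18 5.50
19 5.60
20 5.70
21 5.70
22 5.80
23 5.80
24 5.80
25 5.90
26 5.90
27 6.00
28 6.00
29 6.00
30 6.10

[interior_initiation]
2 1.50
3 1.60
4 1.70
5 1.80
6 2.00
7 2.20
8 2.30
9 2.40
10 2.50
11 2.60
12 2.70
13 2.80
14 2.90
15 2.90
16 3.00
17 3.10
18 3.10
19 3.20
20 3.30
21 3.30
22 3.40
23 3.40
24 3.50
25 3.50
26 3.60
27 3.60
28 3.70
29 3.70
30 3.70

[terminal_mismatch]
# closing_pair x y dG : x, y are the unpaired neighbors 5' and 3' of the pair
AU A A -0.70
AU A C -0.70
AU A G -1.20
AU A U -0.70
AU C A -0.70
AU C C -0.70
AU C G -0.70
AU C U -0.70
AU G A -1.20
AU G C -0.70
AU G G -1.00
AU G U -0.70
AU U A -0.70
AU U C -0.70
AU U G -0.70
AU U U -1.10
CG A A -1.10
CG A C -1.10
CG A G -1.60
CG A U -1.10
CG C A -1.10
CG C C -1.10
CG C G -1.10
CG C U -1.10
CG G A -1.60
CG G C -1.10
CG G G -1.40
CG G U -1.10
CG U A -1.10
CG U C -1.10
CG U G -1.10
CG U U -1.50
GC A A -1.20
GC A C -1.20
GC A G -1.70
GC A U -1.20
GC C A -1.20
GC C C -1.20
GC C G -1.20
GC C U -1.20
GC G A -1.70
GC G C -1.20
GC G G -1.50
GC G U -1.20
GC U A -1.20
GC U C -1.20
GC U G -1.20
GC U U -1.60
GU A A -0.50
GU A C -0.50
GU A G -1.00
GU A U -0.50
GU C A -0.50
GU C C -0.50
GU C G -0.50
GU C U -0.50
GU G A -1.00
GU G C -0.50
GU G G -0.80
GU G U -0.50
GU U A -0.50
GU U C -0.50
GU U G -0.50
GU U U -0.90
UA A A -0.80
UA A C -0.80
UA A G -1.30
UA A U -0.80
UA C A -0.80
UA C C -0.80
UA C G -0.80
UA C U -0.80
UA G A -1.30
UA G C -0.80
UA G G -1.10
UA G U -0.80
UA U A -0.80
UA U C -0.80
UA U G -0.80
UA U U -1.20
UG A A -0.60
UG A C -0.60
UG A G -1.10
UG A U -0.60
UG C A -0.60
UG C C -0.60
UG C G -0.60
UG C U -0.60
UG G A -1.10
UG G C -0.60
UG G G -0.90
UG G U -0.60
UG U A -0.60
UG U C -0.60
UG U G -0.60
UG U U -1.00
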