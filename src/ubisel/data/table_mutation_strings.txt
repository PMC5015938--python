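# Every mutation string appearing in the published per-round summary and the
# round-4/5 clone listing of the worked selection example, verbatim, one per
# line (duplicates kept as printed). Used to verify parser round-tripping.
N804D
E839G
L828S
F825S
W789R
L784W
E759G
None
D833G
D833G
D833G
None
None
D833G
N752S
F791S
M796V
I816V
F825C
N835D
K838R
V788I
E839G
K847R
T701A
N790H
S803P
N809S
S830R
W834R
P705S
D730N
S744G
Y768C
F791T
K847T
R735W
K747R
I795R
S803P
Y818D
F825S
K838N
Complete rearrangement; no insert
N752K
in-frame deletion from K787 on
N752S
N755T
I780
in-frame deletion from L794 on
F742S
E751G
S756P
F791L
W834R
V836A
M840T
L841W
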