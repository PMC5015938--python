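# Clone-level Sanger table for the worked example: five rounds of uracil-dropout
# selection of a Cdc24_428-854 mutant library against Bem1. Per-round totals,
# hotspot multiplicities and the individually reported round-4/5 clone genotypes
# match the original selection experiment; the remaining clones are synthetic
# fill-ins consistent with those published totals.
clone_id	round	mutations	status
R1_01	1	N804D, E759G	evaluated
R1_02	1	N804D, E839G, K747R	evaluated
R1_03	1	N804D, L828S, S744G	evaluated
R1_04	1	N804D, F825S	evaluated
R1_05	1	E759G, W789R, D730N	evaluated
R1_06	1	E759G, L784W	evaluated
R1_07	1	E759G, E839G, Y768C	evaluated
R1_08	1	L828S, W789R	evaluated
R1_09	1	F825S, L784W, P705S	evaluated
R1_10	1	E839G, L828S, F825S	evaluated
R1_11	1	W789R, L784W, N790H	evaluated
R1_12	1	rearrangement within the plasmid	not_evaluated
R1_13	1	rearrangement within the plasmid	not_evaluated
R1_14	1	rearrangement within the plasmid	not_evaluated
R1_15	1	rearrangement within the plasmid	not_evaluated
R1_16	1	rearrangement within the plasmid	not_evaluated
R1_17	1	rearrangement within the plasmid	not_evaluated
R1_18	1	rearrangement within the plasmid	not_evaluated
R1_19	1	rearrangement within the plasmid	not_evaluated
R1_20	1	rearrangement within the plasmid	not_evaluated
R1_21	1	rearrangement within the plasmid	not_evaluated
R1_22	1	rearrangement within the plasmid	not_evaluated
R2_01	2	T701S, Y768H	evaluated
R2_02	2	P705L	evaluated
R2_03	2	D730G, I780V	evaluated
R2_04	2	R735K, N790S	evaluated
R2_05	2	F742L	evaluated
R2_06	2	K747E, M796T	evaluated
R2_07	2	E751K	evaluated
R2_08	2	N752D, S803T	evaluated
R2_09	2	S744P	evaluated
R2_10	2	N755S, F791Y	evaluated
R2_11	2	S756F	evaluated
R2_12	2	E759K, I795V	evaluated
R2_13	2	L784F	evaluated
R2_14	2	V788A, W789L	evaluated
R2_15	2	rearrangement within the plasmid	not_evaluated
R3_01	3	D833G, N752S	evaluated
R3_02	3	D833G, K847R	evaluated
R3_03	3	T701A	evaluated
R3_04	3	N790H, E751G	evaluated
R3_05	3	S803P	evaluated
R3_06	3	Y768C	evaluated
R3_07	3	D730N	evaluated
R3_08	3	F791L	evaluated
R3_09	3	N809S, P705S	evaluated
R3_10	3	M796V	evaluated
R3_11	3	empty plasmid	empty_plasmid
R3_12	3	rearrangement within the plasmid	not_evaluated
R3_13	3	rearrangement within the plasmid	not_evaluated
R3_14	3	rearrangement within the plasmid	not_evaluated
R3_15	3	rearrangement within the plasmid	not_evaluated
R4_M1	4	N752S, F791S, M796V, I816V, F825C, N835D, K838R	evaluated
R4_M2	4	V788I, E839G, K847R	evaluated
R4_M3	4	T701A, N790H, S803P, N809S	evaluated
R4_M4	4	S830R, W834R	evaluated
R4_M5	4	P705S, D730N, S744G, Y768C, F791T, K847T	evaluated
R4_M6	4	R735W, K747R, I795R, S803P, Y818D, F825S, K838N	evaluated
R4_08	4	D833G, N752K, Y768H	evaluated
R4_09	4	D833G, T701S, F742L	evaluated
R4_10	4	D833G, E759K	evaluated
R4_11	4	D833G, V788A, N755S	evaluated
R4_12	4	D833G, I780V	evaluated
R4_13	4	D833G, L784F, S756P	evaluated
R4_14	4	D833G, W789L	evaluated
R4_15	4	K747E	evaluated
R4_16	4	E751K, N790S	evaluated
R4_17	4	P705L	evaluated
R4_18	4	R735K, S803T	evaluated
R4_19	4	F791Y	evaluated
R4_20	4	rearrangement within the plasmid	not_evaluated
R4_21	4	rearrangement within the plasmid	not_evaluated
R5_M1	5	F742S, E751G, S756P, F791L, W834R, V836A, M840T, L841W	evaluated
R5_D1	5	N752K, in-frame deletion from K787 on	evaluated
R5_D2	5	N752S, N755T, I780, in-frame deletion from L794 on	evaluated
R5_04	5	D833G, T701A	evaluated
R5_05	5	D833G, Y768H, N790H	evaluated
R5_06	5	D833G, P705S	evaluated
R5_07	5	S744G, M796T	evaluated
R5_08	5	E759G	evaluated
R5_09	5	I816V	evaluated
R5_10	5	F825C, K847T	evaluated
R5_11	5	N835D	evaluated
R5_12	5	S830R	evaluated
R5_13	5	E839G, I795V	evaluated
R5_14	5	L828S	evaluated
R5_15	5	V788I	evaluated
R5_16	5	N809S	evaluated
R5_17	5	D820G	evaluated
R5_18	5	M796V, D730G	evaluated
R5_R1	5	Complete rearrangement; no insert	not_evaluated
R5_20	5	rearrangement within the plasmid	not_evaluated
R5_21	5	empty plasmid	empty_plasmid
R5_22	5	empty plasmid	empty_plasmid
R5_23	5	empty plasmid	empty_plasmid
R5_24	5	empty plasmid	empty_plasmid
R5_25	5	empty plasmid	empty_plasmid
R5_26	5	empty plasmid	empty_plasmid
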