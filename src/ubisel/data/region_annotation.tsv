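region	residues
pb_domain	781-854
second_helix	831-841
acidic_cluster_1	820,822,824
acidic_cluster_2	833
interface	818,820,822,824,825,830,833
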