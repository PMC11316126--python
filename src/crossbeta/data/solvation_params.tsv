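# Atomic solvation parameters and heavy-atom radii.
# Five-class set after Eisenberg & McLachlan (1986), Nature 319:199-203,
# as used in buried-surface-area free-energy estimates of steric zippers.
# Positive parameters make burial of that atom class favourable.
# source: eisenberg-mclachlan-1986
atom_class	asp_kcal_per_A2	radius_A
C	0.016	1.90
N	-0.006	1.70
O	-0.006	1.40
N_charged	-0.050	1.70
O_charged	-0.024	1.40
S	0.021	1.85
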