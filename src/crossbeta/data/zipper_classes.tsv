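# version: fig1-v1
# Descriptor -> class lookup for steric-zipper topologies.
# sheet_sense: strand sense within each beta-sheet.
# surface_parity: which side-chain surfaces meet at the zipper;
#   "same" = face-to-face or back-to-back, "opposite" = face-to-back.
# sheet_direction: relative N->C direction of the facing strands;
#   "same" = N-to-N / up-up, "opposite" = N-to-C / up-down.
# Classes 9 and 10 have no observed example and no operational geometric
# criterion; they are carried as flagged placeholder rows (extra_symmetry_flag
# "screw") that the measurement-driven classifier never emits.
sheet_sense	surface_parity	sheet_direction	extra_symmetry_flag	class_id
parallel	same	opposite	none	1
parallel	opposite	same	none	2
parallel	same	same	none	3
parallel	opposite	opposite	none	4
antiparallel	opposite	same	none	5
antiparallel	opposite	opposite	none	6
antiparallel	same	same	none	7
antiparallel	same	opposite	none	8
parallel	opposite	same	screw	9
parallel	opposite	opposite	screw	10
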