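# Position-specific amyloidogenicity orderings as published with the
# Budapest Amyloid Predictor (most amyloidogenic residue first).
# Reproduced verbatim, including the known inconsistency in row 4
# (the residue C appears twice and V is absent); this file is an audit
# reference, not the source of truth.  The package derives its working
# orderings from the effect matrix instead.
1	V I C L F M W G Y A H T S Q K N R D E P
2	I F Y V W L C M H Q A T N S G P R E D K
3	I V F C L M W Y H A T Q S E R G N K D P
4	C I L F C W Y M A T N H E S R Q K G D P
5	I W F C Y M V L G H T P A N Q S R D K E
6	V C I F L Y W M A T S H N Q K G R D E P
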