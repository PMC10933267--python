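# Nine-amino-acid transactivation domain (9aaTAD) scan patterns.
#
# Reconstructed from the published 9aaTAD prediction tool's position
# classes: each of the nine window positions lists the residues allowed
# there; optional flank keys list residues disallowed immediately before
# or after the window (a flank constraint is vacuously satisfied at a
# sequence boundary). The "low" stringency classes are positionwise
# supersets of the "moderate" ones. Edit freely: the pattern set is
# data, not code.

[moderate]
pos1 = MDENQSTYG
pos2 = ILVFWMAY
pos3 = ILVFWMAY
pos4 = DENQSTKRH
pos5 = ILVFWMAYGP
pos6 = DENQSTKRHGP
pos7 = ILVFWMAY
pos8 = DENQSTGAY
pos9 = ILVFWMDE
flank_before_disallowed = KR
flank_after_disallowed = KR

[low]
pos1 = MDENQSTYGAPCH
pos2 = ILVFWMAYQT
pos3 = ILVFWMAYQT
pos4 = DENQSTKRHGP
pos5 = ILVFWMAYGPST
pos6 = DENQSTKRHGPAY
pos7 = ILVFWMAYQT
pos8 = DENQSTGAYHKR
pos9 = ILVFWMDEQT
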