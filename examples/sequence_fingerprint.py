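"""Sequence fingerprint of the diagnostic interface positions.

Positions #11 and #15 of the dockerin reference frame (auth 39/43) carry
the nonpolar side chains that dominate hydrophobic cohesin recognition.
A sequence whose #15 is polar cannot present that interface.
"""

from cohdoc.symmetry import DOC1A_FRAME_SEQUENCE, sequence_fingerprint

for label, seq in [
    ("reference frame", DOC1A_FRAME_SEQUENCE),
    ("M at #11 (nonpolar swap)", DOC1A_FRAME_SEQUENCE[:10] + "M" + DOC1A_FRAME_SEQUENCE[11:]),
    ("Q at #15 (polar swap)", DOC1A_FRAME_SEQUENCE[:14] + "Q" + DOC1A_FRAME_SEQUENCE[15:]),
]:
    fp = sequence_fingerprint(seq)
    print(f"{label}: #11={fp.position_11} #15={fp.position_15} "
          f"nonpolar_pass={fp.nonpolar_pass} coverage={fp.coverage:.0%}")
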