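"""Convert an oligo mass concentration to molarity.

A fluorometer reports ug/mL; reactions are pipetted in pmol/uL. With an
average nucleotide weight of 330 pg/pmol, an N-nt oligo at C ug/mL is
C * 1e6 / (1000 * 330 * N) pmol/uL.
"""

import circprobe as cp

for conc, n_nt, label in [
    (3.3, 100, "100-nt ssDNA at 3.3 ug/mL"),
    (100.0, 80, "80-nt circular probe stock at 100 ug/mL"),
    (0.5, 22, "22-nt miRNA at 0.5 ug/mL"),
]:
    pmol_per_ul = cp.moles_per_microliter(conc, n_nt)
    print(f"{label:42s} -> {pmol_per_ul:.4f} pmol/uL")

# The conversion is exactly invertible: multiplying the result by
# N * 330 pg/pmol * 1000 uL/mL / 1e6 pg/ug recovers the input ug/mL,
# which is how gradient dilutions are calibrated from a stock reading.
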