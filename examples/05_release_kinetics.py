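"""The hindered-diffusion chain: can wall pores keep up with degradation?

A peptide of L residues crosses a 1 nm pore in L^2 * x^2 / (2D).  With
D = 3 um^2/s the free 1D diffusion time over 1 nm is ~167 ns; a
decapeptide is hindered 100-fold (~17 us).  The protease generates one
decapeptide-length of product every L/v = 0.25 s at 40 residues/s, so
release through an inert pore is four orders of magnitude faster than
product generation.
"""

import corelandscape as cl

for L in (1, 2, 10):
    print(f"L = {L:2d}: slowdown {cl.slowdown_factor(L):6.0f}x, "
          f"pore transit {cl.pore_release_time(L, 1.0, 3.0):10.1f} ns")

report = cl.release_report(cl.ReleaseParams(D=3.0, x=1.0, L=10, v=40.0))
print()
for key, value in report.items():
    print(f"{key}: {value}")
# orders_of_magnitude = 4: release per product is ~10^4 times faster than
# translocation, so inert pores would not be rate limiting.
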