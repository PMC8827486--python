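"""Planar vs rotating waves through the three-coefficient fingerprint.

Simulates a long-wavelength planar wave traveling diagonally from the
bottom-left to the top-right of the 8x8 array and prints its circular
correlation against rotation maps at (4,4), (1,4) and (4,1); then finds a
rotating wave with the same net direction and a matched (4,4) value and
shows how only the (4,1) coefficient tells the two apart.
"""

from lfpwaves import validation

out = validation.worked_example(seed=0)
print("diagonal planar wave (bottom-left -> top-right):")
print(f"  rho_c(4,4) = {out['planar_rho_44']:.3f}   (high: wave along this map's net direction)")
print(f"  rho_c(1,4) = {out['planar_rho_14']:.3f}   (intermediate: diagonal vs vertical axis)")
print(f"  rho_c(4,1) = {out['planar_rho_41']:.3f}   (intermediate: diagonal vs horizontal axis)")
print()
print(f"rotating wave, same net direction (center {out['rotating_center']}, k={out['rotating_k']:.2f}):")
print(f"  rho_c(4,4) = {out['rotating_rho_44']:.3f}   (matched to the planar wave)")
print(f"  rho_c(4,1) = {out['rotating_rho_41']:.3f}   (reduced: the curvature weakens the horizontal gradient)")
print()
print("one coefficient cannot separate the two wave types; the combination can.")
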