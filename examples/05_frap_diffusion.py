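"""Fit a FRAP recovery curve for the diffusion coefficient.

Simulates recovery of a 10-um-diameter bleached disk under 2D
diffusion (uniform-disk closed form), adds measurement noise, and fits
D and the mobile fraction back.
"""

import filakit as fk

for D_true, label in ((2.3, "free tiles"), (0.38, "membrane-bound filaments")):
    fp = fk.FRAPParams(
        D_um2_per_s=D_true,
        bleach_radius_um=5.0,   # 10 um diameter ROI
        bleach_depth=0.8,
        t_max_s=60.0,           # acquisition window
        dt_s=0.5,
        noise_sd=0.02,
        seed=2,
    )
    fit = fk.fit_frap(fk.simulate_frap(fp))
    print(
        f"{label:28s} true D {D_true:4.2f} -> fitted D {fit.D_um2_per_s:5.3f} "
        f"um^2/s, mobile {fit.mobile_fraction:.2f}, t_half {fit.tau_half_s:5.1f} s"
    )
# Filaments anchored to the membrane diffuse ~6x slower than free
# tiles; both regimes are identifiable within the 60 s window.
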