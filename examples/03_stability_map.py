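"""Loop stability: operating-point verdict and a bandwidth contour.

The linearized reservoir loop has three cascaded one-pole stages and a
three-cycle delay; the characteristic cubic
(z-k1)(z-k2)(z-k3) + G_f*G_h = 0 must have all roots inside the unit
circle.
"""

import numpy as np

from ecgrc import char_roots, chip_operating_point, estimate_nl_gain, stability_contour
from ecgrc.config import NonlinearityParams

g_h = estimate_nl_gain(NonlinearityParams())
op = chip_operating_point(feedback_gain=0.1, nl_gain=g_h)
res = char_roots(op)
print(f"peak nonlinearity gain G_h = {g_h:.3f}")
print(f"operating point (omega1 = omega2 = 2*pi*0.9*rate, G_f = 0.1):")
print(f"  max |z| = {res.max_root_magnitude:.4f} -> "
      f"{'stable' if res.stable else 'UNSTABLE'}")
print(f"  (wide-bandwidth analytic limit: (G_f*G_h)^(1/3) = "
      f"{(0.1 * g_h) ** (1 / 3):.4f})")

w = 2 * np.pi * np.logspace(-2, 0.5, 12)
for g_f in (0.1, 0.3):
    stable, _ = stability_contour(w, w, beta=1.0, feedback_gain=g_f,
                                  nl_gain=g_h, rate=1.0)
    print(f"G_f = {g_f}: {stable.sum()}/{stable.size} grid points stable")
print()
print("Raising the feedback gain shrinks the stable bandwidth region, which")
print("is why the chip parks at G_f = 0.1 with ~0.9x-rate bandwidths: a wide")
print("stability margin at minimal amplifier power.")
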