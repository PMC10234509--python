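"""Isometric activation of a single muscle material point.

Holds the (modified) fiber stretch at the optimal value and switches the
muscle fully on.  The contractile element shortens against the series
elastic element until the two stresses balance; the common stress then
equals the maximum isometric stress sigma0.
"""

import numpy as np

from myofe import MaterialParams
from myofe.constitutive import isometric_steady_state

params = MaterialParams()
for stretch in (0.95, 1.00, 1.05, 1.10, 1.20):
    state = isometric_steady_state(stretch, params, duration=2.0, dt=1e-3)
    print(f"held stretch {stretch:.2f}: steady fiber stress "
          f"{state.sigma_see / 1e3:8.1f} kPa "
          f"(SEE stretch {state.lambda_s:.4f})")

print()
print(f"peak of {params.sigma0/1e3:.0f} kPa occurs at the optimal stretch "
      f"{params.lambda_opt}, where the force-length factor is 1; away from "
      "it the sarcomere overlap penalty reduces the steady stress.")
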