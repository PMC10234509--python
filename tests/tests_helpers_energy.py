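"""Independent closed-form passive strain energy used as a test oracle."""

import numpy as np


def total_passive_energy(lam_ax, lam_lat, params):
    """Strain energy density for F = diag(lam_ax, lam_lat, lam_lat),
    fiber along the axis, written directly from the constitutive formulas
    (no shared code with the stress assembly under test)."""
    J = lam_ax * lam_lat ** 2
    I1 = lam_ax ** 2 + 2.0 * lam_lat ** 2
    I1b = J ** (-2.0 / 3.0) * I1
    lam_fb = J ** (-1.0 / 3.0) * lam_ax
    Wm = params.c * (np.exp(params.b * (I1b - 3.0)) - 1.0)
    Wv = (J - 1.0) ** 2 / params.D
    Wpe = params.sigma0 * params.A / 3.0 * max(lam_fb - 1.0, 0.0) ** 3
    return Wm + Wv + Wpe
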