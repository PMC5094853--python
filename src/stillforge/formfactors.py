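"""Atomic X-ray form factors (4-Gaussian + constant approximation).

Coefficients are the standard International-Tables-style fits
f(q) = Σᵢ aᵢ·exp(−bᵢ·q²) + c with q = sinθ/λ = s/2 (Å⁻¹), tabulated here for
the elements that dominate protein crystals plus calcium.  f(0) equals the
atomic number to within a fraction of an electron.
"""

from __future__ import annotations

import numpy as np

# element -> (a1, b1, a2, b2, a3, b3, a4, b4, c)
COEFFICIENTS: dict[str, tuple[float, ...]] = {
    "H": (0.489918, 20.6593, 0.262003, 7.74039, 0.196767, 49.5519, 0.049879, 2.20159, 0.001305),
    "C": (2.31000, 20.8439, 1.02000, 10.2075, 1.58860, 0.568700, 0.865000, 51.6512, 0.215600),
    "N": (12.2126, 0.005700, 3.13220, 9.89330, 2.01250, 28.9975, 1.16630, 0.582600, -11.529),
    "O": (3.04850, 13.2771, 2.28680, 5.70110, 1.54630, 0.323900, 0.867000, 32.9089, 0.250800),
    "S": (6.90530, 1.46790, 5.20340, 22.2151, 1.43790, 0.253600, 1.58630, 56.1720, 0.866900),
    "Ca": (8.62660, 10.4421, 7.38730, 0.659900, 1.58990, 85.7484, 1.02110, 178.437, 1.37510),
}

ATOMIC_NUMBER = {"H": 1, "C": 6, "N": 7, "O": 8, "S": 16, "Ca": 20}

# Average atomic composition of one amino-acid residue (non-water), the
# usual back-of-envelope protein stoichiometry.
PROTEIN_RESIDUE_COMPOSITION = {"H": 7.8, "C": 4.9, "N": 1.35, "O": 1.47, "S": 0.05}


def form_factor(element: str, s) -> np.ndarray:
    """f(s) for one element; s = 2 sinθ/λ in Å⁻¹ (scalar or array)."""
    try:
        a1, b1, a2, b2, a3, b3, a4, b4, c = COEFFICIENTS[element]
    except KeyError:
        raise KeyError(f"no form-factor coefficients for element {element!r}") from None
    q2 = (np.asarray(s, dtype=float) / 2.0) ** 2
    return (
        a1 * np.exp(-b1 * q2)
        + a2 * np.exp(-b2 * q2)
        + a3 * np.exp(-b3 * q2)
        + a4 * np.exp(-b4 * q2)
        + c
    )
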