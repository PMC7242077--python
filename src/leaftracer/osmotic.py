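"""PEG 6000 osmotic-potential dose design (Michel & Kaufman calibration).

The osmotic potential of a PEG 6000 solution is given by the empirical
polynomial of Michel & Kaufman (1973) in concentration C (g PEG 6000 per kg
H₂O) and temperature T (°C):

    Ψ [bar] = −1.18·10⁻² C − 1.18·10⁻⁴ C² + 2.67·10⁻⁴ C·T + 8.39·10⁻⁷ C²·T

reported here in MPa (1 bar = 0.1 MPa).  At the assay dose of 400 g kg⁻¹ and
20 °C this evaluates to −1.88 MPa, the hyperosmotic shock applied to leaf
discs.  :func:`peg_concentration_for_potential` inverts the polynomial to
design a dose for a target potential.
"""

from __future__ import annotations

import warnings

from scipy.optimize import brentq

#: Validity envelope of the empirical calibration.
C_RANGE = (0.0, 800.0)  # g PEG 6000 per kg H2O
T_RANGE = (5.0, 35.0)  # degrees C

_COEF_C = -1.18e-2
_COEF_C2 = -1.18e-4
_COEF_CT = 2.67e-4
_COEF_C2T = 8.39e-7


def peg6000_osmotic_potential(
    concentration_g_per_kg: float, temperature_c: float = 20.0, unit: str = "MPa"
) -> float:
    """Osmotic potential of a PEG 6000 solution.

    Parameters
    ----------
    concentration_g_per_kg : float
        C, grams of PEG 6000 per kilogram of water (>= 0).
    temperature_c : float
        T in °C; the calibration envelope is 5–35 °C.  Default 20 °C.
    unit : {"MPa", "bar"}
        Output unit; the assays report MPa.

    Returns
    -------
    float
        Ψ ≤ 0; exactly 0 for pure water.
    """
    c = float(concentration_g_per_kg)
    t = float(temperature_c)
    if c < 0:
        raise ValueError(f"PEG concentration must be >= 0, got {c}")
    if not (C_RANGE[0] <= c <= C_RANGE[1]) or not (T_RANGE[0] <= t <= T_RANGE[1]):
        warnings.warn(
            f"(C={c} g/kg, T={t} °C) outside the calibration envelope "
            f"C∈{C_RANGE}, T∈{T_RANGE}; value extrapolated",
            stacklevel=2,
        )
    psi_bar = _COEF_C * c + _COEF_C2 * c**2 + _COEF_CT * c * t + _COEF_C2T * c**2 * t
    if unit == "bar":
        return psi_bar
    if unit == "MPa":
        return psi_bar * 0.1
    raise ValueError(f"unknown unit {unit!r} (use 'MPa' or 'bar')")


def peg_concentration_for_potential(
    psi_target_mpa: float, temperature_c: float = 20.0
) -> float:
    """PEG 6000 concentration (g kg⁻¹ H₂O) achieving a target potential.

    Solves Ψ(C, T) = Ψ_target by bracketed root finding on the calibration
    envelope; the target must be negative and achievable within it.
    """
    if psi_target_mpa >= 0:
        raise ValueError(f"target potential must be < 0 MPa, got {psi_target_mpa}")
    lo, hi = C_RANGE
    psi_min = peg6000_osmotic_potential(hi, temperature_c)
    if psi_target_mpa < psi_min:
        raise ValueError(
            f"target {psi_target_mpa} MPa not achievable with PEG 6000 at "
            f"{temperature_c} °C; achievable range is ({psi_min:.3f}, 0) MPa"
        )
    return float(
        brentq(
            lambda c: peg6000_osmotic_potential(c, temperature_c) - psi_target_mpa,
            lo,
            hi,
            xtol=1e-6,
        )
    )
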