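"""Feature extraction: anodic current, normalized inhibition, circuit fits.

The pipeline reduces each raw measurement to the statistics the classifier
consumes: the anodic-branch current read at +0.5 V, its normalized change
(I_A - I_A0) / I_A0 against the pollutant-free reference, and - for impedance
sweeps - the (R_el, R_db, C_db) parameters of the single-RC double-layer
circuit recovered from the Nyquist semicircle.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from .errors import DomainError, FitDomainError, FitError, RangeError
from .simulate import circuit_impedance
from .types import (
    ANODIC,
    AnodicReading,
    CVScan,
    EquivalentCircuitParams,
    ImpedanceSpectrum,
    ResponseVector,
)

__all__ = [
    "AnodicReading",
    "ResponseVector",
    "anodic_current",
    "relative_change",
    "initial_circuit_estimates",
    "fit_equivalent_circuit",
]


def anodic_current(scan: CVScan, potential_V: float = 0.5) -> float:
    """Anodic-branch current at ``potential_V``, linearly interpolated.

    Exact when a sample sits on the requested potential; raises RangeError if
    the potential is outside the anodic sweep.
    """
    v, i = scan.branch_points(ANODIC)
    if potential_V < v[0] - 1e-12 or potential_V > v[-1] + 1e-12:
        raise RangeError(
            f"potential {potential_V} V outside anodic sweep [{v[0]}, {v[-1]}] V"
        )
    return float(np.interp(potential_V, v, i))


def relative_change(I_A: float, I_A0: float) -> float:
    """Normalized inhibition response (I_A - I_A0) / I_A0; needs I_A0 > 0."""
    if I_A0 <= 0:
        raise DomainError("reference current I_A0 must be positive")
    return (I_A - I_A0) / I_A0


def reading_response(reading: AnodicReading) -> float:
    return relative_change(reading.I_A, reading.I_A0)


def initial_circuit_estimates(spectrum: ImpedanceSpectrum) -> EquivalentCircuitParams:
    """Closed-form starting values from the sweep's limits and apex.

    R_el from the highest-frequency real part, R_db from the low-frequency
    plateau minus R_el, C_db from the -Z_im apex via C = 1/(w_apex * R_db).
    Requires a sweep spanning >= 2 decades whose interior brackets the apex.
    """
    f = spectrum.frequency_Hz
    if np.log10(f[-1] / f[0]) < 2.0:
        raise FitDomainError("sweep must span at least two decades")
    r_el = float(spectrum.z_re_ohm[-1])
    r_db = float(spectrum.z_re_ohm[0]) - r_el
    if r_el <= 0 or r_db <= 0:
        raise FitDomainError("sweep limits do not yield positive resistances")
    apex = int(np.argmax(-spectrum.z_im_ohm))
    if apex in (0, f.size - 1):
        raise FitDomainError("sweep does not bracket the semicircle apex")
    c_db = 1.0 / (spectrum.omega[apex] * r_db)
    return EquivalentCircuitParams(r_el, r_db, c_db)


def fit_equivalent_circuit(spectrum: ImpedanceSpectrum) -> EquivalentCircuitParams:
    """Least-squares fit of the R_el + (R_db || C_db) model to Nyquist data.

    Starts from :func:`initial_circuit_estimates` and refines in log-parameter
    space (guaranteeing positivity) with unit weights on the stacked real and
    imaginary residuals.  The trust-region refinement never increases the
    residual, so the returned fit is at least as good as the initial guess.
    """
    p0 = initial_circuit_estimates(spectrum)
    x0 = np.log(p0.as_array())
    target = np.concatenate([spectrum.z_re_ohm, spectrum.z_im_ohm])

    omega = spectrum.omega

    def residuals(x: np.ndarray) -> np.ndarray:
        # inline model: intermediate iterates may leave the R_el < R_db regime
        r_el, r_db, c_db = np.exp(x)
        z = r_el + r_db / (1.0 + 1j * omega * r_db * c_db)
        return np.concatenate([z.real, z.imag]) - target

    result = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
    if not result.success:
        raise FitError("circuit refinement failed to converge", initial_estimates=p0)
    r_el, r_db, c_db = np.exp(result.x)
    return EquivalentCircuitParams(float(r_el), float(r_db), float(c_db))
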