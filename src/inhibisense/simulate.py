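"""Synthetic electrochemistry for the bacterial inhibition sensor array.

The generator reproduces the statistical structure the downstream analysis
assumes, calibrated to the packaged response table:

* cyclic voltammograms over [-0.5, +0.5] V at 10 mV/s, with Gaussian anodic
  peaks near +0.35 V and a cathodic peak near -0.15 V over a capacitive
  background; immobilized bacteria act as an insulating layer that scales the
  whole trace down (``coverage_attenuation``), and pollutant damage scales it
  back up by ``1 + response_scale``;
* impedance spectra of the series-R / parallel-RC double-layer circuit
  Z(w) = R_el + R_db / (1 + i*w*R_db*C_db) over 100 mHz - 100 kHz;
* labeled 3-channel response datasets, with per-(bacterium, pollutant, level)
  means anchored to the packaged calibration table and multiplicative
  Gaussian measurement noise at the instrument's ~10% reproducibility level.

Randomness: a single integer seed feeds a ``numpy`` ``SeedSequence`` whose
spawned children drive independent per-class streams, so datasets are
bit-reproducible and insensitive to generation order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DomainError
from .registry import BACTERIA, LEVELS_UM, POLLUTANTS, bacterium_index, pollutant_index
from .types import (
    ANODIC,
    CATHODIC,
    CalibrationAnchor,
    CVScan,
    EquivalentCircuitParams,
    ImpedanceSpectrum,
    LabeledSample,
    ResponseVector,
)

__all__ = [
    "CVBaseline",
    "CVScan",
    "ImpedanceSpectrum",
    "EquivalentCircuitParams",
    "CalibrationAnchor",
    "LabeledSample",
    "anchor_table",
    "anchored_levels",
    "circuit_impedance",
    "default_frequencies",
    "generate_dataset",
    "response_surface",
    "simulate_cv",
    "simulate_impedance",
]

#: Grid levels with packaged anchors (the outer levels 0.1 and 1000 uM are
#: clamped extrapolations, not measured anchors).
ANCHORED_LEVELS_UM = (1.0, 10.0, 100.0)


@dataclass(frozen=True)
class CVBaseline:
    """Bare-electrode voltammogram shape: peak positions, widths, background.

    Only the peak positions are constrained by the measurements (anodic
    +0.3..+0.4 V, cathodic about -0.15 V); amplitudes and widths are free
    shape parameters of the simulator.
    """

    anodic_peak_V: float = 0.35
    anodic_peak_uA: float = 10.0
    anodic_width_V: float = 0.06
    cathodic_peak_V: float = -0.15
    cathodic_peak_uA: float = 6.0
    cathodic_width_V: float = 0.06
    capacitive_uA: float = 1.0
    v_min: float = -0.5
    v_max: float = 0.5
    points_per_branch: int = 201

    def __post_init__(self):
        if self.points_per_branch < 2:
            raise DomainError("need at least 2 points per branch")
        if not (self.v_min < self.v_max):
            raise DomainError("v_min must be below v_max")
        for name in ("anodic_width_V", "cathodic_width_V"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")

    def anodic_current(self, v: np.ndarray) -> np.ndarray:
        """Noise-free anodic-branch current of the bare electrode."""
        peak = self.anodic_peak_uA * np.exp(
            -0.5 * ((v - self.anodic_peak_V) / self.anodic_width_V) ** 2
        )
        return self.capacitive_uA + peak

    def cathodic_current(self, v: np.ndarray) -> np.ndarray:
        peak = self.cathodic_peak_uA * np.exp(
            -0.5 * ((v - self.cathodic_peak_V) / self.cathodic_width_V) ** 2
        )
        return -(self.capacitive_uA + peak)


def simulate_cv(
    baseline: CVBaseline | None = None,
    coverage_attenuation: float = 1.0,
    response_scale: float = 0.0,
    seed: int | None = None,
    noise_cv: float = 0.0,
    scan_rate_mV_s: float = 10.0,
) -> CVScan:
    """Simulate a two-branch voltammogram of a (possibly coated) electrode.

    The trace is the bare-electrode baseline scaled by
    ``coverage_attenuation * (1 + response_scale)``: attenuation models the
    insulating bacterial layer, ``response_scale`` the relative current
    recovery when pollutants damage that layer (the quantity the feature
    stage extracts back out as dI_A/I_A0).

    Parameters
    ----------
    baseline:
        Bare-electrode shape; defaults to :class:`CVBaseline`.
    coverage_attenuation:
        In (0, 1]; 1 means an uncoated electrode, ~1/3 reproduces the
        observed threefold current drop after coating.
    response_scale:
        Relative inhibition response, >= -1.
    noise_cv:
        Coefficient of variation of multiplicative Gaussian noise per point.
    """
    baseline = baseline or CVBaseline()
    if not (0.0 < coverage_attenuation <= 1.0):
        raise DomainError("coverage_attenuation must lie in (0, 1]")
    if response_scale < -1.0:
        raise DomainError("response_scale must be >= -1")
    if noise_cv < 0:
        raise DomainError("noise_cv must be >= 0")

    v_up = np.linspace(baseline.v_min, baseline.v_max, baseline.points_per_branch)
    v_down = v_up[::-1]
    scale = coverage_attenuation * (1.0 + response_scale)
    i_up = scale * baseline.anodic_current(v_up)
    i_down = scale * baseline.cathodic_current(v_down)

    potential = np.concatenate([v_up, v_down])
    current = np.concatenate([i_up, i_down])
    if noise_cv > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        current = current * (1.0 + rng.normal(0.0, noise_cv, current.size))
    branch = np.array([ANODIC] * v_up.size + [CATHODIC] * v_down.size, dtype=object)
    return CVScan(potential, current, branch, scan_rate_mV_s=scan_rate_mV_s)


def default_frequencies(
    f_min_Hz: float = 0.1, f_max_Hz: float = 1e5, points_per_decade: int = 50
) -> np.ndarray:
    """Log-spaced sweep, dense enough to resolve the semicircle apex."""
    if f_min_Hz <= 0 or f_max_Hz <= f_min_Hz:
        raise DomainError("need 0 < f_min < f_max")
    n_dec = np.log10(f_max_Hz / f_min_Hz)
    n = int(round(n_dec * points_per_decade)) + 1
    return np.logspace(np.log10(f_min_Hz), np.log10(f_max_Hz), n)


def circuit_impedance(
    params: EquivalentCircuitParams, frequency_Hz: np.ndarray
) -> np.ndarray:
    """Complex impedance of R_el in series with (R_db parallel C_db).

    Z(w) = R_el + R_db / (1 + i*w*R_db*C_db); the Nyquist locus is a
    semicircle of diameter R_db with apex at w = 1/(R_db*C_db), where
    -Z_im = R_db/2.
    """
    omega = 2.0 * np.pi * np.asarray(frequency_Hz, dtype=float)
    return params.R_el_ohm + params.R_db_ohm / (
        1.0 + 1j * omega * params.R_db_ohm * params.C_db_F
    )


def simulate_impedance(
    params: EquivalentCircuitParams,
    frequencies: np.ndarray | None = None,
    noise_cv: float = 0.0,
    seed: int | None = None,
) -> ImpedanceSpectrum:
    """Simulate a Nyquist sweep with multiplicative noise on Re and Im parts."""
    if noise_cv < 0:
        raise DomainError("noise_cv must be >= 0")
    freq = default_frequencies() if frequencies is None else np.asarray(frequencies, float)
    z = circuit_impedance(params, freq)
    z_re, z_im = z.real.copy(), z.imag.copy()
    if noise_cv > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        z_re *= 1.0 + rng.normal(0.0, noise_cv, freq.size)
        z_im *= 1.0 + rng.normal(0.0, noise_cv, freq.size)
    return ImpedanceSpectrum(freq, z_re, z_im)


# ---------------------------------------------------------------------------
# Response surfaces anchored to the packaged calibration table
# ---------------------------------------------------------------------------

_ANCHORS: dict[tuple[str, str, float], float] | None = None


def anchor_table() -> dict[tuple[str, str, float], float]:
    """(bacterium, pollutant, level) -> mean response, from the packaged table.

    Anchors exist at 1, 10 and 100 uM for every pollutant; outer grid levels
    are handled by clamped extrapolation in :func:`response_surface`.
    """
    global _ANCHORS
    if _ANCHORS is None:
        from .io import load_table1  # deferred: io imports annet for validation

        fixture = load_table1()
        table: dict[tuple[str, str, float], float] = {}
        for rec in fixture.records:
            resp = rec.response.as_array()
            for b, value in zip(BACTERIA, resp):
                table[(b, rec.pollutant, rec.level_uM)] = float(value)
        _ANCHORS = table
    return _ANCHORS


def anchored_levels() -> tuple[float, ...]:
    return ANCHORED_LEVELS_UM


def response_surface(
    bacterium: str, pollutant: str, concentration_uM: float
) -> float:
    """Noise-free mean inhibition response of one channel at one concentration.

    Piecewise-linear interpolation in log10(concentration) between the
    packaged anchors; clamped to the nearest anchor outside the 1-100 uM
    anchored range (``np.interp`` semantics), hence exact at every anchor and
    monotone between adjacent ones.
    """
    bacterium_index(bacterium)
    pollutant_index(pollutant)
    if concentration_uM <= 0:
        raise DomainError("concentration must be positive")
    anchors = anchor_table()
    xs = np.log10(ANCHORED_LEVELS_UM)
    ys = np.array([anchors[(bacterium, pollutant, lv)] for lv in ANCHORED_LEVELS_UM])
    return float(np.interp(np.log10(concentration_uM), xs, ys))


def _class_mean(pollutant: str, concentration_uM: float) -> np.ndarray:
    return np.array(
        [response_surface(b, pollutant, concentration_uM) for b in BACTERIA]
    )


def generate_dataset(
    n_per_class: int,
    noise_cv: float = 0.10,
    seed: int | None = None,
    concentration_jitter: bool = False,
) -> list[LabeledSample]:
    """Draw a labeled dataset over all 60 (pollutant, grid level) classes.

    Each 3-channel response is the anchored class mean times ``1 + eps`` with
    ``eps ~ Normal(0, noise_cv)`` independently per channel, truncated so
    responses stay >= -1.  With ``concentration_jitter`` the true spiked
    concentration is drawn log-uniformly within half a decade of the grid
    level (so it still quantizes back to that level) and the mean is
    evaluated at the jittered concentration.

    One integer ``seed`` spawns an independent child stream per class, so the
    draw is bit-reproducible and independent of iteration order.
    """
    if n_per_class < 1:
        raise DomainError("n_per_class must be >= 1")
    if noise_cv < 0:
        raise DomainError("noise_cv must be >= 0")
    children = np.random.SeedSequence(seed).spawn(len(POLLUTANTS) * len(LEVELS_UM))
    samples: list[LabeledSample] = []
    k = 0
    for pollutant in POLLUTANTS:
        for level in LEVELS_UM:
            rng = np.random.default_rng(children[k])
            k += 1
            for rep in range(n_per_class):
                if concentration_jitter:
                    conc = float(
                        10.0 ** rng.uniform(np.log10(level) - 0.5, np.log10(level) + 0.5)
                    )
                else:
                    conc = float(level)
                mean = _class_mean(pollutant, conc)
                eps = rng.normal(0.0, noise_cv, 3) if noise_cv > 0 else np.zeros(3)
                resp = np.maximum(mean * (1.0 + eps), -1.0)
                samples.append(
                    LabeledSample(
                        response=ResponseVector.from_array(resp),
                        pollutant=pollutant,
                        concentration_uM=conc,
                        seed_tag=f"{seed}/{pollutant}/{level:g}/{rep}",
                    )
                )
    return samples
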