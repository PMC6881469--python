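"""Shared domain containers for raw electrochemistry and derived statistics.

These dataclasses validate their physical invariants on construction so the
rest of the pipeline can assume well-formed data.  They are re-exported from
the stage modules (:mod:`inhibisense.simulate`, :mod:`inhibisense.features`)
that conceptually own them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import DomainError, StructureError
from .registry import BACTERIA, LEVELS_UM, POLLUTANTS, level_index, pollutant_index

ANODIC = "anodic"
CATHODIC = "cathodic"


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise StructureError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class CVScan:
    """One cyclic-voltammetry sweep: potential vs current with branch labels.

    The anodic branch is the increasing-potential leg, the cathodic branch the
    decreasing one.  Potentials are restricted to the instrument window
    [-0.5, +0.5] V; currents are in microamps.
    """

    potential_V: np.ndarray
    current_uA: np.ndarray
    branch: np.ndarray
    scan_rate_mV_s: float = 10.0

    def __post_init__(self):
        object.__setattr__(self, "potential_V", _as_float_array(self.potential_V, "potential_V"))
        object.__setattr__(self, "current_uA", _as_float_array(self.current_uA, "current_uA"))
        object.__setattr__(self, "branch", np.asarray(self.branch, dtype=object))
        n = self.potential_V.size
        if n < 2 or self.current_uA.size != n or self.branch.size != n:
            raise StructureError("potential, current and branch must share length >= 2")
        if self.scan_rate_mV_s <= 0:
            raise DomainError("scan_rate_mV_s must be positive")
        if np.any(self.potential_V < -0.5 - 1e-9) or np.any(self.potential_V > 0.5 + 1e-9):
            raise DomainError("potentials must lie within [-0.5, +0.5] V")
        bad = set(self.branch) - {ANODIC, CATHODIC}
        if bad:
            raise StructureError(f"unknown branch labels {sorted(map(str, bad))}")

    def branch_points(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        """(potential, current) of one branch, sorted by increasing potential."""
        mask = self.branch == which
        if not mask.any():
            raise StructureError(f"scan has no {which} branch")
        v = self.potential_V[mask]
        i = self.current_uA[mask]
        order = np.argsort(v, kind="stable")
        return v[order], i[order]


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """A frequency sweep of complex impedance (Nyquist data).

    ``z_im_ohm`` keeps its natural sign: negative for capacitive behaviour.
    Frequencies must be strictly positive and strictly increasing.
    """

    frequency_Hz: np.ndarray
    z_re_ohm: np.ndarray
    z_im_ohm: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "frequency_Hz", _as_float_array(self.frequency_Hz, "frequency_Hz"))
        object.__setattr__(self, "z_re_ohm", _as_float_array(self.z_re_ohm, "z_re_ohm"))
        object.__setattr__(self, "z_im_ohm", _as_float_array(self.z_im_ohm, "z_im_ohm"))
        n = self.frequency_Hz.size
        if self.z_re_ohm.size != n or self.z_im_ohm.size != n:
            raise StructureError("frequency and impedance arrays must share length")
        if np.any(self.frequency_Hz <= 0):
            raise DomainError("frequencies must be strictly positive")
        if np.any(np.diff(self.frequency_Hz) <= 0):
            raise StructureError("frequencies must be strictly increasing")

    @property
    def omega(self) -> np.ndarray:
        """Angular frequency (rad/s)."""
        return 2.0 * np.pi * self.frequency_Hz

    @property
    def z_complex(self) -> np.ndarray:
        return self.z_re_ohm + 1j * self.z_im_ohm


@dataclass(frozen=True)
class EquivalentCircuitParams:
    """R_el + (R_db parallel C_db): the single-RC double-layer model.

    R_el is the series electrolyte resistance, R_db and C_db the double-layer
    (charge-transfer) resistance and capacitance.  The physical regime has
    R_el < R_db.
    """

    R_el_ohm: float
    R_db_ohm: float
    C_db_F: float

    def __post_init__(self):
        if self.R_el_ohm <= 0 or self.R_db_ohm <= 0 or self.C_db_F <= 0:
            raise DomainError("circuit parameters must be strictly positive")
        if self.R_el_ohm >= self.R_db_ohm:
            raise DomainError("expected R_el < R_db for the double-layer model")

    def as_array(self) -> np.ndarray:
        return np.array([self.R_el_ohm, self.R_db_ohm, self.C_db_F])


@dataclass(frozen=True)
class ResponseVector:
    """The 3-channel normalized inhibition statistic, one value per bacterium.

    Each component is a relative anodic-current change (I_A - I_A0) / I_A0 and
    is therefore bounded below by -1 (current cannot go negative).
    """

    delta_e_coli: float
    delta_m_capsulatus: float
    delta_s_oneidensis: float

    def __post_init__(self):
        for name in ("delta_e_coli", "delta_m_capsulatus", "delta_s_oneidensis"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise DomainError(f"{name} must be finite")
            if v < -1.0:
                raise DomainError(f"{name}={v} below -1 implies a negative current")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.delta_e_coli, self.delta_m_capsulatus, self.delta_s_oneidensis]
        )

    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "ResponseVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (3,):
            raise StructureError("a response vector has exactly 3 components")
        return cls(*arr.tolist())


@dataclass(frozen=True)
class AnodicReading:
    """A paired (treated, reference) anodic-current read at one potential."""

    I_A: float
    I_A0: float
    eval_potential_V: float = 0.5

    def __post_init__(self):
        if self.I_A0 <= 0:
            raise DomainError("reference current I_A0 must be positive")


@dataclass(frozen=True)
class CalibrationAnchor:
    """Mean response of one (bacterium, pollutant, grid level) combination."""

    bacterium: str
    pollutant: str
    concentration_uM: float
    mean_response: float

    def __post_init__(self):
        if self.bacterium not in BACTERIA:
            raise DomainError(f"unknown bacterium {self.bacterium!r}")
        pollutant_index(self.pollutant)  # raises RegistryError if unknown
        level_index(self.concentration_uM)  # must sit on the 5-level grid
        if self.mean_response < -1.0:
            raise DomainError("mean_response below -1 implies negative current")


@dataclass(frozen=True)
class LabeledSample:
    """One synthetic array measurement with its ground truth."""

    response: ResponseVector
    pollutant: str
    concentration_uM: float
    seed_tag: str = ""

    def __post_init__(self):
        pollutant_index(self.pollutant)
        if self.concentration_uM <= 0:
            raise DomainError("concentration must be positive")
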