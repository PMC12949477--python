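"""Core record types shared by every pipeline stage.

All containers are thin, validated wrappers over numpy arrays.  Visual
fields hold 52 values in the export order defined by :mod:`sfsim.grid`;
OCT records hold the six circumpapillary RNFL sectors in the fixed order
T, TS, NS, N, NI, TI (temporal, temporal-superior, nasal-superior, nasal,
nasal-inferior, temporal-inferior), matching columns oct.T .. oct.TI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np

from .grid import N_LOCATIONS, THRESHOLD_MIN

#: Fixed cpRNFL sector order (clock-hour sectors of the 3.5-mm scan ring).
SECTORS = ("T", "TS", "NS", "N", "NI", "TI")
N_SECTORS = len(SECTORS)

#: Default visit spacing of the generated series: 10 visits over 5 years.
VISIT_GAP_DAYS = 183
N_VISITS = 10

#: Noise-condition names shipped with the generator.
CONDITIONS = ("Reliable", "Unreliable", "Reliable_gve", "Unreliable_gve")

#: Upper bound accepted for stored threshold values (dB).  Seed records may
#: carry supra-normal sensitivities; measured values are clamped to the
#: narrower instrument range in the measurement simulator.
THRESHOLD_STORE_MAX = 50.0


@dataclass(frozen=True)
class VFMap:
    """One visual field: 52 dB values, either thresholds or total deviations."""

    values: np.ndarray
    kind: str  # "threshold" | "total_deviation"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_LOCATIONS,):
            raise ValueError(f"VFMap needs {N_LOCATIONS} values, got {v.shape}")
        if self.kind not in ("threshold", "total_deviation"):
            raise ValueError(f"unknown VFMap kind: {self.kind!r}")
        if self.kind == "threshold" and (
            (v < THRESHOLD_MIN - 1e-9).any() or (v > THRESHOLD_STORE_MAX + 1e-9).any()
        ):
            raise ValueError("thresholds outside instrument range [0, 50] dB")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class OCTSectors:
    """Six cpRNFL sector thicknesses (microns), order T, TS, NS, N, NI, TI."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_SECTORS,):
            raise ValueError(f"OCTSectors needs {N_SECTORS} values, got {v.shape}")
        if (v < 0).any():
            raise ValueError("sector thickness must be non-negative")
        object.__setattr__(self, "values", v)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(SECTORS, self.values))


def visit_dates(final_date: date = date(2022, 7, 1),
                n_visits: int = N_VISITS,
                gap_days: int = VISIT_GAP_DAYS) -> list[date]:
    """Visit dates ending at ``final_date`` with fixed spacing."""
    return [final_date - timedelta(days=gap_days * (n_visits - v))
            for v in range(1, n_visits + 1)]


@dataclass
class EyeTruth:
    """Ground truth for one eye: final visit, true slopes, noise-free series.

    ``vf_slopes`` / ``oct_slopes`` are the known progression rates (dB/y and
    microns/y); zero means non-progressing.  ``true_td`` / ``true_vf`` /
    ``true_oct`` hold the 10-visit noise-free series produced by
    anti-progression (visit 10 equals the seed final visit).
    """

    eye_id: str
    final_td: VFMap
    final_vf: VFMap
    final_oct: OCTSectors
    vf_slopes: np.ndarray       # (52,) dB/y, <= 0
    oct_slopes: np.ndarray      # (6,) microns/y, <= 0
    true_td: np.ndarray | None = None    # (n_visits, 52)
    true_vf: np.ndarray | None = None    # (n_visits, 52)
    true_oct: np.ndarray | None = None   # (n_visits, 6)
    dates: list[date] = field(default_factory=visit_dates)

    def __post_init__(self):
        self.vf_slopes = np.asarray(self.vf_slopes, dtype=float)
        self.oct_slopes = np.asarray(self.oct_slopes, dtype=float)
        if self.vf_slopes.shape != (N_LOCATIONS,):
            raise ValueError("vf_slopes must have 52 entries")
        if self.oct_slopes.shape != (N_SECTORS,):
            raise ValueError("oct_slopes must have 6 entries")
        if (self.vf_slopes > 1e-9).any() or (self.oct_slopes > 1e-9).any():
            raise ValueError("truth slopes must be <= 0")

    @property
    def normative_offset(self) -> np.ndarray:
        """Per-location threshold minus TD, frozen at the final visit."""
        return self.final_vf.values - self.final_td.values

    @property
    def has_series(self) -> bool:
        return self.true_td is not None


@dataclass
class MeasuredSeries:
    """Measured (noise-injected) 10-visit series for one eye."""

    eye_id: str
    vf_measured: np.ndarray   # (n_visits, 52) thresholds, clamped to range
    td_measured: np.ndarray   # (n_visits, 52)
    oct_measured: np.ndarray  # (n_visits, 6)
    condition: str
    rng_seed: int
    dates: list[date] = field(default_factory=visit_dates)

    def __post_init__(self):
        self.vf_measured = np.asarray(self.vf_measured, dtype=float)
        self.td_measured = np.asarray(self.td_measured, dtype=float)
        self.oct_measured = np.asarray(self.oct_measured, dtype=float)
        n = self.vf_measured.shape[0]
        if self.vf_measured.shape != (n, N_LOCATIONS) or \
           self.td_measured.shape != (n, N_LOCATIONS) or \
           self.oct_measured.shape != (n, N_SECTORS):
            raise ValueError("inconsistent measured series shapes")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass
class Person:
    person_id: str
    sex: str      # "F" | "M"
    age: float    # years at final visit


@dataclass
class DatasetBundle:
    """One generated dataset: all eyes for one status/condition/seed."""

    eyes: list[MeasuredSeries]
    truth: list[EyeTruth]
    status: str        # "progressing" | "stable"
    condition: str
    rng_seed: int
    persons: list[Person] = field(default_factory=list)

    def __post_init__(self):
        if len(self.eyes) != len(self.truth):
            raise ValueError("one truth record required per measured record")
        if self.status not in ("progressing", "stable"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
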