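"""cpRNFL sector measurement noise.

OCT sector thickness noise is additive, Gaussian, and sector-specific,
with a larger spread on the first visit of a series than on subsequent
visits (re-scan alignment is better once a baseline exists).  Values are
clamped at 0 microns and rounded to integer microns, matching the integer
resolution of exported sector thicknesses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import N_SECTORS, SECTORS

#: Per-sector noise SD (microns): first visit row / subsequent visits row.
DEFAULT_FIRST_VISIT_SD = {"T": 4.18, "TS": 5.18, "NS": 4.56,
                          "N": 5.53, "NI": 5.97, "TI": 3.23}
DEFAULT_SUBSEQUENT_SD = {"T": 3.11, "TS": 3.50, "NS": 3.03,
                         "N": 3.55, "NI": 3.81, "TI": 2.43}


@dataclass(frozen=True)
class OCTNoiseTable:
    first_visit_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FIRST_VISIT_SD))
    subsequent_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBSEQUENT_SD))

    def __post_init__(self):
        for table in (self.first_visit_sd, self.subsequent_sd):
            if set(table) != set(SECTORS):
                raise ValueError(f"noise table must cover sectors {SECTORS}")
            if any(v < 0 for v in table.values()):
                raise ValueError("noise SDs must be non-negative")

    def sd_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        first = np.array([self.first_visit_sd[s] for s in SECTORS])
        rest = np.array([self.subsequent_sd[s] for s in SECTORS])
        return first, rest


def add_oct_noise(true_series: np.ndarray,
                  rng: np.random.Generator,
                  table: OCTNoiseTable | None = None) -> np.ndarray:
    """Measured sector series: independent Gaussian noise per sector/visit.

    Visit 1 uses the first-visit SD row, visits 2..n the subsequent row;
    results are clamped at >= 0 and rounded to integer microns.
    """
    true_series = np.asarray(true_series, dtype=float)
    n_visits = true_series.shape[0]
    if true_series.shape != (n_visits, N_SECTORS):
        raise ValueError("true series must be (n_visits, 6)")
    if table is None:
        table = OCTNoiseTable()
    first, rest = table.sd_arrays()
    sd = np.vstack([first[None, :], np.tile(rest, (n_visits - 1, 1))])
    noisy = true_series + rng.normal(0.0, 1.0, true_series.shape) * sd
    return np.round(np.clip(noisy, 0.0, None))
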