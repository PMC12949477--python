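"""Ground-truth derivation: progression criteria and anti-progression.

Given a clinical-like series of visual fields (raw dB thresholds) and OCT
sector thicknesses, this module decides which locations/sectors are truly
progressing, at what rate, and then constructs a 10-visit noise-free
series by "anti-progressing": walking backward from the final visit at the
accepted rates.

Visual-field criteria (per location, slopes fitted on raw dB and
aging-corrected by +0.1 dB/y before testing):

* criterion 1 — outlier-removed slope below a series-length-dependent
  cutoff AND one-sided permutation p < 0.5;
* criterion 2 — negative slope AND permutation p < 0.5 AND at least one
  8-neighbour that passed either criterion; applied iteratively to a fixed
  point so chains of weakly declining locations bridging definite
  progression are captured.

OCT criterion (per sector): outlier-removed slope below -0.1 microns/y AND
min(t-test p, permutation p) < 0.05; no aging correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import N_LOCATIONS, NEIGHBORS
from .records import (EyeTruth, N_SECTORS, N_VISITS, OCTSectors, VFMap,
                      VISIT_GAP_DAYS, visit_dates)
from .slopes import fit_slope

#: Slope cutoffs (dB/y) for visual-field criterion 1 by series length.
VF_SLOPE_CUTOFF = {4: -1.6, 5: -1.1, 6: -0.9, 7: -0.7, 8: -0.5}
VF_SLOPE_CUTOFF_LONG = -0.4  # series of length >= 9

#: Permutation-p gate shared by both VF criteria.
VF_P_GATE = 0.5

#: Aging rate reversed out of clinical VF slopes (dB/y).
VF_AGING_RATE = 0.1

#: OCT sector criterion: slope below this (microns/y) and p < 0.05.
OCT_SLOPE_CUTOFF = -0.1
OCT_P_GATE = 0.05

DAYS_PER_YEAR = 365.25


def vf_slope_cutoff(series_length: int) -> float:
    """Criterion-1 slope cutoff (dB/y) for a given number of visits."""
    if series_length < 4:
        raise ValueError("VF criteria need at least 4 visits")
    return VF_SLOPE_CUTOFF.get(series_length, VF_SLOPE_CUTOFF_LONG)


def aging_correct_vf(slope: float) -> float:
    """Reverse normal aging: add 0.1 dB/y (clamp to <= 0 for truth use)."""
    return min(0.0, slope + VF_AGING_RATE)


@dataclass
class LocationResult:
    slope_raw: float       # fitted on raw dB, before aging correction
    slope: float           # aging-corrected (criteria and truth use this)
    p_perm: float
    criterion: int         # 0 = not progressing, 1 or 2


def detect_vf_progression(values: np.ndarray, years: np.ndarray,
                          rng: np.random.Generator | None = None,
                          n_perm: int = 5000) -> list[LocationResult]:
    """Apply the two-stage progression criteria to one eye's VF series.

    ``values`` is (n_visits, 52) raw dB thresholds; ``years`` the visit
    times.  Returns one :class:`LocationResult` per location; non-flagged
    locations report slope 0.
    """
    values = np.asarray(values, dtype=float)
    years = np.asarray(years, dtype=float)
    n = len(years)
    if values.shape != (n, N_LOCATIONS):
        raise ValueError("values must be (n_visits, 52) matching dates")
    if n < 4:
        raise ValueError("VF criteria need at least 4 visits")
    cutoff = vf_slope_cutoff(n)

    fits = [fit_slope(years, values[:, i], n_perm=n_perm, rng=rng)
            for i in range(N_LOCATIONS)]
    corrected = np.array([f.slope + VF_AGING_RATE for f in fits])
    p_perm = np.array([f.p_perm for f in fits])

    crit1 = (corrected < cutoff) & (p_perm < VF_P_GATE)
    flagged = crit1.copy()
    criterion = np.where(crit1, 1, 0)

    # criterion 2 to a fixed point; each pass reads the previous flag set
    eligible = (corrected < 0.0) & (p_perm < VF_P_GATE) & ~crit1
    while True:
        has_flagged_nb = np.array(
            [any(flagged[j] for j in NEIGHBORS[i]) for i in range(N_LOCATIONS)]
        )
        new = eligible & has_flagged_nb & ~flagged
        if not new.any():
            break
        flagged |= new
        criterion[new] = 2

    out = []
    for i, f in enumerate(fits):
        s = aging_correct_vf(f.slope) if flagged[i] else 0.0
        out.append(LocationResult(slope_raw=f.slope, slope=s,
                                  p_perm=float(p_perm[i]),
                                  criterion=int(criterion[i])))
    return out


@dataclass
class SectorResult:
    slope_raw: float
    slope: float
    p_t: float
    p_perm: float
    progressing: bool


def detect_oct_progression(values: np.ndarray, years: np.ndarray,
                           rng: np.random.Generator | None = None,
                           n_perm: int = 5000) -> list[SectorResult]:
    """Apply the sector progression criterion to one eye's OCT series.

    ``values`` is (n_visits, 6) thicknesses in microns.  A sector is
    progressing iff its outlier-removed slope is below -0.1 microns/y and
    either null test rejects at 0.05.  No aging correction.
    """
    values = np.asarray(values, dtype=float)
    years = np.asarray(years, dtype=float)
    n = len(years)
    if values.shape != (n, N_SECTORS):
        raise ValueError("values must be (n_visits, 6) matching dates")
    if n < 3:
        raise ValueError("OCT criterion needs at least 3 visits")
    out = []
    for s in range(N_SECTORS):
        f = fit_slope(years, values[:, s], n_perm=n_perm, rng=rng)
        prog = (f.slope < OCT_SLOPE_CUTOFF) and \
            (min(f.p_t, f.p_perm) < OCT_P_GATE)
        out.append(SectorResult(slope_raw=f.slope,
                                slope=min(0.0, f.slope) if prog else 0.0,
                                p_t=f.p_t, p_perm=f.p_perm, progressing=prog))
    return out


def antiprogress(final_values: np.ndarray, slopes: np.ndarray,
                 n_visits: int = N_VISITS, gap_days: int = VISIT_GAP_DAYS,
                 cap_at_zero: bool = False) -> np.ndarray:
    """Noise-free series built backward from the final visit.

    Visit v (counting back from the last) takes value(v+1) - slope * dt
    with dt = gap_days / 365.25 years; slopes are <= 0, so values increase
    back in time.  With ``cap_at_zero`` (total-deviation series), a value
    that would exceed 0 is set to 0 and frozen for all earlier visits —
    the measurement-floor behaviour of TD.

    Returns an (n_visits, k) array whose last row equals ``final_values``.
    """
    final_values = np.asarray(final_values, dtype=float)
    slopes = np.asarray(slopes, dtype=float)
    if (slopes > 1e-12).any():
        raise ValueError("anti-progression requires slopes <= 0")
    dt = gap_days / DAYS_PER_YEAR
    series = np.empty((n_visits, final_values.size))
    series[-1] = final_values
    # a TD already above zero at the final visit is never anti-progressed
    frozen = (final_values > 0.0) if cap_at_zero \
        else np.zeros(final_values.size, dtype=bool)
    for v in range(n_visits - 2, -1, -1):
        nxt = series[v + 1]
        cand = np.where(frozen, nxt, nxt - slopes * dt)
        if cap_at_zero:
            hit = ~frozen & (cand > 0.0)
            cand = np.where(hit, 0.0, cand)
            frozen |= hit
        series[v] = cand
    return series


def build_truth(eye_id: str, final_td: np.ndarray, final_vf: np.ndarray,
                final_oct: np.ndarray, vf_slopes: np.ndarray,
                oct_slopes: np.ndarray, n_visits: int = N_VISITS,
                gap_days: int = VISIT_GAP_DAYS) -> EyeTruth:
    """Assemble an :class:`EyeTruth` with its anti-progressed series.

    The TD series carries the zero cap; the threshold series moves in
    lockstep through the per-location normative offset frozen at the final
    visit.  OCT sectors anti-progress without a cap.
    """
    final_td = np.asarray(final_td, dtype=float)
    final_vf = np.asarray(final_vf, dtype=float)
    offset = final_vf - final_td
    td_series = antiprogress(final_td, vf_slopes, n_visits, gap_days,
                             cap_at_zero=True)
    vf_series = td_series + offset
    oct_series = antiprogress(np.asarray(final_oct, dtype=float), oct_slopes,
                              n_visits, gap_days, cap_at_zero=False)
    return EyeTruth(
        eye_id=eye_id,
        final_td=VFMap(final_td, "total_deviation"),
        final_vf=VFMap(final_vf, "threshold"),
        final_oct=OCTSectors(final_oct),
        vf_slopes=np.minimum(vf_slopes, 0.0),
        oct_slopes=np.minimum(oct_slopes, 0.0),
        true_td=td_series, true_vf=vf_series, true_oct=oct_series,
        dates=visit_dates(n_visits=n_visits, gap_days=gap_days),
    )


def derive_truth_from_series(eye_id: str, vf_values: np.ndarray,
                             vf_years: np.ndarray, td_final: np.ndarray,
                             oct_values: np.ndarray, oct_years: np.ndarray,
                             rng: np.random.Generator | None = None) -> EyeTruth:
    """Full clinical-style pipeline: detect progression, then anti-progress.

    ``vf_values`` (visits x 52, raw dB) and ``oct_values`` (visits x 6) are
    the clinical-like input series; the final visit of each anchors the
    truth.  ``td_final`` gives the final-visit total deviations (defines the
    normative offset).
    """
    vf_res = detect_vf_progression(vf_values, vf_years, rng=rng)
    oct_res = detect_oct_progression(oct_values, oct_years, rng=rng)
    vf_slopes = np.array([r.slope for r in vf_res])
    oct_slopes = np.array([r.slope for r in oct_res])
    return build_truth(eye_id, td_final, vf_values[-1], oct_values[-1],
                       vf_slopes, oct_slopes)


def make_stable(truth: EyeTruth) -> EyeTruth:
    """Stable twin of a progressing eye: the final visit repeated 10 times.

    All true slopes become 0; idempotent.
    """
    if not truth.has_series:
        raise ValueError("truth has no series to stabilise")
    n = truth.true_td.shape[0]
    return EyeTruth(
        eye_id=truth.eye_id,
        final_td=truth.final_td, final_vf=truth.final_vf,
        final_oct=truth.final_oct,
        vf_slopes=np.zeros(N_LOCATIONS), oct_slopes=np.zeros(N_SECTORS),
        true_td=np.tile(truth.true_td[-1], (n, 1)),
        true_vf=np.tile(truth.true_vf[-1], (n, 1)),
        true_oct=np.tile(truth.true_oct[-1], (n, 1)),
        dates=list(truth.dates),
    )
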