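"""Perimetric measurement noise: Henson responder + Full Threshold staircase.

Measurement noise is not added as an additive error term.  Instead each
visit is *re-measured*: every location runs a Full Threshold 4-2 staircase
against a stochastic observer whose frequency-of-seeing curve is a
cumulative Gaussian with Henson-type spread (variability grows as
sensitivity falls), contaminated by false-positive and false-negative
response rates.  Noise therefore enters through seen/unseen responses and
through the spatial growth-pattern and decision logic of the staircase,
the way it does on the real instrument.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import erf, exp, sqrt

import numpy as np

from .grid import (GRID, N_LOCATIONS, NEIGHBORS, THRESHOLD_MAX,
                   THRESHOLD_MIN, location_index, normative_thresholds)

#: Henson frequency-of-seeing spread: sigma = min(cap, exp(A*t + B)).
HENSON_A = -0.081
HENSON_B = 3.27
HENSON_CAP = 6.0

#: Safety bound on staircase presentations (the walk is bounded well below).
MAX_PRESENTATIONS = 25

#: Global visit effect magnitude (dB) applied to one random visit.
GVE_SHIFT_DB = 2.0


@dataclass(frozen=True)
class ResponderParams:
    """Stochastic observer: Henson spread + false response rates."""

    A: float = HENSON_A
    B: float = HENSON_B
    sigma_cap: float = HENSON_CAP
    fp_rate: float = 0.03
    fn_rate: float = 0.01

    def __post_init__(self):
        if not (0.0 <= self.fp_rate <= 1.0 and 0.0 <= self.fn_rate <= 1.0):
            raise ValueError("false response rates must be in [0, 1]")
        if self.fp_rate + self.fn_rate >= 1.0:
            raise ValueError("fp_rate + fn_rate must be < 1")
        if self.sigma_cap <= 0:
            raise ValueError("sigma_cap must be positive")


@dataclass(frozen=True)
class NoiseCondition:
    name: str
    fp_rate: float
    fn_rate: float
    gve: bool

    @property
    def responder(self) -> ResponderParams:
        return ResponderParams(fp_rate=self.fp_rate, fn_rate=self.fn_rate)


#: The four shipped noise conditions.
NOISE_CONDITIONS = {
    "Reliable": NoiseCondition("Reliable", 0.03, 0.01, False),
    "Unreliable": NoiseCondition("Unreliable", 0.15, 0.03, False),
    "Reliable_gve": NoiseCondition("Reliable_gve", 0.03, 0.01, True),
    "Unreliable_gve": NoiseCondition("Unreliable_gve", 0.15, 0.03, True),
}


def henson_sigma(true_threshold: float,
                 params: ResponderParams = ResponderParams()) -> float:
    """Frequency-of-seeing spread (dB) at a true sensitivity.

    sigma = min(cap, exp(A*t + B)): ~2.3 dB at 30 dB sensitivity, rising to
    the 6 dB cap below ~18 dB, mirroring the loss of response reliability in
    damaged field regions.
    """
    return min(params.sigma_cap, exp(params.A * true_threshold + params.B))


def prob_seen(stimulus_db: float, true_threshold: float,
              params: ResponderParams) -> float:
    """P(respond seen) to a stimulus of ``stimulus_db`` (higher = dimmer)."""
    sigma = henson_sigma(true_threshold, params)
    z = (stimulus_db - true_threshold) / sigma
    p_detect = 1.0 - 0.5 * (1.0 + erf(z / sqrt(2.0)))
    return params.fp_rate + (1.0 - params.fp_rate - params.fn_rate) * p_detect


def respond(stimulus_db: float, true_threshold: float,
            params: ResponderParams, rng: np.random.Generator) -> bool:
    """One Bernoulli seen/not-seen response."""
    return bool(rng.random() < prob_seen(stimulus_db, true_threshold, params))


def ft_staircase(start_db: float, true_threshold: float,
                 params: ResponderParams, rng: np.random.Generator) -> float:
    """Full Threshold 4-2 staircase estimate of one location (dB).

    Stimuli step 4 dB (dimmer after seen, brighter after not seen) until the
    first response reversal, then 2 dB until the second reversal.  The
    estimate is the last seen stimulus level; a run that never elicits
    "seen" floors at 0 dB.  Levels are clamped to the instrument range
    [0, 40] dB; a not-seen response at 0 dB (or seen at 40 dB) ends the run.
    """
    level = float(np.clip(round(start_db), THRESHOLD_MIN, THRESHOLD_MAX))
    last_seen = None
    prev_response = None
    reversals = 0
    step = 4.0
    for _ in range(MAX_PRESENTATIONS):
        seen = respond(level, true_threshold, params, rng)
        if seen:
            last_seen = level
        if prev_response is not None and seen != prev_response:
            reversals += 1
            step = 2.0
            if reversals == 2:
                break
        prev_response = seen
        if not seen and level <= THRESHOLD_MIN:
            break  # cannot present brighter
        if seen and level >= THRESHOLD_MAX:
            break  # cannot present dimmer
        level = float(np.clip(level + (step if seen else -step),
                              THRESHOLD_MIN, THRESHOLD_MAX))
    return 0.0 if last_seen is None else last_seen


#: Primary growth-pattern seed locations, one per quadrant.
PRIMARY_POINTS = tuple(location_index(x, y)
                       for x in (-9, 9) for y in (9, -9))


def simulate_field(true_vf: np.ndarray, params: ResponderParams,
                   rng: np.random.Generator,
                   normative: np.ndarray | None = None) -> np.ndarray:
    """Measure a whole field through the staircase growth pattern.

    The four primary points (+/-9, +/-9) are thresholded first, starting at
    their age-normal values; every other location starts at the mean of its
    already-completed 8-neighbours (falling back to its normative value),
    spreading outward the way the instrument seeds its starting estimates.
    Returns the 52 measured thresholds (dB, in [0, 40]).
    """
    true_vf = np.asarray(true_vf, dtype=float)
    if true_vf.shape != (N_LOCATIONS,):
        raise ValueError("true field must have 52 values")
    norm = normative_thresholds() if normative is None else np.asarray(normative)
    measured = np.full(N_LOCATIONS, np.nan)
    for i in PRIMARY_POINTS:
        measured[i] = ft_staircase(norm[i], true_vf[i], params, rng)
    # breadth-first waves outward from the completed set, in export order
    while np.isnan(measured).any():
        done_before = ~np.isnan(measured)
        progressed = False
        for i in range(N_LOCATIONS):
            if done_before[i] or not np.isnan(measured[i]):
                continue
            nb = [j for j in NEIGHBORS[i] if done_before[j]]
            if nb:
                start = float(np.mean(measured[nb]))
                measured[i] = ft_staircase(start, true_vf[i], params, rng)
                progressed = True
        if not progressed:  # isolated region: fall back to normative starts
            for i in np.flatnonzero(np.isnan(measured)):
                measured[i] = ft_staircase(norm[i], true_vf[i], params, rng)
    return measured


def apply_gve(true_series: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Global visit effect: +/-2 dB to every location of one random visit.

    One visit index is drawn uniformly and a +2 or -2 dB shift (equal
    chance) is added to its true thresholds before measurement simulation;
    all other visits are untouched.
    """
    series = np.array(true_series, dtype=float)
    visit = int(rng.integers(series.shape[0]))
    sign = 1.0 if rng.random() < 0.5 else -1.0
    series[visit] += sign * GVE_SHIFT_DB
    return series


def eye_visit_rng(dataset_seed: int, eye_index: int,
                  visit_index: int) -> np.random.Generator:
    """Independent stream per (dataset, eye, visit).

    Keyed streams make each eye reproducible regardless of iteration order.
    """
    return np.random.default_rng(
        np.random.SeedSequence((dataset_seed, eye_index, visit_index)))


def simulate_series(true_vf_series: np.ndarray, condition: NoiseCondition,
                    dataset_seed: int, eye_index: int,
                    normative: np.ndarray | None = None) -> np.ndarray:
    """Measure all visits of one eye under a noise condition.

    Applies the global visit effect first when the condition calls for it
    (using the eye's visit-0 stream), then runs the staircase field
    simulation per visit on its own stream.
    """
    series = np.asarray(true_vf_series, dtype=float)
    params = condition.responder
    if condition.gve:
        # dedicated stream, outside the per-visit index range
        series = apply_gve(series,
                           eye_visit_rng(dataset_seed, eye_index, 9_999))
    out = np.empty_like(series)
    for v in range(series.shape[0]):
        rng = eye_visit_rng(dataset_seed, eye_index, v)
        out[v] = simulate_field(series[v], params, rng, normative=normative)
    return out
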