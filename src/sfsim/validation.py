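"""Operating-point harnesses for the progression criteria.

These Monte-Carlo harnesses measure the realised specificity/sensitivity
of the visual-field progression criteria under the same staircase
measurement noise the generator injects: simulate location series (or
whole fields) with known truth, re-measure every visit through the Full
Threshold staircase, and apply the criteria.

They are the package's own check that the conservative criterion design
holds its advertised operating point: ~99% specificity for the pointwise
slope rule, low sensitivity to -0.5 dB/y in short series, and >95%
specificity for the neighbour rule on stable fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import N_LOCATIONS
from .slopes import fit_slope
from .truth import VF_AGING_RATE, VF_P_GATE, detect_vf_progression, \
    vf_slope_cutoff
from .vfnoise import ResponderParams, ft_staircase, simulate_field

#: Harness defaults: age-normal sensitivity, annual visits.
DEFAULT_TRUE_DB = 30.0
ANNUAL_GAP_YEARS = 1.0


def simulate_location_series(n_visits: int, rng: np.random.Generator,
                             true_db: float = DEFAULT_TRUE_DB,
                             slope: float = 0.0,
                             responder: ResponderParams = ResponderParams(),
                             gap_years: float = ANNUAL_GAP_YEARS,
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Measured staircase series for one location with linear truth.

    Every visit is re-measured by a Full Threshold staircase started at the
    age-normal value.  Returns (years, measured dB).
    """
    years = np.arange(n_visits) * gap_years
    truth = true_db + slope * years
    measured = np.array([
        ft_staircase(DEFAULT_TRUE_DB, t, responder, rng) for t in truth])
    return years, measured


def criterion1_flags(years: np.ndarray, measured: np.ndarray,
                     rng: np.random.Generator) -> bool:
    """Criterion-1 decision for one location series.

    Outlier-removed slope (aging-corrected by +0.1 dB/y) below the
    length-dependent cutoff AND one-sided permutation p < 0.5.
    """
    f = fit_slope(years, measured, rng=rng)
    corrected = f.slope + VF_AGING_RATE
    return bool(corrected < vf_slope_cutoff(len(years))
                and f.p_perm < VF_P_GATE)


@dataclass
class Criterion1Result:
    per_length: dict[int, float]  # flag rate per series length
    n_per_length: int

    @property
    def pooled_rate(self) -> float:
        return float(np.mean(list(self.per_length.values())))


def criterion1_rates(lengths, n_series: int, slope: float,
                     rng: np.random.Generator,
                     responder: ResponderParams = ResponderParams(),
                     ) -> Criterion1Result:
    """Criterion-1 flag rate by series length at a fixed true slope.

    ``slope=0`` measures the false-flag rate (1 - specificity);
    a negative slope measures sensitivity.
    """
    rates = {}
    for n in lengths:
        flags = 0
        for _ in range(n_series):
            years, measured = simulate_location_series(
                n, rng, slope=slope, responder=responder)
            flags += criterion1_flags(years, measured, rng)
        rates[n] = flags / n_series
    return Criterion1Result(per_length=rates, n_per_length=n_series)


@dataclass
class NeighborRuleResult:
    n_fields: int
    n_locations: int          # truly stable locations not flagged by c1
    n_c1_flagged: int         # criterion-1 false flags (stable truth)
    n_added: int              # all criterion-2 additions (chains included)
    n_added_direct: int       # additions adjacent to a criterion-1 flag
    n_eligible: int           # stable locations adjacent to a c1 flag

    @property
    def c1_flag_rate(self) -> float:
        total = self.n_locations + self.n_c1_flagged
        return self.n_c1_flagged / total

    @property
    def specificity(self) -> float:
        """1 - P(stable location falsely added next to a false c1 flag).

        The pair mechanism the rule's design bounds by
        P(false criterion-1 neighbour) * P(own permutation p < 0.5).
        """
        return 1.0 - self.n_added_direct / self.n_locations

    @property
    def chain_specificity(self) -> float:
        """As above but counting every addition of the iterated rule.

        Chained additions (an added location qualifying its own
        neighbours) make this noticeably lower than the pair bound; see
        the methods note.
        """
        return 1.0 - self.n_added / self.n_locations


def neighbor_rule_specificity(n_fields: int, n_visits: int,
                              rng: np.random.Generator,
                              true_db: float = DEFAULT_TRUE_DB,
                              responder: ResponderParams = ResponderParams(),
                              ) -> NeighborRuleResult:
    """Criterion-2 error rate on fully stable simulated fields.

    Simulates flat 52-location fields through the staircase, runs
    criterion 1 and the criterion-2 fixed point, and counts how many truly
    stable locations the neighbour rule adds.  Criterion-1 false flags
    arise at their natural rate and seed the rule, so the measured
    addition rate is the unconditional error the rule's design bounds by
    P(false criterion-1 neighbour) * P(own permutation p < 0.5).
    """
    from .grid import NEIGHBORS

    years = np.arange(n_visits, dtype=float)
    truth = np.full(N_LOCATIONS, true_db)
    n_c1 = n_added = n_direct = n_eligible = n_stable = 0
    for _ in range(n_fields):
        measured = np.array([simulate_field(truth, responder, rng)
                             for _ in range(n_visits)])
        res = detect_vf_progression(measured, years, rng=rng)
        crit = np.array([r.criterion for r in res])
        c1 = crit == 1
        n_c1 += int(c1.sum())
        n_added += int((crit == 2).sum())
        stable = ~c1
        n_stable += int(stable.sum())
        for i in np.flatnonzero(stable):
            next_to_c1 = any(c1[j] for j in NEIGHBORS[i])
            n_eligible += next_to_c1
            n_direct += next_to_c1 and crit[i] == 2
    return NeighborRuleResult(n_fields=n_fields, n_locations=n_stable,
                              n_c1_flagged=n_c1, n_added=n_added,
                              n_added_direct=n_direct,
                              n_eligible=n_eligible)
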