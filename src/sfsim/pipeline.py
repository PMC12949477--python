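"""End-to-end dataset generation: seeds -> truth -> measured bundles.

The canonical release layout is eight datasets from one truth population:
four progressing (noise conditions Reliable, Unreliable, Reliable_gve,
Unreliable_gve with RNG seeds 1-4) and four stable twins (the final visit
repeated, seeds 5-8).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .grid import THRESHOLD_MAX
from .octnoise import OCTNoiseTable, add_oct_noise
from .records import (CONDITIONS, DatasetBundle, EyeTruth, MeasuredSeries,
                      Person)
from .seeds import SeedConfig, sample_population
from .truth import build_truth, make_stable
from .vfnoise import NOISE_CONDITIONS, eye_visit_rng, simulate_series

log = logging.getLogger(__name__)

#: Canonical (condition, seed) pairing for a release.
PROGRESSING_SEEDS = dict(zip(CONDITIONS, (1, 2, 3, 4)))
STABLE_SEEDS = dict(zip(CONDITIONS, (5, 6, 7, 8)))


def truth_population(cfg: SeedConfig) -> tuple[list[EyeTruth], list[Person]]:
    """Sample seed eyes and anti-progress each into a 10-visit truth."""
    seeds, persons = sample_population(cfg)
    truths = [build_truth(t.eye_id, t.final_td.values, t.final_vf.values,
                          t.final_oct.values, t.vf_slopes, t.oct_slopes)
              for t in seeds]
    log.info("truth population: %d eyes, mean progressing locations %.1f",
             len(truths),
             float(np.mean([(t.vf_slopes < 0).sum() for t in truths])))
    return truths, persons


def measure_bundle(truths: list[EyeTruth], condition: str, seed: int,
                   status: str, persons: list[Person] | None = None,
                   oct_table: OCTNoiseTable | None = None) -> DatasetBundle:
    """Add measurement noise to a truth population under one condition.

    VF visits are re-measured through the staircase simulator (with the
    global visit effect when the condition carries one); OCT noise is
    additive Gaussian per sector.  Each eye draws from keyed RNG streams of
    ``seed`` so results are order-independent.
    """
    cond = NOISE_CONDITIONS[condition]
    eyes = []
    for idx, t in enumerate(truths):
        if not t.has_series:
            raise ValueError(f"truth {t.eye_id} has no series")
        vf = simulate_series(t.true_vf, cond, seed, idx)
        vf = np.clip(vf, 0.0, THRESHOLD_MAX)
        td = vf - t.normative_offset[None, :]
        oct_rng = eye_visit_rng(seed, idx, 10_000)
        oc = add_oct_noise(t.true_oct, oct_rng, table=oct_table)
        eyes.append(MeasuredSeries(eye_id=t.eye_id, vf_measured=vf,
                                   td_measured=td, oct_measured=oc,
                                   condition=condition, rng_seed=seed,
                                   dates=list(t.dates)))
    return DatasetBundle(eyes=eyes, truth=truths, status=status,
                         condition=condition, rng_seed=seed,
                         persons=list(persons or []))


def generate_release(cfg: SeedConfig, out_dir: str | Path | None = None,
                     conditions: tuple[str, ...] = CONDITIONS,
                     progressing_seeds: dict | None = None,
                     stable_seeds: dict | None = None,
                     ) -> dict[str, DatasetBundle]:
    """Generate the full progressing + stable release.

    Returns bundles keyed ``<condition>_<status>``; writes each to a
    directory under ``out_dir`` when given.
    """
    from .io import write_bundle

    progressing_seeds = progressing_seeds or PROGRESSING_SEEDS
    stable_seeds = stable_seeds or STABLE_SEEDS
    truths, persons = truth_population(cfg)
    stable_truths = [make_stable(t) for t in truths]

    bundles: dict[str, DatasetBundle] = {}
    for condition in conditions:
        for status, truth_set, seeds in (
                ("progressing", truths, progressing_seeds),
                ("stable", stable_truths, stable_seeds)):
            b = measure_bundle(truth_set, condition, seeds[condition],
                               status, persons)
            key = f"{condition}_{status}"
            bundles[key] = b
            if out_dir is not None:
                write_bundle(b, Path(out_dir) / key, name=key)
                log.info("wrote %s (seed %d)", key, b.rng_seed)
    return bundles
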