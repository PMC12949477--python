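"""Readers/writers for the released CSV dialect, manifests, seed bookkeeping.

A generated dataset is a directory:

    data.csv     one row per eye-visit: eye_id, visit, date,
                 vf.1..vf.52, td.1..td.52, oct.T..oct.TI (measured values)
    truth.csv    same layout for the noise-free true series
    slopes.csv   long-format sidecar: eye_id, channel, slope, criterion
                 (channel is vf.<i> or oct.<sector>; criterion records how
                 the slope was accepted: 1, 2, oct, or seed)
    person.csv   person_id, sex, age (age at final visit)
    manifest.json  name, status, condition, rng_seed, generator version,
                 SHA-256 checksums of the CSVs

Seeds 1-8 are flagged as reserved for the canonical release; any seed
below 103 raises a warning so user-generated variants cannot collide with
released noise realisations.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .grid import N_LOCATIONS
from .records import (DatasetBundle, EyeTruth, MeasuredSeries, OCTSectors,
                      Person, SECTORS, VFMap)

RESERVED_SEEDS = frozenset(range(1, 9))
RESERVED_BELOW = 103

VF_COLS = [f"vf.{i}" for i in range(1, N_LOCATIONS + 1)]
TD_COLS = [f"td.{i}" for i in range(1, N_LOCATIONS + 1)]
OCT_COLS = [f"oct.{s}" for s in SECTORS]
DATA_COLS = ["eye_id", "visit", "date"] + VF_COLS + TD_COLS + OCT_COLS


class ReservedSeedWarning(UserWarning):
    """Raised for seeds reserved for released datasets."""


def check_seed(seed: int) -> None:
    """Warn when a seed collides with the reserved release range."""
    if seed in RESERVED_SEEDS:
        warnings.warn(f"seed {seed} is reserved for the canonical release "
                      "(seeds 1-8)", ReservedSeedWarning, stacklevel=2)
    elif seed < RESERVED_BELOW:
        warnings.warn(f"seeds below {RESERVED_BELOW} are reserved for future "
                      f"releases (got {seed})", ReservedSeedWarning,
                      stacklevel=2)


def _series_frame(eye_id: str, dates: list[date], vf: np.ndarray,
                  td: np.ndarray, oct_: np.ndarray) -> pd.DataFrame:
    n = vf.shape[0]
    head = pd.DataFrame({"eye_id": eye_id, "visit": np.arange(1, n + 1),
                         "date": [d.isoformat() for d in dates]})
    body = pd.DataFrame(
        np.round(np.hstack([vf, td, oct_]), 2),
        columns=VF_COLS + TD_COLS + OCT_COLS)
    return pd.concat([head, body], axis=1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_bundle(bundle: DatasetBundle, path: str | Path,
                 name: str | None = None) -> dict:
    """Write one dataset directory; returns the manifest dict."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    check_seed(bundle.rng_seed)

    data = pd.concat(
        [_series_frame(e.eye_id, e.dates, e.vf_measured, e.td_measured,
                       e.oct_measured) for e in bundle.eyes],
        ignore_index=True)[DATA_COLS]
    data.to_csv(path / "data.csv", index=False)

    truth = pd.concat(
        [_series_frame(t.eye_id, t.dates, t.true_vf, t.true_td, t.true_oct)
         for t in bundle.truth], ignore_index=True)[DATA_COLS]
    truth.to_csv(path / "truth.csv", index=False)

    rows = []
    for t in bundle.truth:
        crit = getattr(t, "criteria", None)
        for i in range(N_LOCATIONS):
            rows.append((t.eye_id, f"vf.{i + 1}", round(t.vf_slopes[i], 4),
                         crit["vf"][i] if crit else "seed"))
        for i, s in enumerate(SECTORS):
            rows.append((t.eye_id, f"oct.{s}", round(t.oct_slopes[i], 4),
                         crit["oct"][i] if crit else "seed"))
    pd.DataFrame(rows, columns=["eye_id", "channel", "slope", "criterion"]) \
        .to_csv(path / "slopes.csv", index=False)

    pd.DataFrame([(p.person_id, p.sex, p.age) for p in bundle.persons],
                 columns=["person_id", "sex", "age"]) \
        .to_csv(path / "person.csv", index=False)

    manifest = {
        "name": name or f"{bundle.condition}_{bundle.status}",
        "status": bundle.status,
        "condition": bundle.condition,
        "rng_seed": bundle.rng_seed,
        "reserved": bundle.rng_seed < RESERVED_BELOW,
        "generator_version": __version__,
        "checksums": {f: _sha256(path / f)
                      for f in ("data.csv", "truth.csv", "slopes.csv",
                                "person.csv")},
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _frames_to_series(df: pd.DataFrame):
    for eye_id, g in df.groupby("eye_id", sort=False):
        g = g.sort_values("visit")
        dates = [date.fromisoformat(d) for d in g["date"]]
        yield (eye_id, dates, g[VF_COLS].to_numpy(float),
               g[TD_COLS].to_numpy(float), g[OCT_COLS].to_numpy(float))


def read_bundle(path: str | Path) -> DatasetBundle:
    """Re-read a dataset directory written by :func:`write_bundle`."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    data = pd.read_csv(path / "data.csv")
    truth_df = pd.read_csv(path / "truth.csv")
    slopes = pd.read_csv(path / "slopes.csv")

    eyes = [MeasuredSeries(eye_id=eid, vf_measured=vf, td_measured=td,
                           oct_measured=oc, condition=manifest["condition"],
                           rng_seed=manifest["rng_seed"], dates=dates)
            for eid, dates, vf, td, oc in _frames_to_series(data)]

    truth = []
    slope_map = {eid: g.set_index("channel")["slope"]
                 for eid, g in slopes.groupby("eye_id", sort=False)}
    for eid, dates, vf, td, oc in _frames_to_series(truth_df):
        s = slope_map[eid]
        truth.append(EyeTruth(
            eye_id=eid,
            final_td=VFMap(td[-1], "total_deviation"),
            final_vf=VFMap(vf[-1], "threshold"),
            final_oct=OCTSectors(oc[-1]),
            vf_slopes=np.array([s[f"vf.{i + 1}"]
                                for i in range(N_LOCATIONS)]),
            oct_slopes=np.array([s[f"oct.{sec}"] for sec in SECTORS]),
            true_td=td, true_vf=vf, true_oct=oc, dates=dates))

    persons_df = pd.read_csv(path / "person.csv")
    persons = [Person(str(r.person_id), str(r.sex), float(r.age))
               for r in persons_df.itertuples()]
    return DatasetBundle(eyes=eyes, truth=truth, status=manifest["status"],
                         condition=manifest["condition"],
                         rng_seed=manifest["rng_seed"], persons=persons)


SEED_COLS = ["eye_id"] + VF_COLS + TD_COLS + OCT_COLS


def write_seeds(eyes: list[EyeTruth], persons: list[Person],
                path: str | Path) -> None:
    """Write seed eyes (final visits + slopes, no series) as CSVs."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in eyes:
        row = {"eye_id": t.eye_id}
        row.update({c: round(v, 2)
                    for c, v in zip(VF_COLS, t.final_vf.values)})
        row.update({c: round(v, 2)
                    for c, v in zip(TD_COLS, t.final_td.values)})
        row.update({c: round(v, 2)
                    for c, v in zip(OCT_COLS, t.final_oct.values)})
        rows.append(row)
    pd.DataFrame(rows, columns=SEED_COLS).to_csv(path / "seeds.csv",
                                                 index=False)
    srows = []
    for t in eyes:
        for i in range(N_LOCATIONS):
            srows.append((t.eye_id, f"vf.{i + 1}", round(t.vf_slopes[i], 4)))
        for i, s in enumerate(SECTORS):
            srows.append((t.eye_id, f"oct.{s}", round(t.oct_slopes[i], 4)))
    pd.DataFrame(srows, columns=["eye_id", "channel", "slope"]) \
        .to_csv(path / "slopes.csv", index=False)
    pd.DataFrame([(p.person_id, p.sex, p.age) for p in persons],
                 columns=["person_id", "sex", "age"]) \
        .to_csv(path / "person.csv", index=False)


def read_seeds(path: str | Path) -> tuple[list[EyeTruth], list[Person]]:
    """Read seed eyes written by :func:`write_seeds` (series unfilled)."""
    path = Path(path)
    seeds = pd.read_csv(path / "seeds.csv")
    slopes = pd.read_csv(path / "slopes.csv")
    slope_map = {eid: g.set_index("channel")["slope"]
                 for eid, g in slopes.groupby("eye_id", sort=False)}
    eyes = []
    for _, vals in seeds.iterrows():
        eid = vals["eye_id"]
        s = slope_map[eid]
        eyes.append(EyeTruth(
            eye_id=eid,
            final_vf=VFMap(vals[VF_COLS].to_numpy(float), "threshold"),
            final_td=VFMap(vals[TD_COLS].to_numpy(float), "total_deviation"),
            final_oct=OCTSectors(vals[OCT_COLS].to_numpy(float)),
            vf_slopes=np.array([s[f"vf.{i + 1}"]
                                for i in range(N_LOCATIONS)]),
            oct_slopes=np.array([s[f"oct.{sec}"] for sec in SECTORS])))
    persons_df = pd.read_csv(path / "person.csv")
    persons = [Person(str(r.person_id), str(r.sex), float(r.age))
               for r in persons_df.itertuples()]
    return eyes, persons
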