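"""Reading, writing and validation of e-nose sample curves.

A measurement is the baseline-relative response of a 10-sensor MOS array
(PEN3-style) recorded once per second for 100 s: a 100 x 10 matrix of
G/G0 conductivity ratios, labelled with the pork weight-fraction mixed
into the minced-beef sample and with the day/session it was measured on.

On disk a dataset is a pair of plain CSV files:

* ``curves.csv``  — long format, columns ``sample_id, t_s, W1C, ..., W3S``
  with 100 rows per sample (``t_s`` in 1..100 seconds);
* ``manifest.csv`` — one row per sample,
  columns ``sample_id, day, session, proportion_percent``.

Proportions are stored as percent in files (0–60) but held as fractions
in [0, 1] in memory; the conversion happens only at this I/O boundary.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .synth import StudyDesign

#: PEN3 sensor names, in instrument column order.
PEN3_SENSORS: tuple[str, ...] = (
    "W1C", "W5S", "W3C", "W6S", "W5C", "W1S", "W1W", "W2S", "W2W", "W3S",
)

#: Number of 1-s samples in the collection stage.
N_TIMEPOINTS: int = 100

#: Adulteration fractions used in the study design (0–60 % in 10 % steps).
DESIGN_PROPORTIONS: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6)

SESSIONS = ("A", "B")


class DatasetFormatError(ValueError):
    """A CSV file is structurally malformed (missing column, bad layout)."""


class SampleValidationError(ValueError):
    """A sample violates an invariant (non-positive ratio, wrong length...)."""


@dataclass
class ENoseSample:
    """One e-nose measurement of an adulterated meat sample.

    Parameters
    ----------
    sample_id
        Unique identifier.
    day
        Measurement day, 1-based.
    session
        ``"A"`` (morning) or ``"B"`` (afternoon).
    proportion
        Pork weight-fraction in the beef, as a fraction in [0, 1].
    curves
        ``(100, 10)`` array of G/G0 ratios; rows are seconds 1..100,
        columns follow ``sensor_names``.
    sensor_names
        Ordered sensor labels matching the curve columns.
    """

    sample_id: str
    day: int
    session: str
    proportion: float
    curves: np.ndarray
    sensor_names: tuple[str, ...] = PEN3_SENSORS

    def __post_init__(self) -> None:
        self.curves = np.asarray(self.curves, dtype=float)

    def stable_window(self) -> np.ndarray:
        """Rows for seconds 91..100 (the plateau), shape ``(10, 10)``."""
        return self.curves[N_TIMEPOINTS - 10:N_TIMEPOINTS, :]


def validate_sample(
    sample: ENoseSample, design_conformant: bool = False
) -> list[str]:
    """Return a list of human-readable invariant violations (empty if valid).

    With ``design_conformant=True`` the proportion must additionally sit on
    the study grid {0, 0.1, ..., 0.6}.
    """
    issues: list[str] = []
    c = sample.curves
    if c.ndim != 2 or c.shape[1] != len(sample.sensor_names):
        issues.append(
            f"sample {sample.sample_id}: curves shape {c.shape} does not match "
            f"{len(sample.sensor_names)} sensors"
        )
        return issues
    if c.shape[0] != N_TIMEPOINTS:
        issues.append(
            f"sample {sample.sample_id}: expected {N_TIMEPOINTS} time points, "
            f"got {c.shape[0]}"
        )
    if len(set(sample.sensor_names)) != len(sample.sensor_names):
        issues.append(f"sample {sample.sample_id}: duplicate sensor names")
    bad = ~(np.isfinite(c) & (c > 0))
    if bad.any():
        t, s = np.argwhere(bad)[0]
        issues.append(
            f"sample {sample.sample_id}: non-positive or non-finite G/G0 "
            f"value at t={t + 1} s, sensor {sample.sensor_names[s]}"
        )
    if not 0.0 <= sample.proportion <= 1.0:
        issues.append(
            f"sample {sample.sample_id}: proportion {sample.proportion} "
            f"outside [0, 1]"
        )
    if sample.day < 1:
        issues.append(f"sample {sample.sample_id}: day {sample.day} < 1")
    if sample.session not in SESSIONS:
        issues.append(
            f"sample {sample.sample_id}: session {sample.session!r} not in "
            f"{SESSIONS}"
        )
    if design_conformant and not any(
        abs(sample.proportion - p) < 1e-9 for p in DESIGN_PROPORTIONS
    ):
        issues.append(
            f"sample {sample.sample_id}: proportion {sample.proportion} is "
            f"off the design grid {DESIGN_PROPORTIONS}"
        )
    return issues


@dataclass
class Dataset:
    """Ordered collection of :class:`ENoseSample` sharing a sensor array."""

    samples: list[ENoseSample] = field(default_factory=list)
    design: "StudyDesign | None" = None

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def __getitem__(self, i: int) -> ENoseSample:
        return self.samples[i]

    @property
    def sensor_names(self) -> tuple[str, ...]:
        return self.samples[0].sensor_names if self.samples else PEN3_SENSORS

    def labels(self) -> np.ndarray:
        """Per-sample adulteration fractions, in sample order."""
        return np.array([s.proportion for s in self.samples])

    def days(self) -> np.ndarray:
        return np.array([s.day for s in self.samples])

    def subset(self, indices: Iterable[int]) -> "Dataset":
        return Dataset(samples=[self.samples[i] for i in indices],
                       design=self.design)

    def validate(self, design_conformant: bool = False) -> list[str]:
        issues: list[str] = []
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            issues.append(f"duplicate sample_id(s): {dup}")
        names = {s.sensor_names for s in self.samples}
        if len(names) > 1:
            issues.append("samples disagree on sensor names/order")
        for s in self.samples:
            issues.extend(validate_sample(s, design_conformant))
        return issues


def _resolve_pair(manifest_path: str | Path) -> tuple[Path, Path]:
    """Map a manifest path (or a directory) to (manifest.csv, curves.csv)."""
    p = Path(manifest_path)
    if p.is_dir():
        return p / "manifest.csv", p / "curves.csv"
    name = p.name.replace("manifest", "curves")
    if name == p.name:
        return p, p.with_name("curves.csv")
    return p, p.with_name(name)


def read_dataset(manifest_path: str | Path) -> Dataset:
    """Load a dataset from a manifest CSV (curves CSV resolved alongside).

    ``manifest_path`` may be the manifest file itself or the directory
    holding the ``manifest.csv`` / ``curves.csv`` pair. Manifest row order
    is preserved; every sample is validated on load.
    """
    man_path, cur_path = _resolve_pair(manifest_path)
    manifest = pd.read_csv(man_path, dtype={"sample_id": str})
    for col in ("sample_id", "day", "session", "proportion_percent"):
        if col not in manifest.columns:
            raise DatasetFormatError(
                f"{man_path}: missing manifest column {col!r}"
            )
    curves = pd.read_csv(cur_path, dtype={"sample_id": str})
    if "sample_id" not in curves.columns or "t_s" not in curves.columns:
        raise DatasetFormatError(
            f"{cur_path}: curves CSV must have 'sample_id' and 't_s' columns"
        )
    sensor_names = tuple(
        c for c in curves.columns if c not in ("sample_id", "t_s")
    )
    by_id = dict(tuple(curves.groupby("sample_id", sort=False)))
    samples: list[ENoseSample] = []
    for row in manifest.itertuples(index=False):
        sid = row.sample_id
        if sid not in by_id:
            raise DatasetFormatError(f"sample {sid}: no curve rows found")
        block = by_id[sid].sort_values("t_s")
        if len(block) != N_TIMEPOINTS:
            raise SampleValidationError(
                f"sample {sid}: expected {N_TIMEPOINTS} time points, "
                f"got {len(block)}"
            )
        sample = ENoseSample(
            sample_id=sid,
            day=int(row.day),
            session=str(row.session),
            proportion=float(row.proportion_percent) / 100.0,
            curves=block[list(sensor_names)].to_numpy(dtype=float),
            sensor_names=sensor_names,
        )
        issues = validate_sample(sample)
        if issues:
            raise SampleValidationError("; ".join(issues))
        samples.append(sample)
    return Dataset(samples=samples)


def write_dataset(dataset: Dataset, out_path: str | Path) -> None:
    """Write ``manifest.csv`` and ``curves.csv`` into directory ``out_path``.

    Refuses datasets with duplicate sample ids or invalid samples. An
    empty dataset produces header-only files.
    """
    issues = dataset.validate()
    if issues:
        raise SampleValidationError(
            "refusing to write invalid dataset: " + "; ".join(issues)
        )
    out = Path(out_path)
    out.mkdir(parents=True, exist_ok=True)
    sensors = list(dataset.sensor_names)
    man = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in dataset],
            "day": [s.day for s in dataset],
            "session": [s.session for s in dataset],
            "proportion_percent": [round(s.proportion * 100.0, 10)
                                   for s in dataset],
        },
        columns=["sample_id", "day", "session", "proportion_percent"],
    )
    man.to_csv(out / "manifest.csv", index=False)
    blocks = []
    for s in dataset:
        block = pd.DataFrame(s.curves, columns=sensors)
        block.insert(0, "t_s", np.arange(1, N_TIMEPOINTS + 1))
        block.insert(0, "sample_id", s.sample_id)
        blocks.append(block)
    if blocks:
        curves = pd.concat(blocks, ignore_index=True)
    else:
        curves = pd.DataFrame(columns=["sample_id", "t_s", *sensors])
    curves.to_csv(out / "curves.csv", index=False)
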