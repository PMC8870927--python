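"""Model-input representations and day-blocked splitting.

Two representations feed the estimators:

* **Stable values (SV)** — the plateau segment, seconds 91..100, of each
  curve. Each of the 10 retained time points becomes an independent row
  of 10 sensor readings, so a dataset of ``n`` samples yields a
  ``(10 n, 10)`` matrix with the label repeated over a sample's rows.
  This is the input to the SVR / RFR / BPNN baselines.
* **Multichannel input** — the full 100-point curves transposed to a
  ``(10 channels, 100)`` matrix per sample, stacked into an
  ``(n, 10, 100)`` tensor for the CNN models. No scaling is applied:
  G/G0 ratios are already baseline-relative.

Train/test splits are blocked by measurement day ("first N days" train),
which tests generalization across days rather than within-day
interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Dataset, ENoseSample, N_TIMEPOINTS

#: Stable-value window: seconds 91..100 inclusive (1-based).
SV_START_S = 91
SV_POINTS = N_TIMEPOINTS - SV_START_S + 1


@dataclass
class SVMatrix:
    """Stacked stable-value rows with per-row labels.

    ``rows`` is ``(10 * n_samples, n_sensors)``; ``labels`` repeats each
    sample's fraction over its 10 rows; ``sample_index`` maps each row
    back to its sample_id.
    """

    rows: np.ndarray
    labels: np.ndarray
    sample_index: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.rows.shape[0] // SV_POINTS

    def per_sample_labels(self) -> np.ndarray:
        return self.labels[::SV_POINTS]

    def per_sample_ids(self) -> np.ndarray:
        return self.sample_index[::SV_POINTS]


@dataclass
class MultichannelInput:
    """CNN input tensor ``(n_samples, 10 channels, 100)`` plus labels."""

    tensor: np.ndarray
    labels: np.ndarray
    sample_ids: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.tensor.shape[0]


def extract_stable_values(sample: ENoseSample) -> np.ndarray:
    """Return the ``(10, 10)`` stable-value block (seconds 91..100)."""
    if sample.curves.shape[0] != N_TIMEPOINTS:
        raise ValueError(
            f"sample {sample.sample_id}: expected {N_TIMEPOINTS} time "
            f"points, got {sample.curves.shape[0]}"
        )
    return sample.curves[SV_START_S - 1:N_TIMEPOINTS, :]


def build_sv_matrix(dataset: Dataset) -> SVMatrix:
    """Stack stable-value rows over a dataset, in dataset order."""
    if len(dataset) == 0:
        raise ValueError("cannot build an SV matrix from an empty dataset")
    rows = np.vstack([extract_stable_values(s) for s in dataset])
    labels = np.repeat(dataset.labels(), SV_POINTS)
    idx = np.repeat([s.sample_id for s in dataset], SV_POINTS)
    return SVMatrix(rows=rows, labels=labels, sample_index=idx)


def to_multichannel(dataset: Dataset) -> MultichannelInput:
    """Transpose each 100 x 10 curve matrix to a 10 x 100 channel block."""
    if len(dataset) == 0:
        raise ValueError("cannot build a multichannel input from an empty "
                         "dataset")
    tensor = np.stack([s.curves.T for s in dataset])
    return MultichannelInput(
        tensor=tensor,
        labels=dataset.labels(),
        sample_ids=np.array([s.sample_id for s in dataset]),
    )


def split_by_day(dataset: Dataset, train_days: int) -> tuple[Dataset, Dataset]:
    """Day-blocked split: days <= ``train_days`` train, the rest test.

    The split is a partition of the dataset, order-preserving within
    each part; "first N days" refers to the integer ``day`` field.
    """
    days = dataset.days()
    n_days = int(days.max()) if len(dataset) else 0
    if not 1 <= train_days < n_days:
        raise ValueError(
            f"train_days must be in [1, {n_days - 1}], got {train_days}"
        )
    train_idx = [i for i, d in enumerate(days) if d <= train_days]
    test_idx = [i for i, d in enumerate(days) if d > train_days]
    return dataset.subset(train_idx), dataset.subset(test_idx)
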