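"""Seeded synthetic e-nose data generator.

Real MOS response curves to headspace gas from adulterated minced beef
rise smoothly from the G/G0 = 1 baseline and plateau before the end of
the 100 s collection stage. The simulator reproduces that phenomenology
with a deliberately simple generative model:

    curve_s(t) = 1 + dir_s * A_s * (1 - exp(-t / tau_s(p))) + eps_t

* ``tau_s(p) = tau_s / (1 + kinetic_gain * p)`` is the saturation time
  constant: richer headspace saturates MOS surfaces faster, so the rise
  kinetics themselves carry (drift-robust) information about the pork
  fraction. Baseline taus are capped so every curve reaches >= 99 % of
  its asymptote by 90 s;
* ``A_s`` is the plateau amplitude: sensor loadings applied to a small
  set of latent volatile factors whose intensities increase monotonically
  (affine plus a mild quadratic) with the pork fraction ``p``,
  modulated by nuisance terms that emulate real campaigns —
  a per-(day, session) factor shift (meat batch / ambient conditions),
  a per-(day, session, sensor) sensitivity drift (MOS gain instability),
  a per-sample factor jitter (heterogeneity of individual minced
  samples), and a per-sample per-sensor gain term (adsorption
  repeatability). Together these make neighbouring proportions overlap
  in stable-value space, as observed on real data;
* the response term of every sensor is additionally scaled by a shared
  per-second fluctuation (delivery-flow instability), which inflates
  single-second stable-value rows but averages out over a full curve;
* ``eps_t`` is iid Gaussian measurement noise;
* ``dir_s`` is +1 or -1: some PEN3 channels (W1C, W3C, W5C) respond
  below baseline for meat volatiles.

Cross-sensitivity is encoded by giving every sensor non-zero loadings on
several factors, so sensor signals are correlated but not collinear.
Amplitude magnitudes are order-of-magnitude choices (plateaus roughly
1.5-3.5 on the strongest channels, mild dips on the negative ones) and
all live in the sensor bank, which is plain data and can be serialized
to YAML/JSON.

Seeding is hierarchical (seed -> per-(day, session) -> per-sample) so any
subset of the design is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .io import Dataset, ENoseSample, N_TIMEPOINTS, PEN3_SENSORS

#: Latent volatile factors: shared meaty volatiles, pork-associated
#: volatiles, and lipid-oxidation/sulfur compounds.
N_FACTORS = 3

_FACTOR_BASE = np.array([0.80, 0.05, 0.30])   # intensity at p = 0 (pure beef)
_FACTOR_SLOPE = np.array([0.60, 1.60, 0.90])  # gain per unit pork fraction
_NONLIN = 0.25  # mild quadratic curvature of intensity vs proportion

#: Relative acceleration of saturation kinetics per unit pork fraction.
KINETIC_GAIN = 0.5


@dataclass
class SensorModel:
    """Response model for one MOS channel.

    ``amplitude_loadings`` maps latent factor intensities to the plateau
    amplitude; ``saturation_tau`` (s) sets the rise kinetics; ``noise_sd``
    is the per-second measurement noise in ratio units; ``direction`` is
    +1 for above-baseline channels and -1 for below-baseline ones.
    """

    name: str
    amplitude_loadings: np.ndarray
    saturation_tau: float
    noise_sd: float = 0.02
    direction: int = 1
    baseline: float = 1.0

    def __post_init__(self) -> None:
        self.amplitude_loadings = np.asarray(self.amplitude_loadings, float)
        if self.saturation_tau <= 0:
            raise ValueError("saturation_tau must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")


@dataclass
class StudyDesign:
    """Replication structure of a measurement campaign."""

    n_days: int = 10
    sessions: tuple[str, ...] = ("A", "B")
    proportions: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6)
    samples_per_proportion_per_day_per_session: int = 3
    seed: int = 0
    day_effect_sd: float = 0.03
    sensor_drift_sd: float = 0.02
    sample_jitter_sd: float = 0.01
    sample_gain_sd: float = 0.02
    flow_noise_sd: float = 0.06
    kinetic_gain: float = KINETIC_GAIN

    def __post_init__(self) -> None:
        if self.n_days < 1 or not self.sessions:
            raise ValueError("need at least one day and one session")
        if self.samples_per_proportion_per_day_per_session < 1:
            raise ValueError("need at least one replicate")
        if any(not 0.0 <= p <= 1.0 for p in self.proportions):
            raise ValueError("proportions must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return (self.n_days * len(self.sessions) * len(self.proportions)
                * self.samples_per_proportion_per_day_per_session)


# Loadings rows follow PEN3_SENSORS order; columns are the latent factors.
# W1C, W3C, W5C get direction -1 and small loadings so curves stay positive.
_DEFAULT_BANK = {
    #         loadings              tau    noise  dir
    "W1C": ((0.20, 0.10, 0.05), 15.5, 0.015, -1),
    "W5S": ((0.50, 1.20, 0.40), 18.0, 0.025, +1),
    "W3C": ((0.15, 0.12, 0.08), 16.5, 0.015, -1),
    "W6S": ((0.30, 0.25, 0.10), 17.5, 0.020, +1),
    "W5C": ((0.12, 0.08, 0.06), 15.0, 0.015, -1),
    "W1S": ((0.45, 0.90, 0.35), 19.0, 0.025, +1),
    "W1W": ((0.25, 0.70, 0.90), 16.0, 0.020, +1),
    "W2S": ((0.35, 0.60, 0.25), 18.5, 0.020, +1),
    "W2W": ((0.20, 0.50, 0.70), 17.0, 0.020, +1),
    "W3S": ((0.28, 0.35, 0.15), 15.8, 0.020, +1),
}


def default_sensor_bank() -> list[SensorModel]:
    """The 10-sensor PEN3-style bank with cross-sensitive loadings.

    Taus are kept below 90 / ln(100) ~ 19.5 s so that every noise-free
    curve reaches at least 99 % of its plateau by t = 90 s.
    """
    return [
        SensorModel(name=n, amplitude_loadings=np.array(l), saturation_tau=t,
                    noise_sd=sd, direction=d)
        for n, (l, t, sd, d) in _DEFAULT_BANK.items()
    ]


def factor_intensities(proportion: float) -> np.ndarray:
    """Latent volatile intensities at pork fraction ``proportion``."""
    phi = proportion + _NONLIN * proportion**2
    return _FACTOR_BASE + _FACTOR_SLOPE * phi


def amplitude(sensor: SensorModel, proportion: float,
              day_effect: np.ndarray) -> float:
    """Plateau amplitude of ``sensor`` (before the direction sign)."""
    c = factor_intensities(proportion) * (1.0 + np.asarray(day_effect, float))
    return float(sensor.amplitude_loadings @ c)


def simulate_curve(
    sensor: SensorModel,
    proportion: float,
    day_effect: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    amplitude_override: float | None = None,
    sensitivity: float = 1.0,
    kinetic_gain: float = KINETIC_GAIN,
    flow_noise: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate one sensor's 100-point response curve.

    Returns G/G0 at t = 1..100 s. ``sensitivity`` is a multiplicative
    gain on the amplitude (1.0 = nominal; used for per-day sensor
    drift). ``amplitude_override`` bypasses the factor model (useful for
    controlled kinetics checks). The effective time constant is
    ``saturation_tau / (1 + kinetic_gain * proportion)``.
    ``flow_noise`` is an optional length-100 vector of per-second
    relative fluctuations of the delivered gas concentration; it scales
    the response term of every sensor coherently (the same vector is
    shared across a sample's sensors), emulating second-to-second
    headspace flow instability. Values are guaranteed positive: in the
    vanishingly rare case noise drives a point to <= 0 it is clipped to
    a small positive floor.
    """
    if not 0.0 <= proportion <= 1.0:
        raise ValueError(f"proportion {proportion} outside [0, 1]")
    if day_effect is None:
        day_effect = np.zeros(N_FACTORS)
    if amplitude_override is not None:
        amp = amplitude_override
    else:
        amp = amplitude(sensor, proportion, day_effect)
    tau = sensor.saturation_tau / (1.0 + kinetic_gain * proportion)
    t = np.arange(1, N_TIMEPOINTS + 1, dtype=float)
    response = sensor.direction * sensitivity * amp * (1.0 - np.exp(-t / tau))
    if flow_noise is not None:
        response = response * (1.0 + np.asarray(flow_noise, float))
    curve = sensor.baseline + response
    if sensor.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        curve = curve + rng.normal(0.0, sensor.noise_sd, size=N_TIMEPOINTS)
    return np.clip(curve, 1e-6, None)


def simulate_dataset(
    design: StudyDesign, bank: Sequence[SensorModel] | None = None
) -> Dataset:
    """Simulate a full measurement campaign.

    Day-level nuisance terms (factor shift + per-sensor sensitivity
    drift) are drawn once per (day, session); per-sample factor jitter
    and measurement noise are drawn per sample. Sample count =
    ``n_days * n_sessions * n_proportions * replicates``. Deterministic
    given ``design.seed``.
    """
    if bank is None:
        bank = default_sensor_bank()
    root = np.random.SeedSequence(design.seed)
    day_seeds = root.spawn(design.n_days * len(design.sessions))
    samples: list[ENoseSample] = []
    for di, day in enumerate(range(1, design.n_days + 1)):
        for si, session in enumerate(design.sessions):
            block_ss = day_seeds[di * len(design.sessions) + si]
            block_rng = np.random.default_rng(block_ss)
            day_effect = block_rng.normal(0.0, design.day_effect_sd, N_FACTORS)
            drift = block_rng.normal(1.0, design.sensor_drift_sd, len(bank))
            sample_seeds = block_ss.spawn(
                len(design.proportions)
                * design.samples_per_proportion_per_day_per_session
            )
            k = 0
            for p in design.proportions:
                for rep in range(
                    1, design.samples_per_proportion_per_day_per_session + 1
                ):
                    rng = np.random.default_rng(sample_seeds[k])
                    k += 1
                    jitter = rng.normal(0.0, design.sample_jitter_sd,
                                        N_FACTORS)
                    # combined multiplicative factor shift for this sample
                    shift = (1.0 + day_effect) * (1.0 + jitter) - 1.0
                    # per-sample, per-sensor response-gain repeatability
                    gain = rng.normal(1.0, design.sample_gain_sd, len(bank))
                    # per-second delivery fluctuation, common to all sensors
                    flow = rng.normal(0.0, design.flow_noise_sd, N_TIMEPOINTS)
                    curves = np.column_stack([
                        simulate_curve(s, p, shift, rng,
                                       sensitivity=float(drift[j] * gain[j]),
                                       kinetic_gain=design.kinetic_gain,
                                       flow_noise=flow)
                        for j, s in enumerate(bank)
                    ])
                    samples.append(ENoseSample(
                        sample_id=(
                            f"d{day:02d}{session}_p{round(p * 100):02d}"
                            f"_r{rep}"
                        ),
                        day=day,
                        session=session,
                        proportion=p,
                        curves=curves,
                        sensor_names=tuple(s.name for s in bank),
                    ))
    return Dataset(samples=samples, design=design)


def save_sensor_bank(bank: Sequence[SensorModel], path: str | Path) -> None:
    """Serialize a sensor bank to YAML."""
    payload = []
    for s in bank:
        d = asdict(s)
        d["amplitude_loadings"] = [float(x) for x in s.amplitude_loadings]
        payload.append(d)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_sensor_bank(path: str | Path) -> list[SensorModel]:
    """Load a sensor bank from YAML written by :func:`save_sensor_bank`."""
    payload = yaml.safe_load(Path(path).read_text())
    return [SensorModel(
        name=d["name"],
        amplitude_loadings=np.array(d["amplitude_loadings"], float),
        saturation_tau=float(d["saturation_tau"]),
        noise_sd=float(d["noise_sd"]),
        direction=int(d["direction"]),
        baseline=float(d.get("baseline", 1.0)),
    ) for d in payload]
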