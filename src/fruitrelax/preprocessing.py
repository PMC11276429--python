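"""Raw instrument traces -> model-ready relaxation curves.

Four steps: trim the loading/unloading stages, convert force to stress via
Hertz sphere-on-flat contact, min–max normalise each feature to [0, 1], and
split the population 80/20 stratified by fruit size and probe position.

Units are fixed throughout: force in N, lengths in mm, stress in MPa.  With
F in newtons and D, R in millimetres the Hertz conversion

    E = 3 F (1 - mu^2) / (4 D^1.5 R^0.5),   eps = D / (2R),   sigma = E * eps

yields N/mm^2 = MPa directly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .synthetic_data import ForceTrace, FruitSample, POSITIONS, SIZE_CLASSES

__all__ = [
    "FEATURES",
    "RelaxationCurve",
    "NormalizationSpec",
    "DatasetSplit",
    "TrimError",
    "SplitError",
    "trim_relaxation",
    "force_to_stress",
    "fit_normalizer",
    "split_dataset",
]

#: Feature keys used across normalisation and the LSTM input layer:
#: time (s), force (N), strain (dimensionless), stress (MPa).
FEATURES = ("t", "f", "eps", "sigma")


class TrimError(ValueError):
    """Trace has no relaxation block to retain."""


class SplitError(ValueError):
    """A stratum is too small to populate the test set."""


@dataclass(frozen=True)
class RelaxationCurve:
    """Trimmed relaxation phase of one fruit, in stress units.

    ``times`` are measured from the start of the hold, with the first sample
    strictly positive (one sampling interval in): the fractional-derivative
    model is singular at t = 0.  ``strain0`` is the constant imposed strain
    D / (2R); ``raw_force`` retains the measured force for use as a model
    input feature.
    """

    sample_id: str
    times: np.ndarray
    stress: np.ndarray
    strain0: float
    raw_force: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        stress = np.asarray(self.stress, dtype=float)
        raw = np.asarray(self.raw_force, dtype=float)
        if not (times.shape == stress.shape == raw.shape):
            raise ValueError("times, stress and raw_force must have identical lengths")
        if times.size == 0:
            raise ValueError("relaxation curve cannot be empty")
        if times[0] <= 0 or (times.size > 1 and np.any(np.diff(times) <= 0)):
            raise ValueError("times must be strictly increasing with times[0] > 0")
        if not (0.0 < self.strain0 < 1.0):
            raise ValueError(f"strain0 must lie in (0, 1), got {self.strain0}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "stress", stress)
        object.__setattr__(self, "raw_force", raw)

    def __len__(self) -> int:
        return self.times.size


def trim_relaxation(trace: ForceTrace) -> ForceTrace:
    """Keep only the relaxation block, re-zeroing time to the start of the hold.

    The first retained sample sits one sampling interval after the hold
    begins, so the returned times are strictly positive.
    """
    mask = trace.stage_mask("relaxation")
    if not mask.any():
        raise TrimError(f"trace {trace.sample_id!r} has no relaxation stage to retain")
    times = trace.times[mask]
    if times.size > 1:
        dt = float(np.median(np.diff(times)))
    else:
        dt = float(times[0]) or 1.0
    new_times = times - times[0] + dt
    return ForceTrace(
        sample_id=trace.sample_id,
        times=new_times,
        forces=trace.forces[mask],
        stages=np.array(["relaxation"] * times.size, dtype=object),
    )


def force_to_stress(trace: ForceTrace, sample: FruitSample, deformation_mm: float = 1.0) -> RelaxationCurve:
    """Hertz conversion of a trimmed relaxation trace to stress units.

    sigma = 3 F (1 - mu^2) / (8 D^0.5 R^1.5)  [MPa], with the constant
    imposed strain eps0 = D / (2R).  Homogeneous of degree 1 in F and
    strictly decreasing in R at fixed F, D.
    """
    if deformation_mm <= 0:
        raise ValueError("deformation must be positive")
    if np.any(trace.stages != "relaxation"):
        raise ValueError("force_to_stress expects a trimmed, relaxation-only trace")
    if np.any(trace.forces <= 0):
        raise ValueError(f"trace {trace.sample_id!r} has non-positive forces; cannot convert to stress")
    mu = sample.poisson_ratio
    R = sample.radius_mm
    D = deformation_mm
    sigma = 3.0 * trace.forces * (1.0 - mu**2) / (8.0 * D**0.5 * R**1.5)
    return RelaxationCurve(
        sample_id=trace.sample_id,
        times=trace.times,
        stress=sigma,
        strain0=D / (2.0 * R),
        raw_force=trace.forces,
    )


@dataclass
class NormalizationSpec:
    """Per-feature min–max bounds fitted on a reference dataset.

    ``apply`` maps a feature affinely onto [0, 1] over the reference data
    (values outside the reference range pass through unclipped); ``invert``
    is the exact inverse.  A constant feature is stored as a passthrough
    (identity) with a warning at fit time.
    """

    bounds: dict[str, tuple[float, float] | None]

    def apply(self, values, feature: str):
        values = np.asarray(values, dtype=float)
        b = self._get(feature)
        if b is None:
            return values
        lo, hi = b
        return (values - lo) / (hi - lo)

    def invert(self, values, feature: str):
        values = np.asarray(values, dtype=float)
        b = self._get(feature)
        if b is None:
            return values
        lo, hi = b
        return values * (hi - lo) + lo

    def _get(self, feature: str):
        if feature not in self.bounds:
            raise KeyError(f"unknown feature {feature!r}; expected one of {sorted(self.bounds)}")
        return self.bounds[feature]

    # sidecar (de)serialisation so training and prediction share bounds bit-exactly
    def to_json(self, path) -> None:
        payload = {k: (list(v) if v is not None else None) for k, v in self.bounds.items()}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "NormalizationSpec":
        payload = json.loads(Path(path).read_text())
        return cls({k: (tuple(v) if v is not None else None) for k, v in payload.items()})


def fit_normalizer(curves: Iterable[RelaxationCurve]) -> NormalizationSpec:
    """Fit per-feature min–max bounds over a reference set of relaxation curves.

    The reference set is conventionally the whole dataset (train + test); a
    train-only reference is obtained simply by passing training curves only.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("fit_normalizer needs a nonempty dataset")
    pools = {
        "t": np.concatenate([c.times for c in curves]),
        "f": np.concatenate([c.raw_force for c in curves]),
        "eps": np.array([c.strain0 for c in curves]),
        "sigma": np.concatenate([c.stress for c in curves]),
    }
    bounds: dict[str, tuple[float, float] | None] = {}
    for feat, vals in pools.items():
        lo, hi = float(vals.min()), float(vals.max())
        if hi <= lo:
            warnings.warn(f"feature {feat!r} is constant over the reference set; storing passthrough")
            bounds[feat] = None
        else:
            bounds[feat] = (lo, hi)
    return NormalizationSpec(bounds)


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/test fruit-id sets covering the whole population."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids must be disjoint")


def split_dataset(population: Sequence[FruitSample], fraction: float = 0.2, seed: int = 0) -> DatasetSplit:
    """Stratified train/test split by (size_class, position).

    Each stratum contributes round(fraction * n) fruit (at least one) to the
    test set; reproducible from ``seed``.
    """
    if not (0.0 < fraction < 1.0):
        raise SplitError(f"test fraction must lie in (0, 1), got {fraction}")
    strata: dict[tuple[str, str], list[str]] = {}
    for s in population:
        strata.setdefault((s.size_class, s.position), []).append(s.id)

    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for key in sorted(strata):
        ids = sorted(strata[key])
        if len(ids) < 5:
            raise SplitError(f"stratum {key} has only {len(ids)} fruit; need >= 5 for a test stratum")
        n_test = max(1, int(round(fraction * len(ids))))
        perm = rng.permutation(len(ids))
        test.extend(ids[i] for i in perm[:n_test])
        train.extend(ids[i] for i in perm[n_test:])
    return DatasetSplit(train_ids=tuple(sorted(train)), test_ids=tuple(sorted(test)))
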