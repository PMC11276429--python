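"""Synthetic texture-analyzer data for whole-fruit compression stress relaxation.

Real relaxation datasets for whole tomato fruit are rarely deposited, so this
module emulates the standard instrument protocol: a column probe compresses
the fruit along the calyx–stem axis at constant speed until a target
deformation is reached, the probe holds for a fixed dwell while force decays,
then retracts.  Each simulated fruit carries ground-truth viscoelastic
parameters drawn around published population means for ripe tomato, with a
multiplicative stiffness effect for probe placement over the septum (radial
wall) versus the locule (seed cavity).

Relaxation forces follow from the fruit's constitutive law via the exact
algebraic inverse of the Hertz sphere-on-flat conversion, so the
preprocessing round trip force -> stress reproduces the model stress to
floating point.  Loading and unloading segments are synthesized only so the
trimming stage has something to remove; their shape is deliberately simple
and non-physical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classical_models import CaputoParams, MaxwellParams, caputo_stress, maxwell_stress

__all__ = [
    "SIZE_CLASSES",
    "POSITIONS",
    "DEFAULT_SIZE_BANDS",
    "DEFAULT_POISSON_RATIO",
    "DEFAULT_POSITION_EFFECT",
    "TOMATO_MAXWELL_MEAN",
    "TOMATO_MAXWELL_SD",
    "TOMATO_CAPUTO_MEAN",
    "TOMATO_CAPUTO_SD",
    "FruitSample",
    "CompressionProtocol",
    "ForceTrace",
    "NoiseSpec",
    "ConfigurationError",
    "GeneratorError",
    "FormatError",
    "hertz_force_from_stress",
    "sample_population",
    "generate_force_trace",
    "write_dataset",
    "read_dataset",
]

SIZE_CLASSES = ("large", "medium", "small")
POSITIONS = ("locule", "septum")

# Plausible whole-fruit radius bands (mm) for a Provence-type tomato; only the
# relative ordering large > medium > small matters downstream.
DEFAULT_SIZE_BANDS: dict[str, tuple[float, float]] = {
    "large": (38.0, 44.0),
    "medium": (32.0, 38.0),
    "small": (26.0, 32.0),
}

# Near-incompressible plant tissue convention.
DEFAULT_POISSON_RATIO = 0.49

# Septum (radial wall) stiffness relative to locule (seed cavity).
DEFAULT_POSITION_EFFECT = 1.3

# Published population means ± SDs for ripe tomato relaxation constants.
TOMATO_MAXWELL_MEAN = MaxwellParams(E0=0.222, E1=0.0681, E2=0.0816, T1=0.355, T2=8.672)
TOMATO_MAXWELL_SD = {"E0": 0.0168, "E1": 0.00799, "E2": 0.0144, "T1": 0.0517, "T2": 0.353}
TOMATO_CAPUTO_MEAN = CaputoParams(chi_alpha=0.388, alpha=0.072)
TOMATO_CAPUTO_SD = {"chi_alpha": 0.025, "alpha": 0.0012}


class ConfigurationError(ValueError):
    """Invalid generator configuration (bands, multipliers, noise)."""


class GeneratorError(RuntimeError):
    """A trace was requested for a fruit that cannot produce one."""


class FormatError(ValueError):
    """On-disk dataset violates the expected CSV layout."""


@dataclass(frozen=True)
class FruitSample:
    """One simulated (or measured) tomato fruit.

    ``true_params`` holds the generator's ground-truth constitutive
    parameters and is absent (None) for real instrument data.
    """

    id: str
    radius_mm: float
    size_class: str
    position: str
    poisson_ratio: float = DEFAULT_POISSON_RATIO
    true_params: MaxwellParams | CaputoParams | None = None

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError(f"radius must be positive, got {self.radius_mm}")
        if not (0.0 < self.poisson_ratio < 0.5):
            raise ValueError(f"Poisson ratio must lie in (0, 0.5), got {self.poisson_ratio}")
        if self.size_class not in SIZE_CLASSES:
            raise ValueError(f"unknown size_class {self.size_class!r}; expected one of {SIZE_CLASSES}")
        if self.position not in POSITIONS:
            raise ValueError(f"unknown position {self.position!r}; expected one of {POSITIONS}")


@dataclass(frozen=True)
class CompressionProtocol:
    """Texture-analyzer settings: 1 mm/s loading to 1 mm deformation, 60 s
    hold, 20 Hz sampling, 0.49 N contact trigger by default."""

    loading_speed_mm_s: float = 1.0
    target_deformation_mm: float = 1.0
    hold_duration_s: float = 60.0
    sampling_rate_hz: float = 20.0
    contact_force_trigger_n: float = 0.49

    def __post_init__(self):
        for name in (
            "loading_speed_mm_s",
            "target_deformation_mm",
            "hold_duration_s",
            "sampling_rate_hz",
            "contact_force_trigger_n",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def n_relaxation_samples(self) -> int:
        return int(round(self.hold_duration_s * self.sampling_rate_hz))


@dataclass(frozen=True)
class ForceTrace:
    """Raw time/force series with per-point stage labels.

    Stages form one loading block, then one relaxation block, then one
    unloading block (each possibly empty in fixtures).
    """

    sample_id: str
    times: np.ndarray
    forces: np.ndarray
    stages: np.ndarray  # per-point strings from {"loading", "relaxation", "unloading"}

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        forces = np.asarray(self.forces, dtype=float)
        stages = np.asarray(self.stages, dtype=object)
        if not (times.shape == forces.shape == stages.shape):
            raise ValueError("times, forces and stages must have identical lengths")
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        order = {"loading": 0, "relaxation": 1, "unloading": 2}
        codes = [order.get(s) for s in stages]
        if any(c is None for c in codes):
            raise ValueError("stages must be loading/relaxation/unloading")
        if codes and any(b < a for a, b in zip(codes, codes[1:])):
            raise ValueError("stage sequence must be loading, then relaxation, then unloading")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "forces", forces)
        object.__setattr__(self, "stages", stages)

    def stage_mask(self, stage: str) -> np.ndarray:
        return self.stages == stage


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement and between-fruit variation settings.

    ``force_sd`` is the additive Gaussian SD on every force point (N).  When
    None it defaults to ``force_sd_frac`` of the fruit's noiseless initial
    relaxation force.  ``param_scale`` multiplies the published between-fruit
    parameter SDs (0 collapses every fruit onto the population mean).
    """

    force_sd: float | None = None
    force_sd_frac: float = 0.005
    param_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.force_sd is not None and self.force_sd < 0:
            raise ConfigurationError("force_sd must be >= 0")
        if self.force_sd_frac < 0 or self.param_scale < 0:
            raise ConfigurationError("force_sd_frac and param_scale must be >= 0")


def hertz_force_from_stress(stress, deformation_mm: float, radius_mm: float, poisson_ratio: float):
    """Exact inverse of the Hertz force->stress conversion.

    F = 8 * sigma * D^0.5 * R^1.5 / (3 * (1 - mu^2)), with sigma in MPa,
    D and R in mm, F in N.
    """
    stress = np.asarray(stress, dtype=float)
    return 8.0 * stress * deformation_mm**0.5 * radius_mm**1.5 / (3.0 * (1.0 - poisson_ratio**2))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lower: float = 0.0, upper: float = np.inf) -> float:
    """Normal draw truncated to (lower, upper) by resampling (not clipping)."""
    if sd == 0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lower < x < upper:
            return float(x)
    raise GeneratorError(f"could not draw a value in ({lower}, {upper}) around {mean} ± {sd}")


def _draw_params(rng: np.random.Generator, family: str, param_scale: float):
    if family == "maxwell":
        m, s = TOMATO_MAXWELL_MEAN, TOMATO_MAXWELL_SD
        return MaxwellParams(
            E0=_truncated_normal(rng, m.E0, s["E0"] * param_scale),
            E1=_truncated_normal(rng, m.E1, s["E1"] * param_scale),
            E2=_truncated_normal(rng, m.E2, s["E2"] * param_scale),
            T1=_truncated_normal(rng, m.T1, s["T1"] * param_scale),
            T2=_truncated_normal(rng, m.T2, s["T2"] * param_scale),
        )
    if family == "caputo":
        m, s = TOMATO_CAPUTO_MEAN, TOMATO_CAPUTO_SD
        return CaputoParams(
            chi_alpha=_truncated_normal(rng, m.chi_alpha, s["chi_alpha"] * param_scale),
            alpha=_truncated_normal(rng, m.alpha, s["alpha"] * param_scale, upper=1.0),
        )
    raise ConfigurationError(f"unknown constitutive family {family!r}")


def _validate_bands(size_bands: Mapping[str, tuple[float, float]]) -> None:
    if set(size_bands) != set(SIZE_CLASSES):
        raise ConfigurationError(f"size_bands must define exactly {SIZE_CLASSES}")
    for cls, (lo, hi) in size_bands.items():
        if not (0 < lo < hi):
            raise ConfigurationError(f"band for {cls!r} must satisfy 0 < min < max, got ({lo}, {hi})")
    # decreasing, non-overlapping: large above medium above small
    if not (size_bands["large"][0] >= size_bands["medium"][1] - 1e-12
            and size_bands["medium"][0] >= size_bands["small"][1] - 1e-12):
        raise ConfigurationError("size bands must be non-overlapping with large > medium > small")


def sample_population(
    n_per_group: int,
    size_bands: Mapping[str, tuple[float, float]] | None = None,
    position_effect: float = DEFAULT_POSITION_EFFECT,
    noise: NoiseSpec = NoiseSpec(),
    family: str = "mixed",
    poisson_ratio: float = DEFAULT_POISSON_RATIO,
) -> list[FruitSample]:
    """Draw a simulated tomato population.

    Returns ``n_per_group`` fruit for every (size_class, position)
    combination — 6 groups.  Each fruit's ground-truth parameters are drawn
    independently per component from a normal law around the published ripe
    tomato means with SD scaled by ``noise.param_scale``, truncated to
    positivity by resampling.  Septum fruit have all elastic moduli
    multiplied by ``position_effect`` (> 1: the radial wall reads stiffer
    than the seed cavity).  ``family`` is "maxwell", "caputo" or "mixed"
    (alternating within each group).  Draws are reproducible from
    ``noise.seed``.
    """
    if n_per_group < 1:
        raise ConfigurationError("n_per_group must be >= 1")
    if position_effect <= 0:
        raise ConfigurationError("position_effect must be > 0")
    if family not in ("maxwell", "caputo", "mixed"):
        raise ConfigurationError(f"unknown constitutive family {family!r}")
    bands = dict(size_bands) if size_bands is not None else dict(DEFAULT_SIZE_BANDS)
    _validate_bands(bands)

    rng = np.random.default_rng(noise.seed)
    population: list[FruitSample] = []
    idx = 0
    for size_class in SIZE_CLASSES:
        lo, hi = bands[size_class]
        for position in POSITIONS:
            for k in range(n_per_group):
                fam = family if family != "mixed" else ("maxwell" if k % 2 == 0 else "caputo")
                params = _draw_params(rng, fam, noise.param_scale)
                if position == "septum":
                    params = params.scale_moduli(position_effect)
                radius = float(rng.uniform(lo, hi))
                population.append(
                    FruitSample(
                        id=f"tomato_{idx:03d}_{size_class}_{position}",
                        radius_mm=radius,
                        size_class=size_class,
                        position=position,
                        poisson_ratio=poisson_ratio,
                        true_params=params,
                    )
                )
                idx += 1
    return population


def _relaxation_stress(sample: FruitSample, t: np.ndarray, strain0: float) -> np.ndarray:
    if isinstance(sample.true_params, MaxwellParams):
        return maxwell_stress(sample.true_params, t, strain0)
    return caputo_stress(sample.true_params, t, strain0)


def _trace_rng(noise: NoiseSpec, sample_id: str) -> np.random.Generator:
    # Stable per-fruit stream: the global seed plus a CRC of the fruit id.
    return np.random.default_rng([noise.seed, zlib.crc32(sample_id.encode())])


def generate_force_trace(
    sample: FruitSample,
    protocol: CompressionProtocol = CompressionProtocol(),
    noise: NoiseSpec = NoiseSpec(),
) -> ForceTrace:
    """Simulate one instrument export for a fruit with known ground truth.

    The relaxation block evaluates the fruit's constitutive model at
    eps0 = D / (2R) on the sampling grid (first sample one interval into the
    hold, avoiding the fractional model's singularity at t = 0) and converts
    stress to force through the exact inverse Hertz relation.  A linear
    loading ramp from the contact trigger and a short exponential unloading
    tail bracket the hold.  Additive Gaussian noise is applied to every
    force sample.
    """
    if sample.true_params is None:
        raise GeneratorError(f"fruit {sample.id!r} has no ground-truth parameters to simulate from")

    D = protocol.target_deformation_mm
    R = sample.radius_mm
    dt = 1.0 / protocol.sampling_rate_hz
    strain0 = D / (2.0 * R)

    n_relax = protocol.n_relaxation_samples
    t_hold = dt * np.arange(1, n_relax + 1)
    sigma = _relaxation_stress(sample, t_hold, strain0)
    f_relax = hertz_force_from_stress(sigma, D, R, sample.poisson_ratio)

    # Loading: linear ramp trigger -> first relaxation force over D / speed.
    load_dur = D / protocol.loading_speed_mm_s
    n_load = max(int(round(load_dur * protocol.sampling_rate_hz)), 2)
    f_load = np.linspace(protocol.contact_force_trigger_n, f_relax[0], n_load, endpoint=False)
    t_load = dt * np.arange(n_load)

    # Unloading: short exponential decay back toward zero.
    n_unload = 10
    f_unload = f_relax[-1] * np.exp(-np.arange(1, n_unload + 1) / 2.0)
    t_unload = t_load[-1] + dt + t_hold[-1] + dt * np.arange(1, n_unload + 1)

    times = np.concatenate([t_load, t_load[-1] + dt + t_hold, t_unload])
    forces = np.concatenate([f_load, f_relax, f_unload])
    stages = np.array(
        ["loading"] * n_load + ["relaxation"] * n_relax + ["unloading"] * n_unload, dtype=object
    )

    sd = noise.force_sd if noise.force_sd is not None else noise.force_sd_frac * float(f_relax[0])
    if sd > 0:
        forces = forces + _trace_rng(noise, sample.id).normal(0.0, sd, size=forces.shape)

    return ForceTrace(sample_id=sample.id, times=times, forces=forces, stages=stages)


# --- on-disk dataset -------------------------------------------------------

_META_COLUMNS = ["id", "radius_mm", "size_class", "position", "poisson_ratio", "family",
                 "E0", "E1", "E2", "T1", "T2", "chi_alpha", "alpha"]
_TRACE_COLUMNS = ["time_s", "force_N", "stage"]


def write_dataset(population: Sequence[FruitSample], traces: Sequence[ForceTrace], path) -> None:
    """Write one metadata CSV plus one trace CSV per fruit under ``path``."""
    path = Path(path)
    trace_ids = {t.sample_id for t in traces}
    pop_ids = {s.id for s in population}
    if not trace_ids <= pop_ids:
        raise FormatError(f"traces reference unknown fruit ids: {sorted(trace_ids - pop_ids)}")
    (path / "traces").mkdir(parents=True, exist_ok=True)

    rows = []
    for s in population:
        row = {"id": s.id, "radius_mm": s.radius_mm, "size_class": s.size_class,
               "position": s.position, "poisson_ratio": s.poisson_ratio,
               "family": "", **{k: np.nan for k in _META_COLUMNS[6:]}}
        if isinstance(s.true_params, MaxwellParams):
            row["family"] = "maxwell"
            row.update(E0=s.true_params.E0, E1=s.true_params.E1, E2=s.true_params.E2,
                       T1=s.true_params.T1, T2=s.true_params.T2)
        elif isinstance(s.true_params, CaputoParams):
            row["family"] = "caputo"
            row.update(chi_alpha=s.true_params.chi_alpha, alpha=s.true_params.alpha)
        rows.append(row)
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path / "metadata.csv", index=False)

    for t in traces:
        pd.DataFrame({"time_s": t.times, "force_N": t.forces, "stage": t.stages}).to_csv(
            path / "traces" / f"{t.sample_id}.csv", index=False
        )


def read_dataset(path) -> tuple[list[FruitSample], list[ForceTrace]]:
    """Read a dataset written by :func:`write_dataset`; validates layout."""
    path = Path(path)
    meta_path = path / "metadata.csv"
    if not meta_path.exists():
        raise FormatError(f"missing metadata file {meta_path}")
    meta = pd.read_csv(meta_path)
    missing = [c for c in _META_COLUMNS[:6] if c not in meta.columns]
    if missing:
        raise FormatError(f"{meta_path}: missing metadata columns {missing}")

    population: list[FruitSample] = []
    for i, row in meta.iterrows():
        family = row.get("family")
        params: MaxwellParams | CaputoParams | None = None
        if isinstance(family, str) and family == "maxwell":
            params = MaxwellParams(row["E0"], row["E1"], row["E2"], row["T1"], row["T2"])
        elif isinstance(family, str) and family == "caputo":
            params = CaputoParams(row["chi_alpha"], row["alpha"])
        try:
            population.append(
                FruitSample(
                    id=str(row["id"]), radius_mm=float(row["radius_mm"]),
                    size_class=str(row["size_class"]), position=str(row["position"]),
                    poisson_ratio=float(row["poisson_ratio"]), true_params=params,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{meta_path}, row {i + 2}: {exc}") from exc

    traces: list[ForceTrace] = []
    for s in population:
        trace_path = path / "traces" / f"{s.id}.csv"
        if not trace_path.exists():
            continue
        df = pd.read_csv(trace_path)
        missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{trace_path}: missing columns {missing}")
        try:
            traces.append(ForceTrace(s.id, df["time_s"].to_numpy(float),
                                     df["force_N"].to_numpy(float),
                                     df["stage"].to_numpy(object)))
        except ValueError as exc:
            raise FormatError(f"{trace_path}: {exc}") from exc
    return population, traces
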