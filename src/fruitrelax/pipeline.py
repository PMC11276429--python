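"""End-to-end orchestration: generate -> preprocess -> calibrate/train ->
evaluate, from a single serialisable run configuration.

Every stage is a pure function over in-memory objects; :func:`run` chains
them and (optionally) persists all artifacts — dataset CSVs, normaliser
sidecar, fitted parameters, trained model, metric reports and a structured
log — into one output directory together with the exact configuration that
produced them.  The single run seed fans out to per-stage sub-seeds through
a fixed derivation so each stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import evaluation, lstm_core
from .classical_models import CaputoParams, MaxwellParams, fit_caputo, fit_maxwell, parameter_table
from .evaluation import MetricReport, compare_models, per_fruit_report, reports_to_frame
from .lstm_core import LSTMConfig, LSTMParams, TrainingHistory
from .preprocessing import (NormalizationSpec, RelaxationCurve, fit_normalizer,
                            force_to_stress, split_dataset, trim_relaxation)
from .synthetic_data import (DEFAULT_SIZE_BANDS, CompressionProtocol, ForceTrace,
                             FruitSample, NoiseSpec, generate_force_trace,
                             read_dataset, sample_population, write_dataset)

__all__ = ["RunConfig", "RunResult", "ConfigSchemaError", "sub_seed", "load_config",
           "generate", "prepare_curves", "fit_global_classical", "fit_per_fruit",
           "train_lstm", "evaluate", "run"]


class ConfigSchemaError(ValueError):
    """Run configuration failed validation before any computation."""


def sub_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed derived from the run seed (< 2**31)."""
    return (int(seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one end-to-end run.

    ``sequence_stride`` subsamples the model-ready curves in time (a stride
    of 10 turns the 20 Hz hold into an effective 2 Hz grid); both relaxation
    laws are smooth, so this preserves curve shape while keeping the
    pure-numpy BPTT tractable.  All models are fitted and scored on the
    same strided grid.
    """

    seed: int = 0
    n_per_group: int = 35
    family: str = "mixed"
    position_effect: float = 1.3
    size_bands: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SIZE_BANDS))
    force_sd: float | None = None
    force_sd_frac: float = 0.005
    param_scale: float = 1.0
    protocol: CompressionProtocol = field(default_factory=CompressionProtocol)
    split_fraction: float = 0.2
    normalize_on: str = "all"  # "all" (conventional, whole dataset) or "train"
    sequence_stride: int = 10
    lstm: LSTMConfig = field(default_factory=LSTMConfig)
    sweep_grids: Mapping[str, Sequence] | None = None

    def __post_init__(self):
        if not (0.0 < self.split_fraction < 1.0):
            raise ConfigSchemaError(f"split_fraction must lie in (0, 1), got {self.split_fraction}")
        if self.sequence_stride < 1:
            raise ConfigSchemaError("sequence_stride must be >= 1")
        if self.normalize_on not in ("all", "train"):
            raise ConfigSchemaError("normalize_on must be 'all' or 'train'")
        if self.family not in ("maxwell", "caputo", "mixed"):
            raise ConfigSchemaError(f"unknown constitutive family {self.family!r}")
        if self.n_per_group < 1:
            raise ConfigSchemaError("n_per_group must be >= 1")

    def noise(self) -> NoiseSpec:
        return NoiseSpec(force_sd=self.force_sd, force_sd_frac=self.force_sd_frac,
                         param_scale=self.param_scale, seed=sub_seed(self.seed, "generate"))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["size_bands"] = {k: list(v) for k, v in self.size_bands.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        try:
            if "protocol" in d and isinstance(d["protocol"], Mapping):
                d["protocol"] = CompressionProtocol(**d["protocol"])
            if "lstm" in d and isinstance(d["lstm"], Mapping):
                d["lstm"] = LSTMConfig(**d["lstm"])
            if "size_bands" in d:
                d["size_bands"] = {k: tuple(v) for k, v in d["size_bands"].items()}
            return cls(**d)
        except (TypeError, ValueError) as exc:
            raise ConfigSchemaError(str(exc)) from exc


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    payload = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(payload, dict):
        raise ConfigSchemaError(f"{path}: expected a mapping at top level")
    return RunConfig.from_dict(payload)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


# --- stages ----------------------------------------------------------------

def generate(config: RunConfig) -> tuple[list[FruitSample], list[ForceTrace]]:
    """Draw the fruit population and simulate one instrument trace per fruit."""
    noise = config.noise()
    population = sample_population(
        n_per_group=config.n_per_group, size_bands=config.size_bands,
        position_effect=config.position_effect, noise=noise, family=config.family)
    traces = [generate_force_trace(s, config.protocol, noise) for s in population]
    return population, traces


def prepare_curves(
    config: RunConfig, population: Sequence[FruitSample], traces: Sequence[ForceTrace],
) -> dict[str, RelaxationCurve]:
    """Trim, Hertz-convert and time-stride every trace into a model-ready curve."""
    samples = {s.id: s for s in population}
    stride = config.sequence_stride
    curves: dict[str, RelaxationCurve] = {}
    for trace in traces:
        trimmed = trim_relaxation(trace)
        curve = force_to_stress(trimmed, samples[trace.sample_id],
                                config.protocol.target_deformation_mm)
        if stride > 1:
            sl = slice(stride - 1, None, stride)
            curve = RelaxationCurve(curve.sample_id, curve.times[sl], curve.stress[sl],
                                    curve.strain0, curve.raw_force[sl])
        curves[curve.sample_id] = curve
    return curves


def fit_global_classical(train_curves: Sequence[RelaxationCurve], seed: int):
    """One pooled parameter set per classical model, fit on training curves."""
    maxwell, maxwell_diag = fit_maxwell(train_curves, seed=sub_seed(seed, "maxwell"))
    caputo, caputo_diag = fit_caputo(train_curves, seed=sub_seed(seed, "caputo"))
    return maxwell, caputo, {"maxwell": maxwell_diag, "caputo": caputo_diag}


def fit_per_fruit(curves: Sequence[RelaxationCurve], seed: int):
    """Per-fruit fits of both models, for mean ± SD parameter summaries."""
    maxwell_fits, caputo_fits = [], []
    for c in curves:
        m, _ = fit_maxwell([c], n_starts=1, seed=sub_seed(seed, f"m:{c.sample_id}"))
        k, _ = fit_caputo([c], n_starts=1, seed=sub_seed(seed, f"c:{c.sample_id}"))
        maxwell_fits.append(m)
        caputo_fits.append(k)
    return maxwell_fits, caputo_fits


def train_lstm(config: RunConfig, train_curves: Sequence[RelaxationCurve],
               normalizer: NormalizationSpec, progress: bool = False):
    """Train the LSTM on normalised training sequences."""
    lstm_cfg = replace(config.lstm, seed=sub_seed(config.seed, "lstm"))
    seqs, targets = lstm_core.make_sequences(train_curves, normalizer)
    return lstm_core.train(seqs, targets, lstm_cfg, progress=progress)


def evaluate(
    test_curves: Sequence[RelaxationCurve],
    samples: Mapping[str, FruitSample] | Sequence[FruitSample],
    lstm_params: LSTMParams,
    normalizer: NormalizationSpec,
    maxwell: MaxwellParams,
    caputo: CaputoParams,
):
    """Three-model comparison plus per-(size, position) LSTM breakdown."""
    comparison = compare_models(test_curves, lstm_params, normalizer, maxwell, caputo)
    per_cell = per_fruit_report(test_curves, samples, lstm_params, normalizer)
    return comparison, per_cell


@dataclass
class RunResult:
    """Everything an end-to-end run produced, in memory."""

    config: RunConfig
    population: list[FruitSample]
    curves: dict[str, RelaxationCurve]
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    normalizer: NormalizationSpec
    maxwell_global: MaxwellParams
    caputo_global: CaputoParams
    lstm_params: LSTMParams
    history: TrainingHistory
    comparison: list[MetricReport]
    per_cell: dict[tuple[str, str], MetricReport | None]
    maxwell_table: pd.DataFrame | None = None
    caputo_table: pd.DataFrame | None = None

    def metric(self, model: str, which: str) -> float:
        for r in self.comparison:
            if r.model == model:
                return getattr(r, which)
        raise KeyError(model)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig, outdir=None, per_fruit_tables: bool = True,
        progress: bool = False, log=None) -> RunResult:
    """Full pipeline.  If ``outdir`` is given, every artifact is persisted
    there along with the exact configuration and a structured stage log."""

    out = Path(outdir) if outdir is not None else None
    log_lines: list[str] = []

    def stage(name):
        t0 = time.perf_counter()

        def done(msg=""):
            line = f"[{name}] {time.perf_counter() - t0:.2f}s {msg}".rstrip()
            log_lines.append(line)
            if log:
                log(line)
        return done

    done = stage("generate")
    population, traces = generate(config)
    done(f"{len(population)} fruit")

    done = stage("preprocess")
    curves = prepare_curves(config, population, traces)
    split = split_dataset(population, config.split_fraction, sub_seed(config.seed, "split"))
    train_curves = [curves[i] for i in split.train_ids]
    test_curves = [curves[i] for i in split.test_ids]
    ref = list(curves.values()) if config.normalize_on == "all" else train_curves
    normalizer = fit_normalizer(ref)
    done(f"{len(train_curves)} train / {len(test_curves)} test curves")

    done = stage("fit-classical")
    maxwell, caputo, _ = fit_global_classical(train_curves, config.seed)
    maxwell_table = caputo_table = None
    if per_fruit_tables:
        m_fits, c_fits = fit_per_fruit(train_curves, config.seed)
        maxwell_table = parameter_table(m_fits)
        caputo_table = parameter_table(c_fits)
    done(f"global Maxwell E0={maxwell.E0:.4f}, Caputo alpha={caputo.alpha:.4f}")

    done = stage("train-lstm")
    lstm_params, history = train_lstm(config, train_curves, normalizer, progress=progress)
    done(f"{config.lstm.epochs} epochs, final loss {history.loss[-1]:.3e}")

    done = stage("evaluate")
    comparison, per_cell = evaluate(test_curves, population, lstm_params, normalizer,
                                    maxwell, caputo)
    done("; ".join(f"{r.model} MAPE {r.mape:.3f}%" for r in comparison))

    result = RunResult(
        config=config, population=population, curves=curves,
        train_ids=split.train_ids, test_ids=split.test_ids, normalizer=normalizer,
        maxwell_global=maxwell, caputo_global=caputo, lstm_params=lstm_params,
        history=history, comparison=comparison, per_cell=per_cell,
        maxwell_table=maxwell_table, caputo_table=caputo_table,
    )

    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        save_config(config, out / "config.yaml")
        write_dataset(population, traces, out / "dataset")
        (out / "split.json").write_text(json.dumps(
            {"train_ids": list(split.train_ids), "test_ids": list(split.test_ids)}, indent=1))
        normalizer.to_json(out / "normalizer.json")

        classical_dir = out / "classical"
        classical_dir.mkdir(exist_ok=True)
        (classical_dir / "global_fits.json").write_text(json.dumps({
            "maxwell": {k: getattr(maxwell, k) for k in ("E0", "E1", "E2", "T1", "T2")},
            "caputo": {k: getattr(caputo, k) for k in ("chi_alpha", "alpha")},
        }, indent=1))
        if maxwell_table is not None:
            maxwell_table.to_csv(classical_dir / "parameter_table_maxwell.csv")
            caputo_table.to_csv(classical_dir / "parameter_table_caputo.csv")

        lstm_dir = out / "lstm"
        lstm_dir.mkdir(exist_ok=True)
        lstm_core.save_model(lstm_params, replace(config.lstm, seed=sub_seed(config.seed, "lstm")),
                             lstm_dir / "model.json")
        pd.DataFrame({"epoch": range(len(history.loss)), "loss": history.loss,
                      "lr": history.lr, "wall_time_s": history.wall_time_s}
                     ).to_csv(lstm_dir / "history.csv", index=False)

        reports_dir = out / "reports"
        reports_dir.mkdir(exist_ok=True)
        reports_to_frame(comparison).to_csv(reports_dir / "comparison.csv", index=False)
        reports_to_frame(per_cell.values()).to_csv(reports_dir / "per_fruit.csv", index=False)

        (out / "manifest.json").write_text(json.dumps({
            "model_sha256": _sha256(lstm_dir / "model.json"),
            "normalizer_sha256": _sha256(out / "normalizer.json"),
        }, indent=1))
        (out / "log.txt").write_text("\n".join(log_lines) + "\n")

    return result


def check_artifact_consistency(outdir) -> None:
    """Verify that the model file and normaliser sidecar in ``outdir`` are the
    ones recorded together in the run manifest; raises on mismatch."""
    out = Path(outdir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {out}; was the pipeline run here?")
    manifest = json.loads(manifest_path.read_text())
    for key, rel in (("model_sha256", "lstm/model.json"), ("normalizer_sha256", "normalizer.json")):
        path = out / rel
        if not path.exists():
            raise FileNotFoundError(f"missing artifact {path}")
        if _sha256(path) != manifest[key]:
            raise ValueError(
                f"artifact {rel} does not match the run manifest; model and normalizer "
                "sidecar are inconsistent — regenerate or rerun the pipeline")
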