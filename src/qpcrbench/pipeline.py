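"""One-shot benchmark pipeline: simulate (or load) -> fit -> assess -> report.

The pipeline is configuration-driven and fully deterministic: given the same
:class:`RunConfig` (including its seed) it writes a byte-identical report
bundle.  The run log records the package version, the seed and a hash of the
resolved configuration -- enough to replay any run -- and deliberately no
wall-clock information.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .assess import (
    complete_features_table,
    classify_features,
    expression_comparison,
    limit_of_detection,
    precision_summary,
    quality_summary,
    signal_detect_slopes,
    titration_response,
)
from .datamodel import ExpressionSet, MixtureDesign, default_design, read_amplification_table
from .fitting import estimate_expression
from .simulate import NoiseConfig, TruthConfig, generate_truth, simulate_benchmark

__all__ = ["RunConfig", "StageError", "run_full_benchmark"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything a benchmark run depends on."""

    seed: int = 1
    output_dir: str = "benchmark_out"
    #: models to fit; two models additionally produce a cross-method report
    models: tuple[str, ...] = ("b4",)
    qc_thresholds: dict = field(default_factory=dict)  # per model; default 0.99
    delta_threshold: float = 2.0
    tolerances: tuple[float, ...] = (0.5, 0.75, 1.0)
    # simulation scale (ignored when raw_input is given)
    n_features: int = 754
    n_replicates: int = 4
    n_cycles: int = 46
    noise: dict = field(default_factory=dict)   # NoiseConfig overrides
    truth: dict = field(default_factory=dict)   # TruthConfig overrides
    raw_input: str | None = None                # load this CSV instead of simulating
    write_raw: bool = False

    def __post_init__(self) -> None:
        self.models = tuple(self.models)
        self.tolerances = tuple(sorted(float(t) for t in self.tolerances))
        if not self.models:
            raise ValueError("at least one model is required")

    def qc_threshold(self, model_id: str) -> float:
        return float(self.qc_thresholds.get(model_id, 0.99))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_full_benchmark(config: RunConfig, log=lambda msg: None) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns the summary dictionary that is also written to ``summary.json``.
    ``log`` receives one progress string per stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = default_design()
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "models": list(config.models),
    }

    # -- stage: data -------------------------------------------------------
    truth_table = None
    try:
        if config.raw_input:
            log(f"loading raw data from {config.raw_input}")
            dataset = read_amplification_table(config.raw_input)
        else:
            log(f"simulating {config.n_features} features x {config.n_cycles} cycles (seed {config.seed})")
            truth = generate_truth(
                config.n_features, TruthConfig(**config.truth), seed=config.seed
            )
            noise = NoiseConfig(**{"seed": config.seed + 1, **config.noise})
            dataset, truth_table = simulate_benchmark(
                truth, design, noise, n_replicates=config.n_replicates, n_cycles=config.n_cycles
            )
            truth.table.to_csv(out / "truth_features.csv", index=False)
            truth_table.to_csv(out / "truth_samples.csv", index=False)
            if config.write_raw:
                dataset.to_csv(out / "raw.csv")
    except Exception as err:  # noqa: BLE001 - reported with stage name
        raise StageError("data", err) from err
    summary["n_features"] = len(dataset.features)
    summary["n_samples"] = len(dataset.samples)
    summary["n_cycles"] = dataset.n_cycles

    # -- stage: fit --------------------------------------------------------
    sets: dict[str, ExpressionSet] = {}
    for model_id in config.models:
        try:
            log(f"fitting model {model_id} ({dataset.n_curves} curves)")
            es = estimate_expression(
                dataset, model_id, quality_threshold_default=config.qc_threshold(model_id)
            )
            es.to_csv(out / f"expression_{model_id}.csv", out / f"quality_{model_id}.csv")
            sets[model_id] = es
        except Exception as err:  # noqa: BLE001
            raise StageError(f"fit:{model_id}", err) from err

    # -- stage: assessments ------------------------------------------------
    for model_id, es in sets.items():
        thr = config.qc_threshold(model_id)
        try:
            log(f"assessing {model_id}")
            qs = quality_summary(es)
            qs.quality_by_expression_bin.to_csv(out / f"quality_by_expression_{model_id}.csv", index=False)

            cats = classify_features(es, thr).value_counts()
            summary[f"features_{model_id}"] = {c: int(cats.get(c, 0)) for c in ("complete", "partial", "absent")}

            lod = limit_of_detection(es, design, config.tolerances, thr)
            lod.thresholds.to_csv(out / f"lod_thresholds_{model_id}.csv")
            lod.per_feature.to_csv(out / f"lod_per_feature_{model_id}.csv", index=False)
            summary[f"lod_{model_id}"] = {
                cmp_: {f"{tol:g}": (None if pd.isna(v) else round(float(v), 4)) for tol, v in row.items()}
                for cmp_, row in lod.thresholds.iterrows()
            }

            tit = titration_response(es, design, thr)
            tit.counts.to_csv(out / f"titration_counts_{model_id}.csv")
            tit.binned.to_csv(out / f"titration_binned_{model_id}.csv", index=False)
            summary[f"titration_{model_id}"] = {
                series: {k: int(v) for k, v in row.items()} for series, row in tit.counts.iterrows()
            }

            acc = signal_detect_slopes(es, design, thr)
            acc.per_feature.to_csv(out / f"accuracy_per_feature_{model_id}.csv", index=False)
            acc.summary.to_csv(out / f"accuracy_summary_{model_id}.csv", index=False)
            if len(acc.summary):
                summary[f"accuracy_{model_id}"] = {
                    "median_slope_by_bin": [round(v, 4) for v in acc.summary["median_slope"]],
                    "mad_slope_by_bin": [round(v, 4) for v in acc.summary["mad_slope"]],
                }

            prec = precision_summary(es, thr)
            prec.per_group.to_csv(out / f"precision_per_group_{model_id}.csv", index=False)
            prec.summary.to_csv(out / f"precision_summary_{model_id}.csv", index=False)
            if len(prec.summary):
                summary[f"precision_{model_id}"] = {
                    "median_cv_by_bin": [round(v, 6) for v in prec.summary["median_cv"]],
                }
        except Exception as err:  # noqa: BLE001
            raise StageError(f"assess:{model_id}", err) from err

    # -- stage: cross-method comparison ------------------------------------
    if len(config.models) >= 2:
        m1, m2 = config.models[0], config.models[1]
        try:
            log(f"comparing {m1} vs {m2}")
            table = complete_features_table(
                sets[m1], sets[m2], config.qc_threshold(m1), config.qc_threshold(m2)
            )
            table.table.to_csv(out / f"complete_features_{m1}_vs_{m2}.csv")
            summary["complete_features_table"] = {
                "grand_total": table.grand_total,
                "jointly_complete": int(table.table.loc["complete", "complete"]),
                "jointly_absent": int(table.table.loc["absent", "absent"]),
            }
            comp = expression_comparison(
                sets[m1], sets[m2], config.delta_threshold,
                config.qc_threshold(m1), config.qc_threshold(m2),
            )
            comp.flagged.to_csv(out / f"comparison_flags_{m1}_vs_{m2}.csv", index=False)
            summary["comparison_flags"] = int(len(comp.flagged))
        except Exception as err:  # noqa: BLE001
            raise StageError("compare", err) from err

    _write_json(out / "summary.json", summary)
    _write_json(
        out / "run.json",
        {
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
        },
    )
    log(f"report bundle written to {out}")
    return summary
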