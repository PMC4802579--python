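"""Ground-truthed synthetic amplification data.

The generator emulates a two-pool mixture/dilution titration experiment: each
feature has a true pure-pool threshold cycle in pool A and/or pool B (some
features are pool-specific, some absent from both, mirroring tissue-specific
expression), sample types blend the pools according to a
:class:`~qpcrbench.datamodel.MixtureDesign`, and every curve is a symmetric
logistic whose cpD2 equals the (noisy) target threshold cycle:

    y(x) = c + (d - c) / (1 + exp(-(x - x_mid) / s)),   x_mid = ct + s ln(2 + sqrt 3)

so estimator recovery is directly testable against the truth table.  Noise
enters as Gaussian replicate-to-replicate threshold-cycle jitter, i.i.d.
fluorescence noise on every reading, random fit-failure injection (flat
curves), and a single-molecule detection limit: the number of template copies
in a reaction is Poisson with mean ``2**(M - ct)``, where ``M`` is the
threshold cycle at which one copy is expected on average
(``dropout_expression_midpoint``).  A reaction with zero copies drops out
(flat curve) -- so the dropout probability ``exp(-2**(M - ct))`` rises
sigmoidally beyond ``M`` -- and a detected reaction amplifies from its
*realized* copy number, ``ct = M - log2(n)``.  Observed expression therefore
saturates near ``M`` and grows noisier as abundance falls, reproducing the
divergence between observed and expected expression that defines a limit of
detection.  The plateau also decays gently with the threshold cycle, so late
(low-abundance) curves carry relatively more fluorescence noise and earn
lower fit quality, as real reactions do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .assess import expected_expression
from .datamodel import AmplificationDataset, ExpressionSet, MixtureDesign, default_design, sample_label

__all__ = [
    "TruthConfig",
    "SyntheticTruth",
    "NoiseConfig",
    "generate_truth",
    "simulate_benchmark",
    "expression_set_from_truth",
]

#: offset between a symmetric logistic's midpoint and its cpD2 cycle, in units
#: of the slope scale s
CPD2_OFFSET = math.log(2.0 + math.sqrt(3.0))


@dataclass(frozen=True)
class TruthConfig:
    """Distributional choices for the per-feature ground truth.

    Present pure-pool threshold cycles are uniform on ``ct_range``; a feature
    is pool-A-only / pool-B-only / absent-in-both with the given fractions
    (the remainder is expressed in both pools, with independent draws).
    """

    ct_range: tuple[float, float] = (14.0, 30.0)
    frac_a_only: float = 0.15
    frac_b_only: float = 0.15
    frac_absent: float = 0.15
    plateau_range: tuple[float, float] = (1.5, 4.0)
    baseline_range: tuple[float, float] = (0.0, 0.1)
    slope_range: tuple[float, float] = (1.5, 2.5)

    def __post_init__(self) -> None:
        total = self.frac_a_only + self.frac_b_only + self.frac_absent
        if min(self.frac_a_only, self.frac_b_only, self.frac_absent) < 0 or total > 1.0 + 1e-12:
            raise ValueError("pool-membership fractions must be non-negative and sum to at most 1")
        if not (self.ct_range[0] < self.ct_range[1]):
            raise ValueError("ct_range must be an increasing interval")


@dataclass(frozen=True)
class SyntheticTruth:
    """Per-feature ground truth: pure-pool threshold cycles and curve shape.

    ``ct_a`` / ``ct_b`` are NaN where the feature is absent from that pool
    (zero abundance in every mixture).
    """

    table: pd.DataFrame  # feature_id, ct_a, ct_b, plateau, baseline, slope_scale
    config: TruthConfig

    @property
    def n_features(self) -> int:
        return len(self.table)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.table["feature_id"])


@dataclass(frozen=True)
class NoiseConfig:
    """Stochastic components of the simulation.

    ``dropout_expression_midpoint`` (cycles) is the threshold cycle at which a
    reaction holds one template copy on average; dropout probability rises
    sigmoidally beyond it and detected reactions saturate near it.  ``None``
    disables the detection limit entirely.  ``amp_decay`` is the per-cycle
    exponential decay of the plateau beyond cycle 20, tying fluorescence
    signal-to-noise to abundance.
    """

    ct_noise_sd: float = 0.25
    fluor_noise_sd: float = 0.05
    failure_rate: float = 0.01
    dropout_expression_midpoint: float | None = 32.0
    amp_decay: float = 0.015
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.failure_rate <= 1.0):
            raise ValueError("failure_rate must be a probability")
        if min(self.ct_noise_sd, self.fluor_noise_sd) < 0:
            raise ValueError("noise standard deviations must be non-negative")

    @classmethod
    def noiseless(cls, seed: int = 0) -> "NoiseConfig":
        """All noise off, no failures, no dropout: fully deterministic curves."""
        return cls(
            ct_noise_sd=0.0,
            fluor_noise_sd=0.0,
            failure_rate=0.0,
            dropout_expression_midpoint=None,
            seed=seed,
        )


def generate_truth(
    n_features: int, config: TruthConfig | None = None, seed: int = 0
) -> SyntheticTruth:
    """Draw per-feature ground truth; deterministic given the seed."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    cfg = config or TruthConfig()
    rng = np.random.default_rng(seed)
    frac_shared = 1.0 - cfg.frac_a_only - cfg.frac_b_only - cfg.frac_absent
    category = rng.choice(
        4, size=n_features, p=[frac_shared, cfg.frac_a_only, cfg.frac_b_only, cfg.frac_absent]
    )  # 0 shared, 1 A-only, 2 B-only, 3 absent
    lo, hi = cfg.ct_range
    ct_a = rng.uniform(lo, hi, size=n_features)
    ct_b = rng.uniform(lo, hi, size=n_features)
    ct_a[(category == 2) | (category == 3)] = np.nan
    ct_b[(category == 1) | (category == 3)] = np.nan
    width = len(str(n_features))
    table = pd.DataFrame(
        {
            "feature_id": [f"synth-mir-{i + 1:0{width}d}" for i in range(n_features)],
            "ct_a": ct_a,
            "ct_b": ct_b,
            "plateau": rng.uniform(*cfg.plateau_range, size=n_features),
            "baseline": rng.uniform(*cfg.baseline_range, size=n_features),
            "slope_scale": rng.uniform(*cfg.slope_range, size=n_features),
        }
    )
    return SyntheticTruth(table=table, config=cfg)


def simulate_benchmark(
    truth: SyntheticTruth,
    design: MixtureDesign | None = None,
    noise: NoiseConfig | None = None,
    n_replicates: int = 4,
    n_cycles: int = 46,
) -> tuple[AmplificationDataset, pd.DataFrame]:
    """Synthesize the full benchmark dataset plus its per-curve truth table.

    Returns the validated :class:`AmplificationDataset` and a bookkeeping
    table with one row per (feature, sample): the noise-free mixture
    threshold cycle (``expected_ct``), the per-replicate target after jitter
    (``true_ct``), and the ``failed`` / ``dropped`` / ``flat`` flags
    explaining every missing estimate.
    """
    design = design or default_design()
    noise = noise or NoiseConfig()
    if n_cycles < 20:
        raise ValueError("n_cycles must be >= 20")
    rng = np.random.default_rng(noise.seed)

    types = design.sample_types
    n_f, n_t, n_r = truth.n_features, len(types), n_replicates
    ct_a = truth.table["ct_a"].to_numpy()
    ct_b = truth.table["ct_b"].to_numpy()
    # absent-in-pool features contribute zero abundance, encoded as +inf cycles
    ct_a_inf = np.where(np.isnan(ct_a), np.inf, ct_a)
    ct_b_inf = np.where(np.isnan(ct_b), np.inf, ct_b)

    mix_ct = np.empty((n_f, n_t))
    for j, t in enumerate(types):
        w_a, w_b = design.weights[t]
        mix_ct[:, j] = expected_expression(ct_a_inf, ct_b_inf, w_a, w_b)

    # replicate-level target cycles (vectorized; iteration-order independent)
    jitter = rng.normal(0.0, noise.ct_noise_sd, size=(n_f, n_t, n_r)) if noise.ct_noise_sd > 0 else np.zeros((n_f, n_t, n_r))
    target_ct = mix_ct[:, :, None] + jitter

    failed = rng.random(size=(n_f, n_t, n_r)) < noise.failure_rate
    if noise.dropout_expression_midpoint is None:
        dropped = np.zeros_like(failed)
    else:
        # single-molecule limit: Poisson template copies, mean 2**(M - ct);
        # zero copies -> dropout, otherwise the reaction amplifies from the
        # realized copy number (observed ct saturates near M)
        m = noise.dropout_expression_midpoint
        with np.errstate(over="ignore"):
            lam = np.where(np.isfinite(target_ct), np.exp2(m - target_ct), 0.0)
        lam = np.minimum(lam, 1e12)  # keep Poisson draws cheap for abundant targets
        copies = rng.poisson(lam)
        dropped = copies == 0
        with np.errstate(divide="ignore"):
            target_ct = np.where(dropped, target_ct, m - np.log2(np.maximum(copies, 1)))
    flat = failed | dropped | ~np.isfinite(target_ct)

    plateau = truth.table["plateau"].to_numpy()[:, None, None]
    baseline = truth.table["baseline"].to_numpy()[:, None, None]
    s = truth.table["slope_scale"].to_numpy()[:, None, None]
    ct_safe = np.where(np.isfinite(target_ct), target_ct, 0.0)
    d_eff = plateau * np.exp(-noise.amp_decay * np.maximum(0.0, ct_safe - 20.0))
    x_mid = ct_safe + s * CPD2_OFFSET

    cycles = np.arange(1, n_cycles + 1, dtype=float)
    with np.errstate(over="ignore"):
        curves = baseline[..., None] + (d_eff[..., None] - baseline[..., None]) / (
            1.0 + np.exp(-(cycles - x_mid[..., None]) / s[..., None])
        )
    curves = np.where(flat[..., None], np.broadcast_to(baseline[..., None], curves.shape), curves)
    if noise.fluor_noise_sd > 0:
        curves = curves + rng.normal(0.0, noise.fluor_noise_sd, size=curves.shape)

    feature_ids = np.asarray(truth.feature_ids, dtype=object)
    type_arr = np.asarray(types)
    rep_arr = np.arange(1, n_r + 1)
    n_curves = n_f * n_t * n_r
    raw = pd.DataFrame(
        {
            "feature_id": np.repeat(feature_ids, n_t * n_r * n_cycles),
            "sample_type": np.tile(np.repeat(type_arr, n_r * n_cycles), n_f),
            "replicate": np.tile(np.repeat(rep_arr, n_cycles), n_f * n_t),
            "cycle": np.tile(cycles.astype(int), n_curves),
            "delta_rn": curves.reshape(-1),
        }
    )
    raw["sample_id"] = raw["sample_type"].astype(str) + ":" + raw["replicate"].astype(str)
    dataset = AmplificationDataset(raw)

    sample_table = pd.DataFrame(
        {
            "feature_id": np.repeat(feature_ids, n_t * n_r),
            "sample_type": np.tile(np.repeat(type_arr, n_r), n_f),
            "replicate": np.tile(rep_arr, n_f * n_t),
            "expected_ct": np.repeat(mix_ct.reshape(-1), n_r),
            "true_ct": np.where(np.isfinite(target_ct), target_ct, np.nan).reshape(-1),
            "failed": failed.reshape(-1),
            "dropped": dropped.reshape(-1),
            "flat": flat.reshape(-1),
        }
    )
    sample_table["expected_ct"] = sample_table["expected_ct"].replace([np.inf, -np.inf], np.nan)
    sample_table["sample_id"] = (
        sample_table["sample_type"].astype(str) + ":" + sample_table["replicate"].astype(str)
    )
    return dataset, sample_table


def expression_set_from_truth(
    sample_table: pd.DataFrame, method_name: str = "truth"
) -> ExpressionSet:
    """Build the oracle ExpressionSet directly from a simulation truth table.

    Non-flat curves get their true (jittered) threshold cycle with quality 1;
    flat curves get missing expression with quality 0.  Useful for testing
    assessments independently of any curve-fitting step.
    """
    tbl = sample_table.copy()
    tbl["value"] = np.where(tbl["flat"], np.nan, tbl["true_ct"])
    tbl["q"] = np.where(tbl["flat"], 0.0, 1.0)
    expr = tbl.pivot(index="feature_id", columns="sample_id", values="value")
    qual = tbl.pivot(index="feature_id", columns="sample_id", values="q")
    order = sorted(expr.columns, key=lambda c: tuple(int(p) for p in c.split(":")))
    feat_order = list(dict.fromkeys(sample_table["feature_id"]))
    expr = expr.loc[feat_order, order]
    qual = qual.loc[feat_order, order]
    return ExpressionSet(
        method_name=method_name, expression=expr, quality=qual, quality_threshold_default=0.99
    )
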