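"""Benchmark assessments for expression-estimation methods.

All assessments operate on one or two :class:`~qpcrbench.datamodel.ExpressionSet`
objects plus a :class:`~qpcrbench.datamodel.MixtureDesign`.  Expression is in
threshold-cycle units, so *lower* values mean *higher* abundance; "good
quality" always means quality score >= threshold (inclusive, higher is
better).

The mixture model underlying every expected-expression calculation mixes
abundances, not cycles: a sample blending pool A at weight ``wA`` and pool B
at weight ``wB`` (weights relative to a pure sample) has expected expression

    E = -log2(wA * 2**(-E_A) + wB * 2**(-E_B))

where ``E_A``/``E_B`` are the feature's pure-pool threshold cycles.  A weight
of zero removes that pool's term regardless of its pure value; an infinite
pure value encodes a feature absent from that pool (zero abundance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AlignmentError, ExpressionSet, MixtureDesign, split_sample_label

__all__ = [
    "CATEGORIES",
    "QualitySummary",
    "ComparisonResult",
    "CompleteFeatureTable",
    "LODResult",
    "TitrationResult",
    "AccuracyResult",
    "PrecisionResult",
    "expected_expression",
    "quality_summary",
    "expression_comparison",
    "classify_features",
    "complete_features_table",
    "limit_of_detection",
    "titration_response",
    "signal_detect_slopes",
    "precision_summary",
]

CATEGORIES = ("complete", "partial", "absent")


# ---------------------------------------------------------------------------
# expected expression under the mixture model
# ---------------------------------------------------------------------------


def expected_expression(pure_a, pure_b, weight_a: float, weight_b: float):
    """Expected threshold cycle of a mixture from the pure-pool cycles.

    Supports scalar or array/Series pure values.  Features missing a required
    pure value (NaN with a positive weight) yield a missing result; ``inf``
    pure values contribute zero abundance.
    """
    if weight_a < 0 or weight_b < 0:
        raise ValueError("mixture weights must be non-negative")
    if weight_a == 0 and weight_b == 0:
        raise ValueError("at least one mixture weight must be positive")
    index = None
    if isinstance(pure_a, pd.Series) or isinstance(pure_b, pd.Series):
        index = pure_a.index if isinstance(pure_a, pd.Series) else pure_b.index
    a = np.asarray(pure_a, dtype=float)
    b = np.asarray(pure_b, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        term_a = weight_a * np.exp2(-a) if weight_a > 0 else np.zeros_like(a)
        term_b = weight_b * np.exp2(-b) if weight_b > 0 else np.zeros_like(b)
        out = -np.log2(term_a + term_b)
    if index is not None:
        return pd.Series(out, index=index)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _check_axes(es1: ExpressionSet, es2: ExpressionSet) -> None:
    if es1.features != es2.features or list(es1.expression.columns) != list(es2.expression.columns):
        for ax, a, b in (
            ("feature", es1.features, es2.features),
            ("sample", list(es1.expression.columns), list(es2.expression.columns)),
        ):
            if a != b:
                diff = next((x, y) for x, y in zip(a, b) if x != y) if len(a) == len(b) else None
                raise AlignmentError(
                    f"{ax} axes disagree"
                    + (f" (first mismatch: {diff[0]!r} vs {diff[1]!r})" if diff else f" ({len(a)} vs {len(b)})")
                )


def _type_means(es: ExpressionSet, sample_type: int, threshold: float | None):
    """Per-feature mean expression over good-quality replicates of one type.

    Returns (means, n_good, n_replicates); means is NaN where no replicate is
    good quality.
    """
    cols = es.columns_of_type(sample_type)
    if not cols:
        raise ValueError(f"no samples of type {sample_type} in ExpressionSet")
    good = es.good_quality(threshold)[cols]
    expr = es.expression[cols].where(good)
    means = expr.mean(axis=1)
    return means, good.sum(axis=1), len(cols)


def _pure_means(es: ExpressionSet, design: MixtureDesign, threshold: float | None):
    pa, _, _ = _type_means(es, design.pure_a_type, threshold)
    pb, _, _ = _type_means(es, design.pure_b_type, threshold)
    return pa, pb


# ---------------------------------------------------------------------------
# quality summary
# ---------------------------------------------------------------------------


@dataclass
class QualitySummary:
    """Relationship between expression estimates and quality scores."""

    method_name: str
    present: pd.DataFrame          # columns: feature_id, sample_id, expression, quality
    missing_quality: pd.Series     # quality scores of missing-expression entries
    binned_counts: pd.DataFrame    # 2-D histogram (expression bins x quality bins)
    expression_edges: np.ndarray
    quality_edges: np.ndarray
    quality_by_expression_bin: pd.DataFrame  # median quality per expression bin


def quality_summary(es: ExpressionSet, n_bins: int = 25) -> QualitySummary:
    """Pair every present estimate with its quality score; summarize missing ones."""
    expr = es.expression.stack(future_stack=True)
    qual = es.quality.stack(future_stack=True)
    present_mask = expr.notna()
    present = pd.DataFrame(
        {
            "feature_id": [i for i, _ in expr.index[present_mask]],
            "sample_id": [s for _, s in expr.index[present_mask]],
            "expression": expr[present_mask].to_numpy(),
            "quality": qual[present_mask].to_numpy(),
        }
    )
    missing_quality = qual[~present_mask].dropna().rename("quality")
    if len(present):
        e_edges = np.histogram_bin_edges(present["expression"], bins=n_bins)
        q_edges = np.histogram_bin_edges(present["quality"], bins=n_bins)
        counts, _, _ = np.histogram2d(present["expression"], present["quality"], bins=(e_edges, q_edges))
        binned = pd.DataFrame(counts.astype(int))
        bins = pd.cut(present["expression"], e_edges, include_lowest=True)
        med = present.groupby(bins, observed=True)["quality"].median().rename("median_quality")
        by_bin = med.reset_index()
    else:  # degenerate empty set
        e_edges = q_edges = np.array([])
        binned = pd.DataFrame()
        by_bin = pd.DataFrame(columns=["expression", "median_quality"])
    return QualitySummary(
        method_name=es.method_name,
        present=present,
        missing_quality=missing_quality,
        binned_counts=binned,
        expression_edges=e_edges,
        quality_edges=q_edges,
        quality_by_expression_bin=by_bin,
    )


# ---------------------------------------------------------------------------
# expression comparison
# ---------------------------------------------------------------------------


@dataclass
class ComparisonResult:
    """Paired estimates from two methods plus the flagged discrepancies."""

    method1: str
    method2: str
    delta_threshold: float
    pairs: pd.DataFrame    # feature_id, sample_id, expr1, expr2, difference
    flagged: pd.DataFrame  # subset with |difference| > delta_threshold


def expression_comparison(
    es1: ExpressionSet,
    es2: ExpressionSet,
    delta_threshold: float = 2.0,
    qc_threshold1: float | None = None,
    qc_threshold2: float | None = None,
    restrict: str = "both",
) -> ComparisonResult:
    """Pair estimates from two methods and flag large disagreements.

    ``restrict="both"`` (default) keeps only entries of good quality under
    both methods; ``restrict="present"`` keeps every entry estimated by both.
    """
    _check_axes(es1, es2)
    if restrict == "both":
        mask = es1.good_quality(qc_threshold1) & es2.good_quality(qc_threshold2)
    elif restrict == "present":
        mask = es1.expression.notna() & es2.expression.notna()
    else:
        raise ValueError("restrict must be 'both' or 'present'")
    m = mask.to_numpy()
    rows, cols = np.nonzero(m)
    pairs = pd.DataFrame(
        {
            "feature_id": np.asarray(es1.features, dtype=object)[rows],
            "sample_id": es1.expression.columns.to_numpy()[cols],
            "expr1": es1.expression.to_numpy()[m],
            "expr2": es2.expression.to_numpy()[m],
        }
    )
    pairs["difference"] = pairs["expr1"] - pairs["expr2"]
    flagged = pairs[pairs["difference"].abs() > delta_threshold].reset_index(drop=True)
    return ComparisonResult(
        method1=es1.method_name,
        method2=es2.method_name,
        delta_threshold=delta_threshold,
        pairs=pairs,
        flagged=flagged,
    )


# ---------------------------------------------------------------------------
# complete features
# ---------------------------------------------------------------------------


def classify_features(es: ExpressionSet, qc_threshold: float | None = None) -> pd.Series:
    """Classify each feature as complete / partial / absent.

    complete: detected with good quality in every sample; absent: in none;
    partial: otherwise.  The categories partition the feature set.
    """
    good = es.good_quality(qc_threshold)
    n_good = good.sum(axis=1)
    cat = np.where(n_good == good.shape[1], "complete", np.where(n_good == 0, "absent", "partial"))
    return pd.Series(pd.Categorical(cat, categories=list(CATEGORIES)), index=es.expression.index, name="category")


@dataclass
class CompleteFeatureTable:
    """Cross-tabulation of feature categories under two methods."""

    method1: str
    method2: str
    table: pd.DataFrame  # 3x3 counts, rows = method1 category, cols = method2

    @property
    def margins1(self) -> pd.Series:
        return self.table.sum(axis=1)

    @property
    def margins2(self) -> pd.Series:
        return self.table.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.table.to_numpy().sum())


def complete_features_table(
    es1: ExpressionSet,
    es2: ExpressionSet,
    qc_threshold1: float | None = None,
    qc_threshold2: float | None = None,
) -> CompleteFeatureTable:
    _check_axes(es1, es2)
    c1 = classify_features(es1, qc_threshold1)
    c2 = classify_features(es2, qc_threshold2)
    table = pd.crosstab(c1, c2, dropna=False)
    table = table.reindex(index=list(CATEGORIES), columns=list(CATEGORIES), fill_value=0)
    table.index.name = es1.method_name
    table.columns.name = es2.method_name
    return CompleteFeatureTable(method1=es1.method_name, method2=es2.method_name, table=table)


# ---------------------------------------------------------------------------
# limit of detection
# ---------------------------------------------------------------------------


@dataclass
class LODResult:
    """Limit-of-detection assessment for the low-input sample types."""

    method_name: str
    tolerances: tuple[float, ...]
    per_feature: pd.DataFrame   # comparison, feature_id, expected, observed, difference, proportion_poor_quality
    thresholds: pd.DataFrame    # rows = comparisons, columns = tolerances (NaN if never reached)
    boxplot_data: pd.DataFrame  # feature_id, sample_type, mean_expression, proportion_poor_quality


def _lod_threshold(expected: np.ndarray, diffs: np.ndarray, tolerance: float) -> float:
    """Smallest candidate expected-expression value t such that the median
    |observed - expected| among features with expected >= t is >= tolerance.

    Candidates are the observed expected values themselves (no interpolation);
    NaN when the tolerance is never reached.  Monotone non-decreasing in the
    tolerance by construction.
    """
    order = np.argsort(expected, kind="mergesort")
    exp_s = expected[order]
    abs_s = np.abs(diffs[order])
    for i, cand in enumerate(exp_s):
        if i > 0 and cand == exp_s[i - 1]:
            continue
        if np.median(abs_s[i:]) >= tolerance:
            return float(cand)
    return float("nan")


def limit_of_detection(
    es: ExpressionSet,
    design: MixtureDesign,
    tolerances: Sequence[float] = (0.5, 0.75, 1.0),
    qc_threshold: float | None = None,
) -> LODResult:
    """Estimate potential limits of detection from the low-input types.

    Three comparisons are evaluated: each low-input type against the
    expectation from the pure pools, and the lower-input type against the
    higher-input one (expected shifted by the log2 dilution ratio).  For each
    tolerance the reported threshold is the smallest expected-expression value
    beyond which the median absolute difference reaches the tolerance.
    """
    tolerances = tuple(sorted(float(t) for t in tolerances))
    t9, t10 = design.low_input_types
    pa, pb = _pure_means(es, design, qc_threshold)
    obs = {}
    poor = {}
    for t in (t9, t10):
        means, n_good, n_rep = _type_means(es, t, qc_threshold)
        obs[t] = means
        poor[t] = 1.0 - n_good / n_rep
    ratio = design.weights[t9][0] / design.weights[t10][0]

    comparisons = {
        f"type{t9}_vs_pure": (obs[t9], expected_expression(pa, pb, *design.weights[t9]), poor[t9]),
        f"type{t10}_vs_pure": (obs[t10], expected_expression(pa, pb, *design.weights[t10]), poor[t10]),
        f"type{t10}_vs_type{t9}": (obs[t10], obs[t9] + np.log2(ratio), poor[t10]),
    }

    records = []
    thresholds = pd.DataFrame(index=list(comparisons), columns=list(tolerances), dtype=float)
    for name, (observed, expected, prop_poor) in comparisons.items():
        expected = expected.replace([np.inf, -np.inf], np.nan)
        df = pd.DataFrame(
            {
                "comparison": name,
                "feature_id": es.features,
                "expected": expected.to_numpy(),
                "observed": observed.to_numpy(),
                "proportion_poor_quality": prop_poor.to_numpy(),
            }
        )
        df["difference"] = df["observed"] - df["expected"]
        records.append(df)
        usable = df.dropna(subset=["expected", "observed"])
        for tol in tolerances:
            if len(usable):
                thresholds.loc[name, tol] = _lod_threshold(
                    usable["expected"].to_numpy(), usable["difference"].to_numpy(), tol
                )
    per_feature = pd.concat(records, ignore_index=True)

    # replicate-group summary across all sample types (boxplot companion)
    box = []
    for t in sorted(set(es.sample_types)):
        cols = es.columns_of_type(t)
        good = es.good_quality(qc_threshold)[cols]
        mean_expr = es.expression[cols].mean(axis=1)  # over present estimates
        box.append(
            pd.DataFrame(
                {
                    "feature_id": es.features,
                    "sample_type": t,
                    "mean_expression": mean_expr.to_numpy(),
                    "proportion_poor_quality": 1.0 - good.sum(axis=1).to_numpy() / len(cols),
                }
            )
        )
    return LODResult(
        method_name=es.method_name,
        tolerances=tolerances,
        per_feature=per_feature,
        thresholds=thresholds,
        boxplot_data=pd.concat(box, ignore_index=True),
    )


# ---------------------------------------------------------------------------
# titration response
# ---------------------------------------------------------------------------


@dataclass
class TitrationResult:
    """Monotone-response assessment along the two titration series."""

    method_name: str
    per_feature: pd.DataFrame  # series, feature_id, responder, d, evaluable
    counts: pd.DataFrame       # rows = series, columns = responders / non_responders
    binned: pd.DataFrame       # series, bin_lo, bin_hi, n, proportion_responding


def _series_info(design: MixtureDesign, key: str):
    info = design.series()[key]
    types = list(info["types"])
    titrated_axis = 0 if info["titrated"] == "A" else 1
    # order by increasing titrated weight
    types.sort(key=lambda t: design.weights[t][titrated_axis])
    return types, titrated_axis


def titration_response(
    es: ExpressionSet,
    design: MixtureDesign,
    qc_threshold: float | None = None,
    n_bins: int = 10,
) -> TitrationResult:
    """Flag features whose expression responds monotonically to titration.

    A responder shows strictly decreasing replicate-mean expression (strictly
    increasing abundance) as the titrated component's input doubles along the
    series; ties count as non-response.  The stratum ``d`` is the pure-sample
    expression of the constant component minus that of the titrated component,
    so ``d > 0`` means the titrated component is the more abundant one.
    """
    pa, pb = _pure_means(es, design, qc_threshold)
    frames = []
    for key in ("A", "B"):
        types, titrated_axis = _series_info(design, key)
        means = [
            _type_means(es, t, qc_threshold)[0] for t in types
        ]
        mat = pd.concat(means, axis=1)
        evaluable = mat.notna().all(axis=1)
        diffs = mat.diff(axis=1).iloc[:, 1:]
        responder = evaluable & (diffs < 0).all(axis=1)
        titrated_pure, constant_pure = (pa, pb) if titrated_axis == 0 else (pb, pa)
        d = constant_pure - titrated_pure
        frames.append(
            pd.DataFrame(
                {
                    "series": key,
                    "feature_id": es.features,
                    "evaluable": evaluable.to_numpy(),
                    "responder": responder.to_numpy(),
                    "d": d.to_numpy(),
                }
            )
        )
    per_feature = pd.concat(frames, ignore_index=True)
    ev = per_feature[per_feature["evaluable"]]
    counts = (
        ev.groupby("series")["responder"]
        .agg(responders="sum", non_responders=lambda s: int((~s).sum()))
        .astype(int)
    )

    binned_rows = []
    for key, grp in ev.dropna(subset=["d"]).groupby("series"):
        if len(grp) < 2:
            continue
        k = min(n_bins, max(1, len(grp) // 2))
        bins = pd.qcut(grp["d"], k, duplicates="drop")
        agg = grp.groupby(bins, observed=True)["responder"].agg(["size", "mean"])
        for interval, row in agg.iterrows():
            binned_rows.append(
                {
                    "series": key,
                    "bin_lo": interval.left,
                    "bin_hi": interval.right,
                    "n": int(row["size"]),
                    "proportion_responding": float(row["mean"]),
                }
            )
    return TitrationResult(
        method_name=es.method_name,
        per_feature=per_feature,
        counts=counts,
        binned=pd.DataFrame(binned_rows, columns=["series", "bin_lo", "bin_hi", "n", "proportion_responding"]),
    )


# ---------------------------------------------------------------------------
# accuracy: signal detect slopes
# ---------------------------------------------------------------------------


@dataclass
class AccuracyResult:
    """Signal-detect slopes: observed regressed on expected expression."""

    method_name: str
    per_feature: pd.DataFrame  # series, feature_id, slope, p_value, significant, n_points, d
    summary: pd.DataFrame      # tertile bins over d: bin_lo, bin_hi, n, median_slope, mad_slope


def signal_detect_slopes(
    es: ExpressionSet,
    design: MixtureDesign,
    qc_threshold: float | None = None,
    alpha: float = 0.05,
) -> AccuracyResult:
    """Per feature and titration series, OLS slope of observed on expected.

    Observed values are replicate-level good-quality estimates (up to 12
    points per feature/series); expected values come from the mixture model
    applied to the pure-pool replicate means.  The ideal slope is 1.  Features
    with fewer than 3 usable points (or no spread in expected) get a missing
    slope.  The summary stratifies slopes into tertiles of the pure-sample
    difference ``d`` and reports median and MAD (normal-consistent) per bin.
    """
    pa, pb = _pure_means(es, design, qc_threshold)
    good = es.good_quality(qc_threshold)
    rows = []
    for key in ("A", "B"):
        types, titrated_axis = _series_info(design, key)
        titrated_pure, constant_pure = (pa, pb) if titrated_axis == 0 else (pb, pa)
        d = constant_pure - titrated_pure
        expected_by_type = {
            t: expected_expression(pa, pb, *design.weights[t]).replace([np.inf, -np.inf], np.nan)
            for t in types
        }
        cols_by_type = {t: es.columns_of_type(t) for t in types}
        for fi, feat in enumerate(es.features):
            xs, ys = [], []
            for t in types:
                exp_val = expected_by_type[t].iloc[fi]
                if not np.isfinite(exp_val):
                    continue
                for c in cols_by_type[t]:
                    if good.at[feat, c]:
                        xs.append(exp_val)
                        ys.append(es.expression.at[feat, c])
            slope = p_value = float("nan")
            if len(xs) >= 3 and len(set(xs)) >= 2:
                res = stats.linregress(xs, ys)
                slope = float(res.slope)
                p_value = float(res.pvalue)
            rows.append(
                {
                    "series": key,
                    "feature_id": feat,
                    "slope": slope,
                    "p_value": p_value,
                    "significant": bool(p_value < alpha) if np.isfinite(p_value) else False,
                    "n_points": len(xs),
                    "d": float(d.iloc[fi]) if np.isfinite(d.iloc[fi]) else float("nan"),
                }
            )
    per_feature = pd.DataFrame(rows)

    ev = per_feature.dropna(subset=["slope", "d"])
    summary_rows = []
    if len(ev) >= 3:
        bins = pd.qcut(ev["d"], 3, duplicates="drop")
        for interval, grp in ev.groupby(bins, observed=True):
            summary_rows.append(
                {
                    "bin_lo": interval.left,
                    "bin_hi": interval.right,
                    "n": len(grp),
                    "median_slope": float(grp["slope"].median()),
                    "mad_slope": float(stats.median_abs_deviation(grp["slope"], scale="normal")),
                }
            )
    return AccuracyResult(
        method_name=es.method_name,
        per_feature=per_feature,
        summary=pd.DataFrame(summary_rows, columns=["bin_lo", "bin_hi", "n", "median_slope", "mad_slope"]),
    )


# ---------------------------------------------------------------------------
# precision
# ---------------------------------------------------------------------------


@dataclass
class PrecisionResult:
    """Within-replicate-group spread of the expression estimates."""

    method_name: str
    per_group: pd.DataFrame  # feature_id, sample_type, n, mean, sd, cv
    summary: pd.DataFrame    # 3 equal-size bins by mean expression


def precision_summary(es: ExpressionSet, qc_threshold: float | None = None) -> PrecisionResult:
    """Within-replicate SD and CV per feature x sample-type group.

    A group enters the assessment when every *present* replicate estimate is
    of good quality and at least two are present.  SD uses the n-1
    denominator; CV = SD / mean.  The summary stratifies groups into three
    equal-size bins by mean expression.
    """
    good = es.good_quality(qc_threshold)
    rows = []
    for t in sorted(set(es.sample_types)):
        cols = es.columns_of_type(t)
        expr = es.expression[cols]
        present = expr.notna()
        n_present = present.sum(axis=1)
        # every present replicate must be good quality
        ok = (n_present >= 2) & (good[cols] | ~present).all(axis=1)
        mean = expr.mean(axis=1)
        sd = expr.std(axis=1, ddof=1)
        sub = pd.DataFrame(
            {
                "feature_id": es.features,
                "sample_type": t,
                "n": n_present.to_numpy(),
                "mean": mean.to_numpy(),
                "sd": sd.to_numpy(),
            }
        )[ok.to_numpy()]
        rows.append(sub)
    per_group = pd.concat(rows, ignore_index=True)
    per_group["cv"] = per_group["sd"] / per_group["mean"]

    summary_rows = []
    if len(per_group) >= 3:
        bins = pd.qcut(per_group["mean"], 3, duplicates="drop")
        for interval, grp in per_group.groupby(bins, observed=True):
            summary_rows.append(
                {
                    "bin_lo": interval.left,
                    "bin_hi": interval.right,
                    "n": len(grp),
                    "median_sd": float(grp["sd"].median()),
                    "median_cv": float(grp["cv"].median()),
                }
            )
    return PrecisionResult(
        method_name=es.method_name,
        per_group=per_group,
        summary=pd.DataFrame(summary_rows, columns=["bin_lo", "bin_hi", "n", "median_sd", "median_cv"]),
    )
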