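"""Core data structures and tabular IO.

Raw qPCR data are long-format tables with one baseline-corrected fluorescence
reading (dRn) per (feature, sample, cycle).  Expression estimates live in
paired features x samples matrices: one matrix of threshold cycles (missing
allowed) and one of quality scores (higher is better).  Samples are identified
as ``"<sample_type>:<replicate>"``; sample types follow the two-pool
mixture/dilution design encoded by :class:`MixtureDesign`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "AlignmentError",
    "CurveLookupError",
    "AmplificationCurve",
    "AmplificationDataset",
    "ExpressionSet",
    "MixtureDesign",
    "default_design",
    "read_amplification_table",
    "read_expression_set",
    "sample_label",
    "split_sample_label",
]


class SchemaError(ValueError):
    """An input table is missing a required column."""


class ValidationError(ValueError):
    """An input table violates a dataset invariant."""


class AlignmentError(ValueError):
    """Two matrices that must share axis labels disagree."""


class CurveLookupError(KeyError):
    """A requested (feature, sample) pair is not in the dataset."""


#: canonical column order of the long-format raw table
RAW_COLUMNS = ["feature_id", "sample_type", "replicate", "sample_id", "cycle", "delta_rn"]


def sample_label(sample_type: int, replicate: int) -> str:
    """Return the canonical sample identifier ``"<type>:<replicate>"``."""
    return f"{int(sample_type)}:{int(replicate)}"


def split_sample_label(label: str) -> tuple[int, int]:
    """Inverse of :func:`sample_label`."""
    t, r = str(label).split(":")
    return int(t), int(r)


@dataclass(frozen=True)
class AmplificationCurve:
    """A single amplification trajectory: dRn versus cycle."""

    feature_id: str
    sample_id: str
    cycles: np.ndarray
    delta_rn: np.ndarray

    def __post_init__(self) -> None:
        cy = np.asarray(self.cycles, dtype=float)
        dr = np.asarray(self.delta_rn, dtype=float)
        if cy.shape != dr.shape or cy.ndim != 1:
            raise ValidationError("cycles and delta_rn must be 1-D vectors of equal length")
        if len(cy) > 1 and not np.all(np.diff(cy) > 0):
            raise ValidationError("cycles must be strictly increasing")
        object.__setattr__(self, "cycles", cy)
        object.__setattr__(self, "delta_rn", dr)

    def __len__(self) -> int:
        return len(self.cycles)


class AmplificationDataset:
    """Validated long-format collection of amplification curves.

    Invariants enforced at construction:

    * every curve covers the contiguous cycle range ``1..C`` exactly once,
    * all curves share the same maximum cycle ``C``,
    * ``(sample_type, replicate)`` determines ``sample_id`` uniquely.
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in RAW_COLUMNS if c not in data.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df = data.loc[:, RAW_COLUMNS].copy()
        df["feature_id"] = df["feature_id"].astype(str)
        df["sample_id"] = df["sample_id"].astype(str)
        for col in ("sample_type", "replicate", "cycle"):
            df[col] = df[col].astype(int)
        df["delta_rn"] = df["delta_rn"].astype(float)
        df = df.sort_values(["feature_id", "sample_type", "replicate", "cycle"], kind="mergesort")
        df = df.reset_index(drop=True)
        self.data = df
        self.n_cycles = int(df["cycle"].max())
        self._validate()
        # index of row-block start per curve for O(1) extraction
        self._index = {
            key: pos
            for pos, key in enumerate(
                df.iloc[:: self.n_cycles][["feature_id", "sample_id"]].itertuples(index=False, name=None)
            )
        }

    def _validate(self) -> None:
        df = self.data
        C = self.n_cycles
        if df["cycle"].min() < 1:
            raise ValidationError("cycle numbers must be >= 1")
        sizes = df.groupby(["feature_id", "sample_id"], sort=False).agg(
            n=("cycle", "size"), lo=("cycle", "min"), hi=("cycle", "max"), nuniq=("cycle", "nunique")
        )
        bad = sizes[(sizes["n"] != C) | (sizes["lo"] != 1) | (sizes["hi"] != C) | (sizes["nuniq"] != C)]
        if len(bad):
            offenders = ", ".join(f"({f}, {s})" for f, s in bad.index[:10])
            raise ValidationError(
                f"curves without one reading per cycle 1..{C}: {offenders}"
                + ("..." if len(bad) > 10 else "")
            )
        pairing = df[["sample_id", "sample_type", "replicate"]].drop_duplicates()
        if pairing["sample_id"].duplicated().any() or pairing.duplicated(["sample_type", "replicate"]).any():
            raise ValidationError("(sample_type, replicate) must identify sample_id uniquely")

    # -- accessors ---------------------------------------------------------

    @property
    def features(self) -> list[str]:
        return list(dict.fromkeys(self.data["feature_id"]))

    @property
    def samples(self) -> list[tuple[int, int]]:
        pairs = self.data[["sample_type", "replicate"]].drop_duplicates().sort_values(
            ["sample_type", "replicate"]
        )
        return list(pairs.itertuples(index=False, name=None))

    @property
    def sample_ids(self) -> list[str]:
        return [sample_label(t, r) for t, r in self.samples]

    @property
    def n_curves(self) -> int:
        return len(self.data) // self.n_cycles

    def extract_curve(self, feature_id: str, sample_id: str) -> AmplificationCurve:
        """Return the full curve for one (feature, sample) pair."""
        try:
            pos = self._index[(str(feature_id), str(sample_id))]
        except KeyError:
            raise CurveLookupError(f"no curve for feature {feature_id!r}, sample {sample_id!r}") from None
        block = self.data.iloc[pos * self.n_cycles : (pos + 1) * self.n_cycles]
        return AmplificationCurve(
            feature_id=str(feature_id),
            sample_id=str(sample_id),
            cycles=block["cycle"].to_numpy(dtype=float),
            delta_rn=block["delta_rn"].to_numpy(dtype=float),
        )

    def iter_curves(self) -> Iterable[AmplificationCurve]:
        """Yield every curve in (feature, sample) order."""
        C = self.n_cycles
        feats = self.data["feature_id"].to_numpy()
        sids = self.data["sample_id"].to_numpy()
        drn = self.data["delta_rn"].to_numpy()
        cyc = self.data["cycle"].to_numpy(dtype=float)
        for start in range(0, len(self.data), C):
            yield AmplificationCurve(
                feature_id=feats[start],
                sample_id=sids[start],
                cycles=cyc[start : start + C],
                delta_rn=drn[start : start + C],
            )

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"AmplificationDataset({len(self.features)} features x "
            f"{self.n_curves // max(len(self.features), 1)} samples x {self.n_cycles} cycles)"
        )


def read_amplification_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> AmplificationDataset:
    """Read a delimited long-format amplification table.

    Parameters
    ----------
    path
        CSV file with a header row.
    column_map
        Maps logical names (``feature_id``, ``sample_type``, ``replicate``,
        ``cycle``, ``delta_rn`` and optionally ``sample_id``) to the file's
        native headers, so exports with vendor naming can be ingested without
        rewriting the file.
    """
    df = pd.read_csv(path)
    if column_map:
        inverse = {v: k for k, v in column_map.items()}
        df = df.rename(columns=inverse)
    required = [c for c in RAW_COLUMNS if c != "sample_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if "sample_id" not in df.columns:
        df["sample_id"] = [
            sample_label(t, r) for t, r in zip(df["sample_type"], df["replicate"])
        ]
    return AmplificationDataset(df)


@dataclass
class ExpressionSet:
    """Paired features x samples matrices of expression estimates and quality.

    ``expression`` holds threshold cycles (missing allowed); ``quality`` holds
    the method's quality score with the fixed orientation *higher is better*.
    Quality is never missing where expression is present; entries with missing
    expression may still carry a quality value (set the score to 0 when the
    method reports nothing).
    """

    method_name: str
    expression: pd.DataFrame
    quality: pd.DataFrame
    quality_threshold_default: float = 0.99

    def __post_init__(self) -> None:
        e, q = self.expression, self.quality
        if list(e.index) != list(q.index) or list(e.columns) != list(q.columns):
            raise AlignmentError(_first_axis_mismatch(e, q))
        self.expression = e.astype(float)
        self.quality = q.astype(float)
        bad = self.expression.notna() & self.quality.isna()
        if bad.to_numpy().any():
            f = bad.any(axis=1)
            raise ValidationError(
                f"quality missing where expression present (first feature: {f[f].index[0]!r})"
            )

    # -- axes --------------------------------------------------------------

    @property
    def features(self) -> list[str]:
        return list(self.expression.index)

    @property
    def samples(self) -> list[tuple[int, int]]:
        return [split_sample_label(c) for c in self.expression.columns]

    @property
    def sample_types(self) -> np.ndarray:
        return np.array([t for t, _ in self.samples])

    def good_quality(self, threshold: float | None = None) -> pd.DataFrame:
        """Boolean mask: expression present and quality >= threshold."""
        thr = self.quality_threshold_default if threshold is None else threshold
        return self.expression.notna() & (self.quality >= thr)

    def columns_of_type(self, sample_type: int) -> list[str]:
        return [c for c in self.expression.columns if split_sample_label(c)[0] == sample_type]

    def to_csv(self, expr_path: str | Path, quality_path: str | Path) -> None:
        self.expression.to_csv(expr_path)
        self.quality.to_csv(quality_path)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n_f, n_s = self.expression.shape
        return f"ExpressionSet(method={self.method_name!r}, {n_f} features x {n_s} samples)"


def _first_axis_mismatch(e: pd.DataFrame, q: pd.DataFrame) -> str:
    for ax, a, b in (("feature", e.index, q.index), ("sample", e.columns, q.columns)):
        if len(a) != len(b):
            return f"{ax} axes differ in length ({len(a)} vs {len(b)})"
        for x, y in zip(a, b):
            if x != y:
                return f"first disagreeing {ax} label: {x!r} vs {y!r}"
    return "axes disagree"


_NA_SENTINELS = ["", "NA", "NaN", "nan", "N/A", "null", "Undetermined"]


def read_expression_set(
    expr_path: str | Path,
    quality_path: str | Path,
    method_name: str,
    quality_threshold_default: float = 0.99,
) -> ExpressionSet:
    """Read paired expression / quality CSV matrices.

    Both files must carry identical feature row labels and sample column
    labels; the quality matrix is aligned to the expression matrix by label
    (row/column order in the file does not matter).  Blank cells and the usual
    NA spellings become missing expression.
    """
    expr = pd.read_csv(expr_path, index_col=0, na_values=_NA_SENTINELS, keep_default_na=True)
    qual = pd.read_csv(quality_path, index_col=0, na_values=_NA_SENTINELS, keep_default_na=True)
    expr.index = expr.index.astype(str)
    qual.index = qual.index.astype(str)
    if set(expr.index) != set(qual.index) or set(expr.columns) != set(qual.columns):
        raise AlignmentError(_first_axis_mismatch(expr, qual))
    qual = qual.loc[expr.index, expr.columns]
    return ExpressionSet(
        method_name=method_name,
        expression=expr,
        quality=qual,
        quality_threshold_default=quality_threshold_default,
    )


@dataclass(frozen=True)
class MixtureDesign:
    """The 10-sample-type two-pool mixture/dilution design.

    Pool weights are expressed relative to a pure sample (weight 1.0).  Two
    titration series share a constant component while the other component's
    weight doubles twice (0.2 -> 0.4 -> 0.8); two low-input types dilute an
    equal-parts mixture of both pools.
    """

    weights: Mapping[int, tuple[float, float]]
    pure_a_type: int = 1
    pure_b_type: int = 5
    #: sample types where pool A is constant and pool B is titrated
    series_b_titrated: tuple[int, ...] = (2, 3, 4)
    #: sample types where pool B is constant and pool A is titrated
    series_a_titrated: tuple[int, ...] = (6, 7, 8)
    low_input_types: tuple[int, ...] = (9, 10)

    def __post_init__(self) -> None:
        w = dict(self.weights)
        object.__setattr__(self, "weights", w)
        if w[self.pure_a_type] != (1.0, 0.0) or w[self.pure_b_type] != (0.0, 1.0):
            raise ValidationError("pure sample types must have weights (1,0) and (0,1)")
        for series, titrated_axis in ((self.series_b_titrated, 1), (self.series_a_titrated, 0)):
            const_axis = 1 - titrated_axis
            titrated = [w[t][titrated_axis] for t in series]
            for t in series:
                if w[t][const_axis] != 1.0:
                    raise ValidationError(f"constant component of sample type {t} must have weight 1.0")
            for lo, hi in zip(titrated, titrated[1:]):
                if not np.isclose(hi, 2 * lo):
                    raise ValidationError("titrated weight must double along each series")
        for t in self.low_input_types:
            if w[t][0] != w[t][1]:
                raise ValidationError(f"low-input type {t} must have equal pool weights")

    @property
    def sample_types(self) -> list[int]:
        return sorted(self.weights)

    def series(self) -> dict[str, dict]:
        """The two titration series keyed by the *titrated* component."""
        return {
            "A": {"types": self.series_a_titrated, "titrated": "A", "constant": "B"},
            "B": {"types": self.series_b_titrated, "titrated": "B", "constant": "A"},
        }

    def to_dict(self) -> dict:
        return {
            "weights": {str(t): list(w) for t, w in sorted(self.weights.items())},
            "pure_a_type": self.pure_a_type,
            "pure_b_type": self.pure_b_type,
            "series_b_titrated": list(self.series_b_titrated),
            "series_a_titrated": list(self.series_a_titrated),
            "low_input_types": list(self.low_input_types),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MixtureDesign":
        return cls(
            weights={int(t): tuple(w) for t, w in d["weights"].items()},
            pure_a_type=int(d.get("pure_a_type", 1)),
            pure_b_type=int(d.get("pure_b_type", 5)),
            series_b_titrated=tuple(d.get("series_b_titrated", (2, 3, 4))),
            series_a_titrated=tuple(d.get("series_a_titrated", (6, 7, 8))),
            low_input_types=tuple(d.get("low_input_types", (9, 10))),
        )


def default_design() -> MixtureDesign:
    """The benchmark's standard 10-type design.

    Types 1 and 5 are the pure pools.  In types 2-4 pool A is held constant
    while pool B's relative weight doubles twice (0.2, 0.4, 0.8); types 6-8
    mirror this with pool B constant.  Types 9 and 10 are ten- and
    hundred-fold dilutions of an equal-weight blend of both pools.
    """
    return MixtureDesign(
        weights={
            1: (1.0, 0.0),
            2: (1.0, 0.2),
            3: (1.0, 0.4),
            4: (1.0, 0.8),
            5: (0.0, 1.0),
            6: (0.2, 1.0),
            7: (0.4, 1.0),
            8: (0.8, 1.0),
            9: (0.1, 0.1),
            10: (0.01, 0.01),
        }
    )
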