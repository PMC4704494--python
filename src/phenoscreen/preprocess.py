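"""Well-level preprocessing: glog transform, QC, reproducibility, and
stepwise selection of informative, non-redundant features.

The selection procedure starts from cell number and, at each iteration,
regresses every feature on the already-selected features within each
replicate; the Pearson correlation between the two replicates' residual
vectors scores how much reproducible information a feature still carries.
The feature with the highest score is selected next, and the procedure
stops once fewer than half of all features have positive residual
correlation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .synthgen import ANNOTATION_COLUMNS

__all__ = [
    "glog",
    "glog_inverse",
    "glog_transform",
    "QCRules",
    "qc_wells",
    "replicate_correlation",
    "FeatureSelectionResult",
    "select_features",
    "PHENOPRINT_CATEGORIES",
    "default_category_map",
    "group_phenoprint",
    "plot_phenoprint",
    "feature_columns",
    "align_replicates",
]

_NON_FEATURE = set(ANNOTATION_COLUMNS) | {"qc_flag", "saturated_frac"}


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Columns of a well table that hold feature values."""
    return [c for c in table.columns if c not in _NON_FEATURE]


# ---------------------------------------------------------------------------
# Generalized logarithm
# ---------------------------------------------------------------------------


def glog(x, c: float = 1.0):
    """Generalized log2, ``log2((x + sqrt(x^2 + c^2)) / 2)``.

    Variance-stabilizing: approximately linear near 0, converging to
    ``log2(x)`` for ``x >> c``. Defined at ``x = 0`` (value ``log2(c/2)``).
    """
    if c <= 0:
        raise ValueError("calibration constant c must be positive")
    x = np.asarray(x, dtype=float)
    return np.log2((x + np.sqrt(x * x + c * c)) / 2.0)


def glog_inverse(y, c: float = 1.0):
    """Inverse of :func:`glog`; round-trips to better than 1e-9."""
    if c <= 0:
        raise ValueError("calibration constant c must be positive")
    u = 2.0 * np.exp2(np.asarray(y, dtype=float))
    return (u * u - c * c) / (2.0 * u)


def glog_transform(
    table: pd.DataFrame, c: float = 1.0, columns: list[str] | None = None
) -> pd.DataFrame:
    """Apply :func:`glog` to the feature columns of a well table."""
    out = table.copy()
    for col in columns or feature_columns(table):
        out[col] = glog(out[col].to_numpy(), c)
    return out


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------


@dataclass
class QCRules:
    """Thresholds for flagging failed wells.

    A well is flagged when its cell count is at the floor AND the mean of
    its intensity-like features is at the floor (an empty/blank
    acquisition), or when its saturated-pixel fraction exceeds
    ``max_saturated_frac``. These are generic failure modes, not a
    reconstruction of any particular screen's criteria.
    """

    cell_number_floor: float = 0.5
    intensity_floor: float = 0.5
    max_saturated_frac: float = 0.05
    cell_number_column: str = "cell_number"


def qc_wells(
    table: pd.DataFrame, rules: QCRules | None = None
) -> tuple[pd.DataFrame, dict]:
    """Flag failed wells; returns (table with ``qc_flag``, report).

    Flagged wells must be excluded from all downstream statistics;
    :func:`phenoscreen.interactions.estimate_interactions` drops them.
    """
    rules = rules or QCRules()
    out = table.copy()
    feats = feature_columns(out)
    intensity_cols = [f for f in feats if "int" in f] or [
        f for f in feats if f != rules.cell_number_column
    ]
    blank = out[rules.cell_number_column] <= rules.cell_number_floor
    if intensity_cols:
        blank &= out[intensity_cols].mean(axis=1) <= rules.intensity_floor
    flags = blank.to_numpy()
    if "saturated_frac" in out.columns:
        flags = flags | (out["saturated_frac"] > rules.max_saturated_frac).to_numpy()
    out["qc_flag"] = flags
    report = {"n_flagged": int(flags.sum()), "n_wells": len(out)}
    return out, report


# ---------------------------------------------------------------------------
# Replicate reproducibility
# ---------------------------------------------------------------------------


def align_replicates(
    rep1: pd.DataFrame, rep2: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Match wells between two replicate tables.

    Tables carrying plate/well annotations are matched on
    (compound, cell line, well-within-plate-chunk); bare feature matrices
    are assumed row-aligned.
    """
    keys = [k for k in ("compound_id", "cell_line", "plate", "well") if k in rep1.columns]
    if not keys or not all(k in rep2.columns for k in keys):
        if len(rep1) != len(rep2):
            raise ValueError("replicate tables have no matchable wells")
        return rep1, rep2
    # plate ids differ between replicates; match on the biological identity
    bio = [k for k in ("compound_id", "cell_line", "role") if k in rep1.columns]
    a = rep1.sort_values(bio + [k for k in ("plate", "well") if k in rep1.columns])
    b = rep2.sort_values(bio + [k for k in ("plate", "well") if k in rep2.columns])
    if not (a[bio].reset_index(drop=True) == b[bio].reset_index(drop=True)).all().all():
        raise ValueError("replicate tables do not contain matching wells")
    return a.reset_index(drop=True), b.reset_index(drop=True)


def replicate_correlation(
    rep1: pd.DataFrame, rep2: pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Per-feature correlation between matched replicate wells, ranked.

    Returns a DataFrame (feature, correlation, rank) sorted by descending
    correlation; zero-variance features get an undefined (NaN) correlation
    and rank last.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    a, b = align_replicates(rep1, rep2)
    feats = [f for f in feature_columns(a) if f in feature_columns(b)]
    if not feats or len(a) == 0:
        raise ValueError("no matched wells or shared features between replicates")
    corr = {}
    for f in feats:
        x, y = a[f].to_numpy(float), b[f].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
            corr[f] = np.nan
        elif method == "pearson":
            corr[f] = float(stats.pearsonr(x, y).statistic)
        else:
            corr[f] = float(stats.spearmanr(x, y).statistic)
    out = pd.DataFrame({"feature": feats, "correlation": [corr[f] for f in feats]})
    out = out.sort_values("correlation", ascending=False, na_position="last")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Stepwise selection of non-redundant features
# ---------------------------------------------------------------------------


@dataclass
class FeatureSelectionResult:
    """Outcome of the stepwise residual-correlation selection."""

    selected: list[str]
    scores: list[pd.Series] = field(default_factory=list)  # per-iteration residual corr
    positive_fractions: list[float] = field(default_factory=list)
    stop_reason: str = ""

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    def to_json_dict(self) -> dict:
        return {
            "selected": self.selected,
            "positive_fractions": self.positive_fractions,
            "stop_reason": self.stop_reason,
            "scores": [s.to_dict() for s in self.scores],
        }


def _residual_matrix(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """OLS residuals of every column of Y on the design X (with intercept)."""
    coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn(
            "collinear selected features; dropping redundant directions in the fit",
            stacklevel=3,
        )
    return Y - X @ coef


def select_features(
    rep1: pd.DataFrame,
    rep2: pd.DataFrame,
    start_feature: str = "cell_number",
    threshold: float = 0.5,
    max_features: int | None = None,
    degenerate_tol: float = 1e-8,
) -> FeatureSelectionResult:
    """Stepwise selection of informative, non-redundant features.

    At each iteration every feature is regressed (per replicate, OLS with
    intercept) on the already-selected features; the Pearson correlation of
    the two replicates' residual vectors is the feature's score. The
    highest-scoring unselected feature is added, until the fraction of all
    features with a positive score drops below ``threshold``. Selected
    features have (numerically) zero residuals, hence an undefined score
    that counts as non-positive. Deterministic; ties broken by feature name.
    """
    a, b = align_replicates(rep1, rep2)
    feats = [f for f in feature_columns(a) if f in feature_columns(b)]
    if start_feature not in feats:
        raise ValueError(f"start feature {start_feature!r} not present in both replicates")
    Y1 = a[feats].to_numpy(float)
    Y2 = b[feats].to_numpy(float)
    n = Y1.shape[0]
    scale = np.sqrt(
        np.maximum(
            ((Y1 - Y1.mean(0)) ** 2).sum(0) * ((Y2 - Y2.mean(0)) ** 2).sum(0), 1e-300
        )
    )

    selected = [start_feature]
    result = FeatureSelectionResult(selected=selected)
    limit = max_features or len(feats)
    while True:
        idx = [feats.index(f) for f in selected]
        X1 = np.column_stack([np.ones(n), Y1[:, idx]])
        X2 = np.column_stack([np.ones(n), Y2[:, idx]])
        E1 = _residual_matrix(Y1, X1)
        E2 = _residual_matrix(Y2, X2)
        s1 = np.sqrt((E1**2).sum(0))
        s2 = np.sqrt((E2**2).sum(0))
        denom = s1 * s2
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (E1 * E2).sum(0) / denom
        # features explained (numerically) exactly have no defined residual
        # correlation; count them as non-positive rather than as noise
        degenerate = denom <= degenerate_tol * scale
        corr[degenerate] = np.nan
        scores = pd.Series(corr, index=feats)
        frac_positive = float(np.mean(scores.to_numpy() > 0))
        result.scores.append(scores)
        result.positive_fractions.append(frac_positive)
        if frac_positive < threshold:
            result.stop_reason = "positive-fraction below threshold"
            break
        candidates = scores.drop(index=selected).dropna()
        if candidates.empty:
            result.stop_reason = "no remaining candidates"
            break
        best = candidates.max()
        # deterministic tie-break: lexicographically first name among ties
        tied = sorted(candidates.index[candidates >= best - 1e-12])
        selected.append(tied[0])
        if len(selected) >= limit:
            result.stop_reason = "feature limit reached"
            break
    return result


# ---------------------------------------------------------------------------
# Phenoprints
# ---------------------------------------------------------------------------

PHENOPRINT_CATEGORIES = [
    "cell number",
    "DNA texture/intensity",
    "nuclear shape",
    "cell shape",
    "actin texture/intensity",
]


def default_category_map(features: list[str]) -> dict[str, str]:
    """Map feature names onto the five phenoprint categories by name pattern."""
    mapping = {}
    for f in features:
        name = f.lower()
        if name in ("cell_number", "n_cells", "cell_count"):
            mapping[f] = "cell number"
        elif "dna" in name:
            mapping[f] = "DNA texture/intensity"
        elif "actin" in name:
            mapping[f] = "actin texture/intensity"
        elif name.startswith(("nuc", "n_")):
            mapping[f] = "nuclear shape"
        elif name.startswith(("cell", "c_")):
            mapping[f] = "cell shape"
    return mapping


@dataclass
class PhenoprintSpec:
    """Ordered radar-chart layout: features grouped by phenotypic category."""

    features: list[str]
    categories: list[str]

    @property
    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.categories:
            counts[c] = counts.get(c, 0) + 1
        return counts

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for f, c in zip(self.features, self.categories):
            out.setdefault(c, []).append(f)
        return out


def group_phenoprint(
    selected: list[str], category_map: Mapping[str, str] | None = None
) -> PhenoprintSpec:
    """Order selected features into the radar-chart (phenoprint) layout.

    Every selected feature must map to one of the five categories; the
    radial axes are ordered by category so that related features are
    adjacent on the chart.
    """
    category_map = dict(category_map) if category_map else default_category_map(selected)
    unmapped = [f for f in selected if f not in category_map]
    if unmapped:
        raise ValueError(f"features without a phenoprint category: {unmapped}")
    bad = {f: c for f, c in category_map.items() if f in selected and c not in PHENOPRINT_CATEGORIES}
    if bad:
        raise ValueError(f"unknown phenoprint categories: {bad}")
    order = {c: i for i, c in enumerate(PHENOPRINT_CATEGORIES)}
    ordered = sorted(selected, key=lambda f: (order[category_map[f]], f))
    return PhenoprintSpec(
        features=ordered, categories=[category_map[f] for f in ordered]
    )


def plot_phenoprint(spec: PhenoprintSpec, values: Mapping[str, float], ax=None):
    """Radar chart of a condition's signature; radial distance tracks value."""
    import matplotlib.pyplot as plt

    v = np.array([values[f] for f in spec.features], dtype=float)
    angles = np.linspace(0, 2 * np.pi, len(v), endpoint=False)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ax.plot(np.r_[angles, angles[:1]], np.r_[v, v[:1]])
    ax.fill(np.r_[angles, angles[:1]], np.r_[v, v[:1]], alpha=0.25)
    ax.set_xticks(angles)
    ax.set_xticklabels(spec.features, fontsize=6)
    return ax
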