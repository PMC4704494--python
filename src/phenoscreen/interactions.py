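"""Chemical-genetic interaction scoring.

For every phenotypic feature and replicate, the wells are collapsed to a
compound x cell-line matrix and decomposed by Tukey median polish,

    y[d, c] = m + a[d] + b[c] + pi[d, c],

where the robust row/column effects absorb the compound and genotype main
effects and the residuals ``pi`` are the interaction coefficients: the
deviation of the observed phenotype from what independent combination of
drug and genotype effects would predict. A negative cell-number residual is
a genotype-specific growth defect. Replicate residuals are then tested
against mu = 0 with an empirical-Bayes moderated one-sample t-test
(per-unit variances shrunk toward a prior estimated across all
compound-line units of the feature), and p-values are adjusted per feature
by Benjamini-Hochberg; interactions with adjusted p below the FDR cutoff
(default 0.01) are called significant.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .synthgen import ANNOTATION_COLUMNS, ROLE_KILL, ROLE_SAMPLE, ROLE_VEHICLE
from .preprocess import feature_columns

__all__ = [
    "normalize_cell_number",
    "normalize_cell_number_table",
    "MedianPolishResult",
    "median_polish",
    "InteractionResult",
    "estimate_interactions",
    "trigamma_inverse",
    "estimate_variance_prior",
    "ModeratedTResult",
    "moderated_one_sample_t",
    "bh_adjust",
    "test_interactions",
    "InteractionSummary",
    "call_interactions",
]


# ---------------------------------------------------------------------------
# Cell-number normalization
# ---------------------------------------------------------------------------


def normalize_cell_number(values, negctrl_median: float, kill_ref: float):
    """Range-normalize glog cell numbers for one cell line.

    The negative-control (vehicle) median maps to 1 and the strong-kill
    reference value to 0; values outside [0, 1] are permitted. This puts
    the proliferation scale of cell lines with different growth rates on a
    common footing before interaction scoring.
    """
    if negctrl_median == kill_ref:
        raise ValueError("degenerate normalization range: control anchors are equal")
    return (np.asarray(values, dtype=float) - kill_ref) / (negctrl_median - kill_ref)


def normalize_cell_number_table(
    table: pd.DataFrame, cell_number: str = "cell_number"
) -> pd.DataFrame:
    """Apply per-cell-line cell-number normalization to a well table.

    Anchors are computed within each cell line of the table: the median of
    the vehicle wells (maps to 1) and the median of the kill-reference
    wells (maps to 0).
    """
    out = table.copy()
    for line, sub in table.groupby("cell_line"):
        veh = sub.loc[sub["role"] == ROLE_VEHICLE, cell_number]
        kill = sub.loc[sub["role"] == ROLE_KILL, cell_number]
        if veh.empty or kill.empty:
            raise ValueError(f"cell line {line!r} lacks vehicle or kill-reference wells")
        idx = sub.index
        out.loc[idx, cell_number] = normalize_cell_number(
            sub[cell_number].to_numpy(), float(veh.median()), float(kill.median())
        )
    return out


# ---------------------------------------------------------------------------
# Median polish
# ---------------------------------------------------------------------------


@dataclass
class MedianPolishResult:
    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    converged: bool
    n_iter: int

    def reconstruct(self) -> np.ndarray:
        return (
            self.overall
            + self.row_effects[:, None]
            + self.col_effects[None, :]
            + self.residuals
        )


def median_polish(
    M: np.ndarray, tol: float = 1e-4, max_iter: int = 100
) -> MedianPolishResult:
    """Tukey median polish of a two-way table (robust L1 decomposition).

    Row and column medians are subtracted alternately until the relative
    change in S, the sum of absolute residuals, falls below ``tol``
    (default 1e-4). Missing entries (NaN) are ignored by the medians and
    stay missing in the residuals. The reconstruction identity
    ``M = overall + row + col + residuals`` holds exactly. The median of an
    even-length vector is the mean of the two central order statistics.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.size == 0:
        raise ValueError("median polish needs a non-empty 2-D matrix")
    if np.all(np.isnan(M), axis=1).any() or np.all(np.isnan(M), axis=0).any():
        raise ValueError("median polish cannot handle an all-missing row or column")
    z = M.copy()
    nr, nc = z.shape
    t = 0.0
    r = np.zeros(nr)
    c = np.zeros(nc)
    oldsum = 0.0
    converged = False
    it = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices excluded above
        for it in range(1, max_iter + 1):
            rdelta = np.nanmedian(z, axis=1)
            z -= rdelta[:, None]
            r += rdelta
            delta = np.nanmedian(c)
            c -= delta
            t += delta
            cdelta = np.nanmedian(z, axis=0)
            z -= cdelta[None, :]
            c += cdelta
            delta = np.nanmedian(r)
            r -= delta
            t += delta
            newsum = float(np.nansum(np.abs(z)))
            if newsum == 0.0 or abs(newsum - oldsum) < tol * newsum:
                converged = True
                break
            oldsum = newsum
    return MedianPolishResult(
        overall=t, row_effects=r, col_effects=c, residuals=z, converged=converged, n_iter=it
    )


# ---------------------------------------------------------------------------
# Per-replicate interaction estimation
# ---------------------------------------------------------------------------


@dataclass
class InteractionResult:
    """Interaction coefficients and (after testing) significance calls.

    ``pi`` has shape (replicates, compounds, lines, features); missing
    compound-line combinations are NaN and are excluded from testing.
    """

    compounds: list[str]
    lines: list[str]
    features: list[str]
    pi: np.ndarray  # (R, D, L, F)
    overall: np.ndarray  # (R, F)
    compound_effects: np.ndarray  # (R, D, F)
    line_effects: np.ndarray  # (R, L, F)
    calls: pd.DataFrame | None = None

    @property
    def n_replicates(self) -> int:
        return self.pi.shape[0]

    def pooled_pi(self) -> np.ndarray:
        """Mean interaction coefficient over replicates, shape (D, L, F)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.pi, axis=0)

    def to_long(self) -> pd.DataFrame:
        """Long-format tensor (compound, line, feature, replicate, pi)."""
        R, D, L, F = self.pi.shape
        idx = pd.MultiIndex.from_product(
            [range(1, R + 1), self.compounds, self.lines, self.features],
            names=["replicate", "compound_id", "cell_line", "feature"],
        )
        return (
            pd.Series(self.pi.ravel(), index=idx, name="pi")
            .reset_index()[["compound_id", "cell_line", "feature", "replicate", "pi"]]
        )


def estimate_interactions(
    tables: Sequence[pd.DataFrame],
    normalize_cellnum: bool = True,
    cell_number: str = "cell_number",
    tol: float = 1e-4,
) -> InteractionResult:
    """Estimate the interaction tensor from per-replicate well tables.

    Steps per replicate: drop QC-flagged wells, normalize the cell-number
    feature per cell line against the vehicle/kill-reference anchors (when
    ``normalize_cellnum``), collapse sample wells to one value per
    (compound, line) by the median, and median-polish each feature's
    compound x line matrix. The polish residuals are the interaction
    coefficients.
    """
    if len(tables) < 2:
        raise ValueError("need at least two replicate tables")
    prepared = []
    for tbl in tables:
        if "qc_flag" in tbl.columns:
            tbl = tbl[~tbl["qc_flag"].astype(bool)]
        if normalize_cellnum:
            tbl = normalize_cell_number_table(tbl, cell_number=cell_number)
        prepared.append(tbl[tbl["role"] == ROLE_SAMPLE])

    compounds = sorted(set().union(*[set(t["compound_id"]) for t in prepared]))
    lines = sorted(set().union(*[set(t["cell_line"]) for t in prepared]))
    features = feature_columns(prepared[0])
    R, D, L, F = len(prepared), len(compounds), len(lines), len(features)

    pi = np.full((R, D, L, F), np.nan)
    overall = np.full((R, F), np.nan)
    comp_eff = np.full((R, D, F), np.nan)
    line_eff = np.full((R, L, F), np.nan)
    for r, tbl in enumerate(prepared):
        for k, feat in enumerate(features):
            mat = (
                tbl.pivot_table(
                    index="compound_id", columns="cell_line", values=feat, aggfunc="median"
                )
                .reindex(index=compounds, columns=lines)
                .to_numpy()
            )
            res = median_polish(mat, tol=tol)
            pi[r, :, :, k] = res.residuals
            overall[r, k] = res.overall
            comp_eff[r, :, k] = res.row_effects
            line_eff[r, :, k] = res.col_effects
    return InteractionResult(
        compounds=compounds,
        lines=lines,
        features=features,
        pi=pi,
        overall=overall,
        compound_effects=comp_eff,
        line_effects=line_eff,
    )


# ---------------------------------------------------------------------------
# Empirical-Bayes moderated one-sample t
# ---------------------------------------------------------------------------


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/trigamma)."""
    if y <= 0:
        raise ValueError("trigamma is positive; target must be > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if -dif / x < 1e-8:
            break
    return x


def estimate_variance_prior(
    s2: np.ndarray, df: float
) -> tuple[float, float]:
    """Moment-match the scaled-inverse-chi-square variance prior (d0, s0^2).

    Fits the prior to the observed per-unit sample variances via the
    closed-form moments of log sample variances: with
    e = log(s^2) - digamma(df/2) + log(df/2),
    E[e] = log(s0^2) + log(d0/2) - digamma(d0/2) and
    Var[e] = trigamma(df/2) + trigamma(d0/2). When the observed spread of
    log variances does not exceed the sampling spread, the prior is
    degenerate: d0 = inf with s0^2 the mean observed variance.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        warnings.warn("too few positive variances; using a degenerate prior")
        pooled = float(np.nanmean(s2[np.isfinite(s2)])) if np.isfinite(s2).any() else 1e-8
        return np.inf, max(pooled, 1e-12)
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        return d0, s0sq
    return np.inf, float(np.mean(s2[ok]))


@dataclass
class ModeratedTResult:
    t: np.ndarray
    p: np.ndarray
    mean: np.ndarray
    s2: np.ndarray
    s2_post: np.ndarray
    df_prior: float
    s2_prior: float
    df_total: np.ndarray


def moderated_one_sample_t(
    X: np.ndarray, params: tuple[float, float] | str = "estimate"
) -> ModeratedTResult:
    """Moderated one-sample t-test against mu = 0 for each row of X.

    X has shape (units, replicates). Per-unit sample variances are shrunk
    toward the prior, s2_post = (d0*s0^2 + (R-1)*s^2) / (d0 + R - 1), and
    t = mean / sqrt(s2_post / R) with d0 + R - 1 degrees of freedom (capped
    at the total residual degrees of freedom of the valid units). ``params``
    is either (d0, s0^2) or "estimate" to fit the prior by moment matching.
    Rows with missing replicates are excluded (NaN results).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a (units, replicates>=2) array")
    n_units, R = X.shape
    df = R - 1
    valid = np.isfinite(X).all(axis=1)
    mean = np.where(valid, X.mean(axis=1), np.nan)
    s2 = np.where(valid, X.var(axis=1, ddof=1), np.nan)

    if params == "estimate":
        if np.nanmax(s2, initial=0.0) <= 0.0:
            warnings.warn(
                "all replicate variances are zero; falling back to a pooled epsilon prior"
            )
            d0, s0sq = np.inf, 1e-12
        else:
            d0, s0sq = estimate_variance_prior(s2[valid], df)
    else:
        d0, s0sq = params
        if (np.isfinite(d0) and d0 <= 0) or s0sq <= 0:
            raise ValueError("prior df must be positive (or inf) and prior variance > 0")

    if np.isinf(d0):
        s2_post = np.where(valid, s0sq, np.nan)
        df_total = np.where(valid, float(valid.sum() * df), np.nan)
    else:
        s2_post = (d0 * s0sq + df * s2) / (d0 + df)
        df_total = np.where(valid, min(d0 + df, float(valid.sum() * df)), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / np.sqrt(s2_post / R)
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return ModeratedTResult(
        t=t, p=p, mean=mean, s2=s2, s2_post=s2_post,
        df_prior=float(d0), s2_prior=float(s0sq), df_total=df_total,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (NaN-aware)."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Significance calls and summaries
# ---------------------------------------------------------------------------


def test_interactions(
    result: InteractionResult,
    fdr: float = 0.01,
    moderation: tuple[float, float] | str = "estimate",
) -> pd.DataFrame:
    """Moderated t + BH over the interaction tensor; attaches ``calls``.

    Testing and adjustment run per feature across all (compound, line)
    units, mirroring the per-feature interaction matrices. Returns the long
    calls table (compound, line, feature, pi_mean, t, p, p_adj,
    significant).
    """
    R, D, L, F = result.pi.shape
    frames = []
    for k, feat in enumerate(result.features):
        X = result.pi[:, :, :, k].reshape(R, D * L).T  # (units, R)
        res = moderated_one_sample_t(X, params=moderation)
        p_adj = bh_adjust(res.p)
        grid = pd.MultiIndex.from_product(
            [result.compounds, result.lines], names=["compound_id", "cell_line"]
        )
        frames.append(
            pd.DataFrame(
                {
                    "compound_id": grid.get_level_values(0),
                    "cell_line": grid.get_level_values(1),
                    "feature": feat,
                    "pi_mean": res.mean,
                    "t": res.t,
                    "p": res.p,
                    "p_adj": p_adj,
                    "significant": p_adj < fdr,
                }
            )
        )
    calls = pd.concat(frames, ignore_index=True)
    calls["significant"] = calls["significant"].fillna(False).astype(bool)
    result.calls = calls
    return calls


@dataclass
class InteractionSummary:
    n_significant: int
    n_compounds_with_interactions: int
    per_line: pd.Series
    per_compound_breadth: pd.Series
    per_category_exclusive: pd.Series = field(default=None)


def call_interactions(
    calls: pd.DataFrame,
    fdr: float = 0.01,
    category_map: Mapping[str, str] | None = None,
) -> InteractionSummary:
    """Summarize significance calls at the given FDR cutoff.

    Reports the total number of significant (compound, line, feature)
    interactions, per-genotype counts, the genotype breadth per compound
    (how many lines each interacting compound hits), and - when a category
    map is given - for each phenotypic category the number of
    (compound, line) interactions carried exclusively by that category's
    features.
    """
    sig = calls[(calls["p_adj"] < fdr) & np.isfinite(calls["p_adj"])]
    per_line = sig.groupby("cell_line").size().sort_values(ascending=False)
    per_compound = (
        sig.groupby("compound_id")["cell_line"].nunique().sort_values(ascending=False)
    )
    per_cat = None
    if category_map is not None:
        cat = sig.assign(category=sig["feature"].map(dict(category_map)))
        if cat["category"].isna().any():
            missing = sorted(cat.loc[cat["category"].isna(), "feature"].unique())
            raise ValueError(f"features without a category: {missing}")
        by_unit = cat.groupby(["compound_id", "cell_line"])["category"].agg(set)
        exclusive = by_unit[by_unit.map(len) == 1].map(lambda s: next(iter(s)))
        per_cat = exclusive.value_counts()
    return InteractionSummary(
        n_significant=int(len(sig)),
        n_compounds_with_interactions=int(sig["compound_id"].nunique()),
        per_line=per_line,
        per_compound_breadth=per_compound,
        per_category_exclusive=per_cat,
    )
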