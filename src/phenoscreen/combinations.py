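"""Drug-combination synergy scoring and the proteasome-inhibition statistic.

Plate-reader viability readouts are first log-transformed and normalized
against the plate controls: the normalized percentage inhibition is
NPI = (log(pos) - log(x)) / (log(pos) - log(neg)), where pos/neg are the
mean log intensities of the positive (full-kill) and negative (untreated)
controls, and the compound effect is E = 1 - NPI, so E = 0 at the
untreated level and E = 1 at full kill. (The NPI name notwithstanding,
this is the literal control-anchored formula; E is the self-consistent
effect scale.)

Combinations are scored per dose under Bliss independence,
E_AB = E_A + E_B - E_A:B: the interaction term E_A:B is estimated by
plugging in the arm means, and is zero for non-interacting compounds.
With this sign convention a NEGATIVE E_A:B means the combination kills
more than independence predicts (synergy).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CombinationGrid",
    "BlissResult",
    "normalized_inhibition",
    "bliss_interaction",
    "proteasome_inhibition",
    "proteasome_test",
]


@dataclass
class CombinationGrid:
    """Fixed-ratio dilution series with single-agent and combination arms.

    ``data`` is long format with columns (dose_uM, arm, replicate,
    raw_value); ``arm`` is one of A, B (single agents), AB (combination),
    pos, neg (plate controls, dose NaN). ``truth`` optionally records
    planted per-dose effects for simulated grids.
    """

    data: pd.DataFrame
    truth: pd.DataFrame | None = None

    @property
    def doses(self) -> np.ndarray:
        d = self.data.loc[self.data["arm"].isin(["A", "B", "AB"]), "dose_uM"]
        return np.sort(d.unique())[::-1]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CombinationGrid":
        return cls(pd.read_csv(path))


def normalized_inhibition(raw, pos_mean_log: float, neg_mean_log: float):
    """NPI and effect E = 1 - NPI of log-transformed plate-reader values.

    ``pos_mean_log`` / ``neg_mean_log`` are the means of the
    log-transformed positive / negative control intensities (natural log;
    the base cancels in the ratio). A measurement at the positive-control
    level gives E = 1, at the negative-control level E = 0, and the
    geometric midpoint of the controls gives E = 0.5.
    """
    raw = np.asarray(raw, dtype=float)
    if np.any(raw <= 0):
        raise ValueError("raw plate-reader values must be positive (log transform)")
    if pos_mean_log == neg_mean_log:
        raise ValueError("degenerate controls: positive and negative means are equal")
    npi = (pos_mean_log - np.log(raw)) / (pos_mean_log - neg_mean_log)
    return npi, 1.0 - npi


def _effects(grid: CombinationGrid) -> pd.DataFrame:
    data = grid.data
    pos = data.loc[data["arm"] == "pos", "raw_value"].to_numpy(float)
    neg = data.loc[data["arm"] == "neg", "raw_value"].to_numpy(float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("grid lacks positive or negative control wells")
    lp = float(np.mean(np.log(pos)))
    ln = float(np.mean(np.log(neg)))
    out = data[data["arm"].isin(["A", "B", "AB"])].copy()
    out["E"] = normalized_inhibition(out["raw_value"].to_numpy(float), lp, ln)[1]
    return out


@dataclass
class BlissResult:
    """Per-dose Bliss-independence scores (rows of ``table``).

    ``table`` columns: dose_uM, E_A, E_B, E_AB (arm means), interaction
    (E_A:B = E_A + E_B - E_AB), t, p, and the replicate counts. Negative
    interaction = stronger-than-independent killing.
    """

    table: pd.DataFrame
    method: str


def bliss_interaction(
    grid: CombinationGrid,
    method: str = "welch",
    min_rep_single: int = 2,
    min_rep_combo: int = 2,
) -> BlissResult:
    """Score every dose of a combination grid against Bliss independence.

    The interaction term is the plug-in estimate
    E_A:B = mean(E_A) + mean(E_B) - mean(E_AB). Its deviation from zero is
    tested per dose. ``welch`` (default) is a Welch-style t comparing the
    combination measurements with the independence expectation built from
    the single-agent measurements: on the log-raw scale Bliss independence
    is exactly mean(lA) + mean(lB) - mean(lAB) - mean(l_neg) = 0, a linear
    combination of four independent sample means, so the statistic divides
    that contrast by its pooled standard error (including the plate
    negative-control mean, whose finite sampling otherwise biases the
    test) with Welch-Satterthwaite degrees of freedom. ``plugin`` runs a
    one-sample t of the combination replicates against the constant
    mean(E_A) + mean(E_B), ignoring single-agent and control uncertainty.
    Doses with insufficient replicates are skipped with a warning.
    """
    if method not in ("welch", "plugin"):
        raise ValueError("method must be 'welch' or 'plugin'")
    eff = _effects(grid)
    data = grid.data
    log_neg = np.log(data.loc[data["arm"] == "neg", "raw_value"].to_numpy(float))
    log_pos = np.log(data.loc[data["arm"] == "pos", "raw_value"].to_numpy(float))
    span = float(np.mean(log_pos) - np.mean(log_neg))
    rows = []
    for dose in sorted(eff["dose_uM"].unique(), reverse=True):
        sub = eff[eff["dose_uM"] == dose]
        ea = sub.loc[sub["arm"] == "A", "E"].to_numpy()
        eb = sub.loc[sub["arm"] == "B", "E"].to_numpy()
        eab = sub.loc[sub["arm"] == "AB", "E"].to_numpy()
        if min(len(ea), len(eb)) < min_rep_single or len(eab) < min_rep_combo:
            warnings.warn(f"dose {dose}: insufficient replicates, skipped")
            continue
        interaction = float(ea.mean() + eb.mean() - eab.mean())
        if method == "welch":
            la = np.log(sub.loc[sub["arm"] == "A", "raw_value"].to_numpy(float))
            lb = np.log(sub.loc[sub["arm"] == "B", "raw_value"].to_numpy(float))
            lab = np.log(sub.loc[sub["arm"] == "AB", "raw_value"].to_numpy(float))
            comps = (la, lb, lab, log_neg)
            contrast = la.mean() + lb.mean() - lab.mean() - log_neg.mean()
            parts = [v.var(ddof=1) / len(v) for v in comps]
            var = float(sum(parts))
            if var == 0.0:
                warnings.warn(f"dose {dose}: zero variance, t undefined")
                t, p = np.nan, np.nan
            else:
                # contrast/span = E_A:B; the sign of t tracks the interaction
                t = contrast / np.sqrt(var) * np.sign(span)
                df = var**2 / sum(
                    pp**2 / (len(v) - 1) for pp, v in zip(parts, comps)
                )
                p = 2.0 * stats.t.sf(abs(t), df)
        else:
            t, p = stats.ttest_1samp(eab, popmean=float(ea.mean() + eb.mean()))
            t, p = -t, p  # sign convention: t tracks E_A:B
        rows.append(
            {
                "dose_uM": dose,
                "E_A": float(ea.mean()),
                "E_B": float(eb.mean()),
                "E_AB": float(eab.mean()),
                "interaction": interaction,
                "t": float(t),
                "p": float(p),
                "n_A": len(ea),
                "n_B": len(eb),
                "n_AB": len(eab),
            }
        )
    return BlissResult(table=pd.DataFrame(rows), method=method)


def proteasome_inhibition(PT, PC, VT, VC):
    """Viability-corrected percent proteasome inhibition.

    100 * (1 - (PT/PC) / (VT/VC)): PT/PC are treated/control proteasome
    activities, VT/VC treated/control viabilities. Vehicle treatment
    (PT = PC, VT = VC) gives 0%, complete inhibition (PT = 0) gives 100%,
    and proportional loss of activity and viability (pure cytotoxicity)
    gives 0%. Scale-invariant in (PT, PC) jointly and (VT, VC) jointly.
    """
    PT, PC, VT, VC = (np.asarray(v, dtype=float) for v in (PT, PC, VT, VC))
    if np.any(PC <= 0) or np.any(VT <= 0) or np.any(VC <= 0):
        raise ValueError("PC, VT and VC must be positive")
    return 100.0 * (1.0 - (PT / PC) / (VT / VC))


def proteasome_test(values) -> tuple[float, float]:
    """One-sample, one-sided t-test of percent-inhibition replicates vs 0.

    Alternative: inhibition > 0. With zero replicate variance the t limit
    is reported with a warning: +inf / p=0 for a positive mean, -inf / p=1
    for a negative mean, and t=0 / p=0.5 when all values are exactly zero.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two replicate values")
    if np.std(v, ddof=1) == 0.0:
        warnings.warn("zero variance across replicates; reporting the t limit")
        if v.mean() > 0:
            return np.inf, 0.0
        if v.mean() < 0:
            return -np.inf, 1.0
        return 0.0, 0.5
    res = stats.ttest_1samp(v, popmean=0.0, alternative="greater")
    return float(res.statistic), float(res.pvalue)
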