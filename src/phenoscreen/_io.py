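"""Round-trip helpers for the long-format interaction tensor."""
from __future__ import annotations

import numpy as np
import pandas as pd

from .interactions import InteractionResult


def long_to_result(long: pd.DataFrame) -> InteractionResult:
    """Rebuild an :class:`InteractionResult` from its long-format TSV.

    Only the interaction tensor is recoverable; the per-replicate overall /
    compound / line effects are filled with NaN.
    """
    required = {"compound_id", "cell_line", "feature", "replicate", "pi"}
    if not required.issubset(long.columns):
        raise ValueError(f"long table needs columns {sorted(required)}")
    compounds = sorted(long["compound_id"].unique())
    lines = sorted(long["cell_line"].unique())
    features = list(pd.unique(long["feature"]))
    reps = sorted(long["replicate"].unique())
    index = {
        "compound_id": {c: i for i, c in enumerate(compounds)},
        "cell_line": {l: i for i, l in enumerate(lines)},
        "feature": {f: i for i, f in enumerate(features)},
        "replicate": {r: i for i, r in enumerate(reps)},
    }
    pi = np.full((len(reps), len(compounds), len(lines), len(features)), np.nan)
    pi[
        long["replicate"].map(index["replicate"]),
        long["compound_id"].map(index["compound_id"]),
        long["cell_line"].map(index["cell_line"]),
        long["feature"].map(index["feature"]),
    ] = long["pi"].to_numpy(float)
    R, D, L, F = pi.shape
    return InteractionResult(
        compounds=compounds,
        lines=lines,
        features=features,
        pi=pi,
        overall=np.full((R, F), np.nan),
        compound_effects=np.full((R, D, F), np.nan),
        line_effects=np.full((R, L, F), np.nan),
    )
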