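"""Two-stage feature selection: redundancy filter, then univariate screening.

Stage 1 removes correlated redundancy: whenever two still-kept feature
columns have |Pearson r| above ``r_max`` (default 0.1) on the training rows,
one of the two is dropped at random. The scan order and the coin are driven
by a dedicated seeded RNG stream so classification seeds never perturb
selection. A threshold of 0.1 is extremely aggressive and typically leaves
only a few dozen survivors out of thousands of columns — intentional, as
that is the operating point of the analysis this package implements.

Stage 2 keeps features whose pooled-variance two-sample t test between the
two groups has p strictly below ``p_max`` (default 0.005), with no
multiplicity correction.

Both stages see training rows only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SelectionResult", "correlation_filter", "ttest_filter",
           "select_features"]


@dataclass
class SelectionResult:
    kept: List[str]
    dropped: List[Tuple[str, str, float]]  # (name, reason, statistic)
    r_max: float
    p_max: Optional[float]
    seed: int

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "kept": self.kept,
            "dropped": [{"name": n, "reason": r, "statistic": s}
                        for n, r, s in self.dropped],
            "thresholds": {"r_max": self.r_max, "p_max": self.p_max},
            "seed": self.seed,
        }, indent=2) + "\n")


def correlation_filter(table: pd.DataFrame, features: Sequence[str],
                       r_max: float = 0.1, seed: int = 0) -> SelectionResult:
    """Drop one member of every feature pair with |Pearson r| > r_max.

    Features are scanned in seeded-random order; for each still-kept pair
    exceeding the threshold, a seeded coin picks the member to drop.
    Constant columns cannot correlate and are treated as |r| = 0.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 subjects")
    if not (0.0 < r_max <= 1.0):
        raise ValueError("r_max must be in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    feats = list(features)
    X = table[feats].to_numpy(dtype=np.float64)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.abs(np.nan_to_num(corr, nan=0.0))
    if corr.ndim == 0:  # single feature
        corr = np.ones((1, 1))
    corr[:, sd == 0] = 0.0
    corr[sd == 0, :] = 0.0
    order = rng.permutation(len(feats))
    alive = np.ones(len(feats), dtype=bool)
    dropped: List[Tuple[str, str, float]] = []
    for ai in range(len(order)):
        i = order[ai]
        if not alive[i]:
            continue
        for bi in range(ai + 1, len(order)):
            j = order[bi]
            if not alive[j]:
                continue
            if corr[i, j] > r_max:
                victim = i if rng.random() < 0.5 else j
                alive[victim] = False
                dropped.append((feats[victim], "correlation", float(corr[i, j])))
                if victim == i:
                    break
    kept = [feats[k] for k in range(len(feats)) if alive[k]]
    return SelectionResult(kept, dropped, r_max, None, seed)


def ttest_filter(table: pd.DataFrame, features: Sequence[str], group_col: str,
                 groups: Tuple[str, str], p_max: float = 0.005) -> SelectionResult:
    """Keep features with two-sided pooled-variance t-test p strictly < p_max.

    Features with zero variance in both groups get p = 1 and are dropped.
    """
    if not (0.0 < p_max < 1.0):
        raise ValueError("p_max must be in (0, 1)")
    ga = table[table[group_col] == groups[0]]
    gb = table[table[group_col] == groups[1]]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("both groups need at least 2 subjects")
    kept: List[str] = []
    dropped: List[Tuple[str, str, float]] = []
    a = ga[list(features)].to_numpy(dtype=np.float64)
    b = gb[list(features)].to_numpy(dtype=np.float64)
    res = stats.ttest_ind(a, b, axis=0, equal_var=True)
    p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    for name, pv in zip(features, p):
        if pv < p_max:
            kept.append(name)
        else:
            dropped.append((name, "ttest", float(pv)))
    return SelectionResult(kept, dropped, float("nan"), p_max, 0)


def select_features(table: pd.DataFrame, features: Sequence[str],
                    group_col: str, groups: Tuple[str, str],
                    r_max: float = 0.1, p_max: float = 0.005,
                    seed: int = 0, min_kept: int = 1) -> SelectionResult:
    """Correlation filter, then t-test screening (that fixed order).

    If the t-test stage keeps nothing, the ``min_kept`` smallest-p features
    among the correlation-stage survivors are retained so downstream models
    still have an input; such features carry no real group signal, and on
    null data this fallback leaves classification at chance.
    """
    stage1 = correlation_filter(table, features, r_max=r_max, seed=seed)
    stage2 = ttest_filter(table, stage1.kept, group_col, groups, p_max=p_max)
    kept = stage2.kept
    dropped = stage1.dropped + stage2.dropped
    if not kept and min_kept > 0:
        tt = [(n, s) for n, r, s in stage2.dropped if r == "ttest"]
        tt.sort(key=lambda x: x[1])
        fallback = [n for n, _ in tt[:min_kept]]
        kept = fallback
        dropped = [(n, r, s) for n, r, s in dropped if n not in set(fallback)]
    return SelectionResult(kept, dropped, r_max, p_max, seed)
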