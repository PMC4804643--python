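"""Per-gene differential statistics and the three feature scores.

For a binary contrast (TO-vs-rest or MI-vs-rest) each gene gets a two-sided
Welch t-test p-value and a signed effect size d (difference of group means on
the log2 scale, target minus rest).  Three feature scores are derived:

* ``pval``: -log10(p)
* ``rank``: rank(-log10 p) * rank(|d|), ranks ascending with average ties
* ``norm``: minmax(-log10 p) * minmax(|d|)

The rank and norm products reward genes that are jointly extreme in both
significance and effect size, unlike the pure p-value score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import CohortDataset
from .errors import SelectionError, StatError

FS_TYPES = ("pval", "rank", "norm")

# p-values are clamped below at this value before taking -log10, so an
# underflowed p cannot produce an infinite score.
P_CLAMP = 1e-300


@dataclass(frozen=True)
class BinaryContrast:
    """One-vs-rest contrast for one of the two modeled target classes."""

    target_class: str

    def __post_init__(self) -> None:
        if self.target_class not in ("TO", "MI"):
            raise StatError(
                f"target_class must be 'TO' or 'MI', got {self.target_class!r}"
            )

    @property
    def contrast_name(self) -> str:
        return f"{self.target_class}-vs-rest"


def welch_t(x, y) -> tuple[float, float, float]:
    """Two-sample Welch t-test (unequal variances), two-sided.

    Returns ``(t, df, p)`` with ``t = (mx - my) / sqrt(sx2/nx + sy2/ny)``
    and Welch-Satterthwaite degrees of freedom.

    The degenerate case where both groups have zero variance is resolved by
    convention: equal means give ``t = 0, p = 1`` (an uninformative gene must
    rank last, not crash); unequal constant means give an infinite statistic
    with ``p`` clamped at ``P_CLAMP``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise StatError(f"each group needs >= 2 values, got {nx} and {ny}")
    mx, my = x.mean(), y.mean()
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        df = float(nx + ny - 2)
        if mx == my:
            return 0.0, df, 1.0
        return math_copysign_inf(mx - my), df, P_CLAMP
    t = (mx - my) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(min(max(p, 0.0), 1.0))


def math_copysign_inf(sign_source: float) -> float:
    return float(np.copysign(np.inf, sign_source))


def minmax_norm(x) -> np.ndarray:
    """Elementwise ``(x - min(x)) / (max(x) - min(x))``.

    An all-equal vector maps to all zeros by convention, so a degenerate
    score column cannot abort a grid run.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise StatError("minmax_norm requires a non-empty vector")
    if not np.all(np.isfinite(x)):
        raise StatError("minmax_norm requires finite input")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def _welch_rows(
    values: np.ndarray, target_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch test of target columns vs the rest, per row.

    Returns (p, d) with d = mean(target) - mean(rest).  Degenerate rows
    (zero variance in both groups) follow the welch_t conventions.
    """
    a = values[:, target_mask]
    b = values[:, ~target_mask]
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise StatError(
            f"contrast needs >= 2 samples per group, got {na} vs {nb}"
        )
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    d = ma - mb

    p = np.ones_like(d)
    ok = se2 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(ok, d / np.sqrt(se2), 0.0)
        df = np.where(
            ok,
            se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)),
            float(na + nb - 2),
        )
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    # both groups constant: p=1 when means agree, else effectively zero
    degenerate_diff = (~ok) & (d != 0)
    p[degenerate_diff] = P_CLAMP
    return np.clip(p, 0.0, 1.0), d


def feature_scores_from_stats(genes, p, d) -> pd.DataFrame:
    """Build the feature table from precomputed per-gene (p, d) statistics.

    Ranks are ascending (largest value gets the largest rank) with average
    ties; p is clamped at ``P_CLAMP`` before the log; the rank and norm
    products use |d|.
    """
    p = np.asarray(p, dtype=float)
    d = np.asarray(d, dtype=float)
    if not (len(genes) == p.size == d.size):
        raise StatError("genes, p, and d must have equal length")
    fs_pval = -np.log10(np.maximum(p, P_CLAMP))
    abs_d = np.abs(d)
    rank_p = stats.rankdata(fs_pval, method="average")
    rank_d = stats.rankdata(abs_d, method="average")
    fs_rank = rank_p * rank_d
    fs_norm = minmax_norm(fs_pval) * minmax_norm(abs_d)
    return pd.DataFrame(
        {
            "gene": list(genes),
            "p": p,
            "d": d,
            "abs_d": abs_d,
            "fs_pval": fs_pval,
            "fs_rank": fs_rank,
            "fs_norm": fs_norm,
        }
    )


def compute_feature_table(
    cohort: CohortDataset, contrast: BinaryContrast
) -> pd.DataFrame:
    """Per-gene statistics and feature scores for one binary contrast.

    Returns a DataFrame with columns ``gene, p, d, abs_d, fs_pval, fs_rank,
    fs_norm`` in the cohort's gene order.
    """
    mask = cohort.binary_response(contrast.target_class)
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise StatError(f"contrast {contrast.contrast_name} has an empty group")
    p, d = _welch_rows(cohort.expression.values, mask)
    return feature_scores_from_stats(cohort.expression.gene_ids, p, d)


def select_top_k(table: pd.DataFrame, fs_type: str, k: int) -> list[str]:
    """The k genes with the largest chosen score, in descending score order.

    Ties are broken by smaller p-value, then lexicographic gene id, so the
    selection is deterministic.
    """
    if fs_type not in FS_TYPES:
        raise SelectionError(f"unknown feature score type {fs_type!r}")
    n = len(table)
    if not 1 <= k <= n:
        raise SelectionError(f"k must be in [1, {n}], got {k}")
    col = f"fs_{fs_type}"
    ordered = table.sort_values(
        by=[col, "p", "gene"], ascending=[False, True, True]
    )
    return ordered["gene"].head(k).tolist()


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
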