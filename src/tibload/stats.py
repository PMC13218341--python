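"""Nonparametric statistical layer for repeated-measures condition tables.

Friedman tests with Kendall's W effect size, Wilcoxon signed-rank post
hocs with Bonferroni correction, Spearman/MAE length agreement, 2D-vs-3D
method agreement, and grouped descriptives. Small samples use exact null
distributions: the Wilcoxon statistic by rank-sum enumeration (dynamic
programming over midranks) for n <= 25, the Friedman statistic by full
permutation enumeration for n <= 4 with k = 3.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations, product

import numpy as np
import pandas as pd
from scipy import stats as sps


class DegenerateDataError(ValueError):
    pass


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


# --------------------------------------------------------------------------
# Friedman + Kendall's W
# --------------------------------------------------------------------------

def _friedman_statistic(table: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square from within-row midranks."""
    n, k = table.shape
    ranks = np.apply_along_axis(_midranks, 1, table)
    col = ranks.sum(axis=0)
    num = (k - 1) * ((col - n * (k + 1) / 2.0) ** 2).sum()
    den = ((ranks - (k + 1) / 2.0) ** 2).sum()
    if den == 0:
        return 0.0  # complete within-row ties: no rank signal at all
    return float(num / den)


def friedman_kendall(table: np.ndarray, exact_max_n: int = 4,
                     ) -> tuple[float, float, float]:
    """(chi2, p, Kendall's W) for an n x k repeated-measures table.

    W = chi2 / (n (k-1)). The p-value comes from full enumeration of
    within-row rank permutations when n <= ``exact_max_n`` and k = 3,
    otherwise from the chi-square distribution with k-1 df.
    """
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    chi2 = _friedman_statistic(table)
    w = chi2 / (n * (k - 1))
    if n <= exact_max_n and k == 3:
        p = _friedman_exact_p(table, chi2)
    else:
        p = float(sps.chi2.sf(chi2, k - 1))
    return chi2, p, w


def _friedman_exact_p(table: np.ndarray, observed: float) -> float:
    """P(chi2 >= observed) over all within-row permutations of the data."""
    n, k = table.shape
    row_perms = [list(permutations(row)) for row in table]
    count = 0
    total = 0
    for combo in product(*row_perms):
        stat = _friedman_statistic(np.asarray(combo))
        total += 1
        if stat >= observed - 1e-12:
            count += 1
    return count / total


# --------------------------------------------------------------------------
# Wilcoxon signed rank (exact via DP over midranks)
# --------------------------------------------------------------------------

def _wilcoxon_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p over all 2^n sign assignments.

    Midranks are doubled to integers; the distribution of the positive
    rank sum is built by convolution, so ties are handled exactly.
    """
    r2 = np.round(2 * ranks).astype(int)
    total = r2.sum()
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:len(dist) - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(round(2 * w_plus))
    p_le = dist[: w2 + 1].sum()
    p_ge = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray,
                         exact_max_n: int = 25) -> float:
    """Two-sided paired Wilcoxon p; zero differences dropped, midranks.

    Exact enumeration for n <= ``exact_max_n`` non-zero differences,
    normal approximation (with tie correction) beyond.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    ranks = _midranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        return _wilcoxon_exact_p(ranks, w_plus)
    mean = n * (n + 1) / 4.0
    # tie-corrected variance of W+
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 \
        - (counts ** 3 - counts).sum() / 48.0
    z = (w_plus - mean) / np.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    p_raw: float
    p_corrected: float
    significant: bool


def wilcoxon_pairwise(table: np.ndarray, labels: tuple[str, ...] | None = None,
                      alpha: float = 0.05) -> list[PairwiseResult]:
    """All column pairs with Bonferroni correction over the family."""
    table = np.asarray(table, dtype=float)
    k = table.shape[1]
    labels = labels if labels is not None else tuple(str(i) for i in range(k))
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    m = len(pairs)
    out = []
    for i, j in pairs:
        p = wilcoxon_signed_rank(table[:, i], table[:, j])
        pc = min(1.0, m * p)
        out.append(PairwiseResult(pair=(labels[i], labels[j]), p_raw=p,
                                  p_corrected=pc, significant=pc < alpha))
    return out


# --------------------------------------------------------------------------
# agreement analyses
# --------------------------------------------------------------------------

def length_agreement(marker_lengths: np.ndarray, model_lengths: np.ndarray,
                     ) -> dict[str, float]:
    """Spearman rho/p, MAE (mm) and paired Wilcoxon p for length methods."""
    x = np.asarray(marker_lengths, dtype=float)
    y = np.asarray(model_lengths, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("need paired vectors of length >= 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("constant vector: correlation undefined")
    rho, p_rho = sps.spearmanr(x, y)
    return {"spearman_rho": float(rho), "spearman_p": float(p_rho),
            "mae_mm": float(np.abs(x - y).mean()),
            "wilcoxon_p": wilcoxon_signed_rank(x, y)}


def percent_change(baseline: np.ndarray, changed: np.ndarray) -> np.ndarray:
    base = np.asarray(baseline, dtype=float)
    if np.any(base == 0):
        raise ZeroDivisionError("zero baseline: percentage change undefined")
    return 100.0 * (np.asarray(changed, dtype=float) - base) / base


def method_agreement(pct_change_2d: np.ndarray, pct_change_3d: np.ndarray,
                     ) -> dict:
    """Between-method agreement of per-participant percentage changes.

    Returns the mean and SD of |2D% - 3D%|, the fraction of participants
    whose changes share a sign (directional concordance; a zero change
    counts as concordant with anything), and an identity-line table.
    """
    a = np.asarray(pct_change_2d, dtype=float)
    b = np.asarray(pct_change_3d, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors required")
    diff = np.abs(a - b)
    concordant = np.sign(a) * np.sign(b) >= 0
    table = pd.DataFrame({"pct_change_2d": a, "pct_change_3d": b,
                          "abs_diff": diff, "concordant": concordant})
    return {"mean_abs_diff_pct": float(diff.mean()),
            "sd_abs_diff_pct": float(diff.std(ddof=1)) if len(diff) > 1 else 0.0,
            "concordance_fraction": float(concordant.mean()),
            "table": table}


def group_descriptives(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Per-group mean and SD (ddof=1); descriptive only, no inference."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    rows = []
    for g in pd.unique(groups):
        v = values[groups == g]
        if len(v) == 0:
            raise ValueError(f"empty group '{g}'")
        rows.append({"group": g, "n": len(v), "mean": float(v.mean()),
                     "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0})
    return pd.DataFrame(rows)


def shapiro_check(values: np.ndarray) -> dict[str, float]:
    """Shapiro-Wilk normality screen; reported, never used for branching."""
    stat, p = sps.shapiro(np.asarray(values, dtype=float))
    return {"statistic": float(stat), "p": float(p)}


# --------------------------------------------------------------------------
# condition-table report (main effect + post-hoc letters)
# --------------------------------------------------------------------------

@dataclass
class ConditionReport:
    variable: str
    means: dict[str, float]
    sds: dict[str, float]
    chi2: float
    p: float
    kendall_w: float
    pairwise: list[PairwiseResult]

    def posthoc_letters(self) -> str:
        letters = [chr(ord("A") + i) for i in range(len(self.pairwise))]
        return ", ".join(l for l, pr in zip(letters, self.pairwise)
                         if pr.significant)


def condition_report(table: np.ndarray, labels: tuple[str, ...],
                     variable: str = "") -> ConditionReport:
    """Friedman main effect with Wilcoxon/Bonferroni post hocs."""
    table = np.asarray(table, dtype=float)
    chi2, p, w = friedman_kendall(table)
    return ConditionReport(
        variable=variable,
        means={l: float(table[:, i].mean()) for i, l in enumerate(labels)},
        sds={l: float(table[:, i].std(ddof=1)) for i, l in enumerate(labels)},
        chi2=chi2, p=p, kendall_w=w,
        pairwise=wilcoxon_pairwise(table, labels))
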