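"""Nonparametric statistical toolkit: rank tests, post hoc letters, Spearman.

The workflow these implement: a Shapiro–Wilk screen decides normality; since
the data are typically non-normal, two groups are compared with the Wilcoxon
rank-sum test, and three or more with Kruskal–Wallis followed by Dunn's post
hoc z-tests under Bonferroni correction, summarized as a compact letter
display (groups share a letter exactly when not significantly different).
Monotone associations use Spearman's rank correlation.

All rank statistics use midranks for ties and carry the standard tie
corrections; they are invariant under strictly increasing transforms of the
data.  The Wilcoxon test enumerates the exact rank-sum distribution for
small samples (both n ≤ 8) and uses the tie- and continuity-corrected
normal approximation otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata

__all__ = [
    "TestResult",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "dunn_bonferroni",
    "compact_letter_display",
    "spearman",
    "shapiro_screen",
]

EXACT_WILCOXON_MAX_N = 8


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str
    extra: dict = field(default_factory=dict)


def _tie_term(pooled: np.ndarray) -> float:
    """Σ (t³ − t) over tie groups of the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


# --- Wilcoxon rank-sum -----------------------------------------------------

def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact two-sided p by enumeration of rank assignments when both samples
    have at most 8 observations; otherwise the normal approximation with
    midranks, tie correction and continuity correction.  Two identical
    constant samples give p = 1 with a zero-variance flag.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("each sample needs at least one observation")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[:n1].sum())  # rank sum of x

    if np.ptp(pooled) == 0:
        return TestResult(w, 1.0, (n1, n2), "wilcoxon-rank-sum",
                          {"zero_variance": True})

    if n1 <= EXACT_WILCOXON_MAX_N and n2 <= EXACT_WILCOXON_MAX_N:
        # exact conditional distribution of the rank sum given the pooled
        # midranks: enumerate all C(N, n1) assignments of ranks to x
        sums = np.array([sum(c) for c in
                         itertools.combinations(ranks, n1)])
        n_total = len(sums)
        eps = 1e-9
        p_low = np.sum(sums <= w + eps) / n_total
        p_high = np.sum(sums >= w - eps) / n_total
        p = min(1.0, 2.0 * min(p_low, p_high))
        return TestResult(w, p, (n1, n2), "wilcoxon-rank-sum",
                          {"exact": True})

    n = n1 + n2
    mean_w = n1 * (n + 1) / 2.0
    var_w = (n1 * n2 / 12.0) * ((n + 1) - _tie_term(pooled) / (n * (n - 1)))
    if var_w <= 0:
        return TestResult(w, 1.0, (n1, n2), "wilcoxon-rank-sum",
                          {"zero_variance": True})
    # continuity correction toward the mean
    z = (w - mean_w - 0.5 * np.sign(w - mean_w)) / np.sqrt(var_w)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return TestResult(w, min(1.0, p), (n1, n2), "wilcoxon-rank-sum",
                      {"exact": False, "z": float(z)})


# --- Kruskal–Wallis --------------------------------------------------------

def kruskal_wallis(groups) -> TestResult:
    """Kruskal–Wallis H with tie correction; p from χ²(k−1).

    H = 12/(N(N+1)) Σ nᵢ R̄ᵢ² − 3(N+1), divided by
    C = 1 − Σ(t³−t)/(N³−N).
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 1 for g in groups):
        raise ValueError("every group needs at least one observation")
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    correction = 1.0 - _tie_term(pooled) / (n ** 3 - n)
    if correction == 0:  # all observations identical
        return TestResult(0.0, 1.0, tuple(len(g) for g in groups),
                          "kruskal-wallis", {"zero_variance": True})
    h /= correction
    df = len(groups) - 1
    p = float(sps.chi2.sf(h, df))
    return TestResult(float(h), p, tuple(len(g) for g in groups),
                      "kruskal-wallis", {"df": df})


# --- Dunn's post hoc -------------------------------------------------------

def dunn_bonferroni(groups, labels=None, alpha: float = 0.05) -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled midranks with Bonferroni correction.

    z for groups i, j:  (R̄ᵢ − R̄ⱼ) / sqrt[(N(N+1)/12 − Σ(t³−t)/(12(N−1)))
    (1/nᵢ + 1/nⱼ)].  Two-sided p, multiplied by the number of pairs and
    capped at 1.  Returns a tidy frame (group_1, group_2, z, p_raw, p_adj,
    significant).
    """
    groups = [np.asarray(g, float) for g in groups]
    if any(len(g) < 1 for g in groups):
        raise ValueError("every group needs at least one observation")
    k = len(groups)
    if labels is None:
        labels = [f"group{i + 1}" for i in range(k)]
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = rankdata(pooled)
    means, sizes, start = [], [], 0
    for g in groups:
        means.append(ranks[start:start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    tie_var = n * (n + 1) / 12.0 - _tie_term(pooled) / (12.0 * (n - 1))
    n_pairs = k * (k - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(tie_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:
            z, p_raw = 0.0, 1.0
        else:
            z = (means[i] - means[j]) / se
            p_raw = float(2.0 * sps.norm.sf(abs(z)))
        p_adj = min(1.0, p_raw * n_pairs)
        rows.append((labels[i], labels[j], float(z), p_raw, p_adj,
                     p_adj < alpha))
    return pd.DataFrame(rows, columns=["group_1", "group_2", "z",
                                       "p_raw", "p_adj", "significant"])


# --- compact letter display ------------------------------------------------

def compact_letter_display(pairwise_p: pd.DataFrame,
                           alpha: float = 0.05) -> dict[str, str]:
    """Letters such that two groups share one iff not significantly different.

    ``pairwise_p`` is a symmetric DataFrame of adjusted p-values with group
    labels on both axes (the diagonal is ignored).  Uses the
    insert-and-absorb algorithm: groups are processed in index order; each
    significant pair splits every letter column containing both members, and
    redundant columns are absorbed, yielding a minimal consistent letter
    set.  Deterministic given the group ordering.
    """
    labels = list(pairwise_p.index)
    if list(pairwise_p.columns) != labels:
        raise ValueError("pairwise p matrix must be square with matching labels")
    for a, b in itertools.combinations(labels, 2):
        pab, pba = pairwise_p.loc[a, b], pairwise_p.loc[b, a]
        if pd.isna(pab) or pd.isna(pba):
            raise ValueError(f"missing pairwise p for ({a}, {b})")

    # columns are sets of group labels; start with everyone together
    columns: list[set[str]] = [set(labels)]
    for a, b in itertools.combinations(labels, 2):
        if pairwise_p.loc[a, b] >= alpha:
            continue  # not significantly different: may share letters
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            col_a, col_b = col - {b}, col - {a}
            for new in (col_a, col_b):
                # absorb: keep only if not a subset of an existing column
                if not any(new <= other for other in columns):
                    columns.append(new)
                    columns = [c for c in columns if not (c < new)]
    # stable ordering: by first member's position, then size
    columns.sort(key=lambda c: (min(labels.index(m) for m in c), -len(c)))
    letters = {lab: "" for lab in labels}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for letter, col in zip(itertools.chain(
            alphabet, (a + b for a in alphabet for b in alphabet)), columns):
        for lab in labels:
            if lab in col:
                letters[lab] += letter
    return letters


# --- Spearman --------------------------------------------------------------

def spearman(x, y) -> tuple[float, float]:
    """Spearman's rho as the Pearson correlation of midranks; two-sided p
    from the t approximation with n − 2 degrees of freedom.

    Zero rank variance in either variable yields (nan, nan).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    rx, ry = rankdata(x), rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan"), float("nan")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return rho, p


# --- Shapiro screen --------------------------------------------------------

def shapiro_screen(x, alpha: float = 0.05) -> TestResult:
    """Shapiro–Wilk normality screen (Royston's approximation).

    ``extra["nonnormal"]`` is True when p < alpha, the cue to fall back to
    the rank-based tests above.  Requires 3 ≤ n ≤ 5000 and a non-constant
    sample.
    """
    x = np.asarray(x, float)
    if len(x) < 3 or len(x) > 5000:
        raise ValueError("Shapiro–Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality is undefined")
    w, p = sps.shapiro(x)
    return TestResult(float(w), float(p), (len(x),), "shapiro-wilk",
                      {"nonnormal": p < alpha})
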