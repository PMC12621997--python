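"""Nonparametric group statistics for per-embryo summaries.

Two-sided throughout.  The Mann–Whitney U test uses full enumeration of
group-label assignments when the combined sample size is at most 20 (exact
even with ties), and the normal approximation with tie correction
otherwise.  Kruskal–Wallis is followed by Dunn's pairwise z-tests on pooled
mean ranks with a Bonferroni-style adjustment of the pairwise p-values.
Spearman's rank correlation uses exact permutation p-values for n ≤ 9 and
the t-approximation beyond.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb, factorial

import numpy as np
from scipy import stats as sps

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p: float) -> str:
    """Significance stars as printed in figure legends (ns at p >= 0.05)."""
    for thr, s in STAR_THRESHOLDS:
        if p < thr:
            return s
    return "ns"


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    groups: list[str]
    sizes: list[int]
    pairwise: list[dict] = field(default_factory=list)  # raw + adjusted p per pair
    note: str = ""

    @property
    def stars(self) -> str:
        return stars(self.p_value)


def _rankdata(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values)


def mann_whitney(
    x, y, alternative: str = "two-sided", labels: tuple[str, str] = ("x", "y")
) -> GroupComparison:
    """Mann–Whitney U test (exact enumeration for combined n <= 20).

    The U statistic reported is U of the first sample (number of (x, y)
    pairs with x < y, ties counting one half).  Identical constant samples
    give p = 1 with a warning rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = _rankdata(combined)
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)

    note = ""
    if np.ptp(combined) == 0:
        warnings.warn("all values identical across both samples; p = 1",
                      stacklevel=2)
        return GroupComparison(
            "mann-whitney", u_x, 1.0, list(labels), [nx, ny],
            note="degenerate: identical values",
        )

    n = nx + ny
    if n <= 20:
        # exact null: every assignment of nx positions to the first group
        mean_u = nx * ny / 2.0
        obs_dev = abs(u_x - mean_u)
        count = 0
        total = comb(n, nx)
        offset = nx * (nx + 1) / 2.0
        for idx in itertools.combinations(range(n), nx):
            u = ranks[list(idx)].sum() - offset
            if alternative == "two-sided":
                hit = abs(u - mean_u) >= obs_dev - 1e-12
            elif alternative == "less":
                hit = u <= u_x + 1e-12
            else:
                hit = u >= u_x - 1e-12
            count += hit
        p = count / total
        note = "exact enumeration"
    else:
        res = sps.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
        p = float(res.pvalue)
        note = "normal approximation with tie correction"
    return GroupComparison(
        "mann-whitney", u_x, min(p, 1.0), list(labels), [nx, ny], note=note
    )


def kruskal_wallis_dunn(
    groups: list, labels: list[str] | None = None, adjust: str = "bonferroni"
) -> GroupComparison:
    """Kruskal–Wallis omnibus test with Dunn's pairwise post-hoc z-tests.

    Pairwise z statistics compare pooled mean ranks,

        z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T) (1/n_i + 1/n_j))

    with tie correction ``T = Σ(t³ − t) / (12(N − 1))``; raw two-sided
    normal p-values are multiplied by the number of comparisons
    (Bonferroni-style, capped at 1), so adjusted p >= raw p always.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("need at least 3 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    labels = labels or [f"group{i}" for i in range(len(groups))]
    sizes = [int(g.size) for g in groups]

    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        omnibus_h, omnibus_p = 0.0, 1.0
    else:
        omnibus_h, omnibus_p = sps.kruskal(*groups)

    ranks = _rankdata(pooled)
    n_total = pooled.size
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(float(ranks[start : start + g.size].mean()))
        start += g.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations(range(len(groups)), 2))
    k = len(pairs)
    pairwise = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        raw = float(2.0 * sps.norm.sf(abs(z)))
        adj = min(1.0, raw * k) if adjust == "bonferroni" else raw
        pairwise.append(
            {
                "pair": (labels[i], labels[j]),
                "z": float(z),
                "p_raw": raw,
                "p_adjusted": adj,
                "stars": stars(adj),
            }
        )
    return GroupComparison(
        "kruskal-wallis-dunn",
        float(omnibus_h),
        float(omnibus_p),
        list(labels),
        sizes,
        pairwise=pairwise,
        note=f"Dunn post-hoc, {adjust} adjustment over {k} pairs",
    )


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (rho, two-sided p).

    Exact permutation p for n <= 9, t-approximation otherwise.  Constant
    input is an error (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman rho undefined")
    n = x.size
    rho = float(sps.spearmanr(x, y).statistic)
    if n <= 9:
        rx = _rankdata(x)
        ry = _rankdata(y)
        # rho is monotone in sum(rx * ry_perm); enumerate all orderings
        obs = float(rx @ ry)
        mean = n * ((n + 1) / 2.0) ** 2
        count = sum(
            1
            for perm in itertools.permutations(ry)
            if abs(float(rx @ np.asarray(perm)) - mean) >= abs(obs - mean) - 1e-12
        )
        p = count / factorial(n)
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return rho, min(p, 1.0)
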