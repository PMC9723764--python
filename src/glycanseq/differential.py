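"""ANCOM-style differential lectin analysis on compositional profiles.

Because profiles are compositional (rows sum to 100), a lectin's percentage
cannot be tested directly: an increase in one lectin depresses all others.
Following the ANCOM (Analysis of Compositions of Microbiomes) idea, each
lectin i is instead tested against every partner lectin j through the
per-sample additive log-ratio log((x_i + c) / (x_j + c)), where c is a small
pseudocount guarding zeros. For each ordered lectin the (m - 1) partner
log-ratios are compared between the two groups with a two-sided Welch t-test
(Mann-Whitney optional), the partner p-values are Holm-Bonferroni adjusted
within that lectin's family, and the W statistic counts how many adjusted
partner tests reject at alpha. A lectin is called significant when W reaches
a fraction of its maximum (default 0.7 * (m - 1), common ANCOM practice) and
its best adjusted partner p-value is below alpha.

All knobs (pseudocount, per-pair test, alpha, W fraction) are configurable
because the original adaptation leaves them open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .profiling import ProfileMatrix

WELCH = "welch"
MANN_WHITNEY = "mann-whitney"


class DifferentialError(ValueError):
    pass


def holm_bonferroni(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values, in input order, capped at 1.

    Equivalent to p~_(i) = max_{j<=i} min(1, (m - j + 1) p_(j)) over the
    sorted p-values.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise DifferentialError("pvals must be a non-empty 1-D vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DifferentialError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adj = np.maximum.accumulate(adj)
    out = np.empty(m)
    out[order] = adj
    return out


@dataclass(frozen=True)
class DifferentialConfig:
    pseudocount: float = 0.5  # on the percentage scale
    test: str = WELCH
    alpha: float = 0.05
    w_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise DifferentialError("pseudocount must be > 0")
        if not 0 < self.alpha < 1:
            raise DifferentialError("alpha must be in (0, 1)")
        if not 0 < self.w_fraction <= 1:
            raise DifferentialError("w_fraction must be in (0, 1]")
        if self.test not in (WELCH, MANN_WHITNEY):
            raise DifferentialError(f"unknown test {self.test!r}; options: {[WELCH, MANN_WHITNEY]}")

    @property
    def w_cutoff_fn(self):
        return lambda w_max: math.ceil(self.w_fraction * w_max)


@dataclass
class DifferentialResult:
    """Per-lectin W statistics, partner p-values and significance calls.

    ``raw_p`` / ``adjusted_p`` are m x m DataFrames of partner-test p-values
    (diagonal NaN); adjustment is Holm within each row (each lectin's partner
    family). ``summary`` has per-lectin columns W, W_max, summary_p
    (minimal adjusted partner p) and significant.
    """

    summary: pd.DataFrame
    raw_p: pd.DataFrame
    adjusted_p: pd.DataFrame
    config: DifferentialConfig
    groups: tuple[str, str]

    @property
    def significant_lectins(self) -> list[str]:
        return self.summary.index[self.summary["significant"]].tolist()


def _welch_p_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Welch t-test p-values, elementwise over trailing axes.

    ``a`` and ``b`` are (n_samples, m, m) log-ratio tensors. Degenerate
    pairs with zero variance in both groups get p = 1 when the means are
    equal (no evidence) and p = 0 when they differ (noiseless separation).
    """
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    se2 = va / na + vb / nb
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0
    p[degenerate & (diff == 0)] = 1.0
    p[degenerate & (diff != 0)] = 0.0
    # one group degenerate: df formula yields nan only if both are; remaining
    # nans come from df=0 edge cases with n=2 — treat as no evidence
    p[np.isnan(p)] = 1.0
    return p


def _mannwhitney_p_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    m = a.shape[1]
    p = np.ones((m, m))
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            x, y = a[:, i, j], b[:, i, j]
            if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
                p[i, j] = 1.0
                continue
            p[i, j] = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
    return p


def ancom_adapted(
    profile: ProfileMatrix,
    group_a: str,
    group_b: str,
    config: DifferentialConfig | None = None,
) -> DifferentialResult:
    """Run the adapted ANCOM test between two groups of a profile matrix.

    Requires at least 2 samples per group and at least 3 lectins. Fully
    deterministic.
    """
    if config is None:
        config = DifferentialConfig()
    if profile.groups is None:
        raise DifferentialError("profile has no group labels")
    names = list(profile.values.columns)
    m = len(names)
    if m < 3:
        raise DifferentialError("differential analysis needs at least 3 lectins")
    masks = {}
    for g in (group_a, group_b):
        mask = (profile.groups == g).to_numpy()
        if mask.sum() < 2:
            raise DifferentialError(f"group {g!r} has fewer than 2 samples")
        masks[g] = mask

    logx = np.log(profile.values.to_numpy(dtype=float) + config.pseudocount)
    ratios = logx[:, :, None] - logx[:, None, :]  # (n, m, m): log((x_i+c)/(x_j+c))
    a, b = ratios[masks[group_a]], ratios[masks[group_b]]
    if config.test == WELCH:
        raw = _welch_p_matrix(a, b)
    else:
        raw = _mannwhitney_p_matrix(a, b)
    np.fill_diagonal(raw, np.nan)

    off_diag = ~np.eye(m, dtype=bool)
    adjusted = np.full_like(raw, np.nan)
    W = np.zeros(m, dtype=int)
    summary_p = np.ones(m)
    for i in range(m):
        adj = holm_bonferroni(raw[i, off_diag[i]])
        adjusted[i, off_diag[i]] = adj
        W[i] = int((adj < config.alpha).sum())
        summary_p[i] = float(adj.min())

    w_max = m - 1
    cutoff = config.w_cutoff_fn(w_max)
    significant = (W >= cutoff) & (summary_p < config.alpha)
    summary = pd.DataFrame(
        {
            "W": W,
            "W_max": w_max,
            "summary_p": summary_p,
            "significant": significant,
        },
        index=pd.Index(names, name="lectin"),
    )
    return DifferentialResult(
        summary=summary,
        raw_p=pd.DataFrame(raw, index=names, columns=names),
        adjusted_p=pd.DataFrame(adjusted, index=names, columns=names),
        config=config,
        groups=(group_a, group_b),
    )


def report_differential(result: DifferentialResult, out_path: str | Path) -> pd.DataFrame:
    """Write the per-lectin report TSV, best hits first.

    Sorted by (significant desc, W desc, summary_p asc), ties broken by
    lectin name; returns the sorted frame.
    """
    df = result.summary.reset_index()
    df = df.sort_values(
        by=["significant", "W", "summary_p", "lectin"],
        ascending=[False, False, True, True],
        kind="mergesort",
    )
    out_path = Path(out_path)
    df.to_csv(out_path, sep="\t", index=False)
    return df.set_index("lectin")
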