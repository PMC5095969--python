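"""Phenotype statistics: outlier detection, family comparisons, inbreeding expectation.

Individuals from a mutagenized population are screened for variant
quantitative phenotypes (flowering time in days, rosette diameter in cm)
against the control distribution with a per-individual one-sample Z-test
(z = (x - mean)/sd on control moments).  Progeny families are compared to
control cohorts with the Wilcoxon rank-sum test, allelic-complexity
proportions with a 2x2 Pearson chi-square, and the expected fraction of
initially heterozygous loci fixed after g generations of single-seed
descent is 1 - (1/2)^g.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Baseline",
    "TestResult",
    "control_baseline",
    "trait_summary",
    "ztest_individual",
    "classify_variants",
    "wilcoxon_rank_sum",
    "proportion_chi_square",
    "expected_homozygosity",
]

# direction labels per trait: (low tail, high tail)
DIRECTION_LABELS: dict[str, tuple[str, str]] = {
    "flowering_time": ("early", "late"),
    "rosette_diameter": ("small", "large"),
}


@dataclass(frozen=True)
class Baseline:
    """Control-population moments for one trait (sample sd, n-1 denominator)."""

    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    direction: str  # "low" / "high" / "none", or a trait-specific label
    significant: bool


def _trait_values(
    table: pd.DataFrame, trait: str, group: str | None = None
) -> pd.Series:
    df = table[table["trait"] == trait]
    if group is not None:
        df = df[df["group"] == group]
    return df.set_index("individual")["value"].astype(float)


def control_baseline(
    table: pd.DataFrame, trait: str, control_label: str = "control"
) -> Baseline:
    """Mean/sd/n of the control group for one trait (sample sd)."""
    vals = _trait_values(table, trait, control_label)
    if len(vals) < 2:
        raise ValueError(
            f"need >= 2 control values for trait {trait!r}, got {len(vals)}"
        )
    return Baseline(float(vals.mean()), float(vals.std(ddof=1)), int(len(vals)))


def trait_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Descriptive statistics (mean, sd, n, min, max) per group x trait."""
    g = table.groupby(["trait", "group"])["value"]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), size="count", min="min", max="max")
    return out.reset_index()


def ztest_individual(x: float, baseline: Baseline, alpha: float = 0.05) -> TestResult:
    """Two-sided one-sample Z-test of one value against control moments."""
    if baseline.sd <= 0:
        raise ValueError("degenerate baseline: sd must be > 0")
    z = (x - baseline.mean) / baseline.sd
    p = 2.0 * stats.norm.sf(abs(z))
    direction = "none" if z == 0 else ("high" if z > 0 else "low")
    return TestResult(float(z), float(p), direction, bool(p < alpha))


def classify_variants(
    table: pd.DataFrame,
    alpha: float = 0.05,
    control_label: str = "control",
    bh_correct: bool = False,
    direction_labels: Mapping[str, tuple[str, str]] | None = None,
) -> dict[str, dict[str, list[str]]]:
    """Assign individuals with significant phenotypes to per-trait tail sets.

    Every non-control individual is Z-tested against the control baseline of
    its trait; those with two-sided p < alpha are collected by direction
    (e.g. flowering_time -> early/late, rosette_diameter -> small/large).
    ``bh_correct`` applies Benjamini-Hochberg across individuals per trait
    before thresholding (the default mirrors uncorrected per-individual
    testing).
    """
    labels = dict(DIRECTION_LABELS)
    if direction_labels:
        labels.update(direction_labels)
    out: dict[str, dict[str, list[str]]] = {}
    for trait in sorted(table["trait"].unique()):
        base = control_baseline(table, trait, control_label)
        low_name, high_name = labels.get(trait, ("low", "high"))
        sub = table[(table["trait"] == trait) & (table["group"] != control_label)]
        ids = sub["individual"].astype(str).to_numpy()
        vals = sub["value"].astype(float).to_numpy()
        z = (vals - base.mean) / base.sd
        p = 2.0 * stats.norm.sf(np.abs(z))
        if bh_correct and len(p):
            order = np.argsort(p)
            ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
            adj = np.minimum.accumulate(ranked[::-1])[::-1]
            padj = np.empty_like(p)
            padj[order] = np.minimum(adj, 1.0)
            p = padj
        sig = p < alpha
        out[trait] = {
            low_name: sorted(ids[sig & (z < 0)].tolist()),
            high_name: sorted(ids[sig & (z > 0)].tolist()),
        }
    return out


def wilcoxon_rank_sum(
    sample_a: Sequence[float], sample_b: Sequence[float], alpha: float = 0.05
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when min(n_a, n_b) <= 10 and there are no ties;
    otherwise the normal approximation with continuity and tie correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    mu = len(a) * len(b) / 2.0
    direction = "none" if res.statistic == mu else ("high" if res.statistic > mu else "low")
    return TestResult(float(res.statistic), float(res.pvalue), direction, bool(res.pvalue < alpha))


def proportion_chi_square(
    k1: int, n1: int, k2: int, n2: int, alpha: float = 0.05
) -> TestResult:
    """2x2 Pearson chi-square (df=1, no continuity correction) on two proportions."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    tab = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: zero row or column margin")
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    p1, p2 = k1 / n1, k2 / n2
    direction = "none" if p1 == p2 else ("high" if p1 > p2 else "low")
    return TestResult(float(chi2), float(p), direction, bool(p < alpha))


def expected_homozygosity(generations: int) -> float:
    """Expected fraction of initially heterozygous loci fixed after selfing.

    Under single-seed descent heterozygosity halves each generation, so the
    fixed fraction after g generations is 1 - (1/2)^g.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    return 1.0 - 0.5**generations
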