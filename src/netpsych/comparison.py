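"""Two-group comparison of networks and raw scores.

Each group's network is nonparametrically bootstrapped: subjects are resampled
with replacement, the full estimation pipeline is re-run, and the three
centrality indices are collected per node.  Group differences per node and
metric are assessed with a two-sample z statistic built from the bootstrap
means and standard deviations combined in quadrature, with Bonferroni
correction across all node x metric cells.

Raw score comparisons use Student's t for (effectively) continuous measures
and Mann-Whitney U for ordinal ones, again Bonferroni-adjusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

from .association import _effective_kind
from .centrality import centrality_profile
from .datagen import MeasureTable
from .estimation import estimate_network

__all__ = [
    "METRICS",
    "BootstrapResult",
    "ComparisonReport",
    "bootstrap_networks",
    "centrality_z_test",
    "bonferroni",
    "descriptive_tests",
]

logger = logging.getLogger(__name__)

METRICS = ("strength", "betweenness", "closeness")


@dataclass
class BootstrapResult:
    """Bootstrap distributions of node centralities for one group."""

    group: str
    nodes: list[str]
    B: int
    replicates: dict[str, np.ndarray]  # metric -> (B, p) array
    failures: int = 0
    seed: int | None = None

    def mean(self, metric: str) -> np.ndarray:
        return self.replicates[metric].mean(axis=0)

    def sd(self, metric: str) -> np.ndarray:
        return self.replicates[metric].std(axis=0, ddof=1) if self.B > 1 else np.zeros(
            len(self.nodes)
        )


@dataclass
class ComparisonReport:
    """Per node x metric z statistics with family-wise Bonferroni flags."""

    table: pd.DataFrame  # node, metric, mean/sd per group, z, p, significant
    m: int  # comparisons actually performed
    alpha: float
    groups: tuple[str, str] = ("a", "b")
    extras: dict = field(default_factory=dict)

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def bootstrap_networks(
    table: MeasureTable,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    grid_size: int = 100,
    redraw_cap_factor: int = 10,
) -> BootstrapResult:
    """Case-resampling bootstrap of the full network + centrality pipeline.

    Resamples that yield a constant column or a failed estimation are redrawn
    (up to ``redraw_cap_factor * B`` total draws) and counted as failures.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    groups = table.groups
    if len(groups) != 1:
        raise ValueError(f"bootstrap expects a single-group table, got groups {groups}")
    rng = np.random.default_rng(seed)
    n = table.n
    values = {m: np.empty((B, len(table.names))) for m in METRICS}
    failures = 0
    draws = 0
    cap = redraw_cap_factor * B
    b = 0
    while b < B:
        if draws >= cap:
            raise RuntimeError(
                f"bootstrap redraw cap exceeded: {failures} failures in {draws} draws "
                f"({failures / draws:.1%} failure rate)"
            )
        draws += 1
        idx = rng.integers(0, n, size=n)
        resampled = MeasureTable(
            table.data.iloc[idx].reset_index(drop=True), table.variables
        )
        cols = resampled.values()
        if np.any(np.ptp(cols, axis=0) == 0):
            failures += 1
            continue
        try:
            net = estimate_network(resampled, alpha=alpha, grid_size=grid_size)
            profile = centrality_profile(net)
        except Exception:  # estimation can fail on degenerate resamples
            failures += 1
            continue
        for m in METRICS:
            values[m][b] = getattr(profile, m)
        b += 1
    if failures:
        logger.info("bootstrap for group %r: %d redraws out of %d draws", groups[0], failures, draws)
    return BootstrapResult(
        group=groups[0], nodes=list(table.names), B=B, replicates=values,
        failures=failures, seed=seed,
    )


def bonferroni(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Family-wise significance flags: p_i <= alpha / m."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return p <= alpha / p.size


def centrality_z_test(
    a: BootstrapResult, b: BootstrapResult, alpha: float = 0.05
) -> ComparisonReport:
    """Two-sample z tests on bootstrap centrality distributions.

    z = (mean_a - mean_b) / sqrt(sd_a^2 + sd_b^2); cells where both bootstrap
    SDs are zero are undefined, flagged, and excluded from the Bonferroni
    family size m.
    """
    if a.nodes != b.nodes:
        raise ValueError("bootstrap results cover different node sets")
    rows = []
    for metric in METRICS:
        ma, sa = a.mean(metric), a.sd(metric)
        mb, sb = b.mean(metric), b.sd(metric)
        for i, node in enumerate(a.nodes):
            denom = np.sqrt(sa[i] ** 2 + sb[i] ** 2)
            if denom == 0:
                z = p = np.nan
            else:
                z = (ma[i] - mb[i]) / denom
                p = 2.0 * ndtr(-abs(z))
            rows.append(
                {
                    "node": node, "metric": metric,
                    "mean_a": ma[i], "sd_a": sa[i],
                    "mean_b": mb[i], "sd_b": sb[i],
                    "z": z, "p": p,
                }
            )
    df = pd.DataFrame(rows)
    defined = df["p"].notna()
    m = int(defined.sum())
    flags = np.zeros(len(df), dtype=bool)
    if m > 0:
        flags[defined] = df.loc[defined, "p"].to_numpy() <= alpha / m
    df["significant"] = flags
    return ComparisonReport(df, m=m, alpha=alpha, groups=(a.group, b.group))


def descriptive_tests(
    a: MeasureTable, b: MeasureTable, alpha: float = 0.05, welch: bool = False
) -> pd.DataFrame:
    """Per-measure raw-score comparisons between two groups.

    Continuous(-like) measures get a two-sample t test (pooled variance by
    default), ordinal ones a two-sided Mann-Whitney U.  Flags are Bonferroni
    across all measures tested.
    """
    if a.names != b.names:
        raise ValueError("the two tables declare different measure columns")
    rows = []
    for v in a.variables:
        xa = a.data[v.name].to_numpy(dtype=float)
        xb = b.data[v.name].to_numpy(dtype=float)
        if _effective_kind(v) == "continuous":
            test = "t"
            if np.ptp(xa) == 0 and np.ptp(xb) == 0 and xa.mean() != xb.mean():
                stat, p = np.inf, 0.0  # exact separation with zero variance
            else:
                res = stats.ttest_ind(xa, xb, equal_var=not welch)
                stat, p = float(res.statistic), float(res.pvalue)
                if np.isnan(p):  # identical constants
                    stat, p = 0.0, 1.0
        else:
            test = "mann-whitney"
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append({"measure": v.name, "test": test, "statistic": stat, "p": p})
    df = pd.DataFrame(rows)
    df["significant"] = bonferroni(df["p"].to_numpy(), alpha=alpha)
    return df
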