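"""Presence/absence gene grouping and the expression-association statistics.

Implements Welch's unequal-variance t-test, the Wilcoxon rank-sum test
(exact for small tie-free samples, tie- and continuity-corrected normal
approximation otherwise), Pearson's r, Kendall's tau-b, and Kendall's
partial rank correlation controlling for a third variable with a normal
significance test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneGrouping",
    "PartialTauResult",
    "group_genes",
    "welch_t",
    "wilcoxon_rank_sum",
    "pearson_r",
    "kendall_tau",
    "partial_kendall_tau",
    "association_report",
]


@dataclass(frozen=True)
class GeneGrouping:
    """Partition of the core gene set by presence of a synonymous substitution."""

    with_syn: frozenset[str]
    without_syn: frozenset[str]

    def __post_init__(self):
        if self.with_syn & self.without_syn:
            raise ValueError("gene groups must be disjoint")


@dataclass(frozen=True)
class PartialTauResult:
    tau_xy: float
    tau_xz: float
    tau_yz: float
    tau_partial: float
    z_score: float
    p_two_sided: float
    n: int


def group_genes(per_gene_counts: Mapping[str, int]) -> GeneGrouping:
    """Split genes into those with >= 1 synonymous substitution and the rest."""
    with_syn = frozenset(g for g, c in per_gene_counts.items() if c >= 1)
    without_syn = frozenset(per_gene_counts) - with_syn
    return GeneGrouping(with_syn=with_syn, without_syn=without_syn)


def _as_array(v: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, two-sided p)."""
    x, y = _as_array(x, "x"), _as_array(y, "y")
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_t needs at least 2 observations per sample")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        raise ValueError("both samples have zero variance")
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Wilcoxon rank-sum test; returns (W, two-sided p).

    W is the sum of midranks of ``x`` in the pooled sample.  The p-value
    is exact (full enumeration via the Mann–Whitney null distribution)
    when the pooled size is <= 12 and there are no ties; otherwise the
    normal approximation with tie correction and continuity correction.
    """
    x, y = _as_array(x, "x"), _as_array(y, "y")
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    W = float(ranks[: len(x)].sum())
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = len(pooled) <= 12 and not has_ties
    method = "exact" if small else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return W, float(res.pvalue)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient."""
    x, y = _as_array(x, "x"), _as_array(y, "y")
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson_r needs equal-length samples of size >= 3")
    if x.var() == 0 or y.var() == 0:
        raise ValueError("pearson_r undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall's tau-b (tie-corrected)."""
    x, y = _as_array(x, "x"), _as_array(y, "y")
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("kendall_tau needs equal-length samples of size >= 3")
    if len(np.unique(x)) == 1 or len(np.unique(y)) == 1:
        raise ValueError("kendall_tau undefined for an all-tied variable")
    return float(stats.kendalltau(x, y).statistic)


def partial_kendall_tau(
    x: Sequence[float], y: Sequence[float], z: Sequence[float]
) -> PartialTauResult:
    """Kendall's partial rank correlation of x and y controlling for z.

    ``tau_partial = (t_xy - t_xz * t_yz) / sqrt((1 - t_xz^2)(1 - t_yz^2))``,
    with significance from the normal approximation that reuses the
    ordinary-tau variance ``2(2n+5) / (9 n (n-1))``.
    """
    x, y, z = _as_array(x, "x"), _as_array(y, "y"), _as_array(z, "z")
    n = len(x)
    if not (len(y) == len(z) == n) or n < 10:
        raise ValueError("partial_kendall_tau needs equal-length samples of size >= 10")
    t_xy = kendall_tau(x, y)
    t_xz = kendall_tau(x, z)
    t_yz = kendall_tau(y, z)
    denom = (1 - t_xz**2) * (1 - t_yz**2)
    if denom <= 0:
        raise ValueError("degenerate control: |tau_xz| or |tau_yz| equals 1")
    tau_partial = (t_xy - t_xz * t_yz) / np.sqrt(denom)
    sd = np.sqrt(2.0 * (2 * n + 5) / (9.0 * n * (n - 1)))
    z_score = tau_partial / sd
    p = 2.0 * stats.norm.sf(abs(z_score))
    return PartialTauResult(
        tau_xy=t_xy, tau_xz=t_xz, tau_yz=t_yz,
        tau_partial=float(tau_partial), z_score=float(z_score),
        p_two_sided=float(p), n=n,
    )


def association_report(
    table: pd.DataFrame,
    binary: bool = False,
) -> pd.DataFrame:
    """Run the full association analysis on a per-gene table.

    ``table`` needs columns gene_id, length, n_syn, expression.  The
    substitution variable entering the partial correlation is the per-gene
    count by default, or the 0/1 presence indicator with ``binary=True``.
    Returns a long-format statistics report.
    """
    required = {"gene_id", "length", "n_syn", "expression"}
    if not required.issubset(table.columns):
        raise ValueError(f"association table needs columns {sorted(required)}")
    df = table.dropna(subset=["length", "n_syn", "expression"]).reset_index(drop=True)
    grouping = group_genes(dict(zip(df["gene_id"], df["n_syn"])))
    has = df["gene_id"].isin(grouping.with_syn)
    expr_with, expr_without = df.loc[has, "expression"], df.loc[~has, "expression"]
    len_with, len_without = df.loc[has, "length"], df.loc[~has, "length"]

    rows = []
    t, dof, p = welch_t(expr_with, expr_without)
    rows.append(("welch_t_expression", t, p, f"df={dof:.1f}"))
    W, p = wilcoxon_rank_sum(len_with, len_without)
    rows.append(("wilcoxon_length", W, p, ""))
    rows.append(("mean_length_with_syn", float(len_with.mean()), np.nan, "bp"))
    rows.append(("mean_length_without_syn", float(len_without.mean()), np.nan, "bp"))
    rel_diff = 100.0 * (expr_with.mean() - expr_without.mean()) / expr_without.mean()
    rows.append(("mean_expression_pct_difference", float(rel_diff), np.nan, "%"))
    rows.append(("pearson_expression_length", pearson_r(df["expression"], df["length"]), np.nan, ""))
    subs = (df["n_syn"] >= 1).astype(float) if binary else df["n_syn"].astype(float)
    pt = partial_kendall_tau(subs, df["expression"], df["length"])
    label = "partial_tau_subs_expression_given_length" + ("_binary" if binary else "")
    rows.append((label, pt.tau_partial, pt.p_two_sided, f"z={pt.z_score:.3f}"))
    rows.append(("kendall_tau_subs_expression", pt.tau_xy, np.nan, ""))
    return pd.DataFrame(rows, columns=["statistic", "value", "p_value", "note"])
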