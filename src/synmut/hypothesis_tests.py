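"""Rate models and goodness-of-fit tests over the diversity-ranked gene axis.

Genes are placed on a fixed axis sorted by ascending theta_s (ties broken
by gene_id).  A :class:`RateModel` assigns each gene a probability of
receiving the next synonymous substitution; the observed per-gene counts
give a cumulative curve over the same axis, and the two are compared with
a Kolmogorov–Smirnov sup-difference.  The KS statistic treats each
substitution as an independent draw over the gene axis (effective sample
size = substitution count); the asymptotic p-value uses the Kolmogorov
distribution and a multinomial Monte-Carlo p-value is provided as the
preferred, discreteness-exact alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .codon_model import SPECTRUM_CLASSES
from .mutation_annotation import AnnotatedMutation, GeneAnnotation, LineageClass

__all__ = [
    "RATE_MODES",
    "RateModel",
    "CumulativeCurve",
    "KSResult",
    "build_rate_model",
    "observed_curve",
    "ks_compare",
    "monte_carlo_pvalue",
    "subgroup_tests",
    "spectrum_summary",
    "counts_vector",
]

RATE_MODES = ("length_null", "syn_sites_null", "theta_per_site", "theta_per_gene")


@dataclass(frozen=True)
class RateModel:
    """Per-gene probabilities for where the next substitution lands."""

    mode: str
    gene_ids: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any():
            raise ValueError("rate-model weights must be nonnegative")
        total = w.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("rate-model weights must have a positive finite sum")
        if abs(total - 1.0) > 1e-12:
            raise ValueError("rate-model weights must sum to 1 within 1e-12")
        object.__setattr__(self, "weights", w)

    @property
    def cdf(self) -> np.ndarray:
        c = np.cumsum(self.weights)
        c[-1] = 1.0
        return c


@dataclass(frozen=True)
class CumulativeCurve:
    """Cumulative proportion of substitutions over an ordered gene axis."""

    gene_ids: tuple[str, ...]
    cumulative: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.cumulative, dtype=float)
        if len(c) != len(self.gene_ids):
            raise ValueError("cumulative length != number of genes")
        if (np.diff(c) < -1e-12).any():
            raise ValueError("cumulative curve must be nondecreasing")
        if abs(c[-1] - 1.0) > 1e-9:
            raise ValueError("cumulative curve must end at 1")
        c = np.clip(c, 0.0, 1.0)
        c[-1] = 1.0
        object.__setattr__(self, "cumulative", c)


@dataclass(frozen=True)
class KSResult:
    D: float
    n: int
    p_asymptotic: float
    p_montecarlo: float | None = None
    mc_reps: int | None = None
    mc_seed: int | None = None


def _theta_order(genes: Sequence[GeneAnnotation]) -> list[GeneAnnotation]:
    missing = [g.gene_id for g in genes if g.theta_s is None or np.isnan(g.theta_s)]
    if missing:
        raise ValueError(f"genes missing theta_s (needed for ordering): {missing[:10]}")
    return sorted(genes, key=lambda g: (g.theta_s, g.gene_id))


def build_rate_model(genes: Iterable[GeneAnnotation], mode: str) -> RateModel:
    """Build a rate model over the theta_s-ascending gene axis.

    Weights are proportional to gene length (``length_null``), synonymous
    site count (``syn_sites_null``), theta_s × synonymous sites
    (``theta_per_site``) or theta_s alone (``theta_per_gene``).
    """
    if mode not in RATE_MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {RATE_MODES}")
    ordered = _theta_order(list(genes))
    if not ordered:
        raise ValueError("no genes supplied")
    if mode == "length_null":
        raw = np.array([g.length_bp for g in ordered], dtype=float)
    elif mode == "syn_sites_null":
        raw = np.array([g.syn_sites for g in ordered], dtype=float)
    elif mode == "theta_per_site":
        raw = np.array([g.theta_s * g.syn_sites for g in ordered], dtype=float)
    else:
        raw = np.array([g.theta_s for g in ordered], dtype=float)
    return RateModel(mode=mode, gene_ids=tuple(g.gene_id for g in ordered), weights=raw / raw.sum())


def counts_vector(counts: Mapping[str, int], gene_ids: Sequence[str]) -> np.ndarray:
    """Align a per-gene count mapping to an ordered gene axis."""
    known = set(gene_ids)
    unknown = [g for g in counts if g not in known]
    if unknown:
        raise ValueError(f"genes in counts absent from ordering: {unknown[:10]}")
    return np.array([counts.get(g, 0) for g in gene_ids], dtype=float)


def observed_curve(counts: Mapping[str, int] | np.ndarray, model: RateModel) -> CumulativeCurve:
    """Cumulative proportion of observed substitutions over the model's axis."""
    if isinstance(counts, Mapping):
        vec = counts_vector(counts, model.gene_ids)
    else:
        vec = np.asarray(counts, dtype=float)
        if len(vec) != len(model.gene_ids):
            raise ValueError("counts vector length != number of genes in ordering")
    total = vec.sum()
    if total < 1:
        raise ValueError("need at least one substitution to form an observed curve")
    return CumulativeCurve(gene_ids=model.gene_ids, cumulative=np.cumsum(vec) / total)


def _ks_stat(obs_cdf: np.ndarray, model_cdf: np.ndarray) -> float:
    return float(np.max(np.abs(obs_cdf - model_cdf)))


def ks_asymptotic_pvalue(D: float, n: int) -> float:
    """Kolmogorov-distribution tail with the finite-n effective lambda."""
    if n < 1:
        raise ValueError("n must be >= 1")
    sqrt_n = np.sqrt(n)
    lam = (sqrt_n + 0.12 + 0.11 / sqrt_n) * D
    return float(special.kolmogorov(lam))


def ks_compare(
    obs: CumulativeCurve,
    model: RateModel,
    n: int,
    mc_reps: int | None = None,
    seed: int | None = None,
) -> KSResult:
    """KS sup-difference between an observed curve and a rate model.

    ``n`` is the substitution count (effective sample size).  With
    ``mc_reps`` set, a multinomial Monte-Carlo p-value is attached.
    """
    if obs.gene_ids != model.gene_ids:
        raise ValueError("observed curve and rate model use different gene orderings")
    D = _ks_stat(obs.cumulative, model.cdf)
    result = KSResult(D=D, n=n, p_asymptotic=ks_asymptotic_pvalue(D, n))
    if mc_reps:
        if seed is None:
            raise ValueError("Monte-Carlo p-value requires an explicit seed")
        p_mc = monte_carlo_pvalue(model, n, D, reps=mc_reps, seed=seed)
        result = KSResult(
            D=D, n=n, p_asymptotic=result.p_asymptotic,
            p_montecarlo=p_mc, mc_reps=mc_reps, mc_seed=seed,
        )
    return result


def monte_carlo_pvalue(
    model: RateModel, n: int, D_obs: float, reps: int, seed: int, batch: int = 1000
) -> float:
    """Multinomial Monte-Carlo null for the discrete KS statistic.

    Draws ``reps`` multinomial samples of size ``n`` from the model's
    weights, recomputes D for each, and returns the add-one estimator
    ``(1 + #{D_sim >= D_obs}) / (reps + 1)``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    model_cdf = model.cdf
    exceed = 0
    done = 0
    while done < reps:
        k = min(batch, reps - done)
        draws = rng.multinomial(n, model.weights, size=k)
        sim_cdf = np.cumsum(draws, axis=1) / n
        D_sim = np.max(np.abs(sim_cdf - model_cdf), axis=1)
        exceed += int(np.sum(D_sim >= D_obs - 1e-15))
        done += k
    return (1 + exceed) / (reps + 1)


def subgroup_tests(
    muts: Iterable[AnnotatedMutation],
    genes: Sequence[GeneAnnotation],
    mode: str,
    groups: Sequence[LineageClass] | None = None,
    mc_reps: int | None = None,
    seed: int | None = None,
) -> dict[str, KSResult]:
    """Rerun observed_curve + ks_compare restricted to each lineage class.

    Groups with no substitutions are skipped with a warning.
    """
    import logging

    model = build_rate_model(genes, mode)
    by_class: dict[LineageClass, dict[str, int]] = {}
    for m in muts:
        if m.gene_id is None:
            continue
        d = by_class.setdefault(m.event.lineage_class, {})
        d[m.gene_id] = d.get(m.gene_id, 0) + 1
    if groups is None:
        groups = sorted(by_class, key=lambda c: c.value)
    results: dict[str, KSResult] = {}
    for i, cls in enumerate(groups):
        counts = by_class.get(cls, {})
        n = sum(counts.values())
        if n == 0:
            logging.getLogger(__name__).warning("lineage class %s has no substitutions; skipped", cls.value)
            continue
        sub_seed = None if seed is None else seed + i
        obs = observed_curve(counts, model)
        results[cls.value] = ks_compare(obs, model, n, mc_reps=mc_reps, seed=sub_seed)
    return results


def spectrum_summary(muts: Iterable[AnnotatedMutation], by: str = "clone_id") -> pd.DataFrame:
    """Counts of the six spectrum classes per clone (or per lineage class)."""
    if by not in ("clone_id", "lineage_class"):
        raise ValueError("'by' must be 'clone_id' or 'lineage_class'")
    labels = [c.value for c in SPECTRUM_CLASSES]
    rows: dict[str, dict[str, int]] = {}
    for m in muts:
        key = m.event.clone_id if by == "clone_id" else m.event.lineage_class.value
        row = rows.setdefault(key, {lab: 0 for lab in labels})
        row[m.spectrum.value] += 1
    df = pd.DataFrame.from_dict(rows, orient="index", columns=labels).fillna(0).astype(int)
    df.index.name = by
    return df.sort_index().reset_index()
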