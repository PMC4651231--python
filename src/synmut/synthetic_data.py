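"""Ground-truth-labeled synthetic cohorts for every pipeline stage.

Generates a gene set with realistic length / diversity / expression
distributions, an ancestral genome (FASTA + GFF3), natural-isolate codon
alignments under an infinite-sites amino-acid-invariant model, and
experimental mutation cohorts drawn from a configurable per-gene rate
model with lineage-specific base-substitution spectra.  All randomness
flows from a single seeded generator; identical parameters and seed give
byte-identical output files.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import codon_model
from .codon_model import BASES, SPECTRUM_CLASSES, SpectrumClass, SubstitutionEffect
from .diversity import CodonAlignment, harmonic_a
from .hypothesis_tests import build_rate_model
from .mutation_annotation import GeneAnnotation, GenomeAnnotation, LineageClass, MutationEvent

__all__ = [
    "SyntheticCohortParams",
    "GroundTruth",
    "DEFAULT_SPECTRA",
    "DEFAULT_CLONES",
    "sample_gene_table",
    "generate_genes",
    "generate_alignment",
    "generate_experiment",
    "write_cohort",
]

# ---------------------------------------------------------------------------
# per-codon lookup tables

_NON_STOP_CODONS = sorted(
    b0 + b1 + b2
    for b0 in BASES for b1 in BASES for b2 in BASES
    if (b0 + b1 + b2) not in codon_model.STOP_CODONS
)

# codon code -> list of (codon_pos0, alt_base) synonymous single-base changes
_SYN_CHANGES: dict[int, list[tuple[int, str]]] = {}
# codon code -> {SpectrumClass: [(codon_pos0, ref, alt), ...]} synonymous only
_SYN_BY_CLASS: dict[int, dict[SpectrumClass, list[tuple[int, str, str]]]] = {}
for _codon in _NON_STOP_CODONS:
    _code = int(codon_model.encode_codons(_codon)[0])
    _SYN_CHANGES[_code] = []
    _SYN_BY_CLASS[_code] = {}
    for _pos in range(3):
        for _alt in BASES:
            if _alt == _codon[_pos]:
                continue
            eff = codon_model.classify_substitution(_codon, _pos + 1, _alt)
            if eff is SubstitutionEffect.SYNONYMOUS:
                _SYN_CHANGES[_code].append((_pos, _alt))
                cls = codon_model.spectrum_class(_codon[_pos], _alt)
                _SYN_BY_CLASS[_code].setdefault(cls, []).append((_pos, _codon[_pos], _alt))


DEFAULT_SPECTRA: dict[LineageClass, dict[str, float]] = {
    # mismatch-repair-deficient clones: transition-dominated
    LineageClass.MMR_HYPERMUTATOR: {
        "CG_to_TA": 0.52, "AT_to_GC": 0.40, "AT_to_CG": 0.02,
        "AT_to_TA": 0.02, "CG_to_AT": 0.02, "CG_to_GC": 0.02,
    },
    # mutT-deficient clones: dominated by A:T -> C:G transversions
    LineageClass.MUTT_HYPERMUTATOR: {
        "AT_to_CG": 0.90, "CG_to_TA": 0.03, "AT_to_GC": 0.03,
        "AT_to_TA": 0.02, "CG_to_AT": 0.01, "CG_to_GC": 0.01,
    },
    LineageClass.NONMUTATOR: {
        "CG_to_TA": 0.25, "AT_to_GC": 0.25, "AT_to_CG": 0.15,
        "AT_to_TA": 0.15, "CG_to_AT": 0.10, "CG_to_GC": 0.10,
    },
}

#: 12 clones: 4 mismatch-repair mutators, 2 mutT mutators, 6 nonmutators
DEFAULT_CLONES: dict[str, LineageClass] = {
    "Ara-1": LineageClass.MUTT_HYPERMUTATOR,
    "Ara-2": LineageClass.MMR_HYPERMUTATOR,
    "Ara-3": LineageClass.MMR_HYPERMUTATOR,
    "Ara-4": LineageClass.MMR_HYPERMUTATOR,
    "Ara-5": LineageClass.NONMUTATOR,
    "Ara-6": LineageClass.NONMUTATOR,
    "Ara+1": LineageClass.NONMUTATOR,
    "Ara+2": LineageClass.NONMUTATOR,
    "Ara+3": LineageClass.MMR_HYPERMUTATOR,
    "Ara+4": LineageClass.NONMUTATOR,
    "Ara+5": LineageClass.NONMUTATOR,
    "Ara+6": LineageClass.MUTT_HYPERMUTATOR,
}

_HYPERMUTATOR_SHARE = 1055 / 1069  # fraction of events in mutator lineages


@dataclass
class SyntheticCohortParams:
    """Generator settings for a full synthetic cohort."""

    n_genes: int = 2834
    # gene lengths: lognormal, median ~900 bp, truncated, multiples of 3
    length_median: float = 900.0
    length_sigma: float = 0.62
    length_bounds: tuple[int, int] = (150, 6000)
    # per-gene diversity: lognormal with a guaranteed fold-range
    theta_median: float = 0.02
    theta_sigma: float = 0.80
    theta_min_fold_range: float = 20.0
    # expression: lognormal, Gaussian-copula-coupled to length
    expression_median: float = 100.0
    expression_sigma: float = 0.70
    expression_length_r: float = 0.09
    # experiment
    rate_mode: str = "theta_per_site"
    n_substitutions: int | None = 1069
    clones: Mapping[str, LineageClass] = field(default_factory=lambda: dict(DEFAULT_CLONES))
    spectra: Mapping[LineageClass, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SPECTRA.items()}
    )
    hypermutator_share: float = _HYPERMUTATOR_SHARE
    # neutral-accumulation scale (used when n_substitutions is None:
    # expected events = t * mu * total synonymous sites)
    N_e: float = 2.5e7
    mu: float = 8.9e-11
    t: float = 40000.0
    intergenic_spacer: int = 120
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if self.intergenic_spacer < 0:
            raise ValueError("intergenic spacer must be nonnegative")
        for rate in (self.N_e, self.mu, self.t):
            if rate < 0:
                raise ValueError("N_e, mu and t must be nonnegative")
        for cls, spec in self.spectra.items():
            total = sum(spec.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"spectrum probabilities for {cls} sum to {total}, not 1")


@dataclass
class GroundTruth:
    """Generator bookkeeping: true weights and per-event assignments."""

    rate_mode: str
    gene_ids: list[str]
    weights: list[float]
    events: pd.DataFrame  # clone_id, contig, position(0-based), ref, alt, gene_id, effect, spectrum
    per_gene_counts: dict[str, int]

    def to_json(self) -> str:
        return json.dumps(
            {
                "rate_mode": self.rate_mode,
                "gene_ids": self.gene_ids,
                "weights": self.weights,
                "per_gene_counts": self.per_gene_counts,
                "events": self.events.to_dict(orient="records"),
            },
            indent=1,
        )


def _lognormal_lengths(params: SyntheticCohortParams, rng: np.random.Generator) -> np.ndarray:
    lo, hi = params.length_bounds
    raw = rng.lognormal(np.log(params.length_median), params.length_sigma, size=params.n_genes)
    raw = np.clip(raw, lo, hi)
    lengths = (np.round(raw / 3).astype(int) * 3)
    return np.clip(lengths, ((lo + 2) // 3) * 3, (hi // 3) * 3)


def _theta_values(params: SyntheticCohortParams, rng: np.random.Generator) -> np.ndarray:
    logs = rng.normal(np.log(params.theta_median), params.theta_sigma, size=params.n_genes)
    spread = logs.max() - logs.min()
    need = np.log(params.theta_min_fold_range)
    if spread < need:
        # widen deviations about the mean so the fold-range target holds
        center = logs.mean()
        logs = center + (logs - center) * (1.25 * need / max(spread, 1e-9))
    return np.exp(logs)


def _copula_expression(
    lengths: np.ndarray, params: SyntheticCohortParams, rng: np.random.Generator
) -> np.ndarray:
    """Lognormal expression whose Pearson r with length hits the target.

    The latent correlation of the Gaussian copula is calibrated by
    bisection against the realized length vector and noise draw, so the
    achieved product-moment correlation matches the target closely.
    """
    from scipy import stats as _st

    n = len(lengths)
    ranks = _st.rankdata(lengths, method="average")
    z_len = _st.norm.ppf(ranks / (n + 1))
    eps = rng.standard_normal(n)
    target = params.expression_length_r

    def realized(rho: float) -> np.ndarray:
        latent = rho * z_len + np.sqrt(max(1 - rho**2, 0.0)) * eps
        return np.exp(np.log(params.expression_median) + params.expression_sigma * latent)

    if np.std(lengths) == 0 or n < 4:
        return realized(target)
    lo, hi = -0.999, 0.999
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        r = np.corrcoef(lengths, realized(mid))[0, 1]
        if r < target:
            lo = mid
        else:
            hi = mid
    return realized(0.5 * (lo + hi))


def sample_gene_table(params: SyntheticCohortParams, rng: np.random.Generator) -> pd.DataFrame:
    """Sample per-gene length, theta_s and expression (no sequences)."""
    width = len(str(params.n_genes))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(params.n_genes)]
    lengths = _lognormal_lengths(params, rng)
    thetas = _theta_values(params, rng)
    expression = _copula_expression(lengths.astype(float), params, rng)
    return pd.DataFrame(
        {"gene_id": gene_ids, "length": lengths, "theta_s": thetas, "expression": expression}
    )


def _random_cds(length: int, rng: np.random.Generator) -> str:
    n_codons = length // 3
    idx = rng.integers(0, len(_NON_STOP_CODONS), size=n_codons - 1)
    return "ATG" + "".join(_NON_STOP_CODONS[i] for i in idx)


def generate_genes(
    params: SyntheticCohortParams,
    rng: np.random.Generator | None = None,
    table: pd.DataFrame | None = None,
) -> tuple[GenomeAnnotation, pd.DataFrame]:
    """Realize a gene table as an annotated synthetic chromosome.

    Genes are tiled with intergenic spacers onto one contig; strands
    alternate pseudo-randomly; each CDS starts with ATG and contains no
    stop codons.  Returns the genome annotation and the gene table.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if table is None:
        table = sample_gene_table(params, rng)
    spacer = params.intergenic_spacer
    parts: list[str] = []
    genes: dict[str, GeneAnnotation] = {}
    cursor = 0
    contig = "chr_syn"
    strands = rng.choice(["+", "-"], size=len(table))
    for i, row in enumerate(table.itertuples(index=False)):
        gap = "".join(rng.choice(list(BASES), size=spacer))
        parts.append(gap)
        cursor += spacer
        cds = _random_cds(int(row.length), rng)
        strand = str(strands[i])
        parts.append(cds if strand == "+" else codon_model.reverse_complement(cds))
        genes[row.gene_id] = GeneAnnotation(
            gene_id=row.gene_id,
            contig=contig,
            start=cursor,
            end=cursor + len(cds),
            strand=strand,
            cds=cds,
            syn_sites=codon_model.gene_synonymous_sites_fast(cds),
            theta_s=float(row.theta_s),
            expression=float(row.expression),
        )
        cursor += len(cds)
    parts.append("".join(rng.choice(list(BASES), size=spacer)))
    genome = GenomeAnnotation(contigs={contig: "".join(parts)}, genes=genes)
    table = table.copy()
    table["syn_sites"] = [genes[g].syn_sites for g in table["gene_id"]]
    return genome, table


def generate_alignment(
    cds_or_gene: str | GeneAnnotation,
    n_isolates: int,
    theta_true: float,
    rng: np.random.Generator,
    gene_id: str = "gene",
) -> CodonAlignment:
    """Simulate a natural-isolate codon alignment with known diversity.

    Infinite-sites, amino-acid-invariant model: the number of synonymous
    segregating sites is Poisson with mean ``theta_true * a_n * L_syn``;
    each lands on a distinct site with a synonymous alternative, and the
    derived allele is carried by a uniform 1..n-1 subset of isolates.
    """
    if theta_true < 0:
        raise ValueError("theta_true must be >= 0")
    if isinstance(cds_or_gene, GeneAnnotation):
        cds, gene_id = cds_or_gene.cds, cds_or_gene.gene_id
    else:
        cds = cds_or_gene
    codes = codon_model.encode_codons(cds)
    capable: list[tuple[int, list[tuple[int, str]]]] = []
    for j, code in enumerate(codes):
        changes = _SYN_CHANGES.get(int(code), [])
        if changes:
            capable.append((j, changes))
    l_syn = codon_model.gene_synonymous_sites_fast(cds)
    isolate_ids = tuple(f"iso{i + 1:02d}" for i in range(n_isolates))
    if l_syn == 0 or not capable:
        import logging

        logging.getLogger(__name__).warning("%s: no synonymous sites; invariant alignment", gene_id)
        return CodonAlignment(gene_id=gene_id, isolate_ids=isolate_ids,
                              sequences=tuple(cds for _ in range(n_isolates)))
    a_n = harmonic_a(n_isolates)
    S = int(rng.poisson(theta_true * a_n * l_syn))
    S = min(S, len(capable))
    seqs = [list(cds) for _ in range(n_isolates)]
    chosen = rng.choice(len(capable), size=S, replace=False)
    for c in np.sort(chosen):
        codon_j, changes = capable[int(c)]
        pos, alt = changes[int(rng.integers(0, len(changes)))]
        k = int(rng.integers(1, n_isolates))
        carriers = rng.choice(n_isolates, size=k, replace=False)
        for iso in carriers:
            seqs[int(iso)][3 * codon_j + pos] = alt
    return CodonAlignment(
        gene_id=gene_id,
        isolate_ids=isolate_ids,
        sequences=tuple("".join(s) for s in seqs),
    )


def _gene_sites_by_class(gene: GeneAnnotation) -> dict[SpectrumClass, list[tuple[int, str, str]]]:
    """Synonymous change options per spectrum class, as CDS offsets."""
    out: dict[SpectrumClass, list[tuple[int, str, str]]] = {}
    for j, code in enumerate(codon_model.encode_codons(gene.cds)):
        for cls, options in _SYN_BY_CLASS.get(int(code), {}).items():
            bucket = out.setdefault(cls, [])
            for pos, ref, alt in options:
                bucket.append((3 * j + pos, ref, alt))
    return out


def _clone_probs(params: SyntheticCohortParams) -> tuple[list[str], np.ndarray]:
    clones = sorted(params.clones)
    mutators = [c for c in clones if params.clones[c] is not LineageClass.NONMUTATOR]
    normals = [c for c in clones if params.clones[c] is LineageClass.NONMUTATOR]
    probs = np.zeros(len(clones))
    for i, c in enumerate(clones):
        if c in mutators:
            probs[i] = params.hypermutator_share / max(len(mutators), 1)
        else:
            probs[i] = (1 - params.hypermutator_share) / max(len(normals), 1)
    if not mutators:
        probs[:] = 1.0 / len(clones)
    return clones, probs / probs.sum()


def generate_experiment(
    genome: GenomeAnnotation,
    params: SyntheticCohortParams,
    rng: np.random.Generator,
) -> tuple[list[MutationEvent], GroundTruth]:
    """Draw an experimental cohort of synonymous substitutions.

    Events are distributed over genes by a multinomial draw from the rate
    model implied by ``params.rate_mode``; within a gene each event picks
    a synonymous site compatible with its clone's spectrum by bounded
    rejection sampling.  All events occupy distinct genomic positions.
    """
    genes = list(genome.genes.values())
    model = build_rate_model(genes, params.rate_mode)
    gene_by_id = genome.genes
    if params.n_substitutions is not None:
        n_subs = params.n_substitutions
    else:
        total_syn_sites = sum(g.syn_sites for g in genes)
        n_subs = int(round(params.t * params.mu * total_syn_sites * len(params.clones)))
    counts = rng.multinomial(n_subs, model.weights)
    clone_ids, clone_p = _clone_probs(params)
    spectra = {
        cls: np.array([params.spectra[cls].get(sc.value, 0.0) for sc in SPECTRUM_CLASSES])
        for cls in set(params.clones.values())
    }

    events: list[MutationEvent] = []
    records: list[dict] = []
    used_positions: set[tuple[str, int]] = set()
    for gid, count in zip(model.gene_ids, counts):
        if count == 0:
            continue
        gene = gene_by_id[gid]
        by_class = _gene_sites_by_class(gene)
        if not by_class:
            raise RuntimeError(f"gene {gid} has no synonymous sites but received events")
        available = [sc for sc in SPECTRUM_CLASSES if sc in by_class]
        for _ in range(int(count)):
            clone = clone_ids[int(rng.choice(len(clone_ids), p=clone_p))]
            lineage = params.clones[clone]
            probs = spectra[lineage]
            placed = False
            for _attempt in range(200):
                cls = SPECTRUM_CLASSES[int(rng.choice(len(SPECTRUM_CLASSES), p=probs))]
                options = by_class.get(cls)
                if not options:
                    continue
                offset, ref, alt = options[int(rng.integers(0, len(options)))]
                if gene.strand == "+":
                    pos = gene.start + offset
                    g_ref, g_alt = ref, alt
                else:
                    pos = gene.end - 1 - offset
                    g_ref = codon_model.complement(ref)
                    g_alt = codon_model.complement(alt)
                if (gene.contig, pos) in used_positions:
                    continue
                used_positions.add((gene.contig, pos))
                events.append(
                    MutationEvent(
                        contig=gene.contig, position=pos, ref_base=g_ref,
                        alt_base=g_alt, clone_id=clone, lineage_class=lineage,
                    )
                )
                records.append(
                    {
                        "clone_id": clone,
                        "lineage_class": lineage.value,
                        "contig": gene.contig,
                        "position": pos,
                        "ref_base": g_ref,
                        "alt_base": g_alt,
                        "gene_id": gid,
                        "codon_index": offset // 3 + 1,
                        "codon_position": offset % 3 + 1,
                        "effect": SubstitutionEffect.SYNONYMOUS.value,
                        "spectrum": cls.value,
                    }
                )
                placed = True
                break
            if not placed:
                # fall back to any synonymous site in the gene, any class
                fallback = [sc for sc in available if by_class[sc]]
                if not fallback:
                    raise RuntimeError(
                        f"could not place event in gene {gid}: spectrum incompatible "
                        "with available synonymous changes"
                    )
                raise RuntimeError(
                    f"bounded rejection sampling failed for gene {gid} "
                    f"(clone {clone}); spectrum too restrictive for this gene"
                )
    per_gene = {gid: 0 for gid in model.gene_ids}
    for r in records:
        per_gene[r["gene_id"]] += 1
    truth = GroundTruth(
        rate_mode=params.rate_mode,
        gene_ids=list(model.gene_ids),
        weights=[float(w) for w in model.weights],
        events=pd.DataFrame(records),
        per_gene_counts=per_gene,
    )
    return events, truth


# ---------------------------------------------------------------------------
# writers (text formats only)

def _write_fasta(contigs: Mapping[str, str], path: Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _write_gff(genome: GenomeAnnotation, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, seq in genome.contigs.items():
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for gid in sorted(genome.genes):
            g = genome.genes[gid]
            fh.write(
                f"{g.contig}\tsynmut\tCDS\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t0\t"
                f"ID={g.gene_id}\n"
            )


def _write_vcfs(
    events: Sequence[MutationEvent], genome: GenomeAnnotation, out_dir: Path
) -> list[Path]:
    by_clone: dict[str, list[MutationEvent]] = {}
    for ev in events:
        by_clone.setdefault(ev.clone_id, []).append(ev)
    paths = []
    for clone in sorted(by_clone):
        path = out_dir / f"{clone.replace('+', 'p').replace('-', 'm')}.vcf"
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for name, seq in genome.contigs.items():
                fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
            fh.write(f"##clone_id={clone}\n")
            fh.write(f"##lineage_class={by_clone[clone][0].lineage_class.value}\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for ev in sorted(by_clone[clone], key=lambda e: (e.contig, e.position)):
                fh.write(
                    f"{ev.contig}\t{ev.position + 1}\t.\t{ev.ref_base}\t{ev.alt_base}\t.\tPASS\t.\n"
                )
        paths.append(path)
    return paths


def write_cohort(
    out_dir: str | Path,
    params: SyntheticCohortParams,
    n_isolates: int = 10,
    write_alignments: bool = False,
) -> dict[str, object]:
    """Generate and write a full cohort to ``out_dir``.

    Writes genome FASTA, features GFF3, per-clone VCFs, theta table,
    expression table, core-gene list, clone metadata, ground-truth JSON
    and optionally per-gene isolate alignments.  Returns the in-memory
    objects for further use.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)
    genome, table = generate_genes(params, rng)
    events, truth = generate_experiment(genome, params, rng)

    _write_fasta(genome.contigs, out_dir / "genome.fasta")
    _write_gff(genome, out_dir / "features.gff3")
    vcf_paths = _write_vcfs(events, genome, out_dir)
    table[["gene_id", "theta_s"]].to_csv(out_dir / "theta.tsv", sep="\t", index=False)
    table[["gene_id", "expression"]].to_csv(out_dir / "expression.tsv", sep="\t", index=False)
    with open(out_dir / "core_genes.txt", "w") as fh:
        for gid in sorted(genome.genes):
            fh.write(gid + "\n")
    clone_meta = pd.DataFrame(
        sorted((c, l.value) for c, l in params.clones.items()),
        columns=["clone_id", "lineage_class"],
    )
    clone_meta.to_csv(out_dir / "clones.tsv", sep="\t", index=False)
    with open(out_dir / "ground_truth.json", "w") as fh:
        fh.write(truth.to_json())
    if write_alignments:
        aln_dir = out_dir / "alignments"
        aln_dir.mkdir(exist_ok=True)
        for gid in sorted(genome.genes):
            gene = genome.genes[gid]
            sub_rng = np.random.default_rng([params.seed, zlib.crc32(gid.encode())])
            aln = generate_alignment(gene, n_isolates, gene.theta_s, sub_rng)
            with open(aln_dir / f"{gid}.fasta", "w") as fh:
                for iso, seq in zip(aln.isolate_ids, aln.sequences):
                    fh.write(f">{iso}\n{seq}\n")
    return {
        "genome": genome,
        "table": table,
        "events": events,
        "truth": truth,
        "vcf_paths": vcf_paths,
        "out_dir": out_dir,
    }
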