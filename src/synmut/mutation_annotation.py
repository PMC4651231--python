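"""Place point mutations onto an annotated ancestral genome.

Responsibilities: load a genome FASTA + GFF3 gene annotation into
:class:`GeneAnnotation` records (0-based half-open internally, minus-strand
CDS reverse-complemented), map each :class:`MutationEvent` into its codon,
classify the effect strand-aware, assign the strand-collapsed spectrum
class on genome-strand bases, and restrict collections to the core gene
set of synonymous events.
"""

from __future__ import annotations

import enum
import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO

from . import codon_model
from .codon_model import SpectrumClass, SubstitutionEffect

logger = logging.getLogger(__name__)

__all__ = [
    "LineageClass",
    "GeneAnnotation",
    "MutationEvent",
    "AnnotatedMutation",
    "GenomeAnnotation",
    "load_annotations",
    "annotate",
    "annotate_all",
    "core_synonymous_set",
    "per_gene_counts",
    "read_mutations_vcf",
    "read_mutations_tsv",
    "write_annotated_tsv",
    "write_per_gene_counts",
]


class LineageClass(enum.Enum):
    MMR_HYPERMUTATOR = "MMR_hypermutator"
    MUTT_HYPERMUTATOR = "mutT_hypermutator"
    NONMUTATOR = "nonmutator"


@dataclass
class GeneAnnotation:
    """One protein-coding gene on the ancestral genome.

    Coordinates are 0-based half-open; ``cds`` is already
    reverse-complemented for minus-strand genes.
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    cds: str
    syn_sites: float = 0.0
    theta_s: float | None = None
    expression: float | None = None
    in_core: bool = True

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.end - self.start != len(self.cds):
            raise ValueError(f"{self.gene_id}: cds length != end - start")
        if self.length_bp % 3 != 0:
            raise ValueError(f"{self.gene_id}: length {self.length_bp} not divisible by 3")


@dataclass(frozen=True)
class MutationEvent:
    """A single-nucleotide substitution observed in one evolved clone.

    ``position`` is 0-based (VCF/TSV readers convert from 1-based on disk).
    """

    contig: str
    position: int
    ref_base: str
    alt_base: str
    clone_id: str
    lineage_class: LineageClass = LineageClass.NONMUTATOR


@dataclass(frozen=True)
class AnnotatedMutation:
    """A mutation mapped onto the gene set.

    ``codon_index`` is 1-based (first codon of the CDS = 1), as is
    ``codon_position`` (1..3 within the codon).
    """

    event: MutationEvent
    gene_id: str | None
    codon_index: int | None
    codon_position: int | None
    effect: SubstitutionEffect | None
    spectrum: SpectrumClass
    in_core: bool
    ambiguous: bool = False

    @property
    def intergenic(self) -> bool:
        return self.gene_id is None


@dataclass
class GenomeAnnotation:
    """Genome sequences plus accepted gene annotations and a rejects report."""

    contigs: dict[str, str]
    genes: dict[str, GeneAnnotation]
    rejects: list[tuple[str, str]] = field(default_factory=list)
    _index: dict[str, tuple[list[int], list[GeneAnnotation], int]] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self):
        self._build_index()

    def _build_index(self) -> None:
        # sorted start coordinates per contig; overlap lookup scans left
        # from the insertion point, bounded by the longest gene on the contig
        self._index = {}
        by_contig: dict[str, list[GeneAnnotation]] = {}
        for g in self.genes.values():
            by_contig.setdefault(g.contig, []).append(g)
        for contig, genes in by_contig.items():
            genes.sort(key=lambda g: (g.start, g.gene_id))
            starts = [g.start for g in genes]
            max_len = max(g.length_bp for g in genes)
            self._index[contig] = (starts, genes, max_len)

    def genes_at(self, contig: str, position: int) -> list[GeneAnnotation]:
        if contig not in self._index:
            return []
        starts, genes, max_len = self._index[contig]
        hits = []
        i = bisect_right(starts, position) - 1
        while i >= 0:
            g = genes[i]
            if g.end > position:
                hits.append(g)
            if position - g.start >= max_len:
                break
            i -= 1
        return sorted(hits, key=lambda g: g.gene_id)


def load_annotations(
    genome_fasta: str | Path,
    features_gff: str | Path,
    core_ids: Iterable[str] | None = None,
    feature_types: Sequence[str] = ("CDS",),
) -> GenomeAnnotation:
    """Load the ancestral genome and its CDS features.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open;
    minus-strand CDS are reverse-complemented.  Genes failing invariants
    (missing contig, out-of-range, non-triplet length, internal stops) are
    excluded and listed in the rejects report with a reason.
    """
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome_fasta), "fasta")}
    db = gffutils.create_db(
        str(features_gff),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    core = set(core_ids) if core_ids is not None else None

    genes: dict[str, GeneAnnotation] = {}
    rejects: list[tuple[str, str]] = []
    for ftype in feature_types:
        for feat in db.features_of_type(ftype):
            gene_id = feat.attributes.get("ID", [feat.id])[0]
            if feat.seqid not in contigs:
                rejects.append((gene_id, f"unknown contig {feat.seqid}"))
                continue
            start, end = feat.start - 1, feat.end  # to 0-based half-open
            seq = contigs[feat.seqid]
            if start < 0 or end > len(seq) or start >= end:
                rejects.append((gene_id, f"coordinates [{feat.start}, {feat.end}] out of range"))
                continue
            if (end - start) % 3 != 0:
                rejects.append((gene_id, f"length {end - start} not divisible by 3"))
                continue
            cds = seq[start:end]
            if feat.strand == "-":
                cds = codon_model.reverse_complement(cds)
            elif feat.strand != "+":
                rejects.append((gene_id, f"strand {feat.strand!r} not supported"))
                continue
            try:
                syn_sites = codon_model.gene_synonymous_sites_fast(cds)
            except ValueError as exc:
                rejects.append((gene_id, str(exc)))
                continue
            genes[gene_id] = GeneAnnotation(
                gene_id=gene_id,
                contig=feat.seqid,
                start=start,
                end=end,
                strand=feat.strand,
                cds=cds,
                syn_sites=syn_sites,
                in_core=(core is None or gene_id in core),
            )
    if core is not None:
        missing = core - set(genes)
        for gid in sorted(missing):
            logger.warning("core gene %s absent from accepted annotations", gid)
    for gid, reason in rejects:
        logger.warning("rejected gene %s: %s", gid, reason)
    return GenomeAnnotation(contigs=contigs, genes=genes, rejects=rejects)


def _effect_from_codons(ref_codon: str, alt_codon: str) -> SubstitutionEffect:
    # lenient path used when the reference codon is a (terminal) stop
    ref_aa = codon_model.translate(ref_codon)
    alt_aa = codon_model.translate(alt_codon)
    if alt_aa == ref_aa:
        return SubstitutionEffect.SYNONYMOUS
    if alt_aa == codon_model.STOP:
        return SubstitutionEffect.NONSENSE
    return SubstitutionEffect.NONSYNONYMOUS


def annotate(mut: MutationEvent, genome: GenomeAnnotation) -> AnnotatedMutation:
    """Annotate one mutation against the genome.

    Positions inside overlapping genes are assigned to the
    lexicographically smallest gene_id and flagged ``ambiguous``.
    """
    seq = genome.contigs.get(mut.contig)
    if seq is None:
        raise ValueError(f"unknown contig {mut.contig!r}")
    if not (0 <= mut.position < len(seq)):
        raise ValueError(f"position {mut.position} outside contig {mut.contig}")
    if seq[mut.position] != mut.ref_base.upper():
        raise ValueError(
            f"ref mismatch at {mut.contig}:{mut.position}: "
            f"event says {mut.ref_base}, ancestor has {seq[mut.position]}"
        )
    spectrum = codon_model.spectrum_class(mut.ref_base, mut.alt_base)

    hits = genome.genes_at(mut.contig, mut.position)
    if not hits:
        return AnnotatedMutation(
            event=mut, gene_id=None, codon_index=None, codon_position=None,
            effect=None, spectrum=spectrum, in_core=False,
        )
    gene = hits[0]
    ambiguous = len(hits) > 1
    if ambiguous:
        logger.warning(
            "position %s:%d in %d overlapping genes; assigned to %s",
            mut.contig, mut.position, len(hits), gene.gene_id,
        )
    if gene.strand == "+":
        offset = mut.position - gene.start
        ref, alt = mut.ref_base.upper(), mut.alt_base.upper()
    else:
        offset = gene.end - 1 - mut.position
        ref = codon_model.complement(mut.ref_base)
        alt = codon_model.complement(mut.alt_base)
    codon_index0 = offset // 3
    codon_position = offset % 3 + 1
    ref_codon = gene.cds[3 * codon_index0 : 3 * codon_index0 + 3]
    if ref_codon[codon_position - 1] != ref:
        raise AssertionError(
            f"internal inconsistency: CDS of {gene.gene_id} disagrees with genome"
        )
    alt_codon = ref_codon[: codon_position - 1] + alt + ref_codon[codon_position:]
    if ref_codon in codon_model.STOP_CODONS:
        effect = _effect_from_codons(ref_codon, alt_codon)
    else:
        effect = codon_model.classify_substitution(ref_codon, codon_position, alt)
    return AnnotatedMutation(
        event=mut,
        gene_id=gene.gene_id,
        codon_index=codon_index0 + 1,
        codon_position=codon_position,
        effect=effect,
        spectrum=spectrum,
        in_core=gene.in_core,
        ambiguous=ambiguous,
    )


def annotate_all(muts: Iterable[MutationEvent], genome: GenomeAnnotation) -> list[AnnotatedMutation]:
    return [annotate(m, genome) for m in muts]


def core_synonymous_set(muts: Iterable[AnnotatedMutation]) -> list[AnnotatedMutation]:
    """Retain synonymous substitutions inside core genes."""
    return [m for m in muts if m.effect is SubstitutionEffect.SYNONYMOUS and m.in_core]


def per_gene_counts(
    muts: Iterable[AnnotatedMutation], genome: GenomeAnnotation | None = None
) -> pd.DataFrame:
    """Per-gene synonymous / nonsynonymous counts.

    When ``genome`` is given, every accepted gene appears (zero-filled).
    """
    rows: dict[str, dict[str, int]] = {}
    if genome is not None:
        for gid in genome.genes:
            rows[gid] = {"n_syn": 0, "n_nonsyn": 0, "n_nonsense": 0}
    for m in muts:
        if m.gene_id is None:
            continue
        r = rows.setdefault(m.gene_id, {"n_syn": 0, "n_nonsyn": 0, "n_nonsense": 0})
        if m.effect is SubstitutionEffect.SYNONYMOUS:
            r["n_syn"] += 1
        elif m.effect is SubstitutionEffect.NONSYNONYMOUS:
            r["n_nonsyn"] += 1
        else:
            r["n_nonsense"] += 1
    df = pd.DataFrame(
        [(gid, r["n_syn"], r["n_nonsyn"], r["n_nonsense"]) for gid, r in rows.items()],
        columns=["gene_id", "n_syn", "n_nonsyn", "n_nonsense"],
    )
    return df.sort_values("gene_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# IO

def read_mutations_vcf(
    path: str | Path,
    clone_id: str | None = None,
    lineage_map: Mapping[str, LineageClass | str] | None = None,
) -> list[MutationEvent]:
    """Read SNVs from a VCF.  Multi-nucleotide and indel records are skipped.

    ``clone_id`` defaults to a ``##clone_id=`` header line if present,
    else the file stem; ``lineage_map`` supplies the per-clone lineage
    class (the mutator identities are experimental metadata, not
    inferred from genotype), overridden by a ``##lineage_class=`` header.
    """
    path = Path(path)
    events: list[MutationEvent] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        header_meta = {
            rec.key: rec.value
            for rec in vcf.header.records
            if rec.type == "GENERIC" and rec.key in ("clone_id", "lineage_class")
        }
        if clone_id is None:
            clone_id = header_meta.get("clone_id", path.stem)
        if "lineage_class" in header_meta:
            lineage = LineageClass(header_meta["lineage_class"])
        elif lineage_map and clone_id in lineage_map:
            val = lineage_map[clone_id]
            lineage = val if isinstance(val, LineageClass) else LineageClass(val)
        else:
            lineage = LineageClass.NONMUTATOR
        for rec in vcf:
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1 or alt not in "ACGT":
                    skipped += 1
                    continue
                events.append(
                    MutationEvent(
                        contig=rec.chrom,
                        position=rec.pos - 1,
                        ref_base=rec.ref,
                        alt_base=alt,
                        clone_id=clone_id,
                        lineage_class=lineage,
                    )
                )
    if skipped:
        logger.info("%s: skipped %d non-SNV allele records", path.name, skipped)
    return events


def read_mutations_tsv(
    path: str | Path,
    lineage_map: Mapping[str, LineageClass | str] | None = None,
) -> list[MutationEvent]:
    """Read mutations from a TSV with columns contig, position (1-based),
    ref_base, alt_base and optionally clone_id, lineage_class."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    required = {"contig", "position", "ref_base", "alt_base"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: mutation TSV needs columns {sorted(required)}")
    events = []
    for row in df.itertuples(index=False):
        clone = str(getattr(row, "clone_id", "clone"))
        if hasattr(row, "lineage_class"):
            lineage = LineageClass(getattr(row, "lineage_class"))
        elif lineage_map and clone in lineage_map:
            val = lineage_map[clone]
            lineage = val if isinstance(val, LineageClass) else LineageClass(val)
        else:
            lineage = LineageClass.NONMUTATOR
        events.append(
            MutationEvent(
                contig=str(row.contig),
                position=int(row.position) - 1,
                ref_base=str(row.ref_base),
                alt_base=str(row.alt_base),
                clone_id=clone,
                lineage_class=lineage,
            )
        )
    return events


def annotated_to_frame(muts: Iterable[AnnotatedMutation]) -> pd.DataFrame:
    rows = []
    for m in muts:
        rows.append(
            {
                "contig": m.event.contig,
                "position": m.event.position + 1,  # 1-based on disk
                "ref_base": m.event.ref_base,
                "alt_base": m.event.alt_base,
                "clone_id": m.event.clone_id,
                "lineage_class": m.event.lineage_class.value,
                "gene_id": m.gene_id if m.gene_id is not None else "",
                "codon_index": m.codon_index if m.codon_index is not None else "",
                "codon_position": m.codon_position if m.codon_position is not None else "",
                "effect": m.effect.value if m.effect is not None else "intergenic",
                "spectrum": m.spectrum.value,
                "in_core": m.in_core,
                "ambiguous": m.ambiguous,
            }
        )
    return pd.DataFrame(rows)


def write_annotated_tsv(muts: Iterable[AnnotatedMutation], path: str | Path) -> None:
    annotated_to_frame(muts).to_csv(path, sep="\t", index=False)


def write_per_gene_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
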