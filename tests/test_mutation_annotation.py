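import glob

import pytest

from synmut import codon_model as cm
from synmut import mutation_annotation as ma
from synmut import synthetic_data as sd
from synmut.codon_model import SubstitutionEffect
from synmut.mutation_annotation import LineageClass, MutationEvent

from conftest import write_genome_files


@pytest.fixture
def two_gene_genome(tmp_path):
    """One + strand gene, one - strand gene, with intergenic padding.

    plus gene (1-based 11..19):  ATG GAA TTT
    minus gene (1-based 31..39): gene-strand ATG GAG CTG, stored reverse-
    complemented on the genome.
    """
    plus_cds = "ATGGAATTT"
    minus_cds = "ATGGAGCTG"
    seq = "A" * 10 + plus_cds + "C" * 11 + cm.reverse_complement(minus_cds) + "G" * 10
    fasta, gff = write_genome_files(
        tmp_path,
        {"chr1": seq},
        [
            "chr1\ttest\tCDS\t11\t19\t.\t+\t0\tID=gplus",
            "chr1\ttest\tCDS\t31\t39\t.\t-\t0\tID=gminus",
        ],
    )
    return ma.load_annotations(fasta, gff)


class TestLoadAnnotations:
    def test_two_genes_roundtrip(self, two_gene_genome):
        genome = two_gene_genome
        assert set(genome.genes) == {"gplus", "gminus"}
        assert not genome.rejects
        gplus = genome.genes["gplus"]
        assert (gplus.start, gplus.end, gplus.strand) == (10, 19, "+")
        assert gplus.cds == "ATGGAATTT"
        assert genome.contigs["chr1"][gplus.start:gplus.end] == gplus.cds

    def test_minus_strand_cds_is_reverse_complement_of_slice(self, two_gene_genome):
        g = two_gene_genome.genes["gminus"]
        genome_slice = two_gene_genome.contigs["chr1"][g.start:g.end]
        assert g.cds == cm.reverse_complement(genome_slice)
        assert g.cds == "ATGGAGCTG"

    def test_non_triplet_gene_rejected_with_reason(self, tmp_path):
        seq = "A" * 10 + "ATGGAATTTC" + "A" * 10  # 10 bp CDS
        fasta, gff = write_genome_files(
            tmp_path, {"c": seq}, ["c\ttest\tCDS\t11\t20\t.\t+\t0\tID=bad"]
        )
        genome = ma.load_annotations(fasta, gff)
        assert "bad" not in genome.genes
        assert any("divisible by 3" in reason for gid, reason in genome.rejects if gid == "bad")

    def test_unknown_contig_rejected(self, tmp_path):
        fasta, gff = write_genome_files(
            tmp_path, {"c": "ATGGAATTT" + "A" * 10},
            ["nope\ttest\tCDS\t1\t9\t.\t+\t0\tID=g1"],
        )
        genome = ma.load_annotations(fasta, gff)
        assert genome.rejects and "unknown contig" in genome.rejects[0][1]

    def test_out_of_range_rejected(self, tmp_path):
        fasta, gff = write_genome_files(
            tmp_path, {"c": "ATGGAATTT"}, ["c\ttest\tCDS\t4\t15\t.\t+\t0\tID=g1"]
        )
        genome = ma.load_annotations(fasta, gff)
        assert genome.rejects and "out of range" in genome.rejects[0][1]

    def test_core_flag(self, tmp_path):
        seq = "ATGGAATTT" + "A" * 5 + "ATGCCCGGG" + "A" * 5
        fasta, gff = write_genome_files(
            tmp_path, {"c": seq},
            ["c\ttest\tCDS\t1\t9\t.\t+\t0\tID=g1", "c\ttest\tCDS\t15\t23\t.\t+\t0\tID=g2"],
        )
        genome = ma.load_annotations(fasta, gff, core_ids=["g1"])
        assert genome.genes["g1"].in_core and not genome.genes["g2"].in_core


class TestAnnotate:
    def test_plus_strand_nonsynonymous(self, two_gene_genome):
        # third base of the start codon ATG -> ATA (Met -> Ile)
        mut = MutationEvent("chr1", 12, "G", "A", "cl")
        ann = ma.annotate(mut, two_gene_genome)
        assert ann.gene_id == "gplus"
        assert (ann.codon_index, ann.codon_position) == (1, 3)
        assert ann.effect is SubstitutionEffect.NONSYNONYMOUS

    def test_plus_strand_synonymous(self, two_gene_genome):
        # GAA -> GAG (Glu -> Glu) at the second codon
        mut = MutationEvent("chr1", 15, "A", "G", "cl")
        ann = ma.annotate(mut, two_gene_genome)
        assert ann.gene_id == "gplus"
        assert (ann.codon_index, ann.codon_position) == (2, 3)
        assert ann.effect is SubstitutionEffect.SYNONYMOUS

    def test_minus_strand_worked_example(self, two_gene_genome):
        """Genome-strand C->T inside gminus = gene-strand G->A at codon 2
        position 3: GAG -> GAA, synonymous, spectrum CG_to_TA."""
        g = two_gene_genome.genes["gminus"]
        # gene-strand offset 5 (codon 2, position 3) -> genome position
        pos = g.end - 1 - 5
        assert two_gene_genome.contigs["chr1"][pos] == "C"  # complement of gene-strand G
        ann = ma.annotate(MutationEvent("chr1", pos, "C", "T", "cl"), two_gene_genome)
        assert ann.gene_id == "gminus"
        assert (ann.codon_index, ann.codon_position) == (2, 3)
        assert ann.effect is SubstitutionEffect.SYNONYMOUS
        assert ann.spectrum.value == "CG_to_TA"

    def test_intergenic_keeps_spectrum(self, two_gene_genome):
        ann = ma.annotate(MutationEvent("chr1", 2, "A", "C", "cl"), two_gene_genome)
        assert ann.intergenic
        assert ann.effect is None
        assert not ann.in_core
        assert ann.spectrum.value == "AT_to_CG"

    def test_ref_mismatch_names_position(self, two_gene_genome):
        with pytest.raises(ValueError, match="chr1:2"):
            ma.annotate(MutationEvent("chr1", 2, "G", "C", "cl"), two_gene_genome)

    def test_overlapping_genes_deterministic_and_flagged(self, tmp_path):
        seq = "ATGGAATTTGGG" + "A" * 10
        fasta, gff = write_genome_files(
            tmp_path, {"c": seq},
            ["c\ttest\tCDS\t1\t9\t.\t+\t0\tID=gb", "c\ttest\tCDS\t4\t12\t.\t+\t0\tID=ga"],
        )
        genome = ma.load_annotations(fasta, gff)
        ann = ma.annotate(MutationEvent("c", 5, "A", "G", "cl"), genome)
        assert ann.gene_id == "ga"  # lexicographically smallest
        assert ann.ambiguous

    def test_conservation(self, small_cohort):
        genome = small_cohort["genome"]
        ann = ma.annotate_all(small_cohort["events"], genome)
        n_hits = sum(1 for a in ann if not a.intergenic)
        n_inter = sum(1 for a in ann if a.intergenic)
        assert n_hits + n_inter == len(small_cohort["events"])

    def test_roundtrip_effect_reproducible(self, small_cohort):
        genome = small_cohort["genome"]
        for a in ma.annotate_all(small_cohort["events"], genome):
            gene = genome.genes[a.gene_id]
            codon = gene.cds[3 * (a.codon_index - 1): 3 * a.codon_index]
            if gene.strand == "+":
                alt = a.event.alt_base
            else:
                alt = cm.complement(a.event.alt_base)
            assert cm.classify_substitution(codon, a.codon_position, alt) is a.effect


def mirror_genome(genome):
    """Reverse-complement every contig and mirror the gene features."""
    contigs = {c: cm.reverse_complement(s) for c, s in genome.contigs.items()}
    genes = {}
    for gid, g in genome.genes.items():
        L = len(genome.contigs[g.contig])
        genes[gid] = ma.GeneAnnotation(
            gene_id=gid, contig=g.contig, start=L - g.end, end=L - g.start,
            strand="-" if g.strand == "+" else "+", cds=g.cds,
            syn_sites=g.syn_sites, theta_s=g.theta_s, expression=g.expression,
        )
    return ma.GenomeAnnotation(contigs=contigs, genes=genes)


class TestStrandSymmetry:
    def test_mirrored_genome_gives_identical_annotations(self, small_cohort):
        genome = small_cohort["genome"]
        mirrored = mirror_genome(genome)
        for ev in small_cohort["events"]:
            L = len(genome.contigs[ev.contig])
            mirrored_ev = MutationEvent(
                contig=ev.contig, position=L - 1 - ev.position,
                ref_base=cm.complement(ev.ref_base), alt_base=cm.complement(ev.alt_base),
                clone_id=ev.clone_id, lineage_class=ev.lineage_class,
            )
            a = ma.annotate(ev, genome)
            b = ma.annotate(mirrored_ev, mirrored)
            assert a.gene_id == b.gene_id
            assert a.effect is b.effect
            assert a.spectrum is b.spectrum


class TestCoreSynonymousSet:
    def test_filter_definition(self, two_gene_genome):
        muts = [
            ma.annotate(MutationEvent("chr1", 15, "A", "G", "c1"), two_gene_genome),  # syn core
            ma.annotate(MutationEvent("chr1", 12, "G", "A", "c1"), two_gene_genome),  # nonsyn
            ma.annotate(MutationEvent("chr1", 2, "A", "C", "c1"), two_gene_genome),   # intergenic
        ]
        kept = ma.core_synonymous_set(muts)
        assert len(kept) == 1 and kept[0].gene_id == "gplus"

    def test_empty(self):
        assert ma.core_synonymous_set([]) == []

    def test_non_core_synonymous_dropped(self, tmp_path):
        fasta, gff = write_genome_files(
            tmp_path, {"c": "ATGGAATTT"}, ["c\ttest\tCDS\t1\t9\t.\t+\t0\tID=g1"]
        )
        genome = ma.load_annotations(fasta, gff, core_ids=[])
        ann = ma.annotate(MutationEvent("c", 5, "A", "G", "c1"), genome)
        assert ann.effect is SubstitutionEffect.SYNONYMOUS and not ann.in_core
        assert ma.core_synonymous_set([ann]) == []

    def test_matches_generator_ground_truth(self, small_cohort):
        genome = small_cohort["genome"]
        ann = ma.annotate_all(small_cohort["events"], genome)
        kept = ma.core_synonymous_set(ann)
        truth = small_cohort["truth"]
        assert len(kept) == len(truth.events)
        got = sorted((a.event.contig, a.event.position) for a in kept)
        expected = sorted(zip(truth.events["contig"], truth.events["position"]))
        assert got == expected


class TestIO:
    def test_vcf_reader_roundtrip(self, small_cohort):
        events = []
        lineage_map = {c: l for c, l in sd.DEFAULT_CLONES.items()}
        for path in sorted(glob.glob(str(small_cohort["out_dir"] / "*.vcf"))):
            stem = path.rsplit("/", 1)[-1][:-4]  # e.g. Aram1 <-> Ara-1
            clone = "Ara" + ("-" if stem[3] == "m" else "+") + stem[4:]
            events.append((clone, ma.read_mutations_vcf(path, clone_id=clone, lineage_map=lineage_map)))
        total = sum(len(evs) for _, evs in events)
        assert total == len(small_cohort["events"])
        for clone, evs in events:
            for ev in evs:
                assert ev.clone_id == clone
                assert ev.lineage_class is sd.DEFAULT_CLONES[clone]

    def test_vcf_skips_indels(self, tmp_path):
        vcf = tmp_path / "x.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=c,length=100>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "c\t5\t.\tA\tG\t.\tPASS\t.\n"
            "c\t9\t.\tAT\tA\t.\tPASS\t.\n"
        )
        events = ma.read_mutations_vcf(vcf)
        assert len(events) == 1
        assert events[0].position == 4  # converted to 0-based

    def test_tsv_reader(self, tmp_path):
        tsv = tmp_path / "m.tsv"
        tsv.write_text(
            "contig\tposition\tref_base\talt_base\tclone_id\n"
            "c\t5\tA\tG\tAra-1\n"
        )
        events = ma.read_mutations_tsv(tsv, lineage_map={"Ara-1": "mutT_hypermutator"})
        assert events[0].position == 4
        assert events[0].lineage_class is LineageClass.MUTT_HYPERMUTATOR

    def test_annotated_tsv_writer(self, tmp_path, small_cohort):
        import pandas as pd

        genome = small_cohort["genome"]
        ann = ma.annotate_all(small_cohort["events"], genome)
        out = tmp_path / "ann.tsv"
        ma.write_annotated_tsv(ann, out)
        df = pd.read_csv(out, sep="\t")
        assert len(df) == len(ann)
        assert (df["effect"] == "synonymous").all()

    def test_per_gene_counts_zero_filled(self, small_cohort):
        genome = small_cohort["genome"]
        ann = ma.annotate_all(small_cohort["events"], genome)
        df = ma.per_gene_counts(ma.core_synonymous_set(ann), genome)
        assert len(df) == len(genome.genes)
        assert df["n_syn"].sum() == len(small_cohort["events"])
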