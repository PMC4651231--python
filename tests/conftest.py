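import numpy as np
import pytest

from synmut import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """A small but structurally complete cohort."""
    return sd.SyntheticCohortParams(n_genes=60, n_substitutions=80, seed=11)


@pytest.fixture
def small_cohort(tmp_path, small_params):
    return sd.write_cohort(tmp_path / "cohort", small_params)


def write_genome_files(tmp_path, contigs, gff_lines):
    """Write a hand-constructed FASTA + GFF3 pair; returns the two paths."""
    fasta = tmp_path / "genome.fasta"
    with open(fasta, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n{seq}\n")
    gff = tmp_path / "features.gff3"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in gff_lines:
            fh.write(line + "\n")
    return fasta, gff
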