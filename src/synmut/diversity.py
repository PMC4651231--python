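"""Per-gene synonymous nucleotide diversity from codon alignments.

The estimator is Watterson's theta restricted to synonymous sites:
``theta_s = S_syn / (a_n * L_syn)`` where ``S_syn`` counts nucleotide
columns that are polymorphic while leaving the amino acid at their codon
invariant across all sequences, ``L_syn`` is the Nei–Gojobori synonymous
site count averaged over sequences, and ``a_n = sum_{i=1}^{n-1} 1/i``.

Codon columns containing a gap or ambiguity code in any sequence are
dropped from both S and L before estimation.  Polymorphic columns whose
codons do not preserve amino-acid identity across all sequences are
excluded from S (no substitution-pathway averaging).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .codon_model import BASES, STOP, gene_synonymous_sites_fast, translate

__all__ = [
    "CodonAlignment",
    "ThetaEstimate",
    "harmonic_a",
    "count_segregating_synonymous_sites",
    "watterson_theta",
    "estimate_theta_s",
    "read_alignment_fasta",
    "estimate_directory",
    "write_theta_table",
    "read_theta_table",
]


@dataclass(frozen=True)
class CodonAlignment:
    """An in-frame multiple alignment of one gene across isolates."""

    gene_id: str
    isolate_ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self):
        if len(self.sequences) < 2:
            raise ValueError(f"{self.gene_id}: alignment needs >= 2 sequences")
        if len(self.isolate_ids) != len(self.sequences):
            raise ValueError(f"{self.gene_id}: isolate_ids/sequences length mismatch")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"{self.gene_id}: sequences have unequal lengths {sorted(lengths)}")
        if lengths.pop() % 3 != 0:
            raise ValueError(f"{self.gene_id}: alignment length not divisible by 3")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])


@dataclass(frozen=True)
class ThetaEstimate:
    """Watterson-style synonymous diversity estimate for one gene.

    ``theta_s`` is NaN when ``L_syn == 0`` (estimate undefined; such genes
    are excluded downstream).
    """

    gene_id: str
    n: int
    S_syn: int
    L_syn: float
    theta_s: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.theta_s)


def harmonic_a(n: int) -> float:
    """Watterson's correction factor a_n = sum_{i=1}^{n-1} 1/i."""
    if n < 2:
        raise ValueError(f"need n >= 2 sequences, got {n}")
    return sum(1.0 / i for i in range(1, n))


def _filter_codon_columns(aln: CodonAlignment) -> list[str]:
    """Drop codon columns containing gaps or ambiguity codes in any sequence."""
    n_codons = aln.length // 3
    keep: list[int] = []
    valid = set(BASES)
    for j in range(n_codons):
        ok = True
        for seq in aln.sequences:
            codon = seq[3 * j : 3 * j + 3].upper()
            if any(b not in valid for b in codon):
                ok = False
                break
        if ok:
            keep.append(j)
    return ["".join(seq[3 * j : 3 * j + 3].upper() for j in keep) for seq in aln.sequences]


def count_segregating_synonymous_sites(aln: CodonAlignment) -> tuple[int, float]:
    """Count synonymous segregating nucleotide columns and synonymous sites.

    Returns ``(S_syn, L_syn)``.  A nucleotide column counts toward S_syn
    iff it is polymorphic and the codon containing it translates to the
    same amino acid in every sequence.  L_syn is the per-sequence
    synonymous-site count averaged over the alignment.
    """
    filtered = _filter_codon_columns(aln)
    n_codons = len(filtered[0]) // 3
    s_syn = 0
    for j in range(n_codons):
        codons = [seq[3 * j : 3 * j + 3] for seq in filtered]
        aas = {translate(c) for c in codons}
        if STOP in aas:
            # a terminal stop shared by all sequences is tolerated
            if j == n_codons - 1 and aas == {STOP}:
                continue
            raise ValueError(f"{aln.gene_id}: stop codon inside alignment at codon {j}")
        for k in range(3):
            column = {c[k] for c in codons}
            if len(column) > 1 and len(aas) == 1:
                s_syn += 1
    l_syn = float(np.mean([gene_synonymous_sites_fast(seq) for seq in filtered]))
    return s_syn, l_syn


def watterson_theta(S: int, n: int, L: float) -> float:
    """Watterson's estimator ``S / (a_n * L)``."""
    if S < 0:
        raise ValueError("S must be >= 0")
    if n < 2:
        raise ValueError(f"need n >= 2 sequences, got {n}")
    if L <= 0:
        raise ValueError(f"need L > 0 surveyed sites, got {L}")
    return S / harmonic_a(n) / L


def estimate_theta_s(aln: CodonAlignment) -> ThetaEstimate:
    """Estimate per-synonymous-site diversity for one gene alignment."""
    s_syn, l_syn = count_segregating_synonymous_sites(aln)
    if l_syn <= 0:
        theta = float("nan")
    else:
        theta = watterson_theta(s_syn, aln.n, l_syn)
    return ThetaEstimate(gene_id=aln.gene_id, n=aln.n, S_syn=s_syn, L_syn=l_syn, theta_s=theta)


# ---------------------------------------------------------------------------
# IO

def read_alignment_fasta(path: str | Path, gene_id: str | None = None) -> CodonAlignment:
    """Read one per-gene multi-FASTA alignment."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if gene_id is None:
        gene_id = path.stem
    return CodonAlignment(
        gene_id=gene_id,
        isolate_ids=tuple(r.id for r in records),
        sequences=tuple(str(r.seq).upper() for r in records),
    )


def estimate_directory(
    directory: str | Path,
    pattern: str = "*.fasta",
    exclude: Iterable[str] = (),
) -> pd.DataFrame:
    """Estimate theta_s for every per-gene alignment file in a directory.

    ``exclude`` is a set of gene ids to skip (e.g. pseudogenes or genes
    known to fail estimation upstream).
    """
    exclude = set(exclude)
    rows = []
    for path in sorted(Path(directory).glob(pattern)):
        if path.stem in exclude:
            continue
        est = estimate_theta_s(read_alignment_fasta(path))
        rows.append((est.gene_id, est.n, est.S_syn, est.L_syn, est.theta_s))
    return pd.DataFrame(rows, columns=["gene_id", "n", "S_syn", "L_syn", "theta_s"])


def write_theta_table(estimates: Sequence[ThetaEstimate] | pd.DataFrame, path: str | Path) -> None:
    if not isinstance(estimates, pd.DataFrame):
        estimates = pd.DataFrame(
            [(e.gene_id, e.n, e.S_syn, e.L_syn, e.theta_s) for e in estimates],
            columns=["gene_id", "n", "S_syn", "L_syn", "theta_s"],
        )
    estimates.to_csv(path, sep="\t", index=False)


def read_theta_table(path: str | Path) -> pd.DataFrame:
    """Read a theta table; accepts a full estimate table or (gene_id, theta_s)."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns or "theta_s" not in df.columns:
        raise ValueError(f"{path}: theta table needs 'gene_id' and 'theta_s' columns")
    return df
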