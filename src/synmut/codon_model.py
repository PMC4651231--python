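"""Genetic-code engine.

Codon translation under the bacterial code (NCBI translation table 11),
classification of single-base coding changes as synonymous / nonsynonymous /
nonsense, Nei–Gojobori fractional synonymous-site counting, and the six
strand-collapsed base-substitution spectrum classes.

Conventions
-----------
* Only the bacterial code is supported; ambiguity codes are rejected.
* Changes that create a stop codon count as *nonsynonymous* for site
  counting (so per-codon site totals equal 3 exactly) but are reported as
  the distinct ``NONSENSE`` effect category by :func:`classify_substitution`.
"""

from __future__ import annotations

import enum
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

__all__ = [
    "BASES",
    "STOP",
    "SubstitutionEffect",
    "SpectrumClass",
    "SPECTRUM_CLASSES",
    "translate",
    "classify_substitution",
    "synonymous_sites",
    "gene_synonymous_sites",
    "spectrum_class",
    "complement",
    "reverse_complement",
]

BASES = "ACGT"
STOP = "*"

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_FORWARD = dict(_TABLE11.forward_table)
STOP_CODONS = frozenset(_TABLE11.stop_codons)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class SubstitutionEffect(enum.Enum):
    """Effect of a single-base change within a coding sequence."""

    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    NONSENSE = "nonsense"


class SpectrumClass(enum.Enum):
    """Strand-collapsed base-substitution class.

    The two strand-complementary representations of a change (e.g. A→C on
    one strand is T→G on the other) map to the same class.  ``AT_to_GC``
    and ``CG_to_TA`` are transitions; the other four are transversions.
    """

    AT_to_GC = "AT_to_GC"
    CG_to_TA = "CG_to_TA"
    AT_to_CG = "AT_to_CG"
    AT_to_TA = "AT_to_TA"
    CG_to_AT = "CG_to_AT"
    CG_to_GC = "CG_to_GC"

    @property
    def kind(self) -> str:
        """``"transition"`` or ``"transversion"``."""
        if self in (SpectrumClass.AT_to_GC, SpectrumClass.CG_to_TA):
            return "transition"
        return "transversion"


SPECTRUM_CLASSES = tuple(SpectrumClass)

# genome-strand pair -> collapsed class
_SPECTRUM_MAP = {
    ("A", "G"): SpectrumClass.AT_to_GC,
    ("T", "C"): SpectrumClass.AT_to_GC,
    ("C", "T"): SpectrumClass.CG_to_TA,
    ("G", "A"): SpectrumClass.CG_to_TA,
    ("A", "C"): SpectrumClass.AT_to_CG,
    ("T", "G"): SpectrumClass.AT_to_CG,
    ("A", "T"): SpectrumClass.AT_to_TA,
    ("T", "A"): SpectrumClass.AT_to_TA,
    ("C", "A"): SpectrumClass.CG_to_AT,
    ("G", "T"): SpectrumClass.CG_to_AT,
    ("C", "G"): SpectrumClass.CG_to_GC,
    ("G", "C"): SpectrumClass.CG_to_GC,
}


def _check_codon(codon: str) -> str:
    if not isinstance(codon, str) or len(codon) != 3:
        raise ValueError(f"codon must be a 3-character string, got {codon!r}")
    codon = codon.upper()
    for b in codon:
        if b not in BASES:
            raise ValueError(f"invalid base {b!r} in codon {codon!r} (ambiguity codes rejected)")
    return codon


def complement(base: str) -> str:
    """Watson–Crick complement of a single base."""
    try:
        return _COMPLEMENT[base.upper()]
    except KeyError:
        raise ValueError(f"invalid base {base!r}") from None


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T only)."""
    return "".join(complement(b) for b in reversed(seq))


def translate(codon: str) -> str:
    """Translate a codon under the bacterial code.

    Returns the one-letter amino acid, or ``"*"`` for a stop codon.
    """
    codon = _check_codon(codon)
    if codon in STOP_CODONS:
        return STOP
    return _FORWARD[codon]


def classify_substitution(codon: str, position: int, alt_base: str) -> SubstitutionEffect:
    """Classify the single-base change ``codon[position-1] -> alt_base``.

    Parameters
    ----------
    codon : str
        Reference codon (must not be a stop codon).
    position : int
        Position within the codon, 1-based (1, 2 or 3).
    alt_base : str
        The alternative base; must differ from the reference base.
    """
    codon = _check_codon(codon)
    if codon in STOP_CODONS:
        raise ValueError(f"reference codon {codon} is a stop codon")
    if position not in (1, 2, 3):
        raise ValueError(f"position must be 1, 2 or 3, got {position}")
    alt_base = alt_base.upper()
    if alt_base not in BASES:
        raise ValueError(f"invalid alternative base {alt_base!r}")
    if alt_base == codon[position - 1]:
        raise ValueError(f"alternative base equals reference base at position {position} of {codon}")
    mutant = codon[: position - 1] + alt_base + codon[position:]
    if mutant in STOP_CODONS:
        return SubstitutionEffect.NONSENSE
    if _FORWARD[mutant] == _FORWARD[codon]:
        return SubstitutionEffect.SYNONYMOUS
    return SubstitutionEffect.NONSYNONYMOUS


@lru_cache(maxsize=64)
def synonymous_sites(codon: str) -> float:
    """Nei–Gojobori fractional count of synonymous sites in a codon.

    Each of the three positions contributes (number of synonymous
    single-base changes at that position) / 3.  Stop-creating changes
    count as nonsynonymous, so the synonymous and nonsynonymous site
    fractions of a codon always sum to 3.
    """
    codon = _check_codon(codon)
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no defined synonymous-site count")
    n_syn = 0
    for pos in (1, 2, 3):
        for alt in BASES:
            if alt == codon[pos - 1]:
                continue
            if classify_substitution(codon, pos, alt) is SubstitutionEffect.SYNONYMOUS:
                n_syn += 1
    return n_syn / 3.0


def gene_synonymous_sites(cds: str) -> float:
    """Sum of :func:`synonymous_sites` over the codons of a CDS.

    A terminal stop codon is tolerated and contributes zero sites
    (the conventional exclusion); an internal stop is a data error.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not divisible by 3")
    cds = cds.upper()
    total = 0.0
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            if i == n_codons - 1:
                continue
            raise ValueError(f"internal stop codon {codon} at codon index {i}")
        total += synonymous_sites(codon)
    return total


def spectrum_class(ref_base: str, alt_base: str) -> SpectrumClass:
    """Strand-collapsed spectrum class for a base substitution."""
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if ref_base not in BASES or alt_base not in BASES:
        raise ValueError(f"invalid base pair ({ref_base!r}, {alt_base!r})")
    if ref_base == alt_base:
        raise ValueError("reference and alternative bases are equal")
    return _SPECTRUM_MAP[(ref_base, alt_base)]


# ---------------------------------------------------------------------------
# vectorised helpers (base-4 codon encoding) used by the simulator and the
# diversity estimator on megabase-scale sequences

_BASE_INDEX = np.full(128, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_INDEX[ord(_b)] = _i

#: synonymous-site count per codon, indexed by 16*b0 + 4*b1 + b2; NaN for stops
SYN_SITES_BY_CODE = np.full(64, np.nan)
for _b0 in BASES:
    for _b1 in BASES:
        for _b2 in BASES:
            _c = _b0 + _b1 + _b2
            if _c not in STOP_CODONS:
                _code = 16 * _BASE_INDEX[ord(_b0)] + 4 * _BASE_INDEX[ord(_b1)] + _BASE_INDEX[ord(_b2)]
                SYN_SITES_BY_CODE[_code] = synonymous_sites(_c)


def encode_codons(cds: str) -> np.ndarray:
    """Encode a CDS as an array of base-4 codon codes (0..63)."""
    arr = _BASE_INDEX[np.frombuffer(cds.upper().encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = cds[int(np.argmax(arr < 0))]
        raise ValueError(f"invalid base {bad!r} in sequence")
    arr = arr.astype(np.int64).reshape(-1, 3)
    return 16 * arr[:, 0] + 4 * arr[:, 1] + arr[:, 2]


def gene_synonymous_sites_fast(cds: str) -> float:
    """Vectorised :func:`gene_synonymous_sites` (same semantics)."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not divisible by 3")
    codes = encode_codons(cds)
    sites = SYN_SITES_BY_CODE[codes]
    stops = np.isnan(sites)
    if stops.any():
        idx = int(np.argmax(stops))
        if idx != len(codes) - 1 or stops.sum() > 1:
            first_internal = idx if idx != len(codes) - 1 else int(np.argmax(stops[:-1]))
            raise ValueError(f"internal stop codon at codon index {first_internal}")
        sites = sites[:-1]
    return float(sites.sum())
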