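"""Standard nuclear genetic code and its degeneracy structure.

Every statistic in this package (RSCU, ENC, sENC-x, CAI) is defined on the
61 sense codons of the standard code and on the partition of the 20 amino
acids into synonymous-codon families of size k in {1, 2, 3, 4, 6}.  This
module holds those constants as the single source of truth.

Conventions
-----------
* Codons are DNA trinucleotides over ``ACGT`` (U is normalised to T at parse
  time) and are always ordered alphabetically, ``AAA`` .. ``TTT``; every
  64-vector and matrix column in the package follows this order.
* Amino acids use one-letter codes; stop is ``*``.
* Only the standard nuclear code is supported; bivalve CDS are nuclear
  throughout and alternative code tables are out of scope.
"""

from __future__ import annotations

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
STOP = "*"

#: All 64 codons in alphabetical order (the canonical vector order).
CODONS: tuple[str, ...] = tuple(
    a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES
)

#: Position of each codon in the canonical order.
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.stop_codons))  # TAA, TAG, TGA

#: codon -> one-letter amino acid, or ``*`` for the three stop codons.
CODON_TO_AA: dict[str, str] = {
    c: _STANDARD.forward_table.get(c, STOP) for c in CODONS
}

#: The 61 sense codons, alphabetical.
SENSE_CODONS: tuple[str, ...] = tuple(c for c in CODONS if CODON_TO_AA[c] != STOP)

#: The 20 amino acids, alphabetical by one-letter code.
AMINO_ACIDS: tuple[str, ...] = tuple(sorted({CODON_TO_AA[c] for c in SENSE_CODONS}))

#: amino acid -> its synonymous codons (alphabetical).
FAMILIES: dict[str, tuple[str, ...]] = {
    aa: tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa) for aa in AMINO_ACIDS
}

#: amino acid -> family size k.
FAMILY_SIZE: dict[str, int] = {aa: len(f) for aa, f in FAMILIES.items()}

#: The 18 amino acids with two or more synonymous codons.
DEGENERATE_AAS: tuple[str, ...] = tuple(
    aa for aa in AMINO_ACIDS if FAMILY_SIZE[aa] >= 2
)

#: Degeneracy class -> amino acids of that class (k = 2, 3, 4, 6).
FAMILY_CLASSES: dict[int, tuple[str, ...]] = {
    k: tuple(aa for aa in DEGENERATE_AAS if FAMILY_SIZE[aa] == k)
    for k in (2, 3, 4, 6)
}

#: Degeneracy class -> number of amino acids in it ({2: 9, 3: 1, 4: 5, 6: 3}).
CLASS_SIZES: dict[int, int] = {k: len(v) for k, v in FAMILY_CLASSES.items()}

#: Codons with no synonymous alternative (ATG/Met, TGG/Trp).
SINGLE_CODON_AAS: tuple[str, ...] = tuple(
    aa for aa in AMINO_ACIDS if FAMILY_SIZE[aa] == 1
)

#: The 59 informative codons: sense codons minus ATG, TGG (single-codon
#: amino acids carry no synonymous-choice information), alphabetical.
INFORMATIVE_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if FAMILY_SIZE[CODON_TO_AA[c]] >= 2
)


class AmbiguousCodonError(ValueError):
    """Raised when a codon contains a character outside ``ACGT`` (after
    normalisation).  Callers decide whether to skip or reject."""


def normalize_codon(codon: str) -> str:
    """Uppercase a codon and convert RNA-style U to T.

    Raises :class:`AmbiguousCodonError` if the result is not three
    characters over ``ACGT``.
    """
    c = codon.upper().replace("U", "T")
    if len(c) != 3 or any(ch not in NUCLEOTIDES for ch in c):
        raise AmbiguousCodonError(f"ambiguous codon: {codon!r}")
    return c


def translate(codon: str) -> str:
    """Standard-code assignment of a codon: one-letter amino acid or ``*``."""
    return CODON_TO_AA[normalize_codon(codon)]


def degeneracy_census() -> dict[int, int]:
    """Number of amino acids per degeneracy class.

    For the standard code this is ``{1: 2, 2: 9, 3: 1, 4: 5, 6: 3}``;
    the classes with k >= 2 cover the 18 degenerate amino acids and the
    class sizes weighted by k sum to the 61 sense codons.
    """
    census: dict[int, int] = {}
    for aa in AMINO_ACIDS:
        k = FAMILY_SIZE[aa]
        census[k] = census.get(k, 0) + 1
    return dict(sorted(census.items()))


def informative_codons() -> tuple[str, ...]:
    """The 59 codons used for cross-species RSCU comparison.

    Stops, ATG (Met) and TGG (Trp) are excluded: a codon whose amino acid
    has a single coding option cannot show synonymous preference.  Order is
    alphabetical, matching every other codon vector in the package.
    """
    return INFORMATIVE_CODONS
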