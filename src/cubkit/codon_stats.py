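"""Codon counting and descriptive statistics: frequencies, positional GC, RSCU.

The central container is :class:`CodonCountTable`, a 64-vector of codon
counts in the canonical alphabetical order, built either for a single gene
or pooled over a species' whole conserved-gene set.  Species-level RSCU and
GC statistics are computed from the pooled table ("summing codons over all
sequences"), never by averaging per-gene values.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genetic_code import (
    AMINO_ACIDS,
    CODONS,
    CODON_TO_AA,
    FAMILIES,
    FAMILY_SIZE,
    SENSE_CODONS,
    STOP,
    STOP_CODONS,
)

# byte -> base index (A=0, C=1, G=2, T=3); -1 for anything else.
_BYTE_TO_BASE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BYTE_TO_BASE[_b] = _i

_STOP_IDX = np.array([CODONS.index(c) for c in STOP_CODONS])
_SENSE_MASK = np.array([CODON_TO_AA[c] != STOP for c in CODONS])
# 64 x 3 indicator: codon has G or C at position p.
_GC_AT_POS = np.array([[ch in "GC" for ch in c] for c in CODONS])


def codon_indices(nucleotides: str) -> np.ndarray:
    """Map an in-frame nucleotide string to canonical codon indices.

    Returns an int array of length len(seq)/3; codons containing a
    non-ACGT character map to -1.  The sequence length must be a multiple
    of three.
    """
    arr = _BYTE_TO_BASE[np.frombuffer(nucleotides.encode("ascii"), dtype=np.uint8)]
    if arr.size % 3:
        raise ValueError("sequence length is not a multiple of 3")
    trip = arr.reshape(-1, 3).astype(np.int64)
    idx = trip[:, 0] * 16 + trip[:, 1] * 4 + trip[:, 2]
    idx[(trip < 0).any(axis=1)] = -1
    return idx


@dataclass(frozen=True)
class CodingSequence:
    """A validated in-frame coding sequence.

    ``length_codons`` counts the codons that enter statistics, i.e. it
    excludes a terminal stop codon if one is present in ``nucleotides``.
    """

    id: str
    species: str
    nucleotides: str
    length_codons: int


@dataclass
class CodonCountTable:
    """64-entry codon counts for a gene or a pooled species set.

    ``scope`` is ``"gene"`` or ``"species-pooled"``.  ``skipped_ambiguous``
    tallies codons dropped because they contained non-ACGT characters.
    Stop-codon entries are zero for validated CDS (terminal stops are
    excluded by convention; internal stops invalidate the sequence).
    """

    counts: np.ndarray
    scope: str = "gene"
    skipped_ambiguous: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (64,):
            raise ValueError("counts must be a 64-vector in canonical codon order")
        if (self.counts < 0).any():
            raise ValueError("negative codon count")

    @property
    def n_codons(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_dict(
        cls, counts: dict[str, int], scope: str = "gene"
    ) -> "CodonCountTable":
        vec = np.zeros(64, dtype=np.int64)
        for codon, n in counts.items():
            vec[CODONS.index(codon.upper().replace("U", "T"))] = n
        return cls(vec, scope=scope)

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CODONS), name="count")

    def family_counts(self, aa: str) -> np.ndarray:
        """Counts of the synonymous codons of ``aa`` (alphabetical order)."""
        return self.counts[[CODONS.index(c) for c in FAMILIES[aa]]]


@dataclass(frozen=True)
class RscuVector:
    """Relative synonymous codon usage for one count table.

    ``values`` holds RSCU for every sense codon of every amino acid that is
    present; codons of absent amino acids are *not* included (RSCU is
    undefined there, and reporting 0 would fake "avoided" status) —
    their amino acids are listed in ``undefined_aas``.
    """

    values: dict[str, float]
    undefined_aas: frozenset[str] = field(default_factory=frozenset)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, name="rscu")


def count_codons(
    seqs: Iterable[CodingSequence], scope: str = "species-pooled"
) -> CodonCountTable:
    """Count every non-terminal codon over a collection of validated CDS.

    Pooling is plain addition over sequences.  A terminal stop codon is
    excluded; an internal stop or a frame violation raises ``ValueError``
    (such sequences should have been rejected by
    :func:`cubkit.dataset_prep.validate_cds`).  Codons containing
    non-ACGT characters are skipped and tallied in ``skipped_ambiguous``.
    """
    total = np.zeros(64, dtype=np.int64)
    skipped = 0
    for seq in seqs:
        idx = codon_indices(seq.nucleotides)
        if idx.size and idx[-1] in _STOP_IDX:
            idx = idx[:-1]
        if np.isin(idx, _STOP_IDX).any():
            raise ValueError(f"internal stop codon in unvalidated sequence {seq.id!r}")
        skipped += int((idx == -1).sum())
        idx = idx[idx >= 0]
        total += np.bincount(idx, minlength=64)
    return CodonCountTable(total, scope=scope, skipped_ambiguous=skipped)


def counts_matrix(seqs: Iterable[CodingSequence]) -> np.ndarray:
    """Per-gene codon counts as a (n_genes, 64) matrix (same conventions as
    :func:`count_codons`, ambiguous codons silently skipped)."""
    rows = []
    for seq in seqs:
        idx = codon_indices(seq.nucleotides)
        if idx.size and idx[-1] in _STOP_IDX:
            idx = idx[:-1]
        idx = idx[idx >= 0]
        rows.append(np.bincount(idx, minlength=64))
    if not rows:
        return np.zeros((0, 64), dtype=np.int64)
    return np.asarray(rows, dtype=np.int64)


def codon_frequencies(t: CodonCountTable) -> pd.DataFrame:
    """Codon frequency table in the style of EMBOSS ``cusp``.

    Columns: ``amino_acid``, ``count``, ``fraction`` (share within the
    codon's synonymous family; NaN for amino acids with zero counts) and
    ``per_thousand`` (usage per 1000 counted codons).  Rows cover the 61
    sense codons in alphabetical order.
    """
    if t.n_codons == 0:
        raise ValueError("empty table: no counted codons")
    records = []
    for aa in AMINO_ACIDS:
        fam = FAMILIES[aa]
        fam_counts = t.family_counts(aa)
        fam_total = fam_counts.sum()
        for codon, n in zip(fam, fam_counts):
            frac = n / fam_total if fam_total > 0 else np.nan
            records.append(
                {
                    "codon": codon,
                    "amino_acid": aa,
                    "count": int(n),
                    "fraction": frac,
                    "per_thousand": 1000.0 * n / t.n_codons,
                }
            )
    df = pd.DataFrame.from_records(records).set_index("codon")
    return df.loc[list(SENSE_CODONS)]


def gc_by_position(t: CodonCountTable) -> tuple[float, float, float]:
    """Count-weighted G+C fraction at codon positions 1, 2 and 3.

    Computed over sense codons only (stop counts are zero for validated
    input anyway).  Includes ATG and TGG at every position, matching the
    EMBOSS ``cusp`` convention, so GC3 is not restricted to degenerate
    sites.
    """
    if t.n_codons == 0:
        raise ValueError("empty table: no counted codons")
    counts = np.where(_SENSE_MASK, t.counts, 0)
    gc = counts @ _GC_AT_POS / counts.sum()
    return float(gc[0]), float(gc[1]), float(gc[2])


def gc3_per_gene(matrix: np.ndarray) -> np.ndarray:
    """Vectorised GC3 over a (n_genes, 64) count matrix; NaN for empty rows."""
    counts = np.where(_SENSE_MASK[None, :], matrix, 0).astype(float)
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        gc3 = counts @ _GC_AT_POS[:, 2] / totals
    gc3[totals == 0] = np.nan
    return gc3


def rscu(t: CodonCountTable) -> RscuVector:
    """RSCU_ij = k_i * x_ij / sum_j x_ij (Sharp-style).

    A codon's RSCU is its observed count relative to the expectation under
    uniform synonymous usage, so 1 means no bias and values sum to the
    family size k within each amino acid.  Amino acids with zero total
    count are reported in ``undefined_aas`` rather than given RSCU 0.
    """
    if t.n_codons == 0:
        raise ValueError("empty table: no counted codons")
    values: dict[str, float] = {}
    undefined: set[str] = set()
    for aa in AMINO_ACIDS:
        fam = FAMILIES[aa]
        fam_counts = t.family_counts(aa)
        total = fam_counts.sum()
        if total == 0:
            undefined.add(aa)
            continue
        k = FAMILY_SIZE[aa]
        for codon, n in zip(fam, fam_counts):
            values[codon] = k * n / total
    return RscuVector(values=values, undefined_aas=frozenset(undefined))


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (record id, sequence string) from a FASTA file, gzip-transparent."""
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as handle:
            yield from ((r.id, str(r.seq)) for r in SeqIO.parse(handle, "fasta"))
    else:
        with open(path) as handle:
            yield from ((r.id, str(r.seq)) for r in SeqIO.parse(handle, "fasta"))


def write_codon_frequencies(t: CodonCountTable, path: str | Path) -> None:
    """cusp-compatible TSV: codon, amino_acid, fraction, per_thousand, count."""
    df = codon_frequencies(t).reset_index()
    df = df[["codon", "amino_acid", "fraction", "per_thousand", "count"]]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_rscu(vec: RscuVector, path: str | Path) -> None:
    """Per-species RSCU TSV: codon, amino_acid, rscu (undefined codons omitted)."""
    rows = [
        {"codon": c, "amino_acid": CODON_TO_AA[c], "rscu": vec.values[c]}
        for c in SENSE_CODONS
        if c in vec.values
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
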