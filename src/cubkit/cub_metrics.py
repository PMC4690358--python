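"""Codon usage bias metrics: Wright's ENC, per-amino-acid sENC-x, CAI, TPM.

ENC (effective number of codons) measures how far synonymous usage departs
from uniform.  For each degenerate amino acid the codon "homozygosity" F is
estimated — in ``counts`` mode with Wright's small-sample correction

    F_hat = (n * sum_i p_i**2 - 1) / (n - 1)

(n = amino-acid count, p_i = within-family codon proportions), in
``frequencies`` mode as the uncorrected sum of squared proportions.  Class
averages F_bar_k over the 9 two-fold, 1 three-fold, 5 four-fold and 3
six-fold amino acids then compose

    ENC = 2 + 9/F_bar_2 + 1/F_bar_3 + 5/F_bar_4 + 3/F_bar_6

which is 61 when all sense codons are used equally and 20 when a single
codon serves each amino acid.  The estimator can exceed 61 on near-uniform
counts, so results are capped into [1, 61].

sENC-x rescales the per-amino-acid effective codon number ENC_x = 1/F to
[0, 1] independently of family size: sENC-x = (k - ENC_x) / (k - 1), so 0
means no bias and 1 maximal bias, comparable across degeneracy classes.

CAI is the geometric mean over a gene's codons of relative-adaptiveness
weights w_ij = RSCU_ij / max_j RSCU_ij derived from a reference set of
highly expressed genes; ATG, TGG and stops are excluded from the mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codon_stats import CodonCountTable, rscu as _rscu
from .genetic_code import (
    AMINO_ACIDS,
    CLASS_SIZES,
    CODON_INDEX,
    CODON_TO_AA,
    DEGENERATE_AAS,
    FAMILIES,
    FAMILY_SIZE,
    SENSE_CODONS,
)

_CLASS_KS = (2, 3, 4, 6)
_CLASS_N = np.array([CLASS_SIZES[k] for k in _CLASS_KS], dtype=float)  # 9,1,5,3
_FAMILY_COLS = {aa: [CODON_INDEX[c] for c in FAMILIES[aa]] for aa in DEGENERATE_AAS}
_AA_CLASS_COL = {aa: _CLASS_KS.index(FAMILY_SIZE[aa]) for aa in DEGENERATE_AAS}

# codons entering the CAI geometric mean: sense minus ATG/TGG
_CAI_CODONS = tuple(c for c in SENSE_CODONS if FAMILY_SIZE[CODON_TO_AA[c]] >= 2)


class InsufficientDataError(ValueError):
    """A synonymous family has too little data for a usable homozygosity."""


@dataclass(frozen=True)
class EncResult:
    enc: float
    family_means: dict[int, float]
    missing_families: frozenset[int]
    mode: str


@dataclass(frozen=True)
class SencXVector:
    """Scaled per-amino-acid bias intensity, 0 (none) to 1 (maximal)."""

    values: dict[str, float]
    mode: str


@dataclass(frozen=True)
class CaiWeights:
    """Relative adaptiveness w per sense codon; family maxima are 1 and every
    w is strictly positive (zero reference counts get a pseudocount)."""

    w: dict[str, float]
    reference_n: int


def family_homozygosity(t: CodonCountTable, aa: str, mode: str = "counts") -> float:
    """Codon homozygosity F for one degenerate amino acid.

    ``counts`` mode applies Wright's small-sample correction and requires
    n >= 2; a corrected F <= 0 is unusable.  ``frequencies`` mode is the
    plain sum of squared proportions.  Raises
    :class:`InsufficientDataError` when the family must be treated as
    missing.
    """
    if aa not in DEGENERATE_AAS:
        raise ValueError(f"{aa!r} is not a degenerate amino acid")
    if mode not in ("counts", "frequencies"):
        raise ValueError(f"unknown mode {mode!r}")
    fam_counts = t.family_counts(aa).astype(float)
    n = fam_counts.sum()
    if n == 0:
        raise InsufficientDataError(f"no codons observed for {aa}")
    p2 = float(((fam_counts / n) ** 2).sum())
    if mode == "frequencies":
        return p2
    if n < 2:
        raise InsufficientDataError(f"n={int(n)} < 2 for {aa} in counts mode")
    f_hat = (n * p2 - 1.0) / (n - 1.0)
    if f_hat <= 0:
        raise InsufficientDataError(f"corrected homozygosity <= 0 for {aa}")
    return f_hat


def enc(t: CodonCountTable, mode: str = "counts") -> EncResult:
    """Wright's effective number of codons for a count table.

    Missing-class policy: if the three-fold class (Ile) lacks usable data
    but the two- and four-fold classes do not, F_bar_3 is imputed as their
    mean (Wright's remedy); any other missing class drops its term and the
    composition is rescaled to the 20-amino-acid total.  The result is
    capped into [1, 61].
    """
    if t.n_codons == 0:
        raise ValueError("empty table: no counted codons")
    per_class: dict[int, list[float]] = {k: [] for k in _CLASS_KS}
    for aa in DEGENERATE_AAS:
        try:
            per_class[FAMILY_SIZE[aa]].append(family_homozygosity(t, aa, mode))
        except InsufficientDataError:
            continue
    family_means = {k: float(np.mean(v)) for k, v in per_class.items() if v}
    missing = frozenset(k for k in _CLASS_KS if k not in family_means)
    if len(missing) == 4:
        raise ValueError("ENC undefined: no degenerate family has usable data")
    if 3 in missing and 2 in family_means and 4 in family_means:
        family_means[3] = (family_means[2] + family_means[4]) / 2.0
    base = 2.0 + sum(CLASS_SIZES[k] / f for k, f in family_means.items())
    n_aa_used = 2 + sum(CLASS_SIZES[k] for k in family_means)
    value = base if n_aa_used == 20 else base * 20.0 / n_aa_used
    value = float(np.clip(value, 1.0, 61.0))
    return EncResult(enc=value, family_means=family_means, missing_families=missing, mode=mode)


def enc_per_gene(matrix: np.ndarray, mode: str = "counts") -> np.ndarray:
    """Vectorised ENC over a (n_genes, 64) count matrix.

    Applies the same missing-class rules as :func:`enc`; rows where no
    degenerate family is usable yield NaN.
    """
    m = np.asarray(matrix, dtype=float)
    n_genes = m.shape[0]
    f_aa = np.full((n_genes, len(DEGENERATE_AAS)), np.nan)
    for j, aa in enumerate(DEGENERATE_AAS):
        sub = m[:, _FAMILY_COLS[aa]]
        n = sub.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p2 = (sub**2).sum(axis=1) / n**2
            if mode == "frequencies":
                f = np.where(n > 0, p2, np.nan)
            else:
                f = np.where(n >= 2, (n * p2 - 1.0) / (n - 1.0), np.nan)
                f = np.where(f > 0, f, np.nan)
        f_aa[:, j] = f
    fbar = np.full((n_genes, 4), np.nan)
    for col, k in enumerate(_CLASS_KS):
        cols = [j for j, aa in enumerate(DEGENERATE_AAS) if _AA_CLASS_COL[aa] == col]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            fbar[:, col] = np.nanmean(f_aa[:, cols], axis=1)
    # Ile imputation where classes 2 and 4 are available
    impute = np.isnan(fbar[:, 1]) & ~np.isnan(fbar[:, 0]) & ~np.isnan(fbar[:, 2])
    fbar[impute, 1] = (fbar[impute, 0] + fbar[impute, 2]) / 2.0
    present = ~np.isnan(fbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        base = 2.0 + np.nansum(_CLASS_N[None, :] / fbar, axis=1)
    n_aa_used = 2 + (present * _CLASS_N[None, :]).sum(axis=1)
    value = base * 20.0 / n_aa_used
    value[~present.any(axis=1)] = np.nan
    return np.clip(value, 1.0, 61.0)


def senc_x(t: CodonCountTable, mode: str = "counts") -> SencXVector:
    """Scaled per-amino-acid effective codon number.

    For each degenerate amino acid with usable homozygosity F, the
    amino-acid-level effective number ENC_x = 1/F (clipped into [1, k]) is
    rescaled to sENC-x = (k - ENC_x)/(k - 1), so 0 marks uniform usage and
    1 a single codon.  Families without usable data are absent from the
    result.
    """
    values: dict[str, float] = {}
    for aa in DEGENERATE_AAS:
        try:
            f = family_homozygosity(t, aa, mode)
        except InsufficientDataError:
            continue
        k = FAMILY_SIZE[aa]
        enc_x = float(np.clip(1.0 / f, 1.0, k))
        values[aa] = (k - enc_x) / (k - 1)
    return SencXVector(values=values, mode=mode)


def tpm(counts: np.ndarray | Sequence[float], lengths: np.ndarray | Sequence[float]) -> np.ndarray:
    """Transcripts per million from read counts and effective lengths (nt).

    TPM_i = 1e6 * (c_i / l_i) / sum_j (c_j / l_j); the vector sums to 1e6.
    """
    c = np.asarray(counts, dtype=float)
    l = np.asarray(lengths, dtype=float)
    if (l <= 0).any():
        raise ValueError("effective lengths must be positive")
    rate = c / l
    total = rate.sum()
    if total == 0:
        raise ValueError("all-zero read counts")
    return 1e6 * rate / total


@dataclass
class ExpressionTable:
    """Gene x library read counts with effective lengths.

    ``counts`` is a genes x libraries DataFrame; ``lengths`` a per-gene
    Series of effective lengths in nucleotides, aligned on gene id.
    """

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            raise ValueError("every gene needs an effective length")

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    def tpm(self) -> pd.DataFrame:
        """Per-library TPM; each column sums to 1e6."""
        out = {
            lib: tpm(self.counts[lib].to_numpy(), self.lengths.to_numpy())
            for lib in self.counts.columns
        }
        return pd.DataFrame(out, index=self.counts.index)

    def mean_tpm(self) -> pd.Series:
        """Unweighted arithmetic mean of per-library TPM per gene."""
        return self.tpm().mean(axis=1).rename("mean_tpm")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionTable":
        """Read the long-format dialect: gene_id, library_id, read_count,
        effective_length_nt."""
        df = pd.read_csv(path, sep="\t")
        counts = df.pivot(index="gene_id", columns="library_id", values="read_count")
        lengths = df.groupby("gene_id")["effective_length_nt"].first()
        return cls(counts=counts, lengths=lengths)

    def to_tsv(self, path: str | Path) -> None:
        rows = self.counts.stack().rename("read_count").reset_index()
        rows.columns = ["gene_id", "library_id", "read_count"]
        rows["effective_length_nt"] = rows["gene_id"].map(self.lengths)
        rows.to_csv(path, sep="\t", index=False)


def cai_weights(reference: CodonCountTable, pseudocount: float = 0.5) -> CaiWeights:
    """Relative adaptiveness weights from a reference (highly expressed) pool.

    Zero-count codons in an otherwise observed family receive
    ``pseudocount`` before the RSCU ratio so no weight is exactly zero.
    Amino acids entirely absent from the reference get all weights 1 with a
    warning (they carry no information).
    """
    w: dict[str, float] = {}
    for aa in AMINO_ACIDS:
        fam = FAMILIES[aa]
        counts = reference.family_counts(aa).astype(float)
        if counts.sum() == 0:
            warnings.warn(
                f"amino acid {aa} absent from CAI reference; weights set to 1",
                stacklevel=2,
            )
            for c in fam:
                w[c] = 1.0
            continue
        counts = np.where(counts == 0, pseudocount, counts)
        rel = counts / counts.max()  # == RSCU ratio within the family
        for c, v in zip(fam, rel):
            w[c] = float(v)
    return CaiWeights(w=w, reference_n=reference.n_codons)


def cai(gene: CodonCountTable, weights: CaiWeights) -> float:
    """Codon adaptation index of one gene under given weights.

    Geometric mean of w over the gene's codons, excluding ATG, TGG and
    stops: CAI = exp(sum_c x_c ln w_c / sum_c x_c), in (0, 1].
    """
    x = np.array([gene.counts[CODON_INDEX[c]] for c in _CAI_CODONS], dtype=float)
    total = x.sum()
    if total == 0:
        raise ValueError("no countable codons for CAI")
    logw = np.log([weights.w[c] for c in _CAI_CODONS])
    return float(np.exp((x @ logw) / total))


def cai_per_gene(matrix: np.ndarray, weights: CaiWeights) -> np.ndarray:
    """Vectorised CAI over a (n_genes, 64) count matrix; NaN where a gene has
    no countable codons."""
    cols = [CODON_INDEX[c] for c in _CAI_CODONS]
    x = np.asarray(matrix, dtype=float)[:, cols]
    logw = np.log([weights.w[c] for c in _CAI_CODONS])
    totals = x.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.exp((x @ logw) / totals)
    out[totals == 0] = np.nan
    return out


def preferred_codons(vec) -> tuple[frozenset[str], frozenset[str]]:
    """Split codons with defined RSCU into preferred (RSCU > 1) and avoided
    (RSCU < 1); RSCU exactly 1 is neither."""
    preferred = frozenset(c for c, v in vec.values.items() if v > 1)
    avoided = frozenset(c for c, v in vec.values.items() if v < 1)
    return preferred, avoided


def species_rscu(t: CodonCountTable):
    """Species-level RSCU from the pooled count table (re-export for
    discoverability)."""
    return _rscu(t)
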