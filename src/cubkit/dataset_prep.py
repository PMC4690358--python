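"""Input validation, quality filtering and CAI reference-set selection.

Mirrors the preparation applied to the bivalve transcriptome study design:
only in-frame ORFs strictly longer than 100 codons enter the statistics,
and a species is retained only if it recovers at least 25% of the
conserved-gene backbone with a mean recovered length above 500 nt.  The
CAI reference set is the 50 conserved genes with the highest mean TPM
across the provided RNA-seq libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .codon_stats import CodingSequence, codon_indices, _STOP_IDX
from .cub_metrics import ExpressionTable


@dataclass(frozen=True)
class Rejection:
    """A sequence that failed CDS validation, with a machine-readable reason
    (``frame``, ``internal_stop`` or ``too_short``)."""

    id: str
    species: str
    reason: str


def validate_cds(id: str, species: str, raw: str) -> CodingSequence | Rejection:
    """Normalise and frame-check a raw sequence.

    Normalisation uppercases, strips whitespace and converts U to T; it is
    idempotent.  A sequence is accepted iff its length is a multiple of 3,
    it contains no internal stop codon and it has at least one sense codon.
    A terminal stop codon is tolerated and excluded from ``length_codons``.
    Non-ACGT codons do not invalidate a sequence; they are skipped later at
    counting time.
    """
    seq = "".join(raw.split()).upper().replace("U", "T")
    if len(seq) % 3 != 0 or len(seq) == 0:
        return Rejection(id=id, species=species, reason="frame")
    idx = codon_indices(seq)
    has_terminal_stop = idx[-1] in _STOP_IDX
    interior = idx[:-1] if has_terminal_stop else idx
    if np.isin(interior, _STOP_IDX).any():
        return Rejection(id=id, species=species, reason="internal_stop")
    n_sense = int(((interior >= 0) & ~np.isin(interior, _STOP_IDX)).sum())
    if n_sense == 0:
        return Rejection(id=id, species=species, reason="too_short")
    return CodingSequence(
        id=id, species=species, nucleotides=seq, length_codons=len(interior)
    )


def validate_many(
    records: Iterable[tuple[str, str]], species: str
) -> tuple[list[CodingSequence], list[Rejection]]:
    """Validate (id, sequence) records; returns (accepted, rejected)."""
    accepted: list[CodingSequence] = []
    rejected: list[Rejection] = []
    for rec_id, seq in records:
        out = validate_cds(rec_id, species, seq)
        (accepted if isinstance(out, CodingSequence) else rejected).append(out)
    return accepted, rejected


def filter_orfs(
    seqs: Iterable[CodingSequence], min_codons: int = 100
) -> list[CodingSequence]:
    """Keep ORFs strictly longer than ``min_codons`` codons (a 100-codon ORF
    is dropped under the default)."""
    return [s for s in seqs if s.length_codons > min_codons]


@dataclass
class OrthologTable:
    """Species x conserved-gene presence/length inventory.

    ``table`` is long-format with columns ``gene_id``, ``species``,
    ``length_nt``; ``conserved_gene_ids`` is the full gene backbone the
    species are measured against (a stand-in for the study's
    2,846-conserved-gene selection).  ``metadata`` records provenance of
    the upstream orthology search (e.g. aligner thresholds); the search
    itself is consumed, not re-run.
    """

    conserved_gene_ids: list[str]
    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"gene_id", "species", "length_nt"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"ortholog table needs columns {sorted(required)}")
        if (self.table["length_nt"] <= 0).any():
            raise ValueError("ortholog lengths must be positive")
        unknown = set(self.table["gene_id"]) - set(self.conserved_gene_ids)
        if unknown:
            raise ValueError(
                f"{len(unknown)} gene ids outside the conserved backbone"
            )

    @property
    def species(self) -> list[str]:
        return sorted(self.table["species"].unique())

    def present_genes(self, species: str) -> list[str]:
        return self.table.loc[self.table["species"] == species, "gene_id"].tolist()

    @classmethod
    def from_tsv(cls, path: str | Path, conserved_gene_ids: Sequence[str] | None = None) -> "OrthologTable":
        df = pd.read_csv(path, sep="\t")
        ids = list(conserved_gene_ids) if conserved_gene_ids is not None else sorted(df["gene_id"].unique())
        return cls(conserved_gene_ids=ids, table=df)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class QualityReport:
    species: str
    fraction_recovered: float
    mean_length_nt: float
    passed: bool
    reasons: tuple[str, ...]


def species_quality_filter(
    t: OrthologTable,
    min_coverage: float = 0.25,
    min_avg_len: float = 500.0,
) -> list[QualityReport]:
    """Apply the species quality criteria to an ortholog inventory.

    A species passes iff it recovers at least ``min_coverage`` of the
    conserved backbone (inclusive) and its recovered sequences average
    strictly more than ``min_avg_len`` nucleotides.  One report per species,
    ordered by species name.
    """
    if not t.conserved_gene_ids:
        raise ValueError("empty conserved gene backbone")
    n_backbone = len(t.conserved_gene_ids)
    reports: list[QualityReport] = []
    for species, sub in sorted(t.table.groupby("species")):
        frac = sub["gene_id"].nunique() / n_backbone
        mean_len = float(sub["length_nt"].mean())
        reasons = []
        if frac < min_coverage:
            reasons.append("coverage")
        if not mean_len > min_avg_len:
            reasons.append("length")
        reports.append(
            QualityReport(
                species=species,
                fraction_recovered=frac,
                mean_length_nt=mean_len,
                passed=not reasons,
                reasons=tuple(reasons),
            )
        )
    return reports


def quality_report_frame(reports: Sequence[QualityReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": r.species,
                "fraction_recovered": r.fraction_recovered,
                "mean_length_nt": r.mean_length_nt,
                "passed": r.passed,
                "reasons": ";".join(r.reasons),
            }
            for r in reports
        ]
    )


def select_reference_set(
    e: ExpressionTable, conserved_ids: Sequence[str], n: int = 50
) -> list[str]:
    """Pick the CAI reference genes: the ``n`` conserved genes with the
    highest mean TPM across the expression libraries.

    Genes outside ``conserved_ids`` are ineligible regardless of
    expression.  Ties are broken lexicographically by gene id.  Raises
    ``ValueError`` if fewer than ``n`` candidates exist.
    """
    mean_tpm = e.mean_tpm()
    candidates = mean_tpm[mean_tpm.index.isin(set(conserved_ids))]
    if len(candidates) < n:
        raise ValueError(
            f"only {len(candidates)} conserved genes with expression; need {n}"
        )
    ranked = candidates.to_frame().reset_index()
    ranked.columns = ["gene_id", "mean_tpm"]
    ranked = ranked.sort_values(["mean_tpm", "gene_id"], ascending=[False, True])
    return ranked["gene_id"].head(n).tolist()
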