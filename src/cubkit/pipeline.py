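"""End-to-end orchestration: validate -> filter -> statistics -> clustering
-> correlations, with TSV/Newick outputs and a provenance log.

The pipeline reads per-species CDS FASTA, an ortholog inventory TSV and an
expression TSV for a reference species, applies the quality filters, and
writes every table the comparative analyses produce.  All numeric TSVs are
written with 6-significant-digit formatting so reruns are byte-stable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import codon_stats, comparative, cub_metrics, dataset_prep
from .codon_stats import CodonCountTable
from .genetic_code import DEGENERATE_AAS

logger = logging.getLogger("cubkit")

_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Pipeline configuration; thresholds default to the study criteria."""

    fasta_dir: str
    ortholog_tsv: str
    expression_tsv: str | None = None
    reference_species: str | None = None
    outdir: str = "cubkit_out"
    min_codons: int = 100
    min_coverage: float = 0.25
    min_avg_len: float = 500.0
    reference_n: int = 50
    alpha: float = 0.05
    enc_mode: str = "counts"
    linkage: str = "complete"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.min_codons, self.reference_n) <= 0 or self.min_coverage <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class SpeciesStats:
    """Per-species intermediate results carried between stages."""

    name: str
    pooled: CodonCountTable
    gene_ids: list[str]
    counts_matrix: np.ndarray
    rscu: codon_stats.RscuVector
    enc: float
    gc: tuple[float, float, float]


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> Path:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index)
    return path


def run_pipeline(
    cfg: RunConfig, stages: set[str] = frozenset({"stats", "cluster", "correlate"})
) -> dict:
    """Execute the pipeline; returns a dict of in-memory results and paths.

    Any stage failure propagates with the stage recorded in the log.  A
    rerun with the same config and inputs overwrites deterministically.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance: dict = {"config": asdict(cfg), "stages": sorted(stages), "counts": {}}
    results: dict = {"outdir": outdir, "provenance": provenance}

    # --- preparation: quality filter over the ortholog inventory
    ortho = dataset_prep.OrthologTable.from_tsv(cfg.ortholog_tsv)
    reports = dataset_prep.species_quality_filter(
        ortho, min_coverage=cfg.min_coverage, min_avg_len=cfg.min_avg_len
    )
    report_df = dataset_prep.quality_report_frame(reports)
    _write(report_df, outdir / "quality_report.tsv", index=False)
    passing = [r.species for r in reports if r.passed]
    provenance["counts"]["species_total"] = len(reports)
    provenance["counts"]["species_passing"] = len(passing)
    logger.info("quality filter: %d/%d species pass", len(passing), len(reports))
    results["quality_reports"] = reports

    # --- per-species validation, ORF filter, counting
    stats: dict[str, SpeciesStats] = {}
    validation_counts = {}
    for sp in passing:
        fasta = Path(cfg.fasta_dir) / f"{sp}.fasta"
        accepted, rejected = dataset_prep.validate_many(
            codon_stats.read_fasta(fasta), species=sp
        )
        kept = dataset_prep.filter_orfs(accepted, min_codons=cfg.min_codons)
        conserved = set(ortho.present_genes(sp))
        kept = [s for s in kept if s.id in conserved]
        validation_counts[sp] = {
            "read": len(accepted) + len(rejected),
            "valid": len(accepted),
            "kept": len(kept),
        }
        if not kept:
            logger.warning("species %s has no usable CDS; skipped", sp)
            continue
        pooled = codon_stats.count_codons(kept, scope="species-pooled")
        matrix = codon_stats.counts_matrix(kept)
        stats[sp] = SpeciesStats(
            name=sp,
            pooled=pooled,
            gene_ids=[s.id for s in kept],
            counts_matrix=matrix,
            rscu=codon_stats.rscu(pooled),
            enc=cub_metrics.enc(pooled, mode=cfg.enc_mode).enc,
            gc=codon_stats.gc_by_position(pooled),
        )
    provenance["counts"]["validation"] = validation_counts
    results["species_stats"] = stats
    if not stats:
        raise RuntimeError("stage stats: no species with usable sequences")

    # --- species-level metric tables
    species_df = pd.DataFrame(
        {
            "species": sp,
            "enc": s.enc,
            "gc1": s.gc[0],
            "gc2": s.gc[1],
            "gc3": s.gc[2],
            "n_genes": len(s.gene_ids),
            "n_codons": s.pooled.n_codons,
        }
        for sp, s in sorted(stats.items())
    ).set_index("species")
    _write(species_df, outdir / "species_metrics.tsv")
    results["species_metrics"] = species_df

    senc_df = pd.DataFrame(
        {sp: cub_metrics.senc_x(s.pooled, mode=cfg.enc_mode).values for sp, s in sorted(stats.items())}
    ).T.reindex(columns=list(DEGENERATE_AAS))
    senc_df.index.name = "species"
    _write(senc_df, outdir / "senc_x.tsv")
    results["senc_x"] = senc_df

    rscu_matrix_df = pd.DataFrame(
        {sp: s.rscu.as_series() for sp, s in sorted(stats.items())}
    ).T
    rscu_matrix_df.index.name = "species"
    _write(rscu_matrix_df, outdir / "rscu_matrix.tsv")

    # --- CAI: reference set from the reference species' expression
    gene_df = None
    expression = None
    if cfg.expression_tsv is not None:
        ref_sp = cfg.reference_species or sorted(stats)[0]
        if ref_sp not in stats:
            raise RuntimeError(f"stage stats: reference species {ref_sp!r} unavailable")
        expression = cub_metrics.ExpressionTable.from_tsv(cfg.expression_tsv)
        reference_ids = dataset_prep.select_reference_set(
            expression, ortho.conserved_gene_ids, n=cfg.reference_n
        )
        results["reference_set"] = reference_ids
        mean_tpm = expression.mean_tpm()
        tpm_by_lib = expression.tpm()

        frames = []
        for sp, s in sorted(stats.items()):
            # per-species weights from that species' own orthologs of the
            # reference genes
            ref_rows = [i for i, g in enumerate(s.gene_ids) if g in set(reference_ids)]
            if not ref_rows:
                logger.warning("species %s recovers no reference orthologs; CAI skipped", sp)
                continue
            ref_pool = CodonCountTable(
                s.counts_matrix[ref_rows].sum(axis=0), scope="species-pooled"
            )
            weights = cub_metrics.cai_weights(ref_pool)
            frames.append(
                pd.DataFrame(
                    {
                        "gene": s.gene_ids,
                        "species": sp,
                        "enc": cub_metrics.enc_per_gene(s.counts_matrix, mode="counts"),
                        "gc3": codon_stats.gc3_per_gene(s.counts_matrix),
                        "length_codons": s.counts_matrix.sum(axis=1),
                        "cai": cub_metrics.cai_per_gene(s.counts_matrix, weights),
                        "mean_tpm": pd.Series(s.gene_ids).map(mean_tpm).to_numpy()
                        if sp == ref_sp
                        else np.nan,
                    }
                )
            )
        gene_df = pd.concat(frames, ignore_index=True)
        _write(gene_df.set_index("gene"), outdir / "gene_metrics.tsv")
        results["gene_metrics"] = gene_df

    if "cluster" in stages:
        profiles = {sp: s.rscu for sp, s in sorted(stats.items())}
        matrix = comparative.build_rscu_matrix(profiles)
        dendro = comparative.hierarchical_cluster(matrix, method=cfg.linkage)
        (outdir / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
        _write(comparative.distance_matrix(matrix), outdir / "distance_matrix.tsv")
        results["rscu_matrix"] = matrix
        results["dendrogram"] = dendro
        provenance["linkage"] = cfg.linkage

    if "correlate" in stages:
        profiles = {sp: s.rscu for sp, s in sorted(stats.items())}
        tally = comparative.preferred_codon_tally(profiles)
        freqs = pd.DataFrame(
            {
                sp: codon_stats.codon_frequencies(s.pooled)["per_thousand"] / 1000.0
                for sp, s in sorted(stats.items())
            }
        ).T
        corr = comparative.codon_cub_correlations(
            freqs, species_df["enc"], alpha=cfg.alpha
        )
        fig3 = corr.copy()
        fig3.insert(0, "n_species_preferred", tally)
        _write(fig3, outdir / "codon_preference_correlations.tsv")
        results["codon_correlations"] = fig3

        senc_reg = comparative.senc_enc_regressions(
            senc_df, species_df["enc"], alpha=cfg.alpha
        )
        _write(senc_reg, outdir / "senc_enc_regressions.tsv")
        results["senc_enc_regressions"] = senc_reg

        if len(species_df) >= 3:
            summary = comparative.species_summary_regressions(species_df, gene_df)
            res = summary["enc_vs_gc3"]
            summary_rows = [
                {
                    "analysis": "enc_vs_gc3",
                    "species": "(all)",
                    "pearson_r": res.pearson_r,
                    "r_squared": res.r_squared,
                    "p_value": res.p_value,
                    "n": res.n,
                }
            ]
            for sp, r in summary.get("cai_vs_enc", {}).items():
                summary_rows.append(
                    {
                        "analysis": "cai_vs_enc",
                        "species": sp,
                        "pearson_r": r.pearson_r,
                        "r_squared": r.r_squared,
                        "p_value": r.p_value,
                        "n": r.n,
                    }
                )
            _write(
                pd.DataFrame(summary_rows).set_index("analysis"),
                outdir / "species_regressions.tsv",
            )
            results["summary_regressions"] = summary

        if gene_df is not None and expression is not None:
            ref_sp = cfg.reference_species or sorted(stats)[0]
            sub = gene_df[gene_df["species"] == ref_sp].set_index("gene")
            correlates = comparative.gene_level_correlates(
                sub, expression=tpm_by_lib, alpha=cfg.alpha
            )
            correlates.insert(0, "species", ref_sp)
            _write(correlates, outdir / "gene_level_correlates.tsv")
            results["gene_level_correlates"] = correlates

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True, default=str)
    return results
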