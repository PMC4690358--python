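"""Synthetic multi-species CDS cohorts with known codon-bias forces.

The generator emulates the study design the analysis modules consume: a
backbone of conserved single-copy genes shared across species, per-species
FASTA of in-frame CDS, an ortholog inventory and RNA-seq-style expression
counts — with every force dialled in explicitly so the pipeline's readouts
can be checked against ground truth.

Codon-choice model
------------------
Amino acids are drawn i.i.d. from a fixed composition; within each
synonymous family codon c of gene g is chosen with weight

    w(c) ∝ exp(b_g * m(c)),      m(c) = 1 if the third base is G or C

so the third-position nucleotide is the only bias feature.  The gene-level
log-odds is

    b_g = beta + s * dir_s * z_expr(g) + a * dir_a * z_len(g)

where ``beta`` encodes mutational bias (calibrated by 1-D root finding so
the no-selection cohort mean GC3 hits ``gc3_target``), ``s`` couples codon
choice to standardized log-expression (selection for translational speed),
``a`` to standardized log-length (selection for translational accuracy),
and dir is +1 toward GC, -1 toward AT.  Gene lengths and expression levels
are log-normal.  All randomness derives from a single cohort seed with a
documented per-species derivation, so outputs are byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .codon_stats import CodingSequence
from .cub_metrics import ExpressionTable
from .dataset_prep import OrthologTable
from .genetic_code import AMINO_ACIDS, CODONS, CODON_INDEX, FAMILIES, STOP_CODONS

#: Average amino-acid composition of well-annotated proteomes (Swiss-Prot
#: style frequencies), normalised to sum to 1.
DEFAULT_AA_COMPOSITION: dict[str, float] = {
    "A": 0.0825, "C": 0.0137, "D": 0.0545, "E": 0.0675, "F": 0.0386,
    "G": 0.0707, "H": 0.0227, "I": 0.0596, "K": 0.0584, "L": 0.0966,
    "M": 0.0242, "N": 0.0406, "P": 0.0470, "Q": 0.0393, "R": 0.0553,
    "S": 0.0656, "T": 0.0534, "V": 0.0687, "W": 0.0108, "Y": 0.0292,
}

_LIBRARIES = ("digestive_gland", "gills", "hemocytes")

# Per amino acid: indices of AT-ending and GC-ending codons, padded to 4.
_N_AT = np.zeros(20, dtype=np.int64)
_N_GC = np.zeros(20, dtype=np.int64)
_CLASS_LOOKUP = np.zeros((20, 2, 4), dtype=np.int64)  # aa, is_gc, within-class slot
for _ai, _aa in enumerate(AMINO_ACIDS):
    _at = [CODON_INDEX[c] for c in FAMILIES[_aa] if c[2] in "AT"]
    _gc = [CODON_INDEX[c] for c in FAMILIES[_aa] if c[2] in "GC"]
    _N_AT[_ai], _N_GC[_ai] = len(_at), len(_gc)
    for _j, _c in enumerate(_at):
        _CLASS_LOOKUP[_ai, 0, _j] = _c
    for _j, _c in enumerate(_gc):
        _CLASS_LOOKUP[_ai, 1, _j] = _c

_MET_IDX = AMINO_ACIDS.index("M")
_CODON_STRS = np.array(CODONS)


@dataclass
class SpeciesSimParams:
    """Generative parameters for one synthetic species.

    Defaults describe the study conditions the analyses are exercised
    under: 2,000 conserved genes per species (desk-scale stand-in for the
    2,846-gene backbone), log-normal gene lengths averaging ~280 codons
    (mean recovered length well above 500 nt), log-normal expression
    spanning a few orders of magnitude of TPM, and no selection unless
    dialled in.
    """

    species_id: str
    n_genes: int = 2000
    mean_length_codons: float = 280.0
    sd_log_length: float = 0.35
    min_length_codons: int = 102
    gc3_target: float = 0.5
    speed_selection_s: float = 0.0
    speed_direction: str = "GC"
    accuracy_selection_a: float = 0.0
    accuracy_direction: str = "AT"
    mean_log10_tpm: float = 1.0
    sd_log10_tpm: float = 1.0
    library_noise_sd: float = 0.25
    total_reads: int = 1_000_000
    aa_composition: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0.0 < self.gc3_target < 1.0:
            raise ValueError("gc3_target must lie in (0, 1)")
        for d in (self.speed_direction, self.accuracy_direction):
            if d not in ("AT", "GC"):
                raise ValueError("selection direction must be 'AT' or 'GC'")

    def composition_vector(self) -> np.ndarray:
        comp = dict(self.aa_composition or DEFAULT_AA_COMPOSITION)
        vec = np.array([comp[aa] for aa in AMINO_ACIDS], dtype=float)
        if (vec < 0).any() or vec.sum() <= 0:
            raise ValueError("invalid amino-acid composition")
        return vec / vec.sum()


def expected_gc3(beta: float, aa_comp: np.ndarray) -> float:
    """Mean third-position GC under log-odds ``beta``, averaged over the
    amino-acid composition (Met and Trp contribute 1: ATG and TGG end in G)."""
    with np.errstate(over="ignore"):
        e = np.exp(beta)
        p_gc = np.where(
            _N_GC == 0,
            0.0,
            _N_GC * e / (_N_AT + _N_GC * e),
        )
    return float(aa_comp @ p_gc)


def calibrate_beta(
    gc3_target: float, aa_comp: np.ndarray, bracket: float = 30.0
) -> float:
    """Solve expected_gc3(beta) = gc3_target by Brent root finding.

    Raises ``ValueError`` when the target is outside the range the code
    structure allows (the floor is the Met+Trp share of the composition).
    """
    lo, hi = expected_gc3(-bracket, aa_comp), expected_gc3(bracket, aa_comp)
    if not lo < gc3_target < hi:
        raise ValueError(
            f"gc3_target {gc3_target} infeasible; reachable range is "
            f"({lo:.4f}, {hi:.4f})"
        )
    return float(brentq(lambda b: expected_gc3(b, aa_comp) - gc3_target, -bracket, bracket, xtol=1e-10))


@dataclass
class SpeciesData:
    """One generated species: sequences plus expression and ground truth."""

    params: SpeciesSimParams
    gene_ids: list[str]
    sequences: list[CodingSequence]
    lengths_codons: np.ndarray
    true_mean_tpm: np.ndarray
    counts_matrix: np.ndarray  # (n_genes, 64) interior codon counts
    expression: ExpressionTable
    truth: dict


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_species(
    params: SpeciesSimParams,
    seed: int | np.random.Generator,
    gene_ids: Sequence[str] | None = None,
) -> SpeciesData:
    """Generate one species' CDS set, expression table and truth record.

    Each gene gets a log-normal length and expression level; codons are
    drawn per the log-linear third-position model.  Sequences start with
    ATG and carry a terminal stop codon.  Fully reproducible from the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    aa_comp = params.composition_vector()
    beta = calibrate_beta(params.gc3_target, aa_comp)
    G = params.n_genes
    if gene_ids is None:
        gene_ids = [f"OG{i + 1:05d}" for i in range(G)]
    elif len(gene_ids) != G:
        raise ValueError("gene_ids length must equal n_genes")

    mu_len = np.log(params.mean_length_codons) - params.sd_log_length**2 / 2
    lengths = np.maximum(
        np.round(rng.lognormal(mu_len, params.sd_log_length, size=G)).astype(np.int64),
        params.min_length_codons,
    )
    true_tpm = 10.0 ** rng.normal(params.mean_log10_tpm, params.sd_log10_tpm, size=G)
    true_tpm = 1e6 * true_tpm / true_tpm.sum()

    z_expr = _standardize(np.log(true_tpm))
    z_len = _standardize(np.log(lengths.astype(float)))
    dir_s = 1.0 if params.speed_direction == "GC" else -1.0
    dir_a = 1.0 if params.accuracy_direction == "GC" else -1.0
    b_gene = (
        beta
        + params.speed_selection_s * dir_s * z_expr
        + params.accuracy_selection_a * dir_a * z_len
    )

    # vectorised codon draws across all positions of all genes
    N = int(lengths.sum())
    gene_idx = np.repeat(np.arange(G), lengths)
    cum = np.cumsum(aa_comp)
    aa_idx = np.searchsorted(cum, rng.random(N), side="right")
    starts = np.concatenate(([0], np.cumsum(lengths)[:-1]))
    aa_idx[starts] = _MET_IDX  # every CDS opens with ATG
    b_pos = b_gene[gene_idx]
    n_at = _N_AT[aa_idx]
    n_gc = _N_GC[aa_idx]
    with np.errstate(over="ignore"):
        eb = np.exp(b_pos)
        p_gc = np.where(n_gc == 0, 0.0, n_gc * eb / (n_at + n_gc * eb))
    is_gc = (rng.random(N) < p_gc).astype(np.int64)
    class_size = np.where(is_gc == 1, n_gc, n_at)
    slot = (rng.random(N) * class_size).astype(np.int64)
    codon_idx = _CLASS_LOOKUP[aa_idx, is_gc, slot]

    counts = np.bincount(
        gene_idx * 64 + codon_idx, minlength=G * 64
    ).reshape(G, 64)

    stop_choice = _CODON_STRS[
        np.array([CODON_INDEX[c] for c in STOP_CODONS])[rng.integers(0, 3, size=G)]
    ]
    codon_strs = _CODON_STRS[codon_idx]
    ends = np.cumsum(lengths)
    sequences = [
        CodingSequence(
            id=gene_ids[g],
            species=params.species_id,
            nucleotides="".join(codon_strs[starts[g]:ends[g]]) + stop_choice[g],
            length_codons=int(lengths[g]),
        )
        for g in range(G)
    ]

    # RNA-seq style counts: expected reads proportional to tpm * length
    lengths_nt = 3 * (lengths + 1)
    lib_counts = {}
    for lib in _LIBRARIES:
        rel = true_tpm * np.exp(rng.normal(0.0, params.library_noise_sd, size=G))
        lam = rel * lengths_nt
        lam = params.total_reads * lam / lam.sum()
        lib_counts[lib] = rng.poisson(lam)
    expression = ExpressionTable(
        counts=pd.DataFrame(lib_counts, index=list(gene_ids)),
        lengths=pd.Series(lengths_nt, index=list(gene_ids), name="effective_length_nt"),
    )

    realized_gc3 = float(
        np.sum(counts @ np.array([c[2] in "GC" for c in CODONS], dtype=float))
        / counts.sum()
    )
    truth = {
        "params": {k: v for k, v in asdict(params).items() if k != "aa_composition"},
        "beta": beta,
        "realized_gc3": realized_gc3,
    }
    return SpeciesData(
        params=params,
        gene_ids=list(gene_ids),
        sequences=sequences,
        lengths_codons=lengths,
        true_mean_tpm=true_tpm,
        counts_matrix=counts,
        expression=expression,
        truth=truth,
    )


@dataclass
class Cohort:
    """A self-contained multi-species pipeline input with ground truth."""

    species: dict[str, SpeciesData]
    ortholog_table: OrthologTable
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA per species, the ortholog TSV, expression TSVs and the
        truth record; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        present = {
            sp: set(self.ortholog_table.present_genes(sp)) for sp in self.species
        }
        for sp, data in self.species.items():
            fasta = outdir / f"{sp}.fasta"
            with open(fasta, "w") as fh:
                for seq in data.sequences:
                    if seq.id in present[sp]:
                        fh.write(f">{seq.id}\n{seq.nucleotides}\n")
            paths[f"fasta:{sp}"] = fasta
            expr = outdir / f"expression_{sp}.tsv"
            data.expression.to_tsv(expr)
            paths[f"expression:{sp}"] = expr
        ortho = outdir / "ortholog_table.tsv"
        self.ortholog_table.to_tsv(ortho)
        paths["ortholog_table"] = ortho
        truth_path = outdir / "truth.json"
        with open(truth_path, "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
        paths["truth"] = truth_path
        return paths


def generate_cohort(
    params_list: Sequence[SpeciesSimParams],
    seed: int,
    dropout: Mapping[str, float] | None = None,
) -> Cohort:
    """Generate a multi-species cohort sharing one conserved-gene backbone.

    Every species draws the same gene ids (ortholog design); ``dropout``
    optionally removes a fraction of a species' genes from both its CDS
    set and the ortholog inventory, to exercise the coverage filter.  The
    per-species RNG is derived as ``default_rng([seed, species_index])``.
    """
    if len(params_list) < 2:
        raise ValueError("need at least two species")
    ids = [p.species_id for p in params_list]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate species ids")
    n_genes = {p.n_genes for p in params_list}
    if len(n_genes) != 1:
        raise ValueError("all species must share the conserved backbone size")
    G = n_genes.pop()
    gene_ids = [f"OG{i + 1:05d}" for i in range(G)]
    dropout = dict(dropout or {})

    species: dict[str, SpeciesData] = {}
    rows = []
    truth: dict = {"seed": seed, "species": {}}
    for i, params in enumerate(params_list):
        rng = np.random.default_rng([seed, i])
        data = generate_species(params, rng, gene_ids=gene_ids)
        rate = dropout.get(params.species_id, 0.0)
        keep = rng.random(G) >= rate
        kept_ids = [g for g, k in zip(gene_ids, keep) if k]
        lengths_nt = 3 * (data.lengths_codons + 1)
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": kept_ids,
                    "species": params.species_id,
                    "length_nt": lengths_nt[keep],
                }
            )
        )
        data.truth["dropout"] = rate
        truth["species"][params.species_id] = data.truth
        species[params.species_id] = data
    table = OrthologTable(
        conserved_gene_ids=gene_ids,
        table=pd.concat(rows, ignore_index=True),
        metadata={"origin": "synthetic", "n_backbone": G},
    )
    return Cohort(species=species, ortholog_table=table, truth=truth)


# ---------------------------------------------------------------------------
# Canned cohort designs used by examples and acceptance checks


def gc3_sweep_params(
    n_species: int = 12,
    gc3_range: tuple[float, float] = (0.25, 0.50),
    n_genes: int = 2000,
) -> list[SpeciesSimParams]:
    """Species spanning a mutational-bias gradient, no selection — the
    desk-scale analogue of the cross-species ENC ~ GC3 regression."""
    targets = np.linspace(gc3_range[0], gc3_range[1], n_species)
    return [
        SpeciesSimParams(species_id=f"sp{i + 1:02d}", n_genes=n_genes, gc3_target=float(t))
        for i, t in enumerate(targets)
    ]


def two_regime_params(
    n_per_group: int = 6,
    gc3_low: float = 0.35,
    gc3_high: float = 0.49,
    n_genes: int = 2000,
) -> list[SpeciesSimParams]:
    """Two GC3 regimes (AT-shifted vs balanced), the analogue of the
    high-bias / low-bias species groups recovered by RSCU clustering."""
    params = [
        SpeciesSimParams(species_id=f"low{i + 1:02d}", n_genes=n_genes, gc3_target=gc3_low)
        for i in range(n_per_group)
    ]
    params += [
        SpeciesSimParams(species_id=f"bal{i + 1:02d}", n_genes=n_genes, gc3_target=gc3_high)
        for i in range(n_per_group)
    ]
    return params


def selection_contrast_params(n_genes: int = 2000) -> list[SpeciesSimParams]:
    """An oyster-like species (GC-directed speed selection) and a
    mussel-like species (AT-directed accuracy selection) on an AT-shifted
    mutational background."""
    return [
        SpeciesSimParams(
            species_id="speed_gc",
            n_genes=n_genes,
            gc3_target=0.45,
            speed_selection_s=0.35,
            speed_direction="GC",
        ),
        SpeciesSimParams(
            species_id="accuracy_at",
            n_genes=n_genes,
            gc3_target=0.35,
            accuracy_selection_a=0.35,
            accuracy_direction="AT",
        ),
    ]
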