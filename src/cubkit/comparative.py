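"""Cross-species analyses: RSCU matrix, clustering, correlation/regression.

Species are compared on their RSCU profiles over the 59 informative codons
(sense codons minus ATG and TGG), clustered agglomeratively with Euclidean
distance, and probed for the forces shaping codon bias through Pearson
correlations: codon frequency against overall bias (negative ENC),
per-amino-acid sENC-x against ENC, species ENC against GC3, gene-level CAI
against ENC, and the gene-level signatures of translational speed
(codon usage vs expression) and accuracy (codon usage vs length) selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from io import StringIO
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform
from scipy.stats import linregress
from skbio.tree import TreeNode

from .codon_stats import RscuVector
from .genetic_code import DEGENERATE_AAS, INFORMATIVE_CODONS


class DegenerateDataError(ValueError):
    """Regression input has fewer than 3 points or zero variance."""


@dataclass(frozen=True)
class RegressionResult:
    """Simple linear regression y ~ x with the Pearson correlation.

    ``p_value`` is the two-sided p of the F-test of the regression, which
    for a single predictor equals the slope t-test p.
    """

    pearson_r: float
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


def pearson_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x with Pearson r and F-test p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    if x.size < 3:
        raise DegenerateDataError(f"need n >= 3, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero variance in x or y")
    fit = linregress(x, y)
    return RegressionResult(
        pearson_r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=int(x.size),
    )


# ---------------------------------------------------------------------------
# RSCU matrix and clustering


@dataclass
class RscuMatrix:
    """Species x 59-informative-codon RSCU matrix ready for clustering.

    ``imputed`` masks cells that were filled with the codon's column mean
    because the species never used the amino acid; ``excluded_species``
    lists species dropped for missing more than the allowed share of
    codons.
    """

    values: pd.DataFrame
    imputed: pd.DataFrame
    excluded_species: tuple[str, ...] = ()


def build_rscu_matrix(
    profiles: Mapping[str, RscuVector], max_missing: float = 0.2
) -> RscuMatrix:
    """Assemble per-species RSCU vectors into the clustering matrix.

    Rows are species, columns the 59 informative codons in canonical
    order.  A codon with undefined RSCU in a species (absent amino acid)
    is imputed with the column mean over the species that define it, and
    masked; a species missing more than ``max_missing`` of the columns is
    excluded with a warning.  No NaN survives into the output.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two species")
    raw = pd.DataFrame(
        {sp: [vec.values.get(c, np.nan) for c in INFORMATIVE_CODONS]
         for sp, vec in profiles.items()},
        index=list(INFORMATIVE_CODONS),
    ).T
    frac_missing = raw.isna().mean(axis=1)
    excluded = tuple(frac_missing.index[frac_missing > max_missing])
    if excluded:
        warnings.warn(
            f"excluding species missing >{max_missing:.0%} of informative codons: "
            f"{', '.join(excluded)}",
            stacklevel=2,
        )
        raw = raw.drop(index=list(excluded))
    if len(raw) < 2:
        raise ValueError("fewer than two species left after exclusions")
    mask = raw.isna()
    col_means = raw.mean(axis=0)
    if col_means.isna().any():
        raise ValueError("a codon is undefined in every species; cannot impute")
    values = raw.fillna(col_means)
    return RscuMatrix(values=values, imputed=mask, excluded_species=excluded)


@dataclass
class Dendrogram:
    """Agglomerative clustering result: scipy linkage matrix plus labels."""

    linkage: np.ndarray
    labels: tuple[str, ...]
    method: str
    metric: str

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> tuple[str, ...]:
        return tuple(self.labels[i] for i in sch.leaves_list(self.linkage))

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Flat cluster assignment from cutting the tree into ``n_clusters``."""
        flat = sch.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))

    def top_split(self) -> tuple[frozenset[str], frozenset[str]]:
        """The bipartition produced by the final (highest) merge."""
        assign = self.cut(2)
        groups = sorted(set(assign.values()))
        return tuple(
            frozenset(sp for sp, g in assign.items() if g == grp) for grp in groups
        )  # type: ignore[return-value]

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        tree = TreeNode.from_linkage_matrix(self.linkage, list(self.labels))
        buf = StringIO()
        tree.write(buf, format="newick")
        return buf.getvalue().strip()


def hierarchical_cluster(
    m: RscuMatrix | pd.DataFrame,
    metric: str = "euclidean",
    method: str = "complete",
) -> Dendrogram:
    """Cluster species by their RSCU rows.

    Default is Euclidean distance with complete linkage (monotone merge
    heights); average linkage is available as a configuration switch.
    scipy's agglomeration is deterministic for a fixed row order, breaking
    distance ties by the lowest pair index.
    """
    values = m.values if isinstance(m, RscuMatrix) else m
    if len(values) < 2:
        raise ValueError("need at least two rows to cluster")
    X = values.to_numpy(dtype=float)
    Z = sch.linkage(X, method=method, metric=metric)
    return Dendrogram(
        linkage=Z, labels=tuple(values.index), method=method, metric=metric
    )


def distance_matrix(m: RscuMatrix | pd.DataFrame, metric: str = "euclidean") -> pd.DataFrame:
    """Square species x species distance matrix used by the clustering."""
    values = m.values if isinstance(m, RscuMatrix) else m
    d = squareform(pdist(values.to_numpy(dtype=float), metric=metric))
    return pd.DataFrame(d, index=values.index, columns=values.index)


# ---------------------------------------------------------------------------
# Preferred codons and correlation analyses


def preferred_codon_tally(profiles: Mapping[str, RscuVector]) -> pd.Series:
    """Number of species in which each informative codon is preferred
    (RSCU strictly greater than 1)."""
    if not profiles:
        raise ValueError("no species profiles")
    tally = pd.Series(0, index=list(INFORMATIVE_CODONS), name="n_species_preferred")
    for vec in profiles.values():
        for codon in INFORMATIVE_CODONS:
            v = vec.values.get(codon)
            if v is not None and v > 1:
                tally[codon] += 1
    return tally


def _safe_regression(x: np.ndarray, y: np.ndarray) -> RegressionResult | None:
    try:
        return pearson_regression(x, y)
    except DegenerateDataError:
        return None


def _result_row(res: RegressionResult | None, alpha: float) -> dict:
    if res is None:
        return {
            "pearson_r": np.nan,
            "slope": np.nan,
            "p_value": np.nan,
            "r_squared": np.nan,
            "n": 0,
            "significant": False,
        }
    return {
        "pearson_r": res.pearson_r,
        "slope": res.slope,
        "p_value": res.p_value,
        "r_squared": res.r_squared,
        "n": res.n,
        "significant": res.significant(alpha),
    }


def codon_cub_correlations(
    freqs: pd.DataFrame, enc: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-codon regression of frequency on overall species bias.

    ``freqs`` is species x codon overall codon frequency (fraction of all
    sense codons, i.e. per-thousand / 1000); ``enc`` the species ENC
    vector.  Each of the 59 informative codons is regressed on negative
    ENC, so a positive r means the codon is used more in more biased
    species.  Degenerate inputs (e.g. constant frequency) are flagged
    non-significant with NaN statistics.
    """
    freqs, enc = freqs.align(enc, join="inner", axis=0)
    neg_enc = -enc.to_numpy(dtype=float)
    rows = {}
    for codon in INFORMATIVE_CODONS:
        res = (
            _safe_regression(neg_enc, freqs[codon].to_numpy(dtype=float))
            if codon in freqs.columns
            else None
        )
        rows[codon] = _result_row(res, alpha)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "codon"
    return out


def senc_enc_regressions(
    senc: pd.DataFrame, enc: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-amino-acid regression of sENC-x on species ENC.

    Under mutational-bias-driven usage every degenerate amino acid's bias
    intensity rises as ENC falls, so slopes are negative.  Rows cover the
    amino acids present in ``senc`` (18 when all are usable); columns
    include the mean sENC-x across species.
    """
    senc, enc = senc.align(enc, join="inner", axis=0)
    enc_arr = enc.to_numpy(dtype=float)
    rows = {}
    for aa in DEGENERATE_AAS:
        if aa not in senc.columns:
            continue
        res = _safe_regression(enc_arr, senc[aa].to_numpy(dtype=float))
        row = _result_row(res, alpha)
        row["mean_senc_x"] = float(senc[aa].mean())
        rows[aa] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "amino_acid"
    return out


def species_summary_regressions(
    species_df: pd.DataFrame, gene_df: pd.DataFrame | None = None
) -> dict:
    """Headline cross-species and within-species regressions.

    ``species_df`` needs columns ``gc3`` and ``enc`` (one row per species)
    and feeds the ENC ~ GC3 regression; a positive r reproduces the
    signature of mutational bias (AT-shifted GC3 drags ENC down).
    ``gene_df`` (columns ``species``, ``cai``, ``enc``) yields the per-
    species gene-level CAI ~ ENC Pearson correlations.
    """
    out: dict = {
        "enc_vs_gc3": pearson_regression(
            species_df["gc3"].to_numpy(), species_df["enc"].to_numpy()
        )
    }
    if gene_df is not None:
        cai_vs_enc = {}
        for sp, sub in gene_df.groupby("species"):
            sub = sub.dropna(subset=["cai", "enc"])
            res = _safe_regression(sub["cai"].to_numpy(), sub["enc"].to_numpy())
            if res is not None:
                cai_vs_enc[sp] = res
        out["cai_vs_enc"] = cai_vs_enc
    return out


def gene_level_correlates(
    genes: pd.DataFrame,
    expression: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Table of gene-level selection signatures for one species.

    ``genes`` needs columns ``enc``, ``gc3``, ``length_codons`` indexed by
    gene id; ``expression`` is an optional genes x libraries TPM frame.
    Reported Pearson correlations (CUB measured as negative ENC):

    * CUB vs protein length, GC3 vs protein length — translational
      accuracy; the sign of the GC3 row gives the direction of the
      accuracy force.
    * CUB vs expression and GC3 vs expression per library — translational
      speed.  Expression enters as log10(TPM + 1).
    * CUB vs GC3 — mutational-bias coupling.

    Libraries absent from ``expression`` simply yield no row.
    """
    df = genes.dropna(subset=["enc", "gc3", "length_codons"])
    neg_enc = -df["enc"].to_numpy(dtype=float)
    gc3 = df["gc3"].to_numpy(dtype=float)
    length = df["length_codons"].to_numpy(dtype=float)
    rows = []

    def add(analysis: str, x: np.ndarray, y: np.ndarray) -> None:
        res = _safe_regression(x, y)
        row = {"analysis": analysis}
        row.update(_result_row(res, alpha))
        rows.append(row)

    add("cub_vs_length", length, neg_enc)
    add("gc3_vs_length", length, gc3)
    if expression is not None:
        expr = expression.reindex(df.index)
        for lib in expression.columns:
            x = np.log10(expr[lib].to_numpy(dtype=float) + 1.0)
            ok = ~np.isnan(x)
            add(f"cub_vs_expression_{lib}", x[ok], neg_enc[ok])
            add(f"gc3_vs_expression_{lib}", x[ok], gc3[ok])
    add("cub_vs_gc3", gc3, neg_enc)
    return pd.DataFrame(rows).set_index("analysis")
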