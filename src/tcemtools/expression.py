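"""Map cTEC gene expression onto TCEMs.

Positive selection happens on cortical thymic epithelial cells (cTECs), so a
motif can only tolerize/select T cells if the genes encoding it are expressed
there. The pipeline: TMM-normalize a raw count matrix, convert to RPKM using
effective library sizes, take the per-gene median across cTEC samples, join
proteins to genes through shared gene symbols, and aggregate per motif as the
median over one value per proteome occurrence (a motif occurring k times in a
protein contributes the encoding gene's expression k times).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .motifs import ProteomeIndex

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# TMM normalization (trimmed mean of M-values)
# ---------------------------------------------------------------------------

def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    log_ratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    """TMM scale factor of one sample against a reference sample.

    M-values (log2 expression ratios) are trimmed by `log_ratio_trim` on each
    tail and A-values (average log intensity) by `sum_trim`; the factor is
    2**(precision-weighted mean of surviving M-values), weights being inverse
    asymptotic binomial variances.
    """
    n_obs = obs.sum()
    n_ref = ref.sum()
    keep = (obs > 0) & (ref > 0)
    obs = obs[keep].astype(float)
    ref = ref[keep].astype(float)
    if obs.size == 0:
        return 1.0
    log_r = np.log2((obs / n_obs) / (ref / n_ref))
    abs_e = 0.5 * (np.log2(obs / n_obs) + np.log2(ref / n_ref))
    var = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * log_ratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = rankdata(log_r)
    rank_e = rankdata(abs_e)
    keep2 = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not keep2.any():
        return 1.0
    f = np.sum(log_r[keep2] / var[keep2]) / np.sum(1.0 / var[keep2])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_norm_factors(counts: pd.DataFrame, log_ratio_trim: float = 0.3,
                     sum_trim: float = 0.05) -> pd.Series:
    """Per-sample TMM normalization factors (genes in rows, samples in columns).

    The reference sample is the one whose 75th count-fraction percentile is
    closest to the across-sample mean. Factors are geometric-mean-centered so
    they multiply to 1.

    Raises
    ------
    ValueError
        If a sample has an all-zero library or fewer than two samples exist.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM normalization needs at least two samples")
    lib = counts.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    frac75 = counts.div(lib, axis=1).quantile(0.75, axis=0)
    ref_name = (frac75 - frac75.mean()).abs().idxmin()
    ref = counts[ref_name].to_numpy()
    factors = pd.Series(
        {c: _tmm_pair_factor(counts[c].to_numpy(), ref, log_ratio_trim, sum_trim)
         for c in counts.columns},
        name="norm_factor",
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def normalize_counts(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """TMM factors plus the count matrix scaled by effective library size.

    Returns (factors, matrix of counts-per-effective-library fractions scaled
    back to the mean library size) so equal true expression gives equal
    normalized values across samples.
    """
    factors = tmm_norm_factors(counts)
    eff_lib = counts.sum(axis=0) * factors
    scaled = counts.div(eff_lib, axis=1) * eff_lib.mean()
    return factors, scaled


def compute_rpkm(counts: pd.DataFrame, exon_length: pd.Series,
                 norm_factors: pd.Series | None = None) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads.

    rpkm = count / (exon_length/1e3) / (effective_library/1e6), with the
    effective library size being raw library size times the TMM factor.
    """
    exon_length = exon_length.reindex(counts.index)
    if exon_length.isna().any():
        missing = list(exon_length[exon_length.isna()].index[:5])
        raise ValueError(f"missing exon length for genes, e.g. {missing}")
    if (exon_length <= 0).any():
        raise ValueError("exon lengths must be positive")
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("zero library size")
    if norm_factors is not None:
        lib = lib * norm_factors.reindex(counts.columns)
    per_million = lib / 1e6
    per_kb = exon_length / 1e3
    return counts.div(per_million, axis=1).div(per_kb, axis=0)


def median_gene_expression(rpkm: pd.DataFrame) -> pd.Series:
    """Per-gene median RPKM across samples."""
    if rpkm.shape[1] < 1:
        raise ValueError("need at least one sample")
    return rpkm.median(axis=1)


# ---------------------------------------------------------------------------
# Protein -> gene mapping and per-motif aggregation
# ---------------------------------------------------------------------------

@dataclass
class GeneProteinMap:
    """Protein -> genes join through shared gene symbols."""

    mapping: dict[str, frozenset[str]] = field(default_factory=dict)
    unmapped: set[str] = field(default_factory=set)

    def genes_for(self, protein_id: str) -> frozenset[str]:
        return self.mapping.get(protein_id, frozenset())


def map_proteins_to_genes(protein_symbols: pd.DataFrame,
                          gene_symbols: pd.DataFrame) -> GeneProteinMap:
    """Join proteins to genes on shared symbols.

    Parameters
    ----------
    protein_symbols : DataFrame with columns (protein_id, symbol)
    gene_symbols : DataFrame with columns (gene_id, symbol)

    A protein maps to every gene sharing at least one symbol; proteins with
    no shared symbol land in ``unmapped`` (a reported outcome, not an error).
    """
    if protein_symbols.empty or gene_symbols.empty:
        raise ValueError("symbol tables must be nonempty")
    sym_to_genes: dict[str, set[str]] = {}
    for gene_id, symbol in gene_symbols[["gene_id", "symbol"]].itertuples(index=False):
        sym_to_genes.setdefault(symbol, set()).add(gene_id)
    result = GeneProteinMap()
    for pid, group in protein_symbols.groupby("protein_id"):
        genes: set[str] = set()
        for symbol in group["symbol"]:
            genes |= sym_to_genes.get(symbol, set())
        if genes:
            result.mapping[pid] = frozenset(genes)
        else:
            result.unmapped.add(pid)
    return result


def tcem_expression(index: ProteomeIndex, gene_map: GeneProteinMap,
                    expr: pd.Series) -> pd.DataFrame:
    """Per-motif expression: median over one gene value per occurrence.

    Each occurrence of a motif contributes the median RPKM of every gene
    mapped to the occurrence's protein (multi-gene proteins contribute one
    value per mapped gene per occurrence). Motifs whose occurrences all fall
    in unmapped proteins get NaN and ``n_values`` 0; they are excluded from
    expression-stratified analyses downstream.

    Returns a DataFrame indexed by motif with columns (expression, n_values).
    """
    rows = {}
    for motif, occ in index.occurrences.items():
        values: list[float] = []
        for pid, _start in occ:
            for gene in gene_map.genes_for(pid):
                if gene in expr.index:
                    values.append(float(expr[gene]))
        if values:
            rows[motif] = (float(np.median(values)), len(values))
        else:
            rows[motif] = (np.nan, 0)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["expression", "n_values"])
    out.index.name = "motif"
    return out


def stratify_expression(values: pd.Series, mode: str = "tertile"):
    """Stratify expression values into tertile groups or percentile ranks.

    ``tertile`` returns labels {low, medium, high} split at the 1/3 and 2/3
    quantiles (low: v < q1/3; high: v >= q2/3). ``percentile`` returns
    rank/n in (0, 1] with average ranks for ties.
    """
    values = values.dropna()
    if mode == "percentile":
        if values.empty:
            raise ValueError("no defined values")
        return pd.Series(rankdata(values) / len(values), index=values.index)
    if mode != "tertile":
        raise ValueError(f"unknown mode: {mode!r}")
    if len(values) < 3:
        raise ValueError("need at least 3 defined values for tertiles")
    q1, q2 = np.quantile(values, [1 / 3, 2 / 3])
    if q1 == q2:
        warnings.warn("degenerate expression distribution: single tertile group")
        return pd.Series("medium", index=values.index)
    labels = np.where(values < q1, "low", np.where(values >= q2, "high", "medium"))
    return pd.Series(labels, index=values.index)


def housekeeping_flag(motif: str, index: ProteomeIndex, gene_map: GeneProteinMap,
                      housekeeping_genes: set[str], rule: str = "any") -> bool:
    """Whether a motif is encoded by housekeeping genes.

    ``rule`` controls aggregation over the motif's occurrence genes:
    ``any`` (default), ``majority``, or ``all``.
    """
    if not housekeeping_genes:
        raise ValueError("housekeeping gene list is empty")
    flags: list[bool] = []
    for pid, _start in index.occurrences.get(motif, []):
        for gene in gene_map.genes_for(pid):
            flags.append(gene in housekeeping_genes)
    if not flags:
        return False
    if rule == "any":
        return any(flags)
    if rule == "all":
        return all(flags)
    if rule == "majority":
        return sum(flags) * 2 > len(flags)
    raise ValueError(f"unknown rule: {rule!r}")
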