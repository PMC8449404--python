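"""Repertoire, pathogen, and HLA-association analyses of np-TCEMs.

An np-TCEM ("non-positively-selecting" motif) is one for which specific,
positively selected T cells are expected to be missing from the repertoire:
it occurs fewer than four times in the human proteome, OR its encoding genes
are lowly expressed in cTECs, OR it has a low thymoproteasomal cleavage
score. This module covers three downstream analyses:

* naive CD8+ repertoire fractions -- per healthy individual, the fraction of
  HLA-presented peptides with specific T cells, stratified by TCEM
  attributes, compared with paired signed-rank tests;
* the pathogen scan -- prevalence of np-TCEMs in 9-mer windows of pathogen
  proteomes and in the subsets presented by individual HLA alleles;
* association aggregation -- rank-percentile pooling of per-study HLA
  odds ratios into protective and risk allele groups, compared with the
  np-content of the peptides those groups present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import ProteomeIndex, extract_tcem

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# np-TCEM classification
# ---------------------------------------------------------------------------

@dataclass
class NpCutoffs:
    """Cutoffs pinning the np-TCEM definition, stored so pathogen runs are
    reproducible: frequency threshold, the bottom-tertile expression boundary
    and the first-quartile thymoproteasomal score of the human TCEM
    distributions."""

    frequency_threshold: int = 4
    expression_cutoff: float = 0.0
    thymo_cutoff: float = 0.0
    missing_expression_is_low: bool = True


@dataclass
class NpProfile:
    """Per-motif np flags with the criterion provenance."""

    table: pd.DataFrame  # index motif; columns is_np, by_frequency, by_expression, by_cleavage
    cutoffs: NpCutoffs = field(default_factory=NpCutoffs)

    def is_np(self, motif: str, default: bool = True) -> bool:
        """np status of a motif; motifs absent from the human profile (never
        seen in the human proteome) default to np via the frequency rule."""
        if motif in self.table.index:
            return bool(self.table.loc[motif, "is_np"])
        return default


def np_flag(frequency: pd.Series, expression: pd.Series, thymo_score: pd.Series,
            cutoffs: NpCutoffs) -> NpProfile:
    """Flag motifs as np by the three-way disjunction.

    ``expression`` may contain NaN for motifs without mapped genes; by
    default these count as low expression (they cannot mediate positive
    selection through expression), switchable via the cutoffs object.
    """
    idx = frequency.index
    expression = expression.reindex(idx)
    thymo_score = thymo_score.reindex(idx)
    by_freq = frequency < cutoffs.frequency_threshold
    by_expr = expression < cutoffs.expression_cutoff
    if cutoffs.missing_expression_is_low:
        by_expr = by_expr | expression.isna()
    by_cleav = thymo_score < cutoffs.thymo_cutoff
    table = pd.DataFrame({
        "is_np": by_freq | by_expr | by_cleav,
        "by_frequency": by_freq,
        "by_expression": by_expr,
        "by_cleavage": by_cleav,
    })
    table.index.name = "motif"
    return NpProfile(table=table, cutoffs=cutoffs)


# ---------------------------------------------------------------------------
# Naive CD8+ repertoire analysis
# ---------------------------------------------------------------------------

def eligible_allele_peptide_pairs(predictions: pd.DataFrame, recognition: pd.DataFrame,
                                  genotypes: pd.DataFrame,
                                  affinity_cutoff: float = 50.0,
                                  rank_cutoff: float = 0.5,
                                  min_carriers: int = 2) -> pd.DataFrame:
    """Allele-peptide pairs eligible for the repertoire analysis.

    A pair is kept iff the predicted binding is strong (affinity < 50 nM AND
    rank percentile < 0.5%) and specific T cells were found in at least two
    individuals carrying the allele.

    ``predictions``: (peptide, allele, affinity_nm, rank_pct);
    ``recognition``: (individual, peptide, recognized);
    ``genotypes``: (individual, allele).
    """
    strong = predictions[
        (predictions["affinity_nm"] < affinity_cutoff)
        & (predictions["rank_pct"] < rank_cutoff)
    ][["peptide", "allele"]]
    recognized = recognition[recognition["recognized"].astype(bool)]
    carrier_hits = recognized.merge(genotypes, on="individual")
    counts = (
        carrier_hits.groupby(["peptide", "allele"])["individual"].nunique()
        .rename("n_carriers").reset_index()
    )
    merged = strong.merge(counts, on=["peptide", "allele"], how="left")
    merged["n_carriers"] = merged["n_carriers"].fillna(0)
    return merged[merged["n_carriers"] >= min_carriers][["peptide", "allele"]].reset_index(drop=True)


def per_individual_fractions(recognition: pd.DataFrame, genotypes: pd.DataFrame,
                             eligible_pairs: pd.DataFrame, tcem_groups: pd.Series,
                             min_recognized: int = 20) -> pd.DataFrame:
    """Per individual and TCEM-attribute group, the fraction of presented
    peptides with specific T cells in the repertoire.

    A peptide is "presented" to an individual if some allele in their
    genotype forms an eligible pair with it. Individuals with fewer than
    ``min_recognized`` recognized presented peptides are excluded.
    ``tcem_groups`` maps peptide -> group label. Returns a tidy frame
    (individual, group, n_presented, n_recognized, fraction); groups an
    individual presents no peptide in are absent (flagged undefined).
    """
    allele_peptides = eligible_pairs.groupby("allele")["peptide"].agg(set)
    rec_map = (
        recognition[recognition["recognized"].astype(bool)]
        .groupby("individual")["peptide"].agg(set)
    )
    rows = []
    for individual, alleles in genotypes.groupby("individual")["allele"]:
        presented: set[str] = set()
        for allele in alleles:
            presented |= allele_peptides.get(allele, set())
        if not presented:
            continue
        recognized = rec_map.get(individual, set()) & presented
        if len(recognized) < min_recognized:
            logger.info("individual %s excluded: %d recognized peptides",
                        individual, len(recognized))
            continue
        groups = tcem_groups.reindex(sorted(presented))
        for group, peptides in groups.groupby(groups):
            members = set(peptides.index)
            n_rec = len(members & recognized)
            rows.append({
                "individual": individual, "group": group,
                "n_presented": len(members), "n_recognized": n_rec,
                "fraction": n_rec / len(members),
            })
    return pd.DataFrame(rows)


def paired_group_comparison(fractions: pd.DataFrame, group_a: str, group_b: str
                            ) -> dict[str, float]:
    """Two-sided paired signed-rank test between two per-individual fraction
    columns. Only individuals with both groups defined enter. Returns the
    p-value, the median paired difference (a - b) and the pair count."""
    wide = fractions.pivot(index="individual", columns="group", values="fraction")
    pairs = wide[[group_a, group_b]].dropna()
    if len(pairs) < 6:
        raise ValueError(f"need >= 6 complete pairs, got {len(pairs)}")
    diff = pairs[group_a] - pairs[group_b]
    if (diff == 0).all():
        logger.warning("all paired differences are zero")
        return {"p_value": 1.0, "median_difference": 0.0, "n_pairs": len(pairs)}
    stat = stats.wilcoxon(pairs[group_a], pairs[group_b], alternative="two-sided")
    return {
        "p_value": float(stat.pvalue),
        "median_difference": float(diff.median()),
        "n_pairs": int(len(pairs)),
    }


# ---------------------------------------------------------------------------
# Pathogen proteome scan
# ---------------------------------------------------------------------------

def pathogen_np_fraction(pathogen_index: ProteomeIndex, profile: NpProfile,
                         weighting: str = "window") -> float:
    """Fraction of a pathogen proteome's 9-mer TCEMs flagged np.

    ``weighting="window"`` (default) weights motifs by their window counts
    in the pathogen proteome ("prevalence in the proteome");
    ``"distinct"`` counts each distinct motif once.
    """
    if weighting == "window":
        total = sum(pathogen_index.counts.values())
        hit = sum(c for m, c in pathogen_index.counts.items() if profile.is_np(m))
    elif weighting == "distinct":
        total = len(pathogen_index.counts)
        hit = sum(1 for m in pathogen_index.counts if profile.is_np(m))
    else:
        raise ValueError(f"unknown weighting: {weighting!r}")
    if total == 0:
        raise ValueError("pathogen proteome has no 9-mer windows")
    return hit / total


def allele_presented_np_fraction(peptides: pd.DataFrame, predictions: pd.DataFrame,
                                 profile: NpProfile,
                                 affinity_cutoff: float = 50.0,
                                 rank_cutoff: float = 0.5) -> pd.Series:
    """np-TCEM fraction among peptides each allele presents from a pathogen.

    ``peptides``: DataFrame with column peptide (the pathogen's 9-mers).
    ``predictions``: (peptide, allele, affinity_nm, rank_pct), with the
    allele's locus derivable from its name (HLA-A/B/C).

    An allele binds a peptide if rank < 0.5% and affinity < 50 nM. Alleles
    binding nothing fall back to their N lowest-affinity peptides, N being
    the median bound-count of the other alleles at the same locus (error if
    that median is undefined or zero).
    """
    pred = predictions.merge(peptides[["peptide"]].drop_duplicates(), on="peptide")
    pred = pred.assign(bound=(pred["affinity_nm"] < affinity_cutoff)
                       & (pred["rank_pct"] < rank_cutoff))
    is_np = {p: profile.is_np(extract_tcem(p)) for p in pred["peptide"].unique()}
    bound_counts = pred.groupby("allele")["bound"].sum()
    locus = bound_counts.index.str.slice(0, 5)  # "HLA-A" / "HLA-B" / "HLA-C"
    out = {}
    for allele, grp in pred.groupby("allele"):
        bound = grp[grp["bound"]]
        if bound.empty:
            same_locus = bound_counts[(locus == allele[:5])
                                      & (bound_counts.index != allele)]
            same_locus = same_locus[same_locus > 0]
            if same_locus.empty:
                raise ValueError(
                    f"allele {allele}: no bound peptides and no same-locus "
                    "alleles with binders to define the fallback N"
                )
            n = int(np.median(same_locus))
            bound = grp.nsmallest(n, "affinity_nm")
            logger.info("allele %s: zero binders, falling back to %d lowest-affinity "
                        "peptides", allele, n)
        flags = bound["peptide"].map(is_np)
        out[allele] = float(flags.mean())
    return pd.Series(out, name="np_fraction")


def variance_vs_proteome_size(fractions: pd.DataFrame, proteome_sizes: pd.Series
                              ) -> tuple[pd.Series, float, float]:
    """Across-allele variance of presented np fractions per species, and its
    Spearman correlation with proteome size (two-sided test).

    ``fractions``: species x allele matrix. Returns (per-species variance,
    rho, p).
    """
    if fractions.shape[0] < 3 or fractions.shape[1] < 2:
        raise ValueError("need >= 3 species and >= 2 alleles")
    variance = fractions.var(axis=1, ddof=1)
    sizes = proteome_sizes.reindex(variance.index)
    rho, p = stats.spearmanr(sizes, variance)
    return variance, float(rho), float(p)


# ---------------------------------------------------------------------------
# HLA association aggregation
# ---------------------------------------------------------------------------

def rank_percentile_aggregation(studies: pd.DataFrame, coverage: float = 0.75
                                ) -> pd.DataFrame:
    """Pool per-study odds ratios into per-allele-group mean rank percentiles.

    ``studies``: (study_id, allele_group, odds_ratio). Within each study the
    odds ratios are converted to rank percentiles (rank / n, average ranks for
    ties); allele groups present in at least ``coverage`` of studies get the
    mean of their percentiles. The group with the lowest mean is labelled
    protective, the highest risk. Invariant under any strictly monotone
    within-study transform of the odds ratios.
    """
    n_studies = studies["study_id"].nunique()
    if n_studies < 2:
        raise ValueError("need at least two studies")
    pct = studies.copy()
    pct["percentile"] = (
        pct.groupby("study_id")["odds_ratio"].rank(method="average")
        / pct.groupby("study_id")["odds_ratio"].transform("count")
    )
    presence = pct.groupby("allele_group")["study_id"].nunique()
    kept = presence[presence >= coverage * n_studies].index
    if kept.empty:
        raise ValueError("no allele group meets the coverage requirement")
    means = (
        pct[pct["allele_group"].isin(kept)]
        .groupby("allele_group")["percentile"].mean()
        .rename("mean_rank_percentile").reset_index()
    )
    means["label"] = ""
    means.loc[means["mean_rank_percentile"].idxmin(), "label"] = "protective"
    means.loc[means["mean_rank_percentile"].idxmax(), "label"] = "risk"
    return means


def group_level_np_fraction(allele_values: pd.Series, members: list[str],
                            common_alleles: set[str] | None = None) -> float:
    """Mean presented-np fraction over a group's member alleles.

    Serotype groups average all member alleles with values; two-digit allele
    groups average only members classified as common (pass
    ``common_alleles``). Errors on empty effective membership.
    """
    if common_alleles is not None:
        members = [a for a in members if a in common_alleles]
    values = allele_values.reindex(members).dropna()
    if values.empty:
        raise ValueError("no member allele with a defined value")
    return float(values.mean())
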