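"""Curation of epitope immunogenicity datasets from assay-level records.

Builds two nonoverlapping allele-peptide datasets from T-cell and MHC-binding
assay tables (IEDB-style exports):

* dataset 1 -- T-cell-assayed pairs whose HLA binding is confirmed by
  prediction (affinity < 500 nM or rank percentile < 2%);
* dataset 2 -- pairs with empirical binding evidence (>= 2 binding assays,
  > 60% of them positive, >= 2 T-cell assays), then thinned with an
  iterative k-tuple-distance procedure until every retained pair of peptides
  differs by at least half its residues.

Labels: a pair with solely negative T-cell assays is nonimmunogenic; with
more positive than negative assays, immunogenic; anything else is excluded,
as are peptides labelled oppositely for different alleles. Peptides present
in both datasets are kept only in dataset 2.
"""

from __future__ import annotations

import logging
import math
import re
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motifs import extract_tcem, is_standard

logger = logging.getLogger(__name__)

#: 4-digit HLA-I allele, e.g. HLA-A*02:01.
_ALLELE_RE = re.compile(r"^HLA-[ABC]\*\d{2}:\d{2}$")


def filter_assays(records: pd.DataFrame, human_taxa: tuple[str, ...] = ("Homo sapiens",)
                  ) -> pd.DataFrame:
    """Keep 9/10-mer standard-letter nonhuman peptides with 4-digit alleles.

    ``records`` needs columns (peptide, allele, assay_kind, outcome,
    source_organism). Rejections are logged with counts per reason.
    """
    reasons = Counter()
    keep = []
    for row in records.itertuples(index=False):
        if len(row.peptide) not in (9, 10):
            reasons["length"] += 1
        elif not is_standard(row.peptide):
            reasons["nonstandard_letter"] += 1
        elif row.source_organism in human_taxa:
            reasons["human_source"] += 1
        elif not _ALLELE_RE.match(row.allele):
            reasons["allele_resolution"] += 1
        else:
            keep.append(True)
            continue
        keep.append(False)
    if reasons:
        logger.info("assay filter rejections: %s", dict(reasons))
    return records[pd.Series(keep, index=records.index)].copy()


def label_immunogenicity(tcell_assays: pd.DataFrame) -> pd.DataFrame:
    """Label allele-peptide pairs from grouped T-cell assay outcomes.

    Solely negative -> nonimmunogenic; more positive than negative ->
    immunogenic; otherwise excluded. A peptide labelled immunogenic for one
    allele and nonimmunogenic for another has all its pairs excluded.

    Returns a DataFrame (peptide, allele, label, n_pos, n_neg) keeping only
    labelled pairs.
    """
    grouped = (
        tcell_assays.assign(pos=tcell_assays["outcome"].eq("positive"))
        .groupby(["peptide", "allele"])["pos"]
        .agg(n_pos="sum", n_total="count")
        .reset_index()
    )
    grouped["n_neg"] = grouped["n_total"] - grouped["n_pos"]
    n_pos, n_neg = grouped["n_pos"], grouped["n_neg"]
    grouped["label"] = np.where(
        n_pos == 0, "nonimmunogenic", np.where(n_pos > n_neg, "immunogenic", "excluded")
    )
    labelled = grouped[grouped["label"] != "excluded"].copy()
    # discordant labels for the same peptide across alleles: drop all pairs
    discordant = (
        labelled.groupby("peptide")["label"].nunique().pipe(lambda s: set(s[s > 1].index))
    )
    if discordant:
        logger.info("excluding %d peptides with discordant labels across alleles",
                    len(discordant))
        labelled = labelled[~labelled["peptide"].isin(discordant)]
    return labelled[["peptide", "allele", "label", "n_pos", "n_neg"]].reset_index(drop=True)


def dataset1_binding_filter(pairs: pd.DataFrame, predictions: pd.DataFrame,
                            affinity_cutoff: float = 500.0,
                            rank_cutoff: float = 2.0) -> pd.DataFrame:
    """Keep pairs whose predicted binding passes affinity OR rank percentile.

    ``predictions`` has columns (peptide, allele, affinity_nm, rank_pct).
    Pairs without a prediction are dropped (logged).
    """
    merged = pairs.merge(predictions, on=["peptide", "allele"], how="left")
    missing = merged["affinity_nm"].isna()
    if missing.any():
        logger.info("dropping %d pairs without binding predictions", int(missing.sum()))
    keep = (~missing) & (
        (merged["affinity_nm"] < affinity_cutoff) | (merged["rank_pct"] < rank_cutoff)
    )
    return merged[keep][pairs.columns].reset_index(drop=True)


def dataset2_binding_filter(pairs: pd.DataFrame, binding_assays: pd.DataFrame,
                            min_binding_assays: int = 2, min_tcell_assays: int = 2,
                            positive_fraction: float = 0.60) -> pd.DataFrame:
    """Keep pairs with empirical binding evidence.

    A pair stays iff it has >= ``min_binding_assays`` MHC-binding assays with
    strictly more than ``positive_fraction`` of them positive, and
    >= ``min_tcell_assays`` T-cell assays (n_pos + n_neg from labelling).
    """
    stats = (
        binding_assays.assign(pos=binding_assays["outcome"].eq("positive"))
        .groupby(["peptide", "allele"])["pos"]
        .agg(n_binding="count", n_binding_pos="sum")
        .reset_index()
    )
    merged = pairs.merge(stats, on=["peptide", "allele"], how="left")
    merged[["n_binding", "n_binding_pos"]] = merged[["n_binding", "n_binding_pos"]].fillna(0)
    keep = (
        (merged["n_binding"] >= min_binding_assays)
        & (merged["n_binding_pos"] > positive_fraction * merged["n_binding"])
        & (merged["n_pos"] + merged["n_neg"] >= min_tcell_assays)
    )
    return merged[keep][pairs.columns].reset_index(drop=True)


# ---------------------------------------------------------------------------
# k-tuple distance and iterative redundancy removal
# ---------------------------------------------------------------------------

def ktuple_distance(a: str, b: str, k: int = 1) -> float:
    """k-tuple distance: 1 - shared k-mers / (min(len) - k + 1).

    Shared k-mers are counted as a multiset intersection. With k = 1 a
    distance of 0.5 between equal-length peptides corresponds to a maximum
    50% residue overlap.
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    if len(a) < k or len(b) < k:
        raise ValueError(f"sequences must be at least k={k} long")
    tuples_a = Counter(a[i : i + k] for i in range(len(a) - k + 1))
    tuples_b = Counter(b[i : i + k] for i in range(len(b) - k + 1))
    shared = sum((tuples_a & tuples_b).values())
    return 1.0 - shared / (min(len(a), len(b)) - k + 1)


def ktuple_distance_matrix(peptides: list[str], k: int = 1) -> np.ndarray:
    n = len(peptides)
    d = np.zeros((n, n))
    counters = [Counter(p[i : i + k] for i in range(len(p) - k + 1)) for p in peptides]
    denoms = [len(p) - k + 1 for p in peptides]
    for i in range(n):
        for j in range(i + 1, n):
            shared = sum((counters[i] & counters[j]).values())
            d[i, j] = d[j, i] = 1.0 - shared / min(denoms[i], denoms[j])
    return d


def iterative_dedup(peptides: list[str], threshold: float = 0.5, k: int = 1) -> list[str]:
    """Iteratively thin a peptide set until all pairwise distances >= threshold.

    Each iteration finds the pair(s) at the current minimum distance and
    removes, among their members, the peptide with the lowest mean distance
    to all other remaining peptides (ties broken by lexicographically
    smallest sequence); one peptide is removed per iteration. Deterministic.
    """
    remaining = list(peptides)
    while len(remaining) > 1:
        d = ktuple_distance_matrix(remaining, k=k)
        iu = np.triu_indices(len(remaining), k=1)
        dmin = d[iu].min()
        if dmin >= threshold:
            break
        members = set()
        for i, j in zip(*iu):
            if d[i, j] == dmin:
                members.update((i, j))
        mean_d = d.sum(axis=1) / (len(remaining) - 1)
        candidates = sorted(members, key=lambda i: (mean_d[i], remaining[i]))
        remaining.pop(candidates[0])
    return remaining


# ---------------------------------------------------------------------------
# Secondary anchors in the TCEM region
# ---------------------------------------------------------------------------

def position_entropies(peptides: list[str], base: str = "nats") -> np.ndarray:
    """Shannon entropy of the amino-acid distribution at each position.

    All peptides must share one length. ``base`` is ``"nats"`` (default) or
    ``"bits"``.
    """
    lengths = {len(p) for p in peptides}
    if len(lengths) != 1:
        raise ValueError("peptides must share one length for positional entropy")
    (length,) = lengths
    log = math.log if base == "nats" else math.log2
    out = np.zeros(length)
    for pos in range(length):
        counts = Counter(p[pos] for p in peptides)
        total = sum(counts.values())
        out[pos] = -sum((c / total) * log(c / total) for c in counts.values())
    return out


def anchor_positions(bound_peptides: dict[str, list[str]],
                     entropy_threshold: float = 0.8, min_peptides: int = 20,
                     base: str = "nats") -> dict[tuple[str, int], set[int]]:
    """Anchor positions per (allele, peptide length).

    A position anchors peptides to an allele if the positional amino-acid
    entropy of the allele's bound peptides is below ``entropy_threshold``.
    Alleles (per length) with fewer than ``min_peptides`` bound peptides are
    skipped with a warning. Positions are 1-based.
    """
    anchors: dict[tuple[str, int], set[int]] = {}
    for allele, peps in bound_peptides.items():
        by_len: dict[int, list[str]] = {}
        for p in peps:
            by_len.setdefault(len(p), []).append(p)
        for length, group in by_len.items():
            if len(group) < min_peptides:
                logger.warning("allele %s length %d: only %d bound peptides, skipped",
                               allele, length, len(group))
                continue
            ent = position_entropies(group, base=base)
            anchors[(allele, length)] = {
                i + 1 for i, e in enumerate(ent) if e < entropy_threshold
            }
    return anchors


def tcem_window(length: int) -> set[int]:
    """1-based TCEM positions for a 9- or 10-mer epitope."""
    if length == 9:
        return {4, 5, 6, 7, 8}
    if length == 10:
        return {5, 6, 7, 8, 9}
    raise ValueError(f"epitope length must be 9 or 10, got {length}")


def secondary_anchor_exclusion(curated: pd.DataFrame,
                               anchors: dict[tuple[str, int], set[int]]) -> pd.DataFrame:
    """Drop peptides binding only alleles with anchors inside the TCEM region.

    A peptide is excluded iff every allele it is reported bound by (with an
    available anchor map) has at least one anchor position inside the
    peptide's TCEM window.
    """
    def peptide_excluded(group: pd.DataFrame) -> bool:
        peptide = group["peptide"].iloc[0]
        window = tcem_window(len(peptide))
        verdicts = []
        for allele in group["allele"]:
            key = (allele, len(peptide))
            if key not in anchors:
                return False  # unknown anchors: keep
            verdicts.append(bool(anchors[key] & window))
        return bool(verdicts) and all(verdicts)

    excluded = {
        pep for pep, grp in curated.groupby("peptide") if peptide_excluded(grp)
    }
    if excluded:
        logger.info("secondary-anchor exclusion removed %d peptides", len(excluded))
    return curated[~curated["peptide"].isin(excluded)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Full curation pipeline
# ---------------------------------------------------------------------------

@dataclass
class CuratedDatasets:
    """Output of the two-dataset curation with overlap resolved."""

    dataset1: pd.DataFrame
    dataset2: pd.DataFrame

    def combined(self) -> pd.DataFrame:
        d1 = self.dataset1.assign(dataset=1)
        d2 = self.dataset2.assign(dataset=2)
        return pd.concat([d1, d2], ignore_index=True)


def curate(assays: pd.DataFrame, predictions: pd.DataFrame,
           dedup_threshold: float = 0.5, k: int = 1) -> CuratedDatasets:
    """Run the full two-dataset curation.

    ``assays`` holds both T-cell and MHC-binding assay records (column
    ``assay_kind`` in {tcell, mhc_binding}); ``predictions`` the binding
    prediction table. Peptides found in both datasets are kept only in
    dataset 2. Deterministic: rerunning on the same input is byte-identical.
    """
    filtered = filter_assays(assays)
    tcell = filtered[filtered["assay_kind"] == "tcell"]
    binding = filtered[filtered["assay_kind"] == "mhc_binding"]
    labelled = label_immunogenicity(tcell)

    ds1 = dataset1_binding_filter(labelled, predictions)
    ds2 = dataset2_binding_filter(labelled, binding)
    retained = set(iterative_dedup(sorted(ds2["peptide"].unique()),
                                   threshold=dedup_threshold, k=k))
    ds2 = ds2[ds2["peptide"].isin(retained)].reset_index(drop=True)
    overlap = set(ds1["peptide"]) & set(ds2["peptide"])
    ds1 = ds1[~ds1["peptide"].isin(overlap)].reset_index(drop=True)
    return CuratedDatasets(dataset1=ds1, dataset2=ds2)


def add_tcems(curated: pd.DataFrame) -> pd.DataFrame:
    """Annotate a curated table with each peptide's TCEM."""
    out = curated.copy()
    out["tcem"] = out["peptide"].map(extract_tcem)
    return out
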