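"""Normalized BLOSUM62 similarity, self-similarity scans, and TCR
cross-reactivity estimation.

Similarity between equal-length sequences a, b is the symmetric
geometric-mean normalization

    sim(a, b) = s(a, b) / sqrt(s(a, a) * s(b, b)),   s = sum of per-position
    BLOSUM62 entries,

so sim(a, a) = 1 and sim <= 1 always (BLOSUM62 diagonal entries are maximal
in their rows). Cross-reactivity of a TCR is summarized by the lowest
TCEM-to-cognate-TCEM similarity still compatible with TCR binding, estimated
from single-position mutational scans via ROC analysis and a cost-benefit
optimal cutpoint; the printed scan of the NY-ESO-1 / TCR C259 system puts it
at 0.61.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from sklearn.metrics import roc_curve

from .motifs import AMINO_ACIDS, ProteomeIndex, is_standard

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def _blosum62_matrix() -> np.ndarray:
    """20x20 BLOSUM62 over the standard alphabet, AMINO_ACIDS order."""
    table = substitution_matrices.load("BLOSUM62")
    m = np.empty((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            m[i, j] = table[a, b]
    return m


BLOSUM62 = _blosum62_matrix()
# The normalization guarantees sim <= 1 only because every diagonal entry is
# the maximum of its row; assert once at import.
assert all(BLOSUM62[i, i] == BLOSUM62[i].max() for i in range(20))


def encode(sequence: str) -> np.ndarray:
    if not is_standard(sequence):
        raise ValueError(f"non-standard letters in {sequence!r}")
    return np.array([_AA_INDEX[ch] for ch in sequence])


def _raw_score(a: np.ndarray, b: np.ndarray) -> float:
    return float(BLOSUM62[a, b].sum())


def geometric_mean_normalization(sab: float, saa: float, sbb: float) -> float:
    return sab / np.sqrt(saa * sbb)


def blosum_similarity(a: str, b: str,
                      normalization: Callable[[float, float, float], float]
                      = geometric_mean_normalization) -> float:
    """Normalized BLOSUM62 similarity of two equal-length sequences.

    Symmetric; equals 1 iff the sequences are identical. ``normalization``
    is pluggable (takes s(a,b), s(a,a), s(b,b)).
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    ea, eb = encode(a), encode(b)
    return float(normalization(_raw_score(ea, eb), _raw_score(ea, ea), _raw_score(eb, eb)))


def best_human_hit(peptide: str, index: ProteomeIndex) -> tuple[float, tuple[str, int]]:
    """Exhaustive ungapped best hit of a peptide against a proteome.

    Scans every window of the peptide's length in every protein (windows with
    non-standard letters skipped) and returns the maximum normalized
    similarity with one argmax location (first protein in input order, then
    first position, 1-based). Exhaustive by construction, hence at least as
    sensitive as a heuristic aligner.
    """
    ep = encode(peptide)
    length = len(peptide)
    self_pep = _raw_score(ep, ep)
    diag = np.diag(BLOSUM62)
    best = -np.inf
    best_loc: tuple[str, int] | None = None
    for pid, seq in index.proteins:
        if len(seq) < length:
            continue
        try:
            es = encode(seq)
        except ValueError:
            es = np.array([_AA_INDEX.get(ch, -1) for ch in seq])
        n_win = len(seq) - length + 1
        win = np.lib.stride_tricks.sliding_window_view(es, length)[:n_win]
        valid = (win >= 0).all(axis=1)
        if not valid.any():
            continue
        w = win[valid]
        scores = BLOSUM62[np.broadcast_to(ep, w.shape), w].sum(axis=1)
        selfs = diag[w].sum(axis=1)
        sims = scores / np.sqrt(self_pep * selfs)
        i = int(np.argmax(sims))
        if sims[i] > best:
            best = float(sims[i])
            best_loc = (pid, int(np.nonzero(valid)[0][i]) + 1)
    if best_loc is None:
        raise ValueError("no proteome window long enough for the peptide")
    return best, best_loc


# ---------------------------------------------------------------------------
# TCR mutational-scan classification
# ---------------------------------------------------------------------------

def label_binders(scan: pd.DataFrame, cutoff: float = 0.10) -> pd.Series:
    """Binary binder labels from a TCR scan: binder iff relative binding is
    at least ``cutoff`` (10% of the original epitope's TCR binding by
    default; below that, T-cell activation is negligible)."""
    return scan["relative_binding"] >= cutoff


@dataclass
class RocResult:
    auc: float
    points: pd.DataFrame  # columns fpr, tpr, cutoff (observed scores only)
    optimal_cutoff: float | None = None


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> RocResult:
    """ROC curve and trapezoid AUC with equal scores grouped.

    ``labels`` True marks positives. Raises if only one class is present.
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.all() or (~labels).all():
        raise ValueError("both classes must be present for a ROC curve")
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    # drop the synthetic +inf threshold point; keep observed scores only
    finite = np.isfinite(thresholds)
    points = pd.DataFrame({"fpr": fpr[finite], "tpr": tpr[finite],
                           "cutoff": thresholds[finite]})
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(auc=auc, points=points)


def optimal_cutpoint_costbenefit(roc: RocResult, cost_ratio: float = 1.0,
                                 prevalence: float | None = None) -> float:
    """Cost-benefit optimal ROC cutpoint.

    Maximizes Se - m * (1 - Sp) with slope m = cost_ratio * (1 - p) / p over
    the observed score cutoffs (classification rule: score >= cutoff is
    positive). With cost_ratio 1 and p = 0.5 this reduces to maximizing
    Youden's J. Ties return the smallest maximizing cutoff. ``prevalence``
    defaults to the sample prevalence implied by the ROC extremes, which the
    caller should pass explicitly when it differs.
    """
    pts = roc.points
    if prevalence is None:
        prevalence = 0.5
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    m = cost_ratio * (1 - prevalence) / prevalence
    objective = pts["tpr"] - m * pts["fpr"]
    best = objective.max()
    winners = pts.loc[objective == best, "cutoff"]
    cutoff = float(winners.min())
    roc.optimal_cutoff = cutoff
    return cutoff


def estimate_crossreactivity_cutoff(scan: pd.DataFrame, binder_cutoff: float = 0.10,
                                    cost_ratio: float = 1.0,
                                    prevalence: float | None = None
                                    ) -> tuple[RocResult, float]:
    """Full scan -> cutoff pipeline: label binders, ROC on TCEM similarity,
    cost-benefit cutpoint. ``scan`` needs columns similarity and
    relative_binding. Prevalence defaults to the scan's binder fraction."""
    labels = label_binders(scan, binder_cutoff)
    if prevalence is None:
        prevalence = float(labels.mean())
    roc = roc_auc(scan["similarity"].to_numpy(), labels.to_numpy())
    cutoff = optimal_cutpoint_costbenefit(roc, cost_ratio, prevalence)
    return roc, cutoff


# ---------------------------------------------------------------------------
# Group-against-group cross-reactivity scan
# ---------------------------------------------------------------------------

@dataclass
class CrossreactivityResult:
    """Per-group1-motif fractions of group 2 within cross-reactive reach."""

    fractions: pd.Series  # index group1 motifs, value fraction of group2
    n_pairs: int  # total similarity values computed by the streaming scan

    def summary(self) -> dict[str, float]:
        return {
            "min": float(self.fractions.min()),
            "median": float(self.fractions.median()),
            "max": float(self.fractions.max()),
        }


def crossreactivity_scan(group1: Iterable[str], group2: Iterable[str],
                         cutoff: float) -> CrossreactivityResult:
    """For every motif in group 1, the fraction of group 2 motifs with
    normalized similarity >= cutoff (a T cell specific for the group-2 motif
    could plausibly recognize the group-1 motif).

    Streams over group 1 against a vectorized encoding of group 2, counting
    all |group1| x |group2| pairs without materializing them.
    """
    group1 = list(group1)
    group2 = list(group2)
    if not group1 or not group2:
        raise ValueError("both motif groups must be nonempty")
    enc2 = np.array([[_AA_INDEX[ch] for ch in m] for m in group2])
    self2 = np.diag(BLOSUM62)[enc2].sum(axis=1)
    n2 = len(group2)
    fractions = {}
    n_pairs = 0
    for motif in group1:
        e1 = encode(motif)
        scores = BLOSUM62[np.broadcast_to(e1, enc2.shape), enc2].sum(axis=1)
        sims = scores / np.sqrt(_raw_score(e1, e1) * self2)
        n_pairs += n2
        fractions[motif] = float((sims >= cutoff).sum() / n2)
    return CrossreactivityResult(fractions=pd.Series(fractions), n_pairs=n_pairs)


# ---------------------------------------------------------------------------
# Similarity-stratified immunogenicity ratio (25-bin analysis)
# ---------------------------------------------------------------------------

def similarity_bins(similarities: pd.Series, immunogenic: pd.Series,
                    n_bins: int = 25, spline_smoothing: float | None = None
                    ) -> pd.DataFrame:
    """Equal-count similarity bins with immunogenic:nonimmunogenic ratios.

    Peptides are ranked by best-human-hit similarity and cut into ``n_bins``
    equal-count groups; each bin reports its mean similarity and the ratio of
    immunogenic to nonimmunogenic peptides (NaN and flagged when a bin has no
    nonimmunogenic member). A cubic smoothing spline is fitted over
    (mean similarity, ratio) and its fitted values returned, along with a
    marker for the bin with the highest ratio.
    """
    if len(similarities) < n_bins:
        raise ValueError("fewer peptides than bins")
    df = pd.DataFrame({"sim": similarities, "imm": immunogenic.astype(bool)})
    ranks = df["sim"].rank(method="first")
    df["bin"] = pd.qcut(ranks, n_bins, labels=False)
    rows = []
    for b, grp in df.groupby("bin"):
        n_imm = int(grp["imm"].sum())
        n_non = int((~grp["imm"]).sum())
        rows.append({
            "bin": int(b),
            "mean_similarity": float(grp["sim"].mean()),
            "n_immunogenic": n_imm,
            "n_nonimmunogenic": n_non,
            "ratio": n_imm / n_non if n_non else np.nan,
        })
    out = pd.DataFrame(rows).sort_values("mean_similarity").reset_index(drop=True)
    defined = out.dropna(subset=["ratio"])
    if len(defined) >= 4 and defined["mean_similarity"].nunique() >= 4:
        from scipy.interpolate import UnivariateSpline

        x = defined["mean_similarity"].to_numpy()
        y = defined["ratio"].to_numpy()
        s = spline_smoothing if spline_smoothing is not None else len(x) * np.var(y) * 0.5
        spline = UnivariateSpline(x, y, k=3, s=s)
        out["spline"] = spline(out["mean_similarity"])
    else:
        out["spline"] = np.nan
    argmax = out["ratio"].idxmax()
    out["is_peak"] = out.index == argmax
    return out
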