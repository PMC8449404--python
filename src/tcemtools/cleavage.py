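"""Thymo- and immunoproteasomal cleavage scoring cascade.

cTECs generate their positively selecting peptides with the thymoproteasome,
which (unlike the immunoproteasome) cleaves poorly after hydrophobic
residues. From published amino-acid prevalences at the five positions on
each side of observed cleavage sites, the cascade is:

1. ``c[i, j]`` -- preference score of amino acid j at position
   i in {-5..-1, +1..+5} around a cleavage site: prevalence divided by the
   amino acid's background fraction in the digested substrates.
2. ``C`` -- per inter-residue site, the median of the applicable c values
   (position -1 is the residue N-terminal of the site, +1 the residue
   C-terminal of it).
3. ``Cbar`` -- per 9-mer window, the mean of C at the site before the
   window's first residue and the site after its last residue: the chance
   the peptide is excised intact.
4. per-TCEM score -- the median Cbar over all proteome windows exposing the
   motif.

A uniform preference table propagates to every score being exactly 1, which
is the cascade's main internal consistency check.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .motifs import AMINO_ACIDS, ProteomeIndex, WINDOW_LENGTH

#: Flanking positions around a cleavage site, N-terminal side negative.
POSITIONS = (-5, -4, -3, -2, -1, 1, 2, 3, 4, 5)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def preference_scores(prevalence: pd.DataFrame, background: pd.Series) -> pd.DataFrame:
    """c[i, j] = prevalence of amino acid j at flank position i / background_j.

    Parameters
    ----------
    prevalence : DataFrame indexed by position (-5..-1, 1..5), columns the
        20 amino acids, rows summing to ~1.
    background : Series over the 20 amino acids summing to ~1 (amino-acid
        composition of the digested substrate proteins).
    """
    prevalence = prevalence.reindex(index=list(POSITIONS), columns=list(AMINO_ACIDS))
    background = background.reindex(list(AMINO_ACIDS))
    bad = background.index[(background <= 0) & (prevalence > 0).any(axis=0)]
    if len(bad):
        pos = prevalence.index[(prevalence[bad[0]] > 0)][0]
        raise ValueError(
            f"zero background for amino acid {bad[0]!r} with nonzero prevalence "
            f"at position {pos}"
        )
    return prevalence.div(background, axis=1)


def site_cleavage_scores(protein: str, scores: pd.DataFrame) -> np.ndarray:
    """Cleavage probability score C at each inter-residue site of a protein.

    Site s (1-based, s in 1..L-1) lies between residues s and s+1. For each
    site the c values of the residues at flank positions -5..-1 (residues
    s-4..s) and +1..+5 (residues s+1..s+5) that exist within the protein are
    gathered and C is their median; sites near a terminus simply use the
    available positions. Returns an array of length L-1 (NaN where no
    applicable value exists, e.g. non-standard residues throughout).
    """
    length = len(protein)
    if length < 2:
        raise ValueError("protein must have length >= 2")
    c_matrix = scores.reindex(index=list(POSITIONS), columns=list(AMINO_ACIDS)).to_numpy()
    residues = np.array([_AA_INDEX.get(ch, -1) for ch in protein])
    n_sites = length - 1
    gathered = np.full((n_sites, len(POSITIONS)), np.nan)
    sites = np.arange(1, length)  # 1-based site ids
    for col, pos in enumerate(POSITIONS):
        # residue occupying flank position `pos` relative to each site
        res_idx = sites + pos if pos > 0 else sites + pos + 1  # 1-based
        valid = (res_idx >= 1) & (res_idx <= length)
        aa = residues[res_idx[valid] - 1]
        ok = aa >= 0
        rows = np.nonzero(valid)[0][ok]
        gathered[rows, col] = c_matrix[pos_row(pos), aa[ok]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        return np.nanmedian(gathered, axis=1)


def pos_row(pos: int) -> int:
    """Row index of a flank position in the POSITIONS ordering."""
    return POSITIONS.index(pos)


def formation_scores(protein: str, site_scores: np.ndarray,
                     terminal_mode: str = "exclude") -> np.ndarray:
    """Peptide formation score Cbar for each 9-mer window of a protein.

    The window starting at residue p (1-based) needs cleavage at site p-1
    (before its N terminus) and site p+8 (after its C terminus);
    Cbar = (C[p-1] + C[p+8]) / 2. With ``terminal_mode="exclude"`` (default)
    the first and last windows, which lack an interior flanking site, are NaN
    (a protein terminus needs no cleavage, so scoring it is unfounded); with
    ``"terminus-one"`` the missing site contributes C = 1.

    Returns an array of length L-8 aligned with window starts.
    """
    length = len(protein)
    if length < WINDOW_LENGTH:
        raise ValueError("protein shorter than one 9-mer window")
    if terminal_mode not in ("exclude", "terminus-one"):
        raise ValueError(f"unknown terminal_mode: {terminal_mode!r}")
    n_windows = length - WINDOW_LENGTH + 1
    out = np.full(n_windows, np.nan)
    for p in range(1, n_windows + 1):
        left = site_scores[p - 2] if p >= 2 else np.nan
        right = site_scores[p + 7] if p + 8 <= length - 1 else np.nan
        if np.isnan(left) or np.isnan(right):
            if terminal_mode == "exclude":
                continue
            left = 1.0 if np.isnan(left) else left
            right = 1.0 if np.isnan(right) else right
        out[p - 1] = 0.5 * (left + right)
    return out


def proteome_formation_scores(index: ProteomeIndex, scores: pd.DataFrame,
                              terminal_mode: str = "exclude") -> dict[str, np.ndarray]:
    """Cbar arrays keyed by protein id for every protein long enough."""
    result = {}
    for pid, seq in index.proteins:
        if len(seq) < WINDOW_LENGTH:
            continue
        sites = site_cleavage_scores(seq, scores)
        result[pid] = formation_scores(seq, sites, terminal_mode)
    return result


def tcem_cleavage_scores(index: ProteomeIndex, scores: pd.DataFrame,
                         terminal_mode: str = "exclude") -> pd.DataFrame:
    """Per-motif cleavage score: median Cbar over windows exposing the motif.

    Returns a DataFrame indexed by motif with columns (score, n_windows);
    motifs with no window carrying a defined Cbar get NaN score and 0.
    """
    formation = proteome_formation_scores(index, scores, terminal_mode)
    values: dict[str, list[float]] = {}
    for motif, occ in index.occurrences.items():
        values.setdefault(motif, [])
        for pid, start in occ:
            cbar = formation.get(pid)
            if cbar is None:
                continue
            v = cbar[start - 1]
            if not np.isnan(v):
                values[motif].append(float(v))
    rows = {
        m: (float(np.median(v)) if v else np.nan, len(v)) for m, v in values.items()
    }
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["score", "n_windows"])
    out.index.name = "motif"
    return out


def tcem_cleavage_score(index: ProteomeIndex, formation: dict[str, np.ndarray],
                        motif: str) -> float:
    """Median Cbar for one motif given precomputed per-protein Cbar arrays."""
    vals = [
        float(formation[pid][start - 1])
        for pid, start in index.occurrences.get(motif, [])
        if pid in formation and not np.isnan(formation[pid][start - 1])
    ]
    if not vals:
        return float("nan")
    return float(np.median(vals))


def stratify_cleavage(scores: pd.Series, quantile: float = 0.25) -> pd.Series:
    """Label scores ``low`` (strictly below the first quartile) or ``normal``.

    The quartile uses linear interpolation (numpy default, type 7); values
    equal to Q1 are ``normal``.
    """
    scores = scores.dropna()
    if len(scores) < 4:
        raise ValueError("need at least 4 defined scores")
    q = float(np.quantile(scores, quantile))
    if scores.min() == scores.max():
        warnings.warn("constant cleavage scores: no low group")
        return pd.Series("normal", index=scores.index)
    return pd.Series(np.where(scores < q, "low", "normal"), index=scores.index)
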