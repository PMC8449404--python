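"""Statistical layer for the immunogenicity association analyses.

Contingency odds ratios with Fisher exact tests, rank tests, lowess
probability curves, multivariate logistic models, attribute additivity, and
the amino-acid leave-one-out robustness sweep. Everything is two-sided and
uncorrected by default (a Benjamini-Hochberg switch is provided for users);
all procedures are deterministic given their inputs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .motifs import AMINO_ACIDS

logger = logging.getLogger(__name__)

#: Kyte-Doolittle hydropathy index.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


def fisher_or(table) -> tuple[float, float]:
    """Cross-product odds ratio and two-sided Fisher exact p for a 2x2 table.

    ``table`` is [[a, b], [c, d]]; OR = (a*d)/(b*c), reported as inf or 0
    with a log note when a zero cell makes it degenerate.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("cell counts must be nonnegative")
    if t.sum() == 0:
        raise ValueError("empty table")
    a, b = t[0]
    c, d = t[1]
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
        logger.info("degenerate 2x2 table (zero cell): OR reported as %s", odds)
    else:
        odds = (a * d) / (b * c)
    _, p = sps.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def exposure_or(exposure, outcome) -> tuple[float, float]:
    """Odds ratio of a binary outcome given a binary exposure.

    Builds the 2x2 table (exposure x outcome) and delegates to
    :func:`fisher_or`; OR > 1 means the outcome is enriched among exposed.
    """
    exposure = np.asarray(exposure, dtype=bool)
    outcome = np.asarray(outcome, dtype=bool)
    table = [
        [int((exposure & outcome).sum()), int((exposure & ~outcome).sum())],
        [int((~exposure & outcome).sum()), int((~exposure & ~outcome).sum())],
    ]
    return fisher_or(table)


def ranksum_test(x, y, paired: bool = False) -> dict[str, float]:
    """Two-sided rank test with effect direction.

    Unpaired: Wilcoxon rank-sum (Mann-Whitney); paired: signed-rank on the
    differences (identical vectors give p = 1). Direction is the sign of the
    median difference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need at least 3 observations per group")
    if paired:
        if len(x) != len(y):
            raise ValueError("paired samples must have equal length")
        diff = x - y
        if (diff == 0).all():
            return {"p_value": 1.0, "direction": 0.0}
        res = sps.wilcoxon(x, y, alternative="two-sided")
        direction = float(np.sign(np.median(diff)))
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided")
        direction = float(np.sign(np.median(x) - np.median(y)))
    return {"p_value": float(res.pvalue), "direction": direction}


def lowess_curve(x, y, frac: float = 2 / 3, it: int = 3) -> pd.DataFrame:
    """Locally weighted regression of a binary/continuous response on x.

    Used for the immunogenicity-vs-expression-percentile curves. Returns a
    DataFrame (x, fitted) sorted by x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 30:
        raise ValueError("need at least 30 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant x")
    from statsmodels.nonparametric.smoothers_lowess import lowess

    fitted = lowess(y, x, frac=frac, it=it, return_sorted=True)
    return pd.DataFrame({"x": fitted[:, 0], "fitted": fitted[:, 1]})


def fit_logistic(data: pd.DataFrame, response: str, covariates: list[str],
                 categorical: bool = True) -> pd.DataFrame:
    """Maximum-likelihood logistic regression with Wald two-sided p-values.

    Categorical covariates are dummy-coded against their first level.
    Raises on non-convergence or (quasi-)separation, reported with a
    diagnostic.
    """
    y = data[response].astype(float)
    if y.nunique() < 2:
        raise ValueError("response has a single class")
    if categorical:
        X = pd.get_dummies(data[covariates], drop_first=True, dtype=float)
    else:
        X = data[covariates].astype(float)
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=False, maxiter=200)
    except (sm.tools.sm_exceptions.PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ValueError(f"separation or singular fit: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise ValueError("logistic fit did not converge")
    if np.abs(fit.params).max() > 15:
        raise ValueError("quasi-separation suspected: extreme coefficient")
    out = pd.DataFrame({
        "coefficient": fit.params,
        "std_err": fit.bse,
        "z": fit.tvalues,
        "p_value": fit.pvalues,
    })
    out.index.name = "term"
    return out


def attribute_additivity(data: pd.DataFrame, label_col: str = "immunogenic",
                         low_cols: tuple[str, ...] = ("low_frequency", "low_expression",
                                                      "low_cleavage")) -> pd.DataFrame:
    """Immunogenic fraction stratified by the number of low TCEM attributes.

    Strata are the counts 0..len(low_cols) of attributes flagged low; the
    trend across strata is tested with a logistic regression of the label on
    the count (Wald two-sided p). Empty strata are omitted.
    """
    n_low = data[list(low_cols)].astype(bool).sum(axis=1)
    label = data[label_col].astype(bool)
    rows = []
    for k, grp in label.groupby(n_low):
        rows.append({"n_low_attributes": int(k), "n_peptides": len(grp),
                     "immunogenic_fraction": float(grp.mean())})
    out = pd.DataFrame(rows).sort_values("n_low_attributes").reset_index(drop=True)
    if n_low.nunique() > 1 and label.nunique() > 1:
        X = sm.add_constant(n_low.astype(float))
        with np.errstate(all="ignore"):
            fit = sm.Logit(label.astype(float), X).fit(disp=False)
        out.attrs["trend_p"] = float(fit.pvalues.iloc[1])
        out.attrs["trend_coefficient"] = float(fit.params.iloc[1])
    return out


def aa_enrichment(motifs: pd.Series, immunogenic: pd.Series) -> pd.DataFrame:
    """Per-amino-acid enrichment in immunogenic vs nonimmunogenic motifs.

    For each standard amino acid, a 2x2 Fisher test of motif-contains-letter
    against the immunogenicity label; the odds ratio is oriented so OR > 1
    means enrichment among immunogenic motifs. Letters absent from all
    motifs get NaN and a flag.
    """
    imm = immunogenic.astype(bool)
    rows = []
    for aa in AMINO_ACIDS:
        has = motifs.str.contains(aa, regex=False)
        a = int((has & imm).sum())
        b = int((has & ~imm).sum())
        c = int((~has & imm).sum())
        d = int((~has & ~imm).sum())
        if a + b == 0:
            rows.append({"amino_acid": aa, "odds_ratio": np.nan, "p_value": np.nan,
                         "n_containing": 0, "flag": "absent"})
            continue
        odds, p = fisher_or([[a, b], [c, d]])
        rows.append({"amino_acid": aa, "odds_ratio": odds, "p_value": p,
                     "n_containing": a + b, "flag": ""})
    return pd.DataFrame(rows)


def leave_one_out(motifs: pd.Series, immunogenic: pd.Series,
                  attribute_low: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Re-run the headline attribute tests excluding motifs containing each
    amino acid in turn.

    ``attribute_low`` holds one boolean column per attribute (True = low /
    rare) aligned with ``motifs``. For every amino acid, Fisher tests of each
    attribute against the label are recomputed on the motifs not containing
    it; the output records the ORs, p-values and whether significance at
    ``alpha`` is retained.
    """
    imm = immunogenic.astype(bool)
    rows = []
    for aa in AMINO_ACIDS:
        keep = ~motifs.str.contains(aa, regex=False)
        row: dict = {"excluded_amino_acid": aa, "n_retained": int(keep.sum())}
        for col in attribute_low.columns:
            low = attribute_low[col].astype(bool)[keep]
            lab = imm[keep]
            table = [
                [int((low & lab).sum()), int((low & ~lab).sum())],
                [int((~low & lab).sum()), int((~low & ~lab).sum())],
            ]
            if min(sum(table[0]), sum(table[1])) == 0 or lab.nunique() < 2:
                row[f"{col}_or"] = np.nan
                row[f"{col}_p"] = np.nan
                row[f"{col}_significant"] = False
                continue
            odds, p = fisher_or(table)
            row[f"{col}_or"] = odds
            row[f"{col}_p"] = p
            row[f"{col}_significant"] = p < alpha
        rows.append(row)
    return pd.DataFrame(rows)


def tcem_hydrophobicity(motif: str, scale: dict[str, float] | None = None) -> float:
    """Mean per-residue hydrophobicity of a motif (Kyte-Doolittle default)."""
    scale = scale or KYTE_DOOLITTLE
    try:
        return float(np.mean([scale[ch] for ch in motif]))
    except KeyError as exc:
        raise ValueError(f"non-standard letter in motif {motif!r}") from exc


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (optional; the headline analyses are uncorrected)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values), method="fdr_bh")[1]
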