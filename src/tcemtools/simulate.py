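"""Synthetic-data generators for every pipeline input.

Each generator is a pure function of (config, seed) and emits, next to its
data, a ``ground_truth`` dict holding the planted parameters so recovery
tests can score the pipeline without re-deriving anything. Formats match the
real-input readers (FASTA records, assay/prediction/recognition tables), so
downstream code cannot distinguish synthetic from real inputs.

What is emulated, and what is not: proteomes are i.i.d.-residue (no homology
or domain structure) so motif counts stay analytically controllable;
expression counts are negative-binomial with a planted housekeeping set;
cleavage preference tables plant the thymoproteasome's hydrophobic cleavage
deficit at position -1; immunogenicity is a logistic function of the three
TCEM attributes with a bimodal expression term; TCR scans decay
exponentially in motif similarity; repertoires are Bernoulli with a planted
np recognition penalty. Real HLA motifs, codon structure, and the true human
amino-acid composition are deliberately not mimicked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import NpProfile
from .motifs import AMINO_ACIDS, MOTIF_LENGTH, ProteomeIndex, extract_tcem

#: Residues treated as hydrophobic for the planted thymoproteasomal cleavage
#: deficit (Kyte-Doolittle hydropathy > 0).
HYDROPHOBIC = "ACFILMV"

_AA = np.array(list(AMINO_ACIDS))

#: Default residue composition: the six residues most common in human
#: proteins carry most of the mass. The skew reproduces, at desk scale, the
#: long-tailed TCEM frequency distribution of the human proteome (about 3-4
#: 9-mer windows per observed motif on average), which a uniform composition
#: cannot: with 20 equiprobable letters, desk-scale proteomes would make
#: every motif a singleton and empty the nonrare (count >= 4) class.
DEFAULT_AA_FREQUENCIES: dict[str, float] = {
    **{aa: 0.15 for aa in "ALSGVE"},
    **{aa: 0.10 / 14 for aa in "CDFHIKMNPQRTWY"},
}


@dataclass
class SimulationConfig:
    """Default study conditions for all generators.

    Sizes mirror the emulated studies where they print one (296 repertoire
    peptides, 27 individuals pre-filter, 6 risk vs 7 protective allele
    groups, 50 pathogens in the full design); the remaining values are
    desk-scale choices documented in the methods note.
    """

    seed: int = 0
    # proteome
    n_proteins: int = 120
    mean_protein_length: int = 400
    amino_acid_frequencies: dict[str, float] | None = field(
        default_factory=lambda: dict(DEFAULT_AA_FREQUENCIES))
    # expression
    n_samples: int = 5
    housekeeping_fraction: float = 0.05
    housekeeping_fold: float = 10.0
    nb_dispersion: float = 0.2
    # cleavage
    hydrophobic_deficit: float = 0.2  # theta; 1 = no deficit
    cleavage_jitter: float = 0.15  # positional log-scale spread, scaled by 1 - theta
    # immunogenicity effects (logit scale)
    beta0: float = -0.5
    beta_frequency: float = 1.0
    beta_expression: float = 1.5
    beta_cleavage: float = 0.8
    # TCR scan: lambda = 6 puts the analytic 10%-binding similarity cutoff
    # at 1 + ln(0.1)/6 ~= 0.616, inside the single-substitution sim range
    scan_lambda: float = 6.0
    scan_sigma: float = 0.0
    # repertoire
    n_individuals: int = 27
    n_repertoire_peptides: int = 296
    recognition_base_rate: float = 0.15
    np_penalty: float = 0.5
    min_recognized: int = 20
    # pathogens / associations
    n_risk_groups: int = 6
    n_protective_groups: int = 7


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _aa_probs(freqs: dict[str, float] | None) -> np.ndarray:
    if freqs is None:
        return np.full(20, 1 / 20)
    p = np.array([freqs.get(aa, 0.0) for aa in AMINO_ACIDS], dtype=float)
    if p.sum() <= 0:
        raise ValueError("amino-acid frequencies sum to zero")
    return p / p.sum()


def _random_sequence(rng: np.random.Generator, length: int, probs: np.ndarray) -> str:
    return "".join(rng.choice(_AA, size=length, p=probs))


# ---------------------------------------------------------------------------
# Proteomes
# ---------------------------------------------------------------------------

def gen_proteome(config: SimulationConfig, seed: int | None = None,
                 planted_motifs: dict[str, int] | None = None
                 ) -> tuple[list[tuple[str, str]], dict]:
    """Random proteome with optional motifs planted at exact TCEM counts.

    Proteins draw i.i.d. residues from the configured frequencies with
    Poisson-distributed lengths. Each planted motif is inserted the requested
    number of times with full 9-mer context (three residues upstream, one
    downstream) in dedicated carrier proteins; background proteins that
    happen to expose a planted motif are resampled, so the index count of a
    planted motif equals exactly its requested count.
    """
    rng = _rng(config.seed if seed is None else seed)
    probs = _aa_probs(config.amino_acid_frequencies)
    planted_motifs = planted_motifs or {}
    planted_set = set(planted_motifs)

    def exposes_planted(seq: str) -> bool:
        for start in range(len(seq) - 8):
            if seq[start + 3 : start + 8] in planted_set:
                return True
        return False

    records: list[tuple[str, str]] = []
    for i in range(config.n_proteins):
        length = max(9, int(rng.poisson(config.mean_protein_length)))
        seq = _random_sequence(rng, length, probs)
        for _ in range(200):
            if not planted_set or not exposes_planted(seq):
                break
            seq = _random_sequence(rng, length, probs)
        else:
            raise RuntimeError("could not sample a background protein avoiding "
                               "the planted motifs")
        records.append((f"SYNP{i:05d}", seq))
    for m, (motif, count) in enumerate(sorted(planted_motifs.items())):
        for rep in range(count):
            context = _random_sequence(rng, 3, probs) + motif + _random_sequence(rng, 1, probs)
            for _ in range(200):
                if sum(context[s + 3 : s + 8] in planted_set
                       for s in range(len(context) - 8)) == 1:
                    break
                context = (_random_sequence(rng, 3, probs) + motif
                           + _random_sequence(rng, 1, probs))
            records.append((f"SYNPLANT{m:03d}_{rep:03d}", context))
    ground_truth = {"planted_motifs": dict(planted_motifs),
                    "n_proteins": len(records)}
    return records, ground_truth


def write_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for pid, seq in records:
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def gen_expression(config: SimulationConfig, gene_ids: list[str],
                   seed: int | None = None
                   ) -> tuple[pd.DataFrame, pd.Series, list[str], dict]:
    """Negative-binomial count matrix with a planted housekeeping set.

    A ``housekeeping_fraction`` of genes gets its mean multiplied by
    ``housekeeping_fold``. Returns (counts genes x samples, exon lengths in
    bases, housekeeping gene list, ground truth with per-gene expected
    expression).
    """
    rng = _rng(config.seed + 1 if seed is None else seed)
    n_genes = len(gene_ids)
    base_mean = rng.lognormal(mean=np.log(100), sigma=1.0, size=n_genes)
    n_hk = int(round(config.housekeeping_fraction * n_genes))
    hk_idx = rng.choice(n_genes, size=n_hk, replace=False)
    mean = base_mean.copy()
    mean[hk_idx] *= config.housekeeping_fold
    # NB with dispersion phi: var = mu + phi mu^2, gamma-Poisson mixture
    phi = config.nb_dispersion
    samples = {}
    for s in range(config.n_samples):
        lam = rng.gamma(shape=1 / phi, scale=mean * phi)
        samples[f"cTEC_{s + 1}"] = rng.poisson(lam)
    counts = pd.DataFrame(samples, index=pd.Index(gene_ids, name="gene_id"))
    exon_length = pd.Series(rng.integers(500, 5000, size=n_genes), index=counts.index,
                            name="exon_length")
    housekeeping = [gene_ids[i] for i in sorted(hk_idx)]
    ground_truth = {
        "expected_mean": pd.Series(mean, index=counts.index),
        "housekeeping": housekeeping,
        "housekeeping_fold": config.housekeeping_fold,
    }
    return counts, exon_length, housekeeping, ground_truth


# ---------------------------------------------------------------------------
# Cleavage preference tables
# ---------------------------------------------------------------------------

def gen_cleavage_tables(config: SimulationConfig, seed: int | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, dict]:
    """Thymo- and immunoproteasomal preference tables with a planted deficit.

    Background is the uniform composition. The immunoproteasome table equals
    the background at every flank position (all preference scores 1). The
    thymoproteasome table multiplies the position -1 prevalence of
    hydrophobic residues by theta = ``hydrophobic_deficit``, perturbs every
    position by lognormal jitter of scale ``cleavage_jitter * (1 - theta)``
    (real digestion profiles deviate at all positions; without this spread a
    single deviating flank position would be absorbed by the 10-value site
    median), and renormalizes. theta = 1 reproduces the uniform table
    exactly, for both proteasomes.
    """
    from .cleavage import POSITIONS

    rng = _rng(config.seed + 7 if seed is None else seed)
    theta = config.hydrophobic_deficit
    background = pd.Series(1 / 20, index=pd.Index(list(AMINO_ACIDS), name="amino_acid"),
                           name="background")
    uniform = pd.DataFrame(
        np.full((len(POSITIONS), 20), 1 / 20),
        index=pd.Index(list(POSITIONS), name="position"), columns=list(AMINO_ACIDS),
    )
    immuno = uniform.copy()
    if theta == 1.0:
        thymo = uniform.copy()  # exactly uniform: no deficit, no jitter
    else:
        jitter = np.exp(rng.normal(0.0, config.cleavage_jitter * (1 - theta),
                                   size=uniform.shape))
        thymo = uniform * jitter
        for aa in HYDROPHOBIC:
            thymo.loc[-1, aa] *= theta
        thymo = thymo.div(thymo.sum(axis=1), axis=0)
    ground_truth = {"theta": theta, "hydrophobic": HYDROPHOBIC}
    return thymo, immuno, background, ground_truth


# ---------------------------------------------------------------------------
# Toy binding predictor
# ---------------------------------------------------------------------------

@dataclass
class ToyBindingPredictor:
    """Position-weight-matrix stand-in for an MHC binding predictor.

    Each allele prefers a small residue set at anchor positions 2 and 9 of a
    9-mer. Peptides matching both anchors get strong predicted binding
    (affinity < 50 nM, rank < 0.5%), one anchor intermediate, none weak --
    enough to produce realistic allele-specific presented sets without any
    external tool. Purely synthetic.
    """

    anchors: dict[str, tuple[frozenset[str], frozenset[str]]] = field(default_factory=dict)

    @classmethod
    def make(cls, alleles: list[str], rng: np.random.Generator,
             anchor_set_size: int = 4) -> "ToyBindingPredictor":
        anchors = {}
        for allele in alleles:
            p2 = frozenset(rng.choice(_AA, size=anchor_set_size, replace=False))
            p9 = frozenset(rng.choice(_AA, size=anchor_set_size, replace=False))
            anchors[allele] = (p2, p9)
        return cls(anchors=anchors)

    def predict(self, peptides: list[str], rng: np.random.Generator) -> pd.DataFrame:
        """Prediction table (peptide, allele, affinity_nm, rank_pct)."""
        rows = []
        for allele, (p2, p9) in self.anchors.items():
            for pep in peptides:
                matches = int(pep[1] in p2) + int(pep[-1] in p9)
                if matches == 2:
                    aff = rng.uniform(5, 45)
                    rank = rng.uniform(0.05, 0.45)
                elif matches == 1:
                    aff = rng.uniform(100, 450)
                    rank = rng.uniform(0.6, 1.9)
                else:
                    aff = rng.uniform(1000, 20000)
                    rank = rng.uniform(5, 60)
                rows.append((pep, allele, aff, rank))
        return pd.DataFrame(rows, columns=["peptide", "allele", "affinity_nm", "rank_pct"])


# ---------------------------------------------------------------------------
# Immunogenicity assay datasets
# ---------------------------------------------------------------------------

def expression_bump(percentile: np.ndarray) -> np.ndarray:
    """Bimodal expression effect: a smooth bump peaked at the middle of the
    expression percentile range (both low and overly high expression reduce
    immunogenicity -- missing positive selection vs tolerance)."""
    return 1.0 - ((percentile - 0.5) / 0.5) ** 2


def gen_assay_dataset(config: SimulationConfig, attributes: pd.DataFrame,
                      n_peptides: int = 2000, seed: int | None = None,
                      alleles: list[str] | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Assay + prediction tables with planted attribute effects.

    ``attributes`` is indexed by motif with columns ``count`` (human-proteome
    TCEM frequency), ``expr_pct`` (expression percentile rank in [0, 1]) and
    ``thymo_low`` (bool). Peptide immunogenicity is Bernoulli with

        logit P = beta0 + beta_frequency * 1[count >= 4]
                  + beta_expression * bump(expr_pct)
                  + beta_cleavage * 1[not thymo_low]

    Immunogenic pairs get more positive than negative T-cell assays,
    nonimmunogenic pairs solely negative ones; binding assays and a
    prediction table passing the curation filters are emitted alongside.
    Returns (assays, predictions, ground truth with latent labels).
    """
    rng = _rng(config.seed + 2 if seed is None else seed)
    alleles = alleles or ["HLA-A*02:01", "HLA-B*07:02"]
    motifs = rng.choice(attributes.index.to_numpy(), size=n_peptides, replace=True)
    att = attributes.loc[motifs]
    logit = (
        config.beta0
        + config.beta_frequency * (att["count"].to_numpy() >= 4)
        + config.beta_expression * expression_bump(att["expr_pct"].to_numpy())
        + config.beta_cleavage * (~att["thymo_low"].to_numpy(dtype=bool))
    )
    p_imm = 1.0 / (1.0 + np.exp(-logit))
    immunogenic = rng.random(n_peptides) < p_imm

    prefixes = rng.choice(_AA, size=(n_peptides, 3))
    suffixes = rng.choice(_AA, size=(n_peptides, 1))
    peptides = np.array([
        "".join(prefixes[i]) + motifs[i] + "".join(suffixes[i]) for i in range(n_peptides)
    ])
    # de-duplicate peptide sequences (same motif twice is fine; identical
    # full peptides would merge allele-peptide pairs in curation)
    seen: set[str] = set()
    for i, pep in enumerate(peptides):
        while peptides[i] in seen:
            peptides[i] = ("".join(rng.choice(_AA, size=3)) + motifs[i]
                           + "".join(rng.choice(_AA, size=1)))
        seen.add(peptides[i])
    allele_choice = rng.choice(alleles, size=n_peptides)

    assay_rows = []
    for pep, allele, imm in zip(peptides, allele_choice, immunogenic):
        if imm:
            n_pos = int(rng.integers(2, 4))
            n_neg = int(rng.integers(0, n_pos))  # strictly fewer negatives
        else:
            n_pos = 0
            n_neg = int(rng.integers(1, 4))
        for _ in range(n_pos):
            assay_rows.append((pep, allele, "tcell", "positive", "synthetic virus"))
        for _ in range(n_neg):
            assay_rows.append((pep, allele, "tcell", "negative", "synthetic virus"))
        n_bind = int(rng.integers(2, 4))
        n_bind_pos = n_bind  # empirically confirmed binders
        for k in range(n_bind):
            outcome = "positive" if k < n_bind_pos else "negative"
            assay_rows.append((pep, allele, "mhc_binding", outcome, "synthetic virus"))
    assays = pd.DataFrame(
        assay_rows,
        columns=["peptide", "allele", "assay_kind", "outcome", "source_organism"],
    )
    predictions = pd.DataFrame({
        "peptide": peptides,
        "allele": allele_choice,
        "affinity_nm": rng.uniform(10, 400, size=n_peptides),
        "rank_pct": rng.uniform(0.1, 1.9, size=n_peptides),
    })
    ground_truth = {
        "betas": {"beta0": config.beta0, "beta_frequency": config.beta_frequency,
                  "beta_expression": config.beta_expression,
                  "beta_cleavage": config.beta_cleavage},
        "latent": pd.DataFrame({"peptide": peptides, "motif": motifs,
                                "p_immunogenic": p_imm, "immunogenic": immunogenic}),
    }
    return assays, predictions, ground_truth


# ---------------------------------------------------------------------------
# TCR mutational scan
# ---------------------------------------------------------------------------

def gen_tcr_scan(config: SimulationConfig, epitope: str, seed: int | None = None
                 ) -> tuple[pd.DataFrame, dict]:
    """Single-position mutational scan with similarity-decaying TCR binding.

    Every alternative residue at each of the five TCEM positions of a 9-mer
    epitope yields a variant with

        relative_binding = max(exp(lambda * (sim - 1)) + Normal(0, sigma), 0)

    where sim is the normalized BLOSUM62 similarity between the variant and
    original TCEMs. Activation follows binding through a threshold link
    (negligible below 10% of the original binding). The original epitope is
    included with relative_binding exactly 1. At sigma = 0 the analytic
    10%-binding similarity cutoff is sim* = 1 + ln(0.1) / lambda.
    """
    from .similarity import blosum_similarity

    if len(epitope) != 9:
        raise ValueError("original epitope must be a 9-mer")
    rng = _rng(config.seed + 3 if seed is None else seed)
    lam, sigma = config.scan_lambda, config.scan_sigma
    original_tcem = extract_tcem(epitope)
    rows = [(epitope, original_tcem, 1.0, 1.0, 1.0)]
    for pos in range(3, 8):  # 0-based TCEM positions of a 9-mer
        for aa in AMINO_ACIDS:
            if aa == epitope[pos]:
                continue
            variant = epitope[:pos] + aa + epitope[pos + 1 :]
            tcem = extract_tcem(variant)
            sim = blosum_similarity(original_tcem, tcem)
            binding = max(float(np.exp(lam * (sim - 1.0)) + rng.normal(0.0, sigma)), 0.0)
            activation = binding if binding >= 0.1 else binding * 0.079
            rows.append((variant, tcem, sim, binding, activation))
    scan = pd.DataFrame(rows, columns=["variant_peptide", "tcem", "similarity",
                                       "relative_binding", "relative_activation"])
    ground_truth = {"lambda": lam, "sigma": sigma,
                    "analytic_cutoff": 1.0 + np.log(0.1) / lam}
    return scan, ground_truth


# ---------------------------------------------------------------------------
# Repertoire
# ---------------------------------------------------------------------------

def gen_repertoire(config: SimulationConfig, peptide_np: pd.Series,
                   seed: int | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Multi-individual recognition data with a planted np penalty.

    ``peptide_np`` maps peptide -> bool (np TCEM). Every individual carries
    one shared allele that strongly presents all peptides (the repertoire
    machinery then treats every peptide as presented); recognition is
    Bernoulli(base_rate * np_penalty) for np peptides and
    Bernoulli(base_rate) otherwise.

    Returns (recognition, genotypes, predictions, ground truth).
    """
    rng = _rng(config.seed + 4 if seed is None else seed)
    allele = "HLA-A*01:01"
    individuals = [f"IND{i:03d}" for i in range(config.n_individuals)]
    peptides = list(peptide_np.index)
    rate = np.where(peptide_np.to_numpy(dtype=bool),
                    config.recognition_base_rate * config.np_penalty,
                    config.recognition_base_rate)
    rec = rng.random((len(individuals), len(peptides))) < rate
    recognition = pd.DataFrame({
        "individual": np.repeat(individuals, len(peptides)),
        "peptide": np.tile(peptides, len(individuals)),
        "recognized": rec.ravel(),
    })
    genotypes = pd.DataFrame({"individual": individuals, "allele": allele})
    predictions = pd.DataFrame({
        "peptide": peptides, "allele": allele,
        "affinity_nm": rng.uniform(5, 45, size=len(peptides)),
        "rank_pct": rng.uniform(0.05, 0.45, size=len(peptides)),
    })
    ground_truth = {"np_penalty": config.np_penalty,
                    "base_rate": config.recognition_base_rate}
    return recognition, genotypes, predictions, ground_truth


# ---------------------------------------------------------------------------
# Pathogens and HLA associations
# ---------------------------------------------------------------------------

def sample_np_motifs(profile: NpProfile, rng: np.random.Generator, n: int,
                     want_np: bool) -> list[str]:
    """Sample motifs of known np status from a human-proteome profile."""
    pool = profile.table.index[profile.table["is_np"] == want_np]
    if len(pool) == 0:
        if want_np:
            # motifs absent from the human proteome are np by frequency
            return ["".join(rng.choice(_AA, size=MOTIF_LENGTH)) for _ in range(n)]
        raise ValueError("profile contains no non-np motifs to sample")
    return list(rng.choice(pool.to_numpy(), size=n, replace=True))


def gen_pathogen_proteome(config: SimulationConfig, profile: NpProfile,
                          np_proportion: float, n_peptides: int,
                          seed: int | None = None,
                          species: str = "synthetic pathogen"
                          ) -> tuple[ProteomeIndex, dict]:
    """Pathogen proteome as 9-mer proteins with a planted np-TCEM proportion.

    Each protein is a single 9-mer window whose TCEM is drawn np with
    probability ``np_proportion`` from the human profile, so the
    window-weighted np fraction concentrates on the planted value. Single-
    window proteins keep the per-window np status exactly controllable (a
    contiguous proteome would create uncontrolled overlapping windows).
    """
    rng = _rng(config.seed + 5 if seed is None else seed)
    is_np_flags = rng.random(n_peptides) < np_proportion
    n_np = int(is_np_flags.sum())
    np_motifs = sample_np_motifs(profile, rng, n_np, want_np=True)
    ok_motifs = sample_np_motifs(profile, rng, n_peptides - n_np, want_np=False)
    motifs = iter(np_motifs), iter(ok_motifs)
    records = []
    for i, flag in enumerate(is_np_flags):
        motif = next(motifs[0]) if flag else next(motifs[1])
        seq = "".join(rng.choice(_AA, size=3)) + motif + "".join(rng.choice(_AA, size=1))
        records.append((f"{species.replace(' ', '_')}_{i:05d}", seq))
    index = ProteomeIndex.build(records)
    ground_truth = {"np_proportion": np_proportion, "planted_np": int(n_np),
                    "n_peptides": n_peptides}
    return index, ground_truth


def gen_association_studies(config: SimulationConfig, seed: int | None = None,
                            n_studies: int = 4
                            ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, dict]:
    """HLA association tables with planted risk / protective structure.

    Risk allele groups (default 6) present np-rich peptide sets and carry
    odds ratios above 1; protective groups (default 7) the converse. Returns
    (studies table, group membership table, per-allele np fractions, ground
    truth). Group-level np fractions separate by construction; the noise
    keeps individual alleles overlapping slightly.
    """
    rng = _rng(config.seed + 6 if seed is None else seed)
    groups = (
        [(f"R{i + 1:02d}", "risk") for i in range(config.n_risk_groups)]
        + [(f"P{i + 1:02d}", "protective") for i in range(config.n_protective_groups)]
    )
    membership_rows = []
    allele_np = {}
    for gid, role in groups:
        n_members = int(rng.integers(2, 5))
        center = 0.7 if role == "risk" else 0.3
        for m in range(n_members):
            allele = f"HLA-A*{rng.integers(1, 99):02d}:{rng.integers(1, 99):02d}"
            while allele in allele_np:
                allele = f"HLA-A*{rng.integers(1, 99):02d}:{rng.integers(1, 99):02d}"
            allele_np[allele] = float(np.clip(rng.normal(center, 0.07), 0, 1))
            membership_rows.append((gid, allele, bool(rng.random() < 0.8)))
    membership = pd.DataFrame(membership_rows, columns=["group", "allele", "is_common"])
    study_rows = []
    for s in range(n_studies):
        for gid, role in groups:
            base = 1.6 if role == "risk" else 0.6
            odds = float(np.exp(np.log(base) + rng.normal(0, 0.25)))
            study_rows.append((f"study_{s + 1}", gid, odds))
    studies = pd.DataFrame(study_rows, columns=["study_id", "allele_group", "odds_ratio"])
    ground_truth = {
        "risk_groups": [g for g, r in groups if r == "risk"],
        "protective_groups": [g for g, r in groups if r == "protective"],
    }
    return studies, membership, pd.Series(allele_np, name="np_fraction"), ground_truth


# ---------------------------------------------------------------------------
# Full synthetic attribute pipeline
# ---------------------------------------------------------------------------

@dataclass
class StudyAttributes:
    """Synthetic human-proteome TCEM attributes with the artifacts that
    produced them, ready for assay generation and np classification."""

    index: ProteomeIndex
    attributes: pd.DataFrame  # index motif; columns count, expr_pct, thymo_low
    expression: pd.DataFrame  # motif -> expression, n_values
    thymo_scores: pd.DataFrame  # motif -> score, n_windows
    immuno_scores: pd.DataFrame
    np_profile: NpProfile
    housekeeping: list[str]


def gen_study_attributes(config: SimulationConfig, seed: int | None = None
                         ) -> StudyAttributes:
    """Compose the per-motif attribute table from scratch.

    Runs the actual pipeline on synthetic inputs: proteome -> TCEM index;
    negative-binomial cTEC counts -> TMM -> RPKM -> median -> per-motif
    expression (one synthetic gene per protein); planted cleavage tables ->
    preference -> site -> formation -> per-motif thymo/immuno scores; then
    the np profile with the bottom-tertile expression and first-quartile
    thymo cutoffs.
    """
    from .cleavage import preference_scores, stratify_cleavage, tcem_cleavage_scores
    from .cohort import NpCutoffs, np_flag
    from .expression import (GeneProteinMap, compute_rpkm, median_gene_expression,
                             stratify_expression, tmm_norm_factors)

    base = config.seed if seed is None else seed
    records, _ = gen_proteome(config, seed=base)
    index = ProteomeIndex.build(records)

    gene_ids = [f"GENE{i:05d}" for i in range(len(records))]
    gene_map = GeneProteinMap(
        mapping={pid: frozenset({gid}) for (pid, _), gid in zip(records, gene_ids)}
    )
    counts, exon_length, housekeeping, _ = gen_expression(config, gene_ids, seed=base + 1)
    factors = tmm_norm_factors(counts)
    rpkm = compute_rpkm(counts, exon_length, factors)
    gene_expr = median_gene_expression(rpkm)
    from .expression import tcem_expression

    expr_table = tcem_expression(index, gene_map, gene_expr)
    expr_pct = stratify_expression(expr_table["expression"], mode="percentile")

    thymo, immuno, background, _ = gen_cleavage_tables(config, seed=base + 2)
    thymo_scores = tcem_cleavage_scores(index, preference_scores(thymo, background))
    immuno_scores = tcem_cleavage_scores(index, preference_scores(immuno, background))
    thymo_group = stratify_cleavage(thymo_scores["score"])

    counts_series = pd.Series(dict(index.counts), name="count")
    attributes = pd.DataFrame({
        "count": counts_series,
        "expr_pct": expr_pct.reindex(counts_series.index),
        "thymo_low": thymo_group.reindex(counts_series.index).eq("low"),
    })
    attributes["expr_pct"] = attributes["expr_pct"].fillna(0.0)
    attributes["thymo_low"] = attributes["thymo_low"].fillna(True)
    attributes.index.name = "motif"

    expr_values = expr_table["expression"]
    low_tertile_boundary = float(np.quantile(expr_values.dropna(), 1 / 3))
    thymo_q1 = float(np.quantile(thymo_scores["score"].dropna(), 0.25))
    cutoffs = NpCutoffs(expression_cutoff=low_tertile_boundary, thymo_cutoff=thymo_q1)
    profile = np_flag(counts_series, expr_values, thymo_scores["score"], cutoffs)
    return StudyAttributes(
        index=index, attributes=attributes, expression=expr_table,
        thymo_scores=thymo_scores, immuno_scores=immuno_scores,
        np_profile=profile, housekeeping=housekeeping,
    )
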