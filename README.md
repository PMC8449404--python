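# tcemtools

Analysis toolkit for **T cell exposed motifs (TCEMs)** and the side effect of
self-mediated T cell positive selection on the recognition of nonself
peptides.

## The problem

CD8+ T cells only recognize an HLA-I-presented peptide if a specific T cell
exists in the repertoire, and the repertoire is shaped in the thymus:
thymocytes survive positive selection only if they recognize *self*-peptides
presented by cortical thymic epithelial cells (cTECs). The part of a
presented peptide that the TCR actually contacts is a five-residue motif —
positions 4–8 of a 9-mer or 5–9 of a 10-mer — the TCEM. A foreign peptide
whose TCEM is effectively absent from the self-peptides that drive positive
selection therefore tends to have no specific T cell at all: a structural
blind spot in adaptive immunity.

A TCEM can fail to mediate positive selection in three ways:

1. **frequency** — it occurs fewer than four times among the overlapping
   9-mer windows of the human proteome;
2. **expression** — the genes encoding it are not expressed in cTECs
   (median RPKM across cTEC samples, aggregated per motif occurrence);
3. **presentation** — the thymoproteasome, which generates the positively
   selecting peptides and has weak chymotrypsin-like activity, is unlikely
   to excise a 9-mer exposing it.

Motifs failing any criterion are called **np-TCEMs** (non-positively-
selecting). The package quantifies all three attributes, curates peptide
immunogenicity datasets to test their effect, asks whether TCR
cross-reactivity can bridge the gap, and scans pathogen proteomes and HLA
disease associations for the consequences.

## What is implemented

| module | contents |
| --- | --- |
| `tcemtools.motifs` | TCEM extraction, proteome 9-mer-window index, frequency classification, pentamer-space coverage |
| `tcemtools.expression` | TMM normalization, RPKM, protein↔gene symbol joins, per-motif median expression with occurrence multiplicity, tertile/percentile stratification, housekeeping flags |
| `tcemtools.cleavage` | cleavage-site preference scores c(i, j) → per-site score C (median) → per-window formation score C̄ (mean of flanking sites) → per-motif median, for thymo- and immunoproteasome tables |
| `tcemtools.curation` | assay filtering, immunogenicity labeling, prediction- and assay-based binding filters, k-tuple-distance iterative de-duplication, secondary-anchor (positional entropy) exclusion |
| `tcemtools.similarity` | normalized BLOSUM62 similarity `s(a,b)/√(s(a,a)s(b,b))`, exhaustive ungapped best-hit scans, TCR-scan ROC/AUC, cost–benefit optimal cutpoints, group-vs-group cross-reactivity scans, 25-bin similarity ratios |
| `tcemtools.cohort` | np-TCEM classification, naïve CD8+ repertoire fractions with paired tests, pathogen np fractions, per-allele presented-np fractions with the fallback-N rule, odds-ratio rank-percentile aggregation |
| `tcemtools.stats` | Fisher exact ORs, rank tests, lowess curves, multivariate logistic models, attribute additivity, amino-acid leave-one-out, Kyte–Doolittle hydrophobicity |
| `tcemtools.simulate` | seeded generators for every input (proteomes, count matrices, cleavage tables, assay/prediction tables, TCR scans, repertoires, pathogens, association studies) with planted ground truth |

A thin `tcemtools` CLI (`index`, `cleave`, `curate`, `sim`, `simulate`)
wraps the library for shell use.

## Worked example

```python
from tcemtools import extract_tcem, classify_frequency
from tcemtools.simulate import SimulationConfig, gen_study_attributes, gen_tcr_scan
from tcemtools.similarity import estimate_crossreactivity_cutoff

cfg = SimulationConfig(seed=1)
study = gen_study_attributes(cfg)          # synthetic proteome + full scoring
idx = study.index

print(idx.total_windows())                 # 46792  9-mer windows indexed
print(len(idx.counts))                     # 25240  distinct TCEMs observed

motif = extract_tcem("SLLMWITQC")          # NY-ESO-1 157-165 epitope
print(motif)                               # MWITQ
print(classify_frequency(idx.frequency(motif)))   # rare (absent here)

scan, truth = gen_tcr_scan(cfg, "SLLMWITQC")
roc, cutoff = estimate_crossreactivity_cutoff(scan)
print(round(roc.auc, 3), round(cutoff, 3))  # 1.0 0.621
```

The scan output reads: on a noiseless single-position mutational scan of the
NY-ESO-1 epitope, TCEM similarity classifies binders vs nonbinders perfectly
(AUC 1.0), and the cost–benefit cutpoint recovers the similarity level below
which TCR binding drops under 10% of the original — 0.621 here, one
similarity grid step above the analytic value 1 + ln(0.1)/λ ≈ 0.616.

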