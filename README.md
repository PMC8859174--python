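# tcrtrack

Longitudinal analysis of clonal T-cell receptor (TCRβ) repertoires, built
around the question of how an immuno-ablative therapy remodels the T-cell
compartment over years: which dominant clones persist, how repertoire
diversity evolves, which clonotypes are shared between patients ("public"
clones), and which clones look like they should not have survived thymic
selection.  It is written for immunologists and bioinformaticians analysing
sorted-subset TCRβ sequencing data (CD4/CD8 × naïve/memory) sampled at
multiple timepoints, and for method developers who want every estimator
verifiable against simulated ground truth.

Because patient-level sequencing data cannot be redistributed, the package
ships a synthetic-cohort generator that emulates the structure of such a
study — power-law clone sizes, per-interval dominant-clone attrition,
injected public clonotypes with convergent nucleotide encodings, and raw
structured reads — so every stage of the analysis can be exercised and
checked end to end with known truth.

## What it computes

**Clonotypes and tracking.** A clonotype is the triple (V gene, J gene,
CDR3 amino-acid sequence); the CDR3/junction spans the conserved cysteine
through the conserved phenylalanine.  Dominant clones are the top *n*
(default 100) by UMI-corrected abundance; persistence of the baseline
dominant set, the new-vs-persistent split of repertoire mass, and Jaccard
overlap are computed per subject, subset and timepoint.

**Diversity.** Shannon entropy H = −Σᵢ pᵢ log pᵢ over clone frequencies,
with OLS trend fitting (slope, adjusted R², p) across timepoints.

**Public clones.** A clonotype is public when detected at ≥2 reads in each
of ≥2 individuals.  Sharing patterns (upset-style counts), convergent
recombination (distinct nucleotide encodings of one amino-acid clonotype),
and HLA-stratified analyses (e.g. DRB1\*15:01 carriers) are provided.

**Generation probability.** A parameterized V(D)J recombination model
assigns every junction σ its generation probability

&nbsp;&nbsp;P_GEN(σ) = Σ_scenarios P(V)·P(delV|V)·P(nVD)·∏p(ins)·P(D)·P(del5,del3|D)·P(nDJ)·∏p(ins)·P(J)·P(delJ|J)

marginalized over all recombination scenarios by dynamic programming, at
the nucleotide level and — marginalizing synonymous codons — at the
amino-acid level.  An exhaustive scenario enumerator serves as an
independent oracle on desk-scale models.

**Selection.** A log-linear selection model over CDR3 features (length,
V, J, and positional amino-acid features from both ends),

&nbsp;&nbsp;Q(σ) = exp(Σ_f λ_f − log Z),  P_POST(σ) = Q(σ)·P_GEN(σ),

is fitted by maximizing the observed repertoire's mean log selection factor
under E_baseline[Q] = 1.  Clones are binned by the ratio x = P_POST/P_GEN
(x ≥ 0.1 not-rare; 1e−4 ≤ x < 0.1 intermediate; x < 1e−4 rare);
rare-binned clones are flagged as putative escapees of thymic negative
selection, with log₁₀ P_POST < −10 reported as a separate co-criterion.

**UMI clonotyping.** Structured reads (adapter + 10 bp UMI + spacer +
junction) are processed by mismatch-tolerant extraction, reference-anchored
CDR3 calling against the model's V/J flanks, and directional UMI collapse
(merge at Hamming ≤ 1 when count_large ≥ 2·count_small − 1).

**Motifs.** GLIPH-style k-mer enrichment: interior CDR3 k-mers (k = 3..7,
minimum CDR3 length 7, 3/2 residues trimmed) are Fisher-tested against a
reference repertoire (one-sided, p < 1e−3) with Bonferroni-corrected
binomial V-bias scoring (p < 0.05).

**Cohort statistics.** Exact Wilcoxon matched-pairs signed-rank test
(full null enumeration for n ≤ 15, tie-corrected normal approximation
beyond) and Bonferroni correction.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic cohort (13 subjects, four sorted subsets, months 0–36):

```bash
python analysis/01_simulate_cohort.py 1   # seed 1
python analysis/03_clonal_kinetics.py 1
```

prints

```
mean top-100 persistence (%) by subset and month:
timepoint_months    6     12    24    36
CD4_RA            12.6   2.1   0.7   0.0
CD4_RO            38.6  29.4  22.8  17.0
CD8_RA            12.4   2.1   0.2   0.0
CD8_RO            30.2  21.9  16.3  11.2
```

— the memory pools lose most dominant clones in the first interval and
keep eroding (only ~17%/11% of baseline top-100 CD4/CD8 memory clones
remain detectable at 36 months), while the naïve pools turn over almost
completely; `04_diversity_trends.py` shows the matching entropy decline
(CD4 memory −0.033/month, adj R² 0.97) and `05_public_clones.py` recovers
all 60 injected public clonotypes and their convergent encodings.  Each
script writes tidy TSVs under `results/`.

The same stages are scriptable through a YAML-configured pipeline
(`tcrtrack run --config cfg.yaml --seed 1 --out report/`) or the library
API.

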