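# Methods

This note documents the models, the synthetic study design, the numerical
choices, and the limitations of `tcrtrack`.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The recombination model (P_GEN)

The generative model is a reduced TCRβ V(D)J recombination process: choose
a V segment (3′ flank starting at the conserved cysteine codon), delete
`delV` bases; insert `nVD` i.i.d. bases; choose a D segment, delete
`del5`/`del3`; insert `nDJ` bases; choose a J segment (5′ flank ending at
the conserved phenylalanine codon), delete `delJ`.  The junction string is
the concatenation of the surviving pieces, and a clone's generation
probability marginalizes all scenarios producing it.

Three deliberate simplifications relative to the published TCRβ
recombination statistics (IGoR/OLGA-class models) keep the scenario space
exactly enumerable so that every probability can be checked against brute
force: D usage is independent of J (published models condition P(D|J)),
there are no palindromic (negative) deletions, and insertion nucleotides
are i.i.d. rather than a dinucleotide Markov chain.  Convergent
recombination — the phenomenon the public-clone analysis rests on — is
preserved.  Deletion distributions have bounded support with
max(del5) + max(del3) ≤ |D| (likewise for V/J), so independent deletion
draws always yield a valid scenario and total probability mass over
sequences is exactly 1 (verified to 1e−9 on the enumerable model).

`pgen_nt` is a forward pass over a weighted automaton whose states encode
(V-flank position) × (insertion progress) × (D placement) × (J-suffix
position); each accepting path corresponds to exactly one scenario with
path weight equal to the scenario probability.  `pgen_aa` runs the same
forward pass codon by codon, branching over the synonymous codons of each
amino acid — an exact marginalization over all nucleotide encodings
(checked to 1e−12 against explicit codon expansion).  Both accept an
optional V/J restriction returning the joint probability
P(sequence, V, J), which is what clonotype-level annotation uses since
clonotype keys carry V and J.

Two models ship with the package: `toy_model` (6 V / 2 D / 4 J, the
default everywhere) and `tiny_model` (2 V / 1 D / 2 J), whose complete
sequence space (~4000 strings) is enumerable for conservation and
goodness-of-fit tests.  The toy model's flanks are synthetic but follow
TCRβ conventions (TGT/TGC… junction start, …TTT/TTC end, G-rich D
segments); their interiors were designed pairwise ≥ 2 mismatches apart
within any 6-base window so that anchor-based CDR3 calling is exact at
zero sequencing error.  Real IMGT reference segments are intentionally not
bundled; the model is a configurable input (YAML), not an attempt to match
published parameter sets.

## The selection model (P_POST)

Selection is log-linear over an enumerable feature set: one CDR3-length
feature, one V and one J feature, and one (amino acid, position) feature
per residue anchored from each end, truncated at 12 positions per side to
bound the feature space.  Q(σ) = exp(Σλ_f − log Z) rescales P_GEN to
P_POST.  Fitting maximizes the observed sample's mean Σλ under the
constraint E_baseline[Q] = 1, with the baseline drawn from the generative
model (≥ 10× the observed size is recommended; the acceptance runs use
10×).  The objective is concave; it is ascended with L-BFGS rather than
fixed-step gradient ascent — same optimum, far fewer iterations — and the
gradient max-norm criterion (< 1e−4) is verified at the solution, with a
warning otherwise.

A ridge penalty (default l2 = 0.02) is applied.  Its role is statistical,
not cosmetic: positional features conditioned on rare CDR3 lengths are
observed tens of times at desk scale, and their unpenalized estimates
would have sampling noise well above 0.1.  The penalty also fixes the
model's gauge freedoms (adding a constant to all features of one class is
absorbed by log Z) at the minimum-norm representative.  Both effects
attenuate fitted magnitudes roughly uniformly, which is why recovery of a
planted model is assessed by Pearson correlation rather than absolute
error; the planted-recovery simulation (8 nonzero weights, 2×10⁴ observed,
2×10⁵ baseline) achieves r ≈ 0.97 and the matching null fit keeps all
weights below 0.1.

The P_GEN:P_POST ratio "1:x" is oriented as x = P_POST/P_GEN: x spans
enrichment (> 1) to depletion (≪ 1), and small x means "easily generated
yet unlikely to survive selection".  Bins are half-open with the boundary
assigned to the upper class: x ≥ 0.1 not-rare, 1e−4 ≤ x < 0.1
intermediate, x < 1e−4 rare.  The escapee flag equals membership in the
rare bin; log₁₀ P_POST < −10 is reported as a separate boolean rather than
conjoined, since the two criteria are logically independent.  Under the
null cohort (no planted selection) the rare bin is empty — reaching
x < 1e−4 requires feature-weight sums below −9.2, i.e. genuinely strong
selection — so a zero escapee count on simulated data is the expected,
honest outcome, not a defect.

## UMI clonotyping

Reads follow the library layout adapter + 10 bp UMI + spacer + junction
(the adapter and `ACATGGG` spacer defaults mirror a template-switch oligo
design).  Extraction tolerates one mismatch in the adapter and spacer.
CDR3 calling anchors the junction's own prefix/suffix against the model's
V/J flanks, accepting ≥ 6 matched bases with ≤ 1 mismatch and scoring
matches by length − 2·mismatches (ties to segment-list order); with the
shipped flank design this inverts the simulator exactly at zero error.
Rejections (`no_adapter`, `no_spacer`, `too_short`, `no_v`, `no_j`,
`frame`) are tallied, never raised, and read totals are conserved at every
stage.  UMI collapse is the standard directional-adjacency rule: merge b
into a when Hamming(a, b) ≤ 1 and reads(a) ≥ 2·reads(b) − 1, processing
groups by descending count with lexicographic tie-break, which makes the
result independent of input order.  Base qualities are ignored; the error
model is positional substitution only, and only single-end logic is
implemented (the synthetic reads carry the whole junction in one
sequence).

## The synthetic study design

The generator emulates a longitudinal transplant-style cohort: 13
subjects, subsets CD4/CD8 × naïve/memory, timepoints 0/6/12/24/36 months,
250–400 clones per sample at desk scale (the real protocol's ~0.5M reads
over 10⁵–10⁶ sorted cells is scaled down ~100×; all rates and fractions
are scale-free).  Per (subject, subset):

- **Clone sizes** are Zipf over rank, frequency ∝ rank^(−α), with α = 1.0
  (CD4 memory) / 1.1 (CD8 memory) and α = 0.4 for the near-flat naïve
  pools.  Memory α grows by 10–12% per interval, encoding progressive
  clonal skewing (hence declining entropy) after ablation.
- **Survival** acts on amino-acid clonotypes per interval; once lost, a
  clone never returns.  Baseline top-100 ("dominant") clones survive with
  the dominant schedule, all others with the background schedule.  The
  default memory schedules are two-phase — (0.41, then 0.78)/interval for
  CD4, (0.33, then 0.74) for CD8 dominant clones — reflecting a large
  ablation-driven first-interval loss followed by slower attrition; the
  compound values put ~40%/33% of dominant memory clones at 6 months and
  ~19%/13% at 36 months.  Naïve subsets use low flat survival (high
  turnover).  Lost clones are replaced by newly generated ones, 40 of
  which are spliced into the dominant ranks each interval, emulating
  lymphopenia-induced proliferation of new clones into dominance.
- **Public clones** (default 60) are injected into the CD4 memory pool of
  2–3 subjects each with 1–5 synonymous nucleotide encodings
  (P(>1 encoding) = 12%), every encoding verified generatable under the
  model, placed outside the top ranks with at least 2 molecules per
  encoding so the ≥2-reads-in-≥2-subjects rule detects them with recall 1.
- **Counts**: every present clone receives at least one molecule (the
  emitted repertoire is exactly the alive clone list; detection is then a
  property of the analysis thresholds, not of sampling depth), with the
  remaining molecules multinomial over the Zipf frequencies and read
  counts Poisson-dispersed around `reads_per_umi`.
- **Reads**: each molecule gets a distinct UMI (pairwise Hamming ≥ 2
  within a clonotype — the regime in which directional collapse is exact;
  with a 10-bp UMI space and desk-scale molecule counts, closer collisions
  are rare in reality and would otherwise put a hard ceiling on
  exact-count recovery) and i.i.d. substitution errors at `error_rate`
  (default 0.1%/base).

What the generator does **not** emulate: PCR amplification bias and
chimeras, paired-end read structure, quality-score profiles, mechanistic
thymic-output or homeostatic-proliferation dynamics, real V/D/J allele
diversity, and clinical covariates.  Passing tests therefore demonstrate
estimator correctness under the stated statistical structure, not
robustness to every artefact of real libraries.

Because the toy model's productive sequence space is small, independently
simulated subjects share many clonotypes by chance convergent generation;
"natural" public clones are therefore far more frequent, relative to
repertoire size, than in real cohorts.  This is inherent to the scale, is
exactly the phenomenon the public-clone statistics measure, and is why
registry recovery (recall of *injected* publics) and the brute-force
oracle equivalence are the correctness criteria rather than absolute
public counts.

## Analysis conventions

- Abundance for ranking, frequencies, entropy and fractions uses UMI
  counts when present, read counts otherwise.
- Tracking and public-clone identity are amino-acid level, invariant to
  silent substitutions; nucleotide variants are kept underneath for
  convergence counting.
- "Detected" at follow-up means abundance ≥ 1 by default (`min_reads`
  exposed).  Per-subject persistence is averaged for cohort summaries.
  When a repertoire holds fewer than *n* clones, all of it is used and the
  count reported.
- The public-clone rule applies the ≥2-read threshold per individual (the
  stricter reading); a pooled-total alternative is a flag.
- Entropy uses natural log by default (base 2 and H/ln K normalization
  exposed); the base of the source analyses is not stated anywhere, so
  both are reported where plots are regenerated.
- Antigen annotation requires exact V/J/CDR3 match and an HLA restriction
  carried by the subject, with prefix matching across typing resolutions
  (2- vs 4-digit).  No database confidence filter is applied; the table is
  treated as pre-filtered.  The shipped panel is synthetic (invented
  epitope assignments over simulated clonotypes) and is labelled as such.
- Motif enrichment uses one-sided (enrichment-direction) Fisher tests at
  the clonotype level, k = 3..7 over the CDR3 interior after trimming 3/2
  residues, minimum CDR3 length 7.  V-bias is a Bonferroni-corrected
  binomial tail rather than a simulation-based score: deterministic and
  oracle-checkable.  The pooled-baseline reference mode (all subjects'
  baseline clonotypes as reference for post-treatment samples) is a
  first-class configuration.  Exact-test discreteness makes the Fisher
  stage conservative at α = 1e−3; the calibration check bounds false
  discoveries by the upper Poisson band of α × (motifs tested).
- Wilcoxon signed-rank: zero differences dropped and counted, average
  ranks for ties, exact null by convolution over signed ranks for n ≤ 15,
  tie- and continuity-corrected normal approximation beyond.

## Numerical choices and problem sizes

Forward DP state spaces are a few hundred states for the shipped models;
transition matrices are dense float64 and cached per (model, V, J)
restriction.  Oracle enumeration is guarded (refuses > 10⁷ scenario
iterations with a size estimate).  Selection fitting uses L-BFGS with
ftol 1e−14 and a post-hoc gradient max-norm check at 1e−4; features absent
from both samples are pinned to 0 and reported.  The acceptance runs use:
200 oracle sequences; 50 codon-expansion CDR3s; 2×10⁴ observed / 2×10⁵
baseline clonotypes for recovery; 20 subjects × 100 dominant clones for
survival recovery; ~10⁵ reads over 2000 clones × ~3 molecules for UMI
fidelity (the UMI stage's many-clones/few-molecules regime — per-clone
exact-count recovery is only meaningful when clones do not hold thousands
of molecules each, since molecule-loss probability compounds per
molecule); 8 null and 50 spiked replicates for motif calibration.  The
full suite runs in a few minutes on one CPU.

## Known limitations

- The generative model is desk-scale; absolute P_GEN values are not
  comparable to those from full IGoR/OLGA parameter sets, only their
  relative structure (public > private, convergence effects) is.
- The selection model is identified up to per-class gauge shifts; fitted
  weights are minimum-norm representatives and shrink under the ridge
  penalty, so only their correlation structure is interpretable.
- CDR3 calling is anchor-based against known flanks; it does not do full
  V/D/J alignment, novel-allele detection, or chimera screening.
- Linear mixed-effects modelling of longitudinal means is deliberately
  delegated to standard statistical packages and excluded from the
  oracle-tested surface.
- Single-chain (β) only; no paired αβ or single-cell barcode support.
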