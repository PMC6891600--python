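# Methods

## Mass and modification arithmetic

Peptide masses are monoisotopic sums over the standard 20-residue table
(G = 57.02146, C = 103.00919, …) plus one water (18.010565 Da). Each
intrachain disulfide bond removes two hydrogens from the reduced chain. Two
conventions are implemented:

* **exact** (default): −2 × 1.007825 Da per bond, the physically correct
  correction;
* **paper_compat**: −2.000 Da per bond. Recomputing the published reference
  panel shows the printed theoretical masses follow this rounded convention:
  they agree with `paper_compat` at the printed two-decimal precision
  (raw residuals +0.006 to +0.014 Da, which round to ≤0.01 at two decimals)
  but sit ≈0.033–0.044 Da above `exact` for three-disulfide peptides. The
  residual few-mDa scatter presumably reflects the (unstated) residue mass
  table used for the printed values; both conventions are exposed rather
  than guessing it.

Reduction plus 2-iodoethanol alkylation adds a fixed 45.034 Da per
half-cystine in both modes; disulfide counts inferred from observed mass
pairs use the nearest integer of Δm/45.034 with a 0.1 Da consistency
tolerance (published observed masses sit 0.06–0.08 Da below theoretical, so
0.1 Da is the natural match window). Lysine carbamylation (+43.00581 Da) is
available as an explicit option and never applied silently; the two
reference peptides with a putative carbamylation are flagged in the bundled
panel and excluded from mass-reproduction checks.

The framework classifier uses cysteine spacing only and classifies only
six-cysteine frameworks: one adjacent CC pair in the third/fourth position →
ICK; no adjacent pair with exactly two residues between C2–C3 and one
between C3–C4 (the pacifastin CxxCxC core) → pacifastin; anything else,
including ≥7 or ≤5 cysteines, → unknown. pI is the bisection root of the
Henderson–Hasselbalch net charge on [0, 14] (EMBOSS pKa set recorded in the
output; internal tolerance 0.001 pH, reported to 0.1).

## Precursor processing

Cleavage rules are pure sequence motifs scanned downstream of a
caller-supplied signal-peptide boundary (signal-peptide prediction is an
input, not a computation). Defaults: PPR and DEER/NEER/NEELGR cut
immediately after the motif; dibasic KR/RR/KK/RK cut after the second basic
residue. Motifs are retained on the upstream product — the choice mirrors
the observed PPR-terminated mature peptides; whether dibasic sites are
trimmed in vivo is unknown, so the default retains them and the rule's
`motif_retained_on` field lets callers flag the alternative. Digestion
partitions the propeptide exactly (hydrolysis adds one water per cut, which
the mass-balance property test checks). Products default to
floor(n_cys / 2) disulfides. Activation reports require exactly one
DEER-type site and report average (not monoisotopic) masses in kDa, the
precision regime of gel-scale protein comparisons; a motif with nothing
upstream of it is flagged as a degenerate prodomain rather than an error.

## Expression quantification

FPK = fragments/(ORF length/1000). TPM divides FPK by the whole-transcriptome
total FPK (ΣFPK); with two reference assemblies of the same reads the
arithmetic mean of their totals is used, with one the total is used
directly. ΣFPK denominators include all contigs of the reference (whether
zero-count contigs were excluded upstream is unknowable from the published
description; all-contig totals are the deterministic choice).

The TMM factor for AMG with reference to PMG is written from first
principles because the published rendering of the M/A/w formulas is
typographically corrupted: standard TMM semantics are used — after removing
contigs with a zero count in either library, M = log₂(f_AMG/f_PMG) and
A = ½ log₂(f_AMG·f_PMG) with f = count/library-total, weights are the
inverse delta-method binomial variance (N−k)/(Nk) summed over the two
libraries, the top and bottom 30% of M and 5% of A are rank-trimmed (ties
broken by contig id for determinism), and the factor is 2^(Σ wM/Σ w).
Library totals are taken over the zero-filtered set so that a contig absent
from one library cannot perturb the factor. At least 10 informative contigs
are required. The published empirical factor (0.98 on the real read data) is
not desk-reproducible; the implementation is instead validated against a
brute-force reimplementation on a 1050-contig synthetic fixture and by its
algebraic properties (unity on identical libraries, antisymmetry in log
space, scale invariance).

## Gland-preference and orthologue statistics

Fold change is (max+0.5)/(min+0.5) on TPM; the 0.5 pseudo-count makes
"detected in one gland only" finite and large instead of infinite. Labels
require fold > 100. Housekeeping flags require a shared label with both TPMs
in [10, 2000]. Family tests compare member PMG TPMs vs member AMG TPMs with
a two-group Kruskal–Wallis (tie-corrected H, χ²₁ p); for pooled n ≤ 10 an
exact p from full enumeration of rank assignments is reported alongside.
Families with fewer than three members are reported untested. Direction is
the gland with the larger median member TPM (medians for robustness in small
families). Benjamini–Hochberg FDR is reported next to raw p-values.
Reciprocal best hits take the top-scoring subject per query (ties broken by
subject id) in both directions. Concordance of an orthologue pair is
same-preference-label by default; a looser same-direction-of-bias fraction
is reported when per-species TPMs are available, since the two readings of
"similar pattern" can differ.

## Venom proteomics

Identification uses strict inequalities (confidence > 95, D-score > 0.7),
matching the "> " phrasing of the criteria. Top-3 quantification averages
the three largest precursor counts; with fewer than three peptides the mean
of all available values is used and flagged (the rule presumes ≥1 but is
otherwise silent). Percent-of-maximum is per sample, with a deterministic
`is_top` marker (quant ties broken by protein id). The origin test pools the
detected proteins' PMG TPMs and AMG TPMs as two groups for a Kruskal–Wallis
test — whether the original analysis pooled or paired the vectors is
unstated, so a paired Wilcoxon signed-rank p is reported alongside. The
dominant gland is the higher-median gland, reported only at p < α
(default 0.05); fewer than three proteins yields an untested result.

## Dose-response

Mortality is modelled as binomial with logit(p) = b0 + b1·ln(dose), the
two-parameter log-logistic with asymptotes fixed at 0 and 1 (animals were
uniformly killed at high dose, supporting fixed asymptotes; no alternative
link families are offered). LD50 = exp(−b0/b1); its standard error comes
from the delta method on the GLM covariance. The fit requires ≥3 distinct
doses and mortality bracketing 50%. Perfectly separating data yield the
geometric midpoint of the bracketing doses, flagged quasi-separation, with
undefined SEs. The headline fit pools flies across replicate groups; the
per-dose between-group SD of mortality and a Pearson overdispersion ratio
are reported separately, since a published "±" can be either a fit SE or a
between-replicate SD.

## Synthetic data

Generators are pure functions of (config, seed) using numpy Generator
substreams, one per generator, so adding one output never perturbs another.

*Expression.* Venom contigs follow the observed family structure (96 venom
contigs across ten families, 79 PMG-preferring and 17 AMG-preferring) with
preferred-gland TPM log-normal around 2 × 10⁴ (log-sd 0.3, keeping the
3σ lower tail above the >5000 TPM regime of MS-detected venom transcripts)
and off-gland TPM around 10; 1000 housekeeping contigs sit log-uniformly in
10–2000 TPM with small between-gland jitter. Venom transcriptional mass is
balanced between the glands so the two libraries are compositionally
unbiased — the condition under which the between-library scaling factor is
≈1, as observed on the real data. Counts are multinomial (not Poisson) at
library depths of 42,324,442 and 67,317,010 fragments so library totals are
exact. ORF lengths are uniform on 240–2400 nt.

*Peptides/precursors.* Framework sequences are built from cysteine scaffolds
with cysteine-free spacers, so classification is guaranteed by construction;
precursor-domain spacers additionally exclude K and R so no cleavage motif
can arise by chance and each precursor digests into exactly its intended
products. Redulysin-like precursors pair an acid-alphabet prodomain with a
lysine-rich, D/E-free lytic domain, forcing the prodomain pI below 6 and the
activated pI above 9.

*Evidence.* Each sample detects 20 venom proteins; the number drawn from the
AMG pool is the rounded admixture fraction (deterministic — the sample's
composition is intended structure, not noise), with within-pool detection
weighted by that gland's TPM. Propelled samples and all but the last
electrostimulation-series sample use admixture 0.05 (≈1 AMG protein); the
final series sample jumps to 0.75, strong enough that AMG products dominate
it and the origin call leaves PMG. Confidences are high (~98%), D-scores
0.9, precursor counts log-normal (σ = 0.4) around mixture abundance.

*Dose-response.* Six doses geometric around the true LD50 (12.92 µg/g ×
2^{−2.5…2.5}), slope 4 on the log-dose axis, eight flies per group,
triplicate groups, binomial kills.

What the generators do **not** emulate: mapping ambiguity and multi-mapping
read loss, length-dependent fragment sampling biases, assembly redundancy,
peptide-level FDR structure, missing-value patterns of real MS, and
between-animal variation (the study had one RNA-seq replicate per gland).
Passing recovery tests therefore demonstrates the correctness of the
implemented estimators under their own model assumptions, not robustness to
those real-data artefacts.

## Problem sizes and numerical choices

The test suite and recovery checks use 1096-contig expression tables, a
1050-contig TMM oracle fixture, 20 × 20 RBH matrices, exhaustive
permutation up to pooled n = 10, and 500 dose-response replicates; these
sizes make every stochastic claim estimable with comfortable margins while
the full suite runs in well under a minute. Bisection tolerances: pI 0.001
internal. Trim boundaries use floor(n × fraction) per tail. All tie-breaks
(trim ranks, top hits, top proteins) are by id, for determinism.

## Known limitations

* Disulfide connectivity (which cysteines pair) is out of scope — only bond
  counts are modelled.
* The TMM implementation is the two-library special case; it does not
  generalise to multi-sample designs.
* The origin test treats detected proteins as independent observations; in
  reality co-regulated family members are correlated, so its p-values are
  anti-conservative on real data.
* `paper_compat` mode exists to reproduce published tables; new analyses
  should prefer `exact`.
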