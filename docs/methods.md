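# Methods

This note documents the models, parameter choices and numerical decisions
behind `phosphoflow`, and what the synthetic-data generator does and does
not establish.

## Ratio normalization

SILAC heavy/light ratios are log2-transformed and oriented so that positive
values mean higher abundance in the perturbed condition; experiments run
with inverted labeling are negated via a per-replicate swap map.  Two
systematic errors are then removed per (setup, replicate) group, estimated
from unphosphorylated peptides only:

* **Mixing factor m** (log2 units): unequal amounts of heavy- and
  light-labeled cells shift every ratio by a constant.  m is the mean
  oriented log2 ratio of proline-free unphosphorylated peptides and is
  subtracted from every record.
* **Proline-conversion factor c** (log2 units per proline): cells convert
  part of the heavy arginine pool into heavy proline, so each proline in a
  peptide depresses its apparent heavy signal by a fixed log2 amount.  After
  subtracting m, c is the mean of the pooled per-record residuals of
  one-proline peptides and halved residuals of two-proline peptides.
  Pooling is per record, not per proline class; the two readings of the
  defining sentence differ only in weighting, and the per-record mean is
  the simpler estimator.  Peptides with three or more prolines never enter
  the estimate (too few, too noisy) but are corrected with n·c.

Order matters: m first, then c on m-subtracted residuals.  A group without
proline-free unphosphorylated peptides cannot be normalized (hard error); a
group without 1–2-proline peptides gets c = 0 with a warning.  For
affinity-purification runs where bait abundance differs between conditions,
`normalize_protein_level` additionally centers one protein's peptides on
the median of its unphosphorylated peptides.  Global datasets are *not*
protein-abundance corrected.

Consequences used as test invariants: the corrected reference population
has mean exactly 0 (float precision), and refitting on corrected data gives
m = c = 0.

## Site assembly

The isoform probability of a phosphopeptide with k phosphates is the
product of its k highest per-residue localization probabilities; records
below 0.70 are discarded (exactly 0.70 is retained — the rule discards
strictly-below).  Retained records with ambiguous localization use the
highest-probability position assignment, mirroring the best-scoring
search-engine isoform.

A phosphorylation site is the exact set of phosphorylated residues on one
protein; missed-cleavage and oxidation variants merge.  Ratios are
unweighted two-level means: evidence entries within a replicate, then
replicate means.  Site residue letters are taken from the FASTA when one is
supplied, and a disagreement between evidence and FASTA residues is a hard
error — it catches off-by-one coordinate bugs early.

Phosphoislands are connected components of the graph joining phosphopeptides
that share at least one phosphorylated residue (components via networkx; a
brute-force transitive-closure oracle checks the partition in tests).
Islands are built per run; callers scope the records they pass in.  Each
island's unphosphorylated counter group (UCG) contains all unphosphorylated
peptides overlapping at least one island position and is averaged like a
site; an empty UCG is flagged as undefined rather than imputed.

## Integration and classification

Per-setup site tables are outer-joined on (protein, position set).  Missing
cells remain missing: with high missingness across MS runs, imputation
would fabricate evidence, so all summaries run over non-missing cells only.

Thresholds (`ClassRules`, log2 units): induced ≥ 1 (fold 2), decreased ≤ −1
(fold 0.5), both inclusive at the bound; regulator dependency is |log2|
strictly above 1.  The Set1/Set2 stratification applies inside the universe
of sites induced in both the stress setup and the phosphatase-deletion
setup: Set1 when the endosulfine-deletion stress setup shows log2 ≤ −1,
Set2 when it is negative but above −1.  The Set2 lower edge (0) is a design
choice — the source distinguishes "strongly" from "moderately" suppressed
without printing the moderate bound — and is configurable.

Fisher's exact test (two-sided) reports the sample odds ratio a·d/(b·c);
the p-value is computed by exact hypergeometric enumeration vectorized over
the support (scipy's hypergeometric pmf, scipy's tie tolerance), which is
numerically identical to `scipy.stats.fisher_exact` (cross-checked to
1e-10 in tests) but ~20× faster, fast enough for the exhaustive
enumeration check over all small-margin tables.  Zero-margin tables get a
flagged undefined odds ratio and p = 1.  Rank-sum comparisons use an exact
permutation enumeration (midranks) for pooled n ≤ 14 and scipy's
Mann–Whitney U above; t comparisons are Welch's.

## Motif enrichment

Windows are 13 residues (±6 around the phosphorylated residue), '\_'-padded
past the termini, one window per phosphorylated residue; serine- and
threonine-centered windows are analyzed independently.  Extraction is the
greedy motif-x iteration with the binomial approximation: the candidate
(offset, residue) p-value is the binomial tail of the foreground count with
the background frequency at that offset as success probability (a
hypergeometric variant is available behind `method=`).  A pair is accepted
when p ≤ 0.01 and the restricted foreground keeps ≥ 20 windows (defaults
from the standard settings).  The padding character participates as an
ordinary symbol in background frequencies.  Ties break deterministically:
offsets −6…+6 in order, residues alphabetically.  Reported per-motif score
is the summed −log10 p over accepted steps; raw per-step p-values are kept,
no FDR is applied to motifs.  The background is supplied explicitly by the
caller (the pipeline uses all sites quantified in both the stress and the
endosulfine-deletion setups).

## M-Track statistics

Each blot's 4-point dilution series (loadings 1, 1/2, 1/4, 1/8 of a control
sample) is fitted per channel with a least-squares polynomial of log2
signal vs log2 loading — degree 2 for antibody series 1, degree 1 for
series 2; the two series are normalized separately and never pooled
(antibody batch effects).  Test-lane signals are mapped through the
*inverse* of their blot's curve onto the equivalent-loading scale; the
source states the purpose of the correction but not the algebra, and
interpolation through the fitted curve is the choice made here (documented,
configurable in principle).  Invertibility requires monotonicity: a
degree-2 fit whose vertex falls strictly inside the dilution range falls
back to degree 1 with a warning.  Proximity = equivalent loading(me3K9H3) −
equivalent loading(HA); with a degree-1 curve this is invariant under
scaling all areas of a blot by a common factor.

Proximities are rescaled by subtracting the mean of the negative control
(prey-tag only), making the control mean exactly 0.  Each bait's replicates
are tested against the pooled control with a one-tailed (greater) Welch
t-test; a variance floor of 1e-8 keeps the statistic defined on degenerate
zero-variance synthetic groups.  Benjamini–Hochberg q-values are computed
over the tested bait family (statsmodels; textbook step-up oracle in
tests), with tiers at q < 0.05 and q < 0.01.  Baits with fewer than 2
replicates are skipped with a warning; fewer than 3 is logged.

## Synthetic data: what it emulates and what it does not

The generator writes evidence tables whose raw log2 ratio is
m + n_prolines·c + site effect + N(0, noise_sd), with per-replicate label
swaps, localization probabilities drawn so a configurable fraction falls
below the 0.70 filter, and densitometry tables with planted dilution
curves, per-lane loading factors and per-bait proximity effects.  Defaults
are the stated world of the test suite: noise_sd = 0.3 log2 units
(typical SILAC ratio scatter), 3 replicates, 0.70 localization threshold,
motif settings 20/0.01, M-Track 10 baits × 4 replicates with effects of
+2.0 and noise 0.3.  Planted site-class effects are jittered inside ranges
that respect the classification thresholds, so ground-truth labels are
exact by construction; induced sites are biased 80% toward S/T-P sequence
context to emulate the proline-directed substrate signature.

Not emulated: retention-time/intensity structure, spectrum-level noise,
decoys and FDR, protein inference, correlated missingness between setups,
heavy-tailed ratio errors.  A green recovery test therefore establishes
correctness of the arithmetic and the estimators under the stated noise
model — not robustness to every failure mode of real MS data.

## Numerical choices

* Float comparisons in invariants use 1e-12 absolute tolerance; evidence
  ratios are written with 17 significant digits so log2 values round-trip
  bit-exactly, which makes pipeline reruns byte-identical.
* Estimator-recovery checks use 3·noise_sd/√n as the standard-error bound
  of both m̂ and ĉ (conservative for ĉ because halved two-proline residuals
  shrink the variance).
* Assigned phospho positions from probability-annotated strings are the
  top-k candidates with ties broken toward the N-terminus.
* All randomness flows through `numpy.random.default_rng(seed)`; derived
  stage seeds are small fixed offsets of the run seed.

## Known limitations

* The evidence reader supports a documented simple dialect and a
  maxquant-like column mapping with short modification tags; full MaxQuant
  nested-parenthesis modification syntax is out of scope.
* Phosphoisland construction is per run; cross-experiment island
  intersection is left to the caller.
* Motif extraction reports raw step p-values only; no FDR across motifs.
* The M-Track equivalent-loading inversion assumes the dilution curve is
  monotone over the measured range; signals far outside the fitted range
  are clamped to the parabola vertex for degree-2 curves.
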