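# Methods

This note documents the models, parameter defaults and numerical choices
behind `moevo`, and what the synthetic validation does and does not show
about real data.

## Observation model

Every somatic SNV is treated as heterozygous and diploid: a variant carried
by a cancer-cell fraction (CCF) `c` in a sample of purity `ρ` has expected
allele fraction `ρ·c/2`. Observed AFs are binomial draws at a
Poisson-distributed depth (truncated at ≥ 1 read), and an observed AF below
the detection limit counts as *undetected in that sample*. SNVs overlapping
CNAs are **not** AF-adjusted: aneuploidies are mostly subclonal and shift
shared and private AFs together, so they do not change the relative
cluster pattern the rules read; this is a deliberate simplification.

Defaults: detection limit 0.05 (the working sensitivity of a standard
somatic-calling pipeline at moderate whole-genome depth); mean depth 100;
purity 0.85 for both compartments. Depth 100 was chosen because the AF
cluster/gap detector (below) needs the binomial AF spread at the clonal
cluster (σ ≈ 0.05 at 100×, vs ≈ 0.065 at 60×) to be small enough that a
clonal cluster near AF 0.42 and a subclonal cluster above the detection
limit can be separated by a gap of the prescribed minimum width; at lower
depth the gap criterion has essentially no operating window and the
gap-based rule becomes uninformative rather than wrong.

## AF features

**Partition.** An SNV detected (AF ≥ limit) in both compartments is shared;
in exactly one, private to it. SNVs re-quantified *below* the limit in the
other compartment count as private — the convention a finite-sensitivity
pipeline implies. Fractions are over the union.

**Cluster/gap detection.** A Gaussian KDE with fixed absolute bandwidth
0.03 is evaluated on [detection limit, 1]. Clusters are maximal regions
with density ≥ 0.10 × the global maximum that retain ≥ 5% of the SNVs;
regions separated by less than the minimum gap width 0.08 merge into one
cluster, so "has a gap" is equivalent to "≥ 2 clusters". Fewer than 20 AF
values → "not assessable" (the gap rule abstains). These four constants
are the package's operationalization of a visual gap/no-gap reading; all
are configurable. Degenerate input (zero spread) short-circuits to a
single cluster.

**Cluster position.** The weight-dominant private cluster mode is compared
with the weight-dominant shared mode; |Δ| ≤ 0.10 counts as "equal" (the
same scale as the bandwidth-broadened cluster width). The delta is
absolute, so the claimed purity-invariance of the qualitative pattern holds
for realistic purities (≳ 0.5) but could flip "lower" to "equal" under
extreme AF compression.

**Purity.** Estimated as min(1, 2 × mode of the highest-AF shared cluster).
For neutral-like distributions whose subclonal tail merges with the clonal
cluster into one region, the merged cluster's mode sits below the clonal
mode and the estimate degrades (it is reported, never used by the rules).

**Independent origin.** A driver SNV (flagged, or gene ∈ {APC, KRAS, TP53}
by default) with polyp AF ≥ 0.25 whose cancer AF falls below 0.5 × the
polyp AF, or which vanishes from the cancer, flags the case: the cancer
likely arose from a different clone than the sampled polyp. Flagged cases
vote with rules 1 and 5 only and are reported at low confidence.

## The five rules and the vote

Rule 1 thresholds (fractions of the union): stepwise ≥ 10% cancer-private
AND ≥ 10% polyp-private AND ≥ 40% shared; parallel ≥ 50% private in either
compartment; neutral < 5% private on both sides; eruptive < 5%
cancer-private, ≥ 10% polyp-private, ≥ 80% shared. The stepwise condition
reads the private threshold as applying to both compartments (the
published wording repeats "cancer specific" twice; the symmetric reading is
the only one consistent with the stepwise archetype). Vote sets may
overlap, and an empty vote ("matches no mode") keeps the rule applicable.

Rule 2 maps (polyp gap, cancer gap): yes/yes → {s,p}; no/no → {n};
no/yes → {e}; yes/no matches no mode (the pattern of an independently
arisen cancer). The direction of the eruptive gap is genuinely ambiguous in
the source material; the tabulated no/yes reading is the default and the
alternative is selectable (`eruptive_gap_in="polyp"`).

Rule 3: polyp-private lower than shared → s (and e if the cancer side is
lower too); both equal → p; no private clusters on either side → n; any
"higher" position votes for nothing and records a polyclonal-suspicion
note. A compartment with < 5% private SNVs counts as having *no* private
mutations (the same cutoff rule 1 uses for "majority is shared") — without
this, a neutral case's handful of private SNVs would form a spurious
low-AF cluster.

Rule 4: shared AFs forming a single cluster in *both* compartments
(early-shared and late-shared indistinguishable) → {n,e}; any substructure
→ {s,p}; inapplicable below 20 shared AFs in either compartment.

Rule 5: a compartment is aneuploid when > 10% of its autosomal bp is
altered. Aneuploid polyp → {n,e}; aneuploid cancer only → {s,p,n} (neutral
always stays in the set because drift can fix aneuploidies at any time);
neither → inapplicable; a polyp fraction within ± 0.02 of the threshold is
ambiguous timing and the rule abstains.

Each applicable rule contributes one unweighted tally unit per mode in its
vote set; the final call is the argmax set (ties reported as sets, never
forced to a single label). Zero applicable rules, or a zero maximum tally,
→ "unclassifiable". Confidence is low iff the independent-origin flag is
set or fewer than 3 rules were applicable.

## Simulator archetypes

Cluster placements in CCF space (polyp, cancer; union weight), chosen so
each archetype expresses its defining features at the default purity/depth
— no published quantitative values exist for subclone CCFs or the
selection shift, so these are archetype choices, fixed once:

- **S** (fractions 0.55/0.15/0.30): shared clonal (1, 1; 0.30); the
  selected founding subclone (0.2, 1; 0.25) — shared, subclonal in polyp,
  clonal in cancer; polyp-private (0.2, –; 0.15); cancer-private under
  selection (–, 0.18 + shift; 0.30) with default shift 0.10.
- **P** (0.20/0.25/0.55): shared clonal (1, 1); private clonal-in-own-
  compartment clusters (1, –; 0.15) and (–, 1; 0.35) with subclones at CCF
  0.26 (0.10 and 0.20).
- **N** (0.97/0.015/0.015): shared clonal (1, 1; 0.35) plus a shared
  neutral tail (0.62) with frequencies drawn from the 1/f² density on
  [0.15, 0.5] (frequency units; CCF = 2f, so the tail reaches the clonal
  cluster and leaves no gap); tiny private clusters at CCF 0.3.
- **E** (0.85/0.12/0.03): shared clonal (1, 1; 0.37) plus four early
  subclusters forming a dense polyp CCF ladder (0.75, 0.55, 0.40, 0.28)
  that collapses to a low cancer block (0.25, 0.22, 0.20, 0.24), 0.12
  each; polyp-private (0.25, –; 0.12); minimal cancer-private (–, 0.24).

The 1/f sampler uses exact inverse-CDF draws, so the cumulative count
above f is linear in 1/f by construction (R² ≈ 1 at n = 10⁴); the test
verifies the implementation, not the biology.

CNA events are whole-chromosome (70%) or q-arm-scale (30%)
deletions/duplications on distinct chromosomes among the 12 largest
autosomes (5 events by default, comfortably above the 10% aneuploidy
threshold), with simulated tumor/normal copy numbers that pass the
genotyping filter. Timing follows the archetype: cancer-onset for s/p,
polyp-onset for e, per-event coin flip for n. Trinucleotide contexts are
drawn from toy spectra (flat; deamination-like C>T at NpCpG; MMR-like
C>T/C>A) — shaped stand-ins, not fitted signature vectors; real signature
matrices can be supplied by the user and are matched by cosine similarity.

**What the simulator does not emulate:** regional mutation-rate variation,
mapping artifacts, CNA-induced AF distortion, subclonal copy number,
genome doubling, multi-region sampling, and caller-specific error
profiles. Passing recovery tests therefore shows the rules read the
intended AF/CNA geometry through purity scaling and sequencing noise — not
that they are robust to every failure mode of real somatic calling.

## CNA metric and recurrence

Segments pass the genotyping filter when the matched-normal copy number
lies in (1.75, 2.25) and |tumor − normal| > 0.2; X and Y are excluded.
Per chromosome, similarity is (shared dup bp + shared del bp) / (union of
altered bp), 0 when neither sample has events; the genome score M is the
sum over autosomes (bounded by 22). Interval arithmetic is exact
sorted-merge bookkeeping, cross-checked against a per-bp bitmap oracle to
1e-12.

Recurrence: for each autosome, the per-sample-pair chromosome similarity
is paired against that pair's mean over the other autosomes and tested
with a one-sided Wilcoxon signed-rank test (greater). The paired unit is
the sample pair by default; a per-sample variant (altered fraction per
chromosome) is available (`mode="samples"`). All-zero differences report
p = 1 with a note. Raw p-values are primary; Benjamini–Hochberg values are
reported alongside as advisory.

UPGMA uses scipy average linkage on distances; similarities convert via
d = max(s) − s (monotone and parameter-free); exact ties merge lowest
index first. Spectra cluster on d = 1 − Pearson r; proportions are the
canonical input since Pearson is scale-invariant to count normalization.

## Problem sizes and determinism

Default simulated cases carry 2,000 SNVs — enough for ± 0.05 fraction
fidelity and stable KDE geometry while keeping a 50-case-per-mode recovery
run in tens of seconds on one core. All generators are `numpy`
`default_rng` seeded per scenario; identical scenario + seed reproduces a
byte-identical case and report. The acceptance script
(`scripts/acceptance.py`) derives every stream from its `--seed`.

## Known limitations

- The gap detector's four constants were tuned to the archetype geometry,
  not learned; unusual purity combinations (< 0.6) compress AFs toward the
  detection limit, bias observed private fractions upward and can hide
  gaps.
- The purity estimator degrades on gap-free (neutral-like) distributions.
- Rule 4 votes {n,e} for any case whose shared set is purely clonal — in a
  simulated parallel case this is a systematic minority mis-vote that the
  majority absorbs.
- The rules are qualitative by design; no probabilistic mode assignment is
  attempted.
- Multi-stage cases (tubular + villous + cancer) are supported by stage
  ordering (the most advanced polyp stage is compared against the cancer),
  but which stage best represents the pre-cancer compartment is a
  convention, not an inference.
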