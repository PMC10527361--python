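# Methods

This note records the models, parameter choices, and numerical conventions
behind the pipeline, and what the synthetic-data experiments do and do not
establish about real peptide-array data.

## Signal model and synthetic data

The generator emulates a flow-through peptide-array kinase activity
experiment. A spot's fluorescence at CCD exposure time `t` (ms) is

    I(t) = B + r · t · g_plate · ε,        ε = 2^N(0, σ_noise)

with background `B` (default 50 intensity units), true phosphorylation
rate `r` (intensity/ms), one multiplicative plate factor
`g = 2^N(0, σ_plate)` per 96-array plate (default σ = 0.25 log2 units),
and log-normal spot noise (default σ = 0.25 log2 units) shared across the
exposure ladder — the ladder re-images one physical spot, so its kinetic
series stays exactly linear in `t`. The default ladder is
10/20/50/100/200 ms; the instrument's actual ladder is not publicly
documented, so this is an explicit, configurable assumption, and all
downstream values are referenced to 100 ms.

Rates are kinase-driven: peptide `p` mapped to kinases `K(p)` has
`r = r_0 · Σ_{k∈K(p)} a_sk`, where `a_sk = 2^N(0, 0.25)` is the sample's
kinase activity and `r_0 = 3` intensity/ms/activity-unit puts processed
log2 signals near 8, the range seen on real arrays. Unmapped peptides
carry a small kinase-independent basal rate (uniform 0.05–0.2 activity
units), and 30% of them none at all — these dark peptides are what the
ATP-dependence filter removes, emulating the substantial peptide attrition
seen on real chips. Malignant samples multiply the planted *active*
kinases' activity by `2^effect` (default effect = 1 log2 unit on 3 of 20
kinases). No-ATP arrays retain a configurable nonspecific fraction of the
rate (default 5%).

The kinase→substrate map deals peptides from a shuffled pool without
replacement while supply lasts, so maps are disjoint whenever
`n_kinases × substrates_per_kinase ≤ n_peptides`; disjointness makes
planted-effect recovery well defined (a substrate shared with an inactive
kinase dilutes the planted contrast).

Default cohort sizes mirror the study design the generator stands in for:
21 benign + 34 malignant samples on 240-peptide arrays, each sample in
duplicate with ATP plus once without on a plate, the whole test repeated
on a second plate; and a 13-sample inhibitor run (7 mutation-positive +
6 negative) on 140-peptide arrays with control and inhibitor incubations
on adjacent arrays of the same strip. A *specific* inhibitor multiplies
the targeted kinase's activity by `depth` (default 0.5) in
mutation-positive samples only; a *nonspecific* inhibitor scales the whole
rate matrix by a mild common factor (default 0.8) in all samples —
basal phosphorylation is also kinase-driven, so a pan-kinase inhibitor
suppresses it too.

What the generator does **not** model: spot finding and grid alignment
(inputs are already-quantified intensities), CCD saturation at long
exposures, antibody binding kinetics and washing, spatial plate gradients
(the plate effect is a single scalar), and correlated peptide noise.
Passing recovery tests therefore show the *pipeline arithmetic* is
correct and powerful under the stated noise model, not that the
biological effect sizes of real cohorts are detectable.

## Preprocessing

Fixed order: net signal → exposure integration → ATP correction →
duplicate averaging → log2 → plate normalization → replicate averaging →
peptide filter.

* **Net signal** `max(I − I_bg, 1)`. The unit floor maps non-positive
  corrected signals to log2 = 0; the floor value is also what a truly
  dark spot series integrates to (a floored zero-rate ladder yields
  `100·Σt/Σt² ≈ 0.52` at the default ladder), which the exactness tests
  account for in closed form.
* **Integration**: through-origin OLS slope `Σty/Σt²` evaluated at the
  100 ms reference. Exact for linear kinetics, and the natural kinetic
  readout when only "integration into one value" is specified.
* **ATP correction**: per plate, with-ATP value minus the same sample's
  mean no-ATP value; duplicates averaged *after* correction;
  `log2(max(·, 1))`.
* **Plate normalization**: subtract each plate's median over all its
  cells, add back the grand median over all cells. This equalizes
  per-plate medians exactly and is idempotent. Caveat recorded here
  deliberately: a multiplicative effect injected into one plate is
  removed exactly *between* plates (replicate rows agree bitwise), while
  the absolute level of the whole matrix may shift by a pooled-median
  constant, since any location anchor computed from all plates moves when
  one plate does. Cells sitting on the unit floor cannot track a plate
  factor at all; on real data those are precisely the peptides the filter
  discards.
* **Replicate averaging**: arithmetic mean across plates per sample;
  missing replicates are ignored, never imputed.
* **Filter**: a peptide is kept iff its ATP-corrected value exceeds 0 on
  strictly more than 30% of with-ATP arrays. ATP dependence and the
  increase criterion are one rule here (corrected > 0), since no separate
  operationalization of "ATP-dependent" is available; the threshold is
  configurable.
* **LFC**: per strip, log2(inhibitor, floored) − log2(control, floored),
  replicate strips averaged per sample, computed on un-normalized values
  because paired arrays share a strip and plate effects cancel by
  construction.

## Classification

PLS-DA is implemented as NIPALS PLS1 on the autoscaled matrix (columns
mean-centered and unit-variance scaled with ddof = 1; constant columns get
scale 1) against the coding benign = +1 / malignant = −1. Defaults:
2 latent components — the number of components is genuinely open, and two
is the conventional PLS-DA working dimension; it is configurable and the
full-rank limit provably coincides with least squares. Autoscaling is
refit inside every cross-validation fold; leave-one-out is the primary
error estimator. A prediction score of exactly 0 classifies malignant
(only score > 0 is benign). The permutation test repeats the *entire*
cross-validation under label reassignment (class sizes preserved) and uses
the +1-corrected p-value, so p ≥ 1/(B+1); both LOOCV and k-fold schemes
are supported for the null because the two appear interchangeably in
descriptions of this procedure. Confusion metrics take malignant as the
positive class and report undefined ratios as missing rather than 0.

## Differential testing

Classical pooled-variance Student's t (not Welch — the pooled form is
what "Student's t-test" names), df = n₁+n₂−2, two-tailed. Zero pooled
variance with equal means returns (t = 0, p = 1); with unequal means it is
an error surfaced to the caller. Missing cells are dropped per peptide;
peptides with fewer than 2 values in a group are reported untestable
rather than aborting the table. BH q-values are computed as a reverse
running minimum of `p_(j)·m/j` so each q is exactly one of those terms.
The single "FDR x%" figure attached to a p-threshold set is the maximum
q-value among peptides passing the p cut — a reporting convention, chosen
because it is the only definition that pairs one FDR number with a p cut.

## Upstream kinase scoring

Per peptide, the effect is the standardized mean difference
`(m₂ − m₁)/s_pooled` ("normalized" statistic); per kinase, the statistic
is the mean effect over a substrate set. Significance permutes sample
labels, specificity draws random same-size peptide sets from the filtered
peptides; both use two-sided +1-corrected p-values, so scores are bounded
by log10(B+1) (≈ 2.70 at B = 500). Scores are averaged over a ladder of
top-k substrate sets by mapping confidence rank, k ∈ {4, 6, 8, 10, 12}
truncated to the available substrates (minimum 3 mapped filtered peptides
to be scored at all); the ladder realizes the "mean score" notion when the
original set-size scheme is not reproducible from public descriptions, and
a single-set mode (ladder = {k}) is available. Peptide-set means are
evaluated in sorted column order so identical sets give bit-identical
statistics. One behavioral note: under a matrix-wide shift the specificity
p-value is approximately uniform rather than pinned at 1 (sampling noise
breaks exact ties between peptide sets), so specificity collapses in
median while significance saturates — the decoupling that separates a
global activity change from a substrate-confined one.

PAM30 similarity is the best ungapped-window score of the query peptide in
the target protein divided by the query self-score, using the standard
NCBI PAM30 table over the 20 canonical residues; only ratio exactly 1
(tolerance 1e-12) counts as an unambiguous mapping, and diagonal dominance
of PAM30 guarantees any substitution scores below 1.

## Determinism and problem sizes

All randomness flows from explicit seeds: the generator derives
independent streams per purpose and per (plate, array) from the master
seed, so sub-tables are reproducible in isolation, and rerunning any stage
with the same config is byte-identical (floats serialized at 9 significant
digits). The test suite exercises the full study-scale cohort (55 × 240,
B = 500) once; statistical calibration tests run at reduced sizes chosen
to keep the suite fast while retaining power — 200 null datasets at
B = 99 for the permutation-test calibration, 20 seeded simulations for
kinase-ranking recovery, B = 199 for decoupling checks. These sizes are
the package's own test design; all operational defaults remain B = 500.

## Known limitations

* Median plate normalization assumes classes are balanced across plates
  (the generator interleaves them as the assay design prescribes); a
  confounded plate layout would alias biology into the plate correction.
* The exposure ladder and reference exposure are assumptions; absolute
  log2 levels (not contrasts) depend on them.
* The specificity score inherits the granularity of B and the peptide
  pool; with few filtered peptides, random sets overlap the substrate set
  heavily and specificity saturates low.
* No moderated (limma-style) variance shrinkage: with very small groups
  the per-peptide t-test is noisy, as the wide FDR figures on the
  13-sample inhibitor contrasts show.
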