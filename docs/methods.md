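# Methods

## Data model

The unit of analysis is the **peptidoform**: a bare peptide sequence plus
its set of modifications, with oxidized and unoxidized forms of the same
sequence treated as distinct species. Peptidoform identity is the pair
(bare sequence, set of MSox site positions). Carbamidomethylation is a
fixed sample-prep modification: it is parsed and carried, but excluded
from identity, so charge states or carbamidomethyl variants of the same
species collapse into one record whose per-sample AUC is the sum of the
duplicates (a species is quantified by its total area under the curve).
Two notations are parsed: bracket notation (`LGAD[M]EDLR`, the bracket
marking an oxidized methionine) and PEAKS delta-mass notation
(`LGADM(+15.99)EDLR`; +15.99 on M is MSox, +57.02 on C is
carbamidomethyl, other deltas are carried as OTHER). A `[M]` or +15.99
annotation on a non-methionine residue is rejected as a validation error.

Missing abundances are missing, not zero. A zero AUC cell in a label-free
export means the species was not detected — typically censoring at the
lower limit of detection — so zeros are normalised to missing at ingest.
No imputation is performed anywhere.

Identification-level filtering mirrors standard target–decoy practice:
peptide score (−10logP) ≥ 15 and, when an FDR column is present, FDR ≤ 1%.
Both thresholds are configurable; the filter is idempotent.

## Batches and the design

Each time point was processed as one acquisition batch, and batches are
not absolutely standardized against each other. The design model
therefore enforces that a time-point group maps to a single batch, and
every quantitative comparison (fold change, t-test, occupancy contrast)
refuses sample groups spanning batches (`CrossBatchError`). Across time
points only identification-level comparisons (set overlap) are made.

## Speciation and temporal overlap

A group's MSox-ome contains peptidoforms with ≥1 MSox site and a finite
AUC in at least one sample of the group. Coverage is reported as MSox
peptidoform count, count of proteins they annotate (first accession of a
multi-accession row is canonical), and MSox % with the number of distinct
quantified peptidoforms detected in the same group as denominator — the
most natural denominator for "fraction of the observed proteome", chosen
explicitly since alternatives (all rows in the file, union across groups)
exist. Protein-level MSox-omes per time point are partitioned into the
2³ − 1 disjoint Venn regions; proteins in the triple intersection are
**constant** oxidation targets, all others **dynamic**. Because the
literature describes the overlap either on detected or on significantly
changed proteins, both modes are implemented (`venn_mode =
detected | significant`); detected is the default.

## Differential analysis

Fold change is the ratio of group mean raw AUCs (5XFAD/WT), missing
values excluded. The t-test defaults to Student's pooled-variance test on
log2 AUC: intensities are approximately log-normal, so the log2 transform
stabilizes variance; testing on the raw scale and Welch's test are
available by flag since the choice is not canonical. A p-value requires
≥3 finite values per group; below that the call is NA rather than
imputed. Volcano calls use FC ≥ 2 / FC ≤ 0.5 with p ≤ 0.1 (inclusive
boundaries); the enrichment input set uses the stricter log2FC ≥ 4 with
p ≤ 0.1. Calls are made on raw p-values by design; BH q-values are
reported alongside for transparency but not used for calling, matching
discovery-stage practice for this modification.

## Occupancy (stoichiometry)

For a protein and a peptide pool, each sample's oxidized sum is the AUC
of pool peptidoforms carrying ≥1 MSox site (a doubly oxidized form counts
once) and the unoxidized sum is the AUC of the same bare sequences with
no MSox. Occupancy is `100 · ox/(ox + unox)`, computed **per sample**
and then summarised per group — per-animal occupancies preserve
biological replication and feed Cohen's d directly. A sample with no
detected oxidized form but a detected unoxidized form is below the
detection limit for the oxidized species: it is scored 0% with a
`censored` flag, and an exclude-censored mode is available because the
right handling is context-dependent. If neither form is detected the
occupancy is undefined (NA). Cohen's d uses the classic pooled-SD form
with n₁ + n₂ − 2 degrees of freedom and no small-sample (Hedges)
correction; zero pooled SD with unequal means yields signed infinity
rather than an exception. Site-resolved occupancy for multi-methionine
peptides is out of scope.

## Enrichment

One-sided (overrepresentation) Fisher's exact test: p = P(X ≥ k) for the
hypergeometric count of term members in the target set, with term
membership intersected with the background before counting so the
universe is exactly the quantified proteins. Terms with zero overlap are
reported with p = 1 instead of dropped, keeping MSox-universe and
proteome-universe tables alignable row by row. BH adjustment is the
classical step-up, implemented directly from the running-minimum
formulation and cross-checked against statsmodels in the tests.
Depletion testing, annotation-hierarchy collapsing and live annotation
services are out of scope; annotations are taken as given in the GMT.

## PRM QC

Calibration curves are unweighted OLS of AUC on concentration over the
seven-point ladder 0.1, 0.5, 1, 10, 25, 50, 100 fmol/µL, gated at
R² ≥ 0.996 (configurable); a 1/x-weighted fit is available for the wide
ladder. Background (spontaneous) oxidation of an unmodified standard is
the same function as biological occupancy — one shared implementation,
asserted by a test. Stability over storage months (0, 1, 2, 6, 11) is
summarised as mean, SD, CV and maximum absolute drift of the background
oxidation percentage.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study's shape: three time-point batches,
each with 8 wild-type and 8 5XFAD mice balanced for sex. Per-protein
abundance is log-normal (default mean 2²⁰ AU, SD 2 log2 units, with
per-peptide offsets of SD 1); per-batch log2 intensity shifts are
confounded with time point by construction, so the cross-batch guard is
exercised by the data itself. For every Met-containing peptide the
oxidized and unoxidized forms receive expected AUCs `total · occ/100`
and `total · (1 − occ/100)`, each independently perturbed by mean-one
log-normal noise and then censored at the LOD (default 2¹⁵ AU) —
noise lives at the AUC level, not the occupancy level, so stoichiometry
estimates inherit realistic error and low-occupancy oxidized species
censor first.

Default occupancies encode the study conditions: baseline 6.7%
(wild-type APOE-like level), +10.4 points in 5XFAD at 9 months (17.1%
total) and +3 at 6 months. The default AUC noise CV of 0.21 was
calibrated once, analytically, so that a two-peptide pool's per-group
occupancy spread pools to ≈ 2.3 percentage points at those levels
(SD ≈ p(1 − p)·cv for a two-peptide pool), the spread implied by the
targeted effect size of ≈ 4.4–4.5. A small set of "induced" proteins
models strongly oxidation-upregulated neuroinflammation targets
(wild-type 1%, 5XFAD 25%, high abundance so both genotypes stay above
the LOD); these drive the differential and enrichment stages, and a
planted GMT term collects them. Sex is generated and carried but has no
simulated effect, mirroring the negligible sex differences in this
design. `apoe_like_config()` provides the small single-batch
configuration used for occupancy-recovery studies (6 proteins, 2
peptides each, high abundance).

Not emulated: retention-time/charge-state structure, peptide-specific
ionization efficiency, the growth of MSox detection coverage with age,
correlated (protein-level) biological occupancy variation between
animals, and missingness mechanisms other than LOD censoring. Passing
tests therefore demonstrate correctness of the estimators and the
pipeline contract under the stated noise model, not robustness to every
artefact of real LC-MS data.

PRM simulation: AUC proportional to concentration with multiplicative
noise (default CV 1%, the regime of a well-behaved targeted assay);
stability rows carry the planted background oxidation levels (1.63% and
4.20% for the two standards) plus N(0, 0.15) month-to-month drift.

## Numerical choices

- Occupancy computes `(ox/total)·100` (ratio first) so results stay in
  [0, 100] exactly at the boundaries.
- Identical constant groups give t-test p = 1 (no evidence of
  difference); constant but unequal groups give p = 0.
- BH q-values are computed with a running minimum over the descending
  sorted p-values, clipped at 1, in input order; ties are handled by
  stable sort.
- Pipeline TSV/JSON floats are written at 6 significant digits, making
  reruns byte-identical.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; no global state.

## Problem sizes

The default simulated study uses 150 proteins (~500 peptides, ~600
observed rows per batch) — compact enough for interactive use while
exercising every pipeline branch, including LOD censoring and NA calls.
Recovery studies replicate the 6-protein APOE-like configuration over
hundreds of seeds (500 in the test suite, 300 in the acceptance script);
PRM linearity is assessed over 1,000 fitted curves.
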