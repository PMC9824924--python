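# Methods

This note records the model behind each stage, the defaults and why, the
numerical choices, and what the synthetic validation does and does not
demonstrate.

## Structure standardisation and identity

Standardisation runs largest-organic-fragment selection, charge
neutralisation, stereo removal and tautomer canonicalisation, in that
order, on RDKit's `rdMolStandardize` components. Stereo is removed
*before* the tautomer step because tautomer canonicalisation does not
preserve stereocentres, and flag bookkeeping is cleaner when each step's
effect is observable. Identity is the 14-character connectivity block of
the InChIKey of the standardised structure, so two inputs differing only
in counter-ions, protonation, stereo descriptors or tautomeric form share
a key. Correctness is asserted through idempotence and equivalence-class
tests rather than byte-identity with any particular external tool: the
exact canonical tautomer is backend-dependent, but the contract — equal
keys iff equal heavy-atom connectivity after cleanup — is not.

Mixture tie-breaks: among largest fragments of equal heavy-atom count,
the lexicographically largest canonical SMILES wins (deterministic,
input-order independent). Unparseable and carbon-free inputs become
`rejected` records with a reason; rejection is data, never an exception,
so one bad row cannot abort an ingest.

A `keep_stereo=True` mode exists for the stereo-preserving variant of a
dataset. It deliberately skips tautomer canonicalisation (which would
scramble stereocentres) and is excluded from the deduplication
guarantees; the connectivity-level set is the primary product.

## Activity normalisation

Admitted types are Ki, K_D, IC50, EC50 with molar units (M, mM, µM, nM,
pM; alias table is editable config) and their negative-log transforms,
taken verbatim and flagged `assumed_p_scale` since no unit check is
possible for a bare log value. pChEMBL is carried at full double
precision through aggregation and rounded to two decimals only for
presentation — rounding before pooling would make the mean depend on the
rounding order. Censored records keep their bound; because −log10 is
decreasing, concentration bounds flip orientation on the p-scale. ≤ and ≥
are treated as their strict counterparts for filtering decisions but the
original relation is stored. Binary activity classes are admitted
(carrying a class label, no value) regardless of the stated type string,
since the label, not the type, is the evidence.

No Cheng–Prusoff Ki↔IC50 interconversion is attempted; types stay
separate through aggregation (below).

## Quality tiers

The tier is a pure function of (evidence kind, target-mapping): exact +
single-or-complex-subunit → high; exact + multiple-possible-proteins or
single-homolog → medium; exact + multi-homolog or homolog-complex →
low; censored → low; binary → low. This is the operational decision
table; mapping degradation can never raise a tier (tested). The
target-mapping enum is this module's input contract — deriving it from a
source database's assay confidence scores is upstream of this package.

## Deduplication and aggregation

Lineage is declared data: a mapping from source id to the upstream
sources it repackages, expanded transitively (a cycle is a hard error).
Within a content-identical group (connectivity key, target, assay, type,
relation, value, unit), records from a source that repackages another
present source are dropped; identical rows within one source collapse to
one; genuinely independent equal values all survive. Composite "derived"
score types pass through untouched, flagged `derived`.

Pooling is per (connectivity key, accession, activity type): mean,
sample standard deviation (ddof 1, defined 0 for n = 1) and median
(midpoint rule for even sets) over exact values; censored records are
counted but excluded from the statistics, and censored-only pairs carry
their bound relation(s) instead of statistics. Ki, K_D, IC50 and EC50 are
pooled separately because they answer different assay questions; a
`pool_types` switch exists for use cases that want one number per pair.
The pooled record's quality is the *worst* contributing tier: a pair is
only as reliable as its weakest included point. Binary records are
tiered and counted in measurement-level reports but do not form
aggregated pairs — an aggregated record must carry exact or censored
pChEMBL evidence by construction.

The pair's year span is [earliest, latest] contributing document year;
the earliest year is what splits use (a pair known early belongs to the
past).

## Concordance filter (high-reproducibility subset)

Ki and K_D pass unfiltered. For IC50 and EC50 separately: every pair
measured in ≥ 2 assays takes the median over its measurements (not over
per-assay means), and a point is non-concordant when its absolute
distance to that median strictly exceeds 0.5 log units ("greater than",
so a point at exactly 0.5 stays). Each assay is scored per measurement
over the multi-assay pairs it appears in; it is reproducible when its
concordant fraction is at least 0.75 (inclusive). Singleton points
survive only in reproducible assays; an assay with zero multi-assay
comparisons cannot demonstrate reproducibility, so its singletons are
excluded — the conservative reading consistent with the filter's
purpose. Censored and binary IC50/EC50 records are outside the filter's
remit and are not part of the high-reproducibility subset. Both
thresholds are configuration.

The pass is single-shot: survivors are not re-scored against the new
median. Note the single pass is *not* idempotent as a mathematical
identity — e.g. values [6.0, 6.0, 7.0, 8.0] have median 6.5 and lose only
the 8.0, while re-running on {6, 6, 7} (median 6.0) would also remove the
7.0. On realistic evidence structures (pairs measured by a handful of
assays, outliers well separated) a second pass changes nothing, which is
what the seeded fixture test asserts; an iterative variant is
deliberately out of scope.

### Synthetic recovery conditions

The validation experiment plants a +1.0 log-unit bias in one of six
assays, with measurement noise σ = 0.1 and every pair measured by three
assays, giving each assay roughly 20 comparisons on shared pairs. Over
200 seeded replicates the biased assay must be flagged non-reproducible
in ≥ 95 % of replicates and clean assays in ≤ 5 %; measured rates are
100 % and 0 %. With three measurements per pair the median sits at the
unbiased level, so the planted offset is fully visible; a two-point pair
splits the offset symmetrically (both points at distance bias/2), which
is why the experiment fixes three.

## Benchmark splits

A target is QSAR-eligible when it has ≥ 30 actives *and* ≥ 30 inactives
at the activity threshold (pChEMBL ≥ 6.5 is active; both counts
inclusive) and its mean-pChEMBL spread is ≥ 2 log units (inclusive).
The temporal split assigns year ≥ 2013 to test, earlier to train, using
the pair's earliest contributing year; pairs with no year go to train
(unknown provenance is treated as old, the conservative choice for
prospective evaluation). A target with an empty side is disregarded. The
random split is seeded (`numpy` Generator, default seed 1234), with
`round(n·fraction)` test records and an optional stratified mode that
keeps the test class balance within one record. A seeded k-fold utility
is provided; model fitting itself is out of scope.

## Sphere-exclusion diversity

Fingerprints are folded Morgan, bond radius 3 (ECFP6-equivalent), 1024
bits. The leader algorithm scans in order; a point founds a new centre
iff its Tanimoto distance to every existing centre is strictly greater
than the radius (default 0.65), i.e. a candidate at similarity ≥ 0.35 to
a centre joins that sphere. SE_Div = centres / set size, which lies in
[1/n, 1] and hits both bounds on degenerate sets (all duplicates; all
mutually dissimilar). Because the statistic grows with set size,
datasets are compared via repeated fixed-size subsampling (defaults: 228
compounds, 10,000 repeats) without replacement, independently across
repeats. The scan order is re-randomised per repeat — the leader pick is
order-dependent and a fixed order would bias the statistic by input
sorting — and the dataset is put in a canonical fingerprint order before
sampling so results are invariant to input record order at fixed seed.
Tests and the acceptance script use a reduced protocol (100 repeats) and
check cross-seed agreement within three combined standard errors; the
implementation is verified index-for-index against an independent
brute-force O(n²) oracle on random instances up to n = 200.

## PDB complex matching

Matching is file-based (PDB id, ligand InChI, chain accession rows); no
network access is required or used, though the table can come from any
identifier-mapping export. Both sides run the *same* standardisation
before comparison, so identity is connectivity-level by default — a
deposited ligand differing only in its stereo layer still matches the
stereo-free curated molecule, and deposited-structure mutations are
ignored (complexes map to the wild-type accession's affinity data). All
complex ids of a matched pair are returned, sorted. `strict_inchi=True`
compares full stereo-bearing InChIKeys for the stereo-preserving
variant. Malformed rows are logged and skipped, never fatal.

## Synthetic-data generator

The generator emulates the statistical structure the pipeline assumes:
true pair affinities are i.i.d. N(6.5, 1.5) pChEMBL — centred on the
activity threshold so eligibility and stratification are exercised both
ways — observed as truth + per-assay bias + N(0, σ) noise, re-expressed
in concentration units with varied spellings. Defaults: 40 molecules × 8
targets at 60 % pair density, 10 assays (2 per pair), 3 sources, bias sd
0.3, noise sd 0.1, 5 % random censoring plus detection-window censoring
at pChEMBL 3–11, 5 % binary labels, 10 % structure variants
(counter-ion salt, random atom order, kekulised SMILES), 10 % degraded
target mappings, publication years uniform 2005–2020 (straddling the
2013 cut), and one extra source repackaging 20 % of the first source's
rows with declared lineage. Every planted artefact is listed in a
manifest by (source, row), which is what stage-level recovery tests
check against. All randomness flows from one seed through named
substreams, so one artefact family can change without reshuffling the
others.

What passing on this generator does *not* show: real sources disagree in
ways the generator does not model — inconsistent assay annotations,
heterogeneous unit errors, structure drawing mistakes, correlated (not
independent) measurement errors, and realistic medicinal-chemistry
structure distributions. The molecule library is a deterministic family
of substituted rings and chains chosen for distinct connectivity, not
for chemical realism. Results on synthetic worlds validate the
*mechanics* of each rule, not curation quality on any real database.

## Problem sizes and determinism

The validation suite runs desk-scale worlds (hundreds of measurements,
hundreds of fingerprints, 200 recovery replicates, 100 oracle
instances, 100-repeat diversity protocols); these sizes give the
recovery and stability checks comfortable statistical margins while the
whole suite stays interactive. Every stochastic component takes an
explicit seed; property tests are derandomised. Percentages in reports
round half-up to two decimals via decimal arithmetic (not banker's
rounding), matching the convention of printed summary tables.
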