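# Methods

## Pharmacokinetic model and class definition

The package's canonical CL_int unit is μL/min per mg microsomal protein.
Unit conversion uses the standard physiological scale-up of 45 mg microsomal
protein per g liver and 21 g liver per kg body weight, so 1 μL/min/mg =
0.945 mL/min/kg; a per-g-liver value converts by ×1000/45 and a per-kg-body
value by ÷0.945.  "mL/min/g" is read as per g *liver* by default — this is
precisely the database convention whose misapplication to per-mg-microsome
numbers inflates them 22.2-fold.

Hepatic clearance and availability follow the well-stirred model with
instantaneous mixing and no microsomal binding:

    CL_h = Q_h·f_up·CL_int / (Q_h + f_up·CL_int)
    F_h  = Q_h / (Q_h + f_up·CL_int)

with CL_int rescaled to mL/min/kg before use.  The default hepatic blood
flow is Q_h = 21.215 mL/min/kg.  Note that the often-quoted derivation
5.2 L/min cardiac output × 26.0 % hepatic fraction / 64 kg gives 21.125;
the constant 21.215 is retained because the reference availability values
(0.428/0.130/0.070 at CL_int = 300 for f_up = 0.1/0.5/1.0) are reproduced
only with it.  F_h and CL_h are rounded half-up to 3 decimals at
presentation only, never internally.

Class cutoffs are left-closed upward: stable < 20 ≤ moderate < 300 ≤
unstable (μL/min/mg).

## Curation rules

Basic filtering removes entries without a value, measured outside HLM, or
carrying a non-CL_int unit.  Protocol filtering (curated mode only) requires
37 ± 0.5 °C, pH 7.40 ± 0.05, no inhibitors and an NADPH cofactor; entries
with *missing* protocol fields are rejected under the default strict policy
(a lenient policy is available) — the strict reading reproduces the
conservative spirit of "retain only what is known to conform".

Cross-checking compares each record against its original-publication value
and unit.  A unit mismatch triggers recomputation from the source via the
conversion above (`unit_recalculated`); a value disagreement beyond 1 %
relative (after unit normalization) adopts the source value
(`value_replaced`).  The 1 % tolerance is a package choice; no reference
value exists for it.  Entries without a source record are kept but flagged
unverifiable.

Per-compound resolution intersects, over all surviving entries, the set of
classes each entry is consistent with.  Exact entries pin one class;
qualifier entries contribute the classes their half-line intersects
(">20" → {moderate, unstable}; "≥300" → {unstable}).  A compound is kept iff
the intersection is a single class; its representative CL_int is the
geometric mean of the exact entries (only the class matters downstream).
Compounds kept on the strength of a single class-pinning qualifier are
retained — a documented choice where practice varies.  Every entry receives
exactly one terminal ledger action per mode, so input count always equals
the ledger total (checked at run time).

## Descriptors and fingerprint

The built-in physchem block (17 descriptors: MW, SLogP, TopoPSA with and
without S/P, HBA, HBD, acidic and basic group counts, rotatable bonds, ring
statistics, F/Cl counts, molar refractivity, …) is computed with RDKit.
Larger descriptor sets plug in through the external-provider hook (any
callable returning a named numeric matrix).

The circular fingerprint is implemented in-repo: atom identifiers start from
the invariant tuple (atomic number, heavy degree, total H count, formal
charge, ring flag), are refined diameter/2 times by hashing the atom's
identifier with its sorted (bond order, neighbour identifier) pairs, and are
folded modulo nbits (default 4,096, power of two enforced).  Environments
with identical bond sets collapse to one identifier (the smallest, making
the result independent of atom input order); methane therefore sets exactly
one bit.  Hashing uses BLAKE2b on packed integers, so vectors are
byte-identical across platforms and runs.  No claim of bit-compatibility
with any other toolkit's fingerprint is made — equivalence is structural,
not bitwise.  A "distance cut-off" of 6 recorded in configuration is inert
for diameter-4 environments and kept only for config fidelity.

Feature filtering removes any column with a missing value or with exactly
constant raw values (no variance epsilon), reports each removal with its
reason, and is idempotent.

## Network split

Compounds are nodes; similarity is the biweight midcorrelation (bicor) of
their standardized, filtered descriptor profiles, with u = (x − median)/
(9·MAD) and Tukey weights (1 − u²)² for |u| < 1.  A profile with zero MAD
has no robust scale, so pairs involving it fall back to Pearson.  Adjacency
is the sigmoid a = 1/(1 + e^(−α(s − τ))) applied to the signed similarity
(strong anticorrelation → near-zero adjacency), α = 25 and τ = 0.9 by
default — the slope/midpoint reading of the conventional "power" and
"threshold" parameters.  The topological overlap measure

    TOM_ij = (Σ_{u≠i,j} a_iu·a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

feeds average-linkage clustering on 1 − TOM.  The dendrogram is cut at a
deep_split-dependent fraction of its maximum merge height
(0.999 … 0.99 for deep_split 0 … 4); clusters below min_cluster_size
(default 3) are dissolved and routed to the test set.  This static-fraction
schedule was chosen to reproduce the qualitative behaviour of dynamic tree
cutting on diffuse chemical-similarity data — a handful of clusters with
one dominant — while still recovering planted partitions exactly; exact
replication of the hybrid dynamic-cut heuristics is out of scope.  The
largest cluster becomes the training set (lowest label on ties), everything
else the test set, so test chemistry is systematically dissimilar from
training chemistry.  The module contains no randomness.

Open choices documented: compounds (not features) are the network nodes, and
the network is built on the filtered, standardized matrix.

## Feature selection

The all-relevant screen appends a column-permuted shadow copy of the feature
matrix each iteration, fits a random forest, and scores a hit for every
real feature whose importance exceeds the best shadow importance.  Decisions
use a two-sided binomial test (p = ½) at significance 0.01 Bonferroni-divided
by the feature count; max_runs defaults to 100 and undecided features end
tentative and are excluded downstream (strict).  The default importance is
permutation importance, which is unbiased on sparse binary fingerprint bits;
an impurity option trades that robustness for a large speed-up and is used
in the large end-to-end experiment below.

## Models and tuning

All models centre and scale features with training-set statistics.  Grids:
random forest over mtry (10 log-spaced values in [√p/4, p/2], out-of-bag
validation); AdaBoost over mfinal ∈ {50..500} × maxdepth ∈ {1..10} ×
weight-update flavour; SVMs over cost 2^(−2..7), with the radial kernel's
sigma grid seeded by the median pairwise-distance heuristic.  Non-forest
models use stratified 10-fold cross-validation; model selection maximizes
resample accuracy with κ as tiebreaker, then refits on all training rows.
The three classical AdaBoost weight-update flavours map onto SAMME learning
rates 0.5 (half-log), 1.0 (full log) and 1.5; exact reproduction of other
toolkits' boosting grids is not attempted.  Tuned values from a fidelity
run can be pinned through `fixed_hyperparameters`.

## Synthetic data generator

The generator emulates an open-database CL_int export with known truth.

*Structures*: combinatorial assembly of 12 drug-like scaffolds × 20
medicinal-chemistry substituents at two sites, RDKit-validated,
canonical-deduplicated, filtered to MW 150–550.  Deterministic per seed; the
space supports well over 1,000 unique structures.

*Truth*: log10 CL_int = affine(0.8·SLogP − 0.9·TopoPSA/100) + N(0, 0.3),
clipped to [0.1, 3000] μL/min/mg.  The affine part is quantile-targeted so
the class mix hits the default 40/50/10 stable/moderate/unstable split.
The slopes encode the empirical dominance of lipophilicity (positive) and
polarity (negative) in microsomal stability; the 0.3 log-unit noise is a
realistic twofold inter-assay spread.

*Corruption*: each compound yields 1–3 entries (60/30/10 %).  Error modes
and default rates:

| mode | rate | scope | effect |
|---|---|---|---|
| per-g-liver unit misread | 0.40 | compound | all entries recorded as mL/min/g; naive conversion inflates ×22.2; source record intact |
| transcription | 0.05 | entry | two digits swapped; source intact |
| qualifier range | 0.05 | entry | value replaced by a cutoff bound ("<300", ">20", ">300") |
| conflicting duplicate | 0.05 | compound | extra entry whose *source itself* reports a different class |
| off-protocol | 0.40 | entry | 30 °C, pH 6.8 or no NADPH; value biased ×0.2 (slower turnover), source matches the biased number |

The unit misread is drawn per compound because the error originates in the
source publication's unit being misinterpreted on deposition — every entry
derived from that source inherits it consistently.  The two large rates are
calibrated to the error frequencies large open CL_int collections actually
exhibit, where a majority of surviving records required unit recalculation
and roughly two-fifths of entries came from non-standard protocols.
Cross-checking can repair the misreads and transpositions (the source record
is intact); protocol filtering can only *remove* off-protocol entries; and
conflicting duplicates are irreparable by construction — each error mode
exercises a different curation rule.

What the generator does **not** emulate: real assay noise beyond a
log-normal spread, correlated errors across compounds from one laboratory,
salt/stereoisomer ambiguity, or the full schema of any particular database.
Passing tests therefore demonstrate that the curation machinery repairs the
error taxonomy it models, not that it would capture every failure mode of a
specific real export.

## End-to-end experiment

`run_experiment` builds both datasets from one entry stream, clusters the
curated dataset, trains on the largest cluster, removes the identical test
IDs from the non-curated pool, and — per arm — filters features on training
rows, runs the shadow screen on training rows only, tunes, trains, and
evaluates on the shared test set against the curated labels.  A master seed
fans out to named substreams (simulation, per-arm selection, per-model
fitting), making the whole report byte-reproducible.

The ten-seed acceptance experiment runs n = 600 compounds per seed with the
default corruption rates, a 256-bit fingerprint, the impurity-importance
shadow screen (15 runs, 50 trees) and the radial SVM tuned over the full
10×10 sigma-cost grid.  These problem sizes keep a full ten-seed replicate
around two minutes on a single core while preserving the phenomenon under
study: the curated arm wins on both test κ and critical mis-prediction in
at least 8 of 10 seeds.  The mechanism mirrors the real one: naive unit
conversion inflates a large minority of training labels toward unstable, the
uncorrected arm learns to over-predict instability (and mislabels some truly
stable chemistry as unstable outright), while cross-checking repairs
essentially all repairable labels (recovery ≳ 0.99 vs ≈ 0.55 uncorrected at
default rates).

## Numerical choices and degenerate inputs

- Zero-variance detection is exact equality, not an epsilon.
- bicor falls back to Pearson only for zero-MAD profiles; outputs are
  clipped to [−1, 1] and symmetrized against floating-point drift.
- TOM guards 0/0 (isolated node pairs) to 0 and clips to [0, 1].
- κ with chance agreement 1 raises instead of returning NaN; per-class
  statistics report undefined cells as None.
- Compounds whose every entry fails conversion vanish from the compound
  table but remain in the ledger (`unit_rejected`).
- An all-one-cluster split returns an empty test set with a warning rather
  than failing.
- Representative CL_int uses a 1e-12 floor inside the geometric mean.

## Known limitations

- The built-in physchem block is intentionally compact; reproducing
  thousand-descriptor commercial or academic sets is delegated to the
  provider hook.
- The fingerprint is a faithful member of the ECFP family but not
  bit-compatible with any particular toolkit.
- The dynamic-cut emulation is a static-fraction schedule; dendrograms whose
  genuine module structure sits far below the cut height will under-split.
- Boruta's binomial decision framework treats iterations as independent
  Bernoulli trials, which is approximate when importances are correlated
  across iterations.
- The latent CL_int model is two-descriptor linear in log space; real
  structure–clearance relationships are far richer, so absolute κ values on
  synthetic data are not predictions of real-data performance — only the
  curated/non-curated *contrast* is the object of study.
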