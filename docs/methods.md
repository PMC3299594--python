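# Methods

## Model

A compound is represented by nine 2D physicochemical descriptors, in the
package's fixed canonical order: Wt (daltons), RB, HBA, HBD (counts), SlogP
(unitless), TPSA (Å²), Rings, nN, nO (counts). Kinase-likeness assumes each
descriptor of the kinase-actives training population is approximately
normal, so a compound is scored by a product-free sum of Gaussian kernels:

KLS = Σᵢ exp(−(Xᵢ − μᵢ)²/σᵢ²), with the i-th term set to exactly 0 whenever
Xᵢ falls outside the training population's [P10, P90] window (inclusive at
both ends). The denominator is σ² — not the 2σ² of a normal density — which
halves the length scale of the kernel; the formula is implemented as
defined, not as a probability model. KLS ∈ [0, 9]; it is maximized (exactly
9) at the training mean vector and is non-increasing in |Xᵢ − μᵢ| within
each clamp window.

The library-level score KLSC is the mean absolute difference between two
libraries' 9×9 Pearson descriptor-correlation matrices over the 36 unordered
descriptor pairs. It is 1/36 × the L1 distance on the strict upper triangle,
hence a metric bounded by 2; 0 means identical correlation structure.

## Reference parameters

The built-in profile (`data/kbd_table1.json`) carries the published summary
statistics of 22,615 kinase actives (Kᵢ/IC₅₀ < 10 μM): e.g. Wt 411 ± 96 Da,
TPSA 89 ± 33 Å², SlogP 3.4 ± 1.8, nN 4.3 ± 1.8. The source table prints only
means/SDs, so the P10/P90 clamps default to the normal quantiles
μ ± 1.28155σ (consistent with the approximate normality of the training
distributions), floored at 0 for count descriptors; exact empirical
percentiles override the defaults when present in a profile JSON. Fitted
profiles use the sample (n−1) standard deviation and linear-interpolation
empirical percentiles. The built-in 9×9 correlation matrix
(`data/kbd_table3.csv`) is the published kinase-actives matrix,
symmetrized with a unit diagonal.

## Descriptor definitions

RDKit supplies the primitives: average-isotope MolWt (implicit H included),
Wildman–Crippen SlogP, Ertl TPSA *with* S/P contributions (so TPSA = 0 iff
no N/O/S/P polar contribution), and SSSR ring count. Two descriptors are
defined here:

- **RB** — a bond is rotatable iff it (a) has bond order 1, (b) is not in a
  ring, and (c) each endpoint has ≥ 2 heavy neighbours. This is implemented
  directly rather than via RDKit's SMARTS count, which additionally
  discounts amide and t-butyl-type bonds; the two agree on molecules without
  those motifs (cross-checked in the tests).
- **HBA/HBD** — the training software's definitions are not published.
  HBD = N/O atoms bearing ≥ 1 hydrogen (Lipinski-style). HBA = N/O atoms
  excluding pyrrole-type N–H and amide/sulfonamide N (poor acceptors);
  a `strict=False` flag falls back to counting every N and O. The scoring
  function only requires the same definitions at fit time and score time,
  and the package enforces that by using a single implementation for both.

## Preprocessing

Filtering flags records instead of deleting them, so record count is
conserved and the pipeline is idempotent. Steps, in order: desalt to the
largest fragment by heavy-atom count (ties: molecular weight, then canonical
SMILES); flag structures whose surviving fragment contains an element
outside {H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I} as metal; neutralize
simple charged groups (carboxylates, protonated amines — RDKit's Uncharger;
quaternary ammonium is left charged; no pKa model is applied); flag
molecular weight outside the inclusive [100, 700] Da window. Because the
metal check follows desalting, metal *counterions* are stripped rather than
fatal; only metals in the main fragment exclude a compound. Descriptor
counts (nN, nO, HBD, HBA) are robust to the simple-neutralization
approximation, which is why no full protonation-state enumeration is
attempted (a documented non-goal, as are tautomers and 3D descriptors).

## Seeded-ROC protocol

`seeding_experiment(library, actives, fraction=0.01, n_repeats=10, rng_seed)`
samples ⌈fraction·|actives|⌉ actives without replacement per repeat, labels
them positive against the entire library (negative — undiscovered actives in
the library are deliberately not modelled), ranks the union by KLS and
computes AUC as the Mann–Whitney statistic P(s⁺ > s⁻) + ½P(tie)
(scikit-learn's rank implementation; a brute-force pair-counting oracle
backs it in the tests). The rank form makes the result independent of ROC
axis conventions and of tie ordering. Per-repeat RNG streams are spawned
from the master seed, so a result is bit-reproducible and repeats are
mutually independent. Companion statistics: pooled-variance two-sided
two-sample t-tests per descriptor column and on per-repeat AUC lists, and
the two-sample Kolmogorov–Smirnov statistic (asymptotic p) on KLS
distributions.

## Focused libraries and diversity

`pool_and_dedupe` keys structure identity on canonical SMILES (InChIKey
optional), keeps the first occurrence, and drops anything matching the
supplied known-actives set; counts of both removals are recorded.
`build_focused_library` takes the top-N (default 10,000) by KLS with stable
input order breaking ties — determinism over arbitrary choice.
`average_pairwise_distance` is the mean of 1 − Tanimoto over all unordered
pairs of Morgan fingerprints, radius 3 (ECFP_6-equivalent), folded to 2048
bits (the de facto standard length). The docking validation used in the
original study is proprietary and out of scope; its testable mechanism — a
focused set's mean KLS strictly exceeds a random subset's on any
non-constant pool — is asserted instead.

## Synthetic descriptor tables

`generate_descriptor_table` draws n rows from per-descriptor normal
marginals, by default the published means/SDs of one of the five studied
libraries (`TABLE1_MARGINALS`: KBD, NCI, NPD, MLSMR, WDI, with their real
sizes as default n). An optional target correlation matrix couples the
columns via Cholesky factorization; because a matrix assembled from
2-decimal printed entries need not be PSD, negative eigenvalues are clipped
at 0 and the result rescaled to unit diagonal before factorization. After
sampling, count descriptors are rounded to non-negative integers and Wt is
clipped to the [100, 700] Da preprocessing window. Rounding and clipping
perturb moments and correlations slightly (≲ 0.05 on correlation entries at
n = 20,000, verified in the tests), which the test tolerances account for.

What the generator does *not* emulate: real descriptor skewness and outliers
(real libraries report hundreds to thousands of outliers per descriptor),
integer-valued joint constraints (e.g. HBD ≤ nN + nO can be violated by
independent rounding), and any structure–descriptor consistency (rows are
vectors, not molecules). Passing tests therefore demonstrate correctness of
the scoring/evaluation machinery under the published summary statistics,
not performance on real chemical databases.

## Problem sizes and numerical choices

The self-seeding and cross-library ROC checks use 20,000-row synthetic
libraries and a 2,262-row actives table (1% seeding → 23 spikes per repeat,
10 repeats), matching the protocol's published operating point at a size
where the AUC standard error is a few hundredths. Correlation-recovery
checks use n = 50,000. Degenerate inputs fail loudly: σ = 0 is rejected at
profile construction (so scoring never divides by zero), constant columns
raise in correlation and t-test paths, single-class labels make AUC an
error rather than a NaN. Equality comparisons on floating summaries use
explicit tolerances; score clamps are inclusive at both window ends.

## Known limitations

- The reference profile's clamps are normal-quantile approximations, not
  the training population's exact empirical percentiles; supplying the
  latter via profile JSON changes scores for compounds near window edges.
- HBA/HBD definitions are a reasoned reconstruction (see above); absolute
  KLS values are therefore comparable within this package, not across
  toolkits.
- KLSC compares correlation structure only; two libraries with identical
  correlations but different means are indistinguishable to it (use KLS
  distributions or the t-tests for location differences).
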