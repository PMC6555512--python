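# Methods

## The matrix-of-sequence descriptor

A protein sequence over the 20 standard residues is first reduced to the
seven dipole/side-chain-volume classes ({A,G,V}, {I,L,F,P}, {Y,M,T,S},
{H,N,Q,W}, {R,K}, {D,E}, {C}). For a group sequence s₁…s_L the sequence
matrix is the exact ordered pair count

    m_ij = |{(p, q) : 1 ≤ p ≤ q ≤ L, s_p = i, s_q = j}|,

i.e. every position pair, at every separation, contributes — unlike k-mer
descriptors the whole sequence order enters. It is computed by one
right-to-left streaming pass: walk p = L…1, increment the suffix class-count
vector (VOS) at class s_p, add the whole vector to row s_p. Cost O(L·7),
integer arithmetic throughout (int64; the total L(L+1)/2 overflows 32-bit
for L ≳ 65,000). An O(L²) pair-enumeration oracle (`compute_mos_bruteforce`)
exists purely for cross-checking and is tested elementwise-equal on random
sequences of lengths 1–300.

Three conservation identities follow from the definition and are asserted on
every matrix the tests compute: Σm_ij = L(L+1)/2, m_ii = Cᵢ(Cᵢ+1)/2, and
m_ij + m_ji = CᵢCⱼ for i≠j. Dividing by the forced total L(L+1)/2 yields a
probability-like matrix p summing to 1 (tolerance 1e−12 in tests).

**Feature vector.** The 28 cells on and above the diagonal are flattened
row-major ([1,1], [1,2], …, [1,7], [2,2], …, [7,7]); the flattening order is
arbitrary for learning but frozen for reproducibility. A 29th element, the
sequence tag 1/L, separates equal-composition proteins of different lengths.
The descriptor is deliberately not injective: distinct sequences of equal
length and composition can share a matrix (the tests find such a collision
by exhaustive search over short 2-class sequences). An optional dataset
filter (`collision_filter`, off by default) removes pairs whose proteins
have equal length and identical group counts; it is off by default because
the standard pipeline does not require it, and it is exposed for users who
want to exclude indistinguishable pairs.

## Comparison encoders

Only named dimensionalities pin these down (pair vectors 686 / 420 / 1260),
so the standard reference formulations are used:

* **CT (343/protein):** counts of all 7³ group triads over the L−2 sliding
  windows, scaled per protein as d = (f − min f)/max f. Window count L−2 is
  asserted; needs L ≥ 3.
* **AC (210/protein):** seven physicochemical scales (hydrophobicity,
  hydrophilicity, side-chain volume, polarity, polarizability, solvent-
  accessible surface area, net charge index), each z-standardized over the
  20 residues, then the mean-centered auto-covariance at lags 1..30 with
  denominator L−lag; ordered scale-major. Needs L > 30. A constant sequence
  gives identically zero features (zero variance).
* **LD (630/protein):** ten overlapping regions — four quarters, two halves,
  central 50%, first 75%, last 75%, central 75% — with floor rounding on
  0-based half-open slices; per region 7 composition + 21 unordered-pair
  transition (normalized by region length − 1) + 35 distribution features
  (relative positions of the first, 25%, 50%, 75% and last occurrence of
  each group, occurrence rank by ceil, absent group → zeros). Needs L ≥ 10.

A pair vector is always concat(vec_a, vec_b) in the order the pair file
lists the proteins; no swap augmentation is applied.

## Dataset assembly

Pair lists are cleaned in a fixed cascade, each pair charged to the first
rule it fails: missing sequence; self-interaction; duplicate (unordered by
default — (a,b) ≡ (b,a); an ordered mode exists); unusual residue
(B/J/O/U/X/Z or any non-standard character, including `*` and `-`); length
< 50 (parameter). Removals are counted in an exclusion report, never raised;
filtering is order-stable and idempotent. Residue checks precede the length
check, so a sequence failing both is charged to the residue rule.
Stratified train/holdout splitting takes exact per-class training counts and
holds out the remainder; it is deterministic per seed, disjoint and
exhaustive.

## Classifier

The reference classifier is a fully connected network: `depth` hidden ReLU
layers of `width` units and a logistic output, minimizing mean binary
cross-entropy with Adam in minibatches. The selected configuration is
learning rate 0.01, width 512, depth 3, batch 128, dropout 0; a preset with
(lr 0.001, width 256, depth 3) is provided for the CT/AC/LD comparison
models. The backend is scikit-learn's `MLPClassifier`; consequences:

* Training length is configured in minibatch **steps** and converted to
  ceil(n_steps / steps_per_epoch) full passes, so the realized step count is
  rounded up to a whole epoch.
* Adam's β₁/β₂/ε and the fan-scaled initialization are the backend's
  conventional defaults, fixed by the seed; runs are deterministic per seed.
* Dropout other than 0 is not supported and raises; the selected
  configuration uses dropout 0, so the study setting is fully covered.
* L2 penalty is disabled (alpha 0) to keep the objective the plain mean
  cross-entropy.

Default `n_steps` is 2,000: at the benchmark sizes used here (thousands of
58-dim pairs) the loss plateaus well within that budget, and it keeps a
full train/evaluate cycle in the tens of seconds on one CPU core. Decision
threshold for accuracy/recall is 0.5. Cross-entropy clips probabilities to
[1e−12, 1−1e−12] to stay finite. AUC is the trapezoidal ROC area (rank
statistic with ties counted ½); on single-class label vectors it is NaN
with a warning while the other metrics are still returned. Repeated
hold-out validation derives per-repeat seeds from a base seed and reports
mean ± sample standard deviation (std 0 for a single repeat, by
convention). Decision-tree, k-neighbors and random-forest classifiers are
exposed through the same surface at library defaults (random forest: 200
trees) as a configuration-level swap, not bespoke implementations.

## Synthetic benchmark

The generator emulates the *shape* of a curated interaction benchmark
(FASTA proteome + positive/negative two-column pair lists) with a signal
planted where every encoder in the package can see it: 7-group composition.

Per seed, `n_archetypes` (default 4) latent centers over the seven group
frequencies are drawn from Dirichlet(2·1). Protein i belongs to archetype
i mod K (balanced); its group-frequency target is

    t = (1 − effect) · baseline + effect · center_k,

with the baseline the neutral frequency of each group under uniform residue
usage (group size / 20). The protein's own distribution is a
Dirichlet(60·t) draw (concentration 60 ≈ the sampling noise of a ~100-residue
composition estimate, giving realistic within-class spread), residues are
i.i.d. from it, uniform within each group, and lengths are uniform on
50–200 so everything passes the dataset filters. Positives join two
proteins of the same archetype, negatives join different archetypes; no
self pairs, no duplicates, exact class counts. All randomness flows from
one integer seed through a `SeedSequence` spawning scheme; outputs are
byte-reproducible.

At effect = 0 every protein is a baseline draw, so the labels carry no
recoverable signal and holdout AUC sits at chance; AUC rises monotonically
with effect (tested at 0 / 0.4 / 0.8 over three seeds). At effect 0.8 with
2,000+2,000 pairs the default network reaches holdout AUC ≈ 0.93
(criterion: ≥ 0.90). What passing these tests shows is that the pipeline
recovers a composition-level interaction signal end to end; it does **not**
show performance on real proteomes, where interaction determinants are
interface- and domain-level, homology induces redundancy between train and
test pairs, and negatives are not verified non-interactions.

## Problem sizes

The bundled benchmarks are desk-scale by design: 600 proteins /
2,000+2,000 pairs for the planted-signal check (train 1,500+1,500, holdout
1,000), 300–400 proteins and a 128-unit network for the null runs, and
random-forest probes for the monotonicity sweep. Real benchmark-scale runs
(tens of thousands of pairs, 10⁴–10⁵ steps) use the same code paths through
the CLI; only the configuration differs.

## Known limitations

* MOS discards within-composition order information at equal pair counts
  (non-injectivity above); the 1/L tag separates lengths but not
  permutation-level structure.
* The AC property table is a packaged constant; alternative scale choices
  change the features but not the dimensionality contract.
* `read_pairs` header detection is vocabulary-based (tokens like
  `proteinA`); an exotic header that looks like data will be read as a pair
  and subsequently dropped as a missing-sequence record.
* The MLP backend trains in whole epochs, so very small `n_steps` values
  are rounded up.
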