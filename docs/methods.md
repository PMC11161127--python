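# Methods

## Model

A landscape is defined over `n` sequence positions with `s_k >= 2`
states (alleles) at position `k`; state 0 is the wild-type allele.
Genotypes are ordered by their mixed-radix integer representation with
position 1 the most significant digit, so the wild-type genotype has
rank 1 and ranks are 1-based throughout the API and all file outputs
(which always carry both the rank and the explicit state vector).
Homogeneous landscapes are simply the special case of equal
`state_counts`; there is no separate code path.

Background-averaged epistatic coefficients are `eps = V @ H @ y`:

- `H` is built recursively over positions: adding a (most significant)
  position with `s` states maps `H` to an `s x s` block matrix with
  the first block-row all `+H`, `H` in the first block-column and `-H`
  on the remaining block diagonal, zeros elsewhere. Equivalently `H`
  is the Kronecker product of single-position matrices (first row and
  column ones, `-1` diagonal). For `s_k = 2` everywhere this is the
  canonical Walsh-Hadamard matrix; the zero entries that appear for
  more states exclude phenotypes that are neither relevant
  intermediates nor alternative backgrounds for a coefficient.
- `V` is diagonal with `(V)_ii = (-1)^(n-W) * prod_k (1/s_k)^(w_k)`
  where `w_k` indicates wild-type at position `k` of the i-th state
  vector and `W = sum w_k`: it fixes signs and divides by the number
  of backgrounds averaged over.
- `A = H^{-1}` satisfies its own block recursion (prefactor `1/s`,
  `(1-s)A` on the diagonal below the first block-row) and the element
  closed form `(A)_ij = prod_k (1-s_k)^(e_k) / prod s_k` with
  `e_k = 1` iff both vectors carry the same mutated allele at `k`.

Element formulas exist for every entry of all four matrices, so
sub-matrices (restricted epistatic order, missing genotypes) are built
directly; `feature_matrix` assembles rows of `A @ V^{-1}` in chunks
(default 1,024 rows) so a design matrix for an arbitrarily large
landscape never requires the dense transforms.

### Numerical choices

- Dense builders work in exact integer arithmetic (`H` is integral;
  `A` is an integer numerator over `prod s_k`; `V` diagonals are exact
  rationals) and convert to floats only at the matrix boundary.
- Dense construction refuses spaces above a configurable cap of 4,096
  genotypes and points to the element/chunked APIs.
- Identity and equivalence checks use an absolute tolerance of 1e-9
  per entry.
- The forward and inverse transforms of complete landscapes are
  applied axis-by-axis on the phenotype tensor (one small matrix per
  position), costing O(N * sum s_k) rather than O(N^2); the same
  factorization applied to squared weights gives error propagation.

## Decomposition, error propagation, imputation

`decompose` requires a complete landscape (every genotype measured or
imputed). Measurement errors, when supplied, are treated as
independent per genotype and propagated to first order:
`sigma_eps_i = sqrt( sum_j ((V H)_ij sigma_y_j)^2 )`. On the packaged
worked example this reproduces every printed propagated error at two
decimals. Display rounding is round-half-away-from-zero at 2 dp;
internal computation and machine files are full precision (17
significant digits, round-trip parsing).

`impute_missing` replaces each unmeasured phenotype with the mean
observed phenotype at the same mutation order (number of mutated
positions), the standard order-wise mean imputation for this kind of
data; an order with no observations at all is an error. Imputed ranks
are flagged and carry no measurement error.

Phenotype files are consumed as-is: whether scores are raw or already
wild-type-relative is the caller's convention (the worked example ships
wild-type-relative effects). The transform itself is affine-equivariant
— shifting y only shifts the zeroth-order term.

## Simulation

The generator emulates a combinatorially complete DMS experiment on a
DNA 6-mer (4^6 = 4,096 genotypes) with sparse, low-order architecture:

| parameter | default | meaning |
| --- | --- | --- |
| `space` | (4,4,4,4,4,4) | six positions, four alleles |
| `first_order_dist` | N(-1, 2^2) | single-substitution effects, biased detrimental |
| `interacting_pairs` | [1,2], [3,5], [5,6] | positions with pairwise terms |
| `pairwise_dist` | N(0, 1) | interaction terms at those pairs (all (s-1)^2 = 9 allele combinations per pair) |
| `noise_sd` | 2 (1 and 3 = low/high noise variants) | additive Gaussian measurement noise |

All other coefficients, the zeroth included, are zero. Phenotypes are
`A @ V^{-1} @ truth` plus one noise draw per genotype (a single
replicate); the landscape's error column records the known `noise_sd`,
which downstream defines the technical variance. Draw order is fixed
(first-order by rank, pairwise by rank, noise by rank) from one seeded
generator, so outputs are bit-reproducible.

The generator does *not* emulate global epistasis or nonlinear
measurement transforms, sequencing-count noise, genotype-dependent
error magnitudes, or missing-not-at-random patterns; passing tests
therefore demonstrate correct inference under additive Gaussian noise
with uniformly random missingness, not robustness to those real-data
features.

## Sparse inference

Lasso regression (scikit-learn `LassoCV`) of phenotype on sequence
features, with the L1 penalty `lambda` selected by repeated 10-fold
cross-validation over 50 log-spaced points in [0.005, 0.25] (the
bounds are the study conditions; the grid density is our choice, dense
enough for stable selection; `cv_repeats` defaults to 3). The
intercept is unpenalized and reported as the zeroth-order coefficient;
the zeroth column is excluded from the design. Features are used on
their natural scale by default — the embedding's column scales are
meaningful ((s-1)/s vs -1/s entries shrink with order) — with
standardization available as a config switch; in our measurements
standardizing raises the selected penalty and admits many third-order
false positives on the default simulation, so the natural scale is
also the better-behaved default.

`repeated_fits` trains `n_models` models (study condition: 100; the
test suite and acceptance script use 10-20) on random
`train_fraction` subsets of the measured variants, each model's
held-out measured variants forming its test set; per-model seeds are
spawned from the master seed so any single model is reproducible in
isolation. CV folds are plain random (not stratified by mutation
order). Per-coefficient medians and interquartile ranges are taken
across models and a coefficient is called non-zero when its IQR
excludes zero.

Variance explained is reported both raw (test-set R^2) and as a
fraction of the maximum explainable variance, `1 - technical_variance
/ var(y)`; for simulated data the technical variance is the known
`noise_sd^2`. The known-noise convention matters: with noise sd 2 the
raw R^2 ceiling is `signal/(signal+4)` (typically 0.73-0.85 across
truth draws), so only the normalized quantity has a draw-independent
interpretation.

One-hot ("background-relative"/biochemical) features are provided for
comparison: a column is 1 iff the genotype carries exactly the
coefficient's mutated alleles at its mutated positions. At full order
both embeddings are bases of the same function space (checked
computationally).

## Contact enrichment

For each fitted model, every coefficient of order >= 2 contributes its
C(k,2) position pairs as *occurrences*; the occurrence multiset is
compared against the multiset of pairs in all possible coefficients up
to the model's order, split by membership in the supplied physical
contact set (2x2 table, cross-product odds ratio, two-sided Fisher
exact p-value; Haldane +0.5 correction to the odds ratio only, flagged,
when a cell is zero). Counting occurrences rather than unique pairs is
deliberate: retained interaction terms concentrate their multiplicity
on genuinely interacting pairs, whereas the unique-pair projection of
any moderately dense model covers nearly the whole background and
cannot discriminate. The deduplicated pair set remains available
(`position_pairs_of`) for sparse coefficient sets such as ground-truth
supports.

`random_model_null` draws order-matched random coefficient sets for
null calibration. Being a discrete exact test, the Fisher p-value is
conservative under this null (super-uniform: P(p <= a) <= a up to
discreteness); tests assert that one-sided calibration and that null
odds ratios center on 1, rather than exact uniformity.

## Problem sizes and known limitations

The test suite and acceptance script run the full 4,096-genotype
simulation but scale repeated fits to 10-20 models (medians are stable
at this size; per-coefficient IQRs are coarser than with 100 models).
Coefficient recovery correlation at 64% training varies over truth
draws (r 0.95-0.99) because L1 shrinkage acts more strongly on
higher-order feature columns, whose scale is smaller; correlated
same-position column groups can shrink equal-signed coefficients by up
to (group size) x lambda / Var(column). No conditioning guarantees are
claimed for the extended (non-orthogonal) column sets. Alleles are
opaque integer states: there is no codon/IUPAC semantics, no FASTQ or
upstream DMS processing, and physical contact lists are plain inputs,
not derived from structures.
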