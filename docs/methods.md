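# Methods

## Model

`idpgen` implements a generative autoencoder for IDP conformational
ensembles. The object being modelled is the reduced heavy-atom
representation of a disordered chain: all backbone heavy atoms (N, CA, C,
O, plus ACE/NME cap heavy atoms and terminal OXT) and side-chain atoms
named CB, CG, CD, OE1 or NE2. This selection keeps every heavy atom of a
glutamine side chain and truncates longer ones; a capped 15-residue
glutamine-like chain has exactly 140 such atoms, a 40-residue chain 230.

Preprocessing maps conformations to the unit cube: every frame is
superposed on a reference frame (the first training frame; the choice of
reference is immaterial to the evaluation metrics, which re-superpose every
pair), a single scalar shift makes all coordinates non-negative, and a
single scalar scale (the maximum shifted training coordinate) maps them
into [0, 1]. Shift and scale are fit on training data only and reused
verbatim for test and generated data; test values may fall outside [0, 1],
which is allowed. Inversion restores real coordinates exactly (to 1e-9 Å).

The network is a mirrored dense autoencoder, 3N → 300 → 50 → n → 50 → 300 →
3N, rectified-linear everywhere except the sigmoid output, with
n = round(0.75 · N_res) (half-values up; N_res counts cap groups). The loss
is the per-coordinate binary cross-entropy, optimised by Adam (step 1e-3,
moment decays 0.9/0.999) for 100 epochs at batch size 40; mean squared
error is available and performs equivalently on the fixtures (the test
suite asserts agreement of the resulting coverage within 15%). Everything
is implemented in NumPy with explicit backpropagation; given a seed,
training is reproducible to the bit.

The training latent vectors are modelled by a multivariate normal using
population (1/K) moments. Eq.-level choices:

- The latent density is the standard multivariate normal
  ((2π)ⁿ det σ̃)^(−1/2) exp(−½ (z−μ)ᵀ σ̃⁻¹ (z−μ)); on request it is
  evaluated on a sub-block of dimensions, the usual treatment when the full
  covariance is singular.
- Because the latent layer is rectified-linear, some dimensions are dead
  (identically zero over the data) and the covariance is singular. Sampling
  uses the eigendecomposition with eigenvalues clipped at zero, so dead
  dimensions are sampled exactly at their zero mean — matching what the
  decoder saw in training.
- Distribution comparisons use 2-D histograms of latent-dimension pairs on
  a shared grid (default 50×50 over the union of ranges, padded 1%) and the
  discrete KL divergence Σ p ln(p/q) with zero-count bins contributing
  nothing. Under this zero rule, KL values are grid-dependent and should be
  reported with the bin count; disjoint supports give 0, and KL(p, p) = 0
  exactly.
- An optional k-component Gaussian mixture (EM, k-means initialisation,
  seeded, 200 iterations, 1e-6 tolerance, via scikit-learn) reduces to the
  single-Gaussian moment fit at k = 1.

## Evaluation

All RMSDs re-superpose the pair by the Kabsch rotation (SVD with
reflection guard); the matrix variant used for large evaluations forms the
3×3 cross-covariances of whole blocks of pairs in one matrix product and
takes their singular values from batched symmetric eigenproblems — it is
algebraically identical to per-pair superposition and agrees with it to
1e-9 Å (near-zero RMSDs are limited to ~1e-7 Å by cancellation in the
squared form). Coverage metrics:

- mean reconstruction RMSD over a diluted test set;
- best-match RMSD (per test conformation, the minimum over the reference
  set; ties broken by lowest index; exhaustive, no nearest-neighbour
  shortcuts);
- pairwise diversity (mean over all pairs) and the within-set best-match
  benchmark (mean nearest-neighbour distance, always ≤ diversity).

Decoded conformations are raw network output and violate ideal bond
lengths/angles; `geometry_check` reports deviations beyond 15% of the
ideal length or 15° from the ideal angle against standard residue
templates (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, …). The package reports
these rather than refining them; refinement belongs to standard force-field
minimisation tools. MAPE and RMSE are provided as generic series metrics.

## Synthetic trajectories

Real inputs are MD trajectories; none are bundled, so the fixture module
generates download-free stand-ins with the statistical features the method
relies on:

- basin templates built to exactly ideal geometry by natural-extension
  placement from per-residue torsions drawn from a small rotamer-like
  library (clashes under 1.7 Å between non-bonded atoms are rejected and
  redrawn — torsions do not affect bonds or angles, so templates always
  pass the geometry check);
- a Markov chain over basins (default 3 basins, switch probability 0.02
  per frame) plus AR(1) Cartesian noise (sd 1.0 Å, lag correlation 0.9)
  and a small random rigid motion per frame, giving trajectories whose
  consecutive frames are far more similar than random pairs — the property
  that makes an initial-portion training split meaningful;
- replicate runs drawing overlapping basin subsets (fraction `run_overlap`
  shared), emulating independent MD runs that mine partially overlapping
  regions of conformational space.

The standard fixture is a capped 15-residue chain (140 heavy atoms,
N_res = 17 with caps, latent dimension 13), 5,000 frames, 10% training
split, evaluation on a 10-fold diluted test set, generated sets sized as
multiples of the test size. These sizes keep a full train-generate-evaluate
cycle under half a minute on one CPU while preserving the regime of
interest (training set much smaller than the conformational repertoire).

What the fixtures do *not* emulate: force-field energetics, solvent,
secondary-structure statistics, and the slow conformational drift of real
MD. One consequence: fixture training and test portions are statistically
identical (stationary Markov chain), so the training-vs-test latent
divergence observed for real single-run MD data — and the ordering of
KL(test|Gaussian) below KL(train|test) that follows from it — is not
reproduced here. Passing tests therefore certify the machinery (exact
bookkeeping, oracle-level numerics, and the qualitative coverage effects),
not force-field-level realism.

## Numerical choices and edge cases

- Sigmoid outputs are clamped at 1e-7 before logarithms in the loss.
- The final partial batch is included; training order is reshuffled each
  epoch from the seeded generator. Weights use Glorot-uniform
  initialisation from the same generator.
- Non-finite loss aborts training with a diagnostic rather than continuing.
- Collinear (rank ≤ 1) coordinate sets make the optimal rotation
  ill-determined; the superposition falls back to the identity.
- Dilution keeps frames 0, k, 2k, …; dilutions compose
  (dilute(dilute(E,a),b) = dilute(E,ab)).
- Active latent dimensions are those with max |z| > 1e-3 (scaled latent
  units).
- Generated sets drawn with one seed are prefix-nested across sizes, so
  enlarging a generated set can only improve best-match RMSD; nested-size
  comparisons in the tests exploit this exactly.
- Covariance normalisation is 1/K (population); at the training sizes used
  the difference from 1/(K−1) is negligible, and the moment definitions
  are taken as plain averages.

## Known limitations

- Dense 3N-coordinate input ties a model to one atom table; there is no
  transfer across chain lengths.
- Exhaustive best-match evaluation is O(K_test × K_ref); the
  block-batched implementation keeps 10⁷ pairs in the tens of seconds on
  one CPU, but very large evaluations should dilute first.
- Generated conformations need external refinement before force-field- or
  experiment-facing use (SAXS/chemical-shift back-calculation is out of
  scope here).
- The single-Gaussian latent model underfits strongly multimodal latent
  distributions (irregular single-run landscapes); combining replicate
  runs — which the pipeline supports end to end — is the remedy the
  method itself proposes, and the optional mixture model is provided for
  experimentation.
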