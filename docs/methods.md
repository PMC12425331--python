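# Methods

This note records the models implemented in `commutime`, the conventions
chosen where published definitions are ambiguous, and what the synthetic
study conditions do and do not establish about real neuroimaging data.

## Markov model and closed-form metrics

Signal propagation is modelled as a first-order random walk on the weighted
structural graph: from region *i* the walker steps to *k* with probability
`M_ik = A_ik / D_ii`. All metrics derive from one set of operators per
connectome (degree `D`, Laplacian `Γ = D − A`, pseudoinverse `Γ⁺`,
transition `M`), built by `build_operators` for one of three adjacency
readings: raw streamline counts (`density`, the default), the binary
support, or tract lengths (with an inverse-length option, since longer
tracts arguably couple more weakly — the literature does not fix this
transform).

- **Hitting time** `H_ij` and **commute time** `C_ij = H_ij + H_ji` use the
  Laplacian-pseudoinverse closed forms quoted in the README. The
  pseudoinverse is computed by full symmetric eigendecomposition with
  eigenvalues below `1e-10 ×` the largest treated as the (single) null mode
  of a connected graph. This makes the null space explicit instead of
  delegating it to a generic SVD cutoff, and the builder refuses
  disconnected graphs outright — commute time is undefined across
  components, and silently computing per-component values would be a trap.
- **Resistance distance** `Ω_ij = Γ⁺_ii + Γ⁺_jj − 2Γ⁺_ij` satisfies
  `C = Ω · Σ_k D_kk` with the same pseudoinverse; the identity is asserted in
  the tests as an algebraic cross-check, along with `C = H + Hᵀ`, Rayleigh
  monotonicity, the resistance triangle inequality, and invariance of all
  walk metrics under uniform weight rescaling.
- **MFPT commute time** uses the chain's fundamental matrix
  `Z = (I − M + 1πᵀ)⁻¹` with stationary distribution `π_i = D_ii / Σ D`,
  `m_ij = (Z_jj − Z_ij)/π_j`; the commute variant is `m_ij + m_ji`. For a
  reversible chain this coincides with the hitting-time closed form up to
  numerical error, which is why its rank correlation with commute time is
  ~1.0.
- **Communicability** is the walk sum `Σ_n (A')ⁿ/n!` over the
  degree-normalized adjacency `A'_ij = A_ij/√(D_ii D_jj)`. The printed
  formula in the source literature can be read either as this matrix
  exponential or as an elementwise exponential of `A'`; the factorial
  damping over path lengths only makes sense for the matrix exponential, so
  that is the default, with the elementwise reading available through
  `MetricConfig(communicability_form="elementwise_exp")` for comparison.
- **Search information** measures the bits a random walker needs to follow
  the shortest path: `SI(i,j) = −log2(M_ia · M_ab · … · M_zj)` along the
  shortest path on the tract-length graph (distances `1/A_ij` when no
  lengths exist). It is stored as positive bits; the alternative raw-log
  convention is available in `MetricConfig`. Shortest-path ties are broken
  by always choosing the smallest-index predecessor when backtracking from
  the target, so SI is bit-reproducible across platforms. SI is asymmetric;
  pair-level analyses use the mean of SI(i,j) and SI(j,i).

## Monte-Carlo walker oracle

`walkers` is a deliberately brute-force check on the closed forms: walks are
simulated step by step from `M` (numba-compiled), with one independent
31-bit random stream per (pair, order) derived from the master seed so that
per-pair results do not depend on evaluation order. Each walk is capped at
10⁷ steps; capped walks are excluded and counted, never silently truncated.
Order-2 walkers renormalize the step distribution to exclude the node just
left; order-3 walkers also exclude the node before that. When every
neighbor is excluded (a leaf), backtracking is allowed — the only convention
that keeps the chain well-defined on all connected graphs. The agreement
report compares simulated and analytic commute times pair by pair as
z-scores; estimates with undefined standard error (single walks) are
flagged rather than dropped silently.

## Mean-field Ising simulation

The energy is the ordered-pair sum `E = −λ Σ_ij A_ij s_i s_j` (each
undirected edge counted twice), so flipping spin *i* changes the energy by
`4λ s_i Σ_j A_ij s_j` and the two-spin system has exact equilibrium average
`⟨s₁s₂⟩ = tanh(2λ)` — the oracle the sampler is tested against, together
with a χ² fit of the empirical 4-state distribution (χ² is evaluated on
frames thinned to approximate independence, since the raw trajectory is
strongly autocorrelated and would invalidate the sampling theory).

Conventions that the published description leaves open, and the choices
made:

- **Flip semantics.** "Attempt to flip 15% of the spins per timestep" could
  mean joint acceptance of the whole set or sequential single flips. Joint
  acceptance of ~13 spins at strong coupling has vanishing acceptance
  probability; sequential single-flip Metropolis (accept if ΔE ≤ 0, else
  with probability `exp(−ΔE)`) is implemented and recorded in the config.
- **Adjacency normalization.** Raw tract counts (10²–10⁴) with λ of order
  one would freeze the dynamics instantly, so the adjacency is rescaled
  before simulation; the default divides by the maximum off-diagonal weight
  (`max_one`), with `mean_one` and `none` exposed. Note a structural
  consequence: for any matrix whose largest entry sits on an edge, the
  spectral radius of `A/max(A)` is at least 1, so under this family of
  normalizations the order–disorder transition always occurs at couplings
  below ~0.5 and a working coupling of λ = 6 is deep in the ordered regime.
  The simulated-FC correlations under these defaults are therefore
  substantially weaker and noisier per replicate than the cohort-scale
  values reported on restricted empirical data, whose effective coupling
  scale cannot be reconstructed from the published description. The λ
  *contrast* (stronger coupling → stronger structure–function correlation;
  no correlation at λ = 0; null destruction under structure shuffling) is
  robust and is what the acceptance checks certify.
- **Burn-in.** The first 20% of frames are discarded before FC by default
  (configurable, recorded); a flag restores literal whole-series
  correlation.
- **HRF.** The hemodynamic kernel is the canonical double-gamma: a gamma
  density with mode at 6 time-units minus 1/6 of a gamma density with mode
  at 16, unit dispersions, 32-unit support, normalized to unit sum, applied
  causally with same-length output. One Ising timestep maps to one
  time-unit (no TR calibration is attempted); all kernel parameters are
  serialized with every output.
- **Undefined FC entries.** Regions whose retained series is constant (deep
  in the ordered phase) have undefined correlations; they are flagged, and
  the comparison stage excludes such regions the way missing-data regions
  are excluded from empirical FC.

## Synthetic connectomes

The generator emulates the statistical shape of dMRI tract-count matrices
at the 84-region scale: two equal hemispheric blocks, ~35% intra- vs ~8%
inter-hemisphere pair density, integer log-normal weights (median ≈ 20,
σ_log = 2, so counts span ~1–10⁴ as deterministic tractography yields) with
inter-hemisphere magnitudes shifted one log-unit down, homotopic pairs
defined as (i, i + N/2), tract lengths ≈ 40 ± 10 mm intra-hemisphere and
~1.8× longer between hemispheres on the same support, and deterministic
bridging to guarantee connectedness. It makes no attempt to match any
specific cohort's degree or weight distributions quantitatively; analyses
that depend on those fine properties (e.g. per-subject correlation
magnitudes) cannot be read off the synthetic results, whereas ordering and
null contrasts can.

The shuffled null permutes the upper-triangle weight multiset (resampling
deterministically until connected); a degree sequence is not preserved —
the simplest reading of "shuffled structural connectivity". Homotopic
addition adds k tracts to every (i, i+N/2) pair; the random control adds k
to the same *number* of uniformly chosen non-homotopic pairs, so total
added weight is budget-matched by construction. The homotopic-vs-random
experiment uses a deterministic, homotopically structured target FC (a
monotone decreasing function of the commute time of the
homotopically-enhanced graph), which isolates the structural logic of the
comparison from Ising sampling noise.

## Analysis conventions

- Pair vectors are upper-triangle, row-major, never including the diagonal;
  hemisphere masks restrict to intra-left/intra-right pairs.
- Spearman ρ uses average ranks for ties and the large-n two-sided
  approximation for p (at n = 3486 pairs the difference from exact
  permutation is negligible). Constant inputs flag ρ as undefined rather
  than raising.
- Principal-mode truncation takes eigenvectors of the symmetric matrix
  itself (no row-centering — the FC matrix is treated algebraically), keeps
  the k largest algebraic eigenvalues, and fixes each eigenvector's sign by
  its largest-magnitude component. Default k = 2 for simulated-FC
  comparisons.
- For magnitude-comparable reporting, the additive inverse of commute time,
  MFPT commute, and search information is taken (these anti-correlate with
  FC); the flip is recorded on every report.
- Quartiles in experiment summaries use linear interpolation.

## Problem sizes and limitations

The test suite and acceptance script run entirely on synthetic data at
desk scale: 84 regions for Ising experiments (10–20 replicates), 10–20
regions for walker validation (10⁴ walks per pair), 125k frames for the
two-spin exactness checks. Monte-Carlo thresholds (3σ bands, ±0.02 on the
two-spin average) follow from the standard-error scales at those sizes.
Known limitations: no empirical-data I/O (imaging formats are out of
scope), no Wilson–Cowan or other biophysical simulators (the FC interface
accepts any supplied matrix, which is the intended plug-in path), λ is
always supplied rather than fitted, and the Ising working point under the
default normalization is ordered rather than near-critical (see above), so
absolute correlation magnitudes from the simulation should not be compared
against cohort values.
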