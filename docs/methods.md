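# Methods

This note records the models, estimators, numerical conventions and design
choices behind `narelease`, and what the synthetic-data verification does and
does not demonstrate about real molecular-dynamics (MD) data.

## The analysis model

The pipeline treats an ensemble of equilibrium trajectories as samples of a
reversible Markov process observed through a feature map. The stages and
their assumptions:

**Featurization.** The default feature vector has 12 components chosen for
the sodium-release problem: four distances tracking the tagged ion
(Na2-site ion to the Na1-site ion and to the E428/D421/D79 side-chain
markers), seven intracellular-gate distances (R60–Y335, R60–E446, R60–E428,
R60–D436, Y335–E428, D436–R445, E428–R445) that gate water penetration, and
the ion's water coordination number. Distances are Euclidean in Å; no
periodic-boundary imaging is applied by default (an optional minimum-image
correction would matter only for real MD boxes, not for the synthetic
frames). On synthetic frames each residue is a single marker point, so
"distance to residue" is unambiguous; on real data the adapter should pass
the closest side-chain heavy atom (configurable) for acidic/basic partners.

Water-cavity definitions follow fixed geometric clauses (all cutoffs in Å,
z = membrane normal, positive extracellular): EC vestibule = water oxygen
within 26 of the F326 Cβ marker, not within 5 of any lipid particle, and
z above the marker by no more than 23; the z-clause is deliberately
one-sided — waters far below the marker are excluded only by the sphere
clause, exactly as defined. EC cavity = EC-vestibule waters within 10 of the
ligand (dopamine) center. IC vestibule = within 15 of the ligand center, not
within 5 of lipid, |Δz| to the D436 Cβ marker ≤ 15.5; IC channel = the part
within 12 of any T269 backbone particle, IC cavity the remainder (an exact
partition, asserted at run time). "Lipid" means every particle labeled
lipid, not only headgroups.

The Na⁺ water-coordination cutoff is **3.5 Å** — the conventional first
hydration shell; the source analysis does not state a value, so this default
is prominent in the configuration and overridable everywhere.

**tICA.** Features are mean-centered with the pooled mean (centering is
required for covariance semantics); C is averaged over all frames and
C_TL(τ) over all in-trajectory (t, t+τ) pairs — pairs never span trajectory
boundaries. C_TL is symmetrized as (C_TL + C_TLᵀ)/2 before solving (finite
sampling otherwise yields complex eigenpairs), C is ridge-regularized with
ε = 1e-10·tr(C)/d, eigenvectors are normalized to vᵀCv = 1 and sign-fixed
(largest-magnitude entry positive) for reproducible outputs. Default lag:
16 ns. Component selection is guided by a D'Agostino–Pearson normality
screen: a tIC whose projected distribution is indistinguishable from
Gaussian carries no multi-basin structure worth keeping; the recommended
count is the number of leading non-Gaussian components.

**MSM.** k-means (k-means++ initialization, fixed seed, default k = 100) on
the first two tICs; sliding-window transition counting (strided counting
behind a flag); transpose-average symmetrization C_sym = (C + Cᵀ)/2 —
detailed balance holds by construction and π is proportional to the row
sums; restriction to the largest connected component of the count graph
(required for a unique stationary vector); spectrum via the symmetric
similarity transform, which guarantees real eigenvalues and consistent
left/right eigenvector pairs. Maximum-likelihood reversible estimation,
Bayesian MSMs and hidden Markov models are out of scope. Default production
lag: 48 ns; the Markovianity scan uses a geometric lag ladder with
trajectory-bootstrap error bars (resampling whole trajectories with
replacement, 10 replicates) and reports a flatness diagnostic (max relative
change of the slowest timescale over the upper half of the ladder).
Degenerate eigenvalues are encoded explicitly: λ ≤ 0 → no defined timescale
(NaN); λ ≥ 1 beyond the Perron mode → infinite.

**GMRQ.** Score = Tr[(VᵀSV)⁻¹(VᵀCV)], S = diag(π_test), C = S·T_test. Two
identities anchor correctness and are enforced to 1e-10 in tests: train =
test gives the sum of the top-n eigenvalues, and the score is invariant to
invertible recombination of V's columns. States present in only one of
train/test are handled by restricting both **count** matrices to the common
active set and re-estimating (iterated to a fixed point) — restriction on
counts, not on TPM rows, preserves detailed balance exactly. The scan
reports the mean test score over several random stratified splits (default
5) rather than a single split, which reduces selection noise; single-split
replication is available by setting `gmrq_splits=1`.

**TPT.** Forward committor by the boundary-value linear system; gross flux
f_ij = π_i(1−q_i)T_ij q_j, net flux f⁺ = max(0, f − fᵀ), total flux = net
flow across the source cut; flux conservation at interior nodes is asserted
to 1e-10 on every run. Pathways are extracted by iterative bottleneck
decomposition: find the maximum-bottleneck source→target path, subtract its
bottleneck flux from every edge (zeroing the bottleneck edge), repeat.
Because ties in bottleneck width are generic once fluxes have been
subtracted, the extracted path is made canonical — widest, then shortest,
then lexicographically smallest — so the decomposition is deterministic and
agrees exactly with exhaustive enumeration under the same rule. Full edge
deletion ("remove the path") is available behind a flag. Macrostates use
sign-structure Perron cluster analysis: microstates keyed by the sign vector
of the leading non-Perron right eigenvectors (smallest count giving enough
patterns), surplus patterns merged smallest-population-first into nearest
Hamming neighbours. This deterministic sign-based lumping is a deliberate
divergence from simplex-optimization PCCA+; it matches the kinetic-sign
rationale and needs no optimizer. A macrostate that ends up holding both
source and target microstates (possible with coarse lumpings) is assigned to
the side carrying more stationary weight, with a log message.

**Thermodynamics.** F_b = −ln p_b per tIC-1 bin, min-shifted; profiles are
in kT throughout (temperature enters only as the unit). Empty bins are
reported missing (NaN), never 0 or +∞, to keep error propagation finite.
Default 50 bins. Errors come from a block bootstrap: contiguous blocks with
length drawn uniformly in a configured range (default 180 ± 70 ns, i.e.
110–250 ns; the jitter distribution is a package choice) resampled with
replacement to the original frame count. Blocks must exceed the slowest
relevant correlation time — for multi-well systems that is the *inter-well
hopping time*, not the in-well relaxation; with shorter blocks the
inter-basin offsets are systematically under-dispersed (this is tested).
Basins are local minima with prominence ≥ `min_depth` (default 1 kT),
reported with extents at the flanking barrier tops; the basin count is
non-increasing in `min_depth`. Release events use a sustained-threshold
criterion on the Na2–Na1 distance: > 10 Å for ≥ 10 consecutive frames, the
10 Å figure being the post-release distance-bin boundary and the persistence
guard suppressing barrier-top flicker; the criterion is deliberately not
invariant under frame subsampling coarser than the persistence window
(resampled data should rescale the window).

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical and kinetic structure* of the
study design, not transporter physics:

* **Chains** — a reversible 3-state birth–death chain
  (bound ↔ intermediate ↔ released; self-transition probabilities 0.98 /
  0.90 / 0.98, λ₂ ≈ 0.98, slowest timescale ≈ 49.5 steps) for estimator
  recovery; arbitrary chains accepted.
* **Three-well diffusion** — overdamped Langevin (Euler–Maruyama, fixed
  step, no inertia — the metastable-hopping phenomenology an MSM assumes) on
  U(r) = min_i[E_i + |r−c_i|²/2σ²], centers (−2,0), (0,0), (2,0), offsets
  (0, 2, 0.5) kT with the middle (intermediate) well strictly shallowest in
  population, barrier parameter 3 kT setting σ² = L²/8b, D = 1, dt = 0.01,
  kT = 1. The hard-min form makes minima, basin assignment and Boltzmann
  quadrature exactly computable; the gradient is discontinuous on basin
  ridges, which Euler–Maruyama tolerates. The integrator validates its step
  against both the in-well relaxation (D·dt/kTσ² ≤ 0.5) and the well
  separation, raising an error with a suggested bound otherwise.
* **Coordinate frames** — ~100 labeled pseudo-atoms: gate/site residue
  markers (including E446 and D421 so all 12 features are computable), a
  ligand proxy, Na1/Na2 ions, K⁺ ions, a lipid ring, and ~60 waters split
  into hydration shell, EC vestibule/cavity, baseline IC populations,
  lipid-adjacent probes (exercising the 5 Å exclusion) and a mobile pool
  that migrates intracellularly on release. In a release trajectory the
  tagged ion walks bound → intermediate (near the E428 marker, with a short
  dwell) → released; the Na2–Na1 distance crosses 10 Å and stays above it,
  IC hydration and the ion's coordination number rise, and one K⁺ ion
  reaches the D79 site only after full release. Ensembles default to 50
  trajectories with release in 12, release times uniform over 80–900 ns
  (the observed extremes; the dispersion law is otherwise unconstrained and
  kept as a free parameter), rescaled for shorter trajectories.

Passing tests on these generators demonstrates that every estimator
recovers known ground truth and that all geometric clauses are implemented
exactly as specified. It does **not** demonstrate force-field realism,
convergence properties of real 1 μs trajectories, or that the default
feature set is optimal for any particular transporter — those depend on the
input data, not on this code.

## Problem sizes

Desk-scale defaults keep every check fast while leaving clear statistical
margins: estimator recovery uses 50 × 2·10⁴-step chains (≈ 400 slowest-mode
correlation times); the end-to-end run uses 20 Langevin trajectories ×
2·10⁴ steps subsampled ×10 (40 000 frames, ~60–100 inter-well hops — enough
for basin offsets to ~0.15 kT); the release ensemble uses 50 × 150 frames at
2 ns stride. The full test suite runs in well under a minute; the
acceptance script in seconds.

## Known limitations

* The symmetrized count estimator is biased toward detailed balance even if
  the underlying process is driven; it is the intended estimator here, but
  the maximum-likelihood reversible alternative is not provided.
* Sign-based PCCA can split a metastable set when an eigenvector's sign
  flips inside it at finite sampling; the population-weighted Hamming merge
  mitigates but does not eliminate this.
* The committor solver is dense (`O(k³)`); fine for the ~100-microstate
  regime this pipeline targets.
* Free-energy profiles use raw populations — no reweighting, no 2-D
  surfaces.
* `kplus_site_probability` treats per-frame indicators as independent within
  a bin for its t-tests (as in the emulated analysis); its bootstrap, in
  contrast, resamples whole trajectories.
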