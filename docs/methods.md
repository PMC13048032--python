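# Methods

This note documents the models implemented in `sscpe`, their assumptions,
the numerical choices, and what the synthetic test data do and do not show.

## Elastic networks and the mutation-response model

Two elastic-network variants are built on the native structure. The
Cartesian variant is the standard anisotropic network model on Cα
coordinates: a spring of uniform constant K on every residue pair whose
closest heavy atoms lie within 4.5 Å, acting along the Cα–Cα axis. The
torsional variant (the default everywhere downstream) keeps all heavy atoms
but allows only backbone φ/ψ rotations; springs act along the
closest-heavy-atom axis of each contact, and a restraint
κ_ψ·K·Σ_a(Δθ_a)² with κ_ψ = 0.2 bounds torsional fluctuations. The
torsional Hessian is JᵀHJ with J the analytic rotation Jacobian after
mass-weighted Eckart projection of rigid-body motion; the kinetic metric is
JᵀMJ. A single chain has 3L−6 Cartesian or 2L−2 torsional modes; modes are
returned as Cartesian vectors obeying Σ_i m_i v_α,i v_β,i = δ_αβ.

A mutation (a→b) at site m exerts on each contact partner k a force along
the closest-atom axis with weight
K·R0^g·[W_size(s_b−s_a) + W_stab(U(b,A_k)−U(a,A_k)) + W_dist(d(b,A_k)−d(a,A_k))]/|r_mk|^{1+g},
with g = 2, R0 = 3.25 Å and fitted weights (3.05, 2.39, 15.6) as defaults,
and the reaction −ΣF_k at m, so the total force vanishes. The linear
response Δr = Σ_α v_α F′_α/ω_α² yields the per-mutation RMSD
(√(Σ_i m_i Δr_i²/M), in Å) and the harmonic energy DE = Σ_α(F′_α/ω_α)².
The explicit K prefactor in the force cancels the 1/K of the response, so
the RMSD is exactly independent of K (asserted to 1e-8 in the tests). DE,
being an energy, scales linearly with K; all reported DE values use the
K = 1 convention, and the selection parameter Λ absorbs the scale in every
evolutionary application.

The total mean-square deviation of a real mutant is modeled as three terms,
MSD_mut = Σ(F′/ω²)², MSD_nomut = Σ1/ω² and a cross term
2σ_p√(Σ(F′/ω³)²) with a per-pair sign σ_p = ±1 fitted from the observed
MSD (tie at equality breaks to +1). Observed conformational changes whose
harmonic barrier Σω²c² falls below half the null expectation (amplitudes
c² ∝ 1/ω² rescaled to the observed total) are flagged as likely functional
transitions and excluded from weight fitting; a zero change keeps by
convention. Weight fitting maximizes the Pearson correlation between the
mutation-only predicted RMSD √(WᵀA_pW) (A_p a precomputed 3×3 Gram matrix
per pair) and the observed RMSD, by Nelder–Mead from two fixed starts; the
overall weight scale is not identifiable from a correlation, so unit-norm
weights are returned.

The deformation assigned to the wild-type amino acid is not zero (which
would overfit the crystallized sequence) but the average of the 19 mutant
deformations weighted by exp(Λφ), φ = −deformation, with uniform prior
weights; it therefore depends on Λ and is refreshed during Λ fitting.

## Contact-based folding stability

The native free energy is the sum of contact energies over the
stability-flavor contact map (|i−j| > 2; short-range contacts form in
essentially all compact conformations and cancel from differences). The
unfolded chain contributes G_U = −L·S_U (kT = 1). The misfolded ensemble of
compact decoy conformations is treated with the random energy model:
G_misf = ⟨E⟩ − var(E)/2 − L·S_C above the freezing point, clamped at
⟨E⟩ − √(2·L·S_C·var) when var > 2·L·S_C (continuous at the boundary). The
nonnative free energy combines both channels by a Boltzmann average,
G_nonnat = −log(e^{−G_misf} + e^{−G_U}), computed with log-sum-exp; the
hydrophobic and hydrophilic limits reduce it to G_misf and G_U
respectively. "Neglect misfolding" mode gives ΔG = G_nat + L·S_U exactly.

Decoy moments come in two modes. With an explicit library of equal-length
contact matrices, ⟨E⟩ and var(E) are exact ensemble moments (this is the
mode the Boltzmann-sum oracle tests). In pooled mode the mean contact
probability factorizes as ⟨C_ij⟩ = a(L)·f(|i−j|), with f estimated from the
library, a(L) matching the native mean contact count (linear in L between
library lengths), and the variance assembled from three covariance
summaries — the per-pair Bernoulli variance ⟨C⟩−⟨C⟩², the contact-number
covariance cov(n_i, n_k) and the contact–total covariance cov(C_ij, N_c) —
estimated across decoys within equal-length groups and pooled by sequence
separation. Statistics for a given length are computed once and cached.

Mutational ΔΔG uses cached wild-type contact sums so one mutation updates
only the terms touching the mutated site: the native term is O(n_i), the
misfold mean term O(L), and the variance correction one cached
matrix–vector product (the decoy covariances couple all sites, so a strict
O(n_i) update is impossible without further approximation). The
incremental path agrees with full recomputation to 1e-10 on all fixtures.

S_U = 0.16 and S_C = 0.06 per residue are shipped defaults chosen, together
with the energy scale of the packaged contact table, so that designed
sequences on compact synthetic folds come out at ΔG/L ≈ −0.2 kT per residue
with single-mutation |ΔΔG| of order 1 kT — the regime of real two-state
proteins. No test depends on the specific values, only on limits and oracle
equivalences.

### Parameter tables

The residue size table s(a) is the heavy-atom count. The packaged contact
energies U(a,b) and optimal distances d(a,b) are synthetic stand-ins,
clearly labelled in their files: U is built from normalized Kyte–Doolittle
hydropathies (favourable hydrophobic burial, a polarity-mismatch penalty,
and a small seeded symmetric perturbation providing pair-specific
preferences), d from effective radii r(a) = 1.1 + 0.35·s(a)^{1/3}. Both are
plain TSV files and can be replaced by any 20×20 table; the science of the
package does not depend on the particular parameterization, and the tests
assert limits, oracles and trends rather than table values.

## Site-specific stationary distributions

Every model is P_i(a) ∝ P_glob(a)·exp(Λ_stab φ_stab + Λ_str φ_str).
Fitnesses: WT is −ΔΔG on the wild-type background; MF determines the
stability fitness self-consistently at Λ = 1 — the native-contact channel
averages the Boltzmann factor exactly (it factorizes over sites under the
independence assumption), while the misfold channel closes the average at
first order by evaluating the moments on the distribution-averaged contact
energies; iteration uses damping 0.5, tolerance 1e-6 on the largest
frequency change, at most 500 sweeps. RMSD and DE are minus the predicted
deformations with the Λ-dependent wild-type entries described above.
Combined models add both channels with two Λ's.

Global frequencies solve Σ_i P_i(a) = Σ_i f_i^MSA(a) by fixed-point
iteration (geometric-mean damping after 50 iterations guards against
oscillation at strong selection). Alignment frequencies exclude gaps and
are floored at ε = 0.001 then renormalized; model frequencies are floored
the same way, iterating the floor-renormalize step so floored entries equal
ε exactly.

Λ is fitted by minimizing the mean per-site symmetric KL divergence between
model and alignment (a log-likelihood criterion is available behind a
flag), plus the ridge penalty R·Λ². Optimization scans a geometric grid on
[0, 30] and refines the best bracket by bounded scalar minimization; global
frequencies are re-fitted at every Λ evaluation. Combined models fit the
two Λ's on a coarse 2-D grid followed by three coordinate-refinement
cycles. The ridge strength is chosen where the specific heat ∂KL/∂R
(central finite differences of the unpenalized divergence along the fitted
path, on a geometric R grid) is maximal, refined by a log-parabola through
the three bracketing points; a boundary maximum falls back to the boundary
with a warning.

Site entropies are S_i = −ΣP log P and site rates
R_i = Σ_{a≠b} P_i(a)P_i(b)E_i(a,b).

## Exchangeabilities

The HB option multiplies a global exchangeability by the fixation factor
Z_i(x_b−x_a)/(e^{x_b}−e^{x_a}) with x = combined Λφ, evaluated through the
numerically stable x/expm1(x) form whose equal-fitness limit is
Z_i·e^{−x_a}; the factor is symmetric in (a, b), so detailed balance holds
by construction. The FL option solves the flux-matching condition exactly
from its definition: site-averaged model flux P_i(a)P_i(b)E_i(a,b) equals
the empirical flux per pair, which puts 1/Z_i² (noHB) or the additional
fixation factor (HB) in the denominator; a flux-sum oracle verifies the
match to 1e-8. Per-site exchangeabilities are always normalized to unit
site rate; rate1 additionally stores the model-predicted rate as a scale
factor. JTT, LG and WAG ship as PAML-format files; any PAML-dialect matrix
is accepted.

Model and option selection uses the tree-free short-branch pair likelihood
with the divergence time optimized in closed form,
t* = Σ(N(a)−N(a,a)) / (−ΣN(a,a)P_a E_aa), E_aa = −Σ_{b≠a}E_ab P_b.
Pair counts are symmetrized over the two sequences so an identical pair
contributes only the frequency term at t = 0. Each sequence is paired with
a designated reference row (configurable); per-site counts get per-site
optimal times. Because the per-site time absorbs any rate scale, the rate0
and rate1 variants score identically under this criterion; they differ in
the exported models and in tree likelihoods at fixed branch lengths. Ties
rank by fixed model order (JTT < LG < WAG, then option tuples).

## Phylogenetics

The pruning likelihood supports per-site reversible rate matrices through
their symmetrized eigendecompositions (computed once and cached), treats
gaps as missing data, and rescales partials per node to avoid underflow;
reversibility makes it root-invariant (asserted to 1e-10). Branch lengths
are optimized coordinate-wise by bounded scalar minimization of
−loglik + μ·Σt_b on [0, 10], cycling until the objective improves by less
than 1e-6; μ = 0 gives maximum likelihood. μ itself is the least-squares
slope of log-likelihood against total branch length across candidate trees.

Tree comparison matches branches by leaf-set bipartition. The K score fits
one scale s minimizing Σ(t_comp − s·t_ref)² with bipartitions private to
either tree contributing their (scaled) full length; the score is
√(SSE/Σt_ref²) — normalization by the reference's squared branch lengths is
a convention of this package. K2 fits two scales with the class assignment
either supplied per bipartition or fitted by alternating least squares from
three deterministic seedings (median ratio split, residual-sign split, and
the single-class solution), which guarantees K2 ≤ K. The Robinson–Foulds
distance is the symmetric bipartition difference over 2(n−3).

## Synthetic data

Backbones are grown by natural-extension (NeRF) placement with ideal bond
geometry from φ/ψ dihedrals, so the torsional model's degrees of freedom
are exactly the generative ones; O and a mass-lumped Cβ (carrying the
residue's remaining heavy-atom mass) complete each residue. Helix bundles
interleave ideal helical segments with stochastic turns and keep the most
compact clash-free candidate among a seeded set; they reach contact numbers
of ~2–12, like small globular folds. Decoy libraries reuse the compact
generator. Sequences are designed by greedy ΔG descent (sweeps in seeded
random order until no single substitution improves stability), which
produces hydrophobic-core-like sequences at realistic stability. Alignments
are sampled either independently per sequence from the site distributions
or along a tree via the per-site transition matrices (eigendecomposition of
the reversible generators guarantees real spectra).

What the synthetic data do not emulate: real side-chain packing and
rotamers, heterotachy and among-site rate variation beyond the rate1 scale,
insertions/deletions (gaps appear only through user alignments),
phylogenetic correlation in the independently-sampled alignments, and
epistasis beyond the mean-field coupling. Passing tests therefore establish
internal correctness (oracle equivalences, parameter recovery under the
model's own generating process, qualitative structure–evolution trends),
not predictive accuracy on real proteins, which requires experimental
mutant structures and curated alignments.

Sizes used by the default test suite and the acceptance script — bundles of
30–60 residues, decoy libraries of ~20 maps, alignments of 300–500
sequences, 1000 simulated sites for branch-length recovery — were chosen as
the smallest at which the stochastic checks are decisively powered
(p < 0.01 for the trend tests, ±0.1 for Λ recovery).

## Known limitations

* Single chains only; inter-chain contacts and multimeric assemblies are
  out of scope, as are mmCIF inputs and NMR ensembles beyond model 1.
* The mean-field misfold closure is first-order; its fixed point is exact
  only for the native-contact channel.
* The approximate pair likelihood assumes short branches; it ranks models
  but is not a substitute for the tree likelihood.
* The package evaluates and compares given topologies; it does not search
  tree space.
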