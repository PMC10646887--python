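# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind `mdbind`. Internal units are Å, ps, amu, elementary
charges and kcal mol⁻¹ throughout; quantities quoted in nm or kJ mol⁻¹
are converted at the interface (1 nm = 10 Å, 1 kcal = 4.184 kJ). Boxes
are orthorhombic and all distances use the minimum-image convention when
a box is present.

## Umbrella sampling and WHAM

**Model.** Windows restrain the reaction coordinate ξ (protein–ligand COM
separation) with harmonic biases wᵢ(ξ) = ½k(ξ−ξᵢ)². The defaults mirror
the protocol the package emulates: k = 1000 kJ mol⁻¹ nm⁻² (2.3901
kcal mol⁻¹ Å⁻²), window spacing 0.1 nm, T = 303 K. The PMF is estimated by
direct self-consistent iteration of the WHAM equations on the window
free-energy constants Fᵢ, with F₁ pinned to zero to fix the gauge.
Convergence is declared when max|ΔFᵢ| < 1e-8 kcal mol⁻¹ (default cap 10⁵
iterations; non-convergence raises, carrying the last residual).

**Histograms.** 50 bins per nm by default (bin width 0.2 Å). Bins sit on
a global grid anchored at the smallest window center, so bootstrap
replicates and re-runs share commensurate bin centers. Empty bins carry
NaN, never infinities. Windows whose histograms share no occupied bin are
detected as disconnected components of the overlap graph and flagged in
the profile metadata (relative offsets between components are arbitrary).

**IACT weighting.** Each window's ξ series gets an integrated
autocorrelation time τ = 1 + 2·Σρ_t with the initial-positive-sequence
cutoff (sum stops at the first non-positive autocorrelation), clamped to
[1, n/2]. The per-window τ are smoothed along ξ by Nadaraya–Watson
Gaussian regression with σ = 0.15 nm. Windows then enter WHAM with
effective sample size nᵢ/τᵢ. The weight cancels exactly when all windows
share one τ. The weighting functional form (effective sample size) is one
of several defensible readings of IACT-weighted histograms; it is the
package's documented choice.

**Bootstrap.** 100 replicates by default. Each replicate moving-block
resamples every window's series with block length round(τᵢ), preserving
short-range correlation, and reruns WHAM warm-started from the full-data
Fᵢ. Because each WHAM solution carries an arbitrary additive constant,
replicates are aligned on the bins all replicates share before averaging;
the per-bin standard deviation is the reported error. A single replicate
therefore yields zero errors, and more than 10% failed replicates aborts.
Whether the resampling unit should be points, blocks, or whole windows is
not fixed by the protocol being emulated; block-over-points is the
documented choice.

**Zero reference.** The mean restraint force per window is −k⟨ξ−ξᵢ⟩. The
reference is the bias center with the smallest |mean force| within the
largest-ξ third of windows (where the pull force has decayed), mapped to
the nearest occupied bin. If |force| increases strictly monotonically
with ξ — no plateau, as for a purely harmonic landscape — the largest-ξ
occupied bin is used instead and a warning is raised. The operation is
idempotent. ΔG_bind is the minimum of the referenced profile (ties go to
smaller ξ); a non-negative or noise-level minimum sets a no-binding flag.

**Kd conversion.** ΔG_diss = −RT ln(Kd/c°) with
R = 1.98720425864×10⁻³ kcal mol⁻¹ K⁻¹ and c° = 1 M.

## Synthetic umbrella windows

The sampler integrates overdamped (position) Langevin dynamics with
Euler–Maruyama stepping: dξ = F(ξ)/γ·dt + √(2kBT·dt/γ)·N(0,1), F from an
analytic potential (flat, harmonic, quartic double-well, or tabulated
cubic spline) plus the bias. Inertial dynamics would add nothing to what
the estimators can be tested on; the stationary distribution is the
Boltzmann weight of U + bias regardless of the drag γ. Step stability is
pre-checked (dt·max|U″|/γ < 0.5); excursions beyond the potential domain
are reflected and counted (warning above 1% of steps). The first 10% of
steps are discarded as burn-in and every 10th step is recorded, emulating
trajectory saving and giving IACT estimation realistic correlation
(τ ≈ 4–5 recorded samples at the defaults). Default sampling length is
10⁴ recorded samples per window. All generators take a mandatory seed
(default 1234), use `numpy.random.default_rng`, and are bitwise
reproducible; nothing touches global RNG state.

What the generator does **not** emulate: 3D molecular mechanics, solvent,
pulling hysteresis in the window extraction, or correlated noise across
windows. Passing recovery tests shows the estimators are correct on
equilibrium Boltzmann samples with realistic autocorrelation — not that
any particular MD system is converged.

## SOM microstates

**Features** are protein–ligand atom-pair distances per frame
(minimum-image), used unscaled (Å) by default; an optional z-score switch
is deliberately absent from the default path since distance features
share units. Zero-variance features are dropped with a warning.

**Training** is the classical online Kohonen rule on a 10×10
non-periodic hexagonal sheet: per cycle one frame is drawn uniformly with
replacement (seeded), the best matching unit (BMU) found by Euclidean
distance, and every neuron moved by lr·exp(−d²/(2σ²))·(x−w), where d is
the lattice distance in the offset→Cartesian hexagonal embedding
(x = col + 0.5·(row mod 2), y = row·√3/2; unit neighbor spacing). Over
5000 cycles the learning rate decays linearly 0.05 → 0.01 and the radius
⌈max(grid dims)/2⌉ → 1 — common SOM defaults, exposed as parameters. The
codebook is initialized by sampling input frames, which keeps initial
weights on the data scale. With the radius sent to zero the update
degenerates to online k-means (verified against an independent replay in
the tests). Whether training should sample uniformly or sweep epochs is
ambiguous in the classical description; uniform-with-replacement is
implemented. Training is visit-order dependent through the seed: the same
seed on permuted frames visits different data, so codebooks are
reproducible per (data, seed) pair, and assignment — not training — is
permutation-equivariant.

**Clustering.** Neurons are merged by complete-linkage agglomerative
clustering (Euclidean) and the dendrogram is cut at each k in the scanned
range (default 5–10); every frame inherits its BMU's cluster and the mean
silhouette over frames in feature space picks k (a neuron-level variant
is available). The dendrogram is built over frame-occupied neurons only:
frame-empty neurons are interpolation artifacts of the sheet that would
otherwise absorb cuts — inflating the selected k — without changing any
frame's label; they are attached to the nearest occupied cluster
afterwards so every neuron is labeled. Labels are capital letters in
order of first appearance by neuron index. Ties in the silhouette prefer
the smaller k. Representative frames are the frames closest to the
codebook of a cluster's most populated neuron (population ties → lowest
neuron index, distance ties → lowest frame index).

**Planted-microstate generator.** Isotropic Gaussian blobs in distance
space, centers pairwise ≥ separation apart (rejection sampling with
bounded retries), values clipped non-negative. The default
separation/spread ratio of 10 (5 Å / 0.5 Å) represents well-resolved
microstates; recovery degrades gracefully as the ratio falls and is not
guaranteed below ~6.

## Interaction geometry

**H-bonds.** A donor D (heavy atom with covalently bonded H, flags from
the topology table or guessed from O/N chemistry), hydrogen H and
acceptor A form a hydrogen bond when d(D,A) ≤ 3.0 Å and the A–D–H angle
(vertex at the donor) ≤ 20°. The toy-complex generator plants triplets at
d ≤ 2.8 Å, angle ≤ 8° and forces every decoy geometry to miss by ≥ 0.3 Å
or ≥ 15°, re-drawing the construction if any accidental cross-site
geometry lands in the margin band — so detected counts are stable under
jitter well beyond 0.05 Å.

**rdf.** g(r) = frame-averaged shell counts / (exact shell volume ×
target density N/V), shells 0.1 Å wide, reference either a single atom
(nanoparticle-center convention) or a group. Requires a box;
r_max ≤ L/2.

**Nonbonded energies.** Cross-group sums of CHARMM-form 12-6 LJ
(ε_ij = √(εᵢεⱼ), Rmin_ij = Rmin/2ᵢ + Rmin/2ⱼ) and Coulomb
(332.0637·qᵢqⱼ/r, dielectric 1), both multiplied by the C¹ CHARMM
switching polynomial on [10, 12] Å. Applying the same smooth truncation
to the Coulomb term is an analysis convention that keeps group energies
well-defined without Ewald sums; it is not a claim about any MD engine's
electrostatics. Energies are symmetric in the groups and exactly additive
over partitions. Only cross-group (interaction) terms are reported —
the complex-minus-isolated-parts contract at the nonbonded level.

**Contact surface area.** Standard (unweighted) Voronoi tessellation of
all atoms with explicit periodic images within one box length; the
reported area sums facets shared between a central-image cell of one
group and any cell of the other, counting each physical facet once.
Facets below 1e-9 Å² are dropped as numerical slivers; coincident atoms
are perturbed by 1e-6 Å with a warning. A radical (radius-weighted)
tessellation is not implemented. Note that under periodic boundaries two
half-box slabs meet at **two** interfaces (the central plane and the
wrap-around seam); the two-slab reference fixture therefore plants a thin
separator layer of a third group at the seam, making the central plane —
of exactly the box cross-section, by mirror symmetry of the slab
lattices — the only A|B interface.

**Angle–distance maps.** For each molecule (COM group, tail atom, head
atom): d = |COM − center atom| and θ = the vertex angle at the tail
between tail→center and tail→head, histogrammed over frames and
molecules. θ is rotation-invariant; d is translation-invariant only
jointly with the center atom.

## Problem sizes

The recovery analyses run at 11 windows × 10⁴ samples (umbrella), 2000
frames × 10 features (SOM), 5000 atoms (rdf), ~700 atoms (Voronoi slabs)
and 10⁵-point series (IACT) — sizes chosen so every ground-truth recovery
is statistically decisive while the full battery completes in seconds.

## Known limitations

- WHAM only (no MBAR), 1D reaction coordinates, shared temperature across
  windows.
- The PDB reader accepts single-altloc files and does not interpret chain
  semantics; DCD/XTC binary formats are out of scope (trajectories are
  multi-model PDB or XYZ).
- Donor/acceptor roles come from the topology table; the O/N-based
  fallback is a chemistry heuristic, not force-field typing.
- Electrostatics are switched real-space sums; systems where long-range
  (Ewald) contributions dominate group energetics are outside the intended
  use of the energy report.
- The Voronoi construction replicates all 26 periodic images, which is
  robust but O(27·N) in tessellation size; very large frames should be
  pre-filtered to the interfacial region.
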