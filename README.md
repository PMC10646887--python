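# mdbind

Analysis toolkit for ligand–receptor binding studies from molecular-dynamics
trajectories, built for systems such as folate-functionalized nanoparticles
targeting the folate receptor. It covers the three analysis layers such a
study needs:

- **Umbrella-sampling free energies.** Biased windows of a reaction
  coordinate ξ (a protein–ligand COM separation) are combined with the
  Weighted Histogram Analysis Method (WHAM), solved by self-consistent
  iteration of

  P(ξ_l) = Σᵢ nᵢ(ξ_l)/τᵢ ÷ Σᵢ (Nᵢ/τᵢ) exp[−β(wᵢ(ξ_l) − Fᵢ)],
  Fᵢ = −kBT ln Σ_l P(ξ_l) exp[−β wᵢ(ξ_l)],

  where wᵢ(ξ) = ½k(ξ−ξᵢ)² is the harmonic bias and τᵢ the window's
  integrated autocorrelation time (IACT), Gaussian-smoothed along ξ.
  Errors come from an IACT-aware block bootstrap; the profile is zeroed
  where the mean restraint force drops to its minimum at large ξ, and the
  binding free energy is the profile minimum. Kd ↔ ΔG conversion
  (ΔG = −RT ln Kd/c°) is included.
- **Conformational microstates.** Frames described by protein–ligand
  distances are mapped onto a 10×10 hexagonal self-organizing map (SOM,
  online Kohonen training, 5000 cycles); neurons are merged by
  complete-linkage agglomerative clustering and the cluster count is chosen
  by the silhouette score over a scanned range (default 5–10).
- **Interaction geometry.** Hydrogen bonds (≤3.0 Å donor–acceptor,
  ≤20° acceptor–donor–hydrogen), radial distribution functions with 0.1 Å
  shells, COM distance series, angle–distance conformational maps, Voronoi
  contact surface areas under periodic boundaries, and switched nonbonded
  energies (12-6 Lennard-Jones + Coulomb, CHARMM switching between 10 and
  12 Å).

A synthetic-systems module generates every input with known ground truth —
Brownian umbrella windows from analytic 1D potentials, planted Gaussian
microstates, toy frames with planted hydrogen bonds, and reference
lattice/ideal-gas/two-slab configurations — so the whole pipeline is
testable end to end without MD engines.

## Worked example

Recover a known free-energy profile from synthetic umbrella sampling.
The generator mirrors a standard protocol: bias k = 1000 kJ mol⁻¹ nm⁻²,
window spacing 0.1 nm, T = 303 K:

```python
import numpy as np
from mdbind import pmf, synthetic as syn

potential = syn.Potential1D.harmonic(2.0, 5.0)   # known PMF: 1/2·2·(xi-5)^2
uset = syn.generate_umbrella_set(potential, centers=5.0 + np.arange(11) - 5.0,
                                 samples_per_window=10_000, seed=1)
iact = pmf.iact_profile(uset.windows)
profile = pmf.bootstrap_pmf(uset.windows, n_boot=100, seed=1, iact=iact)
profile = pmf.set_zero_reference(profile, uset.windows)
dg = pmf.binding_free_energy(profile)
m = np.isfinite(profile.w)
a_est = 2.0 * np.polyfit(profile.xi[m], profile.w[m], 2)[0]
print(f"windows: {len(uset.windows)}, samples/window: 10000")
print(f"mean IACT (samples): {iact.tau_smoothed.mean():.2f}")
print(f"recovered curvature: {a_est:.3f} kcal/mol/A^2 (true 2.0)")
print(f"reference xi: {profile.metadata['reference_xi']:.2f} A")
print(f"dG_bind: {dg.value:.2f} +/- {dg.error:.2f} kcal/mol")
```

prints

```
windows: 11, samples/window: 10000
mean IACT (samples): 4.50
recovered curvature: 1.985 kcal/mol/A^2 (true 2.0)
reference xi: 6.90 A
dG_bind: -3.58 +/- 0.02 kcal/mol
```

The recovered curvature matches the generating potential within 1%; the
profile is zeroed at ξ = 6.9 Å (the largest sampled separation, since a
purely harmonic potential has no force plateau — the package warns about
this) and the well depth −3.58 ± 0.02 kcal mol⁻¹ agrees with the analytic
value −½·2·(6.9−5)² = −3.61 within bootstrap error.

The same workflow is available from the shell:

```
mdbind synth umbrella --potential harmonic --curvature 2.0 --center 5 --out us/
mdbind pmf --windows us/windows.csv --boot 100 --seed 1
mdbind synth features --clusters 7 --out feats/
mdbind som --features feats/features.csv --k-range 5:10 --out som_out/
```

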