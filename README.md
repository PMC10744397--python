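# amdmem

Analysis toolkit for accelerated molecular dynamics (aMD) simulations of
membrane-active peptides — peptaibols and similar amphipathic sequences
placed at a water–bilayer interface.

aMD flattens the energy landscape by adding a boost
ΔV(V) = (E−V)²/(α+E−V) wherever the potential drops below a threshold E,
so rare events (peptide insertion, conformational transitions) happen on
tractable timescales. The price is a biased ensemble: every analysis has to
remove the boost again. `amdmem` implements that workflow end to end:

* **Boost bookkeeping** — the aMD boost closed form, the three boost
  criteria (whole-potential, torsion-only, dual boost), the standard recipe
  that seeds (E, α) from classical-run average energies, and a lossless
  reader/writer for per-frame boost logs (the `amd.log` dialect).
* **Canonical reweighting** — frame weights e^{ΔV/k_BT} (exponential
  average) or their truncated Maclaurin series Σ_{j≤k}(ΔV/k_BT)^j/j!
  (noise-suppressed), weighted histograms, and potentials of mean force
  PMF_b = −k_BT·ln(p_b/max p_b) over 1D and 2D reaction coordinates with
  masked empty bins.
* **Dihedral PCA** — backbone φ/ψ series (IUPAC convention,
  terminal-residue angles flagged absent), circular-safe sin/cos features,
  covariance eigendecomposition, and most-populated-cluster extraction on a
  density grid over the top three principal components, with representative
  frames.
* **Membrane observables** — deuterium order parameters
  |S_CD| = |0.5⟨3cos²θ−1⟩| per acyl carbon, the peptide-COM to
  membrane-centre insertion distance feeding a reweighted PMF, and
  per-residue peptide–headgroup contact fractions.
* **Synthetic ground truth** — generators for boosted samples from
  closed-form potentials, planted von Mises torsion clusters, prescribed
  bond-vector tilt laws, and toy membrane+peptide systems, so every stage
  is validated against a known answer.

## Worked example

```python
import numpy as np
import amdmem as am

thermo = am.ThermoParams(temperature=300.0)

# Sample a tilted double well (barrier 3 kcal/mol, unique minimum at x=+1)
# on its aMD-boosted surface, then recover the canonical PMF by reweighting.
pot = am.ToyPotentialSpec("double_well_1d",
                          {"barrier": 3.0, "half_sep": 1.0, "tilt": -0.5},
                          bounds=(-2.0, 2.0))
amd = am.AmdParams(mode=1, e_total=pot.min_energy() + 4.0, alpha_total=2.0)
xs, boost = am.sample_boosted(
    pot, am.SamplerSpec(n_samples=100_000, seed=1, kT=thermo.kT, amd=amd))
w = am.frame_weights(boost, thermo, method="maclaurin", order=10)
fes = am.pmf_1d(xs, w, np.linspace(-2, 2, 41), thermo)
print(f"mean boost       : {boost.total_boost.mean():.3f} kcal/mol")
print(f"PMF minimum at x : {fes.argmin_center():+.3f} (planted well: +1)")
print(f"barrier height   : {np.nanmax(fes.pmf[10:30]):.3f} kcal/mol (analytic: 3.52)")

# Membrane geometry on a constructed toy system.
topo, traj = am.gen_toy_membrane_system(peptide_z_offset=28.0, seed=0)
d = am.com_z_distance(traj, topo)
print(f"peptide-membrane distance: {d.values[0]:.1f} angstrom")
```

Output:

```
mean boost       : 1.494 kcal/mol
PMF minimum at x : +1.050 (planted well: +1)
barrier height   : 3.468 kcal/mol (analytic: 3.52)
peptide-membrane distance: 28.0 angstrom
```

The boosted chain crosses the 3 kcal/mol barrier freely (mean boost
1.5 kcal/mol ≈ 2.5 k_BT), and reweighting puts the free-energy minimum back
in the planted lower well with the barrier height recovered to within the
bin-discretisation error.

## Command line

Every stage is also a subcommand (`amdmem synth`, `reweight`, `dpca`,
`scd`, `distz`, `contacts`, `pmf`), and `amdmem run --config run.yaml`
executes the full sequence — boost parsing, reweighting, dihedral PCA and
clustering, order parameters, insertion PMF, contacts — writing TSV
results, representative-structure PDBs, and a JSON manifest with config and
input hashes so reruns are verifiably reproducible.

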