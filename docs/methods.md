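# Methods

`amdmem` analyses accelerated-MD (aMD) simulations of a peptide interacting
with a lipid bilayer. This note records the models implemented, the
parameters that matter, what the synthetic generators do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Boost potential

aMD flattens the energy landscape by adding a boost wherever the potential
falls below a threshold E:

    dV(V) = (E - V)^2 / (alpha + E - V)   for V < E,   0 otherwise.

The boost is non-negative, bounded by E − V, non-increasing in V, and leaves
V + dV non-decreasing, so the boosted surface preserves the ordering of
states while compressing barriers. Three criteria are supported through
`AmdParams.mode`: whole-potential boost (1), torsion-only boost (2), and
dual boost (3). `params_from_classical_averages` seeds (E, alpha) from
classical-run average energies with the standard dual-boost recipe —
torsional threshold 3.5 kcal/mol per residue above the average dihedral
energy with alpha one fifth of that margin, and total threshold
0.175 kcal/mol per atom above the average potential with alpha equal to the
margin. All three constants are function arguments so the recipe is
auditable and adjustable. The Boltzmann constant is fixed at
0.0019872041 kcal mol⁻¹ K⁻¹ (kT ≈ 0.59616 kcal/mol at 300 K).

## Reweighting

Canonical statistics are recovered by weighting frame i by the Boltzmann
factor of its boost, w_i = exp(dV_i/kT), or by the truncated Maclaurin
series Σ_{j≤k} (dV_i/kT)^j / j!, which suppresses the statistical noise the
exponential develops under large boosts at the cost of a small, k-controlled
bias. The default order is k = 10, the common practice for this estimator;
on dV/kT ∈ [0, 3] it agrees with the exponential to better than 0.05%
relative and the disagreement shrinks monotonically with k (both facts are
asserted by the benchmark suite). Which boost component enters the factor
(total, dihedral-only, or whole-potential-only) is configurable; the default
is the total boost dV_P + dV_D.

PMFs are computed as −kT·ln(p_b/max p_b) from weighted histograms, so the
most populated bin anchors the surface at zero. Empty bins are masked, never
imputed or zero-filled; probabilities over non-empty bins sum to one.
Default binning is 1 Å for the insertion distance and 50×50 bins spanning
the observed range for 2D principal-component surfaces (resolutions the
synthetic benchmarks support comfortably).

## Dihedral PCA and clustering

Backbone φ(i) = C(i−1)–N(i)–CA(i)–C(i) and ψ(i) = N(i)–CA(i)–C(i)–N(i+1)
are computed with the IUPAC sign convention (cis = 0°, verified against
MDAnalysis and biotite). Angles a residue cannot define — chain termini,
the C-terminal amino-alcohol's missing ψ partner — are flagged absent and
excluded column-wise, never zero-filled. Each defined angle is mapped to
(cos χ, sin χ) so the ±180° seam carries no artificial variance; PCA is an
eigendecomposition of the feature covariance (angles stored in degrees,
features computed in radians).

Conformational clusters come from a density grid over the top three
principal components: cells holding at least `min_density` (default 0.2%)
of the frames are dense, connected components of dense cells (full diagonal
adjacency) are basins, frames in sparse cells join the nearest basin within
one cell diagonal or become noise, and basins are ranked by population.
Each cluster's representative is the member frame nearest its centroid.
The default grid resolution is chosen from the frame count (about 25 frames
per cell per axis, clipped to [4, 32]) rather than fixed: at a few thousand
frames a fixed 32-cells-per-axis 3D grid dilutes genuine basins below any
sensible density threshold and shatters them into noise, while the
occupancy-aware default recovers well-separated basins exactly. A fixed
resolution remains available through `grid_bins`.

## Membrane observables

The deuterium order parameter per acyl carbon is
|S_CD| = |0.5⟨3cos²θ − 1⟩| with θ the angle between a C–H bond (the
all-atom stand-in for C–D) and the bilayer normal (+z by default); the
average runs over lipids, frames and the hydrogens of the carbon *before*
the absolute value. Carbons are indexed from the carbonyl carbon = 1, which
bears no hydrogen, so profiles start at carbon 2. Carbons with no
resolvable hydrogen are omitted with a warning, not zero-filled.

The insertion coordinate is |z_COM(peptide) − z_COM(membrane)| with
mass-weighted COMs; the membrane centre is the COM of all lipid atoms, and
peptide atoms are first wrapped to the periodic image nearest the membrane
along z. Contact fractions count, per peptide residue, the fraction of
frames in which any non-backbone heavy atom lies within a cutoff
(default 4.5 Å, a standard heavy-atom contact distance) of any flagged
lipid headgroup heavy atom, minimum-image along periodic axes. Terminal
residues contribute their cap/alcohol heavy atoms, since terminal residues
are exactly where peptide–headgroup anchoring is expected.

## Synthetic data: what it emulates, what it does not

The generators provide every input class with known ground truth:

* **Boosted ensembles** — Metropolis samples from closed-form 1D/2D
  potentials, optionally on the boosted surface V* = V + dV(V), with the
  per-sample boost recorded exactly as an amd.log would. Metropolis (not
  dynamics) is the default because the reweighting contract only requires
  correct stationary statistics; the proposal step is auto-tuned to 30–50%
  acceptance during burn-in so no integrator-timestep error enters the
  benchmarks. An overdamped-Langevin sampler is available for
  dynamics-flavoured streams.
* **Torsion clusters** — von Mises mixtures over per-residue (φ, ψ) with
  planted labels. The two-cluster benchmark uses weights 0.7/0.3, κ = 20
  (circular spread ≈ 13°) and 120° mean separation across 18 residues —
  well-separated but finite-width conformational states.
* **Oriented bond vectors** — delta, isotropic, or von Mises–Fisher polar
  laws about +z with uniform azimuth, for order-parameter closed forms.
* **Toy membrane systems** — mirror-symmetric pseudo-bilayers (headgroup
  bead + hydrogenated chain carbons, PE:PG 3:1) with a pseudo-peptide placed
  at an exact COM offset.

None of this emulates real lipid force fields, water, electrostatics, or
the kinetics of peptide insertion. Passing benchmarks therefore validate
the *analysis machinery* — that reweighting recovers known canonical
statistics, that dPCA clustering recovers planted conformational states,
that the geometric observables return their constructed values — not any
property of a real membrane simulation.

## Benchmark conditions and numerical choices

* **Free-energy recovery**: a 1D double well with a 3 kcal/mol barrier,
  tilted by −0.5 kcal/mol so the global minimum is unique (the symmetric
  well's two minima are exactly degenerate, which would make a
  minimum-location check a coin flip). Sampling on the boosted surface with
  E = min V + 4 kcal/mol, alpha = 2, kT at 300 K, 200,000 samples,
  40 bins; the analytic reference is the exact Boltzmann bin measure by
  quadrature. Recovery is checked to 0.2 kcal/mol on bins with ≥ 200 raw
  counts (sparser bins are dominated by shot noise of the exponential
  weights).
* **Insertion geometry**: a harmonic z-potential centred at 28 Å, sampled
  unboosted and boosted (E = min V + 2, alpha = 1) at 30,000 samples, 1 Å
  bins; the PMF argmin must land within one bin of the planted minimum.
* **Degenerate inputs**: empty boost series parse to empty series;
  all-empty histograms and empty vector sets are errors, not silent zeros;
  ties in the PMF anchor resolve to the first maximal bin.
* Every generator and benchmark is a pure function of (spec, seed); one
  seeded generator per call, no global random state.

## Known limitations

* The whitespace frame table and multi-model PDB are the only trajectory
  carriers; binary formats (DCD/XTC/NetCDF) would be adapter-layer work.
* Maclaurin reweighting bias is not corrected, only bounded by the order;
  cumulant-expansion estimators are out of scope.
* The grid clusterer is deterministic and parameter-light by design; it is
  not a substitute for density-based methods on strongly non-convex or
  overlapping basins.
* United-atom lipids (no explicit H) are not supported by the order
  parameter path; C–H vectors must be resolvable from the topology.
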