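"""Synthetic inputs with known ground truth for every pipeline stage.

Four generator families:

* ``sample_boosted`` — Metropolis (or overdamped-Langevin) samples from a
  toy 1D/2D potential, optionally run on the aMD-boosted surface
  V*(x) = V(x) + dV(V(x)), with the per-sample boost recorded so canonical
  reweighting can be validated against the analytic Boltzmann answer.
* ``gen_torsion_clusters`` — phi/psi series drawn from a von Mises mixture
  with planted cluster labels, for dPCA/cluster-recovery tests.
* ``gen_oriented_vectors`` — unit C-H-like bond vectors with a prescribed
  tilt law about the +z bilayer normal, for order-parameter closed forms.
* ``gen_toy_membrane_system`` — a mirror-symmetric pseudo-bilayer (headgroup
  bead + chain carbons with hydrogens) plus a pseudo-peptide at a chosen
  z offset, for distance/contact geometry with constructed answers.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .amd_model import AmdParams, boost_energy
from .dihedral_pca import DihedralSeries, wrap_degrees
from .io_formats import BoostRecordSeries, Topology, TrajectoryFrameSet


@dataclass(frozen=True)
class ToyPotentialSpec:
    """Closed-form toy potential standing in for the membrane landscape.

    Families (energies kcal/mol, coordinates in arbitrary "angstrom-like"
    units):

    * ``harmonic``: V = 0.5 * k * (x - center)^2
    * ``double_well_1d``: V = barrier * (u^2 - 1)^2 + tilt * u with
      u = (x - center)/half_sep; wells near center +/- half_sep, barrier
      height at the center.  A non-zero ``tilt`` (kcal/mol, default 0)
      lowers one well so the global minimum is unique — needed whenever a
      test compares minimum locations, since the symmetric well is
      degenerate.
    * ``double_well_2d``: the 1D double well along x plus an independent
      harmonic 0.5 * k_y * y^2.
    """

    family: str
    params: dict = field(default_factory=dict)
    bounds: tuple = (-3.0, 3.0)

    def __post_init__(self):
        if self.family not in ("harmonic", "double_well_1d", "double_well_2d"):
            raise ValueError(f"unknown potential family {self.family!r}")

    @property
    def ndim(self) -> int:
        return 2 if self.family == "double_well_2d" else 1

    def _dw1d(self, x):
        h = self.params.get("barrier", 3.0)
        a = self.params.get("half_sep", 1.0)
        c = self.params.get("center", 0.0)
        t = self.params.get("tilt", 0.0)
        u = (np.asarray(x, dtype=float) - c) / a
        return h * (u * u - 1.0) ** 2 + t * u

    def energy(self, x):
        """V(x) in kcal/mol; x scalar/array (1D) or (..., 2) (2D family)."""
        if self.family == "harmonic":
            k = self.params.get("k", 1.0)
            c = self.params.get("center", 0.0)
            return 0.5 * k * (np.asarray(x, dtype=float) - c) ** 2
        if self.family == "double_well_1d":
            return self._dw1d(x)
        xy = np.asarray(x, dtype=float)
        ky = self.params.get("k_y", 1.0)
        return self._dw1d(xy[..., 0]) + 0.5 * ky * xy[..., 1] ** 2

    def min_energy(self, n_grid: int = 20001) -> float:
        """min V over the domain (fine-grid evaluation; exact enough for
        the closed-form 1D families)."""
        if self.ndim != 1:
            raise ValueError("1D families only")
        xs = np.linspace(*self.bounds, n_grid)
        return float(self.energy(xs).min())

    def free_energy(self, x):
        """Analytic profile F(x) = V(x) - min V (1D families)."""
        if self.ndim != 1:
            raise ValueError("analytic free energy available for 1D families only")
        return self.energy(x) - self.min_energy()

    def boltzmann_bin_probabilities(self, edges, kT: float, n_quad: int = 2001):
        """Exact canonical bin probabilities by quadrature of exp(-V/kT)."""
        if self.ndim != 1:
            raise ValueError("1D families only")
        edges = np.asarray(edges, dtype=float)
        probs = np.empty(len(edges) - 1)
        for b in range(len(edges) - 1):
            xs = np.linspace(edges[b], edges[b + 1], n_quad)
            probs[b] = np.trapezoid(np.exp(-self.energy(xs) / kT), xs)
        return probs / probs.sum()


@dataclass(frozen=True)
class SamplerSpec:
    """Sampling protocol for ``sample_boosted``; seed fixes the full stream."""

    n_samples: int
    seed: int
    kT: float
    sampler: str = "metropolis"
    step_size: float = 0.5
    burn_in: int = 2000
    thinning: int = 1
    amd: AmdParams | None = None

    def __post_init__(self):
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.sampler not in ("metropolis", "overdamped_langevin"):
            raise ValueError(f"unknown sampler {self.sampler!r}")


def sample_boosted(potential: ToyPotentialSpec, sampler: SamplerSpec):
    """Draw samples from the (optionally boosted) toy potential.

    With aMD parameters present (whole-potential boost semantics) the chain
    targets the flattened surface V*(x) = V(x) + dV(V(x)); without them it
    targets V itself.  Returns ``(positions, BoostRecordSeries)`` where the
    series records V(x_i) and the applied boost dV(x_i) per retained sample,
    so that reweighting by exp(dV/kT) recovers the canonical density
    proportional to exp(-V(x)/kT).
    """
    rng = np.random.default_rng(sampler.seed)
    d = potential.ndim

    if sampler.amd is not None:
        e, a = sampler.amd.e_total, sampler.amd.alpha_total

        def v_star(v):
            return v + boost_energy(v, e, a)
    else:

        def v_star(v):
            return v

    lo, hi = potential.bounds
    x = np.full(d, 0.5 * (lo + hi)) if d > 1 else np.array([0.5 * (lo + hi)])

    def energy_of(pt):
        return float(potential.energy(pt if d > 1 else pt[0]))

    step = sampler.step_size
    v_cur = energy_of(x)

    if sampler.sampler == "metropolis":
        # burn-in with step-size auto-tuning toward 30-50% acceptance
        n_acc = 0
        for i in range(sampler.burn_in):
            prop = x + rng.normal(0.0, step, size=d)
            v_prop = energy_of(prop)
            if np.log(rng.random()) < (v_star(v_cur) - v_star(v_prop)) / sampler.kT:
                x, v_cur = prop, v_prop
                n_acc += 1
            if (i + 1) % 100 == 0:
                rate = n_acc / 100.0
                if rate > 0.5:
                    step *= 1.1
                elif rate < 0.3:
                    step *= 0.9
                n_acc = 0

        positions = np.empty((sampler.n_samples, d))
        v_series = np.empty(sampler.n_samples)
        for i in range(sampler.n_samples * sampler.thinning):
            prop = x + rng.normal(0.0, step, size=d)
            v_prop = energy_of(prop)
            if np.log(rng.random()) < (v_star(v_cur) - v_star(v_prop)) / sampler.kT:
                x, v_cur = prop, v_prop
            if (i + 1) % sampler.thinning == 0:
                j = (i + 1) // sampler.thinning - 1
                positions[j] = x
                v_series[j] = v_cur
    else:  # overdamped Langevin (Euler-Maruyama on V*, numerical gradient)
        dt = step * step  # interpret step_size as sqrt(dt)
        eps = 1e-5
        positions = np.empty((sampler.n_samples, d))
        v_series = np.empty(sampler.n_samples)
        n_total = sampler.burn_in + sampler.n_samples * sampler.thinning
        kept = 0
        for i in range(n_total):
            grad = np.empty(d)
            for k in range(d):
                xp, xm = x.copy(), x.copy()
                xp[k] += eps
                xm[k] -= eps
                grad[k] = (v_star(energy_of(xp)) - v_star(energy_of(xm))) / (2 * eps)
            x = x - grad * dt + np.sqrt(2 * sampler.kT * dt) * rng.normal(size=d)
            if i >= sampler.burn_in and (i - sampler.burn_in + 1) % sampler.thinning == 0:
                positions[kept] = x
                v_series[kept] = energy_of(x)
                kept += 1

    if sampler.amd is not None:
        dv = boost_energy(v_series, e, a)
    else:
        dv = np.zeros_like(v_series)
    series = BoostRecordSeries(
        step=np.arange(1, sampler.n_samples + 1),
        v_total=v_series,
        v_dih=np.zeros_like(v_series),
        dv_total=dv,
        dv_dih=np.zeros_like(v_series),
        mode=1,
    )
    out = positions[:, 0] if d == 1 else positions
    return out, series


def gen_torsion_clusters(
    n_frames: int,
    n_residues: int,
    weights,
    means_deg,
    kappas,
    seed: int,
):
    """Phi/psi series from a von Mises mixture with planted labels.

    ``weights``: per-cluster probabilities (sum 1 to 1e-9).  ``means_deg``:
    (n_clusters, 2) circular means applied to every residue, or
    (n_clusters, n_residues, 2) per-residue means.  ``kappas``: per-cluster
    von Mises concentration (>= 0; large kappa -> delta at the mean).
    Returns ``(DihedralSeries, labels)``.
    """
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"cluster weights must sum to 1, got {weights.sum()}")
    kappas = np.asarray(kappas, dtype=float)
    if np.any(kappas < 0):
        raise ValueError("concentrations must be >= 0")
    means = np.asarray(means_deg, dtype=float)
    n_clusters = len(weights)
    if means.ndim == 2:
        means = np.broadcast_to(means[:, None, :], (n_clusters, n_residues, 2))
    rng = np.random.default_rng(seed)
    labels = rng.choice(n_clusters, size=n_frames, p=weights)
    angles = np.empty((n_frames, n_residues, 2))
    for c in range(n_clusters):
        members = labels == c
        n_c = int(members.sum())
        if n_c == 0:
            continue
        mu = np.radians(means[c])  # (n_residues, 2)
        if kappas[c] == 0:
            draw = rng.uniform(-np.pi, np.pi, size=(n_c, n_residues, 2))
        else:
            draw = rng.vonmises(mu[None, :, :], kappas[c], size=(n_c, n_residues, 2))
        angles[members] = wrap_degrees(np.degrees(draw))
    if n_frames == 0:
        angles = np.empty((0, n_residues, 2))
    return (
        DihedralSeries(
            angles=angles,
            residue_labels=[f"RES{i + 1}" for i in range(n_residues)],
        ),
        labels,
    )


def gen_oriented_vectors(n_vectors: int, tilt, seed: int):
    """Unit vectors with a prescribed polar-angle law about the +z normal.

    ``tilt`` is ``("delta", theta_deg)``, ``("isotropic",)`` or
    ``("vmf", kappa)`` (von Mises-Fisher about +z).  Azimuth is uniform.
    Returns ``(vectors (n, 3), normal (0, 0, 1))``.
    """
    if n_vectors < 0:
        raise ValueError("n_vectors must be >= 0")
    rng = np.random.default_rng(seed)
    kind = tilt[0]
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n_vectors)
    if kind == "delta":
        cos_t = np.full(n_vectors, np.cos(np.radians(tilt[1])))
    elif kind == "isotropic":
        cos_t = rng.uniform(-1.0, 1.0, size=n_vectors)
    elif kind == "vmf":
        kappa = float(tilt[1])
        if kappa == 0:
            cos_t = rng.uniform(-1.0, 1.0, size=n_vectors)
        else:
            # inverse-CDF sampling of the vMF polar angle about +z
            u = rng.random(n_vectors)
            cos_t = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    else:
        raise ValueError(f"unknown tilt distribution {kind!r}")
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    vectors = np.column_stack(
        (sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t)
    )
    return vectors, np.array([0.0, 0.0, 1.0])


# default pseudo-peptide: the 18-residue peptaibol-like sequence with
# Aib-rich composition and terminal Ser/Gln analogues
DEFAULT_PEPTIDE_RESIDUES = (
    "AIB SER ALA AIB DIV GLN DIV AIB VAL ALA DIV AIB PRO LEU AIB VAL GLN PHL"
).split()

_ELEMENT_FOR_NAME = {"P": "P", "N": "N", "O": "O"}


def gen_toy_membrane_system(
    n_lipids_per_leaflet: int = 16,
    headgroup_z: float = 18.0,
    peptide_z_offset: float = 28.0,
    peptide_residues=DEFAULT_PEPTIDE_RESIDUES,
    seed: int = 0,
    n_frames: int = 1,
    frame_jitter: float = 0.0,
    n_chain_carbons: int = 6,
    box_xy: float | None = None,
    pg_every: int = 4,
):
    """Build a mirror-symmetric pseudo-bilayer plus pseudo-peptide.

    Each lipid is a headgroup bead ``P`` at +/-``headgroup_z`` and chain
    carbons C2..C(n+1) stepping toward z = 0, each carbon with two
    hydrogens; every ``pg_every``-th lipid is PG, the rest PE (3:1 with the
    default).  The two leaflets are exact mirror images about z = 0, so the
    membrane centre of mass sits at z = 0.  All peptide atoms are placed at
    exactly ``peptide_z_offset`` so the peptide COM z is that offset by
    construction.  ``frame_jitter`` adds seeded Gaussian noise (angstrom) to
    frames after the first.

    Returns ``(Topology, TrajectoryFrameSet)``.
    """
    if n_lipids_per_leaflet < 1:
        raise ValueError("n_lipids_per_leaflet must be >= 1")
    rng = np.random.default_rng(seed)
    grid = int(np.ceil(np.sqrt(n_lipids_per_leaflet)))
    spacing = 8.0
    box_l = box_xy if box_xy is not None else grid * spacing

    serial, names, resnames, resids, chains, elements = [], [], [], [], [], []
    classes, headgroup, coords = [], [], []
    next_serial = 1
    next_resid = 1

    def add_atom(name, resname, resid, chain, cls, hg, xyz):
        nonlocal next_serial
        serial.append(next_serial)
        names.append(name)
        resnames.append(resname)
        resids.append(resid)
        chains.append(chain)
        elements.append(_ELEMENT_FOR_NAME.get(name[0], name[0]))
        classes.append(cls)
        headgroup.append(hg)
        coords.append(xyz)
        next_serial += 1

    chain_dz = (headgroup_z - 2.0) / n_chain_carbons
    for leaflet in (+1, -1):
        for li in range(n_lipids_per_leaflet):
            gx, gy = divmod(li, grid)
            x0 = (gx + 0.5) * spacing - box_l / 2
            y0 = (gy + 0.5) * spacing - box_l / 2
            resname = "PG" if (li % pg_every) == pg_every - 1 else "PE"
            rid = next_resid
            next_resid += 1
            add_atom("P", resname, rid, "M", "lipid", True,
                     [x0, y0, leaflet * headgroup_z])
            for ci in range(2, 2 + n_chain_carbons):
                cz = leaflet * (headgroup_z - (ci - 1) * chain_dz)
                add_atom(f"C{ci}", resname, rid, "M", "lipid", False, [x0, y0, cz])
                add_atom(f"H{ci}A", resname, rid, "M", "lipid", False,
                         [x0 + 1.0, y0, cz])
                add_atom(f"H{ci}B", resname, rid, "M", "lipid", False,
                         [x0 - 1.0, y0, cz])

    if peptide_residues:
        for i, resname in enumerate(peptide_residues):
            rid = next_resid
            next_resid += 1
            x0 = -len(peptide_residues) * 1.9 + i * 3.8
            z = peptide_z_offset
            add_atom("N", resname, rid, "A", "peptide", False, [x0, 0.0, z])
            add_atom("CA", resname, rid, "A", "peptide", False, [x0 + 1.2, 0.0, z])
            add_atom("C", resname, rid, "A", "peptide", False, [x0 + 2.4, 0.0, z])
            add_atom("CB", resname, rid, "A", "peptide", False, [x0 + 1.2, 1.5, z])

    from .io_formats import _atom_mass  # masses from standard atomic weights

    mass = np.array([_atom_mass(el, nm) for el, nm in zip(elements, names)])
    topo = Topology(
        serial=np.array(serial),
        name=np.array(names),
        resname=np.array(resnames),
        resid=np.array(resids),
        chain=np.array(chains),
        element=np.array(elements),
        mass=mass,
        molecule_class=np.array(classes),
        headgroup=np.array(headgroup),
    )
    base = np.asarray(coords, dtype=float)
    frames = np.repeat(base[None, :, :], n_frames, axis=0)
    if frame_jitter > 0 and n_frames > 1:
        frames[1:] += rng.normal(0.0, frame_jitter, size=frames[1:].shape)
    box = np.tile(np.array([box_l, box_l, 110.0]), (n_frames, 1))
    return topo, TrajectoryFrameSet(coords=frames, box=box)
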