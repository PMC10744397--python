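"""Self-contained validation benchmarks with synthetic ground truth.

Each function runs one property of the pipeline end to end under fixed
study conditions — boosted sampling from a known potential, planted torsion
clusters, prescribed tilt laws — and reports measured quantities next to
their analytic expectations.  They power both the test suite and the
``scripts/acceptance.py`` reproduction script.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from .amd_model import AmdParams, ThermoParams, boost_energy
from .io_formats import (
    BoostRecordSeries,
    TrajectoryFrameSet,
    parse_amd_log,
    read_frames,
    write_amd_log,
    write_frame_table,
)
from .dihedral_pca import cluster_top_pcs, dpca_fit
from .membrane_observables import ChainVectorSet, insertion_pmf, scd_profile
from .membrane_observables import ReactionCoordinateSeries
from .reweighting import (
    frame_weights,
    maclaurin_weights,
    pmf_2d,
    pmf_from_histogram,
    weighted_histogram,
)
from .synthetic_data import (
    SamplerSpec,
    ToyPotentialSpec,
    gen_oriented_vectors,
    gen_torsion_clusters,
    gen_toy_membrane_system,
    sample_boosted,
)

MAGIC_ANGLE_DEG = float(np.degrees(np.arccos(1.0 / np.sqrt(3.0))))  # 54.7356


def reweighting_recovery(seed: int, n_samples: int = 200_000) -> dict:
    """Boosted double-well sampling -> exponential reweighting -> PMF.

    A tilted 1D double well (barrier 3 kcal/mol, unique minimum) is sampled
    on its boosted surface (E = min V + 4 kcal/mol, alpha = 2) at 300 K and
    the canonical profile is recovered with exponential weights over 40
    bins.  Reports the largest |PMF - analytic| over bins with >= 200 raw
    counts and the bin offset between the recovered and analytic minima.
    """
    thermo = ThermoParams(temperature=300.0)
    pot = ToyPotentialSpec(
        "double_well_1d", {"barrier": 3.0, "half_sep": 1.0, "tilt": -0.5},
        bounds=(-2.0, 2.0),
    )
    amd = AmdParams(mode=1, e_total=pot.min_energy() + 4.0, alpha_total=2.0)
    xs, boost = sample_boosted(
        pot, SamplerSpec(n_samples=n_samples, seed=seed, kT=thermo.kT, amd=amd))
    edges = np.linspace(-2.0, 2.0, 41)
    w = frame_weights(boost, thermo, method="exponential")
    fes = pmf_from_histogram(weighted_histogram(xs, w, edges), thermo)
    p_true = pot.boltzmann_bin_probabilities(edges, thermo.kT)
    pmf_true = -thermo.kT * np.log(p_true / p_true.max())
    reliable = fes.counts >= 200
    err = np.abs(fes.pmf - pmf_true)
    argmin_est = int(np.nanargmin(np.where(fes.mask, np.nan, fes.pmf)))
    argmin_true = int(np.argmin(pmf_true))
    return {
        "n": n_samples,
        "max_abs_error_kcal_mol": float(np.nanmax(err[reliable])),
        "n_reliable_bins": int(reliable.sum()),
        "argmin_bin_offset": abs(argmin_est - argmin_true),
    }


def maclaurin_fidelity(seed: int, n: int = 10_000) -> dict:
    """Order-10 Maclaurin weights vs the exponential on dV/kT in [0, 3]."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 3.0, n)
    exact = np.exp(x)
    errs = [
        float(np.max(np.abs(maclaurin_weights(x, k) - exact) / exact))
        for k in range(1, 11)
    ]
    return {
        "n": n,
        "max_rel_error_order10_pct": errs[-1] * 100.0,
        "error_monotone_in_order": bool(
            all(b <= a + 1e-15 for a, b in zip(errs, errs[1:]))),
    }


def scd_closed_forms(seed: int, n_delta: int = 1000, n_iso: int = 100_000) -> dict:
    """|S_CD| of delta-tilt vector sets vs closed forms, plus isotropic."""
    out = {"n": n_iso}
    for key, theta in (
        ("delta_0deg", 0.0),
        ("delta_30deg", 30.0),
        ("magic_angle", MAGIC_ANGLE_DEG),
        ("delta_90deg", 90.0),
    ):
        v, _ = gen_oriented_vectors(n_delta, ("delta", theta), seed=seed)
        profile = scd_profile(ChainVectorSet.from_vectors(v))
        out[key] = float(profile.s_cd[0])
        out[f"{key}_expected"] = float(
            abs(0.5 * (3.0 * np.cos(np.radians(theta)) ** 2 - 1.0)))
    v, _ = gen_oriented_vectors(n_iso, ("isotropic",), seed=seed + 1)
    out["isotropic"] = float(scd_profile(ChainVectorSet.from_vectors(v)).s_cd[0])
    return out


def dpca_cluster_recovery(seed: int, n_frames: int = 5000) -> dict:
    """Two planted von Mises clusters -> dPCA -> grid clustering -> 2D PMF.

    Weights 0.7/0.3, kappa 20, 120-degree mean separation, 18 residues.
    Reports the recovered cluster count, label agreement with the planted
    labels (best cluster-to-truth mapping), and whether the reweighted
    (unit-weight) PMF over (PC1, PC2) has its global minimum in the
    majority cluster's basin.
    """
    thermo = ThermoParams(temperature=300.0)
    series, labels = gen_torsion_clusters(
        n_frames, 18, [0.7, 0.3], [[-60.0, -60.0], [60.0, 60.0]], [20.0, 20.0],
        seed=seed)
    model = dpca_fit(series)
    clusters = cluster_top_pcs(model, n_components=3)
    mapping = {}
    for r in range(clusters.n_clusters):
        members = clusters.labels == r
        if members.any():
            mapping[r] = int(np.bincount(labels[members]).argmax())
    agreement = float(np.mean(
        [mapping.get(int(l), -9) == int(t)
         for l, t in zip(clusters.labels, labels)]))

    pc1, pc2 = model.projections[:, 0], model.projections[:, 1]
    ex = np.linspace(pc1.min(), np.nextafter(pc1.max(), np.inf), 51)
    ey = np.linspace(pc2.min(), np.nextafter(pc2.max(), np.inf), 51)
    fes = pmf_2d(pc1, pc2, np.ones(n_frames), ex, ey, thermo)
    gx, gy = fes.argmin_center()
    cents = [
        np.array([pc1[labels == c].mean(), pc2[labels == c].mean()])
        for c in (0, 1)
    ]
    d_major = float(np.hypot(gx - cents[0][0], gy - cents[0][1]))
    d_minor = float(np.hypot(gx - cents[1][0], gy - cents[1][1]))
    return {
        "n": n_frames,
        "n_clusters": int(clusters.n_clusters),
        "label_agreement_pct": agreement * 100.0,
        "pmf_min_in_majority_basin": bool(d_major < d_minor),
    }


def insertion_pmf_geometry(seed: int, n_samples: int = 30_000) -> dict:
    """Toy insertion coordinate with its minimum planted at 28 angstrom.

    Samples a harmonic z-potential centred at 28 A (unboosted, and boosted
    with E = 2 kcal/mol above the minimum then exponentially reweighted) and
    reports how far the PMF argmin bin centre lands from 28 A (1 A bins).
    """
    thermo = ThermoParams(temperature=300.0)
    pot = ToyPotentialSpec("harmonic", {"k": 0.5, "center": 28.0},
                           bounds=(20.0, 36.0))
    out = {"n": n_samples}
    for tag, amd in (
        ("unboosted", None),
        ("reweighted", AmdParams(mode=1, e_total=2.0, alpha_total=1.0)),
    ):
        xs, boost = sample_boosted(
            pot, SamplerSpec(n_samples=n_samples, seed=seed, kT=thermo.kT,
                             amd=amd))
        series = ReactionCoordinateSeries(values=xs)
        fes = insertion_pmf(series, boost, thermo, method="exponential",
                            bin_width=1.0)
        out[f"argmin_error_{tag}_angstrom"] = float(
            abs(fes.argmin_center() - 28.0))
    return out


def boost_invariant_violations(seed: int, n_grid: int = 10_000) -> dict:
    """Count violations of the boost-potential invariants on a random grid.

    Checks, over ~10^4 (V, E, alpha) triples: dV = 0 iff V >= E;
    0 <= dV <= E - V below threshold; dV non-increasing and V + dV
    non-decreasing in V.
    """
    rng = np.random.default_rng(seed)
    v = rng.uniform(-100.0, 100.0, n_grid)
    e = rng.uniform(-50.0, 50.0, n_grid)
    alpha = rng.uniform(0.01, 50.0, n_grid)
    violations = 0
    for vi, ei, ai in zip(v, e, alpha):
        dv = boost_energy(vi, ei, ai)
        if vi >= ei:
            violations += dv != 0.0
        else:
            violations += not (0.0 < dv if vi < ei else True)
            violations += not (dv <= ei - vi)
    # monotonicity on a dense V-line per a few (E, alpha) pairs
    vline = np.linspace(-100.0, 100.0, 2001)
    for ei, ai in zip(e[:20], alpha[:20]):
        dv = boost_energy(vline, ei, ai)
        violations += int(np.any(np.diff(dv) > 1e-12))
        violations += int(np.any(np.diff(vline + dv) < -1e-12))
    return {"n": n_grid, "violations": int(violations)}


def format_roundtrip_check(seed: int, n_records: int = 200) -> dict:
    """Lossless write -> read for amd.log and the frame table; rejection of
    malformed inputs (duplicate serials are covered by topology tests)."""
    rng = np.random.default_rng(seed)
    series = BoostRecordSeries(
        step=np.cumsum(rng.integers(1, 1000, n_records)),
        v_total=rng.normal(-1000, 50, n_records),
        v_dih=rng.normal(180, 10, n_records),
        dv_total=rng.uniform(0, 20, n_records),
        dv_dih=rng.uniform(0, 5, n_records),
    )
    from .io_formats import read_topology, write_topology

    topo, _ = gen_toy_membrane_system(n_lipids_per_leaflet=2,
                                      peptide_residues=["ALA"], seed=seed)
    frames = TrajectoryFrameSet(
        coords=rng.normal(size=(4, topo.n_atoms, 3)) * 30,
        box=np.tile([40.0, 40.0, 110.0], (4, 1)),
    )
    with tempfile.TemporaryDirectory() as td:
        td = Path(td)
        write_amd_log(series, td / "amd.log")
        log_exact = parse_amd_log(td / "amd.log") == series
        write_frame_table(frames, td / "frames.dat")
        back = read_frames(td / "frames.dat", topo)
        table_exact = np.array_equal(back.coords, frames.coords)

        rejects = 0
        (td / "bad1.log").write_text("1000 0 0 x 0\n")
        try:
            parse_amd_log(td / "bad1.log")
        except ValueError:
            rejects += 1
        (td / "bad2.log").write_text("2000 0 0 0 0\n1000 0 0 0 0\n")
        try:
            parse_amd_log(td / "bad2.log")
        except ValueError:
            rejects += 1
        (td / "bad3.dat").write_text("frame 0\n0 0 0\n")
        try:
            read_frames(td / "bad3.dat", topo)
        except ValueError:
            rejects += 1
    return {
        "n": n_records,
        "amdlog_roundtrip_exact": bool(log_exact),
        "frame_table_roundtrip_exact": bool(table_exact),
        "malformed_inputs_rejected": int(rejects),
    }
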