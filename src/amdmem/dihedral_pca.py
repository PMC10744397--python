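"""Dihedral principal component analysis and conformational clustering.

Backbone phi/psi torsions are computed per residue, mapped to (cos, sin)
pairs so the +/-180 degree seam is harmless, and PCA is performed on the
covariance of that feature space.  The most populated conformational
clusters are extracted from a density grid over the top principal
components: dense grid cells are joined into basins by connected-component
labelling, frames in sparse cells are attached to an adjacent basin or
marked noise, and basins are ranked by population.  Each cluster reports a
representative frame (the member nearest the basin centroid) mirroring the
representative-structure output of classical trajectory-clustering tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)


@dataclass
class DihedralSeries:
    """Per-frame, per-residue (phi, psi) in degrees within (-180, 180].

    Angles a residue cannot define (chain termini, missing backbone atoms)
    are NaN and flagged absent — never zero-filled.
    """

    angles: np.ndarray  # (n_frames, n_residues, 2), degrees, NaN = absent
    residue_labels: list

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 3 or self.angles.shape[2] != 2:
            raise ValueError("angles must have shape (frames, residues, 2)")
        finite = self.angles[np.isfinite(self.angles)]
        if finite.size and (np.any(finite <= -180.0) or np.any(finite > 180.0)):
            raise ValueError("angles must lie in (-180, 180] degrees")

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    @property
    def n_residues(self) -> int:
        return self.angles.shape[1]

    @property
    def absent(self) -> np.ndarray:
        """(residues, 2) bool: angle undefined in every frame."""
        return np.all(np.isnan(self.angles), axis=0)


@dataclass
class PCModel:
    """dPCA eigenstructure over the sin/cos feature space."""

    mean: np.ndarray  # feature mean (n_features,)
    eigenvalues: np.ndarray  # descending, >= 0
    eigenvectors: np.ndarray  # columns, orthonormal (n_features, n_features)
    projections: np.ndarray  # (n_frames, n_features) centered features @ eigvecs
    feature_angles: np.ndarray  # (n_features,) index of the source angle column

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


@dataclass
class ClusterSet:
    """Most-populated conformational clusters in PC space.

    ``labels`` gives each frame's cluster (0 = most populated) or -1 for
    noise; ``populations`` are descending member counts; ``representatives``
    are frame indices, one per cluster, each carrying its own cluster label.
    """

    labels: np.ndarray  # (n_frames,)
    populations: np.ndarray  # (n_clusters,)
    representatives: np.ndarray  # (n_clusters,)

    @property
    def n_clusters(self) -> int:
        return len(self.populations)


def wrap_degrees(angle) -> np.ndarray:
    """Map any angle in degrees into (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -np.mod(-a + 180.0, 360.0) + 180.0  # lands in (-180, 180]
    return wrapped


def dihedral_angle(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral (degrees) of p0-p1-p2-p3, IUPAC convention.

    Right-handed sign, cis (eclipsed) = 0.  Vectorised over leading axes.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    b2 = p3 - p2
    # components of the outer bonds perpendicular to the central bond
    v = b0 - np.sum(b0 * b1, axis=-1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=-1, keepdims=True) * b1
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    return wrap_degrees(ang)


def compute_phi_psi(traj, topo) -> DihedralSeries:
    """Backbone phi/psi series for all peptide residues of the topology.

    phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1).
    Residues missing a required backbone atom (including chain termini and
    the C-terminal amino-alcohol, which has no following N) contribute NaN
    for that angle, with a logged warning for genuinely missing atoms.
    """
    pep = topo.select(molecule_class="peptide")
    if pep.size == 0:
        raise ValueError("topology contains no peptide residues")
    keys = [k for k in topo.residue_keys()
            if topo.molecule_class[topo.residue_atoms(*k)[0]] == "peptide"]

    def backbone(key, name):
        idx = topo.residue_atoms(*key)
        hit = idx[topo.name[idx] == name]
        return int(hit[0]) if hit.size else None

    n_res = len(keys)
    atoms = {(i, nm): backbone(k, nm) for i, k in enumerate(keys) for nm in ("N", "CA", "C")}
    for (i, nm), a in atoms.items():
        if a is None:
            logger.warning("residue %s missing backbone atom %s; angles flagged absent",
                           keys[i], nm)

    angles = np.full((traj.n_frames, n_res, 2), np.nan)
    X = traj.coords
    for i in range(n_res):
        n_i, ca_i, c_i = atoms[(i, "N")], atoms[(i, "CA")], atoms[(i, "C")]
        c_prev = atoms[(i - 1, "C")] if i > 0 else None
        n_next = atoms[(i + 1, "N")] if i + 1 < n_res else None
        if None not in (c_prev, n_i, ca_i, c_i):
            angles[:, i, 0] = dihedral_angle(
                X[:, c_prev], X[:, n_i], X[:, ca_i], X[:, c_i])
        if None not in (n_i, ca_i, c_i, n_next):
            angles[:, i, 1] = dihedral_angle(
                X[:, n_i], X[:, ca_i], X[:, c_i], X[:, n_next])
    labels = [f"{topo.resname[topo.residue_atoms(*k)[0]]}{k[1]}" for k in keys]
    return DihedralSeries(angles=angles, residue_labels=labels)


def _features(series: DihedralSeries):
    """(cos, sin) feature matrix over defined angles; radians internally."""
    flat = series.angles.reshape(series.n_frames, -1)  # (F, 2R)
    keep = ~np.any(np.isnan(flat), axis=0)  # exclude absent angles column-wise
    if not np.any(keep):
        raise ValueError("no defined dihedral angles in series")
    rad = np.radians(flat[:, keep])
    feats = np.empty((series.n_frames, 2 * rad.shape[1]))
    feats[:, 0::2] = np.cos(rad)
    feats[:, 1::2] = np.sin(rad)
    angle_idx = np.repeat(np.where(keep)[0], 2)
    return feats, angle_idx


def dpca_fit(series: DihedralSeries) -> PCModel:
    """Dihedral PCA: sin/cos features, covariance eigendecomposition.

    Eigenvalues are returned in descending order with orthonormal
    eigenvectors; projections are the centered features on all components.
    """
    if series.n_frames < 2:
        raise ValueError("dPCA requires at least 2 frames")
    feats, angle_idx = _features(series)
    mean = feats.mean(axis=0)
    centered = feats - mean
    cov = centered.T @ centered / (series.n_frames - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    return PCModel(
        mean=mean,
        eigenvalues=evals,
        eigenvectors=evecs,
        projections=centered @ evecs,
        feature_angles=angle_idx,
    )


def cluster_top_pcs(
    model: PCModel,
    n_components: int = 3,
    grid_bins: int | None = None,
    min_density: float = 0.002,
) -> ClusterSet:
    """Density-grid clustering over the top principal components.

    A ``grid_bins``-per-axis histogram over the top ``n_components``
    projections is thresholded at ``min_density`` (fraction of frames) to
    find dense cells; connected components of dense cells (full diagonal
    neighbourhood) are basins.  Frames in sparse cells join the nearest
    basin within one cell diagonal, else become noise (-1).  Clusters are
    relabelled by descending population.

    ``grid_bins=None`` picks the resolution from the frame count so an
    occupied cell can plausibly clear the density threshold (about 25
    frames per cell along each axis, clipped to [4, 32]); a fixed grid that
    is too fine for the sample size shatters genuine basins into noise.
    """
    if n_components > model.n_components:
        raise ValueError(
            f"requested {n_components} components, model has {model.n_components}"
        )
    pts = model.projections[:, :n_components]
    n_frames = len(pts)
    if grid_bins is None:
        grid_bins = int(np.clip(
            round((n_frames / 25.0) ** (1.0 / n_components)), 4, 32))
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    # cell index per frame, clipped so the max lands in the last cell
    cell = np.clip(((pts - lo) / span * grid_bins).astype(int), 0, grid_bins - 1)
    shape = (grid_bins,) * n_components
    counts = np.zeros(shape, dtype=int)
    np.add.at(counts, tuple(cell.T), 1)

    threshold = max(1, int(np.ceil(min_density * n_frames)))
    dense = counts >= threshold
    if not np.any(dense):
        return ClusterSet(
            labels=np.full(n_frames, -1, dtype=int),
            populations=np.zeros(0, dtype=int),
            representatives=np.zeros(0, dtype=int),
        )
    structure = np.ones((3,) * n_components, dtype=bool)  # diagonal adjacency
    basin_of_cell, n_basins = ndimage.label(dense, structure=structure)

    labels = basin_of_cell[tuple(cell.T)] - 1  # -1 where cell not dense
    sparse = labels < 0
    if np.any(sparse):
        # attach sparse-cell frames to an adjacent basin (one cell diagonal)
        dense_cells = np.argwhere(dense)
        dense_basins = basin_of_cell[dense] - 1
        for f in np.where(sparse)[0]:
            d = np.max(np.abs(dense_cells - cell[f]), axis=1)
            near = d <= 1
            if np.any(near):
                # nearest dense cell by Euclidean cell distance
                dist2 = np.sum((dense_cells[near] - cell[f]) ** 2, axis=1)
                labels[f] = dense_basins[near][np.argmin(dist2)]

    # rank basins by population, relabel descending
    pops = np.array([np.sum(labels == b) for b in range(n_basins)])
    order = np.argsort(pops)[::-1]
    keep = order[pops[order] > 0]
    remap = {int(b): r for r, b in enumerate(keep)}
    new_labels = np.array([remap.get(int(l), -1) for l in labels], dtype=int)

    reps = np.empty(len(keep), dtype=int)
    for r in range(len(keep)):
        members = np.where(new_labels == r)[0]
        centroid = pts[members].mean(axis=0)
        reps[r] = members[np.argmin(np.sum((pts[members] - centroid) ** 2, axis=1))]
    return ClusterSet(
        labels=new_labels,
        populations=pops[keep],
        representatives=reps,
    )
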