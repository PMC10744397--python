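"""Membrane-facing observables: |S_CD| profiles, insertion distance, contacts.

The deuterium order parameter of acyl carbon i is

    |S_CD| = | 0.5 * <3 cos^2(theta) - 1> |

with theta the angle between the bilayer normal and the C-H (standing in
for C-D) bond vector, averaged over lipids, frames and the hydrogens of the
carbon before taking the absolute value.  |S_CD| = 1 for bonds along the
normal, 0.5 perpendicular, 0 at the magic angle or for isotropic tumbling.

The peptide-insertion reaction coordinate is the absolute difference of
mass-weighted centre-of-mass z between the peptide and the membrane, after
wrapping the peptide to the periodic image nearest the membrane along z.
Contact fractions count, per peptide residue, the fraction of frames in
which any side-chain heavy atom lies within a cutoff of any lipid headgroup
heavy atom (minimum-image along periodic axes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .amd_model import ThermoParams
from .io_formats import BoostRecordSeries, Topology, TrajectoryFrameSet
from .reweighting import FreeEnergySurface, frame_weights, pmf_1d

logger = logging.getLogger(__name__)

BACKBONE_NAMES = {"N", "CA", "C", "O", "H", "HA", "OXT"}


@dataclass
class ChainVectorSet:
    """Unit C-H bond vectors tagged by acyl chain and carbon index.

    Carbon indices count from the carbonyl carbon = 1 (which bears no H),
    so the first entry of a profile is carbon 2.
    """

    vectors: np.ndarray  # (n, 3), unit length
    carbon: np.ndarray  # (n,) int
    chain: np.ndarray  # (n,) "sn1" | "sn2"
    normal: np.ndarray  # (3,) unit bilayer normal

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        norms = np.linalg.norm(self.vectors, axis=-1)
        if self.vectors.size and np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("chain vectors must be unit length (tol 1e-9)")
        self.carbon = np.asarray(self.carbon, dtype=int)
        self.chain = np.asarray(self.chain, dtype="U4")
        self.normal = np.asarray(self.normal, dtype=float)
        self.normal = self.normal / np.linalg.norm(self.normal)

    def __len__(self) -> int:
        return len(self.vectors)

    @classmethod
    def from_vectors(cls, vectors, normal=(0.0, 0.0, 1.0), carbon: int = 2,
                     chain: str = "sn1") -> "ChainVectorSet":
        """Wrap a bare vector array as a single-carbon single-chain set."""
        n = len(vectors)
        return cls(
            vectors=vectors,
            carbon=np.full(n, carbon),
            chain=np.full(n, chain),
            normal=np.asarray(normal, dtype=float),
        )


@dataclass
class OrderParameterProfile:
    """|S_CD| per acyl carbon per chain with sample counts."""

    chain: np.ndarray  # (k,)
    carbon: np.ndarray  # (k,)
    s_cd: np.ndarray  # (k,) in [0, 1]
    n: np.ndarray  # (k,) vectors averaged per entry

    def value(self, chain: str, carbon: int) -> float:
        hit = np.where((self.chain == chain) & (self.carbon == carbon))[0]
        if hit.size == 0:
            raise KeyError(f"no entry for chain {chain!r} carbon {carbon}")
        return float(self.s_cd[hit[0]])


@dataclass
class ReactionCoordinateSeries:
    """Per-frame scalar reaction coordinate (angstrom)."""

    values: np.ndarray
    name: str = "com_z_distance"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ContactTable:
    """Per-residue headgroup contact fractions at a fixed cutoff."""

    residue_labels: list
    fractions: np.ndarray  # in [0, 1]
    cutoff: float  # angstrom
    headgroup_set: str = "flagged"

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.size and (
            np.any(self.fractions < 0) or np.any(self.fractions > 1)
        ):
            raise ValueError("contact fractions must lie in [0, 1]")


def chain_vectors(
    traj: TrajectoryFrameSet,
    topo: Topology,
    naming_map: dict,
    normal=(0.0, 0.0, 1.0),
) -> ChainVectorSet:
    """Collect normalized C-H bond vectors for every lipid acyl carbon.

    ``naming_map`` maps chain tag -> {carbon_atom_name: [hydrogen names]},
    e.g. ``{"sn1": {"C2": ["H2A", "H2B"], ...}}``; carbon index is parsed
    from the trailing digits of the carbon atom name.  Carbons with no
    resolvable hydrogen are omitted with a logged warning.
    """
    vectors, carbons, chains_out = [], [], []
    lipid_residues = [
        key for key in topo.residue_keys()
        if topo.molecule_class[topo.residue_atoms(*key)[0]] == "lipid"
    ]
    for chain_tag, carbon_map in naming_map.items():
        for c_name, h_names in carbon_map.items():
            digits = "".join(ch for ch in c_name if ch.isdigit())
            c_index = int(digits) if digits else -1
            found_any = False
            for key in lipid_residues:
                idx = topo.residue_atoms(*key)
                c_hit = idx[topo.name[idx] == c_name]
                if c_hit.size == 0:
                    continue
                for h_name in h_names:
                    h_hit = idx[topo.name[idx] == h_name]
                    if h_hit.size == 0:
                        continue
                    found_any = True
                    d = traj.coords[:, h_hit[0]] - traj.coords[:, c_hit[0]]
                    d = d / np.linalg.norm(d, axis=-1, keepdims=True)
                    vectors.append(d)
                    carbons.append(np.full(traj.n_frames, c_index))
                    chains_out.append(np.full(traj.n_frames, chain_tag))
            if not found_any:
                logger.warning(
                    "carbon %s (%s): no resolvable hydrogens; omitted",
                    c_name, chain_tag,
                )
    if not vectors:
        return ChainVectorSet(
            vectors=np.zeros((0, 3)), carbon=np.zeros(0, dtype=int),
            chain=np.zeros(0, dtype="U4"), normal=np.asarray(normal, dtype=float),
        )
    return ChainVectorSet(
        vectors=np.concatenate(vectors),
        carbon=np.concatenate(carbons),
        chain=np.concatenate(chains_out),
        normal=np.asarray(normal, dtype=float),
    )


def scd_profile(vectors: ChainVectorSet) -> OrderParameterProfile:
    """|S_CD| per (chain, carbon): |0.5 mean(3 cos^2 theta - 1)| over all
    lipids, frames and hydrogens — the mean is taken before the absolute
    value."""
    if len(vectors) == 0:
        raise ValueError("empty chain-vector set")
    cos_t = vectors.vectors @ vectors.normal
    term = 3.0 * cos_t**2 - 1.0
    chains, carbons, scds, ns = [], [], [], []
    for chain_tag in np.unique(vectors.chain):
        sel_chain = vectors.chain == chain_tag
        for c in np.unique(vectors.carbon[sel_chain]):
            sel = sel_chain & (vectors.carbon == c)
            chains.append(chain_tag)
            carbons.append(int(c))
            scds.append(abs(0.5 * term[sel].mean()))
            ns.append(int(sel.sum()))
    return OrderParameterProfile(
        chain=np.array(chains), carbon=np.array(carbons),
        s_cd=np.array(scds), n=np.array(ns),
    )


def _com_z(coords_z: np.ndarray, masses: np.ndarray) -> np.ndarray:
    return coords_z @ masses / masses.sum()


def com_z_distance(
    traj: TrajectoryFrameSet,
    topo: Topology,
    peptide_sel=None,
    membrane_sel=None,
) -> ReactionCoordinateSeries:
    """|z_COM(peptide) - z_COM(membrane)| per frame (angstrom).

    Selections default to molecule classes ``peptide`` and ``lipid``.  When
    a box is present, each peptide atom is first wrapped to the periodic
    image nearest the membrane COM along z.
    """
    if peptide_sel is None:
        peptide_sel = topo.select(molecule_class="peptide")
    if membrane_sel is None:
        membrane_sel = topo.select(molecule_class="lipid")
    peptide_sel = np.asarray(peptide_sel)
    membrane_sel = np.asarray(membrane_sel)
    if peptide_sel.size == 0 or membrane_sel.size == 0:
        raise ValueError("empty peptide or membrane selection")
    m_pep = topo.mass[peptide_sel]
    m_mem = topo.mass[membrane_sel]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        z_mem = _com_z(traj.coords[f, membrane_sel, 2], m_mem)
        z_pep_atoms = traj.coords[f, peptide_sel, 2].copy()
        if traj.box is not None:
            lz = traj.box[f, 2]
            z_pep_atoms -= lz * np.round((z_pep_atoms - z_mem) / lz)
        out[f] = abs(_com_z(z_pep_atoms, m_pep) - z_mem)
    return ReactionCoordinateSeries(values=out, name="com_z_distance")


def insertion_pmf(
    series: ReactionCoordinateSeries,
    boost: BoostRecordSeries,
    thermo: ThermoParams,
    method: str = "exponential",
    order: int = 10,
    edges=None,
    bin_width: float = 1.0,
) -> FreeEnergySurface:
    """Reweighted PMF over the peptide-membrane distance (kcal/mol).

    ``edges`` defaults to ``bin_width``-angstrom bins spanning the observed
    range.  The boost series must align frame-for-frame with the distances.
    """
    if len(series) != len(boost):
        raise ValueError(
            f"distance series ({len(series)}) and boost series ({len(boost)}) "
            "must align frame-for-frame"
        )
    if edges is None:
        lo = np.floor(series.values.min() / bin_width) * bin_width
        hi = np.ceil(series.values.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
        edges = np.arange(lo, hi + bin_width / 2, bin_width)
        # half-open bins: pad so the max value is included
        if series.values.max() >= edges[-1]:
            edges = np.append(edges, edges[-1] + bin_width)
    w = frame_weights(boost, thermo, method=method, order=order)
    return pmf_1d(
        series.values, w, edges, thermo,
        coordinate=series.name, bin_width=float(bin_width),
        method=w.method,
    )


def headgroup_contact_fractions(
    traj: TrajectoryFrameSet,
    topo: Topology,
    cutoff: float = 4.5,
) -> ContactTable:
    """Per-residue fraction of frames with a side-chain/headgroup contact.

    A residue is "in contact" in a frame when any of its non-backbone heavy
    atoms lies within ``cutoff`` angstrom of any flagged lipid headgroup
    heavy atom, using the minimum-image convention along periodic axes.
    """
    hg = topo.select(headgroup=True)
    hg = hg[topo.element[hg] != "H"]
    if hg.size == 0:
        raise ValueError("no lipid headgroup atoms flagged in topology")
    pep_keys = [
        key for key in topo.residue_keys()
        if topo.molecule_class[topo.residue_atoms(*key)[0]] == "peptide"
    ]
    if not pep_keys:
        raise ValueError("no peptide residues in topology")
    labels, fracs = [], []
    for key in pep_keys:
        idx = topo.residue_atoms(*key)
        side = idx[
            (~np.isin(topo.name[idx], list(BACKBONE_NAMES)))
            & (topo.element[idx] != "H")
        ]
        labels.append(f"{topo.resname[idx[0]]}{key[1]}")
        if side.size == 0:
            fracs.append(0.0)
            continue
        hits = 0
        for f in range(traj.n_frames):
            d = traj.coords[f, side][:, None, :] - traj.coords[f, hg][None, :, :]
            if traj.box is not None:
                d -= traj.box[f] * np.round(d / traj.box[f])
            if np.any(np.sum(d * d, axis=-1) < cutoff * cutoff):
                hits += 1
        fracs.append(hits / traj.n_frames)
    return ContactTable(
        residue_labels=labels,
        fractions=np.array(fracs),
        cutoff=float(cutoff),
    )
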