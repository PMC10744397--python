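"""On-disk formats: topology PDB, trajectory frames, amd.log, result tables.

PDB reading/writing is delegated to biotite; the boost log ("amd.log"
dialect) and the whitespace frame table are small line-oriented formats
defined here and written losslessly (``%.17g``) so write -> read is an
identity on every numeric field.

amd.log dialect: lines starting with ``#`` are comments; data lines carry
five whitespace-separated columns::

    step  V_total  V_dihedral  dV_total  dV_dihedral

all energies in kcal/mol.  Eight-column Amber-style logs can be ingested by
passing ``column_map`` naming which columns carry each field.

Frame table: ``# ...`` comments; each frame starts with a header line
``frame <index> [box_x box_y box_z]`` followed by one ``x y z`` line per atom
(angstrom).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.info as struc_info
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

#: residue-name -> molecule class lookup (config-extensible via read_topology)
DEFAULT_RESIDUE_CLASSES = {
    # standard amino acids
    **{
        name: "peptide"
        for name in (
            "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO "
            "SER THR TRP TYR VAL"
        ).split()
    },
    # peptaibol specials: Aib, D-isovaline, phenylalaninol, acetyl/amide caps
    "AIB": "peptide",
    "DIV": "peptide",
    "IVA": "peptide",
    "HYP": "peptide",
    "FOL": "peptide",
    "PHL": "peptide",
    "ACE": "peptide",
    "NME": "peptide",
    # lipids (full names and the PE/PG/OL fragments of split residues)
    "DOPE": "lipid",
    "DOPG": "lipid",
    "POPE": "lipid",
    "POPG": "lipid",
    "PE": "lipid",
    "PG": "lipid",
    "PA": "lipid",
    "PC": "lipid",
    "OL": "lipid",
    # solvent
    "WAT": "solvent",
    "HOH": "solvent",
    "TIP3": "solvent",
    "SOL": "solvent",
    # ions
    "K+": "ion",
    "K": "ion",
    "NA+": "ion",
    "NA": "ion",
    "CL-": "ion",
    "CL": "ion",
}

#: per-lipid-residue atom names flagged as headgroup atoms
DEFAULT_HEADGROUP_ATOMS = {
    "PE": {"P", "O11", "O12", "O13", "O14", "N31", "C31", "C32", "N"},
    "PG": {"P", "O11", "O12", "O13", "O14", "C31", "C32", "C33", "O35", "O36"},
    "DOPE": {"P", "O11", "O12", "O13", "O14", "N31", "C31", "C32", "N"},
    "DOPG": {"P", "O11", "O12", "O13", "O14", "C31", "C32", "C33", "O35", "O36"},
}

_FLOAT_FMT = "%.17g"


@dataclass
class Topology:
    """Static description of the system: atoms, residues, molecule classes.

    All fields are per-atom numpy arrays of equal length.  ``molecule_class``
    is one of ``peptide | lipid | solvent | ion | unknown``, assigned per
    residue; ``headgroup`` flags lipid headgroup atoms.
    """

    serial: np.ndarray
    name: np.ndarray
    resname: np.ndarray
    resid: np.ndarray
    chain: np.ndarray
    element: np.ndarray
    mass: np.ndarray
    molecule_class: np.ndarray
    headgroup: np.ndarray

    def __post_init__(self):
        self.serial = np.asarray(self.serial, dtype=int)
        if self.serial.size and np.any(np.diff(self.serial) <= 0):
            dup = self.serial[np.where(np.diff(self.serial) <= 0)[0]]
            raise ValueError(
                f"atom serials must be unique and strictly increasing "
                f"(violation after serial {dup[0]})"
            )
        self.mass = np.asarray(self.mass, dtype=float)
        if np.any(self.mass <= 0):
            raise ValueError("all atom masses must be strictly positive")
        for attr in ("name", "resname", "chain", "element", "molecule_class"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype="U8"))
        self.resid = np.asarray(self.resid, dtype=int)
        self.headgroup = np.asarray(self.headgroup, dtype=bool)

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    def residue_keys(self) -> list[tuple[str, int]]:
        """(chain, resid) pairs in order of first appearance."""
        seen, keys = set(), []
        for ch, ri in zip(self.chain, self.resid):
            if (ch, ri) not in seen:
                seen.add((ch, ri))
                keys.append((ch, ri))
        return keys

    def residue_atoms(self, chain: str, resid: int) -> np.ndarray:
        return np.where((self.chain == chain) & (self.resid == resid))[0]

    def select(
        self,
        molecule_class: str | None = None,
        resname: str | None = None,
        name: str | None = None,
        headgroup: bool | None = None,
    ) -> np.ndarray:
        """Atom indices matching all given criteria."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if molecule_class is not None:
            mask &= self.molecule_class == molecule_class
        if resname is not None:
            mask &= self.resname == resname
        if name is not None:
            mask &= self.name == name
        if headgroup is not None:
            mask &= self.headgroup == headgroup
        return np.where(mask)[0]


@dataclass
class TrajectoryFrameSet:
    """Per-frame Cartesian coordinates (angstrom) and optional box/time."""

    coords: np.ndarray  # (n_frames, n_atoms, 3)
    box: np.ndarray | None = None  # (n_frames, 3) orthorhombic lengths
    time_ns: np.ndarray | None = None  # (n_frames,)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(
                f"coords must have shape (frames, atoms, 3), got {self.coords.shape}"
            )
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (self.n_frames, 3):
                raise ValueError("box must have shape (frames, 3)")
            if np.any(self.box <= 0):
                raise ValueError("box lengths must be positive")
        if self.time_ns is not None:
            self.time_ns = np.asarray(self.time_ns, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass
class BoostRecordSeries:
    """Per-frame boost bookkeeping parsed from (or destined for) amd.log.

    ``dv_total + dv_dih`` is the dV of the canonical reweighting factor
    exp(dV / k_B T); either component may be identically zero depending on
    the boost mode.
    """

    step: np.ndarray
    v_total: np.ndarray
    v_dih: np.ndarray
    dv_total: np.ndarray
    dv_dih: np.ndarray
    mode: int = 3

    def __post_init__(self):
        self.step = np.asarray(self.step, dtype=int)
        for attr in ("v_total", "v_dih", "dv_total", "dv_dih"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=float))
        if self.step.size and np.any(np.diff(self.step) <= 0):
            raise ValueError("step indices must be strictly increasing")
        if np.any(self.dv_total < 0) or np.any(self.dv_dih < 0):
            raise ValueError("boost energies must be non-negative")

    def __len__(self) -> int:
        return len(self.step)

    def __eq__(self, other) -> bool:
        if not isinstance(other, BoostRecordSeries):
            return NotImplemented
        return self.mode == other.mode and all(
            np.array_equal(getattr(self, a), getattr(other, a))
            for a in ("step", "v_total", "v_dih", "dv_total", "dv_dih")
        )

    @property
    def total_boost(self) -> np.ndarray:
        """Total applied boost per frame, dV_total + dV_dihedral (kcal/mol)."""
        return self.dv_total + self.dv_dih


def _atom_mass(element: str, name: str) -> float:
    el = element.strip()
    if not el:  # infer from the first alphabetic character of the atom name
        el = next((c for c in name if c.isalpha()), "")
    m = struc_info.mass(el.capitalize())
    if m is None or m <= 0:
        raise ValueError(f"cannot assign a mass to atom {name!r} (element {el!r})")
    return float(m)


def read_topology(
    path,
    residue_classes: dict | None = None,
    headgroup_atoms: dict | None = None,
) -> Topology:
    """Read a PDB file into a Topology.

    ``residue_classes`` extends/overrides the built-in residue-name lookup;
    unknown residue names are classed ``unknown`` with a logged warning.
    ``headgroup_atoms`` maps lipid residue names to the set of atom names
    flagged as headgroup.
    """
    classes = dict(DEFAULT_RESIDUE_CLASSES)
    if residue_classes:
        classes.update(residue_classes)
    hg_map = dict(DEFAULT_HEADGROUP_ATOMS)
    if headgroup_atoms:
        hg_map.update({k: set(v) for k, v in headgroup_atoms.items()})

    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, extra_fields=["atom_id"])
    serial = np.asarray(atoms.atom_id, dtype=int)
    if len(np.unique(serial)) != len(serial):
        dup = serial[np.where(np.diff(np.sort(serial)) == 0)[0]]
        raise ValueError(f"duplicate atom serial(s) in {path}: {sorted(set(dup))}")

    mol_class = np.empty(len(serial), dtype="U8")
    unknown = set()
    for i, rn in enumerate(atoms.res_name):
        cls = classes.get(rn.strip())
        if cls is None:
            cls = "unknown"
            unknown.add(rn.strip())
        mol_class[i] = cls
    for rn in sorted(unknown):
        logger.warning("unknown residue name %r classed 'unknown'", rn)

    headgroup = np.zeros(len(serial), dtype=bool)
    for i, (rn, an) in enumerate(zip(atoms.res_name, atoms.atom_name)):
        if mol_class[i] == "lipid" and an.strip() in hg_map.get(rn.strip(), ()):
            headgroup[i] = True

    mass = np.array(
        [_atom_mass(el, an) for el, an in zip(atoms.element, atoms.atom_name)]
    )
    return Topology(
        serial=serial,
        name=np.char.strip(atoms.atom_name),
        resname=np.char.strip(atoms.res_name),
        resid=np.asarray(atoms.res_id, dtype=int),
        chain=np.char.strip(atoms.chain_id),
        element=np.char.strip(atoms.element),
        mass=mass,
        molecule_class=mol_class,
        headgroup=headgroup,
    )


def _topology_to_atom_array(topo: Topology, coords: np.ndarray) -> struc.AtomArray:
    arr = struc.AtomArray(topo.n_atoms)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = topo.chain
    arr.res_id = topo.resid
    arr.res_name = topo.resname
    arr.atom_name = topo.name
    arr.element = topo.element
    arr.set_annotation("atom_id", topo.serial)
    return arr


def write_topology(topo: Topology, path, coords: np.ndarray | None = None) -> None:
    """Write a single-model PDB; zero coordinates unless ``coords`` given."""
    if coords is None:
        coords = np.zeros((topo.n_atoms, 3))
    pdb = PDBFile()
    pdb.set_structure(_topology_to_atom_array(topo, coords))
    pdb.write(str(path))


def read_frames(path, topo: Topology) -> TrajectoryFrameSet:
    """Read trajectory frames from a multi-model PDB or a frame table.

    The format is chosen by content: PDB if the file contains ATOM/MODEL
    records, frame table otherwise.  Every frame must carry exactly the
    topology's atom count; a mismatch is an error naming the frame index.
    """
    text = Path(path).read_text()
    if any(
        line.startswith(("ATOM", "HETATM", "MODEL"))
        for line in text.splitlines()
    ):
        return _read_frames_pdb(path, topo)
    return _read_frame_table(text, topo, path)


def _read_frames_pdb(path, topo: Topology) -> TrajectoryFrameSet:
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    coords, boxes = [], []
    for m in range(1, n_models + 1):
        atoms = pdb.get_structure(model=m)
        if atoms.array_length() != topo.n_atoms:
            raise ValueError(
                f"frame {m - 1}: atom count {atoms.array_length()} does not "
                f"match topology ({topo.n_atoms})"
            )
        coords.append(np.asarray(atoms.coord, dtype=float))
        if atoms.box is not None:
            boxes.append(np.diagonal(atoms.box))
    box = np.asarray(boxes) if len(boxes) == len(coords) and boxes else None
    return TrajectoryFrameSet(coords=np.asarray(coords), box=box)


def write_frames_pdb(frames: TrajectoryFrameSet, topo: Topology, path) -> None:
    """Write frames as a multi-model PDB (interoperability carrier)."""
    stack = struc.AtomArrayStack(frames.n_frames, topo.n_atoms)
    template = _topology_to_atom_array(topo, frames.coords[0])
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = np.asarray(frames.coords, dtype=np.float32)
    if frames.box is not None:
        stack.box = np.array([np.diag(b) for b in frames.box])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def _read_frame_table(text: str, topo: Topology, path) -> TrajectoryFrameSet:
    frames, boxes, times = [], [], []
    current: list | None = None

    def _close():
        if current is not None and len(current) != topo.n_atoms:
            raise ValueError(
                f"frame {len(frames)}: atom count {len(current)} does not "
                f"match topology ({topo.n_atoms})"
            )
        if current is not None:
            frames.append(current)

    for lineno, line in enumerate(text.splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        fields = s.split()
        if fields[0].lower() == "frame":
            _close()
            current = []
            if len(fields) >= 5:
                boxes.append([float(x) for x in fields[2:5]])
            if len(fields) >= 6:
                times.append(float(fields[5]))
        else:
            if current is None:
                raise ValueError(f"{path}:{lineno}: atom line before any frame header")
            try:
                xyz = [float(x) for x in fields[:3]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinate") from exc
            current.append(xyz)
    _close()
    n = len(frames)
    return TrajectoryFrameSet(
        coords=np.asarray(frames, dtype=float).reshape(n, topo.n_atoms, 3),
        box=np.asarray(boxes) if len(boxes) == n and n else None,
        time_ns=np.asarray(times) if len(times) == n and n else None,
    )


def write_frame_table(frames: TrajectoryFrameSet, path) -> None:
    """Write the canonical whitespace frame table (lossless round trip)."""
    with open(path, "w") as fh:
        fh.write("# amdmem frame table: 'frame <i> [bx by bz [t_ns]]' then x y z per atom (angstrom)\n")
        for i in range(frames.n_frames):
            header = f"frame {i}"
            if frames.box is not None:
                header += " " + " ".join(_FLOAT_FMT % b for b in frames.box[i])
                if frames.time_ns is not None:
                    header += " " + _FLOAT_FMT % frames.time_ns[i]
            fh.write(header + "\n")
            for xyz in frames.coords[i]:
                fh.write(" ".join(_FLOAT_FMT % c for c in xyz) + "\n")


def parse_amd_log(path, column_map: dict | None = None) -> BoostRecordSeries:
    """Parse a boost log into a BoostRecordSeries.

    Default columns: ``step V_total V_dih dV_total dV_dih``.  ``column_map``
    maps field names (``step``, ``v_total``, ``v_dih``, ``dv_total``,
    ``dv_dih``) to 0-based column indices for other layouts (e.g. 8-column
    Amber logs).  Non-numeric fields and non-monotone steps are hard errors.
    """
    cols = {"step": 0, "v_total": 1, "v_dih": 2, "dv_total": 3, "dv_dih": 4}
    if column_map:
        cols.update(column_map)
    rows = {k: [] for k in cols}
    n_data = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            fields = s.split()
            for key, idx in cols.items():
                if idx >= len(fields):
                    raise ValueError(
                        f"{path}:{lineno}: expected column {idx} for {key!r}, "
                        f"line has {len(fields)} fields"
                    )
                try:
                    rows[key].append(float(fields[idx]))
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric value {fields[idx]!r} "
                        f"in column {idx}"
                    ) from exc
            n_data += 1
    step = np.asarray(rows["step"], dtype=float)
    if step.size and np.any(np.diff(step) <= 0):
        raise ValueError(f"{path}: step indices are not strictly increasing")
    series = BoostRecordSeries(
        step=step.astype(int),
        v_total=rows["v_total"],
        v_dih=rows["v_dih"],
        dv_total=rows["dv_total"],
        dv_dih=rows["dv_dih"],
    )
    assert len(series) == n_data  # parser never silently drops lines
    return series


def write_amd_log(series: BoostRecordSeries, path) -> None:
    """Write the amd.log dialect; refuses negative boosts; lossless."""
    if np.any(series.dv_total < 0) or np.any(series.dv_dih < 0):
        raise ValueError("refusing to write negative boost energies")
    with open(path, "w") as fh:
        fh.write("# amdmem boost log: step V_total V_dih dV_total dV_dih (kcal/mol)\n")
        for i in range(len(series)):
            fh.write(
                f"{series.step[i]} "
                + " ".join(
                    _FLOAT_FMT % x
                    for x in (
                        series.v_total[i],
                        series.v_dih[i],
                        series.dv_total[i],
                        series.dv_dih[i],
                    )
                )
                + "\n"
            )


def write_table(path, columns: dict, units: dict | None = None, header_extra: str = "") -> None:
    """Write a TSV with a one-line '#' header naming columns (and units)."""
    units = units or {}
    names = [
        f"{k}[{units[k]}]" if k in units else k for k in columns
    ]
    arrays = [np.asarray(v) for v in columns.values()]
    with open(path, "w") as fh:
        head = "# " + "\t".join(names)
        if header_extra:
            head += "\t" + header_extra
        fh.write(head + "\n")
        for row in zip(*arrays):
            fh.write("\t".join(_format_cell(x) for x in row) + "\n")


def _format_cell(x) -> str:
    if isinstance(x, (bool, np.bool_)):
        return "1" if x else "0"
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if isinstance(x, (float, np.floating)):
        return _FLOAT_FMT % x
    return str(x)


def read_table(path) -> dict:
    """Read a write_table TSV back into {column_name: array} (names unit-stripped)."""
    with open(path) as fh:
        header = fh.readline().lstrip("# ").rstrip("\n")
        names = [c.split("[")[0] for c in header.split("\t")]
        data = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    cols = list(zip(*data)) if data else [[] for _ in names]
    out = {}
    for name, col in zip(names, cols):
        try:
            out[name] = np.asarray([float(x) for x in col])
        except ValueError:
            out[name] = np.asarray(col)
    return out
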