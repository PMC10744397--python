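"""End-to-end pipeline: boost parsing -> reweighting -> dPCA -> membrane stats.

``run_pipeline`` wires the stages into the standard aMD-analysis sequence
and writes every artifact plus a JSON manifest (package version, fully
materialised config, config hash, input hashes, per-stage record counts and
timings, collected warnings), so a run is self-describing and exactly
reproducible: deterministic stages re-emit byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .amd_model import ThermoParams
from .dihedral_pca import compute_phi_psi, dpca_fit, cluster_top_pcs
from .io_formats import (
    parse_amd_log,
    read_frames,
    read_topology,
    write_table,
    write_topology,
)
from .membrane_observables import (
    chain_vectors,
    com_z_distance,
    headgroup_contact_fractions,
    insertion_pmf,
    scd_profile,
)
from .reweighting import frame_weights, surface_to_table_columns

logger = logging.getLogger(__name__)

STAGES = ("boost", "reweighting", "dpca", "scd", "distance_pmf", "contacts")

#: carbon -> hydrogens naming for the toy pseudo-lipids (C2..C9, H<i>A/B)
DEFAULT_SCD_NAMING = {
    "sn1": {f"C{i}": [f"H{i}A", f"H{i}B"] for i in range(2, 10)},
}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the offending input."""

    def __init__(self, stage: str, path, cause: str):
        self.stage = stage
        self.path = str(path)
        super().__init__(f"stage {stage!r} failed on {path}: {cause}")


@dataclass
class PipelineConfig:
    """Flat run configuration; every default is materialised in the manifest."""

    topology: str
    frames: str
    amd_log: str
    output_dir: str
    temperature: float = 300.0
    reweight_method: str = "maclaurin"
    reweight_order: int = 10
    boost_component: str = "total"
    distance_bin_width: float = 1.0
    n_components: int = 3
    cluster_bins: int = 32
    cluster_min_density: float = 0.002
    contact_cutoff: float = 4.5
    scd_naming: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_SCD_NAMING.items()
    })
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        for stage, p in (("inputs", self.topology), ("inputs", self.frames)):
            if not Path(p).exists():
                raise PipelineError(stage, p, "input path does not exist")
        if not Path(self.amd_log).exists():
            raise PipelineError("reweighting", self.amd_log,
                                "amd.log required for reweighting is missing")


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class _WarningCollector(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record):
        self.messages.append(record.getMessage())


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; return the manifest (also written to the output dir)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    collector = _WarningCollector()
    pkg_logger = logging.getLogger("amdmem")
    pkg_logger.addHandler(collector)

    cfg_dict = asdict(config)
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    manifest = {
        "package": "amdmem",
        "version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "input_hashes": {
            p: _sha256(p) for p in (config.topology, config.frames, config.amd_log)
        },
        "stages": [],
        "warnings": [],
    }
    header = f"seed={config.seed}"
    thermo = ThermoParams(temperature=config.temperature)

    def run_stage(name, fn, path):
        t0 = time.perf_counter()
        try:
            outputs, n_records = fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, path, str(exc)) from exc
        manifest["stages"].append({
            "name": name,
            "status": "completed",
            "outputs": {str(p): _sha256(p) for p in outputs},
            "n_records": n_records,
            "seconds": round(time.perf_counter() - t0, 4),
        })
        logger.info("stage %s: %d records in %.2fs", name, n_records,
                    time.perf_counter() - t0)

    try:
        topo = read_topology(config.topology)
        traj = read_frames(config.frames, topo)

        state: dict = {}

        def stage_boost():
            state["boost"] = parse_amd_log(config.amd_log)
            return [], len(state["boost"])

        def stage_reweighting():
            w = frame_weights(
                state["boost"], thermo,
                method=config.reweight_method, order=config.reweight_order,
                component=config.boost_component,
            )
            state["weights"] = w
            p = out / "weights.tsv"
            write_table(p, {"frame": np.arange(len(w)), "weight": w.weights},
                        header_extra=header)
            return [p], len(w)

        def stage_dpca():
            series = compute_phi_psi(traj, topo)
            model = dpca_fit(series)
            ncomp = min(config.n_components, model.n_components)
            clusters = cluster_top_pcs(
                model, n_components=ncomp,
                grid_bins=config.cluster_bins,
                min_density=config.cluster_min_density,
            )
            p_pcs = out / "pcs.tsv"
            cols = {"frame": np.arange(series.n_frames)}
            for c in range(ncomp):
                cols[f"PC{c + 1}"] = model.projections[:, c]
            cols["cluster"] = clusters.labels
            write_table(p_pcs, cols, header_extra=header)
            p_cl = out / "clusters.tsv"
            write_table(p_cl, {
                "cluster": np.arange(clusters.n_clusters),
                "population": clusters.populations,
                "representative_frame": clusters.representatives,
            }, header_extra=header)
            outputs = [p_pcs, p_cl]
            for rank, rep in enumerate(clusters.representatives):
                p_rep = out / f"cluster_{rank + 1}.pdb"
                write_topology(topo, p_rep, coords=traj.coords[rep])
                outputs.append(p_rep)
            return outputs, series.n_frames

        def stage_scd():
            vecs = chain_vectors(traj, topo, config.scd_naming)
            profile = scd_profile(vecs)
            p = out / "scd.tsv"
            write_table(p, {
                "chain": profile.chain,
                "carbon": profile.carbon,
                "s_cd": profile.s_cd,
                "n": profile.n,
            }, header_extra=header)
            return [p], len(profile.s_cd)

        def stage_distance_pmf():
            series = com_z_distance(traj, topo)
            state["distance"] = series
            p_d = out / "distz.tsv"
            write_table(
                p_d,
                {"frame": np.arange(len(series)), "distance": series.values},
                units={"distance": "angstrom"}, header_extra=header,
            )
            boost = state["boost"]
            if len(boost) != len(series):
                raise ValueError(
                    f"boost series length {len(boost)} != frame count {len(series)}"
                )
            fes = insertion_pmf(
                series, boost, thermo,
                method=config.reweight_method, order=config.reweight_order,
                bin_width=config.distance_bin_width,
            )
            p_p = out / "pmf.tsv"
            write_table(p_p, surface_to_table_columns(fes),
                        units={"bin_center": "angstrom", "pmf_kcal_mol": "kcal/mol"},
                        header_extra=header)
            return [p_d, p_p], len(series)

        def stage_contacts():
            table = headgroup_contact_fractions(traj, topo, config.contact_cutoff)
            p = out / "contacts.tsv"
            write_table(p, {
                "residue": np.array(table.residue_labels),
                "contact_fraction": table.fractions,
            }, header_extra=f"cutoff={table.cutoff}A\t{header}")
            return [p], len(table.fractions)

        run_stage("boost", stage_boost, config.amd_log)
        run_stage("reweighting", stage_reweighting, config.amd_log)
        run_stage("dpca", stage_dpca, config.frames)
        run_stage("scd", stage_scd, config.frames)
        run_stage("distance_pmf", stage_distance_pmf, config.frames)
        run_stage("contacts", stage_contacts, config.frames)
    finally:
        pkg_logger.removeHandler(collector)

    manifest["warnings"] = collector.messages
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
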