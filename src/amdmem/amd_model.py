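"""Accelerated-MD boost potential and parameter bookkeeping.

Accelerated MD (aMD) adds a non-negative boost dV to the potential wherever
it falls below a threshold E, flattening energy wells so barriers are crossed
more often.  The boost has the standard closed form

    dV(V) = (E - V)^2 / (alpha + E - V)      for V < E,   else 0

with alpha > 0 controlling how aggressively wells are filled.  Three boost
criteria exist, selected by ``mode`` (the Amber ``iamd`` flag):

    1 : boost the whole potential,
    2 : boost only the torsional term,
    3 : dual boost — whole potential plus an extra torsional boost.

Canonical statistics are recovered downstream by reweighting each frame by
exp(dV / k_B T); see :mod:`amdmem.reweighting`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Boltzmann constant, kcal mol^-1 K^-1
KB_KCAL_MOL_K = 0.0019872041


@dataclass(frozen=True)
class ThermoParams:
    """Temperature and the derived thermal energy k_B*T (kcal/mol)."""

    temperature: float
    kT: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        kT_expected = KB_KCAL_MOL_K * self.temperature
        if self.kT is None:
            object.__setattr__(self, "kT", kT_expected)
        elif abs(self.kT - kT_expected) > 1e-9:
            raise ValueError(
                f"kT={self.kT} inconsistent with temperature {self.temperature} K "
                f"(expected {kT_expected})"
            )


@dataclass(frozen=True)
class AmdParams:
    """Boost thresholds/steepness for the three aMD criteria.

    All energies in kcal/mol.  ``e_total``/``alpha_total`` act on the whole
    potential (modes 1 and 3); ``e_dih``/``alpha_dih`` on the torsional term
    (modes 2 and 3).
    """

    mode: int
    e_total: float = 0.0
    alpha_total: float = 0.0
    e_dih: float = 0.0
    alpha_dih: float = 0.0

    def __post_init__(self):
        if self.mode not in (1, 2, 3):
            raise ValueError(f"mode must be 1, 2 or 3, got {self.mode}")
        if self.mode in (1, 3) and self.alpha_total <= 0:
            raise ValueError("alpha_total must be > 0 for modes 1 and 3")
        if self.mode in (2, 3) and self.alpha_dih <= 0:
            raise ValueError("alpha_dih must be > 0 for modes 2 and 3")

    def to_config(self) -> dict:
        return {
            "iamd": self.mode,
            "E_total": self.e_total,
            "alpha_total": self.alpha_total,
            "E_dih": self.e_dih,
            "alpha_dih": self.alpha_dih,
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "AmdParams":
        return cls(
            mode=int(cfg["iamd"]),
            e_total=float(cfg.get("E_total", 0.0)),
            alpha_total=float(cfg.get("alpha_total", 0.0)),
            e_dih=float(cfg.get("E_dih", 0.0)),
            alpha_dih=float(cfg.get("alpha_dih", 0.0)),
        )


def boost_energy(v, e: float, alpha: float):
    """Boost energy dV = (E-V)^2/(alpha+E-V) for V < E, else 0 (kcal/mol).

    Vectorised over ``v``.  dV is non-negative, zero iff V >= E, bounded by
    E - V, and non-increasing in V so V + dV is non-decreasing (the boosted
    surface preserves the ordering of states).
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    v = np.asarray(v, dtype=float)
    gap = e - v
    with np.errstate(divide="ignore", invalid="ignore"):
        dv = np.where(gap > 0, gap * gap / (alpha + gap), 0.0)
    if dv.ndim == 0:
        return float(dv)
    return dv


def total_boost(v_p, v_d, params: AmdParams):
    """Apply the boost criterion of ``params.mode`` to (V_total, V_dihedral).

    Returns ``(dV_total, dV_dihedral)``; the component a mode does not boost
    is identically zero.
    """
    v_p = np.asarray(v_p, dtype=float)
    v_d = np.asarray(v_d, dtype=float)
    zero_p = np.zeros_like(v_p) if v_p.ndim else 0.0
    zero_d = np.zeros_like(v_d) if v_d.ndim else 0.0
    if params.mode == 1:
        return boost_energy(v_p, params.e_total, params.alpha_total), zero_d
    if params.mode == 2:
        return zero_p, boost_energy(v_d, params.e_dih, params.alpha_dih)
    if params.mode == 3:
        return (
            boost_energy(v_p, params.e_total, params.alpha_total),
            boost_energy(v_d, params.e_dih, params.alpha_dih),
        )
    raise ValueError(f"unknown mode {params.mode}")


def params_from_classical_averages(
    avg_v_dih: float,
    avg_v_tot: float,
    n_residues: int,
    n_atoms: int,
    mode: int,
    residue_coeff: float = 3.5,
    residue_divisor: float = 5.0,
    atom_coeff: float = 0.175,
) -> AmdParams:
    """Seed aMD thresholds from classical-run average energies.

    The standard dual-boost recipe: the torsional threshold sits
    ``residue_coeff`` kcal/mol per residue above the classical average
    dihedral energy with alpha a fifth of that margin, and the total-potential
    threshold sits ``atom_coeff`` kcal/mol per atom above the average total
    potential with alpha equal to the margin.  All three constants are
    exposed for auditability.
    """
    if n_residues < 1 or n_atoms < 1:
        raise ValueError(
            f"n_residues and n_atoms must be >= 1, got {n_residues}, {n_atoms}"
        )
    margin_dih = residue_coeff * n_residues
    margin_tot = atom_coeff * n_atoms
    return AmdParams(
        mode=mode,
        e_dih=avg_v_dih + margin_dih,
        alpha_dih=margin_dih / residue_divisor,
        e_total=avg_v_tot + margin_tot,
        alpha_total=margin_tot,
    )
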