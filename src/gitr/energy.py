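"""MM-PBSA free-energy bookkeeping and barrier composition.

Recombines the standard molecular-mechanics/Poisson-Boltzmann surface-area
components of a binding free energy,

    dE_polar    = dE_ele + dG_PB
    dE_nonpolar = dE_vdw + dG_SA
    dG_mmpbsa   = dE_polar + dE_nonpolar
    dG_bind     = dG_mmpbsa - T*dS,

and composes transition-state energies from a pulled-ligand PMF endpoint:
the total work to extract a bound ligand contains both the thermodynamic
stabilisation it provided and the purely geometric resistance of the exit
channel, so ``barrier = pmf_total - stabilization`` and the barrier top sits
at ``G_state + barrier`` on the assembly free-energy surface.

The polar-solvation (dG_PB) and entropy (T*dS) terms are consumed as
inputs — solving the Poisson-Boltzmann equation and normal-mode analysis
are upstream of this package. Internal-energy terms (bond/angle/torsion)
cancel in single-trajectory binding deltas and are optional metadata.
Values are stored at full precision; rounding happens only at presentation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "EnergyComponents",
    "BindingSummary",
    "combine_mmpbsa",
    "nonpolar_solvation",
    "binding_delta",
    "insertion_barrier",
    "compose_transition_energy",
    "read_component_table",
    "summary_table",
]

#: accepted ASCII aliases for each component column/row name.
_ALIASES: dict[str, tuple[str, ...]] = {
    "e_vdw": ("evdw", "e_vdw", "devdw", "δe_vdw", "Δe_vdw"),
    "e_ele": ("eele", "e_ele", "deele", "δe_ele", "Δe_ele"),
    "g_pb": ("gpb", "g_pb", "dgpb", "δg_pb", "Δg_pb"),
    "g_sa": ("gsa", "g_sa", "dgsa", "δg_sa", "Δg_sa"),
    "t_delta_s": ("tds", "ts", "t_delta_s", "tdeltas", "tδs", "tΔs"),
}


@dataclass(frozen=True)
class EnergyComponents:
    """Raw MM-PBSA components for one system, kcal/mol.

    ``t_delta_s`` is the gas-phase conformational entropy term T*dS.
    Standard deviations are optional presentation metadata.
    """

    e_vdw: float
    e_ele: float
    g_pb: float
    g_sa: float
    t_delta_s: float
    sd: Mapping[str, float] | None = None
    e_bond: float | None = None
    e_angle: float | None = None
    e_torsion: float | None = None

    def __post_init__(self) -> None:
        for name in ("e_vdw", "e_ele", "g_pb", "g_sa", "t_delta_s"):
            v = getattr(self, name)
            if v is None:
                raise ValueError(f"missing required component {name!r}")
            if not math.isfinite(v):
                raise ValueError(f"component {name!r} is not finite: {v}")
        if self.sd is not None and any(s < 0 for s in self.sd.values()):
            raise ValueError("standard deviations must be non-negative")


@dataclass(frozen=True)
class BindingSummary:
    """Derived MM-PBSA quantities; the defining identities hold exactly."""

    e_polar: float
    e_nonpolar: float
    g_mmpbsa: float
    g_bind: float

    def round(self, ndigits: int = 2) -> "BindingSummary":
        """Presentation rounding; stored values stay full precision."""
        return BindingSummary(
            *(round(getattr(self, f), ndigits)
              for f in ("e_polar", "e_nonpolar", "g_mmpbsa", "g_bind"))
        )


def combine_mmpbsa(c: EnergyComponents) -> BindingSummary:
    """Recombine raw components into the four derived binding quantities."""
    e_polar = c.e_ele + c.g_pb
    e_nonpolar = c.e_vdw + c.g_sa
    g_mmpbsa = e_polar + e_nonpolar
    return BindingSummary(e_polar, e_nonpolar, g_mmpbsa, g_mmpbsa - c.t_delta_s)


def nonpolar_solvation(sasa: float, gamma: float = 0.00542, beta: float = 0.92) -> float:
    """dG_SA = gamma * SASA + beta.

    Parameters
    ----------
    sasa : solvent-accessible surface area, A^2 (>= 0).
    gamma : surface tension, kcal mol^-1 A^-2.
    beta : offset, kcal/mol.

    The defaults are the common PB surface-tension parametrisation; they are
    configuration, not physics fixed by this package.
    """
    if sasa < 0:
        raise ValueError(f"SASA must be non-negative, got {sasa}")
    return gamma * sasa + beta


def binding_delta(
    complex_: EnergyComponents,
    receptor: EnergyComponents,
    ligand: EnergyComponents,
) -> tuple[EnergyComponents, BindingSummary]:
    """Component-wise dX = X_complex - X_receptor - X_ligand, plus its summary.

    All three ledgers must follow the same (single-trajectory) convention;
    internal-energy terms cancel there and are excluded from the delta.
    """
    delta = EnergyComponents(
        e_vdw=complex_.e_vdw - receptor.e_vdw - ligand.e_vdw,
        e_ele=complex_.e_ele - receptor.e_ele - ligand.e_ele,
        g_pb=complex_.g_pb - receptor.g_pb - ligand.g_pb,
        g_sa=complex_.g_sa - receptor.g_sa - ligand.g_sa,
        t_delta_s=complex_.t_delta_s - receptor.t_delta_s - ligand.t_delta_s,
    )
    return delta, combine_mmpbsa(delta)


def insertion_barrier(pmf_total: float, stabilization: float) -> float:
    """Geometric exit-channel barrier = PMF endpoint - ligand stabilisation.

    Pulling a bound ligand out costs the stabilisation it provided plus the
    steric resistance of the channel; subtracting the former isolates the
    latter. A negative result (stabilisation exceeding the total work) is
    physically suspect and triggers a warning.
    """
    if not (math.isfinite(pmf_total) and math.isfinite(stabilization)):
        raise ValueError("inputs must be finite")
    barrier = pmf_total - stabilization
    if barrier < 0:
        warnings.warn(
            f"negative barrier {barrier:.4g} kcal/mol: stabilization exceeds "
            "the PMF endpoint",
            stacklevel=2,
        )
    return barrier


def compose_transition_energy(base_state_g_total: float, barrier: float) -> float:
    """Cluster-level transition-state energy: G_state(total) + barrier.

    Convert to the per-monomer convention through the network model (divide
    by the nu of the destination stable state).
    """
    return base_state_g_total + barrier


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def _canonical(name: str) -> str | None:
    flat = str(name).strip().lower().replace("δ", "").replace("Δ", "").replace("_", "")
    flat = flat.replace("d", "", 1) if flat.startswith(("de", "dg")) else flat
    for canon, aliases in _ALIASES.items():
        if flat in {a.replace("_", "") for a in aliases}:
            return canon
    return None


def read_component_table(path: str | Path) -> dict[str, EnergyComponents]:
    """Read a components table (TSV/CSV), one system per column or per row.

    Header names match the conventional symbols or their ASCII aliases
    (Evdw, Eele, GPB, GSA, TdS). Orientation is auto-detected from which
    axis the component names sit on.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    # detect orientation: component names on the index (systems in columns)?
    if any(_canonical(ix) for ix in df.index):
        df = df.T
    renamed = {}
    for col in df.columns:
        canon = _canonical(col)
        if canon:
            renamed[col] = canon
    df = df.rename(columns=renamed)
    missing = set(_ALIASES) - set(df.columns)
    if missing:
        raise ValueError(f"component table is missing column(s): {sorted(missing)}")
    return {
        str(system): EnergyComponents(
            **{k: float(row[k]) for k in _ALIASES}
        )
        for system, row in df.iterrows()
    }


def summary_table(components: Mapping[str, EnergyComponents]) -> pd.DataFrame:
    """Summaries for several systems as a tidy DataFrame (kcal/mol)."""
    rows = []
    for system, c in components.items():
        s = combine_mmpbsa(c)
        rows.append(
            {
                "system": system,
                "e_vdw": c.e_vdw,
                "e_ele": c.e_ele,
                "g_pb": c.g_pb,
                "g_sa": c.g_sa,
                "e_polar": s.e_polar,
                "e_nonpolar": s.e_nonpolar,
                "g_mmpbsa": s.g_mmpbsa,
                "t_delta_s": c.t_delta_s,
                "g_bind": s.g_bind,
            }
        )
    return pd.DataFrame(rows).set_index("system")
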