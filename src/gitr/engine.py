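"""Inter-state transformation rate solver for self-assembly networks.

The model: transformation out of a stable state ``s`` over a transition
state ``t`` is activated with rate constant ``k_t^s * exp(-(G_t - G_s)/RT)``
(classical transition-state theory on the *per-monomer* free energies, the
rate-determining step being monomer activation); the downhill side from a
transition state to its linked stable states is barrierless and splits
according to the column-stochastic linking-fraction matrix
``Lf[s,t] = k_t^s / sum_s' k_t^s'``. Cluster stoichiometry enters through
the monomer counts ``nu``: concentrations are per cluster, so a flow of
monomers between clusters of different sizes carries a ``nu_src/nu_dst``
factor, and the monomer-weighted total ``sum_s nu_s C_s`` is conserved
exactly by construction.

The absolute scale ``k = (k_B T / h) * A`` is absorbed into a single
``k_scale`` constant (default 1, "reduced rate units"): the theory's
conclusions are rate ratios, and no frequency-factor calibration exists.

Linearity gives ``dC/dt = A C`` with the monomer-count vector a left null
vector of ``A``; time courses are eigen-superpositions ``sum_i z_i xi_i
exp(lambda_i t)``, with a matrix-exponential fallback when the eigenbasis is
ill-conditioned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.special import softmax

from .network import ConcentrationState, SelfAssemblyNetwork

__all__ = [
    "LinkingFractionMatrix",
    "RateTable",
    "KineticSystem",
    "PathRate",
    "linking_fractions",
    "equilibrium_distribution",
    "path_rates",
    "state_rates",
    "equilibrium_flux",
    "kinetic_matrix",
    "evolve",
    "dominant_path",
]

logger = logging.getLogger(__name__)

#: eigenvector-basis condition number beyond which evolve() falls back to
#: the matrix exponential.
EIG_CONDITION_LIMIT = 1e12


@dataclass(frozen=True)
class LinkingFractionMatrix:
    """Column-stochastic distribution of outflow from each transition state."""

    state_ids: tuple[str, ...]
    transition_ids: tuple[str, ...]
    matrix: np.ndarray  # (n_states, n_transitions)

    def __getitem__(self, key: tuple[str, str]) -> float:
        s, t = key
        return float(
            self.matrix[self.state_ids.index(s), self.transition_ids.index(t)]
        )


@dataclass(frozen=True)
class RateTable:
    """Per-path rates R[s,t] and their row sums (state rates).

    Sign convention: negative means net outflow from the stable state via
    that transition state. ``rate_unit_scale`` records the absorbed
    ``(k_B T / h) * A`` prefactor (reduced rate units by default).
    """

    state_ids: tuple[str, ...]
    transition_ids: tuple[str, ...]
    path_rates: np.ndarray  # (n_states, n_transitions)
    rate_unit_scale: float = 1.0

    @property
    def state_rates(self) -> np.ndarray:
        """Concentration change rate of each stable state: exact row sum."""
        return self.path_rates.sum(axis=1)

    def path(self, state_id: str, transition_id: str) -> float:
        return float(
            self.path_rates[
                self.state_ids.index(state_id), self.transition_ids.index(transition_id)
            ]
        )


@dataclass
class KineticSystem:
    """dC/dt = A C with its eigen-solution.

    ``eigenvectors`` columns are the modes xi_i; weights z_i for an initial
    condition are solved on demand in :func:`evolve`.
    """

    state_ids: tuple[str, ...]
    nu: np.ndarray
    matrix: np.ndarray
    eigenvalues: np.ndarray = field(init=False)
    eigenvectors: np.ndarray = field(init=False)
    basis_condition: float = field(init=False)

    def __post_init__(self) -> None:
        self.eigenvalues, self.eigenvectors = scipy.linalg.eig(self.matrix)
        with np.errstate(all="ignore"):
            cond = np.linalg.cond(self.eigenvectors)
        self.basis_condition = float(cond) if np.isfinite(cond) else np.inf


@dataclass(frozen=True)
class PathRate:
    """One ranked entry of a dominant-path analysis."""

    state_id: str
    transition_id: str
    rate: float
    rank: int  # 1-based; joint-dominant paths share a rank


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def _k_matrix(net: SelfAssemblyNetwork, k_scale: float) -> np.ndarray:
    """k_t^s = k_scale * A_t^s; zero where unlinked."""
    return k_scale * net.frequency_factors()


def linking_fractions(
    net: SelfAssemblyNetwork, k_scale: float = 1.0
) -> LinkingFractionMatrix:
    """Lf[s,t] = k_t^s / sum_s' k_t^s'.

    With all frequency factors equal, each column is uniform 1/n over the n
    linked states. Columns sum to 1 exactly (the normalisation is explicit).
    """
    k = _k_matrix(net, k_scale)
    col = k.sum(axis=0)
    if np.any(col <= 0):
        bad = [net.transition_ids[j] for j in np.nonzero(col <= 0)[0]]
        raise ValueError(f"isolated transition state(s): {bad}")
    return LinkingFractionMatrix(net.state_ids, net.transition_ids, k / col)


def equilibrium_distribution(
    net: SelfAssemblyNetwork,
    accessible: tuple[str, ...] | list[str] | None = None,
) -> ConcentrationState:
    """Boltzmann monomer distribution over an accessible subset of states.

    P_s = exp(-G_s/RT) / Z with Z summed over the *accessible* states only
    (kinetically blocked states — e.g. a drug-bound mode before the drug is
    added — are excluded by the caller and get concentration 0). Cluster
    concentrations are C_s = P_s C0 / nu_s. Computed via a shifted softmax
    for overflow safety.
    """
    if accessible is None:
        accessible = net.state_ids
    accessible = tuple(accessible)
    if not accessible:
        raise ValueError("accessible set must be non-empty")
    unknown = set(accessible) - set(net.state_ids)
    if unknown:
        raise ValueError(f"unknown state id(s) in accessible set: {sorted(unknown)}")

    idx = np.array([net.state_index(s) for s in accessible])
    p_sub = softmax(-net.g_state[idx] / net.rt)
    p = np.zeros(net.n_states)
    p[idx] = p_sub
    cs = p * net.c0_monomer / net.nu
    return ConcentrationState(net.state_ids, cs, net.nu)


def path_rates(
    net: SelfAssemblyNetwork,
    conc: ConcentrationState,
    k_scale: float = 1.0,
) -> RateTable:
    """Net transformation rate of every directly linked (state, transition) pair.

    R[s,t] = -k_t^s e^{-(G_t-G_s)/RT} C_s
             + Lf[s,t] * sum_s' k_t^s' e^{-(G_t-G_s')/RT} (nu_s'/nu_s) C_s'

    Boltzmann factors within each transition-state column share G_t, so they
    are evaluated with a per-column max-subtracted exponent and the common
    shift reapplied once — the equilibrium cancellation survives to
    round-off.
    """
    if tuple(conc.state_ids) != net.state_ids:
        raise ValueError("concentration state ids do not match the network")
    if np.any(conc.cs < 0):
        raise ValueError("negative concentration")

    k = _k_matrix(net, k_scale)
    lf = linking_fractions(net, k_scale).matrix
    rtv = net.rt
    nu = net.nu
    cs = conc.cs

    # arg[s,t] = -(G_t - G_s)/RT, meaningful where linked
    arg = (net.g_state[:, None] - net.g_transition[None, :]) / rtv
    linked = k > 0
    r = np.zeros_like(k)
    for j in range(net.n_transitions):
        rows = linked[:, j]
        m = arg[rows, j].max()
        e = np.zeros(net.n_states)
        e[rows] = np.exp(arg[rows, j] - m)
        inflow_total = float((k[:, j] * e * nu * cs).sum())
        r[rows, j] = np.exp(m) * (
            -k[rows, j] * e[rows] * cs[rows] + lf[rows, j] * inflow_total / nu[rows]
        )
    return RateTable(net.state_ids, net.transition_ids, r, rate_unit_scale=k_scale)


def state_rates(rate_table: RateTable) -> np.ndarray:
    """dC_s/dt for each stable state: the exact row sum of the path rates."""
    return rate_table.state_rates


def equilibrium_flux(
    net: SelfAssemblyNetwork,
    accessible: tuple[str, ...] | list[str] | None = None,
    monomer_form: bool = False,
    k_scale: float = 1.0,
) -> RateTable:
    """One-way path flux magnitudes at the equilibrium distribution.

    |R|_eq(s,t) = k_t^s (1/nu_s) (1/Z) e^{-G_t/RT} C0; the monomer-form
    variant omits 1/nu_s. The flux depends only on the transition-state
    energy G_t and the path's frequency factor — not on G_s: a deeper state
    is more populated but pays a correspondingly higher activation energy.
    """
    if accessible is None:
        accessible = net.state_ids
    accessible = tuple(accessible)
    if not accessible:
        raise ValueError("accessible set must be non-empty")
    idx = np.array([net.state_index(s) for s in accessible])

    rtv = net.rt
    # log(1/Z * e^{-Gt/RT}) computed with a shared shift for overflow safety
    g_acc = net.g_state[idx] / rtv
    shift = (-g_acc).max()
    log_z = shift + np.log(np.exp(-g_acc - shift).sum())
    k = _k_matrix(net, k_scale)
    flux = k * np.exp(-net.g_transition[None, :] / rtv - log_z) * net.c0_monomer
    if not monomer_form:
        flux = flux / net.nu[:, None]
    return RateTable(net.state_ids, net.transition_ids, flux, rate_unit_scale=k_scale)


def kinetic_matrix(net: SelfAssemblyNetwork, k_scale: float = 1.0) -> KineticSystem:
    """Assemble A with dC/dt = A C.

    A[s,j] = delta_sj * sum_t(-k_t^s e^{-(G_t-G_s)/RT})
             + sum_t (nu_j/nu_s) Lf[s,t] k_t^j e^{-(G_t-G_j)/RT}

    Because every Lf column sums to 1, the monomer-count vector nu is a left
    null vector of A: total monomer content is conserved exactly.
    """
    k = _k_matrix(net, k_scale)
    lf = linking_fractions(net, k_scale).matrix
    arg = (net.g_state[:, None] - net.g_transition[None, :]) / net.rt
    with np.errstate(over="raise"):
        b = k * np.exp(np.where(k > 0, arg, -np.inf))  # escape rates k_t^s e^{...}
    nu = net.nu
    a = (
        np.diag(-b.sum(axis=1))
        + (lf @ b.T) * (nu[None, :] / nu[:, None])
    )
    return KineticSystem(net.state_ids, nu, a)


def evolve(
    system: KineticSystem,
    c_init,
    times,
) -> list[ConcentrationState]:
    """Time course C(t) = sum_i z_i xi_i e^{lambda_i t} from c_init.

    Uses the eigen-superposition when the eigenbasis is well conditioned;
    otherwise falls back to the matrix exponential (identical contract).
    C(0) equals ``c_init`` and the monomer total is constant along the
    trajectory to floating tolerance.
    """
    c0 = np.asarray(c_init, dtype=float)
    times = np.asarray(times, dtype=float)
    if c0.shape != (len(system.state_ids),):
        raise ValueError("c_init dimension does not match the system")
    if np.any(c0 < 0):
        raise ValueError("negative initial concentration")
    if times.size and (np.any(times < 0) or np.any(np.diff(times) < 0)):
        raise ValueError("times must be sorted and non-negative")

    if system.basis_condition <= EIG_CONDITION_LIMIT:
        z = scipy.linalg.solve(system.eigenvectors, c0.astype(complex))
        traj = (
            system.eigenvectors
            @ (z[:, None] * np.exp(system.eigenvalues[:, None] * times[None, :]))
        ).T
        traj = np.real_if_close(traj, tol=1e6).real
    else:
        logger.info(
            "eigenbasis condition %.3g exceeds %.1g; using matrix exponential",
            system.basis_condition,
            EIG_CONDITION_LIMIT,
        )
        traj = np.empty((times.size, c0.size))
        for i, t in enumerate(times):
            traj[i] = scipy.linalg.expm(system.matrix * t) @ c0
    return [
        ConcentrationState(system.state_ids, traj[i], system.nu, time=float(t))
        for i, t in enumerate(times)
    ]


def dominant_path(
    net: SelfAssemblyNetwork,
    conc: ConcentrationState,
    k_scale: float = 1.0,
    tie_rel_tol: float = 1e-9,
) -> list[PathRate]:
    """Rank the directly linked paths by |R[s,t]|, largest first.

    Paths whose magnitudes agree within ``tie_rel_tol`` (relative) share a
    rank (joint dominance) instead of being ordered arbitrarily. All-zero
    rates yield an empty ranking (logged as a diagnostic).
    """
    table = path_rates(net, conc, k_scale)
    linked = net.frequency_factors() > 0
    entries = [
        (net.state_ids[i], net.transition_ids[j], float(table.path_rates[i, j]))
        for i, j in zip(*np.nonzero(linked))
    ]
    entries.sort(key=lambda e: -abs(e[2]))
    if not entries or abs(entries[0][2]) == 0.0:
        logger.info("all path rates are zero; no dominant path")
        return []

    ranked: list[PathRate] = []
    rank = 0
    prev_mag = None
    for n, (sid, tid, rate) in enumerate(entries, start=1):
        mag = abs(rate)
        if prev_mag is None or prev_mag - mag > tie_rel_tol * prev_mag:
            rank = n
        ranked.append(PathRate(sid, tid, rate, rank))
        prev_mag = mag
    return ranked
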