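"""Declarative data model and file I/O for multi-state self-assembly networks.

A self-assembly network is a bipartite graph of *stable states* (clusters of
``nu`` monomers sitting at local free-energy minima) and *transition states*
(the free-energy maxima on the transformation paths between them). Stable
states never link to each other directly, nor do transition states: every
transformation passes through exactly one transition state.

Free energies are referenced to the free-monomer state (zero by convention)
and stored per cluster for stable states; all rate formulas consume the
per-monomer value ``g_monomer = g_bind_total / nu`` — the average free energy
gained per monomer upon assembly. Transition states carry a per-monomer free
energy directly: the theory assigns no cluster size of its own to a barrier
top, so when a user supplies a cluster-level barrier it is divided by the nu
of a named stable state (see :func:`load_network` schema).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .constants import DEFAULT_TEMPERATURE, R_KCAL, rt

__all__ = [
    "StableState",
    "TransitionState",
    "SelfAssemblyNetwork",
    "ConcentrationState",
    "NetworkSchemaError",
    "load_network",
    "loads_network",
    "save_network",
    "serialize_network",
    "validate_network",
]


class NetworkSchemaError(ValueError):
    """Raised when a network file violates the schema."""


@dataclass(frozen=True)
class StableState:
    """A stable self-assembly cluster.

    Parameters
    ----------
    id : str
        Short unique label (e.g. ``"S1"``).
    nu : int
        Number of protein monomers per cluster; ligands do not count.
    g_bind_total : float
        Free energy of the cluster relative to free monomers, kcal/mol
        (sum of the stepwise binding free energies).
    """

    id: str
    nu: int
    g_bind_total: float

    @property
    def g_monomer(self) -> float:
        """Average per-monomer free energy, kcal/mol."""
        return self.g_bind_total / self.nu


@dataclass(frozen=True)
class TransitionState:
    """A free-energy maximum on a transformation path.

    ``links`` maps directly connected stable-state ids to dimensionless
    frequency factors A > 0. A == 0 means "not linked" and must be omitted.
    """

    id: str
    g_monomer: float
    links: tuple[tuple[str, float], ...]

    def linked_ids(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.links)

    def frequency_factor(self, state_id: str) -> float:
        for s, a in self.links:
            if s == state_id:
                return a
        return 0.0


@dataclass(frozen=True)
class SelfAssemblyNetwork:
    """A validated bipartite self-assembly network.

    Attributes
    ----------
    states, transitions : ordered declarations.
    temperature : K.
    c0_monomer : total analytical monomer concentration (any concentration
        unit; all outputs are linear in it).
    gas_constant : kcal mol^-1 K^-1.
    """

    states: tuple[StableState, ...]
    transitions: tuple[TransitionState, ...]
    temperature: float = DEFAULT_TEMPERATURE
    c0_monomer: float = 1.0
    gas_constant: float = R_KCAL

    def __post_init__(self) -> None:
        problems = validate_network(self)
        if problems:
            raise NetworkSchemaError("; ".join(problems))

    # -- indexed views used by the solver ---------------------------------
    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    @property
    def state_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.states)

    @property
    def transition_ids(self) -> tuple[str, ...]:
        return tuple(t.id for t in self.transitions)

    def state_index(self, state_id: str) -> int:
        return self.state_ids.index(state_id)

    @property
    def nu(self) -> np.ndarray:
        return np.array([s.nu for s in self.states], dtype=float)

    @property
    def g_state(self) -> np.ndarray:
        """Per-monomer stable-state free energies, kcal/mol."""
        return np.array([s.g_monomer for s in self.states])

    @property
    def g_transition(self) -> np.ndarray:
        """Per-monomer transition-state free energies, kcal/mol."""
        return np.array([t.g_monomer for t in self.transitions])

    @property
    def rt(self) -> float:
        return rt(self.temperature)

    def frequency_factors(self) -> np.ndarray:
        """Dense (n_states, n_transitions) matrix of A factors, 0 = unlinked."""
        a = np.zeros((self.n_states, self.n_transitions))
        idx = {s: i for i, s in enumerate(self.state_ids)}
        for j, t in enumerate(self.transitions):
            for sid, aval in t.links:
                a[idx[sid], j] = aval
        return a


@dataclass
class ConcentrationState:
    """Per-cluster concentrations of the stable states at one instant.

    ``cs[i]`` is the cluster concentration of state ``state_ids[i]``;
    the per-monomer view is ``ms = nu * cs``.
    """

    state_ids: tuple[str, ...]
    cs: np.ndarray
    nu: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.cs = np.asarray(self.cs, dtype=float)
        self.nu = np.asarray(self.nu, dtype=float)
        if self.cs.shape != (len(self.state_ids),):
            raise ValueError("cs length must match state_ids")
        if self.nu.shape != (len(self.state_ids),):
            raise ValueError("nu length must match state_ids")

    @property
    def ms(self) -> np.ndarray:
        """Monomer-form concentrations nu_s * C_s."""
        return self.nu * self.cs

    @property
    def total_monomer(self) -> float:
        return float(self.ms.sum())

    @classmethod
    def for_network(
        cls, net: SelfAssemblyNetwork, cs: Sequence[float], time: float = 0.0
    ) -> "ConcentrationState":
        return cls(net.state_ids, np.asarray(cs, dtype=float), net.nu, time)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_network(net: SelfAssemblyNetwork | object) -> list[str]:
    """Collect human-readable invariant violations; empty list means valid.

    Never raises and never mutates; intended both for the constructor and
    for user-facing diagnostics on hand-built objects.
    """
    problems: list[str] = []
    states = getattr(net, "states", ())
    transitions = getattr(net, "transitions", ())

    sids = [s.id for s in states]
    if not sids:
        problems.append("network declares no stable states")
    dup = _duplicates(sids)
    if dup:
        problems.append(f"duplicate stable-state ids: {sorted(dup)}")
    tids = [t.id for t in transitions]
    dup = _duplicates(tids)
    if dup:
        problems.append(f"duplicate transition-state ids: {sorted(dup)}")
    overlap = set(sids) & set(tids)
    if overlap:
        problems.append(f"ids used for both a state and a transition: {sorted(overlap)}")

    for s in states:
        if not isinstance(s.nu, int) or s.nu < 1:
            problems.append(f"state {s.id!r}: nu must be a positive integer, got {s.nu}")
        if not math.isfinite(s.g_bind_total):
            problems.append(f"state {s.id!r}: non-finite g_bind_total")

    known = set(sids)
    for t in transitions:
        if not t.links:
            problems.append(f"transition {t.id!r}: empty link list")
        if not math.isfinite(t.g_monomer):
            problems.append(f"transition {t.id!r}: non-finite g_monomer")
        seen: set[str] = set()
        for sid, a in t.links:
            if sid not in known:
                problems.append(f"transition {t.id!r}: link to undeclared state {sid!r}")
            if sid in seen:
                problems.append(f"transition {t.id!r}: duplicate link to {sid!r}")
            seen.add(sid)
            if not (a > 0):
                problems.append(
                    f"transition {t.id!r} -> {sid!r}: zero frequency factor "
                    "(omit the link instead of declaring A = 0)"
                )

    temperature = getattr(net, "temperature", DEFAULT_TEMPERATURE)
    if not temperature > 0:
        problems.append(f"temperature must be positive, got {temperature}")
    c0 = getattr(net, "c0_monomer", 1.0)
    if not c0 >= 0:
        problems.append(f"c0 must be non-negative, got {c0}")
    return problems


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for x in items:
        if x in seen:
            dups.add(x)
        seen.add(x)
    return dups


# ---------------------------------------------------------------------------
# File I/O. The on-disk dialect is YAML, of which JSON is a subset, so both
# serializations load through the same path.
# ---------------------------------------------------------------------------

def load_network(path: str | Path) -> SelfAssemblyNetwork:
    """Read and validate a network-spec file (YAML or JSON).

    Schema::

        temperature_K: 310.0        # optional, default 310
        c0: 1.0                     # optional, default 1
        states:
          - {id: S1, nu: 2, g_bind_total: -23.63}
        transitions:
          - id: T1
            g_monomer: 0.0          # or: g_total + g_total_over_nu_of
            links:
              - {state: S1, A: 1.0} # A optional, default 1

    A transition may instead give a cluster-level barrier ``g_total``
    together with ``g_total_over_nu_of: <state id>``; the per-monomer value
    is then ``g_total / nu`` of that state.
    """
    text = Path(path).read_text()
    return loads_network(text)


def loads_network(text: str) -> SelfAssemblyNetwork:
    """Parse a network spec from a string; see :func:`load_network`."""
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - message passthrough
        raise NetworkSchemaError(f"unparseable network file: {exc}") from exc
    if not isinstance(raw, dict):
        raise NetworkSchemaError("network file must be a mapping at top level")

    states = tuple(
        _parse_state(i, entry) for i, entry in enumerate(_require_list(raw, "states"))
    )
    nu_of = {s.id: s.nu for s in states}
    transitions = tuple(
        _parse_transition(i, entry, nu_of)
        for i, entry in enumerate(_require_list(raw, "transitions"))
    )
    return SelfAssemblyNetwork(
        states=states,
        transitions=transitions,
        temperature=_number(raw.get("temperature_K", DEFAULT_TEMPERATURE), "temperature_K"),
        c0_monomer=_number(raw.get("c0", 1.0), "c0"),
    )


def _require_list(raw: dict, key: str) -> list:
    value = raw.get(key)
    if not isinstance(value, list) or not value:
        raise NetworkSchemaError(f"{key!r} must be a non-empty list")
    return value


def _number(value, key: str) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise NetworkSchemaError(f"{key!r} must be numeric, got {value!r}")
    return float(value)


def _parse_state(i: int, entry) -> StableState:
    if not isinstance(entry, dict):
        raise NetworkSchemaError(f"states[{i}] must be a mapping")
    try:
        sid = str(entry["id"])
        nu = entry["nu"]
        g = _number(entry["g_bind_total"], f"states[{i}].g_bind_total")
    except KeyError as exc:
        raise NetworkSchemaError(f"states[{i}]: missing key {exc.args[0]!r}") from exc
    if isinstance(nu, bool) or not isinstance(nu, int) or nu < 1:
        raise NetworkSchemaError(f"states[{i}] ({sid!r}): nu must be a positive integer")
    return StableState(id=sid, nu=nu, g_bind_total=g)


def _parse_transition(i: int, entry, nu_of: dict[str, int]) -> TransitionState:
    if not isinstance(entry, dict):
        raise NetworkSchemaError(f"transitions[{i}] must be a mapping")
    try:
        tid = str(entry["id"])
    except KeyError as exc:
        raise NetworkSchemaError(f"transitions[{i}]: missing key 'id'") from exc

    if "g_monomer" in entry:
        g_mon = _number(entry["g_monomer"], f"transitions[{i}].g_monomer")
    elif "g_total" in entry and "g_total_over_nu_of" in entry:
        ref = str(entry["g_total_over_nu_of"])
        if ref not in nu_of:
            raise NetworkSchemaError(
                f"transition {tid!r}: g_total_over_nu_of names undeclared state {ref!r}"
            )
        g_mon = _number(entry["g_total"], f"transitions[{i}].g_total") / nu_of[ref]
    else:
        raise NetworkSchemaError(
            f"transition {tid!r}: give g_monomer, or g_total with g_total_over_nu_of"
        )

    raw_links = entry.get("links")
    if not isinstance(raw_links, list) or not raw_links:
        raise NetworkSchemaError(f"transition {tid!r}: 'links' must be a non-empty list")
    links = []
    for j, ln in enumerate(raw_links):
        if not isinstance(ln, dict) or "state" not in ln:
            raise NetworkSchemaError(f"transition {tid!r}: links[{j}] needs a 'state' key")
        links.append((str(ln["state"]), _number(ln.get("A", 1.0), f"{tid}.links[{j}].A")))
    return TransitionState(id=tid, g_monomer=g_mon, links=tuple(links))


def serialize_network(net: SelfAssemblyNetwork) -> str:
    """Serialize to the YAML schema of :func:`load_network`.

    Bit-stable: identical networks serialize to identical text.
    """
    doc = {
        "temperature_K": net.temperature,
        "c0": net.c0_monomer,
        "states": [
            {"id": s.id, "nu": s.nu, "g_bind_total": s.g_bind_total} for s in net.states
        ],
        "transitions": [
            {
                "id": t.id,
                "g_monomer": t.g_monomer,
                "links": [{"state": sid, "A": a} for sid, a in t.links],
            }
            for t in net.transitions
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def save_network(net: SelfAssemblyNetwork, path: str | Path) -> None:
    Path(path).write_text(serialize_network(net))
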