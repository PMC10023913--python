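"""Causal DAGs, d-separation and backdoor adjustment-set identification.

The outcome model is licensed by the backdoor criterion: a set Z of observed
non-descendants of the treatments that blocks every path into a treatment
carrying non-causal association.  The default graphs encode the domain
knowledge the analysis rests on — meteorology (humidity, temperature,
sea-level pressure, wind speed) drives both the pollutant treatments and the
visit outcome, pollutants interconvert (oxidant gases feed fine particulate,
fine feeds coarse, particulates feed the composite index), and an explicit
node ``U`` stands for unobserved confounders such as pollen or medication
status.  When ``U`` is allowed to point at the treatments no observed
adjustment set exists and identification honestly fails.

d-separation is decided by the ancestral moral-graph construction: restrict
to ancestors of {x, y} ∪ Z, marry co-parents, drop Z, and test undirected
reachability.  A collider therefore unblocks exactly when it (or a
descendant) is conditioned on.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

__all__ = [
    "GraphError",
    "CausalDAG",
    "d_separated",
    "backdoor_set",
    "build_multiple_treatment_dag",
    "build_single_treatment_dag",
    "TREATMENTS",
    "MET_CONFOUNDERS",
    "OUTCOME",
    "UNOBSERVED",
]

ROLES = frozenset({"treatment", "outcome", "confounder", "unobserved"})

TREATMENTS = ["visibility", "precipitation", "aqi", "pm25", "pm10", "so2", "no2", "co"]
POLLUTANT_TREATMENTS = ["aqi", "pm25", "pm10", "so2", "no2", "co"]
MET_CONFOUNDERS = ["humidity", "temperature", "sea_level_pressure", "wind_speed"]
OUTCOME = "visits"
UNOBSERVED = "U"


class GraphError(ValueError):
    """Malformed graph or query."""


@dataclass
class CausalDAG:
    """Directed acyclic graph whose nodes carry causal roles.

    ``roles`` maps every node name to one of treatment / outcome /
    confounder / unobserved; ``edges`` is a collection of ``(cause, effect)``
    pairs.  Exactly one node must carry the outcome role and the graph must
    be acyclic.  ``kind`` labels which model family the graph encodes
    (``multiple``, ``single_with_indirect``, ``single_without_indirect`` or
    ``custom``).
    """

    roles: dict[str, str]
    edges: list[tuple[str, str]]
    kind: str = "custom"

    # plain-dict adjacency caches; rebuilt on construction
    _parents: dict[str, set[str]] = field(init=False, repr=False, default_factory=dict)
    _children: dict[str, set[str]] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        for node, role in self.roles.items():
            if role not in ROLES:
                raise GraphError(f"unknown role {role!r} for node {node!r}")
        outcomes = [n for n, r in self.roles.items() if r == "outcome"]
        if len(outcomes) != 1:
            raise GraphError(f"exactly one outcome node required, got {outcomes}")
        self._parents = {n: set() for n in self.roles}
        self._children = {n: set() for n in self.roles}
        for a, b in self.edges:
            for n in (a, b):
                if n not in self.roles:
                    raise GraphError(f"edge endpoint {n!r} has no declared role")
            self._parents[b].add(a)
            self._children[a].add(b)
        if not self.is_acyclic():
            raise GraphError("graph contains a directed cycle")

    # -- basic structure ---------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return list(self.roles)

    @property
    def outcome(self) -> str:
        return next(n for n, r in self.roles.items() if r == "outcome")

    @property
    def treatments(self) -> list[str]:
        return [n for n, r in self.roles.items() if r == "treatment"]

    @property
    def unobserved(self) -> set[str]:
        return {n for n, r in self.roles.items() if r == "unobserved"}

    def parents(self, node: str) -> set[str]:
        self._require(node)
        return set(self._parents[node])

    def children(self, node: str) -> set[str]:
        self._require(node)
        return set(self._children[node])

    def _require(self, node: str) -> None:
        if node not in self.roles:
            raise GraphError(f"unknown node {node!r}")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.roles)
        g.add_edges_from(self.edges)
        return g

    def is_acyclic(self) -> bool:
        """Cycle check via Kahn's topological ordering."""
        indeg = {n: len(self._parents[n]) for n in self.roles}
        queue = [n for n, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            n = queue.pop()
            seen += 1
            for c in self._children[n]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        return seen == len(self.roles)

    def ancestors(self, nodes: Iterable[str]) -> set[str]:
        """Nodes reachable against edge direction, including the seeds."""
        out = set()
        stack = list(nodes)
        while stack:
            n = stack.pop()
            if n in out:
                continue
            out.add(n)
            stack.extend(self._parents[n])
        return out

    def descendants(self, nodes: Iterable[str]) -> set[str]:
        out = set()
        stack = list(nodes)
        while stack:
            n = stack.pop()
            if n in out:
                continue
            out.add(n)
            stack.extend(self._children[n])
        return out

    # -- serialization -----------------------------------------------------

    def to_text(self) -> str:
        lines = [f"node {n} {r}" for n, r in self.roles.items()]
        lines += [f"{a} -> {b}" for a, b in self.edges]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str, kind: str = "custom") -> "CausalDAG":
        roles: dict[str, str] = {}
        edges: list[tuple[str, str]] = []
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("node "):
                _, name, role = line.split()
                roles[name] = role
            elif "->" in line:
                a, b = (s.strip() for s in line.split("->"))
                edges.append((a, b))
            else:
                raise GraphError(f"unparseable DAG line: {line!r}")
        return cls(roles=roles, edges=edges, kind=kind)


def d_separated(dag: CausalDAG, x: str, y: str, given: Iterable[str] = ()) -> bool:
    """True iff every path between ``x`` and ``y`` is blocked given ``given``.

    Chains and forks block when their middle node is conditioned on; a
    collider blocks unless it or one of its descendants is conditioned on.
    """
    z = set(given)
    for n in (x, y, *z):
        dag._require(n)
    if x == y:
        raise GraphError("d-separation query requires distinct x and y")
    if x in z or y in z:
        raise GraphError("query nodes may not appear in the conditioning set")
    relevant = dag.ancestors({x, y} | z)
    # moralize the ancestral subgraph
    adj: dict[str, set[str]] = {n: set() for n in relevant}
    for b in relevant:
        pa = dag._parents[b] & relevant
        for a in pa:
            adj[a].add(b)
            adj[b].add(a)
        for a in pa:
            for a2 in pa:
                if a != a2:
                    adj[a].add(a2)
    # remove conditioned nodes, then test reachability
    stack = [x]
    seen = {x}
    while stack:
        n = stack.pop()
        for m in adj[n]:
            if m in z or m in seen:
                continue
            if m == y:
                return False
            seen.add(m)
            stack.append(m)
    return True


def _backdoor_graph(dag: CausalDAG, treatments: set[str]) -> CausalDAG:
    """Copy of the DAG with every edge leaving a treatment removed, so only
    backdoor (into-treatment) paths remain between treatments and outcome."""
    edges = [(a, b) for a, b in dag.edges if a not in treatments]
    return CausalDAG(roles=dict(dag.roles), edges=edges, kind=dag.kind)


def backdoor_set(
    dag: CausalDAG,
    treatments: Iterable[str] | None = None,
    outcome: str | None = None,
) -> frozenset[str] | None:
    """Canonical backdoor adjustment set, or ``None`` when not identified.

    The candidate is the set of observed, non-treatment parents of the
    treatments.  It is returned only after verifying that (a) it contains no
    descendant of any treatment and (b) in the graph with treatment-outgoing
    edges removed, each treatment is d-separated from the outcome given the
    candidate plus the remaining treatments.  If verification fails — e.g.
    an unobserved confounder points into a treatment — the effect is not
    identified by covariate adjustment and ``None`` is returned rather than
    a fabricated set.
    """
    ts = set(treatments) if treatments is not None else set(dag.treatments)
    if not ts:
        raise GraphError("treatments must be nonempty")
    y = outcome if outcome is not None else dag.outcome
    dag._require(y)
    for t in ts:
        dag._require(t)
    if y in ts:
        raise GraphError("outcome cannot also be a treatment")
    candidate = set()
    blocked_by_unobserved = False
    for t in ts:
        for p in dag._parents[t]:
            if p in ts:
                continue
            if p in dag.unobserved:
                blocked_by_unobserved = True
            else:
                candidate.add(p)
    forbidden = dag.descendants(ts)
    if candidate & forbidden:
        return None
    bd = _backdoor_graph(dag, ts)
    for t in ts:
        cond = candidate | (ts - {t})
        if not d_separated(bd, t, y, cond):
            return None
    return frozenset(candidate)


def _fig_edges(treatments: list[str]) -> list[tuple[str, str]]:
    """Shared edge content of the default graphs (node set restricted later).

    Meteorological confounders drive every treatment and the outcome;
    precipitation (itself a treatment) settles the pollutant treatments;
    oxidant gases convert into fine particulate, fine into coarse, and the
    particulates feed the composite index; every treatment points at the
    outcome (the unproven edges under test); U points at the outcome only.
    """
    edges: list[tuple[str, str]] = []
    for met in MET_CONFOUNDERS:
        for t in treatments:
            edges.append((met, t))
        edges.append((met, OUTCOME))
    for p in POLLUTANT_TREATMENTS:
        edges.append(("precipitation", p))
    edges += [
        ("so2", "pm25"),
        ("no2", "pm25"),
        ("co", "pm25"),
        ("pm25", "pm10"),
        ("pm10", "aqi"),
    ]
    for t in treatments:
        edges.append((t, OUTCOME))
    edges.append((UNOBSERVED, OUTCOME))
    return edges


def build_multiple_treatment_dag(u_affects_treatments: bool = False) -> CausalDAG:
    """Joint model: 8 treatments, 1 outcome, 4 observed meteorological
    confounders plus the unobserved confounder ``U`` (14 nodes).

    With ``u_affects_treatments=True`` the unobserved node also points at
    every treatment, in which configuration no observed adjustment set is
    valid and :func:`backdoor_set` reports not-identified.
    """
    roles = {t: "treatment" for t in TREATMENTS}
    roles.update({m: "confounder" for m in MET_CONFOUNDERS})
    roles[UNOBSERVED] = "unobserved"
    roles[OUTCOME] = "outcome"
    edges = _fig_edges(TREATMENTS)
    if u_affects_treatments:
        edges += [(UNOBSERVED, t) for t in TREATMENTS]
    return CausalDAG(roles=roles, edges=edges, kind="multiple")


def build_single_treatment_dag(
    treatment: str,
    include_indirect: bool = True,
    u_affects_treatments: bool = False,
) -> CausalDAG:
    """Single-treatment model on the same 14-node scaffold.

    One of the 8 candidate variables is the treatment; the remaining 7 plus
    the 4 meteorological variables plus ``U`` act as confounders (12 in
    total).  With ``include_indirect=False`` the four meteorological nodes —
    indirect causes that influence the treatments but are removed from the
    outcome's direct parents — are dropped entirely, leaving 8 confounders.
    """
    if treatment not in TREATMENTS:
        raise GraphError(
            f"unknown treatment {treatment!r}; expected one of {TREATMENTS}"
        )
    roles = {v: ("treatment" if v == treatment else "confounder") for v in TREATMENTS}
    roles.update({m: "confounder" for m in MET_CONFOUNDERS})
    roles[UNOBSERVED] = "unobserved"
    roles[OUTCOME] = "outcome"
    edges = _fig_edges(TREATMENTS)
    if u_affects_treatments:
        edges.append((UNOBSERVED, treatment))
    kind = "single_with_indirect"
    if not include_indirect:
        kind = "single_without_indirect"
        for m in MET_CONFOUNDERS:
            del roles[m]
        edges = [(a, b) for a, b in edges if a not in MET_CONFOUNDERS and b not in MET_CONFOUNDERS]
    return CausalDAG(roles=roles, edges=edges, kind=kind)
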