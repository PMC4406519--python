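"""Discrete Bayesian network over risk factors and complications.

Factor nodes are roots whose states are half-open bins ]lo, hi] of the
measured value; complication nodes are binary (yes/no) with a conditional
probability table (CPT) holding one row per combination of parent states.
CPT rows are filled by the naïve-Bayes combiner evaluated at each bin's
representative value, so the network is a compiled, discretised view of the
same 1-1 dose-response curves.

Queries are answered by exact enumeration of the joint distribution:
observed factors are fixed to their discretised state, unobserved factors are
summed over their population state priors, and complications are summed over
yes/no. Networks here are small (a handful of factors and complications), so
enumeration is exact and fast.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from .bayes import ClassPrior, FactorObservation, combine_posterior
from .curvefit import FittedCurve

__all__ = [
    "DiscretizationScheme",
    "NodeSpec",
    "CPT",
    "CompiledNetwork",
    "discretize_value",
    "build_cpt",
    "compile_network",
    "infer",
    "root_priors_from_marginals",
]


def _bin_label(lo: float, hi: float) -> str:
    def fmt(v: float) -> str:
        return f"{v:g}"

    return f"]{fmt(lo)}, {fmt(hi)}]"


@dataclass(frozen=True)
class DiscretizationScheme:
    """Half-open binning ]lo, hi] of one continuous factor.

    ``representative_values`` supplies the point at which the 1-1 curves are
    evaluated for each bin; defaults to bin midpoints. Open-ended ranges are
    not supported implicitly: the edges bound the covered range, and any bin
    whose midpoint is a poor summary (e.g. a wide top bin) should be given an
    explicit representative.
    """

    factor_name: str
    bin_edges: tuple[float, ...]
    representative_values: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.bin_edges)
        if len(edges) < 2:
            raise ValueError("need at least 2 bin edges")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("bin edges must be strictly increasing")
        object.__setattr__(self, "bin_edges", edges)
        reps = tuple(float(r) for r in self.representative_values)
        if not reps:
            reps = tuple((a + b) / 2.0 for a, b in zip(edges, edges[1:]))
        if len(reps) != len(edges) - 1:
            raise ValueError("one representative value per bin required")
        for r, (a, b) in zip(reps, zip(edges, edges[1:])):
            if not (a < r <= b):
                raise ValueError(
                    f"representative {r} outside its bin {_bin_label(a, b)}"
                )
        object.__setattr__(self, "representative_values", reps)

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    @property
    def state_labels(self) -> tuple[str, ...]:
        return tuple(
            _bin_label(a, b) for a, b in zip(self.bin_edges, self.bin_edges[1:])
        )

    def bin_index(self, value: float) -> int:
        edges = self.bin_edges
        if not (edges[0] < value <= edges[-1]):
            raise ValueError(
                f"value {value} outside covered range "
                f"]{edges[0]}, {edges[-1]}] for factor {self.factor_name!r}"
            )
        for i, (a, b) in enumerate(zip(edges, edges[1:])):
            if a < value <= b:
                return i
        raise AssertionError("unreachable")  # pragma: no cover

    def representative_for(self, state: str) -> float:
        return self.representative_values[self.state_labels.index(state)]


def discretize_value(value: float, scheme: DiscretizationScheme) -> str:
    """Map a continuous value to its half-open bin label ]lo, hi]."""
    return scheme.state_labels[scheme.bin_index(value)]


@dataclass(frozen=True)
class NodeSpec:
    """One network node: a root risk factor or a binary complication.

    A complication may have other complications as parents (e.g. albuminuria
    stages feeding retinopathy); ``parent_value_map`` then translates each
    parent state into a representative value on the measured scale of the
    factor the 1-1 model was fitted on (yes -> a typical albumin excretion
    rate, say), so the same curve machinery supplies the conditional.
    """

    name: str
    kind: str  # "factor" | "complication"
    states: tuple[str, ...] = ()
    parent_names: tuple[str, ...] = ()
    parent_value_map: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("factor", "complication"):
            raise ValueError("kind must be 'factor' or 'complication'")
        if self.kind == "factor" and self.parent_names:
            raise ValueError(f"factor node {self.name!r} cannot have parents")
        if self.kind == "complication":
            object.__setattr__(self, "states", ("yes", "no"))


@dataclass(frozen=True)
class CPT:
    """Conditional probability table: parent-state combination -> P(yes)."""

    node_name: str
    parent_names: tuple[str, ...]
    rows: Mapping[tuple[str, ...], float]

    def __post_init__(self) -> None:
        for combo, p in self.rows.items():
            if len(combo) != len(self.parent_names):
                raise ValueError("row key length must match parent count")
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"CPT probability {p} outside [0,1]")

    def p_yes(self, combo: tuple[str, ...]) -> float:
        return self.rows[combo]


@dataclass(frozen=True)
class CompiledNetwork:
    """A validated DAG with schemes, CPTs and root-state priors."""

    nodes: tuple[NodeSpec, ...]
    schemes: Mapping[str, DiscretizationScheme]
    cpts: Mapping[str, CPT]
    root_priors: Mapping[str, Mapping[str, float]]

    def node(self, name: str) -> NodeSpec:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes if n.kind == "factor")

    @property
    def complication_names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes if n.kind == "complication")


def build_cpt(
    node: NodeSpec,
    schemes: Mapping[str, DiscretizationScheme],
    models: Mapping[str, FittedCurve],
    prior: ClassPrior,
) -> CPT:
    """Fill one complication's CPT by sweeping all parent-state combinations.

    For each combination the parents' representative values are gathered
    (from the discretisation scheme for factor parents, from
    ``parent_value_map`` for complication parents) and handed to the
    naïve-Bayes combiner; the resulting posterior is the row's P(yes).
    """
    if node.kind != "complication":
        raise ValueError("only complication nodes carry a CPT")
    state_sets: list[tuple[str, ...]] = []
    rep_lookup: list[Mapping[str, float]] = []
    for parent in node.parent_names:
        if parent in schemes:
            sch = schemes[parent]
            state_sets.append(sch.state_labels)
            rep_lookup.append(dict(zip(sch.state_labels, sch.representative_values)))
        elif parent in node.parent_value_map:
            vmap = dict(node.parent_value_map[parent])
            state_sets.append(tuple(vmap))
            rep_lookup.append(vmap)
        else:
            raise ValueError(
                f"parent {parent!r} of {node.name!r} has neither a "
                "discretization scheme nor a parent_value_map entry"
            )
        if parent not in models:
            raise ValueError(
                f"no 1-1 model for parent {parent!r} of node {node.name!r}"
            )
    rows: dict[tuple[str, ...], float] = {}
    for combo in itertools.product(*state_sets):
        obs = [
            FactorObservation(parent, rep_lookup[i][state])
            for i, (parent, state) in enumerate(zip(node.parent_names, combo))
        ]
        rows[combo] = combine_posterior(node.name, obs, models, prior)
    return CPT(node.name, tuple(node.parent_names), rows)


def compile_network(
    nodes: Sequence[NodeSpec],
    schemes: Mapping[str, DiscretizationScheme],
    cpts: Mapping[str, CPT],
    root_priors: Mapping[str, Mapping[str, float]],
) -> CompiledNetwork:
    """Validate and assemble the network: acyclic, complete CPTs, priors sum to 1."""
    g = nx.DiGraph()
    names = [n.name for n in nodes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate node names")
    g.add_nodes_from(names)
    for n in nodes:
        for p in n.parent_names:
            if p not in names:
                raise ValueError(f"unknown parent {p!r} of node {n.name!r}")
            g.add_edge(p, n.name)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"network spec is cyclic: {cycle}")
    for n in nodes:
        if n.kind == "complication":
            if n.name not in cpts:
                raise ValueError(f"complication {n.name!r} lacks a CPT")
            expected = 1
            cpt = cpts[n.name]
            if cpt.parent_names != tuple(n.parent_names):
                raise ValueError(f"CPT parent order mismatch for {n.name!r}")
            for parent in n.parent_names:
                if parent in schemes:
                    expected *= schemes[parent].n_bins
                else:
                    expected *= len(n.parent_value_map[parent])
            if len(cpt.rows) != expected:
                raise ValueError(
                    f"CPT for {n.name!r} has {len(cpt.rows)} rows, expected {expected}"
                )
        else:
            dist = root_priors.get(n.name)
            if dist is None:
                raise ValueError(f"factor {n.name!r} lacks a root state prior")
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"state prior for {n.name!r} sums to {total}, not 1"
                )
    return CompiledNetwork(tuple(nodes), dict(schemes), dict(cpts), dict(root_priors))


def _node_states(net: CompiledNetwork, node: NodeSpec) -> tuple[str, ...]:
    if node.kind == "complication":
        return ("yes", "no")
    if node.name in net.schemes:
        return net.schemes[node.name].state_labels
    return tuple(net.root_priors[node.name])


def infer(
    network: CompiledNetwork,
    observations: Sequence[FactorObservation],
) -> dict[str, float]:
    """Exact posterior P(complication=yes) for every complication.

    Observed factors are discretised and fixed; everything else is summed
    out of the joint P = prod(root priors) * prod(CPT entries). Equivalent to
    brute-force enumeration of the full joint distribution, restricted to the
    observed evidence and normalised.
    """
    evidence: dict[str, str] = {}
    for obs in observations:
        node = network.node(obs.factor_name) if any(
            n.name == obs.factor_name for n in network.nodes
        ) else None
        if node is None or node.kind != "factor":
            raise ValueError(
                f"observation names unknown factor node {obs.factor_name!r}; "
                f"known factors: {list(network.factor_names)}"
            )
        evidence[obs.factor_name] = discretize_value(
            obs.value, network.schemes[obs.factor_name]
        )

    free_nodes = [n for n in network.nodes if n.name not in evidence]
    free_states = [_node_states(network, n) for n in free_nodes]

    total = 0.0
    yes_mass = {c: 0.0 for c in network.complication_names}
    for combo in itertools.product(*free_states):
        assignment = dict(evidence)
        assignment.update({n.name: s for n, s in zip(free_nodes, combo)})
        w = 1.0
        for n in network.nodes:
            s = assignment[n.name]
            if n.kind == "factor":
                w *= network.root_priors[n.name][s]
            else:
                key = tuple(assignment[p] for p in n.parent_names)
                p_yes = network.cpts[n.name].p_yes(key)
                w *= p_yes if s == "yes" else 1.0 - p_yes
            if w == 0.0:
                break
        total += w
        for c in yes_mass:
            if assignment[c] == "yes":
                yes_mass[c] += w
    if total <= 0.0:
        raise ValueError("evidence has zero probability under the network")
    return {c: yes_mass[c] / total for c in yes_mass}


def root_priors_from_marginals(
    marginals: Sequence, schemes: Mapping[str, DiscretizationScheme]
) -> dict[str, dict[str, float]]:
    """Map estimated FactorMarginal bins onto scheme state labels.

    Each marginal's (lo, hi] bin must match a scheme bin exactly; the result
    is the per-factor state distribution the compiled network uses for
    unobserved factors.
    """
    out: dict[str, dict[str, float]] = {}
    for m in marginals:
        scheme = schemes[m.factor_name]
        edges = scheme.bin_edges
        lo, hi = m.bin
        for i in range(scheme.n_bins):
            if abs(edges[i] - lo) < 1e-12 and abs(edges[i + 1] - hi) < 1e-12:
                out.setdefault(m.factor_name, {})[scheme.state_labels[i]] = m.p
                break
        else:
            raise ValueError(
                f"marginal bin ]{lo}, {hi}] does not match any bin of the "
                f"scheme for {m.factor_name!r}"
            )
    return out


# ---------------------------------------------------------------------------
# JSON spec round-trip (nodes, schemes, CPTs, priors)

def network_to_dict(net: CompiledNetwork) -> dict:
    return {
        "nodes": [
            {
                "name": n.name,
                "kind": n.kind,
                "parents": list(n.parent_names),
                "parent_value_map": {
                    p: dict(m) for p, m in n.parent_value_map.items()
                },
            }
            for n in net.nodes
        ],
        "schemes": {
            f: {
                "bin_edges": list(s.bin_edges),
                "representative_values": list(s.representative_values),
            }
            for f, s in net.schemes.items()
        },
        "cpts": {
            name: {
                "parents": list(cpt.parent_names),
                "rows": [
                    {"states": list(k), "p_yes": v} for k, v in cpt.rows.items()
                ],
            }
            for name, cpt in net.cpts.items()
        },
        "root_priors": {f: dict(d) for f, d in net.root_priors.items()},
    }


def network_from_dict(d: dict) -> CompiledNetwork:
    nodes = [
        NodeSpec(
            name=nd["name"],
            kind=nd["kind"],
            parent_names=tuple(nd.get("parents", ())),
            parent_value_map={
                p: dict(m) for p, m in nd.get("parent_value_map", {}).items()
            },
        )
        for nd in d["nodes"]
    ]
    schemes = {
        f: DiscretizationScheme(
            f, tuple(s["bin_edges"]), tuple(s.get("representative_values", ()))
        )
        for f, s in d.get("schemes", {}).items()
    }
    cpts = {
        name: CPT(
            name,
            tuple(c["parents"]),
            {tuple(r["states"]): float(r["p_yes"]) for r in c["rows"]},
        )
        for name, c in d.get("cpts", {}).items()
    }
    return compile_network(nodes, schemes, cpts, d.get("root_priors", {}))


def save_network(net: CompiledNetwork, path: str | Path) -> None:
    Path(path).write_text(json.dumps(network_to_dict(net), indent=2))


def load_network(path: str | Path) -> CompiledNetwork:
    return network_from_dict(json.loads(Path(path).read_text()))
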