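"""Independent brute-force oracles used to cross-check the implementation.

Everything here enumerates full joint distributions by explicit summation,
deliberately sharing no code with the package's own (also exact, but
differently organised) computations.
"""

from __future__ import annotations

import itertools

import numpy as np


# --------------------------------------------------------------------------
# naive-Bayes toy joints

def random_toy_joint(rng: np.random.Generator, n_factors: int = 3, n_values: int = 3):
    """A random joint over (class, f_1..f_n) satisfying class-conditional
    independence: P(c, v) = P(c) * prod_k P_k(v_k | c)."""
    p_yes = float(rng.uniform(0.1, 0.9))
    cond = []  # cond[k][c] = probability vector over factor values
    for _ in range(n_factors):
        tables = {}
        for c in ("yes", "no"):
            w = rng.uniform(0.05, 1.0, size=n_values)
            tables[c] = w / w.sum()
        cond.append(tables)
    return p_yes, cond


def joint_probability(p_yes, cond, c: str, values: tuple[int, ...]) -> float:
    p = p_yes if c == "yes" else 1.0 - p_yes
    for k, v in enumerate(values):
        p *= cond[k][c][v]
    return p


def brute_posterior(p_yes, cond, values: tuple[int, ...]) -> float:
    """P(yes | f=values) by direct summation of the two joint cells."""
    num = joint_probability(p_yes, cond, "yes", values)
    den = num + joint_probability(p_yes, cond, "no", values)
    return num / den


def q_from_joint(p_yes, cond, k: int, v: int) -> float:
    """Single-factor posterior q_k = P(yes | f_k = v) from the joint marginals."""
    yes = p_yes * cond[k]["yes"][v]
    no = (1.0 - p_yes) * cond[k]["no"][v]
    return yes / (yes + no)


def chain_posterior_with_marginals(qs, p_fs, p_yes) -> float:
    """The two-class Bayes chain written exactly as published, keeping the
    factor marginals P(f_k) in both class scores before normalising.

    Used to show the marginals cancel: the result must equal the
    marginal-free implementation for any positive P(f_k).
    """
    s_yes = p_yes
    s_no = 1.0 - p_yes
    for q, pf in zip(qs, p_fs):
        s_yes *= pf * q / p_yes            # P(f_k | yes)
        s_no *= pf * (1.0 - q) / (1.0 - p_yes)  # P(f_k | no)
    return s_yes / (s_yes + s_no)


# --------------------------------------------------------------------------
# Bayesian-network joints

def bn_brute_force(network, evidence: dict[str, str]) -> dict[str, float]:
    """P(complication=yes | evidence) by summation over the full joint.

    Enumerates every assignment of every node (including observed factors),
    multiplies root priors and CPT entries, discards assignments that
    contradict the evidence, and normalises.
    """
    states = {}
    for node in network.nodes:
        if node.kind == "complication":
            states[node.name] = ("yes", "no")
        elif node.name in network.schemes:
            states[node.name] = network.schemes[node.name].state_labels
        else:
            states[node.name] = tuple(network.root_priors[node.name])
    names = list(states)
    complications = [n.name for n in network.nodes if n.kind == "complication"]
    total = 0.0
    yes = {c: 0.0 for c in complications}
    for combo in itertools.product(*(states[n] for n in names)):
        a = dict(zip(names, combo))
        if any(a[f] != s for f, s in evidence.items()):
            continue
        w = 1.0
        for node in network.nodes:
            if node.kind == "factor":
                w *= network.root_priors[node.name][a[node.name]]
            else:
                row = tuple(a[p] for p in node.parent_names)
                p1 = network.cpts[node.name].rows[row]
                w *= p1 if a[node.name] == "yes" else 1.0 - p1
        total += w
        for c in complications:
            if a[c] == "yes":
                yes[c] += w
    return {c: yes[c] / total for c in complications}
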