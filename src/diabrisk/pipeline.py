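"""End-to-end orchestration: cohort -> 1-1 models -> compiled network -> scores.

Mirrors the workflow the CLI exposes, as plain functions: estimate priors
from a training cohort, build empirical dose-response tables per
factor-complication pair, fit and select the best of the seven patterns,
fill the CPTs, and score patients by exact inference.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import pandas as pd

from .bayes import ClassPrior, FactorObservation
from .cohort import binned_risk_table, estimate_priors
from .curvefit import FittedCurve, fit_all, select_best
from .network import (
    CompiledNetwork,
    DiscretizationScheme,
    NodeSpec,
    build_cpt,
    compile_network,
    infer,
    root_priors_from_marginals,
)

__all__ = ["learn_models", "learn_network", "score_cohort"]

logger = logging.getLogger(__name__)


def learn_models(
    cohort: pd.DataFrame,
    schemes: Mapping[str, DiscretizationScheme],
    structure: Mapping[str, Sequence[str]],
    min_count: int = 20,
) -> dict[str, dict[str, FittedCurve]]:
    """Best-pattern 1-1 curves for every complication -> factor edge.

    ``structure`` maps each complication to the factors that influence it.
    Each curve is fitted to the cohort's empirical binned risk table.
    """
    models: dict[str, dict[str, FittedCurve]] = {}
    for comp, factors in structure.items():
        models[comp] = {}
        for f in factors:
            table = binned_risk_table(cohort, f, comp, schemes[f], min_count)
            fits = fit_all(table)
            best = select_best(fits)
            logger.info("%s->%s: selected %s (adj R²=%.3f)",
                        f, comp, best.pattern, best.stats.wherry_adj)
            models[comp][f] = best
    return models


def learn_network(
    cohort: pd.DataFrame,
    schemes: Mapping[str, DiscretizationScheme],
    structure: Mapping[str, Sequence[str]],
    min_count: int = 20,
) -> CompiledNetwork:
    """Learn priors, 1-1 models and CPTs from a cohort; compile the network."""
    marginals, priors = estimate_priors(cohort, schemes, list(structure))
    prior_by_comp = {p.complication_name: p for p in priors}
    models = learn_models(cohort, schemes, structure, min_count)
    nodes = [NodeSpec(f, "factor") for f in schemes]
    cpts = {}
    for comp, factors in structure.items():
        node = NodeSpec(comp, "complication", parent_names=tuple(factors))
        nodes.append(node)
        cpts[comp] = build_cpt(node, schemes, models[comp], prior_by_comp[comp])
    root = root_priors_from_marginals(marginals, schemes)
    return compile_network(nodes, schemes, cpts, root)


def score_cohort(network: CompiledNetwork, cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-patient posterior P(yes) for each complication in the network."""
    rows = []
    for _, patient in cohort.iterrows():
        obs = [
            FactorObservation(f, float(patient[f]))
            for f in network.factor_names
            if f in patient.index and pd.notna(patient[f])
        ]
        rows.append(infer(network, obs))
    return pd.DataFrame(rows, index=cohort.index)
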