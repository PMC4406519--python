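import itertools

import numpy as np
import pytest

from diabrisk import (
    CPT,
    ClassPrior,
    DiscretizationScheme,
    FactorObservation,
    NodeSpec,
    build_cpt,
    compile_network,
    discretize_value,
    fit_pattern,
    infer,
    load_network,
    save_network,
    truth_curve,
)

from _oracles import bn_brute_force
from conftest import make_dataset


class TestDiscretize:
    SCHEME = DiscretizationScheme("hba1c", (7.0, 8.0, 9.0))

    @pytest.mark.parametrize(
        "value,label",
        [(7.8, "]7, 8]"), (8.0, "]7, 8]"), (8.0001, "]8, 9]"), (9.0, "]8, 9]")],
    )
    def test_half_open_bins(self, value, label):
        assert discretize_value(value, self.SCHEME) == label

    @pytest.mark.parametrize("value", [7.0, 6.5, 9.5])
    def test_out_of_range_names_covered_range(self, value):
        with pytest.raises(ValueError, match=r"\]7.0, 9.0\]"):
            discretize_value(value, self.SCHEME)

    def test_default_representatives_are_midpoints(self):
        assert self.SCHEME.representative_values == (7.5, 8.5)

    def test_representative_outside_bin_rejected(self):
        with pytest.raises(ValueError, match="outside its bin"):
            DiscretizationScheme("f", (0.0, 1.0), representative_values=(2.0,))


def _linear_models(slope=4.0, intercept=5.0, factors=("f1", "f2")):
    x = np.array([1.0, 2.0, 4.0, 8.0, 10.0])
    ds = make_dataset(x, intercept + slope * x)
    return {f: fit_pattern(ds, "linear") for f in factors}


class TestBuildCpt:
    def test_row_count_is_cartesian_product(self):
        schemes = {
            "f1": DiscretizationScheme("f1", (0.0, 2.0, 4.0, 6.0)),
            "f2": DiscretizationScheme("f2", (0.0, 5.0, 10.0)),
        }
        node = NodeSpec("comp", "complication", parent_names=("f1", "f2"))
        cpt = build_cpt(node, schemes, _linear_models(), ClassPrior("comp", 0.3))
        assert len(cpt.rows) == 6
        assert all(0.0 <= p <= 1.0 for p in cpt.rows.values())

    def test_single_parent_rows_equal_model_predictions(self):
        scheme = DiscretizationScheme("f1", (0.0, 2.0, 4.0))
        node = NodeSpec("comp", "complication", parent_names=("f1",))
        models = _linear_models(factors=("f1",))
        cpt = build_cpt(node, {"f1": scheme}, models, ClassPrior("comp", 0.3))
        for label, rep in zip(scheme.state_labels, scheme.representative_values):
            expected = models["f1"].predict(rep) / 100.0
            assert cpt.rows[(label,)] == pytest.approx(expected)

    def test_constant_models_at_prior_give_constant_rows(self):
        # q = 0.3 for both parents with p_yes = 0.3: uninformative fixed point
        schemes = {
            "f1": DiscretizationScheme("f1", (0.0, 1.0, 2.0)),
            "f2": DiscretizationScheme("f2", (0.0, 1.0, 2.0)),
        }
        flat = truth_curve("linear", (30.0, 0.0))
        node = NodeSpec("comp", "complication", parent_names=("f1", "f2"))
        cpt = build_cpt(
            node, schemes, {"f1": flat, "f2": flat}, ClassPrior("comp", 0.3)
        )
        assert all(p == pytest.approx(0.3) for p in cpt.rows.values())

    def test_missing_model_rejected(self):
        schemes = {"f1": DiscretizationScheme("f1", (0.0, 1.0))}
        node = NodeSpec("comp", "complication", parent_names=("f1",))
        with pytest.raises(ValueError, match="no 1-1 model"):
            build_cpt(node, schemes, {}, ClassPrior("comp", 0.3))

    def test_complication_parent_through_value_map(self):
        # albuminuria-style parent quantified on the AER scale
        node = NodeSpec(
            "retinopathy",
            "complication",
            parent_names=("micro",),
            parent_value_map={"micro": {"yes": 100.0, "no": 10.0}},
        )
        models = {"micro": truth_curve("linear", (5.0, 0.3))}
        cpt = build_cpt(node, {}, models, ClassPrior("retinopathy", 0.3))
        assert cpt.rows[("yes",)] == pytest.approx(0.35)  # 5 + 0.3*100 = 35%
        assert cpt.rows[("no",)] == pytest.approx(0.08)


def _toy_network(seed=0, observed_scheme=True):
    """2 factors (3 and 2 states) + 1 complication, random CPT and priors."""
    rng = np.random.default_rng(seed)
    schemes = {
        "f1": DiscretizationScheme("f1", (0.0, 1.0, 2.0, 3.0)),
        "f2": DiscretizationScheme("f2", (0.0, 5.0, 10.0)),
    }
    nodes = [
        NodeSpec("f1", "factor"),
        NodeSpec("f2", "factor"),
        NodeSpec("comp", "complication", parent_names=("f1", "f2")),
    ]
    rows = {
        combo: float(rng.uniform(0.05, 0.95))
        for combo in itertools.product(
            schemes["f1"].state_labels, schemes["f2"].state_labels
        )
    }
    cpts = {"comp": CPT("comp", ("f1", "f2"), rows)}

    def rand_dist(labels):
        w = rng.uniform(0.1, 1.0, size=len(labels))
        w /= w.sum()
        return dict(zip(labels, w))

    priors = {
        "f1": rand_dist(schemes["f1"].state_labels),
        "f2": rand_dist(schemes["f2"].state_labels),
    }
    return compile_network(nodes, schemes, cpts, priors)


def _chain_network(seed=0):
    """factor -> comp1 -> comp2 (complication parent), 4 states on the factor."""
    rng = np.random.default_rng(seed)
    schemes = {"f": DiscretizationScheme("f", (0.0, 1.0, 2.0, 3.0, 4.0))}
    nodes = [
        NodeSpec("f", "factor"),
        NodeSpec("comp1", "complication", parent_names=("f",)),
        NodeSpec(
            "comp2",
            "complication",
            parent_names=("comp1",),
            parent_value_map={"comp1": {"yes": 1.0, "no": 0.0}},
        ),
    ]
    labels = schemes["f"].state_labels
    cpts = {
        "comp1": CPT(
            "comp1", ("f",),
            {(s,): float(rng.uniform(0.05, 0.95)) for s in labels},
        ),
        "comp2": CPT(
            "comp2", ("comp1",),
            {("yes",): float(rng.uniform(0.3, 0.9)), ("no",): float(rng.uniform(0.05, 0.3))},
        ),
    }
    w = rng.uniform(0.1, 1.0, size=len(labels))
    priors = {"f": dict(zip(labels, w / w.sum()))}
    return compile_network(nodes, schemes, cpts, priors)


class TestInference:
    @pytest.mark.parametrize("seed", range(5))
    def test_no_evidence_matches_brute_force(self, seed):
        net = _toy_network(seed)
        result = infer(net, [])
        oracle = bn_brute_force(net, {})
        assert result["comp"] == pytest.approx(oracle["comp"], abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_partial_evidence_matches_brute_force(self, seed):
        net = _toy_network(seed)
        obs = [FactorObservation("f1", 1.5)]  # f2 marginalised
        result = infer(net, obs)
        oracle = bn_brute_force(net, {"f1": "]1, 2]"})
        assert result["comp"] == pytest.approx(oracle["comp"], abs=1e-12)

    def test_all_parents_observed_equals_cpt_row(self):
        net = _toy_network(3)
        obs = [FactorObservation("f1", 0.5), FactorObservation("f2", 7.0)]
        result = infer(net, obs)
        assert result["comp"] == pytest.approx(
            net.cpts["comp"].rows[("]0, 1]", "]5, 10]")], abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_complication_parent_chain_matches_brute_force(self, seed):
        net = _chain_network(seed)
        for evidence in ({}, {"f": "]2, 3]"}):
            obs = [FactorObservation("f", 2.5)] if evidence else []
            result = infer(net, obs)
            oracle = bn_brute_force(net, evidence)
            for c in ("comp1", "comp2"):
                assert result[c] == pytest.approx(oracle[c], abs=1e-12)

    def test_conditioning_consistency(self):
        # observing F=s equals the unobserved joint restricted to F=s
        net = _toy_network(7)
        oracle = bn_brute_force(net, {"f2": "]0, 5]"})
        result = infer(net, [FactorObservation("f2", 2.0)])
        assert result["comp"] == pytest.approx(oracle["comp"], abs=1e-12)

    def test_unknown_factor_rejected(self):
        net = _toy_network(0)
        with pytest.raises(ValueError, match="unknown factor"):
            infer(net, [FactorObservation("nope", 1.0)])

    def test_probabilities_within_unit_interval(self):
        net = _chain_network(1)
        for obs in ([], [FactorObservation("f", 0.5)]):
            assert all(0.0 <= p <= 1.0 for p in infer(net, obs).values())


class TestCompileValidation:
    def test_cycle_rejected(self):
        nodes = [
            NodeSpec("a", "complication", parent_names=("b",),
                     parent_value_map={"b": {"yes": 1.0, "no": 0.0}}),
            NodeSpec("b", "complication", parent_names=("a",),
                     parent_value_map={"a": {"yes": 1.0, "no": 0.0}}),
        ]
        cpts = {
            "a": CPT("a", ("b",), {("yes",): 0.5, ("no",): 0.5}),
            "b": CPT("b", ("a",), {("yes",): 0.5, ("no",): 0.5}),
        }
        with pytest.raises(ValueError, match="cyclic"):
            compile_network(nodes, {}, cpts, {})

    def test_missing_cpt_rejected(self):
        nodes = [NodeSpec("c", "complication")]
        with pytest.raises(ValueError, match="lacks a CPT"):
            compile_network(nodes, {}, {}, {})

    def test_priors_must_sum_to_one(self):
        nodes = [NodeSpec("f", "factor")]
        schemes = {"f": DiscretizationScheme("f", (0.0, 1.0, 2.0))}
        with pytest.raises(ValueError, match="sums to"):
            compile_network(nodes, schemes, {}, {"f": {"]0, 1]": 0.5, "]1, 2]": 0.6}})

    def test_json_round_trip(self, tmp_path):
        net = _toy_network(2)
        path = tmp_path / "net.json"
        save_network(net, path)
        back = load_network(path)
        assert infer(back, []) == pytest.approx(infer(net, []))
        obs = [FactorObservation("f1", 2.5), FactorObservation("f2", 1.0)]
        assert infer(back, obs) == pytest.approx(infer(net, obs))
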