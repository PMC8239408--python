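"""Tests of activity inference, the coefficient fit, NPA, and the companion
statistics, including brute-force minimisation of the consistency functional
as an independent oracle for the sparse linear-system solution."""

import numpy as np
import pytest
from scipy.optimize import minimize

from causalnpa import (
    ExpressionProfile,
    FitConfig,
    ModelError,
    ScoringError,
    TranscriptLayer,
    attach_transcript_layer,
    compute_npa,
    confidence_interval,
    fit_coefficients,
    infer_activities,
    k_statistic,
    node_contributions,
    npa_fold_change,
    o_statistic,
    score,
)
from causalnpa.npa_scoring import consistency_functional
from causalnpa.synthetic_data import generate_model, generate_profile

from conftest import chain_network


def brute_force_fit(model, act, lam=1.0):
    """Minimise J(c) numerically, independent of the linear-system path."""
    nodes = model.network.node_ids()
    index = {n: i for i, n in enumerate(nodes)}

    def objective(c):
        j = 0.0
        for e in model.network.scoring_edges():
            j += e.weight * (c[index[e.target]] - e.sign * c[index[e.source]]) ** 2
        for inode, a in act.values.items():
            j += lam * (c[index[inode]] - a) ** 2
        return j

    x0 = np.zeros(len(nodes))
    res = minimize(objective, x0, method="L-BFGS-B", tol=1e-14)
    return dict(zip(nodes, res.x))


def _single_node_model(activity_gene_beta=0.5):
    net = chain_network([])  # one node, no edges
    layer = TranscriptLayer({"p(SYN:x0)": [("G1", 1)]})
    model = attach_transcript_layer(net, layer)
    profile = ExpressionProfile({"G1": (activity_gene_beta, 0.0)})
    return model, profile


class TestActivities:
    def test_signed_mean(self):
        model, _ = _single_node_model()
        layer = TranscriptLayer({"p(SYN:x0)": [("G1", 1), ("G2", -1)]})
        model = attach_transcript_layer(model.network, layer)
        profile = ExpressionProfile({"G1": (2.0, 0.0), "G2": (-2.0, 0.0)})
        act = infer_activities(model, profile)
        assert act.values["p(SYN:x0)"] == pytest.approx(2.0)

    def test_all_zero_betas_give_zero_activity(self):
        model, _ = _single_node_model()
        act = infer_activities(model, ExpressionProfile({"G1": (0.0, 0.0)}))
        assert act.values["p(SYN:x0)"] == 0.0

    def test_unmeasured_genes_skipped_with_coverage(self):
        net = chain_network([])
        layer = TranscriptLayer({"p(SYN:x0)": [("G1", 1), ("G2", 1)]})
        model = attach_transcript_layer(net, layer)
        act = infer_activities(model, ExpressionProfile({"G1": (1.0, 0.0), "OTHER": (3.0, 0.0)}))
        assert act.values["p(SYN:x0)"] == pytest.approx(1.0)
        assert act.coverage["p(SYN:x0)"] == (1, 2)

    def test_no_overlap_errors(self):
        model, _ = _single_node_model()
        with pytest.raises(ScoringError, match="overlap"):
            infer_activities(model, ExpressionProfile({"ZZZ": (1.0, 0.0)}))


class TestFit:
    def test_isolated_anchor_recovers_activity(self):
        model, profile = _single_node_model(0.5)
        coeff = fit_coefficients(model, infer_activities(model, profile))
        assert coeff.values["p(SYN:x0)"] == pytest.approx(0.5, abs=1e-6)

    def test_consistent_propagation_along_positive_edge(self):
        net = chain_network([1])
        layer = TranscriptLayer({"p(SYN:x0)": [("G1", 1)]})
        model = attach_transcript_layer(net, layer)
        act = infer_activities(model, ExpressionProfile({"G1": (1.0, 0.0)}))
        coeff = fit_coefficients(model, act)
        assert coeff.values["p(SYN:x0)"] == pytest.approx(1.0, abs=1e-6)
        assert coeff.values["p(SYN:x1)"] == pytest.approx(1.0, abs=1e-6)
        assert consistency_functional(model, act, coeff) == pytest.approx(0.0, abs=1e-8)

    def test_sign_conflict_analytic_value(self, two_node_conflict_model):
        """Negative edge with both anchors at +1: normal equations give c = 1/3."""
        model, profile = two_node_conflict_model
        coeff = fit_coefficients(model, infer_activities(model, profile))
        assert coeff.values["p(SYN:x0)"] == pytest.approx(1 / 3, abs=1e-6)
        assert coeff.values["p(SYN:x1)"] == pytest.approx(1 / 3, abs=1e-6)
        assert compute_npa(coeff) == pytest.approx(1 / 9, abs=1e-6)

    def test_unanchored_component_reported_and_zero(self):
        net = chain_network([1])  # x0 -> x1
        net2 = chain_network([1], prefix="y")
        for node in net2.nodes.values():
            net.add_node(node)
        for e in net2.edges:
            net.add_edge(e.source, e.target, e.sign, evidence=[{}])
        layer = TranscriptLayer({"p(SYN:x0)": [("G1", 1)]})
        model = attach_transcript_layer(net, layer)
        coeff = fit_coefficients(model, infer_activities(model, ExpressionProfile({"G1": (1.0, 0.0)})))
        assert coeff.unanchored_components == (frozenset({"p(SYN:y0)", "p(SYN:y1)"}),)
        assert coeff.values["p(SYN:y0)"] == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_minimisation(self, seed):
        """Linear-system solution equals numeric minimisation of J on random models."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        model = generate_model(n_nodes=n, n_edges=min(n + 2, n * (n - 1)), frac_inodes=0.6,
                               genes_per_inode=3, seed=seed, acyclic=False)
        profile, _ = generate_profile(model, mode="consistent", tau=0.3, seed=seed + 100)
        act = infer_activities(model, profile)
        coeff = fit_coefficients(model, act)
        oracle = brute_force_fit(model, act)
        for node in model.network.nodes:
            assert coeff.values[node] == pytest.approx(oracle[node], abs=1e-6)


class TestNpa:
    def test_unit_coefficients(self):
        assert compute_npa({"a": 1.0, "b": 1.0}) == pytest.approx(1.0)

    def test_all_zero(self):
        assert compute_npa({"a": 0.0, "b": 0.0}) == 0.0
        assert node_contributions({"a": 0.0}) is None

    def test_conflict_example_value(self):
        assert compute_npa({"a": 1 / 3, "b": 1 / 3}) == pytest.approx(1 / 9)

    def test_contributions_sum_to_one(self):
        contrib = node_contributions({"a": 1.0, "b": 2.0, "c": 0.0})
        assert sum(contrib.values()) == pytest.approx(1.0)
        assert contrib["b"] == pytest.approx(4 / 5)


class TestInvariances:
    @pytest.mark.parametrize("alpha", [0.5, 2.0, -1.0])
    def test_scaling_and_sign_flip(self, alpha):
        model = generate_model(n_nodes=8, n_edges=8, seed=11, acyclic=False)
        profile, _ = generate_profile(model, mode="consistent", tau=0.2, seed=12)
        scaled = ExpressionProfile({g: (alpha * b, v) for g, (b, v) in profile.data.items()})
        c1 = fit_coefficients(model, infer_activities(model, profile))
        c2 = fit_coefficients(model, infer_activities(model, scaled))
        for node in c1.values:
            assert c2.values[node] == pytest.approx(alpha * c1.values[node], abs=1e-9)
        assert compute_npa(c2) == pytest.approx(alpha**2 * compute_npa(c1), rel=1e-9)

    def test_npa_nonnegative_and_zero_iff_all_zero(self):
        model = generate_model(n_nodes=6, n_edges=5, seed=2)
        profile, _ = generate_profile(model, mode="null", tau=0.5, seed=3)
        coeff = fit_coefficients(model, infer_activities(model, profile))
        npa = compute_npa(coeff)
        assert npa >= 0
        if npa == 0:
            assert all(v == 0 for v in coeff.values.values())


class TestConfidenceInterval:
    def test_zero_variance_degenerates_to_point(self, two_node_conflict_model):
        model, profile = two_node_conflict_model
        cfg = FitConfig(ci_draws=50, seed=4)
        lo, hi = confidence_interval(model, profile, cfg)
        npa = compute_npa(fit_coefficients(model, infer_activities(model, profile), cfg))
        assert lo == pytest.approx(npa, abs=1e-9)
        assert hi == pytest.approx(npa, abs=1e-9)

    def test_seeded_reproducibility(self):
        model = generate_model(seed=5)
        profile, _ = generate_profile(model, tau=0.2, seed=6)
        cfg = FitConfig(ci_draws=100, seed=7)
        assert confidence_interval(model, profile, cfg) == confidence_interval(model, profile, cfg)

    def test_width_nondecreasing_in_variance_scale(self):
        model = generate_model(seed=8)
        profile, _ = generate_profile(model, tau=0.0, seed=9)
        widths = []
        for tau2 in (0.01, 0.1, 1.0):
            scaled = ExpressionProfile({g: (b, tau2) for g, (b, _) in profile.data.items()})
            lo, hi = confidence_interval(model, scaled, FitConfig(ci_draws=400, seed=10))
            widths.append(hi - lo)
        assert widths[0] <= widths[1] <= widths[2]

    def test_too_few_draws_rejected(self, two_node_conflict_model):
        model, profile = two_node_conflict_model
        with pytest.raises(ModelError):
            confidence_interval(model, profile, FitConfig(ci_draws=1))


class TestPermutationStatistics:
    def test_o_all_zero_profile_gives_p_one(self):
        model = generate_model(seed=20)
        genes = {g for sig in model.layer.signatures.values() for g, _ in sig}
        profile = ExpressionProfile({g: (0.0, 0.0) for g in genes})
        p, null = o_statistic(model, profile, FitConfig(permutations=50, seed=21))
        assert p == 1.0
        assert np.allclose(null, 0.0)

    def test_o_seeded_reproducibility(self):
        model = generate_model(seed=22)
        profile, _ = generate_profile(model, tau=0.2, seed=23)
        cfg = FitConfig(permutations=50, seed=24)
        p1, null1 = o_statistic(model, profile, cfg)
        p2, null2 = o_statistic(model, profile, cfg)
        assert p1 == p2
        assert np.array_equal(null1, null2)

    def test_o_universe_smaller_than_signature_errors(self):
        net = chain_network([])
        layer = TranscriptLayer({"p(SYN:x0)": [("G1", 1), ("G2", 1), ("G3", 1)]})
        model = attach_transcript_layer(net, layer)
        profile = ExpressionProfile({"G1": (1.0, 0.0), "G2": (1.0, 0.0)})
        with pytest.raises(ScoringError, match="universe"):
            o_statistic(model, profile, FitConfig(permutations=10, seed=0))

    def test_k_single_edge_network_is_invariant(self, two_node_conflict_model):
        """With one scoring edge the target permutation is the identity."""
        model, profile = two_node_conflict_model
        p, null = k_statistic(model, profile, FitConfig(permutations=50, seed=25))
        assert p == 1.0
        assert np.allclose(null, null[0])

    def test_k_no_scoring_edges_errors(self):
        net = chain_network([])
        layer = TranscriptLayer({"p(SYN:x0)": [("G1", 1)]})
        model = attach_transcript_layer(net, layer)
        with pytest.raises(ScoringError):
            k_statistic(model, ExpressionProfile({"G1": (1.0, 0.0)}), FitConfig(permutations=10, seed=0))

    def test_k_seeded_reproducibility(self):
        model = generate_model(seed=26)
        profile, _ = generate_profile(model, tau=0.2, seed=27)
        cfg = FitConfig(permutations=50, seed=28)
        p1, null1 = k_statistic(model, profile, cfg)
        p2, null2 = k_statistic(model, profile, cfg)
        assert p1 == p2
        assert np.array_equal(null1, null2)

    def test_pvalues_have_add_one_bounds(self):
        model = generate_model(seed=29)
        profile, _ = generate_profile(model, tau=0.1, seed=30)
        cfg = FitConfig(permutations=40, ci_draws=10, seed=31)
        result = score(model, profile, cfg)
        n = cfg.permutations
        for p in (result.p_o, result.p_k):
            assert 1 / (n + 1) <= p <= 1.0


class TestFoldChange:
    def _result(self, npa, ci=None):
        from causalnpa.npa_scoring import CoefficientMap, ScoreResult

        return ScoreResult(npa=npa, ci=ci or (npa, npa), p_o=1.0, p_k=1.0,
                           coefficients=CoefficientMap(values={}), contributions=None,
                           config=FitConfig())

    def test_identical_scores_give_fold_one(self):
        r = self._result(2.0)
        fold, _ = npa_fold_change(r, r)
        assert fold == pytest.approx(1.0)

    def test_division_and_ci_scaling(self):
        fold, ci = npa_fold_change(self._result(3.0, (2.0, 4.0)), self._result(2.0))
        assert fold == pytest.approx(1.5)
        assert ci == pytest.approx((1.0, 2.0))

    def test_zero_control_errors(self):
        with pytest.raises(ScoringError, match="control"):
            npa_fold_change(self._result(1.0), self._result(0.0))
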