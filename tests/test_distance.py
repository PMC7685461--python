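"""Design points, mixed-kernel PDPF estimation, and Hellinger distances."""

import numpy as np
import pytest

from emt import distance as dist
from emt.parameters import ParameterBuilder, ParamKey


class TestDesignPoints:
    def test_binary_node_is_uniform(self, bernoulli_submodel):
        spec, _ = bernoulli_submodel(0.5)
        design = dist.draw_design_points(spec, 1000, seed=0)
        freq = np.mean([v == 1 for v in design.columns["U"]])
        assert abs(freq - 0.5) < 3 * np.sqrt(0.25 / 1000)

    def test_single_point_inside_box(self, gaussian_submodel):
        spec, _ = gaussian_submodel(0.0, rng=(-2.0, 2.0))
        design = dist.draw_design_points(spec, 1, seed=4)
        assert -2.0 <= design.columns["U"][0] <= 2.0

    def test_seed_reproducibility(self, gaussian_submodel):
        spec, _ = gaussian_submodel(0.0)
        a = dist.draw_design_points(spec, 50, seed=7)
        b = dist.draw_design_points(spec, 50, seed=7)
        assert a.matches(b)

    def test_unbounded_continuous_node_errors(self):
        from emt.influence import ChanceNodeSpec, SubmodelSpec

        spec = SubmodelSpec(
            id="ecosys", role="ecosystem",
            nodes=(ChanceNodeSpec("U", "continuous"),), output_metrics=("U",),
        )
        with pytest.raises(ValueError, match="range"):
            dist.draw_design_points(spec, 10, seed=0)


class TestPdpfEstimate:
    def test_discrete_indicator_behaviour(self, bernoulli_submodel):
        spec, _ = bernoulli_submodel(0.5)
        design = dist.draw_design_points(spec, 200, seed=1)
        draws = {"U": np.array([1] * 1000, dtype=object)}
        est = dist.estimate_pdpf(draws, design)
        at_one = np.array([v == 1 for v in design.columns["U"]])
        assert np.all(est.values[at_one] == 1.0)
        assert np.all(est.values[~at_one] == 0.0)

    def test_standard_normal_density_at_zero(self, gaussian_submodel):
        spec, b = gaussian_submodel(0.0)
        draws = dist.submodel_draws(spec, b, {}, 100_000, seed=2)
        design = dist.DesignSample(
            {"U": np.array([0.0])}, {"U": "continuous"}, q=1.0 / 14.0, seed=0
        )
        est = dist.estimate_pdpf(draws, design)
        assert est.values[0] == pytest.approx(1.0 / np.sqrt(2 * np.pi), rel=0.05)

    def test_bernoulli_frequency(self, bernoulli_submodel):
        spec, b = bernoulli_submodel(0.3)
        draws = dist.submodel_draws(spec, b, {}, 100_000, seed=3)
        design = dist.DesignSample(
            {"U": np.array([1], dtype=object)}, {"U": "discrete"}, q=0.5, seed=0
        )
        est = dist.estimate_pdpf(draws, design)
        assert abs(est.values[0] - 0.3) < 3 * np.sqrt(0.21 / 100_000)

    def test_zero_variance_falls_back_to_min_bandwidth(self, gaussian_submodel):
        spec, _ = gaussian_submodel(0.0)
        design = dist.draw_design_points(spec, 10, seed=1)
        est = dist.estimate_pdpf({"U": np.zeros(100)}, design)
        assert np.all(np.isfinite(est.values))


class TestHellinger:
    def test_identical_estimates_give_zero(self, bernoulli_submodel):
        spec, b = bernoulli_submodel(0.4)
        design = dist.draw_design_points(spec, 100, seed=0)
        draws = dist.submodel_draws(spec, b, {}, 500, seed=1)
        pf = dist.estimate_pdpf(draws, design)
        assert dist.hellinger(pf, pf) == 0.0

    def test_bernoulli_closed_form_exact(self, bernoulli_submodel):
        s1, b1 = bernoulli_submodel(0.2)
        _, b2 = bernoulli_submodel(0.8)
        p1 = dist.exact_pdpf(s1, b1, {})
        p2 = dist.exact_pdpf(s1, b2, {})
        # Delta^2 = 1 - (sqrt(p1 p2) + sqrt((1-p1)(1-p2))) = 1 - 2 sqrt(0.16) = 0.2
        assert dist.hellinger_exact(p1, p2) == pytest.approx(np.sqrt(0.2), abs=1e-12)

    def test_gaussian_closed_form(self, gaussian_submodel):
        mu = 1.0
        s0, b0 = gaussian_submodel(0.0)
        _, b1 = gaussian_submodel(mu)
        design = dist.draw_design_points(s0, 2000, seed=11)
        d0 = dist.submodel_draws(s0, b0, {}, 20_000, seed=21)
        d1 = dist.submodel_draws(s0, b1, {}, 20_000, seed=22)
        est = dist.hellinger(dist.estimate_pdpf(d0, design), dist.estimate_pdpf(d1, design))
        closed = np.sqrt(1.0 - np.exp(-(mu**2) / 8.0))
        assert est == pytest.approx(closed, abs=0.02)

    def test_symmetry(self, bernoulli_submodel):
        s, b1 = bernoulli_submodel(0.3)
        _, b2 = bernoulli_submodel(0.6)
        design = dist.draw_design_points(s, 500, seed=5)
        pf1 = dist.estimate_pdpf(dist.submodel_draws(s, b1, {}, 2000, seed=6), design)
        pf2 = dist.estimate_pdpf(dist.submodel_draws(s, b2, {}, 2000, seed=7), design)
        assert dist.hellinger(pf1, pf2) == dist.hellinger(pf2, pf1)

    def test_range_clamped_to_unit_interval(self):
        design = dist.DesignSample(
            {"U": np.array([0, 1], dtype=object)}, {"U": "discrete"}, q=0.5, seed=0
        )
        pf1 = dist.PdpfEstimate(np.array([10.0, 0.0]), design, {}, 1)
        pf2 = dist.PdpfEstimate(np.array([0.0, 10.0]), design, {}, 1)
        assert 0.0 <= dist.hellinger(pf1, pf2) <= 1.0

    def test_mismatched_designs_error(self, bernoulli_submodel):
        s, b = bernoulli_submodel(0.5)
        d1 = dist.draw_design_points(s, 100, seed=1)
        d2 = dist.draw_design_points(s, 100, seed=2)
        pf1 = dist.estimate_pdpf(dist.submodel_draws(s, b, {}, 500, seed=3), d1)
        pf2 = dist.estimate_pdpf(dist.submodel_draws(s, b, {}, 500, seed=3), d2)
        with pytest.raises(ValueError, match="design"):
            dist.hellinger(pf1, pf2)


class TestEuclideanAgreement:
    def _vec(self, values, active=True):
        builder = ParameterBuilder()
        for i, v in enumerate(values):
            builder.add(ParamKey("g", (), f"x{i}"), v, "grp")
        out = builder.build()
        out.active[:] = active
        return out

    def test_equal_vectors_give_zero(self):
        a = self._vec([0.1, 0.5])
        assert dist.euclidean_agreement(a, a.copy()) == 0.0

    def test_single_active_difference(self):
        a = self._vec([0.1])
        b = self._vec([0.4])
        assert dist.euclidean_agreement(a, b) == pytest.approx(-0.3)

    def test_random_vector_matches_norm_oracle(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=40), rng.normal(size=40)
        a, b = self._vec(x), self._vec(y)
        oracle = -np.sqrt(sum((xi - yi) ** 2 for xi, yi in zip(x, y)))
        assert dist.euclidean_agreement(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_index_mismatch_errors(self):
        a = self._vec([0.1])
        builder = ParameterBuilder()
        builder.add(ParamKey("other", (), "y"), 0.1, "grp")
        with pytest.raises(ValueError, match="mismatch"):
            dist.euclidean_agreement(a, builder.build())
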