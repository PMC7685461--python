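"""Agreement functions gS, gH and the composite gCA."""

import numpy as np
import pandas as pd
import pytest

from emt import agreement as agr
from emt import models
from emt.data import ActionsDataset
from emt.influence import OutCombination, SimulationRecord, SimulatorSpec


def record_from(times, postings, metric_names=(), metric_means=None):
    mm = (np.zeros((len(times), len(metric_names)))
          if metric_means is None else np.asarray(metric_means, dtype=float))
    return SimulationRecord(np.asarray(times, float), postings, tuple(metric_names),
                            mm, mc_reals=1, seed=0)


def dataset(rows, metrics=None, codes=("krr", "kep", "uep", "ecosys")):
    frame = pd.DataFrame(rows, columns=["time", "group", "action", "target"])
    met = None
    if metrics is not None:
        met = pd.DataFrame(metrics, columns=["time", "metric", "value"])
    return ActionsDataset(frame, met, codes)


class TestSampleGroupAgreement:
    def test_perfect_match_gives_one(self):
        post = [[("krr", OutCombination("poach", "ecosys"))]] * 3
        rec = record_from([0.0, 1.0, 2.0], post)
        ds = dataset([(t, "krr", "poach", "ecosys") for t in (0.0, 1.0, 2.0)])
        g, table = agr.g_sample_group(rec, ds)
        assert g == 1.0

    def test_case_study_fraction(self):
        # 15 matches of 24 observations -> 0.625
        assert agr.match_fraction(24, 15) == pytest.approx(0.625, abs=1e-12)

    def test_hand_marked_three_groups_four_times(self):
        times = [0.0, 1.0, 2.0, 3.0]
        sim_actions = {
            "krr": ["poach", "poach", "farm", "poach"],
            "kep": ["report", "park", "report", "report"],
            "uep": ["a", "a", "a", "a"],
        }
        post = [
            [(g, OutCombination(sim_actions[g][i], "x")) for g in sim_actions]
            for i in range(4)
        ]
        rec = record_from(times, post)
        obs = {
            "krr": ["poach", "farm", "farm", "poach"],  # 3 matches
            "kep": ["report", "report", "report", "report"],  # 3 matches
            "uep": ["a", "b", "b", "b"],  # 1 match
        }
        rows = [(t, g, obs[g][i], "x") for i, t in enumerate(times) for g in obs]
        ds = dataset(sorted(rows), codes=("krr", "kep", "uep"))
        g, table = agr.g_sample_group(rec, ds)
        assert g == pytest.approx(7 / 12, abs=1e-12)

    def test_no_group_records_errors(self):
        rec = record_from([0.0], [[]])
        ds = dataset([(0.0, "krr", "poach", "x")]).take_records([])
        with pytest.raises(ValueError, match="undefined"):
            agr.g_sample_group(rec, ds)

    def test_record_order_invariance(self):
        post = [[("krr", OutCombination("poach", "x")), ("kep", OutCombination("r", "y"))]] * 2
        rec = record_from([0.0, 1.0], post)
        rows = [(0.0, "krr", "poach", "x"), (0.0, "kep", "q", "y"),
                (1.0, "krr", "farm", "x"), (1.0, "kep", "r", "y")]
        g1, _ = agr.g_sample_group(rec, dataset(rows))
        g2, _ = agr.g_sample_group(rec, dataset([rows[1], rows[0], rows[3], rows[2]]))
        assert g1 == g2


class TestSampleEcoAgreement:
    def test_perfect_match_gives_one(self):
        rec = record_from([0.0, 1.0], [[], []], ("z",), [[3.0], [4.0]])
        ds = dataset([(0.0, "krr", "a", "b")],
                     metrics=[(0.0, "z", 3.0), (1.0, "z", 4.0)])
        assert agr.g_sample_eco(rec, ds) == pytest.approx(1.0)

    def test_hand_arithmetic_single_metric(self):
        # z = (0, 10), zhat = (2, 6): 1 - (0.2 + 0.4)/2 = 0.7
        rec = record_from([0.0, 1.0], [[], []], ("z",), [[2.0], [6.0]])
        ds = dataset([(0.0, "krr", "a", "b")],
                     metrics=[(0.0, "z", 0.0), (1.0, "z", 10.0)])
        assert agr.g_sample_eco(rec, ds) == pytest.approx(0.7, abs=1e-12)

    def test_two_metric_spreadsheet_oracle(self):
        z = {"z1": [0.0, 4.0, 2.0], "z2": [10.0, 20.0, 15.0]}
        zh = {"z1": [1.0, 3.0, 2.0], "z2": [12.0, 16.0, 15.0]}
        rec = record_from(
            [0.0, 1.0, 2.0], [[], [], []], ("z1", "z2"),
            np.column_stack([zh["z1"], zh["z2"]]),
        )
        mets = [(t, m, z[m][i]) for i, t in enumerate([0.0, 1.0, 2.0]) for m in z]
        ds = dataset([(0.0, "krr", "a", "b")], metrics=mets)
        # hand oracle: R1 = 4, R2 = 10
        errs = [1 / 4, 1 / 4, 0.0, 2 / 10, 4 / 10, 0.0]
        oracle = 1.0 - np.mean(errs)
        assert agr.g_sample_eco(rec, ds) == pytest.approx(oracle, abs=1e-12)

    def test_zero_range_metric_excluded(self):
        rec = record_from([0.0, 1.0], [[], []], ("z", "flat"),
                          [[2.0, 1.0], [6.0, 1.0]])
        ds = dataset([(0.0, "krr", "a", "b")],
                     metrics=[(0.0, "z", 0.0), (1.0, "z", 10.0),
                              (0.0, "flat", 1.0), (1.0, "flat", 1.0)])
        assert agr.g_sample_eco(rec, ds) == pytest.approx(0.7, abs=1e-12)


class TestHypothesisAgreement:
    def test_identity_gives_one_in_exact_mode(self, group_only):
        sim, b = group_only
        overall, per_id = agr.g_hypothesis(b, b.copy(), sim)
        assert overall == 1.0
        assert per_id["krr"] == 1.0

    def test_single_combination_formula(self, bernoulli_submodel):
        # one ID, known Delta -> gH = 1 - Delta
        from emt.distance import exact_pdpf, hellinger_exact

        s, b1 = bernoulli_submodel(0.2)
        _, b2 = bernoulli_submodel(0.8)
        sim = SimulatorSpec(groups=(), ecosystem=s)
        delta = hellinger_exact(exact_pdpf(s, b1, {}), exact_pdpf(s, b2, {}))
        overall, _ = agr.g_hypothesis(b1, b2, sim)
        assert overall == pytest.approx(1.0 - delta, abs=1e-12)

    def test_two_id_hand_oracle(self):
        # two scenario groups; per-ID distance identical across the l_i
        # conditioning combinations (the scenario CPT ignores the decision
        # nodes), so gH^(i) = 1 - Delta_i and gH = mean of the two
        from emt.distance import hellinger_exact
        from emt.influence import build_parameter_vector

        g1, h1 = models.scenario_group("krr", ("a", "b"), "x", (0.3, 0.7))
        g2, h2 = models.scenario_group("kep", ("c", "d"), "x", (0.5, 0.5))
        sim = SimulatorSpec(groups=(g1, g2))
        b_h = build_parameter_vector(sim.submodels, {"krr": h1, "kep": h2})
        b = build_parameter_vector(
            sim.submodels,
            {"krr": {"scenario": (0.6, 0.4), "oga": None},
             "kep": {"scenario": (0.2, 0.8), "oga": None}},
        )
        d1 = hellinger_exact({0: 0.6, 1: 0.4}, {0: 0.3, 1: 0.7})
        d2 = hellinger_exact({0: 0.2, 1: 0.8}, {0: 0.5, 1: 0.5})
        oracle = np.mean([1 - d1, 1 - d2])
        overall, per_id = agr.g_hypothesis(b, b_h, sim)
        assert overall == pytest.approx(oracle, abs=1e-12)


class TestComposite:
    def _pieces(self, group_only):
        sim, b_h = group_only
        _, b = models.group_only_simulator(probs=(0.5, 0.3, 0.2))
        b.active[:] = True
        post = [[("krr", OutCombination("poach", "ecosys"))]] * 2
        rec = record_from([0.0, 1.0], post)
        ds = dataset([(0.0, "krr", "poach", "ecosys"), (1.0, "krr", "farm", "ecosys")],
                     codes=("krr",))
        return sim, b, b_h, rec, ds

    def test_ch_zero_reduces_to_msde(self, group_only):
        sim, b, b_h, rec, ds = self._pieces(group_only)
        br = agr.g_ca(b, b_h, rec, ds, sim, cH=0.0, mode="hellinger")
        assert br.gCA == pytest.approx(br.gS, abs=1e-12)

    def test_ch_one_at_hypothesis_is_one(self, group_only):
        sim, _, b_h, rec, ds = self._pieces(group_only)
        br = agr.g_ca(b_h, b_h.copy(), rec, ds, sim, cH=1.0, mode="hellinger")
        assert br.gCA == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("cH", [0.25, 0.5, 0.99])
    def test_affine_in_ch(self, group_only, cH):
        sim, b, b_h, rec, ds = self._pieces(group_only)
        br = agr.g_ca(b, b_h, rec, ds, sim, cH=cH, mode="hellinger")
        assert br.gCA == pytest.approx((1 - cH) * br.gS + cH * br.gH, abs=1e-12)

    def test_euclidean_mode_breakdown(self, group_only):
        sim, b, b_h, rec, ds = self._pieces(group_only)
        br = agr.g_ca(b, b_h, rec, ds, sim, cH=0.99, mode="euclidean")
        assert br.eH_grp is not None and br.eH_grp <= 0
        assert br.gCA == pytest.approx(
            0.01 * br.gS + 0.99 * (br.eH_grp + br.eH_eco), abs=1e-12
        )


def test_relative_improvement_reproduces_case_study_arithmetic():
    # initial -1.1394, final -0.8483 -> printed 25.5%
    assert round(agr.relative_improvement(-1.1394, -0.8483), 1) == 25.5
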