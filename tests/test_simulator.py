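import math

import numpy as np
import pytest

from nestcare import simulate as sim
from nestcare import windows as win
from nestcare import repeatability as rpt
from nestcare.ethogram import FULL_DAY, MIDDAY_3H


def plain_config(**kw):
    """Homogeneous config: no diurnal, stage, individual or coupling terms."""
    cfg = sim.SimulationConfig(**kw)
    cfg.validate()
    return cfg


class TestSimulateNest:
    def test_deterministic_given_seed(self):
        cfg = sim.preset_paperlike()
        a = sim.simulate_nest(cfg, "N1", "incubation", 3, FULL_DAY,
                              rng=np.random.default_rng(99),
                              individual_intercepts={"male": 0.1, "female": 0.2})
        b = sim.simulate_nest(cfg, "N1", "incubation", 3, FULL_DAY,
                              rng=np.random.default_rng(99),
                              individual_intercepts={"male": 0.1, "female": 0.2})
        assert a.intervals == b.intervals
        assert a.feedings == b.feedings

    def test_output_satisfies_core_invariants(self):
        cfg = sim.preset_paperlike()
        rec = sim.simulate_nest(cfg, "N1", "provisioning", 3, FULL_DAY,
                                rng=np.random.default_rng(0))
        rec.validate()
        for parent in ("male", "female"):
            for state in ("care", "inside"):
                track = rec.track(parent, state)
                for (s1, e1), (s2, e2) in zip(track, track[1:]):
                    assert e1 <= s2
            # a parent is never in two states at once
            care = rec.track(parent, "care")
            inside = rec.track(parent, "inside")
            from nestcare import intervals as iv
            assert iv.total_length(iv.intersect(care, inside)) == 0.0

    def test_feedings_only_when_provisioning(self):
        cfg = sim.preset_paperlike()
        inc = sim.simulate_nest(cfg, "N1", "incubation", 3, FULL_DAY,
                                rng=np.random.default_rng(1))
        prov = sim.simulate_nest(cfg, "N1", "provisioning", 3, FULL_DAY,
                                 rng=np.random.default_rng(1))
        assert not inc.feedings
        assert prov.feedings

    def test_stationary_occupancy_matches_generator(self):
        # sigma=0, no diurnal/stage terms, coupling off: long-run care
        # occupancy equals the CTMC stationary distribution
        cfg = plain_config()
        pi = sim.stationary_distribution(cfg.base_rates["male"])
        rng = np.random.default_rng(7)
        props = []
        for i in range(40):
            rec = sim.simulate_nest(cfg, f"N{i}", "incubation", 3, FULL_DAY,
                                    rng=rng)
            props.append(win.daily_effort(rec, "male_care"))
        props = np.asarray(props)
        se = props.std(ddof=1) / math.sqrt(props.size)
        assert abs(props.mean() - pi["care"]) < 3 * se + 0.01

    def test_uncoupled_joint_is_product_of_marginals(self):
        cfg = plain_config()
        assert cfg.joint_coupling == 1.0
        rng = np.random.default_rng(11)
        joint, prod = [], []
        for i in range(40):
            rec = sim.simulate_nest(cfg, f"N{i}", "incubation", 3, FULL_DAY,
                                    rng=rng)
            joint.append(win.daily_effort(rec, "joint_care"))
            prod.append(win.daily_effort(rec, "male_care")
                        * win.daily_effort(rec, "female_care"))
        diff = np.asarray(joint) - np.asarray(prod)
        se = diff.std(ddof=1) / math.sqrt(diff.size)
        assert abs(diff.mean()) < 3 * se + 0.01

    def test_coupling_raises_joint_care(self):
        rng1, rng2 = np.random.default_rng(3), np.random.default_rng(3)
        base = plain_config()
        coupled = plain_config(joint_coupling=3.0)
        j_base = np.mean([win.daily_effort(
            sim.simulate_nest(base, f"N{i}", "incubation", 3, FULL_DAY,
                              rng=rng1), "joint_care") for i in range(30)])
        j_coup = np.mean([win.daily_effort(
            sim.simulate_nest(coupled, f"N{i}", "incubation", 3, FULL_DAY,
                              rng=rng2), "joint_care") for i in range(30)])
        assert j_coup > j_base


class TestSchedule:
    def test_actual_design_570h(self):
        cfg = sim.SimulationConfig(n_nests=10)
        assert sim.scheduled_hours(sim.schedule(cfg)) == 570.0

    def test_counterfactual_design_840h(self):
        cfg = sim.SimulationConfig(n_nests=10)
        assert sim.scheduled_hours(
            sim.schedule(cfg, all_full_day=True)) == 840.0

    def test_single_nest_scales_to_57h(self):
        cfg = sim.SimulationConfig(n_nests=1)
        assert sim.scheduled_hours(sim.schedule(cfg)) == 57.0

    def test_population_layout(self, paperlike_corpus):
        assert len(paperlike_corpus) == 70
        inc_nests = {r.nest_id for r in paperlike_corpus
                     if r.nest_id.startswith("I")}
        prov_nests = {r.nest_id for r in paperlike_corpus
                      if r.nest_id.startswith("P")}
        assert len(inc_nests) == len(prov_nests) == 10
        # provisioning nests also recorded on incubation day 8
        p_inc = [r for r in paperlike_corpus
                 if r.nest_id.startswith("P") and r.stage == "incubation"]
        assert all(r.stage_day == 8 and r.span == MIDDAY_3H for r in p_inc)

    def test_population_deterministic(self):
        cfg = sim.preset_paperlike()
        cfg.seed = 5
        a = sim.simulate_population(cfg)
        b = sim.simulate_population(cfg)
        assert all(x.intervals == y.intervals and x.feedings == y.feedings
                   for x, y in zip(a, b))


class TestPresetPaperlike:
    def test_female_bias_and_monotone_brooding(self, paperlike_corpus):
        d3 = [r for r in paperlike_corpus
              if r.stage == "incubation" and r.stage_day == 3]
        male = np.mean([win.daily_effort(r, "male_care") for r in d3])
        female = np.mean([win.daily_effort(r, "female_care") for r in d3])
        assert female - male >= 0.15
        brood = [np.mean([win.window_effort(r, "total_care", MIDDAY_3H)
                          for r in paperlike_corpus
                          if r.stage == "provisioning" and r.stage_day == d])
                 for d in (3, 10, 17)]
        assert brood[0] > brood[1] > brood[2]

    def test_total_care_never_exceeds_one(self, paperlike_corpus):
        for r in paperlike_corpus[:10]:
            for w in win.make_windows(r, 1.0):
                assert win.window_effort(r, "total_care", w) <= 1.0

    def test_sigma_individual_monotone_in_repeatability(self):
        # expected Harper r increases with individual-intercept SD
        means = []
        for sigma in (0.1, 0.45, 1.0):
            rs = []
            for rep in range(40):
                cfg = sim.preset_paperlike()
                cfg.sigma_individual = sigma
                rng = np.random.default_rng(10_000 * rep + int(sigma * 100))
                recs = []
                for i in range(10):
                    icpt = {s: rng.normal(0, sigma) for s in ("male", "female")}
                    recs.append(sim.simulate_nest(
                        cfg, f"N{i}", "incubation", 3, FULL_DAY, rng=rng,
                        individual_intercepts=icpt))
                mat = win.effort_matrix(recs, "female_care", 3.0)
                rs.append(rpt.harper_r(rpt.one_way_anova(mat)).r)
            means.append(np.mean(rs))
        assert means[0] < means[1] < means[2]


class TestConfigRoundTrip:
    def test_dict_round_trip(self):
        cfg = sim.preset_paperlike()
        cfg.seed = 42
        d = sim.config_to_dict(cfg)
        back = sim.config_from_dict(d)
        assert back == cfg

    def test_yaml_round_trip(self, tmp_path):
        import yaml
        cfg = sim.preset_paperlike()
        text = yaml.safe_dump(sim.config_to_dict(cfg))
        back = sim.config_from_dict(yaml.safe_load(text))
        assert back == cfg

    def test_invalid_rate_rejected(self):
        cfg = sim.SimulationConfig()
        cfg.base_rates["male"][("off", "care")] = 0.0
        with pytest.raises(ValueError):
            cfg.validate()
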