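"""Priors, reference entries, model choice and parameter estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gfgcoal import (
    ReferenceTable,
    ScenarioPrior,
    SumStatVector,
    cross_validate,
    draw_prior,
    estimate_parameters,
    model_choice,
    simulate_reference_entry,
)
from gfgcoal.sumstats import STAT_COLUMNS

PARAM_ZERO = dict.fromkeys(["s", "c_H", "c_P", "N_H", "N_P"], 0.0)


def synthetic_table(rows_by_model, rng, scenario=2, r=1, param_fn=None):
    """Reference table with statistics drawn from given samplers."""
    records = []
    for model, (n, sampler) in rows_by_model.items():
        for _ in range(n):
            rec = {"model": model, **PARAM_ZERO}
            if param_fn is not None:
                rec.update(param_fn(model, rng))
            rec.update(dict(zip(STAT_COLUMNS, sampler(rng))))
            records.append(rec)
    return ReferenceTable(data=pd.DataFrame.from_records(records),
                          scenario=scenario, r=r)


class TestDrawPrior:
    def test_scenario2_supports(self, rng):
        draws = [draw_prior(ScenarioPrior(scenario=2), "coevolution", rng)
                 for _ in range(100_000)]
        s = np.array([d["s"] for d in draws])
        ch = np.array([d["c_H"] for d in draws])
        cp = np.array([d["c_P"] for d in draws])
        assert s.min() > 0.1 and s.max() < 0.9
        assert ch.min() > 0.01 and ch.max() < 0.35
        assert cp.min() > 0.01 and cp.max() < 0.35
        assert all(d["N_H"] == 10_000 and d["N_P"] == 10_000 for d in draws[:100])

    def test_scenario2_neutral_has_no_free_parameters(self, rng):
        d = draw_prior(ScenarioPrior(scenario=2), "neutral", rng)
        assert d["N_H"] == d["N_P"] == 10_000
        assert d["s"] == d["c_H"] == d["c_P"] == 0.0

    def test_scenario1_population_size_is_log_uniform(self, rng):
        prior = ScenarioPrior(scenario=1)
        draws = [draw_prior(prior, "neutral", rng) for _ in range(100_000)]
        nh = np.array([d["N_H"] for d in draws], dtype=float)
        assert nh.min() >= 2_000 and nh.max() <= 40_000
        # KS of log(N_H) against U(log 2000, log 40000) (analytic CDF)
        z = (np.log(nh) - np.log(2_000)) / (np.log(40_000) - np.log(2_000))
        assert sps.kstest(z, "uniform").pvalue > 0.01
        ch_fixed = draw_prior(prior, "coevolution", rng)
        assert ch_fixed["c_H"] == 0.05 and ch_fixed["c_P"] == 0.1


class TestSimulateReferenceEntry:
    def test_neutral_watterson_unbiased(self):
        """Averaged host theta_w over r replicates is centred on theta = 5."""
        prior = ScenarioPrior(scenario=2, r=10)
        draw = {"N_H": 10_000, "N_P": 10_000}
        vals = [
            simulate_reference_entry(draw, prior, "neutral",
                                     np.random.default_rng(i)).host_theta_w
            for i in range(120)
        ]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 5.0) < 4 * se

    def test_seeded_entry_is_bit_reproducible(self):
        prior = ScenarioPrior(scenario=2, r=3, g_max_override=1_000)
        draw = {"N_H": 2_000, "N_P": 2_000, "s": 0.5, "c_H": 0.05, "c_P": 0.1}
        a = simulate_reference_entry(draw, prior, "coevolution", np.random.default_rng(4))
        b = simulate_reference_entry(draw, prior, "coevolution", np.random.default_rng(4))
        assert a.to_array() == pytest.approx(b.to_array(), abs=0)

    def test_degenerate_coevolution_looks_neutral(self):
        """s < c_H: coevolution entries match neutral entries statistically."""
        prior = ScenarioPrior(scenario=2, r=5)
        coev, neut = [], []
        for i in range(12):
            draw = {"N_H": 10_000, "N_P": 10_000, "s": 0.04, "c_H": 0.05, "c_P": 0.1}
            coev.append(
                simulate_reference_entry(draw, prior, "coevolution",
                                         np.random.default_rng(500 + i)).to_array()
            )
            neut.append(
                simulate_reference_entry(draw, prior, "neutral",
                                         np.random.default_rng(900 + i)).to_array()
            )
        coev, neut = np.array(coev), np.array(neut)
        for col in ("host_pi", "para_pi", "host_tajimas_d", "para_tajimas_d"):
            j = STAT_COLUMNS.index(col)
            t = sps.ttest_ind(coev[:, j], neut[:, j])
            assert t.pvalue > 0.001, f"{col} differs: {t}"


class TestModelChoice:
    def test_distance_zero_recovers_own_model(self, rng):
        tab = synthetic_table(
            {"coevolution": (150, lambda r: r.normal(0, 1, 17)),
             "neutral": (150, lambda r: r.normal(8, 1, 17))},
            rng,
        )
        obs = SumStatVector.from_array(
            tab.rows_for("coevolution")[list(STAT_COLUMNS)].iloc[0].to_numpy()
        )
        res = model_choice(obs, tab)
        assert res.posterior["coevolution"] == 1.0

    def test_posteriors_sum_to_one_and_separated_clouds(self, rng):
        tab = synthetic_table(
            {"coevolution": (300, lambda r: r.normal(0, 1, 17)),
             "neutral": (300, lambda r: r.normal(10, 1, 17))},
            rng,
        )
        res = model_choice(SumStatVector.from_array(np.zeros(17)), tab)
        assert sum(res.posterior.values()) == pytest.approx(1.0)
        assert res.posterior["coevolution"] >= 0.99
        assert len(res.retained_indices) == int(np.ceil(0.01 * 600))

    def test_invariance_to_column_rescaling_and_row_order(self, rng):
        tab = synthetic_table(
            {"coevolution": (120, lambda r: r.normal(0, 1, 17)),
             "neutral": (120, lambda r: r.normal(2, 1, 17))},
            rng,
        )
        obs_vec = rng.normal(0.5, 1, 17)
        base = model_choice(SumStatVector.from_array(obs_vec), tab).posterior
        # rescale one statistic column by a positive constant
        scaled = tab.data.copy()
        scaled["host_pi"] *= 37.0
        obs2 = obs_vec.copy()
        obs2[STAT_COLUMNS.index("host_pi")] *= 37.0
        res2 = model_choice(
            SumStatVector.from_array(obs2),
            ReferenceTable(data=scaled, scenario=2, r=1),
        ).posterior
        assert res2 == pytest.approx(base)
        # permute rows
        shuffled = tab.data.sample(frac=1, random_state=1).reset_index(drop=True)
        res3 = model_choice(
            SumStatVector.from_array(obs_vec),
            ReferenceTable(data=shuffled, scenario=2, r=1),
        ).posterior
        assert res3 == pytest.approx(base)

    def test_zero_mad_column_dropped(self, rng, caplog):
        def sampler_const(r):
            v = r.normal(0, 1, 17)
            v[3] = 7.0  # constant column
            return v

        tab = synthetic_table(
            {"coevolution": (100, sampler_const),
             "neutral": (100, lambda r: np.concatenate([r.normal(5, 1, 3), [7.0],
                                                        r.normal(5, 1, 13)]))},
            rng,
        )
        obs = np.zeros(17)
        obs[3] = 7.0
        res = model_choice(SumStatVector.from_array(obs), tab)
        assert sum(res.posterior.values()) == pytest.approx(1.0)


class TestCrossValidate:
    def test_symmetric_models_near_fifty_fifty(self, rng):
        tab = synthetic_table(
            {"coevolution": (300, lambda r: r.normal(0, 1, 17)),
             "neutral": (300, lambda r: r.normal(0, 1, 17))},
            rng,
        )
        cm = cross_validate(tab, rng, n_val=150)
        assert cm.correct["coevolution"] + cm.incorrect["coevolution"] == 150
        assert cm.correct["neutral"] + cm.incorrect["neutral"] == 150
        assert 35 < cm.fnr_percent < 65
        assert 35 < cm.fpr_percent < 65

    def test_separated_models_classified_perfectly(self, rng):
        tab = synthetic_table(
            {"coevolution": (200, lambda r: r.normal(0, 1, 17)),
             "neutral": (200, lambda r: r.normal(12, 1, 17))},
            rng,
        )
        cm = cross_validate(tab, rng, n_val=100)
        assert cm.fnr_percent == 0.0
        assert cm.fpr_percent == 0.0


class TestEstimateParameters:
    @staticmethod
    def _identity_table(rng, n=1500, noise=0.02):
        """para_pi equals the parameter s plus small noise."""
        records = []
        for _ in range(n):
            s = rng.uniform(0.1, 0.9)
            stats = rng.normal(0, 1, 17)
            stats[STAT_COLUMNS.index("para_pi")] = s + rng.normal(0, noise)
            rec = {"model": "coevolution", **PARAM_ZERO, "s": s,
                   "N_H": 10_000, "N_P": 10_000}
            rec.update(dict(zip(STAT_COLUMNS, stats)))
            records.append(rec)
        return ReferenceTable(data=pd.DataFrame.from_records(records),
                              scenario=2, r=1)

    def test_identity_map_recovers_parameter(self, rng):
        noise = 0.02
        tab = self._identity_table(rng, noise=noise)
        obs = np.zeros(17)
        obs[STAT_COLUMNS.index("para_pi")] = 0.47
        post = estimate_parameters(SumStatVector.from_array(obs), tab,
                                   n_retain=1000, stat_subset="parasite_only")
        assert abs(post["s"].median - 0.47) < 2 * noise

    def test_constant_columns_ignored(self, rng):
        tab = self._identity_table(rng)
        data = tab.data.copy()
        data["host_S"] = 3.0  # constant -> dropped from the regression
        tab2 = ReferenceTable(data=data, scenario=2, r=1)
        obs = np.zeros(17)
        obs[STAT_COLUMNS.index("para_pi")] = 0.6
        obs[STAT_COLUMNS.index("host_S")] = 3.0
        post = estimate_parameters(SumStatVector.from_array(obs), tab2,
                                   n_retain=1000, stat_subset="joint")
        assert abs(post["s"].median - 0.6) < 0.05

    def test_affine_equivariance(self, rng):
        """Mapping s -> 2 s + 1 in the table maps the posterior median
        (computed on the transformed support) identically."""
        tab = self._identity_table(rng)
        obs = np.zeros(17)
        obs[STAT_COLUMNS.index("para_pi")] = 0.3
        base = estimate_parameters(SumStatVector.from_array(obs), tab,
                                   n_retain=800, stat_subset="parasite_only")

        data2 = tab.data.copy()
        data2["s"] = 2.0 * data2["s"] + 1.0
        tab2 = ReferenceTable(data=data2, scenario=2, r=1)
        moved = estimate_parameters(
            SumStatVector.from_array(obs), tab2, n_retain=800,
            stat_subset="parasite_only", supports={"s": (1.2, 2.8)},
        )
        assert moved["s"].median == pytest.approx(2 * base["s"].median + 1, abs=1e-6)

    def test_median_clamped_to_support(self, rng):
        tab = self._identity_table(rng)
        obs = np.zeros(17)
        obs[STAT_COLUMNS.index("para_pi")] = 2.5  # far outside the prior
        post = estimate_parameters(SumStatVector.from_array(obs), tab,
                                   n_retain=500, stat_subset="parasite_only")
        assert 0.1 <= post["s"].median <= 0.9
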