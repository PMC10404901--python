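"""Synthetic-study generator: scale bounds, ground-truth attunement,
closed-form correlation structure, network and demographic properties,
and full determinism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from dyadisc import SimulationConfig, simulate_study
from dyadisc.errors import ValidationError
from dyadisc.simulate import (
    attunement_from_loneliness,
    attunement_matrix,
    generate_demographics,
    generate_loneliness_scores,
    generate_network,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_subjects": 1},
            {"attunement_max": 1.5},
            {"attunement_slope": -0.1},
            {"noise_sd": 0.0},
            {"item_min": 4, "item_max": 4},
            {"affected_parcels": (0,)},
            {"affected_parcels": (999,)},
            {"network_mean_degree": -1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValidationError):
            SimulationConfig(n_parcels=5, **kw)


class TestLonelinessScores:
    def test_item_total_consistency_and_bounds(self):
        cfg = SimulationConfig(n_subjects=200, n_parcels=2, seed=1)
        t = generate_loneliness_scores(cfg)
        items = t[[f"item_{i}" for i in range(1, 9)]]
        assert (items.sum(axis=1) == t["uls8_total"]).all()
        assert items.min().min() >= 1 and items.max().max() <= 4
        assert t["uls8_total"].between(8, 32).all()

    def test_extreme_targets_pin_scale_endpoints(self):
        lo = SimulationConfig(n_subjects=5, n_parcels=2, loneliness_mean=-50,
                              loneliness_sd=1, seed=0)
        hi = SimulationConfig(n_subjects=5, n_parcels=2, loneliness_mean=90,
                              loneliness_sd=1, seed=0)
        assert (generate_loneliness_scores(lo)["uls8_total"] == 8).all()
        assert (generate_loneliness_scores(hi)["uls8_total"] == 32).all()

    def test_targets_approximately_honoured(self):
        """Sample moments match the truncated-normal implied moments (the
        asymmetric truncation at the scale bounds shifts them slightly off
        the nominal targets)."""
        from scipy import stats as sps

        cfg = SimulationConfig(n_subjects=4000, n_parcels=2, seed=9)
        a = (cfg.score_min - cfg.loneliness_mean) / cfg.loneliness_sd
        b = (cfg.score_max - cfg.loneliness_mean) / cfg.loneliness_sd
        dist = sps.truncnorm(a, b, loc=cfg.loneliness_mean,
                             scale=cfg.loneliness_sd)
        t = generate_loneliness_scores(cfg)["uls8_total"]
        assert abs(t.mean() - dist.mean()) < 0.3
        assert abs(t.std(ddof=1) - dist.std()) < 0.3


class TestAttunement:
    CFG = SimulationConfig(n_parcels=10, affected_parcels=(3,),
                           attunement_max=0.8, attunement_slope=0.3,
                           loneliness_mean=16.0, loneliness_sd=4.0)

    def test_clip_formula_in_affected_parcel(self):
        # standardized total +2 -> 0.8 - 0.3*2 = 0.2
        assert attunement_from_loneliness(24, 3, self.CFG) == pytest.approx(0.2)

    def test_unaffected_parcel_ignores_loneliness(self):
        for total in (8, 16, 32):
            assert attunement_from_loneliness(total, 1, self.CFG) == 0.8

    def test_zero_slope_is_identity(self):
        cfg = dataclasses.replace(self.CFG, attunement_slope=0.0)
        for total in (8, 20, 32):
            assert attunement_from_loneliness(total, 3, cfg) == 0.8

    def test_out_of_scale_total_rejected(self):
        with pytest.raises(ValidationError):
            attunement_from_loneliness(7, 1, self.CFG)

    def test_values_clipped_to_unit_interval(self):
        cfg = dataclasses.replace(self.CFG, attunement_slope=2.0)
        w = attunement_matrix(np.array([8, 16, 32]), cfg)
        assert (w >= 0).all() and (w <= 1).all()

    def test_matrix_agrees_with_scalar_map(self):
        totals = np.array([10, 16, 28])
        w = attunement_matrix(totals, self.CFG)
        for i, t in enumerate(totals):
            for p in range(1, 11):
                assert w[i, p - 1] == pytest.approx(
                    attunement_from_loneliness(t, p, self.CFG)
                )


class TestTimeseriesModel:
    def test_pairwise_correlation_closed_form(self):
        """Empirical r converges to w_i * w_j in affected parcels."""
        cfg = SimulationConfig(
            n_subjects=4, n_parcels=2, affected_parcels=(1,), n_runs=1,
            timepoints_per_run=10_000, attunement_max=0.8,
            attunement_slope=0.25, seed=7,
        )
        errs = []
        for rep in range(5):
            st = simulate_study(dataclasses.replace(cfg, seed=100 + rep))
            w = st.truth.pivot(index="subject_id", columns="parcel_id",
                               values="attunement")
            for i in range(1, 4):
                for j in range(i + 1, 5):
                    x = st.series[i][1][0]
                    y = st.series[j][1][0]
                    r = np.corrcoef(x, y)[0, 1]
                    errs.append(abs(r - w.at[i, 1] * w.at[j, 1]))
        assert np.mean(errs) < 0.05

    def test_zero_attunement_means_independent_noise(self):
        cfg = SimulationConfig(
            n_subjects=3, n_parcels=1, affected_parcels=(1,),
            attunement_max=0.0, attunement_slope=0.0, n_runs=1,
            timepoints_per_run=8_000, seed=3,
        )
        st = simulate_study(cfg)
        r = np.corrcoef(st.series[1][1][0], st.series[2][1][0])[0, 1]
        assert abs(r) < 0.05

    def test_full_attunement_gives_identical_series(self):
        cfg = SimulationConfig(
            n_subjects=2, n_parcels=1, attunement_max=1.0,
            attunement_slope=0.0, n_runs=1, timepoints_per_run=50, seed=0,
        )
        st = simulate_study(cfg)
        np.testing.assert_allclose(st.series[1][1], st.series[2][1])

    def test_series_shapes(self, small_study, small_cfg):
        for runs in small_study.series.values():
            assert sorted(runs) == list(range(1, small_cfg.n_runs + 1))
            for m in runs.values():
                assert m.shape == (small_cfg.n_parcels,
                                   small_cfg.timepoints_per_run)


class TestNetwork:
    def test_zero_mean_degree_gives_empty_edge_list(self):
        cfg = SimulationConfig(n_subjects=10, n_parcels=2,
                               network_mean_degree=0.0, seed=0)
        t = generate_loneliness_scores(cfg)
        assert len(generate_network(cfg, t)) == 0

    def test_no_self_nominations_and_distinct_nominees(self, small_study):
        edges = small_study.network
        assert (edges["nominator_id"] != edges["nominee_id"]).all()
        assert not edges.duplicated().any()

    def test_decoupled_loneliness_outdegree(self):
        """With coupling 0 the score/out-degree correlation is ~0."""
        corrs = []
        for seed in range(30):
            cfg = SimulationConfig(n_subjects=60, n_parcels=2, seed=seed,
                                   network_mean_degree=6.0,
                                   degree_loneliness_corr=0.0)
            t = generate_loneliness_scores(cfg)
            e = generate_network(cfg, t)
            deg = e.groupby("nominator_id").size().reindex(
                t["subject_id"], fill_value=0)
            corrs.append(np.corrcoef(t["uls8_total"], deg)[0, 1])
        assert abs(np.mean(corrs)) < 0.05

    def test_positive_coupling_links_degree_to_loneliness(self):
        cfg = SimulationConfig(n_subjects=300, n_parcels=2, seed=5,
                               network_mean_degree=6.0,
                               degree_loneliness_corr=0.8)
        t = generate_loneliness_scores(cfg)
        e = generate_network(cfg, t)
        deg = e.groupby("nominator_id").size().reindex(t["subject_id"],
                                                       fill_value=0)
        assert np.corrcoef(t["uls8_total"], deg)[0, 1] > 0.3


class TestDemographics:
    def test_default_ages_in_range(self, small_study):
        assert small_study.subject_table["age"].between(18, 21).all()

    def test_single_category_table_has_zero_variance(self):
        cfg = SimulationConfig(n_subjects=20, n_parcels=2,
                               gender_probs={"female": 1.0}, seed=0)
        d = generate_demographics(cfg)
        assert (d["gender"] == "female").all()


class TestDeterminism:
    def test_identical_config_gives_bit_identical_study(self, small_cfg):
        a = simulate_study(small_cfg)
        b = simulate_study(dataclasses.replace(small_cfg))
        pd.testing.assert_frame_equal(a.subject_table, b.subject_table)
        pd.testing.assert_frame_equal(a.network, b.network)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        for sid in a.series:
            for run in a.series[sid]:
                assert np.array_equal(a.series[sid][run], b.series[sid][run])

    def test_truth_in_unit_interval(self, small_study):
        assert small_study.truth["attunement"].between(0, 1).all()
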