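"""Synthetic-data generators: determinism, ground truth and the
statistical structure the estimators rely on."""

import numpy as np
import pytest

from synprime import io
from synprime.nanocluster import dbscan, radius_of_gyration
from synprime.quantal import DEFAULT_Q_STAR, binned_event_rate
from synprime.simulator import DEFAULT_CA_PARAMS, WT_PARAMS
from synprime.synthetic import (HK_MINUS, WT_MINUS, gen_az_clouds,
                                gen_hotspot_roi, gen_mepsc_stream,
                                gen_train_cohort, get_preset,
                                ptp_rate_profile, trains_from_table)


class TestPresets:
    def test_lookup(self):
        assert get_preset("wtminus") is WT_MINUS
        assert get_preset("HK/-") is HK_MINUS
        with pytest.raises(KeyError):
            get_preset("nope")

    def test_preset_realizes_stated_regime(self):
        p = WT_MINUS.model_params()
        assert p.resting_f_ts == pytest.approx(0.28, abs=1e-9)
        assert p.p_fusion_0 == 0.34
        h = HK_MINUS.model_params()
        assert h.resting_f_ts == pytest.approx(0.455, abs=1e-3)
        assert h.sigma1 == pytest.approx(0.15 * WT_PARAMS.sigma1)

    def test_pool_spread_is_about_sevenfold(self):
        lo, hi = WT_MINUS.frp_range
        assert hi / lo == pytest.approx(7.6, abs=0.1)


class TestTrainCohort:
    def test_deterministic_under_seed(self):
        a, ta = gen_train_cohort(WT_MINUS, n_synapses=2, freqs=(200.0,),
                                 n_ap=10, seed=5, n_sweeps=2)
        b, tb = gen_train_cohort(WT_MINUS, n_synapses=2, freqs=(200.0,),
                                 n_ap=10, seed=5, n_sweeps=2)
        assert a.equals(b)
        assert ta == tb

    def test_amplitude_quanta_consistency(self):
        table, _ = gen_train_cohort(WT_MINUS, n_synapses=1, freqs=(200.0,),
                                    n_ap=10, seed=1, n_sweeps=1)
        np.testing.assert_allclose(table["amplitude_pA"] / DEFAULT_Q_STAR,
                                   table["m"], rtol=1e-12)

    def test_mean_field_first_response_matches_truth(self):
        table, truth = gen_train_cohort(WT_MINUS, n_synapses=3,
                                        freqs=(100.0,), n_ap=5, seed=2,
                                        noise="none")
        for sid, rec in truth["synapses"].items():
            m1 = table[(table.synapse_id == sid)
                       & (table.stim_index == 1)]["m"].iloc[0]
            assert m1 == pytest.approx(rec["p_fusion"] * rec["M_TS"],
                                       rel=1e-9)

    def test_pools_within_preset_range_and_composition(self):
        _, truth = gen_train_cohort(WT_MINUS, n_synapses=8, freqs=(200.0,),
                                    n_ap=5, seed=3, noise="none")
        for rec in truth["synapses"].values():
            lo, hi = WT_MINUS.frp_range
            assert lo <= rec["FRP"] <= hi
            assert rec["M_TS"] + rec["M_LS"] == pytest.approx(rec["FRP"])
            assert rec["f_TS"] == pytest.approx(
                rec["M_TS"] / rec["FRP"], rel=1e-9)

    def test_table_round_trips_to_trains(self):
        table, _ = gen_train_cohort(WT_MINUS, n_synapses=2,
                                    freqs=(100.0, 200.0), n_ap=6, seed=4,
                                    n_sweeps=1)
        trains = trains_from_table(table)
        assert len(trains) == 4
        assert {t.f_stim for t in trains} == {100.0, 200.0}


class TestMepscStream:
    def test_constant_rate_event_count(self):
        s, truth = gen_mepsc_stream(10.0, 100.0, seed=4)
        n = len(s.event_times)
        assert abs(n - 1000) < 3 * np.sqrt(1000)
        assert truth["n_events"] == n

    def test_zero_rate_empty(self):
        s, _ = gen_mepsc_stream(0.0, 50.0, seed=1)
        assert s.event_times.size == 0

    def test_deterministic(self):
        a, _ = gen_mepsc_stream(5.0, 30.0, seed=9)
        b, _ = gen_mepsc_stream(5.0, 30.0, seed=9)
        np.testing.assert_array_equal(a.event_times, b.event_times)

    def test_potentiation_profile_fold_recovered(self):
        rate = ptp_rate_profile(2.0, 7.0, 100.0)
        s, _ = gen_mepsc_stream(rate, 200.0, seed=5)
        rates = binned_event_rate(s, 2.0)
        early = rates[0] / 2.0
        assert early == pytest.approx(7.0, rel=0.35)

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            ptp_rate_profile(-1.0, 2.0, 10.0)


class TestAzClouds:
    def test_requested_radius_of_gyration(self):
        m, _, _ = gen_az_clouds(n_az=1, clusters_per_az=1, bsn_clusters=1,
                                loc_error=0.0, clutter_density=0.0, seed=1,
                                locs_per_cluster=10_000)
        assert radius_of_gyration(m.points) == pytest.approx(48.0, rel=0.02)

    def test_localization_error_adds_in_quadrature(self):
        m, _, truth = gen_az_clouds(n_az=1, clusters_per_az=1, bsn_clusters=1,
                                    loc_error=20.0, clutter_density=0.0,
                                    seed=1, locs_per_cluster=10_000)
        assert radius_of_gyration(m.points) == pytest.approx(
            truth["effective_rg_munc13"], rel=0.02)

    def test_cluster_count_recovered_without_clutter(self):
        m, _, truth = gen_az_clouds(n_az=4, clutter_density=0.0, seed=2)
        counts = [dbscan(m.points[m.az_id == az]).n_clusters
                  for az in range(4)]
        assert abs(np.median(counts) - truth["clusters_per_az"]) <= 1

    def test_deterministic(self):
        a, _, _ = gen_az_clouds(n_az=2, seed=3)
        b, _, _ = gen_az_clouds(n_az=2, seed=3)
        np.testing.assert_array_equal(a.points, b.points)

    def test_ground_truth_centers_recorded(self):
        m, b, truth = gen_az_clouds(n_az=2, seed=4)
        for az in range(2):
            assert len(truth["az"][az]["munc13_centers"]) == 7
            assert len(truth["az"][az]["bsn_centers"]) == 3


class TestHotspotRoi:
    def test_expected_enrichment_close(self):
        roi, bg, truth = gen_hotspot_roi(contrast=6.0, seed=3)
        from synprime.nanocluster import hotspot_enrichment
        res = hotspot_enrichment(roi, bg)
        assert res.enrichment == pytest.approx(truth["expected_enrichment"],
                                               rel=0.10)

    def test_no_bright_pixels_means_no_enrichment(self):
        roi, bg, _ = gen_hotspot_roi(contrast=6.0, bright_fraction=0.0,
                                     seed=2)
        from synprime.nanocluster import hotspot_enrichment
        res = hotspot_enrichment(roi, bg)
        assert res.enrichment == pytest.approx(1.0, abs=0.1)

    def test_invalid_background_refused(self):
        with pytest.raises(ValueError):
            gen_hotspot_roi(bg_sigma=0.0, seed=1)


class TestIO:
    def test_train_table_roundtrip(self, tmp_path):
        table, _ = gen_train_cohort(WT_MINUS, n_synapses=2, freqs=(100.0,),
                                    n_ap=5, seed=1, n_sweeps=1)
        trains = trains_from_table(table)
        path = tmp_path / "trains.csv"
        io.write_train_table(trains, path)
        back = io.read_train_table(path)
        assert len(back) == len(trains)
        np.testing.assert_allclose(back[0].m, trains[0].m)

    def test_event_stream_roundtrip(self, tmp_path):
        s, _ = gen_mepsc_stream(5.0, 20.0, seed=2)
        path = tmp_path / "events.csv"
        io.write_event_stream(s, path)
        back = io.read_event_stream(path, duration=20.0)
        np.testing.assert_allclose(back.event_times, s.event_times)

    def test_localization_roundtrip(self, tmp_path):
        m, b, _ = gen_az_clouds(n_az=1, seed=5)
        path = tmp_path / "locs.csv"
        io.write_localizations([m, b], path)
        back = io.read_localizations(path)
        np.testing.assert_allclose(back["Munc13-1"].points, m.points)
        np.testing.assert_allclose(back["BSN"].points, b.points)

    def test_model_config_roundtrip(self, tmp_path):
        path = tmp_path / "cfg.json"
        io.save_model_config(WT_PARAMS, DEFAULT_CA_PARAMS, path)
        p, c = io.load_model_config(path)
        assert p == WT_PARAMS
        assert c == DEFAULT_CA_PARAMS
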