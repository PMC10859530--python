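"""Centesimal stress trajectories, k-medoids clustering and class naming."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from sorglt import envirotyping as et


def bundle(center: np.ndarray, n: int, noise: float, rng) -> list:
    out = []
    for i in range(n):
        v = np.clip(center + rng.normal(0, noise, 100), 0, 1)
        out.append(et.StressTrajectory(season_id=f"s{i}", values=v))
    return out


class TestToCentesimal:
    def test_constant_stays_constant(self):
        t = et.to_centesimal(np.ones(50), np.linspace(0, 900, 50))
        assert np.allclose(t.values, 1.0)

    def test_step_function_lands_at_half(self):
        w = np.concatenate([np.ones(50), np.zeros(50)])
        tt = np.linspace(0, 1000, 100)
        t = et.to_centesimal(w, tt)
        assert np.all(t.values[:49] > 0.9)
        assert np.all(t.values[51:] < 0.1)

    def test_length_always_100(self):
        for n in (10, 120, 400):
            t = et.to_centesimal(np.random.default_rng(0).random(n),
                                 np.linspace(0, 700, n))
            assert t.values.shape == (100,)

    def test_invariant_to_tt_rescaling(self):
        rng = np.random.default_rng(1)
        w = rng.random(80)
        tt = np.sort(rng.random(80)) * 900
        a = et.to_centesimal(w, tt)
        b = et.to_centesimal(w, tt * 3.7)
        np.testing.assert_allclose(a.values, b.values)

    def test_failed_season_excluded(self, belt_soil, ed_weather):
        from sorglt import cropmodel as cm
        w = ed_weather.copy()
        w["rain"] = 0.0
        res = cm.run_season(w, belt_soil, cm.make_cultivar("short"),
                            cm.Management(initial_fraction=0.2))
        assert res.failed
        with pytest.raises(ValueError, match="failed season"):
            et.season_trajectory(res)


class TestClustering:
    def test_two_far_bundles_choose_k2(self):
        rng = np.random.default_rng(0)
        low = bundle(np.full(100, 0.2), 12, 0.03, rng)
        high = bundle(np.full(100, 0.9), 12, 0.03, rng)
        cls = et.cluster_trajectories(low + high, range(2, 7), seed=0)
        assert cls.k == 2
        labels = cls.labels
        assert len(set(labels[:12])) == 1 and len(set(labels[12:])) == 1

    def test_silhouette_of_chosen_k_is_maximal(self):
        rng = np.random.default_rng(3)
        trajs = (bundle(np.full(100, 0.1), 10, 0.05, rng)
                 + bundle(np.full(100, 0.5), 10, 0.05, rng)
                 + bundle(np.full(100, 0.9), 10, 0.05, rng))
        cls = et.cluster_trajectories(trajs, range(2, 8), seed=0)
        assert cls.silhouette_by_k[cls.k] == max(cls.silhouette_by_k.values())

    def test_duplication_leaves_medoids_and_k(self):
        rng = np.random.default_rng(2)
        trajs = (bundle(np.full(100, 0.15), 9, 0.04, rng)
                 + bundle(np.full(100, 0.85), 9, 0.04, rng))
        cls1 = et.cluster_trajectories(trajs, range(2, 6), seed=0)
        cls2 = et.cluster_trajectories(trajs + trajs, range(2, 6), seed=0)
        assert cls2.k == cls1.k
        np.testing.assert_allclose(
            np.sort(cls1.medoids, axis=0), np.sort(cls2.medoids, axis=0))

    def test_pam_matches_clara_with_full_sample(self):
        rng = np.random.default_rng(4)
        trajs = (bundle(np.full(100, 0.2), 6, 0.05, rng)
                 + bundle(np.full(100, 0.8), 6, 0.05, rng))
        X = np.stack([t.values for t in trajs])
        D = cdist(X, X)
        pam_medoids = et.pam(D, 2)
        clara_medoids = et.clara(X, 2, sample_size=len(X), n_draws=1, seed=0)
        pam_labels = np.argmin(D[:, pam_medoids], axis=1)
        clara_labels = np.argmin(D[:, clara_medoids], axis=1)
        assert et.label_agreement(pam_labels, clara_labels) == 1.0

    def test_k_range_validation(self):
        rng = np.random.default_rng(5)
        trajs = bundle(np.full(100, 0.5), 10, 0.05, rng)
        with pytest.raises(ValueError):
            et.cluster_trajectories(trajs, range(2, 30), seed=0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(6)
        trajs = (bundle(np.full(100, 0.3), 8, 0.05, rng)
                 + bundle(np.full(100, 0.7), 8, 0.05, rng))
        a = et.cluster_trajectories(trajs, range(2, 5), seed=9)
        b = et.cluster_trajectories(trajs, range(2, 5), seed=9)
        assert np.array_equal(a.labels, b.labels) and a.k == b.k


class TestNaming:
    def _classify(self, medians):
        k = len(medians)
        cls = et.EnvClassification(
            k=k, labels=np.arange(k), medoid_indices=np.arange(k),
            medoids=np.stack(medians), silhouette_by_k={k: 0.5},
            season_ids=[str(i) for i in range(k)],
            medians=np.stack(medians))
        return et.name_environments(cls)

    def test_flat_one_is_ww(self):
        g = np.arange(1, 101)
        flat = np.ones(100)
        late = np.where(g > 70, 0.2, 1.0)
        mid = np.where((g > 35) & (g < 70), 0.2, 1.0)
        early = np.where(g < 30, 0.2, 1.0)
        cls = self._classify([late, flat, early, mid])
        assert cls.names[1] == "WW"
        assert cls.names[0] == "LD"
        assert cls.names[3] == "MD"
        assert cls.names[2] == "ED"

    def test_extra_clusters_get_generic_names(self):
        g = np.arange(1, 101)
        meds = [np.ones(100),
                np.where(g > 80, 0.1, 1.0),
                np.where(g > 60, 0.1, 1.0),
                np.where((g > 30) & (g < 60), 0.1, 1.0),
                np.where(g < 25, 0.1, 1.0)]
        cls = self._classify(meds)
        assert sorted(cls.names.values()) == sorted(["WW", "LD", "MD", "ED", "X5"])


class TestFrequencies:
    def test_rows_sum_to_one(self):
        labels = ["WW", "WW", "ED", "MD", "LD", "WW"]
        sites = [0, 0, 0, 1, 1, 1]
        freq = et.environment_frequencies(labels, sites)
        assert np.allclose(freq.sum(axis=1), 1.0)
        assert freq.loc[0, "WW"] == pytest.approx(2 / 3)

    def test_single_class_site(self):
        freq = et.environment_frequencies(["WW"] * 4, [0] * 4)
        assert freq.loc[0, "WW"] == 1.0

    def test_western_sites_more_drought_prone(self):
        """Gradient sites feed drier archetype draws in the west."""
        from sorglt import weathergen as wg
        rng = np.random.default_rng(0)
        sites = wg.generate_gradient_sites(5)
        labels, site_ids = [], []
        for s in sites:
            for _ in range(200):
                labels.append(s.draw_archetype(rng))
                site_ids.append(s.site_id)
        freq = et.environment_frequencies(labels, site_ids)
        dry = freq["MD"] + freq["ED"]
        assert dry.iloc[-1] > dry.iloc[0]


class TestIO:
    def test_csv_round_trip(self, tmp_path):
        import pandas as pd
        rows = []
        rng = np.random.default_rng(0)
        for sid in ("a", "b"):
            w = rng.random(60)
            tt = np.linspace(0, 800, 60)
            rows.append(pd.DataFrame({
                "season_id": sid, "day": np.arange(60),
                "watersd": w, "cum_tt": tt}))
        path = tmp_path / "runs.csv"
        pd.concat(rows).to_csv(path, index=False)
        trajs = et.trajectories_from_csv(path)
        assert [t.season_id for t in trajs] == ["a", "b"]
        assert all(t.values.shape == (100,) for t in trajs)
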