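import numpy as np
import pytest
from scipy import stats

from vsatnet import synthetic as syn
from vsatnet.datatypes import PlantedCovariance
from vsatnet.paradigm import ParadigmSpec


def parcel_mean_series(vol, atlas, label):
    return vol.data[atlas.labels == label].mean(axis=0)


class TestToyAtlas:
    def test_requested_parcels_disjoint_and_large_enough(self):
        atlas = syn.make_toy_atlas((24, 24, 16), 6, 10, seed=1)
        assert atlas.n_labels == 16
        sizes = np.bincount(atlas.labels.ravel())[1:]
        assert len(sizes) == 16 and (sizes >= 150).all()
        assert atlas.labels_of_tissue("WM") == list(range(1, 7))
        assert atlas.labels_of_tissue("GM") == list(range(7, 17))
        # labels are disjoint by construction; WM and GM never share a voxel
        assert not (atlas.tissue_mask("WM") & atlas.tissue_mask("GM")).any()

    def test_too_small_grid_raises(self):
        with pytest.raises(ValueError, match="cannot host"):
            syn.make_toy_atlas((4, 4, 4), 6, 10, seed=1)

    def test_same_seed_is_bit_identical(self):
        a = syn.make_toy_atlas((24, 24, 16), 6, 10, seed=7)
        b = syn.make_toy_atlas((24, 24, 16), 6, 10, seed=7)
        c = syn.make_toy_atlas((24, 24, 16), 6, 10, seed=8)
        assert np.array_equal(a.labels, b.labels)
        assert not np.array_equal(a.labels, c.labels)

    def test_minimum_compartment_counts(self):
        with pytest.raises(ValueError):
            syn.make_toy_atlas((24, 24, 16), 1, 10, seed=1)


class TestCohort:
    def test_group_sizes_and_score_targets(self):
        recs = syn.simulate_cohort(43, 42, seed=7)
        assert len(recs) == 85
        assert len({r.subject_id for r in recs}) == 85
        tbi = [r.inattentive_raw for r in recs if r.group == "TBI"]
        # target mean 9.31, SD 6.28 -> 3 SE band
        se = 6.28 / np.sqrt(42)
        assert abs(np.mean(tbi) - 9.31) < 3 * se
        assert all(r.inattentive_raw >= 0 and r.hyperactive_raw >= 0 for r in recs)
        assert all(18 <= r.age <= 27 for r in recs)

    def test_zero_sd_gives_exact_means(self):
        params = {
            g: {f: (syn.DEFAULT_SCORE_PARAMS[g][f][0], 0.0)
                for f in ("age", "edu_years", "mother_edu_years",
                          "father_edu_years", "inattentive_raw",
                          "hyperactive_raw")}
            for g in ("NC", "TBI")
        }
        recs = syn.simulate_cohort(10, 10, score_params=params, seed=1)
        nc = [r for r in recs if r.group == "NC"]
        assert all(r.inattentive_raw == 4.67 for r in nc)
        assert all(r.age == 22.36 for r in nc)

    def test_group_difference_detectable_at_large_n(self):
        recs = syn.simulate_cohort(200, 200, seed=3)
        nc = [r.inattentive_raw for r in recs if r.group == "NC"]
        tbi = [r.inattentive_raw for r in recs if r.group == "TBI"]
        _, p = stats.ttest_ind(tbi, nc)
        assert p < 0.001

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="negative SD"):
            syn.simulate_cohort(
                5, 5, score_params={"NC": {"age": (22.0, -1.0)}}, seed=0
            )


class TestSimulateBold:
    def test_perfectly_correlated_parcels_noiseless(self, small_atlas):
        n = small_atlas.n_labels
        R = np.eye(n)
        R[0, 1] = R[1, 0] = 1.0  # two WM parcels share one latent signal
        cov = PlantedCovariance(latent_corr=R)
        vol = syn.simulate_bold(
            small_atlas, ParadigmSpec(), cov, noise_sd=0.0, seed=5
        )
        s1 = parcel_mean_series(vol, small_atlas, 1)
        s2 = parcel_mean_series(vol, small_atlas, 2)
        assert abs(np.corrcoef(s1, s2)[0, 1] - 1.0) < 1e-10

    def test_null_offdiagonal_correlations_small(self, small_atlas):
        vals = []
        for seed in range(5):
            vol = syn.simulate_bold(
                small_atlas, ParadigmSpec(), None, noise_sd=1.0, seed=seed,
                task_amplitude=0.0,
            )
            series = np.stack(
                [parcel_mean_series(vol, small_atlas, lab)
                 for lab in range(1, small_atlas.n_labels + 1)]
            )
            R = np.corrcoef(series)
            vals.append(np.abs(R[np.triu_indices_from(R, 1)]).mean())
        assert np.mean(vals) < 0.2

    def test_planted_group_difference_recovered(self, small_atlas):
        """TBI-only planted r=0.6 on a WM pair shows up as a group FC
        difference of about 0.6 on that pair."""
        n = small_atlas.n_labels
        delta = np.zeros((n, n))
        delta[0, 1] = delta[1, 0] = 0.6
        cov = PlantedCovariance(
            latent_corr=np.eye(n), group_delta={"TBI": delta}
        )
        diffs = {"NC": [], "TBI": []}
        for grp in ("NC", "TBI"):
            for rep in range(40):
                vol = syn.simulate_bold(
                    small_atlas, ParadigmSpec(), cov, noise_sd=0.5,
                    subject_group=grp, seed=10_000 + rep, task_amplitude=0.0,
                )
                s1 = parcel_mean_series(vol, small_atlas, 1)
                s2 = parcel_mean_series(vol, small_atlas, 2)
                diffs[grp].append(np.corrcoef(s1, s2)[0, 1])
        gap = np.mean(diffs["TBI"]) - np.mean(diffs["NC"])
        assert abs(gap - 0.6) < 0.1

    def test_wm_spectral_bump_peaks_near_0017(self, small_atlas):
        vol = syn.simulate_bold(
            small_atlas, ParadigmSpec(), None, noise_sd=0.0, seed=11,
            wm_bump_gain=3.0,
        )
        s = parcel_mean_series(vol, small_atlas, 1)  # a WM parcel
        freqs = np.fft.rfftfreq(len(s), 1.0)
        spec = np.abs(np.fft.rfft(s - s.mean())) ** 2
        peak_bin = np.argmax(spec)
        pos = np.flatnonzero(freqs > 0)
        expected = pos[np.argmin(np.abs(freqs[pos] - 0.017))]
        assert peak_bin == expected

    def test_same_seed_bit_identical(self, small_atlas):
        v1 = syn.simulate_bold(small_atlas, seed=3)
        v2 = syn.simulate_bold(small_atlas, seed=3)
        assert np.array_equal(v1.data, v2.data)

    def test_mismatched_covariance_rejected(self, small_atlas):
        cov = PlantedCovariance(latent_corr=np.eye(small_atlas.n_labels + 2))
        with pytest.raises(ValueError, match="nodes"):
            syn.simulate_bold(small_atlas, cov=cov, seed=0)

    def test_recovery_improves_with_more_timepoints(self, small_atlas):
        """Frobenius distance to the planted correlation matrix shrinks
        as the series lengthens (bias floor aside)."""
        n = small_atlas.n_labels
        R = syn.ring_shortcut_corr(n, rho=0.5, seed=0)
        cov = PlantedCovariance(latent_corr=R)
        dist = {}
        for T in (150, 300, 1200):
            ds = []
            for seed in range(20):
                vol = syn.simulate_bold(
                    small_atlas, ParadigmSpec(), cov, noise_sd=0.3,
                    seed=seed, n_timepoints=T, task_amplitude=0.0,
                )
                series = np.stack(
                    [parcel_mean_series(vol, small_atlas, lab)
                     for lab in range(1, n + 1)]
                )
                ds.append(np.linalg.norm(np.corrcoef(series) - R))
            dist[T] = np.mean(ds)
        assert dist[150] > dist[300] > dist[1200]


class TestPlantedCovariance:
    def test_non_psd_delta_projected_with_warning(self):
        R = np.eye(3)
        R[0, 1] = R[1, 0] = 0.9
        R[1, 2] = R[2, 1] = 0.9
        delta = np.zeros((3, 3))
        delta[0, 2] = delta[2, 0] = -0.9  # breaks PSD badly
        cov = PlantedCovariance(latent_corr=R, group_delta={"TBI": delta})
        atlas = syn.make_toy_atlas((12, 12, 8), 2, 2, seed=2,
                                   min_parcel_voxels=24)
        # 4 parcels needed; rebuild R at the right size
        n = atlas.n_labels
        R4 = np.eye(n)
        R4[0, 1] = R4[1, 0] = 0.9
        R4[1, 2] = R4[2, 1] = 0.9
        d4 = np.zeros((n, n))
        d4[0, 2] = d4[2, 0] = -0.9
        cov = PlantedCovariance(latent_corr=R4, group_delta={"TBI": d4})
        with pytest.warns(UserWarning, match="positive semidefinite"):
            syn.simulate_bold(atlas, cov=cov, subject_group="TBI",
                              noise_sd=0.0, seed=0)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            PlantedCovariance(latent_corr=np.array([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises(ValueError):
            PlantedCovariance(latent_corr=np.array([[1.0, 0.5], [0.4, 1.0]]))


def test_weighted_masks_bounded_and_seeded(small_atlas):
    m1 = syn.simulate_wm_weighted_masks(small_atlas, 3, seed=4)
    m2 = syn.simulate_wm_weighted_masks(small_atlas, 3, seed=4)
    assert len(m1) == 3
    for a, b in zip(m1, m2):
        assert np.array_equal(a, b)
        assert a.min() >= 0 and a.max() <= 1
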