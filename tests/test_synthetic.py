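"""Ground-truthed scene generation: landscapes, change events, rendering."""

import datetime as dt

import numpy as np
import pytest

from cmri import synthetic
from cmri.indices import compute_cmri
from cmri.synthetic import (BARE, MANGROVE_LABELS, MANGROVE_OTHER,
                            MANGROVE_RM, TERRESTRIAL, WATER,
                            PhenologyProfile, build_landscape,
                            default_profiles, inject_change,
                            pairwise_bayes_error, render_scenes)

FRACTIONS = {WATER: 0.3, TERRESTRIAL: 0.2, BARE: 0.1,
             MANGROVE_RM: 0.2, MANGROVE_OTHER: 0.2}


class TestBuildLandscape:
    def test_fractions_and_coverage(self):
        truth = build_landscape(seed=1, shape=(100, 100),
                                class_fractions=FRACTIONS, patch_scale=8)
        assert truth.label_grid.size == 10000
        for label, frac in FRACTIONS.items():
            count = int((truth.label_grid == label).sum())
            assert abs(count - frac * 10000) <= 200  # within 2 pp

    def test_determinism(self):
        a = build_landscape(seed=1, shape=(64, 64))
        b = build_landscape(seed=1, shape=(64, 64))
        assert np.array_equal(a.label_grid, b.label_grid)
        c = build_landscape(seed=2, shape=(64, 64))
        assert not np.array_equal(a.label_grid, c.label_grid)

    def test_bad_fractions_rejected(self):
        bad = dict(FRACTIONS)
        bad[WATER] = 0.2  # sums to 0.9
        with pytest.raises(ValueError, match="sum"):
            build_landscape(seed=1, shape=(64, 64), class_fractions=bad)

    def test_patch_scale_and_size_limits(self):
        with pytest.raises(ValueError, match="patch_scale"):
            build_landscape(seed=1, shape=(64, 64), patch_scale=64)
        with pytest.raises(ValueError, match="32"):
            build_landscape(seed=1, shape=(16, 16))

    def test_patches_are_contiguous(self):
        from scipy import ndimage
        truth = build_landscape(seed=4, shape=(64, 64), patch_scale=8)
        # each class should form few blobs, not salt-and-pepper
        for label in FRACTIONS:
            mask = truth.label_grid == label
            if mask.any():
                _, n = ndimage.label(mask)
                assert n <= mask.sum() / 10


class TestInjectChange:
    def test_bookkeeping(self):
        truth = build_landscape(seed=1, shape=(64, 64))
        out = inject_change(truth, n_loss=2, n_gain=0, area_px=40,
                            event_year=2020, seed=9)
        assert len(out.change_events) == 2
        assert sum(ev.area_px for ev in out.change_events) == 80
        # 80 px = 0.8 ha at 10 m: truth area drops by exactly that
        before = truth.mangrove_area_ha(dt.date(2019, 12, 31))
        after = out.mangrove_area_ha(dt.date(2020, 12, 31))
        assert before - after == pytest.approx(0.8)
        # input truth untouched
        assert truth.change_events == []

    def test_identity_when_no_events(self):
        truth = build_landscape(seed=1, shape=(64, 64))
        out = inject_change(truth, 0, 0, area_px=10, event_year=2020, seed=0)
        assert out.change_events == []
        assert np.array_equal(out.labels_at(dt.date(2021, 1, 1)),
                              truth.label_grid)

    def test_patches_contiguous_and_disjoint(self):
        from scipy import ndimage
        truth = build_landscape(seed=1, shape=(64, 64))
        out = inject_change(truth, n_loss=3, n_gain=1, area_px=25,
                            event_year=2020, seed=9)
        seen = np.zeros(truth.shape, bool)
        for ev in out.change_events:
            _, n = ndimage.label(ev.mask)
            assert n == 1  # one connected patch
            assert not (seen & ev.mask).any()
            seen |= ev.mask

    def test_gain_only_on_non_mangrove_loss_only_on_mangrove(self):
        truth = build_landscape(seed=1, shape=(64, 64))
        out = inject_change(truth, n_loss=1, n_gain=1, area_px=20,
                            event_year=2020, seed=9)
        for ev in out.change_events:
            src = truth.label_grid[ev.mask]
            if ev.kind == "loss":
                assert np.isin(src, MANGROVE_LABELS).all()
            else:
                assert not np.isin(src, MANGROVE_LABELS).any()

    def test_insufficient_area_rejected(self):
        truth = build_landscape(seed=1, shape=(64, 64))
        n_mangrove = int(np.isin(truth.label_grid, MANGROVE_LABELS).sum())
        with pytest.raises(ValueError, match="insufficient|could not"):
            inject_change(truth, n_loss=n_mangrove // 10 + 1, n_gain=0,
                          area_px=11, event_year=2020, seed=0)


class TestProfiles:
    def test_validation(self):
        with pytest.raises(ValueError, match="6"):
            PhenologyProfile(0, (0.1, 0.2), 0.05)
        with pytest.raises(ValueError, match="non-negative"):
            PhenologyProfile(0, (0,) * 6, -0.1)
        with pytest.raises(ValueError, match=r"\[-2, 2\]"):
            PhenologyProfile(0, (2.5,) + (0,) * 5, 0.1)

    def test_default_mangrove_profiles_separable(self):
        profiles = default_profiles()
        err = pairwise_bayes_error(profiles[MANGROVE_RM],
                                   profiles[MANGROVE_OTHER])
        assert err < 0.05


class TestRenderScenes:
    def test_noise_free_round_trip_exact(self, noisefree_world):
        """With sd = 0 the CMRI of a rendered scene equals the period
        mean of each pixel's class, to floating-point precision."""
        truth, profiles, scenes = noisefree_world
        assert len(scenes) == 6
        for scene in scenes:
            period = (scene.date.month - 1) // 2
            cmri = compute_cmri(scene)
            for label, prof in profiles.items():
                sel = truth.label_grid == label
                expected = prof.bimonthly_cmri_means[period]
                np.testing.assert_allclose(cmri.values[sel], expected,
                                           atol=1e-10)

    def test_scene_count_and_dates(self):
        truth = build_landscape(seed=3, shape=(32, 32), patch_scale=4)
        scenes = render_scenes(truth, default_profiles(), years=2,
                               scenes_per_period=3, seed=0,
                               start_year=2019)
        assert len(scenes) == 6 * 2 * 3
        for s in scenes:
            period = (s.date.month - 1) // 2 + 1
            assert s.date.year in (2019, 2020) and 1 <= period <= 6

    def test_no_clouds_when_range_zero(self, noisefree_world):
        _, _, scenes = noisefree_world
        assert all(s.cloud_fraction == 0.0 for s in scenes)

    def test_cloud_fraction_within_range(self):
        truth = build_landscape(seed=3, shape=(64, 64))
        scenes = render_scenes(truth, default_profiles(), years=1,
                               scenes_per_period=3,
                               cloud_fraction_range=(0.1, 0.3), seed=0)
        fracs = [s.cloud_fraction for s in scenes]
        assert all(0.05 <= f <= 0.35 for f in fracs)  # quantile granularity
        assert len(set(fracs)) > 1

    def test_determinism(self):
        truth = build_landscape(seed=3, shape=(32, 32), patch_scale=4)
        a = render_scenes(truth, default_profiles(), years=1,
                          scenes_per_period=2, seed=11)
        b = render_scenes(truth, default_profiles(), years=1,
                          scenes_per_period=2, seed=11)
        for sa, sb in zip(a, b):
            assert sa.date == sb.date
            np.testing.assert_array_equal(sa.nir, sb.nir)
            np.testing.assert_array_equal(sa.cloud_mask, sb.cloud_mask)

    def test_missing_profile_rejected(self):
        truth = build_landscape(seed=3, shape=(32, 32), patch_scale=4)
        profiles = default_profiles()
        del profiles[WATER]
        with pytest.raises(ValueError, match="profile"):
            render_scenes(truth, profiles, years=1, seed=0)

    def test_monte_carlo_mean_recovery(self):
        """sd = 0.05, 10 scenes/period: the per-pixel sample mean of the
        CMRI lies within 0.05 of the profile mean on >= 99% of pixels."""
        truth = build_landscape(seed=0, shape=(48, 48), patch_scale=6)
        profiles = default_profiles(mangrove_sd=0.05)
        scenes = render_scenes(truth, profiles, years=1,
                               scenes_per_period=10,
                               cloud_fraction_range=(0.0, 0.0), seed=0)
        per_period = {}
        for s in scenes:
            p = (s.date.month - 1) // 2
            per_period.setdefault(p, []).append(compute_cmri(s).values)
        hits = total = 0
        for p, stack in per_period.items():
            mean = np.mean(stack, axis=0)
            expected = np.zeros(truth.shape)
            for label, prof in profiles.items():
                expected[truth.label_grid == label] = \
                    prof.bimonthly_cmri_means[p]
            hits += int((np.abs(mean - expected) < 0.05).sum())
            total += mean.size
        assert hits / total >= 0.99

    def test_change_event_alters_rendered_index(self):
        truth = build_landscape(seed=3, shape=(48, 48), patch_scale=6)
        truth = inject_change(truth, n_loss=1, n_gain=0, area_px=30,
                              event_year=2020, seed=1)
        profiles = {k: PhenologyProfile(k, p.bimonthly_cmri_means, 0.0)
                    for k, p in default_profiles().items()}
        scenes = render_scenes(truth, profiles, years=[2019, 2020],
                               scenes_per_period=1,
                               cloud_fraction_range=(0, 0), seed=0)
        ev = truth.change_events[0]
        before = [s for s in scenes if s.date.year == 2019]
        after = [s for s in scenes if s.date.year == 2020]
        high = compute_cmri(before[0]).values[ev.mask].mean()
        low = compute_cmri(after[0]).values[ev.mask].mean()
        assert high > 0.5 and low < 0.2  # mangrove became bare
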