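"""Synthetic cohort generator: demographics, atlas, image synthesis, IO."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import volmatch as vm
from volmatch.cohort import TruncNormLaw, read_cohort


class TestDemographics:
    def test_per_sex_tiv_means_near_profile(self):
        records = vm.sample_demographics(vm.SHIP_PROFILE, seed=0)
        df = pd.DataFrame([dataclasses.asdict(r) for r in records])
        assert len(df) == 3298
        for sex, law in [("male", vm.SHIP_PROFILE.tiv_law_male),
                         ("female", vm.SHIP_PROFILE.tiv_law_female)]:
            sub = df[df.sex == sex]
            se = law.sd / np.sqrt(len(sub))
            assert abs(sub.tiv_ml.mean() - law.mean) < 3 * se
            assert sub.tiv_ml.between(law.lo, law.hi).all()

    def test_degenerate_male_fraction(self):
        prof = dataclasses.replace(vm.SHIP_PROFILE, n=50, male_fraction=0.0)
        records = vm.sample_demographics(prof, seed=1)
        assert all(r.sex == "female" for r in records)

    def test_seeded_determinism(self):
        a = vm.sample_demographics(vm.HCP_PROFILE, seed=7)
        b = vm.sample_demographics(vm.HCP_PROFILE, seed=7)
        assert a == b

    def test_unique_ids(self):
        records = vm.sample_demographics(vm.HCP_PROFILE, seed=0)
        ids = [r.subject_id for r in records]
        assert len(set(ids)) == len(ids)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            dataclasses.replace(
                vm.SHIP_PROFILE,
                age_law=TruncNormLaw(50.0, 10.0, 90.0, 21.0))


class TestAtlas:
    def test_single_region_equals_mask(self):
        atlas = vm.build_atlas((14, 16, 14), 1, seed=0)
        assert np.array_equal(atlas.label_grid > 0, atlas.label_grid == 1)

    def test_partition_properties(self, desk_atlas):
        atlas = desk_atlas
        labels = np.unique(atlas.label_grid)
        assert set(labels.tolist()) == set(range(18))  # 0 + 17 regions
        # regions cover the mask and are pairwise disjoint by construction
        assert (atlas.label_grid > 0).sum() == sum(
            atlas.region_voxel_counts().values())

    def test_region_counts_match_brute_force(self, desk_atlas):
        counts = desk_atlas.region_voxel_counts()
        for lab in desk_atlas.label_table:
            assert counts[lab] == int((desk_atlas.label_grid == lab).sum())
            assert counts[lab] > 0

    def test_determinism_and_overflow_guard(self):
        a = vm.build_atlas((14, 16, 14), 4, seed=5)
        b = vm.build_atlas((14, 16, 14), 4, seed=5)
        assert np.array_equal(a.label_grid, b.label_grid)
        with pytest.raises(ValueError):
            vm.build_atlas((6, 6, 6), 10_000, seed=0)


def _record(sex="female", tiv=1500.0):
    return vm.SubjectRecord(subject_id="s0", sex=sex, age_years=50.0,
                            tiv_ml=tiv, cohort_label="test")


def _flat_effects(atlas, tiv_ref=1500.0, beta=1.0, s=0.0, noise=0.0):
    counts = atlas.region_voxel_counts()
    base = np.array([counts[i + 1] for i in range(atlas.n_regions)], float)
    base *= 600.0 / base.sum()
    return vm.EffectSpec(base_volume_ml=base,
                         tiv_exponent=np.full(atlas.n_regions, beta),
                         sex_effect=np.full(atlas.n_regions, s),
                         noise_sd_ml=noise, tiv_ref_ml=tiv_ref)


class TestSynthesizeImage:
    def test_proportional_scaling_limit(self, tiny_atlas):
        """beta=1, s=0, zero noise: image is TIV/TIV_ref times the template."""
        eff = _flat_effects(tiny_atlas)
        ref = vm.synthesize_image(_record(tiv=1500.0), tiny_atlas, eff, seed=0)
        img = vm.synthesize_image(_record(tiv=1800.0), tiny_atlas, eff, seed=0)
        np.testing.assert_allclose(img.values, ref.values * 1.2, rtol=1e-5)

    def test_planted_effect_exact(self, tiny_atlas):
        eff = _flat_effects(tiny_atlas)
        eff.sex_effect[1] = 0.1
        male = vm.synthesize_image(_record("male"), tiny_atlas, eff, seed=0)
        female = vm.synthesize_image(_record("female"), tiny_atlas, eff, seed=0)
        r1 = tiny_atlas.region_mask(2)
        assert np.isclose(female.values[r1].sum(), 1.1 * male.values[r1].sum(),
                          rtol=1e-5)
        np.testing.assert_allclose(female.values[~r1], male.values[~r1],
                                   rtol=1e-6)

    def test_power_law_closed_form(self, tiny_atlas):
        eff = _flat_effects(tiny_atlas)
        eff.tiv_exponent[0] = 0.8
        a = vm.synthesize_image(_record(tiv=1500.0), tiny_atlas, eff, seed=0)
        b = vm.synthesize_image(_record(tiv=3000.0), tiny_atlas, eff, seed=0)
        r0 = tiny_atlas.region_mask(1)
        ratio = b.values[r0].sum() / a.values[r0].sum()
        assert np.isclose(ratio, 2.0 ** 0.8, rtol=1e-5)

    def test_negative_volume_rejected(self, tiny_atlas):
        with pytest.raises(ValueError):
            vm.EffectSpec(base_volume_ml=np.ones(4),
                          tiv_exponent=np.ones(4),
                          sex_effect=np.array([0.0, 0.0, 0.0, -1.0]),
                          noise_sd_ml=0.0, tiv_ref_ml=1500.0)

    def test_voxel_sum_tracks_gmv(self, ship600):
        cohort, frame, _ = ship600
        sums = cohort.images.reshape(cohort.n, -1).sum(axis=1)
        np.testing.assert_allclose(sums, frame.gmv_ml, rtol=0.01)


class TestCohortIO:
    def test_round_trip(self, tiny_cohort, tmp_path):
        cohort, frame, _ = tiny_cohort
        vm.write_cohort(cohort, tmp_path)
        df, images, atlas = read_cohort(tmp_path)
        assert len(df) == cohort.n
        np.testing.assert_allclose(images, cohort.images, atol=1e-6)
        assert np.array_equal(atlas.label_grid, cohort.atlas.label_grid)
        # voxel sums of written images agree with the recorded GMV
        sums = images.reshape(len(df), -1).sum(axis=1)
        np.testing.assert_allclose(sums, df.gmv_ml, rtol=0.01)


class TestGeneratorProperties:
    def test_seed_determinism_full_cohort(self, tiny_atlas):
        a = vm.simulate_cohort(vm.HCP_PROFILE, seed=9, n=12, atlas=tiny_atlas)
        b = vm.simulate_cohort(vm.HCP_PROFILE, seed=9, n=12, atlas=tiny_atlas)
        assert a.records == b.records
        np.testing.assert_array_equal(a.images, b.images)

    def test_tiv_decodable_with_heterogeneous_beta(self, ship600):
        """Normalized images still carry TIV information when regional
        volumes follow heterogeneous power laws."""
        from sklearn.linear_model import Ridge
        from sklearn.model_selection import train_test_split

        cohort, frame, norm = ship600
        X = norm.reshape(cohort.n, -1)
        Xtr, Xte, ytr, yte = train_test_split(
            X, frame.tiv_ml.to_numpy(), random_state=0)
        assert Ridge(alpha=10.0).fit(Xtr, ytr).score(Xte, yte) > 0.2

    def test_proportional_scaling_removes_all_information(self, tiny_atlas):
        """With beta=1 and no noise, normalization makes same-sex images
        identical, so no TIV signal can survive."""
        from volmatch.preprocess import normalize_stack

        eff = _flat_effects(tiny_atlas)
        # distinct per-region densities so the normalized image is nontrivial
        eff.base_volume_ml *= np.array([0.5, 1.0, 1.5, 2.0])[:tiny_atlas.n_regions]
        cohort = vm.simulate_cohort(vm.SHIP_PROFILE, seed=4, n=20,
                                    atlas=tiny_atlas, effects=eff)
        norm = normalize_stack(cohort.images, tiny_atlas.mask)
        female = norm[cohort.labels == 1]
        spread = np.abs(female - female[0]).max()
        assert spread < 1e-4


class TestProfileYaml:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "profile.yaml"
        vm.save_profile(vm.HCP_PROFILE, path)
        loaded = vm.load_profile(path)
        assert loaded == vm.HCP_PROFILE
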