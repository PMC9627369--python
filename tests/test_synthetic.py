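import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nacfc.fc import seed_fc_maps
from nacfc.synthetic import (
    SCORE_RANGES,
    AtlasSpec,
    RoiSpec,
    SimulationSpec,
    SiteSpec,
    apply_site_effects,
    assign_targets,
    generate_atlas,
    generate_bold,
    generate_cohort,
    qc_filter,
)


class TestAtlas:
    def test_degenerate_blob_is_single_voxel(self):
        spec = AtlasSpec(rois=(RoiSpec("core_L", (5, 5, 5), 0.0),
                               RoiSpec("core_R", (15, 15, 15), 0.0)))
        atlas = generate_atlas(spec)
        pmap = atlas.rois["core_L"]
        assert pmap[5, 5, 5] == 1.0
        assert np.sum(pmap > 0) == 1

    def test_deterministic(self):
        a, b = generate_atlas(seed=1), generate_atlas(seed=1)
        for name in a.rois:
            assert a.rois[name].tobytes() == b.rois[name].tobytes()
        assert a.brain_mask.tobytes() == b.brain_mask.tobytes()

    def test_gaussian_kernel_falloff(self):
        spec = AtlasSpec(rois=(RoiSpec("core_L", (6, 12, 12), 2.0),
                               RoiSpec("core_R", (18, 12, 12), 2.0)))
        atlas = generate_atlas(spec)
        pmap = atlas.rois["core_L"]
        ratio = pmap[7, 12, 12] / pmap[6, 12, 12]
        assert ratio == pytest.approx(np.exp(-1 / (2 * 4)), rel=1e-12)

    def test_invariants_on_default_atlas(self, atlas):
        for name, pmap in atlas.rois.items():
            assert pmap.min() >= 0 and pmap.max() <= 1
            assert not np.any((pmap > 0) & ~atlas.brain_mask)
            assert np.sum(pmap > 0.5) >= 10
        centroid_x = {
            name: np.average(np.arange(atlas.grid_dims[0]),
                             weights=pmap.sum(axis=(1, 2)))
            for name, pmap in atlas.rois.items()
        }
        for part in ("core", "shell"):
            assert centroid_x[f"{part}_L"] < centroid_x[f"{part}_R"]

    def test_overlapping_rois_rejected(self):
        spec = AtlasSpec(rois=(RoiSpec("core_L", (10, 10, 10), 2.0),
                               RoiSpec("shell_L", (11, 10, 10), 2.0)))
        with pytest.raises(ValueError, match="overlap"):
            generate_atlas(spec)

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError, match="at least 20"):
            generate_atlas(AtlasSpec(grid_dims=(16, 24, 24)))


class TestCohort:
    def test_decoupled_scores_uncorrelated(self):
        spec = SimulationSpec(n_pd=2000, n_hc=10,
                              behavior_loadings={}, seed=3)
        table = generate_cohort(spec)
        pd_rows = table[table.group == "PD"]
        r = np.corrcoef(pd_rows.GDS, pd_rows.MoCA)[0, 1]
        assert abs(r) < 0.08

    def test_planted_loadings_induce_negative_correlation(self):
        spec = SimulationSpec(
            n_pd=1000, n_hc=10, seed=4,
            behavior_loadings={"GDS": 8.0, "MoCA": -8.0},
        )
        table = generate_cohort(spec)
        pd_rows = table[table.group == "PD"]
        assert np.corrcoef(pd_rows.GDS, pd_rows.MoCA)[0, 1] < -0.2

    def test_pd_shifts_follow_clinical_directions(self):
        table = generate_cohort(SimulationSpec(n_pd=400, n_hc=400, seed=5))
        g = table.groupby("group")
        for col in ("GDS", "STAI", "apathy", "RBDSQ", "ESS"):
            assert g[col].mean()["PD"] > g[col].mean()["HC"]
        for col in ("MoCA", "UPSIT"):
            assert g[col].mean()["PD"] < g[col].mean()["HC"]

    def test_deterministic(self):
        spec = SimulationSpec(n_pd=30, n_hc=30, seed=9)
        pd.testing.assert_frame_equal(generate_cohort(spec),
                                      generate_cohort(spec))

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        n_pd=st.integers(2, 60),
        n_hc=st.integers(2, 60),
        seed=st.integers(0, 2**20),
        slope=st.floats(0.0, 0.6),
    )
    def test_table_invariants_over_random_specs(self, n_pd, n_hc, seed, slope):
        spec = SimulationSpec(n_pd=n_pd, n_hc=n_hc, seed=seed,
                              coupling_loss_slope=slope)
        table = generate_cohort(spec)
        assert len(table) == n_pd + n_hc
        for score, (lo, hi) in SCORE_RANGES.items():
            assert table[score].between(lo, hi).all()
        hc = table[table.group == "HC"]
        assert (hc.duration == 0).all() and (hc.ledd == 0).all()
        assert (hc.latent_severity == 0).all()
        assert (table.mean_fd >= 0).all()


class TestBold:
    def test_null_coupling_gives_null_correlations(self, atlas):
        spec = SimulationSpec(n_pd=2, n_hc=2, n_timepoints=400,
                              coupling_hc=0.0, coupling_loss_slope=0.0,
                              n_target_voxels=200, seed=6)
        targets = assign_targets(atlas, spec)
        cohort = generate_cohort(spec)
        bold = generate_bold(cohort.iloc[0], atlas, targets, spec)
        fcmap = seed_fc_maps(bold, atlas, seeds=["core_L"])["core_L"]
        r = np.tanh(fcmap.values[targets["core_L"]])
        assert np.mean(np.abs(r) < 3 / np.sqrt(400)) >= 0.99

    def test_noiseless_unit_coupling_is_perfect_correlation(self):
        # seeds far enough apart that their probability tails do not overlap,
        # so the extracted reference is the pure seed signal
        atlas = generate_atlas(AtlasSpec(rois=(
            RoiSpec("core_L", (4, 12, 12), 1.2),
            RoiSpec("core_R", (19, 12, 12), 1.2))))
        spec = SimulationSpec(n_pd=2, n_hc=2, n_timepoints=60, noise_sd=0.0,
                              coupling_hc=1.0, coupling_loss_slope=0.0,
                              n_target_voxels=50, seed=6,
                              effect_seeds=("core_L",))
        targets = assign_targets(atlas, spec)
        cohort = generate_cohort(spec)
        bold = generate_bold(cohort.iloc[-1], atlas, targets, spec)  # HC row
        fcmap = seed_fc_maps(bold, atlas, seeds=["core_L"])["core_L"]
        z = fcmap.values[targets["core_L"]]
        assert np.allclose(z, np.arctanh(1 - 1e-7))

    def test_coupling_closed_form_correlation(self, atlas):
        # population r = a sigma_s / sqrt(a^2 sigma_s^2 + sigma_eps^2)
        spec = SimulationSpec(n_pd=2, n_hc=2, n_timepoints=2000,
                              coupling_hc=0.5, coupling_loss_slope=0.0,
                              noise_sd=1.0, n_target_voxels=200, seed=8)
        targets = assign_targets(atlas, spec)
        cohort = generate_cohort(spec)
        bold = generate_bold(cohort.iloc[-1], atlas, targets, spec)
        fcmap = seed_fc_maps(bold, atlas, seeds=["core_L"])["core_L"]
        r = np.tanh(fcmap.values[targets["core_L"]])
        expected = 0.5 / np.sqrt(1.25)
        assert np.mean(r) == pytest.approx(expected, abs=0.03)

    def test_deterministic_per_subject(self, atlas, small_spec, small_targets,
                                       small_cohort):
        row = small_cohort.iloc[0]
        b1 = generate_bold(row, atlas, small_targets, small_spec)
        b2 = generate_bold(row, atlas, small_targets, small_spec)
        assert b1.data.tobytes() == b2.data.tobytes()


class TestSiteEffects:
    def _maps(self, cohort, n_vox=300, seed=0):
        from nacfc.fc import FCMap

        rng = np.random.default_rng(seed)
        shape = (n_vox, 1, 1)
        return [FCMap(row.subject_id, "core_L", rng.normal(size=shape))
                for row in cohort.itertuples()]

    def _cohort(self, n, sites):
        half = n // 2
        return pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "group": ["PD"] * n,
            "site": [sites[0]] * half + [sites[1]] * (n - half),
        })

    def test_identity_sites(self):
        spec = SimulationSpec(sites=(SiteSpec("a", 0.5), SiteSpec("b", 0.5)))
        cohort = self._cohort(20, ("a", "b"))
        maps = self._maps(cohort)
        out = apply_site_effects(maps, cohort, spec)
        for m_in, m_out in zip(maps, out):
            assert np.array_equal(m_in.values, m_out.values)

    def test_additive_offset_shifts_site_mean(self):
        spec = SimulationSpec(sites=(SiteSpec("a", 0.5, 0.0, 1.0),
                                     SiteSpec("b", 0.5, 1.0, 1.0)))
        cohort = self._cohort(40, ("a", "b"))
        out = apply_site_effects(self._maps(cohort), cohort, spec)
        A = np.stack([m.values for m, s in zip(out, cohort.site) if s == "a"])
        B = np.stack([m.values for m, s in zip(out, cohort.site) if s == "b"])
        raw = self._maps(cohort)
        Ar = np.stack([m.values for m, s in zip(raw, cohort.site) if s == "a"])
        Br = np.stack([m.values for m, s in zip(raw, cohort.site) if s == "b"])
        shift = (B.mean(axis=0) - A.mean(axis=0)) - (Br.mean(axis=0) - Ar.mean(axis=0))
        assert np.allclose(shift, 1.0, atol=1e-12)

    def test_scale_factor_inflates_site_variance(self):
        spec = SimulationSpec(sites=(SiteSpec("a", 0.5, 0.0, 1.0),
                                     SiteSpec("b", 0.5, 0.0, 2.0)))
        cohort = self._cohort(1000, ("a", "b"))
        out = apply_site_effects(self._maps(cohort, n_vox=200), cohort, spec)
        A = np.stack([m.values for m, s in zip(out, cohort.site) if s == "a"])
        B = np.stack([m.values for m, s in zip(out, cohort.site) if s == "b"])
        ratio = B.var(axis=0) / A.var(axis=0)
        assert ratio.mean() == pytest.approx(4.0, rel=0.1)

    def test_unknown_site_rejected(self):
        spec = SimulationSpec(sites=(SiteSpec("a", 0.5), SiteSpec("b", 0.5)))
        cohort = self._cohort(10, ("a", "zzz"))
        with pytest.raises(ValueError, match="site"):
            apply_site_effects(self._maps(cohort), cohort, spec)


class TestQcFilter:
    def _manifest(self, n_pd, flagged_pd, n_hc, flagged_hc):
        return pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n_pd + n_hc)],
            "group": ["PD"] * n_pd + ["HC"] * n_hc,
            "motion_flag": [i < flagged_pd for i in range(n_pd)]
            + [i < flagged_hc for i in range(n_hc)],
        })

    def test_study_exclusion_counts(self):
        table = self._manifest(129, 13, 106, 6)
        kept, excluded = qc_filter(table)
        counts = kept.group.value_counts()
        assert counts["PD"] == 116 and counts["HC"] == 100
        assert excluded == {"PD": 13, "HC": 6}

    def test_no_flags_is_identity(self):
        table = self._manifest(10, 0, 10, 0)
        kept, excluded = qc_filter(table)
        assert len(kept) == 20 and excluded == {"PD": 0, "HC": 0}

    def test_all_flagged_warns_not_raises(self):
        table = self._manifest(4, 4, 3, 3)
        with pytest.warns(UserWarning, match="all subjects"):
            kept, _ = qc_filter(table)
        assert kept.empty

    def test_fd_threshold_criterion(self):
        table = pd.DataFrame({
            "subject_id": list("abcd"),
            "group": ["PD", "PD", "HC", "HC"],
            "mean_fd": [0.2, 0.7, 0.1, 0.9],
        })
        kept, excluded = qc_filter(table, flag_col=None, fd_threshold=0.5)
        assert list(kept.subject_id) == ["a", "c"]
        assert excluded == {"PD": 1, "HC": 1}

    def test_missing_columns_rejected(self):
        table = pd.DataFrame({"subject_id": ["a"], "group": ["PD"]})
        with pytest.raises(ValueError):
            qc_filter(table)
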