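"""Synthetic generator: determinism, structural constraints, planted effects."""

import numpy as np
import pytest
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components as sp_cc

import stconnectome as st
from conftest import pool_from_cohort


class TestParcellation:
    def test_minimal_one_region_per_system(self):
        parc = st.generate_parcellation(8, tuple([1] * 8), seed=0)
        assert parc.n_regions == 8
        assert set(parc.systems) == set(st.SYSTEMS)

    def test_deterministic_for_fixed_seed(self):
        a = st.generate_parcellation(80, tuple([10] * 8), seed=1)
        b = st.generate_parcellation(80, tuple([10] * 8), seed=1)
        assert np.array_equal(a.systems, b.systems)
        assert np.array_equal(a.region_names, b.region_names)

    def test_full_scale_dimensioning(self):
        parc = st.generate_parcellation(506)
        assert parc.n_regions == 506
        assert all(s in st.SYSTEMS for s in parc.systems)
        # all 8 systems nonempty
        assert set(parc.systems) == set(st.SYSTEMS)

    def test_mismatched_counts_raise(self):
        with pytest.raises(st.DimensionError):
            st.generate_parcellation(10, tuple([1] * 8), seed=0)


class TestStructuralConnectome:
    def test_full_within_none_between_is_block_structure(self):
        parc = st.generate_parcellation(24, tuple([3] * 8), seed=2)
        sc = st.generate_structural_connectome(parc, p_in=1.0, p_out=0.0, seed=3)
        adj = sc.binarized()
        same = parc.system_idx[:, None] == parc.system_idx[None, :]
        off_diag = ~np.eye(24, dtype=bool)
        assert np.all(adj[same & off_diag])
        assert not np.any(adj[~same])
        n_comp, _ = sp_cc(sparse.csr_matrix(adj), directed=False)
        assert n_comp == 8  # one structural module per system

    def test_zero_probabilities_give_empty_graph(self):
        parc = st.generate_parcellation(16, tuple([2] * 8), seed=2)
        sc = st.generate_structural_connectome(parc, 0.0, 0.0, seed=3)
        assert sc.weights.sum() == 0

    def test_empirical_densities_match_binomial_targets(self):
        parc = st.generate_parcellation(80, tuple([10] * 8), seed=4)
        p_in, p_out = 0.5, 0.05
        same = parc.system_idx[:, None] == parc.system_idx[None, :]
        upper = np.triu(np.ones((80, 80), dtype=bool), k=1)
        n_in = int((same & upper).sum())
        n_out = int((~same & upper).sum())
        hits_in = hits_out = 0
        n_seeds = 200
        for seed in range(n_seeds):
            adj = st.generate_structural_connectome(parc, p_in, p_out, seed=seed).binarized()
            hits_in += int(adj[same & upper].sum())
            hits_out += int(adj[~same & upper].sum())
        for hits, n_pairs, p in ((hits_in, n_in, p_in), (hits_out, n_out, p_out)):
            total = n_pairs * n_seeds
            se = np.sqrt(p * (1 - p) / total)
            assert abs(hits / total - p) < 3 * se

    def test_invalid_probabilities_raise(self):
        parc = st.generate_parcellation(16, tuple([2] * 8), seed=2)
        with pytest.raises(st.ValidationError):
            st.generate_structural_connectome(parc, p_in=1.2, p_out=0.0)
        with pytest.raises(st.ValidationError):
            st.generate_structural_connectome(parc, p_in=0.1, p_out=0.5)


class TestCohort:
    def test_zero_event_rate_gives_all_zero_rasters(self, small_template):
        labels, sc = small_template
        params = st.SimParams(
            n_regions=40, n_frames=50, n_subjects_a=2, n_subjects_b=2, event_rate=0.0, seed=5
        )
        cohort = st.generate_cohort(params, labels, sc)
        for s in cohort.subjects:
            assert not s.data.any()

    def test_no_propagation_gives_isolated_single_cell_cascades(self, small_template):
        labels, sc = small_template
        params = st.SimParams(
            n_regions=40,
            n_frames=60,
            n_subjects_a=2,
            n_subjects_b=2,
            event_rate=0.3,
            spread_prob=0.0,
            persist_prob=0.0,
            seed=6,
        )
        cohort = st.generate_cohort(params, labels, sc, log_cascades=True)
        assert cohort.cascade_log  # events did occur
        for entry in cohort.cascade_log:
            assert len(entry["nodes"]) == 1

    def test_cascades_confined_to_structural_components(self, small_template):
        """Every region pair co-active within one cascade has a structural path."""
        labels, sc = small_template
        params = st.SimParams(
            n_regions=40, n_frames=60, n_subjects_a=2, n_subjects_b=2,
            cross_system_coupling=0.5, drift_prob=0.4, seed=7,
        )
        cohort = st.generate_cohort(params, labels, sc, log_cascades=True)
        n_comp, memb = sp_cc(sparse.csr_matrix(sc.binarized()), directed=False)
        for entry in cohort.cascade_log:
            regions = {r for r, _ in entry["nodes"]}
            assert len({memb[r] for r in regions}) == 1

    def test_bit_identical_for_fixed_seed(self, small_template):
        labels, sc = small_template
        params = st.SimParams(n_regions=40, n_frames=40, n_subjects_a=2, n_subjects_b=2, seed=9)
        a = st.generate_cohort(params, labels, sc)
        b = st.generate_cohort(params, labels, sc)
        for sa, sb in zip(a.subjects, b.subjects):
            assert sa.subject_id == sb.subject_id and sa.age == sb.age
            assert np.array_equal(sa.data, sb.data)

    def test_invalid_mode_raises(self, small_template):
        labels, sc = small_template
        params = st.SimParams(n_regions=40, n_frames=10, n_subjects_a=1, n_subjects_b=1)
        with pytest.raises(st.ValidationError):
            st.generate_cohort(params, labels, sc, mode="nifti")

    def test_cross_coupling_raises_multi_system_cc_fraction(self, small_template):
        """eta_A = 0.9 vs eta_B = 0.1 yields more multi-system CCs in A."""
        labels, sc = small_template
        wins = 0
        n_rep = 10
        for seed in range(n_rep):
            params = st.SimParams(
                n_regions=40, n_frames=100, n_subjects_a=4, n_subjects_b=4,
                cross_system_coupling=(0.9, 0.1), seed=seed,
            )
            cohort = st.generate_cohort(params, labels, sc)
            pool = pool_from_cohort(cohort, labels, sc)
            att = pool.attribution_mask(0.20)
            multi = att.sum(axis=1) >= 2
            in_a = np.array([s.startswith("A") for s in pool.subjects])
            frac_a = multi[in_a].mean()
            frac_b = multi[~in_a].mean()
            wins += frac_a > frac_b
        assert wins >= 8  # sign test over replicates


class TestBoldMode:
    def test_kernel_peak_at_lag_zero(self):
        assert np.argmax(st.BOLD_KERNEL) == 0
        assert st.BOLD_KERNEL[0] == 1.0

    def test_point_process_recovers_planted_cells(self, small_template):
        """At noise 0.2 x kernel peak: >= 80% recall, <= 5% spurious cells."""
        labels, sc = small_template
        params = st.SimParams(
            n_regions=40, n_frames=200, n_subjects_a=3, n_subjects_b=3,
            noise_sd=0.2, seed=10,
        )
        planted = st.generate_cohort(params, labels, sc, mode="raster")
        bold = st.generate_cohort(params, labels, sc, mode="bold")
        recalls, spurious = [], []
        for p_subj, b_subj in zip(planted.subjects, bold.subjects):
            truth = p_subj.data.astype(bool)
            got = st.zscore_threshold(b_subj.data, 2.0).active
            recalls.append((got & truth).sum() / max(truth.sum(), 1))
            spurious.append((got & ~truth).sum() / (~truth).sum())
        assert np.mean(recalls) >= 0.80
        assert np.mean(spurious) <= 0.05

    def test_bold_mode_is_raster_convolution_plus_noise(self, small_template):
        labels, sc = small_template
        params = st.SimParams(
            n_regions=40, n_frames=50, n_subjects_a=1, n_subjects_b=1,
            noise_sd=0.0, seed=11,
        )
        raster = st.generate_cohort(params, labels, sc, mode="raster")
        bold = st.generate_cohort(params, labels, sc, mode="bold")
        for r_subj, b_subj in zip(raster.subjects, bold.subjects):
            expected = np.apply_along_axis(
                lambda row: np.convolve(row, st.BOLD_KERNEL)[:50],
                1,
                r_subj.data.astype(float),
            )
            assert np.allclose(b_subj.data, expected)


class TestMonotonicity:
    """Rank correlation of the dials with their target metrics (5-point grids)."""

    @staticmethod
    def _grid_metric(small_template, values, make_params, measure):
        labels, sc = small_template
        xs, ys = [], []
        for v in values:
            for seed in range(10):
                cohort = st.generate_cohort(make_params(v, seed), labels, sc)
                pool = pool_from_cohort(cohort, labels, sc)
                xs.append(v)
                ys.append(measure(pool))
        return stats.spearmanr(xs, ys).statistic

    def test_sd_non_decreasing_in_cross_coupling(self, small_template):
        rho = self._grid_metric(
            small_template,
            [0.0, 0.2, 0.4, 0.6, 0.8],
            lambda eta, seed: st.SimParams(
                n_regions=40, n_frames=80, n_subjects_a=3, n_subjects_b=3,
                cross_system_coupling=eta, seed=seed,
            ),
            lambda pool: st.system_diversity(pool).value,
        )
        assert rho > 0

    def test_std_non_decreasing_in_drift(self, small_template):
        rho = self._grid_metric(
            small_template,
            [0.0, 0.15, 0.3, 0.45, 0.6],
            lambda drift, seed: st.SimParams(
                n_regions=40, n_frames=80, n_subjects_a=3, n_subjects_b=3,
                cross_system_coupling=0.05, drift_prob=drift, seed=seed,
            ),
            lambda pool: st.spatiotemporal_diversity(pool).value,
        )
        assert rho > 0

    def test_mean_height_increasing_in_spread(self, small_template):
        def mean_height(pool):
            return float(np.mean([c.height for c in pool.components]))

        rho = self._grid_metric(
            small_template,
            [0.05, 0.15, 0.25, 0.35, 0.45],
            lambda spread, seed: st.SimParams(
                n_regions=40, n_frames=80, n_subjects_a=3, n_subjects_b=3,
                spread_prob=spread, max_extent=40, seed=seed,
            ),
            mean_height,
        )
        assert rho > 0


class TestAgeEffect:
    def test_age_shrinks_cascade_extent_cap(self, small_template):
        labels, sc = small_template
        young = {"A": [5.0], "B": [5.0]}
        old = {"A": [17.0], "B": [17.0]}
        heights = {}
        for name, ages in (("young", young), ("old", old)):
            vals = []
            for seed in range(6):
                params = st.SimParams(
                    n_regions=40, n_frames=80, n_subjects_a=1, n_subjects_b=1,
                    spread_prob=0.5, persist_prob=0.6, max_extent=8,
                    age_effect=0.08, ages=ages, seed=seed,
                )
                cohort = st.generate_cohort(params, labels, sc)
                pool = pool_from_cohort(cohort, labels, sc)
                vals.append(np.mean([c.height for c in pool.components]))
            heights[name] = np.mean(vals)
        assert heights["young"] > heights["old"]


def test_write_cohort_layout(tmp_path, small_template):
    labels, sc = small_template
    params = st.SimParams(n_regions=40, n_frames=20, n_subjects_a=2, n_subjects_b=1, seed=13)
    cohort = st.generate_cohort(params, labels, sc)
    out = st.write_cohort(tmp_path / "study", cohort, labels, sc, params)
    assert (out / "labels.tsv").exists()
    assert (out / "sc.tsv").exists()
    assert (out / "params.yaml").exists()
    manifest = st.read_manifest(out / "manifest.csv")
    assert len(manifest) == 3
    for rec in manifest.itertuples(index=False):
        data, _ = st.read_matrix_tsv(out / rec.path)
        assert data.shape == (40, 20)
        assert set(np.unique(data)) <= {0.0, 1.0}
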