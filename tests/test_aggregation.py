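"""Surface aggregation: HR binning, exponent densities, group averaging."""
import numpy as np
import pytest
from scipy import stats as sps

from ddfa_hrv import (
    CohortManifest,
    DDFALandscape,
    Group,
    ManifestEntry,
    density_surface,
    group_surface,
    hr_surface,
    split_subgroups,
)


def fake_landscape(alpha, hr, scales=None):
    alpha = np.asarray(alpha, dtype=float)
    hr = np.asarray(hr, dtype=float)
    scales = np.arange(5, 5 + alpha.shape[1]) if scales is None else np.asarray(scales)
    return DDFALandscape(
        alpha=alpha,
        t=np.cumsum(np.ones_like(alpha), axis=0),
        hr=hr,
        scales=scales,
        n_windows=np.full(alpha.shape[1], alpha.shape[0]),
    )


class TestHRSurface:
    def test_default_binning_is_190_one_bpm_bins(self):
        landscape = fake_landscape([[1.0]], [[75.0]])
        surface = hr_surface(landscape)
        assert surface.alpha_mean.shape[0] == 190
        assert surface.hr_edges[0] == 30.0 and surface.hr_edges[-1] == 220.0
        np.testing.assert_allclose(np.diff(surface.hr_edges), 1.0)

    def test_single_hr_occupies_one_bin_per_scale(self):
        landscape = fake_landscape(np.ones((20, 3)), np.full((20, 3), 75.4))
        surface = hr_surface(landscape)
        assert np.all((surface.counts > 0).sum(axis=0) == 1)
        row = int(np.flatnonzero(surface.counts[:, 0])[0])
        assert surface.hr_edges[row] <= 75.4 < surface.hr_edges[row + 1]

    def test_values_land_in_their_bins_exactly(self):
        landscape = fake_landscape(
            [[0.8], [1.2]], [[60.0], [120.0]]
        )
        surface = hr_surface(landscape)
        assert surface.alpha_mean[30, 0] == pytest.approx(0.8)  # 60 bpm -> bin 30
        assert surface.alpha_mean[90, 0] == pytest.approx(1.2)  # 120 bpm -> bin 90

    def test_out_of_range_entries_dropped_and_counted(self):
        landscape = fake_landscape(
            [[1.0], [1.0], [1.0]], [[25.0], [75.0], [230.0]]
        )
        surface = hr_surface(landscape)
        assert surface.counts.sum() == 1
        assert surface.dropped.sum() == 2

    def test_count_conservation(self):
        rng = np.random.default_rng(0)
        alpha = rng.uniform(0, 2, (200, 4))
        alpha[rng.uniform(size=alpha.shape) < 0.3] = np.nan
        hr = rng.uniform(20.0, 240.0, (200, 4))
        landscape = fake_landscape(alpha, hr)
        surface = hr_surface(landscape)
        for j in range(4):
            defined_j = np.isfinite(alpha[:, j]).sum()
            assert surface.counts[:, j].sum() + surface.dropped[j] == defined_j


class TestDensitySurface:
    def test_default_binning_is_50_uniform_bins(self):
        surface = density_surface(fake_landscape([[1.0]], [[75.0]]))
        assert surface.rho.shape[0] == 50
        assert surface.alpha_edges[0] == 0.0 and surface.alpha_edges[-1] == 2.0
        np.testing.assert_allclose(np.diff(surface.alpha_edges), 0.04)

    def test_point_mass_lands_in_one_bin(self):
        surface = density_surface(fake_landscape(np.ones((30, 1)), np.full((30, 1), 70.0)))
        assert surface.rho[:, 0].sum() == pytest.approx(1.0)
        assert (surface.rho[:, 0] > 0).sum() == 1
        assert surface.rho[25, 0] == pytest.approx(1.0)  # 1.0 falls in bin [1.0, 1.04)

    def test_columns_sum_to_one_where_nonempty(self):
        rng = np.random.default_rng(1)
        alpha = rng.uniform(0, 2, (500, 5))
        alpha[:, 2] = np.nan  # one empty scale
        surface = density_surface(fake_landscape(alpha, np.full((500, 5), 80.0)))
        sums = surface.rho.sum(axis=0)
        np.testing.assert_allclose(sums[[0, 1, 3, 4]], 1.0, atol=1e-9)
        assert sums[2] == 0.0

    def test_out_of_range_alpha_excluded_not_clipped(self):
        alpha = np.array([[0.5], [2.5], [-0.5]])
        surface = density_surface(fake_landscape(alpha, np.full((3, 1), 80.0)))
        assert surface.rho[:, 0].sum() == pytest.approx(1.0)
        assert surface.rho[12, 0] == pytest.approx(1.0)  # only 0.5 survives

    def test_uniform_sample_yields_uniform_density(self):
        rng = np.random.default_rng(2)
        n = 100_000
        alpha = rng.uniform(0.0, 2.0, (n, 1))
        surface = density_surface(fake_landscape(alpha, np.full((n, 1), 80.0)))
        counts = surface.rho[:, 0] * n
        assert sps.chisquare(counts).pvalue > 0.01


class TestGroupSurface:
    def _subject(self, value, rows=None):
        landscape = fake_landscape(np.full((4, 2), value), np.full((4, 2), 80.0))
        return hr_surface(landscape)

    def test_subjects_weighted_equally(self):
        a = hr_surface(fake_landscape(np.full((100, 2), 0.8), np.full((100, 2), 80.0)))
        b = hr_surface(fake_landscape(np.full((3, 2), 1.2), np.full((3, 2), 80.0)))
        combined = group_surface([a, b])
        cell = combined.alpha_mean[50, 0]  # 80 bpm -> bin 50
        assert cell == pytest.approx(1.0)  # not dragged by a's 100 windows

    def test_single_subject_identity(self):
        a = self._subject(0.9)
        out = group_surface([a])
        np.testing.assert_array_equal(
            np.isnan(out.alpha_mean), np.isnan(a.alpha_mean)
        )
        defined = ~np.isnan(a.alpha_mean)
        np.testing.assert_allclose(out.alpha_mean[defined], a.alpha_mean[defined])

    def test_empty_bins_do_not_drag_the_mean(self):
        a = hr_surface(fake_landscape([[1.0]], [[80.0]]))
        b = hr_surface(fake_landscape([[1.4]], [[80.0]]))
        c = hr_surface(fake_landscape([[0.2]], [[120.0]]))  # different bin
        out = group_surface([a, b, c])
        assert out.alpha_mean[50, 0] == pytest.approx(1.2)
        assert out.counts[50, 0] == 2
        assert out.alpha_mean[90, 0] == pytest.approx(0.2)

    def test_permutation_invariance(self):
        subjects = [self._subject(v) for v in (0.7, 1.0, 1.3)]
        fwd = group_surface(subjects)
        rev = group_surface(subjects[::-1])
        np.testing.assert_array_equal(fwd.alpha_mean, rev.alpha_mean)

    def test_binning_mismatch_rejected(self):
        a = self._subject(1.0)
        other = hr_surface(
            fake_landscape(np.ones((4, 3)), np.full((4, 3), 80.0))
        )
        with pytest.raises(ValueError, match="mismatch"):
            group_surface([a, other])


class TestSubgroups:
    def _manifest(self):
        return CohortManifest(
            entries=[
                ManifestEntry("a", "c1", Group.CHF, nyha="II"),
                ManifestEntry("b", "c2", Group.CHF, nyha="IV"),
                ManifestEntry("c", "c3", Group.CHF),
                ManifestEntry("d", "a1", Group.AF, sr_fraction=0.95),
                ManifestEntry("e", "a2", Group.AF, sr_fraction=0.4),
                ManifestEntry("f", "a3", Group.AF, sr_fraction=0.005),
                ManifestEntry("g", "h1", Group.HEALTHY),
            ]
        )

    def test_chf_split_by_nyha(self):
        split = split_subgroups(self._manifest())
        assert [e.subject_id for e in split["chf_mild"]] == ["c1"]
        assert [e.subject_id for e in split["chf_severe"]] == ["c2"]
        assert [e.subject_id for e in split["chf_unknown"]] == ["c3"]

    def test_af_split_by_sr_fraction(self):
        split = split_subgroups(self._manifest())
        assert [e.subject_id for e in split["af_sr_gt80"]] == ["a1"]
        assert [e.subject_id for e in split["af_sr_1_80"]] == ["a2"]
        assert [e.subject_id for e in split["af_sr_lt1"]] == ["a3"]
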