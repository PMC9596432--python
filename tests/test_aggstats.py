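"""Autocorrelation statistic, offset-exponential fit, particle clustering."""

import numpy as np
import pytest

from piliagg import dynamics as dyn
from piliagg.aggstats import (
    UndefinedNormalizationError,
    aggregate_size,
    autocorrelation,
    cluster_cells,
    fit_correlation,
)
from piliagg.imaging import BinaryImage
from piliagg.synthetic import FixtureSpec, make_correlated_binary, make_exponential_profile


def brute_force_radial_autocorrelation(phi: np.ndarray, periodic: bool):
    """O(N^4) pair-counting oracle: all ordered pixel pairs, radially binned."""
    ny, nx = phi.shape
    num: dict[int, float] = {}
    cnt: dict[int, float] = {}
    for y1 in range(ny):
        for x1 in range(nx):
            for y2 in range(ny):
                for x2 in range(nx):
                    dy, dx = y2 - y1, x2 - x1
                    if periodic:
                        dy = (dy + ny // 2) % ny - ny // 2
                        dx = (dx + nx // 2) % nx - nx // 2
                    b = int(round(np.hypot(dy, dx)))
                    num[b] = num.get(b, 0.0) + phi[y1, x1] * phi[y2, x2]
                    cnt[b] = cnt.get(b, 0.0) + 1.0
    bins = sorted(num)
    C = np.array([num[b] / cnt[b] for b in bins]) / phi.mean()
    return np.array(bins, float), C, np.array([cnt[b] for b in bins])


class TestAutocorrelation:
    def test_all_ones_image_is_perfectly_correlated(self):
        img = BinaryImage(np.ones((32, 32), bool), periodic=True)
        prof = autocorrelation(img)
        assert np.allclose(prof.C, 1.0, atol=1e-12)

    def test_zero_lag_is_exactly_one(self):
        img, _ = make_correlated_binary(FixtureSpec("smoothed_noise", size=128, seed=2))
        prof = autocorrelation(img)
        assert prof.r[0] == 0.0
        assert prof.C[0] == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_image_rejected(self):
        with pytest.raises(UndefinedNormalizationError):
            autocorrelation(BinaryImage(np.zeros((16, 16), bool), periodic=True))

    def test_iid_noise_decorrelates_to_area_fraction(self):
        # for Bernoulli(p): C(0) = 1 and C(r>0) -> p
        img, meta = make_correlated_binary(FixtureSpec("bernoulli", size=512,
                                                       seed=4, area_fraction=0.3))
        prof = autocorrelation(img, max_r=50)
        assert np.abs(prof.C[1:] - img.area_fraction).max() < 0.01

    @pytest.mark.parametrize("periodic", [True, False])
    def test_fft_matches_pair_counting_oracle(self, periodic):
        rng = np.random.default_rng(7 if periodic else 8)
        phi = rng.random((16, 16)) < 0.4
        img = BinaryImage(phi, periodic=periodic)
        prof = autocorrelation(img)
        r_o, C_o, cnt_o = brute_force_radial_autocorrelation(phi.astype(float), periodic)
        assert np.allclose(prof.r, r_o)
        assert np.abs(prof.C - C_o).max() < 1e-10
        assert np.allclose(prof.pair_count, cnt_o)


class TestFit:
    def test_exact_profile_recovered_to_machine_precision(self):
        prof = make_exponential_profile(0.2, 7.0, 100)
        fit = fit_correlation(prof, min_pairs=1)
        assert fit.converged
        assert fit.C_inf == pytest.approx(0.2, abs=1e-6)
        assert fit.a == pytest.approx(7.0, abs=1e-6)

    def test_flat_profile_flagged_as_degenerate(self):
        prof = make_exponential_profile(0.0, 5.0, 60)
        prof.C[:] = 1.0
        fit = fit_correlation(prof, min_pairs=1)
        assert not fit.converged

    def test_too_few_points_rejected(self):
        prof = make_exponential_profile(0.1, 3.0, 2)
        with pytest.raises(ValueError):
            fit_correlation(prof, min_pairs=1)

    def test_noisy_profiles_recover_length_within_five_percent(self):
        hits = 0
        for seed in range(100):
            prof = make_exponential_profile(0.2, 7.0, 100, noise_sd=0.01, seed=seed)
            fit = fit_correlation(prof, min_pairs=1)
            if fit.converged and abs(fit.a - 7.0) / 7.0 < 0.05:
                hits += 1
        assert hits >= 95


class TestAggregateSize:
    @staticmethod
    def _disk_image(R, n=256):
        y, x = np.mgrid[:n, :n]
        return BinaryImage((y - n / 2) ** 2 + (x - n / 2) ** 2 <= R * R, periodic=False)

    def test_size_grows_with_disk_radius(self):
        sizes = [aggregate_size(self._disk_image(R)).size for R in (5, 10, 20, 40)]
        assert all(b > a for a, b in zip(sizes, sizes[1:]))

    def test_size_is_twice_correlation_length(self):
        res = aggregate_size(self._disk_image(12))
        assert res.size == 2.0 * res.fit.a

    def test_translation_invariance_on_torus(self):
        img, _ = make_correlated_binary(FixtureSpec("smoothed_noise", size=128, seed=9))
        rolled = BinaryImage(np.roll(img.pixels, (37, -12), axis=(0, 1)), periodic=True)
        s1 = aggregate_size(img)
        s2 = aggregate_size(rolled)
        assert s1.size == pytest.approx(s2.size, rel=1e-9)

    def test_unstructured_noise_has_pixel_scale_size(self):
        img, _ = make_correlated_binary(FixtureSpec("bernoulli", size=512, seed=12))
        res = aggregate_size(img)
        assert res.size < 2.5  # no structure beyond the pixel scale


class TestClusterCells:
    @staticmethod
    def _state_with_positions(positions, box=200.0):
        n = len(positions)
        quat = np.zeros((n, 4))
        quat[:, 0] = 1.0
        return dyn.SystemState(
            np.asarray(positions, float), quat, np.zeros((n, 3)), np.zeros((n, 3)),
            np.array([box] * 3),
        )

    def test_touching_pair_forms_one_cluster(self, dispersed_template, params):
        # place cell 2 so its adhesin 1 lands half a cutoff from cell 1's
        # adhesin 0 (both identity-oriented): exactly one binding contact
        L = dispersed_template.local_coords
        c1 = np.array([50.0, 50.0, 50.0])
        c2 = c1 + L[0] - L[1] + np.array([0.5 * params.r_c, 0.0, 0.0])
        state = self._state_with_positions([c1, c2])
        labels, sizes = cluster_cells(state, dispersed_template, params.r_c)
        assert len(sizes) == 1 and sizes[0] == 2

    def test_isolated_cells_stay_singletons(self, dispersed_template, params):
        state = self._state_with_positions([[20, 20, 20], [80, 80, 80], [150, 150, 150]])
        labels, sizes = cluster_cells(state, dispersed_template, params.r_c)
        assert len(sizes) == 3 and np.all(sizes == 1)

    def test_labels_match_brute_force_transitive_closure(self, dispersed_template, params):
        cfg = dyn.desk_config(n_cells=24, box_lengths=(55.0, 55.0, 55.0), seed=13)
        state = dyn.initialize_system(cfg, dispersed_template, params, seed=13)
        labels, _ = cluster_cells(state, dispersed_template, params.r_c)
        # oracle: direct O(N^2 na^2) adjacency + transitive closure
        coords = state.adhesin_world_coords(dispersed_template)
        n = state.n_cells
        adj = np.eye(n, dtype=bool)
        for i in range(n):
            for j in range(i + 1, n):
                d = coords[j][None, :, :] - coords[i][:, None, :]
                d = dyn.minimum_image(d.reshape(-1, 3), state.box)
                if (np.linalg.norm(d, axis=1) < params.r_c).any():
                    adj[i, j] = adj[j, i] = True
        closure = adj.copy()
        for _ in range(n):
            closure = closure | ((closure.astype(np.uint8) @ closure.astype(np.uint8)) > 0)
        for i in range(n):
            for j in range(n):
                assert (labels[i] == labels[j]) == closure[i, j]
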