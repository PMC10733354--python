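import numpy as np
import pytest

from btseg import metrics, nlfcm
from btseg.nlfcm import FCMConfig


def brute_force_nonlocal_mean(img, patch_radius, search_radius, h_nl):
    """Independent double-loop nonlocal mean with periodic boundaries."""
    H, W = img.shape
    out = np.zeros((H, W))
    size = 2 * patch_radius + 1
    for r in range(H):
        for c in range(W):
            ws, vals = [], []
            for dr in range(-search_radius, search_radius + 1):
                for dc in range(-search_radius, search_radius + 1):
                    if (dr, dc) == (0, 0):
                        continue
                    d2 = 0.0
                    for pr in range(-patch_radius, patch_radius + 1):
                        for pc in range(-patch_radius, patch_radius + 1):
                            a = img[(r + pr) % H, (c + pc) % W]
                            b = img[(r + dr + pr) % H, (c + dc + pc) % W]
                            d2 += (a - b) ** 2
                    d2 /= size**2
                    ws.append(np.exp(-d2 / h_nl**2))
                    vals.append(img[(r + dr) % H, (c + dc) % W])
            ws = np.array(ws) / np.sum(ws)
            out[r, c] = float(ws @ np.array(vals))
    return out


def classical_fcm_memberships(x, v, m):
    """Hand formula: u_ik = d_ik^(-2/(m-1)) / sum_l d_lk^(-2/(m-1))."""
    d2 = (x[None, :] - v[:, None]) ** 2
    if (d2 == 0).any():
        u = np.zeros_like(d2)
        hits = d2 == 0
        u[:, hits.any(0)] = hits[:, hits.any(0)] / hits[:, hits.any(0)].sum(0)
        free = ~hits.any(0)
        p = d2[:, free] ** (-1.0 / (m - 1))
        u[:, free] = p / p.sum(0)
        return u
    p = d2 ** (-1.0 / (m - 1))
    return p / p.sum(axis=0)


def two_region_image(rng, lo=50, hi=200, sigma=5.0, size=24):
    img = np.full((size, size), float(lo))
    img[:, size // 2:] = hi
    img += rng.normal(0, sigma, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(int)


class TestNonlocalMean:
    def test_constant_image_unchanged(self):
        x = np.full((8, 8), 7.0)
        assert np.allclose(nlfcm.nonlocal_mean(x), 7.0)

    def test_piecewise_constant_interior(self):
        x = np.full((12, 12), 50.0)
        x[:, 6:] = 200.0
        xbar = nlfcm.nonlocal_mean(x, patch_radius=1, search_radius=1, h_nl=10.0)
        assert xbar[6, 2] == pytest.approx(50.0)
        assert xbar[6, 9] == pytest.approx(200.0)

    def test_matches_brute_force_oracle(self, rng):
        x = rng.normal(100, 20, size=(5, 5))
        mine = nlfcm.nonlocal_mean(x, patch_radius=1, search_radius=2, h_nl=15.0)
        ref = brute_force_nonlocal_mean(x, 1, 2, 15.0)
        assert np.abs(mine - ref).max() < 1e-10

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError):
            nlfcm.nonlocal_mean(np.ones((4, 4)), search_radius=3)


class TestWeights:
    def test_constant_image_beta_zero(self):
        a, beta, xbar = nlfcm.compute_weights(np.full((8, 8), 50.0), FCMConfig())
        assert np.allclose(beta, 0.0, atol=1e-12)
        assert np.allclose(a, 0.0)

    def test_dispersion_formula_hand_value(self):
        """One dominant weight 0.9 among 5: beta = (0.9 - 0.2) / 0.2 = 3.5."""
        w = np.array([0.9, 0.025, 0.025, 0.025, 0.025])
        beta = (w.max() - w.mean()) / w.mean()
        assert beta == pytest.approx(3.5)
        # the same statistic as computed from a weight stack
        stack = w[:, None, None] * np.ones((5, 1, 1))
        assert ((stack.max(0) - stack.mean(0)) / stack.mean(0))[0, 0] == pytest.approx(3.5)

    def test_constant_a_mode(self):
        cfg = FCMConfig(a_mode="constant", a_const=0.5)
        a, _, _ = nlfcm.compute_weights(np.full((8, 8), 50.0), cfg)
        assert np.allclose(a, 0.5)


class TestMembershipUpdate:
    def test_rows_sum_to_one(self, rng):
        x = rng.uniform(0, 255, 50)
        cfg = FCMConfig(c=3)
        u = nlfcm.update_memberships(x, x.copy(), np.array([10.0, 100.0, 200.0]),
                                     np.ones(50), np.zeros(50),
                                     rng.uniform(0, 2, 50), cfg)
        assert np.allclose(u.sum(axis=0), 1.0, atol=1e-9)
        assert (u >= 0).all() and (u <= 1).all()

    def test_reduces_to_classical_fcm_hand_values(self):
        """4-pixel instance, c=2, m=2, centers (1, 5): memberships equal the
        classical closed form, e.g. u for pixel 0 is 25/26 vs 1/26."""
        x = np.array([0.0, 1.0, 5.0, 6.0])
        v = np.array([1.0, 5.0])
        cfg = FCMConfig(c=2, m=2.0, window_radius=0)
        u = nlfcm.update_memberships(x, x.copy(), v, np.ones(4), np.zeros(4),
                                     np.zeros(4), cfg)
        expected = classical_fcm_memberships(x, v, 2.0)
        assert np.abs(u - expected).max() < 1e-10
        assert u[0, 0] == pytest.approx(25 / 26, abs=1e-10)
        assert u[0, 3] == pytest.approx(1 / 26, abs=1e-10)

    def test_exact_hit_is_crisp(self):
        x = np.array([5.0, 2.0])
        v = np.array([5.0, 0.0])
        cfg = FCMConfig(c=2)
        u = nlfcm.update_memberships(x, x.copy(), v, np.ones(2), np.zeros(2),
                                     np.zeros(2), cfg)
        assert u[0, 0] == 1.0 and u[1, 0] == 0.0


class TestCenterUpdate:
    def test_classical_fcm_center_formula(self, rng):
        x = rng.uniform(0, 255, 30)
        u = rng.dirichlet(np.ones(2), 30).T
        cfg = FCMConfig(c=2, m=2.0)
        v = nlfcm.update_centers(x, x.copy(), u, np.ones(30), np.zeros(30), cfg)
        expected = (u**2 @ x) / (u**2).sum(axis=1)
        assert np.allclose(v, expected, atol=1e-10)

    def test_crisp_memberships_on_two_values(self):
        x = np.array([10.0, 10.0, 200.0, 200.0])
        u = np.array([[1.0, 1.0, 0.0, 0.0], [0.0, 0.0, 1.0, 1.0]])
        cfg = FCMConfig(c=2)
        v = nlfcm.update_centers(x, x.copy(), u, np.ones(4), np.zeros(4), cfg)
        assert np.allclose(v, [10.0, 200.0])

    def test_matches_direct_sum_oracle(self, rng):
        """Independent elementwise evaluation of the center update sums."""
        n = 20
        x = rng.uniform(0, 255, n)
        xbar = rng.uniform(0, 255, n)
        u = rng.dirichlet(np.ones(3), n).T
        b = rng.uniform(0.8, 1.2, n)
        beta = rng.uniform(0, 2, n)
        cfg = FCMConfig(c=3, m=1.8)
        v = nlfcm.update_centers(x, xbar, u, b, beta, cfg)
        for i in range(3):
            num = sum(b[k] * (x[k] + beta[k] * xbar[k]) * u[i, k] ** 1.8
                      for k in range(n))
            den = sum(b[k] ** 2 * (1 + beta[k]) * u[i, k] ** 1.8 for k in range(n))
            assert v[i] == pytest.approx(num / den, abs=1e-10)


class TestObjective:
    def test_zero_at_perfect_crisp_fit(self):
        x = np.array([10.0, 10.0, 200.0])
        u = np.array([[1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        v = np.array([10.0, 200.0])
        cfg = FCMConfig(c=2)
        j = nlfcm.objective(x, x.copy(), u, v, np.ones(3), np.zeros(3),
                            np.zeros(3), cfg, (1, 3))
        assert j == pytest.approx(0.0, abs=1e-12)

    def test_quadratic_scaling_of_data_term(self, rng):
        x = rng.uniform(0, 10, 9)
        u = rng.dirichlet(np.ones(2), 9).T
        v = np.array([0.0, 0.0])
        cfg = FCMConfig(c=2)
        args = (np.ones(9), np.zeros(9), np.zeros(9), cfg, (3, 3))
        j1 = nlfcm.objective(x, np.zeros(9), u, v, *args)
        j2 = nlfcm.objective(2 * x, np.zeros(9), u, v, *args)
        assert j2 == pytest.approx(4 * j1, rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_nonincreasing_under_alternating_updates(self, seed):
        rng = np.random.default_rng(seed)
        img = two_region_image(rng)
        cfg = FCMConfig(c=2, seed=seed, max_iter=40)
        state, _ = nlfcm.segment(img, cfg)
        trace = np.array(state.objective_trace)
        assert (np.diff(trace) <= 1e-7 * np.maximum(1.0, trace[:-1])).all()


class TestSegment:
    def test_two_region_center_recovery(self):
        rng = np.random.default_rng(7)
        img = two_region_image(rng, 50, 200, sigma=5.0)
        state, _ = nlfcm.segment(img, FCMConfig(c=2, seed=7))
        v = np.sort(state.v)
        assert abs(v[0] - 50) <= 2.0 and abs(v[1] - 200) <= 2.0

    def test_same_seed_identical_labels(self):
        rng = np.random.default_rng(3)
        img = two_region_image(rng)
        _, l1 = nlfcm.segment(img, FCMConfig(seed=5))
        _, l2 = nlfcm.segment(img, FCMConfig(seed=5))
        assert np.array_equal(l1, l2)

    def test_noiseless_two_value_image_dice_one(self):
        img = np.full((16, 16), 50)
        gt = np.zeros((16, 16), dtype=bool)
        gt[4:12, 4:12] = True
        img[gt] = 200
        state, labels = nlfcm.segment(img, FCMConfig(c=2, seed=0))
        bright = int(np.argmax(state.v))
        assert metrics.dice(labels == bright, gt) == 1.0

    def test_membership_constraints_after_convergence(self):
        rng = np.random.default_rng(11)
        img = two_region_image(rng)
        state, _ = nlfcm.segment(img, FCMConfig(seed=11))
        assert np.allclose(state.u.sum(axis=0), 1.0, atol=1e-9)
        assert state.converged

    def test_reduction_to_classical_fcm_fixed_point(self):
        """With beta=0, a=0, r=0, b=1 the fixed point matches an independent
        classical FCM run from the same initialization."""
        rng = np.random.default_rng(13)
        img = two_region_image(rng)
        cfg = FCMConfig(c=2, m=2.0, window_radius=0, beta_mode="constant",
                        beta_const=0.0, seed=13, tol=1e-10, max_iter=300)
        state, _ = nlfcm.segment(img, cfg)
        x = img.ravel().astype(float)
        v = nlfcm._init_centers(x, cfg)
        for _ in range(300):
            u = classical_fcm_memberships(x, v, 2.0)
            v_new = (u**2 @ x) / (u**2).sum(axis=1)
            if np.abs(v_new - v).max() < 1e-12:
                v = v_new
                break
            v = v_new
        assert np.abs(np.sort(state.v) - np.sort(v)).max() < 1e-6
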