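import datetime as dt
import math

import numpy as np
import pytest

from ctdemog import secr_density as sd
from ctdemog.synthetic_data import (
    SimConfig,
    detector_grid,
    simulate_detections,
    simulate_secr_survey,
)

from conftest import ann, single_event


# ---------------------------------------------------------------------------
# independent brute-force likelihood (plain loops, no shared code paths)


def g_scalar(d, params):
    if params.kind == "HN":
        return params.g0 * math.exp(-d * d / (2 * params.sigma**2))
    if params.kind == "EX":
        return params.g0 * math.exp(-d / params.sigma)
    r = (d / params.sigma) ** (-params.z) if d > 0 else float("inf")
    return params.g0 * (1.0 - math.exp(-r)) if math.isfinite(r) else params.g0


def nll_brute_force(ch, mask, params):
    w = mask.cell_area
    n, S, K = ch.detections.shape
    pdot = []
    for X in mask.points:
        miss = 1.0
        for s in range(S):
            for k in range(K):
                d = math.dist(X, ch.detector_xy[k])
                miss *= 1.0 - ch.usage[k, s] * g_scalar(d, params)
        pdot.append(1.0 - miss)
    a = sum(pdot) * w
    total = 0.0
    for i in range(n):
        acc = 0.0
        for X in mask.points:
            pr = 1.0
            for s in range(S):
                for k in range(K):
                    d = math.dist(X, ch.detector_xy[k])
                    p = ch.usage[k, s] * g_scalar(d, params)
                    pr *= p if ch.detections[i, s, k] else (1.0 - p)
            acc += pr * w
        total -= math.log(acc)
    return total + n * math.log(a)


def random_instance(rng):
    K = int(rng.integers(1, 4))
    S = int(rng.integers(1, 4))
    M = int(rng.integers(1, 10))
    n = int(rng.integers(1, 5))
    det_xy = rng.uniform(0, 3000, size=(K, 2))
    mask = sd.HabitatMask(points=rng.uniform(-500, 3500, size=(M, 2)), spacing=400.0)
    usage = (rng.random((K, S)) < 0.8).astype(np.int8)
    if usage.sum() == 0:
        usage[0, 0] = 1
    detections = np.zeros((n, S, K), dtype=np.int8)
    for i in range(n):
        while detections[i].sum() == 0:
            detections[i] = ((rng.random((S, K)) < 0.35) & (usage.T > 0))
    ch = sd.CaptureHistory(
        individuals=[f"i{j}" for j in range(n)],
        occasions=list(range(S)),
        detector_ids=[f"d{k}" for k in range(K)],
        detector_xy=det_xy,
        detections=detections,
        usage=usage,
    )
    kind = ["HN", "EX", "HR"][int(rng.integers(3))]
    params = sd.DetFnParams(
        kind=kind,
        g0=float(rng.uniform(0.05, 0.9)),
        sigma=float(rng.uniform(300, 2500)),
        z=float(rng.uniform(1.5, 5.0)) if kind == "HR" else None,
    )
    return ch, mask, params


class TestDetectionFunctions:
    @pytest.mark.parametrize("kind", sd.DETFN_KINDS)
    def test_value_at_zero_is_g0(self, kind):
        p = sd.DetFnParams(kind, g0=0.4, sigma=1000.0,
                           z=2.5 if kind == "HR" else None)
        assert sd.detection_probability(0.0, p) == pytest.approx(0.4)

    def test_halfnormal_at_sigma(self):
        p = sd.DetFnParams("HN", 0.4, 1000.0)
        assert sd.detection_probability(1000.0, p) == \
            pytest.approx(0.4 * math.exp(-0.5))

    def test_hazard_rate_at_sigma(self):
        p = sd.DetFnParams("HR", 0.4, 1000.0, z=3.0)
        assert sd.detection_probability(1000.0, p) == \
            pytest.approx(0.4 * (1 - math.exp(-1)))

    @pytest.mark.parametrize("kind", sd.DETFN_KINDS)
    def test_non_increasing_in_distance(self, kind):
        p = sd.DetFnParams(kind, 0.6, 800.0, z=2.0 if kind == "HR" else None)
        d = np.linspace(0, 6000, 200)
        g = sd.detection_probability(d, p)
        assert np.all(np.diff(g) <= 1e-12)
        assert np.all(g <= 0.6 + 1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            sd.DetFnParams("HN", g0=1.5, sigma=100.0)
        with pytest.raises(ValueError):
            sd.DetFnParams("HR", g0=0.5, sigma=100.0, z=0.9)


class TestMask:
    def test_single_detector_disc(self):
        grid = detector_grid(SimConfig(n_detectors_side=1))
        mask = sd.make_mask(grid, buffer=100.0, spacing=100.0)
        # 3x3 candidate grid; the four corners at sqrt(2)*100 fall outside
        assert mask.n_points == 5
        assert mask.area == pytest.approx(0.05)

    def test_doubling_spacing_quarters_points(self):
        grid = detector_grid(SimConfig(n_detectors_side=3))
        fine = sd.make_mask(grid, buffer=4000.0, spacing=250.0)
        coarse = sd.make_mask(grid, buffer=4000.0, spacing=500.0)
        assert fine.n_points == pytest.approx(4 * coarse.n_points, rel=0.05)

    def test_area_matches_monte_carlo_union(self, rng):
        # 71-detector layout: mask area vs hit-or-miss area of the union
        # of discs, the independent geometric oracle
        grid = detector_grid(SimConfig(n_detectors_side=9,
                                       detector_spacing=2315.0))[:71]
        buffer = 8000.0
        mask = sd.make_mask(grid, buffer=buffer, spacing=buffer / 32)
        xy = np.array([[d.x, d.y] for d in grid])
        lo = xy.min(axis=0) - buffer
        hi = xy.max(axis=0) + buffer
        pts = rng.uniform(lo, hi, size=(400_000, 2))
        d2 = np.min(((pts[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2), axis=1)
        frac = (d2 <= buffer**2).mean()
        box_km2 = (hi - lo).prod() / 1e6
        assert mask.area == pytest.approx(frac * box_km2, rel=0.02)

    def test_bad_geometry_rejected(self):
        grid = detector_grid(SimConfig(n_detectors_side=1))
        with pytest.raises(ValueError):
            sd.make_mask(grid, buffer=-5.0, spacing=10.0)


class TestCaptureHistories:
    def test_single_detection(self):
        grid = detector_grid(SimConfig(n_detectors_side=2))
        ev = single_event([[ann("ADM", "m1")]], camera=grid[0].camera_id)
        ch = sd.build_capture_histories([ev], grid)
        assert ch.n == 1 and ch.n_detections == 1

    def test_same_day_repeats_collapse(self):
        grid = detector_grid(SimConfig(n_detectors_side=2))
        cam = grid[0].camera_id
        ev1 = single_event([[ann("ADM", "m1")]], camera=cam, start_minutes=100)
        ev2 = single_event([[ann("ADM", "m1")]], camera=cam, start_minutes=300)
        ch = sd.build_capture_histories([ev1, ev2], grid)
        assert ch.n_detections == 1               # same day, same detector

    def test_planted_detections_match_tabulation(self, rng):
        grid = detector_grid(SimConfig(n_detectors_side=3))
        cams = [d.camera_id for d in grid]
        planted = set()
        events = []
        for j in range(40):
            ident = f"m{rng.integers(6)}"
            cam = cams[rng.integers(len(cams))]
            day = int(rng.integers(5))
            planted.add((ident, day, cam))
            events.append(single_event([[ann("ADM", ident)]], camera=cam,
                                       start_minutes=100 + j, day=day))
        ch = sd.build_capture_histories([e for e in events], grid)
        assert ch.n_detections == len(planted)
        for (ident, day, cam) in planted:
            i = ch.individuals.index(ident)
            s = ch.occasions.index(dt.date(2018, 2, 1) + dt.timedelta(days=day))
            k = ch.detector_ids.index(cam)
            assert ch.detections[i, s, k] == 1

    def test_detection_on_unused_occasion_rejected(self):
        with pytest.raises(ValueError, match="not used"):
            sd.CaptureHistory(
                individuals=["a"], occasions=[0], detector_ids=["d"],
                detector_xy=np.zeros((1, 2)),
                detections=np.ones((1, 1, 1)),
                usage=np.zeros((1, 1)))


class TestLikelihood:
    def test_hand_computed_two_occasions(self):
        # one detector, one mask point on top of it, p = 0.5, history (1, 0)
        ch = sd.CaptureHistory(
            individuals=["a"], occasions=[0, 1], detector_ids=["d"],
            detector_xy=np.zeros((1, 2)),
            detections=np.array([[[1], [0]]]),
            usage=np.ones((1, 2)))
        mask = sd.HabitatMask(points=np.zeros((1, 2)), spacing=100.0)
        params = sd.DetFnParams("HN", g0=0.5, sigma=1000.0)
        assert sd.neg_log_likelihood(ch, mask, params) == \
            pytest.approx(math.log(3.0), abs=1e-10)

    def test_single_occasion_single_point_conditioning_cancels(self):
        ch = sd.CaptureHistory(
            individuals=["a"], occasions=[0], detector_ids=["d"],
            detector_xy=np.zeros((1, 2)),
            detections=np.ones((1, 1, 1)),
            usage=np.ones((1, 1)))
        mask = sd.HabitatMask(points=np.zeros((1, 2)), spacing=100.0)
        params = sd.DetFnParams("EX", g0=0.37, sigma=700.0)
        assert sd.neg_log_likelihood(ch, mask, params) == \
            pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(40):
            ch, mask, params = random_instance(rng)
            fast = sd.neg_log_likelihood(ch, mask, params)
            slow = nll_brute_force(ch, mask, params)
            assert fast == pytest.approx(slow, abs=1e-10, rel=1e-10)

    def test_esa_monotone_in_g0_and_occasions(self):
        grid = detector_grid(SimConfig(n_detectors_side=3))
        mask = sd.make_mask(grid, buffer=6000.0, spacing=1000.0)
        det_xy = np.array([[d.x, d.y] for d in grid])

        def esa(g0, S):
            ch = sd.CaptureHistory(
                individuals=["a"], occasions=list(range(S)),
                detector_ids=[d.camera_id for d in grid],
                detector_xy=det_xy,
                detections=np.concatenate(
                    [np.ones((1, 1, len(grid))), np.zeros((1, S - 1, len(grid)))],
                    axis=1) if S > 1 else np.ones((1, 1, len(grid))),
                usage=np.ones((len(grid), S)))
            return sd.effective_sampling_area(
                ch, mask, sd.DetFnParams("HN", g0, 1500.0))

        esas_g = [esa(g, 5) for g in (0.05, 0.1, 0.2, 0.4)]
        assert all(a < b for a, b in zip(esas_g, esas_g[1:]))
        esas_s = [esa(0.1, S) for S in (1, 3, 10, 30)]
        assert all(a < b for a, b in zip(esas_s, esas_s[1:]))


@pytest.fixture(scope="module")
def hn_fit():
    cfg = SimConfig(seed=11, detfn=sd.DetFnParams("HN", g0=0.05, sigma=2000.0),
                    n_detectors_side=7, n_occasions=50)
    rng = np.random.default_rng(cfg.seed)
    dets = detector_grid(cfg)
    from ctdemog.synthetic_data import simulate_centres

    centres = simulate_centres(cfg, rng)
    ch, _ = simulate_detections(centres, dets, cfg.detfn, cfg.n_occasions,
                                rng, collapse=None)
    mask = sd.make_mask(dets, buffer=8000.0, spacing=1000.0)
    return cfg, ch, mask, sd.fit_secr(ch, mask, "HN")


class TestFit:
    def test_recovers_true_parameters_within_two_se(self, hn_fit):
        cfg, ch, mask, res = hn_fit
        table = res.param_table().set_index("parameter")
        for name, truth in (("g0", cfg.detfn.g0), ("sigma", cfg.detfn.sigma)):
            est, se = table.loc[name, "estimate"], table.loc[name, "se"]
            assert abs(est - truth) < 2 * se

    def test_refit_from_mle_is_stationary(self, hn_fit):
        _, ch, mask, res = hn_fit
        again = sd.fit_secr(ch, mask, "HN", start=res.params)
        assert again.params.g0 == pytest.approx(res.params.g0, rel=1e-3)
        assert again.params.sigma == pytest.approx(res.params.sigma, rel=1e-3)

    def test_density_invariant_to_translation_and_rotation(self, hn_fit):
        _, ch, mask, res = hn_fit
        d0 = res.derive_density().D
        theta = 0.7
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        shift = np.array([1e5, -3e4])
        ch2 = sd.CaptureHistory(
            individuals=ch.individuals, occasions=ch.occasions,
            detector_ids=ch.detector_ids,
            detector_xy=ch.detector_xy @ rot.T + shift,
            detections=ch.detections, usage=ch.usage)
        mask2 = sd.HabitatMask(points=mask.points @ rot.T + shift,
                               spacing=mask.spacing)
        res2 = sd.fit_secr(ch2, mask2, "HN", start=res.params)
        assert res2.derive_density().D == pytest.approx(d0, rel=1e-3)

    def test_density_stable_in_buffer(self, hn_fit):
        cfg, ch, mask, res = hn_fit
        dets = detector_grid(cfg)
        sigma_hat = res.params.sigma
        ds = []
        for mult in (4.0, 8.0):
            m = sd.make_mask(dets, buffer=mult * sigma_hat,
                             spacing=4.0 * sigma_hat / 16)
            ds.append(sd.fit_secr(ch, m, "HN", start=res.params)
                      .derive_density().D)
        assert abs(ds[1] - ds[0]) / ds[0] < 0.02

    def test_aicc_small_sample_penalty(self):
        # 30 individuals, 2 link parameters, logLik forced to 0:
        # AICc = 4 + 12/27
        grid = detector_grid(SimConfig(n_detectors_side=2))
        K = len(grid)
        detections = np.zeros((30, 1, K), dtype=np.int8)
        detections[:, 0, 0] = 1
        ch = sd.CaptureHistory(
            individuals=[f"i{j}" for j in range(30)], occasions=[0],
            detector_ids=[d.camera_id for d in grid],
            detector_xy=np.array([[d.x, d.y] for d in grid]),
            detections=detections, usage=np.ones((K, 1)))
        mask = sd.make_mask(grid, buffer=2000.0, spacing=1000.0)
        model = sd.SECRModel(ch, mask, "HN")
        res = sd.SECRResults(model, np.array([0.0, 7.0]), None,
                             llf=0.0, converged=True)
        assert res.aicc == pytest.approx(4 + 12 / 27)

    def test_saturated_detection_gives_n_over_area(self):
        # p.(X) ~ 1 everywhere: esa -> mask area and D -> n / A
        grid = detector_grid(SimConfig(n_detectors_side=3))
        mask = sd.make_mask(grid, buffer=2000.0, spacing=1000.0)
        n, S, K = 4, 60, len(grid)
        rng = np.random.default_rng(1)
        detections = (rng.random((n, S, K)) < 0.9).astype(np.int8)
        detections[:, 0, 0] = 1
        ch = sd.CaptureHistory(
            individuals=[f"i{j}" for j in range(n)],
            occasions=list(range(S)),
            detector_ids=[d.camera_id for d in grid],
            detector_xy=np.array([[d.x, d.y] for d in grid]),
            detections=detections, usage=np.ones((K, S)))
        params = sd.DetFnParams("HN", g0=0.9, sigma=5000.0)
        esa = sd.effective_sampling_area(ch, mask, params)
        assert esa == pytest.approx(mask.area, rel=1e-6)


class TestRanking:
    def _two_fits(self):
        ch, dets, _, _ = simulate_secr_survey(SimConfig(seed=5))
        mask = sd.make_mask(dets, buffer=8000.0, spacing=1000.0)
        return [sd.fit_secr(ch, mask, k) for k in ("HN", "EX")]

    def test_single_fit(self):
        fits = self._two_fits()[:1]
        df = sd.rank_models(fits)
        assert df.loc[0, "dAICc"] == 0.0 and df.loc[0, "weight"] == 1.0

    def test_equal_aicc_gives_equal_weights(self):
        fits = self._two_fits()
        df = sd.rank_models([fits[0], fits[0]])
        assert df["weight"].tolist() == pytest.approx([0.5, 0.5])

    def test_weights_sum_to_one_sorted(self):
        df = sd.rank_models(self._two_fits())
        assert df["weight"].sum() == pytest.approx(1.0)
        assert df["AICc"].is_monotonic_increasing

    def test_mixed_datasets_rejected(self):
        a = self._two_fits()[0]
        ch, dets, _, _ = simulate_secr_survey(SimConfig(seed=6))
        mask = sd.make_mask(dets, buffer=8000.0, spacing=1000.0)
        b = sd.fit_secr(ch, mask, "HN")
        with pytest.raises(ValueError, match="identical data"):
            sd.rank_models([a, b])


class TestDensityEstimate:
    def test_abundance_is_density_times_area(self):
        d = sd.DensityEstimate(D=0.138, se=0.01, ci_low=0.1, ci_high=0.19,
                               mask_area=1413.0, esa=300.0)
        assert d.n_hat == pytest.approx(0.138 * 1413.0)

    def test_zero_cv_collapses_interval(self):
        ch, dets, _, _ = simulate_secr_survey(SimConfig(seed=5))
        mask = sd.make_mask(dets, buffer=8000.0, spacing=1000.0)
        res = sd.fit_secr(ch, mask, "HN")
        dens = res.derive_density()
        assert dens.ci_low <= dens.D <= dens.ci_high
        assert dens.se > 0

    def test_summary_mentions_key_quantities(self):
        ch, dets, _, _ = simulate_secr_survey(SimConfig(seed=5))
        mask = sd.make_mask(dets, buffer=8000.0, spacing=1000.0)
        text = sd.fit_secr(ch, mask, "HN").summary()
        for token in ("density", "AICc", "g0", "sigma", "esa"):
            assert token in text
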