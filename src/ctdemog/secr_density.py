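"""Spatially explicit capture-recapture (SECR) for proximity detectors.

The model: animals hold fixed home-range centres X distributed as a 2-D
Poisson process; a camera ("proximity detector") at x_k detects an animal
on an occasion independently with probability g(||X - x_k||), where g is a
monotone detection function

* half-normal  (HN):  g(d) = g0 exp(-d^2 / (2 sigma^2))
* exponential  (EX):  g(d) = g0 exp(-d / sigma)
* hazard rate  (HR):  g(d) = g0 (1 - exp(-(d / sigma)^(-z))),  z > 1

Centres are integrated over a discrete *habitat mask*.  The likelihood is
*conditional* on the n observed individuals (Borchers-Efford style): with
detection history omega_i, per-occasion-and-detector Bernoulli cells and
p.(X) = 1 - prod(1 - p_sk(X)),

    -logL = - sum_i log[ sum_X Pr(omega_i | X) w ] + n log[ sum_X p.(X) w ]

with w the mask cell area.  Density is the derived Horvitz-Thompson-like
estimator D = n / a(theta), where the effective sampling area
a(theta) = sum_X p.(X) w; its variance combines Poisson variation in n
with parameter uncertainty through the delta method, and intervals are
lognormal.  Abundance over the mask is N = D x mask area.

Model classes follow the statsmodels convention: build a
:class:`SECRModel` from data, call :meth:`~SECRModel.fit`, inspect the
returned :class:`SECRResults` (estimates, SEs, AICc, ``summary()``).
Detection-function choice is ranked by AICc with the small-sample n equal
to the number of distinct individuals.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit
from scipy.special import logsumexp
from statsmodels.tools.numdiff import approx_fprime, approx_hess

logger = logging.getLogger(__name__)

DETFN_KINDS = ("HN", "EX", "HR")
_Z_DEFAULT = 2.5


# ---------------------------------------------------------------------------
# data containers


@dataclass
class CaptureHistory:
    """individual x occasion x detector binary detection array with usage.

    ``detections[i, s, k]`` is 1 iff individual ``i`` was detected at
    detector ``k`` on occasion ``s``; ``usage[k, s]`` is 1 iff the detector
    was operating that occasion.  Detections on unused cells are invalid;
    every individual must have at least one detection.
    """

    individuals: list[str]
    occasions: list
    detector_ids: list[str]
    detector_xy: np.ndarray          # (K, 2) metres
    detections: np.ndarray           # (n, S, K) 0/1
    usage: np.ndarray                # (K, S) 0/1

    def __post_init__(self) -> None:
        self.detections = np.asarray(self.detections, dtype=np.int8)
        self.usage = np.asarray(self.usage, dtype=np.int8)
        self.detector_xy = np.asarray(self.detector_xy, dtype=float)
        n, S, K = self.detections.shape
        if (len(self.individuals), len(self.occasions), len(self.detector_ids)) != (n, S, K):
            raise ValueError("capture history dimensions do not match labels")
        if self.usage.shape != (K, S):
            raise ValueError("usage must be detectors x occasions")
        if np.any(self.detections & (self.usage.T[None, :, :] == 0)):
            raise ValueError("detection recorded on an occasion the detector was not used")
        if n and np.any(self.detections.sum(axis=(1, 2)) == 0):
            raise ValueError("individual with no detections")
        multi = np.where(self.detections.sum(axis=2) > 1)
        if multi[0].size:
            logger.warning(
                "%d individual-occasions with detections at multiple detectors "
                "(allowed for proximity detectors)", multi[0].size,
            )

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def n_detections(self) -> int:
        return int(self.detections.sum())

    def to_frame(self) -> pd.DataFrame:
        """Long capthist-style table: session,individual,occasion,detector."""
        i, s, k = np.nonzero(self.detections)
        return pd.DataFrame(
            {
                "session": 1,
                "individual": [self.individuals[a] for a in i],
                "occasion": [self.occasions[a] for a in s],
                "detector": [self.detector_ids[a] for a in k],
            }
        )


@dataclass(frozen=True)
class HabitatMask:
    """Discretised region of potential home-range centres."""

    points: np.ndarray               # (M, 2) metres
    spacing: float                   # metres

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("mask points must be (M, 2)")
        if self.points.shape[0] == 0:
            raise ValueError("empty mask")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def cell_area(self) -> float:
        """km^2 per mask cell."""
        return self.spacing**2 / 1e6

    @property
    def area(self) -> float:
        """Total mask area, km^2."""
        return self.n_points * self.cell_area


@dataclass(frozen=True)
class DetFnParams:
    kind: str
    g0: float
    sigma: float
    z: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in DETFN_KINDS:
            raise ValueError(f"unknown detection function {self.kind!r}")
        if not 0.0 < self.g0 < 1.0:
            raise ValueError("g0 must be in (0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive (metres)")
        if self.kind == "HR":
            if self.z is None or self.z <= 1.0:
                raise ValueError("hazard-rate shape z must exceed 1")


@dataclass(frozen=True)
class DensityEstimate:
    """Derived density with lognormal interval and mask-scaled abundance."""

    D: float                         # animals / km^2
    se: float
    ci_low: float
    ci_high: float
    mask_area: float                 # km^2
    esa: float                       # km^2

    @property
    def n_hat(self) -> float:
        return self.D * self.mask_area

    @property
    def n_ci(self) -> tuple[float, float]:
        return self.ci_low * self.mask_area, self.ci_high * self.mask_area


# ---------------------------------------------------------------------------
# detection functions


def detection_probability(d, params: DetFnParams) -> np.ndarray:
    """g(d) for distances ``d`` (metres); scalar or array."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    s = params.sigma
    if params.kind == "HN":
        g = params.g0 * np.exp(-(d**2) / (2.0 * s * s))
    elif params.kind == "EX":
        g = params.g0 * np.exp(-d / s)
    else:  # HR
        with np.errstate(divide="ignore", over="ignore"):
            r = np.where(d > 0, (d / s) ** (-params.z), np.inf)
        g = params.g0 * (-np.expm1(-r))
    return g


def _to_link(params: DetFnParams) -> np.ndarray:
    theta = [logit(params.g0), math.log(params.sigma)]
    if params.kind == "HR":
        theta.append(math.log(params.z - 1.0))
    return np.array(theta)


def _from_link(theta: np.ndarray, kind: str) -> DetFnParams:
    g0 = float(expit(theta[0]))
    sigma = float(np.exp(theta[1]))
    z = float(1.0 + np.exp(theta[2])) if kind == "HR" else None
    return DetFnParams(kind=kind, g0=min(g0, 1 - 1e-12), sigma=sigma, z=z)


# ---------------------------------------------------------------------------
# capture histories and masks


def build_capture_histories(events, detectors, occasions=None) -> CaptureHistory:
    """Daily capture histories of identified individuals from events.

    One calendar day is one occasion.  Cell (i, s, k) is set iff individual
    i was identified in an event at detector k starting on day s; repeat
    detections of an individual at the same detector on the same day
    collapse to a single 1 (logged).  ``occasions`` defaults to the full
    day range spanned by the events; detector usage defaults to all-on over
    those days unless the deployments carry operational days.
    """
    det_ids = [d.camera_id for d in detectors]
    det_xy = np.array([[d.x, d.y] for d in detectors], dtype=float)
    det_index = {c: k for k, c in enumerate(det_ids)}
    triples = []
    for ev in events:
        if ev.camera_id not in det_index:
            raise ValueError(f"event at unknown detector {ev.camera_id!r}")
        for ind in ev.identified_ids:
            triples.append((ind, ev.start.date(), ev.camera_id))
    if not triples:
        raise ValueError("no identified individuals in events")
    if occasions is None:
        days = sorted({d for _, d, _ in triples})
        first, last = days[0], days[-1]
        occasions = [first + dt.timedelta(days=i) for i in range((last - first).days + 1)]
    occ_index = {d: s for s, d in enumerate(occasions)}
    individuals = sorted({i for i, _, _ in triples})
    ind_index = {i: a for a, i in enumerate(individuals)}
    detections = np.zeros((len(individuals), len(occasions), len(det_ids)), dtype=np.int8)
    n_collapsed = 0
    for ind, day, cam in triples:
        if day not in occ_index:
            raise ValueError(f"detection on {day} outside the occasion calendar")
        cell = (ind_index[ind], occ_index[day], det_index[cam])
        if detections[cell]:
            n_collapsed += 1
        detections[cell] = 1
    if n_collapsed:
        logger.info("collapsed %d repeat same-day detections", n_collapsed)
    usage = np.zeros((len(det_ids), len(occasions)), dtype=np.int8)
    any_calendar = any(getattr(d, "operational_days", None) for d in detectors)
    for k, d in enumerate(detectors):
        ops = getattr(d, "operational_days", None)
        if any_calendar and ops:
            for s, day in enumerate(occasions):
                usage[k, s] = day in ops
        else:
            usage[k, :] = 1
    return CaptureHistory(
        individuals=individuals,
        occasions=list(occasions),
        detector_ids=det_ids,
        detector_xy=det_xy,
        detections=detections,
        usage=usage,
    )


def make_mask(detectors, buffer: float, spacing: float) -> HabitatMask:
    """Square-grid mask of points within ``buffer`` metres of a detector."""
    if buffer <= 0 or spacing <= 0:
        raise ValueError("buffer and spacing must be positive")
    if spacing > buffer:
        logger.warning("mask spacing %.0f m exceeds buffer %.0f m: coarse mask",
                       spacing, buffer)
    xy = _detector_xy(detectors)
    xs = np.arange(xy[:, 0].min() - buffer, xy[:, 0].max() + buffer + spacing / 2, spacing)
    ys = np.arange(xy[:, 1].min() - buffer, xy[:, 1].max() + buffer + spacing / 2, spacing)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    d2 = ((pts[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2).min(axis=1)
    keep = pts[d2 <= buffer**2]
    return HabitatMask(points=keep, spacing=spacing)


def _detector_xy(detectors) -> np.ndarray:
    if isinstance(detectors, np.ndarray):
        return np.asarray(detectors, dtype=float)
    return np.array([[d.x, d.y] for d in detectors], dtype=float)


# ---------------------------------------------------------------------------
# likelihood


def _log_g_matrices(ch: CaptureHistory, mask: HabitatMask, params: DetFnParams):
    """log g and log(1-g) over detectors x mask points."""
    diff = ch.detector_xy[:, None, :] - mask.points[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    g = detection_probability(d, params)
    g = np.clip(g, 0.0, 1.0 - 1e-15)
    with np.errstate(divide="ignore"):
        logg = np.log(g)
    log1mg = np.log1p(-g)
    return logg, log1mg


def p_dot(ch: CaptureHistory, mask: HabitatMask, params: DetFnParams) -> np.ndarray:
    """Overall detection probability p.(X) at each mask point."""
    _, log1mg = _log_g_matrices(ch, mask, params)
    u = ch.usage.sum(axis=1).astype(float)          # occasions used per detector
    s0 = u @ log1mg                                  # (M,) log prob never detected
    return -np.expm1(s0)


def effective_sampling_area(ch: CaptureHistory, mask: HabitatMask, params: DetFnParams) -> float:
    """a(theta) = sum_X p.(X) w, in km^2."""
    return float(p_dot(ch, mask, params).sum() * mask.cell_area)


def neg_log_likelihood(ch: CaptureHistory, mask: HabitatMask, params: DetFnParams) -> float:
    """Conditional SECR negative log-likelihood (see module docstring)."""
    if mask.n_points == 0:
        raise ValueError("empty mask")
    logg, log1mg = _log_g_matrices(ch, mask, params)
    u = ch.usage.sum(axis=1).astype(float)           # (K,)
    c = ch.detections.sum(axis=1).astype(float)      # (n, K) detections per detector
    with np.errstate(invalid="ignore"):
        log_pr = c @ logg + (u[None, :] - c) @ log1mg    # (n, M)
    log_pr = np.where(np.isnan(log_pr), -np.inf, log_pr)
    logw = math.log(mask.cell_area)
    per_ind = logsumexp(log_pr, axis=1) + logw       # log sum_X Pr(omega_i|X) w
    if np.any(np.isneginf(per_ind)):
        bad = [ch.individuals[i] for i in np.where(np.isneginf(per_ind))[0]]
        raise FloatingPointError(
            f"zero likelihood over the mask for individuals {bad[:3]} "
            "(mask too small or degenerate parameters)"
        )
    s0 = u @ log1mg
    with np.errstate(divide="ignore"):
        log_pdot = np.log(-np.expm1(s0))    # -inf where p.(X) = 0 is fine
    log_a = logsumexp(log_pdot) + logw
    return float(-per_ind.sum() + ch.n * log_a)


# ---------------------------------------------------------------------------
# model / results


class SECRModel:
    """Null-model SECR (constant g0, sigma) for binary proximity data.

    Parameters
    ----------
    capture_history : CaptureHistory
    mask : HabitatMask
    detfn : {"HN", "EX", "HR"}
        Detection-function family.
    """

    def __init__(self, capture_history: CaptureHistory, mask: HabitatMask,
                 detfn: str = "HN") -> None:
        if detfn not in DETFN_KINDS:
            raise ValueError(f"unknown detection function {detfn!r}")
        if capture_history.n < 2:
            raise ValueError("need at least two individuals")
        self.capture_history = capture_history
        self.mask = mask
        self.detfn = detfn

    # -- starting values ----------------------------------------------------
    def _default_start(self) -> DetFnParams:
        ch = self.capture_history
        # scale: spread of each individual's detection locations, falling
        # back to half the median nearest-detector spacing
        locs = []
        for i in range(ch.n):
            _, k = np.nonzero(ch.detections[i])
            locs.append(ch.detector_xy[k])
        spread = [np.sqrt(((xy - xy.mean(0)) ** 2).sum(1).mean())
                  for xy in locs if len(xy) > 1]
        sigma0 = float(np.mean([s for s in spread if s > 0])) if any(
            s > 0 for s in spread) else 0.0
        if sigma0 <= 0:
            d = np.sqrt(((ch.detector_xy[:, None] - ch.detector_xy[None, :]) ** 2).sum(2))
            np.fill_diagonal(d, np.inf)
            sigma0 = float(np.median(d.min(axis=1)))
        mean_dets = ch.n_detections / max(ch.n, 1)
        occ = max(int(ch.usage.sum(axis=0).max()), 1)
        g0_0 = min(max(mean_dets / (occ * 2.0), 1e-3), 0.5)
        z = _Z_DEFAULT if self.detfn == "HR" else None
        return DetFnParams(kind=self.detfn, g0=g0_0, sigma=sigma0, z=z)

    def _nll_link(self, theta: np.ndarray) -> float:
        try:
            params = _from_link(theta, self.detfn)
            return neg_log_likelihood(self.capture_history, self.mask, params)
        except FloatingPointError:
            return 1e10

    def fit(self, start: DetFnParams | None = None, maxiter: int = 500) -> "SECRResults":
        """Maximise the conditional likelihood on link scales.

        Link scales: logit g0, log sigma and (hazard rate only) log(z - 1),
        which keeps g0 in (0,1), sigma positive and z above 1 without
        explicit constraints.  The covariance of the link-scale estimates
        is the inverse numerical Hessian at the optimum.
        """
        if start is not None and start.kind != self.detfn:
            raise ValueError("start parameters are for a different detection function")
        theta0 = _to_link(start or self._default_start())
        res = optimize.minimize(self._nll_link, theta0, method="Nelder-Mead",
                                options={"maxiter": maxiter * 4, "xatol": 1e-6,
                                         "fatol": 1e-8})
        res = optimize.minimize(self._nll_link, res.x, method="BFGS",
                                options={"maxiter": maxiter, "gtol": 1e-6})
        converged = bool(res.success) or float(np.linalg.norm(res.jac)) < 1e-2
        if not converged:
            logger.warning("SECR fit (%s) did not converge: %s", self.detfn, res.message)
        try:
            hess = approx_hess(res.x, self._nll_link)
            cov = np.linalg.inv(hess)
            if np.any(np.diag(cov) <= 0):
                raise np.linalg.LinAlgError("non-positive variance")
        except np.linalg.LinAlgError:
            logger.warning("singular Hessian: SEs unavailable")
            cov = None
        return SECRResults(model=self, params_link=res.x, cov_link=cov,
                           llf=-float(res.fun), converged=converged)


class SECRResults:
    """Fitted SECR model: estimates, uncertainty, AICc and derived density."""

    def __init__(self, model: SECRModel, params_link: np.ndarray,
                 cov_link: np.ndarray | None, llf: float, converged: bool) -> None:
        self.model = model
        self.params_link = np.asarray(params_link, dtype=float)
        self.cov_link = cov_link
        self.llf = llf
        self.converged = converged

    # -- basic quantities ---------------------------------------------------
    @property
    def detfn(self) -> str:
        return self.model.detfn

    @property
    def params(self) -> DetFnParams:
        return _from_link(self.params_link, self.detfn)

    @property
    def k_params(self) -> int:
        return self.params_link.size

    @property
    def n(self) -> int:
        return self.model.capture_history.n

    @property
    def aicc(self) -> float:
        k, n = self.k_params, self.n
        if n - k - 1 <= 0:
            raise ValueError("AICc undefined: n <= K + 1")
        return -2.0 * self.llf + 2 * k + 2 * k * (k + 1) / (n - k - 1)

    @property
    def esa(self) -> float:
        """Effective sampling area a(theta-hat), km^2."""
        return effective_sampling_area(self.model.capture_history,
                                       self.model.mask, self.params)

    def param_table(self) -> pd.DataFrame:
        """Natural-scale estimates with delta-method SEs."""
        names = ["g0", "sigma"] + (["z"] if self.detfn == "HR" else [])
        est = [self.params.g0, self.params.sigma]
        # d(natural)/d(link)
        deriv = [self.params.g0 * (1 - self.params.g0), self.params.sigma]
        if self.detfn == "HR":
            est.append(self.params.z)
            deriv.append(self.params.z - 1.0)
        if self.cov_link is not None:
            se = np.sqrt(np.diag(self.cov_link)) * np.abs(deriv)
        else:
            se = np.full(len(est), np.nan)
        return pd.DataFrame({"parameter": names, "estimate": est, "se": se})

    # -- density ------------------------------------------------------------
    def derive_density(self) -> DensityEstimate:
        """Horvitz-Thompson-like density with delta-method lognormal CI.

        Var(D)/D^2 = 1/n + (grad a / a)' V (grad a / a), treating n as
        Poisson; CI = (D / C, D * C) with
        C = exp(1.96 sqrt(ln(1 + CV^2))).
        """
        a = self.esa
        if a <= 0:
            raise ValueError("non-positive effective sampling area")
        n = self.n
        D = n / a
        cv2 = 1.0 / n
        if self.cov_link is not None:
            grad = approx_fprime(
                self.params_link,
                lambda th: effective_sampling_area(
                    self.model.capture_history, self.model.mask,
                    _from_link(th, self.detfn)),
                centered=True,
            ).ravel() / a
            cv2 += float(grad @ self.cov_link @ grad)
        se = D * math.sqrt(cv2)
        if cv2 > 0:
            C = math.exp(1.959963984540054 * math.sqrt(math.log1p(cv2)))
        else:
            C = 1.0
        return DensityEstimate(D=D, se=se, ci_low=D / C, ci_high=D * C,
                               mask_area=self.model.mask.area, esa=a)

    def summary(self) -> str:
        ch = self.model.capture_history
        dens = self.derive_density()
        lines = [
            "SECR conditional-likelihood fit (proximity detectors)",
            "=" * 56,
            f"detection function   {self.detfn}",
            f"individuals          {ch.n}",
            f"detections           {ch.n_detections}",
            f"occasions            {len(ch.occasions)}",
            f"detectors            {len(ch.detector_ids)}",
            f"mask                 {self.model.mask.n_points} points, "
            f"{self.model.mask.area:.1f} km2",
            f"log-likelihood       {self.llf:.3f}",
            f"AICc                 {self.aicc:.3f}",
            f"converged            {self.converged}",
            "-" * 56,
        ]
        for _, row in self.param_table().iterrows():
            lines.append(f"{row['parameter']:<8s} {row['estimate']:>12.6g}"
                         f"   SE {row['se']:>10.4g}")
        lines += [
            "-" * 56,
            f"esa a(theta)         {dens.esa:.2f} km2",
            f"density D            {dens.D:.4f} / km2   SE {dens.se:.4f}",
            f"95% CI               ({dens.ci_low:.4f}, {dens.ci_high:.4f})",
            f"N over mask          {dens.n_hat:.1f}  "
            f"({dens.n_ci[0]:.1f}, {dens.n_ci[1]:.1f})",
        ]
        return "\n".join(lines)


def fit_secr(capture_history: CaptureHistory, mask: HabitatMask, kind: str = "HN",
             start: DetFnParams | None = None) -> SECRResults:
    """Convenience wrapper: build a :class:`SECRModel` and fit it."""
    return SECRModel(capture_history, mask, detfn=kind).fit(start=start)


def rank_models(fits: list[SECRResults]) -> pd.DataFrame:
    """AICc ranking with delta-AICc and Akaike weights.

    All fits must share the same capture history (same data, different
    detection functions).
    """
    if not fits:
        raise ValueError("no fits to rank")
    ch0 = fits[0].model.capture_history
    for f in fits[1:]:
        ch = f.model.capture_history
        if ch.n != ch0.n or not np.array_equal(ch.detections, ch0.detections):
            raise ValueError("fits are not on identical data")
    rows = []
    for f in fits:
        dens = f.derive_density()
        rows.append({"detfn": f.detfn, "logLik": f.llf, "K": f.k_params,
                     "AICc": f.aicc, "esa": f.esa, "D": dens.D})
    df = pd.DataFrame(rows).sort_values("AICc", kind="stable").reset_index(drop=True)
    df["dAICc"] = df["AICc"] - df["AICc"].min()
    rel = np.exp(-0.5 * df["dAICc"])
    df["weight"] = rel / rel.sum()
    return df


def derive_density(fit: SECRResults, mask: HabitatMask | None = None) -> DensityEstimate:
    """Module-level alias for :meth:`SECRResults.derive_density`."""
    if mask is not None and mask is not fit.model.mask:
        fit = SECRResults(SECRModel(fit.model.capture_history, mask, fit.detfn),
                          fit.params_link, fit.cov_link, fit.llf, fit.converged)
    return fit.derive_density()


def abundance_from_density(D: float, mask_area: float) -> float:
    """N-hat = D x mask area (volume under a flat density surface)."""
    return D * mask_area
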