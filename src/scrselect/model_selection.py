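"""Bayesian model-selection criteria computed from posterior draws.

Evidence (marginal likelihood) estimators
    * Gelfand-Dey with a tuning density g, in two flavours for the
      high-dimensional latents: fix them at an iteratively improved MAP
      estimate (GD-MAP), or integrate them out (GD-IL, with z and missing
      sexes marginalized analytically and activity centers by Riemann sum).
    * Harmonic mean (the g = prior special case of Gelfand-Dey).

Information criteria
    * DIC with p_DIC1 (mean-deviance gap at the MAP) and p_DIC2 (twice the
      posterior variance of the log-likelihood).
    * WAIC partitioned by augmented individual, with p_WAIC1 (lppd gap),
      p_WAIC2 (pointwise posterior variance) and p_WAIC3 (twice the pointwise
      posterior mean absolute deviation -- the absolute-error analogue).

Predictive loss
    * Gelfand-Ghosh D_infinity: squared bias plus predictive variance over the
      2*M*J*K vectorized binary cells, from replicates simulated at each
      retained draw.

All evidence computations run in log space; non-finite summands are dropped
with the count reported in the result metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2, multivariate_normal, multivariate_t

from .capture_data import (BilateralData, StateSpace, TrapArray,
                           reorder_by_permutation, summarize_all)
from .likelihoods import (LatentState, ScalarParams, detection_loglik_terms,
                          integrated_loglik, log_prior, sex_prior_terms,
                          squared_distances, uses_entry)
from .mcmc import PosteriorDraws


class EstimationError(RuntimeError):
    """No usable summands remain for an evidence estimator."""


#: the nine tuning-density variants of the study
TUNING_VARIANTS: tuple = (
    ("mvnormal", None),
    ("mvt", 10), ("mvt", 100), ("mvt", 500), ("mvt", 1000), ("mvt", 10000),
    ("truncated_normal", 0.90), ("truncated_normal", 0.95),
    ("truncated_normal", 0.99),
)

_EVIDENCE_METHODS = frozenset({"gd_map", "gd_il", "hm"})


@dataclass(frozen=True)
class TuningDensity:
    """Fitted tuning density g on the transformed parameter scale."""

    kind: str                    # mvnormal | mvt | truncated_normal
    location: np.ndarray
    scale: np.ndarray            # positive-definite scale matrix
    df: float | None = None      # mvt degrees of freedom
    conf: float | None = None    # truncation confidence coefficient

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        if self.kind == "mvnormal":
            return np.atleast_1d(
                multivariate_normal.logpdf(x, self.location, self.scale))
        if self.kind == "mvt":
            return np.atleast_1d(
                multivariate_t.logpdf(x, self.location, self.scale,
                                      df=self.df))
        if self.kind == "truncated_normal":
            lp = np.atleast_1d(
                multivariate_normal.logpdf(x, self.location, self.scale))
            dev = x - self.location
            maha = np.einsum("np,pq,nq->n", dev,
                             np.linalg.inv(self.scale), dev)
            cut = chi2.ppf(self.conf, df=self.location.size)
            # renormalize the retained ellipsoid mass to 1
            return np.where(maha <= cut, lp - np.log(self.conf), -np.inf)
        raise ValueError(f"unknown tuning-density kind {self.kind!r}")


def fit_tuning_density(draws_transformed: np.ndarray, kind: str = "mvnormal",
                       df: float | None = None,
                       conf: float | None = None) -> TuningDensity:
    """Fit g by moment matching on the transformed-scale draws.

    For the multivariate t the scale matrix is shrunk by (df-2)/df so the
    fitted variance matches the sample covariance.
    """
    x = np.atleast_2d(np.asarray(draws_transformed, dtype=float))
    if x.shape[1] > x.shape[0] - 2:
        raise ValueError("need at least p+2 draws to fit the tuning density")
    loc = x.mean(axis=0)
    cov = np.cov(x, rowvar=False).reshape(x.shape[1], x.shape[1])
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance; adding ridge 1e-8", stacklevel=2)
        cov = cov + 1e-8 * np.eye(cov.shape[0])
    if kind == "mvnormal":
        return TuningDensity("mvnormal", loc, cov)
    if kind == "mvt":
        if df is None or df <= 2:
            raise ValueError("mvt tuning density needs df > 2")
        return TuningDensity("mvt", loc, cov * (df - 2.0) / df, df=df)
    if kind == "truncated_normal":
        if conf is None or not 0 < conf < 1:
            raise ValueError("truncated normal needs a confidence coefficient")
        return TuningDensity("truncated_normal", loc, cov, conf=conf)
    raise ValueError(f"unknown tuning-density kind {kind!r}")


@dataclass
class CriterionResult:
    """One model-selection score."""

    method: str
    value: float
    model_id: str
    penalty: float | None = None
    metadata: dict = field(default_factory=dict)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        pen = "" if self.penalty is None else f", penalty={self.penalty:.3f}"
        return (f"CriterionResult({self.method}, {self.model_id}, "
                f"value={self.value:.4f}{pen})")


# ---------------------------------------------------------------------------
# Gelfand-Dey core

def gd_log_marginal(log_g: np.ndarray, log_f: np.ndarray,
                    log_pi: np.ndarray) -> tuple[float, int]:
    """log of the Gelfand-Dey estimator from per-draw log components.

    Returns (log m_hat, number of non-finite summands dropped).
    """
    with np.errstate(invalid="ignore"):
        terms = np.asarray(log_g) - np.asarray(log_f) - np.asarray(log_pi)
    # -inf terms are legitimate zero summands (e.g. a draw outside a
    # truncated tuning density's support); only +inf / nan are unusable
    usable = np.isfinite(terms) | (terms == -np.inf)
    n_drop = int((~usable).sum())
    kept = terms[usable]
    if kept.size == 0 or np.all(kept == -np.inf):
        raise EstimationError("no usable Gelfand-Dey summands")
    return float(-(logsumexp(kept) - np.log(kept.size))), n_drop


def log_marginal_hm(loglik_draws: np.ndarray) -> CriterionResult:
    """Harmonic-mean estimator of the marginal likelihood."""
    ll = np.asarray(loglik_draws, dtype=float)
    finite = np.isfinite(ll)
    if not finite.any():
        raise EstimationError("no finite log-likelihood draws")
    kept = ll[finite]
    value = float(-(logsumexp(-kept) - np.log(kept.size)))
    return CriterionResult("hm", value, model_id="",
                           metadata={"n_dropped": int((~finite).sum())})


# ---------------------------------------------------------------------------
# MAP search over the retained draws (alternating scalar / latent scans)

@dataclass
class MapEstimate:
    params: ScalarParams
    latents: LatentState
    log_kernel: float         # log f(Y|mu) pi(mu) at the estimate
    loglik: float             # complete-data log-likelihood at the estimate
    kernel_trace: list        # kernel value after each improvement sweep


class _FixedLatentEvaluator:
    """Evaluates scalar-draw kernels at a fixed latent configuration."""

    def __init__(self, data: BilateralData, traps: TrapArray,
                 space: StateSpace, latents: LatentState):
        self.data = data
        self.K = data.K
        self.M = data.M
        y2s = reorder_by_permutation(data.y2, latents.L)
        self.counts = summarize_all(data.y1, y2s)
        self.dist2 = squared_distances(latents.S, traps)
        self.z = np.asarray(latents.z)
        self.u = np.asarray(latents.u)
        self.nz = int(self.z.sum())
        self.const = (-self.M * np.log(space.area)
                      - gammaln(self.M + 1))  # uniform S and L priors
        self.impossible = np.any((self.z == 0) & (self.counts["ydd"] > 0))

    def loglik(self, params: ScalarParams) -> float:
        """Complete-data log-likelihood at these latents."""
        if self.impossible:
            return -np.inf
        det = detection_loglik_terms(params, self.dist2,
                                     params.sigma_of_sex(self.u),
                                     self.counts, self.K)
        return float((self.z * det).sum()
                     + sex_prior_terms(params, self.u).sum())

    def log_latent_prior(self, params: ScalarParams) -> float:
        return (self.nz * np.log(params.psi)
                + (self.M - self.nz) * np.log1p(-params.psi) + self.const)

    def kernel(self, params: ScalarParams) -> float:
        lp = log_prior(params)
        if not np.isfinite(lp):
            return -np.inf
        return self.loglik(params) + self.log_latent_prior(params) + lp


def _latent_snapshots(draws: PosteriorDraws) -> list[LatentState]:
    lat = draws.latents
    if len(lat.get("z", [])) == 0:
        raise EstimationError("no latent snapshots stored in the chain")
    return [LatentState(z=lat["z"][b], u=lat["u"][b], S=lat["S"][b],
                        L=lat["L"][b]) for b in range(len(lat["z"]))]


def map_search(draws: PosteriorDraws, data: BilateralData, traps: TrapArray,
               space: StateSpace, max_sweeps: int = 50) -> MapEstimate:
    """Iterative MAP search: start from the best joint draw, then alternately
    rescan all scalar draws at the fixed latents and all latent snapshots at
    the fixed scalars, accepting only improvements.  The kernel sequence is
    non-decreasing and ends at least as high as the best joint draw."""
    snapshots = _latent_snapshots(draws)
    idx = np.asarray(draws.latents["draw_index"], dtype=int)
    evaluators = [_FixedLatentEvaluator(data, traps, space, s)
                  for s in snapshots]
    all_params = [ScalarParams.from_vector(v, draws.model_id, R=draws.R)
                  for v in draws.params]

    joint = [ev.kernel(all_params[i]) for ev, i in zip(evaluators, idx)]
    b_best = int(np.argmax(joint))
    p_best = int(idx[b_best])
    best = joint[b_best]
    trace = [best]
    for _ in range(max_sweeps):
        improved = False
        ev = evaluators[b_best]
        vals = np.array([ev.kernel(p) for p in all_params])
        d = int(np.argmax(vals))
        if vals[d] > best:
            best, p_best, improved = float(vals[d]), d, True
        pars = all_params[p_best]
        vals_b = np.array([e.kernel(pars) for e in evaluators])
        b = int(np.argmax(vals_b))
        if vals_b[b] > best:
            best, b_best, improved = float(vals_b[b]), b, True
        trace.append(best)
        if not improved:
            break
    params_hat = all_params[p_best]
    latents_hat = snapshots[b_best]
    return MapEstimate(params=params_hat, latents=latents_hat,
                       log_kernel=best,
                       loglik=evaluators[b_best].loglik(params_hat),
                       kernel_trace=trace)


# ---------------------------------------------------------------------------
# Gelfand-Dey with the MAP approximation for the latents

def log_marginal_gd_map(draws: PosteriorDraws, data: BilateralData,
                        traps: TrapArray, space: StateSpace,
                        tuning: str = "mvnormal", df: float | None = None,
                        conf: float | None = None,
                        g: TuningDensity | None = None,
                        map_estimate: MapEstimate | None = None,
                        ) -> CriterionResult:
    """Gelfand-Dey log marginal with latents fixed at the searched MAP.

    The denominator couples the complete-data likelihood at the fixed latents
    with the latent prior (the joint density of (Y, mu_s_hat) given mu_p) and
    the scalar prior with logit-scale Jacobians; g is fitted on the
    transformed scale so its support is the whole space.
    """
    if map_estimate is None:
        map_estimate = map_search(draws, data, traps, space)
    if g is None:
        g = fit_tuning_density(draws.transformed, tuning, df=df, conf=conf)
    ev = _FixedLatentEvaluator(data, traps, space, map_estimate.latents)
    log_f = np.empty(draws.n_retained)
    log_pi = np.empty(draws.n_retained)
    for d in range(draws.n_retained):
        p = ScalarParams.from_vector(draws.params[d], draws.model_id,
                                     R=draws.R)
        log_f[d] = ev.loglik(p) + ev.log_latent_prior(p)
        log_pi[d] = log_prior(p, on_transformed_scale=True)
    log_g = g.logpdf(draws.transformed)
    value, n_drop = gd_log_marginal(log_g, log_f, log_pi)
    return CriterionResult("gd_map", value, draws.model_id,
                           metadata={"tuning": g.kind, "df": g.df,
                                     "conf": g.conf, "n_dropped": n_drop})


def log_marginal_gd_il(draws: PosteriorDraws, data: BilateralData,
                       traps: TrapArray, space: StateSpace,
                       tuning: str = "mvnormal", df: float | None = None,
                       conf: float | None = None,
                       g: TuningDensity | None = None,
                       grid_resolution: tuple[int, int] = (50, 70),
                       draw_stride: int = 1) -> CriterionResult:
    """Gelfand-Dey log marginal with the integrated likelihood.

    z and missing sexes are marginalized analytically and the activity
    centers by a Riemann sum; the permutation keeps its posterior draw, and
    the uniform permutation prior 1/M! cancels against the same factor in the
    tuning density g(mu_p, L) = g(mu_p)/M!.
    """
    if draws.L_draws is None or len(draws.L_draws) == 0:
        raise EstimationError("chain did not store permutation draws")
    sel = np.arange(0, draws.n_retained, draw_stride)
    if g is None:
        g = fit_tuning_density(draws.transformed[sel], tuning, df=df,
                               conf=conf)
    log_f = np.empty(sel.size)
    log_pi = np.empty(sel.size)
    for j, d in enumerate(sel):
        p = ScalarParams.from_vector(draws.params[d], draws.model_id,
                                     R=draws.R)
        log_f[j] = integrated_loglik(data, p, draws.L_draws[d], traps, space,
                                     grid_resolution=grid_resolution)
        log_pi[j] = log_prior(p, on_transformed_scale=True)
    log_g = g.logpdf(draws.transformed[sel])
    value, n_drop = gd_log_marginal(log_g, log_f, log_pi)
    return CriterionResult("gd_il", value, draws.model_id,
                           metadata={"tuning": g.kind, "df": g.df,
                                     "conf": g.conf, "n_dropped": n_drop,
                                     "grid": tuple(grid_resolution),
                                     "stride": draw_stride})


# ---------------------------------------------------------------------------
# DIC / WAIC

def dic(loglik_draws: np.ndarray, loglik_at_map: float,
        variant: int = 1, model_id: str = "") -> CriterionResult:
    """Deviance information criterion with the MAP plug-in deviance."""
    ll = np.asarray(loglik_draws, dtype=float)
    if variant == 1:
        p_dic = 2.0 * (loglik_at_map - ll.mean())
    elif variant == 2:
        p_dic = 2.0 * ll.var(ddof=0)
    else:
        raise ValueError("DIC variant must be 1 or 2")
    value = -2.0 * loglik_at_map + 2.0 * p_dic
    return CriterionResult(f"dic{variant}", float(value), model_id,
                           penalty=float(p_dic))


def waic(indiv_loglik: np.ndarray, variant: int = 1,
         model_id: str = "") -> CriterionResult:
    """WAIC over the M augmented individuals."""
    ll = np.asarray(indiv_loglik, dtype=float)
    n = ll.shape[0]
    lppd = logsumexp(ll, axis=0) - np.log(n)   # [M]
    mean_ll = ll.mean(axis=0)
    if variant == 1:
        p_waic = 2.0 * (lppd - mean_ll).sum()
    elif variant == 2:
        p_waic = ll.var(axis=0, ddof=0).sum()
    elif variant == 3:
        p_waic = 2.0 * np.abs(ll - mean_ll).mean(axis=0).sum()
    else:
        raise ValueError("WAIC variant must be 1, 2 or 3")
    value = -2.0 * lppd.sum() + 2.0 * p_waic
    return CriterionResult(f"waic{variant}", float(value), model_id,
                           penalty=float(p_waic))


# ---------------------------------------------------------------------------
# posterior predictive loss (Gelfand-Ghosh, w -> infinity)

def ppl_from_moments(y_vec: np.ndarray, rep_mean: np.ndarray,
                     rep_var: np.ndarray, model_id: str = "") -> CriterionResult:
    """D_infinity from per-cell predictive means and variances."""
    gof = float(((y_vec - rep_mean) ** 2).sum())
    pen = float(rep_var.sum())
    return CriterionResult("ppl", gof + pen, model_id, penalty=pen,
                           metadata={"goodness_of_fit": gof})


def _simulate_replicate(data: BilateralData, params: ScalarParams,
                        latents: LatentState, traps: TrapArray,
                        rng: np.random.Generator) -> np.ndarray:
    """One replicate (Y1, Y2) in the observed detector-2 row order."""
    M, J, K = data.M, data.J, data.K
    act = np.flatnonzero(np.asarray(latents.z) == 1)
    dist2 = squared_distances(latents.S[act], traps)
    sigma_i = params.sigma_of_sex(np.asarray(latents.u)[act])
    g = np.exp(-dist2 / (2.0 * sigma_i[:, None] ** 2))
    y1 = np.zeros((M, J, K), dtype=np.uint8)
    y2s = np.zeros((M, J, K), dtype=np.uint8)
    if uses_entry(params.model_id):
        eta = params.omega0 * g
        entered = rng.random((act.size, J, K)) < eta[:, :, None]
        y1[act] = entered & (rng.random((act.size, J, K)) < params.phi)
        y2s[act] = entered & (rng.random((act.size, J, K)) < params.phi)
    else:
        p = (params.p0 * g)[:, :, None]
        y1[act] = rng.random((act.size, J, K)) < p
        y2s[act] = rng.random((act.size, J, K)) < p
    # place detector-2 replicate rows back into detector-2 row order
    y2 = y2s[np.asarray(latents.L)]
    return np.concatenate([y1.ravel(), y2.ravel()]).astype(np.float64)


def posterior_predictive_loss(draws: PosteriorDraws, data: BilateralData,
                              traps: TrapArray, space: StateSpace,
                              n_rep_per_draw: int = 1, seed: int = 0,
                              ) -> CriterionResult:
    """D_infinity from replicates simulated at each stored latent snapshot."""
    snapshots = _latent_snapshots(draws)
    idx = np.asarray(draws.latents["draw_index"], dtype=int)
    if len(snapshots) < 10:
        warnings.warn("fewer than 10 draws for posterior predictive loss",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    y_vec = np.concatenate([data.y1.ravel(), data.y2.ravel()]).astype(float)
    total = np.zeros_like(y_vec)
    total_sq = np.zeros_like(y_vec)
    n = 0
    for lat, d in zip(snapshots, idx):
        p = ScalarParams.from_vector(draws.params[d], draws.model_id,
                                     R=draws.R)
        for _ in range(n_rep_per_draw):
            rep = _simulate_replicate(data, p, lat, traps, rng)
            total += rep
            total_sq += rep * rep
            n += 1
    mean = total / n
    var = total_sq / n - mean ** 2
    np.clip(var, 0.0, None, out=var)
    res = ppl_from_moments(y_vec, mean, var, model_id=draws.model_id)
    res.metadata["n_replicates"] = n
    return res


# ---------------------------------------------------------------------------
# winner selection

_N_SCALARS = {"M1": 6, "M2": 5, "M3": 4, "M4": 3}


@dataclass(frozen=True)
class SelectionOutcome:
    model_id: str
    tied: bool
    tied_models: tuple


def select_model(results: dict[str, CriterionResult],
                 method: str | None = None) -> SelectionOutcome:
    """Pick the winner: largest log-marginal for evidence methods, smallest
    value otherwise; ties go to the model with fewer scalar parameters."""
    methods = {r.method for r in results.values()}
    if len(methods) != 1:
        raise ValueError(f"mixed criterion methods: {sorted(methods)}")
    meth = method or methods.pop()
    larger_better = meth in _EVIDENCE_METHODS
    vals = {m: r.value for m, r in results.items()}
    best = max(vals.values()) if larger_better else min(vals.values())
    tied = tuple(sorted(m for m, v in vals.items() if v == best))
    winner = min(tied, key=lambda m: (_N_SCALARS.get(m, 99), m))
    return SelectionOutcome(model_id=winner, tied=len(tied) > 1,
                            tied_models=tied)


def all_criteria(draws: PosteriorDraws, data: BilateralData,
                 traps: TrapArray, space: StateSpace,
                 grid_resolution: tuple[int, int] = (50, 70),
                 il_draw_stride: int = 1, ppl_seed: int = 0,
                 include_gd_il: bool = True) -> pd.DataFrame:
    """All 25 criterion variants (9 tunings x 2 GD approaches, HM, 2 DIC,
    3 WAIC, PPL) for one fitted model, as a tidy table."""
    rows = []
    map_est = map_search(draws, data, traps, space)
    for kind, par in TUNING_VARIANTS:
        df_ = par if kind == "mvt" else None
        conf = par if kind == "truncated_normal" else None
        rows.append(log_marginal_gd_map(draws, data, traps, space,
                                        tuning=kind, df=df_, conf=conf,
                                        map_estimate=map_est))
    if include_gd_il:
        for kind, par in TUNING_VARIANTS:
            df_ = par if kind == "mvt" else None
            conf = par if kind == "truncated_normal" else None
            rows.append(log_marginal_gd_il(draws, data, traps, space,
                                           tuning=kind, df=df_, conf=conf,
                                           grid_resolution=grid_resolution,
                                           draw_stride=il_draw_stride))
    hm = log_marginal_hm(draws.loglik)
    hm.model_id = draws.model_id
    rows.append(hm)
    for v in (1, 2):
        rows.append(dic(draws.loglik, map_est.loglik, variant=v,
                        model_id=draws.model_id))
    for v in (1, 2, 3):
        rows.append(waic(draws.indiv_loglik, variant=v,
                         model_id=draws.model_id))
    rows.append(posterior_predictive_loss(draws, data, traps, space,
                                          seed=ppl_seed))
    return pd.DataFrame([{
        "model": r.model_id, "method": r.method, "value": r.value,
        "penalty": r.penalty,
        "tuning": r.metadata.get("tuning"),
        "df": r.metadata.get("df"), "conf": r.metadata.get("conf"),
    } for r in rows])
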