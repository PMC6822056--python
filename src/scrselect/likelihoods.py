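"""Model likelihoods for the four competing partial-identity SCR models.

Model M1 separates trap entry from detection and uses a sex-specific movement
scale; M3 is its sexless version.  Under M1/M3 an individual at activity
center ``s`` enters trap ``j`` on an occasion with probability
``eta_j(s) = omega0 * exp(-d(s, x_j)^2 / (2 sigma^2))`` and, given entry, each
of the two detectors fires independently with probability ``phi``.  The
per-trap/occasion cell therefore has outcome probabilities::

    (0,0): (1 - eta) + eta (1 - phi)^2      (no entry, or entry undetected)
    (1,0), (0,1): eta phi (1 - phi)
    (1,1): eta phi^2

a zero-inflated Bernoulli pair.  Models M2/M4 fold movement into the
observation process: each detector fires with probability
``p_j(s) = p0 * exp(-d^2 / (2 sigma^2))`` independently (2K Bernoulli trials
per trap), with (M2) or without (M4) a sex-specific sigma.

Scalar parameters carry uniform priors: U(0,1) for probabilities, U(0,R) for
movement scales.  All densities are evaluated in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit, logit, logsumexp, xlogy

from .capture_data import (SEX_UNKNOWN, BilateralData, StateSpace, TrapArray,
                           invert_permutation, reorder_by_permutation,
                           summarize_all)

MODEL_IDS = ("M1", "M2", "M3", "M4")

#: scalar parameters per model, in canonical order
MODEL_PARAMS: dict[str, tuple[str, ...]] = {
    "M1": ("psi", "theta", "phi", "omega0", "sigma_m", "sigma_f"),
    "M2": ("psi", "theta", "p0", "sigma_m", "sigma_f"),
    "M3": ("psi", "phi", "omega0", "sigma"),
    "M4": ("psi", "p0", "sigma"),
}

_SCALE_PARAMS = frozenset({"sigma", "sigma_m", "sigma_f"})


def is_sexed(model_id: str) -> bool:
    return model_id in ("M1", "M2")


def uses_entry(model_id: str) -> bool:
    """Whether the model separates trap entry (omega0, phi) from detection."""
    return model_id in ("M1", "M3")


@dataclass(frozen=True)
class ScalarParams:
    """Scalar (non-latent) parameters of one model.

    Only the fields listed in ``MODEL_PARAMS[model_id]`` are meaningful; the
    rest stay ``None``.  ``R`` is the upper bound of the uniform prior on the
    movement scales.
    """

    model_id: str
    psi: float = None
    theta: float = None
    phi: float = None
    omega0: float = None
    p0: float = None
    sigma_m: float = None
    sigma_f: float = None
    sigma: float = None
    R: float = 10.0

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_PARAMS:
            raise ValueError(f"unknown model {self.model_id!r}")
        for name in self.names:
            if getattr(self, name) is None:
                raise ValueError(f"{self.model_id} requires parameter {name!r}")

    @property
    def names(self) -> tuple[str, ...]:
        return MODEL_PARAMS[self.model_id]

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.names], dtype=float)

    @classmethod
    def from_vector(cls, vec, model_id: str, R: float = 10.0) -> "ScalarParams":
        names = MODEL_PARAMS[model_id]
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(names),):
            raise ValueError("vector length does not match model")
        return cls(model_id=model_id, R=R, **dict(zip(names, vec)))

    def in_support(self) -> bool:
        for name in self.names:
            v = getattr(self, name)
            hi = self.R if name in _SCALE_PARAMS else 1.0
            if not (0.0 < v < hi):
                return False
        return True

    def sigma_of_sex(self, u: np.ndarray) -> np.ndarray:
        """Movement scale per individual given sex indicators (1=male)."""
        if is_sexed(self.model_id):
            return np.where(np.asarray(u) == 1, self.sigma_m, self.sigma_f)
        return np.full(np.shape(u), self.sigma, dtype=float)

    def replace(self, **kw) -> "ScalarParams":
        return replace(self, **kw)


@dataclass
class LatentState:
    """High-dimensional latent variables of the augmented model.

    z: inclusion indicators (N = sum z); u: sex indicators (1 = male, used by
    M1/M2 only); S: activity centers; L: identity permutation (L[i] = true
    index of detector-2 row i).
    """

    z: np.ndarray
    u: np.ndarray
    S: np.ndarray
    L: np.ndarray

    def copy(self) -> "LatentState":
        return LatentState(self.z.copy(), self.u.copy(), self.S.copy(),
                           self.L.copy())


# ---------------------------------------------------------------------------
# detection kernels

def trap_entry_prob(omega0, sigma, distance):
    """Half-normal trap-entry probability eta = omega0 exp(-d^2/(2 sigma^2))."""
    d = np.asarray(distance, dtype=float)
    return omega0 * np.exp(-d * d / (2.0 * sigma * sigma))


def detection_prob_royle(p0, sigma, distance):
    """Half-normal detection probability p = p0 exp(-d^2/(2 sigma^2))."""
    d = np.asarray(distance, dtype=float)
    return p0 * np.exp(-d * d / (2.0 * sigma * sigma))


def squared_distances(S: np.ndarray, traps: TrapArray) -> np.ndarray:
    """[M, J] squared Euclidean distances from activity centers to traps."""
    diff = np.atleast_2d(S)[:, None, :] - traps.coordinates[None, :, :]
    return np.einsum("mjd,mjd->mj", diff, diff)


# ---------------------------------------------------------------------------
# per-individual detection factors (vectorized over individuals)

def _entry_detection_terms(params, dist2, sigma_i, counts, K):
    """log detection factor per individual for the entry models M1/M3."""
    eta = params.omega0 * np.exp(-dist2 / (2.0 * sigma_i[:, None] ** 2))
    phi = params.phi
    q = (1.0 - eta) + eta * (1.0 - phi) ** 2
    ydd, ndot, n_ij = counts["ydd"], counts["n_dot"], counts["n_ij"]
    return (xlogy(ydd, phi) + xlogy(2 * ndot - ydd, 1.0 - phi)
            + xlogy(n_ij, eta).sum(axis=1)
            + xlogy(K - n_ij, q).sum(axis=1))


def _royle_detection_terms(params, dist2, sigma_i, counts, K):
    """log detection factor per individual for the direct models M2/M4."""
    p = params.p0 * np.exp(-dist2 / (2.0 * sigma_i[:, None] ** 2))
    y_ij = counts["y_ij"]
    return (xlogy(y_ij, p).sum(axis=1)
            + xlogy(2 * K - y_ij, 1.0 - p).sum(axis=1))


def detection_loglik_terms(params: ScalarParams, dist2: np.ndarray,
                           sigma_i: np.ndarray, counts: dict, K: int) -> np.ndarray:
    """[M] log detection factors (the part raised to the power z_i)."""
    if uses_entry(params.model_id):
        return _entry_detection_terms(params, dist2, sigma_i, counts, K)
    return _royle_detection_terms(params, dist2, sigma_i, counts, K)


def sex_prior_terms(params: ScalarParams, u: np.ndarray) -> np.ndarray:
    """[M] log theta^u (1-theta)^(1-u); zero for sexless models."""
    if not is_sexed(params.model_id):
        return np.zeros(np.shape(u)[0])
    u = np.asarray(u)
    return xlogy(u, params.theta) + xlogy(1 - u, 1.0 - params.theta)


def per_individual_loglik(data: BilateralData, params: ScalarParams,
                          latents: LatentState, traps: TrapArray,
                          counts: dict | None = None) -> np.ndarray:
    """[M] factors of the complete-data log-likelihood (model density of
    (Y*, u_obs) given all parameters and latents).

    A row with observed detections but z=0 is impossible and yields -inf.
    """
    if counts is None:
        y2s = reorder_by_permutation(data.y2, latents.L)
        counts = summarize_all(data.y1, y2s)
    dist2 = squared_distances(latents.S, traps)
    sigma_i = params.sigma_of_sex(latents.u)
    det = detection_loglik_terms(params, dist2, sigma_i, counts, data.K)
    z = np.asarray(latents.z)
    out = sex_prior_terms(params, latents.u) + np.where(z == 1, det, 0.0)
    out = np.where((z == 0) & (counts["ydd"] > 0), -np.inf, out)
    return out


def complete_data_loglik(data: BilateralData, params: ScalarParams,
                         latents: LatentState, traps: TrapArray,
                         counts: dict | None = None) -> float:
    """Complete-data log-likelihood log f(Y*, u_obs | mu_p, mu_s)."""
    return float(per_individual_loglik(data, params, latents, traps, counts).sum())


def individual_loglik(i: int, data: BilateralData, params: ScalarParams,
                      latents: LatentState, traps: TrapArray) -> float:
    """The i-th factor of the complete-data log-likelihood."""
    if not 0 <= i < data.M:
        raise IndexError(f"individual index {i} out of range")
    return float(per_individual_loglik(data, params, latents, traps)[i])


# ---------------------------------------------------------------------------
# priors and transformations

def log_prior(params: ScalarParams, on_transformed_scale: bool = False) -> float:
    """Log prior density of the scalar parameters.

    On the natural scale the prior is a product of uniforms (density 1 on
    (0,1) for probabilities, 1/R on (0,R) for scales).  On the transformed
    (logit) scale the log-Jacobian of each map is included, making the support
    all of Euclidean space.
    """
    if not params.in_support():
        return -np.inf
    lp = 0.0
    for name in params.names:
        v = getattr(params, name)
        if name in _SCALE_PARAMS:
            lp += -np.log(params.R)
            if on_transformed_scale:
                # dsigma/dx = sigma (R - sigma) / R for sigma = R expit(x)
                lp += np.log(v) + np.log(params.R - v) - np.log(params.R)
        else:
            if on_transformed_scale:
                lp += np.log(v) + np.log1p(-v)
    return lp


def transform_params(params: ScalarParams) -> np.ndarray:
    """Map scalars to the unconstrained scale: logit(p), logit(sigma/R)."""
    out = []
    for name in params.names:
        v = getattr(params, name)
        out.append(logit(v / params.R) if name in _SCALE_PARAMS else logit(v))
    return np.array(out, dtype=float)


def untransform_params(vector, model_id: str, R: float = 10.0) -> ScalarParams:
    """Inverse of :func:`transform_params`."""
    vector = np.asarray(vector, dtype=float)
    if not np.all(np.isfinite(vector)):
        raise ValueError("transformed vector must be finite")
    names = MODEL_PARAMS[model_id]
    vals = {}
    for name, x in zip(names, vector):
        p = expit(x)
        vals[name] = R * p if name in _SCALE_PARAMS else p
    return ScalarParams(model_id=model_id, R=R, **vals)


# ---------------------------------------------------------------------------
# integrated likelihood (z, u0 marginalized analytically; S by Riemann sum)

def state_space_grid(space: StateSpace, gx: int, gy: int) -> np.ndarray:
    """[gx*gy, 2] cell centers of a regular partition of V."""
    xs = space.x_min + (space.x_max - space.x_min) * (np.arange(gx) + 0.5) / gx
    ys = space.y_min + (space.y_max - space.y_min) * (np.arange(gy) + 0.5) / gy
    gxv, gyv = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([gxv.ravel(), gyv.ravel()])


def pinned_sex(data: BilateralData, L: np.ndarray) -> np.ndarray:
    """[M] observed sex per true-individual slot under permutation L.

    Detector-1 rows carry their own sex; a sexed detector-2 row pins the slot
    it is currently assigned to.  A conflict (both sides sexed, different)
    is marked with -2.
    """
    pin = data.sex1.astype(np.int8).copy()
    Linv = invert_permutation(L)
    s2 = data.sex2[Linv]  # sex of the detector-2 row assigned to each slot
    conflict = (pin != SEX_UNKNOWN) & (s2 != SEX_UNKNOWN) & (pin != s2)
    pin = np.where((pin == SEX_UNKNOWN) & (s2 != SEX_UNKNOWN), s2, pin)
    pin[conflict] = -2
    return pin


def integrated_loglik(data: BilateralData, params: ScalarParams,
                      L: np.ndarray, traps: TrapArray, space: StateSpace,
                      grid_resolution: tuple[int, int] = (50, 70)) -> float:
    """log f(Y*, u_obs | mu_p, L): z and missing sexes marginalized in closed
    form, activity centers by a Riemann sum over a gx-by-gy grid on V.

    Per individual (after reordering detector-2 rows by L)::

        log[ sum_u  P(u|theta) * ( (1-psi) 1{row all-zero}
                                   + psi * mean_cells f_i(Y_i | s=cell, u) ) ]

    where the u-sum runs over the observed sex only when the slot is pinned.
    """
    gx, gy = grid_resolution
    cells = state_space_grid(space, gx, gy)
    ncells = cells.shape[0]
    y2s = reorder_by_permutation(data.y2, L)
    counts = summarize_all(data.y1, y2s)
    zero_row = counts["ydd"] == 0
    M, K = data.M, data.K

    diff = cells[:, None, :] - traps.coordinates[None, :, :]
    dist2 = np.einsum("cjd,cjd->cj", diff, diff)  # [ncells, J]

    def cell_logliks(sigma: float) -> np.ndarray:
        """[M, ncells] log f_i(Y_i | s=cell) for one movement scale."""
        if uses_entry(params.model_id):
            log_eta = (np.log(params.omega0)
                       - dist2 / (2.0 * sigma * sigma))  # eta>0 everywhere
            eta = np.exp(log_eta)
            phi = params.phi
            log_q = np.log((1.0 - eta) + eta * (1.0 - phi) ** 2)
            ll = (counts["n_ij"] @ log_eta.T
                  + (K - counts["n_ij"]) @ log_q.T)
            ll += (xlogy(counts["ydd"], phi)
                   + xlogy(2 * counts["n_dot"] - counts["ydd"], 1.0 - phi)
                   )[:, None]
        else:
            p = params.p0 * np.exp(-dist2 / (2.0 * sigma * sigma))
            ll = (counts["y_ij"] @ np.log(p).T
                  + (2 * K - counts["y_ij"]) @ np.log1p(-p).T)
        return ll

    # log mean over cells of f_i, per sex class actually needed
    if is_sexed(params.model_id):
        pin = pinned_sex(data, L)
        if np.any(pin == -2):
            return -np.inf  # assignment implies two different observed sexes
        lmean = {u: logsumexp(cell_logliks({1: params.sigma_m,
                                            0: params.sigma_f}[u]),
                              axis=1) - np.log(ncells)
                 for u in (0, 1)}
        log_theta = {1: np.log(params.theta), 0: np.log1p(-params.theta)}
        with np.errstate(divide="ignore"):
            log_psi = np.log(params.psi)
            log_1mpsi = np.log1p(-params.psi)
        factors = np.empty(M)
        for i in range(M):
            sexes = (0, 1) if pin[i] == SEX_UNKNOWN else (int(pin[i]),)
            terms = []
            for u in sexes:
                inner = log_psi + lmean[u][i]
                if zero_row[i]:
                    inner = np.logaddexp(inner, log_1mpsi)
                terms.append(log_theta[u] + inner)
            factors[i] = logsumexp(terms)
        return float(factors.sum())

    lmean = logsumexp(cell_logliks(params.sigma), axis=1) - np.log(ncells)
    with np.errstate(divide="ignore"):
        inner = np.log(params.psi) + lmean
        inner = np.where(zero_row,
                         np.logaddexp(inner, np.log1p(-params.psi)), inner)
    return float(inner.sum())
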