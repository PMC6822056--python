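"""Metropolis-within-Gibbs sampler with data augmentation and latent
identity-permutation updates.

Per sweep, in fixed order: random-walk Metropolis on each transformed scalar;
Metropolis random-walk (with boundary reflection) on the activity centers of
included individuals and a prior refresh for excluded ones; Gibbs on the
inclusion indicators z of undetected rows; Gibbs on the missing sex
indicators (models M1/M2); and a sweep of identity-permutation swap
proposals that never disturb known links.  Observed sexes travel with their
rows: a sexed detector-2 row pins the sex of whichever true-individual slot
it is currently assigned to, and swaps that would assign two different
observed sexes to one slot are rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .capture_data import (SEX_UNKNOWN, BilateralData, IdentityInfo,
                           IdentityConflictError, StateSpace, TrapArray,
                           invert_permutation, reorder_by_permutation,
                           summarize_all)
from .likelihoods import (LatentState, ScalarParams, _SCALE_PARAMS,
                          MODEL_PARAMS, detection_loglik_terms, is_sexed,
                          log_prior, sex_prior_terms, squared_distances,
                          transform_params, untransform_params, uses_entry)


@dataclass
class ChainConfig:
    """Sampler configuration.

    The study-scale run uses 30,000 iterations with a 10,000 burn-in; the
    scaled-down preset used throughout the test surface is 5,000/1,000.
    """

    n_iter: int = 5000
    burn_in: int = 1000
    thin: int = 1
    seed: int = 0
    proposal_scales: dict | float = 0.1
    s_proposal_scale: float = 0.25
    store_latents: bool = True
    latent_thin: int = 10
    adapt: bool = False
    n_perm_proposals: int | None = None  # default M per sweep
    # test hooks: freeze parts of the state
    update_scalars: tuple | None = None  # None = all model scalars
    update_s: bool = True
    update_z: bool = True
    update_u: bool = True
    update_l: bool = True
    init_params: ScalarParams | None = None
    init_latents: LatentState | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1 or self.latent_thin < 1:
            raise ValueError("thinning intervals must be >= 1")


@dataclass
class PosteriorDraws:
    """Retained MCMC output of one chain."""

    model_id: str
    param_names: tuple
    params: np.ndarray        # [n_ret, p] natural scale
    transformed: np.ndarray   # [n_ret, p] logit scale
    loglik: np.ndarray        # [n_ret] complete-data log-likelihood
    indiv_loglik: np.ndarray  # [n_ret, M]
    N: np.ndarray             # [n_ret] per-draw population size sum(z)
    latents: dict             # arrays z,u,S,L at latent-thinned draws
    R: float
    seed: int
    accept_rates: dict = field(default_factory=dict)
    L_draws: np.ndarray | None = None  # [n_ret, M] permutation at every draw

    @property
    def n_retained(self) -> int:
        return self.params.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.params, columns=list(self.param_names))
        df["loglik"] = self.loglik
        df["N"] = self.N
        return df

    def param(self, name: str) -> np.ndarray:
        return self.params[:, list(self.param_names).index(name)]

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(out / "draws.csv", index=False)
        sidecar = {k: np.asarray(v) for k, v in self.latents.items()}
        if self.L_draws is not None:
            sidecar["L_draws"] = self.L_draws
        np.savez_compressed(out / "latents.npz", indiv_loglik=self.indiv_loglik,
                            transformed=self.transformed, **sidecar)
        meta = {"model_id": self.model_id, "param_names": list(self.param_names),
                "R": self.R, "seed": self.seed,
                "accept_rates": self.accept_rates}
        (out / "chain.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, out_dir) -> "PosteriorDraws":
        out = Path(out_dir)
        meta = json.loads((out / "chain.json").read_text())
        df = pd.read_csv(out / "draws.csv")
        with np.load(out / "latents.npz") as z:
            sidecar = {k: z[k] for k in z.files}
        names = tuple(meta["param_names"])
        return cls(model_id=meta["model_id"], param_names=names,
                   params=df[list(names)].to_numpy(),
                   transformed=sidecar.pop("transformed"),
                   loglik=df["loglik"].to_numpy(),
                   indiv_loglik=sidecar.pop("indiv_loglik"),
                   N=df["N"].to_numpy(),
                   L_draws=sidecar.pop("L_draws", None),
                   latents=sidecar, R=meta["R"], seed=meta["seed"],
                   accept_rates=meta.get("accept_rates", {}))


# ---------------------------------------------------------------------------

def _consistent_assignment(data: BilateralData, identity: IdentityInfo,
                           rng: np.random.Generator) -> np.ndarray:
    """A permutation L consistent with known links and observed sexes."""
    M = data.M
    L = np.full(M, -1, dtype=int)
    taken = np.zeros(M, dtype=bool)
    for a, b in identity.known_links:
        L[b] = a
        taken[a] = True
    free_rows = [r for r in range(M) if L[r] < 0]
    free_slots = [t for t in range(M) if not taken[t]]
    # prefer empty detector-1 slots for observed detector-2 rows, sexed first
    obs = [r for r in free_rows if r < data.n_obs2]
    obs.sort(key=lambda r: data.sex2[r] == SEX_UNKNOWN)
    aug = [r for r in free_rows if r >= data.n_obs2]
    empty_first = sorted(free_slots, key=lambda t: (t < data.n_obs1, t))
    remaining = list(empty_first)
    for r in obs:
        s2 = data.sex2[r]
        pick = None
        for t in remaining:
            if s2 == SEX_UNKNOWN or data.sex1[t] in (SEX_UNKNOWN, s2):
                pick = t
                break
        if pick is None:
            raise IdentityConflictError(
                "no identity assignment consistent with links and sexes")
        remaining.remove(pick)
        L[r] = pick
    for r, t in zip(aug, remaining):
        L[r] = t
    return L


def init_state(data: BilateralData, identity: IdentityInfo, model_id: str,
               seed: int, traps: TrapArray, space: StateSpace,
               R: float = 10.0) -> tuple[ScalarParams, LatentState]:
    """Initial state: scalars from their priors; L link-consistent; z = 1 for
    detected rows; S at mean capture locations (uniform if undetected)."""
    rng = np.random.default_rng(seed)
    names = MODEL_PARAMS[model_id]
    vals = {n: (rng.uniform(0, R) if n in _SCALE_PARAMS else rng.uniform())
            for n in names}
    params = ScalarParams(model_id=model_id, R=R, **vals)

    M = data.M
    L = _consistent_assignment(data, identity, rng)
    y2s = reorder_by_permutation(data.y2, L)
    both = (data.y1 | y2s)
    has_det = both.reshape(M, -1).any(axis=1)
    z = np.where(has_det, 1, rng.random(M) < params.psi).astype(np.int8)

    pin = _pins(data, L)
    u = np.where(pin >= 0, pin, (rng.random(M) < 0.5)).astype(np.int8)

    S = np.column_stack([rng.uniform(space.x_min, space.x_max, M),
                         rng.uniform(space.y_min, space.y_max, M)])
    per_trap = both.sum(axis=2).astype(float)  # [M, J]
    tot = per_trap.sum(axis=1)
    det_rows = tot > 0
    S[det_rows] = (per_trap[det_rows] @ traps.coordinates
                   ) / tot[det_rows, None]
    return params, LatentState(z=z, u=u, S=S, L=L)


def _pins(data: BilateralData, L: np.ndarray) -> np.ndarray:
    """Observed sex per slot (-1 none); raises on a conflicting assignment."""
    pin = data.sex1.astype(np.int8).copy()
    s2 = data.sex2[invert_permutation(L)]
    conflict = (pin != SEX_UNKNOWN) & (s2 != SEX_UNKNOWN) & (pin != s2)
    if np.any(conflict):
        raise IdentityConflictError("assignment implies two observed sexes")
    return np.where(pin == SEX_UNKNOWN, s2, pin)


class _Sampler:
    """Mutable chain state with cached per-row summaries."""

    def __init__(self, data: BilateralData, identity: IdentityInfo,
                 model_id: str, traps: TrapArray, space: StateSpace,
                 config: ChainConfig, R: float = 10.0):
        self.data = data
        self.identity = identity
        self.model_id = model_id
        self.traps = traps
        self.space = space
        self.cfg = config
        self.R = R
        self.M, self.J, self.K = data.M, data.J, data.K
        self.rng = np.random.default_rng(config.seed)
        self.sexed = is_sexed(model_id)

        params, lat = init_state(data, identity, model_id,
                                 seed=int(self.rng.integers(2 ** 31)),
                                 traps=traps, space=space, R=R)
        if config.init_params is not None:
            params = config.init_params
        if config.init_latents is not None:
            lat = config.init_latents.copy()
        self.params = params
        self.z = lat.z.astype(np.int8).copy()
        self.u = lat.u.astype(np.int8).copy()
        self.S = lat.S.astype(float).copy()
        self.L = lat.L.astype(int).copy()
        self.Linv = invert_permutation(self.L)

        linked2 = {b for _, b in identity.known_links}
        linked_slots = {a for a, _ in identity.known_links}
        self.free_rows = np.array(
            [r for r in range(self.M) if r not in linked2], dtype=int)
        self.free_slots = np.array(
            [t for t in range(self.M) if t not in linked_slots], dtype=int)

        self._recount_all()
        if np.any((self.z == 0) & (self.counts["ydd"] > 0)):
            raise ValueError("initial z inconsistent with detections")
        self.pin = _pins(data, self.L) if self.sexed else None
        if self.sexed:
            self.u = np.where(self.pin >= 0, self.pin, self.u).astype(np.int8)
        self.dist2 = squared_distances(self.S, traps)
        self.det = self._det_full(self.params)
        if not np.all(np.isfinite(self.det[self.z == 1])):
            raise RuntimeError("non-finite log-likelihood at initialization")

        scales = config.proposal_scales
        names = self.update_names = (tuple(config.update_scalars)
                                     if config.update_scalars is not None
                                     else params.names)
        if isinstance(scales, dict):
            self.scales = {n: float(scales.get(n, 0.1)) for n in names}
        else:
            self.scales = {n: float(scales) for n in names}
        self.acc = {n: 0 for n in names}
        self.acc["S"] = 0
        self.acc["L"] = 0
        self.n_prop = {n: 0 for n in self.acc}

    # -- summaries ---------------------------------------------------------
    def _recount_all(self) -> None:
        y2s = reorder_by_permutation(self.data.y2, self.L)
        self.counts = summarize_all(self.data.y1, y2s)
        self.has_det = self.counts["ydd"] > 0

    def _slot_counts(self, t: int, r: int) -> dict:
        """Summaries for slot t when detector-2 row r is assigned to it."""
        both = self.data.y1[t].astype(np.int64) + self.data.y2[r]
        n_ij = (both > 0).sum(axis=1)
        y_ij = both.sum(axis=1)
        return {"ydd": both.sum(), "n_ij": n_ij, "n_dot": n_ij.sum(),
                "y_ij": y_ij}

    def _det_full(self, params: ScalarParams, u: np.ndarray | None = None,
                  dist2: np.ndarray | None = None) -> np.ndarray:
        u = self.u if u is None else u
        dist2 = self.dist2 if dist2 is None else dist2
        sigma_i = params.sigma_of_sex(u)
        return detection_loglik_terms(params, dist2, sigma_i, self.counts,
                                      self.K)

    def _det_rows(self, slots: np.ndarray, counts_rows: dict,
                  u_rows: np.ndarray) -> np.ndarray:
        sigma_i = self.params.sigma_of_sex(u_rows)
        return detection_loglik_terms(self.params, self.dist2[slots], sigma_i,
                                      counts_rows, self.K)

    # -- complete-data log-likelihood --------------------------------------
    def indiv_loglik(self) -> np.ndarray:
        return sex_prior_terms(self.params, self.u) + np.where(
            self.z == 1, self.det, 0.0)

    def loglik(self) -> float:
        return float(self.indiv_loglik().sum())

    def _log_z_prior(self, psi: float) -> float:
        nz = int(self.z.sum())
        return nz * np.log(psi) + (self.M - nz) * np.log1p(-psi)

    # -- update steps ------------------------------------------------------
    def update_scalars(self) -> None:
        vec = transform_params(self.params)
        names = self.params.names
        for name in self.update_names:
            i = names.index(name)
            prop = vec.copy()
            prop[i] += self.rng.normal(0.0, self.scales[name])
            cand = untransform_params(prop, self.model_id, self.R)
            delta = (log_prior(cand, on_transformed_scale=True)
                     - log_prior(self.params, on_transformed_scale=True))
            new_det = None
            if name == "psi":
                delta += (self._log_z_prior(cand.psi)
                          - self._log_z_prior(self.params.psi))
            elif name == "theta":
                delta += float((sex_prior_terms(cand, self.u)
                                - sex_prior_terms(self.params, self.u)).sum())
            else:
                new_det = self._det_full(cand)
                delta += float((self.z * (new_det - self.det)).sum())
            self.n_prop[name] += 1
            if np.log(self.rng.random()) < delta:
                self.params = cand
                vec = prop
                if new_det is not None:
                    self.det = new_det
                self.acc[name] += 1

    def update_activity_centers(self) -> None:
        sp = self.space
        step = self.rng.normal(0.0, self.cfg.s_proposal_scale, (self.M, 2))
        prop = self.S + step
        prop[:, 0] = _reflect(prop[:, 0], sp.x_min, sp.x_max)
        prop[:, 1] = _reflect(prop[:, 1], sp.y_min, sp.y_max)
        off = self.z == 0  # prior refresh: likelihood flat for excluded rows
        n_off = int(off.sum())
        if n_off:
            prop[off, 0] = self.rng.uniform(sp.x_min, sp.x_max, n_off)
            prop[off, 1] = self.rng.uniform(sp.y_min, sp.y_max, n_off)
        dist2_prop = squared_distances(prop, self.traps)
        det_prop = self._det_full(self.params, dist2=dist2_prop)
        logu = np.log(self.rng.random(self.M))
        accept = off | (logu < det_prop - self.det)
        self.S[accept] = prop[accept]
        self.dist2[accept] = dist2_prop[accept]
        self.det[accept] = det_prop[accept]
        self.acc["S"] += int(accept[~off].sum())
        self.n_prop["S"] += int((~off).sum())

    def update_inclusion(self) -> None:
        """Gibbs on z for undetected rows: odds psi*f0 : (1-psi)."""
        ll0 = self._zero_row_loglik()
        p1 = expit(np.log(self.params.psi) - np.log1p(-self.params.psi) + ll0)
        draw = (self.rng.random(self.M) < p1).astype(np.int8)
        self.z = np.where(self.has_det, 1, draw).astype(np.int8)

    def _zero_row_loglik(self) -> np.ndarray:
        """[M] detection factor of an all-zero history at each row's (s,u)."""
        sigma_i = self.params.sigma_of_sex(self.u)
        g = np.exp(-self.dist2 / (2.0 * sigma_i[:, None] ** 2))
        if uses_entry(self.model_id):
            eta = self.params.omega0 * g
            q = (1.0 - eta) + eta * (1.0 - self.params.phi) ** 2
            return self.K * np.log(q).sum(axis=1)
        p = self.params.p0 * g
        return 2 * self.K * np.log1p(-p).sum(axis=1)

    def update_sexes(self) -> None:
        """Gibbs on missing sex indicators (two-point full conditional)."""
        if not self.sexed:
            return
        det_m = self._det_full(self.params, u=np.ones(self.M, dtype=np.int8))
        det_f = self._det_full(self.params, u=np.zeros(self.M, dtype=np.int8))
        lw1 = np.log(self.params.theta) + self.z * det_m
        lw0 = np.log1p(-self.params.theta) + self.z * det_f
        draw = (self.rng.random(self.M) < expit(lw1 - lw0)).astype(np.int8)
        self.u = np.where(self.pin >= 0, self.pin, draw).astype(np.int8)
        self.det = np.where(self.u == 1, det_m, det_f)

    def update_permutation(self, n_proposals: int | None = None) -> None:
        """Swap proposals for the latent identity permutation."""
        if len(self.free_rows) < 2:
            return
        n = n_proposals or self.cfg.n_perm_proposals or self.M
        rows = self.rng.choice(self.free_rows, size=n)
        slots = self.rng.choice(self.free_slots, size=n)
        logus = np.log(self.rng.random(n))
        y2 = self.data.y2
        for r1, t2, logu in zip(rows, slots, logus):
            t1 = self.L[r1]
            if t1 == t2:
                continue
            r2 = self.Linv[t2]
            self.n_prop["L"] += 1
            zero1 = not y2[r1].any()
            zero2 = not y2[r2].any()
            if zero1 and zero2:
                # both detector-2 rows empty: likelihood (and pins) unchanged
                self._apply_swap(r1, r2, t1, t2)
                self.acc["L"] += 1
                continue
            c1 = self._slot_counts(t1, r2)
            c2 = self._slot_counts(t2, r1)
            if (self.z[t1] == 0 and c1["ydd"] > 0) or \
               (self.z[t2] == 0 and c2["ydd"] > 0):
                continue  # detections on an excluded row: density zero
            u_new = self.u.copy()
            if self.sexed:
                ok, u1, u2 = self._swap_pins(r1, r2, t1, t2)
                if not ok:
                    continue
                u_new[t1], u_new[t2] = u1, u2
            tt = np.array([t1, t2])
            cnts = {k: np.stack([c1[k], c2[k]]) for k in
                    ("ydd", "n_ij", "n_dot", "y_ij")}
            det_new = self._det_rows(tt, cnts, u_new[tt])
            old = (self.z[tt] * self.det[tt]
                   + sex_prior_terms(self.params, self.u[tt])).sum()
            new = (self.z[tt] * det_new
                   + sex_prior_terms(self.params, u_new[tt])).sum()
            if logu < new - old:
                self._apply_swap(r1, r2, t1, t2)
                for k in ("ydd", "n_ij", "n_dot", "y_ij"):
                    self.counts[k][tt] = cnts[k]
                self.has_det[tt] = self.counts["ydd"][tt] > 0
                self.det[tt] = det_new
                if self.sexed:
                    self.u[tt] = u_new[tt]
                    self.pin[t1] = _pin_of(self.data, t1, r2)
                    self.pin[t2] = _pin_of(self.data, t2, r1)
                self.acc["L"] += 1

    def _swap_pins(self, r1, r2, t1, t2):
        """Sexes after the swap; False if an assignment conflicts."""
        d = self.data
        p1 = _pin_of(d, t1, r2)
        p2 = _pin_of(d, t2, r1)
        if p1 == -2 or p2 == -2:
            return False, 0, 0
        u1 = p1 if p1 >= 0 else self.u[t1]
        u2 = p2 if p2 >= 0 else self.u[t2]
        return True, u1, u2

    def _apply_swap(self, r1, r2, t1, t2) -> None:
        self.L[r1], self.L[r2] = t2, t1
        self.Linv[t1], self.Linv[t2] = r2, r1

    # -- driver ------------------------------------------------------------
    def sweep(self) -> None:
        if self.update_names:
            self.update_scalars()
        if self.cfg.update_s:
            self.update_activity_centers()
        if self.cfg.update_z:
            self.update_inclusion()
        if self.cfg.update_u:
            self.update_sexes()
        if self.cfg.update_l:
            self.update_permutation()

    def adapt_scales(self, window_acc: dict, window_n: dict) -> None:
        for name in self.update_names:
            n = window_n.get(name, 0)
            if n:
                rate = window_acc[name] / n
                self.scales[name] *= np.exp(0.5 * (rate - 0.3))


def _pin_of(data: BilateralData, t: int, r: int) -> int:
    """Observed sex of slot t with detector-2 row r assigned (-2 conflict)."""
    s1 = data.sex1[t]
    s2 = data.sex2[r]
    if s1 != SEX_UNKNOWN and s2 != SEX_UNKNOWN and s1 != s2:
        return -2
    return s1 if s1 != SEX_UNKNOWN else s2


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold a random-walk step back into [lo, hi] (symmetric proposal)."""
    width = hi - lo
    y = np.mod(x - lo, 2 * width)
    y = np.where(y > width, 2 * width - y, y)
    return lo + y


def update_identity_permutation(state: LatentState, data: BilateralData,
                                params: ScalarParams, rng_or_seed,
                                identity: IdentityInfo, traps: TrapArray,
                                space: StateSpace,
                                n_proposals: int | None = None) -> LatentState:
    """One sweep of identity-permutation swap updates on a latent state."""
    seed = (rng_or_seed if isinstance(rng_or_seed, (int, np.integer))
            else int(rng_or_seed.integers(2 ** 31)))
    cfg = ChainConfig(n_iter=2, burn_in=0, seed=seed, update_scalars=(),
                      update_s=False, update_z=False, update_u=False,
                      init_params=params, init_latents=state)
    smp = _Sampler(data, identity, params.model_id, traps, space, cfg,
                   R=params.R)
    smp.update_permutation(n_proposals)
    return LatentState(z=smp.z, u=smp.u, S=smp.S, L=smp.L)


def run_chain(data: BilateralData, identity: IdentityInfo, model_id: str,
              config: ChainConfig, traps: TrapArray, space: StateSpace,
              R: float = 10.0) -> PosteriorDraws:
    """Run one chain and return retained draws (after burn-in and thinning)."""
    smp = _Sampler(data, identity, model_id, traps, space, config, R=R)
    n_ret = (config.n_iter - config.burn_in + config.thin - 1) // config.thin
    p = len(smp.params.names)
    out_params = np.empty((n_ret, p))
    out_trans = np.empty((n_ret, p))
    out_ll = np.empty(n_ret)
    out_indiv = np.empty((n_ret, smp.M))
    out_N = np.empty(n_ret, dtype=int)
    out_L = np.empty((n_ret, smp.M), dtype=np.int32)
    lat: dict = {"z": [], "u": [], "S": [], "L": [], "draw_index": []}

    window_acc = {n: 0 for n in smp.acc}
    window_n = {n: 0 for n in smp.n_prop}
    d = 0
    for it in range(config.n_iter):
        smp.sweep()
        if config.adapt and it < config.burn_in and (it + 1) % 50 == 0:
            cur_acc = {n: smp.acc[n] - window_acc[n] for n in smp.acc}
            cur_n = {n: smp.n_prop[n] - window_n[n] for n in smp.n_prop}
            smp.adapt_scales(cur_acc, cur_n)
            window_acc = dict(smp.acc)
            window_n = dict(smp.n_prop)
        if it < config.burn_in or (it - config.burn_in) % config.thin:
            continue
        out_params[d] = smp.params.to_vector()
        out_trans[d] = transform_params(smp.params)
        indiv = smp.indiv_loglik()
        out_indiv[d] = indiv
        out_ll[d] = indiv.sum()
        out_N[d] = int(smp.z.sum())
        out_L[d] = smp.L
        if config.store_latents and d % config.latent_thin == 0:
            lat["z"].append(smp.z.copy())
            lat["u"].append(smp.u.copy())
            lat["S"].append(smp.S.copy())
            lat["L"].append(smp.L.copy())
            lat["draw_index"].append(d)
        d += 1

    latents = {k: np.asarray(v) for k, v in lat.items()}
    rates = {n: (smp.acc[n] / smp.n_prop[n] if smp.n_prop[n] else np.nan)
             for n in smp.acc}
    return PosteriorDraws(model_id=model_id, param_names=smp.params.names,
                          params=out_params[:d], transformed=out_trans[:d],
                          loglik=out_ll[:d], indiv_loglik=out_indiv[:d],
                          N=out_N[:d], latents=latents, R=R,
                          seed=config.seed, accept_rates=rates,
                          L_draws=out_L[:d])
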