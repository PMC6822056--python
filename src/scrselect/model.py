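"""Model / Results front end for partial-identity SCR fits.

``PartialIdentitySCR`` bundles one data set (bilateral histories, identity
links, traps, state space) with one of the four competing likelihoods;
``fit()`` runs the posterior sampler and returns ``SCRResults``, which
carries the draws and exposes posterior summaries and every model-selection
criterion.

Example
-------
>>> from scrselect import PartialIdentitySCR
>>> from scrselect.evaluation import scaled_down_design
>>> from scrselect.simulator import simulate_dataset
>>> d = scaled_down_design()
>>> data, identity, truth = simulate_dataset(d.scenario, d.traps, d.space, 7)
>>> model = PartialIdentitySCR(data, identity, d.traps, d.space, model="M1")
>>> res = model.fit(n_iter=2000, burn_in=500, seed=1)
>>> print(res.summary())                            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .capture_data import (BilateralData, IdentityInfo, StateSpace,
                           TrapArray, load_capture_files)
from .likelihoods import (LatentState, ScalarParams, complete_data_loglik,
                          individual_loglik, integrated_loglik)
from .mcmc import ChainConfig, PosteriorDraws, run_chain
from .model_selection import (MapEstimate, all_criteria, dic,
                              log_marginal_gd_il, log_marginal_gd_map,
                              log_marginal_hm, map_search,
                              posterior_predictive_loss, waic)


class PartialIdentitySCR:
    """One competing SCR model bound to one bilateral data set."""

    def __init__(self, data: BilateralData, identity: IdentityInfo,
                 traps: TrapArray, state_space: StateSpace,
                 model: str = "M1", R: float = 10.0):
        self.data = data
        self.identity = identity
        self.traps = traps
        self.space = state_space
        self.model_id = model
        self.R = R

    @classmethod
    def from_files(cls, captures_csv, traps_csv, K: int, M: int,
                   state_space: StateSpace, identities_csv=None,
                   model: str = "M1", R: float = 10.0) -> "PartialIdentitySCR":
        data, identity, traps = load_capture_files(
            captures_csv, traps_csv, K=K, M=M, identities_csv=identities_csv)
        return cls(data, identity, traps, state_space, model=model, R=R)

    # -- likelihood surface -------------------------------------------------
    def loglike(self, params: ScalarParams, latents: LatentState) -> float:
        """Complete-data log-likelihood at given parameters and latents."""
        return complete_data_loglik(self.data, params, latents, self.traps)

    def loglike_individual(self, i: int, params, latents) -> float:
        return individual_loglik(i, self.data, params, latents, self.traps)

    def integrated_loglike(self, params: ScalarParams, L: np.ndarray,
                           grid_resolution=(50, 70)) -> float:
        """Likelihood with z and missing sexes summed out and activity
        centers integrated over a Riemann grid, at a fixed permutation."""
        return integrated_loglik(self.data, params, L, self.traps, self.space,
                                 grid_resolution=grid_resolution)

    # -- fitting ------------------------------------------------------------
    def fit(self, config: ChainConfig | None = None, **kwargs) -> "SCRResults":
        """Run the Metropolis-within-Gibbs sampler.

        Keyword arguments (n_iter, burn_in, seed, ...) override fields of
        ``config`` (or of the default ``ChainConfig``).
        """
        cfg = config if config is not None else ChainConfig()
        if kwargs:
            cfg = replace(cfg, **kwargs)
        draws = run_chain(self.data, self.identity, self.model_id, cfg,
                          self.traps, self.space, R=self.R)
        return SCRResults(self, draws)


class SCRResults:
    """Posterior draws of one fit plus criteria computed on demand."""

    def __init__(self, model: PartialIdentitySCR, draws: PosteriorDraws):
        self.model = model
        self.draws = draws
        self._map_estimate: MapEstimate | None = None

    # -- summaries ----------------------------------------------------------
    @property
    def N(self) -> np.ndarray:
        """Per-draw population size sum(z)."""
        return self.draws.N

    def posterior_table(self) -> pd.DataFrame:
        rows = []
        mat = np.column_stack([self.draws.params,
                               self.draws.N.astype(float)])
        names = list(self.draws.param_names) + ["N"]
        for name, col in zip(names, mat.T):
            q = np.percentile(col, [2.5, 50, 97.5])
            rows.append({"parameter": name, "mean": col.mean(),
                         "sd": col.std(ddof=1), "q2.5": q[0],
                         "median": q[1], "q97.5": q[2]})
        return pd.DataFrame(rows).set_index("parameter")

    def summary(self) -> str:
        tab = self.posterior_table()
        lines = [
            f"Partial-identity SCR fit: model {self.draws.model_id}",
            f"retained draws: {self.draws.n_retained}   "
            f"M = {self.model.data.M}   J = {self.model.data.J}   "
            f"K = {self.model.data.K}",
            "",
            tab.to_string(float_format=lambda v: f"{v:10.4f}"),
        ]
        return "\n".join(lines)

    # -- MAP / criteria -----------------------------------------------------
    def map_estimate(self) -> MapEstimate:
        if self._map_estimate is None:
            self._map_estimate = map_search(self.draws, self.model.data,
                                            self.model.traps,
                                            self.model.space)
        return self._map_estimate

    def log_marginal(self, method: str = "gd_map", tuning: str = "mvnormal",
                     df=None, conf=None, grid_resolution=(50, 70),
                     draw_stride: int = 1):
        m = self.model
        if method == "gd_map":
            return log_marginal_gd_map(self.draws, m.data, m.traps, m.space,
                                       tuning=tuning, df=df, conf=conf,
                                       map_estimate=self.map_estimate())
        if method == "gd_il":
            return log_marginal_gd_il(self.draws, m.data, m.traps, m.space,
                                      tuning=tuning, df=df, conf=conf,
                                      grid_resolution=grid_resolution,
                                      draw_stride=draw_stride)
        if method == "hm":
            res = log_marginal_hm(self.draws.loglik)
            res.model_id = self.draws.model_id
            return res
        raise ValueError(f"unknown evidence method {method!r}")

    def dic(self, variant: int = 1):
        return dic(self.draws.loglik, self.map_estimate().loglik,
                   variant=variant, model_id=self.draws.model_id)

    def waic(self, variant: int = 1):
        return waic(self.draws.indiv_loglik, variant=variant,
                    model_id=self.draws.model_id)

    def posterior_predictive_loss(self, n_rep_per_draw: int = 1,
                                  seed: int = 0):
        m = self.model
        return posterior_predictive_loss(self.draws, m.data, m.traps,
                                         m.space,
                                         n_rep_per_draw=n_rep_per_draw,
                                         seed=seed)

    def criteria(self, grid_resolution=(50, 70), il_draw_stride: int = 20,
                 include_gd_il: bool = True, ppl_seed: int = 0
                 ) -> pd.DataFrame:
        """All criterion variants as a tidy table."""
        m = self.model
        return all_criteria(self.draws, m.data, m.traps, m.space,
                            grid_resolution=grid_resolution,
                            il_draw_stride=il_draw_stride,
                            include_gd_il=include_gd_il, ppl_seed=ppl_seed)
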