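"""Generate bilateral capture-recapture data under the entry-detection model.

The default design reproduces the simulation study layout: a 5 x 7 state
space with a 1-unit buffer, a 10 x 16 trap grid (J = 160, spacing 0.3 on X and
0.3125 on Y), K = 50 occasions, N = 100 individuals of which 40 are male, and
augmentation bound M = 400, across 12 scenarios of (omega0, phi, sigma_m,
sigma_f).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .capture_data import (SEX_UNKNOWN, BilateralData, IdentityInfo,
                           StateSpace, TrapArray)
from .likelihoods import trap_entry_prob, detection_prob_royle


@dataclass(frozen=True)
class Scenario:
    """Data-generating parameters for one simulation scenario."""

    omega0: float
    phi: float
    sigma_m: float
    sigma_f: float
    N: int = 100
    N_male: int = 40
    M: int = 400
    K: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.omega0 < 1 and 0 < self.phi < 1):
            raise ValueError("probabilities must lie in (0,1)")
        if self.sigma_m <= 0 or self.sigma_f <= 0:
            raise ValueError("movement scales must be positive")
        if not (0 <= self.N_male <= self.N <= self.M):
            raise ValueError("need 0 <= N_male <= N <= M")


@dataclass
class TruthRecord:
    """Ground truth retained by the simulator but hidden from the model."""

    S_true: np.ndarray       # [N, 2]
    u_true: np.ndarray       # [N] sex indicators, 1 = male
    link1: np.ndarray        # detector-1 observed row -> true individual
    link2: np.ndarray        # detector-2 observed row -> true individual
    params_true: Scenario
    model_id: str = "M1"


#: (omega0, phi, sigma_m, sigma_f) for the 12 scenarios
_SCENARIOS = {
    1: (0.01, 0.3, 0.3, 0.15),
    2: (0.01, 0.9, 0.3, 0.15),
    3: (0.01, 0.3, 0.4, 0.20),
    4: (0.01, 0.9, 0.4, 0.20),
    5: (0.03, 0.8, 0.3, 0.15),
    6: (0.03, 0.8, 0.4, 0.20),
    7: (0.05, 0.3, 0.3, 0.15),
    8: (0.05, 0.5, 0.3, 0.15),
    9: (0.05, 0.9, 0.3, 0.15),
    10: (0.05, 0.3, 0.4, 0.20),
    11: (0.05, 0.5, 0.4, 0.20),
    12: (0.05, 0.9, 0.4, 0.20),
}


def scenario_params(scenario_id: int) -> Scenario:
    """Parameters of one of the 12 study scenarios."""
    if scenario_id not in _SCENARIOS:
        raise ValueError(f"unknown scenario id {scenario_id}; expected 1..12")
    omega0, phi, sm, sf = _SCENARIOS[scenario_id]
    return Scenario(omega0=omega0, phi=phi, sigma_m=sm, sigma_f=sf)


def default_state_space() -> StateSpace:
    return StateSpace(0.0, 5.0, 0.0, 7.0, buffer=1.0)


def build_trap_grid(nx: int, ny: int, space: StateSpace,
                    buffer: float | None = None) -> TrapArray:
    """Regular nx-by-ny trap grid inside the buffered state space.

    Traps sit at the cell centers of an nx-by-ny partition of the buffered
    interior, so the spacing is (extent - 2*buffer)/n on each axis (0.3 and
    0.3125 for the default 10 x 16 design).
    """
    if nx < 1 or ny < 1:
        raise ValueError("grid dimensions must be >= 1")
    b = space.buffer if buffer is None else buffer
    wx = space.x_max - space.x_min - 2 * b
    wy = space.y_max - space.y_min - 2 * b
    if wx <= 0 or wy <= 0:
        raise ValueError("buffer too large for the state space")
    xs = space.x_min + b + wx * (np.arange(nx) + 0.5) / nx
    ys = space.y_min + b + wy * (np.arange(ny) + 0.5) / ny
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    coords = np.column_stack([gx.ravel(), gy.ravel()])
    return TrapArray(coordinates=coords, trap_ids=np.arange(1, nx * ny + 1))


def default_trap_grid() -> TrapArray:
    return build_trap_grid(10, 16, default_state_space())


def simulate_full_histories(scenario: Scenario, traps: TrapArray,
                            space: StateSpace, rng: np.random.Generator,
                            model_id: str = "M1"):
    """Latent per-individual paired histories [N, J, K] plus truth draws."""
    N, K = scenario.N, scenario.K
    S = np.column_stack([
        rng.uniform(space.x_min, space.x_max, N),
        rng.uniform(space.y_min, space.y_max, N),
    ])
    u = np.zeros(N, dtype=np.int8)
    u[rng.permutation(N)[:scenario.N_male]] = 1
    sigma_i = np.where(u == 1, scenario.sigma_m, scenario.sigma_f)
    diff = S[:, None, :] - traps.coordinates[None, :, :]
    dist = np.sqrt(np.einsum("njd,njd->nj", diff, diff))
    if model_id in ("M1", "M3"):
        # entry first, then two conditionally independent detections
        eta = trap_entry_prob(scenario.omega0, 1.0, dist / sigma_i[:, None])
        entered = rng.random((N, traps.J, K)) < eta[:, :, None]
        y1 = entered & (rng.random((N, traps.J, K)) < scenario.phi)
        y2 = entered & (rng.random((N, traps.J, K)) < scenario.phi)
    elif model_id in ("M2", "M4"):
        # direct Bernoulli detections; scenario.phi plays the role of p0
        p = detection_prob_royle(scenario.phi, 1.0, dist / sigma_i[:, None])
        y1 = rng.random((N, traps.J, K)) < p[:, :, None]
        y2 = rng.random((N, traps.J, K)) < p[:, :, None]
    else:
        raise ValueError(f"unknown model {model_id!r}")
    return y1.astype(np.uint8), y2.astype(np.uint8), S, u


def split_observed(y1_full: np.ndarray, y2_full: np.ndarray,
                   u_true: np.ndarray, M: int,
                   rng: np.random.Generator,
                   reveal_sex: bool = True):
    """Split latent histories into the observed bilateral data set.

    Individuals with at least one simultaneous (both-detector, same trap and
    occasion) capture are fully identified; all others contribute separate,
    unlinked detector-1-only and detector-2-only rows.  All-zero individuals
    are dropped.  Detector-2 observed rows are shuffled so that row order
    carries no identity information.
    """
    N = y1_full.shape[0]
    cap1 = y1_full.reshape(N, -1).any(axis=1)
    cap2 = y2_full.reshape(N, -1).any(axis=1)
    simul = (y1_full & y2_full).reshape(N, -1).any(axis=1)

    rows1 = np.flatnonzero(cap1)
    rows2_true = np.flatnonzero(cap2)
    rows2 = rows2_true[rng.permutation(len(rows2_true))]

    n1, n2 = len(rows1), len(rows2)
    if M < max(n1, n2):
        raise ValueError("augmentation bound M too small for simulated capture count")
    J, K = y1_full.shape[1], y1_full.shape[2]
    y1 = np.zeros((M, J, K), dtype=np.uint8)
    y2 = np.zeros((M, J, K), dtype=np.uint8)
    y1[:n1] = y1_full[rows1]
    y2[:n2] = y2_full[rows2]

    sex1 = np.full(M, SEX_UNKNOWN, dtype=np.int8)
    sex2 = np.full(M, SEX_UNKNOWN, dtype=np.int8)
    if reveal_sex:
        sex1[:n1] = u_true[rows1]
        sex2[:n2] = u_true[rows2]

    idx1 = {t: r for r, t in enumerate(rows1)}
    idx2 = {t: r for r, t in enumerate(rows2)}
    links = sorted((idx1[t], idx2[t]) for t in np.flatnonzero(simul))
    linked1 = {a for a, _ in links}
    linked2 = {b for _, b in links}

    data = BilateralData(y1=y1, y2=y2, K=K, M=M, n_obs1=n1, n_obs2=n2,
                         sex1=sex1, sex2=sex2)
    identity = IdentityInfo(
        known_links=links,
        free1=np.array(sorted(set(range(n1)) - linked1), dtype=int),
        free2=np.array(sorted(set(range(n2)) - linked2), dtype=int),
    )
    return data, identity, rows1, rows2


def simulate_dataset(scenario: Scenario, traps: TrapArray, space: StateSpace,
                     seed: int, model_id: str = "M1", reveal_sex: bool = True,
                     ) -> tuple[BilateralData, IdentityInfo, TruthRecord]:
    """Simulate one bilateral data set under the given scenario and model."""
    rng = np.random.default_rng(seed)
    y1f, y2f, S, u = simulate_full_histories(scenario, traps, space, rng,
                                             model_id=model_id)
    data, identity, rows1, rows2 = split_observed(
        y1f, y2f, u, scenario.M, rng, reveal_sex=reveal_sex)
    truth = TruthRecord(S_true=S, u_true=u, link1=rows1, link2=rows2,
                        params_true=scenario, model_id=model_id)
    return data, identity, truth


# ---------------------------------------------------------------------------
# CSV export (round-trips through capture_data.load_capture_data)

def write_dataset(out_dir, data: BilateralData, identity: IdentityInfo,
                  traps: TrapArray, truth: TruthRecord | None = None) -> None:
    """Write traps.csv, captures.csv, identities.csv (and truth.json).

    Linked detector-1/2 rows share one individual id; partial rows get
    side-specific ids so that no identity information leaks through labels.
    Events at a (trap, occasion) where both detectors fired for a linked pair
    are flagged simultaneous.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traps.to_table().to_csv(out / "traps.csv", index=False)

    link12 = dict(identity.known_links)
    link21 = {b: a for a, b in identity.known_links}
    sex_label = {1: "m", 0: "f", SEX_UNKNOWN: ""}

    def ident1(r):
        return f"ind{r + 1:04d}"

    def ident2(r):
        return ident1(link21[r]) if r in link21 else f"d2_{r + 1:04d}"

    rows = []
    for r in range(data.n_obs1):
        partner = link12.get(r)
        for j, k in zip(*np.nonzero(data.y1[r])):
            simul = int(partner is not None and data.y2[partner, j, k] == 1)
            rows.append((ident1(r), 1, j + 1, k + 1, simul,
                         sex_label[int(data.sex1[r])]))
    for r in range(data.n_obs2):
        partner = link21.get(r)
        for j, k in zip(*np.nonzero(data.y2[r])):
            simul = int(partner is not None and data.y1[partner, j, k] == 1)
            rows.append((ident2(r), 2, j + 1, k + 1, simul,
                         sex_label[int(data.sex2[r])]))
    pd.DataFrame(rows, columns=["individual_id", "detector", "trap_id",
                                "occasion", "simultaneous", "sex"]
                 ).to_csv(out / "captures.csv", index=False)

    pd.DataFrame([(ident1(a), ident2(b)) for a, b in identity.known_links],
                 columns=["detector1_id", "detector2_id"]
                 ).to_csv(out / "identities.csv", index=False)

    if truth is not None:
        payload = {
            "scenario": asdict(truth.params_true),
            "model_id": truth.model_id,
            "N": int(truth.params_true.N),
            "S_true": truth.S_true.tolist(),
            "u_true": truth.u_true.tolist(),
            "link1": np.asarray(truth.link1).tolist(),
            "link2": np.asarray(truth.link2).tolist(),
        }
        (out / "truth.json").write_text(json.dumps(payload, indent=1))
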