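"""Data model and I/O for bilateral spatial capture-recapture histories.

A camera-trap station carries two detectors (one per flank).  Each detector
yields a binary history per observed individual over ``J`` traps and ``K``
occasions.  An individual photographed by both detectors *simultaneously* at
least once is fully identified (its two flank histories are linked); otherwise
the correspondence between detector-1 and detector-2 histories is a latent
permutation to be estimated.

Files are 1-based (trap ids, occasions); in-memory arrays are 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Input table violates the expected layout or value ranges."""


class CapacityError(ValueError):
    """Augmented size M is too small for the observed individuals."""


class IdentityConflictError(ValueError):
    """Identity links are not a partial injective map."""


SEX_UNKNOWN = -1
SEX_FEMALE = 0
SEX_MALE = 1

_SEX_CODES = {"m": SEX_MALE, "male": SEX_MALE, "1": SEX_MALE,
              "f": SEX_FEMALE, "female": SEX_FEMALE, "0": SEX_FEMALE}


@dataclass(frozen=True)
class StateSpace:
    """Rectangular state space V with an optional habitat buffer."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    buffer: float = 0.0

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("state space rectangle is degenerate")
        if self.buffer < 0:
            raise ValueError("buffer must be nonnegative")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    @property
    def extent(self) -> tuple[float, float]:
        return (self.x_max - self.x_min, self.y_max - self.y_min)

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        return ((pts[:, 0] >= self.x_min) & (pts[:, 0] <= self.x_max)
                & (pts[:, 1] >= self.y_min) & (pts[:, 1] <= self.y_max))


@dataclass(frozen=True)
class TrapArray:
    """J trap stations (paired detectors) with 1-based labels."""

    coordinates: np.ndarray  # [J, 2]
    trap_ids: np.ndarray     # [J] ints, unique

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        ids = np.asarray(self.trap_ids, dtype=int)
        if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 1:
            raise ValueError("coordinates must be a [J, 2] array with J >= 1")
        if len(np.unique(ids)) != len(ids):
            raise FormatError("trap ids must be unique")
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "trap_ids", ids)

    @property
    def J(self) -> int:
        return self.coordinates.shape[0]

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "TrapArray":
        for col in ("trap_id", "x", "y"):
            if col not in table.columns:
                raise FormatError(f"trap table lacks column {col!r}")
        return cls(table[["x", "y"]].to_numpy(float),
                   table["trap_id"].to_numpy(int))

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame({"trap_id": self.trap_ids,
                             "x": self.coordinates[:, 0],
                             "y": self.coordinates[:, 1]})


@dataclass
class BilateralData:
    """Zero-augmented paired binary detection arrays.

    ``y1``/``y2`` have shape [M, J, K]; rows beyond the observed individuals on
    each side are all-zero.  ``sex1``/``sex2`` carry per-row observed sex
    (-1 unknown) for detector-1 and detector-2 rows respectively.
    """

    y1: np.ndarray
    y2: np.ndarray
    K: int
    M: int
    n_obs1: int
    n_obs2: int
    sex1: np.ndarray = field(default=None)
    sex2: np.ndarray = field(default=None)
    row_ids1: list = field(default=None)
    row_ids2: list = field(default=None)

    def __post_init__(self) -> None:
        self.y1 = np.asarray(self.y1, dtype=np.uint8)
        self.y2 = np.asarray(self.y2, dtype=np.uint8)
        if self.y1.shape != self.y2.shape or self.y1.ndim != 3:
            raise ValueError("y1 and y2 must share shape [M, J, K]")
        M, J, K = self.y1.shape
        if M != self.M or K != self.K:
            raise ValueError("array shape inconsistent with M, K")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        for arr, n in ((self.y1, self.n_obs1), (self.y2, self.n_obs2)):
            if np.any(arr > 1):
                raise ValueError("detection entries must be binary")
            if np.any(arr[n:]):
                raise ValueError("augmented rows must be all-zero")
        if self.M < max(self.n_obs1, self.n_obs2):
            raise CapacityError("M smaller than observed individual count")
        if self.sex1 is None:
            self.sex1 = np.full(self.M, SEX_UNKNOWN, dtype=np.int8)
        if self.sex2 is None:
            self.sex2 = np.full(self.M, SEX_UNKNOWN, dtype=np.int8)
        self.sex1 = np.asarray(self.sex1, dtype=np.int8)
        self.sex2 = np.asarray(self.sex2, dtype=np.int8)

    @property
    def J(self) -> int:
        return self.y1.shape[1]


@dataclass
class IdentityInfo:
    """Known links between detector-1 and detector-2 rows, and free rows.

    ``known_links`` is a partial injective map: each row index appears in at
    most one link.  ``free1``/``free2`` are the *observed* rows on each side
    that remain unlinked (partial identities).
    """

    known_links: list  # [(row1, row2), ...]
    free1: np.ndarray
    free2: np.ndarray

    def __post_init__(self) -> None:
        r1 = [a for a, _ in self.known_links]
        r2 = [b for _, b in self.known_links]
        if len(set(r1)) != len(r1) or len(set(r2)) != len(r2):
            raise IdentityConflictError("a row is claimed by two links")
        self.free1 = np.asarray(sorted(set(int(i) for i in self.free1) - set(r1)), dtype=int)
        self.free2 = np.asarray(sorted(set(int(i) for i in self.free2) - set(r2)), dtype=int)


@dataclass(frozen=True)
class SummaryCounts:
    """Per-individual detection summaries used by the model likelihoods."""

    y1_total: int
    y2_total: int
    y_dotdot: int
    n_ij: np.ndarray   # [J] occasions with >= 1 detection at trap j
    n_dot: int
    y_ij_dot: np.ndarray  # [J] combined per-trap detection totals


def summarize_individual(y1_row: np.ndarray, y2_row: np.ndarray) -> SummaryCounts:
    """Detection summaries for one individual's paired [J, K] histories."""
    y1_row = np.asarray(y1_row)
    y2_row = np.asarray(y2_row)
    if y1_row.shape != y2_row.shape or y1_row.ndim != 2:
        raise ValueError("rows must be [J, K] arrays of equal shape")
    both = y1_row.astype(np.int64) + y2_row.astype(np.int64)
    n_ij = (both > 0).sum(axis=1)
    y_ij = both.sum(axis=1)
    return SummaryCounts(
        y1_total=int(y1_row.sum()),
        y2_total=int(y2_row.sum()),
        y_dotdot=int(both.sum()),
        n_ij=n_ij,
        n_dot=int(n_ij.sum()),
        y_ij_dot=y_ij,
    )


def summarize_all(y1: np.ndarray, y2_star: np.ndarray) -> dict:
    """Vectorized per-row summaries for aligned arrays (after reordering)."""
    both = y1.astype(np.int64) + y2_star.astype(np.int64)
    n_ij = (both > 0).sum(axis=2)
    y_ij = both.sum(axis=2)
    return {
        "ydd": both.sum(axis=(1, 2)),
        "n_ij": n_ij,
        "n_dot": n_ij.sum(axis=1),
        "y_ij": y_ij,
    }


def reorder_by_permutation(y2: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Reorder detector-2 rows into true-individual order.

    ``L[i]`` is the true index of detector-2 row ``i``; the output ``Y2*``
    satisfies ``Y2*[L[i]] = Y2[i]``.
    """
    L = np.asarray(L, dtype=int)
    M = y2.shape[0]
    if L.shape != (M,) or not np.array_equal(np.sort(L), np.arange(M)):
        raise ValueError("L must be a bijection on 0..M-1")
    out = np.empty_like(y2)
    out[L] = y2
    return out


def invert_permutation(L: np.ndarray) -> np.ndarray:
    L = np.asarray(L, dtype=int)
    inv = np.empty_like(L)
    inv[L] = np.arange(L.size)
    return inv


def find_full_identities(y1_obs: np.ndarray, y2_obs: np.ndarray,
                         sim1: set, sim2: set) -> IdentityInfo:
    """Derive known links from verified simultaneous captures.

    ``sim1``/``sim2`` contain (row, trap, occasion) triples (0-based) flagged
    as verified-simultaneous on each side.  A flagged detector-1 event and a
    flagged detector-2 event at the same (trap, occasion) identify one
    individual; full identity requires such metadata (e.g. capture times).
    """
    n1 = y1_obs.shape[0]
    n2 = y2_obs.shape[0]
    for (r, j, k) in sim1:
        if not y1_obs[r, j, k]:
            raise FormatError("simultaneity flag without a detector-1 detection")
    for (r, j, k) in sim2:
        if not y2_obs[r, j, k]:
            raise FormatError("simultaneity flag without a detector-2 detection")
    by_jk1: dict = {}
    by_jk2: dict = {}
    for (r, j, k) in sim1:
        by_jk1.setdefault((j, k), []).append(r)
    for (r, j, k) in sim2:
        by_jk2.setdefault((j, k), []).append(r)
    link1: dict = {}
    link2: dict = {}
    for jk, rows1 in by_jk1.items():
        rows2 = by_jk2.get(jk, [])
        if not rows2:
            continue
        if len(rows1) > 1 or len(rows2) > 1:
            raise IdentityConflictError(
                f"ambiguous simultaneous captures at trap/occasion {jk}")
        a, b = rows1[0], rows2[0]
        if link1.get(a, b) != b or link2.get(b, a) != a:
            raise IdentityConflictError("a row is linked to two partners")
        link1[a] = b
        link2[b] = a
    links = sorted(link1.items())
    return IdentityInfo(
        known_links=links,
        free1=np.setdiff1d(np.arange(n1), list(link1)),
        free2=np.setdiff1d(np.arange(n2), list(link2)),
    )


def _parse_sex(val) -> int:
    if pd.isna(val) or str(val).strip() == "":
        return SEX_UNKNOWN
    code = _SEX_CODES.get(str(val).strip().lower())
    if code is None:
        raise FormatError(f"unrecognized sex label {val!r}")
    return code


def load_capture_data(capture_events: pd.DataFrame, trap_table: pd.DataFrame,
                      K: int, M: int,
                      identities: pd.DataFrame | None = None,
                      ) -> tuple[BilateralData, IdentityInfo, TrapArray]:
    """Build zero-augmented arrays from event records.

    ``capture_events`` columns: individual_id, detector (1/2), trap_id,
    occasion (1..K), simultaneous (0/1) and optionally sex (m/f).  Known links
    come from (a) the same individual_id appearing on both detectors, and
    (b) the optional ``identities`` table (detector1_id, detector2_id).
    Duplicate events collapse to a single binary detection with a warning.
    """
    traps = TrapArray.from_table(trap_table)
    ev = capture_events.copy()
    required = {"individual_id", "detector", "trap_id", "occasion", "simultaneous"}
    missing = required - set(ev.columns)
    if missing:
        raise FormatError(f"capture table lacks columns {sorted(missing)}")
    trap_index = {int(t): j for j, t in enumerate(traps.trap_ids)}
    J = traps.J

    if len(ev):
        if not ev["detector"].isin([1, 2]).all():
            raise FormatError("detector must be 1 or 2")
        if not ev["occasion"].between(1, K).all():
            raise FormatError("occasion out of range 1..K")
        if not ev["trap_id"].astype(int).isin(trap_index).all():
            raise FormatError("event references unknown trap_id")
        dup = ev.duplicated(subset=["individual_id", "detector", "trap_id", "occasion"])
        if dup.any():
            warnings.warn(f"collapsed {int(dup.sum())} duplicate event row(s)",
                          stacklevel=2)
            ev = ev[~dup]

    ids1 = list(dict.fromkeys(ev.loc[ev["detector"] == 1, "individual_id"]))
    ids2 = list(dict.fromkeys(ev.loc[ev["detector"] == 2, "individual_id"]))
    if M < max(len(ids1), len(ids2), 1):
        raise CapacityError(
            f"M={M} is smaller than the number of observed individuals")
    row1 = {ident: r for r, ident in enumerate(ids1)}
    row2 = {ident: r for r, ident in enumerate(ids2)}

    y1 = np.zeros((M, J, K), dtype=np.uint8)
    y2 = np.zeros((M, J, K), dtype=np.uint8)
    sex1 = np.full(M, SEX_UNKNOWN, dtype=np.int8)
    sex2 = np.full(M, SEX_UNKNOWN, dtype=np.int8)
    has_sex = "sex" in ev.columns
    for rec in ev.itertuples(index=False):
        j = trap_index[int(rec.trap_id)]
        k = int(rec.occasion) - 1
        if rec.detector == 1:
            r = row1[rec.individual_id]
            y1[r, j, k] = 1
            target = (sex1, r)
        else:
            r = row2[rec.individual_id]
            y2[r, j, k] = 1
            target = (sex2, r)
        if has_sex:
            s = _parse_sex(rec.sex)
            if s != SEX_UNKNOWN:
                arr, r_ = target
                if arr[r_] not in (SEX_UNKNOWN, s):
                    raise FormatError(
                        f"conflicting sex labels for individual {rec.individual_id!r}")
                arr[r_] = s

    links: dict[int, int] = {}
    shared = set(ids1) & set(ids2)
    for ident in shared:
        links[row1[ident]] = row2[ident]
    if identities is not None and len(identities):
        for rec in identities.itertuples(index=False):
            a = row1.get(rec.detector1_id)
            b = row2.get(rec.detector2_id)
            if a is None or b is None:
                raise FormatError("identities table references unknown individual")
            if links.get(a, b) != b or b in {v for k, v in links.items() if k != a}:
                raise IdentityConflictError("conflicting identity links")
            links[a] = b
    # linked pairs share one individual: detector-1 row carries the sex
    for a, b in links.items():
        if sex1[a] == SEX_UNKNOWN:
            sex1[a] = sex2[b]
        elif sex2[b] not in (SEX_UNKNOWN, sex1[a]):
            raise FormatError("linked rows carry conflicting sex labels")

    data = BilateralData(y1=y1, y2=y2, K=K, M=M,
                         n_obs1=len(ids1), n_obs2=len(ids2),
                         sex1=sex1, sex2=sex2,
                         row_ids1=ids1, row_ids2=ids2)
    identity = IdentityInfo(
        known_links=sorted(links.items()),
        free1=np.setdiff1d(np.arange(len(ids1)), list(links)),
        free2=np.setdiff1d(np.arange(len(ids2)), list(links.values())),
    )
    return data, identity, traps


def load_capture_files(captures_csv, traps_csv, K: int, M: int,
                       identities_csv=None):
    """Read the CSV trio (captures, traps, optional identities)."""
    events = pd.read_csv(captures_csv)
    traps = pd.read_csv(traps_csv)
    idents = pd.read_csv(identities_csv) if identities_csv is not None else None
    return load_capture_data(events, traps, K=K, M=M, identities=idents)
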