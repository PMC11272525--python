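"""Synthetic inputs with known ground truth.

No patient-level data are deposited for the trials behind this analysis;
published survival enters the model as digitized curve coordinates and
pooled hazard ratios.  This module generates stand-ins for each of those
inputs — pseudo individual-patient event times, noiseless digitized
Kaplan-Meier coordinates, and per-trial log-HR tables on a connected
treatment network — so every downstream stage (curve fitting, network
pooling, the survival model itself) can be exercised against a known truth.

All generators are pure functions of their parameters and a seed.
Times are in months.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConnectivityError, InvalidArgumentError
from .weibull import WeibullCurve

__all__ = [
    "PseudoIPD",
    "KMPointSet",
    "TrialHRTable",
    "simulate_ipd",
    "generate_km_points",
    "generate_trial_table",
    "DEFAULT_NETWORK_LOGHR",
    "DEFAULT_NETWORK_SE",
]

# Path-shaped treatment network linking the two immunochemotherapy arms
# through their shared chemotherapy comparators (CTC - TC - GP - SGP).
# Values are illustrative defaults for the generator, not trial estimates.
DEFAULT_NETWORK_LOGHR = {
    ("CTC", "TC"): -0.75,
    ("TC", "GP"): 0.05,
    ("SGP", "GP"): -0.45,
}
DEFAULT_NETWORK_SE = {
    ("CTC", "TC"): 0.12,
    ("TC", "GP"): 0.15,
    ("SGP", "GP"): 0.12,
}


@dataclass(frozen=True)
class PseudoIPD:
    """Pseudo individual-patient data: observation times (months) with a
    1=event / 0=censored indicator."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        e = np.asarray(self.event, dtype=int)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "event", e)
        if t.size == 0:
            raise InvalidArgumentError("need at least one record")
        if t.shape != e.shape:
            raise InvalidArgumentError("time and event must align")
        if not np.all(np.isfinite(t)) or np.any(t < 0):
            raise InvalidArgumentError("times must be finite and >= 0")
        if not np.all(np.isin(e, (0, 1))):
            raise InvalidArgumentError("event indicator must be 0 or 1")

    def __len__(self):
        return len(self.time)

    def to_csv(self, path_or_buf=None):
        return self.to_frame().to_csv(path_or_buf, index=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.time, "event": self.event})

    @classmethod
    def from_csv(cls, path_or_buf) -> "PseudoIPD":
        df = pd.read_csv(path_or_buf)
        return cls(time=df["time_months"].to_numpy(),
                   event=df["event"].to_numpy())


@dataclass(frozen=True)
class KMPointSet:
    """Digitized survival-curve coordinates: (time, survival) pairs with
    time strictly increasing from 0 and survival non-increasing from 1."""

    time: np.ndarray
    survival: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "survival", s)
        if t.size == 0 or t.shape != s.shape:
            raise InvalidArgumentError("need matching, non-empty coordinates")
        if t[0] != 0 or s[0] != 1.0:
            raise InvalidArgumentError("first point must be (0, 1)")
        if np.any(np.diff(t) <= 0):
            raise InvalidArgumentError("times must be strictly increasing")
        if np.any(np.diff(s) > 0):
            raise InvalidArgumentError("survival must be non-increasing")
        if np.any((s < 0) | (s > 1)):
            raise InvalidArgumentError("survival must lie in [0, 1]")

    def __len__(self):
        return len(self.time)

    def to_csv(self, path_or_buf=None):
        return pd.DataFrame(
            {"time_months": self.time, "survival": self.survival}
        ).to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "KMPointSet":
        df = pd.read_csv(path_or_buf)
        return cls(time=df["time_months"].to_numpy(),
                   survival=df["survival"].to_numpy())


@dataclass(frozen=True)
class TrialHRTable:
    """Per-trial log hazard-ratio estimates over a treatment network.

    One row per two-arm comparison: trial id, the two treatment labels,
    the log-HR of arm_a relative to arm_b, its standard error, and an
    endpoint tag (PFS or OS).  The rows must form a connected graph.
    """

    frame: pd.DataFrame = field(repr=False)

    COLUMNS = ("trial", "arm_a", "arm_b", "loghr", "se", "endpoint")

    def __post_init__(self):
        df = self.frame
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise InvalidArgumentError(f"missing columns: {missing}")
        if len(df) == 0:
            raise InvalidArgumentError("table must have at least one row")
        if np.any(df["se"].to_numpy(dtype=float) <= 0):
            raise InvalidArgumentError("all SEs must be positive")
        if np.any(df["arm_a"] == df["arm_b"]):
            raise InvalidArgumentError("self-comparisons are not allowed")
        if not self.is_connected():
            raise ConnectivityError("treatment network is not connected")

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.treatments())
        g.add_edges_from(zip(self.frame["arm_a"], self.frame["arm_b"]))
        return g

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph())

    def treatments(self) -> list:
        return sorted(set(self.frame["arm_a"]) | set(self.frame["arm_b"]))

    def to_csv(self, path_or_buf=None):
        return self.frame[list(self.COLUMNS)].to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "TrialHRTable":
        return cls(frame=pd.read_csv(path_or_buf))


def simulate_ipd(curve: WeibullCurve, n: int, censor_hazard: float,
                 admin_cutoff: float, seed: int) -> PseudoIPD:
    """Draw right-censored event times from a Weibull law.

    Event times come from ``S(t) = exp(-scale * t**shape)`` by inversion;
    censoring is independent exponential with rate ``censor_hazard`` per
    month plus an administrative cutoff at ``admin_cutoff`` months.  The
    observed time is the minimum of the three, with event=1 when the event
    time wins.
    """
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    if censor_hazard < 0:
        raise InvalidArgumentError("censor_hazard must be >= 0")
    if not admin_cutoff > 0:
        raise InvalidArgumentError("admin_cutoff must be positive")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    t_event = np.power(-np.log(u) / curve.scale, 1.0 / curve.shape)
    if censor_hazard > 0:
        t_cens = rng.exponential(scale=1.0 / censor_hazard, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, admin_cutoff)
    obs = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return PseudoIPD(time=obs, event=event)


def generate_km_points(curve: WeibullCurve, grid) -> KMPointSet:
    """Noiseless digitization stand-in: evaluate the curve on a time grid.

    The grid must be sorted ascending and start at 0 (where S=1), mirroring
    the axis of a published Kaplan-Meier figure.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or grid[0] != 0:
        raise InvalidArgumentError("grid must start at 0")
    if np.any(np.diff(grid) <= 0) and grid.size > 1:
        raise InvalidArgumentError("grid must be sorted strictly ascending")
    return KMPointSet(time=grid, survival=np.atleast_1d(curve.survival(grid)))


def generate_trial_table(true_loghr_per_edge: dict | None = None,
                         ses: dict | None = None,
                         seed: int = 0,
                         endpoint: str = "PFS") -> TrialHRTable:
    """Simulate one trial per network edge with normally perturbed log-HRs.

    ``true_loghr_per_edge`` maps ``(arm_a, arm_b)`` pairs to the true
    log-HR of a vs b; ``ses`` maps the same pairs to the sampling SE of
    each trial's estimate.  Rows are emitted in sorted edge order so the
    same seed always yields the same table.  Defaults reproduce the
    CTC-TC-GP-SGP path network.
    """
    if true_loghr_per_edge is None:
        true_loghr_per_edge = DEFAULT_NETWORK_LOGHR
    if ses is None and true_loghr_per_edge is DEFAULT_NETWORK_LOGHR:
        ses = DEFAULT_NETWORK_SE
    if ses is None or set(ses) != set(true_loghr_per_edge):
        raise InvalidArgumentError("ses must cover exactly the same edges")
    if any(se <= 0 for se in ses.values()):
        raise InvalidArgumentError("all SEs must be positive")

    edges = sorted(true_loghr_per_edge)
    g = nx.Graph()
    for a, b in edges:
        if a == b:
            raise InvalidArgumentError("self-edges are not allowed")
        g.add_edge(a, b)
    if not nx.is_connected(g):
        raise ConnectivityError("edge set does not form a connected network")

    rng = np.random.default_rng(seed)
    rows = []
    for i, (a, b) in enumerate(edges, start=1):
        est = true_loghr_per_edge[(a, b)] + rng.normal(0.0, ses[(a, b)])
        rows.append({"trial": f"trial_{i}", "arm_a": a, "arm_b": b,
                     "loghr": est, "se": ses[(a, b)], "endpoint": endpoint})
    return TrialHRTable(frame=pd.DataFrame(rows))
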