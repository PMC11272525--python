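"""Fixed-effect network meta-analysis of log hazard ratios.

Trial-level log-HRs on a connected treatment network are pooled by
inverse-variance weighted least squares on the edge-incidence matrix: with
incidence matrix B (one row per comparison, +1/-1 at the two arms), weights
W = diag(1/se^2) and observations y, the treatment effects d solve the
normal equations L d = B'Wy with L = B'WB the weighted graph Laplacian.
L is singular (effects are identified only up to contrasts), so the
Moore-Penrose pseudo-inverse is used and results are reported as contrasts
against a chosen reference; contrast variances come from the same
pseudo-inverse.  On a path-shaped network this reduces exactly to the
Bucher chain: log-HRs add along the path and variances add.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError

__all__ = ["HazardRatioEstimate", "NetworkModel", "pool_network", "summarize_hr"]


@dataclass(frozen=True)
class HazardRatioEstimate:
    """A pooled hazard ratio with its confidence interval and log-scale SE."""

    hr: float
    ci_low: float
    ci_high: float
    se_log: float
    endpoint: str = ""

    def __post_init__(self):
        if not (0 < self.ci_low <= self.hr <= self.ci_high):
            raise InvalidArgumentError(
                f"require 0 < ci_low <= hr <= ci_high, got "
                f"({self.ci_low}, {self.hr}, {self.ci_high})")
        if self.se_log < 0:
            raise InvalidArgumentError("se_log must be non-negative")


@dataclass(frozen=True)
class NetworkModel:
    """Design pieces of a fitted network: treatment labels, incidence
    matrix, inverse-variance weights and the Laplacian pseudo-inverse."""

    treatments: tuple
    incidence: np.ndarray
    weights: np.ndarray
    laplacian_pinv: np.ndarray
    effects: np.ndarray


def _build_network(table):
    df = table.frame
    treatments = tuple(table.treatments())
    index = {t: i for i, t in enumerate(treatments)}
    m, k = len(df), len(treatments)
    B = np.zeros((m, k))
    for row_i, (a, b) in enumerate(zip(df["arm_a"], df["arm_b"])):
        B[row_i, index[a]] = 1.0
        B[row_i, index[b]] = -1.0
    w = 1.0 / df["se"].to_numpy(dtype=float) ** 2
    y = df["loghr"].to_numpy(dtype=float)
    L = B.T @ (w[:, None] * B)
    Lp = np.linalg.pinv(L)
    d = Lp @ (B.T @ (w * y))
    return NetworkModel(treatments=treatments, incidence=B, weights=w,
                        laplacian_pinv=Lp, effects=d), index


def pool_network(table, reference: str, endpoint: str | None = None) -> dict:
    """Pool a trial table into consistent log-HRs against a reference.

    Returns ``{treatment: (loghr_vs_reference, se)}`` for every treatment
    in the network (the reference maps to ``(0.0, 0.0)``).  ``endpoint``
    selects rows of a mixed PFS/OS table; a table left with rows for more
    than one endpoint is rejected.
    """
    from .synthetic import TrialHRTable  # local import to avoid a cycle

    df = table.frame
    if endpoint is not None:
        df = df[df["endpoint"] == endpoint]
        if len(df) == 0:
            raise InvalidArgumentError(f"no rows for endpoint {endpoint!r}")
        table = TrialHRTable(frame=df.reset_index(drop=True))
    elif df["endpoint"].nunique() > 1:
        raise InvalidArgumentError(
            "table mixes endpoints; pass endpoint='PFS' or 'OS'")

    if reference not in table.treatments():
        raise InvalidArgumentError(f"reference {reference!r} not in network")

    model, index = _build_network(table)
    r = index[reference]
    Lp, d = model.laplacian_pinv, model.effects
    out = {}
    for t, i in index.items():
        est = d[i] - d[r]
        var = Lp[i, i] + Lp[r, r] - 2.0 * Lp[i, r]
        out[t] = (float(est), float(math.sqrt(max(var, 0.0))))
    return out


def summarize_hr(loghr: float, se: float, level: float = 0.95,
                 endpoint: str = "") -> HazardRatioEstimate:
    """Exponentiate a pooled log-HR into an HR with a Wald interval."""
    if se <= 0:
        raise InvalidArgumentError("se must be positive")
    if not 0 < level < 1:
        raise InvalidArgumentError("confidence level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return HazardRatioEstimate(
        hr=math.exp(loghr),
        ci_low=math.exp(loghr - z * se),
        ci_high=math.exp(loghr + z * se),
        se_log=se,
        endpoint=endpoint,
    )


def pooled_table(table, reference: str, level: float = 0.95) -> pd.DataFrame:
    """Pool every endpoint in a table and return a tidy frame
    (endpoint, treatment, loghr, se, hr, ci_low, ci_high)."""
    rows = []
    for ep in sorted(table.frame["endpoint"].unique()):
        pooled = pool_network(table, reference, endpoint=ep)
        for trt, (loghr, se) in sorted(pooled.items()):
            if se == 0.0:
                hr, lo, hi = 1.0, 1.0, 1.0
            else:
                est = summarize_hr(loghr, se, level, endpoint=ep)
                hr, lo, hi = est.hr, est.ci_low, est.ci_high
            rows.append({"endpoint": ep, "treatment": trt, "loghr": loghr,
                         "se": se, "hr": hr, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)
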