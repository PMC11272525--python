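"""Deterministic (tornado) and probabilistic sensitivity analyses.

One-way DSA re-runs the full deterministic engine with exactly one
parameter moved to its low, then high, bound.  The PSA draws every
non-fixed parameter from a distribution assigned by role — beta for
probabilities and (dis)utilities, gamma for costs, normal for hazard
ratios — parameterized by method of moments from the baseline and the
published low/high range (read as a 95% interval unless an explicit SE is
given).  Hazard ratios are sampled on the log scale by default, matching
the asymmetry of their published intervals; a natural-scale normal
truncated at zero is available.  Draws are independent across parameters
and seeded.  The probabilistic ICER is the ratio of the mean incremental
cost to the mean incremental QALY; the mean of per-draw ratios is kept
only as a diagnostic because it is unstable when the QALY difference
changes sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig, evaluate_base_case, get_value, set_value
from .errors import InfeasibleMomentsError, InvalidArgumentError

__all__ = [
    "ParameterSpec",
    "TornadoEntry",
    "Distribution",
    "enumerate_parameters",
    "method_of_moments",
    "one_way_dsa",
    "run_psa",
    "ceac",
    "default_wtp_grid",
]

_Z95 = 1.959964  # two-sided 95% standard-normal quantile


@dataclass(frozen=True)
class ParameterSpec:
    """One sensitivity-analysis parameter: where it lives in the
    configuration, its baseline and range, and its sampling family."""

    name: str
    path: tuple               # path to the {baseline, low, high} mapping
    baseline: float
    low: float
    high: float
    family: str               # beta | gamma | normal | fixed
    role: str                 # cost | utility | disutility | probability | hr | discount

    def __post_init__(self):
        if self.low > self.high:
            raise InvalidArgumentError(f"{self.name}: low > high")


@dataclass(frozen=True)
class TornadoEntry:
    """ICER endpoints when one parameter is pushed to its bounds."""

    name: str
    icer_low: float
    icer_high: float

    @property
    def width(self) -> float:
        return abs(self.icer_high - self.icer_low)


def enumerate_parameters(config: AnalysisConfig | dict) -> list[ParameterSpec]:
    """All ranged parameters of a configuration, with their sampling
    family implied by role.  The discount rate is 'fixed' (varied only in
    the DSA, never sampled)."""
    raw = config.raw if isinstance(config, AnalysisConfig) else config
    params: list[ParameterSpec] = []

    def add(path, family, role):
        node = get_value(raw, path)
        params.append(ParameterSpec(
            name=".".join(map(str, path)), path=path,
            baseline=float(node["baseline"]), low=float(node["low"]),
            high=float(node["high"]), family=family, role=role))

    for ep in ("pfs", "os"):
        add(("hazard_ratios", ep), "normal", "hr")
    add(("settings", "annual_discount"), "fixed", "discount")
    for drug in raw["drug_costs"]:
        add(("drug_costs", drug), "gamma", "cost")
    for ae in raw["ae_costs"]:
        add(("ae_costs", ae), "gamma", "cost")
    for u in raw["utilities"]:
        add(("utilities", u), "beta", "utility")
    for ae in raw["disutilities"]:
        add(("disutilities", ae), "beta", "disutility")
    for strat in raw["strategies"]:
        for ae in raw["strategies"][strat]["ae_incidence"]:
            add(("strategies", strat, "ae_incidence", ae), "beta", "probability")
    return params


@dataclass(frozen=True)
class Distribution:
    """A sampling distribution with its method-of-moments parameters."""

    family: str               # beta | gamma | normal | lognormal | truncnormal | point
    params: dict
    mean: float

    def sample(self, rng: np.random.Generator, size: int):
        p = self.params
        if self.family == "point":
            return np.full(size, self.mean)
        if self.family == "beta":
            return rng.beta(p["alpha"], p["beta"], size=size)
        if self.family == "gamma":
            return rng.gamma(p["shape"], p["scale"], size=size)
        if self.family == "normal":
            return rng.normal(p["loc"], p["scale"], size=size)
        if self.family == "lognormal":
            return np.exp(rng.normal(p["mu"], p["sigma"], size=size))
        if self.family == "truncnormal":  # natural-scale HR, truncated at 0
            out = rng.normal(p["loc"], p["scale"], size=size)
            while np.any(out <= 0):
                bad = out <= 0
                out[bad] = rng.normal(p["loc"], p["scale"], size=int(bad.sum()))
            return out
        raise InvalidArgumentError(f"unknown family {self.family!r}")


def _range_se(spec: ParameterSpec) -> float:
    return (spec.high - spec.low) / (2.0 * _Z95)


def method_of_moments(spec: ParameterSpec, se: float | None = None,
                      hr_mode: str = "lognormal") -> Distribution:
    """Distribution parameters from the mean and standard error.

    The SE defaults to (high - low) / 3.92, reading the range as a 95%
    interval.  Formulas: beta alpha = m(m(1-m)/s^2 - 1), beta = (1-m)(...);
    gamma shape = m^2/s^2, scale = s^2/m; normal (m, s).  A zero SE (or a
    boundary mean for the beta/gamma families) degenerates to a point mass.
    """
    if spec.family == "fixed":
        raise InvalidArgumentError(f"{spec.name}: fixed parameters are not sampled")
    m = spec.baseline
    s = _range_se(spec) if se is None else se
    if s < 0:
        raise InvalidArgumentError("se must be >= 0")

    if spec.role == "hr":
        if hr_mode == "lognormal":
            if spec.low <= 0:
                raise InvalidArgumentError(f"{spec.name}: log-scale HR needs low > 0")
            sigma = (math.log(spec.high) - math.log(spec.low)) / (2.0 * _Z95)
            if sigma == 0:
                return Distribution("point", {}, m)
            return Distribution("lognormal",
                                {"mu": math.log(m), "sigma": sigma}, m)
        if hr_mode == "natural":
            if s == 0:
                return Distribution("point", {}, m)
            return Distribution("truncnormal", {"loc": m, "scale": s}, m)
        raise InvalidArgumentError(f"unknown hr_mode {hr_mode!r}")

    if s == 0:
        return Distribution("point", {}, m)
    if spec.family == "beta":
        if not 0 < m < 1:
            if m in (0.0, 1.0):
                return Distribution("point", {}, m)
            raise InfeasibleMomentsError(f"{spec.name}: beta mean must be in [0, 1]")
        if s * s >= m * (1 - m):
            raise InfeasibleMomentsError(
                f"{spec.name}: variance {s*s:.4g} >= m(1-m) = {m*(1-m):.4g}")
        nu = m * (1 - m) / (s * s) - 1.0
        return Distribution("beta", {"alpha": m * nu, "beta": (1 - m) * nu}, m)
    if spec.family == "gamma":
        if m < 0:
            raise InfeasibleMomentsError(f"{spec.name}: gamma mean must be >= 0")
        if m == 0:
            return Distribution("point", {}, 0.0)
        return Distribution("gamma",
                            {"shape": m * m / (s * s), "scale": s * s / m}, m)
    if spec.family == "normal":
        return Distribution("normal", {"loc": m, "scale": s}, m)
    raise InvalidArgumentError(f"unknown family {spec.family!r}")


def one_way_dsa(config: AnalysisConfig,
                parameters: list[ParameterSpec] | None = None) -> list[TornadoEntry]:
    """Tornado analysis: ICER with each parameter at its low and high bound,
    all others at baseline, sorted by bar width (descending)."""
    if parameters is None:
        parameters = enumerate_parameters(config)
    entries = []
    for spec in parameters:
        endpoint_icers = []
        for bound in (spec.low, spec.high):
            work = config.copy().raw
            set_value(work, spec.path + ("baseline",), bound)
            endpoint_icers.append(evaluate_base_case(work).incremental.icer_qaly)
        entries.append(TornadoEntry(name=spec.name,
                                    icer_low=endpoint_icers[0],
                                    icer_high=endpoint_icers[1]))
    # nan widths (undefined ICERs) sort last; ties broken by name
    return sorted(entries,
                  key=lambda e: (-(e.width if math.isfinite(e.width) else -math.inf),
                                 e.name))


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([{"parameter": e.name, "icer_low": e.icer_low,
                          "icer_high": e.icer_high, "width": e.width}
                         for e in entries])


def run_psa(config: AnalysisConfig, n_draws: int, seed: int,
            hr_mode: str | None = None) -> tuple[pd.DataFrame, dict]:
    """Monte-Carlo probabilistic sensitivity analysis.

    Every non-fixed parameter is drawn independently from its assigned
    distribution; both arms are re-evaluated under the shared draw.
    Returns the per-draw samples (draw, delta_cost, delta_qaly, delta_ly)
    and a summary with the means and the probabilistic ICER (ratio of
    means).  Fully reproducible for a given (config, seed).
    """
    if n_draws < 1:
        raise InvalidArgumentError("n_draws must be >= 1")
    if hr_mode is None:
        hr_mode = config.raw["settings"]["hr_sampling"]
    params = [p for p in enumerate_parameters(config) if p.family != "fixed"]
    dists = [method_of_moments(p, hr_mode=hr_mode) for p in params]

    rng = np.random.default_rng(seed)
    draws = np.column_stack([d.sample(rng, n_draws) for d in dists])
    # beta/gamma/HR supports are already valid model inputs; plain-normal
    # parameters could stray outside their domain and are clipped there
    for j, p in enumerate(params):
        if dists[j].family == "normal" and p.role in ("utility", "disutility",
                                                      "probability"):
            draws[:, j] = np.clip(draws[:, j], 0.0, 1.0)

    work = config.copy().raw  # every sampled field is overwritten each draw
    records = []
    for i in range(n_draws):
        for p, v in zip(params, draws[i]):
            set_value(work, p.path + ("baseline",), float(v))
        res = evaluate_base_case(work)
        inc = res.incremental
        records.append((i, inc.delta_cost, inc.delta_qaly, inc.delta_ly))
    samples = pd.DataFrame(records,
                           columns=["draw", "delta_cost", "delta_qaly", "delta_ly"])

    mean_dc = float(samples["delta_cost"].mean())
    mean_dq = float(samples["delta_qaly"].mean())
    mean_dl = float(samples["delta_ly"].mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        per_draw = samples["delta_cost"].to_numpy() / samples["delta_qaly"].to_numpy()
    summary = {
        "n_draws": int(n_draws),
        "seed": int(seed),
        "mean_delta_cost": mean_dc,
        "mean_delta_qaly": mean_dq,
        "mean_delta_ly": mean_dl,
        "icer": mean_dc / mean_dq if mean_dq != 0 else math.nan,
        "mean_of_per_draw_icers_diagnostic":
            float(np.mean(per_draw[np.isfinite(per_draw)]))
            if np.any(np.isfinite(per_draw)) else math.nan,
    }
    return samples, summary


def default_wtp_grid(low: float = 12734.0, high: float = 38202.0) -> np.ndarray:
    """0 to 50,000 USD/QALY in steps of 500, guaranteed to contain the two
    GDP-based thresholds exactly."""
    grid = np.arange(0.0, 50001.0, 500.0)
    return np.unique(np.concatenate([grid, [low, high]]))


def ceac(samples: pd.DataFrame, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve under the net-monetary-benefit
    rule: at threshold w the reference strategy is preferred in a draw when
    w * delta_qaly - delta_cost > 0.  The two strategies' probabilities are
    complementary at every threshold."""
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if len(samples) == 0 or wtp_grid.size == 0:
        raise InvalidArgumentError("samples and wtp_grid must be non-empty")
    dq = samples["delta_qaly"].to_numpy()
    dc = samples["delta_cost"].to_numpy()
    nmb = wtp_grid[:, None] * dq[None, :] - dc[None, :]
    p_ref = (nmb > 0).mean(axis=1)
    return pd.DataFrame({"wtp": wtp_grid, "p_reference": p_ref,
                         "p_comparator": 1.0 - p_ref})
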