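"""Three-state partitioned survival model (PFS / progressed / dead).

State occupancy is read directly off two survival curves: at each cycle's
evaluation time t, the progression-free fraction is min(S_pfs(t), S_os(t)),
the dead fraction is 1 - S_os(t), and the progressed fraction is the
remainder — the defining trick of a partitioned survival model, which needs
no transition probabilities.  Life-years, quality-adjusted life-years and
costs are accrued per cycle under continuous-time discounting and summed
over the horizon.

Conventions that the source publications of such models rarely state are
explicit settings here:

* ``cycle_eval``: state membership is evaluated at cycle midpoints by
  default (equivalent to a half-cycle correction); start-of-cycle is
  available.
* Adverse-event management costs and disutilities accrue per cycle over
  progression-free occupancy by default; a one-off (costs) or
  induction-only (disutilities) variant can be configured.
* Drug costs stop at progression; induction components are billed for the
  first six cycles, the maintenance component until the PD-1 treatment cap
  (24 months from treatment start by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .weibull import WeibullCurve

__all__ = [
    "ModelSettings",
    "AdverseEvent",
    "StrategySpec",
    "SurvivalTrace",
    "CEResult",
    "IncrementalReport",
    "build_trace",
    "accrue_outcomes",
    "accrue_costs",
    "evaluate_strategy",
    "compute_icer",
]

DAYS_PER_MONTH = 365.25 / 12.0
MONTHS_PER_YEAR = 12.0


@dataclass(frozen=True)
class ModelSettings:
    """Global model conventions and horizon.

    ``months_per_cycle`` normally derives from ``cycle_length_days`` but may
    be overridden for exact-unit constructions (e.g. 12/52 months to make
    52 cycles exactly one year).
    """

    cycle_length_days: float = 21.0
    n_cycles: int = 173
    annual_discount: float = 0.05
    wtp_low: float = 12734.0
    wtp_high: float = 38202.0
    cycle_eval: str = "midpoint"          # midpoint | start
    ae_cost_mode: str = "per_cycle"       # per_cycle | one_off
    ae_disutility_mode: str = "per_cycle"  # per_cycle | induction_only
    induction_cycles: int = 6
    months_per_cycle: float | None = None

    def __post_init__(self):
        if self.cycle_length_days <= 0:
            raise InvalidArgumentError("cycle_length_days must be positive")
        if self.n_cycles < 1:
            raise InvalidArgumentError("n_cycles must be >= 1")
        if not 0 <= self.annual_discount < 1:
            raise InvalidArgumentError("annual_discount must be in [0, 1)")
        if self.wtp_low > self.wtp_high:
            raise InvalidArgumentError("wtp_low must not exceed wtp_high")
        if self.cycle_eval not in ("midpoint", "start"):
            raise InvalidArgumentError("cycle_eval must be midpoint|start")
        if self.ae_cost_mode not in ("per_cycle", "one_off"):
            raise InvalidArgumentError("ae_cost_mode must be per_cycle|one_off")
        if self.ae_disutility_mode not in ("per_cycle", "induction_only"):
            raise InvalidArgumentError(
                "ae_disutility_mode must be per_cycle|induction_only")
        if self.months_per_cycle is None:
            object.__setattr__(self, "months_per_cycle",
                               self.cycle_length_days / DAYS_PER_MONTH)
        elif self.months_per_cycle <= 0:
            raise InvalidArgumentError("months_per_cycle must be positive")

    @property
    def cycle_years(self) -> float:
        return self.months_per_cycle / MONTHS_PER_YEAR

    def eval_times_months(self) -> np.ndarray:
        offset = 0.5 if self.cycle_eval == "midpoint" else 0.0
        return (np.arange(self.n_cycles) + offset) * self.months_per_cycle


@dataclass(frozen=True)
class AdverseEvent:
    """One severe adverse event: incidence in the arm, per-episode
    management cost (USD) and utility decrement."""

    name: str
    incidence: float
    cost: float
    disutility: float

    def __post_init__(self):
        if not 0 <= self.incidence <= 1:
            raise InvalidArgumentError(f"{self.name}: incidence must be in [0,1]")
        if self.cost < 0:
            raise InvalidArgumentError(f"{self.name}: cost must be >= 0")
        if self.disutility < 0:
            raise InvalidArgumentError(f"{self.name}: disutility must be >= 0")


@dataclass(frozen=True)
class StrategySpec:
    """One arm's drug schedule, adverse-event profile and utilities.

    ``induction`` lists (drug, cost per cycle) pairs billed for the first
    six cycles; ``maintenance`` is the single (drug, cost per cycle)
    continued until the cap.  Costs are USD per 21-day cycle.
    """

    name: str
    induction: tuple          # ((drug, cost_per_cycle), ...)
    maintenance: tuple        # (drug, cost_per_cycle)
    maintenance_cap_months: float
    adverse_events: tuple     # (AdverseEvent, ...)
    pfs_utility: float
    pd_utility: float

    def __post_init__(self):
        for _, cost in self.induction:
            if cost < 0:
                raise InvalidArgumentError(f"{self.name}: negative induction cost")
        if self.maintenance[1] < 0:
            raise InvalidArgumentError(f"{self.name}: negative maintenance cost")
        if self.maintenance_cap_months <= 0:
            raise InvalidArgumentError(f"{self.name}: cap must be positive")
        for u in (self.pfs_utility, self.pd_utility):
            if not 0 <= u <= 1:
                raise InvalidArgumentError(f"{self.name}: utilities must be in [0,1]")

    @property
    def induction_cost_per_cycle(self) -> float:
        return sum(cost for _, cost in self.induction)

    @property
    def ae_cost_per_cycle(self) -> float:
        return sum(ae.incidence * ae.cost for ae in self.adverse_events)

    @property
    def ae_disutility(self) -> float:
        return sum(ae.incidence * ae.disutility for ae in self.adverse_events)


@dataclass(frozen=True)
class SurvivalTrace:
    """Per-cycle state membership with discount weights.

    Memberships sum to one at every cycle; pfs and pfs+pd are
    non-increasing; discount weights lie in (0, 1] and are non-increasing.
    """

    time_months: np.ndarray
    pfs: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    discount: np.ndarray

    def __post_init__(self):
        arrays = [np.asarray(a, dtype=float) for a in
                  (self.time_months, self.pfs, self.pd, self.dead, self.discount)]
        for name, a in zip(("time_months", "pfs", "pd", "dead", "discount"), arrays):
            object.__setattr__(self, name, a)
        n = len(self.time_months)
        if any(len(a) != n for a in arrays):
            raise InvalidArgumentError("trace columns must align")
        total = self.pfs + self.pd + self.dead
        if np.max(np.abs(total - 1.0)) > 1e-12:
            raise InvalidArgumentError("state memberships must sum to 1")
        for name in ("pfs", "pd", "dead"):
            a = getattr(self, name)
            if np.any((a < -1e-15) | (a > 1 + 1e-15)):
                raise InvalidArgumentError(f"{name} must lie in [0, 1]")
        if np.any(np.diff(self.pfs) > 1e-12):
            raise InvalidArgumentError("pfs must be non-increasing")
        if np.any(np.diff(self.pfs + self.pd) > 1e-12):
            raise InvalidArgumentError("pfs+pd must be non-increasing")
        if np.any((self.discount <= 0) | (self.discount > 1)):
            raise InvalidArgumentError("discount weights must lie in (0, 1]")

    def __len__(self):
        return len(self.time_months)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cycle": np.arange(len(self)),
            "time_months": self.time_months,
            "pfs": self.pfs,
            "pd": self.pd,
            "dead": self.dead,
            "discount": self.discount,
        })


@dataclass(frozen=True)
class CEResult:
    """Discounted totals for one strategy; components sum to totals."""

    strategy: str
    ly: float
    pf_ly: float
    pd_ly: float
    qaly: float
    pfs_qaly: float
    pd_qaly: float
    total_cost: float
    drug_cost: float
    ae_cost: float

    def to_row(self) -> dict:
        return {
            "strategy": self.strategy,
            "ly": self.ly, "pf_ly": self.pf_ly, "pd_ly": self.pd_ly,
            "qaly": self.qaly, "pfs_qaly": self.pfs_qaly,
            "pd_qaly": self.pd_qaly,
            "total_cost": self.total_cost, "drug_cost": self.drug_cost,
            "ae_cost": self.ae_cost,
        }


@dataclass(frozen=True)
class IncrementalReport:
    """Incremental statistics of strategy a over strategy b."""

    strategy_a: str
    strategy_b: str
    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer_qaly: float          # nan when delta_qaly == 0
    icer_ly: float            # nan when delta_ly == 0
    classification: str       # dominant | dominated | ratio | undefined

    def to_dict(self) -> dict:
        return {
            "strategy_a": self.strategy_a,
            "strategy_b": self.strategy_b,
            "delta_cost": self.delta_cost,
            "delta_ly": self.delta_ly,
            "delta_qaly": self.delta_qaly,
            "icer_qaly": None if math.isnan(self.icer_qaly) else self.icer_qaly,
            "icer_ly": None if math.isnan(self.icer_ly) else self.icer_ly,
            "classification": self.classification,
        }


def build_trace(pfs_curve: WeibullCurve, os_curve: WeibullCurve,
                settings: ModelSettings) -> SurvivalTrace:
    """Partition survival into state occupancy at each cycle's evaluation time."""
    t = settings.eval_times_months()
    s_pfs = np.atleast_1d(pfs_curve.survival(t))
    s_os = np.atleast_1d(os_curve.survival(t))
    pfs = np.minimum(s_pfs, s_os)          # PFS cannot exceed OS
    dead = 1.0 - s_os
    pd_state = s_os - pfs                  # >= 0 by construction
    t_years = t / MONTHS_PER_YEAR
    discount = np.power(1.0 + settings.annual_discount, -t_years)
    return SurvivalTrace(time_months=t, pfs=pfs, pd=pd_state, dead=dead,
                         discount=discount)


def accrue_outcomes(trace: SurvivalTrace, strategy: StrategySpec,
                    settings: ModelSettings) -> dict:
    """Discounted life-years and QALYs accrued over the trace.

    Each cycle contributes occupancy x cycle length (years) x discount.
    The PFS utility is reduced by the incidence-weighted adverse-event
    disutility during the configured application window.
    """
    dt = settings.cycle_years
    w = trace.discount
    pf_ly = float(np.sum(trace.pfs * dt * w))
    pd_ly = float(np.sum(trace.pd * dt * w))

    if settings.ae_disutility_mode == "per_cycle":
        dis_window = np.ones(len(trace))
    else:  # induction_only
        dis_window = (np.arange(len(trace)) < settings.induction_cycles).astype(float)
    pfs_util = strategy.pfs_utility - strategy.ae_disutility * dis_window
    pfs_util = np.clip(pfs_util, 0.0, None)
    pfs_qaly = float(np.sum(trace.pfs * pfs_util * dt * w))
    pd_qaly = float(np.sum(trace.pd * strategy.pd_utility * dt * w))
    return {
        "ly": pf_ly + pd_ly, "pf_ly": pf_ly, "pd_ly": pd_ly,
        "qaly": pfs_qaly + pd_qaly, "pfs_qaly": pfs_qaly, "pd_qaly": pd_qaly,
    }


def accrue_costs(trace: SurvivalTrace, strategy: StrategySpec,
                 settings: ModelSettings) -> dict:
    """Discounted drug and adverse-event cost accrual.

    Drug costs apply only to progression-free occupancy: the full induction
    regimen for the first six cycles, then the maintenance drug until the
    cap (months from treatment start).  Adverse-event management costs
    accrue per cycle as incidence x cost over PFS occupancy, or once at
    model entry in one-off mode.
    """
    cycles = np.arange(len(trace))
    w = trace.discount
    induction_mask = cycles < settings.induction_cycles
    cap_cycles = int(np.floor(strategy.maintenance_cap_months
                              / settings.months_per_cycle))
    maintenance_mask = (cycles >= settings.induction_cycles) & (cycles < cap_cycles)

    drug_per_cycle = (strategy.induction_cost_per_cycle * induction_mask
                      + strategy.maintenance[1] * maintenance_mask)
    drug_cost = float(np.sum(drug_per_cycle * trace.pfs * w))

    if settings.ae_cost_mode == "per_cycle":
        ae_cost = float(np.sum(strategy.ae_cost_per_cycle * trace.pfs * w))
    else:  # one_off: incidence-weighted cost once at entry (t=0, undiscounted)
        ae_cost = float(sum(ae.incidence * ae.cost
                            for ae in strategy.adverse_events))
    return {"total_cost": drug_cost + ae_cost, "drug_cost": drug_cost,
            "ae_cost": ae_cost}


def evaluate_strategy(trace: SurvivalTrace, strategy: StrategySpec,
                      settings: ModelSettings) -> CEResult:
    """Full discounted outcome and cost accrual for one arm."""
    out = accrue_outcomes(trace, strategy, settings)
    cost = accrue_costs(trace, strategy, settings)
    return CEResult(strategy=strategy.name, **out, **cost)


def compute_icer(a: CEResult, b: CEResult) -> IncrementalReport:
    """Incremental cost-effectiveness of a relative to b.

    'dominant' means a is cheaper and more effective (in QALYs);
    'dominated' the reverse; otherwise the ratio is reported.  A zero QALY
    difference leaves the ICER undefined (flagged, not an error).
    """
    d_cost = a.total_cost - b.total_cost
    d_ly = a.ly - b.ly
    d_qaly = a.qaly - b.qaly
    icer_q = d_cost / d_qaly if d_qaly != 0 else math.nan
    icer_l = d_cost / d_ly if d_ly != 0 else math.nan
    if d_qaly == 0:
        cls = "undefined"
    elif d_cost < 0 and d_qaly > 0:
        cls = "dominant"
    elif d_cost > 0 and d_qaly < 0:
        cls = "dominated"
    else:
        cls = "ratio"
    return IncrementalReport(
        strategy_a=a.strategy, strategy_b=b.strategy,
        delta_cost=d_cost, delta_ly=d_ly, delta_qaly=d_qaly,
        icer_qaly=icer_q, icer_ly=icer_l, classification=cls,
    )
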