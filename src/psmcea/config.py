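"""Configuration loading, validation and model assembly.

The configuration file is the single source of all model inputs (prices,
incidences, utilities, survival parameters, hazard ratios, conventions);
no engine module hard-codes an input value.  ``load_config`` validates the
nested structure and reports every offending field path at once;
``evaluate_base_case`` assembles curves, strategies and settings from a
(possibly perturbed) configuration and runs the model end to end.
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field

import yaml

from .errors import ConfigValidationError, InvalidArgumentError
from .psm import (
    AdverseEvent,
    CEResult,
    IncrementalReport,
    ModelSettings,
    StrategySpec,
    SurvivalTrace,
    build_trace,
    compute_icer,
    evaluate_strategy,
)
from .weibull import WeibullCurve, adjust_curve_by_hr

__all__ = [
    "AnalysisConfig",
    "load_config",
    "default_config",
    "validate_config",
    "evaluate_base_case",
    "BaseCaseResult",
    "set_value",
    "get_value",
]

_TRIPLE_KEYS = {"baseline", "low", "high"}


def _is_number(x) -> bool:
    return isinstance(x, (int, float)) and not isinstance(x, bool)


def _check_triple(node, path, problems, lo=None, hi=None, allow_equal=True):
    if not isinstance(node, dict) or not _TRIPLE_KEYS <= set(node):
        problems.append(f"{path}: expected {{baseline, low, high}} mapping")
        return
    for k in sorted(_TRIPLE_KEYS):
        v = node[k]
        if not _is_number(v):
            problems.append(f"{path}.{k}: expected a number, got {v!r}")
            return
        if lo is not None and v < lo:
            problems.append(f"{path}.{k}: {v} below minimum {lo}")
        if hi is not None and v > hi:
            problems.append(f"{path}.{k}: {v} above maximum {hi}")
    if node["low"] > node["high"]:
        problems.append(f"{path}: low > high")


def validate_config(raw: dict) -> None:
    """Validate the nested configuration; raises ConfigValidationError
    naming every offending field path."""
    problems: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigValidationError("root: expected a mapping")

    for section in ("metadata", "settings", "survival", "hazard_ratios",
                    "drug_costs", "ae_costs", "utilities", "disutilities",
                    "strategies"):
        if section not in raw:
            problems.append(f"{section}: missing section")
    if problems:
        raise ConfigValidationError(problems)

    st = raw["settings"]
    for key, lo, hi in (("cycle_length_days", 1e-9, None),
                        ("wtp_low", 0, None), ("wtp_high", 0, None)):
        if not _is_number(st.get(key)):
            problems.append(f"settings.{key}: expected a number")
        elif st[key] < lo:
            problems.append(f"settings.{key}: must be >= {lo}")
    if not isinstance(st.get("n_cycles"), int) or st.get("n_cycles", 0) < 1:
        problems.append("settings.n_cycles: expected a positive integer")
    _check_triple(st.get("annual_discount"), "settings.annual_discount",
                  problems, lo=0, hi=0.999)
    for key, allowed in (("cycle_eval", ("midpoint", "start")),
                         ("ae_cost_mode", ("per_cycle", "one_off")),
                         ("ae_disutility_mode", ("per_cycle", "induction_only")),
                         ("hr_direction", ("divide", "multiply")),
                         ("hr_sampling", ("lognormal", "natural"))):
        if st.get(key) not in allowed:
            problems.append(f"settings.{key}: expected one of {allowed}")

    for ep in ("pfs", "os"):
        node = raw["survival"].get(ep)
        if not isinstance(node, dict):
            problems.append(f"survival.{ep}: expected a mapping")
            continue
        for k in ("scale", "shape"):
            v = node.get(k)
            if not _is_number(v) or v <= 0:
                problems.append(f"survival.{ep}.{k}: expected a positive number")
        _check_triple(raw["hazard_ratios"].get(ep), f"hazard_ratios.{ep}",
                      problems, lo=1e-12)

    for section, lo, hi in (("drug_costs", 0, None), ("ae_costs", 0, None),
                            ("utilities", 0, 1), ("disutilities", 0, 1)):
        for name, node in raw[section].items():
            _check_triple(node, f"{section}.{name}", problems, lo=lo, hi=hi)

    strategies = raw["strategies"]
    if len(strategies) != 2:
        problems.append("strategies: exactly two strategies are required")
    for sname, snode in strategies.items():
        base = f"strategies.{sname}"
        drugs = set(raw["drug_costs"])
        for drug in snode.get("induction", []):
            if drug not in drugs:
                problems.append(f"{base}.induction: unknown drug {drug!r}")
        if snode.get("maintenance") not in drugs:
            problems.append(f"{base}.maintenance: unknown drug "
                            f"{snode.get('maintenance')!r}")
        cap = snode.get("maintenance_cap_months")
        if not _is_number(cap) or cap <= 0:
            problems.append(f"{base}.maintenance_cap_months: expected > 0")
        inc = snode.get("ae_incidence", {})
        for ae, node in inc.items():
            if ae not in raw["ae_costs"]:
                problems.append(f"{base}.ae_incidence.{ae}: no matching ae_costs entry")
            if ae not in raw["disutilities"]:
                problems.append(f"{base}.ae_incidence.{ae}: no matching disutilities entry")
            _check_triple(node, f"{base}.ae_incidence.{ae}", problems, lo=0, hi=1)

    ref = raw["metadata"].get("reference")
    comp = raw["metadata"].get("comparator")
    if ref not in strategies:
        problems.append("metadata.reference: not a strategy name")
    if comp not in strategies:
        problems.append("metadata.comparator: not a strategy name")

    if problems:
        raise ConfigValidationError(problems)


@dataclass(frozen=True)
class AnalysisConfig:
    """A validated configuration; ``raw`` is the nested mapping."""

    raw: dict = field(repr=False)

    def __post_init__(self):
        validate_config(self.raw)

    def copy(self) -> "AnalysisConfig":
        return AnalysisConfig(raw=copy.deepcopy(self.raw))

    @property
    def reference(self) -> str:
        return self.raw["metadata"]["reference"]

    @property
    def comparator(self) -> str:
        return self.raw["metadata"]["comparator"]

    def to_yaml(self, path=None) -> str | None:
        text = yaml.safe_dump(self.raw, sort_keys=True)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None


def default_config() -> AnalysisConfig:
    """The packaged default configuration (the published base case)."""
    ref = importlib.resources.files("psmcea").joinpath("data/default_config.yaml")
    return AnalysisConfig(raw=yaml.safe_load(ref.read_text()))


def load_config(path) -> AnalysisConfig:
    """Load and validate a configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return AnalysisConfig(raw=raw)


def get_value(raw: dict, path: tuple):
    """Fetch a nested value by key path."""
    node = raw
    for key in path:
        try:
            node = node[key]
        except (KeyError, TypeError):
            raise InvalidArgumentError(f"unresolvable path {'.'.join(map(str, path))}")
    return node


def set_value(raw: dict, path: tuple, value) -> None:
    """Set a nested value by key path (in place)."""
    node = get_value(raw, path[:-1])
    if path[-1] not in node:
        raise InvalidArgumentError(f"unresolvable path {'.'.join(map(str, path))}")
    node[path[-1]] = value


def build_settings(raw: dict) -> ModelSettings:
    st = raw["settings"]
    return ModelSettings(
        cycle_length_days=st["cycle_length_days"],
        n_cycles=st["n_cycles"],
        annual_discount=st["annual_discount"]["baseline"],
        wtp_low=st["wtp_low"],
        wtp_high=st["wtp_high"],
        cycle_eval=st["cycle_eval"],
        ae_cost_mode=st["ae_cost_mode"],
        ae_disutility_mode=st["ae_disutility_mode"],
    )


def build_curves(raw: dict) -> dict:
    """Per-arm (pfs_curve, os_curve): the reference arm straight from the
    survival section, the comparator via hazard-ratio adjustment."""
    ref = raw["metadata"]["reference"]
    comp = raw["metadata"]["comparator"]
    direction = raw["settings"]["hr_direction"]
    ref_curves = {ep: WeibullCurve(scale=raw["survival"][ep]["scale"],
                                   shape=raw["survival"][ep]["shape"])
                  for ep in ("pfs", "os")}
    comp_curves = {ep: adjust_curve_by_hr(ref_curves[ep],
                                          raw["hazard_ratios"][ep]["baseline"],
                                          direction=direction)
                   for ep in ("pfs", "os")}
    return {ref: (ref_curves["pfs"], ref_curves["os"]),
            comp: (comp_curves["pfs"], comp_curves["os"])}


def build_strategies(raw: dict) -> dict:
    drug_costs = {d: node["baseline"] for d, node in raw["drug_costs"].items()}
    out = {}
    for name, snode in raw["strategies"].items():
        aes = tuple(
            AdverseEvent(
                name=ae,
                incidence=node["baseline"],
                cost=raw["ae_costs"][ae]["baseline"],
                disutility=raw["disutilities"][ae]["baseline"],
            )
            for ae, node in snode["ae_incidence"].items()
        )
        out[name] = StrategySpec(
            name=name,
            induction=tuple((d, drug_costs[d]) for d in snode["induction"]),
            maintenance=(snode["maintenance"], drug_costs[snode["maintenance"]]),
            maintenance_cap_months=snode["maintenance_cap_months"],
            adverse_events=aes,
            pfs_utility=raw["utilities"]["pfs"]["baseline"],
            pd_utility=raw["utilities"]["pd"]["baseline"],
        )
    return out


@dataclass(frozen=True)
class BaseCaseResult:
    """Everything the deterministic model produces for one configuration."""

    settings: ModelSettings
    traces: dict            # arm -> SurvivalTrace
    results: dict           # arm -> CEResult
    incremental: IncrementalReport


def evaluate_base_case(config: AnalysisConfig | dict) -> BaseCaseResult:
    """Run the deterministic model for a configuration.

    Accepts either a validated :class:`AnalysisConfig` or a raw mapping
    (already-validated copies perturbed by the sensitivity analyses skip
    re-validation for speed).
    """
    raw = config.raw if isinstance(config, AnalysisConfig) else config
    settings = build_settings(raw)
    curves = build_curves(raw)
    strategies = build_strategies(raw)
    traces = {}
    results = {}
    for arm, (pfs_c, os_c) in curves.items():
        trace = build_trace(pfs_c, os_c, settings)
        traces[arm] = trace
        results[arm] = evaluate_strategy(trace, strategies[arm], settings)
    ref = raw["metadata"]["reference"]
    comp = raw["metadata"]["comparator"]
    incremental = compute_icer(results[ref], results[comp])
    return BaseCaseResult(settings=settings, traces=traces, results=results,
                          incremental=incremental)
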