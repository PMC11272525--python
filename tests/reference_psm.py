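"""Independently coded brute-force reference for the partitioned survival
engine.

Deliberately written as a single plain-Python per-cycle loop with no
shared code or numpy: same documented conventions (midpoint or start
evaluation, per-cycle or one-off adverse-event accrual, divide or multiply
hazard-ratio direction), different implementation.  Used only to
cross-check the vectorized engine.
"""

import math

DAYS_PER_MONTH = 365.25 / 12.0


def reference_evaluate(raw):
    """Evaluate both arms of a raw configuration mapping.

    Returns {arm: {ly, pf_ly, pd_ly, qaly, pfs_qaly, pd_qaly,
    total_cost, drug_cost, ae_cost}}.
    """
    st = raw["settings"]
    mpc = st["cycle_length_days"] / DAYS_PER_MONTH
    disc = st["annual_discount"]["baseline"]
    n_cycles = st["n_cycles"]
    midpoint = st["cycle_eval"] == "midpoint"
    ref = raw["metadata"]["reference"]
    comp = raw["metadata"]["comparator"]
    u_pfs = raw["utilities"]["pfs"]["baseline"]
    u_pd = raw["utilities"]["pd"]["baseline"]

    out = {}
    for arm in (ref, comp):
        lam = {ep: raw["survival"][ep]["scale"] for ep in ("pfs", "os")}
        gam = {ep: raw["survival"][ep]["shape"] for ep in ("pfs", "os")}
        if arm == comp:
            for ep in ("pfs", "os"):
                hr = raw["hazard_ratios"][ep]["baseline"]
                lam[ep] = lam[ep] / hr if st["hr_direction"] == "divide" \
                    else lam[ep] * hr

        snode = raw["strategies"][arm]
        induction_cost = sum(raw["drug_costs"][d]["baseline"]
                             for d in snode["induction"])
        maint_cost = raw["drug_costs"][snode["maintenance"]]["baseline"]
        cap_cycles = math.floor(snode["maintenance_cap_months"] / mpc)
        ae_cost_cycle = 0.0
        ae_disutil = 0.0
        for ae, node in snode["ae_incidence"].items():
            ae_cost_cycle += node["baseline"] * raw["ae_costs"][ae]["baseline"]
            ae_disutil += node["baseline"] * raw["disutilities"][ae]["baseline"]

        acc = dict(ly=0.0, pf_ly=0.0, pd_ly=0.0, qaly=0.0, pfs_qaly=0.0,
                   pd_qaly=0.0, total_cost=0.0, drug_cost=0.0, ae_cost=0.0)
        for i in range(n_cycles):
            t = (i + 0.5) * mpc if midpoint else i * mpc
            s_pfs = math.exp(-lam["pfs"] * t ** gam["pfs"])
            s_os = math.exp(-lam["os"] * t ** gam["os"])
            pfs = min(s_pfs, s_os)
            pd = s_os - pfs
            w = (1.0 + disc) ** (-(t / 12.0))
            dt = mpc / 12.0

            acc["pf_ly"] += pfs * dt * w
            acc["pd_ly"] += pd * dt * w
            if st["ae_disutility_mode"] == "per_cycle" or i < 6:
                u_eff = max(u_pfs - ae_disutil, 0.0)
            else:
                u_eff = u_pfs
            acc["pfs_qaly"] += pfs * u_eff * dt * w
            acc["pd_qaly"] += pd * u_pd * dt * w

            if i < 6:
                acc["drug_cost"] += induction_cost * pfs * w
            elif i < cap_cycles:
                acc["drug_cost"] += maint_cost * pfs * w
            if st["ae_cost_mode"] == "per_cycle":
                acc["ae_cost"] += ae_cost_cycle * pfs * w
        if st["ae_cost_mode"] == "one_off":
            acc["ae_cost"] = ae_cost_cycle
        acc["ly"] = acc["pf_ly"] + acc["pd_ly"]
        acc["qaly"] = acc["pfs_qaly"] + acc["pd_qaly"]
        acc["total_cost"] = acc["drug_cost"] + acc["ae_cost"]
        out[arm] = acc
    return out
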