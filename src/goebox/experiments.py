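"""Scenario-sweep experiments, delay curves, tipping analysis, calibration.

Three experiment families:

* the nominal chronology (N2 fixation 3.8 Ga, oxygenic photosynthesis
  3.5 Ga) and its oxygenation diagnostics;
* the metabolic-onset sweep: three fixation cases x six photosynthesis
  onsets, yielding the delay-versus-onset-age curves;
* the phosphorus sweep: mantle-P multipliers {0.5, 1, 2} x six onsets,
  yielding the surface-P tipping point for rapid oxygenation.

``calibrate`` pins the model's free constants to printed anchor values of
the oxygenation chronology with a derivative-free simplex search; the
shipped defaults in :class:`~goebox.params.Params` are the result of that
procedure and are treated as frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import diagnostics as diag
from .engine import run, RunResult
from .params import Params
from .scenario import Scenario, nominal_scenario, fig2_grid, fig3_grid

#: Oxygenation delay below which a scenario counts as "rapidly oxygenating"
#: in the tipping analysis: one metabolic ramp duration.  Delay is measured
#: from the very start of the logistic expansion, and the detector adds its
#: 10-Myr debounce, so even the limiting instant case registers ~60-70 Myr;
#: a GOE completed within the ramp is "negligible" delay.
RAPID_DELAY_YR = 1.0e8


@dataclass
class DelayCurve:
    """Delay between oxygenesis onset and oxygenation, per scenario group."""

    label: str
    entries: pd.DataFrame          # op_onset_ga, delay_yr, goe_age_ga, scenario_id
    non_oxygenating: list = field(default_factory=list)


def _delay_curve(label: str, results: Sequence[RunResult]) -> DelayCurve:
    rows, missing = [], []
    for res in results:
        if res.events:
            ev = res.events[0]
            rows.append({"op_onset_ga": res.scenario.t_op_on,
                         "delay_yr": ev.delay,
                         "goe_age_ga": ev.age_goe,
                         "scenario_id": res.scenario.id})
        else:
            missing.append(res.scenario.id)
    df = pd.DataFrame(rows, columns=["op_onset_ga", "delay_yr",
                                     "goe_age_ga", "scenario_id"])
    return DelayCurve(label=label, entries=df, non_oxygenating=missing)


def run_grid(grid: Iterable[Scenario], progress: bool = False) -> list[RunResult]:
    out = []
    for sc in grid:
        if progress:
            print(f"  running {sc.id} ...", flush=True)
        out.append(run(sc))
    return out


def analyze_fig2(results: Sequence[RunResult]) -> dict:
    """Delay curves per fixation case from finished metabolic-onset runs."""
    curves = {}
    for label in ("eofix", "paleofix", "nofix"):
        members = [r for r in results if r.scenario.id.startswith(label)]
        if members:
            curves[label] = _delay_curve(label, members)
    return curves


def run_fig2(grid: Optional[Sequence[Scenario]] = None, progress: bool = False):
    """Metabolic-onset experiment: returns (results, {fixation case -> DelayCurve})."""
    grid = list(grid) if grid is not None else fig2_grid()
    results = run_grid(grid, progress)
    return results, analyze_fig2(results)


def surface_P_at_onset(res: RunResult) -> float:
    """Surface-P percent of modern at the oxygenesis onset age."""
    i = int(np.argmin(np.abs(res.t - res.scenario.t_op_model)))
    return float(res.diagnostics["surface_P_pct"].iloc[i])


@dataclass
class TippingAnalysis:
    """Surface-P threshold separating rapid from delayed oxygenation."""

    table: pd.DataFrame            # one row per scenario
    tipping_fraction_pct: Optional[float]   # min surface-P% among rapid scenarios

    @property
    def rapid(self) -> pd.DataFrame:
        return self.table[self.table["rapid"]]


def analyze_fig3(results: Sequence[RunResult]):
    """Delay curves per P multiplier plus the tipping analysis."""
    curves = {}
    for mult in sorted({r.scenario.p_multiplier for r in results}):
        members = [r for r in results if r.scenario.p_multiplier == mult]
        curves[mult] = _delay_curve(f"p{mult:g}", members)

    rows = []
    for res in results:
        ev = res.events[0] if res.events else None
        delay = ev.delay if ev else np.inf
        rows.append({
            "scenario_id": res.scenario.id,
            "p_multiplier": res.scenario.p_multiplier,
            "op_onset_ga": res.scenario.t_op_on,
            "surface_P_pct_at_onset": surface_P_at_onset(res),
            "delay_yr": delay,
            "goe_age_ga": ev.age_goe if ev else np.nan,
            "rapid": bool(delay < RAPID_DELAY_YR),
        })
    table = pd.DataFrame(rows)
    rapid = table[table["rapid"]]
    tipping = (float(rapid["surface_P_pct_at_onset"].min())
               if len(rapid) else None)
    return curves, TippingAnalysis(table=table, tipping_fraction_pct=tipping)


def run_fig3(grid: Optional[Sequence[Scenario]] = None, progress: bool = False):
    """Phosphorus experiment: returns (results, {p_multiplier -> DelayCurve},
    TippingAnalysis)."""
    grid = list(grid) if grid is not None else fig3_grid()
    results = run_grid(grid, progress)
    curves, tipping = analyze_fig3(results)
    return results, curves, tipping


# ---------------------------------------------------------------------------
# calibration

@dataclass(frozen=True)
class Anchor:
    """One printed quantity the calibrated model must reproduce."""

    name: str
    target: float
    tolerance: float               # |log(value/target)| accepted, or abs for log-type
    weight: float = 1.0
    log: bool = True               # compare in log space


def nominal_anchor_values(params: Params) -> dict:
    """Compute the anchor quantities from a nominal run with ``params``."""
    res = run(nominal_scenario(params=params))
    d = res.diagnostics
    age = res.age_ga
    out = {}
    ev = res.events[0] if res.events else None
    out["goe_age_ga"] = ev.age_goe if ev else 0.0

    fix_win = (age <= 3.0) & (age >= 2.5)
    out["fix_plateau"] = float(d["fix_bio"].to_numpy()[fix_win].mean())

    remin_win = (age <= 3.4) & (age >= 2.5)
    out["deep_remin_pct"] = float(np.nanmean(d["deep_remin_pct"].to_numpy()[remin_win]))

    p_pct = d["surface_P_pct"].to_numpy()
    above = np.flatnonzero(p_pct >= 20.0)
    out["p20_age_ga"] = float(age[above[0]]) if len(above) else 0.0

    ratio_win = (age <= 3.3) & (age >= 2.6)
    f = res.fluxes
    o2_rel = np.maximum(f["o2_airsea"].to_numpy(), 1.0)
    out["ch4_o2_ratio"] = float(
        (f["ch4_bio"].to_numpy()[ratio_win] / o2_rel[ratio_win]).mean())

    npp_r = d["npp"].to_numpy() / np.maximum(d["r"].to_numpy(), 1.0)
    out["log10_npp_over_r"] = float(np.log10(npp_r[ratio_win]).mean())
    return out


DEFAULT_ANCHORS = (
    Anchor("goe_age_ga", 2.4, tolerance=np.log(2.5 / 2.4), weight=3.0),
    Anchor("fix_plateau", 1.0e13, tolerance=np.log(2.0)),
    Anchor("deep_remin_pct", 94.0, tolerance=np.log(96.0 / 94.0)),
    Anchor("p20_age_ga", 3.25, tolerance=np.log(3.35 / 3.25), weight=3.0),
    Anchor("ch4_o2_ratio", 0.5, tolerance=np.log(0.6 / 0.5)),
    Anchor("log10_npp_over_r", 2.15, tolerance=0.15, log=False),
)

#: Free parameters of the standard calibration and their search bounds.
DEFAULT_FREE_PARAMS = {
    "r0": (5e13, 4e14),
    "tau_r": (2.5e9, 8e9),
    "k_ox": (5e2, 1e5),
    "k_erupt": (1e-11, 2e-10),
    "k_w_P": (5e-10, 2e-8),
    "k_rem_anaer_deep": (0.02, 0.4),
    "beta_anox": (0.1, 1.0),
    "fix_max": (5e12, 1e14),
}


@dataclass
class CalibrationReport:
    fitted: dict
    residuals: pd.DataFrame        # anchor, target, value, log_residual, ok
    converged: bool
    n_evaluations: int

    @property
    def all_ok(self) -> bool:
        return bool(self.residuals["ok"].all())


def calibrate(anchors: Sequence[Anchor] = DEFAULT_ANCHORS,
              free_params: Optional[dict] = None,
              params0: Optional[Params] = None,
              compute_values: Callable[[Params], dict] = nominal_anchor_values,
              max_evaluations: int = 60) -> CalibrationReport:
    """Fit the free constants to the anchor set.

    Derivative-free Nelder-Mead in log-parameter space minimizing the
    weighted squared residuals (log space unless an anchor says otherwise);
    deterministic given a fixed starting point.  With the shipped defaults
    the starting point already satisfies every anchor and the search is a
    cheap fixed-point confirmation.
    """
    free_params = dict(free_params or DEFAULT_FREE_PARAMS)
    params0 = params0 or Params()
    names = list(free_params)
    x0 = np.array([np.log(getattr(params0, n)) for n in names])
    lo = np.array([np.log(free_params[n][0]) for n in names])
    hi = np.array([np.log(free_params[n][1]) for n in names])

    evals = {"n": 0}

    def make_params(x) -> Params:
        x = np.clip(x, lo, hi)
        return params0.replace(**{n: float(np.exp(v)) for n, v in zip(names, x)})

    def residuals_for(values) -> list:
        rows = []
        for a in anchors:
            v = values.get(a.name, np.nan)
            if a.log:
                resid = (np.log(max(v, 1e-300) / a.target)
                         if np.isfinite(v) and v > 0 else 1e3)
            else:
                resid = v - a.target if np.isfinite(v) else 1e3
            rows.append((a, v, float(resid)))
        return rows

    def objective(x) -> float:
        evals["n"] += 1
        try:
            values = compute_values(make_params(x))
        except Exception:
            return 1e6
        return sum(a.weight * r * r for a, _, r in residuals_for(values))

    f0 = objective(x0)
    rows0 = residuals_for(compute_values(make_params(x0)))
    if all(abs(r) <= a.tolerance for a, _, r in rows0):
        # fixed point: anchors already satisfied, nothing to fit
        best_x, converged = x0, True
    else:
        opt = minimize(objective, x0, method="Nelder-Mead",
                       options={"maxfev": max_evaluations, "xatol": 0.02,
                                "fatol": 1e-4})
        best_x = opt.x if opt.fun <= f0 else x0
        converged = bool(opt.success or opt.fun < f0)

    best_params = make_params(best_x)
    rows = residuals_for(compute_values(best_params))
    table = pd.DataFrame(
        [{"anchor": a.name, "target": a.target, "value": v,
          "residual": r, "tolerance": a.tolerance, "ok": abs(r) <= a.tolerance}
         for a, v, r in rows])
    fitted = {n: getattr(best_params, n) for n in names}
    return CalibrationReport(fitted=fitted, residuals=table,
                             converged=converged, n_evaluations=evals["n"])


# ---------------------------------------------------------------------------
# summary

def summarize(results: Sequence[RunResult]) -> pd.DataFrame:
    """One summary row per finished run (machine-readable report table)."""
    rows = []
    for res in results:
        ev = res.events[0] if res.events else None
        d = res.diagnostics
        age = res.age_ga
        pre = (age <= 3.4) & (age >= 2.5)
        rows.append({
            "scenario_id": res.scenario.id,
            "t_fix_on": res.scenario.t_fix_on,
            "t_op_on": res.scenario.t_op_on,
            "p_multiplier": res.scenario.p_multiplier,
            "goe_age_ga": ev.age_goe if ev else np.nan,
            "delay_yr": ev.delay if ev else np.nan,
            "oxic_reached": bool(ev.oxic_reached) if ev else False,
            "max_pO2": float(d["pO2"].max()),
            "deep_remin_pct_pre": float(np.nanmean(d["deep_remin_pct"].to_numpy()[pre]))
                                  if pre.any() else np.nan,
            "surface_P_pct_at_onset": surface_P_at_onset(res),
        })
    return pd.DataFrame(rows)
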