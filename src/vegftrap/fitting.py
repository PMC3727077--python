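"""Bounded weighted least-squares parameter estimation with multi-start.

The objective is the weighted sum of squared residuals

    WSSR(theta) = sum_i W_i (C_exp,i - C_sim,i(theta))^2,   W_i = 1 / C_exp,i,

over pooled plasma time-course measurements (free VEGF Trap and the
mouse-VEGF/Trap and human-VEGF/Trap complexes, across dose levels). The
minimization uses scipy's trust-region-reflective ``least_squares`` with box
bounds; optimization is carried out in log10 parameter space (rates span
orders of magnitude), with the bounds mapped accordingly. A multi-start
protocol draws starting points log-uniformly within the bounds and reports
the mean and standard deviation of the converged optima.
"""

from __future__ import annotations

import copy
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .config import set_param
from .engine import CompiledModel, DoseSchedule

__all__ = [
    "FreeParameter",
    "FitProblem",
    "FitResult",
    "PARAMETER_PRESETS",
    "wssr",
    "fit",
    "sweep",
]

log = logging.getLogger(__name__)

OBSERVABLES = ("trap_free", "trap_mVEGF", "trap_hVEGF")

#: published fitting bounds: secretion rates 1.5e-6 .. 2 molecules/cell/s
#: (lower bound = 10 pg/ml ELISA detection limit); clearances one order of
#: magnitude around ln2/72h = 1.6e-4 min^-1; Trap Kd 0.25 .. 5 pM; normal
#: Trap permeability one order around 3e-8 cm/s.
_CLEAR0 = 1.6e-4 / 60.0  # s^-1
_TRAP_KON = 1.0e7  # M^-1 s^-1 (koff = Kd * kon)
PARAMETER_PRESETS: dict[str, tuple[str, float, float]] = {
    "q_muscle": ("secretion.q_muscle_molecules_per_cell_s", 1.5e-6, 2.0),
    "q_EC": ("secretion.q_ec_molecules_per_cell_s", 1.5e-6, 2.0),
    "q_tumor": ("secretion.q_tumor_molecules_per_cell_s", 1.5e-6, 2.0),
    "c_trap": ("transport.clearance_per_s.Trap", _CLEAR0 / 10.0, _CLEAR0 * 10.0),
    "c_trap_complex": ("transport.clearance_per_s.Trap_V", _CLEAR0 / 10.0, _CLEAR0 * 10.0),
    "kd_trap": (
        "kinetics.Trap:V.koff_per_s",
        0.25e-12 * _TRAP_KON,
        5.0e-12 * _TRAP_KON,
    ),
    "kp_trap_normal": ("transport.permeability_cm_per_s.normal.Trap", 3.0e-9, 3.0e-7),
}


@dataclass(frozen=True)
class FreeParameter:
    """One free parameter: a dotted config path with finite box bounds."""

    name: str
    path: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ValueError(f"{self.name}: bounds must be finite")
        if not (0 < self.lower < self.upper):
            raise ValueError(f"{self.name}: need 0 < lower < upper for log-scale fitting")

    @staticmethod
    def preset(name: str) -> "FreeParameter":
        path, lo, hi = PARAMETER_PRESETS[name]
        return FreeParameter(name, path, lo, hi)


@dataclass
class FitProblem:
    """Dataset plus model context for WSSR minimization.

    ``data`` columns: time_days (from first injection), dose_mg_per_kg,
    observable in {trap_free, trap_mVEGF, trap_hVEGF}, value_pM (> 0, since
    the weights are 1/value).
    """

    base_config: dict
    free: tuple[FreeParameter, ...]
    data: pd.DataFrame
    schedule_times_days: tuple[float, ...] = (0.0, 3.5, 7.0, 10.5)
    sim_rtol: float = 1e-6
    failure_penalty: float = 1e6

    def __post_init__(self) -> None:
        required = {"time_days", "dose_mg_per_kg", "observable", "value_pM"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"dataset missing columns {sorted(missing)}")
        if (self.data["value_pM"] <= 0).any():
            raise ValueError("all experimental values must be > 0 (weights are 1/C)")
        bad = set(self.data["observable"]) - set(OBSERVABLES)
        if bad:
            raise ValueError(f"unknown observables {sorted(bad)}")
        if not self.free:
            raise ValueError("no free parameters")

    @property
    def theta0(self) -> np.ndarray:
        from .config import get_param

        return np.array([get_param(self.base_config, p.path) for p in self.free])


class _Simulator:
    """Residual evaluator with warm-started pre-equilibration."""

    def __init__(self, problem: FitProblem):
        self.problem = problem
        self.doses = sorted(problem.data["dose_mg_per_kg"].unique())
        self.warm_ss: np.ndarray | None = None
        self.n_eval = 0

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        p = self.problem
        self.n_eval += 1
        cfg = copy.deepcopy(p.base_config)
        for fp, value in zip(p.free, theta):
            set_param(cfg, fp.path, float(value))
        try:
            model = CompiledModel.from_config(cfg)
            y_ss = model.steady_state(y0=self.warm_ss)
            self.warm_ss = y_ss
            y_trig = model.state_at_trigger(y_ss, rtol=p.sim_rtol)
            res = []
            for dose in self.doses:
                sub = p.data[p.data["dose_mg_per_kg"] == dose]
                times = np.array(sorted(sub["time_days"].unique()))
                sim = model.simulate(
                    schedule=DoseSchedule(dose, p.schedule_times_days),
                    t_out_days=times,
                    y_at_trigger=y_trig,
                    horizon_days=float(times.max()),
                    rtol=p.sim_rtol,
                )
                for _, row in sub.iterrows():
                    i = int(np.argmin(np.abs(sim.t_days - row["time_days"])))
                    c_sim = sim.observable(row["observable"])[i]
                    w = 1.0 / row["value_pM"]
                    res.append(np.sqrt(w) * (row["value_pM"] - c_sim))
            return np.asarray(res)
        except Exception as exc:  # noqa: BLE001 — penalize, log, keep optimizing
            log.warning("simulation failed at theta=%s: %s", theta, exc)
            return np.full(len(p.data), np.sqrt(p.failure_penalty / len(p.data)))


def wssr(theta: np.ndarray, problem: FitProblem,
         simulator: _Simulator | None = None) -> float:
    """Weighted sum of squared residuals at one parameter vector."""
    sim = simulator or _Simulator(problem)
    r = sim.residuals(np.asarray(theta, dtype=float))
    return float(np.dot(r, r))


@dataclass
class FitResult:
    runs: pd.DataFrame  # one row per start: theta*, wssr, success, nfev, at_bound
    free: tuple[FreeParameter, ...]
    n_converged: int
    mean: dict[str, float]
    sd: dict[str, float]
    best: dict[str, float]
    best_wssr: float

    def summary(self) -> pd.DataFrame:
        rows = [
            (fp.name, self.mean[fp.name], self.sd[fp.name], self.best[fp.name],
             fp.lower, fp.upper)
            for fp in self.free
        ]
        return pd.DataFrame(
            rows, columns=["parameter", "mean", "sd", "best", "lower", "upper"]
        )


def fit(problem: FitProblem, n_starts: int = 20, seed: int = 0,
        ftol: float = 1e-8, xtol: float = 1e-8, max_nfev: int | None = None) -> FitResult:
    """Multi-start bounded trust-region-reflective least squares.

    Starting points are drawn log-uniformly within the bounds under ``seed``.
    Non-convergent runs are excluded from the mean/SD but reported.
    """
    rng = np.random.default_rng(seed)
    lo = np.log10([fp.lower for fp in problem.free])
    hi = np.log10([fp.upper for fp in problem.free])
    sim = _Simulator(problem)

    def residuals_log(z: np.ndarray) -> np.ndarray:
        return sim.residuals(10.0**z)

    rows = []
    for run in range(n_starts):
        z0 = rng.uniform(lo, hi)
        t0 = time.perf_counter()
        try:
            out = least_squares(
                residuals_log, z0, bounds=(lo, hi), method="trf",
                ftol=ftol, xtol=xtol, gtol=1e-10,
                diff_step=1e-3, max_nfev=max_nfev,
            )
            theta = 10.0**out.x
            cost = 2.0 * out.cost  # least_squares cost = 0.5 * sum r^2
            success = bool(out.success)
            nfev = out.nfev
        except Exception as exc:  # noqa: BLE001
            log.warning("run %d failed: %s", run, exc)
            theta = np.full(len(problem.free), np.nan)
            cost, success, nfev = np.nan, False, 0
        at_bound = [
            bool(np.isfinite(t) and (np.isclose(np.log10(t), l, atol=1e-6)
                                     or np.isclose(np.log10(t), h, atol=1e-6)))
            for t, l, h in zip(theta, lo, hi)
        ]
        row = {"run": run, "wssr": cost, "success": success, "nfev": nfev,
               "seconds": time.perf_counter() - t0, "at_bound": any(at_bound)}
        for fp, val, ab in zip(problem.free, theta, at_bound):
            row[fp.name] = val
            row[f"{fp.name}_at_bound"] = ab
        rows.append(row)
    runs = pd.DataFrame(rows)
    ok = runs[runs["success"]]
    if ok.empty:
        raise RuntimeError(
            "all optimization runs failed; per-run diagnostics:\n"
            + runs.to_string(index=False)
        )
    names = [fp.name for fp in problem.free]
    best_row = ok.loc[ok["wssr"].idxmin()]
    return FitResult(
        runs=runs,
        free=problem.free,
        n_converged=int(ok.shape[0]),
        mean={n: float(ok[n].mean()) for n in names},
        sd={n: float(ok[n].std(ddof=1)) if len(ok) > 1 else 0.0 for n in names},
        best={n: float(best_row[n]) for n in names},
        best_wssr=float(best_row["wssr"]),
    )


def sweep(parameter_path: str, values, problem: FitProblem,
          observables: tuple[str, ...] = ("trap_free", "trap_mVEGF"),
          trajectory_times_days: np.ndarray | None = None,
          ) -> tuple[pd.DataFrame, dict[float, pd.DataFrame]]:
    """Fit-quality curve: WSSR and observable trajectories vs one parameter.

    All other parameters stay at their configured values; this is the
    one-at-a-time identifiability sweep (e.g. muscle secretion 0 -> 0.02
    molecules/cell/s while endothelial secretion dominates). Returns the
    (value, wssr) curve and, per swept value, a long-format trajectory table.
    An empty value list yields an empty curve.
    """
    rows = []
    trajectories: dict[float, pd.DataFrame] = {}
    doses = sorted(problem.data["dose_mg_per_kg"].unique())
    if trajectory_times_days is None:
        t_max = float(problem.data["time_days"].max())
        trajectory_times_days = np.linspace(0.0, t_max, 29)
    for v in values:
        cfg = copy.deepcopy(problem.base_config)
        set_param(cfg, parameter_path, float(v))
        prob_v = FitProblem(
            base_config=cfg,
            free=problem.free,
            data=problem.data,
            schedule_times_days=problem.schedule_times_days,
            sim_rtol=problem.sim_rtol,
        )
        sim = _Simulator(prob_v)
        w = wssr(prob_v.theta0, prob_v, sim)
        rows.append({"value": float(v), "wssr": w})
        model = CompiledModel.from_config(cfg)
        y_trig = model.state_at_trigger(rtol=problem.sim_rtol)
        traj_rows = []
        for dose in doses:
            res = model.simulate(
                schedule=DoseSchedule(dose, problem.schedule_times_days),
                t_out_days=trajectory_times_days,
                y_at_trigger=y_trig,
                horizon_days=float(trajectory_times_days.max()),
                rtol=problem.sim_rtol,
            )
            for obs in observables:
                series = res.observable(obs)
                for t, c in zip(res.t_days, series):
                    traj_rows.append((float(dose), obs, float(t), float(c)))
        trajectories[float(v)] = pd.DataFrame(
            traj_rows, columns=["dose_mg_per_kg", "observable", "time_days", "value_pM"]
        )
    return pd.DataFrame(rows, columns=["value", "wssr"]), trajectories
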