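"""End-to-end orchestration: trend analysis (H1), homogeneous-Poisson
battery on the split series (H2), and the simulation comparison study.

Each stage returns a plain dict report and can write it as CSV + JSON
so downstream plotting is optional.  All randomness flows from the
config seed; re-running with the same input, config and seed produces
identical reports.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import core_events as ce
from . import intensity_trend as it
from . import distribution_tests as dt
from . import poisson_fit as pf
from . import dependence as dep
from . import compare as cmp
from . import simulate as sim

log = logging.getLogger("copycatdetect")

__all__ = ["AnalysisConfig", "run_h1", "run_h2", "run_simulation_study",
           "make_synthetic_events", "write_report"]


@dataclass
class AnalysisConfig:
    input_path: str | None = None
    window_start: str | None = None
    window_end: str | None = None
    ma_windows: tuple[int, ...] = it.MA_WINDOWS
    lb_lags: tuple[int, ...] = dep.DEFAULT_LAGS
    delta_grid: tuple[float, ...] = sim.DELTA_GRID
    r_grid: tuple[int, ...] = sim.R_GRID
    n_runs: int = 500
    alpha: float = 0.05
    seed: int = 0
    split_day: int | None = None  # override the detected change-point
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        for name in ("ma_windows", "lb_lags", "delta_grid", "r_grid"):
            if not tuple(getattr(self, name)):
                raise ValueError(f"{name} must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def load_series(config: AnalysisConfig) -> ce.DailyCountSeries:
    cal = ce.parse_event_dates(config.input_path,
                               window_start=config.window_start,
                               window_end=config.window_end)
    return ce.to_daily_counts(cal)


def make_synthetic_events(kind: str = "two_segment", seed: int = 0,
                          T: int = 4018) -> ce.DailyCountSeries:
    """Demo inputs so the whole pipeline runs without any download.

    kinds: "homogeneous" (rate 0.163), "two_segment" (0.19 for the
    first 1811 days then 0.14 — the shape of the study series) and
    "copycat" (delta = 1, r = 7 on base 0.163).
    """
    rng = np.random.default_rng(seed)
    if kind == "homogeneous":
        s = sim.simulate_homogeneous(0.163, T, rng)
    elif kind == "two_segment":
        t1 = min(1811, T - 1)
        a = sim.simulate_homogeneous(0.19, t1, rng)
        b = sim.simulate_homogeneous(0.14, T - t1, rng)
        s = ce.DailyCountSeries(counts=np.concatenate([a.counts, b.counts]))
    elif kind == "copycat":
        s = sim.simulate_copycat(
            sim.CopycatParams(delta=1.0, r=7, base_lambda=0.163, T=T), rng)
    else:
        raise ValueError(f"unknown synthetic kind {kind!r}")
    return ce.DailyCountSeries(counts=s.counts, origin_date=_dt.date(2007, 1, 1))


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            out = fn(*args, **kwargs)
            log.info("stage %s finished in %.1fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("h1")
def run_h1(series: ce.DailyCountSeries, config: AnalysisConfig) -> dict:
    """Trend and change-point analysis of the full series.

    Emits the uniformity/runs p-values, Dunn pairwise tables per
    grouping scheme, and per-MA-window change-point and Cox-Stuart
    trend rows.
    """
    if series.total < 30:
        raise ValueError("fewer than 30 events: trend tests are underpowered")
    uniformity = {m: dt.uniformity_test(series, m).as_dict()
                  for m in dt.UNIFORMITY_METHODS}
    runs = dt.runs_test(series.binarize()).as_dict()
    dunn = {}
    if series.origin_date is not None:
        for scheme in ce.GROUPING_SCHEMES:
            table = dt.dunn_test(ce.group_counts(series, scheme))
            dunn[scheme] = {
                "kruskal_p": table.kruskal_p,
                "significant_pairs": table.significant_pairs(config.alpha),
                "pairs": table.as_rows(),
            }
    changepoints, trend = [], []
    for s in config.ma_windows:
        if s >= series.T:
            continue
        est = it.moving_average_intensity(series, s)
        cp = it.changepoint_on_intensity(est, alpha=config.alpha)
        changepoints.append({"ma_window": s, "tau_day": cp.tau,
                             "pre_mean": cp.pre_mean, "post_mean": cp.post_mean,
                             "significant": cp.significant,
                             "method": "amoc_meanvar"})
        cs = it.cox_stuart_test(est.values, alternative="decreasing")
        trend.append({"ma_window": s, "trend_p": cs.p_value,
                      "method": "cox_stuart_decreasing"})
    return {"uniformity": uniformity, "runs": runs, "dunn": dunn,
            "changepoints": changepoints, "trend": trend}


@_stage("h2")
def run_h2(series: ce.DailyCountSeries, config: AnalysisConfig,
           split_day: int | None = None) -> dict:
    """Homogeneous-Poisson battery on the full series and its two halves."""
    if split_day is None:
        split_day = config.split_day
    if split_day is None:
        # reuse the H1 change-point at the mid-range MA window
        s_mid = sorted(config.ma_windows)[len(config.ma_windows) // 2]
        est = it.moving_average_intensity(series, min(s_mid, 2 * (series.T // 4)))
        split_day = it.changepoint_on_intensity(est).tau
    n1, n2 = ce.split_at(series, split_day)
    report: dict = {"split_day": split_day, "frequency_tables": {},
                    "battery": {}, "merged_geometric": {}, "ljung_box": {},
                    "acf": {}}
    for label, part in (("N", series), ("N1", n1), ("N2", n2)):
        report["frequency_tables"][label] = pf.observed_frequencies(part).as_rows()
        report["battery"][label] = cmp.h2_battery(part, lb_lags=())
        lam = pf.estimate_rate(part).lambda_hat
        try:
            merged = pf.geometric_gof(
                ce.inter_arrival_times(part),
                pf.GeometricFit.from_rate(lam, merge_first_two=True))
            report["merged_geometric"][label] = merged.p_value
        except ValueError:
            report["merged_geometric"][label] = float("nan")
        gaps = ce.inter_arrival_times(part).gaps
        lb = {}
        for L in config.lb_lags:
            lb[f"events_{L}"] = dep.ljung_box(part.counts, L).p_value
            lb[f"times_{L}"] = dep.ljung_box(gaps, L).p_value if len(gaps) > L else float("nan")
        report["ljung_box"][label] = lb
        L = max(config.lb_lags) * 2
        if part.T > L:
            cg = dep.acf(part.counts, L)
            report["acf"][label] = {"lags": cg.lags.tolist(),
                                    "values": cg.values.tolist(),
                                    "band": cg.band}
    return report


@_stage("simstudy")
def run_simulation_study(series: ce.DailyCountSeries, config: AnalysisConfig,
                         split_day: int | None = None,
                         versus: bool = True) -> dict:
    """The simulation comparison protocol.

    Self-mode median-p tables for the homogeneous processes matched to
    N, N1, N2 and the copycat grids based on the two halves, pooled over
    the r grid at each delta; optionally the versus-mode comparison of
    the real halves against their matched batches.
    """
    rng = np.random.default_rng(config.seed)
    split_day = split_day or config.split_day or 1811
    n1, n2 = ce.split_at(series, split_day)
    lam = {"N": pf.estimate_rate(series).lambda_hat,
           "N1": pf.estimate_rate(n1).lambda_hat,
           "N2": pf.estimate_rate(n2).lambda_hat}
    T = {"N": series.T, "N1": n1.T, "N2": n2.T}

    self_rows, versus_rows = [], []
    for label in ("N", "N1", "N2"):
        spec = {"generator": "homogeneous", "lam": lam[label], "T": T[label],
                "filter_rate": lam[label], "label": f"P_H[{label}]"}
        self_rows += cmp.run_comparison_battery(
            None, spec, n_runs=config.n_runs, seed=rng, mode="self",
            lb_lags=config.lb_lags, alpha=config.alpha).rows
    for base_label, base_series in (("1", n1), ("2", n2)):
        for delta in config.delta_grid:
            spec = {"generator": "copycat", "delta": delta,
                    "r_grid": config.r_grid,
                    "base_lambda": lam[f"N{base_label}"],
                    "T": T[f"N{base_label}"],
                    "label": f"PC_{base_label},{delta}"}
            rep = cmp.run_comparison_battery(
                None, spec, n_runs=config.n_runs, seed=rng, mode="self",
                lb_lags=config.lb_lags, alpha=config.alpha)
            self_rows += rep.rows
            if versus:
                vrep = cmp.run_comparison_battery(
                    base_series, spec, n_runs=config.n_runs, seed=rng,
                    mode="versus", alpha=config.alpha)
                versus_rows += vrep.rows
    if versus:
        for label, part in (("N", series), ("N1", n1), ("N2", n2)):
            spec = {"generator": "homogeneous", "lam": lam[label],
                    "T": T[label], "filter_rate": lam[label],
                    "label": f"{label} vs P_H[{label}]"}
            versus_rows += cmp.run_comparison_battery(
                part, spec, n_runs=config.n_runs, seed=rng,
                mode="versus", alpha=config.alpha).rows
    return {"self_mode": self_rows, "versus_mode": versus_rows,
            "rates": lam, "lengths": T, "split_day": split_day}


def write_report(report: dict, out_dir: str | Path, name: str) -> None:
    """Write a stage report as JSON plus flat CSVs for tabular sections."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / f"{name}.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    for key, value in report.items():
        if isinstance(value, list) and value and isinstance(value[0], dict):
            pd.DataFrame(value).to_csv(out / f"{name}_{key}.csv", index=False)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
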