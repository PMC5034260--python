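"""In-silico experiments: replicate runs, phase summaries, sweeps, regimes.

The paper-style protocol is 10 stochastic replicates of 12 menstrual
cycles per parameter constellation, monitoring relative cell numbers
(immune or damaged counts divided by the epithelial count), the
per-1000-cell proliferation/apoptosis indices, within-cycle amplitudes and
spatial summaries. Parameter sweeps over the damage probability k_dge, the
killing rate k_kill, the hormone level theta and the follicular-phase
length reproduce the regime structure: inflammation is PHYSIOLOGICAL while
epithelial damage grows linearly with k_dge and the infiltrate resolves to
its healthy band every cycle, CHRONIC when the infiltrate never returns to
the healthy band within any cycle, and SEVERE in between.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import hormones
from .engine import Simulation
from .geometry import LatticeDomain
from .params import SimulationParams
from .trafficking import PHASE_WINDOWS, _phase_window_masks

logger = logging.getLogger(__name__)

PHYSIOLOGICAL = "PHYSIOLOGICAL"
SEVERE = "SEVERE"
CHRONIC = "CHRONIC"


@dataclass
class TimeSeries:
    """Per-step population counts and event read-outs of one run."""

    t_h: np.ndarray
    n_epi: np.ndarray
    n_damaged: np.ndarray
    n_dying: np.ndarray
    n_eff_active: np.ndarray
    n_eff_inactive: np.ndarray
    n_reg_active: np.ndarray
    n_reg_inactive: np.ndarray
    div_events: np.ndarray
    apt_events: np.ndarray
    dt: float = 1.0
    snapshots: dict = field(default_factory=dict)

    @property
    def n_eff(self) -> np.ndarray:
        return self.n_eff_active + self.n_eff_inactive

    @property
    def n_reg(self) -> np.ndarray:
        return self.n_reg_active + self.n_reg_inactive

    @property
    def n_immune(self) -> np.ndarray:
        return self.n_eff + self.n_reg

    @property
    def rel_eff(self) -> np.ndarray:
        return self.n_eff / self.n_epi

    @property
    def rel_reg(self) -> np.ndarray:
        return self.n_reg / self.n_epi

    @property
    def rel_immune(self) -> np.ndarray:
        return self.n_immune / self.n_epi

    @property
    def rel_damaged(self) -> np.ndarray:
        return self.n_damaged / self.n_epi

    @property
    def pi_sample(self) -> np.ndarray:
        """Division-clock firings per 1000 epithelial cells per hour."""
        return 1000.0 * self.div_events / (self.n_epi * self.dt)

    @property
    def ai_sample(self) -> np.ndarray:
        """Apoptosis entries per 1000 epithelial cells per hour."""
        return 1000.0 * self.apt_events / (self.n_epi * self.dt)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_h": self.t_h, "n_epi": self.n_epi, "n_damaged": self.n_damaged,
            "n_dying": self.n_dying, "n_eff_active": self.n_eff_active,
            "n_eff_inactive": self.n_eff_inactive, "n_reg_active": self.n_reg_active,
            "n_reg_inactive": self.n_reg_inactive, "div_events": self.div_events,
            "apt_events": self.apt_events, "rel_eff": self.rel_eff,
            "rel_reg": self.rel_reg, "rel_damaged": self.rel_damaged,
            "pi_sample": self.pi_sample, "ai_sample": self.ai_sample,
        })


@dataclass
class RegimeReport:
    """Summary statistics of one parameter point of a sweep."""

    k_dge: float
    k_kill: float
    theta: float
    follicular_len: float
    mean_rel_damaged: float
    mean_rel_immune: float
    sd_rel_immune: float
    max_rel_immune: float
    amplitude_immune: float      # mean over cycles of (max - min) within the cycle
    amplitude_eff: float
    amplitude_reg: float
    reg_minus_eff: float         # mean difference of relative numbers
    cycle_min_infiltrate: np.ndarray  # per-cycle minimum of rel_immune
    n_clusters: float = 0.0
    mean_cluster_size: float = 0.0
    regime: str | None = None
    n_runs_pooled: int = 0
    n_failed: int = 0


def replicate_seed(master_seed: int, rep: int) -> np.random.SeedSequence:
    """Counter-based per-replicate stream: reproducible and parallelizable."""
    return np.random.SeedSequence(master_seed, spawn_key=(rep,))


def run_replicates(
    domain: LatticeDomain,
    params: SimulationParams,
    profile: hormones.HormoneProfile | None = None,
    n_reps: int = 10,
    n_cycles: int = 12,
    master_seed: int = 0,
    snapshot_days: tuple[float, ...] = (),
) -> list[TimeSeries]:
    """Independent seeded replicate runs of ``n_cycles`` menstrual cycles.

    Runs in which the epithelium goes extinct are flagged, excluded and
    logged; at least one replicate must survive. ``snapshot_days`` records
    cell tables at those days of the *last* cycle of each run.
    """
    if profile is None:
        profile = hormones.default_profile()
    profile = profile.with_theta(params.theta)
    per_cycle = int(round(profile.cycle_len_hours / params.dt))
    snap_times = [((n_cycles - 1) * profile.cycle_len_days + d) * 24.0 for d in snapshot_days]
    out, failed = [], 0
    for rep in range(n_reps):
        sim = Simulation(domain, params, profile, seed=replicate_seed(master_seed, rep))
        ts = sim.run(per_cycle * n_cycles, snapshot_times=snap_times)
        if (ts.n_epi == 0).any():
            failed += 1
            logger.warning("replicate %d: epithelial extinction; excluded from pooling", rep)
            continue
        out.append(ts)
    if not out:
        raise RuntimeError("all replicates went extinct; nothing to pool")
    if failed:
        logger.warning("%d/%d replicates excluded (epithelial extinction)", failed, n_reps)
    out[0].snapshots["n_failed"] = failed  # bookkeeping for sweep()
    return out


def pooled_mean(ts_list: list[TimeSeries], attr: str) -> np.ndarray:
    """Pointwise mean of an attribute across replicates."""
    return np.mean([getattr(ts, attr) for ts in ts_list], axis=0)


def phase_means(
    ts_list: TimeSeries | list[TimeSeries],
    cycle_len_days: float = 28.0,
) -> dict:
    """Pooled per-phase means of rel_eff plus the overall mean of rel_reg.

    Phases follow the calibration windows: follicular days 1-11, in-between
    days 11-17, luteal days 17-28 (scaled windows apply only to the 28-day
    cycle; pass the actual cycle length for other cycles).
    """
    if isinstance(ts_list, TimeSeries):
        ts_list = [ts_list]
    sums = {k: 0.0 for k in ("follicular", "inbetween", "luteal", "regulatory_all")}
    counts = {k: 0 for k in sums}
    for ts in ts_list:
        masks = _phase_window_masks(ts.t_h, cycle_len_days)
        for phase in ("follicular", "inbetween", "luteal"):
            sums[phase] += ts.rel_eff[masks[phase]].sum()
            counts[phase] += int(masks[phase].sum())
        sums["regulatory_all"] += ts.rel_reg.sum()
        counts["regulatory_all"] += len(ts.rel_reg)
    return {k: sums[k] / max(counts[k], 1) for k in sums}


def cycle_profile(ts_list: list[TimeSeries], attr: str, cycle_len_hours: float,
                  dt: float = 1.0):
    """Mean of an attribute by hour-of-cycle, pooled over cycles and replicates."""
    n_bins = int(round(cycle_len_hours / dt))
    acc = np.zeros(n_bins)
    cnt = np.zeros(n_bins, dtype=int)
    for ts in ts_list:
        vals = getattr(ts, attr)
        idx = np.rint((np.mod(ts.t_h - dt / 2, cycle_len_hours)) / dt - 0.5).astype(int) % n_bins
        np.add.at(acc, idx, vals)
        np.add.at(cnt, idx, 1)
    hours = (np.arange(n_bins) + 1) * dt
    return hours, acc / np.maximum(cnt, 1)


def pi_ai_readout(ts_list: TimeSeries | list[TimeSeries],
                  cycle_len_hours: float = 28 * 24.0) -> pd.DataFrame:
    """Hour-of-cycle profiles of the simulated PI and AI (per 1000 cells per hour)."""
    if isinstance(ts_list, TimeSeries):
        ts_list = [ts_list]
    dt = ts_list[0].dt
    hours, pi = cycle_profile(ts_list, "pi_sample", cycle_len_hours, dt)
    _, ai = cycle_profile(ts_list, "ai_sample", cycle_len_hours, dt)
    return pd.DataFrame({"hour_of_cycle": hours, "pi_sample": pi, "ai_sample": ai})


def _per_cycle_minima(ts: TimeSeries, cycle_len_hours: float) -> np.ndarray:
    cyc = np.floor((ts.t_h - 1e-9) / cycle_len_hours).astype(int)
    rel = ts.rel_immune
    return np.array([rel[cyc == c].min() for c in range(cyc.max() + 1)])


def _amplitude(ts: TimeSeries, attr: str, cycle_len_hours: float) -> float:
    cyc = np.floor((ts.t_h - 1e-9) / cycle_len_hours).astype(int)
    vals = getattr(ts, attr)
    return float(np.mean([vals[cyc == c].max() - vals[cyc == c].min()
                          for c in range(cyc.max() + 1)]))


def summarize_point(
    ts_list: list[TimeSeries],
    params: SimulationParams,
    follicular_len: float,
    cycle_len_hours: float,
    cluster_min: int = 3,
    domain: LatticeDomain | None = None,
) -> RegimeReport:
    """Condense replicate runs at one parameter point into a RegimeReport."""
    from .spatial import cluster_stats

    n_clusters, csizes = [], []
    for ts in ts_list:
        for key, snap in ts.snapshots.items():
            if key == "n_failed" or snap is None:
                continue
            imm = snap[snap["cell_type"].isin(["EFFECTOR", "REGULATORY"])]
            shape = domain.shape if domain is not None else None
            nc, sizes = cluster_stats(imm[["x", "y"]].to_numpy(), grid_shape=shape,
                                      cluster_min=cluster_min)
            n_clusters.append(nc)
            csizes.extend(sizes)
    minima = np.concatenate([_per_cycle_minima(ts, cycle_len_hours) for ts in ts_list])
    rel_imm = np.concatenate([ts.rel_immune for ts in ts_list])
    return RegimeReport(
        k_dge=params.k_dge, k_kill=params.k_kill, theta=params.theta,
        follicular_len=follicular_len,
        mean_rel_damaged=float(np.mean([ts.rel_damaged.mean() for ts in ts_list])),
        mean_rel_immune=float(rel_imm.mean()),
        sd_rel_immune=float(rel_imm.std()),
        max_rel_immune=float(rel_imm.max()),
        amplitude_immune=float(np.mean([_amplitude(ts, "rel_immune", cycle_len_hours)
                                        for ts in ts_list])),
        amplitude_eff=float(np.mean([_amplitude(ts, "rel_eff", cycle_len_hours)
                                     for ts in ts_list])),
        amplitude_reg=float(np.mean([_amplitude(ts, "rel_reg", cycle_len_hours)
                                     for ts in ts_list])),
        reg_minus_eff=float(np.mean([(ts.rel_reg - ts.rel_eff).mean() for ts in ts_list])),
        cycle_min_infiltrate=minima,
        n_clusters=float(np.mean(n_clusters)) if n_clusters else 0.0,
        mean_cluster_size=float(np.mean(csizes)) if csizes else 0.0,
        n_runs_pooled=len(ts_list),
        n_failed=int(ts_list[0].snapshots.get("n_failed", 0)),
    )


def sweep(
    grid: dict,
    domain: LatticeDomain,
    base_params: SimulationParams,
    profile: hormones.HormoneProfile | None = None,
    n_reps: int = 3,
    n_cycles: int = 6,
    master_seed: int = 0,
    snapshot_days: tuple[float, ...] = (25.0,),
) -> list[RegimeReport]:
    """Run replicates over the Cartesian grid of parameter values.

    ``grid`` maps any of {"k_dge", "k_kill", "theta", "follicular_len"} to a
    list of values; omitted axes use the base parameter/profile values.
    Per-point failures are logged and skipped rather than aborting.
    """
    if profile is None:
        profile = hormones.default_profile()
    axes = {k: list(v) for k, v in grid.items()}
    names = list(axes)
    reports = []
    for combo in itertools.product(*(axes[k] for k in names)):
        point = dict(zip(names, combo))
        foll = point.pop("follicular_len", profile.follicular_len)
        prof = hormones.rescale_follicular(profile, foll)
        p = replace(base_params, **point)
        try:
            ts_list = run_replicates(domain, p, prof, n_reps=n_reps, n_cycles=n_cycles,
                                     master_seed=master_seed, snapshot_days=snapshot_days)
            reports.append(summarize_point(ts_list, p, foll, prof.cycle_len_hours,
                                           domain=domain))
        except Exception:
            logger.exception("sweep point %s failed; continuing", {**point, "follicular_len": foll})
    return reports


def sweep_frame(reports: list[RegimeReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        d = {k: getattr(r, k) for k in (
            "k_dge", "k_kill", "theta", "follicular_len", "mean_rel_damaged",
            "mean_rel_immune", "amplitude_immune", "reg_minus_eff",
            "n_clusters", "mean_cluster_size", "regime")}
        rows.append(d)
    return pd.DataFrame(rows)


def classify_regime(
    report: RegimeReport,
    baseline: RegimeReport,
    linearity_window: list[tuple[float, float]],
    linear_tol: float = 0.10,
    burnin_cycles: int = 1,
) -> str:
    """Three-regime classification of one sweep point.

    PHYSIOLOGICAL: the point's mean damaged fraction lies on the linear
    low-k_dge segment (relative residual from the straight-line fit through
    ``linearity_window`` below ``linear_tol``) AND the infiltrate resolves:
    every cycle's minimum relative infiltrate returns to the healthy band
    (baseline mean + 2 SD). CHRONIC: the cycle minimum exceeds the baseline
    *maximum* in every cycle -- inflammation never resolves. SEVERE:
    everything in between. All runs start from the healthy state, so the
    first ``burnin_cycles`` cycles (during which inflammation is still
    building up) are excluded from the cycle-minimum checks.
    """
    if baseline is None:
        raise ValueError("classify_regime requires the k_dge=0 baseline report")
    pts = np.asarray(sorted(linearity_window))
    if report.k_dge <= 0:
        return PHYSIOLOGICAL
    band_hi = baseline.mean_rel_immune + 2.0 * baseline.sd_rel_immune
    minima = np.asarray(report.cycle_min_infiltrate)
    n_reps = max(report.n_runs_pooled, 1)
    n_cyc = len(minima) // n_reps
    if n_cyc > burnin_cycles:
        keep = np.ones(n_cyc, dtype=bool)
        keep[:burnin_cycles] = False
        minima = minima[np.tile(keep, n_reps)]
    if len(minima) and (minima > baseline.max_rel_immune).all():
        return CHRONIC
    # linearity of damage growth in k_dge
    if len(pts) >= 2:
        slope, intercept = np.polyfit(pts[:, 0], pts[:, 1], 1)
    else:
        slope, intercept = pts[0, 1] / max(pts[0, 0], 1e-12), 0.0
    pred = slope * report.k_dge + intercept
    lin_ok = (abs(report.mean_rel_damaged - pred)
              <= linear_tol * max(abs(pred), 1e-12))
    resolves = bool((minima <= band_hi + 1e-12).all()) if len(minima) else True
    if lin_ok and resolves:
        return PHYSIOLOGICAL
    return SEVERE


def classify_sweep(reports: list[RegimeReport], linear_tol: float = 0.10,
                   n_linear: int = 3) -> list[RegimeReport]:
    """Label every report of a sweep in place (grouped by k_kill, theta, cycle)."""
    key = lambda r: (r.k_kill, r.theta, r.follicular_len)
    groups: dict = {}
    for r in reports:
        groups.setdefault(key(r), []).append(r)
    for grp in groups.values():
        grp.sort(key=lambda r: r.k_dge)
        baseline = next((r for r in grp if r.k_dge == 0), grp[0])
        window = [(r.k_dge, r.mean_rel_damaged) for r in grp[:n_linear]]
        for r in grp:
            r.regime = classify_regime(r, baseline, window, linear_tol)
    return reports
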