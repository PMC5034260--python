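"""Immune cell entry/exit through homogeneously distributed vasculature.

Blood vessels are assumed homogeneously distributed in the stroma, so
immune cells may enter (and leave) the TDLU from any stromal node. Influx
is a domain-level Poisson process whose intensity is linear in the mean
chemokine concentration over stromal nodes; the damaged-cell chemokine
recruits both immune types, the dying-cell "find-me" signal recruits
effectors only. Inactive (and permanently inactivated) immune cells leave
at per-cell rate ``lam_out``; activated cells stay.

RNG draw order inside :func:`apply_trafficking` is documented and stable:
(1) Poisson effector entries, (2) Poisson regulatory entries, (3) placement
draws, (4) one uniform per inactive immune cell for efflux. Tests replay
this stream from a cloned generator state as an independent oracle.

Calibration
-----------
At the healthy baseline (``k_dge = 0``) the epithelial and chemokine
dynamics are entirely independent of the trafficking parameters, and the
expected inactive-pool size obeys the exact linear recursion

    E[N_{k+1}] = E[N_k] * exp(-lam_out*dt) + lambda(t_k)*dt .

:func:`calibrate` exploits this: a single probe run records the mean
dying-cell chemokine and the epithelial count over the cycle; the phase
means of the expected relative effector number are then *linear* in
``(lam0_E, beta_E)`` for each candidate ``lam_out``, so a nonnegative
least-squares solve gives a near-optimal starting point. A coordinate
search over (lam0_E, beta_E, lam0_R, lam_out), scored on true agent-based
replicate runs with fixed seeds, then verifies (and if needed refines) the
candidate against the calibration targets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .params import SimulationParams, TraffickingParams

logger = logging.getLogger(__name__)

#: Phase windows (days within the cycle) used for calibration read-outs.
PHASE_WINDOWS = {"follicular": (1.0, 11.0), "inbetween": (11.0, 17.0), "luteal": (17.0, 28.0)}


class CalibrationError(RuntimeError):
    """Raised when the coordinate search exhausts its budget off-target."""


def influx_intensities(fields, domain, params: TraffickingParams) -> tuple[float, float]:
    """Deterministic influx intensities (lambda_E, lambda_R) in cells/h."""
    stroma = domain.stroma_mask
    mean_dam = float(fields.c_dam.ravel()[stroma].mean())
    mean_dying = float(fields.c_dying.ravel()[stroma].mean())
    lam_e = params.lam0_E + params.alpha_E * mean_dam + params.beta_E * mean_dying
    lam_r = params.lam0_R + params.alpha_R * mean_dam
    return lam_e, lam_r


def apply_trafficking(sim) -> tuple[int, int]:
    """End-of-step immune population update; returns the entry counts drawn."""
    from . import engine  # deferred to avoid an import cycle

    tp = sim.params.trafficking
    dt = sim.params.dt
    lam_e, lam_r = influx_intensities(sim.fields, sim.domain, tp)
    n_e = int(sim.rng.poisson(lam_e * dt))
    n_r = int(sim.rng.poisson(lam_r * dt))
    # efflux applies to the pre-entry pool: cells do not exit in their entry step
    leavers = [c for c in sim.cells
               if c.alive and c.is_immune and c.immune_state != engine.ACTIVE]
    for ctype, count in ((engine.EFFECTOR, n_e), (engine.REGULATORY, n_r)):
        for _ in range(count):
            node = sim._random_free_stromal_node()
            if node is None:
                sim.discarded_entries += 1
                logger.warning("no free stromal node: immune entry discarded at t=%.1f h", sim.t_h)
                continue
            sim.add_immune(ctype, node)
    if tp.lam_out > 0:
        p_out = -math.expm1(-tp.lam_out * dt)
        if leavers:
            u = sim.rng.random(len(leavers))
            for cell, ui in zip(leavers, u):
                if ui < p_out:
                    sim.remove_cell(cell)
    return n_e, n_r


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    params: TraffickingParams
    achieved: dict          # phase label -> simulated mean relative number
    targets: dict           # phase label -> (target, tolerance)
    residual: float         # weighted RMS residual (units of tolerances)
    n_evals: int
    converged: bool


def _phase_window_masks(t_h: np.ndarray, cycle_days: float) -> dict:
    day = (t_h / 24.0) % cycle_days
    return {k: (day >= lo) & (day < hi) for k, (lo, hi) in PHASE_WINDOWS.items()}


def _probe_baseline(domain, profile, params, seed, n_cycles=3):
    """Record <C_dying>(t) over stroma and N_epi(t); trafficking-independent."""
    from .engine import Simulation

    p = replace(params, trafficking=TraffickingParams(0, 0, 0, 0, 0, 0.1))
    sim = Simulation(domain, p, profile, seed=seed, init_immune=False)
    steps = int(round(n_cycles * profile.cycle_len_hours / p.dt))
    stroma = domain.stroma_mask
    m = np.empty(steps)
    n_epi = np.empty(steps)
    t_h = np.empty(steps)
    for i in range(steps):
        sim.step()
        m[i] = sim.fields.c_dying.ravel()[stroma].mean()
        n_epi[i] = sim.n_epi_alive
        t_h[i] = sim.t_h
    # keep the final cycle (periodic regime) as the template
    per_cycle = int(round(profile.cycle_len_hours / p.dt))
    return t_h[-per_cycle:] - t_h[-per_cycle], m[-per_cycle:], n_epi[-per_cycle:]


def _expected_pool(lam: np.ndarray, lam_out: float, dt: float, n_cycles: int) -> np.ndarray:
    """Expected inactive-pool trajectory under periodic influx lambda(t)."""
    decay = math.exp(-lam_out * dt)
    steps = len(lam) * n_cycles
    n = np.empty(steps)
    x = lam[0] * dt / (1 - decay) if lam_out > 0 else 0.0
    for i in range(steps):
        x = x * decay + lam[i % len(lam)] * dt
        n[i] = x
    return n


def _meanfield_candidate(t_h, m_dying, n_epi, targets, lam_out_grid, dt):
    """NNLS fit of (lam0_E, beta_E) and closed-form lam0_R per lam_out."""
    from scipy.optimize import nnls

    cycle_days = t_h[-1] / 24.0 + dt / 24.0
    masks = _phase_window_masks(np.tile(t_h, 2) + np.repeat([0, t_h[-1] + dt], len(t_h)),
                                cycle_days)
    best = None
    for lam_out in lam_out_grid:
        resp0 = _expected_pool(np.ones_like(m_dying), lam_out, dt, 2)
        resp_m = _expected_pool(m_dying, lam_out, dt, 2)
        n_epi2 = np.tile(n_epi, 2)
        a = np.zeros((3, 2))
        b = np.zeros(3)
        w = np.zeros(3)
        for i, phase in enumerate(("follicular", "inbetween", "luteal")):
            mask = masks[phase]
            a[i, 0] = (resp0[mask] / n_epi2[mask]).mean()
            a[i, 1] = (resp_m[mask] / n_epi2[mask]).mean()
            tgt, tol = targets[phase]
            b[i] = tgt
            w[i] = 1.0 / max(tol, 1e-6)
        coef, _ = nnls(a * w[:, None], b * w)
        resid = float(np.sqrt((((a @ coef - b) * w) ** 2).mean()))
        if best is None or resid < best[0]:
            tgt_reg, _ = targets["regulatory_all"]
            # discrete-map stationarity: E[N] = lam*dt / (1 - exp(-lam_out*dt))
            lam0_r = tgt_reg * float(n_epi.mean()) * (-math.expm1(-lam_out * dt)) / dt
            best = (resid, TraffickingParams(
                lam0_E=float(coef[0]), alpha_E=0.0, beta_E=float(coef[1]),
                lam0_R=float(lam0_r), alpha_R=0.0, lam_out=float(lam_out)))
    return best[1]


def _evaluate_abm(domain, profile, params, tp, seed, n_reps, n_cycles):
    """Phase means of rel_eff and overall rel_reg from real ABM replicates."""
    from .engine import Simulation

    per_cycle = int(round(profile.cycle_len_hours / params.dt))
    p = replace(params, trafficking=tp)
    sums = {k: 0.0 for k in ("follicular", "inbetween", "luteal", "regulatory_all")}
    counts = {k: 0 for k in sums}
    for rep in range(n_reps):
        ss = np.random.SeedSequence(seed, spawn_key=(rep,))
        sim = Simulation(domain, p, profile, seed=ss)
        ts = sim.run(per_cycle * n_cycles)
        masks = _phase_window_masks(ts.t_h, profile.cycle_len_days)
        rel_eff = (ts.n_eff_active + ts.n_eff_inactive) / ts.n_epi
        rel_reg = (ts.n_reg_active + ts.n_reg_inactive) / ts.n_epi
        for phase in ("follicular", "inbetween", "luteal"):
            sums[phase] += rel_eff[masks[phase]].sum()
            counts[phase] += int(masks[phase].sum())
        sums["regulatory_all"] += rel_reg.sum()
        counts["regulatory_all"] += len(rel_reg)
    return {k: sums[k] / counts[k] for k in sums}


def calibrate(
    fixture,
    domain,
    profile,
    params: SimulationParams,
    seed: int = 0,
    n_reps: int = 3,
    n_cycles: int = 12,
    lam_out_grid=(0.05, 0.1, 0.2),
    max_evals: int = 12,
    alpha_default: float = 300.0,
) -> CalibrationResult:
    """Fit trafficking parameters to per-phase relative-number targets.

    ``fixture`` maps phase labels (follicular, inbetween, luteal,
    regulatory_all) to (target, tolerance) pairs, e.g. a
    :class:`tdlusim.fixtures.CalibrationFixture`. Baseline runs use
    ``k_dge = 0``. The chemokine couplings alpha_E/alpha_R cannot be
    identified at baseline (the damaged-cell field is identically zero) and
    are set to ``alpha_default``.
    """
    targets = fixture.as_dict() if hasattr(fixture, "as_dict") else dict(fixture)
    base = replace(params, k_dge=0.0)

    if all(t == 0 for t, _ in targets.values()):
        tp = TraffickingParams(0, 0, 0, 0, 0, params.trafficking.lam_out)
        achieved = {k: 0.0 for k in targets}
        return CalibrationResult(tp, achieved, targets, 0.0, 0, True)

    t_h, m_dying, n_epi = _probe_baseline(domain, profile, base, seed)
    cand = _meanfield_candidate(t_h, m_dying, n_epi, targets, lam_out_grid, base.dt)
    cand = replace(cand, alpha_E=alpha_default, alpha_R=alpha_default)

    weights = {k: 1.0 / max(tol, 1e-6) for k, (_, tol) in targets.items()}

    def score(tp):
        achieved = _evaluate_abm(domain, profile, base, tp, seed + 1, n_reps, n_cycles)
        resid = math.sqrt(sum(((achieved[k] - targets[k][0]) * weights[k]) ** 2
                              for k in targets) / len(targets))
        within = all(abs(achieved[k] - targets[k][0]) <= targets[k][1] + 1e-12
                     for k in targets)
        return achieved, resid, within

    n_evals = 0
    best_tp, (best_ach, best_resid, within) = cand, score(cand)
    n_evals += 1
    step_frac = 0.2
    names = ("lam0_E", "beta_E", "lam0_R", "lam_out")
    while not within and n_evals < max_evals:
        improved = False
        for name in names:
            if within or n_evals >= max_evals:
                break
            val = getattr(best_tp, name)
            for factor in (1 + step_frac, 1 - step_frac):
                trial = replace(best_tp, **{name: max(val * factor, 0.0)})
                ach, resid, w_in = score(trial)
                n_evals += 1
                if resid < best_resid:
                    best_tp, best_ach, best_resid, within = trial, ach, resid, w_in
                    improved = True
                    break
                if w_in:
                    best_tp, best_ach, best_resid, within = trial, ach, resid, w_in
                    break
                if n_evals >= max_evals:
                    break
        if not improved and not within:
            step_frac *= 0.5
            if step_frac < 0.02:
                break

    result = CalibrationResult(best_tp, best_ach, targets, best_resid, n_evals, within)
    if not within:
        raise CalibrationError(
            f"calibration did not reach all targets within tolerance after {n_evals} "
            f"evaluations; best weighted RMS residual {best_resid:.3f} "
            f"(achieved {best_ach})"
        )
    return result
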