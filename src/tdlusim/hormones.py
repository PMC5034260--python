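"""Menstrual-cycle modulation of epithelial cell turnover.

The proliferation index (PI, Ki-67-like) and apoptotic index (AI,
TUNEL-like) of the lobular epithelium oscillate over the menstrual cycle:
PI peaks late in the luteal phase and shows a smaller local maximum in the
follicular phase (at 13.45/30.46 of the global maximum, matching the
experimentally reported PI range), while AI is maximal at the beginning and
end of the cycle. This module provides normalized versions of those curves,
f_PI and f_AI in [0, 1], which scale the intrinsic division rate k_pro and
apoptosis rate k_apt:

    rate_pro(t) = k_pro * theta * f_PI(t mod T),
    rate_apt(t) = k_apt * theta * f_AI(t mod T),

with theta a positive "hormone level" scaling factor (theta = 1 is the
normal status) and T the cycle length. Variable cycle lengths are modelled
by linearly dilating/contracting the follicular segment of the curves while
keeping the luteal segment's shape (always 14 days) invariant.

The default curve shapes are smooth monotone-cubic (PCHIP) interpolants
through anchor points that realise the qualitative features above; exact
experimental shapes can be substituted via a CSV with columns
``day,f_pi,f_ai``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

#: Ratio between the follicular-phase local PI maximum and the luteal-phase
#: global maximum (13.45 and 30.46 events per 1000 epithelial cells).
FOLLICULAR_PI_RATIO = 13.45 / 30.46

#: Anchor points (day, value) of the default normalized curves on the
#: reference 28-day cycle (follicular days 0-14, luteal days 14-28).
PI_ANCHORS = (
    (0.0, 0.30),
    (3.0, 0.25),
    (7.0, FOLLICULAR_PI_RATIO),
    (11.0, 0.28),
    (14.0, 0.26),
    (18.0, 0.40),
    (24.0, 1.0),
    (28.0, 0.30),
)
AI_ANCHORS = (
    (0.0, 1.0),
    (2.0, 0.35),
    (5.0, 0.15),
    (8.0, 0.10),
    (11.0, 0.08),
    (14.0, 0.08),
    (17.0, 0.10),
    (21.0, 0.25),
    (25.0, 0.75),
    (28.0, 1.0),
)

#: Sampling step (days) of the packaged reference curve table.
GRID_STEP_DAYS = 0.25


@dataclass(frozen=True)
class HormoneProfile:
    """Normalized PI/AI curves over one cycle plus hormone level and phase lengths."""

    t_grid: np.ndarray  # days within one cycle, ascending, t_grid[0] == 0
    f_pi: np.ndarray
    f_ai: np.ndarray
    follicular_len: float = 14.0
    luteal_len: float = 14.0
    theta: float = 1.0

    def __post_init__(self):
        t = np.asarray(self.t_grid, dtype=float)
        object.__setattr__(self, "t_grid", t)
        object.__setattr__(self, "f_pi", np.asarray(self.f_pi, dtype=float))
        object.__setattr__(self, "f_ai", np.asarray(self.f_ai, dtype=float))
        if self.theta <= 0:
            raise ValueError("hormone level theta must be positive")
        if (self.f_pi < 0).any() or (self.f_ai < 0).any():
            raise ValueError("normalized curves must be nonnegative")

    @property
    def cycle_len_days(self) -> float:
        return self.follicular_len + self.luteal_len

    @property
    def cycle_len_hours(self) -> float:
        return 24.0 * self.cycle_len_days

    def with_theta(self, theta: float) -> "HormoneProfile":
        return replace(self, theta=theta)

    # -- CSV interface ----------------------------------------------------
    def to_csv(self, path) -> None:
        pd.DataFrame({"day": self.t_grid, "f_pi": self.f_pi, "f_ai": self.f_ai}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, follicular_len: float = 14.0, luteal_len: float = 14.0,
                 theta: float = 1.0) -> "HormoneProfile":
        df = pd.read_csv(path)
        return cls(
            t_grid=df["day"].to_numpy(),
            f_pi=df["f_pi"].to_numpy(),
            f_ai=df["f_ai"].to_numpy(),
            follicular_len=follicular_len,
            luteal_len=luteal_len,
            theta=theta,
        )


def reference_curve_table() -> pd.DataFrame:
    """Evaluate the default anchors on the reference grid (pure function).

    The packaged data file ``data/hormone_curves.csv`` is this table; a test
    asserts they agree so the shipped fixture can never drift from the code.
    """
    t = np.round(np.arange(0.0, 28.0 + GRID_STEP_DAYS / 2, GRID_STEP_DAYS), 6)
    pi_d, pi_v = zip(*PI_ANCHORS)
    ai_d, ai_v = zip(*AI_ANCHORS)
    f_pi = np.minimum(PchipInterpolator(pi_d, pi_v)(t), 1.0)
    f_ai = np.minimum(PchipInterpolator(ai_d, ai_v)(t), 1.0)
    return pd.DataFrame({"day": t, "f_pi": f_pi, "f_ai": f_ai})


def default_profile(theta: float = 1.0) -> HormoneProfile:
    """The packaged reference 28-day profile (follicular 0-14 d, luteal 14-28 d)."""
    with resources.files("tdlusim").joinpath("data/hormone_curves.csv").open("r") as fh:
        df = pd.read_csv(fh)
    return HormoneProfile(
        t_grid=df["day"].to_numpy(),
        f_pi=df["f_pi"].to_numpy(),
        f_ai=df["f_ai"].to_numpy(),
        theta=theta,
    )


def _interp_periodic(t_days, grid, values, cycle_len):
    return np.interp(np.mod(t_days, cycle_len), grid, values)


def evaluate(profile: HormoneProfile, t_hours, k_pro: float, k_apt: float):
    """Hormone-modulated rates at time ``t_hours`` since simulation start.

    Returns ``(rate_pro, rate_apt)`` in 1/h. Linear interpolation between
    grid points, periodic extension across cycles, both rates scaled by the
    profile's ``theta``.
    """
    if profile.theta <= 0:
        raise ValueError("hormone level theta must be positive")
    t_days = np.asarray(t_hours, dtype=float) / 24.0
    if np.any(t_days < 0):
        raise ValueError("t must be >= 0")
    cyc = profile.cycle_len_days
    f_pi = _interp_periodic(t_days, profile.t_grid, profile.f_pi, cyc)
    f_ai = _interp_periodic(t_days, profile.t_grid, profile.f_ai, cyc)
    return k_pro * profile.theta * f_pi, k_apt * profile.theta * f_ai


def rescale_follicular(profile: HormoneProfile, new_follicular_len: float) -> HormoneProfile:
    """Dilate/contract the follicular segment of the curves to a new length.

    The follicular time axis [0, follicular_len] maps linearly onto
    [0, new_follicular_len]; the luteal segment is translated so its shape
    (and duration) is unchanged. Curve values are preserved pointwise under
    the time map.
    """
    if new_follicular_len <= 0:
        raise ValueError("new_follicular_len must be positive")
    old = profile.follicular_len
    t = profile.t_grid
    scale = new_follicular_len / old
    new_t = np.where(t <= old, t * scale, t + (new_follicular_len - old))
    return replace(profile, t_grid=new_t, follicular_len=float(new_follicular_len))
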