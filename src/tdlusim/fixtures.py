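"""Packaged fixtures and synthetic inputs; no downloads required.

Provides the per-phase calibration targets (the quantified relative immune
cell numbers in healthy lobules), the default normalized hormone-cycle
curve table, and seeded synthetic point patterns with known ground truth
for exercising the spatial statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from . import hormones

#: Observed mean relative effector numbers by cycle phase (and overall
#: regulatory mean) in healthy breast lobules, with their tolerances.
CALIBRATION_TARGETS = {
    "follicular": (0.05, 0.01),
    "inbetween": (0.04, 0.01),
    "luteal": (0.07, 0.02),
    "regulatory_all": (0.055, 0.01),
}


@dataclass(frozen=True)
class CalibrationFixture:
    """Per-phase relative-number targets with tolerances."""

    phases: tuple
    targets: tuple
    tolerances: tuple

    def as_dict(self) -> dict:
        return {p: (t, tol) for p, t, tol in zip(self.phases, self.targets, self.tolerances)}

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "phase": self.phases, "target_mean": self.targets, "tolerance": self.tolerances
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CalibrationFixture":
        df = pd.read_csv(path)
        return cls(tuple(df["phase"]), tuple(df["target_mean"]), tuple(df["tolerance"]))


def make_calibration_fixture() -> CalibrationFixture:
    """The packaged healthy-baseline targets (effector by phase, regulatory overall)."""
    phases = tuple(CALIBRATION_TARGETS)
    return CalibrationFixture(
        phases=phases,
        targets=tuple(CALIBRATION_TARGETS[p][0] for p in phases),
        tolerances=tuple(CALIBRATION_TARGETS[p][1] for p in phases),
    )


def load_calibration_fixture() -> CalibrationFixture:
    """Read the version-controlled fixture CSV shipped with the package."""
    with resources.files("tdlusim").joinpath("data/calibration_targets.csv").open("r") as fh:
        return CalibrationFixture.from_csv(fh)


def default_hormone_table() -> pd.DataFrame:
    """The default normalized PI/AI curve table (see :mod:`tdlusim.hormones`)."""
    return hormones.reference_curve_table()


def make_synthetic_pattern(
    kind: str,
    n: int,
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
    admissible: np.ndarray | None = None,
    n_parents: int = 5,
    sigma: float = 1.5,
    m_target: float = 1.5,
):
    """Seeded synthetic point pattern with documented ground truth.

    kind='csr': uniform without replacement over the admissible nodes
    (truth: g(r) = 1). kind='clustered': Neyman-Scott style parent/offspring
    pattern with ``n_parents`` parents and Gaussian offspring displacement
    ``sigma`` (truth: clusters at small r). kind='power_law': offspring
    radial distances drawn with density proportional to r^(1-m_target), so
    the local pair density around a parent decays like r^-m_target.

    Returns ``(points, truth)`` where points is an (n, 2) int array of
    distinct (x, y) nodes and truth a dict describing the construction.
    """
    if n < 2:
        raise ValueError("need n >= 2 points")
    rng = np.random.default_rng(seed)
    h, w = shape
    if admissible is None:
        admissible = np.ones(shape, dtype=bool)
    adm_nodes = np.flatnonzero(admissible.ravel())

    def snap(raw_xy):
        """Snap continuous proposals to distinct admissible nodes."""
        chosen = []
        used = set()
        for x, y in raw_xy:
            xi, yi = int(round(x)) % w, int(round(y)) % h
            node = yi * w + xi
            if admissible[yi, xi] and node not in used:
                used.add(node)
                chosen.append((xi, yi))
        return chosen

    if kind == "csr":
        idx = rng.choice(len(adm_nodes), size=n, replace=False)
        nodes = adm_nodes[idx]
        pts = np.stack([nodes % w, nodes // w], axis=1)
        return pts, {"kind": "csr", "g_expected": 1.0}

    if kind in ("clustered", "power_law"):
        parents = np.stack([rng.uniform(0, w, n_parents), rng.uniform(0, h, n_parents)], axis=1)
        pts: list = []
        guard = 0
        while len(pts) < n and guard < 50 * n:
            guard += 1
            par = parents[rng.integers(n_parents)]
            if kind == "clustered":
                prop = par + rng.normal(0, sigma, 2)
            else:
                # radius pdf ~ r^(1-m) on [0.5, r_max]: inverse-CDF sampling
                r_max = 4.0 * sigma
                u = rng.random()
                expo = 2.0 - m_target
                r = ((0.5 ** expo) + u * (r_max ** expo - 0.5 ** expo)) ** (1.0 / expo)
                phi = rng.uniform(0, 2 * np.pi)
                prop = par + r * np.array([np.cos(phi), np.sin(phi)])
            pts.extend(snap([prop]))
        truth = {"kind": kind, "n_parents": n_parents, "sigma": sigma}
        if kind == "power_law":
            truth["m_target"] = m_target
        return np.array(pts[:n], dtype=int), truth

    raise ValueError(f"unknown pattern kind: {kind}")


def write_fixture_files(outdir) -> list:
    """Write all packaged fixture files into ``outdir``; returns the paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    p = outdir / "calibration_targets.csv"
    make_calibration_fixture().to_csv(p)
    paths.append(p)
    p = outdir / "hormone_curves.csv"
    default_hormone_table().to_csv(p, index=False)
    paths.append(p)
    return paths
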