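"""Chemokine concentration fields on the TDLU lattice.

Two continuous, nonnegative scalar fields live on the non-lumen nodes of
the domain: one sourced by aberrantly damaged epithelial cells (an
inflammatory, activating signal) and one by dying cells (the apoptotic
"find-me" signal). Each evolves by diffusion, first-order decay and
constant secretion from its source cells:

    dC/dt = D * lap(C) - lambda * C + s * 1_sources

integrated by forward Euler on a von Neumann (4-point) stencil with
zero-flux boundaries at the grid edge and at lumen boundaries (lumina are
reflecting obstacles: chemokines do not enter the lumen, mirroring immune
exclusion). The explicit scheme is stable and positivity-preserving for
dt <= 1/(4 D + lambda); `step_field` enforces that bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import LatticeDomain


class StabilityError(ValueError):
    """Raised when the requested dt violates the explicit-scheme bound."""


@dataclass
class ChemokineFields:
    """Damaged-cell and dying-cell chemokine fields plus their PDE parameters.

    Concentrations are in arbitrary units; diffusion coefficients in
    nodes^2/h, decay rates in 1/h, secretion rates in units/h per source
    cell. Defaults give a quasi-steady halo of ~5-10 nodes around a small
    group of source cells, the interaction range that produces localized
    immune clusters rather than domain-wide activation.
    """

    c_dam: np.ndarray
    c_dying: np.ndarray
    d_dam: float = 5.0
    d_dying: float = 5.0
    lambda_dam: float = 0.5
    lambda_dying: float = 0.5
    s_dam: float = 1.0
    s_dying: float = 1.0

    @classmethod
    def zeros(cls, domain: LatticeDomain, **params) -> "ChemokineFields":
        shape = domain.shape
        return cls(c_dam=np.zeros(shape), c_dying=np.zeros(shape), **params)

    def max_stable_dt(self) -> tuple[float, float]:
        return (
            1.0 / (4.0 * self.d_dam + self.lambda_dam),
            1.0 / (4.0 * self.d_dying + self.lambda_dying),
        )

    def total_mass(self) -> tuple[float, float]:
        return float(self.c_dam.sum()), float(self.c_dying.sum())

    def to_tsv(self, path) -> None:
        h, w = self.c_dam.shape
        ys, xs = np.divmod(np.arange(h * w), w)
        pd.DataFrame(
            {"node_x": xs, "node_y": ys,
             "c_dam": self.c_dam.ravel(), "c_dying": self.c_dying.ravel()}
        ).to_csv(path, sep="\t", index=False)


class DiffusionStencil:
    """The masked 4-point Laplacian of a domain, as a sparse operator.

    A neighbour pair contributes to the Laplacian only if both nodes are
    outside lumina; missing pairs act as zero-flux (reflecting) walls. The
    operator is assembled once per domain as a sparse matrix, so each
    application is a single matvec.
    """

    def __init__(self, domain: LatticeDomain):
        from scipy import sparse

        active = domain.flat != 0  # non-lumen
        self.active = active.reshape(domain.shape)
        n = domain.n_nodes
        rows, cols = [], []
        for k in range(domain.nbr_vn.shape[1]):
            nb = domain.nbr_vn[:, k]
            ok = (nb >= 0) & active & active[np.clip(nb, 0, n - 1)]
            rows.append(np.flatnonzero(ok))
            cols.append(nb[ok])
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        data = np.ones(len(rows))
        a = sparse.coo_matrix((data, (rows, cols)), shape=(n, n))
        deg = np.asarray(a.sum(axis=1)).ravel()
        self.matrix = (a - sparse.diags(deg)).tocsr()
        self._shape = domain.shape

    def laplacian(self, c: np.ndarray) -> np.ndarray:
        return (self.matrix @ c.ravel()).reshape(self._shape)


def step_field(
    fields: ChemokineFields,
    domain: LatticeDomain,
    sources_dam: np.ndarray,
    sources_dying: np.ndarray,
    dt: float,
    stencil: DiffusionStencil | None = None,
) -> ChemokineFields:
    """One forward-Euler step of both fields (in place; returns ``fields``).

    ``sources_dam``/``sources_dying`` are flat node indices of the cells
    currently secreting each chemokine.
    """
    if stencil is None:
        stencil = DiffusionStencil(domain)
    dt_dam, dt_dying = fields.max_stable_dt()
    if dt > dt_dam + 1e-12:
        raise StabilityError(
            f"dt={dt} exceeds the stability bound {dt_dam:.4g} for the damaged-cell field"
        )
    if dt > dt_dying + 1e-12:
        raise StabilityError(
            f"dt={dt} exceeds the stability bound {dt_dying:.4g} for the dying-cell field"
        )
    for c, d, lam, s, src in (
        (fields.c_dam, fields.d_dam, fields.lambda_dam, fields.s_dam, sources_dam),
        (fields.c_dying, fields.d_dying, fields.lambda_dying, fields.s_dying, sources_dying),
    ):
        if len(src) == 0 and not c.any():
            continue  # identically zero stays zero
        c += dt * (d * stencil.laplacian(c) - lam * c)
        if len(src):
            c.ravel()[np.asarray(src)] += dt * s
    return fields


def evolve(
    fields: ChemokineFields,
    domain: LatticeDomain,
    sources_dam,
    sources_dying,
    dt_total: float,
    stencil: DiffusionStencil | None = None,
    safety: float = 0.9,
) -> ChemokineFields:
    """Advance both fields by ``dt_total`` using automatic stable substeps."""
    if stencil is None:
        stencil = DiffusionStencil(domain)
    dt_max = safety * min(fields.max_stable_dt())
    n_sub = max(1, int(np.ceil(dt_total / dt_max)))
    dt = dt_total / n_sub
    for _ in range(n_sub):
        step_field(fields, domain, sources_dam, sources_dying, dt, stencil)
    return fields


def local_gradient(fields: ChemokineFields, domain: LatticeDomain, node: int):
    """Per-neighbour concentration differences at ``node`` for each chemokine.

    Returns ``(neighbors, d_dam, d_dying)``: admissible (in-grid, non-lumen)
    Moore neighbours and, for each, C(neighbour) - C(node).
    """
    if domain.flat[node] == 0:
        raise ValueError("gradients are undefined inside lumina")
    nbrs = domain.nbr_moore[node]
    nbrs = nbrs[nbrs >= 0]
    nbrs = nbrs[domain.flat[nbrs] != 0]
    cd = fields.c_dam.ravel()
    cy = fields.c_dying.ravel()
    return nbrs, cd[nbrs] - cd[node], cy[nbrs] - cy[node]
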