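"""Stochastic per-time-step update of all cells on the TDLU lattice.

Cell types and states
---------------------
Epithelial cells (luminal or myoepithelial) are firmly placed on epithelium
nodes and never move. They are NORMAL, DAMAGED (aberrant daughters arising
with probability ``k_dge`` per division of a normal parent; damaged parents
breed damaged daughters) or DYING (debris awaiting lysis). Normal cells
undergo apoptosis at the hormone-modulated rate ``k_apt * theta * f_AI(t)``;
damaged cells never die by apoptosis and must be killed by contact with
activated effector cells at rate ``k_kill`` per adjacent active effector.

Immune cells (effector or regulatory) live on any non-lumen node, move by
chemotaxis-biased random walks, and are ACTIVE exactly while the local
damaged-cell chemokine is at or above the threshold ``c_act``; effectors can
additionally be permanently inactivated (PERM_INACTIVE) by contact with
active regulatory cells (rate ``k_sup`` per adjacent active regulatory
cell). Immune cells do not
proliferate; their numbers change only through trafficking.

Update order (one step of ``dt`` hours)
---------------------------------------
Cells are visited in a fresh random permutation to avoid order bias. For
each cell: damaged epithelial cells pass a killing checkpoint; immune cells
pass activation and (effectors) suppression checkpoints; then one of the
cell's candidate processes -- motility (immune), proliferation (epithelial),
apoptosis (normal epithelial) -- is tried in random order until one fires.
Afterwards the chemokine fields advance by ``dt``, expired dying cells are
lysed, and trafficking updates the immune populations.

A proliferation event is logged whenever the intrinsic division clock fires
(this is the Ki-67-like read-out: the cell has entered the division
program); the daughter cell is actually placed only if a free epithelial
neighbour node exists. Crowding therefore limits *realised* divisions --
this free-node rule is what reconciles ``k_pro >> k_apt`` with tissue
homeostasis -- while the proliferation-index read-out tracks
``1000 * k_pro * theta * f_PI(t)`` as measured experimentally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import hormones
from .chemokine import ChemokineFields, DiffusionStencil, evolve
from .geometry import LatticeDomain
from .params import SimulationParams

# cell_type codes
EPI_LUMINAL = 0
EPI_MYO = 1
EFFECTOR = 2
REGULATORY = 3

# epi_state codes
NORMAL = 0
DAMAGED = 1
DYING = 2

# immune_state codes
ACTIVE = 0
INACTIVE = 1
PERM_INACTIVE = 2

# occupancy codes (occ_code flat array; 0 = empty node)
_EMPTY = 0
_OCC_EPI_NORMAL = 1
_OCC_EPI_DAMAGED = 2
_OCC_EPI_DYING = 3
_OCC_EFF_ACTIVE = 4
_OCC_EFF_OFF = 5
_OCC_REG_ACTIVE = 6
_OCC_REG_OFF = 7

TYPE_NAMES = {EPI_LUMINAL: "EPI_LUMINAL", EPI_MYO: "EPI_MYO",
              EFFECTOR: "EFFECTOR", REGULATORY: "REGULATORY"}
EPI_STATE_NAMES = {NORMAL: "NORMAL", DAMAGED: "DAMAGED", DYING: "DYING"}
IMMUNE_STATE_NAMES = {ACTIVE: "ACTIVE", INACTIVE: "INACTIVE",
                      PERM_INACTIVE: "PERM_INACTIVE"}


@dataclass(slots=True)
class CellAgent:
    """One epithelial or immune cell."""

    id: int
    node: int                 # flat lattice index
    cell_type: int
    epi_state: int = NORMAL   # epithelial only
    immune_state: int = INACTIVE  # immune only
    dying_since: float = -1.0
    alive: bool = True

    @property
    def is_epithelial(self) -> bool:
        return self.cell_type <= EPI_MYO

    @property
    def is_immune(self) -> bool:
        return self.cell_type >= EFFECTOR


def event_probability(rate: float, n_contacts: int, dt: float) -> float:
    """Probability of a contact-mediated event in one step.

    The hazard is ``rate * n_contacts`` (proportional to the number of
    adjacent active cells), so p = 1 - exp(-rate * n_contacts * dt).
    """
    if rate < 0 or n_contacts < 0 or dt <= 0:
        raise ValueError("rate and n_contacts must be >= 0 and dt > 0")
    return -math.expm1(-rate * n_contacts * dt)


class Simulation:
    """Mutable simulation state: domain, cells, fields, clock and RNG.

    All randomness flows through ``self.rng`` (one numpy Generator), so a
    run is bit-reproducible given its seed.
    """

    def __init__(
        self,
        domain: LatticeDomain,
        params: SimulationParams,
        profile: hormones.HormoneProfile | None = None,
        seed: int | np.random.SeedSequence = 0,
        init_immune: bool = True,
    ):
        self.domain = domain
        self.params = params
        if profile is None:
            profile = hormones.default_profile()
        self.profile = profile.with_theta(params.theta)
        self.rng = np.random.default_rng(seed)
        self.fields = ChemokineFields.zeros(domain, **params.chemokine_kwargs())
        self.stencil = DiffusionStencil(domain)
        self.t_h = 0.0
        self._next_id = 0

        n = domain.n_nodes
        self.occ_code = np.zeros(n, dtype=np.int8)
        self._epi_mask = domain.epithelium_mask
        self._lumen_mask = domain.lumen_mask
        self.stroma_nodes = np.flatnonzero(domain.stroma_mask)

        self.cells: list[CellAgent] = []
        self._damaged: list[CellAgent] = []
        self._dying: list[CellAgent] = []

        # population counters
        self.n_normal = 0
        self.n_damaged = 0
        self.n_dying = 0
        self.n_eff_active = 0
        self.n_eff_inactive = 0
        self.n_eff_perm = 0
        self.n_reg_active = 0
        self.n_reg_inactive = 0
        # per-step event log (proliferation clock firings / apoptosis entries)
        self.div_events = 0
        self.apt_events = 0
        self.discarded_entries = 0

        self._seed_epithelium()
        if init_immune:
            self._seed_immune()

    # ------------------------------------------------------------------
    @property
    def n_epi_alive(self) -> int:
        return self.n_normal + self.n_damaged

    @property
    def n_eff(self) -> int:
        return self.n_eff_active + self.n_eff_inactive + self.n_eff_perm

    @property
    def n_reg(self) -> int:
        return self.n_reg_active + self.n_reg_inactive

    def _new_id(self) -> int:
        self._next_id += 1
        return self._next_id - 1

    def _seed_epithelium(self) -> None:
        comp = self.domain.flat
        for node in np.flatnonzero(self._epi_mask):
            ctype = EPI_LUMINAL if comp[node] == 1 else EPI_MYO
            cell = CellAgent(self._new_id(), int(node), ctype, epi_state=NORMAL)
            self.cells.append(cell)
            self.occ_code[node] = _OCC_EPI_NORMAL
            self.n_normal += 1

    def _seed_immune(self) -> None:
        # start the inactive pools at their zero-field stationary sizes
        tp = self.params.trafficking
        if tp.lam_out <= 0:
            return
        for ctype, lam0 in ((EFFECTOR, tp.lam0_E), (REGULATORY, tp.lam0_R)):
            for _ in range(int(self.rng.poisson(lam0 / tp.lam_out))):
                node = self._random_free_stromal_node()
                if node is None:
                    break
                self.add_immune(ctype, node)

    def _random_free_stromal_node(self, max_tries: int = 200):
        nodes = self.stroma_nodes
        for _ in range(max_tries):
            node = int(nodes[self.rng.integers(len(nodes))])
            if self.occ_code[node] == _EMPTY:
                return node
        free = nodes[self.occ_code[nodes] == _EMPTY]
        if len(free) == 0:
            return None
        return int(free[self.rng.integers(len(free))])

    def add_immune(self, cell_type: int, node: int, state: int = INACTIVE) -> CellAgent:
        cell = CellAgent(self._new_id(), int(node), cell_type, immune_state=state)
        self.cells.append(cell)
        self._set_immune_occ(cell)
        if cell_type == EFFECTOR:
            if state == ACTIVE:
                self.n_eff_active += 1
            elif state == INACTIVE:
                self.n_eff_inactive += 1
            else:
                self.n_eff_perm += 1
        else:
            if state == ACTIVE:
                self.n_reg_active += 1
            else:
                self.n_reg_inactive += 1
        return cell

    def _set_immune_occ(self, cell: CellAgent) -> None:
        if cell.cell_type == EFFECTOR:
            code = _OCC_EFF_ACTIVE if cell.immune_state == ACTIVE else _OCC_EFF_OFF
        else:
            code = _OCC_REG_ACTIVE if cell.immune_state == ACTIVE else _OCC_REG_OFF
        self.occ_code[cell.node] = code

    def remove_cell(self, cell: CellAgent) -> None:
        """Remove an immune cell (efflux) or lysed debris; frees its node."""
        self.occ_code[cell.node] = _EMPTY
        cell.alive = False
        if cell.is_immune:
            if cell.cell_type == EFFECTOR:
                if cell.immune_state == ACTIVE:
                    self.n_eff_active -= 1
                elif cell.immune_state == INACTIVE:
                    self.n_eff_inactive -= 1
                else:
                    self.n_eff_perm -= 1
            else:
                if cell.immune_state == ACTIVE:
                    self.n_reg_active -= 1
                else:
                    self.n_reg_inactive -= 1
        else:
            self.n_dying -= 1

    # -- state transitions ---------------------------------------------
    def _enter_dying(self, cell: CellAgent) -> None:
        if cell.epi_state == DAMAGED:
            self.n_damaged -= 1
            self._damaged.remove(cell)
        else:
            self.n_normal -= 1
        cell.epi_state = DYING
        cell.dying_since = self.t_h + self.params.dt  # enters at the step's end time
        self.occ_code[cell.node] = _OCC_EPI_DYING
        self.n_dying += 1
        self._dying.append(cell)

    def _set_immune_state(self, cell: CellAgent, state: int) -> None:
        if state == cell.immune_state:
            return
        old = cell.immune_state
        cell.immune_state = state
        if cell.cell_type == EFFECTOR:
            deltas = {ACTIVE: "n_eff_active", INACTIVE: "n_eff_inactive",
                      PERM_INACTIVE: "n_eff_perm"}
        else:
            deltas = {ACTIVE: "n_reg_active", INACTIVE: "n_reg_inactive"}
        setattr(self, deltas[old], getattr(self, deltas[old]) - 1)
        setattr(self, deltas[state], getattr(self, deltas[state]) + 1)
        self._set_immune_occ(cell)

    def _count_adjacent(self, node: int, code: int) -> int:
        occ = self.occ_code
        n = 0
        for nb in self.domain.nbr_moore[node]:
            if nb >= 0 and occ[nb] == code:
                n += 1
        return n

    # -- per-cell processes (exposed for unit testing) ------------------
    def kill_check(self, cell: CellAgent, u: float | None = None) -> bool:
        """Damaged cell dies with hazard k_kill per adjacent active effector."""
        n_act = self._count_adjacent(cell.node, _OCC_EFF_ACTIVE)
        if n_act == 0:
            return False
        p = event_probability(self.params.k_kill, n_act, self.params.dt)
        if (self.rng.random() if u is None else u) < p:
            self._enter_dying(cell)
            return True
        return False

    def suppression_check(self, cell: CellAgent, u: float | None = None) -> bool:
        """Active effector is permanently inactivated by adjacent active regulatory cells."""
        n_reg = self._count_adjacent(cell.node, _OCC_REG_ACTIVE)
        if n_reg == 0:
            return False
        p = event_probability(self.params.k_sup, n_reg, self.params.dt)
        if (self.rng.random() if u is None else u) < p:
            self._set_immune_state(cell, PERM_INACTIVE)
            return True
        return False

    def activation_update(self, cell: CellAgent) -> None:
        """ACTIVE iff the damaged-cell chemokine at the node reaches c_act (inclusive)."""
        if cell.immune_state == PERM_INACTIVE:
            return
        c = self.fields.c_dam.ravel()[cell.node]
        self._set_immune_state(cell, ACTIVE if c >= self.params.c_act else INACTIVE)

    def attempt_division(self, cell: CellAgent, p_div: float,
                         u_event: float, log: bool = True) -> CellAgent | None:
        """Fire the division clock with probability ``p_div``; place a daughter if space allows."""
        if u_event >= p_div:
            return None
        if log:
            self.div_events += 1
        occ = self.occ_code
        epi = self._epi_mask
        cands = [int(nb) for nb in self.domain.nbr_moore[cell.node]
                 if nb >= 0 and epi[nb] and occ[nb] == _EMPTY]
        if not cands:
            return None
        node = cands[self.rng.integers(len(cands))] if len(cands) > 1 else cands[0]
        if cell.epi_state == DAMAGED:
            damaged = True
        else:
            damaged = self.rng.random() < self.params.k_dge
        ctype = EPI_LUMINAL if self.domain.flat[node] == 1 else EPI_MYO
        daughter = CellAgent(self._new_id(), node, ctype,
                             epi_state=DAMAGED if damaged else NORMAL)
        self.cells.append(daughter)
        occ[node] = _OCC_EPI_DAMAGED if damaged else _OCC_EPI_NORMAL
        if damaged:
            self.n_damaged += 1
            self._damaged.append(daughter)
        else:
            self.n_normal += 1
        return daughter

    def attempt_apoptosis(self, cell: CellAgent, p_apt: float, u_event: float) -> bool:
        """Normal epithelial cell enters DYING with probability ``p_apt``."""
        if cell.epi_state != NORMAL:
            return False  # damaged cells never die by apoptosis
        if u_event < p_apt:
            self.apt_events += 1
            self._enter_dying(cell)
            return True
        return False

    def move_immune(self, cell: CellAgent, u_event: float, p_move: float) -> bool:
        """Chemotaxis-biased step to one free non-lumen Moore neighbour.

        Effectors climb C_dam + C_dying; regulatory cells climb C_dam;
        permanently inactivated cells no longer respond to chemokines and
        move uniformly. Weight exp(chi * dC); stays put if no admissible
        neighbour.
        """
        if u_event >= p_move:
            return False
        occ = self.occ_code
        lumen = self._lumen_mask
        node = cell.node
        nbrs = [int(nb) for nb in self.domain.nbr_moore[node]
                if nb >= 0 and not lumen[nb] and occ[nb] == _EMPTY]
        if not nbrs:
            return False
        chi = self.params.chi
        if chi > 0 and cell.immune_state != PERM_INACTIVE:
            cd = self.fields.c_dam.ravel()
            if cell.cell_type == EFFECTOR:
                cy = self.fields.c_dying.ravel()
                here = cd[node] + cy[node]
                w = [math.exp(min(chi * (cd[nb] + cy[nb] - here), 50.0)) for nb in nbrs]
            else:
                here = cd[node]
                w = [math.exp(min(chi * (cd[nb] - here), 50.0)) for nb in nbrs]
            total = 0.0
            for x in w:
                total += x
            r = self.rng.random() * total
            acc = 0.0
            target = nbrs[-1]
            for nb, x in zip(nbrs, w):
                acc += x
                if r < acc:
                    target = nb
                    break
        else:
            target = nbrs[self.rng.integers(len(nbrs))] if len(nbrs) > 1 else nbrs[0]
        code = occ[node]
        occ[node] = _EMPTY
        occ[target] = code
        cell.node = target
        return True

    def lysis_update(self, now: float | None = None) -> int:
        """Delete DYING cells whose debris persisted for tau_lys hours."""
        if now is None:
            now = self.t_h
        tau = self.params.tau_lys
        removed = 0
        keep = []
        for cell in self._dying:
            if now - cell.dying_since >= tau - 1e-9:
                self.remove_cell(cell)
                removed += 1
            else:
                keep.append(cell)
        self._dying = keep
        return removed

    # ------------------------------------------------------------------
    def step(self) -> None:
        """One engine time step of ``params.dt`` hours."""
        from . import trafficking  # deferred: trafficking imports engine types

        p = self.params
        dt = p.dt
        rate_pro, rate_apt = hormones.evaluate(self.profile, self.t_h, p.k_pro, p.k_apt)
        p_pro = -math.expm1(-float(rate_pro) * dt)
        p_apt = -math.expm1(-float(rate_apt) * dt)
        p_move = -math.expm1(-p.m_rate * dt)
        self.div_events = 0
        self.apt_events = 0

        snapshot = [c for c in self.cells if c.alive]
        order = self.rng.permutation(len(snapshot))
        uni = self.rng.random((len(snapshot), 3))
        c_dam = self.fields.c_dam.ravel()
        c_act = p.c_act

        for k in order:
            cell = snapshot[k]
            if not cell.alive:
                continue
            u0, u1, u2 = uni[k]
            if cell.cell_type <= EPI_MYO:
                st = cell.epi_state
                if st == DYING:
                    continue
                if st == DAMAGED:
                    if self.kill_check(cell, u=u2):
                        continue
                    self.attempt_division(cell, p_pro, u0)
                else:
                    # {proliferation, apoptosis} in random order until one fires
                    if u2 < 0.5:
                        fired = u0 < p_pro
                        self.attempt_division(cell, p_pro, u0)
                        if not fired:
                            self.attempt_apoptosis(cell, p_apt, u1)
                    else:
                        if not self.attempt_apoptosis(cell, p_apt, u1):
                            self.attempt_division(cell, p_pro, u0)
            else:
                if cell.immune_state != PERM_INACTIVE:
                    self._set_immune_state(
                        cell, ACTIVE if c_dam[cell.node] >= c_act else INACTIVE
                    )
                if (cell.cell_type == EFFECTOR and cell.immune_state == ACTIVE
                        and p.k_sup > 0):
                    self.suppression_check(cell, u=u1)
                self.move_immune(cell, u0, p_move)

        # chemokine fields advance by dt with the current source sets
        src_dam = np.array([c.node for c in self._damaged], dtype=np.int64)
        src_dying = np.array([c.node for c in self._dying], dtype=np.int64)
        evolve(self.fields, self.domain, src_dam, src_dying, dt, self.stencil)

        self.t_h += dt
        self.lysis_update(self.t_h)
        trafficking.apply_trafficking(self)

        if len(self.cells) > 2 * max(1, self.n_epi_alive + self.n_dying + self.n_eff + self.n_reg):
            self.cells = [c for c in self.cells if c.alive]

    # ------------------------------------------------------------------
    def run(self, n_steps: int, snapshot_times: list[float] | None = None):
        """Advance ``n_steps`` steps, recording counts after each.

        Returns a :class:`tdlusim.experiments.TimeSeries`. ``snapshot_times``
        (hours) additionally records immune/epithelial cell tables at the
        first step boundary >= each requested time.
        """
        from .experiments import TimeSeries

        cols = {name: np.empty(n_steps) for name in (
            "t_h", "n_epi", "n_damaged", "n_dying", "n_eff_active", "n_eff_inactive",
            "n_reg_active", "n_reg_inactive", "div_events", "apt_events")}
        snap_at = sorted(snapshot_times) if snapshot_times else []
        snap_i = 0
        snapshots = {}
        for i in range(n_steps):
            self.step()
            cols["t_h"][i] = self.t_h
            cols["n_epi"][i] = self.n_epi_alive
            cols["n_damaged"][i] = self.n_damaged
            cols["n_dying"][i] = self.n_dying
            cols["n_eff_active"][i] = self.n_eff_active
            cols["n_eff_inactive"][i] = self.n_eff_inactive + self.n_eff_perm
            cols["n_reg_active"][i] = self.n_reg_active
            cols["n_reg_inactive"][i] = self.n_reg_inactive
            cols["div_events"][i] = self.div_events
            cols["apt_events"][i] = self.apt_events
            while snap_i < len(snap_at) and self.t_h >= snap_at[snap_i] - 1e-9:
                snapshots[snap_at[snap_i]] = self.snapshot_table()
                snap_i += 1
        return TimeSeries(dt=self.params.dt, snapshots=snapshots, **cols)

    def snapshot_table(self):
        """Current cells as a records array (t_h, cell_id, x, y, cell_type, state)."""
        import pandas as pd

        rows = []
        w = self.domain.width
        for c in self.cells:
            if not c.alive:
                continue
            state = (EPI_STATE_NAMES[c.epi_state] if c.is_epithelial
                     else IMMUNE_STATE_NAMES[c.immune_state])
            rows.append((self.t_h, c.id, c.node % w, c.node // w,
                         TYPE_NAMES[c.cell_type], state))
        return pd.DataFrame(rows, columns=["t_h", "cell_id", "x", "y", "cell_type", "state"])

    def immune_points(self) -> np.ndarray:
        """(n, 2) array of (x, y) positions of all living immune cells."""
        w = self.domain.width
        pts = [(c.node % w, c.node // w) for c in self.cells if c.alive and c.is_immune]
        return np.array(pts, dtype=int).reshape(-1, 2)

    def check_occupancy(self) -> None:
        """Assert the occupancy table matches the cell list (test support)."""
        occ = np.zeros_like(self.occ_code)
        for c in self.cells:
            if not c.alive:
                continue
            if occ[c.node] != _EMPTY:
                raise AssertionError(f"two cells on node {c.node}")
            occ[c.node] = 1
        if ((self.occ_code != _EMPTY) != (occ != _EMPTY)).any():
            raise AssertionError("occupancy table out of sync with cell list")
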