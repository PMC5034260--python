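"""Cell processes, the step loop and its invariants."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tdlusim
from tdlusim import SimulationParams, Simulation, TraffickingParams, event_probability
from tdlusim import engine as eng
from tdlusim.hormones import HormoneProfile


def flat_profile(pi=1.0, ai=1.0):
    return HormoneProfile(t_grid=[0.0, 14.0, 28.0], f_pi=[pi] * 3, f_ai=[ai] * 3)


def quiet_params(**kw):
    """No turnover, no trafficking unless overridden."""
    defaults = dict(k_pro=0.0, k_apt=0.0,
                    trafficking=TraffickingParams(0, 0, 0, 0, 0, 0))
    defaults.update(kw)
    return SimulationParams(**defaults)


def make_sim(domain, params, seed=0, profile=None):
    return Simulation(domain, params, profile or flat_profile(), seed=seed)


class TestEventProbability:
    def test_zero_contacts_gives_zero(self):
        assert event_probability(0.5, 0, 1.0) == 0.0

    @pytest.mark.parametrize("rate,n,dt,expected", [
        (0.05, 1, 1.0, 0.04877057549928599),   # 1 - e^-0.05
        (0.10, 3, 1.0, 0.25918177931828213),   # 1 - e^-0.3
        (0.05, 2, 1.0, 0.09516258196404048),   # 1 - e^-0.1
    ])
    def test_closed_forms(self, rate, n, dt, expected):
        assert event_probability(rate, n, dt) == pytest.approx(expected, rel=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(rate=st.floats(1e-4, 1.0), n=st.integers(1, 8), dt=st.floats(0.1, 2.0))
    def test_hazard_is_exactly_linear_in_contacts(self, rate, n, dt):
        p = event_probability(rate, n, dt)
        hazard = -math.log1p(-p) / dt
        assert hazard == pytest.approx(rate * n, rel=1e-9)


class TestDivisionAndApoptosis:
    def test_no_free_neighbour_blocks_placement_but_logs_event(self, tiny_domain):
        sim = make_sim(tiny_domain, quiet_params())
        cell = next(c for c in sim.cells if c.is_epithelial)
        n0 = len([c for c in sim.cells if c.alive])
        daughter = sim.attempt_division(cell, p_div=1.0, u_event=0.0)
        assert daughter is None  # epithelium starts fully occupied
        assert sim.div_events == 1
        assert len([c for c in sim.cells if c.alive]) == n0

    def test_daughter_of_normal_parent_is_normal_when_kdge_zero(self, tiny_domain):
        sim = make_sim(tiny_domain, quiet_params(k_dge=0.0))
        cell = next(c for c in sim.cells if c.is_epithelial)
        # free a neighbouring epithelial node
        nb = next(int(n) for n in tiny_domain.nbr_moore[cell.node]
                  if n >= 0 and sim._epi_mask[n])
        victim = next(c for c in sim.cells if c.alive and c.node == nb)
        victim.alive = False
        sim.occ_code[nb] = 0
        sim.n_normal -= 1
        daughter = sim.attempt_division(cell, p_div=1.0, u_event=0.0)
        assert daughter is not None and daughter.epi_state == eng.NORMAL

    def test_damaged_parent_always_breeds_damaged_daughter(self, tiny_domain):
        sim = make_sim(tiny_domain, quiet_params(k_dge=0.0))
        cell = next(c for c in sim.cells if c.is_epithelial)
        cell.epi_state = eng.DAMAGED
        sim._damaged.append(cell)
        nb = next(int(n) for n in tiny_domain.nbr_moore[cell.node]
                  if n >= 0 and sim._epi_mask[n])
        victim = next(c for c in sim.cells if c.alive and c.node == nb)
        victim.alive = False
        sim.occ_code[nb] = 0
        sim.n_normal -= 1
        daughter = sim.attempt_division(cell, p_div=1.0, u_event=0.0)
        assert daughter is not None and daughter.epi_state == eng.DAMAGED

    def test_damaged_cells_never_die_by_apoptosis(self, tiny_domain):
        sim = make_sim(tiny_domain, quiet_params())
        cell = next(c for c in sim.cells if c.is_epithelial)
        cell.epi_state = eng.DAMAGED
        assert sim.attempt_apoptosis(cell, p_apt=1.0, u_event=0.0) is False
        assert cell.epi_state == eng.DAMAGED

    def test_apoptosis_threshold(self, tiny_domain):
        p = 1 - math.exp(-0.0021)
        sim = make_sim(tiny_domain, quiet_params())
        cell = next(c for c in sim.cells if c.is_epithelial)
        assert not sim.attempt_apoptosis(cell, p, u_event=p + 1e-9)
        assert sim.attempt_apoptosis(cell, p, u_event=p - 1e-9)
        assert cell.epi_state == eng.DYING


class TestKillAndSuppression:
    def _sim_with_immune(self, domain, **kw):
        sim = make_sim(domain, quiet_params(**kw))
        return sim

    def test_kill_requires_adjacent_active_effector(self, tiny_domain):
        sim = self._sim_with_immune(tiny_domain, k_kill=1e9)
        target = next(c for c in sim.cells if c.is_epithelial)
        target.epi_state = eng.DAMAGED
        sim._damaged.append(target)
        assert sim.kill_check(target, u=0.0) is False  # no effector anywhere
        # place an INACTIVE effector adjacent: still no kill
        nb = next(int(n) for n in tiny_domain.nbr_moore[target.node]
                  if n >= 0 and sim.occ_code[n] == 0 and not sim._lumen_mask[n])
        effector = sim.add_immune(eng.EFFECTOR, nb, state=eng.INACTIVE)
        assert sim.kill_check(target, u=0.0) is False
        # activate it: kill fires at the closed-form probability threshold
        sim._set_immune_state(effector, eng.ACTIVE)
        p = event_probability(sim.params.k_kill, 1, 1.0)
        assert sim.kill_check(target, u=min(p - 1e-9, 0.999999)) is True
        assert target.epi_state == eng.DYING

    def test_suppression_probability_and_irreversibility(self, tiny_domain):
        sim = self._sim_with_immune(tiny_domain, k_sup=0.05)
        node = int(np.flatnonzero(tiny_domain.stroma_mask)[40])
        effector = sim.add_immune(eng.EFFECTOR, node, state=eng.ACTIVE)
        assert sim.suppression_check(effector, u=0.0) is False  # no regulators
        placed = 0
        for nb in tiny_domain.nbr_moore[node]:
            if placed < 2 and nb >= 0 and sim.occ_code[nb] == 0 and not sim._lumen_mask[nb]:
                sim.add_immune(eng.REGULATORY, int(nb), state=eng.ACTIVE)
                placed += 1
        assert placed == 2
        p = event_probability(0.05, 2, 1.0)
        assert sim.suppression_check(effector, u=p + 1e-9) is False
        assert sim.suppression_check(effector, u=p - 1e-9) is True
        assert effector.immune_state == eng.PERM_INACTIVE
        # permanently inactivated: high chemokine never reactivates it
        sim.fields.c_dam[:] = 100.0
        sim.activation_update(effector)
        assert effector.immune_state == eng.PERM_INACTIVE


class TestActivation:
    def test_threshold_is_inclusive(self, tiny_domain):
        sim = make_sim(tiny_domain, quiet_params(c_act=0.02))
        node = int(np.flatnonzero(tiny_domain.stroma_mask)[0])
        cell = sim.add_immune(eng.EFFECTOR, node)
        sim.fields.c_dam.ravel()[node] = 0.02
        sim.activation_update(cell)
        assert cell.immune_state == eng.ACTIVE
        sim.fields.c_dam.ravel()[node] = 0.0199999
        sim.activation_update(cell)
        assert cell.immune_state == eng.INACTIVE

    def test_zero_field_means_inactive(self, tiny_domain):
        sim = make_sim(tiny_domain, quiet_params())
        node = int(np.flatnonzero(tiny_domain.stroma_mask)[0])
        cell = sim.add_immune(eng.REGULATORY, node, state=eng.ACTIVE)
        sim.activation_update(cell)
        assert cell.immune_state == eng.INACTIVE


class TestMotility:
    def test_flat_field_moves_uniformly(self, tiny_domain):
        sim = make_sim(tiny_domain, quiet_params(chi=50.0), seed=5)
        start = int(np.flatnonzero(tiny_domain.stroma_mask)[60])
        counts = {}
        n_draws = 10_000
        for _ in range(n_draws):
            cell = eng.CellAgent(sim._new_id(), start, eng.EFFECTOR)
            sim.occ_code[start] = 5
            sim.move_immune(cell, u_event=0.0, p_move=1.0)
            counts[cell.node] = counts.get(cell.node, 0) + 1
            sim.occ_code[cell.node] = 0
        nbrs = [int(n) for n in tiny_domain.nbr_moore[start]
                if n >= 0 and not sim._lumen_mask[n]]
        assert set(counts) <= set(nbrs)
        expected = n_draws / len(nbrs)
        chi2 = sum((c - expected) ** 2 / expected for c in counts.values())
        assert chi2 < 26.0  # chi^2_(7 dof) 99.95% quantile

    def test_lumen_neighbour_never_selected(self, tiny_domain):
        sim = make_sim(tiny_domain, quiet_params())
        # find a stromal/epithelial-free node adjacent to a lumen node
        lumen_adjacent = None
        for node in np.flatnonzero(tiny_domain.epithelium_mask):
            victim = next(c for c in sim.cells if c.alive and c.node == node)
            if any(nb >= 0 and sim._lumen_mask[nb] for nb in tiny_domain.nbr_moore[node]):
                lumen_adjacent = int(node)
                victim.alive = False
                sim.occ_code[node] = 0
                sim.n_normal -= 1
                break
        assert lumen_adjacent is not None
        cell = sim.add_immune(eng.EFFECTOR, lumen_adjacent)
        for _ in range(500):
            sim.move_immune(cell, u_event=0.0, p_move=1.0)
            assert not sim._lumen_mask[cell.node]

    def test_strong_gradient_climbs_uphill_with_softmax_weights(self, tiny_domain):
        sim = make_sim(tiny_domain, quiet_params(chi=100.0), seed=3)
        start = int(np.flatnonzero(tiny_domain.stroma_mask)[60])
        w = tiny_domain.width
        ramp = (np.arange(tiny_domain.n_nodes) % w) * 0.05
        sim.fields.c_dam[:] = ramp.reshape(tiny_domain.shape)
        uphill = 0
        n_draws = 2000
        for _ in range(n_draws):
            cell = eng.CellAgent(sim._new_id(), start, eng.EFFECTOR)
            sim.occ_code[start] = 5
            sim.move_immune(cell, u_event=0.0, p_move=1.0)
            if cell.node % w > start % w:
                uphill += 1
            sim.occ_code[cell.node] = 0
        # brute-force softmax over the admissible neighbourhood
        nbrs = [int(n) for n in tiny_domain.nbr_moore[start]
                if n >= 0 and not sim._lumen_mask[n]]
        weights = np.exp(np.minimum(100.0 * (ramp[nbrs] - ramp[start]), 50.0))
        p_uphill = weights[[n % w > start % w for n in nbrs]].sum() / weights.sum()
        assert p_uphill > 0.9
        assert uphill / n_draws == pytest.approx(p_uphill, abs=0.03)


class TestLysis:
    def test_zero_lag_removes_in_same_step(self, tiny_domain):
        sim = make_sim(tiny_domain, quiet_params(k_apt=10.0, tau_lys=0.0),
                       profile=flat_profile())
        sim.step()
        assert sim.n_dying == 0
        assert sim.apt_events > 0  # cells did die this step

    def test_debris_persists_for_tau_then_frees_node(self, tiny_domain):
        sim = make_sim(tiny_domain, quiet_params(tau_lys=12.0))
        cell = next(c for c in sim.cells if c.is_epithelial)
        node = cell.node
        sim.t_h = 4.0  # entering DYING during the step ending at t=5
        sim.attempt_apoptosis(cell, p_apt=1.0, u_event=0.0)
        assert cell.dying_since == pytest.approx(5.0)
        for t in (6.0, 12.0, 16.9):
            sim.lysis_update(now=t)
            assert cell.alive and sim.occ_code[node] != 0
        sim.lysis_update(now=17.0)
        assert not cell.alive and sim.occ_code[node] == 0


class TestStep:
    def test_identical_seeds_give_bit_identical_trajectories(self, small_domain):
        p = SimulationParams(k_dge=0.1, k_kill=0.05)
        a = Simulation(small_domain, p, seed=11)
        b = Simulation(small_domain, p, seed=11)
        ts_a = a.run(48)
        ts_b = b.run(48)
        assert np.array_equal(ts_a.n_epi, ts_b.n_epi)
        assert np.array_equal(ts_a.n_eff_active, ts_b.n_eff_active)
        assert sorted((c.node, c.cell_type) for c in a.cells if c.alive) == \
               sorted((c.node, c.cell_type) for c in b.cells if c.alive)

    def test_occupancy_invariant_holds_through_dynamics(self, small_domain):
        sim = Simulation(small_domain, SimulationParams(k_dge=0.2, k_kill=0.05), seed=2)
        for _ in range(60):
            sim.step()
        sim.check_occupancy()

    def test_instant_kill_limit(self, tiny_domain):
        sim = make_sim(tiny_domain, quiet_params(k_kill=1e9, c_act=0.0))
        target = next(c for c in sim.cells if c.is_epithelial)
        target.epi_state = eng.DAMAGED
        sim.occ_code[target.node] = 2
        sim._damaged.append(target)
        sim.n_normal -= 1
        sim.n_damaged += 1
        nb = next(int(n) for n in tiny_domain.nbr_moore[target.node]
                  if n >= 0 and sim.occ_code[n] == 0 and not sim._lumen_mask[n])
        sim.add_immune(eng.EFFECTOR, nb, state=eng.ACTIVE)
        sim.fields.c_dam[:] = 1.0  # keep the effector active (c_act=0 anyway)
        sim.step()
        assert target.epi_state == eng.DYING

    def test_immune_headcount_conserved_without_trafficking(self, small_domain):
        sim = make_sim(small_domain, quiet_params(m_rate=10.0))
        for _ in range(10):
            node = sim._random_free_stromal_node()
            sim.add_immune(eng.EFFECTOR if _ % 2 else eng.REGULATORY, node)
        for _ in range(30):
            sim.step()
        assert sim.n_eff + sim.n_reg == 10

    def test_damaged_count_monotone_when_killing_disabled(self, small_domain):
        p = SimulationParams(k_dge=0.3, k_kill=0.0,
                             trafficking=TraffickingParams(0, 0, 0, 0, 0, 0))
        sim = Simulation(small_domain, p, seed=4)
        ts = sim.run(24 * 10)
        assert (np.diff(ts.n_damaged) >= 0).all()
        assert ts.n_damaged[-1] > 0

    def test_short_run_homeostasis(self, small_domain):
        sim = Simulation(small_domain, SimulationParams(), seed=9)
        ts = sim.run(24 * 28 * 2)
        mean = ts.n_epi.mean()
        assert abs(ts.n_epi[-1] - mean) / mean < 0.10
        assert ts.n_epi.min() > 0.8 * small_domain.n_epithelial
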