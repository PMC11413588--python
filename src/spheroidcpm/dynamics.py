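"""Metropolis index-copy dynamics and the Monte Carlo Step clock.

One Monte Carlo Step (MCS) = a fixed number of index-copy attempts (default:
one per lattice voxel) followed by the cell/ECM lifecycle update.  Time is
calibrated as 1 MCS = 6 min, 240 MCS = 1 culture day, with 0 MCS representing
day 1 of culture (so 3120 MCS is day 14).

Moves are accepted with the Metropolis–Boltzmann rule
``P(accept) = min(1, exp(−ΔH / Tm))`` at domain temperature Tm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import kernel, lifecycle
from .energy import EnergyModel, delta_for_relabel
from .lattice import (MEDIUM_ID, Neighborhood, VoxelLattice, apply_index_copy,
                      neighbor_voxels)
from .params import ParameterSet


@dataclass
class DomainParameters:
    """Domain-level Monte Carlo settings."""

    Tm: float = 37.0
    attempts_per_mcs: int | None = None   # None = one attempt per voxel
    neighborhood: Neighborhood = field(default_factory=lambda: Neighborhood(2))
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.Tm <= 0:
            raise ValueError("domain temperature Tm must be positive")
        if self.attempts_per_mcs is not None and self.attempts_per_mcs < 1:
            raise ValueError("attempts_per_mcs must be at least 1")


@dataclass
class SimulationClock:
    """Maps MCS to culture days: day(mcs) = day_at_mcs_zero + mcs/steps_per_day."""

    mcs: int = 0
    minutes_per_step: float = 6.0
    steps_per_day: int = 240
    day_at_mcs_zero: float = 1.0

    @property
    def day(self) -> float:
        return self.day_at_mcs_zero + self.mcs / self.steps_per_day


def mcs_for_day(clock: SimulationClock, day: float) -> int:
    """MCS index corresponding to a culture day (day 1 → 0, day 14 → 3120)."""
    if day < clock.day_at_mcs_zero:
        raise ValueError(f"day {day} precedes the simulation origin "
                         f"(day {clock.day_at_mcs_zero})")
    return round((day - clock.day_at_mcs_zero) * clock.steps_per_day)


def acceptance_probability(delta_h: float, Tm: float) -> float:
    """Metropolis rule: 1 for downhill/neutral moves, exp(−ΔH/Tm) uphill."""
    if Tm <= 0:
        raise ValueError("Tm must be positive")
    if delta_h <= 0:
        return 1.0
    return math.exp(-delta_h / Tm)


_COUNTER_KEYS = ("attempts", "distinct_attempts", "accepted", "mitoses",
                 "secretions_ECMst", "secretions_ECMv", "ecm_deletions",
                 "cell_deaths", "secretions_blocked")


class SimulationState:
    """Lattice + parameters + clock + RNG: the unit advanced one MCS at a time.

    Two seeded streams derive from ``domain.rng_seed``: an xorshift128+ state
    driving the compiled sweep and a numpy Generator driving the lifecycle, so
    a (config, seed) pair fixes the whole trajectory.
    """

    BBOX_REFRESH_INTERVAL = 25

    def __init__(self, lattice: VoxelLattice, params: ParameterSet,
                 domain: DomainParameters | None = None,
                 ecm_target_mode: str = "decay",
                 independent_action_draws: bool = False):
        if ecm_target_mode not in ("decay", "unconstrained"):
            raise ValueError("ecm_target_mode must be 'decay' or 'unconstrained'")
        self.lattice = lattice
        self.params = params
        self.domain = domain or DomainParameters()
        self.model = EnergyModel.from_parameters(params, self.domain.neighborhood)
        if ecm_target_mode == "unconstrained":
            from .lattice import CompartmentType
            self.model.constraint.applies_to = frozenset({CompartmentType.Cell})
        self.ecm_target_mode = ecm_target_mode
        self.independent_action_draws = independent_action_draws
        self.clock = SimulationClock()
        self.rng = np.random.default_rng(self.domain.rng_seed)
        self.kernel_state = kernel.seed_state(self.domain.rng_seed)
        self.counters = {k: 0 for k in _COUNTER_KEYS}
        self.event_log: list[tuple] = []

    # -- energy -----------------------------------------------------------

    def total_energy(self) -> float:
        from .energy import total_energy
        return total_energy(self.lattice, self.model)

    def attempts_per_mcs(self) -> int:
        if self.domain.attempts_per_mcs is not None:
            return self.domain.attempts_per_mcs
        return int(np.prod(self.lattice.dims))

    # -- logging ----------------------------------------------------------

    def log_event(self, event: str, cid: int) -> None:
        zone = self.params.zone.value
        self.event_log.append((self.clock.mcs, event, cid, zone))


def attempt_index_copy(state: SimulationState, rng: np.random.Generator) -> bool:
    """One index-copy attempt through the reference (non-compiled) path.

    Samples a target voxel uniformly and a source site uniformly among its
    neighbors; same-label draws are counted and rejected without an energy
    evaluation.  Returns whether a copy was applied.
    """
    lat = state.lattice
    nx, ny, nz = lat.dims
    t = (int(rng.integers(nx)), int(rng.integers(ny)), int(rng.integers(nz)))
    sites = neighbor_voxels(lat, t, state.domain.neighborhood)
    site = sites[int(rng.integers(len(sites)))]
    old = lat.label_at(t)
    state.counters["attempts"] += 1
    if site.label == old:
        return False
    state.counters["distinct_attempts"] += 1
    dh = delta_for_relabel(lat, state.model, t, site.label)
    if dh > 0 and rng.random() >= acceptance_probability(dh, state.domain.Tm):
        return False
    if site.inside:
        apply_index_copy(lat, site.coord, t)
    else:  # virtual medium source at the fixed boundary
        lat.labels[t] = MEDIUM_ID
        lat.volume[MEDIUM_ID] += 1
        lat.volume[old] -= 1
    state.counters["accepted"] += 1
    return True


def run_mcs(state: SimulationState, n_mcs: int = 1,
            use_kernel: bool = True) -> SimulationState:
    """Advance the simulation by ``n_mcs`` Monte Carlo Steps.

    Each step performs the index-copy attempts, then the cell/ECM lifecycle
    update, then advances the clock.
    """
    for _ in range(n_mcs):
        n_att = state.attempts_per_mcs()
        if use_kernel:
            args = kernel.sweep_args(state.lattice, state.model)
            att, dist, acc = kernel.metropolis_sweep(
                state.lattice.labels, args["class_of"], state.lattice.volume,
                state.lattice.target_volume, args["constrained"], args["jmat"],
                args["lam"], float(state.domain.Tm), n_att, args["offsets"],
                args["periodic"], state.lattice.bbox, state.kernel_state)
            state.counters["attempts"] += int(att)
            state.counters["distinct_attempts"] += int(dist)
            state.counters["accepted"] += int(acc)
        else:
            for _ in range(n_att):
                attempt_index_copy(state, state.rng)
        lifecycle.step(state)
        state.clock.mcs += 1
        if state.clock.mcs % SimulationState.BBOX_REFRESH_INTERVAL == 0:
            kernel.tighten_bboxes(state.lattice.labels,
                                  state.lattice.bbox[: state.lattice.n_ids])
    return state
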