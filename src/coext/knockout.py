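"""Core extinction engine.

Implements the fractional-loss threshold rule, the effective threshold, the
survivor curve a(p) and its normalized area (robustness R), and the three
knockout models:

* SO (Secondary Only): plants removed in uniform-random order; pollinators
  die when they have lost a fraction >= T of their original edges (binary)
  or total weight (weighted).
* DA (Deterministic Avalanche): as SO, but plants that have themselves lost
  a fraction >= T go extinct too, so a single random trigger can set off an
  avalanche of alternating plant/pollinator extinctions.
* RW (Random Walk): extinction hops from the current plant e to a neighbor
  g with probability proportional to the number of pollinators they still
  share; the threshold rule applies to pollinators only. When e shares no
  pollinators with any surviving plant, a fresh random trigger is drawn.

Within a DA avalanche, plants crossing the threshold are removed one at a
time in uniform-random order, with a(p) recorded and thresholds re-checked
after every single removal, so the survivor curve always has P + 1 points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network_io import BipartiteNetwork

__all__ = [
    "ModelConfig",
    "ExtinctionState",
    "ExtinctionRun",
    "robustness",
    "effective_threshold",
    "node_average_effective_threshold",
    "remove_plant",
    "run_so",
    "run_da",
    "run_rw",
    "run_ordered",
    "run_model",
    "shared_pollinator_matrix",
]

SO, DA, RW = "SO", "DA", "RW"
_MODELS = (SO, DA, RW)

# slack for 'loss >= T * original' comparisons under float accumulation
_EPS = 1e-9


@dataclass(frozen=True)
class ModelConfig:
    """Which model to run, in which mode, at which threshold."""

    model: str = SO
    weighted: bool = False
    T: float = 0.5
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "model", str(self.model).upper())
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}, got {self.model!r}")
        if not 0 < self.T <= 1:
            raise ValueError(f"threshold must satisfy 0 < T <= 1, got {self.T}")


class ExtinctionState:
    """Mutable state of one simulation: reduced matrix plus loss bookkeeping.

    ``C`` is the original matrix restricted to surviving species (removed
    species' rows/columns zeroed). Original per-node totals are frozen at
    construction; losses are tracked incrementally.
    """

    def __init__(self, net: BipartiteNetwork, weighted: bool):
        W = net.M.astype(float) if weighted else (net.M > 0).astype(float)
        self.C = W.copy()
        self.n_animals, self.n_plants = W.shape
        self.weighted = weighted
        self.alive_animals = np.ones(self.n_animals, dtype=bool)
        self.alive_plants = np.ones(self.n_plants, dtype=bool)
        self.animal_original = W.sum(axis=1)
        self.plant_original = W.sum(axis=0)
        if np.any(self.animal_original == 0) or np.any(self.plant_original == 0):
            raise ValueError("extinction runs require every species to have >= 1 interaction")
        self.animal_remaining = self.animal_original.copy()
        self.plant_remaining = self.plant_original.copy()

    def alive_animal_count(self) -> int:
        return int(self.alive_animals.sum())

    def alive_plant_indices(self) -> np.ndarray:
        return np.flatnonzero(self.alive_plants)

    def plants_over_threshold(self, T: float) -> np.ndarray:
        """Indices of surviving plants that have lost a fraction >= T."""
        loss = self.plant_original - self.plant_remaining
        hit = self.alive_plants & (loss >= T * self.plant_original - _EPS)
        return np.flatnonzero(hit)


@dataclass(frozen=True)
class ExtinctionRun:
    """Record of one full extinction sequence."""

    plant_sequence: tuple  # plant indices in removal order
    a_curve: np.ndarray  # surviving-pollinator counts for p = 0..P
    R: float
    ranks: np.ndarray  # per-plant extinction rank, 1..P
    trigger_flags: tuple  # True where the removal was a random trigger

    @property
    def n_triggers(self) -> int:
        return sum(self.trigger_flags)


def robustness(a_curve, A: int, P: int) -> float:
    """Normalized area under the survivor curve: (1/(A*P)) * sum_p a(p)."""
    a = np.asarray(a_curve, dtype=float)
    if a.shape != (P + 1,):
        raise ValueError(f"a_curve must have P+1={P + 1} entries, got {a.shape}")
    if a[0] != A or a[-1] != 0:
        raise ValueError("a_curve must start at A and end at 0")
    if np.any(np.diff(a) > 0):
        raise ValueError("a_curve must be non-increasing")
    return float(a.sum() / (A * P))


def effective_threshold(k: int, T: float) -> float:
    """Smallest realizable lost-edge fraction >= T for a binary node of degree k.

    ceil(T*k)/k; e.g. a node with 5 edges at T = 0.5 dies on its 3rd loss,
    an effective threshold of 0.6.
    """
    if k < 1:
        raise ValueError(f"degree must be >= 1, got {k}")
    if not 0 < T <= 1:
        raise ValueError(f"threshold must satisfy 0 < T <= 1, got {T}")
    return math.ceil(T * k - _EPS) / k


def node_average_effective_threshold(
    net: BipartiteNetwork, T: float, guild: str = "both"
) -> float:
    """Mean effective threshold over network nodes (binary degrees).

    ``guild`` selects ``'both'`` (all A + P nodes, the default), ``'plants'``
    or ``'animals'``.
    """
    B = net.binary_pattern()
    plant_k = B.sum(axis=0)
    animal_k = B.sum(axis=1)
    if guild == "both":
        ks = np.concatenate([animal_k, plant_k])
    elif guild == "plants":
        ks = plant_k
    elif guild == "animals":
        ks = animal_k
    else:
        raise ValueError(f"guild must be 'both', 'plants' or 'animals', got {guild!r}")
    return float(np.mean([effective_threshold(int(k), T) for k in ks]))


def remove_plant(state: ExtinctionState, plant: int, config: ModelConfig):
    """Remove one plant; apply the pollinator threshold rule.

    All pollinators crossing the threshold after this single plant removal
    are removed simultaneously (their rows zeroed, plant losses updated).
    Returns ``(state, newly_extinct_animal_indices)``.
    """
    if not state.alive_plants[plant]:
        raise ValueError(f"plant {plant} is already extinct")
    col = state.C[:, plant].copy()
    state.alive_plants[plant] = False
    state.C[:, plant] = 0.0
    state.animal_remaining -= col
    state.plant_remaining[plant] = 0.0
    loss = state.animal_original - state.animal_remaining
    newly = np.flatnonzero(
        state.alive_animals & (loss >= config.T * state.animal_original - _EPS)
    )
    for i in newly:
        state.alive_animals[i] = False
        row = state.C[i, :].copy()
        state.C[i, :] = 0.0
        state.plant_remaining -= row
    return state, newly


def shared_pollinator_matrix(state: ExtinctionState) -> np.ndarray:
    """P x P matrix F: F[e, g] = surviving pollinators shared by plants e, g.

    Symmetric, zero diagonal; rows/columns of extinct plants are zero.
    """
    B = (state.C > 0).astype(int)
    F = B.T @ B
    np.fill_diagonal(F, 0)
    return F


def _shared_row(state: ExtinctionState, e: int) -> np.ndarray:
    """Row e of the shared-pollinator matrix against the current state."""
    col = state.C[:, e] > 0
    row = ((state.C > 0) & col[:, None]).sum(axis=0)
    row[e] = 0
    return row


def _finish(state: ExtinctionState, seq, a_curve, flags) -> ExtinctionRun:
    P = state.n_plants
    ranks = np.empty(P, dtype=int)
    ranks[np.asarray(seq)] = np.arange(1, P + 1)
    R = robustness(a_curve, state.n_animals, P)
    return ExtinctionRun(
        plant_sequence=tuple(int(p) for p in seq),
        a_curve=np.asarray(a_curve, dtype=int),
        R=R,
        ranks=ranks,
        trigger_flags=tuple(flags),
    )


def _rng_for(config: ModelConfig, rng):
    return np.random.default_rng(config.seed) if rng is None else rng


def run_so(net: BipartiteNetwork, config: ModelConfig, rng=None) -> ExtinctionRun:
    """Secondary Only: uniform-random plant order, threshold rule on pollinators."""
    rng = _rng_for(config, rng)
    state = ExtinctionState(net, config.weighted)
    a = [state.alive_animal_count()]
    seq, flags = [], []
    while state.alive_plants.any():
        e = int(rng.choice(state.alive_plant_indices()))
        remove_plant(state, e, config)
        seq.append(e)
        flags.append(True)
        a.append(state.alive_animal_count())
    return _finish(state, seq, a, flags)


def run_da(net: BipartiteNetwork, config: ModelConfig, rng=None) -> ExtinctionRun:
    """Deterministic Avalanche: random triggers with threshold-driven plant spread."""
    rng = _rng_for(config, rng)
    state = ExtinctionState(net, config.weighted)
    a = [state.alive_animal_count()]
    seq, flags = [], []

    def _remove(plant, is_trigger):
        remove_plant(state, plant, config)
        seq.append(plant)
        flags.append(is_trigger)
        a.append(state.alive_animal_count())

    while state.alive_plants.any():
        trigger = int(rng.choice(state.alive_plant_indices()))
        _remove(trigger, True)
        while True:
            candidates = state.plants_over_threshold(config.T)
            if candidates.size == 0:
                break
            _remove(int(rng.choice(candidates)), False)
    return _finish(state, seq, a, flags)


def run_rw(net: BipartiteNetwork, config: ModelConfig, rng=None) -> ExtinctionRun:
    """Random Walk: extinction hops between plants via shared pollinators.

    The next victim is chosen (proportional to shared surviving pollinators,
    computed before the current plant is removed); plants die only by being
    visited, never by the threshold rule.
    """
    rng = _rng_for(config, rng)
    state = ExtinctionState(net, config.weighted)
    a = [state.alive_animal_count()]
    seq, flags = [], []
    while state.alive_plants.any():
        e = int(rng.choice(state.alive_plant_indices()))
        is_trigger = True
        while True:
            row = _shared_row(state, e)
            total = row.sum()
            if total > 0:
                nxt = int(rng.choice(state.n_plants, p=row / total))
            else:
                nxt = None
            remove_plant(state, e, config)
            seq.append(e)
            flags.append(is_trigger)
            a.append(state.alive_animal_count())
            if nxt is None:
                break
            e, is_trigger = nxt, False
    return _finish(state, seq, a, flags)


def run_ordered(net: BipartiteNetwork, order, config: ModelConfig) -> ExtinctionRun:
    """SO mechanics with a deterministic primary sequence.

    ``order`` is ``'increasing_degree'``, ``'decreasing_degree'`` or an
    explicit permutation of plant indices. Degree ties break by original
    column index (stable sort).
    """
    P = net.n_plants
    deg = net.binary_pattern().sum(axis=0)
    if isinstance(order, str):
        if order == "increasing_degree":
            seq = np.argsort(deg, kind="stable")
        elif order == "decreasing_degree":
            seq = np.argsort(-deg, kind="stable")
        else:
            raise ValueError(f"unknown order {order!r}")
    else:
        seq = np.asarray(list(order), dtype=int)
        if sorted(seq.tolist()) != list(range(P)):
            raise ValueError("explicit order must be a permutation of all plant indices")
    state = ExtinctionState(net, config.weighted)
    a = [state.alive_animal_count()]
    flags = []
    for e in seq:
        remove_plant(state, int(e), config)
        flags.append(True)
        a.append(state.alive_animal_count())
    return _finish(state, list(seq), a, flags)


_RUNNERS = {SO: run_so, DA: run_da, RW: run_rw}


def run_model(net: BipartiteNetwork, config: ModelConfig, rng=None) -> ExtinctionRun:
    """Dispatch one simulation according to ``config.model``."""
    return _RUNNERS[config.model](net, config, rng)
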