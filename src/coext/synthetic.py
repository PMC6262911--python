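"""Synthetic network generation.

Produces validated fixture networks with controllable size, edge count,
plant-degree skew and weight distribution, so simulations and tests run
without any external data. The skewed mode plants a single hub of degree
about ``hub_fraction * A`` and fills the remaining edges by preferential
attachment over the non-hub plants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network_io import BipartiteNetwork

__all__ = [
    "GeneratorSpec",
    "GeneratorError",
    "generate",
    "perfect_matching",
    "star",
    "two_component",
    "nested_triangle",
    "ac_like",
    "fixture_library",
]

UNIFORM = "uniform"
SKEWED = "skewed"
UNIT = "unit"
GEOMETRIC = "geometric"


class GeneratorError(ValueError):
    """Requested network is infeasible; message names the violated bound."""


@dataclass(frozen=True)
class GeneratorSpec:
    n_plants: int
    n_animals: int
    n_edges: int
    skew: str = UNIFORM  # 'uniform' | 'skewed'
    hub_fraction: float = 0.0
    weight_model: str = UNIT  # 'unit' | 'geometric'
    weight_mean: float = 3.0
    seed: int | None = None

    def __post_init__(self):
        P, A, E = self.n_plants, self.n_animals, self.n_edges
        if P < 1 or A < 1:
            raise GeneratorError("need n_plants >= 1 and n_animals >= 1")
        if E < max(A, P):
            raise GeneratorError(
                f"E={E} < max(A, P)={max(A, P)}: every species needs an edge"
            )
        if E > A * P:
            raise GeneratorError(f"E={E} > A*P={A * P}: too many edges")
        if self.skew not in (UNIFORM, SKEWED):
            raise GeneratorError(f"skew must be '{UNIFORM}' or '{SKEWED}'")
        if self.skew == SKEWED:
            if not 0 < self.hub_fraction <= 1:
                raise GeneratorError("hub_fraction must lie in (0, 1]")
            if E < A + P - 1:
                raise GeneratorError(
                    f"skewed mode needs E >= A+P-1 = {A + P - 1}, got E={E}"
                )
        if self.weight_model not in (UNIT, GEOMETRIC):
            raise GeneratorError(f"weight_model must be '{UNIT}' or '{GEOMETRIC}'")
        if self.weight_model == GEOMETRIC and self.weight_mean < 1:
            raise GeneratorError("weight_mean must be >= 1")


def _labels(prefix: str, n: int):
    return [f"{prefix}{i + 1}" for i in range(n)]


def _uniform_pattern(A: int, P: int, E: int, rng) -> np.ndarray:
    """Cyclic spanning assignment (covers both guilds with max(A,P) edges),
    then uniform fill of empty cells."""
    B = np.zeros((A, P), dtype=int)
    animals = rng.permutation(A)
    plants = rng.permutation(P)
    for idx in range(max(A, P)):
        B[animals[idx % A], plants[idx % P]] = 1
    need = E - int(B.sum())
    if need > 0:
        empty = np.flatnonzero(B.ravel() == 0)
        B.ravel()[rng.choice(empty, size=need, replace=False)] = 1
    return B


def _skewed_pattern(A: int, P: int, E: int, hub_fraction: float, rng) -> np.ndarray:
    """Hub plant of degree ~ hub_fraction*A, every species covered, remaining
    edges by preferential attachment over non-hub plants."""
    B = np.zeros((A, P), dtype=int)
    hub = 0
    h = min(max(1, round(hub_fraction * A)), A, E - (P - 1))
    B[rng.choice(A, size=h, replace=False), hub] = 1
    nonhub = np.arange(1, P) if P > 1 else np.array([hub])
    # cover animals the hub missed
    for i in np.flatnonzero(B.sum(axis=1) == 0):
        B[i, rng.choice(nonhub)] = 1
    # cover still-empty plants
    for j in np.flatnonzero(B.sum(axis=0) == 0):
        B[rng.choice(A), j] = 1
    # preferential fill among non-hub plants
    guard = 0
    while int(B.sum()) < E:
        deg = B[:, nonhub].sum(axis=0).astype(float) + 1.0
        j = int(rng.choice(nonhub, p=deg / deg.sum()))
        free = np.flatnonzero(B[:, j] == 0)
        if free.size:
            B[int(rng.choice(free)), j] = 1
        guard += 1
        if guard > 50 * E:
            # non-hub columns saturated; spill the remainder anywhere
            empty = np.flatnonzero(B.ravel() == 0)
            need = E - int(B.sum())
            B.ravel()[rng.choice(empty, size=need, replace=False)] = 1
    return B


def generate(spec: GeneratorSpec) -> BipartiteNetwork:
    """Generate a validated network with exactly ``spec.n_edges`` edges and
    no zero-degree species. Deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    A, P, E = spec.n_animals, spec.n_plants, spec.n_edges
    if spec.skew == SKEWED:
        B = _skewed_pattern(A, P, E, spec.hub_fraction, rng)
    else:
        B = _uniform_pattern(A, P, E, rng)
    assert int(B.sum()) == E
    if spec.weight_model == GEOMETRIC:
        W = np.zeros((A, P))
        ii, jj = np.nonzero(B)
        W[ii, jj] = rng.geometric(p=1.0 / spec.weight_mean, size=E)
        weighted = True
    else:
        W = B.astype(float)
        weighted = False
    return BipartiteNetwork(_labels("A", A), _labels("P", P), W, weighted=weighted)


# -- canned fixtures ---------------------------------------------------------


def perfect_matching(p: int = 4) -> BipartiteNetwork:
    """p x p identity pattern: every plant has one private pollinator."""
    return BipartiteNetwork(_labels("A", p), _labels("P", p), np.eye(p), weighted=False)


def star(a: int = 5) -> BipartiteNetwork:
    """One plant visited by all ``a`` pollinators."""
    return BipartiteNetwork(
        _labels("A", a), ["P1"], np.ones((a, 1)), weighted=False
    )


def two_component() -> BipartiteNetwork:
    """Two disconnected 2x2 complete blocks (block-diagonal pattern)."""
    M = np.zeros((4, 4))
    M[:2, :2] = 1
    M[2:, 2:] = 1
    return BipartiteNetwork(_labels("A", 4), _labels("P", 4), M, weighted=False)


def nested_triangle() -> BipartiteNetwork:
    """Perfectly nested 3x3 triangular pattern (NODF = 100)."""
    M = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0]], dtype=float)
    return BipartiteNetwork(_labels("A", 3), _labels("P", 3), M, weighted=False)


#: fixed seed so the ac_like fixture is identical across sessions
_AC_SEED = 20181031


def ac_like(seed: int = _AC_SEED) -> BipartiteNetwork:
    """Skewed weighted fixture with P=25, A=79, E=299 (connectance 0.151)
    and a hub plant of degree ~ 0.6 * A, emulating a highly skewed
    plant-degree empirical network."""
    return generate(
        GeneratorSpec(
            n_plants=25,
            n_animals=79,
            n_edges=299,
            skew=SKEWED,
            hub_fraction=0.6,
            weight_model=GEOMETRIC,
            weight_mean=3.0,
            seed=seed,
        )
    )


def fixture_library() -> dict:
    """Deterministic named fixtures used throughout the tests."""
    return {
        "perfect_matching": perfect_matching(4),
        "star": star(5),
        "two_component": two_component(),
        "nested_triangle": nested_triangle(),
        "ac_like": ac_like(),
    }
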