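"""Degree-distribution manipulation null models.

Three randomization schemes for a binary network: ``full`` places all E
interactions between uniformly random (animal, plant) pairs; the guild
schemes keep one guild's degrees exact and redistribute the other guild's
entries at random. From an ensemble of draws we compute the expected degree
distributions (G_A, G_P) and pick the single exemplar network whose degree
distributions are closest to them in L1 distance.

Individual draws may leave species with zero degree; those are legal inside
the ensemble (the statistics are well-defined) but ineligible as exemplars,
because extinction runs require every species to start with an interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network_io import BipartiteNetwork, to_binary

__all__ = [
    "RandomizationScheme",
    "FULL",
    "RANDOMIZE_PLANTS",
    "RANDOMIZE_ANIMALS",
    "randomize_full",
    "randomize_guild",
    "expected_degree_distribution",
    "degree_distance",
    "select_exemplar",
    "build_exemplar",
]

FULL = "full"
RANDOMIZE_PLANTS = "randomize_plants"
RANDOMIZE_ANIMALS = "randomize_animals"
_MODES = (FULL, RANDOMIZE_PLANTS, RANDOMIZE_ANIMALS)


@dataclass(frozen=True)
class RandomizationScheme:
    mode: str = FULL
    ensemble_size: int = 10_000

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")


def _wrap(net: BipartiteNetwork, B: np.ndarray) -> BipartiteNetwork:
    return BipartiteNetwork(
        net.animal_labels,
        net.plant_labels,
        B.astype(float),
        weighted=False,
        allow_zero_degree=True,
    )


def randomize_full(net: BipartiteNetwork, rng) -> BipartiteNetwork:
    """Place E interactions on E distinct uniformly random cells."""
    B0 = net.binary_pattern()
    A, P = B0.shape
    E = int(B0.sum())
    cells = rng.choice(A * P, size=E, replace=False)
    B = np.zeros(A * P, dtype=int)
    B[cells] = 1
    return _wrap(net, B.reshape(A, P))


def randomize_guild(net: BipartiteNetwork, preserve: str, rng) -> BipartiteNetwork:
    """Keep one guild's degrees exact; redistribute the other at random.

    ``preserve='animals'``: each pollinator keeps its degree but its entries
    land in a uniformly random set of plant columns (plant degrees change).
    ``preserve='plants'``: the symmetric operation on columns.
    """
    B0 = net.binary_pattern()
    A, P = B0.shape
    B = np.zeros_like(B0)
    if preserve == "animals":
        for i in range(A):
            k = int(B0[i].sum())
            B[i, rng.choice(P, size=k, replace=False)] = 1
    elif preserve == "plants":
        for j in range(P):
            k = int(B0[:, j].sum())
            B[rng.choice(A, size=k, replace=False), j] = 1
    else:
        raise ValueError(f"preserve must be 'animals' or 'plants', got {preserve!r}")
    return _wrap(net, B)


def _draw(net: BipartiteNetwork, mode: str, rng) -> BipartiteNetwork:
    if mode == FULL:
        return randomize_full(net, rng)
    if mode == RANDOMIZE_PLANTS:
        return randomize_guild(net, "animals", rng)  # plant degrees randomized
    return randomize_guild(net, "plants", rng)  # pollinator degrees randomized


def _degree_counts(B: np.ndarray, axis: int, length: int) -> np.ndarray:
    """Counts of species per degree k (index k, including k = 0)."""
    return np.bincount(B.sum(axis=axis), minlength=length)


def _counts_to_dict(counts: np.ndarray) -> dict:
    return {int(k): float(c) for k, c in enumerate(counts) if c > 0}


def degree_distance(gA: dict, gP: dict, GA: dict, GP: dict) -> float:
    """L1 distance sum_k |gA(k) - GA(k)| + |gP(k) - GP(k)|."""
    d = 0.0
    for g, G in ((gA, GA), (gP, GP)):
        for k in set(g) | set(G):
            d += abs(g.get(k, 0.0) - G.get(k, 0.0))
    return d


def _ensemble_counts(net: BipartiteNetwork, scheme: RandomizationScheme, master_seed):
    """Per-draw degree-count arrays for both guilds (memory-light: matrices
    are regenerable from the spawned child seeds)."""
    A, P = net.n_animals, net.n_plants
    children = np.random.SeedSequence(master_seed).spawn(scheme.ensemble_size)
    ga = np.empty((scheme.ensemble_size, P + 1), dtype=int)
    gp = np.empty((scheme.ensemble_size, A + 1), dtype=int)
    for i, child in enumerate(children):
        B = _draw(net, scheme.mode, np.random.default_rng(child)).binary_pattern()
        ga[i] = _degree_counts(B, axis=1, length=P + 1)
        gp[i] = _degree_counts(B, axis=0, length=A + 1)
    return ga, gp, children


def expected_degree_distribution(
    scheme: RandomizationScheme, net: BipartiteNetwork, master_seed
) -> tuple[dict, dict]:
    """Ensemble-average degree distributions (G_A(k), G_P(k)).

    Means of per-k species counts over the generated ensemble; a preserved
    guild's distribution equals the observed one exactly.
    """
    ga, gp, _ = _ensemble_counts(net, scheme, master_seed)
    return _counts_to_dict(ga.mean(axis=0)), _counts_to_dict(gp.mean(axis=0))


def select_exemplar(ensemble, G_A: dict, G_P: dict) -> BipartiteNetwork:
    """The ensemble member with minimal L1 degree-distribution distance.

    Networks containing zero-degree species are excluded; ties break by
    generation index.
    """
    best, best_d = None, np.inf
    for member in ensemble:
        B = member.binary_pattern()
        if np.any(B.sum(axis=1) == 0) or np.any(B.sum(axis=0) == 0):
            continue
        gA = _counts_to_dict(np.bincount(B.sum(axis=1)))
        gP = _counts_to_dict(np.bincount(B.sum(axis=0)))
        d = degree_distance(gA, gP, G_A, G_P)
        if d < best_d:
            best, best_d = member, d
    if best is None:
        raise ValueError("no exemplar candidate: every draw has a zero-degree species")
    return best


def build_exemplar(
    net: BipartiteNetwork, scheme: RandomizationScheme, master_seed
) -> tuple[BipartiteNetwork, dict]:
    """Full pipeline: ensemble -> (G_A, G_P) -> closest eligible exemplar.

    Returns the exemplar (validated, no zero-degree species) and a report
    with the distance, the winning draw index and the G distributions.
    Only degree counts are kept per draw; the winner is regenerated from its
    per-draw seed.
    """
    ga, gp, children = _ensemble_counts(net, scheme, master_seed)
    G_A = _counts_to_dict(ga.mean(axis=0))
    G_P = _counts_to_dict(gp.mean(axis=0))
    eligible = (ga[:, 0] == 0) & (gp[:, 0] == 0)  # no zero-degree species
    if not eligible.any():
        raise ValueError("no exemplar candidate: every draw has a zero-degree species")
    distances = np.full(scheme.ensemble_size, np.inf)
    for i in np.flatnonzero(eligible):
        distances[i] = degree_distance(
            _counts_to_dict(ga[i]), _counts_to_dict(gp[i]), G_A, G_P
        )
    winner = int(np.argmin(distances))  # argmin takes the first, ties by index
    exemplar = _draw(net, scheme.mode, np.random.default_rng(children[winner]))
    exemplar = BipartiteNetwork(  # re-validate with zero-degree checks on
        exemplar.animal_labels, exemplar.plant_labels, exemplar.M, weighted=False
    )
    report = {
        "mode": scheme.mode,
        "ensemble_size": scheme.ensemble_size,
        "winner_index": winner,
        "distance": float(distances[winner]),
        "G_A": G_A,
        "G_P": G_P,
    }
    return exemplar, report
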