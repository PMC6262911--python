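"""Structural descriptors of bipartite networks.

Connectance, guild degree distributions, NODF nestedness, the largest plant
degree, and degree-distribution skewness. Degrees are always computed on the
binary zero pattern, even for weighted networks: "degree" counts interaction
partners, not visits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network_io import BipartiteNetwork

__all__ = [
    "DegreeDistribution",
    "ZeroVarianceError",
    "connectance",
    "degrees",
    "degree_distribution",
    "nodf",
    "largest_plant_degree",
    "degree_skewness",
    "summary",
]

PLANTS = "plants"
ANIMALS = "animals"


class ZeroVarianceError(ValueError):
    """A statistic is undefined because its input has no variance."""


@dataclass(frozen=True)
class DegreeDistribution:
    """Counts of species per degree k for one guild."""

    guild: str
    counts: dict  # k -> number of species with that degree

    def degree_list(self) -> np.ndarray:
        """Per-species degree values, expanded from the counts."""
        out = []
        for k in sorted(self.counts):
            out.extend([k] * self.counts[k])
        return np.array(out, dtype=float)

    @property
    def n_species(self) -> int:
        return sum(self.counts.values())

    @property
    def n_edges(self) -> int:
        return sum(k * c for k, c in self.counts.items())


def connectance(net: BipartiteNetwork) -> float:
    """Proportion of realized interactions, E / (A * P)."""
    return net.n_edges / (net.n_animals * net.n_plants)


def degrees(net: BipartiteNetwork, guild: str) -> np.ndarray:
    """Per-species binary degrees for one guild."""
    B = net.binary_pattern()
    if guild == PLANTS:
        return B.sum(axis=0)
    if guild == ANIMALS:
        return B.sum(axis=1)
    raise ValueError(f"guild must be {PLANTS!r} or {ANIMALS!r}, got {guild!r}")


def degree_distribution(net: BipartiteNetwork, guild: str) -> DegreeDistribution:
    ks = degrees(net, guild)
    uniq, cnt = np.unique(ks, return_counts=True)
    return DegreeDistribution(guild, {int(k): int(c) for k, c in zip(uniq, cnt)})


def _pair_overlap_sum(rows: np.ndarray) -> float:
    """Sum of NODF paired-overlap percentages over ordered row pairs.

    A pair (i, j) with fill(i) > fill(j) > 0 contributes
    100 * |ones(i) & ones(j)| / fill(j); pairs with equal (or increasing)
    marginal totals contribute 0 (strict decreasing-fill condition).
    """
    fills = rows.sum(axis=1)
    overlap = rows @ rows.T  # pairwise shared ones
    total = 0.0
    n = rows.shape[0]
    for i in range(n):
        for j in range(n):
            if i != j and fills[i] > fills[j] > 0:
                total += 100.0 * overlap[i, j] / fills[j]
    return total


def nodf(net: BipartiteNetwork) -> float:
    """NODF nestedness of the binary pattern, on the 0-100 scale."""
    B = net.binary_pattern()
    A, P = B.shape
    npairs = A * (A - 1) / 2 + P * (P - 1) / 2
    if npairs == 0:
        return 0.0
    return (_pair_overlap_sum(B) + _pair_overlap_sum(B.T)) / npairs


def largest_plant_degree(net: BipartiteNetwork) -> int:
    return int(degrees(net, PLANTS).max())


def degree_skewness(dist: DegreeDistribution, bias_corrected: bool = False) -> float:
    """Skewness (third standardized moment) of the per-species degree list.

    Uses the uncorrected sample moment by default; ``bias_corrected`` applies
    the usual adjusted (Fisher-Pearson) factor.
    """
    x = dist.degree_list()
    n = x.size
    m2 = float(np.mean((x - x.mean()) ** 2))
    if m2 == 0.0:
        raise ZeroVarianceError("skewness undefined: all degrees equal")
    m3 = float(np.mean((x - x.mean()) ** 3))
    g1 = m3 / m2 ** 1.5
    if bias_corrected:
        if n < 3:
            raise ZeroVarianceError("bias-corrected skewness needs n >= 3")
        g1 *= np.sqrt(n * (n - 1)) / (n - 2)
    return g1


def summary(net: BipartiteNetwork) -> dict:
    """One-line structural summary (P, A, E, c, NODF, largest plant degree)."""
    return {
        "P": net.n_plants,
        "A": net.n_animals,
        "E": net.n_edges,
        "connectance": connectance(net),
        "nodf": nodf(net),
        "largest_plant_degree": largest_plant_degree(net),
    }
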