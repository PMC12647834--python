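"""Simpson (turnover-only) taxonomic and phylogenetic dissimilarity.

The Simpson dissimilarity beta_sim = min(b, c) / (a + min(b, c)) captures pure
species (or branch-length) turnover and is insensitive to richness differences:
a flora nested inside another has dissimilarity 0. The phylogenetic flavour
replaces shared/unique species counts with shared/unique branch lengths of the
two communities' root-spanning subtrees.
"""

from __future__ import annotations

from dataclasses import dataclass

from .phylo import TreeIndex, shared_branch_lengths as _partition

__all__ = ["BranchPartition", "simpson_taxonomic", "simpson_phylogenetic", "PairwiseDissimilarityCache"]


@dataclass(frozen=True)
class BranchPartition:
    """Shared (A) and exclusive (B to x, C to y) branch lengths of two communities."""

    shared: float
    unique_x: float
    unique_y: float


def _simpson(a: float, b: float, c: float) -> float:
    m = min(b, c)
    denom = a + m
    if denom == 0.0:  # two empty overlaps cannot occur (communities non-empty) except degenerate trees
        return 0.0
    return m / denom


def simpson_taxonomic(set_x, set_y) -> float:
    """Simpson taxonomic dissimilarity between two species sets.

    ``min(b, c) / (a + min(b, c))`` with a = shared, b/c = exclusive counts;
    0 when one flora is nested in the other, 1 for disjoint floras.
    """
    x, y = set(set_x), set(set_y)
    if not x or not y:
        raise ValueError("communities must be non-empty")
    a = len(x & y)
    b = len(x - y)
    c = len(y - x)
    return _simpson(float(a), float(b), float(c))


def simpson_phylogenetic(index: TreeIndex, set_x, set_y) -> float:
    """Simpson phylogenetic dissimilarity: branch-length analogue of beta_sim."""
    a, b, c = _partition(index, set_x, set_y)
    return _simpson(a, b, c)


class PairwiseDissimilarityCache:
    """Lazy, symmetric cache of pairwise region dissimilarities.

    The distance engine revisits the same region pair for many species; values
    are computed once per unordered pair. Semantically invisible: results are
    identical to direct calls.
    """

    def __init__(self, index: TreeIndex, region_masks: dict, flavor: str = "phylogenetic") -> None:
        if flavor not in ("phylogenetic", "taxonomic"):
            raise ValueError(f"unknown dissimilarity flavor {flavor!r}")
        self._index = index
        self._masks = region_masks  # region_id -> boolean tip mask (or species set for taxonomic)
        self._flavor = flavor
        self._cache: dict = {}

    def __call__(self, region_a, region_b) -> float:
        key = (region_a, region_b) if region_a <= region_b else (region_b, region_a)
        val = self._cache.get(key)
        if val is None:
            if self._flavor == "phylogenetic":
                val = simpson_phylogenetic(self._index, self._masks[region_a], self._masks[region_b])
            else:
                val = simpson_taxonomic(self._masks[region_a], self._masks[region_b])
            self._cache[key] = val
        return val
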