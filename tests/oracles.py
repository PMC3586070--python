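"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_complete_linkage(distances: np.ndarray, cutoff: float) -> set[frozenset[int]]:
    """Naive agglomerative complete linkage, recomputed from scratch.

    Pure-python clusters-as-sets; at every step the complete-linkage distance
    of every cluster pair is recomputed directly from the input matrix (no
    incremental update), the closest pair at <= cutoff is merged, ties broken
    by (larger merged size, smallest member index).  Returns the partition as
    a set of frozensets of row indices.
    """
    clusters: list[set[int]] = [{i} for i in range(len(distances))]
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = max(distances[i, j] for i in clusters[a] for j in clusters[b])
            size = len(clusters[a]) + len(clusters[b])
            anchor = min(clusters[a] | clusters[b])
            key = (d, -size, anchor)
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _, _), a, b = best
        if d > cutoff:
            break
        clusters[a] |= clusters[b]
        del clusters[b]
    return {frozenset(c) for c in clusters}


def monte_carlo_rarefaction(
    abundances: list[int], depth: int, replicates: int, seed: int
) -> float:
    """Mean observed OTU count over uniform subsamples without replacement."""
    rng = np.random.default_rng(seed)
    counts = np.asarray(abundances, dtype=np.int64)
    draws = rng.multivariate_hypergeometric(counts, depth, size=replicates)
    return float((draws > 0).sum(axis=1).mean())


def enumerate_words(sequence: str, k: int) -> set[str]:
    """All distinct k-mers of a sequence containing only ACGT."""
    return {
        sequence[i : i + k]
        for i in range(len(sequence) - k + 1)
        if set(sequence[i : i + k]) <= set("ACGT")
    }
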