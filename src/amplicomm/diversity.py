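"""OTU clustering and alpha-diversity statistics.

Implements the cluster-based workflow used with pyrosequencing amplicon
surveys: depth normalization by subsampling without replacement, pairwise
distances from end-gap-free global alignment, agglomerative complete-linkage
clustering at fixed distance cutoffs (3% / 6%), analytic rarefaction with
Monte-Carlo confidence bands, and the Chao1, Shannon and Good's coverage
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from Bio import Align


@dataclass
class OTUPartition:
    """A partition of reads into OTUs at one distance cutoff."""

    cutoff: float
    otus: dict[str, list[str]]  # otu_id -> member ids

    @property
    def abundances(self) -> np.ndarray:
        """OTU sizes sorted descending."""
        return np.array(sorted((len(m) for m in self.otus.values()), reverse=True), dtype=np.int64)

    @property
    def n_otus(self) -> int:
        return len(self.otus)


@dataclass
class AlphaStats:
    """Alpha-diversity summary for one sample at one cutoff."""

    n: int
    otus: int
    chao1: float
    shannon: float
    goods_coverage: float

    def __post_init__(self) -> None:
        if self.chao1 < self.otus - 1e-9:
            raise ValueError("Chao1 cannot fall below the observed OTU count")
        if not 0.0 <= self.goods_coverage <= 100.0:
            raise ValueError("Good's coverage is a percentage in [0, 100]")


def subsample(items: Sequence, depth: int, rng: np.random.Generator | int | None = None) -> list:
    """Uniform sample of exactly ``depth`` items without replacement."""
    if depth > len(items):
        raise ValueError(f"subsample depth {depth} exceeds available {len(items)} items")
    rng = np.random.default_rng(rng)
    idx = rng.choice(len(items), size=depth, replace=False)
    return [items[i] for i in sorted(idx)]


_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-2,
)


def pairwise_distance(a: str, b: str) -> float:
    """Alignment distance between two sequences in [0, 1].

    Global alignment (match 1, mismatch -1, gap -2); distance =
    (mismatched columns + internal gap columns) / aligned columns, where
    terminal-overhang columns are excluded from both numerator and
    denominator, so length differences at the ends are free.  End gaps are
    penalised *during* alignment — otherwise two unrelated sequences could
    slide into a tiny perfect overlap and come out spuriously close.  The
    argument pair is ordered canonically before aligning so co-optimal
    alignments cannot break symmetry.
    """
    if not a or not b:
        raise ValueError("cannot compute a distance for an empty sequence")
    a, b = a.upper(), b.upper()
    if a == b:
        return 0.0
    if b < a:
        a, b = b, a
    aln = _aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    # interior = columns between the first and last position where both rows
    # have a residue; outside lies only end-gap overhang
    both = [i for i in range(len(sa)) if sa[i] != "-" and sb[i] != "-"]
    if not both:
        return 1.0
    start, stop = both[0], both[-1] + 1
    diffs = sum(1 for i in range(start, stop) if sa[i] != sb[i])
    return diffs / (stop - start)


def distance_matrix(sequences: Sequence[str], method: str = "auto") -> np.ndarray:
    """Symmetric pairwise distance matrix for a set of sequences.

    ``method`` is "align" (the :func:`pairwise_distance` definition),
    "hamming" (positional differences / length; requires equal lengths), or
    "auto" which picks hamming when all sequences share one length — for
    same-region amplicons the two coincide at the small distances that matter
    for OTU cutoffs, and the hamming path is vectorised.
    """
    n = len(sequences)
    lengths = {len(s) for s in sequences}
    if method == "auto":
        method = "hamming" if len(lengths) == 1 else "align"
    if method == "hamming":
        if len(lengths) != 1:
            raise ValueError("hamming distances require equal-length sequences")
        L = lengths.pop()
        arr = np.frombuffer("".join(s.upper() for s in sequences).encode(), dtype=np.uint8)
        arr = arr.reshape(n, L)
        dm = np.zeros((n, n), dtype=np.float64)
        for i in range(n):
            dm[i, i + 1:] = (arr[i + 1:] != arr[i]).mean(axis=1)
        return dm + dm.T
    if method != "align":
        raise ValueError(f"unknown method {method!r}")
    dm = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = pairwise_distance(sequences[i], sequences[j])
    return dm


def cluster_otus(
    distances: np.ndarray,
    cutoff: float,
    ids: Sequence[str] | None = None,
    weights: Sequence[int] | None = None,
) -> OTUPartition:
    """Agglomerative complete-linkage clustering stopped at ``cutoff``.

    Repeatedly merges the pair of clusters with the smallest complete-linkage
    (maximum) distance while that distance is <= ``cutoff``.  Ties are broken
    deterministically: prefer the merge producing the larger cluster, then
    the one containing the smallest member index.  ``weights`` expands row i
    into that many members (ids ``<id>/k``) so dereplicated sequences can be
    clustered without materialising every read.
    """
    distances = np.asarray(distances, dtype=np.float64)
    if distances.ndim != 2 or distances.shape[0] != distances.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(distances, distances.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(distances) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    n = distances.shape[0]
    if ids is None:
        ids = [str(i) for i in range(n)]
    if len(ids) != n:
        raise ValueError("ids length must match the matrix")

    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    dm = distances.copy()
    np.fill_diagonal(dm, np.inf)
    sizes = np.ones(n) if weights is None else np.asarray(weights, dtype=np.float64)
    active = np.ones(n, dtype=bool)

    while active.sum() > 1:
        d = dm.min()
        if d > cutoff:
            break
        # candidate merges at the minimum distance; deterministic tie-break
        best = None
        for i, j in np.argwhere(dm == d):
            i, j = int(i), int(j)
            if i >= j:
                continue
            key = (-(sizes[i] + sizes[j]), min(members[i][0], members[j][0]), i, j)
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        # complete linkage: new distance = max of the two
        merged_row = np.maximum(dm[i], dm[j])
        dm[i], dm[:, i] = merged_row, merged_row
        dm[i, i] = np.inf
        active[j] = False
        dm[j], dm[:, j] = np.inf, np.inf
        members[i].extend(members.pop(j))
        sizes[i] += sizes[j]

    otus: dict[str, list[str]] = {}
    clusters = sorted(members.values(), key=lambda m: (-len(m), min(m)))
    for k, member_idx in enumerate(clusters):
        out: list[str] = []
        for mi in sorted(member_idx):
            if weights is None:
                out.append(ids[mi])
            else:
                w = int(weights[mi])
                out.extend([ids[mi]] if w == 1 else [f"{ids[mi]}/{r}" for r in range(w)])
        otus[f"OTU_{k + 1}"] = out
    return OTUPartition(cutoff=cutoff, otus=otus)


def _log_choose(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefy(
    abundances: Sequence[int],
    depths: Sequence[int],
    n_replicates: int = 100,
    rng: np.random.Generator | int | None = None,
    band: float = 95.0,
) -> pd.DataFrame:
    """Analytic rarefaction curve with Monte-Carlo confidence bands.

    The expected number of OTUs in a uniform subsample of n reads is

        E[S(n)] = sum_i (1 - C(N - N_i, n) / C(N, n))

    evaluated in log space.  The ``band``% interval comes from
    ``n_replicates`` seeded multivariate-hypergeometric subsamples.
    Returns a DataFrame with columns depth, expected, lo, hi.
    """
    counts = np.asarray(abundances, dtype=np.int64)
    if counts.size == 0 or np.any(counts <= 0):
        raise ValueError("abundances must be positive")
    N = int(counts.sum())
    rng = np.random.default_rng(rng)
    rows = []
    for depth in depths:
        if depth > N:
            raise ValueError(f"rarefaction depth {depth} exceeds total reads {N}")
        log_denom = _log_choose(np.float64(N), depth)
        absent = np.zeros(counts.size)
        feasible = (N - counts) >= depth
        absent[feasible] = np.exp(_log_choose((N - counts[feasible]).astype(np.float64), depth) - log_denom)
        expected = float(np.sum(1.0 - absent))
        reps = rng.multivariate_hypergeometric(counts, depth, size=n_replicates)
        observed = (reps > 0).sum(axis=1)
        lo, hi = np.percentile(observed, [(100 - band) / 2, 100 - (100 - band) / 2])
        rows.append((depth, expected, float(lo), float(hi)))
    return pd.DataFrame(rows, columns=["depth", "expected", "lo", "hi"])


def chao1(abundances: Sequence[int], bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton/doubleton counts.

    The bias-corrected form S_obs + F1(F1-1)/(2(F2+1)) is the default; the
    classic form S_obs + F1^2/(2 F2) is available (undefined when F2 = 0).
    """
    counts = np.asarray([a for a in abundances if a > 0], dtype=np.int64)
    if counts.size == 0:
        raise ValueError("chao1 of an empty community")
    s_obs = counts.size
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        raise ZeroDivisionError("classic Chao1 is undefined without doubletons")
    return s_obs + f1 * f1 / (2.0 * f2)


def shannon(abundances: Sequence[int]) -> float:
    """Shannon diversity H = -sum p_i ln p_i (natural log)."""
    counts = np.asarray([a for a in abundances if a > 0], dtype=np.float64)
    if counts.size == 0:
        raise ValueError("shannon of an empty community")
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def goods_coverage(abundances: Sequence[int]) -> float:
    """Good's coverage (1 - F1/N) as a percentage."""
    counts = np.asarray([a for a in abundances if a > 0], dtype=np.int64)
    if counts.size == 0:
        raise ValueError("coverage of an empty community")
    f1 = int((counts == 1).sum())
    return (1.0 - f1 / counts.sum()) * 100.0


def alpha_stats(partition: OTUPartition) -> AlphaStats:
    """Table-style alpha-diversity summary of one OTU partition."""
    ab = partition.abundances
    return AlphaStats(
        n=int(ab.sum()),
        otus=int(ab.size),
        chao1=chao1(ab),
        shannon=shannon(ab),
        goods_coverage=goods_coverage(ab),
    )
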