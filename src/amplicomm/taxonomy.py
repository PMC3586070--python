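"""Taxonomy containers and the two assignment engines.

Two independent engines are provided:

* :class:`NaiveBayesClassifier` — a word-based (k-mer) naive-Bayes classifier
  with bootstrap confidence estimation, in the style of the RDP classifier
  (Wang et al. 2007).  Used for rescuing flagged chimeras and for removing
  archaeal contaminants.
* :func:`lca_assign` — lowest-common-ancestor assignment over a tabular
  alignment hit list with a bitscore cutoff and a top-percent window, in the
  style of MEGAN.  Used to build community profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

RANKS: tuple[str, ...] = ("domain", "phylum", "class", "order", "family", "genus")

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


class TaxonomyError(ValueError):
    """Raised for malformed trees, unknown taxa or untrained classifiers."""


@dataclass(frozen=True)
class TaxNode:
    taxon_id: str
    name: str
    rank: str | None  # None for the root
    parent: str | None


class TaxonomyTree:
    """Rooted, rank-labelled taxonomy (domain -> genus).

    Node ids are ``"rank:name"`` strings so that the same name may appear at
    different ranks without collision.  Built most conveniently from full
    six-rank lineages via :meth:`from_lineages`.
    """

    ROOT_ID = "root"

    def __init__(self) -> None:
        self.nodes: dict[str, TaxNode] = {
            self.ROOT_ID: TaxNode(self.ROOT_ID, "root", None, None)
        }

    @staticmethod
    def node_id(rank: str, name: str) -> str:
        return f"{rank}:{name}"

    @classmethod
    def from_lineages(cls, lineages: Iterable[Sequence[str]]) -> "TaxonomyTree":
        """Build a tree from full domain→genus lineages (6 names each)."""
        tree = cls()
        for lineage in lineages:
            tree.add_lineage(lineage)
        return tree

    def add_lineage(self, lineage: Sequence[str]) -> str:
        if len(lineage) != len(RANKS):
            raise TaxonomyError(
                f"lineage must have {len(RANKS)} ranks (domain..genus), got {len(lineage)}"
            )
        parent = self.ROOT_ID
        for rank, name in zip(RANKS, lineage):
            nid = self.node_id(rank, name)
            existing = self.nodes.get(nid)
            if existing is None:
                self.nodes[nid] = TaxNode(nid, name, rank, parent)
            elif existing.parent != parent:
                raise TaxonomyError(f"taxon {name!r} at rank {rank!r} has conflicting parents")
            parent = nid
        return parent

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.nodes

    def path(self, taxon_id: str) -> list[str]:
        """Node ids from the root down to ``taxon_id`` inclusive."""
        if taxon_id not in self.nodes:
            raise TaxonomyError(f"unknown taxon {taxon_id!r}")
        out = []
        cur: str | None = taxon_id
        while cur is not None:
            out.append(cur)
            cur = self.nodes[cur].parent
        return out[::-1]

    def ancestor_at(self, taxon_id: str, rank: str) -> str | None:
        """Ancestor-or-self of ``taxon_id`` at ``rank``, or None if above it."""
        for nid in self.path(taxon_id):
            if self.nodes[nid].rank == rank:
                return nid
        return None

    def lca(self, taxon_ids: Sequence[str]) -> str:
        """Lowest common ancestor of a non-empty set of node ids."""
        if not taxon_ids:
            raise TaxonomyError("lca of an empty taxon set")
        paths = [self.path(t) for t in taxon_ids]
        lca = self.ROOT_ID
        for level in zip(*paths):
            if len(set(level)) == 1:
                lca = level[0]
            else:
                break
        return lca

    def rank_of(self, taxon_id: str) -> str | None:
        return self.nodes[taxon_id].rank

    def name_of(self, taxon_id: str) -> str:
        return self.nodes[taxon_id].name


@dataclass
class Assignment:
    """Result of assigning one read to a taxonomy node.

    ``taxon_id`` is a node id of the tree (any rank) or ``None`` when the
    read could not be assigned.  ``confidences`` maps rank -> bootstrap
    confidence for the classifier engine and is ``None`` for the LCA engine.
    """

    read_id: str
    taxon_id: str | None
    engine: str  # "nb" or "lca"
    confidences: dict[str, float] | None = None
    reason: str | None = None


@dataclass(frozen=True)
class HitRecord:
    """One row of a 12-column tabular alignment hit file."""

    read_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    bitscore: float
    subject_taxon: str  # genus name

    def __post_init__(self) -> None:
        if self.bitscore < 0:
            raise ValueError(f"negative bitscore for {self.read_id}->{self.subject_id}")


def kmer_indices(sequence: str, word_size: int) -> np.ndarray:
    """Indices (base-4 codes) of all valid overlapping words of a sequence.

    Words containing non-ACGT characters are dropped.  Returns an int array of
    length <= len(sequence) - word_size + 1.
    """
    codes = _BASE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if codes.size < word_size:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, word_size)
    valid = (windows >= 0).all(axis=1)
    powers = 4 ** np.arange(word_size - 1, -1, -1, dtype=np.int64)
    return (windows[valid] * powers).sum(axis=1)


class NaiveBayesClassifier:
    """Word-matching naive-Bayes taxonomic classifier with bootstrap support.

    Training estimates, for every genus G and every possible word w of size
    ``word_size``, the probability that a sequence of G contains w:

        P(w | G) = (m(w) + P(w)) / (M + 1)

    where m(w) counts training sequences of G containing w, M is the number
    of training sequences of G, and P(w) = (n(w) + 0.5) / (N + 1) is the
    corpus-wide prior with add-half smoothing (n(w) sequences containing w
    out of N total).  A query is assigned to the genus maximising the joint
    log-likelihood over all its words; confidence is the fraction of
    bootstrap replicates (each resampling floor(W/8) of the query's W words
    with replacement) won by a genus under the same higher-rank taxon.
    """

    def __init__(self, word_size: int = 8) -> None:
        if not 1 <= word_size <= 12:
            raise ValueError("word_size must be in [1, 12]")
        self.word_size = word_size
        self.genera: list[str] = []
        self.tree: TaxonomyTree | None = None
        self._log_prob: np.ndarray | None = None  # (G, 4**word_size)
        self._rank_codes: np.ndarray | None = None  # (G, len(RANKS)) int codes
        self._lineages: dict[str, tuple[str, ...]] = {}

    @property
    def is_trained(self) -> bool:
        return self._log_prob is not None

    def train(self, references: Sequence[tuple[str, Sequence[str]]]) -> "NaiveBayesClassifier":
        """Fit the model from ``(sequence, lineage)`` pairs.

        Every lineage must be a full six-rank path (domain..genus).  Genera
        whose references contain no valid word are dropped with a warning in
        the returned model's ``skipped`` attribute.
        """
        by_genus: dict[str, list[np.ndarray]] = {}
        lineages: dict[str, tuple[str, ...]] = {}
        for seq, lineage in references:
            lineage = tuple(lineage)
            if len(lineage) != len(RANKS):
                raise TaxonomyError("every reference needs a full domain..genus lineage")
            genus = lineage[-1]
            prev = lineages.setdefault(genus, lineage)
            if prev != lineage:
                raise TaxonomyError(f"conflicting lineages for genus {genus!r}")
            words = np.unique(kmer_indices(seq, self.word_size))
            by_genus.setdefault(genus, []).append(words)

        self.skipped: list[str] = [g for g, ws in by_genus.items() if all(w.size == 0 for w in ws)]
        genera = sorted(g for g in by_genus if g not in self.skipped)
        if not genera:
            raise TaxonomyError("no trainable genera in the reference set")

        n_words = 4 ** self.word_size
        n_total = sum(len(by_genus[g]) for g in genera)
        corpus = np.zeros(n_words, dtype=np.float64)
        for g in genera:
            for words in by_genus[g]:
                corpus[words] += 1.0
        prior = (corpus + 0.5) / (n_total + 1.0)

        log_prob = np.empty((len(genera), n_words), dtype=np.float32)
        for gi, g in enumerate(genera):
            m = np.zeros(n_words, dtype=np.float64)
            for words in by_genus[g]:
                m[words] += 1.0
            log_prob[gi] = np.log((m + prior) / (len(by_genus[g]) + 1.0))

        # integer codes per rank for fast bootstrap-agreement counting
        rank_codes = np.empty((len(genera), len(RANKS)), dtype=np.int64)
        for ri in range(len(RANKS)):
            names = {}
            for gi, g in enumerate(genera):
                rank_codes[gi, ri] = names.setdefault(lineages[g][ri], len(names))

        self.genera = genera
        self._log_prob = log_prob
        self._rank_codes = rank_codes
        self._lineages = {g: lineages[g] for g in genera}
        self.tree = TaxonomyTree.from_lineages(self._lineages[g] for g in genera)
        return self

    def lineage_of(self, genus: str) -> tuple[str, ...]:
        return self._lineages[genus]

    def classify(
        self,
        sequence: str,
        read_id: str = "",
        n_bootstrap: int = 100,
        rng: np.random.Generator | int | None = None,
    ) -> Assignment:
        """Assign a read to a genus with per-rank bootstrap confidences.

        Reads shorter than the word size (or containing no valid word) come
        back unassigned with a reason.  Deterministic for a fixed rng state.
        """
        if not self.is_trained:
            raise TaxonomyError("classifier is not trained")
        rng = np.random.default_rng(rng)
        words = kmer_indices(sequence, self.word_size)
        if words.size == 0:
            return Assignment(read_id, None, "nb", None, reason="too_short")

        scores = self._log_prob[:, words]  # (G, W)
        joint = scores.sum(axis=1, dtype=np.float64)
        winner = int(np.argmax(joint))  # ties -> lowest index = lexicographic genus

        w = words.size
        n_draw = max(1, w // 8)
        idx = rng.integers(0, w, size=(n_bootstrap, n_draw))
        boot = scores[:, idx].sum(axis=2, dtype=np.float64)  # (G, B)
        boot_winners = np.argmax(boot, axis=0)
        # exact ties within a replicate are broken uniformly at random (the
        # final assignment below stays lexicographic); otherwise equally
        # supported genera would never share bootstrap confidence
        tied = (boot == boot.max(axis=0)).sum(axis=0) > 1
        for col in np.where(tied)[0]:
            choices = np.where(boot[:, col] == boot[:, col].max())[0]
            boot_winners[col] = choices[rng.integers(choices.size)]

        confidences: dict[str, float] = {}
        for ri, rank in enumerate(RANKS):
            agree = self._rank_codes[boot_winners, ri] == self._rank_codes[winner, ri]
            confidences[rank] = float(np.mean(agree))
        genus = self.genera[winner]
        return Assignment(
            read_id,
            TaxonomyTree.node_id("genus", genus),
            "nb",
            confidences,
        )


def filter_domain(
    reads: Sequence,
    classifier: NaiveBayesClassifier,
    domain_to_remove: str = "Archaea",
    n_bootstrap: int = 100,
    rng: np.random.Generator | int | None = None,
) -> tuple[list, int]:
    """Remove reads whose winning domain is ``domain_to_remove``.

    The plain maximum-likelihood winner decides the domain (no confidence
    threshold).  Reads the classifier cannot place (too short) are kept.
    Returns ``(kept_reads, removed_count)``.
    """
    if not classifier.is_trained:
        raise TaxonomyError("classifier is not trained")
    rng = np.random.default_rng(rng)
    if not any(lin[0] == domain_to_remove for lin in classifier._lineages.values()):
        return list(reads), 0
    kept = []
    removed = 0
    for read in reads:
        asg = classifier.classify(read.sequence, read.read_id, n_bootstrap=1, rng=rng)
        if asg.taxon_id is not None:
            genus = classifier.tree.name_of(asg.taxon_id)
            if classifier.lineage_of(genus)[0] == domain_to_remove:
                removed += 1
                continue
        kept.append(read)
    return kept, removed


def lca_assign(
    hits: Sequence[HitRecord],
    tree: TaxonomyTree,
    min_bitscore: float = 86.0,
    top_percent: float = 0.1,
    read_id: str | None = None,
) -> Assignment:
    """Lowest-common-ancestor assignment for one read's hit list.

    Hits below ``min_bitscore`` are discarded; of the survivors only those
    within ``top_percent`` of the best bitscore are kept; the read is
    assigned to the LCA of the kept hits' genera.  No surviving hits means
    unassigned.
    """
    if read_id is None:
        read_id = hits[0].read_id if hits else ""
    survivors = [h for h in hits if h.bitscore >= min_bitscore]
    if not survivors:
        return Assignment(read_id, None, "lca", None, reason="no_hits_above_cutoff")
    best = max(h.bitscore for h in survivors)
    kept = [h for h in survivors if h.bitscore >= (1.0 - top_percent) * best]
    taxa = []
    for h in kept:
        nid = TaxonomyTree.node_id("genus", h.subject_taxon)
        if nid not in tree:
            raise TaxonomyError(f"hit subject taxon {h.subject_taxon!r} not in taxonomy tree")
        taxa.append(nid)
    return Assignment(read_id, tree.lca(taxa), "lca", None)


@dataclass
class CommunityProfile:
    """Per-taxon relative abundances at one rank for one sample.

    ``scope`` distinguishes 16S gene-copy fractions ("gene") from corrected
    cell fractions ("cell").  ``fractions`` are computed over all input
    reads, so named taxa plus ``unassigned`` sum to 1.
    """

    scope: str  # "gene" or "cell"
    rank: str
    fractions: dict[str, float]
    unassigned: float
    total_assigned: int
    n_reads: int

    def __post_init__(self) -> None:
        total = sum(self.fractions.values()) + self.unassigned
        if self.n_reads > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError(f"profile fractions sum to {total}, expected 1")


def build_profile(
    assignments: Sequence[Assignment],
    tree: TaxonomyTree,
    rank: str,
    min_support: int = 30,
    scope: str = "gene",
) -> CommunityProfile:
    """Aggregate per-read assignments into a relative-abundance profile.

    Each read is projected to its ancestor-or-self at ``rank``; reads
    assigned above that rank (or unassigned) contribute to the explicit
    ``unassigned`` mass.  Taxa supported by more than ``min_support`` reads
    are reported; reads of suppressed taxa are re-attributed to their nearest
    reported ancestor, which at a single rank means they join the
    ``unassigned`` mass rather than being dropped (read mass is conserved).
    """
    if rank not in RANKS:
        raise TaxonomyError(f"unknown rank {rank!r}")
    counts: dict[str, int] = {}
    above = 0
    for asg in assignments:
        if asg.taxon_id is None:
            above += 1
            continue
        node = tree.ancestor_at(asg.taxon_id, rank)
        if node is None:
            above += 1
        else:
            counts[node] = counts.get(node, 0) + 1

    n = len(assignments)
    fractions: dict[str, float] = {}
    assigned = 0
    for node, c in sorted(counts.items()):
        if c > min_support:
            fractions[tree.name_of(node)] = c / n if n else 0.0
            assigned += c
        else:
            above += c
    return CommunityProfile(
        scope=scope,
        rank=rank,
        fractions=fractions,
        unassigned=(above / n) if n else 0.0,
        total_assigned=assigned,
        n_reads=n,
    )
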