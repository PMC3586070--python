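"""Abundance-based denoising and de-novo bimera handling.

``precluster`` absorbs rare sequencing-noise variants into more abundant
neighbours within a small mismatch budget (the pre-clustering heuristic used
to denoise pyrosequencing reads).  ``flag_bimeras`` searches for two-parent
chimeras de novo: a query is flagged when some single-breakpoint combination
of two sufficiently more abundant sequences explains it markedly better than
any single candidate parent.  ``rescue`` then applies the classifier-
confidence rule: flagged reads that can still be assigned to a known genus
at the confidence threshold rejoin the effective set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from amplicomm.read_qc import ConfigurationError, Read
from amplicomm.taxonomy import NaiveBayesClassifier

_BYTE = {b: i for i, b in enumerate("ACGTN")}


@dataclass
class UniqueSeq:
    """A dereplicated sequence with its abundance and member read ids."""

    sequence: str
    member_ids: list[str]

    @property
    def abundance(self) -> int:
        return len(self.member_ids)

    @property
    def uid(self) -> str:
        # first member id collected in deterministic order
        return self.member_ids[0]


@dataclass
class ChimeraVerdict:
    """Per-unique-sequence bimera verdict, later expanded to member reads."""

    uid: str
    flagged: bool
    parents: tuple[str, str] | None = None
    breakpoint: int | None = None
    score_gain: float = 0.0
    rescued: bool = False
    rescue_genus: str | None = None
    rescue_confidence: float | None = None

    def __post_init__(self) -> None:
        if self.rescued and not self.flagged:
            raise ValueError("only flagged sequences can be rescued")


def dereplicate(reads: Sequence[Read]) -> list[UniqueSeq]:
    """Collapse identical sequences, sorted by abundance desc then sequence.

    Member ids within a unique keep their input order, so the representative
    id is deterministic for a fixed input order.
    """
    groups: dict[str, list[str]] = {}
    for read in reads:
        groups.setdefault(read.sequence.upper(), []).append(read.read_id)
    uniques = [UniqueSeq(seq, ids) for seq, ids in groups.items()]
    uniques.sort(key=lambda u: (-u.abundance, u.sequence))
    return uniques


def _mismatches(a: str, b: str) -> int:
    """End-gap-free mismatch count: positional over the shared prefix."""
    n = min(len(a), len(b))
    aa = np.frombuffer(a[:n].encode(), dtype=np.uint8)
    bb = np.frombuffer(b[:n].encode(), dtype=np.uint8)
    return int((aa != bb).sum())


def precluster(uniques: Sequence[UniqueSeq], diffs: int = 2) -> list[UniqueSeq]:
    """Merge each unique into the first more-abundant unique within ``diffs``.

    Sequences are visited in (abundance desc, lexicographic) order; each is
    compared against already-accepted uniques in that same order and merged
    into the first one at <= ``diffs`` mismatches (abundances summed, member
    ids appended).  Output re-sorted by the same deterministic key.
    """
    if diffs < 0:
        raise ValueError("diffs must be >= 0")
    ordered = sorted(uniques, key=lambda u: (-u.abundance, u.sequence))
    accepted: list[UniqueSeq] = []
    for uniq in ordered:
        target = None
        for acc in accepted:
            if abs(len(acc.sequence) - len(uniq.sequence)) <= diffs and \
                    _mismatches(acc.sequence, uniq.sequence) <= diffs:
                target = acc
                break
        if target is None:
            accepted.append(UniqueSeq(uniq.sequence, list(uniq.member_ids)))
        else:
            target.member_ids.extend(uniq.member_ids)
    accepted.sort(key=lambda u: (-u.abundance, u.sequence))
    return accepted


def _match_profile(query: np.ndarray, parent: str) -> np.ndarray:
    """Boolean per-position match vector of a parent against the query.

    Positions beyond the shorter sequence count as mismatches so that a
    truncated parent cannot spuriously explain the query's tail.
    """
    out = np.zeros(query.size, dtype=bool)
    n = min(query.size, len(parent))
    pp = np.frombuffer(parent[:n].encode(), dtype=np.uint8)
    out[:n] = query[:n] == pp
    return out


def flag_bimeras(
    uniques: Sequence[UniqueSeq],
    min_parent_fold: float = 2.0,
    min_score_gain: float = 3.0,
    min_model_identity: float = 0.9,
) -> list[ChimeraVerdict]:
    """De-novo two-parent chimera search over preclustered uniques.

    For each query, candidate parents are uniques with abundance >=
    ``min_parent_fold`` times the query's.  The query is flagged iff the best
    left-parent/right-parent single-breakpoint model (left segment from A,
    right from B, A != B) matches at least ``min_score_gain`` more positions
    of the query than the best single parent does, and the model itself
    explains the query well (identity >= ``min_model_identity``).  The
    identity requirement keeps sequences that merely lack any similar parent
    — e.g. the sole representative of a divergent taxon — from being flagged
    on a chance improvement assembled from unrelated sequences.
    """
    verdicts: list[ChimeraVerdict] = []
    ordered = sorted(uniques, key=lambda u: (-u.abundance, u.sequence))
    for query in ordered:
        candidates = [
            p for p in ordered
            if p is not query and p.abundance >= min_parent_fold * query.abundance
        ]
        if len(candidates) < 2:
            verdicts.append(ChimeraVerdict(query.uid, False))
            continue

        q = np.frombuffer(query.sequence.encode(), dtype=np.uint8)
        L = q.size
        # prefix[i, b] = matches of candidate i over query[:b]
        profiles = np.stack([_match_profile(q, p.sequence) for p in candidates])
        prefix = np.zeros((len(candidates), L + 1), dtype=np.int64)
        np.cumsum(profiles, axis=1, out=prefix[:, 1:])
        totals = prefix[:, -1]
        suffix = totals[:, None] - prefix

        best_single = int(totals.max())
        left_best = prefix.max(axis=0)          # over parents, per breakpoint
        left_arg = prefix.argmax(axis=0)
        right_best = suffix.max(axis=0)
        right_arg = suffix.argmax(axis=0)
        chimera_scores = left_best + right_best
        b = int(chimera_scores.argmax())        # first/leftmost best breakpoint
        gain = float(chimera_scores[b] - best_single)

        a_idx, b_idx = int(left_arg[b]), int(right_arg[b])
        model_identity = float(chimera_scores[b]) / L if L else 0.0
        if gain >= min_score_gain and a_idx != b_idx and model_identity >= min_model_identity:
            verdicts.append(
                ChimeraVerdict(
                    query.uid,
                    True,
                    parents=(candidates[a_idx].uid, candidates[b_idx].uid),
                    breakpoint=b,
                    score_gain=gain,
                )
            )
        else:
            verdicts.append(ChimeraVerdict(query.uid, False))
    return verdicts


def rescue(
    verdicts: Sequence[ChimeraVerdict],
    uniques: Sequence[UniqueSeq],
    classifier: NaiveBayesClassifier,
    conf_threshold: float = 0.5,
    n_bootstrap: int = 100,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[str], list[str], list[ChimeraVerdict]]:
    """Classifier-confidence rescue of flagged sequences.

    Flagged uniques whose genus-level bootstrap confidence reaches
    ``conf_threshold`` are rescued; unflagged uniques pass through.  Returns
    ``(effective_read_ids, removed_read_ids, updated_verdicts)`` expanded to
    member reads; effective + removed partition the input exactly.
    """
    if not classifier.is_trained:
        raise ConfigurationError("rescue requires a trained classifier")
    rng = np.random.default_rng(rng)
    by_uid = {u.uid: u for u in uniques}
    if set(v.uid for v in verdicts) != set(by_uid):
        raise ValueError("verdicts and uniques do not describe the same sequences")

    effective: list[str] = []
    removed: list[str] = []
    updated: list[ChimeraVerdict] = []
    for verdict in verdicts:
        uniq = by_uid[verdict.uid]
        if not verdict.flagged:
            effective.extend(uniq.member_ids)
            updated.append(verdict)
            continue
        asg = classifier.classify(uniq.sequence, uniq.uid, n_bootstrap=n_bootstrap, rng=rng)
        conf = asg.confidences["genus"] if asg.confidences else 0.0
        genus = classifier.tree.name_of(asg.taxon_id) if asg.taxon_id else None
        if conf >= conf_threshold and genus is not None:
            effective.extend(uniq.member_ids)
            updated.append(
                ChimeraVerdict(
                    verdict.uid, True, verdict.parents, verdict.breakpoint,
                    verdict.score_gain, rescued=True, rescue_genus=genus,
                    rescue_confidence=conf,
                )
            )
        else:
            removed.extend(uniq.member_ids)
            updated.append(
                ChimeraVerdict(
                    verdict.uid, True, verdict.parents, verdict.breakpoint,
                    verdict.score_gain, rescued=False, rescue_genus=genus,
                    rescue_confidence=conf,
                )
            )
    return effective, removed, updated
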