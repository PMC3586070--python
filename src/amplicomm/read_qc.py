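"""Demultiplexing, quality trimming and per-sample accounting.

The trimming policy follows the three numbered rules of the pyrosequencing
quality-check workflow this package models:

1. remove reads with more than one ambiguous base ('N');
2. require the complete 5' adaptor followed by an exact barcode (demultiplex);
3. remove reads shorter than a minimum length after stripping.

Rule 2 is applied by :func:`demultiplex` before the others; within
:func:`quality_filter` each rejected read gets exactly one reason, assigned
in rule order (ambiguous -> no_primer -> short).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Data.IUPACData import ambiguous_dna_values


class ConfigurationError(ValueError):
    """Invalid run configuration (duplicate barcodes, bad IUPAC codes...)."""


class PipelineOrderError(ValueError):
    """Stage counts that cannot arise from the documented stage order."""


@dataclass
class Read:
    """A single sequencing read with optional sample provenance."""

    read_id: str
    sequence: str
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SampleAccounting:
    """Stage-by-stage read counts for one sample.

    Mirrors the columns of a per-sample trimming table: raw reads, reads
    passing QC ("effective"), chimera-flagged reads split into rescued
    (assigned to a genus at the confidence threshold) and removed, effective
    reads after chimera removal, archaeal reads, bacterial reads, and the
    common normalization depth.
    """

    sample_id: str
    raw_reads: int
    post_qc: int
    chimera_flagged_rescued: int
    chimera_flagged_removed: int
    post_chimera: int
    archaeal: int
    bacterial: int
    normalized: int | None = None

    def __post_init__(self) -> None:
        counts = [self.raw_reads, self.post_qc, self.chimera_flagged_rescued,
                  self.chimera_flagged_removed, self.post_chimera, self.archaeal,
                  self.bacterial]
        if any(c < 0 for c in counts):
            raise PipelineOrderError(f"negative count in accounting for {self.sample_id!r}")
        if self.post_chimera != self.post_qc - self.chimera_flagged_removed:
            raise PipelineOrderError(
                f"{self.sample_id!r}: post_chimera must equal post_qc - chimera_flagged_removed"
            )
        if self.bacterial != self.post_chimera - self.archaeal:
            raise PipelineOrderError(
                f"{self.sample_id!r}: bacterial must equal post_chimera - archaeal"
            )
        if not (self.raw_reads >= self.post_qc >= self.post_chimera >= self.bacterial):
            raise PipelineOrderError(f"{self.sample_id!r}: counts must not increase along the pipeline")
        if self.normalized is not None and self.normalized > self.bacterial:
            raise PipelineOrderError(f"{self.sample_id!r}: normalization depth exceeds bacterial count")


def tally(
    sample_id: str,
    raw_reads: int,
    post_qc: int,
    chimera_flagged_rescued: int,
    chimera_flagged_removed: int,
    archaeal: int,
    normalized: int | None = None,
) -> SampleAccounting:
    """Derive the dependent accounting columns from stage counts.

    ``post_chimera`` and ``bacterial`` are computed, never supplied, so the
    bookkeeping identities hold by construction; impossible inputs raise
    :class:`PipelineOrderError`.
    """
    post_chimera = post_qc - chimera_flagged_removed
    bacterial = post_chimera - archaeal
    return SampleAccounting(
        sample_id=sample_id,
        raw_reads=raw_reads,
        post_qc=post_qc,
        chimera_flagged_rescued=chimera_flagged_rescued,
        chimera_flagged_removed=chimera_flagged_removed,
        post_chimera=post_chimera,
        archaeal=archaeal,
        bacterial=bacterial,
        normalized=normalized,
    )


_IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")


def _iupac_sets(pattern: str) -> list[frozenset[str]]:
    sets = []
    for ch in pattern.upper():
        if ch not in _IUPAC_CODES:
            raise ConfigurationError(f"invalid IUPAC code {ch!r} in pattern {pattern!r}")
        sets.append(frozenset(ambiguous_dna_values[ch]))
    return sets


def matches_iupac(sequence: str, pattern_sets: Sequence[frozenset[str]]) -> bool:
    """Exact 5' match of a sequence prefix against per-position IUPAC sets."""
    if len(sequence) < len(pattern_sets):
        return False
    return all(base in allowed for base, allowed in zip(sequence.upper(), pattern_sets))


def demultiplex(
    reads: Iterable[Read],
    barcode_map: Mapping[str, str],
    adaptor: str,
) -> tuple[dict[str, list[Read]], list[Read]]:
    """Assign reads to samples by exact 5' adaptor + barcode match.

    A read is assigned iff its 5' end carries the complete adaptor followed
    by one of the (unique, equal-length) barcodes; the matched prefix is
    stripped.  Everything else lands in the unassigned bin untouched.
    """
    barcodes = list(barcode_map.values())
    if len(set(barcodes)) != len(barcodes):
        raise ConfigurationError("duplicate barcodes in barcode map")
    if len({len(b) for b in barcodes}) > 1:
        raise ConfigurationError("barcodes must share one length")
    by_barcode = {bc.upper(): sid for sid, bc in barcode_map.items()}
    bc_len = len(barcodes[0]) if barcodes else 0
    ad_len = len(adaptor)
    adaptor = adaptor.upper()

    assigned: dict[str, list[Read]] = {sid: [] for sid in barcode_map}
    unassigned: list[Read] = []
    for read in reads:
        seq = read.sequence.upper()
        sid = None
        if seq.startswith(adaptor):
            sid = by_barcode.get(seq[ad_len:ad_len + bc_len])
        if sid is None or len(seq) <= ad_len + bc_len:
            unassigned.append(read)
        else:
            assigned[sid].append(Read(read.read_id, read.sequence[ad_len + bc_len:], sid))
    return assigned, unassigned


def quality_filter(
    reads: Iterable[Read],
    primer: str | None,
    max_ambig: int = 1,
    min_len: int = 150,
) -> tuple[list[Read], Counter]:
    """Apply ambiguity, primer and length rules; strip the forward primer.

    Reads with more than ``max_ambig`` 'N' bases are rejected ("ambiguous");
    reads lacking the degenerate forward primer at the 5' end are rejected
    ("no_primer"); reads shorter than ``min_len`` after primer stripping are
    rejected ("short").  Reasons are disjoint, assigned in that order.
    ``primer=None`` skips the primer rule (e.g. on already-stripped reads),
    making the filter idempotent.
    """
    primer_sets = _iupac_sets(primer) if primer else []
    plen = len(primer_sets)
    kept: list[Read] = []
    reasons: Counter = Counter()
    for read in reads:
        if read.sequence.upper().count("N") > max_ambig:
            reasons["ambiguous"] += 1
            continue
        if primer_sets and not matches_iupac(read.sequence, primer_sets):
            reasons["no_primer"] += 1
            continue
        body = read.sequence[plen:]
        if len(body) < min_len:
            reasons["short"] += 1
            continue
        kept.append(Read(read.read_id, body, read.sample_id))
    return kept, reasons
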