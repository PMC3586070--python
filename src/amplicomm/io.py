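"""Readers and writers for the pipeline's plain-text formats.

FASTA/FASTQ go through Biopython; tabular files (barcode maps, hit tables,
copy-number tables, accounting) are TSVs handled with pandas.  Reference
FASTA headers carry greengenes-style lineage strings
(``k__...;p__...;c__...;o__...;f__...;g__...``).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO

from amplicomm.read_qc import Read, SampleAccounting

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_fasta(path: str | Path) -> list[Read]:
    return [Read(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_fastq(path: str | Path) -> list[Read]:
    return [Read(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def read_sequences(path: str | Path) -> list[Read]:
    """FASTA or FASTQ, decided by extension (.fq/.fastq -> FASTQ)."""
    suffix = Path(path).suffix.lower()
    return read_fastq(path) if suffix in {".fq", ".fastq"} else read_fasta(path)


def read_barcode_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "barcode"}.issubset(df.columns):
        raise ValueError("barcode map needs 'sample_id' and 'barcode' columns")
    return dict(zip(df["sample_id"], df["barcode"]))


def parse_lineage_header(description: str) -> tuple[str, ...] | None:
    """Extract a six-rank lineage from a ``k__...;...;g__...`` header."""
    for token in description.split():
        if "__" in token and ";" in token:
            parts = [p.split("__", 1)[1] for p in token.split(";") if "__" in p]
            if len(parts) == 6:
                return tuple(parts)
    return None


def read_reference_fasta(path: str | Path) -> list[tuple[str, str, tuple[str, ...]]]:
    """(subject_id, sequence, lineage) triples from a lineage-annotated FASTA."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        lineage = parse_lineage_header(rec.description)
        if lineage is None:
            raise ValueError(f"reference {rec.id!r} lacks a k__..g__ lineage in its header")
        out.append((rec.id, str(rec.seq), lineage))
    return out


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """12-column tabular alignment file, with or without a header line."""
    with open(path) as fh:
        first = fh.readline()
    header = 0 if first.startswith("qseqid") else None
    df = pd.read_csv(path, sep="\t", header=header, names=HIT_COLUMNS)
    return df


def write_accounting(accounting: Sequence[SampleAccounting], path: str | Path) -> None:
    rows = [
        (
            a.sample_id, a.raw_reads, a.post_qc, a.chimera_flagged_rescued,
            a.chimera_flagged_removed, a.post_chimera, a.archaeal, a.bacterial,
            a.normalized if a.normalized is not None else "",
        )
        for a in accounting
    ]
    pd.DataFrame(
        rows,
        columns=[
            "sample_id", "raw_reads", "post_qc", "chimera_flagged_rescued",
            "chimera_flagged_removed", "post_chimera", "archaeal", "bacterial",
            "normalized",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_verdicts(verdicts, path: str | Path) -> None:
    rows = [
        (
            v.uid, v.flagged,
            v.parents[0] if v.parents else "", v.parents[1] if v.parents else "",
            v.breakpoint if v.breakpoint is not None else "",
            v.rescued, v.rescue_genus or "",
            "" if v.rescue_confidence is None else v.rescue_confidence,
        )
        for v in verdicts
    ]
    pd.DataFrame(
        rows,
        columns=["uid", "flagged", "parent_a", "parent_b", "breakpoint",
                 "rescued", "rescue_genus", "confidence"],
    ).to_csv(path, sep="\t", index=False)


def write_otu_table(partition, path: str | Path) -> None:
    rows = [(otu, len(members), ",".join(members)) for otu, members in partition.otus.items()]
    pd.DataFrame(rows, columns=["otu_id", "size", "member_ids"]).to_csv(
        path, sep="\t", index=False
    )


def write_profile(profile, path: str | Path) -> None:
    rows = [(t, f) for t, f in sorted(profile.fractions.items(), key=lambda x: -x[1])]
    rows.append(("unassigned", profile.unassigned))
    df = pd.DataFrame(rows, columns=["taxon", "fraction"])
    df.insert(0, "rank", profile.rank)
    df.insert(0, "scope", profile.scope)
    df.to_csv(path, sep="\t", index=False)


def read_profile(path: str | Path):
    from amplicomm.taxonomy import CommunityProfile

    df = pd.read_csv(path, sep="\t")
    named = df[df["taxon"] != "unassigned"]
    unassigned = float(df.loc[df["taxon"] == "unassigned", "fraction"].sum())
    return CommunityProfile(
        scope=str(df["scope"].iloc[0]),
        rank=str(df["rank"].iloc[0]),
        fractions=dict(zip(named["taxon"], named["fraction"].astype(float))),
        unassigned=unassigned,
        total_assigned=0,
        n_reads=0,
    )
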