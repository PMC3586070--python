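"""Synthetic multiplexed amplicon communities with full ground truth.

Emulates a four-sample multiplexed pyrosequencing run of the 16S V4 region:
per-sample genus compositions, per-genus rRNA operon copy numbers (so that
read counts follow gene fractions, i.e. cell fraction x copy number),
substitution errors, reads carrying ambiguous bases, truncated reads,
two-parent PCR chimeras, and archaeal contaminant reads.  Every emitted read
has a ground-truth record, which makes each downstream stage of the pipeline
testable without any external sequence data.

Reference sequences are random DNA organised around per-family shared cores
(roughly 70% identity between genera of one family) so that classification,
LCA and clustering behave realistically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from amplicomm.read_qc import Read
from amplicomm.taxonomy import RANKS, HitRecord

DEFAULT_ADAPTOR = "CGTATCGCCTCCCTCGCGCCATCAG"
FORWARD_PRIMER = "AYTGGGYDTAAAGNG"
DEFAULT_READ_LENGTH = 207  # average effective amplicon length this generator emulates

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class CommunitySpecError(ValueError):
    """A community spec violating one of its invariants; message names it."""


@dataclass(frozen=True)
class GenusSpec:
    """One genus: full lineage, operon copy number and reference sequence."""

    name: str
    lineage: tuple[str, ...]  # domain..genus
    copy_number: int
    reference: str


@dataclass
class SampleSpec:
    sample_id: str
    barcode: str
    composition: dict[str, float]  # genus -> cell fraction


@dataclass
class CommunitySpec:
    """Full description of a synthetic multiplexed run."""

    samples: list[SampleSpec]
    genera: dict[str, GenusSpec]
    error_rate: float = 0.005
    ambig_rate: float = 0.2
    chimera_rate: float = 0.1
    archaea_fraction: float = 0.005
    short_rate: float = 0.25
    n_reads: int = 2000
    seed: int = 0
    adaptor: str = DEFAULT_ADAPTOR
    primer: str = FORWARD_PRIMER

    def validate(self) -> None:
        for rate_name in ("error_rate", "ambig_rate", "chimera_rate", "archaea_fraction", "short_rate"):
            rate = getattr(self, rate_name)
            if not 0.0 <= rate <= 1.0:
                raise CommunitySpecError(f"rate {rate_name} = {rate} outside [0, 1]")
        if self.chimera_rate + self.archaea_fraction > 1.0:
            raise CommunitySpecError("chimera_rate + archaea_fraction exceeds 1")
        if self.n_reads < 0:
            raise CommunitySpecError("n_reads must be non-negative")
        if not self.samples:
            raise CommunitySpecError("spec has no samples")
        barcodes = [s.barcode for s in self.samples]
        if len(set(barcodes)) != len(barcodes) or len({len(b) for b in barcodes}) > 1:
            raise CommunitySpecError("sample barcodes must be unique and equal length")
        for sample in self.samples:
            total = sum(sample.composition.values())
            if abs(total - 1.0) > 1e-9:
                raise CommunitySpecError(
                    f"cell fractions for sample {sample.sample_id!r} sum to {total}, not 1"
                )
            for genus, frac in sample.composition.items():
                if frac < 0:
                    raise CommunitySpecError(f"negative cell fraction for {genus!r}")
                if genus not in self.genera:
                    raise CommunitySpecError(f"sample genus {genus!r} missing from spec.genera")
        for genus in self.genera.values():
            if genus.copy_number < 1:
                raise CommunitySpecError(f"copy number for {genus.name!r} must be >= 1")
            if len(genus.lineage) != len(RANKS):
                raise CommunitySpecError(f"genus {genus.name!r} needs a full domain..genus lineage")

    def archaeal_genera(self) -> list[str]:
        return sorted(g for g, spec in self.genera.items() if spec.lineage[0] == "Archaea")

    def references(self) -> list[tuple[str, tuple[str, ...]]]:
        """(sequence, lineage) training pairs for the classifier."""
        return [(g.reference, g.lineage) for _, g in sorted(self.genera.items())]


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one emitted read."""

    read_id: str
    sample_id: str
    source: str  # genus name, "chimera", or "archaea"
    genus: str | None  # archaeal genus for contaminants, None for chimeras
    parents: tuple[str, str] | None
    breakpoint: int | None
    qc_fail_reason: str | None  # "ambiguous" | "short" | None
    amplicon_start: int


@dataclass
class GroundTruth:
    """Per-read truth records plus per-sample true profiles."""

    records: dict[str, TruthRecord]
    gene_fractions: dict[str, dict[str, float]]  # sample -> genus -> fraction
    cell_fractions: dict[str, dict[str, float]]

    def for_sample(self, sample_id: str) -> list[TruthRecord]:
        return [r for r in self.records.values() if r.sample_id == sample_id]


def _mutate(rng: np.random.Generator, codes: np.ndarray, rate: float) -> np.ndarray:
    """Substitute bases at ``rate`` per position, never to the same base."""
    out = codes.copy()
    hit = np.where(rng.random(codes.size) < rate)[0]
    if hit.size:
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _encode(seq: str) -> np.ndarray:
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def build_reference_set(
    families: Mapping[tuple[str, ...], Sequence[tuple[str, int]]],
    length: int = DEFAULT_READ_LENGTH,
    family_divergence: float = 0.15,
    rng: np.random.Generator | int | None = None,
) -> dict[str, GenusSpec]:
    """Random references with shared family cores.

    ``families`` maps a (domain, phylum, class, order, family) path to its
    genera as ``(name, copy_number)`` pairs.  Each family gets one random
    core; each genus mutates ``family_divergence`` of the core's positions,
    so two genera of one family share roughly
    ``(1 - family_divergence)**2`` of their positions (~72% at the default).
    """
    rng = np.random.default_rng(rng)
    genera: dict[str, GenusSpec] = {}
    for path in sorted(families):
        core = rng.integers(0, 4, size=length).astype(np.uint8)
        for name, copies in sorted(families[path]):
            ref = _mutate(rng, core, family_divergence)
            genera[name] = GenusSpec(
                name=name,
                lineage=tuple(path) + (name,),
                copy_number=copies,
                reference=_decode(ref),
            )
    return genera


# genus -> per-species copy numbers whose mean equals the genus truth exactly
DEFAULT_SPECIES_COPIES: dict[str, list[int]] = {
    "Caldilinea": [1],
    "Clostridium": [8, 9, 10],
    "Desulfovibrio": [3, 4, 5],
    "Kosmotoga": [2],
    "Lactobacillus": [4, 5, 6],
    "Methanobacterium": [2],
    "Methanosaeta": [2],
    "Mycobacterium": [1, 1],
    "Nitrosomonas": [1],
    "Parvibaculum": [1],
    "Planctomyces": [1],
    "Rhodopirellula": [1],
    "Syntrophus": [1],
    "Vibrio": [8, 9, 10],
}

DEFAULT_FAMILIES: dict[tuple[str, ...], list[tuple[str, int]]] = {
    ("Bacteria", "Planctomycetes", "Planctomycetia", "Planctomycetales", "Planctomycetaceae"):
        [("Planctomyces", 1), ("Rhodopirellula", 1)],
    ("Bacteria", "Actinobacteria", "Actinomycetia", "Corynebacteriales", "Mycobacteriaceae"):
        [("Mycobacterium", 1)],
    ("Bacteria", "Proteobacteria", "Deltaproteobacteria", "Syntrophobacterales", "Syntrophaceae"):
        [("Syntrophus", 1)],
    ("Bacteria", "Proteobacteria", "Deltaproteobacteria", "Desulfovibrionales", "Desulfovibrionaceae"):
        [("Desulfovibrio", 4)],
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Vibrionales", "Vibrionaceae"):
        [("Vibrio", 9)],
    ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rhizobiales", "Rhodobiaceae"):
        [("Parvibaculum", 1)],
    ("Bacteria", "Proteobacteria", "Betaproteobacteria", "Nitrosomonadales", "Nitrosomonadaceae"):
        [("Nitrosomonas", 1)],
    ("Bacteria", "Thermotogae", "Thermotogae", "Thermotogales", "Thermotogaceae"):
        [("Kosmotoga", 2)],
    ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae"):
        [("Clostridium", 9)],
    ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae"):
        [("Lactobacillus", 5)],
    ("Bacteria", "Chloroflexi", "Caldilineae", "Caldilineales", "Caldilineaceae"):
        [("Caldilinea", 1)],
    ("Archaea", "Euryarchaeota", "Methanomicrobia", "Methanosarcinales", "Methanosaetaceae"):
        [("Methanosaeta", 2)],
    ("Archaea", "Euryarchaeota", "Methanobacteria", "Methanobacteriales", "Methanobacteriaceae"):
        [("Methanobacterium", 2)],
}

DEFAULT_COMPOSITIONS: dict[str, dict[str, float]] = {
    "activated_sludge": {
        "Planctomyces": 0.14, "Mycobacterium": 0.12, "Rhodopirellula": 0.10,
        "Caldilinea": 0.12, "Nitrosomonas": 0.10, "Parvibaculum": 0.10,
        "Desulfovibrio": 0.08, "Clostridium": 0.08, "Vibrio": 0.06,
        "Lactobacillus": 0.05, "Syntrophus": 0.03, "Kosmotoga": 0.02,
    },
    "digestion_sludge": {
        "Kosmotoga": 0.60, "Syntrophus": 0.12, "Clostridium": 0.10,
        "Desulfovibrio": 0.08, "Caldilinea": 0.04, "Mycobacterium": 0.03,
        "Lactobacillus": 0.03,
    },
    "influent": {
        "Desulfovibrio": 0.22, "Clostridium": 0.20, "Lactobacillus": 0.15,
        "Vibrio": 0.12, "Parvibaculum": 0.10, "Mycobacterium": 0.08,
        "Syntrophus": 0.05, "Nitrosomonas": 0.04, "Kosmotoga": 0.04,
    },
    "effluent": {
        "Vibrio": 0.20, "Mycobacterium": 0.16, "Parvibaculum": 0.14,
        "Nitrosomonas": 0.10, "Desulfovibrio": 0.10, "Lactobacillus": 0.08,
        "Clostridium": 0.08, "Planctomyces": 0.06, "Rhodopirellula": 0.05,
        "Kosmotoga": 0.03,
    },
}

DEFAULT_BARCODES: dict[str, str] = {
    "activated_sludge": "ACGAGTGC",
    "digestion_sludge": "TGCATCGA",
    "influent": "CGTAGCTA",
    "effluent": "GATCGTAC",
}


def default_community_spec(seed: int = 0, n_reads: int = 2000, **overrides) -> CommunitySpec:
    """The stock four-sample wastewater-style community.

    Twelve bacterial genera across eleven families (one sample dominated by
    a single genus, the others diverse), two archaeal contaminant genera,
    copy numbers spanning 1-10, and noise rates chosen so that roughly half
    the raw reads survive QC.  Keyword overrides replace any spec field.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA11C0)))
    genera = build_reference_set(DEFAULT_FAMILIES, rng=rng)
    samples = [
        SampleSpec(sid, DEFAULT_BARCODES[sid], dict(DEFAULT_COMPOSITIONS[sid]))
        for sid in ("activated_sludge", "digestion_sludge", "influent", "effluent")
    ]
    spec = CommunitySpec(samples=samples, genera=genera, n_reads=n_reads, seed=seed, **overrides)
    spec.validate()
    return spec


def true_profiles(spec: CommunitySpec, sample: SampleSpec) -> tuple[dict[str, float], dict[str, float]]:
    """(gene_fractions, cell_fractions) implied by a sample's composition."""
    genera = sorted(sample.composition)
    cell = np.array([sample.composition[g] for g in genera])
    weights = cell * np.array([spec.genera[g].copy_number for g in genera])
    gene = weights / weights.sum()
    return (
        {g: float(f) for g, f in zip(genera, gene)},
        {g: float(c) for g, c in zip(genera, cell)},
    )


def generate(spec: CommunitySpec) -> tuple[list[Read], GroundTruth]:
    """Emit a multiplexed read set and its ground truth.

    Per read: a source is drawn (two-parent chimera with probability
    ``chimera_rate``, archaeal contaminant with ``archaea_fraction``, else a
    genus in proportion to cell fraction x copy number); substitution errors
    are applied to the amplicon at ``error_rate``; with probability
    ``ambig_rate`` two 'N' bases are injected, else with ``short_rate`` the
    amplicon is truncated below the minimum length.  Each read is
    adaptor + barcode + a realised degenerate-primer instance + amplicon.
    Deterministic for a fixed seed.
    """
    spec.validate()
    primer_options = [_IUPAC[ch] for ch in spec.primer]
    arch = spec.archaeal_genera()
    reads: list[Read] = []
    records: dict[str, TruthRecord] = {}
    gene_profiles: dict[str, dict[str, float]] = {}
    cell_profiles: dict[str, dict[str, float]] = {}

    children = np.random.SeedSequence(spec.seed).spawn(len(spec.samples))
    for sample, child in zip(spec.samples, children):
        rng = np.random.default_rng(child)
        gene, cell = true_profiles(spec, sample)
        gene_profiles[sample.sample_id] = gene
        cell_profiles[sample.sample_id] = cell
        genera = sorted(gene)
        weights = np.array([gene[g] for g in genera])
        refs = {g: _encode(spec.genera[g].reference) for g in spec.genera}

        for i in range(spec.n_reads):
            read_id = f"{sample.sample_id}_r{i:05d}"
            u = rng.random()
            parents = breakpoint = None
            if u < spec.chimera_rate and len(genera) >= 2:
                source, genus = "chimera", None
                pa, pb = rng.choice(len(genera), size=2, replace=False, p=weights)
                ra, rb = refs[genera[pa]], refs[genera[pb]]
                L = min(ra.size, rb.size)
                breakpoint = int(np.floor(L * (0.3 + 0.4 * rng.random())))
                amplicon = np.concatenate([ra[:breakpoint], rb[breakpoint:]])
                parents = (genera[pa], genera[pb])
            elif u < spec.chimera_rate + spec.archaea_fraction and arch:
                source = "archaea"
                genus = arch[int(rng.integers(len(arch)))]
                amplicon = refs[genus].copy()
            else:
                source = genus = genera[int(rng.choice(len(genera), p=weights))]
                amplicon = refs[genus].copy()

            amplicon = _mutate(rng, amplicon, spec.error_rate)
            body = _decode(amplicon)

            qc_fail = None
            v = rng.random()
            if v < spec.ambig_rate:
                qc_fail = "ambiguous"
                pos = rng.choice(len(body), size=min(2, len(body)), replace=False)
                chars = list(body)
                for p in pos:
                    chars[p] = "N"
                body = "".join(chars)
            elif v < spec.ambig_rate + spec.short_rate:
                qc_fail = "short"
                body = body[: int(rng.integers(20, 150))]

            primer_inst = "".join(opts[int(rng.integers(len(opts)))] for opts in primer_options)
            prefix = spec.adaptor + sample.barcode + primer_inst
            reads.append(Read(read_id, prefix + body))
            records[read_id] = TruthRecord(
                read_id=read_id,
                sample_id=sample.sample_id,
                source=source,
                genus=genus,
                parents=parents,
                breakpoint=breakpoint,
                qc_fail_reason=qc_fail,
                amplicon_start=len(prefix),
            )

    return reads, GroundTruth(records, gene_profiles, cell_profiles)


def make_hit_table(
    reads: Sequence[Read],
    spec: CommunitySpec,
    score_noise: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Fabricate a 12-column tabular alignment hit file for a read set.

    Stands in for an alignment search of each read against the genus
    reference set: the bitscore-like value of a hit is the number of
    positionally matching bases between the read's amplicon portion and a
    reference, plus Gaussian noise of s.d. ``score_noise``.  Hits below 35%
    of the amplicon length are dropped (except that each read keeps its best
    hit, which for reads unrelated to any reference stays sub-threshold).
    Columns follow the conventional tabular alignment format.
    """
    if score_noise < 0:
        raise CommunitySpecError("score_noise must be non-negative")
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x417)))
    barcode_len = len(spec.samples[0].barcode)
    prefix_len = len(spec.adaptor) + barcode_len + len(spec.primer)
    names = sorted(spec.genera)
    L = max(len(spec.genera[g].reference) for g in names)
    ref_mat = np.full((len(names), L), 255, dtype=np.uint8)
    for gi, g in enumerate(names):
        enc = _encode(spec.genera[g].reference)
        ref_mat[gi, : enc.size] = enc

    rows = []
    for read in reads:
        seq = read.sequence.upper()
        start = prefix_len if seq.startswith(spec.adaptor) else 0
        amp = seq[start:]
        if not amp:
            continue
        lut = np.full(256, 254, dtype=np.uint8)
        for i, b in enumerate("ACGT"):
            lut[ord(b)] = i
        enc = lut[np.frombuffer(amp.encode(), dtype=np.uint8)]
        n = min(enc.size, L)
        matches = (ref_mat[:, :n] == enc[:n]).sum(axis=1)
        floor = 0.35 * n
        keep = matches >= floor
        if not keep.any():
            keep[int(matches.argmax())] = True
        for gi in np.where(keep)[0]:
            m = int(matches[gi])
            bitscore = max(0.0, m + (rng.normal(0.0, score_noise) if score_noise else 0.0))
            rows.append(
                (
                    read.read_id,
                    f"ref|{names[gi]}",
                    round(100.0 * m / n, 2),
                    n,
                    n - m,
                    0,
                    1,
                    n,
                    1,
                    n,
                    float(f"{max(2.0 ** (-bitscore) * n * L, 1e-180):.2e}"),
                    round(bitscore, 1),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore",
        ],
    )


def hit_records(
    table: pd.DataFrame, subject_taxa: Mapping[str, str]
) -> dict[str, list[HitRecord]]:
    """Group a 12-column hit table into per-read :class:`HitRecord` lists.

    ``subject_taxa`` maps subject ids (e.g. ``ref|Vibrio``) to genus names.
    """
    out: dict[str, list[HitRecord]] = {}
    for row in table.itertuples(index=False):
        subject = row.sseqid
        if subject not in subject_taxa:
            raise KeyError(f"subject {subject!r} has no taxon mapping")
        out.setdefault(row.qseqid, []).append(
            HitRecord(
                read_id=row.qseqid,
                subject_id=subject,
                percent_identity=float(row.pident),
                alignment_length=int(row.length),
                bitscore=float(row.bitscore),
                subject_taxon=subject_taxa[subject],
            )
        )
    return out


# ---------------------------------------------------------------------------
# plain-text writers


def write_fasta(reads: Sequence[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f">{read.read_id}\n{read.sequence}\n")


def write_fastq(reads: Sequence[Read], path: str | Path, quality: int = 30) -> None:
    """FASTQ with a uniform quality score (no quality model is simulated)."""
    qchar = chr(quality + 33)
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{qchar * len(read.sequence)}\n")


def write_barcode_map(spec: CommunitySpec, path: str | Path) -> None:
    pd.DataFrame(
        [(s.sample_id, s.barcode) for s in spec.samples],
        columns=["sample_id", "barcode"],
    ).to_csv(path, sep="\t", index=False)


def write_reference_fasta(spec: CommunitySpec, path: str | Path) -> None:
    """Reference FASTA with greengenes-style lineage strings in headers."""
    prefixes = "kpcofg"
    with open(path, "w") as fh:
        for name in sorted(spec.genera):
            g = spec.genera[name]
            lineage = ";".join(f"{p}__{t}" for p, t in zip(prefixes, g.lineage))
            fh.write(f">ref|{name} {lineage}\n{g.reference}\n")


def write_copy_table(spec: CommunitySpec, path: str | Path,
                     species_copies: Mapping[str, Sequence[float]] | None = None) -> None:
    """Copy-number TSV (genus, species, copy_number).

    By default each genus gets the per-species values of
    ``DEFAULT_SPECIES_COPIES`` when their mean equals the genus copy number,
    otherwise a single species row carrying the genus value.
    """
    rows = []
    for name in sorted(spec.genera):
        g = spec.genera[name]
        values: Sequence[float] | None = None
        if species_copies is not None:
            values = species_copies.get(name)
        elif name in DEFAULT_SPECIES_COPIES and \
                np.isclose(np.mean(DEFAULT_SPECIES_COPIES[name]), g.copy_number):
            values = DEFAULT_SPECIES_COPIES[name]
        if values is None:
            values = [g.copy_number]
        for i, v in enumerate(values):
            rows.append((name, f"{name}_sp{i + 1}", v))
    pd.DataFrame(rows, columns=["genus", "species", "copy_number"]).to_csv(
        path, sep="\t", index=False
    )


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    rows = [
        (
            r.read_id, r.sample_id, r.source, r.genus or "",
            r.parents[0] if r.parents else "", r.parents[1] if r.parents else "",
            r.breakpoint if r.breakpoint is not None else "",
            r.qc_fail_reason or "", r.amplicon_start,
        )
        for r in truth.records.values()
    ]
    pd.DataFrame(
        rows,
        columns=["read_id", "sample_id", "source", "genus", "parent_a", "parent_b",
                 "breakpoint", "qc_fail_reason", "amplicon_start"],
    ).to_csv(path, sep="\t", index=False)
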