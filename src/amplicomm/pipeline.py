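"""Configuration-driven orchestration of the full amplicon pipeline.

Stage order: demultiplex -> quality filter -> precluster -> bimera flagging
-> classifier rescue -> archaea removal -> depth normalization -> (OTU
clustering + alpha statistics per cutoff, and LCA profile -> copy-number
correction).  Every stage's in/out counts are reconciled in a per-sample
accounting record; a fixed seed makes the whole run deterministic.
"""

from __future__ import annotations

import hashlib
import logging
import time
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from amplicomm import io as amio
from amplicomm.copy_correction import CopyNumberTable, gene_to_cell
from amplicomm.denoise import dereplicate, flag_bimeras, precluster, rescue
from amplicomm.diversity import AlphaStats, OTUPartition, alpha_stats, cluster_otus, distance_matrix, rarefy, subsample
from amplicomm.read_qc import Read, SampleAccounting, demultiplex, quality_filter, tally
from amplicomm.synthetic import (
    DEFAULT_SPECIES_COPIES,
    CommunitySpec,
    GroundTruth,
    generate,
    hit_records,
    make_hit_table,
)
from amplicomm.taxonomy import (
    CommunityProfile,
    NaiveBayesClassifier,
    build_profile,
    filter_domain,
    lca_assign,
)

logger = logging.getLogger("amplicomm")


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage and sample it occurred in."""


@dataclass
class PipelineConfig:
    """All tunable parameters of a run, with their conventional defaults."""

    # QC
    max_ambig: int = 1
    min_len: int = 150
    adaptor: str | None = None  # None: take from the community spec / CLI input
    primer: str | None = None
    # denoising / chimera
    precluster_diffs: int = 2
    min_parent_fold: float = 2.0
    min_score_gain: float = 3.0
    min_model_identity: float = 0.9
    rescue_confidence: float = 0.5
    # classifier
    word_size: int = 8
    n_bootstrap: int = 100
    # LCA
    min_bitscore: float = 86.0
    top_percent: float = 0.1
    min_support: int = 30
    # diversity
    cluster_cutoffs: tuple[float, ...] = (0.03, 0.06)
    normalization_depth: int | str = "min"
    rarefaction_points: int = 10
    rarefaction_replicates: int = 100
    # profiles
    profile_ranks: tuple[str, ...] = ("order", "genus")
    # synthetic hit-table noise
    score_noise: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.max_ambig < 0 or self.min_len < 1:
            raise ValueError("max_ambig must be >= 0 and min_len >= 1")
        if self.precluster_diffs < 0:
            raise ValueError("precluster_diffs must be >= 0")
        if not 0.0 <= self.rescue_confidence <= 1.0:
            raise ValueError("rescue_confidence must lie in [0, 1]")
        if not 0.0 <= self.top_percent <= 1.0:
            raise ValueError("top_percent must lie in [0, 1]")
        if self.min_bitscore < 0 or self.min_support < 0:
            raise ValueError("min_bitscore and min_support must be >= 0")
        if any(not 0.0 < c < 1.0 for c in self.cluster_cutoffs):
            raise ValueError("cluster cutoffs must lie in (0, 1)")
        if isinstance(self.normalization_depth, str) and self.normalization_depth != "min":
            raise ValueError("normalization_depth is 'min' or a positive integer")
        if isinstance(self.normalization_depth, int) and self.normalization_depth < 1:
            raise ValueError("normalization_depth is 'min' or a positive integer")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cluster_cutoffs" in data:
            data["cluster_cutoffs"] = tuple(data["cluster_cutoffs"])
        if "profile_ranks" in data:
            data["profile_ranks"] = tuple(data["profile_ranks"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        blob = yaml.safe_dump(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self).items()},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class SampleResult:
    """Everything computed for one sample."""

    accounting: SampleAccounting
    qc_reasons: Counter
    verdicts: list
    alpha: dict[float, AlphaStats]
    partitions: dict[float, OTUPartition]
    rarefaction: dict[float, pd.DataFrame]
    gene_profiles: dict[str, CommunityProfile]
    cell_profile: CommunityProfile | None
    correction_report: pd.DataFrame | None
    normalized_reads: list[Read]


@dataclass
class RunReport:
    """Full pipeline output: accounting, statistics, profiles, provenance."""

    samples: dict[str, SampleResult]
    normalization_depth: int
    seed: int
    config_hash: str
    unassigned_reads: int = 0

    @property
    def accounting(self) -> dict[str, SampleAccounting]:
        return {sid: s.accounting for sid, s in self.samples.items()}


def _stage(stage: str, sample: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        result = fn(*args, **kwargs)
    except Exception as exc:  # annotate and re-raise
        raise PipelineError(f"stage {stage!r} failed for sample {sample!r}: {exc}") from exc
    logger.info("stage=%s sample=%s elapsed=%.3fs", stage, sample, time.perf_counter() - t0)
    return result


def analyze(
    reads: Sequence[Read],
    barcode_map: Mapping[str, str],
    adaptor: str,
    primer: str,
    classifier: NaiveBayesClassifier,
    hits: Mapping[str, list],
    copy_table: CopyNumberTable | None,
    config: PipelineConfig,
) -> RunReport:
    """Run every stage on an already-loaded read set.

    ``hits`` maps read ids to :class:`HitRecord` lists for the LCA engine;
    reads without hits are unassigned in the profiles.  ``copy_table`` may be
    None to skip the gene->cell conversion.
    """
    config.validate()
    tree = classifier.tree
    root_seq = np.random.SeedSequence((config.seed, 0x9155))
    per_sample_seeds = root_seq.spawn(len(barcode_map) * 2)

    assigned, unassigned = demultiplex(reads, barcode_map, adaptor)

    results: dict[str, SampleResult] = {}
    bacterial_reads: dict[str, list[Read]] = {}
    interim: dict[str, dict] = {}
    for si, (sample_id, sample_reads) in enumerate(sorted(assigned.items())):
        rng = np.random.default_rng(per_sample_seeds[2 * si])
        kept, reasons = _stage("quality_filter", sample_id, quality_filter,
                               sample_reads, primer, config.max_ambig, config.min_len)
        uniques = _stage("precluster", sample_id, lambda: precluster(dereplicate(kept), config.precluster_diffs))
        verdicts = _stage("flag_bimeras", sample_id, flag_bimeras,
                          uniques, config.min_parent_fold, config.min_score_gain,
                          config.min_model_identity)
        effective_ids, removed_ids, verdicts = _stage(
            "rescue", sample_id, rescue, verdicts, uniques, classifier,
            config.rescue_confidence, config.n_bootstrap, rng)
        if len(effective_ids) + len(removed_ids) != len(kept):
            raise PipelineError(f"stage 'rescue' lost reads for sample {sample_id!r}")
        eff_set = set(effective_ids)
        effective = [r for r in kept if r.read_id in eff_set]
        by_uid = {u.uid: u for u in uniques}
        rescued_count = sum(by_uid[v.uid].abundance for v in verdicts if v.rescued)
        bacterial, archaeal_n = _stage("filter_domain", sample_id, filter_domain,
                                       effective, classifier, "Archaea", 1, rng)
        accounting = tally(
            sample_id,
            raw_reads=len(sample_reads),
            post_qc=len(kept),
            chimera_flagged_rescued=rescued_count,
            chimera_flagged_removed=len(removed_ids),
            archaeal=archaeal_n,
        )
        bacterial_reads[sample_id] = bacterial
        interim[sample_id] = {"accounting": accounting, "reasons": reasons, "verdicts": verdicts}

    # depth normalization across samples
    counts = {sid: len(rs) for sid, rs in bacterial_reads.items()}
    if config.normalization_depth == "min":
        depth = min(counts.values()) if counts else 0
    else:
        depth = int(config.normalization_depth)
        for sid, c in counts.items():
            if depth > c:
                raise PipelineError(
                    f"stage 'normalize' failed for sample {sid!r}: depth {depth} exceeds {c} reads"
                )

    for si, (sample_id, bact) in enumerate(sorted(bacterial_reads.items())):
        rng = np.random.default_rng(per_sample_seeds[2 * si + 1])
        normalized = _stage("normalize", sample_id, subsample, bact, depth, rng)
        acct = interim[sample_id]["accounting"]
        acct.normalized = depth

        uniques = dereplicate(normalized)
        seqs = [u.sequence for u in uniques]
        weights = [u.abundance for u in uniques]
        dm = _stage("distances", sample_id, distance_matrix, seqs)
        partitions: dict[float, OTUPartition] = {}
        alpha: dict[float, AlphaStats] = {}
        curves: dict[float, pd.DataFrame] = {}
        for cutoff in config.cluster_cutoffs:
            part = _stage(f"cluster@{cutoff}", sample_id, cluster_otus,
                          dm, cutoff, [u.uid for u in uniques], weights)
            partitions[cutoff] = part
            alpha[cutoff] = alpha_stats(part)
            depths = np.unique(np.linspace(1, depth, config.rarefaction_points).astype(int))
            curves[cutoff] = rarefy(part.abundances, depths,
                                    config.rarefaction_replicates, rng)

        assignments = []
        for read in normalized:
            read_hits = hits.get(read.read_id, [])
            assignments.append(
                lca_assign(read_hits, tree, config.min_bitscore, config.top_percent, read.read_id)
            )
        gene_profiles = {
            rank: build_profile(assignments, tree, rank, config.min_support)
            for rank in config.profile_ranks
        }
        cell_profile = correction = None
        if copy_table is not None and "genus" in gene_profiles:
            cell_profile, correction = _stage("copy_correction", sample_id, gene_to_cell,
                                              gene_profiles["genus"], copy_table)

        results[sample_id] = SampleResult(
            accounting=acct,
            qc_reasons=interim[sample_id]["reasons"],
            verdicts=interim[sample_id]["verdicts"],
            alpha=alpha,
            partitions=partitions,
            rarefaction=curves,
            gene_profiles=gene_profiles,
            cell_profile=cell_profile,
            correction_report=correction,
            normalized_reads=normalized,
        )

    return RunReport(
        samples=results,
        normalization_depth=depth,
        seed=config.seed,
        config_hash=config.config_hash(),
        unassigned_reads=len(unassigned),
    )


def copy_table_from_spec(spec: CommunitySpec) -> CopyNumberTable:
    """Per-species copy-number table consistent with a community spec."""
    table: dict[str, list[float]] = {}
    for name in sorted(spec.genera):
        g = spec.genera[name]
        values = DEFAULT_SPECIES_COPIES.get(name)
        if values is None or abs(float(np.mean(values)) - g.copy_number) > 1e-12:
            values = [g.copy_number]
        table[name] = [float(v) for v in values]
    return CopyNumberTable(table)


def run_synthetic(
    spec: CommunitySpec,
    config: PipelineConfig | None = None,
    truth_out: list | None = None,
) -> RunReport:
    """Generate a synthetic run and push it through the full pipeline.

    ``truth_out``, if given an empty list, receives the
    (reads, :class:`GroundTruth`) pair for downstream comparison.
    """
    config = config or PipelineConfig(seed=spec.seed)
    reads, truth = generate(spec)
    if truth_out is not None:
        truth_out.append((reads, truth))
    table = make_hit_table(reads, spec, config.score_noise, seed=config.seed)
    subject_taxa = {f"ref|{g}": g for g in spec.genera}
    hits = hit_records(table, subject_taxa)
    classifier = NaiveBayesClassifier(config.word_size).train(spec.references())
    barcode_map = {s.sample_id: s.barcode for s in spec.samples}
    return analyze(
        reads, barcode_map, spec.adaptor, spec.primer, classifier, hits,
        copy_table_from_spec(spec), config,
    )


def run(
    config: PipelineConfig,
    reads_path: str | Path,
    barcode_map_path: str | Path,
    reference_path: str | Path,
    adaptor: str,
    primer: str,
    hit_table_path: str | Path | None = None,
    copy_table_path: str | Path | None = None,
) -> RunReport:
    """File-based entry point: load inputs, then :func:`analyze`."""
    reads = amio.read_sequences(reads_path)
    barcode_map = amio.read_barcode_map(barcode_map_path)
    refs = amio.read_reference_fasta(reference_path)
    classifier = NaiveBayesClassifier(config.word_size).train(
        [(seq, lineage) for _, seq, lineage in refs]
    )
    subject_taxa = {sid: lineage[-1] for sid, _, lineage in refs}
    hits: dict[str, list] = {}
    if hit_table_path is not None:
        table = amio.read_hit_table(hit_table_path)
        hits = hit_records(table, subject_taxa)
    copy_table = CopyNumberTable.from_tsv(copy_table_path) if copy_table_path else None
    return analyze(reads, barcode_map, adaptor, primer, classifier, hits, copy_table, config)


def report_table(report: RunReport) -> pd.DataFrame:
    """Per-sample summary table in the conventional column order.

    Raw reads, effective (post-QC), chimeras rescued/removed, effective after
    chimera removal, archaeal, bacterial, normalization depth, then per
    cutoff: Chao1, Shannon, OTU count, Good's coverage.
    """
    rows = []
    cutoffs: list[float] = []
    for sid in sorted(report.samples):
        s = report.samples[sid]
        a = s.accounting
        # re-check the bookkeeping identities at render time
        tally(sid, a.raw_reads, a.post_qc, a.chimera_flagged_rescued,
              a.chimera_flagged_removed, a.archaeal, a.normalized)
        row: dict = {
            "sample": sid,
            "raw_reads": a.raw_reads,
            "effective": a.post_qc,
            "chimera_rescued": a.chimera_flagged_rescued,
            "chimera_removed": a.chimera_flagged_removed,
            "post_chimera": a.post_chimera,
            "archaeal": a.archaeal,
            "bacterial": a.bacterial,
            "normalized": a.normalized,
        }
        for cutoff in sorted(s.alpha):
            if cutoff not in cutoffs:
                cutoffs.append(cutoff)
            st = s.alpha[cutoff]
            pct = int(round(cutoff * 100))
            row[f"chao1_{pct}pct"] = round(st.chao1, 1)
            row[f"shannon_{pct}pct"] = round(st.shannon, 2)
            row[f"otus_{pct}pct"] = st.otus
            row[f"coverage_{pct}pct"] = round(st.goods_coverage, 1)
        rows.append(row)
    columns = ["sample", "raw_reads", "effective", "chimera_rescued", "chimera_removed",
               "post_chimera", "archaeal", "bacterial", "normalized"]
    for cutoff in sorted(cutoffs):
        pct = int(round(cutoff * 100))
        columns += [f"chao1_{pct}pct", f"shannon_{pct}pct", f"otus_{pct}pct", f"coverage_{pct}pct"]
    return pd.DataFrame(rows, columns=columns)
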