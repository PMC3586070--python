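"""The mock-community generator and its ground truth."""

import numpy as np
import pytest
from scipy import stats

from amplicomm.read_qc import demultiplex, quality_filter
from amplicomm.synthetic import (
    CommunitySpec,
    CommunitySpecError,
    GenusSpec,
    SampleSpec,
    default_community_spec,
    generate,
    hit_records,
    make_hit_table,
    true_profiles,
)


def _two_genus_spec(**overrides):
    rng = np.random.default_rng(0)
    genera = {}
    for name, copies, fam in (("Alphagenus", 2, "F1"), ("Betagenus", 4, "F2")):
        seq = "".join(rng.choice(list("ACGT"), size=207))
        genera[name] = GenusSpec(
            name, ("Bacteria", "P1", "C1", "O1", fam, name), copies, seq
        )
    kwargs = dict(
        samples=[SampleSpec("s1", "ACGTACGT", {"Alphagenus": 0.5, "Betagenus": 0.5})],
        genera=genera,
        error_rate=0.0, ambig_rate=0.0, chimera_rate=0.0,
        archaea_fraction=0.0, short_rate=0.0, n_reads=10, seed=1,
    )
    kwargs.update(overrides)
    return CommunitySpec(**kwargs)


class TestSpecValidation:
    def test_cell_fractions_must_sum_to_one(self):
        spec = _two_genus_spec()
        spec.samples[0].composition["Alphagenus"] = 0.9
        with pytest.raises(CommunitySpecError, match="sum"):
            spec.validate()

    def test_rates_outside_unit_interval_named(self):
        spec = _two_genus_spec(error_rate=1.5)
        with pytest.raises(CommunitySpecError, match="error_rate"):
            spec.validate()

    def test_copy_number_below_one_rejected(self):
        spec = _two_genus_spec()
        bad = GenusSpec("Bad", ("Bacteria", "P", "C", "O", "F", "Bad"), 0, "ACGT" * 50)
        spec.genera["Bad"] = bad
        with pytest.raises(CommunitySpecError, match="copy number"):
            spec.validate()

    def test_duplicate_barcodes_rejected(self):
        spec = _two_genus_spec()
        spec.samples.append(
            SampleSpec("s2", "ACGTACGT", {"Alphagenus": 1.0})
        )
        with pytest.raises(CommunitySpecError, match="barcode"):
            spec.validate()

    def test_generate_refuses_invalid_spec(self):
        spec = _two_genus_spec(n_reads=-1)
        with pytest.raises(CommunitySpecError):
            generate(spec)


class TestGenerate:
    def test_single_source_degenerate_case(self):
        spec = _two_genus_spec()
        spec.samples[0].composition = {"Alphagenus": 1.0}
        reads, truth = generate(spec)
        assert len(reads) == 10
        amplicons = {
            r.sequence[truth.records[r.read_id].amplicon_start:] for r in reads
        }
        assert len(amplicons) == 1  # identical amplicons (error-free, one source)
        assert all(rec.source == "Alphagenus" for rec in truth.records.values())

    def test_true_gene_fractions_weight_by_copy_number(self):
        spec = _two_genus_spec()
        gene, cell = true_profiles(spec, spec.samples[0])
        assert gene["Alphagenus"] == pytest.approx(1 / 3)
        assert gene["Betagenus"] == pytest.approx(2 / 3)
        assert cell == {"Alphagenus": 0.5, "Betagenus": 0.5}

    def test_read_counts_conserved_per_sample(self, noisy_data):
        spec, reads, truth = noisy_data
        for sample in spec.samples:
            n = sum(1 for r in truth.records.values() if r.sample_id == sample.sample_id)
            assert n == spec.n_reads
        assert len(reads) == len(truth.records) == spec.n_reads * len(spec.samples)

    def test_chimera_count_within_binomial_99_interval(self):
        spec = _two_genus_spec(n_reads=2000, chimera_rate=0.1, seed=17)
        _, truth = generate(spec)
        chimeras = sum(1 for r in truth.records.values() if r.source == "chimera")
        lo, hi = stats.binom.ppf([0.005, 0.995], 2000, 0.1)
        assert lo <= chimeras <= hi

    def test_reruns_are_byte_identical(self):
        spec = default_community_spec(seed=13, n_reads=150)
        r1, t1 = generate(spec)
        r2, t2 = generate(spec)
        assert [(r.read_id, r.sequence) for r in r1] == [(r.read_id, r.sequence) for r in r2]
        assert t1.records == t2.records

    def test_different_seed_changes_reads(self):
        a, _ = generate(default_community_spec(seed=1, n_reads=50))
        b, _ = generate(default_community_spec(seed=2, n_reads=50))
        assert [r.sequence for r in a] != [r.sequence for r in b]

    def test_chimera_breakpoint_in_central_window(self, noisy_data):
        spec, _, truth = noisy_data
        L = 207
        for rec in truth.records.values():
            if rec.source == "chimera":
                assert 0.3 * L - 1 <= rec.breakpoint <= 0.7 * L

    def test_empirical_gene_fractions_converge_to_truth(self):
        # total variation distance of clean-read genus frequencies vs truth
        spec = default_community_spec(
            seed=29, n_reads=5000, chimera_rate=0.0, archaea_fraction=0.0
        )
        spec.samples = spec.samples[:1]
        spec.validate()
        _, truth = generate(spec)
        sid = spec.samples[0].sample_id
        counts: dict[str, int] = {}
        total = 0
        for rec in truth.records.values():
            counts[rec.genus] = counts.get(rec.genus, 0) + 1
            total += 1
        gene = truth.gene_fractions[sid]
        tv = 0.5 * sum(
            abs(counts.get(g, 0) / total - frac) for g, frac in gene.items()
        )
        assert tv < 0.05

    def test_gene_to_cell_round_trip_on_truth(self, noiseless_run):
        from amplicomm.copy_correction import gene_to_cell
        from amplicomm.pipeline import copy_table_from_spec
        from amplicomm.taxonomy import CommunityProfile

        spec, _, truth, _ = noiseless_run
        table = copy_table_from_spec(spec)
        for sid, gene in truth.gene_fractions.items():
            profile = CommunityProfile("gene", "genus", gene, 0.0, 100, 100)
            cell, _ = gene_to_cell(profile, table)
            for genus, frac in truth.cell_fractions[sid].items():
                assert cell.fractions[genus] == pytest.approx(frac, abs=1e-9)


class TestHitTable:
    def test_top_hit_is_true_genus_without_noise(self, noiseless_spec):
        reads, truth = generate(noiseless_spec)
        table = make_hit_table(reads, noiseless_spec, score_noise=0.0, seed=0)
        best = table.loc[table.groupby("qseqid")["bitscore"].idxmax()]
        for row in best.itertuples(index=False):
            rec = truth.records[row.qseqid]
            assert row.sseqid == f"ref|{rec.genus}"

    def test_chimera_reads_hit_both_parent_families(self):
        spec = default_community_spec(
            seed=31, n_reads=200, error_rate=0.0, ambig_rate=0.0,
            chimera_rate=0.3, archaea_fraction=0.0, short_rate=0.0,
        )
        reads, truth = generate(spec)
        table = make_hit_table(reads, spec, score_noise=0.0, seed=0)
        by_read = dict(iter(table.groupby("qseqid")))
        families = {g: spec.genera[g].lineage[4] for g in spec.genera}
        checked = 0
        for rec in truth.records.values():
            if rec.source != "chimera" or rec.parents is None:
                continue
            fa, fb = families[rec.parents[0]], families[rec.parents[1]]
            if fa == fb or rec.read_id not in by_read:
                continue
            hit_genera = {s.split("|", 1)[1] for s in by_read[rec.read_id]["sseqid"]}
            hit_fams = {families[g] for g in hit_genera}
            assert {fa, fb} <= hit_fams
            checked += 1
        assert checked > 10

    def test_fixed_seed_reproduces_table(self, noiseless_spec):
        reads, _ = generate(noiseless_spec)
        t1 = make_hit_table(reads, noiseless_spec, score_noise=2.0, seed=4)
        t2 = make_hit_table(reads, noiseless_spec, score_noise=2.0, seed=4)
        assert t1.equals(t2)

    def test_hit_records_grouping(self, noiseless_spec):
        reads, _ = generate(noiseless_spec)
        table = make_hit_table(reads[:20], noiseless_spec, score_noise=0.0, seed=0)
        subject_taxa = {f"ref|{g}": g for g in noiseless_spec.genera}
        grouped = hit_records(table, subject_taxa)
        assert set(grouped) == set(table["qseqid"])
        for read_id, hits in grouped.items():
            assert all(h.read_id == read_id for h in hits)

    def test_negative_noise_rejected(self, noiseless_spec):
        with pytest.raises(CommunitySpecError):
            make_hit_table([], noiseless_spec, score_noise=-1.0, seed=0)


class TestWriters:
    def test_fasta_barcode_truth_round_trip(self, tmp_path):
        from amplicomm import io as amio
        from amplicomm.synthetic import write_barcode_map, write_fasta, write_truth

        spec = default_community_spec(seed=3, n_reads=30)
        reads, truth = generate(spec)
        write_fasta(reads, tmp_path / "reads.fasta")
        write_barcode_map(spec, tmp_path / "barcodes.tsv")
        write_truth(truth, tmp_path / "truth.tsv")

        back = amio.read_sequences(tmp_path / "reads.fasta")
        assert [(r.read_id, r.sequence) for r in back] == [
            (r.read_id, r.sequence) for r in reads
        ]
        bm = amio.read_barcode_map(tmp_path / "barcodes.tsv")
        assert bm == {s.sample_id: s.barcode for s in spec.samples}

    def test_reference_fasta_lineages_parse_back(self, tmp_path):
        from amplicomm import io as amio
        from amplicomm.synthetic import write_reference_fasta

        spec = default_community_spec(seed=3, n_reads=10)
        write_reference_fasta(spec, tmp_path / "refs.fasta")
        refs = amio.read_reference_fasta(tmp_path / "refs.fasta")
        assert len(refs) == len(spec.genera)
        for sid, seq, lineage in refs:
            genus = lineage[-1]
            assert spec.genera[genus].reference == seq
            assert spec.genera[genus].lineage == lineage
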