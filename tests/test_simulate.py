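"""Synthetic-data generator: determinism, composition, ground-truth contracts."""

from __future__ import annotations

import math

import pytest

from carpmir.preprocess import clean_reads, collapse
from carpmir.simulate import (
    DEFAULT_ISOMIR_PROFILE,
    SimulationConfig,
    generate_genome,
    make_ncrna_reference,
    simulate_ct_table,
    simulate_reads,
)


class TestConfig:
    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(contaminant_fraction=0.7, junk_fraction=0.4)

    def test_profile_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            SimulationConfig(isomir_profile={0: 0.5})

    def test_profile_must_stay_in_read_envelope(self):
        # a -5 offset on a 22 nt mature would give 17 nt inserts
        with pytest.raises(ValueError):
            SimulationConfig(isomir_profile={-5: 0.5, 0: 0.5})

    def test_default_profile_mass_in_21_23(self):
        mass = sum(p for off, p in DEFAULT_ISOMIR_PROFILE.items() if -1 <= off <= 1)
        assert mass == pytest.approx(0.9349)


class TestGenerateGenome:
    def test_zero_hairpins(self):
        cfg = SimulationConfig(n_hairpins=0, genome_length=5_000)
        genome, hairpins, _ = generate_genome(cfg)
        assert hairpins == [] and len(genome["contig_1"]) == 5_000

    def test_infeasible_config_fails(self):
        with pytest.raises(ValueError, match="cannot hold"):
            generate_genome(SimulationConfig(n_hairpins=100, genome_length=10_000))

    def test_deterministic_bytes(self):
        a = generate_genome(SimulationConfig(seed=1, total_reads=10))
        b = generate_genome(SimulationConfig(seed=1, total_reads=10))
        assert a[0] == b[0]
        assert [h.precursor_seq for h in a[1]] == [h.precursor_seq for h in b[1]]

    def test_planted_invariants(self, small_sim):
        """Matures are substrings of their precursors, loci non-overlapping,
        half on each strand, and the locus carries the precursor."""
        _cfg, genome, hairpins, _ = small_sim
        seq = genome["contig_1"]
        spans = []
        for h in hairpins:
            assert h.mature_seq in h.precursor_seq
            contig, start, end, strand = h.genome_locus
            spans.append((start, end))
            planted = seq[start:end].replace("T", "U")
            if strand == "+":
                assert planted == h.precursor_seq
            else:
                comp = {"A": "U", "U": "A", "C": "G", "G": "C"}
                assert "".join(comp[c] for c in reversed(planted)) == h.precursor_seq
        spans.sort()
        assert all(b[0] >= a[1] for a, b in zip(spans, spans[1:]))
        assert sum(h.genome_locus[3] == "+" for h in hairpins) == len(hairpins) // 2


class TestSimulateReads:
    def test_manifest_covers_every_read(self, small_sim):
        cfg, _genome, hairpins, ref = small_sim
        records, manifest = simulate_reads(cfg, hairpins, ref)
        assert len(records) == cfg.total_reads
        assert len(manifest.reads) == cfg.total_reads
        assert manifest.origin_counts().sum() == cfg.total_reads

    def test_pure_mirna_source(self):
        cfg = SimulationConfig(
            total_reads=500, contaminant_fraction=0.0, junk_fraction=0.0, seed=2
        )
        _genome, hairpins, _ = generate_genome(cfg)
        records, manifest = simulate_reads(cfg, hairpins, [])
        assert set(manifest.reads["origin"]) == {"mirna"}
        matures = {h.name: h for h in hairpins}
        for row in manifest.reads.itertuples():
            h = matures[row.origin_name]
            assert row.insert in h.precursor_seq
            assert abs(len(row.insert) - len(h.mature_seq)) <= 5

    def test_offset_zero_profile_forces_21_23(self):
        cfg = SimulationConfig(
            total_reads=300, isomir_profile={0: 1.0}, junk_fraction=0.0,
            contaminant_fraction=0.0, seed=4,
        )
        _genome, hairpins, _ = generate_genome(cfg)
        _records, manifest = simulate_reads(cfg, hairpins, [])
        lengths = manifest.reads["insert"].str.len()
        assert ((lengths >= 21) & (lengths <= 23)).all()

    def test_contaminants_require_reference(self):
        cfg = SimulationConfig(total_reads=10, contaminant_fraction=0.5, seed=2)
        _genome, hairpins, _ = generate_genome(cfg)
        with pytest.raises(ValueError, match="ncRNA reference"):
            simulate_reads(cfg, hairpins, [])

    def test_cleaning_report_equals_manifest_exactly(self, small_sim):
        """The generator's round-trip guarantee: every junk read is discarded
        for its intended reason and nothing else is discarded."""
        cfg, _genome, hairpins, ref = small_sim
        records, manifest = simulate_reads(cfg, hairpins, ref)
        raw = ((rid, seq, [ord(c) - 33 for c in q]) for rid, seq, q in records)
        _inserts, report = clean_reads(raw, cfg.adapter_3p, cfg.adapter_5p)
        from carpmir.simulate import JUNK_TO_DISCARD_REASON

        junk = manifest.reads[manifest.reads.origin == "junk"]
        expected = {reason: 0 for reason in report.discards}
        for cls, n in junk["origin_name"].value_counts().items():
            expected[JUNK_TO_DISCARD_REASON[cls]] += int(n)
        assert report.discards == expected

    def test_contaminants_are_reference_substrings(self, small_sim):
        cfg, _genome, hairpins, ref = small_sim
        _records, manifest = simulate_reads(cfg, hairpins, ref)
        by_class: dict[str, list[str]] = {}
        for _rid, cls, seq in ref:
            by_class.setdefault(cls, []).append(seq)
        nc = manifest.reads[manifest.reads.origin == "ncrna"]
        sample = nc.sample(n=min(len(nc), 200), random_state=0)
        for row in sample.itertuples():
            assert any(row.insert in s for s in by_class[row.origin_name])


class TestSimulateCtTable:
    def test_zero_noise_all_folds_one_gives_flat_ct(self):
        t = simulate_ct_table({"30dph": 1.0, "1y": 1.0}, noise_sd=0.0, seed=1)
        dct = t.groupby("group").apply(
            lambda s: s.ct_target.mean() - s.ct_reference.mean(), include_groups=False
        )
        assert dct.max() - dct.min() == pytest.approx(0.0, abs=1e-12)

    def test_fold_two_shifts_ct_by_one_cycle(self):
        t = simulate_ct_table({"30dph": 1.0, "2y": 2.0}, noise_sd=0.0, seed=1)
        ct = t.groupby("group")["ct_target"].mean()
        assert ct["30dph"] - ct["2y"] == pytest.approx(1.0, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="calibrator"):
            simulate_ct_table({"1y": 2.0})
        with pytest.raises(ValueError, match="fold 1"):
            simulate_ct_table({"30dph": 2.0})
        with pytest.raises(ValueError, match="non-positive"):
            simulate_ct_table({"30dph": 1.0, "1y": -1.0})
        with pytest.raises(ValueError, match="replicates"):
            simulate_ct_table({"30dph": 1.0}, n_replicates=1)


def test_ncrna_reference_classes():
    ref = make_ncrna_reference(0)
    assert {cls for _i, cls, _s in ref} == {"rRNA", "tRNA", "snRNA", "snoRNA"}
    assert all(seq and set(seq) <= set("ACGU") for _i, _c, seq in ref)
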