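"""Catalog matching, isomiR clustering, seeds and conservation partitioning."""

from __future__ import annotations

import itertools
import random

import pytest

from carpmir.discovery import (
    CatalogEntry,
    MatureCatalog,
    category_compatible,
    classify_conservation,
    cluster_categories,
    compare_external_set,
    conservation_partition,
    extract_seed,
    match_known,
    normalize_name,
)
from carpmir.preprocess import UniqueRead
from carpmir.tables import load_table

from _oracles import brute_force_match

MIR1 = "UGGAAUGUAAAGAAGUAUGUAU"
LET7H = "UGAGGUAGUAAGUUGUGUUGU"


class TestExtractSeed:
    @pytest.mark.parametrize(
        "seq,seed", [(MIR1, "GGAAUGU"), (LET7H, "GAGGUAG")]
    )
    def test_positions_2_to_8(self, seq, seed):
        assert extract_seed(seq) == seed

    def test_too_short_fails(self):
        with pytest.raises(ValueError, match="seed"):
            extract_seed("UGAGGUA")


def _catalog(entries):
    return MatureCatalog([CatalogEntry(n, s, q) for n, s, q in entries])


class TestMatchKnown:
    def test_exact_match_zero_edits(self):
        cat = _catalog([("cca-miR-1", "cca", MIR1)])
        matches, unmatched = match_known([UniqueRead(MIR1, 10)], cat)
        assert unmatched == []
        (read, entry, cost) = matches[0]
        assert entry.name == "cca-miR-1" and cost == 0

    def test_end_trim_still_matches(self):
        cat = _catalog([("cca-miR-1", "cca", MIR1)])
        matches, _ = match_known([UniqueRead(MIR1[:-2], 1)], cat)
        assert matches and matches[0][1].name == "cca-miR-1" and matches[0][2] == 2

    def test_different_seed_never_matches(self):
        cat = _catalog([("cca-miR-1", "cca", MIR1)])
        other = "UCCGAUGUAAAGAAGUAUGUAU"  # seed differs
        _, unmatched = match_known([UniqueRead(other, 1)], cat)
        assert len(unmatched) == 1

    def test_matches_brute_force_on_random_reads(self):
        """Match decisions equal the direct-definition edit check for random
        reads against a 50-entry catalog."""
        rng = random.Random(21)
        entries = []
        for i in range(50):
            seq = "".join(rng.choice("ACGU") for _ in range(rng.randint(20, 23)))
            entries.append((f"cca-sim-{i}", "cca", seq))
        cat = _catalog(entries)
        reads = []
        for _ in range(120):
            if rng.random() < 0.5:
                base = entries[rng.randrange(50)][2]
                # random end perturbation
                t5 = rng.randint(0, 2)
                t3 = rng.randint(0, 3)
                seq = base[t5 : len(base) - t3]
            else:
                seq = "".join(rng.choice("ACGU") for _ in range(22))
            if 18 <= len(seq) <= 23:
                reads.append(UniqueRead(seq, 1))
        matches, unmatched = match_known(reads, cat)
        decided = {r.sequence: c for r, _e, c in matches}
        for r in reads:
            oracle = [
                c
                for c in (brute_force_match(r.sequence, e[2]) for e in entries)
                if c is not None
            ]
            if oracle:
                assert decided[r.sequence] == min(oracle)
            else:
                assert r.sequence not in decided

    def test_empty_catalog_all_unmatched(self):
        reads = [UniqueRead(MIR1, 1)]
        matches, unmatched = match_known(reads, MatureCatalog([]))
        assert matches == [] and unmatched == reads


class TestClusterCategories:
    def test_trim_series_forms_one_category(self):
        e = CatalogEntry("cca-miR-1", "cca", MIR1)
        reads = [
            (UniqueRead(MIR1, 100), e, 0),
            (UniqueRead(MIR1[:-1], 10), e, 1),
            (UniqueRead(MIR1[:-2], 5), e, 2),
        ]
        cats = cluster_categories(reads)
        assert len(cats) == 1
        assert cats[0].representative.sequence == MIR1
        assert cats[0].seed == "GGAAUGU"
        assert cats[0].read_total == 115

    def test_different_seeds_split(self):
        e1 = CatalogEntry("cca-miR-1", "cca", MIR1)
        e2 = CatalogEntry("cca-let-7h", "cca", LET7H)
        cats = cluster_categories([(UniqueRead(MIR1, 5), e1, 0), (UniqueRead(LET7H, 5), e2, 0)])
        assert len(cats) == 2

    def test_permutation_invariance_and_representative_maximality(self):
        """On random isomiR clouds, clustering is order-independent, every
        read lands in exactly one category, and each representative has the
        maximal count."""
        rng = random.Random(31)
        for _trial in range(20):
            clouds = []
            for c in range(rng.randint(2, 4)):
                base = "".join(rng.choice("ACGU") for _ in range(22))
                entry = CatalogEntry(f"cca-sim-{_trial}-{c}", "cca", base)
                n = rng.randint(2, 5)
                seqs = {base}
                for _ in range(n):
                    t3 = rng.randint(1, 4)
                    seqs.add(base[:-t3])
                clouds.append(
                    [(UniqueRead(s, rng.randint(1, 500)), entry, 0) for s in seqs]
                )
            flat = [x for cloud in clouds for x in cloud]
            cats = cluster_categories(flat)
            shuffled = flat[:]
            rng.shuffle(shuffled)
            cats2 = cluster_categories(shuffled)
            key = lambda cs: [
                (c.assigned_name, c.representative.sequence, sorted(m.sequence for m in c.members))
                for c in cs
            ]
            assert key(cats) == key(cats2)
            assert sum(len(c.members) for c in cats) == len(flat)
            for c in cats:
                assert c.representative.count == max(m.count for m in c.members)
                for m in c.members:
                    assert extract_seed(m.sequence) == c.seed

    def test_compatibility_predicate_requires_seed(self):
        assert category_compatible(MIR1, MIR1[:-3])
        assert not category_compatible(MIR1, LET7H)


class TestConservation:
    def test_teleost_only_example(self):
        assert classify_conservation({"dre"}) == "teleost_only"

    def test_carp_specific_empty(self):
        assert classify_conservation(set()) == "carp_specific"

    def test_vertebrate_conserved(self):
        assert classify_conservation({"xtr", "dre", "gga", "mmu", "hsa"}) == "vertebrate_conserved"

    def test_pan_bilaterian_beats_vertebrate(self):
        present = {"cel", "dme", "xtr", "dre", "gga", "mmu", "hsa"}
        assert classify_conservation(present) == "pan_bilaterian"

    def test_unknown_species_named_in_error(self):
        with pytest.raises(ValueError, match="zzz"):
            classify_conservation({"zzz"})

    def test_classes_exclusive_and_exhaustive(self):
        """Every subset of a representative species pool gets exactly one class."""
        pool = ["dre", "ola", "mmu", "hsa", "xtr", "gga", "cel"]
        for r in range(len(pool) + 1):
            for subset in itertools.combinations(pool, r):
                cls = classify_conservation(set(subset))
                assert cls in {
                    "pan_bilaterian",
                    "vertebrate_conserved",
                    "teleost_only",
                    "carp_specific",
                    "partially_conserved",
                }

    def test_teleost_table_all_classified_teleost_only(self):
        """A catalog built from the teleost-restricted table's species
        columns classifies all 31 miRNAs teleost_only."""
        rows = load_table("T2")
        entries, cats = [], []
        for row in rows:
            entries.append(CatalogEntry(row.mirna, "cca", row.sequence))
            for sp in row.conserved_species:
                entries.append(
                    CatalogEntry(f"{sp}-{row.mirna.split('-', 1)[1]}", sp, row.sequence)
                )
            read = UniqueRead(row.sequence, row.frequency)
            cats.append(
                cluster_categories([(read, entries[-len(row.conserved_species) - 1], 0)])[0]
            )
        catalog = MatureCatalog(sorted(set(entries), key=lambda e: (e.name, e.species)))
        profiles = conservation_partition(cats, catalog)
        assert len(profiles) == 31
        assert all(p.conservation_class == "teleost_only" for p in profiles)


class TestCompareExternalSet:
    def test_full_overlap(self):
        cats = cluster_categories(
            [(UniqueRead(MIR1, 5), CatalogEntry("cca-miR-1", "cca", MIR1), 0)]
        )
        assert compare_external_set(cats, ["hno-miR-1"]) == 1.0
        assert compare_external_set(cats, []) == 0.0

    def test_fractional_overlap(self):
        rng = random.Random(3)
        cands = []
        for i in range(10):
            seq = "".join(rng.choice("ACGU") for _ in range(22))
            cands.append((UniqueRead(seq, 1), CatalogEntry(f"cca-miR-x{i}", "cca", seq), 0))
        cats = cluster_categories(cands)
        other = [f"hno-miR-x{i}" for i in range(8)]
        assert compare_external_set(cats, other) == pytest.approx(0.8)

    def test_empty_categories_fail(self):
        with pytest.raises(ValueError):
            compare_external_set([], ["x"])

    def test_name_normalization(self):
        assert normalize_name("cca-miR-133a-3p") == "mir-133a-3p"
        assert normalize_name("cca-miR-133a-3p", strip_arm=True) == "mir-133a"
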