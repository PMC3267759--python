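"""End-to-end orchestration: simulate -> clean -> collapse -> annotate ->
map -> conserved identification -> isomiR clustering -> novel prediction ->
conservation partition -> report.

A run is driven by a serializable :class:`RunConfig`; re-running with the
same configuration reproduces identical outputs byte for byte.  Stage
outputs and a count report mirroring the narrative of a small-RNA survey
(raw reads, clean reads, unique reads, annotated, mapped, conserved
candidates, categories, novel) are written under the output directory.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import annotate as annotate_mod
from . import discovery, novel, preprocess
from .io_utils import rna_to_dna, write_fasta, write_fastq
from .simulate import (
    GroundTruthManifest,
    PlantedHairpin,
    SimulationConfig,
    generate_genome,
    make_ncrna_reference,
    simulate_reads,
)

logger = logging.getLogger("carpmir")


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_in_catalog: int = 12  # planted matures entered into the known catalog
    index_k: int = 12
    max_loci: int = 20
    clean: preprocess.CleanParams = field(default_factory=preprocess.CleanParams)
    hairpin: novel.HairpinParams = field(default_factory=novel.HairpinParams)
    match_min_len: int = 18
    match_max_len: int = 23
    outdir: str = "carpmir_run"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if key == "simulation":
                value = SimulationConfig(**value)
            elif key == "clean":
                value = preprocess.CleanParams(**value)
            elif key == "hairpin":
                value = novel.HairpinParams(**value)
            elif not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            setattr(cfg, key, value)
        return cfg


def build_simulated_catalog(
    hairpins: list[PlantedHairpin], n_in_catalog: int
) -> discovery.MatureCatalog:
    """Known-mature catalog for a simulated run.

    The first ``n_in_catalog`` planted matures are entered as carp entries;
    to exercise the conservation classes, every third of them also gets
    teleost entries, every third vertebrate-model entries, and the rest
    stay carp-only.
    """
    entries = []
    for i, h in enumerate(hairpins[:n_in_catalog]):
        name = f"cca-{h.name}"
        entries.append(discovery.CatalogEntry(name, "cca", h.mature_seq))
        extra: tuple[str, ...] = ()
        if i % 3 == 0:
            extra = tuple(sorted(discovery.SPECIES_GROUPS["teleosts"]))
        elif i % 3 == 1:
            extra = tuple(sorted(discovery.SPECIES_GROUPS["vertebrate_models"]))
        for sp in extra:
            entries.append(discovery.CatalogEntry(f"{sp}-{h.name}", sp, h.mature_seq))
    return discovery.MatureCatalog(entries)


@dataclass
class RunReport:
    raw_reads: int = 0
    clean_reads: int = 0
    discards: dict[str, int] = field(default_factory=dict)
    unique_reads: int = 0
    ncrna_annotated_uniques: int = 0
    mapped_uniques: int = 0
    mapped_reads: int = 0
    conserved_candidate_uniques: int = 0
    conserved_candidate_reads: int = 0
    category_count: int = 0
    novel_count: int = 0
    fraction_21_23: float = 0.0

    def check_identities(self) -> None:
        """Count-conservation identities that must hold for any run."""
        assert self.raw_reads == self.clean_reads + sum(self.discards.values())

    def to_text(self) -> str:
        lines = [
            f"raw reads\t{self.raw_reads}",
            f"clean reads\t{self.clean_reads}",
        ]
        lines += [f"discarded ({k})\t{v}" for k, v in self.discards.items()]
        lines += [
            f"unique reads\t{self.unique_reads}",
            f"ncRNA-annotated uniques\t{self.ncrna_annotated_uniques}",
            f"genome-mapped uniques\t{self.mapped_uniques}",
            f"genome-mapped reads\t{self.mapped_reads}",
            f"conserved-candidate uniques\t{self.conserved_candidate_uniques}",
            f"conserved-candidate reads\t{self.conserved_candidate_reads}",
            f"miRNA categories\t{self.category_count}",
            f"novel miRNAs\t{self.novel_count}",
            f"fraction 21-23 nt\t{self.fraction_21_23:.4f}",
        ]
        return "\n".join(lines) + "\n"


@dataclass
class RunResult:
    report: RunReport
    manifest: GroundTruthManifest
    categories: list[discovery.MiRNACategory]
    profiles: list[discovery.ConservationProfile]
    novel_mirnas: list[novel.NovelMiRNA]
    unique_reads: list[preprocess.UniqueRead]
    catalog: discovery.MatureCatalog


def run_pipeline(config: RunConfig, write: bool = True) -> RunResult:
    """Execute the full simulated pipeline described by ``config``."""
    outdir = Path(config.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    report = RunReport()
    try:
        logger.info("stage simulate: genome with %d hairpins", sim.n_hairpins)
        genome, hairpins, _ = generate_genome(sim, config.hairpin)
        ncrna = make_ncrna_reference(sim.seed)
        records, manifest = simulate_reads(sim, hairpins, ncrna)
        catalog = build_simulated_catalog(hairpins, config.n_in_catalog)

        logger.info("stage clean: %d raw reads", len(records))
        raw = ((rid, seq, [ord(c) - 33 for c in qual]) for rid, seq, qual in records)
        inserts, clean_report = preprocess.clean_reads(
            raw, sim.adapter_3p, sim.adapter_5p, config.clean
        )
        report.raw_reads = clean_report.raw_total
        report.clean_reads = clean_report.clean_read_total
        report.discards = dict(clean_report.discards)

        uniques = preprocess.collapse(inserts)
        report.unique_reads = len(uniques)
        dist = preprocess.length_distribution(uniques)
        report.fraction_21_23 = sum(dist.get(ln, (0, 0, 0.0))[2] for ln in (21, 22, 23))

        annotated, remaining = annotate_mod.annotate_ncrna(
            uniques, annotate_mod.NcRNAReference(list(ncrna))
        )
        report.ncrna_annotated_uniques = len(annotated)

        index = annotate_mod.build_index(genome, config.index_k)
        mapping = annotate_mod.map_reads(remaining, index, config.max_loci)
        mapped = [r for r in remaining if r.mapped_loci]
        report.mapped_uniques = len(mapped)
        report.mapped_reads = sum(r.count for r in mapped)

        in_gate = [
            r
            for r in remaining
            if config.match_min_len <= len(r.sequence) <= config.match_max_len
        ]
        matches, unmatched_gate = discovery.match_known(in_gate, catalog)
        matched_seqs = {m[0].sequence for m in matches}
        for r, _e, _c in matches:
            r.annotation = preprocess.Annotation.KNOWN_MIRNA
        report.conserved_candidate_uniques = len(matches)
        report.conserved_candidate_reads = sum(m[0].count for m in matches)

        categories = discovery.cluster_categories(matches)
        report.category_count = len(categories)
        profiles = discovery.conservation_partition(categories, catalog)

        novel_input = [
            r for r in mapped if r.sequence not in matched_seqs
        ]
        novel_mirnas = novel.predict_novel(novel_input, genome, config.hairpin)
        for nm in novel_mirnas:
            for r in novel_input:
                if r.sequence == nm.mature_sequence:
                    r.annotation = preprocess.Annotation.NOVEL_MIRNA
        report.novel_count = len(novel_mirnas)
        report.check_identities()
    except Exception:
        if write:
            (outdir / "FAILED").write_text("pipeline run failed; see log\n")
        raise

    if write:
        _write_outputs(
            outdir, genome, ncrna, records, manifest, catalog, clean_report,
            uniques, dist, mapping, categories, profiles, novel_mirnas, report,
        )
    return RunResult(
        report=report,
        manifest=manifest,
        categories=categories,
        profiles=profiles,
        novel_mirnas=novel_mirnas,
        unique_reads=uniques,
        catalog=catalog,
    )


def _write_outputs(
    outdir, genome, ncrna, records, manifest, catalog, clean_report,
    uniques, dist, mapping, categories, profiles, novel_mirnas, report,
) -> None:
    write_fasta(outdir / "genome.fa", genome.items())
    write_fasta(
        outdir / "ncrna_ref.fa",
        ((f"{rid} class={cls}", rna_to_dna(seq)) for rid, cls, seq in ncrna),
    )
    write_fastq(outdir / "reads.fastq", records)
    manifest.reads.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    with open(outdir / "catalog.tsv", "w") as fh:
        fh.write("name\tspecies\tsequence\n")
        for e in catalog.entries:
            fh.write(f"{e.name}\t{e.species}\t{e.sequence}\n")
    with open(outdir / "cleaning_report.tsv", "w") as fh:
        fh.write("reason\tcount\n")
        for k, v in clean_report.discards.items():
            fh.write(f"{k}\t{v}\n")
        fh.write(f"clean_total\t{clean_report.clean_read_total}\n")
    write_fasta(
        outdir / "collapsed.fa",
        (
            (f"u{i + 1} count={r.count}", rna_to_dna(r.sequence))
            for i, r in enumerate(uniques)
        ),
    )
    with open(outdir / "length_distribution.tsv", "w") as fh:
        fh.write("length\tunique_count\tread_count\tread_fraction\n")
        for ln, (u, c, f) in dist.items():
            fh.write(f"{ln}\t{u}\t{c}\t{f:.6f}\n")
    with open(outdir / "mapping.tsv", "w") as fh:
        fh.write("sequence\tcontig\tstart\tend\tstrand\n")
        for seq in sorted(mapping.loci):
            for contig, start, strand in mapping.loci[seq]:
                fh.write(f"{seq}\t{contig}\t{start}\t{start + len(seq)}\t{strand}\n")
    with open(outdir / "categories.tsv", "w") as fh:
        fh.write("name\trepresentative\tmember_count\tread_total\n")
        for c in categories:
            fh.write(
                f"{c.assigned_name}\t{c.representative.sequence}\t"
                f"{len(c.members)}\t{c.read_total}\n"
            )
    with open(outdir / "conservation.tsv", "w") as fh:
        fh.write("miRNA\tpresent_in\tclass\n")
        for p in profiles:
            fh.write(
                f"{p.mirna_name}\t{','.join(sorted(p.present_in))}\t{p.conservation_class}\n"
            )
    with open(outdir / "novel.tsv", "w") as fh:
        fh.write("miRNA\tSequence\tFrequency\n")
        for nm in novel_mirnas:
            fh.write(f"{nm.name}\t{nm.mature_sequence}\t{nm.count}\n")
    write_fasta(
        outdir / "novel_precursors.fa",
        ((nm.name, rna_to_dna(nm.precursor_sequence)) for nm in novel_mirnas),
    )
    with open(outdir / "novel_precursors.dot", "w") as fh:
        for nm in novel_mirnas:
            fh.write(f">{nm.name}\n{nm.precursor_sequence}\n{nm.structure}\n")
    with open(outdir / "novel_precursors.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for nm in novel_mirnas:
            contig, start, end, strand = nm.precursor_locus
            fh.write(
                f"{contig}\tcarpmir\tmiRNA_primary_transcript\t{start + 1}\t{end}\t"
                f".\t{strand}\t.\tID={nm.name};energy={nm.energy:.2f}\n"
            )
    (outdir / "report.txt").write_text(report.to_text())
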