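"""Synthetic small-RNA-seq data with a ground-truth manifest.

Generates a toy genome with planted pre-miRNA hairpins, a raw FASTQ read
set whose statistical shape matches a muscle small-RNA library (mature
reads 18-30 nt dominated by 21-23 nt, isomiR end variants, ncRNA
contaminants, adapter/poly(A)/short-read junk), an ncRNA reference, and
qPCR Ct tables with known fold changes.  Every emitted read carries a
manifest label, and every planted precursor is verified against the
pre-miRNA criteria before planting, so downstream recovery failures are
pipeline bugs rather than generator artefacts.

Precursors are built constructively: a 22-30 nt arm, its reverse
complement with 0-3 mismatches, and a 6-10 nt loop, which guarantees a
foldable stem-loop without rejection sampling of random sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_utils import dna_to_rna, revcomp_dna, revcomp_rna, rna_to_dna
from .novel import HairpinParams, evaluate_precursor
from .preprocess import CleanParams, classify_read

#: Illumina TruSeq small-RNA adapters (the library chemistry of the assay is
#: not part of the model; these are configurable defaults).
DEFAULT_ADAPTER_3P = "TGGAATTCTCGGGTGCCAAGG"
DEFAULT_ADAPTER_5P = "GTTCAGAGTTCTACAGTCCGACGATC"

#: Default isomiR 3'-end offset profile for 22 nt matures.  Mass on offsets
#: -1/0/+1 (insert lengths 21-23) is 0.9349, the 21-23 nt read fraction the
#: generator emulates.
DEFAULT_ISOMIR_PROFILE = {
    -4: 0.0045,
    -3: 0.008,
    -2: 0.02,
    -1: 0.10,
    0: 0.7349,
    1: 0.10,
    2: 0.02,
    3: 0.008,
    4: 0.003,
    5: 0.0016,
}

JUNK_CLASSES = (
    "low_quality",
    "adapter5_pollution",
    "no_3p_adapter",
    "adapter_dimer",
    "polyA",
    "short_insert",
)

#: how each junk class is discarded by the cleaning cascade
JUNK_TO_DISCARD_REASON = {
    "low_quality": "low_quality",
    "adapter5_pollution": "adapter5_pollution",
    "no_3p_adapter": "no_3p_adapter",
    "adapter_dimer": "no_insert",
    "polyA": "polyA",
    "short_insert": "too_short",
}

_RNA = np.array(list("ACGU"))


@dataclass
class SimulationConfig:
    n_hairpins: int = 20
    genome_length: int = 50_000
    contaminant_fraction: float = 0.15
    junk_fraction: float = 0.12
    isomir_profile: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_ISOMIR_PROFILE)
    )
    total_reads: int = 100_000
    adapter_3p: str = DEFAULT_ADAPTER_3P
    adapter_5p: str = DEFAULT_ADAPTER_5P
    read_length: int = 42
    mature_length: int = 22
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.contaminant_fraction <= 1 or not 0 <= self.junk_fraction <= 1:
            raise ValueError("fractions must be in [0, 1]")
        if self.mirna_fraction < 0:
            raise ValueError("contaminant and junk fractions exceed 1")
        s = sum(self.isomir_profile.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"isomir_profile probabilities sum to {s}, not 1")
        for off in self.isomir_profile:
            if not -5 <= off <= 5:
                raise ValueError(f"isomiR offset {off} outside [-5, 5]")
            if not 18 <= self.mature_length + off <= 30:
                raise ValueError(
                    f"offset {off} takes inserts outside the 18-30 nt envelope"
                )

    @property
    def mirna_fraction(self) -> float:
        return 1.0 - self.contaminant_fraction - self.junk_fraction


@dataclass
class PlantedHairpin:
    name: str
    precursor_seq: str  # RNA
    genome_locus: tuple[str, int, int, str]  # 0-based half-open
    mature_seq: str  # RNA
    mature_offset: int  # start of mature within precursor
    arm: str  # "5p" | "3p"
    expression_weight: float


@dataclass
class GroundTruthManifest:
    reads: pd.DataFrame  # read_id, origin, origin_name, insert (RNA)
    hairpins: list[PlantedHairpin] = field(default_factory=list)
    true_folds: dict[str, float] = field(default_factory=dict)

    def origin_counts(self) -> pd.Series:
        return self.reads["origin"].value_counts()


def _random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_RNA, size=n))


_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}


def _build_precursor(
    rng: np.random.Generator, cfg: SimulationConfig, hp: HairpinParams
) -> tuple[str, int, int]:
    """One verified precursor; returns (RNA seq, mature_start, mature_end)."""
    clean = CleanParams()
    mlen = cfg.mature_length
    for _attempt in range(300):
        arm_len = int(rng.integers(mlen, 31))
        loop_len = int(rng.integers(6, 11))
        arm5 = _random_rna(rng, arm_len)
        arm3 = list(revcomp_rna(arm5))
        for k in rng.choice(arm_len, size=int(rng.integers(0, 4)), replace=False):
            choices = [b for b in "ACGU" if b != arm3[k] and b != _COMPLEMENT[arm3[k]]]
            arm3[k] = choices[int(rng.integers(0, len(choices)))]
        prec = arm5 + _random_rna(rng, loop_len) + "".join(arm3)
        on_5p = bool(rng.integers(0, 2))
        if on_5p:
            ms = int(rng.integers(0, arm_len - mlen + 1))
        else:
            lo = arm_len + loop_len
            hi = min(len(prec) - mlen - 5, len(prec) - mlen)
            if hi < lo:
                continue
            ms = int(rng.integers(lo, hi + 1))
        me = ms + mlen
        if not _variants_clean(prec, ms, me, cfg, clean):
            continue
        cand = evaluate_precursor(prec, ms, me, count=hp.min_count, params=hp)
        if cand.verdict:
            return prec, ms, me
    raise RuntimeError("failed to construct a passing precursor in 300 attempts")


def _variants_clean(
    prec: str, ms: int, me: int, cfg: SimulationConfig, clean: CleanParams
) -> bool:
    """Every isomiR end variant must survive the cleaning cascade intact."""
    pad = ("CGTACGTGCA" * 10)
    for off in cfg.isomir_profile:
        if me + off > len(prec) or me + off - ms < clean.min_insert_len:
            return False
        variant = rna_to_dna(prec[ms : me + off])
        read = (variant + cfg.adapter_3p + pad)[: cfg.read_length]
        insert, reason = classify_read(
            read, [40] * len(read), cfg.adapter_3p, cfg.adapter_5p, clean
        )
        if reason is not None or insert != variant:
            return False
    return True


def generate_genome(
    config: SimulationConfig, hairpin_params: Optional[HairpinParams] = None
) -> tuple[dict[str, str], list[PlantedHairpin], GroundTruthManifest]:
    """Toy genome (DNA) with non-overlapping planted hairpins, half per strand.

    The background is i.i.d. uniform A/C/G/T; precursors overwrite the
    background at their loci (reverse-complemented on the minus strand).
    Fails outright, with no partial output, if the genome cannot hold the
    requested hairpins.
    """
    if config.genome_length < config.n_hairpins * 200:
        raise ValueError(
            f"genome_length {config.genome_length} cannot hold "
            f"{config.n_hairpins} hairpins (need >= n_hairpins * 200)"
        )
    hp = hairpin_params or HairpinParams()
    rng = np.random.default_rng([config.seed, 0])
    contig = "contig_1"
    genome_arr = rng.choice(np.array(list("ACGT")), size=config.genome_length)

    hairpins: list[PlantedHairpin] = []
    if config.n_hairpins > 0:
        margin = 150
        slot = (config.genome_length - 2 * margin) // config.n_hairpins
        if slot < 100 + 300:
            raise ValueError("genome too short for non-interacting hairpin loci")
        used_seeds: set[str] = set()
        for i in range(config.n_hairpins):
            while True:
                prec, ms, me = _build_precursor(rng, config, hp)
                seed7 = prec[ms + 1 : ms + 8]
                if seed7 not in used_seeds:
                    used_seeds.add(seed7)
                    break
            plen = len(prec)
            lo = margin + i * slot
            start = lo + int(rng.integers(0, slot - plen - 300))
            end = start + plen
            strand = "+" if i % 2 == 0 else "-"
            dna = rna_to_dna(prec)
            planted = dna if strand == "+" else revcomp_dna(dna)
            genome_arr[start:end] = list(planted)
            arm = "5p" if me - 1 < plen // 2 else "3p"
            weight = float(rng.lognormal(mean=0.0, sigma=1.0))
            hairpins.append(
                PlantedHairpin(
                    name=f"sim-mir-{i + 1}",
                    precursor_seq=prec,
                    genome_locus=(contig, start, end, strand),
                    mature_seq=prec[ms:me],
                    mature_offset=ms,
                    arm=arm,
                    expression_weight=weight,
                )
            )
    genome = {contig: "".join(genome_arr)}
    manifest = GroundTruthManifest(reads=pd.DataFrame(), hairpins=hairpins)
    return genome, hairpins, manifest


#: (class, count, length) recipe for the default ncRNA reference
_NCRNA_RECIPE = (
    ("rRNA", 3, (500, 1500)),
    ("tRNA", 5, (72, 90)),
    ("snRNA", 4, (100, 190)),
    ("snoRNA", 4, (70, 130)),
)


def make_ncrna_reference(seed: int = 0) -> list[tuple[str, str, str]]:
    """Synthetic ncRNA reference records: (id, class, RNA sequence)."""
    rng = np.random.default_rng([seed, 7])
    out = []
    for cls, n, (lo, hi) in _NCRNA_RECIPE:
        for k in range(n):
            length = int(rng.integers(lo, hi + 1))
            out.append((f"{cls}_{k + 1}", cls, _random_rna(rng, length)))
    return out


def _emit_read(
    insert_dna: str, cfg: SimulationConfig, rng: np.random.Generator, quality: str = "I"
) -> str:
    tail_needed = cfg.read_length - len(insert_dna) - len(cfg.adapter_3p)
    pad = "".join(rng.choice(np.array(list("ACGT")), size=max(tail_needed, 0) + 4))
    return (insert_dna + cfg.adapter_3p + pad)[: cfg.read_length]


def simulate_reads(
    config: SimulationConfig,
    hairpins: Sequence[PlantedHairpin],
    ncrna_ref: Sequence[tuple[str, str, str]],
) -> tuple[list[tuple[str, str, str]], GroundTruthManifest]:
    """Simulate a raw FASTQ read set with per-read ground-truth labels.

    Returns (records, manifest): records are (id, DNA sequence, quality)
    triples; the manifest has exactly one row per emitted read.  Junk reads
    are constructed so that the cleaning cascade assigns each one its
    intended discard reason, and miRNA/contaminant reads so that cleaning
    recovers their insert exactly — verified read by read at generation
    time, which makes manifest counts an exact oracle for the cleaner.
    """
    if config.mirna_fraction > 0 and not hairpins:
        raise ValueError("hairpins required when the miRNA fraction is positive")
    if config.contaminant_fraction > 0 and not ncrna_ref:
        raise ValueError("contaminant_fraction > 0 requires a non-empty ncRNA reference")
    rng = np.random.default_rng([config.seed, 1])
    clean = CleanParams()

    weights = np.array([h.expression_weight for h in hairpins], dtype=float)
    if weights.size:
        weights = weights / weights.sum() * config.mirna_fraction
    probs = np.concatenate(
        [
            weights,
            [config.contaminant_fraction],
            np.full(len(JUNK_CLASSES), config.junk_fraction / len(JUNK_CLASSES)),
        ]
    )
    probs = probs / probs.sum()
    choices = rng.choice(len(probs), size=config.total_reads, p=probs)

    offsets = np.array(sorted(config.isomir_profile))
    offset_probs = np.array([config.isomir_profile[o] for o in sorted(config.isomir_profile)])

    records: list[tuple[str, str, str]] = []
    rows: list[tuple[str, str, str, str]] = []
    n_h = len(hairpins)
    for i, c in enumerate(choices):
        rid = f"r{i + 1:07d}"
        if c < n_h:
            h = hairpins[c]
            off = int(rng.choice(offsets, p=offset_probs))
            ms, me = h.mature_offset, h.mature_offset + len(h.mature_seq)
            insert = rna_to_dna(h.precursor_seq[ms : me + off])
            seq, qual = _verified_read(insert, config, rng, clean)
            records.append((rid, seq, qual))
            rows.append((rid, "mirna", h.name, dna_to_rna(insert)))
        elif c == n_h:
            seq, qual, insert, cls = _contaminant_read(config, rng, ncrna_ref, clean)
            records.append((rid, seq, qual))
            rows.append((rid, "ncrna", cls, dna_to_rna(insert)))
        else:
            cls = JUNK_CLASSES[c - n_h - 1]
            seq, qual = _junk_read(cls, config, rng, clean)
            records.append((rid, seq, qual))
            rows.append((rid, "junk", cls, ""))
    reads_df = pd.DataFrame(rows, columns=["read_id", "origin", "origin_name", "insert"])
    manifest = GroundTruthManifest(reads=reads_df, hairpins=list(hairpins))
    return records, manifest


def _verified_read(
    insert_dna: str, cfg: SimulationConfig, rng: np.random.Generator, clean: CleanParams
) -> tuple[str, str]:
    """Insert + adapter + pad, re-padded until the cleaner recovers the insert."""
    for _ in range(20):
        seq = _emit_read(insert_dna, cfg, rng)
        got, reason = classify_read(
            seq, [40] * len(seq), cfg.adapter_3p, cfg.adapter_5p, clean
        )
        if reason is None and got == insert_dna:
            return seq, "I" * len(seq)
    raise RuntimeError(f"could not emit a clean read for insert {insert_dna}")


def _contaminant_read(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    ncrna_ref: Sequence[tuple[str, str, str]],
    clean: CleanParams,
) -> tuple[str, str, str, str]:
    for _ in range(100):
        _rid, cls, seq_rna = ncrna_ref[int(rng.integers(0, len(ncrna_ref)))]
        length = int(rng.integers(18, 31))
        if len(seq_rna) < length:
            continue
        start = int(rng.integers(0, len(seq_rna) - length + 1))
        insert = rna_to_dna(seq_rna[start : start + length])
        read = _emit_read(insert, cfg, rng)
        got, reason = classify_read(
            read, [40] * len(read), cfg.adapter_3p, cfg.adapter_5p, clean
        )
        if reason is None and got == insert:
            return read, "I" * len(read), insert, cls
    raise RuntimeError("could not draw a clean contaminant read")


def _junk_read(
    cls: str, cfg: SimulationConfig, rng: np.random.Generator, clean: CleanParams
) -> tuple[str, str]:
    expect = JUNK_TO_DISCARD_REASON[cls]
    for _ in range(100):
        qual_char = "I"
        if cls == "low_quality":
            seq = _emit_read("".join(rng.choice(np.array(list("ACGT")), size=22)), cfg, rng)
            qual_char = "#"
        elif cls == "adapter5_pollution":
            tail = "".join(rng.choice(np.array(list("ACGT")), size=cfg.read_length))
            seq = (cfg.adapter_5p + tail)[: cfg.read_length]
        elif cls == "no_3p_adapter":
            seq = "".join(rng.choice(np.array(list("ACGT")), size=cfg.read_length))
        elif cls == "adapter_dimer":
            seq = _emit_read("", cfg, rng)
        elif cls == "polyA":
            seq = _emit_read("A" * int(rng.integers(18, 26)), cfg, rng)
        elif cls == "short_insert":
            seq = _emit_read(
                "".join(rng.choice(np.array(list("ACGT")), size=int(rng.integers(10, 18)))),
                cfg,
                rng,
            )
        else:  # pragma: no cover
            raise ValueError(cls)
        phred = 2 if qual_char == "#" else 40
        _got, reason = classify_read(
            seq, [phred] * len(seq), cfg.adapter_3p, cfg.adapter_5p, clean
        )
        if reason == expect:
            return seq, qual_char * len(seq)
    raise RuntimeError(f"could not construct junk read of class {cls}")


def simulate_ct_table(
    true_folds: dict[str, float],
    n_replicates: int = 5,
    noise_sd: float = 0.1,
    seed: int = 0,
    mirna: str = "miR-1",
    calibrator: str = "30dph",
    ct_target_base: float = 25.0,
    ct_reference_base: float = 18.0,
) -> pd.DataFrame:
    """Replicate Ct measurements consistent with known fold changes.

    Ct(target) = base - log2(fold) + N(0, sd); Ct(reference) = base + N(0, sd).
    The calibrator group must be present with fold 1.
    """
    if calibrator not in true_folds:
        raise ValueError(f"calibrator group {calibrator!r} missing from true_folds")
    if not math.isclose(true_folds[calibrator], 1.0):
        raise ValueError("calibrator group must have fold 1")
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates")
    for g, f in true_folds.items():
        if f <= 0:
            raise ValueError(f"non-positive fold {f} for group {g!r}")
    rng = np.random.default_rng([seed, 2])
    rows = []
    for group, fold in true_folds.items():
        for rep in range(1, n_replicates + 1):
            ct_t = ct_target_base - math.log2(fold) + rng.normal(0.0, noise_sd)
            ct_r = ct_reference_base + rng.normal(0.0, noise_sd)
            rows.append((mirna, group, rep, ct_t, ct_r))
    return pd.DataFrame(
        rows, columns=["mirna", "group", "replicate", "ct_target", "ct_reference"]
    )
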