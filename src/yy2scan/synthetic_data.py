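"""Seeded synthetic-data generator with truth tables.

Produces every input the pipeline consumes — genome FASTA, feature
catalog, IP/control aligned reads, Ct tables — with known ground truth
so that recovery can be tested end to end.

Layout strategy: each requested peak owns a "cassette", a span of
genome wide enough (220 kb for class-constrained peaks) that features
placed for one peak cannot perturb the location class of another.
Features are placed inside the cassette in the geometry that guarantees
the intended class:

* ``TSS`` — gene TSS ~1 kb beyond a peak edge;
* ``O``   — gene spanning the peak, TSS 10 kb away (outside the 2.5 kb
  promoter radius);
* ``DU``  — gene 10 kb away on the peak's 3'-of-peak side so the peak
  lies 5' of its TSS (4 kb when a 5 kb lncRNA tier is also requested);
* ``DD``  — gene 10 kb away with its transcribed end facing the peak;
* ``I``   — an empty cassette (no feature within 100 kb);
* ``any`` — a small unconstrained cassette, for read-recovery tests
  that do not exercise annotation.

Class geometry is mirrored at random between '+' and '-' orientations.
Extra background genes, lncRNAs and the repeat family live in a
dedicated zone > 100 kb beyond the last peak.

All randomness flows from one ``numpy`` Generator seeded by the config;
identical configs produce byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from yy2scan.io_genomics import (
    AlignedRead,
    FeatureCatalog,
    FeatureRecord,
    GenomicInterval,
    write_alignments_bed,
    write_fasta,
    write_features_tsv,
)

CASSETTE_SIZE = 220_000
PEAK_ANCHOR = 110_000  # peak start offset within a class cassette
DEFAULT_MOTIF = "ANAGAAGTGG"

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

PeakClass = Literal["TSS", "O", "DU", "DD", "I", "any"]
LncIntent = Literal["within_5kb", "within_100kb", "other"]


class PlacementError(RuntimeError):
    """A peak spec or feature set cannot be placed as requested."""


@dataclass
class PeakSpec:
    """One planted peak: intended location class, enrichment fold, width."""

    location_class: PeakClass = "any"
    fold: float = 8.0
    width: int = 300
    lnc: LncIntent = "other"

    def __post_init__(self):
        if self.fold < 0:
            raise ValueError("fold must be >= 0")
        if self.location_class == "I" and self.lnc != "other":
            raise PlacementError(
                "intergenic peaks cannot have a lncRNA within 100 kb (spec contradiction)"
            )


@dataclass
class RepeatFamilySpec:
    n_copies: int = 0
    copy_length: int = 500
    divergence: float = 0.02

    def __post_init__(self):
        if not (0 <= self.divergence < 1):
            raise ValueError("divergence must be in [0, 1)")


@dataclass
class CtDesign:
    """Expression targets with their true fold changes, plus noise settings."""

    true_folds: dict[str, float] = field(default_factory=dict)
    reference_gene: str = "Gapdh"
    ct_sd: float = 0.1
    replicates: int = 3
    base_ct: float = 24.0
    sample: str = "knockdown"
    calibrator: str = "control"


@dataclass
class SimulationConfig:
    seed: int
    chrom_lengths: dict[str, int] | None = None
    n_genes: int = 0
    n_lncrnas: int = 0
    repeat_family: RepeatFamilySpec = field(default_factory=RepeatFamilySpec)
    peaks: list[PeakSpec] = field(default_factory=list)
    motif: str = DEFAULT_MOTIF
    read_length: int = 50
    control_depth: float = 20.0  # expected control reads overlapping one window
    window_width: int = 100
    any_cassette_size: int = 6_000
    gene_length: int = 5_000
    ct_design: CtDesign = field(default_factory=CtDesign)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for c in self.motif.upper():
            if c not in _IUPAC:
                raise ValueError(f"invalid IUPAC code {c!r} in motif")
        if self.read_length > self.window_width:
            raise ValueError("read length must not exceed the window width")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "peaks" in raw:
            raw["peaks"] = [PeakSpec(**p) for p in raw["peaks"]]
        if "repeat_family" in raw:
            raw["repeat_family"] = RepeatFamilySpec(**raw["repeat_family"])
        if "ct_design" in raw:
            raw["ct_design"] = CtDesign(**raw["ct_design"])
        return cls(**raw)


@dataclass
class PeakTruth:
    peak_id: str
    interval: GenomicInterval
    fold: float
    location_class: PeakClass
    lnc_tier: str
    motif_offset: int | None = None
    motif_instance: str | None = None


@dataclass
class TruthTable:
    peaks: list[PeakTruth] = field(default_factory=list)
    repeat_copies: list[GenomicInterval] = field(default_factory=list)
    n_repeat_origin: dict[str, int] = field(default_factory=dict)
    true_expression_folds: dict[str, float] = field(default_factory=dict)
    # internal layout: planned anchor interval per peak spec index
    anchors: list[GenomicInterval] = field(default_factory=list)


@dataclass
class SyntheticGenome:
    sequences: dict[str, str]
    catalog: FeatureCatalog
    truth: TruthTable

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _cassette_size(spec: PeakSpec, any_size: int) -> int:
    return CASSETTE_SIZE if spec.location_class != "any" else max(any_size, 2 * spec.width + 200)


def _place_class_features(
    spec: PeakSpec,
    peak: GenomicInterval,
    gene_length: int,
    orientation: str,
    index: int,
    catalog: FeatureCatalog,
) -> None:
    """Place cassette features guaranteeing `spec.location_class` for `peak`."""
    chrom = peak.chrom
    cls = spec.location_class
    if cls in ("I", "any"):
        pass
    else:
        biotype = "lncRNA" if spec.lnc == "within_5kb" else "protein_coding"
        # gap between peak and the class gene; tightened when the gene itself
        # must double as the <= 5 kb lncRNA
        gap = 4_000 if (spec.lnc == "within_5kb" and cls in ("DU", "DD")) else 10_000
        if cls == "TSS":
            gap = 1_000
        if cls == "TSS":
            if orientation == "+":
                iv = GenomicInterval(chrom, peak.end + gap, peak.end + gap + gene_length, "+")
            else:
                iv = GenomicInterval(chrom, peak.start - gap - gene_length, peak.start - gap, "-")
        elif cls == "O":
            iv = GenomicInterval(chrom, peak.start - gap, peak.end + gap, orientation)
        elif cls == "DU":
            # peak must sit 5' of the gene's TSS
            if orientation == "+":
                iv = GenomicInterval(chrom, peak.end + gap, peak.end + gap + gene_length, "+")
            else:
                iv = GenomicInterval(chrom, peak.start - gap - gene_length, peak.start - gap, "-")
        elif cls == "DD":
            # peak must sit 3' of the gene's transcribed end
            if orientation == "+":
                iv = GenomicInterval(chrom, peak.start - gap - gene_length, peak.start - gap, "+")
            else:
                iv = GenomicInterval(chrom, peak.end + gap, peak.end + gap + gene_length, "-")
        else:
            raise PlacementError(f"unknown location class {cls!r}")
        fid = f"pk{index}_gene"
        catalog.add(FeatureRecord(fid, fid, biotype, iv, iv.strand))
        if cls == "TSS" and spec.lnc == "within_5kb" and biotype != "lncRNA":
            pass  # already lncRNA by construction above
    if spec.lnc == "within_100kb":
        # a lncRNA 50 kb away on the side that cannot disturb the class
        if cls in ("TSS", "O"):
            side_left = orientation == "+"  # opposite side of the class gene
        elif cls == "DU":
            side_left = orientation == "+"
        elif cls == "DD":
            side_left = orientation == "-"
        else:
            raise PlacementError("lnc within_100kb is incompatible with class I")
        if side_left:
            iv = GenomicInterval(peak.chrom, peak.start - 50_000 - 2_000, peak.start - 50_000, "+")
        else:
            iv = GenomicInterval(peak.chrom, peak.end + 50_000, peak.end + 50_000 + 2_000, "+")
        fid = f"pk{index}_lnc"
        catalog.add(FeatureRecord(fid, fid, "lncRNA", iv, "+"))


def generate_genome(config: SimulationConfig) -> SyntheticGenome:
    """Build the genome sequence, feature catalog and truth-table stub.

    Cassette anchors for every peak spec are planned here (features must
    surround them); the peaks themselves are written by
    :func:`plant_peaks_and_motif`.
    """
    rng = np.random.default_rng(config.seed)
    sizes = [_cassette_size(p, config.any_cassette_size) for p in config.peaks]

    # background zone: extra genes + lncRNAs + repeat copies, 1 kb spacing
    n_extra = config.n_genes + config.n_lncrnas
    bg_len = n_extra * (config.gene_length + 1_000) + config.repeat_family.n_copies * (
        config.repeat_family.copy_length + 1_000
    )
    needed = sum(sizes) + bg_len + 10_000

    if config.chrom_lengths is None:
        chrom_lengths = {"chr1": max(needed, 20_000)}
    else:
        chrom_lengths = dict(config.chrom_lengths)
        if sum(chrom_lengths.values()) < needed:
            raise PlacementError(
                f"configured chromosomes ({sum(chrom_lengths.values())} bp) cannot hold "
                f"{len(config.peaks)} cassettes + background ({needed} bp)"
            )

    sequences = {c: _random_sequence(rng, L) for c, L in chrom_lengths.items()}
    catalog = FeatureCatalog()
    truth = TruthTable()

    # lay cassettes greedily across chromosomes in order
    chroms = list(chrom_lengths)
    ci, cursor = 0, 0
    anchors: list[GenomicInterval] = []
    for i, (spec, size) in enumerate(zip(config.peaks, sizes)):
        while ci < len(chroms) and cursor + size > chrom_lengths[chroms[ci]]:
            ci, cursor = ci + 1, 0
        if ci >= len(chroms):
            raise PlacementError(f"peak spec {i} does not fit on any chromosome")
        chrom = chroms[ci]
        offset = PEAK_ANCHOR if spec.location_class != "any" else (size - spec.width) // 2
        peak = GenomicInterval(chrom, cursor + offset, cursor + offset + spec.width)
        anchors.append(peak)
        orientation = "+" if rng.random() < 0.5 else "-"
        _place_class_features(spec, peak, config.gene_length, orientation, i, catalog)
        cursor += size
    truth.anchors = anchors

    # background zone on the last chromosome in use (or the first when no peaks)
    if n_extra or config.repeat_family.n_copies:
        if ci >= len(chroms):
            ci = len(chroms) - 1
        chrom = chroms[ci]
        pos = cursor
        for j in range(config.n_genes + config.n_lncrnas):
            biotype = "protein_coding" if j < config.n_genes else "lncRNA"
            end = pos + config.gene_length
            if end > chrom_lengths[chrom]:
                raise PlacementError("background genes do not fit; enlarge the genome")
            strand = "+" if rng.random() < 0.5 else "-"
            fid = f"bg_{biotype}_{j}"
            catalog.add(FeatureRecord(fid, fid, biotype, GenomicInterval(chrom, pos, end, strand), strand))
            pos = end + 1_000
        rf = config.repeat_family
        if rf.n_copies:
            master = _random_sequence(rng, rf.copy_length)
            seq = list(sequences[chrom])
            for _ in range(rf.n_copies):
                end = pos + rf.copy_length
                if end > chrom_lengths[chrom]:
                    raise PlacementError("repeat copies do not fit; enlarge the genome")
                copy = list(master)
                n_sub = rng.binomial(rf.copy_length, rf.divergence)
                for site in rng.choice(rf.copy_length, size=n_sub, replace=False):
                    alt = "ACGT".replace(copy[site], "")
                    copy[site] = alt[rng.integers(0, 3)]
                seq[pos:end] = copy
                truth.repeat_copies.append(GenomicInterval(chrom, pos, end))
                pos = end + 1_000
            sequences[chrom] = "".join(seq)

    return SyntheticGenome(sequences, catalog, truth)


def _instantiate_iupac(pattern: str, rng: np.random.Generator) -> str:
    return "".join(
        c if len(_IUPAC[c]) == 1 else _IUPAC[c][rng.integers(0, len(_IUPAC[c]))]
        for c in pattern.upper()
    )


def plant_peaks_and_motif(genome: SyntheticGenome, config: SimulationConfig) -> SyntheticGenome:
    """Record peak truth at the planned anchors and write one motif
    instantiation at each peak center.  Validates class geometry."""
    rng = np.random.default_rng(config.seed + 1)
    truth = genome.truth
    if len(truth.anchors) != len(config.peaks):
        raise PlacementError("genome was generated for a different peak spec list")
    for i, (spec, peak) in enumerate(zip(config.peaks, truth.anchors)):
        _validate_class(spec, peak, genome.catalog, i)
        word = _instantiate_iupac(config.motif, rng)
        center = peak.start + (len(peak) - len(word)) // 2
        seq = genome.sequences[peak.chrom]
        genome.sequences[peak.chrom] = seq[:center] + word + seq[center + len(word):]
        tier = {"within_5kb": "lnc_within_5kb", "within_100kb": "lnc_within_100kb", "other": "other"}[spec.lnc]
        truth.peaks.append(
            PeakTruth(f"peak{i}", peak, spec.fold, spec.location_class, tier, center, word)
        )
    return genome


def _validate_class(spec: PeakSpec, peak: GenomicInterval, catalog: FeatureCatalog, i: int) -> None:
    feats = catalog.on_chrom(peak.chrom)

    def gap(f):
        if peak.overlaps(f.interval):
            return 0
        return max(peak.start, f.interval.start) - min(peak.end, f.interval.end)

    near = [f for f in feats if gap(f) <= 100_000]
    cls = spec.location_class
    if cls == "I" and near:
        raise PlacementError(f"peak spec {i}: class I but features within 100 kb")
    if cls == "TSS" and not any(
        min(abs(peak.start - f.tss), abs(peak.end - 1 - f.tss)) <= 2_500
        or peak.start <= f.tss < peak.end
        for f in near
    ):
        raise PlacementError(f"peak spec {i}: class TSS needs a TSS within 2500 bp")
    if cls == "O" and not any(peak.overlaps(f.interval) for f in near):
        raise PlacementError(f"peak spec {i}: class O needs an overlapping feature")
    if cls in ("DU", "DD") and not near:
        raise PlacementError(f"peak spec {i}: class {cls} needs a feature within 100 kb")


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def _poisson_uniform_reads(
    rng: np.random.Generator, chrom: str, length: int, rate_per_bp: float, read_length: int
) -> list[int]:
    hi = length - read_length
    if hi <= 0:
        return []
    n = rng.poisson(rate_per_bp * hi)
    return sorted(int(s) for s in rng.integers(0, hi + 1, size=n))


def simulate_reads(
    genome: SyntheticGenome, truth: TruthTable, config: SimulationConfig
) -> tuple[list[AlignedRead], list[AlignedRead]]:
    """Generate IP and control read sets from the planted truth.

    Control reads fall Poisson-uniform at a per-bp rate that yields the
    configured expected count per window; IP reads add
    (fold - 1)-proportional extra reads inside each planted peak.  Reads
    that originate inside a repeat copy become class ``repeated`` and
    are re-placed at a uniformly chosen copy of the family.
    """
    rng = np.random.default_rng(config.seed + 2)
    rl = config.read_length
    # a window of width W is overlapped by reads starting in a (W + rl - 1) span
    rate = config.control_depth / (config.window_width + rl - 1)

    def emit(dataset: str, extra_peaks: bool) -> list[AlignedRead]:
        reads: list[AlignedRead] = []
        n_rep = 0
        for chrom, L in genome.chrom_lengths.items():
            starts = _poisson_uniform_reads(rng, chrom, L, rate, rl)
            if extra_peaks:
                for pk in truth.peaks:
                    if pk.interval.chrom != chrom or pk.fold <= 1:
                        continue
                    lo = max(0, pk.interval.start - rl + 1)
                    hi = min(L - rl, pk.interval.end - 1)
                    if hi <= lo:
                        continue
                    n = rng.poisson((pk.fold - 1) * rate * (hi - lo))
                    starts.extend(int(s) for s in rng.integers(lo, hi + 1, size=n))
            copies = [c for c in truth.repeat_copies if c.chrom == chrom]
            for s in starts:
                iv = GenomicInterval(chrom, s, s + rl)
                origin = next((c for c in copies if iv.overlaps(c)), None)
                if origin is not None and truth.repeat_copies:
                    n_rep += 1
                    target = truth.repeat_copies[rng.integers(0, len(truth.repeat_copies))]
                    new_start = min(max(0, target.start + (s - origin.start)),
                                    genome.chrom_lengths[target.chrom] - rl)
                    reads.append(AlignedRead(
                        GenomicInterval(target.chrom, new_start, new_start + rl),
                        "repeated", dataset))
                else:
                    reads.append(AlignedRead(iv, "unique", dataset))
        truth.n_repeat_origin[dataset] = n_rep
        return reads

    control = emit("control", extra_peaks=False)
    ip = emit("ip", extra_peaks=True)
    return ip, control


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------

def simulate_ct_table(config: SimulationConfig):
    """Ct table for the configured expression design, plus the truth folds.

    Ct = base - log2(true relative quantity) + Gaussian noise; the
    reference gene has true fold 1 by construction.
    """
    import pandas as pd
    from yy2scan.qpcr_quant import CtTable

    rng = np.random.default_rng(config.seed + 3)
    d = config.ct_design
    rows = []
    targets = dict(d.true_folds)
    targets.setdefault(d.reference_gene, 1.0)
    for target, fold in targets.items():
        if fold <= 0:
            raise ValueError(f"true fold for {target} must be positive")
        for sample, quantity in ((d.calibrator, 1.0), (d.sample, fold)):
            ct_mean = d.base_ct - math.log2(quantity)
            for _ in range(d.replicates):
                noise = float(rng.normal(0.0, d.ct_sd)) if d.ct_sd > 0 else 0.0
                rows.append({"sample": sample, "target": target, "role": "expression",
                             "ct": ct_mean + noise})
    table = CtTable(pd.DataFrame(rows))
    return table, dict(targets)


# ---------------------------------------------------------------------------
# Whole-dataset driver
# ---------------------------------------------------------------------------

def generate_dataset(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Generate and write the full synthetic dataset; returns output paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(config)
    plant_peaks_and_motif(genome, config)
    ip, control = simulate_reads(genome, genome.truth, config)
    ct, _folds = simulate_ct_table(config)

    paths = {
        "genome": outdir / "genome.fa",
        "features": outdir / "features.tsv",
        "ip": outdir / "ip.bed",
        "control": outdir / "control.bed",
        "truth": outdir / "truth.tsv",
        "ct": outdir / "ct.csv",
    }
    write_fasta(genome.sequences, paths["genome"])
    write_features_tsv(genome.catalog, paths["features"])
    write_alignments_bed(ip, paths["ip"])
    write_alignments_bed(control, paths["control"])
    write_truth_tsv(genome.truth, paths["truth"])
    ct.to_csv(paths["ct"])
    return paths


def write_truth_tsv(truth: TruthTable, path) -> None:
    import pandas as pd

    rows = [
        {
            "peak_id": p.peak_id,
            "chrom": p.interval.chrom,
            "start": p.interval.start,
            "end": p.interval.end,
            "fold": p.fold,
            "location_class": p.location_class,
            "lnc_tier": p.lnc_tier,
            "motif_offset": p.motif_offset,
            "motif_instance": p.motif_instance,
        }
        for p in truth.peaks
    ]
    pd.DataFrame(
        rows,
        columns=["peak_id", "chrom", "start", "end", "fold", "location_class",
                 "lnc_tier", "motif_offset", "motif_instance"],
    ).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> TruthTable:
    import pandas as pd

    truth = TruthTable()
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for row in df.itertuples(index=False):
        truth.peaks.append(
            PeakTruth(
                peak_id=str(row.peak_id),
                interval=GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
                fold=float(row.fold),
                location_class=row.location_class,
                lnc_tier=row.lnc_tier,
                motif_offset=None if pd.isna(row.motif_offset) else int(row.motif_offset),
                motif_instance=None if pd.isna(row.motif_instance) else str(row.motif_instance),
            )
        )
    return truth
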