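"""Genomic interval types and format I/O.

All coordinates are 0-based half-open internally.  External formats that
use 1-based inclusive pairs (the peak table, the TSV feature table) are
converted at (de)serialization only; the conversion preserves length:
``end1 - start1 + 1 == end0 - start0``.

Chromosome names are matched by exact string equality.  An optional
``normalize_chrom`` helper strips a leading ``chr`` prefix for callers
that need it; it is never applied implicitly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import pandas as pd

Strand = Literal["+", "-", "."]
MappingClass = Literal["unique", "repeated"]
Dataset = Literal["ip", "control"]
Biotype = Literal["protein_coding", "lncRNA", "other"]

VALID_BIOTYPES = ("protein_coding", "lncRNA", "other")

PEAK_TABLE_COLUMNS = [
    "peak_no",
    "code",
    "chrom",
    "start",
    "end",
    "score",
    "reads_ip",
    "reads_control",
    "feature",
    "biotype",
    "distance_to_tss",
    "location_class",
    "lnc_tier",
]


class ParseError(ValueError):
    """Raised for malformed records; carries the offending line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


def normalize_chrom(name: str) -> str:
    """Strip a leading 'chr' prefix. Opt-in; matching is exact by default."""
    return name[3:] if name.startswith("chr") and len(name) > 3 else name


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome span, 0-based half-open, with optional strand."""

    chrom: str
    start: int
    end: int
    strand: Strand = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def gap_to(self, other: "GenomicInterval") -> int:
        """Minimum bp separation to `other`; 0 when overlapping or abutting."""
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        if self.start < other.end and other.start < self.end:
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


@dataclass(frozen=True)
class AlignedRead:
    """One mapped read with its unique/repeated class label."""

    interval: GenomicInterval
    mapping_class: MappingClass
    dataset: Dataset = "ip"

    def __post_init__(self):
        if self.mapping_class not in ("unique", "repeated"):
            raise ValueError(f"invalid mapping_class {self.mapping_class!r}")
        if self.dataset not in ("ip", "control"):
            raise ValueError(f"invalid dataset {self.dataset!r}")


@dataclass(frozen=True)
class FeatureRecord:
    """An annotated gene-like feature. Strand is mandatory: the TSS depends on it."""

    feature_id: str
    name: str
    biotype: Biotype
    interval: GenomicInterval
    strand: Literal["+", "-"]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.feature_id}: strand must be + or -")
        if self.biotype not in VALID_BIOTYPES:
            raise ValueError(f"feature {self.feature_id}: invalid biotype {self.biotype!r}")

    @property
    def tss(self) -> int:
        """0-based TSS position: start on '+', end-1 on '-'."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def transcribed_end(self) -> int:
        """0-based last transcribed position (3' end)."""
        return self.interval.end - 1 if self.strand == "+" else self.interval.start


class FeatureCatalog:
    """Feature collection indexed by chromosome."""

    def __init__(self, features: Iterable[FeatureRecord] = ()):
        self._by_chrom: dict[str, list[FeatureRecord]] = {}
        self._features: list[FeatureRecord] = []
        for f in features:
            self.add(f)

    def add(self, feature: FeatureRecord) -> None:
        self._features.append(feature)
        self._by_chrom.setdefault(feature.interval.chrom, []).append(feature)

    def __len__(self) -> int:
        return len(self._features)

    def __iter__(self) -> Iterator[FeatureRecord]:
        return iter(self._features)

    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def on_chrom(self, chrom: str) -> Sequence[FeatureRecord]:
        return self._by_chrom.get(chrom, [])

    def by_biotype(self, biotype: Biotype, chrom: str | None = None) -> list[FeatureRecord]:
        pool = self._features if chrom is None else self.on_chrom(chrom)
        return [f for f in pool if f.biotype == biotype]


# ---------------------------------------------------------------------------
# Alignment readers
# ---------------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
# CIGAR ops that consume reference bases
_REF_OPS = frozenset("MDN=X")


def _cigar_reference_span(cigar: str) -> int:
    span = 0
    consumed = 0
    for m in _CIGAR_RE.finditer(cigar):
        consumed += len(m.group(0))
        if m.group(2) in _REF_OPS:
            span += int(m.group(1))
    if consumed != len(cigar):
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return span


def read_alignments(
    path,
    dialect: Literal["bed", "minimal_sam"] = "bed",
    dataset: Dataset = "ip",
) -> list[AlignedRead]:
    """Read aligned reads from BED6 or a minimal SAM dialect.

    BED6: start/end taken verbatim (0-based half-open); the score column
    carries the mapping class by convention (0 = unique, 1 = repeated).

    minimal SAM: ``QNAME FLAG RNAME POS MAPQ CIGAR`` columns; POS is
    converted from 1-based; MAPQ 0 means repeated.  Header lines (``@``)
    and unmapped records (FLAG 0x4 or RNAME ``*``) are skipped.
    """
    if dialect not in ("bed", "minimal_sam"):
        raise ValueError(f"unknown dialect {dialect!r}")
    reads: list[AlignedRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if dialect == "minimal_sam" and line.startswith("@"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                if dialect == "bed":
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    score = int(fields[4]) if len(fields) > 4 else 0
                    strand = fields[5] if len(fields) > 5 else "."
                    mapping_class = "repeated" if score == 1 else "unique"
                    interval = GenomicInterval(chrom, start, end, strand)
                else:
                    _qname, flag, rname, pos, mapq = (
                        fields[0], int(fields[1]), fields[2], int(fields[3]), int(fields[4]),
                    )
                    cigar = fields[5]
                    if flag & 0x4 or rname == "*":
                        continue
                    span = _cigar_reference_span(cigar)
                    if span == 0:
                        raise ValueError("CIGAR consumes no reference bases")
                    strand = "-" if flag & 0x10 else "+"
                    mapping_class = "repeated" if mapq == 0 else "unique"
                    interval = GenomicInterval(rname, pos - 1, pos - 1 + span, strand)
            except (IndexError, ValueError) as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            reads.append(AlignedRead(interval, mapping_class, dataset))
    return reads


def write_alignments_bed(reads: Iterable[AlignedRead], path) -> None:
    """Write reads as BED6; score column encodes the class (0 unique, 1 repeated)."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            iv = r.interval
            score = 1 if r.mapping_class == "repeated" else 0
            strand = iv.strand if iv.strand != "." else "+"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tr{i}\t{score}\t{strand}\n")


# ---------------------------------------------------------------------------
# Feature readers
# ---------------------------------------------------------------------------

def _gff3_attributes(raw: str) -> dict[str, str]:
    out = {}
    for item in raw.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_features(path, format: Literal["gff3", "tsv"] = "gff3") -> FeatureCatalog:
    """Read a feature catalog from GFF3 or a flat TSV.

    GFF3 records use the ``biotype`` attribute (missing -> ``other``) and
    ``ID``/``Name`` attributes; 1-based inclusive coordinates converted.
    Records without a usable strand are rejected with a warning because
    their TSS is undefined.

    TSV columns: feature_id, name, biotype, chrom, start1, end1, strand
    (coordinates 1-based inclusive).
    """
    import warnings

    catalog = FeatureCatalog()
    if format == "gff3":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) != 9:
                    raise ParseError(path, lineno, f"expected 9 GFF3 columns, got {len(cols)}")
                chrom, _src, _type, start1, end1, _score, strand, _phase, attrs_raw = cols
                if strand not in ("+", "-"):
                    warnings.warn(
                        f"{path}:{lineno}: record without strand skipped (TSS undefined)"
                    )
                    continue
                attrs = _gff3_attributes(attrs_raw)
                biotype = attrs.get("biotype", "other")
                if biotype not in VALID_BIOTYPES:
                    raise ParseError(path, lineno, f"invalid biotype {biotype!r}")
                feature_id = attrs.get("ID", f"feature_{lineno}")
                name = attrs.get("Name", feature_id)
                try:
                    interval = GenomicInterval(chrom, int(start1) - 1, int(end1), strand)
                except ValueError as exc:
                    raise ParseError(path, lineno, str(exc)) from exc
                catalog.add(FeatureRecord(feature_id, name, biotype, interval, strand))
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        required = {"feature_id", "name", "biotype", "chrom", "start1", "end1", "strand"}
        missing = required - set(df.columns)
        if missing:
            raise ParseError(path, 1, f"missing columns: {sorted(missing)}")
        import warnings

        for row in df.itertuples(index=False):
            if row.strand not in ("+", "-"):
                warnings.warn(f"{path}: feature {row.feature_id} without strand skipped")
                continue
            interval = GenomicInterval(str(row.chrom), int(row.start1) - 1, int(row.end1), row.strand)
            catalog.add(FeatureRecord(str(row.feature_id), str(row.name), row.biotype, interval, row.strand))
    else:
        raise ValueError(f"unknown format {format!r}")
    return catalog


def write_features_tsv(catalog: FeatureCatalog, path) -> None:
    rows = [
        {
            "feature_id": f.feature_id,
            "name": f.name,
            "biotype": f.biotype,
            "chrom": f.interval.chrom,
            "start1": f.interval.start + 1,
            "end1": f.interval.end,
            "strand": f.strand,
        }
        for f in catalog
    ]
    pd.DataFrame(rows, columns=["feature_id", "name", "biotype", "chrom", "start1", "end1", "strand"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Peak table
# ---------------------------------------------------------------------------

def write_peak_table(peaks, path) -> None:
    """Write ranked peaks as TSV with 1-based inclusive coordinates.

    A peak at 0-based [92432349, 92432500) prints as start 92432350,
    end 92432500.  Round-trips losslessly through :func:`read_peak_table`.
    """
    rows = []
    for p in peaks:
        ann = getattr(p, "annotation", None)
        rows.append(
            {
                "peak_no": p.rank,
                "code": p.code or "",
                "chrom": p.interval.chrom,
                "start": p.interval.start + 1,
                "end": p.interval.end,
                "score": repr(p.score),
                "reads_ip": p.reads_ip,
                "reads_control": p.reads_control,
                "feature": ann.feature.name if ann is not None and ann.feature else "",
                "biotype": ann.feature.biotype if ann is not None and ann.feature else "",
                "distance_to_tss": (
                    ann.distance_to_tss if ann is not None and ann.distance_to_tss is not None else ""
                ),
                "location_class": ann.location_class if ann is not None else "",
                "lnc_tier": ann.lnc_tier if ann is not None else "",
            }
        )
    pd.DataFrame(rows, columns=PEAK_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_peak_table(path) -> list:
    """Read a peak TSV written by :func:`write_peak_table` back into Peak objects."""
    from yy2scan.enrichment_scoring import Peak

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "code": str}, float_precision="round_trip")
    peaks = []
    for row in df.itertuples(index=False):
        peaks.append(
            Peak(
                interval=GenomicInterval(str(row.chrom), int(row.start) - 1, int(row.end)),
                score=float(row.score),
                reads_ip=int(row.reads_ip),
                reads_control=int(row.reads_control),
                rank=int(row.peak_no),
                code=None if pd.isna(row.code) or row.code == "" else str(row.code),
            )
        )
    return peaks


# ---------------------------------------------------------------------------
# FASTA (small genomes; linear scan)
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a (small) FASTA file into an ordered dict of upper-case sequences."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def extract_sequence(genome: dict[str, str], interval: GenomicInterval) -> str:
    seq = genome[interval.chrom][interval.start : interval.end]
    if interval.strand == "-":
        seq = reverse_complement(seq)
    return seq


_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]
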