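"""Sequence, interval and variant-file primitives shared by the scanners.

All coordinates are 0-based half-open internally (BED convention). VCF
positions are converted at the boundary: ``pos - 1`` on read, ``start + 1``
on write. Multi-allelic VCF records are split into one record per alternate
allele on read and written back split.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

__all__ = [
    "GenomicInterval",
    "PaddedRegion",
    "ReferenceWindow",
    "VariantRecord",
    "reverse_complement",
    "complement_base",
    "pad_and_merge",
    "fetch_window",
    "read_bed",
    "write_bed",
    "read_vcf",
    "write_vcf",
    "trim_alleles",
    "left_align_indel",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANTGCAN")
_VALID_RE = re.compile(r"^[ACGTNacgtn]*$")

BLACKLIST_FILTER_TAG = "ivps_blacklist"


def complement_base(base: str) -> str:
    """Watson-Crick complement of a single uppercase base (N -> N)."""
    try:
        return _COMPLEMENT[base.upper()]
    except KeyError:
        raise ValueError(f"non-IUPAC base {base!r}") from None


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}, case-insensitive, uppercased.

    Ambiguity codes other than N are rejected with the offending position:
    the scanners define base pairing only over the four canonical bases.
    """
    if not _VALID_RE.match(seq):
        for i, ch in enumerate(seq):
            if ch not in "ACGTNacgtn":
                raise ValueError(f"non-IUPAC character {ch!r} at position {i}")
    return seq.translate(_RC_TABLE)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open region ``[start, end)`` on a named reference sequence."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_pos(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class PaddedRegion:
    """A padded/merged interval remembering its contributing origin intervals."""

    interval: GenomicInterval
    origins: tuple[GenomicInterval, ...]


@dataclass(frozen=True)
class ReferenceWindow:
    """An uppercase reference slice over a padded region.

    ``origins`` are the unpadded regions the window derives from; blacklist
    sites are restricted to them.
    """

    interval: GenomicInterval
    seq: str
    origins: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.interval):
            raise ValueError("window sequence length does not match its interval")
        for o in self.origins:
            if not self.interval.contains(o):
                raise ValueError(f"origin {o} not contained in window {self.interval}")

    def to_genomic(self, offset: int) -> int:
        return self.interval.start + offset

    def in_origin(self, start: int, end: int) -> bool:
        """True when genomic span [start, end) overlaps any origin interval."""
        probe = GenomicInterval(self.interval.chrom, start, max(end, start + 1))
        return any(probe.overlaps(o) for o in self.origins)


@dataclass
class VariantRecord:
    """A single-allele variant, VCF-style 1-based position, anchored alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("VCF positions are 1-based")
        if not self.ref or not self.alt or self.ref == self.alt:
            raise ValueError(f"bad alleles {self.ref!r}>{self.alt!r}")

    @property
    def span(self) -> GenomicInterval:
        """0-based half-open span of the reference bases after allele trimming."""
        pos0, ref, _ = trim_alleles(self.pos - 1, self.ref, self.alt)
        return GenomicInterval(self.chrom, pos0, pos0 + len(ref))

    def normalized(self) -> tuple[str, int, str, str]:
        pos0, ref, alt = trim_alleles(self.pos - 1, self.ref, self.alt)
        return self.chrom, pos0, ref, alt


def trim_alleles(pos0: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared suffix then prefix, keeping at least one base of each allele.

    Returns the minimal (0-based pos, ref, alt) representation; this is the
    reference-free part of variant normalization (left-alignment against the
    reference is :func:`left_align_indel`).
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos0 += 1
    return pos0, ref, alt


def left_align_indel(pos0: int, ref: str, alt: str, seq: str) -> tuple[int, str, str]:
    """Left-normalize an anchored indel against reference sequence ``seq``.

    ``seq`` is the full sequence of the chromosome (or a window whose
    coordinate 0 matches pos0's frame). SNVs and already-minimal records are
    returned unchanged apart from affix trimming.
    """
    pos0, ref, alt = trim_alleles(pos0, ref, alt)
    if len(ref) == len(alt):
        return pos0, ref, alt
    # classic left-shift: while the last bases of ref and alt agree, roll left
    while pos0 > 0 and ref[-1] == alt[-1]:
        prev = seq[pos0 - 1].upper()
        ref = prev + ref[:-1]
        alt = prev + alt[:-1]
        pos0 -= 1
    return trim_alleles(pos0, ref, alt)


def pad_and_merge(
    intervals: Sequence[GenomicInterval],
    pad: int,
    chrom_sizes: Mapping[str, int],
) -> list[PaddedRegion]:
    """Grow each interval by ``pad`` on both sides, clamp, and merge.

    Overlapping or abutting padded intervals on the same chromosome are
    merged; each output remembers the origin intervals that contributed to
    it. Output sorted by (chrom, start).
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    for iv in intervals:
        size = chrom_sizes.get(iv.chrom)
        if size is None:
            raise ValueError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > size:
            raise ValueError(f"interval {iv} extends beyond chromosome end ({size})")
    padded = sorted(
        (
            GenomicInterval(
                iv.chrom, max(0, iv.start - pad), min(chrom_sizes[iv.chrom], iv.end + pad)
            ),
            iv,
        )
        for iv in intervals
    )
    merged: list[PaddedRegion] = []
    for grown, origin in padded:
        if (
            merged
            and merged[-1].interval.chrom == grown.chrom
            and grown.start <= merged[-1].interval.end
        ):
            last = merged[-1]
            merged[-1] = PaddedRegion(
                GenomicInterval(
                    grown.chrom, last.interval.start, max(last.interval.end, grown.end)
                ),
                last.origins + (origin,),
            )
        else:
            merged.append(PaddedRegion(grown, (origin,)))
    return merged


def fetch_window(
    reference, padded: GenomicInterval, origins: Iterable[GenomicInterval] | None = None
) -> ReferenceWindow:
    """Extract an uppercased window from a ``pyfaidx.Fasta`` handle.

    Soft-masked (lowercase) reference sequence is accepted and uppercased.
    ``origins`` defaults to the padded interval itself.
    """
    if padded.chrom not in reference:
        raise KeyError(f"chromosome {padded.chrom!r} absent from FASTA")
    rec = reference[padded.chrom]
    if padded.end > len(rec):
        raise ValueError(f"interval {padded} beyond end of {padded.chrom} ({len(rec)})")
    seq = str(rec[padded.start : padded.end]).upper()
    origins = tuple(origins) if origins is not None else (padded,)
    return ReferenceWindow(padded, seq, origins)


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file; extra columns (name, score, strand, ...) are ignored.

    Scanning is strand-symmetric by construction, so a strand column carries
    no information for this tool.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            out.append(iv)
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# VCF (via pysam; uncompressed VCF v4.2)

def _ensure_vcf_header(
    contigs: Mapping[str, int] | None, extra_filters: bool = True
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele fraction">')
    header.add_line(
        '##INFO=<ID=BLSTRUCT,Number=1,Type=String,Description='
        '"Blacklist structure that matched this call">'
    )
    if extra_filters:
        header.add_line(
            f'##FILTER=<ID={BLACKLIST_FILTER_TAG},Description='
            '"Site predicted artifact-prone by fold-back structure blacklist">'
        )
    if contigs:
        for name, size in contigs.items():
            header.contigs.add(name, length=size)
    return header


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a VCF, splitting multi-allelic records one VariantRecord per alt."""
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            af = rec.info.get("AF")
            if isinstance(af, tuple):
                afs = list(af)
            else:
                afs = [af] * len(rec.alts or ())
            for i, alt in enumerate(rec.alts or ()):
                vaf = afs[i] if i < len(afs) and afs[i] is not None else None
                out.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=str(alt),
                        vaf=float(vaf) if vaf is not None else None,
                        extra={
                            "id": rec.id,
                            "qual": rec.qual,
                            "filter": list(rec.filter.keys()),
                        },
                    )
                )
    return out


def write_vcf(
    records: Iterable[VariantRecord],
    path: str | Path,
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write VariantRecords to an uncompressed VCF (one line per allele)."""
    records = list(records)
    if contigs is None:
        sizes: dict[str, int] = {}
        for r in records:
            need = r.pos + len(r.ref) + 1
            sizes[r.chrom] = max(sizes.get(r.chrom, 0), need)
        contigs = sizes
    header = _ensure_vcf_header(contigs)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r in records:
            rec = vcf.new_record(
                contig=r.chrom,
                start=r.pos - 1,
                alleles=(r.ref, r.alt),
                id=r.extra.get("id"),
                qual=r.extra.get("qual"),
            )
            if r.vaf is not None:
                rec.info["AF"] = round(float(r.vaf), 6)
            if r.extra.get("struct"):
                rec.info["BLSTRUCT"] = str(r.extra["struct"])
            for f in r.extra.get("filter", []) or []:
                if f != "PASS":
                    rec.filter.add(f)
            vcf.write(rec)
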