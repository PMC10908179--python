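"""Assemble, serialize and apply the potential mutation blacklist.

The blacklist is the union of artifact sites predicted from imperfect
inverted repeats (PBIVS) and imperfect palindromes (PBPS) within the target
regions of a panel. Entries use BED-style 0-based half-open coordinates;
the variant filter converts VCF positions on comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pyfaidx
from intervaltree import IntervalTree

from .genome_io import (
    GenomicInterval,
    VariantRecord,
    fetch_window,
    pad_and_merge,
    trim_alleles,
)

__all__ = [
    "BlacklistEntry",
    "Blacklist",
    "build_blacklist",
    "filter_variants",
    "write_blacklist",
    "read_blacklist",
    "DEFAULT_PAD",
]

DEFAULT_PAD = 50  # bp added to each side of a target region before scanning


@dataclass(frozen=True, order=True)
class BlacklistEntry:
    """One predicted artifact site.

    ``ref`` is the reference allele over [start, end); ``predicted_alt`` is
    the artifact allele a chimeric repair event would write there (anchored
    VCF-style for indels).
    """

    chrom: str
    start: int
    end: int
    ref: str
    predicted_alt: str
    source: str  # IVS | PS
    structure_id: str

    def __post_init__(self) -> None:
        if self.ref == self.predicted_alt or not self.ref or not self.predicted_alt:
            raise ValueError("predicted_alt must differ from ref and be non-empty")
        if self.end - self.start != len(self.ref):
            raise ValueError("entry span must cover its reference allele")


@dataclass(frozen=True)
class Blacklist:
    entries: tuple[BlacklistEntry, ...]
    params_fingerprint: str = ""

    def __post_init__(self) -> None:
        keys = [(e.chrom, e.start, e.end, e.predicted_alt) for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate blacklist entries")
        if list(self.entries) != sorted(self.entries):
            object.__setattr__(self, "entries", tuple(sorted(self.entries)))

    def __len__(self) -> int:
        return len(self.entries)

    def _trees(self) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for e in self.entries:
            trees.setdefault(e.chrom, IntervalTree()).addi(e.start, e.end, e)
        return trees


def _fingerprint(reference_id: str, pad: int, ivs_params, ps_params) -> str:
    ip, pp = ivs_params, ps_params
    return (
        f"ref={reference_id};pad={pad};"
        f"min_spacer={ip.min_spacer};min_arm={ip.min_arm};min_edge={ip.min_edge};"
        f"seed_len={ip.seed_len};max_interrupt={ip.max_interrupt};"
        f"max_spacer={ip.max_spacer};"
        f"min_helix={pp.min_helix};stop_mismatches={pp.stop_mismatches};"
        f"even_centers={pp.include_even_centers}"
    )


def build_blacklist(
    reference,
    bed: Sequence[GenomicInterval],
    ivs_params=None,
    ps_params=None,
    pad: int = DEFAULT_PAD,
    sources: tuple[str, ...] = ("IVS", "PS"),
) -> Blacklist:
    """Scan padded target regions and union the IVS and PS blacklists.

    ``reference`` is a pyfaidx.Fasta handle or a FASTA path. Each region is
    grown by ``pad`` bp on each side to catch structures straddling the
    region edge, but only sites inside the original regions are kept.
    Deterministic for fixed inputs.
    """
    from .ivs_scanner import IVSParams, ivs_blacklist, scan_ivs
    from .ps_scanner import PSParams, ps_blacklist, scan_ps

    ivs_params = ivs_params or IVSParams()
    ps_params = ps_params or PSParams()
    if isinstance(reference, (str, Path)):
        reference = pyfaidx.Fasta(str(reference))
    ref_id = Path(getattr(reference, "filename", "unknown")).name
    fp = _fingerprint(ref_id, pad, ivs_params, ps_params)
    if not bed:
        warnings.warn("empty BED: building an empty blacklist")
        return Blacklist((), fp)
    chrom_sizes = {name: len(reference[name]) for name in reference.keys()}
    entries: dict[tuple, BlacklistEntry] = {}
    for region in pad_and_merge(bed, pad, chrom_sizes):
        window = fetch_window(reference, region.interval, region.origins)
        if "IVS" in sources:
            for e in ivs_blacklist(scan_ivs(window, ivs_params), window, ivs_params):
                entries.setdefault((e.chrom, e.start, e.end, e.predicted_alt), e)
        if "PS" in sources:
            for e in ps_blacklist(scan_ps(window, ps_params), window, ps_params):
                entries.setdefault((e.chrom, e.start, e.end, e.predicted_alt), e)
    return Blacklist(tuple(sorted(entries.values())), fp)


def filter_variants(
    variants: Iterable[VariantRecord],
    blacklist: Blacklist,
    mode: str = "position",
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Partition variants into (retained, removed) against the blacklist.

    ``position`` mode removes any variant whose trimmed reference span
    overlaps an entry span by at least one base (conservative: an MNV
    touching an entry is removed). ``allele`` mode additionally requires the
    predicted artifact allele to equal the called allele. Removed records
    are annotated with the matching structure id. Idempotent.
    """
    if mode not in ("position", "allele"):
        raise ValueError(f"unknown filter mode {mode!r}")
    trees = blacklist._trees()
    retained: list[VariantRecord] = []
    removed: list[VariantRecord] = []
    for v in variants:
        chrom, pos0, ref, alt = v.normalized()
        hits = trees.get(chrom, IntervalTree()).overlap(pos0, pos0 + len(ref))
        match = None
        for hit in sorted(hits, key=lambda h: (h.begin, h.end)):
            e: BlacklistEntry = hit.data
            if mode == "position":
                match = e
                break
            if (pos0, ref, alt) == trim_alleles(e.start, e.ref, e.predicted_alt):
                match = e
                break
        if match is None:
            retained.append(v)
        else:
            annotated = replace(v, extra={**v.extra, "struct": match.structure_id})
            removed.append(annotated)
    return retained, removed


def write_blacklist(blacklist: Blacklist, path: str | Path) -> None:
    """TSV with a `#params:` fingerprint header; round-trip lossless."""
    with open(path, "w") as fh:
        fh.write(f"#params:{blacklist.params_fingerprint}\n")
        fh.write("#chrom\tstart\tend\tref\tpredicted_alt\tsource\tstructure_id\n")
        for e in blacklist.entries:
            fh.write(
                f"{e.chrom}\t{e.start}\t{e.end}\t{e.ref}\t{e.predicted_alt}"
                f"\t{e.source}\t{e.structure_id}\n"
            )


def read_blacklist(path: str | Path) -> Blacklist:
    entries: list[BlacklistEntry] = []
    fingerprint = ""
    saw_params = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#params:"):
                fingerprint = line[len("#params:") :]
                saw_params = True
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns")
            entries.append(
                BlacklistEntry(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    ref=fields[3],
                    predicted_alt=fields[4],
                    source=fields[5],
                    structure_id=fields[6],
                )
            )
    if not saw_params:
        warnings.warn(f"{path}: no #params fingerprint line; provenance unknown")
    return Blacklist(tuple(sorted(entries)), fingerprint)


def verify_against_reference(blacklist: Blacklist, reference) -> list[BlacklistEntry]:
    """Return entries whose ref allele disagrees with the reference."""
    if isinstance(reference, (str, Path)):
        reference = pyfaidx.Fasta(str(reference))
    bad = []
    for e in blacklist.entries:
        actual = str(reference[e.chrom][e.start : e.end]).upper()
        if actual != e.ref:
            bad.append(e)
    return bad
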