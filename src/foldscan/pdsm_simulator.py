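"""Synthetic references and PDSM chimera simulation.

PDSM (pairing of partial single strands derived from a similar molecule) is
the mechanistic model for library-preparation chimeras: fragmentation
exposes partial single strands; where the genome carries an inverted repeat
(IVS) or palindrome (PS), a strand ending inside one arm anneals to the
other arm of a similar molecule, exonuclease trimming and polymerase fill
then produce a chimeric template. If the fold-back pairing is imperfect,
the fill writes the "perfecting" base at the imperfection - a predictable
artifact variant.

Two fragmentation chemistries are modeled:

* sonication - random double-strand breaks anywhere; when a break lands in
  an IVS arm the resulting template is a heteroduplex: one strand keeps the
  original base at the mismatch site, the other carries the induced allele.
  Unbiased PCR therefore propagates the mutation into exactly half of the
  descendant molecules (the 50% chimeric-read prediction).
* enzymatic - nicks inside palindromes; end repair resolves the mismatch
  before any amplification, so the induced allele sits on both strands
  (homoduplex) and all descendant chimeric reads carry it.

The module also provides a naive pileup caller so the full loop
(simulate -> blacklist -> call -> filter) closes without an aligner: reads
carry their true placement, and the chimeric copy is mapped to the apparent
position an aligner would assign it from the structure geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome_io import GenomicInterval, VariantRecord, complement_base, left_align_indel, reverse_complement

__all__ = [
    "PlantedIVS",
    "PlantedPS",
    "PlantedVariant",
    "SyntheticSpec",
    "SyntheticReference",
    "ChimericTemplate",
    "SimRead",
    "make_synthetic_reference",
    "simulate_sonication_chimeras",
    "simulate_enzymatic_chimeras",
    "simulate_plain_templates",
    "pcr_and_sample",
    "pcr_molecule_count",
    "naive_pileup",
]

# ---------------------------------------------------------------------------
# synthetic reference construction

@dataclass(frozen=True)
class PlantedIVS:
    """An inverted repeat to plant: two reverse-complementary arms of
    ``arm_len`` aligned columns around a ``spacer_len`` loop, with optional
    interruptions (column offset from the outer end of arm 1, kind, length).
    Kinds: ``mismatch`` (arm-2 base broken), ``gap_arm1``/``gap_arm2``
    (bulge of ``length`` extra bases on that arm before the given column).
    """

    arm_len: int = 12
    spacer_len: int = 6
    interruptions: tuple[tuple[int, str, int], ...] = ((4, "mismatch", 1),)

    def __post_init__(self) -> None:
        for off, kind, length in self.interruptions:
            if kind == "mismatch":
                ok = 1 <= off and off + length <= self.arm_len - 1
            else:
                ok = 1 <= off <= self.arm_len - 1 and kind in ("gap_arm1", "gap_arm2")
            if not ok:
                raise ValueError(f"interruption {(off, kind, length)} does not fit the arm")


@dataclass(frozen=True)
class PlantedPS:
    """A palindrome to plant: odd ``helix_len`` span with an optional single
    internal mismatch at column ``mismatch_k`` (1-based distance from the
    center; None plants a perfect palindrome)."""

    helix_len: int = 21
    mismatch_k: int | None = 4

    def __post_init__(self) -> None:
        if self.helix_len % 2 == 0 or self.helix_len < 5:
            raise ValueError("helix_len must be odd and >= 5")
        half = (self.helix_len - 1) // 2
        if self.mismatch_k is not None and not (1 <= self.mismatch_k <= half - 1):
            raise ValueError("mismatch_k must be internal (1 .. half-1)")


@dataclass(frozen=True)
class PlantedVariant:
    """A true variant carried by sample molecules at the target VAF.

    ``pos``/``alt`` may be None for automatic placement away from planted
    structures and predicted blacklist sites.
    """

    vaf: float = 0.3
    pos: int | None = None
    alt: str | None = None


@dataclass(frozen=True)
class SyntheticSpec:
    length: int = 4000
    gc: float = 0.5
    planted_ivs: tuple[PlantedIVS, ...] = ()
    planted_ps: tuple[PlantedPS, ...] = ()
    true_variants: tuple[PlantedVariant, ...] = ()
    seed: int = 0
    chrom: str = "synth1"


@dataclass
class StructureTruth:
    """Genomic record of one planted structure and its expected artifact sites."""

    kind: str  # IVS | PS
    arm1: GenomicInterval
    arm2: GenomicInterval
    spacer_len: int
    diag: int  # anti-diagonal of the outer alignment (p + q = diag)
    mismatch_pairs: list[tuple[int, int]] = field(default_factory=list)
    expected_entries: list[tuple[int, int, str, str]] = field(default_factory=list)
    center: int | None = None  # PS only


@dataclass
class SyntheticReference:
    chrom: str
    seq: str
    structures: list[StructureTruth]
    true_variants: list[VariantRecord]
    spec: SyntheticSpec

    def to_fasta(self, path: str | Path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        rec = SeqRecord(Seq(self.seq), id=self.chrom, description="")
        SeqIO.write([rec], str(path), "fasta")

    @property
    def expected_blacklist_sites(self) -> list[tuple[int, int, str, str]]:
        out = []
        for s in self.structures:
            out.extend(s.expected_entries)
        return sorted(set(out))


def _rand_bases(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return ["ACGT"[i] for i in rng.choice(4, size=n, p=p)]


def _nonpairing_base(rng: np.random.Generator, partners: Sequence[str], avoid=()) -> str:
    """A base that pairs with none of ``partners`` and is not in ``avoid``."""
    forbidden = {complement_base(b) for b in partners if b != "N"} | set(avoid)
    options = [b for b in "ACGT" if b not in forbidden]
    if not options:  # fall back: only break the primary pairing
        options = [b for b in "ACGT" if b != complement_base(partners[0])]
    return options[int(rng.integers(len(options)))]


def make_synthetic_reference(spec: SyntheticSpec):
    """Build a random reference with planted structures and a truth table.

    The background is i.i.d. at the requested GC. Planted structures are
    made exactly maximal: the pairing columns immediately outside the arms
    and inside the spacer are forced non-complementary so the scanners
    recover precisely the planted extent. Auto-placed true variants avoid
    planted structures and all blacklisted sites of the finished sequence.
    Deterministic for a fixed spec (seed included).
    """
    rng = np.random.default_rng(spec.seed)
    seq = _rand_bases(rng, spec.length, spec.gc)
    structures: list[StructureTruth] = []
    margin = 12
    blocks: list[tuple[int, int]] = []  # occupied [start, end)

    def build_blocks():
        specs: list[tuple[str, object]] = [("IVS", s) for s in spec.planted_ivs]
        specs += [("PS", s) for s in spec.planted_ps]
        if not specs:
            return
        slot = (spec.length - 2 * margin) // len(specs)
        for i, (kind, s) in enumerate(specs):
            if kind == "IVS":
                block, meta = _build_ivs_block(rng, s)
            else:
                block, meta = _build_ps_block(rng, s)
            if len(block) + 2 * margin > slot:
                raise ValueError("planted structures overlap: reference too short")
            start = margin + i * slot + (slot - len(block)) // 2
            seq[start : start + len(block)] = list(block)
            blocks.append((start, start + len(block)))
            structures.append(_materialize_truth(kind, s, meta, start, spec.chrom))

    build_blocks()
    _protect_flanks(rng, seq, structures, blocks)
    for st in structures:
        _fill_expected_entries(st, seq)

    ref_seq = "".join(seq)
    true_vars = _place_true_variants(rng, ref_seq, spec, blocks)
    return SyntheticReference(spec.chrom, ref_seq, structures, true_vars, spec)


def _build_ivs_block(rng, s: PlantedIVS):
    core = _rand_bases(rng, s.arm_len, 0.5)
    arm2 = [complement_base(b) for b in core[::-1]]  # rc(core), column t <-> arm2[arm_len-1-t]
    arm1 = list(core)
    gaps = []  # (side, col_offset, length, bulge)
    mms = []  # column offsets
    for off, kind, length in s.interruptions:
        if kind == "mismatch":
            for i in range(length):
                t = off + i
                j = s.arm_len - 1 - t
                arm2[j] = _nonpairing_base(rng, [core[t]], avoid=("N",))
                mms.append(t)
        else:
            bulge = _rand_bases(rng, length, 0.5)
            gaps.append((kind, off, length, bulge))
    # the detector reports either mismatch chains or a single pure gap
    if len(gaps) > 1 or (gaps and mms):
        raise ValueError("a planted IVS takes either mismatches or one gap")
    if gaps:
        kind, off, length, bulge = gaps[0]
        if kind == "gap_arm1":
            arm1 = arm1[:off] + bulge + arm1[off:]
        else:
            j = s.arm_len - off
            arm2 = arm2[:j] + bulge + arm2[j:]
    spacer = _rand_bases(rng, s.spacer_len, 0.5)
    block = arm1 + spacer + arm2
    meta = {
        "arm1_len": len(arm1),
        "arm2_len": len(arm2),
        "spacer": s.spacer_len,
        "mms": mms,
        "gap": gaps[0] if gaps else None,
        "arm_cols": s.arm_len,
    }
    return "".join(block), meta


def _build_ps_block(rng, s: PlantedPS):
    half = (s.helix_len - 1) // 2
    left = _rand_bases(rng, half, 0.5)
    center = _rand_bases(rng, 1, 0.5)
    right = [complement_base(b) for b in left[::-1]]
    if s.mismatch_k is not None:
        k = s.mismatch_k
        right[k - 1] = _nonpairing_base(rng, [left[half - k]], avoid=("N",))
    block = left + center + right
    return "".join(block), {"half": half, "k": s.mismatch_k}


def _materialize_truth(kind, s, meta, start, chrom) -> StructureTruth:
    if kind == "IVS":
        a1_len, a2_len = meta["arm1_len"], meta["arm2_len"]
        a1s, a1e = start, start + a1_len
        a2s = a1e + meta["spacer"]
        a2e = a2s + a2_len
        gap = meta["gap"]
        st = StructureTruth(
            kind="IVS",
            arm1=GenomicInterval(chrom, a1s, a1e),
            arm2=GenomicInterval(chrom, a2s, a2e),
            spacer_len=meta["spacer"],
            diag=a1s + a2e - 1,
        )
        st.gap = gap  # type: ignore[attr-defined]
        st.arm_cols = meta["arm_cols"]  # type: ignore[attr-defined]
        if gap is None:
            for t in meta["mms"]:
                p = a1s + t
                q = st.diag - p
                st.mismatch_pairs.append((p, q))
        return st
    half, k = meta["half"], meta["k"]
    center = start + half
    st = StructureTruth(
        kind="PS",
        arm1=GenomicInterval(chrom, start, center),
        arm2=GenomicInterval(chrom, center + 1, start + 2 * half + 1),
        spacer_len=1,
        diag=2 * center,
        center=center,
    )
    if k is not None:
        st.mismatch_pairs.append((center - k, center + k))
    return st


def _protect_flanks(rng, seq, structures: list[StructureTruth], blocks) -> None:
    """Force pairing columns just outside each structure (and through the
    spacer) to be non-complementary, so planted extents are maximal."""
    n = len(seq)

    def in_block(pos: int) -> bool:
        return any(b0 <= pos < b1 for b0, b1 in blocks)

    for st in structures:
        d = st.diag
        # inward: every spacer column must not pair (prevents inward chaining)
        gap = getattr(st, "gap", None)
        d_in = d
        if st.kind == "IVS" and gap is not None:
            d_in = d + gap[2] if gap[0] == "gap_arm1" else d - gap[2]
        x = st.arm1.end
        y = d_in - x
        while x < y:
            # spacer bases belong to the planted block; rewrite in place
            if seq[x] != "N" and seq[y] == complement_base(seq[x]):
                seq[y] = _nonpairing_base(rng, [seq[x]])
            x += 1
            y -= 1
        # bulge bases of a gap must not pair on either bounding diagonal,
        # or the reported junction/extent would shift
        if st.kind == "IVS" and gap is not None:
            kind, off, g, _ = gap
            j = st.arm1.start + off - 1
            bulge0 = st.arm1.start + off if kind == "gap_arm1" else d - j - g
            for x in range(bulge0, bulge0 + g):
                partners = [seq[d - x]] if 0 <= d - x < n else []
                if 0 <= d_in - x < n:
                    partners.append(seq[d_in - x])
                if partners and seq[x] in {complement_base(b) for b in partners if b != "N"}:
                    seq[x] = _nonpairing_base(rng, partners)
        # outward: enough consecutive non-pairing columns to stop chaining
        for k in range(1, 5):
            x = st.arm1.start - k
            y = st.arm2.end - 1 + k
            if x < 0 or y >= n:
                break
            if in_block(x) or in_block(y):
                continue
            if seq[x] != "N" and seq[y] == complement_base(seq[x]):
                seq[y] = _nonpairing_base(rng, [seq[x]])


def _fill_expected_entries(st: StructureTruth, seq: list[str]) -> None:
    text = seq  # list of bases, genomic frame
    if st.kind == "PS":
        for left, right in st.mismatch_pairs:
            bl, br = text[left], text[right]
            st.expected_entries.append((left, left + 1, bl, complement_base(br)))
            st.expected_entries.append((right, right + 1, br, complement_base(bl)))
        return
    gap = getattr(st, "gap", None)
    for p, q in st.mismatch_pairs:
        bp, bq = text[p], text[q]
        st.expected_entries.append((p, p + 1, bp, complement_base(bq)))
        st.expected_entries.append((q, q + 1, bq, complement_base(bp)))
    if gap is not None:
        kind, off, g, _bulge = gap
        s = "".join(text)
        j = st.arm1.start + off - 1  # last outer alignment column (arm-1 side)
        if kind == "gap_arm1":
            bulge0 = j + 1
            anchor = st.diag - j - 1  # arm-2 base left of the mirrored junction
        else:
            bulge0 = st.diag - j - g
            anchor = j
        bulge = s[bulge0 : bulge0 + g]
        # deletion of the bulge at its own site
        d0 = bulge0 - 1
        ref = s[d0 : d0 + g + 1]
        pos, nref, nalt = left_align_indel(d0, ref, ref[0], s)
        st.expected_entries.append((pos, pos + len(nref), nref, nalt))
        # insertion of the reverse-complement bulge on the partner arm
        base = s[anchor]
        pos, nref, nalt = left_align_indel(anchor, base, base + reverse_complement(bulge), s)
        st.expected_entries.append((pos, pos + len(nref), nref, nalt))


def _place_true_variants(rng, ref_seq: str, spec: SyntheticSpec, blocks):
    variants: list[VariantRecord] = []
    if not spec.true_variants:
        return variants
    forbidden = set()
    for b0, b1 in blocks:
        forbidden.update(range(max(0, b0 - 2), min(len(ref_seq), b1 + 2)))
    forbidden |= _blacklisted_positions(ref_seq, spec.chrom)
    candidates = [i for i in range(5, len(ref_seq) - 5) if i not in forbidden]
    for pv in spec.true_variants:
        if pv.pos is not None:
            pos = pv.pos
            if pos in forbidden:
                raise ValueError(f"true variant at {pos} collides with a structure/blacklist site")
        else:
            if not candidates:
                raise ValueError("no free position for a true variant")
            pos = int(candidates[int(rng.integers(len(candidates)))])
        ref = ref_seq[pos]
        alt = pv.alt or "ACGT"[(("ACGT".index(ref)) + 1 + int(rng.integers(3))) % 4]
        if alt == ref:
            alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        variants.append(VariantRecord(spec.chrom, pos + 1, ref, alt, vaf=pv.vaf))
        forbidden.add(pos)
        if pos in candidates:
            candidates.remove(pos)
    variants.sort(key=lambda v: v.pos)
    return variants


def _blacklisted_positions(ref_seq: str, chrom: str) -> set[int]:
    """Positions covered by the default-parameter blacklist of this sequence."""
    from .genome_io import ReferenceWindow
    from .ivs_scanner import IVSParams, ivs_blacklist, scan_ivs
    from .ps_scanner import PSParams, ps_blacklist, scan_ps

    iv = GenomicInterval(chrom, 0, len(ref_seq))
    window = ReferenceWindow(iv, ref_seq, (iv,))
    sites: set[int] = set()
    for e in ivs_blacklist(scan_ivs(window, IVSParams()), window, IVSParams()):
        sites.update(range(e.start, e.end))
    for e in ps_blacklist(scan_ps(window, PSParams()), window, PSParams()):
        sites.update(range(e.start, e.end))
    return sites


# ---------------------------------------------------------------------------
# chimera formation

@dataclass
class ChimericTemplate:
    """A double-stranded template molecule.

    ``seq`` is the top-strand sequence of strand A (the strand that retains
    the original fragment); ``junction`` is the offset of the chimera
    breakpoint, None for a non-chimeric template. ``apparent_pos`` maps each
    base to the reference position an aligner would assign (-1: clipped).
    For a heteroduplex, strand B's top-strand equivalent carries the induced
    allele at ``site_off``; for an enzymatic homoduplex both strands carry
    it (already substituted into ``seq``).
    """

    chrom: str
    seq: str
    apparent_pos: np.ndarray
    junction: int | None
    induced_site: tuple[int, str, str] | None  # (0-based pos, ref, alt)
    site_off: int | None
    heteroduplex: bool
    chemistry: str | None
    template_id: int
    extra_variants: tuple[tuple[int, str, str], ...] = ()

    @property
    def is_chimeric(self) -> bool:
        return self.junction is not None

    @property
    def strand_a(self) -> str:
        return self.seq

    @property
    def strand_b(self) -> str:
        return reverse_complement(self.top_b)

    @property
    def top_a(self) -> str:
        return self.seq

    @property
    def top_b(self) -> str:
        if self.heteroduplex and self.site_off is not None:
            alt = self.induced_site[2]
            return self.seq[: self.site_off] + alt + self.seq[self.site_off + 1 :]
        return self.seq


def pcr_molecule_count(cycles: int) -> int:
    """Double-stranded molecules descending from one template after
    error-free, unbiased PCR: 2**cycles, split equally between the two
    original strands' lineages."""
    if cycles < 1:
        raise ValueError("cycles >= 1")
    return 2 ** cycles


def _pick_fragment(rng, lo: int, hi: int) -> int:
    return int(rng.integers(lo, hi + 1))


def _right_chimera(
    rng, refseq, chrom, b, a1s, a2s, a2e, d, mismatch_pairs, tid, chemistry, frag
):
    """Break at b inside the downstream arm; original part [u, b), filled
    tail copies the partner strand leftward from the mirror of b."""
    u = max(0, b - _pick_fragment(rng, *frag))
    tail_len = _pick_fragment(rng, *frag)
    w = max(0, d - b + 1 - tail_len)
    original = refseq[u:b]
    tail = reverse_complement(refseq[w : d - b + 1])
    seq = original + tail
    junction = len(original)
    app = np.full(len(seq), -1, dtype=np.int64)
    app[:junction] = np.arange(u, b)
    # the copied tail extends the apparent alignment through the arm mirror
    t_valid = min(len(tail), a2e - b)
    if t_valid > 0:
        app[junction : junction + t_valid] = np.arange(b, b + t_valid)
    site = None
    site_off = None
    for p, q in mismatch_pairs:
        if a2s <= q < b:
            site = (q, refseq[q], complement_base(refseq[d - q]))
            site_off = q - u
            break
    return _finish_template(refseq, chrom, seq, app, junction, site, site_off, tid, chemistry)


def _left_chimera(
    rng, refseq, chrom, b, a1s, a1e, d, mismatch_pairs, tid, chemistry, frag
):
    """Break at b inside the upstream arm; original part [b, v), tail
    prepended, apparent positions descending into the arm."""
    L = len(refseq)
    v = min(L, b + _pick_fragment(rng, *frag))
    tail_len = _pick_fragment(rng, *frag)
    x_lo = max(0, d - L + 1, b - tail_len)
    original = refseq[b:v]
    tail = "".join(complement_base(refseq[d - x]) for x in range(x_lo, b))
    seq = tail + original
    junction = len(tail)
    app = np.full(len(seq), -1, dtype=np.int64)
    app[junction:] = np.arange(b, v)
    xs = np.arange(x_lo, b)
    valid = xs >= a1s
    app[:junction][valid] = xs[valid]
    site = None
    site_off = None
    for p, q in mismatch_pairs:
        if b <= p < a1e:
            site = (p, refseq[p], complement_base(refseq[d - p]))
            site_off = junction + (p - b)
            break
    return _finish_template(refseq, chrom, seq, app, junction, site, site_off, tid, chemistry)


def _finish_template(refseq, chrom, seq, app, junction, site, site_off, tid, chemistry):
    heteroduplex = site is not None and chemistry == "sonication"
    if site is not None and chemistry == "enzymatic":
        # end repair resolves the mismatch before amplification: the induced
        # allele is written into both strands of the template
        seq = seq[:site_off] + site[2] + seq[site_off + 1 :]
    return ChimericTemplate(
        chrom=chrom,
        seq=seq,
        apparent_pos=app,
        junction=junction,
        induced_site=site,
        site_off=site_off if site is not None else None,
        heteroduplex=heteroduplex,
        chemistry=chemistry,
        template_id=tid,
    )


def simulate_sonication_chimeras(
    reference: SyntheticReference | str,
    ivs: StructureTruth,
    n_templates: int,
    seed: int,
    frag_len: tuple[int, int] = (120, 180),
    chrom: str = "synth1",
) -> list[ChimericTemplate]:
    """Random double-strand breaks; breaks landing inside an IVS arm form
    chimeric templates (heteroduplex when the retained strand spans the
    mismatch), other breaks yield plain templates."""
    refseq, chrom = _ref_and_chrom(reference, chrom)
    rng = np.random.default_rng(seed)
    a1s, a1e = ivs.arm1.start, ivs.arm1.end
    a2s, a2e = ivs.arm2.start, ivs.arm2.end
    d = ivs.diag
    out = []
    for tid in range(n_templates):
        b = int(rng.integers(0, len(refseq)))
        if a2s + 1 <= b <= a2e:
            out.append(
                _right_chimera(
                    rng, refseq, chrom, b, a1s, a2s, a2e, d,
                    ivs.mismatch_pairs, tid, "sonication", frag_len,
                )
            )
        elif a1s <= b <= a1e - 1:
            out.append(
                _left_chimera(
                    rng, refseq, chrom, b, a1s, a1e, d,
                    ivs.mismatch_pairs, tid, "sonication", frag_len,
                )
            )
        else:
            u = max(0, b - _pick_fragment(rng, *frag_len))
            seq = refseq[u:b] if b > u else refseq[u : u + 1]
            app = np.arange(u, u + len(seq), dtype=np.int64)
            out.append(
                ChimericTemplate(
                    chrom=chrom, seq=seq, apparent_pos=app, junction=None,
                    induced_site=None, site_off=None, heteroduplex=False,
                    chemistry="sonication", template_id=tid,
                )
            )
    return out


def simulate_enzymatic_chimeras(
    reference: SyntheticReference | str,
    ps: StructureTruth,
    n_templates: int,
    seed: int,
    frag_len: tuple[int, int] = (60, 100),
    chrom: str = "synth1",
) -> list[ChimericTemplate]:
    """Nicks inside the palindrome arms; fold-back and end repair write the
    induced allele into the template before amplification (homoduplex), so
    chimeric spans are shorter and the mutation, when induced, is carried by
    every descendant strand."""
    refseq, chrom = _ref_and_chrom(reference, chrom)
    rng = np.random.default_rng(seed)
    c = ps.center
    s, e = ps.arm1.start, ps.arm2.end
    d = 2 * c
    out = []
    left_sites = list(range(s, c - 1))  # left-arm breaks (>=1 annealed base)
    right_sites = list(range(c + 2, e + 1))  # right-arm breaks
    sites = left_sites + right_sites
    for tid in range(n_templates):
        b = sites[int(rng.integers(len(sites)))]
        if b >= c + 2:
            out.append(
                _right_chimera(
                    rng, refseq, chrom, b, s, c + 1, e, d,
                    ps.mismatch_pairs, tid, "enzymatic", frag_len,
                )
            )
        else:
            out.append(
                _left_chimera(
                    rng, refseq, chrom, b, s, c, d,
                    ps.mismatch_pairs, tid, "enzymatic", frag_len,
                )
            )
    return out


def simulate_plain_templates(
    reference: SyntheticReference | str,
    n_templates: int,
    seed: int,
    true_variants: Sequence[VariantRecord] = (),
    frag_len: tuple[int, int] = (120, 180),
    chrom: str = "synth1",
) -> list[ChimericTemplate]:
    """Ordinary (non-chimeric) templates; each carries each overlapping true
    variant with probability equal to its VAF (SNVs only)."""
    refseq, chrom = _ref_and_chrom(reference, chrom)
    rng = np.random.default_rng(seed)
    if isinstance(reference, SyntheticReference) and not true_variants:
        true_variants = reference.true_variants
    out = []
    L = len(refseq)
    for tid in range(n_templates):
        flen = _pick_fragment(rng, *frag_len)
        u = int(rng.integers(0, max(1, L - flen)))
        v = min(L, u + flen)
        seq = refseq[u:v]
        carried = []
        for tv in true_variants:
            pos0 = tv.pos - 1
            if u <= pos0 < v and len(tv.ref) == 1 and len(tv.alt) == 1:
                if rng.random() < (tv.vaf or 0):
                    seq = seq[: pos0 - u] + tv.alt + seq[pos0 - u + 1 :]
                    carried.append((pos0, tv.ref, tv.alt))
        out.append(
            ChimericTemplate(
                chrom=chrom, seq=seq,
                apparent_pos=np.arange(u, v, dtype=np.int64),
                junction=None, induced_site=None, site_off=None,
                heteroduplex=False, chemistry=None, template_id=tid,
                extra_variants=tuple(carried),
            )
        )
    return out


def _ref_and_chrom(reference, chrom):
    if isinstance(reference, SyntheticReference):
        return reference.seq, reference.chrom
    return reference, chrom


# ---------------------------------------------------------------------------
# PCR and read sampling

@dataclass
class SimRead:
    """A sampled read in top-strand orientation with its truth placement."""

    sequence: str
    apparent_pos: np.ndarray
    template_id: int
    start_off: int
    lineage: str  # 'a' | 'b'
    carries_mutation: bool
    is_chimeric: bool


def pcr_and_sample(
    templates: Sequence[ChimericTemplate],
    cycles: int,
    n_reads: int,
    read_len: int = 100,
    seed: int = 0,
) -> list[SimRead]:
    """Amplify templates by unbiased error-free doubling and sample reads.

    Exact doubling keeps the two strand lineages of every template at equal
    frequency in the final pool, so reads draw a template uniformly and a
    lineage with probability 1/2. Chimeric reads are truncated around the
    junction so they retain the soft-clip signature (and the induced site,
    which always lies within one arm length of the junction).
    """
    if cycles < 1:
        raise ValueError("cycles >= 1")
    if not templates:
        return []
    rng = np.random.default_rng(seed)
    t_idx = rng.integers(0, len(templates), size=n_reads)
    lin = rng.integers(0, 2, size=n_reads)
    out: list[SimRead] = []
    for i in range(n_reads):
        tpl = templates[int(t_idx[i])]
        lineage = "a" if lin[i] == 0 else "b"
        top = tpl.top_a if lineage == "a" else tpl.top_b
        L = len(top)
        if L <= read_len:
            wstart = 0
            wend = L
        elif tpl.junction is not None:
            wstart = min(max(0, tpl.junction - read_len // 2), L - read_len)
            wend = wstart + read_len
        else:
            wstart = int(rng.integers(0, L - read_len + 1))
            wend = wstart + read_len
        carries = False
        if tpl.site_off is not None and wstart <= tpl.site_off < wend:
            carries = top[tpl.site_off] == tpl.induced_site[2]
        chim = tpl.junction is not None and wstart < tpl.junction < wend
        out.append(
            SimRead(
                sequence=top[wstart:wend],
                apparent_pos=tpl.apparent_pos[wstart:wend],
                template_id=tpl.template_id,
                start_off=wstart,
                lineage=lineage,
                carries_mutation=carries,
                is_chimeric=chim,
            )
        )
    return out


# ---------------------------------------------------------------------------
# naive pileup caller

def naive_pileup(
    reads: Sequence[SimRead],
    reference: SyntheticReference | str,
    min_vaf: float = 0.01,
    min_alt_reads: int = 2,
    chrom: str = "synth1",
) -> list[VariantRecord]:
    """Per-position allele counting over read placements.

    Bases map to their true positions for the non-chimeric portion and to
    the mirror (apparent) positions for the chimeric copy - emulating the
    misalignment that creates artifact calls. SNVs with alt-read support
    >= ``min_alt_reads`` and VAF >= ``min_vaf`` are emitted.
    """
    refseq, chrom = _ref_and_chrom(reference, chrom)
    if not reads:
        return []
    pos_all = np.concatenate([r.apparent_pos for r in reads])
    base_all = np.concatenate(
        [np.frombuffer(r.sequence.encode(), dtype=np.uint8) for r in reads]
    )
    valid = pos_all >= 0
    pos_all = pos_all[valid]
    base_all = base_all[valid]
    L = len(refseq)
    depth = np.bincount(pos_all, minlength=L)
    ref_codes = np.frombuffer(refseq.encode(), dtype=np.uint8)
    is_alt = base_all != ref_codes[pos_all]
    alt_pos = pos_all[is_alt]
    alt_base = base_all[is_alt]
    keys, counts = np.unique(alt_pos * 256 + alt_base, return_counts=True)
    out: list[VariantRecord] = []
    for key, cnt in zip(keys, counts):
        pos, code = int(key) // 256, int(key) % 256
        base = chr(code)
        if base == "N":
            continue
        dp = int(depth[pos])
        vaf = cnt / dp if dp else 0.0
        if cnt >= min_alt_reads and vaf >= min_vaf:
            out.append(VariantRecord(chrom, pos + 1, refseq[pos], base, vaf=float(vaf)))
    out.sort(key=lambda v: (v.pos, v.alt))
    return out
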