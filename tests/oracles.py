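"""Brute-force reference implementations used as test oracles.

These enumerate structures directly from their definitions (every column
pair, every center, every junction) without the run-merging/seed machinery
of the production scanners, so agreement between the two is meaningful.
"""

from __future__ import annotations

import numpy as np

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def col_state(seq: str, p: int, q: int) -> int:
    """1 = Watson-Crick pair, 0 = mismatch, -1 = N involved."""
    a, b = seq[p], seq[q]
    if a == "N" or b == "N":
        return -1
    return 1 if _COMP[a] == b else 0


# ---------------------------------------------------------------------------
# inverted repeats

def _diag_vals(seq: str, d: int):
    W = len(seq)
    p_lo = max(0, d - W + 1)
    p_hi = (d - 1) // 2
    if p_hi < p_lo:
        return None, p_lo
    vals = np.array([col_state(seq, p, d - p) for p in range(p_lo, p_hi + 1)])
    return vals, p_lo


def _maximal_of_class(valid: np.ndarray) -> np.ndarray:
    """valid[a, b] -> mask of segments not strictly contained in another
    valid segment of the same class (a' <= a, b' >= b)."""
    n = valid.shape[0]
    P = valid.copy()
    for a in range(1, n):
        P[a] |= P[a - 1]
    for b in range(n - 2, -1, -1):
        P[:, b] |= P[:, b + 1]
    sup = np.zeros_like(valid)
    sup[1:, :] |= P[:-1, :]
    sup[:, :-1] |= P[:, 1:]
    return valid & ~sup


def oracle_scan_ivs(seq: str, params) -> set[tuple]:
    """Literal enumeration of maximal imperfect inverted repeats.

    Gapless: every (start, end) column segment on every anti-diagonal with
    pairing ends and at most one internal non-pairing run of length
    <= max_interrupt, kept if maximal in its class. Gapped: every junction
    joining maximal exact pairing on two anti-diagonals differing by
    g <= max_interrupt, left-normalized. Thresholds and the cross-structure
    containment rule mirror the scanner contract.
    """
    W = len(seq)
    eff = params.effective_seed
    found = {}  # key -> record

    def spacer_ok(sp):
        return params.min_spacer <= sp <= params.max_spacer

    def add(a1s, a1e, a2s, a2e, spacer, aligned, ints):
        key = (a1s, a1e, a2s, a2e, ints)
        found.setdefault(key, (a1s, a1e, a2s, a2e, spacer, aligned, ints))

    for d in range(1, 2 * W - 2):
        vals, p_lo = _diag_vals(seq, d)
        if vals is None or not len(vals):
            continue
        n = len(vals)
        A = np.arange(n)[:, None]
        B = np.arange(n)[None, :]
        m = (vals == 0).astype(int)
        nn = (vals == -1).astype(int)
        csm = np.concatenate(([0], np.cumsum(m)))
        csn = np.concatenate(([0], np.cumsum(nn)))
        mc = csm[B + 1] - csm[A]
        nc = csn[B + 1] - csn[A]
        mmidx = np.flatnonzero(vals == 0)
        if len(mmidx):
            pos_a = np.searchsorted(mmidx, np.arange(n), side="left")
            first = np.where(pos_a < len(mmidx), mmidx[np.minimum(pos_a, len(mmidx) - 1)], n)
            pos_b = np.searchsorted(mmidx, np.arange(n), side="right") - 1
            last = np.where(pos_b >= 0, mmidx[np.maximum(pos_b, 0)], -1)
        else:
            first = np.full(n, n)
            last = np.full(n, -1)
        fa = first[A.ravel()].reshape(n, 1)
        lb = last[B.ravel()].reshape(1, n)
        ends_ok = (vals[A.ravel()].reshape(n, 1) == 1) & (
            vals[B.ravel()].reshape(1, n) == 1
        )
        base = (B >= A) & ends_ok & (nc == 0)
        one_run = (
            (mc > 0)
            & (mc <= params.max_interrupt)
            & ((lb - fa + 1) == mc)
            & (fa > A)
            & (lb < B)
        )
        v0 = base & (mc == 0)
        v1 = base & one_run
        for valid, with_mm in ((v0, False), (v1, True)):
            if not valid.any():
                continue
            for a, b in zip(*np.nonzero(_maximal_of_class(valid))):
                a, b = int(a), int(b)
                p1, p2 = p_lo + a, p_lo + b
                aligned = p2 - p1 + 1
                spacer = d - 2 * p2 - 1
                if aligned < params.min_arm or not spacer_ok(spacer):
                    continue
                if with_mm:
                    f, l = int(first[a]), int(last[b])
                    maxblk = max(f - a, b - l)
                    if maxblk < eff:
                        continue
                    s_col, e_col = p_lo + f, p_lo + l
                    ints = (
                        (
                            "mismatch",
                            s_col - p1,
                            (d - e_col) - (d - p2),
                            seq[s_col : e_col + 1],
                            seq[d - e_col : d - s_col + 1],
                            e_col - s_col + 1,
                            s_col - p1,
                            p2 - e_col,
                        ),
                    )
                else:
                    if aligned < eff:
                        continue
                    ints = ()
                add(p1, p2 + 1, d - p2, d - p1 + 1, spacer, aligned, ints)

    # gapped: one bulge of g bases on one arm, exact pairing elsewhere
    for d in range(1, 2 * W - 2):
        vals_d, p_lo_d = _diag_vals(seq, d)
        if vals_d is None:
            continue

        def val_at(vals, p_lo, col):
            i = col - p_lo
            if vals is None or i < 0 or i >= len(vals):
                return -2
            return int(vals[i])

        for g in range(1, params.max_interrupt + 1):
            for side, d_inner in (("gap_arm1", d + g), ("gap_arm2", d - g)):
                vals_i, p_lo_i = _diag_vals(seq, d_inner)
                if vals_i is None:
                    continue
                skip = g + 1 if side == "gap_arm1" else 1
                for jj in range(len(vals_d)):
                    if vals_d[jj] != 1:
                        continue
                    j = p_lo_d + jj
                    if val_at(vals_i, p_lo_i, j + skip) != 1:
                        continue
                    # canonical (left-normalized) junction
                    if (
                        val_at(vals_d, p_lo_d, j - 1) == 1
                        and val_at(vals_i, p_lo_i, j - 1 + skip) == 1
                    ):
                        continue
                    p1 = j
                    while val_at(vals_d, p_lo_d, p1 - 1) == 1:
                        p1 -= 1
                    p3 = j + skip
                    while val_at(vals_i, p_lo_i, p3 + 1) == 1:
                        p3 += 1
                    outer_len = j - p1 + 1
                    inner_len = p3 - (j + skip) + 1
                    aligned = outer_len + inner_len
                    spacer = d_inner - 2 * p3 - 1
                    if aligned < params.min_arm or not spacer_ok(spacer):
                        continue
                    if max(outer_len, inner_len) < eff:
                        continue
                    if side == "gap_arm1":
                        bulge = seq[j + 1 : j + g + 1]
                        ints = (
                            (
                                "gap_arm1",
                                j + 1 - p1,
                                (d - j - 1) - (d_inner - p3),
                                bulge,
                                "",
                                g,
                                outer_len,
                                inner_len,
                            ),
                        )
                    else:
                        bulge = seq[d - j - g : d - j]
                        ints = (
                            (
                                "gap_arm2",
                                j - p1,
                                (d - j - g) - (d_inner - p3),
                                "",
                                bulge,
                                g,
                                outer_len,
                                inner_len,
                            ),
                        )
                    add(p1, p3 + 1, d_inner - p3, d - p1 + 1, spacer, aligned, ints)

    # cross-structure containment (overlaps kept, equal arms kept)
    recs = list(found.values())
    kept = set()
    for r in recs:
        contained = any(
            o is not r
            and o[0] <= r[0]
            and o[1] >= r[1]
            and o[2] <= r[2]
            and o[3] >= r[3]
            and (o[0] < r[0] or o[1] > r[1] or o[2] < r[2] or o[3] > r[3])
            for o in recs
        )
        if not contained:
            kept.add(r)
    return kept


def scanner_ivs_tuples(structs, win0: int = 0) -> set[tuple]:
    """Canonical comparable form of scanner output (window-local coords)."""
    out = set()
    for s in structs:
        ints = tuple(
            (
                i.kind,
                i.arm1_off,
                i.arm2_off,
                i.arm1_bases,
                i.arm2_bases,
                i.length,
                i.left_cols,
                i.right_cols,
            )
            for i in s.interruptions
        )
        out.add(
            (
                s.arm1.start - win0,
                s.arm1.end - win0,
                s.arm2.start - win0,
                s.arm2.end - win0,
                s.spacer_len,
                s.aligned_len,
                ints,
            )
        )
    return out


# ---------------------------------------------------------------------------
# palindromes

def oracle_scan_ps(seq: str, params) -> set[tuple]:
    """Position-by-position central expansion, written from the definition."""
    n = len(seq)
    found = []
    for c in range(n):
        mms = []
        K = 0
        k = 1
        while c - k >= 0 and c + k < n:
            st = col_state(seq, c - k, c + k)
            if st == 1:
                K = k
            else:
                if len(mms) + 1 >= params.stop_mismatches:
                    break
                mms.append(k)
                K = k
            k += 1
        while mms and mms[-1] == K:
            mms.pop()
            K -= 1
        if K < 1:
            continue
        helix = 2 * K + 1
        if helix < params.min_helix:
            continue
        mm = tuple(
            (c - k, c + k, seq[c - k], seq[c + k]) for k in mms
        )
        found.append((c, c - K, c + K + 1, helix, mm))
    kept = set()
    for rec in found:
        c, s, e, helix, mm = rec
        key = tuple((l, r) for l, r, *_ in mm)
        contained = any(
            o is not rec
            and o[3] > helix
            and o[1] <= s
            and o[2] >= e
            and tuple((l, r) for l, r, *_ in o[4]) == key
            for o in found
        )
        if not contained:
            kept.add(rec)
    return kept


def scanner_ps_tuples(palindromes, win0: int = 0) -> set[tuple]:
    out = set()
    for p in palindromes:
        mm = tuple((l - win0, r - win0, bl, br) for l, r, bl, br in p.mismatches)
        out.add(
            (p.center - win0, p.span.start - win0, p.span.end - win0, p.helix_len, mm)
        )
    return out


# ---------------------------------------------------------------------------
# interval padding/merging

def oracle_pad_merge(intervals, pad, chrom_sizes):
    """Mark padded bases on a per-chromosome array; maximal runs are the
    merged regions."""
    out = []
    for chrom in sorted({iv.chrom for iv in intervals}):
        size = chrom_sizes[chrom]
        covered = np.zeros(size, dtype=bool)
        for iv in intervals:
            if iv.chrom == chrom:
                covered[max(0, iv.start - pad) : min(size, iv.end + pad)] = True
        pos = np.flatnonzero(covered)
        if not len(pos):
            continue
        breaks = np.flatnonzero(np.diff(pos) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(pos) - 1]))
        for s, e in zip(starts, ends):
            out.append((chrom, int(pos[s]), int(pos[e]) + 1))
    return out
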