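# Methods

## Model

`foldscan` treats library-preparation chimeras as a deterministic
consequence of reference sequence structure. The PDSM mechanism (pairing
of partial single strands derived from a similar molecule) runs:

1. Fragmentation exposes partial single strands. Sonication breaks the
   duplex at uniform random positions; enzymatic cocktails nick
   preferentially inside palindromes.
2. A strand whose end falls inside one arm of a fold-back structure
   anneals to the complementary arm of a similar molecule (for an inverted
   repeat, the downstream arm is the reverse complement of the upstream
   arm on the *same* strand, so two same-sense strands can pair there).
3. 3′ overhangs are trimmed and the gap is filled by copying the partner
   strand. The filled sequence is the reverse complement of a reference
   segment — the soft-clip signature of the resulting chimeric reads.
4. At every imperfection of the fold-back pairing, the fill writes the
   base that would make pairing perfect. For a mismatched column with arm
   bases `b1`/`b2` the induced allele at the `b2` site is
   `complement(b1)`; a bulge of g bases induces a g-base deletion at its
   own site and an insertion of the reverse-complemented bulge at the
   mirrored site on the partner arm.

Under sonication the repaired template is a heteroduplex; error-free
unbiased PCR keeps the two strand lineages at exactly equal frequency
(from counts `(x_a, x_b)` one cycle gives `(x_a + x_b, x_a + x_b)`), so
the induced allele appears in half of the descendant molecules and hence
in ~50% of sampled chimeric reads. Under enzymatic fragmentation the end
repair resolves the mismatch before amplification, so the template is
homoduplex at the site and every descendant read carries the allele.

Since the induced allele depends only on the reference, all candidate
artifact sites can be precomputed: that is the potential mutation
blacklist (PBIVS for inverted repeats, PBPS for palindromes).

## Inverted-repeat detection

Positions p (upstream arm) and q (downstream arm) pair in a gapless
fold-back alignment iff p + q is constant, so detection enumerates pairing
**anti-diagonals**. Per diagonal, each column is classified as pairing,
mismatch, or N; maximal exact runs are the seeds. Reported structures are:

* an exact run (no interruption);
* two adjacent exact runs bridged by one mismatch run of at most
  `max_interrupt` columns;
* two exact runs on anti-diagonals differing by g ≤ `max_interrupt`,
  which is a single g-base bulge on one arm. The junction is
  left-normalized (the bulge placed as far left as the runs allow), the
  same convention VCF uses for indels.

A structure carries **at most one interruption**. This mirrors the
palindrome scanner's one-mismatch rule and keeps the blacklist selective:
bridging unlimited interruptions makes uniform-random DNA saturate with
spurious "repeats" (measured: >80% of positions blacklisted on a random
2 kb sequence), which would indiscriminately remove true variants.
Structures combining a bulge with mismatches, or with two or more bulges,
are outside the detector's reported classes — a known limitation.

Maximality is applied per class (a run or bridged pair is never
extendable along its diagonal); thresholds (`min_arm` aligned columns,
`min_spacer ≤ spacer ≤ max_spacer`) then *drop* failing structures rather
than trimming them; finally any structure whose two arms are both
contained in another reported structure's arms is removed (overlaps are
kept). The conceptual all-K k-mer enumeration of the workflow is exposed
as `kmer_census` for verification; detection itself requires an exact
block of at least `min(seed_len, ceil((min_arm − max_interrupt)/2))`
columns, the longest block a threshold-qualifying structure is guaranteed
to contain, so seeding never costs completeness. Completeness is the
binding contract: the test suite asserts exact equality with a
brute-force enumeration oracle on hundreds of random windows.

## Palindrome detection

Every position is a candidate center (odd-center: the center base is
unpaired). Expansion compares `seq[c−k]` with `complement(seq[c+k])` for
k = 1, 2, …; the first non-pairing column is recorded as the structure's
internal mismatch and expansion halts immediately before the
`stop_mismatches`-th (default second) one or at a sequence end. A
structure whose outermost column is its mismatch is trimmed to the
perfect core. With one internal mismatch, the longest continuously
matched stretch is `helix_len − 2` (one column lost to the center, one to
the mismatch); this identity is asserted in tests. N counts as a mismatch
for stopping but never produces a blacklist entry. Even (between-base)
centers are available behind `include_even_centers` for blunt-palindrome
chemistries; the default is odd-only.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `pad` | 50 bp | extension of each target region before scanning; blacklist sites are restricted back to the unpadded regions |
| `min_spacer` | 5 bp | minimum loop between IVS arms (N in the criteria) |
| `max_spacer` | 300 bp | search horizon between arms; bounds pairing to intra-fragment distances of short-insert libraries |
| `min_arm` | 8 bp | minimum aligned columns per arm |
| `min_edge` | 2 bp | minimum columns between an interruption and either alignment end for it to be blacklisted (applied at extraction, not detection) |
| `max_interrupt` | 1 bp | largest mismatch run / bulge bridged into one structure; 1 keeps random-sequence hits sparse (see above), larger values are selectable |
| `seed_len` | 8 bp | exact-block requirement, capped at run time as described |
| `min_helix` | 17 bp | minimum palindrome span |
| `stop_mismatches` | 2 | expansion halts before this mismatch count |

Filtering is by position by default (any overlap between the normalized
variant span and an entry span removes the call — conservative for MNVs);
`allele` mode additionally requires the called allele to equal the
predicted artifact allele. Removed records are FILTER-tagged rather than
deleted unless `--drop` is given, keeping clinical-style pipelines
auditable.

## Synthetic data

`make_synthetic_reference` draws an i.i.d. background at the requested GC
(default 0.5) and pastes structure blocks into evenly spaced slots.
Planted structures are made *exactly* maximal: all spacer columns and the
four pairing columns outside each arm are forced non-complementary, and
bulge bases are forced non-pairing on both bounding diagonals — otherwise
chance pairing of flanking bases would extend or reshape the reported
structure in a seed-dependent fraction of runs. True variants are placed
(or validated) away from planted structures and away from every
blacklisted site of the finished sequence, which is what makes the
zero-true-variant-loss property exact rather than statistical; artifact
templates are built from reference-allele molecules, the dominant case at
the low VAFs where these artifacts matter.

Chimera simulation draws sonication breaks uniformly over the molecule
(enzymatic nicks uniformly within the palindrome arms, with shorter
fragments: 60–100 bp vs 120–180 bp), forms the chimeric strand from the
structure geometry, and records for every template the apparent reference
position of each base — the position an aligner would assign, with the
chimeric copy mapped through the arm mirror and clipped where it leaves
the arm. PCR is exact unbiased doubling with zero polymerase error,
isolating the PDSM mechanism from polymerase-fidelity artifacts. Reads
(default 100 bp, single-ended; pairing is not modeled) are truncated
around the junction so they retain both the soft-clip signature and the
induced site, which always lies within one arm length of the junction.
`naive_pileup` counts alleles over those placements and emits SNVs above
`min_vaf`/`min_alt_reads`; it stands in for a production
alignment-and-calling pipeline at desk scale.

What the simulator does **not** emulate: sequencing error, base
qualities, UMI/duplex structure, GC or amplification bias, read pairing,
nick-site sequence preference, and indel artifact *reads* (gap-interrupted
structures are planted and their deletion/insertion blacklist entries are
recovered and filter-tested, but chimeric read formation is simulated for
mismatch imperfections only). Passing tests therefore demonstrate the
mechanism and the blacklist logic, not performance on real sequencing
noise.

## Numerical and design choices

* Coordinates are 0-based half-open everywhere internally; VCF positions
  convert at the boundary. Multi-allelic records are split per alternate
  allele.
* Indel blacklist entries and variant spans are left-aligned against the
  reference; allele comparison first trims shared affixes.
* Both positions of a mismatched pair are blacklisted, because the copy
  direction of the chimera depends on which strand seeds it.
* Ambiguity codes other than N are rejected; N never pairs, terminates
  extension, and never yields an allele prediction.
* Ties in structure maximality are broken leftmost (arm 1 start, then
  arm 2 start); output order is deterministic, as are all simulations
  given a seed.
* Scanning cost is O(W²) in window length with small vectorized
  constants; intended inputs are padded panel regions (10²–10³ bp), for
  which a full scan takes milliseconds to a few seconds.

## Verification problem sizes

The test suite runs both scanners against independent brute-force oracles
on 100 random 300 bp windows each (including N-containing windows and a
wider `max_interrupt=3` setting); verifies the 50% heteroduplex
prediction on 10,000+ chimeric reads from 1,000 templates; and closes the
full simulate → blacklist → pileup → filter loop on 20 random 1.2 kb
references with planted IVS + PS structures and two true variants each,
requiring 100% artifact-call removal and 0% true-variant removal.
`scripts/acceptance.py` recomputes the 50% quantity from scratch at the
same sizes.
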