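# foldscan

Detection of fold-back DNA structures — imperfect **inverted repeat
sequences (IVS)** and **palindromic sequences (PS)** — in panel target
regions, and filtering of variant calls at the artifact-prone sites these
structures create during sequencing library preparation.

## The problem

Hybridization-capture panels routinely show unexpected low-VAF SNVs and
indels that trace back to library preparation, not biology. The mechanism
(the **PDSM** model: *pairing of partial single strands derived from a
similar molecule*) is that fragmentation exposes partial single strands;
wherever the genome carries an inverted repeat or a palindrome, a strand
ending inside one arm can anneal to the other arm of a similar molecule.
Exonuclease trimming and polymerase fill then produce a chimeric template.
If the fold-back pairing is imperfect, the fill writes the *pairing-perfect*
base at each imperfection — a predictable artifact variant:

* at a mismatched column with arm bases `b1`/`b2`, the induced allele at
  the `b2` site is `complement(b1)` (and symmetrically);
* at a bulge of g unpaired bases, a g-base deletion on the bulge arm and a
  g-base insertion of the reverse-complemented bulge on the partner arm.

Sonication breaks double strands anywhere, so the repaired template is a
**heteroduplex** — one strand original, one strand mutated — and unbiased
PCR propagates the mutation into exactly **50% of the chimeric
(soft-clipped) reads**. Enzymatic fragmentation nicks inside palindromes
and the mismatch is resolved *before* amplification (homoduplex), so all
chimeric reads from such a template carry it.

Because the artifact allele is fully determined by the reference sequence,
the sites can be enumerated ahead of time. `foldscan` scans the (padded)
target regions, extracts every qualifying imperfection into a **potential
mutation blacklist** (PBIVS ∪ PBPS), and partitions VCF calls against it.
Default criteria: arm-to-arm spacer ≥ 5 bp, per-arm alignment ≥ 8 bp,
interruption ≥ 2 bp from the arm ends, palindrome helix ≥ 17 bp, regions
padded by 50 bp.

A simulator closes the loop without any external data: it plants structures
and true variants in a synthetic reference, forms PDSM chimeras for both
chemistries, amplifies and samples reads, calls variants with a naive
pileup, and verifies that blacklist filtering removes every induced
artifact call while keeping every true variant.

## Worked example

```python
from foldscan import (
    IVSParams, PSParams, SyntheticSpec, PlantedIVS, PlantedVariant,
    make_synthetic_reference, simulate_sonication_chimeras,
    pcr_and_sample, naive_pileup, build_blacklist, filter_variants,
    GenomicInterval,
)

spec = SyntheticSpec(
    length=600,
    planted_ivs=(PlantedIVS(arm_len=12, spacer_len=6,
                            interruptions=((4, "mismatch", 1),)),),
    seed=17,
)
ref = make_synthetic_reference(spec)
ivs = ref.structures[0]
print(ivs.arm1, ivs.arm2, ivs.expected_entries)

het = [t for t in simulate_sonication_chimeras(ref, ivs, 5000, seed=17)
       if t.heteroduplex]
reads = [r for r in pcr_and_sample(het[:1000], cycles=10, n_reads=11000,
                                   seed=17) if r.is_chimeric]
frac = sum(r.carries_mutation for r in reads) / len(reads)
print(f"{100 * frac:.1f}% of chimeric reads carry the induced mutation")
```

prints

```
GenomicInterval(chrom='synth1', start=285, end=297) GenomicInterval(chrom='synth1', start=303, end=315) [(289, 290, 'C', 'G'), (310, 311, 'C', 'G')]
49.1% of chimeric reads carry the induced mutation
```

The planted repeat sits at 285–315 with its mismatched pair at positions
289/310; those two sites, with the pairing-perfect allele `C>G` on each
side, are exactly what the blacklist predicts, and half of the chimeric
reads from the heteroduplex templates carry the induced base — the PDSM
50% prediction.

On real files the same flow is three commands:

```bash
foldscan build-blacklist -r ref.fa -b panel.bed -o panel.blacklist.tsv
foldscan scan-ivs -r ref.fa -b panel.bed -o ivs_report.tsv
foldscan filter -v calls.vcf -B panel.blacklist.tsv -o calls.tagged.vcf
```

Removed records are FILTER-tagged `ivps_blacklist` (use `--drop` to delete
them) and annotated with the structure that predicted the site.

## Layout

| module | contents |
| --- | --- |
| `foldscan.genome_io` | intervals, FASTA/BED/VCF I/O, reverse complement, allele normalization |
| `foldscan.ivs_scanner` | inverted-repeat detection (anti-diagonal pairing runs), k-mer census, PBIVS extraction |
| `foldscan.ps_scanner` | palindrome detection by central expansion, PBPS extraction |
| `foldscan.blacklist` | blacklist assembly/serialization and the VCF filter |
| `foldscan.pdsm_simulator` | synthetic references, chimera formation for both chemistries, PCR/read sampling, naive pileup |
| `foldscan.cli` | `foldscan` command with build-blacklist / scan-ivs / scan-ps / filter / simulate / end-to-end |

See `docs/methods.md` for the model, parameter semantics and limitations.
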