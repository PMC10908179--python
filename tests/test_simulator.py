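import pytest

from foldscan.genome_io import GenomicInterval, ReferenceWindow, reverse_complement
from foldscan.ivs_scanner import IVSParams, ivs_blacklist, scan_ivs
from foldscan.pdsm_simulator import (
    PlantedIVS,
    PlantedPS,
    PlantedVariant,
    SyntheticSpec,
    make_synthetic_reference,
    naive_pileup,
    pcr_and_sample,
    pcr_molecule_count,
    simulate_enzymatic_chimeras,
    simulate_plain_templates,
    simulate_sonication_chimeras,
)
from foldscan.ps_scanner import PSParams, ps_blacklist, scan_ps


def whole_window(ref):
    iv = GenomicInterval(ref.chrom, 0, len(ref.seq))
    return ReferenceWindow(iv, ref.seq, (iv,))


class TestMakeSyntheticReference:
    def test_planted_ivs_recovered_exactly(self):
        spec = SyntheticSpec(
            length=600,
            planted_ivs=(PlantedIVS(arm_len=12, spacer_len=6, interruptions=((4, "mismatch", 1),)),),
            seed=17,
        )
        ref = make_synthetic_reference(spec)
        win = whole_window(ref)
        truth = ref.structures[0]
        match = [
            s for s in scan_ivs(win, IVSParams())
            if s.arm1 == truth.arm1.__class__(ref.chrom, truth.arm1.start, truth.arm1.end)
            and (s.arm2.start, s.arm2.end) == (truth.arm2.start, truth.arm2.end)
        ]
        assert len(match) == 1
        assert match[0].spacer_len == 6 and match[0].aligned_len == 12

    def test_empty_spec_truth_table(self):
        ref = make_synthetic_reference(SyntheticSpec(length=200, seed=1))
        assert ref.structures == [] and ref.true_variants == []
        assert len(ref.seq) == 200

    def test_determinism_byte_identical_fasta(self, tmp_path):
        spec = SyntheticSpec(length=400, planted_ps=(PlantedPS(),), seed=9)
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        make_synthetic_reference(spec).to_fasta(p1)
        make_synthetic_reference(spec).to_fasta(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_overlapping_plants_rejected(self):
        spec = SyntheticSpec(length=80, planted_ivs=(PlantedIVS(), PlantedIVS()), seed=0)
        with pytest.raises(ValueError, match="overlap"):
            make_synthetic_reference(spec)

    @pytest.mark.parametrize("seed", range(8))
    def test_planted_sites_always_blacklisted(self, seed):
        """100% recovery: every expected artifact site of every planted
        structure appears in the scanners' blacklist."""
        spec = SyntheticSpec(
            length=1200,
            planted_ivs=(PlantedIVS(),),
            planted_ps=(PlantedPS(),),
            true_variants=(PlantedVariant(vaf=0.3),),
            seed=seed,
        )
        ref = make_synthetic_reference(spec)
        win = whole_window(ref)
        ip, pp = IVSParams(), PSParams()
        got = {
            (e.start, e.end, e.ref, e.predicted_alt)
            for e in ivs_blacklist(scan_ivs(win, ip), win, ip)
            + ps_blacklist(scan_ps(win, pp), win, pp)
        }
        assert set(ref.expected_blacklist_sites) <= got

    @pytest.mark.parametrize("kind", ["gap_arm1", "gap_arm2"])
    def test_planted_gap_yields_indel_sites(self, kind):
        spec = SyntheticSpec(
            length=700,
            planted_ivs=(PlantedIVS(arm_len=12, spacer_len=6, interruptions=((5, kind, 2),)),),
            seed=3,
        )
        ref = make_synthetic_reference(spec)
        win = whole_window(ref)
        params = IVSParams(max_interrupt=2)
        got = {
            (e.start, e.end, e.ref, e.predicted_alt)
            for e in ivs_blacklist(scan_ivs(win, params), win, params)
        }
        exp = set(ref.expected_blacklist_sites)
        assert exp <= got
        # one deletion-style and one insertion-style site
        lens = sorted(len(r) - len(a) for _, _, r, a in exp)
        assert lens == [-2, 2]


class TestChimeraFormation:
    def _ivs_ref(self, seed=17):
        spec = SyntheticSpec(
            length=600,
            planted_ivs=(PlantedIVS(arm_len=12, spacer_len=6, interruptions=((4, "mismatch", 1),)),),
            seed=seed,
        )
        ref = make_synthetic_reference(spec)
        return ref, ref.structures[0]

    def test_sonication_heteroduplex_structure(self):
        ref, ivs = self._ivs_ref()
        tpls = simulate_sonication_chimeras(ref, ivs, 3000, seed=1)
        het = [t for t in tpls if t.heteroduplex]
        assert het, "breaks inside arms must produce heteroduplexes"
        for t in het[:50]:
            pos, rbase, alt = t.induced_site
            assert ref.seq[pos] == rbase
            assert t.top_a[t.site_off] == rbase  # strand A keeps the original
            assert t.top_b[t.site_off] == alt    # strand B carries the induced base
            # induced allele is the one the blacklist predicts at that site
            assert (pos, pos + 1, rbase, alt) in set(ivs.expected_entries)

    def test_chimeric_templates_have_reverse_complement_tail(self):
        ref, ivs = self._ivs_ref()
        tpls = [t for t in simulate_sonication_chimeras(ref, ivs, 2000, seed=2) if t.is_chimeric]
        assert tpls
        for t in tpls[:50]:
            head, tail = t.seq[: t.junction], t.seq[t.junction :]
            parts = sorted((head, tail), key=len)
            # one part aligns forward, the other is the reverse complement of
            # a reference segment (the soft-clip signature)
            assert head in ref.seq or tail in ref.seq
            rc_part = tail if head in ref.seq else head
            if len(rc_part) >= 8:
                assert reverse_complement(rc_part) in ref.seq

    def test_breaks_outside_arms_are_plain(self):
        ref, ivs = self._ivs_ref()
        tpls = simulate_sonication_chimeras(ref, ivs, 500, seed=3)
        for t in tpls:
            if not t.is_chimeric:
                assert t.induced_site is None and t.seq in ref.seq

    def test_zero_templates(self):
        ref, ivs = self._ivs_ref()
        assert simulate_sonication_chimeras(ref, ivs, 0, seed=1) == []

    def test_enzymatic_homoduplex_before_amplification(self):
        spec = SyntheticSpec(length=500, planted_ps=(PlantedPS(),), seed=8)
        ref = make_synthetic_reference(spec)
        ps = ref.structures[0]
        tpls = simulate_enzymatic_chimeras(ref, ps, 1000, seed=4)
        with_site = [t for t in tpls if t.induced_site]
        assert with_site
        for t in with_site[:50]:
            assert not t.heteroduplex
            assert t.top_a[t.site_off] == t.top_b[t.site_off] == t.induced_site[2]
            assert t.is_chimeric  # mutation always coupled with a junction

    def test_perfect_palindrome_induces_no_variant(self):
        spec = SyntheticSpec(length=500, planted_ps=(PlantedPS(mismatch_k=None),), seed=8)
        ref = make_synthetic_reference(spec)
        tpls = simulate_enzymatic_chimeras(ref, ref.structures[0], 300, seed=5)
        assert all(t.induced_site is None for t in tpls)
        assert all(t.is_chimeric for t in tpls)


class TestPCRAndSampling:
    def test_molecule_count_doubles(self):
        assert pcr_molecule_count(1) == 2
        assert pcr_molecule_count(10) == 1024
        with pytest.raises(ValueError):
            pcr_molecule_count(0)

    def test_heteroduplex_mutated_fraction_is_half(self):
        spec = SyntheticSpec(
            length=600,
            planted_ivs=(PlantedIVS(arm_len=12, spacer_len=6, interruptions=((4, "mismatch", 1),)),),
            seed=17,
        )
        ref = make_synthetic_reference(spec)
        het = [
            t for t in simulate_sonication_chimeras(ref, ref.structures[0], 20000, seed=17)
            if t.heteroduplex
        ][:1000]
        reads = [r for r in pcr_and_sample(het, cycles=10, n_reads=12000, seed=17) if r.is_chimeric]
        assert len(reads) >= 10000
        frac = sum(r.carries_mutation for r in reads) / len(reads)
        se = (0.25 / len(reads)) ** 0.5
        assert abs(frac - 0.5) <= 3 * se

    def test_homoduplex_fraction_is_one(self):
        spec = SyntheticSpec(length=500, planted_ps=(PlantedPS(),), seed=8)
        ref = make_synthetic_reference(spec)
        tpls = [t for t in simulate_enzymatic_chimeras(ref, ref.structures[0], 500, seed=6) if t.induced_site]
        reads = [
            r for r in pcr_and_sample(tpls, cycles=4, n_reads=3000, seed=7)
            if r.is_chimeric
        ]
        assert reads
        # both strands carry the induced base, so every chimeric read that
        # spans the site reports the mutation (sites sit within one arm
        # length of the junction, inside every centered read)
        assert sum(r.carries_mutation for r in reads) == len(reads)

    def test_determinism(self):
        spec = SyntheticSpec(length=500, planted_ivs=(PlantedIVS(),), seed=2)
        ref = make_synthetic_reference(spec)
        tpls = simulate_sonication_chimeras(ref, ref.structures[0], 500, seed=9)
        r1 = pcr_and_sample(tpls, 5, 500, seed=11)
        r2 = pcr_and_sample(tpls, 5, 500, seed=11)
        assert [r.sequence for r in r1] == [r.sequence for r in r2]
        assert [r.carries_mutation for r in r1] == [r.carries_mutation for r in r2]

    def test_cycles_required(self):
        with pytest.raises(ValueError):
            pcr_and_sample([], cycles=0, n_reads=1)


class TestNaivePileup:
    def test_true_variant_called_at_its_vaf(self):
        spec = SyntheticSpec(length=800, true_variants=(PlantedVariant(vaf=0.3),), seed=4)
        ref = make_synthetic_reference(spec)
        tv = ref.true_variants[0]
        tpls = simulate_plain_templates(ref, 2000, seed=5)
        reads = pcr_and_sample(tpls, cycles=5, n_reads=15000, seed=6)
        calls = naive_pileup(reads, ref, min_vaf=0.05, min_alt_reads=3)
        assert [(c.pos, c.ref, c.alt) for c in calls] == [(tv.pos, tv.ref, tv.alt)]
        assert calls[0].vaf == pytest.approx(0.3, abs=0.08)

    def test_induced_site_called_with_predicted_alt(self):
        spec = SyntheticSpec(
            length=600,
            planted_ivs=(PlantedIVS(arm_len=12, spacer_len=6, interruptions=((4, "mismatch", 1),)),),
            seed=17,
        )
        ref = make_synthetic_reference(spec)
        het = [
            t for t in simulate_sonication_chimeras(ref, ref.structures[0], 4000, seed=8)
            if t.heteroduplex
        ]
        reads = pcr_and_sample(het, cycles=5, n_reads=4000, seed=9)
        calls = naive_pileup(reads, ref, min_vaf=0.05, min_alt_reads=5)
        expected = {(p + 1, r, a) for p, _, r, a in
                    ((p0, p0 + 1, r, a) for p0, _, r, a in ref.structures[0].expected_entries)}
        got = {(c.pos, c.ref, c.alt) for c in calls}
        assert got & expected, "the heteroduplex site must be called"

    def test_min_alt_reads_gate(self):
        spec = SyntheticSpec(length=400, true_variants=(PlantedVariant(vaf=0.3),), seed=4)
        ref = make_synthetic_reference(spec)
        tpls = simulate_plain_templates(ref, 50, seed=5)
        reads = pcr_and_sample(tpls, cycles=3, n_reads=200, seed=6)
        assert naive_pileup(reads, ref, min_vaf=0.0, min_alt_reads=10**6) == []
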