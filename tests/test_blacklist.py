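import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from foldscan.blacklist import (
    Blacklist,
    BlacklistEntry,
    build_blacklist,
    filter_variants,
    read_blacklist,
    verify_against_reference,
    write_blacklist,
)
from foldscan.genome_io import GenomicInterval, VariantRecord
from foldscan.pdsm_simulator import (
    PlantedIVS,
    PlantedPS,
    SyntheticSpec,
    make_synthetic_reference,
)


@pytest.fixture
def planted_reference(tiny_fasta):
    spec = SyntheticSpec(
        length=1200, planted_ivs=(PlantedIVS(),), planted_ps=(PlantedPS(),), seed=11
    )
    ref = make_synthetic_reference(spec)
    path = tiny_fasta({ref.chrom: ref.seq})
    return ref, path


def _entry(chrom="chr1", start=10, ref="A", alt="G", source="IVS", sid="IVS:x"):
    return BlacklistEntry(chrom, start, start + len(ref), ref, alt, source, sid)


class TestBuildBlacklist:
    def test_planted_structures_recovered(self, planted_reference):
        ref, path = planted_reference
        bed = [GenomicInterval(ref.chrom, 0, len(ref.seq))]
        bl = build_blacklist(path, bed, pad=0)
        got = {(e.start, e.end, e.ref, e.predicted_alt) for e in bl.entries}
        for site in ref.expected_blacklist_sites:
            assert site in got
        assert not verify_against_reference(bl, path)

    def test_union_of_separate_builds(self, planted_reference):
        ref, path = planted_reference
        bed = [GenomicInterval(ref.chrom, 0, len(ref.seq))]
        both = build_blacklist(path, bed, pad=0)
        ivs_only = build_blacklist(path, bed, pad=0, sources=("IVS",))
        ps_only = build_blacklist(path, bed, pad=0, sources=("PS",))
        assert set(both.entries) == set(ivs_only.entries) | set(ps_only.entries)

    def test_empty_bed_warns_and_is_empty(self, planted_reference):
        _, path = planted_reference
        with pytest.warns(UserWarning, match="empty BED"):
            bl = build_blacklist(path, [])
        assert len(bl) == 0 and bl.params_fingerprint

    def test_structure_straddling_bed_boundary_restricted(self, planted_reference):
        ref, path = planted_reference
        ivs = next(s for s in ref.structures if s.kind == "IVS")
        # region ends well before the structure: its sites sit in the pad only
        bed = [GenomicInterval(ref.chrom, max(0, ivs.arm1.start - 60), ivs.arm1.start - 40)]
        bl = build_blacklist(path, bed, pad=50)
        sites = {(e.start, e.end) for e in bl.entries}
        for s0, s1, *_ in ivs.expected_entries:
            assert (s0, s1) not in sites

    def test_deterministic(self, planted_reference):
        ref, path = planted_reference
        bed = [GenomicInterval(ref.chrom, 0, len(ref.seq))]
        assert build_blacklist(path, bed).entries == build_blacklist(path, bed).entries


class TestFilterVariants:
    bl = Blacklist(
        (
            _entry("chr1", 10, "A", "G"),
            _entry("chr1", 50, "CTT", "C", sid="IVS:y"),
        ),
        "fp",
    )

    def test_position_mode_partitions(self):
        variants = [
            VariantRecord("chr1", 11, "A", "G"),   # on entry, same allele
            VariantRecord("chr1", 11, "A", "C"),   # on entry, different allele
            VariantRecord("chr1", 52, "T", "A"),   # inside the indel span
            VariantRecord("chr1", 30, "G", "T"),   # clear
            VariantRecord("chr2", 11, "A", "G"),   # other chromosome
        ]
        retained, removed = filter_variants(variants, self.bl, mode="position")
        assert len(retained) == 2 and len(removed) == 3
        assert {v.pos for v in retained} == {30, 11}
        assert all(v.extra.get("struct") for v in removed)
        assert sorted(v.pos for v in retained + removed) == sorted(
            v.pos for v in variants
        )

    def test_allele_mode_requires_predicted_alt(self):
        variants = [
            VariantRecord("chr1", 11, "A", "G"),
            VariantRecord("chr1", 11, "A", "C"),
        ]
        retained, removed = filter_variants(variants, self.bl, mode="allele")
        assert [v.alt for v in removed] == ["G"]
        assert [v.alt for v in retained] == ["C"]

    def test_idempotent(self):
        variants = [VariantRecord("chr1", i, "A", "G") for i in (5, 11, 40)]
        r1, _ = filter_variants(variants, self.bl)
        r2, _ = filter_variants(r1, self.bl)
        assert r1 == r2

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_fuzzed_partition_and_idempotence(self, seed):
        rng = np.random.default_rng(seed)
        variants = []
        for _ in range(60):
            pos = int(rng.integers(1, 80))
            ref = "ACGT"[rng.integers(4)]
            alt = "ACGT"[rng.integers(4)]
            if alt == ref:
                alt = ref + "T"  # turn collisions into insertions
            variants.append(VariantRecord("chr1", pos, ref, alt))
        retained, removed = filter_variants(variants, self.bl)
        assert len(retained) + len(removed) == len(variants)
        keys = lambda vs: sorted((v.chrom, v.pos, v.ref, v.alt) for v in vs)
        assert keys(retained + removed) == keys(variants)
        r2, rm2 = filter_variants(retained, self.bl)
        assert r2 == retained and rm2 == []

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            filter_variants([], self.bl, mode="strict")


class TestBlacklistIO:
    def test_round_trip(self, tmp_path):
        bl = Blacklist((_entry(), _entry(start=20, ref="T", alt="TAC")), "ref=x;pad=50")
        path = tmp_path / "bl.tsv"
        write_blacklist(bl, path)
        back = read_blacklist(path)
        assert back.entries == bl.entries
        assert back.params_fingerprint == bl.params_fingerprint

    def test_empty_round_trip(self, tmp_path):
        bl = Blacklist((), "ref=x")
        path = tmp_path / "bl.tsv"
        write_blacklist(bl, path)
        back = read_blacklist(path)
        assert back.entries == () and back.params_fingerprint == "ref=x"

    def test_hand_written_entry(self, tmp_path):
        path = tmp_path / "bl.tsv"
        path.write_text(
            "#params:ref=toy.fa;pad=50\n"
            "chr9\t7\t8\tG\tC\tPS\tPS:chr9:12\n"
        )
        (entry,) = read_blacklist(path).entries
        assert entry == BlacklistEntry("chr9", 7, 8, "G", "C", "PS", "PS:chr9:12")

    def test_missing_fingerprint_warns(self, tmp_path):
        path = tmp_path / "bl.tsv"
        path.write_text("chr9\t7\t8\tG\tC\tPS\tPS:chr9:12\n")
        with pytest.warns(UserWarning, match="fingerprint"):
            read_blacklist(path)

    def test_duplicate_entries_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Blacklist((_entry(), _entry()), "fp")

    def test_entry_invariants(self):
        with pytest.raises(ValueError):
            BlacklistEntry("chr1", 5, 6, "A", "A", "IVS", "x")
        with pytest.raises(ValueError):
            BlacklistEntry("chr1", 5, 7, "A", "G", "IVS", "x")
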