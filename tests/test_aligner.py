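import random

import pytest

from mirnome.aligner import (
    AlignerConfig,
    ReferenceIndex,
    TagAssignment,
    Unmapped,
    align_library,
    align_tag,
)
from mirnome.reference_io import GenomeLocus, PrecursorRecord, revcomp
from mirnome.tag_io import Library, Tag

from brute_oracle import oracle_align
from conftest import MAT_A, MAT_B


@pytest.fixture(scope="module")
def index(toy_records, toy_groups):
    return ReferenceIndex(toy_records, toy_groups, mode="precursor")


CFG = AlignerConfig.precursor_default()


def mutate(seq, pos, base):
    assert seq[pos] != base
    return seq[:pos] + base + seq[pos + 1 :]


class TestArchetypes:
    """The four canonical read archetypes the stratified search must resolve."""

    def test_exact_canonical_maps_at_step0_iteration0(self, index):
        a = align_tag(Tag(MAT_B, 1), index, CFG)
        assert isinstance(a, TagAssignment)
        assert (a.step, a.iteration, a.mismatches, a.nta_suffix) == (0, 0, 0, "")
        assert (a.offset5, a.offset3) == (0, 0)

    def test_pure_nta_trimmed_at_step0(self, index):
        a = align_tag(Tag(MAT_B + "AA", 1), index, CFG)
        assert (a.step, a.iteration, a.mismatches, a.nta_suffix) == (0, 2, 0, "AA")
        assert a.offset3 == 0

    def test_inner_mismatch_maps_at_step1_full_length(self, index):
        tag = Tag(mutate(MAT_B, 8, "C"), 1)
        a = align_tag(tag, index, CFG)
        assert (a.step, a.iteration, a.mismatches, a.nta_suffix) == (1, 0, 1, "")
        assert a.mismatch_positions == ((8, MAT_B[8], "C"),)

    def test_mixed_nta_and_variant_reports_only_the_variant(self, index):
        # NTA plus one inner substitution: the suffix is trimmed at the
        # higher-mismatch step and only the genomic variation remains
        tag = Tag(mutate(MAT_B, 8, "C") + "AA", 1)
        a = align_tag(tag, index, CFG)
        assert (a.step, a.iteration, a.mismatches) == (1, 2, 1)
        assert a.nta_suffix == "AA"
        assert a.mismatch_positions == ((8, MAT_B[8], "C"),)


class TestAmbiguityRules:
    def test_multilocus_hit_kept_with_shared_group(self, index):
        a = align_tag(Tag(MAT_A, 1), index, CFG)
        assert isinstance(a, TagAssignment)
        assert a.group.member_precursors == ("mir-a-1", "mir-a-2")

    def test_equidistant_family_members_discarded(self, index, toy_records):
        # one substitution placing the tag at Hamming distance 1 from both
        # miR-b1-5p and its near-paralog miR-b2-5p
        tag = Tag(mutate(MAT_B, 4, "G"), 1)
        res = align_tag(tag, index, CFG)
        assert res == Unmapped(tag, "ambiguous")

    def test_antisense_match_rejected_in_precursor_mode(self, index):
        tag = Tag(revcomp(MAT_A), 1)
        res = align_tag(tag, index, CFG)
        assert res == Unmapped(tag, "antisense_only")

    def test_match_outside_canonical_window_reported(self, index, toy_records):
        rec = next(r for r in toy_records if r.precursor_id == "mir-c")
        tag = Tag(rec.sequence[40:60], 1)
        res = align_tag(tag, index, CFG)
        assert res == Unmapped(tag, "out_of_window")

    def test_window_boundary_is_inclusive(self, index, toy_records):
        rec = next(r for r in toy_records if r.precursor_id == "mir-c")
        m5 = rec.mature("5p")
        at_window = Tag(rec.sequence[m5.start - 5 : m5.end], 1)
        beyond = Tag(rec.sequence[m5.start - 6 : m5.end], 1)
        a = align_tag(at_window, index, CFG)
        assert isinstance(a, TagAssignment) and a.offset5 == -5
        assert align_tag(beyond, index, CFG) == Unmapped(beyond, "out_of_window")


class TestLibraryStats:
    def test_all_exact_library_maps_fully_at_step0(self, index, toy_groups):
        tags = [Tag(MAT_B, 10), Tag(MAT_A, 5)]
        lib = Library("s", tags, library_size=15)
        _, stats = align_library(lib, index, CFG)
        assert stats.step_fraction(0) == 1.0

    def test_fractions_weight_reads_not_tags(self, index):
        lib = Library("s", [Tag(MAT_B, 999), Tag("ACGT" * 5, 1)], library_size=1000)
        _, stats = align_library(lib, index, CFG)
        assert stats.mapped_fraction == pytest.approx(0.999)

    def test_empty_reference_is_hard_error(self, toy_groups):
        with pytest.raises(ValueError, match="empty"):
            ReferenceIndex([], toy_groups, mode="precursor")


def random_tags(records, n, seed):
    """Tags spanning the interesting regimes: isomiR slices, NTAs,
    substitutions, antisense reads and unrelated sequence."""
    rng = random.Random(seed)
    matures = [(r, m) for r in records for m in r.matures]
    tags = []
    for _ in range(n):
        kind = rng.random()
        if kind < 0.8:
            rec, m = rng.choice(matures)
            o5 = rng.randint(-7, 7)
            o3 = rng.randint(-7, 7)
            s, e = max(0, m.start + o5), min(len(rec.sequence), m.end + o3)
            seq = rec.sequence[s:e]
            for _ in range(rng.randint(0, 3)):
                p = rng.randrange(len(seq))
                seq = seq[:p] + rng.choice("ACGT".replace(seq[p], "")) + seq[p + 1 :]
            seq += "".join(rng.choice("ACGT") for _ in range(rng.randint(0, 3)))
            if rng.random() < 0.1:
                seq = revcomp(seq)
        else:
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(18, 26)))
        if len(seq) >= 18:
            tags.append(Tag(seq, 1))
    return tags


def as_oracle_tuple(result):
    if isinstance(result, TagAssignment):
        return ("mapped", result.step, result.iteration, result.mismatches)
    return ("unmapped",)


class TestOracleEquivalence:
    def test_randomized_tags_match_brute_force(self, toy_records, toy_groups, index):
        # mature ids are the grouping key, so the oracle's map is identity
        mature_group = {m.mature_id: m.mature_id for r in toy_records for m in r.matures}
        for tag in random_tags(toy_records, 150, seed=3):
            expected = oracle_align(tag.sequence, toy_records, mature_group)
            got = align_tag(tag, index, CFG)
            assert as_oracle_tuple(got) == expected[:4], tag.sequence
            if expected[0] == "mapped":
                assert got.mature_id in expected[4]

    def test_monotonicity_in_window_and_ladder(self, toy_records, toy_groups, index):
        wide = AlignerConfig(mismatch_ladder=(0, 1, 2, 3), window=7)
        narrow = AlignerConfig(mismatch_ladder=(0, 1), window=3)
        idx = index
        for tag in random_tags(toy_records, 60, seed=5):
            base = align_tag(tag, idx, CFG)
            if isinstance(base, TagAssignment):
                assert isinstance(align_tag(tag, idx, wide), TagAssignment)
            if isinstance(align_tag(tag, idx, narrow), TagAssignment):
                assert isinstance(base, TagAssignment)

    def test_nta_conservation(self, toy_records, index):
        for tag in random_tags(toy_records, 80, seed=9):
            res = align_tag(tag, index, CFG)
            if isinstance(res, TagAssignment):
                assert res.mapped_sequence + res.nta_suffix == tag.sequence
                assert len(res.nta_suffix) == res.iteration

    def test_reverse_complement_of_mapped_tag_is_antisense(self, toy_records, index):
        n_checked = 0
        for tag in random_tags(toy_records, 200, seed=13):
            res = align_tag(tag, index, CFG)
            if isinstance(res, TagAssignment) and res.mismatches == 0 and res.iteration == 0:
                flipped = Tag(revcomp(tag.sequence), 1)
                back = align_tag(flipped, index, CFG)
                assert back == Unmapped(flipped, "antisense_only")
                n_checked += 1
        assert n_checked > 5


@pytest.fixture(scope="module")
def genome_setup(toy_records, toy_groups):
    """Toy genome embedding each precursor, alternating strands."""
    parts, pos, placed = [], 0, []
    rng = random.Random(42)
    for i, rec in enumerate(toy_records):
        spacer = "".join(rng.choice("ACGT") for _ in range(30))
        parts.append(spacer)
        pos += len(spacer)
        strand = "+" if i % 2 == 0 else "-"
        insert = rec.sequence if strand == "+" else revcomp(rec.sequence)
        placed.append(PrecursorRecord(
            rec.precursor_id, rec.sequence, rec.matures,
            genome_locus=GenomeLocus("chrT", pos, pos + len(rec.sequence), strand)))
        parts.append(insert)
        pos += len(insert)
    genome = {"chrT": "".join(parts)}
    index = ReferenceIndex(placed, toy_groups, mode="genome", genome=genome)
    return placed, genome, index


GCFG = AlignerConfig.genome_default()


class TestGenomeMode:
    def test_plus_and_minus_strand_loci_give_zero_offsets(self, genome_setup):
        placed, _, index = genome_setup
        for rec in placed:
            for m in rec.matures:
                a = align_tag(Tag(m.canonical_sequence, 1), index, GCFG)
                assert isinstance(a, TagAssignment), m.mature_id
                assert (a.offset5, a.offset3) == (0, 0)

    def test_multilocus_genome_hits_kept(self, genome_setup):
        _, _, index = genome_setup
        a = align_tag(Tag(MAT_A, 1), index, GCFG)
        assert isinstance(a, TagAssignment)
        assert set(a.group.member_precursors) == {"mir-a-1", "mir-a-2"}

    def test_max_trim_limits_nta_removal(self, genome_setup, index):
        _, _, gindex = genome_setup
        tag = Tag(MAT_B + "AAAA", 1)
        a = align_tag(tag, index, CFG)  # precursor mode trims all 4 bases
        assert isinstance(a, TagAssignment) and a.nta_suffix == "AAAA"
        res = align_tag(tag, gindex, GCFG)  # genome: max 2 trimmed bases
        assert isinstance(res, Unmapped)

    def test_extra_genomic_copy_triggers_repeat_discard(self, toy_records, toy_groups):
        # plant a second, non-miRNA copy of miR-b1's mature in the genome
        rec = next(r for r in toy_records if r.precursor_id == "mir-b1")
        genome = {"chrT": "GGCCAAGGCC" + rec.sequence + "TTCCGGAA" + MAT_B + "CCGGTTAA"}
        placed = [PrecursorRecord(
            rec.precursor_id, rec.sequence, rec.matures,
            genome_locus=GenomeLocus("chrT", 10, 10 + len(rec.sequence), "+"))]
        index = ReferenceIndex(placed, toy_groups, mode="genome", genome=genome)
        tag = Tag(MAT_B, 1)
        assert align_tag(tag, index, GCFG) == Unmapped(tag, "ambiguous")

    def test_minus_strand_mismatch_reported_in_mature_frame(self, genome_setup):
        placed, _, index = genome_setup
        minus = next(r for r in placed if r.genome_locus.strand == "-")
        m = minus.matures[0]
        tag = Tag(mutate(m.canonical_sequence, 6, {"A": "C"}.get(m.canonical_sequence[6], "A")), 1)
        a = align_tag(tag, index, GCFG)
        assert isinstance(a, TagAssignment)
        assert a.mismatch_positions[0][0] == 6
        assert a.mismatch_positions[0][1] == m.canonical_sequence[6]
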