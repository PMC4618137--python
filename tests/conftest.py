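import pytest

from mirnome.reference_io import (
    MatureAnnotation,
    PrecursorRecord,
    build_multilocus_groups,
)
from mirnome.simulate import SimConfig, simulate


def make_precursor(prec_id, mature5=None, mature3=None, flank5="ACGTACGTACGT",
                   loop="CCGCGTTTAAGGCCG", flank3="GCGCGTACGTAC"):
    """Assemble a precursor from explicit mature sequences."""
    parts = [flank5]
    matures = []
    pos = len(flank5)
    if mature5:
        mid, seq = mature5
        matures.append(MatureAnnotation(mid, "5p", pos, pos + len(seq), seq))
        parts.append(seq)
        pos += len(seq)
    parts.append(loop)
    pos += len(loop)
    if mature3:
        mid, seq = mature3
        matures.append(MatureAnnotation(mid, "3p", pos, pos + len(seq), seq))
        parts.append(seq)
        pos += len(seq)
    parts.append(flank3)
    return PrecursorRecord(prec_id, "".join(parts), tuple(matures))


def make_assignment(group, count, offset5=0, offset3=0, nta="", mismatches=(),
                    step=0, seq=None):
    """A synthetic TagAssignment for analytics-level tests."""
    from mirnome.aligner import TagAssignment
    from mirnome.tag_io import Tag

    length = len(group.canonical_sequence) + offset3 - offset5 + len(nta)
    sequence = seq or ("A" * max(length, 18))
    return TagAssignment(
        tag=Tag(sequence, count), mature_id=group.base_name, group=group,
        step=step, iteration=len(nta), mismatches=len(mismatches),
        nta_suffix=nta, offset5=offset5, offset3=offset3,
        mismatch_positions=tuple(mismatches),
    )


MAT_A = "TGAGGTAGTAGGTTGTATAGCG"  # 22 nt, C/G tail
MAT_B = "CACTAGATTGTGAGCTCCTGCG"
MAT_C = "TTCAAGTAATCCAGGATAGGCG"


@pytest.fixture(scope="session")
def toy_records():
    """Two loci sharing one mature (multi-locus group) + two family paralogs
    differing by 2 nt + one unrelated both-arm precursor."""
    par_b2 = MAT_B[:4] + "GA" + MAT_B[6:]  # Hamming distance 2 from MAT_B
    return [
        make_precursor("mir-a-1", mature5=("miR-a-5p", MAT_A),
                       flank5="GGCCTTAAGGCCAT", flank3="TTGACCAGTGCA"),
        make_precursor("mir-a-2", mature5=("miR-a-5p", MAT_A),
                       flank5="TCTCTAGAGAGA", flank3="CATGGATCCATG"),
        make_precursor("mir-b1", mature5=("miR-b1-5p", MAT_B)),
        make_precursor("mir-b2", mature5=("miR-b2-5p", par_b2),
                       flank5="AATTGGCCAATT", flank3="GGATCCGGATCC"),
        make_precursor("mir-c", mature5=("miR-c-5p", MAT_C),
                       mature3=("miR-c-3p", "AGGCAACAAATCAGTATTGGCG"),
                       flank5="CAGTCAGTCAGT", flank3="GTCAGTCAGTCA"),
    ]


@pytest.fixture(scope="session")
def toy_groups(toy_records):
    return build_multilocus_groups(toy_records)


@pytest.fixture(scope="session")
def sim_small():
    """Moderate-depth simulation shared across unit tests."""
    return simulate(SimConfig(depth=20_000, seed=7))
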