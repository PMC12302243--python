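import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repdeplete.errors import LocusError, ValidationError
from repdeplete.repertoire_metrics import (
    AbundanceVector,
    clonality,
    sample_overlap,
    split_vd2,
    top_n_overlap,
    top_n_proportion,
)

from conftest import make_rec, make_sample


def ab(counts, key=None):
    return AbundanceVector(counts=dict(counts), key=key)


# --- clonality ---------------------------------------------------------------


def test_uniform_repertoire_has_zero_clonality():
    assert clonality(ab({"a": 1, "b": 1, "c": 1, "d": 1})) == pytest.approx(0.0)


def test_single_clone_is_fully_clonal():
    assert clonality(ab({"only": 7})) == 1.0


def test_clonality_hand_computed_value():
    # counts [2,1,1]: H = 1.03972, ln 3 = 1.09861 -> 1 - H/ln3 = 0.0536
    assert clonality(ab({"a": 2, "b": 1, "c": 1})) == pytest.approx(0.0536, abs=1e-3)


def test_clonality_rejects_empty():
    with pytest.raises(ValidationError):
        clonality(ab({}))


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.integers(min_value=1, max_value=1000), min_size=1, max_size=20))
def test_clonality_in_unit_interval_and_label_invariant(counts):
    vec = ab({f"c{i}": c for i, c in enumerate(counts)})
    relabeled = ab({f"zz{i}": c for i, c in enumerate(counts)})
    value = clonality(vec)
    assert 0.0 <= value <= 1.0 + 1e-12
    assert clonality(relabeled) == pytest.approx(value)


# --- top-N proportion ---------------------------------------------------------


def test_top_n_proportion_examples():
    vec = ab({"a": 50, "b": 30, "c": 20})
    assert top_n_proportion(vec, 2) == pytest.approx(0.8)
    assert top_n_proportion(vec, 3) == 1.0
    assert top_n_proportion(vec, 10) == 1.0  # n beyond richness uses all clones


def test_top_n_proportion_tie_value_is_stable():
    vec = ab({"a": 5, "b": 5, "c": 5})
    assert top_n_proportion(vec, 2) == pytest.approx(10 / 15)


@settings(derandomize=True, max_examples=30)
@given(st.lists(st.integers(min_value=1, max_value=50), min_size=1, max_size=15))
def test_top_n_proportion_nondecreasing_in_n(counts):
    vec = ab({f"c{i}": c for i, c in enumerate(counts)})
    values = [top_n_proportion(vec, n) for n in range(1, len(counts) + 2)]
    assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
    assert values[-1] == pytest.approx(1.0)


# --- sample overlap -----------------------------------------------------------


def test_overlap_is_one_when_all_followup_known():
    base = make_sample([make_rec("b1", sequence="AAAA"), make_rec("b2", sequence="CCCC")])
    follow = make_sample([make_rec("f1", sequence="AAAA", duplicate_count=3)])
    assert sample_overlap(follow, base).overlap_fraction == 1.0


def test_overlap_zero_for_disjoint_sets():
    base = make_sample([make_rec("b1", sequence="AAAA")])
    follow = make_sample([make_rec("f1", sequence="TTTT")])
    assert sample_overlap(follow, base).overlap_fraction == 0.0


def test_overlap_counts_molecules():
    base = make_sample([make_rec("b1", sequence="AAAA")])
    follow = make_sample(
        [make_rec(f"f{i}", sequence=s) for i, s in enumerate("AAAA TTTT GGGG CCCC".split())]
    )
    assert sample_overlap(follow, base).overlap_fraction == pytest.approx(0.25)


def test_self_overlap_is_one_with_large_cap():
    sample = make_sample(
        [make_rec(f"r{i}", sequence=f"AA{s}AA", duplicate_count=i + 1)
         for i, s in enumerate(("CC", "GG", "TT"))]
    )
    result = sample_overlap(sample, sample, baseline_cap=10**6, seed=1)
    assert result.overlap_fraction == 1.0


def test_overlap_baseline_cap_applies():
    base = make_sample([make_rec(f"b{i}", sequence=f"S{i}", duplicate_count=10)
                        for i in range(10)])
    # cap below baseline size: the reference set is a strict subsample
    follow = make_sample([make_rec("f", sequence="S0")])
    result = sample_overlap(follow, base, baseline_cap=30, seed=0)
    assert result.n_baseline_reference == 30


def test_overlap_rejects_locus_mismatch():
    base = make_sample([make_rec("b", locus="TRB")], locus="TRB")
    follow = make_sample([make_rec("f", locus="IGH")], locus="IGH")
    with pytest.raises(LocusError):
        sample_overlap(follow, base)


# --- top-N overlap ------------------------------------------------------------


def test_top_n_overlap_examples():
    key = {c: f"seq_{c}" for c in "ABCD"}
    base = ab({"A": 10, "B": 8, "C": 1}, key=key)
    follow = ab({"B": 9, "C": 7, "D": 1}, key=key)
    assert top_n_overlap(base, follow, 2) == pytest.approx(0.5)  # {A,B} vs {B,C}
    same = ab({"A": 10, "B": 8}, key=key)
    assert top_n_overlap(same, same, 2) == 1.0
    disjoint_follow = ab({"D": 5}, key=key)
    assert top_n_overlap(base, disjoint_follow, 2) == 0.0


def test_top_n_overlap_symmetric_at_full_richness():
    key = {c: f"s{c}" for c in "ABCDEF"}
    base = ab({"A": 9, "B": 7, "C": 5, "D": 1}, key=key)
    follow = ab({"C": 9, "D": 7, "E": 5, "F": 1}, key=key)
    assert top_n_overlap(base, follow, 3) == top_n_overlap(follow, base, 3)


def test_top_n_overlap_denominator_is_followup_richness_when_small():
    key = {c: f"s{c}" for c in "AB"}
    base = ab({"A": 5, "B": 3}, key=key)
    follow = ab({"A": 2}, key=key)
    assert top_n_overlap(base, follow, 10) == 1.0


# --- Vd2 partition ------------------------------------------------------------


def test_split_vd2_is_definitional_and_conserving():
    records = [
        make_rec(f"p{i}", locus="TRD", v_call="TRDV2*01", j_call="TRDJ1*01")
        for i in range(4)
    ] + [
        make_rec(f"m{i}", locus="TRD", v_call=f"TRDV{g}*01", j_call="TRDJ1*01")
        for i, g in enumerate([1, 1, 3, 3, 1, 3])
    ]
    sample = make_sample(records, locus="TRD")
    plus, minus = split_vd2(sample)
    assert len(plus) == 4 and len(minus) == 6
    assert all(r.v_call.startswith("TRDV2") for r in plus.records)
    # idempotent: re-splitting the plus stratum changes nothing
    plus2, empty = split_vd2(plus)
    assert len(plus2) == 4 and len(empty) == 0
    assert plus.total_molecules + minus.total_molecules == sample.total_molecules


def test_split_vd2_rejects_other_loci(trb_sample):
    with pytest.raises(LocusError):
        split_vd2(trb_sample)
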