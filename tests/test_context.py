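"""Orientation classification, separations and the distance rule."""
import pytest

from tfrctx.context import (
    Group,
    Thresholds,
    arrangement,
    boundary_gap,
    classify_context,
    extract_igr,
    intergenic_separation,
    neighbors,
    predict_targets,
    translational_start,
)
from tfrctx.model import GeneRecord, Replicon
from tfrctx.reference import REPRESSED_PANEL, reference_context_calls

from conftest import make_bundle, make_replicon
from helpers_oracle import brute_force_classify


def g(locus, strand, start, end, rid="chr1"):
    return GeneRecord(rid, locus, strand, start, end)


# --- translational start -----------------------------------------------------

@pytest.mark.parametrize("strand,expected", [("+", 100), ("-", 400)])
def test_translational_start_is_first_base_of_start_codon(strand, expected):
    assert translational_start(g("x", strand, 100, 400)) == expected


def test_translational_start_mirrors_under_replicon_reversal():
    rep = make_replicon([("x", "+", 100, 400)], length=1000)
    mirrored = rep.mirror().gene("x")
    # base 100 on the forward strand maps to base 901 of the mirror
    assert translational_start(mirrored) == 1000 - 100 + 1


# --- neighbors ---------------------------------------------------------------

def test_neighbors_middle_gene(three_gene_replicon):
    rep = three_gene_replicon
    left, right = neighbors(rep, rep.gene("B"))
    assert (left.locus_tag, right.locus_tag) == ("A", "C")


def test_neighbors_linear_ends_are_absent(three_gene_replicon):
    rep = three_gene_replicon
    left, right = neighbors(rep, rep.gene("A"))
    assert left is None and right.locus_tag == "B"
    left, right = neighbors(rep, rep.gene("C"))
    assert left.locus_tag == "B" and right is None


def test_neighbors_wrap_on_circular_replicon():
    rep = make_replicon(
        [("A", "+", 100, 400), ("B", "-", 600, 900), ("C", "+", 1200, 1500)],
        topology="circular",
    )
    left, right = neighbors(rep, rep.gene("A"))
    assert (left.locus_tag, right.locus_tag) == ("C", "B")


def test_neighbors_unknown_gene_raises(three_gene_replicon):
    with pytest.raises(KeyError):
        neighbors(three_gene_replicon, g("zz", "+", 1, 10))


# --- arrangement & separations ----------------------------------------------

@pytest.mark.parametrize(
    "sa,sb,expected",
    [("-", "+", "divergent"), ("+", "-", "convergent"), ("+", "+", "tandem"), ("-", "-", "tandem")],
)
def test_arrangement(sa, sb, expected):
    assert arrangement(g("a", sa, 10, 90), g("b", sb, 200, 290)) == expected


def test_arrangement_order_violation_raises():
    with pytest.raises(ValueError):
        arrangement(g("a", "+", 200, 290), g("b", "-", 10, 90))


def test_separation_counts_bases_strictly_between_starts():
    # '-' gene start codon at 500, '+' gene start codon at 611: positions
    # 501..610 lie strictly between, i.e. 110 bp (enumerated independently)
    left = g("l", "-", 200, 500)
    right = g("r", "+", 611, 900)
    enumerated = len(range(501, 611))
    sep = intergenic_separation(left, right)
    assert enumerated == 110
    assert sep.raw_bp == 110 and sep.clamped_bp == 110


def test_separation_abutting_starts_is_zero():
    sep = intergenic_separation(g("l", "-", 200, 500), g("r", "+", 501, 900))
    assert sep.raw_bp == 0


def test_separation_requires_divergent_pair():
    with pytest.raises(ValueError, match="divergent"):
        intergenic_separation(g("l", "+", 200, 500), g("r", "+", 601, 900))


@pytest.mark.parametrize(
    "left_end,right_start,expected", [(100, 121, 20), (100, 101, 0), (100, 97, -4)]
)
def test_boundary_gap_signed(left_end, right_start, expected):
    assert boundary_gap(g("l", "+", 10, left_end), g("r", "+", right_start, 400)) == expected


def test_boundary_gap_rejects_different_strands():
    with pytest.raises(ValueError):
        boundary_gap(g("l", "+", 10, 100), g("r", "-", 200, 300))


# --- classification ----------------------------------------------------------

def test_divergent_neighbor_at_any_distance():
    bundle = make_bundle([("n", "-", 100, 400), ("t", "+", 1401, 1900)])
    (call,) = classify_context(bundle, ["t"])
    assert call.group is Group.DIVERGENT
    assert call.divergent_neighbor == "n"
    assert call.separation.clamped_bp == 1000
    assert not call.mixed_flag


def test_operonic_when_same_strand_within_gap():
    bundle = make_bundle(
        [("u", "+", 100, 400), ("t", "+", 421, 900), ("c", "-", 1000, 1300)]
    )
    (call,) = classify_context(bundle, ["t"])
    assert call.group is Group.OPERONIC
    assert call.operonic_neighbors == ("u",)


def test_overlapping_same_strand_counts_as_operonic():
    bundle = make_bundle([("u", "+", 100, 400), ("t", "+", 397, 900)])
    (call,) = classify_context(bundle, ["t"])
    assert call.group is Group.OPERONIC


def test_mixed_context_is_divergent_with_flag():
    # divergent on the left, co-transcribed within 10 bp on the right
    bundle = make_bundle(
        [("n", "-", 100, 400), ("t", "+", 501, 900), ("d", "+", 911, 1300)]
    )
    (call,) = classify_context(bundle, ["t"])
    assert call.group is Group.DIVERGENT and call.mixed_flag
    assert call.operonic_neighbors == ("d",)


def test_other_when_no_relationship():
    bundle = make_bundle(
        [("u", "+", 100, 400), ("t", "+", 501, 900), ("c", "-", 1000, 1300)]
    )
    (call,) = classify_context(bundle, ["t"])
    assert call.group is Group.OTHER


def test_unknown_locus_raises_listing_offender():
    bundle = make_bundle([("t", "+", 100, 400)])
    with pytest.raises(KeyError, match="nope"):
        classify_context(bundle, ["t", "nope"])


def test_operon_gap_boundary_exactly_35():
    bundle = make_bundle([("u", "+", 100, 400), ("t", "+", 436, 900)])
    (call,) = classify_context(bundle, ["t"])
    assert call.group is Group.OPERONIC
    bundle2 = make_bundle([("u", "+", 100, 400), ("t", "+", 437, 900)])
    (call2,) = classify_context(bundle2, ["t"])
    assert call2.group is Group.OTHER


def test_classification_matches_brute_force_oracle():
    """Random 20-gene replicons: implementation vs exhaustive case analysis."""
    import numpy as np

    rng = np.random.default_rng(2024)
    for trial in range(60):
        pos = 1
        genes = []
        for i in range(20):
            length = int(rng.integers(90, 600))
            gap = int(rng.integers(0, 120))
            start = pos + gap
            genes.append(
                (f"g{i:02d}", "+-"[int(rng.integers(0, 2))], start, start + length)
            )
            pos = start + length
        topology = "circular" if trial % 3 == 0 else "linear"
        rep = make_replicon(genes, topology=topology)
        bundle = make_bundle(genes, topology=topology)
        loci = [t[0] for t in genes]
        calls = {c.tfr_locus: c.group.value for c in classify_context(bundle, loci)}
        for locus in loci:
            assert calls[locus] == brute_force_classify(rep, locus), (
                trial, locus, genes,
            )


def test_strand_flip_invariance_of_groups_and_separations():
    genes = [
        ("a", "-", 100, 400), ("t1", "+", 511, 900),   # divergent, 110 bp
        ("u", "+", 1200, 1500), ("t2", "+", 1521, 1900),  # operonic
        ("v", "+", 2100, 2400), ("t3", "+", 2600, 2900),  # other
    ]
    bundle = make_bundle(genes)
    loci = ["t1", "t2", "t3"]
    fwd = {
        c.tfr_locus: (c.group, c.separation.clamped_bp if c.separation else None)
        for c in classify_context(bundle, loci)
    }
    rev = {
        c.tfr_locus: (c.group, c.separation.clamped_bp if c.separation else None)
        for c in classify_context(bundle.mirror(), loci)
    }
    assert fwd == rev


# --- target prediction -------------------------------------------------------

def test_reference_panel_five_predictions():
    calls = reference_context_calls()
    preds = predict_targets(calls, Thresholds())
    predicted = {p.tfr_locus for p in preds if p.predicted}
    assert predicted == REPRESSED_PANEL
    assert len(preds) == 9


def test_threshold_zero_predicts_nothing():
    preds = predict_targets(
        reference_context_calls(), Thresholds(target_distance_max=0)
    )
    assert sum(p.predicted for p in preds) == 0


def test_prediction_count_monotone_in_threshold():
    calls = reference_context_calls()
    counts = [
        sum(
            p.predicted
            for p in predict_targets(calls, Thresholds(target_distance_max=t))
        )
        for t in range(0, 1201, 10)
    ]
    assert counts == sorted(counts)
    assert counts[-1] == 9


def test_strict_less_flag():
    calls = reference_context_calls()
    at_212 = Thresholds(target_distance_max=212, threshold_inclusive=True)
    strictly = Thresholds(target_distance_max=212, threshold_inclusive=False)
    assert sum(p.predicted for p in predict_targets(calls, at_212)) == 6
    assert sum(p.predicted for p in predict_targets(calls, strictly)) == 5


def test_non_divergent_calls_yield_no_prediction():
    bundle = make_bundle([("u", "+", 100, 400), ("t", "+", 421, 900)])
    calls = classify_context(bundle, ["t"])
    assert predict_targets(calls) == []


# --- IGR extraction ----------------------------------------------------------

def _seq_bundle():
    seq = "".join("ACGT"[(i // 3) % 4] for i in range(2000))
    genes = [("n", "-", 101, 400), ("t", "+", 511, 900)]
    return make_bundle(genes, length=2000, sequence=seq)


def test_extract_igr_length_equals_separation():
    bundle = _seq_bundle()
    (call,) = classify_context(bundle, ["t"])
    sl = extract_igr(bundle.replicons[0], call)
    assert len(sl.sequence) == call.separation.raw_bp == 110
    assert (sl.start, sl.end) == (401, 510)
    assert (sl.bed_start, sl.bed_end) == (400, 510)
    assert sl.sequence == bundle.replicons[0].sequence[400:510]


def test_extract_igr_strand_flip_gives_reverse_complement():
    from tfrctx.model import reverse_complement

    bundle = _seq_bundle()
    (call,) = classify_context(bundle, ["t"])
    fwd = extract_igr(bundle.replicons[0], call)
    mirrored = bundle.mirror()
    (mcall,) = classify_context(mirrored, ["t"])
    rev = extract_igr(mirrored.replicons[0], mcall)
    assert rev.sequence == reverse_complement(fwd.sequence)


def test_extract_igr_abutting_starts_empty_with_warning():
    seq = "A" * 1000
    bundle = make_bundle([("n", "-", 101, 400), ("t", "+", 401, 700)],
                         length=1000, sequence=seq)
    (call,) = classify_context(bundle, ["t"])
    with pytest.warns(UserWarning, match="empty IGR"):
        sl = extract_igr(bundle.replicons[0], call)
    assert sl.sequence == ""


def test_extract_igr_requires_sequence():
    bundle = make_bundle([("n", "-", 101, 400), ("t", "+", 511, 900)])
    (call,) = classify_context(bundle, ["t"])
    with pytest.raises(ValueError, match="no sequence"):
        extract_igr(bundle.replicons[0], call)
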