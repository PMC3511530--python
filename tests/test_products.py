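"""Rule-driven categorisation of target-gene products."""
import pytest

from tfrctx.context import Thresholds, classify_context, predict_targets
from tfrctx.model import DomainHit, GeneRecord
from tfrctx.products import (
    CategoryRule,
    ProductCategory,
    categorize_all,
    categorize_product,
    load_rules,
    parse_category,
)

from conftest import make_bundle


def gene(product, locus="gx"):
    return GeneRecord("chr1", locus, "+", 100, 400, "CDS", product)


def test_builtin_table_loads_with_core_rules():
    rules = load_rules()
    assert len(rules) >= 6
    patterns = {(r.pattern.lower(), r.match_kind) for r in rules}
    for expected in [
        ("mfs", "keyword"), ("abc", "keyword"), ("rnd", "keyword"),
        ("cl09931", "accession"), ("cl09933", "accession"),
    ]:
        assert expected in patterns
    assert [r.priority for r in rules] == sorted(r.priority for r in rules)


def test_user_table_overrides_builtin(tmp_path):
    p = tmp_path / "rules.tsv"
    p.write_text(
        "pattern\tmatch_kind\tcategory\tpriority\n"
        "widget\tkeyword\tENZYME:5\t1\n"
    )
    rules = load_rules(p)
    assert len(rules) == 1
    call = categorize_product(gene("widget maker"), [], rules)
    assert call.category == ProductCategory("ENZYME", ec_class=5)


def test_duplicate_priorities_rejected(tmp_path):
    p = tmp_path / "rules.tsv"
    p.write_text(
        "pattern\tmatch_kind\tcategory\tpriority\n"
        "a\tkeyword\tENZYME:1\t1\nb\tkeyword\tENZYME:2\t1\n"
    )
    with pytest.raises(ValueError, match="duplicate"):
        load_rules(p)


def test_malformed_category_label_named_error():
    with pytest.raises(ValueError, match="WIDGETASE"):
        parse_category("WIDGETASE")
    with pytest.raises(ValueError, match="EC class"):
        parse_category("ENZYME:x")


@pytest.mark.parametrize(
    "product,hits,major,sub",
    [
        ("MFS transporter", [], "MEMBRANE_TRANSPORTER", "MFS"),
        ("ABC transporter permease", [], "MEMBRANE_TRANSPORTER", "ABC"),
        ("putative oxidoreductase", [], "ENZYME", 1),
        ("acyltransferase", [], "ENZYME", 2),
        ("glycosyl hydrolase", [], "ENZYME", 3),
        ("protein of unknown function, EC 6", [], "ENZYME", 6),
        ("integral membrane protein", [], "MEMBRANE_OTHER", None),
        ("transcriptional regulator", [], "OTHER_PROTEIN", None),
        ("hypothetical protein", [], "UNKNOWN", None),
    ],
)
def test_keyword_categorisation(product, hits, major, sub):
    call = categorize_product(gene(product), hits, load_rules())
    assert call.category.major == major
    if major == "ENZYME":
        assert call.category.ec_class == sub
    elif major == "MEMBRANE_TRANSPORTER":
        assert call.category.transporter_family == sub


def test_rossmann_fold_domain_hit_gives_ec1():
    hits = [DomainHit("gx", "cl09931", "NADB_Rossmann")]
    call = categorize_product(gene("conserved protein"), hits, load_rules())
    assert call.category == ProductCategory("ENZYME", ec_class=1)
    assert "cl09931" in call.evidence


def test_unknown_has_no_matched_rule():
    call = categorize_product(gene("hypothetical protein"), [], load_rules())
    assert call.category.major == "UNKNOWN"
    assert call.matched_rule is None


def test_transporter_rule_outranks_enzyme_rule():
    """An ABC pump with a nucleotide-binding (enzyme-looking) annotation
    still counts as a transporter: pump rules carry lower priority."""
    call = categorize_product(
        gene("ABC transporter ATP-binding protein, dehydrogenase-like"),
        [], load_rules(),
    )
    assert call.category.major == "MEMBRANE_TRANSPORTER"
    assert call.category.transporter_family == "ABC"


def test_rule_application_is_priority_deterministic(tmp_path):
    rows = [
        "pump\tkeyword\tMEMBRANE_TRANSPORTER:other\t5",
        "pump\tkeyword\tENZYME:1\t9",
    ]
    header = "pattern\tmatch_kind\tcategory\tpriority\n"
    a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
    a.write_text(header + "\n".join(rows) + "\n")
    b.write_text(header + "\n".join(reversed(rows)) + "\n")
    ga = categorize_product(gene("proton pump"), [], load_rules(a))
    gb = categorize_product(gene("proton pump"), [], load_rules(b))
    assert ga.category == gb.category == ProductCategory("MEMBRANE_TRANSPORTER", transporter_family="other")


def _pipeline(products):
    genes = []
    pos = 100
    loci = []
    for i, product in enumerate(products):
        n, t = f"n{i}", f"t{i}"
        genes.append((n, "-", pos, pos + 300, product))
        genes.append((t, "+", pos + 401, pos + 800))
        loci.append(t)
        pos += 1200
    bundle = make_bundle(genes)
    calls = classify_context(bundle, loci)
    preds = predict_targets(calls, Thresholds())
    return bundle, preds


def test_categorize_all_tally_and_invariants():
    bundle, preds = _pipeline(
        ["NADH dehydrogenase", "putative oxidoreductase", "MFS transporter", "hypothetical protein"]
    )
    calls, summary = categorize_all(preds, bundle, [], load_rules())
    assert summary.counts["ENZYME"] == 2
    assert summary.counts["MEMBRANE_TRANSPORTER"] == 1
    assert summary.counts["UNKNOWN"] == 1
    assert sum(summary.counts.values()) == summary.n_targets == 4
    assert sum(summary.ec_counts.values()) == summary.counts["ENZYME"]
    assert summary.frac_within_threshold["ENZYME"] == 1.0


def test_categorize_all_empty_predictions():
    calls, summary = categorize_all([], make_bundle([("x", "+", 1, 10)]), [], load_rules())
    assert calls == [] and summary.n_targets == 0
    assert sum(summary.counts.values()) == 0


def test_planted_categories_fully_recovered():
    """Generator round-trip: product labels planted on divergent neighbors
    come back through classification + categorisation unchanged."""
    from tfrctx.simulate import FixtureSpec, generate_fixture, tfr_loci

    bundle, truth = generate_fixture(
        FixtureSpec(n_tfr=18, group_mix=(1.0, 0.0, 0.0), separation_range=(40, 190), seed=11)
    )
    calls = classify_context(bundle, tfr_loci(truth))
    preds = predict_targets(calls, Thresholds())
    cat_calls, _ = categorize_all(preds, bundle, [], load_rules())
    by_locus = {e.true_neighbor: e.true_category for e in truth.entries}
    for call in cat_calls:
        assert call.category.label == by_locus[call.locus_tag]
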