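"""Categorisation of predicted target-gene products.

Target products are sorted into the survey categories: enzymes by top-level
EC class (1 oxidoreductases .. 6 ligases), membrane transporters by family
(MFS / ABC / RND / other), other membrane proteins, other proteins (e.g.
regulators), and unknowns. Assignment is rule-table driven: each rule is a
domain accession, a domain-name substring, or a product-text keyword mapped
to a category, and the lowest-priority-number match wins. The packaged
default table puts transporter rules ahead of enzyme rules so that ABC
pumps — whose nucleotide-binding domains look enzymatic — count as
transporters; no sequence-based domain detection is performed here, hit
tables are taken as given.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import DomainHit, GeneRecord

MAJORS = ("ENZYME", "MEMBRANE_TRANSPORTER", "MEMBRANE_OTHER", "OTHER_PROTEIN", "UNKNOWN")
TRANSPORTER_FAMILIES = ("MFS", "ABC", "RND", "other")


@dataclass(frozen=True)
class ProductCategory:
    major: str
    ec_class: Optional[int] = None
    transporter_family: Optional[str] = None

    def __post_init__(self) -> None:
        if self.major not in MAJORS:
            raise ValueError(f"unknown major category {self.major!r}")
        if (self.major == "ENZYME") != (self.ec_class is not None):
            raise ValueError("ec_class present iff major is ENZYME")
        if self.ec_class is not None and not 1 <= self.ec_class <= 6:
            raise ValueError("ec_class must be 1..6")
        if (self.major == "MEMBRANE_TRANSPORTER") != (self.transporter_family is not None):
            raise ValueError("transporter_family present iff major is MEMBRANE_TRANSPORTER")
        if self.transporter_family is not None and self.transporter_family not in TRANSPORTER_FAMILIES:
            raise ValueError(f"unknown transporter family {self.transporter_family!r}")

    @property
    def label(self) -> str:
        if self.major == "ENZYME":
            return f"ENZYME:{self.ec_class}"
        if self.major == "MEMBRANE_TRANSPORTER":
            return f"MEMBRANE_TRANSPORTER:{self.transporter_family}"
        return self.major


UNKNOWN = ProductCategory("UNKNOWN")


def parse_category(label: str) -> ProductCategory:
    """Parse labels like ENZYME:1, MEMBRANE_TRANSPORTER:MFS, UNKNOWN."""
    major, _, sub = label.partition(":")
    if major == "ENZYME":
        if not sub.isdigit():
            raise ValueError(f"ENZYME category needs an EC class 1..6, got {label!r}")
        return ProductCategory("ENZYME", ec_class=int(sub))
    if major == "MEMBRANE_TRANSPORTER":
        return ProductCategory("MEMBRANE_TRANSPORTER", transporter_family=sub or "other")
    if sub:
        raise ValueError(f"category {major!r} takes no subtype, got {label!r}")
    return ProductCategory(major)


@dataclass(frozen=True)
class CategoryRule:
    pattern: str
    match_kind: str  # accession | name | keyword
    category: ProductCategory
    priority: int

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("rule pattern must be non-empty")
        if self.match_kind not in ("accession", "name", "keyword"):
            raise ValueError(f"unknown match_kind {self.match_kind!r}")

    def matches(self, locus: GeneRecord, hits: Sequence[DomainHit]) -> Optional[str]:
        """Evidence string when the rule fires, else None."""
        p = self.pattern.lower()
        if self.match_kind == "accession":
            for h in hits:
                if h.domain_accession.lower() == p:
                    return f"domain accession {h.domain_accession}"
        elif self.match_kind == "name":
            for h in hits:
                if p in h.domain_name.lower():
                    return f"domain name {h.domain_name}"
        else:
            if p in locus.product_text.lower():
                return f"product text {locus.product_text!r}"
        return None


@dataclass(frozen=True)
class CategoryCall:
    locus_tag: str
    category: ProductCategory
    matched_rule: Optional[CategoryRule]
    evidence: str

    def __post_init__(self) -> None:
        if (self.matched_rule is None) != (self.category.major == "UNKNOWN"):
            raise ValueError("matched_rule absent iff category UNKNOWN")


def load_rules(path=None) -> list[CategoryRule]:
    """Load a rule table (TSV: pattern/match_kind/category/priority).

    With ``path=None`` the packaged default table is used; a user-supplied
    table replaces it entirely. Duplicate priorities are an error so that
    rule application never depends on file order.
    """
    if path is None:
        with resources.files("tfrctx.data").joinpath("category_rules.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    missing = {"pattern", "match_kind", "category", "priority"} - set(df.columns)
    if missing:
        raise ValueError(f"rule table missing columns: {sorted(missing)}")
    if df["priority"].duplicated().any():
        dupes = sorted(df.loc[df["priority"].duplicated(), "priority"].unique())
        raise ValueError(f"duplicate rule priorities: {dupes}")
    rules = [
        CategoryRule(
            pattern=str(r.pattern),
            match_kind=str(r.match_kind),
            category=parse_category(str(r.category)),
            priority=int(r.priority),
        )
        for r in df.itertuples(index=False)
    ]
    rules.sort(key=lambda r: r.priority)
    return rules


def categorize_product(
    locus: GeneRecord,
    hits: Sequence[DomainHit],
    rules: Sequence[CategoryRule],
) -> CategoryCall:
    """First matching rule (lowest priority number) decides the category;
    no informative match yields UNKNOWN."""
    own_hits = [h for h in hits if h.locus_tag == locus.locus_tag]
    for rule in sorted(rules, key=lambda r: r.priority):
        evidence = rule.matches(locus, own_hits)
        if evidence is not None:
            return CategoryCall(locus.locus_tag, rule.category, rule, evidence)
    return CategoryCall(locus.locus_tag, UNKNOWN, None, "no rule matched")


@dataclass
class CategorySummary:
    counts: dict[str, int]            # by major category
    ec_counts: dict[int, int]         # within ENZYME, by EC class
    family_counts: dict[str, int]     # within MEMBRANE_TRANSPORTER
    frac_within_threshold: dict[str, float]  # per major, fraction predicted
    n_targets: int


def categorize_all(
    predictions,
    bundle,
    hits: Iterable[DomainHit],
    rules: Sequence[CategoryRule],
) -> tuple[list[CategoryCall], CategorySummary]:
    """Categorise every predicted-target locus and tally the categories.

    Also reports, per major category, the fraction of divergent targets
    whose separation fell within the prediction threshold (the quantity
    that shows distance, not product type, drives regulatory likelihood).
    """
    hits = list(hits)
    calls = []
    counts = {m: 0 for m in MAJORS}
    ec_counts = {k: 0 for k in range(1, 7)}
    family_counts = {f: 0 for f in TRANSPORTER_FAMILIES}
    within = {m: 0 for m in MAJORS}
    for pred in predictions:
        _, gene = bundle.find(pred.target_locus)
        call = categorize_product(gene, hits, rules)
        calls.append(call)
        cat = call.category
        counts[cat.major] += 1
        if cat.major == "ENZYME":
            ec_counts[cat.ec_class] += 1
        if cat.major == "MEMBRANE_TRANSPORTER":
            family_counts[cat.transporter_family] += 1
        if pred.predicted:
            within[cat.major] += 1
    frac = {
        m: (within[m] / counts[m]) if counts[m] else 0.0 for m in MAJORS
    }
    summary = CategorySummary(
        counts={m: c for m, c in counts.items()},
        ec_counts=ec_counts,
        family_counts=family_counts,
        frac_within_threshold=frac,
        n_targets=len(calls),
    )
    assert sum(counts.values()) == summary.n_targets
    assert sum(ec_counts.values()) == counts["ENZYME"]
    return calls, summary


def calls_to_table(calls: Sequence[CategoryCall]) -> pd.DataFrame:
    rows = [
        {
            "locus_tag": c.locus_tag,
            "major": c.category.major,
            "ec_class": c.category.ec_class if c.category.ec_class else "",
            "family": c.category.transporter_family or "",
            "matched_pattern": c.matched_rule.pattern if c.matched_rule else "",
            "evidence": c.evidence,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=["locus_tag", "major", "ec_class", "family", "matched_pattern", "evidence"],
    )
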