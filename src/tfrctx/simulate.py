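"""Synthetic replicons with planted regulator contexts and operators.

The generator lays out gene cassettes along a linear (optionally circular)
replicon: each cassette carries one TetR-family regulator gene in a chosen
arrangement — a head-to-head partner at a sampled separation (DIVERGENT), a
same-strand neighbor within the operon gap (OPERONIC), or a same-strand
neighbor too far away for either relationship (OTHER). Background sequence
is i.i.d. with streptomycete-like GC (default 0.72); start codons are
rendered ATG. For divergent cassettes a perfect palindromic operator of the
requested arm/loop can be written into the intergenic region at a recorded
offset, with the immediately flanking base pair forced to mismatch so the
planted site is arm-exact under scanning. Every planted fact is emitted as
ground truth so the full pipeline can be scored for recovery.

Cassettes are separated by >35 bp and oriented so that no unplanned
divergent or operonic relationship involves a regulator; incidental
background palindromes are permitted (recovery is scored at planted offsets
only).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .context import ContextCall, Group
from .model import AnnotationBundle, GeneRecord, Replicon, reverse_complement
from .operators import PalindromeSite

_PRODUCT_POOL = [
    ("MFS transporter", "MEMBRANE_TRANSPORTER:MFS"),
    ("ABC transporter ATP-binding protein", "MEMBRANE_TRANSPORTER:ABC"),
    ("RND family efflux pump", "MEMBRANE_TRANSPORTER:RND"),
    ("NADH dehydrogenase", "ENZYME:1"),
    ("acyltransferase", "ENZYME:2"),
    ("glycosyl hydrolase", "ENZYME:3"),
    ("integral membrane protein", "MEMBRANE_OTHER"),
    ("transcriptional regulator", "OTHER_PROTEIN"),
    ("hypothetical protein", "UNKNOWN"),
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic replicon.

    ``group_mix`` gives DIVERGENT/OPERONIC/OTHER proportions (the survey
    genomes run roughly 0.67/0.15/0.18); separation and operon-gap samplers
    are (low, high) bounds of uniform integer draws, the separation range
    0..1123 echoing the observed spread of divergent-pair separations.
    """

    n_tfr: int = 20
    group_mix: tuple[float, float, float] = (0.67, 0.15, 0.18)
    separation_range: tuple[int, int] = (0, 1123)
    operon_gap_range: tuple[int, int] = (0, 35)
    plant_operators: bool = False
    operator_arm: int = 7
    operator_loop: int = 1
    operator_mismatches: int = 0
    gc_content: float = 0.72
    topology: str = "linear"
    include_plasmid: bool = False
    replicon_id: str = "synchr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.group_mix) - 1.0) > 1e-9:
            raise ValueError("group_mix proportions must sum to 1")
        if any(p < 0 for p in self.group_mix):
            raise ValueError("group_mix proportions must be >= 0")
        for lo, hi in (self.separation_range, self.operon_gap_range):
            if lo < 0 or hi < lo:
                raise ValueError("sampler bounds must satisfy 0 <= low <= high")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if self.n_tfr < 1:
            raise ValueError("n_tfr must be >= 1")


@dataclass(frozen=True)
class PlantedOperator:
    offset_in_igr: int  # 0-based, forward strand, from the IGR's left end
    arm_len: int
    loop_len: int
    mismatches: int


@dataclass(frozen=True)
class TruthEntry:
    locus_tag: str
    true_group: str
    true_neighbor: Optional[str]
    true_separation: Optional[int]
    true_category: Optional[str]
    operator: Optional[PlantedOperator]
    tfr_is_left: bool = False  # divergent cassettes: regulator left of the IGR


@dataclass
class PlantedTruth:
    entries: list[TruthEntry] = field(default_factory=list)

    def by_locus(self) -> dict[str, TruthEntry]:
        return {e.locus_tag: e for e in self.entries}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([asdict(e) for e in self.entries], fh, indent=1)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _group_counts(n: int, mix: Sequence[float]) -> list[int]:
    # largest-remainder apportionment: deterministic, sums to n
    raw = [n * p for p in mix]
    counts = [int(x) for x in raw]
    rem = n - sum(counts)
    order = sorted(range(len(mix)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


def _random_palindrome(rng, arm: int, loop: int) -> str:
    left = "".join(rng.choice(list("ACGT"), size=arm))
    spacer = "".join(rng.choice(list("ACGT"), size=loop))
    return left + spacer + reverse_complement(left)


class _Builder:
    def __init__(self, spec: FixtureSpec, rng, replicon_id: str, tag_prefix: str):
        self.spec = spec
        self.rng = rng
        self.replicon_id = replicon_id
        self.tag_prefix = tag_prefix
        self.genes: list[GeneRecord] = []
        self.edits: list[tuple[int, str]] = []  # (1-based position, text)
        self.cursor = int(rng.integers(200, 400))
        self.counter = 0

    def _tag(self) -> str:
        self.counter += 1
        return f"{self.tag_prefix}{self.counter:04d}"

    def _gene_len(self) -> int:
        return int(self.rng.integers(100, 300)) * 3

    def add_gene(self, strand: str, length: int, product: str) -> GeneRecord:
        start = self.cursor + 1
        end = start + length - 1
        g = GeneRecord(self.replicon_id, self._tag(), strand, start, end, "CDS", product)
        self.genes.append(g)
        # stamp the start codon
        if strand == "+":
            self.edits.append((start, "ATG"))
        else:
            self.edits.append((end - 2, "CAT"))
        self.cursor = end
        return g

    def advance(self, gap: int) -> None:
        self.cursor += gap

    def intercassette_gap(self) -> int:
        return int(self.rng.integers(100, 300))


def _build_cassette(b: _Builder, group: str, truth: list[TruthEntry]) -> None:
    spec, rng = b.spec, b.rng
    product, category = _PRODUCT_POOL[int(rng.integers(0, len(_PRODUCT_POOL)))]
    flipped = bool(rng.integers(0, 2))  # mirror the cassette layout

    if group == "DIVERGENT":
        sep = int(rng.integers(spec.separation_range[0], spec.separation_range[1] + 1))
        operator = None
        if not flipped:
            partner = b.add_gene("-", b._gene_len(), product)
            b.advance(sep)
            tfr = b.add_gene("+", b._gene_len(), "TetR family transcriptional regulator")
            igr_left = partner.end + 1
        else:
            tfr = b.add_gene("-", b._gene_len(), "TetR family transcriptional regulator")
            b.advance(sep)
            partner = b.add_gene("+", b._gene_len(), product)
            igr_left = tfr.end + 1
        site_len = 2 * spec.operator_arm + spec.operator_loop
        if spec.plant_operators and sep >= site_len + 2:
            # keep one IGR base on each flank so pairing can be broken there
            offset = int(rng.integers(1, sep - site_len))
            operator = PlantedOperator(offset, spec.operator_arm, spec.operator_loop, 0)
            site = _random_palindrome(rng, spec.operator_arm, spec.operator_loop)
            b.edits.append((igr_left + offset, site))
            # force the flanking pair to mismatch: right flank base must not
            # complement the left flank base, else scanning extends the arms
            left_flank = igr_left + offset - 1
            right_flank = igr_left + offset + site_len
            b.edits.append((left_flank, "A"))
            b.edits.append((right_flank, "A"))
        truth.append(
            TruthEntry(
                tfr.locus_tag, "DIVERGENT", partner.locus_tag, sep, category,
                operator, tfr_is_left=flipped,
            )
        )
    elif group == "OPERONIC":
        gap = int(rng.integers(spec.operon_gap_range[0], spec.operon_gap_range[1] + 1))
        if not flipped:
            mate = b.add_gene("+", b._gene_len(), product)
            b.advance(gap)
            tfr = b.add_gene("+", b._gene_len(), "TetR family transcriptional regulator")
        else:
            tfr = b.add_gene("-", b._gene_len(), "TetR family transcriptional regulator")
            b.advance(gap)
            mate = b.add_gene("-", b._gene_len(), product)
        truth.append(
            TruthEntry(tfr.locus_tag, "OPERONIC", mate.locus_tag, None, None, None)
        )
    else:  # OTHER: same-strand neighbor beyond the operon gap
        gap = int(rng.integers(60, 180))
        if not flipped:
            b.add_gene("+", b._gene_len(), "hypothetical protein")
            b.advance(gap)
            tfr = b.add_gene("+", b._gene_len(), "TetR family transcriptional regulator")
        else:
            tfr = b.add_gene("-", b._gene_len(), "TetR family transcriptional regulator")
            b.advance(gap)
            b.add_gene("-", b._gene_len(), "hypothetical protein")
        truth.append(TruthEntry(tfr.locus_tag, "OTHER", None, None, None, None))


def _render_sequence(rng, length: int, gc: float, edits) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    arr = rng.choice(np.array(list("ACGT")), size=length, p=p)
    for pos1, text in edits:
        arr[pos1 - 1 : pos1 - 1 + len(text)] = list(text)
    return "".join(arr)


def generate_fixture(spec: FixtureSpec) -> tuple[AnnotationBundle, PlantedTruth]:
    """Build a synthetic annotation bundle (with sequence) plus ground truth.

    Deterministic for a fixed spec (single RNG stream seeded by
    ``spec.seed``); raises if the requested separations cannot fit.
    """
    rng = np.random.default_rng(spec.seed)
    # two genes (>=300 bp each) plus the sampled gap per cassette
    floor_length = spec.n_tfr * (600 + spec.separation_range[0])
    if floor_length > 50_000_000:
        raise ValueError("requested fixture does not fit a plausible replicon")
    counts = _group_counts(spec.n_tfr, spec.group_mix)
    groups = (
        ["DIVERGENT"] * counts[0] + ["OPERONIC"] * counts[1] + ["OTHER"] * counts[2]
    )
    rng.shuffle(groups)

    truth_entries: list[TruthEntry] = []
    b = _Builder(spec, rng, spec.replicon_id, "SYN")
    for i, group in enumerate(groups):
        _build_cassette(b, group, truth_entries)
        if i < len(groups) - 1:
            b.advance(b.intercassette_gap())
    length = b.cursor + int(rng.integers(200, 400))
    if length > 50_000_000:
        raise ValueError("requested fixture does not fit a plausible replicon")
    seq = _render_sequence(rng, length, spec.gc_content, b.edits)
    replicons = [Replicon(spec.replicon_id, length, spec.topology, seq, b.genes)]

    if spec.include_plasmid:
        pb = _Builder(spec, rng, "synpls1", "SYNP")
        _build_cassette(pb, "DIVERGENT", truth_entries)
        plen = pb.cursor + int(rng.integers(200, 400))
        pseq = _render_sequence(rng, plen, spec.gc_content, pb.edits)
        replicons.append(Replicon("synpls1", plen, "linear", pseq, pb.genes))

    return AnnotationBundle(replicons, source_path="synthetic"), PlantedTruth(truth_entries)


def tfr_loci(truth: PlantedTruth) -> set[str]:
    return {e.locus_tag for e in truth.entries}


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    confusion: dict[tuple[str, str], int]
    group_accuracy: float
    separation_match_rate: float
    operator_recovery_rate: float
    n_tfr: int
    n_divergent_truth: int
    n_planted_operators: int


def evaluate_recovery(
    truth: PlantedTruth,
    calls: Sequence[ContextCall],
    sites_by_tfr: Optional[dict[str, Sequence[PalindromeSite]]] = None,
) -> RecoveryReport:
    """Score pipeline output against planted ground truth.

    Group recovery is a confusion tally over the three groups; separations
    must match exactly; a planted operator counts as recovered only when a
    reported site has its exact IGR offset and exact arm length.
    """
    truth_by_locus = truth.by_locus()
    call_by_locus = {c.tfr_locus: c for c in calls}
    if set(truth_by_locus) != set(call_by_locus):
        raise ValueError(
            "locus universe mismatch between truth and calls: "
            f"{sorted(set(truth_by_locus) ^ set(call_by_locus))[:5]} ..."
        )
    confusion: dict[tuple[str, str], int] = {}
    correct = 0
    sep_total = sep_match = 0
    op_total = op_hit = 0
    for locus, entry in truth_by_locus.items():
        call = call_by_locus[locus]
        key = (entry.true_group, call.group.value)
        confusion[key] = confusion.get(key, 0) + 1
        if entry.true_group == call.group.value:
            correct += 1
        if entry.true_group == "DIVERGENT":
            sep_total += 1
            if (
                call.group is Group.DIVERGENT
                and call.separation is not None
                and call.separation.clamped_bp == entry.true_separation
                and call.divergent_neighbor == entry.true_neighbor
            ):
                sep_match += 1
        if entry.operator is not None and sites_by_tfr is not None:
            op_total += 1
            for site in sites_by_tfr.get(locus, ()):
                if (
                    site.offset == entry.operator.offset_in_igr
                    and site.arm_len == entry.operator.arm_len
                ):
                    op_hit += 1
                    break
    n = len(truth_by_locus)
    return RecoveryReport(
        confusion=confusion,
        group_accuracy=correct / n if n else 1.0,
        separation_match_rate=sep_match / sep_total if sep_total else 1.0,
        operator_recovery_rate=op_hit / op_total if op_total else 1.0,
        n_tfr=n,
        n_divergent_truth=sep_total,
        n_planted_operators=op_total,
    )
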