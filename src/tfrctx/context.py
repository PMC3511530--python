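"""Genome-context classification of TetR-family regulators.

Each regulator gene is placed in one of three groups by its orientation to
its immediate chromosomal neighbors:

``DIVERGENT``
    transcribed head-to-head with the adjacent gene, the two translational
    starts facing a shared intergenic region (the TetR/tetA arrangement) —
    regardless of how long that region is;
``OPERONIC``
    same strand as an adjacent gene with at most ``operon_gap_max`` bp
    (default 35) between the ORF extremes, hence probably co-transcribed;
``OTHER``
    neither relationship.

A regulator with a divergent neighbor on one side and a co-transcribed
neighbor on the other is classed DIVERGENT with ``mixed_flag`` set.

Separations between divergent pairs are measured between the first bases of
the two start codons (transcription start sites are unknown for almost all
of these genes, so translational starts stand in for them). The target
prediction rule: a divergent neighbor within ``target_distance_max`` bp
(default 200, inclusive) is called a probable direct regulatory target.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from .model import AnnotationBundle, GeneRecord, Replicon


class Group(str, Enum):
    DIVERGENT = "DIVERGENT"
    OPERONIC = "OPERONIC"
    OTHER = "OTHER"


@dataclass(frozen=True)
class Thresholds:
    """Tunable distance cut-offs, in bp.

    ``operon_gap_max``: largest ORF-to-ORF gap still treated as
    co-transcription (35 bp). ``target_distance_max``: largest start-to-start
    separation still predictive of direct regulation (200 bp);
    ``threshold_inclusive`` selects <= (default) versus strict <.
    """

    operon_gap_max: int = 35
    target_distance_max: int = 200
    threshold_inclusive: bool = True

    def __post_init__(self) -> None:
        if self.operon_gap_max < 0 or self.target_distance_max < 0:
            raise ValueError("thresholds must be >= 0")

    def within(self, separation: int) -> bool:
        if self.threshold_inclusive:
            return separation <= self.target_distance_max
        return separation < self.target_distance_max


@dataclass(frozen=True)
class SeparationResult:
    """Start-codon to start-codon separation for a divergent pair.

    ``raw_bp`` counts the bases strictly between the two start-codon first
    bases and can be negative when annotated starts overlap; ``clamped_bp``
    floors it at 0 (the smallest separation reportable for a real pair).
    """

    raw_bp: int
    clamped_bp: int
    left_locus: str
    right_locus: str

    def __post_init__(self) -> None:
        if self.clamped_bp != max(self.raw_bp, 0):
            raise ValueError("clamped_bp must equal max(raw_bp, 0)")


@dataclass
class ContextCall:
    tfr_locus: str
    replicon_id: str
    group: Group
    divergent_neighbor: Optional[str] = None
    separation: Optional[SeparationResult] = None
    operonic_neighbors: tuple[str, ...] = ()
    mixed_flag: bool = False

    def __post_init__(self) -> None:
        if (self.group is Group.DIVERGENT) != (self.divergent_neighbor is not None):
            raise ValueError("group DIVERGENT iff divergent_neighbor present")
        if self.group is Group.OPERONIC and not self.operonic_neighbors:
            raise ValueError("OPERONIC call requires >=1 operonic neighbor")


@dataclass(frozen=True)
class TargetPrediction:
    tfr_locus: str
    target_locus: str
    separation_bp: int
    threshold_bp: int
    predicted: bool
    tier: str  # "strong" within threshold, "weak" beyond


@dataclass(frozen=True)
class IgrSlice:
    """Forward-strand intergenic sequence between two divergent start codons.

    ``start``/``end`` are 1-based inclusive genome coordinates of the slice;
    ``bed_start``/``bed_end`` give the 0-based half-open rendering.
    """

    replicon_id: str
    sequence: str
    start: int
    end: int

    @property
    def bed_start(self) -> int:
        return self.start - 1

    @property
    def bed_end(self) -> int:
        return self.end


# ---------------------------------------------------------------------------
# elementary geometry
# ---------------------------------------------------------------------------

def translational_start(gene: GeneRecord) -> int:
    """Coordinate of the first base of the start codon."""
    return gene.start if gene.strand == "+" else gene.end


def neighbors(
    replicon: Replicon, gene: GeneRecord
) -> tuple[Optional[GeneRecord], Optional[GeneRecord]]:
    """Immediate left/right neighbors in coordinate order.

    Exact-coordinate duplicates of the query gene are skipped. Linear
    replicon ends have an absent outward neighbor; circular replicons wrap.
    """
    ordered = [
        g
        for g in replicon.genes
        if g.locus_tag == gene.locus_tag or not (g.start == gene.start and g.end == gene.end)
    ]
    try:
        idx = next(i for i, g in enumerate(ordered) if g.locus_tag == gene.locus_tag)
    except StopIteration:
        raise KeyError(
            f"gene {gene.locus_tag!r} not on replicon {replicon.replicon_id}"
        ) from None
    n = len(ordered)
    if replicon.topology == "circular" and n > 1:
        return ordered[(idx - 1) % n], ordered[(idx + 1) % n]
    left = ordered[idx - 1] if idx > 0 else None
    right = ordered[idx + 1] if idx < n - 1 else None
    return left, right


def arrangement(gene_a: GeneRecord, gene_b: GeneRecord) -> str:
    """Relative orientation of two genes, ``gene_a`` strictly left of ``gene_b``.

    head-to-head (left '-', right '+') is ``divergent``; tail-to-tail is
    ``convergent``; same strand is ``tandem``.
    """
    if gene_a.start >= gene_b.start:
        raise ValueError(
            f"{gene_a.locus_tag} must lie strictly left of {gene_b.locus_tag}"
        )
    if gene_a.strand == "-" and gene_b.strand == "+":
        return "divergent"
    if gene_a.strand == "+" and gene_b.strand == "-":
        return "convergent"
    return "tandem"


def intergenic_separation(left_gene: GeneRecord, right_gene: GeneRecord) -> SeparationResult:
    """Bases strictly between the start-codon first bases of a divergent pair."""
    if arrangement(left_gene, right_gene) != "divergent":
        raise ValueError(
            f"{left_gene.locus_tag}/{right_gene.locus_tag}: separation is defined "
            "for divergent pairs only (use boundary_gap for same-strand pairs)"
        )
    raw = translational_start(right_gene) - translational_start(left_gene) - 1
    return SeparationResult(raw, max(raw, 0), left_gene.locus_tag, right_gene.locus_tag)


def boundary_gap(left_gene: GeneRecord, right_gene: GeneRecord) -> int:
    """Signed gap between ORF extremes of adjacent same-strand genes.

    Negative values mean the annotated ORFs overlap; overlap still counts
    as co-transcription-compatible spacing.
    """
    if left_gene.strand != right_gene.strand:
        raise ValueError(
            f"{left_gene.locus_tag}/{right_gene.locus_tag}: boundary gap is "
            "defined for same-strand pairs"
        )
    return right_gene.start - left_gene.end - 1


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _divergent_partner(
    gene: GeneRecord, left: Optional[GeneRecord], right: Optional[GeneRecord]
) -> Optional[GeneRecord]:
    # head-to-head geometry is single-sided: a '+' gene can only face its
    # left neighbor, a '-' gene only its right neighbor
    if gene.strand == "+" and left is not None and left.strand == "-":
        return left
    if gene.strand == "-" and right is not None and right.strand == "+":
        return right
    return None


def _context_gap(rep: Replicon, nb: GeneRecord, gene: GeneRecord, nb_is_left: bool) -> int:
    """ORF gap to a same-strand neighbor, wrap-aware on circular replicons."""
    left, right = (nb, gene) if nb_is_left else (gene, nb)
    gap = right.start - left.end - 1
    if rep.topology == "circular" and left.start > right.start:
        gap += rep.length  # the pair spans the origin
    return gap


def _separation_for(rep: Replicon, gene: GeneRecord, partner: GeneRecord) -> SeparationResult:
    left, right = (partner, gene) if gene.strand == "+" else (gene, partner)
    raw = translational_start(right) - translational_start(left) - 1
    if rep.topology == "circular" and left.start > right.start:
        raw += rep.length
    return SeparationResult(raw, max(raw, 0), left.locus_tag, right.locus_tag)


def classify_context(
    bundle: AnnotationBundle,
    tfrs: Iterable[str],
    thresholds: Thresholds = Thresholds(),
) -> list[ContextCall]:
    """Assign each regulator locus to DIVERGENT / OPERONIC / OTHER.

    Divergence is checked on the head-to-head side only and holds at any
    separation; the operonic test accepts a same-strand neighbor within
    ``operon_gap_max`` on either side. When both hold the call is DIVERGENT
    with ``mixed_flag`` set. Raises on locus tags absent from the bundle.
    """
    tfrs = sorted(set(tfrs))
    missing = []
    calls = []
    for locus in tfrs:
        try:
            rep, gene = bundle.find(locus)
        except KeyError:
            missing.append(locus)
            continue
        left, right = neighbors(rep, gene)
        partner = _divergent_partner(gene, left, right)
        operonic = []
        for nb, is_left in ((left, True), (right, False)):
            if nb is None or nb.strand != gene.strand or nb.locus_tag == gene.locus_tag:
                continue
            if _context_gap(rep, nb, gene, is_left) <= thresholds.operon_gap_max:
                operonic.append(nb.locus_tag)
        if partner is not None:
            sep = _separation_for(rep, gene, partner)
            calls.append(
                ContextCall(
                    locus,
                    rep.replicon_id,
                    Group.DIVERGENT,
                    divergent_neighbor=partner.locus_tag,
                    separation=sep,
                    operonic_neighbors=tuple(operonic),
                    mixed_flag=bool(operonic),
                )
            )
        elif operonic:
            calls.append(
                ContextCall(
                    locus, rep.replicon_id, Group.OPERONIC,
                    operonic_neighbors=tuple(operonic),
                )
            )
        else:
            calls.append(ContextCall(locus, rep.replicon_id, Group.OTHER))
    if missing:
        raise KeyError(f"locus tags not found in bundle: {', '.join(missing)}")
    return calls


def predict_targets(
    calls: Iterable[ContextCall], thresholds: Thresholds = Thresholds()
) -> list[TargetPrediction]:
    """One regulatory-target prediction per DIVERGENT call.

    ``predicted`` is true when the clamped separation falls within
    ``target_distance_max``; beyond it the divergent neighbor is retained
    as a 'weak' tier candidate but not predicted (long-gap regulators are
    frequently autoregulatory only, or act on the far promoter as
    activators, so no directional claim is made for them).
    """
    preds = []
    for call in calls:
        if call.group is not Group.DIVERGENT:
            continue
        sep = call.separation.clamped_bp
        hit = thresholds.within(sep)
        preds.append(
            TargetPrediction(
                tfr_locus=call.tfr_locus,
                target_locus=call.divergent_neighbor,
                separation_bp=sep,
                threshold_bp=thresholds.target_distance_max,
                predicted=hit,
                tier="strong" if hit else "weak",
            )
        )
    return preds


def extract_igr(replicon: Replicon, call: ContextCall) -> IgrSlice:
    """Forward-strand DNA strictly between the two divergent start codons.

    Length equals the raw separation; abutting or overlapping starts yield
    an empty slice with a warning.
    """
    import warnings

    if replicon.sequence is None:
        raise ValueError(f"{replicon.replicon_id}: no sequence attached")
    if call.group is not Group.DIVERGENT:
        raise ValueError(f"{call.tfr_locus}: IGR extraction needs a DIVERGENT call")
    gene = replicon.gene(call.tfr_locus)
    partner = replicon.gene(call.divergent_neighbor)
    left, right = (partner, gene) if gene.strand == "+" else (gene, partner)
    lo = translational_start(left) + 1
    hi = translational_start(right) - 1
    if hi < lo:
        warnings.warn(
            f"{call.tfr_locus}: divergent starts abut or overlap; empty IGR"
        )
        return IgrSlice(replicon.replicon_id, "", lo, lo - 1)
    return IgrSlice(replicon.replicon_id, replicon.sequence[lo - 1 : hi], lo, hi)


def pair_separation(bundle: AnnotationBundle, locus_a: str, locus_b: str) -> SeparationResult:
    """Start-to-start separation of a named divergent gene pair.

    Convenience for spot-checking published pairs against an annotation:
    genes are ordered by coordinate and must be head-to-head.
    """
    _, a = bundle.find(locus_a)
    _, b = bundle.find(locus_b)
    left, right = (a, b) if a.start < b.start else (b, a)
    return intergenic_separation(left, right)


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def calls_to_table(
    calls: Sequence[ContextCall], predictions: Sequence[TargetPrediction] = ()
):
    """Per-regulator classification table (one row per call) as a DataFrame."""
    import pandas as pd

    pred_by_locus = {p.tfr_locus: p for p in predictions}
    rows = []
    for c in calls:
        p = pred_by_locus.get(c.tfr_locus)
        rows.append(
            {
                "tfr_locus": c.tfr_locus,
                "replicon": c.replicon_id,
                "group": c.group.value,
                "mixed_flag": c.mixed_flag,
                "divergent_neighbor": c.divergent_neighbor or "",
                "separation_raw": c.separation.raw_bp if c.separation else "",
                "separation_clamped": c.separation.clamped_bp if c.separation else "",
                "predicted": p.predicted if p else "",
                "tier": p.tier if p else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "tfr_locus", "replicon", "group", "mixed_flag", "divergent_neighbor",
            "separation_raw", "separation_clamped", "predicted", "tier",
        ],
    )
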