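"""Independent brute-force oracles used to cross-check the implementations.

These deliberately avoid the incremental algorithms in the package: the
palindrome oracle enumerates every (offset, arm, loop) triple, slices the
arms, and counts mismatched pairs directly; the context oracle re-derives
the three-group classification from first principles on small replicons.
"""
from __future__ import annotations

from tfrctx.model import Replicon
from tfrctx.operators import PalindromeSite

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def brute_force_inverted_repeats(
    seq: str, min_arm: int = 5, max_loop: int = 6, max_mismatch: int = 2
) -> list[PalindromeSite]:
    seq = seq.upper()
    n = len(seq)
    candidates = []
    for offset in range(n):
        for loop in range(max_loop + 1):
            arm = min_arm
            while offset + 2 * arm + loop <= n:
                left = seq[offset : offset + arm]
                right = seq[offset + arm + loop : offset + 2 * arm + loop]
                mism = sum(
                    0 if (x, y) in _PAIRS else 1 for x, y in zip(left, right[::-1])
                )
                if mism <= max_mismatch:
                    candidates.append(
                        PalindromeSite(offset, arm, loop, mism, seq[offset : offset + 2 * arm + loop])
                    )
                arm += 1
    kept = []
    for s in candidates:
        dominated = any(
            t is not s
            and t.offset <= s.offset
            and t.offset + t.span >= s.offset + s.span
            and t.arm_len >= s.arm_len
            and t.mismatches <= s.mismatches
            and (t.offset, t.span, t.arm_len, t.mismatches)
            != (s.offset, s.span, s.arm_len, s.mismatches)
            for t in candidates
        )
        if not dominated:
            kept.append(s)
    kept.sort(key=lambda s: (s.offset, -s.arm_len, s.loop_len, s.mismatches))
    return kept


def brute_force_classify(replicon: Replicon, locus: str, operon_gap_max: int = 35) -> str:
    """Three-group call for one gene by exhaustive case analysis."""
    genes = sorted(replicon.genes, key=lambda g: (g.start, g.locus_tag))
    idx = next(i for i, g in enumerate(genes) if g.locus_tag == locus)
    gene = genes[idx]
    left = genes[idx - 1] if idx > 0 else None
    right = genes[idx + 1] if idx < len(genes) - 1 else None
    if replicon.topology == "circular" and len(genes) > 1:
        left = genes[idx - 1]
        right = genes[(idx + 1) % len(genes)]

    divergent = (
        gene.strand == "+" and left is not None and left.strand == "-"
    ) or (gene.strand == "-" and right is not None and right.strand == "+")

    operonic = False
    if left is not None and left.strand == gene.strand and left is not gene:
        gap = gene.start - left.end - 1
        if replicon.topology == "circular" and left.start > gene.start:
            gap += replicon.length
        operonic = operonic or gap <= operon_gap_max
    if right is not None and right.strand == gene.strand and right is not gene:
        gap = right.start - gene.end - 1
        if replicon.topology == "circular" and right.start < gene.start:
            gap += replicon.length
        operonic = operonic or gap <= operon_gap_max

    if divergent:
        return "DIVERGENT"
    if operonic:
        return "OPERONIC"
    return "OTHER"
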