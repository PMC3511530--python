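"""Inverted-repeat operator discovery and IUPAC consensus matching.

TetR-family repressors bind their operators as dimers, and the classical
operator is a palindrome: a left arm, an optional unconstrained loop, and a
right arm equal to the reverse complement of the left up to a small number
of mismatches. The scanner enumerates every center (arm boundary plus loop
length), extends the arms outward under a mismatch budget, and reports the
arm-maximal sites per center.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .model import reverse_complement

IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_SET_TO_CODE = {v: k for k, v in IUPAC.items()}


@dataclass(frozen=True)
class PalindromeSite:
    """An inverted-repeat candidate within a scanned sequence.

    ``offset`` is the 0-based start of the site; the site spans
    ``2*arm_len + loop_len`` bases. ``mismatches`` counts arm positions where
    the left arm fails to reverse-complement the right arm (N never pairs).
    """

    offset: int
    arm_len: int
    loop_len: int
    mismatches: int
    site_seq: str

    def __post_init__(self) -> None:
        if len(self.site_seq) != 2 * self.arm_len + self.loop_len:
            raise ValueError("site_seq length inconsistent with arm/loop")

    @property
    def left_arm(self) -> str:
        return self.site_seq[: self.arm_len]

    @property
    def loop(self) -> str:
        return self.site_seq[self.arm_len : self.arm_len + self.loop_len]

    @property
    def right_arm(self) -> str:
        return self.site_seq[self.arm_len + self.loop_len :]

    @property
    def span(self) -> int:
        return 2 * self.arm_len + self.loop_len

    @property
    def midpoint(self) -> float:
        return self.offset + self.span / 2


@dataclass(frozen=True)
class ConsensusMatch:
    offset: int
    matched_text: str
    strand: str = "+"


@dataclass(frozen=True)
class PlacementCall:
    """Where an operator sits within its intergenic region.

    ``fraction`` runs 0 -> 1 from the regulator's own translational start
    toward the target's; the zone cut points default to thirds.
    """

    site: PalindromeSite
    fraction: float
    zone: str  # TFR_PROXIMAL | CENTRAL | TARGET_PROXIMAL


def _is_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


def _validate_dna(seq: str, allow_n: bool = True) -> str:
    seq = seq.upper()
    allowed = set("ACGTN") if allow_n else set("ACGT")
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"invalid DNA characters: {sorted(bad)}")
    return seq


def find_inverted_repeats(
    seq: str,
    min_arm: int = 5,
    max_loop: int = 6,
    max_mismatch: int = 2,
) -> list[PalindromeSite]:
    """All arm-maximal inverted repeats under a mismatch budget.

    For every center — a boundary position plus a loop of 0..``max_loop``
    unconstrained bases — arms are grown outward one pair at a time while
    cumulative mismatches stay within ``max_mismatch``. A site is emitted
    only when it is maximal: any candidate whose span is covered by another
    candidate with at least the same arm length and at most the same number
    of mismatches is suppressed (this collapses both nested shorter arms at
    one center and equal-span re-renderings of one palindrome with a wider
    loop). Results sort by offset then descending arm length.
    """
    seq = _validate_dna(seq)
    if min_arm < 2:
        raise ValueError("min_arm must be >= 2")
    n = len(seq)
    candidates = []
    for loop in range(0, max_loop + 1):
        # left arm ends at index c-1, loop occupies [c, c+loop)
        for c in range(1, n - loop):
            cum = 0
            frontier: list[tuple[int, int]] = []  # (arm, cumulative mismatches)
            arm = 0
            while True:
                li = c - arm - 1
                ri = c + loop + arm
                if li < 0 or ri >= n:
                    break
                add = 0 if _is_pair(seq[li], seq[ri]) else 1
                if cum + add > max_mismatch:
                    break
                arm += 1
                cum += add
                if add and arm - 1 >= 1:
                    # previous arm was Pareto-optimal: extending cost a mismatch
                    frontier.append((arm - 1, cum - 1))
            if arm >= 1:
                frontier.append((arm, cum))
            for a, m in frontier:
                if a < min_arm:
                    continue
                start = c - a
                candidates.append(
                    PalindromeSite(start, a, loop, m, seq[start : c + loop + a])
                )
    sites = _suppress_dominated(candidates)
    sites.sort(key=lambda s: (s.offset, -s.arm_len, s.loop_len, s.mismatches))
    return sites


def _suppress_dominated(candidates: list[PalindromeSite]) -> list[PalindromeSite]:
    """Drop every candidate covered by an equal-or-longer-armed candidate
    with at most the same mismatches (containment dominance)."""
    kept = []
    for s in candidates:
        dominated = False
        for t in candidates:
            if t is s:
                continue
            if (
                t.offset <= s.offset
                and t.offset + t.span >= s.offset + s.span
                and t.arm_len >= s.arm_len
                and t.mismatches <= s.mismatches
                and (t.offset, t.span, t.arm_len, t.mismatches)
                != (s.offset, s.span, s.arm_len, s.mismatches)
            ):
                dominated = True
                break
        if not dominated:
            kept.append(s)
    return kept


def match_consensus(
    seq: str,
    pattern: str,
    both_strands: bool = False,
) -> list[ConsensusMatch]:
    """Every offset where the sequence fits an IUPAC consensus pattern.

    Matching is case-insensitive; ``U`` and other non-IUPAC symbols are
    rejected. With ``both_strands`` the reverse complement is also scanned
    and hits are reported at forward-strand offsets with strand '-'.
    """
    seq = _validate_dna(seq)
    pattern = pattern.upper()
    bad = set(pattern) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC symbols in pattern: {sorted(bad)}")
    L = len(pattern)
    sets = [IUPAC[p] for p in pattern]

    def scan(s: str) -> list[int]:
        return [
            i
            for i in range(len(s) - L + 1)
            if all(s[i + j] in sets[j] for j in range(L))
        ]

    matches = [ConsensusMatch(i, seq[i : i + L], "+") for i in scan(seq)]
    if both_strands:
        rc = reverse_complement(seq)
        n = len(seq)
        for i in scan(rc):
            fwd = n - L - i
            matches.append(ConsensusMatch(fwd, seq[fwd : fwd + L], "-"))
        matches.sort(key=lambda m: (m.offset, m.strand))
    return matches


def build_consensus(seqs: Iterable[str], mode: str = "n") -> str:
    """Column-wise degenerate consensus of equal-length sequences.

    Default mode emits the base on unanimity and ``N`` on any disagreement
    (the convention for writing operator consensi such as TGGAACGNCGTTCCA);
    ``mode='iupac'`` emits the minimal IUPAC code covering the observed
    bases instead.
    """
    seqs = [_validate_dna(s, allow_n=False) for s in seqs]
    if len(seqs) < 2:
        raise ValueError("need >= 2 sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences must be of equal length")
    if mode not in ("n", "iupac"):
        raise ValueError(f"unknown consensus mode {mode!r}")
    out = []
    for col in zip(*seqs):
        observed = frozenset(col)
        if len(observed) == 1:
            out.append(col[0])
        elif mode == "n":
            out.append("N")
        else:
            out.append(_SET_TO_CODE[observed])
    return "".join(out)


def classify_placement(
    site: PalindromeSite,
    igr_length: int,
    toward_target: bool = True,
    cut_low: float = 1 / 3,
    cut_high: float = 2 / 3,
) -> PlacementCall:
    """Zone of an operator within its intergenic region.

    ``toward_target`` states whether the scanned sequence runs from the
    regulator's start codon toward the target's (set False when it runs the
    other way; the fraction is then mirrored). Operators near the regulator
    side are typical of autoregulation-only binding; target-proximal or
    central placement is what represses the divergent promoter.
    """
    if igr_length <= 0:
        raise ValueError("igr_length must be > 0")
    if not (0 < cut_low < cut_high < 1):
        raise ValueError("require 0 < cut_low < cut_high < 1")
    if site.offset + site.span > igr_length:
        raise ValueError("site extends beyond the intergenic region")
    frac = site.midpoint / igr_length
    if not toward_target:
        frac = 1.0 - frac
    if frac < cut_low:
        zone = "TFR_PROXIMAL"
    elif frac <= cut_high:
        zone = "CENTRAL"
    else:
        zone = "TARGET_PROXIMAL"
    return PlacementCall(site, frac, zone)


def verify_site(site: PalindromeSite) -> bool:
    """Recheck a site's bookkeeping: the arm-pairwise Hamming distance of
    left arm vs reverse-complemented right arm must equal ``mismatches``."""
    rc = reverse_complement(site.right_arm)
    if len(rc) != site.arm_len:
        return False
    dist = sum(
        1
        for a, b in zip(site.left_arm, rc)
        if a != b or a == "N" or b == "N"
    )
    return dist == site.mismatches
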