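"""Retrotransposition signatures at a locus: target-site duplication (TSD),
downstream repeat partner, poly(A) tract, truncation, assembly gaps — and the
structural-group decision cascade.

TSD search follows a three-stage scheme.  Region A is the upstream flank plus
the first ``boundary_slack`` nt of the copy; region B is the last
``boundary_slack`` nt of the copy plus the downstream flank.  Stage 1 looks
for the longest exact common substring of length >= ``min_tsd_length``;
stage 2 repeats the exact search with region B extended to the 6-kb
downstream context; stage 3 allows a single internal mismatch (no indels)
with a raised minimum length.  Ties are broken by the longest segment, then
by the occurrence pair closest to the copy boundaries, then by the leftmost
position in region A — consistent with defining the TSD as the longest
identical segment at each extremity of the copy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from Bio import Align

from .scan import Locus, PseudogeneAlignment, ScanParams, _alignment_counts
from .seqmodel import ReferenceRNA, SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)


class StructuralGroup(str, Enum):
    ALONE = "Alone"
    REPEAT = "Repeat"
    POLYA = "PolyA"
    THREE_PRIME_TRUNC = "ThreePrimeTrunc"
    TO_CHECK = "ToCheck"
    GAPS = "Gaps"


#: groups entering cross-genome comparisons (ToCheck and Gaps are excluded)
COMPARISON_GROUPS = (
    StructuralGroup.ALONE,
    StructuralGroup.REPEAT,
    StructuralGroup.POLYA,
    StructuralGroup.THREE_PRIME_TRUNC,
)


@dataclass
class TsdParams:
    """TSD search parameters.

    ``anchor_slack`` constrains the upstream TSD occurrence to end within
    that many nt of the copy 5' boundary: a target-site duplication abuts
    the insertion on its upstream side (only the downstream side can carry
    an inter-region), and without the anchor, chance >=10-nt matches in the
    6-kb extended search would be common.
    """

    min_tsd_length: int = 10
    boundary_slack: int = 10  # copy bases included in the search regions
    max_mismatches_stage3: int = 1
    anchor_slack: int = 10

    def __post_init__(self) -> None:
        if self.min_tsd_length < 5:
            raise ValueError("min_tsd_length must be >= 5")
        if self.boundary_slack < 0 or self.anchor_slack < 0:
            raise ValueError("boundary_slack and anchor_slack must be >= 0")


@dataclass
class TsdCall:
    """The duplicated target segment found at both extremities of a copy."""

    tsd_seq: str
    upstream_start_offset: int  # within region A
    downstream_start_offset: int  # within region B
    length: int
    stage: str  # exact_near | exact_extended | mismatch_extended
    mismatches: int = 0


@dataclass
class RepeatAnnotation:
    family: str
    orientation: str  # sense | antisense, relative to the copy
    region_start: int  # within the inter-region
    region_end: int
    identity: float
    aligned_length: int


@dataclass
class PolyACall:
    start_offset: int  # from the copy 3' end
    length: int
    a_fraction: float


@dataclass
class TruncationCall:
    five_prime_truncated: bool
    three_prime_truncated: bool
    ref_start: int
    ref_end: int
    tolerance: int = 5


@dataclass
class Boundaries:
    """Insertion boundaries after the TSD-based rebuild.

    ``inter_region`` is the active substrate between the copy 3' end and the
    downstream TSD start (empty when the TSD abuts or overlaps the copy);
    ``copy_tsd_overlap`` counts aligned copy bases that are part of the
    called downstream TSD occurrence (boundary ambiguity absorbed by the
    longest-segment TSD definition).
    """

    inter_region: str
    region_seq: str  # upstream TSD start .. downstream TSD end, copy orientation
    copy_tsd_overlap: int


# ---------------------------------------------------------------------------
# TSD search
# ---------------------------------------------------------------------------


def _longest_common_substrings(
    a: str, b: str, min_len: int, end_window: tuple[int, int] | None = None
):
    """All (start_a, start_b) pairs achieving the maximal common-substring
    length >= min_len, optionally restricted to substrings whose exclusive
    end position in ``a`` falls inside ``end_window`` (lo, hi inclusive).
    Returns (length, pairs) or (0, [])."""
    if not a or not b:
        return 0, []
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    prev = np.zeros(len(b), dtype=np.int32)
    best = 0
    ends: list[tuple[int, int]] = []  # (i_end, j_end) inclusive indices
    for i in range(len(a)):
        eq = (arr_b == arr_a[i]).astype(np.int32)
        cur = eq.copy()
        cur[1:] += prev[:-1] * eq[1:]
        prev = cur
        if end_window is not None and not end_window[0] <= i + 1 <= end_window[1]:
            continue
        m = int(cur.max()) if len(cur) else 0
        if m > best:
            best = m
            ends = [(i, j) for j in np.flatnonzero(cur == m)]
        elif m == best and best > 0:
            ends.extend((i, j) for j in np.flatnonzero(cur == m))
    if best < min_len:
        return 0, []
    return best, [(i - best + 1, j - best + 1) for i, j in ends]


def _mismatch_common_segments(
    a: str, b: str, min_len: int, max_mm: int, end_window: tuple[int, int] | None = None
):
    """Longest common segments allowing up to max_mm internal mismatches
    (no indels); segments start and end on a match, and their exclusive end
    position in ``a`` may be restricted to ``end_window``.  Returns
    (length, [(start_a, start_b, mismatches)])."""
    la, lb = len(a), len(b)
    lo, hi = end_window if end_window is not None else (1, la)
    lo, hi = max(1, lo), min(la, hi)
    best = 0
    hits: list[tuple[int, int, int]] = []
    for end_a in range(lo - 1, hi):  # inclusive end index in a
        ca = a[end_a]
        for end_b in range(lb):
            if b[end_b] != ca:
                continue
            mm = 0
            p = 0
            seg_len = 0
            seg_mm = 0
            while True:
                ia, ib = end_a - p, end_b - p
                if ia < 0 or ib < 0:
                    break
                if a[ia] == b[ib]:
                    seg_len, seg_mm = p + 1, mm
                else:
                    mm += 1
                    if mm > max_mm:
                        break
                p += 1
            if seg_len < min_len or seg_len < best:
                continue
            if seg_len > best:
                best = seg_len
                hits = []
            hits.append((end_a - seg_len + 1, end_b - seg_len + 1, seg_mm))
    return best, hits


def _select_tsd(
    candidates: list[tuple[int, int, int]],
    length: int,
    copy5_in_a: int,
    copy3_in_b: int,
) -> tuple[int, int, int]:
    """Tie-break: closest combined distance to the copy boundaries, then
    leftmost in region A."""

    def key(c):
        i, j, _ = c
        return (abs((i + length) - copy5_in_a) + abs(j - copy3_in_b), i, j)

    return min(candidates, key=key)


def find_tsd(locus: Locus, params: TsdParams | None = None) -> TsdCall | None:
    """Three-stage TSD search around a locus; absence is a valid result."""
    params = params or TsdParams()
    copy = locus.copy_seq
    slack = min(params.boundary_slack, len(copy))
    region_a = locus.upstream + (copy[:slack] if slack else "")
    copy5_in_a = len(locus.upstream)
    copy3_in_b = slack
    anchor = (copy5_in_a - params.anchor_slack, copy5_in_a + params.anchor_slack)

    region_b_near = (copy[-slack:] if slack else "") + locus.downstream
    region_b_ext = (copy[-slack:] if slack else "") + locus.downstream_extended

    length, pairs = _longest_common_substrings(
        region_a, region_b_near, params.min_tsd_length, end_window=anchor
    )
    stage = "exact_near"
    mismatches = 0
    if length == 0:
        length, pairs = _longest_common_substrings(
            region_a, region_b_ext, params.min_tsd_length, end_window=anchor
        )
        stage = "exact_extended"
    if length == 0:
        length, mm_hits = _mismatch_common_segments(
            region_a,
            region_b_ext,
            params.min_tsd_length + 2,
            params.max_mismatches_stage3,
            end_window=anchor,
        )
        stage = "mismatch_extended"
        pairs = [(i, j) for i, j, _ in mm_hits]
        mm_by_pair = {(i, j): mm for i, j, mm in mm_hits}
    if length == 0:
        return None

    candidates = [(i, j, 0) for i, j in pairs]
    i, j, _ = _select_tsd(candidates, length, copy5_in_a, copy3_in_b)
    if stage == "mismatch_extended":
        mismatches = mm_by_pair[(i, j)]
    return TsdCall(
        tsd_seq=region_a[i : i + length],
        upstream_start_offset=i,
        downstream_start_offset=j,
        length=length,
        stage=stage,
        mismatches=mismatches,
    )


def rebuild_boundaries(
    locus: Locus, tsd: TsdCall, params: TsdParams | None = None
) -> Boundaries:
    """Set insertion boundaries from the TSD and expose the inter-region.

    The inter-region — between the copy 3' end and the downstream TSD start
    — becomes the substrate for the repeat and poly(A) searches.
    """
    if tsd is None:
        raise ValueError("rebuild_boundaries requires a TSD call")
    params = params or TsdParams()
    copy = locus.copy_seq
    slack = min(params.boundary_slack, len(copy))
    rel = tsd.downstream_start_offset - slack  # offset from the copy 3' end
    inter = locus.downstream_extended[:rel] if rel > 0 else ""
    full = locus.upstream + copy + locus.downstream_extended
    up_start_full = tsd.upstream_start_offset  # region A maps onto `full`
    down_start_full = len(locus.upstream) + len(copy) + rel
    region_seq = full[up_start_full : down_start_full + tsd.length]
    return Boundaries(
        inter_region=inter,
        region_seq=region_seq,
        copy_tsd_overlap=max(0, -rel),
    )


# ---------------------------------------------------------------------------
# Repeat / poly(A) / truncation / gaps
# ---------------------------------------------------------------------------


def annotate_repeat(
    inter_region: str,
    library: list[SequenceRecord],
    min_identity: float = 0.8,
    min_aligned: int = 30,
    params: ScanParams | None = None,
) -> RepeatAnnotation | None:
    """Best local alignment of the inter-region against a repeat library.

    Reported when identity >= min_identity over >= min_aligned aligned
    columns; orientation is sense when the library strand matches the copy
    orientation.
    """
    if len(inter_region) < 20:
        return None
    if not library:
        logger.warning("repeat annotation requested with an empty library")
        return None
    params = params or ScanParams()
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match_score
    aligner.mismatch_score = params.mismatch_score
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend

    best: RepeatAnnotation | None = None
    best_score = 0.0
    for entry in library:
        for orientation, lib_seq in (
            ("sense", entry.seq),
            ("antisense", reverse_complement(entry.seq)),
        ):
            alns = aligner.align(inter_region, lib_seq)
            if len(alns) == 0 or alns.score <= best_score:
                continue
            counts = _alignment_counts(alns[0], inter_region, lib_seq)
            if counts is None:
                continue
            matches, mismatches, gaps, (ts, te), _ = counts
            columns = matches + mismatches + gaps
            identity = matches / columns if columns else 0.0
            if columns >= min_aligned and identity >= min_identity:
                best_score = float(alns.score)
                best = RepeatAnnotation(
                    family=entry.id,
                    orientation=orientation,
                    region_start=ts,
                    region_end=te,
                    identity=identity,
                    aligned_length=columns,
                )
    return best


def detect_polya(
    substrate: str, window: int = 10, min_a: int = 7, scan_limit: int = 30
) -> PolyACall | None:
    """Sliding-window poly(A) test on the sequence following the copy 3' end.

    Positive iff some ``window``-nt window starting within the first
    ``scan_limit`` nt contains at least ``min_a`` adenosines (the ">6 A in a
    10-nt window" rule).  The call extent is the longest run of qualifying
    windows, trimmed to the outermost A.
    """
    if len(substrate) < window:
        return None
    last_start = min(scan_limit - 1, len(substrate) - window)
    counts = [substrate[w : w + window].count("A") for w in range(last_start + 1)]
    qualifying = [w for w, c in enumerate(counts) if c >= min_a]
    if not qualifying:
        return None
    # longest consecutive run of qualifying window starts (first on ties)
    runs: list[tuple[int, int]] = []
    start = prev = qualifying[0]
    for w in qualifying[1:]:
        if w == prev + 1:
            prev = w
        else:
            runs.append((start, prev))
            start = prev = w
    runs.append((start, prev))
    r0, r1 = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
    lo, hi = r0, r1 + window  # [lo, hi) region covered by the run
    segment = substrate[lo:hi]
    first_a = segment.find("A")
    last_a = segment.rfind("A")
    if first_a < 0:  # pragma: no cover - a qualifying window always has an A
        return None
    start_offset = lo + first_a
    length = last_a - first_a + 1
    region = substrate[start_offset : start_offset + length]
    return PolyACall(
        start_offset=start_offset,
        length=length,
        a_fraction=region.count("A") / length,
    )


def call_truncation(
    alignment: PseudogeneAlignment, ref: ReferenceRNA, tolerance: int = 5
) -> TruncationCall:
    """Flag 5'/3' truncation; ref_end is the last reference base present."""
    return TruncationCall(
        five_prime_truncated=alignment.ref_start > 1 + tolerance,
        three_prime_truncated=alignment.ref_end < ref.length - tolerance,
        ref_start=alignment.ref_start,
        ref_end=alignment.ref_end,
        tolerance=tolerance,
    )


def detect_gaps(
    locus: Locus, boundaries: Boundaries | None = None, min_run: int = 5
) -> bool:
    """True iff a run of >= min_run consecutive N lies within the insertion
    boundaries (post-rebuild when a TSD exists, else copy +/- flank)."""
    if boundaries is not None:
        region = boundaries.region_seq
    else:
        region = locus.upstream + locus.copy_seq + locus.downstream
    return "N" * min_run in region


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


@dataclass
class Classification:
    label: StructuralGroup
    flags: tuple[str, ...] = ()


def classify(
    tsd: TsdCall | None,
    repeat: RepeatAnnotation | None,
    polya: PolyACall | None,
    truncation: TruncationCall,
    has_gap: bool,
) -> Classification:
    """Decision cascade assigning exactly one structural group per locus.

    Evidence precedence (Repeat > PolyA > ThreePrimeTrunc) mirrors the
    successive analysis steps of the pipeline; 5'-truncated copies without a
    repeat explanation are routed to ToCheck for curation, as are
    3'-truncated copies lacking a TSD.
    """
    if truncation is None:
        raise ValueError("classification requires truncation evidence")
    flags: list[str] = []
    if has_gap:
        label = StructuralGroup.GAPS
    elif tsd is not None:
        if repeat is not None:
            label = StructuralGroup.REPEAT
        elif polya is not None:
            label = StructuralGroup.POLYA
        elif truncation.three_prime_truncated:
            label = StructuralGroup.THREE_PRIME_TRUNC
        else:
            label = StructuralGroup.TO_CHECK
            flags.append("full_length_tsd")
    else:
        if (
            not truncation.five_prime_truncated
            and not truncation.three_prime_truncated
            and repeat is None
            and polya is None
        ):
            label = StructuralGroup.ALONE
        else:
            label = StructuralGroup.TO_CHECK
            if truncation.three_prime_truncated:
                flags.append("three_prime_trunc_no_tsd")
    if (
        truncation.five_prime_truncated
        and label not in (StructuralGroup.REPEAT, StructuralGroup.GAPS)
    ):
        label = StructuralGroup.TO_CHECK
        if "five_prime_truncated" not in flags:
            flags.append("five_prime_truncated")
    return Classification(label=label, flags=tuple(flags))


def flag_inverted_chimera(
    group: StructuralGroup,
    tsd: TsdCall | None,
    repeat: RepeatAnnotation | None,
    truncation: TruncationCall,
) -> bool:
    """Twin-priming signature: antisense repeat partner plus 3'-truncated
    copy inside one TSD pair.  Only meaningful for Repeat-group copies."""
    if group is not StructuralGroup.REPEAT or repeat is None or tsd is None:
        raise ValueError("inverted-chimera flag applies to Repeat copies with TSD")
    return repeat.orientation == "antisense" and truncation.three_prime_truncated
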