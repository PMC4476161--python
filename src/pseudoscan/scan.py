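"""Candidate-locus discovery: seed-and-extend search, refinement, filtering,
flank extraction and segmental-duplication removal.

The native search backend is a word-seeded local alignment: exact reference
k-mers anchor candidate genomic windows, each window is aligned with an
affine-gap Smith-Waterman (Bio.Align), and alignment ends are then extended
ungapped to their maximal-score endpoints so that full-length copies carrying
one or two mismatches near their extremities are reported with their complete
reference span instead of a clipped one.  Both strands are scanned; minus
strand hits are found by scanning the reverse complement of the genome and
mapping coordinates back, which makes strand symmetry exact by construction.

E-values use an ungapped Karlin-Altschul approximation with fixed lambda and
K for the default scoring; identity and length are the dominant filters, so
e-value precision is non-critical.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

from Bio import Align

from .seqmodel import GenomicInterval, ReferenceRNA, SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)

UNPLACED_PATTERNS = ("chrun", "random", "unplaced", "scaffold", "hap")


@dataclass
class ScanParams:
    """Thresholds and scoring for the homology scan.

    Defaults follow the selective parameters of the original pipeline:
    97.5% identity, >=26 nt, e-value cutoff 10, 100-nt flanks with a 6-kb
    downstream extension for the distant-TSD search.
    """

    min_identity: float = 0.975
    min_hit_length: int = 26
    evalue_cutoff: float = 10.0
    flank_length: int = 100
    extended_flank: int = 6000
    word_size: int = 11
    match_score: int = 1
    mismatch_score: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    ka_lambda: float = 1.28
    ka_k: float = 0.46
    dedup_similarity: float = 0.9
    unplaced_patterns: tuple[str, ...] = UNPLACED_PATTERNS

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_hit_length < self.word_size:
            raise ValueError("min_hit_length must be >= word_size")
        if self.flank_length >= self.extended_flank:
            raise ValueError("flank_length must be < extended_flank")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be positive")


@dataclass
class PseudogeneAlignment:
    """One candidate hit: a local alignment of the reference to the genome.

    ``ref_start``/``ref_end`` are 1-based inclusive positions on the
    reference RNA; ``genome_interval`` is 0-based half-open on the plus
    strand of the genome, with ``strand`` recording copy orientation.
    """

    genome_interval: GenomicInterval
    ref_start: int
    ref_end: int
    identity: float
    matches: int
    mismatches: int
    gap_columns: int
    score: float
    evalue: float = math.inf
    unplaced_flag: bool = False

    @property
    def strand(self) -> str:
        return self.genome_interval.strand

    @property
    def genome_length_aligned(self) -> int:
        return self.genome_interval.length


@dataclass
class Locus:
    """A candidate locus with strand-normalized flank context.

    All sequence strings read 5'->3' in copy orientation, i.e. for
    minus-strand alignments they are reverse-complemented so the copy reads
    like the reference.
    """

    alignment: PseudogeneAlignment
    upstream: str
    downstream: str
    downstream_extended: str
    copy_seq: str
    edge_5p: bool = False
    edge_3p: bool = False
    # filled in by deduplicate_segmental
    dedup_cluster: int | None = None
    is_representative: bool = True


def _make_aligner(params: ScanParams, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = params.match_score
    aligner.mismatch_score = params.mismatch_score
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _alignment_counts(alignment, target: str, query: str):
    """matches / mismatches / gap columns and spans from an alignment."""
    t_blocks, q_blocks = alignment.aligned
    matches = mismatches = gaps = 0
    prev_t_end = prev_q_end = None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_t_end is not None:
            gaps += (ts - prev_t_end) + (qs - prev_q_end)
        for tc, qc in zip(target[ts:te], query[qs:qe]):
            if tc == qc:
                matches += 1
            else:
                mismatches += 1
        prev_t_end, prev_q_end = te, qe
    if len(t_blocks) == 0:
        return None
    t_span = (int(t_blocks[0][0]), int(t_blocks[-1][1]))
    q_span = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    return matches, mismatches, gaps, t_span, q_span


def _extend_end(
    window: str, ref: str, t_pos: int, q_pos: int, direction: int, params: ScanParams
) -> tuple[int, float]:
    """Ungapped end extension; returns (columns extended, score delta).

    Walks outward from the alignment end while both sequences last, keeping
    the farthest position whose cumulative score is maximal (ties go to the
    farthest, so a mismatch flanked by recovering matches is absorbed but a
    terminal mismatch is not).
    """
    best_k, best_score = 0, 0.0
    score = 0.0
    k = 0
    while True:
        t = t_pos + direction * (k + 1)
        q = q_pos + direction * (k + 1)
        if not (0 <= t < len(window) and 0 <= q < len(ref)):
            break
        score += (
            params.match_score if window[t] == ref[q] else params.mismatch_score
        )
        k += 1
        if score >= best_score:
            best_score = score
            best_k = k
    return best_k, best_score


def _evalue(score: float, m: int, n: int, params: ScanParams) -> float:
    return params.ka_k * m * n * math.exp(-params.ka_lambda * score)


def _align_window(
    oriented: str,
    win_start: int,
    win_end: int,
    ref: str,
    params: ScanParams,
    aligner: Align.PairwiseAligner,
    genome_len: int,
):
    """Local alignment of the reference to one window, with end extension.

    Returns (orient_start, orient_end, ref_start0, ref_end0_excl, matches,
    mismatches, gaps, score) in oriented-genome coordinates, or None.
    """
    window = oriented[win_start:win_end]
    alignments = aligner.align(window, ref)
    if len(alignments) == 0 or alignments.score <= 0:
        return None
    aln = alignments[0]
    counts = _alignment_counts(aln, window, ref)
    if counts is None:
        return None
    matches, mismatches, gaps, (ts, te), (qs, qe) = counts
    score = float(alignments.score)

    # maximal-span ungapped extension at both ends
    k_left, ds_left = _extend_end(window, ref, ts, qs, -1, params)
    k_right, ds_right = _extend_end(window, ref, te - 1, qe - 1, +1, params)
    for k, ds, sign in ((k_left, ds_left, -1), (k_right, ds_right, +1)):
        if k == 0:
            continue
        if sign < 0:
            seg_t, seg_q = window[ts - k : ts], ref[qs - k : qs]
            ts, qs = ts - k, qs - k
        else:
            seg_t, seg_q = window[te : te + k], ref[qe : qe + k]
            te, qe = te + k, qe + k
        m_new = sum(1 for a, b in zip(seg_t, seg_q) if a == b)
        matches += m_new
        mismatches += k - m_new
        score += ds

    return (win_start + ts, win_start + te, qs, qe, matches, mismatches, gaps, score)


def _seed_windows(oriented: str, ref: str, params: ScanParams) -> list[tuple[int, int]]:
    """Candidate genomic windows from exact reference k-mer seeds."""
    k = params.word_size
    ref_kmers: dict[str, list[int]] = {}
    for i in range(len(ref) - k + 1):
        ref_kmers.setdefault(ref[i : i + k], []).append(i)
    pad = 30
    ref_len = len(ref)
    windows: list[tuple[int, int]] = []
    for g in range(len(oriented) - k + 1):
        positions = ref_kmers.get(oriented[g : g + k])
        if positions is None:
            continue
        for rpos in positions:
            lo = max(0, g - rpos - pad)
            hi = min(len(oriented), g + (ref_len - rpos) + pad)
            windows.append((lo, hi))
    if not windows:
        return []
    windows.sort()
    merged = [windows[0]]
    for lo, hi in windows[1:]:
        if lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def _is_unplaced(seq_id: str, params: ScanParams) -> bool:
    name = seq_id.lower()
    return any(pat in name for pat in params.unplaced_patterns)


def find_hits(
    genome: SequenceRecord, ref: ReferenceRNA, params: ScanParams | None = None
) -> list[PseudogeneAlignment]:
    """Scan both strands of a genome sequence for copies of the reference.

    Hits passing the e-value cutoff are returned; overlapping same-strand
    hits are merged into the best-scoring one.  Identity/length filtering is
    a separate step (:func:`filter_hits`).
    """
    params = params or ScanParams()
    if ref.length < params.word_size:
        raise ValueError(
            f"reference length {ref.length} is shorter than word size "
            f"{params.word_size}"
        )
    if genome.length < ref.length:
        raise ValueError("genome is shorter than the reference")

    aligner = _make_aligner(params, "local")
    glen = genome.length
    hits: list[PseudogeneAlignment] = []
    for strand in "+-":
        oriented = genome.seq if strand == "+" else reverse_complement(genome.seq)
        for win_start, win_end in _seed_windows(oriented, ref.seq, params):
            res = _align_window(
                oriented, win_start, win_end, ref.seq, params, aligner, glen
            )
            if res is None:
                continue
            os_, oe, qs, qe, matches, mismatches, gaps, score = res
            evalue = _evalue(score, ref.length, glen, params)
            if evalue > params.evalue_cutoff:
                continue
            if strand == "+":
                gs, ge = os_, oe
            else:
                gs, ge = glen - oe, glen - os_
            total = matches + mismatches + gaps
            hits.append(
                PseudogeneAlignment(
                    genome_interval=GenomicInterval(genome.id, gs, ge, strand),
                    ref_start=qs + 1,
                    ref_end=qe,
                    identity=matches / total if total else 0.0,
                    matches=matches,
                    mismatches=mismatches,
                    gap_columns=gaps,
                    score=score,
                    evalue=evalue,
                    unplaced_flag=_is_unplaced(genome.id, params),
                )
            )
    return merge_overlapping(hits)


def merge_overlapping(hits: list[PseudogeneAlignment]) -> list[PseudogeneAlignment]:
    """Keep only the best-scoring hit among same-strand overlapping ones."""
    kept: list[PseudogeneAlignment] = []
    for hit in sorted(hits, key=lambda h: (-h.score, h.genome_interval.start)):
        if any(
            k.strand == hit.strand and k.genome_interval.overlaps(hit.genome_interval)
            for k in kept
        ):
            continue
        kept.append(hit)
    kept.sort(key=lambda h: (h.genome_interval.seq_id, h.genome_interval.start))
    return kept


def refine_alignment(
    genome: SequenceRecord,
    ref: ReferenceRNA,
    hit: PseudogeneAlignment,
    params: ScanParams | None = None,
    _oriented: str | None = None,
) -> PseudogeneAlignment:
    """Re-align the full reference against the hit's padded genomic window.

    The window is the hit's genomic span extended by the unaligned reference
    overhang plus 20 nt on each side, so end segments clipped by the seeded
    search (typically 1-2 mismatches in the terminal 10-15 nt) are recovered.
    The refined reference span never shrinks below the seed span.
    """
    params = params or ScanParams()
    glen = genome.length
    oriented = _oriented
    if oriented is None:
        oriented = (
            genome.seq if hit.strand == "+" else reverse_complement(genome.seq)
        )
    iv = hit.genome_interval
    if hit.strand == "+":
        os_, oe = iv.start, iv.end
    else:
        os_, oe = glen - iv.end, glen - iv.start
    pad_left = (hit.ref_start - 1) + 20
    pad_right = (ref.length - hit.ref_end) + 20
    win_start = max(0, os_ - pad_left)
    win_end = min(glen, oe + pad_right)

    aligner = _make_aligner(params, "local")
    res = _align_window(oriented, win_start, win_end, ref.seq, params, aligner, glen)
    if res is None:  # pragma: no cover - a seeded hit always realigns
        return hit
    ns, ne, qs, qe, matches, mismatches, gaps, score = res
    # never decrease the aligned reference span
    if qe - qs < hit.ref_end - (hit.ref_start - 1):
        return hit
    if hit.strand == "+":
        gs, ge = ns, ne
    else:
        gs, ge = glen - ne, glen - ns
    total = matches + mismatches + gaps
    return replace(
        hit,
        genome_interval=GenomicInterval(iv.seq_id, gs, ge, hit.strand),
        ref_start=qs + 1,
        ref_end=qe,
        identity=matches / total if total else 0.0,
        matches=matches,
        mismatches=mismatches,
        gap_columns=gaps,
        score=score,
        evalue=_evalue(score, ref.length, glen, params),
    )


def filter_hits(
    hits: list[PseudogeneAlignment], params: ScanParams | None = None
) -> list[PseudogeneAlignment]:
    """Identity/length selection: >= min_identity and >= min_hit_length nt."""
    params = params or ScanParams()
    kept = [
        h
        for h in hits
        if h.identity >= params.min_identity
        and h.genome_length_aligned >= params.min_hit_length
    ]
    kept.sort(key=lambda h: (h.genome_interval.seq_id, h.genome_interval.start))
    return kept


def extract_locus(
    genome: SequenceRecord,
    alignment: PseudogeneAlignment,
    params: ScanParams | None = None,
    _oriented: str | None = None,
) -> Locus:
    """Collect strand-normalized flanks around a refined alignment."""
    params = params or ScanParams()
    glen = genome.length
    oriented = _oriented
    if oriented is None:
        oriented = (
            genome.seq if alignment.strand == "+" else reverse_complement(genome.seq)
        )
    iv = alignment.genome_interval
    if alignment.strand == "+":
        s, e = iv.start, iv.end
    else:
        s, e = glen - iv.end, glen - iv.start
    up_start = max(0, s - params.flank_length)
    return Locus(
        alignment=alignment,
        upstream=oriented[up_start:s],
        downstream=oriented[e : e + params.flank_length],
        downstream_extended=oriented[e : e + params.extended_flank],
        copy_seq=oriented[s:e],
        edge_5p=s < params.flank_length,
        edge_3p=e + params.flank_length > glen,
    )


def _flank_identity(a: Locus, b: Locus, aligner: Align.PairwiseAligner) -> float:
    """Global-alignment identity between the concatenated flanks of two loci."""
    sa = a.upstream + a.downstream
    sb = b.upstream + b.downstream
    if not sa or not sb:
        return 0.0
    aln = aligner.align(sa, sb)[0]
    counts = _alignment_counts(aln, sa, sb)
    if counts is None:
        return 0.0
    matches, mismatches, gaps, _, _ = counts
    columns = max(len(sa), len(sb))
    return matches / columns


def deduplicate_segmental(
    loci: list[Locus],
    similarity_threshold: float = 0.9,
    params: ScanParams | None = None,
) -> list[Locus]:
    """Collapse loci that are part of large genomic duplications.

    Loci whose concatenated flanks align at >= similarity_threshold identity
    are clustered (single linkage); the representative is the copy with the
    highest alignment identity, ties broken by lowest genomic coordinate.
    Cluster membership is recorded on every locus (``dedup_cluster``,
    ``is_representative``) so removed copies can be reported.
    """
    params = params or ScanParams()
    n = len(loci)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    aligner = _make_aligner(params, "global")
    for i in range(n):
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            if _flank_identity(loci[i], loci[j], aligner) >= similarity_threshold:
                parent[find(j)] = find(i)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    kept: list[Locus] = []
    for cluster_id, members in enumerate(sorted(clusters.values(), key=min)):
        best = min(
            members,
            key=lambda i: (
                -loci[i].alignment.identity,
                loci[i].alignment.genome_interval.start,
            ),
        )
        for i in members:
            loci[i].dedup_cluster = cluster_id
            loci[i].is_representative = i == best
        kept.append(loci[best])
    kept.sort(key=lambda l: l.alignment.genome_interval.start)
    return kept
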