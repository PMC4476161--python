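"""End-to-end orchestration: find -> refine -> filter -> extract -> dedup ->
TSD -> rebuild -> repeat/poly(A) -> truncation/gaps -> classify -> statistics.

One pipeline-level rule sits on top of the signature operations: a TSD found
in the extended or mismatch-tolerant stages whose inter-region is long yet
carries neither a repeat partner nor a poly(A) tract is discarded as a
chance match (the locus is then re-annotated through the TSD-less path).
Distant TSDs exist to explain chimeric inserts; an unexplained distant match
in 6 kb of sequence is overwhelmingly likely to be noise.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

from . import __version__
from .scan import (
    Locus,
    PseudogeneAlignment,
    ScanParams,
    deduplicate_segmental,
    extract_locus,
    filter_hits,
    find_hits,
    merge_overlapping,
    refine_alignment,
)
from .seqmodel import ReferenceRNA, SequenceRecord, reverse_complement
from .signatures import (
    Boundaries,
    Classification,
    PolyACall,
    RepeatAnnotation,
    StructuralGroup,
    TruncationCall,
    TsdCall,
    TsdParams,
    annotate_repeat,
    call_truncation,
    classify,
    detect_gaps,
    detect_polya,
    find_tsd,
    flag_inverted_chimera,
    rebuild_boundaries,
)
from .stats import JunctionResult, cleavage_window, junction_homology

logger = logging.getLogger(__name__)


@dataclass
class ClassifiedCopy:
    """A retained locus with its structural group and all evidence fields."""

    locus_id: str
    locus: Locus
    group: StructuralGroup
    flags: tuple[str, ...]
    tsd: TsdCall | None
    boundaries: Boundaries | None
    repeat: RepeatAnnotation | None
    polya: PolyACall | None
    truncation: TruncationCall
    has_gap: bool
    inverted_chimera: bool | None = None  # only defined for Repeat copies
    junction: JunctionResult | None = None
    cleavage: str | None = None
    discarded_tsd: TsdCall | None = None  # implausible distant match, if any

    @property
    def interval(self):
        return self.locus.alignment.genome_interval

    @property
    def alignment(self) -> PseudogeneAlignment:
        return self.locus.alignment

    def gff_attributes(self) -> dict:
        attrs = {
            "ID": self.locus_id,
            "Group": self.group.value,
            "identity": f"{self.alignment.identity:.4f}",
            "ref_span": f"{self.alignment.ref_start}-{self.alignment.ref_end}",
        }
        if self.tsd:
            attrs["tsd_length"] = self.tsd.length
            attrs["tsd_seq"] = self.tsd.tsd_seq
        if self.repeat:
            attrs["repeat_family"] = self.repeat.family
            attrs["repeat_orientation"] = self.repeat.orientation
        if self.polya:
            attrs["polyA_length"] = self.polya.length
        if self.truncation.three_prime_truncated:
            attrs["truncation_3p"] = self.truncation.ref_end
        if self.truncation.five_prime_truncated:
            attrs["truncation_5p"] = self.truncation.ref_start
        if self.flags:
            attrs["flags"] = ",".join(self.flags)
        return attrs

    def bed_name(self) -> str:
        return f"{self.locus_id}|{self.group.value}"


@dataclass
class DroppedLocus:
    description: str
    reason: str  # identity_fail | length_fail | dedup


@dataclass
class ScanResult:
    genome_label: str
    copies: list[ClassifiedCopy]
    total_hits: int
    hits_selected: int
    dropped: list[DroppedLocus]
    params: ScanParams
    tsd_params: TsdParams

    @property
    def hits_analyzed(self) -> int:
        return len(self.copies)

    def group_counts(self) -> dict[str, int]:
        counts = {g.value: 0 for g in StructuralGroup}
        for c in self.copies:
            counts[c.group.value] += 1
        return counts

    def with_tsd_counts(self) -> dict[str, int]:
        counts = {g.value: 0 for g in StructuralGroup}
        for c in self.copies:
            if c.tsd is not None:
                counts[c.group.value] += 1
        return counts

    def summary(self) -> dict:
        return {
            "tool": "pseudoscan",
            "version": __version__,
            "genome": self.genome_label,
            "total_hits": self.total_hits,
            "hits_selected": self.hits_selected,
            "hits_analyzed": self.hits_analyzed,
            "group_counts": self.group_counts(),
            "with_tsd_counts": self.with_tsd_counts(),
            "dropped": [dataclasses.asdict(d) for d in self.dropped],
            "params": dataclasses.asdict(self.params),
            "tsd_params": dataclasses.asdict(self.tsd_params),
        }


def _polya_substrate(boundaries: Boundaries, locus: Locus, window: int = 10) -> str:
    """The poly(A) substrate starts at the copy 3' boundary; inter-regions
    shorter than one window are padded with the genomic continuation."""
    inter = boundaries.inter_region
    if len(inter) >= window:
        return inter
    continuation = locus.downstream_extended[len(inter) :]
    return inter + continuation[: window - len(inter)]


def tsd_is_plausible(
    tsd: TsdCall,
    boundaries: Boundaries,
    repeat: RepeatAnnotation | None,
    polya: PolyACall | None,
    tsd_params: TsdParams,
) -> bool:
    """Near-boundary TSDs always stand; distant ones need an explained
    inter-region (repeat partner or poly(A) tract)."""
    if repeat is not None or polya is not None:
        return True
    return len(boundaries.inter_region) <= 2 * tsd_params.boundary_slack


def annotate_locus(
    locus: Locus,
    ref: ReferenceRNA,
    repeat_library: list[SequenceRecord] | None,
    tsd_params: TsdParams,
    locus_id: str = "locus",
    trunc_tolerance: int = 5,
    cleavage_u: int = 5,
    cleavage_d: int = 5,
) -> ClassifiedCopy:
    """Run the full signature cascade on one extracted locus."""
    library = repeat_library or []
    tsd = find_tsd(locus, tsd_params)
    boundaries = repeat = polya = None
    discarded = None
    if tsd is not None:
        boundaries = rebuild_boundaries(locus, tsd, tsd_params)
        repeat = annotate_repeat(boundaries.inter_region, library)
        polya = detect_polya(_polya_substrate(boundaries, locus))
        if not tsd_is_plausible(tsd, boundaries, repeat, polya, tsd_params):
            discarded, tsd, boundaries = tsd, None, None
            repeat = polya = None
    if tsd is None:
        repeat = annotate_repeat(locus.downstream, library)
        polya = detect_polya(locus.downstream)

    truncation = call_truncation(locus.alignment, ref, trunc_tolerance)
    has_gap = detect_gaps(locus, boundaries)
    cls = classify(tsd, repeat, polya, truncation, has_gap)

    inverted = None
    if cls.label is StructuralGroup.REPEAT:
        inverted = flag_inverted_chimera(cls.label, tsd, repeat, truncation)

    junction = None
    if tsd is not None and truncation.three_prime_truncated and boundaries is not None:
        junction = junction_homology(
            locus, tsd, truncation, boundaries, ref, tsd_params
        )

    cleavage = None
    if tsd is not None:
        try:
            cleavage = cleavage_window(
                locus, tsd, u=cleavage_u, d=cleavage_d, tsd_params=tsd_params
            )
        except ValueError:
            logger.debug("locus %s: insufficient flank for cleavage window", locus_id)

    return ClassifiedCopy(
        locus_id=locus_id,
        locus=locus,
        group=cls.label,
        flags=cls.flags,
        tsd=tsd,
        boundaries=boundaries,
        repeat=repeat,
        polya=polya,
        truncation=truncation,
        has_gap=has_gap,
        inverted_chimera=inverted,
        junction=junction,
        cleavage=cleavage,
        discarded_tsd=discarded,
    )


def scan_genome(
    genome: SequenceRecord,
    ref: ReferenceRNA,
    params: ScanParams | None = None,
    tsd_params: TsdParams | None = None,
    repeat_library: list[SequenceRecord] | None = None,
    trunc_tolerance: int = 5,
    cleavage_u: int = 5,
    cleavage_d: int = 5,
) -> ScanResult:
    """Scan one genome sequence for copies of the reference RNA and classify
    every retained locus."""
    params = params or ScanParams()
    tsd_params = tsd_params or TsdParams()

    oriented = {"+": genome.seq, "-": reverse_complement(genome.seq)}
    raw = find_hits(genome, ref, params)
    refined = merge_overlapping(
        [
            refine_alignment(genome, ref, h, params, _oriented=oriented[h.strand])
            for h in raw
        ]
    )
    selected = filter_hits(refined, params)
    dropped: list[DroppedLocus] = []
    for h in refined:
        if h in selected:
            continue
        reason = (
            "identity_fail" if h.identity < params.min_identity else "length_fail"
        )
        dropped.append(
            DroppedLocus(
                description=(
                    f"{h.genome_interval.seq_id}:{h.genome_interval.start}-"
                    f"{h.genome_interval.end}({h.strand})"
                ),
                reason=reason,
            )
        )

    loci = [
        extract_locus(genome, h, params, _oriented=oriented[h.strand])
        for h in selected
    ]
    kept = deduplicate_segmental(loci, params.dedup_similarity, params)
    for locus in loci:
        if not locus.is_representative:
            iv = locus.alignment.genome_interval
            dropped.append(
                DroppedLocus(
                    description=(
                        f"{iv.seq_id}:{iv.start}-{iv.end}({iv.strand})"
                        f" cluster={locus.dedup_cluster}"
                    ),
                    reason="dedup",
                )
            )

    copies = [
        annotate_locus(
            locus,
            ref,
            repeat_library,
            tsd_params,
            locus_id=f"{genome.id}_copy{i:04d}",
            trunc_tolerance=trunc_tolerance,
            cleavage_u=cleavage_u,
            cleavage_d=cleavage_d,
        )
        for i, locus in enumerate(kept)
    ]
    return ScanResult(
        genome_label=genome.id,
        copies=copies,
        total_hits=len(raw),
        hits_selected=len(selected),
        dropped=dropped,
        params=params,
        tsd_params=tsd_params,
    )
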