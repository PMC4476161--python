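"""Deterministic fixture generator: random background genomes with planted
pseudogene insertions of every structural group, plus a machine-readable
truth table, so every pipeline stage is testable without downloads.

Insertion semantics follow target-site primed reverse transcription: the
target segment at the chosen site is duplicated on both sides of the
inserted body ([TSD][copy (+ poly(A) / repeat partner)][TSD]), so TSDs are
genuine duplications of local sequence, not random strings.  Optional edits
write a pre-insertion cleavage context (e.g. a bottom-strand TTTT/A site)
and engineered junction microhomology into the target before duplication.
All coordinates in the truth table point at the planted copy exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqmodel import ReferenceRNA, SequenceRecord, reverse_complement
from .signatures import StructuralGroup

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class InsertionSpec:
    """Blueprint for one planted insertion.

    ``truncation_5p``/``truncation_3p`` are 1-based first/last reference
    positions present in the copy (None = intact end).  ``target_motif`` is
    written into the pre-insertion target in copy orientation as
    ``"<context>/<tsd-start>"`` with the nick at the slash.
    ``junction_homology_a``/``_b`` engineer exact microhomology lengths at
    the 5'/3' sides of the junction (the next base is forced to mismatch).
    """

    group: StructuralGroup
    tsd_length: int = 12
    polya_length: int = 0
    truncation_5p: int | None = None
    truncation_3p: int | None = None
    repeat_name: str | None = None
    repeat_fragment_length: int = 300
    repeat_orientation: str = "sense"
    divergence: float = 0.0
    strand: str = "+"
    target_motif: str | None = None
    junction_homology_a: int | None = None
    junction_homology_b: int | None = None
    gap_run_length: int = 15

    def validate(self, ref_length: int) -> None:
        g = self.group
        if self.tsd_length < 0:
            raise ValueError("tsd_length must be >= 0")
        if not 0 <= self.divergence < 0.5:
            raise ValueError("divergence must be in [0, 0.5)")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if g is StructuralGroup.REPEAT and not self.repeat_name:
            raise ValueError("group=Repeat requires repeat_name")
        if g is StructuralGroup.POLYA and self.polya_length < 7:
            raise ValueError("group=PolyA requires polya_length >= 7")
        if g is StructuralGroup.THREE_PRIME_TRUNC and self.truncation_3p is None:
            raise ValueError("group=ThreePrimeTrunc requires truncation_3p")
        if g is StructuralGroup.ALONE and (
            self.tsd_length
            or self.polya_length
            or self.repeat_name
            or self.truncation_3p
            or self.truncation_5p
        ):
            raise ValueError("group=Alone plants a bare full-length copy")
        if g in (
            StructuralGroup.REPEAT,
            StructuralGroup.POLYA,
            StructuralGroup.THREE_PRIME_TRUNC,
            StructuralGroup.GAPS,
        ) and self.tsd_length == 0:
            raise ValueError(f"group={g.value} requires a TSD")
        if self.truncation_3p is not None and not 1 <= self.truncation_3p <= ref_length:
            raise ValueError("truncation_3p outside the reference")
        if self.truncation_5p is not None and not 1 <= self.truncation_5p <= ref_length:
            raise ValueError("truncation_5p outside the reference")
        if self.junction_homology_b is not None:
            if self.truncation_3p is None:
                raise ValueError("junction_homology_b requires truncation_3p")
            if self.truncation_3p + self.junction_homology_b >= ref_length:
                raise ValueError("junction_homology_b runs past the reference end")
        if self.target_motif is not None and (
            self.junction_homology_a is not None or self.junction_homology_b is not None
        ):
            raise ValueError("target_motif and junction engineering conflict")
        if self.target_motif is not None:
            ctx, _, part = self.target_motif.partition("/")
            if len(part) > self.tsd_length:
                raise ValueError("target_motif TSD part longer than the TSD")

    def body_length(self, ref_length: int) -> int:
        t5 = self.truncation_5p or 1
        t3 = self.truncation_3p or ref_length
        n = t3 - t5 + 1 + self.polya_length
        if self.group is StructuralGroup.GAPS:
            n += self.gap_run_length
        if self.repeat_name:
            n += self.repeat_fragment_length
        return n


@dataclass
class TruthRecord:
    """Ground truth for one planted insertion (copy coordinates exact)."""

    insertion_id: str
    start: int  # 0-based half-open interval of the copy in the final genome
    end: int
    strand: str
    group: StructuralGroup
    tsd_length: int
    tsd_seq: str
    polya_length: int
    truncation_5p: int | None
    truncation_3p: int | None
    repeat_name: str | None
    repeat_orientation: str | None
    divergence: float
    junction_a: int | None = None
    junction_b: int | None = None
    duplicate_of: str | None = None


@dataclass
class SimulationConfig:
    genome_length: int
    insertions: list[InsertionSpec]
    gc_content: float = 0.5
    seed: int = 0
    n_gap_runs: int = 0
    n_segmental_duplications: int = 0
    genome_id: str = "synth"

    def validate(self, ref_length: int) -> None:
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        planted = sum(
            2 * s.tsd_length + s.body_length(ref_length) for s in self.insertions
        )
        if planted >= self.genome_length / 2:
            raise ValueError("total planted material must be < genome_length / 2")
        for spec in self.insertions:
            spec.validate(ref_length)


def random_background(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)].tobytes().decode()


def mutate(
    seq: str, rate: float, rng: np.random.Generator, indel_rate: float = 0.0
) -> str:
    """i.i.d. substitutions to a different base at the given rate; optional
    single-base indels at ``indel_rate`` (default 0)."""
    if not 0 <= rate < 0.5:
        raise ValueError("rate must be in [0, 0.5)")
    if rate == 0 and indel_rate == 0:
        return seq
    lookup = {b: _BASES[_BASES != ord(b)] for b in "ACGT"}
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hit:
        c = chr(arr[i])
        if c in lookup:
            arr[i] = rng.choice(lookup[c])
    out = arr.tobytes().decode()
    if indel_rate > 0:
        chars = []
        for c in out:
            r = rng.random()
            if r < indel_rate / 2:
                continue  # deletion
            chars.append(c)
            if indel_rate / 2 <= r < indel_rate:
                chars.append("ACGT"[rng.integers(4)])  # insertion
        out = "".join(chars)
    return out


def make_repeat_library(seed: int = 2024) -> list[SequenceRecord]:
    """A small synthetic stand-in for a mobile-element library: three random
    consensus-like entries named after familiar repeat families."""
    rng = np.random.default_rng(seed)
    sizes = {"L1": 1200, "Alu": 300, "MIR": 260}
    return [
        SequenceRecord(id=name, seq=random_background(n, 0.5, rng))
        for name, n in sizes.items()
    ]


def _apply_copy_oriented_edits(
    genome: list[str], position: int, tsd_length: int, strand: str, edits
) -> None:
    """Write (offset, base) edits given in copy orientation around the nick.

    Offset 0 is the first base of the TSD source (the downstream junction in
    copy orientation); negative offsets are the pre-insertion context 5' of
    the nick.  Minus-strand edits land reverse-complemented.
    """
    for off, base in edits:
        if strand == "+":
            idx = position + off
            genome[idx] = base
        else:
            idx = position + tsd_length - 1 - off
            genome[idx] = _COMP[base]


def _other_base(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(3)]


def plant_insertion(
    genome: str,
    position: int,
    spec: InsertionSpec,
    ref: ReferenceRNA,
    repeat_library: list[SequenceRecord] | None,
    rng: np.random.Generator,
    insertion_id: str = "ins",
) -> tuple[str, TruthRecord]:
    """Insert one planted pseudogene at ``position``; returns the modified
    genome and the exact truth record."""
    spec.validate(ref.length)
    t5 = spec.truncation_5p or 1
    t3 = spec.truncation_3p or ref.length
    copy = mutate(ref.seq[t5 - 1 : t3], spec.divergence, rng)
    t = spec.tsd_length

    g = list(genome)
    edits: list[tuple[int, str]] = []
    if spec.target_motif is not None:
        ctx, _, part = spec.target_motif.partition("/")
        edits += [(-len(ctx) + m, c) for m, c in enumerate(ctx)]
        edits += [(m, c) for m, c in enumerate(part)]
    if spec.junction_homology_b is not None:
        b = spec.junction_homology_b
        edits += [(i, ref.seq[t3 + i]) for i in range(b)]
        edits.append((b, _other_base(ref.seq[t3 + b], rng)))
    if spec.junction_homology_a is not None:
        a = spec.junction_homology_a
        if a + 1 > len(copy):
            raise ValueError("junction_homology_a exceeds the copy length")
        edits += [(-k, copy[-k]) for k in range(1, a + 1)]
        edits.append((-(a + 1), _other_base(copy[-(a + 1)], rng)))
    _apply_copy_oriented_edits(g, position, t, spec.strand, edits)
    genome = "".join(g)

    tsd_src = genome[position : position + t]
    body = copy
    body += "A" * spec.polya_length
    if spec.group is StructuralGroup.GAPS:
        body += "N" * spec.gap_run_length
    if spec.repeat_name:
        if not repeat_library:
            raise ValueError("spec requests a repeat partner but no library given")
        entry = next((e for e in repeat_library if e.id == spec.repeat_name), None)
        if entry is None:
            raise ValueError(f"repeat {spec.repeat_name!r} not in the library")
        frag = entry.seq[-spec.repeat_fragment_length :]  # 5'-truncated partner
        frag = mutate(frag, spec.divergence, rng)
        if spec.repeat_orientation == "antisense":
            frag = reverse_complement(frag)
        body += frag

    genomic_body = body if spec.strand == "+" else reverse_complement(body)
    new_genome = (
        genome[:position] + tsd_src + genomic_body + genome[position:]
    )
    if spec.strand == "+":
        copy_start = position + t
        copy_end = copy_start + len(copy)
    else:
        copy_end = position + t + len(genomic_body)
        copy_start = copy_end - len(copy)
    truth = TruthRecord(
        insertion_id=insertion_id,
        start=copy_start,
        end=copy_end,
        strand=spec.strand,
        group=spec.group,
        tsd_length=t,
        tsd_seq=tsd_src,
        polya_length=spec.polya_length,
        truncation_5p=spec.truncation_5p,
        truncation_3p=spec.truncation_3p,
        repeat_name=spec.repeat_name,
        repeat_orientation=spec.repeat_orientation if spec.repeat_name else None,
        divergence=spec.divergence,
        junction_a=spec.junction_homology_a,
        junction_b=spec.junction_homology_b,
    )
    return new_genome, truth


def _choose_sites(
    n: int, genome_length: int, rng: np.random.Generator, margin: int, min_gap: int
) -> list[int]:
    for _ in range(1000):
        sites = np.sort(rng.integers(margin, genome_length - margin, size=n))
        if n <= 1 or np.all(np.diff(sites) >= min_gap):
            return [int(s) for s in sites]
    raise RuntimeError(
        "could not place all insertions without overlap after 1000 attempts"
    )


def generate_genome(
    config: SimulationConfig,
    ref: ReferenceRNA,
    repeat_library: list[SequenceRecord] | None = None,
) -> tuple[SequenceRecord, list[TruthRecord]]:
    """Build a background genome with the configured planted insertions.

    Identical configs and seeds yield byte-identical genomes and truth
    tables.  Insertion sites are at least 250 nt apart so flank windows do
    not interleave.
    """
    config.validate(ref.length)
    rng = np.random.default_rng(config.seed)
    genome = random_background(config.genome_length, config.gc_content, rng)

    margin = 150
    min_gap = 250
    sites = _choose_sites(
        len(config.insertions), config.genome_length, rng, margin, min_gap
    )

    # assembly-gap stretches in the background, kept away from insertions
    if config.n_gap_runs:
        g = list(genome)
        placed = 0
        guard = 0
        while placed < config.n_gap_runs and guard < 1000:
            guard += 1
            run = int(rng.integers(30, 81))
            pos = int(rng.integers(margin, config.genome_length - margin - run))
            if all(abs(pos - s) > 6200 for s in sites):
                g[pos : pos + run] = "N" * run
                placed += 1
        genome = "".join(g)

    truths: list[TruthRecord] = []
    offset = 0  # accumulated growth from earlier insertions
    for idx, (site, spec) in enumerate(zip(sites, config.insertions)):
        before = len(genome)
        genome, truth = plant_insertion(
            genome,
            site + offset,
            spec,
            ref,
            repeat_library,
            rng,
            insertion_id=f"ins{idx:03d}",
        )
        offset += len(genome) - before
        truths.append(truth)

    # whole-locus segmental duplications appended at the genome end
    for k in range(config.n_segmental_duplications):
        src = truths[k % len(truths)]
        lo = max(0, src.start - src.tsd_length - 130)
        hi = min(len(genome), src.end + src.tsd_length + 130)
        spacer = random_background(200, config.gc_content, rng)
        dup_start = len(genome) + len(spacer) + (src.start - lo)
        segment = genome[lo:hi]
        genome = genome + spacer + segment
        truths.append(
            dataclasses.replace(
                src,
                insertion_id=f"dup{k:03d}",
                start=dup_start,
                end=dup_start + (src.end - src.start),
                duplicate_of=src.insertion_id,
            )
        )

    record = SequenceRecord(id=config.genome_id, seq=genome)
    return record, truths


def default_insertion_specs(
    n_per_group: int,
    rng: np.random.Generator,
    groups: tuple[StructuralGroup, ...] = (
        StructuralGroup.REPEAT,
        StructuralGroup.POLYA,
        StructuralGroup.THREE_PRIME_TRUNC,
        StructuralGroup.ALONE,
    ),
    divergence: float = 0.01,
    tsd_range: tuple[int, int] = (10, 16),
    ref_length: int = 106,
) -> list[InsertionSpec]:
    """Study-condition insertion mix: equal numbers per structural group,
    TSD lengths uniform in ``tsd_range``, alternating strands; Repeat
    partners alternate sense (template switch) and antisense + 3'-truncated
    (twin priming)."""
    specs: list[InsertionSpec] = []
    for group in groups:
        for i in range(n_per_group):
            tsd = int(rng.integers(tsd_range[0], tsd_range[1] + 1))
            strand = "+" if i % 2 == 0 else "-"
            if group is StructuralGroup.ALONE:
                specs.append(
                    InsertionSpec(
                        group=group, tsd_length=0, divergence=divergence, strand=strand
                    )
                )
            elif group is StructuralGroup.POLYA:
                specs.append(
                    InsertionSpec(
                        group=group,
                        tsd_length=tsd,
                        polya_length=20,
                        divergence=divergence,
                        strand=strand,
                    )
                )
            elif group is StructuralGroup.THREE_PRIME_TRUNC:
                specs.append(
                    InsertionSpec(
                        group=group,
                        tsd_length=tsd,
                        truncation_3p=int(rng.integers(40, min(86, ref_length - 21))),
                        divergence=divergence,
                        strand=strand,
                    )
                )
            elif group is StructuralGroup.REPEAT:
                antisense = i % 2 == 1
                specs.append(
                    InsertionSpec(
                        group=group,
                        tsd_length=tsd,
                        repeat_name="L1",
                        repeat_fragment_length=300,
                        repeat_orientation="antisense" if antisense else "sense",
                        truncation_3p=60 if antisense else None,
                        divergence=divergence,
                        strand=strand,
                    )
                )
            else:
                raise ValueError(f"no default spec for group {group}")
    return specs


def truth_to_dataframe(truths: list[TruthRecord]) -> pd.DataFrame:
    rows = []
    for t in truths:
        d = dataclasses.asdict(t)
        d["group"] = t.group.value
        rows.append(d)
    return pd.DataFrame(rows)


def write_truth_tsv(truths: list[TruthRecord], path) -> None:
    truth_to_dataframe(truths).to_csv(path, sep="\t", index=False)
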