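import numpy as np
import pytest

from pseudoscan import load_bundled_reference
from pseudoscan.scan import Locus, PseudogeneAlignment
from pseudoscan.seqmodel import GenomicInterval
from pseudoscan.synthetic import make_repeat_library


@pytest.fixture(scope="session")
def ref():
    return load_bundled_reference()


@pytest.fixture(scope="session")
def library():
    return make_repeat_library(seed=2024)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def make_locus(
    upstream: str,
    copy_seq: str,
    downstream: str,
    downstream_extended: str | None = None,
    strand: str = "+",
    seq_id: str = "fix",
    start: int = 1000,
    ref_start: int = 1,
    ref_end: int | None = None,
    identity: float = 1.0,
) -> Locus:
    """Assemble a Locus fixture directly, bypassing the scanner."""
    ref_end = ref_end if ref_end is not None else len(copy_seq)
    aln = PseudogeneAlignment(
        genome_interval=GenomicInterval(seq_id, start, start + len(copy_seq), strand),
        ref_start=ref_start,
        ref_end=ref_end,
        identity=identity,
        matches=len(copy_seq),
        mismatches=0,
        gap_columns=0,
        score=float(len(copy_seq)),
    )
    return Locus(
        alignment=aln,
        upstream=upstream,
        downstream=downstream,
        downstream_extended=downstream_extended
        if downstream_extended is not None
        else downstream,
        copy_seq=copy_seq,
    )
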