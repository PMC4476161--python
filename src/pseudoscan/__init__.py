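"""pseudoscan: detection and structural classification of retrotransposed
small-RNA pseudogene copies in genome sequences."""

__version__ = "0.1.0"

from .seqmodel import (  # noqa: F401
    GenomicInterval,
    ReferenceRNA,
    SequenceRecord,
    read_fasta,
    reverse_complement,
)
from .scan import Locus, PseudogeneAlignment, ScanParams  # noqa: F401
from .signatures import StructuralGroup, TsdParams  # noqa: F401


def load_bundled_reference(name: str = "U6") -> ReferenceRNA:
    """The packaged human U6 snRNA reference sequence."""
    from importlib.resources import files

    path = files("pseudoscan.data").joinpath(f"{name}.fa")
    records = read_fasta(str(path))
    return ReferenceRNA(record=records[0], name=name)
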