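"""Signature statistics.

Three independent pieces live here:

* the junction-microhomology statistic for 3'-truncated copies and its
  analytic null P(n) = (n+1) * p**n * (1-p)**2 — the distribution of the sum
  of two independent geometric variables (upstream and downstream
  single-nucleotide matches, each succeeding with probability ``p``);
* the cleavage-site window and position-frequency matrix (PFM), reported in
  the bottom-strand convention so that the canonical L1 endonuclease site
  reads 5'-TTTT/A with the nick between window halves;
* an exact r x 2 Fisher test (full enumeration under the multivariate
  hypergeometric with fixed margins, Monte-Carlo fallback) and the
  all-pairs genome comparison matrix built from it.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .scan import Locus
from .seqmodel import ReferenceRNA, reverse_complement
from .signatures import (
    Boundaries,
    COMPARISON_GROUPS,
    StructuralGroup,
    TruncationCall,
    TsdCall,
    TsdParams,
)

logger = logging.getLogger(__name__)

_TIE_RTOL = 1e-12
_MAX_ENUMERATION = 10_000_000


@dataclass(frozen=True)
class JunctionResult:
    """Microhomology at the 3'-junction: n = a + b.

    ``a`` counts identities between the copy end and the pre-insertion
    upstream context; ``b`` counts identities between the reference
    continuation past the truncation point and the genomic sequence at the
    downstream TSD start.
    """

    a: int
    b: int

    @property
    def n(self) -> int:
        return self.a + self.b


@dataclass
class NullParams:
    p: float = 0.25  # single-nucleotide match probability (unbiased base composition)
    n_max: int = 15

    def __post_init__(self) -> None:
        if not 0 < self.p < 1:
            raise ValueError("p must be in (0, 1)")


@dataclass
class NullDistribution:
    probs: np.ndarray  # P(n) for n = 0..n_max
    tail: float  # mass beyond n_max
    p: float = 0.25

    @property
    def mean(self) -> float:
        """Analytic mean of the sum of two geometric(p) variables."""
        return 2 * self.p / (1 - self.p)


@dataclass
class CleavageSiteModel:
    """Per-position nucleotide counts over aligned cleavage windows."""

    u: int  # bases 3' of the nick in the reported (bottom-strand) string
    d: int  # bases 5' of the nick in the reported string
    counts: pd.DataFrame  # index = position (0-based), columns = A,C,G,T
    n_sites: int
    n_dropped: pd.Series  # per-position windows dropped for N

    @property
    def consensus(self) -> str:
        letters = self.counts.idxmax(axis=1)
        s = "".join(letters)
        return s[: self.d] + "/" + s[self.d :]

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "position"
        out.to_csv(path, sep="\t")


@dataclass
class GroupCountTable:
    """Per-genome counts over the four comparable structural groups."""

    genome_label: str
    counts: dict[StructuralGroup, int]

    def __post_init__(self) -> None:
        self.counts = {g: int(self.counts.get(g, 0)) for g in COMPARISON_GROUPS}
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("group counts must be non-negative")

    def vector(self) -> np.ndarray:
        return np.array([self.counts[g] for g in COMPARISON_GROUPS], dtype=np.int64)


# ---------------------------------------------------------------------------
# Junction microhomology
# ---------------------------------------------------------------------------


def common_prefix_len(a: str, b: str) -> int:
    k = 0
    for x, y in zip(a, b):
        if x != y:
            break
        k += 1
    return k


def common_suffix_len(a: str, b: str) -> int:
    return common_prefix_len(a[::-1], b[::-1])


def junction_homology(
    locus: Locus,
    tsd: TsdCall,
    truncation: TruncationCall,
    boundaries: Boundaries,
    ref: ReferenceRNA,
    tsd_params: TsdParams | None = None,
) -> JunctionResult:
    """Measure microhomology at the 3'-junction of a 3'-truncated copy.

    The truncation point is backed off by the overlap between the aligned
    copy and the called downstream TSD occurrence: bases that the
    longest-segment TSD definition assigns to the TSD may equally be copy
    sequence, and counting them once (as junction homology) keeps the
    statistic consistent with its null.
    """
    if tsd is None:
        raise ValueError("junction homology requires a TSD")
    if truncation is None or not truncation.three_prime_truncated:
        raise ValueError("junction homology applies to 3'-truncated copies")
    params = tsd_params or TsdParams()
    copy = locus.copy_seq
    slack = min(params.boundary_slack, len(copy))

    overlap = boundaries.copy_tsd_overlap
    t = truncation.ref_end - overlap  # 1-based last copy-derived reference base

    region_b_ext = (copy[-slack:] if slack else "") + locus.downstream_extended
    f_seq = region_b_ext[tsd.downstream_start_offset :]
    b = common_prefix_len(f_seq, ref.seq[t:])

    region_a = locus.upstream + (copy[:slack] if slack else "")
    u_seq = region_a[: tsd.upstream_start_offset]
    copy_end = copy[: len(copy) - overlap] if overlap else copy
    a = common_suffix_len(copy_end, u_seq)
    return JunctionResult(a=a, b=b)


def junction_null(params: NullParams | None = None) -> NullDistribution:
    """Exact evaluation of P(n) = (n+1) p^n (1-p)^2 for n = 0..n_max."""
    params = params or NullParams()
    n = np.arange(params.n_max + 1)
    probs = (n + 1) * params.p ** n * (1 - params.p) ** 2
    return NullDistribution(probs=probs, tail=float(1.0 - probs.sum()), p=params.p)


def expected_counts(null: NullDistribution, n_events: int) -> np.ndarray:
    """Element-wise N * P(n); the tail mass scales identically."""
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    return null.probs * n_events


def simulate_junctions(
    n_events: int, rng: np.random.Generator, flank_length: int = 40
) -> np.ndarray:
    """Draw junction microhomology lengths n = a + b from i.i.d. uniform
    sequences, exercising the same prefix/suffix matching as the measurement."""
    out = np.empty(n_events, dtype=np.int64)
    for side in range(2):
        x = rng.integers(0, 4, size=(n_events, flank_length))
        y = rng.integers(0, 4, size=(n_events, flank_length))
        neq = x != y
        has_mm = neq.any(axis=1)
        first_mm = np.where(has_mm, neq.argmax(axis=1), flank_length)
        if side == 0:
            out[:] = first_mm
        else:
            out += first_mm
    return out


# ---------------------------------------------------------------------------
# Cleavage-site consensus
# ---------------------------------------------------------------------------


def cleavage_window(
    locus: Locus, tsd: TsdCall, u: int = 5, d: int = 5, tsd_params: TsdParams | None = None
) -> str:
    """Bottom-strand window around the first-strand nick.

    Takes the ``u`` genomic bases immediately 5' of the upstream TSD
    occurrence followed by the first ``d`` bases of the TSD (copy
    orientation) and reverse-complements, so the nick reads between
    positions ``d`` and ``d+1`` — the 5'-TTTT/A convention.
    """
    params = tsd_params or TsdParams()
    copy = locus.copy_seq
    slack = min(params.boundary_slack, len(copy))
    full_up = locus.upstream + copy  # region A plus the rest of the copy
    i = tsd.upstream_start_offset
    if i < u:
        raise ValueError("insufficient flank for the cleavage window")
    window = full_up[i - u : i + d]
    if len(window) < u + d:
        raise ValueError("insufficient flank for the cleavage window")
    return reverse_complement(window)


def build_pfm(windows: list[str], d: int = 5) -> CleavageSiteModel:
    """Per-position counts over equal-length cleavage windows.

    Windows contribute to every position where they carry an unambiguous
    base; positions where a window has N are dropped from that position and
    tracked in ``n_dropped``.
    """
    if not windows:
        raise ValueError("build_pfm requires at least one window")
    width = len(windows[0])
    if any(len(w) != width for w in windows):
        raise ValueError("all cleavage windows must have the same length")
    bases = ["A", "C", "G", "T"]
    counts = pd.DataFrame(0, index=range(width), columns=bases, dtype=np.int64)
    dropped = pd.Series(0, index=range(width), dtype=np.int64)
    for w in windows:
        for pos, c in enumerate(w):
            if c == "N":
                dropped[pos] += 1
            else:
                counts.loc[pos, c] += 1
    return CleavageSiteModel(
        u=width - d, d=d, counts=counts, n_sites=len(windows), n_dropped=dropped
    )


# ---------------------------------------------------------------------------
# Fisher's exact test (r x 2) and the all-pairs comparison matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FisherResult:
    pvalue: float
    method: str  # exact | monte_carlo
    se: float | None = None  # standard error of the Monte-Carlo estimate


def _table_count(rows: np.ndarray, c1: int) -> int:
    """Number of r x 2 tables with the given margins (DP count)."""
    counts = {0: 1}
    for r in rows:
        nxt: dict[int, int] = {}
        for s, c in counts.items():
            for k in range(0, int(r) + 1):
                if s + k <= c1:
                    nxt[s + k] = nxt.get(s + k, 0) + c
        counts = nxt
    return counts.get(c1, 0)


def _log_prob(ks: np.ndarray, rows: np.ndarray, c1: int, total: int) -> float:
    """log P(table) under the fixed-margin multivariate hypergeometric."""
    lp = -(
        gammaln(total + 1) - gammaln(c1 + 1) - gammaln(total - c1 + 1)
    )
    lp += float(
        np.sum(
            gammaln(rows + 1)
            - gammaln(ks + 1)
            - gammaln(rows - ks + 1)
        )
    )
    return lp


def fisher_exact_rc(
    table,
    method: str = "exact",
    mc_reps: int = 100_000,
    seed: int = 0,
) -> FisherResult:
    """Two-sided Fisher's exact test for an r x 2 contingency table.

    The two-sided p-value sums the probabilities (under the multivariate
    hypergeometric with fixed margins) of all tables at most as probable as
    the observed one, with a 1e-12 relative tolerance on probability ties.
    Falls back to Monte Carlo with a fixed seed when the candidate table
    space exceeds 10^7, or when ``method='monte_carlo'`` is requested.
    Zero rows and columns are permitted; an all-zero table yields p = 1.
    """
    arr = np.asarray(table)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected an r x 2 table")
    if np.any(arr < 0):
        raise ValueError("table entries must be non-negative")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValueError("table entries must be integers")
        arr = arr.astype(np.int64)
    rows = arr.sum(axis=1)
    c1 = int(arr[:, 0].sum())
    total = int(arr.sum())
    if total == 0:
        return FisherResult(pvalue=1.0, method="exact")

    obs_lp = _log_prob(arr[:, 0], rows, c1, total)
    log_tie = math.log1p(_TIE_RTOL)

    if method == "exact" and _table_count(rows, c1) <= _MAX_ENUMERATION:
        psum = 0.0
        nonzero = [int(r) for r in rows]

        def recurse(idx: int, remaining: int, lp_acc: float) -> None:
            nonlocal psum
            if idx == len(nonzero) - 1:
                k = remaining
                if 0 <= k <= nonzero[idx]:
                    lp = lp_acc + (
                        gammaln(nonzero[idx] + 1)
                        - gammaln(k + 1)
                        - gammaln(nonzero[idx] - k + 1)
                    )
                    if lp <= obs_lp + log_tie + _norm_const:
                        psum += math.exp(lp - _norm_const)
                return
            r = nonzero[idx]
            tail_cap = sum(nonzero[idx + 1 :])
            for k in range(max(0, remaining - tail_cap), min(r, remaining) + 1):
                recurse(
                    idx + 1,
                    remaining - k,
                    lp_acc
                    + gammaln(r + 1)
                    - gammaln(k + 1)
                    - gammaln(r - k + 1),
                )

        _norm_const = gammaln(total + 1) - gammaln(c1 + 1) - gammaln(total - c1 + 1)
        # recurse accumulates sum(C(r_i,k_i)); probability = that / C(N, c1)
        recurse(0, c1, 0.0)
        return FisherResult(pvalue=min(1.0, psum), method="exact")

    rng = np.random.default_rng(seed)
    ks = rng.multivariate_hypergeometric(rows.astype(np.int64), c1, size=mc_reps)
    lps = (
        np.sum(
            gammaln(rows + 1)[None, :]
            - gammaln(ks + 1)
            - gammaln(rows[None, :] - ks + 1),
            axis=1,
        )
        - (gammaln(total + 1) - gammaln(c1 + 1) - gammaln(total - c1 + 1))
    )
    hits = np.count_nonzero(lps <= obs_lp + log_tie)
    p_hat = hits / mc_reps
    se = math.sqrt(max(p_hat * (1 - p_hat), 1.0 / mc_reps) / mc_reps)
    return FisherResult(pvalue=p_hat, method="monte_carlo", se=se)


@dataclass
class GenomeComparison:
    labels: list[str]
    pvalues: pd.DataFrame
    alpha_display: float

    @property
    def not_different(self) -> pd.DataFrame:
        """Pairs with p > alpha are flagged 'not statistically different'."""
        return self.pvalues > self.alpha_display

    def to_tsv(self, path) -> None:
        out = self.pvalues.copy()
        out.index.name = "genome"
        out.to_csv(path, sep="\t")


def compare_genomes(
    tables: list[GroupCountTable],
    alpha_display: float = 0.01,
    mc_reps: int = 100_000,
    seed: int = 0,
) -> GenomeComparison:
    """All-pairs Fisher comparison of per-genome structural-group counts."""
    if len(tables) < 2:
        raise ValueError("compare_genomes requires at least 2 tables")
    labels = [t.genome_label for t in tables]
    n = len(tables)
    mat = np.ones((n, n))
    for i, j in itertools.combinations(range(n), 2):
        contingency = np.column_stack([tables[i].vector(), tables[j].vector()])
        res = fisher_exact_rc(contingency, mc_reps=mc_reps, seed=seed)
        mat[i, j] = mat[j, i] = res.pvalue
    return GenomeComparison(
        labels=labels,
        pvalues=pd.DataFrame(mat, index=labels, columns=labels),
        alpha_display=alpha_display,
    )
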