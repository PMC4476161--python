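"""Tabular and JSON outputs for a scan: per-copy report, run summary,
junction histogram and cleavage-site matrix."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pipeline import ClassifiedCopy, ScanResult
from .stats import (
    CleavageSiteModel,
    NullParams,
    build_pfm,
    expected_counts,
    junction_null,
)

REPORT_COLUMNS = [
    "locus_id",
    "seq_id",
    "start",  # 1-based inclusive, report convention
    "end",
    "strand",
    "ref_start",
    "ref_end",
    "identity",
    "group",
    "flags",
    "tsd_len",
    "tsd_seq",
    "tsd_stage",
    "repeat_family",
    "repeat_orientation",
    "inverted_chimera",
    "polyA_len",
    "truncation_5p",
    "truncation_3p",
    "gap_flag",
    "dedup_cluster",
    "junction_a",
    "junction_b",
    "cleavage_window",
]


def copies_to_dataframe(copies: list[ClassifiedCopy]) -> pd.DataFrame:
    rows = []
    for c in copies:
        iv = c.interval
        aln = c.alignment
        rows.append(
            {
                "locus_id": c.locus_id,
                "seq_id": iv.seq_id,
                "start": iv.start + 1,
                "end": iv.end,
                "strand": iv.strand,
                "ref_start": aln.ref_start,
                "ref_end": aln.ref_end,
                "identity": round(aln.identity, 6),
                "group": c.group.value,
                "flags": ",".join(c.flags),
                "tsd_len": c.tsd.length if c.tsd else 0,
                "tsd_seq": c.tsd.tsd_seq if c.tsd else "",
                "tsd_stage": c.tsd.stage if c.tsd else "",
                "repeat_family": c.repeat.family if c.repeat else "",
                "repeat_orientation": c.repeat.orientation if c.repeat else "",
                "inverted_chimera": bool(c.inverted_chimera)
                if c.inverted_chimera is not None
                else "",
                "polyA_len": c.polya.length if c.polya else 0,
                "truncation_5p": aln.ref_start
                if c.truncation.five_prime_truncated
                else "",
                "truncation_3p": aln.ref_end
                if c.truncation.three_prime_truncated
                else "",
                "gap_flag": c.has_gap,
                "dedup_cluster": c.locus.dedup_cluster,
                "junction_a": c.junction.a if c.junction else "",
                "junction_b": c.junction.b if c.junction else "",
                "cleavage_window": c.cleavage or "",
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_copies_tsv(copies: list[ClassifiedCopy], path) -> None:
    copies_to_dataframe(copies).to_csv(path, sep="\t", index=False)


def write_summary_json(result: ScanResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(result.summary(), fh, indent=2)
        fh.write("\n")


def junction_histogram(
    junction_lengths: list[int], p: float = 0.25, n_max: int = 15
) -> pd.DataFrame:
    """Observed junction-microhomology counts next to the analytic null."""
    null = junction_null(NullParams(p=p, n_max=n_max))
    n_events = len(junction_lengths)
    observed = np.zeros(n_max + 1, dtype=int)
    tail_observed = 0
    for n in junction_lengths:
        if n <= n_max:
            observed[n] += 1
        else:
            tail_observed += 1
    df = pd.DataFrame(
        {
            "n": list(range(n_max + 1)) + [f">{n_max}"],
            "observed": list(observed) + [tail_observed],
            "expected": list(expected_counts(null, n_events))
            + [null.tail * n_events],
        }
    )
    return df


def write_junction_tsv(copies: list[ClassifiedCopy], path, p: float = 0.25) -> None:
    lengths = [c.junction.n for c in copies if c.junction is not None]
    junction_histogram(lengths, p=p).to_csv(path, sep="\t", index=False)


def pfm_from_copies(copies: list[ClassifiedCopy], d: int = 5) -> CleavageSiteModel | None:
    windows = [c.cleavage for c in copies if c.cleavage]
    if not windows:
        return None
    return build_pfm(windows, d=d)


def write_scan_outputs(result: ScanResult, out_dir, cleavage_d: int = 5) -> dict:
    """Write the standard output set for one scan; returns the file map."""
    from .seqmodel import write_bed, write_gff3

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "copies_tsv": out / "copies.tsv",
        "gff3": out / "copies.gff3",
        "bed": out / "copies.bed",
        "summary_json": out / "summary.json",
        "junctions_tsv": out / "junctions.tsv",
    }
    write_copies_tsv(result.copies, files["copies_tsv"])
    write_gff3(result.copies, files["gff3"])
    write_bed(result.copies, files["bed"])
    write_summary_json(result, files["summary_json"])
    write_junction_tsv(result.copies, files["junctions_tsv"])
    pfm = pfm_from_copies(result.copies, d=cleavage_d)
    if pfm is not None:
        files["pfm_tsv"] = out / "cleavage_pfm.tsv"
        pfm.to_tsv(files["pfm_tsv"])
    return {k: str(v) for k, v in files.items()}
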