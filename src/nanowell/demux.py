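"""Demultiplexing of paired reads by perfect well-barcode match.

Read 1 carries the 11 bp well barcode followed by the 10 bp UMI; a read
pair is assigned to a well only when the barcode matches an expected
barcode exactly — no error correction is attempted, so a single
sequencing error in the barcode sends the pair to the unassigned pool.
UMIs containing N are retained here; they are excluded downstream during
quantification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pysam

from .chipsim import ReadStructure

__all__ = [
    "BarcodeMap",
    "parse_read1",
    "load_barcode_map",
    "demultiplex",
]


@dataclass
class BarcodeMap:
    """Barcode -> (row, col, sample) lookup with uniqueness enforced."""

    lookup: dict[str, tuple[int, int, str]]

    def __post_init__(self) -> None:
        if not self.lookup:
            raise ValueError("barcode map is empty")
        lens = {len(b) for b in self.lookup}
        if len(lens) != 1:
            raise ValueError("barcodes have mixed lengths")

    @property
    def barcode_len(self) -> int:
        return len(next(iter(self.lookup)))


def load_barcode_map(path: str | Path) -> BarcodeMap:
    """Load a barcode map TSV (columns row, col, barcode, sample).

    Raises on duplicate barcodes: with duplicates, well assignment would
    be ambiguous.
    """
    df = pd.read_csv(path, sep="\t")
    lookup: dict[str, tuple[int, int, str]] = {}
    for r, c, b, s in zip(df["row"], df["col"], df["barcode"], df["sample"]):
        if b in lookup:
            raise ValueError(f"duplicate barcode {b!r} in {path}")
        lookup[b] = (int(r), int(c), str(s))
    return BarcodeMap(lookup)


def parse_read1(seq: str, structure: ReadStructure | None = None) -> tuple[str, str] | None:
    """Split read 1 into (barcode, umi); None when the read is too short.

    The barcode occupies the first ``barcode_len`` bases and the UMI the
    next ``umi_len``; any remaining bases are ignored.
    """
    structure = structure or ReadStructure()
    need = structure.barcode_len + structure.umi_len
    if len(seq) < need:
        return None
    return seq[: structure.barcode_len], seq[structure.barcode_len: need]


def demultiplex(
    r1_path: str | Path,
    r2_path: str | Path,
    barcode_map: BarcodeMap,
    structure: ReadStructure | None = None,
    out_tsv: str | Path | None = None,
    report_path: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Demultiplex a FASTQ pair into tagged reads.

    Returns a DataFrame of assigned reads (read_id, barcode, umi, cdna,
    row, col, sample) and a report dict. Read conservation holds:
    ``assigned + unassigned + too_short == total_pairs``.
    """
    structure = structure or ReadStructure()
    rows = []
    report = {"total_pairs": 0, "assigned": 0, "unassigned": 0, "too_short": 0}
    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        for e1, e2 in zip(f1, f2):
            report["total_pairs"] += 1
            parsed = parse_read1(e1.sequence, structure)
            if parsed is None:
                report["too_short"] += 1
                continue
            barcode, umi = parsed
            hit = barcode_map.lookup.get(barcode)
            if hit is None:
                report["unassigned"] += 1
                continue
            r, c, sample = hit
            rows.append((e1.name, barcode, umi, e2.sequence, r, c, sample))
            report["assigned"] += 1
    tagged = pd.DataFrame(
        rows, columns=["read_id", "barcode", "umi", "cdna", "row", "col", "sample"]
    )
    if out_tsv is not None:
        tagged.to_csv(out_tsv, sep="\t", index=False)
    if report_path is not None:
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2)
    return tagged, report
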