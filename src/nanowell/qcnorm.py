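"""Per-cell QC statistics, filtering, normalization and depth saturation.

The six QC statistics inspected per cell are the total sequenced reads,
alignment rate, mapped reads, total detected transcripts, percentage of
mitochondrial transcripts, and number of detected genes. Cells pass QC
when their total transcript count reaches a per-dataset cutoff.
Normalization divides each cell's counts by a scale factor equal to its
total transcript count over the median total across cells, so every
normalized cell total equals the median raw total. The saturation
analysis re-samples gene-aligned reads at reduced depth and re-runs the
full UMI-cluster counting to obtain detected genes/transcripts versus
depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .quantify import CountingConfig, TranscriptCountMatrix, count_transcripts

__all__ = [
    "DownsampleSpec",
    "compute_cell_qc",
    "qc_filter",
    "normalize",
    "downsample_counts",
]


@dataclass
class DownsampleSpec:
    """Target sequencing depth: sample a fraction d/D of each cell's reads."""

    D: float
    d: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.d <= self.D:
            raise ValueError("need 0 < d <= D")

    @property
    def fraction(self) -> float:
        return self.d / self.D


def compute_cell_qc(
    tcm: TranscriptCountMatrix,
    total_reads: pd.Series | None = None,
    mapped_reads: pd.Series | None = None,
) -> pd.DataFrame:
    """Compute per-cell QC statistics.

    ``total_reads`` is the number of demultiplexed read pairs per cell and
    ``mapped_reads`` the number that mapped uniquely; the alignment rate
    is their ratio. Transcript statistics come from the count matrix:
    detected genes are genes with count >= 1 and the mitochondrial
    percentage uses the gene_meta ``mito`` flag. A cell with zero
    transcripts gets pct_mito 0 with a warning.
    """
    totals = tcm.cell_totals()
    dense = tcm.matrix
    n_genes = np.asarray((dense > 0).sum(axis=0)).ravel()
    mito_mask = tcm.gene_meta["mito"].to_numpy()
    mito_totals = np.asarray(dense[mito_mask].sum(axis=0)).ravel() if mito_mask.any() \
        else np.zeros_like(totals)
    if (totals == 0).any():
        warnings.warn("cells with zero transcripts: pct_mito set to 0", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_mito = np.where(totals > 0, 100.0 * mito_totals / np.maximum(totals, 1), 0.0)

    qc = pd.DataFrame(index=pd.Index(tcm.cell_ids, name="cell"))
    tr = total_reads.reindex(tcm.cell_ids).fillna(0) if total_reads is not None else \
        pd.Series(np.nan, index=tcm.cell_ids)
    mr = mapped_reads.reindex(tcm.cell_ids).fillna(0) if mapped_reads is not None else \
        pd.Series(np.nan, index=tcm.cell_ids)
    qc["total_reads"] = tr
    qc["mapped_reads"] = mr
    with np.errstate(divide="ignore", invalid="ignore"):
        qc["alignment_rate"] = np.where(tr.to_numpy() > 0,
                                        mr.to_numpy() / np.maximum(tr.to_numpy(), 1), np.nan)
    qc["total_transcripts"] = totals
    qc["pct_mito"] = pct_mito
    qc["n_genes_detected"] = n_genes
    return qc


def qc_filter(qc: pd.DataFrame, min_transcripts: int) -> pd.DataFrame:
    """Flag cells passing the minimum-transcripts QC cutoff."""
    if min_transcripts < 0:
        raise ValueError("min_transcripts must be >= 0")
    out = qc.copy()
    out["qc_pass"] = out["total_transcripts"] >= min_transcripts
    return out


def normalize(tcm: TranscriptCountMatrix) -> tuple[pd.DataFrame, pd.Series]:
    """Median-ratio library-size normalization.

    factor(c) = total(c) / median(totals); normalized(g, c) =
    count(g, c) / factor(c). Every cell's normalized total equals the
    median raw total, and re-normalizing is the identity (all factors 1).
    Cells with zero total have an undefined factor and are excluded with
    a warning.
    """
    totals = tcm.cell_totals().astype(float)
    nonzero = totals > 0
    if not nonzero.any():
        raise ValueError("no cell with nonzero total")
    if (~nonzero).any():
        warnings.warn(
            f"excluding {int((~nonzero).sum())} zero-total cell(s) from normalization",
            stacklevel=2,
        )
    med = float(np.median(totals[nonzero]))
    factors = pd.Series(totals / med, index=tcm.cell_ids, name="scale_factor")
    dense = tcm.to_dense_df().loc[:, nonzero]
    norm = dense / factors[nonzero]
    return norm, factors[nonzero]


def downsample_counts(
    gene_reads: pd.DataFrame,
    depths: Sequence[float],
    config: CountingConfig | None = None,
    D: float | None = None,
    seed: int = 0,
    method: str = "hypergeometric",
    gene_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Simulate reduced sequencing depth and recompute detection medians.

    For each target mean depth d, every cell's gene-aligned reads are
    sampled at fraction d/D (without replacement by default, matching
    sampling a fixed fraction of existing reads; ``method='bernoulli'``
    thins reads independently instead), then the full counting chain —
    N-exclusion having already been applied upstream, UMI clustering and
    the singleton filter — is re-run on the sampled reads.

    Returns a DataFrame with columns depth, median_genes,
    median_transcripts over the cells present in ``gene_reads``.

    ``D`` defaults to the observed mean gene-aligned reads per cell.
    """
    config = config or CountingConfig()
    if method not in ("hypergeometric", "bernoulli"):
        raise ValueError("method must be 'hypergeometric' or 'bernoulli'")
    per_cell = gene_reads.groupby("cell").size()
    if D is None:
        D = float(per_cell.mean())
    rng = np.random.default_rng(seed)
    rows = []
    cells = list(per_cell.index)
    grouped = {c: sub.index.to_numpy() for c, sub in gene_reads.groupby("cell")}
    for d in depths:
        if d > D:
            raise ValueError(f"target depth {d} exceeds observed depth {D}")
        f = d / D
        keep_idx = []
        for c in cells:
            idx = grouped[c]
            if f >= 1.0:
                keep_idx.append(idx)
            elif method == "hypergeometric":
                k = int(round(f * idx.size))
                keep_idx.append(rng.choice(idx, size=k, replace=False))
            else:
                keep_idx.append(idx[rng.random(idx.size) < f])
        sampled = gene_reads.loc[np.concatenate(keep_idx)]
        tcm = count_transcripts(sampled, config, gene_ids=gene_ids)
        qc = compute_cell_qc(tcm)
        qc = qc.reindex(cells).fillna({"n_genes_detected": 0, "total_transcripts": 0})
        rows.append((
            d,
            float(qc["n_genes_detected"].median()),
            float(qc["total_transcripts"].median()),
        ))
    return pd.DataFrame(rows, columns=["depth", "median_genes", "median_transcripts"])
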