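"""UMI-cluster transcript counting from tagged alignments.

The counting model: only uniquely mapping reads are considered; reads
whose UMI contains an N are excluded; within each (cell, gene) the
remaining UMIs are clustered by single-linkage over the <=1-mismatch
Hamming graph (connected components), so sequencing errors in the UMI do
not inflate transcript counts; clusters supported by fewer than
``min_reads_per_umi`` reads (default 2) are discarded as likely chimeric
products; and the per-gene transcript count is the number of surviving
clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import scipy.io
import scipy.sparse

__all__ = [
    "CountingConfig",
    "GeneModel",
    "UMICluster",
    "TranscriptCountMatrix",
    "load_gene_model",
    "read_alignments",
    "filter_alignments",
    "assign_genes",
    "drop_n_umis",
    "cluster_umis",
    "count_transcripts",
    "count_matrix",
]

MITO_PREFIXES = ("mt-", "MT-")


@dataclass
class CountingConfig:
    """Counting thresholds.

    ``min_reads_per_umi`` is the minimum read support of a UMI cluster
    (the singleton filter; 1 disables it). ``umi_max_mismatch`` is the
    Hamming radius used to join UMIs into clusters (0 disables
    clustering).
    """

    min_reads_per_umi: int = 2
    umi_max_mismatch: int = 1
    strand_policy: str = "sense"  # or "unstranded"

    def __post_init__(self) -> None:
        if self.min_reads_per_umi < 1:
            raise ValueError("min_reads_per_umi must be >= 1")
        if self.umi_max_mismatch < 0:
            raise ValueError("umi_max_mismatch must be >= 0")
        if self.strand_policy not in ("sense", "unstranded"):
            raise ValueError("strand_policy must be 'sense' or 'unstranded'")


# ---------------------------------------------------------------------------
# Gene model
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """One-interval-per-gene annotation (0-based half-open internally)."""

    genes: pd.DataFrame  # gene_id, chrom, start, end, strand
    _by_chrom: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for chrom, sub in self.genes.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            self._by_chrom[chrom] = (
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
                sub["strand"].to_numpy(),
                sub["gene_id"].to_numpy(),
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes["gene_id"])

    def assign(self, chrom: str, start: int, end: int, strand: str,
               policy: str = "sense") -> str | None:
        """Gene id of the unique gene overlapping the interval, else None.

        Intergenic reads and reads overlapping more than one gene are
        unassigned; under the sense policy the read strand must match the
        gene strand.
        """
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ends, strands, ids = entry
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        hits = [
            i for i in range(lo, hi)
            if policy == "unstranded" or strands[i] == strand
        ]
        if len(hits) == 1:
            return str(ids[hits[0]])
        return None


def load_gene_model(gtf_path: str | Path) -> GeneModel:
    """Read a minimal GTF (gene feature lines) into a GeneModel.

    Malformed lines raise with the offending line number. GTF coordinates
    are 1-based closed and converted to 0-based half-open.
    """
    rows = []
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{gtf_path}:{lineno}: expected 9 tab-separated fields")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = parts
            if feature != "gene":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ValueError(f"{gtf_path}:{lineno}: non-integer coordinates") from None
            if start_i < 1 or end_i < start_i:
                raise ValueError(f"{gtf_path}:{lineno}: invalid interval {start}-{end}")
            if strand not in "+-":
                raise ValueError(f"{gtf_path}:{lineno}: invalid strand {strand!r}")
            gene_id = None
            for chunk in attrs.split(";"):
                chunk = chunk.strip()
                if chunk.startswith("gene_id"):
                    gene_id = chunk.split(None, 1)[1].strip().strip('"')
            if not gene_id:
                raise ValueError(f"{gtf_path}:{lineno}: missing gene_id attribute")
            rows.append((gene_id, chrom, start_i - 1, end_i, strand))
    if not rows:
        raise ValueError(f"{gtf_path}: no gene features found")
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    if genes["gene_id"].duplicated().any():
        dup = genes.loc[genes["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{gtf_path}: duplicate gene_id {dup!r}")
    return GeneModel(genes)


# ---------------------------------------------------------------------------
# Alignment ingestion and filtering
# ---------------------------------------------------------------------------


def read_alignments(
    sam_path: str | Path,
    tagged_reads: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Load tagged alignments into a DataFrame.

    Cell barcode and UMI come from the demultiplexer's tagged-read table
    (joined on read id) when given, otherwise from CB/UB tags on the
    records. Uniqueness comes from the NH tag; records without NH raise,
    since the unique-mapping filter cannot be applied without it.
    """
    tag_lookup = None
    if tagged_reads is not None:
        tag_lookup = {
            rid: (bc, umi) for rid, bc, umi in zip(
                tagged_reads["read_id"], tagged_reads["barcode"], tagged_reads["umi"]
            )
        }
    rows = []
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                rows.append((rec.query_name, None, None, None, -1, -1, "+", 0, False, True))
                continue
            if not rec.has_tag("NH"):
                raise ValueError(
                    f"record {rec.query_name} lacks the NH tag; cannot apply the "
                    "unique-mapping filter"
                )
            unique = rec.get_tag("NH") == 1
            if tag_lookup is not None:
                hit = tag_lookup.get(rec.query_name)
                if hit is None:
                    continue  # read was not assigned to a well
                barcode, umi = hit
            else:
                barcode = rec.get_tag("CB") if rec.has_tag("CB") else None
                umi = rec.get_tag("UB") if rec.has_tag("UB") else None
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            strand = "-" if rec.is_reverse else "+"
            rows.append((
                rec.query_name, barcode, umi, rec.reference_name,
                rec.reference_start, rec.reference_end, strand, nm, unique, False,
            ))
    return pd.DataFrame(rows, columns=[
        "read_id", "cell", "umi", "chrom", "start", "end", "strand",
        "n_mismatch", "unique", "unmapped",
    ])


def filter_alignments(aln: pd.DataFrame, stats: dict | None = None) -> pd.DataFrame:
    """Keep uniquely mapping reads only; drop unmapped and multimappers."""
    if "unique" not in aln.columns:
        raise ValueError("alignments carry no uniqueness information")
    if stats is not None:
        stats["unmapped"] = int(aln["unmapped"].sum())
        stats["multimapped"] = int((~aln["unmapped"] & ~aln["unique"]).sum())
    kept = aln[~aln["unmapped"] & aln["unique"] & aln["cell"].notna()]
    if stats is not None:
        stats["unique"] = int(len(kept))
    return kept


def assign_genes(aln: pd.DataFrame, model: GeneModel,
                 policy: str = "sense", stats: dict | None = None) -> pd.DataFrame:
    """Assign each alignment to the unique overlapping gene.

    Reads overlapping no gene or more than one gene are dropped (counted
    as intergenic/ambiguous together under ``unassigned_gene``).
    """
    genes = [
        model.assign(ch, int(s), int(e), st, policy)
        for ch, s, e, st in zip(aln["chrom"], aln["start"], aln["end"], aln["strand"])
    ]
    out = aln.assign(gene=genes)
    kept = out[out["gene"].notna()]
    if stats is not None:
        stats["unassigned_gene"] = int(len(out) - len(kept))
        stats["gene_assigned"] = int(len(kept))
    return kept


def drop_n_umis(aln: pd.DataFrame, stats: dict | None = None) -> pd.DataFrame:
    """Exclude read pairs whose UMI contains a non-ACGT character."""
    ok = aln["umi"].map(lambda u: set(u) <= set("ACGT"))
    if stats is not None:
        stats["umi_with_n"] = int((~ok).sum())
    return aln[ok]


# ---------------------------------------------------------------------------
# UMI clustering
# ---------------------------------------------------------------------------


@dataclass
class UMICluster:
    """A connected component of the <=k-mismatch UMI graph."""

    members: tuple[str, ...]
    read_support: int


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cluster_umis(
    umi_counts: Mapping[str, int] | Sequence[tuple[str, int]],
    max_mismatch: int = 1,
) -> list[UMICluster]:
    """Cluster UMIs into connected components of the Hamming graph.

    Two UMIs are joined when their Hamming distance is at most
    ``max_mismatch``; clusters are the transitive closure (connected
    components), so a chain u1-u2-u3 with d(u1,u3)=2 still forms one
    cluster. Cluster read support is the sum over member read counts.
    Output order and member order are deterministic (lexicographic).
    """
    items = sorted(umi_counts.items() if isinstance(umi_counts, Mapping) else umi_counts)
    if not items:
        return []
    umis = [u for u, _ in items]
    lens = {len(u) for u in umis}
    if len(lens) != 1:
        raise ValueError("mixed UMI lengths")
    counts = {}
    for u, n in items:
        counts[u] = counts.get(u, 0) + int(n)
    umis = sorted(counts)
    n = len(umis)
    uf = _UnionFind(n)
    if max_mismatch == 1:
        # join via wildcard masks: two UMIs at distance <=1 share a mask
        masks: dict[str, int] = {}
        for i, u in enumerate(umis):
            for p in range(len(u)):
                key = f"{u[:p]}*{u[p + 1:]}"
                j = masks.setdefault(key, i)
                if j != i:
                    uf.union(j, i)
    elif max_mismatch >= 2:
        for i in range(n):
            ui = umis[i]
            for j in range(i + 1, n):
                d = sum(a != b for a, b in zip(ui, umis[j]))
                if d <= max_mismatch:
                    uf.union(i, j)
    clusters: dict[int, list[str]] = {}
    for i, u in enumerate(umis):
        clusters.setdefault(uf.find(i), []).append(u)
    out = [
        UMICluster(tuple(sorted(members)), sum(counts[u] for u in members))
        for members in clusters.values()
    ]
    out.sort(key=lambda cl: cl.members[0])
    return out


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------


@dataclass
class TranscriptCountMatrix:
    """Genes x cells UMI-cluster counts with metadata.

    ``matrix`` is CSR sparse with rows in ``gene_ids`` order and columns
    in ``cell_ids`` order. ``gene_meta`` carries the mitochondrial flag;
    ``cell_meta`` the well coordinate and sample when known.
    """

    matrix: scipy.sparse.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    gene_meta: pd.DataFrame
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("matrix dimensions inconsistent with metadata")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("counts must be non-negative")

    def to_dense_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix.toarray(), index=self.gene_ids, columns=self.cell_ids
        )

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=0)).ravel()

    def write_mtx(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(out_dir / "matrix.mtx", scipy.sparse.coo_matrix(self.matrix))
        self.gene_meta.to_csv(out_dir / "genes.tsv", sep="\t")
        self.cell_meta.to_csv(out_dir / "cells.tsv", sep="\t")

    @classmethod
    def read_mtx(cls, in_dir: str | Path) -> "TranscriptCountMatrix":
        in_dir = Path(in_dir)
        mat = scipy.sparse.csr_matrix(scipy.io.mmread(in_dir / "matrix.mtx"))
        gene_meta = pd.read_csv(in_dir / "genes.tsv", sep="\t", index_col=0)
        cell_meta = pd.read_csv(in_dir / "cells.tsv", sep="\t", index_col=0)
        return cls(mat, list(gene_meta.index), list(cell_meta.index), gene_meta, cell_meta)

    def to_anndata(self):
        """Convert to an AnnData (cells x genes) for interoperability."""
        import anndata

        return anndata.AnnData(
            X=self.matrix.T.tocsr(), obs=self.cell_meta.copy(), var=self.gene_meta.copy()
        )


def _mito_flags(gene_ids: Sequence[str], prefixes: Iterable[str] = MITO_PREFIXES) -> pd.Series:
    return pd.Series(
        [any(g.startswith(p) for p in prefixes) for g in gene_ids],
        index=list(gene_ids), name="mito",
    )


def count_transcripts(
    gene_reads: pd.DataFrame,
    config: CountingConfig | None = None,
    gene_ids: Sequence[str] | None = None,
    cell_meta: pd.DataFrame | None = None,
    return_audit: bool = False,
):
    """Count transcripts as qualifying UMI clusters per (cell, gene).

    ``gene_reads`` is the per-read table with columns cell, gene, umi
    (one row per uniquely-mapped, gene-assigned, N-free read). Reads with
    identical (cell, gene, UMI) collapse to one UMI entry with summed
    read count before clustering. count(cell, gene) is the number of
    clusters with read support >= ``min_reads_per_umi``.
    """
    config = config or CountingConfig()
    collapsed = (
        gene_reads.groupby(["cell", "gene", "umi"], sort=True).size().rename("n_reads").reset_index()
    )
    if gene_ids is None:
        gene_ids = sorted(collapsed["gene"].unique())
    cell_ids = sorted(collapsed["cell"].unique())
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    cell_index = {c: i for i, c in enumerate(cell_ids)}

    ii, jj, vv = [], [], []
    audit_rows = []
    for (cell, gene), sub in collapsed.groupby(["cell", "gene"], sort=True):
        clusters = cluster_umis(
            list(zip(sub["umi"], sub["n_reads"])), config.umi_max_mismatch
        )
        n = sum(1 for cl in clusters if cl.read_support >= config.min_reads_per_umi)
        if return_audit:
            for cl in clusters:
                audit_rows.append((
                    cell, gene, cl.members[0], len(cl.members), cl.read_support,
                    cl.read_support >= config.min_reads_per_umi,
                ))
        if n:
            ii.append(gene_index[gene])
            jj.append(cell_index[cell])
            vv.append(n)
    mat = scipy.sparse.csr_matrix(
        (vv, (ii, jj)), shape=(len(gene_ids), len(cell_ids)), dtype=np.int64
    )
    gene_meta = pd.DataFrame({"mito": _mito_flags(gene_ids)})
    if cell_meta is None:
        cell_meta = pd.DataFrame(index=pd.Index(cell_ids, name="cell"))
    else:
        cell_meta = cell_meta.reindex(cell_ids)
    tcm = TranscriptCountMatrix(mat, list(gene_ids), cell_ids, gene_meta, cell_meta)
    if return_audit:
        audit = pd.DataFrame(audit_rows, columns=[
            "cell", "gene", "representative_umi", "n_members", "read_support", "kept",
        ])
        return tcm, audit
    return tcm


def count_matrix(
    sam_path: str | Path,
    gene_model: GeneModel,
    config: CountingConfig | None = None,
    tagged_reads: pd.DataFrame | None = None,
) -> tuple[TranscriptCountMatrix, pd.DataFrame, dict]:
    """Full counting pipeline: SAM -> filtered, gene-assigned reads -> counts.

    Returns the count matrix, the per-read gene-aligned table (used by the
    read-depth saturation simulation) and a stats dict of filter counters.
    """
    config = config or CountingConfig()
    stats: dict = {}
    aln = read_alignments(sam_path, tagged_reads=tagged_reads)
    stats["total_records"] = int(len(aln))
    aln = filter_alignments(aln, stats)
    aln = assign_genes(aln, gene_model, config.strand_policy, stats)
    aln = drop_n_umis(aln, stats)
    gene_reads = aln[["read_id", "cell", "gene", "umi"]].reset_index(drop=True)

    cell_meta = None
    if tagged_reads is not None and len(tagged_reads):
        cell_meta = (
            tagged_reads.drop_duplicates("barcode")
            .set_index("barcode")[["row", "col", "sample"]]
        )
    tcm = count_transcripts(
        gene_reads, config, gene_ids=gene_model.gene_ids, cell_meta=cell_meta
    )
    return tcm, gene_reads, stats
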