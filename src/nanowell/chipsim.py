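"""Synthetic data generator for the nanowell single-cell RNA-seq pipeline.

Produces every input the downstream modules consume — chip layouts with
per-well barcodes, Poisson well occupancies, ground-truth expression
matrices, paired FASTQ reads, truth-derived SAM alignments, two-channel
well images, and checkerboard qPCR tables — together with serialized
ground truth so recovery can be verified exactly.

The default chip is the 72 x 72 layout of 5184 nanowells (150 nl each),
with an 11 bp well barcode and a 10 bp UMI read out on read 1 (25 bp)
while read 2 (50 bp) carries the cDNA sequence.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "ChipLayout",
    "DispenseSpec",
    "ReadStructure",
    "SimNoiseModel",
    "ImagingConfig",
    "CheckerboardConfig",
    "SimTruth",
    "SyntheticGenome",
    "ReadSet",
    "WellImageSet",
    "simulate_dispense",
    "simulate_expression",
    "emit_reads",
    "simulate_barnyard",
    "render_well_images",
    "simulate_checkerboard",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_N_CODE = ord("N")


def _decode(codes: np.ndarray) -> list[str]:
    """Convert an (n, L) array of base codes 0..3 into DNA strings."""
    chars = _BASES[codes]
    return [row.tobytes().decode("ascii") for row in chars]


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.empty(arr.size, dtype=np.uint8)
    for i, b in enumerate(_BASES):
        out[arr == b] = i
    return out


# ---------------------------------------------------------------------------
# Chip layout and dispense
# ---------------------------------------------------------------------------


@dataclass
class ChipLayout:
    """Geometry and barcoding of a nanowell microchip.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; the production chip is 72 x 72 (5184 wells).
    well_volume_nl
        Nominal well volume in nanolitres (150 nl on the production chip).
    barcode_map
        Mapping from well coordinate ``(row, col)`` to its 11-mer DNA
        barcode. All barcodes must be unique and over {A, C, G, T}.
    sample_regions
        Mapping from well coordinate to a sample label; the dispenser
        supports up to eight samples per chip.
    """

    n_rows: int = 72
    n_cols: int = 72
    well_volume_nl: float = 150.0
    barcode_map: dict[tuple[int, int], str] = field(default_factory=dict)
    sample_regions: dict[tuple[int, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("chip dimensions must be positive")
        if self.barcode_map:
            bcs = list(self.barcode_map.values())
            if len(set(bcs)) != len(bcs):
                raise ValueError("well barcodes must be unique")
            for bc in bcs:
                if len(bc) != len(bcs[0]) or set(bc) - set("ACGT"):
                    raise ValueError(f"invalid barcode {bc!r}")
        if len(set(self.sample_regions.values())) > 8:
            raise ValueError("at most 8 samples per chip")

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    def wells(self) -> list[tuple[int, int]]:
        return [(r, c) for r in range(self.n_rows) for c in range(self.n_cols)]

    @classmethod
    def generate(
        cls,
        n_rows: int = 72,
        n_cols: int = 72,
        seed: int = 0,
        barcode_len: int = 11,
        min_hamming: int = 3,
        samples: Sequence[str] = ("sample1",),
        well_volume_nl: float = 150.0,
    ) -> "ChipLayout":
        """Generate a layout with rejection-sampled well barcodes.

        Barcodes are drawn uniformly over 4**barcode_len and accepted only
        if at least ``min_hamming`` mismatches from every barcode already
        accepted, so that perfect-match demultiplexing is unambiguous even
        in the presence of one or two sequencing errors.

        Samples are assigned to contiguous row bands of equal height.
        """
        n = n_rows * n_cols
        rng = np.random.default_rng(seed)
        accepted = np.empty((n, barcode_len), dtype=np.uint8)
        k = 0
        while k < n:
            batch = rng.integers(0, 4, size=(max(256, n - k), barcode_len), dtype=np.uint8)
            for cand in batch:
                if k:
                    d = (accepted[:k] != cand).sum(axis=1)
                    if d.min() < min_hamming:
                        continue
                accepted[k] = cand
                k += 1
                if k == n:
                    break
        barcodes = _decode(accepted)
        wells = [(r, c) for r in range(n_rows) for c in range(n_cols)]
        barcode_map = dict(zip(wells, barcodes))
        band = max(1, n_rows // len(samples))
        sample_regions = {
            (r, c): samples[min(r // band, len(samples) - 1)] for (r, c) in wells
        }
        return cls(n_rows, n_cols, well_volume_nl, barcode_map, sample_regions)

    def to_tsv(self, path: str | Path) -> None:
        """Write the barcode map as TSV (columns row, col, barcode, sample)."""
        rows = [
            (r, c, self.barcode_map[(r, c)], self.sample_regions.get((r, c), "sample1"))
            for (r, c) in sorted(self.barcode_map)
        ]
        pd.DataFrame(rows, columns=["row", "col", "barcode", "sample"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "ChipLayout":
        df = pd.read_csv(path, sep="\t")
        barcode_map = {
            (int(r), int(c)): b for r, c, b in zip(df["row"], df["col"], df["barcode"])
        }
        sample_regions = {
            (int(r), int(c)): s for r, c, s in zip(df["row"], df["col"], df["sample"])
        }
        n_rows = int(df["row"].max()) + 1
        n_cols = int(df["col"].max()) + 1
        return cls(n_rows, n_cols, barcode_map=barcode_map, sample_regions=sample_regions, **kwargs)


@dataclass
class DispenseSpec:
    """Limiting-dilution dispense model: cells per well are i.i.d. Poisson."""

    lambda_cells_per_well: float = 1.0
    live_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_cells_per_well <= 0:
            raise ValueError("lambda_cells_per_well must be positive")
        if not 0.0 <= self.live_fraction <= 1.0:
            raise ValueError("live_fraction must be in [0, 1]")


@dataclass
class ReadStructure:
    """Read geometry: read 1 carries barcode + UMI, read 2 the cDNA."""

    barcode_len: int = 11
    umi_len: int = 10
    read1_len: int = 25
    read2_len: int = 50

    def __post_init__(self) -> None:
        if self.barcode_len + self.umi_len > self.read1_len:
            raise ValueError("barcode + UMI must fit within read 1")


@dataclass
class SimNoiseModel:
    """Library noise model.

    Parameters
    ----------
    base_error_rate
        Per-base substitution probability applied to the barcode portion of
        read 1 and to read 2 (typical Illumina substitution rates).
    umi_error_rate
        Per-base substitution probability on the UMI.
    umi_n_rate
        Per-base probability of an N no-call within the UMI.
    pcr_duplication
        Distribution of reads per molecule (mean >= 1): an int for a
        constant, or ``("poisson", m)`` / ``("geometric", m)`` for
        1 + Poisson(m - 1) or 1 + Geometric with mean m.
    chimera_rate
        Probability that a read's cDNA is swapped to a random gene while
        keeping its UMI (chimeric PCR product).
    ambient_fraction
        Fraction of each cell's molecules replaced by molecules drawn from
        the pooled expression background (ambient RNA).
    """

    base_error_rate: float = 0.005
    umi_error_rate: float = 0.005
    umi_n_rate: float = 0.002
    pcr_duplication: int | tuple[str, float] = ("geometric", 4.0)
    chimera_rate: float = 0.01
    ambient_fraction: float = 0.02

    def __post_init__(self) -> None:
        for r in (self.base_error_rate, self.umi_error_rate, self.umi_n_rate,
                  self.chimera_rate, self.ambient_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError("noise rates must be in [0, 1]")
        if isinstance(self.pcr_duplication, (int, np.integer)):
            if self.pcr_duplication < 1:
                raise ValueError("reads per molecule must be >= 1")
        else:
            kind, m = self.pcr_duplication
            if kind not in ("poisson", "geometric") or m < 1:
                raise ValueError("pcr_duplication must have mean >= 1")

    @classmethod
    def noiseless(cls, reads_per_umi: int = 2) -> "SimNoiseModel":
        return cls(0.0, 0.0, 0.0, reads_per_umi, 0.0, 0.0)

    def draw_reads_per_molecule(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if isinstance(self.pcr_duplication, (int, np.integer)):
            return np.full(n, int(self.pcr_duplication), dtype=np.int64)
        kind, m = self.pcr_duplication
        if kind == "poisson":
            return 1 + rng.poisson(m - 1.0, size=n)
        # geometric on {1, 2, ...} with mean m
        return rng.geometric(1.0 / m, size=n)


@dataclass
class SimTruth:
    """Ground truth shared by all recovery tests.

    Attributes
    ----------
    well_contents
        Well coordinate -> list of ``(cell_id, species, live)`` tuples.
    true_counts
        Cells x genes integer DataFrame of true molecule counts.
    cell_types
        Optional per-cell type labels (index matches ``true_counts``).
    doublet_flags
        Well -> True when the well holds two or more cells.
    provenance
        Per-read provenance table filled in by :func:`emit_reads`.
    """

    well_contents: dict[tuple[int, int], list[tuple[str, str, bool]]] = field(default_factory=dict)
    true_counts: pd.DataFrame | None = None
    cell_types: pd.Series | None = None
    doublet_flags: dict[tuple[int, int], bool] = field(default_factory=dict)
    provenance: pd.DataFrame | None = None

    def occupancy_counts(self) -> np.ndarray:
        """Number of cells per well as a flat array over all listed wells."""
        return np.array([len(v) for v in self.well_contents.values()], dtype=int)

    def well_of_cell(self) -> dict[str, tuple[int, int]]:
        out: dict[str, tuple[int, int]] = {}
        for well, cells in self.well_contents.items():
            for cid, _species, _live in cells:
                out[cid] = well
        return out

    def single_live_cell_wells(self) -> set[tuple[int, int]]:
        """Wells containing exactly one cell, which is live.

        These are the wells an ideal image-based selection would pick:
        one object in the live-stain channel and none in the dead-stain
        channel.
        """
        out = set()
        for well, cells in self.well_contents.items():
            if len(cells) == 1 and cells[0][2]:
                out.add(well)
        return out

    def place_cells(self, layout: ChipLayout, cell_ids: Sequence[str] | None = None,
                    species: str = "sample1") -> None:
        """Assign cells from ``true_counts`` one per well, row-major.

        Convenience for expression-only truths that were not produced by
        :func:`simulate_dispense`.
        """
        if cell_ids is None:
            if self.true_counts is None:
                raise ValueError("no cells to place")
            cell_ids = list(self.true_counts.index)
        wells = [(r, c) for r in range(layout.n_rows) for c in range(layout.n_cols)]
        if len(cell_ids) > len(wells):
            raise ValueError("more cells than wells")
        for cid, well in zip(cell_ids, wells):
            self.well_contents[well] = [(cid, species, True)]
            self.doublet_flags[well] = False


def simulate_dispense(layout: ChipLayout, spec: DispenseSpec) -> SimTruth:
    """Dispense cells into wells with i.i.d. Poisson occupancy.

    Each well receives ``Poisson(lambda_cells_per_well)`` cells; each cell
    is independently live with probability ``live_fraction``. The species
    label of a cell is the sample label of its well. At lambda = 1 about a
    third of wells hold exactly one cell (5184 e^-1 ~ 1907 wells on the
    full chip).
    """
    rng = np.random.default_rng(spec.seed)
    wells = layout.wells()
    counts = rng.poisson(spec.lambda_cells_per_well, size=len(wells))
    truth = SimTruth()
    cell_no = 0
    for well, n in zip(wells, counts):
        contents = []
        for _ in range(int(n)):
            live = bool(rng.random() < spec.live_fraction)
            species = layout.sample_regions.get(well, "sample1")
            contents.append((f"cell{cell_no:06d}", species, live))
            cell_no += 1
        truth.well_contents[well] = contents
        truth.doublet_flags[well] = n >= 2
    return truth


# ---------------------------------------------------------------------------
# Expression truth
# ---------------------------------------------------------------------------


def simulate_expression(
    n_cell_types: int,
    markers_per_type: int,
    n_genes: int,
    depth: float,
    seed: int = 0,
    n_cells: int = 200,
    abundances: Sequence[float] | None = None,
    fold_change: float = 10.0,
    dispersion: float = 0.2,
    n_mito_genes: int = 5,
    mito_fraction: float = 0.06,
    mito_prefix: str = "mt-",
) -> SimTruth:
    """Draw a ground-truth cells x genes count matrix with marker structure.

    Each cell type has ``markers_per_type`` genes whose mean expression is
    multiplied by ``fold_change`` in that type. Counts are negative
    binomial with gene-wise mean scaled so the expected total per cell is
    ``depth``; ``dispersion`` is the NB overdispersion (variance =
    m + dispersion * m^2; 0 gives Poisson). The first ``n_mito_genes``
    non-marker genes are named with ``mito_prefix`` and tuned so that the
    expected mitochondrial share of transcripts is ``mito_fraction``.

    ``abundances`` gives relative cell-type frequencies (default uniform);
    the islet benchmark uses 38/26/22/14%.
    """
    if n_genes < n_cell_types * markers_per_type + n_mito_genes:
        raise ValueError("n_genes too small for requested markers and mito genes")
    if abundances is None:
        abundances = [1.0 / n_cell_types] * n_cell_types
    if len(abundances) != n_cell_types:
        raise ValueError("abundances must have one entry per cell type")
    abund = np.asarray(abundances, float)
    abund = abund / abund.sum()
    rng = np.random.default_rng(seed)

    marker_ids: list[np.ndarray] = []
    gene_names = []
    idx = 0
    for i in range(n_mito_genes):
        gene_names.append(f"{mito_prefix}g{idx:04d}")
        idx += 1
    for t in range(n_cell_types):
        ids = np.arange(idx, idx + markers_per_type)
        marker_ids.append(ids)
        for _ in range(markers_per_type):
            gene_names.append(f"g{idx:04d}")
            idx += 1
    while idx < n_genes:
        gene_names.append(f"g{idx:04d}")
        idx += 1

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    if n_mito_genes:
        base[:n_mito_genes] = rng.lognormal(0.0, 0.25, size=n_mito_genes)

    # per-type mean profiles
    means = np.tile(base, (n_cell_types, 1))
    for t in range(n_cell_types):
        means[t, marker_ids[t]] *= fold_change
    # calibrate the expected mitochondrial share of each type's library
    if n_mito_genes:
        non_mito = means[:, n_mito_genes:].sum(axis=1)
        mito = means[:, :n_mito_genes].sum(axis=1)
        means[:, :n_mito_genes] *= (
            mito_fraction / (1 - mito_fraction) * non_mito / mito
        )[:, None]
    means *= depth / means.sum(axis=1, keepdims=True)

    n_per_type = rng.multinomial(n_cells, abund)
    type_of_cell = np.repeat(np.arange(n_cell_types), n_per_type)
    m = means[type_of_cell]
    if dispersion > 0:
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, m * dispersion)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(m)

    cell_ids = [f"cell{i:06d}" for i in range(n_cells)]
    truth = SimTruth(
        true_counts=pd.DataFrame(counts, index=cell_ids, columns=gene_names),
        cell_types=pd.Series([f"type{t}" for t in type_of_cell], index=cell_ids, name="cell_type"),
    )
    return truth


# ---------------------------------------------------------------------------
# Synthetic genome / gene model
# ---------------------------------------------------------------------------


@dataclass
class SyntheticGenome:
    """One-interval-per-gene synthetic annotation with sequence.

    Genes are laid end to end (with spacers) on a single contig, all on the
    plus strand, so gene assignment of an aligned read is unambiguous.
    Coordinates are 0-based half-open internally; the GTF writer emits the
    standard 1-based closed convention.
    """

    chrom: str
    length: int
    seq_codes: np.ndarray  # uint8 codes 0..3 for the whole contig
    genes: pd.DataFrame    # gene_id, start, end (0-based half-open), strand

    @classmethod
    def generate(cls, gene_ids: Sequence[str], seed: int = 0,
                 gene_length: int = 300, spacer: int = 100) -> "SyntheticGenome":
        rng = np.random.default_rng(seed)
        n = len(gene_ids)
        length = n * (gene_length + spacer) + spacer
        seq = rng.integers(0, 4, size=length, dtype=np.uint8)
        starts = spacer + np.arange(n) * (gene_length + spacer)
        genes = pd.DataFrame({
            "gene_id": list(gene_ids),
            "start": starts,
            "end": starts + gene_length,
            "strand": "+",
        })
        return cls("chrS", length, seq, genes)

    def write_gtf(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for _, g in self.genes.iterrows():
                attrs = f'gene_id "{g.gene_id}";'
                fh.write(
                    f"{self.chrom}\tnanowell_sim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )

    def write_fasta(self, path: str | Path) -> None:
        seq = _BASES[self.seq_codes].tobytes().decode("ascii")
        with open(path, "w") as fh:
            fh.write(f">{self.chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# Read emission
# ---------------------------------------------------------------------------


@dataclass
class ReadSet:
    """Paths and provenance of an emitted synthetic library."""

    r1_path: Path
    r2_path: Path
    sam_path: Path
    genome: SyntheticGenome
    provenance: pd.DataFrame


def _umi_neighbors(code: int, umi_len: int) -> Iterable[int]:
    """All integer UMI codes at Hamming distance exactly 1."""
    for p in range(umi_len):
        digit = (code >> (2 * p)) & 3
        for d in range(4):
            if d != digit:
                yield code ^ ((digit ^ d) << (2 * p))


def _draw_umis(rng: np.random.Generator, mol_cell: np.ndarray, mol_gene: np.ndarray,
               umi_len: int, collision_free: bool) -> np.ndarray:
    n = mol_cell.size
    space = 4 ** umi_len
    if not collision_free:
        return rng.integers(0, space, size=n, dtype=np.int64)
    umis = np.empty(n, dtype=np.int64)
    order = np.lexsort((mol_gene, mol_cell))
    key = mol_cell.astype(np.int64) * (mol_gene.max() + 1 if n else 1) + mol_gene
    blocked: set[int] = set()
    prev_key = None
    for i in order:
        k = key[i]
        if k != prev_key:
            blocked = set()
            prev_key = k
        while True:
            cand = int(rng.integers(0, space))
            if cand not in blocked:
                break
        umis[i] = cand
        blocked.add(cand)
        blocked.update(_umi_neighbors(cand, umi_len))
    return umis


def _codes_to_strings(codes: np.ndarray) -> np.ndarray:
    """(n, L) uint8 ASCII array -> array of python strings."""
    return codes.view(f"S{codes.shape[1]}").ravel().astype(str)


def _apply_subs(rng: np.random.Generator, codes: np.ndarray, rate: float) -> np.ndarray:
    """Substitute bases (codes 0..3) in place at the given rate; returns mask."""
    if rate <= 0:
        return np.zeros(codes.shape, dtype=bool)
    mask = rng.random(codes.shape) < rate
    shift = rng.integers(1, 4, size=mask.sum())
    codes[mask] = (codes[mask] + shift) % 4
    return mask


def emit_reads(
    truth: SimTruth,
    layout: ChipLayout,
    structure: ReadStructure | None = None,
    noise: SimNoiseModel | None = None,
    seed: int = 0,
    genome: SyntheticGenome | None = None,
    out_dir: str | Path = ".",
    prefix: str = "sim",
    collision_free_umis: bool = False,
) -> ReadSet:
    """Emit paired FASTQ, a truth-derived SAM, and a provenance table.

    Every true molecule receives a UMI uniform over 4**umi_len (with
    replacement by default, so collisions are possible and testable; set
    ``collision_free_umis`` to force pairwise Hamming distance >= 2 within
    each (cell, gene), which makes noiseless quantification an exact
    identity). Molecules are expanded into PCR duplicate reads, ambient
    molecules and chimeric reads are injected per the noise model, and
    substitution errors are applied to barcode, UMI and cDNA bases.

    Read 1 is barcode + UMI padded with T to ``read1_len``; read 2 is a
    ``read2_len`` window of the (possibly chimeric) gene sequence, poly-A
    filled when the gene is shorter than the read. The SAM holds one
    record per pair, keyed by the read-2 alignment, with the sequenced
    barcode and UMI in CB/UB tags, the substitution count in NM, and NH=1.

    Output is byte-identical for identical inputs and seed.
    """
    structure = structure or ReadStructure()
    noise = noise or SimNoiseModel()
    if truth.true_counts is None:
        raise ValueError("truth has no expression matrix")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cells = list(truth.true_counts.index)
    genes = list(truth.true_counts.columns)
    well_of = truth.well_of_cell()
    for cid in cells:
        if cid not in well_of:
            raise ValueError(f"cell {cid} is not placed in any well")
        if well_of[cid] not in layout.barcode_map:
            raise ValueError(f"well {well_of[cid]} has no barcode")
    if genome is None:
        genome = SyntheticGenome.generate(genes, seed=seed + 1)

    counts = truth.true_counts.to_numpy()
    n_cells, n_genes = counts.shape

    # ambient RNA: replace a fraction of each cell's molecules by draws
    # from the pooled profile
    own = counts
    ambient = np.zeros_like(counts)
    if noise.ambient_fraction > 0:
        own = rng.binomial(counts, 1.0 - noise.ambient_fraction)
        pooled = counts.sum(axis=0).astype(float)
        pooled /= pooled.sum()
        lost = counts.sum(axis=1) - own.sum(axis=1)
        for i in range(n_cells):
            if lost[i] > 0:
                ambient[i] = rng.multinomial(lost[i], pooled)

    def flatten(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cell_idx, gene_idx = np.nonzero(mat)
        reps = mat[cell_idx, gene_idx]
        return np.repeat(cell_idx, reps), np.repeat(gene_idx, reps)

    oc, og = flatten(own)
    ac, ag = flatten(ambient)
    mol_cell = np.concatenate([oc, ac])
    mol_gene = np.concatenate([og, ag])
    mol_ambient = np.concatenate([
        np.zeros(oc.size, dtype=bool), np.ones(ac.size, dtype=bool)
    ])
    n_mol = mol_cell.size

    mol_umi = _draw_umis(rng, mol_cell, mol_gene, structure.umi_len, collision_free_umis)

    # PCR expansion
    dup = noise.draw_reads_per_molecule(rng, n_mol)
    read_mol = np.repeat(np.arange(n_mol), dup)
    n_reads = read_mol.size

    r_cell = mol_cell[read_mol]
    r_gene_true = mol_gene[read_mol]
    r_umi = mol_umi[read_mol]
    r_ambient = mol_ambient[read_mol]

    # chimeric reads keep their UMI but their cDNA comes from a random gene
    r_gene_obs = r_gene_true.copy()
    chimeric = np.zeros(n_reads, dtype=bool)
    if noise.chimera_rate > 0 and n_reads:
        chimeric = rng.random(n_reads) < noise.chimera_rate
        r_gene_obs[chimeric] = rng.integers(0, n_genes, size=int(chimeric.sum()))

    gene_starts = genome.genes["start"].to_numpy()
    gene_ends = genome.genes["end"].to_numpy()
    gene_lens = gene_ends - gene_starts
    L2 = structure.read2_len

    span = np.maximum(gene_lens[r_gene_obs] - L2, 0)
    frag_off = (rng.random(n_reads) * (span + 1)).astype(np.int64)
    abs_start = gene_starts[r_gene_obs] + frag_off

    # read 2 sequence codes, poly-A fill past the gene end
    window = abs_start[:, None] + np.arange(L2)
    within = window < gene_ends[r_gene_obs][:, None]
    window = np.minimum(window, genome.length - 1)
    r2_codes = genome.seq_codes[window]
    r2_codes[~within] = 0  # code 0 == A (poly-A tail)
    r2_errs = _apply_subs(rng, r2_codes, noise.base_error_rate)
    nm = r2_errs.sum(axis=1)

    # barcode codes per read (true well barcode, then sequencing errors)
    bc_codes_by_cell = np.stack([
        _encode(layout.barcode_map[well_of[cid]]) for cid in cells
    ])
    bc_codes = bc_codes_by_cell[r_cell].copy()
    _apply_subs(rng, bc_codes, noise.base_error_rate)

    # UMI codes: decode integer UMIs, apply substitutions and N no-calls
    shifts = 2 * np.arange(structure.umi_len)
    umi_codes = ((r_umi[:, None] >> shifts) & 3).astype(np.uint8)
    _apply_subs(rng, umi_codes, noise.umi_error_rate)
    umi_chars = _BASES[umi_codes]
    if noise.umi_n_rate > 0 and n_reads:
        nmask = rng.random(umi_codes.shape) < noise.umi_n_rate
        umi_chars[nmask] = _N_CODE

    true_umi_codes = ((mol_umi[:, None] >> shifts) & 3).astype(np.uint8)

    pad = structure.read1_len - structure.barcode_len - structure.umi_len
    r1_chars = np.concatenate([
        _BASES[bc_codes], umi_chars,
        np.full((n_reads, pad), ord("T"), dtype=np.uint8),
    ], axis=1)
    r2_chars = _BASES[r2_codes]

    read_ids = np.array([f"{prefix}:{i:08d}" for i in range(n_reads)])
    r1_strs = _codes_to_strings(r1_chars)
    r2_strs = _codes_to_strings(r2_chars)
    umi_strs = _codes_to_strings(umi_chars)
    bc_strs = _codes_to_strings(_BASES[bc_codes])

    q1 = "I" * structure.read1_len
    q2 = "I" * structure.read2_len
    r1_path = out_dir / f"{prefix}_R1.fastq.gz"
    r2_path = out_dir / f"{prefix}_R2.fastq.gz"
    with gzip.open(r1_path, "wt") as f1, gzip.open(r2_path, "wt") as f2:
        for rid, s1, s2 in zip(read_ids, r1_strs, r2_strs):
            f1.write(f"@{rid}\n{s1}\n+\n{q1}\n")
            f2.write(f"@{rid}\n{s2}\n+\n{q2}\n")

    sam_path = out_dir / f"{prefix}.sam"
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": genome.chrom, "LN": int(genome.length)}],
    }
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as bam:
        for i in range(n_reads):
            a = pysam.AlignedSegment(bam.header)
            a.query_name = read_ids[i]
            a.query_sequence = r2_strs[i]
            a.flag = 0
            a.reference_id = 0
            a.reference_start = int(abs_start[i])
            a.mapping_quality = 60
            a.cigarstring = f"{L2}M"
            a.query_qualities = pysam.qualitystring_to_array(q2)
            a.set_tags([
                ("NH", 1, "i"),
                ("NM", int(nm[i]), "i"),
                ("CB", bc_strs[i], "Z"),
                ("UB", umi_strs[i], "Z"),
            ])
            bam.write(a)

    gene_names = np.array(genes)
    cell_names = np.array(cells)
    true_umi_strs = _codes_to_strings(_BASES[true_umi_codes])
    provenance = pd.DataFrame({
        "read_id": read_ids,
        "cell_id": cell_names[r_cell],
        "gene_true": gene_names[r_gene_true],
        "gene_obs": gene_names[r_gene_obs],
        "umi_true": np.asarray(true_umi_strs)[read_mol],
        "umi_seq": umi_strs,
        "barcode_seq": bc_strs,
        "chimeric": chimeric,
        "ambient": r_ambient,
    })
    truth.provenance = provenance
    return ReadSet(r1_path, r2_path, sam_path, genome, provenance)


# ---------------------------------------------------------------------------
# Barnyard simulation
# ---------------------------------------------------------------------------


def simulate_barnyard(
    n_human: int,
    n_mouse: int,
    doublet_rate: float = 0.024,
    impurity: float = 0.03,
    seed: int = 0,
    depth_mean: float = 2000.0,
    depth_dispersion: float = 0.3,
) -> pd.DataFrame:
    """Simulate a one-to-one species-mixing (barnyard) experiment.

    Each of ``n_human + n_mouse`` barcodes holds one cell of the stated
    species; with probability ``doublet_rate`` a second cell whose species
    is drawn from the mixture proportions joins it (so in a balanced
    mixture half of all doublets are cross-species, and doubling the
    observed cross-species rate recovers the overall rate). Each member
    cell draws a negative-binomial total transcript count and assigns a
    fraction ``1 - impurity`` of its transcripts to its own species.

    Returns a per-barcode DataFrame with columns ``transcripts_h``,
    ``transcripts_m``, ``true_label`` in {human, mouse, doublet_same,
    doublet_cross} and ``is_doublet``.
    """
    if not 0.0 <= doublet_rate <= 1.0 or not 0.0 <= impurity <= 1.0:
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = n_human + n_mouse
    species = np.array(["human"] * n_human + ["mouse"] * n_mouse)
    rng.shuffle(species)
    p_h = n_human / n

    def draw_depth(k: int) -> np.ndarray:
        if depth_dispersion > 0:
            lam = rng.gamma(1.0 / depth_dispersion, depth_mean * depth_dispersion, size=k)
            return rng.poisson(lam)
        return rng.poisson(depth_mean, size=k)

    is_doublet = rng.random(n) < doublet_rate
    partner = np.where(rng.random(n) < p_h, "human", "mouse")

    th = np.zeros(n, dtype=np.int64)
    tm = np.zeros(n, dtype=np.int64)
    depths = draw_depth(n)
    partner_depths = draw_depth(n)
    for i in range(n):
        members = [(species[i], depths[i])]
        if is_doublet[i]:
            members.append((partner[i], partner_depths[i]))
        for sp, d in members:
            own = rng.binomial(d, 1.0 - impurity)
            if sp == "human":
                th[i] += own
                tm[i] += d - own
            else:
                tm[i] += own
                th[i] += d - own

    label = species.astype(object)
    cross = is_doublet & (partner != species)
    same = is_doublet & (partner == species)
    label[cross] = "doublet_cross"
    label[same] = "doublet_same"
    return pd.DataFrame({
        "cell_id": [f"cell{i:06d}" for i in range(n)],
        "transcripts_h": th,
        "transcripts_m": tm,
        "true_label": label,
        "is_doublet": is_doublet,
    }).set_index("cell_id")


# ---------------------------------------------------------------------------
# Well image rendering
# ---------------------------------------------------------------------------


@dataclass
class ImagingConfig:
    """Optics of the synthetic well imager.

    A field covers a 6 x 6 block of wells; the full 72 x 72 chip therefore
    yields 144 fields per channel (288 images total for the two stains).
    """

    blob_sigma: float = 1.3
    snr: float = 10.0
    well_px: int = 16
    wells_per_field_side: int = 6
    background: float = 1000.0
    amplitude: float = 20000.0
    position_jitter_px: float = 0.25

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("SNR must be positive")

    @property
    def field_px(self) -> int:
        return self.well_px * self.wells_per_field_side

    @property
    def noise_sd(self) -> float:
        return self.amplitude / self.snr


@dataclass
class WellImageSet:
    """Rendered two-channel field images plus the truth object table."""

    fields: np.ndarray        # (n_fields, 2, H, W) uint16; channel 0 = live stain
    field_grid: tuple[int, int]
    config: ImagingConfig
    layout: ChipLayout
    objects: pd.DataFrame     # row, col, field, y, x (field pixels), live

    @property
    def n_fields(self) -> int:
        return self.fields.shape[0]

    def well_pixel_bounds(self, field: int, row: int, col: int) -> tuple[int, int, int, int]:
        cfg = self.config
        s = cfg.wells_per_field_side
        fy, fx = divmod(field, self.field_grid[1])
        r0 = row - fy * s
        c0 = col - fx * s
        return (r0 * cfg.well_px, (r0 + 1) * cfg.well_px,
                c0 * cfg.well_px, (c0 + 1) * cfg.well_px)

    def well_of_pixel(self, field: int, y: float, x: float) -> tuple[int, int] | None:
        cfg = self.config
        s = cfg.wells_per_field_side
        fy, fx = divmod(field, self.field_grid[1])
        r = int(y // cfg.well_px) + fy * s
        c = int(x // cfg.well_px) + fx * s
        if 0 <= r < self.layout.n_rows and 0 <= c < self.layout.n_cols:
            return (r, c)
        return None

    def write_tiffs(self, out_dir: str | Path, prefix: str = "field") -> list[Path]:
        import tifffile

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for f in range(self.n_fields):
            for ch in range(2):
                p = out_dir / f"{prefix}_{f:03d}_ch{ch + 1}.tif"
                tifffile.imwrite(p, self.fields[f, ch])
                paths.append(p)
        return paths


def render_well_images(
    truth: SimTruth,
    layout: ChipLayout,
    optics: ImagingConfig | None = None,
    seed: int = 0,
    noiseless: bool = False,
) -> WellImageSet:
    """Render 16-bit two-channel images of the dispensed chip.

    Live cells appear as Gaussian blobs in channel 1 (nuclear stain); dead
    cells appear in both channels (membrane-compromised cells take up the
    dead stain as well). Cells within a well are positioned with a minimum
    separation so they resolve as distinct objects. Gaussian background
    noise is added at ``amplitude / snr`` unless ``noiseless``.
    """
    optics = optics or ImagingConfig()
    if layout.n_rows % optics.wells_per_field_side or layout.n_cols % optics.wells_per_field_side:
        raise ValueError("chip dimensions must be a multiple of the field size")
    rng = np.random.default_rng(seed)
    s = optics.wells_per_field_side
    grid = (layout.n_rows // s, layout.n_cols // s)
    n_fields = grid[0] * grid[1]
    H = optics.field_px
    fields = np.zeros((n_fields, 2, H, H), dtype=np.float64)
    fields += optics.background

    obj_rows = []
    # Cells settle at well anchor positions (corners plus centre of each
    # well, >= 5 px apart at the default geometry) with a small jitter, so
    # co-occupying cells resolve as distinct blobs at the default scale.
    anchors = [(0.25, 0.25), (0.75, 0.75), (0.25, 0.75), (0.75, 0.25), (0.5, 0.5)]
    for (r, c), cells in truth.well_contents.items():
        if not cells:
            continue
        fy, fx = r // s, c // s
        f = fy * grid[1] + fx
        y0 = (r - fy * s) * optics.well_px
        x0 = (c - fx * s) * optics.well_px
        for i, (cid, _species, live) in enumerate(cells):
            ay, ax = anchors[i % len(anchors)]
            j = optics.position_jitter_px
            y = y0 + ay * optics.well_px + rng.uniform(-j, j)
            x = x0 + ax * optics.well_px + rng.uniform(-j, j)
            obj_rows.append((r, c, f, y, x, live))
            yy, xx = np.mgrid[0:H, 0:H]
            blob = optics.amplitude * np.exp(
                -((yy - y) ** 2 + (xx - x) ** 2) / (2 * optics.blob_sigma ** 2)
            )
            fields[f, 0] += blob
            if not live:
                fields[f, 1] += blob

    if not noiseless:
        fields += rng.normal(0.0, optics.noise_sd, size=fields.shape)
    fields = np.clip(fields, 0, 65535).astype(np.uint16)
    objects = pd.DataFrame(obj_rows, columns=["row", "col", "field", "y", "x", "live"])
    return WellImageSet(fields, grid, optics, layout, objects)


# ---------------------------------------------------------------------------
# Checkerboard dispenser QC simulation
# ---------------------------------------------------------------------------


@dataclass
class CheckerboardConfig:
    """Signal models for the checkerboard qPCR assay.

    Positive wells amplify lambda DNA (Ct ~ Normal(ct_mean, ct_sd), Tm ~
    Normal(tm_mean, tm_sd)). A ``true_misalignment`` fraction of Test
    wells receives the same product via dispenser-tip misalignment. An
    unrelated ``background_rate`` of false signal with on-target melt
    hits Test and NTC wells equally (the subtraction estimator removes
    it), and an ``offtarget_rate`` produces signal with melt temperature
    drawn from the off-target model (removed by the melt filter).
    """

    true_misalignment: float = 0.001
    background_rate: float = 0.0005
    offtarget_rate: float = 0.0
    ct_mean: float = 20.0
    ct_sd: float = 1.0
    tm_mean: float = 85.0
    tm_sd: float = 0.3
    offtarget_tm_mean: float = 75.0
    offtarget_tm_sd: float = 1.0


def simulate_checkerboard(
    layout: ChipLayout | None = None,
    n_ntc: int = 2520,
    n_positive: int = 1024,
    n_test: int = 1496,
    config: CheckerboardConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the checkerboard dispenser-QC assay.

    The default well-class counts follow the production chip protocol:
    negative control master mix in one half of the chip (2520 NTC wells)
    and lambda DNA / negative mix in an alternating pattern in the other
    half (1024 Positive and 1496 Test wells).

    Returns a per-well DataFrame with columns ``row, col, well_class, ct,
    tm`` plus a truth column ``origin`` in
    {none, positive, misaligned, background, offtarget}.
    """
    layout = layout or ChipLayout(72, 72)
    config = config or CheckerboardConfig()
    total = n_ntc + n_positive + n_test
    if total > layout.n_wells:
        raise ValueError("well classes do not fit on the chip")
    rng = np.random.default_rng(seed)

    wells = layout.wells()[:total]
    classes = ["NTC"] * n_ntc
    pos_left, test_left = n_positive, n_test
    for i in range(n_positive + n_test):
        if (i % 2 == 0 and pos_left) or not test_left:
            classes.append("Positive")
            pos_left -= 1
        else:
            classes.append("Test")
            test_left -= 1

    rows = []
    for (r, c), cls in zip(wells, classes):
        ct = np.nan
        tm = np.nan
        origin = "none"
        if cls == "Positive":
            origin = "positive"
            ct = rng.normal(config.ct_mean, config.ct_sd)
            tm = rng.normal(config.tm_mean, config.tm_sd)
        else:
            u = rng.random()
            if cls == "Test" and u < config.true_misalignment:
                origin = "misaligned"
                ct = rng.normal(config.ct_mean + 2.0, config.ct_sd)
                tm = rng.normal(config.tm_mean, config.tm_sd)
            elif rng.random() < config.background_rate:
                origin = "background"
                ct = rng.normal(config.ct_mean + 5.0, config.ct_sd)
                tm = rng.normal(config.tm_mean, config.tm_sd)
            elif rng.random() < config.offtarget_rate:
                origin = "offtarget"
                ct = rng.normal(config.ct_mean + 8.0, config.ct_sd)
                tm = rng.normal(config.offtarget_tm_mean, config.offtarget_tm_sd)
        rows.append((r, c, cls, ct, tm, origin))
    return pd.DataFrame(rows, columns=["row", "col", "well_class", "ct", "tm", "origin"])
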