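"""Shared fixtures: a small noiseless chip run used across modules."""

from __future__ import annotations

import pytest

from nanowell import chipsim, demux, quantify


@pytest.fixture(scope="session")
def small_layout():
    return chipsim.ChipLayout.generate(6, 6, seed=11)


@pytest.fixture(scope="session")
def noiseless_run(tmp_path_factory, small_layout):
    """A small noiseless library: 20 cells x 60 genes, 2 reads per UMI.

    Returns a dict with the truth, layout, emitted read set, barcode map,
    demultiplexed reads and gene model — enough to exercise every stage.
    """
    out = tmp_path_factory.mktemp("noiseless_run")
    truth = chipsim.simulate_expression(
        n_cell_types=2, markers_per_type=5, n_genes=60, depth=300,
        seed=21, n_cells=20,
    )
    truth.place_cells(small_layout)
    reads = chipsim.emit_reads(
        truth, small_layout, noise=chipsim.SimNoiseModel.noiseless(reads_per_umi=2),
        seed=22, out_dir=out, collision_free_umis=True,
    )
    barcodes_tsv = out / "barcodes.tsv"
    gtf = out / "genes.gtf"
    small_layout.to_tsv(barcodes_tsv)
    reads.genome.write_gtf(gtf)
    bmap = demux.load_barcode_map(barcodes_tsv)
    tagged, report = demux.demultiplex(reads.r1_path, reads.r2_path, bmap)
    model = quantify.load_gene_model(gtf)
    return {
        "truth": truth,
        "layout": small_layout,
        "reads": reads,
        "barcodes_tsv": barcodes_tsv,
        "gtf": gtf,
        "barcode_map": bmap,
        "tagged": tagged,
        "demux_report": report,
        "gene_model": model,
        "out_dir": out,
    }


def barcode_of_cell(run) -> dict[str, str]:
    """Map truth cell ids to their well barcodes."""
    layout = run["layout"]
    return {
        cid: layout.barcode_map[w] for cid, w in run["truth"].well_of_cell().items()
    }
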