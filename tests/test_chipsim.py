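"""Generator correctness: occupancy statistics, read emission, truth tables."""

import gzip

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nanowell import chipsim


class TestDispense:
    def test_rejects_nonpositive_lambda(self):
        with pytest.raises(ValueError):
            chipsim.DispenseSpec(lambda_cells_per_well=0.0)
        with pytest.raises(ValueError):
            chipsim.DispenseSpec(lambda_cells_per_well=-1.0)

    def test_single_cell_wells_near_poisson_expectation(self):
        """At lambda=1 the expected single-cell wells are n*e^-1 ~ 1907/5184."""
        layout = chipsim.ChipLayout(72, 72)
        spec = chipsim.DispenseSpec(1.0, live_fraction=1.0, seed=3)
        truth = chipsim.simulate_dispense(layout, spec)
        occ = truth.occupancy_counts()
        p1 = np.exp(-1.0)
        expected = layout.n_wells * p1
        sd = np.sqrt(layout.n_wells * p1 * (1 - p1))
        assert abs((occ == 1).sum() - expected) < 3 * sd

    def test_vanishing_lambda_gives_empty_chip(self):
        layout = chipsim.ChipLayout(72, 72)
        truth = chipsim.simulate_dispense(layout, chipsim.DispenseSpec(1e-9, seed=0))
        assert truth.occupancy_counts().sum() == 0

    def test_occupancy_histogram_matches_poisson_pmf(self):
        """Chi-square goodness of fit of the 0..4+ histogram at alpha=0.01."""
        layout = chipsim.ChipLayout(72, 72)
        truth = chipsim.simulate_dispense(layout, chipsim.DispenseSpec(1.0, seed=7))
        occ = truth.occupancy_counts()
        kmax = 5
        observed = np.array([(occ == k).sum() for k in range(kmax)] + [(occ >= kmax).sum()])
        pmf = stats.poisson.pmf(np.arange(kmax), 1.0)
        expected = np.append(pmf, 1 - pmf.sum()) * layout.n_wells
        _stat, p = stats.chisquare(observed, expected)
        assert p > 0.01

    def test_doublet_flags_mark_multioccupied_wells(self):
        layout = chipsim.ChipLayout(12, 12)
        truth = chipsim.simulate_dispense(layout, chipsim.DispenseSpec(2.0, seed=1))
        for well, cells in truth.well_contents.items():
            assert truth.doublet_flags[well] == (len(cells) >= 2)


class TestLayout:
    def test_barcodes_unique_and_min_distance(self):
        layout = chipsim.ChipLayout.generate(8, 8, seed=0)
        bcs = list(layout.barcode_map.values())
        assert len(set(bcs)) == len(bcs) == 64
        assert all(len(b) == 11 and set(b) <= set("ACGT") for b in bcs)
        arrs = np.array([[ord(c) for c in b] for b in bcs])
        d = (arrs[:, None, :] != arrs[None, :, :]).sum(axis=2)
        np.fill_diagonal(d, 99)
        assert d.min() >= 3

    def test_tsv_round_trip(self, tmp_path):
        layout = chipsim.ChipLayout.generate(6, 6, seed=4, samples=("a", "b"))
        p = tmp_path / "bc.tsv"
        layout.to_tsv(p)
        back = chipsim.ChipLayout.from_tsv(p)
        assert back.barcode_map == layout.barcode_map
        assert back.sample_regions == layout.sample_regions

    def test_duplicate_barcodes_rejected(self):
        with pytest.raises(ValueError):
            chipsim.ChipLayout(
                1, 2, barcode_map={(0, 0): "A" * 11, (0, 1): "A" * 11}
            )


class TestExpression:
    def test_markers_elevated_per_type(self):
        truth = chipsim.simulate_expression(
            4, 5, 100, depth=1000, seed=5, n_cells=200, fold_change=20.0
        )
        df = truth.true_counts
        for t in range(4):
            cells = truth.cell_types[truth.cell_types == f"type{t}"].index
            markers = [f"g{5 + 5 * t + i:04d}" for i in range(5)]
            others = [g for g in df.columns if g not in markers and not g.startswith("mt-")]
            assert df.loc[cells, markers].mean().mean() > df.loc[cells, others].mean().mean()

    def test_unit_fold_change_is_null(self):
        """fold_change=1: a type's markers are not elevated in that type."""
        truth = chipsim.simulate_expression(
            2, 5, 60, depth=500, seed=6, n_cells=200, fold_change=1.0
        )
        df = truth.true_counts
        markers_t0 = [f"g{5 + i:04d}" for i in range(5)]
        own = truth.cell_types == "type0"
        _t, p = stats.ttest_ind(
            df.loc[own, markers_t0].sum(axis=1),
            df.loc[~own, markers_t0].sum(axis=1),
        )
        assert p > 0.01

    def test_abundances_respected(self):
        truth = chipsim.simulate_expression(
            4, 5, 100, depth=500, seed=7, n_cells=1000,
            abundances=[0.38, 0.26, 0.22, 0.14],
        )
        frac = truth.cell_types.value_counts(normalize=True)
        for t, a in zip(range(4), [0.38, 0.26, 0.22, 0.14]):
            assert abs(frac[f"type{t}"] - a) < 0.05

    def test_dimension_validation(self):
        with pytest.raises(ValueError):
            chipsim.simulate_expression(4, 10, 20, depth=100, seed=0)


class TestEmitReads:
    def test_noiseless_duplication_arithmetic(self, tmp_path):
        """5 molecules at 2 reads each -> 10 pairs with 5 distinct doubled UMIs."""
        layout = chipsim.ChipLayout.generate(2, 2, seed=1)
        truth = chipsim.SimTruth(
            true_counts=pd.DataFrame({"gA": [5]}, index=["cell000000"])
        )
        truth.place_cells(layout)
        rs = chipsim.emit_reads(
            truth, layout, noise=chipsim.SimNoiseModel.noiseless(reads_per_umi=2),
            seed=2, out_dir=tmp_path, collision_free_umis=True,
        )
        prov = rs.provenance
        assert len(prov) == 10
        counts = prov["umi_true"].value_counts()
        assert len(counts) == 5 and (counts == 2).all()
        with gzip.open(rs.r1_path, "rt") as fh:
            lines = fh.read().splitlines()
        assert len(lines) == 40
        assert all(len(s) == 25 for s in lines[1::4])

    def test_provenance_conserves_reads(self, noiseless_run):
        n_pairs = noiseless_run["demux_report"]["total_pairs"]
        assert len(noiseless_run["reads"].provenance) == n_pairs

    def test_same_seed_byte_identical_different_seed_not(self, tmp_path):
        layout = chipsim.ChipLayout.generate(3, 3, seed=5)
        truth = chipsim.simulate_expression(2, 3, 20, depth=50, seed=6, n_cells=4)
        truth.place_cells(layout)
        outs = []
        for name, seed in (("a", 9), ("b", 9), ("c", 10)):
            rs = chipsim.emit_reads(truth, layout, seed=seed, out_dir=tmp_path / name)
            with gzip.open(rs.r1_path, "rb") as fh:
                outs.append(fh.read())
        assert outs[0] == outs[1]
        assert outs[0] != outs[2]

    def test_chimera_fraction_recovered_in_provenance(self, tmp_path):
        noise = chipsim.SimNoiseModel(
            base_error_rate=0.0, umi_error_rate=0.0, umi_n_rate=0.0,
            pcr_duplication=2, chimera_rate=0.05, ambient_fraction=0.0,
        )
        layout = chipsim.ChipLayout.generate(6, 6, seed=1)
        truth = chipsim.simulate_expression(2, 5, 50, depth=1500, seed=2, n_cells=30)
        truth.place_cells(layout)
        rs = chipsim.emit_reads(truth, layout, noise=noise, seed=3, out_dir=tmp_path)
        n = len(rs.provenance)
        frac = rs.provenance["chimeric"].mean()
        sd = np.sqrt(0.05 * 0.95 / n)
        assert abs(frac - 0.05) < 3 * sd
        # chimeric reads observe a different gene most of the time
        chim = rs.provenance[rs.provenance["chimeric"]]
        assert (chim["gene_obs"] != chim["gene_true"]).mean() > 0.9

    def test_unplaced_cell_rejected(self):
        layout = chipsim.ChipLayout.generate(2, 2, seed=0)
        truth = chipsim.SimTruth(true_counts=pd.DataFrame({"g": [1]}, index=["c0"]))
        with pytest.raises(ValueError, match="not placed"):
            chipsim.emit_reads(truth, layout)


class TestBarnyard:
    def test_pure_singlets_have_no_cross_species_transcripts(self):
        df = chipsim.simulate_barnyard(50, 50, doublet_rate=0.0, impurity=0.0, seed=1)
        human = df[df["true_label"] == "human"]
        mouse = df[df["true_label"] == "mouse"]
        assert (human["transcripts_m"] == 0).all()
        assert (mouse["transcripts_h"] == 0).all()

    def test_impurity_sets_singlet_own_fraction(self):
        df = chipsim.simulate_barnyard(250, 250, doublet_rate=0.0, impurity=0.03, seed=2)
        own = np.where(
            df["true_label"] == "human",
            df["transcripts_h"] / (df["transcripts_h"] + df["transcripts_m"]),
            df["transcripts_m"] / (df["transcripts_h"] + df["transcripts_m"]),
        )
        assert abs(np.median(own) - 0.97) < 0.01

    def test_doublet_rate_and_cross_fraction(self):
        df = chipsim.simulate_barnyard(1000, 1000, doublet_rate=0.1, impurity=0.0, seed=7)
        n = len(df)
        observed = df["is_doublet"].mean()
        assert abs(observed - 0.1) < 3 * np.sqrt(0.1 * 0.9 / n)
        # in a balanced mixture half the doublets are cross-species
        cross = (df["true_label"] == "doublet_cross").sum()
        doublets = df["is_doublet"].sum()
        assert abs(cross / doublets - 0.5) < 3 * np.sqrt(0.25 / doublets)


class TestImages:
    def test_empty_chip_renders_noise_only(self):
        layout = chipsim.ChipLayout(6, 6)
        truth = chipsim.SimTruth(well_contents={(r, c): [] for r in range(6) for c in range(6)})
        imgs = chipsim.render_well_images(truth, layout, seed=1, noiseless=True)
        assert imgs.objects.empty
        cfg = imgs.config
        assert (imgs.fields == int(cfg.background)).all()

    def test_single_live_cell_blob_inside_well_bounds(self):
        layout = chipsim.ChipLayout(6, 6)
        truth = chipsim.SimTruth(well_contents={(2, 3): [("c0", "s", True)]})
        imgs = chipsim.render_well_images(truth, layout, seed=2, noiseless=True)
        obj = imgs.objects.iloc[0]
        y0, y1, x0, x1 = imgs.well_pixel_bounds(int(obj.field), 2, 3)
        assert y0 <= obj.y < y1 and x0 <= obj.x < x1
        assert imgs.well_of_pixel(int(obj.field), obj.y, obj.x) == (2, 3)
        # live cell appears in channel 1 only
        f = int(obj.field)
        assert imgs.fields[f, 0].max() > imgs.fields[f, 1].max()

    def test_dead_cell_marks_both_channels(self):
        layout = chipsim.ChipLayout(6, 6)
        truth = chipsim.SimTruth(well_contents={(0, 0): [("c0", "s", False)]})
        imgs = chipsim.render_well_images(truth, layout, seed=3, noiseless=True)
        bg = imgs.config.background
        assert imgs.fields[0, 0].max() > bg + 1000
        assert imgs.fields[0, 1].max() > bg + 1000

    def test_full_chip_field_count(self):
        """72x72 wells tiled as 6x6-well fields give 144 fields per channel."""
        layout = chipsim.ChipLayout(72, 72)
        truth = chipsim.SimTruth(well_contents={})
        imgs = chipsim.render_well_images(truth, layout, seed=4, noiseless=True)
        assert imgs.n_fields == 144
        assert imgs.fields.shape[1] == 2

    def test_tiff_round_trip(self, tmp_path):
        import tifffile

        layout = chipsim.ChipLayout(6, 6)
        truth = chipsim.SimTruth(well_contents={(1, 1): [("c0", "s", True)]})
        imgs = chipsim.render_well_images(truth, layout, seed=5)
        paths = imgs.write_tiffs(tmp_path)
        assert len(paths) == 2
        back = tifffile.imread(paths[0])
        assert back.dtype == np.uint16
        np.testing.assert_array_equal(back, imgs.fields[0, 0])


class TestCheckerboard:
    def test_default_class_counts(self):
        df = chipsim.simulate_checkerboard(seed=0)
        counts = df["well_class"].value_counts()
        assert counts["NTC"] == 2520
        assert counts["Positive"] == 1024
        assert counts["Test"] == 1496

    def test_clean_assay_has_no_false_signal(self):
        cfg = chipsim.CheckerboardConfig(
            true_misalignment=0.0, background_rate=0.0, offtarget_rate=0.0
        )
        df = chipsim.simulate_checkerboard(config=cfg, seed=1)
        nonpos = df[df["well_class"] != "Positive"]
        assert nonpos["ct"].isna().all()
        assert (df.loc[df["well_class"] == "Positive", "ct"].notna()).all()

    def test_misaligned_wells_are_test_wells(self):
        cfg = chipsim.CheckerboardConfig(true_misalignment=0.01)
        df = chipsim.simulate_checkerboard(config=cfg, seed=2)
        mis = df[df["origin"] == "misaligned"]
        assert len(mis) > 0
        assert (mis["well_class"] == "Test").all()
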