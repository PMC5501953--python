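"""UMI clustering, gene assignment and transcript counting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nanowell import chipsim, quantify
from nanowell.quantify import CountingConfig, cluster_umis, count_transcripts

from conftest import barcode_of_cell


def brute_force_clusters(umi_counts: dict[str, int], max_mismatch: int):
    """Independent oracle: O(n^2) pairwise Hamming + connected components."""
    import scipy.sparse
    import scipy.sparse.csgraph

    umis = sorted(umi_counts)
    n = len(umis)
    codes = np.array([[ord(c) for c in u] for u in umis]) if n else np.empty((0, 0))
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if (codes[i] != codes[j]).sum() <= max_mismatch:
                adj[i, j] = adj[j, i] = True
    ncomp, labels = scipy.sparse.csgraph.connected_components(
        scipy.sparse.csr_matrix(adj), directed=False
    )
    comps = {}
    for i, lab in enumerate(labels):
        comps.setdefault(lab, []).append(umis[i])
    return sorted(
        (tuple(sorted(members)), sum(umi_counts[u] for u in members))
        for members in comps.values()
    )


class TestClusterUmis:
    def test_two_clusters_with_supports(self):
        clusters = cluster_umis(
            {"AAAAAAAAAA": 3, "AAAAAAAAAT": 1, "CCCCCCCCCC": 2}, max_mismatch=1
        )
        got = sorted((c.members, c.read_support) for c in clusters)
        assert got == [
            (("AAAAAAAAAA", "AAAAAAAAAT"), 4),
            (("CCCCCCCCCC",), 2),
        ]

    def test_single_umi(self):
        [c] = cluster_umis({"ACGTACGTAC": 7})
        assert c.members == ("ACGTACGTAC",) and c.read_support == 7

    def test_transitive_chain_merges(self):
        """d(u1,u2)=1, d(u2,u3)=1 but d(u1,u3)=2 still one cluster."""
        u1 = "AAAAAAAAAA"
        u2 = "AAAAAAAAAT"
        u3 = "AAAAAAAAGT"
        assert sum(a != b for a, b in zip(u1, u3)) == 2
        clusters = cluster_umis({u1: 1, u2: 1, u3: 1}, max_mismatch=1)
        assert len(clusters) == 1
        assert clusters[0].members == (u1, u2, u3)

    def test_zero_mismatch_keeps_distinct_umis_apart(self):
        clusters = cluster_umis({"AAAAAAAAAA": 1, "AAAAAAAAAT": 1}, max_mismatch=0)
        assert len(clusters) == 2

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            cluster_umis({"AAAA": 1, "AAAAA": 1})

    def test_empty_input(self):
        assert cluster_umis({}) == []

    @given(st.data())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, data):
        """Connected components agree with the pairwise-Hamming oracle."""
        L = data.draw(st.integers(4, 8))
        n_seeds = data.draw(st.integers(1, 8))
        rng_seed = data.draw(st.integers(0, 2 ** 20))
        rng = np.random.default_rng(rng_seed)
        bases = "ACGT"
        umis: dict[str, int] = {}
        seeds = ["".join(rng.choice(list(bases), L)) for _ in range(n_seeds)]
        for s in seeds:
            umis[s] = umis.get(s, 0) + int(rng.integers(1, 5))
            for _ in range(int(rng.integers(0, 4))):
                pos = int(rng.integers(0, L))
                mut = s[:pos] + bases[int(rng.integers(0, 4))] + s[pos + 1:]
                umis[mut] = umis.get(mut, 0) + int(rng.integers(1, 3))
        mm = data.draw(st.sampled_from([0, 1, 2]))
        got = sorted((c.members, c.read_support) for c in cluster_umis(umis, mm))
        assert got == brute_force_clusters(umis, mm)


class TestCountTranscripts:
    @staticmethod
    def reads_df(support_by_umi):
        rows = []
        for umi, n in support_by_umi.items():
            rows += [("cellA", "gene1", umi)] * n
        return pd.DataFrame(rows, columns=["cell", "gene", "umi"])

    @pytest.mark.parametrize("min_reads,expected", [(1, 3), (2, 2), (3, 1)])
    def test_read_support_thresholds(self, min_reads, expected):
        """Clusters with supports {4,2,1} survive per the minimum-reads rule."""
        df = self.reads_df({"AAAAAAAAAA": 4, "CCCCCCCCCC": 2, "GGGGGGGGGG": 1})
        tcm = count_transcripts(df, CountingConfig(min_reads_per_umi=min_reads))
        assert tcm.to_dense_df().loc["gene1", "cellA"] == expected

    def test_two_singletons_at_distance_one_survive_the_filter(self):
        """Two 1-read UMIs one mismatch apart form a support-2 cluster."""
        df = self.reads_df({"AAAAAAAAAA": 1, "AAAAAAAAAT": 1})
        cfg = CountingConfig(min_reads_per_umi=2, umi_max_mismatch=1)
        assert count_transcripts(df, cfg).to_dense_df().loc["gene1", "cellA"] == 1
        cfg0 = CountingConfig(min_reads_per_umi=2, umi_max_mismatch=0)
        assert count_transcripts(df, cfg0).matrix.nnz == 0

    def test_no_reads_gives_empty_matrix(self):
        df = pd.DataFrame(columns=["cell", "gene", "umi"])
        tcm = count_transcripts(df, gene_ids=["g1"])
        assert tcm.matrix.shape == (1, 0)

    def test_counts_monotone_in_min_reads(self, noiseless_run):
        model = noiseless_run["gene_model"]
        prev = None
        for mr in (1, 2, 3):
            cfg = CountingConfig(min_reads_per_umi=mr)
            tcm, _gr, _st = quantify.count_matrix(
                noiseless_run["reads"].sam_path, model, cfg,
                tagged_reads=noiseless_run["tagged"],
            )
            dense = tcm.to_dense_df()
            if prev is not None:
                assert (dense <= prev).all().all()
            prev = dense

    def test_matrix_total_equals_qualifying_clusters(self):
        df = self.reads_df({"AAAAAAAAAA": 4, "CCCCCCCCCC": 2, "GGGGGGGGGG": 1})
        tcm, audit = count_transcripts(
            df, CountingConfig(min_reads_per_umi=2), return_audit=True
        )
        assert tcm.matrix.sum() == audit["kept"].sum() == 2


class TestGeneModel:
    def test_gtf_round_trip(self, noiseless_run):
        model = noiseless_run["gene_model"]
        genome = noiseless_run["reads"].genome
        assert model.gene_ids == list(genome.genes["gene_id"])
        g = genome.genes.iloc[0]
        assert model.assign("chrS", int(g.start), int(g.start) + 50, "+") == g.gene_id

    def test_intergenic_and_antisense_unassigned(self, noiseless_run):
        model = noiseless_run["gene_model"]
        genome = noiseless_run["reads"].genome
        g = genome.genes.iloc[0]
        assert model.assign("chrS", 0, 50, "+") is None  # spacer region
        assert model.assign("chrS", int(g.start), int(g.start) + 50, "-") is None
        assert model.assign(
            "chrS", int(g.start), int(g.start) + 50, "-", policy="unstranded"
        ) == g.gene_id

    def test_read_overlapping_two_genes_is_ambiguous(self):
        genes = pd.DataFrame({
            "gene_id": ["a", "b"], "chrom": ["c1", "c1"],
            "start": [0, 90], "end": [100, 200], "strand": ["+", "+"],
        })
        model = quantify.GeneModel(genes)
        assert model.assign("c1", 85, 95, "+") is None
        assert model.assign("c1", 10, 60, "+") == "a"

    @pytest.mark.parametrize("line,msg", [
        ("chr1\tx\tgene\t1\t100\t.\t+\t.", "9 tab-separated"),
        ("chr1\tx\tgene\tone\t100\t.\t+\t.\tgene_id \"g\";", "non-integer"),
        ("chr1\tx\tgene\t100\t10\t.\t+\t.\tgene_id \"g\";", "invalid interval"),
        ("chr1\tx\tgene\t1\t100\t.\t*\t.\tgene_id \"g\";", "invalid strand"),
        ("chr1\tx\tgene\t1\t100\t.\t+\t.\tfoo \"g\";", "missing gene_id"),
    ])
    def test_malformed_gtf_reports_line_number(self, tmp_path, line, msg):
        p = tmp_path / "bad.gtf"
        p.write_text('chr1\tx\tgene\t1\t50\t.\t+\t.\tgene_id "ok";\n' + line + "\n")
        with pytest.raises(ValueError, match="2"):
            quantify.load_gene_model(p)


class TestFilters:
    def test_multimapper_dropped(self, tmp_path, noiseless_run):
        aln = pd.DataFrame({
            "read_id": ["a", "b", "c"],
            "cell": ["x", "x", "x"], "umi": ["A" * 10] * 3,
            "chrom": ["c"] * 3, "start": [0] * 3, "end": [50] * 3,
            "strand": ["+"] * 3, "n_mismatch": [0] * 3,
            "unique": [True, False, True], "unmapped": [False, False, True],
        })
        stats = {}
        kept = quantify.filter_alignments(aln, stats)
        assert list(kept["read_id"]) == ["a"]
        assert stats["multimapped"] == 1 and stats["unmapped"] == 1

    def test_missing_uniqueness_is_hard_error(self):
        with pytest.raises(ValueError, match="uniqueness"):
            quantify.filter_alignments(pd.DataFrame({"read_id": []}))

    def test_missing_nh_tag_is_hard_error(self, tmp_path):
        import pysam

        path = tmp_path / "no_nh.sam"
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "c", "LN": 1000}]}
        with pysam.AlignmentFile(str(path), "w", header=header) as fh:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = "r1"
            a.query_sequence = "A" * 50
            a.reference_id = 0
            a.reference_start = 10
            a.cigarstring = "50M"
            fh.write(a)
        with pytest.raises(ValueError, match="NH"):
            quantify.read_alignments(path)

    @pytest.mark.parametrize("umi,kept", [
        ("ACGTNACGTA", False), ("ACGTACGTAC", True), ("NNNNNNNNNN", False),
    ])
    def test_n_umi_exclusion(self, umi, kept):
        df = pd.DataFrame({"umi": [umi]})
        out = quantify.drop_n_umis(df)
        assert (len(out) == 1) is kept

    def test_n_umi_fraction_matches_binomial(self, tmp_path, small_layout):
        """Excluded fraction ~ 1 - (1 - p_N)^10 at UMI N-rate p_N."""
        pN = 0.01
        truth = chipsim.simulate_expression(2, 3, 30, depth=500, seed=41, n_cells=10)
        truth.place_cells(small_layout)
        noise = chipsim.SimNoiseModel(0.0, 0.0, pN, 1, 0.0, 0.0)
        rs = chipsim.emit_reads(truth, small_layout, noise=noise, seed=42, out_dir=tmp_path)
        aln = quantify.read_alignments(rs.sam_path)
        stats = {}
        quantify.drop_n_umis(aln, stats)
        p = 1 - (1 - pN) ** 10
        n = len(aln)
        assert abs(stats["umi_with_n"] / n - p) < 3 * np.sqrt(p * (1 - p) / n)


class TestEndToEnd:
    def test_noiseless_counts_equal_truth(self, noiseless_run):
        """Noiseless reads, min_reads=1: recovered counts == true counts."""
        cfg = CountingConfig(min_reads_per_umi=1)
        tcm, _gr, _stats = quantify.count_matrix(
            noiseless_run["reads"].sam_path, noiseless_run["gene_model"], cfg,
            tagged_reads=noiseless_run["tagged"],
        )
        truth = noiseless_run["truth"].true_counts.T  # genes x cells
        bc = barcode_of_cell(noiseless_run)
        rec = tcm.to_dense_df().reindex(
            index=truth.index, columns=[bc[c] for c in truth.columns]
        ).fillna(0).astype(int)
        rec.columns = truth.columns
        pd.testing.assert_frame_equal(rec, truth, check_names=False)

    def test_umi_clustering_reduces_count_error(self, tmp_path, small_layout):
        """With UMI errors, 1-mismatch clustering lowers RMSE to truth."""
        truth = chipsim.simulate_expression(2, 5, 40, depth=500, seed=51, n_cells=15)
        truth.place_cells(small_layout)
        noise = chipsim.SimNoiseModel(0.0, 0.02, 0.0, 2, 0.0, 0.0)
        rs = chipsim.emit_reads(
            truth, small_layout, noise=noise, seed=52, out_dir=tmp_path,
            collision_free_umis=True,
        )
        bc = {cid: small_layout.barcode_map[w] for cid, w in truth.well_of_cell().items()}
        genome = rs.genome
        gtf = tmp_path / "g.gtf"
        genome.write_gtf(gtf)
        model = quantify.load_gene_model(gtf)
        truthm = truth.true_counts.T

        def rmse(mm):
            cfg = CountingConfig(min_reads_per_umi=2, umi_max_mismatch=mm)
            tcm, _g, _s = quantify.count_matrix(rs.sam_path, model, cfg)
            rec = tcm.to_dense_df().reindex(
                index=truthm.index, columns=[bc[c] for c in truthm.columns]
            ).fillna(0)
            return float(np.sqrt(((rec.to_numpy() - truthm.to_numpy()) ** 2).mean()))

        assert rmse(1) < rmse(0)


class TestMatrixIO:
    def test_mtx_round_trip(self, tmp_path):
        df = TestCountTranscripts.reads_df({"AAAAAAAAAA": 4, "CCCCCCCCCC": 2})
        df = pd.concat([df, pd.DataFrame(
            [("cellB", "mt-g1", "GGGGGGGGGG")] * 3, columns=df.columns
        )])
        tcm = count_transcripts(df, CountingConfig(min_reads_per_umi=1))
        tcm.write_mtx(tmp_path)
        back = quantify.TranscriptCountMatrix.read_mtx(tmp_path)
        assert back.to_dense_df().equals(tcm.to_dense_df())
        assert back.gene_meta["mito"].tolist() == [False, True]

    def test_anndata_conversion(self):
        df = TestCountTranscripts.reads_df({"AAAAAAAAAA": 2})
        tcm = count_transcripts(df, CountingConfig(min_reads_per_umi=1))
        ad = tcm.to_anndata()
        assert ad.shape == (1, 1)
        assert ad.X.sum() == 1
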