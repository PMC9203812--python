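"""QC boundaries, gene-activity scoring, normalization and the
subpopulation statistic."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from chromkit.genome_io import GenomicInterval, IntervalSet
from chromkit.single_cell import (
    CellMatrix,
    ScConfig,
    gene_activity,
    normalize_atac,
    normalize_rna,
    qc_and_subsample,
    read_cell_matrix,
    relative_activity,
    subpopulation_enrichment,
    write_cell_matrix,
)


def atac_matrix(n_cells, n_feats=4, seed=0):
    rng = np.random.default_rng(seed)
    counts = rng.poisson(3, size=(n_cells, n_feats))
    feats = IntervalSet(
        [GenomicInterval("c", 100 * i, 100 * i + 80, "+", f"f{i}") for i in range(n_feats)]
    )
    return CellMatrix(
        sp.csr_matrix(counts),
        [f"cell{i:04d}" for i in range(n_cells)],
        [f"f{i}" for i in range(n_feats)],
        "atac_fragments",
        feats,
    )


class TestQcBoundaries:
    def test_atac_threshold_is_strict(self):
        m = atac_matrix(5)
        ann = pd.DataFrame(
            {
                "cell_id": m.cell_ids,
                "sample_id": "s1",
                "group": "control",
                "passed_filters": [500, 501, 502, 503, 504],
            }
        )
        cfg = ScConfig(atac_cells_per_sample=4)
        m2, ann2 = qc_and_subsample(m, ann, cfg)
        assert len(m2.cell_ids) == 4
        assert "cell0000" not in m2.cell_ids  # exactly 500 is dropped

    def test_rna_boundaries_kept(self):
        counts = sp.csr_matrix(np.ones((4, 3), dtype=int))
        m = CellMatrix(counts, [f"c{i}" for i in range(4)], ["g1", "g2", "g3"],
                       "rna_umis")
        ann = pd.DataFrame(
            {
                "cell_id": m.cell_ids,
                "sample_id": "s1",
                "group": "control",
                "pct_mito": [7.5, 7.6, 2.0, 2.0],
                "n_features": [800, 1000, 4000, 4001],
            }
        )
        cfg = ScConfig(rna_cells_per_sample=2)
        m2, _ = qc_and_subsample(m, ann, cfg)
        # pct_mito == 7.5 kept, 7.6 dropped; n_features 800 and 4000 kept,
        # 4001 dropped
        assert set(m2.cell_ids) == {"c0", "c2"}

    def test_exact_subsample_sizes(self):
        m = atac_matrix(30)
        ann = pd.DataFrame(
            {
                "cell_id": m.cell_ids,
                "sample_id": ["a"] * 15 + ["b"] * 15,
                "group": ["control"] * 15 + ["case"] * 15,
                "passed_filters": 1000,
            }
        )
        cfg = ScConfig(atac_cells_per_sample=10)
        m2, ann2 = qc_and_subsample(m, ann, cfg)
        assert ann2.groupby("sample_id").size().tolist() == [10, 10]

    def test_insufficient_cells_error_reports_counts(self):
        m = atac_matrix(5)
        ann = pd.DataFrame(
            {
                "cell_id": m.cell_ids,
                "sample_id": "s1",
                "group": "control",
                "passed_filters": [100, 100, 1000, 1000, 1000],
            }
        )
        with pytest.raises(ValueError, match="3 cells"):
            qc_and_subsample(m, ann, ScConfig(atac_cells_per_sample=4))

    def test_deterministic_and_order_invariant(self):
        m = atac_matrix(20)
        ann = pd.DataFrame(
            {
                "cell_id": m.cell_ids,
                "sample_id": "s1",
                "group": "control",
                "passed_filters": 1000,
            }
        )
        cfg = ScConfig(atac_cells_per_sample=8, seed=5)
        first, _ = qc_and_subsample(m, ann, cfg)
        second, _ = qc_and_subsample(m, ann, cfg)
        assert first.cell_ids == second.cell_ids
        perm = list(reversed(range(20)))
        m_shuf = CellMatrix(
            m.counts[perm], [m.cell_ids[i] for i in perm], m.feature_ids,
            m.modality, m.feature_intervals,
        )
        third, _ = qc_and_subsample(m_shuf, ann, cfg)
        assert third.cell_ids == first.cell_ids


class TestGeneActivity:
    def test_zero_fragment_cell_stays_zero(self):
        m = atac_matrix(3)
        m.counts[0] = 0
        m.counts.eliminate_zeros()
        genes = IntervalSet([GenomicInterval("c", 0, 400, "+", "G")])
        act = gene_activity(m, genes, ScConfig())
        assert act.counts[0].sum() == 0

    def test_upstream_extension_boundary(self):
        feats = IntervalSet(
            [
                GenomicInterval("c", 2999, 3000, "+", "just_in"),
                GenomicInterval("c", 2998, 2999, "+", "just_out"),
            ]
        )
        m = CellMatrix(
            sp.csr_matrix(np.array([[1, 1]])), ["c1"], ["just_in", "just_out"],
            "atac_fragments", feats,
        )
        genes = IntervalSet([GenomicInterval("c", 5000, 6000, "+", "G")])
        act = gene_activity(m, genes, ScConfig(gene_upstream_extension=2000))
        # window is [3000, 6000): a fragment ending at 3000 misses it,
        # one reaching base 3000 would be counted
        assert act.counts.toarray().tolist() == [[0]]
        feats2 = IntervalSet(
            [
                GenomicInterval("c", 3000, 3001, "+", "just_in"),
                GenomicInterval("c", 2998, 2999, "+", "just_out"),
            ]
        )
        m2 = CellMatrix(
            sp.csr_matrix(np.array([[1, 1]])), ["c1"], ["just_in", "just_out"],
            "atac_fragments", feats2,
        )
        assert gene_activity(m2, genes, ScConfig()).counts.toarray().tolist() == [[1]]

    def test_unstranded_gene_with_extension_rejected(self):
        m = atac_matrix(2)
        genes = IntervalSet([GenomicInterval("c", 0, 100, ".", "G")])
        with pytest.raises(ValueError, match="unstranded"):
            gene_activity(m, genes, ScConfig())

    def test_matches_brute_force_assignment(self):
        rng = np.random.default_rng(42)
        n_cells, n_feats, n_genes = 50, 60, 20
        feats = []
        for i in range(n_feats):
            start = int(rng.integers(0, 20_000))
            feats.append(
                GenomicInterval("c", start, start + int(rng.integers(20, 400)),
                                "+", f"f{i}")
            )
        counts = rng.poisson(1.0, size=(n_cells, n_feats))
        m = CellMatrix(
            sp.csr_matrix(counts),
            [f"cell{i}" for i in range(n_cells)],
            [f"f{i}" for i in range(n_feats)],
            "atac_fragments",
            IntervalSet(feats),
        )
        genes = IntervalSet(
            [
                GenomicInterval("c", int(s), int(s) + 800,
                                "-" if i % 2 else "+", f"g{i}")
                for i, s in enumerate(rng.integers(2000, 18_000, n_genes))
            ]
        )
        cfg = ScConfig(gene_upstream_extension=2000)
        act = gene_activity(m, genes, cfg)
        got = act.counts.toarray()
        order = {g: j for j, g in enumerate(act.feature_ids)}
        for g in genes:
            lo = g.start if g.strand == "-" else g.start - 2000
            hi = g.end + 2000 if g.strand == "-" else g.end
            expect = np.zeros(n_cells, dtype=int)
            for i, f in enumerate(feats):
                if f.start < hi and f.end > max(0, lo):
                    expect += counts[:, i]
            assert np.array_equal(got[:, order[g.name]], expect)


class TestNormalization:
    def test_rna_hand_computed_toy(self):
        counts = np.array([[0, 10], [5, 5], [100, 0]])
        m = CellMatrix(sp.csr_matrix(counts), ["a", "b", "c"], ["g1", "g2"],
                       "rna_umis")
        cfg = ScConfig(rna_scale_factor=10.0)
        norm = normalize_rna(m, cfg)
        assert norm.loc["a", "g1"] == 0.0
        # cell b: total 10 = scale factor -> ln(1 + count)
        assert norm.loc["b", "g1"] == pytest.approx(math.log(6))
        assert norm.loc["c", "g1"] == pytest.approx(math.log(11))

    def test_rna_preserves_within_cell_rank_order(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(4, size=(20, 15))
        m = CellMatrix(
            sp.csr_matrix(counts + 1), [f"c{i}" for i in range(20)],
            [f"g{i}" for i in range(15)], "rna_umis",
        )
        norm = normalize_rna(m, ScConfig())
        for i in range(20):
            assert np.array_equal(
                np.argsort(counts[i] + 1, kind="stable"),
                np.argsort(norm.iloc[i].to_numpy(), kind="stable"),
            )

    def test_sum_hba_added(self):
        counts = np.array([[4, 6, 10, 80]])
        m = CellMatrix(sp.csr_matrix(counts), ["a"], ["HBA1", "HBA2", "HBM", "HBB"],
                       "rna_umis")
        norm = normalize_rna(m, ScConfig(rna_scale_factor=100.0))
        assert norm.loc["a", "sumHBA"] == pytest.approx(math.log(11))

    def test_zero_total_cell_rejected(self):
        m = CellMatrix(sp.csr_matrix(np.zeros((1, 2), dtype=int)), ["a"],
                       ["g1", "g2"], "rna_umis")
        with pytest.raises(ValueError, match="zero-total"):
            normalize_rna(m, ScConfig())


class TestRelativeActivity:
    def _ann(self, cells, group="control"):
        return pd.DataFrame(
            {"cell_id": cells, "sample_id": group, "group": group}
        )

    def test_proportional_levels_give_constant_ratio(self):
        act = pd.DataFrame(
            {"HBB": [10.0, 20.0, 40.0], "HBA": [5.0, 10.0, 20.0]},
            index=["a", "b", "c"],
        )
        ann = relative_activity(
            act, self._ann(["a", "b", "c"]), "HBB", ["HBA"], ScConfig(), "atac"
        )
        assert np.allclose(ann["HBA_ratio"], 0.5)

    def test_zero_anchor_ratio_undefined(self):
        act = pd.DataFrame({"HBB": [0.0, 10.0], "HBA": [5.0, 5.0]}, index=["a", "b"])
        ann = relative_activity(
            act, self._ann(["a", "b"]), "HBB", ["HBA"], ScConfig(), "atac"
        )
        assert np.isnan(ann.set_index("cell_id").loc["a", "HBA_ratio"])

    def test_missing_locus_rejected(self):
        act = pd.DataFrame({"HBB": [1.0]}, index=["a"])
        with pytest.raises(ValueError, match="HBA"):
            relative_activity(act, self._ann(["a"]), "HBB", ["HBA"], ScConfig())

    def test_rna_anchor_high_uses_fixed_threshold(self):
        act = pd.DataFrame(
            {"HBB": [7.9, 8.1], "sumHBA": [5.0, 5.0]}, index=["a", "b"]
        )
        ann = relative_activity(
            act, self._ann(["a", "b"]), "HBB", ["sumHBA"], ScConfig(), "rna"
        ).set_index("cell_id")
        assert not ann.loc["a", "anchor_high"]
        assert bool(ann.loc["b", "anchor_high"])


class TestSubpopulation:
    def _derived(self, n_ctrl, n_case, rng, silenced_idx=()):
        rows = []
        for i in range(n_ctrl + n_case):
            group = "control" if i < n_ctrl else "case"
            anchor = rng.uniform(1, 100)
            ratio = rng.normal(1.0, 0.05)
            if i in silenced_idx:
                anchor = rng.uniform(80, 100)
                ratio = 0.2
            rows.append((f"c{i}", group, group, anchor, ratio))
        df = pd.DataFrame(
            rows, columns=["cell_id", "sample_id", "group", "anchor_level",
                           "ratio_mean"],
        )
        df["anchor_high"] = df["anchor_level"] > 75
        return df

    def test_all_flagged_in_case_gives_infinite_or(self):
        rng = np.random.default_rng(1)
        ann = self._derived(50, 50, rng)
        # silence every anchor-high case cell
        mask = (ann["group"] == "case") & ann["anchor_high"]
        ann.loc[mask, "ratio_mean"] = 0.0
        ann.loc[ann["group"] == "control", "ratio_mean"] = 1.0
        res, flagged, _ = subpopulation_enrichment(ann, ScConfig(ratio_quantile=0.0))
        assert res.odds_ratio == math.inf
        assert set(flagged) <= set(ann.loc[mask, "cell_id"])

    def test_single_group_rejected(self):
        rng = np.random.default_rng(2)
        ann = self._derived(20, 0, rng)
        with pytest.raises(ValueError, match="groups"):
            subpopulation_enrichment(ann, ScConfig())

    def test_per_sample_tables(self):
        rng = np.random.default_rng(3)
        ann = self._derived(100, 100, rng, silenced_idx=range(150, 200))
        ann.loc[ann["group"] == "case", "sample_id"] = (
            ["case1"] * 50 + ["case2"] * 50
        )
        res, flagged, per = subpopulation_enrichment(
            ann, ScConfig(), per_sample=True
        )
        assert set(per) == {"case1", "case2"}
        # the silenced cells live in case2 rows 150-199
        assert per["case2"].odds_ratio > per["case1"].odds_ratio


def test_mtx_round_trip(tmp_path):
    m = atac_matrix(6)
    write_cell_matrix(m, tmp_path / "mm")
    back = read_cell_matrix(tmp_path / "mm")
    assert back.cell_ids == m.cell_ids
    assert back.feature_ids == m.feature_ids
    assert (back.counts != m.counts).nnz == 0
    assert back.modality == m.modality
    ivs = [(i.chrom, i.start, i.end) for i in back.feature_intervals]
    assert ivs == [(i.chrom, i.start, i.end) for i in m.feature_intervals]
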