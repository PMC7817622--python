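"""Window handling, CpG-subset enrichment and per-gene enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from epiedit.enrichment import (
    GenomicWindowSet,
    extend_windows,
    gene_enrichment,
    probes_in_windows,
    select_top_offtargets,
    subset_enrichment,
    topk_loadings,
)


def windows_of(*triples, name="w"):
    return GenomicWindowSet(
        name, pd.DataFrame(triples, columns=["chrom", "start", "end"])
    )


class TestExtendWindows:
    def test_clipping_at_zero(self):
        w = extend_windows(windows_of(("chr1", 500, 700)), flank=1000)
        assert w.windows.iloc[0].tolist() == ["chr1", 0, 1700]

    def test_symmetric_extension(self):
        w = extend_windows(windows_of(("chrX", 5000, 6000)), flank=1000)
        assert w.windows.iloc[0].tolist() == ["chrX", 4000, 7000]

    def test_zero_flank_identity(self):
        original = windows_of(("chr1", 10, 20), ("chr2", 5, 9))
        w = extend_windows(original, flank=0)
        pd.testing.assert_frame_equal(w.windows, original.windows)

    def test_count_and_order_preserved(self):
        original = windows_of(("chr2", 100, 200), ("chr1", 50, 60), ("chr1", 10, 20))
        w = extend_windows(original, flank=5)
        assert len(w) == 3
        assert list(w.windows["chrom"]) == sorted(w.windows["chrom"])
        starts = w.windows.groupby("chrom")["start"]
        assert all((g.diff().dropna() >= 0).all() for _, g in starts)

    def test_negative_flank_rejected(self):
        with pytest.raises(ValueError):
            extend_windows(windows_of(("chr1", 0, 1)), flank=-1)


def scored_predictions(n_per_sgrna, sgrnas, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in sgrnas:
        for i in range(n_per_sgrna):
            rows.append(
                {
                    "sgrna_id": s,
                    "chrom": "chr1",
                    "start": 1000 * i,
                    "end": 1000 * i + 100,
                    "score": float(rng.uniform(0, 100)),
                }
            )
    return pd.DataFrame(rows)


class TestSelectTopOfftargets:
    def test_top_fifty_of_eighty(self):
        preds = scored_predictions(80, ["sg1"])
        assert len(select_top_offtargets(preds)) == 50

    def test_twelve_sgrnas_default_yield_600(self):
        preds = scored_predictions(60, [f"sg{i}" for i in range(12)])
        assert len(select_top_offtargets(preds)) == 600

    def test_fewer_than_top_n_all_retained(self):
        preds = scored_predictions(30, ["sg1"])
        assert len(select_top_offtargets(preds)) == 30

    def test_boundary_ties_all_kept(self):
        preds = scored_predictions(10, ["sg1"])
        preds["score"] = [9, 8, 7, 5, 5, 5, 5, 1, 1, 1]
        sel = select_top_offtargets(preds, top_n=5)
        assert len(sel) == 7  # 9,8,7 plus the four tied 5s

    def test_highest_scores_selected(self):
        preds = scored_predictions(10, ["sg1"])
        sel = select_top_offtargets(preds, top_n=3)
        cutoff = preds["score"].nlargest(3).min()
        kept_starts = set(sel.windows["start"])
        expected = set(preds.loc[preds["score"] >= cutoff, "start"])
        assert kept_starts == expected


class TestProbesInWindows:
    def test_half_open_boundaries(self, small_manifest):
        # probe positions on chr1 are 50, 150, 250, ...
        inside = probes_in_windows(small_manifest, windows_of(("chr1", 0, 51)))
        assert inside == {"cg00000000"}
        outside = probes_in_windows(small_manifest, windows_of(("chr1", 0, 50)))
        assert outside == set()
        at_start = probes_in_windows(small_manifest, windows_of(("chr1", 50, 51)))
        assert at_start == {"cg00000000"}

    def test_overlapping_windows_count_once(self, small_manifest):
        hits = probes_in_windows(
            small_manifest, windows_of(("chr1", 0, 200), ("chr1", 100, 300))
        )
        assert hits == {"cg00000000", "cg00000001", "cg00000002"}

    def test_unknown_chromosome_warns_not_raises(self, small_manifest, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            hits = probes_in_windows(small_manifest, windows_of(("chr9", 0, 100)))
        assert hits == set()
        assert any("chr9" in r.message for r in caplog.records)


class TestSubsetEnrichment:
    def test_perfect_overlap_matches_enumeration(self):
        background = [f"p{i}" for i in range(20)]
        focal = background[:5]
        res = subset_enrichment(focal, focal, background)
        assert (res.a, res.b, res.c, res.d) == (5, 0, 0, 15)
        assert res.p_two_sided == pytest.approx(1 / 15504, rel=1e-12)
        assert res.direction == "enriched"

    def test_disjoint_large_sets_depleted(self):
        background = [f"p{i}" for i in range(100)]
        res = subset_enrichment(background[:40], background[40:90], background)
        assert res.direction == "depleted"

    def test_table_conservation(self):
        background = [f"p{i}" for i in range(50)]
        res = subset_enrichment(background[:20], background[10:35], background)
        assert res.a + res.b + res.c + res.d == 50

    def test_transposition_symmetry(self):
        background = [f"p{i}" for i in range(60)]
        r1 = subset_enrichment(background[:20], background[15:40], background)
        r2 = subset_enrichment(background[15:40], background[:20], background)
        assert r1.p_two_sided == pytest.approx(r2.p_two_sided, rel=1e-12)

    def test_subset_outside_background_rejected(self):
        with pytest.raises(ValueError, match="contained"):
            subset_enrichment(["x"], ["a"], ["a", "b"])

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            subset_enrichment([], [], [])


class FakePca:
    def __init__(self, loadings):
        self.loadings = loadings


class TestTopkLoadings:
    def test_ranked_by_absolute_loading(self):
        loadings = pd.DataFrame(
            {"PC1": [0.9, -0.5, 0.1]}, index=["a", "b", "c"]
        )
        assert topk_loadings(FakePca(loadings), "PC1", k=2) == ["a", "b"]

    def test_k_equal_probe_count_returns_all(self):
        loadings = pd.DataFrame({"PC1": [0.2, 0.1]}, index=["a", "b"])
        assert topk_loadings(FakePca(loadings), "PC1", k=2) == ["a", "b"]

    def test_k_above_probe_count_warns_and_returns_all(self, caplog):
        import logging

        loadings = pd.DataFrame({"PC1": [0.2, 0.1]}, index=["a", "b"])
        with caplog.at_level(logging.WARNING):
            out = topk_loadings(FakePca(loadings), "PC1", k=10)
        assert out == ["a", "b"]
        assert any("exceeds" in r.message for r in caplog.records)

    def test_ties_broken_by_probe_id(self):
        loadings = pd.DataFrame({"PC1": [0.5, -0.5, 0.5]}, index=["z", "m", "a"])
        assert topk_loadings(FakePca(loadings), "PC1", k=2) == ["a", "m"]

    def test_unknown_component_rejected(self):
        loadings = pd.DataFrame({"PC1": [0.5]}, index=["a"])
        with pytest.raises(ValueError, match="component"):
            topk_loadings(FakePca(loadings), "PC9")


class TestGeneEnrichment:
    def test_frozen_table_example(self, small_manifest):
        # focal list: 8 of gene G's 10 probes + 12 unannotated probes
        # -> table (8, 12, 2, 78), OR 26, p from the enumeration oracle
        focal = list(small_manifest.probe_ids[:8]) + list(
            small_manifest.probe_ids[80:92]
        )
        table = gene_enrichment(focal, small_manifest)
        row = table[table["gene"] == "G"].iloc[0]
        assert (row["hits"], row["gene_total"]) == (8, 10)
        assert row["odds_ratio"] == pytest.approx(26.0)
        assert row["p_two_sided"] == pytest.approx(2.3782749640379137e-05, rel=1e-12)

    def test_empty_focal_list(self, small_manifest):
        assert gene_enrichment([], small_manifest).empty

    def test_unknown_probe_rejected(self, small_manifest):
        with pytest.raises(ValueError, match="absent"):
            gene_enrichment(["cg_nope"], small_manifest)

    def test_ranked_by_q_then_p_then_gene(self, small_manifest):
        focal = list(small_manifest.probe_ids[:20])
        table = gene_enrichment(focal, small_manifest)
        keys = list(zip(table["q_fdr"], table["p_two_sided"], table["gene"]))
        assert keys == sorted(keys)

    def test_multi_gene_probes_hit_every_gene(self):
        table = pd.DataFrame(
            {
                "chrom": ["chr1"] * 6,
                "pos": [10, 20, 30, 40, 50, 60],
                "genes": [("A", "B"), ("A",), ("B",), (), (), ()],
            },
            index=pd.Index([f"p{i}" for i in range(6)], name="probe_id"),
        )
        from epiedit.arraydm import ProbeManifest

        manifest = ProbeManifest(table)
        out = gene_enrichment(["p0"], manifest)
        assert set(out["gene"]) == {"A", "B"}
        assert (out["hits"] == 1).all()
        assert int(out["hits"].sum()) == 2  # one hit per annotated gene

    def test_conservation_in_every_table(self, small_manifest):
        focal = list(small_manifest.probe_ids[5:25])
        table = gene_enrichment(focal, small_manifest)
        n = len(small_manifest)
        for _, row in table.iterrows():
            a = row["hits"]
            b = len(focal) - a
            c = row["gene_total"] - a
            d = n - a - b - c
            assert a + b + c + d == n
            assert d >= 0
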