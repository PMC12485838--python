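"""Fold-change estimation, DE-table ingest, CDFs and motif-conditioned bins."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import clipmotif as cm
from clipmotif.expression import (
    bin_by_region,
    bin_by_site_count,
    cdf,
    compute_log2fc,
    ingest_de_table,
    size_factors_median_of_ratios,
    variant_tile,
    write_de_table,
)
from clipmotif.motifs import GeneMotifSummary


def _design(n=3):
    samples = [f"ctl_{i}" for i in range(n)] + [f"ind_{i}" for i in range(n)]
    return pd.DataFrame(
        {"sample": samples, "condition": ["control"] * n + ["induced"] * n}
    )


def _summary(gene, n_utr3=0, n_cds=0, n_utr5=0, n_in_clusters=0, variants=()):
    s = GeneMotifSummary(
        gene_id=gene, transcript_id=gene + "_t", n_utr3=n_utr3, n_cds=n_cds,
        n_utr5=n_utr5, n_in_clusters=n_in_clusters,
    )
    for v in variants:
        s.variant_presence[v] = True
    return s


class TestComputeLog2fc:
    def test_identical_conditions_zero_lfc(self):
        rng = np.random.default_rng(0)
        block = rng.integers(10, 1000, (50, 3))
        counts = pd.DataFrame(
            np.hstack([block, block]),
            index=[f"g{i}" for i in range(50)],
            columns=_design()["sample"],
        )
        expr = compute_log2fc(counts, _design())
        assert np.allclose(expr.records["log2fc"], 0.0)

    def test_exact_doubling(self):
        rng = np.random.default_rng(1)
        block = rng.integers(100, 1000, (50, 3))
        counts = pd.DataFrame(
            np.hstack([block, 2 * block]),
            index=[f"g{i}" for i in range(50)],
            columns=_design()["sample"],
        )
        expr = compute_log2fc(counts, _design())
        # size factors absorb the doubling: the per-sample scale is removed,
        # so within-gene ratios must come out at zero lfc
        assert np.allclose(expr.records["log2fc"], 0.0, atol=1e-9)

    def test_single_gene_doubles_against_flat_background(self):
        rng = np.random.default_rng(2)
        base = rng.integers(500, 1000, (200, 3))
        induced = base.copy()
        induced[0] *= 2  # one DE gene: size factors stay ~1
        counts = pd.DataFrame(
            np.hstack([base, induced]),
            index=[f"g{i}" for i in range(200)],
            columns=_design()["sample"],
        )
        expr = compute_log2fc(counts, _design())
        assert expr.records.loc[0, "log2fc"] == pytest.approx(1.0, abs=0.01)

    def test_all_zero_rows_retained(self):
        counts = pd.DataFrame(
            [[0] * 6, [10, 12, 11, 9, 10, 13]],
            index=["dead", "alive"],
            columns=_design()["sample"],
        )
        expr = compute_log2fc(counts, _design())
        row = expr.records.set_index("gene_id").loc["dead"]
        assert row["baseMean"] == 0.0 and row["log2fc"] == 0.0

    def test_single_sample_condition_errors(self):
        counts = pd.DataFrame(
            [[1, 2, 3]], index=["g"], columns=["ctl_0", "ctl_1", "ind_0"]
        )
        design = pd.DataFrame(
            {
                "sample": ["ctl_0", "ctl_1", "ind_0"],
                "condition": ["control", "control", "induced"],
            }
        )
        with pytest.raises(ValueError):
            compute_log2fc(counts, design)

    def test_size_factors_scale_recovery(self):
        rng = np.random.default_rng(3)
        base = rng.integers(100, 1000, (300, 4)).astype(float)
        scales = np.array([0.5, 1.0, 2.0, 4.0])
        counts = pd.DataFrame(base * scales, index=[f"g{i}" for i in range(300)],
                              columns=list("abcd"))
        sf = size_factors_median_of_ratios(counts)
        ratios = sf.to_numpy() / scales
        assert np.allclose(ratios, ratios[0], rtol=0.1)


class TestIngestDeTable:
    def test_toy_table(self, tmp_path):
        p = tmp_path / "de.tsv"
        p.write_text(
            "gene_id\tbaseMean\tlog2FoldChange\tpadj\n"
            "g1\t100.0\t-1.5\t0.001\n"
            "g2\t50.0\t0.2\t\n"
            "g3\t5.0\t2.0\t0.5\n"
        )
        expr = ingest_de_table(p)
        assert len(expr.records) == 3
        assert expr.records["padj"].isna().sum() == 1
        sig = expr.significant()
        assert sig["gene_id"].tolist() == ["g1"]

    def test_missing_column_errors(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("gene_id\tbaseMean\n" "g1\t1.0\n")
        with pytest.raises(ValueError, match="log2FoldChange"):
            ingest_de_table(p)

    def test_write_ingest_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        records = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(20)],
                "baseMean": rng.uniform(0, 1000, 20),
                "log2fc": rng.normal(0, 2, 20),
                "padj": rng.uniform(0, 1, 20),
            }
        )
        table = cm.ExpressionTable(records=records)
        p = tmp_path / "de.tsv"
        write_de_table(table, p)
        back = ingest_de_table(p)
        pd.testing.assert_frame_equal(
            back.records, records, check_exact=False, rtol=1e-9
        )


class TestCdf:
    def test_single_value(self):
        assert cdf([0.0]) == [(0.0, 1.0)]

    def test_ties_share_step(self):
        assert cdf([1, 2, 2, 3]) == [(1.0, 0.25), (2.0, 0.75), (3.0, 1.0)]

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            cdf([])

    def test_median_log2_commutes_with_log2_of_median(self):
        """For odd n, median(log2 fc) == log2(median fc): monotone transform."""
        rng = np.random.default_rng(7)
        fcs = rng.lognormal(0, 1, 101)
        assert np.median(np.log2(fcs)) == pytest.approx(np.log2(np.median(fcs)))

    def test_matches_sort_rank_oracle(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 1, 200)
        points = cdf(vals)
        svals = np.sort(vals)
        for v, f in points:
            assert f == pytest.approx((svals <= v).mean())
        fracs = [f for _, f in points]
        assert fracs == sorted(fracs) and fracs[-1] == 1.0


class TestBinning:
    def _expr(self, lfc_by_gene, basemean=100.0):
        records = pd.DataFrame(
            {
                "gene_id": list(lfc_by_gene),
                "baseMean": basemean,
                "log2fc": list(lfc_by_gene.values()),
                "padj": np.nan,
            }
        )
        return cm.ExpressionTable(records=records)

    def test_median_of_symmetric_values(self):
        expr = self._expr({"a": -1.0, "b": 0.0, "c": 1.0})
        summaries = {g: _summary(g, n_utr3=1) for g in "abc"}
        bins = {b.label: b for b in bin_by_region(expr, summaries)}
        assert bins["utr3_1"].median_lfc == 0.0

    def test_basemean_filter_empties_bins(self):
        expr = self._expr({"a": -1.0, "b": 1.0}, basemean=5.0)
        summaries = {g: _summary(g, n_utr3=1) for g in "ab"}
        bins = bin_by_region(expr, summaries, min_basemean=10)
        assert all(b.n == 0 for b in bins)

    def test_region_priority_utr3_over_cds(self):
        expr = self._expr({"a": -1.0})
        bins = {
            b.label: b
            for b in bin_by_region(expr, {"a": _summary("a", n_utr3=1, n_cds=1)})
        }
        assert bins["utr3_1"].n == 1 and bins["cds"].n == 0

    def test_cds_only_gene_in_cds_bin(self):
        expr = self._expr({"a": -1.0})
        bins = {b.label: b for b in bin_by_region(expr, {"a": _summary("a", n_cds=1)})}
        assert bins["cds"].n == 1

    def test_bins_partition_filtered_genes(self):
        rng = np.random.default_rng(6)
        genes = {f"g{i}": float(rng.normal()) for i in range(60)}
        summaries = {
            g: _summary(
                g,
                n_utr3=int(rng.integers(0, 3)),
                n_cds=int(rng.integers(0, 2)),
                n_utr5=int(rng.integers(0, 2)),
            )
            for g in genes
        }
        expr = self._expr(genes)
        bins = bin_by_region(expr, summaries)
        seen = [g for b in bins for g in b.gene_ids]
        assert sorted(seen) == sorted(genes)

    def test_site_count_bins_with_bound_info(self):
        expr = self._expr({"a": -2.0, "b": -1.0, "c": 0.0, "d": 0.1})
        summaries = {
            "a": _summary("a", n_utr3=2),
            "b": _summary("b", n_utr3=1),
            "c": _summary("c"),
            "d": _summary("d"),
        }
        bins = {
            b.label: b
            for b in bin_by_site_count(expr, summaries, bound_genes={"c"})
        }
        assert bins["ge2"].gene_ids == ["a"]
        assert bins["one"].gene_ids == ["b"]
        assert bins["bound_no_motif"].gene_ids == ["c"]
        assert bins["unbound"].gene_ids == ["d"]

    def test_suppression_ordering_on_generator(self):
        """delta=1 simulation: median lfc ordering ge2 < one < none (3 seeds)."""
        for seed in (1, 2, 3):
            cfg = cm.SimConfig(
                n_transcripts=400, seed=seed, delta=1.0, nb_dispersion=0.05,
                utr5_range=(20, 30), cds_range=(60, 90), utr3_range=(50, 80),
            )
            tx = cm.generate_transcriptome(cfg)
            plan = [(f"tx{i:04d}", "utr3", cm.CANONICAL_MOTIF, 2) for i in range(20)]
            plan += [(f"tx{i:04d}", "utr3", cm.CANONICAL_MOTIF, 1) for i in range(20, 60)]
            tx, placements = cm.plant_motifs(tx, plan, seed=seed)
            csim = cm.simulate_counts(tx, placements, cfg)
            expr = compute_log2fc(csim.counts, csim.design)
            k = csim.truth.set_index("gene_id")["k_canonical"]
            summaries = {g: _summary(g, n_utr3=int(k[g])) for g in k.index}
            bins = {b.label: b for b in bin_by_site_count(expr, summaries)}
            assert (
                bins["ge2"].median_lfc < bins["one"].median_lfc < bins["no_motif"].median_lfc
            )
            assert -1.3 <= bins["one"].median_lfc <= -0.7


class TestVariantTile:
    def test_cell_definition_and_count(self):
        expr_vals = {"v1": -0.1, "v2": -0.2, "canon": -1.0}
        records = pd.DataFrame(
            {
                "gene_id": list(expr_vals),
                "baseMean": 100.0,
                "log2fc": list(expr_vals.values()),
                "padj": np.nan,
            }
        )
        expr = cm.ExpressionTable(records=records)
        summaries = {
            "v1": _summary("v1", variants=["pos3C"]),
            "v2": _summary("v2", variants=["pos3C"]),
            "canon": _summary("canon", n_utr3=1),
        }
        cells, canonical = variant_tile(expr, summaries)
        assert len(cells) == 21
        assert len({(c.position, c.base) for c in cells}) == 21
        assert all(
            c.base != cm.CANONICAL_MOTIF[c.position - 1] for c in cells
        )
        cell = next(c for c in cells if (c.position, c.base) == (3, "C"))
        assert cell.n == 2 and cell.median_lfc == pytest.approx(-0.15)
        assert canonical.n == 1 and canonical.median_lfc == -1.0

    def test_variant_cells_flat_when_only_canonical_suppressed(self):
        """Generator suppressing only the canonical motif: every variant cell's
        |median lfc| is below half the canonical cell's."""
        cfg = cm.SimConfig(
            n_transcripts=360, seed=4, delta=1.0, nb_dispersion=0.05,
            utr5_range=(20, 30), cds_range=(60, 90), utr3_range=(50, 80),
        )
        tx = cm.generate_transcriptome(cfg)
        variants = cm.enumerate_variants()
        plan = []
        for j, v in enumerate(variants):  # 10 genes per variant
            for i in range(10):
                plan.append((f"tx{j * 10 + i:04d}", "utr3", v.seq, 1))
        plan += [
            (f"tx{i:04d}", "utr3", cm.CANONICAL_MOTIF, 1) for i in range(210, 250)
        ]
        tx, placements = cm.plant_motifs(tx, plan, seed=4)
        csim = cm.simulate_counts(tx, placements, cfg)
        expr = compute_log2fc(csim.counts, csim.design)
        summaries = {}
        gene_of = {t.transcript_id: t.gene_id for t in tx}
        planted = {}
        for p in placements:
            planted.setdefault(gene_of[p.transcript_id], []).append(p.motif_seq)
        variant_label = {v.seq: v.label for v in variants}
        for t in tx:
            seqs = planted.get(t.gene_id, [])
            s = _summary(
                t.gene_id,
                n_utr3=sum(x == cm.CANONICAL_MOTIF for x in seqs),
                variants=[variant_label[x] for x in seqs if x in variant_label],
            )
            summaries[t.gene_id] = s
        cells, canonical = variant_tile(expr, summaries)
        assert canonical.median_lfc < -0.5
        for c in cells:
            assert c.n == 10
            assert abs(c.median_lfc) < 0.5 * abs(canonical.median_lfc)
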