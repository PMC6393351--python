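"""Gene-level summarization, clustering, and hotspot detection."""

import numpy as np
import pandas as pd
import pytest

from vitiflora.exprsum import (
    cluster_expression,
    detect_hotspots,
    summarize_by_gene,
)
from vitiflora.probemap import build_probe_gene_map, classify_probes
from vitiflora.synthgen import gen_expression, gen_probe_design


def _mapped(design):
    pg = build_probe_gene_map(design.probe_dict(), design.gene_dict())
    return pg, classify_probes(pg)


class TestSummarizeByGene:
    def test_single_probe_gene_equals_probe_row(self):
        d = gen_probe_design(3, 1, 0, probe_length=24, gene_length=120, seed=2)
        pg, cls = _mapped(d)
        expr, _ = gen_expression(d, ["s1", "s2"], seed=1)
        gem = summarize_by_gene(expr, cls, pg)
        for gene, probes in gem.provenance.items():
            assert len(probes) == 1
            pd.testing.assert_series_equal(
                gem.matrix.loc[gene], expr.loc[probes[0]], check_names=False
            )

    def test_hand_mean_of_two_probes(self, small_design):
        pg, cls = _mapped(small_design)
        probes = [p.probe_id for p in small_design.probes]
        expr = pd.DataFrame(
            {"s1": np.arange(len(probes), dtype=float)}, index=probes
        )
        gem = summarize_by_gene(expr, cls, pg)
        # gene001 holds the first two probes valued 0.0 and 1.0
        g1_probes = gem.provenance["gene001"]
        expected = expr.loc[g1_probes, "s1"].mean()
        assert gem.matrix.loc["gene001", "s1"] == pytest.approx(expected)

    def test_ambiguous_only_genes_dropped(self):
        d = gen_probe_design(
            n_genes=49, probes_per_gene=2, n_ambiguous=28,
            ambiguous_only_genes=14, probe_length=24, gene_length=150, seed=3,
        )
        pg, cls = _mapped(d)
        expr, _ = gen_expression(d, ["s1", "s2"], seed=0)
        gem = summarize_by_gene(expr, cls, pg)
        assert len(gem.matrix) == 35
        assert len(gem.dropped_genes) == 14
        assert not set(gem.dropped_genes) & set(gem.matrix.index)

    def test_unknown_probe_rows_rejected(self, small_design):
        pg, cls = _mapped(small_design)
        expr = pd.DataFrame({"s1": [1.0]}, index=["mystery_probe"])
        with pytest.raises(ValueError, match="mystery_probe"):
            summarize_by_gene(expr, cls, pg)


class TestClusterExpression:
    def test_identical_rows_merge_first_at_zero(self):
        m = pd.DataFrame(
            [[1.0, 2.0], [1.0, 2.0], [9.0, 8.0]],
            index=list("abc"), columns=["s1", "s2"],
        )
        res = cluster_expression(m, axis="rows")
        Z = res["row_linkage"]
        assert Z[0, 2] == pytest.approx(0.0)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_average_linkage_pairs_near_points_first(self):
        """1-D points {0, 1, 10, 11}: {0,1} and {10,11} merge (at height 1)
        before the final join at the average inter-pair distance 10."""
        m = pd.DataFrame({"x": [0.0, 1.0, 10.0, 11.0]},
                         index=list("abcd"))
        Z = cluster_expression(m, axis="rows")["row_linkage"]
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx(1.0)
        assert Z[2, 2] == pytest.approx(10.0)
        first_pairs = {frozenset((int(Z[i, 0]), int(Z[i, 1]))) for i in (0, 1)}
        assert first_pairs == {frozenset((0, 1)), frozenset((2, 3))}

    def test_row_permutation_invariance(self):
        """Shuffling input rows leaves tree topology and heights unchanged
        (compared via label-indexed cophenetic distances)."""
        from scipy.cluster.hierarchy import cophenet

        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.normal(size=(6, 4)),
                         index=[f"g{i}" for i in range(6)])
        perm = m.sample(frac=1, random_state=1)

        def _coph(frame):
            res = cluster_expression(frame, axis="rows")
            d = cophenet(res["row_linkage"])
            labels = list(frame.index)
            out = {}
            k = 0
            for i in range(len(labels)):
                for j in range(i + 1, len(labels)):
                    out[frozenset((labels[i], labels[j]))] = round(d[k], 10)
                    k += 1
            return out

        assert _coph(m) == _coph(perm)

    def test_constant_rows_under_correlation_are_named(self):
        m = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"]
        )
        with pytest.raises(ValueError, match="flat"):
            cluster_expression(m, axis="rows", metric="correlation")

    def test_missing_values_rejected(self):
        m = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="missing"):
            cluster_expression(m)


class TestDetectHotspots:
    @staticmethod
    def _planted_matrix(seed, n_genes=20, n_samples=20, block=5, effect=3.0):
        # noise sd 0.5 emulates a gene matrix averaged from 4 probes of unit sd
        rng = np.random.default_rng(seed)
        vals = rng.normal(8.0, 0.5, size=(n_genes, n_samples))
        vals[:block, :block] += effect
        return pd.DataFrame(
            vals,
            index=[f"g{i:02d}" for i in range(n_genes)],
            columns=[f"s{i:02d}" for i in range(n_samples)],
        )

    def test_constant_matrix_has_no_blocks(self):
        m = pd.DataFrame(np.full((5, 5), 7.0))
        assert detect_hotspots(m).blocks == []

    def test_planted_block_recovered_exactly(self):
        m = self._planted_matrix(seed=17)
        rep = detect_hotspots(m)
        assert len(rep.blocks) == 1
        assert rep.blocks[0]["genes"] == [f"g{i:02d}" for i in range(5)]
        assert rep.blocks[0]["samples"] == [f"s{i:02d}" for i in range(5)]
        assert rep.blocks[0]["mean_z"] >= 1.5

    def test_raising_threshold_never_adds_blocks(self):
        m = self._planted_matrix(seed=23)
        counts = [
            len(detect_hotspots(m, z_threshold=t).blocks)
            for t in (0.5, 1.0, 1.5, 2.5, 4.0, 8.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_nonconstant_matrix_yields_block_at_zero_threshold(self):
        rng = np.random.default_rng(31)
        m = pd.DataFrame(rng.normal(size=(8, 8)))
        rep = detect_hotspots(m, z_threshold=0.0, min_genes=1, min_samples=1)
        assert len(rep.blocks) >= 1

    def test_full_chain_recovery_from_probe_level(self):
        """Generator -> remap -> summarize -> detect recovers the planted
        sample x gene block at default parameters."""
        d = gen_probe_design(12, 4, 0, seed=2, gene_length=500)
        genes = [g for g, _ in d.genes]
        samples = [f"s{i:02d}" for i in range(12)]
        expr, _ = gen_expression(
            d, samples, hotspot=(samples[:4], genes[:4], 3.0), seed=77
        )
        pg = build_probe_gene_map(d.probe_dict(), d.gene_dict())
        cls = classify_probes(pg)
        gem = summarize_by_gene(expr, cls, pg)
        rep = detect_hotspots(gem.matrix, min_genes=2, min_samples=2)
        assert len(rep.blocks) == 1
        assert rep.blocks[0]["genes"] == sorted(genes[:4])
        assert rep.blocks[0]["samples"] == sorted(samples[:4])
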