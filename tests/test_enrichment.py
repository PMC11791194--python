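"""Hypergeometric enrichment, interval overlap, PRC/TF rules, gene domains."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import cetclock as cc
from cetclock.types import ValidationError


def _ids(n, prefix="cg"):
    return [f"{prefix}{i}" for i in range(n)]


def enumeration_oracle(N, K, n, k):
    """Exact tail probabilities by counting n-subsets of an N-universe
    (first K elements = set members). Independent of scipy."""
    total = math.comb(N, n)
    p_ge = sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, min(K, n) + 1))
    p_le = sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(0, min(k, K, n) + 1))
    return p_ge / total, p_le / total


class TestHypergeom:
    def test_worked_example(self):
        """N=10, K=5, n=4, k=4: FC=2, enrichment p = C(5,4)/C(10,4) = 5/210."""
        bg = _ids(10)
        row = cc.hypergeom_enrichment(bg[:4], bg[:5], bg, set_name="s")
        assert row.fold_change == pytest.approx(2.0)
        assert row.p_enrichment == pytest.approx(5 / 210, rel=1e-12)

    def test_matches_enumeration_oracle_exhaustively(self):
        """Every (N<=30, K, n, k) configuration on a coarse lattice agrees
        with subset-counting to 1e-12 relative in both tails."""
        for N in (5, 11, 18, 30):
            bg = _ids(N)
            for K in range(0, N + 1, max(1, N // 4)):
                for n in range(1, N + 1, max(1, N // 4)):
                    for k in range(0, min(K, n) + 1):
                        if K == 0:
                            continue
                        fg = bg[:k] + bg[K : K + (n - k)]
                        if len(fg) != n:
                            continue
                        row = cc.hypergeom_enrichment(fg, bg[:K], bg)
                        p_ge, p_le = enumeration_oracle(N, K, n, k)
                        assert row.p_enrichment == pytest.approx(p_ge, rel=1e-12, abs=1e-300)
                        assert row.p_depletion == pytest.approx(p_le, rel=1e-12, abs=1e-300)

    def test_literal_subset_enumeration_tiny(self):
        """Spot-check against literally enumerating all n-subsets."""
        N, K, n = 8, 3, 4
        bg = _ids(N)
        members = set(bg[:K])
        counts = {}
        for sub in itertools.combinations(bg, n):
            k = len(set(sub) & members)
            counts[k] = counts.get(k, 0) + 1
        total = sum(counts.values())
        for k in range(0, min(K, n) + 1):
            fg = bg[:k] + [c for c in bg[K:] if c not in bg[:k]][: n - k]
            row = cc.hypergeom_enrichment(fg, members, bg)
            p_ge = sum(v for kk, v in counts.items() if kk >= k) / total
            assert row.p_enrichment == pytest.approx(p_ge, rel=1e-12)

    def test_saturated_foreground(self):
        bg = _ids(10)
        row = cc.hypergeom_enrichment(bg, bg, bg)
        assert row.fold_change == pytest.approx(1.0)
        assert row.p_enrichment == pytest.approx(1.0)

    def test_zero_overlap_tails(self):
        N, K, n = 12, 4, 3
        bg = _ids(N)
        row = cc.hypergeom_enrichment(bg[K : K + n], bg[:K], bg)
        assert row.p_enrichment == pytest.approx(1.0)
        assert row.p_depletion == pytest.approx(
            math.comb(N - K, n) / math.comb(N, n), rel=1e-12
        )

    def test_tails_partition_probability(self):
        from scipy.stats import hypergeom

        for N, K, n, k in [(30, 10, 8, 3), (20, 5, 5, 1), (25, 12, 10, 6)]:
            assert hypergeom.sf(k - 1, N, K, n) + hypergeom.cdf(k - 1, N, K, n) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_empty_sets_rejected_and_k_zero_degenerate(self):
        bg = _ids(5)
        with pytest.raises(ValidationError):
            cc.hypergeom_enrichment([], bg[:2], bg)
        row = cc.hypergeom_enrichment(bg[:2], [], bg)
        assert row.degenerate and row.k == 0 and row.p_enrichment == 1.0

    def test_odds_ratio_haldane_only_when_zero_cell(self):
        bg = _ids(20)
        row = cc.hypergeom_enrichment(bg[:5], bg[2:10], bg)
        a, b, c, d = row.k, row.n - row.k, row.K - row.k, row.N - row.K - row.n + row.k
        assert min(a, b, c, d) > 0
        assert row.odds_ratio == pytest.approx((a / b) / (c / d))
        full = cc.hypergeom_enrichment(bg[:5], bg[:5], bg)  # b = c = 0
        assert np.isfinite(full.odds_ratio)


class TestOverlap:
    def _map(self, rows):
        return cc.CpGMap(pd.DataFrame(rows, columns=["cpg_id", "chromosome", "position"]))

    def test_buffered_inclusion_example(self):
        cmap = self._map([("cgA", "chr1", 1000)])
        rs = cc.RegionSet("s", [("chr1", 1150, 1300)])
        assert cc.overlap_cpgs(cmap, rs, buffer_bp=200) == {"cgA"}
        assert cc.overlap_cpgs(cmap, rs, buffer_bp=0) == set()

    def test_buffer_still_short(self):
        cmap = self._map([("cgA", "chr1", 500)])
        rs = cc.RegionSet("s", [("chr1", 800, 900)])
        assert cc.overlap_cpgs(cmap, rs, buffer_bp=200) == set()

    def test_point_overlap_half_open_boundaries(self):
        cmap = self._map([("cgA", "chr1", 100), ("cgB", "chr1", 101), ("cgC", "chr1", 99)])
        rs = cc.RegionSet("s", [("chr1", 99, 100)])  # covers bases 99 only (0-based)
        # CpG at 1-based 100 occupies [99,100): inside; 101 -> [100,101): outside
        assert cc.overlap_cpgs(cmap, rs) == {"cgA"}

    def test_monotone_in_buffer(self):
        rng = np.random.default_rng(0)
        cmap = self._map([(f"cg{i}", "chr1", int(p)) for i, p in
                          enumerate(sorted(rng.choice(10000, 50, replace=False) + 1))])
        rs = cc.RegionSet("s", [("chr1", int(s), int(s) + 30) for s in
                                rng.choice(9000, 10, replace=False)])
        prev = set()
        for b in (0, 10, 100, 1000):
            cur = cc.overlap_cpgs(cmap, rs, buffer_bp=b)
            assert prev <= cur
            prev = cur

    def test_unknown_chromosome_ignored(self):
        cmap = self._map([("cgA", "chr1", 100)])
        rs = cc.RegionSet("s", [("chr9", 0, 1000)])
        assert cc.overlap_cpgs(cmap, rs) == set()


class TestPrcAnnotate:
    def _fixture(self):
        cmap = cc.CpGMap(pd.DataFrame({
            "cpg_id": ["cg1", "cg2", "cg3"],
            "chromosome": ["chr1"] * 3,
            "position": [100, 200, 300],
        }))
        peak = lambda *pos: cc.RegionSet("p", [("chr1", p - 5, p + 5) for p in pos])
        return cmap, peak

    def test_two_member_rule(self):
        cmap, peak = self._fixture()
        out = cc.prc_annotate(
            {"EED": peak(100), "SUZ12": peak(100, 200), "EZH2": peak(300),
             "RING1": peak(200)},
            cmap,
        )
        assert out["PRC2"] == {"cg1"}  # EED+SUZ12 at cg1; cg2, cg3 single-member
        assert out["PRC1"] == set()  # only RING1 supplied -> warned empty

    def test_prc1_pair(self):
        cmap, peak = self._fixture()
        out = cc.prc_annotate({"RING1": peak(200), "BMI1": peak(200)}, cmap)
        assert out["PRC1"] == {"cg2"}


class TestTfEnrichment:
    def _setup(self, n_bg=40):
        cmap = cc.CpGMap(pd.DataFrame({
            "cpg_id": _ids(n_bg),
            "chromosome": ["chr1"] * n_bg,
            "position": np.arange(1, n_bg + 1) * 1000,
        }))
        bg = _ids(n_bg)
        fg = bg[:8]

        def peaks(idxs):
            return cc.RegionSet("p", [("chr1", (i + 1) * 1000 - 10, (i + 1) * 1000 + 10)
                                      for i in idxs])
        return cmap, bg, fg, peaks

    def test_broad_tf_filtered_unless_yamanaka(self):
        cmap, bg, fg, peaks = self._setup()
        broad = peaks(range(30))  # K/N = 0.75 > 0.5
        rows = cc.tf_enrichment(fg, bg, {("ZNF1", "d1"): broad}, cmap, buffer_bp=0)
        assert rows == []
        rows = cc.tf_enrichment(fg, bg, {("OCT4", "d1"): broad}, cmap, buffer_bp=0)
        assert [r.set_name for r in rows] == ["OCT4"]

    def test_median_p_dataset_rule_odd(self):
        cmap, bg, fg, peaks = self._setup()
        sets = {
            ("TFX", "strong"): peaks(range(8)),        # all fg covered
            ("TFX", "middle"): peaks([0, 1, 2, 20]),
            ("TFX", "weak"): peaks([30, 31]),
        }
        rows = cc.tf_enrichment(fg, bg, sets, cmap, buffer_bp=0)
        assert len(rows) == 1
        assert rows[0].source_label == "middle"

    def test_median_p_even_takes_more_significant(self):
        cmap, bg, fg, peaks = self._setup()
        sets = {
            ("TFX", "a"): peaks(range(8)),
            ("TFX", "b"): peaks([0, 1, 2, 20]),
            ("TFX", "c"): peaks([0, 20, 21]),
            ("TFX", "d"): peaks([30, 31]),
        }
        rows = cc.tf_enrichment(fg, bg, sets, cmap, buffer_bp=0)
        ordered = sorted(sets, key=lambda key: cc.hypergeom_enrichment(
            fg, cc.overlap_cpgs(cmap, sets[key]), bg).log_p_enrichment)
        assert rows[0].source_label == ordered[1][1]  # lower middle of four


class TestGeneDomains:
    def test_lone_plus_strand_gene(self):
        tss = pd.DataFrame({
            "gene_id": ["g1"], "chromosome": ["chr1"], "tss": [100000], "strand": ["+"],
        })
        dom = cc.build_gene_domains(tss).table.iloc[0]
        assert (dom["basal_start"], dom["basal_end"]) == (94999, 101000)
        assert (dom["ext_start"], dom["ext_end"]) == (44999, 151000)

    def test_minus_strand_mirrored(self):
        tss = pd.DataFrame({
            "gene_id": ["g1"], "chromosome": ["chr1"], "tss": [100000], "strand": ["-"],
        })
        dom = cc.build_gene_domains(tss).table.iloc[0]
        assert (dom["basal_start"], dom["basal_end"]) == (98999, 105000)

    def test_adjacent_genes_clip_extensions(self):
        tss = pd.DataFrame({
            "gene_id": ["g1", "g2"], "chromosome": ["chr1", "chr1"],
            "tss": [100000, 108000], "strand": ["+", "+"],
        })
        t = cc.build_gene_domains(tss).table.set_index("gene_id")
        # g1 basal [94999,101000), g2 basal [102999,109000)
        assert t.loc["g1", "ext_end"] == 102999   # stops at g2's basal start
        assert t.loc["g2", "ext_start"] == 101000  # stops at g1's basal end
        assert t.loc["g1", "ext_start"] == 94999 - 50000

    def test_duplicate_gene_ids_rejected(self):
        tss = pd.DataFrame({
            "gene_id": ["g1", "g1"], "chromosome": ["chr1", "chr1"],
            "tss": [1000, 2000], "strand": ["+", "+"],
        })
        with pytest.raises(ValidationError):
            cc.build_gene_domains(tss)

    def test_chromosome_edge_clipped_at_zero(self):
        tss = pd.DataFrame({
            "gene_id": ["g1"], "chromosome": ["chr1"], "tss": [2000], "strand": ["+"],
        })
        dom = cc.build_gene_domains(tss).table.iloc[0]
        assert dom["basal_start"] == 0 and dom["ext_start"] == 0


class TestGeneSetEnrichment:
    def _setup(self):
        n = 60
        cmap = cc.CpGMap(pd.DataFrame({
            "cpg_id": _ids(n),
            "chromosome": ["chr1"] * n,
            "position": np.arange(1, n + 1) * 200000,  # far apart: one CpG per domain
        }))
        tss = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "chromosome": ["chr1"] * n,
            "tss": np.arange(1, n + 1) * 200000,
            "strand": ["+"] * n,
        })
        domains = cc.build_gene_domains(tss)
        bg = _ids(n)
        fg = bg[:10]
        return cmap, domains, bg, fg

    def test_enriched_set_reported_with_fc_above_one(self):
        cmap, domains, bg, fg = self._setup()
        sets = {"hit": [f"g{i}" for i in range(8)],
                "miss": [f"g{i}" for i in range(40, 55)]}
        rows = cc.gene_set_enrichment(fg, bg, domains, sets, cmap)
        assert [r.set_name for r in rows] == ["hit"]
        assert rows[0].fold_change > 1
        assert rows[0].n_genes == 8

    def test_min_gene_filter(self):
        cmap, domains, bg, fg = self._setup()
        sets = {"two_genes": ["g0", "g1"]}
        assert cc.gene_set_enrichment(fg, bg, domains, sets, cmap) == []

    def test_no_foreground_overlap_filtered(self):
        cmap, domains, bg, fg = self._setup()
        sets = {"elsewhere": [f"g{i}" for i in range(40, 50)]}
        assert cc.gene_set_enrichment(fg, bg, domains, sets, cmap) == []

    def test_empty_gene_sets(self):
        cmap, domains, bg, fg = self._setup()
        assert cc.gene_set_enrichment(fg, bg, domains, {}, cmap) == []


class TestFixtureEnrichmentRecovery:
    def test_planted_state_top_ranked_at_factor_five(self, standard_run):
        _, panel, betas, cpg_map, truth = standard_run
        sets = cc.generate_annotation_fixture(truth, cpg_map, 5.0, seed=1)
        states = [rs for rs in sets if rs.source_label is None][:4]
        fg = truth.positive_age_cpgs
        rows = cc.region_set_enrichment(fg, betas.cpg_ids, states, cpg_map)
        best = min(rows, key=lambda r: r.log_p_enrichment)
        assert best.set_name == "BivProm_sim"
        assert 3.5 <= best.fold_change <= 6.5
        assert best.log_p_enrichment < -6
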