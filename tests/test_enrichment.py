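import math

import numpy as np
import pandas as pd
import pytest

from polyarch import enrichment as enr
from polyarch.errors import AnnotationError, DegenerateDesignError, DomainError


def lead_frame(rows):
    return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos_bp", "pos_cm", "p"])


class TestClumpAssoc:
    def _assoc(self, rows):
        return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos_bp", "p"])

    def test_no_significant_gives_empty(self):
        assoc = self._assoc([("a", "chr1", 100, 0.5), ("b", "chr1", 200, 0.9)])
        out = enr.clump_assoc(assoc, {}, p1=1e-4, p2=1e-4)
        assert len(out) == 0

    def test_hand_traced_greedy(self):
        assoc = self._assoc([
            ("A", "chr1", 1_000_000, 1e-10),
            ("B", "chr1", 1_500_000, 1e-6),
            ("C", "chr1", 2_000_000, 1e-5),
        ])
        ld = {("A", "B"): 0.5, ("A", "C"): 0.001, ("B", "C"): 0.001}
        out = enr.clump_assoc(assoc, ld, p1=1e-4, p2=1e-4, r2_min=0.01, kb_window=10_000)
        assert out["variant_id"].tolist() == ["A", "C"]
        assert out.loc[out["variant_id"] == "A", "clump_members"].item() == "B"

    def test_singleton_is_own_lead(self):
        assoc = self._assoc([("x", "chr1", 500, 1e-9)])
        out = enr.clump_assoc(assoc, {})
        assert out["variant_id"].tolist() == ["x"]
        assert out["clump_members"].item() == ""

    def test_kb_window_respected(self):
        assoc = self._assoc([
            ("A", "chr1", 1_000_000, 1e-10),
            ("B", "chr1", 50_000_000, 1e-6),  # 49 Mb away: outside 10 Mb window
        ])
        ld = {("A", "B"): 0.9}
        out = enr.clump_assoc(assoc, ld, kb_window=10_000)
        assert out["variant_id"].tolist() == ["A", "B"]

    def test_missing_ld_treated_as_zero(self, caplog):
        assoc = self._assoc([
            ("A", "chr1", 1_000_000, 1e-10),
            ("B", "chr1", 1_100_000, 1e-6),
        ])
        with caplog.at_level("WARNING"):
            out = enr.clump_assoc(assoc, {})
        assert out["variant_id"].tolist() == ["A", "B"]

    def test_deterministic_tie_break_by_position(self):
        assoc = self._assoc([
            ("B", "chr1", 2_000_000, 1e-8),
            ("A", "chr1", 1_000_000, 1e-8),
        ])
        out = enr.clump_assoc(assoc, {("A", "B"): 0.5})
        assert out["variant_id"].iloc[0] == "A"


class TestMergeLeadsCm:
    def test_singleton_unchanged(self):
        leads = lead_frame([("a", "chr1", 100, 0.05, 1e-10)])
        out = enr.merge_leads_cm(leads)
        assert out["variant_id"].tolist() == ["a"]

    def test_anchor_absorbs_both_neighbours(self):
        # leads at 0.00/0.05/0.12 cM with p 1e-10/1e-30/1e-9: the 0.05 lead
        # (minimum p) anchors and absorbs both within 0.1 cM
        leads = lead_frame([
            ("a", "chr1", 1000, 0.00, 1e-10),
            ("b", "chr1", 2000, 0.05, 1e-30),
            ("c", "chr1", 3000, 0.12, 1e-9),
        ])
        out = enr.merge_leads_cm(leads, window_cm=0.1)
        assert out["variant_id"].tolist() == ["b"]
        assert out["pos_cm"].item() == 0.05

    def test_all_gaps_wide_noop(self):
        leads = lead_frame([
            ("a", "chr1", 1000, 0.0, 1e-10),
            ("b", "chr1", 2000, 0.5, 1e-12),
            ("c", "chr1", 3000, 1.1, 1e-9),
        ])
        out = enr.merge_leads_cm(leads, window_cm=0.1)
        assert sorted(out["variant_id"]) == ["a", "b", "c"]

    def test_merged_leads_pairwise_separated(self):
        rng = np.random.default_rng(5)
        leads = lead_frame([
            (f"v{i}", "chr1", 1000 * i, float(c), float(p))
            for i, (c, p) in enumerate(zip(
                np.sort(rng.uniform(0, 2, 40)), rng.uniform(1e-30, 1e-8, 40)
            ))
        ])
        out = enr.merge_leads_cm(leads, window_cm=0.1)
        cm = np.sort(out["pos_cm"].to_numpy())
        assert np.all(np.diff(cm) > 0.1)

    def test_chain_mode_merges_transitively(self):
        leads = lead_frame([
            ("a", "chr1", 1000, 0.00, 1e-30),
            ("b", "chr1", 2000, 0.09, 1e-10),
            ("c", "chr1", 3000, 0.18, 1e-9),
        ])
        anchor_out = enr.merge_leads_cm(leads, window_cm=0.1, chain=False)
        chain_out = enr.merge_leads_cm(leads, window_cm=0.1, chain=True)
        assert sorted(anchor_out["variant_id"]) == ["a", "c"]
        assert chain_out["variant_id"].tolist() == ["a"]


class TestGeneWindows:
    def test_left_truncation(self):
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [50_000], "end": [60_000], "name": ["g"]})
        out = enr.gene_windows(genes, 100_000, {"chr1": 1_000_000})
        assert out["start"].item() == 0
        assert out["end"].item() == 160_000

    def test_mid_chromosome_exact_flanks(self):
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [500_000], "end": [520_000], "name": ["g"]})
        out = enr.gene_windows(genes, 100_000, {"chr1": 10_000_000})
        assert out["start"].item() == 400_000
        assert out["end"].item() == 620_000

    def test_zero_flank_identity(self):
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200], "name": ["g"]})
        out = enr.gene_windows(genes, 0, {"chr1": 1000})
        assert out["start"].item() == 100
        assert out["end"].item() == 200

    def test_unknown_chromosome_raises(self):
        genes = pd.DataFrame({"chrom": ["chrX"], "start": [0], "end": [10], "name": ["g"]})
        with pytest.raises(AnnotationError):
            enr.gene_windows(genes, 100, {"chr1": 1000})


class TestGenesNearHits:
    def _windows(self):
        return pd.DataFrame({
            "chrom": ["chr1", "chr1"],
            "start": [1000, 5000],
            "end": [2000, 6000],
            "name": ["g1", "g2"],
        })

    def test_no_qualifying_leads(self):
        leads = lead_frame([("a", "chr1", 1500, 0.0, 1e-5)])
        flags = enr.genes_near_hits(self._windows(), leads, p_max=5e-8)
        assert not flags.any()

    def test_boundary_half_open(self):
        # 1-based position 1001 maps to 0-based point 1000 == window start
        leads_in = lead_frame([("a", "chr1", 1001, 0.0, 1e-10)])
        flags = enr.genes_near_hits(self._windows(), leads_in)
        assert flags["g1"]
        # 1-based position 2001 maps to point 2000 == window end: outside
        leads_out = lead_frame([("b", "chr1", 2001, 0.0, 1e-10)])
        flags = enr.genes_near_hits(self._windows(), leads_out)
        assert not flags["g1"]

    def test_hand_enumerated_layout(self):
        windows = pd.DataFrame({
            "chrom": ["chr1"] * 5,
            "start": [0, 1000, 3000, 7000, 9000],
            "end": [500, 2000, 4000, 8000, 9500],
            "name": list("abcde"),
        })
        leads = lead_frame([
            ("x", "chr1", 101, 0.0, 1e-10),     # in a
            ("y", "chr1", 3500, 0.0, 1e-10),    # in c
            ("z", "chr1", 8500, 0.0, 1e-10),    # between d and e
        ])
        flags = enr.genes_near_hits(windows, leads)
        assert flags.to_dict() == {"a": True, "b": False, "c": True, "d": False, "e": False}


class TestFisher:
    def test_all_hit_single_table(self):
        universe = [f"g{i}" for i in range(10)]
        hits = {g: True for g in universe}
        res = enr.fisher_pathway_enrichment(hits, set(universe[:5]), universe)
        assert res.fold == 1.0
        assert res.p == 1.0

    def test_matches_hypergeometric_enumeration(self):
        # table: in-hit 4, in-miss 1, out-hit 2, out-miss 8
        universe = [f"g{i}" for i in range(15)]
        pathway = set(universe[:5])
        hits = {g: False for g in universe}
        for g in universe[:4]:
            hits[g] = True
        for g in universe[5:7]:
            hits[g] = True
        res = enr.fisher_pathway_enrichment(hits, pathway, universe)

        # independent enumeration oracle
        K, N, m = 5, 15, 6
        def table_prob(k):
            return (math.comb(K, k) * math.comb(N - K, m - k)) / math.comb(N, m)
        obs_p = table_prob(4)
        expect = sum(table_prob(k) for k in range(max(0, m - (N - K)), min(K, m) + 1)
                     if table_prob(k) <= obs_p + 1e-12)
        assert res.p == pytest.approx(expect, abs=1e-12)

    def test_zero_hit_pathway_fold_zero(self):
        universe = [f"g{i}" for i in range(20)]
        hits = {g: (g not in universe[:5]) for g in universe}
        res = enr.fisher_pathway_enrichment(hits, set(universe[:5]), universe)
        assert res.fold == 0.0

    def test_empty_pathway_raises(self):
        with pytest.raises(DomainError):
            enr.fisher_pathway_enrichment({"g": True}, set(), ["g"])

    def test_exhaustive_small_margins_oracle(self):
        # all 2x2 tables with every margin <= 12 (scaled-down exhaustive)
        from scipy import stats as ss

        for N in range(2, 13):
            for K in range(1, N):
                for m in range(0, N + 1):
                    for k in range(max(0, m - (N - K)), min(K, m) + 1):
                        table = [[k, K - k], [m - k, N - K - (m - k)]]
                        p_scipy = ss.fisher_exact(table, alternative="two-sided")[1]
                        probs = [
                            math.comb(K, kk) * math.comb(N - K, m - kk) / math.comb(N, m)
                            for kk in range(max(0, m - (N - K)), min(K, m) + 1)
                        ]
                        obs = math.comb(K, k) * math.comb(N - K, m - k) / math.comb(N, m)
                        p_oracle = sum(p for p in probs if p <= obs * (1 + 1e-10))
                        assert min(p_scipy, 1.0) == pytest.approx(min(p_oracle, 1.0), abs=1e-9)


class TestPoisson:
    def _windows(self, spans):
        return pd.DataFrame([
            {"chrom": "chr1", "start": s, "end": e} for s, e in spans
        ])

    def _leads_at(self, positions):
        return lead_frame([
            (f"v{i}", "chr1", p, 0.0, 1e-10) for i, p in enumerate(positions)
        ])

    def test_equal_rates_ratio_one(self):
        pw = self._windows([(0, 10_000_000)])
        bg = self._windows([(20_000_000, 120_000_000)])
        leads = self._leads_at(
            list(range(1, 10_000_001, 1_000_000))[:10]
            + list(range(20_000_001, 120_000_001, 1_000_000))[:100]
        )
        res = enr.poisson_rate_enrichment(leads, pw, bg)
        assert res.fold == pytest.approx(1.0)

    def test_tenfold_rate_matches_binomial_oracle(self):
        from scipy import stats as ss

        pw = self._windows([(0, 2_000_000)])
        bg = self._windows([(10_000_000, 210_000_000)])
        inside = np.linspace(1, 1_999_999, 10).astype(int)
        outside = np.linspace(10_000_001, 209_999_999, 100).astype(int)
        leads = self._leads_at(list(inside) + list(outside))
        res = enr.poisson_rate_enrichment(leads, pw, bg)
        assert res.fold == pytest.approx(10.0)
        expect = ss.binomtest(10, 110, 2 / 202).pvalue
        assert res.p == pytest.approx(expect, abs=1e-12)

    def test_no_hits_p_one(self):
        pw = self._windows([(0, 1_000_000)])
        bg = self._windows([(5_000_000, 10_000_000)])
        res = enr.poisson_rate_enrichment(self._leads_at([]), pw, bg)
        assert res.p == 1.0

    def test_zero_mb_raises(self):
        pw = self._windows([])
        bg = self._windows([(0, 1_000_000)])
        with pytest.raises(DegenerateDesignError):
            enr.poisson_rate_enrichment(self._leads_at([100]), pw, bg)


class TestMatchedNullSets:
    def _variant_table(self, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "variant_id": [f"v{i}" for i in range(n)],
            "maf": rng.uniform(0.01, 0.5, n),
            "ldscore": rng.uniform(1, 50, n),
            "gene_distance": rng.integers(0, 500_000, n).astype(float),
        })

    def _leads_from(self, vt, idx):
        return pd.DataFrame({
            "variant_id": vt["variant_id"].iloc[idx].to_numpy(),
            "chrom": "chr1",
            "pos_bp": 1000,
            "p": 1e-10,
        })

    def test_set_cardinality(self):
        vt = self._variant_table()
        leads = self._leads_from(vt, [3, 77, 500])
        sets = enr.matched_null_sets(leads, vt, n_sets=5, seed=1)
        assert len(sets) == 5
        assert all(len(s) == 3 for s in sets)

    def test_leads_excluded(self):
        vt = self._variant_table()
        leads = self._leads_from(vt, [3, 77, 500])
        sets = enr.matched_null_sets(leads, vt, n_sets=10, seed=2)
        lead_ids = set(leads["variant_id"])
        for s in sets:
            assert not (set(s["variant_id"]) & lead_ids)

    def test_bins_match_when_no_fallback(self):
        vt = self._variant_table(5000, seed=3)
        leads = self._leads_from(vt, [10, 200, 3000])
        sets = enr.matched_null_sets(leads, vt, n_sets=3, seed=4)
        codes = np.column_stack([
            enr._decile(vt["maf"].to_numpy()),
            enr._decile(vt["ldscore"].to_numpy()),
            enr._decile(vt["gene_distance"].to_numpy()),
        ])
        by_id = {v: i for i, v in enumerate(vt["variant_id"])}
        for s in sets:
            for _, row in s.iterrows():
                if row["fallback"]:
                    continue
                src = codes[by_id[row["source_lead"]]]
                got = codes[by_id[row["variant_id"]]]
                assert np.array_equal(src, got)

    def test_determinism(self):
        vt = self._variant_table()
        leads = self._leads_from(vt, [3, 77])
        a = enr.matched_null_sets(leads, vt, n_sets=3, seed=9)
        b = enr.matched_null_sets(leads, vt, n_sets=3, seed=9)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)


class TestPlantedEnrichment:
    def test_planted_signal_recovered_by_fisher(self):
        # plant causal variants inside one pathway's windows; Fisher p should
        # be small in nearly all seeds
        from polyarch.synthdata import simulate_gene_landscape

        wins = 0
        n_seeds = 30
        for seed in range(n_seeds):
            genes, sets = simulate_gene_landscape(
                120, {"chr1": 60_000_000}, {"core": 12}, seed=seed
            )
            windows = enr.gene_windows(genes, 50_000, {"chr1": 60_000_000})
            rng = np.random.default_rng(1000 + seed)
            core = set(sets["core"])
            core_windows = windows.loc[windows["name"].isin(core)]
            # leads at the centre of each core-gene window
            leads = pd.DataFrame({
                "variant_id": [f"hit{i}" for i in range(len(core_windows))],
                "chrom": "chr1",
                "pos_bp": ((core_windows["start"] + core_windows["end"]) // 2 + 1).to_numpy(),
                "p": 1e-12,
            })
            flags = enr.genes_near_hits(windows, leads)
            res = enr.fisher_pathway_enrichment(flags, core, list(genes["name"]))
            if res.p < 1e-3:
                wins += 1
        assert wins >= 0.95 * n_seeds


class TestMatchedNullComparison:
    def test_planted_leads_beat_matched_nulls(self):
        # leads planted inside core-pathway windows hit more core genes than
        # nearly all matched random variant sets
        from polyarch.synthdata import plant_causal_mask, simulate_gene_landscape

        rng = np.random.default_rng(21)
        genes, sets = simulate_gene_landscape(
            150, {"chr1": 80_000_000}, {"core": 15}, seed=22
        )
        windows = enr.gene_windows(genes, 50_000, {"chr1": 80_000_000})
        core_windows = windows.loc[windows["name"].isin(sets["core"])]

        n_var = 20_000
        pos = np.sort(rng.choice(80_000_000, n_var, replace=False)) + 1
        vt = pd.DataFrame({
            "variant_id": [f"v{i}" for i in range(n_var)],
            "maf": rng.uniform(0.01, 0.5, n_var),
            "ldscore": rng.uniform(1, 30, n_var),
        })
        vmap = pd.DataFrame({
            "variant_id": vt["variant_id"], "chrom": "chr1", "position_bp": pos,
        })
        # gene distance: 0 if inside any gene body, else distance to nearest
        starts = genes["start"].to_numpy()
        ends = genes["end"].to_numpy()
        p0 = pos - 1
        d = np.full(n_var, np.inf)
        for s, e in zip(starts, ends):
            d = np.minimum(d, np.where((p0 >= s) & (p0 < e), 0, np.minimum(abs(p0 - s), abs(p0 - e))))
        vt["gene_distance"] = d

        mask = plant_causal_mask(vmap, core_windows, n_causal=12, seed=23)
        leads = pd.DataFrame({
            "variant_id": vmap.loc[mask, "variant_id"].to_numpy(),
            "chrom": "chr1",
            "pos_bp": vmap.loc[mask, "position_bp"].to_numpy(),
            "p": 1e-12,
        })

        def core_hits(lead_df):
            flags = enr.genes_near_hits(core_windows, lead_df)
            return int(flags.sum())

        true_hits = core_hits(leads)
        null_sets = enr.matched_null_sets(leads, vt, n_sets=100, seed=24)
        beat = 0
        for s in null_sets:
            null_leads = s[["variant_id"]].merge(vmap, on="variant_id")
            null_leads = null_leads.rename(columns={"position_bp": "pos_bp"})
            null_leads["p"] = 1e-12
            beat += core_hits(null_leads) < true_hits
        assert beat >= 95


def test_decile_uniformity():
    x = np.random.default_rng(0).standard_normal(1000)
    d = enr._decile(x)
    counts = np.bincount(d, minlength=10)
    assert counts.min() >= 90
    assert counts.max() <= 110
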