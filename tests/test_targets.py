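"""Seed windows, site scanning, Venn algebra, Fisher enrichment."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from isomirseq.reference import revcomp
from isomirseq.targets import (SeedError, SeedInfo, enrich, predict_targets,
                               scan_utr, seed_collisions, seed_of,
                               site_motifs, target_overlap)

MATURE = "TAGCTTATCAGACTGATGTTGA"   # a let-7-family-like mature sequence


class TestSeedOf:
    def test_canonical_window_is_positions_2_to_8(self):
        assert seed_of(MATURE, 0) == "AGCTTAT"

    def test_positive_offset_shifts_window_3primeward(self):
        assert seed_of(MATURE, 1) == "GCTTATC"

    def test_negative_offset_prepends_templated_upstream(self):
        assert seed_of(MATURE, -1, upstream="CCG") == "TAGCTTA"
        assert seed_of(MATURE, -2, upstream="CCG") == "GTAGCTT"

    def test_idempotent_at_fixed_offset(self):
        assert seed_of(MATURE, 0) == seed_of(MATURE, 0)

    def test_missing_upstream_bases_error(self):
        with pytest.raises(SeedError, match="upstream"):
            seed_of(MATURE, -2, upstream="C")

    def test_window_escape_error(self):
        with pytest.raises(SeedError):
            seed_of("ACGTACG", 0)


class TestSiteScanning:
    def test_8mer_site_hits_all_three_types(self):
        seed = "AGCTTAT"
        utr = "CCC" + site_motifs(seed)["8mer"] + "CCC"
        counts = scan_utr(utr, seed)
        assert counts == {"8mer": 1, "7mer-m8": 1, "7mer-A1": 1}

    def test_7mer_m8_without_downstream_a(self):
        seed = "AGCTTAT"
        utr = "CCC" + revcomp(seed) + "CCC"
        counts = scan_utr(utr, seed)
        assert counts["7mer-m8"] == 1 and counts["8mer"] == 0
        assert counts["7mer-A1"] == 0

    def test_7mer_a1_requires_a_after_six_mer(self):
        seed = "AGCTTAT"
        utr = "CC" + revcomp(seed[:6]) + "A" + "CC"
        counts = scan_utr(utr, seed)
        assert counts["7mer-A1"] == 1 and counts["7mer-m8"] == 0

    def test_utr_without_complement_has_no_sites(self):
        # poly-A UTR cannot complement a seed containing no T
        assert sum(scan_utr("A" * 60, "AGCGCAG").values()) == 0

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_position_scan(self, seed_int):
        """Site counts equal an exhaustive per-position window check."""
        rng = np.random.default_rng(seed_int)
        utr = "".join(rng.choice(list("ACGT"), size=120))
        seed = "".join(rng.choice(list("ACGT"), size=7))
        motifs = site_motifs(seed)
        brute = {t: sum(1 for i in range(len(utr) - len(m) + 1)
                        if utr[i:i + len(m)] == m)
                 for t, m in motifs.items()}
        assert scan_utr(utr, seed) == brute

    def test_predict_targets_returns_genes_with_any_site(self):
        seed = "AGCTTAT"
        utrs = {"hit": "CC" + site_motifs(seed)["7mer-m8"] + "CC",
                "miss": "A" * 40}
        ts = predict_targets(seed, utrs)
        assert ts.genes == {"hit"}
        assert ts.site_counts["hit"] == 1


class TestSeedCollisions:
    def test_self_pair_excluded_and_collision_found(self):
        canonical = {"miR-A": "AGCTTAT", "miR-B": "GCTTATC"}
        # miR-A's +1 isomiR adopts miR-B's canonical seed
        infos = [SeedInfo("miR-A|+1|0", "GCTTATC"),
                 SeedInfo("miR-B|+1|0", "GCTTATC")]   # not B's own seed? it is
        pairs = seed_collisions(infos, canonical)
        assert ("miR-A|+1|0", "miR-B") in pairs
        assert all(src.split("|")[0] != arm for src, arm in pairs)

    def test_empty_input_empty_output(self):
        assert seed_collisions([], {"m": "AGCTTAT"}) == []


class TestTargetOverlap:
    def test_identical_sets(self):
        venn = target_overlap({"a": {"g1", "g2"}, "b": {"g1", "g2"}})
        both = venn[(venn.a) & (venn.b)]["count"].iloc[0]
        only = venn[(venn.a) & (~venn.b)]["count"].iloc[0]
        assert both == 2 and only == 0

    def test_disjoint_sets(self):
        venn = target_overlap({"a": {"g1"}, "b": {"g2"}})
        assert venn[(venn.a) & (venn.b)]["count"].iloc[0] == 0

    def test_three_way_regions_sum_to_union(self):
        sets = {"a": {"g1", "g2", "g3"}, "b": {"g2", "g3", "g4"},
                "c": {"g3", "g4", "g5"}}
        venn = target_overlap(sets)
        assert venn["count"].sum() == len(set().union(*sets.values()))
        triple = venn[venn.a & venn.b & venn.c]["count"].iloc[0]
        assert triple == 1  # g3

    def test_planted_shared_pool_recovered(self):
        shared = {f"s{i}" for i in range(35)}
        sets = {"x": shared | {"x1", "x2"}, "y": shared | {"y1"},
                "z": shared | {"z1", "z2", "z3"}}
        venn = target_overlap(sets)
        assert venn[venn.x & venn.y & venn.z]["count"].iloc[0] == 35

    def test_more_than_three_sets_gives_pairwise_matrix(self):
        sets = {k: {k} for k in "abcd"}
        m = target_overlap(sets)
        assert m.shape == (4, 4)
        assert (np.diag(m) == 1).all()


class TestEnrich:
    def test_whole_set_as_targets_is_most_significant(self):
        gene_sets = {"hit_set": {f"g{i}" for i in range(20)},
                     "other": {f"h{i}" for i in range(20)},
                     "other2": {f"k{i}" for i in range(20)}}
        res = enrich({f"g{i}" for i in range(20)}, gene_sets)
        assert res.index[0] == "hit_set"
        assert res.iloc[0].p < res.iloc[1].p

    def test_fisher_p_equals_hypergeometric_survival(self):
        """One-sided Fisher p == hypergeometric tail, to 1e-12 relative."""
        universe = {f"g{i}" for i in range(1000)}
        gene_set = {f"g{i}" for i in range(100)}
        targets = {f"g{i}" for i in range(80, 100)} | \
                  {f"g{i}" for i in range(900, 980)}
        res = enrich(targets, {"s": gene_set}, universe)
        k, K, n, N = 20, 100, 100, 1000
        oracle = sps.hypergeom.sf(k - 1, N, K, n)
        assert res.loc["s", "p"] == pytest.approx(oracle, rel=1e-12)

    def test_table_level_oracle(self):
        # 2x2 table (10, 90, 10, 890): p equals hypergeometric tail
        universe = {f"u{i}" for i in range(1000)}
        gene_set = set(list(sorted(universe))[:100])
        in_set_targets = set(list(sorted(gene_set))[:10])
        out_targets = set(list(sorted(universe - gene_set))[:10])
        res = enrich(in_set_targets | out_targets, {"s": gene_set}, universe)
        oracle = sps.hypergeom.sf(9, 1000, 100, 20)
        assert res.loc["s", "p"] == pytest.approx(oracle, rel=1e-12)

    def test_ratio_reporting(self):
        # 34 of 47 genes targeted -> ratio 72.3%
        gene_set = {f"g{i}" for i in range(47)}
        targets = {f"g{i}" for i in range(34)}
        res = enrich(targets, {"s": gene_set},
                     universe=gene_set | {f"bg{i}" for i in range(200)})
        assert round(100 * res.loc["s", "ratio"], 1) == 72.3

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            enrich({"g"}, {})
        with pytest.raises(ValueError):
            enrich({"g"}, {"s": {"x"}}, universe=set())

    def test_bh_applied_across_sets(self):
        gene_sets = {f"s{i}": {f"g{i}_{j}" for j in range(10)}
                     for i in range(5)}
        res = enrich(gene_sets["s0"], gene_sets)
        assert (res.fdr >= res.p - 1e-15).all()
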