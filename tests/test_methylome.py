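"""Methylation tracks, DMRs, forest/prairie domains, profiles, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylhic import methylome as me
from methylhic.io_formats import PAIR_COLUMNS, GenomeSpec


def genome_with_cpgs(cpgs, length=100_000):
    return GenomeSpec(chrom_names=["chr1"], chrom_lengths={"chr1": length},
                      cpg_positions={"chr1": np.asarray(cpgs)})


def track(pos, meth, total, floor=1):
    df = pd.DataFrame({"chrom": "chr1", "pos": pos, "meth": meth,
                       "total": total})
    return me.MethylationTrack(data=df, coverage_floor=floor)


class TestMethylationFromPairs:
    def test_full_methylation_attribution(self):
        genome = genome_with_cpgs([1000, 1050])
        pairs = pd.DataFrame(
            [("chr1", 990, "chr1", 50_000, 2, 2, 0, 0)],
            columns=PAIR_COLUMNS)
        out = me.methylation_from_pairs(pairs, genome, coverage_floor=1)
        both = out.data.set_index("pos")
        assert both.loc[1000, "meth"] == both.loc[1000, "total"] == 1.0
        assert both.loc[1050, "meth"] == both.loc[1050, "total"] == 1.0

    def test_coverage_floor_masks_levels(self):
        t = track([100], [4], [9], floor=10)
        assert t.levels().empty
        t2 = track([100], [4], [10], floor=10)
        assert len(t2.levels()) == 1

    def test_footprint_outside_chromosome_rejected(self):
        genome = genome_with_cpgs([1000], length=2000)
        pairs = pd.DataFrame([("chr1", 1950, "chr1", 1990, 0, 1, 0, 1)],
                             columns=PAIR_COLUMNS)
        with pytest.raises(ValueError, match="footprint"):
            me.methylation_from_pairs(pairs, genome)

    def test_binned_beta_equals_brute_force(self):
        rng = np.random.default_rng(30)
        for _ in range(50):
            n = rng.integers(5, 60)
            pos = np.sort(rng.choice(np.arange(100_000), n, replace=False))
            total = rng.integers(1, 40, n)
            meth = rng.binomial(total, 0.5)
            t = track(pos, meth, total, floor=1)
            genome = genome_with_cpgs(pos)
            binned = t.binned(genome, 10_000)
            for _, row in binned.iterrows():
                sel = (pos >= row["start"]) & (pos < row["start"] + 10_000)
                if total[sel].sum() == 0:
                    assert np.isnan(row["beta"])
                else:
                    brute = meth[sel].sum() / total[sel].sum()
                    assert abs(row["beta"] - brute) <= 1e-9 * max(brute, 1e-9)


class TestCallDmrs:
    def test_strong_region_called_hyper(self):
        pos = np.arange(1000, 1600, 100)  # 6 CpGs
        wt = track(pos, [2] * 6, [20] * 6)
        tko = track(pos, [18] * 6, [20] * 6)
        dmrs = me.call_dmrs(wt, tko)
        assert len(dmrs) == 1
        d = dmrs.iloc[0]
        assert d["direction"] == "hyper"
        assert abs(d["diff"] - 0.8) < 1e-12
        assert d["n_cpgs"] == 6

    def test_four_cpg_region_rejected(self):
        pos = np.arange(1000, 1400, 100)
        wt = track(pos, [2] * 4, [20] * 4)
        tko = track(pos, [18] * 4, [20] * 4)
        assert me.call_dmrs(wt, tko).empty

    def test_identical_tracks_yield_nothing(self):
        rng = np.random.default_rng(31)
        pos = np.sort(rng.choice(np.arange(50_000), 200, replace=False))
        total = rng.integers(10, 30, 200)
        meth = rng.binomial(total, 0.7)
        t = track(pos, meth, total)
        assert me.call_dmrs(t, t).empty

    def test_direction_antisymmetric_under_swap(self):
        rng = np.random.default_rng(32)
        pos = np.sort(rng.choice(np.arange(100_000), 300, replace=False))
        total = rng.integers(15, 25, 300)
        base = np.clip(0.6 + 0.05 * rng.standard_normal(300), 0, 1)
        shifted = base.copy()
        shifted[100:130] = np.clip(base[100:130] + 0.35, 0, 1)
        wt = track(pos, rng.binomial(total, base), total)
        tko = track(pos, rng.binomial(total, shifted), total)
        fwd = me.call_dmrs(wt, tko)
        rev = me.call_dmrs(tko, wt)
        pd.testing.assert_frame_equal(
            fwd[["chrom", "start", "end", "n_cpgs"]],
            rev[["chrom", "start", "end", "n_cpgs"]])
        flip = {"hyper": "hypo", "hypo": "hyper"}
        assert (fwd["direction"].map(flip) == rev["direction"]).all()

    def test_disjoint_cpg_sets_rejected(self):
        a = track([100], [1], [10])
        b = track([200], [1], [10])
        with pytest.raises(ValueError, match="shared"):
            me.call_dmrs(a, b)


class TestCgiDomains:
    def genome(self, length=300_000):
        return GenomeSpec(chrom_names=["chr1"],
                          chrom_lengths={"chr1": length},
                          cpg_positions={"chr1": np.arange(0, length, 97)})

    def cgis(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def test_gap_rule_arithmetic(self):
        cgis = self.cgis([("chr1", 0, 1000), ("chr1", 5000, 6000),
                          ("chr1", 200_000, 201_000)])
        domains = me.cgi_domains(self.genome(), cgis, gap_threshold=50_000)
        forest = domains[domains["label"] == "forest"]
        assert [(f["start"], f["end"]) for _, f in forest.iterrows()] == \
            [(0, 6000), (200_000, 201_000)]
        prairie = domains[domains["label"] == "prairie"]
        assert (6000, 200_000) in [(p["start"], p["end"])
                                   for _, p in prairie.iterrows()]

    def test_infinite_gap_single_forest(self):
        cgis = self.cgis([("chr1", 10_000, 11_000),
                          ("chr1", 250_000, 251_000)])
        domains = me.cgi_domains(self.genome(), cgis,
                                 gap_threshold=10 ** 12)
        forest = domains[domains["label"] == "forest"]
        assert len(forest) == 1
        assert (forest.iloc[0]["start"], forest.iloc[0]["end"]) == \
            (10_000, 251_000)

    def test_domains_tile_chromosome(self):
        rng = np.random.default_rng(33)
        starts = np.sort(rng.choice(np.arange(0, 290_000, 1000), 12,
                                    replace=False))
        cgis = self.cgis([("chr1", int(s), int(s) + 500) for s in starts])
        domains = me.cgi_domains(self.genome(), cgis, gap_threshold=30_000)
        domains = domains.sort_values("start")
        assert domains.iloc[0]["start"] == 0
        assert domains.iloc[-1]["end"] == 300_000
        assert (domains["start"].to_numpy()[1:]
                == domains["end"].to_numpy()[:-1]).all()

    def test_no_cgis_whole_prairie(self, caplog):
        domains = me.cgi_domains(self.genome(), self.cgis([]))
        assert list(domains["label"]) == ["prairie"]


class TestDomainMethylation:
    def test_identical_conditions_zero_delta(self):
        pos = np.arange(0, 90_000, 500)
        total = np.full(len(pos), 20)
        t = track(pos, (total * 0.6).astype(int), total, floor=10)
        domains = pd.DataFrame(
            [("chr1", 0, 50_000, "forest"), ("chr1", 50_000, 90_000,
                                             "prairie")],
            columns=["chrom", "start", "end", "label"])
        out = me.domain_methylation_difference(domains, t, t)
        assert np.allclose(out["table"]["delta"], 0.0)

    def test_class_means_match_brute_force(self):
        rng = np.random.default_rng(34)
        pos = np.sort(rng.choice(np.arange(100_000), 400, replace=False))
        total = rng.integers(10, 30, 400)
        meth = rng.binomial(total, 0.5)
        t = track(pos, meth, total, floor=10)
        domains = pd.DataFrame(
            [("chr1", 0, 40_000, "forest"), ("chr1", 40_000, 100_000,
                                             "prairie")],
            columns=["chrom", "start", "end", "label"])
        levels = me.domain_mean_levels(domains, t)
        for k, (_, d) in enumerate(domains.iterrows()):
            sel = (pos >= d["start"]) & (pos < d["end"]) & (total >= 10)
            brute = meth[sel].sum() / total[sel].sum()
            assert abs(levels[k] - brute) <= 1e-12


class TestProfiles:
    def test_constant_signal_flat_profile(self):
        signal = pd.DataFrame([("chr1", 0, 1_000_000, 2.0)],
                              columns=["chrom", "start", "end", "value"])
        refs = pd.DataFrame({"chrom": ["chr1"] * 3,
                             "pos": [100_000, 300_000, 500_000]})
        out = me.profile_matrix(signal, refs, flank=5_000, n_bins=10)
        np.testing.assert_allclose(out["mean"], 2.0)
        np.testing.assert_allclose(out["se"], 0.0)

    def test_minus_strand_reversed(self):
        signal = pd.DataFrame([("chr1", 0, 100_000, 1.0),
                               ("chr1", 100_000, 200_000, 5.0)],
                              columns=["chrom", "start", "end", "value"])
        plus = pd.DataFrame({"chrom": ["chr1"], "pos": [100_000],
                             "strand": ["+"]})
        minus = plus.assign(strand="-")
        p = me.profile_matrix(signal, plus, flank=20_000, n_bins=8)
        m = me.profile_matrix(signal, minus, flank=20_000, n_bins=8)
        np.testing.assert_allclose(p["mean"], m["mean"][::-1])

    def test_triangular_signal_resampled(self):
        # stepwise ramp; column means must equal the exact step integrals
        steps = [("chr1", i * 1000, (i + 1) * 1000, float(i))
                 for i in range(100)]
        signal = pd.DataFrame(steps,
                              columns=["chrom", "start", "end", "value"])
        refs = pd.DataFrame({"chrom": ["chr1"], "pos": [50_000]})
        out = me.profile_matrix(signal, refs, flank=10_000, n_bins=20)
        # columns are 1 kb wide and aligned with the steps: exact values
        np.testing.assert_allclose(out["mean"], np.arange(40, 60))


class TestEnrichment:
    def genome(self):
        return GenomeSpec(chrom_names=["chr1"],
                          chrom_lengths={"chr1": 1_000_000})

    def test_self_enrichment_extreme(self):
        q = pd.DataFrame([("chr1", i, i + 500) for i in
                          range(0, 100_000, 10_000)],
                         columns=["chrom", "start", "end"])
        out = me.interval_enrichment(q, q, self.genome(), n_shuffles=99,
                                     seed=1)
        assert out["p"] == pytest.approx(1 / 100)
        assert out["z"] > 3

    def test_zero_shuffles_rejected(self):
        q = pd.DataFrame([("chr1", 0, 100)],
                         columns=["chrom", "start", "end"])
        with pytest.raises(ValueError):
            me.interval_enrichment(q, q, self.genome(), n_shuffles=0, seed=1)

    def test_independent_sets_modest_z(self):
        rng = np.random.default_rng(35)
        zs = []
        for rep in range(10):
            q = pd.DataFrame([("chr1", int(s), int(s) + 1000) for s in
                              rng.integers(0, 990_000, 20)],
                             columns=["chrom", "start", "end"])
            t = pd.DataFrame([("chr1", int(s), int(s) + 1000) for s in
                              rng.integers(0, 990_000, 20)],
                             columns=["chrom", "start", "end"])
            out = me.interval_enrichment(q, t, self.genome(),
                                         n_shuffles=60, seed=rep)
            zs.append(out["z"])
        assert abs(np.mean(zs)) < 1.0


class TestGeneBody:
    def test_weighted_mean_arithmetic(self):
        pos = [1000, 2000]
        t_wt = track(pos, [0, 0], [10, 30], floor=10)
        # levels 0.2 @ 10 reads and 0.4 @ 30 reads -> weighted 0.35
        t_tko = track(pos, [2, 12], [10, 30], floor=10)
        genes = pd.DataFrame([("chr1", 0, 5000, "g1"),
                              ("chr1", 5000, 9000, "g2"),
                              ("chr1", 9000, 12_000, "g3")],
                             columns=["chrom", "start", "end", "name"])
        levels = me.domain_mean_levels(genes, t_tko)
        assert abs(levels[0] - 0.35) < 1e-12

    def test_absent_subset_gene_rejected(self):
        genes = pd.DataFrame([("chr1", 0, 5000, "g1")],
                             columns=["chrom", "start", "end", "name"])
        t = track([1000], [1], [10])
        with pytest.raises(ValueError, match="absent"):
            me.gene_body_methylation(genes, t, t, ["nope"], 5, 1)

    def test_planted_subset_exceeds_random_draws(self):
        rng = np.random.default_rng(36)
        n_genes = 60
        gene_rows, pos_all, meth_wt, meth_tko, totals = [], [], [], [], []
        subset = [f"g{i}" for i in range(8)]
        for g in range(n_genes):
            start = g * 10_000
            gene_rows.append(("chr1", start, start + 8000, f"g{g}"))
            pos = np.arange(start + 500, start + 8000, 400)
            tot = np.full(len(pos), 25)
            base = 0.5
            bump = 0.1 if f"g{g}" in subset else 0.0
            meth_wt.append(rng.binomial(tot, base))
            meth_tko.append(rng.binomial(tot, base + bump))
            pos_all.append(pos)
            totals.append(tot)
        genes = pd.DataFrame(gene_rows,
                             columns=["chrom", "start", "end", "name"])
        pos = np.concatenate(pos_all)
        t_wt = track(pos, np.concatenate(meth_wt), np.concatenate(totals),
                     floor=10)
        t_tko = track(pos, np.concatenate(meth_tko), np.concatenate(totals),
                      floor=10)
        out = me.gene_body_methylation(genes, t_wt, t_tko, subset,
                                       n_random=60, seed=2)
        assert out["frac_random_below"] >= 0.95
        assert out["welch"]["p"] < 0.01
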