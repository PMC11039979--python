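"""Generator properties: determinism, planted structure, closed-form counts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methylhic as mh
from methylhic import synthetic as syn

from conftest import SEED


class TestBuildModel:
    def test_seeded_determinism(self):
        cfg = mh.SyntheticConfig()
        a = mh.build_genome_model(cfg, 7)
        b = mh.build_genome_model(cfg, 7)
        for c in a.genome.chrom_names:
            np.testing.assert_array_equal(a.genome.cpgs(c), b.genome.cpgs(c))
            np.testing.assert_array_equal(a.compartment_labels[c],
                                          b.compartment_labels[c])
            np.testing.assert_array_equal(
                a.conditions["WT"].methylation_surface[c],
                b.conditions["WT"].methylation_surface[c])
        pd.testing.assert_frame_equal(a.tads, b.tads)
        pd.testing.assert_frame_equal(a.conditions["WT"].loops,
                                      b.conditions["WT"].loops)
        pa = mh.simulate_contacts(a, "WT", 10_000, 3)
        pb = mh.simulate_contacts(b, "WT", 10_000, 3)
        pd.testing.assert_frame_equal(pa, pb)

    def test_bin_bookkeeping(self, wt_model):
        # 2 chromosomes x 10 Mb at 50 kb -> 400 bins, labels partition them
        total = sum(len(wt_model.compartment_labels[c])
                    for c in wt_model.genome.chrom_names)
        assert total == 400
        for c in wt_model.genome.chrom_names:
            lab = wt_model.compartment_labels[c]
            assert set(lab) == {"A", "B"}
            sign = np.where(lab == "A", 1, -1)
            agree = np.sign(wt_model.ev_truth[c]) == sign
            assert agree.mean() > 0.9  # smoothing only blurs block edges

    def test_tads_tile_each_chromosome(self, wt_model):
        for c, sub in wt_model.tads.groupby("chrom"):
            sub = sub.sort_values("start")
            assert sub.iloc[0]["start"] == 0
            assert sub.iloc[-1]["end"] == wt_model.genome.chrom_lengths[c]
            assert (sub["start"].to_numpy()[1:]
                    == sub["end"].to_numpy()[:-1]).all()
            assert len(sub) == 20

    def test_forest_prairie_cpg_contrast(self, wt_model):
        # configured 10x forest/prairie density contrast, Poisson noise
        dens = {}
        for label in ("forest", "prairie"):
            blocks = wt_model.forests[wt_model.forests["label"] == label]
            n_cpg = bp = 0
            for _, b in blocks.iterrows():
                cpgs = wt_model.genome.cpgs(b["chrom"])
                n_cpg += np.searchsorted(cpgs, b["end"]) \
                    - np.searchsorted(cpgs, b["start"])
                bp += b["end"] - b["start"]
            dens[label] = n_cpg / bp
        ratio = dens["forest"] / dens["prairie"]
        assert 8.0 < ratio < 12.0

    def test_indivisible_binsize_rejected(self):
        cfg = mh.SyntheticConfig(chrom_lengths={"chr1": 10_000_123})
        with pytest.raises(ValueError, match="divide"):
            mh.build_genome_model(cfg, 1)


class TestSimulateContacts:
    def test_zero_pairs_empty_stream(self, wt_model):
        pairs = mh.simulate_contacts(wt_model, "WT", 0, 1)
        assert pairs.empty and list(pairs.columns) == [
            "chrom1", "pos1", "chrom2", "pos2",
            "meth1", "total1", "meth2", "total2"]

    def test_unknown_condition_rejected(self, wt_model):
        with pytest.raises(KeyError, match="condition"):
            mh.simulate_contacts(wt_model, "KO9", 10, 1)

    def test_pure_power_law_decay_slope(self):
        # structureless model: contact frequency ~ d^-1
        cfg = mh.SyntheticConfig(chrom_lengths={"chr1": 10_000_000},
                                 f_comp=1.0, f_tad=1.0, f_loop=1.0,
                                 n_loops_per_chrom=0)
        model = mh.build_genome_model(cfg, 2)
        pairs = mh.simulate_contacts(model, "WT", 1_000_000, 3)
        d = (pairs["pos2"] - pairs["pos1"]).to_numpy()
        bins = np.geomspace(100_000, 8_000_000, 12)
        counts, edges = np.histogram(d, bins=bins)
        centers = np.sqrt(edges[:-1] * edges[1:])
        # frequency per locus pair: correct for the (L - d) availability
        dens = counts / np.diff(edges) / (10_000_000 - centers)
        slope = np.polyfit(np.log(centers), np.log(dens), 1)[0]
        assert abs(slope - (-1.0)) < 0.1

    def test_planted_loop_pixel_enrichment(self):
        cfg = mh.SyntheticConfig(chrom_lengths={"chr1": 10_000_000},
                                 f_comp=1.0, f_tad=1.0, n_loops_per_chrom=1)
        model = mh.build_genome_model(cfg, 4)
        lp = model.conditions["WT"].loops.iloc[0]
        pairs = mh.simulate_contacts(model, "WT", 2_000_000, 5)
        b1 = pairs["pos1"] // 50_000
        b2 = pairs["pos2"] // 50_000
        at_loop = ((b1 == lp["bin1"]) & (b2 == lp["bin2"])).sum()
        d = lp["bin2"] - lp["bin1"]
        background = ((b2 - b1) == d).sum() / (200 - d)  # same-distance mean
        # background mean includes the loop pixel itself
        ratio = at_loop / ((background * (200 - d) - at_loop) / (199 - d))
        assert 4.0 < ratio < 6.5

    def test_expected_pixel_counts_match_empirical(self, wt_model):
        n_pairs = 1_000_000
        lam = syn.expected_pixel_counts(wt_model, "WT", n_pairs)
        pairs = mh.simulate_contacts(wt_model, "WT", n_pairs, 6)
        c = "chr1"
        sub = pairs[pairs["chrom1"] == c]
        n = wt_model.genome.n_bins(c, wt_model.binsize)
        obs = np.zeros((n, n))
        np.add.at(obs, (sub["pos1"].to_numpy() // 50_000,
                        sub["pos2"].to_numpy() // 50_000), 1)
        # stratified check: every (compartment, TAD, loop) stratum within 3 SE
        strata = {"loop": [], "bulk": [], "short": []}
        i, j = np.triu_indices(n, k=1)
        lam_ij = lam[c][i, j]
        obs_ij = obs[i, j]
        loops = wt_model.conditions["WT"].loops
        loop_set = {(a, b) for a, b in zip(loops["bin1"], loops["bin2"])
                    if loops["chrom"].iloc[0] == c}
        for k in range(len(i)):
            key = "loop" if (i[k], j[k]) in loop_set else (
                "short" if j[k] - i[k] < 10 else "bulk")
            strata[key].append((obs_ij[k], lam_ij[k]))
        for name, vals in strata.items():
            if not vals:
                continue
            o = np.array([v[0] for v in vals])
            e = np.array([v[1] for v in vals])
            se = np.sqrt(e.sum())
            assert abs(o.sum() - e.sum()) < 3 * se, name


class TestPerturbation:
    def test_identity_perturbation_is_noop(self, wt_model):
        pert = syn.PerturbationConfig(
            cgi_rich_hyper_delta=0.0, boundary_peak_hyper_delta=0.0,
            compartment_contrast_scale=1.0, tad_contrast_scale=1.0,
            long_loop_depletion=0.0, rho_increase=0.0)
        model = syn.apply_perturbation(wt_model, pert)
        wt, tko = model.conditions["WT"], model.conditions["TKO"]
        assert tko.f_comp == wt.f_comp and tko.f_tad == wt.f_tad
        assert tko.concordance_rho == wt.concordance_rho
        pd.testing.assert_frame_equal(tko.loops, wt.loops)
        for c in model.genome.chrom_names:
            np.testing.assert_array_equal(tko.methylation_surface[c],
                                          wt.methylation_surface[c])

    def test_forest_delta_additive(self, wt_model):
        pert = syn.PerturbationConfig(cgi_rich_hyper_delta=0.15,
                                      long_loop_depletion=0.0,
                                      rho_increase=0.0)
        model = syn.apply_perturbation(wt_model, pert)
        c = model.genome.chrom_names[0]
        pos = model.genome.cpgs(c)
        forest = model.forests[(model.forests["chrom"] == c)
                               & (model.forests["label"] == "forest")].iloc[0]
        sel = (pos >= forest["start"]) & (pos < forest["end"])
        wt_s = model.conditions["WT"].methylation_surface[c][sel]
        tko_s = model.conditions["TKO"].methylation_surface[c][sel]
        unclipped = wt_s + 0.15 <= 1.0
        np.testing.assert_allclose(tko_s[unclipped],
                                   wt_s[unclipped] + 0.15)

    def test_long_loop_depletion_count(self, wt_model):
        wt_loops = wt_model.conditions["WT"].loops
        cutoff = 500_000
        n_long = ((wt_loops["bin2"] - wt_loops["bin1"]) * 50_000
                  > cutoff).sum()
        model = syn.apply_perturbation(
            wt_model, syn.PerturbationConfig(long_loop_depletion=1.0,
                                             loop_distance_cutoff=cutoff))
        assert len(model.conditions["TKO"].loops) == len(wt_loops) - n_long

    def test_wt_condition_untouched(self, wt_model):
        before = {c: wt_model.conditions["WT"].methylation_surface[c].copy()
                  for c in wt_model.genome.chrom_names}
        syn.apply_perturbation(wt_model, syn.PerturbationConfig())
        for c, s in before.items():
            np.testing.assert_array_equal(
                wt_model.conditions["WT"].methylation_surface[c], s)


class TestAttachMethylation:
    def test_saturated_surface_fully_methylated(self):
        cfg = mh.SyntheticConfig(chrom_lengths={"chr1": 1_000_000},
                                 meth_cgi=1.0, meth_forest=1.0,
                                 meth_prairie=1.0, meth_noise_sd=0.0,
                                 n_tads_per_chrom=4, n_loops_per_chrom=1,
                                 loop_distance_bins=(4, 10))
        model = mh.build_genome_model(cfg, 8)
        for c in model.genome.chrom_names:
            model.conditions["WT"].methylation_surface[c][:] = 1.0
        pairs = mh.simulate_contacts(model, "WT", 5_000, 9)
        pairs = mh.attach_methylation(pairs, model, "WT", 10)
        assert (pairs["meth1"] == pairs["total1"]).all()
        assert (pairs["meth2"] == pairs["total2"]).all()

    def test_independent_mates_uncorrelated(self, dense_flat_model):
        model = dense_flat_model
        model.conditions["WT"].concordance_rho = 0.0
        try:
            pairs = mh.simulate_contacts(model, "WT", 20_000, 12)
            pairs = mh.attach_methylation(pairs, model, "WT", 13)
            ok = (pairs["total1"] >= 5) & (pairs["total2"] >= 5)
            x = pairs.loc[ok, "meth1"] / pairs.loc[ok, "total1"]
            y = pairs.loc[ok, "meth2"] / pairs.loc[ok, "total2"]
            r = stats.pearsonr(x, y).statistic
            assert abs(r) < 0.03
        finally:
            model.conditions["WT"].concordance_rho = 0.6

    def test_high_rho_large_totals_recovered(self):
        cfg = mh.SyntheticConfig(
            chrom_lengths={"chr1": 10_000_000},
            cpg_rate_prairie=0.25, cpg_rate_forest=0.25, cgi_fold=1.0,
            meth_cgi=0.5, meth_forest=0.5, meth_prairie=0.5,
            meth_noise_sd=0.0, concordance_rho=0.99, latent_sigma=1.0)
        model = mh.build_genome_model(cfg, 14)
        pairs = mh.simulate_contacts(model, "WT", 50_000, 15)
        pairs = mh.attach_methylation(pairs, model, "WT", 16)
        ok = (pairs["total1"] >= 20) & (pairs["total2"] >= 20)
        x = pairs.loc[ok, "meth1"] / pairs.loc[ok, "total1"]
        y = pairs.loc[ok, "meth2"] / pairs.loc[ok, "total2"]
        r = stats.pearsonr(x, y).statistic
        assert r > 0.9

    def test_methylation_surface_recovered_at_high_coverage(self, wt_model):
        from methylhic import methylome
        track = syn.simulate_methylation_tracks(wt_model, "WT", 50, 17)
        binned = track.binned(wt_model.genome, 50_000)
        c = wt_model.genome.chrom_names[0]
        surf = wt_model.conditions["WT"].methylation_surface[c]
        pos = wt_model.genome.cpgs(c)
        sub = binned[binned["chrom"] == c]
        truth = np.full(len(sub), np.nan)
        for k, start in enumerate(sub["start"]):
            sel = (pos >= start) & (pos < start + 50_000)
            if sel.any():
                truth[k] = surf[sel].mean()
        ok = np.isfinite(truth) & np.isfinite(sub["beta"].to_numpy())
        rmse = np.sqrt(np.mean(
            (sub["beta"].to_numpy()[ok] - truth[ok]) ** 2))
        assert rmse < 0.02
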