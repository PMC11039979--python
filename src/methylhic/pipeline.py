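"""End-to-end two-condition run on a synthetic model.

Glues the stages together in the order the method runs — simulate, bin,
balance, O/E, compartments, TADs, loops, methylome, concordance — and
writes every declared output file.  Returns a summary dictionary of the
headline numbers so callers (CLI, acceptance script) can report them.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import (compartments, concordance, contact_matrix, io_formats, loops,
               methylome, synthetic, tads)

logger = logging.getLogger("methylhic")

COMPARTMENT_BINSIZE = 250_000


def analyze_condition(model, cond_name: str, n_pairs: int, seed: int) -> dict:
    """Simulate one condition and run every per-condition analysis stage."""
    genome = model.genome
    pairs = synthetic.simulate_contacts(model, cond_name, n_pairs, seed)
    pairs = synthetic.attach_methylation(pairs, model, cond_name, seed + 1)
    pairs = io_formats.filter_pairs(pairs, min_distance=1000)

    raw50 = contact_matrix.bin_pairs(pairs, genome, model.binsize)
    bal50 = {c: contact_matrix.balance(m) for c, m in raw50.items()}
    oe50 = {c: contact_matrix.oe_transform(m)[1] for c, m in bal50.items()}
    raw250 = contact_matrix.bin_pairs(pairs, genome, COMPARTMENT_BINSIZE)
    bal250 = {c: contact_matrix.balance(m) for c, m in raw250.items()}
    oe250 = {c: contact_matrix.oe_transform(m)[1] for c, m in bal250.items()}

    cpg_cov = methylome.cpg_density_per_bin(genome, COMPARTMENT_BINSIZE)
    evs = {c: compartments.compartment_eigenvector(oe250[c], cpg_cov[c])
           for c in genome.chrom_names}
    saddles = {c: compartments.saddle(oe250[c], evs[c])
               for c in genome.chrom_names}

    ins = {c: tads.insulation_scores(bal50[c]) for c in genome.chrom_names}
    tadsets = {c: tads.call_boundaries(ins[c]) for c in genome.chrom_names}
    tad_frame = pd.concat([t.tads for t in tadsets.values()],
                          ignore_index=True)

    loop_calls = pd.concat(
        [loops.call_loops(bal50[c]) for c in genome.chrom_names],
        ignore_index=True)

    track = methylome.methylation_from_pairs(pairs, genome)
    return {"pairs": pairs, "raw": raw50, "balanced": bal50, "oe": oe50,
            "balanced250": bal250, "oe250": oe250, "ev": evs,
            "saddle": saddles, "insulation": ins, "tadsets": tadsets,
            "tads": tad_frame, "loops": loop_calls, "meth": track}


def run_pipeline(outdir: str | Path, seed: int = 0,
                 n_pairs: int = 1_000_000,
                 config: synthetic.SyntheticConfig | None = None,
                 perturbation: synthetic.PerturbationConfig | None = None
                 ) -> dict:
    """Simulate WT and TKO, run all analyses, write outputs, summarise."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or synthetic.SyntheticConfig()
    perturbation = perturbation or synthetic.PerturbationConfig()
    model = synthetic.build_genome_model(config, seed)
    model = synthetic.apply_perturbation(model, perturbation)
    genome = model.genome

    res = {cond: analyze_condition(model, cond, n_pairs, seed + k * 101)
           for k, cond in enumerate(("WT", "TKO"))}

    # --- cross-condition analyses
    switch_frames = [compartments.classify_switches(res["WT"]["ev"][c],
                                                    res["TKO"]["ev"][c])
                     for c in genome.chrom_names]
    switches = pd.concat(switch_frames, ignore_index=True)
    proportions = compartments.switch_proportions(switches)

    overlap = tads.tad_overlap(res["WT"]["tads"], res["TKO"]["tads"])

    scaled = {cond: contact_matrix.scale_total(res[cond]["raw"])
              for cond in ("WT", "TKO")}
    diff = loops.differential_loops(res["WT"]["loops"], res["TKO"]["loops"],
                                    res["WT"]["oe"], res["TKO"]["oe"])

    dmrs = methylome.call_dmrs(res["WT"]["meth"], res["TKO"]["meth"])
    domains = methylome.cgi_domains(genome, model.cgis)
    domain_diff = methylome.domain_methylation_difference(
        domains, res["WT"]["meth"], res["TKO"]["meth"])

    bins = concordance.log_distance_bins(1_000, 5_000_000, 8)
    profiles = concordance.concordance_profiles(
        res["WT"]["pairs"], res["TKO"]["pairs"], bins,
        cpg_thresholds=[1, 3, 5])

    # --- outputs
    for cond in ("WT", "TKO"):
        io_formats.write_pairs(res[cond]["pairs"],
                               outdir / f"{cond}.pairs.tsv")
        io_formats.write_bed(res[cond]["tads"], outdir / f"{cond}.tads.bed")
        io_formats.write_loops(res[cond]["loops"],
                               outdir / f"{cond}.loops.bedpe")
        for c in genome.chrom_names:
            io_formats.write_matrix(res[cond]["balanced"][c],
                                    outdir / f"{cond}.{c}.balanced.tsv")
        binned = res[cond]["meth"].binned(genome, model.binsize)
        bg = binned.dropna(subset=["beta"])[["chrom", "start"]].copy()
        bg["end"] = bg["start"] + model.binsize
        bg["value"] = binned.dropna(subset=["beta"])["beta"].to_numpy()
        io_formats.write_bedgraph(bg, outdir / f"{cond}.methylation.bedgraph")
        ev_rows = []
        for c in genome.chrom_names:
            ev = res[cond]["ev"][c]
            for b, v in enumerate(ev.ev):
                ev_rows.append((c, b * ev.binsize, (b + 1) * ev.binsize,
                                0.0 if not np.isfinite(v) else v))
        io_formats.write_bedgraph(
            pd.DataFrame(ev_rows, columns=io_formats.BEDGRAPH_COLUMNS),
            outdir / f"{cond}.eigenvector.bedgraph")
    io_formats.write_bed(dmrs.rename(columns={"direction": "name"}),
                         outdir / "dmrs.bed")
    io_formats.write_bed(domains.rename(columns={"label": "name"}),
                         outdir / "domains.bed")
    io_formats.write_bed(model.cgis.assign(name="cgi"),
                         outdir / "truth.cgis.bed")
    io_formats.write_bed(model.tads, outdir / "truth.tads.bed")
    io_formats.write_loops(synthetic.loop_truth_frame(model, "WT"),
                           outdir / "truth.loops.WT.bedpe")
    for cond in ("WT", "TKO"):
        concordance.results_frame(
            concordance.concordance_pcc(res[cond]["pairs"], bins)
        ).to_csv(outdir / f"{cond}.concordance.tsv", sep="\t", index=False)

    summary = {
        "n_pairs": n_pairs,
        "saddle_strength": {cond: float(np.mean(
            [s.strength for s in res[cond]["saddle"].values()]))
            for cond in ("WT", "TKO")},
        "switch_proportions": proportions,
        "n_tads": {cond: len(res[cond]["tads"]) for cond in ("WT", "TKO")},
        "tad_overlap_matched": overlap["matched_a"],
        "n_loops": {cond: len(res[cond]["loops"]) for cond in ("WT", "TKO")},
        "loss_to_gain_ratio": float(diff["loss_to_gain_ratio"]),
        "n_dmrs": len(dmrs),
        "forest_prairie_gap": domain_diff["gap"],
        "concordance_trend": profiles["trend"],
        "scaled_total": {cond: float(sum(np.nansum(m.values)
                                         for m in scaled[cond].values()))
                         for cond in ("WT", "TKO")},
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return {"model": model, "results": res, "switches": switches,
            "differential": diff, "dmrs": dmrs, "domains": domains,
            "domain_diff": domain_diff, "profiles": profiles,
            "summary": summary}
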