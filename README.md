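# methylhic

Joint analysis of DNA methylation and 3D chromosome organization from
Methyl-HiC-style data.

Methyl-HiC captures a chromatin contact and the CpG methylation state of
both ligated fragments on the same molecule.  That single readout supports
two otherwise separate analysis stacks — and one analysis impossible with
either alone.  This package implements all three, for researchers studying
how methylation dynamics (e.g. loss of the Tet demethylases, which causes
regional hypermethylation) reshape genome architecture:

* **Contact-map analyses.** Binned per-chromosome matrices, ICE balancing,
  distance-normalised O/E; A/B compartment eigenvectors with GC/CpG
  orientation, compartment switching, saddle compartmentalization
  strength; multi-window insulation TAD calling, TAD overlap, intra/inter-
  TAD means, aggregate TAD analysis (ATA); donut local-background loop
  calling, differential (lost/gained) loops, APA and pairwise-region
  aggregation.
* **Methylome analyses.** Per-CpG tracks from mate-level counts, DMR
  calling with the standard gates (≥5 CpGs, |Δβ| > 0.20, p < 0.01), CGI
  forest/prairie domain segmentation, profile aggregation and interval
  enrichment, gene-body methylation comparisons.
* **Read-level concordance.** The Pearson correlation of mate methylation
  fractions across interacting read pairs, stratified by genomic distance
  and CpG count, overall and restricted to loop anchors — the statistic
  that quantifies shared methylation state of spatially proximal DNA.

A first-class synthetic generator plants compartments, TADs, loops,
region-specific methylation and a mate-level methylation correlation into
a two-condition (WT vs knockout) model, so every stage can be validated
against known truth.

## The statistics in brief

With per-bin eigenvector $e_i$ (leading eigenvector of the O/E Pearson
correlation matrix, sign-fixed against CpG density), compartment strength
is the saddle corner ratio $(\overline{AA}+\overline{BB})/2\,\overline{AB}$
over eigenvector quantiles.  Insulation at bin edge $e$ and window $w$ is
the mean balanced signal over the diamond
$\{(a,b): e-w \le a < e \le b < e+w\}$; boundaries are significant
prominent minima of the z-scored multi-window score.  A loop pixel must
beat $\max$(donut, lower-left) local expectation in a Poisson tail test at
BH-FDR 0.05 with focal enrichment.  Concordance is
$\mathrm{PCC}(m_1/t_1,\, m_2/t_2)$ over mate pairs, where $m_i/t_i$ are
methylated/covered CpG counts of mate $i$.

## Worked example

```python
import methylhic as mh
from methylhic import contact_matrix as cm, compartments as comp, \
    methylome as me, synthetic as syn, tads, loops as lp

model = mh.build_genome_model(mh.SyntheticConfig(), seed=11)
model = syn.apply_perturbation(model, syn.PerturbationConfig())
pairs = mh.simulate_contacts(model, "WT", 2_000_000, seed=12)
pairs = mh.attach_methylation(pairs, model, "WT", seed=13)

raw = cm.bin_pairs(pairs, model.genome, binsize=250_000)
cov = me.cpg_density_per_bin(model.genome, 250_000)
_, oe = cm.oe_transform(cm.balance(raw["chr1"]))
ev = comp.compartment_eigenvector(oe, cov["chr1"])
print("A/B label agreement:", (ev.labels == model.labels_at("chr1", 250_000)).mean())
print("saddle strength:", round(comp.saddle(oe, ev).strength, 2))

bal = cm.balance(cm.bin_pairs(pairs, model.genome, 50_000)["chr1"])
tadset = tads.call_boundaries(tads.insulation_scores(bal))
print("TAD boundaries called:", len(tadset.boundaries),
      "| planted:", len(syn.boundary_truth(model, "chr1")))
print("loops called:", len(lp.call_loops(bal)))
```

Output:

```
A/B label agreement: 1.0
saddle strength: 1.4
TAD boundaries called: 18 | planted: 19
loops called: 14
```

Every unmasked 250-kb bin receives the planted compartment label; the
saddle strength of ~1.4 reflects the simulated same-compartment contact
enrichment; 18 of 19 planted TAD boundaries and 14 of 15 planted loops on
chr1 are recovered at 2 million pairs.

A thin CLI mirrors the library: `mhk simulate`, `mhk pipeline`,
`mhk tads`, `mhk loops`, `mhk concord`, `mhk convert`.  The full
two-condition run is one call:

```sh
mhk pipeline --outdir out --seed 11 --n-pairs 1000000
```

which writes pairs files, balanced matrices, eigenvector and methylation
bedGraphs, TAD/loop/DMR/domain BED(PE) files, concordance tables and a
JSON summary.

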