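"""Two-condition synthetic Methyl-HiC generator with planted ground truth.

The generator builds a small genome with the structures the analysis
modules are meant to recover, so every downstream stage can be scored
against known truth:

* alternating A/B compartment blocks (multiples of 250 kb) with a smooth
  signed eigenvector truth signal;
* CGI forests (= A blocks) carrying CpG islands, a configurable
  forest-to-prairie CpG density contrast, and lower methylation than
  prairies (mES-like: forests ~0.65, prairies ~0.80, islands ~0.10);
* a TAD partition tiling each chromosome and a list of focal loops;
* mate-level methylation generated through a latent-Gaussian copula whose
  correlation parameter rho is the planted concordance.

Contacts are sampled from a closed-form pixel distribution: the
probability of a (bin i, bin j) pixel is proportional to d^(-decay)
multiplied by f_comp when the bins share a compartment label, f_tad when
they share a TAD, and f_loop at loop pixels — so expected pixel counts are
available exactly for any stratum.

The knockout condition ("TKO") is derived from the wild type by a
:class:`PerturbationConfig`: forests hypermethylated, compartment and TAD
contrast scaled down, long loops depleted, concordance raised — the
directions reported for Tet-deficient cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.stats import norm

from .io_formats import PAIR_COLUMNS, GenomeSpec
from .methylome import MethylationTrack

logger = logging.getLogger("methylhic")


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic genome (defaults are the model)."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000})
    binsize: int = 50_000
    comp_unit: int = 250_000          # compartment blocks snap to this grid
    comp_block_units: tuple[int, int] = (4, 8)   # 1-2 Mb blocks
    n_tads_per_chrom: int = 20
    min_tad_bins: int = 4
    n_loops_per_chrom: int = 15
    loop_distance_bins: tuple[int, int] = (4, 36)  # 200 kb - 1.8 Mb at 50 kb
    f_comp: float = 1.6
    f_tad: float = 2.0
    f_loop: float = 5.0
    decay_exponent: float = 1.0
    cgi_fold: float = 10.0            # forest/prairie CpG density contrast
    cpg_rate_prairie: float = 0.002   # CpGs per bp outside forests
    cpg_rate_forest: float = 0.004    # forest background outside islands
    cgi_width: int = 1_000
    cgi_spacing: int = 10_000
    meth_cgi: float = 0.10
    meth_forest: float = 0.65
    meth_prairie: float = 0.80
    meth_noise_sd: float = 0.03
    concordance_rho: float = 0.6
    latent_sigma: float = 0.5
    rho_decay_length: float | None = None   # bp scale of rho(d) decay
    rho_loop: float | None = None           # rho override at loop pixels
    mate_footprint: int = 100


@dataclass
class PerturbationConfig:
    """Knockout effects applied on top of the wild-type model."""

    cgi_rich_hyper_delta: float = 0.10
    boundary_peak_hyper_delta: float = 0.0
    compartment_contrast_scale: float = 0.5
    tad_contrast_scale: float = 0.5
    long_loop_depletion: float = 1.0
    loop_distance_cutoff: int = 500_000
    rho_increase: float = 0.2
    # planted DMRs (inactive by default; ground truth for DMR recovery)
    dmr_hyper_delta: float = 0.0
    n_dmr_regions: int = 0
    dmr_width: int = 2_000
    dmr_min_cpgs: int = 8


@dataclass
class Condition:
    name: str
    f_comp: float
    f_tad: float
    f_loop: float
    loops: pd.DataFrame                      # chrom, bin1, bin2, fold
    methylation_surface: dict[str, np.ndarray]
    concordance_rho: float
    rho_decay_length: float | None = None
    rho_loop: float | None = None


@dataclass
class GenomeModel:
    genome: GenomeSpec
    binsize: int
    config: SyntheticConfig
    compartment_labels: dict[str, np.ndarray]  # per model bin, 'A'/'B'
    ev_truth: dict[str, np.ndarray]
    tads: pd.DataFrame                         # chrom, start, end
    cgis: pd.DataFrame
    forests: pd.DataFrame                      # chrom, start, end, label
    conditions: dict[str, Condition]
    dmr_regions: pd.DataFrame                  # planted truth (may be empty)
    seed: int = 0

    def condition(self, name: str) -> Condition:
        if name not in self.conditions:
            raise KeyError(f"condition {name!r} not in model "
                           f"(has {sorted(self.conditions)})")
        return self.conditions[name]

    def labels_at(self, chrom: str, binsize: int) -> np.ndarray:
        """Compartment truth labels re-gridded to another bin size.

        Exact for bin sizes that divide, or are multiples of (up to the
        block grid), the model bin size: the label of the first model bin
        in each target bin is used and blocks snap to the 250 kb grid.
        """
        labels = self.compartment_labels[chrom]
        step = binsize / self.binsize
        idx = (np.arange(self.genome.n_bins(chrom, binsize)) * step).astype(int)
        return labels[np.minimum(idx, len(labels) - 1)]


def _empty_pairs() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=(object if c.startswith("chrom")
                                             else np.int64))
                         for c in PAIR_COLUMNS})


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def _poisson_positions(rng, start: int, end: int, rate: float) -> np.ndarray:
    n = rng.poisson(rate * (end - start))
    if n == 0:
        return np.empty(0, dtype=np.int64)
    return np.unique(rng.integers(start, end, size=n))


def build_genome_model(config: SyntheticConfig, seed: int) -> GenomeModel:
    """Deterministically build the wild-type model from a config and seed."""
    rng = np.random.default_rng(seed)
    if config.comp_unit % config.binsize:
        raise ValueError("comp_unit must be a multiple of binsize")
    chrom_names = list(config.chrom_lengths)
    labels: dict[str, np.ndarray] = {}
    ev_truth: dict[str, np.ndarray] = {}
    forests_rows, cgi_rows, tad_rows, loop_rows = [], [], [], []
    cpg_positions: dict[str, np.ndarray] = {}
    bins_per_unit = config.comp_unit // config.binsize

    for chrom, length in config.chrom_lengths.items():
        if length % config.binsize:
            raise ValueError(f"binsize does not divide length of {chrom}")
        n_units = length // config.comp_unit
        n_bins = length // config.binsize

        # --- alternating compartment blocks on the 250 kb grid
        unit_labels = []
        current = "A" if rng.integers(2) else "B"
        while len(unit_labels) < n_units:
            block = int(rng.integers(config.comp_block_units[0],
                                     config.comp_block_units[1] + 1))
            unit_labels.extend([current] * block)
            current = "B" if current == "A" else "A"
        unit_labels = np.array(unit_labels[:n_units], dtype=object)
        lab = np.repeat(unit_labels, bins_per_unit)
        labels[chrom] = lab
        sign = np.where(lab == "A", 1.0, -1.0)
        amp = 1.0 + 0.2 * rng.standard_normal(n_bins)
        ev_truth[chrom] = gaussian_filter1d(sign * np.abs(amp), sigma=1.0)

        # --- forests = A blocks, with CpG islands inside
        block_bounds = np.concatenate([[0], np.flatnonzero(
            np.diff(sign) != 0) + 1, [n_bins]])
        for b0, b1 in zip(block_bounds[:-1], block_bounds[1:]):
            s, e = int(b0 * config.binsize), int(b1 * config.binsize)
            kind = "forest" if sign[b0] > 0 else "prairie"
            forests_rows.append((chrom, s, e, kind))
            if kind == "forest":
                for cs in range(s, e - config.cgi_width,
                                config.cgi_spacing):
                    jitter = int(rng.integers(0, config.cgi_spacing
                                              - config.cgi_width))
                    a = cs + jitter
                    if a + config.cgi_width <= e:
                        cgi_rows.append((chrom, a, a + config.cgi_width))

        # --- CpG positions: piecewise-Poisson with region-specific rates
        chrom_cgis = [(a, b) for c, a, b in cgi_rows if c == chrom]
        pos_parts = []
        for c, s, e, kind in forests_rows:
            if c != chrom:
                continue
            if kind == "prairie":
                pos_parts.append(_poisson_positions(rng, s, e,
                                                    config.cpg_rate_prairie))
                continue
            inside = [(a, b) for a, b in chrom_cgis if a >= s and b <= e]
            cgi_bp = sum(b - a for a, b in inside)
            f = cgi_bp / (e - s) if e > s else 0.0
            # island rate chosen so the forest-average density hits the
            # configured forest/prairie contrast
            target = config.cgi_fold * config.cpg_rate_prairie
            r_cgi = ((target - (1 - f) * config.cpg_rate_forest) / f
                     if f > 0 else config.cpg_rate_forest)
            r_cgi = max(r_cgi, config.cpg_rate_forest)
            prev = s
            for a, b in inside:
                pos_parts.append(_poisson_positions(rng, prev, a,
                                                    config.cpg_rate_forest))
                pos_parts.append(_poisson_positions(rng, a, b, r_cgi))
                prev = b
            pos_parts.append(_poisson_positions(rng, prev, e,
                                                config.cpg_rate_forest))
        cpg_positions[chrom] = np.unique(np.concatenate(pos_parts)) \
            if pos_parts else np.empty(0, dtype=np.int64)

        # --- TAD partition: n_tads parts of >= min_tad_bins bins
        extra = n_bins - config.n_tads_per_chrom * config.min_tad_bins
        if extra < 0:
            raise ValueError("chromosome too short for the TAD count")
        sizes = config.min_tad_bins + rng.multinomial(
            extra, np.full(config.n_tads_per_chrom,
                           1 / config.n_tads_per_chrom))
        bounds = np.concatenate([[0], np.cumsum(sizes)])
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            tad_rows.append((chrom, int(b0) * config.binsize,
                             int(b1) * config.binsize))

        # --- loops: anchors on bin centers, spread of genomic distances
        placed: list[tuple[int, int]] = []
        attempts = 0
        while len(placed) < config.n_loops_per_chrom and attempts < 10_000:
            attempts += 1
            d = int(rng.integers(config.loop_distance_bins[0],
                                 config.loop_distance_bins[1] + 1))
            if n_bins - 7 - d <= 7:
                continue
            a1 = int(rng.integers(7, n_bins - 7 - d))
            a2 = a1 + d
            if all(max(abs(a1 - p1), abs(a2 - p2)) > 3
                   for p1, p2 in placed):
                placed.append((a1, a2))
        for a1, a2 in sorted(placed):
            loop_rows.append((chrom, a1, a2, config.f_loop))

    genome = GenomeSpec(chrom_names=chrom_names,
                        chrom_lengths=dict(config.chrom_lengths),
                        cpg_positions=cpg_positions)
    forests = pd.DataFrame(forests_rows,
                           columns=["chrom", "start", "end", "label"])
    cgis = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"])
    tads = pd.DataFrame(tad_rows, columns=["chrom", "start", "end"])
    loops = pd.DataFrame(loop_rows, columns=["chrom", "bin1", "bin2", "fold"])

    surface: dict[str, np.ndarray] = {}
    for chrom in chrom_names:
        pos = genome.cpgs(chrom)
        level = np.full(len(pos), config.meth_prairie)
        for _, f in forests[(forests["chrom"] == chrom)
                            & (forests["label"] == "forest")].iterrows():
            sel = (pos >= f["start"]) & (pos < f["end"])
            level[sel] = config.meth_forest
        for _, c in cgis[cgis["chrom"] == chrom].iterrows():
            sel = (pos >= c["start"]) & (pos < c["end"])
            level[sel] = config.meth_cgi
        level = level + config.meth_noise_sd * rng.standard_normal(len(pos))
        surface[chrom] = np.clip(level, 0.02, 0.98)

    wt = Condition(name="WT", f_comp=config.f_comp, f_tad=config.f_tad,
                   f_loop=config.f_loop, loops=loops,
                   methylation_surface=surface,
                   concordance_rho=config.concordance_rho,
                   rho_decay_length=config.rho_decay_length,
                   rho_loop=config.rho_loop)
    return GenomeModel(genome=genome, binsize=config.binsize, config=config,
                       compartment_labels=labels, ev_truth=ev_truth,
                       tads=tads, cgis=cgis, forests=forests,
                       conditions={"WT": wt},
                       dmr_regions=pd.DataFrame(
                           columns=["chrom", "start", "end", "n_cpgs"]),
                       seed=seed)


def apply_perturbation(model: GenomeModel, pert: PerturbationConfig,
                       seed: int | None = None,
                       name: str = "TKO") -> GenomeModel:
    """Derive the knockout condition; the wild-type condition is untouched.

    Returns a new model carrying both conditions plus the planted-DMR
    ground truth (if any were requested).
    """
    if "WT" not in model.conditions:
        raise ValueError("apply_perturbation expects a model with a WT condition")
    rng = np.random.default_rng(model.seed + 1 if seed is None else seed)
    wt = model.conditions["WT"]
    cfg = model.config
    surface = {c: s.copy() for c, s in wt.methylation_surface.items()}
    dmr_rows = []

    for chrom in model.genome.chrom_names:
        pos = model.genome.cpgs(chrom)
        s = surface[chrom]
        if pert.cgi_rich_hyper_delta:
            for _, f in model.forests[
                    (model.forests["chrom"] == chrom)
                    & (model.forests["label"] == "forest")].iterrows():
                s[(pos >= f["start"]) & (pos < f["end"])] += \
                    pert.cgi_rich_hyper_delta
        if pert.boundary_peak_hyper_delta:
            tads_c = model.tads[model.tads["chrom"] == chrom]
            for b in sorted(set(tads_c["start"]) | set(tads_c["end"]))[1:-1]:
                bin_i = b // model.binsize
                lab = model.compartment_labels[chrom][
                    min(bin_i, len(model.compartment_labels[chrom]) - 1)]
                if lab == "A":
                    sel = (pos >= b - model.binsize) & (pos < b + model.binsize)
                    s[sel] += pert.boundary_peak_hyper_delta

    if pert.n_dmr_regions and pert.dmr_hyper_delta:
        # plant DMRs in forest background (moderate base level, CpG-dense
        # enough), outside islands so the full delta survives clipping
        forest_blocks = model.forests[model.forests["label"] == "forest"]
        candidates = []
        for _, p in forest_blocks.iterrows():
            pos = model.genome.cpgs(p["chrom"])
            cgis_c = model.cgis[model.cgis["chrom"] == p["chrom"]]
            for a in range(int(p["start"]) + 5_000,
                           int(p["end"]) - pert.dmr_width - 5_000,
                           5 * pert.dmr_width):
                b = a + pert.dmr_width
                if ((cgis_c["start"] < b) & (cgis_c["end"] > a)).any():
                    continue
                n_cpg = int(np.searchsorted(pos, b) - np.searchsorted(pos, a))
                if n_cpg >= pert.dmr_min_cpgs:
                    candidates.append((p["chrom"], a, b, n_cpg))
        if len(candidates) < pert.n_dmr_regions:
            raise ValueError("not enough CpG-dense prairie windows for the "
                             "requested DMR count")
        pick = rng.choice(len(candidates), size=pert.n_dmr_regions,
                          replace=False)
        for k in sorted(pick):
            chrom, a, b, n_cpg = candidates[k]
            pos = model.genome.cpgs(chrom)
            sel = (pos >= a) & (pos < b)
            surface[chrom][sel] += pert.dmr_hyper_delta
            dmr_rows.append((chrom, a, b, n_cpg))

    clipped = 0
    for chrom, s in surface.items():
        out = (s < 0.0) | (s > 1.0)
        clipped += int(out.sum())
        np.clip(s, 0.0, 1.0, out=s)
    if clipped:
        logger.warning("perturbation clipped %d CpG levels to [0, 1]", clipped)

    loops = wt.loops.copy()
    long = (loops["bin2"] - loops["bin1"]) * model.binsize \
        > pert.loop_distance_cutoff
    n_remove = int(round(pert.long_loop_depletion * long.sum()))
    if n_remove:
        drop = rng.choice(np.flatnonzero(long.to_numpy()), size=n_remove,
                          replace=False)
        loops = loops.drop(loops.index[drop]).reset_index(drop=True)

    tko = Condition(
        name=name,
        f_comp=1.0 + (wt.f_comp - 1.0) * pert.compartment_contrast_scale,
        f_tad=1.0 + (wt.f_tad - 1.0) * pert.tad_contrast_scale,
        f_loop=wt.f_loop, loops=loops, methylation_surface=surface,
        concordance_rho=min(0.99, wt.concordance_rho + pert.rho_increase),
        rho_decay_length=wt.rho_decay_length, rho_loop=wt.rho_loop)
    return replace(model,
                   conditions={**model.conditions, name: tko},
                   dmr_regions=pd.DataFrame(
                       dmr_rows, columns=["chrom", "start", "end", "n_cpgs"]))


# ---------------------------------------------------------------------------
# contact simulation
# ---------------------------------------------------------------------------

def pixel_weights(model: GenomeModel, condition: str,
                  chrom: str) -> np.ndarray:
    """Unnormalised sampling weight of every upper-triangle pixel (d >= 1)."""
    cond = model.condition(condition)
    n = model.genome.n_bins(chrom, model.binsize)
    lab = model.compartment_labels[chrom]
    tad_id = np.full(n, -1)
    for t, (_, row) in enumerate(
            model.tads[model.tads["chrom"] == chrom].iterrows()):
        tad_id[row["start"] // model.binsize:row["end"] // model.binsize] = t
    i, j = np.triu_indices(n, k=1)
    d_bp = (j - i) * model.binsize
    w = d_bp.astype(float) ** (-model.config.decay_exponent)
    w *= np.where(lab[i] == lab[j], cond.f_comp, 1.0)
    w *= np.where((tad_id[i] == tad_id[j]) & (tad_id[i] >= 0),
                  cond.f_tad, 1.0)
    W = np.zeros((n, n))
    W[i, j] = w
    for _, lp in cond.loops[cond.loops["chrom"] == chrom].iterrows():
        W[int(lp["bin1"]), int(lp["bin2"])] *= lp["fold"]
    return W


def expected_pixel_counts(model: GenomeModel, condition: str,
                          n_pairs: int) -> dict[str, np.ndarray]:
    """Closed-form expected count of every pixel for an n-pair simulation."""
    weights = {c: pixel_weights(model, condition, c)
               for c in model.genome.chrom_names}
    total = sum(w.sum() for w in weights.values())
    return {c: n_pairs * w / total for c, w in weights.items()}


def simulate_contacts(model: GenomeModel, condition: str, n_pairs: int,
                      seed: int) -> pd.DataFrame:
    """Sample mate-pair coordinates from the planted pixel distribution.

    Returns an extended-pairs frame with zeroed methylation columns;
    positions are uniform within each sampled bin pair.
    """
    cond = model.condition(condition)  # validates the condition name
    if n_pairs < 0:
        raise ValueError("n_pairs must be >= 0")
    if n_pairs == 0:
        return _empty_pairs()
    rng = np.random.default_rng(seed)
    weights = {c: pixel_weights(model, condition, c)
               for c in model.genome.chrom_names}
    total = sum(w.sum() for w in weights.values())
    chrom_share = np.array([w.sum() / total for w in weights.values()])
    n_per_chrom = rng.multinomial(n_pairs, chrom_share)
    frames = []
    for (chrom, W), n_c in zip(weights.items(), n_per_chrom):
        flat = W.ravel()
        nz = np.flatnonzero(flat)
        counts = rng.multinomial(n_c, flat[nz] / flat[nz].sum())
        used = counts > 0
        idx = np.repeat(nz[used], counts[used])
        n = W.shape[0]
        b1, b2 = idx // n, idx % n
        # leave room for the mate footprint so reads stay inside the bin
        span = model.binsize - model.config.mate_footprint
        u1 = rng.integers(0, span, size=len(idx))
        u2 = rng.integers(0, span, size=len(idx))
        frames.append(pd.DataFrame({
            "chrom1": chrom, "pos1": b1 * model.binsize + u1,
            "chrom2": chrom, "pos2": b2 * model.binsize + u2,
            "meth1": 0, "total1": 0, "meth2": 0, "total2": 0}))
    pairs = pd.concat(frames, ignore_index=True)
    return pairs[PAIR_COLUMNS]


# ---------------------------------------------------------------------------
# methylation attachment (latent-Gaussian copula)
# ---------------------------------------------------------------------------

def _local_surface_mean(cpgs: np.ndarray, surface: np.ndarray,
                        lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    cum = np.concatenate([[0.0], np.cumsum(surface)])
    k = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(k > 0, (cum[hi] - cum[lo]) / np.maximum(k, 1), np.nan)


def attach_methylation(pairs: pd.DataFrame, model: GenomeModel,
                       condition: str, seed: int) -> pd.DataFrame:
    """Fill mate methylation counts via the latent-Gaussian copula.

    For each pair a bivariate standard normal (z1, z2) with correlation
    rho is drawn; mate i's methylation probability is
    Phi(sqrt(1 + sigma^2) * Phi^-1(m_i) + sigma * z_i) where m_i is the
    mean planted surface level under the mate footprint, so the marginal
    mean equals m_i exactly.  Counts are Binomial(total_i, p_i) with
    total_i the CpGs under the footprint (kept at 0/0 when none).

    rho may decay with genomic distance (``rho_decay_length``) and may be
    overridden at loop pixels (``rho_loop``).
    """
    cond = model.condition(condition)
    rng = np.random.default_rng(seed)
    out = pairs.reset_index(drop=True).copy()
    fp = model.config.mate_footprint
    sigma = model.config.latent_sigma
    scale = np.sqrt(1.0 + sigma ** 2)
    meth = {s: np.zeros(len(out), dtype=np.int64) for s in ("1", "2")}
    total = {s: np.zeros(len(out), dtype=np.int64) for s in ("1", "2")}
    m_level = {s: np.full(len(out), 0.5) for s in ("1", "2")}

    for chrom, sub in out.groupby("chrom1", observed=True):
        cpgs = model.genome.cpgs(chrom)
        surf = cond.methylation_surface[chrom]
        for s, poscol in (("1", "pos1"), ("2", "pos2")):
            pos = sub[poscol].to_numpy()
            lo = np.searchsorted(cpgs, pos)
            hi = np.searchsorted(cpgs, pos + fp)
            total[s][sub.index] = hi - lo
            m = _local_surface_mean(cpgs, surf, lo, hi)
            m_level[s][sub.index] = np.where(np.isfinite(m), m, 0.5)

    # per-pair correlation
    rho = np.full(len(out), cond.concordance_rho)
    d = np.abs(out["pos2"].to_numpy() - out["pos1"].to_numpy())
    if cond.rho_decay_length is not None:
        rho = rho * np.exp(-d / cond.rho_decay_length)
    if cond.rho_loop is not None and len(cond.loops):
        b1 = out["pos1"].to_numpy() // model.binsize
        b2 = out["pos2"].to_numpy() // model.binsize
        key = pd.MultiIndex.from_arrays(
            [out["chrom1"], b1, b2]).isin(
            pd.MultiIndex.from_arrays([cond.loops["chrom"],
                                       cond.loops["bin1"],
                                       cond.loops["bin2"]]))
        rho = np.where(key, cond.rho_loop, rho)
    rho = np.clip(rho, -0.999, 0.999)

    e1 = rng.standard_normal(len(out))
    e2 = rng.standard_normal(len(out))
    z1 = e1
    z2 = rho * e1 + np.sqrt(1.0 - rho ** 2) * e2
    for s, z in (("1", z1), ("2", z2)):
        m = m_level[s]
        core = norm.cdf(scale * norm.ppf(np.clip(m, 1e-6, 1 - 1e-6))
                        + sigma * z)
        p = np.where(m >= 1.0, 1.0, np.where(m <= 0.0, 0.0, core))
        meth[s] = rng.binomial(total[s], p)
    out["meth1"], out["total1"] = meth["1"], total["1"]
    out["meth2"], out["total2"] = meth["2"], total["2"]
    return out


def simulate_methylation_tracks(model: GenomeModel, condition: str,
                                mean_coverage: float,
                                seed: int) -> MethylationTrack:
    """Direct per-CpG count track: total ~ Poisson(coverage), meth ~ Binom."""
    cond = model.condition(condition)
    rng = np.random.default_rng(seed)
    frames = []
    for chrom in model.genome.chrom_names:
        pos = model.genome.cpgs(chrom)
        tot = rng.poisson(mean_coverage, size=len(pos))
        m = rng.binomial(tot, cond.methylation_surface[chrom])
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos,
                                    "meth": m, "total": tot}))
    return MethylationTrack(data=pd.concat(frames, ignore_index=True))


def loop_truth_frame(model: GenomeModel, condition: str) -> pd.DataFrame:
    """Planted loops as a BEDPE-style frame at the model bin size."""
    cond = model.condition(condition)
    lp = cond.loops
    return pd.DataFrame({
        "chrom1": lp["chrom"], "start1": lp["bin1"] * model.binsize,
        "end1": (lp["bin1"] + 1) * model.binsize,
        "chrom2": lp["chrom"], "start2": lp["bin2"] * model.binsize,
        "end2": (lp["bin2"] + 1) * model.binsize,
        "bin1": lp["bin1"], "bin2": lp["bin2"],
        "distance": (lp["bin2"] - lp["bin1"]) * model.binsize,
    })


def boundary_truth(model: GenomeModel, chrom: str) -> np.ndarray:
    """Internal TAD boundary bin edges for one chromosome."""
    sub = model.tads[model.tads["chrom"] == chrom]
    edges = sorted(set(sub["start"]) | set(sub["end"]))
    n_bins = model.genome.n_bins(chrom, model.binsize)
    return np.array([e // model.binsize for e in edges
                     if 0 < e // model.binsize < n_bins])
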