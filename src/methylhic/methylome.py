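"""Methylation tracks, DMR calling, CGI forest/prairie domains, profiles.

Per-CpG methylation is accumulated from the mate-level counts carried by
extended pairs: each mate's (meth, total) is attributed uniformly to the
CpGs under its footprint.  CpGs below the coverage floor (10 reads by
default) are masked.

DMRs are called with a fully specified smoothing + two-proportion +
Stouffer procedure and gated by the standard published thresholds: at
least 5 CpGs, absolute methylation difference above 0.20, region p below
0.01.

CGI forests (CGI-rich domains) are maximal runs of CpG islands separated
by gaps below a threshold; prairies are the complement.  Forests
correspond to compartment A, prairies to B.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomeSpec
from .loops import welch_t

logger = logging.getLogger("methylhic")

DEFAULT_COVERAGE_FLOOR = 10
DMR_MIN_CPGS = 5
DMR_MIN_DIFF = 0.20
DMR_P_MAX = 0.01


@dataclass
class MethylationTrack:
    """Per-CpG methylated/total counts with a coverage floor for levels."""

    data: pd.DataFrame  # chrom, pos, meth, total
    coverage_floor: int = DEFAULT_COVERAGE_FLOOR

    def levels(self) -> pd.DataFrame:
        """CpGs meeting the coverage floor, with level beta = meth/total."""
        ok = self.data["total"] >= self.coverage_floor
        out = self.data.loc[ok].copy()
        out["beta"] = out["meth"] / out["total"]
        return out

    def binned(self, genome: GenomeSpec, binsize: int) -> pd.DataFrame:
        """Per-bin weighted mean level sum(meth)/sum(total) and CpG count."""
        lv = self.levels()
        frames = []
        for chrom in genome.chrom_names:
            n = genome.n_bins(chrom, binsize)
            sub = lv[lv["chrom"] == chrom]
            meth = np.zeros(n)
            total = np.zeros(n)
            cnt = np.zeros(n, dtype=int)
            if len(sub):
                b = (sub["pos"].to_numpy() // binsize).astype(int)
                np.add.at(meth, b, sub["meth"].to_numpy(dtype=float))
                np.add.at(total, b, sub["total"].to_numpy(dtype=float))
                np.add.at(cnt, b, 1)
            with np.errstate(invalid="ignore", divide="ignore"):
                beta = np.where(total > 0, meth / total, np.nan)
            frames.append(pd.DataFrame({
                "chrom": chrom, "bin": np.arange(n),
                "start": np.arange(n) * binsize, "beta": beta,
                "n_cpgs": cnt, "total": total}))
        return pd.concat(frames, ignore_index=True)


def methylation_from_pairs(pairs: pd.DataFrame, genome: GenomeSpec,
                           coverage_floor: int = DEFAULT_COVERAGE_FLOOR,
                           footprint: int = 100) -> MethylationTrack:
    """Accumulate mate-level counts into a per-CpG methylation track.

    Each mate's counts are distributed uniformly over the CpGs under its
    ``footprint``; accumulation is fractional, so a mate covering k CpGs
    contributes total/k (and meth/k) to each.
    """
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in genome.chrom_names:
        cpgs = genome.cpgs(chrom)
        per_chrom[chrom] = (np.zeros(len(cpgs)), np.zeros(len(cpgs)))
    for side in ("1", "2"):
        cols = pairs[[f"chrom{side}", f"pos{side}", f"meth{side}",
                      f"total{side}"]]
        cols.columns = ["chrom", "pos", "meth", "total"]
        for chrom, sub in cols.groupby("chrom", observed=True):
            if chrom not in per_chrom:
                raise ValueError(f"unknown chromosome {chrom!r}")
            cpgs = genome.cpgs(chrom)
            pos = sub["pos"].to_numpy()
            if (pos < 0).any() or (pos + footprint > genome.chrom_lengths[chrom]).any():
                raise ValueError(f"mate footprint outside {chrom!r}")
            lo = np.searchsorted(cpgs, pos, side="left")
            hi = np.searchsorted(cpgs, pos + footprint, side="left")
            k = hi - lo
            use = k > 0
            meth_w = sub["meth"].to_numpy(dtype=float)[use] / k[use]
            tot_w = sub["total"].to_numpy(dtype=float)[use] / k[use]
            idx = np.concatenate([np.arange(a, b)
                                  for a, b in zip(lo[use], hi[use])]) \
                if use.any() else np.empty(0, dtype=int)
            reps = k[use]
            macc, tacc = per_chrom[chrom]
            np.add.at(macc, idx, np.repeat(meth_w, reps))
            np.add.at(tacc, idx, np.repeat(tot_w, reps))
    frames = []
    for chrom in genome.chrom_names:
        macc, tacc = per_chrom[chrom]
        frames.append(pd.DataFrame({"chrom": chrom,
                                    "pos": genome.cpgs(chrom),
                                    "meth": macc, "total": tacc}))
    data = pd.concat(frames, ignore_index=True)
    return MethylationTrack(data=data, coverage_floor=coverage_floor)


# ---------------------------------------------------------------------------
# DMR calling
# ---------------------------------------------------------------------------

def _smooth_counts(pos: np.ndarray, meth: np.ndarray, total: np.ndarray,
                   window_bp: int) -> tuple[np.ndarray, np.ndarray]:
    """Windowed (pos +/- window_bp/2) sums of meth and total per CpG."""
    half = window_bp // 2
    cm = np.concatenate([[0.0], np.cumsum(meth)])
    ct = np.concatenate([[0.0], np.cumsum(total)])
    lo = np.searchsorted(pos, pos - half, side="left")
    hi = np.searchsorted(pos, pos + half, side="right")
    return cm[hi] - cm[lo], ct[hi] - ct[lo]


def _two_proportion_z(m1, t1, m2, t2) -> np.ndarray:
    """Signed z for H0 p1 = p2 (direction: condition2 minus condition1)."""
    p1 = m1 / t1
    p2 = m2 / t2
    pp = (m1 + m2) / (t1 + t2)
    se = np.sqrt(pp * (1 - pp) * (1 / t1 + 1 / t2))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (p2 - p1) / se
    return np.where(se > 0, z, 0.0)


def call_dmrs(track_wt: MethylationTrack, track_tko: MethylationTrack,
              min_cpgs: int = DMR_MIN_CPGS, min_diff: float = DMR_MIN_DIFF,
              p_max: float = DMR_P_MAX, smooth_bp: int = 1000,
              per_cpg_p: float = 0.001) -> pd.DataFrame:
    """Differentially methylated regions between two conditions.

    Candidate regions are maximal runs of consecutive CpGs whose smoothed
    (``smooth_bp`` window) level difference keeps one sign and whose per-CpG
    two-proportion z-test — computed on the windowed count sums, so that
    single noisy CpGs do not fragment a region — gives p < ``per_cpg_p``.
    A region is reported iff it covers at least ``min_cpgs`` CpGs, its
    pooled absolute difference (from raw counts) exceeds ``min_diff``, and
    the Stouffer-combined region p is below ``p_max``.  Because adjacent
    windowed z's share reads, the Stouffer denominator uses an effective
    count n/m rather than n, where m is the mean window/raw read-count
    ratio over the region (a Satterthwaite-style overlap correction).
    Direction is hyper when TKO is above WT.
    """
    merged = track_wt.data.merge(track_tko.data, on=["chrom", "pos"],
                                 suffixes=("_wt", "_tko"))
    merged = merged[(merged["total_wt"] > 0) & (merged["total_tko"] > 0)]
    if merged.empty:
        raise ValueError("no CpGs shared between conditions")
    out = []
    for chrom, sub in merged.groupby("chrom", observed=True):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        m_wt, t_wt = sub["meth_wt"].to_numpy(), sub["total_wt"].to_numpy()
        m_tko, t_tko = sub["meth_tko"].to_numpy(), sub["total_tko"].to_numpy()
        sm_wt_m, sm_wt_t = _smooth_counts(pos, m_wt, t_wt, smooth_bp)
        sm_tko_m, sm_tko_t = _smooth_counts(pos, m_tko, t_tko, smooth_bp)
        sm_diff = sm_tko_m / sm_tko_t - sm_wt_m / sm_wt_t
        z = _two_proportion_z(sm_wt_m, sm_wt_t, sm_tko_m, sm_tko_t)
        p = 2 * stats.norm.sf(np.abs(z))
        candidate = (p < per_cpg_p) & (np.sign(sm_diff) != 0)
        sign = np.sign(sm_diff)
        # maximal runs of candidate CpGs with constant smoothed-diff sign
        i = 0
        n = len(pos)
        while i < n:
            if not candidate[i]:
                i += 1
                continue
            j = i
            while (j + 1 < n and candidate[j + 1]
                   and sign[j + 1] == sign[i]):
                j += 1
            run = slice(i, j + 1)
            n_cpgs = j - i + 1
            if n_cpgs >= min_cpgs:
                beta_wt = m_wt[run].sum() / t_wt[run].sum()
                beta_tko = m_tko[run].sum() / t_tko[run].sum()
                diff = beta_tko - beta_wt
                m_overlap = max(1.0, float(np.mean(
                    (sm_wt_t[run] + sm_tko_t[run])
                    / (t_wt[run] + t_tko[run]))))
                z_comb = z[run].sum() / np.sqrt(n_cpgs * m_overlap)
                p_region = 2 * stats.norm.sf(abs(z_comb))
                if abs(diff) > min_diff and p_region < p_max:
                    out.append({
                        "chrom": chrom, "start": int(pos[i]),
                        "end": int(pos[j]) + 1, "n_cpgs": n_cpgs,
                        "beta_wt": float(beta_wt),
                        "beta_tko": float(beta_tko), "diff": float(diff),
                        "p": float(p_region),
                        "direction": "hyper" if diff > 0 else "hypo"})
            i = j + 1
    return pd.DataFrame(out, columns=["chrom", "start", "end", "n_cpgs",
                                      "beta_wt", "beta_tko", "diff", "p",
                                      "direction"])


# ---------------------------------------------------------------------------
# CGI forest / prairie domains
# ---------------------------------------------------------------------------

def cgi_domains(genome: GenomeSpec, cgi_set: pd.DataFrame,
                gap_threshold: int = 50_000) -> pd.DataFrame:
    """Segment each chromosome into CGI forests and prairies.

    Forests are maximal CGI runs with inter-CGI gaps below
    ``gap_threshold``, spanning from the first to the last CGI of the run;
    prairies tile the remainder, so forest and prairie together cover the
    chromosome exactly.  Per-domain CpG density is reported as the mean
    CpG count over 1-kb non-overlapping windows (CpGs per kb).
    """
    rows = []
    for chrom in genome.chrom_names:
        length = genome.chrom_lengths[chrom]
        sub = cgi_set[cgi_set["chrom"] == chrom].sort_values("start")
        forests = []
        if sub.empty:
            logger.warning("no CGIs on %s: whole chromosome is prairie", chrom)
        else:
            cur = [int(sub.iloc[0]["start"]), int(sub.iloc[0]["end"])]
            for _, cgi in sub.iloc[1:].iterrows():
                if cgi["start"] - cur[1] < gap_threshold:
                    cur[1] = max(cur[1], int(cgi["end"]))
                else:
                    forests.append(tuple(cur))
                    cur = [int(cgi["start"]), int(cgi["end"])]
            forests.append(tuple(cur))
        prev = 0
        for fs, fe in forests:
            if fs > prev:
                rows.append((chrom, prev, fs, "prairie"))
            rows.append((chrom, fs, fe, "forest"))
            prev = fe
        if prev < length:
            rows.append((chrom, prev, length, "prairie"))
    domains = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    densities = []
    for _, d in domains.iterrows():
        cpgs = genome.cpgs(d["chrom"])
        count = np.searchsorted(cpgs, d["end"]) - np.searchsorted(cpgs, d["start"])
        n_windows = max(1, (d["end"] - d["start"]) // 1000)
        densities.append(count / n_windows)
    domains["cpg_density"] = densities
    return domains


def domain_mean_levels(domains: pd.DataFrame,
                       track: MethylationTrack) -> np.ndarray:
    """Coverage-weighted mean level per domain (NaN if uncovered)."""
    lv = track.levels()
    out = np.full(len(domains), np.nan)
    for k, (_, d) in enumerate(domains.iterrows()):
        sub = lv[(lv["chrom"] == d["chrom"]) & (lv["pos"] >= d["start"])
                 & (lv["pos"] < d["end"])]
        if sub["total"].sum() > 0:
            out[k] = sub["meth"].sum() / sub["total"].sum()
    return out


def domain_methylation_difference(domains: pd.DataFrame,
                                  track_wt: MethylationTrack,
                                  track_tko: MethylationTrack) -> dict:
    """Forest vs prairie methylation change between conditions.

    Reports per-domain delta beta (TKO - WT), class means, the Welch test
    between forest and prairie deltas, and the prairie-minus-forest level
    gap in each condition.  The gap pools CpG counts over all domains of a
    class (coverage-weighted), so tiny sliver domains do not distort it.
    """
    beta_wt = domain_mean_levels(domains, track_wt)
    beta_tko = domain_mean_levels(domains, track_tko)
    ok = np.isfinite(beta_wt) & np.isfinite(beta_tko)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("%d domains without covered CpGs excluded", n_dropped)
    table = domains.loc[ok].copy()
    table["beta_wt"] = beta_wt[ok]
    table["beta_tko"] = beta_tko[ok]
    table["delta"] = table["beta_tko"] - table["beta_wt"]
    forest = table[table["label"] == "forest"]
    prairie = table[table["label"] == "prairie"]
    if len(forest) >= 2 and len(prairie) >= 2:
        t, df, p = welch_t(forest["delta"], prairie["delta"])
    else:
        t = df = p = np.nan
    gaps = {}
    for cond, tr in (("wt", track_wt), ("tko", track_tko)):
        pooled = {}
        for label, sub in (("forest", forest), ("prairie", prairie)):
            lv = tr.levels()
            meth = tot = 0.0
            for _, d in sub.iterrows():
                sel = lv[(lv["chrom"] == d["chrom"])
                         & (lv["pos"] >= d["start"])
                         & (lv["pos"] < d["end"])]
                meth += sel["meth"].sum()
                tot += sel["total"].sum()
            pooled[label] = meth / tot if tot else np.nan
        gaps[cond] = float(pooled["prairie"] - pooled["forest"])
    return {"table": table,
            "mean_delta_forest": float(forest["delta"].mean()),
            "mean_delta_prairie": float(prairie["delta"].mean()),
            "welch": {"t": t, "df": df, "p": p},
            "gap": gaps}


# ---------------------------------------------------------------------------
# profiles and enrichment
# ---------------------------------------------------------------------------

def _stepwise_mean(starts, ends, values, a: float, b: float) -> float:
    """Mean of a stepwise bedGraph signal over [a, b); uncovered bp count 0."""
    lo = np.searchsorted(ends, a, side="right")
    hi = np.searchsorted(starts, b, side="left")
    if hi <= lo or b <= a:
        return 0.0
    s = starts[lo:hi].copy()
    e = ends[lo:hi].copy()
    v = values[lo:hi]
    np.clip(s, a, b, out=s)
    np.clip(e, a, b, out=e)
    return float(np.sum((e - s) * v) / (b - a))


def profile_matrix(signal: pd.DataFrame, references: pd.DataFrame,
                   flank: int, n_bins: int,
                   genome: GenomeSpec | None = None) -> dict:
    """Aggregate a bedGraph signal around reference points.

    Each reference row contributes one profile row of ``n_bins`` columns
    spanning center +/- ``flank``; minus-strand references are flipped.
    Rows whose window leaves the chromosome are masked.  Returns the
    per-column mean, standard error, and the full matrix.
    """
    mat = np.full((len(references), n_bins), np.nan)
    width = 2 * flank / n_bins
    by_chrom = {c: s.sort_values("start")
                for c, s in signal.groupby("chrom", observed=True)}
    for r, (_, ref) in enumerate(references.iterrows()):
        if "pos" in ref:
            center = float(ref["pos"])
        else:
            center = (ref["start"] + ref["end"]) / 2
        chrom = ref["chrom"]
        if genome is not None:
            length = genome.chrom_lengths.get(chrom, np.inf)
            if center - flank < 0 or center + flank > length:
                continue
        sub = by_chrom.get(chrom)
        if sub is None:
            row = np.zeros(n_bins)
        else:
            starts = sub["start"].to_numpy(dtype=float)
            ends = sub["end"].to_numpy(dtype=float)
            vals = sub["value"].to_numpy(dtype=float)
            row = np.array([_stepwise_mean(starts, ends, vals,
                                           center - flank + k * width,
                                           center - flank + (k + 1) * width)
                            for k in range(n_bins)])
        if ref.get("strand", "+") == "-":
            row = row[::-1]
        mat[r] = row
    ok = np.isfinite(mat).all(axis=1)
    used = mat[ok]
    mean = used.mean(axis=0) if len(used) else np.full(n_bins, np.nan)
    se = (used.std(axis=0, ddof=1) / np.sqrt(len(used))
          if len(used) > 1 else np.zeros(n_bins))
    return {"mean": mean, "se": se, "matrix": mat, "n_used": int(ok.sum())}


def interval_enrichment(query: pd.DataFrame, target: pd.DataFrame,
                        genome: GenomeSpec, n_shuffles: int,
                        seed: int) -> dict:
    """Overlap enrichment of query in target vs shuffled placements.

    The null preserves each query interval's chromosome and length and
    redraws its start uniformly; z is (observed - null mean)/null sd and
    the empirical p carries the +1 correction.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    tgt = {c: s[["start", "end"]].sort_values("start").to_numpy()
           for c, s in target.groupby("chrom", observed=True)}

    def count(starts_by_row: np.ndarray) -> int:
        hits = 0
        for (chrom, length), start in zip(meta, starts_by_row):
            t = tgt.get(chrom)
            if t is None:
                continue
            end = start + length
            if ((t[:, 0] < end) & (t[:, 1] > start)).any():
                hits += 1
        return hits

    meta = []
    for _, q in query.iterrows():
        length = int(q["end"] - q["start"])
        if length > genome.chrom_lengths[q["chrom"]]:
            raise ValueError("query interval longer than its chromosome")
        meta.append((q["chrom"], length))
    obs = count(query["start"].to_numpy())
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        starts = np.array([rng.integers(0, genome.chrom_lengths[c] - ln + 1)
                           for c, ln in meta])
        null[s] = count(starts)
    sd = null.std()
    z = (obs - null.mean()) / sd if sd > 0 else np.inf
    p = (1 + np.sum(null >= obs)) / (n_shuffles + 1)
    return {"observed": obs, "null_mean": float(null.mean()),
            "null_sd": float(sd), "z": float(z), "p": float(p)}


def gene_body_methylation(genes: pd.DataFrame, track_wt: MethylationTrack,
                          track_tko: MethylationTrack,
                          gene_subset: list[str], n_random: int,
                          seed: int) -> dict:
    """Gene-body methylation change of a gene subset vs random gene draws.

    Per-gene delta beta is the coverage-weighted body-level difference
    (TKO - WT); the subset mean is compared with ``n_random`` same-size
    random draws and with a Welch test against the pooled random genes.
    """
    if "name" not in genes.columns:
        raise ValueError("gene intervals need a 'name' column")
    names = genes["name"].tolist()
    missing = [g for g in gene_subset if g not in names]
    if missing:
        raise ValueError(f"subset genes absent from gene set: {missing[:5]}")
    beta_wt = domain_mean_levels(genes, track_wt)
    beta_tko = domain_mean_levels(genes, track_tko)
    delta = beta_tko - beta_wt
    table = genes.copy()
    table["delta"] = delta
    ok = np.isfinite(delta)
    sub_mask = genes["name"].isin(gene_subset).to_numpy() & ok
    subset_mean = float(delta[sub_mask].mean())
    rng = np.random.default_rng(seed)
    pool = np.flatnonzero(ok & ~genes["name"].isin(gene_subset).to_numpy())
    k = int(sub_mask.sum())
    draws = np.array([delta[rng.choice(pool, size=k, replace=False)].mean()
                      for _ in range(n_random)])
    t, df, p = welch_t(delta[sub_mask], delta[pool])
    return {"table": table, "subset_mean": subset_mean,
            "random_means": draws,
            "frac_random_below": float(np.mean(draws < subset_mean)),
            "welch": {"t": t, "df": df, "p": p}}


def cpg_density_per_bin(genome: GenomeSpec, binsize: int) -> dict[str, np.ndarray]:
    """CpG count per bin for every chromosome (eigenvector orientation)."""
    out = {}
    for chrom in genome.chrom_names:
        n = genome.n_bins(chrom, binsize)
        cpgs = genome.cpgs(chrom)
        counts = np.zeros(n)
        if len(cpgs):
            np.add.at(counts, cpgs // binsize, 1.0)
        out[chrom] = counts
    return out
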