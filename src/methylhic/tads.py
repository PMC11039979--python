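"""Insulation-based TAD calling and TAD-level statistics.

Boundary detection follows the multi-window insulation ("TAD separation
score") approach: for each bin edge and each diamond window size between
``min_depth`` and ``max_depth`` (200-500 kb by default, 50 kb steps), the
mean balanced contact value crossing the edge is recorded; per-window
tracks are z-scored per chromosome and averaged into a combined score.
Candidate boundaries are local minima of the combined score, tested by a
one-sided rank-sum comparison of flanking (intra-domain) diamond values
against the boundary's own diamond values across window sizes, and kept at
p below ``p_threshold`` with sufficient prominence.  TADs tile the
chromosome between consecutive kept boundaries.

Also here: TAD overlap under the reciprocal >60% rule, intra- vs inter-TAD
interaction means, aggregate TAD analysis (ATA), and the four-way
(hyper/hypo methylation x compartment A/B) boundary classification.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats

from .compartments import EigenvectorTrack
from .contact_matrix import ContactMatrix

logger = logging.getLogger("methylhic")

DEFAULT_MIN_DEPTH = 200_000
DEFAULT_MAX_DEPTH = 500_000
DEFAULT_STEP = 50_000
DEFAULT_P_THRESHOLD = 0.05
DEFAULT_DELTA_MIN = 0.05


@dataclass
class InsulationTrack:
    chrom: str
    binsize: int
    windows: np.ndarray        # window sizes in bins
    per_window: np.ndarray     # (n_windows, n_edges) raw diamond means
    combined: np.ndarray       # mean of z-scored per-window tracks

    @property
    def n_edges(self) -> int:
        return self.per_window.shape[1]


@dataclass
class TADSet:
    tads: pd.DataFrame         # chrom, start, end
    boundaries: pd.DataFrame   # chrom, pos, bin_edge, score, p


def diamond_score(values: np.ndarray, edge: int, w: int) -> float:
    """Mean over the w x w diamond crossing bin edge ``edge``.

    The diamond is the cell set {(a, b): edge-w <= a < edge <= b < edge+w};
    NaN (masked) cells are excluded; NaN if the window leaves the matrix or
    no cell is usable.
    """
    n = values.shape[0]
    if edge - w < 0 or edge + w > n:
        return np.nan
    block = values[edge - w:edge, edge:edge + w]
    ok = np.isfinite(block)
    if not ok.any():
        return np.nan
    return float(block[ok].mean())


def insulation_scores(matrix: ContactMatrix,
                      min_depth: int = DEFAULT_MIN_DEPTH,
                      max_depth: int = DEFAULT_MAX_DEPTH,
                      step: int = DEFAULT_STEP) -> InsulationTrack:
    if matrix.state not in ("balanced", "raw"):
        raise ValueError("insulation expects a balanced (or raw) matrix")
    if max_depth < min_depth:
        raise ValueError("max_depth < min_depth")
    for depth in (min_depth, max_depth, step):
        if depth % matrix.binsize:
            raise ValueError("depths must be multiples of the bin size")
    windows = np.arange(min_depth // matrix.binsize,
                        max_depth // matrix.binsize + 1,
                        step // matrix.binsize)
    n = matrix.n_bins
    edges = np.arange(n + 1)
    per_window = np.full((len(windows), len(edges)), np.nan)
    for wi, w in enumerate(windows):
        for e in range(w, n - w + 1):
            per_window[wi, e] = diamond_score(matrix.values, e, int(w))
    z = np.full_like(per_window, np.nan)
    for wi in range(len(windows)):
        row = per_window[wi]
        ok = np.isfinite(row)
        if ok.any():
            sd = row[ok].std()
            z[wi, ok] = 0.0 if sd == 0 else (row[ok] - row[ok].mean()) / sd
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        combined = np.nanmean(z, axis=0)
    return InsulationTrack(chrom=matrix.chrom, binsize=matrix.binsize,
                           windows=windows, per_window=per_window,
                           combined=combined)


def call_boundaries(ins: InsulationTrack,
                    p_threshold: float = DEFAULT_P_THRESHOLD,
                    delta_min: float = DEFAULT_DELTA_MIN,
                    chrom_length: int | None = None) -> TADSet:
    """Boundaries = significant prominent local minima of the combined score."""
    comb = ins.combined
    n_bins = ins.n_edges - 1
    length = chrom_length if chrom_length is not None else n_bins * ins.binsize
    max_w = int(ins.windows.max())
    if n_bins < 2 * max_w:
        logger.warning("%s shorter than twice the max window; no boundaries",
                       ins.chrom)
        return TADSet(tads=pd.DataFrame(columns=["chrom", "start", "end"]),
                      boundaries=pd.DataFrame(
                          columns=["chrom", "pos", "bin_edge", "score", "p"]))
    filled = np.where(np.isfinite(comb), comb, np.inf)
    candidates, props = signal.find_peaks(-filled, prominence=delta_min)
    neg = np.where(np.isfinite(comb), comb, -np.inf)
    maxima, _ = signal.find_peaks(neg)
    kept = []
    for e, prom in zip(candidates, props["prominences"]):
        # flanks = nearest insulation maxima (intra-domain positions);
        # diamonds there sit inside the adjacent domains
        left = maxima[maxima < e]
        right = maxima[maxima > e]
        flank_pos = [left[-1] if len(left) else max(0, e - 2),
                     right[0] if len(right) else min(ins.n_edges - 1, e + 2)]
        boundary_vals, flank_vals = [], []
        for wi, w in enumerate(ins.windows):
            v = ins.per_window[wi, e]
            if np.isfinite(v):
                boundary_vals.append(v)
            for f in flank_pos:
                if np.isfinite(ins.per_window[wi, f]):
                    flank_vals.append(ins.per_window[wi, f])
        if len(boundary_vals) < 2 or len(flank_vals) < 2:
            continue
        p = stats.mannwhitneyu(flank_vals, boundary_vals,
                               alternative="greater").pvalue
        if p < p_threshold:
            kept.append((int(e), float(comb[e]), float(p), float(prom)))
    # enforce a minimum 2-bin TAD width: of edges closer than 2 bins keep the
    # deeper minimum
    kept.sort()
    pruned: list[tuple] = []
    for item in kept:
        if pruned and item[0] - pruned[-1][0] < 2:
            if item[1] < pruned[-1][1]:
                pruned[-1] = item
        else:
            pruned.append(item)
    boundaries = pd.DataFrame(pruned, columns=["bin_edge", "score", "p",
                                               "prominence"])
    boundaries.insert(0, "chrom", ins.chrom)
    boundaries.insert(1, "pos", boundaries["bin_edge"] * ins.binsize)
    edges = [0] + list(boundaries["bin_edge"]) + [n_bins]
    tads = pd.DataFrame({
        "chrom": ins.chrom,
        "start": [e * ins.binsize for e in edges[:-1]],
        "end": [min(e * ins.binsize, length) for e in edges[1:]],
    })
    tads = tads[(tads["end"] - tads["start"]) >= 2 * ins.binsize]
    return TADSet(tads=tads.reset_index(drop=True), boundaries=boundaries)


def tad_overlap(tads_a: pd.DataFrame, tads_b: pd.DataFrame,
                min_frac: float = 0.6) -> dict:
    """Reciprocal-overlap matching: |a n b| must exceed ``min_frac`` of both."""
    matches = []
    for chrom, sub_a in tads_a.groupby("chrom", observed=True):
        sub_b = tads_b[tads_b["chrom"] == chrom]
        for ia, a in sub_a.iterrows():
            for ib, b in sub_b.iterrows():
                inter = min(a["end"], b["end"]) - max(a["start"], b["start"])
                if inter <= 0:
                    continue
                fa = inter / (a["end"] - a["start"])
                fb = inter / (b["end"] - b["start"])
                if fa > min_frac and fb > min_frac:
                    matches.append((ia, ib))
    matched_a = {m[0] for m in matches}
    matched_b = {m[1] for m in matches}
    return {
        "matches": matches,
        "n_a": len(tads_a), "n_b": len(tads_b),
        "matched_a": len(matched_a), "matched_b": len(matched_b),
        "unmatched_a": len(tads_a) - len(matched_a),
        "unmatched_b": len(tads_b) - len(matched_b),
    }


def intra_inter_tad(matrix: ContactMatrix, tads: pd.DataFrame) -> dict:
    """Mean contact within each TAD square and between adjacent TAD pairs."""
    sub = tads[tads["chrom"] == matrix.chrom].sort_values("start")
    spans = []
    for _, t in sub.iterrows():
        b0, b1 = int(t["start"] // matrix.binsize), int(-(-t["end"] // matrix.binsize))
        if b1 > matrix.n_bins or b0 < 0:
            raise ValueError("TAD outside matrix")
        spans.append((b0, b1))
    intra = []
    for b0, b1 in spans:
        block = matrix.values[b0:b1, b0:b1]
        intra.append(float(np.nanmean(block)) if np.isfinite(block).any()
                     else np.nan)
    inter = []
    for (a0, a1), (b0, b1) in zip(spans[:-1], spans[1:]):
        rect = matrix.values[a0:a1, b0:b1]
        inter.append(float(np.nanmean(rect)) if np.isfinite(rect).any()
                     else np.nan)
    return {
        "intra": np.array(intra), "inter": np.array(inter),
        "mean_intra": float(np.nanmean(intra)) if intra else np.nan,
        "mean_inter": float(np.nanmean(inter)) if inter else np.nan,
    }


def _rescale(block: np.ndarray, out_size: int) -> np.ndarray:
    """Bilinear resample of a square block to out_size x out_size."""
    m = block.shape[0]
    coords = np.linspace(0, m - 1, out_size)
    return ndimage.map_coordinates(block,
                                   np.meshgrid(coords, coords, indexing="ij"),
                                   order=1, mode="nearest")


def aggregate_tads(oe_matrices: dict[str, ContactMatrix], tads: pd.DataFrame,
                   out_size: int = 30, min_bins: int = 4) -> dict:
    """Aggregate TAD analysis: mean O/E over rescaled TADs with 50% flanks.

    Returns the mean rescaled matrix and the center/flank enrichment ratio
    (central half square vs the two distal diagonal corner squares).
    """
    stack = []
    for _, t in tads.iterrows():
        mat = oe_matrices.get(t["chrom"])
        if mat is None:
            continue
        b0 = int(t["start"] // mat.binsize)
        b1 = int(-(-t["end"] // mat.binsize))
        size = b1 - b0
        if size < min_bins:
            continue
        flank = size // 2
        lo, hi = b0 - flank, b1 + flank
        if lo < 0 or hi > mat.n_bins:
            continue
        if not mat.mask[lo:hi].all():
            continue  # window touches a masked bin
        window = mat.values[lo:hi, lo:hi]
        # isolated data-free cells (e.g. the empty O/E diagonal) are
        # neutral on the O/E scale
        window = np.where(np.isfinite(window), window, 1.0)
        stack.append(_rescale(window, out_size))
    if not stack:
        raise ValueError("no eligible TADs for aggregation")
    mean_mat = np.mean(stack, axis=0)
    q = out_size // 4
    center = mean_mat[q:out_size - q, q:out_size - q].mean()
    flank = 0.5 * (mean_mat[:q, :q].mean() + mean_mat[-q:, -q:].mean())
    return {"matrix": mean_mat, "n_tads": len(stack),
            "center_mean": float(center), "flank_mean": float(flank),
            "ratio": float(center / flank)}


def classify_boundaries(boundaries: pd.DataFrame,
                        methylation_diff: np.ndarray,
                        ev: EigenvectorTrack,
                        flank_bins: int = 2,
                        binsize: int | None = None) -> pd.DataFrame:
    """Four-way boundary classes: hyper/hypo methylation x compartment A/B.

    ``methylation_diff`` is a per-bin (TKO - WT) methylation change at the
    boundary bin size; the boundary is hyper if the mean change over
    +/-``flank_bins`` bins is positive.  Compartment comes from the sign of
    the eigenvector at the (coarser) compartment bin containing the
    boundary.  Boundaries in masked eigenvector bins are dropped.
    """
    if binsize is None:
        raise ValueError("binsize of the methylation_diff track is required")
    rows = []
    n_skipped = 0
    for _, b in boundaries.iterrows():
        bin_i = int(b["pos"] // binsize)
        lo, hi = max(0, bin_i - flank_bins), min(len(methylation_diff),
                                                 bin_i + flank_bins + 1)
        window = np.asarray(methylation_diff[lo:hi], dtype=float)
        window = window[np.isfinite(window)]
        comp_bin = int(b["pos"] // ev.binsize)
        if (comp_bin >= len(ev.ev) or not np.isfinite(ev.ev[comp_bin])
                or window.size == 0):
            n_skipped += 1
            continue
        meth_class = "hyper" if window.mean() > 0 else "hypo"
        compartment = "A" if ev.ev[comp_bin] > 0 else "B"
        rows.append({"chrom": b["chrom"], "pos": int(b["pos"]),
                     "mean_diff": float(window.mean()),
                     "meth_class": meth_class, "compartment": compartment})
    if n_skipped:
        logger.warning("classify_boundaries: %d boundaries skipped "
                       "(masked compartment or no methylation)", n_skipped)
    return pd.DataFrame(rows, columns=["chrom", "pos", "mean_diff",
                                       "meth_class", "compartment"])


def boundary_class_counts(classified: pd.DataFrame) -> pd.DataFrame:
    """2x2 table of boundary counts: meth_class rows, compartment columns."""
    return (classified.groupby(["meth_class", "compartment"]).size()
            .unstack(fill_value=0)
            .reindex(index=["hyper", "hypo"], columns=["A", "B"],
                     fill_value=0))
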