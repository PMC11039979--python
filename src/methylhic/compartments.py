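"""A/B compartment analysis.

The compartment signal is the leading eigenvector of the Pearson
correlation matrix of the observed/expected contact map, computed per
chromosome at coarse resolution (250 kb by default).  Its sign is
arbitrary, so the track is oriented against a sequence covariate (GC
fraction or CpG density): active A compartments are GC/CpG rich, so the
eigenvector is flipped if it anti-correlates with the covariate.  Bins with
positive entries are labelled A, negative B.

Compartmentalization strength is summarised GENOVA-style from the saddle
plot: bins are ranked by eigenvector, O/E aggregated over quantile pairs,
and strength = (mean AA corner + mean BB corner) / (2 x mean AB corner)
using the outer 20% of quantiles as corners.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contact_matrix import ContactMatrix

DEFAULT_BINSIZE = 250_000


@dataclass
class EigenvectorTrack:
    chrom: str
    binsize: int
    ev: np.ndarray        # NaN where masked
    labels: np.ndarray    # 'A' | 'B' | '' (masked)

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.ev)


@dataclass
class SaddleResult:
    aggregate: np.ndarray   # n_quantiles x n_quantiles mean O/E
    strength: float
    n_quantiles: int
    corner_fraction: float


def _labels_from_ev(ev: np.ndarray) -> np.ndarray:
    labels = np.full(len(ev), "", dtype=object)
    labels[np.nan_to_num(ev) > 0] = "A"
    labels[np.nan_to_num(ev) < 0] = "B"
    labels[~np.isfinite(ev)] = ""
    return labels


def compartment_eigenvector(oe_matrix: ContactMatrix,
                            covariate: np.ndarray) -> EigenvectorTrack:
    """Leading eigenvector of the O/E correlation matrix, GC/CpG oriented.

    ``covariate`` is a per-bin orientation signal (GC fraction or CpG
    density).  Masked bins are excluded from the correlation and reported
    with NaN eigenvector entries and empty labels.
    """
    if oe_matrix.state != "oe":
        raise ValueError("compartment_eigenvector expects an O/E matrix")
    covariate = np.asarray(covariate, dtype=float)
    if len(covariate) != oe_matrix.n_bins:
        raise ValueError("covariate length does not match bin count")
    keep = oe_matrix.mask
    sub = oe_matrix.values[np.ix_(keep, keep)]
    if sub.shape[0] < 3:
        raise ValueError("too few unmasked bins")
    sd = sub.std(axis=0)
    if np.any(sd == 0) or not np.all(np.isfinite(sd)):
        raise ValueError("degenerate O/E matrix: constant column")
    corr = np.corrcoef(sub, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    lead = evecs[:, -1]

    cov_sub = covariate[keep]
    r = np.corrcoef(lead, cov_sub)[0, 1] if np.std(cov_sub) > 0 else 0.0
    if r < 0:
        lead = -lead
    elif r == 0:
        # tie-break: mean ev over the top covariate decile made positive
        top = cov_sub >= np.quantile(cov_sub, 0.9)
        if lead[top].mean() < 0:
            lead = -lead

    ev = np.full(oe_matrix.n_bins, np.nan)
    ev[keep] = lead
    return EigenvectorTrack(chrom=oe_matrix.chrom, binsize=oe_matrix.binsize,
                            ev=ev, labels=_labels_from_ev(ev))


def classify_switches(ev_wt: EigenvectorTrack,
                      ev_tko: EigenvectorTrack) -> pd.DataFrame:
    """Per-bin compartment switching categories between two conditions.

    Returns a frame with one row per bin usable in both conditions and a
    ``category`` column in {'stable A', 'stable B', 'A to B', 'B to A'}.
    """
    if (ev_wt.binsize != ev_tko.binsize
            or len(ev_wt.ev) != len(ev_tko.ev)
            or ev_wt.chrom != ev_tko.chrom):
        raise ValueError("binning mismatch between eigenvector tracks")
    ok = ev_wt.mask & ev_tko.mask
    idx = np.flatnonzero(ok)
    a_wt = ev_wt.ev[ok] > 0
    a_tko = ev_tko.ev[ok] > 0
    category = np.where(a_wt & a_tko, "stable A",
               np.where(~a_wt & ~a_tko, "stable B",
               np.where(a_wt & ~a_tko, "A to B", "B to A")))
    return pd.DataFrame({"bin": idx, "ev_wt": ev_wt.ev[ok],
                         "ev_tko": ev_tko.ev[ok], "category": category})


def switch_proportions(switches: pd.DataFrame) -> dict[str, float]:
    n = len(switches)
    counts = switches["category"].value_counts()
    return {cat: counts.get(cat, 0) / n
            for cat in ("stable A", "stable B", "A to B", "B to A")}


def saddle(oe_matrix: ContactMatrix, ev: EigenvectorTrack,
           n_quantiles: int = 20, corner_fraction: float = 0.2) -> SaddleResult:
    """Quantile-aggregated O/E saddle and compartmentalization strength."""
    if n_quantiles < 5:
        raise ValueError("n_quantiles must be >= 5")
    keep = oe_matrix.mask & ev.mask
    n_keep = int(keep.sum())
    if n_keep < n_quantiles:
        raise ValueError("fewer usable bins than quantiles")
    order = np.argsort(ev.ev[keep], kind="stable")  # ascending: B ... A
    # quantile index per ranked bin
    qidx = np.floor(np.arange(n_keep) * n_quantiles / n_keep).astype(int)
    q_of_bin = np.empty(n_keep, dtype=int)
    q_of_bin[order] = qidx
    sub = oe_matrix.values[np.ix_(keep, keep)]
    agg = np.zeros((n_quantiles, n_quantiles))
    cnt = np.zeros((n_quantiles, n_quantiles))
    finite = np.isfinite(sub)
    vals = np.where(finite, sub, 0.0)
    np.add.at(agg, (q_of_bin[:, None].repeat(n_keep, 1),
                    q_of_bin[None, :].repeat(n_keep, 0)), vals)
    np.add.at(cnt, (q_of_bin[:, None].repeat(n_keep, 1),
                    q_of_bin[None, :].repeat(n_keep, 0)), finite.astype(float))
    with np.errstate(invalid="ignore"):
        agg = agg / cnt
    k = max(1, int(round(corner_fraction * n_quantiles)))
    bb = np.nanmean(agg[:k, :k])
    aa = np.nanmean(agg[-k:, -k:])
    ab = np.nanmean(np.concatenate([agg[:k, -k:].ravel(), agg[-k:, :k].ravel()]))
    strength = (aa + bb) / (2.0 * ab)
    return SaddleResult(aggregate=agg, strength=float(strength),
                        n_quantiles=n_quantiles, corner_fraction=corner_fraction)


def ev_methylation_correlation(ev: EigenvectorTrack,
                               methylation_diff: np.ndarray,
                               min_bins: int = 3) -> dict[str, dict]:
    """Pearson r of eigenvector vs per-bin methylation change, per compartment."""
    diff = np.asarray(methylation_diff, dtype=float)
    if len(diff) != len(ev.ev):
        raise ValueError("track length mismatch")
    out: dict[str, dict] = {}
    for comp in ("A", "B"):
        sel = (ev.labels == comp) & np.isfinite(diff) & ev.mask
        n = int(sel.sum())
        if n < min_bins:
            raise ValueError(f"fewer than {min_bins} usable bins in {comp}")
        r, p = stats.pearsonr(ev.ev[sel], diff[sel])
        out[comp] = {"r": float(r), "p": float(p), "n": n}
    return out
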