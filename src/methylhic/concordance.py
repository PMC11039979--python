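"""Read-level methylation concordance across interacting mate pairs.

Each ligated Methyl-HiC pair gives two mate-level methylation fractions
(x, y) = (meth1/total1, meth2/total2).  Concordance is the Pearson
correlation of those fractions over qualifying intra-chromosomal pairs,
stratified by genomic distance and by the minimum CpG count per mate —
quantifying whether spatially proximal DNA fragments share methylation
state beyond what their genomic positions alone would give.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MIN_N = 100


@dataclass
class ConcordanceResult:
    distance_lo: float
    distance_hi: float
    min_cpg_per_mate: int
    n_pairs: int
    pcc: float          # NaN when undefined
    p: float
    defined: bool


def log_distance_bins(lo: int = 1_000, hi: int = 10_000_000,
                      n: int = 10) -> np.ndarray:
    """Default log-spaced distance bin edges (n bins, n+1 edges)."""
    return np.geomspace(lo, hi, n + 1)


def _mate_fractions(pairs: pd.DataFrame,
                    min_cpg_per_mate: int) -> pd.DataFrame:
    cis = pairs[pairs["chrom1"] == pairs["chrom2"]]
    ok = (cis["total1"] >= max(1, min_cpg_per_mate)) \
        & (cis["total2"] >= max(1, min_cpg_per_mate))
    sub = cis.loc[ok].copy()
    sub["x"] = sub["meth1"] / sub["total1"]
    sub["y"] = sub["meth2"] / sub["total2"]
    sub["distance"] = (sub["pos2"] - sub["pos1"]).abs()
    return sub


def _pcc(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan, False
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), True


def concordance_pcc(pairs: pd.DataFrame, distance_bins: np.ndarray,
                    min_cpg_per_mate: int = 3,
                    min_n: int = DEFAULT_MIN_N) -> list[ConcordanceResult]:
    """Pearson concordance of mate methylation fractions per distance bin.

    Pairs where either mate covers fewer than ``min_cpg_per_mate`` CpGs are
    excluded pairwise.  Strata with fewer than ``min_n`` pairs, or with
    zero variance in either coordinate, are reported as undefined rather
    than dropped.
    """
    distance_bins = np.asarray(distance_bins, dtype=float)
    if distance_bins.size < 2:
        raise ValueError("need at least two distance bin edges")
    sub = _mate_fractions(pairs, min_cpg_per_mate)
    out = []
    for lo, hi in zip(distance_bins[:-1], distance_bins[1:]):
        sel = sub[(sub["distance"] >= lo) & (sub["distance"] < hi)]
        n = len(sel)
        if n < min_n:
            out.append(ConcordanceResult(lo, hi, min_cpg_per_mate, n,
                                         np.nan, np.nan, False))
            continue
        r, p, defined = _pcc(sel["x"].to_numpy(), sel["y"].to_numpy())
        out.append(ConcordanceResult(lo, hi, min_cpg_per_mate, n, r, p,
                                     defined))
    return out


def global_pcc(pairs: pd.DataFrame, min_cpg_per_mate: int = 3,
               min_n: int = DEFAULT_MIN_N) -> ConcordanceResult:
    """Concordance over all qualifying cis pairs, unstratified."""
    sub = _mate_fractions(pairs, min_cpg_per_mate)
    if len(sub) < min_n:
        return ConcordanceResult(0, np.inf, min_cpg_per_mate, len(sub),
                                 np.nan, np.nan, False)
    r, p, defined = _pcc(sub["x"].to_numpy(), sub["y"].to_numpy())
    return ConcordanceResult(0, np.inf, min_cpg_per_mate, len(sub), r, p,
                             defined)


def results_frame(results: list[ConcordanceResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def concordance_profiles(pairs_wt: pd.DataFrame, pairs_tko: pd.DataFrame,
                         distance_bins: np.ndarray,
                         cpg_thresholds: list[int],
                         min_cpg_per_mate: int = 3,
                         min_n: int = DEFAULT_MIN_N) -> dict:
    """Paired concordance-vs-distance and concordance-vs-CpG curves.

    Both conditions are evaluated on identical strata; Spearman trend
    statistics over the defined strata summarise monotonicity.
    """
    by_dist = {}
    by_cpg = {}
    for name, pp in (("WT", pairs_wt), ("TKO", pairs_tko)):
        res = concordance_pcc(pp, distance_bins, min_cpg_per_mate, min_n)
        by_dist[name] = results_frame(res)
        rows = []
        for thr in cpg_thresholds:
            r = global_pcc(pp, min_cpg_per_mate=thr, min_n=min_n)
            rows.append({"min_cpg": thr, "n_pairs": r.n_pairs, "pcc": r.pcc,
                         "defined": r.defined})
        by_cpg[name] = pd.DataFrame(rows)
    trends = {}
    for name in ("WT", "TKO"):
        d = by_dist[name]
        ok = d["defined"]
        if ok.sum() >= 3:
            rho, p = stats.spearmanr(np.arange(len(d))[ok], d.loc[ok, "pcc"])
            trends[name] = {"distance_spearman": float(rho), "p": float(p)}
        else:
            trends[name] = {"distance_spearman": np.nan, "p": np.nan}
    return {"by_distance": by_dist, "by_cpg_threshold": by_cpg,
            "trend": trends}


def concordance_at_loops(pairs: pd.DataFrame, loops: pd.DataFrame,
                         pad: int = 0, min_cpg_per_mate: int = 3,
                         min_n: int = DEFAULT_MIN_N) -> ConcordanceResult:
    """Concordance restricted to pairs bridging the two anchors of a loop.

    A pair qualifies when mate1 falls in the padded upstream anchor and
    mate2 in the padded downstream anchor of the same loop (cis pairs are
    stored with pos1 <= pos2, and loop anchors are ordered, so no
    orientation swap is needed).
    """
    sub = _mate_fractions(pairs, min_cpg_per_mate)
    if loops.empty or sub.empty:
        return ConcordanceResult(0, np.inf, min_cpg_per_mate, 0,
                                 np.nan, np.nan, False)
    mask = np.zeros(len(sub), dtype=bool)
    p1 = sub["pos1"].to_numpy()
    p2 = sub["pos2"].to_numpy()
    chrom = sub["chrom1"].to_numpy()
    for _, lp in loops.iterrows():
        in1 = (p1 >= lp["start1"] - pad) & (p1 < lp["end1"] + pad)
        in2 = (p2 >= lp["start2"] - pad) & (p2 < lp["end2"] + pad)
        mask |= (chrom == lp["chrom1"]) & in1 & in2
    sel = sub.loc[mask]
    if len(sel) < min_n:
        return ConcordanceResult(0, np.inf, min_cpg_per_mate, len(sel),
                                 np.nan, np.nan, False)
    r, p, defined = _pcc(sel["x"].to_numpy(), sel["y"].to_numpy())
    return ConcordanceResult(0, np.inf, min_cpg_per_mate, len(sel), r, p,
                             defined)
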