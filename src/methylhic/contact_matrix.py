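"""Binned contact matrices: construction, ICE balancing, O/E, scaling.

A :class:`ContactMatrix` is a dense symmetric per-chromosome matrix at one
resolution, in one of three states:

``raw``
    integer ligation counts straight from binned pairs;
``balanced``
    after iterative correction (ICE) — every unmasked row sums to the same
    value, and ``balanced = raw * w_i * w_j`` for per-bin weights ``w``;
``oe``
    observed over distance-matched expected, computed from a balanced
    matrix so that every unmasked diagonal averages to 1.

Bins with poor coverage are masked (rows/columns set to NaN) before
balancing and excluded from all downstream means.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io_formats import GenomeSpec

#: bins whose raw marginal is below this fraction of the median marginal
#: are masked before balancing
COVERAGE_FLOOR_FRACTION = 0.1


class BalanceError(RuntimeError):
    pass


@dataclass
class ContactMatrix:
    chrom: str
    binsize: int
    values: np.ndarray
    state: str = "raw"
    balance_weights: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def mask(self) -> np.ndarray:
        """Boolean per-bin flag: True where the bin is valid (unmasked)."""
        return ~np.all(np.isnan(self.values), axis=1)

    def raw_counts(self) -> np.ndarray:
        """Recover count-scale values from a balanced matrix."""
        if self.state == "raw":
            return self.values
        if self.state == "balanced" and self.balance_weights is not None:
            w = self.balance_weights
            return self.values / np.outer(w, w)
        raise ValueError(f"cannot recover counts from state {self.state!r}")


@dataclass
class ExpectedProfile:
    """Mean contact value per genomic-distance bin (distance in bins)."""

    binsize: int
    values: np.ndarray  # index = distance in bins

    def at(self, d: int | np.ndarray) -> np.ndarray:
        return self.values[np.asarray(d)]


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def bin_pairs(pairs, genome: GenomeSpec, binsize: int) -> dict[str, ContactMatrix]:
    """Accumulate cis pairs into symmetric per-chromosome count matrices.

    Each pair increments cell ``(pos1//binsize, pos2//binsize)`` and its
    transpose mirror; diagonal (self-bin) pairs are counted once.
    """
    matrices: dict[str, ContactMatrix] = {}
    cis = pairs[pairs["chrom1"] == pairs["chrom2"]]
    for chrom in genome.chrom_names:
        n = genome.n_bins(chrom, binsize)
        mat = np.zeros((n, n))
        sub = cis[cis["chrom1"] == chrom]
        if len(sub):
            b1 = sub["pos1"].to_numpy() // binsize
            b2 = sub["pos2"].to_numpy() // binsize
            if b1.max(initial=0) >= n or b2.max(initial=0) >= n:
                raise ValueError(f"pair beyond end of {chrom}")
            np.add.at(mat, (b1, b2), 1.0)
            off = b1 != b2
            np.add.at(mat, (b2[off], b1[off]), 1.0)
        matrices[chrom] = ContactMatrix(chrom=chrom, binsize=binsize, values=mat)
    return matrices


# ---------------------------------------------------------------------------
# balancing (iterative correction)
# ---------------------------------------------------------------------------

def coverage_mask(values: np.ndarray,
                  floor_fraction: float = COVERAGE_FLOOR_FRACTION) -> np.ndarray:
    """True for bins kept; low-coverage bins fall below the median floor."""
    marg = np.nansum(np.where(np.isnan(values), 0.0, values), axis=1)
    positive = marg[marg > 0]
    if positive.size == 0:
        return np.zeros(len(marg), dtype=bool)
    return marg >= floor_fraction * np.median(positive)


def balance(matrix: ContactMatrix, max_iter: int = 1000,
            tol: float = 1e-5) -> ContactMatrix:
    """ICE-balance a raw matrix so unmasked row sums are equal.

    Alternately divides by row/column marginals (normalised to mean 1)
    until the worst relative marginal deviation drops below ``tol``.
    """
    if matrix.state != "raw":
        raise ValueError("balance expects a raw matrix")
    keep = coverage_mask(matrix.values)
    vals = matrix.values.astype(float).copy()
    vals[~keep, :] = np.nan
    vals[:, ~keep] = np.nan
    weights = np.full(matrix.n_bins, np.nan)
    weights[keep] = 1.0
    if not keep.any():
        return ContactMatrix(matrix.chrom, matrix.binsize, vals,
                             state="balanced", balance_weights=weights)
    sub = vals[np.ix_(keep, keep)]
    w = np.ones(keep.sum())
    for _ in range(max_iter):
        marg = sub.sum(axis=1)
        dev = np.abs(marg / marg.mean() - 1.0)
        if dev.max() < tol:
            break
        corr = marg / marg.mean()
        corr[corr == 0] = 1.0
        sub /= np.outer(corr, corr)
        w /= corr
    else:
        worst = int(np.argmax(dev))
        raise BalanceError(
            f"ICE did not converge in {max_iter} iterations on {matrix.chrom} "
            f"(worst bin {np.flatnonzero(keep)[worst]}, deviation {dev.max():.3g})")
    vals[np.ix_(keep, keep)] = sub
    weights[keep] = w
    return ContactMatrix(matrix.chrom, matrix.binsize, vals,
                         state="balanced", balance_weights=weights)


# ---------------------------------------------------------------------------
# expected-by-distance and observed/expected
# ---------------------------------------------------------------------------

def expected_by_distance(matrix: ContactMatrix) -> ExpectedProfile:
    n = matrix.n_bins
    exp = np.full(n, np.nan)
    for d in range(n):
        diag = np.diagonal(matrix.values, offset=d)
        ok = np.isfinite(diag)
        if ok.any():
            exp[d] = diag[ok].mean()
    return ExpectedProfile(binsize=matrix.binsize, values=exp)


def oe_transform(matrix: ContactMatrix) -> tuple[ExpectedProfile, ContactMatrix]:
    """Observed/expected: each cell divided by the mean of its diagonal."""
    if matrix.state != "balanced":
        raise ValueError("oe_transform expects a balanced matrix")
    expected = expected_by_distance(matrix)
    n = matrix.n_bins
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = matrix.values / expected.values[d]
    bad = (expected.values[d] == 0) & (np.nan_to_num(matrix.values) > 0)
    if np.any(bad):
        raise ValueError("nonzero cell at distance with zero expected")
    return expected, ContactMatrix(matrix.chrom, matrix.binsize, oe,
                                   state="oe",
                                   balance_weights=matrix.balance_weights)


def scale_total(matrices: dict[str, ContactMatrix],
                target: float = 1e9) -> dict[str, ContactMatrix]:
    """Scale one sample's matrices so the genome-wide sum equals ``target``.

    Puts samples of different sequencing depth on a common count scale for
    direct comparison of interaction strengths.
    """
    total = sum(np.nansum(m.values) for m in matrices.values())
    if total == 0:
        raise ValueError("zero genome-wide total")
    factor = target / total
    return {c: replace(m, values=m.values * factor)
            for c, m in matrices.items()}
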