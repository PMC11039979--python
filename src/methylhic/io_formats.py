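"""Readers and writers for every on-disk format the pipeline touches.

All coordinates are 0-based, half-open ``[start, end)`` — BED and bedGraph
native.  Pair positions are the 0-based leftmost coordinate of each mate.

The extended pairs dialect is a tab-separated superset of the 4DN pairs
idea: a mandatory header line names the columns

    chrom1  pos1  chrom2  pos2  meth1  total1  meth2  total2

where ``meth``/``total`` are the methylated / covered CpG counts of each
mate.  Per-read methylation from Methyl-HiC has no standard file format, so
this package defines one.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger("methylhic")

PAIR_COLUMNS = [
    "chrom1", "pos1", "chrom2", "pos2",
    "meth1", "total1", "meth2", "total2",
]

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
BEDGRAPH_COLUMNS = ["chrom", "start", "end", "value"]
BEDPE_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]


class FormatError(ValueError):
    """Malformed or inconsistent on-disk data."""


# ---------------------------------------------------------------------------
# genome specification
# ---------------------------------------------------------------------------

@dataclass
class GenomeSpec:
    """Chromosome names/lengths plus per-chromosome sorted CpG coordinates.

    Stands in for a reference genome (real or synthetic): downstream code
    only ever needs chromosome bounds and where the CpGs are.
    """

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    cpg_positions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.chrom_names:
            if name not in self.chrom_lengths:
                raise FormatError(f"no length for chromosome {name!r}")
            if self.chrom_lengths[name] <= 0:
                raise FormatError(f"non-positive length for {name!r}")
        for name, pos in self.cpg_positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            if pos.size and (np.any(np.diff(pos) <= 0)):
                raise FormatError(f"CpG positions not strictly increasing on {name!r}")
            if pos.size and (pos[0] < 0 or pos[-1] >= self.chrom_lengths[name]):
                raise FormatError(f"CpG position outside {name!r}")
            self.cpg_positions[name] = pos

    def n_bins(self, chrom: str, binsize: int) -> int:
        return -(-self.chrom_lengths[chrom] // binsize)

    def cpgs(self, chrom: str) -> np.ndarray:
        return self.cpg_positions.get(chrom, np.empty(0, dtype=np.int64))


class PairRecord(NamedTuple):
    """One ligated Methyl-HiC mate pair with per-mate CpG counts."""

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    meth1: int
    total1: int
    meth2: int
    total2: int


# ---------------------------------------------------------------------------
# pairs
# ---------------------------------------------------------------------------

def validate_pairs(pairs: pd.DataFrame, genome: GenomeSpec | None = None) -> None:
    """Raise :class:`FormatError` on any invariant violation."""
    for side in ("1", "2"):
        meth, total = pairs[f"meth{side}"], pairs[f"total{side}"]
        bad = (meth < 0) | (meth > total)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(f"record {i}: meth{side} outside [0, total{side}]")
    cis = pairs["chrom1"] == pairs["chrom2"]
    if (pairs.loc[cis, "pos1"] > pairs.loc[cis, "pos2"]).any():
        raise FormatError("intra-chromosomal record with pos1 > pos2")
    if genome is not None:
        for c, p in (("chrom1", "pos1"), ("chrom2", "pos2")):
            for chrom, sub in pairs.groupby(c, observed=True):
                if chrom not in genome.chrom_lengths:
                    raise FormatError(f"unknown chromosome {chrom!r}")
                pos = sub[p]
                if (pos < 0).any() or (pos >= genome.chrom_lengths[chrom]).any():
                    raise FormatError(f"position outside {chrom!r}")


def canonicalize_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Store cis records with ``pos1 <= pos2`` (mate counts swap along)."""
    pairs = pairs.copy()
    flip = (pairs["chrom1"] == pairs["chrom2"]) & (pairs["pos1"] > pairs["pos2"])
    if flip.any():
        f = flip.to_numpy()
        for a, b in (("pos1", "pos2"), ("meth1", "meth2"), ("total1", "total2")):
            va, vb = pairs[a].to_numpy().copy(), pairs[b].to_numpy().copy()
            pairs.loc[f, a], pairs.loc[f, b] = vb[f], va[f]
    return pairs


def filter_pairs(pairs: pd.DataFrame, min_distance: int) -> pd.DataFrame:
    """Drop cis pairs with genomic distance strictly below ``min_distance``.

    Short-range ligation products carry no long-range contact information;
    records at exactly the threshold are kept (strict ``<`` rule).
    """
    if min_distance < 0:
        raise ValueError("min_distance must be >= 0")
    cis = pairs["chrom1"] == pairs["chrom2"]
    short = cis & ((pairs["pos2"] - pairs["pos1"]).abs() < min_distance)
    n = int(short.sum())
    if n:
        logger.info("dropped %d short-range pairs (< %d bp)", n, min_distance)
    return pairs.loc[~short].reset_index(drop=True)


def read_pairs(
    path: str | Path,
    min_distance: int = 1000,
    genome: GenomeSpec | None = None,
) -> pd.DataFrame:
    """Read an extended pairs file, validate, and apply the distance filter."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().lstrip("#").split("\t")
    missing = [c for c in PAIR_COLUMNS if c not in header]
    if missing:
        raise FormatError(f"{path}: header missing columns {missing}")
    try:
        pairs = pd.read_csv(
            path, sep="\t", skiprows=1, names=header,
            dtype={c: (str if c.startswith("chrom") else np.int64) for c in header},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    pairs = pairs[PAIR_COLUMNS]
    pairs = canonicalize_pairs(pairs)
    validate_pairs(pairs, genome)
    return filter_pairs(pairs, min_distance)


def write_pairs(pairs: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(PAIR_COLUMNS) + "\n")
        pairs[PAIR_COLUMNS].to_csv(fh, sep="\t", header=False, index=False)


def iter_pair_records(pairs: pd.DataFrame) -> Iterable[PairRecord]:
    for row in pairs[PAIR_COLUMNS].itertuples(index=False):
        yield PairRecord(*row)


# ---------------------------------------------------------------------------
# intervals: BED / bedGraph / BEDPE
# ---------------------------------------------------------------------------

def _check_intervals(df: pd.DataFrame, start: str = "start", end: str = "end") -> None:
    if (df[end] <= df[start]).any():
        raise FormatError(f"interval with {end} <= {start}")


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in ("chrom", "start", "chrom1", "start1") if c in df.columns]
    return df.sort_values(cols, kind="stable").reset_index(drop=True)


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED4/BED6 -> DataFrame with chrom,start,end[,name[,score[,strand]]]."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED_COLUMNS[: df.shape[1]]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    _check_intervals(df)
    return sort_intervals(df)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=BEDGRAPH_COLUMNS)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    _check_intervals(df)
    df = sort_intervals(df)
    for _, sub in df.groupby("chrom", observed=True):
        if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
            raise FormatError("overlapping bedGraph intervals")
    return df


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df[BEDGRAPH_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_loops(path: str | Path) -> pd.DataFrame:
    """BEDPE-like loop file: six coordinate fields, optional name/score."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = BEDPE_COLUMNS + ["name", "score"][: df.shape[1] - 6]
    df.columns = names
    for s in ("1", "2"):
        df[f"start{s}"] = df[f"start{s}"].astype(np.int64)
        df[f"end{s}"] = df[f"end{s}"].astype(np.int64)
        _check_intervals(df, f"start{s}", f"end{s}")
    cis = df["chrom1"] == df["chrom2"]
    if (df.loc[cis, "start1"] > df.loc[cis, "start2"]).any():
        raise FormatError("loop with anchor1 downstream of anchor2")
    return sort_intervals(df)


def write_loops(df: pd.DataFrame, path: str | Path) -> None:
    cols = BEDPE_COLUMNS + [c for c in ("name", "score") if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# dense contact matrices (TSV + JSON sidecar)
# ---------------------------------------------------------------------------

def write_matrix(matrix, path: str | Path) -> None:
    """Dense per-chromosome matrix as TSV plus a ``.json`` metadata sidecar."""
    path = Path(path)
    np.savetxt(path, matrix.values, delimiter="\t", fmt="%.10g")
    meta = {
        "chrom": matrix.chrom,
        "binsize": int(matrix.binsize),
        "state": matrix.state,
        "n_bins": int(matrix.values.shape[0]),
    }
    if matrix.balance_weights is not None:
        meta["balance_weights"] = [None if not np.isfinite(w) else float(w)
                                   for w in matrix.balance_weights]
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_matrix(path: str | Path):
    from .contact_matrix import ContactMatrix

    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FormatError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "binsize" not in meta:
        raise FormatError("sidecar missing binsize")
    values = np.loadtxt(path, delimiter="\t", ndmin=2)
    if values.shape[0] != values.shape[1]:
        raise FormatError("contact matrix is not square")
    finite = np.where(np.isfinite(values), values, 0.0)
    if not np.allclose(finite, finite.T, atol=1e-9):
        raise FormatError("contact matrix is not symmetric")
    weights = meta.get("balance_weights")
    if weights is not None:
        weights = np.array([np.nan if w is None else w for w in weights])
    return ContactMatrix(
        chrom=meta["chrom"], binsize=int(meta["binsize"]), values=values,
        state=meta.get("state", "raw"), balance_weights=weights,
    )
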