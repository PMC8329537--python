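"""Marker maps and genomic-interval masks.

A :class:`MarkerMap` is an ordered table of autosomal biallelic SNPs
(chromosome, bp position, alleles, optionally a genetic-map position in cM).
Coordinates are 0-based; mask intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def _chrom_sort_key(c: str):
    s = str(c)
    return (0, int(s)) if s.isdigit() else (1, s)


class MarkerMap:
    """Sorted map of biallelic markers.

    Parameters
    ----------
    table : DataFrame with columns ``chrom``, ``pos`` (int bp), optionally
        ``ref``, ``alt``, ``cm``.  Rows are canonically sorted by
        (chromosome, position); positions must be strictly increasing within
        a chromosome.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"chrom", "pos"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"marker table lacks columns: {sorted(missing)}")
        table = table.copy()
        table["chrom"] = table["chrom"].astype(str)
        order = sorted(table["chrom"].unique(), key=_chrom_sort_key)
        table["chrom"] = pd.Categorical(table["chrom"], categories=order, ordered=True)
        table = table.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        table["chrom"] = table["chrom"].astype(str)
        for chrom, grp in table.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {chrom}")
        self.table = table
        self.chroms: list[str] = order
        self._bounds: dict[str, tuple[int, int]] = {}
        start = 0
        counts = table["chrom"].value_counts()
        for chrom in order:
            n = int(counts[chrom])
            self._bounds[chrom] = (start, start + n)
            start += n

    def __len__(self) -> int:
        return len(self.table)

    @property
    def positions(self) -> np.ndarray:
        return self.table["pos"].to_numpy()

    @property
    def chrom_codes(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    def chrom_bounds(self, chrom: str) -> tuple[int, int]:
        """Row slice ``[start, stop)`` of one chromosome's markers."""
        return self._bounds[str(chrom)]

    def subset(self, keep: np.ndarray) -> tuple["MarkerMap", np.ndarray]:
        """New map restricted to boolean mask/indices; also returns kept row indices."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return MarkerMap(self.table.iloc[idx]), idx


def read_bed_mask(path: str | Path) -> pd.DataFrame:
    """Read a BED file of excluded regions (chrom, start, end; 0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"], dtype={0: str},
    )
    _validate_intervals(df)
    return df


def write_bed_mask(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def _validate_intervals(df: pd.DataFrame) -> None:
    bad = df[df["start"] >= df["end"]]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"malformed mask interval {row['chrom']}:{row['start']}-{row['end']} (start >= end)"
        )


def apply_region_mask(marker_map: MarkerMap, mask: pd.DataFrame | None) -> tuple[MarkerMap, np.ndarray]:
    """Drop markers falling inside any masked interval.

    ``mask`` has columns chrom/start/end with 0-based half-open intervals.
    Returns the filtered map and the indices (into the input map) of the
    surviving markers.
    """
    if mask is None or len(mask) == 0:
        return marker_map, np.arange(len(marker_map))
    _validate_intervals(mask)
    keep = np.ones(len(marker_map), dtype=bool)
    mask = mask.copy()
    mask["chrom"] = mask["chrom"].astype(str)
    for chrom, grp in mask.groupby("chrom"):
        if chrom not in marker_map._bounds:
            continue
        lo, hi = marker_map.chrom_bounds(chrom)
        pos = marker_map.positions[lo:hi]
        inside = np.zeros(hi - lo, dtype=bool)
        for start, end in grp[["start", "end"]].itertuples(index=False):
            inside |= (pos >= start) & (pos < end)
        keep[lo:hi] = ~inside
    return marker_map.subset(keep)
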