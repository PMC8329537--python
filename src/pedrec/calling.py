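"""Crossover calling from three-generation families.

For each family the focal parent's two haplotypes are phased by grandparental
origin with single-pass Mendelian deduction (no population phasing): a site
is phase-known only when one grandparent's genotype forces the assignment.
The allele the parent transmitted to the offspring is deduced where possible
(offspring homozygous, or heterozygous with the other parent homozygous).
Sites that are parent-heterozygous, phase-known and transmission-resolved are
*informative*; a crossover is called into the interval between two adjacent
informative markers whose grandparental origins differ.  Intervals are
0-based half-open ``[left_bp, right_bp)``.

Mendelian inconsistencies (genotyping errors) are never fatal: the site is
dropped and counted, and families whose inconsistency rate exceeds a
configurable threshold are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import MAX_CROSSOVERS
from .io import MISSING, GenotypeData
from .markers import MarkerMap, apply_region_mask

__all__ = [
    "PhasedParent", "OriginVector", "phase_parent", "informative_sites",
    "trace_origin", "call_crossovers", "qc_filter_meioses",
    "call_meiosis", "process_families", "apply_region_mask",
]

GRANDPATERNAL = 0
GRANDMATERNAL = 1


@dataclass
class PhasedParent:
    """Per-marker grandparental alleles of the focal parent.

    ``gpa``/``gma`` are the alleles on the grandpaternal / grandmaternal
    haplotype (0/1; -1 where phase-unknown); ``known`` marks sites where the
    deduction succeeded; ``inconsistent`` marks Mendelian conflicts among
    parent and grandparents (excluded from phasing).
    """

    gpa: np.ndarray
    gma: np.ndarray
    known: np.ndarray
    inconsistent: np.ndarray


@dataclass
class OriginVector:
    """Grandparental origin of the transmitted allele at informative markers."""

    marker_idx: np.ndarray  # indices into the MarkerMap
    origin: np.ndarray      # GRANDPATERNAL (0) or GRANDMATERNAL (1)


def _fill(geno, m: int) -> np.ndarray:
    if geno is None:
        return np.full(m, MISSING, dtype=np.int8)
    return np.asarray(geno, dtype=np.int8)


def phase_parent(parent: np.ndarray, grandsire=None, granddam=None) -> PhasedParent:
    """Phase the focal parent's haplotypes by grandparental origin.

    Deduction at heterozygous parent sites: a homozygous grandsire fixes the
    grandpaternal allele; otherwise a homozygous granddam fixes the
    grandmaternal allele (hence the other).  Homozygous parent sites are
    trivially phased (both haplotypes carry the same allele).  Sites where
    both grandparents are heterozygous or missing stay phase-unknown.
    """
    par = np.asarray(parent, dtype=np.int8)
    m = par.shape[0]
    gs, gd = _fill(grandsire, m), _fill(granddam, m)

    incons = ((par == 0) & ((gs == 2) | (gd == 2))
              | (par == 2) & ((gs == 0) | (gd == 0))
              | (par == 1) & (((gs == 0) & (gd == 0)) | ((gs == 2) & (gd == 2))))

    gpa = np.full(m, -1, dtype=np.int8)
    gma = np.full(m, -1, dtype=np.int8)
    hom0, hom2, het = par == 0, par == 2, par == 1
    gpa[hom0] = 0; gma[hom0] = 0
    gpa[hom2] = 1; gma[hom2] = 1
    # heterozygous parent: one informative grandparent settles the phase
    from_gs = het & ((gs == 0) | (gs == 2))
    gpa[from_gs] = (gs[from_gs] == 2).astype(np.int8)
    from_gd = het & ~from_gs & ((gd == 0) | (gd == 2))
    gpa[from_gd] = (gd[from_gd] == 0).astype(np.int8)
    het_known = from_gs | from_gd
    gma[het_known] = 1 - gpa[het_known]

    known = (hom0 | hom2 | het_known) & ~incons
    gpa[~known] = -1
    gma[~known] = -1
    return PhasedParent(gpa=gpa, gma=gma, known=known, inconsistent=incons)


def informative_sites(phased: PhasedParent, parent: np.ndarray,
                      offspring: np.ndarray, other_parent=None):
    """Mask of informative markers plus the transmitted focal allele.

    Informative: parent heterozygous, phase-known, and the allele the focal
    parent transmitted is determinable — offspring homozygous, or offspring
    heterozygous with the other parent homozygous.  Returns
    ``(informative, transmitted, mendel_error)``; transmitted is -1 where
    unknown.
    """
    par = np.asarray(parent, dtype=np.int8)
    off = np.asarray(offspring, dtype=np.int8)
    oth = _fill(other_parent, par.shape[0])

    err = ((off == 0) & ((par == 2) | (oth == 2))
           | (off == 2) & ((par == 0) | (oth == 0))
           | (off == 1) & (((par == 0) & (oth == 0)) | ((par == 2) & (oth == 2))))

    trans = np.full(par.shape[0], -1, dtype=np.int8)
    trans[off == 0] = 0
    trans[off == 2] = 1
    het_off = off == 1
    trans[het_off & (oth == 0)] = 1
    trans[het_off & (oth == 2)] = 0
    trans[err] = -1

    informative = (par == 1) & phased.known & (trans >= 0) & ~err
    return informative, trans, err


def trace_origin(phased: PhasedParent, informative: np.ndarray,
                 transmitted: np.ndarray) -> OriginVector:
    """Label each informative site with the grandparental haplotype transmitted."""
    idx = np.flatnonzero(informative)
    origin = np.where(transmitted[idx] == phased.gpa[idx],
                      GRANDPATERNAL, GRANDMATERNAL).astype(np.int8)
    return OriginVector(marker_idx=idx, origin=origin)


def call_crossovers(origin: OriginVector, marker_map: MarkerMap) -> pd.DataFrame:
    """Crossover events: one per adjacent informative pair with differing origin.

    Returns a frame with columns chrom, left_bp, right_bp (0-based half-open
    interval between the two flanking informative markers).
    """
    rows = []
    pos = marker_map.positions
    for chrom in marker_map.chroms:
        lo, hi = marker_map.chrom_bounds(chrom)
        sel = (origin.marker_idx >= lo) & (origin.marker_idx < hi)
        idx = origin.marker_idx[sel]
        org = origin.origin[sel]
        if idx.size < 2:
            continue
        switch = np.flatnonzero(np.diff(org) != 0)
        for s in switch:
            rows.append(dict(chrom=chrom, left_bp=int(pos[idx[s]]),
                             right_bp=int(pos[idx[s + 1]])))
    return pd.DataFrame(rows, columns=["chrom", "left_bp", "right_bp"])


def qc_filter_meioses(records: pd.DataFrame, max_count: int = MAX_CROSSOVERS,
                      count_col: str = "r") -> pd.DataFrame:
    """Drop meioses with more than ``max_count`` genome-wide crossovers."""
    return records[records[count_col] <= max_count].reset_index(drop=True)


def call_meiosis(family, genotypes: GenotypeData, marker_map: MarkerMap | None = None):
    """Call crossovers for one three-generation family.

    ``family`` provides offspring_id, focal_parent_id and optional
    other_parent_id / grandsire_id / granddam_id.  Returns
    ``(record_dict, events_frame)``; the record carries the genome-wide
    count, informative-marker count and Mendelian-inconsistency tally.
    """
    mm = genotypes.markers if marker_map is None else marker_map

    def maybe(animal):
        return genotypes.row(animal) if animal is not None and animal in genotypes else None

    par = genotypes.row(family["focal_parent_id"])
    off = genotypes.row(family["offspring_id"])
    phased = phase_parent(par, maybe(family.get("grandsire_id")),
                          maybe(family.get("granddam_id")))
    informative, trans, err = informative_sites(
        phased, par, off, maybe(family.get("other_parent_id")))
    origin = trace_origin(phased, informative, trans)
    events = call_crossovers(origin, mm)
    n_incons = int(phased.inconsistent.sum() + (err & ~phased.inconsistent).sum())
    record = dict(
        meiosis_id=f"{family['focal_parent_id']}|{family['offspring_id']}",
        parent_id=family["focal_parent_id"],
        offspring_id=family["offspring_id"],
        r=int(len(events)),
        n_informative=int(informative.sum()),
        n_inconsistent=n_incons,
        inconsistency_rate=n_incons / max(len(mm), 1),
    )
    return record, events


def process_families(families: pd.DataFrame, genotypes: GenotypeData,
                     region_mask: pd.DataFrame | None = None,
                     max_inconsistency_rate: float = 0.02,
                     max_count: int | None = MAX_CROSSOVERS):
    """Call crossovers for every family, with masking and QC filters.

    Returns ``(records, events, stats)``: per-meiosis counts, per-event
    intervals, and a dict of drop tallies.
    """
    mm, keep_idx = apply_region_mask(genotypes.markers, region_mask)
    gt = genotypes.subset_markers(keep_idx, mm) if len(keep_idx) != len(genotypes.markers) else genotypes

    records, event_frames = [], []
    n_incons_dropped = 0
    for _, fam in families.iterrows():
        rec, ev = call_meiosis(fam.to_dict(), gt)
        if rec["inconsistency_rate"] > max_inconsistency_rate:
            n_incons_dropped += 1
            continue
        ev = ev.copy()
        ev.insert(0, "meiosis_id", rec["meiosis_id"])
        records.append(rec)
        event_frames.append(ev)
    rec_df = pd.DataFrame(records, columns=[
        "meiosis_id", "parent_id", "offspring_id", "r", "n_informative",
        "n_inconsistent", "inconsistency_rate"])
    ev_df = (pd.concat(event_frames, ignore_index=True) if event_frames
             else pd.DataFrame(columns=["meiosis_id", "chrom", "left_bp", "right_bp"]))
    n_before = len(rec_df)
    if max_count is not None:
        rec_df = qc_filter_meioses(rec_df, max_count)
        ev_df = ev_df[ev_df["meiosis_id"].isin(set(rec_df["meiosis_id"]))].reset_index(drop=True)
    stats = dict(
        n_families=int(len(families)),
        n_dropped_inconsistency=n_incons_dropped,
        n_dropped_max_count=n_before - len(rec_df),
        n_meioses=int(len(rec_df)),
        n_events=int(len(ev_df)),
    )
    return rec_df, ev_df, stats
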