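"""Shared independent oracles for the crossover-calling tests."""

import numpy as np

from pedrec.calling import informative_sites, phase_parent


def transmissible(geno: int, allele: int) -> bool:
    """Can a genotype (dosage; -1 missing) transmit the given allele?"""
    if geno == -1:
        return True
    return {0: allele == 0, 1: True, 2: allele == 1}[geno]


def oracle_phase(par: int, gs: int, gd: int):
    """Enumerate haplotype assignments consistent with the grandparents.

    Returns (gpa, known, inconsistent): the grandpaternal allele when the
    assignment is unique, whether phase is known, and whether no assignment
    is consistent (Mendelian conflict).
    """
    if par == -1:
        return -1, False, False
    pairs = [(a, par - a) for a in (0, 1) if 0 <= par - a <= 1]
    ok = [(a, b) for a, b in pairs if transmissible(gs, a) and transmissible(gd, b)]
    if not ok:
        return -1, False, True
    gpas = {a for a, _ in ok}
    if len(gpas) == 1:
        return ok[0][0], True, False
    return -1, False, False


def oracle_transmission(off: int, oth: int):
    """Feasible focal-parent transmissions at a parent-heterozygous site.

    Returns (transmitted, error): the allele when unique, -1 when ambiguous
    or the offspring is missing; error=True when no transmission is feasible.
    """
    if off == -1:
        return -1, False
    feasible = {a for a in (0, 1)
                if 0 <= off - a <= 1 and transmissible(oth, off - a)}
    if not feasible:
        return -1, True
    if len(feasible) == 1:
        return feasible.pop(), False
    return -1, False


def informative_positions_by_chrom(family: dict, genotypes):
    """Informative-marker bp positions per chromosome for one family."""
    mm = genotypes.markers

    def maybe(aid):
        return genotypes.row(aid) if aid is not None and aid in genotypes else None

    par = genotypes.row(family["focal_parent_id"])
    off = genotypes.row(family["offspring_id"])
    phased = phase_parent(par, maybe(family.get("grandsire_id")),
                          maybe(family.get("granddam_id")))
    informative, _, _ = informative_sites(phased, par, off,
                                          maybe(family.get("other_parent_id")))
    out = {}
    for c in mm.chroms:
        lo, hi = mm.chrom_bounds(c)
        out[c] = mm.positions[lo:hi][informative[lo:hi]]
    return out


def parity_oracle(true_pos: np.ndarray, informative_pos: np.ndarray):
    """Detectable crossover count: intervals between consecutive informative
    markers containing an odd number of true events; returns (count, odd
    interval list)."""
    if informative_pos.size < 2:
        return 0, []
    j = np.searchsorted(informative_pos, true_pos, side="right") - 1
    j = j[(j >= 0) & (j < informative_pos.size - 1)]
    counts = np.bincount(j, minlength=informative_pos.size - 1)
    odd = np.flatnonzero(counts % 2 == 1)
    intervals = [(int(informative_pos[k]), int(informative_pos[k + 1])) for k in odd]
    return len(intervals), intervals
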