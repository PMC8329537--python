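"""Crossover caller: phasing/transmission deduction oracles, switch calling,
region masking, QC filters, and truth-level equivalence on clean data."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from helpers import (informative_positions_by_chrom, oracle_phase,
                     oracle_transmission, parity_oracle)
from pedrec.calling import (OriginVector, apply_region_mask, call_crossovers,
                            informative_sites, phase_parent, process_families,
                            qc_filter_meioses, trace_origin)
from pedrec.families import extract_three_gen_families
from pedrec.markers import MarkerMap

GENOS = (-1, 0, 1, 2)


def test_phasing_matches_enumeration_oracle():
    """Single-pass Mendelian deduction agrees with exhaustive haplotype
    enumeration over every (parent, grandsire, granddam) genotype combo."""
    combos = list(itertools.product(GENOS, repeat=3))
    par = np.array([c[0] for c in combos], dtype=np.int8)
    gs = np.array([c[1] for c in combos], dtype=np.int8)
    gd = np.array([c[2] for c in combos], dtype=np.int8)
    phased = phase_parent(par, gs, gd)
    for i, (p, s, d) in enumerate(combos):
        gpa, known, incons = oracle_phase(p, s, d)
        assert bool(phased.inconsistent[i]) == incons, (p, s, d)
        assert bool(phased.known[i]) == known, (p, s, d)
        if known and p == 1:
            assert phased.gpa[i] == gpa, (p, s, d)
            assert phased.gpa[i] + phased.gma[i] == p
        if known:
            assert phased.gpa[i] + phased.gma[i] == p


def test_phase_examples():
    # het parent, grandsire homozygous alt -> grandpaternal allele is alt
    ph = phase_parent(np.array([1], dtype=np.int8), np.array([2], dtype=np.int8),
                      np.array([-1], dtype=np.int8))
    assert ph.gpa[0] == 1 and ph.gma[0] == 0 and ph.known[0]
    # all three heterozygous -> phase unknown
    ph = phase_parent(np.array([1], dtype=np.int8), np.array([1], dtype=np.int8),
                      np.array([1], dtype=np.int8))
    assert not ph.known[0]


def test_transmission_matches_enumeration_oracle():
    """Transmitted-allele deduction at het/phase-known parent sites agrees
    with feasibility enumeration over (offspring, other parent) genotypes."""
    combos = list(itertools.product(GENOS, repeat=2))
    m = len(combos)
    par = np.ones(m, dtype=np.int8)
    gs = np.zeros(m, dtype=np.int8)  # forces phase known: gpa=0
    phased = phase_parent(par, gs, None)
    assert phased.known.all()
    off = np.array([c[0] for c in combos], dtype=np.int8)
    oth = np.array([c[1] for c in combos], dtype=np.int8)
    informative, trans, err = informative_sites(phased, par, off, oth)
    for i, (o, t) in enumerate(combos):
        exp_trans, exp_err = oracle_transmission(o, t)
        assert bool(err[i]) == exp_err, (o, t)
        assert trans[i] == exp_trans, (o, t)
        assert bool(informative[i]) == (exp_trans >= 0 and not exp_err), (o, t)


def test_phase_unknown_site_never_informative():
    par = np.array([1], dtype=np.int8)
    phased = phase_parent(par, np.array([1], dtype=np.int8), None)
    informative, _, _ = informative_sites(phased, par, np.array([0], dtype=np.int8))
    assert not informative[0]


def _map10():
    return MarkerMap(pd.DataFrame({"chrom": "1", "pos": np.arange(10) * 1000 + 100}))


class TestCallCrossovers:
    def test_single_switch(self):
        mm = _map10()
        ov = OriginVector(marker_idx=np.arange(5), origin=np.array([0, 0, 1, 1, 1]))
        ev = call_crossovers(ov, mm)
        assert len(ev) == 1
        assert ev.iloc[0]["left_bp"] == 1100 and ev.iloc[0]["right_bp"] == 2100

    def test_constant_origin_no_events(self):
        ev = call_crossovers(OriginVector(np.arange(3), np.zeros(3, int)), _map10())
        assert ev.empty

    def test_double_switch(self):
        ev = call_crossovers(OriginVector(np.arange(3), np.array([0, 1, 0])), _map10())
        assert len(ev) == 2

    def test_empty_origin_vector(self):
        ev = call_crossovers(OriginVector(np.array([], int), np.array([], int)), _map10())
        assert ev.empty

    @given(st.lists(st.integers(0, 1), min_size=0, max_size=10))
    def test_count_equals_switch_enumeration(self, origins):
        mm = _map10()
        ov = OriginVector(np.arange(len(origins)), np.array(origins, dtype=np.int8))
        expected = sum(a != b for a, b in zip(origins, origins[1:]))
        assert len(call_crossovers(ov, mm)) == expected


def test_trace_origin_alternating():
    par = np.ones(4, dtype=np.int8)
    phased = phase_parent(par, np.zeros(4, dtype=np.int8), None)  # gpa=0 everywhere
    informative = np.ones(4, dtype=bool)
    trans = np.array([0, 1, 0, 1], dtype=np.int8)
    ov = trace_origin(phased, informative, trans)
    assert np.array_equal(ov.origin, [0, 1, 0, 1])


class TestRegionMask:
    def test_empty_mask_identity(self):
        mm = _map10()
        out, idx = apply_region_mask(mm, None)
        assert len(out) == 10 and np.array_equal(idx, np.arange(10))

    def test_full_chromosome_masked(self):
        mm = _map10()
        mask = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [10**7]})
        out, _ = apply_region_mask(mm, mask)
        assert len(out) == 0

    def test_interval_membership(self):
        mm = _map10()  # positions 100, 1100, ..., 9100
        mask = pd.DataFrame({"chrom": ["1"], "start": [1100], "end": [3101]})
        out, idx = apply_region_mask(mm, mask)
        assert len(out) == 7
        assert 1100 not in out.positions and 3100 not in out.positions
        assert 4100 in out.positions

    def test_malformed_interval_rejected(self):
        mask = pd.DataFrame({"chrom": ["1"], "start": [500], "end": [500]})
        with pytest.raises(ValueError, match="malformed"):
            apply_region_mask(_map10(), mask)


def test_qc_filter_over_45():
    df = pd.DataFrame({"meiosis_id": list("abc"), "r": [46, 45, 23]})
    kept = qc_filter_meioses(df, 45)
    assert sorted(kept["r"]) == [23, 45]
    pd.testing.assert_frame_equal(qc_filter_meioses(df, 10**9), df)


def test_marker_map_canonical_after_shuffle(rng):
    tab = pd.DataFrame({"chrom": ["2"] * 5 + ["1"] * 5,
                        "pos": list(range(0, 5000, 1000)) * 2})
    shuffled = tab.sample(frac=1.0, random_state=3)
    a, b = MarkerMap(tab), MarkerMap(shuffled)
    pd.testing.assert_frame_equal(a.table, b.table)
    assert a.chroms == ["1", "2"]


def test_called_counts_match_parity_oracle_on_clean_data(small_bundle):
    """On error-free simulated meioses the caller reproduces, exactly, the
    number of detectable true crossovers (odd parity between informative
    neighbours), and every detectable event lies in a called interval."""
    b = small_bundle
    fams = extract_three_gen_families(b.pedigree, set(b.genotypes.ids))
    records, events, _ = process_families(fams, b.genotypes, max_count=None)
    truth = b.truth_events.set_index("meiosis_id")
    ev_by_id = dict(tuple(events.groupby("meiosis_id")))
    checked = 0
    for rec in records.itertuples():
        fam = fams[fams["offspring_id"] == rec.offspring_id].iloc[0].to_dict()
        info = informative_positions_by_chrom(fam, b.genotypes)
        tr = truth.loc[[rec.meiosis_id]] if rec.meiosis_id in truth.index else None
        called = ev_by_id.get(rec.meiosis_id)
        for chrom, ipos in info.items():
            tpos = (tr[tr["chrom"] == chrom]["pos_bp"].to_numpy()
                    if tr is not None else np.array([]))
            n_exp, intervals = parity_oracle(tpos, ipos)
            csub = (called[called["chrom"] == chrom] if called is not None
                    else pd.DataFrame(columns=["left_bp", "right_bp"]))
            assert len(csub) == n_exp, (rec.meiosis_id, chrom)
            got = set(zip(csub["left_bp"], csub["right_bp"]))
            assert got == set(intervals), (rec.meiosis_id, chrom)
            checked += 1
    assert checked > 100
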