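"""Three-generation family extraction and eligibility filters.

A three-generation family is the unit in which one parental meiosis is
observable: a genotyped offspring, its genotyped focal parent (the dam, for
maternal crossovers), and at least one genotyped grandparent on the focal
side.  Families sharing a dam are separate meioses.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .config import CHIP_PANELS, MIN_PANEL_MARKERS

__all__ = ["extract_three_gen_families", "filter_by_panel"]

FAMILY_COLUMNS = [
    "offspring_id", "focal_parent_id", "other_parent_id",
    "grandsire_id", "granddam_id",
]


def _check_acyclic(pedigree: pd.DataFrame) -> None:
    g = nx.DiGraph()
    for rec in pedigree.itertuples():
        for parent in (rec.sire_id, rec.dam_id):
            if parent is not None and not pd.isna(parent):
                g.add_edge(parent, rec.animal_id)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        return
    path = " -> ".join(str(e[0]) for e in cycle) + f" -> {cycle[-1][1]}"
    raise ValueError(f"pedigree contains a cycle: {path}")


def extract_three_gen_families(pedigree: pd.DataFrame, genotyped_ids,
                               focal_sex: str = "F") -> pd.DataFrame:
    """All (focal parent, offspring) meioses with the three-generation pattern.

    A family is returned when the offspring is genotyped, the focal parent
    (dam when ``focal_sex="F"``) is genotyped, and at least one of the focal
    parent's own parents is genotyped.  The other parent of the offspring is
    recorded when present (genotyped or not); it is only used downstream to
    resolve transmitted alleles.
    """
    genotyped = set(genotyped_ids)
    _check_acyclic(pedigree)
    ped = pedigree.set_index("animal_id", drop=False)
    parent_col = "dam_id" if focal_sex == "F" else "sire_id"
    other_col = "sire_id" if focal_sex == "F" else "dam_id"

    rows = []
    for rec in pedigree.itertuples():
        if rec.animal_id not in genotyped:
            continue
        focal = getattr(rec, parent_col)
        if focal is None or pd.isna(focal) or focal not in genotyped:
            continue
        if focal not in ped.index:
            continue
        frec = ped.loc[focal]
        gsire, gdam = frec["sire_id"], frec["dam_id"]
        gsire_g = gsire is not None and not pd.isna(gsire) and gsire in genotyped
        gdam_g = gdam is not None and not pd.isna(gdam) and gdam in genotyped
        if not (gsire_g or gdam_g):
            continue
        other = getattr(rec, other_col)
        rows.append(dict(
            offspring_id=rec.animal_id,
            focal_parent_id=focal,
            other_parent_id=None if (other is None or pd.isna(other)) else other,
            grandsire_id=gsire if gsire_g else None,
            granddam_id=gdam if gdam_g else None,
        ))
    return pd.DataFrame(rows, columns=FAMILY_COLUMNS)


def filter_by_panel(families: pd.DataFrame, pedigree: pd.DataFrame,
                    genotyped_ids,
                    min_marker_count: int = MIN_PANEL_MARKERS,
                    panel_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Keep families whose genotyped members are all on dense-enough panels.

    ``min_marker_count`` is the nominal marker count (e.g. 50,000) a member's
    panel must reach.  Unknown chip-class labels raise.
    """
    panel_sizes = CHIP_PANELS if panel_sizes is None else panel_sizes
    genotyped = set(genotyped_ids)
    chips = pedigree.set_index("animal_id")["chip_class"]

    def panel_of(animal) -> int:
        label = chips.loc[animal]
        if label not in panel_sizes:
            raise ValueError(f"unknown chip class {label!r} for animal {animal}")
        return panel_sizes[label]

    keep = []
    for rec in families.itertuples():
        members = [rec.offspring_id, rec.focal_parent_id,
                   rec.other_parent_id, rec.grandsire_id, rec.granddam_id]
        members = [a for a in members if a is not None and a in genotyped]
        keep.append(all(panel_of(a) >= min_marker_count for a in members))
    return families[pd.Series(keep, index=families.index)].reset_index(drop=True)
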