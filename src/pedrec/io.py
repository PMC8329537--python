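"""Genotype container and file I/O (VCF, pedigree/temperature CSV).

Genotypes are stored as allele-dosage matrices (animals x markers, int8,
values 0/1/2 with -1 for missing).  VCF files are read with cyvcf2 and
written as plain uncompressed VCF 4.2 with a GT field.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .markers import MarkerMap

MISSING = -1


@dataclass
class GenotypeData:
    """Dosage matrix aligned to a marker map."""

    ids: list[str]
    markers: MarkerMap
    dosages: np.ndarray  # (n_animals, n_markers) int8; -1 = missing

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.ids), len(self.markers)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.ids)} animals x {len(self.markers)} markers"
            )
        self._index = {a: i for i, a in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise ValueError("duplicate animal ids in genotype data")

    def __contains__(self, animal_id: str) -> bool:
        return animal_id in self._index

    def row(self, animal_id: str) -> np.ndarray:
        return self.dosages[self._index[animal_id]]

    def rows(self, animal_ids) -> np.ndarray:
        idx = [self._index[a] for a in animal_ids]
        return self.dosages[idx]

    def subset_markers(self, keep_idx: np.ndarray, markers: MarkerMap) -> "GenotypeData":
        return GenotypeData(self.ids, markers, self.dosages[:, keep_idx])


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gt: GenotypeData, path: str | Path) -> None:
    """Write genotypes as uncompressed VCF 4.2 (GT only, unphased)."""
    tab = gt.markers.table
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pedrec\n")
        for chrom in gt.markers.chroms:
            lo, hi = gt.markers.chrom_bounds(chrom)
            length = int(tab["pos"].iloc[hi - 1]) + 1000
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gt.ids) + "\n")
        ref = tab["ref"] if "ref" in tab else pd.Series(["A"] * len(tab))
        alt = tab["alt"] if "alt" in tab else pd.Series(["G"] * len(tab))
        dos = gt.dosages
        for j in range(len(tab)):
            row = tab.iloc[j]
            # VCF POS is 1-based
            fields = [str(row["chrom"]), str(int(row["pos"]) + 1), f"snp{j}",
                      str(ref.iloc[j]), str(alt.iloc[j]), ".", "PASS", ".", "GT"]
            fields.extend(_GT_STRINGS[int(d)] for d in dos[:, j])
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str | Path) -> GenotypeData:
    """Read biallelic SNP genotypes from a VCF into a dosage matrix."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    chroms, pos, ref, alt, rows = [], [], [], [], []
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    code = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        chroms.append(v.CHROM)
        pos.append(v.POS - 1)  # back to 0-based
        ref.append(v.REF)
        alt.append(v.ALT[0])
        rows.append(code[v.gt_types])
    vcf.close()
    table = pd.DataFrame({"chrom": chroms, "pos": pos, "ref": ref, "alt": alt})
    markers = MarkerMap(table)
    dosages = np.column_stack(rows) if rows else np.zeros((len(ids), 0), dtype=np.int8)
    # MarkerMap may have re-sorted rows; realign columns to the canonical order
    order = table.sort_values(
        ["chrom", "pos"], kind="mergesort",
        key=lambda s: s.map({c: i for i, c in enumerate(markers.chroms)}) if s.name == "chrom" else s,
    ).index.to_numpy()
    return GenotypeData(ids, markers, dosages[:, order])


def read_pedigree(path: str | Path) -> pd.DataFrame:
    """Read a pedigree CSV (animal_id, sire_id, dam_id, sex, birth_date, farm_id, chip_class)."""
    df = pd.read_csv(path, dtype={"animal_id": str, "sire_id": str, "dam_id": str, "farm_id": str})
    df["birth_date"] = pd.to_datetime(df["birth_date"])
    for col in ("sire_id", "dam_id"):
        df[col] = df[col].where(df[col].notna() & (df[col] != ""), None)
    return df


def write_pedigree(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["birth_date"] = pd.to_datetime(out["birth_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_temperature(path: str | Path) -> pd.DataFrame:
    """Read a monthly temperature CSV (farm_id, year, month, tavg_c)."""
    return pd.read_csv(path, dtype={"farm_id": str})


def write_temperature(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
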