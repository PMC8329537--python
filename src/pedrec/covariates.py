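"""Covariate construction: maternal age, birth year, temperature categories,
age groups, and the residual-adjusted recombination phenotype Y.

The phenotype entering the mixed model is not the raw genome-wide crossover
count R but its residual after regressing out nuisance ascertainment terms:
the genotyping-panel class of the dam (categorical) and her number of
informative markers (continuous).  Denser panels resolve more crossovers, so
without this adjustment panel density would masquerade as biology.
"""

from __future__ import annotations

import datetime as dt
import math
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import COLD_THRESHOLD_C, HOT_THRESHOLD_C

__all__ = [
    "maternal_age_months", "month_prior", "temp_month_prior",
    "categorize_temperature", "age_group", "adjust_rate",
    "build_analysis_table",
]


def _as_date(d) -> dt.date:
    if isinstance(d, str):
        return dt.date.fromisoformat(d)
    if isinstance(d, pd.Timestamp):
        return d.date()
    if isinstance(d, dt.datetime):
        return d.date()
    return d


def maternal_age_months(parent_birth, offspring_birth) -> int:
    """Complete calendar months between the dam's and the offspring's birth."""
    pb, ob = _as_date(parent_birth), _as_date(offspring_birth)
    if ob < pb:
        raise ValueError(f"offspring born {ob} before parent {pb}")
    months = (ob.year - pb.year) * 12 + (ob.month - pb.month)
    if ob.day < pb.day:
        months -= 1
    return months


def month_prior(year: int, month: int) -> tuple[int, int]:
    """Calendar month immediately preceding (year, month)."""
    return (year - 1, 12) if month == 1 else (year, month - 1)


def temp_month_prior(series: pd.DataFrame, birth, farm_id: str,
                     reference: str = "pre_birth_month") -> float | None:
    """Monthly average temperature for the month preceding a birth date.

    ``reference="pre_birth_month"`` uses the calendar month before the birth
    month; ``"conception_month"`` instead uses the calendar month before the
    estimated conception date (birth minus a 280-day gestation).  Returns
    ``None`` when the station/month is absent so callers can flag and
    exclude the record from temperature analyses.
    """
    b = _as_date(birth)
    if reference == "conception_month":
        b = b - dt.timedelta(days=280)
    elif reference != "pre_birth_month":
        raise ValueError(f"unknown temperature reference {reference!r}")
    y, m = month_prior(b.year, b.month)
    hit = series[(series["farm_id"] == str(farm_id))
                 & (series["year"] == y) & (series["month"] == m)]
    if hit.empty:
        return None
    return float(hit["tavg_c"].iloc[0])


def categorize_temperature(t: float, hot: float = HOT_THRESHOLD_C,
                           cold: float = COLD_THRESHOLD_C) -> str:
    """Three-level heat-stress category: hot iff t > hot, cold iff t < cold.

    Boundary values fall in "normal" (the thresholds are strict, matching
    'above'/'below' definitions).
    """
    t = float(t)
    if not math.isfinite(t):
        raise ValueError(f"temperature must be finite, got {t}")
    if t > hot:
        return "hot"
    if t < cold:
        return "cold"
    return "normal"


def age_group(age_months, start: int = 20, width: int = 10,
              n_groups: int = 10) -> np.ndarray:
    """Ten maternal-age bins: [20,30), [30,40), ... with an open last bin.

    Ages below ``start`` are returned as NaN (excluded from grouped
    displays); everything at or above the last cut falls in group
    ``n_groups``.
    """
    a = np.asarray(age_months, dtype=float)
    grp = np.floor((a - start) / width) + 1
    grp = np.where(a < start, np.nan, np.minimum(grp, n_groups))
    return grp


def adjust_rate(records: pd.DataFrame, count_col: str = "r",
                chip_col: str = "chip_class",
                informative_col: str = "n_informative") -> pd.Series:
    """Residualize crossover counts on panel class and informative-marker count.

    Ordinary least squares of R on an intercept, chip-class indicators and
    the informative-marker count; returns the residuals Y.  Residuals sum to
    zero within each chip class by construction.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to adjust crossover counts")
    y = records[count_col].to_numpy(dtype=float)
    X = pd.get_dummies(records[chip_col].astype(str), prefix="chip",
                       drop_first=True, dtype=float)
    X[informative_col] = records[informative_col].to_numpy(dtype=float)
    # drop constant columns (e.g. identical informative counts)
    X = X.loc[:, X.nunique() > 1]
    X.insert(0, "const", 1.0)
    fit = sm.OLS(y, X.to_numpy()).fit()
    return pd.Series(fit.resid, index=records.index, name="Y")


def build_analysis_table(counts: pd.DataFrame, pedigree: pd.DataFrame,
                         temperature: pd.DataFrame | None = None,
                         temperature_reference: str = "pre_birth_month",
                         hot: float = HOT_THRESHOLD_C,
                         cold: float = COLD_THRESHOLD_C) -> pd.DataFrame:
    """Assemble the analysis-ready table: one row per meiosis.

    ``counts`` needs meiosis_id, parent_id, offspring_id, r, n_informative,
    chip_class.  Output adds Y, A, A2, B, B2, T1, T2 and a
    ``has_temperature`` flag; records with a missing station-month keep
    T1/T2 as NA and are excluded from temperature analyses downstream.
    """
    ped = pedigree.set_index("animal_id")
    df = counts.copy()
    ages, byear, t1, t2, has_t = [], [], [], [], []
    if temperature is not None:
        tidx = {(str(r.farm_id), int(r.year), int(r.month)): float(r.tavg_c)
                for r in temperature.itertuples()}
    for rec in df.itertuples():
        pb = ped.loc[rec.parent_id, "birth_date"]
        ob = ped.loc[rec.offspring_id, "birth_date"]
        ages.append(maternal_age_months(pb, ob))
        byear.append(_as_date(pb).year)
        if temperature is None:
            t1.append(None); t2.append(None); has_t.append(False)
            continue
        b1 = _as_date(ob)
        if temperature_reference == "conception_month":
            b1 = b1 - dt.timedelta(days=280)
        y1, m1 = month_prior(b1.year, b1.month)
        v1 = tidx.get((str(ped.loc[rec.offspring_id, "farm_id"]), y1, m1))
        b2 = _as_date(pb)
        if temperature_reference == "conception_month":
            b2 = b2 - dt.timedelta(days=280)
        y2, m2 = month_prior(b2.year, b2.month)
        v2 = tidx.get((str(ped.loc[rec.parent_id, "farm_id"]), y2, m2))
        ok = v1 is not None and v2 is not None
        has_t.append(ok)
        t1.append(categorize_temperature(v1, hot, cold) if v1 is not None else None)
        t2.append(categorize_temperature(v2, hot, cold) if v2 is not None else None)
    df["A"] = np.asarray(ages, dtype=float)
    df["A2"] = df["A"] ** 2
    df["B"] = np.asarray(byear, dtype=float)
    df["B2"] = df["B"] ** 2
    df["T1"] = t1
    df["T2"] = t2
    df["has_temperature"] = has_t
    n_missing = int((~df["has_temperature"]).sum())
    if temperature is not None and n_missing:
        warnings.warn(f"{n_missing} meioses lack a station-month temperature "
                      "and are excluded from temperature analyses")
    df["Y"] = adjust_rate(df)
    return df
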