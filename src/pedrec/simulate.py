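"""Synthetic cattle pedigree, genotype, meiosis and temperature generator.

The generator emulates the structure of a genotyped national dairy pedigree:
a multi-generation pedigree with birth dates and farm assignments, ~50K-class
SNP panels on a desk-scale genome (default 5 autosomes x 400 markers), and
maternal genome-wide crossover counts that are heritable and overdispersed.

Crossover-count model
---------------------
The observed count of one maternal meiosis is Poisson given a latent rate

    lambda_i = alpha + beta . x_i + g_i + e_i          (floored at a small
                                                        positive value)

where ``x_i`` collects maternal age (months) and its square, dam birth year
and its square, and hot/cold indicators of the temperature category during
fetal development of the offspring (and optionally of the dam); ``g_i`` is
the dam's additive genetic value, a weighted sum of her centered marker
dosages, and ``e_i`` an independent Gaussian non-genetic deviation.  The
intercept ``alpha`` and the variance of ``e`` are calibrated so that the
marginal count distribution has mean ``base_rate_mu`` (default 23.2) and
variance ``rate_variance`` (default 98.3):

    var(count) = E[lambda] + var(lambda)
               = mu + sigma_g^2 + sigma_e^2 + var(beta . x).

Because the Poisson layer contributes the mean to the variance, the latent
variance is the remainder ``rate_variance - mu``; the genetic share is
``h2_true * rate_variance`` so heritability on the count scale equals
``h2_true``.

Crossover placement is uniform on genetic distance (no interference), which
is all the downstream interval-calling analysis uses.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig
from .covariates import categorize_temperature, month_prior
from .io import MISSING, GenotypeData
from .markers import MarkerMap

__all__ = [
    "SyntheticBundle", "RateStudy",
    "simulate_pedigree", "simulate_temperature", "draw_crossover_count",
    "simulate_meiosis", "generate_dataset", "simulate_rate_study",
    "rate_covariate_effect", "build_marker_map",
]


def add_months(date: dt.date, months: int) -> dt.date:
    """Shift a date by whole months, clipping the day to the target month."""
    y, m = divmod((date.year * 12 + date.month - 1) + months, 12)
    m += 1
    day = min(date.day, [31, 29 if y % 4 == 0 and (y % 100 != 0 or y % 400 == 0) else 28,
                         31, 30, 31, 30, 31, 31, 30, 31, 30, 31][m - 1])
    return dt.date(y, m, day)


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate a multi-generation pedigree with dates, farms and chip labels.

    Generation 1 animals are founders (no recorded parents); every animal of
    generation k>1 has a sire and dam drawn from generation k-1.  The dam's
    age at calving is drawn from the configured gamma law, so birth dates of
    offspring always follow their parents'.
    """
    if config.n_generations < 3:
        raise ValueError(
            "n_generations must be >= 3: three-generation families need "
            "grandparents, parents and offspring"
        )
    rng = np.random.default_rng(config.seed) if rng is None else rng
    farms = [f"FARM{i:02d}" for i in range(config.n_farms)]
    chips = list(config.chip_mix)
    chip_p = np.array([config.chip_mix[c] for c in chips], dtype=float)
    chip_p /= chip_p.sum()

    rows = []
    prev_m: list[dict] = []
    prev_f: list[dict] = []
    y0, y1 = config.founder_birth_years
    for gen in range(1, config.n_generations + 1):
        cur_m, cur_f = [], []
        for i in range(config.n_founders):
            aid = f"G{gen}_{i:04d}"
            sex = "M" if i % 2 == 0 else "F"
            chip = chips[rng.choice(len(chips), p=chip_p)]
            if gen == 1:
                birth = dt.date(int(rng.integers(y0, y1 + 1)),
                                int(rng.integers(1, 13)), int(rng.integers(1, 29)))
                farm = farms[rng.integers(len(farms))]
                sire = dam = None
                age = np.nan
            else:
                dam_rec = prev_f[rng.integers(len(prev_f))]
                shape, scale = config.age_gamma
                age = int(np.clip(20 + rng.gamma(shape, scale), 20, 180))
                birth = add_months(dam_rec["birth_date"], age)
                # sire must also precede the offspring in birth date
                eligible = [r for r in prev_m if r["birth_date"] < birth]
                while not eligible:
                    age += 6
                    birth = add_months(dam_rec["birth_date"], age)
                    eligible = [r for r in prev_m if r["birth_date"] < birth]
                sire_rec = eligible[rng.integers(len(eligible))]
                farm = dam_rec["farm_id"]
                sire, dam = sire_rec["animal_id"], dam_rec["animal_id"]
            rec = dict(animal_id=aid, sire_id=sire, dam_id=dam, sex=sex,
                       birth_date=birth, farm_id=farm, chip_class=chip,
                       generation=gen, dam_age_months=age)
            rows.append(rec)
            (cur_m if sex == "M" else cur_f).append(rec)
        prev_m, prev_f = cur_m, cur_f
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# temperature
# ---------------------------------------------------------------------------

def seasonal_mean(config: SimConfig, month) -> np.ndarray:
    """Expected monthly average temperature (degC); annual cosine peaking in July."""
    mean, amp, _ = config.seasonal_temp
    return mean + amp * np.cos(2 * np.pi * (np.asarray(month, dtype=float) - 7.0) / 12.0)


def simulate_temperature(config: SimConfig, farms: list[str],
                         years: tuple[int, int],
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Monthly average temperatures per farm: seasonal cosine plus noise."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    _, _, noise = config.seasonal_temp
    yy = np.arange(years[0], years[1] + 1)
    months = np.arange(1, 13)
    out = []
    for farm in farms:
        for y in yy:
            t = seasonal_mean(config, months) + noise * rng.standard_normal(12)
            out.append(pd.DataFrame({"farm_id": farm, "year": y, "month": months,
                                     "tavg_c": np.round(t, 3)}))
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# crossover counts
# ---------------------------------------------------------------------------

def rate_covariate_effect(config: SimConfig, age_months, birth_year,
                          t1_cat, t2_cat) -> np.ndarray:
    """Raw fixed-effect contribution beta . x on the latent-rate scale."""
    a = np.asarray(age_months, dtype=float)
    b = np.asarray(birth_year, dtype=float)
    t1 = np.asarray(t1_cat, dtype=object)
    t2 = np.asarray(t2_cat, dtype=object)
    eff = (config.beta_age * a + config.beta_age2 * a ** 2
           + config.beta_birthyear * b + config.beta_birthyear2 * b ** 2)
    eff = eff + np.where(t1 == "hot", config.beta_hot, 0.0)
    eff = eff + np.where(t1 == "cold", config.beta_cold, 0.0)
    eff = eff + np.where(t2 == "hot", config.beta_t2_hot, 0.0)
    eff = eff + np.where(t2 == "cold", config.beta_t2_cold, 0.0)
    return eff


def calibrate_rate_model(config: SimConfig, raw_effects: np.ndarray) -> tuple[float, float]:
    """Intercept and non-genetic latent variance matching the target moments.

    Returns ``(alpha, sigma_e2_latent)`` such that the marginal count mean is
    ``base_rate_mu`` and the marginal count variance is ``rate_variance``
    given the realized covariate spread and the genetic variance implied by
    ``h2_true``.
    """
    raw = np.asarray(raw_effects, dtype=float)
    alpha = config.base_rate_mu - float(raw.mean()) if raw.size else config.base_rate_mu
    var_f = float(raw.var()) if raw.size else 0.0
    sigma_e2 = max(config.rate_variance - config.base_rate_mu - config.sigma_g2 - var_f, 0.0)
    return alpha, sigma_e2


def draw_crossover_count(mu, covariate_effect, g, rng: np.random.Generator,
                         floor: float = 0.5) -> np.ndarray:
    """Poisson crossover count given latent rate mu + beta.x + g (floored)."""
    lam = np.maximum(np.asarray(mu, dtype=float) + covariate_effect + g, floor)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# meiosis / gametes
# ---------------------------------------------------------------------------

def simulate_meiosis(hap_pair: np.ndarray, marker_cm: np.ndarray,
                     chrom_cm: float, n_crossovers: int,
                     rng: np.random.Generator):
    """One chromosome's gamete given the parent's haplotype pair.

    Crossover positions are uniform on genetic distance (no interference).
    Returns ``(gamete, strands, xo_cm)`` where ``strands`` gives the parental
    haplotype of origin (0/1) at every marker.
    """
    if n_crossovers < 0:
        raise ValueError("n_crossovers must be >= 0")
    hap_pair = np.asarray(hap_pair)
    if hap_pair.shape[0] != marker_cm.shape[0]:
        raise ValueError("haplotypes and marker map differ in length")
    xo = np.sort(rng.uniform(0.0, chrom_cm, size=n_crossovers))
    start = int(rng.integers(2))
    strands = (start + np.searchsorted(xo, marker_cm, side="left")) % 2
    gamete = hap_pair[np.arange(hap_pair.shape[0]), strands]
    return gamete, strands, xo


def build_marker_map(config: SimConfig, rng: np.random.Generator) -> MarkerMap:
    """Random marker positions per chromosome with a uniform genetic map."""
    L_cm = config.map_length_per_chrom * 100.0
    frames = []
    bases = np.array(list("ACGT"))
    for c in range(1, config.n_chromosomes + 1):
        pos = np.sort(rng.choice(config.bp_per_chrom // 100, size=config.markers_per_chrom,
                                 replace=False)) * 100 + 50
        cm = pos / config.bp_per_chrom * L_cm
        ref = bases[rng.integers(0, 4, config.markers_per_chrom)]
        alt_off = rng.integers(1, 4, config.markers_per_chrom)
        alt = bases[(np.searchsorted(bases, ref) + alt_off) % 4]
        frames.append(pd.DataFrame({"chrom": str(c), "pos": pos, "ref": ref,
                                    "alt": alt, "cm": cm}))
    return MarkerMap(pd.concat(frames, ignore_index=True))


def _gamete_genome(haps: np.ndarray, mm: MarkerMap, chrom_cm: dict[str, float],
                   chrom_bp: int, n_total: int, rng: np.random.Generator):
    """Genome-wide gamete: allocate crossovers to chromosomes by map length.

    ``chrom_bp`` must be the physical length the marker cM positions were
    scaled against, so the cM -> bp conversion of event positions stays on
    the same linear map as the markers.
    """
    lens = np.array([chrom_cm[c] for c in mm.chroms])
    alloc = rng.multinomial(n_total, lens / lens.sum())
    gamete = np.empty(len(mm), dtype=np.int8)
    events = []
    cm_all = mm.table["cm"].to_numpy()
    for c, k in zip(mm.chroms, alloc):
        lo, hi = mm.chrom_bounds(c)
        gam, _, xo = simulate_meiosis(haps[lo:hi], cm_all[lo:hi], chrom_cm[c], int(k), rng)
        gamete[lo:hi] = gam
        # uniform genetic map: cM -> bp is linear
        bp = xo / chrom_cm[c] * chrom_bp
        events.extend((c, int(b)) for b in bp)
    return gamete, events


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    """A complete simulated study with ground truth for every stage."""

    config: SimConfig
    pedigree: pd.DataFrame
    genotypes: GenotypeData
    temperature: pd.DataFrame
    truth_meioses: pd.DataFrame   # one row per maternal meiosis
    truth_events: pd.DataFrame    # true crossover positions (maternal)
    truth_animals: pd.DataFrame   # true additive genetic values
    haplotypes: np.ndarray = field(repr=False)  # pre-error (n, m, 2)

    def write(self, outdir) -> dict[str, str]:
        from pathlib import Path

        from .io import write_pedigree, write_temperature, write_vcf

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        ped_cols = ["animal_id", "sire_id", "dam_id", "sex", "birth_date",
                    "farm_id", "chip_class"]
        write_pedigree(self.pedigree[ped_cols], out / "pedigree.csv")
        paths["pedigree"] = str(out / "pedigree.csv")
        write_vcf(self.genotypes, out / "genotypes.vcf")
        paths["genotypes"] = str(out / "genotypes.vcf")
        write_temperature(self.temperature, out / "temperature.csv")
        paths["temperature"] = str(out / "temperature.csv")
        for name in ("truth_meioses", "truth_events", "truth_animals"):
            p = out / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False)
            paths[name] = str(p)
        return paths


def _lookup_temp(temp_idx: dict, farm: str, year: int, month: int):
    return temp_idx.get((farm, year, month))


def generate_dataset(config: SimConfig) -> SyntheticBundle:
    """Simulate pedigree, temperatures, genotypes and maternal meioses.

    Offspring genotypes are exact Mendelian transmissions of parental
    haplotypes (with simulated crossovers) before genotyping errors and
    missingness are injected at the configured rates.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ped = simulate_pedigree(config, rng)
    farms = sorted(ped["farm_id"].unique())
    years = (min(d.year for d in ped["birth_date"]) - 1,
             max(d.year for d in ped["birth_date"]))
    temp = simulate_temperature(config, farms, years, rng)
    temp_idx = {(r.farm_id, int(r.year), int(r.month)): float(r.tavg_c)
                for r in temp.itertuples()}

    mm = build_marker_map(config, rng)
    m = len(mm)
    n = len(ped)
    idx = {a: i for i, a in enumerate(ped["animal_id"])}
    chrom_cm = {c: config.map_length_per_chrom * 100.0 for c in mm.chroms}

    # founder allele frequencies, marker effects for the polygenic value
    lo_maf, hi_maf = config.founder_maf_range
    p = rng.uniform(lo_maf, hi_maf, m)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    u = rng.normal(0.0, np.sqrt(config.sigma_g2 / denom), m)

    # covariates of every maternal meiosis (non-founders), then calibration
    nonf = ped[ped["generation"] > 1]
    ped_by_id = ped.set_index("animal_id")
    A = nonf["dam_age_months"].to_numpy(dtype=float)
    dam_birth = ped_by_id.loc[nonf["dam_id"], "birth_date"].to_list()
    B = np.array([d.year for d in dam_birth], dtype=float)
    t1_raw, t2_raw, t1c, t2c = [], [], [], []
    for rec, db in zip(nonf.itertuples(), dam_birth):
        y1, m1 = month_prior(rec.birth_date.year, rec.birth_date.month)
        t1 = _lookup_temp(temp_idx, rec.farm_id, y1, m1)
        dam_farm = ped_by_id.loc[rec.dam_id, "farm_id"]
        y2, m2 = month_prior(db.year, db.month)
        t2 = _lookup_temp(temp_idx, dam_farm, y2, m2)
        t1_raw.append(t1)
        t2_raw.append(t2)
        t1c.append(categorize_temperature(t1) if t1 is not None else "normal")
        t2c.append(categorize_temperature(t2) if t2 is not None else "normal")
    raw_eff = rate_covariate_effect(config, A, B, t1c, t2c)
    alpha, sigma_e2 = calibrate_rate_model(config, raw_eff)

    # build haplotypes generation by generation
    haps = np.zeros((n, m, 2), dtype=np.int8)
    g_val = np.zeros(n)
    founders = ped[ped["generation"] == 1]
    for rec in founders.itertuples():
        i = idx[rec.animal_id]
        haps[i] = (rng.random((m, 2)) < p[:, None]).astype(np.int8)
        g_val[i] = float((haps[i].sum(axis=1) - 2 * p) @ u)

    meio_rows, event_rows = [], []
    e_lat = rng.normal(0.0, np.sqrt(sigma_e2), len(nonf))
    for k, rec in enumerate(nonf.itertuples()):
        i = idx[rec.animal_id]
        dam_i, sire_i = idx[rec.dam_id], idx[rec.sire_id]
        lam = max(alpha + raw_eff[k] + g_val[dam_i] + e_lat[k], config.rate_floor)
        r_mat = int(rng.poisson(lam))
        r_pat = int(rng.poisson(config.base_rate_mu))
        gam_m, ev_m = _gamete_genome(haps[dam_i], mm, chrom_cm,
                                     config.bp_per_chrom, r_mat, rng)
        gam_p, _ = _gamete_genome(haps[sire_i], mm, chrom_cm,
                                  config.bp_per_chrom, r_pat, rng)
        haps[i, :, 0] = gam_m
        haps[i, :, 1] = gam_p
        g_val[i] = float((haps[i].sum(axis=1) - 2 * p) @ u)
        mid = f"{rec.dam_id}|{rec.animal_id}"
        meio_rows.append(dict(meiosis_id=mid, parent_id=rec.dam_id,
                              offspring_id=rec.animal_id, n_crossovers=r_mat,
                              lam=lam, A=A[k], B=B[k], T1=t1c[k], T2=t2c[k],
                              t1_c=t1_raw[k], t2_c=t2_raw[k]))
        for c, bp in ev_m:
            event_rows.append(dict(meiosis_id=mid, chrom=c, pos_bp=bp))

    dosages = haps.sum(axis=2).astype(np.int8)
    if config.genotyping_error_rate > 0:
        emask = rng.random(dosages.shape) < config.genotyping_error_rate
        shift = rng.integers(1, 3, size=dosages.shape).astype(np.int8)
        dosages = np.where(emask, (dosages + shift) % 3, dosages).astype(np.int8)
    if config.missing_rate > 0:
        mmask = rng.random(dosages.shape) < config.missing_rate
        dosages = np.where(mmask, np.int8(MISSING), dosages)

    gt = GenotypeData(list(ped["animal_id"]), mm, dosages)
    truth_meioses = pd.DataFrame(meio_rows)
    truth_events = pd.DataFrame(event_rows, columns=["meiosis_id", "chrom", "pos_bp"])
    truth_animals = pd.DataFrame({"animal_id": ped["animal_id"], "g": g_val})
    return SyntheticBundle(config=config, pedigree=ped, genotypes=gt,
                           temperature=temp, truth_meioses=truth_meioses,
                           truth_events=truth_events, truth_animals=truth_animals,
                           haplotypes=haps)


# ---------------------------------------------------------------------------
# direct phenotype study (no gamete placement) for estimator experiments
# ---------------------------------------------------------------------------

@dataclass
class RateStudy:
    """Crossover-count phenotypes with genotypes and full latent truth."""

    table: pd.DataFrame          # parent_id, r, A, A2, B, B2, T1, T2
    parent_ids: list[str]
    dosages: np.ndarray          # founders x markers
    g: np.ndarray                # true genetic values per parent
    lam: np.ndarray              # latent rates per meiosis
    alpha: float
    sigma_e2_latent: float


def simulate_rate_study(config: SimConfig, n_parents: int,
                        meioses_per_parent: int = 1,
                        rng: np.random.Generator | None = None,
                        n_markers: int = 800) -> RateStudy:
    """Simulate counts from the generative rate model for unrelated dams.

    This is the count-generating layer of :func:`generate_dataset` without
    gamete placement: founder genotypes give each dam a polygenic value,
    covariates are drawn from the same laws (age gamma, uniform birth months
    through the seasonal temperature model), and counts are Poisson around
    the calibrated latent rate.  Used for calibration and estimator-recovery
    experiments at sizes where full transmission simulation is unnecessary.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lo_maf, hi_maf = config.founder_maf_range
    p = rng.uniform(lo_maf, hi_maf, n_markers)
    dos = rng.binomial(2, p, size=(n_parents, n_markers)).astype(np.int8)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    u = rng.normal(0.0, np.sqrt(config.sigma_g2 / denom), n_markers)
    g = (dos - 2 * p) @ u
    parent_ids = [f"P{i:05d}" for i in range(n_parents)]

    n = n_parents * meioses_per_parent
    pidx = np.repeat(np.arange(n_parents), meioses_per_parent)
    shape, scale = config.age_gamma
    A = np.clip(20 + rng.gamma(shape, scale, n), 20, 180).astype(int).astype(float)
    B = rng.integers(2005, 2016, n).astype(float)
    _, _, noise = config.seasonal_temp

    def draw_cats(months):
        t = seasonal_mean(config, months) + noise * rng.standard_normal(n)
        return np.array([categorize_temperature(v) for v in t], dtype=object)

    T1 = draw_cats(rng.integers(1, 13, n))
    T2 = draw_cats(rng.integers(1, 13, n))
    raw = rate_covariate_effect(config, A, B, T1, T2)
    alpha, sigma_e2 = calibrate_rate_model(config, raw)
    e = rng.normal(0.0, np.sqrt(sigma_e2), n)
    lam = np.maximum(alpha + raw + g[pidx] + e, config.rate_floor)
    r = rng.poisson(lam)
    table = pd.DataFrame({
        "parent_id": [parent_ids[i] for i in pidx],
        "r": r, "A": A, "A2": A ** 2, "B": B, "B2": B ** 2,
        "T1": T1, "T2": T2,
    })
    return RateStudy(table=table, parent_ids=parent_ids, dosages=dos, g=g,
                     lam=lam, alpha=alpha, sigma_e2_latent=sigma_e2)
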