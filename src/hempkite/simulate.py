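"""Synthetic hybrid-trial generator.

Builds virtual common-parent hemp trials with the statistical structure the
analysis modules assume, so the whole pipeline is exercisable without field
data:

* 23 families × ~15 progeny sharing a common parent, with a major-effect
  flowering locus (common parent heterozygous) whose Mendelian sampling
  reproduces all-early / all-late / ~1:1 / ~2:1 family segregation patterns;
* a log–log allometric cascade rooted at basal stem diameter (the trial's
  best single size predictor): height scales as diameter^0.65 and wet
  biomass as diameter^1.7, with measurement error on both log axes placed
  proportionally to the signal spread — the errors-in-both-variables
  structure under which ranged-major-axis regression is consistent;
* configurable per-trait half-sib heritability via σ²_F = h²·σ²_P/4 on the
  log latent scale;
* the packaged wet→dry biomass calibrations with their stated residual sds;
* powdery-mildew progress negatively coupled to flowering day;
* chemotype-stratified cannabinoid profiles (CBD-dominant majority);
* planted aerial scenes on the trial's 1.83 m × 1.22 m grid.

Every generator is a pure function of (config, seed): the master seed fans
out into independent per-module streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .growth import GrowthSeries, flowering_class
from .uas import Scene
from .yields import REFERENCE_CALIBRATION, cannabinoid_yield

__all__ = ["TrialConfig", "TruthBundle", "simulate_trial", "simulate_growth",
           "simulate_scene", "simulate_half_sib_trait"]

LOG10E = math.log10(math.e)


def _noise_fraction(r_squared: float) -> float:
    """Proportional error level f giving a log–log fit quality R² under the
    symmetric errors-in-both-variables construction: R² = 1/(1+f²)²."""
    return math.sqrt(1.0 / math.sqrt(r_squared) - 1.0)


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu_log10, sigma_log10) of a lognormal with given mean and CV."""
    s2 = math.log(1.0 + cv * cv)
    mu_ln = math.log(mean) - s2 / 2.0
    return mu_ln * LOG10E, math.sqrt(s2) * LOG10E


# Cross types: (seed-parent genotype, pollen-parent genotype) at the
# major flowering locus; 'e' is the recessive early allele.  The default
# mix yields all-late, ~3:1, ~1:1, and all-early (selfed S2-like) families.
_DEFAULT_CROSSES = (
    [("ee", "ee")] * 2 + [("EE", "Ee")] * 6 + [("Ee", "Ee")] * 7
    + [("ee", "Ee")] * 8
)

_GAMETES = {"EE": ("E", "E"), "Ee": ("E", "e"), "ee": ("e", "e")}


@dataclass
class TrialConfig:
    """Generator configuration; defaults are the trial's study conditions."""

    n_families: int = 23
    progeny_per_family: int = 15
    family_crosses: list = field(default_factory=lambda: list(_DEFAULT_CROSSES))

    # flowering major-locus phenotype distributions (DAP)
    early_mean: float = 42.0
    early_sd: float = 3.0
    late_mean: float = 75.0
    late_sd: float = 6.0

    # allometric cascade (log10–log10 exponents and fit qualities)
    dia_mean: float = 4.44
    dia_cv: float = 0.23
    ht_exponent: float = 0.65
    ht_mean: float = 157.7
    wbm_exponent: float = 1.7
    wbm_mean: float = 6.31
    allometry_r2: float = 0.78      # for both HT–DIA and WBM–DIA pairs
    mcd_exponent: float = 0.6
    mcd_mean: float = 125.9
    mcd_cv: float = 0.19

    # foliar cascade
    li_mean: float = 0.563          # leaves per cm³ stem volume
    li_sigma_log10: float = 0.20
    lfdw_exponent: float = -0.71
    lfdw_mean: float = 0.25
    lfdw_r2: float = 0.66
    spa_exponent: float = 2.08
    spa_mean: float = 34.8
    spa_r2: float = 0.55
    sla_mean: float = 167.2
    sla_cv: float = 0.10

    # heritability targets (log latent scale), σ²_F = h²·σ²_P/4
    h2: dict = field(default_factory=lambda: {"DIA": 0.85, "CBD": 0.86})

    # disease coupling
    pm_base: tuple = (16.0, 37.0, 58.0)     # mean severities at 71/86/97 DAP
    pm_flower_corr: float = -0.6            # latent coupling to flowering day
    pm_sigma_ln: float = 0.52

    # cannabinoids: chemotype mix and total-potential means (% dry mass)
    chemotype_probs: dict = field(default_factory=lambda: {
        "CBD-dominant": 0.87, "intermediate": 0.10, "THC-dominant": 0.03})
    cbd_mean: float = 8.9
    minor_means: dict = field(default_factory=lambda: {
        "CBC": 0.52, "CBG": 0.27, "THCV": 0.03, "CBDV": 0.16, "CBL": 0.04})
    decarb_factor: float = 0.877

    master_seed: int = 0

    def validate(self) -> None:
        if self.n_families < 1 or self.progeny_per_family < 1:
            raise ValueError("family counts must be positive")
        if len(self.family_crosses) < self.n_families:
            raise ValueError("need a cross type for every family")
        for r2 in (self.allometry_r2, self.lfdw_r2, self.spa_r2):
            if not 0 < r2 <= 1:
                raise ValueError(f"fit quality must be in (0, 1], got {r2}")
        for t, h in self.h2.items():
            if not 0 <= h <= 1:
                raise ValueError(f"h2[{t!r}] must lie in [0, 1]")
        if abs(sum(self.chemotype_probs.values()) - 1.0) > 1e-9:
            raise ValueError("chemotype probabilities must sum to 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrialConfig":
        d = dict(d)
        d["family_crosses"] = [tuple(c) for c in d.get(
            "family_crosses", _DEFAULT_CROSSES)]
        return cls(**d)


@dataclass
class TruthBundle:
    """Ground truth recorded by the generator for recovery tests."""

    config: TrialConfig
    family_crosses: list
    genotypes: np.ndarray          # per-plant flowering genotype
    flowering_day: np.ndarray
    latent_log_dia: np.ndarray     # ξ: error-free log10 diameter
    latent_log_li: np.ndarray
    h2: dict
    exponents: dict
    scene_centers: np.ndarray | None = None
    scene_heights: np.ndarray | None = None


def _cross_progeny(seed_gt: str, pollen_gt: str, n: int,
                   rng: np.random.Generator) -> np.ndarray:
    gs = _GAMETES[seed_gt]
    gp = _GAMETES[pollen_gt]
    a = rng.integers(0, 2, n)
    b = rng.integers(0, 2, n)
    return np.array(["".join(sorted(gs[i] + gp[j], key=str.upper))
                     for i, j in zip(a, b)])


def simulate_half_sib_trait(h2: float, n_families: int, n_per_family: int,
                            sigma_p: float = 1.0, mean: float = 0.0,
                            seed: int | None = None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """A single trait under the one-way half-sib model: family effects with
    σ²_F = h²·σ²_P/4 plus residuals making up the phenotypic variance.

    Returns (values, family_ids)."""
    if not 0 <= h2 <= 1:
        raise ValueError("h2 must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    s2f = h2 * sigma_p**2 / 4.0
    s2e = sigma_p**2 - s2f
    fam = np.repeat(np.arange(n_families), n_per_family)
    eff = rng.normal(0.0, math.sqrt(s2f), n_families)
    y = mean + eff[fam] + rng.normal(0.0, math.sqrt(s2e), fam.size)
    return y, fam


def simulate_trial(cfg: TrialConfig | None = None,
                   seed: int | None = None) -> tuple[pd.DataFrame, TruthBundle]:
    """Generate one virtual trial: a per-plant trait table plus ground truth.

    Deterministic for a fixed (config, seed); ``seed`` overrides the
    config's master seed when given.
    """
    cfg = cfg or TrialConfig()
    cfg.validate()
    master = cfg.master_seed if seed is None else seed
    streams = np.random.SeedSequence(master).spawn(8)
    rng_gen = np.random.default_rng(streams[0])     # genetics / flowering
    rng_size = np.random.default_rng(streams[1])    # size cascade
    rng_fol = np.random.default_rng(streams[2])     # foliar cascade
    rng_arch = np.random.default_rng(streams[3])    # canopy shape
    rng_dis = np.random.default_rng(streams[4])     # disease
    rng_bm = np.random.default_rng(streams[5])      # biomass calibration
    rng_cb = np.random.default_rng(streams[6])      # cannabinoids

    k, m = cfg.n_families, cfg.progeny_per_family
    n = k * m
    fam = np.repeat(np.arange(k), m)
    fam_ids = np.array([f"F{j + 1:02d}" for j in range(k)])

    # ---- flowering genotypes and days -----------------------------------
    crosses = cfg.family_crosses[:k]
    genotypes = np.concatenate([
        _cross_progeny(s, p, m, rng_gen) for s, p in crosses])
    is_early = genotypes == "ee"
    ptfd = np.where(
        is_early,
        rng_gen.normal(cfg.early_mean, cfg.early_sd, n),
        rng_gen.normal(cfg.late_mean, cfg.late_sd, n),
    )
    ptfd = np.clip(ptfd, 25.0, 95.0)
    tfd = ptfd + rng_gen.normal(9.5, 2.0, n)        # terminal ~1.5 wk later
    fclass = np.array([flowering_class(d) for d in ptfd])

    # leaflet number tied to flowering class (means 3.9 / 5.3 / 6.3)
    lfltn_mean = np.select(
        [fclass == "early", fclass == "mid"], [3.9, 5.3], default=6.3)
    lfltn = np.clip(
        np.round((lfltn_mean + rng_gen.normal(0, 0.9, n) - 3.0) / 2.0)
        * 2.0 + 3.0, 3, 9)

    # ---- size cascade rooted at basal stem diameter ---------------------
    f = _noise_fraction(cfg.allometry_r2)
    mu_dia, sigma_p = _lognormal_params(cfg.dia_mean, cfg.dia_cv)
    sigma_xi = sigma_p / math.sqrt(1.0 + f * f)     # error-free latent sd
    delta = f * sigma_xi                            # measurement error sd

    h2_dia = cfg.h2.get("DIA", 0.85)
    s_f = math.sqrt(h2_dia / 4.0) * sigma_p
    s_bio = math.sqrt(max(sigma_xi**2 - s_f**2, 1e-12))
    fam_eff = rng_size.normal(0.0, s_f, k)
    xi = fam_eff[fam] + rng_size.normal(0.0, s_bio, n)      # centered latent
    log_dia = mu_dia + xi + rng_size.normal(0.0, delta, n)
    dia = 10.0**log_dia

    def _allo(exponent: float, mean: float, noise: np.ndarray) -> np.ndarray:
        """y = c·(latent dia)^exponent · 10^noise, with c set so the
        lognormal mean of y equals ``mean``."""
        s2_log10 = (exponent * sigma_xi) ** 2 + float(np.var(noise))
        mu = math.log10(mean) - s2_log10 * math.log(10.0) / 2.0
        return 10.0 ** (mu + exponent * xi + noise)

    # Height noise budget: sd = exponent·delta (the symmetric share matching
    # the x measurement error).  Half of its variance is a growth-duration
    # component that follows flowering day (late plants grow longer, hence
    # taller); the rest is independent scatter.
    zf = (ptfd - ptfd.mean()) / ptfd.std()
    tau_ht = cfg.ht_exponent * delta
    rho = 0.5
    ht_noise = tau_ht * (rho * zf
                         + math.sqrt(1.0 - rho**2) * rng_size.normal(0, 1, n))
    ht = _allo(cfg.ht_exponent, cfg.ht_mean, ht_noise)
    tau_wbm = cfg.wbm_exponent * delta
    wbm = _allo(cfg.wbm_exponent, cfg.wbm_mean,
                rng_size.normal(0.0, tau_wbm, n))

    # canopy diameter: shallower scaling with its own scatter
    _, sigma_mcd = _lognormal_params(cfg.mcd_mean, cfg.mcd_cv)
    sig_sig = cfg.mcd_exponent * sigma_xi
    e_mcd = math.sqrt(max(sigma_mcd**2 - sig_sig**2, 1e-12))
    s2_ln = sigma_mcd**2 * (math.log(10.0))**2
    mu_mcd = math.log10(cfg.mcd_mean) - s2_ln / 2.0 * LOG10E
    mcd = 10.0 ** (mu_mcd + cfg.mcd_exponent * xi
                   + rng_arch.normal(0.0, e_mcd, n))

    # kite verticals: MCDH a fraction of height, TRKL short and variable
    u = np.clip(rng_arch.normal(0.545, 0.06, n), 0.25, 0.85)
    mcdh = u * ht
    mu_t, sig_t = _lognormal_params(12.2, 0.70)
    trkl = np.minimum(10.0 ** rng_arch.normal(mu_t, sig_t, n), 0.8 * mcdh)
    bpair = np.clip(np.round(
        10.0 ** rng_arch.normal(*_lognormal_params(7.45, 0.26), n)), 4, 16)

    # ---- foliar cascade off a leafing-intensity latent ------------------
    f_li = _noise_fraction(cfg.lfdw_r2)
    sigma_lam = cfg.li_sigma_log10 / math.sqrt(1.0 + f_li**2)
    lam_from_size = -1.4 * xi
    s_extra = math.sqrt(max(sigma_lam**2 - (1.4 * sigma_xi)**2, 1e-12))
    lam = lam_from_size + rng_fol.normal(0.0, s_extra, n)
    delta_li = f_li * sigma_lam
    mu_li = math.log10(cfg.li_mean) - (
        cfg.li_sigma_log10**2 * (math.log(10.0))**2) / 2.0 * LOG10E
    li = 10.0 ** (mu_li + lam + rng_fol.normal(0.0, delta_li, n))

    def _foliar_allo(exponent, mean, tau, rng):
        s2_ln = ((exponent * sigma_lam)**2 + tau**2) * (math.log(10.0))**2
        mu = math.log10(mean) - s2_ln / 2.0 * LOG10E
        return 10.0 ** (mu + exponent * lam + rng.normal(0.0, tau, n))

    lfdw = _foliar_allo(cfg.lfdw_exponent, cfg.lfdw_mean,
                        abs(cfg.lfdw_exponent) * delta_li, rng_fol)
    # SPA noise set from its printed fit quality (x-error fixed by the
    # leaf-mass pair, so this pair is slightly noisier than symmetric)
    r_spa = math.sqrt(cfg.spa_r2)
    beta_sig = cfg.spa_exponent * sigma_lam
    sd_y = beta_sig / (r_spa * math.sqrt(1.0 + f_li**2))
    tau_spa = math.sqrt(max(sd_y**2 - beta_sig**2, 1e-12))
    spa = _foliar_allo(cfg.spa_exponent, cfg.spa_mean, tau_spa, rng_fol)

    mu_sla, sig_sla = _lognormal_params(cfg.sla_mean, cfg.sla_cv)
    sla = 10.0 ** rng_fol.normal(mu_sla, sig_sla, n)
    lfa = sla * lfdw
    ptdw = 10.0 ** rng_fol.normal(*_lognormal_params(0.03, 0.54), n)
    pta = spa * ptdw
    lfl = 10.0 ** rng_fol.normal(*_lognormal_params(14.3, 0.11), n)
    mlfw = 10.0 ** rng_fol.normal(*_lognormal_params(1.70, 0.21), n)
    stem_vol = (math.pi / 3.0) * (dia / 2.0) ** 2 * ht
    leaf_count = li * stem_vol

    # ---- disease progress coupled to flowering --------------------------
    s_lat = (cfg.pm_flower_corr * zf
             + math.sqrt(1 - cfg.pm_flower_corr**2) * rng_dis.normal(0, 1, n))
    gamma = np.exp(cfg.pm_sigma_ln * s_lat - cfg.pm_sigma_ln**2 / 2.0)
    pm = {d: np.clip(base * gamma + rng_dis.normal(0, 2.0, n), 0.0, 100.0)
          for d, base in zip((71, 86, 97), cfg.pm_base)}

    # ---- biomass via the packaged calibration (with its residual noise) -
    cal = REFERENCE_CALIBRATION
    dbm = np.maximum(cal.dbm.intercept + cal.dbm.slope * wbm
                     + rng_bm.normal(0, cal.dbm.residual_sd, n), 0.05)
    dsbm = np.maximum(cal.dsbm.intercept + cal.dsbm.slope * wbm
                      + rng_bm.normal(0, cal.dsbm.residual_sd, n), 0.05)

    # ---- cannabinoids ---------------------------------------------------
    chems = list(cfg.chemotype_probs)
    fam_chem = rng_cb.choice(chems, size=k,
                             p=[cfg.chemotype_probs[c] for c in chems])
    chem = fam_chem[fam]
    h2_cbd = cfg.h2.get("CBD", 0.86)
    mu_cbd, sig_cbd = _lognormal_params(cfg.cbd_mean, 0.30)
    fam_cbd = rng_cb.normal(0.0, math.sqrt(h2_cbd / 4.0) * sig_cbd, k)
    res_cbd = rng_cb.normal(
        0.0, math.sqrt(max(sig_cbd**2 * (1 - h2_cbd / 4.0), 1e-12)), n)
    potency = 10.0 ** (mu_cbd + fam_cbd[fam] + res_cbd)   # total major cannabinoid
    ratio_td = np.select(
        [chem == "CBD-dominant", chem == "intermediate"],
        [rng_cb.uniform(0.03, 0.06, n), rng_cb.uniform(0.8, 1.2, n)],
        default=rng_cb.uniform(15.0, 25.0, n))            # THC:CBD ratio
    cbd_tot = potency / (1.0 + ratio_td)
    thc_tot = potency - cbd_tot
    minors = {c: 10.0 ** rng_cb.normal(*_lognormal_params(mu, 0.6), n)
              for c, mu in cfg.minor_means.items()}
    totals = {"THC": thc_tot, "CBD": cbd_tot, **minors}
    cb_total = sum(totals.values())
    cb_yield = cb_total / 100.0 * dsbm * 1000.0

    # acid/neutral split consistent with the decarboxylation ground truth
    neutral_frac = rng_cb.uniform(0.02, 0.10, n)
    acids = {c + "A": (v * (1 - neutral_frac)) / cfg.decarb_factor
             for c, v in totals.items()}
    neutrals = {c: v * neutral_frac for c, v in totals.items()}

    df = pd.DataFrame({
        "family": fam_ids[fam],
        "plant": [f"{fam_ids[j]}-{i % m + 1:02d}" for i, j in enumerate(fam)],
        "genotype": genotypes,
        "PTFD": ptfd, "TFD": tfd, "flowering_class": fclass,
        "LFLTN": lfltn,
        "HT": ht, "MCD": mcd, "MCDH": mcdh, "TRKL": trkl,
        "DIA": dia, "BPAIR": bpair, "VOL": stem_vol,
        "LEAF_COUNT": leaf_count, "LI": li,
        "LFDW": lfdw, "LFA": lfa, "SLA": sla,
        "PTDW": ptdw, "PTA": pta, "SPA": spa,
        "LFL": lfl, "MLFW": mlfw,
        "MLFA": (2.0 / 3.0) * lfl * mlfw,
        "PM71": pm[71], "PM86": pm[86], "PM97": pm[97],
        "WBM": wbm, "DBM": dbm, "DSBM": dsbm,
        "chemotype": chem,
        **{f"{c}_total": v for c, v in totals.items()},
        **{f"{c}_neutral": v for c, v in neutrals.items()},
        **{f"{c}_acid": v for c, v in acids.items()},
        "CB_total": cb_total, "CB_yield": cb_yield,
    })
    truth = TruthBundle(
        config=cfg,
        family_crosses=crosses,
        genotypes=genotypes,
        flowering_day=ptfd,
        latent_log_dia=mu_dia + xi,
        latent_log_li=mu_li + lam,
        h2=dict(cfg.h2),
        exponents={"HT~DIA": cfg.ht_exponent, "WBM~DIA": cfg.wbm_exponent,
                   "LFDW~LI": cfg.lfdw_exponent, "SPA~LI": cfg.spa_exponent},
    )
    return df, truth


def simulate_growth(df: pd.DataFrame, truth: TruthBundle,
                    days: np.ndarray | None = None,
                    noise_sd: float = 1.5,
                    seed: int | None = None) -> dict[str, GrowthSeries]:
    """Weekly height series per plant: logistic curves whose inflection
    follows flowering day (day of maximum growth correlates positively
    with days to flower) plus measurement noise."""
    rng = np.random.default_rng(
        truth.config.master_seed + 1000 if seed is None else seed)
    if days is None:
        days = np.arange(7.0, 71.0, 7.0)        # 10 weekly visits
    days = np.asarray(days, dtype=float)
    out: dict[str, GrowthSeries] = {}
    for _, row in df.iterrows():
        K = float(row["HT"])
        t0 = 0.55 * float(row["PTFD"]) + 12.0 + rng.normal(0, 2.0)
        r = max(rng.normal(0.10, 0.012), 0.05)
        h = K / (1.0 + np.exp(-r * (days - t0)))
        if noise_sd > 0:
            h = np.maximum(h + rng.normal(0, noise_sd, days.size), 0.0)
        out[row["plant"]] = GrowthSeries(days=days, heights=h)
    return out


def simulate_scene(centers: np.ndarray, heights: np.ndarray,
                   seed: int | None = None,
                   gsd: float = 0.02,
                   ground_sd: float = 0.005,
                   ground_density: float = 150.0,
                   canopy_points_per_plant: int = 400,
                   margin: float = 1.5) -> tuple[Scene, dict]:
    """Render a planted field: rasters plus a colorized point cloud.

    Parameters
    ----------
    centers : (n, 2) plant ground positions (m).
    heights : (n,) plant heights (m).
    gsd : ground sampling distance of both rasters (m/px).

    Plants are cone-shaped point clusters (radius ~ 0.22·height + 0.15 m)
    on a rough ground plane; the RGB raster shows green canopies on brown
    soil and the 5-band raster elevates NIR on vegetation.  Returns the
    Scene and a truth dict with the centers and heights.
    """
    rng = np.random.default_rng(seed)
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    heights = np.asarray(heights, dtype=float).ravel()
    if centers.size:
        x_min, y_min = centers.min(axis=0) - margin
        x_max, y_max = centers.max(axis=0) + margin
    else:
        x_min = y_min = 0.0
        x_max = y_max = 4.0
    W = int(np.ceil((x_max - x_min) / gsd))
    H = int(np.ceil((y_max - y_min) / gsd))
    geotransform = (x_min, gsd, 0.0, y_max, 0.0, -gsd)

    # ground points
    n_ground = int(ground_density * (x_max - x_min) * (y_max - y_min))
    gx = rng.uniform(x_min, x_max, n_ground)
    gy = rng.uniform(y_min, y_max, n_ground)
    gz = rng.normal(0.0, ground_sd, n_ground)
    clouds = [np.column_stack([gx, gy, gz,
                               np.full(n_ground, 0.45),
                               np.full(n_ground, 0.35),
                               np.full(n_ground, 0.25)])]
    radii = 0.22 * heights + 0.15
    for (cx, cy), h, rad in zip(centers, heights, radii):
        frac = rng.uniform(0, 1, canopy_points_per_plant) ** 0.7
        z = h * (1.0 - frac)                       # denser near the top? cone
        r_at = rad * frac * np.sqrt(rng.uniform(0, 1, canopy_points_per_plant))
        th = rng.uniform(0, 2 * np.pi, canopy_points_per_plant)
        px = cx + r_at * np.cos(th)
        py = cy + r_at * np.sin(th)
        clouds.append(np.column_stack([
            px, py, z,
            np.full(canopy_points_per_plant, 0.20),
            np.full(canopy_points_per_plant, 0.55),
            np.full(canopy_points_per_plant, 0.15)]))
    cloud = np.vstack(clouds)

    # rasters: vegetation mask from the plant disks (windowed per plant)
    cols = x_min + (np.arange(W) + 0.5) * gsd
    rows = y_max - (np.arange(H) + 0.5) * gsd
    veg = np.zeros((H, W), dtype=bool)
    for (cx, cy), rad in zip(centers, radii):
        c0 = max(int((cx - rad - x_min) / gsd) - 1, 0)
        c1 = min(int((cx + rad - x_min) / gsd) + 2, W)
        r0 = max(int((y_max - cy - rad) / gsd) - 1, 0)
        r1 = min(int((y_max - cy + rad) / gsd) + 2, H)
        if c0 >= c1 or r0 >= r1:
            continue
        XX, YY = np.meshgrid(cols[c0:c1], rows[r0:r1])
        veg[r0:r1, c0:c1] |= (XX - cx) ** 2 + (YY - cy) ** 2 <= rad**2
    rgb = np.empty((H, W, 3))
    rgb[..., 0] = np.where(veg, 0.20, 0.45)
    rgb[..., 1] = np.where(veg, 0.55, 0.35)
    rgb[..., 2] = np.where(veg, 0.15, 0.25)
    rgb += rng.normal(0.0, 0.02, rgb.shape)
    msp = np.empty((H, W, 5))
    msp[..., 0] = np.where(veg, 0.05, 0.12)       # blue
    msp[..., 1] = np.where(veg, 0.12, 0.18)       # green
    msp[..., 2] = np.where(veg, 0.07, 0.25)       # red
    msp[..., 3] = np.where(veg, 0.35, 0.28)       # red edge
    msp[..., 4] = np.where(veg, 0.65, 0.30)       # NIR
    msp += rng.normal(0.0, 0.01, msp.shape)
    msp = np.clip(msp, 0.0, 1.0)

    scene = Scene(rgb=rgb, msp=msp, cloud=cloud, geotransform=geotransform)
    truth = {"centers": centers, "heights": heights, "radii": radii}
    return scene, truth


def grid_layout(n_rows: int, n_cols: int, row_spacing: float = 1.83,
                col_spacing: float = 1.22) -> np.ndarray:
    """Plant centers on the trial grid: rows ``row_spacing`` apart (across
    rows) and plants ``col_spacing`` apart within a row."""
    xs = np.arange(n_rows) * row_spacing
    ys = np.arange(n_cols) * col_spacing
    XX, YY = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([XX.ravel(), YY.ravel()])
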