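"""Synthetic glioblastoma cohort generator with known ground truth.

The generator emulates the statistical structure the clinical analysis
assumes: covariate marginals matching a multi-site cohort (age truncated
normal, WBC log-normal, neutrophil fraction beta, zero-inflated-gamma
steroid dosing that shifts the WBC log-mean), a proportional-hazards link
from covariates to overall and progression-free survival with a Weibull
baseline (inverse-transform sampling gives exact uncensored event times),
administrative-plus-dropout censoring, a four-site center mix, and a
missingness plan combining per-center never-collected blocks with
cell-level MCAR.  Ground truth (true betas, uncensored times, config) is
returned alongside, enabling parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_data import CENTERS, CohortTable, derive_variables

PROTECTED_FIELDS = ("patient_id", "os_days", "os_event")

#: fields never collected at each non-reference site (site-blocked
#: missingness; the reference site OSU collects everything).
DEFAULT_MISSING_BLOCKS: dict[str, tuple[str, ...]] = {
    "UMMC": ("ethnicity", "lesion_side", "lesion_lobe", "lesion_size",
             "midline_shift", "atrx", "p53_positive", "ki67",
             "egfr_amplified", "mgmt_methylated", "radiation_dose",
             "radiation_fractions", "radiation_time", "tmz_dose",
             "tmz_cycles", "enhancement_status", "weight", "height", "bmi",
             "cci_score"),
    "Barretos": ("race", "weight", "height", "bmi", "cci_score",
                 "midline_shift", "p53_positive", "ki67", "egfr_amplified",
                 "steroid_dose", "lesion_size", "tmz_dose",
                 "enhancement_status", "platelets"),
    "FLENI": ("race", "lesion_side", "lesion_lobe", "lesion_size",
              "midline_shift", "atrx", "p53_positive", "ki67",
              "egfr_amplified", "mgmt_methylated", "platelets",
              "radiation_dose", "radiation_fractions", "radiation_time",
              "tmz_dose", "tmz_cycles", "enhancement_status", "weight",
              "height", "bmi", "cci_score"),
}


@dataclass
class MissingnessPlan:
    """Per-center blocks of never-collected fields plus a global MCAR
    cell rate over non-protected fields."""

    center_blocks: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_BLOCKS))
    mcar_rate: float = 0.02

    def __post_init__(self):
        if not (0 <= self.mcar_rate < 1):
            raise ValueError("mcar_rate must lie in [0, 1)")
        for center, fields_ in self.center_blocks.items():
            bad = set(fields_) & set(PROTECTED_FIELDS)
            if bad:
                raise ValueError(
                    f"plan masks protected fields {sorted(bad)} "
                    f"for center {center}")


@dataclass
class CohortGeneratorConfig:
    """Marginals, hazard model, censoring and missingness for one cohort.

    Defaults target the published multi-site summary: mean age ~61 y,
    WBC mean ~9.8e9/L two to four weeks post-surgery, neutrophil fraction
    ~0.74, steroids mean ~2.8 mg/day with roughly half the cohort tapered
    to zero, MGMT methylated in 43%, and a baseline median OS near 540
    days.  Log-hazard coefficients default to the published univariate
    scale (per-unit betas).
    """

    n: int = 500
    seed: int = 0

    # covariate marginals
    age_mean: float = 61.0
    age_sd: float = 12.0
    age_bounds: tuple[float, float] = (20.0, 89.0)
    wbc_median: float = 9.0
    wbc_sigma: float = 0.38          # log-scale dispersion
    neut_frac_a: float = 22.2        # beta(a, b): mean ~0.74
    neut_frac_b: float = 7.8
    lymph_share_mean: float = 0.70   # mean share of non-neutrophil WBC
    lymph_share_kappa: float = 20.0  # beta concentration of that share
    platelet_mean: float = 236.0
    platelet_sd: float = 75.0
    mgmt_p: float = 0.43
    steroid_zero_p: float = 0.45
    steroid_gamma_shape: float = 1.6
    steroid_gamma_scale: float = 3.2
    steroid_wbc_shift: float = 0.018  # added to WBC log-mean per mg/day
    radiation_dose_mean: float = 55.6
    radiation_dose_sd: float = 8.0
    tmz_cycles_lam: float = 3.0

    # proportional-hazards model (per-unit log-hazards)
    baseline_shape: float = 1.0      # Weibull shape; 1 = exponential
    baseline_median: float = 540.0   # days, at covariate means
    beta_age: float = 0.02
    beta_wbc: float = 0.03
    beta_neutrophils: float = 0.047
    beta_mgmt: float = -0.43
    beta_radiation_dose: float = -0.05
    beta_tmz_cycles: float = -0.16
    pfs_median: float = 270.0        # baseline PFS median, same betas

    # censoring
    admin_horizon: float = 2200.0    # days
    dropout_rate: float = 1.0 / 4000.0

    center_probs: tuple[float, ...] = (0.65, 0.10, 0.16, 0.09)
    missingness: MissingnessPlan = field(default_factory=MissingnessPlan)

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if not np.isclose(sum(self.center_probs), 1.0):
            raise ValueError("center_probs must sum to 1")
        if self.baseline_shape <= 0 or self.baseline_median <= 0:
            raise ValueError("baseline parameters must be positive")
        for name in ("mgmt_p", "steroid_zero_p"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def true_betas(self) -> dict[str, float]:
        return {"age_at_surgery": self.beta_age, "wbc": self.beta_wbc,
                "neutrophils": self.beta_neutrophils,
                "mgmt_methylated": self.beta_mgmt,
                "radiation_dose": self.beta_radiation_dose,
                "tmz_cycles": self.beta_tmz_cycles}


@dataclass
class CohortGroundTruth:
    """Uncensored event times, the true beta vector and a config snapshot."""

    event_time: np.ndarray
    censor_time: np.ndarray
    pfs_event_time: np.ndarray
    linear_predictor: np.ndarray
    true_betas: dict[str, float]
    config: dict


def _truncnorm(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    remaining = np.arange(size)
    while remaining.size:
        draw = rng.normal(mean, sd, remaining.size)
        ok = (draw >= lo) & (draw <= hi)
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    return out


def generate_cohort(config: CohortGeneratorConfig,
                    ) -> tuple[CohortTable, CohortGroundTruth]:
    """Draw a cohort from the configured model.

    Survival times come from inverse-transform sampling of the Weibull
    proportional-hazards model S(t | x) = exp(-lam * t^k * exp(eta)) with
    eta the centered linear predictor, so the true betas are exactly
    recoverable in expectation.  All schema fields are populated before
    the missingness plan is applied.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    # independent child streams per stage: covariates, survival, missingness
    child = rng.spawn(3)
    n = cfg.n
    if n == 0:
        empty = CohortTable(pd.DataFrame(
            {"patient_id": pd.Series([], dtype="string"),
             "os_days": pd.Series([], dtype=float),
             "os_event": pd.Series([], dtype="boolean")}))
        truth = CohortGroundTruth(np.array([]), np.array([]), np.array([]),
                                  np.array([]), cfg.true_betas,
                                  _config_dict(cfg))
        return empty, truth

    rc = child[0]
    center = rc.choice(CENTERS, size=n, p=cfg.center_probs)
    age = _truncnorm(rc, cfg.age_mean, cfg.age_sd, *cfg.age_bounds, size=n)
    gender = rc.choice(["Male", "Female"], size=n, p=[0.59, 0.41])
    race = rc.choice(
        ["Caucasian", "Black or African", "Asian", "More than One Race",
         "Unknown"], size=n, p=[0.885, 0.057, 0.008, 0.027, 0.023])
    ethnicity = rc.choice(["Hispanic/Latino", "Non-Hispanic/Latino"],
                          size=n, p=[0.29, 0.71])
    height = _truncnorm(rc, 172.5, 9.0, 147, 196, size=n)
    bmi_draw = _truncnorm(rc, 29.1, 5.5, 17.8, 66.1, size=n)
    weight = bmi_draw * (height / 100.0) ** 2
    cci = np.minimum(rc.poisson(3.7, size=n), 11)
    lesion_side = rc.choice(["Left", "Right", "Both"], size=n,
                            p=[0.52, 0.45, 0.03])
    lesion_lobe = rc.choice(
        ["Frontal", "Temporal", "Parietal", "Occipital", "Brain Stem",
         "Cerebellum", "Mixed"], size=n,
        p=[0.355, 0.345, 0.205, 0.05, 0.025, 0.005, 0.015])
    lesion_size = np.clip(rc.normal(4.34, 1.6, size=n), 0.1, 9.5)
    midline_shift = rc.random(n) < 0.39
    atrx = rc.choice(["intact", "loss"], size=n, p=[0.98, 0.02])
    p53 = rc.random(n) < 0.78
    ki67 = np.clip(rc.normal(31.8, 18.0, size=n), 4, 95)
    egfr = rc.random(n) < 0.56
    mgmt = rc.random(n) < cfg.mgmt_p

    # steroid dose first; its use shifts the WBC log-mean (leukocytosis)
    on_steroids = rc.random(n) >= cfg.steroid_zero_p
    steroid = np.where(
        on_steroids,
        np.clip(rc.gamma(cfg.steroid_gamma_shape, cfg.steroid_gamma_scale,
                         size=n), 0.25, 24.0),
        0.0)
    log_wbc = (np.log(cfg.wbc_median) + cfg.steroid_wbc_shift * steroid
               + rc.normal(0.0, cfg.wbc_sigma, size=n))
    wbc = np.exp(log_wbc)
    neut_frac = rc.beta(cfg.neut_frac_a, cfg.neut_frac_b, size=n)
    neutrophils = wbc * neut_frac
    # per-patient lymphocyte share of the non-neutrophil compartment (the
    # remainder stands in for monocytes/eosinophils/basophils)
    share = rc.beta(cfg.lymph_share_mean * cfg.lymph_share_kappa,
                    (1 - cfg.lymph_share_mean) * cfg.lymph_share_kappa,
                    size=n)
    lymphocytes = np.maximum(wbc * (1 - neut_frac) * share, 0.05)
    platelets = np.clip(rc.normal(cfg.platelet_mean, cfg.platelet_sd,
                                  size=n), 43, 593)
    radiation_dose = np.clip(rc.normal(cfg.radiation_dose_mean,
                                       cfg.radiation_dose_sd, size=n),
                             5.0, 75.0)
    radiation_fractions = np.clip(
        np.round(radiation_dose / 2.0 + rc.normal(0, 2.0, size=n)),
        1, 50).astype(int)
    radiation_time = np.clip(rc.normal(42.0, 10.0, size=n), 0, 336)
    tmz_cycles = np.minimum(rc.poisson(cfg.tmz_cycles_lam, size=n), 19)
    tmz_dose = np.clip(rc.normal(238.0, 80.0, size=n), 0, 500)

    # linear predictor over centered covariates keeps baseline median at
    # the configured value for the average patient
    covs = {"age_at_surgery": age, "wbc": wbc, "neutrophils": neutrophils,
            "mgmt_methylated": mgmt.astype(float),
            "radiation_dose": radiation_dose,
            "tmz_cycles": tmz_cycles.astype(float)}
    eta = np.zeros(n)
    for name, beta in cfg.true_betas.items():
        x = covs[name]
        eta += beta * (x - x.mean())

    rs = child[1]
    k = cfg.baseline_shape
    lam_os = np.log(2.0) / cfg.baseline_median ** k
    lam_pfs = np.log(2.0) / cfg.pfs_median ** k
    u_os = rs.random(n)
    u_pfs = rs.random(n)
    t_event = (-np.log(u_os) / (lam_os * np.exp(eta))) ** (1.0 / k)
    t_pfs = (-np.log(u_pfs) / (lam_pfs * np.exp(eta))) ** (1.0 / k)
    dropout = rs.exponential(1.0 / cfg.dropout_rate, size=n)
    censor = np.minimum(cfg.admin_horizon, dropout)
    os_days = np.minimum(t_event, censor)
    os_event = t_event <= censor
    pfs_days = np.minimum.reduce([t_pfs, t_event, censor])
    pfs_event = t_pfs <= np.minimum(t_event, censor)
    os_days = np.maximum(np.round(os_days), 1.0)
    pfs_days = np.maximum(np.round(pfs_days), 1.0)
    enh = rc.choice(["recurrent", "reactive", "stable"], size=n,
                    p=[0.64, 0.275, 0.085])

    df = pd.DataFrame({
        "patient_id": [f"SYN-{i:05d}" for i in range(n)],
        "center": center, "age_at_surgery": age, "gender": gender,
        "race": race, "ethnicity": ethnicity, "weight": weight,
        "height": height, "bmi": np.full(n, np.nan), "cci_score": cci,
        "lesion_side": lesion_side, "lesion_lobe": lesion_lobe,
        "lesion_size": lesion_size, "midline_shift": midline_shift,
        "atrx": atrx, "p53_positive": p53, "ki67": ki67,
        "egfr_amplified": egfr, "mgmt_methylated": mgmt, "wbc": wbc,
        "neutrophils": neutrophils, "lymphocytes": lymphocytes,
        "platelets": platelets, "nlr": np.full(n, np.nan),
        "steroid_dose": steroid, "radiation_dose": radiation_dose,
        "radiation_fractions": radiation_fractions,
        "radiation_time": radiation_time, "tmz_dose": tmz_dose,
        "tmz_cycles": tmz_cycles, "os_days": os_days,
        "os_event": os_event, "pfs_days": pfs_days,
        "pfs_event": pfs_event, "enhancement_status": enh,
    })
    for col in ("midline_shift", "p53_positive", "egfr_amplified",
                "mgmt_methylated", "os_event", "pfs_event"):
        df[col] = df[col].astype("boolean")
    for col in ("patient_id", "center", "gender", "race", "ethnicity",
                "lesion_side", "lesion_lobe", "atrx", "enhancement_status"):
        df[col] = df[col].astype("string")
    df[["cci_score", "radiation_fractions", "tmz_cycles"]] = df[
        ["cci_score", "radiation_fractions", "tmz_cycles"]].astype(float)

    table = derive_variables(CohortTable(df))
    table = inject_missingness(table, cfg.missingness,
                               seed=int(child[2].integers(2 ** 31)))
    truth = CohortGroundTruth(t_event, censor, t_pfs, eta, cfg.true_betas,
                              _config_dict(cfg))
    return table, truth


def inject_missingness(table: CohortTable, plan: MissingnessPlan,
                       seed: int) -> CohortTable:
    """Apply site-blocked then MCAR missingness; protected fields
    (patient id, OS time/event) are never masked."""
    out = table.copy()
    df = out.df
    for center, fields_ in plan.center_blocks.items():
        bad = set(fields_) & set(PROTECTED_FIELDS)
        if bad:
            raise ValueError(f"plan masks protected fields {sorted(bad)}")
        unknown = set(fields_) - set(df.columns)
        if unknown:
            raise ValueError(f"plan references unknown fields "
                             f"{sorted(unknown)}")
        rows = (df["center"] == center).to_numpy()
        for f in fields_:
            df.loc[rows, f] = pd.NA if str(df[f].dtype) in (
                "string", "boolean") else np.nan
    if plan.mcar_rate > 0:
        rng = np.random.default_rng(seed)
        maskable = [c for c in df.columns if c not in PROTECTED_FIELDS
                    and c != "center"]
        hit = rng.random((len(df), len(maskable))) < plan.mcar_rate
        for j, f in enumerate(maskable):
            rows = hit[:, j]
            df.loc[rows, f] = pd.NA if str(df[f].dtype) in (
                "string", "boolean") else np.nan
    return out


def _config_dict(cfg: CohortGeneratorConfig) -> dict:
    d = asdict(cfg)
    d["missingness"]["center_blocks"] = {
        k: list(v) for k, v in d["missingness"]["center_blocks"].items()}
    return d
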