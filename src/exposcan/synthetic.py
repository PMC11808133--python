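"""Synthetic cohort, genotype, and GWAS-summary generators.

Everything downstream of this module (preprocessing, the exposure-wide
scan, domain scores, gene–environment models, mediation, MR, PAF) is
exercised against cohorts produced here, where the generative truth —
per-variable log hazard ratios, the genetic liability, per-domain
attributable fractions — is known exactly.

The cohort emulates the structure of a large prospective biobank:

* seven exposure domains (socioeconomic status, medical history,
  psychosocial, physical measures, early life, local environment,
  lifestyle) with a mix of continuous, binary and 3-level categorical
  variables, equicorrelated within domain;
* questionnaire-style raw codes (−1 "do not know", −3 "prefer not to
  answer", −10 "less than one") and item missingness;
* some variables measured at two instances (time points);
* an exponential proportional-hazards event process with administrative
  censoring at the end of follow-up plus random exponential censoring;
* a polygenic score built from independent biallelic SNPs that
  contributes to the hazard.

All randomness flows from one master seed through numbered child streams
(`SeedSequence(seed, spawn_key=(stage,))`), so each stage is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidConfigError

DOMAINS = (
    "socioeconomic_status",
    "medical_history",
    "psychosocial",
    "physical_measures",
    "early_life",
    "local_environment",
    "lifestyle",
)

#: domains that enter composite risk scores and PAF estimation
SCOREABLE_DOMAINS = (
    "socioeconomic_status",
    "medical_history",
    "psychosocial",
    "physical_measures",
    "lifestyle",
)

ASSAY_COLUMNS = ("lymphocyte_pct", "neutrophil_pct", "total_bilirubin")

# stage indices for child seed streams
_STAGE_COVARIATES = 0
_STAGE_GENOTYPES = 1
_STAGE_EVENTS = 2
_STAGE_CENSORING = 3
_STAGE_ASSAYS = 4
_STAGE_RAW_CODES = 5
_STAGE_MR = 6
_STAGE_FLAGS = 7


def child_rng(seed: int, stage: int) -> np.random.Generator:
    """Child generator for one pipeline stage, derived from the master seed
    by spawn key so stages are independently reproducible."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    ``true_log_hr`` maps variable names to log hazard ratios (per SD for
    continuous variables, per category step otherwise); variables not
    listed have no effect. ``baseline_hazard_scale`` is the event rate per
    person-year for a participant at the reference covariate profile.
    """

    n_participants: int = 10_000
    n_variables_per_domain: Mapping[str, int] = dc_field(
        default_factory=lambda: {d: 3 for d in DOMAINS}
    )
    true_log_hr: Mapping[str, float] = dc_field(default_factory=dict)
    baseline_hazard_scale: float = 0.005
    followup_years: float = 12.0
    censoring_rate: float = 0.10
    missing_rate: float = 0.03
    special_code_rate: float = 0.02
    n_snps: int = 100
    snp_effect_sd: float = 0.1
    prs_log_hr: float = 0.25
    domain_correlation: float = 0.2
    binary_prevalence: float = 0.3
    n_centers: int = 5
    age_log_hr: float = 0.05  # per year, centered at the cohort mean
    sex_log_hr: float = 0.30  # male vs female
    prevalent_rate: float = 0.0
    missing_genetics_rate: float = 0.0
    # exposure -> assay generative coefficients for mediation designs:
    # assay = direct * burden + via_disease * event + noise
    assay_direct: float = -0.4
    assay_via_disease: float = -1.0
    two_instance_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 2:
            raise InvalidConfigError("n_participants must be at least 2")
        for name, rate in [
            ("censoring_rate", self.censoring_rate),
            ("missing_rate", self.missing_rate),
            ("special_code_rate", self.special_code_rate),
            ("prevalent_rate", self.prevalent_rate),
            ("missing_genetics_rate", self.missing_genetics_rate),
            ("two_instance_fraction", self.two_instance_fraction),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1], got {rate}")
        if not 0.0 <= self.domain_correlation < 1.0:
            raise InvalidConfigError("domain_correlation must lie in [0, 1)")
        if self.baseline_hazard_scale <= 0:
            raise InvalidConfigError("baseline_hazard_scale must be positive")
        unknown = set(self.n_variables_per_domain) - set(DOMAINS)
        if unknown:
            raise InvalidConfigError(f"unknown domains: {sorted(unknown)}")
        catalog_vars = {
            v for d, k in self.n_variables_per_domain.items() for v in _var_names(d, k)
        }
        missing = set(self.true_log_hr) - catalog_vars
        if missing:
            raise InvalidConfigError(
                f"true_log_hr names variables absent from the catalog: {sorted(missing)}"
            )


@dataclass
class TruthRecord:
    """Ground truth for one generated cohort."""

    true_log_hr: dict[str, float]
    prs: np.ndarray
    linear_predictor: np.ndarray
    hazard: np.ndarray
    generative_paf: dict[tuple[str, int], float]
    domain_linear_predictor: pd.DataFrame | None = None


def _var_names(domain: str, k: int) -> list[str]:
    """Variable names for one domain: types cycle continuous, binary,
    3-level categorical (even index ordinal, odd nominal)."""
    return [f"{domain}_v{i}" for i in range(k)]


def _var_type(i: int) -> str:
    kind = i % 3
    if kind == 0:
        return "continuous"
    if kind == 1:
        return "binary"
    return "ordinal" if (i // 3) % 2 == 0 else "nominal"


def build_catalog(config: GeneratorConfig) -> pd.DataFrame:
    """Variable catalog: name, domain, measurement type, modifiability,
    instance count, and whether the raw encoding uses −10 for 'less than
    one' (count-style variables)."""
    rows = []
    for domain in DOMAINS:
        k = config.n_variables_per_domain.get(domain, 0)
        for i, name in enumerate(_var_names(domain, k)):
            vtype = _var_type(i)
            rows.append(
                {
                    "variable": name,
                    "domain": domain,
                    "var_type": vtype,
                    "modifiable": True,
                    "n_instances": 1,
                    "count_coded": vtype == "continuous" and i == 0,
                }
            )
    return pd.DataFrame(rows)


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Generate a cohort table, its variable catalog, and the ground truth.

    The cohort has one row per participant with columns ``id, time, event,
    age, sex, center, batch, prs, prevalent_disease, has_genetics``, three
    blood-assay columns, and one column per catalog variable. Event times
    follow an exponential proportional-hazards model with linear predictor
    Σ b_v·X_v + b_age·(age−mean) + b_sex·sex + b_prs·PRS.
    """
    config.validate()
    catalog = build_catalog(config)
    n = config.n_participants
    rng = child_rng(config.seed, _STAGE_COVARIATES)

    age = rng.uniform(40, 69, size=n)
    sex = rng.binomial(1, 0.471, size=n)  # 1 = male
    center = rng.integers(0, config.n_centers, size=n)
    batch = rng.integers(0, 2, size=n)

    data: dict[str, np.ndarray] = {}
    rho = config.domain_correlation
    for domain in DOMAINS:
        k = config.n_variables_per_domain.get(domain, 0)
        if k == 0:
            continue
        shared = rng.standard_normal(n)
        for i, name in enumerate(_var_names(domain, k)):
            z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal(n)
            vtype = _var_type(i)
            if vtype == "continuous":
                data[name] = z
            elif vtype == "binary":
                cut = stats.norm.ppf(1 - config.binary_prevalence)
                data[name] = (z > cut).astype(float)
            else:  # 3-level categorical from tertiles of the latent
                cuts = stats.norm.ppf([1 / 3, 2 / 3])
                data[name] = np.digitize(z, cuts).astype(float)
    variables = pd.DataFrame(data)

    # genotypes and the true polygenic score
    genotypes, weights = generate_genotypes(
        n, config.n_snps, (0.05, 0.5), config.seed, effect_sd=config.snp_effect_sd
    )
    raw_prs = genotypes.to_numpy() @ weights["weight"].to_numpy()
    sd = raw_prs.std(ddof=1)
    prs = (raw_prs - raw_prs.mean()) / sd if sd > 0 else np.zeros(n)

    # linear predictor and event process
    lp = np.zeros(n)
    domain_lp = {}
    for domain in DOMAINS:
        k = config.n_variables_per_domain.get(domain, 0)
        contrib = np.zeros(n)
        for name in _var_names(domain, k):
            b = config.true_log_hr.get(name, 0.0)
            if b:
                contrib = contrib + b * variables[name].to_numpy()
        domain_lp[domain] = contrib
        lp += contrib
    lp = lp + config.age_log_hr * (age - age.mean()) + config.sex_log_hr * sex
    lp = lp + config.prs_log_hr * prs
    hazard = config.baseline_hazard_scale * np.exp(lp)

    rng_ev = child_rng(config.seed, _STAGE_EVENTS)
    event_time = rng_ev.exponential(1.0 / hazard)
    rng_cens = child_rng(config.seed, _STAGE_CENSORING)
    if config.censoring_rate > 0:
        # exponential censoring with rate chosen so that, when events are
        # rare, about the configured fraction of participants are randomly
        # censored before the end of follow-up:
        # P(C < followup) = 1 - exp(-rate * followup) = censoring_rate
        cens_rate = -np.log(1 - config.censoring_rate) / config.followup_years
        cens_time = rng_cens.exponential(1.0 / cens_rate, size=n)
    else:
        cens_time = np.full(n, np.inf)
    observed = np.minimum(np.minimum(event_time, cens_time), config.followup_years)
    event = (event_time <= np.minimum(cens_time, config.followup_years)).astype(int)

    # blood assays: affected directly by the scoreable-domain risk burden
    # and, on top, by disease status (the mediated path)
    rng_assay = child_rng(config.seed, _STAGE_ASSAYS)
    burden = sum(domain_lp[d] for d in SCOREABLE_DOMAINS)
    assays = {}
    for j, col in enumerate(ASSAY_COLUMNS):
        sign = -1.0 if col == "lymphocyte_pct" else 1.0
        assays[col] = (
            sign * config.assay_direct * burden
            + sign * config.assay_via_disease * event
            + rng_assay.standard_normal(n)
        )

    rng_flags = child_rng(config.seed, _STAGE_FLAGS)
    prevalent = rng_flags.binomial(1, config.prevalent_rate, size=n)
    has_genetics = 1 - rng_flags.binomial(1, config.missing_genetics_rate, size=n)

    cohort = pd.DataFrame(
        {
            "id": np.arange(n),
            "time": observed,
            "event": event,
            "age": age,
            "sex": sex,
            "center": center,
            "batch": batch,
            "prs": prs,
            "prevalent_disease": prevalent,
            "has_genetics": has_genetics,
            **assays,
        }
    )
    cohort = pd.concat([cohort, variables], axis=1)

    # two-instance measurements: split designated continuous variables into
    # two noisy instance columns (the catalog records the instance count)
    if config.two_instance_fraction > 0:
        cont = [
            r.variable
            for r in catalog.itertuples()
            if r.var_type == "continuous"
        ]
        n_multi = int(round(config.two_instance_fraction * len(cont)))
        for name in cont[:n_multi]:
            base = cohort[name].to_numpy()
            cohort[f"{name}__i0"] = base + 0.1 * rng.standard_normal(n)
            cohort[f"{name}__i1"] = base + 0.1 * rng.standard_normal(n)
            cohort = cohort.drop(columns=[name])
            catalog.loc[catalog["variable"] == name, "n_instances"] = 2

    # plain item missingness on variable columns
    if config.missing_rate > 0:
        var_cols = [c for c in cohort.columns if _is_variable_column(c, catalog)]
        mask = rng.uniform(size=(n, len(var_cols))) < config.missing_rate
        vals = cohort[var_cols].to_numpy(dtype=float)
        vals[mask] = np.nan
        cohort[var_cols] = vals

    truth = TruthRecord(
        true_log_hr=dict(config.true_log_hr),
        prs=prs,
        linear_predictor=lp,
        hazard=hazard,
        generative_paf=_generative_pafs(config, domain_lp, lp),
        domain_linear_predictor=pd.DataFrame(domain_lp),
    )
    return cohort, catalog, truth


def _is_variable_column(col: str, catalog: pd.DataFrame) -> bool:
    base = col.split("__i")[0]
    return base in set(catalog["variable"])


def _generative_pafs(
    config: GeneratorConfig, domain_lp: dict[str, np.ndarray], lp: np.ndarray
) -> dict[tuple[str, int], float]:
    """Per-domain generative PAF under the two counterfactual models.

    For domain d, the exposed group is the top tertile (model 1) or top two
    tertiles (model 2) of the domain's true linear-predictor contribution.
    The generative PAF is Levin's formula evaluated at the generator's own
    quantities: the true exposed fraction and the true marginal hazard
    ratio of the contrast, E[e^lp | exposed] / E[e^lp | unexposed] — the
    same functional the downstream estimator applies to its fitted inputs,
    here with exact inputs and no event noise.
    """
    rel_hazard = np.exp(lp)
    out: dict[tuple[str, int], float] = {}
    for domain in SCOREABLE_DOMAINS:
        contrib = domain_lp.get(domain)
        if contrib is None or np.allclose(contrib, contrib[0]):
            out[(domain, 1)] = 0.0
            out[(domain, 2)] = 0.0
            continue
        for model in (1, 2):
            q = 2 / 3 if model == 1 else 1 / 3
            cut = np.quantile(contrib, q)
            exposed = contrib > cut
            if exposed.sum() == 0 or (~exposed).sum() == 0:
                out[(domain, model)] = 0.0
                continue
            p = exposed.mean()
            hr = rel_hazard[exposed].mean() / rel_hazard[~exposed].mean()
            x = p * (hr - 1.0)
            out[(domain, model)] = float(x / (x + 1.0))
    return out


# ---------------------------------------------------------------------------
# raw questionnaire codes
# ---------------------------------------------------------------------------


def inject_raw_codes(
    cohort: pd.DataFrame, catalog: pd.DataFrame, config: GeneratorConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Overwrite a fraction of variable cells with biobank-style raw codes.

    Cells of count-coded variables get −10 ("less than one"); cells of all
    other variables get −1 ("do not know") or −3 ("prefer not to answer"),
    half and half. Returns the recoded cohort and a registry of altered
    cells (row id, variable, original value, injected code).
    """
    if not 0.0 <= config.special_code_rate <= 1.0:
        raise InvalidConfigError("special_code_rate must lie in [0, 1]")
    out = cohort.copy()
    records = []
    if config.special_code_rate == 0:
        return out, pd.DataFrame(columns=["id", "variable", "original", "code"])
    rng = child_rng(config.seed, _STAGE_RAW_CODES)
    count_vars = set(catalog.loc[catalog["count_coded"], "variable"])
    var_cols = [c for c in cohort.columns if _is_variable_column(c, catalog)]
    for col in var_cols:
        vals = out[col].to_numpy(dtype=float)
        hit = (rng.uniform(size=len(vals)) < config.special_code_rate) & ~np.isnan(
            vals
        )
        idx = np.flatnonzero(hit)
        if idx.size == 0:
            continue
        base = col.split("__i")[0]
        if base in count_vars:
            codes = np.full(idx.size, -10.0)
        else:
            codes = np.where(rng.uniform(size=idx.size) < 0.5, -1.0, -3.0)
        for i, code in zip(idx, codes):
            records.append(
                {
                    "id": int(out["id"].iloc[i]),
                    "variable": col,
                    "original": float(vals[i]),
                    "code": float(code),
                }
            )
        vals[idx] = codes
        out[col] = vals
    registry = pd.DataFrame(records, columns=["id", "variable", "original", "code"])
    return out, registry


# ---------------------------------------------------------------------------
# genotypes and GWAS summary statistics
# ---------------------------------------------------------------------------


def generate_genotypes(
    n: int,
    m: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    effect_sd: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Independent biallelic dosages: SNP j has minor-allele frequency
    drawn uniformly from ``maf_range`` and dosages Binomial(2, maf).

    Returns (dosage matrix n×m with columns snp0..snp{m-1}, weight table
    with per-SNP effect sizes drawn N(0, effect_sd)).
    """
    if m < 1:
        raise InvalidConfigError("need at least one SNP")
    if n < 1:
        raise InvalidConfigError("need at least one participant")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise InvalidConfigError("maf_range must be within (0, 0.5]")
    rng = child_rng(seed, _STAGE_GENOTYPES)
    mafs = rng.uniform(lo, hi, size=m)
    dosages = rng.binomial(2, mafs, size=(n, m)).astype(float)
    weights = rng.normal(0.0, effect_sd, size=m)
    cols = [f"snp{j}" for j in range(m)]
    gmat = pd.DataFrame(dosages, columns=cols)
    wtab = pd.DataFrame({"snp": cols, "maf": mafs, "weight": weights})
    return gmat, wtab


def generate_mr_summary(
    true_effect: float,
    n_snps: int,
    pleiotropy: float = 0.0,
    seed: int = 0,
    exposure_beta_sd: float = 0.15,
    se_exposure: float = 0.01,
    se_outcome: float = 0.03,
    outcome_noise: float = 1.0,
    weak_fraction: float = 0.0,
) -> pd.DataFrame:
    """Two-sample GWAS summary statistics with a known causal effect.

    ``beta_outcome = true_effect·beta_exposure + pleiotropy + noise`` with
    noise N(0, outcome_noise·se_outcome); ``outcome_noise = 0`` gives the
    exact noiseless limit. Exposure effects are drawn positive (effect
    alleles oriented to increase the exposure), so a constant pleiotropy
    term is directional in the MR-Egger sense. A ``weak_fraction`` of SNPs
    get inflated exposure SEs so that their exposure p-values fall between
    the primary and relaxed instrument-selection thresholds.
    """
    if n_snps < 2:
        raise InvalidConfigError("need at least 2 SNPs for an MR summary table")
    rng = child_rng(seed, _STAGE_MR)
    beta_exp = np.abs(rng.normal(0.0, exposure_beta_sd, size=n_snps))
    beta_exp = np.maximum(beta_exp, 0.02)
    se_exp = np.full(n_snps, se_exposure, dtype=float)
    n_weak = int(round(weak_fraction * n_snps))
    if n_weak:
        # weak instruments: z between ~4.6 and ~5.4 (p in (5e-8, 5e-6))
        z_weak = rng.uniform(4.7, 5.3, size=n_weak)
        se_exp[:n_weak] = np.abs(beta_exp[:n_weak]) / z_weak
    p_exp = 2.0 * stats.norm.sf(np.abs(beta_exp) / se_exp)
    se_out = np.full(n_snps, se_outcome, dtype=float)
    noise = outcome_noise * rng.normal(0.0, se_out)
    beta_out = true_effect * beta_exp + pleiotropy + noise
    return pd.DataFrame(
        {
            "snp": [f"rs{j}" for j in range(n_snps)],
            "beta_exp": beta_exp,
            "se_exp": se_exp,
            "p_exp": p_exp,
            "beta_out": beta_out,
            "se_out": se_out,
        }
    )
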