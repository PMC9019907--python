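"""Synthetic multi-cohort generator with planted signature structure.

Each cohort carries a genes x samples log2 expression matrix, a binary
anchor-gene mutation status, and a clinical table with overall and
recurrence-free survival. The planted structure mirrors the discovery
design the pipeline targets:

* a latent two-level risk group (LR/HR) per patient, with a higher
  anchor-mutation rate and a worse hazard in the HR group;
* a planted signature gene set whose log2 expression shifts with mutation
  status (``delta_log2``, per-gene random sign) and with the latent group
  (``group_delta_log2``, independent per-gene random sign);
* a single shared latent factor loading equally on the anchor and all
  signature genes, calibrated analytically so the expected Pearson
  correlation between a signature gene and the anchor equals ``rho``;
* exponential proportional-hazards survival with independent exponential
  censoring, administratively capped at 120 months;
* per-gene location/scale platform shifts in every cohort after the first,
  emulating cross-platform heterogeneity.

Determinism: all draws flow from ``config.seed`` through per-cohort
``numpy.random.SeedSequence`` spawn keys; the gene-level structure (which
genes are planted, sign patterns, baselines, platform parameters) is shared
across cohorts of one configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fatsig.config import FOLLOW_UP_CAP, SimulationConfig
from fatsig.errors import InvalidConfigError

ANCHOR_GENE = "ANCHOR"

#: marginal frequencies of the binary clinical covariates (training-cohort-like)
_COVARIATE_FREQS = {
    "age_ge60": 0.56,
    "male": 0.73,
    "smoking": 0.75,
    "alcohol": 0.66,
    "t34": 0.55,
    "n_pos": 0.55,
    "stage_adv": 0.75,
}
_RT_RATE = 0.6            # radiotherapy frequency
_HPV_POS_LR = 0.36        # HPV-positive rate in the latent LR group
_HPV_POS_HR = 0.07        # ... and in the HR group
_RFS_HAZARD_FACTOR = 1.5  # recurrence hazard relative to death hazard


@dataclass
class SyntheticCohort:
    """One simulated cohort plus its ground truth."""

    name: str
    expression: pd.DataFrame         # genes x samples, log2 scale
    mutation: pd.Series              # sample -> 0/1
    clinical: pd.DataFrame           # sample-indexed clinical table
    truth_labels: pd.Series          # sample -> {"LR", "HR"}
    truth_genes: list[str]
    anchor_gene: str = ANCHOR_GENE
    truth_mut_sign: pd.Series = field(default=None, repr=False)
    truth_group_sign: pd.Series = field(default=None, repr=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.columns)


def latent_factor_loading(config: SimulationConfig) -> float:
    """Loading of the shared factor that realizes the target anchor correlation.

    With a common loading ``lam`` on the anchor and every signature gene, the
    sign-averaged Pearson correlation between a signature gene and the anchor is

        r = lam^2 / sqrt((lam^2 + A)(lam^2 + B))

    where A and B collect the non-shared variance of the anchor and of a
    signature gene (residual noise plus mutation/group shift variance).
    Setting r = rho gives a quadratic in lam^2 with one admissible root.
    """
    if config.rho == 0.0:
        return 0.0
    p_mut = (config.frac_hr * config.mutation_rate_hr
             + (1.0 - config.frac_hr) * config.mutation_rate_lr)
    v_mut = p_mut * (1.0 - p_mut)
    v_grp = config.frac_hr * (1.0 - config.frac_hr)
    s2 = config.noise_sd ** 2
    a = s2 + config.anchor_mut_delta ** 2 * v_mut
    b = s2 + config.delta_log2 ** 2 * v_mut + config.group_delta_log2 ** 2 * v_grp
    rho2 = config.rho ** 2
    # (1 - rho2) x^2 - rho2 (a + b) x - rho2 a b = 0, x = lam^2
    disc = rho2 ** 2 * (a + b) ** 2 + 4.0 * (1.0 - rho2) * rho2 * a * b
    x = (rho2 * (a + b) + math.sqrt(disc)) / (2.0 * (1.0 - rho2))
    return math.copysign(math.sqrt(x), config.rho)


def _structure(config: SimulationConfig) -> dict:
    """Gene-level structure shared by every cohort of one configuration."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(0,)))
    gene_ids = [ANCHOR_GENE] + [f"G{i:05d}" for i in range(1, config.n_genes)]
    candidates = np.arange(1, config.n_genes)  # anchor never planted
    sig_idx = np.sort(rng.choice(candidates, size=config.n_signature,
                                 replace=False))
    baselines = rng.normal(8.0, 1.5, size=config.n_genes)
    mut_sign = rng.choice([-1.0, 1.0], size=config.n_signature)
    group_sign = rng.choice([-1.0, 1.0], size=config.n_signature)
    # platform parameters for cohorts > 0
    shifts, scales = [], []
    for _ in range(1, config.n_cohorts):
        shifts.append(rng.normal(0.0, config.platform_shift_sd,
                                 size=config.n_genes))
        scales.append(np.exp(rng.normal(0.0, config.platform_scale_sd,
                                        size=config.n_genes)))
    return {
        "gene_ids": gene_ids,
        "sig_idx": sig_idx,
        "baselines": baselines,
        "mut_sign": mut_sign,
        "group_sign": group_sign,
        "platform_shifts": shifts,
        "platform_scales": scales,
        "lam": latent_factor_loading(config),
    }


def _draw_survival(rng: np.random.Generator, hazard: np.ndarray,
                   censor_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times vs independent censoring, capped at 120 months."""
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        t_cens = rng.exponential(1.0 / censor_rate, size=hazard.shape)
    else:
        t_cens = np.full(hazard.shape, np.inf)
    t_cens = np.minimum(t_cens, FOLLOW_UP_CAP)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event


def simulate_cohort(config: SimulationConfig, cohort_index: int = 0,
                    _structure_cache: dict | None = None) -> SyntheticCohort:
    """Simulate one cohort; index 0 is the training cohort (no platform shift)."""
    if cohort_index >= config.n_cohorts or cohort_index < 0:
        raise InvalidConfigError(
            f"cohort_index {cohort_index} outside [0, {config.n_cohorts})")
    st = _structure_cache if _structure_cache is not None else _structure(config)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(cohort_index + 1,)))
    n, g = config.n_samples, config.n_genes
    sample_ids = [f"C{cohort_index}S{i:04d}" for i in range(n)]

    group = (rng.random(n) < config.frac_hr).astype(int)  # 1 = HR
    rate = np.where(group == 1, config.mutation_rate_hr, config.mutation_rate_lr)
    mutated = (rng.random(n) < rate).astype(int)

    u = rng.normal(0.0, 1.0, size=n)                      # shared latent factor
    values = rng.normal(0.0, config.noise_sd, size=(g, n))
    values += st["baselines"][:, None]
    lam = st["lam"]
    # anchor row
    values[0] += lam * u + config.anchor_mut_delta * mutated
    # signature rows
    sig = st["sig_idx"]
    values[sig] += lam * u[None, :]
    values[sig] += (st["mut_sign"][:, None] * config.delta_log2) * mutated[None, :]
    values[sig] += (st["group_sign"][:, None] * config.group_delta_log2) * group[None, :]
    if cohort_index > 0:
        off = st["platform_shifts"][cohort_index - 1]
        sc = st["platform_scales"][cohort_index - 1]
        values = off[:, None] + sc[:, None] * values

    rt = (rng.random(n) < _RT_RATE).astype(int)
    log_h = (math.log(config.baseline_hazard)
             + math.log(config.hr_hazard_ratio) * group
             + math.log(config.rt_hazard_ratio) * rt
             + math.log(config.interaction_effect) * group * rt)
    hazard = np.exp(log_h)
    os_months, os_event = _draw_survival(rng, hazard, config.censor_rate)
    rfs_months, rfs_event = _draw_survival(
        rng, hazard * _RFS_HAZARD_FACTOR, config.censor_rate)

    cov = {k: (rng.random(n) < p).astype(int) for k, p in _COVARIATE_FREQS.items()}
    hpv_p = np.where(group == 1, _HPV_POS_HR, _HPV_POS_LR)
    hpv = (rng.random(n) < hpv_p).astype(int)

    clinical = pd.DataFrame({
        "os_months": os_months,
        "os_event": os_event,
        "rfs_months": rfs_months,
        "rfs_event": rfs_event,
        "age_group": np.where(cov["age_ge60"] == 1, ">=60", "<60"),
        "sex": np.where(cov["male"] == 1, "male", "female"),
        "smoking": np.where(cov["smoking"] == 1, "yes", "no"),
        "alcohol": np.where(cov["alcohol"] == 1, "yes", "no"),
        "t_class": np.where(cov["t34"] == 1, "T3-T4", "T1-T2"),
        "n_class": np.where(cov["n_pos"] == 1, "N1-3", "N0"),
        "stage": np.where(cov["stage_adv"] == 1, "III-IV", "I-II"),
        "hpv": np.where(hpv == 1, "pos", "neg"),
        "radiotherapy": np.where(rt == 1, "yes", "no"),
    }, index=pd.Index(sample_ids, name="sample_id"))

    expression = pd.DataFrame(values, index=pd.Index(st["gene_ids"], name="gene_id"),
                              columns=sample_ids)
    mutation = pd.Series(mutated, index=clinical.index, name="mutated")
    labels = pd.Series(np.where(group == 1, "HR", "LR"), index=clinical.index,
                       name="truth_label")
    truth_genes = [st["gene_ids"][i] for i in st["sig_idx"]]
    return SyntheticCohort(
        name="training" if cohort_index == 0 else f"validation_{cohort_index}",
        expression=expression,
        mutation=mutation,
        clinical=clinical,
        truth_labels=labels,
        truth_genes=truth_genes,
        truth_mut_sign=pd.Series(st["mut_sign"], index=truth_genes),
        truth_group_sign=pd.Series(st["group_sign"], index=truth_genes),
    )


def simulate_multi_cohort(config: SimulationConfig) -> list[SyntheticCohort]:
    """Simulate all cohorts of a configuration; cohort 0 is the training set."""
    st = _structure(config)
    return [simulate_cohort(config, k, _structure_cache=st)
            for k in range(config.n_cohorts)]
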