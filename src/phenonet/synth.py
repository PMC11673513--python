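"""Synthetic cohorts and LC-MS-like feature tables with planted structure.

The generator emulates the statistical skeleton an untargeted plasma
metabolomics study hands to its analysis pipeline: an unbalanced 2x2 cohort
(lean/obese BMI crossed with low/high activity, default cell sizes
13/7/20/9), a feature table of positive abundances organised in correlated
blocks, pooled-QC technical replicates, and planted group effects whose
identity is recorded so downstream selection can be scored against truth.

Abundances are log-normal: each feature block has a latent Gaussian with
equicorrelation ``block_rho``, scaled by ``latent_sigma`` and exponentiated.
Planted effects are additive shifts of ``effect_size * latent_sigma`` on the
latent (log) scale -- i.e. ``effect_size`` is a Cohen's d on the scale the
noise lives on.  Interaction features are shifted in exactly one designated
cell (default ObeseLow), the generative reading of "the effect of one factor
depends on the level of the other".
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CELLS, classify_cohort, validate_cohort
from .tables import (
    ROLE_QC,
    ROLE_STUDY,
    TRUTH_BMI,
    TRUTH_INTERACTION,
    TRUTH_IPAQ,
    TRUTH_NULL,
    TRUTH_RSD_FAIL,
    FeatureTable,
)

# Continuous phenotype bounds used to realise each class by construction.
BMI_LEAN_RANGE = (18.0, 25.0)       # lean: 18 <= BMI < 25
BMI_OBESE_RANGE = (25.0, 40.0)      # obese: 25 <= BMI <= 40
IPAQ_LOW_RANGE = (0.0, 3066.0)      # low: IPAQ <= 3066
IPAQ_HIGH_RANGE = (3066.0, 15000.0)  # high: IPAQ > 3066 (open at 3066)
HEIGHT_RANGE = (1.50, 1.90)
AGE_RANGE = (18, 60)
LOG_MEAN_RANGE = (np.log(1e4), np.log(1e6))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated study.

    Defaults reproduce the reference study conditions: 49 subjects in cells
    LeanLow/LeanHigh/ObeseLow/ObeseHigh of sizes 13/7/20/9, a raw table of
    2534 features of which 719 are planted to fail the QC-RSD filter, and
    64 / 5 / 26 features carrying BMI / IPAQ / interaction effects.
    """

    n_per_cell: tuple[int, int, int, int] = (13, 7, 20, 9)
    n_features: int = 2534
    n_qc: int = 6
    n_affected_bmi: int = 64
    n_affected_ipaq: int = 5
    n_affected_interaction: int = 26
    effect_size: float = 1.5
    block_size: int = 5
    block_rho: float = 0.6
    qc_cv_pass: float = 0.05
    qc_cv_fail: float = 0.6
    n_fail_rsd: int = 719
    latent_sigma: float = 0.5
    interaction_cell: str = "ObeseLow"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_cell) != 4 or any(n < 2 for n in self.n_per_cell):
            raise ValueError("n_per_cell must be four integers >= 2")
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        n_planted = (
            self.n_affected_bmi + self.n_affected_ipaq + self.n_affected_interaction
        )
        if min(self.n_affected_bmi, self.n_affected_ipaq,
               self.n_affected_interaction, self.n_fail_rsd, self.n_qc) < 0:
            raise ValueError("counts must be non-negative")
        if n_planted + self.n_fail_rsd > self.n_features:
            raise ValueError(
                "planted effect features plus RSD-fail features exceed n_features"
            )
        if not 0 <= self.block_rho < 1:
            raise ValueError("block_rho must lie in [0, 1)")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if self.qc_cv_pass < 0 or self.qc_cv_fail < 0:
            raise ValueError("QC coefficients of variation must be non-negative")
        if self.latent_sigma <= 0:
            raise ValueError("latent_sigma must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.interaction_cell not in CELLS:
            raise ValueError(f"interaction_cell must be one of {CELLS}")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    @property
    def n_study(self) -> int:
        return int(sum(self.n_per_cell))


def _draw_phenotypes(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    k = 0
    for cell, n in zip(CELLS, config.n_per_cell):
        lean = cell.startswith("Lean")
        low = cell.endswith("Low")
        lo, hi = BMI_LEAN_RANGE if lean else BMI_OBESE_RANGE
        bmi = rng.uniform(lo, hi, n)
        lo, hi = IPAQ_LOW_RANGE if low else IPAQ_HIGH_RANGE
        ipaq = rng.uniform(np.nextafter(lo, hi) if not low else lo, hi, n)
        height = rng.uniform(*HEIGHT_RANGE, n)
        sex = rng.choice(["F", "M"], n)
        age = rng.integers(AGE_RANGE[0], AGE_RANGE[1] + 1, n)
        for j in range(n):
            k += 1
            rows.append(
                {
                    "subject_id": f"S{k:03d}",
                    "sex": sex[j],
                    "age": int(age[j]),
                    # body mass derived so BMI = mass / height^2 holds exactly
                    "body_mass": bmi[j] * height[j] ** 2,
                    "height": height[j],
                    "bmi_value": bmi[j],
                    "ipaq_score": ipaq[j],
                }
            )
    return classify_cohort(pd.DataFrame(rows))


def _truth_labels(config: SimConfig) -> np.ndarray:
    labels = np.full(config.n_features, TRUTH_NULL, dtype=object)
    a, b, c = (
        config.n_affected_bmi,
        config.n_affected_ipaq,
        config.n_affected_interaction,
    )
    labels[:a] = TRUTH_BMI
    labels[a : a + b] = TRUTH_IPAQ
    labels[a + b : a + b + c] = TRUTH_INTERACTION
    if config.n_fail_rsd:
        labels[config.n_features - config.n_fail_rsd :] = TRUTH_RSD_FAIL
    return labels


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, FeatureTable]:
    """Simulate cohort metadata and the study-sample abundance table.

    Deterministic for a fixed config (including seed).  Returns the
    classified metadata table and a FeatureTable of study samples with
    per-feature truth labels; QC rows are added separately by
    :func:`add_qc_samples`.
    """
    rng = np.random.default_rng(config.seed)
    meta = _draw_phenotypes(config, rng)
    validate_cohort(meta)

    n = config.n_study
    p = config.n_features
    labels = _truth_labels(config)

    mu = rng.uniform(*LOG_MEAN_RANGE, p)
    latent = np.empty((n, p))
    rho = config.block_rho
    for start in range(0, p, config.block_size):
        stop = min(start + config.block_size, p)
        width = stop - start
        shared = rng.standard_normal((n, 1))
        eps = rng.standard_normal((n, width))
        latent[:, start:stop] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps
    latent = mu[None, :] + config.latent_sigma * latent

    shift = config.effect_size * config.latent_sigma
    obese = (meta["bmi_class"] == "overweight_obese").to_numpy()
    high = (meta["ipaq_class"] == "high").to_numpy()
    in_cell = (meta["cell"] == config.interaction_cell).to_numpy()
    if shift > 0:
        latent[np.ix_(obese, labels == TRUTH_BMI)] += shift
        latent[np.ix_(high, labels == TRUTH_IPAQ)] += shift
        latent[np.ix_(in_cell, labels == TRUTH_INTERACTION)] += shift
    else:
        # zero effect: nothing is planted, so nothing is labelled as planted
        labels = np.where(
            np.isin(labels, [TRUTH_BMI, TRUTH_IPAQ, TRUTH_INTERACTION]),
            TRUTH_NULL,
            labels,
        )

    feature_ids = pd.Index([f"F{j+1:05d}" for j in range(p)])
    abund = pd.DataFrame(
        np.exp(latent), index=pd.Index(meta["subject_id"]), columns=feature_ids
    )
    abund.index.name = None
    roles = pd.Series(ROLE_STUDY, index=abund.index)
    truth = pd.Series(labels, index=feature_ids)
    return meta, FeatureTable(abund, roles, truth)


def add_qc_samples(table: FeatureTable, config: SimConfig) -> FeatureTable:
    """Append pooled-QC technical replicates to a study table.

    Each QC row has expected value equal to the per-feature study mean, with
    multiplicative Gaussian noise of coefficient of variation ``qc_cv_fail``
    for features planted to fail the RSD filter and ``qc_cv_pass`` otherwise
    (truncated at zero so abundances stay non-negative).
    """
    if config.n_qc == 0:
        return table
    if not table.study_mask().any():
        raise ValueError("table has no study samples")
    if config.n_qc < 2 and config.n_fail_rsd > 0:
        raise ValueError("RSD is undefined on fewer than 2 QC replicates")

    rng = np.random.default_rng([config.seed, 1])
    mean = table.study_values().mean(axis=0, skipna=True).to_numpy()
    cv = np.full(table.n_features, config.qc_cv_pass)
    if table.truth_labels is not None:
        cv[(table.truth_labels == TRUTH_RSD_FAIL).to_numpy()] = config.qc_cv_fail

    noise = rng.standard_normal((config.n_qc, table.n_features))
    qc = np.clip(mean[None, :] * (1.0 + cv[None, :] * noise), 0.0, None)
    qc_ids = pd.Index([f"QC{j+1:02d}" for j in range(config.n_qc)])
    qc_df = pd.DataFrame(qc, index=qc_ids, columns=table.feature_ids)

    abund = pd.concat([table.abundances, qc_df])
    roles = pd.concat([table.roles, pd.Series(ROLE_QC, index=qc_ids)])
    truth = None if table.truth_labels is None else table.truth_labels.copy()
    return FeatureTable(abund, roles, truth)


def make_rsd_fixture(
    n_total: int, n_fail: int, threshold: float = 0.30
) -> FeatureTable:
    """Deterministic table where exactly ``n_fail`` features fail the RSD filter.

    Each feature gets three QC replicates ``(m, m + x, m - x)`` whose RSD is
    exactly ``x / m``: passing features use ``x = threshold/2 * m`` (RSD
    strictly below threshold), failing features ``x = 2 * threshold * m``
    (strictly above).  Two constant study rows are included so the table is
    a complete pipeline input.
    """
    if n_fail > n_total:
        raise ValueError("n_fail cannot exceed n_total")
    if threshold <= 0:
        raise ValueError("threshold must be positive")

    m = 100.0
    x = np.where(np.arange(n_total) < n_fail, 2.0 * threshold * m, 0.5 * threshold * m)
    qc = np.vstack([np.full(n_total, m), m + x, m - x])
    study = np.vstack([np.full(n_total, m), np.full(n_total, 1.1 * m)])

    feature_ids = pd.Index([f"F{j+1:05d}" for j in range(n_total)])
    sample_ids = pd.Index(["S001", "S002", "QC01", "QC02", "QC03"])
    abund = pd.DataFrame(
        np.vstack([study, qc]), index=sample_ids, columns=feature_ids
    )
    roles = pd.Series(
        [ROLE_STUDY, ROLE_STUDY, ROLE_QC, ROLE_QC, ROLE_QC], index=sample_ids
    )
    truth = pd.Series(
        np.where(np.arange(n_total) < n_fail, TRUTH_RSD_FAIL, TRUTH_NULL),
        index=feature_ids,
    )
    return FeatureTable(abund, roles, truth)
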