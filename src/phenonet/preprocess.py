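"""Feature-table preprocessing: QC-RSD filtering, then normalization.

The chain mirrors standard untargeted-metabolomics practice: features whose
pooled-QC relative standard deviation (sd/mean over QC replicates) exceeds a
threshold are discarded as technically irreproducible; surviving study rows
are divided by their sample median, cube-root transformed, and range scaled
per feature so every feature is centred with unit range.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import FeatureTable, ProcessedTable, ROLE_STUDY

logger = logging.getLogger(__name__)

#: Default QC-RSD cutoff (30%), the common untargeted-LC-MS convention.
DEFAULT_RSD_THRESHOLD = 0.30


@dataclass
class RsdReport:
    """Per-feature QC relative standard deviation and the filter verdict.

    ``frame`` is indexed by feature id with columns ``rsd`` (NaN when the QC
    mean is zero, i.e. undefined) and ``retained`` (RSD defined and
    <= threshold).
    """

    frame: pd.DataFrame
    threshold: float

    @property
    def n_input(self) -> int:
        return len(self.frame)

    @property
    def n_retained(self) -> int:
        return int(self.frame["retained"].sum())

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained

    def retained_features(self) -> pd.Index:
        return self.frame.index[self.frame["retained"]]

    def to_csv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.index.name = "feature_id"
        out.to_csv(path)


def impute_missing(table: FeatureTable) -> FeatureTable:
    """Replace missing entries by half the feature's minimum positive value.

    Features with no observed positive value anywhere are dropped with a
    warning; everything else is returned unchanged if already complete.
    """
    if table.abundances.size == 0:
        raise ValueError("empty feature table")
    abund = table.abundances
    if not abund.isna().to_numpy().any():
        return table

    abund = abund.copy()
    positive_min = abund.where(abund > 0).min(axis=0, skipna=True)
    dead = positive_min.isna()
    if dead.any():
        dropped = list(abund.columns[dead])
        logger.warning(
            "dropping %d feature(s) with no observed positive value: %s",
            len(dropped), dropped[:5],
        )
        abund = abund.loc[:, ~dead.to_numpy()]
        positive_min = positive_min[~dead]
    fill = positive_min / 2.0
    abund = abund.fillna(fill)
    truth = None
    if table.truth_labels is not None:
        truth = table.truth_labels.loc[abund.columns]
    return FeatureTable(abund, table.roles.copy(), truth)


def compute_qc_rsd(
    table: FeatureTable, threshold: float = DEFAULT_RSD_THRESHOLD
) -> RsdReport:
    """Relative standard deviation of each feature over the QC replicates.

    RSD = sample standard deviation (n-1 denominator) / mean of the feature's
    QC values.  A zero QC mean leaves the RSD undefined; such features are
    marked not retained.
    """
    qc = table.qc_values()
    if len(qc) < 2:
        raise ValueError("RSD requires at least 2 QC samples")
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=1)
    rsd = sd / mean.where(mean != 0)
    retained = rsd.notna() & (rsd <= threshold)
    frame = pd.DataFrame({"rsd": rsd, "retained": retained})
    return RsdReport(frame, threshold)


def filter_by_rsd(
    table: FeatureTable, threshold: float = DEFAULT_RSD_THRESHOLD
) -> tuple[FeatureTable, RsdReport]:
    """Drop features whose QC-RSD is undefined or above ``threshold``.

    Sample order and the relative order of retained features are preserved.
    """
    report = compute_qc_rsd(table, threshold)
    return table.select_features(report.retained_features()), report


def normalize_sample_median(table: FeatureTable) -> FeatureTable:
    """Divide each study row by its median abundance; drop QC/blank rows.

    Pooled-QC and blank samples have served their purpose (the RSD filter)
    and are excluded from all downstream statistics.
    """
    study = table.study_values()
    medians = study.median(axis=1)
    bad = medians[medians <= 0]
    if len(bad):
        raise ValueError(
            f"non-positive sample median for sample(s) {list(bad.index[:5])}"
        )
    normalized = study.div(medians, axis=0)
    roles = table.roles.loc[normalized.index].copy()
    truth = None if table.truth_labels is None else table.truth_labels.copy()
    return FeatureTable(normalized, roles, truth)


def cube_root_transform(table: FeatureTable) -> FeatureTable:
    """Elementwise signed cube root, sign(x) * |x|^(1/3).

    Abundances are non-negative so the signed form only matters defensively;
    it keeps the transform total and strictly increasing.
    """
    abund = table.abundances
    out = np.sign(abund) * np.abs(abund) ** (1.0 / 3.0)
    truth = None if table.truth_labels is None else table.truth_labels.copy()
    return FeatureTable(out, table.roles.copy(), truth)


def range_scale(table: FeatureTable) -> ProcessedTable:
    """Per feature: subtract the mean, divide by (max - min).

    Non-constant features end up with zero mean and unit range; constant
    (zero-range) features are set to all-zero with a warning, since they are
    statistically inert downstream.
    """
    study = table.study_values()
    if len(study) < 2:
        raise ValueError("range scaling requires at least 2 study samples")
    centered = study - study.mean(axis=0)
    rng = study.max(axis=0) - study.min(axis=0)
    zero = rng == 0
    if zero.any():
        logger.warning(
            "%d zero-range feature(s) set to all-zero", int(zero.sum())
        )
    scaled = centered.div(rng.where(~zero, 1.0), axis=1)
    scaled.loc[:, zero] = 0.0
    return ProcessedTable(scaled, [{"step": "range_scale"}])


def preprocess_pipeline(
    table: FeatureTable, threshold: float = DEFAULT_RSD_THRESHOLD
) -> tuple[ProcessedTable, RsdReport]:
    """Full chain: impute, RSD-filter, median-normalize, cube root, range scale."""
    imputed = impute_missing(table)
    filtered, report = filter_by_rsd(imputed, threshold)
    normalized = normalize_sample_median(filtered)
    transformed = cube_root_transform(normalized)
    processed = range_scale(transformed)
    processed.provenance = [
        {"step": "impute_missing", "rule": "half-minimum"},
        {"step": "filter_by_rsd", "threshold": threshold,
         "n_input": report.n_input, "n_removed": report.n_removed,
         "n_retained": report.n_retained},
        {"step": "normalize_sample_median"},
        {"step": "cube_root_transform"},
        {"step": "range_scale"},
    ]
    logger.info(
        "preprocess: %d -> %d features (RSD <= %g), %d study samples",
        report.n_input, report.n_retained, threshold, len(processed.data),
    )
    return processed, report
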