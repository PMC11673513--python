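"""In-memory containers for feature tables and their delimited-text format.

A :class:`FeatureTable` is the object every pipeline stage transforms: a
samples x features abundance matrix (non-negative reals, NaN for missing)
with a role per sample (``study``, ``qc`` or ``blank``) and, for synthetic
tables, a ground-truth tag per feature.

On disk the table is a plain CSV: first column the sample id, second the
sample role, one further column per feature, missing values as empty fields.
Truth labels travel in a separate two-column CSV (feature_id, truth_label).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

ROLE_STUDY = "study"
ROLE_QC = "qc"
ROLE_BLANK = "blank"
ROLES = (ROLE_STUDY, ROLE_QC, ROLE_BLANK)

TRUTH_NULL = "null"
TRUTH_BMI = "bmi"
TRUTH_IPAQ = "ipaq"
TRUTH_INTERACTION = "interaction"
TRUTH_RSD_FAIL = "rsd_fail"
TRUTH_LABELS = (TRUTH_NULL, TRUTH_BMI, TRUTH_IPAQ, TRUTH_INTERACTION, TRUTH_RSD_FAIL)


@dataclass
class FeatureTable:
    """Abundance matrix with per-sample roles and optional per-feature truth.

    Parameters
    ----------
    abundances
        DataFrame indexed by sample id, one float column per feature id.
        NaN encodes a missing measurement.
    roles
        Series indexed identically to ``abundances``, values in
        ``{"study", "qc", "blank"}``.
    truth_labels
        Optional Series indexed by feature id with the generative tag of each
        feature (synthetic tables only).
    """

    abundances: pd.DataFrame
    roles: pd.Series
    truth_labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.abundances.index.equals(self.roles.index):
            raise ValueError("roles index must equal abundance sample index")
        bad = set(self.roles.unique()) - set(ROLES)
        if bad:
            raise ValueError(f"unknown sample roles: {sorted(bad)}")
        if self.truth_labels is not None:
            if not self.truth_labels.index.equals(self.abundances.columns):
                raise ValueError("truth_labels index must equal feature ids")

    @property
    def sample_ids(self) -> pd.Index:
        return self.abundances.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.abundances.columns

    @property
    def n_samples(self) -> int:
        return self.abundances.shape[0]

    @property
    def n_features(self) -> int:
        return self.abundances.shape[1]

    def study_mask(self) -> pd.Series:
        return self.roles == ROLE_STUDY

    def qc_mask(self) -> pd.Series:
        return self.roles == ROLE_QC

    def study_values(self) -> pd.DataFrame:
        """Abundance rows of study samples only."""
        return self.abundances.loc[self.study_mask()]

    def qc_values(self) -> pd.DataFrame:
        """Abundance rows of pooled-QC samples only."""
        return self.abundances.loc[self.qc_mask()]

    def select_features(self, feature_ids) -> "FeatureTable":
        """Sub-table restricted to ``feature_ids`` (order preserved)."""
        truth = None
        if self.truth_labels is not None:
            truth = self.truth_labels.loc[feature_ids]
        return FeatureTable(self.abundances[list(feature_ids)], self.roles.copy(), truth)

    def copy(self) -> "FeatureTable":
        truth = None if self.truth_labels is None else self.truth_labels.copy()
        return FeatureTable(self.abundances.copy(), self.roles.copy(), truth)


@dataclass
class ProcessedTable:
    """Study-samples-only matrix after preprocessing, with step provenance.

    ``data`` has the same shape contract as a FeatureTable restricted to study
    samples; ``provenance`` records each applied step and its parameters in
    order.
    """

    data: pd.DataFrame
    provenance: list[dict] = field(default_factory=list)

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.columns


# ---------------------------------------------------------------------------
# Delimited-text round trip
# ---------------------------------------------------------------------------

def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a FeatureTable as CSV (sample_id, role, one column per feature)."""
    out = table.abundances.copy()
    out.insert(0, "role", table.roles)
    out.index.name = "sample_id"
    out.to_csv(path, na_rep="")


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read the CSV written by :func:`write_feature_table`."""
    df = pd.read_csv(path, index_col="sample_id")
    roles = df.pop("role")
    df.columns.name = None
    return FeatureTable(df.astype(float), roles)


def write_truth_labels(table: FeatureTable, path: str | Path) -> None:
    if table.truth_labels is None:
        raise ValueError("table carries no truth labels")
    out = table.truth_labels.rename("truth_label").to_frame()
    out.index.name = "feature_id"
    out.to_csv(path)


def read_truth_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, index_col="feature_id")
    return df["truth_label"]


def write_cohort(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
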