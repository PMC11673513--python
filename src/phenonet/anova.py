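"""Per-feature two-way ANOVA, significance sets, post hoc contrasts.

Each feature is fit with the two-factor linear model with interaction,

    y ~ bmi_class + ipaq_class + bmi_class : ipaq_class,

on the (generally unbalanced) 2x2 design.  Sums of squares are sequential
(Type I) with the BMI factor entered first, the convention of the web
platforms metabolomics practitioners usually run this test on; Type II is
available as an option.  F = MS_effect / MS_error with error df = n - 4,
p from the upper tail of the F distribution.

Selection uses raw p < alpha (no multiplicity correction by default, with
optional Benjamini-Hochberg columns), and the three significance sets (BMI,
IPAQ, interaction) are partitioned into the seven disjoint Venn regions.
Post hoc comparisons are Fisher's LSD contrasts of every cell against a
reference cell (default ObeseLow) using the pooled within-cell mean square.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CELLS, HIGH, LEAN, LOW, OBESE, PHENOTYPE_VARIABLES
from .tables import ProcessedTable

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
_EFFECTS = ("bmi", "ipaq", "interaction")

#: Venn region keys, in canonical order.
VENN_REGIONS = (
    "bmi_only",
    "ipaq_only",
    "interaction_only",
    "bmi_ipaq",
    "bmi_interaction",
    "ipaq_interaction",
    "triple",
)


@dataclass
class AnovaRecord:
    """Two-way ANOVA result for one feature."""

    feature_id: str
    F_bmi: float
    F_ipaq: float
    F_interaction: float
    p_bmi: float
    p_ipaq: float
    p_interaction: float
    cell_means: dict[str, float]
    dir_bmi: str  # "up" iff obese mean > lean mean
    dir_ipaq: str  # "up" iff high-IPAQ mean > low-IPAQ mean


def _factor_arrays(bmi_class, ipaq_class) -> tuple[np.ndarray, np.ndarray]:
    b = np.asarray([1.0 if v == OBESE else 0.0 for v in bmi_class])
    i = np.asarray([1.0 if v == HIGH else 0.0 for v in ipaq_class])
    return b, i


def _check_design(b: np.ndarray, i: np.ndarray) -> None:
    for bv in (0, 1):
        for iv in (0, 1):
            if np.sum((b == bv) & (i == iv)) < 2:
                raise ValueError(
                    "two-way ANOVA requires >= 2 samples in every cell"
                )


def _sequential_ss(Y: np.ndarray, b: np.ndarray, i: np.ndarray):
    """Type I sums of squares (BMI, then IPAQ, then interaction) per column."""
    n = len(b)
    X = np.column_stack([np.ones(n), b, i, b * i])
    Q, _ = np.linalg.qr(X)
    C = Q.T @ Y  # (4, p)
    ss_total = np.einsum("ij,ij->j", Y, Y) - C[0] ** 2
    ss = np.vstack([C[1] ** 2, C[2] ** 2, C[3] ** 2])
    ss_err = np.clip(ss_total - ss.sum(axis=0), 0.0, None)
    return ss, ss_err


def _rss(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X)
    C = Q.T @ Y
    return np.einsum("ij,ij->j", Y, Y) - np.einsum("ij,ij->j", C, C)


def _type2_ss(Y: np.ndarray, b: np.ndarray, i: np.ndarray):
    """Type II sums of squares: main effects adjusted for each other."""
    n = len(b)
    ones = np.ones(n)
    rss_bi = _rss(Y, np.column_stack([ones, b, i]))
    rss_b = _rss(Y, np.column_stack([ones, b]))
    rss_i = _rss(Y, np.column_stack([ones, i]))
    rss_full = _rss(Y, np.column_stack([ones, b, i, b * i]))
    ss = np.vstack(
        [rss_i - rss_bi, rss_b - rss_bi, rss_bi - rss_full]
    )
    return np.clip(ss, 0.0, None), np.clip(rss_full, 0.0, None)


def _f_and_p(ss: np.ndarray, ss_err: np.ndarray, df_err: int):
    """F statistics and p-values, handling the zero-error-variance edge."""
    ms_err = ss_err / df_err
    scale = np.maximum(ss.sum(axis=0) + ss_err, 1.0)
    degenerate = ms_err <= 1e-12 * scale
    if np.any(degenerate):
        warnings.warn(
            "zero error variance for some features; p set to 0 for effects "
            "with positive SS and 1 otherwise",
            RuntimeWarning,
            stacklevel=3,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(degenerate[None, :], np.inf, ss / np.maximum(ms_err, 1e-300))
        p = stats.f.sf(F, 1, df_err)
    F = np.where(degenerate[None, :] & (ss <= 1e-12 * scale), 0.0, F)
    p = np.where(degenerate[None, :], np.where(ss > 1e-12 * scale, 0.0, 1.0), p)
    return F, p


def _anova_matrix(
    Y: np.ndarray, bmi_class, ipaq_class, ss_type: str = "I"
):
    """Vectorized two-way ANOVA over the columns of ``Y`` (n x p)."""
    b, i = _factor_arrays(bmi_class, ipaq_class)
    _check_design(b, i)
    n = len(b)
    if ss_type == "I":
        ss, ss_err = _sequential_ss(Y, b, i)
    elif ss_type == "II":
        ss, ss_err = _type2_ss(Y, b, i)
    else:
        raise ValueError("ss_type must be 'I' or 'II'")
    F, p = _f_and_p(ss, ss_err, n - 4)
    return F, p, b, i


def two_way_anova(
    values, bmi_class, ipaq_class, feature_id: str = "feature", ss_type: str = "I"
) -> AnovaRecord:
    """Two-way ANOVA with interaction for a single feature.

    ``values`` are per-sample responses; ``bmi_class`` and ``ipaq_class`` the
    per-sample factor levels (``lean``/``overweight_obese`` and
    ``low``/``high``).
    """
    y = np.asarray(values, dtype=float)
    F, p, b, i = _anova_matrix(y[:, None], bmi_class, ipaq_class, ss_type)
    cell_means = {}
    for cell, bv, iv in zip(CELLS, (0, 0, 1, 1), (0, 1, 0, 1)):
        cell_means[cell] = float(y[(b == bv) & (i == iv)].mean())
    dir_bmi = "up" if y[b == 1].mean() > y[b == 0].mean() else "down"
    dir_ipaq = "up" if y[i == 1].mean() > y[i == 0].mean() else "down"
    return AnovaRecord(
        feature_id=feature_id,
        F_bmi=float(F[0, 0]),
        F_ipaq=float(F[1, 0]),
        F_interaction=float(F[2, 0]),
        p_bmi=float(p[0, 0]),
        p_ipaq=float(p[1, 0]),
        p_interaction=float(p[2, 0]),
        cell_means=cell_means,
        dir_bmi=dir_bmi,
        dir_ipaq=dir_ipaq,
    )


def run_anova(
    processed: ProcessedTable,
    meta: pd.DataFrame,
    ss_type: str = "I",
    fdr: bool = True,
) -> pd.DataFrame:
    """Tablewise two-way ANOVA; one row per feature, sorted by feature id.

    Samples are matched to subjects by id.  Returns a DataFrame indexed by
    feature id with F/p per effect, the four cell means, marginal directions,
    and (optionally) Benjamini-Hochberg adjusted q-values.
    """
    meta_idx = meta.set_index("subject_id")
    missing = processed.sample_ids.difference(meta_idx.index)
    if len(missing):
        raise ValueError(f"samples absent from cohort metadata: {list(missing)[:5]}")
    meta_aligned = meta_idx.loc[processed.sample_ids]

    Y = processed.data.to_numpy(dtype=float)
    F, p, b, i = _anova_matrix(
        Y, meta_aligned["bmi_class"], meta_aligned["ipaq_class"], ss_type
    )
    out = pd.DataFrame(
        {
            "F_bmi": F[0], "p_bmi": p[0],
            "F_ipaq": F[1], "p_ipaq": p[1],
            "F_interaction": F[2], "p_interaction": p[2],
        },
        index=processed.feature_ids,
    )
    for cell, bv, iv in zip(CELLS, (0, 0, 1, 1), (0, 1, 0, 1)):
        mask = (b == bv) & (i == iv)
        out[f"mean_{cell}"] = Y[mask].mean(axis=0)
    obese_mean = Y[b == 1].mean(axis=0)
    lean_mean = Y[b == 0].mean(axis=0)
    high_mean = Y[i == 1].mean(axis=0)
    low_mean = Y[i == 0].mean(axis=0)
    out["dir_bmi"] = np.where(obese_mean > lean_mean, "up", "down")
    out["dir_ipaq"] = np.where(high_mean > low_mean, "up", "down")
    if fdr:
        for eff in _EFFECTS:
            out[f"q_{eff}"] = _benjamini_hochberg(out[f"p_{eff}"].to_numpy())
    out.index.name = "feature_id"
    return out.sort_index()


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(q, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# Significance sets and Venn partition
# ---------------------------------------------------------------------------

@dataclass
class SignificanceSets:
    """The three raw-p significance sets and their seven-region Venn partition."""

    set_bmi: frozenset
    set_ipaq: frozenset
    set_interaction: frozenset
    alpha: float
    venn: dict[str, frozenset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.venn:
            self.venn = _venn_partition(
                self.set_bmi, self.set_ipaq, self.set_interaction
            )

    @property
    def union(self) -> frozenset:
        return self.set_bmi | self.set_ipaq | self.set_interaction

    def region_counts(self) -> dict[str, int]:
        counts = {k: len(v) for k, v in self.venn.items()}
        counts["union"] = len(self.union)
        return counts


def _venn_partition(a: frozenset, b: frozenset, c: frozenset) -> dict[str, frozenset]:
    return {
        "bmi_only": a - b - c,
        "ipaq_only": b - a - c,
        "interaction_only": c - a - b,
        "bmi_ipaq": (a & b) - c,
        "bmi_interaction": (a & c) - b,
        "ipaq_interaction": (b & c) - a,
        "triple": a & b & c,
    }


def select_significant(
    records: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> SignificanceSets:
    """Partition features by which effects reach raw p < alpha (strict)."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    sets = {}
    for eff in _EFFECTS:
        if len(records):
            sets[eff] = frozenset(records.index[records[f"p_{eff}"] < alpha])
        else:
            sets[eff] = frozenset()
    return SignificanceSets(
        set_bmi=sets["bmi"],
        set_ipaq=sets["ipaq"],
        set_interaction=sets["interaction"],
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Post hoc: Fisher's LSD against a reference cell
# ---------------------------------------------------------------------------

@dataclass
class Contrast:
    cell: str
    difference: float  # cell mean - reference mean
    t: float
    p: float
    significant: bool


@dataclass
class PosthocRecord:
    feature_id: str
    reference_cell: str
    contrasts: dict[str, Contrast]
    ms_error: float
    df_error: int


def posthoc_lsd(
    values,
    cells,
    reference_cell: str = "ObeseLow",
    alpha: float = DEFAULT_ALPHA,
    feature_id: str = "feature",
) -> PosthocRecord:
    """Fisher's least-significant-difference contrasts vs a reference cell.

    Uses the pooled within-cell mean square of the cell-means model as error
    variance (df = n - number of non-empty cells); each non-reference,
    non-empty cell contributes one unadjusted two-sided t contrast.
    """
    y = np.asarray(values, dtype=float)
    cells = np.asarray(cells)
    present = [c for c in CELLS if np.any(cells == c)]
    if reference_cell not in present:
        raise ValueError(f"reference cell {reference_cell!r} is empty")

    ss_within = 0.0
    means, ns = {}, {}
    for c in present:
        vals = y[cells == c]
        means[c] = vals.mean()
        ns[c] = len(vals)
        ss_within += float(((vals - vals.mean()) ** 2).sum())
    df = len(y) - len(present)
    if df <= 0:
        raise ValueError("no residual degrees of freedom for the LSD contrasts")
    mse = ss_within / df

    contrasts = {}
    for c in present:
        if c == reference_cell:
            continue
        diff = means[c] - means[reference_cell]
        se = np.sqrt(mse * (1.0 / ns[c] + 1.0 / ns[reference_cell]))
        if se == 0:
            t = np.inf if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        else:
            t = diff / se
            p = 2.0 * stats.t.sf(abs(t), df)
        contrasts[c] = Contrast(c, float(diff), float(t), float(p), p < alpha)
    return PosthocRecord(feature_id, reference_cell, contrasts, mse, df)


def run_posthoc(
    processed: ProcessedTable,
    meta: pd.DataFrame,
    feature_ids,
    reference_cell: str = "ObeseLow",
    alpha: float = DEFAULT_ALPHA,
) -> dict[str, PosthocRecord]:
    """LSD contrasts for each listed feature, keyed by feature id."""
    meta_aligned = meta.set_index("subject_id").loc[processed.sample_ids]
    cells = meta_aligned["cell"].to_numpy()
    out = {}
    for fid in feature_ids:
        out[fid] = posthoc_lsd(
            processed.data[fid].to_numpy(), cells, reference_cell, alpha, fid
        )
    return out


# ---------------------------------------------------------------------------
# Reporting tables
# ---------------------------------------------------------------------------

def direction_table(
    records: pd.DataFrame,
    posthoc: dict[str, PosthocRecord],
    sets: SignificanceSets,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-selected-feature summary of effect directions and LSD outcomes.

    One row per feature in the combined significance set: the BMI direction
    arrow ("up"/"down", dash when not significant) with its p, likewise for
    IPAQ, one column per interaction cell with the LSD verdict vs the
    reference cell ("up*"/"down*" when significant, "-" otherwise; the
    reference's own column shows the opposing direction when any contrast is
    significant), and the interaction p.
    """
    rows = []
    for fid in sorted(sets.union):
        rec = records.loc[fid]
        ph = posthoc.get(fid)
        row = {
            "feature_id": fid,
            "bmi_dir": rec["dir_bmi"] if rec["p_bmi"] < alpha else "-",
            "p_bmi": rec["p_bmi"],
            "ipaq_dir": rec["dir_ipaq"] if rec["p_ipaq"] < alpha else "-",
            "p_ipaq": rec["p_ipaq"],
        }
        for cell in CELLS:
            row[cell] = "-"
        if ph is not None:
            sig = [c for c in ph.contrasts.values() if c.significant]
            for c in ph.contrasts.values():
                if c.significant:
                    row[c.cell] = ("up*" if c.difference > 0 else "down*")
            if sig:
                mean_diff = np.mean([c.difference for c in sig])
                row[ph.reference_cell] = "up" if mean_diff < 0 else "down"
        row["p_interaction"] = rec["p_interaction"]
        rows.append(row)
    cols = ["feature_id", "bmi_dir", "p_bmi", "ipaq_dir", "p_ipaq",
            *CELLS, "p_interaction"]
    return pd.DataFrame(rows, columns=cols)


def subgroup_correlations(meta: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between continuous BMI and IPAQ within each cell and overall.

    Returns rows for the four interaction cells plus ``overall`` with columns
    ``r``, ``n``, ``p`` (two-sided, via the t transform with n-2 df).  Cells
    with fewer than 3 subjects or degenerate variance report NaN.
    """
    rows = []
    groups = [(c, meta[meta["cell"] == c]) for c in CELLS] + [("overall", meta)]
    for label, grp in groups:
        n = len(grp)
        x = grp["bmi_value"].to_numpy(dtype=float)
        y = grp["ipaq_score"].to_numpy(dtype=float)
        if n < 3 or np.std(x) == 0 or np.std(y) == 0:
            rows.append({"group": label, "r": np.nan, "n": n, "p": np.nan})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"group": label, "r": float(r), "n": n, "p": float(p)})
    return pd.DataFrame(rows).set_index("group")


def group_summary(meta: pd.DataFrame) -> pd.DataFrame:
    """Descriptive mean +/- SD per group with a one-way ANOVA p per variable.

    Groupings are the BMI dichotomy (lean vs overweight/obese) and the IPAQ
    dichotomy (low vs high); variables are age, body mass, height, BMI and
    IPAQ score.
    """
    rows = []
    for grouping, levels in (
        ("bmi_class", (LEAN, OBESE)),
        ("ipaq_class", (LOW, HIGH)),
    ):
        g1 = meta[meta[grouping] == levels[0]]
        g2 = meta[meta[grouping] == levels[1]]
        for var in PHENOTYPE_VARIABLES:
            a = g1[var].to_numpy(dtype=float)
            b = g2[var].to_numpy(dtype=float)
            if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
                p = 1.0
            else:
                _, p = stats.f_oneway(a, b)
            rows.append(
                {
                    "grouping": grouping,
                    "variable": var,
                    "level_a": levels[0],
                    "mean_a": a.mean(),
                    "sd_a": a.std(ddof=1),
                    "level_b": levels[1],
                    "mean_b": b.mean(),
                    "sd_b": b.std(ddof=1),
                    "p": float(p),
                }
            )
    return pd.DataFrame(rows)
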