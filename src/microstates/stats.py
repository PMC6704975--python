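"""Group comparisons and clinical correlations of microstate parameters.

Two analyses mirror the standard clinical-EEG workflow: independent
two-sample t-tests comparing each temporal parameter (duration, occurrence,
coverage) of each microstate class between patients and controls, corrected
for multiple comparisons with the Benjamini-Hochberg false-discovery-rate
procedure applied within each parameter family (the K classes); and
Spearman rank correlations of every microstate parameter with clinical
covariates (depression severity scores, episode count, illness duration,
medication measures) in the patient group, flagged at alpha = 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupTestResult",
    "CorrelationResult",
    "PARAMETERS",
    "CLINICAL_VARIABLES",
    "group_ttests",
    "spearman_corr",
    "correlate_with_clinical",
    "validate_clinical",
]

#: Temporal-parameter columns of the tidy metrics table.
PARAMETERS = ("duration_ms", "occurrence_per_s", "coverage")

#: Clinical covariates correlated against microstate parameters.
CLINICAL_VARIABLES = (
    "madrs",
    "cgi",
    "n_episodes",
    "illness_duration_y",
    "bzd_equivalent",
    "medication_scale",
)


@dataclass
class GroupTestResult:
    parameter: str
    class_label: str
    t: float
    df: float
    p_raw: float
    p_fdr: float
    n_group1: int
    n_group2: int


@dataclass
class CorrelationResult:
    parameter: str
    class_label: str
    clinical_variable: str
    rho: float
    p: float
    n: int
    significant: bool


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Schema check for a clinical covariate table.

    Requires a ``subject`` column; validates value ranges where they are
    structurally constrained (MADRS >= 0, medication scale in 0..4 with 0
    meaning unmedicated/control).
    """
    if "subject" not in clinical.columns:
        raise ValueError("clinical table must have a 'subject' column")
    if clinical["subject"].duplicated().any():
        dupes = clinical.loc[clinical["subject"].duplicated(), "subject"].tolist()
        raise ValueError(f"duplicate subjects in clinical table: {dupes}")
    if "madrs" in clinical.columns and (clinical["madrs"].dropna() < 0).any():
        raise ValueError("MADRS scores must be non-negative")
    if "medication_scale" in clinical.columns:
        vals = set(clinical["medication_scale"].dropna().astype(int))
        if not vals <= {0, 1, 2, 3, 4}:
            raise ValueError(f"medication_scale must lie in 0..4, got {sorted(vals)}")
    return clinical


def group_ttests(
    metrics: pd.DataFrame,
    parameters: tuple[str, ...] = PARAMETERS,
    groups: tuple[str, str] = ("patient", "control"),
    welch: bool = False,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Independent t-tests per (parameter, class) with per-family FDR correction.

    ``metrics`` is the tidy per-subject table (columns ``subject``,
    ``group``, ``class`` and the parameter columns).  For each parameter
    family the K class-wise two-sided tests are corrected together with
    Benjamini-Hochberg.  The pooled-variance (classical) t-test is the
    default; set ``welch=True`` for unequal variances.  A cell where both
    groups are constant has an undefined t statistic and is reported as NaN
    while the remaining cells proceed.
    """
    for col in ("group", "class", *parameters):
        if col not in metrics.columns:
            raise ValueError(f"metrics table lacks required column {col!r}")
    g1, g2 = groups
    present = set(metrics["group"])
    if g1 not in present or g2 not in present:
        raise ValueError(f"both groups {groups} must be present, found {sorted(present)}")
    classes = sorted(metrics["class"].unique())
    rows: list[GroupTestResult] = []
    for param in parameters:
        fam: list[GroupTestResult] = []
        for cls in classes:
            sub = metrics[metrics["class"] == cls]
            x = sub.loc[sub["group"] == g1, param].dropna().to_numpy(float)
            y = sub.loc[sub["group"] == g2, param].dropna().to_numpy(float)
            if len(x) < 2 or len(y) < 2:
                raise ValueError(
                    f"need >= 2 subjects per group for {param}/{cls}, "
                    f"got {len(x)} and {len(y)}"
                )
            if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
                t = p = np.nan
                dof = np.nan
            else:
                res = sps.ttest_ind(x, y, equal_var=not welch)
                t, p = float(res.statistic), float(res.pvalue)
                dof = float(res.df)
            fam.append(
                GroupTestResult(param, str(cls), t, dof, p, np.nan, len(x), len(y))
            )
        pvals = np.array([r.p_raw for r in fam])
        ok = ~np.isnan(pvals)
        if ok.any():
            adj = multipletests(pvals[ok], alpha=fdr_alpha, method="fdr_bh")[1]
            j = 0
            for i, r in enumerate(fam):
                if ok[i]:
                    r.p_fdr = float(adj[j])
                    j += 1
        rows.extend(fam)
    return pd.DataFrame(
        [r.__dict__ for r in rows]
    ).rename(columns={"class_label": "class"})


def spearman_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    The coefficient is the Pearson correlation of mid-ranks (average ranks
    for ties); the p-value uses the t distribution with n - 2 degrees of
    freedom, the standard approximation at moderate n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values must be removed (pairwise) before correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def correlate_with_clinical(
    metrics: pd.DataFrame,
    clinical: pd.DataFrame,
    alpha: float = 0.01,
    parameters: tuple[str, ...] = PARAMETERS,
    clinical_variables: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Spearman correlations of microstate parameters with clinical covariates.

    Patients only: the subjects of the clinical table must match the patient
    subjects of the metrics table exactly.  One row is produced per
    (parameter x class x clinical variable), with the significance flag at
    ``alpha`` (default 0.01); the full table is returned, not only the
    significant rows.  Cells with missing metric values use pairwise
    deletion; cells left with fewer than 3 pairs, or with a constant vector,
    are reported with NaN rho and p.
    """
    validate_clinical(clinical)
    if clinical_variables is None:
        clinical_variables = tuple(
            v for v in CLINICAL_VARIABLES if v in clinical.columns
        )
        if not clinical_variables:
            raise ValueError(
                f"clinical table has none of the known covariates {CLINICAL_VARIABLES}"
            )
    pat = metrics[metrics["group"] == "patient"] if "group" in metrics.columns else metrics
    m_subj = set(pat["subject"])
    c_subj = set(clinical["subject"])
    if m_subj != c_subj:
        raise ValueError(
            f"subject mismatch between metrics and clinical tables: "
            f"only in metrics {sorted(m_subj - c_subj)}, "
            f"only in clinical {sorted(c_subj - m_subj)}"
        )
    classes = sorted(pat["class"].unique())
    rows: list[CorrelationResult] = []
    for param in parameters:
        for cls in classes:
            cell = pat.loc[pat["class"] == cls, ["subject", param]]
            merged = cell.merge(clinical, on="subject")
            for var in clinical_variables:
                pair = merged[[param, var]].dropna()
                try:
                    rho, p = spearman_corr(pair[param].to_numpy(), pair[var].to_numpy())
                except ValueError:
                    rho, p = np.nan, np.nan
                rows.append(
                    CorrelationResult(
                        param, str(cls), var, rho, p, len(pair),
                        bool(p < alpha) if not np.isnan(p) else False,
                    )
                )
    return pd.DataFrame([r.__dict__ for r in rows]).rename(
        columns={"class_label": "class"}
    )
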