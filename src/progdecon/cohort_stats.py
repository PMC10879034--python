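"""Cohort-level GLM statistics for cell frequencies and program features.

For every cell cluster independently, differential abundance across
disease conditions is modeled by a binomial GLM with logit link on the
per-sample response (n_cat, n_total - n_cat):

    (n_cat, n_total - n_cat) ~ Disease + Age/25 + Gender + Project

with healthy as the disease baseline, age scaled by 25 years to match the
magnitude of the other covariates, male as the gender reference and the
first-observed project as the project reference. Qualitative change of a
gene program within a cluster is modeled by ordinary least squares of the
per-sample mean program activity on the same linear predictor. p-values
are Wald tests; multiple testing is corrected by Benjamini-Hochberg FDR
across clusters within one term (frequency model) or within one
(term, component) pair (feature model).

A sample-level QC precedes model fitting: sex is inferred from mean XIST
raw counts (> 0.05 means female) and samples whose inferred sex conflicts
with their metadata are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .containers import DomainError, FormatError

__all__ = [
    "AGE_SCALE",
    "XIST_THRESHOLD",
    "CohortTable",
    "infer_sex_qc",
    "apply_sex_qc",
    "fit_frequency_model",
    "fit_feature_model",
    "fit_cohort_models",
    "adjust_fdr",
    "scale_intercepts",
]

#: Age is divided by this number of years in all design matrices.
AGE_SCALE = 25.0

#: Mean raw XIST count above which a sample is inferred female.
XIST_THRESHOLD = 0.05

_ESTIMATE_COLUMNS = [
    "cluster", "component", "term", "coefficient", "std_error", "p_value", "note",
]


@dataclass
class CohortTable:
    """Per-sample metadata, per-cluster cell counts and program features.

    ``meta`` is indexed by sample_id with columns ``disease``, ``age``,
    ``gender``, ``project`` and optionally ``mean_xist``; ``counts`` is a
    samples x clusters integer table (row sums define n_total); ``features``
    is a tidy table (sample_id, cluster, component, value) of per-sample
    mean program activities and may be None.
    """

    meta: pd.DataFrame
    counts: pd.DataFrame
    features: pd.DataFrame | None = None

    def __post_init__(self):
        required = {"disease", "age", "gender", "project"}
        missing = required - set(self.meta.columns)
        if missing:
            raise FormatError(f"meta is missing columns: {sorted(missing)}")
        if not self.meta.index.is_unique:
            raise FormatError("duplicate sample_id in meta")
        if not self.counts.index.equals(self.meta.index):
            self.counts = self.counts.reindex(self.meta.index)
            if self.counts.isna().any().any():
                raise FormatError("counts and meta sample_ids do not match")
        if (self.counts.to_numpy() < 0).any():
            raise DomainError("negative cell counts")
        if self.features is not None:
            needed = {"sample_id", "cluster", "component", "value"}
            if not needed <= set(self.features.columns):
                raise FormatError(f"features needs columns {sorted(needed)}")

    @property
    def clusters(self) -> list[str]:
        return [str(c) for c in self.counts.columns]

    @property
    def n_total(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def subset(self, sample_ids) -> "CohortTable":
        sample_ids = list(sample_ids)
        feats = None
        if self.features is not None:
            feats = self.features[self.features["sample_id"].isin(sample_ids)]
        return CohortTable(
            self.meta.loc[sample_ids].copy(), self.counts.loc[sample_ids].copy(), feats
        )


def infer_sex_qc(table: CohortTable, threshold: float = XIST_THRESHOLD) -> pd.DataFrame:
    """Compare XIST-inferred sex with metadata; flag conflicting samples.

    A sample is inferred female iff its mean raw XIST count exceeds
    ``threshold``. Samples without a ``mean_xist`` value pass with a
    notice. Returns one row per sample with columns ``sample_id``,
    ``inferred_gender``, ``metadata_gender``, ``flagged``, ``note``.
    """
    rows = []
    has_xist = "mean_xist" in table.meta.columns
    for sid, row in table.meta.iterrows():
        xist = row.get("mean_xist") if has_xist else None
        if xist is None or (isinstance(xist, float) and np.isnan(xist)):
            rows.append((sid, None, row["gender"], False, "no mean_xist; not checked"))
            continue
        inferred = "female" if xist > threshold else "male"
        flagged = inferred != str(row["gender"]).lower()
        rows.append((sid, inferred, row["gender"], flagged, ""))
    return pd.DataFrame(
        rows, columns=["sample_id", "inferred_gender", "metadata_gender", "flagged", "note"]
    )


def apply_sex_qc(table: CohortTable, threshold: float = XIST_THRESHOLD) -> CohortTable:
    """Drop samples whose inferred and recorded sex conflict."""
    qc = infer_sex_qc(table, threshold)
    keep = qc.loc[~qc["flagged"], "sample_id"]
    n_drop = int(qc["flagged"].sum())
    if n_drop:
        warnings.warn(f"sex QC removed {n_drop} sample(s)", stacklevel=2)
    return table.subset(keep)


def _first_observed_levels(series: pd.Series) -> list[str]:
    seen: list[str] = []
    for v in series:
        v = str(v)
        if v not in seen:
            seen.append(v)
    return seen


def _build_design(meta: pd.DataFrame, notes: list[str]) -> pd.DataFrame:
    """Intercept + one-hot design with the model's fixed reference levels."""
    design = pd.DataFrame(index=meta.index)
    design["Intercept"] = 1.0

    disease_levels = _first_observed_levels(meta["disease"])
    if "healthy" in disease_levels:
        ref = "healthy"
    else:
        ref = disease_levels[0]
        notes.append(f"no 'healthy' level; using {ref!r} as disease baseline")
    others = [l for l in disease_levels if l != ref]
    if not others:
        notes.append("disease has a single level; disease terms dropped")
    for lev in others:
        design[f"disease[{lev}]"] = (meta["disease"].astype(str) == lev).astype(float)

    design["age"] = meta["age"].astype(float) / AGE_SCALE

    genders = set(meta["gender"].astype(str).str.lower())
    if len(genders) > 1:
        design["gender[female]"] = (
            meta["gender"].astype(str).str.lower() == "female"
        ).astype(float)
    else:
        notes.append("gender has a single level; gender term dropped")

    project_levels = _first_observed_levels(meta["project"])
    if len(project_levels) > 1:
        for lev in project_levels[1:]:
            design[f"project[{lev}]"] = (
                meta["project"].astype(str) == lev
            ).astype(float)
    else:
        notes.append("project has a single level; project term dropped")
    return design


def _drop_aliased(design: pd.DataFrame, notes: list[str]) -> pd.DataFrame:
    """Drop columns that do not increase design rank (aliased terms)."""
    X = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return design
    keep: list[int] = []
    for j in range(X.shape[1]):
        trial = keep + [j]
        if np.linalg.matrix_rank(X[:, trial]) == len(trial):
            keep.append(j)
    dropped = [design.columns[j] for j in range(X.shape[1]) if j not in keep]
    notes.append(f"aliased terms dropped: {dropped}")
    warnings.warn(f"rank-deficient design; dropped {dropped}", stacklevel=3)
    return design.iloc[:, keep]


def _estimates_frame(cluster, component, params, bse, pvals, terms, note=""):
    return pd.DataFrame(
        {
            "cluster": cluster,
            "component": component,
            "term": terms,
            "coefficient": params,
            "std_error": bse,
            "p_value": pvals,
            "note": note,
        },
        columns=_ESTIMATE_COLUMNS,
    )


def fit_frequency_model(table: CohortTable, cluster: str) -> pd.DataFrame:
    """Binomial GLM of one cluster's cell frequency on the cohort covariates."""
    if cluster not in table.counts.columns:
        raise DomainError(f"unknown cluster {cluster!r}")
    n_total = table.n_total
    keep = n_total > 0
    if (~keep).any():
        warnings.warn(
            f"{int((~keep).sum())} sample(s) with zero cells excluded", stacklevel=2
        )
    meta = table.meta.loc[keep]
    n_cat = table.counts.loc[keep, cluster].to_numpy(dtype=float)
    n_tot = n_total.loc[keep].to_numpy(dtype=float)

    notes: list[str] = []
    design = _drop_aliased(_build_design(meta, notes), notes)
    endog = np.column_stack([n_cat, n_tot - n_cat])
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = sm.GLM(endog, design, family=sm.families.Binomial()).fit()
        for w in caught:
            if "separation" in str(w.message).lower():
                notes.append("possible perfect separation; estimates unstable")
                warnings.warn(str(w.message), stacklevel=2)
    except PerfectSeparationError:
        warnings.warn(
            f"perfect separation in cluster {cluster}; estimates undefined",
            stacklevel=2,
        )
        nan = np.full(design.shape[1], np.nan)
        return _estimates_frame(
            cluster, None, nan, nan, nan, list(design.columns), "perfect separation"
        )
    return _estimates_frame(
        cluster, None, res.params.to_numpy(), res.bse.to_numpy(),
        res.pvalues.to_numpy(), list(design.columns), "; ".join(notes),
    )


def fit_feature_model(table: CohortTable, cluster: str, component: str) -> pd.DataFrame:
    """OLS of one (cluster, component) mean program activity on the covariates."""
    if table.features is None:
        raise DomainError("cohort table has no feature values")
    feats = table.features
    sel = (feats["cluster"].astype(str) == str(cluster)) & (
        feats["component"].astype(str) == str(component)
    )
    sub = feats.loc[sel].dropna(subset=["value"])
    if sub.empty:
        raise DomainError(f"no feature values for ({cluster}, {component})")
    sub = sub.set_index("sample_id")
    meta = table.meta.loc[table.meta.index.intersection(sub.index)]
    y = sub.loc[meta.index, "value"].to_numpy(dtype=float)

    notes: list[str] = []
    design = _drop_aliased(_build_design(meta, notes), notes)
    if len(meta) <= design.shape[1]:
        raise DomainError(
            f"only {len(meta)} samples for {design.shape[1]} design terms"
        )
    res = sm.OLS(y, design).fit()
    return _estimates_frame(
        cluster, component, res.params.to_numpy(), res.bse.to_numpy(),
        res.pvalues.to_numpy(), list(design.columns), "; ".join(notes),
    )


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg q-values, input order preserved, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _adjust_within(estimates: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    estimates = estimates.copy()
    estimates["q_value"] = np.nan
    for _, idx in estimates.groupby(keys, dropna=False).groups.items():
        pv = estimates.loc[idx, "p_value"]
        ok = pv.notna()
        if ok.any():
            estimates.loc[idx[ok], "q_value"] = adjust_fdr(pv[ok].to_numpy())
    return estimates


def fit_cohort_models(
    table: CohortTable,
    clusters=None,
    components=None,
    sex_qc: bool = True,
) -> pd.DataFrame:
    """Fit frequency models for all clusters and feature models for all
    (cluster, component) pairs, with BH-FDR applied within the families
    described in the module docstring. Returns one tidy estimates table
    with a ``model`` column (``frequency`` or ``feature``).
    """
    if sex_qc:
        table = apply_sex_qc(table)
    clusters = list(clusters) if clusters is not None else table.clusters
    out = []
    for cl in clusters:
        est = fit_frequency_model(table, cl)
        est["model"] = "frequency"
        out.append(est)
    freq = _adjust_within(pd.concat(out, ignore_index=True), ["term"])

    parts = [freq]
    if table.features is not None:
        if components is None:
            components = sorted(table.features["component"].astype(str).unique())
        feat_rows = []
        for comp in components:
            for cl in clusters:
                try:
                    est = fit_feature_model(table, cl, comp)
                except DomainError:
                    continue
                est["model"] = "feature"
                feat_rows.append(est)
        if feat_rows:
            feat = _adjust_within(
                pd.concat(feat_rows, ignore_index=True), ["term", "component"]
            )
            parts.append(feat)
    return pd.concat(parts, ignore_index=True)


def scale_intercepts(estimates: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale feature-model intercepts across clusters per component.

    The scaled intercept serves as a comparable baseline program activity
    per cluster. Raw intercepts are kept alongside. A single cluster or a
    degenerate (zero) range yields scaled value 0 with a warning.
    """
    ic = estimates[
        (estimates["term"] == "Intercept") & estimates["component"].notna()
    ]
    if ic.empty:
        raise DomainError("no feature-model intercepts found")
    rows = []
    for comp, grp in ic.groupby("component"):
        vals = grp["coefficient"].to_numpy(dtype=float)
        rng = vals.max() - vals.min()
        if len(vals) < 2 or rng == 0:
            warnings.warn(
                f"component {comp}: degenerate intercept range; scaled values set to 0",
                stacklevel=2,
            )
            scaled = np.zeros(len(vals))
        else:
            scaled = (vals - vals.min()) / rng
        for (_, r), s in zip(grp.iterrows(), scaled):
            rows.append((r["cluster"], comp, r["coefficient"], s))
    return pd.DataFrame(
        rows, columns=["cluster", "component", "intercept", "scaled_intercept"]
    )
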