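"""Synthetic bases, expression matrices and cohorts with known ground truth.

Every generator is a pure function of its arguments and seed, so fixtures
are reproducible bit-exactly and no external download is needed. The
expression generator follows the generative model the decomposition
assumes: a block-structured nonnegative basis, gamma-distributed
(right-skewed, occasionally near-zero) per-column program activities, and
either clipped-Gaussian or Poisson count noise around W.H. The cohort
generator draws per-sample covariates, passes them through the same
logit/linear models the statistics layer fits, and embeds the true
coefficients for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_stats import AGE_SCALE, CohortTable
from .containers import (
    DomainError,
    ExpressionMatrix,
    GeneProgramBasis,
    ProgramActivity,
    default_component_ids,
)

__all__ = [
    "SimulationTruth",
    "make_gene_ids",
    "simulate_basis",
    "simulate_expression",
    "simulate_cohort",
]


@dataclass
class SimulationTruth:
    """Ground truth embedded in a synthetic dataset."""

    seed: int
    true_basis: GeneProgramBasis | None = None
    true_activity: ProgramActivity | None = None
    noise_model: str = "none"
    noise_scale: float = 0.0
    cohort_effects: dict = field(default_factory=dict)


def make_gene_ids(n_genes: int, vdj_fraction: float = 0.0, seed: int = 0) -> list[str]:
    """G000001... identifiers with an optional fraction of VDJ-prefixed decoys."""
    if not 0 <= vdj_fraction <= 1:
        raise DomainError("vdj_fraction must be in [0, 1]")
    ids = [f"G{i + 1:06d}" for i in range(n_genes)]
    n_vdj = int(round(vdj_fraction * n_genes))
    if n_vdj:
        rng = np.random.default_rng(seed)
        pos = rng.choice(n_genes, size=n_vdj, replace=False)
        for rank, p in enumerate(sorted(pos)):
            ids[p] = f"TRBV{rank + 1}-{ids[p]}"
    return ids


def simulate_basis(
    n_genes: int,
    k: int,
    overlap: float = 0.0,
    seed: int = 0,
    vdj_fraction: float = 0.0,
) -> GeneProgramBasis:
    """Block-structured nonnegative basis with k programs.

    Each component owns ``n_genes // k`` dominant genes (gamma weights
    shifted away from zero); ``overlap`` in [0, 1] controls how much
    weight bleeds across components (0 gives disjoint supports).
    """
    if n_genes < 10 * k:
        raise DomainError(f"need n_genes >= 10*k (got {n_genes} < {10 * k})")
    if not 0 <= overlap <= 1:
        raise DomainError("overlap must be in [0, 1]")
    rng = np.random.default_rng(seed)
    W = overlap * 0.3 * rng.gamma(2.0, 1.0, size=(n_genes, k))
    block = n_genes // k
    for c in range(k):
        lo = c * block
        hi = n_genes if c == k - 1 else (c + 1) * block
        W[lo:hi, c] = rng.gamma(2.0, 1.0, size=hi - lo) + 1.0
    gene_ids = make_gene_ids(n_genes, vdj_fraction=vdj_fraction, seed=seed)
    return GeneProgramBasis(W, gene_ids, default_component_ids(k))


def simulate_expression(
    W_true: GeneProgramBasis,
    n_columns: int,
    noise_model: str = "gaussian_clipped",
    noise_scale: float = 0.05,
    seed: int = 0,
    activity_shape: float = 2.0,
    activity_scale: float = 1.0,
    target_column_sum: float | None = None,
) -> tuple[ExpressionMatrix, ProgramActivity]:
    """Draw activities and a noisy expression matrix around W.H.

    ``noise_model`` is ``none``, ``gaussian_clipped`` (additive normal of
    sd ``noise_scale``, clipped at 0) or ``poisson`` (counts with mean
    W.H; ``noise_scale`` is ignored). ``target_column_sum`` rescales the
    mean matrix (and the returned true H) so column sums match a typical
    library size before sampling.
    """
    if n_columns <= 0:
        raise DomainError(f"n_columns must be positive, got {n_columns}")
    if noise_scale < 0:
        raise DomainError("noise_scale must be >= 0")
    if noise_model not in ("none", "gaussian_clipped", "poisson"):
        raise DomainError(f"unknown noise model {noise_model!r}")
    rng = np.random.default_rng(seed)
    k = W_true.n_components
    H = rng.gamma(activity_shape, activity_scale, size=(k, n_columns))
    M = W_true.weights @ H
    if target_column_sum is not None:
        s = target_column_sum / M.sum(axis=0).mean()
        M *= s
        H = H * s
    if noise_model == "none":
        X = M
    elif noise_model == "gaussian_clipped":
        X = np.clip(M + rng.normal(0.0, noise_scale, size=M.shape), 0.0, None)
    else:
        X = rng.poisson(M).astype(float)
    col_ids = [f"C{j + 1:05d}" for j in range(n_columns)]
    xm = ExpressionMatrix(X, list(W_true.gene_ids), col_ids, value_kind="raw_count")
    act = ProgramActivity(H, list(W_true.component_ids), col_ids)
    return xm, act


def _cohort_design_row(disease, age, gender, project, effects, ref_disease="healthy"):
    """Linear-predictor contribution of one sample's covariates."""
    eta = 0.0
    if disease != ref_disease:
        eta += effects.get(f"disease[{disease}]", 0.0)
    eta += effects.get("age", 0.0) * (age / AGE_SCALE)
    if gender == "female":
        eta += effects.get("gender[female]", 0.0)
    eta += effects.get(f"project[{project}]", 0.0)
    return eta


def simulate_cohort(
    n_samples: int,
    diseases=("healthy", "case"),
    freq_effects: dict | None = None,
    feature_effects: dict | None = None,
    baseline_prob: float = 0.1,
    feature_baseline: float = 1.0,
    feature_residual_sd: float = 0.3,
    cells_per_sample: int = 1000,
    n_projects: int = 2,
    component: str = "NMF0",
    seed: int = 0,
) -> tuple[CohortTable, SimulationTruth]:
    """Cohort with a target cluster whose frequency follows a logit model.

    Per sample, disease (uniform over ``diseases``), age (uniform 20-70),
    gender and project are drawn; the target cluster C0's probability is
    logit(baseline) plus the declared ``freq_effects`` (log-odds scale,
    keys like ``disease[case]``, ``age``, ``gender[female]``,
    ``project[P1]``); cell counts are binomial draws with the remainder in
    cluster C1. Per-sample mean activities of ``component`` in C0 follow
    the linear model with ``feature_effects`` and Gaussian residuals.
    XIST means are generated consistent with the drawn sex.
    """
    if n_samples <= 0:
        raise DomainError("n_samples must be positive")
    if "healthy" not in diseases:
        raise DomainError("diseases must include the 'healthy' baseline")
    if not 0 < baseline_prob < 1:
        raise DomainError("baseline_prob must be in (0, 1)")
    freq_effects = dict(freq_effects or {})
    feature_effects = dict(feature_effects or {})
    known = {"age", "gender[female]"}
    known |= {f"disease[{d}]" for d in diseases if d != "healthy"}
    known |= {f"project[P{p}]" for p in range(n_projects)}
    for eff in (freq_effects, feature_effects):
        unknown = set(eff) - known
        if unknown:
            raise DomainError(f"effects reference undeclared terms: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    disease = rng.choice(list(diseases), size=n_samples)
    age = rng.uniform(20.0, 70.0, size=n_samples)
    gender = np.where(rng.random(n_samples) < 0.5, "female", "male")
    project = np.array([f"P{p}" for p in rng.integers(0, n_projects, size=n_samples)])

    base_logit = np.log(baseline_prob / (1 - baseline_prob))
    eta = np.array(
        [
            base_logit
            + _cohort_design_row(d, a, g, p, freq_effects)
            for d, a, g, p in zip(disease, age, gender, project)
        ]
    )
    prob = 1.0 / (1.0 + np.exp(-eta))
    if np.any(prob <= 0) or np.any(prob >= 1):
        raise DomainError(
            f"cluster probabilities left (0,1): min={prob.min()}, max={prob.max()}"
        )
    n_cat = rng.binomial(cells_per_sample, prob)

    mu = np.array(
        [
            feature_baseline + _cohort_design_row(d, a, g, p, feature_effects)
            for d, a, g, p in zip(disease, age, gender, project)
        ]
    )
    feat = mu + rng.normal(0.0, feature_residual_sd, size=n_samples)

    mean_xist = np.where(
        gender == "female",
        0.3 + rng.gamma(2.0, 0.1, size=n_samples),
        rng.uniform(0.0, 0.04, size=n_samples),
    )

    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    meta = pd.DataFrame(
        {
            "disease": disease,
            "age": age,
            "gender": gender,
            "project": project,
            "mean_xist": mean_xist,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    counts = pd.DataFrame(
        {"C0": n_cat, "C1": cells_per_sample - n_cat},
        index=meta.index,
    )
    features = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cluster": "C0",
            "component": component,
            "value": feat,
        }
    )
    truth = SimulationTruth(
        seed=seed,
        cohort_effects={
            "frequency": {"Intercept": base_logit, **freq_effects},
            "feature": {"Intercept": feature_baseline, **feature_effects},
        },
    )
    return CohortTable(meta, counts, features), truth
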