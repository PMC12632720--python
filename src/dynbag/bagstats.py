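"""Brain-age gaps (BAG) and their association with cognition.

The BAG is predicted brain age minus chronological age (years); positive
values mean an older-appearing brain. Each (modality, scope) BAG is
regressed on a cognitive outcome by ordinary least squares with the
fixed covariate set {age, sex, site, age^2, age x sex, diagnosis}, after
restricting to participants strictly older than ``min_age`` (default 38,
where FNC brain-age models are reliable). Reported per test: the BAG
coefficient beta with SE and normal-approximation 95% CI, the partial
correlation r between outcome and BAG given the covariates (computed
from the t statistic, sign-consistent with beta), raw p, and
Benjamini-Hochberg FDR-adjusted p within the test family. Families are
corrected per outcome: the two wide-brain modalities together, and the
7 networks x 2 modalities = 14 sub-network tests together.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .partition import NETWORK_ORDER

__all__ = [
    "SingularDesignError",
    "AssociationSpec",
    "AssociationResult",
    "compute_bag",
    "build_design",
    "fit_association",
    "bh_fdr",
    "run_suite",
    "MODALITIES",
]

MODALITIES = ("sfnc", "dfnc")
COVARIATE_TERMS = ("age", "sex", "site", "age2", "age_x_sex", "dx")


class SingularDesignError(ValueError):
    """Raised when the GLM design matrix is rank deficient."""


@dataclass(frozen=True)
class AssociationSpec:
    """Covariate scheme and age filter for the association suite."""

    min_age: float = 38.0          # strict: participants older than this
    covariates: tuple[str, ...] = COVARIATE_TERMS

    def __post_init__(self) -> None:
        if tuple(self.covariates) != COVARIATE_TERMS:
            raise ValueError(f"covariate set is fixed to {COVARIATE_TERMS}")


@dataclass
class AssociationResult:
    """One BAG-outcome test."""

    outcome: str
    modality: str
    scope: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    r: float
    p_raw: float
    n: int
    p_fdr: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome, "modality": self.modality, "scope": self.scope,
            "beta": self.beta, "se": self.se, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "r": self.r, "p_raw": self.p_raw,
            "p_fdr": self.p_fdr, "n": self.n,
        }


def compute_bag(
    predictions: Union[Mapping[str, float], pd.Series],
    phenotypes: pd.DataFrame,
    modality: str,
    scope: str,
) -> pd.DataFrame:
    """BAG records: one row per subject, bag = predicted - chronological."""
    pred = pd.Series(predictions, dtype=float)
    missing = set(phenotypes["id"]) - set(pred.index)
    if missing:
        raise ValueError(f"missing predictions for subjects: {sorted(missing)[:5]}")
    rows = phenotypes[["id", "age"]].copy()
    rows["predicted_age"] = rows["id"].map(pred)
    out = pd.DataFrame({
        "subject_id": rows["id"],
        "modality": modality,
        "scope": scope,
        "predicted_age": rows["predicted_age"],
        "chronological_age": rows["age"],
        "bag": rows["predicted_age"] - rows["age"],
    })
    return out.reset_index(drop=True)


def build_design(df: pd.DataFrame) -> pd.DataFrame:
    """Design matrix: intercept, bag, then the fixed covariates.

    Age is mean-centered before squaring (tames age/age^2 collinearity
    without changing the BAG coefficient); sex and diagnosis are 0/1
    indicators (M, SZ); site enters as treatment dummies against the
    lexicographically first site.
    """
    age_c = df["age"] - df["age"].mean()
    design = pd.DataFrame({"const": 1.0, "bag": df["bag"].to_numpy()},
                          index=df.index)
    design["age"] = age_c
    design["sex_M"] = (df["sex"] == "M").astype(float)
    sites = sorted(df["site"].unique())
    for s in sites[1:]:
        design[f"site_{s}"] = (df["site"] == s).astype(float)
    design["age2"] = age_c ** 2
    design["age_x_sex"] = age_c * design["sex_M"]
    design["dx_SZ"] = (df["dx"] == "SZ").astype(float)
    return design


def _check_rank(design: pd.DataFrame) -> None:
    x = design.to_numpy()
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        bad = [design.columns[i] for i in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {rank} < {x.shape[1]}); "
            f"collinear columns: {bad}"
        )


def fit_association(
    bags: pd.DataFrame,
    phenotypes: pd.DataFrame,
    spec: AssociationSpec,
    test: tuple[str, str],
    outcome: str,
) -> AssociationResult:
    """OLS fit of ``outcome`` on [intercept, BAG, covariates] for one
    (modality, scope) test, after the strict age filter."""
    modality, scope = test
    sub = bags[(bags["modality"] == modality) & (bags["scope"] == scope)]
    if sub.empty:
        raise ValueError(f"no BAG records for (modality={modality}, scope={scope})")
    df = sub.merge(phenotypes, left_on="subject_id", right_on="id", how="inner")
    df = df[df["age"] > spec.min_age]
    needed = ["bag", "age", "sex", "site", "dx", outcome]
    df = df.dropna(subset=needed).reset_index(drop=True)
    design = build_design(df)
    if len(df) <= design.shape[1] + 2:
        raise ValueError(
            f"only {len(df)} rows survive the age>{spec.min_age} filter; "
            f"need more than {design.shape[1] + 2}"
        )
    _check_rank(design)
    fit = sm.OLS(df[outcome].to_numpy(), design.to_numpy()).fit()
    k = list(design.columns).index("bag")
    beta = float(fit.params[k])
    se = float(fit.bse[k])
    t = float(fit.tvalues[k])
    dof = float(fit.df_resid)
    r = t / np.sqrt(t * t + dof)  # partial correlation of outcome and BAG
    return AssociationResult(
        outcome=outcome, modality=modality, scope=scope,
        beta=beta, se=se, ci_low=beta - 1.96 * se, ci_high=beta + 1.96 * se,
        r=float(r), p_raw=float(fit.pvalues[k]), n=int(len(df)),
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj[i] = min over j with p(j) >= p(i) of p(j) * m / rank(j), capped
    at 1; the original input order is restored.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("need a non-empty 1-D array of p-values")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def run_suite(
    bags: pd.DataFrame,
    phenotypes: pd.DataFrame,
    outcomes: Iterable[str] = ("attention", "working_memory"),
    spec: AssociationSpec = AssociationSpec(),
    networks: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Run the full association suite and correct within families.

    Per outcome: a wide-brain family of 2 tests (sFNC, dFNC) is
    FDR-corrected together, and a sub-network family of 7 networks x 2
    modalities = 14 tests is corrected together. Raw and adjusted
    p-values are both reported.
    """
    if bags is None or len(bags) == 0:
        raise ValueError("empty BAG table: nothing to test")
    available = set(zip(bags["modality"], bags["scope"]))
    if networks is None:
        present = {s for _, s in available if s != "wide"}
        networks = [n for n in NETWORK_ORDER if n in present]
    families = {
        "wide": [(m, "wide") for m in MODALITIES],
        "subnetwork": [(m, n) for n in networks for m in MODALITIES],
    }
    gaps = [t for tests in families.values() for t in tests if t not in available]
    if gaps:
        raise ValueError(f"missing BAG records for (modality, scope) tests: {gaps}")
    rows = []
    for outcome in outcomes:
        for family, tests in families.items():
            if not tests:
                continue
            results = [fit_association(bags, phenotypes, spec, t, outcome)
                       for t in tests]
            adj = bh_fdr([res.p_raw for res in results])
            for res, a in zip(results, adj):
                res.p_fdr = float(a)
                row = res.to_dict()
                row["family"] = family
                rows.append(row)
    out = pd.DataFrame(rows)
    cols = ["outcome", "family", "modality", "scope", "n", "beta", "se",
            "ci_low", "ci_high", "r", "p_raw", "p_fdr"]
    return out[cols]
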