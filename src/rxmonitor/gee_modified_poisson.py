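"""Modified-Poisson regression for correlates of baseline monitoring.

Binary outcomes (did the patient receive a baseline test?) are modeled with
Poisson estimating equations and a log link, so that exponentiated
coefficients are incidence proportion ratios (IPRs) rather than odds ratios.
Patients are clustered within medical institutions; an independence working
correlation is used, which keeps the point estimates equal to the pooled
Poisson score solution, and inference relies on the cluster-robust sandwich
covariance.  Adjusted incidence proportions come from marginal
standardization: fix a covariate at each level for every subject, average the
model-predicted probabilities over the cohort.

The fit itself is delegated to statsmodels' GEE machinery; this module owns
the design specification, the IPR/CI extraction, the crude (univariable)
closed forms, and the standardization step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import exp, log, sqrt

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["DesignSpec", "GeeFit", "fit_gee_poisson", "crude_ipr",
           "adjusted_proportions", "DEFAULT_REFERENCES"]

#: Reference level per factor (the reporting convention used in tables).
DEFAULT_REFERENCES = {
    "provider_type": "clinic",
    "setting": "inpatient",
    "prescriber": "nonpsychiatrist",
    "sex": "boy",
    "age_group": "16-18",
    "index_drug_category": "aripiprazole",
    "ap_type": "FGA",
    "cpz_dose_category": "0-99",
}


@dataclass
class DesignSpec:
    """Model design: binary outcome, categorical factors, cluster variable."""

    outcome: str
    factors: tuple[str, ...]
    cluster: str = "institution_id"
    references: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_REFERENCES))

    def __post_init__(self):
        if "index_drug_category" in self.factors and "ap_type" in self.factors:
            raise ValueError(
                "index_drug_category and ap_type are collinear by construction; "
                "include exactly one (main vs sensitivity analysis)")

    def formula(self) -> str:
        terms = []
        for f in self.factors:
            ref = self.references.get(f)
            if ref is not None:
                terms.append(f"C({f}, Treatment({ref!r}))")
            else:
                terms.append(f"C({f})")
        return f"{self.outcome} ~ " + " + ".join(terms)


@dataclass
class GeeFit:
    """Fitted modified-Poisson model with cluster-robust covariance."""

    spec: DesignSpec
    params: pd.Series
    cov_robust: pd.DataFrame
    converged: bool
    n_clusters: int
    n_obs: int
    result: object = field(repr=False, default=None)

    def robust_se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_robust)),
                         index=self.params.index)

    def ipr_table(self, level: float = 0.95) -> pd.DataFrame:
        """IPR = exp(coef) with Wald CI on the log scale from robust SEs."""
        z = stats.norm.ppf(0.5 + level / 2)
        se = self.robust_se()
        rows = []
        for name in self.params.index:
            if name == "Intercept":
                continue
            factor, lvl = _parse_term(name)
            b, s = self.params[name], se[name]
            rows.append({
                "factor": factor, "level": lvl,
                "ipr": exp(b), "ci_low": exp(b - z * s), "ci_high": exp(b + z * s),
            })
        return pd.DataFrame(rows)

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.result.predict(data))


def _parse_term(name: str) -> tuple[str, str]:
    # patsy term like "C(sex, Treatment('boy'))[T.girl]" -> ("sex", "girl")
    factor = name.split("(", 1)[1].split(",")[0].split(")")[0].strip()
    lvl = name.rsplit("[T.", 1)[1].rstrip("]") if "[T." in name else name
    return factor, lvl


def fit_gee_poisson(data: pd.DataFrame, spec: DesignSpec,
                    maxiter: int = 100, tol: float = 1e-8) -> GeeFit:
    """Fit the log-link Poisson GEE with independence working correlation.

    Raises
    ------
    ValueError
        If fewer than two clusters are present or the outcome is not binary.
    RuntimeError
        If the solver fails to converge within ``maxiter`` iterations.
    """
    y = data[spec.outcome]
    if not set(pd.unique(y)) <= {0, 1, True, False}:
        raise ValueError(f"outcome {spec.outcome!r} must be binary")
    clusters = data[spec.cluster]
    n_clusters = clusters.nunique()
    if n_clusters < 2:
        raise ValueError("at least two clusters are required for cluster-robust inference")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels warns on non-integer Poisson outcomes
        model = sm.GEE.from_formula(
            spec.formula(), groups=spec.cluster, data=data,
            family=sm.families.Poisson(),
            cov_struct=sm.cov_struct.Independence(),
        )
        result = model.fit(maxiter=maxiter, ctol=tol)
    converged = bool(getattr(result, "converged", True))
    if not converged:
        raise RuntimeError(
            f"GEE did not converge in {maxiter} iterations; last params: "
            f"{dict(result.params)}")
    return GeeFit(
        spec=spec,
        params=result.params,
        cov_robust=pd.DataFrame(result.cov_params(),
                                index=result.params.index,
                                columns=result.params.index),
        converged=converged,
        n_clusters=n_clusters,
        n_obs=len(data),
        result=result,
    )


def crude_ipr(x1: int, n1: int, x0: int, n0: int, level: float = 0.95) -> dict:
    """Crude incidence proportion ratio (x1/n1)/(x0/n0) with robust CI.

    The CI uses the log-ratio variance 1/x1 - 1/n1 + 1/x0 - 1/n0, which is
    exactly the cluster-robust sandwich variance of the saturated univariable
    modified-Poisson fit with each subject its own cluster.

    A zero numerator in the exposed group gives IPR 0 with a degenerate CI
    (flagged); a zero reference numerator is an error (undefined ratio).
    """
    if n1 < 1 or n0 < 1:
        raise ValueError("both group sizes must be >= 1")
    if x0 == 0:
        raise ValueError("reference group has zero events; IPR undefined")
    p1, p0 = x1 / n1, x0 / n0
    ipr = p1 / p0
    if x1 == 0:
        return {"ipr": 0.0, "ci_low": float("nan"), "ci_high": float("nan"),
                "degenerate": True}
    z = stats.norm.ppf(0.5 + level / 2)
    se = sqrt(1 / x1 - 1 / n1 + 1 / x0 - 1 / n0)
    return {"ipr": ipr, "ci_low": exp(log(ipr) - z * se),
            "ci_high": exp(log(ipr) + z * se), "degenerate": False}


def adjusted_proportions(fit: GeeFit, data: pd.DataFrame, factor: str) -> dict[str, float]:
    """Marginally standardized incidence proportions for each level of ``factor``.

    Every subject's ``factor`` is set to each observed level in turn, other
    covariates stay at their observed values, and the model-predicted
    probabilities are averaged over the full cohort.  A log-link Poisson model
    can predict above 1 for extreme covariate patterns; such predictions are
    averaged as-is but trigger a warning.
    """
    if factor not in fit.spec.factors:
        raise ValueError(f"factor {factor!r} is not in the fitted design")
    levels = sorted(pd.unique(data[factor]))
    out = {}
    for lvl in levels:
        counterfactual = data.copy()
        counterfactual[factor] = lvl
        pred = fit.predict(counterfactual)
        if (pred > 1).any():
            warnings.warn(
                f"{int((pred > 1).sum())} predicted probabilities exceed 1 "
                f"when standardizing {factor}={lvl!r} (log-link artifact)",
                RuntimeWarning)
        out[lvl] = float(pred.mean())
    return out
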