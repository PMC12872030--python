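"""Random-intercept model fitting and derived effect-size quantities.

The analysis model for a two-arm CRT is a two-level linear mixed model with
the treatment arm (and optional participant-level covariates) as fixed
effects and a random intercept per cluster:

    y_ij = beta0 + beta1 * arm_j + x_ij' gamma + u_j + e_ij.

``fit_random_intercept`` estimates beta1, its standard error and the two
variance components by restricted maximum likelihood. Balanced data without
covariates use an exact closed form (for balanced two-level designs with a
cluster-level treatment, REML coincides with the ANOVA moment estimator and
generalized least squares reduces to ordinary least squares on cluster
means); everything else goes through statsmodels' MixedLM, with a plain
maximum-likelihood retry on non-convergence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .design import TrialData
from .exceptions import (
    DegenerateDesignError,
    EstimationFailureError,
    InvalidIccError,
    UndefinedIccError,
)

__all__ = [
    "ParameterEstimate",
    "fit_random_intercept",
    "icc_from_components",
    "effective_sample_size",
    "hedges_effect_size",
]


def icc_from_components(var_cluster: float, var_residual: float) -> float:
    """Intraclass correlation rho = sigma2_u / (sigma2_u + sigma2_e)."""
    if var_cluster < 0 or var_residual < 0:
        raise InvalidIccError("variance components must be nonnegative")
    total = var_cluster + var_residual
    if total == 0:
        raise UndefinedIccError("ICC undefined when both variance components are zero")
    return var_cluster / total


def effective_sample_size(n1: float, n2: float, icc: float) -> float:
    """Information-equivalent independent sample size of clustered data.

    N_eff = n1 * n2 / (1 + (n1 - 1) * icc) with cluster size n1 and number
    of clusters n2; equals n1*n2 at icc = 0 and n2 for singleton clusters.
    """
    if not 0.0 <= icc < 1.0:
        raise InvalidIccError(f"icc must be in [0, 1), got {icc}")
    if n1 < 1 or n2 < 1:
        raise ValueError("n1 and n2 must be >= 1")
    return n1 * n2 / (1.0 + (n1 - 1.0) * icc)


def hedges_effect_size(estimate: float, var_cluster: float,
                       var_residual: float) -> float:
    """Standardized mean difference: estimate / sqrt(sigma2_u + sigma2_e)."""
    total = var_cluster + var_residual
    if total <= 0:
        raise UndefinedIccError("effect size undefined with zero total variance")
    return estimate / math.sqrt(total)


@dataclass(frozen=True)
class ParameterEstimate:
    """Treatment-effect estimate with variance components and design size.

    ``cluster_size`` is the mean cluster size for unbalanced data, which is
    what the effective-sample-size formula assumes.
    """

    estimate: float
    std_error: float
    var_cluster: float
    var_residual: float
    icc_hat: float
    n_clusters: int
    cluster_size: float
    n_total: int
    converged: bool = True
    method: str = "reml"

    @property
    def n_eff(self) -> float:
        return effective_sample_size(self.cluster_size, self.n_clusters,
                                     self.icc_hat)

    @property
    def hedges_g(self) -> float:
        return hedges_effect_size(self.estimate, self.var_cluster,
                                  self.var_residual)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_eff"] = self.n_eff
        return d


# ---------------------------------------------------------------------------
# fitting


def _check_design(data: TrialData) -> None:
    arms = pd.DataFrame({"c": data.cluster_id, "a": data.arm}).groupby("c")["a"].first()
    if (arms == 1).sum() < 2 or (arms == 0).sum() < 2:
        raise DegenerateDesignError("need at least 2 clusters in each arm")


def _fit_balanced_reml(data: TrialData) -> ParameterEstimate:
    # Exact REML for balanced data with a cluster-level treatment only.
    sizes = data.cluster_sizes()
    n1 = int(sizes.iloc[0])
    clusters, inv = np.unique(data.cluster_id, return_inverse=True)
    n2 = len(clusters)
    N = data.n_total
    y = data.outcome
    cm = np.bincount(inv, weights=y) / n1
    arm_c = np.bincount(inv, weights=data.arm).astype(int) // n1

    ssw = float(np.sum((y - cm[inv]) ** 2))
    if n1 > 1:
        var_e = ssw / (N - n2)
    else:
        var_e = 0.0
    m1 = int(arm_c.sum())
    m0 = n2 - m1
    mu1 = cm[arm_c == 1].mean()
    mu0 = cm[arm_c == 0].mean()
    est = float(mu1 - mu0)
    ssb = float(np.sum((cm[arm_c == 1] - mu1) ** 2)
                + np.sum((cm[arm_c == 0] - mu0) ** 2))
    var_means = ssb / (n2 - 2)  # variance of cluster means about arm means
    var_u = var_means - var_e / n1

    if var_u < 0 or (n1 == 1):
        # boundary: zero cluster variance, model collapses to OLS on y
        var_u = 0.0
        resid = y - np.where(data.arm == 1, mu1, mu0)
        s2 = float(np.sum(resid ** 2)) / (N - 2)
        var_e = s2
        se = math.sqrt(s2 * (1.0 / (m1 * n1) + 1.0 / (m0 * n1)))
    else:
        se = math.sqrt(var_means * (1.0 / m1 + 1.0 / m0))

    if not (se > 0 and math.isfinite(se)):
        raise EstimationFailureError("no finite standard error (constant outcomes?)")
    return ParameterEstimate(estimate=est, std_error=se, var_cluster=var_u,
                             var_residual=var_e,
                             icc_hat=icc_from_components(var_u, var_e),
                             n_clusters=n2, cluster_size=float(n1), n_total=N,
                             method="reml-closed")


def _fit_mixedlm(data: TrialData, covariates: list[str]) -> ParameterEstimate:
    import statsmodels.formula.api as smf

    df = data.to_frame()
    if data.covariates is not None:
        bad = [c for c in covariates if c not in data.covariates.columns]
    else:
        bad = list(covariates)
    if bad:
        raise KeyError(f"covariates not present in the data: {bad}")

    terms = ["arm"]
    for c in covariates:
        numeric = pd.api.types.is_numeric_dtype(df[c])
        terms.append(c if numeric else f"C({c})")
    formula = "outcome ~ " + " + ".join(terms)

    res = None
    used = "reml"
    # Powell first: the derivative-free search is far more robust near the
    # zero-variance boundary than the gradient-based optimizers.
    for reml in (True, False):
        for opt in ("powell", "lbfgs", "cg"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = smf.mixedlm(formula, df, groups=df["cluster"])
                    cand = model.fit(reml=reml, method=[opt])
                if cand.converged and np.isfinite(cand.bse["arm"]):
                    res = cand
                    used = "reml" if reml else "ml"
                    break
            except Exception:
                continue
        if res is not None:
            break
    if res is None:
        raise EstimationFailureError("mixed-model fit failed to converge")

    var_u = max(float(np.asarray(res.cov_re)[0, 0]), 0.0)
    var_e = float(res.scale)
    se = float(res.bse["arm"])
    if not (se > 0 and math.isfinite(se)):
        raise EstimationFailureError("no finite standard error (constant outcomes?)")
    sizes = data.cluster_sizes()
    return ParameterEstimate(estimate=float(res.params["arm"]), std_error=se,
                             var_cluster=var_u, var_residual=var_e,
                             icc_hat=icc_from_components(var_u, var_e),
                             n_clusters=data.n_clusters,
                             cluster_size=float(sizes.mean()),
                             n_total=data.n_total,
                             converged=bool(res.converged), method=used)


def fit_random_intercept(data: TrialData, covariates: list[str] | None = None,
                         method: str = "auto") -> ParameterEstimate:
    """Fit the two-level random-intercept model and extract beta1.

    Parameters
    ----------
    data : TrialData
    covariates : list of column names in ``data.covariates`` entering as
        additional fixed effects (non-numeric columns are treated as factors).
    method : "auto" (closed form when balanced and unadjusted, MixedLM
        otherwise), "closed" or "mixedlm".

    Negative cluster-variance estimates are clamped to zero, in which case
    the fit reduces to ordinary least squares; such singular fits are
    retained rather than discarded so simulation summaries stay unbiased.
    """
    covariates = list(covariates or [])
    _check_design(data)
    if float(np.var(data.outcome)) == 0.0:
        raise EstimationFailureError("constant outcome: variance components undefined")
    if method == "closed" or (method == "auto" and not covariates
                              and data.is_balanced()):
        if not data.is_balanced() or covariates:
            raise ValueError("closed-form fit requires balanced data without covariates")
        return _fit_balanced_reml(data)
    return _fit_mixedlm(data, covariates)
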