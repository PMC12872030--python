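"""Approximated adjusted fractional Bayes factors for one treatment effect.

The Bayes factor of a constrained hypothesis against the unconstrained
hypothesis H_u is the ratio of its *fit* to its *complexity*:

* the posterior of beta is approximated by N(estimate, SE^2);
* the default (fractional, adjusted) prior is normal, centered at the
  constraint boundary, with variance SE^2 / b, where the fraction
  b = J / N_eff uses the effective sample size of the clustered data and a
  robustness multiplier J in {1, 2, 3} (J = 1 is the minimal training
  sample);
* for an inequality hypothesis (beta > 0), fit and complexity are the
  posterior and prior mass of the constrained region (complexity is exactly
  1/2 for a boundary-centered prior, so BF_1u is bounded by 2);
* for the equality hypothesis (beta = 0) they are the posterior and prior
  *density* at the boundary — a Savage–Dickey density ratio, which gives
  the closed form BF_0u = sqrt(N_eff / J) * exp(-z^2 / 2) with z =
  estimate / SE.

Posterior model probabilities (PMPs) normalize the BF_iu over a hypothesis
set under equal prior model probabilities. The same quantities are produced
by the R packages bain and BFpack for this one-parameter case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import pandas as pd
from scipy import stats

from .estimation import ParameterEstimate, effective_sample_size
from .exceptions import ImproperPriorError, UndefinedPmpError

__all__ = [
    "HypothesisSpec",
    "H0", "H1", "H2", "HU", "HC",
    "FractionSpec",
    "Normal",
    "prior_and_posterior",
    "fit_and_complexity",
    "bf_vs_unconstrained",
    "bf_vs_complement",
    "bf_pair",
    "posterior_model_probabilities",
    "BayesFactorResult",
    "evaluate_hypotheses",
]


@dataclass(frozen=True)
class HypothesisSpec:
    """A constraint on the treatment effect beta.

    kinds: ``equality`` (beta = boundary), ``greater`` (beta > boundary),
    ``less_equal`` (beta <= boundary), ``unconstrained``, or ``complement``
    of another (non-complement) hypothesis.
    """

    kind: str
    boundary: float = 0.0
    complement_of: "HypothesisSpec | None" = field(default=None)
    name: str = ""

    _KINDS = ("equality", "greater", "less_equal", "unconstrained", "complement")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown hypothesis kind {self.kind!r}")
        if not math.isfinite(self.boundary):
            raise ValueError("boundary must be finite")
        if self.kind == "complement":
            if self.complement_of is None:
                raise ValueError("complement requires a reference hypothesis")
            if self.complement_of.kind == "complement":
                raise ValueError("complement of a complement is not allowed")
        elif self.complement_of is not None:
            raise ValueError("complement_of is only valid for kind='complement'")


H0 = HypothesisSpec("equality", name="H0")
H1 = HypothesisSpec("greater", name="H1")
H2 = HypothesisSpec("less_equal", name="H2")
HU = HypothesisSpec("unconstrained", name="Hu")
HC = HypothesisSpec("complement", complement_of=H1, name="Hc")


@dataclass(frozen=True)
class FractionSpec:
    """Fraction of information used to build the default prior: b = J/N_eff."""

    n_eff: float
    j_multiplier: int = 1

    def __post_init__(self):
        if self.j_multiplier not in (1, 2, 3):
            raise ValueError("j_multiplier must be 1, 2 or 3")
        if not self.n_eff > 0:
            raise ValueError("n_eff must be positive")

    @property
    def b(self) -> float:
        b = self.j_multiplier / self.n_eff
        if b <= 0:
            raise ImproperPriorError("fraction b must be positive")
        return min(b, 1.0)


class Normal(NamedTuple):
    mean: float
    sd: float


class PriorPosterior(NamedTuple):
    prior: Normal
    posterior: Normal


def prior_and_posterior(est: ParameterEstimate | None, frac: FractionSpec,
                        boundary: float = 0.0, estimate: float | None = None,
                        std_error: float | None = None) -> PriorPosterior:
    """Normal approximations: posterior N(estimate, SE), prior N(boundary,
    SE/sqrt(b)). Accepts either a ParameterEstimate or raw numbers."""
    if est is not None:
        estimate, std_error = est.estimate, est.std_error
    if std_error is None or not std_error > 0:
        raise ValueError("std_error must be positive")
    b = frac.b
    if b == 0:
        raise ImproperPriorError("fraction b = 0 yields an improper prior")
    return PriorPosterior(prior=Normal(boundary, std_error / math.sqrt(b)),
                          posterior=Normal(float(estimate), std_error))


def fit_and_complexity(h: HypothesisSpec, prior: Normal,
                       posterior: Normal) -> tuple[float, float]:
    """Posterior (fit) and prior (complexity) agreement with a hypothesis.

    Mass of the constrained region for inequality hypotheses, density at the
    boundary for the equality hypothesis, 1 for the unconstrained.
    """
    if h.kind == "unconstrained":
        return 1.0, 1.0
    if h.kind == "complement":
        ref = h.complement_of
        if ref.kind == "equality":
            # the complement of a point null is the whole line
            return 1.0, 1.0
        f, c = fit_and_complexity(ref, prior, posterior)
        return 1.0 - f, 1.0 - c
    if h.kind == "equality":
        return (stats.norm.pdf(h.boundary, posterior.mean, posterior.sd),
                stats.norm.pdf(h.boundary, prior.mean, prior.sd))
    if h.kind == "greater":
        return (stats.norm.sf(h.boundary, posterior.mean, posterior.sd),
                stats.norm.sf(h.boundary, prior.mean, prior.sd))
    # less_equal
    return (stats.norm.cdf(h.boundary, posterior.mean, posterior.sd),
            stats.norm.cdf(h.boundary, prior.mean, prior.sd))


def bf_vs_unconstrained(fit: float, complexity: float) -> float:
    """BF_iu = fit / complexity."""
    if complexity <= 0:
        raise ZeroDivisionError("complexity must be positive for BF_iu")
    return fit / complexity


def bf_vs_complement(fit: float, complexity: float,
                     equality: bool = False) -> float:
    """BF of a hypothesis against its own complement.

    For the equality hypothesis the complement equals the unconstrained, so
    BF_0c = BF_0u. For an inequality hypothesis,
    BF_ic = [fit/(1-fit)] * [(1-complexity)/complexity]; a fit of exactly 1
    gives +inf (finite printed values arise only from rounding the fit).
    """
    if equality:
        return bf_vs_unconstrained(fit, complexity)
    if not 0 < complexity < 1:
        raise ValueError("inequality complexity must be in (0, 1)")
    if fit >= 1.0:
        return math.inf
    return (fit / (1.0 - fit)) * ((1.0 - complexity) / complexity)


def bf_pair(bf_iu: float, bf_ju: float) -> float:
    """BF_ij = BF_iu / BF_ju (both against the unconstrained)."""
    if bf_ju == 0:
        return math.inf if bf_iu > 0 else math.nan
    return bf_iu / bf_ju


def posterior_model_probabilities(bf_u_values: dict[str, float]) -> dict[str, float]:
    """PMP_i = BF_iu / sum_j BF_ju under equal prior model probabilities."""
    if any(v < 0 for v in bf_u_values.values()):
        raise ValueError("Bayes factors must be nonnegative")
    total = sum(bf_u_values.values())
    if total == 0:
        raise UndefinedPmpError("all Bayes factors are zero; PMPs undefined")
    return {k: v / total for k, v in bf_u_values.items()}


# ---------------------------------------------------------------------------
# the standard four-hypothesis evaluation (H0, H1, Hu, Hc)


@dataclass
class BayesFactorResult:
    """Per-hypothesis fit, complexity, BF_u, BF_c and the three PMP sets.

    PMP_a compares {H0, H1}; PMP_b adds the unconstrained Hu (BF_uu = 1);
    PMP_c compares {H0, H1, Hc}. Each PMP column sums to one. All values are
    unrounded; rounding belongs to the presentation layer.
    """

    table: pd.DataFrame
    n_eff: float
    b: float
    estimate: float
    std_error: float

    def to_frame(self, decimals: int | None = None) -> pd.DataFrame:
        if decimals is None:
            return self.table.copy()
        return self.table.round(decimals)

    def __getitem__(self, hyp: str) -> pd.Series:
        return self.table.loc[hyp]


def evaluate_hypotheses(estimate: float, std_error: float, n1: float,
                        n2: int, icc: float, j_multiplier: int = 1,
                        boundary: float = 0.0) -> BayesFactorResult:
    """Evaluate H0: beta = 0, H1: beta > 0, Hu and Hc: beta < 0.

    Produces the full report table (fit, complexity, BF_u, BF_c, PMP_a,
    PMP_b, PMP_c). ``n1``, ``n2`` and ``icc`` determine the effective sample
    size entering the fraction b = J/N_eff.
    """
    n_eff = effective_sample_size(n1, n2, icc)
    frac = FractionSpec(n_eff=n_eff, j_multiplier=j_multiplier)
    prior, posterior = prior_and_posterior(None, frac, boundary=boundary,
                                           estimate=estimate,
                                           std_error=std_error)
    hyps = {
        "H0": HypothesisSpec("equality", boundary, name="H0"),
        "H1": HypothesisSpec("greater", boundary, name="H1"),
        "Hu": HU,
        "Hc": HypothesisSpec("complement", boundary, name="Hc",
                             complement_of=HypothesisSpec("greater", boundary)),
    }
    rows = {}
    bfu = {}
    for name, h in hyps.items():
        f, c = fit_and_complexity(h, prior, posterior)
        bf_u = bf_vs_unconstrained(f, c)
        if h.kind == "unconstrained":
            bf_c = math.nan  # no complement exists for Hu
        else:
            bf_c = bf_vs_complement(f, c, equality=(h.kind == "equality"))
        rows[name] = {"fit": f, "complexity": c, "bf_u": bf_u, "bf_c": bf_c}
        bfu[name] = bf_u

    pmp_a = posterior_model_probabilities({k: bfu[k] for k in ("H0", "H1")})
    pmp_b = posterior_model_probabilities({k: bfu[k] for k in ("H0", "H1", "Hu")})
    pmp_c = posterior_model_probabilities({k: bfu[k] for k in ("H0", "H1", "Hc")})
    for name in rows:
        rows[name]["pmp_a"] = pmp_a.get(name, math.nan)
        rows[name]["pmp_b"] = pmp_b.get(name, math.nan)
        rows[name]["pmp_c"] = pmp_c.get(name, math.nan)

    table = pd.DataFrame.from_dict(rows, orient="index")
    table = table.loc[["H0", "H1", "Hu", "Hc"]]
    return BayesFactorResult(table=table, n_eff=n_eff, b=frac.b,
                             estimate=estimate, std_error=std_error)


def bf01_bf10(estimate: float, std_error: float, n1: float, n2: int,
              icc: float, j_multiplier: int = 1) -> tuple[float, float]:
    """BF_01 and BF_10 for hypothesis set 1 (H0: beta = 0 vs H1: beta > 0)."""
    res = evaluate_hypotheses(estimate, std_error, n1, n2, icc, j_multiplier)
    b0, b1 = res["H0"]["bf_u"], res["H1"]["bf_u"]
    return bf_pair(b0, b1), bf_pair(b1, b0)


def bf12(estimate: float, std_error: float, n1: float, n2: int, icc: float,
         j_multiplier: int = 1) -> float:
    """BF_12 for hypothesis set 2 (H1: beta > 0 vs its complement
    H2: beta <= 0); equals BF_1c."""
    res = evaluate_hypotheses(estimate, std_error, n1, n2, icc, j_multiplier)
    return float(res["H1"]["bf_c"])
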