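"""Monte-Carlo Bayesian power and a priori sample size determination.

Bayesian power is the probability eta that the Bayes factor for the true
hypothesis exceeds a user-chosen threshold BF_thres under repeated sampling
from the design. Two hypothesis sets are supported:

* set 1 — H0: beta = 0 versus H1: beta > 0. The sample size criterion
  requires BOTH P(BF_01 >= BF_thres | H0) >= eta and
  P(BF_10 >= BF_thres | H1) >= eta, so trials are simulated under each
  hypothesis in turn.
* set 2 — H1: beta > 0 versus H2: beta <= 0. The hypotheses are
  complementary, so the criterion is required for H1 only and trials are
  simulated under H1 alone (BF_12 = BF_1c).

Each replicate simulates a balanced trial, fits the random-intercept model
and computes the fractional Bayes factors with b = J/N_eff, where N_eff
uses the replicate's *estimated* ICC by default (mirroring the analysis of
real data; set ``icc_for_neff="design"`` for a sensitivity analysis).

``find_sample_size`` searches the free design dimension (cluster size at a
fixed number of clusters, or total clusters at a fixed cluster size) by
bracket doubling followed by bisection, evaluating every candidate with
common random numbers. Search minima are 6 participants per cluster and 8
clusters in total.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import (
    FractionSpec,
    HypothesisSpec,
    bf_pair,
    bf_vs_complement,
    bf_vs_unconstrained,
    fit_and_complexity,
    prior_and_posterior,
)
from .design import DesignSpec, simulate_crt, substream
from .estimation import effective_sample_size, fit_random_intercept
from .exceptions import (
    EstimationFailureError,
    InvalidAlternativeError,
    SampleSizeNotFoundError,
    SimulationUnstableError,
)

__all__ = [
    "PowerCriterion",
    "PowerResult",
    "SsdResult",
    "estimate_power",
    "find_sample_size",
    "run_grid",
    "MIN_CLUSTER_SIZE",
    "MIN_TOTAL_CLUSTERS",
]

logger = logging.getLogger("crtbayes")

MIN_CLUSTER_SIZE = 6
MIN_TOTAL_CLUSTERS = 8
_FAILURE_CAP = 0.05  # refitted replicates allowed, as a share of reps


@dataclass(frozen=True)
class PowerCriterion:
    """Bayesian power criterion: P(BF >= bf_thres | true hypothesis) >= eta."""

    bf_thres: float = 3.0
    eta: float = 0.8
    hypothesis_set: str = "set1"

    def __post_init__(self):
        if self.bf_thres < 1:
            raise ValueError("bf_thres must be >= 1")
        if not 0.0 < self.eta < 1.0:
            raise ValueError("eta must be in (0, 1)")
        if self.hypothesis_set not in ("set1", "set2"):
            raise ValueError("hypothesis_set must be 'set1' or 'set2'")


@dataclass
class PowerResult:
    """Monte-Carlo exceedance probabilities for one design.

    For set 1, ``p_exceed_under_i`` is P(BF_01 >= thres | H0) and
    ``p_exceed_under_i_prime`` is P(BF_10 >= thres | H1). For set 2 only
    ``p_exceed_under_i`` (under H1) is filled.
    """

    p_exceed_under_i: float
    p_exceed_under_i_prime: float | None
    replications: int
    seed: int | None
    criterion: PowerCriterion
    n_refits: int = 0
    bf_samples: dict = field(default_factory=dict, repr=False)

    @property
    def mc_std_error(self) -> float:
        p = self.p_exceed_under_i
        return math.sqrt(p * (1.0 - p) / self.replications)

    @property
    def mc_std_error_i_prime(self) -> float | None:
        if self.p_exceed_under_i_prime is None:
            return None
        p = self.p_exceed_under_i_prime
        return math.sqrt(p * (1.0 - p) / self.replications)

    def meets(self, crit: PowerCriterion | None = None) -> bool:
        crit = crit or self.criterion
        if self.criterion.hypothesis_set == "set1":
            return (self.p_exceed_under_i >= crit.eta
                    and self.p_exceed_under_i_prime >= crit.eta)
        return self.p_exceed_under_i >= crit.eta

    def to_dict(self) -> dict:
        return {
            "p_exceed_under_i": self.p_exceed_under_i,
            "p_exceed_under_i_prime": self.p_exceed_under_i_prime,
            "replications": self.replications,
            "mc_std_error": self.mc_std_error,
            "mc_std_error_i_prime": self.mc_std_error_i_prime,
            "seed": self.seed,
            "bf_thres": self.criterion.bf_thres,
            "eta": self.criterion.eta,
            "hypothesis_set": self.criterion.hypothesis_set,
            "n_refits": self.n_refits,
        }


def _replicate_bfs(design: DesignSpec, seed, stream_key: tuple,
                   j_multiplier: int, icc_for_neff: str) -> tuple[float, float, float]:
    """Simulate one trial, fit it, return (BF_01, BF_10, BF_12)."""
    data = simulate_crt(design, substream(seed, *stream_key))
    est = fit_random_intercept(data, method="closed")
    icc = est.icc_hat if icc_for_neff == "estimated" else design.icc
    n_eff = effective_sample_size(design.cluster_size, design.n_clusters_total, icc)
    frac = FractionSpec(n_eff=n_eff, j_multiplier=j_multiplier)
    prior, posterior = prior_and_posterior(est, frac)
    f0, c0 = fit_and_complexity(HypothesisSpec("equality"), prior, posterior)
    f1, c1 = fit_and_complexity(HypothesisSpec("greater"), prior, posterior)
    bf0u = bf_vs_unconstrained(f0, c0)
    bf1u = bf_vs_unconstrained(f1, c1)
    return (bf_pair(bf0u, bf1u), bf_pair(bf1u, bf0u),
            bf_vs_complement(f1, c1))


def _exceedance(design: DesignSpec, which_bf: int, crit: PowerCriterion,
                j_multiplier: int, reps: int, seed, hyp_tag: int,
                icc_for_neff: str, batch: int | None,
                collect: list | None) -> tuple[int, int]:
    """Count replicates whose BF exceeds the threshold. ``which_bf`` selects
    BF_01 (0), BF_10 (1) or BF_12 (2)."""
    count = 0
    refits = 0
    max_refits = max(1, int(_FAILURE_CAP * reps))
    batch = batch or reps
    for start in range(0, reps, batch):
        stop = min(start + batch, reps)
        for r in range(start, stop):
            attempt = 0
            while True:
                try:
                    bfs = _replicate_bfs(design, seed, (hyp_tag, r, attempt),
                                         j_multiplier, icc_for_neff)
                    break
                except EstimationFailureError as err:
                    refits += 1
                    attempt += 1
                    if refits > max_refits:
                        raise SimulationUnstableError(
                            f"more than {max_refits} replicates failed to fit "
                            f"(last: {err})") from err
            bf = bfs[which_bf]
            if collect is not None:
                collect.append(bf)
            if bf >= crit.bf_thres:
                count += 1
        logger.info("batch %d-%d done (hyp %d): running exceedance %.3f",
                    start, stop, hyp_tag, count / stop)
    return count, refits


def estimate_power(design: DesignSpec, crit: PowerCriterion,
                   j_multiplier: int = 1, reps: int = 1000,
                   seed: int | None = None, batch: int | None = None,
                   icc_for_neff: str = "estimated",
                   collect_bf: bool = False) -> PowerResult:
    """Monte-Carlo estimate of the Bayesian power of a design.

    Set 1 simulates ``reps`` trials under H0 (effect 0) scoring
    BF_01 >= bf_thres, and ``reps`` trials under H1 (the design's effect
    size) scoring BF_10 >= bf_thres. Set 2 simulates under H1 only, scoring
    BF_12. Replicates whose fit fails are re-simulated from a fresh
    substream (at most 5% of ``reps``). Identical (design, seed, reps) give
    identical results regardless of ``batch``.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100 for a usable exceedance estimate")
    if icc_for_neff not in ("estimated", "design"):
        raise ValueError("icc_for_neff must be 'estimated' or 'design'")
    if design.effect_size <= 0:
        raise InvalidAlternativeError(
            "the alternative-true simulation needs effect_size > 0")

    samples: dict[str, list] = {}
    refits = 0
    if crit.hypothesis_set == "set1":
        null_design = design.with_effect(0.0)
        col0 = [] if collect_bf else None
        col1 = [] if collect_bf else None
        c01, r0 = _exceedance(null_design, 0, crit, j_multiplier, reps, seed,
                              0, icc_for_neff, batch, col0)
        c10, r1 = _exceedance(design, 1, crit, j_multiplier, reps, seed,
                              1, icc_for_neff, batch, col1)
        refits = r0 + r1
        if collect_bf:
            samples = {"bf01_under_h0": col0, "bf10_under_h1": col1}
        result = PowerResult(c01 / reps, c10 / reps, reps, seed, crit,
                             refits, samples)
    else:
        col = [] if collect_bf else None
        c12, refits = _exceedance(design, 2, crit, j_multiplier, reps, seed,
                                  1, icc_for_neff, batch, col)
        if collect_bf:
            samples = {"bf12_under_h1": col}
        result = PowerResult(c12 / reps, None, reps, seed, crit, refits, samples)

    logger.info("power at %d clusters x %d: %s (MC se %.4f, %d refits)",
                design.n_clusters_total, design.cluster_size,
                result.p_exceed_under_i, result.mc_std_error, refits)
    return result


@dataclass
class SsdResult:
    """Smallest design dimension meeting the Bayesian power criterion."""

    fixed_dimension: str
    fixed_value: int
    free_dimension: str
    found_value: int
    power_at_solution: PowerResult
    search_trace: list[tuple[int, PowerResult]]

    def to_dict(self) -> dict:
        return {
            "fixed_dimension": self.fixed_dimension,
            "fixed_value": self.fixed_value,
            "free_dimension": self.free_dimension,
            "found_value": self.found_value,
            "power_at_solution": self.power_at_solution.to_dict(),
            "search_trace": [(c, p.to_dict()) for c, p in self.search_trace],
        }


def _design_for(fixed: str, fixed_value: int, candidate: int,
                effect_size: float, icc: float) -> DesignSpec:
    if fixed == "cluster_size":
        return DesignSpec.from_total_clusters(candidate, fixed_value,
                                              effect_size, icc)
    return DesignSpec.from_total_clusters(fixed_value, candidate,
                                          effect_size, icc)


def find_sample_size(fixed: str, fixed_value: int, effect_size: float,
                     icc: float, crit: PowerCriterion,
                     j_multiplier: int = 1, reps: int = 1000,
                     seed: int | None = None, cap: int = 1000,
                     icc_for_neff: str = "estimated",
                     batch: int | None = None) -> SsdResult:
    """Smallest cluster size or total cluster count meeting the criterion.

    ``fixed`` names the dimension held constant ("cluster_size" or
    "n_clusters"); the other dimension is searched over integers starting
    at the documented minimum (6 per cluster, 8 total clusters), doubling
    an upper bracket until the criterion holds and then bisecting. All
    candidates reuse the same random-number streams (common random numbers),
    and a candidate passes when its exceedance point estimate(s) reach eta.
    """
    if fixed not in ("cluster_size", "n_clusters"):
        raise ValueError("fixed must be 'cluster_size' or 'n_clusters'")
    free = "n_clusters" if fixed == "cluster_size" else "cluster_size"
    lo_bound = MIN_TOTAL_CLUSTERS if free == "n_clusters" else MIN_CLUSTER_SIZE

    trace: list[tuple[int, PowerResult]] = []

    def power_at(candidate: int) -> PowerResult:
        design = _design_for(fixed, fixed_value, candidate, effect_size, icc)
        res = estimate_power(design, crit, j_multiplier, reps, seed, batch,
                             icc_for_neff)
        trace.append((candidate, res))
        logger.info("SSD candidate %s=%d: p_i=%.3f p_i'=%s", free, candidate,
                    res.p_exceed_under_i, res.p_exceed_under_i_prime)
        return res

    res = power_at(lo_bound)
    if res.meets():
        return SsdResult(fixed, fixed_value, free, lo_bound, res, trace)

    lo, hi = lo_bound, lo_bound
    hi_res = None
    while True:
        hi = min(2 * hi, cap)
        hi_res = power_at(hi)
        if hi_res.meets():
            break
        lo = hi
        if hi >= cap:
            raise SampleSizeNotFoundError(
                f"criterion not met below {free} = {cap}", trace=trace)

    # bisect (lo fails, hi passes)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        mid_res = power_at(mid)
        if mid_res.meets():
            hi, hi_res = mid, mid_res
        else:
            lo = mid
    return SsdResult(fixed, fixed_value, free, hi, hi_res, trace)


def run_grid(effect_sizes, iccs, thresholds, etas, hypothesis_sets,
             fixed: str, fixed_value: int, j_multiplier: int = 1,
             reps: int = 1000, seed: int | None = None,
             cap: int = 1000) -> pd.DataFrame:
    """Required sample size over a factor grid, as a tidy table.

    One row per (effect_size, icc, bf_thres, eta, hypothesis_set) cell with
    the found value of the free dimension (NaN when the criterion is not
    reachable below ``cap``).
    """
    rows = []
    for hset in hypothesis_sets:
        for d in effect_sizes:
            for icc in iccs:
                for thres in thresholds:
                    for eta in etas:
                        crit = PowerCriterion(thres, eta, hset)
                        try:
                            ssd = find_sample_size(fixed, fixed_value, d, icc,
                                                   crit, j_multiplier, reps,
                                                   seed, cap)
                            found = ssd.found_value
                            p_i = ssd.power_at_solution.p_exceed_under_i
                            p_ip = ssd.power_at_solution.p_exceed_under_i_prime
                        except SampleSizeNotFoundError:
                            found, p_i, p_ip = math.nan, math.nan, math.nan
                        rows.append({"hypothesis_set": hset, "effect_size": d,
                                     "icc": icc, "bf_thres": thres, "eta": eta,
                                     "fixed_dimension": fixed,
                                     "fixed_value": fixed_value,
                                     "found_value": found,
                                     "p_exceed_under_i": p_i,
                                     "p_exceed_under_i_prime": p_ip})
    return pd.DataFrame(rows)
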