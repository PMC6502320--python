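"""Closed-form dual-list population-size estimators.

For two lists of sizes n1 and n2 sharing m individuals, drawn independently
from a closed population of unknown size N:

* Lincoln-Petersen:  N_hat = n1*n2/m,
  Var = n1*n2*(n1-m)*(n2-m)/m^3.
* Chapman (nearly unbiased for small m):
  N_hat = (n1+1)(n2+1)/(m+1) - 1,
  Var = (n1+1)(n2+1)(n1-m)(n2-m) / ((m+1)^2 (m+2)).

Intervals are Wald: N_hat +/- 1.96*SE.  Point estimates, interval bounds and
the 1.96*SE half-width are reported rounded half-up to integers, matching the
convention of published surveillance tables.  The stratified estimator sums
per-stratum estimates and variances (independence across strata).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from ._util import round_half_up
from .registry import ContingencyTable

logger = logging.getLogger(__name__)

Z_95 = 1.96


class EstimatorError(ValueError):
    """Estimator undefined for the given table."""


@dataclass(frozen=True)
class EstimateResult:
    """A population-size estimate with its Wald 95% interval.

    ``n_hat``, ``ci_low``, ``ci_high`` and ``half_width`` are rounded
    half-up to integers; ``se`` and ``n_hat_exact`` keep full precision for
    downstream arithmetic (completeness, prevalence).
    """

    n_hat: int
    se: float
    half_width: int
    ci_low: int
    ci_high: int
    method: str
    n_hat_exact: float
    details: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n_hat": self.n_hat,
            "se": self.se,
            "half_width": self.half_width,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "inputs": self.details,
        }


def _package(n_hat: float, variance: float, method: str, details: dict) -> EstimateResult:
    se = math.sqrt(variance)
    hw = Z_95 * se
    return EstimateResult(
        n_hat=int(round_half_up(n_hat)),
        se=se,
        half_width=int(round_half_up(hw)),
        ci_low=int(round_half_up(n_hat - hw)),
        ci_high=int(round_half_up(n_hat + hw)),
        method=method,
        n_hat_exact=n_hat,
        details=details,
    )


def lincoln_petersen(t: ContingencyTable) -> EstimateResult:
    """Lincoln-Petersen estimate from one contingency table.

    Requires at least one matched case (m >= 1); with no overlap the
    estimator diverges — use :func:`chapman` instead.
    """
    if t.m < 1:
        raise EstimatorError(
            "Lincoln-Petersen is undefined when the lists share no case (m = 0); "
            "use the Chapman estimator, which remains finite."
        )
    n1, n2, m = t.n1, t.n2, t.m
    n_hat = n1 * n2 / m
    variance = n1 * n2 * (n1 - m) * (n2 - m) / m**3
    return _package(n_hat, variance, "lincoln_petersen", t.to_dict())


def chapman(t: ContingencyTable) -> EstimateResult:
    """Chapman's nearly unbiased estimate; finite even when m = 0."""
    n1, n2, m = t.n1, t.n2, t.m
    n_hat = (n1 + 1) * (n2 + 1) / (m + 1) - 1
    variance = (n1 + 1) * (n2 + 1) * (n1 - m) * (n2 - m) / ((m + 1) ** 2 * (m + 2))
    return _package(n_hat, variance, "chapman", t.to_dict())


def stratified_estimate(
    tables: list[ContingencyTable], base: str = "lincoln_petersen"
) -> EstimateResult:
    """Sum of per-stratum estimates; variance summed across strata.

    Stratification absorbs between-stratum catchability heterogeneity that
    would bias the pooled estimate.  A stratum with m = 0 falls back to
    Chapman under the Lincoln-Petersen base (logged); strata with no
    observed case contribute nothing.
    """
    if base not in ("lincoln_petersen", "chapman"):
        raise EstimatorError(f"unknown base estimator {base!r}")
    if not tables:
        raise EstimatorError("stratified_estimate requires at least one stratum table")
    total = variance = 0.0
    per_stratum = []
    for t in tables:
        if t.union == 0:
            continue
        if base == "lincoln_petersen" and t.m == 0:
            logger.info("stratum %r has m=0: falling back to Chapman", t.label)
            est = chapman(t)
        else:
            est = lincoln_petersen(t) if base == "lincoln_petersen" else chapman(t)
        total += est.n_hat_exact
        variance += est.se**2
        per_stratum.append({"label": t.label, "n_hat": est.n_hat, "method": est.method})
    result = _package(total, variance, f"stratified_{'lp' if base == 'lincoln_petersen' else 'chapman'}",
                      {"strata": per_stratum})
    return result
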