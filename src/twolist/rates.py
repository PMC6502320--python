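"""Surveillance completeness and prevalence from population-size estimates.

Completeness of a source is the share of the estimated true case population
that the source captured; prevalence divides the estimated case count by a
census denominator.  Both are percentages rounded half-up to one decimal,
the precision at which such figures are conventionally reported.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._util import percent


class RatesError(ValueError):
    """Inconsistent inputs for a completeness or prevalence computation."""


@dataclass(frozen=True)
class PrevalenceReport:
    """One prevalence figure with the completeness of each source against
    the same estimate."""

    n_hat: float
    population: int
    prevalence_pct: float
    scope: str  # "all_ages" or "age_65_plus"
    completeness_pct: dict

    def to_dict(self) -> dict:
        return {
            "n_hat": self.n_hat,
            "population": self.population,
            "prevalence_pct": self.prevalence_pct,
            "scope": self.scope,
            "completeness_pct": dict(self.completeness_pct),
        }


def completeness(source_total: int, n_hat: float) -> float:
    """Percentage of the estimated case population captured by one source."""
    if source_total <= 0:
        raise RatesError("source_total must be positive")
    if n_hat < source_total:
        raise RatesError(
            f"estimate {n_hat} is below the observed list size {source_total}; "
            "an estimated population cannot be smaller than a list drawn from it"
        )
    return percent(source_total, n_hat)


def prevalence(n_hat: float, population: int) -> float:
    """Estimated cases per 100 population, to one decimal."""
    if population <= 0:
        raise RatesError("population denominator must be positive")
    if n_hat > population:
        raise RatesError(f"estimate {n_hat} exceeds the population denominator {population}")
    if n_hat < 0:
        raise RatesError("estimate must be non-negative")
    return percent(n_hat, population)


def age_restricted_estimate(
    stratum_estimates: dict, cutoff: int, scheme=None
) -> float:
    """Sum per-stratum estimates over strata lying entirely at or above an age cutoff.

    ``stratum_estimates`` maps stratum label -> estimate, with labels of the
    form produced by :class:`~twolist.registry.StratumScheme` (optionally
    gender-prefixed, e.g. ``"F:85-89"``).  A stratum whose age interval
    straddles the cutoff cannot be split after the fact: the call fails and
    asks for a stratification with a class boundary at the cutoff.
    """
    total = 0.0
    any_at_or_above = False
    for label, est in stratum_estimates.items():
        lo, hi = _parse_age_interval(label)
        if lo >= cutoff:
            total += est
            any_at_or_above = True
        elif hi is not None and hi < cutoff:
            continue  # entirely below the cutoff
        elif hi is None or hi >= cutoff:
            raise RatesError(
                f"stratum {label!r} spans ages {lo}-{hi if hi is not None else 'inf'} "
                f"and straddles the cutoff {cutoff}; restratify with a class "
                f"boundary at {cutoff}"
            )
    return total if any_at_or_above else 0.0


def _parse_age_interval(label: str) -> tuple[int, int | None]:
    """Age bounds [lo, hi] (inclusive; hi None when open) from a stratum label."""
    age_part = label.split(":", 1)[-1]
    try:
        if age_part.startswith("<="):
            return 0, int(age_part[2:])
        if age_part.startswith(">="):
            return int(age_part[2:]), None
        lo, hi = age_part.split("-")
        return int(lo), int(hi)
    except ValueError as exc:
        raise RatesError(f"cannot parse age interval from stratum label {label!r}") from exc


def build_report(
    n_hat: float,
    population: int,
    source_totals: dict,
    scope: str = "all_ages",
) -> PrevalenceReport:
    """Bundle prevalence with the per-source completeness against one estimate."""
    return PrevalenceReport(
        n_hat=n_hat,
        population=population,
        prevalence_pct=prevalence(n_hat, population),
        scope=scope,
        completeness_pct={src: completeness(tot, n_hat)
                          for src, tot in source_totals.items()},
    )
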