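"""Bayesian closed-population M_t model via data augmentation.

Capture probability varies by source (the two "occasions") and by
demographic stratum, but not between individuals within a stratum.  Each
stratum s is augmented to a super-population of M_s potential individuals
with latent inclusion indicators:

    z_i   ~ Bernoulli(psi_s)                    i = 1..M_s
    y_iA  ~ Bernoulli(z_i * p_sA),  y_iB ~ Bernoulli(z_i * p_sB)
    N_s   = sum_i z_i,   N_total = sum_s N_s

with flat priors p_sA, p_sB ~ Beta(1,1) and psi_s ~ Uniform(0,1).  Mixing a
Binomial(M_s, psi_s) over a uniform psi_s makes the induced prior on N_s
uniform on {0..M_s}, so the posterior mode sits at the maximum-likelihood
solution — for a single stratum, the Lincoln-Petersen estimate.

The sampler is a conjugate Gibbs scheme.  Observed individuals have z_i = 1
deterministically; the never-captured augmented individuals are exchangeable,
so their z-sum is updated in one Binomial draw with success probability
psi*q / (psi*q + 1 - psi), q = (1-pA)(1-pB), rather than M_s individual
Bernoulli updates — the same full conditional, collapsed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._util import spawn_rngs
from .registry import ContingencyTable

logger = logging.getLogger(__name__)

#: Default augmentation factor: M_s = 10 x observed union per stratum.
DEFAULT_AUGMENTATION_FACTOR = 10

#: Convergence threshold on the potential scale reduction factor.
RHAT_THRESHOLD = 1.1


class McmcError(RuntimeError):
    """Sampler misconfiguration, augmentation exhaustion, or (strict) non-convergence."""


@dataclass(frozen=True)
class MtModelSpec:
    """Model layout: stratum labels and augmentation sizes.

    ``M`` maps stratum label -> super-population size; every M_s must
    strictly exceed that stratum's observed union (default 10x).
    """

    strata: tuple[str, ...]
    M: dict = field(default_factory=dict)

    @classmethod
    def from_tables(
        cls, tables: list[ContingencyTable],
        augmentation_factor: float = DEFAULT_AUGMENTATION_FACTOR,
    ) -> "MtModelSpec":
        labels, M = [], {}
        for t in tables:
            if t.union == 0:
                logger.info("stratum %r has no observed case: dropped from the model", t.label)
                continue
            labels.append(t.label)
            M[t.label] = int(math.ceil(augmentation_factor * t.union))
        if not labels:
            raise McmcError("no stratum has any observed case")
        return cls(strata=tuple(labels), M=M)

    def validate(self, tables: list[ContingencyTable]) -> None:
        by_label = {t.label: t for t in tables}
        for lab in self.strata:
            if lab not in by_label:
                raise McmcError(f"spec stratum {lab!r} has no matching table")
            if self.M[lab] <= by_label[lab].union:
                raise McmcError(
                    f"augmentation size M={self.M[lab]} for stratum {lab!r} must exceed "
                    f"the observed union {by_label[lab].union}"
                )


@dataclass(frozen=True)
class McmcConfig:
    """Chain layout; defaults follow common practice for this model size:
    two chains, 5,000 burn-in, 25,000 retained draws, no thinning."""

    n_chains: int = 2
    n_burn: int = 5_000
    n_keep: int = 25_000
    seed: int = 0
    thin: int = 1

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise McmcError("at least 2 chains are required for convergence diagnostics")
        if self.n_keep < 1_000:
            raise McmcError("retain at least 1,000 draws per chain")
        if self.thin < 1 or self.n_burn < 0:
            raise McmcError("thin must be >= 1 and n_burn >= 0")


@dataclass(frozen=True)
class PosteriorSummary:
    """Pooled post-burn-in draws reduced to location, 95% HPDI and diagnostics."""

    name: str
    mean: float
    median: float
    hpdi_low: float
    hpdi_high: float
    r_hat: float
    ess: float


@dataclass(frozen=True)
class MtFit:
    """Posterior draws (per chain) and summaries for every tracked parameter.

    ``draws[name]`` has shape (n_chains, n_keep).  ``converged`` is False when
    any parameter's r_hat exceeds 1.1 (degenerate constant parameters, with
    r_hat = nan, do not count against convergence).
    """

    draws: dict
    summaries: dict
    spec: MtModelSpec
    config: McmcConfig
    converged: bool

    def summary(self, name: str) -> PosteriorSummary:
        return self.summaries[name]

    def to_dict(self) -> dict:
        return {
            "converged": self.converged,
            "parameters": {
                n: {"mean": s.mean, "median": s.median,
                    "hpdi_low": s.hpdi_low, "hpdi_high": s.hpdi_high,
                    "r_hat": None if math.isnan(s.r_hat) else s.r_hat,
                    "ess": None if math.isnan(s.ess) else s.ess}
                for n, s in self.summaries.items()
            },
        }


def hpdi(draws, prob: float = 0.95) -> tuple[float, float]:
    """Highest posterior density interval: the shortest contiguous window of
    ``ceil(prob * n)`` sorted draws; ties broken toward the lowest lower bound."""
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 100:
        raise McmcError(f"hpdi needs at least 100 draws, got {n}")
    if not 0.0 < prob < 1.0:
        raise McmcError("prob must lie strictly between 0 and 1")
    k = int(math.ceil(prob * n))
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))  # argmin returns the first minimum: lowest lower bound
    return float(x[i]), float(x[i + k - 1])


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor from between/within-chain variances.

    Returns nan (the degenerate flag) when the within-chain variance is zero,
    as with constant chains.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise McmcError("gelman_rubin needs >= 2 equal-length chains")
    n = arr.shape[1]
    if n < 100:
        raise McmcError("gelman_rubin needs chains of length >= 100")
    within = float(np.mean(np.var(arr, axis=1, ddof=1)))
    between_over_n = float(np.var(np.mean(arr, axis=1), ddof=1))
    if within == 0.0:
        return math.nan
    var_plus = (n - 1) / n * within + between_over_n
    return math.sqrt(var_plus / within)


def _effective_draws(arr: np.ndarray) -> float:
    """Effective sample size of the pooled chains (arviz's estimator)."""
    import arviz as az

    if np.ptp(arr) == 0.0:
        return math.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(arr))  # (chain, draw) array


def _run_chain(
    tables: list[ContingencyTable],
    spec: MtModelSpec,
    cfg: McmcConfig,
    rng: np.random.Generator,
    chain_index: int,
) -> dict:
    """One chain over all strata; strata are conditionally independent so the
    per-stratum updates are vectorised across strata within each sweep."""
    by_label = {t.label: t for t in tables}
    S = len(spec.strata)
    n_obs = np.array([by_label[s].union for s in spec.strata])
    nA = np.array([by_label[s].n1 for s in spec.strata])
    nB = np.array([by_label[s].n2 for s in spec.strata])
    M = np.array([spec.M[s] for s in spec.strata])
    n_aug = M - n_obs

    # Over-dispersed starts: chains begin at staggered inclusion fractions.
    start_frac = (chain_index % 2) * 0.9 + 0.05
    u = np.minimum(np.round(start_frac * n_aug).astype(int), n_aug)

    keep_N = np.empty((cfg.n_keep, S), dtype=np.int64)
    keep_pA = np.empty((cfg.n_keep, S))
    keep_pB = np.empty((cfg.n_keep, S))
    total_iters = cfg.n_burn + cfg.n_keep * cfg.thin
    stored = 0
    for it in range(total_iters):
        Nz = n_obs + u
        pA = rng.beta(1 + nA, 1 + Nz - nA)
        pB = rng.beta(1 + nB, 1 + Nz - nB)
        psi = rng.beta(1 + Nz, 1 + M - Nz)
        q = (1.0 - pA) * (1.0 - pB)
        w = psi * q / (psi * q + 1.0 - psi)
        u = rng.binomial(n_aug, w)
        if it >= cfg.n_burn and (it - cfg.n_burn) % cfg.thin == 0:
            keep_N[stored] = n_obs + u
            keep_pA[stored] = pA
            keep_pB[stored] = pB
            stored += 1
    return {"N": keep_N, "pA": keep_pA, "pB": keep_pB}


def fit_mt(
    tables: list[ContingencyTable],
    spec: MtModelSpec | None = None,
    cfg: McmcConfig = McmcConfig(),
    strict: bool = False,
) -> MtFit:
    """Fit the stratified M_t model and summarise the posterior.

    Tracked parameters: ``N_total``, per-stratum ``N[label]``, ``p_A[label]``
    and ``p_B[label]``.  Raises :class:`McmcError` if posterior mass piles up
    at any augmentation bound (the super-population was too small), and flags
    (or, in strict mode, raises on) r_hat > 1.1.
    """
    if spec is None:
        spec = MtModelSpec.from_tables(tables)
    spec.validate(tables)
    rngs = spawn_rngs(cfg.seed, cfg.n_chains)
    chains = [_run_chain(tables, spec, cfg, rngs[c], c) for c in range(cfg.n_chains)]

    S = len(spec.strata)
    M = np.array([spec.M[s] for s in spec.strata])
    N = np.stack([c["N"] for c in chains])          # (chains, keep, S)
    pA = np.stack([c["pA"] for c in chains])
    pB = np.stack([c["pB"] for c in chains])

    # Augmentation exhaustion: posterior must not press against M_s.
    pile = (N >= np.ceil(0.95 * M)).mean(axis=(0, 1))
    for s_idx in np.flatnonzero(pile > 0.01):
        raise McmcError(
            f"posterior mass piles at the augmentation bound in stratum "
            f"{spec.strata[s_idx]!r} (P(N >= 0.95*M) = {pile[s_idx]:.3f}); "
            f"refit with a larger M than {M[s_idx]}"
        )

    draws: dict[str, np.ndarray] = {"N_total": N.sum(axis=2).astype(float)}
    for j, lab in enumerate(spec.strata):
        draws[f"N[{lab}]"] = N[:, :, j].astype(float)
        draws[f"p_A[{lab}]"] = pA[:, :, j]
        draws[f"p_B[{lab}]"] = pB[:, :, j]

    summaries: dict[str, PosteriorSummary] = {}
    converged = True
    for name, arr in draws.items():
        pooled = arr.ravel()
        lo, hi = hpdi(pooled, 0.95)
        r = gelman_rubin(arr)
        if not math.isnan(r) and r > RHAT_THRESHOLD:
            converged = False
        summaries[name] = PosteriorSummary(
            name=name,
            mean=float(pooled.mean()),
            median=float(np.median(pooled)),
            hpdi_low=lo,
            hpdi_high=hi,
            r_hat=r,
            ess=_effective_draws(arr),
        )
    if not converged:
        worst = max((s for s in summaries.values() if not math.isnan(s.r_hat)),
                    key=lambda s: s.r_hat)
        msg = (f"chains have not converged: r_hat = {worst.r_hat:.3f} for "
               f"{worst.name!r} (threshold {RHAT_THRESHOLD})")
        if strict:
            raise McmcError(msg)
        logger.warning(msg)
    return MtFit(draws=draws, summaries=summaries, spec=spec, config=cfg,
                 converged=converged)
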