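"""End-to-end pipeline: link, stratify, estimate, model, report.

``run_pipeline`` composes every stage into one consolidated JSON-ready
report mirroring the structure of a published two-source surveillance
analysis: observed union and overlap, Lincoln-Petersen / Chapman / stratified
estimates with intervals, the Bayesian M_t posterior, per-source
completeness under each estimate, and prevalence against census
denominators.  Identical configuration and seed give byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from ._util import percent, round_half_up
from .bayes import McmcConfig, MtModelSpec, fit_mt
from .estimators import chapman, lincoln_petersen, stratified_estimate
from .rates import completeness, prevalence
from .registry import (ContingencyTable, StratumScheme, dedupe, link_sources,
                       read_case_csv, stratify)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """One reproducible run: inputs, stratification, model and denominators."""

    source_a: str | None = None
    source_b: str | None = None
    age_breaks: tuple[int, ...] = (85, 90)
    use_gender: bool = True
    seed: int = 0
    mcmc: McmcConfig | None = None
    population: int | None = None
    population_65_plus: int | None = None
    n_hat_65_plus: dict = field(default_factory=dict)  # method -> externally supplied estimate
    run_bayes: bool = True
    strict: bool = False

    def content_hash(self) -> str:
        payload = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else
                 v.__dict__ if isinstance(v, McmcConfig) else v)
             for k, v in self.__dict__.items()},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    return wrap


def run_pipeline(
    config: RunConfig,
    records_a=None,
    records_b=None,
) -> dict:
    """Execute link -> stratify -> estimators -> Bayes M_t -> rates.

    Case lists may be passed in memory or read from ``config.source_a/b``
    CSV paths.  Returns the consolidated report dict (JSON-serialisable).
    """
    if records_a is None:
        if config.source_a is None:
            raise PipelineError("stage 'load' failed: no source A (path or records)")
        records_a = _stage("load")(read_case_csv, config.source_a, "A")
    if records_b is None:
        if config.source_b is None:
            raise PipelineError("stage 'load' failed: no source B (path or records)")
        records_b = _stage("load")(read_case_csv, config.source_b, "B")

    raw_a, raw_b = len(records_a), len(records_b)
    a = _stage("dedupe")(dedupe, records_a, strict=config.strict)
    b = _stage("dedupe")(dedupe, records_b, strict=config.strict)
    logger.info("dedupe: source A %d -> %d, source B %d -> %d", raw_a, len(a), raw_b, len(b))

    overall = _stage("link")(link_sources, a, b)
    logger.info("link: m=%d a_only=%d b_only=%d union=%d",
                overall.m, overall.a_only, overall.b_only, overall.union)
    scheme = StratumScheme(age_breaks=config.age_breaks, use_gender=config.use_gender)
    tables = _stage("stratify")(stratify, a, b, scheme, strict=config.strict)
    logger.info("stratify: %d strata, %d non-empty",
                len(tables), sum(t.union > 0 for t in tables))

    lp = _stage("estimate")(lincoln_petersen, overall)
    ch = _stage("estimate")(chapman, overall)
    strat = _stage("estimate")(stratified_estimate, tables, "lincoln_petersen")
    estimates = {"lincoln_petersen": lp, "chapman": ch, "stratified_lp": strat}

    bayes_block = None
    if config.run_bayes:
        cfg = config.mcmc or McmcConfig(seed=config.seed)
        if cfg.seed != config.seed:
            cfg = McmcConfig(n_chains=cfg.n_chains, n_burn=cfg.n_burn,
                             n_keep=cfg.n_keep, seed=config.seed, thin=cfg.thin)
        fit = _stage("bayes")(fit_mt, tables, MtModelSpec.from_tables(tables), cfg,
                              strict=config.strict)
        s = fit.summary("N_total")
        bayes_block = {
            "mean": round_half_up(s.mean),
            "median": round_half_up(s.median),
            "hpdi_low": round_half_up(s.hpdi_low),
            "hpdi_high": round_half_up(s.hpdi_high),
            "r_hat": None if s.r_hat != s.r_hat else round(s.r_hat, 4),
            "converged": fit.converged,
            "parameters": fit.to_dict()["parameters"],
        }
        estimates_for_rates = {**{k: v.n_hat_exact for k, v in estimates.items()},
                               "bayes_mt": s.mean}
    else:
        estimates_for_rates = {k: v.n_hat_exact for k, v in estimates.items()}

    source_totals = {"A": overall.n1, "B": overall.n2}
    completeness_block = {
        method: {src: completeness(tot, n_hat) for src, tot in source_totals.items()}
        for method, n_hat in estimates_for_rates.items()
    }

    prevalence_block: dict = {}
    if config.population:
        prevalence_block["all_ages"] = {
            method: prevalence(n_hat, config.population)
            for method, n_hat in estimates_for_rates.items()
        }
    if config.population_65_plus:
        sub: dict = {}
        for method, n65 in config.n_hat_65_plus.items():
            sub[method] = prevalence(n65, config.population_65_plus)
        prevalence_block["age_65_plus"] = sub or None

    report = {
        "provenance": {
            "package": "twolist",
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.content_hash(),
        },
        "counts": {
            "raw_records": {"A": raw_a, "B": raw_b},
            "deduped": {"A": len(a), "B": len(b)},
            "table": overall.to_dict(),
            "union": overall.union,
            "overlap_pct": percent(overall.m, overall.union),
        },
        "strata": [t.to_dict() for t in tables],
        "estimates": {k: v.to_dict() for k, v in estimates.items()},
        "bayes_mt": bayes_block,
        "completeness_pct": completeness_block,
        "prevalence_pct": prevalence_block,
    }
    return report


def render_table1(t: ContingencyTable, n_hat: float | None = None) -> str:
    """Render the 2x2 capture-history table with margins.

    The never-observed cell is the estimate minus the union, shown between
    asterisks (it is inferred, not counted); with no estimate available the
    cell is left blank with a note.
    """
    if n_hat is not None:
        unobserved = f"*{int(round_half_up(n_hat - t.union))}*"
        total = str(int(round_half_up(n_hat)))
    else:
        unobserved, total = "", "(no estimate)"
    rows = [
        ["", "", "Source A", "", ""],
        ["", "", "Yes", "No", "Total"],
        ["Source B", "Yes", str(t.m), str(t.b_only), str(t.n2)],
        ["", "No", str(t.a_only), unobserved, ""],
        ["", "Total", str(t.n1), "", total],
    ]
    widths = [max(len(r[c]) for r in rows) for c in range(5)]
    lines = ["  ".join(r[c].rjust(widths[c]) for c in range(5)).rstrip() for r in rows]
    if n_hat is None:
        lines.append("note: never-observed cell requires a population estimate")
    return "\n".join(lines) + "\n"


def render_table1_csv(t: ContingencyTable, n_hat: float | None = None) -> str:
    unobs = "" if n_hat is None else int(round_half_up(n_hat - t.union))
    total = "" if n_hat is None else int(round_half_up(n_hat))
    return (
        "cell,source_a,source_b,count,estimated\n"
        f"both,yes,yes,{t.m},no\n"
        f"a_only,yes,no,{t.a_only},no\n"
        f"b_only,no,yes,{t.b_only},no\n"
        f"never_observed,no,no,{unobs},yes\n"
        f"total,,,{total},yes\n"
    )


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
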