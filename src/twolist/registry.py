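"""Case-list ingestion, deduplication, exact-key linkage and stratification.

Two surveillance sources report cases of the same condition: source A is an
administrative health-insurance style list, source B a clinical memory-clinic
style list.  Each person carries an opaque key; linkage across sources is
exact on that key (probabilistic name-based linkage is out of scope — the
synthetic data carry shared keys by construction).  The product of this
module is the 2x2 capture-history contingency table (captured by both,
A only, B only), overall and per demographic stratum, which is the sole
input to every estimator downstream.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

VALID_SOURCES = ("A", "B")
VALID_GENDERS = ("F", "M")

#: Age-class boundaries used throughout: classes <=84, 85-89, >=90.
#: The printed class description leaves ages 84 and 90 unassigned; the
#: contiguous partition keeping the interior 85-89 class intact is used.
DEFAULT_AGE_BREAKS = (85, 90)


class RegistryError(ValueError):
    """Invalid case records or inconsistent registry input."""


@dataclass(frozen=True)
class CaseRecord:
    """One surveillance report: a person seen by one source.

    Parameters
    ----------
    person_id : opaque non-empty string key shared across sources.
    source : "A" (insurance-like list) or "B" (memory-clinic-like list).
    age : integer years in [0, 130], or None when unrecorded.
    gender : "F" or "M", or None when unrecorded.
    """

    person_id: str
    source: str
    age: int | None = None
    gender: str | None = None

    def __post_init__(self) -> None:
        if not self.person_id:
            raise RegistryError("person_id must be non-empty")
        if self.source not in VALID_SOURCES:
            raise RegistryError(f"source must be one of {VALID_SOURCES}, got {self.source!r}")
        if self.age is not None and not (0 <= self.age <= 130):
            raise RegistryError(f"age must lie in [0, 130], got {self.age}")
        if self.gender is not None and self.gender not in VALID_GENDERS:
            raise RegistryError(f"gender must be one of {VALID_GENDERS}, got {self.gender!r}")


@dataclass(frozen=True)
class ContingencyTable:
    """Capture-history counts for one stratum (or the pooled lists).

    ``m`` persons appear on both lists, ``a_only``/``b_only`` on exactly one.
    The never-captured cell is unobserved; estimating it is the whole game.
    """

    m: int
    a_only: int
    b_only: int
    label: str = "overall"

    def __post_init__(self) -> None:
        if min(self.m, self.a_only, self.b_only) < 0:
            raise RegistryError("contingency counts must be non-negative")

    @property
    def n1(self) -> int:
        """Size of list A (captured by A, whether or not also by B)."""
        return self.m + self.a_only

    @property
    def n2(self) -> int:
        """Size of list B."""
        return self.m + self.b_only

    @property
    def union(self) -> int:
        """Distinct persons observed by at least one source."""
        return self.m + self.a_only + self.b_only

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "m": self.m,
            "a_only": self.a_only,
            "b_only": self.b_only,
            "n1": self.n1,
            "n2": self.n2,
            "union": self.union,
        }


@dataclass(frozen=True)
class StratumScheme:
    """Partition of the demographic space into age classes x gender.

    ``age_breaks`` are left-closed cut points: breaks (85, 90) give classes
    [0, 85), [85, 90), [90, inf) — i.e. <=84, 85-89, >=90 in whole years.
    """

    age_breaks: tuple[int, ...] = DEFAULT_AGE_BREAKS
    use_gender: bool = True

    def __post_init__(self) -> None:
        if list(self.age_breaks) != sorted(set(self.age_breaks)) or not self.age_breaks:
            raise RegistryError("age_breaks must be strictly increasing and non-empty")

    @property
    def n_age_classes(self) -> int:
        return len(self.age_breaks) + 1

    def age_class(self, age: int) -> int:
        """0-based index of the age class containing ``age``."""
        for i, b in enumerate(self.age_breaks):
            if age < b:
                return i
        return len(self.age_breaks)

    def age_class_label(self, idx: int) -> str:
        lo = 0 if idx == 0 else self.age_breaks[idx - 1]
        if idx == len(self.age_breaks):
            return f">={lo}"
        hi = self.age_breaks[idx] - 1
        return f"<={hi}" if idx == 0 else f"{lo}-{hi}"

    def age_class_bounds(self, idx: int) -> tuple[int, int | None]:
        """[low, high) bounds in years; high is None for the open top class."""
        lo = 0 if idx == 0 else self.age_breaks[idx - 1]
        hi = None if idx == len(self.age_breaks) else self.age_breaks[idx]
        return lo, hi

    def labels(self) -> list[str]:
        """All stratum labels in canonical order (age class major, F before M)."""
        out = []
        for i in range(self.n_age_classes):
            a = self.age_class_label(i)
            if self.use_gender:
                out.extend([f"F:{a}", f"M:{a}"])
            else:
                out.append(a)
        return out

    def stratum_label(self, age: int, gender: str | None) -> str:
        a = self.age_class_label(self.age_class(age))
        return f"{gender}:{a}" if self.use_gender else a


def dedupe(records: Sequence[CaseRecord], strict: bool = False) -> list[CaseRecord]:
    """Collapse a single source's list to one record per person.

    Demographics are taken from the first occurrence.  A later occurrence
    disagreeing on gender, or on age by more than one year, is logged as a
    conflict (raised in strict mode — it suggests a key collision).
    """
    sources = {r.source for r in records}
    if len(sources) > 1:
        raise RegistryError(f"dedupe expects records from a single source, got {sorted(sources)}")
    seen: dict[str, CaseRecord] = {}
    removed = conflicts = 0
    for r in records:
        first = seen.get(r.person_id)
        if first is None:
            seen[r.person_id] = r
            continue
        removed += 1
        age_conflict = (
            first.age is not None and r.age is not None and abs(first.age - r.age) > 1
        )
        gender_conflict = (
            first.gender is not None and r.gender is not None and first.gender != r.gender
        )
        if age_conflict or gender_conflict:
            conflicts += 1
            msg = (f"conflicting duplicate for person {r.person_id!r}: "
                   f"{(first.age, first.gender)} vs {(r.age, r.gender)}")
            if strict:
                raise RegistryError(msg)
            logger.warning(msg)
    if removed:
        logger.info("dedupe: removed %d duplicate record(s) (%d with conflicts)",
                    removed, conflicts)
    return list(seen.values())


def link_sources(a: Sequence[CaseRecord], b: Sequence[CaseRecord]) -> ContingencyTable:
    """Exact-key linkage of two deduplicated lists into the overall table."""
    keys_a = {r.person_id for r in a}
    keys_b = {r.person_id for r in b}
    if len(keys_a) != len(a) or len(keys_b) != len(b):
        raise RegistryError("link_sources requires deduplicated inputs (run dedupe first)")
    m = len(keys_a & keys_b)
    return ContingencyTable(m=m, a_only=len(keys_a) - m, b_only=len(keys_b) - m)


def _resolve_demographics(
    a: Sequence[CaseRecord], b: Sequence[CaseRecord], prefer_source: str
) -> dict[str, tuple[int | None, str | None]]:
    """Map person -> (age, gender), cross-source conflicts won by one source.

    Source A (administrative) wins by default: civil-status fields there are
    verified at registration.
    """
    first, second = (a, b) if prefer_source == "A" else (b, a)
    demo: dict[str, tuple[int | None, str | None]] = {}
    for r in list(second) + list(first):  # preferred source written last
        demo[r.person_id] = (r.age, r.gender)
    return demo


def stratify(
    a: Sequence[CaseRecord],
    b: Sequence[CaseRecord],
    scheme: StratumScheme,
    strict: bool = False,
    prefer_source: str = "A",
) -> list[ContingencyTable]:
    """Split the linked table by demographic stratum.

    Returns one table per stratum label of ``scheme`` (empty strata
    included), summing cell-wise to the overall table minus any records
    excluded for missing demographics.
    """
    demo = _resolve_demographics(a, b, prefer_source)
    keys_a = {r.person_id for r in a}
    keys_b = {r.person_id for r in b}
    counts: dict[str, list[int]] = {lab: [0, 0, 0] for lab in scheme.labels()}
    excluded = 0
    for pid in keys_a | keys_b:
        age, gender = demo[pid]
        if age is None or (scheme.use_gender and gender is None):
            excluded += 1
            if strict:
                raise RegistryError(f"person {pid!r} has missing demographics")
            continue
        lab = scheme.stratum_label(age, gender)
        cell = 0 if (pid in keys_a and pid in keys_b) else (1 if pid in keys_a else 2)
        counts[lab][cell] += 1
    if excluded:
        logger.warning("stratify: excluded %d record(s) with missing demographics", excluded)
    return [ContingencyTable(m=c[0], a_only=c[1], b_only=c[2], label=lab)
            for lab, c in counts.items()]


def union_count(t: ContingencyTable) -> int:
    """Observed case count: persons on at least one list."""
    return t.union


def overlap_proportion(t: ContingencyTable, as_percent: bool = False) -> float:
    """Fraction (or half-up 1-decimal percentage) of observed cases on both lists."""
    if t.union == 0:
        raise RegistryError("overlap_proportion undefined for an empty table")
    frac = t.m / t.union
    if as_percent:
        from ._util import percent
        return percent(t.m, t.union)
    return frac


# ---------------------------------------------------------------------------
# File formats: per-source CSV in, tables as JSON/CSV out.

def read_case_csv(path: str | Path, source: str) -> list[CaseRecord]:
    """Read a case list CSV with header ``person_id,age,gender``.

    Blank age/gender fields become None (handled downstream per strict mode).
    """
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"person_id", "age", "gender"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise RegistryError(f"{path}: expected CSV header with columns {sorted(required)}")
        for row in reader:
            age = row["age"].strip()
            gender = row["gender"].strip().upper()
            records.append(CaseRecord(
                person_id=row["person_id"].strip(),
                source=source,
                age=int(age) if age else None,
                gender=gender or None,
            ))
    if not records:
        raise RegistryError(f"{path}: case list is empty")
    return records


def write_case_csv(records: Iterable[CaseRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["person_id", "age", "gender"])
        for r in records:
            w.writerow([r.person_id, "" if r.age is None else r.age, r.gender or ""])


def write_tables_json(tables: Sequence[ContingencyTable], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([t.to_dict() for t in tables], fh, indent=2)
        fh.write("\n")


def read_tables_json(path: str | Path) -> list[ContingencyTable]:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return [ContingencyTable(m=d["m"], a_only=d["a_only"], b_only=d["b_only"],
                             label=d.get("label", "overall")) for d in raw]


def write_tables_csv(tables: Sequence[ContingencyTable], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "m", "a_only", "b_only", "n1", "n2", "union"])
        for t in tables:
            w.writerow([t.label, t.m, t.a_only, t.b_only, t.n1, t.n2, t.union])
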