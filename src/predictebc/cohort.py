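"""Cohort schema, I/O, staging exclusion and mean imputation.

The canonical cohort table has one row per patient:

``id,age_dx,size_mm,grade,nodes_pos,nodes_sampled,er,her2,ki67,detection,therapy,follow_up_years,outcome``

Missing values are empty cells.  Grade accepts ``1/2/3`` or
``low/intermediate/high`` and is stored internally as an ordinal code
(low=0, intermediate=1, high=2); mean imputation may therefore produce
fractional grade codes, which round-trip through the CSV as decimals.
HER2 and KI67 accept ``pos``/``neg`` and are stored as 1.0/0.0; after
imputation they may hold a fractional status in [0, 1] interpreted
downstream as a positivity weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

__all__ = [
    "PatientRecord",
    "Cohort",
    "CohortSchemaError",
    "CohortRowError",
    "COHORT_COLUMNS",
    "read_cohort",
    "write_cohort",
    "apply_staging_exclusion",
    "impute_missing",
]

COHORT_COLUMNS = [
    "id",
    "age_dx",
    "size_mm",
    "grade",
    "nodes_pos",
    "nodes_sampled",
    "er",
    "her2",
    "ki67",
    "detection",
    "therapy",
    "follow_up_years",
    "outcome",
]

GRADE_NAMES = {"low": 0.0, "intermediate": 1.0, "high": 2.0}
GRADE_CODES_TO_NAME = {0.0: "low", 1.0: "intermediate", 2.0: "high"}
THERAPIES = ("none", "chemo", "endocrine", "both")
OUTCOMES = ("censored", "bc_death", "other_death")
DETECTIONS = ("screen", "symptomatic")


class CohortSchemaError(ValueError):
    """Raised when a cohort file does not match the canonical schema."""


class CohortRowError(ValueError):
    """Raised when one or more rows cannot be parsed; carries row numbers."""

    def __init__(self, problems: list[tuple[int, str]]):
        self.problems = problems
        lines = "; ".join(f"row {r}: {msg}" for r, msg in problems)
        super().__init__(f"{len(problems)} unparseable row(s): {lines}")


@dataclass
class PatientRecord:
    """One patient's covariates, therapy, follow-up and outcome.

    ``grade`` is an ordinal code in [0, 2]; ``her2``/``ki67`` are
    positivity statuses in [0, 1] (fractional after mean imputation);
    ``node_code`` holds an imputed fractional node-category code when
    ``nodes_pos`` itself is missing.
    """

    id: str
    age_dx: float
    size_mm: float | None
    grade: float | None
    nodes_pos: float | None
    nodes_sampled: float | None
    er: str
    her2: float | None
    ki67: float | None
    detection: str | None
    therapy: str
    follow_up_years: float
    outcome: str
    node_code: float | None = None

    def __post_init__(self) -> None:
        if self.er not in ("pos", "neg"):
            raise ValueError(f"record {self.id}: er must be pos/neg, got {self.er!r}")
        if self.therapy not in THERAPIES:
            raise ValueError(f"record {self.id}: unknown therapy {self.therapy!r}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"record {self.id}: unknown outcome {self.outcome!r}")
        if self.detection is not None and self.detection not in DETECTIONS:
            raise ValueError(f"record {self.id}: unknown detection {self.detection!r}")
        if self.age_dx <= 0:
            raise ValueError(f"record {self.id}: age_dx must be positive")
        if self.follow_up_years < 0:
            raise ValueError(f"record {self.id}: follow_up_years must be >= 0")
        if self.size_mm is not None and self.size_mm <= 0:
            raise ValueError(f"record {self.id}: size_mm must be positive")
        if self.grade is not None and not (0.0 <= self.grade <= 2.0):
            raise ValueError(f"record {self.id}: grade code outside [0, 2]")
        for name in ("her2", "ki67"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"record {self.id}: {name} status outside [0, 1]")
        for name in ("nodes_pos", "nodes_sampled"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"record {self.id}: {name} must be >= 0")
        if (
            self.nodes_pos is not None
            and self.nodes_sampled is not None
            and self.nodes_pos > self.nodes_sampled
        ):
            raise ValueError(
                f"record {self.id}: nodes_pos ({self.nodes_pos}) exceeds "
                f"nodes_sampled ({self.nodes_sampled})"
            )


@dataclass
class Cohort:
    """Ordered patient records with provenance and an imputation log."""

    records: list[PatientRecord]
    provenance: str = ""
    imputation_log: dict = field(default_factory=dict)
    exclusion_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            seen, dups = set(), set()
            for i in ids:
                (dups if i in seen else seen).add(i)
            raise ValueError(f"duplicate patient ids in cohort: {sorted(dups)[:10]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, ids: set[str], provenance: str | None = None) -> "Cohort":
        recs = [r for r in self.records if r.id in ids]
        return Cohort(
            recs,
            provenance=provenance or self.provenance,
            imputation_log=dict(self.imputation_log),
            exclusion_log=dict(self.exclusion_log),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "id": r.id,
                    "age_dx": r.age_dx,
                    "size_mm": r.size_mm,
                    "grade": _format_grade(r.grade),
                    "nodes_pos": r.nodes_pos,
                    "nodes_sampled": r.nodes_sampled,
                    "er": r.er,
                    "her2": _format_marker(r.her2),
                    "ki67": _format_marker(r.ki67),
                    "detection": r.detection or "",
                    "therapy": r.therapy,
                    "follow_up_years": r.follow_up_years,
                    "outcome": r.outcome,
                }
            )
        return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def _format_grade(code: float | None) -> str:
    if code is None:
        return ""
    if code in GRADE_CODES_TO_NAME:
        return GRADE_CODES_TO_NAME[code]
    return repr(code)


def _format_marker(v: float | None) -> str:
    if v is None:
        return ""
    if v == 0.0:
        return "neg"
    if v == 1.0:
        return "pos"
    return repr(v)


def _parse_grade(raw: str) -> float | None:
    s = raw.strip().lower()
    if s == "":
        return None
    if s in GRADE_NAMES:
        return GRADE_NAMES[s]
    v = float(s)  # may raise ValueError, caught per-row
    if v in (1.0, 2.0, 3.0):
        return v - 1.0
    if 0.0 <= v <= 2.0:
        return v  # fractional grade code (round trip of imputed values)
    raise ValueError(f"grade {raw!r} not a recognised grade")


def _parse_marker(raw: str, name: str) -> float | None:
    s = raw.strip().lower()
    if s in ("", "missing"):
        return None
    if s in ("pos", "positive", "+"):
        return 1.0
    if s in ("neg", "negative", "-"):
        return 0.0
    v = float(s)
    if 0.0 <= v <= 1.0:
        return v
    raise ValueError(f"{name} status {raw!r} outside [0, 1]")


def _parse_float(raw: str) -> float | None:
    s = str(raw).strip()
    return None if s == "" else float(s)


def read_cohort(path: str | Path, schema_strict: bool = True) -> Cohort:
    """Read a canonical cohort CSV into a :class:`Cohort`.

    With ``schema_strict`` the header must contain exactly the canonical
    columns; otherwise extra columns are ignored.  All rows are parsed and
    validated; unparseable rows are reported together by row number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortSchemaError(f"missing mandatory column(s): {missing_cols}")
    if schema_strict:
        extra = [c for c in df.columns if c not in COHORT_COLUMNS]
        if extra:
            raise CohortSchemaError(f"unexpected column(s): {extra}")

    records: list[PatientRecord] = []
    problems: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        rownum = int(i) + 2  # 1-based with header
        try:
            det = row["detection"].strip().lower() or None
            if det == "missing":
                det = None
            records.append(
                PatientRecord(
                    id=row["id"].strip(),
                    age_dx=float(row["age_dx"]),
                    size_mm=_parse_float(row["size_mm"]),
                    grade=_parse_grade(row["grade"]),
                    nodes_pos=_parse_float(row["nodes_pos"]),
                    nodes_sampled=_parse_float(row["nodes_sampled"]),
                    er=row["er"].strip().lower(),
                    her2=_parse_marker(row["her2"], "her2"),
                    ki67=_parse_marker(row["ki67"], "ki67"),
                    detection=det,
                    therapy=row["therapy"].strip().lower(),
                    follow_up_years=float(row["follow_up_years"]),
                    outcome=row["outcome"].strip().lower(),
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append((rownum, str(exc)))
    if problems:
        raise CohortRowError(problems)
    return Cohort(records, provenance=str(path))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to the canonical CSV format (lossless round trip)."""
    cohort.to_frame().to_csv(path, index=False)


def apply_staging_exclusion(cohort: Cohort) -> Cohort:
    """Drop node-negative patients with inadequate axillary staging.

    A record is excluded when ``nodes_pos == 0`` and ``nodes_sampled < 4``
    (fewer than four nodes sampled gives an unreliable node-negative call).
    Records with missing staging fields are retained.  Idempotent.
    """
    kept, excluded = [], []
    for r in cohort.records:
        if (
            r.nodes_pos is not None
            and r.nodes_sampled is not None
            and r.nodes_pos == 0
            and r.nodes_sampled < 4
        ):
            excluded.append(r.id)
        else:
            kept.append(r)
    out = Cohort(
        kept,
        provenance=cohort.provenance,
        imputation_log=dict(cohort.imputation_log),
        exclusion_log=dict(cohort.exclusion_log),
    )
    out.exclusion_log["staging"] = out.exclusion_log.get("staging", 0) + len(excluded)
    return out


def impute_missing(cohort: Cohort) -> Cohort:
    """Mean-impute tumour size, grade, HER2, KI67 and nodal category.

    Size is replaced by the cohort mean of observed sizes (mm); grade by the
    mean of observed ordinal codes (a fractional code); HER2/KI67 by the
    observed positivity proportion (a fractional status); a missing nodal
    count by the cohort mean of observed node-*category* codes, stored on
    ``node_code``.  Observed values are left untouched.  Raises if a
    variable to impute has no observed value at all.
    """
    from .engine import DEFAULT_CODING  # local import avoids a cycle

    recs = list(cohort.records)
    log: dict[str, dict] = {}

    def observed(getter):
        return [getter(r) for r in recs if getter(r) is not None]

    plans: list[tuple[str, object, object]] = [
        ("size_mm", lambda r: r.size_mm, None),
        ("grade", lambda r: r.grade, None),
        ("her2", lambda r: r.her2, None),
        ("ki67", lambda r: r.ki67, None),
    ]
    new = recs
    for name, getter, _ in plans:
        missing_idx = [i for i, r in enumerate(new) if getter(r) is None]
        if not missing_idx:
            continue
        obs = observed(getter)
        if not obs:
            raise ValueError(f"cannot impute {name!r}: no observed values in cohort")
        value = float(sum(obs)) / len(obs)
        new = [
            replace(r, **{name: value}) if i in set(missing_idx) else r
            for i, r in enumerate(new)
        ]
        log[name] = {"n_imputed": len(missing_idx), "value": value}

    # nodal category: impute the category code, not the raw count
    node_missing = [i for i, r in enumerate(new) if r.nodes_pos is None]
    if node_missing:
        codes = [
            DEFAULT_CODING.node_code(r.nodes_pos)
            for r in new
            if r.nodes_pos is not None
        ]
        if not codes:
            raise ValueError("cannot impute nodal category: no observed node counts")
        value = float(sum(codes)) / len(codes)
        new = [
            replace(r, node_code=value) if i in set(node_missing) else r
            for i, r in enumerate(new)
        ]
        log["node_code"] = {"n_imputed": len(node_missing), "value": value}

    merged_log = dict(cohort.imputation_log)
    merged_log.update(log)
    return Cohort(
        new,
        provenance=cohort.provenance,
        imputation_log=merged_log,
        exclusion_log=dict(cohort.exclusion_log),
    )

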