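"""Patient-level cohort model for endocervical adenocarcinoma risk analysis.

Holds the validated per-patient pathology record (Silva pattern, tumor
size, depth of stromal invasion, LVSI grade, nodal/margin/parametrial
status) together with censored recurrence-free and overall survival
outcomes, plus the operations every downstream stage relies on: CSV
round-trip, factor dichotomization into named cutoff variables, DSI
thirds, and the high-risk exclusion that defines the intermediate-risk
analysis set.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "PatientRecord",
    "Cohort",
    "CutoffVariable",
    "CutoffConfig",
    "SchemaError",
    "CohortValidationError",
    "CANONICAL_COLUMNS",
    "SILVA_PATTERNS",
    "LVSI_GRADES",
    "LN_SITES",
    "read_cohort",
    "write_cohort",
    "dsi_third",
    "make_cutoff_variables",
    "default_model_variables",
    "variable_by_name",
    "factor_value",
    "is_high_risk",
    "filter_intermediate",
]

SILVA_PATTERNS = ("A", "B", "C")
LVSI_GRADES = ("none", "mild", "substantial")
LN_SITES = ("none", "pelvic", "common_iliac", "para_aortic")

CANONICAL_COLUMNS = (
    "patient_id",
    "age",
    "figo_stage",
    "silva",
    "tumor_size_cm",
    "dsi_fraction",
    "lvsi",
    "ln_site",
    "margin_positive",
    "parametrial_positive",
    "pni",
    "adjuvant",
    "rfs_months",
    "rfs_event",
    "os_months",
    "os_event",
)


class SchemaError(ValueError):
    """A cohort file does not expose the required columns."""


class CohortValidationError(ValueError):
    """A record (or file row) violates the cohort data contract."""


@dataclass(frozen=True)
class PatientRecord:
    """One subject: pathology factors plus censored RFS/OS outcomes.

    ``dsi_fraction`` is the invaded fraction of cervical stromal
    thickness in [0, 1] (0 = no stromal invasion).  Times are months
    from initial diagnosis; event flags mark observed recurrence /
    cancer death (0 = censored at the recorded time).
    """

    patient_id: str
    age: float
    figo_stage: int
    silva: str
    tumor_size: float
    dsi_fraction: float
    lvsi: str
    ln_site: str
    margin_positive: bool
    parametrial_positive: bool
    pni: bool
    adjuvant: bool
    rfs_time: float
    rfs_event: bool
    os_time: float
    os_event: bool

    def __post_init__(self) -> None:
        def bad(fieldname: str, msg: str) -> CohortValidationError:
            return CohortValidationError(
                f"patient {self.patient_id!r}, field {fieldname!r}: {msg}"
            )

        if not self.patient_id:
            raise CohortValidationError("patient_id must be non-empty")
        if not self.age > 0:
            raise bad("age", f"must be positive, got {self.age}")
        if self.figo_stage not in (1, 2):
            raise bad("figo_stage", f"must be 1 or 2, got {self.figo_stage}")
        if self.silva not in SILVA_PATTERNS:
            raise bad("silva", f"must be one of {SILVA_PATTERNS}, got {self.silva!r}")
        if self.tumor_size < 0:
            raise bad("tumor_size", f"must be non-negative, got {self.tumor_size}")
        if not 0.0 <= self.dsi_fraction <= 1.0:
            raise bad("dsi_fraction", f"must lie in [0, 1], got {self.dsi_fraction}")
        if self.lvsi not in LVSI_GRADES:
            raise bad("lvsi", f"must be one of {LVSI_GRADES}, got {self.lvsi!r}")
        if self.ln_site not in LN_SITES:
            raise bad("ln_site", f"must be one of {LN_SITES}, got {self.ln_site!r}")
        if self.silva == "A" and self.lvsi != "none":
            # Pattern A is by definition non-destructive invasion without LVSI.
            raise bad("lvsi", "Silva pattern A records cannot carry LVSI")
        if not self.rfs_time > 0:
            raise bad("rfs_months", f"must be positive, got {self.rfs_time}")
        if not self.os_time > 0:
            raise bad("os_months", f"must be positive, got {self.os_time}")
        if self.rfs_time > self.os_time:
            raise bad(
                "rfs_months",
                f"recurrence-free time {self.rfs_time} exceeds overall time {self.os_time}",
            )


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of validated patient records."""

    records: tuple[PatientRecord, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen: set[str] = set()
        for rec in self.records:
            if rec.patient_id in seen:
                raise CohortValidationError(
                    f"duplicate patient_id {rec.patient_id!r} in cohort"
                )
            seen.add(rec.patient_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, idx: int) -> PatientRecord:
        return self.records[idx]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "age": r.age,
                    "figo_stage": r.figo_stage,
                    "silva": r.silva,
                    "tumor_size_cm": r.tumor_size,
                    "dsi_fraction": r.dsi_fraction,
                    "lvsi": r.lvsi,
                    "ln_site": r.ln_site,
                    "margin_positive": int(r.margin_positive),
                    "parametrial_positive": int(r.parametrial_positive),
                    "pni": int(r.pni),
                    "adjuvant": int(r.adjuvant),
                    "rfs_months": r.rfs_time,
                    "rfs_event": int(r.rfs_event),
                    "os_months": r.os_time,
                    "os_event": int(r.os_event),
                }
            )
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


# ---------------------------------------------------------------------------
# CSV I/O


_BOOL_VALUES = {"0": False, "1": True, "false": False, "true": True}


def _parse_bool(text: str) -> bool:
    try:
        return _BOOL_VALUES[text.strip().lower()]
    except KeyError:
        raise ValueError(f"expected 0/1 boolean, got {text!r}") from None


def _parse_category(text: str, allowed: Sequence[str]) -> str:
    value = text.strip().lower()
    lookup = {a.lower(): a for a in allowed}
    if value not in lookup:
        raise ValueError(f"expected one of {allowed}, got {text!r}")
    return lookup[value]


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    label: str | None = None,
) -> Cohort:
    """Read a cohort CSV into a validated :class:`Cohort`.

    ``schema`` optionally maps canonical column names to the names used
    in the file.  Categorical fields are decoded case-insensitively;
    row order is preserved.  Errors name the offending column, or the
    1-based data row and patient for cell-level problems.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap = {c: c for c in CANONICAL_COLUMNS}
    if schema:
        colmap.update({k: v for k, v in schema.items() if k in colmap})
    missing = [colmap[c] for c in CANONICAL_COLUMNS if colmap[c] not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records: list[PatientRecord] = []
    for idx in range(len(df)):
        i = idx + 1  # 1-based data-row reporting
        raw = {c: df.iloc[idx][colmap[c]] for c in CANONICAL_COLUMNS}
        pid = str(raw["patient_id"]).strip()
        current_field = "patient_id"
        try:
            current_field = "age"
            age = float(raw["age"])
            current_field = "figo_stage"
            figo = int(float(raw["figo_stage"]))
            current_field = "silva"
            silva = _parse_category(raw["silva"], SILVA_PATTERNS)
            current_field = "tumor_size_cm"
            size = float(raw["tumor_size_cm"])
            current_field = "dsi_fraction"
            dsi = float(raw["dsi_fraction"])
            current_field = "lvsi"
            lvsi = _parse_category(raw["lvsi"], LVSI_GRADES)
            current_field = "ln_site"
            ln_site = _parse_category(raw["ln_site"], LN_SITES)
            current_field = "margin_positive"
            margin = _parse_bool(raw["margin_positive"])
            current_field = "parametrial_positive"
            parametrial = _parse_bool(raw["parametrial_positive"])
            current_field = "pni"
            pni = _parse_bool(raw["pni"])
            current_field = "adjuvant"
            adjuvant = _parse_bool(raw["adjuvant"])
            current_field = "rfs_months"
            rfs_time = float(raw["rfs_months"])
            current_field = "rfs_event"
            rfs_event = _parse_bool(raw["rfs_event"])
            current_field = "os_months"
            os_time = float(raw["os_months"])
            current_field = "os_event"
            os_event = _parse_bool(raw["os_event"])
            current_field = "(record)"
            records.append(
                PatientRecord(
                    patient_id=pid,
                    age=age,
                    figo_stage=figo,
                    silva=silva,
                    tumor_size=size,
                    dsi_fraction=dsi,
                    lvsi=lvsi,
                    ln_site=ln_site,
                    margin_positive=margin,
                    parametrial_positive=parametrial,
                    pni=pni,
                    adjuvant=adjuvant,
                    rfs_time=rfs_time,
                    rfs_event=rfs_event,
                    os_time=os_time,
                    os_event=os_event,
                )
            )
        except CohortValidationError as exc:
            raise CohortValidationError(f"row {i}: {exc}") from None
        except (ValueError, TypeError) as exc:
            raise CohortValidationError(
                f"row {i}, patient {pid!r}, field {current_field!r}: {exc}"
            ) from None
    return Cohort(records=tuple(records), label=label if label is not None else str(path))


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort to CSV with the canonical header; inverse of read."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CANONICAL_COLUMNS)
        for r in cohort:
            writer.writerow(
                [
                    r.patient_id,
                    r.age,
                    r.figo_stage,
                    r.silva,
                    r.tumor_size,
                    r.dsi_fraction,
                    r.lvsi,
                    r.ln_site,
                    int(r.margin_positive),
                    int(r.parametrial_positive),
                    int(r.pni),
                    int(r.adjuvant),
                    r.rfs_time,
                    int(r.rfs_event),
                    r.os_time,
                    int(r.os_event),
                ]
            )
    return path


# ---------------------------------------------------------------------------
# Depth-of-invasion thirds and dichotomization


def dsi_third(record: PatientRecord | float) -> str:
    """Map a stromal-invasion fraction to {none, superficial, middle, deep}.

    Thirds are left-open / right-closed: 0 -> none, (0, 1/3] ->
    superficial, (1/3, 2/3] -> middle, (2/3, 1] -> deep, matching the
    strict ">" convention of the dichotomized DSI factors.
    """
    frac = record.dsi_fraction if isinstance(record, PatientRecord) else float(record)
    if not 0.0 <= frac <= 1.0:
        raise ValueError(f"dsi fraction must lie in [0, 1], got {frac}")
    if frac == 0.0:
        return "none"
    if frac <= 1.0 / 3.0:
        return "superficial"
    if frac <= 2.0 / 3.0:
        return "middle"
    return "deep"


@dataclass(frozen=True)
class CutoffVariable:
    """A named binary predicate over a patient record.

    ``factor`` is one of {age, silva, size, dsi, lvsi}; ``direction``
    is "at-or-above" (inclusive) or "strictly-above".  Ordinal factors
    (silva, lvsi) compare category ranks.
    """

    name: str
    factor: str
    threshold: float | str
    direction: str  # "at-or-above" | "strictly-above"

    def __post_init__(self) -> None:
        if self.factor not in ("age", "silva", "size", "dsi", "lvsi"):
            raise ValueError(f"unknown factor {self.factor!r}")
        if self.direction not in ("at-or-above", "strictly-above"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def evaluate(self, record: PatientRecord) -> bool:
        if self.factor == "age":
            value, cut = record.age, float(self.threshold)
        elif self.factor == "size":
            value, cut = record.tumor_size, float(self.threshold)
        elif self.factor == "dsi":
            value, cut = record.dsi_fraction, float(self.threshold)
        elif self.factor == "silva":
            value = float(SILVA_PATTERNS.index(record.silva))
            cut = float(SILVA_PATTERNS.index(str(self.threshold)))
        else:  # lvsi
            value = float(LVSI_GRADES.index(record.lvsi))
            cut = float(LVSI_GRADES.index(str(self.threshold)))
        return value >= cut if self.direction == "at-or-above" else value > cut


@dataclass(frozen=True)
class CutoffConfig:
    """Cut-point lists defining the candidate dichotomized variables."""

    age_cuts: tuple[float, ...] = (40.0, 50.0, 60.0)
    silva_variants: tuple[str, ...] = ("BC", "C")
    size_cuts: tuple[float, ...] = (2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0)
    dsi_cuts: tuple[tuple[int, int], ...] = ((1, 3), (2, 3))
    lvsi_variants: tuple[str, ...] = ("ge_mild", "gt_mild")


def _size_name(cut: float) -> str:
    return f"size_ge_{cut:g}"


def make_cutoff_variables(config: CutoffConfig | None = None) -> list[CutoffVariable]:
    """Build the deterministic, canonically named candidate variables.

    Defaults enumerate age at 40/50/60 years, Silva B+C and Silva C,
    tumor size at 2..5 cm by 0.5 (inclusive thresholds), DSI strictly
    above 1/3 and 2/3, and the two LVSI dichotomies (any LVSI; strictly
    more than mild, i.e. substantial).
    """
    config = config or CutoffConfig()
    variables: list[CutoffVariable] = []
    for cut in config.age_cuts:
        variables.append(
            CutoffVariable(f"age_ge_{cut:g}", "age", float(cut), "at-or-above")
        )
    for variant in config.silva_variants:
        if variant == "BC":
            variables.append(CutoffVariable("silva_BC", "silva", "B", "at-or-above"))
        elif variant == "C":
            variables.append(CutoffVariable("silva_C", "silva", "C", "at-or-above"))
        else:
            raise ValueError(f"unknown Silva variant {variant!r}")
    for cut in config.size_cuts:
        variables.append(CutoffVariable(_size_name(cut), "size", float(cut), "at-or-above"))
    for num, den in config.dsi_cuts:
        variables.append(
            CutoffVariable(f"dsi_gt_{num}_{den}", "dsi", num / den, "strictly-above")
        )
    for variant in config.lvsi_variants:
        if variant == "ge_mild":
            variables.append(CutoffVariable("lvsi_ge_mild", "lvsi", "mild", "at-or-above"))
        elif variant == "gt_mild":
            variables.append(CutoffVariable("lvsi_gt_mild", "lvsi", "mild", "strictly-above"))
        else:
            raise ValueError(f"unknown LVSI variant {variant!r}")
    names = [v.name for v in variables]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate canonical variable name(s): {', '.join(dupes)}")
    return variables


def default_model_variables() -> list[CutoffVariable]:
    """The six retained dichotomized risk variables used by the rule models:
    Silva B+C, Silva C, >=3 cm, >=3.5 cm, DSI > 2/3, and >mild LVSI."""
    config = CutoffConfig(
        age_cuts=(),
        silva_variants=("BC", "C"),
        size_cuts=(3.0, 3.5),
        dsi_cuts=((2, 3),),
        lvsi_variants=("gt_mild",),
    )
    return make_cutoff_variables(config)


_FULL_REGISTRY: dict[str, CutoffVariable] = {
    v.name: v
    for v in make_cutoff_variables(
        CutoffConfig(
            age_cuts=(40.0, 50.0, 60.0),
            silva_variants=("BC", "C"),
            size_cuts=(2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0),
            dsi_cuts=((1, 3), (2, 3)),
            lvsi_variants=("ge_mild", "gt_mild"),
        )
    )
}


def variable_by_name(name: str) -> CutoffVariable:
    """Resolve a canonical variable name against the default registry."""
    try:
        return _FULL_REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown cutoff variable {name!r}") from None


def factor_value(record: PatientRecord, variable: CutoffVariable) -> bool:
    """Evaluate a dichotomized risk variable on one record."""
    return variable.evaluate(record)


# ---------------------------------------------------------------------------
# High-risk exclusion


def is_high_risk(record: PatientRecord) -> bool:
    """True iff the record carries any high-risk factor: nodal
    metastasis, positive surgical margin, or parametrial involvement."""
    return (
        record.ln_site != "none"
        or record.margin_positive
        or record.parametrial_positive
    )


def filter_intermediate(cohort: Cohort) -> Cohort:
    """Drop high-risk patients, keeping order; the intermediate-risk set."""
    kept = tuple(r for r in cohort if not is_high_risk(r))
    return Cohort(records=kept, label=cohort.label)
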