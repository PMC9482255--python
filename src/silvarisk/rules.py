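"""Executable clinical decision rules.

Two rule systems live here.  The Sedlis criteria are the established
trigger for adjuvant therapy in intermediate-risk cervical cancer,
combining LVSI, depth of stromal invasion in thirds, and tumor size.
The Silva-based k-of-m families generalize them: a model names a set
of dichotomized risk variables (one variant per factor) and declares a
patient positive when at least k of them are present.  The module
enumerates the three families exhaustively — 12 four-factor, 30
three-factor and 16 two-factor models under the default variant sets —
and renders each as a stable, parseable human-readable label.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .cohort import (
    Cohort,
    CutoffVariable,
    PatientRecord,
    dsi_third,
    factor_value,
    variable_by_name,
)

__all__ = [
    "RuleModel",
    "SedlisInput",
    "EnumerationConfig",
    "KOfMClassifier",
    "sedlis_positive",
    "sedlis_from_record",
    "enumerate_models",
    "enumerate_all_models",
    "apply_rule",
    "model_label",
    "parse_model_label",
]

FAMILIES = ("four_factor", "three_factor", "two_factor", "sedlis")

# Display names used in model labels, keyed by canonical variable name.
_DISPLAY = {
    "silva_BC": "Silva B+C",
    "silva_C": "Silva C",
    "size_ge_2": "≥2 cm",
    "size_ge_2.5": "≥2.5 cm",
    "size_ge_3": "≥3 cm",
    "size_ge_3.5": "≥3.5 cm",
    "size_ge_4": "≥4 cm",
    "size_ge_4.5": "≥4.5 cm",
    "size_ge_5": "≥5 cm",
    "dsi_gt_1_3": "DSI >1/3",
    "dsi_gt_2_3": "DSI >2/3",
    "lvsi_ge_mild": "≥mild LVSI",
    "lvsi_gt_mild": ">mild LVSI",
    "age_ge_40": "age ≥40",
    "age_ge_50": "age ≥50",
    "age_ge_60": "age ≥60",
}
_DISPLAY_INV = {v: k for k, v in _DISPLAY.items()}

_FACTOR_ORDER = {"silva": 0, "size": 1, "dsi": 2, "lvsi": 3, "age": 4}


def _variable_factor(name: str) -> str:
    return variable_by_name(name).factor


@dataclass(frozen=True)
class RuleModel:
    """A k-of-m decision rule over named cutoff variables."""

    model_id: str
    family: str
    variables: tuple[str, ...]
    k: int

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("model variables must be distinct")
        if not 1 <= self.k <= len(self.variables):
            raise ValueError(
                f"k must satisfy 1 <= k <= {len(self.variables)}, got {self.k}"
            )
        factors = [_variable_factor(v) for v in self.variables]
        if len(set(factors)) != len(factors):
            raise ValueError(
                "a model may use at most one variant per factor, got "
                + ", ".join(self.variables)
            )


@dataclass(frozen=True)
class SedlisInput:
    """The three Sedlis ingredients: any-LVSI flag, DSI third, size in cm."""

    lvsi_present: bool
    dsi_third: str  # none | superficial | middle | deep
    tumor_size: float

    def __post_init__(self) -> None:
        if self.dsi_third not in ("none", "superficial", "middle", "deep"):
            raise ValueError(f"unknown DSI third {self.dsi_third!r}")
        if self.tumor_size < 0:
            raise ValueError("tumor size must be non-negative")


def sedlis_positive(inp: SedlisInput) -> bool:
    """True iff any Sedlis clause holds:

    (a) LVSI and deep-third DSI;
    (b) LVSI, middle-third DSI and size >= 2 cm;
    (c) LVSI, superficial-third DSI and size >= 5 cm;
    (d) no LVSI, middle- or deep-third DSI and size >= 4 cm.

    A record with no stromal invasion never triggers.
    """
    third, size = inp.dsi_third, inp.tumor_size
    if inp.lvsi_present:
        if third == "deep":
            return True
        if third == "middle" and size >= 2.0:
            return True
        if third == "superficial" and size >= 5.0:
            return True
        return False
    return third in ("middle", "deep") and size >= 4.0


def sedlis_from_record(record: PatientRecord) -> SedlisInput:
    """Sedlis ingredients for a patient record; LVSI is any-grade
    (the criteria predate graded LVSI)."""
    return SedlisInput(
        lvsi_present=record.lvsi != "none",
        dsi_third=dsi_third(record),
        tumor_size=record.tumor_size,
    )


# ---------------------------------------------------------------------------
# Enumeration


@dataclass(frozen=True)
class EnumerationConfig:
    """Variant sets and per-family k ranges for model enumeration."""

    silva_variants: tuple[str, ...] = ("silva_BC", "silva_C")
    size_variants: tuple[str, ...] = ("size_ge_3", "size_ge_3.5")
    dsi_variants: tuple[str, ...] = ("dsi_gt_2_3",)
    lvsi_variants: tuple[str, ...] = ("lvsi_gt_mild",)
    k_ranges: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: {
            "four_factor": (2, 3, 4),
            "three_factor": (1, 2, 3),
            "two_factor": (1, 2),
        }
    )

    def variants_for(self, factor: str) -> tuple[str, ...]:
        return {
            "silva": self.silva_variants,
            "size": self.size_variants,
            "dsi": self.dsi_variants,
            "lvsi": self.lvsi_variants,
        }[factor]


def _sort_vars(names: tuple[str, ...]) -> tuple[str, ...]:
    return tuple(sorted(names, key=lambda n: _FACTOR_ORDER[_variable_factor(n)]))


def _make_model(family: str, names: tuple[str, ...], k: int) -> RuleModel:
    names = _sort_vars(names)
    model_id = f"{family}|{'+'.join(names)}|k{k}"
    return RuleModel(model_id=model_id, family=family, variables=names, k=k)


def enumerate_models(
    family: str, config: EnumerationConfig | None = None
) -> list[RuleModel]:
    """Exhaustively enumerate one model family in canonical order.

    four_factor: one variant for each of Silva/size/DSI/LVSI, k in
    {2,3,4}.  three_factor: Silva replaces exactly one of size/DSI/LVSI,
    k in {1,2,3}.  two_factor: Silva plus exactly one other factor, k in
    {1,2}.  The smaller families always contain a Silva variant (they
    are Silva-based by construction).
    """
    config = config or EnumerationConfig()
    if family not in ("four_factor", "three_factor", "two_factor"):
        raise ValueError(f"unknown enumerable family {family!r}")
    ks = config.k_ranges[family]
    models: list[RuleModel] = []
    if family == "four_factor":
        factor_sets = [("silva", "size", "dsi", "lvsi")]
    elif family == "three_factor":
        # Silva stands in for one replaced factor among size/DSI/LVSI
        factor_sets = [
            ("silva", "dsi", "lvsi"),   # replaces size
            ("silva", "size", "lvsi"),  # replaces DSI
            ("silva", "size", "dsi"),   # replaces LVSI
        ]
    else:
        factor_sets = [("silva", "size"), ("silva", "dsi"), ("silva", "lvsi")]
    for factors in factor_sets:
        variant_lists = [config.variants_for(f) for f in factors]
        for combo in itertools.product(*variant_lists):
            for k in ks:
                if k <= len(combo):
                    models.append(_make_model(family, tuple(combo), k))
    return models


def enumerate_all_models(config: EnumerationConfig | None = None) -> list[RuleModel]:
    """All three families, four-factor first."""
    out: list[RuleModel] = []
    for family in ("four_factor", "three_factor", "two_factor"):
        out.extend(enumerate_models(family, config))
    return out


# ---------------------------------------------------------------------------
# Application and labels


def apply_rule(model: RuleModel, record: PatientRecord) -> bool:
    """True iff at least k of the model's variables hold for the record."""
    count = 0
    for name in model.variables:
        try:
            var = variable_by_name(name)
        except KeyError as exc:
            raise ValueError(f"model {model.model_id}: {exc}") from None
        count += factor_value(record, var)
    return count >= model.k


def model_label(model: RuleModel) -> str:
    """Human-readable label, bijective with the model identity.

    "Any 3 of 4: Silva C, ≥3 cm, DSI >2/3, >mild LVSI"; all-of
    rules read "All 4: ...".
    """
    parts = ", ".join(_DISPLAY[v] for v in model.variables)
    m = len(model.variables)
    prefix = f"All {m}" if model.k == m else f"Any {model.k} of {m}"
    return f"{prefix}: {parts}"


def parse_model_label(label: str) -> RuleModel:
    """Inverse of :func:`model_label` (family inferred from the
    variable count; drill-down labels of other sizes are rejected)."""
    head, _, body = label.partition(": ")
    if not body:
        raise ValueError(f"malformed model label {label!r}")
    names = tuple(_DISPLAY_INV[p.strip()] for p in body.split(", "))
    m = len(names)
    if head.startswith("All "):
        k = int(head.removeprefix("All "))
        if k != m:
            raise ValueError(f"label head {head!r} disagrees with {m} variables")
    else:
        k_str, _, m_str = head.removeprefix("Any ").partition(" of ")
        k = int(k_str)
        if int(m_str) != m:
            raise ValueError(f"label head {head!r} disagrees with {m} variables")
    family = {4: "four_factor", 3: "three_factor", 2: "two_factor"}.get(m)
    if family is None:
        raise ValueError(f"cannot infer a family for {m} variables")
    return _make_model(family, names, k)


class KOfMClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn-style wrapper for a fixed k-of-m decision rule.

    The rule is not learned from data: ``fit`` only validates the
    configuration.  ``predict`` accepts a :class:`Cohort` or an
    iterable of :class:`PatientRecord` and returns a boolean array.
    """

    def __init__(self, variables: tuple[str, ...] = (), k: int = 1) -> None:
        self.variables = variables
        self.k = k

    def _model(self) -> RuleModel:
        n = len(self.variables)
        family = {4: "four_factor", 3: "three_factor", 2: "two_factor"}.get(
            n, "four_factor" if n else None
        )
        if family is None:
            raise ValueError("variables must be non-empty")
        return _make_model(family, tuple(self.variables), int(self.k))

    def fit(self, X=None, y=None) -> "KOfMClassifier":
        self.rule_ = self._model()
        self.classes_ = np.array([False, True])
        return self

    def predict(self, X: Cohort | list[PatientRecord]) -> np.ndarray:
        rule = getattr(self, "rule_", None) or self._model()
        return np.array([apply_rule(rule, r) for r in X], dtype=bool)
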