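"""Domain types for pairwise RCT comparisons and tabular readers/writers.

A treatment-regimen evidence network is assembled from two-arm randomized
controlled trial (RCT) comparisons.  Each comparison carries one or more
outcome records (an endpoint, its surrogacy class, a P value, and an effect
size); exactly one outcome per comparison enters the valuation algorithm,
chosen by :func:`select_outcome`.

Endpoints are weighted by surrogacy: an endpoint that directly measures
clinical benefit (overall survival) is *strong*; time-to-event surrogates
(progression-free survival) are *intermediate*; response-rate style markers
are *weak*.  The relative value (RV) attached to each class enters the
vertex valuation formula multiplicatively.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SurrogacyClass",
    "EffectMeasure",
    "FavoredArm",
    "RVTable",
    "OutcomeRecord",
    "TrialComparison",
    "SchemaError",
    "ValidationError",
    "EndpointLookupError",
    "DEFAULT_RV_WEIGHTS",
    "default_rv_table",
    "read_trials",
    "write_trials",
    "expand_multiarm",
    "select_outcome",
]


class SchemaError(ValueError):
    """A required column or field is missing from an input table."""


class ValidationError(ValueError):
    """A record violates a domain invariant (e.g. a P value outside (0, 1])."""


class EndpointLookupError(KeyError):
    """An endpoint name has no surrogacy-class entry in the RV table."""


class SurrogacyClass(enum.Enum):
    """Surrogacy class of an endpoint; lower ``order`` = less surrogate."""

    STRONG = 0
    INTERMEDIATE = 1
    WEAK = 2

    @property
    def order(self) -> int:
        """Surrogacy rank: STRONG (0) < INTERMEDIATE (1) < WEAK (2)."""
        return self.value


class EffectMeasure(enum.Enum):
    HAZARD_RATIO = "hazard_ratio"
    ODDS_RATIO = "odds_ratio"
    MEDIAN_RATIO = "median_ratio"
    POINT_ESTIMATE_RATIO = "point_estimate_ratio"
    NONINFERIORITY = "noninferiority"


class FavoredArm(enum.Enum):
    A = "A"
    B = "B"
    NONE = "NONE"


#: Default relative-value weight per surrogacy class.
DEFAULT_RV_WEIGHTS: Mapping[SurrogacyClass, float] = {
    SurrogacyClass.STRONG: 1.0,
    SurrogacyClass.INTERMEDIATE: 0.8,
    SurrogacyClass.WEAK: 0.7,
}

_DEFAULT_ENDPOINT_CLASSES: Mapping[str, SurrogacyClass] = {
    "overall survival": SurrogacyClass.STRONG,
    "os": SurrogacyClass.STRONG,
    "progression-free survival": SurrogacyClass.INTERMEDIATE,
    "pfs": SurrogacyClass.INTERMEDIATE,
    "event-free survival": SurrogacyClass.INTERMEDIATE,
    "efs": SurrogacyClass.INTERMEDIATE,
    "time to progression": SurrogacyClass.INTERMEDIATE,
    "overall response rate": SurrogacyClass.WEAK,
    "orr": SurrogacyClass.WEAK,
    "response rate": SurrogacyClass.WEAK,
    "complete response rate": SurrogacyClass.WEAK,
}


@dataclass(frozen=True)
class RVTable:
    """Maps endpoint names to surrogacy classes and classes to RV weights.

    Endpoint-name lookup is case-insensitive.  ``weights`` may be overridden
    (e.g. for the RV sensitivity analysis); each weight must lie in (0, 1].
    """

    classes: Mapping[str, SurrogacyClass] = field(
        default_factory=lambda: dict(_DEFAULT_ENDPOINT_CLASSES)
    )
    weights: Mapping[SurrogacyClass, float] = field(
        default_factory=lambda: dict(DEFAULT_RV_WEIGHTS)
    )

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "classes", {k.lower(): v for k, v in self.classes.items()}
        )
        for cls, w in self.weights.items():
            if not w > 0:
                raise ValidationError(f"RV weight for {cls.name} must be > 0, got {w}")

    def class_for(self, endpoint_name: str) -> SurrogacyClass:
        try:
            return self.classes[endpoint_name.lower()]
        except KeyError:
            raise EndpointLookupError(
                f"endpoint {endpoint_name!r} has no surrogacy-class entry in the RV table"
            ) from None

    def rv_for(self, endpoint_name: str) -> float:
        return self.weights[self.class_for(endpoint_name)]

    def scaled(self, factor: float, cap: float = 1.0) -> "RVTable":
        """Return a copy with every weight multiplied by ``factor`` (capped).

        RV is a relative weight with a defining maximum of 1.0, so upward
        perturbations are capped there.
        """
        if factor <= 0:
            raise ValidationError(f"RV scale factor must be > 0, got {factor}")
        new = {cls: min(w * factor, cap) for cls, w in self.weights.items()}
        return replace(self, weights=new)


def default_rv_table() -> RVTable:
    """RV table shipped by default (fully overridable via config)."""
    return RVTable()


@dataclass(frozen=True)
class OutcomeRecord:
    """One endpoint result of a pairwise comparison."""

    endpoint_name: str
    endpoint_class: SurrogacyClass
    rv: float
    p_value: float
    effect_measure: EffectMeasure
    effect_value: float
    is_primary: bool
    favored_arm: FavoredArm

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(
                f"p_value must be in (0, 1], got {self.p_value} "
                f"(endpoint {self.endpoint_name!r})"
            )
        if not self.effect_value > 0:
            raise ValidationError(
                f"effect_value must be > 0, got {self.effect_value} "
                f"(endpoint {self.endpoint_name!r})"
            )
        if not self.rv > 0:
            raise ValidationError(f"rv must be > 0, got {self.rv}")
        if (
            self.favored_arm is FavoredArm.NONE
            and self.effect_value != 1.0
            and self.effect_measure is not EffectMeasure.NONINFERIORITY
        ):
            raise ValidationError(
                f"favored_arm=NONE requires effect_value=1 or a noninferiority "
                f"outcome (endpoint {self.endpoint_name!r}, "
                f"effect_value={self.effect_value})"
            )


@dataclass(frozen=True)
class TrialComparison:
    """A dated two-regimen comparison with its outcomes and total N."""

    trial_id: str
    pub_year: int
    regimen_a: str
    regimen_b: str
    n_total: int
    outcomes: tuple[OutcomeRecord, ...]
    update_years: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "outcomes", tuple(self.outcomes))
        object.__setattr__(self, "update_years", tuple(self.update_years))
        if self.regimen_a == self.regimen_b:
            raise ValidationError(
                f"trial {self.trial_id!r}: regimen_a and regimen_b must differ"
            )
        if self.n_total < 2:
            raise ValidationError(
                f"trial {self.trial_id!r}: n_total must be >= 2, got {self.n_total}"
            )
        if not self.outcomes:
            raise ValidationError(f"trial {self.trial_id!r}: outcomes must be non-empty")
        if not any(o.is_primary for o in self.outcomes):
            raise ValidationError(
                f"trial {self.trial_id!r}: at least one outcome must be primary"
            )
        for y in self.update_years:
            if y < self.pub_year:
                raise ValidationError(
                    f"trial {self.trial_id!r}: update year {y} precedes "
                    f"publication year {self.pub_year}"
                )


def select_outcome(trial: TrialComparison) -> OutcomeRecord:
    """Select the single outcome that enters the valuation algorithm.

    Rule: among the predefined primary endpoints, take the least-surrogate
    one (ties broken by lowest P value, then input order).  If that primary
    is met (P <= .05) and a *strictly* less-surrogate secondary endpoint has
    marginal or better significance (P <= .10), substitute the secondary;
    the least-surrogate such secondary wins.  If the primary is not met, the
    primary is used regardless of any significant secondary.
    """
    primaries = [(i, o) for i, o in enumerate(trial.outcomes) if o.is_primary]
    if not primaries:
        raise ValidationError(f"trial {trial.trial_id!r} has no primary outcome")
    idx, primary = min(
        primaries, key=lambda t: (t[1].endpoint_class.order, t[1].p_value, t[0])
    )
    if primary.p_value <= 0.05:
        candidates = [
            (i, o)
            for i, o in enumerate(trial.outcomes)
            if not o.is_primary
            and o.endpoint_class.order < primary.endpoint_class.order
            and o.p_value <= 0.10
        ]
        if candidates:
            _, best = min(
                candidates, key=lambda t: (t[1].endpoint_class.order, t[1].p_value, t[0])
            )
            return best
    return primary


def expand_multiarm(
    trial_id: str,
    pub_year: int,
    arms: Sequence[tuple[str, int]],
    pair_outcomes: Mapping[tuple[str, str], Sequence[OutcomeRecord]],
    update_years: Sequence[int] = (),
) -> list[TrialComparison]:
    """Expand a multi-arm trial into pairwise comparisons.

    The valuation formula is defined over pairwise comparisons only, so a
    trial with k arms contributes one comparison per *reported* pair; each
    comparison's ``n_total`` is the sum of its two arms' sample sizes.
    Pair ``(a, b)`` keeps a/b as regimen_a/regimen_b, so outcome
    ``favored_arm`` labels refer to that orientation.
    """
    if len(arms) < 2:
        raise ValidationError(f"trial {trial_id!r}: need >= 2 arms, got {len(arms)}")
    sizes = dict(arms)
    if len(sizes) != len(arms):
        raise ValidationError(f"trial {trial_id!r}: duplicate arm labels")
    comparisons = []
    for (a, b), outcomes in pair_outcomes.items():
        for arm in (a, b):
            if arm not in sizes:
                raise ValidationError(
                    f"trial {trial_id!r}: pair ({a}, {b}) references unknown arm {arm!r}"
                )
        comparisons.append(
            TrialComparison(
                trial_id=f"{trial_id}:{a}-vs-{b}" if len(pair_outcomes) > 1 else trial_id,
                pub_year=pub_year,
                regimen_a=a,
                regimen_b=b,
                n_total=sizes[a] + sizes[b],
                outcomes=tuple(outcomes),
                update_years=tuple(update_years),
            )
        )
    return comparisons


# --- tabular I/O ------------------------------------------------------------

CSV_COLUMNS = [
    "trial_id",
    "pub_year",
    "update_years",
    "regimen_a",
    "regimen_b",
    "n_total",
    "endpoint",
    "p_value",
    "effect_measure",
    "effect_value",
    "is_primary",
    "favored_arm",
]

_TRUE_STRINGS = {"true", "1", "yes", "y", "t"}


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in _TRUE_STRINGS


def _parse_update_years(value) -> tuple[int, ...]:
    if value is None:
        return ()
    if isinstance(value, (list, tuple)):
        return tuple(int(v) for v in value)
    s = str(value).strip()
    if not s or s.lower() == "nan":
        return ()
    return tuple(int(tok) for tok in s.replace(";", "|").split("|") if tok.strip())


def _make_outcome(row: Mapping, rv_table: RVTable, trial_id: str) -> OutcomeRecord:
    name = str(row["endpoint"])
    cls = rv_table.class_for(name)
    try:
        measure = EffectMeasure(str(row["effect_measure"]).strip().lower())
    except ValueError:
        raise ValidationError(
            f"trial {trial_id!r}: unknown effect_measure {row['effect_measure']!r}"
        ) from None
    favored = str(row["favored_arm"]).strip().upper() or "NONE"
    try:
        favored_arm = FavoredArm(favored)
    except ValueError:
        raise ValidationError(
            f"trial {trial_id!r}: favored_arm must be A, B, or NONE, got {favored!r}"
        ) from None
    try:
        return OutcomeRecord(
            endpoint_name=name,
            endpoint_class=cls,
            rv=rv_table.rv_for(name),
            p_value=float(row["p_value"]),
            effect_measure=measure,
            effect_value=float(row["effect_value"]),
            is_primary=_parse_bool(row["is_primary"]),
            favored_arm=favored_arm,
        )
    except ValidationError as exc:
        raise ValidationError(f"trial {trial_id!r}: {exc}") from None


def read_trials(
    path: str | Path,
    fmt: str | None = None,
    rv_table: RVTable | None = None,
) -> list[TrialComparison]:
    """Load validated comparisons from CSV or JSON.

    CSV: UTF-8, comma-separated, header row required, one outcome per row
    with the trial-level fields repeated (see :data:`CSV_COLUMNS`).
    JSON: a list of objects, one per trial, each with a nested ``outcomes``
    array.  ``fmt`` defaults to the file extension.
    """
    path = Path(path)
    rv_table = rv_table or default_rv_table()
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    fmt = fmt.lower()
    if fmt == "csv":
        return _read_csv(path, rv_table)
    if fmt == "json":
        return _read_json(path, rv_table)
    raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'json'")


def _read_csv(path: Path, rv_table: RVTable) -> list[TrialComparison]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    trials: list[TrialComparison] = []
    for trial_id, group in df.groupby("trial_id", sort=False):
        head = group.iloc[0]
        outcomes = tuple(
            _make_outcome(row, rv_table, str(trial_id)) for _, row in group.iterrows()
        )
        trials.append(
            TrialComparison(
                trial_id=str(trial_id),
                pub_year=int(head["pub_year"]),
                regimen_a=str(head["regimen_a"]),
                regimen_b=str(head["regimen_b"]),
                n_total=int(head["n_total"]),
                outcomes=outcomes,
                update_years=_parse_update_years(head["update_years"]),
            )
        )
    return trials


_JSON_TRIAL_FIELDS = ["trial_id", "pub_year", "regimen_a", "regimen_b", "n_total", "outcomes"]
_JSON_OUTCOME_FIELDS = ["endpoint", "p_value", "effect_measure", "effect_value", "is_primary", "favored_arm"]


def _read_json(path: Path, rv_table: RVTable) -> list[TrialComparison]:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise SchemaError("JSON input must be a list of trial objects")
    trials = []
    for obj in raw:
        for f in _JSON_TRIAL_FIELDS:
            if f not in obj:
                raise SchemaError(f"trial object missing required field {f!r}")
        outcomes = []
        for rec in obj["outcomes"]:
            for f in _JSON_OUTCOME_FIELDS:
                if f not in rec:
                    raise SchemaError(
                        f"trial {obj['trial_id']!r}: outcome missing required field {f!r}"
                    )
            outcomes.append(_make_outcome(rec, rv_table, str(obj["trial_id"])))
        trials.append(
            TrialComparison(
                trial_id=str(obj["trial_id"]),
                pub_year=int(obj["pub_year"]),
                regimen_a=str(obj["regimen_a"]),
                regimen_b=str(obj["regimen_b"]),
                n_total=int(obj["n_total"]),
                outcomes=tuple(outcomes),
                update_years=_parse_update_years(obj.get("update_years")),
            )
        )
    return trials


def write_trials(
    trials: Iterable[TrialComparison], path: str | Path, fmt: str | None = None
) -> None:
    """Write comparisons back to the CSV or JSON schema (round-trip safe)."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    fmt = fmt.lower()
    if fmt == "csv":
        rows = []
        for t in trials:
            for o in t.outcomes:
                rows.append(
                    {
                        "trial_id": t.trial_id,
                        "pub_year": t.pub_year,
                        "update_years": "|".join(str(y) for y in t.update_years),
                        "regimen_a": t.regimen_a,
                        "regimen_b": t.regimen_b,
                        "n_total": t.n_total,
                        "endpoint": o.endpoint_name,
                        "p_value": repr(o.p_value),
                        "effect_measure": o.effect_measure.value,
                        "effect_value": repr(o.effect_value),
                        "is_primary": o.is_primary,
                        "favored_arm": o.favored_arm.value,
                    }
                )
        pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)
    elif fmt == "json":
        objs = []
        for t in trials:
            objs.append(
                {
                    "trial_id": t.trial_id,
                    "pub_year": t.pub_year,
                    "update_years": list(t.update_years),
                    "regimen_a": t.regimen_a,
                    "regimen_b": t.regimen_b,
                    "n_total": t.n_total,
                    "outcomes": [
                        {
                            "endpoint": o.endpoint_name,
                            "p_value": o.p_value,
                            "effect_measure": o.effect_measure.value,
                            "effect_value": o.effect_value,
                            "is_primary": o.is_primary,
                            "favored_arm": o.favored_arm.value,
                        }
                        for o in t.outcomes
                    ],
                }
            )
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(objs, fh, indent=1)
    else:
        raise ValueError(f"unknown format {fmt!r}")
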