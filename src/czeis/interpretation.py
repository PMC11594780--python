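"""Flagging of index panels against reference intervals and pattern calls.

Each of the ten index values is flagged low / normal / high against its
reference interval (strict comparisons at full precision; an undefined light
chain index is flagged ``undefined``).  A data-driven rule table then maps
the ten flags to one overall pattern:

* ``suspect_monoclonal`` — a high sharpness index, or a light chain index
  outside its interval (or undefined), in either zone: the signature of a
  narrow clonal spike or a skewed kappa/lambda balance.
* ``polyclonal`` — some immunoglobulin index high without any monoclonal
  trigger (no high/undefined sharpness, light chain in range): diffuse
  hypergammaglobulinemia.
* ``hypogammaglobulinemia`` — some immunoglobulin index low with everything
  else normal.
* ``normal`` — all ten flags normal.
* ``mixed_other`` — any combination not covered above.

Patterns are evaluated in precedence order (monoclonal suspicion first, for
screening sensitivity).  The rule table ships as editable YAML
(``czeis/data/rules.yaml``) so laboratories can adjust triggers and
precedence without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .graphic_indexes import EVAL_ZONES, INDEX_NAMES, IndexPanel, UndefinedIndex
from .reference_interval import ReferenceInterval

__all__ = [
    "FLAGS",
    "CaseInterpretation",
    "MissingIntervalError",
    "default_rules",
    "load_rules",
    "flag_panel",
    "interpret",
    "interpret_panel",
]

FLAGS = ("low", "normal", "high", "undefined")

FlagMap = Mapping[tuple[str, str], str]  # (index, zone) -> flag


class MissingIntervalError(KeyError):
    """Raised when a defined panel value has no reference interval."""


@dataclass(frozen=True)
class CaseInterpretation:
    case_id: str
    pattern: str
    flags: dict[tuple[str, str], str]
    rationale: tuple[str, ...] = ()
    values: dict[tuple[str, str], float | None] = field(default_factory=dict)
    intervals: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)


def default_rules() -> dict:
    """The packaged rule table (deep copy, safe to edit)."""
    text = resources.files("czeis").joinpath("data/rules.yaml").read_text()
    return yaml.safe_load(text)


def load_rules(path: str | Path) -> dict:
    """Load a rule table from a YAML file."""
    return yaml.safe_load(Path(path).read_text())


def flag_panel(
    panel: IndexPanel, ris: Mapping[tuple[str, str], ReferenceInterval]
) -> dict[tuple[str, str], str]:
    """Flag every index/zone value against its interval.

    Strict comparisons: a value exactly equal to a limit is normal.  Raises
    :class:`MissingIntervalError` when a defined value has no interval.
    """
    flags: dict[tuple[str, str], str] = {}
    for zone in EVAL_ZONES:
        for index in INDEX_NAMES:
            value = panel.value(index, zone)
            if isinstance(value, UndefinedIndex) or value is None:
                flags[(index, zone)] = "undefined"
                continue
            key = (index, zone)
            if key not in ris:
                raise MissingIntervalError(
                    f"no reference interval for {index} in {zone}"
                )
            ri = ris[key]
            if value < ri.lower:
                flags[key] = "low"
            elif value > ri.upper:
                flags[key] = "high"
            else:
                flags[key] = "normal"
    return flags


def _trigger_hits(trigger: Mapping, flags: FlagMap) -> list[tuple[str, str, str]]:
    index = trigger["index"]
    wanted = set(trigger["flags"])
    return [
        (index, zone, flags[(index, zone)])
        for zone in EVAL_ZONES
        if flags.get((index, zone)) in wanted
    ]


def _matches(pattern_spec: Mapping, flags: FlagMap) -> tuple[bool, list[str]]:
    rationale: list[str] = []
    for name in pattern_spec.get("require_normal", []):
        for zone in EVAL_ZONES:
            if flags.get((name, zone)) != "normal":
                return False, []
    for trigger in pattern_spec.get("forbid", []):
        if _trigger_hits(trigger, flags):
            return False, []
    any_triggers = pattern_spec.get("any")
    if any_triggers:
        hits = [h for trig in any_triggers for h in _trigger_hits(trig, flags)]
        if not hits:
            return False, []
        rationale = [f"{zone} {index} {flag}" for index, zone, flag in hits]
    return True, rationale


def interpret(
    flags: FlagMap, rules: Mapping | None = None, case_id: str = ""
) -> CaseInterpretation:
    """Map a complete set of ten flags to a pattern call.

    Deterministic and total over the flag space: any combination not matched
    by a pattern falls back to ``mixed_other`` with the abnormal flags as
    rationale.
    """
    rules = rules or default_rules()
    for missing in (
        (index, zone)
        for zone in EVAL_ZONES
        for index in INDEX_NAMES
        if (index, zone) not in flags
    ):
        raise ValueError(f"incomplete flag set: missing {missing}")
    for pattern in rules["precedence"]:
        ok, rationale = _matches(rules["patterns"][pattern], flags)
        if ok:
            if pattern == "normal" and not rationale:
                rationale = ["all indexes within reference intervals"]
            return CaseInterpretation(
                case_id=case_id,
                pattern=pattern,
                flags=dict(flags),
                rationale=tuple(rationale),
            )
    abnormal = [
        f"{zone} {index} {flag}"
        for (index, zone), flag in flags.items()
        if flag != "normal"
    ]
    return CaseInterpretation(
        case_id=case_id,
        pattern=rules.get("fallback", "mixed_other"),
        flags=dict(flags),
        rationale=tuple(abnormal) or ("no pattern matched",),
    )


def interpret_panel(
    panel: IndexPanel,
    ris: Mapping[tuple[str, str], ReferenceInterval],
    rules: Mapping | None = None,
) -> CaseInterpretation:
    """Convenience: flag a panel and interpret it, carrying values and
    intervals along for reporting."""
    flags = flag_panel(panel, ris)
    call = interpret(flags, rules=rules, case_id=panel.case_id)
    values = {}
    intervals = {}
    for key, flag in flags.items():
        index, zone = key
        v = panel.value(index, zone)
        values[key] = None if isinstance(v, UndefinedIndex) else float(v)
        if key in ris:
            intervals[key] = (ris[key].lower, ris[key].upper)
    return CaseInterpretation(
        case_id=call.case_id,
        pattern=call.pattern,
        flags=call.flags,
        rationale=call.rationale,
        values=values,
        intervals=intervals,
    )


def ris_by_key(ris) -> dict[tuple[str, str], ReferenceInterval]:
    """Index a collection of reference intervals by (index name, zone)."""
    return {(ri.name, ri.zone): ri for ri in ris}
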