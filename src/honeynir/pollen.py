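"""Melissopalynological typing: pollen frequency classes and rule-based
assignment of botanical honey type from pollen percentages (plus optional
electrical conductivity for honeydew)."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
import warnings

import pandas as pd


class PollenError(ValueError):
    """Invalid pollen profile or typing rules."""


class FrequencyClass(str, Enum):
    PREDOMINANT = "predominant"        # > 45 %
    SECONDARY = "secondary"            # 15 - 45 %
    IMPORTANT_MINOR = "important_minor"  # 3 - < 15 %
    MINOR = "minor"                    # < 3 %


def frequency_class(pct: float) -> FrequencyClass:
    """Classical pollen frequency class for a percentage of counted grains.

    Boundaries are closed on the lower side: >45 predominant, [15, 45]
    secondary, [3, 15) important minor, [0, 3) minor.
    """
    if not 0 <= pct <= 100:
        raise PollenError(f"pollen percentage out of [0, 100]: {pct}")
    if pct > 45:
        return FrequencyClass.PREDOMINANT
    if pct >= 15:
        return FrequencyClass.SECONDARY
    if pct >= 3:
        return FrequencyClass.IMPORTANT_MINOR
    return FrequencyClass.MINOR


@dataclass
class PollenProfile:
    percentages: dict[str, float]
    tolerance: float = 0.5

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.percentages.values()):
            raise PollenError("pollen percentages must be non-negative")
        total = sum(self.percentages.values())
        if abs(total - 100.0) > self.tolerance:
            raise PollenError(
                f"pollen percentages sum to {total:.2f}, expected 100 "
                f"+/- {self.tolerance}")

    def get(self, taxon: str) -> float | None:
        return self.percentages.get(taxon)


@dataclass(frozen=True)
class UnifloralRule:
    honey_type: str
    taxon: str
    min_pct: float
    min_ec: float | None = None   # mS/cm; honeydew stand-in rule
    max_pct: float | None = None  # excludes an over-represented competitor

    def __post_init__(self):
        if not 0 < self.min_pct <= 100:
            raise PollenError(f"threshold for {self.honey_type} not in (0, 100]")


@dataclass
class TypingRules:
    """Ordered unifloral rules; first match wins, default is multifloral.

    Default thresholds encode under-represented taxa first (heather's
    *Erica* fires before chestnut's *Castanea*); the honeydew rule —
    predominant *Castanea* below the chestnut cutoff plus high electrical
    conductivity — is an operational stand-in, not an official criterion.
    """

    rules: list[UnifloralRule] = field(default_factory=lambda: [
        UnifloralRule("heather", "Erica", 35.0),
        UnifloralRule("eucalyptus", "Eucalyptus", 70.0),
        UnifloralRule("blackberry", "Rubus", 45.0),
        UnifloralRule("chestnut", "Castanea", 70.0),
        UnifloralRule("honeydew", "Castanea", 45.0, min_ec=0.8, max_pct=70.0),
    ])
    default_type: str = "multifloral"

    @property
    def honey_types(self) -> list[str]:
        return [r.honey_type for r in self.rules] + [self.default_type]


@dataclass
class TypingTrace:
    honey_type: str
    rule: UnifloralRule | None
    pct: float | None
    note: str


def assign_honey_type(profile: PollenProfile, ec: float | None = None,
                      rules: TypingRules | None = None) -> TypingTrace:
    """Assign a botanical honey type; deterministic, with a rule trace.

    ``ec`` is electrical conductivity in mS/cm (only honeydew-style rules
    consult it). Rules naming taxa absent from the profile are skipped with
    a warning.
    """
    rules = rules or TypingRules()
    for rule in rules.rules:
        pct = profile.get(rule.taxon)
        if pct is None:
            warnings.warn(
                f"rule for {rule.honey_type!r} references absent taxon "
                f"{rule.taxon!r}; skipped", stacklevel=2)
            continue
        if pct < rule.min_pct:
            continue
        if rule.max_pct is not None and pct >= rule.max_pct:
            continue
        if rule.min_ec is not None:
            if ec is None or ec < rule.min_ec:
                continue
            note = (f"{rule.taxon} {pct:.1f}% >= {rule.min_pct}% and "
                    f"EC {ec:.2f} >= {rule.min_ec} mS/cm")
        else:
            note = f"{rule.taxon} {pct:.1f}% >= {rule.min_pct}%"
        return TypingTrace(rule.honey_type, rule, pct, note)
    return TypingTrace(rules.default_type, None, None, "no unifloral rule matched")


def type_table(pollen: pd.DataFrame, ec: pd.Series | None = None,
               rules: TypingRules | None = None) -> pd.DataFrame:
    """Type every row of a wide pollen table (index = sample ids)."""
    rows = []
    for sid, row in pollen.iterrows():
        profile = PollenProfile({str(k): float(v) for k, v in row.items()})
        ec_val = float(ec.loc[sid]) if ec is not None else None
        trace = assign_honey_type(profile, ec=ec_val, rules=rules)
        rows.append({"sample_id": sid, "honey_type": trace.honey_type,
                     "rule_note": trace.note})
    return pd.DataFrame(rows).set_index("sample_id")
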