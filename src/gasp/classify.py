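"""Rule-based primary-specificity classification from S1 triplets.

The classifier is a deterministic lookup: a literal triplet table is
consulted first (consensus and putative assignments for the known
enzyme groups), then a fallback keyed on position 189 alone (Asp →
tryptase, Ser → chymase, both putative), since 189 dominates primary
specificity while 226 is secondary and 216 least informative.  A broken
catalytic triad overrides everything: the protein is proteolytically
inactive and its triplet carries no significance.  Incomplete triplets
(containing ``-``) are never classified.

Precedence: inactive > literal rule > position-189 fallback > unassigned.

The packaged rule table (``data/specificity_rules.yaml``) can be
replaced or extended by the user via :func:`load_rules`.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from gasp.errors import InputError
from gasp.features import SpecificityProfile
from gasp.numbering import AMINO_ACIDS

logger = logging.getLogger(__name__)

LABELS = {
    "tryptase",
    "chymase",
    "asp-ase",
    "met-ase",
    "elastase",
    "chymase_with_tryptase",
    "unknown",
}
TIERS = {"exact", "putative", "inactive", "unassigned"}

_TRIPLET_ALPHABET = set(AMINO_ACIDS) | {"-", "X"}


@dataclass(frozen=True)
class SpecificityRule:
    """One classification rule: a literal triplet or a position-189 key."""

    pattern: str  # 3-letter triplet, or 1 letter for a position-189 rule
    label: str
    tier: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise InputError(f"unknown label {self.label!r}")
        if self.tier not in TIERS:
            raise InputError(f"unknown tier {self.tier!r}")
        if len(self.pattern) not in (1, 3):
            raise InputError(f"rule pattern must be 1 or 3 letters: {self.pattern!r}")


@dataclass(frozen=True)
class RuleTable:
    """The classifier's rule set: literal triplets + position-189 fallback."""

    triplets: Mapping[str, SpecificityRule]
    position_189: Mapping[str, SpecificityRule]


@dataclass(frozen=True)
class Classification:
    """Outcome of classifying one triplet."""

    label: str
    tier: str
    matched_rule: str | None


def load_rules(path: str | Path | None = None) -> RuleTable:
    """Load a rule table from YAML (packaged default when ``path`` is None)."""
    if path is None:
        text = (resources.files("gasp") / "data" / "specificity_rules.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    triplets = {
        trip: SpecificityRule(pattern=trip, label=spec["label"], tier=spec["tier"])
        for trip, spec in raw.get("triplets", {}).items()
    }
    fallback = {
        res: SpecificityRule(pattern=res, label=spec["label"], tier=spec["tier"])
        for res, spec in raw.get("position_189", {}).items()
    }
    return RuleTable(triplets=triplets, position_189=fallback)


_DEFAULT_RULES: RuleTable | None = None


def default_rules() -> RuleTable:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_rules()
    return _DEFAULT_RULES


def classify_triplet(
    triplet: str,
    triad_intact: bool,
    rules: RuleTable | None = None,
) -> Classification:
    """Classify one S1 triplet.

    Raises
    ------
    InputError
        Triplet not of length 3 or containing an illegal character.
    """
    if len(triplet) != 3:
        raise InputError(f"triplet must have length 3, got {triplet!r}")
    for ch in triplet:
        if ch not in _TRIPLET_ALPHABET:
            raise InputError(f"illegal triplet character {ch!r} in {triplet!r}")
    rules = rules or default_rules()

    if not triad_intact:
        return Classification(label="unknown", tier="inactive", matched_rule=None)
    if "-" in triplet:
        return Classification(label="unknown", tier="unassigned", matched_rule=None)
    hit = rules.triplets.get(triplet)
    if hit is not None:
        return Classification(label=hit.label, tier=hit.tier, matched_rule=hit.pattern)
    fallback = rules.position_189.get(triplet[0])
    if fallback is not None:
        return Classification(
            label=fallback.label, tier=fallback.tier, matched_rule=f"189:{fallback.pattern}"
        )
    return Classification(label="unknown", tier="unassigned", matched_rule=None)


def classify_batch(
    profiles: Iterable[SpecificityProfile],
    rules: RuleTable | None = None,
) -> pd.DataFrame:
    """Classify a sequence of feature profiles, order preserved.

    Returns a DataFrame with one row per profile and logs summary
    counts per label.
    """
    rules = rules or default_rules()
    rows = []
    for prof in profiles:
        cls = classify_triplet(prof.triplet, prof.triad_intact, rules)
        rows.append(
            {
                "seq_id": prof.seq_id,
                "triplet": prof.triplet,
                "triad_intact": prof.triad_intact,
                "cys93": prof.has_cys93,
                "bridge_191_220": prof.has_bridge_191_220,
                "oligomer_call": prof.oligomer_call,
                "label": cls.label,
                "tier": cls.tier,
                "matched_rule": cls.matched_rule,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "seq_id",
            "triplet",
            "triad_intact",
            "cys93",
            "bridge_191_220",
            "oligomer_call",
            "label",
            "tier",
            "matched_rule",
        ],
    )
    counts = Counter(table["label"]) if len(table) else Counter()
    logger.info("classified %d profiles: %s", len(table), dict(sorted(counts.items())))
    return table
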