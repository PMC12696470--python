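"""Reference fixtures: the nine-cultivar benchmark orderings.

These are the published composite (membership-function) and TOPSIS
orderings of nine soybean cultivars evaluated under combined NaCl/NaHCO3
stress, used here as a concordance fixture: the two orderings differ only
in that the cultivars in second and third place are exchanged. The raw
physiological measurements behind them are not redistributable, so only the
orderings and the composite scores are carried as data.
"""

from __future__ import annotations

# Composite membership-function ordering, most to least tolerant.
MEMBERSHIP_ORDER: tuple[str, ...] = (
    "JD1", "CD32", "QN52", "TQ1", "TD5", "TD15", "JD46", "JD49", "QN54",
)

# Composite membership scores U_i in the same order.
MEMBERSHIP_SCORES: dict[str, float] = {
    "JD1": 0.76,
    "CD32": 0.64,
    "QN52": 0.49,
    "TQ1": 0.41,
    "TD5": 0.27,
    "TD15": 0.25,
    "JD46": 0.19,
    "JD49": 0.10,
    "QN54": 0.04,
}

# TOPSIS relative-closeness ordering of the same cultivars.
TOPSIS_ORDER: tuple[str, ...] = (
    "JD1", "QN52", "CD32", "TQ1", "TD5", "TD15", "JD46", "JD49", "QN54",
)

# The seven physiological indicators with their effect directions:
# larger change rates of the five positive indicators, and smaller change
# rates of MDA and Pro, indicate stronger saline-alkaline tolerance.
INDICATOR_DIRECTIONS: dict[str, str] = {
    "SOD": "positive",
    "CAT": "positive",
    "POD": "positive",
    "SP": "positive",
    "AOC": "positive",
    "MDA": "negative",
    "Pro": "negative",
}
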