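"""Threshold-based fusion calling over chimeric-evidence tables.

Discordant-mate counts ride along for reporting and candidate context, but
positivity is decided by junction-spanning reads alone against a single
inclusive threshold (default 16).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from panelval.errors import ParameterError
from panelval.synthetic import ChimericEvidence, FusionTruth

__all__ = [
    "FusionCall",
    "DEFAULT_MIN_SPANNING",
    "call_fusions",
    "replicate_detection",
]

DEFAULT_MIN_SPANNING = 16

TIER_ACTIONABLE = "actionable"
TIER_SECONDARY = "secondary"


@dataclass(frozen=True)
class FusionCall:
    gene5: str
    gene3: str
    n_spanning: int
    n_discordant: int
    tier: str
    reported: bool

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.gene5, self.gene3))


def _normalize_pairs(pairs: Iterable) -> set[frozenset[str]]:
    out = set()
    for p in pairs:
        fs = frozenset(p)
        if len(fs) != 2:
            raise ParameterError(f"actionable pair {p!r} is not a pair of two genes")
        out.add(fs)
    return out


def call_fusions(
    evidence: Sequence[ChimericEvidence],
    actionable_pairs: Iterable = (),
    min_spanning: int = DEFAULT_MIN_SPANNING,
) -> list[FusionCall]:
    """One call per evidence row; reported iff spanning reads reach threshold.

    Tier matching is on the unordered gene pair; 5'/3' orientation is
    preserved for display. Output is sorted by descending spanning support,
    then lexicographically — identical evidence always yields identical
    ordered output.
    """
    if min_spanning < 1:
        raise ParameterError("min_spanning must be >= 1")
    actionable = _normalize_pairs(actionable_pairs)
    calls = [
        FusionCall(
            gene5=e.gene5,
            gene3=e.gene3,
            n_spanning=e.n_spanning,
            n_discordant=e.n_discordant,
            tier=TIER_ACTIONABLE if e.pair in actionable else TIER_SECONDARY,
            reported=e.n_spanning >= min_spanning,
        )
        for e in evidence
    ]
    calls.sort(key=lambda c: (-c.n_spanning, c.gene5, c.gene3))
    return calls


def replicate_detection(
    replicates: Sequence[Sequence[ChimericEvidence]],
    truth: Sequence[FusionTruth],
    actionable_pairs: Iterable = (),
    min_spanning: int = DEFAULT_MIN_SPANNING,
) -> dict[frozenset[str], int]:
    """Per truth fusion, in how many replicate libraries it is reported."""
    if not replicates:
        raise ParameterError("need at least one replicate")
    counts = {t.pair: 0 for t in truth}
    for table in replicates:
        reported = {
            c.pair for c in call_fusions(table, actionable_pairs, min_spanning) if c.reported
        }
        for pair in counts:
            if pair in reported:
                counts[pair] += 1
    return counts
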