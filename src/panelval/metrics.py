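"""Confusion-matrix construction and validation statistics.

This is the arithmetic layer behind every rate in a validation report:
event matching (SNV/indel by genomic identity, CNV by gene and verdict class,
fusions by unordered gene pair), sensitivity / PPV / specificity with explicit
zero-denominator errors, VAF concordance, and per-titer summaries.

Presentation helpers round half-up (0.984375 -> "98.4%"), never banker's.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from panelval.cnv import VERDICT_NORMAL, CnvCall
from panelval.errors import ParameterError, UndefinedMetricError
from panelval.fusion import FusionCall
from panelval.somatic import VariantCall
from panelval.synthetic import CnvTruth, FusionTruth, TruthVariant

__all__ = [
    "ConfusionCounts",
    "ConcordancePair",
    "TiterResult",
    "match_events",
    "sensitivity",
    "ppv",
    "specificity",
    "round_rate",
    "format_percent",
    "vaf_concordance",
    "titration_summary",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    context: str = ""

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ParameterError("confusion counts must be >= 0")


@dataclass(frozen=True)
class ConcordancePair:
    """One event measured by two laboratories/runs."""

    event: str
    vaf_a: float
    vaf_b: float

    def __post_init__(self) -> None:
        if not (0 <= self.vaf_a <= 1 and 0 <= self.vaf_b <= 1):
            raise ParameterError(f"{self.event}: VAFs must lie in [0, 1]")


@dataclass(frozen=True)
class TiterResult:
    titer: float
    counts: ConfusionCounts
    ppv: float
    sensitivity: float


# ---------------------------------------------------------------------------
# Event matching
# ---------------------------------------------------------------------------

_CNV_EVENT_TO_VERDICT = {
    "amplification": "amplified",
    "homozygous_deletion": "homozygous_deletion",
}


def match_events(
    calls: Sequence,
    truth: Sequence,
    mode: str,
    negatives: Iterable | None = None,
    context: str = "",
) -> ConfusionCounts:
    """Tally TP/FP/FN (and TN where a negative universe exists).

    Identity per mode: ``snv_indel`` — (contig, pos, ref, alt); ``cnv`` —
    (gene, verdict class); ``fusion`` — unordered gene pair. Only *reported*
    calls participate. For cnv/fusion an explicit ``negatives`` universe
    (gene ids / gene pairs assayed and expected negative) defines tn; for
    snv_indel tn is 0 (the negative universe of a sequencing panel is not
    enumerable at event granularity).
    """
    if mode == "snv_indel":
        truth_keys = {t.key for t in truth}
        call_keys = {c.key for c in calls if c.reported}
        tp = len(truth_keys & call_keys)
        return ConfusionCounts(
            tp=tp,
            fp=len(call_keys - truth_keys),
            fn=len(truth_keys - call_keys),
            tn=0,
            context=context,
        )
    if mode == "cnv":
        truth_map = {
            t.gene_id: _CNV_EVENT_TO_VERDICT[t.event]
            for t in truth
            if t.event in _CNV_EVENT_TO_VERDICT
        }
        call_map = {c.gene_id: c.verdict for c in calls if c.reported}
        tp = sum(1 for g, v in truth_map.items() if call_map.get(g) == v)
        fn = len(truth_map) - tp
        fp = sum(1 for g in call_map if call_map[g] != truth_map.get(g))
        neg = set(negatives or ())
        tn = sum(1 for g in neg if g not in call_map)
        return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn, context=context)
    if mode == "fusion":
        truth_pairs = {t.pair for t in truth}
        call_pairs = {c.pair for c in calls if c.reported}
        tp = len(truth_pairs & call_pairs)
        neg = {frozenset(p) for p in (negatives or ())}
        return ConfusionCounts(
            tp=tp,
            fp=len(call_pairs - truth_pairs),
            fn=len(truth_pairs - call_pairs),
            tn=len(neg - call_pairs),
            context=context,
        )
    raise ParameterError(f"unknown matching mode {mode!r}")


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------


def _rate(num: int, den: int, name: str) -> float:
    if den == 0:
        raise UndefinedMetricError(f"{name} undefined: denominator is zero")
    return num / den


def sensitivity(counts: ConfusionCounts) -> float:
    """tp / (tp + fn)."""
    return _rate(counts.tp, counts.tp + counts.fn, "sensitivity")


def ppv(counts: ConfusionCounts) -> float:
    """tp / (tp + fp)."""
    return _rate(counts.tp, counts.tp + counts.fp, "PPV")


def specificity(counts: ConfusionCounts) -> float:
    """tn / (tn + fp)."""
    return _rate(counts.tn, counts.tn + counts.fp, "specificity")


def round_rate(x: float, ndigits: int = 2) -> float:
    """Half-up decimal rounding of a rate (0.984375 -> 0.98, 0.945 -> 0.95)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(x: float, ndigits: int = 1) -> str:
    """Half-up percentage formatting (0.984375 -> '98.4%')."""
    return f"{round_rate(100 * x, ndigits):.{ndigits}f}%"


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------


def vaf_concordance(pairs: Sequence[ConcordancePair]) -> dict[str, float]:
    """Pearson correlation of paired VAFs plus dispersion of the differences.

    Returns ``pearson_r``, ``r_squared`` (kept distinct — they are different
    numbers) and ``cv``, the coefficient of variation of per-pair differences
    (std of differences over mean absolute VAF, a scale-free reproducibility
    measure).
    """
    if len(pairs) < 2:
        raise ParameterError("need at least 2 pairs")
    a = np.array([p.vaf_a for p in pairs], dtype=float)
    b = np.array([p.vaf_b for p in pairs], dtype=float)
    if np.std(a) < 1e-12 or np.std(b) < 1e-12:
        raise UndefinedMetricError("correlation undefined: zero variance")
    r = float(stats.pearsonr(a, b).statistic)
    diffs = a - b
    mean_level = float(np.mean((a + b) / 2))
    if mean_level == 0:
        raise UndefinedMetricError("CV undefined: zero mean VAF")
    return {
        "pearson_r": r,
        "r_squared": r * r,
        "cv": float(np.std(diffs, ddof=1)) / mean_level,
        "n": float(len(pairs)),
    }


# ---------------------------------------------------------------------------
# Titration summaries
# ---------------------------------------------------------------------------


def titration_summary(
    per_titer: Sequence[tuple[float, Sequence[VariantCall], Sequence[TruthVariant]]],
) -> list[TiterResult]:
    """Confusion counts and rounded rates for each titer, highest first."""
    titers = [t for t, _, _ in per_titer]
    if len(set(titers)) != len(titers):
        raise ParameterError("titers must be distinct")
    results = []
    for titer, calls, truth in sorted(per_titer, key=lambda x: -x[0]):
        counts = match_events(calls, truth, "snv_indel", context=f"titer={titer}")
        results.append(
            TiterResult(
                titer=titer,
                counts=counts,
                ppv=round_rate(ppv(counts)),
                sensitivity=round_rate(sensitivity(counts)),
            )
        )
    return results
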