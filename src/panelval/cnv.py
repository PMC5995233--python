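"""Purity-adjusted per-gene copy-number presence/absence calling.

Only a verdict is produced (amplified / homozygous_deletion /
normal_equivocal), never an exact integer copy number. The admixture
correction assumes a diploid contaminating normal fraction:

    ratio = (p * C + 2 * (1 - p)) / 2   =>   C = (2 * ratio - 2 * (1 - p)) / p
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Mapping, Sequence

from panelval.errors import ConsistencyError, DegenerateInputError, ParameterError
from panelval.synthetic import GeneCoverage

__all__ = [
    "CnvCall",
    "coverage_ratio",
    "estimate_copies",
    "call_gene_cnv",
    "VERDICT_AMPLIFIED",
    "VERDICT_DELETED",
    "VERDICT_NORMAL",
]

VERDICT_AMPLIFIED = "amplified"
VERDICT_DELETED = "homozygous_deletion"
VERDICT_NORMAL = "normal_equivocal"


@dataclass(frozen=True)
class CnvCall:
    gene_id: str
    ratio: float
    estimated_copies: float
    verdict: str

    @property
    def reported(self) -> bool:
        """Presence/absence reporting: only non-normal verdicts are reported."""
        return self.verdict != VERDICT_NORMAL


def coverage_ratio(
    tumor: Sequence[GeneCoverage], normal: Sequence[GeneCoverage]
) -> dict[str, float]:
    """Median-normalized tumor/normal depth ratio per gene.

    Each sample is first normalized by its own panel-wide median gene depth so
    library size cancels; the ratio of the normalized depths is returned.
    """
    t = {g.gene_id: g.mean_depth for g in tumor}
    n = {g.gene_id: g.mean_depth for g in normal}
    if set(t) != set(n):
        raise ConsistencyError(
            f"gene sets differ: {sorted(set(t) ^ set(n))[:5]} ..."
        )
    if not t:
        raise ParameterError("empty coverage tables")
    t_med = median(t.values())
    n_med = median(n.values())
    if t_med <= 0 or n_med <= 0:
        raise DegenerateInputError("non-positive median depth")
    ratios = {}
    for gene_id in t:
        if n[gene_id] <= 0:
            raise DegenerateInputError(f"zero normal depth for {gene_id}")
        ratios[gene_id] = (t[gene_id] / t_med) / (n[gene_id] / n_med)
    return ratios


def estimate_copies(ratio: float, purity: float) -> float:
    """Invert the diploid-admixture model; result floored at 0 copies."""
    if purity <= 0 or purity > 1:
        raise ParameterError(f"purity {purity} outside (0, 1]")
    if ratio < 0:
        raise ParameterError("ratio must be >= 0")
    return max(0.0, (2.0 * ratio - 2.0 * (1.0 - purity)) / purity)


def call_gene_cnv(
    ratios: Mapping[str, float],
    purity: float,
    amplification_cutoff: float = 6.0,
    deletion_cutoff: float = 0.5,
) -> list[CnvCall]:
    """Verdict per gene from purity-corrected copy estimates.

    The amplification boundary is inclusive (estimated copies == cutoff is
    amplified). Below 20% purity the admixture inversion is unreliable and is
    rejected outright.
    """
    if purity < 0.2:
        raise ParameterError(f"purity {purity} below the 0.2 reliability floor")
    if deletion_cutoff >= amplification_cutoff:
        raise ParameterError("deletion_cutoff must be < amplification_cutoff")
    calls = []
    for gene_id in sorted(ratios):
        copies = estimate_copies(ratios[gene_id], purity)
        if copies >= amplification_cutoff:
            verdict = VERDICT_AMPLIFIED
        elif copies <= deletion_cutoff:
            verdict = VERDICT_DELETED
        else:
            verdict = VERDICT_NORMAL
        calls.append(
            CnvCall(
                gene_id=gene_id,
                ratio=float(ratios[gene_id]),
                estimated_copies=copies,
                verdict=verdict,
            )
        )
    return calls
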