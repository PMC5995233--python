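"""Tiered tumor/normal SNV and indel caller.

Decision rules are deliberately simple thresholds: a candidate is any
non-reference allele with enough supporting reads in the tumor; it is then
annotated with filters for depth QC, germline subtraction, tier-specific limit
of detection, and (separately, see :func:`apply_classification_filter`) a
benign-classification lookup. A call is reported iff no filter fired.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from panelval.errors import ConsistencyError, ParameterError
from panelval.synthetic import GeneAnnotation, SiteCounts

__all__ = [
    "TierConfig",
    "VariantCall",
    "QCReport",
    "FILTER_LOW_DEPTH",
    "FILTER_GERMLINE",
    "FILTER_BENIGN",
    "FILTER_BELOW_LOD",
    "qc_coverage",
    "call_somatic",
    "apply_classification_filter",
]

FILTER_LOW_DEPTH = "LOW_DEPTH"
FILTER_GERMLINE = "GERMLINE"
FILTER_BENIGN = "BENIGN"
FILTER_BELOW_LOD = "BELOW_LOD"


@dataclass(frozen=True)
class TierConfig:
    """Thresholds of the tiered calling and coverage-QC rules.

    ``tier1_lod``/``tier2_lod`` are observed-VAF detection cutoffs;
    ``min_alt_reads`` and ``germline_vaf_cutoff`` are engineering defaults not
    dictated by the validation design and are exposed here for tuning.
    """

    tier1_lod: float = 0.05
    tier2_lod: float = 0.10
    min_alt_reads: int = 5
    germline_vaf_cutoff: float = 0.02
    min_locus_depth: int = 300
    target_mean_depth: int = 500
    uniformity_fraction: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.tier1_lod <= self.tier2_lod < 1:
            raise ParameterError("need 0 < tier1_lod <= tier2_lod < 1")
        for name in ("germline_vaf_cutoff", "uniformity_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ParameterError(f"{name} must be in (0, 1)")
        if self.min_alt_reads < 1:
            raise ParameterError("min_alt_reads must be >= 1")

    def lod_for_tier(self, tier: int) -> float:
        return self.tier1_lod if tier == 1 else self.tier2_lod


@dataclass
class VariantCall:
    contig: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    vaf: float
    alt_count: int
    depth: int
    gene_id: str
    tier: int
    filters: set[str] = field(default_factory=set)

    @property
    def reported(self) -> bool:
        return not self.filters

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class QCReport:
    mean_on_target_depth: float
    fraction_bases_ge_min: float
    passed: bool
    flagged_loci: tuple[tuple[str, int], ...]


class _PanelIndex:
    """Position -> gene lookup over non-overlapping intervals."""

    def __init__(self, panel: Sequence[GeneAnnotation]):
        if not panel:
            raise ParameterError("empty panel")
        self._by_contig: dict[str, tuple[list[int], list[GeneAnnotation]]] = {}
        for g in sorted(panel, key=lambda g: (g.contig, g.start)):
            starts, genes = self._by_contig.setdefault(g.contig, ([], []))
            starts.append(g.start)
            genes.append(g)

    def lookup(self, contig: str, pos: int) -> GeneAnnotation | None:
        """Gene containing a 1-based position, or None if untargeted."""
        entry = self._by_contig.get(contig)
        if entry is None:
            return None
        starts, genes = entry
        i = bisect.bisect_right(starts, pos - 1) - 1
        if i >= 0 and genes[i].start <= pos - 1 < genes[i].end:
            return genes[i]
        return None


def qc_coverage(
    sample: Sequence[SiteCounts],
    panel: Sequence[GeneAnnotation],
    config: TierConfig = TierConfig(),
) -> QCReport:
    """Mean on-target depth, uniformity fraction and low-depth loci.

    ``passed`` requires both the uniformity rule (fraction of panel bases at or
    above ``min_locus_depth`` >= ``uniformity_fraction``) and the mean-depth
    floor (``target_mean_depth``).
    """
    index = _PanelIndex(panel)
    depths = []
    flagged = []
    for s in sample:
        if index.lookup(s.contig, s.pos) is None:
            continue
        depths.append(s.depth)
        if s.depth < config.min_locus_depth:
            flagged.append((s.contig, s.pos))
    if not depths:
        raise ParameterError("sample covers no panel sites")
    mean_depth = sum(depths) / len(depths)
    frac = sum(1 for d in depths if d >= config.min_locus_depth) / len(depths)
    return QCReport(
        mean_on_target_depth=mean_depth,
        fraction_bases_ge_min=frac,
        passed=frac >= config.uniformity_fraction
        and mean_depth >= config.target_mean_depth,
        flagged_loci=tuple(flagged),
    )


def call_somatic(
    tumor: Sequence[SiteCounts],
    normal: Sequence[SiteCounts],
    panel: Sequence[GeneAnnotation],
    config: TierConfig = TierConfig(),
) -> list[VariantCall]:
    """Threshold-based paired calling with germline subtraction.

    At every site, each non-reference allele with at least ``min_alt_reads``
    tumor reads becomes a candidate. Filters:

    - ``BELOW_LOD``: observed VAF below the LOD of the gene's tier;
    - ``GERMLINE``: the same allele in the matched normal at VAF >=
      ``germline_vaf_cutoff`` with >= 2 supporting reads;
    - ``LOW_DEPTH``: tumor depth below ``min_locus_depth``.

    Output is sorted by (contig, pos, alt allele). Multi-allelic sites yield
    one candidate per allele.
    """
    if len(tumor) != len(normal):
        raise ConsistencyError("tumor and normal cover different numbers of sites")
    index = _PanelIndex(panel)
    calls: list[VariantCall] = []
    for t, n in zip(tumor, normal):
        if (t.contig, t.pos) != (n.contig, n.pos):
            raise ConsistencyError(
                f"site mismatch: {t.contig}:{t.pos} vs {n.contig}:{n.pos}"
            )
        gene = index.lookup(t.contig, t.pos)
        if gene is None:
            continue
        for allele, count in t.allele_counts.items():
            if allele == t.ref or count < config.min_alt_reads:
                continue
            vaf = count / t.depth if t.depth else 0.0
            filters: set[str] = set()
            if vaf < config.lod_for_tier(gene.tier):
                filters.add(FILTER_BELOW_LOD)
            # an allele equal to the normal's own reference representation
            # (e.g. a deletion's anchor base) is not germline variant evidence
            n_count = 0 if allele == n.ref else n.count(allele)
            if n_count >= 2 and n.depth and n_count / n.depth >= config.germline_vaf_cutoff:
                filters.add(FILTER_GERMLINE)
            if t.depth < config.min_locus_depth:
                filters.add(FILTER_LOW_DEPTH)
            calls.append(
                VariantCall(
                    contig=t.contig,
                    pos=t.pos,
                    ref_allele=t.ref,
                    alt_allele=allele,
                    vaf=vaf,
                    alt_count=count,
                    depth=t.depth,
                    gene_id=gene.gene_id,
                    tier=gene.tier,
                    filters=filters,
                )
            )
    calls.sort(key=lambda c: (c.contig, c.pos, c.alt_allele))
    return calls


def apply_classification_filter(
    calls: Sequence[VariantCall],
    classification_table: Mapping[tuple[str, int, str, str], str],
) -> list[VariantCall]:
    """Suppress calls whose known classification is benign.

    The table maps (gene_id, pos, ref, alt) to a classification string; calls
    classified ``benign`` gain the BENIGN filter, everything else passes
    through untouched. Input calls are not mutated.
    """
    out = []
    for c in calls:
        filters = set(c.filters)
        cls = classification_table.get((c.gene_id, c.pos, c.ref_allele, c.alt_allele))
        if cls == "benign":
            filters.add(FILTER_BENIGN)
        out.append(
            VariantCall(
                contig=c.contig,
                pos=c.pos,
                ref_allele=c.ref_allele,
                alt_allele=c.alt_allele,
                vaf=c.vaf,
                alt_count=c.alt_count,
                depth=c.depth,
                gene_id=c.gene_id,
                tier=c.tier,
                filters=filters,
            )
        )
    return out
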