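"""Seeded generators for every input the calling pipeline consumes.

Everything is simulated at the evidence level (per-site pileup counts, per-gene
coverage, chimeric read tables) rather than at the read level: all downstream
decision rules are functions of counts, so counts are what we generate.

All generators are deterministic for a fixed seed. Per-sample randomness is
derived from a master seed and the sample id via a stable CRC32 hash, so adding
samples to a study never perturbs existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

from panelval.errors import CapacityError, ConsistencyError, ParameterError

BASES = ("A", "C", "G", "T")

__all__ = [
    "BASES",
    "ToyReference",
    "GeneAnnotation",
    "TruthVariant",
    "SiteCounts",
    "SampleProfile",
    "CnvTruth",
    "FusionTruth",
    "GeneCoverage",
    "ChimericEvidence",
    "derive_rng",
    "generate_reference",
    "generate_truth_variants",
    "simulate_site_counts",
    "mix_titration",
    "simulate_gene_coverage",
    "simulate_fusion_library",
    "load_hotspot_templates",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneAnnotation:
    """A panel gene interval: BED-style 0-based, half-open coordinates."""

    gene_id: str
    contig: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    tier: int  # 1 = actionable (low LOD), 2 = analytic

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ParameterError(f"{self.gene_id}: start {self.start} >= end {self.end}")
        if self.tier not in (1, 2):
            raise ParameterError(f"{self.gene_id}: tier must be 1 or 2, got {self.tier}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ToyReference:
    """A small stand-in reference genome plus its targeted gene panel."""

    contigs: Mapping[str, str]
    genes: tuple[GeneAnnotation, ...]
    seed: int

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ParameterError(f"contig {name} is empty")
            if set(seq) - set(BASES):
                raise ParameterError(f"contig {name} contains non-ACGT characters")
        by_contig: dict[str, list[GeneAnnotation]] = {}
        for g in self.genes:
            if g.contig not in self.contigs:
                raise ParameterError(f"gene {g.gene_id} on unknown contig {g.contig}")
            if g.end > len(self.contigs[g.contig]):
                raise ParameterError(f"gene {g.gene_id} extends past contig end")
            by_contig.setdefault(g.contig, []).append(g)
        for genes in by_contig.values():
            ordered = sorted(genes, key=lambda g: g.start)
            for a, b in zip(ordered, ordered[1:]):
                if b.start < a.end:
                    raise ParameterError(f"genes {a.gene_id} and {b.gene_id} overlap")

    def gene_by_id(self, gene_id: str) -> GeneAnnotation:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise ConsistencyError(f"unknown gene {gene_id}")

    def base_at(self, contig: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return self.contigs[contig][pos - 1]

    def panel_sites(self) -> list[tuple[str, int]]:
        """All targeted (contig, 1-based pos) pairs, in panel order."""
        return [
            (g.contig, p + 1) for g in self.genes for p in range(g.start, g.end)
        ]


@dataclass(frozen=True)
class TruthVariant:
    """A ground-truth somatic event (anchored, VCF-style representation)."""

    contig: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    vtype: str  # SNV | INS | DEL
    true_vaf: float
    gene_id: str
    classification: str = "pathogenic"  # pathogenic | VUS | benign

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ParameterError(f"{self}: ref == alt")
        if self.vtype == "SNV" and (len(self.ref_allele) != 1 or len(self.alt_allele) != 1):
            raise ParameterError(f"{self}: SNV alleles must be single bases")
        if not 0 < self.true_vaf <= 1:
            raise ParameterError(f"{self}: true_vaf {self.true_vaf} outside (0, 1]")
        if self.vtype not in ("SNV", "INS", "DEL"):
            raise ParameterError(f"{self}: bad vtype {self.vtype}")
        if self.classification not in ("pathogenic", "VUS", "benign"):
            raise ParameterError(f"{self}: bad classification {self.classification}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class SiteCounts:
    """Pileup summary at one targeted site of one sample.

    ``allele_counts`` maps allele strings (anchored alt representation for
    indels) to read counts and always sums to ``depth``. ``ref`` is the
    anchored reference allele at the site (single base except at deletion
    anchor sites).
    """

    contig: str
    pos: int  # 1-based
    depth: int
    allele_counts: dict[str, int]
    ref: str = ""

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ParameterError(f"negative depth at {self.contig}:{self.pos}")
        if sum(self.allele_counts.values()) != self.depth:
            raise ConsistencyError(
                f"allele counts do not sum to depth at {self.contig}:{self.pos}"
            )

    def count(self, allele: str) -> int:
        return self.allele_counts.get(allele, 0)

    def vaf(self, allele: str) -> float:
        return self.count(allele) / self.depth if self.depth else 0.0


@dataclass(frozen=True)
class SampleProfile:
    """Sequencing profile of one simulated library."""

    sample_id: str
    role: str  # tumor | normal
    purity: float = 1.0
    mean_depth: int = 500
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.purity <= 1:
            raise ParameterError(f"purity {self.purity} outside [0, 1]")
        if not 0 <= self.error_rate <= 0.05:
            raise ParameterError(f"error_rate {self.error_rate} outside [0, 0.05]")
        if self.role not in ("tumor", "normal"):
            raise ParameterError(f"role must be tumor or normal, got {self.role}")


@dataclass(frozen=True)
class CnvTruth:
    """True copy state of one gene."""

    gene_id: str
    true_copies: float
    event: str = ""  # derived if empty

    def __post_init__(self) -> None:
        if self.true_copies < 0:
            raise ParameterError("true_copies must be >= 0")
        expected = classify_copies(self.true_copies)
        if self.event == "":
            object.__setattr__(self, "event", expected)
        elif self.event != expected:
            raise ConsistencyError(
                f"{self.gene_id}: event {self.event!r} inconsistent with "
                f"{self.true_copies} copies (expected {expected!r})"
            )


def classify_copies(copies: float, amplification_cutoff: float = 6.0) -> str:
    if copies >= amplification_cutoff:
        return "amplification"
    if copies == 0:
        return "homozygous_deletion"
    return "normal"


@dataclass(frozen=True)
class FusionTruth:
    """A ground-truth fusion with its simulated evidence strength."""

    gene5: str
    gene3: str
    n_spanning: int
    n_discordant: int = 0
    actionable: bool = False

    def __post_init__(self) -> None:
        if self.gene5 == self.gene3:
            raise ParameterError("gene5 == gene3")
        if self.n_spanning < 0 or self.n_discordant < 0:
            raise ParameterError("read counts must be >= 0")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.gene5, self.gene3))


@dataclass(frozen=True)
class GeneCoverage:
    """Mean sequencing depth over one gene in one sample."""

    gene_id: str
    mean_depth: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ParameterError(f"{self.gene_id}: negative mean_depth")


@dataclass(frozen=True)
class ChimericEvidence:
    """Chimeric-read support for one ordered gene pair."""

    gene5: str
    gene3: str
    n_spanning: int
    n_discordant: int = 0

    def __post_init__(self) -> None:
        if self.n_spanning < 0 or self.n_discordant < 0:
            raise ParameterError("read counts must be >= 0")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.gene5, self.gene3))


# ---------------------------------------------------------------------------
# Random streams
# ---------------------------------------------------------------------------


def derive_rng(master_seed: int, *labels: str) -> np.random.Generator:
    """Generator for a named sub-stream of the master seed.

    Sub-streams are independent across labels and stable across runs: the
    label is folded in via CRC32, not Python's salted ``hash``.
    """
    entropy = [int(master_seed)] + [zlib.crc32(lab.encode()) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# Hotspot templates (static stand-in for an external mutation catalogue)
# ---------------------------------------------------------------------------


def load_hotspot_templates() -> list[dict[str, str]]:
    """Bundled substitution/indel templates used to style generated variants."""
    text = (
        resources.files("panelval").joinpath("data/hotspot_templates.tsv").read_text()
    )
    rows = []
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    header = lines[0].split("\t")
    for ln in lines[1:]:
        rows.append(dict(zip(header, ln.split("\t"))))
    return rows


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def generate_reference(
    seed: int,
    n_genes: int,
    gene_length: int = 300,
    tier1_fraction: float = 0.5,
    spacer: int = 10,
    contig: str = "chr1",
) -> ToyReference:
    """Random reference contig with ``n_genes`` equal-length panel genes.

    Genes are laid out left to right with ``spacer`` untargeted bases between
    them. ``round(tier1_fraction * n_genes)`` genes are assigned tier 1 (which
    genes is itself seeded).
    """
    if n_genes < 1:
        raise ParameterError("n_genes must be >= 1")
    if gene_length < 50:
        raise ParameterError("gene_length must be >= 50")
    if not 0 <= tier1_fraction <= 1:
        raise ParameterError("tier1_fraction must be in [0, 1]")
    rng = derive_rng(seed, "reference")
    total = n_genes * gene_length + (n_genes + 1) * spacer
    seq = "".join(rng.choice(list(BASES), size=total))
    n_tier1 = round(tier1_fraction * n_genes)
    tier1_idx = set(rng.choice(n_genes, size=n_tier1, replace=False).tolist())
    genes = []
    cursor = spacer
    for i in range(n_genes):
        genes.append(
            GeneAnnotation(
                gene_id=f"GENE{i + 1:04d}",
                contig=contig,
                start=cursor,
                end=cursor + gene_length,
                tier=1 if i in tier1_idx else 2,
            )
        )
        cursor += gene_length + spacer
    return ToyReference(contigs={contig: seq}, genes=tuple(genes), seed=seed)


def generate_truth_variants(
    reference: ToyReference,
    n_variants: int,
    vaf: float,
    indel_fraction: float = 0.0,
    benign_fraction: float = 0.0,
    seed: int = 0,
) -> list[TruthVariant]:
    """Place ``n_variants`` somatic events at distinct panel positions.

    ``round(indel_fraction * n)`` events are indels (split evenly between
    insertions and 1-bp deletions), the rest SNVs styled after the bundled
    hotspot templates. ``round(benign_fraction * n)`` events are classified
    benign, the rest pathogenic.
    """
    if not 0 < vaf <= 1:
        raise ParameterError(f"vaf {vaf} outside (0, 1]")
    if n_variants < 0:
        raise ParameterError("n_variants must be >= 0")
    if n_variants == 0:
        return []
    # deletions need pos+1 inside the gene, so exclude each gene's last base
    candidates = [
        (g, p + 1) for g in reference.genes for p in range(g.start, g.end)
    ]
    if n_variants > len(candidates):
        raise CapacityError(
            f"{n_variants} variants requested but panel has {len(candidates)} sites"
        )
    rng = derive_rng(seed, "truth_variants")
    chosen = rng.choice(len(candidates), size=n_variants, replace=False)
    chosen = sorted(chosen.tolist(), key=lambda i: candidates[i][1])

    n_indels = round(indel_fraction * n_variants)
    n_benign = round(benign_fraction * n_variants)
    indel_slots = set(rng.choice(n_variants, size=n_indels, replace=False).tolist())
    benign_slots = set(rng.choice(n_variants, size=n_benign, replace=False).tolist())

    templates = load_hotspot_templates()
    snv_alts: dict[str, list[str]] = {}
    for row in templates:
        if row["vtype"] == "SNV":
            snv_alts.setdefault(row["ref"], []).append(row["alt"])

    variants: list[TruthVariant] = []
    used_positions: set[int] = set()
    for slot, idx in enumerate(chosen):
        gene, pos = candidates[idx]
        # deletions consume pos..pos+1; keep events at fully distinct positions
        if pos in used_positions or (pos + 1) in used_positions:
            for alt_idx in range(len(candidates)):
                g2, p2 = candidates[alt_idx]
                if p2 not in used_positions and (p2 + 1) not in used_positions:
                    gene, pos = g2, p2
                    break
            else:  # pragma: no cover - capacity guard
                raise CapacityError("no free positions left for variant placement")
        ref_base = reference.base_at(gene.contig, pos)
        if slot in indel_slots:
            if pos + 1 <= gene.end and rng.random() < 0.5:
                # 1-bp deletion, anchored on ref_base
                ref_allele = ref_base + reference.base_at(gene.contig, pos + 1)
                alt_allele = ref_base
                vtype = "DEL"
                used_positions.update((pos, pos + 1))
            else:
                ins = "".join(rng.choice(list(BASES), size=int(rng.integers(1, 4))))
                ref_allele = ref_base
                alt_allele = ref_base + ins
                vtype = "INS"
                used_positions.add(pos)
        else:
            pool = snv_alts.get(ref_base, [b for b in BASES if b != ref_base])
            pool = [b for b in pool if b != ref_base] or [
                b for b in BASES if b != ref_base
            ]
            alt_allele = str(rng.choice(pool))
            ref_allele = ref_base
            vtype = "SNV"
            used_positions.add(pos)
        variants.append(
            TruthVariant(
                contig=gene.contig,
                pos=pos,
                ref_allele=ref_allele,
                alt_allele=alt_allele,
                vtype=vtype,
                true_vaf=vaf,
                gene_id=gene.gene_id,
                classification="benign" if slot in benign_slots else "pathogenic",
            )
        )
    variants.sort(key=lambda v: (v.contig, v.pos, v.alt_allele))
    return variants


def retitrate(truths: Sequence[TruthVariant], vaf: float) -> list[TruthVariant]:
    """The same event set re-inserted at a different allele fraction."""
    return [replace(v, true_vaf=vaf) for v in truths]


def simulate_site_counts(
    reference: ToyReference,
    truths: Sequence[TruthVariant],
    profile: SampleProfile,
) -> list[SiteCounts]:
    """Pileup counts for every targeted site of one sample.

    Depth is Poisson around ``profile.mean_depth``. At a truth site the alt
    count is Binomial(depth, effective_vaf) with

        effective_vaf = purity * true_vaf + (1 - purity * true_vaf) * error_rate / 3

    (the error term lets a fully erased signal still accrue background); the
    remaining reads split between the reference allele and the two other
    substitution alleles at ``error_rate / 3`` each. Sites without a truth
    event accrue substitution errors at ``error_rate`` split evenly across the
    three non-reference bases.
    """
    if profile.mean_depth < 1:
        raise ParameterError("mean_depth must be >= 1")
    truth_by_site: dict[tuple[str, int], TruthVariant] = {}
    panel = set(reference.panel_sites())
    for v in truths:
        if (v.contig, v.pos) not in panel:
            raise ConsistencyError(f"truth variant at {v.contig}:{v.pos} outside panel")
        if (v.contig, v.pos) in truth_by_site:
            raise ConsistencyError(f"two truth variants at {v.contig}:{v.pos}")
        truth_by_site[(v.contig, v.pos)] = v

    rng = derive_rng(profile.seed, "pileup", profile.sample_id)
    err3 = profile.error_rate / 3.0
    out: list[SiteCounts] = []
    for contig, pos in reference.panel_sites():
        depth = int(rng.poisson(profile.mean_depth))
        base = reference.base_at(contig, pos)
        truth = truth_by_site.get((contig, pos))
        if truth is None:
            others = [b for b in BASES if b != base]
            probs = [err3, err3, err3]
            counts = rng.multinomial(depth, probs + [1.0 - sum(probs)])
            allele_counts = {o: int(c) for o, c in zip(others, counts[:3])}
            allele_counts[base] = int(counts[3])
            ref_allele = base
        else:
            ref_allele = truth.ref_allele
            signal = profile.purity * truth.true_vaf
            eff = signal + (1.0 - signal) * err3
            err_alleles = [b for b in BASES if b != base and b != truth.alt_allele]
            probs = [eff] + [err3] * len(err_alleles)
            counts = rng.multinomial(depth, probs + [1.0 - sum(probs)])
            allele_counts = {truth.alt_allele: int(counts[0])}
            for o, c in zip(err_alleles, counts[1 : 1 + len(err_alleles)]):
                allele_counts[o] = int(c)
            allele_counts[ref_allele] = int(counts[-1])
        allele_counts = {a: c for a, c in allele_counts.items() if c > 0 or a == ref_allele}
        out.append(
            SiteCounts(
                contig=contig, pos=pos, depth=depth, allele_counts=allele_counts, ref=ref_allele
            )
        )
    return out


def mix_titration(
    tumor: Sequence[SiteCounts],
    normal: Sequence[SiteCounts],
    tumor_fraction: float,
    seed: int = 0,
) -> list[SiteCounts]:
    """Binomially thin and recombine two samples at a given tumor fraction.

    Each tumor read survives with probability ``tumor_fraction`` and each
    normal read with ``1 - tumor_fraction``; total depth is preserved in
    expectation. Fractions 0 and 1 are degenerate and return exact copies.
    """
    if not 0 <= tumor_fraction <= 1:
        raise ParameterError("tumor_fraction must be in [0, 1]")
    if len(tumor) != len(normal):
        raise ConsistencyError("tumor and normal cover different numbers of sites")
    rng = derive_rng(seed, "titration")
    out: list[SiteCounts] = []
    for t, n in zip(tumor, normal):
        if (t.contig, t.pos) != (n.contig, n.pos):
            raise ConsistencyError(
                f"site mismatch: {t.contig}:{t.pos} vs {n.contig}:{n.pos}"
            )
        mixed: dict[str, int] = {}
        for allele, c in t.allele_counts.items():
            kept = int(rng.binomial(c, tumor_fraction)) if 0 < tumor_fraction < 1 else (
                c if tumor_fraction == 1 else 0
            )
            if kept:
                mixed[allele] = mixed.get(allele, 0) + kept
        for allele, c in n.allele_counts.items():
            kept = int(rng.binomial(c, 1 - tumor_fraction)) if 0 < tumor_fraction < 1 else (
                c if tumor_fraction == 0 else 0
            )
            if kept:
                mixed[allele] = mixed.get(allele, 0) + kept
        ref = t.ref if len(t.ref) >= len(n.ref) else n.ref
        mixed.setdefault(ref, 0)
        out.append(
            SiteCounts(
                contig=t.contig,
                pos=t.pos,
                depth=sum(mixed.values()),
                allele_counts=mixed,
                ref=ref,
            )
        )
    return out


def expected_coverage_scale(purity: float, true_copies: float) -> float:
    """Admixture scale factor: (purity * C + (1 - purity) * 2) / 2."""
    return (purity * true_copies + (1.0 - purity) * 2.0) / 2.0


def simulate_gene_coverage(
    reference: ToyReference,
    cnv_truths: Sequence[CnvTruth],
    profile: SampleProfile,
    dispersion: float = 0.05,
) -> list[GeneCoverage]:
    """Per-gene mean depths under an admixture copy-number model.

    The depth of gene g is ``mean_depth * scale(g) * exp(N(0, dispersion))``
    where scale is the purity-weighted copy ratio; genes absent from
    ``cnv_truths`` are diploid.
    """
    if dispersion <= 0:
        raise ParameterError("dispersion must be > 0")
    known = {g.gene_id for g in reference.genes}
    copies = {g.gene_id: 2.0 for g in reference.genes}
    for t in cnv_truths:
        if t.gene_id not in known:
            raise ConsistencyError(f"unknown gene {t.gene_id}")
        copies[t.gene_id] = float(t.true_copies)
    rng = derive_rng(profile.seed, "coverage", profile.sample_id)
    out = []
    for g in reference.genes:
        scale = expected_coverage_scale(profile.purity, copies[g.gene_id])
        noise = float(np.exp(rng.normal(0.0, dispersion)))
        out.append(
            GeneCoverage(
                gene_id=g.gene_id,
                mean_depth=profile.mean_depth * scale * noise,
                sample_id=profile.sample_id,
            )
        )
    return out


def simulate_fusion_library(
    fusion_truths: Sequence[FusionTruth],
    n_noise_events: int = 0,
    noise_max_reads: int = 15,
    seed: int = 0,
    noise_gene_pool: int = 200,
) -> list[ChimericEvidence]:
    """A chimeric-evidence table: one row per truth fusion plus random noise.

    Noise rows are distinct random gene pairs (never colliding with a truth
    pair) with spanning counts uniform on [1, noise_max_reads] — sub-threshold
    by construction when ``noise_max_reads`` sits below the caller threshold.
    """
    if n_noise_events < 0:
        raise ParameterError("n_noise_events must be >= 0")
    if n_noise_events > 0 and noise_max_reads < 1:
        raise ParameterError("noise_max_reads must be >= 1")
    rng = derive_rng(seed, "fusion_library")
    rows = [
        ChimericEvidence(t.gene5, t.gene3, t.n_spanning, t.n_discordant)
        for t in fusion_truths
    ]
    truth_pairs = {t.pair for t in fusion_truths}
    seen = set(truth_pairs)
    made = 0
    while made < n_noise_events:
        i, j = rng.choice(noise_gene_pool, size=2, replace=False)
        pair = frozenset((f"NOISE{i + 1:04d}", f"NOISE{j + 1:04d}"))
        if pair in seen:
            continue
        seen.add(pair)
        g5, g3 = sorted(pair)
        rows.append(
            ChimericEvidence(
                gene5=g5,
                gene3=g3,
                n_spanning=int(rng.integers(1, noise_max_reads + 1)),
                n_discordant=int(rng.integers(0, noise_max_reads + 1)),
            )
        )
        made += 1
    return rows


def mean_observed_vaf(
    sites: Iterable[SiteCounts], truths: Sequence[TruthVariant]
) -> float:
    """Mean observed alt-allele fraction over the truth sites (QC helper)."""
    by_site = {(v.contig, v.pos): v for v in truths}
    vafs = [
        s.vaf(by_site[(s.contig, s.pos)].alt_allele)
        for s in sites
        if (s.contig, s.pos) in by_site
    ]
    if not vafs:
        raise ParameterError("no truth sites present in the pileup")
    return float(np.mean(vafs))
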