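"""End-to-end experiment recipes.

Each study regenerates its inputs from a master seed, runs the relevant
caller, and returns a JSON-serializable report embedding the seed, a config
hash and the package version, so re-running with the same seed reproduces the
report byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from typing import Sequence

import panelval
from panelval import cnv, fusion, metrics, somatic, synthetic
from panelval.errors import ParameterError

__all__ = ["run_titration_study", "run_cnv_cohort", "run_fusion_replicates"]


def _provenance(seed: int, params: dict) -> dict:
    blob = json.dumps(params, sort_keys=True).encode()
    return {
        "seed": seed,
        "config_hash": hashlib.sha256(blob).hexdigest()[:16],
        "version": panelval.__version__,
        "params": params,
    }


def run_titration_study(
    seed: int,
    titers: Sequence[float] = (0.25, 0.15, 0.05),
    n_variants: int = 110,
    depth: int = 500,
    n_genes: int = 20,
    gene_length: int = 300,
    error_rate: float = 0.001,
    indel_fraction: float = 0.1,
    config: somatic.TierConfig | None = None,
) -> dict:
    """Digital spike-in titration: insert one variant set at each titer VAF,
    call against a matched variant-free normal, and summarize per-titer
    confusion counts, PPV and sensitivity.

    The panel is generated all-tier-1 so the 5% LOD governs every titer.
    """
    if not titers:
        raise ParameterError("need at least one titer")
    config = config or somatic.TierConfig()
    params = {
        "titers": list(titers),
        "n_variants": n_variants,
        "depth": depth,
        "n_genes": n_genes,
        "gene_length": gene_length,
        "error_rate": error_rate,
        "indel_fraction": indel_fraction,
    }
    reference = synthetic.generate_reference(
        seed, n_genes=n_genes, gene_length=gene_length, tier1_fraction=1.0
    )
    base_truth = synthetic.generate_truth_variants(
        reference, n_variants, vaf=1.0, indel_fraction=indel_fraction, seed=seed
    )
    normal_profile = synthetic.SampleProfile(
        sample_id="normal", role="normal", purity=0.0,
        mean_depth=depth, error_rate=error_rate, seed=seed,
    )
    normal = synthetic.simulate_site_counts(reference, [], normal_profile)

    per_titer = []
    for titer in titers:
        truths = synthetic.retitrate(base_truth, titer)
        tumor_profile = synthetic.SampleProfile(
            sample_id=f"tumor_titer_{titer:g}", role="tumor", purity=1.0,
            mean_depth=depth, error_rate=error_rate, seed=seed,
        )
        tumor = synthetic.simulate_site_counts(reference, truths, tumor_profile)
        calls = somatic.call_somatic(tumor, normal, reference.genes, config)
        per_titer.append((titer, calls, truths))

    summary = metrics.titration_summary(per_titer)
    report = {
        "study": "titration",
        "provenance": _provenance(seed, params),
        "titers": [
            {
                "titer": r.titer,
                "tp": r.counts.tp,
                "fp": r.counts.fp,
                "fn": r.counts.fn,
                "n_truth": r.counts.tp + r.counts.fn,
                "ppv": r.ppv,
                "sensitivity": r.sensitivity,
            }
            for r in summary
        ],
    }
    return report


def run_cnv_cohort(
    seed: int,
    n_positive: int = 6,
    n_negative: int = 16,
    true_copies: float = 8.0,
    purity: float = 0.5,
    target_gene: str | None = None,
    depth: int = 500,
    dispersion: float = 0.05,
    n_genes: int = 20,
    amplification_cutoff: float = 6.0,
) -> dict:
    """Amplification presence/absence cohort: known positives carrying one
    amplified gene under purity admixture versus diploid known negatives."""
    if n_positive + n_negative < 1:
        raise ParameterError("cohort must contain at least one sample")
    params = {
        "n_positive": n_positive,
        "n_negative": n_negative,
        "true_copies": true_copies,
        "purity": purity,
        "depth": depth,
        "dispersion": dispersion,
        "n_genes": n_genes,
    }
    reference = synthetic.generate_reference(seed, n_genes=n_genes)
    target = target_gene or reference.genes[0].gene_id
    truths = [synthetic.CnvTruth(gene_id=target, true_copies=true_copies)]

    def _call_sample(sample_id: str, cnv_truths, sample_purity: float) -> cnv.CnvCall:
        tumor_prof = synthetic.SampleProfile(
            sample_id=f"{sample_id}_T", role="tumor", purity=sample_purity,
            mean_depth=depth, seed=seed,
        )
        normal_prof = synthetic.SampleProfile(
            sample_id=f"{sample_id}_N", role="normal", purity=0.0,
            mean_depth=depth, seed=seed,
        )
        tumor_cov = synthetic.simulate_gene_coverage(
            reference, cnv_truths, tumor_prof, dispersion
        )
        normal_cov = synthetic.simulate_gene_coverage(
            reference, [], normal_prof, dispersion
        )
        ratios = cnv.coverage_ratio(tumor_cov, normal_cov)
        calls = cnv.call_gene_cnv(
            ratios, sample_purity, amplification_cutoff=amplification_cutoff
        )
        return next(c for c in calls if c.gene_id == target)

    positive_calls = [
        _call_sample(f"pos{i + 1:02d}", truths, purity) for i in range(n_positive)
    ]
    negative_calls = [
        _call_sample(f"neg{i + 1:02d}", [], purity) for i in range(n_negative)
    ]

    n_pos_amp = sum(1 for c in positive_calls if c.verdict == cnv.VERDICT_AMPLIFIED)
    n_neg_normal = sum(1 for c in negative_calls if c.verdict == cnv.VERDICT_NORMAL)
    report = {
        "study": "cnv_cohort",
        "provenance": _provenance(seed, params),
        "target_gene": target,
        "positive": {
            "n": n_positive,
            "amplified": n_pos_amp,
            "calls": [
                {"verdict": c.verdict, "estimated_copies": round(c.estimated_copies, 3)}
                for c in positive_calls
            ],
        },
        "negative": {
            "n": n_negative,
            "normal_equivocal": n_neg_normal,
            "calls": [
                {"verdict": c.verdict, "estimated_copies": round(c.estimated_copies, 3)}
                for c in negative_calls
            ],
        },
    }
    return report


def run_fusion_replicates(
    seed: int,
    n_replicates: int = 12,
    truth_spanning: int = 30,
    noise_events: int = 50,
    noise_max_reads: int = 15,
    min_spanning: int = fusion.DEFAULT_MIN_SPANNING,
    gene5: str = "FUSA",
    gene3: str = "FUSB",
) -> dict:
    """Replicate RNA libraries with one actionable truth fusion plus
    sub-threshold noise; reports per-replicate detection and pooled PPV."""
    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    params = {
        "n_replicates": n_replicates,
        "truth_spanning": truth_spanning,
        "noise_events": noise_events,
        "noise_max_reads": noise_max_reads,
        "min_spanning": min_spanning,
    }
    truth = [
        synthetic.FusionTruth(
            gene5=gene5, gene3=gene3, n_spanning=truth_spanning,
            n_discordant=max(1, truth_spanning // 3), actionable=True,
        )
    ]
    actionable = {(gene5, gene3)}
    replicates = [
        synthetic.simulate_fusion_library(
            truth, noise_events, noise_max_reads,
            seed=int(synthetic.derive_rng(seed, f"replicate{i}").integers(2**31)),
        )
        for i in range(n_replicates)
    ]
    detection = fusion.replicate_detection(replicates, truth, actionable, min_spanning)

    tp = fp = 0
    for table in replicates:
        calls = fusion.call_fusions(table, actionable, min_spanning)
        counts = metrics.match_events(calls, truth, "fusion")
        tp += counts.tp
        fp += counts.fp
    pooled = metrics.ConfusionCounts(tp=tp, fp=fp, context="pooled replicates")
    report = {
        "study": "fusion_replicates",
        "provenance": _provenance(seed, params),
        "fusion": {"gene5": gene5, "gene3": gene3},
        "detected_in": detection[truth[0].pair],
        "n_replicates": n_replicates,
        "pooled_tp": tp,
        "pooled_fp": fp,
        "ppv": metrics.round_rate(metrics.ppv(pooled)) if tp + fp else None,
    }
    return report
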