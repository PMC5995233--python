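# panelval

Desk-scale validation toolkit for a tumor/normal targeted NGS panel. It
regenerates, from seeded synthetic data, the analytic experiments behind a
clinical assay validation:

- **`panelval.synthetic`** — seeded generators for a toy reference + gene
  panel, ground-truth somatic variant sets, tumor/normal pileup counts with
  digital spike-ins, purity titration mixtures, per-gene coverage under a
  copy-number admixture model, and chimeric-read evidence tables for fusion
  libraries. Simulation is at the evidence level (counts, not reads): every
  downstream decision rule is a function of counts.
- **`panelval.somatic`** — tiered threshold SNV/indel caller: 5% observed-VAF
  limit of detection for tier-1 genes, 10% for tier-2, matched-normal germline
  subtraction, depth QC (500× mean target, 95% of bases ≥ 300×, per-locus
  LOW_DEPTH flagging) and a benign-classification filter.
- **`panelval.cnv`** — per-gene presence/absence copy-number calls from
  median-normalized tumor/normal coverage ratios with diploid-admixture purity
  correction; amplification at ≥ 6 estimated copies (inclusive), homozygous
  deletion at ≤ 0.5, validated down to 30% purity.
- **`panelval.fusion`** — fusion calls from junction-spanning / discordant-mate
  evidence; positivity requires ≥ 16 spanning reads (discordant mates are
  reported but do not decide), actionable-tier assignment on unordered pairs.
- **`panelval.metrics`** — confusion-matrix construction with per-class event
  matching, sensitivity / PPV / specificity with explicit undefined-metric
  errors, half-up presentation rounding, VAF concordance (Pearson r and r²
  kept distinct), per-titer summaries.
- **`panelval.workflows` / CLI** — end-to-end study recipes: in-silico
  titration (110 variants at 25/15/5% VAF), amplification cohort
  (6 positives + 16 negatives), and 12-replicate fusion detection.

## CLI

```sh
panelval simulate --seed 3 --n-variants 30 --vaf 0.25 --out-dir run/
panelval call-snv --tumor run/tumor.counts.tsv --normal run/normal.counts.tsv \
    --panel run/panel.bed --out run/calls.vcf
panelval validate --calls run/calls.vcf --truth run/truth.vcf --out run/report.json
panelval call-cnv --tumor tumor_cov.tsv --normal normal_cov.tsv --purity 0.5 --out cnv.tsv
panelval call-fusion --evidence chimeric.tsv --actionable pairs.tsv --out fusions.tsv

panelval study titration --seed 42 --out titration.json
panelval study cnv-cohort --seed 42 --out cnv_cohort.json
panelval study fusion-replicates --seed 42 --out fusions.json
```

All studies are deterministic per master seed; reports embed the seed, a
config hash and the package version.

## Notes

- The titer of an in-silico titration is interpreted as the *expected observed
  VAF* of the inserted variants; purity-scaled mixing of whole samples is a
  separate operation (`synthetic.mix_titration`).
- At the 5% titer — exactly the tier-1 LOD — a caller thresholding observed
  VAF detects roughly half of the inserted variants (binomial sampling around
  the cutoff); per-titer results are reported directly from computed counts.
- `min_alt_reads` (5) and `germline_vaf_cutoff` (0.02) are engineering
  defaults, configurable via `somatic.TierConfig`.
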