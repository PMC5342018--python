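# txfeedback

Analysis pipeline for short-term transcriptional feedback after inhibition of
the EGFR signaling network, built around an uncertainty-weighted nonnegative
matrix factorization of condition-mean expression data.

When cells are treated with EGFR inhibitors (cetuximab, gefitinib, afatinib),
drug-sensitive lines do not simply shut pathway transcription down: within
days they *induce* a compensatory program that includes growth-factor
receptors such as EGFR itself. This package re-implements that analysis as a
tested pipeline and exercises it end-to-end on a synthetic cohort that
emulates the study design — four genetic backgrounds (Mock, EGFR-overexpressing,
HRAS-mutant, PIK3CA-mutant) crossed with four treatments in triplicate — with
planted ground truth, so every stage's answer is checkable.

## The model

Expression is summarized per experimental condition as a gene × condition
matrix **D** of replicate means with elementwise uncertainties **Σ**
(replicate standard deviations, floored at 5% of signal). The factorization
model is elementwise normal,

    D ~ N(A P, Σ),   A ≥ 0 (genes × k),   P ≥ 0 (k × conditions),

fit by minimizing the weighted residual χ² = Σᵢⱼ ((Dᵢⱼ − (AP)ᵢⱼ)/Σᵢⱼ)² with
deterministic alternating weighted nonnegative least squares. Pattern rows
are normalized to sum to one (A absorbs the scale), so each row of **P** is
the relative activity of one expression program across conditions.
Uncertainty in **A** comes from a parametric bootstrap (refits on
D* ~ N(AP, Σ)); the per-entry z-score mean/SD over draws feeds gene-set
statistics. The pattern count k is chosen by robustness: patterns that
survive refitting under redrawn noise are real, and the largest k whose
worst matched-pattern correlation stays ≥ 0.9 is selected.

Downstream, TF target sets are scored against patterns with a permutation
gene-set statistic; a reference gene (EGFR's role) is associated with TFs by
correlating amplitude z-score rows and comparing target vs non-target
correlations with a one-sided Wilcoxon rank-sum (BH-corrected); the
feedback signature splits the implicated TF's targets into "up"/"down" sets
by clustering their treatment-induced changes; and a mutation/GISTIC survey
tallies alteration frequencies over signaling-network nodes (a sample is
altered on a mutation or GISTIC ±2, families collapse by boolean OR).

## Worked example

The numbered drivers under `analysis/` run the whole study on the synthetic
cohort and write their tables under `results/` (large intermediates go to
`scratch/`):

```bash
python analysis/01_simulate_cohort.py      # cohort + planted truth
python analysis/02_preprocess.py           # probe collapse, D/Sigma, gene filter
python analysis/03_factorize_patterns.py   # k scan + factorization
python analysis/04_tf_enrichment.py        # TF set and association statistics
python analysis/05_feedback_signature.py   # up/down signature + survival
python analysis/06_alteration_survey.py    # network alteration survey
```

Output of the factorization and signature steps (seed 17):

```
robustness by k: {2: 1.0, 3: 0.99, 4: 0.8, 5: 0.81, 6: 0.3} -> selected k = 3
  planted 'constant'  ~ inferred 'pattern_1': r = 1.000
  planted 'oncogenic' ~ inferred 'pattern_2': r = 0.951
  planted 'feedback'  ~ inferred 'pattern_3': r = 0.998
signature: 24 up / 16 down genes (membership accuracy vs planted truth: 100.0%)
up-set enrichment vs reference change profile: one-sided Wilcoxon p = 8.67e-16
feedback pattern (pattern_3) treatment delta vs relative survival:
  r = -0.998 (p = 6.37e-13) — induction is strongest where cells die
```

Reading: the scan recovers the three planted programs (a flat baseline, an
oncogene-driven program repressed by treatment, and a treatment-induced
feedback program); the signature clustering reproduces the planted up/down
memberships; and the feedback program's induction after treatment is
anti-correlated with relative colony survival — sensitive backgrounds mount
the strongest feedback, the qualitative hallmark of the original analysis.

The same stages are scriptable through one config:

```bash
txfeedback pipeline run --config configs/pipeline.yaml
```

and each stage has a CLI of its own (`txfeedback simulate|preprocess|
factorize|enrich|tf-assoc|signature|stratify|survey`).

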