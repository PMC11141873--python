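# promoscreen

A coexpression-anchored promoter motif enrichment screen for nominating
candidate transcriptional regulators of a gene of interest from bulk
RNA-Seq, a genome and a library of consensus binding sites. The design
follows the screen that nominated TCF4 — via its E-box site
5'-CAGGTG/CACCTG-3' — as a negative regulator of the keratinocyte
cytokine gene *IL17C* in psoriatic skin.

## Who it is for

Computational biologists who have (1) a gene whose regulation they want
to understand, (2) a cohort of expression profiles in the relevant
tissue, and (3) no ChIP data for the candidate regulators. The screen
leverages the observation that the targets of a shared regulator are
coexpressed: genes tracking the seed gene across samples should share
binding sites in their promoters.

## The method

1. **Detection filter.** A gene is *detected* in a sample when its CPM
   exceeds a threshold (default 0.25) and the lower bound of an exact
   Poisson 95% confidence interval on its FPKM is positive; genes
   detected in at least 5% of samples are kept.
2. **Correlation screen.** Counts become log2-CPM intensities
   (log2((k + 0.5)/(N + 1) × 10⁶)); every kept gene is Spearman-correlated
   with the seed gene, and a recorded policy (default ρ ≥ 0.5 and
   BH-FDR ≤ 0.05, positive sign) cuts the correlated gene set.
3. **Promoter extraction.** Strand-aware TSS-anchored windows (e.g.
   10 kb upstream + 1 kb downstream) are extracted from an indexed
   FASTA; minus-strand promoters are reverse-complemented so position 1
   is always most-distal upstream.
4. **Motif scanning.** Each IUPAC consensus (and its reverse complement)
   is slid over every promoter; matches at the same window from the two
   orientations collapse to one occurrence, so a palindromic pair such
   as CAGGTG/CACCTG is never double-counted.
5. **Enrichment.** Per motif *m* with per-gene occurrence x_g, a
   semiparametric logistic GAM

       logit P(member_g = 1) = β₀ + β₁·log(1 + x_g) + s(GC_g) + s(log L_g)

   with penalized cubic-spline smooths absorbs promoter-composition
   confounding; β₁ is tested by a likelihood-ratio test and p-values
   are Benjamini–Hochberg adjusted within one window-size family.
   Motifs with fewer than a minimum number of sites in the seed gene's
   own window (default 5) are excluded first.
6. **Target prediction.** Per motif, genes are ranked by the geometric
   mean of the within-universe quantiles of (motif count, seed
   correlation) — a gene high on both axes tops the list.

A fully deterministic synthetic-data generator (negative-binomial
counts driven by a latent regulator activity; promoters with planted
motif instances) makes every stage testable end to end.

## Worked example

Simulate a cohort (400 genes × 60 samples, 80 target genes driven by a
latent regulator with log-effect 1.5; target promoters planted with the
E-box at 3 expected sites versus 1 for background), screen it, and
score recovery:

```sh
promoscreen simulate --outdir demo --seed 7 --n-genes 400 \
    --n-samples 60 --n-targets 80 --promoter-len 1000
promoscreen screen --config demo/screen_config.yaml
promoscreen evaluate --dataset-dir demo --results-dir demo/results
```

The screen's manifest reports each stage:

```
"correlation": { "n_tested": 399, "n_selected": 80,
                 "selection_rule": "sign=positive,rho_min=0.5,fdr_max=0.05" },
"enrichment_1000up_0down": { "n_motifs_tested": 17, "n_fdr_05": 1 }
```

meaning 80 of 399 genes passed the correlation policy and exactly one
of 17 motifs was enriched at FDR < 0.05. The enrichment table ranks the
planted motif first with a log-odds effect of 2.96 per unit of
log(1 + count) and FDR = 2.2 × 10⁻²²:

```
motif_id  name           window_bp  effect  p_value   fdr       ...
PLANTED   planted E-box  1000       2.955   1.30e-23  2.20e-22
D19       decoy 19       1000       0.862   2.88e-02  2.45e-01
```

and `evaluate` confirms perfect recovery of the simulated truth:

```
{ "precision": 1.0, "recall": 1.0,
  "planted_motif_rank": 1, "planted_motif_fdr": 2.2e-22 }
```

## Layout

- `src/promoscreen/expression.py` — CPM/FPKM, detection filter, log-CPM, qPCR ratio
- `src/promoscreen/correlation.py` — Spearman screen, set selection, pairwise correlation
- `src/promoscreen/promoters.py` — TSS windows, FASTA extraction, BED6/GFF3 input
- `src/promoscreen/motifs.py` — IUPAC matching, double-strand scanning, library I/O
- `src/promoscreen/enrichment.py` — logistic GAM, LR test, BH-FDR, screen driver
- `src/promoscreen/targets.py` — motif target ranking
- `src/promoscreen/synthetic.py` — synthetic cohort/genome generator with truth labels
- `src/promoscreen/pipeline.py`, `cli.py` — orchestration, manifest, CLI

See `docs/methods.md` for the modelling choices, defaults and known
limitations.
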