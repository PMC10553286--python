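# eatrhythm

Analysis toolkit for the question: **do infants who eat at more regular
times sleep more maturely, and is that link carried by the maturation of
their gut microbiota?**  It is aimed at researchers working with infant
meal-time diaries, actigraphy-derived sleep composites, and 16S-style
taxa count tables from longitudinal cohorts (assessments at 3, 6 and
12 months of age).

The toolkit provides, as importable modules and as a CLI:

* **Eating Regularity Index (ERI).**  Each diary day becomes a binary
  vector over 96 fifteen-minute epochs (1 where a meal starts), smoothed
  by a double circular simple moving average of width *k* = 4 epochs.
  The ERI of a subject × assessment is the mean cosine similarity over
  all day pairs,

  `ERI = (2/(n(n−1))) Σ_{i<j} ⟨v_i, v_j⟩ / (‖v_i‖‖v_j‖) ∈ [0, 1]`,

  with 0 = highly irregular and 1 = identical timing every day.
  Subjects with fewer than 5 valid diary days are excluded.  The
  SMA-width selection procedure (maximise between-subject ERI variance
  per age group) is included.
* **Gut-microbiota maturation markers**: alpha diversity (Observed,
  Shannon in nats, bias-corrected Chao1), a random-forest
  microbiota-for-age maturation index (out-of-bag predicted age minus
  actual age), two-cluster enterotypes (*Bifidobacterium*-rich A vs
  *Bacteroides*-rich B) from weighted-UniFrac distances via
  deterministic k-medoids with Calinski–Harabasz and
  prediction-strength scores, and phylum-level relative abundances.
* **Association models**: five linear mixed models (one per sleep
  composite) with ERI + covariates as fixed effects, AIC/BIC-guided
  choice between random-intercept and random-intercept+slope,
  Satterthwaite degrees of freedom, per-age GLMs, and the one-way
  ANOVA + Tukey age trend of the ERI.
* **Baron–Kenny mediation**: the 4-step causal-steps screen of every
  microbiota marker against every sleep composite.
* **A synthetic cohort generator** with known ground truth (latent
  regularity trait, configurable effect sizes, enterotype mixtures,
  switchable mediation structure), so the whole pipeline is testable
  without access to cohort data.

See `docs/methods.md` for the full model descriptions and design
rationale.

## Worked example

```python
from eatrhythm import CohortConfig, simulate_cohort, compute_eri_table
from eatrhythm.models import select_random_structure, age_trend_anova

cohort = simulate_cohort(CohortConfig(n_subjects=150, seed=1))
eri = compute_eri_table(cohort["diaries"])          # k=4, min_days=5
data = (eri[~eri.excluded]
        .merge(cohort["sleep"], on=["subject_id", "age"]))

trend = age_trend_anova(data["eri"], data["age"])
print(f"ERI age trend: F({trend.df_between}, {trend.df_within}) "
      f"= {trend.f:.2f}, p = {trend.p:.3g}")

sel = select_random_structure(data, "SleepVariability")
print(sel.final.report_line("eri"), f"[random: {sel.chosen}]")
```

Output:

```
ERI age trend: F(2, 447) = 0.46, p = 0.632
SleepVariability ~ eri: t(165.798) = -4.291, b = -1.886, p <0.001 [random: intercept]
```

Reading: in this synthetic cohort the latent regularity trait is
age-constant, so the ERI shows no age trend (F ≈ 0.5, n.s.), while the
configured slope of −2 of Sleep Variability on regularity is recovered
through the ERI as b = −1.89 (the small shrinkage is the documented
measurement-error attenuation of a diary-based index), highly
significant with Satterthwaite df ≈ 166, and AIC keeps the
random-intercept structure.

The same flow from the shell:

```bash
eatrhythm run --out results/demo --seed 1        # full pipeline
eatrhythm eri --diaries meals.csv --out eri.csv  # single stage
eatrhythm select-k --diaries meals.csv --candidates 1..10 --out sma.csv
```

`eatrhythm run` writes per-stage CSVs (`eri.csv`, `markers.csv`,
`model_coefficients.csv`, `mediation.csv`), a `report.md` assembled from
those CSVs, a log, and the resolved `config.yaml` for provenance.

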