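# healthrank

Objective multi-criteria ranking of health-system performance.
`healthrank` takes a decision matrix — countries (or any alternatives)
scored on indicators with benefit/cost directions — derives criterion
weights from the data with **CRITIC**, ranks the alternatives with
**MAIRCA** and **MARCOS**, and quantifies how much the two rankings
agree. It ships the 27-country × 6-indicator OECD health-system matrix
(life expectancy, health spending per capita, avoidable mortality,
chronic disease morbidity, infant mortality, maternal mortality) as an
embedded fixture, so the full analysis runs out of the box.

The package is aimed at health-policy analysts and anyone comparing
alternatives on conflicting indicators without hand-picked weights.

## Methods

**CRITIC** (Criteria Importance Through Intercriteria Correlation)
weights criterion *j* by its information content on the min-max
normalized matrix *r*:

```
σ_j = sd(r_·j)                    (sample, m − 1)
C_j = σ_j · Σ_k (1 − ρ_jk)        (contrast × conflict, Pearson ρ)
w_j = C_j / Σ_k C_k
```

**MAIRCA** gives every alternative uniform prior preference `P = 1/m`,
builds a theoretical evaluation matrix `Tp_ij = P·w_j` and a real one
`Tr_ij = Tp_ij · r_ij`, and scores each alternative by its total gap
`G_i = Σ_j (Tp_ij − Tr_ij)` — the smaller, the better.

**MARCOS** appends ideal (per-column best) and anti-ideal (worst)
reference rows, ratio-normalizes so the ideal row equals 1
(`x_ij/x_AI_j` for benefit, `x_AI_j/x_ij` for cost), weights, sums to
`S_i`, forms utility degrees `K⁺ = S_i/S_AI`, `K⁻ = S_i/S_AAI`, and
combines them with the compromise utility function

```
f_i = (K⁺ + K⁻) / (1 + (1 − f(K⁺))/f(K⁺) + (1 − f(K⁻))/f(K⁻)),
f(K⁺) = K⁻/(K⁺+K⁻),  f(K⁻) = K⁺/(K⁺+K⁻)
```

— the larger, the better. Alternative normalization and utility
variants (anti-ideal-referenced cost normalization; simple mean of the
utility degrees) are available behind flags; see `docs/methods.md`.

Agreement between the two rankings is measured with Spearman's ρ plus
per-alternative rank shifts and top-k/bottom-k stability sets.

## Worked example

```python
from healthrank import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(fixture="oecd"))
print(report.weights.as_dict()["C2"])          # 0.22254995044167622
print(report.mairca.score_of("Switzerland"))   # 0.0029071961374034306
print(report.marcos.score_of("Switzerland"))   # 0.7769700110796784
print(round(report.concordance.rho, 4))        # 0.9591
```

Health spending per capita (C2) gets the largest CRITIC weight
(≈0.2225); the importance ordering is C2 > C1 > C3 > C5 > C6 > C4.
Switzerland has the smallest MAIRCA total gap (0.002907196, rank 1 of
27) and the highest MARCOS utility (0.776970011, rank 1), while Mexico
ranks last under both methods. The two rankings agree at ρ = 0.9591
(Σd² = 134), with Switzerland, Sweden, Denmark and Japan in the top
five of both methods and Costa Rica, Hungary, Mexico and Türkiye in
the bottom five of both.

The same run from the shell:

```bash
healthrank run --fixture oecd --out results/oecd
healthrank weights --fixture oecd
healthrank synth --spec spec.yaml --seed 42 --out synthetic.csv
```

Your own data go in as a CSV with a header of criterion codes plus a
YAML config mapping each code to `{direction: benefit|cost, name: ...}`;
see `tests/test_pipeline.py` for a round-trip example.

The numbered scripts under `analysis/` re-run each stage of the OECD
analysis as a narrative (weights, rankings, concordance, noise
sensitivity) and write their tables under `results/`.

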