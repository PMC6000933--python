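# feedquant

Feed-efficiency quantitative genetics for poultry feeding trials: derive
residual feed intake (RFI) and feed conversion ratio (FCR) from daily
feeding-station records, estimate heritabilities and genetic/phenotypic
correlations with a pedigree animal model by REML, compare the efficiency of
indirect selection, and analyse candidate SNPs (Hardy-Weinberg, linkage
disequilibrium, EM haplotype frequencies, genotype-trait association with
LSD letters). A synthetic-data generator with known ground truth makes every
stage testable without access to real birds.

Intended users: animal breeders and quantitative-genetics students working
with growth/intake trials (chickens in particular), and anyone needing a
small, transparent, fully tested reference implementation of the
RFI/animal-model/candidate-gene workflow.

## The model in brief

Per bird, body weight over the test window is linear, BW = μ + a·DOT + e,
with slope a = ADG; mid-test metabolic weight is MMBW = (μ + a·25)^0.75.
Within each sex, expected feed intake is the regression

    ADFI = b0 + b1·MMBW + b2·ADG + e

and **RFI is the residual e** — intake not explained by maintenance and
growth — so ADFI ≡ EFI + RFI, within-sex ΣRFI = 0, and RFI is orthogonal to
MMBW and ADG by construction. FCR = total feed / weight gain.

Genetic parameters come from the animal model y = Xb + Za + e with
a ~ N(0, A σ²ₐ), A the pedigree relationship matrix; single- and two-trait
average-information REML (EM fallback) yields h² = σ²ₐ/(σ²ₐ+σ²ₑ),
r_g = G₁₂/√(G₁₁G₂₂) and r_p. The relative efficiency of indirect selection
is (h₁/h₂)·r_g. SNP-side: 1-df chi-square HWE tests, EM haplotype
frequencies for locus pairs (double heterozygotes resolved by posterior
weight h₁₁h₂₂/(h₁₁h₂₂+h₁₂h₂₁)), Lewontin D′ and r², and per-SNP GLM
association Y = μ + genotype + family + sex + e with type-III F-tests and
LSD compact letters. See `docs/methods.md` for assumptions and numerical
choices.

## Worked example

Simulate a study-scale trial (1,220 phenotyped birds, 50-day window, 10
candidate SNPs), derive phenotypes and contrast the RFI deciles:

```python
import feedquant as fq
from feedquant import simulate as sm

cfg = sm.default_config(seed=1)
pop = sm.simulate_population(cfg)
pheno, models = fq.derive_phenotypes(pop.records)
m = models["M"]
print(f"EFI[M]: ADFI = {m.b0:.3f} + {m.b1:.3f}*MMBW + {m.b2:.3f}*ADG "
      f"(R2={m.r_squared:.3f}, n={m.n_birds})")
print(fq.decile_contrast(pheno).round(3).loc[["RFI", "FCR", "ADG", "ADFI"]])
```

```
EFI[M]: ADFI = -9.271 + 0.377*MMBW + 0.544*ADG (R2=0.657, n=600)
       mean_high  sd_high  mean_low   sd_low  difference  p_value  n_per_group
trait
RFI       10.622    2.573   -10.638    2.558      21.260    0.000          120
FCR        4.409    0.551     3.302    0.305       1.107    0.000          120
ADG       21.362    4.195    21.854    4.115      -0.492    0.360          120
ADFI      90.638   12.090    70.163   11.876      20.475    0.000          120
```

Reading this: the male expected-intake equation attributes 0.377 g of feed
per g^0.75 of metabolic weight and 0.544 g per g/day of gain (R² = 0.657).
The highest-RFI decile eats 20.5 g/day more and converts feed 1.1 FCR units
worse than the lowest decile, while growing at the same rate (ADG
P = 0.36) — the signature of RFI as a measure of metabolic efficiency
rather than growth.

SNP-side, the genotype class counts 59/220/248 at a candidate locus conform
to Hardy-Weinberg proportions, and combining heritabilities with a genetic
correlation gives an indirect-selection efficiency:

```python
print(fq.hwe_test((59, 220, 248), locus="C334A"))
print(round(fq.selection_efficiency(0.282, 0.288, 0.334, "RFI", "ADFI").efficiency, 3))
```

```
HWEResult(locus='C334A', n_hom_minor=59, n_het=220, n_hom_major=248,
          p=0.3207, chi2=0.923, p_value=0.337, conforms=True)
0.327
```

The same stages are available as CLI subcommands (`feedquant simulate`,
`derive-phenotypes`, `estimate`, `popgen`, `associate`, `run-all`); `run-all`
writes TSV analogues of the six standard report tables plus a JSON summary
and a log with the seed and package versions.

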