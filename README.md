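# scatniche

Dietary-niche and trophic-level analysis of predator scat data, built for
the question of how a native predator's diet responds when an invasive prey
species becomes abundant. The motivating system is the Neotropical river
otter (*Lontra longicaudis*) in northern Guatemala, where the invasive
armored catfish (*Pterygoplichthys* spp., a low-trophic-level detritivore)
now dominates the otter's diet in invaded rivers; the methods are generic
for any scat-based diet study with river/year (or site/period) grouping.

## What it computes

Given long-format scat records (one row per scat × prey taxon), per-scat
stable-isotope values, and a prey reference table (fractional trophic level
and maximum total length per taxon), the package computes per
(river, year) group:

* **Occurrence tables** — record counts, % of scats containing each taxon
  (%S) and each taxon's share of all prey records (%R, the
  diet-composition proportions p_j).
* **Levin's niche breadth** — B = 1/Σp_j², standardized
  B_a = (B−1)/(n−1) ∈ [0, 1], with percentile confidence intervals from
  resampling whole scats with replacement (1000 replicates by default).
* **Species-accumulation curves** — the sample-based (Mao Tau) expected
  richness τ(h) = S_obs − Σ_j α_jh·S_j with
  α_jh = (H−h)!(H−j)!/((H−h−j)!H!), evaluated in log-gamma space, plus a
  scat-bootstrap band.
* **Fractional trophic level** — the Pauly–Palomares consumer level
  FTL_i = 1 + Σ_j FTL_j·DC_ij with DC_ij the %R-based diet proportions,
  unknown-FTL taxa excluded and renormalized; and conversion of δ¹⁵N
  differences to trophic-level shifts via the 3.4 ‰-per-level trophic
  enrichment factor.
* **Isotope statistics** — δ notation (δ = (R_sample/R_standard − 1)·1000),
  group variances of δ¹⁵N/δ¹³C as isotopic niche widths with omnibus and
  pairwise Levene tests, Shapiro–Wilk normality advisories, a two-factor
  (river × year) Type-I ANOVA on log δ¹⁵N, and pairwise t-tests with
  Bonferroni correction.

A synthetic-data module generates scat collections and isotope samples
with known ground truth (including the exact record proportions induced by
within-scat sampling without replacement), and a packaged fixture expands
the study's printed occurrence table into a deterministic scat-level
collection.

## Worked example

```python
import scatniche as sn

collection = sn.table3_fixture()            # 285 scats, 5 river-year groups
occ = sn.tabulate_occurrences(collection)

res = sn.standardized_levins(occ.counts("Pasion", 2015))
print(round(res.b, 2), round(res.b_a, 2), res.n_taxa, res.classification)
# 3.68 0.18 16 specialist

catfish = occ.proportions("Pasion", 2015)["Pterygoplichthys spp"]
print(round(100 * catfish, 1))              # 49.3  (% of diet records)

ref = sn.filter_prey_by_length(sn.packaged_prey_reference(), 100.0)
ftl = sn.fractional_trophic_level(occ.counts("Pasion", 2015), ref)
print(round(ftl.ftl, 2))                    # 3.43  (consumer trophic level)

print(round(sn.ftl_shift_from_d15N(2.78), 1))  # 0.8  (trophic levels per 2.78 permil)
```

Interpretation: in the invaded Pasión River, seven years after the catfish
invasion, one prey dominates the diet (B_a = 0.18, specialist side of the
0.4 cutoff), the catfish alone accounts for 49.3 % of prey records, and the
otter feeds about half a trophic level lower than a piscivore-only diet
would imply — the catfish's low trophic level pulls the consumer down.

The same analyses run from the shell:

```bash
scatniche niche --scats scats.csv --n-boot 1000 --seed 17 --out niche.csv
scatniche report --config config.yaml     # full pipeline, all tables
scatniche simulate --scenario docs/example_scenario.yaml --seed 17 \
    --out-scats scats.csv --out-iso iso.csv
```

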