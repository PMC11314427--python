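# nichecol

Niche dynamics of periphytic-algal colonization.

When algae colonize a fresh substrate in flowing water, the community
passes through recognizable phases — initial colonization by pioneer
diatoms, rapid community formation, then primary succession in which
competition sorts winners from losers. `nichecol` is a Python toolkit for
analyzing such colonization time series (species x sample count tables
with collection days and replicates, optionally with water chemistry)
through niche theory, for ecologists working on periphyton, biofilms, or
any repeated-sampling community series where the same questions arise.

For each colonization stage it computes, per species i over the stage's
r samples (P_ij = n_ij / N_i the utilization profile):

* dominance **D_i = (N_i/N) · f_i** (relative abundance x occurrence
  frequency; D_i ≥ 0.02 ⇒ dominant),
* Levins' standardized niche width **B_i = 1 / (r Σ_j P_ij²)** ∈ [1/r, 1],
* Pianka's niche overlap
  **O_ik = Σ_j P_ij P_kj / √(Σ_j P_ij² Σ_j P_kj²)**,
* resource-occupancy change **ΔO_i = Σ_{k≠i}(A_ik − A_ki)** from the
  directed overlap A_ik = Σ_j P_ij P_kj / Σ_j P_kj² (what i captures from
  others minus what others capture from i; Σ_i ΔO_i = 0),
* ecological response rate **R_i = B_i · ΔO_i**,

plus the pairwise framework (B_ik, ΔO_ik, R_ik, O_ik), alpha diversity
(Chao1, Shannon, Pielou J), Bray–Curtis and environmental Euclidean
distances with globally normalized dissimilarities
**Xd = Bray/(Bray_max + 0.001)** and Ed, Baselga's turnover/nestedness
partition of beta diversity, PCoA, seeded PERMANOVA / PERMDISP / ANOSIM,
RDA with a permutation test, exact dynamic-programming stage
segmentation, and a synthetic colonization-series generator with known
ground truth. See `docs/methods.md` for the model details and design
choices.

## Worked example

Simulate a default 45-day colonization series (150-species pool, samples
every 3 days, 4 replicates) and inspect the formation-stage niche table:

```python
import nichecol as nc
from nichecol.simulate import SimulationConfig, simulate_colonization

bundle, truth = simulate_colonization(SimulationConfig(seed=1))
part = nc.assign_stages(bundle.meta, nc.DEFAULT_STAGE_RANGES)
stages = nc.split_by_stage(bundle, part)

rec = nc.stage_niche_records(stages["T2"], nc.AnalysisConfig())
print(rec.sort_values("Di", ascending=False).head(5).round(3))
```

```
                   phylum     Di   fi     Bi     dOi      Ri  dominant
species
Het007   Heterokontophyta  0.130  1.0  0.913 -22.044 -20.126      True
Het002   Heterokontophyta  0.098  1.0  0.960 -28.927 -27.766      True
Het005   Heterokontophyta  0.089  1.0  0.933 -25.796 -24.058      True
Het004   Heterokontophyta  0.089  1.0  0.903 -24.206 -21.869      True
Het006   Heterokontophyta  0.080  1.0  0.925 -24.486 -22.653      True
```

The formation stage here holds 106 species of which 11 are dominant —
early-arriving diatoms with near-maximal niche widths (mean B_i 0.90 vs
0.68 for non-dominants) and negative ΔO_i: wide-niche species are net
donors of resource occupancy, and the response rate R_i = B_i·ΔO_i is
correspondingly negative for dominants. Non-dominant species show larger
occupancy swings (mean |ΔO_i| 25.2 vs 22.8).

The same analysis runs end-to-end from the shell:

```bash
nichecol simulate --seed 42 --out sim/
nichecol run --counts sim/counts.csv --meta sim/metadata.csv \
             --taxa sim/taxa.csv --env sim/env.csv --seed 42 --out run/
```

`run/` then contains tidy CSVs (per-stage niche records, overlap pairs,
the pairwise framework, alpha diversity, distances, Xd/Ed by stage, beta
partition, PCoA/RDA axes, permutation-test JSONs) and a `summary.json`
that is byte-identical across reruns with the same inputs and seed.

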