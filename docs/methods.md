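# Methods

`nichecol` analyzes periphytic-algal colonization time series — repeated
scrapes of artificial substrates in flowing water, identified and counted
to species — through the lens of niche theory: who dominates, how wide
each species' niche is, who takes resources from whom, and how community
composition and its environmental context turn over as colonization
proceeds.

## Data model

A dataset is a bundle of four aligned tables: an integer abundance matrix
(taxa x samples), sample metadata (collection day, replicate), a
species-to-phylum map, and an optional samples x variables table of water
chemistry (TN, NH3-N, NO3-N, TP, PO4-P, CODMn, T, DO, SPC, pH). Taxa and
samples are canonicalized to lexicographic order at load time so that any
seeded permutation test gives the same answer regardless of input file
order. Missing environmental values are a hard error — no imputation.

Samples are assigned to colonization stages either by configured day
windows (defaults: initial colonization T1 = days 3–6, community
formation T2 = days 12–18, primary succession T3 = days 24–27; days
outside every window are excluded from stage statistics as "unassigned")
or by `auto_segment`, an exact dynamic program that partitions the
day-ordered series into k time-contiguous blocks minimizing the within-
block sum of squared Bray–Curtis distances. The DP never splits replicates
of one day and breaks ties toward the earliest boundaries; its objective
is verified against brute-force enumeration in the tests.

## Niche statistics

Within a stage, the resource states are that stage's samples, with
replicates kept as distinct states (how the original field replicates
were pooled is unknowable from the study description; keeping them
separate is the convention of the R `spaa` package and preserves
within-day heterogeneity). Species absent from a stage are dropped from
that stage's species set before any metric. For species i with counts
n_ij over the stage's r samples, N_i = Σ_j n_ij, grand total N:

* utilization profile  P_ij = n_ij / N_i;
* dominance  D_i = (N_i / N) · f_i, with f_i the fraction of samples where
  the species occurs. Species with D_i ≥ 0.02 are classified dominant.
  The threshold is the McNaughton convention common in plankton and
  periphyton work and is configurable; ties sit on the dominant side.
* Levins' standardized niche width  B_i = 1 / (r · Σ_j P_ij²) ∈ [1/r, 1];
* Pianka's symmetric overlap
  O_ik = Σ_j P_ij P_kj / sqrt(Σ_j P_ij² · Σ_j P_kj²);
* directed (MacArthur–Levins) overlap  A_ik = Σ_j P_ij P_kj / Σ_j P_kj²,
  read as the share of k's utilization captured by i;
* resource-occupancy change  ΔO_i = Σ_{k≠i} (A_ik − A_ki): what i
  occupies from others minus what others occupy from i. A definition of
  ΔO_i as a difference of symmetric-overlap sums is identically zero, so
  the directed matrix is the only self-consistent reading; the
  antisymmetric pairing guarantees Σ_i ΔO_i = 0 exactly, which the tests
  enforce to 1e−9 on random tables.
* ecological response rate  R_i = B_i · ΔO_i (product mode, the default:
  defined everywhere, zero in occupancy balance, negative for wide-niche
  net losers — the signature of dominants). A ratio mode B_i / ΔO_i is
  available but undefined at ΔO_i = 0 and not recommended.

Pairwise signed differences B_ik = B_i − B_k, ΔO_ik, R_ik together with
O_ik form the three-way evaluation framework exported per stage. Group
summaries average the per-species metrics by stage x phylum x dominance
class and report dominant-minus-non-dominant and phylum-vs-rest gaps;
empty groups are omitted rather than imputed.

A useful first-order approximation, which drives several design choices
below: because profiles are row-normalized, A-asymmetries reduce to
ΔO_i ≈ Σ_k C_ik · r · (B_k − B_i) with C_ik = Σ_j P_ij P_kj ≥ 0. A
species' occupancy change is therefore roughly proportional to how far
its niche width sits from the overlap-weighted community mean — wide
generalists are net donors, concentrated newcomers net gainers.

## Diversity and dissimilarity

* Bray–Curtis on raw counts by default (a relative-abundance switch
  exists); Euclidean distances on environmental variables, z-scored by
  default because the variables differ in scale by four orders of
  magnitude (SPC ~218 vs PO4-P ~0.01); zero-variance variables are
  dropped under standardization.
* Normalized dissimilarities Xd (community) and Ed (environment) divide
  every pairwise value by the global maximum over the full dataset plus
  0.001 (the epsilon guards exact-zero similarity); a stage's value is
  the mean over its within-stage pairs only.
* Alpha diversity: observed richness, bias-corrected Chao1
  S_obs + F1(F1−1)/(2(F2+1)) (the classic form is not offered — it is
  singular at F2 = 0), Shannon H with natural log, Pielou J = H / ln S_obs
  (undefined and flagged for S_obs ≤ 1). Natural log is required for J's
  0–1 range.
* Beta diversity is partitioned into species turnover and nestedness with
  the Sørensen/Simpson (Baselga) family on presence–absence data:
  pairwise β_sor = β_sim + β_sne exactly, and Baselga's multi-site
  partition per stage with turnover/nestedness shares of total β. The
  Jaccard-family and abundance-based partitions are out of scope.
* Environmental summary: per-stage mean, sample SD, CV% = 100·SD/mean
  (flagged where the mean is zero).

## Ordination and permutation inference

PCoA Gower-double-centers −½D², eigendecomposes, orders axes by
decreasing eigenvalue and scales coordinates by √λ. Negative eigenvalues
(Bray–Curtis is not Euclidean-embeddable) are reported verbatim and
excluded from percent-variance denominators; no Cailliez/Lingoes
correction is applied by default.

PERMANOVA uses Anderson's one-way pseudo-F from within/between sums of
squared distances; ANOSIM ranks all pairwise distances and compares
between- to within-group mean ranks, R = (r_B − r_W)/(M/2); PERMDISP
embeds the samples by PCoA, measures each sample's distance to its own
group centroid (the group mean — not the spatial median), computes a
one-way F over those distances, and permutes group labels over them (the
scheme of vegan's `permutest.betadisper`). All permutation tests draw
from one seeded generator and report p = (1 + #{perm ≥ obs})/(1 + n_perm),
never zero, bit-reproducible given (matrix, labels, seed, n_perm). The
observed statistics match scikit-bio's implementations exactly on shared
test cases; calibration is verified by simulation (type-I error of
PERMANOVA within [0.03, 0.07] at α = 0.05 over 500 null draws).

RDA Hellinger-transforms the species table by default (robust for sparse
counts; raw and chord transforms selectable), z-scores the environmental
matrix, reduces it to full column rank (collinear variables dropped with
a warning), projects the response onto the environmental space by least
squares, and decomposes the fitted values by SVD into constrained axes.
Axis percentages are reported against total variance, and
constrained + unconstrained variance equals total variance to machine
precision. The global test permutes response rows and compares the
pseudo-F (SS_fit/m)/(SS_res/(n−m−1)). For the per-stage dominant-species
RDA a stage has only 8–12 samples against 10 environmental variables, so
the variables are reduced to the (n−2) with highest within-stage CV%
before fitting; the selection is logged. Multi-factor designs, partial
RDA and variation partitioning are out of scope.

## Synthetic colonization series

No field data accompany the study design this package targets, so the
generator is a first-class module that produces series with the
statistical structure the analysis assumes: 15 sampling days (3, 6, …,
45), 4 replicate scrapes per day, a 150-species pool split
Heterokontophyta 90 / Cyanobacteria 25 / Chlorophyta 20 / Charophyta 10 /
Cryptista 5, phylum-structured arrival with diatoms first, rising
richness, total density rising and then declining after day 27, and
near-homogeneous chemistry drawn Normal(mean, SD) from the habitat-table
defaults (TN 1.18 ± 0.04 … pH 8.42 ± 0.01).

Species belong to three latent classes:

* **core** (designed dominants; 8 diatoms arriving days 1–3 plus 2
  cyanobacteria and 2 chlorophytes arriving days 6–9): carrying capacity
  ~2500 (mid-phyla ~1200), settlement inoculum 50 — dominant colonizers
  arrive early and at high propagule pressure, so the dominance index
  separates them from the background from the first sampling day;
* **ubiquitous** (45% of the background pool): arrive within the first
  week of their phylum's window at capacity ~150 and inoculum 10. They
  are the "present everywhere, never abundant" tier; their niche widths
  bracket the cores', which keeps the dominants near the middle of the
  breadth distribution — by the ΔO approximation above, that is what
  gives dominants their near-balanced occupancy change;
* **transient** (the rest): arrive continuously through the experiment at
  capacity ~3.5 with mortality 0.2–0.4 d⁻¹. They bloom briefly and fade
  as the community brake tightens — the ephemeral, concentrated-profile
  tail that donates occupancy to nobody for long and is replaced
  continuously, producing turnover-dominated beta diversity.

Latent dynamics are daily logistic steps toward each species' capacity
multiplied by a shared community brake (1 − X_total/K_total, K_total =
50 000) standing in for competition for space and nutrients, minus
class-specific mortality; pairwise interaction coefficients are not
modeled — the brake plus mortality suffice to produce the compression
and replacement patterns the analysis measures. After day 27 the whole
community is scaled by 0.92 per day (sloughing/senescence). Observed
counts are negative-binomial per replicate (gamma–Poisson, dispersion
15): replicate scrapes of attached biofilm are overdispersed, but strong
enough noise would swamp the planted class structure, so the default is
moderate. Absolute density scales are arbitrary — the study prints none —
and only patterns, not magnitudes, are matched.

What the generator does **not** emulate: true pairwise competition
coefficients, environmental forcing of the community (chemistry is
independent of counts unless a stage shift is planted), spatial structure
among substrates, detection/identification error beyond count noise, and
seasonal succession beyond the single decline phase. Tests passing on
this generator therefore certify the statistical machinery and the
internal consistency of the niche framework, not field-data behavior.

Determinism: one `numpy` generator seeded from the config drives species
assembly, dynamics and observation; identical config + seed give
bit-identical tables. Ground truth (class, arrival, capacity, growth,
mortality per species) is returned for recovery tests: designed dominants
must out-rank the background on the dominance index, and on 60 validation
seeds the qualitative patterns (richness ordering, dominant niche-width
advantage, turnover > nestedness, post-onset decline, Xd higher in the
formation than the succession stage) hold in 57–60 of 60 runs; the
dominant-vs-non-dominant |ΔO| contrast is the tightest at 57/60 — it
rides on the balance described above and single-seed exceptions occur in
the two-day T1 window, where only eight samples inform the profiles.

## Numerical choices and degenerate inputs

Ties at the dominance threshold are dominant. Both-empty sample pairs get
Bray–Curtis 0 with a warning; a fully empty stage is a hard error. The
PCoA eigenvalue cutoff for "positive" is 1e−10 relative to the largest
eigenvalue. The segmentation DP requires strict improvement (1e−15) to
move a boundary later, implementing the earliest-boundary tie-break.
Permutation counts below 99 are rejected. The pipeline writes every table
as CSV next to a `summary.json` whose numbers are each traceable to one
table; reruns with identical inputs, config and seed are byte-identical.

## Known limitations

The dominance cutoff (0.02) is a convention, not an estimate; published
stage-wise dominant lists can disagree with any fixed threshold. ΔO mode
"directed" is one resolution of an under-determined definition — the
config exposes the mode so alternative readings can be plugged in.
PERMDISP permutes residual distances rather than recomputing centroids
per permutation; for strongly unbalanced designs the two schemes can
differ. The per-stage RDA variable screening by CV% is pragmatic, not
inferential. The Xd-based stage comparison tests the distance matrix by
stage labels; comparing scalar per-pair dissimilarities directly between
stages would require a different (pair-level, non-exchangeable) null and
is not offered.
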