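# Methods

This note documents the models, conventions and numerical choices behind
the package, and what the simulator does and does not emulate.

## Study system and data model

Three parallel fishways pass a river intake dam, each with its own
hydraulics (defaults, configurable):

| fishway    | discharge (m³/s) | velocity (m/s) | length (m) |
|------------|------------------|----------------|------------|
| ice-harbor | 1.637            | 1.27–2.43      | 210        |
| stair      | 0.133            | 0.87–1.05      | 240        |
| rock-ramp  | 0.071            | 0.64           | 260        |

Water samples are taken hourly (9:00–17:00) at the three fishway
entrances (st2–st4) and at one upstream control point (st1) above the
split, so st1 measures the eDNA flowing into all three. Trap baskets at
the upstream end of each fishway are checked hourly 10:00–17:00. The
st→fishway mapping is a survey convention (default st2=ice-harbor,
st3=stair, st4=rock-ramp) and is configurable because nothing downstream
depends on the labels.

Dates are ISO-8601; times are integer hour slots — the survey operates
hourly and nothing in the analysis needs finer resolution.

## Read processing

The preprocessing chain mirrors the standard usearch-style 12S workflow.
Parameters and defaults:

* **Tail trimming**: truncate at the first base with Phred ≤ 2.
* **Merging**: best ungapped suffix–prefix overlap, minimum 16 nt (the
  protocol does not state a minimum; 16 nt makes a chance overlap at the
  5% mismatch level vanishingly unlikely for ~170 bp amplicons), rejected
  at > 5 mismatches in the overlap or merged length < 50 bp.
  Disagreements take the higher-quality base.
* **Quality filter**: expected errors E = Σ 10^(−Q/10); the "error rate
  > 1%" rule is read per base (reject iff E/len > 0.01) so that it scales
  with read length; the classic absolute-maxEE reading is available via
  `mode="absolute"`.
* **Dereplication**: exact-sequence grouping; abundance ≤ 3 (singletons,
  doubletons, tripletons) removed.
* **Denoising**: greedy UNOISE-style clustering in abundance order; a
  unique at edit distance d joins a centroid when its abundance ≤
  centroid_abundance / 2^(αd+1), α = 2 (the published default). Chimera
  detection is not implemented (no parameters are stated for it); the
  low-abundance filter plus the skew rule remove the error classes the
  synthetic data generates.
* **Taxonomy**: global alignment against every reference. Identity is
  defined as 1 − edit_distance / max(len_query, len_ref) — an
  alignment-invariant quantity (the naive "matches / alignment columns"
  differs between co-optimal alignments and is therefore not
  well-defined). Assignment requires identity strictly > 0.80. Ties
  between distinct references are merged into a single combined label
  (" / "-joined, sorted) and never split downstream, matching the field
  convention for indistinguishable candidate species. Edit distances use
  edlib; the test suite checks them against an independent full-DP oracle.
* No length ceiling is applied to merged inserts; the ~170 bp target
  length is informational only.

Read-count conservation holds by construction and is logged per stage:
input = rejected(merge) + rejected(primer) + rejected(quality) +
removed(low-abundance) + tabulated (assigned + unassigned).

## Attribution

Concentration = count × dilution / volume (reads per liter). Raw read
counts are not comparable between samples (PCR inhibitors, template
dilution, cycle saturation); the per-volume conversion with the recorded
dilution factor puts samples on one linear scale, which is all the
downstream analysis needs — the scale itself is arbitrary.

Attributable signal per (taxon, fishway, date, hour):
max(0, entrance − control), with exact slot matching and no interpolation
(all stations are sampled at the same times). Entrance slots without a
same-slot control partner are skipped and reported, not imputed.

Detection defaults to "any positive attributed signal" (threshold 0,
configurable — no numeric threshold is part of the protocol). Richness
for concordance is computed from the attributed table, because the
subtraction is what isolates fishway-derived eDNA; raw-station richness
can be computed by passing the unsubtracted concentrations through the
same functions.

## Composition

Case 1 categories: the five focal species individually, plus groups G1
(mainly ice-harbor), G2 (ice-harbor + stair), G3 (mainly rock-ramp), G4
(no clear preference). Unknown taxa default to G4. Case 2 splits G2 and
G3 by lifestyle (midwater / benthic), redistributing each group's
proportion by the underlying per-taxon shares, so the split is exactly
conservative (merging the subcategories recovers Case 1).

eDNA profiles are the arithmetic mean of per-day share vectors over the
index days — each analysed day is one compositional observation — not a
pooled-read ratio (pooling is available for sensitivity analysis via the
per-taxon shares). Days with zero total signal are skipped and logged
rather than imputed as uniform, which would fabricate signal. Capture
profiles pool total individuals over the whole survey period.

## Concordance

Windows around a 15:00 index slot: that hour, that day, ±3 days (7-day
span), ±7 days (15-day span), all closed/inclusive, so the slot sets nest
and capture richness is monotone along the chain. "That time" uses the
hourly basket, not the cumulative day.

Pearson r is computed from centered dot products; R² = r²; the two-sided
p-value uses the t transform with n − 2 df. Constant vectors and n < 3
are flagged and excluded rather than reported. No multiple-testing
correction is applied by default (results are reported per stratum ×
window, as the monitoring design does). For per-species concordance,
entrance signals and captures are pooled across fishways; per-fishway
restriction is available through the same functions. Index slots are
configuration (the bundled default is the survey design's eight 15:00
slots across two Junes), not hard-coded.

The statistics layer also exposes the two-sided Student-t critical value
(e.g. 2.447 at df = 6, α = 0.05) used when comparing overlap proportions
across survey years.

## Simulator

What it emulates: species-specific June migration pulses (Gaussian
seasonal mean with peak day and duration; daily totals Poisson; split
across fishways by preference weights and uniformly across hours);
eDNA shedding in a fishway with residence time τ = length / mean
velocity, first-order decay over τ, and dilution by discharge
(entrance = background + m·τ·shed·e^(−decay·τ) / (Q·3.6·10⁶ L/h));
fixed-depth multinomial sequencing; Poisson trap catches with optional
benthic transit lag; and primer-flanked amplicon reads with a uniform
per-base substitution error model and consistent Phred scores.

The recorded dilution factor scales with total sample DNA (concentrated
samples are diluted more before PCR, dilution = sample total / smallest
positive total), so count × dilution / volume reconstructs concentrations
on one common linear scale — the mechanism by which the fixed-depth
multinomial draw remains informative about absolute differences between
stations. This is an idealization of real dilution practice.

What it does not emulate: hydrodynamic transport and long-range
persistence (upstream eDNA arrives only through the static background
term), PCR amplification bias and inhibitor variation, chimera formation,
tag jumping, spawning-season eDNA spikes, and day-to-day environmental
covariates (temperature, turbidity). Passing recovery tests therefore
demonstrates that the analysis chain is correct and well-calibrated under
the generating model, not that field data of this shape will behave as
cleanly.

Default community: 12 species emulating the surveyed fauna — the five focal
species with their reported fishway preferences (e.g. ~82% of
*O. platypus* through the stair fishway, ~70% of *T. hakonensis* through
the ice-harbor fishway, the benthic focal species on the rock ramp) plus
G1–G4 representatives. Migration peaks sit in mid-June with durations of
6–24 days; daily maxima span 8–400 individuals/day; trap efficiency is
0.5. Shedding rates are order-of-magnitude placeholders on an arbitrary
linear scale (absolute eDNA copy numbers never enter the analysis);
background at st1 defaults to a small constant per species.

The recovery benchmark ("strong signal") uses zero background, zero
decay, uniform shedding 10⁷, depth 10⁵, 10 species, 20 days, trap
efficiency 0.5. Shedding is uniform there because the benchmark asks
whether migrant *counts* are recovered in rank; species-specific shedding
would confound the ranks by design. Recovery is measured per fishway
(Spearman over species within each fishway) because attributed
concentration scales inversely with discharge, which differs 23× between
fishways — within a fishway the discharge factor is constant and rank
recovery is meaningful.

## Problem sizes

The bundled analyses and tests run at desk scale by choice: simulated
seasons of 8–29 days at read depths of 2 000–100 000, amplicon runs of a
few thousand read pairs, and property suites of 200–1000 random tables.
These sizes are where the distributional checks (Monte-Carlo means within
5%, law-of-large-numbers proportions within 3σ) are already tight; the
pipeline itself is linear in samples and reads.

## Known limitations

* The amplicon merger assumes the insert is longer than a single read
  (no read-through/adapter trimming).
* Primer search scans the whole merged read; a spurious interior primer
  site (possible in adversarial synthetic sequences) would shorten the
  insert.
* The benthic capture lag clamps arrivals into the same day's basket
  slots rather than carrying them to the next day.
* The attributed scale is relative; nothing in the package estimates
  absolute biomass or eDNA copy number, and no transport-distance
  correction is applied.
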