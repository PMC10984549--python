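# fishway-edna

Environmental-DNA (eDNA) monitoring of fish passage through multiple
fishways, as a tested, reusable analysis pipeline.

## The problem

Dams interrupt river continuity; fishways restore it, but verifying that
they work has traditionally required trap surveys — catching every fish at
the upstream end of each fishway, hourly, for a month. That burdens the
fish and requires large field crews. eDNA metabarcoding of water samples
(a universal fish 12S marker amplified from filtered river water) offers a
low-burden alternative, but a fishway is a hard setting: the water entering
it already carries eDNA from the whole upstream community, so the signal of
fish *in the fishway* must be isolated, and a water sample integrates eDNA
over an unknown time span, so eDNA detections must be matched to capture
records over the right temporal window.

This package implements that analysis chain for a system of three
hydraulically distinct fishways (ice-harbor, stair, and rock-ramp type)
sampled at their downstream entrances (stations st2–st4) with an upstream
control station (st1), together with a ground-truth simulator so every
stage is testable without field data.

## The method

1. **Read processing** (`read_processing`): paired-end amplicon reads are
   tail-trimmed at Phred ≤ 2, merged (rejecting pairs with > 5 overlap
   differences or merged length < 50 bp), primer-trimmed (IUPAC-aware),
   quality-filtered at expected-error rate > 1%, dereplicated with
   singletons/doubletons/tripletons removed, denoised into ASVs by a
   UNOISE-style abundance-skew rule (a variant at edit distance *d* is
   absorbed by a centroid when its abundance ≤ centroid / 2^(αd+1), α = 2),
   and assigned taxonomy by global alignment, accepted only at identity
   strictly > 80%. Indistinguishable candidate species are merged into one
   combined label.
2. **Attribution** (`attribution`): counts are converted to reads per liter
   (count × dilution / volume), and the fishway-attributable signal is

       A(s, f, t) = max(0, C(s, entrance_f, t) − C(s, st1, t))

   per taxon *s*, fishway *f* and (date, hour) slot *t* — the control
   station is subtracted slot-by-slot and negative differences are zero.
3. **Composition** (`composition`): per-fishway profiles over the five
   focal species (*O. platypus*, *T. hakonensis*, *P. altivelis*,
   *C. biwae*, *R. kurodai*) plus usage groups G1–G4 (Case 1), with G2/G3
   split into midwater/benthic lifestyles (Case 2). eDNA profiles are the
   mean of per-day share vectors over index days; capture profiles pool
   individuals over the survey period.
4. **Concordance** (`concordance`): each day's 15:00 eDNA result is paired
   with capture results over four nested windows — that hour, that day,
   ±3 days, ±7 days — and Pearson r / R² / p (t transform, n−2 df) is
   computed per fishway and per focal species, plus eDNA/capture species
   overlap summaries.
5. **Simulator** (`simulate`): Gaussian-pulse migrations split across
   fishways by preference weights, eDNA shedding diluted by fishway
   discharge with first-order decay over residence time, fixed-depth
   multinomial read sampling, and Poisson trap catches — all
   seed-deterministic, with ground truth returned.

## Worked example

The numbered scripts under `analysis/` run the chain on a simulated
29-day season (12 species, 50 000 reads/sample) and write their tables
under `results/`:

```bash
python analysis/01_simulate_season.py --seed 1
python analysis/02_process_reads.py --seed 1
python analysis/03_attribute_signal.py
python analysis/04_composition_profiles.py
python analysis/05_concordance_windows.py
```

With seed 1 this prints, among other lines:

```
5226 read pairs in -> 10 ASVs
  10/10 reference species recovered at exact abundance
  contaminant ASVs surviving: 0
...
  ice_harbor: top eDNA categories P. altivelis=0.44, T. hakonensis=0.41, O. platypus=0.04
  stair: top eDNA categories P. altivelis=0.35, T. hakonensis=0.28, O. platypus=0.26
  rock_ramp: top eDNA categories R. kurodai=0.40, G3=0.32, G4=0.07
  rock-ramp G3 benthic:midwater = 0.221:0.101
...
  richness r (that_time): 0.801 (p=0.000)
  overlap: 12 both / 0 eDNA-only / 0 capture-only (100.0% of eDNA species also caught)
```

Read: the amplicon pipeline recovers the generating species table exactly
on clean reads and drops spiked low-abundance contaminants; the attributed
composition reproduces each fishway's character (the midwater migrants
dominate the high-flow fishways, the benthic species the rock ramp, with
the benthic G3 share about twice the midwater share); and eDNA richness at
15:00 tracks capture richness across the window chain.

There is also a `fishway-edna` CLI (`validate`, `simulate`,
`process-reads`, `attribute`, `composition`, `concordance`, `run-all`)
wrapping the same library calls.

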