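# Methods

## Problem setting

`glycoquant` analyzes site-specific N-glycosylation of tissue pairs
profiled by intact-glycopeptide LC-MS/MS with isobaric (TMT) labeling.
The experimental unit is the glyco-PSM: one MS/MS spectrum matched to a
peptide carrying a specific glycan composition at a specific
asparagine, with one reporter-ion intensity per TMT channel.  The
default design is a 4-plex of pooled samples: paracancer and tumor
tissue from hepatocellular-carcinoma patients with low serum AFP
(channels 126 and 127N) and with high serum AFP (128C and 129N).
Because each pool occupies a single channel there are no replicates;
all downstream calls are fold-change based, and the package's test
surface is *recovery of planted effects in simulation*, not
statistical inference.

## Glycan model

A composition is a 4-vector of counts (HexNAc, Hex, Fuc, NeuAc),
written `N#H#F#S#`.  Subtypes are assigned by composition rules that
partition all valid compositions:

| subtype | rule |
|---|---|
| oligo-mannose | HexNAc = 2, Hex >= 4, NeuAc = 0 (fucose allowed) |
| hybrid | HexNAc >= 3 and Hex > HexNAc + 1 |
| complex | HexNAc >= 3 and Hex <= HexNAc + 1 |
| pauci/other | everything else (truncated cores such as N2H3) |

Fucosylated oligo-mannose compositions are classified as oligo-mannose
without asserting the fucose position: composition data cannot
distinguish core from antennary placement, so the package uses a
first-fucose-is-core heuristic with an optional per-composition
override table for structure-level knowledge (e.g. antennary-only
glycans).  Bisecting GlcNAc is likewise not inferable from counts;
`bisecting` is a tri-state that defaults to "unknown" and is resolved
only through an annotation file.  Antenna number for complex glycans
is HexNAc − 2 (one GlcNAc per branch beyond the chitobiose core),
minus one if bisecting is annotated, clamped to 1–6.

Monoisotopic masses are residue-mass sums (HexNAc 203.07937, Hex
162.05282, dHex 146.05791, NeuAc 291.09542 Da) for the glycan moiety
only.

## Normalization

Channel loading differences are removed with factors derived from the
global-proteome PSMs only (glyco-PSMs are enrichment-biased and never
contribute).  For each complete protein PSM the intensity vector is
divided by its geometric mean across channels, making it scale-free;
the factor for a channel is the median of these relative values over
all PSMs.  Dividing intensities by the factors equalizes channel
medians.  On a channel uniformly scaled by *c* in a 4-plex the factors
are exactly c^(3/4) on that channel and c^(−1/4) elsewhere, and all
post-normalization ratios are unchanged — both properties are tested
in closed form.

Reporter isotope-impurity correction is not implemented; inputs are
assumed to be impurity-corrected upstream if at all.  This is a known
limitation.

## Quantitation

Features are glycopeptides (protein x glycosite x glycan) or proteins
(accession).  A feature is quantified only if it has at least
`min_psms` (default 5) PSMs with a complete, positive reporter vector.
The feature's channel value is the median of normalized PSM
intensities per channel; each named comparison is the log2 ratio of
two channel values.  The median is taken per channel and then ratioed
(rather than a median of per-PSM ratios) so that one set of channel
values serves every comparison consistently; with complete PSM vectors
the two estimators are near-identical, and the per-channel form is
associative across multi-comparison designs.

Glycosylation occupancy change is the glycopeptide log2 ratio minus
the parent protein's log2 ratio (parent matched by accession alone —
one protein ratio per protein).  It isolates glycosylation-level from
expression-level change: a pure protein-abundance shift cancels to an
occupancy change of zero.  Glycopeptides whose parent protein is not
quantified carry no occupancy value and are ineligible for
occupancy-gated calls.

## Differential cascades

All thresholds are inclusive: |log2 r| >= log2(cutoff) is changed,
<= is stable.

**Commonly altered** (cutoff 2.0): up requires the tumor/paracancer
ratio >= cutoff in *both* AFP groups; down requires both <= 1/cutoff.
Features crossing the cutoff in opposite directions in the two groups
are labelled `none` and flagged `discordant`; they are reported but
form no changed set.

**Group-unique** (cutoff 1.5): low-AFP-unique requires tumorL/tumorH
>= cutoff *and* paracancer stability — the paraL/paraH comparison
within the cutoff at the glycopeptide, parent-protein and occupancy
levels simultaneously.  High-AFP-unique is symmetric.  The
three-level paracancer gate removes patient-pool-level confounders:
an expression-level difference between the patient pools moves the
protein and glycopeptide paracancer ratios together (and is caught at
those gates, with zero occupancy effect), while a patient-level
glycosylation difference is caught at the glycopeptide and occupancy
gates.  No per-feature test statistic is used anywhere: the pooled
design provides no replicate-based variance estimate.

## Over-representation test

A generic one-sided hypergeometric test replaces web-service GO/KEGG
enrichment.  For each user-supplied term set, p = P(X >= k) with
population = background, successes = term ∩ background, draws =
selected.  Retention requires overlap >= 3 ("count > 2") and raw
p < 0.05; a Benjamini-Hochberg column over all tested terms is emitted
for reference but does not filter, matching the raw-p convention of
the workflow the test replaces.  The recommended background is the set
of quantified glycoproteins of the run, not a whole proteome; both are
accepted.

## Synthetic data

The generator emulates the deposited PSM-table structure so every
stage is testable without downloads:

* **Catalog**: ~200 glycoproteins, sites per protein = 1 + Poisson(0.8),
  glycans per site = 1 + Poisson(1.8) (≈1,000 glycopeptides in
  expectation).  Compositions are drawn from a fixed pool of 37
  real-world compositions weighted to give ≈59.8 / 29.1 / 11.1 %
  complex / oligo-mannose / hybrid PSM mass, with N4H5S2 the single
  most site-prevalent glycan as in liver tissue.  A random 35% of
  proteins are marked endomembrane-like and receive boosted
  oligo-mannose weights (high-mannose glycans reside in the ER/Golgi);
  the boost and its complement are solved in closed form so the
  marginal subtype mix is preserved.
* **Intensities**: per-glycopeptide log2 baselines ~ Normal(20, 3.3)
  (≈4 orders of magnitude, stressing median robustness); PSM counts
  1 + NB(mean 7, size 4) (total mean ~8); per-PSM per-channel
  log-normal noise sigma = 0.25 log2 units; fixed per-channel loading
  factors (1.0, 1.3, 0.75, 1.15) that normalization must remove.
  Protein PSMs are generated analogously (count mean ~15) for the
  glycoproteins plus 100 non-glyco background proteins.
* **Planted effects** (fractions of the catalog, defaults): common
  tumor effects 2.5% up + 2.5% down at 4-fold; group-unique effects 3%
  per group at 2-fold (one tumor channel only); protein-driven
  effects 3% at 2-fold — whole proteins shifted in both tissues of one
  patient pool, i.e. an expression-level confounder with zero
  occupancy effect; occupancy-shift effects 2% at 2-fold — the
  glycopeptide alone shifted in both tissues of one pool.  Ground
  truth records the exact per-comparison log2 effect at the
  glycopeptide, protein and occupancy levels.

All randomness flows through one NumPy PCG64 generator; every output
is bit-reproducible per seed.

**What the simulation does not model**: identification error and decoy
FDR, missing reporter channels, TMT isotope impurity, peptide-level
interference/ratio compression, shared peptides across proteins, and
correlated biological variation between glycopeptides of one protein.
Passing recovery tests therefore demonstrates the correctness of the
quantitation and calling logic under the stated noise model, not
end-to-end performance on raw instrument data.

## Recovery scoring

`evaluate_recovery` reports, per planted label, precision and two
recalls: `recall` over all planted features (features that never
reached the >= 5-PSM quantitation depth count as misses) and
`recall_quantified` over planted features that were quantified.  The
second is the cascade's own recovery measure: under the default
PSM-depth distribution ~20–25% of glycopeptides fall below 5 PSMs by
sampling alone, which bounds all-planted recall regardless of the
caller.  Both numbers are reported side by side.

## Problem sizes and numerical choices

Default test and acceptance runs use the default configuration
(~1,000 glycopeptides, ~7,500 glyco-PSMs, ~300 proteins), which the
package processes in a few seconds; the exact-oracle sweeps
(hypergeometric tails for all populations <= 30, subtype partition for
all counts <= 10) run exhaustively.  Ties in glycan rankings break by
PSM count then canonical string; all-zero compositions, empty PSM
tables, empty changed sets and unquantified parents are rejected or
flagged explicitly rather than silently dropped.
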