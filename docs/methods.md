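# Methods

This note documents the models, conventions and design choices behind
`amphiscan`, in the order the pipeline runs them.

## Mass conventions

All masses are the observed m/z of singly charged sodium adducts; no
neutral-mass conversion is performed anywhere, because the diagnostic
arithmetic (120 Da sulfate loss, arm losses, 58 Da pairs, 218/200 Da
terminus losses) operates directly on adduct m/z. The instrument class
is a unit-resolution triple quadrupole, so masses are stored as decimals
but matched with an absolute tolerance, default **±0.5 Da** everywhere.
Retention times are stored in minutes (MGF `RTINSECONDS` converted on
read) and matched with a default tolerance of **±0.1 min**, which
absorbs the small differences between independently reported retention
times for the same variant (up to ~0.06 min).

## CID rule engine

The annotator composes four detectors, in order:

1. **Sulfation** — a fragment at `precursor − 120` (±tol) marks a
   sulfated variant; the observed fragment is the desulfated ion.
2. **Arm assignment** — a fragment at `base − arm` for any arm mass in
   the library (default {392, 398, 426} Da), where `base` is the
   desulfated ion for sulfated variants and the precursor otherwise.
   Ties are resolved by smallest mass error, then largest fragment
   intensity, then smallest arm mass — a total order, so annotation is
   deterministic.
3. **Carbonyl pairs** — all fragment pairs separated by 58 ± tol Da,
   searched across the whole peak list (both the high-mass,
   precursor-linked series and the low-mass, cleavage-linked series
   carry the signature); the precursor ion itself is excluded.
4. **Terminus loss** — 218 Da from the precursor, or 200 Da from the
   desulfated ion of a sulfated variant; 218 takes precedence when both
   match. A 200-type loss is recorded as evidence that the variant is
   the sulfated counterpart of a 218-type analog.

Hydrophilic-arm typing: *LP-D-type* when the C1/C1′ cleavage fragment is
the base peak of the spectrum; *AM-18-type* when at least one carbonyl
pair co-occurs with a terminus loss. The labels can co-occur.

**Verdict.** A spectrum is *known:<variant>* when it matches a
transition-library entry (Q1 within mass tolerance, RT within RT
tolerance, and a fragment at Q3); *novel* when unmatched but carrying
positive structural evidence — an assigned arm, **or** carbonyl pairs
together with a terminus loss; otherwise *non-AM*. Requiring positive
evidence (rather than merely a mass in the AM range) prevents full-scan
noise masses from being auto-promoted to candidates.

Two documented source ambiguities are resolved in the fixtures: the
ARC-6 desulfated ion is taken as 1326 (= 1446 − 120, the value the
arithmetic and the spectrum figure support) rather than the
inconsistently quoted 1278; and the ARC-8 fixture is built from its own
spectrum figure (desulfation 1608→1488, 426 Da arm loss, 58 Da pairs,
200 Da terminus loss from 1488) because the running-text pair listing
for ARC-8 repeats ARC-7's series.

## Screening

* **SRM** — a chromatographic peak is a hit when Q1 and Q3 both match a
  transition within the mass tolerance and RT within the RT tolerance.
* **NL** — channel L fires on a spectrum when some fragment f satisfies
  `|precursor − L − f| ≤ tol` with S/N ≥ 3. The default library has 14
  channels: seven non-sulfated arm losses and seven sulfated
  counterparts. Only three non-sulfated losses (392, 398, 426 Da) are
  published; the other four are placeholders flagged
  `provenance="placeholder"` and are expected to be replaced by the
  user's instrument-method values. Sulfated counterparts are derived as
  `loss + 120` (the neutral arm retains NaHSO₄), flagged
  `provenance="derived"` — a convention, also user-replaceable.
* **FS** — precursors inside m/z 1000–1800 and RT 2.0–4.2 min with
  base-peak S/N ≥ 3, deduplicated against NL/SRM hits. Windows are
  inclusive; precursors just outside the RT window (within 0.25 min)
  are logged rather than silently dropped, because published AM
  retention times can sit on or past the nominal window edge.

**S/N estimation.** For continuous traces, S/N = (peak max − baseline
median) / noise, with noise = 1.4826 × MAD of the off-peak samples (the
Gaussian-consistent robust scale); zero noise yields 0 for a flat trace
and +inf when the peak rises above baseline. The estimator is a design
choice — robust and configurable — since no estimator is prescribed by
the method description. Peak lists are not traces, so fragment-level
S/N takes its noise floor from the low-intensity half of the other
fragments (the population dominated by noise peaks); spectra with fewer
than 8 fragments carry no measurable noise floor and no fragment can be
rejected (sentinel +inf for any nonzero fragment).

## Quantification

Concentrations are LPD equivalents from a single-point external
calibration; cell quotas scale by extract volume (default 500 µL, the
reconstitution volume of the extraction protocol) and cell count; the
LoD is the quota at which the analyte would reach S/N = 3 given the
standard's S/N. The default standard concentration is **12.5 ng/µL**
(10 µg LPD dissolved in 800 µL methanol, computed exactly rather than
the rounded "about 13"); any value can be configured. Per-strain totals
**exclude** below-LoD variants by default — the source procedure does
not state the rule, and excluding unreliable trace signals is the
conservative choice; `include_below_lod_in_total=True` flips it. All
outputs are explicitly semi-quantitative (no per-variant response
factors exist).

## Toxicity

The plate layout is 3 treatment + 6 control wells (~60 *Artemia*
nauplii each). Adjusted deaths = max(0, treatment − initial − control
mean); DMSO and seawater controls are pooled for the control mean
(they are not distinguished in the protocol; configurable). The rate is
`ln(adjusted dead at 48 h)/48 h × 24 h` — the log of a **count**, kept
verbatim because the reported rate range (~0–2.25 d⁻¹) matches this
form for 60-individual wells; adjusted counts ≤ 1 map to rate 0 (log
undefined or zero, warned at 0). A proportion-based hazard,
`−ln(1 − D/60)/2`, is available via `mode="hazard"` but is never the
default. The 24 h counts are carried through for reporting but do not
enter the rate, matching the published formula.

## Multivariate profiling

Features (per-variant quotas, total AM, mortality rate) are min-max
scaled to [0, 1] per feature (constant features map to 0) and then
ln(x+1)-transformed, bounding all values by ln 2. PCoA is classical
scaling of the pairwise distance matrix (scikit-bio's implementation);
the distance is **Euclidean** by default (the conventional input to
classical scaling; under it PCoA scores equal centered PCA scores,
which the tests verify), with Bray–Curtis available. Negative
eigenvalues from non-Euclidean metrics are truncated to 0 for the
percent-variability computation. Clustering is agglomerative (complete
linkage by default) on Euclidean distances between score rows, using
all axes with positive eigenvalues; **k is a required choice with
default 3** — the source analysis describes three main chemotype
groups while its dendrogram figure labels five, so k is deliberately
left to the user. Output labels are 1..k by decreasing cluster size
with first-occurrence tie-breaking, making the labeling deterministic.

## Synthetic data

The generator emits exactly the grammar-implied fragments: precursor
(low intensity), desulfated ion if sulfated, cleavage fragment, terminus
fragment, and — for carbonyl variants — a high-mass 58 Da pair anchored
at the terminus fragment plus a low-mass pair shifted down by the arm
mass. This canonical layout reproduces the ARC-7 series (1288/1230 and
862/804 from precursor 1506). When a carbonyl variant has no terminus
loss, the anchor sits at a fixed 170 Da structural offset chosen clear
of every rule position. Decoy peaks are uniform in m/z, kept ≥ 2 Da from
every rule-consistent position *and* from any 58 Da offset to existing
peaks, so decoys can never satisfy a rule at the 0.5 Da tolerance —
this is what makes the 100%-flag-recovery robustness property exact
rather than statistical. Structural fragment intensities are uniform in
[300, 800] (base peak 1000, precursor 30–80), decoys in [10, 100],
placing decoys firmly below the screening noise floor.

Panels default to **54 strains** in three planted chemotype archetypes
(equal thirds): a low-quota background chemotype (tens of fg/cell of
AM20(S)/KAR-A/KAR-B, death probability 0.02), and two high-quota
chemotypes (~800–1600 fg/cell) with distinct variant profiles and
death probabilities 0.12 and 0.25 — spanning the low/moderate/high
toxicity and quota ranges observed in real strain panels (quotas from
non-detectable to a few thousand fg/cell, rates from ~0 to ~2 d⁻¹).
Peak areas are planted-quota-proportional through the same calibration
the quantifier inverts, multiplied by mean-preserving lognormal noise
with CV 0.25 by default; assay deaths are binomial per well.
`area_cv=0` switches the whole panel to expected values (including
deterministic assay counts), producing a fully deterministic panel on
which planted-cluster recovery is required to be exact (ARI = 1.0); at
the default noise the requirement is ARI ≥ 0.8. All randomness flows
from a single seed recorded in the truth manifest.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: chromatographic peak shapes and
integration (areas are consumed as tabulated values), isotope
envelopes, in-source fragmentation, co-eluting isobars, matrix effects
on ionization, per-variant response factors, and real within-archetype
biological variability beyond lognormal area noise. Tests demonstrate
the correctness of the rules and arithmetic, not instrument-level
performance.

## Problem sizes and numerics

Property suites run 500 random variant specs for grammar round-trips,
1000 random spectra for the NL brute-force equivalence, 300 strains for
the Monte-Carlo mortality check and 54-strain panels for cluster
recovery — sizes chosen to exercise the combinatorics thoroughly while
keeping the full suite in seconds. Degenerate inputs are defined
explicitly: empty MGF → empty list with a warning; empty transition
table → no known matches; all-control plates → no toxicity records;
constant features → scaled to 0; duplicated strains → identical PCoA
scores; identical points under clustering → deterministic labels via
first-occurrence tie-breaking.

## Known limitations

* The eleven unpublished NL channel masses are placeholders; screening
  with the default library is only as complete as the three published
  channels until the user supplies their method's list.
* The known-AM transition entries bundled for the novelty tests carry
  synthetic Q1/Q3/RT stand-ins (the real values are unpublished
  instrument-method metadata); the shipped `transitions.csv` contains
  only the eight ARC variants, whose parameters are fully recoverable.
* Single-point calibration ignores detector nonlinearity; quantification
  is semi-quantitative by construction.
* The log-count mortality rate depends on the number of individuals per
  well; it is comparable across strains only under the standard ~60
  individuals/well layout.
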