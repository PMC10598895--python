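# Methods

## Coordinate frame and anatomy template

All geometry lives in a two-dimensional sagittal plane with the patient
supine: the origin is the neutral-position upper incisor apex, +x points
caudad (toward the feet) and +y ventral (toward the ceiling — the direction
a laryngoscope lifts).  Lengths are millimetres internally; the record
interface uses the clinical units the quantities are measured in (cm,
except the TMJ range of motion in mm).

One reference landmark set (upper and lower incisor apices, TMJ condyle,
gnathion, atlanto-occipital pivot, posterior pharyngeal wall, a display
tongue outline) serves both sexes and is scaled uniformly about the origin
by *(height / reference_height)^scaling_exponent* with reference height
170 cm and exponent 1.0.  Two quantities deliberately break similarity:

* the glottal anteroposterior span is a fixed 25 mm (male) / 22 mm
  (female), never scaled;
* a small mandible (lower incisor to chin tip < 4 cm) is modelled as a
  fixed 35 mm body, whatever the height.

Weight and age are validated and carried through but have no geometric
effect: no published size law uses them, and making weight inert keeps the
template reproducible.  The Mallampati grade is a statistical covariate
only.  The reference coordinates themselves are model data, shipped in the
configuration; they were calibrated once, numerically, against the
constraint set in "Calibration" below and are not meant to be retuned per
study.

## Laryngoscopy kinematics

The transformation order is fixed: extension → opening → lift → larynx
placement → tongue compression.  Identical inputs give bit-identical
scenes.

**Head extension.** The whole head — cranium with the closed mandible and
its attached tongue — rotates dorsally about the atlanto-occipital pivot by
an angle looked up from the sniffing-position grade:
grade 1 → 25°, 2 → 15°, 3 → 8°, 4 → 3° (configurable; any strictly
decreasing map is legal).  Rotating the mandible with the cranium is what
keeps the closed-mouth inter-incisor gap invariant; rotating the cranium
alone would open a spurious gap larger than many measured mouth openings
and make the opening equation unsolvable.

**Mouth opening.** The mandible (lower incisor, gnathion, tongue) rotates
about the displaced TMJ condyle by the unique angle in (0°, 70°] whose
inter-incisor gap equals the measured opening, found by bracketed root
finding to a gap error below 10⁻⁶ mm.  Openings smaller than the template's
neutral gap, or beyond 70° of rotation, raise an `unreachable-opening`
error.

**Laryngoscope lift.** The mandible + tongue block translates by exactly
the TMJ range of motion along the 45° ventral-caudad direction ("forward
and downward" with equal components).  No cap is applied by default; a
configurable cap exists for sensitivity analyses.

**Larynx and hyoid placement.** The larynx belongs to the cervical column,
not the head: the thyroid notch and hyoid are placed at the measured
thyromental and hyomental distances from the *neutral chin rest position*
(the pre-extension gnathion of the normal-length body) along a world-fixed
anterior-neck ray, 89° dorsal of the caudad axis — essentially straight
dorsal of the chin.  The anterior commissure anchors to the thyroid notch;
the posterior commissure lies one anteroposterior span further along the
(parallel) glottal axis.  Three consequences are intentional:

* head extension moves the sight origin and the tongue but not the
  glottis, which is what makes a better sniffing position open the viewing
  corridor;
* jaw opening and lift do not drag the larynx;
* a recessed chin does not pull the larynx toward the mouth — the
  small-mandible handicap acts through tongue crowding (below).
  Anchoring at the *post-extension* or shortened chin makes extension or a
  small mandible *improve* the computed view in deep-miss scenes, the
  wrong clinical direction.

Thyromental below hyomental is clinically odd but accepted as measured
(with a warning); both placements use the values as given.

**Tongue compression.** The blade retains a fraction ρ = 2/3 of the
measured tongue thickness.  The compressed tongue is rebuilt as a slab on
the floor chord from the (opened, lifted) lower incisor to the lifted
tongue base at the hyoid; its corridor-facing surface is sampled over the
mid-to-base portion of the chord (parameters 0.45–1.0) at perpendicular
offset ρ·t, bulging toward the upper-incisor side of the chord.  Near the
teeth the corridor is bounded by the lower incisor itself, which is part of
the obstruction set.  A small mandible multiplies the slab thickness by
(reference body length / 35 mm): the same tongue volume crowded into a
shorter floor, by area conservation.  The slab's maximal perpendicular
thickness equals ρ·t exactly (rotating-calipers checked in the tests).

## The sight line and V

The obstruction set is the compressed tongue surface plus the lower incisor
apex.  Obstructing tissue lies on the ventral side of its surface, so a ray
from the upper incisor apex is clear exactly when every obstruction vertex
lies on or ventral of it; the limiting ray is the most ventral clear ray —
the tangent through the vertex of minimum direction angle (ties broken
toward the vertex nearest the incisor; an empty set yields the ray through
the anterior commissure).

Two numerical guards define the extreme regime.  First, a vertex's
occlusion direction saturates just short of the mouth-frame vertical
(−89° + extension angle in world coordinates): the oral aperture itself
bounds how steeply the sight can dive, and the bound rotates with the
extended head.  Second, when the limiting ray points more than 90° away
from the posterior commissure, the miss distance is the distance to the ray
(which plateaus at |P − origin|) rather than to its supporting line.  Both
guards only act in fully-occluded configurations; inside them they make the
response to every input provably monotone (see "Calibration").

With limiting line L and glottal segment G = [A, P]:

* L crosses G at X → **V = +|X − P|** (the visible posterior portion);
* L passes on the visible side of the whole segment → **V = +|A − P|**
  (full exposure; V can never exceed the anteroposterior span);
* P is hidden → **V = −dist(P, limiting ray)**.

V is reported to 0.1 mm; the screening thresholds (difficult laryngoscopy
V ≤ −1 mm, difficult intubation V ≤ −4 mm, both inclusive as printed)
compare against the unrounded value.

## Calibration

The free template coordinates and the defaults above were fixed, once,
against this constraint set:

1. a favourable male reference patient (170 cm, mouth opening 4.5 cm,
   thyromental 9 cm, hyomental 5.5 cm, tongue 5.0 cm, TMJ 15 mm, grade 1,
   normal mandible) attains full exposure, V = +25.0 mm (22.0 mm female);
2. V is non-decreasing in thyromental distance, mouth opening and TMJ
   range of motion, non-increasing in tongue thickness and head-up grade,
   and never increased by the small-mandible flag, across cohorts of
   generator-drawn base patients swept variable-by-variable over the
   clinical ranges;
3. each single-variable worsening of the published example panels —
   thyromental 9 → 7 cm, TMJ 15 → 5 mm, tongue 5.5 → 7 cm, grade 1 → 2 —
   strictly decreases V;
4. on the default synthetic cohort the score separates the groups with
   AUC ≥ 0.9 and group-mean visibilities near the published ones
   (difficult ≈ −18 mm, non-difficult ≈ +9 mm here, vs −11.0 and
   +9.6 reported).

The thyromental direction is structural rather than tuned: with the neck
ray at 89° and occlusion saturated at −89° + extension, the limiting ray is
always shallower than the axis the glottis moves along, which makes
dV/d(thyromental) ≥ 0 for every admissible input.

## Synthetic cohorts

`default_spec_from_table1()` encodes the published group-conditional
summaries for difficult (n = 56) versus non-difficult (n = 2012)
intubation: means/SDs for thyromental (6.7/0.8 vs 7.7/0.9 cm), mouth
opening (3.4/0.5 vs 4.1/0.6 cm), hyomental (4.6/0.4 vs 5.3/0.5 cm), tongue
thickness (6.3/0.5 vs 5.9/0.5 cm) and TMJ range of motion (9.5/2.5 vs
14.0/2.3 mm); small-mandible rates 26.8% vs 2.5%; head-up grade counts
30/26/0/0 vs 2006/6/0/0; Mallampati > 2 rates 60.7% vs 26.7%; sex counts
32/24 vs 969/1043; prevalence 56/2068.  Ages are log-normal fits to the
published medians/IQRs (62 [52–69] vs 50 [41–62] years); heights are
sex-specific population normals (male 170 ± 6.5, female 158 ± 6.0 cm, an
East-Asian adult surgical population) and weight derives from the group's
BMI distribution (23.4 ± 3.6 vs 22.9 ± 3.5 kg/m²).

Continuous variables are drawn *independently within group* from truncated
normals (inverse-CDF; bounds inside the record validity ranges and ≥ 3.7 SD
from every group mean, so sampled moments match the targets).  Only
marginals are published; no joint structure is imposed.  Because the
published table conditions on the outcome, generated inputs are
label-conditional by construction: the generator emulates the *study
population*, not the causal path from anatomy to outcome.  Passing
end-to-end tests therefore shows that the geometry separates the two
published measurement profiles — not that real-world predictive accuracy
would match, since within-patient correlations (e.g. short thyromental
co-occurring with small mandibles) and measurement error are absent.

## Numerical choices

* Mouth-opening rotation: bracketed Brent root finding, gap tolerance
  10⁻⁶ mm (an independent pure-bisection oracle agrees to 10⁻⁴ °).
* Angular ties in the limiting-ray sweep: nearest vertex to the incisor.
* Over-exposure is clamped at the anteroposterior span; degenerate glottis
  segments raise a configuration error.
* AUC by the Mann–Whitney identity with ties counted ½; CIs and the paired
  marker comparison by DeLong's estimator; sensitivity/specificity
  intervals exact Clopper–Pearson; 2×2 odds ratios with Woolf logit
  intervals and a flagged Haldane–Anscombe 0.5 correction on zero cells;
  sample size by upward scan of a two-sided z-test under Hanley–McNeil
  variances.
* Everything is deterministic given a seed; the SVG renderer emits
  byte-identical documents for identical scenes.

## Known limitations

* The model is two-dimensional by design; no epiglottis, no soft-tissue
  mechanics beyond the single retained-fraction compression, no
  neck-circumference effect.
* In fully-occluded extremes outside the study population (tongue
  ≥ ~8 cm combined with very short thyromental distance and minimal
  opening, V below roughly −38 mm), the ordinal benefit of head extension
  can tie or reverse by under 1 mm — a second-order effect of the sight
  origin moving with the head while the glottis stays column-fixed.
  Within generator-drawn cohorts no violation of any monotonicity is
  observed.
* Group-mean visibilities of the synthetic cohort bracket but do not
  exactly reproduce the published ones (the authors' template geometry is
  unpublished); the screening operating points at the fixed thresholds
  shift accordingly.
* The AUC-driven sample-size routine documents Hanley–McNeil variances; the
  formula behind the published "> 2000" figure is unstated, so only
  order-of-magnitude agreement is claimed.
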