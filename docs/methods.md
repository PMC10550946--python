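# Methods

This note documents the models and conventions behind `mucintools`, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the design choices that were genuinely open.

## Glycan compositions

O-glycans are represented by monosaccharide counts only — N (HexNAc),
H (hexose), A (NeuAc), F (fucose) — with residue monoisotopic masses
computed from the elemental formulas C8H13NO5, C6H10O5, C11H17NO8 and
C6H10O4 (203.07937, 162.05282, 291.09542 and 146.05791 Da).  Linkage and
topology (including sialic-acid linkage ambiguity) are deliberately out
of scope: every decision in the pipeline depends only on composition.

Residual-mass enumeration searches the bounded lattice N ≤ 6, H ≤ 6,
A ≤ 4, F ≤ 3 within ±0.02 Da by default.  The bounds comfortably cover
the bundled 12-composition O-glycan database (`data/glycan_database.csv`)
and common extensions; both the bounds and the tolerance are arguments.

Core classification is a composition-level approximation of the glycan
core families:

* **Tn** — N = 1, H = 0, with at most one of A or F (covers sialyl-Tn
  and fucosyl-Tn);
* **core 1** — N = 1, H ≥ 1;
* **core 2** — N ≥ 2, H ≥ 1;
* **other** — everything else (e.g. N ≥ 2 without hexose).

Because compositions cannot distinguish isomeric cores (e.g. core 3 from
core 2), the map is exposed as a function rather than baked into data
structures; the category of sialyl-/fucosyl-Tn was an open choice and is
documented here rather than hidden.

The multi-site decomposition rule splits a composition C over n
unresolved sites into n identical parts C/n only when (i) the 138.055 /
144.07 oxonium intensity ratio is strictly below 1.2, indicating
core 1 type fragmentation, (ii) no HexNAc2 oxonium at 407 m/z is
present (which would place both HexNAcs on one site), and (iii) the part
classifies as Tn or core 1.  Indivisible compositions keep a single
assignment with a warning rather than an error.

## Spectra and fragments

Conventions: proton mass 1.007276 Da; fragment charges 1..(precursor
charge − 1); b/y ions are generated glycan-free (O-glycans are labile
under beam-type collisional activation) with an option to add
glycan-retaining forms; c ions are b + NH3; z ions are z-dot radicals
(y − NH2, 16.01872 Da); Y0 is the intact peptide stripped of all glycans
at charges up to the precursor charge.  Carbamidomethyl Cys is fixed,
Met oxidation variable; the oxidized-Met side-chain loss used by the
naked-peptide rule is CH4SO (63.9983 Da).

Peak matching is greedy nearest-m/z within a ppm window (default 20 ppm
for MS2, matching the acquisition described); an observed peak claimed
by several theoretical ions yields matches flagged ambiguous, mirroring
the "?" notation of manual annotation.

The product-dependent ETD trigger is implemented verbatim from the
acquisition method: at least 3 of the 8 fingerprint ions 126.055,
138.055, 144.07, 168.065, 186.076, 204.086, 274.092, 292.103 within
±0.1 m/z at >5 % of the base peak, with the precursor in 300–1500 m/z
at charge 2–6.  The mixed precision of the printed ion list is kept
as-is; at a ±0.1 m/z window the inconsistency is immaterial.

## Validation engine

The manual-curation procedure is encoded as deterministic rules with a
fixed precedence:

1. **Naked peptide** (necessary): a peak at Y0 at any charge up to the
   precursor charge, or — for oxidized-Met peptides — at Y0 − 63.9983 Da.
2. **Backbone coverage** (necessary): for peptides of ≤ 12 residues,
   at least 80 % of backbone bonds covered by glycan-free b/y ions
   ("nearly full coverage"; the fraction is configurable since no number
   is stated in the source procedure).  For longer peptides, every bond
   N-terminal to a Pro and C-terminal to an Asp must be covered; when a
   long peptide has no Pro/Asp anchors the fractional rule applies
   instead, so that coverage is never vacuously satisfied.  A bond
   covered by either its b or its y ion counts, which makes b(n−1) alone
   sufficient for a C-terminal Pro.
3. **Localization** (affects per-site status only): every placement of
   the glycan multiset over the candidate Ser/Thr sites is enumerated;
   matched c/z ions — including glycan-free ones — form the evidence; an
   arrangement is consistent if it implies every evidence ion; a site is
   *localized* iff all consistent arrangements agree on a non-empty
   glycan there, *contradicted* (all sites) if no arrangement survives,
   and *unlocalized* otherwise.  This replaces "sufficient c/z ions"
   human judgment with exhaustive arrangement consistency; peptides
   whose placement count exceeds a cap (default 50 000) are left
   unlocalized rather than adjudicated partially.  Only c/z ions carry
   localization weight; glycan-stripped b/y ions are positionally
   uninformative, and conflicting-evidence cases are recorded as
   contradicted rather than resolved by guesswork.
4. **Decomposition**: when two or more candidate sites remain
   unlocalized and glycan mass is unassigned, the multi-site rule above
   distributes it; the result is recorded as an assignment, not as
   localization evidence.

Identification transfer to weaker spectra of the same naked peptide
computes cosine similarity over the strong spectrum's matched
backbone-fragment channels; the default threshold 0.7 is a configurable
choice (the source procedure gives none).  Scan averaging is
intensity-summed peak merging within ±10 ppm.  Review reports are plain
data structures (rules with pass/fail and details); no attempt is made
to reproduce annotated PDF layouts.

## Quantitation

XIC areas use trapezoidal integration with boundary interpolation.
Isotope channels follow the mass-dependent rule — monoisotopic only
below 1600 Da, plus the first 13C isotope up to and including 2400 Da,
three isotopes above — read literally from the stated procedure
("under" strict, "up to" inclusive, "over" strict) and applied to the
*neutral* mass (the stated values carry Da units).  Channels sit at
(M + k·1.00335 + z·1.007276)/z and are looked up within ±10 ppm; the
retention-time window defaults to the validated scans' times padded by
±0.5 min.  All observed charge states are summed.  Site aggregation
sums AUCs of every peptide containing a (site, glycan) pair; the
most-abundant-glycan selection first picks the core category with the
largest combined area, then the largest glycan within it; exact ties
break by the fixed category order Tn < core 1 < core 2 < other, then by
canonical composition string, for determinism.

## Landscape accounting

Coordinates are 1-based; a cleavage event is recorded by the index of
its P1′ residue (the residue immediately C-terminal to the scissile
bond), matching "cleaves N-terminally to" phrasing.  Peptides mapping
ambiguously (or not at all) to the protein are excluded from event
derivation, so recovery guarantees hold only for unambiguous mappings.
Boundaries C-terminal to Lys/Arg are excluded when trypsin was part of
the digest.  Implied glycosites are Ser/Thr at the P1′ of an observed
cleavage that were never localized by MS.  Glycoform identity includes
the localization pattern, so unlocalized variants of one composition
collapse to a single glycoform; this definition is recorded in outputs
because the alternative (counting them separately) is also defensible.
The motif export is a positions × residues frequency matrix (P5..P1,
P1′..P5′, gap-padded at termini, columns summing to 1) consumable by
standard sequence-logo tools, plus P1/P1′ glycan tallies.

## Polymer metrics

All metrics operate on mass-weighted residue centres of mass and are
invariant under rigid transforms.  The polymer chain for persistence
length is the ordered N, CA, C backbone of the selected residue range
(single pseudo-atom chains, as produced by the worm-like-chain
generator, degrade gracefully to whatever chain atoms exist).  The bond
autocorrelation C(n) averages cos θ between bonds n apart over frames
and positions; C(0) = 1 exactly.  The fit is least squares through the
origin on log C(n) for n from 1 up to the first lag with C(n) < e⁻²
(or half the chain), restricted to positive C(n); l_p = −l_b/slope with
l_b the mean bond length.  A chain that never decorrelates (straight
rod) reports l_p = ∞ with a flag.  Each replica trajectory gives an
independent estimate; results report all replicas with mean ± SD, using
the last 1000 frames by default (the equilibrated-window convention is
shared by height-per-glycan).  The TIM-3/TIM-4 anchor sets used in the
receptor analyses are bundled as `TIM3_SELECTION` / `TIM4_SELECTION`
(polymer ranges 133–198 and 137–310; bending anchors 131/166/202 and
135/225/314; 14 glycans / 71 residues and 51 glycans / 179 residues).
The bending anchors deliberately extend beyond the polymer range for
TIM-3, following the respective calculation definitions verbatim.

Height per glycan divides the mucin range's end-to-end distance (not
contour length — the measure describes protrusion height) by the glycan
count: frame 0 gives the outstretched ("total glycosylation") value,
the final frame window the equilibrated ("effective glycosylation")
value, with SD across replicas.

## SPR kinetics

The dissociation phase is fit per replicate by unweighted nonlinear
least squares to Y = (Y0 − NS)·exp(−K·X) + NS with K bounded positive,
initialized at Y0 = first response, NS = last response, K = 3/span.
Replicate K values are summarised as mean ± sample SD (SD = 0 with an
n = 1 flag for single replicates).  A fit is flagged non-converged when
the optimizer fails, the amplitude Y0 − NS does not exceed twice the
residual RMSE (flat or pure-noise traces), or the decay over the window
is indistinguishable from zero.  The window extractor defaults to the
375–500 s dissociation phase of the sensorgrams this models, re-zeroed
at the window start.  Fitting is per replicate (then averaged) rather
than pooled, matching a "mean ± SD for n = 3" summary.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (seed, parameters).

* **Glycoproteins**: a Ser/Thr-enriched mucin region (default the middle
  half, 45 % S/T) whose S/T are glycosylated with probability
  `site_density` (default 0.6), drawing from a heterogeneous, core 1
  dominated composition distribution with sialylated, fucosylated and
  core 2 species.  These defaults produce the adjacent-glycosite runs
  (typically ~40 % of glycosites have a glycosylated neighbour) that
  differentiate the enzyme rules.
* **Digestion**: SmE cuts N-terminal to any glycosylated S/T; ImpA
  likewise but never when the P1 residue is itself glycosylated; OgpA is
  additionally blocked by NeuAc on the P1′ glycan (sialidase
  co-treatment is modelled by stripping A counts first); StcE requires
  the T/S*-X-T/S context and by default cuts C-terminal to the
  glycosylated P1 residue (the exact scissile position within the motif
  is not settled, so it is a config option).  Products carry
  0..`missed_cleavages` internal uncleaved sites.  ImpA's reported P1
  amino-acid preferences are noted but not parameterized beyond the
  glycan policy.
* **Acquisition**: HCD spectra contain all glycan-free b/y ions subject
  to a per-ion dropout probability, Y0 at every charge, oxonium
  fingerprints scaled by glycan content (sialic-acid ions only for
  sialylated glycans, the 407 m/z ion only when a single site carries
  N ≥ 2, and a 138/144 ratio below 1.2 consistent with the core 1
  dominated glycan distribution), and low-level uniform noise below the
  trigger floor.  An EThcD spectrum of glycan-retaining c/z ions is
  generated exactly when the trigger fires on the synthetic HCD scan.
  MS1 traces are Gaussian elution peaks (σ = 0.2 min) whose total area
  equals the planted abundance, distributed over precisely the isotope
  and charge channels the quantitation rules integrate — so planted
  abundance ratios are recoverable exactly in the noiseless limit.
  Not emulated: real instrument noise structure, co-isolation,
  deisotoping errors, retention-time drift, decoy-aware FDR.  Passing
  recovery tests therefore demonstrates the correctness and internal
  consistency of the rules, not their error rates on real data.
* **Worm-like chains**: each frame is an independent chain whose
  successive bond deflection is drawn from p(cos θ) ∝ exp(κ cos θ) with
  κ solved (Langevin function) so that ⟨cos θ⟩ = exp(−l_b/l_p); the
  planted autocorrelation is exactly C(n) = exp(−n·l_b/l_p).  Defaults
  l_b = 3.8 Å, 200 monomers, 2000 frames.  Frames are independent, so
  the ensemble has no autocorrelation in time — adequate for testing the
  estimator, unlike a real MD trajectory.
* **SPR decays**: the one-phase model plus i.i.d. Gaussian noise, on a
  125 s window sampled at 2.5 Hz (the nominal collection rate of the
  instrument class this emulates).

## Problem sizes and reproducibility

The acceptance script (`scripts/acceptance.py`) recomputes its metrics
from scratch at these sizes, chosen as the package's standard synthetic
study conditions: 20 glycoproteins of 200 residues for the enzyme
contrast; ~120 planted glycopeptides at 20 % fragment dropout (and as
many shuffled-sequence decoys) for validation recovery; 1000 random
residual masses for the enumeration oracle; the 240-row exhaustive
trigger truth table; one 200-monomer, 2000-frame ensemble per planted
persistence length (20/100/400 Å); 200 sensorgrams with K uniform in
[0.01, 0.5] s⁻¹ at signal-to-noise 20.  Every random draw derives from
the single `--seed` argument.

## Known limitations

* Composition-only glycan semantics cannot separate isomeric cores or
  linkages; "core 2" means N ≥ 2 with hexose, nothing finer.
* The validation engine intentionally reproduces a curation *procedure*;
  it has no statistical error model and no FDR.
* Localization treats arrangement enumeration as exact; peptides with
  very many candidate sites fall back to "unlocalized" wholesale.
* Persistence-length estimates on real, time-correlated trajectories
  carry replica-to-replica variance that the independent-frame generator
  does not reproduce; the estimator is validated for bias, not for its
  uncertainty on correlated data.
* HCD/ETD evidence conflicts are recorded (site status "contradicted"),
  never adjudicated.
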