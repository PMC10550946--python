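# mucintools

Tools for mucin-domain glycoproteomics with O-glycoproteases
(mucinases) and for the structural dynamics of mucin domains.

Mucin domains are Ser/Thr-rich protein regions carrying dense O-linked
glycosylation that resists conventional proteomics: trypsin cannot cut
inside them, glycans are labile under collisional activation, and the
same peptide occurs as dozens of glycoforms.  Bacterial O-glycoproteases
such as SmE, ImpA, OgpA and StcE cleave at (or next to) glycosylated
Ser/Thr and make these regions tractable.  `mucintools` implements the
downstream computational workflow for such experiments as a tested,
reusable library:

* **Glycan composition algebra** (`mucintools.glyco`) — N/H/A/F
  (HexNAc/Hex/NeuAc/Fuc) count vectors with monoisotopic masses,
  residual-mass enumeration against bounded composition space, core-type
  classification (Tn / core 1 / core 2 / other), and the rule that splits
  an unlocalized N2, H2N2 or H2N2A4 composition into two simple
  structures when the oxonium evidence supports it.
* **Spectra** (`mucintools.spectra`) — glycopeptide fragment generation
  (glycan-free b/y, glycan-retaining c/z-dot, Y0), ppm peak matching,
  the oxonium-fingerprint product-dependent ETD trigger (3 of 8 ions at
  126.055–292.103 m/z, ±0.1 m/z, >5 % relative intensity, precursor
  300–1500 m/z at charge 2–6), and MGF / TSV peak-list I/O.
* **Validation** (`mucintools.validation`) — the manual-curation rulebook
  as a deterministic engine: Y0 naked-peptide check (including the
  oxidized-Met side-chain loss), backbone-coverage rules with the
  b(n−1)/C-terminal-Pro and Pro/Asp expected-fragment provisions, c/z
  site localization by exhaustive arrangement consistency, de novo
  residual-mass matching, and cosine-similarity identification transfer.
* **Quantitation** (`mucintools.quant`) — XIC areas with mass-dependent
  isotope channels (1 below 1600 Da, 2 up to 2400 Da, 3 above), summation
  over all charge states, per-site relative abundances, and the
  category-first most-abundant-glycan selection.
* **Landscape** (`mucintools.landscape`) — peptide-to-protein mapping,
  cleavage events (recorded at the P1′ residue), localized vs implied
  glycosite accounting, mapped-structure / unique-glycoform counts,
  enzyme overlap sets and ±5-residue cleavage-motif frequency matrices.
* **Polymer metrics** (`mucintools.mdmetrics`) — normalized end-to-end
  distance, bending angle, persistence length from the bond-vector
  autocorrelation `C(n) = exp(−n·l_b/l_p)` of the N/CA/C backbone chain,
  and height-per-glycan (total vs effective glycosylation) on
  multi-model PDB / DCD trajectories.
* **SPR kinetics** (`mucintools.kinetics`) — one-phase exponential
  dissociation fits `Y = (Y0 − NS)·exp(−K·X) + NS` giving k_off with
  replicate mean ± SD, via a statsmodels-style `DissociationModel` /
  `DissociationResults` pair.
* **Synthetic data** (`mucintools.synthetic`) — seeded generators with
  planted ground truth for every input above: glycoproteins, enzyme
  digests, HCD/ETD runs with MS1 elution traces, worm-like-chain
  trajectories of known persistence length, and SPR decays of known rate.

## Worked example

Digest a synthetic mucin with SmE, simulate acquisition, validate and
localize one glycopeptide:

```python
from mucintools.synthetic import make_glycoprotein, digest, make_run, SME
from mucintools.validation import validate

protein = make_glycoprotein(seed=7, length=240, site_density=0.6)
peptides = [p for p in digest(protein, SME) if p.site_glycans][:5]
run = make_run(peptides, seed=1)

planted = run.truth[0]
hcd = run.hcd_spectra[0]
decision = validate(planted.glycopeptide, hcd, run.etd_for(hcd))
print(planted.glycopeptide)
print(decision.status.value, decision.site_status)
```

prints (seed 7):

```
S[N2H2A1]G
accept {1: <SiteStatus.LOCALIZED: 'localized'>}
```

i.e. the first glycosylated digest product is the dipeptide SG carrying
a sialylated core 2 glycan on its Ser; the validation engine accepts it
(Y0 present, backbone covered) and the c/z evidence localizes the glycan
to the planted site.

Fit a dissociation sensorgram:

```python
from mucintools.synthetic import make_spr_sensorgram
from mucintools.kinetics import fit_dissociation

t, y = make_spr_sensorgram(seed=5, K=0.27, Y0=120.0, NS=8.0, sigma=1.0)
print(fit_dissociation(t, y).summary())
```

```
One-phase exponential dissociation fit
Y = (Y0 - NS) * exp(-K * t) + NS
============================================
n observations: 313
converged:      True
RSS:            287.4
--------------------------------------------
param       estimate       std err
Y0           119.884         0.573
NS           7.98235        0.0579
K           0.271326       0.00213
--------------------------------------------
k_off = 0.2713 s^-1
```

The fitted K is the dissociation rate constant k_off in s⁻¹; Y0 and NS
are the response at the start of dissociation and the nonspecific
plateau, in RU.

A command-line interface (`mucintools simulate | validate | quantify |
md-metrics | spr-fit`) wraps the same functions for shell use; see
`mucintools --help`.

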