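# Methods

## Model

A dicationic ion-pairing reagent R²⁺ (default: the
1,5-pentanediyl-bis(1-butylpyrrolidinium) dication, C21H44N2, charge +2,
supplied as the difluoride salt) forms electrostatic pairs with singly
deprotonated metabolites. The resulting [M−H+R]⁺ ion is singly charged and
detectable in positive mode, so species that normally require a negative-mode
acquisition become visible in one positive-mode run. All of the package's
chemistry reduces to exact-mass bookkeeping on elemental compositions:

* monoisotopic mass = Σ count × principal-isotope mass (NIST values shipped
  as `data/isotopes.tsv`);
* ion m/z = (neutral-composition mass − z·mₑ)/|z| with mₑ = 0.000548579909 Da —
  electron correction is mandatory at the 4-decimal precision used
  throughout (the dication m/z 162.1747 is off by 3×10⁻⁴ without it);
* anion convention: [M−H]⁻ mass = neutral mass − m(H⁺), m(H⁺) = 1.00727646677 Da;
* dication mass (the annotation shift) = m(C21H44N2) − 2mₑ = 324.3494 Da.

### MS/MS fragmentation model

Under HCD the adducts cleave covalent bonds before the ionic pair breaks:

* every adduct loses one butylpyrrolidine arm, C₈H₁₇N (127.1361 Da), from
  the precursor;
* the bare reagent yields the fragment C₁₃H₂₆N⁺ (m/z 196.2060). The
  composition follows from C21H44N2 − C8H17N − H: the reagent must shed one
  additional hydrogen to leave a +1 ion, and no other composition lies
  within 2 mDa of the reported value;
* glycerophospholipids keep the reagent paired with the polar headgroup:
  [headgroup anion + R − C₈H₁₇N]⁺, i.e. dihydrogen phosphate for PA,
  phosphoethanolamine for PE, inositol monophosphate for PI. The PI
  headgroup is modeled as the C₆H₁₂O₉P⁻ anion — the composition consistent
  with the reported fragment m/z 456.2353 (alternatives sit ≈18 Da away);
* PE's headgroup fragment loses a further C₂H₅N (43.0422 Da), which is why
  PA and PE spectra share the 294.1829 peak.

Headgroup rules live in `data/headgroup_rules.tsv` and are deliberately
data, not code: other reagents or lipid classes can be explored by editing
a table. PC deliberately has no headgroup rule — PCs appear protonated,
not adducted. Acyl-chain-level fragments are out of scope (they are
suppressed in the ion-pairing regime), as are charge states |z| > 2 and
multiply adducted species.

Validation of an observed MS/MS spectrum (`match_msms`, tolerance 0.01 Da —
fragment spectra are matched in Da, not ppm, because a 1.0–1.5 Da isolation
window feeds high-resolution product scans across a wide m/z range) reports
each predicted fragment as found/missing and assigns a tier: **high** when
the reagent fragment plus at least one class-specific fragment are present,
**medium** when only the generic arm-loss is, **low** otherwise. A missing
fragment (e.g. when the precursor is too weak to yield the arm-loss peak)
is reported, never fatal.

## Isotope patterns, carbon counting and spectral accuracy

`isotope_pattern` convolves per-element isotope distributions and bins
isotopologues by nucleon-count offset (M, M+1, M+2 …) — the regime of
Orbitrap-class resolution, where the ¹³C, ²H, ¹⁵N and ¹⁷O M+1 species merge
into one peak. Bin mass offsets are abundance-weighted means. The
implementation is exact polynomial algebra; the test suite checks it to
1e-6 against an independent brute-force enumeration of all isotopologues.

Carbon counts are estimated as round(M+1 relative abundance / 0.0111). The
divisor mirrors the "~1.11 %" ¹³C convention of spectral-accuracy practice
and is configurable; the shipped natural abundance is 0.0107. The two
biases — a divisor above the natural ¹³C/¹²C ratio versus ²H/¹⁵N/¹⁷O
inflating the merged M+1 peak — largely cancel for CHNOPS metabolites, and
the estimate stays within ±1 carbon for every bundled formula up to C50
(verified in the acceptance tests).

`spectral_accuracy_score` pairs an observed envelope with theory at ppm
tolerance and reports per-peak relative deviations; pass requires the M+1
deviation ≤ 20 % (configurable). A missing monoisotopic or M+1 peak yields
"untested", not failure; an M+1/M ratio above 1.2 suppresses the carbon
estimate but still fails the deviation gate.

## Pixel-grid pipeline

Key defaults (all configurable): match tolerance **±2.5 ppm**, tissue
specificity **≥1.5×** on/off mean abundance, ROI geometry **20×20 on-tissue
+ 10×10 off-tissue** pixels at **150 µm** pitch.

* **Clustering** is greedy and abundance-ranked: peaks are visited in
  decreasing abundance; each joins the first cluster (in cluster-creation,
  i.e. prominence, order) whose running abundance-weighted mean lies within
  tolerance and that lacks a peak from the same pixel, else seeds a new
  cluster. Prominence-order joining, rather than nearest-mean joining,
  prevents rare jitter outliers from seeding satellite clusters that drain
  the main population. The procedure is deterministic and pixel-order
  invariant (ties broken by m/z).
* **ROI means include zeros** for pixels lacking the peak, penalizing
  sporadic noise; `pixel_frequency` records the fraction of on-tissue
  pixels containing it.
* **Zero off-tissue means** are floored at the smallest positive off-tissue
  mean among all clusters (machine-tiny fallback) before the ratio test, so
  tissue-exclusive peaks survive without infinite ratios.
* **A pixel-frequency floor (default 5 % of on-tissue pixels)** accompanies
  the ratio filter. Jitter outliers of an abundant ion form sporadic
  clusters present in ~1 % of pixels; when their few members happen to fall
  on-tissue the off-mean is zero and the ratio test alone would keep them.
  Frequency thresholds are standard in MSI peak finders.
* **Annotation** searches each tissue peak against the library: negative
  runs under [M−H]⁻, positive runs under [M+H]⁺, adducted runs under both
  [M+H]⁺ and [M−H+R]⁺ (query = observed m/z − 324.3494 against [M−H]⁻
  masses; ppm error evaluated on the theoretical mass). When the paired
  plain-positive peak list is supplied, a peak also present there is
  excluded from adduct assignment — adduct candidacy demands being observed
  only in the adducted run; without a paired run, assignment is m/z-only
  and flagged as weaker evidence. Light charge-1 deisotoping flags peaks
  sitting one or two ¹³C spacings above a stronger peak and carries them
  through unannotated; they still feed the parent's spectral-accuracy
  check. All in-tolerance candidates are returned (isomers tie); no
  multiple-testing control is applied — this is candidate listing, not
  hypothesis testing.
* **Coverage** is reported as
  `percent_increase = round(100 × n_adduct_new / n_positive)` and the
  report prints this definition, because several near-equivalent readings
  of a "coverage increase" exist; with the published rat-liver counts
  (73 new adducts, 167 positive-mode species) it evaluates to 44 %.
* **Ion images** sum per-pixel abundances within tolerance of a target m/z
  into a row-major (ny, nx) array, (0,0) top-left; out-of-window targets
  yield an all-zero image with a warning.

### imzML I/O

Datasets are written as processed-mode imzML 1.1 with float64 m/z *and*
intensities, making the round trip bit-exact. Scan polarity is stored in
the imzML; the remaining dataset metadata (mode, m/z window, pixel pitch,
grid shape) travels in a JSON sidecar (`<stem>.meta.json`) because the
format has no standard slot for it. The imzML standard cannot represent
zero-length spectra, so empty pixels are declared in the sidecar and
restored on read; undeclared coordinate gaps are filled as empty pixels
with a warning. imzML files embed a fresh UUID on every write, so seeded
reruns are compared content-wise for imzML and byte-wise for the TSV/JSON
tables, which are fully deterministic.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the acquisition design the pipeline targets: a
30×20 grid (20×20 on-tissue block, 10×10 off-tissue block, the rest
background-only), 150 µm pitch, three modes from one ground truth. Species
are drawn from the bundled 69-entry lipid library (`default_truth`),
weighted so fatty acids dominate the adduct-formers with PAs/PEs/PIs in the
minority, while PCs/DGs/TGs populate the positive mode; positive-mode
species also appear, at their usual m/z, in the adducted run. Defaults: 20
adduct-formers, 30 positive species, 15 of the adduct-formers also
negative-mode detectable.

Per on-tissue pixel, each species contributes its ion plus M+1/M+2
companions at theoretical relative abundances; m/z jitter is Gaussian with
σ = 1 ppm (appropriate inside a ±2.5 ppm gate for a 240k-resolution
instrument) and abundance noise is lognormal with CV = 0.2 (strictly
positive and heavy-tailed, like MSI intensities; no noise model is
prescribed by the acquisition itself). Ten background ions are drawn
uniformly over the window and planted on *and* off tissue at equal mean
intensity, so the 1.5× filter removes them by construction; adducted-mode
pixels additionally carry the reagent dication (162.1747) and fluoride
ion-pair (343.3483) peaks everywhere, like any solvent-borne signal.
Imaging tests use a two-disc "follicle-like" pattern with hard edges.
Each acquisition was designed for two m/z windows per condition
(150–600 and 450–1800 on the development tissue); one simulated dataset
stands for their merged union (150–1800) so reagent peaks and high-mass
adducts coexist, with the per-mode window pairs exposed as constants.

Not emulated: profile-mode spectra, detector saturation, chimeric MS/MS,
ionization-efficiency differences between species, spatial intensity
gradients, or correlated (structured) background. Passing the recovery
tests therefore demonstrates the pipeline's logic — shift arithmetic,
filtering, paired-run exclusion, isotope checks — under idealized but
noisy conditions, not performance on real tissue, where isobaric
interference, suppression and matrix effects dominate.

## Problem sizes and determinism

Default test and pipeline runs use the 600-pixel grid with ~50 species and
complete in seconds; the MS/MS robustness checks use 100 seeded replicates.
All randomness flows through `numpy.random.default_rng` seeded from a
single integer; identical configuration and seed give byte-identical
truth, peak and annotation tables.

## Known limitations

* Mass-shift annotation is inherently one candidate list per peak; isomers
  are indistinguishable by m/z and are all returned.
* The greedy clusterer is order-deterministic but not a global optimum;
  equivalence with any particular MSI peak-finding tool is not claimed.
* The carbon-count heuristic assumes the merged M+1 peak is ¹³C-dominated;
  it degrades for sulfur-rich or halogenated species.
* The ±1.5× / ±2.5 ppm defaults are acquisition-matched conventions, not
  fitted thresholds; datasets with different mass accuracy need retuning.
* Reagent coordination beyond 1:1 (double adducts, +2 species) is out of
  scope.
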