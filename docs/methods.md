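# Methods

This note documents the quantification model, the numerical choices behind
it, what the simulator does and does not emulate, and the package's known
limitations.

## Isotope patterns (module `chem`)

The theoretical isotope pattern `V` of a peptide is computed from its
elemental composition (residue table + one water + fixed-modification
deltas) by iterated discrete convolution of per-element isotope vectors,
with binary exponentiation per element count.  Fine isotopologues are
aggregated per nominal isotopomer using abundance-weighted mean masses, and
terms below 1e-12 relative abundance are pruned; at most 12 isotopomers are
kept because the deconvolution only ever consumes six channels.

Isotope masses and natural abundances are shipped as a plain-text table of
NIST/CODATA reference values (`data/isotopes.tsv`), so every oracle in the
test suite is self-contained; the residue composition table
(`data/residues.tsv`) and the fixed-modification defaults (cysteine →
cysteic acid +3 O, methionine → methionine sulfone +2 O, matching a
performic-acid sample workflow) are equally overridable through the config.

Abundances are normalized as fractions of the *total* distribution rather
than max = 100.  The non-negative least squares step is scale-consistent
either way; sum-normalization makes conservation checks exact (the
recovered form total equals the injected light+heavy signal in the
noise-free forward model).

The ¹⁸O label is *not* a chem-level modification: it is handled
structurally by the cluster geometry, because the label shifts the whole
envelope rather than changing the natural pattern.

## Cluster geometry and extraction (module `cluster`)

The six channels are anchored at the observed precursor m/z.  For a PSM
identified as the modified (heavy) form the precursor is the ¹⁸O₂
monoisotope and the natural form lies `2d/z` below; for an unmodified PSM
the precursor *is* the natural monoisotope.  `d = mass(¹⁸O) − mass(¹⁶O) ≈
2.004245 Da` and `c = mass(¹³C) − mass(¹²C) ≈ 1.003355 Da` come from the
same constants table.

Centroided spectra do not store per-peak charge assignments, so "the charge
of the ion" is operationalized as *charge evidence*: a centroid within the
matching tolerance of the channel plus a ¹³C partner at spacing `c/z` with
at least `charge_evidence_min_fraction` (default 0.01) of the monoisotope's
intensity.  This is how charge is read off high-resolution isotope spacing
in practice.  Elution-profile extension walks outward from the
identification scan over MS1 scans (MS2 scans are skipped, not treated as
gaps) and stops, per direction, at the first scan where *both* the ¹⁶O and
¹⁸O₂ channels lack evidence; that scan is excluded.  Gap tolerance is 0 by
default and configurable.  If the identification scan itself lacks
evidence it is still retained alone, so every PSM yields a (possibly
low-quality) quantification flagged `weak_evidence` rather than vanishing.

Peak matching takes the most intense centroid within ±`tol_ppm` (default
10 ppm, the usual high-resolution precursor tolerance); "nearest" is
available behind the config.  Most-intense is robust to small calibration
offsets; it also means a sufficiently intense interference inside the
tolerance window displaces the true peak, which is exactly the failure mode
the validation workflow (scan-range restriction) corrects.

Per-channel sums over retained scans use exact (`fsum`) summation, so the
observed vector is independent of scan order and exactly additive.

## Deconvolution and purity split (module `quant`)

`Y = X·A` is solved by Lawson–Hanson NNLS (scipy).  The design matrix
places the natural pattern at channel offsets 0/+2/+4 — one ¹⁸O label
(+2.0042 Da) is treated as coincident with two ¹³C shifts (+2.0067 Da),
which a 60k-resolution instrument cannot separate at typical peptide m/z
(≈ 1.2 mTh apart at z = 2); this unresolved overlap is the entire reason
deconvolution is needed.

The light/heavy split assumes complete exchange of both C-terminal oxygens
with per-site ¹⁸O incorporation probability `p` (the heavy-water purity),
so the heavy sample distributes over 0/1/2 labels binomially.  Since the
¹⁸O₁ and ¹⁸O₂ forms can only originate from the heavy sample,
`A(heavy)` is the least-squares projection of `(A(¹⁸O₁), A(¹⁸O₂))` onto
`(f₁, f₂)`; the heavy sample's unlabeled fraction `f₀` is then subtracted
from the natural form.  This split is exact under the forward model, is
invertible for every `p ∈ (0, 1]`, and reduces to `light = A(¹⁶O)`,
`heavy = A(¹⁸O₂)` at `p = 1`.  A negative light remainder is clipped to 0
and flagged `purity_overcorrection`.  An alternative would be to fold the
purity fractions into the design matrix and fit light/heavy directly; the
two coincide in the noise-free case, and the post-hoc split keeps the form
abundances available for diagnostics.  Incomplete back-exchange and
labeling kinetics beyond `p` are not modeled.

The per-peptide ratio is heavy/light (labeled/unlabeled); the inverse is
also exported.  A zero light abundance yields a missing ratio flagged
`no_light_signal`, never an infinity.

## Protein rollup (module `protein`)

Peptide points `(lightᵢ, heavyᵢ)` are fit through the origin by
iteratively reweighted least squares with the Huber ψ function, tuning
constant 1.345 and scale = 1.4826 × median(|residual|) (about zero, the
natural center for a no-intercept model), re-estimated each iteration —
the conventional defaults of robust-regression practice.  The slope is the
protein ratio, so no intercept is fit by default (an intercept has no
physical meaning for abundances; one is available behind the config).
Convergence is |Δβ|/|β| < 1e-8 with a cap of 200 iterations: with as few
as 3 peptides the scale re-estimation makes the fixed-point iteration
contract slowly (factor ≈ 0.85), so a 1e-8 tolerance needs on the order of
100 iterations.  Non-convergence is reported as `fit_failed`, never
silently.  When the scale collapses (an exact fit for the majority of
points) residual-free points keep weight 1 and all others drop to 0 — the
Huber weight limit as scale → 0 — which keeps perfectly collinear inputs
exact.  Degenerate geometry (all light ≈ 0) is `fit_failed` rather than a
huge slope.

Unique peptides are distinct core sequences ignoring charge and
modification state; proteins need ≥ 2 (configurable) to be `quantified`.
Peptides shared between protein groups contribute to every group they are
listed under, flagged `shared`.  Whether the rollup should fit
abundance-space points or per-peptide log-ratios is genuinely open; the
abundance-space fit is used because the slope is then directly the
labeled/unlabeled ratio and high-abundance peptides carry more weight,
which matches their lower relative noise.

## Simulator (module `synthdata`)

The simulator realizes the same generative assumptions the engine inverts:
Gaussian elution weights over MS1 scans; the light sample lays down the
natural pattern on the channel ladder; the heavy sample (ratio × light)
distributes binomially over 0/+2/+4 ladder offsets; every peak gets
multiplicative log-normal noise with the requested CV (mean-corrected so
expectations are preserved — intensities are positive and spreads are
reported on the log2 scale); spurious interference peaks are added
verbatim.  Peaks below a detection floor (`min_peak_intensity`, default 50
counts against a default base intensity of 10⁶) are dropped, which is what
terminates the elution window for the extraction step.

Peptide sequences are drawn from a packaged pool of tryptic sequences
(K/R C-termini) so elemental compositions are peptide-realistic.  The
acceptance-suite builder additionally rejects sequences whose channel
ladders fall within 30 ppm of an already-chosen peptide's ladder: co-eluting
isobaric overlap is an identification-level ambiguity, and the
designed-ratio experiment is meant to measure quantification accuracy, not
identification robustness (interference is exercised separately, with
explicit interference specs).

What the simulator does **not** emulate: chromatographic tailing or
scan-to-scan correlation of noise, charge-state envelopes beyond the
assigned charge, electronic baseline, dynamic-range compression, missed
monoisotope assignment, or MS2 acquisition.  Passing the designed-ratio
suite therefore demonstrates correct inversion of the stated forward model
under realistic noise — not robustness to every pathology of real raw
files, which is what the manual validation workflow is for.

Study conditions of the designed-ratio experiment: three samples at
labeled/unlabeled 1:1, 1:2, and 2:1; 30 proteins × 3 peptides; purity
0.95; noise CV 0.1; charges alternating 2/3; one fixed seed per sample.
These sizes run the whole experiment in a few seconds, and the recovered
means sit well inside the ±10 % acceptance band.

## Numerical details

- Matching tolerance `tol_ppm` default 10; tie-break most-intense.
- NNLS all-zero observation returns A = 0 flagged `zero_observed`.
- Scan numbers are native mzML 1-based ids; scan ranges are closed.
- CSV exports use shortest-repr floats, dot decimal separator, no
  timestamps — byte-identical for identical inputs (timestamps live only
  in `manifest.json`).
- All simulator randomness flows from one `numpy` generator seeded per run.

## Known limitations

- mzML support covers centroided spectra with uncompressed or
  zlib-compressed 32/64-bit float arrays; vendor raw files and profile
  spectra are out of scope (profile MS1 is rejected with a clear error).
- The PSM table is this package's own minimal dialect; converters from
  specific search-engine exports are an extension point.
- No cross-run alignment or normalization, no protein-level inference or
  FDR (identification quality is upstream), no per-peptide variance model
  beyond the NNLS residual and robust-fit weights.
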