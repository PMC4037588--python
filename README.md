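# proteo18

Quantification engine for proteolytic **¹⁶O/¹⁸O-labeled** LC-MS data:
per-peptide isotope-cluster extraction and deconvolution into light/heavy
abundances, and robust-linear-model rollup of peptide abundances into
protein ratios — with a synthetic-data simulator and scan/peptide/protein
level CSV reporting.

## The problem

In proteolytic ¹⁸O labeling, tryptic digestion in heavy water exchanges the
two C-terminal carboxyl oxygens of every peptide, shifting the labeled
sample by +2 Da per incorporated ¹⁸O (up to +4 Da).  When a labeled and an
unlabeled sample are mixed and measured together, each peptide appears as a
six-channel isotope cluster

```
mp = { m(¹⁶O), m(¹⁶O)+c, m(¹⁸O₁), m(¹⁸O₁)+c, m(¹⁸O₂), m(¹⁸O₂)+c }
```

where `c ≈ 1.0034 Da` is the ¹³C–¹²C spacing and the heavy forms sit
`d ≈ 2.0042 Da` (and `2d`) above the natural form.  Because one ¹⁸O shift is
only 2.4 mDa away from two ¹³C shifts, the three forms' natural isotope
envelopes overlap and must be deconvolved rather than simply integrated.

## The model

For each peptide-spectrum match the engine:

1. locates the six cluster channels from the observed precursor m/z, charge
   `z`, and ¹⁸O modification state;
2. extends across the elution profile: neighbouring MS1 scans are included
   while either the ¹⁶O or the ¹⁸O₂ ion still shows charge evidence
   (monoisotope + ¹³C partner at spacing `c/z`), and per-scan intensities
   are summed into the observed vector `Y = (y₁…y₆)`, `yᵢ = Σₖ aₖ,ᵢ`;
3. solves the non-negative least-squares problem `Y = X·A`, `A ≥ 0`, where
   the 6×3 design matrix `X` stacks the peptide's theoretical isotope
   pattern `V = (v₁…v₆)` (computed by polynomial convolution of elemental
   isotope vectors) at channel offsets 0, +2, +4 — giving the form
   abundances `A = (A(¹⁶O), A(¹⁸O₁), A(¹⁸O₂))`;
4. splits `A` into sample abundances using the heavy-water purity `p`: the
   heavy sample distributes over 0/1/2 labels as
   `(f₀, f₁, f₂) = ((1−p)², 2p(1−p), p²)`, so
   `A(heavy) = (f₁A(¹⁸O₁) + f₂A(¹⁸O₂))/(f₁² + f₂²)` and
   `A(light) = A(¹⁶O) − f₀·A(heavy)` (clipped at 0);
5. rolls peptides up to proteins by a robust linear model: `heavyᵢ = β·lightᵢ`
   through the origin, fit by IRLS with Huber weights (c = 1.345, MAD scale),
   so outlier peptides are down-weighted instead of removed.  `β` is the
   protein's labeled/unlabeled ratio; proteins need ≥ 2 unique peptides
   (distinct core sequences, ignoring modification state and charge).

Results can be reviewed at three levels and corrected by *validation edits*:
restricting a peptide to a clean scan window (e.g. when early scans carry a
co-eluting interference on a heavy channel) or excluding it outright, then
re-quantifying.

## Worked example

Simulate a two-protein run at a designed labeled/unlabeled ratio of 2:1 and
quantify it:

```sh
$ cat spec.toml
seed = 9
purity_p = 0.95
noise_cv = 0.05

[[proteins]]
accession = "PA"
true_ratio = 2.0
peptides = ["LVNELTEFAK", "YLYEIAR", "QTALVELLK"]

[[proteins]]
accession = "PB"
true_ratio = 2.0
peptides = ["HLVDEPQNLIK", "LGEYGFQNALIVR", "KVPQVSTPTLVEVSR"]

$ echo 'purity_p = 0.95' > config.toml
$ proteo18 simulate spec.toml simout
wrote simout/sim.mzML, simout/sim.psms.tsv, simout/sim.truth.csv
$ proteo18 quantify --mzml simout/sim.mzML --psm-table simout/sim.psms.tsv \
      --config config.toml --outdir quant
quantified 6/6 peptide records and 2/2 proteins
log2(ratio) over quantified proteins: 0.995 +/- 0.002
$ cat quant/proteins.csv
protein,ratio,log2_ratio,robust_scale,n_peptides_used,n_unique_peptides,peptide_weights,status
PA,1.9959373671462544,0.9970664493699438,270688.4013046948,3,3,1.0;1.0;1.0,quantified
PB,1.9912894927680553,0.9937029746598757,175890.41942171147,3,3,1.0;1.0;1.0,quantified
```

Both proteins recover the designed 2:1 ratio to within 0.5 % under 5 %
multiplicative intensity noise; `log2(ratio) = 0.995 ± 0.002` means the
run-level mean is unbiased and the spread across proteins is small.  The
`quant/` directory also holds `peptides.csv` and `scans.csv` (per-channel
intensities per scan), `summary.json`, and a provenance `manifest.json`.

To apply manual-validation edits (scan-range restriction / exclusion) and
re-quantify:

```sh
$ cat edits.toml
[[restrict]]
sequence = "YLYEIAR"
first = 8
last = 11
$ proteo18 validate quant edits.toml
validated results written to quant/validated-001
```

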