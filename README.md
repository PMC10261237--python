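# mpxval

Validation toolkit for a qualitative multiplex BCR::ABL1 PCR read out on
agarose gels, evaluated against quantitative TaqMan qRT-PCR on the percent
international scale (%IS). The package covers the full analysis chain:

- **`mpxval.synthetic`** — seeded generator of paired (continuous %IS,
  binary assay call) cohorts. Patients fall into %IS bins
  (&lt;0.001, 0.001–0.1, 0.1–1, 1–10, &gt;10) with configurable probabilities
  (defaults 9/35/25/24/126 of 219); non-zero %IS is log-uniform within its
  bin; the binary assay follows a logistic detection-probability model on
  the log10(%IS) scale with a detection limit near 10⁻³ and an optional
  false-positive rate at zero transcript.
- **`mpxval.qpcr`** — calibration curves (Ct vs log10 copies/µL over
  individual wells, 10–10⁶ plasmid standards), Ct→copy-number
  extrapolation, duplicate summation, and conversion to %IS via a
  lab-specific conversion factor (default 0.542; some sources print 0.5 —
  it is a required, configurable input). Amplification efficiency is
  `10^(−1/slope) − 1` with a QC warning outside [0.9, 1.1].
- **`mpxval.mpx`** — deterministic classification of gel band sizes into
  transcript variants (310 bp b2a2, 385 bp b3a2, 481 bp e1a2, 927 bp e19a2,
  1125 bp e6a2, 1319 bp e8a2; 808 bp wild-type internal control) and the
  binary positive/negative/invalid call.
- **`mpxval.cutoffs`** — the statistical core: strict `> cutoff`
  dichotomization of the reference, inverted sensitivity/specificity/
  accuracy sweep over a cutoff grid (default 0.1–1.0 %IS in 10 steps), the
  all-cutoffs ROC profile, the DeLong AUC (Mann–Whitney with midrank ties,
  placement-component variance, Wald or logit CI), and Youden-optimal
  cutoff selection (max-accuracy and closest-to-(0,1) criteria available).
  Note the inverted profile conditions on the dichotomized reference while
  the DeLong AUC treats the binary call as the class label; both
  constructions are exposed and documented.
- **`mpxval.reporting` / `mpxval.pipeline` / `mpxval.cli`** — cohort
  summary tables (%IS bins, treatment-duration categories, sex ratio, with
  half-up rounding to one decimal), figure export, and an end-to-end
  pipeline whose outputs are a pure function of (inputs, config, seed).

## CLI

```bash
mpxval simulate -n 219 --seed 1 -o cohort.csv        # synthetic paired cohort
mpxval evaluate cohort.csv -d out/ --plot            # sweep, ROC, DeLong AUC
mpxval calibrate calibration.csv -o curves.json      # standard-curve fits
mpxval quantify calibration.csv samples.csv -o q.csv # Ct -> %IS
mpxval classify-bands bands.csv -o calls.csv         # gel bands -> calls
mpxval report pipeline.yaml                          # full configured run
```

`mpxval report` takes a YAML config with a `seed`, an `output_dir`, and any
of the stage blocks `simulate` (or `cohort_csv`), `quantify`, `classify`,
`evaluate`; it writes `sweep.csv`, `roc.csv`, `auc.json`, `summary.json`
and a `manifest.json` run record. Re-running the same config reproduces
byte-identical outputs.

File formats are plain CSVs documented in each module: paired cohorts
(`sample_id, qrt_percent_is, mpx_result` accepting 0/1 or pos/neg),
calibration wells (`target, copies_per_ul, ct`), sample Cts
(`sample_id, target, replicate, ct`, blank/`undetermined` allowed), and
band patterns (`sample_id, band_sizes` with `;`-separated bp values).

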