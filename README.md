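# tricomp

Body-composition and cardiovascular analysis for whole-body adolescent MRI:

- **segmentation** — adipose-compartment segmentation of fat-fraction
  image stacks: background removal, fat thresholding, radial tracing of the
  subcutaneous ring's outer/inner boundaries, and SAT / VAT / NAT volume
  summation (NAT is the residual tissue volume).
- **hemodynamics** — QA-method pulse wave velocity (flow-gradient over
  area-gradient in the reflection-free early-systolic window, robust Huber
  slopes), plus SV, EF, CO, LV mass (density 1.05 g/mL), mass:EDV, total
  arterial compliance and systemic vascular resistance.
- **anthropometry** — BMI, Haycock body surface area, LMS z-scores with
  pluggable reference tables, and the BMI-z weight-status classification
  (normal: > −2 and ≤ 1; overweight/obese: > 1).
- **stats** — the statistical core: zero-skew shifted-log transform
  (`lnskew0`), OLS residualization, the orthogonalized three-compartment
  predictor set (NAT, rSAT, rVAT — pairwise correlation zero by
  construction), and standardized age/sex-adjusted association grids with a
  P < 0.01 significance rule and clinic-recruit sensitivity reruns.
- **synthetic** — seeded generators for phantoms (with mask-counted
  ground-truth volumes), flow/area waveforms (exact known wave speed), and
  cohort tables (known standardized effect matrix), so every stage is
  testable without external data.
- **pipeline** — end-to-end orchestration with flat-file config, group
  summary tables (median [IQR] by weight status), and deterministic
  reports carrying a config hash and seed.

## CLI

All functionality is exposed through one console script:

```sh
tricomp simulate phantom  --out-dir scratch/ph --slices 4 --seed 1
tricomp simulate waveform --out-csv scratch/wf.csv --true-pwv 4.0
tricomp simulate cohort   --out-csv scratch/cohort.csv --n 82 --seed 1

tricomp segment --fat-fraction scratch/ph/phantom_fat_fraction.nii \
                --combined-signal scratch/ph/phantom_combined_signal.nii \
                --out-dir scratch/seg --ff-threshold 0.5 --rays 360

tricomp hemo --waveform-csv scratch/wf.csv --edv 141 --esv 59 \
             --myocardial-volume 100 --sbp 111 --dbp 58 --heart-rate 69 --mbp 80

tricomp anthro    --cohort-csv scratch/cohort.csv --out-csv scratch/aug.csv
tricomp associate --cohort-csv scratch/aug.csv --out-csv scratch/assoc.csv \
                  --model three-comp --exclude-clinic
tricomp run --out-dir scratch/run --n 82 --seed 1
```

Phantoms are written as NIfTI (one file per channel) with a JSON
ground-truth sidecar; waveforms are CSV with columns `t_ms, Q_ml_s, A_mm2`;
cohorts and association tables are CSV. Segmentation label maps use
0 = background, 1 = NAT, 2 = SAT, 3 = VAT.

LMS reference tables are plain CSV (`measure, sex, age_years, L, M, S`);
the bundled table is synthetic and exists for testing — point
`tricomp anthro --lms-reference` at published reference CSVs for real use.

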