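# multiorgan

Analysis toolbox for noninvasive multi-organ function imaging in small
animals: multispectral optoacoustic tomography (MSOT) of contrast-agent
clearance for liver and kidney function, M-mode ultrasound read-outs for
cardiac function, and ex vivo bioluminescence imaging (BLI) for cell
biodistribution — plus a seeded synthetic cohort generator so the whole
pipeline can be exercised and validated without animal data.

## The problem

In a mouse model of multi-organ injury (a single adriamycin dose damaging
kidney, liver and heart simultaneously), organ function is monitored
longitudinally on two imaging days and expressed per mouse as the change
between days. The toolbox computes the functional statistics from the raw
instrument exports:

* **Liver** — indocyanine green (ICG) is cleared from blood exclusively by
  the liver, with a healthy blood half-life of about 3 minutes. A
  six-wavelength stack (700, 730, 760, 800, 850, 900 nm) is spectrally
  unmixed per pixel by linear least squares against ICG, oxy- and
  deoxyhaemoglobin reference spectra; the vessel-ROI mean-intensity curve
  gives the area under the clearance curve, ICG AUC. Hepatic injury slows
  clearance and raises the AUC; the per-mouse statistic is
  ΔICG AUC = AUC(day 4) − AUC(day 1).
* **Kidney** — IRDye 800 carboxylate is filtered exclusively by the kidney.
  A two-wavelength difference protocol (775 nm − 850 nm) isolates the dye,
  trading spectral redundancy for a 3× faster multispectral cycle. The
  statistic is the ratio of the areas under the renal-cortex and
  renal-pelvis curves, AUC C:P, which rises with injury because it captures
  both impaired cortical clearance and delayed pelvic accumulation, and is
  invariant to overall signal gain. Reported per mouse as ΔAUC C:P.
* **Heart** — from M-mode left-ventricular internal diameters (LVIDd,
  LVIDs) and heart rate: FS = 100·(LVIDd − LVIDs)/LVIDd, LV volumes by the
  Teichholz formula V = 7D³/(2.4 + D) (µl, D in mm), EF = 100·(EDV −
  ESV)/EDV, SV = EDV − ESV, CO = SV·HR. An area-length volume model is
  available as an alternative.
* **Biodistribution** — total photon flux per organ ROI from ex vivo BLI of
  luciferase-labelled macrophages; the study-level signal is flux decay in
  all organs of healthy mice versus accumulation in the injured liver and
  kidneys.
* **Statistics** — one-way ANOVA with Tukey's HSD post hoc (significance at
  P < 0.05), Pearson correlations between imaging metrics and serum
  biomarkers (BUN, SCr, ALT), and histology score aggregation (ten 0–5
  kidney field scores; a 0–4 liver grade binned from % area affected).

The synthetic generator drives every read-out from a per-mouse injury
severity in [0, 1] with the three-arm structure of the original study
(saline control, injured, injured + macrophage therapy), so the pipeline's
statistical behaviour can be validated against known ground truth.

## Worked example

```bash
multiorgan run-all --outdir results/demo
```

generates a synthetic cohort (4 control, 5 injured, 6 treated mice, two
imaging days), computes all per-mouse metrics and day-1 → day-4 deltas, and
writes `cohort_table.csv`, `deltas.csv`, `comparisons.csv`,
`correlations.csv`, `flux_summary.csv` and a run manifest. With the default
seed 0 the group comparisons include (from `comparisons.csv`):

| metric          | F     | P        | control | ADR   | ADR+BMDM |
|-----------------|-------|----------|---------|-------|----------|
| delta_auc_cp    | 22.66 | 8.4e-05  | 0.015   | 0.497 | 0.113    |
| delta_icg_auc   | 35.43 | 9.2e-06  | −2.8    | 98.2  | 25.4     |
| delta_sv (µl)   | 8.71  | 4.6e-03  | 0.44    | −6.9  | −9.2     |
| delta_co (ml/min)| 5.45 | 2.1e-02  | −0.38   | −3.8  | −5.0     |
| delta_fs (pp)   | 1.60  | 0.24     | −0.06   | 1.97  | −0.32    |
| delta_ef (pp)   | 1.69  | 0.23     | −0.07   | 3.02  | 0.14     |

Reading: clearance deltas for kidney (ΔAUC C:P) and liver (ΔICG AUC) are
elevated in the injured arm (Tukey: injured vs control significant, treated
vs control not), stroke volume and cardiac output drop in both injured
arms, and fractional shortening / ejection fraction show no significant
change — the qualitative fingerprint of adriamycin multi-organ injury with
a therapy that helps kidney and liver but not the heart. The correlations
table shows day-4 AUC C:P tracking BUN and day-4 ICG AUC tracking ALT
(r ≈ 0.85–0.88 at these settings).

Stage-level commands (`multiorgan simulate | unmix | kinetics | cardiac |
biodist | stats`) operate on exported TIFF stacks with CSV sidecars and CSV
tables; see `--help` on each.

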