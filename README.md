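# ctcscan

Semi-automated microscopy pipeline for circulating tumor cells (CTCs)
enriched on 8-µm-pore filtration membranes, plus a fully seeded simulator so
every stage runs and is testable at desk scale without scanner data.

Two combined workflows are covered:

1. **Phenotype + cytomorphology** — four-colour fluorescence scan (DAPI,
   CD45, epithelial/AF488, mesenchymal/AF546) → automated DAPI⁺/CD45⁻
   candidate selection (DAPI intensity, CD45 intensity, nuclear area > 55 µm²,
   plus a CD45-blind cluster gate at > 150 µm² = three pore-equivalents) →
   eight-category phenotype classification and a reviewable image gallery →
   snick-fiducial relocation to the brightfield round → morphometrics and
   rule-based CTC calls (five epithelial criteria; three marker-negative
   criteria).
2. **Phenotype + break-apart FISH** — candidate selection → per-cell z-stack
   acquisition (up to 30 stacks, 0.5–0.8 µm steps, exposures 5–100 ms) →
   Laplacian-of-Gaussian spot detection with cross-plane linking →
   multi-exposure fusion (max countable spots, ties to the lowest exposure,
   saturated-merged blobs disqualified) → fused/split pairing and
   rearranged / native / native-copy-gain verdicts → per-setting
   detection-rate tables.

## Layout

| module | role |
| --- | --- |
| `ctcscan.simulate` | synthetic filter spots, focal surface, 8-bit exposure model, FISH z-stacks with ground truth |
| `ctcscan.segment` | DAPI nucleus segmentation (threshold + watershed), background estimation, candidate measurement, CD45⁻ selection gates |
| `ctcscan.phenotype` | eight-category classification, gallery records |
| `ctcscan.cytomorph` | snick registration (rigid transform), morphometrics, CTC calling rules |
| `ctcscan.fafish` | spot detection, multi-exposure fusion, break-apart calls, spot-count tables, `detection_rate`, z-stack/step sweeps |
| `ctcscan.io` / `ctcscan.cli` / `ctcscan.config` | TIFF + CSV + JSON formats, pipeline configuration, command line |
| `ctcscan.data` | bundled per-CTC spot-count calibration tables (z-stack and step sweeps; `n.i.` = non-interpretable) |

Units are µm / µm² / ms throughout; intensities are 8-bit (detector gain
ceiling 255).

## CLI

```sh
ctcscan simulate spot --seed 1 --out run/sim --n-leukocytes 500 --n-ctcs 5
ctcscan select   --in run/sim --out run/sel
ctcscan classify --in run/sim --out run/cls          # gallery.csv / gallery.json
ctcscan cytomorph --snick-a a.csv --snick-b b.csv    # round registration
ctcscan fish --red red.tiff --green green.tiff --out run/fish
ctcscan sweep --mode zstacks --seed 1 --out run/sweep
ctcscan tables --bundled zstacks_alk --setting 30    # -> "82 %"
ctcscan tables --csv mytable.csv --setting 0.6
ctcscan review --gallery run/cls/gallery.json --record 3 --status confirmed
```

Every subcommand writes a `log.json` (parameters, seeds, counts, timing);
all randomness flows from the explicit `--seed`.

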