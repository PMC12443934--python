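# phantomqa

Automated quality-assurance analysis for an open-source, 3D-printable
low-field (64 mT) MRI phantom — plus a digital model of the phantom and a
synthetic MR slice simulator so the full pipeline can be exercised without
scanner data.

The phantom is a water-filled cylinder (18 cm OD / 14.8 cm ID, flat or domed
top) holding up to 24 sample tubes (water, olive oil, and three zinc–copper
supplement solutions) on an insertable plate. The package measures, per
image:

- **1-D geometric distortion** — vial circles are detected automatically
  (threshold → circular Hough → gradient-weighted sub-pixel refinement),
  consecutive inter-vial distances and their average are computed, and two
  same-placement scans are compared (difference, relative %, within-pixel
  flag).
- **SNR** — mean of a 5×5 signal region over the sample standard deviation
  of two pooled 10×10 background-noise regions.
- **CNR** — (signal mean − noise mean) over the noise standard deviation.

## Layout

| module | purpose |
| --- | --- |
| `phantomqa.digital_phantom` | parametric geometry, material catalog, ground-truth projections, config (de)serialization |
| `phantomqa.mr_simulator` | IR-SE / SE signal models, slice rendering, Rician/Gaussian noise, injectable affine/radial distortion |
| `phantomqa.vial_detection` | threshold + Hough vial ROI identification, principal-axis ordering |
| `phantomqa.qa_metrics` | distances, averages, scan comparison, SNR/CNR, automatic region placement |
| `phantomqa.io_reporting` | NIfTI/PNG/TIFF (+ optional DICOM) I/O, JSON/CSV reports, four-scan fixture set |

## CLI

```sh
# render a synthetic T2w coronal slice of the default phantom
phantomqa simulate --out scan --sequence t2w --plane coronal --sigma 2.4 --seed 1

# detect vial circles
phantomqa detect --image scan.nii --out rois.json

# distances + SNR/CNR report (auto region placement)
phantomqa analyze --image scan.nii --rois rois.json --mode t2w --out report.json --csv report.csv

# compare two same-placement scans
phantomqa compare report_t1w.json report_t2w.json

# generate the four-scan synthetic fixture set
phantomqa fixtures --out fixtures/ --seed 1
```

Exit codes: 0 success, 2 validation/configuration, 3 detection, 4 file I/O.

## Notes / limitations

- The simulator uses the standard IR-SE magnitude expression and a
  mono-exponential effective-TE SE model; echo-train, B1 and slice-profile
  effects are ignored. The scanner's 3D-FSE effective-TE semantics are
  proprietary, so the T2w model is an approximation.
- Default material relaxation values at 64 mT are placeholders (reference
  relaxometry of the supplement solutions has not been performed); they are
  chosen to reproduce the expected qualitative contrast orderings and are
  fully configurable.
- Reported SNR applies no Rician bias correction; a Rayleigh-corrected
  estimate is logged alongside in every report.
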