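# avcalc

Semiautomated quantification of **aortic valve calcification (AVC)** on
non-contrast, ECG-gated cardiac CT, for imaging researchers validating
calcium-scoring workflows (e.g. in pre-TAVR planning) and for anyone who
needs a fully testable, open reimplementation of annulus-referenced
Agatston scoring.

## What it computes

The **Agatston score** over an annulus-referenced region of interest.
Per axial slice, each connected lesion of voxels with attenuation
>= 130 HU contributes

    area (mm^2) x w(peak HU) x (slice thickness / 3 mm)

with density weight w = 1 for peak HU in [130, 200), 2 for [200, 300),
3 for [300, 400), 4 for >= 400; the total is the sum over lesions. The
region of interest is the slab from **5.0 mm below to 20 mm above the
aortic annulus plane**, the plane through the nadirs of the three valve
cusps (supplied as landmarks), measured along the plane normal. Calcium
outside the slab — LVOT, mitral annulus — is excluded geometrically;
residual sinus/coronary calcium by manual exclude masks. A calcium
volume score (mm^3) and an optional per-leaflet breakdown are reported.

A companion statistics module implements the method-agreement protocol
used to validate such scoring tools: ICC(2,1) with 95% CI (other forms
selectable), Bland-Altman limits of agreement, relative-difference
discordance counts, and median/IQR + Shapiro-Wilk summaries.

A phantom module generates synthetic CT volumes with analytically known
ground-truth scores — including decoy "mitral" calcium touching valve
calcium across the slab face — so every stage is testable without
patient data.

## Worked example

Generate a phantom with two valve lesions (450 HU and 250 HU plateaus)
and score it:

```sh
avcalc phantom --spec valve_phantom.yaml --out-dir phantom/
avcalc score --volume phantom/phantom.nii.gz \
             --landmarks phantom/landmarks.json --out report.json
```

```
INFO avcalc: scoring with threshold 130 HU, slab [-5.0, 20.0] mm
INFO avcalc: found 2 lesions, total score 39.50
```

`report.json` (abridged):

```json
{
  "total_score": 39.5,
  "volume_mm3": 40.5,
  "thickness_factor": 1.0,
  "lesions": [
    {"slice_index": 7, "area_mm2": 6.25, "peak_hu": 450.0, "weight": 4, "lesion_score": 25.0},
    {"slice_index": 9, "area_mm2": 7.25, "peak_hu": 250.0, "weight": 2, "lesion_score": 14.5}
  ]
}
```

The 450 HU lesion covers 6.25 mm^2 on one 3 mm slice, so it scores
6.25 x 4 = 25.0; the 250 HU lesion scores 7.25 x 2 = 14.5; the total,
39.5, is their sum. The volume score is the 54 mask voxels x 0.75 mm^3.
The same numbers come from the library API:

```python
from avcalc import generate_phantom, score_study, spec_from_yaml

volume, landmarks, truth = generate_phantom(spec_from_yaml("valve_phantom.yaml"))
result = score_study(volume, landmarks)
print(result.total_score)  # 39.5
```

Paired score tables are compared with
`avcalc compare --pairs scores.csv --out agreement.json` (CSV columns
`subject_id,method_a,method_b`), which reports the ICC with its 95% CI,
the mean difference with both its CI and the 1.96-SD limits of
agreement, and the counts of subjects differing by more than 5% / 10%.

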