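# epmap

Analysis toolkit for high-density electro-anatomical maps (HDEAM) of the
right ventricle, as used in drug-challenge electrophysiology studies:

* **Per-point electrogram features** — surface-ECG J-point detection
  (derivative-threshold QRS offset), unipolar J-point elevation (Uni-JEl)
  relative to a pre-QRS baseline, activation time (AT, steepest unipolar
  downstroke vs. a surface-lead fiducial inside the window of interest),
  activation recovery interval (ARI, minimum QRS dV/dt to maximum T-wave
  dV/dt) with noise / premature-beat / abnormal-T quality rejection,
  Bazett-corrected ARI, and window peak-to-peak unipolar voltage.
* **3D parametric mapping** — scattered-to-mesh interpolation of per-point
  features onto a triangulated chamber surface (nearest-neighbor default;
  linear and smooth variants), with legacy-VTK export.
* **ROI selection** — polygonal regions specified by vertex IDs, closed by
  shortest edge paths, with surface-partition interior semantics,
  membership tests and ROI-restricted re-interpolation.
* **Pre/post pairing** — nearest-point spatial pairing with a 5 mm
  exclusion threshold (many-to-one default, optional one-to-one mode) and
  differential feature maps (post − pre).
* **Quantification & reporting** — threshold-area computation (single and
  joint conditions, mm² and % of total surface), summary statistics
  (mean/median/SD/IQR/range), total activation duration (RVAT), and a
  deterministic per-study/per-ROI/per-feature CSV report.
* **Synthetic study generator** — complete studies with analytically
  planted AT/ARI/Uni-JEl ground truth, configurable noise, contact-force
  distribution and post-phase point dropout (default 36%), so the entire
  pipeline is testable without clinical data.

Studies are stored in a documented HDF5 container (mm/ms/mV/grams, 0-based
indices); OpenEP-style `userdata` MAT files can be imported.

## CLI

```bash
epmap simulate --n-points 400 --dropout 0.36 --seed 7 -o pre.h5 post.h5
epmap filter pre.h5 --force-min 5 --force-max 25 -o pre_f.h5
epmap features pre_f.h5 --lead V2 -o features.csv
epmap map features.csv pre_f.h5 --feature uni_jel_mv -o map.vtk
epmap roi pre_f.h5 --contour 12,85,203,417 --hint 150 -o rvot.json
epmap pair pre.h5 post.h5 --threshold 5 -o pairs.csv
epmap area map.vtk --feature uni_jel_mv --ge 0.85
epmap report pre.h5 post.h5 --roi rvot.json -o report.csv
epmap import --openep userdata.mat -o study.h5
```

## Notes on conventions

* Contact-force filter bounds are inclusive ([5, 25] g); missing forces are
  retained and flagged `force_unknown`.
* Pairing distances exactly at the threshold are retained; strictly greater
  are excluded.
* Threshold areas count a triangle when **all three** vertices satisfy the
  condition (majority/centroid rules selectable); percentages are relative
  to the total mesh area.
* Quartiles use linear interpolation (type-7); SD uses the n−1 denominator
  and is reported missing for n < 2.
* The surface-lead activation fiducial is the literal amplitude minimum by
  default; a config switch (`FeatureConfig.v2_fiducial`) selects the
  derivative minimum instead.
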