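# ieloc

Headless electrode localization for intracranial EEG (iEEG).

Clinical and research iEEG implants carry tens to hundreds of electrode
contacts — stereotactic depth shafts (sEEG) inserted through burr holes and
subdural grids/strips (ECoG) placed on the cortex. Before any neuroscience
inference, every contact must be assigned an accurate position in the
subject's anatomy. Metal contacts are bright, easily detected densities in
the post-implant CT, but clicking hundreds of them by hand is slow and
error-prone, and the raw CT positions disagree with the pre-implant MRI for
subdural contacts because the brain itself shifts after a craniotomy.

`ieloc` is a batch library + CLI covering every computational step of that
workflow on co-registered NIfTI volumes, with no GUI:

- **CT density refinement** — a clicked/seeded position is moved to the
  intensity-weighted center of the nearby above-threshold CT voxels,
  iterated to convergence, so every coordinate sits at the physical contact
  center with sub-voxel precision. The CT is always used at native
  resolution; down-sampling to MRI resolution can erase small contacts
  entirely (the package tests demonstrate exactly this failure).
- **Automatic extrapolation / interpolation** — from two clicked contacts
  (the first two, or the two ends) the remaining contacts of a shaft or
  strip are placed by a stepping rule: predict the next contact from the
  local inter-contact vector, then snap to the best CT density within a
  2 mm search window, excluding voxels near already-placed contacts so no
  density is claimed twice. Re-aiming each step tracks bent shafts and
  strips curving 90° around the occipital pole.
- **Anatomic labeling** — each contact takes the modal label of the 3×3×3
  cube of parcellation voxels centered on it (ties go to the center voxel),
  which is robust to sub-voxel coordinate jitter.
- **Brain-shift correction** — ECoG contacts found *inside* the pial
  envelope of the pre-implant MRI must be there because of brain shift, so
  they are projected to the nearest point on the envelope while a topology
  penalty keeps neighbouring contacts at their original spacing. sEEG
  contacts are never touched; original and shifted coordinates are both
  reported.
- **Value mapping** — per-electrode scalars (power, stimulation-mapping
  categories, time series) are spread onto surface vertices as
  `v · exp(−d · decay_factor / max_radius)` with defaults
  `decay_factor = 1.5`, `max_radius = 1` mm, inverse-distance averaging
  where electrodes overlap, and a nearest-electrode mode for categorical
  data.
- **Interoperability** — one-row-per-electrode plain-text tables and
  BIDS-iEEG export (`*_electrodes.tsv` + `*_coordsystem.json`); value import
  ignores blank/`n/a` cells.

All coordinates are world millimetres, subject-native scanner RAS. The
package consumes the outputs of external registration (ANTs/NiftyReg/FLIRT)
and segmentation (FreeSurfer) tools; it does not run them.

## Worked example

A complete synthetic subject — an 8-contact sEEG shaft and a 6-contact
curved subdural strip rendered into a noisy 0.5 mm CT, a two-region
parcellation, and a spherical pial envelope — can be generated and processed
end to end:

```bash
ieloc simulate --out-dir run --seed 5
ieloc localize --ct run/ct.nii.gz --plan run/plan.json --seeds run/seeds.tsv --out-dir run
ieloc label    --table run/electrodes_table.tsv --parcellation run/labels.nii.gz --lut run/lut.txt --out-dir run
ieloc shift    --table run/electrodes_table.tsv --plan run/plan.json --surface run/pial.surf.gii --out-dir run
ieloc export-bids --table run/electrodes_table.tsv --subject-tag sub-01 --out-dir run
```

which prints

```
fixture bundle written to run
localized 14 of 14 contacts -> run/electrodes_table.tsv
labelled table -> run/electrodes_table.tsv
shift-corrected table -> run/electrodes_table.tsv
exported run/sub-01_electrodes.tsv and run/sub-01_coordsystem.json
```

and the exported BIDS table begins

```
name	x	y	z	size	group
LA1	9.992553	23.997180	20.003037	n/a	LA
LA2	13.502351	23.996596	20.004459	n/a	LA
LA3	16.999687	24.003530	19.992325	n/a	LA
```

The shaft was planted with its first contact at (10, 24, 20) mm and 3.5 mm
pitch, so each row is within a few hundredths of a millimetre of ground
truth despite only the first two contacts having been seeded — the rest were
extrapolated and snapped to the CT. The strip rows additionally carry
`shifted_*` columns with their positions projected back onto the pial
sphere, and every row has an anatomic label from the two-region
parcellation.

The same operations are available as a library
(`ieloc.refine_contact`, `ieloc.extrapolate_shaft`, `ieloc.majority_label`,
`ieloc.correct_brain_shift`, `ieloc.map_values`, …); see the docstrings and
`docs/methods.md`.

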