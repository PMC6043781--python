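# seegloc

Headless SEEG electrode localization and cohort analysis.

In stereoelectroencephalography (SEEG), ~12 depth electrodes with ~10–18
contacts each are implanted along straight trajectories to localize the
epileptogenic zone before resective surgery. Interpreting the recordings —
and pooling them across patients and centers — requires knowing, for every
contact, *where it is*: which atlas parcel, which tissue class (gray/white
matter, CSF), whether it ended up inside the surgical resection, and where
it sits in a common (MNI) reference frame. `seegloc` provides that pipeline
as a Python library plus a thin CLI, for methods developers and clinical
researchers who need reproducible, scriptable localization rather than a GUI:

- **Electrode geometry** — parametric electrode models (segments of contacts
  with lengths and gaps); contact centers computed from a two-point
  trajectory (tip + any shaft point), contact 1 deepest.
- **Contact labeling** — for contact center *c* and sphere radius *r* = 3 mm,
  the label is the mode of atlas values over voxels *v* with
  ‖x(v) − c‖ ≤ r; for cortical atlases the vote is restricted to gray-matter
  voxels, so a contact mostly in white matter still gets a cortical label if
  any labeled GM voxels fall in its sphere. Tissue class by the same majority
  vote; statistical maps (epileptogenicity, PET) by the sphere mean
  (r = 1.5 mm).
- **Resection analysis** — resection mask = seeded connected component of the
  morphological opening of (pre-op brain mask ∧ ¬ post-op brain mask), with
  volume and per-parcel overlap percentages.
- **Cohort store** — single-file SQLite database of patient records
  (electrodes, labels, resection overlap, stimulation responses, Engel
  outcome, MNI coordinates) with conjunctive multi-criteria queries.
- **Group QC** — per-parcel MNI contact clouds screened for parcellation
  failures by two robust detectors: flag point *i* when
  dᵢ − median(d) > 4·MAD with dᵢ the distance to the cloud median and
  MAD = median(|dᵢ − median(d)|); and the Chauvenet criterion
  n·erfc(|xᵢ − mean(x)|/std(x)) < 0.5 per axis.
- **Synthetic fixtures** — deterministic generators of heads, atlases,
  implantations, post-op masks and whole cohorts, so everything above is
  testable without clinical data.

Image registration, segmentation and MNI normalization are out of scope:
transforms, masks and parcellations are *inputs* (NIfTI volumes, 4×4
plain-text matrices, TSV label tables), as produced by SPM/ANTs/FreeSurfer/
BrainVisa-style tooling.

## Worked example

```python
from seegloc import FixtureSpec, make_cohort, qc_report

spec = FixtureSpec(seed=11, n_patients=20, outlier_rate=0.1)
store, truth = make_cohort(spec)       # 20 patients, 12 electrodes x 15 contacts
rep = qc_report(store, "synthatlas")   # 4xMAD + Chauvenet per parcel cloud
print(truth.outlier_patients)          # ['P001', 'P005']
print(rep.flagged_patients("mad"))     # ['P001', 'P005']
print(rep.flagged_patients("chauvenet"))  # ['P001', 'P005']
```

Two of the twenty synthetic patients carry a planted 40 mm normalization
error; both detectors flag exactly those two patients and no one else —
their contacts sit far outside the ~2 mm scatter of each parcel's pooled
contact cloud. More narrative scripts live in `examples/` (placement +
labeling, resection overlap, cohort queries, group QC); each prints the
numbers it computes and what they mean. The same workflow is available from
the shell:

```sh
seegloc simulate --seed 1 --out demo/
seegloc label --electrodes demo/electrodes.json \
    --atlas demo/atlas.nii.gz:demo/atlas.tsv --tissue demo/tissue.nii.gz \
    --out labels.csv
seegloc resection --pre demo/brain_mask_pre.nii.gz --post demo/brain_mask_post.nii.gz \
    --transform demo/post_to_pre.txt --seed 4,-2,-2 --out resec.nii.gz
seegloc qc demo/cohort.db --atlas synthatlas --out suspicious.csv
```

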