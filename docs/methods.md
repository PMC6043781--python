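# Methods

This note documents the models and procedures `seegloc` implements, the
defaults and why, what the synthetic generators emulate (and do not), and
the numerical choices that matter for reproducibility.

## Coordinate conventions

Voxel indices are 0-based; a volume's 4×4 affine maps voxel *centers* to
world millimeters in RAS orientation (the NIfTI convention, as read by
nibabel). Rigid world→world transforms are 4×4 matrices with an orthonormal
rotation part (tolerance 1e-6, determinant +1); they are inputs produced by
an external registration tool, never estimated here. Transform text files
state the direction in a header comment: target-grid world → source-image
world, which is the direction `resample_nearest` consumes.

Resampling is nearest-neighbor only. Every volume this pipeline resamples is
categorical (labels, tissue classes, binary masks), where interpolation
would manufacture values; voxels mapping outside the source grid are filled
with 0 because 0 uniformly means background/unlabeled, and edge-clamping
would silently extend anatomy.

## Contact labeling

An electrode model is an ordered list of segments
`(n_contacts, contact_length_mm, gap_after_mm)` plus an optional
`tip_offset_mm` (default 0: contact 1 starts exactly at the tip point; the
offset field exists so true manufacturer geometries can be encoded).
Contact *i*'s center is `tip + u·(offset_i + L_i/2)` with `u` the unit
vector from tip to shaft point. Contacts are numbered 1 = deepest, matching
clinical convention. The bundled model catalog is *illustrative* (2 mm
contacts at 3.5 mm pitch and variants), not certified manufacturer data.

A contact's atlas label is the modal label over voxels whose centers lie
within a 3 mm-radius sphere of the contact center. For cortical atlases the
candidate set is restricted to voxels that are gray matter *and* carry a
nonzero label — so a contact sitting mostly in white matter is still
assigned a cortical parcel when any labeled GM voxels enter its sphere.
Whether an atlas is cortical is metadata on its label lookup (default
true), not hard-coded per atlas name. Tissue class uses the same sphere and
a majority over nonzero tissue voxels. Statistical maps (epileptogenicity,
PET) are summarized by the sphere *mean* with a separate default radius of
1.5 mm (3 mm diameter); both radii are caller-overridable, and the two
defaults are kept distinct deliberately rather than harmonized. Resection
membership is a single containing-voxel lookup, not a sphere vote — it is a
binary inside/outside call.

Numerical choices: sphere membership is decided on voxel centers at
distance ≤ r (+1e-9 slack against float rounding), which keeps an exact
brute-force oracle possible; majority ties break to the smallest label
integer, tissue ties by fixed GM > WM > CSF priority. The paper-style
labeling rules leave ties unspecified; determinism is required for testing,
so the tie-breaks are part of the contract.

## Resection mask

Pipeline: (1) resample the post-resection brain mask onto the
pre-implantation grid (nearest neighbor — the mask is binary); (2) keep
voxels that are brain pre-operatively but not post-operatively; (3) apply
one morphological opening; (4) label connected components and keep only the
one containing the user's seed point. Defaults: opening by the 6-connected
cross element, 1 iteration — the smallest opening that removes the 1-voxel
misregistration fringe while preserving small resections; components at
26-connectivity — the most permissive choice, avoiding splits of
diagonally-touching cavities. Both are exposed as options ({6,18,26},
iteration count) because no principled single choice exists.

Volume is voxel count × |det| of the affine's 3×3 part. Per-parcel overlap
is the voxel-count percentage of each parcel removed; parcels at 0% are
omitted. Reports carry `brain_shift_unreliable = true`: post-operative
brain deformation is not modeled, so percentages are qualitative.

Error cases are explicit: an empty pre/post difference ("no resection
detected") and a seed falling in no surviving component (reported with the
component count and sizes) are typed errors, never empty masks.

## Cohort store and queries

A patient record holds metadata (center, acquisition year, Engel outcome
class I–IV/unknown), placed electrodes, contact labels, the resection
overlap report, stimulation events and MNI contact coordinates. Records are
persisted in a single-file SQLite database: the full record as a canonical
JSON document plus normalized side tables (labels, MNI coordinates,
resected parcels, stimulation events) that back the SQL queries. A
canonical JSON dump (sorted keys, fixed formatting) provides a portable
export whose bytes are stable across save/load cycles.

Stimulation semantics use closed vocabularies in explicit columns —
response category {not_stimulated, no_response, response_non_epileptic,
seizure_like} and classifications {motor, sensitive, sensory, vegetative,
emotional, experiential, superior_function}, frequencies {1, 50} Hz —
replacing the font/background color coding used in clinical spreadsheets
(gray/black/blue/red font ↔ the four categories;
red/blue/green/yellow/purple/pink/brown background ↔ the seven
classifications). Colors are presentation, not data. Bipoles must pair
adjacent contacts.

Queries are conjunctive: every provided criterion must hold; empty criteria
match all patients and results are sorted by id. "Resected parcel" means
strictly more than `min_percent` removed (default 0: "at least partially").
A stimulated bipole is in a parcel when *either* of its contacts carries
that label (mode `both` available). Parcel and vocabulary names are
validated against the store before querying. The left/right flip for
pooled-hemisphere analyses negates x where x < 0 (an idempotent fold onto
the right half-space).

## Group quality control

A parcel cloud pools, over the cohort, the MNI positions of all contacts
labeled with one parcel. Two detectors flag suspicious contacts:

- **4×MAD rule.** dᵢ = Euclidean distance from point i to the
  component-wise median; MAD = median(|dᵢ − median(d)|); flag when
  dᵢ − median(d) > 4·MAD. Operating on distances (rather than per-axis
  coordinates, which is offered as an option) makes the rule rotation- and
  translation-invariant. When MAD = 0 (degenerate scale), any strictly
  excess distance flags.
- **Chauvenet criterion.** Per axis: flag when
  n·erfc(|xᵢ − mean(x)| / std(x)) < 0.5, with the *population* standard
  deviation and *no* √2 in the argument. This is deliberately the literal
  criterion as used in the SEEG QC practice this package follows, which is
  stricter than the textbook normal-model form; `classic=True` restores the
  √2. The choice of population (not sample) std is stated because it
  changes flags at small n. Zero-variance axes are skipped; a point is
  suspicious if flagged on any axis.

Clouds with fewer than 3 points are never flagged; they are reported as
"insufficient data". The QC report emits one row per flagged contact per
method plus a per-patient summary, in deterministic order.

A consequence worth knowing: on clean Gaussian scatter with no gross
outlier, the literal (no-√2) Chauvenet criterion is aggressive — it will
flag the most extreme honest points, because nothing inflates the standard
deviation. In the failure mode it exists to catch (a whole patient's
contacts displaced tens of mm by a bad normalization), the displaced points
themselves inflate the per-axis std and honest points fall well inside the
threshold. It is a screening tool for gross failures, not a calibrated
hypothesis test.

## Synthetic fixtures

The generators produce structurally faithful stand-ins for the clinical
inputs, fully determined by a `FixtureSpec` (every output is a pure
function of the spec including its seed):

- **Head**: an ellipsoidal brain (semi-axes 0.45× the grid extent) with
  nested shells — CSF outside normalized radius 0.92, gray matter 0.40–0.92,
  white matter inside 0.40 — on a 72³ grid at 1 mm isotropic by default.
  The GM shell is far thicker than real cortex, so 3 mm label spheres fit
  inside single parcels and each electrode collects ~6–7 in-parcel
  contacts; this is what makes exact ground-truth recovery testable.
- **Atlas**: the GM shell partitioned into angular wedges per hemisphere
  (labels 1..n, names `P01_L/P01_R`...), a seeded angular offset, every
  nonzero voxel GM, parcels exactly partitioning GM.
- **Implantation**: 12 electrodes × 15 contacts by default (the scale of a
  typical SEEG case). Each electrode targets a distinct parcel's centroid
  along a radial trajectory — mimicking clinical targeting of chosen
  regions — with a seeded depth jitter and a pairwise contact-separation
  check. Ground truth records, per contact, the parcel when its 3 mm sphere
  is entirely inside one parcel, else "mixed".
- **Post-op mask**: the brain mask minus a rectangular block, with the
  intersected block returned as truth.
- **Cohort**: 20 patients by default, all sharing the template implantation
  (as if implanted under one stereotactic plan). MNI coordinates are the
  template contact positions (the fixture world frame doubles as the MNI
  frame via a fixed identity affine — normalization is out of scope and the
  QC math only needs a shared frame) plus a *per-patient* Gaussian offset
  (σ = 2 mm): normalization error is a property of a patient's warp, not of
  individual contacts. ⌈outlier_rate·n⌉ patients (default 10%) get an
  additional 40 mm displacement along the (1,1,1) diagonal — a planted
  normalization failure. The diagonal direction matters: real failures
  displace in a generic 3D direction, and a displacement confined to one
  axis would leave the other axes' standard deviations clean, where the
  literal Chauvenet criterion then flags honest scatter. Engel classes,
  stimulation events and per-parcel resection percentages are drawn from
  the closed vocabularies; one parcel is reserved so that exactly one
  patient satisfies the combined "contact in parcel AND parcel resected"
  query, giving the query engine a planted exact answer.

What the generators do **not** emulate: MRI intensities and contrast, gyral
anatomy, partial-volume effects at tissue boundaries, electrode bending,
registration error between native volumes (all volumes share the
pre-implantation grid; resampling is exercised with synthetic rigid
transforms), and non-linear MNI warps. Passing tests therefore demonstrate
the correctness of the geometry, counting, morphology, query and outlier
logic on exactly-known ground truth — not robustness to segmentation or
registration noise in real images.

## Problem sizes used in tests and the acceptance script

Oracle comparisons run at: 100 random grids for sphere neighborhoods, 1000
random (volume, center) pairs for labeling, 100 random atlas/mask pairs for
parcel overlap, 500 random clouds for the outlier statistics, 200 random
criteria on a 50-patient cohort for queries, and the full 12×15 = 180
contact implantation for geometry recovery. These sizes give every code
path and tie-break repeated coverage while keeping the whole suite around a
minute on one CPU; the acceptance script reruns them all in a few seconds.

## Known limitations

- Only rigid, straight electrode models; curved-shaft fitting and
  grid/strip geometries are not implemented.
- Resection overlap percentages ignore post-surgical brain shift (flagged
  in the report metadata).
- The gray-matter restriction uses binary tissue classes; no
  distance-to-boundary or cortical-thickness-normalized proximity index.
- `mgz` images are not read; convert to NIfTI first.
- The store validates vocabulary and referential integrity but is not
  concurrent-writer safe; it targets single-analyst workflows.
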