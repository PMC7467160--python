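# Methods

## The model

An NXmx data set is represented as a flat dictionary of positioning axes
keyed by absolute HDF5 path, plus provenance, beam, sample, detector trees
and an image-data reference. Each axis is a rotation or translation with a
dimensionless unit vector (rejected if |v| deviates from 1 by more than
1e-6), an offset vector, and a scalar or per-frame setting. Settings are
normalised on construction and on read to canonical units — degrees for
rotations, millimetres for translations (`m`, `cm`, `um`, `deg`, `rad`
inputs are converted) — so downstream geometry works in one unit system.
Wavelengths are in ångström.

`depends_on` references are stored absolute; a relative reference is
resolved against the referring element's parent group. Chain resolution
walks leaf → root, returns the supporting axes in that order (an element
depending directly on `"."` yields an empty chain), and raises distinct
errors for dangling references and cycles; the validator converts both into
findings instead of exceptions.

## Geometry

One axis at setting *s* realises the rigid transform
`T = Translate(offset) ∘ Motion(s)`: rotations act right-handedly about the
axis vector (matrices from `scipy.spatial.transform.Rotation`), translations
displace by `s·v`. A chain composes leaf-first,
`P_lab = T_root · … · T_leaf · P_local`, matching the convention that each
offset is the displacement from the previous axis in the chain to the base
of the next. The test suite cross-checks this composition against an
independent brute-force oracle (explicit Rodrigues formula and 4×4
homogeneous-matrix products, sharing no code with the implementation) on
1000 seeded random chains of depth ≤ 6, at 1e-12 on rotation entries and
1e-9 mm on translations.

Pixel (i, j) — i slow, j fast, 0-based — refers to the **centre** of the
pixel, and the module origin is the centre of pixel (0, 0). The convention
is a genuine free choice (corner vs centre); centres make beam-centre
recovery symmetric and are what the round-trip tests pin down. Positions are
affine in (i, j), which is itself a tested invariant.

The beam centre intersects the ray from the origin along the beam direction
with each module plane (plane from the module origin and the two in-plane
readout vectors) and expresses the intersection in fractional pixel units by
solving the 3×2 in-plane system by least squares; a module whose plane is
parallel to the beam (|b·n| below 1e-12 of the normal's scale) reports a
no-intersection marker rather than an error. The detector distance is the
along-beam parameter of that intersection for the first intersecting module
— for a tilted detector this is the slant distance (e.g. 200/cos 10° mm for
a whole-detector 10° tilt of a 200 mm rail), not the perpendicular one.

Scattering vectors use the crystallographic convention
`q = (ŝ − b̂)/λ` with `|q| = 2 sin θ/λ`; the magnitude is checked against
the closed form to 1e-12 and is rotation-invariant by construction.

Rotation-scan settings are reported at the **start** of each frame
(`start + k·increment`); integration code wanting mid-frame angles should
shift by `increment/2`. A per-frame angle array stored in the file always
wins over the start+increment reconstruction.

## Laboratory frames

All model vectors live in the McStas frame (Z along the incident beam, Y
up, X left as seen from the source, origin at the sample). The CBF frame is
constructed from the data set itself: X along the principal goniometer axis
(the outermost sample rotation axis), Z the component of the Source vector
(−beam) orthogonal to X — exact Gram–Schmidt, so Z·X = 0 even for a
non-orthogonal beam — and Y = Z × X. Y may point up or down depending on
the goniometer-axis direction; handedness is always right, and the code
computes the actual rotation rather than assuming the common 180°-about-
vertical relation (which it reproduces exactly for the standard layout).

Two deliberate choices:

- **"Vertical" is −Gravity**, not McStas Y, so tilted installations stay
  correct; the Gravity axis is otherwise metadata only.
- **Stills have no goniometer**, leaving CBF X undefined by the standard;
  conversion accepts an explicit axis or defaults to −X_mcstas and records
  that in the data set's notes.

Conversion back to McStas reconstructs the basis from the named Beam and
Gravity vectors as currently expressed, making mcstas→cbf→mcstas a numeric
round trip (< 1e-12, tested). Conversion touches metadata vectors only;
settings and image arrays are never modified.

## Validation

The core rule set is the body of the standard's explicit demands: start_time
and end_time_estimated present and ISO 8601 UTC with the `Z` suffix (end
times not preceding the start), instrument and source names, the NXsample
group always present (name `"."` signals a sample-less run, e.g. a dark
collection), every axis chain resolvable to `"."`, unit axis vectors,
a positive incident wavelength, module readout directions, module slices
inside the image array, and an image-data reference. short_name acronyms,
the beamline time_zone and an observed end_time are recommended-level
(warnings). The fuller supplementary field census is an extension point;
`FieldSpec` carries requirement level and null conventions per field.

Null semantics follow the standard: `"."` marks an absent text value, `"?"`
a value intended to be filled in later, IEEE NaN the float null, and —
since integers have no general null — values outside a declared range (by
default, negative counts on photon-counting data) act as integer nulls.
Placeholder `"?"` values pass required-level validation with a
non-error finding, reading `"?"` as an intent-to-fill marker rather than a
violation.

Reports are deterministic (findings ordered by path then rule id), rules
fire at most once per offending path, and validation is side-effect free.
The mutation catalogue in `synth` gives the rule set a bijection test: each
of 13 single-defect mutants trips exactly its one matching error.

## Synthetic data

The generators emit the two experiment shapes the standard targets:

- **Rotation fixture** (synchrotron use case): one 64 × 60 px panel at
  75 µm pitch, 5 frames of a 0.1°/frame omega scan about −X, wavelength
  0.9795 Å, detector 200 mm downstream, fractional beam centre
  (1225.54, 1306.17) px encoded in the module offset so geometric recovery
  of distance and beam centre is exact by construction. end_time_estimated
  is start + n_frames/frame_rate (default 100 Hz).
- **Hierarchical fixture** (XFEL stills use case): the JUNGFRAU-16M
  topology — 4 quadrants × 8 modules × 8 ASICs (4 × 2) — as a five-level
  chain rail → detector → quadrant → module → ASIC. Quadrant/module/ASIC
  axes point along Z with zero rotation; all positioning is carried in the
  X–Y-plane offset vectors, and group names follow the D{d}Q{q}M{m}A{a}
  scheme (which the generator writes but no code ever parses for meaning).
  ASICs are 8 × 16 px rather than detector-scale: the standard exercises
  topology, not pixel count. The 0.3 mm inter-ASIC gap (doubled between
  modules, quadrupled between quadrants) is a synthetic value chosen only
  to keep panel footprints disjoint, which a pairwise bounding-box test
  verifies in the lab frame.

Image payloads are cosmetic — a seeded Poisson background (λ = 1) with a
few Gaussian spots, int32 — because no metadata operation inspects
intensities; they exist so files have realistic structure and checksums.
Generators are deterministic under a fixed seed. What the fixtures do *not*
emulate: real detector distortions, panel misalignments (all settings are
nominal), realistic diffraction physics, or facility-specific metadata
extensions — so passing tests demonstrate correctness of the metadata
machinery, not robustness to miscalibrated real beamline files.

## I/O

Files follow the NXtransformations pattern: each axis is a dataset whose
value is its setting, with `transformation_type`, `vector`, `offset`,
`offset_units`, `units` and `depends_on` as attributes; every group carries
an `NX_class`. A data set is written as a directory-local pair — entry file
plus `*_data_000001.h5` payload — in either dialect: `master` (exposed
external link) or `vds` (HDF5 virtual data set). Reading accepts both and
yields identical models. Link policies: `follow` (default) resolves the
payload lazily and degrades to metadata-only with a note if the data file
is missing; `skip-data` never touches payloads (geometry stays fully
usable); `error-on-missing` raises. Image payloads in fixtures are written
uncompressed so no compression filter plugins are required to read them.
The writer refuses a data set that fails required-level validation unless
forced, and `track_times` is disabled so outputs are byte-reproducible.

## Known limitations

- Only the body-text core rule list is enforced; the complete
  required/recommended/optional field census is an extension point.
- No imgCIF/CBF file writing — frame conversion re-expresses axis metadata
  only.
- Refined-axis "variants" and NXreflections/NXpdb content are out of scope.
- Whether a module_offset positions the corner or the centre of pixel
  (0, 0) is an interoperability risk against foreign files; this package
  uses centres throughout.
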