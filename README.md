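# nxmxkit

Tools for working with **NXmx** — the NeXus/HDF5 application definition for
macromolecular-crystallography diffraction images — aimed at beamline and
data-pipeline developers who need to read, write, validate and geometrically
resolve such data sets without site-specific patches.

A compliant data set carries the image arrays *and* every piece of metadata
needed to map each pixel into reciprocal space: positioning axes are stored
as `depends_on` chains of `NXtransformations` fields, each with a
dimensionless unit vector **v**, an offset vector **o** (mm) and a setting
(angle in degrees or length in mm), terminating at the beamline fixed point
`"."`. `nxmxkit` provides:

- an in-memory **model** of the whole tree (axes, detector hierarchy, beam,
  sample, provenance) with `resolve_depends_on` chain resolution;
- **geometry**: each axis realises a rigid transform — a rotation `R(v, θ)`
  (right-handed, via Rodrigues) or translation `t = o + s·v` — and a chain
  composes leaf-first, `P_lab = T_root ⋯ T_leaf P_local`. Pixel (i, j) of a
  panel sits at `i·p_slow·ŝ + j·p_fast·f̂` in module coordinates; from its
  lab position the scattering vector is `q = (ŝ − b̂)/λ`, `|q| = 2 sin θ/λ`;
- **frames**: the NeXus McStas frame (Z along the beam, Y up) and the
  imgCIF/CBF frame (X along the principal goniometer axis, Z toward the
  source, Gram–Schmidt-orthogonalised for tilted beams), with exact
  conversion of whole data sets between them;
- a **validator** for the core required/recommended rules (collection
  times in UTC `Z` form, instrument/source names, the always-required
  NXsample group, resolvable axis chains, unit vectors, wavelength, data),
  plus the standard's null-value semantics (`"."`, `"?"`, NaN,
  out-of-range integers);
- **HDF5 I/O** for both common dialects — `*_master.h5` files with exposed
  external links and `.nxs` virtual-data-set (VDS) files;
- a **synthetic generator** for fully compliant fixtures (a single-axis
  rotation series, and a JUNGFRAU-16M-like hierarchy of 4 quadrants ×
  8 modules × 8 ASICs) and a catalogue of single-defect mutants for
  validator testing — so everything is testable offline.

## Worked example

Generate a compliant 5-frame rotation data set, inspect it, and place a
pixel in the laboratory frame:

```console
$ nxmx generate --template rotation --out demo --seed 1
wrote demo/rotation_master.h5

$ nxmx describe demo/rotation_master.h5
instrument: Synthetic Beamline S01 (S01)
source:     Synthetic Light Source (SYNLS)
start_time: 2026-03-02T10:00:00Z   end_time_estimated: 2026-03-02T10:00:00Z
frame convention: mcstas
data: external link, shape (5, 64, 60)
sample chain: omega -> .
detectors: 1; module leaves: 1
  ELE_D0/ARRAY_D0M0 chain (2 axes): AXIS_D0M0 -> AXIS_RAIL -> .

$ nxmx geometry demo/rotation_master.h5 --pixel 32 30 --q
pixel (32, 30) of ARRAY_D0M0 @ frame 0: (95.712750, 89.515500, 200.000000) mm
q: (0.408664, 0.382204, -0.166991) 1/angstrom, |q| = 0.583928

$ nxmx validate demo/rotation_master.h5 --level recommended
verdict: COMPLIANT (0 errors, 0 warnings)
```

The pixel position is in McStas coordinates: the detector rail places the
panel 200 mm downstream (Z), and the module offset puts the fractional beam
centre (1225.54, 1306.17 px at 75 µm pitch) on the beam axis, so pixel
(32, 30) lands at X = (1306.17 − 30)·0.075 ≈ 95.71 mm, Y = (1225.54 −
32)·0.075 ≈ 89.52 mm. Its scattering vector at λ = 0.9795 Å has
|q| ≈ 0.584 Å⁻¹ (≈ 1.7 Å resolution).

Converting the same file to the imgCIF/CBF frame reports the applied
rotation — for this standard layout, exactly the textbook relation:

```console
$ nxmx convert demo/rotation_master.h5 --to cbf --out demo/rotation_cbf_master.h5
converted mcstas -> cbf: rotation 180.000000 deg about (0.000000, 1.000000, 0.000000)
wrote demo/rotation_cbf_master.h5
```

The same operations are available as a library (`nxmxkit.read_nxmx`,
`validate`, `beam_center`, `detector_distance`, `scattering_vector`,
`convert_dataset`, `make_rotation_fixture`, …).

## Layout

- `src/nxmxkit/model.py` — domain types, chain resolution, unit handling
- `src/nxmxkit/geometry.py` — axis transforms, pixel/lab mapping, q vectors
- `src/nxmxkit/frames.py` — McStas/CBF conventions and conversion
- `src/nxmxkit/validator.py` — core-rule compliance reports, null semantics
- `src/nxmxkit/io_nxmx.py` — master-link and VDS HDF5 dialects
- `src/nxmxkit/synth.py` — compliant fixtures and single-defect mutants
- `src/nxmxkit/cli.py` — `nxmx validate | describe | geometry | convert | generate`
- `docs/methods.md` — models, conventions and design choices in detail
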