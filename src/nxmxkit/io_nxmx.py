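"""Serialisation of the data-set model to and from NeXus/HDF5 NXmx files.

Two on-disk dialects are supported, mirroring common beamline practice:
a ``master`` file whose /entry/data/data is an exposed external link into a
separate data file, and a ``vds`` file whose /entry/data/data is an HDF5
virtual data set over the same payload.  Axes are stored the NXtransformations
way: each axis is a field whose value is the setting (scalar or per-frame
array) carrying transformation_type, vector, offset, offset_units, units and
depends_on as attributes.
"""

from __future__ import annotations

import os
import posixpath
from dataclasses import dataclass, field
from typing import Optional

import h5py
import numpy as np

from .model import (
    TERMINATOR,
    AxisDefinition,
    BeamDescriptor,
    DataReference,
    DetectorModuleSpec,
    DetectorTree,
    NXmxDataSet,
    NXmxError,
    PixelDirection,
    ProvenanceBlock,
    SampleBlock,
    Scan,
    angle_to_degrees,
    length_to_mm,
    wavelength_to_angstrom,
)

__all__ = ["LinkResolutionPolicy", "read_nxmx", "write_nxmx"]

_BEAM_AXIS = "/entry/instrument/transformations/Beam"
_GRAVITY_AXIS = "/entry/instrument/transformations/Gravity"
_MODULE_FIELDS = ("fast_pixel_direction", "slow_pixel_direction", "module_offset")


@dataclass
class LinkResolutionPolicy:
    """How to treat external/virtual image-data links while reading.

    ``follow`` resolves links and records the payload location (tolerating a
    missing data file, since geometry never needs pixel values);
    ``skip-data`` loads metadata only; ``error-on-missing`` raises when a
    linked data file cannot be found.
    """

    mode: str = "follow"  # follow | skip-data | error-on-missing
    search_dirs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in ("follow", "skip-data", "error-on-missing"):
            raise ValueError(f"unknown link policy mode {self.mode!r}")


def _dset(group: h5py.Group, name: str, data, **attrs) -> h5py.Dataset:
    ds = group.create_dataset(name, data=data, track_times=False)
    for key, value in attrs.items():
        ds.attrs[key] = value
    return ds


def _group(parent, name: str, nx_class: str) -> h5py.Group:
    grp = parent.require_group(name)
    grp.attrs["NX_class"] = nx_class
    return grp


def _write_axis(fh: h5py.File, axis: AxisDefinition) -> None:
    parent_path, leaf = posixpath.split(axis.name)
    grp = _group(fh, parent_path, "NXtransformations")
    _dset(
        grp,
        leaf,
        axis.setting,
        transformation_type=axis.transformation_type,
        vector=np.asarray(axis.vector, dtype=float),
        offset=np.asarray(axis.offset, dtype=float),
        offset_units=axis.offset_units,
        units=axis.setting_units,
        depends_on=axis.depends_on,
    )


def _write_pixel_direction(grp: h5py.Group, name: str, pd: PixelDirection) -> None:
    _dset(
        grp,
        name,
        pd.pitch_mm,
        transformation_type="translation",
        vector=np.asarray(pd.vector, dtype=float),
        offset=np.zeros(3),
        units="mm",
        depends_on=pd.depends_on,
    )


def write_nxmx(
    dataset: NXmxDataSet,
    path,
    dialect: str = "master",
    force: bool = False,
) -> str:
    """Write a data set to disk; returns the entry-file path written.

    The image payload (when held in memory) goes into a sibling
    ``*_data_000001.h5`` file; the entry file references it through an
    external link (``master`` dialect) or a virtual data set (``vds``).
    A data set failing required-level validation is refused unless
    ``force`` is set.
    """
    if dialect not in ("master", "vds"):
        raise ValueError(f"unknown dialect {dialect!r}")
    from .validator import validate  # local import to avoid a cycle

    report = validate(dataset, "required")
    if not report.verdict and not force:
        raise NXmxError(
            "refusing to write a non-compliant data set (use force=True): "
            + "; ".join(f.rule_id for f in report.errors())
        )

    path = os.fspath(path)
    stem = path
    for suffix in (".nxs", ".h5", ".hdf5"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    if stem.endswith("_master"):
        stem = stem[: -len("_master")]

    data_ref = dataset.data
    data_fname = None
    if data_ref is not None and data_ref.link != "internal":
        data_fname = f"{os.path.basename(stem)}_data_000001.h5"
        data_path = os.path.join(os.path.dirname(path) or ".", data_fname)
        payload = None
        if data_ref.array is not None:
            payload = data_ref.array
        elif data_ref.source_file is not None and os.path.exists(data_ref.source_file):
            payload = data_ref.materialize()
        if payload is not None:
            with h5py.File(data_path, "w") as dfh:
                dfh.create_dataset(
                    "data", data=payload, track_times=False, chunks=(1,) + payload.shape[1:]
                )

    with h5py.File(path, "w") as fh:
        entry = _group(fh, "entry", "NXentry")
        _dset(entry, "definition", "NXmx")
        prov = dataset.provenance
        for name in ("start_time", "end_time_estimated", "end_time"):
            value = getattr(prov, name)
            if value is not None:
                _dset(entry, name, value)

        instrument = _group(entry, "instrument", "NXinstrument")
        if prov.instrument_name is not None:
            attrs = {}
            if prov.instrument_short_name is not None:
                attrs["short_name"] = prov.instrument_short_name
            _dset(instrument, "name", prov.instrument_name, **attrs)
        if prov.time_zone is not None:
            _dset(instrument, "time_zone", prov.time_zone)

        source = _group(entry, "source", "NXsource")
        if prov.source_name is not None:
            attrs = {}
            if prov.source_short_name is not None:
                attrs["short_name"] = prov.source_short_name
            _dset(source, "name", prov.source_name, **attrs)

        if dataset.beam is not None:
            beam_grp = _group(instrument, "beam", "NXbeam")
            _dset(
                beam_grp,
                "incident_wavelength",
                dataset.beam.incident_wavelength,
                units="angstrom",
            )
            # named Beam and Gravity direction axes, so the metadata fully
            # document the McStas frame without consulting the literature
            for apath, vec in (
                (_BEAM_AXIS, dataset.beam.beam_direction),
                (_GRAVITY_AXIS, dataset.beam.gravity_direction),
            ):
                _write_axis(
                    fh,
                    AxisDefinition(
                        name=apath,
                        transformation_type="translation",
                        vector=vec,
                        setting=0.0,
                        depends_on=TERMINATOR,
                    ),
                )

        if dataset.sample is not None:
            sample = _group(entry, "sample", "NXsample")
            _dset(sample, "name", dataset.sample.name)
            _dset(sample, "depends_on", dataset.sample.depends_on)

        for axis in dataset.axes.values():
            _write_axis(fh, axis)

        for det in dataset.detectors:
            det_grp = _group(instrument, det.name, "NXdetector")
            _dset(det_grp, "depends_on", det.depends_on)
            for module in det.modules:
                mod_grp = _group(det_grp, module.name, "NXdetector_module")
                _dset(mod_grp, "data_origin", np.asarray(module.data_origin, dtype=np.int64))
                _dset(mod_grp, "data_size", np.asarray(module.data_size, dtype=np.int64))
                if module.fast_pixel_direction is not None:
                    _write_pixel_direction(
                        mod_grp, "fast_pixel_direction", module.fast_pixel_direction
                    )
                if module.slow_pixel_direction is not None:
                    _write_pixel_direction(
                        mod_grp, "slow_pixel_direction", module.slow_pixel_direction
                    )
                if module.module_offset is not None:
                    _write_axis(fh, module.module_offset)

        data_grp = _group(entry, "data", "NXdata")
        data_grp.attrs["signal"] = "data"
        if data_ref is not None:
            if data_ref.link == "internal":
                payload = data_ref.materialize()
                data_grp.create_dataset("data", data=payload, track_times=False)
            elif dialect == "master":
                data_grp["data"] = h5py.ExternalLink(data_fname, "/data")
            else:  # vds dialect
                shape = tuple(data_ref.shape)
                layout = h5py.VirtualLayout(shape=shape, dtype=data_ref.dtype)
                layout[...] = h5py.VirtualSource(data_fname, "data", shape=shape)
                data_grp.create_virtual_dataset("data", layout)

        if dataset.notes:
            _dset(entry, "notes", "\n".join(dataset.notes))
        fh["/entry"].attrs["frame_convention"] = dataset.frame
    return path


# ---------------------------------------------------------------------------
# reading


def _read_str(obj) -> str:
    value = obj[()] if isinstance(obj, h5py.Dataset) else obj
    if isinstance(value, bytes):
        return value.decode("utf-8")
    return str(value)


def _attr_str(ds, name: str, default=None):
    if name not in ds.attrs:
        return default
    value = ds.attrs[name]
    if isinstance(value, bytes):
        return value.decode("utf-8")
    return str(value)


def _read_axis(ds: h5py.Dataset, path: str) -> AxisDefinition:
    ttype = _attr_str(ds, "transformation_type")
    units = _attr_str(ds, "units", "deg" if ttype == "rotation" else "mm")
    setting = ds[()]
    if ttype == "rotation":
        setting = angle_to_degrees(setting, units)
    else:
        setting = length_to_mm(setting, units)
    if np.ndim(setting) == 0:
        setting = float(setting)
    return AxisDefinition(
        name=path,
        transformation_type=ttype,
        vector=np.asarray(ds.attrs["vector"], dtype=float),
        offset=np.asarray(ds.attrs.get("offset", np.zeros(3)), dtype=float),
        offset_units=_attr_str(ds, "offset_units", "mm"),
        setting=setting,
        setting_units="deg" if ttype == "rotation" else "mm",
        depends_on=_attr_str(ds, "depends_on", TERMINATOR),
    )


def _read_pixel_direction(ds: h5py.Dataset) -> PixelDirection:
    units = _attr_str(ds, "units", "mm")
    return PixelDirection(
        vector=np.asarray(ds.attrs["vector"], dtype=float),
        pitch_mm=float(length_to_mm(ds[()], units)),
        depends_on=_attr_str(ds, "depends_on", TERMINATOR),
    )


def _nx_class(obj) -> Optional[str]:
    return _attr_str(obj, "NX_class") if hasattr(obj, "attrs") else None


def _collect_axes(entry: h5py.Group, entry_prefix: str) -> dict:
    """All NXtransformations-style axis fields, keyed by absolute path."""
    axes = {}

    def visit(name, obj):
        if not isinstance(obj, h5py.Dataset):
            return
        if "transformation_type" not in obj.attrs or "vector" not in obj.attrs:
            return
        leaf = posixpath.basename(name)
        if leaf in _MODULE_FIELDS:
            return  # module-level fields are read with their module
        path = f"{entry_prefix}/{name}"
        if path in (_BEAM_AXIS, _GRAVITY_AXIS):
            return  # folded into the BeamDescriptor
        axes[path] = _read_axis(obj, path)

    entry.visititems(visit)
    return axes


def _resolve_data_file(fname: str, master_path: str, policy: LinkResolutionPolicy):
    candidates = [os.path.join(os.path.dirname(master_path) or ".", fname), fname]
    candidates += [os.path.join(d, os.path.basename(fname)) for d in policy.search_dirs]
    for cand in candidates:
        if os.path.exists(cand):
            return cand
    return None


def read_nxmx(path, policy: Optional[LinkResolutionPolicy] = None) -> NXmxDataSet:
    """Read an NXmx entry file (master-link or VDS dialect) into the model."""
    if policy is None:
        policy = LinkResolutionPolicy()
    path = os.fspath(path)
    with h5py.File(path, "r") as fh:
        entry = None
        for name, obj in fh.items():
            if isinstance(obj, h5py.Group) and _nx_class(obj) == "NXentry":
                entry = obj
                break
        if entry is None:
            raise NXmxError(f"{path}: no NXentry group found")
        prefix = entry.name  # absolute path of the entry group

        ds = NXmxDataSet()
        ds.frame = _attr_str(entry, "frame_convention", "mcstas")
        prov = ProvenanceBlock()
        for fname in ("start_time", "end_time_estimated", "end_time"):
            if fname in entry:
                setattr(prov, fname, _read_str(entry[fname]))
        instrument = entry.get("instrument")
        if instrument is not None:
            if "name" in instrument:
                prov.instrument_name = _read_str(instrument["name"])
                prov.instrument_short_name = _attr_str(instrument["name"], "short_name")
            if "time_zone" in instrument:
                prov.time_zone = _read_str(instrument["time_zone"])
        source = entry.get("source")
        if source is not None and "name" in source:
            prov.source_name = _read_str(source["name"])
            prov.source_short_name = _attr_str(source["name"], "short_name")
        ds.provenance = prov

        if "notes" in entry:
            ds.notes = _read_str(entry["notes"]).splitlines()

        if instrument is not None and "beam" in instrument:
            beam_grp = instrument["beam"]
            wl = float("nan")
            if "incident_wavelength" in beam_grp:
                wl_ds = beam_grp["incident_wavelength"]
                wl = wavelength_to_angstrom(
                    wl_ds[()], _attr_str(wl_ds, "units", "angstrom")
                )
            beam_dir, gravity_dir = None, None
            trans = instrument.get("transformations")
            if trans is not None:
                if "Beam" in trans:
                    beam_dir = np.asarray(trans["Beam"].attrs["vector"], dtype=float)
                if "Gravity" in trans:
                    gravity_dir = np.asarray(trans["Gravity"].attrs["vector"], dtype=float)
            ds.beam = BeamDescriptor(wl, beam_dir, gravity_dir)

        if "sample" in entry:
            sample_grp = entry["sample"]
            name = _read_str(sample_grp["name"]) if "name" in sample_grp else TERMINATOR
            dep = (
                _read_str(sample_grp["depends_on"])
                if "depends_on" in sample_grp
                else TERMINATOR
            )
            ds.sample = SampleBlock(name=name, depends_on=dep)

        ds.axes = _collect_axes(entry, prefix)

        if instrument is not None:
            for det_name, det_obj in instrument.items():
                if _nx_class(det_obj) != "NXdetector":
                    continue
                dep = (
                    _read_str(det_obj["depends_on"])
                    if "depends_on" in det_obj
                    else TERMINATOR
                )
                det = DetectorTree(name=det_name, depends_on=dep)
                for mod_name, mod_obj in det_obj.items():
                    if _nx_class(mod_obj) != "NXdetector_module":
                        continue
                    fast = slow = offset_axis = None
                    if "fast_pixel_direction" in mod_obj:
                        fast = _read_pixel_direction(mod_obj["fast_pixel_direction"])
                    if "slow_pixel_direction" in mod_obj:
                        slow = _read_pixel_direction(mod_obj["slow_pixel_direction"])
                    if "module_offset" in mod_obj:
                        offset_axis = _read_axis(
                            mod_obj["module_offset"], f"{mod_obj.name}/module_offset"
                        )
                    det.modules.append(
                        DetectorModuleSpec(
                            name=mod_name,
                            data_origin=tuple(mod_obj["data_origin"][()]),
                            data_size=tuple(mod_obj["data_size"][()]),
                            fast_pixel_direction=fast,
                            slow_pixel_direction=slow,
                            module_offset=offset_axis,
                        )
                    )
                det.modules.sort(key=lambda m: m.name)
                ds.detectors.append(det)
            ds.detectors.sort(key=lambda d: d.name)

        # ---- image data reference --------------------------------------
        data_grp = entry.get("data")
        link = data_grp.get("data", getlink=True) if data_grp is not None else None
        if link is not None:
            ref = DataReference(path=f"{data_grp.name}/data")
            if isinstance(link, h5py.ExternalLink):
                ref.link = "external"
                if policy.mode != "skip-data":
                    target = _resolve_data_file(link.filename, path, policy)
                    if target is None:
                        if policy.mode == "error-on-missing":
                            raise FileNotFoundError(
                                f"external data file {link.filename!r} not found"
                            )
                        ds.notes.append(
                            f"external data file {link.filename!r} missing; metadata-only"
                        )
                    else:
                        ref.source_file = target
                        ref.source_dataset = link.path
                        with h5py.File(target, "r") as dfh:
                            ref.shape = dfh[link.path].shape
                            ref.dtype = str(dfh[link.path].dtype)
            else:
                dset = data_grp["data"]
                ref.shape = dset.shape
                ref.dtype = str(dset.dtype)
                if dset.is_virtual:
                    ref.link = "virtual"
                    if policy.mode != "skip-data":
                        sources = dset.virtual_sources()
                        if sources:
                            target = _resolve_data_file(
                                sources[0].file_name, path, policy
                            )
                            if target is None and policy.mode == "error-on-missing":
                                raise FileNotFoundError(
                                    f"VDS source {sources[0].file_name!r} not found"
                                )
                            ref.source_file = target
                            ref.source_dataset = sources[0].dset_name
                else:
                    ref.link = "internal"
                    if policy.mode != "skip-data":
                        ref.array = dset[()]
            ds.data = ref

        # ---- scan reconstruction ----------------------------------------
        if ds.sample is not None and ds.sample.depends_on in ds.axes:
            axis = ds.axes[ds.sample.depends_on]
            if axis.is_rotation and np.ndim(axis.setting) == 1:
                arr = np.asarray(axis.setting)
                inc = float(arr[1] - arr[0]) if arr.size > 1 else 0.0
                ds.scan = Scan(
                    axis_path=axis.name,
                    start_deg=float(arr[0]),
                    increment_deg=max(inc, 0.0),
                    n_frames=arr.size,
                    per_frame=arr,
                )
    return ds
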