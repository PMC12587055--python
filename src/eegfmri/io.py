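"""File formats: BrainVision EEG triples and NIfTI volumes.

EEG is written as a BrainVision triple (.vhdr header, .vmrk markers,
.eeg binary) with multiplexed IEEE float32 samples in microvolts — the
dialect that round-trips losslessly at float32 precision.  Pipeline
event types map to marker (type, description) pairs (configurable);
channel roles and montage are persisted in a commented JSON block in the
header, which third-party readers ignore.  Volumes use NIfTI-1 via
nibabel, with the TR stored in ``pixdim[4]``.
"""

from __future__ import annotations

import json
import os

import nibabel as nib
import numpy as np

from .recording import EEGRecording
from .volumes import Parcellation, VolumeSeries

__all__ = [
    "write_brainvision",
    "read_brainvision",
    "write_nifti",
    "read_nifti",
    "write_parcellation",
    "read_parcellation",
    "BrainVisionParseError",
]


class BrainVisionParseError(ValueError):
    """Malformed BrainVision file; message names the offending line."""


#: event type -> (marker type, marker description)
DEFAULT_MARKER_MAP = {
    "volume_trigger": ("Response", "R  1"),
    "r_peak": ("Response", "R128"),
    "block_open": ("Stimulus", "S  1"),
    "block_closed": ("Stimulus", "S  2"),
}


def write_brainvision(
    rec: EEGRecording, basepath: str, marker_map: dict | None = None
) -> None:
    """Write ``basepath``.vhdr/.vmrk/.eeg (float32 multiplexed, microvolts)."""
    marker_map = DEFAULT_MARKER_MAP if marker_map is None else marker_map
    base = os.path.basename(basepath)
    meta = {
        "roles": rec.roles,
        "reference": rec.reference,
        "bad_channels": sorted(rec.bad_channels),
        "montage": None if rec.montage is None else rec.montage.tolist(),
    }
    interval_us = 1e6 / rec.rate
    lines = [
        "BrainVision Data Exchange Header File Version 1.0",
        "; Written by eegfmri",
        f"; eegfmri-meta: {json.dumps(meta)}",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={base}.eeg",
        f"MarkerFile={base}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={interval_us!r}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, lab in enumerate(rec.labels):
        lines.append(f"Ch{i + 1}={lab},,1,µV")
    with open(basepath + ".vhdr", "w", encoding="utf-8") as f:
        f.write("\n".join(lines) + "\n")

    mlines = [
        "BrainVision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={base}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0",
    ]
    for i, (s, etype) in enumerate(sorted(rec.events)):
        mtype, mdesc = marker_map.get(etype, ("Comment", etype))
        # BrainVision positions are 1-based
        mlines.append(f"Mk{i + 2}={mtype},{mdesc},{s + 1},1,0")
    with open(basepath + ".vmrk", "w", encoding="utf-8") as f:
        f.write("\n".join(mlines) + "\n")

    rec.data.astype("<f4").T.tofile(basepath + ".eeg")


def _parse_sections(path: str) -> tuple[dict, dict]:
    """Parse an INI-like BrainVision file into {section: {key: value}}."""
    sections: dict[str, dict] = {}
    meta = {}
    current = None
    with open(path, encoding="utf-8") as f:
        for lineno, raw in enumerate(f, start=1):
            line = raw.strip()
            if line.startswith("; eegfmri-meta:"):
                meta = json.loads(line.split(":", 1)[1])
                continue
            if not line or line.startswith(";"):
                continue
            if line.startswith("[") and line.endswith("]"):
                current = line[1:-1]
                sections[current] = {}
                continue
            if line.startswith("Brain"):
                continue
            if "=" not in line:
                raise BrainVisionParseError(
                    f"{os.path.basename(path)} line {lineno}: expected key=value, got {line!r}"
                )
            if current is None:
                raise BrainVisionParseError(
                    f"{os.path.basename(path)} line {lineno}: entry before any section"
                )
            key, val = line.split("=", 1)
            sections[current][key.strip()] = val.strip()
    return sections, meta


def read_brainvision(path: str, marker_map: dict | None = None) -> EEGRecording:
    """Read a BrainVision triple written by :func:`write_brainvision`.

    ``path`` may point to the .vhdr or be the extensionless base path.
    """
    marker_map = DEFAULT_MARKER_MAP if marker_map is None else marker_map
    inverse = {v: k for k, v in marker_map.items()}
    if path.endswith(".vhdr"):
        base = path[:-5]
    else:
        base = path
    sections, meta = _parse_sections(base + ".vhdr")
    common = sections.get("Common Infos", {})
    binary = sections.get("Binary Infos", {})
    if binary.get("BinaryFormat") != "IEEE_FLOAT_32":
        raise BrainVisionParseError(
            f"unsupported binary layout {binary.get('BinaryFormat')!r}"
        )
    if common.get("DataOrientation", "MULTIPLEXED") != "MULTIPLEXED":
        raise BrainVisionParseError("only multiplexed orientation supported")
    n_ch = int(common["NumberOfChannels"])
    rate = 1e6 / float(common["SamplingInterval"])
    chans = sections.get("Channel Infos", {})
    labels = []
    for i in range(n_ch):
        entry = chans.get(f"Ch{i + 1}")
        if entry is None:
            raise BrainVisionParseError(f"missing channel entry Ch{i + 1}")
        labels.append(entry.split(",")[0])
    raw = np.fromfile(base + ".eeg", dtype="<f4")
    if raw.size % n_ch:
        raise BrainVisionParseError(
            f"binary size {raw.size} not a multiple of {n_ch} channels"
        )
    data = raw.reshape(-1, n_ch).T.astype(np.float64)

    events = []
    msec, _ = _parse_sections(base + ".vmrk")
    for key, val in msec.get("Marker Infos", {}).items():
        parts = val.split(",")
        if len(parts) < 3:
            raise BrainVisionParseError(f"malformed marker {key}={val!r}")
        mtype, mdesc, pos = parts[0], parts[1], int(parts[2])
        if mtype == "New Segment":
            continue
        etype = inverse.get((mtype, mdesc), mdesc or mtype)
        events.append((pos - 1, etype))

    roles = meta.get("roles") or ["scalp"] * n_ch
    montage = meta.get("montage")
    return EEGRecording(
        data=data,
        rate=rate,
        labels=labels,
        roles=roles,
        events=sorted(events),
        bad_channels=set(meta.get("bad_channels", [])),
        montage=None if montage is None else np.asarray(montage),
        reference=meta.get("reference", "recording"),
    )


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------


def write_nifti(vol: VolumeSeries, path: str) -> None:
    """Write a NIfTI-1 image; voxel sizes and TR go into pixdim."""
    affine = np.diag(list(vol.voxel_size) + [1.0])
    img = nib.Nifti1Image(vol.data.astype(np.float32), affine)
    zooms = list(vol.voxel_size)
    if vol.data.ndim == 4:
        zooms.append(vol.tr if vol.tr else 1.0)
        img.header.set_xyzt_units("mm", "sec")
    img.header.set_zooms(zooms)
    nib.save(img, path)


def read_nifti(path: str) -> VolumeSeries:
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim not in (3, 4):
        raise ValueError(f"expected 3D or 4D image, got {data.ndim}D")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if data.ndim == 4 and len(zooms) > 3 else None
    return VolumeSeries(data=data, voxel_size=tuple(float(z) for z in zooms[:3]), tr=tr)


def write_parcellation(parc: Parcellation, path: str) -> None:
    """Label volume as int16 NIfTI plus a JSON name-map sidecar."""
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(parc.labels.astype(np.int16), affine), path)
    sidecar = {
        "names": {str(k): v for k, v in parc.names.items()},
        "background_label": parc.background_label,
    }
    with open(_sidecar_path(path), "w", encoding="utf-8") as f:
        json.dump(sidecar, f, indent=1)


def read_parcellation(path: str) -> Parcellation:
    img = nib.load(path)
    labels = np.asarray(img.dataobj).astype(np.int32)
    names, background = {}, 0
    sc = _sidecar_path(path)
    if os.path.exists(sc):
        with open(sc, encoding="utf-8") as f:
            side = json.load(f)
        names = {int(k): v for k, v in side.get("names", {}).items()}
        background = side.get("background_label", 0)
    return Parcellation(labels=labels, names=names, background_label=background)


def _sidecar_path(path: str) -> str:
    for ext in (".nii.gz", ".nii"):
        if path.endswith(ext):
            return path[: -len(ext)] + ".json"
    return path + ".json"
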