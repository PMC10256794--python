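"""On-disk formats: TSV tables, text streamlines, NIfTI volumes, JSON truth.

All text formats are plain TSV with header ids and 12-significant-digit
floats, so write -> read round-trips are identity to ~1e-9.  Volumes go
through NIfTI-1 with a diagonal affine (RAS mm); non-diagonal affines
are rejected rather than resampled.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import (
    BoldVolume,
    ConnectivityMatrix,
    ContactSet,
    StreamlineSet,
    TimeSeriesPanel,
    WmCouplingError,
)
from .synth import GroundTruth

__all__ = [
    "FormatError",
    "MalformedHeaderError",
    "IdMismatchError",
    "DimensionMismatchError",
    "DuplicateIdError",
    "read_contacts", "write_contacts",
    "read_matrix", "write_matrix",
    "read_panel", "write_panel",
    "read_streamlines", "write_streamlines",
    "read_volume", "write_volume",
    "read_ground_truth", "write_ground_truth",
    "read_study_table", "write_study_table",
]

_FLOAT_FMT = "%.12g"


class FormatError(WmCouplingError):
    """Malformed on-disk artifact."""


class MalformedHeaderError(FormatError):
    """Missing or wrong header line/columns."""


class IdMismatchError(FormatError):
    """Ids disagree between related files or within one file."""


class DimensionMismatchError(FormatError):
    """Row/column counts disagree with the declared ids."""


class DuplicateIdError(FormatError):
    """An id column contains duplicates."""


CONTACT_COLUMNS = ["contact_id", "x_mm", "y_mm", "z_mm", "tissue"]


def write_contacts(path: str | Path, contacts: ContactSet) -> None:
    df = pd.DataFrame(
        {
            "contact_id": contacts.ids,
            "x_mm": contacts.coords[:, 0],
            "y_mm": contacts.coords[:, 1],
            "z_mm": contacts.coords[:, 2],
            "tissue": contacts.tissue,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_contacts(path: str | Path) -> ContactSet:
    df = pd.read_csv(path, sep="\t", dtype={"contact_id": str})
    if list(df.columns) != CONTACT_COLUMNS:
        raise MalformedHeaderError(
            f"contact table needs columns {CONTACT_COLUMNS}, got {list(df.columns)}"
        )
    if df["contact_id"].duplicated().any():
        dup = df.loc[df["contact_id"].duplicated(), "contact_id"].tolist()
        raise DuplicateIdError(f"duplicate contact id(s): {dup}")
    return ContactSet(
        ids=tuple(df["contact_id"]),
        coords=df[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
        tissue=tuple(df["tissue"]),
    )


def write_matrix(path: str | Path, m: ConnectivityMatrix) -> None:
    df = pd.DataFrame(m.values, index=list(m.nodes), columns=list(m.nodes))
    with open(path, "w") as fh:
        fh.write(f"# modality: {m.modality}\n")
        if m.band is not None:
            fh.write(f"# band: {m.band}\n")
        df.to_csv(fh, sep="\t", float_format=_FLOAT_FMT, index_label="node")


def read_matrix(path: str | Path) -> ConnectivityMatrix:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", index_col=0)
    if "modality" not in meta:
        raise MalformedHeaderError("matrix file lacks a '# modality:' header")
    cols = [str(c) for c in df.columns]
    rows = [str(r) for r in df.index]
    if cols != rows:
        raise IdMismatchError("matrix row ids do not match column ids")
    if len(set(cols)) != len(cols):
        raise DuplicateIdError("duplicate node ids in matrix header")
    if df.shape[0] != df.shape[1]:
        raise DimensionMismatchError(f"matrix is {df.shape}, expected square")
    return ConnectivityMatrix(
        values=df.to_numpy(float), nodes=tuple(cols),
        modality=meta["modality"], band=meta.get("band"),
    )


def write_panel(path: str | Path, panel: TimeSeriesPanel) -> None:
    t = np.arange(panel.n_samples) / panel.fs
    df = pd.DataFrame(panel.values.T, columns=list(panel.channel_ids))
    df.insert(0, "time_s", t)
    with open(path, "w") as fh:
        fh.write(f"# fs_hz: {panel.fs:.12g}\n")
        fh.write(f"# modality: {panel.modality}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_panel(path: str | Path) -> TimeSeriesPanel:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    if df.columns[0] != "time_s":
        raise MalformedHeaderError("panel file must start with a 'time_s' column")
    if "fs_hz" in meta:
        fs = float(meta["fs_hz"])
    else:
        dt = np.diff(df["time_s"].to_numpy(float))
        if len(dt) == 0 or np.ptp(dt) > 1e-9 * dt[0]:
            raise FormatError("cannot infer sampling rate from irregular time column")
        fs = 1.0 / float(dt[0])
    chans = [str(c) for c in df.columns[1:]]
    if len(set(chans)) != len(chans):
        raise DuplicateIdError("duplicate channel ids in panel header")
    return TimeSeriesPanel(
        values=df[df.columns[1:]].to_numpy(float).T,
        fs=fs, channel_ids=tuple(chans), modality=meta.get("modality", "seeg"),
    )


def write_streamlines(path: str | Path, lines: StreamlineSet) -> None:
    """One polyline per block of 'x y z' rows; blocks separated by blank lines."""
    with open(path, "w") as fh:
        fh.write("# streamlines: one polyline per block of x y z rows (mm)\n")
        for line in lines.streamlines:
            for pt in line:
                fh.write(f"{pt[0]:.12g} {pt[1]:.12g} {pt[2]:.12g}\n")
            fh.write("\n")


def read_streamlines(path: str | Path) -> StreamlineSet:
    lines: list[np.ndarray] = []
    block: list[list[float]] = []
    with open(path) as fh:
        for raw in fh:
            text = raw.strip()
            if text.startswith("#"):
                continue
            if not text:
                if block:
                    lines.append(np.array(block))
                    block = []
                continue
            parts = text.split()
            if len(parts) != 3:
                raise FormatError(f"streamline row needs 3 columns, got {text!r}")
            block.append([float(v) for v in parts])
    if block:
        lines.append(np.array(block))
    return StreamlineSet(streamlines=tuple(lines))


def write_volume(path: str | Path, vol: BoldVolume) -> None:
    affine = np.diag([vol.voxel_mm] * 3 + [1.0])
    affine[:3, 3] = vol.origin_mm
    img = nib.Nifti1Image(vol.data.astype(np.float64), affine)
    img.header.set_zooms((vol.voxel_mm,) * 3 + (vol.tr,))
    nib.save(img, str(path))


def read_volume(path: str | Path) -> BoldVolume:
    img = nib.load(str(path))
    affine = img.affine
    off_diag = affine[:3, :3] - np.diag(np.diag(affine[:3, :3]))
    if np.abs(off_diag).max() > 1e-6:
        raise FormatError("only diagonal (RAS mm) affines are supported")
    zooms = np.diag(affine[:3, :3])
    if np.ptp(zooms) > 1e-6 or zooms[0] <= 0:
        raise FormatError("only positive isotropic voxel grids are supported")
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 2.0
    return BoldVolume(
        data=np.asarray(img.dataobj, dtype=float),
        voxel_mm=float(zooms[0]),
        origin_mm=affine[:3, 3].copy(),
        tr=tr,
    )


def write_ground_truth(dirpath: str | Path, truth: GroundTruth) -> None:
    """JSON metadata plus TSV matrices under ``dirpath``."""
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "coupling_strength": truth.coupling_strength,
                "node_ids": list(truth.node_ids),
            },
            fh, indent=2,
        )
    write_matrix(
        d / "sc_weights.tsv",
        ConnectivityMatrix(values=truth.sc_weights, nodes=truth.node_ids, modality="sc"),
    )
    np.savetxt(d / "dynamic_coupling.tsv", truth.dynamic_coupling, delimiter="\t", fmt=_FLOAT_FMT)


def read_ground_truth(dirpath: str | Path) -> GroundTruth:
    d = Path(dirpath)
    with open(d / "ground_truth.json") as fh:
        meta = json.load(fh)
    sc = read_matrix(d / "sc_weights.tsv")
    if tuple(meta["node_ids"]) != sc.nodes:
        raise IdMismatchError("ground-truth node ids disagree with SC matrix")
    dyn = np.loadtxt(d / "dynamic_coupling.tsv", delimiter="\t", ndmin=2)
    return GroundTruth(
        sc_weights=sc.values, dynamic_coupling=dyn,
        coupling_strength=float(meta["coupling_strength"]),
        node_ids=sc.nodes,
    )


def write_study_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_study_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
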