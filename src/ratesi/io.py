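"""Format readers/writers: EDF, CSV recordings, events TSV, NIfTI maps,
Gmsh meshes, HDF5 lead fields, and the run manifest.

EDF is the canonical EEG container (16-bit integer records); reading goes
through MNE, writing uses a minimal EDF writer (uniform sampling rate,
one data record per second).  Plain CSV is the frictionless fixture
format.  Source maps rasterize onto the labeled-volume voxel lattice for
NIfTI export.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
import yaml

from .headmodel import LabeledVolume, SourceGrid, TetMesh
from .recording import SensorRecording

__all__ = [
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "source_map_to_nifti",
    "source_map_to_csv",
    "write_msh",
    "read_msh",
    "load_leadfield",
    "RunManifest",
]


# ---------------------------------------------------------------------------
# Recordings
# ---------------------------------------------------------------------------

def read_recording(path, fmt: str | None = None) -> SensorRecording:
    """Load a recording from EDF or CSV (format inferred from suffix).

    CSV layout: header ``time,<ch1>,<ch2>,...`` with the time column in
    seconds; the sampling rate is inferred from the time column and must
    be uniform to 1e-6 relative.
    """
    path = str(path)
    if fmt is None:
        fmt = "edf" if path.lower().endswith(".edf") else "csv"
    if fmt == "edf":
        import mne
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return SensorRecording(data=raw.get_data(), fs=float(raw.info["sfreq"]),
                               labels=list(raw.ch_names))
    if fmt == "csv":
        df = pd.read_csv(path)
        if df.empty or df.shape[1] < 2:
            raise ValueError(f"{path}: empty or malformed recording CSV")
        t = df.iloc[:, 0].to_numpy(dtype=float)
        dt = np.diff(t)
        if len(dt) == 0 or np.any(dt <= 0):
            raise ValueError(f"{path}: non-increasing time column")
        if (dt.max() - dt.min()) > 1e-6 * dt.mean():
            raise ValueError(f"{path}: non-uniform sampling (max deviation "
                             f"{(dt.max() - dt.min()) / dt.mean():.2e})")
        return SensorRecording(data=df.iloc[:, 1:].to_numpy(dtype=float).T,
                               fs=1.0 / dt.mean(),
                               labels=list(df.columns[1:]))
    raise ValueError(f"unknown recording format {fmt!r}")


def write_recording(path, rec: SensorRecording, fmt: str | None = None) -> None:
    path = str(path)
    if fmt is None:
        fmt = "edf" if path.lower().endswith(".edf") else "csv"
    if fmt == "edf":
        _write_edf(path, rec)
    elif fmt == "csv":
        t = np.arange(rec.n_samples) / rec.fs
        df = pd.DataFrame({"time": t})
        for i, lab in enumerate(rec.labels):
            df[lab] = rec.data[i]
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown recording format {fmt!r}")


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(path: str, rec: SensorRecording) -> None:
    """Minimal EDF writer: one 1-second data record per block, int16."""
    n_ch = rec.n_channels
    spr = int(round(rec.fs))            # samples per record (1 s records)
    n_rec = int(np.ceil(rec.n_samples / spr))
    data = np.zeros((n_ch, n_rec * spr))
    data[:, :rec.n_samples] = rec.data
    # Physical limits are stored as 8-char ASCII; digitize against the
    # values the reader will parse back, so the round trip is exact to
    # the 16-bit quantum.
    amp = np.maximum(np.abs(data).max(axis=1), 1e-12)

    def _fit8(v: float) -> str:
        for prec in (4, 3, 2, 1):
            s = f"{v:.{prec}g}"
            if len(s) <= 7:             # leave room for the minus sign
                return s
        return f"{v:.0e}"

    pmax_s = []
    for v in amp:
        s = _fit8(v)
        while float(s) < v:             # never clip: round the limit up
            s = _fit8(float(s) * 1.02)
        pmax_s.append(s)
    pmax = np.array([float(s) for s in pmax_s])
    pmin = -pmax
    digital = np.round(data / pmax[:, None] * 32767).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    hdr = b"".join([
        _edf_field("0", 8),
        _edf_field("synthetic subject", 80),
        _edf_field("synthetic recording", 80),
        _edf_field(now.strftime("%d.%m.%y"), 8),
        _edf_field(now.strftime("%H.%M.%S"), 8),
        _edf_field(256 + 256 * n_ch, 8),
        _edf_field("", 44),
        _edf_field(n_rec, 8),
        _edf_field("1", 8),
        _edf_field(n_ch, 4),
    ])
    hdr += b"".join(_edf_field(l, 16) for l in rec.labels)
    hdr += b"".join(_edf_field("", 80) for _ in range(n_ch))
    hdr += b"".join(_edf_field("V", 8) for _ in range(n_ch))
    hdr += b"".join(_edf_field("-" + s, 8) for s in pmax_s)
    hdr += b"".join(_edf_field(s, 8) for s in pmax_s)
    hdr += b"".join(_edf_field(-32767, 8) for _ in range(n_ch))
    hdr += b"".join(_edf_field(32767, 8) for _ in range(n_ch))
    hdr += b"".join(_edf_field("", 80) for _ in range(n_ch))
    hdr += b"".join(_edf_field(spr, 8) for _ in range(n_ch))
    hdr += b"".join(_edf_field("", 32) for _ in range(n_ch))
    with open(path, "wb") as f:
        f.write(hdr)
        for r in range(n_rec):
            block = digital[:, r * spr:(r + 1) * spr]
            f.write(block.tobytes())


def read_events(path) -> np.ndarray:
    """Two-column events TSV (sample, code) -> (n, 2) int array."""
    df = pd.read_csv(path, sep="\t")
    return df.iloc[:, :2].to_numpy(dtype=np.int64)


def write_events(path, events: np.ndarray) -> None:
    pd.DataFrame(np.asarray(events, dtype=np.int64),
                 columns=["sample", "code"]).to_csv(path, sep="\t", index=False)


def read_labeled_volume(path, threshold: float | None = None) -> LabeledVolume:
    """Load a labeled (or intensity) volume from NIfTI.

    ``threshold`` binarizes an intensity image into a single-label mask
    (the atlas-ingestion path); integer images are taken as region labels
    directly.  Requires an axis-aligned affine with isotropic voxels.
    """
    import nibabel as nib
    img = nib.load(str(path))
    aff = np.asarray(img.affine, dtype=float)
    scales = np.linalg.norm(aff[:3, :3], axis=0)
    if not np.allclose(scales, scales[0], rtol=1e-3):
        raise ValueError("anisotropic voxels are not supported")
    arr = np.asarray(img.dataobj)
    if threshold is not None:
        arr = (arr > threshold).astype(np.int16)
    else:
        arr = np.rint(arr).astype(np.int16)
    return LabeledVolume(labels=arr, voxel=float(scales[0]), affine=aff)


# ---------------------------------------------------------------------------
# Source maps
# ---------------------------------------------------------------------------

def source_map_to_nifti(values: np.ndarray, grid: SourceGrid,
                        vol: LabeledVolume, path) -> None:
    """Rasterize per-dipole values to the labeled volume's voxel lattice
    (nearest-voxel assignment) and write NIfTI."""
    import nibabel as nib
    arr = np.zeros(vol.labels.shape, dtype=np.float32)
    vc = vol.world_to_voxel(grid.positions)
    idx = np.floor(vc + 0.5).astype(int)
    ok = np.all((idx >= 0) & (idx < np.array(vol.labels.shape)), axis=1)
    arr[idx[ok, 0], idx[ok, 1], idx[ok, 2]] = np.asarray(values)[ok]
    nib.save(nib.Nifti1Image(arr, vol.affine), str(path))


def source_map_to_csv(values: np.ndarray, grid: SourceGrid, path) -> None:
    pd.DataFrame({"x_mm": grid.positions[:, 0], "y_mm": grid.positions[:, 1],
                  "z_mm": grid.positions[:, 2],
                  "value": np.asarray(values)}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Meshes (Gmsh MSH v2.2 ASCII)
# ---------------------------------------------------------------------------

def write_msh(path, mesh: TetMesh) -> None:
    with open(path, "w") as f:
        f.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        f.write(f"$Nodes\n{mesh.n_nodes}\n")
        for i, (x, y, z) in enumerate(mesh.nodes, start=1):
            f.write(f"{i} {x:.9g} {y:.9g} {z:.9g}\n")
        f.write(f"$EndNodes\n$Elements\n{mesh.n_elems}\n")
        for i, el in enumerate(mesh.elems, start=1):
            a, b, c, d = el + 1
            f.write(f"{i} 4 2 0 1 {a} {b} {c} {d}\n")
        f.write("$EndElements\n")


def read_msh(path, sigma: float = 0.33) -> TetMesh:
    nodes, elems = [], []
    with open(path) as f:
        lines = iter(f.read().splitlines())
    for line in lines:
        if line.strip() == "$Nodes":
            n = int(next(lines))
            for _ in range(n):
                parts = next(lines).split()
                nodes.append([float(v) for v in parts[1:4]])
        elif line.strip() == "$Elements":
            n = int(next(lines))
            for _ in range(n):
                parts = next(lines).split()
                if parts[1] == "4":     # 4-node tetrahedron
                    n_tags = int(parts[2])
                    elems.append([int(v) - 1 for v in parts[3 + n_tags:]])
    if not nodes or not elems:
        raise ValueError(f"{path}: no tetrahedra found")
    return TetMesh(nodes=np.asarray(nodes), elems=np.asarray(elems),
                   sigma=sigma)


# ---------------------------------------------------------------------------
# Lead fields / manifest
# ---------------------------------------------------------------------------

def load_leadfield(path) -> dict:
    """Load the HDF5 lead-field export as plain arrays
    (K flat N x 3P, positions, channel labels, attributes)."""
    with h5py.File(path, "r") as f:
        return {"K": f["K"][()], "positions": f["positions"][()],
                "labels": [l.decode() if isinstance(l, bytes) else str(l)
                           for l in f["labels"][()]],
                "units": f.attrs.get("units", ""),
                "referencing": f.attrs.get("referencing", "")}


@dataclass
class RunManifest:
    """Reproducibility record written next to every CLI artifact."""

    stage: str
    seed: int
    config: dict = field(default_factory=dict)
    version: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__
            self.version = __version__
        if not self.timestamp:
            self.timestamp = _dt.datetime.now().isoformat(timespec="seconds")

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump({"stage": self.stage, "seed": self.seed,
                            "config": self.config, "version": self.version,
                            "timestamp": self.timestamp}, f,
                           default_flow_style=False)

    @staticmethod
    def from_yaml(path) -> "RunManifest":
        with open(path) as f:
            d = yaml.safe_load(f)
        return RunManifest(**d)
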