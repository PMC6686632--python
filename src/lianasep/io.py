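"""Read and write point clouds in the formats the pipeline touches.

Supported formats
-----------------
``xyz``
    Whitespace-separated ASCII, one point per line: ``x y z [c]``. Lines
    starting with ``#`` are comments. A fourth numeric column is read as
    class labels when every value is 1 or 2, otherwise as class-1
    probabilities (which must then lie in [0, 1]).
``ply``
    Vertex-only PLY. Written as ascii 1.0 with double x/y/z and optional
    ``label`` (uchar) and ``prob`` (double) properties; ascii and
    binary_little_endian files are read.
``las``
    LAS 1.2, point record format 0. The classification byte carries the
    {1, 2} label; probabilities are not representable and are dropped on
    write. Coordinates are stored scaled (1e-6 m resolution for plot-sized
    clouds).

All coordinates are meters; no unit conversion is ever implicit.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .cloud import LIANA, OTHER, PointCloud

__all__ = ["read_cloud", "write_cloud", "ParseError", "detect_format"]

_FORMATS = ("xyz", "ply", "las")


class ParseError(ValueError):
    """Raised when a point-cloud file cannot be parsed."""


def detect_format(path) -> str:
    """Infer the format from a file suffix (``.xyz``/``.txt``, ``.ply``, ``.las``)."""
    suffix = Path(path).suffix.lower()
    if suffix in (".xyz", ".txt", ".asc"):
        return "xyz"
    if suffix in (".ply", ".las"):
        return suffix[1:]
    raise ParseError(f"cannot infer point-cloud format from suffix {suffix!r}")


def read_cloud(path, format: str | None = None) -> PointCloud:
    """Read a point cloud from ``path`` in the named (or inferred) format."""
    fmt = format or detect_format(path)
    if fmt not in _FORMATS:
        raise ParseError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    reader = {"xyz": _read_xyz, "ply": _read_ply, "las": _read_las}[fmt]
    cloud = reader(Path(path))
    cloud.source_id = cloud.source_id or Path(path).stem
    return cloud


def write_cloud(cloud: PointCloud, path, format: str | None = None) -> None:
    """Write ``cloud`` to ``path``; re-readable by :func:`read_cloud`."""
    fmt = format or detect_format(path)
    if fmt not in _FORMATS:
        raise ParseError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    writer = {"xyz": _write_xyz, "ply": _write_ply, "las": _write_las}[fmt]
    writer(cloud, Path(path))


# ---------------------------------------------------------------------------
# ASCII xyz


def _classify_extra_column(col: np.ndarray):
    """Interpret a 4th xyz column as labels if all values are 1/2, else probs."""
    if col.size == 0:
        return None, None
    integral = np.all(col == np.round(col))
    if integral and np.isin(col, (LIANA, OTHER)).all():
        return col.astype(np.int64), None
    if col.min() >= 0.0 and col.max() <= 1.0:
        return None, col
    raise ParseError(
        "4th column is neither a {1,2} label column nor probabilities in [0,1]"
    )


def _read_xyz(path: Path) -> PointCloud:
    try:
        frame = pd.read_csv(path, sep=r"\s+", comment="#", header=None, dtype=np.float64)
    except Exception:
        return _read_xyz_slow(path)  # re-parse to report the offending line
    if frame.isna().to_numpy().any():
        return _read_xyz_slow(path)
    data = frame.to_numpy()
    if data.shape[1] < 3 or data.shape[1] > 4:
        raise ParseError(f"{path}: expected 3 or 4 columns, found {data.shape[1]}")
    labels = probs = None
    if data.shape[1] == 4:
        labels, probs = _classify_extra_column(data[:, 3])
    return PointCloud(data[:, :3], labels=labels, probs=probs)


def _read_xyz_slow(path: Path) -> PointCloud:
    rows: list[list[float]] = []
    width = None
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.split()
            if len(parts) not in (3, 4):
                raise ParseError(f"{path}:{lineno}: expected 3 or 4 columns, found {len(parts)}")
            try:
                values = [float(p) for p in parts]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if width is None:
                width = len(values)
            elif len(values) != width:
                raise ParseError(f"{path}:{lineno}: inconsistent column count")
            rows.append(values)
    data = np.asarray(rows, dtype=np.float64).reshape(len(rows), width or 3)
    labels = probs = None
    if data.shape[1] == 4:
        labels, probs = _classify_extra_column(data[:, 3])
    return PointCloud(data[:, :3], labels=labels, probs=probs)


def _write_xyz(cloud: PointCloud, path: Path) -> None:
    cols = [cloud.coords]
    fmt = ["%.7f", "%.7f", "%.7f"]
    if cloud.labels is not None:
        cols.append(cloud.labels[:, None].astype(np.float64))
        fmt.append("%d")
    elif cloud.probs is not None:
        cols.append(cloud.probs[:, None])
        fmt.append("%.7f")
    data = np.hstack(cols) if len(cloud) else np.empty((0, len(fmt)))
    np.savetxt(path, data, fmt=" ".join(fmt))


# ---------------------------------------------------------------------------
# PLY (vertex element only)

_PLY_TYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


def _read_ply(path: Path) -> PointCloud:
    with open(path, "rb") as handle:
        magic = handle.readline().strip()
        if magic != b"ply":
            raise ParseError(f"{path}: not a PLY file")
        fmt = None
        n_vertex = None
        props: list[tuple[str, str]] = []
        in_vertex = False
        lineno = 1
        while True:
            raw = handle.readline()
            lineno += 1
            if not raw:
                raise ParseError(f"{path}:{lineno}: unexpected end of header")
            line = raw.decode("ascii", errors="replace").strip()
            if line == "end_header":
                break
            parts = line.split()
            if not parts or parts[0] == "comment":
                continue
            if parts[0] == "format":
                fmt = parts[1]
            elif parts[0] == "element":
                in_vertex = parts[1] == "vertex"
                if in_vertex:
                    n_vertex = int(parts[2])
            elif parts[0] == "property" and in_vertex:
                if parts[1] == "list":
                    raise ParseError(f"{path}:{lineno}: list properties unsupported")
                if parts[1] not in _PLY_TYPES:
                    raise ParseError(f"{path}:{lineno}: unknown property type {parts[1]!r}")
                props.append((parts[2], _PLY_TYPES[parts[1]]))
        if fmt not in ("ascii", "binary_little_endian"):
            raise ParseError(f"{path}: unsupported PLY format {fmt!r}")
        if n_vertex is None:
            raise ParseError(f"{path}: no vertex element")
        names = [name for name, _ in props]
        for axis in "xyz":
            if axis not in names:
                raise ParseError(f"{path}: vertex element lacks property {axis!r}")
        dtype = np.dtype([(name, "<" + code) for name, code in props])
        if fmt == "ascii":
            try:
                table = pd.read_csv(
                    handle, sep=r"\s+", header=None, names=names, nrows=n_vertex,
                    dtype=np.float64,
                ) if n_vertex else pd.DataFrame(columns=names)
            except Exception as exc:
                raise ParseError(f"{path}: malformed ascii vertex data: {exc}") from None
            if len(table) != n_vertex or table.isna().to_numpy().any():
                raise ParseError(f"{path}: expected {n_vertex} vertices")
            columns = {name: table[name].to_numpy() for name in names}
        else:
            buf = handle.read(dtype.itemsize * n_vertex)
            if len(buf) != dtype.itemsize * n_vertex:
                raise ParseError(f"{path}: truncated binary vertex data")
            rec = np.frombuffer(buf, dtype=dtype)
            columns = {name: rec[name].astype(np.float64) for name in names}
    coords = np.column_stack([columns["x"], columns["y"], columns["z"]])
    labels = probs = None
    for key in ("label", "class", "classification"):
        if key in columns:
            labels = columns[key].astype(np.int64)
            if labels.size and not np.isin(labels, (LIANA, OTHER)).all():
                raise ParseError(f"{path}: property {key!r} holds values outside {{1,2}}")
            break
    for key in ("prob", "probability", "scalar_prob"):
        if key in columns:
            probs = columns[key]
            break
    return PointCloud(coords, labels=labels, probs=probs)


def _write_ply(cloud: PointCloud, path: Path) -> None:
    header = ["ply", "format ascii 1.0", f"element vertex {len(cloud)}"]
    header += [f"property double {axis}" for axis in "xyz"]
    cols = [cloud.coords[:, 0], cloud.coords[:, 1], cloud.coords[:, 2]]
    fmt = ["%.7f"] * 3
    if cloud.labels is not None:
        header.append("property uchar label")
        cols.append(cloud.labels)
        fmt.append("%d")
    if cloud.probs is not None:
        header.append("property double prob")
        cols.append(cloud.probs)
        fmt.append("%.7f")
    header.append("end_header")
    with open(path, "w") as handle:
        handle.write("\n".join(header) + "\n")
        if len(cloud):
            np.savetxt(handle, np.column_stack(cols), fmt=" ".join(fmt))


# ---------------------------------------------------------------------------
# LAS 1.2, point data record format 0

_LAS_HEADER_SIZE = 227
_LAS_RECORD_SIZE = 20


def _read_las(path: Path) -> PointCloud:
    data = Path(path).read_bytes()
    if len(data) < _LAS_HEADER_SIZE or data[:4] != b"LASF":
        raise ParseError(f"{path}: not a LAS file")
    (offset_to_points,) = struct.unpack_from("<I", data, 96)
    point_format, record_len = struct.unpack_from("<BH", data, 104)
    (n_points,) = struct.unpack_from("<I", data, 107)
    scales = struct.unpack_from("<3d", data, 131)
    offsets = struct.unpack_from("<3d", data, 155)
    if point_format not in (0, 1, 2, 3):
        raise ParseError(f"{path}: unsupported LAS point format {point_format}")
    need = offset_to_points + n_points * record_len
    if len(data) < need:
        raise ParseError(f"{path}: truncated point data ({len(data)} < {need} bytes)")
    base = np.dtype(
        [("X", "<i4"), ("Y", "<i4"), ("Z", "<i4"), ("intensity", "<u2"),
         ("flags", "u1"), ("cls", "u1")]
    )
    dtype = np.dtype({
        "names": base.names, "formats": [base[name] for name in base.names],
        "offsets": [base.fields[name][1] for name in base.names],
        "itemsize": record_len,
    })
    rec = np.frombuffer(data, dtype=dtype, count=n_points, offset=offset_to_points)
    coords = np.column_stack(
        [rec[axis].astype(np.float64) * scale + off
         for axis, scale, off in zip("XYZ", scales, offsets)]
    ) if n_points else np.empty((0, 3))
    labels = None
    cls = rec["cls"].astype(np.int64) if n_points else np.empty(0, dtype=np.int64)
    if cls.size and cls.any():
        if not np.isin(cls, (LIANA, OTHER)).all():
            raise ParseError(f"{path}: classification values outside {{1,2}}")
        labels = cls
    return PointCloud(coords, labels=labels)


def _write_las(cloud: PointCloud, path: Path) -> None:
    n = len(cloud)
    if n:
        lo, hi = cloud.bounds()
    else:
        lo = hi = np.zeros(3)
    extent = float(np.max(hi - lo)) if n else 0.0
    # 1e-6 m resolution unless the cloud is too large for int32 at that scale
    scale = max(1e-6, extent / (2**31 - 2))
    header = bytearray(_LAS_HEADER_SIZE)
    struct.pack_into("<4s", header, 0, b"LASF")
    struct.pack_into("<BB", header, 24, 1, 2)  # version 1.2
    struct.pack_into("<32s", header, 26, b"lianasep")
    struct.pack_into("<32s", header, 58, b"lianasep")
    struct.pack_into("<H", header, 94, _LAS_HEADER_SIZE)
    struct.pack_into("<I", header, 96, _LAS_HEADER_SIZE)
    struct.pack_into("<I", header, 100, 0)
    struct.pack_into("<BH", header, 104, 0, _LAS_RECORD_SIZE)
    struct.pack_into("<I", header, 107, n)
    struct.pack_into("<3d", header, 131, scale, scale, scale)
    struct.pack_into("<3d", header, 155, *lo)
    struct.pack_into(
        "<6d", header, 179, hi[0], lo[0], hi[1], lo[1], hi[2], lo[2]
    )
    rec = np.zeros(
        n,
        dtype=[("X", "<i4"), ("Y", "<i4"), ("Z", "<i4"), ("intensity", "<u2"),
               ("flags", "u1"), ("cls", "u1"), ("angle", "i1"), ("user", "u1"),
               ("source", "<u2")],
    )
    if n:
        scaled = np.round((cloud.coords - lo) / scale)
        rec["X"], rec["Y"], rec["Z"] = scaled[:, 0], scaled[:, 1], scaled[:, 2]
        if cloud.labels is not None:
            rec["cls"] = cloud.labels
    with open(path, "wb") as handle:
        handle.write(bytes(header))
        handle.write(rec.tobytes())
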