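"""Readers/writers and pipeline configuration.

Point sets travel as vertex-only PLY (ascii or binary little-endian) or
3-column CSV; cohorts as one PLY per bone per subject plus a metadata CSV
and a JSON sidecar (landmark maps + generator config); shape models and
alignment transforms as HDF5; pipeline configuration as YAML. The PLY
reader/writer preserves point order bit-exactly and reports parse errors
with line numbers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .core import ANGLE_NAMES, BONE_IDS, SIDES, AngleSet, Cohort, CorrespondedShape, Subject
from .synthetic import GeneratorConfig

__all__ = [
    "ShapeFileError",
    "PipelineConfig",
    "read_shape_file",
    "write_shape_file",
    "save_cohort",
    "load_cohort",
    "save_model",
    "load_model",
    "save_transforms",
]


class ShapeFileError(ValueError):
    """Malformed shape file; carries the offending line number when known."""

    def __init__(self, path, message, line=None):
        loc = f"{path}:{line}" if line is not None else str(path)
        super().__init__(f"{loc}: {message}")
        self.line = line


# ---------------------------------------------------------------------------
# PLY / CSV point sets

_PLY_TYPES = {"float": ("<f4", 4), "float32": ("<f4", 4), "double": ("<f8", 8), "float64": ("<f8", 8)}


def _read_ply(path: Path) -> np.ndarray:
    raw = path.read_bytes()
    end = raw.find(b"end_header")
    if end < 0:
        raise ShapeFileError(path, "missing end_header")
    header_end = raw.find(b"\n", end) + 1
    lines = raw[:header_end].decode("ascii", errors="replace").splitlines()
    if not lines or lines[0].strip() != "ply":
        raise ShapeFileError(path, "not a PLY file (missing 'ply' magic)", line=1)
    fmt, n_vertex, props = None, None, []
    for lineno, line in enumerate(lines[1:], start=2):
        tok = line.split()
        if not tok or tok[0] == "comment":
            continue
        if tok[0] == "format":
            if tok[1] not in ("ascii", "binary_little_endian"):
                raise ShapeFileError(path, f"unsupported format {tok[1]!r}", line=lineno)
            fmt = tok[1]
        elif tok[0] == "element":
            if tok[1] != "vertex":
                raise ShapeFileError(path, f"unsupported element {tok[1]!r} (vertex-only PLY expected)", line=lineno)
            n_vertex = int(tok[2])
        elif tok[0] == "property":
            if len(tok) != 3 or tok[1] not in _PLY_TYPES:
                raise ShapeFileError(path, f"unsupported property {line.strip()!r}", line=lineno)
            props.append((tok[2], tok[1]))
        elif tok[0] == "end_header":
            break
        else:
            raise ShapeFileError(path, f"unexpected header line {line.strip()!r}", line=lineno)
    if fmt is None or n_vertex is None:
        raise ShapeFileError(path, "incomplete header (format/element missing)")
    if [p[0] for p in props] != ["x", "y", "z"]:
        raise ShapeFileError(path, f"expected properties x, y, z; got {[p[0] for p in props]}")
    n_header_lines = len(lines)
    if fmt == "ascii":
        body = raw[header_end:].decode("ascii", errors="replace").splitlines()
        rows = []
        for k, line in enumerate(body):
            if len(rows) == n_vertex:
                break
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 3:
                raise ShapeFileError(path, f"expected 3 columns, got {len(tok)}", line=n_header_lines + 1 + k)
            try:
                rows.append([float(v) for v in tok])
            except ValueError:
                raise ShapeFileError(path, f"non-numeric value in {line.strip()!r}", line=n_header_lines + 1 + k)
        if len(rows) != n_vertex:
            raise ShapeFileError(path, f"expected {n_vertex} vertices, found {len(rows)}")
        return np.asarray(rows, dtype=float)
    dtype = np.dtype([(name, _PLY_TYPES[t][0]) for name, t in props])
    body = raw[header_end : header_end + dtype.itemsize * n_vertex]
    if len(body) < dtype.itemsize * n_vertex:
        raise ShapeFileError(path, f"binary payload truncated: {len(body)} bytes for {n_vertex} vertices")
    rec = np.frombuffer(body, dtype=dtype, count=n_vertex)
    return np.column_stack([rec["x"], rec["y"], rec["z"]]).astype(float)


def _read_csv_points(path: Path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = [t for t in line.strip().split(",") if t != ""]
            if not tok:
                continue
            if lineno == 1 and any(not _is_number(t) for t in tok):
                continue  # header row
            if len(tok) != 3:
                raise ShapeFileError(path, f"expected 3 columns, got {len(tok)}", line=lineno)
            try:
                rows.append([float(t) for t in tok])
            except ValueError:
                raise ShapeFileError(path, f"non-numeric value in {line.strip()!r}", line=lineno)
    if not rows:
        raise ShapeFileError(path, "no coordinate rows found")
    return np.asarray(rows, dtype=float)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _infer_bone_id(path: Path):
    for bone in BONE_IDS:
        if path.stem.endswith(bone):
            return bone
    return None


def read_shape_file(path, bone_id=None, landmark_index_map=None) -> CorrespondedShape:
    """Read a PLY or CSV point set, preserving point order.

    ``bone_id`` is inferred from the filename when it ends in a bone name.
    """
    path = Path(path)
    pts = _read_csv_points(path) if path.suffix.lower() == ".csv" else _read_ply(path)
    bone_id = bone_id or _infer_bone_id(path)
    if bone_id is None:
        raise ValueError(f"{path}: bone_id not given and not inferrable from filename")
    return CorrespondedShape(bone_id, pts, dict(landmark_index_map or {}))


def write_shape_file(shape, path, binary: bool = False) -> None:
    """Write a point set (CorrespondedShape or (N,3) array) as PLY or CSV."""
    path = Path(path)
    pts = np.asarray(shape.points if isinstance(shape, CorrespondedShape) else shape, dtype=float)
    if path.suffix.lower() == ".csv":
        with open(path, "w") as fh:
            fh.write("x,y,z\n")
            for p in pts:
                fh.write(f"{p[0]:.17g},{p[1]:.17g},{p[2]:.17g}\n")
        return
    header = (
        "ply\n"
        f"format {'binary_little_endian' if binary else 'ascii'} 1.0\n"
        f"element vertex {len(pts)}\n"
        "property double x\nproperty double y\nproperty double z\n"
        "end_header\n"
    )
    if binary:
        with open(path, "wb") as fh:
            fh.write(header.encode("ascii"))
            fh.write(pts.astype("<f8").tobytes())
    else:
        with open(path, "w") as fh:
            fh.write(header)
            for p in pts:
                fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")


# ---------------------------------------------------------------------------
# cohorts


def _landmarks_to_json(lm: dict) -> dict:
    return {k: (int(v) if np.ndim(v) == 0 else np.asarray(v).astype(int).tolist()) for k, v in lm.items()}


def _landmarks_from_json(lm: dict) -> dict:
    return {k: (int(v) if np.ndim(v) == 0 else np.asarray(v, dtype=int)) for k, v in lm.items()}


def save_cohort(cohort: Cohort, out_dir) -> None:
    """Write one PLY per bone per subject, metadata CSV, and a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for subj in cohort.subjects:
        for bone in BONE_IDS:
            write_shape_file(subj.shapes[bone], out / f"{subj.subject_id}_{bone}.ply")
        for side in SIDES:
            ang = subj.true_angles[side]
            rows.append(
                {
                    "subject_id": subj.subject_id,
                    "sex": subj.sex,
                    "side": side,
                    "dysplasia": subj.dysplasia[side],
                    **{k: getattr(ang, k) for k in ANGLE_NAMES},
                    "seed": getattr(subj.params, "seed", -1),
                }
            )
    pd.DataFrame(rows).to_csv(out / "metadata.csv", index=False, float_format="%.17g")
    ref = cohort.subjects[0]
    sidecar = {
        "subject_ids": [s.subject_id for s in cohort.subjects],
        "landmark_index_map": {
            bone: _landmarks_to_json(ref.shapes[bone].landmark_index_map) for bone in BONE_IDS
        },
        "generator_config": cohort.config.to_dict() if cohort.config is not None else None,
    }
    (out / "cohort.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def load_cohort(in_dir) -> Cohort:
    in_dir = Path(in_dir)
    sidecar = json.loads((in_dir / "cohort.json").read_text())
    meta = pd.read_csv(in_dir / "metadata.csv", float_precision="round_trip")
    lm = {bone: _landmarks_from_json(m) for bone, m in sidecar["landmark_index_map"].items()}
    subjects = []
    for sid in sidecar["subject_ids"]:
        shapes = {
            bone: read_shape_file(in_dir / f"{sid}_{bone}.ply", bone_id=bone, landmark_index_map=lm[bone])
            for bone in BONE_IDS
        }
        rows = meta[meta["subject_id"] == sid].set_index("side")
        true_angles = {
            side: AngleSet(**{k: float(rows.loc[side, k]) for k in ("ce", "ai", "acav", "aasa", "pasa")})
            for side in SIDES
        }
        dysplasia = {side: bool(rows.loc[side, "dysplasia"]) for side in SIDES}
        subjects.append(
            Subject(
                subject_id=sid,
                sex=str(rows["sex"].iloc[0]),
                shapes=shapes,
                true_angles=true_angles,
                dysplasia=dysplasia,
            )
        )
    cfg = sidecar.get("generator_config")
    return Cohort(subjects=subjects, config=GeneratorConfig.from_dict(cfg) if cfg else None)


# ---------------------------------------------------------------------------
# model / transform archives (HDF5)


def save_model(pdm, path, landmark_index_map=None, extras=None) -> None:
    """Write a PDM archive: mean shape, modes, eigenvalues, bone composition."""
    from .ssm import PDM  # local import to keep module load light

    assert isinstance(pdm, PDM)
    with h5py.File(path, "w") as f:
        f.create_dataset("mean_shape", data=pdm.mean_shape)
        f.create_dataset("modes", data=pdm.modes)
        f.create_dataset("eigenvalues", data=pdm.eigenvalues)
        f.attrs["n_training"] = pdm.n_training
        comp = f.create_group("composition")
        comp.create_dataset("bone_ids", data=np.array([b for b, _ in pdm.composition], dtype="S16"))
        comp.create_dataset("n_points", data=np.array([n for _, n in pdm.composition], dtype=int))
        if landmark_index_map is not None:
            f.attrs["landmark_index_map"] = json.dumps(
                {bone: _landmarks_to_json(m) for bone, m in landmark_index_map.items()}
            )
        for key, arr in (extras or {}).items():
            f.create_dataset(key, data=arr)


def load_model(path):
    from .ssm import PDM

    with h5py.File(path, "r") as f:
        comp = list(
            zip(
                [b.decode() for b in f["composition/bone_ids"][()]],
                [int(n) for n in f["composition/n_points"][()]],
            )
        )
        pdm = PDM(
            mean_shape=f["mean_shape"][()],
            modes=f["modes"][()],
            eigenvalues=f["eigenvalues"][()],
            n_training=int(f.attrs["n_training"]),
            composition=comp,
        )
        lm = f.attrs.get("landmark_index_map")
        landmark_index_map = (
            {bone: _landmarks_from_json(m) for bone, m in json.loads(lm).items()} if lm else None
        )
        extras = {
            k: f[k][()]
            for k in f.keys()
            if k not in ("mean_shape", "modes", "eigenvalues", "composition")
        }
    return pdm, landmark_index_map, extras


def save_transforms(aligned, path) -> None:
    """Write alignment transforms, head centres and iteration logs to HDF5."""
    with h5py.File(path, "w") as f:
        g = f.create_group("pelvis")
        g.create_dataset("rotation", data=np.stack([t.rotation for t in aligned.pelvis_transforms]))
        g.create_dataset("translation", data=np.stack([t.translation for t in aligned.pelvis_transforms]))
        g.create_dataset("scale", data=np.array([t.scale for t in aligned.pelvis_transforms]))
        g.create_dataset("iteration_log", data=np.asarray(aligned.gpa_iterations))
        for side in SIDES:
            g = f.create_group(f"femur_{side}")
            ts = aligned.femur_transforms[side]
            g.create_dataset("rotation", data=np.stack([t.rotation for t in ts]))
            g.create_dataset("translation", data=np.stack([t.translation for t in ts]))
            g.create_dataset("scale", data=np.array([t.scale for t in ts]))
            g.create_dataset("head_centers_before", data=aligned.head_centers_before[side])
            g.create_dataset("head_centers_after", data=aligned.head_centers_after[side])
            g.create_dataset("iteration_log", data=np.asarray(aligned.pose_iterations[side]))


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, serializable to YAML."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    allow_scale: bool = True
    gpa_tol: float = 1e-7
    pose_tol: float = 1e-5
    max_iter: int = 100
    variance_fraction: float = 0.95
    ridge: float = 1e-4
    n_modes: int | None = None
    refit_basis_per_fold: bool = False
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = self.generator.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        gen = d.pop("generator", None)
        if isinstance(gen, dict):
            gen = GeneratorConfig.from_dict(gen)
        return cls(generator=gen or GeneratorConfig(), **d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
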