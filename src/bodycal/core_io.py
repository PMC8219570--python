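"""Mesh and composition-table I/O for corresponded body-scan cohorts.

A cohort is a set of body meshes sharing one topology: every mesh has the
same vertex count and ordering, so vertex *i* marks the same anatomical
location on every identity.  Statistical shape modelling operates on the
flattened representation: each mesh becomes a row vector of (x, y, z)
triples, in centimetres, concatenated in ascending vertex index.

Vertices carry a region label (``torso``, ``arm``, ``leg`` or ``excluded``);
the head, neck, hands and feet are tagged ``excluded`` and dropped before
flattening.  Region labels live in a sidecar CSV (``vertex_index,label``)
because OBJ and PLY have no standard per-vertex tag channel.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import trimesh

logger = logging.getLogger("bodycal")

REGIONS = ("torso", "arm", "leg", "excluded")
#: regions retained for shape modelling (everything but head/hands/feet)
RETAINED_REGIONS = ("torso", "arm", "leg")

#: Vertex-budget presets.  ``full`` mirrors a high-resolution scan pipeline:
#: 79,522 raw vertices of which 26,665 (torso + limbs) survive exclusion and
#: 12,697 belong to the torso, giving 79,995-element shape vectors.
#: ``small`` is the default for simulation and testing.
VERTEX_PRESETS: dict[str, dict[str, int]] = {
    "small": {"torso": 300, "arm": 60, "leg": 70, "excluded": 40},
    "full": {"torso": 12_697, "arm": 3_492, "leg": 3_492, "excluded": 52_857},
}


def preset_counts(name: str) -> dict[str, int]:
    """Total / retained / torso vertex counts implied by a preset."""
    p = VERTEX_PRESETS[name]
    retained = p["torso"] + 2 * p["arm"] + 2 * p["leg"]
    return {
        "total": retained + p["excluded"],
        "retained": retained,
        "torso": p["torso"],
    }


class CorrespondenceError(ValueError):
    """Meshes that should share a topology do not."""


class SchemaError(ValueError):
    """A table is missing mandatory columns."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class BodyMesh:
    """One identity's corresponded 3D body surface, coordinates in cm."""

    identity_id: str
    vertices: np.ndarray  # (n, 3) float64
    faces: np.ndarray | None = None  # (m, 3) int, optional
    region_labels: np.ndarray | None = None  # (n,) str

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError(f"{self.identity_id}: non-finite vertex coordinates")
        if self.faces is not None:
            self.faces = np.asarray(self.faces, dtype=int)
        if self.region_labels is None:
            self.region_labels = np.full(len(self.vertices), "torso", dtype="<U8")
        else:
            self.region_labels = np.asarray(self.region_labels, dtype="<U8")
            if len(self.region_labels) != len(self.vertices):
                raise ValueError(
                    f"{self.identity_id}: {len(self.region_labels)} labels for "
                    f"{len(self.vertices)} vertices"
                )
        unknown = set(np.unique(self.region_labels)) - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown region labels: {sorted(unknown)}")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def region_mask(self, regions: Iterable[str]) -> np.ndarray:
        regions = tuple(regions)
        if not regions:
            raise ValueError("regions must be nonempty")
        return np.isin(self.region_labels, regions)

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def centroid_size(self) -> float:
        """Root sum of squared distances from the centroid (scale measure)."""
        return float(np.linalg.norm(self.vertices - self.centroid()))

    def same_topology_as(self, other: "BodyMesh") -> bool:
        if self.n_vertices != other.n_vertices:
            return False
        a, b = self.faces, other.faces
        if (a is None) != (b is None):
            return False
        if a is not None and (a.shape != b.shape or not np.array_equal(a, b)):
            return False
        return True

    def copy(self, identity_id: str | None = None) -> "BodyMesh":
        return BodyMesh(
            identity_id=identity_id or self.identity_id,
            vertices=self.vertices.copy(),
            faces=None if self.faces is None else self.faces.copy(),
            region_labels=self.region_labels.copy(),
        )


@dataclass
class CompositionRecord:
    """Body-composition and anthropometric measures for one identity.

    ``fatm`` and ``smm`` are total fat mass and skeletal muscle mass in kg
    from bioelectrical impedance analysis; ``psych`` is an optional
    dimensionless psychometric score.
    """

    identity_id: str
    sex: str  # "male" | "female"
    fatm: float
    smm: float
    height: float | None = None  # cm
    weight: float | None = None  # kg
    bmi: float | None = None  # kg/m^2
    age: float | None = None  # years
    psych: float | None = None

    def validate(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"{self.identity_id}: sex must be male/female")
        if not (self.fatm >= 0):
            raise ValueError(f"{self.identity_id}: fatm must be >= 0")
        if not (self.smm > 0):
            raise ValueError(f"{self.identity_id}: smm must be > 0")
        if self.height is not None and not (self.height > 0):
            raise ValueError(f"{self.identity_id}: height must be > 0")
        if self.weight is not None:
            if not (self.weight > 0):
                raise ValueError(f"{self.identity_id}: weight must be > 0")
            if self.fatm + self.smm >= self.weight:
                raise ValueError(
                    f"{self.identity_id}: fatm + smm must be below total weight"
                )
        if self.height is not None and self.weight is not None:
            implied = self.weight / (self.height / 100.0) ** 2
            if self.bmi is None:
                self.bmi = implied
            elif abs(self.bmi - implied) > 1e-3 * max(abs(implied), 1.0):
                raise ValueError(
                    f"{self.identity_id}: bmi {self.bmi:.3f} inconsistent with "
                    f"weight/height ({implied:.3f})"
                )

    def predictor(self, name: str) -> float:
        value = getattr(self, name)
        if value is None:
            raise ValueError(f"{self.identity_id}: predictor {name!r} missing")
        return float(value)


@dataclass
class VertexTopology:
    """Mapping between shape vectors and full-resolution meshes.

    ``index_map`` lists the retained (flattened) vertex indices in the full
    mesh; ``template`` supplies faces, labels and coordinates for vertices
    outside the retained set when a vector is lifted back to a mesh.
    """

    index_map: np.ndarray  # retained vertex indices, ascending
    template: BodyMesh

    @property
    def n_retained(self) -> int:
        return len(self.index_map)

    @property
    def vector_length(self) -> int:
        return 3 * self.n_retained


@dataclass
class ShapeMatrix:
    """Flattened cohort: one shape vector per identity (row)."""

    data: np.ndarray  # (c, 3k) float64
    identity_ids: list[str]
    topology: VertexTopology

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[1] % 3:
            raise ValueError("row length must be divisible by 3")
        if self.data.shape[1] != self.topology.vector_length:
            raise ValueError("row length inconsistent with topology")
        if self.data.shape[0] != len(self.identity_ids):
            raise ValueError("one identity id per row required")

    @property
    def n_identities(self) -> int:
        return self.data.shape[0]


# ---------------------------------------------------------------------------
# mesh files
# ---------------------------------------------------------------------------


def _labels_sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".labels.csv")


def read_labels(path: Path | str) -> np.ndarray:
    """Read a ``vertex_index,label`` sidecar CSV into a label array."""
    df = pd.read_csv(path)
    if not {"vertex_index", "label"} <= set(df.columns):
        raise SchemaError(f"{path}: expected columns vertex_index,label")
    idx = df["vertex_index"].to_numpy()
    labels = np.full(int(idx.max()) + 1, "torso", dtype="<U8")
    labels[idx] = df["label"].to_numpy(dtype="<U8")
    return labels


def write_labels(labels: Sequence[str], path: Path | str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["vertex_index", "label"])
        for i, lab in enumerate(labels):
            w.writerow([i, lab])


def read_mesh(
    path: Path | str,
    fmt: str | None = None,
    expect_n_vertices: int | None = None,
) -> BodyMesh:
    """Read an OBJ or PLY mesh, preserving vertex order exactly.

    Region labels come from ``<name>.<ext>.labels.csv`` next to the mesh if
    present, otherwise every vertex is tagged ``torso``.  Coordinates are
    taken as centimetres.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in ("obj", "ply"):
        raise ValueError(f"unsupported mesh format {fmt!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        loaded = trimesh.load(path, file_type=fmt, process=False, maintain_order=True)
    except Exception as exc:  # trimesh raises assorted types on bad input
        raise ValueError(f"{path}: failed to parse as {fmt}: {exc}") from exc
    vertices = np.asarray(loaded.vertices, dtype=float)
    faces = getattr(loaded, "faces", None)
    if faces is not None:
        faces = np.asarray(faces, dtype=int)
        if faces.size == 0:
            faces = None
    if expect_n_vertices is not None and len(vertices) != expect_n_vertices:
        raise CorrespondenceError(
            f"{path}: {len(vertices)} vertices, expected {expect_n_vertices}"
        )
    labels = None
    sidecar = _labels_sidecar(path)
    if sidecar.exists():
        labels = read_labels(sidecar)
        if len(labels) != len(vertices):
            raise CorrespondenceError(
                f"{sidecar}: {len(labels)} labels for {len(vertices)} vertices"
            )
    scalar = _ply_scalar(loaded) if fmt == "ply" else None
    mesh = BodyMesh(path.stem, vertices, faces=faces, region_labels=labels)
    if scalar is not None:
        mesh.scalar = scalar  # type: ignore[attr-defined]
    return mesh


def _ply_scalar(loaded) -> np.ndarray | None:
    """Extract a per-vertex ``error_prop`` property from a loaded PLY."""
    raw = getattr(loaded, "metadata", {}).get("_ply_raw", {})
    vert = raw.get("vertex", {})
    data = vert.get("data", {})
    if isinstance(data, dict) and "error_prop" in data:
        return np.asarray(data["error_prop"], dtype=float).ravel()
    if hasattr(data, "dtype") and data.dtype.names and "error_prop" in data.dtype.names:
        return np.asarray(data["error_prop"], dtype=float).ravel()
    return None


def write_mesh(
    mesh: BodyMesh,
    path: Path | str,
    fmt: str | None = None,
    scalar: np.ndarray | None = None,
    write_label_sidecar: bool | None = None,
) -> Path:
    """Write a mesh as OBJ or PLY.

    PLY output is ascii with double-precision coordinates and, when
    ``scalar`` is given, a per-vertex float property ``error_prop`` (used
    for normalized prediction-error heatmaps).  OBJ cannot carry the scalar
    and drops it with a warning.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in ("obj", "ply"):
        raise ValueError(f"unsupported mesh format {fmt!r}")
    if scalar is not None:
        scalar = np.asarray(scalar, dtype=float)
        if scalar.shape != (mesh.n_vertices,):
            raise ValueError("scalar must have one value per vertex")
    if fmt == "obj":
        if scalar is not None:
            logger.warning("OBJ output has no scalar channel; error_prop dropped")
        tm = trimesh.Trimesh(
            vertices=mesh.vertices,
            faces=np.empty((0, 3), int) if mesh.faces is None else mesh.faces,
            process=False,
        )
        text = trimesh.exchange.obj.export_obj(tm, include_normals=False)
        if mesh.faces is None:  # keep the file a pure point list
            text = "\n".join(l for l in text.splitlines() if not l.startswith("f "))
        path.write_text(text + "\n")
    else:
        _write_ply_ascii(mesh, path, scalar)
    if write_label_sidecar is None:
        write_label_sidecar = bool(np.any(mesh.region_labels != "torso"))
    if write_label_sidecar:
        write_labels(mesh.region_labels, _labels_sidecar(path))
    return path


def _write_ply_ascii(mesh: BodyMesh, path: Path, scalar: np.ndarray | None) -> None:
    # double-precision coordinates: trimesh's exporter writes float32, which
    # loses the 6th decimal at body scale (~180 cm)
    n_faces = 0 if mesh.faces is None else len(mesh.faces)
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {mesh.n_vertices}",
        "property double x",
        "property double y",
        "property double z",
    ]
    if scalar is not None:
        lines.append("property double error_prop")
    lines += [
        f"element face {n_faces}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    cols = mesh.vertices if scalar is None else np.column_stack([mesh.vertices, scalar])
    for row in cols:
        lines.append(" ".join(format(v, ".10g") for v in row))
    if mesh.faces is not None:
        for f in mesh.faces:
            lines.append("3 " + " ".join(str(int(i)) for i in f))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# composition tables
# ---------------------------------------------------------------------------

#: canonical CSV dialect
COMPOSITION_COLUMNS = (
    "id",
    "sex",
    "fatm_kg",
    "smm_kg",
    "height_cm",
    "weight_kg",
    "bmi",
    "age",
    "psych",
)
_MANDATORY = ("id", "sex", "fatm_kg", "smm_kg")


def read_composition_table(path: Path | str) -> list[CompositionRecord]:
    """Read a composition CSV into validated records.

    Rows violating the record invariants (negative masses, BMI inconsistent
    with weight/height, fat + muscle exceeding weight) are rejected with a
    row-numbered warning rather than aborting the whole table.
    """
    df = pd.read_csv(path)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    if df.empty:
        warnings.warn(f"{path}: empty composition table")
        return []
    records: list[CompositionRecord] = []
    for i, row in df.iterrows():
        def _opt(col):
            v = row.get(col)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

        try:
            rec = CompositionRecord(
                identity_id=str(row["id"]),
                sex=str(row["sex"]).strip().lower(),
                fatm=float(row["fatm_kg"]),
                smm=float(row["smm_kg"]),
                height=_opt("height_cm"),
                weight=_opt("weight_kg"),
                bmi=_opt("bmi"),
                age=_opt("age"),
                psych=_opt("psych"),
            )
            rec.validate()
        except (ValueError, TypeError) as exc:
            warnings.warn(f"{path} row {i + 2}: rejected ({exc})")
            continue
        records.append(rec)
    return records


def write_composition_table(records: Sequence[CompositionRecord], path: Path | str) -> None:
    rows = [
        {
            "id": r.identity_id,
            "sex": r.sex,
            "fatm_kg": r.fatm,
            "smm_kg": r.smm,
            "height_cm": r.height,
            "weight_kg": r.weight,
            "bmi": r.bmi,
            "age": r.age,
            "psych": r.psych,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=COMPOSITION_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# flattening
# ---------------------------------------------------------------------------


def check_correspondence(meshes: Sequence[BodyMesh]) -> None:
    first = meshes[0]
    for m in meshes[1:]:
        if not first.same_topology_as(m):
            raise CorrespondenceError(
                f"{m.identity_id}: topology differs from {first.identity_id}"
            )
        if not np.array_equal(first.region_labels, m.region_labels):
            raise CorrespondenceError(
                f"{m.identity_id}: region labels differ from {first.identity_id}"
            )


def flatten_cohort(
    meshes: Sequence[BodyMesh],
    regions: Iterable[str] = RETAINED_REGIONS,
) -> ShapeMatrix:
    """Flatten corresponded meshes into a (c, 3k) shape matrix.

    Each row concatenates the retained vertices of one identity in ascending
    vertex index as contiguous (x, y, z) triples.
    """
    if len(meshes) == 0:
        raise ValueError("cohort is empty")
    check_correspondence(meshes)
    mask = meshes[0].region_mask(regions)
    index_map = np.nonzero(mask)[0]
    if index_map.size == 0:
        raise ValueError(f"no vertices in regions {tuple(regions)}")
    data = np.stack([m.vertices[index_map].reshape(-1) for m in meshes])
    topo = VertexTopology(index_map=index_map, template=meshes[0].copy())
    return ShapeMatrix(data=data, identity_ids=[m.identity_id for m in meshes], topology=topo)


def flatten_mesh(mesh: BodyMesh, topology: VertexTopology) -> np.ndarray:
    """Flatten one mesh with an existing topology's retained-vertex map."""
    if mesh.n_vertices != topology.template.n_vertices:
        raise CorrespondenceError(
            f"{mesh.identity_id}: {mesh.n_vertices} vertices, topology expects "
            f"{topology.template.n_vertices}"
        )
    return mesh.vertices[topology.index_map].reshape(-1)


def unflatten(
    vector: np.ndarray,
    topology: VertexTopology,
    identity_id: str = "reconstructed",
    fill: BodyMesh | None = None,
) -> BodyMesh:
    """Lift a shape vector back to a mesh (exact inverse of flattening).

    Vertices outside the retained regions are copied from ``fill`` (default:
    the topology's template mesh).
    """
    vector = np.asarray(vector, dtype=float).ravel()
    if vector.size != topology.vector_length:
        raise ValueError(
            f"vector length {vector.size} != 3 x {topology.n_retained} retained vertices"
        )
    donor = fill if fill is not None else topology.template
    mesh = donor.copy(identity_id=identity_id)
    mesh.vertices[topology.index_map] = vector.reshape(-1, 3)
    return mesh
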