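"""PCA-plus-regressions statistical model of body shape vs composition.

The model works in the flattened shape space: aligned shape vectors are
mean-centred and decomposed by PCA into at most c − 1 principal directions
(c identities).  For every retained direction separately, an ordinary
least-squares regression predicts the identity scores from the chosen
composition predictors — fat mass and skeletal muscle mass (kg) by default,
or BMI for the unidimensional comparator.  Every direction is kept
regardless of regression significance: directions unrelated to composition
simply receive near-zero slopes and contribute nothing to predicted change.

Prediction inverts the pipeline: predictor values -> per-direction scores
-> mean + basis @ scores -> mesh.  Morphing applies the *difference* of two
predicted score vectors to an individual's own shape, so shape change is
personalised rather than anchored at the population mean.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_io import (
    BodyMesh,
    CompositionRecord,
    CorrespondenceError,
    ShapeMatrix,
    VertexTopology,
    flatten_mesh,
    unflatten,
)

logger = logging.getLogger("bodycal")

CLAMP_POLICIES = ("clamp_warn", "refuse", "allow")


class RangeError(ValueError):
    """Predictor value outside the training range under the refuse policy."""


class CollinearityError(ValueError):
    """Predictors are constant or linearly dependent across identities."""


@dataclass
class ShapeModel:
    """Mean shape, orthonormal PC basis and per-PC regression coefficients."""

    mean_vector: np.ndarray  # (3k,)
    basis: np.ndarray  # (3k, m), orthonormal columns
    pc_variances: np.ndarray  # (m,) sample variance of scores along each PC
    predictor_names: list[str]
    coefficients: np.ndarray  # (m, 1 + p): intercept then one slope per predictor
    training_ranges: np.ndarray  # (p, 2) observed [min, max] per predictor
    c: int  # number of training identities
    topology: VertexTopology

    @property
    def n_components(self) -> int:
        return self.basis.shape[1]

    # -- persistence --------------------------------------------------------

    def save(self, path: Path | str) -> Path:
        """Serialise as a single .npz bundle (arrays + JSON metadata)."""
        path = Path(path)
        meta = {
            "predictor_names": self.predictor_names,
            "c": self.c,
        }
        np.savez_compressed(
            path,
            mean_vector=self.mean_vector,
            basis=self.basis,
            pc_variances=self.pc_variances,
            coefficients=self.coefficients,
            training_ranges=self.training_ranges,
            index_map=self.topology.index_map,
            template_vertices=self.topology.template.vertices,
            template_faces=(
                np.empty((0, 3), int)
                if self.topology.template.faces is None
                else self.topology.template.faces
            ),
            template_labels=self.topology.template.region_labels,
            meta=np.array(json.dumps(meta)),
        )
        return path

    @classmethod
    def load(cls, path: Path | str) -> "ShapeModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            faces = z["template_faces"]
            template = BodyMesh(
                "template",
                z["template_vertices"],
                faces=None if faces.size == 0 else faces,
                region_labels=z["template_labels"],
            )
            return cls(
                mean_vector=z["mean_vector"],
                basis=z["basis"],
                pc_variances=z["pc_variances"],
                predictor_names=list(meta["predictor_names"]),
                coefficients=z["coefficients"],
                training_ranges=z["training_ranges"],
                c=int(meta["c"]),
                topology=VertexTopology(index_map=z["index_map"], template=template),
            )


def _predictor_matrix(
    records: Sequence[CompositionRecord],
    identity_ids: Sequence[str],
    predictors: Sequence[str],
) -> np.ndarray:
    by_id = {r.identity_id: r for r in records}
    missing = [i for i in identity_ids if i not in by_id]
    if missing:
        raise ValueError(f"no composition record for identities {missing[:5]}")
    return np.array(
        [[by_id[i].predictor(p) for p in predictors] for i in identity_ids], dtype=float
    )


def fit_shape_model(
    shapes: ShapeMatrix,
    records: Sequence[CompositionRecord],
    predictors: Sequence[str] = ("fatm", "smm"),
    variance_fraction: float | None = None,
) -> ShapeModel:
    """Fit the PCA + regressions model on an aligned, flattened cohort.

    PCA is computed by SVD of the mean-centred shape matrix with no
    per-coordinate rescaling; at most c − 1 components have nonzero
    variance and all of them are retained by default
    (``variance_fraction`` < 1 truncates the basis for speed).  Component
    signs are fixed so each direction's largest-magnitude loading is
    positive, which makes fits reproducible.
    """
    predictors = list(predictors)
    if not predictors:
        raise ValueError("predictors must be nonempty")
    c = shapes.n_identities
    if c < len(predictors) + 2:
        raise ValueError(
            f"need at least {len(predictors) + 2} identities for "
            f"{len(predictors)} predictors, got {c}"
        )
    p_mat = _predictor_matrix(records, shapes.identity_ids, predictors)
    for j, name in enumerate(predictors):
        if np.ptp(p_mat[:, j]) == 0:
            raise CollinearityError(f"predictor {name!r} is constant across identities")

    mean_vector = shapes.data.mean(axis=0)
    centred = shapes.data - mean_vector
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    # rank cut: components with numerically nonzero variance, at most c - 1
    tol = s[0] * max(centred.shape) * np.finfo(float).eps if s.size else 0.0
    m = int(min(np.sum(s > tol), c - 1))
    basis = vt[:m].T
    scores = u[:, :m] * s[:m]
    # deterministic sign: largest-|loading| positive per component
    for j in range(m):
        k = int(np.argmax(np.abs(basis[:, j])))
        if basis[k, j] < 0:
            basis[:, j] = -basis[:, j]
            scores[:, j] = -scores[:, j]
    pc_var = s[:m] ** 2 / (c - 1)
    if variance_fraction is not None:
        if not (0 < variance_fraction <= 1):
            raise ValueError("variance_fraction must be in (0, 1]")
        cum = np.cumsum(pc_var) / pc_var.sum()
        m = int(np.searchsorted(cum, variance_fraction) + 1)
        basis, scores, pc_var = basis[:, :m], scores[:, :m], pc_var[:m]

    # one OLS per PC, shared design [1, predictors]
    design = np.column_stack([np.ones(c), p_mat])
    coef, _, rank, _ = np.linalg.lstsq(design, scores, rcond=None)
    if rank < design.shape[1]:
        raise CollinearityError(
            f"predictors {predictors} are linearly dependent across identities"
        )
    ranges = np.column_stack([p_mat.min(axis=0), p_mat.max(axis=0)])
    return ShapeModel(
        mean_vector=mean_vector,
        basis=basis,
        pc_variances=pc_var,
        predictor_names=predictors,
        coefficients=coef.T,
        training_ranges=ranges,
        c=c,
        topology=shapes.topology,
    )


def _apply_clamp(model: ShapeModel, values: np.ndarray, clamp: str) -> np.ndarray:
    if clamp not in CLAMP_POLICIES:
        raise ValueError(f"clamp must be one of {CLAMP_POLICIES}")
    lo, hi = model.training_ranges[:, 0], model.training_ranges[:, 1]
    below, above = values < lo, values > hi
    if not (below.any() or above.any()) or clamp == "allow":
        return values
    names = [
        f"{n}={v:g} outside [{l:g}, {h:g}]"
        for n, v, l, h, b in zip(
            model.predictor_names, values, lo, hi, below | above
        )
        if b
    ]
    if clamp == "refuse":
        raise RangeError("; ".join(names))
    logger.warning("clamping out-of-range predictors: %s", "; ".join(names))
    return np.clip(values, lo, hi)


def predict_scores(
    model: ShapeModel, values: Sequence[float], clamp: str = "clamp_warn"
) -> np.ndarray:
    """Predicted PC scores for one predictor-value tuple."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size != len(model.predictor_names):
        raise ValueError(
            f"expected {len(model.predictor_names)} values "
            f"({model.predictor_names}), got {values.size}"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError("predictor values must be finite")
    values = _apply_clamp(model, values, clamp)
    return model.coefficients[:, 0] + model.coefficients[:, 1:] @ values


def predict_vector(
    model: ShapeModel, values: Sequence[float], clamp: str = "clamp_warn"
) -> np.ndarray:
    """Predicted flattened shape vector at the given predictor values."""
    return model.mean_vector + model.basis @ predict_scores(model, values, clamp)


def predict_shape(
    model: ShapeModel,
    values: Sequence[float],
    clamp: str = "clamp_warn",
    identity_id: str = "predicted",
) -> BodyMesh:
    """Predicted body mesh at the given composition values.

    Values outside the training range are, by default, clamped to it with a
    warning: the model is linear and extrapolates formally, but its accuracy
    outside the observed composition range is unverifiable.
    """
    return unflatten(predict_vector(model, values, clamp), model.topology, identity_id)


def morph_individual(
    model: ShapeModel,
    individual: BodyMesh,
    current: Sequence[float],
    target: Sequence[float],
    clamp: str = "clamp_warn",
) -> BodyMesh:
    """Apply the model's predicted shape *change* to a specific person.

    The starting point in shape space is the individual's own shape; the
    morph adds ``basis @ (scores(target) − scores(current))``, so
    ``target == current`` returns the individual unchanged.
    """
    if individual.n_vertices != model.topology.template.n_vertices:
        raise CorrespondenceError(
            f"{individual.identity_id}: topology does not match model"
        )
    delta = model.basis @ (
        predict_scores(model, target, clamp) - predict_scores(model, current, clamp)
    )
    vec = flatten_mesh(individual, model.topology) + delta
    return unflatten(
        vec, model.topology, identity_id=f"{individual.identity_id}_morphed",
        fill=individual,
    )
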