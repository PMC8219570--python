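"""Leave-one-out comparison of composition-based vs BMI-based shape models.

For each identity the cohort consensus, the PCA subspace and both
regression models are refit on the remaining identities; the held-out scan
is aligned to the fold's mean and its shape predicted from its *measured*
predictor values under each model.  Prediction error is the mean straight-
line 3D distance between original and predicted vertex positions, by
default over the torso only — limb positioning is idiosyncratic (arm/leg
placement is unconstrained during scanning) and would contaminate the
comparison.

The two per-identity error series are compared with a paired two-tailed
t-test; the effect size is the paired Cohen's d_z = mean(diff)/SD(diff),
which equals t/sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .alignment import align_to_reference, build_consensus
from .core_io import BodyMesh, CompositionRecord, CorrespondenceError, flatten_cohort
from .shapemodel import fit_shape_model, predict_vector, unflatten


def mean_point_error(
    predicted: BodyMesh,
    original: BodyMesh,
    regions: Iterable[str] = ("torso",),
) -> float:
    """Mean Euclidean vertex distance (cm) over the given regions."""
    if predicted.n_vertices != original.n_vertices:
        raise CorrespondenceError(
            f"{predicted.identity_id} vs {original.identity_id}: vertex counts differ"
        )
    mask = original.region_mask(regions)
    if not mask.any():
        raise ValueError(f"no vertices in regions {tuple(regions)}")
    d = np.linalg.norm(predicted.vertices[mask] - original.vertices[mask], axis=1)
    return float(d.mean())


def cohen_dz_from_t(t: float, n: int) -> float:
    """Paired-samples effect size d_z implied by a t statistic: t/sqrt(n)."""
    return t / np.sqrt(n)


@dataclass
class LooResult:
    """Paired leave-one-out errors for two competing predictor sets."""

    identity_ids: list[str]
    errors_a: np.ndarray  # per-identity mean torso error, model A (cm)
    errors_b: np.ndarray
    model_a: tuple[str, ...]
    model_b: tuple[str, ...]
    t: float  # positive when model A has the lower error
    df: int
    p: float
    cohen_dz: float

    @property
    def mean_a(self) -> float:
        return float(self.errors_a.mean())

    @property
    def mean_b(self) -> float:
        return float(self.errors_b.mean())

    @property
    def sd_a(self) -> float:
        return float(self.errors_a.std(ddof=1))

    @property
    def sd_b(self) -> float:
        return float(self.errors_b.std(ddof=1))


def paired_comparison(errors_a: np.ndarray, errors_b: np.ndarray) -> tuple[float, int, float, float]:
    """Paired t-test of error reduction (B − A) and Cohen's d_z.

    Positive t means model A predicts better.  A zero-variance difference
    (identical models) is reported as t = 0, p = 1 rather than undefined.
    """
    diff = np.asarray(errors_b, float) - np.asarray(errors_a, float)
    n = diff.size
    sd = diff.std(ddof=1)
    if sd == 0:
        return 0.0, n - 1, 1.0, 0.0
    t = float(diff.mean() / (sd / np.sqrt(n)))
    p = float(2 * stats.t.sf(abs(t), n - 1))
    return t, n - 1, p, float(t / np.sqrt(n))


def loo_compare(
    meshes: Sequence[BodyMesh],
    records: Sequence[CompositionRecord],
    model_a: Sequence[str] = ("fatm", "smm"),
    model_b: Sequence[str] = ("bmi",),
    regions: Iterable[str] = ("torso",),
    iterations: int = 1,
    align_heldout: str = "fold_mean",
) -> LooResult:
    """Leave-one-out prediction-error comparison of two predictor sets.

    Within each fold the consensus alignment and PCA are refit from scratch
    on the n − 1 training identities, so no information about the held-out
    scan leaks into either model.  ``align_heldout`` chooses the reference
    the held-out scan is aligned to before errors are measured:
    ``fold_mean`` (strict, default) or ``full_mean`` (the all-identity
    consensus computed once up front).
    """
    model_a, model_b = tuple(model_a), tuple(model_b)
    n = len(meshes)
    n_pred = max(len(model_a), len(model_b))
    if n < n_pred + 3:
        raise ValueError(f"need at least {n_pred + 3} identities, got {n}")
    if align_heldout not in ("fold_mean", "full_mean"):
        raise ValueError("align_heldout must be 'fold_mean' or 'full_mean'")
    by_id = {r.identity_id: r for r in records}
    full_mean = None
    if align_heldout == "full_mean":
        full_mean, _, _ = build_consensus(meshes, iterations=iterations)

    regions = tuple(regions)
    errors_a = np.empty(n)
    errors_b = np.empty(n)
    ids = [m.identity_id for m in meshes]
    for i, held in enumerate(meshes):
        train = [m for j, m in enumerate(meshes) if j != i]
        fold_mean, aligned, _ = build_consensus(train, iterations=iterations)
        shapes = flatten_cohort(aligned)
        ref = fold_mean if align_heldout == "fold_mean" else full_mean
        held_aligned = align_to_reference(held, ref).aligned
        rec = by_id[held.identity_id]
        for preds, out in ((model_a, errors_a), (model_b, errors_b)):
            model = fit_shape_model(shapes, records, predictors=preds)
            values = [rec.predictor(p) for p in preds]
            vec = predict_vector(model, values, clamp="allow")
            pred_mesh = unflatten(vec, model.topology, identity_id="pred")
            out[i] = mean_point_error(pred_mesh, held_aligned, regions)
    t, df, p, dz = paired_comparison(errors_a, errors_b)
    return LooResult(
        identity_ids=ids,
        errors_a=errors_a,
        errors_b=errors_b,
        model_a=model_a,
        model_b=model_b,
        t=t,
        df=df,
        p=p,
        cohen_dz=dz,
    )


def error_proportion_map(
    original: BodyMesh,
    predicted_a: BodyMesh,
    predicted_b: BodyMesh,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-vertex prediction errors normalised by the shared maximum.

    Both models' per-vertex distances are divided by the single maximum
    error across the two, so the resulting maps (values in [0, 1]) are on a
    common colour scale for one identity.  If both predictions are exact the
    maps are all zero by convention.

    Returns ``(prop_a, prop_b, max_error_cm)``.
    """
    for m in (predicted_a, predicted_b):
        if m.n_vertices != original.n_vertices:
            raise CorrespondenceError("meshes are not corresponded")
    d_a = np.linalg.norm(predicted_a.vertices - original.vertices, axis=1)
    d_b = np.linalg.norm(predicted_b.vertices - original.vertices, axis=1)
    max_error = float(max(d_a.max(), d_b.max()))
    if max_error == 0:
        return np.zeros_like(d_a), np.zeros_like(d_b), 0.0
    return d_a / max_error, d_b / max_error, max_error
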