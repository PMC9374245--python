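"""Superimposition machinery.

Generalised Procrustes Analysis (GPA) removes position, scale and
orientation from a sample of landmark configurations, leaving shape: each
specimen is centred, scaled to unit centroid size, and rotated to a
running consensus until the consensus stabilises.  The module also
provides sliding semilandmarks (bending-energy or Procrustes-distance
criterion), thin-plate-spline interpolation, TPS-based missing-landmark
estimation within reference groups, pairwise Procrustes distances, and a
landmark-sampling adequacy curve that measures how well random landmark
subsets reproduce the full scheme's shape space.

Conventions: partial Procrustes (specimens stay at unit centroid size
during the rotation step) and no reflections anywhere — left/right
anatomy must never flip.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import orthogonal_procrustes

from .datatypes import LandmarkConfiguration, LandmarkDataset, SliderSpec

__all__ = [
    "AlignedSample",
    "LasecCurve",
    "centroid_size",
    "optimal_superimposition",
    "gpa",
    "procrustes_distance",
    "pairwise_procrustes_distances",
    "tps_interpolate",
    "bending_energy_matrix",
    "estimate_missing",
    "lasec",
]


@dataclass
class AlignedSample:
    """Output of a GPA run: superimposed shapes plus size information."""

    shapes: np.ndarray  # n x k x d, centred (unit CS when scaled)
    centroid_sizes: np.ndarray  # n, in pre-scaling units
    consensus: np.ndarray  # k x d mean shape
    iterations: int
    converged: bool
    specimen_ids: list[str]
    scaled: bool = True

    @property
    def n(self) -> int:
        return self.shapes.shape[0]

    @property
    def k(self) -> int:
        return self.shapes.shape[1]

    @property
    def d(self) -> int:
        return self.shapes.shape[2]

    @property
    def log_cs(self) -> np.ndarray:
        return np.log(self.centroid_sizes)

    def flattened(self) -> np.ndarray:
        """n x (k*d) matrix of Procrustes shape coordinates (row-major per landmark)."""
        return self.shapes.reshape(self.n, -1)

    def subset(self, index: np.ndarray) -> "AlignedSample":
        index = np.asarray(index)
        return replace(
            self,
            shapes=self.shapes[index],
            centroid_sizes=self.centroid_sizes[index],
            specimen_ids=[self.specimen_ids[i] for i in np.atleast_1d(index)],
        )


@dataclass
class LasecCurve:
    """Median fit between subsampled and full-scheme shape spaces, by landmark count."""

    landmark_counts: np.ndarray
    fits_per_iteration: np.ndarray  # iterations x len(landmark_counts)
    median_fit: np.ndarray

    def count_for_fit(self, target: float) -> int:
        """Smallest landmark count whose median fit reaches ``target``."""
        ok = np.nonzero(self.median_fit >= target)[0]
        if len(ok) == 0:
            raise ValueError(f"median fit never reaches {target}")
        return int(self.landmark_counts[ok[0]])


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Square root of summed squared landmark distances from the centroid."""
    if isinstance(config, LandmarkConfiguration):
        if not config.is_complete:
            raise ValueError(f"{config.specimen_id}: missing landmarks present")
        coords = config.coords
    else:
        coords = np.asarray(config, dtype=float)
    centred = coords - coords.mean(axis=0)
    return float(np.sqrt(np.sum(centred**2)))


def _optimal_rotation(b: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Rotation R (det +1, no reflection) minimising ||a - b R||_F for centred a, b."""
    h = b.T @ a
    u, _, vt = np.linalg.svd(h)
    flip = np.ones(h.shape[0])
    flip[-1] = np.sign(np.linalg.det(u @ vt))
    return (u * flip) @ vt


def optimal_superimposition(
    a: np.ndarray, b: np.ndarray, allow_scale: bool = False
) -> tuple[dict, float]:
    """Optimal rigid (optionally similarity) fit of ``b`` onto ``a``.

    Returns a transform dict with ``rotation`` (det +1), ``scale`` and
    ``translation`` such that ``scale * b @ rotation + translation``
    minimises the summed squared distance to ``a``, and the residual
    (square root of that minimised sum).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    nb = np.sqrt(np.sum(bc**2))
    if nb < 1e-300:
        raise ValueError("degenerate configuration: all points coincident")
    rot = _optimal_rotation(bc, ac)
    trace = float(np.sum((bc @ rot) * ac))
    scale = max(trace, 0.0) / nb**2 if allow_scale else 1.0
    translation = a.mean(axis=0) - scale * b.mean(axis=0) @ rot
    residual = float(np.sqrt(np.sum((scale * bc @ rot - ac) ** 2)))
    return {"rotation": rot, "scale": scale, "translation": translation}, residual


def _principal_axes_rotation(consensus: np.ndarray) -> np.ndarray:
    """Proper rotation aligning the consensus principal axes with the
    coordinate axes, with deterministic signs (largest-magnitude loading of
    each axis positive; last axis sign chosen so det = +1)."""
    c = consensus - consensus.mean(axis=0)
    d = c.shape[1]
    _, _, vt = np.linalg.svd(c, full_matrices=True)
    v = vt.T
    for j in range(d - 1):
        lead = np.argmax(np.abs(c @ v[:, j]))
        if (c @ v[:, j])[lead] < 0:
            v[:, j] = -v[:, j]
    if np.linalg.det(v) < 0:
        v[:, -1] = -v[:, -1]
    return v


def _centre_scale(coords: np.ndarray, scale: bool) -> tuple[np.ndarray, float]:
    centred = coords - coords.mean(axis=0)
    cs = float(np.sqrt(np.sum(centred**2)))
    if cs < 1e-300:
        raise ValueError("degenerate configuration with zero centroid size")
    return (centred / cs if scale else centred), cs


def gpa(
    dataset: LandmarkDataset,
    sliders: SliderSpec | None = None,
    scale: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
    slide_criterion: str = "bending_energy",
    slide_iters: int = 5,
) -> AlignedSample:
    """Generalised Procrustes Analysis with optional semilandmark sliding.

    Each outer iteration rotates every specimen onto the current consensus,
    updates the consensus (renormalised to unit centroid size when scaling),
    and, when ``sliders`` are given, slides semilandmarks along their chord
    tangents against the consensus.  Sliding runs for the first
    ``slide_iters`` outer iterations only — the tangent linearisation lets
    semilandmarks creep along the curve indefinitely if re-slid forever —
    after which plain GPA iterates until the root-mean-square consensus
    change falls below ``tol`` or ``max_iter`` is reached; non-convergence
    is flagged, not fatal.
    """
    if dataset.n < 2:
        raise ValueError("GPA needs at least 2 specimens")
    if sliders is not None:
        sliders.validate(dataset.k)
        if dataset.d != 2:
            raise ValueError("semilandmark sliding is implemented for 2-D data")
    raw = dataset.coords_array()
    n, k, d = raw.shape
    shapes = np.empty_like(raw)
    sizes = np.empty(n)
    for i in range(n):
        shapes[i], sizes[i] = _centre_scale(raw[i], scale)

    consensus, _ = _centre_scale(shapes[0], scale)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], consensus)
        if sliders is not None and iterations <= slide_iters:
            shapes = _slide_all(shapes, consensus, sliders, slide_criterion)
            for i in range(n):
                shapes[i], _ = _centre_scale(shapes[i], scale)
        new_consensus, _ = _centre_scale(shapes.mean(axis=0), scale)
        change = float(np.sqrt(np.mean((new_consensus - consensus) ** 2)))
        consensus = new_consensus
        if change < tol:
            converged = True
            break
    # final rotation pass so every shape is aligned to the final consensus
    for i in range(n):
        shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], consensus)
    # canonical orientation: principal axes of the consensus, signs fixed,
    # det +1 — makes the output invariant to input order and rigid pre-motion
    rot = _principal_axes_rotation(shapes.mean(axis=0))
    shapes = shapes @ rot
    consensus = consensus @ rot
    return AlignedSample(
        shapes=shapes,
        centroid_sizes=sizes,
        consensus=shapes.mean(axis=0),
        iterations=iterations,
        converged=converged,
        specimen_ids=dataset.specimen_ids,
        scaled=scale,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two unit-centroid-size shapes.

    Square root of the minimised summed squared coordinate differences
    after optimal rotation (no reflection, no extra scaling).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"landmark count mismatch: {a.shape} vs {b.shape}")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    _, residual = optimal_superimposition(ac, bc, allow_scale=False)
    return residual


def pairwise_procrustes_distances(aligned: AlignedSample) -> np.ndarray:
    """Symmetric n x n matrix of pairwise Procrustes distances."""
    n = aligned.n
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = procrustes_distance(aligned.shapes[i], aligned.shapes[j])
    return out


def _tps_kernel(r: np.ndarray, d: int) -> np.ndarray:
    if d == 2:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(r > 0, r**2 * np.log(r), 0.0)
        return out
    return r


def _tps_system(source: np.ndarray) -> np.ndarray:
    k, d = source.shape
    r = np.linalg.norm(source[:, None, :] - source[None, :, :], axis=2)
    kmat = _tps_kernel(r, d)
    p = np.hstack([np.ones((k, 1)), source])
    top = np.hstack([kmat, p])
    bottom = np.hstack([p.T, np.zeros((d + 1, d + 1))])
    return np.vstack([top, bottom])


def tps_interpolate(
    source: np.ndarray, target: np.ndarray, query_points: np.ndarray
) -> np.ndarray:
    """Thin-plate-spline map taking ``source`` landmarks exactly onto
    ``target``, evaluated at ``query_points``.

    Kernel r^2 log r in 2-D and |r| in 3-D.  Reproduces any affine map
    exactly, which is what makes it usable for missing-landmark estimation.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    query_points = np.atleast_2d(np.asarray(query_points, dtype=float))
    k, d = source.shape
    if target.shape != (k, d):
        raise ValueError("source and target must share k and d")
    if k < d + 1:
        raise ValueError(f"need at least d+1={d + 1} landmarks, have {k}")
    lmat = _tps_system(source)
    rhs = np.vstack([target, np.zeros((d + 1, d))])
    try:
        params = np.linalg.solve(lmat, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular TPS system (coincident or degenerate source landmarks)") from exc
    w, affine = params[:k], params[k:]
    r = np.linalg.norm(query_points[:, None, :] - source[None, :, :], axis=2)
    u = _tps_kernel(r, d)
    pq = np.hstack([np.ones((query_points.shape[0], 1)), query_points])
    return u @ w + pq @ affine


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """k x k bending-energy matrix of the TPS anchored on ``reference``.

    The quadratic form ``sum_j v[:, j]^T B v[:, j]`` measures the
    non-affine deformation energy of displacements ``v`` (k x d) away
    from the reference; affine displacements have zero energy.
    """
    reference = np.asarray(reference, dtype=float)
    k = reference.shape[0]
    lmat = _tps_system(reference)
    linv = np.linalg.inv(lmat)
    b = linv[:k, :k]
    return 0.5 * (b + b.T)


def _slide_all(
    shapes: np.ndarray, consensus: np.ndarray, sliders: SliderSpec, criterion: str
) -> np.ndarray:
    if criterion not in ("bending_energy", "procrustes_distance"):
        raise ValueError(f"unknown sliding criterion {criterion!r}")
    n, k, d = shapes.shape
    bmat = bending_energy_matrix(consensus) if criterion == "bending_energy" else None
    out = shapes.copy()
    for i in range(n):
        out[i] = _slide_one(shapes[i], consensus, sliders, bmat)
    return out


def _slide_one(
    shape: np.ndarray,
    consensus: np.ndarray,
    sliders: SliderSpec,
    bmat: np.ndarray | None,
) -> np.ndarray:
    """Displace each semilandmark along its chord tangent to minimise the
    criterion against the consensus.  The tangent at a slider is the unit
    chord between its before/after anchors; with the tangents fixed the
    criterion is quadratic in the displacements, so the joint minimiser is
    a single linear solve.
    """
    k, d = shape.shape
    s = len(sliders)
    tangents = np.zeros((s, d))
    idx = np.zeros(s, dtype=int)
    for m, (before, slider, after) in enumerate(sliders.triplets):
        chord = shape[after] - shape[before]
        norm = np.linalg.norm(chord)
        if norm < 1e-12:
            raise ValueError(f"anchors {before},{after} coincide; slider tangent undefined")
        tangents[m] = chord / norm
        idx[m] = slider
    v0 = (shape - consensus).reshape(-1)
    u = np.zeros((k * d, s))
    for m in range(s):
        u[idx[m] * d : idx[m] * d + d, m] = tangents[m]
    if bmat is None:
        e = np.eye(k * d)
    else:
        e = np.kron(bmat, np.eye(d))
    a = u.T @ e @ u
    rhs = -u.T @ e @ v0
    t, *_ = np.linalg.lstsq(a, rhs, rcond=None)
    return shape + (u @ t).reshape(k, d)


def sliding_criterion_value(
    shape: np.ndarray, consensus: np.ndarray, criterion: str = "bending_energy"
) -> float:
    """Value of the sliding objective for one shape against the consensus."""
    v = shape - consensus
    if criterion == "procrustes_distance":
        return float(np.sum(v**2))
    b = bending_energy_matrix(consensus)
    return float(sum(v[:, j] @ b @ v[:, j] for j in range(shape.shape[1])))


def slide_semilandmarks(
    aligned: AlignedSample,
    sliders: SliderSpec,
    criterion: str = "bending_energy",
) -> AlignedSample:
    """One sliding + re-superimposition pass on an already aligned sample."""
    if aligned.d != 2:
        raise ValueError("semilandmark sliding is implemented for 2-D data")
    sliders.validate(aligned.k)
    shapes = _slide_all(aligned.shapes, aligned.consensus, sliders, criterion)
    for i in range(aligned.n):
        shapes[i], _ = _centre_scale(shapes[i], aligned.scaled)
        shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], aligned.consensus)
    consensus = shapes.mean(axis=0)
    return replace(aligned, shapes=shapes, consensus=consensus)


def estimate_missing(dataset: LandmarkDataset, group_by: str = "species") -> LandmarkDataset:
    """Estimate missing landmarks by TPS-warping each group's consensus.

    Within each level of ``group_by`` (a metadata key: species, sex or
    part), the consensus of the *complete* specimens is computed by GPA;
    for every incomplete specimen the consensus is thin-plate-spline
    warped onto the specimen through the landmarks both share, and the
    missing positions are read off the warped consensus.  Observed
    coordinates are never altered.
    """
    meta = dataset.metadata()
    if group_by not in meta.columns:
        raise KeyError(f"unknown metadata key {group_by!r}")
    groups = meta[group_by]
    configs = {c.specimen_id: c.copy() for c in dataset}
    d = dataset.d
    for level in groups.unique():
        sids = list(groups.index[groups == level])
        complete = [sid for sid in sids if configs[sid].is_complete]
        incomplete = [sid for sid in sids if not configs[sid].is_complete]
        if not incomplete:
            continue
        if not complete:
            raise ValueError(f"group {level!r} has no complete specimen to build a reference")
        if len(complete) == 1:
            consensus = configs[complete[0]].coords.copy()
            consensus -= consensus.mean(axis=0)
        else:
            ref = gpa(dataset.subset(complete), scale=True)
            consensus = ref.consensus
        for sid in incomplete:
            c = configs[sid]
            obs = ~c.missing
            if obs.sum() < d + 1:
                raise ValueError(
                    f"{sid}: only {int(obs.sum())} observed landmarks; need at least {d + 1}"
                )
            est = tps_interpolate(consensus[obs], c.coords[obs], consensus[c.missing])
            coords = c.coords.copy()
            coords[c.missing] = est
            configs[sid] = replace(
                c, coords=coords, missing=np.zeros(c.k, dtype=bool)
            )
    return LandmarkDataset(
        [configs[sid] for sid in dataset.specimen_ids], list(dataset.landmark_labels)
    )


def _ordination_fit(full_scores: np.ndarray, sub_scores: np.ndarray) -> float:
    """Fit in [0, 1] between two specimen ordinations: 1 minus the
    Procrustes residual of the subsample ordination superimposed
    (rotation + scaling) on the full one, as a fraction of total variance."""
    m = min(full_scores.shape[1], sub_scores.shape[1])
    f = full_scores[:, :m] - full_scores[:, :m].mean(axis=0)
    s = sub_scores[:, :m] - sub_scores[:, :m].mean(axis=0)
    denom = np.sum(f**2)
    if denom < 1e-300:
        return 1.0
    ns = np.sqrt(np.sum(s**2))
    if ns < 1e-300:
        return 0.0
    rot, _ = orthogonal_procrustes(s, f)
    scale = float(np.sum((s @ rot) * f)) / ns**2
    resid = np.sum((f - scale * (s @ rot)) ** 2)
    return float(np.clip(1.0 - resid / denom, 0.0, 1.0))


def _pc_scores(flat: np.ndarray) -> np.ndarray:
    x = flat - flat.mean(axis=0)
    u, sv, _ = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(sv > sv[0] * 1e-10)) if sv.size else 0
    return u[:, :rank] * sv[:rank]


def lasec(dataset: LandmarkDataset, iterations: int = 100, seed: int = 0) -> LasecCurve:
    """Landmark-sampling adequacy curve.

    Per iteration: a random landmark order is drawn; starting from 3
    landmarks and adding one at a time, the subsampled data are GPA-aligned
    and the fit between the subsample ordination and the full-scheme
    ordination is recorded.  The curve of median fits against landmark
    count shows how many landmarks suffice to capture the shape space
    (fit at k is exactly 1 by construction).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if dataset.k < 4:
        raise ValueError("need at least 4 landmarks")
    if dataset.n < 3:
        raise ValueError("need at least 3 specimens")
    rng = np.random.default_rng(seed)
    k = dataset.k
    counts = np.arange(3, k + 1)
    full_scores = _pc_scores(gpa(dataset).flattened())
    fits = np.empty((iterations, len(counts)))
    raw = dataset.coords_array()
    ids = dataset.specimen_ids
    for it in range(iterations):
        order = rng.permutation(k)
        for ci, count in enumerate(counts):
            keep = np.sort(order[:count])
            sub = LandmarkDataset(
                [
                    LandmarkConfiguration(specimen_id=ids[i], coords=raw[i][keep])
                    for i in range(dataset.n)
                ]
            )
            sub_scores = _pc_scores(gpa(sub).flattened())
            fits[it, ci] = _ordination_fit(full_scores, sub_scores)
    return LasecCurve(
        landmark_counts=counts,
        fits_per_iteration=fits,
        median_fit=np.median(fits, axis=0),
    )
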