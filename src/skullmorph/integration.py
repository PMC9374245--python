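"""Cranium–mandible integration: two-block partial least squares.

Two-block PLS decomposes the between-block covariance matrix by SVD into
paired singular axes (SAs) of maximal covariation; the strength of
integration is summarised by the percentage of squared covariance on SA1
and the correlation of the paired SA1 scores, with significance from
permuting the specimen correspondence between blocks.  Between-group
similarity of integration patterns is measured by the angle between SA1
vectors, tested against the null of two independent random directions
(expected angle 90 degrees in high dimension): the squared cosine of the
folded angle between random unit vectors in dimension p is a
Beta(1/2, (p-1)/2) variate, giving a closed-form P.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import beta

__all__ = [
    "PLSResult",
    "AngleComparison",
    "two_block_pls",
    "vector_angle",
    "random_angle_p",
    "compare_group_pls",
    "pad_to_3d",
]


@dataclass
class PLSResult:
    """Per-axis-pair singular values, covariance fractions, scores and test."""

    singular_values: np.ndarray  # descending
    percent_sq_cov: np.ndarray  # 100 * s_i^2 / sum s_j^2
    scores_a: np.ndarray  # n x m projections of block A
    scores_b: np.ndarray
    axes_a: np.ndarray  # m x p unit-norm rows
    axes_b: np.ndarray  # m x q
    axis_correlations: np.ndarray  # r of paired scores per axis
    perm_p: float  # permutation P for SA1 singular value
    permutations: int

    @property
    def sa1_correlation(self) -> float:
        return float(self.axis_correlations[0])


@dataclass
class AngleComparison:
    """Folded angle between two axis vectors and its random-vector null P."""

    angle_deg: float
    dimension: int
    p_value: float


def pad_to_3d(flat_2d: np.ndarray, k: int) -> np.ndarray:
    """Zero-pad flattened 2-D shape coordinates (n x 2k) to 3-D (n x 3k).

    Used when a 2-D block (photographed mandibles) is analysed together
    with a 3-D block: each landmark gains a z coordinate of 0.0.
    """
    x = np.asarray(flat_2d, dtype=float)
    if x.shape[1] != 2 * k:
        raise ValueError(f"expected n x {2 * k} input for k={k} landmarks")
    out = np.zeros((x.shape[0], 3 * k))
    out[:, 0::3] = x[:, 0::2]
    out[:, 1::3] = x[:, 1::2]
    return out


def two_block_pls(
    block_a: np.ndarray,
    block_b: np.ndarray,
    permutations: int = 999,
    seed: int = 0,
) -> PLSResult:
    """Two-block partial least squares of paired shape-variable blocks.

    Rows are specimens (same order in both blocks).  The SVD of the
    between-block covariance matrix yields paired singular axes; the
    permutation test re-randomises specimen correspondence between blocks
    and uses the first singular value as statistic (observed included in
    the null set).
    """
    a = np.asarray(block_a, dtype=float)
    b = np.asarray(block_b, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"blocks disagree on n: {a.shape[0]} vs {b.shape[0]}")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 specimens")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)

    def svd_cov(bb: np.ndarray):
        cov = ac.T @ bb / (n - 1)
        u, s, vt = np.linalg.svd(cov, full_matrices=False)
        return u, s, vt

    u, s, vt = svd_cov(bc)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    rank = max(rank, 1)
    u, s, vt = u[:, :rank], s[:rank], vt[:rank]
    scores_a = ac @ u
    scores_b = bc @ vt.T
    corrs = np.array(
        [
            np.corrcoef(scores_a[:, i], scores_b[:, i])[0, 1]
            if scores_a[:, i].std() > 0 and scores_b[:, i].std() > 0
            else np.nan
            for i in range(rank)
        ]
    )
    pct = 100.0 * s**2 / np.sum(s**2)

    perm_p = np.nan
    if permutations > 0:
        rng = np.random.default_rng(seed)
        count = 1  # observed included
        for _ in range(permutations):
            perm = rng.permutation(n)
            _, s_star, _ = svd_cov(bc[perm])
            if s_star[0] >= s[0] - 1e-12:
                count += 1
        perm_p = count / (permutations + 1)

    return PLSResult(
        singular_values=s,
        percent_sq_cov=pct,
        scores_a=scores_a,
        scores_b=scores_b,
        axes_a=u.T,
        axes_b=vt,
        axis_correlations=corrs,
        perm_p=float(perm_p),
        permutations=permutations,
    )


def vector_angle(v1: np.ndarray, v2: np.ndarray, fold: bool = True) -> float:
    """Angle in degrees between two vectors; folded into [0, 90] by default
    because the sign of a shape axis is arbitrary."""
    v1 = np.asarray(v1, dtype=float).reshape(-1)
    v2 = np.asarray(v2, dtype=float).reshape(-1)
    if v1.shape != v2.shape:
        raise ValueError("vectors must have equal length")
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero vector has no direction")
    c = float(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))
    if fold:
        c = abs(c)
    return float(np.degrees(np.arccos(c)))


def random_angle_p(angle_deg: float, dimension: int) -> float:
    """P(folded angle between two random unit vectors in R^p <= angle_deg).

    For independent uniform directions the squared cosine of their angle
    follows Beta(1/2, (p-1)/2), so the P-value is the upper tail of that
    distribution at cos^2(angle).  Small P means the observed vectors are
    more aligned than chance.
    """
    if dimension < 2:
        raise ValueError("dimension must be >= 2")
    if not 0.0 <= angle_deg <= 90.0:
        raise ValueError("folded angle must lie in [0, 90] degrees")
    c2 = np.cos(np.radians(angle_deg)) ** 2
    return float(beta.sf(c2, 0.5, (dimension - 1) / 2.0))


def compare_group_pls(
    block_a: np.ndarray,
    block_b: np.ndarray,
    groups: np.ndarray,
    permutations: int = 999,
    seed: int = 0,
    angle_dimension: int | None = None,
) -> tuple[dict[str, PLSResult], dict[str, AngleComparison]]:
    """Per-group two-block PLS and SA1 angle comparison between two groups.

    Runs the PLS separately within each of the two group levels and
    reports, per block, the folded angle between the groups' SA1 vectors
    with its random-vector P.  The null dimension defaults to the rank of
    the group-centred data of the block (shape data are rank-deficient
    after superimposition, so the nominal variable count would overstate
    the dimension); pass ``angle_dimension`` to override.
    """
    groups = np.asarray(groups)
    levels = [g for g in dict.fromkeys(groups.tolist())]
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    results: dict[str, PLSResult] = {}
    for i, lv in enumerate(levels):
        idx = groups == lv
        if idx.sum() < 3:
            raise ValueError(f"group {lv!r} too small (n={int(idx.sum())})")
        results[str(lv)] = two_block_pls(
            block_a[idx], block_b[idx], permutations=permutations, seed=seed + i
        )

    def group_centred_rank(block: np.ndarray) -> int:
        parts = [block[groups == lv] - block[groups == lv].mean(axis=0) for lv in levels]
        stacked = np.vstack(parts)
        sv = np.linalg.svd(stacked, compute_uv=False)
        return max(int(np.sum(sv > sv[0] * 1e-10)), 2) if sv.size and sv[0] > 0 else 2

    angles: dict[str, AngleComparison] = {}
    for name, block, axes in (
        ("block_a", block_a, [results[str(lv)].axes_a[0] for lv in levels]),
        ("block_b", block_b, [results[str(lv)].axes_b[0] for lv in levels]),
    ):
        p_dim = angle_dimension if angle_dimension is not None else group_centred_rank(block)
        ang = vector_angle(axes[0], axes[1], fold=True)
        angles[name] = AngleComparison(
            angle_deg=ang, dimension=p_dim, p_value=random_angle_p(ang, p_dim)
        )
    return results, angles
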