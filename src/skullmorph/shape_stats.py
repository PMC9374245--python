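"""Shape-space ordination and permutation-based linear models of shape.

Shape PCA is an eigendecomposition of the covariance of Procrustes shape
coordinates about the consensus.  Procrustes ANOVA decomposes the summed
squared Procrustes deviations sequentially over an ordered list of model
terms (covariates, factors and their interactions), with significance
from permutation — by default randomisation of reduced-model residuals
(RRPP), which respects the nesting of terms.  The same engine handles
univariate responses (e.g. centroid size for size-dimorphism tests).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .procrustes import AlignedSample, gpa
from .datatypes import LandmarkConfiguration, LandmarkDataset

__all__ = [
    "ShapeSpace",
    "ProcrustesAnovaTable",
    "shape_pca",
    "procrustes_anova",
    "allometry_free_shapes",
]


@dataclass
class ShapeSpace:
    """PCA of aligned shapes: scores, axes and variance fractions."""

    mean: np.ndarray  # k x d consensus
    eigenvalues: np.ndarray  # descending, length m
    percent_variance: np.ndarray  # sums to 100
    scores: np.ndarray  # n x m
    axes: np.ndarray  # m x (k*d), unit-norm rows
    specimen_ids: list[str]

    @property
    def m(self) -> int:
        return len(self.eigenvalues)

    def reconstruct(self) -> np.ndarray:
        """n x (k*d) shape coordinates rebuilt from mean + scores . axes."""
        return self.mean.reshape(1, -1) + self.scores @ self.axes


@dataclass
class ProcrustesAnovaTable:
    """Sequential (type-I) ANOVA rows for shape or size responses."""

    table: pd.DataFrame  # index: term names + "Residuals" + "Total"
    permutations: int
    seed: int
    permute: str

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda v: f"{v:.4f}")

    @property
    def total_ss(self) -> float:
        return float(self.table.loc["Total", "SS"])

    def rsq(self, term: str) -> float:
        return float(self.table.loc[term, "Rsq"])

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "P"])


def shape_pca(
    aligned: AlignedSample, drop_landmarks: list[int] | None = None
) -> ShapeSpace:
    """PCA of Procrustes shape coordinates about the consensus.

    ``drop_landmarks`` removes landmarks (0-based) and re-runs GPA before
    the decomposition, for analyses on a reduced landmark scheme.
    """
    if aligned.n < 2:
        raise ValueError("PCA needs at least 2 specimens")
    if drop_landmarks:
        configs = [
            LandmarkConfiguration(specimen_id=sid, coords=aligned.shapes[i])
            for i, sid in enumerate(aligned.specimen_ids)
        ]
        reduced = LandmarkDataset(configs).drop_landmarks(drop_landmarks)
        sub = gpa(reduced, scale=aligned.scaled)
        aligned = AlignedSample(
            shapes=sub.shapes,
            centroid_sizes=aligned.centroid_sizes,
            consensus=sub.consensus,
            iterations=sub.iterations,
            converged=sub.converged,
            specimen_ids=aligned.specimen_ids,
            scaled=aligned.scaled,
        )
    flat = aligned.flattened()
    centred = flat - flat.mean(axis=0)
    u, sv, vt = np.linalg.svd(centred, full_matrices=False)
    if sv.size and sv[0] > 0:
        rank = int(np.sum(sv > sv[0] * 1e-10))
    else:
        rank = 0
    eig = sv[:rank] ** 2 / (aligned.n - 1)
    total = eig.sum()
    pct = 100 * eig / total if total > 0 else np.zeros(rank)
    return ShapeSpace(
        mean=flat.mean(axis=0).reshape(aligned.k, aligned.d),
        eigenvalues=eig,
        percent_variance=pct,
        scores=u[:, :rank] * sv[:rank],
        axes=vt[:rank],
        specimen_ids=list(aligned.specimen_ids),
    )


def _term_columns(term: str, data: pd.DataFrame) -> np.ndarray:
    """Design columns for one term: numeric column, factor dummies
    (first level dropped), or their ':'-interaction products."""
    parts = [p.strip() for p in term.split(":")]
    blocks: list[np.ndarray] = []
    for p in parts:
        if p not in data.columns:
            raise KeyError(f"model term component {p!r} not in data")
        col = data[p]
        if pd.api.types.is_numeric_dtype(col):
            blocks.append(col.to_numpy(dtype=float).reshape(-1, 1))
        else:
            levels = sorted(col.astype(str).unique())
            if len(levels) < 2:
                raise ValueError(f"factor {p!r} has a single level")
            dummies = np.column_stack(
                [(col.astype(str) == lv).to_numpy(dtype=float) for lv in levels[1:]]
            )
            blocks.append(dummies)
    out = blocks[0]
    for b in blocks[1:]:
        out = np.einsum("ij,il->ijl", out, b).reshape(len(data), -1)
    return out


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthonormal basis Q of col(x) and its rank."""
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    keep = diag > (diag.max() * 1e-10 if diag.size and diag.max() > 0 else 1.0)
    return q[:, keep], int(keep.sum())


def procrustes_anova(
    shapes: np.ndarray,
    terms: list[str],
    data: pd.DataFrame,
    permutations: int = 999,
    seed: int = 0,
    permute: str = "residuals",
) -> ProcrustesAnovaTable:
    """Permutation Procrustes ANOVA with sequential sums of squares.

    Parameters
    ----------
    shapes
        n x p response matrix (flattened Procrustes coordinates, or a
        single column for size responses).
    terms
        ordered model terms over columns of ``data``; ``a:b`` denotes an
        interaction.  Decomposition is sequential, so order matters.
    permutations
        number of random permutations (0 disables the test: F reported,
        Z/P set to NaN).
    permute
        ``"residuals"`` permutes reduced-model residuals per term (RRPP);
        ``"raw"`` permutes response rows.

    P is the proportion of permuted statistics >= observed with the
    observed included in the null set; Z is the standardised position of
    log F within the permuted log F distribution.
    """
    y = np.asarray(shapes, dtype=float)
    if y.ndim == 1:
        y = y.reshape(-1, 1)
    n = y.shape[0]
    if len(data) != n:
        raise ValueError("data must have one row per specimen")
    if permutations and permutations < 99 and permutations != 0:
        raise ValueError("use at least 99 permutations (or 0 to skip the test)")
    if permute not in ("residuals", "raw"):
        raise ValueError("permute must be 'residuals' or 'raw'")

    designs = [np.ones((n, 1))]
    for t in terms:
        designs.append(np.hstack([designs[-1], _term_columns(t, data)]))
    qs, ranks = zip(*(_hat(x) for x in designs))
    dfs = [ranks[i + 1] - ranks[i] for i in range(len(terms))]
    for t, df in zip(terms, dfs):
        if df == 0:
            raise ValueError(f"term {t!r} is aliased with earlier terms")
    df_res = n - ranks[-1]
    if df_res <= 0:
        raise ValueError("model saturates the data; no residual degrees of freedom")

    def decompose(yy: np.ndarray) -> tuple[np.ndarray, float]:
        """Sequential term SS and residual SS for response yy."""
        fits = [qs[i].T @ yy for i in range(len(qs))]
        ss_fit = [float(np.sum(f**2)) for f in fits]
        term_ss = np.array([ss_fit[i + 1] - ss_fit[i] for i in range(len(terms))])
        ss_res = float(np.sum(yy**2) - ss_fit[-1])
        return term_ss, ss_res

    term_ss, ss_res = decompose(y)
    yc = y - qs[0] @ (qs[0].T @ y)
    ss_total = float(np.sum(yc**2))
    ms = term_ss / np.array(dfs)
    ms_res = ss_res / df_res
    f_obs = ms / ms_res

    p_vals = np.full(len(terms), np.nan)
    z_vals = np.full(len(terms), np.nan)
    if permutations > 0:
        rng = np.random.default_rng(seed)
        f_perm = np.empty((permutations, len(terms)))
        fitted = [qs[i] @ (qs[i].T @ y) for i in range(len(qs))]
        resid_reduced = [y - fitted[i] for i in range(len(terms))]
        for b in range(permutations):
            perm = rng.permutation(n)
            for ti in range(len(terms)):
                if permute == "residuals":
                    ystar = fitted[ti] + resid_reduced[ti][perm]
                else:
                    ystar = y[perm]
                ss_star, ss_res_star = decompose(ystar)
                ms_res_star = ss_res_star / df_res
                f_perm[b, ti] = (ss_star[ti] / dfs[ti]) / ms_res_star
        for ti in range(len(terms)):
            null = np.append(f_perm[:, ti], f_obs[ti])
            p_vals[ti] = float(np.mean(null >= f_obs[ti] - 1e-12))
            logs = np.log(np.maximum(null, 1e-300))
            sd = logs.std(ddof=1)
            z_vals[ti] = (np.log(max(f_obs[ti], 1e-300)) - logs.mean()) / sd if sd > 0 else 0.0

    rows = []
    for ti, t in enumerate(terms):
        rows.append(
            {
                "Df": dfs[ti],
                "SS": term_ss[ti],
                "MS": ms[ti],
                "Rsq": term_ss[ti] / ss_total if ss_total > 0 else np.nan,
                "F": f_obs[ti],
                "Z": z_vals[ti],
                "P": p_vals[ti],
            }
        )
    rows.append(
        {
            "Df": df_res,
            "SS": ss_res,
            "MS": ms_res,
            "Rsq": ss_res / ss_total if ss_total > 0 else np.nan,
            "F": np.nan,
            "Z": np.nan,
            "P": np.nan,
        }
    )
    rows.append(
        {"Df": n - 1, "SS": ss_total, "MS": np.nan, "Rsq": np.nan, "F": np.nan, "Z": np.nan, "P": np.nan}
    )
    table = pd.DataFrame(rows, index=terms + ["Residuals", "Total"])
    return ProcrustesAnovaTable(
        table=table, permutations=permutations, seed=seed, permute=permute
    )


def allometry_free_shapes(
    shapes: np.ndarray,
    log_cs: np.ndarray,
    grouping: np.ndarray | None = None,
) -> np.ndarray:
    """Residual shapes after regressing out log centroid size.

    With ``grouping``, separate slopes (and intercepts) are fitted per
    group.  Residuals are re-centred on the grand mean so they remain
    valid shape coordinates for ordination.
    """
    y = np.asarray(shapes, dtype=float)
    x = np.asarray(log_cs, dtype=float).reshape(-1)
    if np.ptp(x) == 0:
        raise ValueError("log centroid size has zero variance")
    grand_mean = y.mean(axis=0)
    resid = np.empty_like(y)
    if grouping is None:
        groups = [np.arange(len(x))]
    else:
        grouping = np.asarray(grouping)
        groups = [np.nonzero(grouping == g)[0] for g in pd.unique(grouping)]
    for idx in groups:
        design = np.column_stack([np.ones(len(idx)), x[idx]])
        beta, *_ = np.linalg.lstsq(design, y[idx], rcond=None)
        resid[idx] = y[idx] - design @ beta
    return resid + grand_mean
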