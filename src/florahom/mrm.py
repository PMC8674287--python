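"""Multiple regression on distance matrices (MRM) with a permutation null.

The response and predictor matrices are vectorized over the strict lower
triangle and fitted by ordinary least squares.  Because the n(n-1)/2 pairs
share regions and are not independent, significance is assessed by
simultaneously permuting the rows and columns of the response matrix,
refitting, and comparing the observed coefficients with the permutation
distribution (two-sided, with the +1 small-sample correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .checklists import ADMIN_DEPENDENCY, ADMIN_SAME_COUNTRY, AdminLookup, classify_admin_relation
from .exceptions import CollinearityError, DomainError
from .geoclim import DistanceMatrix

__all__ = [
    "vectorize_lower",
    "devectorize_lower",
    "permute_response",
    "mrm_fit",
    "admin_dummy_matrices",
    "slope_contrast",
    "MRMResult",
    "SlopeContrastResult",
]


def _as_matrix(M) -> np.ndarray:
    M = M.values if isinstance(M, DistanceMatrix) else np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise DomainError("expected a square matrix")
    if not np.allclose(M, M.T, equal_nan=True):
        raise DomainError("matrix must be symmetric")
    return M


def vectorize_lower(M) -> np.ndarray:
    """Strict lower triangle in row-major order (row i > column j)."""
    M = _as_matrix(M)
    i, j = np.tril_indices(M.shape[0], -1)
    return M[i, j]


def devectorize_lower(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vectorize_lower`; zero diagonal, symmetric output."""
    v = np.asarray(v, dtype=float)
    n = int(round((1 + np.sqrt(1 + 8 * v.size)) / 2))
    if n * (n - 1) // 2 != v.size:
        raise DomainError(f"vector length {v.size} is not n(n-1)/2 for integer n")
    M = np.zeros((n, n))
    i, j = np.tril_indices(n, -1)
    M[i, j] = v
    M[j, i] = v
    return M


def permute_response(M, permutation: Sequence[int]) -> np.ndarray:
    """Simultaneous row/column shuffle: out[i, j] = in[perm[i], perm[j]]."""
    M = _as_matrix(M)
    perm = np.asarray(permutation)
    if sorted(perm.tolist()) != list(range(M.shape[0])):
        raise DomainError("invalid permutation")
    return M[np.ix_(perm, perm)]


@dataclass
class MRMResult:
    terms: list[str]
    coefficients: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    n_pairs: int
    n_perm: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "coefficient": [self.coefficients[t] for t in self.terms],
                "p_perm": [self.p_values.get(t, np.nan) for t in self.terms],
                "R2": self.r_squared,
                "n_pairs": self.n_pairs,
                "n_perm": self.n_perm,
                "seed": self.seed,
            }
        )


def _is_binary(v: np.ndarray) -> bool:
    return set(np.unique(v)).issubset({0.0, 1.0})


def _build_design(
    predictors: Mapping[str, np.ndarray],
    interactions: Iterable[tuple[str, ...]],
    n_pairs: int,
):
    """Design matrix from vectorized predictors; continuous terms are centered
    before interaction products are formed to tame collinearity."""
    columns = {"intercept": np.ones(n_pairs)}
    centered = {}
    for name, vec in predictors.items():
        vec = np.asarray(vec, dtype=float)
        if vec.size != n_pairs:
            raise DomainError(f"predictor {name!r} has wrong length")
        columns[name] = vec
        centered[name] = vec if _is_binary(vec) else vec - vec.mean()
    for combo in interactions:
        label = ":".join(combo)
        prod = np.ones(n_pairs)
        for name in combo:
            if name not in centered:
                raise DomainError(f"interaction references unknown predictor {name!r}")
            prod = prod * centered[name]
        columns[label] = prod
    names = list(columns)
    X = np.column_stack([columns[k] for k in names])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via QR pivoting on correlations
        _, R = np.linalg.qr(X)
        bad = [names[k] for k in range(X.shape[1]) if abs(R[k, k]) < 1e-8]
        raise CollinearityError(f"rank-deficient design; collinear term(s): {bad}")
    return X, names


def mrm_fit(
    response,
    predictors: Mapping[str, object],
    n_perm: int = 999,
    seed: int | None = None,
    interactions: Iterable[tuple[str, ...]] = (),
) -> MRMResult:
    """MRM: OLS on vectorized lower triangles with a matrix-permutation null.

    ``response`` and every predictor are symmetric matrices sharing the same
    region ordering.  ``seed`` is mandatory so permutation p-values are
    reproducible.
    """
    if seed is None:
        raise DomainError("mrm_fit requires an explicit seed")
    if n_perm < 1:
        raise DomainError("n_perm must be >= 1")
    R = _as_matrix(response)
    n = R.shape[0]
    il, jl = np.tril_indices(n, -1)
    y = R[il, jl]
    keep = np.isfinite(y)
    pred_vecs = {}
    for name, M in predictors.items():
        Mv = _as_matrix(M)
        if Mv.shape != R.shape:
            raise DomainError(f"predictor {name!r} shape mismatch")
        pred_vecs[name] = Mv[il, jl]
    if not keep.all():
        y = y[keep]
        pred_vecs = {k: v[keep] for k, v in pred_vecs.items()}
    X, names = _build_design(pred_vecs, interactions, y.size)

    pinv = np.linalg.pinv(X)
    beta = pinv @ y
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(names))
    abs_obs = np.abs(beta)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y_perm = R[perm[il], perm[jl]]
        y_perm = y_perm[keep] if not keep.all() else y_perm
        beta_perm = pinv @ y_perm
        exceed += np.abs(beta_perm) >= abs_obs
    p = (1.0 + exceed) / (n_perm + 1.0)

    return MRMResult(
        terms=names,
        coefficients=dict(zip(names, beta.tolist())),
        p_values=dict(zip(names, p.tolist())),
        r_squared=r2,
        n_pairs=int(y.size),
        n_perm=n_perm,
        seed=seed,
    )


def admin_dummy_matrices(
    regions: pd.DataFrame, lookup: AdminLookup
) -> tuple[DistanceMatrix, DistanceMatrix]:
    """Binary pair matrices for same-country and dependency relations.

    "No administrative relation" is the omitted baseline category; the two
    matrices are mutually exclusive entrywise.
    """
    ids = [str(r) for r in regions["region_id"]]
    n = len(ids)
    same = np.zeros((n, n))
    dep = np.zeros((n, n))
    countries = [lookup.region_to_country.get(r) for r in ids]
    missing = [r for r, c in zip(ids, countries) if c is None]
    if missing:
        from .exceptions import MissingReferenceError

        raise MissingReferenceError(f"unknown region(s): {missing[:5]}")
    # cache country-pair classification
    pair_cache: dict[frozenset, bool] = {}
    for i in range(n):
        for j in range(i + 1, n):
            if countries[i] == countries[j]:
                same[i, j] = same[j, i] = 1.0
            else:
                key = frozenset((countries[i], countries[j]))
                linked = pair_cache.get(key)
                if linked is None:
                    linked = lookup.linked_countries(countries[i], countries[j])
                    pair_cache[key] = linked
                if linked:
                    dep[i, j] = dep[j, i] = 1.0
    return (
        DistanceMatrix(ids, same, units="binary"),
        DistanceMatrix(ids, dep, units="binary"),
    )


@dataclass
class SlopeContrastResult:
    slopes: dict[str, float]
    contrasts: dict[tuple[str, str], float]
    p_values: dict[tuple[str, str], float]
    method: str
    n_perm: int = 0
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "category_a": a,
                "category_b": b,
                "slope_a": self.slopes[a],
                "slope_b": self.slopes[b],
                "contrast": c,
                "p": self.p_values[(a, b)],
            }
            for (a, b), c in self.contrasts.items()
        ]
        return pd.DataFrame(rows)


def slope_contrast(
    response,
    distance,
    categories,
    n_perm: int = 999,
    seed: int | None = None,
    method: str = "permutation",
) -> SlopeContrastResult:
    """Compare distance-decay slopes of H across administrative categories.

    Fits H ~ distance * category (per-category intercepts and slopes) on the
    vectorized pairs; the contrast for a category pair is the difference of
    their slopes.  Significance comes from the same simultaneous row/column
    permutation of the response matrix as :func:`mrm_fit` (default) or from a
    parametric ANCOVA-style t-test on the interaction.
    """
    R = _as_matrix(response)
    D = _as_matrix(distance)
    n = R.shape[0]
    cats = np.asarray(categories)
    if cats.shape != R.shape:
        raise DomainError("category labels must form a pair matrix")
    il, jl = np.tril_indices(n, -1)
    y = R[il, jl]
    d = D[il, jl]
    labels = cats[il, jl]
    keep = np.isfinite(y)
    y, d, labels = y[keep], d[keep], labels[keep]
    levels = sorted(pd.unique(labels).tolist())
    if len(levels) < 2:
        raise DomainError("need at least 2 categories")
    counts = {lv: int((labels == lv).sum()) for lv in levels}
    small = [lv for lv, c in counts.items() if c < 3]
    if small:
        raise DomainError(f"category with < 3 pairs: {small}")

    def _design(lab):
        cols = [np.ones(lab.size)]
        names = ["intercept"]
        for lv in levels[1:]:
            cols.append((lab == lv).astype(float))
            names.append(f"cat[{lv}]")
        cols.append(d)
        names.append("distance")
        for lv in levels[1:]:
            cols.append(d * (lab == lv))
            names.append(f"distance:cat[{lv}]")
        return np.column_stack(cols), names

    X, names = _design(labels)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError("rank-deficient slope-contrast design")
    pinv = np.linalg.pinv(X)
    beta = pinv @ y

    def _slopes(b) -> dict[str, float]:
        base = b[names.index("distance")]
        out = {levels[0]: float(base)}
        for lv in levels[1:]:
            out[lv] = float(base + b[names.index(f"distance:cat[{lv}]")])
        return out

    slopes = _slopes(beta)
    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
    contrasts = {(a, b): slopes[b] - slopes[a] for a, b in pairs}

    if method == "permutation":
        if seed is None:
            raise DomainError("permutation slope_contrast requires a seed")
        rng = np.random.default_rng(seed)
        exceed = {pair: 0 for pair in pairs}
        for _ in range(n_perm):
            perm = rng.permutation(n)
            y_perm = R[perm[il], perm[jl]][keep]
            s_perm = _slopes(pinv @ y_perm)
            for a, b in pairs:
                if abs(s_perm[b] - s_perm[a]) >= abs(contrasts[(a, b)]):
                    exceed[(a, b)] += 1
        p_values = {
            pair: (1.0 + cnt) / (n_perm + 1.0) for pair, cnt in exceed.items()
        }
        return SlopeContrastResult(slopes, contrasts, p_values, "permutation", n_perm, seed)

    # parametric: t-test on each slope difference via the OLS covariance
    resid = y - X @ beta
    dof = y.size - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    p_values = {}
    for a, b in pairs:
        contrast_vec = np.zeros(X.shape[1])
        if a != levels[0]:
            contrast_vec[names.index(f"distance:cat[{a}]")] -= 1
        if b != levels[0]:
            contrast_vec[names.index(f"distance:cat[{b}]")] += 1
        se = np.sqrt(sigma2 * contrast_vec @ XtX_inv @ contrast_vec)
        t = contrasts[(a, b)] / se if se > 0 else np.inf
        p_values[(a, b)] = float(2 * stats.t.sf(abs(t), dof))
    return SlopeContrastResult(slopes, contrasts, p_values, "parametric")
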