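"""Region-level aggregation: mean homogenization, hotspot ranking, and the
multiple regression of mean H on region/flora characteristics with a spatial
autocovariate.

Per-region covariates: native and naturalized richness, native and
naturalized Faith phylogenetic diversity (total branch length of the minimal
rooted subtree spanning the flora, root edge included), the proportion of
endemic natives (natives occurring natively nowhere else in the dataset), the
donor score (average number of other regions in which the region's native
species are naturalized), area and insularity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .checklists import PresenceData
from .exceptions import CollinearityError, DomainError, EmptyInputError
from .geoclim import pairwise_geographic
from .phylo import PhyloIndex

logger = logging.getLogger(__name__)


def mean_homogenization(pair_table: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of pairwise H per region (taxonomic and phylogenetic).

    Flagged pairs are excluded; the number of usable pairs per region is
    reported alongside.
    """
    usable = pair_table[pair_table.get("flag", "") == ""]
    regions = pd.unique(
        pd.concat([pair_table["region_a"], pair_table["region_b"]], ignore_index=True)
    )
    rows = []
    for region in regions:
        mask = (usable["region_a"] == region) | (usable["region_b"] == region)
        sub = usable.loc[mask]
        n_total = int(
            ((pair_table["region_a"] == region) | (pair_table["region_b"] == region)).sum()
        )
        rows.append(
            {
                "region_id": region,
                "mean_h_tax": sub["h_tax"].mean() if len(sub) else np.nan,
                "mean_h_phyl": sub["h_phyl"].mean() if len(sub) else np.nan,
                "n_pairs": len(sub),
                "n_flagged": n_total - len(sub),
            }
        )
    return pd.DataFrame(rows)


def donor_scores(presence: PresenceData) -> pd.Series:
    """Donor score per region: mean over its native species of the number of
    regions where that species is naturalized."""
    nat_counts = presence.naturalized.sum(axis=0)  # per species
    scores = {}
    for i, region in enumerate(presence.regions):
        natives = presence.native[i]
        if not natives.any():
            raise EmptyInputError(f"region {region!r} has no native species")
        scores[region] = float(nat_counts[natives].mean())
    return pd.Series(scores, name="donor_score")


def donor_score(presence: PresenceData, region_id: str) -> float:
    return float(donor_scores(presence)[region_id])


def endemic_proportions(presence: PresenceData) -> pd.Series:
    """Fraction of each region's natives occurring natively nowhere else."""
    native_counts = presence.native.sum(axis=0)
    out = {}
    for i, region in enumerate(presence.regions):
        natives = presence.native[i]
        if not natives.any():
            raise EmptyInputError(f"region {region!r} has no native species")
        out[region] = float((native_counts[natives] == 1).mean())
    return pd.Series(out, name="endemic_proportion")


def endemic_proportion(presence: PresenceData, region_id: str) -> float:
    return float(endemic_proportions(presence)[region_id])


def faith_pd(tree, flora) -> float:
    """Faith phylogenetic diversity: branch length of the minimal rooted
    subtree spanning the flora (root-inclusive convention)."""
    index = tree if isinstance(tree, PhyloIndex) else PhyloIndex(tree)
    flora = set(flora)
    if not flora:
        raise EmptyInputError("Faith PD undefined for an empty flora")
    return index.total_length(index.flora_mask(flora))


def spatial_autocovariate(
    coords: np.ndarray,
    response: np.ndarray,
    radius_km: float | None = None,
) -> np.ndarray:
    """Inverse-distance-weighted mean of the response over neighbours.

    ``coords`` is (n, 2) lon/lat in degrees.  The default radius is the
    smallest radius at which every region has at least one neighbour.
    """
    coords = np.asarray(coords, dtype=float)
    y = np.asarray(response, dtype=float)
    D = pairwise_geographic(coords[:, 0], coords[:, 1])
    n = D.shape[0]
    if n < 2:
        raise DomainError("need at least two regions")
    off = D + np.diag(np.full(n, np.inf))
    min_radius = off.min(axis=1).max()
    if radius_km is None:
        radius_km = min_radius * (1 + 1e-9)
    elif radius_km < min_radius:
        isolated = np.flatnonzero(off.min(axis=1) > radius_km)
        raise DomainError(
            f"{isolated.size} region(s) isolated at radius {radius_km} km; "
            f"use radius >= {min_radius:.1f} km"
        )
    out = np.empty(n)
    for i in range(n):
        neigh = np.flatnonzero((off[i] <= radius_km))
        w = 1.0 / np.maximum(off[i, neigh], 1e-9)
        out[i] = float((w * y[neigh]).sum() / w.sum())
    return out


def morans_i(values: np.ndarray, coords: np.ndarray) -> float:
    """Moran's I with inverse-distance weights over all pairs."""
    y = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    D = pairwise_geographic(coords[:, 0], coords[:, 1])
    W = np.zeros_like(D)
    mask = D > 0
    W[mask] = 1.0 / D[mask]
    z = y - y.mean()
    denom = float(z @ z)
    if denom == 0:
        return 0.0
    return float(len(y) / W.sum() * (z @ W @ z) / denom)


def build_region_summary(
    presence: PresenceData,
    tree,
    pair_table: pd.DataFrame,
    regions: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the per-region summary table used by the hotspot regression."""
    index = tree if isinstance(tree, PhyloIndex) else PhyloIndex(tree)
    mean_h = mean_homogenization(pair_table).set_index("region_id")
    donors = donor_scores(presence)
    endemics = endemic_proportions(presence)
    meta = regions.set_index(regions["region_id"].astype(str))
    rows = []
    for i, region in enumerate(presence.regions):
        native_mask = index.flora_mask(
            [presence.species[j] for j in np.flatnonzero(presence.native[i])]
        )
        nat_idx = np.flatnonzero(presence.naturalized[i])
        nat_mask = index.flora_mask([presence.species[j] for j in nat_idx])
        rows.append(
            {
                "region_id": region,
                "mean_h_tax": mean_h.loc[region, "mean_h_tax"],
                "mean_h_phyl": mean_h.loc[region, "mean_h_phyl"],
                "native_richness": int(presence.native[i].sum()),
                "naturalized_richness": int(presence.naturalized[i].sum()),
                "native_pd": index.total_length(native_mask),
                "naturalized_pd": (
                    index.total_length(nat_mask) if nat_idx.size else 0.0
                ),
                "endemic_proportion": endemics[region],
                "donor_score": donors[region],
                "area_km2": float(meta.loc[region, "area_km2"]),
                "is_island": bool(meta.loc[region, "is_island"]),
            }
        )
    return pd.DataFrame(rows)


def hotspot_ranking(summary: pd.DataFrame, column: str = "mean_h_tax") -> pd.DataFrame:
    """Regions ranked by mean homogenization, strongest first."""
    return summary.sort_values(column, ascending=False).reset_index(drop=True)


@dataclass
class RegionRegressionResult:
    table: pd.DataFrame  # term, estimate, ci_low, ci_high, p
    response: str
    moran_i_residuals: float
    include_autocov: bool


_TAX_PREDICTORS = [
    ("native_richness", "log"),
    ("naturalized_richness", "log"),
    ("endemic_proportion", "raw"),
    ("donor_score", "log"),
    ("area_km2", "log"),
    ("is_island", "raw"),
]
_PHYL_PREDICTORS = [
    ("native_pd", "log"),
    ("naturalized_pd", "log"),
    ("endemic_proportion", "raw"),
    ("donor_score", "log"),
    ("area_km2", "log"),
    ("is_island", "raw"),
]


def region_regression(
    summary: pd.DataFrame,
    coords: np.ndarray,
    response: str = "mean_h_tax",
    include_autocov: bool = True,
    predictors: list[tuple[str, str]] | None = None,
) -> RegionRegressionResult:
    """Linear regression of mean H on scaled region/flora characteristics.

    Richness/PD, donor score and area are natural-log transformed; all
    predictors are then z-scaled so coefficients are comparable.  The
    optional spatial autocovariate (inverse-distance weighted mean of the
    response over neighbours) absorbs residual spatial autocorrelation,
    quantified by Moran's I on the residuals.
    """
    if response not in ("mean_h_tax", "mean_h_phyl"):
        raise DomainError(f"unknown response {response!r}")
    if len(summary) < 10:
        raise DomainError("need at least 10 regions for the region regression")
    chosen = predictors or (_TAX_PREDICTORS if response == "mean_h_tax" else _PHYL_PREDICTORS)
    y = summary[response].to_numpy(float)
    if np.any(~np.isfinite(y)):
        raise DomainError("response contains non-finite values")
    cols, names = [], []
    for name, transform in chosen:
        v = summary[name].to_numpy(float)
        if transform == "log":
            if np.any(v <= 0):
                raise DomainError(
                    f"predictor {name!r} must be strictly positive for log transform"
                )
            v = np.log(v)
        cols.append(v)
        names.append(name)
    if include_autocov:
        cols.append(spatial_autocovariate(coords, y))
        names.append("autocovariate")
    X = np.column_stack(cols)
    sds = X.std(axis=0, ddof=0)
    if np.any(sds == 0):
        bad = [names[k] for k in np.flatnonzero(sds == 0)]
        raise CollinearityError(f"constant predictor(s): {bad}")
    Xs = (X - X.mean(axis=0)) / sds
    design = sm.add_constant(Xs)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        corr = np.corrcoef(Xs, rowvar=False)
        dup = [
            (names[i], names[j])
            for i in range(len(names))
            for j in range(i + 1, len(names))
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise CollinearityError(f"collinear predictors: {dup or names}")
    fit = sm.OLS(y, design).fit()
    ci = fit.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "term": ["intercept", *names],
            "estimate": fit.params,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "p": fit.pvalues,
        }
    ).reset_index(drop=True)
    moran = morans_i(fit.resid, coords)
    return RegionRegressionResult(
        table=table,
        response=response,
        moran_i_residuals=moran,
        include_autocov=include_autocov,
    )
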