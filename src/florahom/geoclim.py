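"""Geographic and climatic distances between regions.

Geographic distance is the great-circle (haversine) distance between region
centroids on a sphere of radius 6371.0088 km.  Climatic distance is the
Euclidean distance between region centroids in the space of the first three
principal components of the 19 bioclimatic variables, after a per-variable
Yeo-Johnson normalization and z-scaling; PC1-only and PC2-only distances are
also provided because the leading axes separate temperature- and
precipitation-driven variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import skew
from sklearn.decomposition import PCA
from sklearn.preprocessing import PowerTransformer

from .exceptions import DomainError, FormatError, MissingReferenceError

EARTH_RADIUS_KM = 6371.0088

BIOCLIM_COLUMNS = [f"bio{i}" for i in range(1, 20)]


# ---------------------------------------------------------------------------
# geographic distance
# ---------------------------------------------------------------------------


def great_circle_distance(lonlat_a, lonlat_b) -> float:
    """Haversine distance in km between two (lon, lat) points in degrees."""
    lon1, lat1 = lonlat_a
    lon2, lat2 = lonlat_b
    for lon, lat in ((lon1, lat1), (lon2, lat2)):
        if abs(lon) > 180 or abs(lat) > 90:
            raise DomainError(f"coordinate ({lon}, {lat}) out of range")
    return float(_haversine(np.array([lon1]), np.array([lat1]),
                            np.array([lon2]), np.array([lat2]))[0])


def _haversine(lon1, lat1, lon2, lat2) -> np.ndarray:
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def pairwise_geographic(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Symmetric haversine distance matrix (km) for centroid vectors."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lon) > 180) or np.any(np.abs(lat) > 90):
        raise DomainError("coordinates out of range")
    D = _haversine(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    np.fill_diagonal(D, 0.0)
    return D


# ---------------------------------------------------------------------------
# climate normalization and PCA
# ---------------------------------------------------------------------------


@dataclass
class NormalizationReport:
    columns: list[str]
    lambdas: np.ndarray  # Yeo-Johnson exponents
    skew_before: np.ndarray
    skew_after: np.ndarray


@dataclass
class ClimatePCA:
    columns: list[str]
    transformer: PowerTransformer
    components: np.ndarray  # (n_components, n_vars), orthonormal rows
    explained_variance_ratio: np.ndarray
    mean_: np.ndarray

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        X = self.transformer.transform(table[self.columns].to_numpy(float))
        return (X - self.mean_) @ self.components.T


def normalize_bioclim(
    table: pd.DataFrame, columns: Sequence[str] | None = None
) -> tuple[pd.DataFrame, NormalizationReport, PowerTransformer]:
    """Yeo-Johnson transform then z-scale each bioclimatic column.

    Output columns have mean 0 and SD 1; the report records the fitted
    exponents and the skewness before/after.  A constant column is an error
    because it cannot be scaled.
    """
    columns = list(columns) if columns is not None else [
        c for c in table.columns if c in BIOCLIM_COLUMNS
    ]
    if not columns:
        raise FormatError("no bioclimatic columns found")
    X = table[columns].to_numpy(float)
    if np.any(~np.isfinite(X)):
        raise FormatError("climate table contains missing or non-finite values")
    stds = X.std(axis=0)
    tol = 1e-12 * np.maximum(1.0, np.abs(X.mean(axis=0)))
    if np.any(stds <= tol):
        bad = columns[int(np.argmin(stds - tol))]
        raise DomainError(f"climate variable {bad!r} is constant")
    transformer = PowerTransformer(method="yeo-johnson", standardize=True)
    Z = transformer.fit_transform(X)
    report = NormalizationReport(
        columns=columns,
        lambdas=np.asarray(transformer.lambdas_),
        skew_before=skew(X, axis=0),
        skew_after=skew(Z, axis=0),
    )
    out = table.copy()
    out[columns] = Z
    return out, report, transformer


def climate_pca(
    normalized: pd.DataFrame,
    transformer: PowerTransformer,
    columns: Sequence[str] | None = None,
    n_components: int = 3,
) -> tuple[ClimatePCA, np.ndarray]:
    """PCA of the normalized climate table; returns the model and row scores.

    Axis signs are fixed so each loading vector's largest-magnitude
    coefficient is positive, removing run-to-run sign ambiguity.
    """
    columns = list(columns) if columns is not None else [
        c for c in normalized.columns if c in BIOCLIM_COLUMNS
    ]
    X = normalized[columns].to_numpy(float)
    if X.shape[0] < 4:
        raise DomainError("need at least 4 climate rows for a PCA")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if rank < n_components:
        raise DomainError(
            f"climate table rank {rank} < {n_components} requested components"
        )
    pca = PCA(n_components=min(X.shape[0] - 1, X.shape[1]), svd_solver="full")
    scores = pca.fit_transform(X)
    components = pca.components_
    # sign convention
    for k in range(components.shape[0]):
        j = np.argmax(np.abs(components[k]))
        if components[k, j] < 0:
            components[k] *= -1
            scores[:, k] *= -1
    model = ClimatePCA(
        columns=columns,
        transformer=transformer,
        components=components[:n_components],
        explained_variance_ratio=pca.explained_variance_ratio_[:n_components],
        mean_=pca.mean_,
    )
    return model, scores[:, :n_components]


def climate_centroid(scores: np.ndarray) -> np.ndarray:
    """Mean position of one region's cell scores in PC space."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.size == 0:
        raise DomainError("no climate cells for region")
    return scores.mean(axis=0)


def region_centroids(
    region_ids: Iterable[str], scores: np.ndarray, region_order: Sequence[str]
) -> np.ndarray:
    """Per-region climate centroids from (possibly repeated) cell rows."""
    frame = pd.DataFrame(scores)
    frame["region_id"] = list(region_ids)
    grouped = frame.groupby("region_id").mean()
    missing = set(region_order) - set(grouped.index)
    if missing:
        raise MissingReferenceError(
            f"no climate rows for region(s): {sorted(missing)[:5]}"
        )
    return grouped.loc[list(region_order)].to_numpy()


def climatic_distance(
    centroid_a: np.ndarray, centroid_b: np.ndarray, axes: Iterable[int] = (1, 2, 3)
) -> float:
    """Euclidean distance between climate centroids on the selected PC axes."""
    axes = sorted(set(axes))
    if any(a not in (1, 2, 3) for a in axes) or not axes:
        raise DomainError(f"axes must be a nonempty subset of {{1, 2, 3}}, got {axes}")
    idx = [a - 1 for a in axes]
    diff = np.asarray(centroid_a, float)[idx] - np.asarray(centroid_b, float)[idx]
    return float(np.sqrt(np.sum(diff**2)))


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    units: str = "km"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise FormatError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise DomainError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise DomainError("distance matrix must have a zero diagonal")
        if np.any(self.values < 0):
            raise DomainError("distance matrix must be nonnegative")

    def write_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path, units: str = "") -> "DistanceMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(labels=[str(c) for c in frame.columns], values=frame.to_numpy(), units=units)


@dataclass
class DistanceMatrixSet:
    geographic: DistanceMatrix
    climatic: DistanceMatrix
    pc1: DistanceMatrix
    pc2: DistanceMatrix
    pca: ClimatePCA | None = None

    def as_dict(self) -> dict[str, DistanceMatrix]:
        return {
            "geographic": self.geographic,
            "climatic": self.climatic,
            "pc1": self.pc1,
            "pc2": self.pc2,
        }


def build_distance_matrices(
    regions: pd.DataFrame, climate: pd.DataFrame
) -> DistanceMatrixSet:
    """Geographic, 3-axis climatic, PC1-only and PC2-only distance matrices.

    ``climate`` holds one or more rows per region (cell samples are averaged
    into a per-region centroid after normalization and PCA).
    """
    region_ids = [str(r) for r in regions["region_id"]]
    if "region_id" not in climate.columns:
        raise FormatError("climate table needs a region_id column")
    normalized, _, transformer = normalize_bioclim(climate)
    model, scores = climate_pca(normalized, transformer)
    centroids = region_centroids(
        climate["region_id"].astype(str), scores, region_ids
    )

    geo = pairwise_geographic(
        regions["centroid_lon"].to_numpy(float), regions["centroid_lat"].to_numpy(float)
    )

    def _euclid(cols) -> np.ndarray:
        sub = centroids[:, cols]
        diff = sub[:, None, :] - sub[None, :, :]
        D = np.sqrt((diff**2).sum(axis=-1))
        np.fill_diagonal(D, 0.0)
        return D

    return DistanceMatrixSet(
        geographic=DistanceMatrix(region_ids, geo, units="km"),
        climatic=DistanceMatrix(region_ids, _euclid([0, 1, 2]), units="pc"),
        pc1=DistanceMatrix(region_ids, _euclid([0]), units="pc"),
        pc2=DistanceMatrix(region_ids, _euclid([1]), units="pc"),
        pca=model,
    )
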