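"""End-to-end orchestration: from checklists (or a simulated world) to pair
tables, distance matrices, decay fits, matrix regressions, region summaries
and a run manifest.

The pipeline is a pure function of (inputs, config): identical inputs and
configuration reproduce identical numeric outputs, which the manifest makes
checkable via a configuration hash and row counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .checklists import (
    ADMIN_DEPENDENCY,
    ADMIN_NONE,
    ADMIN_SAME_COUNTRY,
    AdminLookup,
    PresenceData,
    build_presence,
    classify_admin_relation,
    clean_checklists,
    read_admin_pairs,
    read_checklists,
    read_regions,
)
from .decay import decay_curves
from .exceptions import DomainError, FloraHomError, FormatError
from .geoclim import DistanceMatrixSet, build_distance_matrices
from .mrm import admin_dummy_matrices, mrm_fit, slope_contrast
from .phylo import PhyloIndex, graft_missing_species, read_tree
from .regions import build_region_summary, hotspot_ranking, region_regression
from .similarity import h_matrix, pairwise_table
from .synth import SyntheticDataset, WorldParams, generate_dataset

logger = logging.getLogger(__name__)

_INPUT_KEYS = ("checklists", "regions", "colonial_ties", "dependencies", "climate", "tree")

MRM_INTERACTIONS = [
    ("geographic", "climatic"),
    ("geographic", "same_country"),
    ("geographic", "dependency"),
    ("climatic", "same_country"),
    ("climatic", "dependency"),
]


@dataclass
class PipelineConfig:
    """Pipeline configuration; either the six input paths or a simulate block."""

    inputs: dict[str, str] | None = None
    simulate: WorldParams | None = None
    scenario: str = "all"
    index: str = "simpson"
    offset: float = 0.001
    n_perm: int = 999
    seed: int = 0
    outdir: str = "florahom_out"
    with_phylogeny: bool = True

    def validate(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise DomainError(
                "config must provide exactly one of: input paths, simulate block"
            )
        if self.inputs is not None:
            missing = [k for k in _INPUT_KEYS if k not in self.inputs]
            if missing:
                raise DomainError(f"config lacks input path(s): {missing}")
        if self.scenario not in ("all", "native_to_one", "non_native_to_both"):
            raise DomainError(f"unknown scenario {self.scenario!r}")
        if self.index not in ("simpson", "sorensen"):
            raise DomainError(f"unknown index {self.index!r}")
        if self.n_perm < 1:
            raise DomainError("n_perm must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        simulate = None
        if raw.pop("simulate", False):
            world_fields = {f.name for f in dataclasses.fields(WorldParams)}
            params = {k: raw.pop(k) for k in list(raw) if k in world_fields}
            simulate = WorldParams(**params)
        inputs = None
        if any(k in raw for k in _INPUT_KEYS):
            inputs = {k: str(raw.pop(k)) for k in _INPUT_KEYS if k in raw}
        known = {f.name for f in dataclasses.fields(cls)} - {"inputs", "simulate"}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config key(s): {sorted(unknown)}")
        return cls(inputs=inputs, simulate=simulate, **raw)

    def to_dict(self) -> dict:
        out: dict = {
            "scenario": self.scenario,
            "index": self.index,
            "offset": self.offset,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "outdir": self.outdir,
            "with_phylogeny": self.with_phylogeny,
        }
        if self.inputs is not None:
            out.update(self.inputs)
        if self.simulate is not None:
            out["simulate"] = True
            out.update(dataclasses.asdict(self.simulate))
        return out

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineBundle:
    config: PipelineConfig
    presence: PresenceData
    regions: pd.DataFrame
    lookup: AdminLookup
    phylo_index: PhyloIndex | None
    pair_table: pd.DataFrame
    distances: DistanceMatrixSet
    decay_fits: pd.DataFrame
    mrm_results: pd.DataFrame
    slope_contrasts: pd.DataFrame
    region_summary: pd.DataFrame
    region_regressions: pd.DataFrame
    manifest: dict
    truth: object | None = None


def load_inputs(config: PipelineConfig):
    """Load (or simulate) all raw inputs for the pipeline."""
    if config.simulate is not None:
        dataset = generate_dataset(config.simulate, with_tree=config.with_phylogeny)
        inputs_dir = Path(config.outdir) / "inputs"
        dataset.write(inputs_dir) if config.with_phylogeny else _write_no_tree(
            dataset, inputs_dir
        )
        return (
            dataset.presence,
            dataset.world.regions,
            dataset.world.lookup,
            dataset.tree,
            dataset.world.climate,
            dataset.truth,
        )
    paths = {k: Path(v) for k, v in config.inputs.items()}
    records = read_checklists(paths["checklists"])
    cleaned, report = clean_checklists(records)
    if report.excluded:
        logger.info("cleaning excluded %d records: %s", len(report.excluded), report.counts_by_rule())
    regions = read_regions(paths["regions"])
    presence = build_presence(cleaned, regions)
    lookup = AdminLookup.from_tables(
        regions,
        read_admin_pairs(paths["colonial_ties"]),
        read_admin_pairs(paths["dependencies"]),
    )
    climate = pd.read_csv(paths["climate"])
    tree = None
    if config.with_phylogeny:
        tree = read_tree(paths["tree"])
        tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        missing = [s for s in presence.species if s not in tips]
        if missing:
            tree, graft_report = graft_missing_species(tree, missing)
            if graft_report.unplaceable:
                logger.warning(
                    "%d species unplaceable in tree", len(graft_report.unplaceable)
                )
    return presence, regions, lookup, tree, climate, None


def _write_no_tree(dataset: SyntheticDataset, outdir: Path) -> None:
    tree = dataset.tree
    dataset.tree = None
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.world.regions.to_csv(outdir / "regions.csv", index=False)
    dataset.presence.write_csv(outdir / "checklists.csv")
    dataset.world.climate.to_csv(outdir / "climate.csv", index=False)
    dataset.tree = tree


def admin_category_matrix(regions: pd.DataFrame, lookup: AdminLookup) -> np.ndarray:
    """Region-pair matrix of administrative categories (strings)."""
    ids = [str(r) for r in regions["region_id"]]
    n = len(ids)
    cats = np.full((n, n), ADMIN_NONE, dtype=object)
    same, dep = admin_dummy_matrices(regions, lookup)
    cats[same.values == 1] = ADMIN_SAME_COUNTRY
    cats[dep.values == 1] = ADMIN_DEPENDENCY
    return cats


def run_pipeline(config: PipelineConfig) -> PipelineBundle:
    """Execute every stage and write all tabular outputs plus a manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    presence, regions, lookup, tree, climate, truth = load_inputs(config)
    phylo_index = PhyloIndex(tree) if tree is not None else None

    distances = build_distance_matrices(regions, climate)
    for name, matrix in distances.as_dict().items():
        matrix.write_csv(outdir / f"distance_{name}.csv")

    pair_table = pairwise_table(
        presence,
        tree=phylo_index,
        scenario=config.scenario,
        index=config.index,
        offset=config.offset,
    )
    pair_table.to_csv(outdir / "pair_table.csv", index=False)

    fits = [decay_curves(pair_table, distances.geographic, predictor="geographic")]
    fits.append(decay_curves(pair_table, distances.climatic, predictor="climatic"))
    decay_fits = pd.concat(fits, ignore_index=True)
    decay_fits.to_csv(outdir / "decay_fits.csv", index=False)

    same, dep = admin_dummy_matrices(regions, lookup)
    geo_km3 = distances.geographic.values / 1000.0  # per 1000 km for readable slopes
    predictors = {
        "geographic": geo_km3,
        "climatic": distances.climatic.values,
        "same_country": same.values,
        "dependency": dep.values,
    }
    mrm_frames = []
    responses = ["h_tax"] + (["h_phyl"] if phylo_index is not None else [])
    for k, column in enumerate(responses):
        H = h_matrix(pair_table, presence.regions, column)
        result = mrm_fit(
            H,
            predictors,
            n_perm=config.n_perm,
            seed=config.seed + k,
            interactions=MRM_INTERACTIONS,
        )
        frame = result.to_frame()
        frame.insert(0, "response", column)
        mrm_frames.append(frame)
    mrm_results = pd.concat(mrm_frames, ignore_index=True)
    mrm_results.to_csv(outdir / "mrm_results.csv", index=False)

    categories = admin_category_matrix(regions, lookup)
    contrast_frames = []
    for k, column in enumerate(responses):
        H = h_matrix(pair_table, presence.regions, column)
        try:
            contrast = slope_contrast(
                H, geo_km3, categories, n_perm=config.n_perm, seed=config.seed + 10 + k
            )
            frame = contrast.to_frame()
            frame.insert(0, "response", column)
            contrast_frames.append(frame)
        except FloraHomError as exc:
            logger.warning("slope contrast skipped for %s: %s", column, exc)
    slope_contrasts = (
        pd.concat(contrast_frames, ignore_index=True)
        if contrast_frames
        else pd.DataFrame()
    )
    slope_contrasts.to_csv(outdir / "slope_contrasts.csv", index=False)

    if phylo_index is not None:
        summary = build_region_summary(presence, phylo_index, pair_table, regions)
    else:
        from .regions import donor_scores, endemic_proportions, mean_homogenization

        mean_h = mean_homogenization(pair_table).set_index("region_id")
        meta = regions.set_index(regions["region_id"].astype(str))
        summary = pd.DataFrame(
            {
                "region_id": presence.regions,
                "mean_h_tax": [mean_h.loc[r, "mean_h_tax"] for r in presence.regions],
                "mean_h_phyl": [mean_h.loc[r, "mean_h_phyl"] for r in presence.regions],
                "native_richness": presence.native.sum(axis=1),
                "naturalized_richness": presence.naturalized.sum(axis=1),
                "endemic_proportion": endemic_proportions(presence).values,
                "donor_score": donor_scores(presence).values,
                "area_km2": [float(meta.loc[r, "area_km2"]) for r in presence.regions],
                "is_island": [bool(meta.loc[r, "is_island"]) for r in presence.regions],
            }
        )
    summary.to_csv(outdir / "region_summary.csv", index=False)

    coords = regions[["centroid_lon", "centroid_lat"]].to_numpy(float)
    regression_frames = []
    for response in ["mean_h_tax"] + (
        ["mean_h_phyl"] if phylo_index is not None else []
    ):
        try:
            result = region_regression(summary, coords, response=response)
            frame = result.table.copy()
            frame.insert(0, "response", response)
            frame["moran_i_residuals"] = result.moran_i_residuals
            regression_frames.append(frame)
        except FloraHomError as exc:
            logger.warning("region regression skipped for %s: %s", response, exc)
    region_regressions = (
        pd.concat(regression_frames, ignore_index=True)
        if regression_frames
        else pd.DataFrame()
    )
    region_regressions.to_csv(outdir / "region_regressions.csv", index=False)

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_regions": presence.n_regions,
        "n_species": presence.n_species,
        "n_pairs": len(pair_table),
        "n_flagged_pairs": int((pair_table["flag"] != "").sum()),
        "row_counts": {
            "pair_table": len(pair_table),
            "decay_fits": len(decay_fits),
            "mrm_results": len(mrm_results),
            "region_summary": len(summary),
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return PipelineBundle(
        config=config,
        presence=presence,
        regions=regions,
        lookup=lookup,
        phylo_index=phylo_index,
        pair_table=pair_table,
        distances=distances,
        decay_fits=decay_fits,
        mrm_results=mrm_results,
        slope_contrasts=slope_contrasts,
        region_summary=summary,
        region_regressions=region_regressions,
        manifest=manifest,
        truth=truth,
    )


def percent(count: int, total: int, decimals: int = 1) -> float:
    """Share of pairs as a percentage, rounded for reporting."""
    if total <= 0:
        raise DomainError("total must be positive")
    return round(100.0 * count / total, decimals)


def percent_change_from_h(h) -> np.ndarray:
    """Back-transform H to a percentage change in similarity: 100*(exp(H)-1)."""
    return 100.0 * (np.exp(np.asarray(h, dtype=float)) - 1.0)


def report_summary(bundle: PipelineBundle) -> str:
    """Human-readable summary of a pipeline run."""
    table = bundle.pair_table
    usable = table[table["flag"] == ""]
    n = len(usable)
    if n == 0:
        raise FloraHomError("no usable pairs in bundle")
    lines = ["florahom run summary", "=" * 50]
    lines.append(f"regions: {bundle.presence.n_regions}; species: {bundle.presence.n_species}")
    lines.append(f"region pairs: {len(table)} ({len(table) - n} flagged)")
    for label, column in [("taxonomic", "h_tax"), ("phylogenetic", "h_phyl")]:
        h = usable[column].dropna()
        if h.empty:
            continue
        n_hom = int((h > 0).sum())
        n_diff = int((h < 0).sum())
        med = float(np.median(percent_change_from_h(h)))
        lines.append(
            f"{label}: homogenized pairs {n_hom}/{len(h)} ({percent(n_hom, len(h))}%), "
            f"differentiated {n_diff} ({percent(n_diff, len(h))}%), "
            f"median change in similarity {med:+.1f}%"
        )
    geo = bundle.decay_fits[bundle.decay_fits["predictor"] == "geographic"]
    for _, row in geo.iterrows():
        lines.append(
            f"halving distance ({row.similarity_type}, {row.variant}): "
            f"{row.halving_distance:.0f} km"
        )
    if not bundle.mrm_results.empty:
        lines.append("-" * 50)
        lines.append("MRM coefficients (permutation p):")
        for _, row in bundle.mrm_results.iterrows():
            if row["term"] == "intercept":
                continue
            lines.append(
                f"  {row['response']} ~ {row['term']}: {row['coefficient']:+.4f} "
                f"(p={row['p_perm']:.3f})"
            )
    top = hotspot_ranking(bundle.region_summary).head(10)
    lines.append("-" * 50)
    lines.append("top homogenization hotspots (mean taxonomic H):")
    for _, row in top.iterrows():
        lines.append(f"  {row.region_id}: {row.mean_h_tax:+.3f}")
    return "\n".join(lines)
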