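"""Reading, validation and cleaning of species checklists and region metadata.

Checklists are long-format tables of (species, region_id, status) records with
status ``native`` or ``naturalized``.  Cleaning collapses infraspecific taxa to
the binomial, removes hybrids, and resolves conflicting native/naturalized
status.  The cleaned records are assembled into a :class:`PresenceData`
structure: paired region-by-species boolean matrices for the native and the
naturalized flora.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DomainError,
    EmptyInputError,
    FormatError,
    MissingReferenceError,
)

logger = logging.getLogger(__name__)

VALID_STATUSES = ("native", "naturalized")

ADMIN_SAME_COUNTRY = "same_country"
ADMIN_DEPENDENCY = "dependency"
ADMIN_NONE = "none"

_HYBRID_TOKENS = {"x", "×"}  # infix " x " or the multiplication sign


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChecklistRecord:
    species: str
    region_id: str
    status: str


@dataclass
class CleaningRules:
    """Switches controlling :func:`clean_checklists`.

    ``global_conflict_exclusion`` drops a species from *every* region when it
    has a native/naturalized conflict anywhere; the default only drops the
    conflicting (species, region) records.
    """

    collapse_infraspecific: bool = True
    exclude_hybrids: bool = True
    global_conflict_exclusion: bool = False


@dataclass
class ExclusionReport:
    """Every record excluded by cleaning, with the rule that removed it."""

    excluded: list[tuple[ChecklistRecord, str]] = field(default_factory=list)
    n_duplicates_collapsed: int = 0

    def counts_by_rule(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, rule in self.excluded:
            out[rule] = out.get(rule, 0) + 1
        return out


def normalize_name(name: str) -> str:
    """Canonicalize whitespace and case of a taxon name.

    Genus is capitalized, remaining tokens lower-cased (the hybrid sign is
    preserved).  No synonym resolution is attempted.
    """
    tokens = name.strip().split()
    if not tokens:
        return ""
    head = tokens[0].capitalize()
    rest = [t if t == "×" else t.lower() for t in tokens[1:]]
    return " ".join([head, *rest])


def is_hybrid_name(name: str) -> bool:
    """Heuristic hybrid detection: multiplication sign, infix " x ", or "hybrid"."""
    if "×" in name:
        return True
    lowered = name.lower()
    if "hybrid" in lowered:
        return True
    tokens = lowered.split()
    return any(t in _HYBRID_TOKENS for t in tokens[1:])


def collapse_to_binomial(name: str) -> str:
    """Drop infraspecific epithets, keeping genus + specific epithet."""
    tokens = name.split()
    return " ".join(tokens[:2])


def read_checklists(path: str | Path) -> list[ChecklistRecord]:
    """Read a checklist CSV/TSV with columns species, region_id, status.

    Duplicate identical rows are collapsed (set semantics) with the count
    logged.  Unknown status values are rejected with the offending row number.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        frame = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"checklist file {path} is empty") from exc
    missing = {"species", "region_id", "status"} - set(frame.columns)
    if missing:
        raise FormatError(
            f"checklist file {path} lacks required column(s): {sorted(missing)}"
        )
    if frame.empty:
        raise EmptyInputError(f"checklist file {path} contains no records")
    bad = frame.loc[~frame["status"].isin(VALID_STATUSES)]
    if not bad.empty:
        row = bad.index[0] + 2  # header + 1-based
        raise FormatError(
            f"invalid status {bad['status'].iloc[0]!r} at {path}:{row}; "
            f"expected one of {VALID_STATUSES}"
        )
    records = [
        ChecklistRecord(species=s, region_id=r, status=st)
        for s, r, st in frame[["species", "region_id", "status"]].itertuples(index=False)
    ]
    unique = list(dict.fromkeys(records))
    n_dup = len(records) - len(unique)
    if n_dup:
        logger.info("collapsed %d duplicate checklist rows from %s", n_dup, path)
    return unique


def write_checklists(records: Iterable[ChecklistRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(r.species, r.region_id, r.status) for r in records],
        columns=["species", "region_id", "status"],
    )
    frame.to_csv(path, index=False)


def clean_checklists(
    records: Sequence[ChecklistRecord],
    rules: CleaningRules | None = None,
) -> tuple[list[ChecklistRecord], ExclusionReport]:
    """Apply name and status cleaning rules.

    Infraspecific taxa are collapsed to the binomial, hybrids removed, and any
    (species, region) flagged both native and naturalized has both records
    dropped (conflict).  Idempotent: cleaning a cleaned list is a no-op.
    """
    rules = rules or CleaningRules()
    report = ExclusionReport()

    staged: list[ChecklistRecord] = []
    for rec in records:
        name = normalize_name(rec.species)
        if rules.exclude_hybrids and is_hybrid_name(name):
            report.excluded.append((rec, "hybrid"))
            continue
        if rules.collapse_infraspecific:
            name = collapse_to_binomial(name)
        if len(name.split()) != 2:
            report.excluded.append((rec, "not_binomial"))
            continue
        staged.append(ChecklistRecord(name, rec.region_id, rec.status))

    deduped = list(dict.fromkeys(staged))
    report.n_duplicates_collapsed = len(staged) - len(deduped)

    by_pair: dict[tuple[str, str], set[str]] = {}
    for rec in deduped:
        by_pair.setdefault((rec.species, rec.region_id), set()).add(rec.status)
    conflict_pairs = {k for k, v in by_pair.items() if len(v) > 1}
    conflict_species = {s for s, _ in conflict_pairs}

    cleaned: list[ChecklistRecord] = []
    for rec in deduped:
        if rules.global_conflict_exclusion and rec.species in conflict_species:
            report.excluded.append((rec, "status_conflict"))
        elif (rec.species, rec.region_id) in conflict_pairs:
            report.excluded.append((rec, "status_conflict"))
        else:
            cleaned.append(rec)
    return cleaned, report


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

REGION_COLUMNS = [
    "region_id",
    "name",
    "country_code",
    "centroid_lon",
    "centroid_lat",
    "area_km2",
    "is_island",
]


def read_regions(path: str | Path) -> pd.DataFrame:
    """Read and validate the region registry CSV."""
    frame = pd.read_csv(path)
    missing = set(REGION_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"region registry lacks column(s): {sorted(missing)}")
    return validate_regions(frame)


def validate_regions(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    frame["region_id"] = frame["region_id"].astype(str)
    if frame["region_id"].duplicated().any():
        dup = frame.loc[frame["region_id"].duplicated(), "region_id"].iloc[0]
        raise FormatError(f"duplicate region_id {dup!r} in region registry")
    lon = frame["centroid_lon"].to_numpy(float)
    lat = frame["centroid_lat"].to_numpy(float)
    if np.any(np.abs(lon) > 180) or np.any(np.abs(lat) > 90):
        raise DomainError("region centroid coordinates out of bounds")
    if np.any(frame["area_km2"].to_numpy(float) <= 0):
        raise DomainError("region areas must be positive")
    frame["is_island"] = frame["is_island"].astype(bool)
    return frame.reset_index(drop=True)


# ---------------------------------------------------------------------------
# administrative relationships
# ---------------------------------------------------------------------------


@dataclass
class AdminLookup:
    """Country membership plus colonial-tie / dependency pair sets.

    Pairs are unordered country-code pairs.  ``colonial_ties`` holds empire
    member <-> member and colonizer <-> colony pairs; ``dependencies`` holds
    current dependent-territory relations.
    """

    region_to_country: dict[str, str]
    colonial_ties: set[frozenset] = field(default_factory=set)
    dependencies: set[frozenset] = field(default_factory=set)

    @classmethod
    def from_tables(
        cls,
        regions: pd.DataFrame,
        colonial_ties: pd.DataFrame | None = None,
        dependencies: pd.DataFrame | None = None,
    ) -> "AdminLookup":
        r2c = dict(zip(regions["region_id"].astype(str), regions["country_code"].astype(str)))
        known = set(r2c.values())

        def _pairs(frame: pd.DataFrame | None, what: str) -> set[frozenset]:
            if frame is None or frame.empty:
                return set()
            out = set()
            for a, b in frame[["country_a", "country_b"]].itertuples(index=False):
                a, b = str(a), str(b)
                unknown = {a, b} - known
                if unknown:
                    raise MissingReferenceError(
                        f"{what} table references unknown country {sorted(unknown)}"
                    )
                if a != b:
                    out.add(frozenset((a, b)))
            return out

        return cls(
            region_to_country=r2c,
            colonial_ties=_pairs(colonial_ties, "colonial_ties"),
            dependencies=_pairs(dependencies, "dependencies"),
        )

    def linked_countries(self, country_a: str, country_b: str) -> bool:
        """True if the two countries have a direct or shared-controller tie."""
        if country_a == country_b:
            return False
        pair = frozenset((country_a, country_b))
        ties = self.colonial_ties | self.dependencies
        if pair in ties:
            return True
        # two territories sharing the same controlling country
        neigh_a = {next(iter(p - {country_a})) for p in ties if country_a in p}
        neigh_b = {next(iter(p - {country_b})) for p in ties if country_b in p}
        return bool(neigh_a & neigh_b)


def classify_admin_relation(region_a: str, region_b: str, lookup: AdminLookup) -> str:
    """Classify a region pair: same_country, dependency, or none (symmetric)."""
    try:
        ca = lookup.region_to_country[region_a]
        cb = lookup.region_to_country[region_b]
    except KeyError as exc:
        raise MissingReferenceError(f"unknown region {exc.args[0]!r}") from exc
    if ca == cb:
        return ADMIN_SAME_COUNTRY
    if lookup.linked_countries(ca, cb):
        return ADMIN_DEPENDENCY
    return ADMIN_NONE


# ---------------------------------------------------------------------------
# presence structures
# ---------------------------------------------------------------------------


@dataclass
class PresenceData:
    """Aligned region-by-species boolean matrices for native and naturalized floras."""

    regions: list[str]
    species: list[str]
    native: np.ndarray  # bool, shape (n_regions, n_species)
    naturalized: np.ndarray  # bool, same shape

    def __post_init__(self) -> None:
        self.native = np.asarray(self.native, dtype=bool)
        self.naturalized = np.asarray(self.naturalized, dtype=bool)
        shape = (len(self.regions), len(self.species))
        if self.native.shape != shape or self.naturalized.shape != shape:
            raise FormatError("presence matrices do not match region/species lists")
        if np.any(self.native & self.naturalized):
            raise FormatError(
                "a species is flagged both native and naturalized in the same "
                "region; clean the checklists first"
            )

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def region_index(self, region_id: str) -> int:
        try:
            return self.regions.index(region_id)
        except ValueError as exc:
            raise MissingReferenceError(f"unknown region {region_id!r}") from exc

    def native_set(self, region_id: str) -> set:
        i = self.region_index(region_id)
        return {self.species[j] for j in np.flatnonzero(self.native[i])}

    def naturalized_set(self, region_id: str) -> set:
        i = self.region_index(region_id)
        return {self.species[j] for j in np.flatnonzero(self.naturalized[i])}

    def combined_set(self, region_id: str) -> set:
        return self.native_set(region_id) | self.naturalized_set(region_id)

    def to_records(self) -> list[ChecklistRecord]:
        out = []
        for status, mat in (("native", self.native), ("naturalized", self.naturalized)):
            rows, cols = np.nonzero(mat)
            out.extend(
                ChecklistRecord(self.species[j], self.regions[i], status)
                for i, j in zip(rows.tolist(), cols.tolist())
            )
        return out

    def write_csv(self, path: str | Path) -> None:
        write_checklists(self.to_records(), path)


def build_presence(
    records: Sequence[ChecklistRecord],
    regions: pd.DataFrame,
    require_native: bool = True,
) -> PresenceData:
    """Assemble cleaned records into aligned boolean presence matrices.

    Region order follows the registry; species are sorted.  Species with zero
    occurrences are dropped.  Every region must retain at least one native
    species.
    """
    if not records:
        raise EmptyInputError("no checklist records to assemble")
    region_ids = [str(r) for r in regions["region_id"]]
    region_pos = {r: i for i, r in enumerate(region_ids)}
    unknown = {r.region_id for r in records} - set(region_pos)
    if unknown:
        raise MissingReferenceError(
            f"checklist references region(s) absent from registry: {sorted(unknown)[:5]}"
        )
    species = sorted({r.species for r in records})
    species_pos = {s: j for j, s in enumerate(species)}
    native = np.zeros((len(region_ids), len(species)), dtype=bool)
    naturalized = np.zeros_like(native)
    for rec in records:
        i, j = region_pos[rec.region_id], species_pos[rec.species]
        (native if rec.status == "native" else naturalized)[i, j] = True
    if np.any(native & naturalized):
        raise FormatError(
            "conflicting native/naturalized records present; run clean_checklists"
        )
    if require_native:
        lacking = [r for i, r in enumerate(region_ids) if not native[i].any()]
        if lacking:
            raise EmptyInputError(
                f"region lacks native flora: {lacking[:5]}"
            )
    keep = (native | naturalized).any(axis=0)
    return PresenceData(
        regions=region_ids,
        species=[s for s, k in zip(species, keep) if k],
        native=native[:, keep],
        naturalized=naturalized[:, keep],
    )


def read_admin_pairs(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str)
    missing = {"country_a", "country_b"} - set(frame.columns)
    if missing:
        raise FormatError(f"admin pair table lacks column(s): {sorted(missing)}")
    return frame
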