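"""Taxonomic and phylogenetic similarity of regional floras and the
homogenization index.

Taxonomic similarity uses the Simpson index

    SimTax = 1 - min(b, c) / (a + min(b, c))

where ``a`` is the number of species shared by the two regions and ``b``,
``c`` the numbers unique to each; the Sorensen index ``2a / (2a + b + c)`` is
available as an alternative that is additionally sensitive to nestedness.
The phylogenetic analogues replace species counts by summed branch lengths
(A, B, C) of the rooted subtrees spanned by each flora.

The homogenization index for a region pair is the log-response ratio

    H = ln((Sim_combined + eps) / (Sim_native + eps)),   eps = 0.001,

where the combined flora adds the naturalized species to the native ones.
Positive H means the naturalizations made the two floras more similar
(homogenization), negative H less similar (differentiation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal

import dendropy
import numpy as np
import pandas as pd

from .checklists import PresenceData
from .exceptions import (
    DomainError,
    EmptyInputError,
    MissingReferenceError,
    UndefinedSimilarityError,
)
from .phylo import PhyloIndex

logger = logging.getLogger(__name__)

DEFAULT_OFFSET = 0.001

Scenario = Literal["all", "native_to_one", "non_native_to_both"]
IndexName = Literal["simpson", "sorensen"]

PAIR_TABLE_COLUMNS = [
    "region_a",
    "region_b",
    "sim_tax_native",
    "sim_tax_combined",
    "sim_phyl_native",
    "sim_phyl_combined",
    "h_tax",
    "h_phyl",
    "scenario",
    "index",
    "flag",
]


@dataclass(frozen=True)
class TaxonomicOverlap:
    a: int  # shared species
    b: int  # only in first
    c: int  # only in second


@dataclass(frozen=True)
class BranchOverlap:
    A: float  # branch length spanned by both floras
    B: float  # spanned only by first
    C: float  # spanned only by second


def taxonomic_overlap(flora_a: set, flora_b: set) -> TaxonomicOverlap:
    shared = len(flora_a & flora_b)
    return TaxonomicOverlap(shared, len(flora_a) - shared, len(flora_b) - shared)


def _check_nonempty(flora_a, flora_b) -> None:
    if not flora_a or not flora_b:
        raise UndefinedSimilarityError("similarity undefined for an empty flora")


def simpson_tax(flora_a: set, flora_b: set) -> float:
    _check_nonempty(flora_a, flora_b)
    ov = taxonomic_overlap(flora_a, flora_b)
    m = min(ov.b, ov.c)
    return 1.0 - m / (ov.a + m) if (ov.a + m) else 1.0


def sorensen_tax(flora_a: set, flora_b: set) -> float:
    _check_nonempty(flora_a, flora_b)
    ov = taxonomic_overlap(flora_a, flora_b)
    return 2 * ov.a / (2 * ov.a + ov.b + ov.c)


def branch_overlap(
    tree: dendropy.Tree | PhyloIndex, flora_a: Iterable[str], flora_b: Iterable[str]
) -> BranchOverlap:
    """Shared and unique branch lengths of the subtrees spanned by two floras."""
    index = tree if isinstance(tree, PhyloIndex) else PhyloIndex(tree)
    sa = index.spans(index.flora_mask(flora_a))
    sb = index.spans(index.flora_mask(flora_b))
    return BranchOverlap(
        A=float(index.lengths[sa & sb].sum()),
        B=float(index.lengths[sa & ~sb].sum()),
        C=float(index.lengths[sb & ~sa].sum()),
    )


def simpson_phylo(tree, flora_a, flora_b) -> float:
    flora_a, flora_b = set(flora_a), set(flora_b)
    _check_nonempty(flora_a, flora_b)
    ov = branch_overlap(tree, flora_a, flora_b)
    m = min(ov.B, ov.C)
    if ov.A + m == 0:
        raise UndefinedSimilarityError("no branch length spanned by either flora")
    return 1.0 - m / (ov.A + m)


def sorensen_phylo(tree, flora_a, flora_b) -> float:
    flora_a, flora_b = set(flora_a), set(flora_b)
    _check_nonempty(flora_a, flora_b)
    ov = branch_overlap(tree, flora_a, flora_b)
    denom = 2 * ov.A + ov.B + ov.C
    if denom == 0:
        raise UndefinedSimilarityError("no branch length spanned by either flora")
    return 2 * ov.A / denom


def homogenization_index(
    sim_combined: float, sim_native: float, offset: float = DEFAULT_OFFSET
) -> float:
    """Log-response ratio of combined vs native similarity, offset-stabilized."""
    for value in (sim_combined, sim_native):
        if not (0.0 <= value <= 1.0):
            raise DomainError(f"similarity {value} outside [0, 1]")
    return math.log((sim_combined + offset) / (sim_native + offset))


def scenario_naturalized_sets(
    native_a: set,
    native_b: set,
    nat_a: set,
    nat_b: set,
    scenario: Scenario = "all",
) -> tuple[set, set]:
    """Restrict each region's naturalized set to a naturalization scenario.

    ``native_to_one`` keeps naturalized species that are native to the other
    region of the pair (these can only increase similarity);
    ``non_native_to_both`` keeps species native to neither region (these can
    increase or decrease similarity depending on whether they arrive in both
    regions or only one).
    """
    if scenario == "all":
        return set(nat_a), set(nat_b)
    if scenario == "native_to_one":
        return nat_a & native_b, nat_b & native_a
    if scenario == "non_native_to_both":
        return nat_a - native_b, nat_b - native_a
    raise DomainError(f"unknown scenario {scenario!r}")


def remove_widely_naturalized(
    presence: PresenceData, decile: float = 0.1, end: Literal["most", "least"] = "most"
) -> PresenceData:
    """Drop the most (or least) widely naturalized species from the
    naturalized matrix only; the native matrix is untouched.

    Species are ranked by the number of regions in which they are
    naturalized; ties are broken by species-name order.  ``ceil(decile * S)``
    species are removed, where S counts species naturalized anywhere.
    """
    if not 0 < decile < 1:
        raise DomainError("decile must lie strictly between 0 and 1")
    if end not in ("most", "least"):
        raise DomainError(f"end must be 'most' or 'least', got {end!r}")
    counts = presence.naturalized.sum(axis=0)
    candidates = [
        (int(counts[j]), presence.species[j], j) for j in np.flatnonzero(counts > 0)
    ]
    if not candidates:
        raise EmptyInputError("no naturalized species to remove")
    k = math.ceil(decile * len(candidates))
    reverse = end == "most"
    # sort by count (desc for "most"), name ascending as tie break
    candidates.sort(key=lambda t: ((-t[0] if reverse else t[0]), t[1]))
    drop = [j for _, _, j in candidates[:k]]
    naturalized = presence.naturalized.copy()
    naturalized[:, drop] = False
    logger.info("removed %d %s widely naturalized species", k, end)
    return PresenceData(
        regions=list(presence.regions),
        species=list(presence.species),
        native=presence.native.copy(),
        naturalized=naturalized,
    )


# ---------------------------------------------------------------------------
# pairwise tables
# ---------------------------------------------------------------------------


def _sim_from_counts(a, b, c, index: IndexName):
    """Vectorized similarity; returns (values, undefined_mask)."""
    a = a.astype(float)
    if index == "simpson":
        m = np.minimum(b, c)
        denom = a + m
    else:
        m = None
        denom = 2 * a + b + c
    undefined = denom <= 0
    safe = np.where(undefined, 1.0, denom)
    if index == "simpson":
        values = 1.0 - np.minimum(b, c) / safe
    else:
        values = 2 * a / safe
    return values, undefined


def _pairwise_counts(P: np.ndarray):
    Pf = P.astype(np.float32)
    a = Pf @ Pf.T
    rich = Pf.sum(axis=1)
    return a, rich[:, None] - a, rich[None, :] - a


def _pairwise_branch(index: PhyloIndex, P: np.ndarray):
    spanned = index.spanned_matrix(P)
    W = spanned * index.lengths[None, :]
    A = W @ spanned.T.astype(float)
    totals = W.sum(axis=1)
    return A, totals[:, None] - A, totals[None, :] - A


def pairwise_table(
    presence: PresenceData,
    tree: dendropy.Tree | PhyloIndex | None = None,
    scenario: Scenario = "all",
    index: IndexName = "simpson",
    offset: float = DEFAULT_OFFSET,
) -> pd.DataFrame:
    """Similarities and homogenization indices for every unordered region pair.

    One row per pair (n*(n-1)/2 rows).  Pairs whose similarity is undefined
    (an empty effective flora) are flagged rather than aborting the run and
    carry NaN similarities; downstream fits exclude them.
    """
    if presence.n_regions < 2:
        raise EmptyInputError("need at least two regions for a pairwise table")
    if index not in ("simpson", "sorensen"):
        raise DomainError(f"unknown similarity index {index!r}")
    phylo_index = None
    if tree is not None:
        phylo_index = (
            tree if isinstance(tree, PhyloIndex) else PhyloIndex(tree)
        )
        # align species universe
        missing = set(presence.species) - set(phylo_index.species)
        if missing:
            raise MissingReferenceError(
                f"species absent from tree: {sorted(missing)[:5]}"
            )

    n = presence.n_regions
    iu = np.triu_indices(n, 1)

    native = presence.native
    if scenario == "all":
        combined = native | presence.naturalized
        sim_nat, und_n = _tri(_sim_from_counts(*_pairwise_counts(native), index), iu)
        sim_com, und_c = _tri(_sim_from_counts(*_pairwise_counts(combined), index), iu)
        if phylo_index is not None:
            cols = [phylo_index._col[s] for s in presence.species]
            Pn = _expand(native, cols, len(phylo_index.species))
            Pc = _expand(combined, cols, len(phylo_index.species))
            ps_nat, pund_n = _tri(
                _sim_from_branch(_pairwise_branch(phylo_index, Pn), index), iu
            )
            ps_com, pund_c = _tri(
                _sim_from_branch(_pairwise_branch(phylo_index, Pc), index), iu
            )
        else:
            ps_nat = ps_com = np.full(iu[0].size, np.nan)
            pund_n = pund_c = np.zeros(iu[0].size, dtype=bool)
    else:
        sim_nat, sim_com, ps_nat, ps_com, und_n, und_c, pund_n, pund_c = (
            _pairwise_scenario(presence, phylo_index, scenario, index, iu)
        )

    undefined = und_n | und_c | pund_n | pund_c
    sim_nat = np.where(und_n, np.nan, sim_nat)
    sim_com = np.where(und_c, np.nan, sim_com)
    ps_nat = np.where(pund_n, np.nan, ps_nat)
    ps_com = np.where(pund_c, np.nan, ps_com)

    with np.errstate(invalid="ignore"):
        h_tax = np.log((sim_com + offset) / (sim_nat + offset))
        h_phyl = np.log((ps_com + offset) / (ps_nat + offset))

    regions = np.asarray(presence.regions)
    table = pd.DataFrame(
        {
            "region_a": regions[iu[0]],
            "region_b": regions[iu[1]],
            "sim_tax_native": sim_nat,
            "sim_tax_combined": sim_com,
            "sim_phyl_native": ps_nat,
            "sim_phyl_combined": ps_com,
            "h_tax": h_tax,
            "h_phyl": h_phyl,
            "scenario": scenario,
            "index": index,
            "flag": np.where(undefined, "undefined_similarity", ""),
        }
    )
    n_flagged = int(undefined.sum())
    if n_flagged:
        logger.warning("%d region pairs flagged with undefined similarity", n_flagged)
    return table


def _expand(P: np.ndarray, cols, width: int) -> np.ndarray:
    out = np.zeros((P.shape[0], width), dtype=bool)
    out[:, cols] = P
    return out


def _sim_from_branch(abc, index: IndexName):
    A, B, C = abc
    if index == "simpson":
        m = np.minimum(B, C)
        denom = A + m
        undefined = denom <= 0
        values = 1.0 - np.minimum(B, C) / np.where(undefined, 1.0, denom)
    else:
        denom = 2 * A + B + C
        undefined = denom <= 0
        values = 2 * A / np.where(undefined, 1.0, denom)
    return values, undefined


def _tri(sim_und, iu):
    values, undefined = sim_und
    return values[iu], undefined[iu]


def _pairwise_scenario(presence, phylo_index, scenario, index, iu):
    """Per-pair loop for the pair-dependent naturalization scenarios."""
    n = presence.n_regions
    native = presence.native
    nat = presence.naturalized
    n_pairs = iu[0].size
    sim_nat = np.empty(n_pairs)
    sim_com = np.empty(n_pairs)
    ps_nat = np.full(n_pairs, np.nan)
    ps_com = np.full(n_pairs, np.nan)
    und = np.zeros((4, n_pairs), dtype=bool)

    if phylo_index is not None:
        cols = [phylo_index._col[s] for s in presence.species]
        width = len(phylo_index.species)
        native_masks = _expand(native, cols, width)
        spans_native = [phylo_index.spans(native_masks[i]) for i in range(n)]
        lengths = phylo_index.lengths

    for k, (i, j) in enumerate(zip(iu[0], iu[1])):
        na, nb = native[i], native[j]
        if scenario == "native_to_one":
            fa, fb = nat[i] & nb, nat[j] & na
        else:  # non_native_to_both
            fa, fb = nat[i] & ~nb, nat[j] & ~na
        ca, cb = na | fa, nb | fb

        sim_nat[k], und[0, k] = _set_sim(na, nb, index)
        sim_com[k], und[1, k] = _set_sim(ca, cb, index)

        if phylo_index is not None:
            sa, sb = spans_native[i], spans_native[j]
            ps_nat[k], und[2, k] = _branch_sim(lengths, sa, sb, index)
            sca = phylo_index.spans(_expand(ca[None, :], cols, width)[0])
            scb = phylo_index.spans(_expand(cb[None, :], cols, width)[0])
            ps_com[k], und[3, k] = _branch_sim(lengths, sca, scb, index)
    return sim_nat, sim_com, ps_nat, ps_com, und[0], und[1], und[2], und[3]


def _set_sim(row_a, row_b, index):
    a = int((row_a & row_b).sum())
    b = int(row_a.sum()) - a
    c = int(row_b.sum()) - a
    if index == "simpson":
        m = min(b, c)
        denom = a + m
        return (1.0 - m / denom if denom else np.nan), denom == 0
    denom = 2 * a + b + c
    return (2 * a / denom if denom else np.nan), denom == 0


def _branch_sim(lengths, sa, sb, index):
    A = float(lengths[sa & sb].sum())
    B = float(lengths[sa & ~sb].sum())
    C = float(lengths[sb & ~sa].sum())
    if index == "simpson":
        m = min(B, C)
        denom = A + m
        return (1.0 - m / denom if denom else np.nan), denom == 0
    denom = 2 * A + B + C
    return (2 * A / denom if denom else np.nan), denom == 0


def h_matrix(table: pd.DataFrame, regions: list[str], column: str = "h_tax") -> np.ndarray:
    """Symmetric matrix of H values from a pair table (NaN for flagged pairs)."""
    pos = {r: i for i, r in enumerate(regions)}
    n = len(regions)
    M = np.zeros((n, n))
    for ra, rb, h in table[["region_a", "region_b", column]].itertuples(index=False):
        i, j = pos[ra], pos[rb]
        M[i, j] = M[j, i] = h
    return M
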