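"""Presence–absence matrix of complex subunits and its conservation classes.

The census produces, for every chromatin-modifier complex subunit and every
species, a presence call. This module assembles those calls into the subunit
x species matrix (species in species-tree order) and classifies each subunit
row into one of the conservation categories used to summarize the panel:

* conserved in all species;
* specific to a single species;
* absent from all Aspergilli with a patchy pattern in the outgroup;
* present in all Aspergilli with a patchy pattern in the outgroup;
* present in all outgroup species with a patchy pattern in Aspergilli;
* patchy in both groups;
* anything else (e.g. absent everywhere) falls into a catch-all class.

Presence recovered by the genomic rescue search counts as presence (those
cells correct false absences) but is tracked as a distinct cell state so it
can be rendered separately.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from .census import Evidence, PresenceCall
from .io import ASPERGILLI, OUTGROUP, SpeciesCatalog


class CellState(enum.Enum):
    PRESENT = "1"
    ABSENT = "0"
    PRESENT_RESCUED = "R"

    @property
    def is_present(self) -> bool:
        return self is not CellState.ABSENT

    @classmethod
    def from_token(cls, token: str) -> "CellState":
        for state in cls:
            if state.value == token:
                return state
        raise ValueError(f"unknown matrix token {token!r}")


@dataclass(frozen=True)
class SubunitCatalog:
    """Ordered complexes, each an ordered subunit list, catalytic first."""

    complexes: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self):
        names = [s for _, subs in self.complexes for s in subs]
        if len(set(names)) != len(names):
            raise ValueError("subunit names must be unique across the catalog")
        if any(not subs for _, subs in self.complexes):
            raise ValueError("every complex must have at least one subunit")

    @property
    def subunits(self) -> list[str]:
        return [s for _, subs in self.complexes for s in subs]

    @property
    def n_complexes(self) -> int:
        return len(self.complexes)

    def complex_of(self, subunit: str) -> str:
        for name, subs in self.complexes:
            if subunit in subs:
                return name
        raise KeyError(subunit)


@dataclass(frozen=True)
class PapMatrix:
    """Subunit x species presence/absence matrix."""

    rows: tuple[str, ...]
    cols: tuple[str, ...]
    cells: Mapping[tuple[str, str], CellState]

    def __post_init__(self):
        missing = [
            (r, c) for r in self.rows for c in self.cols if (r, c) not in self.cells
        ]
        if missing:
            raise ValueError(f"unassigned cells, e.g. {missing[:3]}")

    def cell(self, row: str, col: str) -> CellState:
        return self.cells[(row, col)]

    def token(self, row: str, col: str) -> str:
        return self.cells[(row, col)].value

    def row_presence(self, row: str) -> dict[str, bool]:
        return {c: self.cells[(row, c)].is_present for c in self.cols}


class CategoryKind(enum.Enum):
    CONSERVED_ALL = "conserved_all"
    SPECIES_SPECIFIC = "species_specific"
    PAP_BOTH = "pap_both"
    OUTGROUP_PAP_ASP_ABSENT = "outgroup_pap_asp_absent"
    OUTGROUP_PAP_ASP_ALL = "outgroup_pap_asp_all"
    OUTGROUP_ALL_ASP_PAP = "outgroup_all_asp_pap"
    OTHER = "other"


@dataclass(frozen=True)
class SubunitCategory:
    kind: CategoryKind
    species: str | None = None  # set only for SPECIES_SPECIFIC


def build_pap_matrix(
    calls: Sequence[PresenceCall],
    catalog: SubunitCatalog,
    species: SpeciesCatalog,
) -> PapMatrix:
    """Assemble presence calls into a complete matrix.

    Pairs without a call default to ABSENT; rescue-tier evidence becomes the
    distinct PRESENT_RESCUED state. Conflicting duplicate calls are an error.
    """
    rows = tuple(catalog.subunits)
    cols = tuple(species.species_ids)
    row_set, col_set = set(rows), set(cols)
    cells: dict[tuple[str, str], CellState] = {
        (r, c): CellState.ABSENT for r in rows for c in cols
    }
    seen: dict[tuple[str, str], PresenceCall] = {}
    for call in calls:
        key = (call.family_or_subunit, call.species_id)
        if call.family_or_subunit not in row_set:
            raise KeyError(f"call references unknown subunit {call.family_or_subunit!r}")
        if call.species_id not in col_set:
            raise KeyError(f"call references unknown species {call.species_id!r}")
        if key in seen and seen[key] != call:
            raise ValueError(f"conflicting duplicate calls for {key}")
        seen[key] = call
        if not call.present:
            state = CellState.ABSENT
        elif call.evidence is Evidence.RESCUE:
            state = CellState.PRESENT_RESCUED
        else:
            state = CellState.PRESENT
        cells[key] = state
    return PapMatrix(rows, cols, cells)


def categorize_subunit(
    presence: Mapping[str, bool],
    species: SpeciesCatalog,
    exclude: Sequence[str] = (),
) -> SubunitCategory:
    """Classify one subunit row into its conservation category.

    ``presence`` maps species id to a boolean (rescued presence counts as
    present). Precedence: conserved-in-all, then single-species, then the
    three one-group-uniform patterns, then patchy-in-both; everything else
    (including absent-everywhere and all-of-one-group-only) is OTHER.
    """
    excluded = set(exclude)
    asp = [s for s in species.in_group(ASPERGILLI) if s not in excluded]
    out = [s for s in species.in_group(OUTGROUP) if s not in excluded]
    considered = asp + out
    missing = [s for s in considered if s not in presence]
    if missing:
        raise KeyError(f"row is missing species {missing[:3]}")
    present = [s for s in considered if presence[s]]
    n_asp = sum(1 for s in asp if presence[s])
    n_out = sum(1 for s in out if presence[s])

    if len(present) == len(considered):
        return SubunitCategory(CategoryKind.CONSERVED_ALL)
    if len(present) == 1:
        return SubunitCategory(CategoryKind.SPECIES_SPECIFIC, species=present[0])
    asp_all, asp_none = n_asp == len(asp), n_asp == 0
    out_all, out_none = n_out == len(out), n_out == 0
    out_mixed = not (out_all or out_none)
    asp_mixed = not (asp_all or asp_none)
    if asp_none and out_mixed:
        return SubunitCategory(CategoryKind.OUTGROUP_PAP_ASP_ABSENT)
    if asp_all and out_mixed:
        return SubunitCategory(CategoryKind.OUTGROUP_PAP_ASP_ALL)
    if out_all and asp_mixed:
        return SubunitCategory(CategoryKind.OUTGROUP_ALL_ASP_PAP)
    if asp_mixed and out_mixed:
        return SubunitCategory(CategoryKind.PAP_BOTH)
    return SubunitCategory(CategoryKind.OTHER)


def categorize_matrix(
    matrix: PapMatrix,
    species: SpeciesCatalog,
    exclude: Sequence[str] = (),
) -> dict[str, SubunitCategory]:
    return {
        row: categorize_subunit(matrix.row_presence(row), species, exclude)
        for row in matrix.rows
    }


def summarize_categories(
    matrix: PapMatrix,
    species: SpeciesCatalog,
    exclude: Sequence[str] = (),
) -> Counter:
    """Count subunit rows per conservation category (sums to the row count)."""
    counts: Counter = Counter()
    for cat in categorize_matrix(matrix, species, exclude).values():
        counts[cat.kind] += 1
    return counts


def species_specific_breakdown(
    matrix: PapMatrix,
    species: SpeciesCatalog,
    exclude: Sequence[str] = (),
) -> Counter:
    """Per-species counts of single-species subunits."""
    counts: Counter = Counter()
    for cat in categorize_matrix(matrix, species, exclude).values():
        if cat.kind is CategoryKind.SPECIES_SPECIFIC:
            counts[cat.species] += 1
    return counts


def order_matrix(matrix: PapMatrix, species: SpeciesCatalog) -> PapMatrix:
    """Permute columns to species-tree order (rows keep catalog order)."""
    order = species.species_ids
    unknown = set(matrix.cols) - set(order)
    if unknown:
        raise KeyError(f"matrix columns not in species catalog: {sorted(unknown)}")
    missing = set(order) - set(matrix.cols)
    if missing:
        raise KeyError(f"species missing from matrix: {sorted(missing)}")
    return PapMatrix(matrix.rows, tuple(order), dict(matrix.cells))


def plot_pap_heatmap(matrix: PapMatrix, species: SpeciesCatalog, path):
    """Render the matrix as a three-color heatmap (present/absent/rescued),
    species in tree order."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np
    from matplotlib.colors import ListedColormap

    ordered = order_matrix(matrix, species)
    code = {CellState.ABSENT: 0, CellState.PRESENT: 1, CellState.PRESENT_RESCUED: 2}
    data = np.array(
        [[code[ordered.cell(r, c)] for c in ordered.cols] for r in ordered.rows]
    )
    fig, ax = plt.subplots(
        figsize=(max(4, len(ordered.cols) * 0.12), max(3, len(ordered.rows) * 0.12))
    )
    cmap = ListedColormap(["#e8e8e8", "#2c5f8a", "#8a5a2c"])
    ax.imshow(data, aspect="auto", cmap=cmap, vmin=0, vmax=2, interpolation="none")
    ax.set_xticks(range(len(ordered.cols)))
    ax.set_xticklabels(ordered.cols, rotation=90, fontsize=3)
    ax.set_yticks(range(len(ordered.rows)))
    ax.set_yticklabels(ordered.rows, fontsize=3)
    fig.tight_layout()
    fig.savefig(path, dpi=200)
    plt.close(fig)
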