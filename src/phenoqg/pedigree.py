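"""Pedigree handling and the additive relationship matrix.

The study population is a clonally replicated crossing trial: founder trees
are crossed to produce full-sib families, family members (genotypes) are
clonally propagated, and each field tree (ramet) is a copy of exactly one
genotype.  Genetic effects are modelled at the genotype level, so relatedness
is summarised by the additive relationship matrix A among genotypes: twice
the kinship coefficient, with diagonal 1 + F (F the inbreeding coefficient).

A is built by the tabular method, processing individuals parents-first:

    A[i, i] = 1 + 0.5 * A[sire(i), dam(i)]
    A[i, j] = 0.5 * (A[j, sire(i)] + A[j, dam(i)])   for j earlier than i

with unknown-parent contributions equal to zero.  Founders are assumed
non-inbred and mutually unrelated (base-population assumption).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

UNKNOWN = None


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees or clone maps."""


def _norm(parent) -> str | None:
    """Map the CSV conventions for 'unknown parent' onto None."""
    if parent is None:
        return None
    if isinstance(parent, float) and np.isnan(parent):
        return None
    s = str(parent).strip()
    if s == "" or s.upper() in {"NA", "0", "UNKNOWN", "."}:
        return None
    return s


@dataclass(frozen=True)
class PedigreeRecord:
    genotype_id: str
    sire_id: str | None
    dam_id: str | None

    @property
    def is_founder(self) -> bool:
        return self.sire_id is None and self.dam_id is None


@dataclass
class Pedigree:
    """Topologically sorted pedigree: every record's parents precede it."""

    records: list[PedigreeRecord]
    genotype_index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.genotype_index = {r.genotype_id: i for i, r in enumerate(self.records)}

    @property
    def ids(self) -> list[str]:
        return [r.genotype_id for r in self.records]

    @property
    def founder_count(self) -> int:
        return sum(r.is_founder for r in self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class RelationshipMatrix:
    """Dense additive relationship matrix with its row/column id order."""

    values: np.ndarray
    ids: list[str]

    def submatrix(self, keep_ids) -> "RelationshipMatrix":
        idx = [self.ids.index(g) for g in keep_ids]
        return RelationshipMatrix(self.values[np.ix_(idx, idx)], list(keep_ids))

    def inverse(self) -> np.ndarray:
        # Dense direct solve; the genotype layer is small (~10^2), so
        # Henderson's sparse rules buy nothing here.
        return np.linalg.inv(self.values)


@dataclass
class CloneMap:
    """tree_id -> genotype_id mapping plus per-genotype ramet counts."""

    tree_to_genotype: dict[str, str]
    ramet_counts: pd.Series

    def __len__(self) -> int:
        return len(self.tree_to_genotype)


def build_pedigree(records) -> Pedigree:
    """Validate raw (genotype, sire, dam) triples and sort parents-first.

    Parameters
    ----------
    records : iterable of (genotype_id, sire_id, dam_id)
        Unknown parents as None, NaN or empty string.  Parents must be both
        known or both unknown: the crossing design has full crosses only, so
        a single known parent is a data error and is rejected loudly.
    """
    triples = [(str(g), _norm(s), _norm(d)) for g, s, d in records]
    if not triples:
        raise PedigreeError("empty pedigree")
    ids = [g for g, _, _ in triples]
    if len(set(ids)) != len(ids):
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        raise PedigreeError(f"duplicate genotype ids: {dupes}")
    known = set(ids)
    graph = nx.DiGraph()
    graph.add_nodes_from(ids)
    for g, s, d in triples:
        if (s is None) != (d is None):
            raise PedigreeError(f"{g}: one known and one unknown parent")
        for p in (s, d):
            if p is None:
                continue
            if p == g:
                raise PedigreeError(f"{g}: is its own parent")
            if p not in known:
                raise PedigreeError(f"{g}: unknown parent reference {p!r}")
            graph.add_edge(p, g)
    try:
        order = list(nx.lexicographical_topological_sort(graph))
    except nx.NetworkXUnfeasible:
        chain = [u for u, _ in nx.find_cycle(graph)]
        raise PedigreeError(f"pedigree cycle detected: {' -> '.join(chain)}")
    by_id = {g: PedigreeRecord(g, s, d) for g, s, d in triples}
    return Pedigree([by_id[g] for g in order])


def additive_relationship(pedigree: Pedigree) -> RelationshipMatrix:
    """Tabular-method additive relationship matrix over the pedigree order."""
    n = len(pedigree)
    idx = pedigree.genotype_index
    A = np.zeros((n, n))
    for i, rec in enumerate(pedigree.records):
        s = idx[rec.sire_id] if rec.sire_id is not None else None
        d = idx[rec.dam_id] if rec.dam_id is not None else None
        if s is not None and s >= i or d is not None and d >= i:
            raise PedigreeError("pedigree is not sorted parents-first")
        A[i, i] = 1.0 if s is None else 1.0 + 0.5 * A[s, d]
        for j in range(i):
            a = 0.0
            if s is not None:
                a = 0.5 * (A[j, s] + A[j, d])
            A[i, j] = A[j, i] = a
    return RelationshipMatrix(A, pedigree.ids)


def clone_incidence(tree_table: pd.DataFrame, pedigree: Pedigree) -> CloneMap:
    """Map field trees (ramets) onto pedigree genotypes.

    Clones of a genotype are repeated measures of one genetic individual;
    this map realises the incidence of tree-level records onto genotype-level
    genetic effects.
    """
    if tree_table.empty:
        raise PedigreeError("empty tree table")
    required = {"tree_id", "genotype_id"}
    if not required.issubset(tree_table.columns):
        raise PedigreeError(f"tree table needs columns {sorted(required)}")
    trees = tree_table["tree_id"].astype(str)
    if trees.duplicated().any():
        raise PedigreeError("duplicate tree ids in tree table")
    genos = tree_table["genotype_id"].astype(str)
    missing = sorted(set(genos) - set(pedigree.genotype_index))
    if missing:
        raise PedigreeError(f"trees reference genotypes absent from pedigree: {missing}")
    mapping = dict(zip(trees, genos))
    counts = genos.value_counts().sort_index()
    counts.name = "ramet_count"
    return CloneMap(mapping, counts)


def read_pedigree_csv(path) -> Pedigree:
    """Read `genotype_id,sire_id,dam_id` (empty string = unknown parent)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return build_pedigree(df[["genotype_id", "sire_id", "dam_id"]].itertuples(index=False))


def write_pedigree_csv(pedigree: Pedigree, path) -> None:
    rows = [
        (r.genotype_id, r.sire_id or "", r.dam_id or "")
        for r in pedigree.records
    ]
    pd.DataFrame(rows, columns=["genotype_id", "sire_id", "dam_id"]).to_csv(path, index=False)


def read_clone_map_csv(path, pedigree: Pedigree) -> CloneMap:
    """Read `tree_id,genotype_id`."""
    df = pd.read_csv(path, dtype=str)
    return clone_incidence(df, pedigree)


def write_clone_map_csv(clone_map: CloneMap, path) -> None:
    pd.DataFrame(
        sorted(clone_map.tree_to_genotype.items()), columns=["tree_id", "genotype_id"]
    ).to_csv(path, index=False)
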