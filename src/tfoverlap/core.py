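"""Core domain types shared by every analysis stage.

A study starts from two interaction tables — significant TF–gene *binding*
calls (ChIP-chip style) and significant TF–gene *knockout-effect* calls
(deletion-strain differential expression) — each a (tf, gene, p-value)
record list.  Thresholding at a common alpha turns a table into a
:class:`SignificantSetMap` (regulator → significant gene set and its
gene-keyed transpose), and the two maps are reconciled onto a shared
:class:`StudyUniverse` of regulators present in both datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

DATASET_KINDS = ("binding", "knockout")

__all__ = [
    "InteractionTable",
    "SignificantSetMap",
    "StudyUniverse",
    "read_interaction_table",
    "write_interaction_table",
    "threshold_significant",
    "transpose_map",
    "intersect_universe",
    "restrict_to_universe",
]


@dataclass(frozen=True)
class InteractionTable:
    """Raw (regulator, gene, p-value) records for one dataset.

    Invariants: no duplicate (tf, gene) pair, p-values in [0, 1],
    identifiers non-empty.  Enforced at construction.
    """

    records: tuple[tuple[str, str, float], ...]
    dataset_kind: str

    def __post_init__(self) -> None:
        if self.dataset_kind not in DATASET_KINDS:
            raise ValueError(f"unknown dataset_kind {self.dataset_kind!r}")
        seen: set[tuple[str, str]] = set()
        for tf, gene, p in self.records:
            if not tf or not gene:
                raise ValueError("empty regulator or gene identifier")
            if not (0.0 <= p <= 1.0) or math.isnan(p):
                raise ValueError(f"p-value out of range for ({tf}, {gene}): {p}")
            if (tf, gene) in seen:
                raise ValueError(f"duplicate interaction ({tf}, {gene})")
            seen.add((tf, gene))

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["tf", "gene", "pvalue"])


@dataclass(frozen=True)
class SignificantSetMap:
    """Regulator → significant gene set, with its gene-keyed transpose.

    ``by_gene`` is always the exact transpose of ``by_regulator``:
    g ∈ by_regulator[t] ⇔ t ∈ by_gene[g].  Entities with empty sets are
    absent from the maps; querying them returns the empty set via
    :meth:`genes_of` / :meth:`regulators_of`.
    """

    by_regulator: Mapping[str, frozenset[str]]
    by_gene: Mapping[str, frozenset[str]]
    alpha: float
    dataset_kind: str

    @property
    def n_pairs(self) -> int:
        return sum(len(s) for s in self.by_regulator.values())

    def genes_of(self, tf: str) -> frozenset[str]:
        return self.by_regulator.get(tf, frozenset())

    def regulators_of(self, gene: str) -> frozenset[str]:
        return self.by_gene.get(gene, frozenset())


@dataclass(frozen=True)
class StudyUniverse:
    """The regulator and gene identifier sets every computation restricts to."""

    tfs: tuple[str, ...]
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.tfs or not self.genes:
            raise ValueError("empty universe")

    @property
    def tf_set(self) -> frozenset[str]:
        return frozenset(self.tfs)

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)


def read_interaction_table(path: str | Path, dataset_kind: str) -> InteractionTable:
    """Read a `tf<TAB>gene<TAB>pvalue` TSV into a validated table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={"tf": str, "gene": str})
    missing = {"tf", "gene", "pvalue"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df[["tf", "gene", "pvalue"]].isna().any().any():
        raise ValueError(f"{path}: malformed row (missing field)")
    records = tuple(
        (str(r.tf), str(r.gene), float(r.pvalue))
        for r in df.itertuples(index=False)
    )
    return InteractionTable(records=records, dataset_kind=dataset_kind)


def write_interaction_table(table: InteractionTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def threshold_significant(
    table: InteractionTable,
    alpha: float,
    *,
    pre_thresholded: bool = False,
) -> SignificantSetMap:
    """Call pairs with p < alpha significant and build both set maps.

    Significance is strict inequality.  With ``pre_thresholded`` every
    recorded pair is taken as significant regardless of its p-value
    (for datasets that circulate as already-filtered pair lists).
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha out of range: {alpha}")
    by_reg: dict[str, set[str]] = {}
    by_gene: dict[str, set[str]] = {}
    for tf, gene, p in table.records:
        if pre_thresholded or p < alpha:
            by_reg.setdefault(tf, set()).add(gene)
            by_gene.setdefault(gene, set()).add(tf)
    return SignificantSetMap(
        by_regulator={t: frozenset(s) for t, s in by_reg.items()},
        by_gene={g: frozenset(s) for g, s in by_gene.items()},
        alpha=alpha,
        dataset_kind=table.dataset_kind,
    )


def transpose_map(m: SignificantSetMap) -> SignificantSetMap:
    """Swap the regulator-keyed and gene-keyed roles; an involution."""
    return SignificantSetMap(
        by_regulator=m.by_gene,
        by_gene=m.by_regulator,
        alpha=m.alpha,
        dataset_kind=m.dataset_kind,
    )


def intersect_universe(
    binding: SignificantSetMap,
    knockout: SignificantSetMap,
    binding_tfs: Iterable[str] | None = None,
    knockout_tfs: Iterable[str] | None = None,
) -> StudyUniverse:
    """Build the shared universe: TFs assayed in both datasets, and every
    gene either dataset records for those TFs.

    The TF lists default to the regulators appearing in each map; passing
    them explicitly lets assayed-but-empty regulators stay in the universe.
    """
    btfs = frozenset(binding_tfs) if binding_tfs is not None else frozenset(binding.by_regulator)
    ktfs = frozenset(knockout_tfs) if knockout_tfs is not None else frozenset(knockout.by_regulator)
    tfs = btfs & ktfs
    if not tfs:
        raise ValueError("empty universe: no TF is present in both datasets")
    genes: set[str] = set()
    for m in (binding, knockout):
        for t in tfs:
            genes.update(m.genes_of(t))
    if not genes:
        raise ValueError("empty universe: retained TFs have no recorded genes")
    return StudyUniverse(tfs=tuple(sorted(tfs)), genes=tuple(sorted(genes)))


def restrict_to_universe(m: SignificantSetMap, universe: StudyUniverse) -> SignificantSetMap:
    """Drop pairs whose TF or gene falls outside the universe."""
    tfs, genes = universe.tf_set, universe.gene_set
    by_reg: dict[str, frozenset[str]] = {}
    for t, s in m.by_regulator.items():
        if t in tfs:
            kept = s & genes
            if kept:
                by_reg[t] = frozenset(kept)
    by_gene: dict[str, set[str]] = {}
    for t, s in by_reg.items():
        for g in s:
            by_gene.setdefault(g, set()).add(t)
    return SignificantSetMap(
        by_regulator=by_reg,
        by_gene={g: frozenset(s) for g, s in by_gene.items()},
        alpha=m.alpha,
        dataset_kind=m.dataset_kind,
    )
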