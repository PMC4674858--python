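"""Generic stratified overlap-percentage comparisons over TF and gene properties.

Every comparison in a study — functional-redundancy strata at the TF
level; expression, plasticity, bound-TF count, TFBS count and TFBS–TSS
distance at the gene level; TATA / NFR / ribosomal / chromatin-remodelling
class splits — is an instance of the same pipeline: pick two entity
groups, pool their binding pairs into overlap percentages, and compare
the two proportions with a one-sided z test.

Numeric properties are split into the bottom-X% and top-X% strata over a
grid of X values; categorical properties compare two explicit lists or a
list against the rest of the universe.  By convention *group 1* is the
bottom stratum (numeric mode) or the first list (categorical modes), and
``expected_direction`` states which way group 1's OP is expected to go.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import (
    SignificantSetMap,
    StudyUniverse,
    intersect_universe,
    read_interaction_table,
    restrict_to_universe,
    threshold_significant,
)
from .overlap import (
    OverlapResult,
    ProportionTestResult,
    op_for_gene_set,
    op_for_tf_set,
    per_entity_op_table,
    proportion_test,
    stratify_top_bottom,
)
from .redundancy import read_annotation_catalog, score_all_redundancy

__all__ = [
    "PropertySpec",
    "AnalysisRow",
    "AnalysisResult",
    "StudyResults",
    "analyze_numeric",
    "analyze_categorical",
    "run_full_study",
    "results_frame",
    "read_property_table",
    "read_id_list",
    "bound_tf_counts",
    "DEFAULT_X_GRID",
]

DEFAULT_X_GRID = (10.0, 20.0, 30.0, 40.0, 50.0)

MODES = ("numeric_top_bottom", "categorical_two_lists", "categorical_vs_rest")
DIRECTIONS = ("first_group_lower", "first_group_higher", "none")


@dataclass(frozen=True)
class PropertySpec:
    """Layout of one comparison: what is stratified, how, and the
    expected direction of group 1's OP relative to group 2's."""

    name: str
    level: str  # "tf" | "gene"
    mode: str
    x_grid: tuple[float, ...] = DEFAULT_X_GRID
    expected_direction: str = "none"
    annotation_source: str = ""

    def __post_init__(self) -> None:
        if self.level not in ("tf", "gene"):
            raise ValueError(f"{self.name}: level must be tf or gene")
        if self.mode not in MODES:
            raise ValueError(f"{self.name}: unknown mode {self.mode!r}")
        if self.expected_direction not in DIRECTIONS:
            raise ValueError(f"{self.name}: unknown direction {self.expected_direction!r}")
        for x in self.x_grid:
            if not (0.0 < x <= 50.0):
                raise ValueError(f"{self.name}: X={x} outside (0, 50]")

    @property
    def alternative(self) -> str:
        # the one-sided alternative implied by the expected direction;
        # direction-free comparisons still report a one-sided p, read
        # jointly with the sign of z
        return "group1_greater" if self.expected_direction == "first_group_higher" else "group1_less"


@dataclass(frozen=True)
class AnalysisRow:
    """One grid point (numeric) or the single split (categorical)."""

    x_percent: float | None
    group1: OverlapResult
    group2: OverlapResult
    test: ProportionTestResult


@dataclass(frozen=True)
class AnalysisResult:
    spec: PropertySpec
    rows: tuple[AnalysisRow, ...]
    exclusions: tuple[tuple[str, str], ...] = field(default=())


@dataclass(frozen=True)
class StudyResults:
    """Everything one full run produces, in deterministic order."""

    universe: StudyUniverse
    binding: SignificantSetMap
    knockout: SignificantSetMap
    overall: OverlapResult
    analyses: tuple[AnalysisResult, ...]
    per_tf: pd.DataFrame
    per_gene: pd.DataFrame


def _op_at_level(level: str):
    return op_for_tf_set if level == "tf" else op_for_gene_set


def _universe_entities(level: str, universe: StudyUniverse) -> frozenset[str]:
    return universe.tf_set if level == "tf" else universe.gene_set


def analyze_numeric(
    spec: PropertySpec,
    scores: Mapping[str, float],
    binding: SignificantSetMap,
    knockout: SignificantSetMap,
    universe: StudyUniverse,
) -> AnalysisResult:
    """Bottom-X% vs top-X% comparison of a numeric property at each X."""
    if spec.mode != "numeric_top_bottom":
        raise ValueError(f"{spec.name}: analyze_numeric needs numeric_top_bottom mode")
    members = _universe_entities(spec.level, universe)
    kept = {e: float(v) for e, v in scores.items() if e in members}
    exclusions = tuple(
        (e, "outside universe") for e in sorted(set(scores) - members)
    )
    if not kept:
        raise ValueError(f"{spec.name}: no scored entity inside the universe")
    if len(set(kept.values())) == 1:
        raise ValueError(f"{spec.name}: all scores identical, strata undefined")
    op_fn = _op_at_level(spec.level)
    rows = []
    for x in spec.x_grid:
        bottom = stratify_top_bottom(kept, x, "bottom")
        top = stratify_top_bottom(kept, x, "top")
        g1 = op_fn(sorted(bottom), binding, knockout, label=f"{spec.name} bottom {x:g}%")
        g2 = op_fn(sorted(top), binding, knockout, label=f"{spec.name} top {x:g}%")
        if g1.denominator == 0 or g2.denominator == 0:
            raise ValueError(f"{spec.name}: stratum at X={x:g} has no binding pairs")
        rows.append(AnalysisRow(x_percent=x, group1=g1, group2=g2,
                                test=proportion_test(g1, g2, spec.alternative)))
    return AnalysisResult(spec=spec, rows=tuple(rows), exclusions=exclusions)


def analyze_categorical(
    spec: PropertySpec,
    list_a: Iterable[str],
    list_b_or_rest: Iterable[str] | str,
    binding: SignificantSetMap,
    knockout: SignificantSetMap,
    universe: StudyUniverse,
) -> AnalysisResult:
    """Two-list or list-vs-rest comparison of a categorical property."""
    members = _universe_entities(spec.level, universe)
    set_a_raw = set(list_a)
    set_a = set_a_raw & members
    exclusions = [(e, "outside universe") for e in sorted(set_a_raw - set_a)]
    if spec.mode == "categorical_vs_rest":
        if not (isinstance(list_b_or_rest, str) and list_b_or_rest == "rest"):
            raise ValueError(f"{spec.name}: vs-rest mode takes the literal 'rest'")
        set_b = members - set_a
        label_b = "rest"
        if not set_b:
            raise ValueError(f"{spec.name}: empty complement, list covers the whole universe")
    elif spec.mode == "categorical_two_lists":
        set_b_raw = set(list_b_or_rest)
        set_b = set_b_raw & members
        exclusions += [(e, "outside universe") for e in sorted(set_b_raw - set_b)]
        label_b = "group2"
    else:
        raise ValueError(f"{spec.name}: analyze_categorical needs a categorical mode")
    if not set_a or not set_b:
        raise ValueError(f"{spec.name}: empty group after universe restriction")
    op_fn = _op_at_level(spec.level)
    g1 = op_fn(sorted(set_a), binding, knockout, label=f"{spec.name} group1")
    g2 = op_fn(sorted(set_b), binding, knockout, label=f"{spec.name} {label_b}")
    if g1.denominator == 0 or g2.denominator == 0:
        raise ValueError(f"{spec.name}: a group has no binding pairs")
    row = AnalysisRow(x_percent=None, group1=g1, group2=g2,
                      test=proportion_test(g1, g2, spec.alternative))
    return AnalysisResult(spec=spec, rows=(row,), exclusions=tuple(sorted(exclusions)))


def read_property_table(path: str | Path) -> dict[str, float]:
    """Two-column `entity<TAB>value` TSV (header line required)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (entity, value)")
    ids = df.iloc[:, 0].astype(str)
    vals = pd.to_numeric(df.iloc[:, 1], errors="raise")
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate entity {dup!r}")
    return dict(zip(ids, vals.astype(float)))


def read_id_list(path: str | Path) -> frozenset[str]:
    """One identifier per line; `#` comments and blank lines ignored."""
    out = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return frozenset(out)


def bound_tf_counts(binding: SignificantSetMap, universe: StudyUniverse) -> dict[str, float]:
    """Number of distinct TFs binding each universe gene, |T_B(g)| —
    the one numeric property fully determined by the binding map."""
    return {g: float(len(binding.regulators_of(g))) for g in universe.genes}


def _load_scores(entry: Mapping, base: Path, universe: StudyUniverse,
                 binding: SignificantSetMap) -> tuple[dict[str, float], list[tuple[str, str]]]:
    name = entry["name"]
    pre_excluded: list[tuple[str, str]] = []
    if "scores" in entry:
        scores = read_property_table(base / entry["scores"])
    elif "annotations" in entry:
        catalog = read_annotation_catalog(base / entry["annotations"])
        red = score_all_redundancy(catalog, universe.tfs)
        scores = dict(red.fr_by_tf)
        pre_excluded = list(red.excluded)
    elif entry.get("derived") == "n_bound_tfs":
        scores = bound_tf_counts(binding, universe)
    else:
        raise ValueError(f"property {name!r}: needs one of scores / annotations / derived")
    return scores, pre_excluded


def run_full_study(config: Mapping, base_dir: str | Path) -> StudyResults:
    """Execute every comparison named in a study configuration.

    The configuration carries the dataset paths (relative to
    ``base_dir``), the significance threshold, and one entry per
    property with its level, mode, input file(s), expected direction and
    X grid.  Any stage failure is re-raised with the property name
    attached.
    """
    base = Path(base_dir)
    alpha = float(config.get("alpha", 0.005))
    binding_tbl = read_interaction_table(base / config["binding"], "binding")
    knockout_tbl = read_interaction_table(base / config["knockout"], "knockout")
    pre = bool(config.get("pre_thresholded", False))
    binding_map = threshold_significant(binding_tbl, alpha, pre_thresholded=pre)
    knockout_map = threshold_significant(knockout_tbl, alpha, pre_thresholded=pre)
    universe = intersect_universe(binding_map, knockout_map)
    binding_map = restrict_to_universe(binding_map, universe)
    knockout_map = restrict_to_universe(knockout_map, universe)

    overall = op_for_tf_set(universe.tfs, binding_map, knockout_map, label="all TFs")
    analyses: list[AnalysisResult] = []
    for entry in config.get("properties", ()):
        name = entry.get("name", "<unnamed>")
        try:
            spec = PropertySpec(
                name=name,
                level=entry["level"],
                mode=entry["mode"],
                x_grid=tuple(float(x) for x in entry.get("x_grid", DEFAULT_X_GRID)),
                expected_direction=entry.get("direction", "none"),
                annotation_source=entry.get("annotation_source", ""),
            )
            if spec.mode == "numeric_top_bottom":
                scores, pre_excl = _load_scores(entry, base, universe, binding_map)
                res = analyze_numeric(spec, scores, binding_map, knockout_map, universe)
                if pre_excl:
                    res = AnalysisResult(spec=res.spec, rows=res.rows,
                                         exclusions=tuple(pre_excl) + res.exclusions)
            else:
                list_a = read_id_list(base / entry["list_a"])
                second: frozenset[str] | str
                if spec.mode == "categorical_vs_rest":
                    second = "rest"
                else:
                    second = read_id_list(base / entry["list_b"])
                res = analyze_categorical(spec, list_a, second,
                                          binding_map, knockout_map, universe)
        except Exception as exc:
            raise RuntimeError(f"property {name!r}: {exc}") from exc
        analyses.append(res)

    per_tf = per_entity_op_table(binding_map, knockout_map, universe.tfs, level="tf")
    per_gene = per_entity_op_table(binding_map, knockout_map, universe.genes, level="gene")
    return StudyResults(
        universe=universe,
        binding=binding_map,
        knockout=knockout_map,
        overall=overall,
        analyses=tuple(analyses),
        per_tf=per_tf,
        per_gene=per_gene,
    )


def results_frame(analyses: Sequence[AnalysisResult]) -> pd.DataFrame:
    """Tabular form of the comparisons: one row per group per grid point."""
    rows = []
    for res in analyses:
        for r in res.rows:
            sides = (
                ("bottom", r.group1), ("top", r.group2)
            ) if r.x_percent is not None else (
                ("group1", r.group1), ("group2", r.group2)
            )
            for side, grp in sides:
                rows.append(
                    {
                        "comparison": res.spec.name,
                        "annotation_source": res.spec.annotation_source,
                        "X": r.x_percent if r.x_percent is not None else "",
                        "side": side,
                        "n_entities": grp.n_entities,
                        "numerator": grp.numerator,
                        "denominator": grp.denominator,
                        "op": grp.op,
                        "z": r.test.z,
                        "p_value": r.test.p_value,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["comparison", "annotation_source", "X", "side", "n_entities",
                 "numerator", "denominator", "op", "z", "p_value"],
    )
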