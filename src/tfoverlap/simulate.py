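"""Seeded generator of complete synthetic study inputs.

The generative model is the minimal one consistent with the masking
hypothesis: a functionally redundant partner TF can compensate for a
knocked-out TF, so binding targets of paralog-paired TFs convert to
knockout effects at a reduced rate.

World construction, in order:

1. A fraction of TFs is paired into "paralog" couples whose annotation
   term sets are drawn from a shared base set (true high functional
   redundancy); the remaining TFs draw near-disjoint sets from the term
   pool (true low redundancy).
2. Each TF binds a Poisson-sized set of genes, sampled with weights from
   a long-tailed per-gene binding propensity (so bound-TF counts vary
   across genes, as in real promoter data).
3. A bound pair (t, g) converts to a knockout effect with probability

       base_effect_prob
         × (1 − masking_strength · 1[t is paralog-paired])
         × Π class multipliers (TATA / NFR / ribosomal genes,
                                chromatin-remodelling TFs)
         × exp(Σ_p c_p · z_p(g) − c_p²/2)

   where z_p are the z-scored numeric gene properties (expression,
   plasticity, TFBS count, TFBS–TSS distance, realized bound-TF count)
   and c_p their log-scale couplings; the exp factor is mean-normalized
   so couplings reshape but do not shift the overall effect rate.
   Probabilities are clipped to [0, 1].
4. Unbound pairs convert to knockout effects at an independent small
   background rate (indirect regulatory effects), keeping the knockout
   dataset about the size of the binding dataset.
5. Significant pairs receive p-values uniform on (0, significant_p_scale·alpha);
   a fraction of non-significant pairs is also recorded, with p-values
   above nonsig_p_floor, so thresholding is exercised.

Default sizes emulate the real study scale: 173 TFs, 4065 genes,
~11.4k significant binding pairs, a knockout dataset of similar size,
and an overall overlap percentage near 4%.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .core import (
    InteractionTable,
    SignificantSetMap,
    StudyUniverse,
    intersect_universe,
    restrict_to_universe,
    threshold_significant,
    write_interaction_table,
)
from .redundancy import AnnotationCatalog, write_annotation_catalog

__all__ = [
    "WorldParams",
    "WorldTruth",
    "SyntheticWorld",
    "generate_world",
    "world_maps",
    "write_world",
    "load_manifest",
    "null_params",
    "default_study_config",
]

# frozen after one-time calibration to overall OP ~= 0.04 at defaults
DEFAULT_BASE_EFFECT_PROB = 0.0590
DEFAULT_BACKGROUND_EFFECT_PROB = 0.0167

_GENE_CLASS_FRACTIONS = {"tata_containing": 0.19, "nfr_containing": 0.50, "ribosomal": 0.032}
_TF_CLASS_FRACTIONS = {"chromatin_remodelling": 0.06}
_CLASS_MULTIPLIERS = {
    "tata_containing": 1.8,
    "nfr_containing": 0.55,
    "ribosomal": 2.5,
    "chromatin_remodelling": 2.0,
}
_NUMERIC_COUPLINGS = {
    "expression": 0.5,
    "plasticity": 0.5,
    "n_bound_tfs": 0.4,
    "n_tfbs": 0.4,
    "tfbs_tss_distance": 0.4,
}


@dataclass(frozen=True)
class WorldParams:
    """Knobs of the generative model; defaults are the study conditions."""

    n_tfs: int = 173
    n_genes: int = 4065
    mean_targets_per_tf: float = 65.75
    base_effect_prob: float = DEFAULT_BASE_EFFECT_PROB
    masking_strength: float = 0.8
    background_effect_prob: float = DEFAULT_BACKGROUND_EFFECT_PROB
    paralog_fraction: float = 0.5
    n_terms: int = 300
    mean_terms_per_tf: float = 8.0
    term_share_prob: float = 0.9
    gene_class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(_GENE_CLASS_FRACTIONS))
    tf_class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(_TF_CLASS_FRACTIONS))
    gene_class_effect_multipliers: Mapping[str, float] = field(
        default_factory=lambda: dict(_CLASS_MULTIPLIERS))
    numeric_property_coupling: Mapping[str, float] = field(
        default_factory=lambda: dict(_NUMERIC_COUPLINGS))
    binding_propensity_sigma: float = 0.8
    significant_p_scale: float = 0.8
    nonsig_p_floor: float = 0.05
    nonsig_fraction: float = 0.1
    alpha: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_effect_prob", "masking_strength",
                     "background_effect_prob", "paralog_fraction",
                     "term_share_prob", "significant_p_scale", "nonsig_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} outside [0,1]: {v}")
        if self.n_tfs < 4:
            raise ValueError("need n_tfs >= 4")
        if self.n_genes < 10:
            raise ValueError("need n_genes >= 10")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha outside (0,1]: {self.alpha}")
        if not (self.alpha <= self.nonsig_p_floor <= 1.0):
            raise ValueError("nonsig_p_floor must lie in [alpha, 1]")
        for m in self.gene_class_effect_multipliers.values():
            if m <= 0:
                raise ValueError("class multipliers must be positive")
        # deterministic part of the effect probability must be a probability;
        # the stochastic log-linear factor is clipped at sampling time
        worst = self.base_effect_prob
        for cls, m in self.gene_class_effect_multipliers.items():
            if m > 1.0:
                worst *= m
        if worst > 1.0:
            raise ValueError(
                f"base_effect_prob with class multipliers exceeds 1 ({worst:.3f})")


@dataclass(frozen=True)
class WorldTruth:
    """Ground truth sufficient to recompute every realized effect probability."""

    paired_tfs: frozenset[str]
    partner: Mapping[str, str]
    gene_classes: Mapping[str, frozenset[str]]
    tf_classes: Mapping[str, frozenset[str]]
    effect_probs: pd.DataFrame  # tf, gene, p_effect for every bound pair


@dataclass(frozen=True)
class SyntheticWorld:
    params: WorldParams
    binding_table: InteractionTable
    knockout_table: InteractionTable
    annotation_catalog: AnnotationCatalog
    numeric_properties: Mapping[str, Mapping[str, float]]
    class_lists: Mapping[str, frozenset[str]]
    truth: WorldTruth


def null_params(seed: int = 0, **overrides) -> WorldParams:
    """The null world: no masking, unit multipliers, zero couplings —
    every binding pair converts with the same probability."""
    base = dict(
        masking_strength=0.0,
        gene_class_effect_multipliers={k: 1.0 for k in _CLASS_MULTIPLIERS},
        numeric_property_coupling={k: 0.0 for k in _NUMERIC_COUPLINGS},
        base_effect_prob=0.04,
        seed=seed,
    )
    base.update(overrides)
    return WorldParams(**base)


def _zscore(x: np.ndarray) -> np.ndarray:
    s = x.std()
    if s == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / s


def generate_world(params: WorldParams) -> SyntheticWorld:
    """Sample one complete world from the generative model; all
    randomness flows from ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    nt, ng = params.n_tfs, params.n_genes
    tf_ids = np.array([f"TF{i:03d}" for i in range(nt)])
    gene_ids = np.array([f"G{j:04d}" for j in range(ng)])

    # --- paralog pairing -------------------------------------------------
    n_paired = 2 * int(params.paralog_fraction * nt / 2)
    perm = rng.permutation(nt)
    paired_idx = perm[:n_paired]
    is_paired = np.zeros(nt, dtype=bool)
    is_paired[paired_idx] = True
    partner: dict[str, str] = {}
    for a, b in paired_idx.reshape(-1, 2):
        partner[str(tf_ids[a])] = str(tf_ids[b])
        partner[str(tf_ids[b])] = str(tf_ids[a])

    # --- annotation terms ------------------------------------------------
    terms = np.array([f"TERM{k:04d}" for k in range(params.n_terms)])
    terms_by_tf: dict[str, frozenset[str]] = {}

    def _draw_terms(size: int) -> np.ndarray:
        size = min(max(size, 1), params.n_terms)
        return rng.choice(params.n_terms, size=size, replace=False)

    for a, b in paired_idx.reshape(-1, 2):
        base_size = 2 + rng.poisson(max(params.mean_terms_per_tf - 2.0, 0.0))
        base_terms = _draw_terms(base_size)
        for i in (a, b):
            keep = base_terms[rng.random(len(base_terms)) < params.term_share_prob]
            extra = _draw_terms(rng.poisson(0.5)) if rng.random() < 0.5 else np.array([], dtype=int)
            mine = np.union1d(keep, extra)
            if mine.size == 0:
                mine = base_terms[:1]
            terms_by_tf[str(tf_ids[i])] = frozenset(terms[mine])
    for i in np.where(~is_paired)[0]:
        size = 2 + rng.poisson(max(params.mean_terms_per_tf - 2.0, 0.0))
        terms_by_tf[str(tf_ids[i])] = frozenset(terms[_draw_terms(size)])
    catalog = AnnotationCatalog(
        terms_by_entity={t: terms_by_tf[t] for t in sorted(terms_by_tf)},
        source_label="synthetic_terms",
    )

    # --- classes ---------------------------------------------------------
    gene_class_mask = {
        cls: rng.random(ng) < frac for cls, frac in sorted(params.gene_class_fractions.items())
    }
    tf_class_mask = {
        cls: rng.random(nt) < frac for cls, frac in sorted(params.tf_class_fractions.items())
    }

    # --- numeric gene properties ----------------------------------------
    expr_z = rng.standard_normal(ng)
    plas_z = rng.standard_normal(ng)
    n_tfbs = rng.poisson(10.0, ng)
    tss_dist = np.clip(rng.normal(200.0, 80.0, ng), 5.0, None)

    # --- binding ---------------------------------------------------------
    propensity = np.exp(params.binding_propensity_sigma * rng.standard_normal(ng))
    bound = np.zeros((nt, ng), dtype=bool)
    for i in range(nt):
        k = min(max(int(rng.poisson(params.mean_targets_per_tf)), 1), ng)
        keys = rng.exponential(1.0, ng) / propensity
        idx = np.argpartition(keys, k - 1)[:k]
        bound[i, idx] = True
    n_bound_tfs = bound.sum(axis=0)

    # --- effect probabilities on bound pairs -----------------------------
    prop_values = {
        "expression": np.exp(5.0 + 1.2 * expr_z),
        "plasticity": np.exp(1.0 + 0.8 * plas_z),
        "n_bound_tfs": n_bound_tfs.astype(float),
        "n_tfbs": n_tfbs.astype(float),
        "tfbs_tss_distance": tss_dist,
    }
    # log-odds adjustment from the z-scored numeric properties, clipped so
    # no single gene's odds move more than ~e^2.5; mean-normalized per slope
    log_odds_shift = np.zeros(ng)
    for name, c in sorted(params.numeric_property_coupling.items()):
        if c == 0.0 or name not in prop_values:
            continue
        z = np.clip(_zscore(prop_values[name]), -2.5, 2.5)
        log_odds_shift += c * z - c * c / 2.0

    gene_mult = np.ones(ng)
    mult = params.gene_class_effect_multipliers
    for cls, mask in gene_class_mask.items():
        m = mult.get(cls, 1.0)
        gene_mult = gene_mult * np.where(mask, m, 1.0)

    tf_factor = params.base_effect_prob * (1.0 - params.masking_strength * is_paired)
    for cls, mask in tf_class_mask.items():
        m = mult.get(cls, 1.0)
        tf_factor = tf_factor * np.where(mask, m, 1.0)

    p_det = np.clip(np.outer(tf_factor, gene_mult), 0.0, 1.0)
    with np.errstate(divide="ignore"):
        logit = np.log(p_det) - np.log1p(-np.clip(p_det, 0.0, 1.0 - 1e-12))
    p_effect = 1.0 / (1.0 + np.exp(-(logit + log_odds_shift[None, :])))
    p_effect = np.clip(np.nan_to_num(p_effect, nan=0.0), 0.0, 1.0)

    # --- knockout effects ------------------------------------------------
    direct = bound & (rng.random((nt, ng)) < p_effect)
    background = (~bound) & (rng.random((nt, ng)) < params.background_effect_prob)
    affected = direct | background

    # --- interaction tables with p-values --------------------------------
    def _make_table(sig: np.ndarray, kind: str) -> InteractionTable:
        ti, gi = np.nonzero(sig)
        p_sig = rng.uniform(0.0, params.significant_p_scale * params.alpha, ti.size)
        rows = list(zip(tf_ids[ti], gene_ids[gi], p_sig))
        # recorded-but-nonsignificant rows exercise the thresholding step
        n_extra = int(params.nonsig_fraction * ti.size)
        if n_extra:
            sig_pairs = set(zip(tf_ids[ti], gene_ids[gi]))
            cand_t = rng.integers(0, nt, 2 * n_extra)
            cand_g = rng.integers(0, ng, 2 * n_extra)
            p_non = rng.uniform(params.nonsig_p_floor, 1.0, 2 * n_extra)
            taken: set[tuple[str, str]] = set()
            for t_i, g_i, p in zip(cand_t, cand_g, p_non):
                pair = (str(tf_ids[t_i]), str(gene_ids[g_i]))
                if pair in sig_pairs or pair in taken:
                    continue
                taken.add(pair)
                rows.append((pair[0], pair[1], p))
                if len(taken) >= n_extra:
                    break
        rows.sort(key=lambda r: (r[0], r[1]))
        return InteractionTable(
            records=tuple((str(t), str(g), float(p)) for t, g, p in rows),
            dataset_kind=kind,
        )

    binding_table = _make_table(bound, "binding")
    knockout_table = _make_table(affected, "knockout")

    # --- truth sidecar ---------------------------------------------------
    ti, gi = np.nonzero(bound)
    effect_probs = pd.DataFrame(
        {"tf": tf_ids[ti], "gene": gene_ids[gi], "p_effect": p_effect[ti, gi]}
    ).sort_values(["tf", "gene"], ignore_index=True)
    truth = WorldTruth(
        paired_tfs=frozenset(tf_ids[is_paired]),
        partner=partner,
        gene_classes={cls: frozenset(gene_ids[m]) for cls, m in gene_class_mask.items()},
        tf_classes={cls: frozenset(tf_ids[m]) for cls, m in tf_class_mask.items()},
        effect_probs=effect_probs,
    )

    numeric_properties = {
        name: {str(g): float(v) for g, v in zip(gene_ids, vals)}
        for name, vals in prop_values.items()
    }
    # bound-TF count is a property of bound promoters; genes no TF binds
    # have no defined value (they would pool 0/0 into every bottom stratum)
    numeric_properties["n_bound_tfs"] = {
        str(g): float(v) for g, v in zip(gene_ids, n_bound_tfs) if v > 0
    }
    class_lists: dict[str, frozenset[str]] = {}
    for cls, m in gene_class_mask.items():
        class_lists[cls] = frozenset(gene_ids[m])
        anti = cls.replace("_containing", "_less")
        if anti != cls:
            class_lists[anti] = frozenset(gene_ids[~m])
    for cls, m in tf_class_mask.items():
        class_lists[cls] = frozenset(tf_ids[m])

    return SyntheticWorld(
        params=params,
        binding_table=binding_table,
        knockout_table=knockout_table,
        annotation_catalog=catalog,
        numeric_properties=numeric_properties,
        class_lists=class_lists,
        truth=truth,
    )


def world_maps(
    world: SyntheticWorld,
) -> tuple[SignificantSetMap, SignificantSetMap, StudyUniverse]:
    """Threshold a world's tables at its alpha and restrict both maps to
    the shared universe — the standard entry into the analysis stage."""
    bm = threshold_significant(world.binding_table, world.params.alpha)
    km = threshold_significant(world.knockout_table, world.params.alpha)
    universe = intersect_universe(bm, km)
    return (restrict_to_universe(bm, universe),
            restrict_to_universe(km, universe), universe)


def default_study_config() -> dict:
    """The study configuration matching the files write_world emits:
    one entry per comparison, with the direction the model injects."""
    num = lambda name, direction: {
        "name": name, "level": "gene", "mode": "numeric_top_bottom",
        "scores": f"properties/{name}.tsv", "direction": direction,
    }
    return {
        "alpha": 0.005,
        "binding": "binding.tsv",
        "knockout": "knockout.tsv",
        "properties": [
            {
                "name": "functional_redundancy", "level": "tf",
                "mode": "numeric_top_bottom", "annotations": "annotations.tsv",
                "annotation_source": "synthetic_terms",
                "direction": "first_group_higher",  # bottom = low FR, unmasked
            },
            num("expression", "first_group_lower"),
            num("plasticity", "first_group_lower"),
            num("n_bound_tfs", "first_group_lower"),
            num("n_tfbs", "first_group_lower"),
            num("tfbs_tss_distance", "first_group_lower"),
            {
                "name": "tata_box", "level": "gene", "mode": "categorical_two_lists",
                "list_a": "lists/tata_less.txt", "list_b": "lists/tata_containing.txt",
                "direction": "first_group_lower",
            },
            {
                "name": "nfr", "level": "gene", "mode": "categorical_two_lists",
                "list_a": "lists/nfr_containing.txt", "list_b": "lists/nfr_less.txt",
                "direction": "first_group_lower",
            },
            {
                "name": "ribosomal", "level": "gene", "mode": "categorical_vs_rest",
                "list_a": "lists/ribosomal.txt", "direction": "first_group_higher",
            },
            {
                "name": "chromatin_remodelling", "level": "tf",
                "mode": "categorical_vs_rest",
                "list_a": "lists/chromatin_remodelling.txt",
                "direction": "first_group_higher",
            },
        ],
    }


def write_world(world: SyntheticWorld, directory: str | Path) -> dict:
    """Emit every file the pipeline consumes, a ground-truth sidecar, a
    study configuration, and a manifest that regenerates the world."""
    out = Path(directory)
    (out / "properties").mkdir(parents=True, exist_ok=True)
    (out / "lists").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)

    write_interaction_table(world.binding_table, out / "binding.tsv")
    write_interaction_table(world.knockout_table, out / "knockout.tsv")
    write_annotation_catalog(world.annotation_catalog, out / "annotations.tsv")
    for name, table in sorted(world.numeric_properties.items()):
        df = pd.DataFrame(sorted(table.items()), columns=["entity", "value"])
        df.to_csv(out / "properties" / f"{name}.tsv", sep="\t", index=False)
    for name, ids in sorted(world.class_lists.items()):
        (out / "lists" / f"{name}.txt").write_text(
            "".join(f"{i}\n" for i in sorted(ids)), encoding="utf-8")

    tf_rows = [
        {"tf": t, "paired": int(t in world.truth.paired_tfs),
         "partner": world.truth.partner.get(t, "")}
        for t in sorted({r[0] for r in world.binding_table.records})
    ]
    pd.DataFrame(tf_rows).to_csv(out / "truth" / "tf_truth.tsv", sep="\t", index=False)
    world.truth.effect_probs.to_csv(out / "truth" / "effect_probs.tsv", sep="\t", index=False)

    config = default_study_config()
    config["alpha"] = world.params.alpha
    with open(out / "study.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)

    manifest = {
        "params": _params_to_jsonable(world.params),
        "seed": world.params.seed,
        "n_binding_records": len(world.binding_table),
        "n_knockout_records": len(world.knockout_table),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _params_to_jsonable(params: WorldParams) -> dict:
    d = dataclasses.asdict(params)
    for k, v in d.items():
        if isinstance(v, Mapping):
            d[k] = dict(v)
    return d


def load_manifest(path: str | Path) -> WorldParams:
    """Read a manifest back into the exact parameters that produced it."""
    with open(path, encoding="utf-8") as fh:
        manifest = json.load(fh)
    return WorldParams(**manifest["params"])
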