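"""Overlap-percentage statistics and the stratified proportion test.

The overlap percentage (OP) of a TF set M pools binding pairs over M:

    OP = Σ_{t∈M} |G_B(t) ∩ G_K(t)| / Σ_{t∈M} |G_B(t)|

i.e. the fraction of significant binding pairs whose gene is also
significantly affected by the TF's knockout.  The gene-set form is the
transpose (T_B(g), T_K(g) summed over a gene set N); over the full
universe both forms count the same distinct (t, g) pairs and are
identical.  Group comparisons use the one-sided two-sample proportion
test with pooled variance, treating each binding pair as a Bernoulli
trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .core import SignificantSetMap

__all__ = [
    "OverlapResult",
    "ProportionTestResult",
    "op_for_tf_set",
    "op_for_gene_set",
    "per_entity_op_table",
    "stratify_top_bottom",
    "proportion_test",
]

ALTERNATIVES = ("group1_less", "group1_greater")


@dataclass(frozen=True)
class OverlapResult:
    """Pooled overlap count / binding count for one entity set."""

    numerator: int
    denominator: int
    entity_set_label: str = ""
    n_entities: int | None = None

    def __post_init__(self) -> None:
        if self.numerator < 0 or self.denominator < 0:
            raise ValueError("negative count")
        if self.numerator > self.denominator:
            raise ValueError("overlap count exceeds binding count")

    @property
    def op(self) -> float | None:
        """The overlap percentage as a fraction in [0, 1]; None if no
        binding pair exists (0/0 is undefined, not zero)."""
        if self.denominator == 0:
            return None
        return self.numerator / self.denominator

    @property
    def op_percent(self) -> float | None:
        return None if self.op is None else 100.0 * self.op


@dataclass(frozen=True)
class ProportionTestResult:
    z: float
    p_value: float
    group1: OverlapResult
    group2: OverlapResult
    alternative: str
    degenerate: bool = False


def op_for_tf_set(
    tf_set: Iterable[str],
    binding: SignificantSetMap,
    knockout: SignificantSetMap,
    label: str = "",
) -> OverlapResult:
    """OP pooled over a TF set: Σ|G_B(t) ∩ G_K(t)| / Σ|G_B(t)|."""
    num = den = n = 0
    for t in tf_set:
        gb = binding.genes_of(t)
        num += len(gb & knockout.genes_of(t))
        den += len(gb)
        n += 1
    return OverlapResult(numerator=num, denominator=den,
                         entity_set_label=label, n_entities=n)


def op_for_gene_set(
    gene_set: Iterable[str],
    binding: SignificantSetMap,
    knockout: SignificantSetMap,
    label: str = "",
) -> OverlapResult:
    """OP pooled over a gene set: Σ|T_B(g) ∩ T_K(g)| / Σ|T_B(g)|."""
    num = den = n = 0
    for g in gene_set:
        tb = binding.regulators_of(g)
        num += len(tb & knockout.regulators_of(g))
        den += len(tb)
        n += 1
    return OverlapResult(numerator=num, denominator=den,
                         entity_set_label=label, n_entities=n)


def per_entity_op_table(
    binding: SignificantSetMap,
    knockout: SignificantSetMap,
    entities: Iterable[str],
    level: str = "tf",
) -> pd.DataFrame:
    """Per-TF or per-gene OP table: entity, n_bound, n_affected, n_overlap, op.

    OP is left missing (NaN) for entities with no binding pair.
    """
    rows = []
    for e in sorted(set(entities)):
        if level == "tf":
            b, k = binding.genes_of(e), knockout.genes_of(e)
        elif level == "gene":
            b, k = binding.regulators_of(e), knockout.regulators_of(e)
        else:
            raise ValueError(f"unknown level {level!r}")
        n_overlap = len(b & k)
        rows.append(
            {
                "entity": e,
                "n_bound": len(b),
                "n_affected": len(k),
                "n_overlap": n_overlap,
                "op": n_overlap / len(b) if b else math.nan,
            }
        )
    return pd.DataFrame(rows, columns=["entity", "n_bound", "n_affected", "n_overlap", "op"])


def stratify_top_bottom(
    scores: Mapping[str, float],
    x_percent: float,
    side: str,
) -> frozenset[str]:
    """The floor(N·X/100) entities with largest (top) or smallest (bottom)
    scores.  Boundary ties break by lexicographic identifier so the top
    and bottom strata at X ≤ 50 are always disjoint and runs are
    reproducible."""
    if not scores:
        raise ValueError("no scored entities")
    if not (0.0 < x_percent <= 50.0):
        raise ValueError(f"x_percent out of (0, 50]: {x_percent}")
    if side not in ("top", "bottom"):
        raise ValueError(f"side must be top or bottom, got {side!r}")
    k = math.floor(len(scores) * x_percent / 100.0)
    if k == 0:
        raise ValueError(f"stratum empty at X={x_percent} with N={len(scores)}")
    # one global order: descending score, id ascending; bottom reads from the tail
    ordered = sorted(scores, key=lambda e: (-scores[e], e))
    chosen = ordered[:k] if side == "top" else ordered[-k:]
    return frozenset(chosen)


def proportion_test(
    group1: OverlapResult,
    group2: OverlapResult,
    alternative: str,
) -> ProportionTestResult:
    """One-sided two-sample proportion test with pooled variance.

    z = (p̂1 − p̂2) / sqrt(p̂(1−p̂)(1/n1 + 1/n2)), p̂ pooled; the one-sided
    p-value is the standard-normal tail matching ``alternative``.  When
    the pooled proportion is 0 or 1 the statistic is degenerate and the
    conventional (z=0, p=0.5) is returned with a flag.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    n1, n2 = group1.denominator, group2.denominator
    if n1 == 0 or n2 == 0:
        raise ValueError("proportion test needs non-zero denominators in both groups")
    p1, p2 = group1.numerator / n1, group2.numerator / n2
    pooled = (group1.numerator + group2.numerator) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return ProportionTestResult(
            z=0.0, p_value=0.5, group1=group1, group2=group2,
            alternative=alternative, degenerate=True,
        )
    z = (p1 - p2) / math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    if alternative == "group1_less":
        p_value = stats.norm.cdf(z)
    else:
        p_value = stats.norm.sf(z)
    return ProportionTestResult(
        z=float(z), p_value=float(p_value), group1=group1, group2=group2,
        alternative=alternative,
    )
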