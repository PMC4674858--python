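"""Functional similarity and functional redundancy of transcription factors.

Each TF carries a flat set of functional annotation terms (GO or MIPS
FunCat identifiers, consumed as given — no ontology propagation).  The
functional similarity of two TFs is the Jaccard index of their term sets,

    FS(t, q) = |A_t ∩ A_q| / |A_t ∪ A_q|,

and the functional redundancy of a TF is its best match over every other
TF in the study universe,

    FR(t) = max over q ≠ t of FS(t, q).

A TF with FR near 1 has a functional near-twin that could compensate for
its loss; a TF with FR near 0 does something no other TF is annotated
to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "AnnotationCatalog",
    "RedundancyScores",
    "read_annotation_catalog",
    "write_annotation_catalog",
    "functional_similarity",
    "functional_redundancy",
    "score_all_redundancy",
]


@dataclass(frozen=True)
class AnnotationCatalog:
    """entity → set of annotation term identifiers (flat, source-specific)."""

    terms_by_entity: Mapping[str, frozenset[str]]
    source_label: str = ""

    def __post_init__(self) -> None:
        for entity, terms in self.terms_by_entity.items():
            if "" in terms:
                raise ValueError(f"empty term for entity {entity!r}")

    def terms_of(self, entity: str) -> frozenset[str]:
        return self.terms_by_entity.get(entity, frozenset())


@dataclass(frozen=True)
class RedundancyScores:
    """FR score and argmax partner per TF, plus the exclusion log.

    ``excluded`` lists (tf, reason) for universe TFs that could not be
    scored — no annotation, or no annotated partner.  They are missing
    data, not FR = 0.
    """

    fr_by_tf: Mapping[str, float]
    argmax_partner: Mapping[str, str]
    excluded: tuple[tuple[str, str], ...] = field(default=())

    def __post_init__(self) -> None:
        for t, s in self.fr_by_tf.items():
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"FR out of [0,1] for {t}: {s}")
            if self.argmax_partner.get(t) == t:
                raise ValueError(f"self-partner for {t}")


def read_annotation_catalog(path: str | Path, source_label: str | None = None) -> AnnotationCatalog:
    """Read a two-column `entity<TAB>term` TSV; repeated entity lines
    accumulate into a set.  Lines starting with `#` are ignored."""
    path = Path(path)
    terms: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}:{ln}: malformed annotation line {line!r}")
            terms.setdefault(parts[0], set()).add(parts[1])
    return AnnotationCatalog(
        terms_by_entity={e: frozenset(s) for e, s in terms.items()},
        source_label=source_label if source_label is not None else path.stem,
    )


def write_annotation_catalog(catalog: AnnotationCatalog, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for entity in sorted(catalog.terms_by_entity):
            for term in sorted(catalog.terms_by_entity[entity]):
                fh.write(f"{entity}\t{term}\n")


def functional_similarity(terms_t: frozenset[str] | set[str], terms_q: frozenset[str] | set[str]) -> float:
    """Jaccard index of two term sets; undefined (error) when both are empty."""
    if not terms_t and not terms_q:
        raise ValueError("similarity undefined: both term sets empty")
    inter = len(terms_t & terms_q)
    union = len(terms_t | terms_q)
    return inter / union


def functional_redundancy(
    tf: str,
    catalog: AnnotationCatalog,
    universe_tfs: Iterable[str],
) -> tuple[float, str]:
    """FR(t) = max over annotated q ≠ t in the universe of FS(A_t, A_q).

    Returns (score, argmax partner); ties broken by lexicographic partner
    identifier.  Raises if ``tf`` is unannotated or no annotated partner
    exists.
    """
    terms_t = catalog.terms_of(tf)
    if not terms_t:
        raise ValueError(f"FR undefined: {tf} has no annotation terms")
    best: tuple[float, str] | None = None
    for q in sorted(universe_tfs):
        if q == tf:
            continue
        terms_q = catalog.terms_of(q)
        if not terms_q:
            continue
        fs = functional_similarity(terms_t, terms_q)
        if best is None or fs > best[0]:
            best = (fs, q)
    if best is None:
        raise ValueError(f"FR undefined: no annotated partner for {tf}")
    return best


def score_all_redundancy(
    catalog: AnnotationCatalog,
    universe_tfs: Iterable[str],
) -> RedundancyScores:
    """Score every annotated universe TF; unscorable TFs go to the
    exclusion log instead of receiving FR = 0."""
    tfs = sorted(set(universe_tfs))
    annotated = [t for t in tfs if catalog.terms_of(t)]
    if len(annotated) < 2:
        raise ValueError("need at least 2 annotated TFs in the universe")
    fr: dict[str, float] = {}
    partner: dict[str, str] = {}
    excluded: list[tuple[str, str]] = []
    for t in tfs:
        if not catalog.terms_of(t):
            excluded.append((t, "unannotated"))
            continue
        try:
            score, p = functional_redundancy(t, catalog, tfs)
        except ValueError:
            excluded.append((t, "no annotated partner"))
            continue
        fr[t] = score
        partner[t] = p
    return RedundancyScores(fr_by_tf=fr, argmax_partner=partner, excluded=tuple(excluded))
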