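"""Overrepresentation statistics for thematic clusters.

Two families of tests share one machinery:

* entity overrepresentation — for each (cluster, entity), is the entity
  mentioned in more of the cluster's documents than expected given its
  corpus-wide document frequency?
* category overrepresentation — for each (cluster, category), do more of the
  cluster's proteins map to the category than expected given the background
  protein universe?

Both use the upper-tail hypergeometric probability
P(X >= k) with X ~ Hypergeom(N_bg, K_bg, n) — equivalent to a one-sided
Fisher exact test — and the Benjamini–Hochberg step-up false discovery rate
within each cluster's family of tests.  Raw p and BH-FDR are reported side by
side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import Mention
from .errors import ValidationError
from .themes import ClusteringResult

__all__ = [
    "EnrichmentResult",
    "CategoryMap",
    "hypergeom_upper",
    "bh_fdr",
    "cluster_entity_enrichment",
    "category_enrichment",
    "read_category_map_tsv",
    "write_category_map_tsv",
    "results_to_frame",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """One overrepresentation test: item observed ``k`` times among ``n``
    cluster members, against ``K_bg`` of ``N_bg`` in the background."""

    cluster: int
    item: str
    k: int
    n: int
    K_bg: int
    N_bg: int
    p_value: float
    fdr: float


@dataclass
class CategoryMap:
    """Entity -> category annotations (e.g. disease-ontology terms), with
    human-readable category descriptions."""

    mapping: dict[str, frozenset[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [k for k, v in self.mapping.items() if not v]
        if empty:
            raise ValidationError(f"entities with empty category sets: {empty}")

    @property
    def domain(self) -> set[str]:
        return set(self.mapping)


def hypergeom_upper(k: int, n: int, K_bg: int, N_bg: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k) for X drawn as the
    overlap of an n-subset with a K_bg-subset of an N_bg universe.

    k = 0 returns exactly 1.
    """
    if not (0 <= K_bg <= N_bg and 0 <= n <= N_bg):
        raise ValidationError(f"invalid background: n={n}, K_bg={K_bg}, N_bg={N_bg}")
    if not 0 <= k <= min(n, K_bg):
        raise ValidationError(f"k={k} outside [0, min(n={n}, K_bg={K_bg})]")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N_bg, K_bg, n))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted values, in the input order:
    q_(i) = min_{j >= i} (m * p_(j) / j), clipped at 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    return [float(q) for q in stats.false_discovery_control(p, method="bh")]


def cluster_entity_enrichment(
    mentions: Sequence[Mention],
    clustering: ClusteringResult,
    type_filter: str | None = None,
    alpha: float = 0.1,
    min_count: int = 2,
) -> list[EnrichmentResult]:
    """Per-cluster entity overrepresentation at the document level.

    For cluster c and entity e: k = documents of c mentioning e, n = cluster
    size, K_bg = documents in the whole corpus mentioning e, N_bg = corpus
    size.  Entities observed in fewer than ``min_count`` cluster documents are
    not tested; BH-FDR is computed within each cluster's family of performed
    tests; rows with p >= ``alpha`` are then dropped.  Sorted by (cluster, p,
    entity).
    """
    in_corpus = set(clustering.doc_ids)
    docs_by_entity: dict[str, set[str]] = {}
    for m in mentions:
        if type_filter is not None and m.type != type_filter:
            continue
        if m.doc_id in in_corpus:
            docs_by_entity.setdefault(m.preflabel, set()).add(m.doc_id)
    labels = clustering.labels
    N_bg = len(clustering.doc_ids)
    out: list[EnrichmentResult] = []
    for c in range(clustering.k):
        members = {d for d, l in labels.items() if l == c}
        n = len(members)
        tested: list[tuple[str, int, int, float]] = []
        for entity in sorted(docs_by_entity):
            docs = docs_by_entity[entity]
            k = len(docs & members)
            if k < min_count:
                continue
            p = hypergeom_upper(k, n, len(docs), N_bg)
            tested.append((entity, k, len(docs), p))
        if not tested:
            continue
        fdrs = bh_fdr([t[3] for t in tested])
        for (entity, k, K_bg, p), q in zip(tested, fdrs):
            if p < alpha:
                out.append(
                    EnrichmentResult(
                        cluster=c, item=entity, k=k, n=n,
                        K_bg=K_bg, N_bg=N_bg, p_value=p, fdr=q,
                    )
                )
    out.sort(key=lambda r: (r.cluster, r.p_value, r.item))
    return out


def category_enrichment(
    cluster_entities: Mapping[int, Set[str]],
    catmap: CategoryMap,
    background: Set[str],
) -> list[EnrichmentResult]:
    """Per-cluster category overrepresentation over entity sets.

    Entities without any category mapping are counted out: n is the number of
    mapped cluster entities and N_bg the number of mapped background entities.
    BH-FDR is computed within each cluster's family; all tested categories are
    returned, sorted by (cluster, p, category).
    """
    mapped_bg = set(background) & catmap.domain
    if not mapped_bg:
        raise ValidationError("empty mapped background")
    N_bg = len(mapped_bg)
    bg_by_cat: dict[str, int] = {}
    for e in mapped_bg:
        for cat in catmap.mapping[e]:
            bg_by_cat[cat] = bg_by_cat.get(cat, 0) + 1
    out: list[EnrichmentResult] = []
    for c in sorted(cluster_entities):
        mapped = {e for e in cluster_entities[c] if e in catmap.mapping}
        n = len(mapped)
        if n == 0:
            continue
        k_by_cat: dict[str, int] = {}
        for e in mapped:
            for cat in catmap.mapping[e]:
                k_by_cat[cat] = k_by_cat.get(cat, 0) + 1
        cats = sorted(k_by_cat)
        ps = [hypergeom_upper(k_by_cat[cat], n, bg_by_cat[cat], N_bg) for cat in cats]
        fdrs = bh_fdr(ps)
        for cat, p, q in zip(cats, ps, fdrs):
            out.append(
                EnrichmentResult(
                    cluster=c, item=cat, k=k_by_cat[cat], n=n,
                    K_bg=bg_by_cat[cat], N_bg=N_bg, p_value=p, fdr=q,
                )
            )
    out.sort(key=lambda r: (r.cluster, r.p_value, r.item))
    return out


def read_category_map_tsv(path: str | Path) -> CategoryMap:
    """Read a category map TSV: preflabel, category_id, category_description
    ('#' lines are comments)."""
    mapping: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValidationError(f"line {lineno}: expected 3 tab-separated columns")
        entity, cat, desc = parts
        mapping.setdefault(entity, set()).add(cat)
        if desc:
            descriptions[cat] = desc
    return CategoryMap(
        mapping={k: frozenset(v) for k, v in mapping.items()},
        descriptions=descriptions,
    )


def write_category_map_tsv(catmap: CategoryMap, path: str | Path) -> None:
    lines = ["# preflabel\tcategory_id\tcategory_description"]
    for entity in sorted(catmap.mapping):
        for cat in sorted(catmap.mapping[entity]):
            lines.append("\t".join([entity, cat, catmap.descriptions.get(cat, "")]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster": r.cluster,
                "item": r.item,
                "k": r.k,
                "n": r.n,
                "K_bg": r.K_bg,
                "N_bg": r.N_bg,
                "p_value": r.p_value,
                "fdr": r.fdr,
            }
            for r in results
        ],
        columns=["cluster", "item", "k", "n", "K_bg", "N_bg", "p_value", "fdr"],
    )
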