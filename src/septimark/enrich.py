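"""Consensus miRNA-target selection and Fisher-exact over-representation.

Target sets (one gene set per miRNA, one GMT file per prediction database)
and annotation sets (GO-style terms) are consumed as plain GMT files —
``term <TAB> description <TAB> gene...``.  A consensus target set keeps the
genes predicted by every database (or by at least ``min_dbs`` of them), and
enrichment of a query set against an annotation collection uses the
one-sided Fisher exact (hypergeometric upper-tail) probability

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

with Benjamini-Hochberg adjustment across terms.  Only over-representation
is scored; depletion is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, SeptimarkError, ValidationError


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets over a background universe.

    ``sets`` maps term id -> (description, member genes); every set must be
    non-empty and contained in ``background``.
    """

    sets: Mapping[str, tuple[str, frozenset[str]]]
    background: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "background", frozenset(self.background))
        sets = {term: (desc, frozenset(genes)) for term, (desc, genes) in self.sets.items()}
        object.__setattr__(self, "sets", sets)
        if not sets:
            raise ValidationError("gene-set collection is empty")
        for term, (_, genes) in sets.items():
            if not genes:
                raise ValidationError(f"term {term!r} has an empty gene set")
            stray = genes - self.background
            if stray:
                raise ValidationError(
                    f"term {term!r} contains genes outside the background: {sorted(stray)[:5]}")


def read_gmt(path) -> dict[str, tuple[str, frozenset[str]]]:
    """Parse a GMT file into term -> (description, gene set)."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}:{lineno}: GMT line needs term, description, >=1 gene")
            term, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if term in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate term {term!r}")
            sets[term] = (desc, frozenset(genes))
    if not sets:
        raise ValidationError(f"{path}: GMT file contains no gene sets")
    return sets


def write_gmt(sets: Mapping[str, tuple[str, Iterable[str]]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(sets):
            desc, genes = sets[term]
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def collection_from_gmt(path, background: Iterable[str] | None = None) -> GeneSetCollection:
    """Load an annotation GMT; background defaults to the union of all set genes."""
    sets = read_gmt(path)
    if background is None:
        background = frozenset().union(*(genes for _, genes in sets.values()))
    return GeneSetCollection(sets=sets, background=frozenset(background))


def top_k_by_fold(de: pd.DataFrame, k: int = 10) -> list[str]:
    """The k features with the largest |fold difference| (max of fc and 1/fc).

    Ties break by feature symbol ascending; shorter input returns everything,
    sorted the same way.
    """
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    if de.empty:
        raise SeptimarkError("differential table is empty")
    magnitude = de["fold_change"].where(de["fold_change"] >= 1, 1.0 / de["fold_change"])
    ordered = de.assign(_mag=magnitude).sort_values(
        ["_mag", "feature"], ascending=[False, True], kind="mergesort")
    return ordered["feature"].head(k).tolist()


def target_consensus(per_db_targets: Mapping[str, Iterable[str]],
                     min_dbs: int | None = None) -> frozenset[str]:
    """Genes predicted by every database (default) or by >= ``min_dbs`` of them."""
    if not per_db_targets:
        raise SeptimarkError("no target databases supplied")
    sets = {db: frozenset(genes) for db, genes in per_db_targets.items()}
    need = len(sets) if min_dbs is None else int(min_dbs)
    if not 1 <= need <= len(sets):
        raise ConfigError(f"min_dbs must lie in 1..{len(sets)}, got {min_dbs}")
    counts: dict[str, int] = {}
    for genes in sets.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    return frozenset(g for g, c in counts.items() if c >= need)


def fisher_enrichment(query: Iterable[str], collection: GeneSetCollection) -> pd.DataFrame:
    """One-sided over-representation of a query set in each annotation term.

    Per term of size K in a background of size N, with a query of size n
    overlapping the term in k genes, ``p = P(X >= k)`` for
    X ~ Hypergeometric(N, K, n).  Results carry BH-adjusted p-values and are
    sorted by p ascending (ties by term id).
    """
    query = frozenset(query)
    if not query:
        raise SeptimarkError("query gene set is empty")
    stray = query - collection.background
    if stray:
        raise ValidationError(f"query genes outside the background: {sorted(stray)}")
    N = len(collection.background)
    n = len(query)
    rows = []
    for term in sorted(collection.sets):
        desc, genes = collection.sets[term]
        K = len(genes)
        k = len(query & genes)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "description": desc,
                     "k": k, "K": K, "n": n, "N": N, "p": min(max(p, 0.0), 1.0)})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out = out.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    return out
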