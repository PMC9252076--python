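"""Hypergeometric term and gene-set enrichment with FDR control.

Implements the singular-enrichment-analysis (SEA) step: for each ontology
term, the number k of study genes annotated to it is compared with the
K of N universe genes annotated, via the upper-tail hypergeometric
probability P(X >= k); p-values are corrected with the
Benjamini-Yekutieli method (valid under the arbitrary dependence induced
by the ontology DAG; Benjamini-Hochberg available as an option). Results
from several pool contrasts are merged into a term x contrast FDR matrix
(the cross-comparison view), and the same machinery runs over arbitrary
gene-set collections (GMT) for pathway enrichment.

Annotations must satisfy the true-path rule before testing:
:func:`propagate_annotations` closes each gene's term set under ancestors.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

_ADJUST_METHODS = {"by": "fdr_by", "bh": "fdr_bh"}


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


def propagate_annotations(
    annotations: dict[str, set[str]], graph: nx.MultiDiGraph
) -> dict[str, set[str]]:
    """Close every gene's term set under ancestors (true-path rule).

    Annotations to terms absent from the graph are skipped. Idempotent.
    """
    closure: dict[str, frozenset[str]] = {}
    out: dict[str, set[str]] = {}
    skipped = set()
    for gene, terms in annotations.items():
        full: set[str] = set()
        for t in terms:
            if t not in graph:
                skipped.add(t)
                continue
            if t not in closure:
                closure[t] = frozenset(nx.descendants(graph, t)) | {t}
            full |= closure[t]
        out[gene] = full
    if skipped:
        import logging

        logging.getLogger(__name__).warning(
            "skipped annotations to %d unknown term(s): %s",
            len(skipped),
            sorted(skipped)[:10],
        )
    return out


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric P(X >= k) drawing n from N with K marked."""
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def adjust_pvalues(p, method: str = "by") -> np.ndarray:
    """Multiple-testing adjustment; ``method`` is "by" (default) or "bh".

    Ties in p receive equal adjusted values; results are capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in _ADJUST_METHODS:
        raise ValueError(f"unknown method {method!r}; use 'by' or 'bh'")
    return multipletests(p, method=_ADJUST_METHODS[method])[1]


def by_adjust(p) -> np.ndarray:
    """Benjamini-Yekutieli adjusted p-values."""
    return adjust_pvalues(p, method="by")


def _check_study(study: set[str], universe: set[str]) -> None:
    stray = study - universe
    if stray:
        raise ValueError(
            f"{len(stray)} study gene(s) not in the universe: "
            f"{sorted(stray)[:10]}"
        )


def sea(
    study_genes,
    universe_genes,
    annotations: dict[str, set[str]],
    method: str = "by",
    fdr_threshold: float | None = 0.05,
    min_k: int = 1,
) -> pd.DataFrame:
    """Per-term over-representation of a study list against a universe.

    ``annotations`` must already be propagated (true-path rule). Terms with
    fewer than ``min_k`` study genes are not tested. Returns a DataFrame
    (term, k, n, K, N, p_value, fdr) sorted by p; when ``fdr_threshold``
    is set only rows with fdr below it are returned.
    """
    study_list = list(study_genes)
    study = set(study_list)
    universe = set(universe_genes)
    if len(study) != len(study_list):
        import logging

        logging.getLogger(__name__).warning("duplicate study genes removed")
    _check_study(study, universe)
    term_universe: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in universe:
        for t in annotations.get(gene, ()):
            term_universe[t] = term_universe.get(t, 0) + 1
            if gene in study:
                term_study[t] = term_study.get(t, 0) + 1
    N, n = len(universe), len(study)
    rows = []
    for t, k in term_study.items():
        if k < min_k:
            continue
        K = term_universe[t]
        rows.append((t, k, n, K, N, hypergeom_tail(k, N, K, n)))
    df = pd.DataFrame(
        rows, columns=["term", "k", "n", "K", "N", "p_value"]
    ).sort_values(["p_value", "term"], kind="stable").reset_index(drop=True)
    df["fdr"] = adjust_pvalues(df["p_value"].to_numpy(), method=method)
    if fdr_threshold is not None:
        df = df[df["fdr"] < fdr_threshold].reset_index(drop=True)
    return df


def cross_compare(results_by_contrast: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Merge per-contrast SEA tables into a term x contrast FDR matrix.

    Rows are the union of tested terms, columns the contrasts, cells the
    FDR (NaN = not tested/enriched in that contrast). The matrix carries
    summary counts in ``df.attrs``: terms shared by all contrasts, by a
    majority, and unique to one.
    """
    if len(results_by_contrast) < 2:
        raise ValueError("cross comparison needs >= 2 contrasts")
    cols = {}
    for contrast, df in results_by_contrast.items():
        cols[contrast] = df.set_index("term")["fdr"]
    matrix = pd.DataFrame(cols).sort_index()
    present = matrix.notna().sum(axis=1)
    n_contrasts = matrix.shape[1]
    matrix.attrs["n_shared_all"] = int((present == n_contrasts).sum())
    matrix.attrs["n_shared_majority"] = int((present > n_contrasts / 2).sum())
    matrix.attrs["n_unique"] = int((present == 1).sum())
    return matrix


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT gene-set collection (name, description, genes...)."""
    sets = []
    seen = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, desc, genes = fields[0], fields[1], fields[2:]
            if name in seen:
                raise ValueError(f"duplicate gene-set name {name!r}")
            seen.add(name)
            sets.append(
                GeneSet(name=name, description=desc,
                        genes=frozenset(g for g in genes if g))
            )
    return sets


def pathway_enrich(
    gene_list,
    collection,
    universe_genes,
    method: str = "by",
) -> pd.DataFrame:
    """Over-representation of a gene list in each set of a collection.

    Same hypergeometric machinery as :func:`sea`, applied to gene sets
    restricted to the universe; sets with no study overlap are untested.
    """
    study = set(gene_list)
    if not study:
        raise ValueError("gene list is empty")
    universe = set(universe_genes)
    _check_study(study, universe)
    if not (study & universe):
        raise ValueError("gene list has no overlap with the universe")
    N, n = len(universe), len(study)
    rows = []
    for gs in collection:
        members = gs.genes & universe
        k = len(study & members)
        if k == 0:
            continue
        K = len(members)
        rows.append(
            (gs.name, gs.description, k, n, K, N, hypergeom_tail(k, N, K, n))
        )
    df = pd.DataFrame(
        rows, columns=["set", "description", "k", "n", "K", "N", "p_value"]
    ).sort_values(["p_value", "set"], kind="stable").reset_index(drop=True)
    df["fdr"] = adjust_pvalues(df["p_value"].to_numpy(), method=method)
    df.attrs["adjust_method"] = method
    return df
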