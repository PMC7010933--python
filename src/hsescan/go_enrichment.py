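"""Hypergeometric GO over-representation with BH correction.

For a study set of n genes drawn from a universe of N genes, a term
annotating K universe genes and k study genes is scored with the
hypergeometric upper tail P(X >= k), adjusted across all tested terms
with Benjamini-Hochberg; fold enrichment is (k/n)/(K/N).  Terms are
used exactly as provided in the term-to-gene map — no propagation up
the GO graph is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Union

import pandas as pd
from scipy.stats import hypergeom

from hsescan.response_analysis import adjust_bh


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int  # study genes annotated with the term
    n: int  # study size
    K: int  # universe genes annotated with the term
    N: int  # universe size
    p: float
    q: float
    fold_enrichment: float
    retained: bool


def read_term_map(path) -> dict[str, set[str]]:
    """Two-column TSV (term_id, gene_id) -> {term: set of genes}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term_id", "gene_id"],
                     dtype=str, comment="#")
    out: dict[str, set[str]] = {}
    for term, grp in df.groupby("term_id"):
        out[term] = set(grp["gene_id"])
    return out


def enrich(
    study: Iterable[str],
    universe: Iterable[str],
    term_map: Mapping[str, Union[set, frozenset, list]],
    q_cut: float = 0.01,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of each term in the study set.

    Term gene sets are intersected with the universe first; terms with
    no universe gene are skipped.  Results are sorted by q, then p,
    then term_id, and flagged ``retained`` when q < ``q_cut``.
    """
    study = set(study)
    universe = set(universe)
    if not study or not universe:
        raise ValueError("study and universe must be non-empty")
    if not study <= universe:
        extra = sorted(study - universe)[:3]
        raise ValueError(f"study genes outside the universe, e.g. {extra}")
    N, n = len(universe), len(study)
    rows = []
    for term_id, genes in term_map.items():
        term_genes = set(genes) & universe
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & study)
        p = float(hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N)
        rows.append((term_id, k, K, p, fold))
    if not rows:
        return []
    q = adjust_bh([r[3] for r in rows])
    results = [
        EnrichmentResult(
            term_id=term_id,
            k=k,
            n=n,
            K=K,
            N=N,
            p=p,
            q=float(qi),
            fold_enrichment=fold,
            retained=bool(qi < q_cut),
        )
        for (term_id, k, K, p, fold), qi in zip(rows, q)
    ]
    results.sort(key=lambda r: (r.q, r.p, r.term_id))
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "p": r.p,
                "q": r.q,
                "fold_enrichment": r.fold_enrichment,
                "retained": r.retained,
            }
            for r in results
        ]
    )
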