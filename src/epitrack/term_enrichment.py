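"""Over-representation analysis of an interactor set against term annotations.

One-sided Fisher's exact test (upper-tail hypergeometric) per term against an
explicit background — the whole set of quantified proteins, never an implicit
genome-wide default — with Benjamini-Hochberg adjustment applied within each
annotation namespace (BP/CC/MF/KEGG are separate test families).  Also
produces the long-format protein-to-term mapping used for chord diagrams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationSet",
    "read_gmt",
    "write_gmt",
    "fisher_term_test",
    "bh_adjust",
    "enrich_terms",
    "chord_data",
]


@dataclass
class AnnotationSet:
    """Term -> member mapping, namespaced (e.g. BP, CC, MF, KEGG)."""

    terms: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["term_id", "term_name", "namespace"]))
    members: dict = field(default_factory=dict)  # term_id -> frozenset of ids

    def __len__(self) -> int:
        return len(self.terms)


def read_gmt(path: str | Path, *, namespace: str = "NA") -> AnnotationSet:
    """Read a GMT file (``term<TAB>description<TAB>member...`` per line).

    A description of the form ``namespace:...`` overrides the default
    namespace for that term.  Terms with no members raise.
    """
    rows, members = [], {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs term, "
                             "description and >= 1 member")
        term, desc = parts[0], parts[1]
        ns, name = (desc.split(":", 1) if ":" in desc else (namespace, desc))
        ids = frozenset(p for p in parts[2:] if p)
        if not ids:
            raise ValueError(f"{path}:{lineno}: term {term!r} has no members")
        if term in members:
            raise ValueError(f"{path}:{lineno}: duplicate term id {term!r}")
        rows.append((term, name, ns))
        members[term] = ids
    return AnnotationSet(
        pd.DataFrame(rows, columns=["term_id", "term_name", "namespace"]),
        members,
    )


def write_gmt(annotations: AnnotationSet, path: str | Path) -> Path:
    path = Path(path)
    lines = []
    for row in annotations.terms.itertuples(index=False):
        ids = sorted(annotations.members[row.term_id])
        lines.append("\t".join([row.term_id, f"{row.namespace}:{row.term_name}",
                                *ids]))
    path.write_text("\n".join(lines) + "\n")
    return path


def fisher_term_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    ``k`` query members in the term, ``n`` query size, ``K`` term size in the
    background, ``N`` background size.
    """
    if not (0 <= k <= n <= N and k <= K <= N and k >= max(0, n + K - N) - 0):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q values (order-stable, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_terms(query, annotations: AnnotationSet, background,
                 *, alpha: float = 0.05, include_empty: bool = False
                 ) -> pd.DataFrame:
    """Per-term over-representation table, BH-adjusted within namespace.

    ``query`` is an id iterable or a selection audit DataFrame (selected rows'
    index).  Query ids missing from the background raise, listing them.
    Terms with no query member are excluded by default (they are untestable
    rows that would only inflate the family size m).  Result rows are sorted
    by q, then p, then term id, and carry ``pass_fdr`` at ``alpha``.
    """
    if isinstance(query, pd.DataFrame):
        q_ids = set(query[query["selected"]].index if "selected" in query
                    else query.index)
    else:
        q_ids = set(query)
    bg = set(background)
    missing = q_ids - bg
    if missing:
        raise ValueError(f"query ids missing from background: "
                         f"{sorted(missing)[:10]}")
    N, n = len(bg), len(q_ids)

    rows = []
    for row in annotations.terms.itertuples(index=False):
        members = annotations.members[row.term_id] & bg
        K = len(members)
        if K == 0:
            continue
        k = len(members & q_ids)
        if k == 0 and not include_empty:
            continue
        p = fisher_term_test(k, n, K, N)
        rows.append((row.term_id, row.term_name, row.namespace, k, n, K, N, p))
    result = pd.DataFrame(rows, columns=["term_id", "term_name", "namespace",
                                         "k", "n", "K", "N", "p_value"])
    if result.empty:
        result["q_value"] = []
        result["pass_fdr"] = []
        return result
    result["q_value"] = np.nan
    for ns, idx in result.groupby("namespace").groups.items():
        result.loc[idx, "q_value"] = bh_adjust(result.loc[idx, "p_value"])
    result["pass_fdr"] = result["q_value"] <= alpha
    return result.sort_values(["q_value", "p_value", "term_id"],
                              kind="mergesort").reset_index(drop=True)


def chord_data(results: pd.DataFrame, query, annotations: AnnotationSet,
               *, top_n: int = 15, ratios: dict | None = None) -> pd.DataFrame:
    """Long-format (protein, ratio, term) table for the top terms.

    ``query`` as in :func:`enrich_terms`; ``ratios`` maps protein id to its
    enrichment ratio (taken from a ``mean_ratio`` column when ``query`` is a
    DataFrame).  Proteins in none of the ``top_n`` best-ranked terms are
    excluded; the included-protein count is in ``attrs['n_included']``.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if isinstance(query, pd.DataFrame):
        df = query[query["selected"]] if "selected" in query else query
        q_ids = list(df.index)
        if ratios is None and "mean_ratio" in df:
            ratios = df["mean_ratio"].to_dict()
    else:
        q_ids = list(query)
    ratios = ratios or {}
    top_terms = results.head(top_n)

    rows = []
    for term_row in top_terms.itertuples(index=False):
        members = annotations.members[term_row.term_id]
        for pid in q_ids:
            if pid in members:
                rows.append((pid, ratios.get(pid, np.nan), term_row.term_id,
                             term_row.term_name))
    out = pd.DataFrame(rows, columns=["protein_id", "ratio", "term_id",
                                      "term_name"])
    out.attrs["n_included"] = out["protein_id"].nunique()
    out.attrs["n_query"] = len(q_ids)
    return out
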