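"""Hypergeometric over-representation analysis of protein sets.

A generic replacement for web-service GO/KEGG enrichment: given a
selected accession set (e.g. glycoproteins carrying altered
site-specific glycans), a background set, and user-supplied term sets
(GMT format), each term is scored with the one-sided hypergeometric
upper tail

    p = P(X >= k),  X ~ Hypergeom(N=|background|,
                                  K=|term ∩ background|,
                                  n=|selected|)

where k is the observed overlap.  Terms are retained when the overlap
count reaches ``min_count`` (default 3, i.e. "count > 2") and
p < alpha (default 0.05) on the raw p-value; a Benjamini-Hochberg
column is emitted for reference but does not participate in
filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["TermSet", "read_gmt", "overrepresentation_test"]


@dataclass(frozen=True)
class TermSet:
    """One annotation term with its member accessions."""

    term_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"term {self.term_id!r} has no members")


def read_gmt(path) -> list[TermSet]:
    """Read term sets from a GMT file (term, description, members...)."""
    terms = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT lines need term, description "
                    "and at least one member"
                )
            members = frozenset(m for m in fields[2:] if m)
            terms.append(TermSet(fields[0], fields[1], members))
    return terms


def overrepresentation_test(
    selected: Iterable[str],
    background: Iterable[str],
    terms: Sequence[TermSet],
    min_count: int = 3,
    alpha: float = 0.05,
    keep_all: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` within each term.

    Parameters
    ----------
    selected, background
        Accession sets; ``selected`` must be a subset of ``background``.
    min_count
        Minimum overlap k for a term to be retained.
    alpha
        Raw-p threshold (exclusive) for retention.
    keep_all
        Return all terms (with a ``retained`` column) instead of only
        the filtered rows.

    Returns
    -------
    DataFrame sorted ascending by p-value with columns term_id, name,
    overlap, term_size, term_in_background, selected_size,
    background_size, p_value, bh_q (BH over all tested terms).
    """
    sel = set(selected)
    bg = set(background)
    stray = sorted(sel - bg)
    if stray:
        raise ValueError(
            f"selected accessions missing from background: {stray}"
        )
    N, n = len(bg), len(sel)

    rows = []
    for t in terms:
        in_bg = t.members & bg
        k = len(t.members & sel)
        K = len(in_bg)
        # P(X >= k) with survival function at k-1
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        p = min(p, 1.0)
        rows.append(
            {
                "term_id": t.term_id,
                "name": t.name,
                "overlap": k,
                "term_size": len(t.members),
                "term_in_background": K,
                "selected_size": n,
                "background_size": N,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["bh_q"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["retained"] = (out["overlap"] >= min_count) & (
            out["p_value"] < alpha
        )
        out = out.sort_values(
            ["p_value", "term_id"], kind="mergesort"
        ).reset_index(drop=True)
        if not keep_all:
            out = out[out["retained"]].drop(columns="retained").reset_index(
                drop=True
            )
    return out
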