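"""Census-style profiling of a glyco-PSM table.

Profiling summarizes identifications only — reporter intensities play
no role — so it is invariant to row order and channel subsetting, and
it keeps PSMs whose reporter vectors are incomplete.

The central object is the glycan x glycosite PSM-count matrix; its
marginals give the number of glycosites modified by each glycan and
the number of glycans observed at each site.  On top of it sit the
PSM-weighted feature summaries: subtype percentages (over the three
canonical subtypes complex / oligo-mannose / hybrid), antenna-number
fractions among complex-glycan PSMs, and binned sialic-acid and fucose
counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .glycan import GlycanSubtype, classify_glycan, parse_composition

__all__ = [
    "SiteGlycanMatrix",
    "build_site_glycan_matrix",
    "subtype_psm_fractions",
    "rank_glycans_by_sites",
    "glycan_feature_distribution",
    "site_subtype_purity",
    "classify_table",
]

#: Binning for fucose counts per glycan (PSM-weighted summaries).
FUCOSE_BINS = ("0", "1", ">=2")
#: Binning for sialic-acid counts.
SIALYL_BINS = ("0", "1", "2", "3", ">=4")


@dataclass(frozen=True)
class SiteGlycanMatrix:
    """PSM counts per (glycan, glycosite) with marginals.

    ``counts`` is glycans x sites; ``glycans_per_site`` and
    ``sites_per_glycan`` are support sizes (numbers of nonzero cells in
    a column / row); ``psms_per_glycan`` is the row sum.
    """

    counts: pd.DataFrame
    glycans_per_site: pd.Series
    sites_per_glycan: pd.Series
    psms_per_glycan: pd.Series
    n_psms: int
    n_glycopeptides: int


def _site_key(df: pd.DataFrame) -> pd.Series:
    return df["protein"].astype(str) + "@" + df["glycosite"].astype(int).astype(str)


def build_site_glycan_matrix(psms: pd.DataFrame) -> SiteGlycanMatrix:
    """Aggregate PSMs into the glycan x glycosite count matrix.

    The number of distinct glycopeptides equals the number of nonzero
    cells; cell values sum to the PSM total.
    """
    if len(psms) == 0:
        raise ValueError("empty PSM table")
    site = _site_key(psms)
    counts = (
        pd.crosstab(psms["glycan"], site)
        .rename_axis(index="glycan", columns="site")
    )
    nonzero = counts.to_numpy() > 0
    return SiteGlycanMatrix(
        counts=counts,
        glycans_per_site=pd.Series(
            nonzero.sum(axis=0), index=counts.columns, name="glycans_per_site"
        ),
        sites_per_glycan=pd.Series(
            nonzero.sum(axis=1), index=counts.index, name="sites_per_glycan"
        ),
        psms_per_glycan=counts.sum(axis=1).rename("n_psms"),
        n_psms=int(counts.to_numpy().sum()),
        n_glycopeptides=int(nonzero.sum()),
    )


def classify_table(
    glycans: Iterable[str],
    bisecting_annotation: Optional[Iterable[str]] = None,
    core_fucose_override: Optional[Mapping[str, bool]] = None,
) -> pd.DataFrame:
    """Classify each distinct composition string once.

    Returns a table indexed by canonical glycan string with columns
    subtype, mannose_count, antennae, n_sia, n_fuc_total, n_core_fuc,
    n_antennary_fuc, bisecting.
    """
    rows = {}
    for g in glycans:
        if g in rows:
            continue
        c = classify_glycan(
            parse_composition(g),
            bisecting_annotation=bisecting_annotation,
            core_fucose_override=core_fucose_override,
        )
        rows[g] = {
            "subtype": c.subtype.value,
            "mannose_count": c.mannose_count,
            "antennae": c.antennae,
            "n_sia": c.n_sia,
            "n_fuc_total": c.n_fuc_total,
            "n_core_fuc": c.n_core_fuc,
            "n_antennary_fuc": c.n_antennary_fuc,
            "bisecting": c.bisecting,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "glycan"
    return out


_THREE_SUBTYPES = (
    GlycanSubtype.COMPLEX.value,
    GlycanSubtype.OLIGO_MANNOSE.value,
    GlycanSubtype.HYBRID.value,
)


def subtype_psm_fractions(
    psms: pd.DataFrame, classes: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """PSM counts and percentages per glycan subtype.

    Percentages are reported over the sum of the three canonical
    subtypes (complex, oligo-mannose, hybrid), rounded to one decimal;
    pauci/other PSMs are counted but excluded from that denominator
    (their ``percent`` is NaN).
    """
    if classes is None:
        classes = classify_table(psms["glycan"].unique())
    subtype = classes["subtype"].reindex(psms["glycan"]).to_numpy()
    counts = pd.Series(subtype).value_counts()
    counts = counts.reindex(
        [s for s in (*_THREE_SUBTYPES, GlycanSubtype.PAUCI_OTHER.value) if s in counts.index]
    )
    denom = counts.reindex(_THREE_SUBTYPES).fillna(0).sum()
    out = counts.rename_axis("subtype").rename("n_psms").reset_index()
    out["percent"] = [
        round(100.0 * n / denom, 1) if s in _THREE_SUBTYPES and denom > 0 else np.nan
        for s, n in zip(out["subtype"], out["n_psms"])
    ]
    return out


def rank_glycans_by_sites(matrix: SiteGlycanMatrix, n: int = 10) -> pd.DataFrame:
    """Top-n glycans by number of modified glycosites.

    Ties broken by total PSM count (descending), then canonical glycan
    string (ascending) so the ranking is deterministic.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    tbl = pd.DataFrame(
        {
            "n_sites": matrix.sites_per_glycan,
            "n_psms": matrix.psms_per_glycan,
        }
    ).rename_axis("glycan").reset_index()
    tbl = tbl.sort_values(
        ["n_sites", "n_psms", "glycan"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return tbl.head(n)


def glycan_feature_distribution(
    psms: pd.DataFrame, classes: Optional[pd.DataFrame] = None
) -> dict[str, pd.Series]:
    """PSM fractions by antenna number, sialyl-count bin and
    fucose-count bin.

    Antenna fractions are over complex-glycan PSMs only; sialyl bins
    are {0,1,2,3,>=4} and fucose bins {0,1,>=2} over all PSMs.  Each
    returned Series sums to 1 (when its denominator is nonzero).
    """
    if classes is None:
        classes = classify_table(psms["glycan"].unique())
    joined = classes.reindex(psms["glycan"])

    out: dict[str, pd.Series] = {}

    complex_mask = joined["subtype"].to_numpy() == GlycanSubtype.COMPLEX.value
    ant = joined.loc[complex_mask, "antennae"].astype(int)
    if len(ant):
        out["antennae"] = (
            ant.value_counts(normalize=True).sort_index().rename("fraction")
        )
    else:
        out["antennae"] = pd.Series(dtype=float, name="fraction")

    sia = joined["n_sia"].to_numpy()
    sia_binned = np.where(sia >= 4, ">=4", sia.astype(str))
    out["sialyl"] = (
        pd.Series(sia_binned)
        .value_counts(normalize=True)
        .reindex([b for b in SIALYL_BINS if b in set(sia_binned)])
        .rename("fraction")
    )

    fuc = joined["n_fuc_total"].to_numpy()
    fuc_binned = np.where(fuc >= 2, ">=2", fuc.astype(str))
    out["fucose"] = (
        pd.Series(fuc_binned)
        .value_counts(normalize=True)
        .reindex([b for b in FUCOSE_BINS if b in set(fuc_binned)])
        .rename("fraction")
    )
    return out


def site_subtype_purity(
    psms: pd.DataFrame, classes: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Per-site subtype occupancy: which sites are solely occupied by
    one glycan subtype.

    Returns one row per glycosite with ``n_subtypes``, ``sole_subtype``
    (the subtype when only one is observed, else None).
    """
    if classes is None:
        classes = classify_table(psms["glycan"].unique())
    df = pd.DataFrame(
        {
            "site": _site_key(psms),
            "subtype": classes["subtype"].reindex(psms["glycan"]).to_numpy(),
        }
    )
    per_site = df.groupby("site")["subtype"].agg(["nunique", "unique"])
    return pd.DataFrame(
        {
            "site": per_site.index,
            "n_subtypes": per_site["nunique"].to_numpy(),
            "sole_subtype": [
                u[0] if len(u) == 1 else None for u in per_site["unique"]
            ],
        }
    ).reset_index(drop=True)
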