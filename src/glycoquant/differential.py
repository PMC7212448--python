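"""Fold-change cascades for differential site-specific glycosylation.

The pooled one-channel-per-group TMT design has no replicates, so
differential calls are made by fold-change thresholds rather than by a
per-feature test statistic.  Two cascades are implemented:

* **Commonly altered** (default cutoff 2-fold): a glycopeptide is
  called up when its tumor/paracancer ratio reaches the cutoff in
  *both* AFP groups, down when both fall below the reciprocal.
  Discordant features (2-fold up in one group, 2-fold down in the
  other) are labelled ``none`` and flagged separately.

* **AFP-group-unique** (default cutoff 1.5-fold): a glycopeptide is
  unique to the low-AFP group when its tumorL/tumorH ratio reaches the
  cutoff while the paraL/paraH comparison stays within the cutoff at
  all three levels — glycopeptide ratio, parent-protein ratio and
  occupancy change; the high-AFP call is symmetric.  Features whose
  parent protein was not quantified are ineligible.

Boundary handling is inclusive on both sides: |log2 r| >= log2(cutoff)
counts as changed, |log2 r| <= log2(cutoff) counts as stable.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .glycan import GlycanClass, classify_glycan, parse_composition
from .tables_io import (
    CMP_PARA_LOW_VS_HIGH,
    CMP_TUMOR_LOW_VS_HIGH,
    CMP_TUMOR_VS_PARA_HIGH,
    CMP_TUMOR_VS_PARA_LOW,
)

__all__ = [
    "within_fold_fraction",
    "call_common_altered",
    "call_group_unique",
    "call_differential",
    "summarize_changed_features",
    "changed_percentage",
]

DEFAULT_COMMON_CUTOFF = 2.0
DEFAULT_UNIQUE_CUTOFF = 1.5


def within_fold_fraction(log2_ratios, k: float) -> float:
    """Fraction of features whose |log2 ratio| <= log2(k).

    Used to report ratio-stability frequencies (e.g. the fraction of
    glycopeptides varying within two-fold between the two paracancer
    groups) and to justify fold cutoffs.  NaN ratios are excluded from
    both numerator and denominator.
    """
    if k <= 1:
        raise ValueError(f"fold k must be > 1, got {k}")
    arr = np.asarray(log2_ratios, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("no finite ratios given")
    return float(np.mean(np.abs(arr) <= np.log2(k)))


def changed_percentage(n_changed: int, n_total: int) -> float:
    """Percentage of changed features, rounded to one decimal for
    reporting (82 of 1110 -> 7.4)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_changed / n_total, 1)


def call_common_altered(
    features: pd.DataFrame,
    cutoff: float = DEFAULT_COMMON_CUTOFF,
    comparisons: Sequence[str] = (CMP_TUMOR_VS_PARA_LOW, CMP_TUMOR_VS_PARA_HIGH),
) -> pd.DataFrame:
    """Label glycopeptides commonly altered in both AFP groups.

    Returns a table with ``feature_id``, ``common_label`` in
    {up, down, none} and a ``discordant`` flag for features that pass
    the cutoff in opposite directions in the two groups.
    """
    if cutoff <= 1:
        raise ValueError(f"cutoff must be > 1, got {cutoff}")
    t = np.log2(cutoff)
    cols = [f"log2_{c}" for c in comparisons]
    r = features[cols].to_numpy(dtype=float)
    up = (r >= t).all(axis=1)
    down = (r <= -t).all(axis=1)
    discordant = (np.abs(r) >= t).all(axis=1) & ~up & ~down
    label = np.where(up, "up", np.where(down, "down", "none"))
    return pd.DataFrame(
        {
            "feature_id": features["feature_id"].to_numpy(),
            "common_label": label,
            "discordant": discordant,
        }
    )


def call_group_unique(
    features: pd.DataFrame,
    occupancy: pd.DataFrame,
    cutoff: float = DEFAULT_UNIQUE_CUTOFF,
    tumor_comparison: str = CMP_TUMOR_LOW_VS_HIGH,
    para_comparison: str = CMP_PARA_LOW_VS_HIGH,
) -> pd.DataFrame:
    """Label glycopeptides uniquely increased in one AFP tumor group.

    low-AFP-unique requires tumorL/tumorH >= cutoff and paracancer
    stability (|log2| <= log2(cutoff)) at the glycopeptide, parent
    protein and occupancy levels; high-AFP-unique is symmetric.  The
    returned level-evidence flags record which paracancer gates passed.
    """
    if cutoff <= 1:
        raise ValueError(f"cutoff must be > 1, got {cutoff}")
    t = np.log2(cutoff)
    occ = occupancy.set_index("feature_id")
    idx = features["feature_id"]

    tumor_r = features[f"log2_{tumor_comparison}"].to_numpy(dtype=float)
    para_glyco = features[f"log2_{para_comparison}"].to_numpy(dtype=float)
    para_protein = (
        occ[f"protein_log2_{para_comparison}"].reindex(idx).to_numpy(dtype=float)
    )
    para_occ = (
        occ[f"occ_log2_{para_comparison}"].reindex(idx).to_numpy(dtype=float)
    )
    parent_ok = (
        occ["parent_protein_quantified"]
        .reindex(idx)
        .fillna(False)
        .to_numpy(dtype=bool)
    )

    glyco_stable = np.abs(para_glyco) <= t
    protein_stable = parent_ok & (np.abs(para_protein) <= t)
    occ_stable = parent_ok & (np.abs(para_occ) <= t)
    para_stable = glyco_stable & protein_stable & occ_stable

    low = (tumor_r >= t) & para_stable
    high = (tumor_r <= -t) & para_stable
    label = np.where(low, "lowAFP-unique", np.where(high, "highAFP-unique", "none"))
    return pd.DataFrame(
        {
            "feature_id": idx.to_numpy(),
            "unique_label": label,
            "parent_protein_quantified": parent_ok,
            "para_glyco_stable": glyco_stable,
            "para_protein_stable": protein_stable,
            "para_occupancy_stable": occ_stable,
        }
    )


def call_differential(
    features: pd.DataFrame,
    occupancy: pd.DataFrame,
    common_cutoff: float = DEFAULT_COMMON_CUTOFF,
    unique_cutoff: float = DEFAULT_UNIQUE_CUTOFF,
) -> pd.DataFrame:
    """Run both cascades and merge into one calls table carrying the
    feature's ratios, occupancy values, labels and evidence flags."""
    common = call_common_altered(features, cutoff=common_cutoff)
    unique = call_group_unique(features, occupancy, cutoff=unique_cutoff)
    out = features.merge(common, on="feature_id").merge(
        unique, on="feature_id"
    )
    occ_cols = [c for c in occupancy.columns if c.startswith(("occ_", "protein_log2_"))]
    out = out.merge(
        occupancy[["feature_id"] + occ_cols], on="feature_id", how="left"
    )
    return out


_CHANGED_SETS = {
    "common-up": lambda df: df["common_label"] == "up",
    "common-down": lambda df: df["common_label"] == "down",
    "low-unique": lambda df: df["unique_label"] == "lowAFP-unique",
    "high-unique": lambda df: df["unique_label"] == "highAFP-unique",
}


def summarize_changed_features(
    calls: pd.DataFrame,
    bisecting_annotation: Optional[Iterable[str]] = None,
    core_fucose_override: Optional[Mapping[str, bool]] = None,
) -> pd.DataFrame:
    """Frequency table of glycan features among each changed set.

    For every changed set (common-up, common-down, low-unique,
    high-unique) counts glycopeptides by glycan subtype, antenna
    number, sialic-acid count, core-fucose status and bisecting status.
    ``calls`` must carry a ``glycan`` column of canonical composition
    strings.  Rows are (set, dimension, bin, count); within each
    (set, dimension) the counts sum to the set's size.
    """
    rows = []
    cache: dict[str, GlycanClass] = {}

    def cls_of(g: str) -> GlycanClass:
        if g not in cache:
            cache[g] = classify_glycan(
                parse_composition(g),
                bisecting_annotation=bisecting_annotation,
                core_fucose_override=core_fucose_override,
            )
        return cache[g]

    for set_name, selector in _CHANGED_SETS.items():
        sub = calls.loc[selector(calls)]
        dims: dict[str, dict] = {
            "subtype": {},
            "antennae": {},
            "n_sia": {},
            "core_fucose": {},
            "bisecting": {},
        }
        for g in sub["glycan"]:
            c = cls_of(g)
            dims["subtype"][c.subtype.value] = (
                dims["subtype"].get(c.subtype.value, 0) + 1
            )
            ant = "n/a" if c.antennae is None else str(c.antennae)
            dims["antennae"][ant] = dims["antennae"].get(ant, 0) + 1
            sia = str(c.n_sia)
            dims["n_sia"][sia] = dims["n_sia"].get(sia, 0) + 1
            cf = "core-fucosylated" if c.n_core_fuc > 0 else "no-core-fucose"
            dims["core_fucose"][cf] = dims["core_fucose"].get(cf, 0) + 1
            dims["bisecting"][c.bisecting] = (
                dims["bisecting"].get(c.bisecting, 0) + 1
            )
        for dim, counter in dims.items():
            for bin_name, count in sorted(counter.items()):
                rows.append((set_name, dim, bin_name, count))
    return pd.DataFrame(
        rows, columns=["set", "dimension", "bin", "count"]
    )
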