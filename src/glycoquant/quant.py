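"""TMT reporter quantitation: channel normalization, median feature
values, comparison ratios and glycosylation-occupancy changes.

Normalization derives one positive factor per channel from the protein
(global-proteome) PSMs only: for every complete protein PSM the channel
intensity is divided by the geometric mean of that PSM's intensities
across channels, and the factor is the per-channel median of those
scale-free values.  Dividing all intensities by the factors equalizes
channel medians, removing channel loading differences while leaving
within-PSM ratios intact.

Feature quantitation follows the median-ratio recipe: PSMs are grouped
into features (glycopeptide = protein + glycosite + glycan, or protein
accession), features with fewer than ``min_psms`` complete PSMs are
dropped, each channel value is the median of the normalized PSM
intensities, and each named comparison yields
``log2(numerator channel value / denominator channel value)``.

Glycosylation occupancy change isolates glycosylation-level from
expression-level effects: per comparison it is the glycopeptide log2
ratio minus the parent protein's log2 ratio.  Glycopeptides whose
parent protein did not pass quantitation carry no occupancy value.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .tables_io import ChannelDesign

__all__ = [
    "compute_channel_factors",
    "normalize_intensities",
    "quantify_features",
    "occupancy_ratios",
    "glycopeptide_id",
]

#: Default PSM-depth threshold for quantifying a feature.
DEFAULT_MIN_PSMS = 5


def glycopeptide_id(df: pd.DataFrame) -> pd.Series:
    """Feature id of a glycopeptide: ``protein|glycosite|glycan``."""
    return (
        df["protein"].astype(str)
        + "|"
        + df["glycosite"].astype(int).astype(str)
        + "|"
        + df["glycan"].astype(str)
    )


def _complete_mask(df: pd.DataFrame, channels) -> np.ndarray:
    if "complete" in df.columns:
        return df["complete"].to_numpy(dtype=bool)
    vals = df[list(channels)].to_numpy(dtype=float)
    return np.isfinite(vals).all(axis=1) & (vals > 0).all(axis=1)


def compute_channel_factors(
    protein_psms: pd.DataFrame, design: ChannelDesign
) -> pd.Series:
    """Per-channel normalization factors from complete protein PSMs.

    factor_c = median over PSMs of I_c / geomean_channels(I).

    Raises
    ------
    ValueError
        If no complete protein PSM is available.
    """
    channels = list(design.channels)
    mask = _complete_mask(protein_psms, channels)
    if not mask.any():
        raise ValueError("no complete protein PSMs to derive factors from")
    vals = protein_psms.loc[mask, channels].to_numpy(dtype=float)
    log_vals = np.log(vals)
    rel = np.exp(log_vals - log_vals.mean(axis=1, keepdims=True))
    factors = np.median(rel, axis=0)
    return pd.Series(factors, index=channels, name="factor")


def normalize_intensities(
    psms: pd.DataFrame, factors: pd.Series, design: ChannelDesign
) -> pd.DataFrame:
    """Divide each channel's intensities by its factor (copy)."""
    out = psms.copy()
    for ch in design.channels:
        out[ch] = out[ch] / factors[ch]
    return out


def quantify_features(
    psms: pd.DataFrame,
    factors: pd.Series,
    design: ChannelDesign,
    min_psms: int = DEFAULT_MIN_PSMS,
    kind: str = "glyco",
) -> pd.DataFrame:
    """Median-based feature quantitation.

    Parameters
    ----------
    psms
        Validated PSM table (see :mod:`glycoquant.tables_io`).
    factors
        Channel factors from :func:`compute_channel_factors`.
    min_psms
        Minimum number of complete PSMs for a feature to be emitted.
    kind
        ``"glyco"`` groups by (protein, glycosite, glycan);
        ``"protein"`` groups by accession.

    Returns
    -------
    DataFrame with one row per quantified feature: ``feature_id``, the
    grouping keys, ``n_psms``, one ``value_<channel>`` column per
    channel and one ``log2_<comparison>`` column per named comparison.
    Output is sorted by feature_id, so row order of the input never
    matters.
    """
    if min_psms < 1:
        raise ValueError(f"min_psms must be >= 1, got {min_psms}")
    channels = list(design.channels)
    mask = _complete_mask(psms, channels)
    work = psms.loc[mask].copy()
    if kind == "glyco":
        keys = ["protein", "glycosite", "glycan"]
        work["feature_id"] = glycopeptide_id(work)
    elif kind == "protein":
        keys = ["protein"]
        work["feature_id"] = work["protein"].astype(str)
    else:
        raise ValueError(f"kind must be 'glyco' or 'protein', got {kind!r}")

    for ch in channels:
        work[ch] = work[ch] / factors[ch]

    grouped = work.groupby("feature_id", sort=True)
    n = grouped.size()
    medians = grouped[channels].median()
    key_table = grouped[keys].first()

    enough = n[n >= min_psms].index
    out = key_table.loc[enough].copy()
    out.insert(len(keys), "n_psms", n.loc[enough])
    for ch in channels:
        out[f"value_{ch}"] = medians.loc[enough, ch]
    for name, (num, den) in design.comparisons.items():
        out[f"log2_{name}"] = np.log2(
            out[f"value_{num}"] / out[f"value_{den}"]
        )
    return out.reset_index()


def occupancy_ratios(
    glyco_features: pd.DataFrame,
    protein_features: pd.DataFrame,
    design: ChannelDesign,
) -> pd.DataFrame:
    """Per-comparison occupancy log2 changes.

    Joins each quantified glycopeptide to its parent protein by
    accession.  Output columns per comparison: the parent's
    ``protein_log2_<cmp>`` and ``occ_log2_<cmp>`` = glycopeptide log2
    ratio - protein log2 ratio; both are NaN (and
    ``parent_protein_quantified`` False) when the parent protein is not
    in ``protein_features``.
    """
    prot = protein_features.set_index("protein")
    out = glyco_features[["feature_id", "protein"]].copy()
    quantified = out["protein"].isin(prot.index)
    out["parent_protein_quantified"] = quantified.to_numpy()
    for name in design.comparisons:
        prot_col = prot[f"log2_{name}"].reindex(out["protein"]).to_numpy()
        out[f"protein_log2_{name}"] = prot_col
        out[f"occ_log2_{name}"] = (
            glyco_features[f"log2_{name}"].to_numpy() - prot_col
        )
    return out
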