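"""End-to-end convenience wrapper: PSM tables in, calls tables out."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from . import differential, quant
from .tables_io import ChannelDesign

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    factors: pd.Series
    glyco_features: pd.DataFrame
    protein_features: pd.DataFrame
    occupancy: pd.DataFrame
    calls: pd.DataFrame


def run_pipeline(
    glyco_psms: pd.DataFrame,
    protein_psms: pd.DataFrame,
    design: Optional[ChannelDesign] = None,
    min_psms: int = quant.DEFAULT_MIN_PSMS,
    common_cutoff: float = differential.DEFAULT_COMMON_CUTOFF,
    unique_cutoff: float = differential.DEFAULT_UNIQUE_CUTOFF,
) -> PipelineResult:
    """Normalize, quantify, derive occupancy and call differential
    glycopeptides with the default thresholds (>=5 PSMs, 2-fold common,
    1.5-fold group-unique)."""
    if design is None:
        design = ChannelDesign.default()
    factors = quant.compute_channel_factors(protein_psms, design)
    glyco_features = quant.quantify_features(
        glyco_psms, factors, design, min_psms=min_psms, kind="glyco"
    )
    protein_features = quant.quantify_features(
        protein_psms, factors, design, min_psms=min_psms, kind="protein"
    )
    occupancy = quant.occupancy_ratios(glyco_features, protein_features, design)
    calls = differential.call_differential(
        glyco_features,
        occupancy,
        common_cutoff=common_cutoff,
        unique_cutoff=unique_cutoff,
    )
    return PipelineResult(
        factors=factors,
        glyco_features=glyco_features,
        protein_features=protein_features,
        occupancy=occupancy,
        calls=calls,
    )
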