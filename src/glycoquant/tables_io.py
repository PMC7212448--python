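"""Reading, validating and writing PSM and result tables.

The pipeline consumes two tab-separated PSM tables produced by an
upstream search engine:

* glyco-PSM table: one row per glycopeptide-spectrum match with columns
  ``spectrum_id``, ``peptide``, ``protein``, ``glycosite``, ``glycan``
  and one reporter-intensity column per TMT channel;
* protein-PSM table: the same minus the glyco columns.

Glycosites are 1-based positions in the protein sequence; peptide
strings mark the glycosylated asparagine with ``#`` directly after it
(``YKN#NSDISSTR``).  Intensity columns are named after the channel
labels (``126``, ``127N`` ...).

Rows with a missing, zero or non-finite intensity in any channel are
kept but flagged incomplete (``complete == False``): profiling is a
census over identifications and keeps them, quantitation requires a
full reporter vector and drops them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .glycan import format_composition, parse_composition

__all__ = [
    "ChannelDesign",
    "TableError",
    "read_psm_table",
    "write_results",
    "GROUP_TUMOR_LOW",
    "GROUP_PARA_LOW",
    "GROUP_TUMOR_HIGH",
    "GROUP_PARA_HIGH",
    "CMP_TUMOR_VS_PARA_LOW",
    "CMP_TUMOR_VS_PARA_HIGH",
    "CMP_TUMOR_LOW_VS_HIGH",
    "CMP_PARA_LOW_VS_HIGH",
]

GROUP_TUMOR_LOW = "tumor-lowAFP"
GROUP_PARA_LOW = "para-lowAFP"
GROUP_TUMOR_HIGH = "tumor-highAFP"
GROUP_PARA_HIGH = "para-highAFP"

# Canonical comparison names used throughout the pipeline.
CMP_TUMOR_VS_PARA_LOW = "tumorL_vs_paraL"
CMP_TUMOR_VS_PARA_HIGH = "tumorH_vs_paraH"
CMP_TUMOR_LOW_VS_HIGH = "tumorL_vs_tumorH"
CMP_PARA_LOW_VS_HIGH = "paraL_vs_paraH"

GLYCO_KEY_COLUMNS = ["spectrum_id", "peptide", "protein", "glycosite", "glycan"]
PROTEIN_KEY_COLUMNS = ["spectrum_id", "peptide", "protein"]


class TableError(ValueError):
    """Raised for unreadable or (in strict mode) partially invalid tables."""


@dataclass(frozen=True)
class ChannelDesign:
    """Ordered TMT channels, their sample-group assignment and the
    named channel comparisons (numerator, denominator)."""

    channels: tuple[str, ...]
    groups: Mapping[str, str]
    comparisons: Mapping[str, tuple[str, str]]

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channel labels")
        missing = [c for c in self.channels if c not in self.groups]
        if missing:
            raise ValueError(f"channels without group assignment: {missing}")
        extra = [c for c in self.groups if c not in self.channels]
        if extra:
            raise ValueError(f"groups reference unknown channels: {extra}")
        for name, (num, den) in self.comparisons.items():
            for ch in (num, den):
                if ch not in self.channels:
                    raise ValueError(
                        f"comparison {name!r} references unknown channel {ch!r}"
                    )

    @classmethod
    def default(cls) -> "ChannelDesign":
        """The 4-plex tumor/paracancer design: 126 = paracancer-lowAFP,
        127N = tumor-lowAFP, 128C = paracancer-highAFP, 129N =
        tumor-highAFP, with the four standard comparisons."""
        return cls(
            channels=("126", "127N", "128C", "129N"),
            groups={
                "126": GROUP_PARA_LOW,
                "127N": GROUP_TUMOR_LOW,
                "128C": GROUP_PARA_HIGH,
                "129N": GROUP_TUMOR_HIGH,
            },
            comparisons={
                CMP_TUMOR_VS_PARA_LOW: ("127N", "126"),
                CMP_TUMOR_VS_PARA_HIGH: ("129N", "128C"),
                CMP_TUMOR_LOW_VS_HIGH: ("127N", "129N"),
                CMP_PARA_LOW_VS_HIGH: ("126", "128C"),
            },
        )

    @classmethod
    def from_dict(cls, d: Mapping) -> "ChannelDesign":
        return cls(
            channels=tuple(str(c) for c in d["channels"]),
            groups={str(k): str(v) for k, v in d["groups"].items()},
            comparisons={
                str(k): (str(v[0]), str(v[1]))
                for k, v in d["comparisons"].items()
            },
        )

    @classmethod
    def from_yaml(cls, path) -> "ChannelDesign":
        with open(path, "rt", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "channels": list(self.channels),
            "groups": dict(self.groups),
            "comparisons": {k: list(v) for k, v in self.comparisons.items()},
        }

    def channel_for_group(self, group: str) -> str:
        hits = [c for c in self.channels if self.groups[c] == group]
        if len(hits) != 1:
            raise ValueError(f"group {group!r} maps to {len(hits)} channels")
        return hits[0]


def read_psm_table(
    path,
    design: ChannelDesign,
    kind: str = "glyco",
    strict: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Read and validate a PSM table.

    Returns the validated table (with canonicalized glycan strings and a
    boolean ``complete`` column) and a list of per-row error messages
    for rows that were rejected.  With ``strict=True`` any rejected row
    raises :class:`TableError` instead.
    """
    if kind not in ("glyco", "protein"):
        raise ValueError(f"kind must be 'glyco' or 'protein', got {kind!r}")
    key_cols = GLYCO_KEY_COLUMNS if kind == "glyco" else PROTEIN_KEY_COLUMNS
    channel_cols = list(design.channels)

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in key_cols + channel_cols if c not in df.columns]
    if missing:
        raise TableError(f"{path}: missing required columns {missing}")

    errors: list[str] = []
    keep = np.ones(len(df), dtype=bool)

    # Intensities: non-numeric strings other than empty/NA reject the row;
    # empty/NA/zero/negative values flag it incomplete.
    intens = np.full((len(df), len(channel_cols)), np.nan)
    for j, col in enumerate(channel_cols):
        raw = df[col].str.strip()
        is_na = raw.isin(("", "NA", "NaN", "nan", "na"))
        numeric = pd.to_numeric(raw.where(~is_na, other="nan"), errors="coerce")
        bad = numeric.isna() & ~is_na
        for i in np.flatnonzero(bad.to_numpy()):
            errors.append(
                f"{path}: line {i + 2}: non-numeric intensity "
                f"{raw.iloc[i]!r} in channel {col}"
            )
        keep &= ~bad.to_numpy()
        intens[:, j] = numeric.to_numpy()

    if kind == "glyco":
        glycosite = pd.to_numeric(df["glycosite"], errors="coerce")
        bad_site = glycosite.isna() | (glycosite < 1)
        for i in np.flatnonzero(bad_site.to_numpy()):
            errors.append(
                f"{path}: line {i + 2}: invalid glycosite "
                f"{df['glycosite'].iloc[i]!r}"
            )
        keep &= ~bad_site.to_numpy()

        canonical = np.empty(len(df), dtype=object)
        for i, text in enumerate(df["glycan"].to_numpy()):
            try:
                canonical[i] = format_composition(parse_composition(text))
            except ValueError as exc:
                errors.append(f"{path}: line {i + 2}: {exc}")
                keep[i] = False
                canonical[i] = None

    if errors and strict:
        raise TableError(
            f"{path}: {len(errors)} invalid rows\n" + "\n".join(errors)
        )

    out = df.loc[keep, key_cols].copy()
    if kind == "glyco":
        out["glycosite"] = (
            pd.to_numeric(out["glycosite"]).astype(int)
        )
        out["glycan"] = canonical[keep]
    for j, col in enumerate(channel_cols):
        out[col] = intens[keep, j]
    vals = out[channel_cols].to_numpy()
    out["complete"] = np.isfinite(vals).all(axis=1) & (vals > 0).all(axis=1)
    out = out.reset_index(drop=True)
    return out, errors


def _stable_json(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"), default=str)


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir,
    config: Optional[Mapping] = None,
    seed: Optional[int] = None,
    float_format: str = "%.6g",
) -> dict:
    """Write result tables as TSV plus a run manifest.

    Column order is preserved as given; an empty table produces a
    header-only file.  The manifest records a hash of the config, the
    seed and library versions so identical inputs yield byte-identical
    outputs (no timestamps).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, table in tables.items():
        dest = out_dir / f"{name}.tsv"
        table.to_csv(dest, sep="\t", index=False, float_format=float_format)
        written[name] = str(dest)

    config = dict(config) if config else {}
    manifest = {
        "tables": sorted(tables.keys()),
        "config": config,
        "config_sha256": hashlib.sha256(
            _stable_json(config).encode()
        ).hexdigest(),
        "seed": seed,
        "versions": {
            "glycoquant": _package_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out_dir / "manifest.json", "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("glycoquant")
    except Exception:  # pragma: no cover - not installed
        return "unknown"
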