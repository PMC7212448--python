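"""Synthetic glyco-PSM and protein-PSM tables with known ground truth.

The generator emulates the statistical structure of a pooled 4-plex
TMT intact-glycopeptide experiment on tumor/paracancer pairs from two
patient groups (low / high serum AFP):

* a glycopeptide catalog over a realistic composition pool whose
  default weights give roughly a 60 / 29 / 11 complex / oligo-mannose /
  hybrid PSM split, with oligo-mannose compositions preferentially
  placed on proteins marked endomembrane-like (high-mannose glycans
  reside mostly in the ER/Golgi);
* per-glycopeptide PSM counts from a shifted negative binomial
  (1 + NB, total mean ~8) and log-normal reporter noise (sigma in log2
  units) around a log-normal baseline spanning several orders of
  magnitude;
* per-channel loading factors that the normalization step must remove;
* planted effect blocks with exact per-comparison truth at the
  glycopeptide, protein and occupancy levels:

  - ``common-up`` / ``common-down``: the glycopeptide moves in both
    tumor channels relative to its paracancers;
  - ``lowAFP-unique`` / ``highAFP-unique``: the glycopeptide moves in
    one tumor channel only;
  - ``protein-driven``: a whole protein (and hence all its
    glycopeptides) differs between the low- and high-AFP patient pools
    in both tissues — an expression-level difference with zero
    occupancy effect;
  - ``occupancy-shift``: the glycopeptide (but not its protein)
    differs between patient pools in both tissues — a
    glycosylation-level patient difference that is not tumor-specific.

Each pool is one TMT channel (no replicates), faithful to the pooled
design; recovery of planted labels, not statistical inference, is the
test surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .glycan import classify_glycan, parse_composition, GlycanSubtype
from .tables_io import (
    ChannelDesign,
    GROUP_PARA_HIGH,
    GROUP_PARA_LOW,
    GROUP_TUMOR_HIGH,
    GROUP_TUMOR_LOW,
)

__all__ = [
    "SimConfig",
    "SimResult",
    "default_composition_pool",
    "generate_catalog",
    "simulate_experiment",
    "evaluate_recovery",
]

# (composition, subtype-internal weight) — subtype mass fractions are
# applied on top of these in default_composition_pool().
_OLIGO_POOL = [
    ("N2H8", 0.22), ("N2H7", 0.20), ("N2H6", 0.18), ("N2H5", 0.14),
    ("N2H9", 0.12), ("N2H4", 0.04), ("N2H5F1", 0.04), ("N2H6F1", 0.03),
    ("N2H7F1", 0.03),
]
_COMPLEX_POOL = [
    # bi-antennary ~2/3 of complex PSM mass; N4H5S2 is the most
    # site-prevalent glycan in liver tissue, clearly ahead of the rest
    ("N4H5S2", 0.22), ("N4H5S1", 0.11), ("N4H5F1S1", 0.10),
    ("N4H5F1S2", 0.08), ("N4H5F1", 0.07), ("N4H5", 0.05),
    ("N4H4F1", 0.02), ("N4H4", 0.01), ("N3H4", 0.01),
    # tri-antennary
    ("N5H6S1", 0.06), ("N5H6S2", 0.05), ("N5H6S3", 0.05),
    ("N5H6F1S1", 0.04), ("N5H6F1S2", 0.03), ("N5H6F1S3", 0.02),
    # tetra-antennary
    ("N6H7S2", 0.02), ("N6H7S3", 0.02), ("N6H7F1S2", 0.02),
    ("N6H7S4", 0.01), ("N6H7F1S4", 0.01),
]
_HYBRID_POOL = [
    ("N3H6", 0.25), ("N3H5", 0.20), ("N3H6S1", 0.15), ("N3H7", 0.12),
    ("N4H6", 0.10), ("N4H6S1", 0.08), ("N3H5F1", 0.06), ("N3H6F1", 0.04),
]

_AA_ALPHABET = np.array(list("ACDEFGHILMPQSTVWY"))


@dataclass
class SimConfig:
    """Parameters of one simulated experiment.

    Effect fractions are fractions of the glycopeptide catalog; folds
    are linear fold changes.  ``psm_nb_mean`` / ``psm_nb_r`` set the
    negative-binomial part of the shifted PSM-count distribution
    (total mean = 1 + psm_nb_mean).
    """

    n_glycoproteins: int = 200
    n_background_proteins: int = 100
    mean_extra_sites: float = 0.8
    mean_extra_glycans: float = 1.8
    psm_nb_mean: float = 7.0
    psm_nb_r: float = 4.0
    protein_psm_nb_mean: float = 14.0
    protein_psm_nb_r: float = 6.0
    sigma_log2: float = 0.25
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 3.3
    channel_loadings: tuple = (1.0, 1.3, 0.75, 1.15)
    endomembrane_fraction: float = 0.35
    oligo_endo_boost: float = 2.0
    subtype_mass_fractions: tuple = (0.598, 0.291, 0.111)  # complex, oligo, hybrid
    frac_common_up: float = 0.025
    frac_common_down: float = 0.025
    common_fold: float = 4.0
    frac_low_unique: float = 0.03
    frac_high_unique: float = 0.03
    unique_fold: float = 2.0
    frac_protein_driven: float = 0.03
    protein_fold: float = 2.0
    frac_occupancy_shift: float = 0.02
    occupancy_fold: float = 2.0

    def validate(self) -> None:
        fracs = (
            self.frac_common_up
            + self.frac_common_down
            + self.frac_low_unique
            + self.frac_high_unique
            + self.frac_protein_driven
            + self.frac_occupancy_shift
        )
        if fracs > 1:
            raise ValueError(f"effect fractions sum to {fracs} > 1")
        for name in (
            "frac_common_up", "frac_common_down", "frac_low_unique",
            "frac_high_unique", "frac_protein_driven", "frac_occupancy_shift",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_glycoproteins < 1:
            raise ValueError("n_glycoproteins must be >= 1")
        if self.sigma_log2 < 0:
            raise ValueError("sigma_log2 must be >= 0")
        for name in ("common_fold", "unique_fold", "protein_fold", "occupancy_fold"):
            if getattr(self, name) <= 1:
                raise ValueError(f"{name} must be > 1")
        if abs(sum(self.subtype_mass_fractions) - 1.0) > 1e-9:
            raise ValueError("subtype_mass_fractions must sum to 1")
        if len(self.channel_loadings) != 4:
            raise ValueError("channel_loadings needs one value per channel")
        if any(l <= 0 for l in self.channel_loadings):
            raise ValueError("channel_loadings must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channel_loadings"] = list(self.channel_loadings)
        d["subtype_mass_fractions"] = list(self.subtype_mass_fractions)
        return d

    @classmethod
    def from_dict(cls, d) -> "SimConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in d.items()})
        for name in ("channel_loadings", "subtype_mass_fractions"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class SimResult:
    glyco_psms: pd.DataFrame
    protein_psms: pd.DataFrame
    truth: pd.DataFrame
    catalog: pd.DataFrame
    config: SimConfig
    seed: int


def default_composition_pool(
    subtype_mass_fractions=(0.598, 0.291, 0.111),
) -> pd.DataFrame:
    """The built-in composition pool with sampling weights.

    Weights are normalized so the expected PSM mass per subtype matches
    ``subtype_mass_fractions`` (complex, oligo-mannose, hybrid).
    """
    f_complex, f_oligo, f_hybrid = subtype_mass_fractions
    rows = []
    for pool, frac, subtype in (
        (_COMPLEX_POOL, f_complex, GlycanSubtype.COMPLEX),
        (_OLIGO_POOL, f_oligo, GlycanSubtype.OLIGO_MANNOSE),
        (_HYBRID_POOL, f_hybrid, GlycanSubtype.HYBRID),
    ):
        total = sum(w for _, w in pool)
        for comp, w in pool:
            assert classify_glycan(parse_composition(comp)).subtype is subtype
            rows.append((comp, subtype.value, frac * w / total))
    pool_df = pd.DataFrame(rows, columns=["glycan", "subtype", "weight"])
    pool_df["weight"] /= pool_df["weight"].sum()
    return pool_df


def _oligo_weight_multipliers(
    pool: pd.DataFrame, endo_fraction: float, boost: float
) -> tuple[float, float]:
    """Endo and non-endo oligo-mannose weight multipliers chosen so
    the mixture keeps the pool's marginal oligo-mannose mass."""
    w_o = pool.loc[
        pool["subtype"] == GlycanSubtype.OLIGO_MANNOSE.value, "weight"
    ].sum()
    w_rest = 1.0 - w_o
    if endo_fraction in (0.0, 1.0) or w_o == 0 or w_rest <= 0:
        return (1.0, 1.0)
    f_endo = boost * w_o / (boost * w_o + w_rest)
    f_non = (w_o - endo_fraction * f_endo) / (1.0 - endo_fraction)
    f_non = min(max(f_non, 1e-6), 1 - 1e-6)
    down = f_non * w_rest / ((1.0 - f_non) * w_o)
    return (boost, down)


def _random_peptide(rng: np.random.Generator) -> str:
    """Tryptic-looking peptide with the glycosylated Asn marked '#' and
    a sequon-completing S/T after it."""
    n_left = int(rng.integers(2, 7))
    n_right = int(rng.integers(2, 7))
    left = "".join(rng.choice(_AA_ALPHABET, size=n_left))
    right = "".join(rng.choice(_AA_ALPHABET, size=n_right))
    return (
        left + "N#" + ("S" if rng.random() < 0.5 else "T") + right
        + ("K" if rng.random() < 0.5 else "R")
    )


def generate_catalog(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the glycopeptide catalog: proteins, glycosites and site
    glycans, deterministic for a given generator state.

    Returns one row per glycopeptide with columns glycopeptide_id,
    protein, glycosite, peptide, glycan, subtype, endomembrane.
    """
    config.validate()
    pool = default_composition_pool(config.subtype_mass_fractions)
    boost, down = _oligo_weight_multipliers(
        pool, config.endomembrane_fraction, config.oligo_endo_boost
    )
    is_oligo = (
        pool["subtype"] == GlycanSubtype.OLIGO_MANNOSE.value
    ).to_numpy()
    base_w = pool["weight"].to_numpy()
    glycans = pool["glycan"].to_numpy()
    subtypes = pool["subtype"].to_numpy()

    rows = []
    for i in range(config.n_glycoproteins):
        protein = f"GP{i:04d}"
        endo = bool(rng.random() < config.endomembrane_fraction)
        mult = boost if endo else down
        w = np.where(is_oligo, base_w * mult, base_w)
        w = w / w.sum()
        n_sites = 1 + int(rng.poisson(config.mean_extra_sites))
        positions = np.sort(
            rng.choice(np.arange(30, 1200), size=n_sites, replace=False)
        )
        for pos in positions:
            peptide = _random_peptide(rng)
            n_glycans = 1 + int(rng.poisson(config.mean_extra_glycans))
            n_glycans = min(n_glycans, len(glycans))
            chosen = rng.choice(
                len(glycans), size=n_glycans, replace=False, p=w
            )
            for j in sorted(chosen):
                rows.append(
                    (
                        f"{protein}|{pos}|{glycans[j]}",
                        protein,
                        int(pos),
                        peptide,
                        glycans[j],
                        subtypes[j],
                        endo,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "glycopeptide_id", "protein", "glycosite", "peptide",
            "glycan", "subtype", "endomembrane",
        ],
    )


def _group_indices(design: ChannelDesign) -> dict[str, int]:
    return {
        group: design.channels.index(design.channel_for_group(group))
        for group in (
            GROUP_PARA_LOW, GROUP_TUMOR_LOW, GROUP_PARA_HIGH, GROUP_TUMOR_HIGH
        )
    }


def _assign_effects(
    catalog: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    design: ChannelDesign,
) -> tuple[np.ndarray, dict[str, np.ndarray], np.ndarray]:
    """Plant effect blocks.

    Returns (labels per glycopeptide, protein log2-delta per channel
    keyed by protein, glyco log2-delta array (n_gp, n_channels)).
    """
    n_gp = len(catalog)
    n_ch = len(design.channels)
    gi = _group_indices(design)
    labels = np.array(["null"] * n_gp, dtype=object)
    glyco_delta = np.zeros((n_gp, n_ch))
    protein_delta: dict[str, np.ndarray] = {}

    # protein-driven: whole proteins shifted between patient pools
    target = config.frac_protein_driven * n_gp
    proteins = catalog["protein"].to_numpy()
    unique_proteins = rng.permutation(pd.unique(proteins))
    n_assigned = 0
    protein_driven: list[str] = []
    for prot in unique_proteins:
        if n_assigned >= target:
            break
        protein_driven.append(prot)
        n_assigned += int((proteins == prot).sum())
    d = np.log2(config.protein_fold)
    for prot in protein_driven:
        delta = np.zeros(n_ch)
        side_low = rng.random() < 0.5
        sign = 1.0 if rng.random() < 0.5 else -1.0
        if side_low:
            delta[gi[GROUP_PARA_LOW]] = sign * d
            delta[gi[GROUP_TUMOR_LOW]] = sign * d
        else:
            delta[gi[GROUP_PARA_HIGH]] = sign * d
            delta[gi[GROUP_TUMOR_HIGH]] = sign * d
        protein_delta[prot] = delta
        labels[proteins == prot] = "protein-driven"

    # remaining blocks drawn from glycopeptides of unaffected proteins
    free = np.flatnonzero(labels == "null")
    free = rng.permutation(free)
    blocks = [
        ("common-up", round(config.frac_common_up * n_gp)),
        ("common-down", round(config.frac_common_down * n_gp)),
        ("lowAFP-unique", round(config.frac_low_unique * n_gp)),
        ("highAFP-unique", round(config.frac_high_unique * n_gp)),
        ("occupancy-shift", round(config.frac_occupancy_shift * n_gp)),
    ]
    pos = 0
    d_common = np.log2(config.common_fold)
    d_unique = np.log2(config.unique_fold)
    d_occ = np.log2(config.occupancy_fold)
    for label, count in blocks:
        take = free[pos : pos + count]
        pos += count
        labels[take] = label
        for idx in take:
            if label == "common-up":
                glyco_delta[idx, gi[GROUP_TUMOR_LOW]] = d_common
                glyco_delta[idx, gi[GROUP_TUMOR_HIGH]] = d_common
            elif label == "common-down":
                glyco_delta[idx, gi[GROUP_TUMOR_LOW]] = -d_common
                glyco_delta[idx, gi[GROUP_TUMOR_HIGH]] = -d_common
            elif label == "lowAFP-unique":
                glyco_delta[idx, gi[GROUP_TUMOR_LOW]] = d_unique
            elif label == "highAFP-unique":
                glyco_delta[idx, gi[GROUP_TUMOR_HIGH]] = d_unique
            elif label == "occupancy-shift":
                sign = 1.0 if rng.random() < 0.5 else -1.0
                if rng.random() < 0.5:
                    glyco_delta[idx, gi[GROUP_PARA_LOW]] = sign * d_occ
                    glyco_delta[idx, gi[GROUP_TUMOR_LOW]] = sign * d_occ
                else:
                    glyco_delta[idx, gi[GROUP_PARA_HIGH]] = sign * d_occ
                    glyco_delta[idx, gi[GROUP_TUMOR_HIGH]] = sign * d_occ
    return labels, protein_delta, glyco_delta


def _nb_counts(
    rng: np.random.Generator, size: int, mean: float, r: float
) -> np.ndarray:
    """1 + NB(r, p) counts with NB mean ``mean``."""
    p = r / (r + mean)
    return 1 + rng.negative_binomial(r, p, size=size)


def _truth_table(
    catalog: pd.DataFrame,
    labels: np.ndarray,
    glyco_delta: np.ndarray,
    protein_delta: dict[str, np.ndarray],
    design: ChannelDesign,
) -> pd.DataFrame:
    n_ch = len(design.channels)
    prot_d = np.zeros((len(catalog), n_ch))
    for i, prot in enumerate(catalog["protein"]):
        if prot in protein_delta:
            prot_d[i] = protein_delta[prot]
    total = glyco_delta + prot_d
    out = catalog[["glycopeptide_id", "protein", "glycosite", "glycan"]].copy()
    out["label"] = labels
    for name, (num, den) in design.comparisons.items():
        i_num = design.channels.index(num)
        i_den = design.channels.index(den)
        out[f"true_glyco_log2_{name}"] = total[:, i_num] - total[:, i_den]
        out[f"true_protein_log2_{name}"] = prot_d[:, i_num] - prot_d[:, i_den]
        out[f"true_occ_log2_{name}"] = (
            glyco_delta[:, i_num] - glyco_delta[:, i_den]
        )
    return out


def simulate_experiment(
    config: SimConfig,
    seed: int,
    design: Optional[ChannelDesign] = None,
) -> SimResult:
    """Generate one full synthetic experiment.

    Fully deterministic per seed (NumPy PCG64 generator).  Returns the
    glyco-PSM table, the protein-PSM table and the ground-truth table.
    """
    config.validate()
    if design is None:
        design = ChannelDesign.default()
    rng = np.random.default_rng(seed)
    catalog = generate_catalog(config, rng)
    n_gp = len(catalog)
    labels, protein_delta, glyco_delta = _assign_effects(
        catalog, config, rng, design
    )

    loadings = np.asarray(config.channel_loadings, dtype=float)
    n_ch = len(design.channels)

    # glycopeptide baselines and channel means
    baseline = rng.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, size=n_gp
    )
    prot_d = np.zeros((n_gp, n_ch))
    for i, prot in enumerate(catalog["protein"]):
        if prot in protein_delta:
            prot_d[i] = protein_delta[prot]
    mu = baseline[:, None] + glyco_delta + prot_d

    counts = _nb_counts(rng, n_gp, config.psm_nb_mean, config.psm_nb_r)
    gp_index = np.repeat(np.arange(n_gp), counts)
    n_psms = len(gp_index)
    noise = (
        rng.normal(0.0, config.sigma_log2, size=(n_psms, n_ch))
        if config.sigma_log2 > 0
        else np.zeros((n_psms, n_ch))
    )
    intens = np.exp2(mu[gp_index] + noise) * loadings

    glyco_psms = pd.DataFrame(
        {
            "spectrum_id": [f"GS{i:06d}" for i in range(n_psms)],
            "peptide": catalog["peptide"].to_numpy()[gp_index],
            "protein": catalog["protein"].to_numpy()[gp_index],
            "glycosite": catalog["glycosite"].to_numpy()[gp_index],
            "glycan": catalog["glycan"].to_numpy()[gp_index],
        }
    )
    for j, ch in enumerate(design.channels):
        glyco_psms[ch] = intens[:, j]

    # protein PSMs: glycoproteins plus non-glyco background
    glyco_proteins = pd.unique(catalog["protein"])
    background = [f"BG{i:04d}" for i in range(config.n_background_proteins)]
    all_proteins = np.concatenate([glyco_proteins, background])
    n_prot = len(all_proteins)
    prot_baseline = rng.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, size=n_prot
    )
    prot_delta_mat = np.zeros((n_prot, n_ch))
    for i, prot in enumerate(all_proteins):
        if prot in protein_delta:
            prot_delta_mat[i] = protein_delta[prot]
    mu_p = prot_baseline[:, None] + prot_delta_mat
    counts_p = _nb_counts(
        rng, n_prot, config.protein_psm_nb_mean, config.protein_psm_nb_r
    )
    p_index = np.repeat(np.arange(n_prot), counts_p)
    n_ppsms = len(p_index)
    noise_p = (
        rng.normal(0.0, config.sigma_log2, size=(n_ppsms, n_ch))
        if config.sigma_log2 > 0
        else np.zeros((n_ppsms, n_ch))
    )
    intens_p = np.exp2(mu_p[p_index] + noise_p) * loadings

    peptides_p = np.array(
        [_random_peptide(rng).replace("N#", "Q") for _ in range(n_prot)]
    )
    protein_psms = pd.DataFrame(
        {
            "spectrum_id": [f"PS{i:06d}" for i in range(n_ppsms)],
            "peptide": peptides_p[p_index],
            "protein": all_proteins[p_index],
        }
    )
    for j, ch in enumerate(design.channels):
        protein_psms[ch] = intens_p[:, j]

    truth = _truth_table(catalog, labels, glyco_delta, protein_delta, design)
    return SimResult(
        glyco_psms=glyco_psms,
        protein_psms=protein_psms,
        truth=truth,
        catalog=catalog,
        config=config,
        seed=seed,
    )


_POSITIVE_LABELS = {
    "common-up": ("common_label", "up"),
    "common-down": ("common_label", "down"),
    "lowAFP-unique": ("unique_label", "lowAFP-unique"),
    "highAFP-unique": ("unique_label", "highAFP-unique"),
}


def evaluate_recovery(calls: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Score differential calls against planted truth.

    For each positive label: tp / fp / fn, precision, recall over all
    planted features (features that never reached quantitation count as
    misses) and ``recall_quantified`` over the planted features present
    in the calls table.  Null, protein-driven and occupancy-shift
    truths are negatives for every label.  Precision is NaN when the
    label was never called.

    Raises
    ------
    ValueError
        If the calls table contains feature ids absent from the truth.
    """
    truth_ids = set(truth["glycopeptide_id"])
    call_ids = set(calls["feature_id"])
    stray = sorted(call_ids - truth_ids)
    if stray:
        raise ValueError(f"calls reference unknown glycopeptides: {stray[:5]}")

    truth_label = truth.set_index("glycopeptide_id")["label"]
    rows = []
    for label, (col, value) in _POSITIVE_LABELS.items():
        predicted = set(calls.loc[calls[col] == value, "feature_id"])
        true_set = set(truth_label.index[truth_label == label])
        true_quant = true_set & call_ids
        tp = len(predicted & true_set)
        fp = len(predicted - true_set)
        fn = len(true_set - predicted)
        precision = tp / (tp + fp) if (tp + fp) else np.nan
        recall = tp / len(true_set) if true_set else np.nan
        recall_q = tp / len(true_quant) if true_quant else np.nan
        rows.append(
            {
                "label": label,
                "n_true": len(true_set),
                "n_true_quantified": len(true_quant),
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "precision": precision,
                "recall": recall,
                "recall_quantified": recall_q,
            }
        )
    return pd.DataFrame(rows)
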