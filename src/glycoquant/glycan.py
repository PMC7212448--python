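"""N-glycan composition parsing, canonicalization and classification.

A glycan *composition* records monosaccharide counts without topology:
HexNAc (N), Hex (H), deoxyhexose/fucose (F) and sialic acid NeuAc (S).
Compositions are written in a compact code such as ``N4H5F1S1`` (=
HexNAc4 Hex5 Fuc1 NeuAc1); the long spelling ``HexNAc4Hex5Fuc1Sia1`` is
accepted on input.

Classification into the biosynthetic subtypes (oligo-mannose, hybrid,
complex, pauci/other) follows standard composition logic:

* oligo-mannose: the HexNAc2 chitobiose core carrying only mannoses
  (Hex >= 4) and no sialic acid; fucosylated variants stay oligo-mannose.
* hybrid: at least one GlcNAc-initiated antenna next to an untrimmed
  mannose arm, i.e. HexNAc >= 3 with Hex > HexNAc + 1.
* complex: both arms antennary, i.e. HexNAc >= 3 with Hex <= HexNAc + 1.
* pauci/other: anything smaller (truncated cores such as N2H3, N1H1).

These four rules partition every valid composition.  Antenna number for
a complex glycan is HexNAc - 2 (one GlcNAc per branch beyond the core),
minus one when a bisecting GlcNAc is annotated.  Bisecting GlcNAc and
the core/antennary position of fucoses are not derivable from counts
alone, so both accept optional annotation tables; the default fucose
heuristic places the first fucose on the core.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional

__all__ = [
    "GlycanComposition",
    "GlycanClass",
    "GlycanSubtype",
    "parse_composition",
    "format_composition",
    "classify_glycan",
    "partition_fucose",
    "monoisotopic_mass",
    "read_flag_table",
    "MONOSACCHARIDE_MASSES",
]

#: Residue (dehydrated) monoisotopic masses in Da.
MONOSACCHARIDE_MASSES: Mapping[str, float] = {
    "hexnac": 203.07937,
    "hex": 162.05282,
    "fuc": 146.05791,
    "neuac": 291.09542,
}

# Accepted monosaccharide spellings (lower-cased) -> field name.
_NAME_TO_FIELD = {
    "n": "n_hexnac",
    "hexnac": "n_hexnac",
    "h": "n_hex",
    "hex": "n_hex",
    "f": "n_fuc",
    "fuc": "n_fuc",
    "dhex": "n_fuc",
    "s": "n_neuac",
    "sia": "n_neuac",
    "neuac": "n_neuac",
}

_TOKEN_RE = re.compile(r"([A-Za-z]+)(\d+)")


class GlycanSubtype(str, Enum):
    """The four-way biosynthetic subtype partition."""

    OLIGO_MANNOSE = "oligo-mannose"
    HYBRID = "hybrid"
    COMPLEX = "complex"
    PAUCI_OTHER = "pauci/other"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Monosaccharide counts of one N-glycan composition."""

    n_hexnac: int = 0
    n_hex: int = 0
    n_fuc: int = 0
    n_neuac: int = 0

    def __post_init__(self) -> None:
        for name, value in self.counts().items():
            if not isinstance(value, int) or isinstance(value, bool):
                raise TypeError(f"{name} must be an integer, got {value!r}")
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
        if self.total == 0:
            raise ValueError("composition must contain at least one residue")

    def counts(self) -> dict[str, int]:
        return {
            "n_hexnac": self.n_hexnac,
            "n_hex": self.n_hex,
            "n_fuc": self.n_fuc,
            "n_neuac": self.n_neuac,
        }

    @property
    def total(self) -> int:
        return self.n_hexnac + self.n_hex + self.n_fuc + self.n_neuac

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        if not isinstance(other, GlycanComposition):
            return NotImplemented
        return GlycanComposition(
            self.n_hexnac + other.n_hexnac,
            self.n_hex + other.n_hex,
            self.n_fuc + other.n_fuc,
            self.n_neuac + other.n_neuac,
        )

    def __str__(self) -> str:
        return format_composition(self)

    @classmethod
    def parse(cls, text: str) -> "GlycanComposition":
        return parse_composition(text)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


def parse_composition(text: str) -> GlycanComposition:
    """Parse a composition string in short (``N4H5F1S1``) or long
    (``HexNAc4Hex5Fuc1Sia1``) dialect.

    Letters may appear in any order but each monosaccharide at most
    once; absent letters mean a count of zero.  Long names are matched
    case-insensitively.

    Raises
    ------
    ValueError
        Naming the offending token for unknown codes, duplicated
        monosaccharides, missing counts or an empty string.
    """
    if not isinstance(text, str) or not text.strip():
        raise ValueError("empty composition string")
    s = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _TOKEN_RE.finditer(s):
        if match.start() != pos:
            raise ValueError(
                f"invalid composition {text!r}: unparseable token "
                f"{s[pos:match.start()]!r}"
            )
        name, digits = match.group(1), match.group(2)
        field = _NAME_TO_FIELD.get(name.lower())
        if field is None:
            raise ValueError(
                f"invalid composition {text!r}: unknown monosaccharide "
                f"{name + digits!r}"
            )
        if field in counts:
            raise ValueError(
                f"invalid composition {text!r}: duplicated monosaccharide "
                f"{name!r}"
            )
        counts[field] = int(digits)
        pos = match.end()
    if pos != len(s):
        raise ValueError(
            f"invalid composition {text!r}: trailing token {s[pos:]!r}"
        )
    if not counts:
        raise ValueError(f"invalid composition {text!r}: no tokens found")
    return GlycanComposition(**counts)


def format_composition(comp: GlycanComposition) -> str:
    """Canonical short form: letters in fixed N, H, F, S order with
    zero counts omitted (``N4H5F1S2``, ``N2H8``)."""
    parts = []
    for letter, value in (
        ("N", comp.n_hexnac),
        ("H", comp.n_hex),
        ("F", comp.n_fuc),
        ("S", comp.n_neuac),
    ):
        if value:
            parts.append(f"{letter}{value}")
    if not parts:
        raise ValueError("cannot format an all-zero composition")
    return "".join(parts)


def monoisotopic_mass(comp: GlycanComposition) -> float:
    """Sum of residue monoisotopic masses in Da (glycan moiety only,
    no water and no peptide)."""
    m = MONOSACCHARIDE_MASSES
    return (
        comp.n_hexnac * m["hexnac"]
        + comp.n_hex * m["hex"]
        + comp.n_fuc * m["fuc"]
        + comp.n_neuac * m["neuac"]
    )


def partition_fucose(
    comp: GlycanComposition,
    core_fucose_override: Optional[Mapping[str, bool]] = None,
) -> tuple[int, int]:
    """Split the fucose count into (core, antennary).

    The default heuristic assigns the first fucose to the core (the
    innermost GlcNAc) and any remainder to the antennae.  An override
    table keyed by canonical composition string replaces the heuristic:
    ``True`` forces one core fucose (when any fucose is present),
    ``False`` marks the composition as purely antennary-fucosylated.
    """
    if comp.n_fuc == 0:
        return (0, 0)
    if core_fucose_override is not None:
        key = format_composition(comp)
        if key in core_fucose_override:
            core = 1 if core_fucose_override[key] else 0
            return (core, comp.n_fuc - core)
    return (1, comp.n_fuc - 1)


@dataclass(frozen=True)
class GlycanClass:
    """Feature classification of one composition.

    ``antennae`` is defined only for complex glycans; ``mannose_count``
    only for oligo-mannose.  ``bisecting`` is a tri-state: compositions
    cannot reveal a bisecting GlcNAc, so it is ``"unknown"`` unless an
    annotation set is supplied.
    """

    subtype: GlycanSubtype
    mannose_count: Optional[int]
    antennae: Optional[int]
    n_sia: int
    n_fuc_total: int
    n_core_fuc: int
    n_antennary_fuc: int
    bisecting: str  # "yes" | "no" | "unknown"

    def __post_init__(self) -> None:
        if self.bisecting not in ("yes", "no", "unknown"):
            raise ValueError(f"invalid bisecting flag {self.bisecting!r}")
        if self.n_core_fuc + self.n_antennary_fuc != self.n_fuc_total:
            raise ValueError("fucose partition does not add up")


def classify_glycan(
    comp: GlycanComposition,
    bisecting_annotation: Optional[Iterable[str]] = None,
    core_fucose_override: Optional[Mapping[str, bool]] = None,
) -> GlycanClass:
    """Assign subtype, antenna number, sialylation and fucosylation
    features to a composition.

    Parameters
    ----------
    comp
        A valid composition.
    bisecting_annotation
        Canonical composition strings known (from structure-level
        evidence) to carry a bisecting GlcNAc.  When given, membership
        decides ``bisecting`` yes/no; when absent it is "unknown".
    core_fucose_override
        Passed through to :func:`partition_fucose`.
    """
    key = format_composition(comp)
    if bisecting_annotation is None:
        bisecting = "unknown"
    else:
        bisecting = "yes" if key in set(bisecting_annotation) else "no"

    if comp.n_hexnac == 2 and comp.n_hex >= 4 and comp.n_neuac == 0:
        subtype = GlycanSubtype.OLIGO_MANNOSE
    elif comp.n_hexnac >= 3 and comp.n_hex > comp.n_hexnac + 1:
        subtype = GlycanSubtype.HYBRID
    elif comp.n_hexnac >= 3 and comp.n_hex <= comp.n_hexnac + 1:
        subtype = GlycanSubtype.COMPLEX
    else:
        subtype = GlycanSubtype.PAUCI_OTHER

    mannose_count = comp.n_hex if subtype is GlycanSubtype.OLIGO_MANNOSE else None
    antennae = None
    if subtype is GlycanSubtype.COMPLEX:
        antennae = comp.n_hexnac - 2 - (1 if bisecting == "yes" else 0)
        # one GlcNAc per branch; bisected tri-HexNAc cores still carry
        # a single antenna, and >6 branches are not biosynthetic
        antennae = max(1, min(6, antennae))

    core, antennary = partition_fucose(comp, core_fucose_override)
    return GlycanClass(
        subtype=subtype,
        mannose_count=mannose_count,
        antennae=antennae,
        n_sia=comp.n_neuac,
        n_fuc_total=comp.n_fuc,
        n_core_fuc=core,
        n_antennary_fuc=antennary,
        bisecting=bisecting,
    )


def read_flag_table(path) -> dict[str, bool]:
    """Read a two-column TSV of (canonical composition string, flag)
    used for bisecting and core-fucose annotations.

    Flags accepted: 1/0, true/false, yes/no (case-insensitive).
    Compositions are re-canonicalized on read.
    """
    truthy = {"1", "true", "yes", "y"}
    falsy = {"0", "false", "no", "n"}
    out: dict[str, bool] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            comp, flag = fields
            flag_l = flag.strip().lower()
            if flag_l in truthy:
                value = True
            elif flag_l in falsy:
                value = False
            else:
                raise ValueError(f"{path}:{lineno}: invalid flag {flag!r}")
            out[format_composition(parse_composition(comp))] = value
    return out
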