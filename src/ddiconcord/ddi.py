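"""Per-source DDI lists: canonical ingredient pairs and severity harmonization.

Seven interaction sources feed the concordance analysis.  KEGG is the single
Japanese source (drug-label contraindications/precautions keyed by KEGG D
numbers); the six international sources — FrenchDB, NDF-RT, OSCAR,
World Vista, ONC High Priority and ONC Noninterruptive — come from an
aggregated DrugBank-keyed knowledge base.  Native severity vocabularies are
incomparable across sources, so each is mapped onto a 3-level controlled
scale:

====================  ==========================================  =============
Source                Native label                                Controlled
====================  ==========================================  =============
FrenchDB              CI                                          Highest class
                      AD, PE, PC                                  Other class
NDF-RT                Critical                                    Highest class
                      Significant                                 Other class
OSCAR                 3                                           Highest class
                      2, 1                                        Other class
World Vista           Contraindication                            Highest class
                      Not recommended, Precaution for use,
                      Take into account                           Other class
ONC High Priority     (list membership)                           Highest class
ONC Noninterruptive   (list membership)                           Other class
KEGG                  CI                                          Highest class
                      P                                           Other class
====================  ==========================================  =============

The third level, *No information*, arises only at integration time, for
pairs absent from a source.

Interactions are compared on unordered pairs of ingredient-class RxCUIs.
Symmetric duplicates (A-B vs B-A) collapse onto one canonical pair, and a
pair carrying several native labels in one source (a Japanese label can tag
the same combination CI for one partner and P for the other) takes the most
severe one: any label mapping to Highest wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .codes import CodeSystem, ValidatedCode, validate_code
from .mapping import CrosswalkRow, KeggDrugRecord, VerificationStatus

__all__ = [
    "SourceId",
    "ControlledLevel",
    "RawDDI",
    "CanonicalPair",
    "HarmonizedDDI",
    "SEVERITY_MAPPINGS",
    "SelfPairError",
    "UnknownLabelError",
    "ConversionStats",
    "canonical_pair",
    "convert_ddi_codes",
    "dedupe_and_harmonize",
    "build_kegg_endpoint_map",
    "build_drugbank_endpoint_map",
    "load_ddi_table",
    "write_harmonized",
    "load_harmonized",
]

log = logging.getLogger(__name__)


class SourceId(str, Enum):
    FRENCHDB = "FRENCHDB"
    NDFRT = "NDFRT"
    OSCAR = "OSCAR"
    WORLDVISTA = "WORLDVISTA"
    ONC_HIGH = "ONC_HIGH"
    ONC_NONINT = "ONC_NONINT"
    KEGG = "KEGG"

    @property
    def is_japanese(self) -> bool:
        return self is SourceId.KEGG


INTERNATIONAL_SOURCES: tuple[SourceId, ...] = tuple(
    s for s in SourceId if not s.is_japanese
)


class ControlledLevel(str, Enum):
    """3-level controlled severity scale."""

    HIGHEST = "HIGHEST"
    OTHER = "OTHER"
    NOINFO = "NOINFO"


#: Native severity vocabulary -> controlled level, per source.  Keys are
#: stored casefolded; lookups trim and casefold (see ``_lookup_label``).
SEVERITY_MAPPINGS: dict[SourceId, dict[str, ControlledLevel]] = {
    SourceId.FRENCHDB: {
        "ci": ControlledLevel.HIGHEST,
        "ad": ControlledLevel.OTHER,
        "pe": ControlledLevel.OTHER,
        "pc": ControlledLevel.OTHER,
    },
    SourceId.NDFRT: {
        "critical": ControlledLevel.HIGHEST,
        "significant": ControlledLevel.OTHER,
    },
    SourceId.OSCAR: {
        "3": ControlledLevel.HIGHEST,
        "2": ControlledLevel.OTHER,
        "1": ControlledLevel.OTHER,
    },
    SourceId.WORLDVISTA: {
        "contraindication": ControlledLevel.HIGHEST,
        "not recommended": ControlledLevel.OTHER,
        "precaution for use": ControlledLevel.OTHER,
        "take into account": ControlledLevel.OTHER,
    },
    SourceId.ONC_HIGH: {"high priority": ControlledLevel.HIGHEST},
    SourceId.ONC_NONINT: {"noninterruptive": ControlledLevel.OTHER},
    SourceId.KEGG: {
        "ci": ControlledLevel.HIGHEST,
        "p": ControlledLevel.OTHER,
    },
}


class SelfPairError(ValueError):
    """Both endpoints of an interaction resolve to the same ingredient."""


class UnknownLabelError(ValueError):
    def __init__(self, source: SourceId, label: str):
        self.source = source
        self.label = label
        super().__init__(f"unknown severity label {label!r} for source {source.value}")


@dataclass(frozen=True, order=True)
class CanonicalPair:
    """Unordered ingredient pair, stored with ``low < high`` lexicographically."""

    low: ValidatedCode
    high: ValidatedCode


@dataclass(frozen=True)
class RawDDI:
    """One interaction row as read from a source file (pre-conversion)."""

    source: SourceId
    code_a: ValidatedCode
    code_b: ValidatedCode
    raw_label: str


@dataclass
class HarmonizedDDI:
    """One (pair, source) interaction on the controlled scale."""

    pair: CanonicalPair
    source: SourceId
    level: ControlledLevel
    raw_labels: frozenset[str] = field(default_factory=frozenset)


@dataclass
class ConversionStats:
    """Bookkeeping for rows lost while translating endpoint codes."""

    n_input: int = 0
    n_converted: int = 0
    n_dropped_unmapped: int = 0
    n_dropped_self: int = 0


def canonical_pair(a: ValidatedCode, b: ValidatedCode) -> CanonicalPair:
    """Order-insensitive pair constructor: ``canonical_pair(a, b) ==
    canonical_pair(b, a)``.

    Raises
    ------
    SelfPairError
        When both endpoints are the same concept — a pair-keyed comparison
        cannot represent an ingredient interacting with itself.
    """
    if a.value == b.value and a.system is b.system:
        raise SelfPairError(f"self pair: {a.value}")
    return CanonicalPair(a, b) if a.value < b.value else CanonicalPair(b, a)


def _lookup_label(source: SourceId, label: str) -> ControlledLevel:
    level = SEVERITY_MAPPINGS[source].get(label.strip().casefold())
    if level is None:
        raise UnknownLabelError(source, label)
    return level


# ---------------------------------------------------------------------------
# endpoint maps


def build_kegg_endpoint_map(
    records: Iterable[KeggDrugRecord],
    crosswalk: Iterable[CrosswalkRow],
    include_inaccurate: bool = False,
) -> dict[str, frozenset[ValidatedCode]]:
    """Map KEGG D numbers to ingredient RxCUIs via their YJ codes.

    Japanese interaction rows are keyed by D number; each D number reaches
    its RxCUIs through the YJ codes of its KEGG DRUG record and the
    YJ-RxCUI crosswalk (rows flagged ``INACCURATE`` are skipped by default).
    """
    yj_to_rxcui: dict[str, set[ValidatedCode]] = {}
    for row in crosswalk:
        if row.verification_status is VerificationStatus.INACCURATE and not include_inaccurate:
            continue
        yj_to_rxcui.setdefault(row.yj.value, set()).add(row.rxcui)
    out: dict[str, frozenset[ValidatedCode]] = {}
    for rec in records:
        rxcuis: set[ValidatedCode] = set()
        for yj in rec.yj_codes:
            rxcuis |= yj_to_rxcui.get(yj.value, set())
        if rxcuis:
            out[rec.d_number.value] = frozenset(rxcuis)
    return out


def build_drugbank_endpoint_map(
    db_map: Mapping[str, ValidatedCode],
) -> dict[str, frozenset[ValidatedCode]]:
    """Invert the 1:1 RxCUI->DrugBank map to translate international rows."""
    inv: dict[str, set[ValidatedCode]] = {}
    for rxcui_value, db in db_map.items():
        if db is None:
            continue
        inv.setdefault(db.value, set()).add(
            validate_code(CodeSystem.RXCUI, rxcui_value)
        )
    return {k: frozenset(v) for k, v in inv.items()}


# ---------------------------------------------------------------------------
# operations


def convert_ddi_codes(
    raw: Iterable[RawDDI],
    endpoint_map: Mapping[str, frozenset[ValidatedCode]],
    stats: Optional[ConversionStats] = None,
) -> list[tuple[CanonicalPair, SourceId, str]]:
    """Translate both endpoints of each raw interaction to ingredient RxCUIs.

    An endpoint mapping to several ingredient concepts (a multi-ingredient
    product) fans out to every combination.  Rows with an untranslatable
    endpoint are dropped and counted; so are rows whose endpoints collapse to
    one ingredient (self pairs).
    """
    if stats is None:
        stats = ConversionStats()
    out: list[tuple[CanonicalPair, SourceId, str]] = []
    for row in raw:
        stats.n_input += 1
        cands_a = endpoint_map.get(row.code_a.value)
        cands_b = endpoint_map.get(row.code_b.value)
        if not cands_a or not cands_b:
            stats.n_dropped_unmapped += 1
            continue
        emitted = False
        for a in sorted(cands_a):
            for b in sorted(cands_b):
                try:
                    pair = canonical_pair(a, b)
                except SelfPairError:
                    continue
                out.append((pair, row.source, row.raw_label))
                emitted = True
        if emitted:
            stats.n_converted += 1
        else:
            stats.n_dropped_self += 1
    log.info(
        "converted %d/%d rows (%d unmapped, %d self-pairs dropped)",
        stats.n_converted, stats.n_input, stats.n_dropped_unmapped, stats.n_dropped_self,
    )
    return out


def dedupe_and_harmonize(
    converted: Iterable[tuple[CanonicalPair, SourceId, str]],
    mappings: Optional[Mapping[SourceId, Mapping[str, ControlledLevel]]] = None,
) -> list[HarmonizedDDI]:
    """Collapse symmetric/duplicate rows and harmonize severity labels.

    One record per (pair, source); raw labels are unioned across duplicates
    and the controlled level is Highest if *any* label maps to Highest, else
    Other.  This generalizes the Japanese-label rule — a combination tagged
    both CI and P counts as contraindicated — to every source; it only ever
    fires elsewhere if a source genuinely carries mixed labels, which is
    logged.

    Raises
    ------
    UnknownLabelError
        If a raw label is absent from its source's vocabulary.
    """
    if mappings is None:
        mappings = SEVERITY_MAPPINGS
    groups: dict[tuple[CanonicalPair, SourceId], set[str]] = {}
    for pair, source, label in converted:
        # validate eagerly so an unknown label names its row's source
        vocab = mappings[source]
        if vocab.get(label.strip().casefold()) is None:
            raise UnknownLabelError(source, label)
        groups.setdefault((pair, source), set()).add(label.strip())
    out: list[HarmonizedDDI] = []
    for (pair, source) in sorted(groups, key=lambda k: (k[0], k[1].value)):
        labels = groups[(pair, source)]
        levels = {mappings[source][l.casefold()] for l in labels}
        level = (
            ControlledLevel.HIGHEST
            if ControlledLevel.HIGHEST in levels
            else ControlledLevel.OTHER
        )
        if len(levels) > 1 and source is not SourceId.KEGG:
            log.info(
                "mixed severity labels %s for %s pair %s-%s; highest wins",
                sorted(labels), source.value, pair.low.value, pair.high.value,
            )
        out.append(HarmonizedDDI(pair, source, level, frozenset(labels)))
    return out


# ---------------------------------------------------------------------------
# I/O


def load_ddi_table(path: str | Path, source: SourceId) -> list[RawDDI]:
    """Load one source's raw interaction list.

    Columns: ``code_a, code_b, raw_label``.  Endpoints are KEGG D numbers
    for the Japanese source and DrugBank accessions for international ones.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"DDI table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("code_a", "code_b", "raw_label") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    system = CodeSystem.KEGG_D if source.is_japanese else CodeSystem.DRUGBANK
    return [
        RawDDI(
            source=source,
            code_a=validate_code(system, row.code_a),
            code_b=validate_code(system, row.code_b),
            raw_label=row.raw_label,
        )
        for row in df.itertuples(index=False)
    ]


def write_harmonized(records: Iterable[HarmonizedDDI], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "low_rxcui": r.pair.low.value,
                "high_rxcui": r.pair.high.value,
                "source": r.source.value,
                "level": r.level.value,
                "raw_labels": "|".join(sorted(r.raw_labels)),
            }
            for r in sorted(records, key=lambda r: (r.pair, r.source.value))
        ],
        columns=["low_rxcui", "high_rxcui", "source", "level", "raw_labels"],
    )
    df.to_csv(path, sep="\t", index=False)


def load_harmonized(path: str | Path) -> list[HarmonizedDDI]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        pair = canonical_pair(
            validate_code(CodeSystem.RXCUI, row.low_rxcui),
            validate_code(CodeSystem.RXCUI, row.high_rxcui),
        )
        out.append(
            HarmonizedDDI(
                pair,
                SourceId(row.source),
                ControlledLevel(row.level),
                frozenset(row.raw_labels.split("|")) if row.raw_labels else frozenset(),
            )
        )
    return out
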