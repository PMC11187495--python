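"""Crosswalk construction: YJ code -> RxCUI -> DrugBank identifier.

Builds the two correspondence tables the concordance analysis runs on:

* the **YJ-RxCUI table**, linking Japanese commercial drug codes to
  ingredient-class RxNorm concepts through KEGG DRUG entries and U.S.
  National Drug Codes; and
* the **YJ-RxCUI-DB table**, which joins a 1:1 RxCUI -> DrugBank map onto it
  and restricts to oral and injectable ingredients.

Three data-quality rules from the upstream resources are enforced here:

1. *NDC history*: an NDC whose RxNorm link has been inactivated must not
   contribute a correspondence (inactive links can otherwise make a single
   NDC emit two different ingredients, e.g. a statin and an anticonvulsant
   sharing one recycled code).
2. *Ingredient-notation agreement*: when the ingredient name recorded on the
   KEGG side of a D-number<->NDC edge disagrees with the RxNorm side, the
   resulting (YJ, RxCUI) row is flagged ``INACCURATE`` and excluded from
   downstream joins.  This automated detector is an explicit proxy for the
   manual pharmacist verification such mappings receive in practice; an
   optional review file can override statuses.
3. *Allergen extracts* are dropped before mapping because the Japanese and
   international product sets differ too much for ingredient-level joins.

All operations are deterministic: identical input files produce
byte-identical output tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .codes import CodeSystem, ValidatedCode, validate_code

__all__ = [
    "Category",
    "VerificationStatus",
    "Scope",
    "KeggDrugRecord",
    "NdcRxcuiLink",
    "RxcuiDrugbankLink",
    "CrosswalkRow",
    "ConflictReport",
    "SchemaError",
    "load_kegg_drug_table",
    "load_ndc_rxcui_table",
    "load_rxcui_drugbank_table",
    "load_scope_table",
    "filter_allergen_extracts",
    "resolve_ndc_to_rxcui",
    "detect_ingredient_mismatch",
    "build_yj_rxcui",
    "resolve_rxcui_to_drugbank",
    "build_yj_rxcui_db",
    "apply_review_file",
    "normalize_ingredient_name",
    "load_salt_tokens",
    "write_crosswalk",
    "write_conflicts",
]

log = logging.getLogger(__name__)


class Category(str, Enum):
    STANDARD = "STANDARD"
    ALLERGEN_EXTRACT = "ALLERGEN_EXTRACT"


class VerificationStatus(str, Enum):
    UNVERIFIED = "UNVERIFIED"
    ACCURATE = "ACCURATE"
    INACCURATE = "INACCURATE"


class Scope(str, Enum):
    ORAL = "ORAL"
    INJECTABLE = "INJECTABLE"
    OTHER = "OTHER"


@dataclass
class KeggDrugRecord:
    """One KEGG DRUG entry with its linked YJ codes and NDCs."""

    d_number: ValidatedCode
    yj_codes: frozenset[ValidatedCode]
    ndcs: frozenset[ValidatedCode]
    category: Category = Category.STANDARD
    ingredient_name: str = ""


@dataclass(frozen=True)
class NdcRxcuiLink:
    """One NDC -> ingredient-class RxCUI correspondence with activity history."""

    ndc: ValidatedCode
    rxcui: ValidatedCode
    active: bool
    inactivation_date: Optional[date] = None
    concept_class: str = "IN"  # IN or MIN
    ingredient_name: str = ""


@dataclass(frozen=True)
class RxcuiDrugbankLink:
    rxcui: ValidatedCode
    drugbank_id: ValidatedCode
    name_rxnorm: str = ""
    name_drugbank: str = ""


@dataclass
class CrosswalkRow:
    """One YJ -> RxCUI (-> DrugBank) correspondence."""

    yj: ValidatedCode
    rxcui: ValidatedCode
    drugbank_id: Optional[ValidatedCode] = None
    verification_status: VerificationStatus = VerificationStatus.UNVERIFIED
    scope: Scope = Scope.OTHER


@dataclass
class ConflictReport:
    """Ambiguities and disagreements surfaced while building the crosswalk."""

    multi_rxcui_ndcs: list[tuple[ValidatedCode, frozenset[ValidatedCode]]] = field(
        default_factory=list
    )
    ingredient_mismatches: list[tuple[ValidatedCode, ValidatedCode, str, str]] = field(
        default_factory=list
    )  # (d_number, ndc, name_kegg, name_rxnorm)
    unresolved_drugbank: list[ValidatedCode] = field(default_factory=list)
    drugbank_ties: list[tuple[ValidatedCode, frozenset[ValidatedCode]]] = field(
        default_factory=list
    )  # rxcui with two candidates where the name rule could not decide

    def mismatch_edges(self) -> set[tuple[str, str]]:
        """(d_number, ndc) canonical-value pairs flagged for name disagreement."""
        return {(d.value, n.value) for d, n, _, _ in self.ingredient_mismatches}


class SchemaError(ValueError):
    """An input table is missing required columns."""


# ---------------------------------------------------------------------------
# ingredient-name normalization


def load_salt_tokens() -> frozenset[str]:
    """Load the packaged editable list of salt/counter-ion tokens."""
    text = resources.files("ddiconcord").joinpath("data/salts.txt").read_text()
    toks = set()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            toks.add(line.casefold())
    return frozenset(toks)


_DEFAULT_SALTS = None


def normalize_ingredient_name(name: str, salts: Optional[frozenset[str]] = None) -> str:
    """Case-fold, trim, collapse whitespace and drop exact-token salt names.

    Only whole tokens found in the salt list are removed; suffixes that are
    part of the ingredient identity (e.g. ``mononitrate`` in isosorbide
    mononitrate) survive because they are not listed.
    """
    global _DEFAULT_SALTS
    if salts is None:
        if _DEFAULT_SALTS is None:
            _DEFAULT_SALTS = load_salt_tokens()
        salts = _DEFAULT_SALTS
    tokens = name.casefold().replace(",", " ").split()
    kept = [t for t in tokens if t not in salts]
    return " ".join(kept)


# ---------------------------------------------------------------------------
# loaders


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def _validate_cell(system: CodeSystem, raw: str, path: Path, row: int) -> ValidatedCode:
    try:
        return validate_code(system, raw)
    except ValueError as exc:
        raise ValueError(f"{path} row {row + 2}: {exc}") from exc  # +2: header, 1-based


def load_kegg_drug_table(path: str | Path) -> list[KeggDrugRecord]:
    """Load a KEGG-DRUG-like edge table (one D-number/YJ/NDC edge per row).

    Columns: ``d_number, yj_code, ndc, category, ingredient_name``; the
    ``yj_code`` and ``ndc`` cells may be empty.  Rows are aggregated into one
    record per D number.
    """
    path = Path(path)
    df = _read_tsv(path, ["d_number", "yj_code", "ndc", "category", "ingredient_name"])
    records: dict[str, KeggDrugRecord] = {}
    yj_sets: dict[str, set[ValidatedCode]] = {}
    ndc_sets: dict[str, set[ValidatedCode]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        d = _validate_cell(CodeSystem.KEGG_D, row.d_number, path, i)
        if d.value not in records:
            records[d.value] = KeggDrugRecord(
                d_number=d,
                yj_codes=frozenset(),
                ndcs=frozenset(),
                category=Category(row.category),
                ingredient_name=row.ingredient_name,
            )
            yj_sets[d.value] = set()
            ndc_sets[d.value] = set()
        if row.yj_code:
            yj_sets[d.value].add(_validate_cell(CodeSystem.YJ, row.yj_code, path, i))
        if row.ndc:
            ndc_sets[d.value].add(_validate_cell(CodeSystem.NDC, row.ndc, path, i))
    out = []
    for key in records:
        rec = records[key]
        rec.yj_codes = frozenset(yj_sets[key])
        rec.ndcs = frozenset(ndc_sets[key])
        out.append(rec)
    log.info("loaded %d KEGG DRUG records (%d edges) from %s", len(out), len(df), path)
    return out


def load_ndc_rxcui_table(path: str | Path) -> list[NdcRxcuiLink]:
    """Load NDC->RxCUI links with activity history.

    Columns: ``ndc, rxcui, concept_class, active, inactivation_date,
    ingredient_name``; ``active`` is ``true``/``false`` and the date is
    ISO-formatted or empty.
    """
    path = Path(path)
    df = _read_tsv(
        path,
        ["ndc", "rxcui", "concept_class", "active", "inactivation_date", "ingredient_name"],
    )
    links = []
    for i, row in enumerate(df.itertuples(index=False)):
        active = row.active.strip().lower() in ("true", "1", "yes")
        inact = date.fromisoformat(row.inactivation_date) if row.inactivation_date else None
        links.append(
            NdcRxcuiLink(
                ndc=_validate_cell(CodeSystem.NDC, row.ndc, path, i),
                rxcui=_validate_cell(CodeSystem.RXCUI, row.rxcui, path, i),
                active=active,
                inactivation_date=inact,
                concept_class=row.concept_class or "IN",
                ingredient_name=row.ingredient_name,
            )
        )
    log.info("loaded %d NDC-RxCUI links from %s", len(links), path)
    return links


def load_rxcui_drugbank_table(path: str | Path) -> list[RxcuiDrugbankLink]:
    """Load candidate RxCUI->DrugBank links (possibly 1:2 before resolution)."""
    path = Path(path)
    df = _read_tsv(path, ["rxcui", "drugbank_id", "name_rxnorm", "name_drugbank"])
    return [
        RxcuiDrugbankLink(
            rxcui=_validate_cell(CodeSystem.RXCUI, row.rxcui, path, i),
            drugbank_id=_validate_cell(CodeSystem.DRUGBANK, row.drugbank_id, path, i),
            name_rxnorm=row.name_rxnorm,
            name_drugbank=row.name_drugbank,
        )
        for i, row in enumerate(df.itertuples(index=False))
    ]


def load_scope_table(path: str | Path) -> dict[str, Scope]:
    """Load the YJ-code -> therapeutic scope (ORAL/INJECTABLE/OTHER) map."""
    path = Path(path)
    df = _read_tsv(path, ["yj_code", "scope"])
    out = {}
    for i, row in enumerate(df.itertuples(index=False)):
        yj = _validate_cell(CodeSystem.YJ, row.yj_code, path, i)
        out[yj.value] = Scope(row.scope)
    return out


# ---------------------------------------------------------------------------
# operations


def filter_allergen_extracts(records: Iterable[KeggDrugRecord]) -> list[KeggDrugRecord]:
    """Drop allergen-extract records (Japanese and international allergen
    product sets differ too much for ingredient-level mapping)."""
    records = list(records)
    kept = [r for r in records if r.category is Category.STANDARD]
    removed = len(records) - len(kept)
    if removed:
        log.info("excluded %d allergen-extract records", removed)
    return kept


def _index_links(links: Iterable[NdcRxcuiLink]) -> dict[str, list[NdcRxcuiLink]]:
    idx: dict[str, list[NdcRxcuiLink]] = {}
    for link in links:
        idx.setdefault(link.ndc.value, []).append(link)
    return idx


def resolve_ndc_to_rxcui(
    ndc: ValidatedCode,
    links: Iterable[NdcRxcuiLink] | Mapping[str, list[NdcRxcuiLink]],
    report: Optional[ConflictReport] = None,
) -> frozenset[ValidatedCode]:
    """Resolve an NDC to its ingredient RxCUIs, honouring the NDC history.

    Only links marked active participate: inactivated links are how a single
    recycled NDC comes to emit two unrelated ingredients.  When more than one
    active RxCUI remains the NDC is appended to the conflict report's
    ``multi_rxcui_ndcs`` and all candidates are returned.
    """
    idx = links if isinstance(links, Mapping) else _index_links(links)
    cands = idx.get(ndc.value, [])
    active = frozenset(l.rxcui for l in cands if l.active)
    if not cands:
        log.debug("NDC %s has no RxNorm links", ndc.value)
    if len(active) > 1 and report is not None:
        report.multi_rxcui_ndcs.append((ndc, active))
    return active


def detect_ingredient_mismatch(
    records: Iterable[KeggDrugRecord],
    links: Iterable[NdcRxcuiLink],
    salts: Optional[frozenset[str]] = None,
    report: Optional[ConflictReport] = None,
) -> ConflictReport:
    """Flag D-number<->NDC edges whose two sides name different ingredients.

    A mismatch row is emitted whenever the normalized KEGG-side ingredient
    name differs from the normalized RxNorm-side name on an active link of
    that edge (e.g. a D number for isosorbide mononitrate whose NDC resolves
    to timolol).  Serves as the automated stand-in for manual notation
    verification.
    """
    if report is None:
        report = ConflictReport()
    idx = _index_links(links)
    for rec in sorted(records, key=lambda r: r.d_number.value):
        kegg_norm = normalize_ingredient_name(rec.ingredient_name, salts)
        for ndc in sorted(rec.ndcs):
            for link in idx.get(ndc.value, []):
                if not link.active:
                    continue
                rx_norm = normalize_ingredient_name(link.ingredient_name, salts)
                if kegg_norm and rx_norm and kegg_norm != rx_norm:
                    report.ingredient_mismatches.append(
                        (rec.d_number, ndc, rec.ingredient_name, link.ingredient_name)
                    )
    return report


def build_yj_rxcui(
    records: Iterable[KeggDrugRecord],
    links: Iterable[NdcRxcuiLink],
    report: Optional[ConflictReport] = None,
    salts: Optional[frozenset[str]] = None,
) -> list[CrosswalkRow]:
    """Build the YJ-RxCUI table: one row per (YJ, RxCUI) reachable through a
    D number and an *active* NDC link.

    ``records`` should already be filtered of allergen extracts.  Rows whose
    every supporting edge carries an ingredient-name mismatch are marked
    ``INACCURATE`` (automated proxy for pharmacist verification) and will be
    excluded from downstream joins.
    """
    records = list(records)
    if report is None:
        report = ConflictReport()
        detect_ingredient_mismatch(records, links, salts=salts, report=report)
    bad_edges = report.mismatch_edges()
    idx = _index_links(links)
    rows: dict[tuple[str, str], CrosswalkRow] = {}
    flagged: dict[tuple[str, str], bool] = {}
    for rec in sorted(records, key=lambda r: r.d_number.value):
        for ndc in sorted(rec.ndcs):
            rxcuis = resolve_ndc_to_rxcui(ndc, idx, report=None)
            edge_bad = (rec.d_number.value, ndc.value) in bad_edges
            for rxcui in sorted(rxcuis):
                for yj in sorted(rec.yj_codes):
                    key = (yj.value, rxcui.value)
                    if key not in rows:
                        rows[key] = CrosswalkRow(yj=yj, rxcui=rxcui)
                        flagged[key] = edge_bad
                    else:
                        flagged[key] = flagged[key] or edge_bad
    for key, row in rows.items():
        if flagged[key]:
            row.verification_status = VerificationStatus.INACCURATE
    out = [rows[k] for k in sorted(rows)]
    n_bad = sum(1 for r in out if r.verification_status is VerificationStatus.INACCURATE)
    log.info("YJ-RxCUI table: %d rows (%d flagged INACCURATE)", len(out), n_bad)
    return out


def resolve_rxcui_to_drugbank(
    links: Iterable[RxcuiDrugbankLink],
    report: Optional[ConflictReport] = None,
    salts: Optional[frozenset[str]] = None,
) -> tuple[dict[str, ValidatedCode], list[ValidatedCode]]:
    """Collapse candidate RxCUI->DrugBank links to a functional 1:1 map.

    RxCUIs with a single candidate map directly.  For the occasional 1:2
    correspondence the candidate whose DrugBank name equals the RxNorm name
    (after normalization) wins; if neither or both match, the
    lexicographically smallest accession is kept and the RxCUI is flagged in
    the conflict report so the tie-break is visible.  RxCUIs present in the
    crosswalk but absent here belong on the caller's unresolved list.

    Returns the map plus the list of flagged/tied RxCUIs.
    """
    by_rxcui: dict[str, list[RxcuiDrugbankLink]] = {}
    for l in links:
        by_rxcui.setdefault(l.rxcui.value, []).append(l)
    resolved: dict[str, ValidatedCode] = {}
    flagged: list[ValidatedCode] = []
    for rxcui in sorted(by_rxcui):
        cands = sorted(by_rxcui[rxcui], key=lambda l: l.drugbank_id.value)
        uniq = {c.drugbank_id.value: c for c in cands}
        cands = [uniq[k] for k in sorted(uniq)]
        if len(cands) == 1:
            resolved[rxcui] = cands[0].drugbank_id
            continue
        matches = [
            c
            for c in cands
            if normalize_ingredient_name(c.name_drugbank, salts)
            == normalize_ingredient_name(c.name_rxnorm, salts)
        ]
        if len(matches) == 1:
            resolved[rxcui] = matches[0].drugbank_id
        else:
            resolved[rxcui] = cands[0].drugbank_id
            flagged.append(cands[0].rxcui)
            if report is not None:
                report.drugbank_ties.append(
                    (cands[0].rxcui, frozenset(c.drugbank_id for c in cands))
                )
    return resolved, flagged


def build_yj_rxcui_db(
    crosswalk: Iterable[CrosswalkRow],
    db_map: Mapping[str, ValidatedCode],
    scope_table: Mapping[str, Scope],
    report: Optional[ConflictReport] = None,
    include_inaccurate: bool = False,
) -> list[CrosswalkRow]:
    """Join DrugBank identifiers onto the crosswalk and restrict scope.

    Keeps rows whose YJ code is an oral or injectable NHI-listed ingredient
    and whose verification status is not ``INACCURATE`` (override with
    ``include_inaccurate``).  Rows whose RxCUI has no resolved DrugBank
    identifier are retained with a null identifier and logged; the RxCUI goes
    to the conflict report's ``unresolved_drugbank`` list.
    """
    out: list[CrosswalkRow] = []
    unresolved_seen: set[str] = set()
    for row in crosswalk:
        scope = scope_table.get(row.yj.value, Scope.OTHER)
        if scope not in (Scope.ORAL, Scope.INJECTABLE):
            continue
        if row.verification_status is VerificationStatus.INACCURATE and not include_inaccurate:
            continue
        db = db_map.get(row.rxcui.value)
        if db is None:
            log.warning("RxCUI %s has no DrugBank identifier; kept with null", row.rxcui.value)
            if report is not None and row.rxcui.value not in unresolved_seen:
                report.unresolved_drugbank.append(row.rxcui)
                unresolved_seen.add(row.rxcui.value)
        out.append(
            CrosswalkRow(
                yj=row.yj,
                rxcui=row.rxcui,
                drugbank_id=db,
                verification_status=row.verification_status,
                scope=scope,
            )
        )
    out.sort(key=lambda r: (r.yj.value, r.rxcui.value))
    log.info("YJ-RxCUI-DB table: %d rows", len(out))
    return out


def apply_review_file(rows: Iterable[CrosswalkRow], path: str | Path) -> list[CrosswalkRow]:
    """Override verification statuses from a manual review TSV
    (columns ``yj_code, rxcui, status``)."""
    path = Path(path)
    df = _read_tsv(path, ["yj_code", "rxcui", "status"])
    overrides = {
        (r.yj_code, r.rxcui): VerificationStatus(r.status)
        for r in df.itertuples(index=False)
    }
    out = []
    for row in rows:
        status = overrides.get((row.yj.value, row.rxcui.value), row.verification_status)
        out.append(
            CrosswalkRow(row.yj, row.rxcui, row.drugbank_id, status, row.scope)
        )
    return out


# ---------------------------------------------------------------------------
# writers


def write_crosswalk(rows: Iterable[CrosswalkRow], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "yj_code": r.yj.value,
                "rxcui": r.rxcui.value,
                "drugbank_id": r.drugbank_id.value if r.drugbank_id else "",
                "verification_status": r.verification_status.value,
                "scope": r.scope.value,
            }
            for r in sorted(rows, key=lambda r: (r.yj.value, r.rxcui.value))
        ],
        columns=["yj_code", "rxcui", "drugbank_id", "verification_status", "scope"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_conflicts(report: ConflictReport, path: str | Path) -> None:
    """Serialize the conflict report as a long-format TSV."""
    rows = []
    for ndc, rxcuis in report.multi_rxcui_ndcs:
        rows.append(
            {"kind": "multi_rxcui_ndc", "key": ndc.value,
             "detail": "|".join(sorted(c.value for c in rxcuis))}
        )
    for d, ndc, kegg_name, rx_name in report.ingredient_mismatches:
        rows.append(
            {"kind": "ingredient_mismatch", "key": f"{d.value}:{ndc.value}",
             "detail": f"{kegg_name} != {rx_name}"}
        )
    for rxcui in report.unresolved_drugbank:
        rows.append({"kind": "unresolved_drugbank", "key": rxcui.value, "detail": ""})
    for rxcui, dbs in report.drugbank_ties:
        rows.append(
            {"kind": "drugbank_tie", "key": rxcui.value,
             "detail": "|".join(sorted(d.value for d in dbs))}
        )
    pd.DataFrame(rows, columns=["kind", "key", "detail"]).to_csv(path, sep="\t", index=False)
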