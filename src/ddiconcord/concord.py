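"""Cross-source concordance: integration, cross-tabulation and Cohen's kappa.

Harmonized per-source interaction sets are merged on canonical ingredient
pairs into one record per pair, holding a controlled level per source
(*No information* where the pair is absent).  Agreement is quantified two
ways:

* a 3x3 cross-tabulation of the Japanese level against a single aggregated
  international level (by default the maximum severity over the six
  international sources — a safety-oriented choice: any source calling a
  combination contraindicated makes the international axis "Highest"); and
* pairwise Cohen's kappa between all sources over the 3-level labels,
  kappa = (p_o - p_e) / (1 - p_e), with observed agreement p_o and chance
  agreement p_e taken from the contingency marginals, interpreted on the
  McHugh banding scale.

For a pairwise comparison, pairs absent from *both* sources are excluded:
they are unobservable for that comparison, and including them would require
an undefined universe of all conceivable drug pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .ddi import (
    INTERNATIONAL_SOURCES,
    CanonicalPair,
    ControlledLevel,
    HarmonizedDDI,
    SourceId,
)

__all__ = [
    "LEVEL_ORDER",
    "IntegratedRecord",
    "ContingencyTable",
    "KappaMatrix",
    "DiscordanceReport",
    "DegenerateTableError",
    "AGGREGATION_RULES",
    "integrate",
    "aggregate_international",
    "crosstab",
    "cohen_kappa",
    "kappa_matrix",
    "kappa_band",
    "discordance_report",
    "write_heatmap",
    "write_integrated",
    "write_crosstab",
    "write_kappa_matrix",
]

log = logging.getLogger(__name__)

#: Display/computation order for controlled levels (HC, OC, NI).
LEVEL_ORDER: tuple[ControlledLevel, ...] = (
    ControlledLevel.HIGHEST,
    ControlledLevel.OTHER,
    ControlledLevel.NOINFO,
)


class DegenerateTableError(ValueError):
    """Chance agreement is 1 but observed agreement is not: kappa undefined."""


@dataclass
class IntegratedRecord:
    """One canonical pair with its controlled level in every source."""

    pair: CanonicalPair
    levels: dict[SourceId, ControlledLevel]
    japanese_level: ControlledLevel = ControlledLevel.NOINFO
    international_level: ControlledLevel = ControlledLevel.NOINFO


@dataclass
class ContingencyTable:
    """A KxK cross-tabulation with marginals and agreement proportions."""

    row_labels: tuple
    col_labels: tuple
    counts: np.ndarray
    row_marginals: np.ndarray = field(init=False)
    col_marginals: np.ndarray = field(init=False)
    total: int = field(init=False)
    p_o: Optional[float] = field(init=False)
    p_e: Optional[float] = field(init=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k_r, k_c = len(self.row_labels), len(self.col_labels)
        if self.counts.shape != (k_r, k_c):
            raise ValueError(
                f"counts shape {self.counts.shape} != labels ({k_r}, {k_c})"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        self.row_marginals = self.counts.sum(axis=1)
        self.col_marginals = self.counts.sum(axis=0)
        self.total = int(self.counts.sum())
        if self.total == 0:
            self.p_o = None
            self.p_e = None
        else:
            k = min(k_r, k_c)
            self.p_o = float(np.trace(self.counts[:k, :k])) / self.total
            self.p_e = float(
                (self.row_marginals[:k] * self.col_marginals[:k]).sum()
            ) / self.total**2

    @classmethod
    def from_counts(cls, counts, labels: Sequence) -> "ContingencyTable":
        """Build a square table directly from a count matrix."""
        return cls(tuple(labels), tuple(labels), np.asarray(counts))


@dataclass
class KappaMatrix:
    """Symmetric pairwise Cohen's kappa among sources, with agreement bands."""

    sources: tuple[SourceId, ...]
    values: np.ndarray  # float matrix; NaN where kappa is undefined
    bands: list[list[Optional[str]]]


@dataclass
class DiscordanceReport:
    """Pairs binned by (international level, Japanese level), with the two
    headline discordance cells pulled out explicitly."""

    cells: dict[tuple[ControlledLevel, ControlledLevel], list[CanonicalPair]]
    intl_high_jp_missing: list[CanonicalPair] = field(init=False)
    jp_high_intl_missing: list[CanonicalPair] = field(init=False)

    def __post_init__(self):
        self.intl_high_jp_missing = self.cells.get(
            (ControlledLevel.HIGHEST, ControlledLevel.NOINFO), []
        )
        self.jp_high_intl_missing = self.cells.get(
            (ControlledLevel.NOINFO, ControlledLevel.HIGHEST), []
        )


# ---------------------------------------------------------------------------
# integration


def _max_severity(levels: Iterable[ControlledLevel]) -> ControlledLevel:
    rank = {l: i for i, l in enumerate(LEVEL_ORDER)}
    return min(levels, key=lambda l: rank[l], default=ControlledLevel.NOINFO)


def aggregate_international(
    record: IntegratedRecord, rule: str = "max"
) -> ControlledLevel:
    """Collapse the six international source levels onto one axis.

    The default ``max`` rule takes the most severe level present (Highest if
    any source says Highest, else Other if any says Other, else No
    information).
    """
    fn = AGGREGATION_RULES.get(rule)
    if fn is None:
        raise ValueError(f"unknown aggregation rule {rule!r}; known: {sorted(AGGREGATION_RULES)}")
    return fn(record)


def _aggregate_max(record: IntegratedRecord) -> ControlledLevel:
    return _max_severity(record.levels[s] for s in INTERNATIONAL_SOURCES)


def _aggregate_majority(record: IntegratedRecord) -> ControlledLevel:
    present = [
        record.levels[s]
        for s in INTERNATIONAL_SOURCES
        if record.levels[s] is not ControlledLevel.NOINFO
    ]
    if not present:
        return ControlledLevel.NOINFO
    n_high = sum(1 for l in present if l is ControlledLevel.HIGHEST)
    return ControlledLevel.HIGHEST if 2 * n_high > len(present) else ControlledLevel.OTHER


AGGREGATION_RULES: dict[str, Callable[[IntegratedRecord], ControlledLevel]] = {
    "max": _aggregate_max,
    "majority": _aggregate_majority,
}


def integrate(
    harmonized_sets: Mapping[SourceId, Iterable[HarmonizedDDI]],
    aggregation: str = "max",
) -> list[IntegratedRecord]:
    """Merge per-source harmonized sets into one record per canonical pair.

    Every record carries an entry for every source (*No information* where
    the pair is absent), the Japanese level (= the KEGG entry) and the
    aggregated international level.  Output is sorted by pair for
    deterministic downstream tables.
    """
    by_pair: dict[CanonicalPair, dict[SourceId, ControlledLevel]] = {}
    for source, records in harmonized_sets.items():
        source = SourceId(source)
        for rec in records:
            levels = by_pair.setdefault(
                rec.pair, {s: ControlledLevel.NOINFO for s in SourceId}
            )
            levels[source] = rec.level
    out = []
    for pair in sorted(by_pair):
        rec = IntegratedRecord(pair=pair, levels=by_pair[pair])
        rec.japanese_level = rec.levels[SourceId.KEGG]
        rec.international_level = aggregate_international(rec, aggregation)
        out.append(rec)
    log.info("integrated %d canonical pairs across %d sources", len(out), len(SourceId))
    return out


# ---------------------------------------------------------------------------
# cross-tabulation and kappa


def crosstab(
    records: Iterable[IntegratedRecord],
    axis_a: Callable[[IntegratedRecord], ControlledLevel],
    axis_b: Callable[[IntegratedRecord], ControlledLevel],
    labels: Sequence[ControlledLevel] = LEVEL_ORDER,
) -> ContingencyTable:
    """Cross-tabulate two level extractors over the integrated records.

    ``counts[i][j]`` is the number of records with ``axis_a`` level
    ``labels[i]`` and ``axis_b`` level ``labels[j]``.
    """
    labels = tuple(labels)
    idx = {l: i for i, l in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for rec in records:
        counts[idx[axis_a(rec)], idx[axis_b(rec)]] += 1
    return ContingencyTable(labels, labels, counts)


def cohen_kappa(table: ContingencyTable) -> float:
    """Cohen's chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    Raises
    ------
    ValueError
        On an empty table.
    DegenerateTableError
        When chance agreement is exactly 1 but observed agreement is not
        (all mass in one diagonal cell gives kappa = 1 by convention).
    """
    if table.total == 0 or table.p_o is None:
        raise ValueError("cohen_kappa requires a nonempty table")
    if math.isclose(table.p_e, 1.0, abs_tol=1e-15):
        if math.isclose(table.p_o, 1.0, abs_tol=1e-15):
            return 1.0
        raise DegenerateTableError(
            "chance agreement is 1 but observed agreement is not"
        )
    return (table.p_o - table.p_e) / (1.0 - table.p_e)


def kappa_band(value: float) -> str:
    """McHugh interpretation band for a kappa value.

    <=0.20 none, 0.21-0.39 minimal, 0.40-0.59 weak, 0.60-0.79 moderate,
    0.80-0.90 strong, >0.90 almost perfect.
    """
    if not (-1.0 - 1e-12 <= value <= 1.0 + 1e-12):
        raise ValueError(f"kappa out of range [-1, 1]: {value}")
    if value > 0.90:
        return "almost perfect"
    if value >= 0.80:
        return "strong"
    if value >= 0.60:
        return "moderate"
    if value >= 0.40:
        return "weak"
    if value >= 0.21:
        return "minimal"
    return "none"


def kappa_matrix(
    records: Sequence[IntegratedRecord],
    sources: Sequence[SourceId] = tuple(SourceId),
) -> KappaMatrix:
    """Pairwise Cohen's kappa among sources on the 3-level labels.

    For each source pair the 3x3 cross-tab is built over records present in
    at least one of the two sources (*No information* participates only when
    the other source has the pair).  Degenerate cells propagate as NaN with
    a warning.
    """
    sources = tuple(SourceId(s) for s in sources)
    if len(sources) < 2:
        raise ValueError("kappa_matrix requires at least 2 sources")
    n = len(sources)
    values = np.eye(n)
    bands: list[list[Optional[str]]] = [[None] * n for _ in range(n)]
    for i in range(n):
        bands[i][i] = kappa_band(1.0)
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = sources[i], sources[j]
            subset = [
                r
                for r in records
                if r.levels[si] is not ControlledLevel.NOINFO
                or r.levels[sj] is not ControlledLevel.NOINFO
            ]
            if not subset:
                values[i, j] = values[j, i] = np.nan
                log.warning("no shared observable pairs for %s vs %s", si.value, sj.value)
                continue
            table = crosstab(subset, lambda r: r.levels[si], lambda r: r.levels[sj])
            try:
                k = cohen_kappa(table)
            except DegenerateTableError:
                log.warning("degenerate table for %s vs %s; kappa undefined", si.value, sj.value)
                k = np.nan
            values[i, j] = values[j, i] = k
            if not math.isnan(k):
                bands[i][j] = bands[j][i] = kappa_band(max(-1.0, min(1.0, k)))
    return KappaMatrix(sources=sources, values=values, bands=bands)


def discordance_report(records: Iterable[IntegratedRecord]) -> DiscordanceReport:
    """Bin every pair by (international level, Japanese level).

    The two headline lists are the discordance gaps: combinations the
    international sources rank Highest that Japanese labels omit entirely,
    and Japanese contraindications the international sources lack.
    """
    cells: dict[tuple[ControlledLevel, ControlledLevel], list[CanonicalPair]] = {
        (a, b): [] for a in LEVEL_ORDER for b in LEVEL_ORDER
    }
    for rec in records:
        cells[(rec.international_level, rec.japanese_level)].append(rec.pair)
    return DiscordanceReport(cells=cells)


# ---------------------------------------------------------------------------
# output


def write_integrated(records: Iterable[IntegratedRecord], path: str | Path) -> None:
    cols = ["low_rxcui", "high_rxcui"] + [s.value.lower() for s in SourceId] + [
        "japanese_level",
        "international_level",
    ]
    rows = []
    for r in sorted(records, key=lambda r: r.pair):
        row = {
            "low_rxcui": r.pair.low.value,
            "high_rxcui": r.pair.high.value,
            "japanese_level": r.japanese_level.value,
            "international_level": r.international_level.value,
        }
        for s in SourceId:
            row[s.value.lower()] = r.levels[s].value
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_crosstab(table: ContingencyTable, path: str | Path) -> None:
    """Write a contingency table with marginals as TSV."""
    labels_r = [str(getattr(l, "value", l)) for l in table.row_labels]
    labels_c = [str(getattr(l, "value", l)) for l in table.col_labels]
    df = pd.DataFrame(table.counts, index=labels_r, columns=labels_c)
    df["total"] = table.row_marginals
    totals = list(table.col_marginals) + [table.total]
    df.loc["total"] = totals
    df.index.name = "level"
    df.to_csv(path, sep="\t")


def write_kappa_matrix(matrix: KappaMatrix, path: str | Path) -> None:
    names = [s.value for s in matrix.sources]
    df = pd.DataFrame(np.round(matrix.values, 6), index=names, columns=names)
    df.index.name = "source"
    df.to_csv(path, sep="\t")


def write_heatmap(matrix: KappaMatrix, path: str | Path) -> None:
    """Render the kappa matrix as a deterministic SVG/PNG heatmap.

    Cell colors follow the McHugh-band semantics (anything below "minimal"
    reads as no agreement).  Rendering settings are pinned so identical
    matrices produce identical bytes.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    import seaborn as sns

    with matplotlib.rc_context({"svg.hashsalt": "ddiconcord"}):
        fig, ax = plt.subplots(figsize=(7, 6))
        names = [s.value for s in matrix.sources]
        sns.heatmap(
            matrix.values,
            vmin=-0.2,
            vmax=1.0,
            annot=True,
            fmt=".2f",
            cmap="YlGnBu",
            xticklabels=names,
            yticklabels=names,
            cbar_kws={"label": "Cohen's kappa"},
            ax=ax,
        )
        ax.set_title("Agreement of controlled DDI severity classifications")
        fig.tight_layout()
        fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
        plt.close(fig)
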