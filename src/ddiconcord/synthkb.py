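"""Synthetic knowledge-base generator with planted ground truth.

The upstream resources the pipeline consumes — a KEGG-DRUG-like product
table, an RxNorm NDC history, an RxCUI<->DrugBank link table and seven
per-source interaction lists — are licensed and cannot be redistributed, so
every test and demonstration runs on synthetic snapshots produced here.  The
generator emulates the *structure* of the real resources, not their
pharmacology: ingredient names are synthetic tokens, and the documented
failure modes of the real data are injected at configurable rates:

* NDC->RxCUI links inactivated in the NDC history (a recycled code that
  would emit a second, wrong ingredient if history were ignored);
* 1:2 RxCUI->DrugBank candidate correspondences;
* ingredient-notation disagreements between the KEGG and RxNorm sides;
* allergen-extract product records;
* symmetric duplicate interaction rows (A-B alongside B-A) and Japanese
  labels carrying both CI and P for one combination;
* "group" precautions fanning one hub ingredient out to many partners,
  which inflates the Japanese *Other class* the way therapeutic-category
  precautions do in real labels.

Severity is generated from a latent per-pair propensity ``u ~ U(0,1)``.  A
source covering the pair reports *Highest* when its comparison draw falls
below its configured Highest fraction; with probability ``agreement`` the
draw is the shared latent ``u`` (maximally concordant coupling), otherwise
an independent uniform.  Marginal Highest fractions therefore match the
configured per-source proportions exactly in expectation for **any**
agreement value, while cross-source agreement rises monotonically with it.

``expected_truth`` recomputes the integrated cross-tabulation and pairwise
kappa matrix by direct enumeration of the planted assignments, in plain
loops deliberately independent of the pipeline modules, so recovery tests
compare two separate code paths.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .ddi import SEVERITY_MAPPINGS, ControlledLevel, SourceId

__all__ = ["SynthConfig", "SyntheticBundle", "generate", "expected_truth", "write_bundle"]

#: Per-source interaction volumes on the published scale (count of Highest,
#: count of Other) used to derive default Highest fractions and relative
#: coverage of the synthetic pair universe.
SOURCE_VOLUMES: dict[SourceId, tuple[int, int]] = {
    SourceId.FRENCHDB: (1820, 60227),
    SourceId.NDFRT: (688, 1188),
    SourceId.OSCAR: (451, 8657),
    SourceId.WORLDVISTA: (1527, 12166),
    SourceId.ONC_HIGH: (1930, 0),
    SourceId.ONC_NONINT: (0, 2101),
    SourceId.KEGG: (3230, 112589),
}


def _default_high_fractions() -> dict[SourceId, float]:
    return {s: h / (h + o) for s, (h, o) in SOURCE_VOLUMES.items()}


def _default_coverage() -> dict[SourceId, float]:
    # Relative volumes scaled so the largest source covers ~85% of the
    # synthetic pair universe.
    totals = {s: h + o for s, (h, o) in SOURCE_VOLUMES.items()}
    peak = max(totals.values())
    return {s: max(0.04, round(0.85 * t / peak, 3)) for s, t in totals.items()}


@dataclass
class SynthConfig:
    """Knobs of the synthetic knowledge-base generator.

    Defaults emulate the published per-source volumes (Highest/Other
    proportions; relative coverage) on a scaled-down pair universe.
    ``agreement`` in [0, 1] couples severity across sources: 0 makes sources
    independent given their marginals, 1 maximally concordant.
    """

    seed: int
    n_ingredients: int = 200
    n_drugs: int = 240
    n_pairs: int = 2000
    n_groups: int = 5
    group_size: int = 15
    agreement: float = 0.7
    coverage: dict[SourceId, float] = field(default_factory=_default_coverage)
    high_fraction: dict[SourceId, float] = field(default_factory=_default_high_fractions)
    # noise rates
    inactive_ndc_rate: float = 0.03       # a drug's only RxNorm link is inactivated
    extra_inactive_link_rate: float = 0.03  # recycled NDC: extra inactive wrong-ingredient link
    multi_drugbank_rate: float = 0.03     # RxCUI with two DrugBank candidates
    name_mismatch_rate: float = 0.03      # KEGG vs RxNorm ingredient-notation disagreement
    allergen_rate: float = 0.02           # allergen-extract product records
    salt_suffix_rate: float = 0.10        # benign salt-suffix notation differences
    scope_other_rate: float = 0.05        # products outside the oral/injectable scope
    symmetric_duplicate_rate: float = 0.30
    mixed_label_rate: float = 0.20        # Japanese CI rows also emitted with P

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in (
            "agreement", "inactive_ndc_rate", "extra_inactive_link_rate",
            "multi_drugbank_rate", "name_mismatch_rate", "allergen_rate",
            "salt_suffix_rate", "scope_other_rate", "symmetric_duplicate_rate",
            "mixed_label_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_ingredients", "n_drugs", "n_pairs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_drugs < self.n_ingredients:
            raise ValueError("n_drugs must be >= n_ingredients (one primary drug each)")
        self.coverage = {SourceId(s): float(v) for s, v in self.coverage.items()}
        self.high_fraction = {SourceId(s): float(v) for s, v in self.high_fraction.items()}
        for d in (self.coverage, self.high_fraction):
            for s, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{s.value}: probability out of [0, 1]: {v}")
        if self.n_pairs > self.n_ingredients * (self.n_ingredients - 1) // 2:
            raise ValueError("n_pairs exceeds the number of distinct ingredient pairs")


@dataclass
class SyntheticBundle:
    """Generated resource snapshots plus the planted truth."""

    config: SynthConfig
    kegg_drug: pd.DataFrame       # d_number, yj_code, ndc, category, ingredient_name
    ndc_rxcui: pd.DataFrame       # ndc, rxcui, concept_class, active, inactivation_date, ingredient_name
    rxcui_drugbank: pd.DataFrame  # rxcui, drugbank_id, name_rxnorm, name_drugbank
    scope: pd.DataFrame           # yj_code, scope
    ddi: dict[SourceId, pd.DataFrame]  # code_a, code_b, raw_label
    # planted truth
    truth_crosswalk: set[tuple[str, str]]            # (yj, rxcui) expected in the DB table
    truth_source_levels: dict[SourceId, dict[tuple[str, str], str]]  # pair -> HIGHEST/OTHER
    truth_jp_mappable: set[str]                      # rxcuis reachable from Japanese labels


def _other_labels(source: SourceId) -> list[str]:
    vocab = SEVERITY_MAPPINGS[source]
    return sorted(l for l, lev in vocab.items() if lev is ControlledLevel.OTHER)


def _high_labels(source: SourceId) -> list[str]:
    vocab = SEVERITY_MAPPINGS[source]
    return sorted(l for l, lev in vocab.items() if lev is ControlledLevel.HIGHEST)


def generate(config: SynthConfig) -> SyntheticBundle:
    """Generate a complete synthetic bundle, deterministically for a seed."""
    rng = np.random.default_rng(config.seed)
    n_ing = config.n_ingredients

    # --- ingredient universe -------------------------------------------------
    rxcuis = [str(10000 + i) for i in range(n_ing)]
    names = [f"ingredient{i:04d}" for i in range(n_ing)]
    prefixes = [f"{1000000 + i:07d}" for i in range(n_ing)]
    db_primary = [f"DB{10000 + i:05d}" for i in range(n_ing)]
    concept_class = ["MIN" if rng.random() < 0.08 else "IN" for _ in range(n_ing)]

    # --- drugs (one primary per ingredient, extras round-robin) --------------
    letters = "ABCDEFGHJK"
    kegg_rows, link_rows, scope_rows = [], [], []
    jp_mappable: set[str] = set()
    truth_crosswalk: set[tuple[str, str]] = set()
    for d in range(config.n_drugs):
        i = d % n_ing
        d_number = f"D{10000 + d:05d}"
        yj = prefixes[i] + letters[int(rng.integers(len(letters)))] + f"{d % 10000:04d}"
        ndc = f"{20000 + d:05d}0010"  # canonical labeler+product form
        allergen = rng.random() < config.allergen_rate
        inactive_only = rng.random() < config.inactive_ndc_rate
        mismatch = rng.random() < config.name_mismatch_rate
        salted = rng.random() < config.salt_suffix_rate
        scope_other = rng.random() < config.scope_other_rate
        extra_inactive = rng.random() < config.extra_inactive_link_rate

        kegg_name = names[i] + (" hydrochloride" if salted else "")
        link_name = names[(i + 1) % n_ing] if mismatch else names[i]
        category = "ALLERGEN_EXTRACT" if allergen else "STANDARD"
        scope = "OTHER" if scope_other else ("ORAL" if rng.random() < 0.5 else "INJECTABLE")

        kegg_rows.append(
            {"d_number": d_number, "yj_code": yj, "ndc": ndc,
             "category": category, "ingredient_name": kegg_name}
        )
        link_rows.append(
            {"ndc": ndc, "rxcui": rxcuis[i], "concept_class": concept_class[i],
             "active": "false" if inactive_only else "true",
             "inactivation_date": "2020-09-01" if inactive_only else "",
             "ingredient_name": link_name}
        )
        if extra_inactive:
            # recycled NDC: a second, inactivated link pointing at another ingredient
            j = (i + 7) % n_ing
            link_rows.append(
                {"ndc": ndc, "rxcui": rxcuis[j], "concept_class": concept_class[j],
                 "active": "false", "inactivation_date": "2019-03-01",
                 "ingredient_name": names[j]}
            )
        scope_rows.append({"yj_code": yj, "scope": scope})

        survives = (
            not allergen
            and not inactive_only
            and not mismatch
            and scope in ("ORAL", "INJECTABLE")
        )
        if survives:
            truth_crosswalk.add((yj, rxcuis[i]))
            if d == i:  # primary drug carries the interaction listings
                jp_mappable.add(rxcuis[i])

    # --- RxCUI -> DrugBank candidates ----------------------------------------
    db_rows = []
    for i in range(n_ing):
        db_rows.append(
            {"rxcui": rxcuis[i], "drugbank_id": db_primary[i],
             "name_rxnorm": names[i], "name_drugbank": names[i]}
        )
        if rng.random() < config.multi_drugbank_rate:
            tie = rng.random() < 0.5
            db_rows.append(
                {"rxcui": rxcuis[i], "drugbank_id": f"DB{50000 + i:05d}",
                 "name_rxnorm": names[i],
                 "name_drugbank": names[i] if tie else "variant " + names[i]}
            )

    # --- planted pair universe -----------------------------------------------
    pair_set: set[tuple[int, int]] = set()
    while len(pair_set) < config.n_pairs:
        need = config.n_pairs - len(pair_set)
        a = rng.integers(0, n_ing, size=2 * need + 8)
        b = rng.integers(0, n_ing, size=2 * need + 8)
        for x, y in zip(a, b):
            if x == y:
                continue
            pair_set.add((min(int(x), int(y)), max(int(x), int(y))))
            if len(pair_set) == config.n_pairs:
                break
    pairs = sorted(pair_set)
    latent = rng.random(len(pairs))

    sources = list(SourceId)
    truth_source_levels: dict[SourceId, dict[tuple[str, str], str]] = {
        s: {} for s in sources
    }
    ddi_rows: dict[SourceId, list[dict]] = {s: [] for s in sources}

    def endpoint(source: SourceId, idx: int) -> str:
        if source is SourceId.KEGG:
            return f"D{10000 + idx:05d}"  # primary drug's D number
        return db_primary[idx]

    for (i, j), u in zip(pairs, latent):
        for s in sources:
            if rng.random() >= config.coverage.get(s, 0.0):
                continue
            draw = u if rng.random() < config.agreement else rng.random()
            high = draw < config.high_fraction.get(s, 0.0)
            # single-level list sources (the ONC lists) can only express one
            # level; clamp if an override made the other level reachable
            if high and not _high_labels(s):
                high = False
            elif not high and not _other_labels(s):
                high = True
            level = "HIGHEST" if high else "OTHER"
            label = (
                _high_labels(s)[0]
                if high
                else _other_labels(s)[int(rng.integers(len(_other_labels(s))))]
            )
            a, b = endpoint(s, i), endpoint(s, j)
            ddi_rows[s].append({"code_a": a, "code_b": b, "raw_label": label})
            if rng.random() < config.symmetric_duplicate_rate:
                ddi_rows[s].append({"code_a": b, "code_b": a, "raw_label": label})
            if s is SourceId.KEGG and high and rng.random() < config.mixed_label_rate:
                ddi_rows[s].append({"code_a": b, "code_b": a, "raw_label": "P"})
            # planted truth honours endpoint mappability
            key = (rxcuis[min(i, j)], rxcuis[max(i, j)])
            reachable = (
                rxcuis[i] in jp_mappable and rxcuis[j] in jp_mappable
                if s is SourceId.KEGG
                else True  # every ingredient resolves to one DrugBank id
            )
            if reachable:
                prev = truth_source_levels[s].get(key)
                if prev != "HIGHEST":
                    truth_source_levels[s][key] = level if prev is None else (
                        "HIGHEST" if "HIGHEST" in (prev, level) else "OTHER"
                    )

    # --- Japanese group precautions (hub fans out with P) --------------------
    for _ in range(config.n_groups):
        hub = int(rng.integers(n_ing))
        partners = rng.choice(
            [k for k in range(n_ing) if k != hub],
            size=min(config.group_size, n_ing - 1),
            replace=False,
        )
        for p in sorted(int(x) for x in partners):
            a, b = endpoint(SourceId.KEGG, hub), endpoint(SourceId.KEGG, p)
            ddi_rows[SourceId.KEGG].append({"code_a": a, "code_b": b, "raw_label": "P"})
            key = (
                rxcuis[min(hub, p)],
                rxcuis[max(hub, p)],
            )
            if rxcuis[hub] in jp_mappable and rxcuis[p] in jp_mappable:
                truth_source_levels[SourceId.KEGG].setdefault(key, "OTHER")

    bundle = SyntheticBundle(
        config=config,
        kegg_drug=pd.DataFrame(
            kegg_rows, columns=["d_number", "yj_code", "ndc", "category", "ingredient_name"]
        ),
        ndc_rxcui=pd.DataFrame(
            link_rows,
            columns=["ndc", "rxcui", "concept_class", "active", "inactivation_date", "ingredient_name"],
        ),
        rxcui_drugbank=pd.DataFrame(
            db_rows, columns=["rxcui", "drugbank_id", "name_rxnorm", "name_drugbank"]
        ),
        scope=pd.DataFrame(scope_rows, columns=["yj_code", "scope"]),
        ddi={s: pd.DataFrame(ddi_rows[s], columns=["code_a", "code_b", "raw_label"]) for s in sources},
        truth_crosswalk=truth_crosswalk,
        truth_source_levels=truth_source_levels,
        truth_jp_mappable=jp_mappable,
    )
    return bundle


# ---------------------------------------------------------------------------
# independent truth enumeration (the oracle the pipeline is checked against)


_LEVELS = ("HIGHEST", "OTHER", "NOINFO")
_INTL = [s for s in SourceId if s is not SourceId.KEGG]


def _truth_integrated(bundle: SyntheticBundle) -> dict[tuple[str, str], dict]:
    """Enumerate planted pairs with per-source, Japanese and aggregated
    international levels — plain dict walking, no pipeline code."""
    universe: set[tuple[str, str]] = set()
    for levels in bundle.truth_source_levels.values():
        universe |= set(levels)
    out = {}
    for key in sorted(universe):
        per_source = {
            s: bundle.truth_source_levels[s].get(key, "NOINFO") for s in SourceId
        }
        intl_levels = [per_source[s] for s in _INTL]
        if "HIGHEST" in intl_levels:
            intl = "HIGHEST"
        elif "OTHER" in intl_levels:
            intl = "OTHER"
        else:
            intl = "NOINFO"
        out[key] = {"levels": per_source, "jp": per_source[SourceId.KEGG], "intl": intl}
    return out


def _truth_kappa_from_labels(xs: list[str], ys: list[str]) -> float:
    """Cohen's kappa by item-level counting (independent of the pipeline).

    Agreement counts stay integers until the final divisions so the result
    carries no accumulated float error.
    """
    n = len(xs)
    agree = sum(1 for x, y in zip(xs, ys) if x == y)
    chance_num = 0
    for lev in _LEVELS:
        chance_num += sum(1 for x in xs if x == lev) * sum(1 for y in ys if y == lev)
    p_o = agree / n
    p_e = chance_num / (n * n)
    if math.isclose(p_e, 1.0, abs_tol=1e-15):
        return 1.0 if math.isclose(p_o, 1.0, abs_tol=1e-15) else float("nan")
    return (p_o - p_e) / (1.0 - p_e)


def expected_truth(bundle: SyntheticBundle) -> tuple[np.ndarray, np.ndarray]:
    """Recompute the integrated 3x3 cross-tabulation (international level x
    Japanese level, both ordered Highest/Other/NoInfo) and the 7x7 pairwise
    kappa matrix (source order = ``SourceId`` declaration order) directly
    from the planted assignments.

    This is the oracle path for recovery testing: straightforward counting
    over the truth dictionaries, sharing no code with the pipeline modules.
    """
    integ = _truth_integrated(bundle)
    idx = {l: k for k, l in enumerate(_LEVELS)}
    table = np.zeros((3, 3), dtype=np.int64)
    for rec in integ.values():
        table[idx[rec["intl"]], idx[rec["jp"]]] += 1

    sources = list(SourceId)
    n = len(sources)
    kappa = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            sa, sb = sources[a], sources[b]
            xs, ys = [], []
            for rec in integ.values():
                la, lb = rec["levels"][sa], rec["levels"][sb]
                if la == "NOINFO" and lb == "NOINFO":
                    continue
                xs.append(la)
                ys.append(lb)
            k = _truth_kappa_from_labels(xs, ys) if xs else float("nan")
            kappa[a, b] = kappa[b, a] = k
    return table, kappa


# ---------------------------------------------------------------------------
# serialization


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> None:
    """Write the snapshot TSVs plus ``truth/`` tables under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.kegg_drug.to_csv(outdir / "kegg_drug.tsv", sep="\t", index=False)
    bundle.ndc_rxcui.to_csv(outdir / "ndc_rxcui.tsv", sep="\t", index=False)
    bundle.rxcui_drugbank.to_csv(outdir / "rxcui_drugbank.tsv", sep="\t", index=False)
    bundle.scope.to_csv(outdir / "scope.tsv", sep="\t", index=False)
    for s, df in bundle.ddi.items():
        df.to_csv(outdir / f"ddi_{s.value.lower()}.tsv", sep="\t", index=False)

    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    rows = [
        {"low_rxcui": lo, "high_rxcui": hi, "source": s.value, "level": lev}
        for s in SourceId
        for (lo, hi), lev in sorted(bundle.truth_source_levels[s].items())
    ]
    pd.DataFrame(rows, columns=["low_rxcui", "high_rxcui", "source", "level"]).to_csv(
        truth_dir / "source_levels.tsv", sep="\t", index=False
    )
    table, kappa = expected_truth(bundle)
    pd.DataFrame(table, index=list(_LEVELS), columns=list(_LEVELS)).to_csv(
        truth_dir / "crosstab.tsv", sep="\t"
    )
    names = [s.value for s in SourceId]
    pd.DataFrame(np.round(kappa, 6), index=names, columns=names).to_csv(
        truth_dir / "kappa.tsv", sep="\t"
    )
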