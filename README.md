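# ddiconcord

Cross-terminology concordance analysis of drug–drug interaction (DDI)
severity.  The package builds a crosswalk from Japanese commercial drug
codes (YJ codes) through RxNorm ingredient-class concepts (RxCUIs) to
DrugBank accession numbers, harmonizes the native severity vocabularies of
seven DDI knowledge sources onto a 3-level controlled scale, integrates the
Japanese and international interaction sets on canonical ingredient pairs,
and quantifies their (dis)agreement.

It is aimed at medical informaticians and pharmacovigilance researchers who
need to compare drug-label interaction information across national
terminologies — for example to find combinations that one country's labels
treat as contraindicated while another's omit entirely.

## The analysis

**Crosswalk.**  A KEGG-DRUG-like product table links YJ codes and U.S.
National Drug Codes (NDCs) to common product entries; an RxNorm NDC table
resolves each NDC to an ingredient-class RxCUI (IN or MIN); an
RxCUI↔DrugBank table connects ingredients to the identifier space of the
international DDI knowledge base.  Three data-quality rules guard the join:
NDC→RxCUI links inactivated in the NDC history are excluded (a recycled NDC
otherwise emits two unrelated ingredients), allergen-extract products are
dropped, and edges whose two sides name different ingredients are flagged
`INACCURATE` and excluded.  Occasional 1:2 RxCUI→DrugBank correspondences
are collapsed to 1:1 by name match with a visible, reported tie-break.

**Severity harmonization.**  Each source's native labels map onto
*Highest class* / *Other class*; *No information* arises at integration for
pairs a source lacks.  E.g. FrenchDB `CI` → Highest and `AD`/`PE`/`PC` →
Other; the Japanese labels `CI` (contraindication) → Highest and `P`
(precaution) → Other, with a combination carrying both CI and P counting as
Highest.  Symmetric duplicates (A–B vs B–A) collapse onto one canonical
unordered RxCUI pair.

**Agreement.**  Japanese vs aggregated-international severity is
cross-tabulated on the 3×3 grid, and every source pair gets Cohen's
chance-corrected kappa

    κ = (p_o − p_e) / (1 − p_e)

with observed agreement p_o and chance agreement p_e from the contingency
marginals, interpreted on the McHugh banding scale (≤ 0.20 none, 0.21–0.39
minimal, 0.40–0.59 weak, …).  A discordance report lists the headline gap
cells: pairs internationally ranked Highest that Japanese labels omit, and
Japanese contraindications absent internationally.

Because the upstream resources are licensed and non-redistributable, the
package ships a synthetic knowledge-base generator (`ddiconcord.synthkb`)
that emulates their structure — including inactive NDC links, 1:2 DrugBank
candidates, notation mismatches, allergen records, symmetric duplicates and
group-precaution fan-out — with planted ground truth and an independent
enumeration oracle, so the entire pipeline is testable offline.

## Worked example

```sh
ddiconcord simulate --out bundle/ --seed 17
ddiconcord all --input-dir bundle/ --out results/
ddiconcord report --summary results/summary.json
```

prints (seed 17, default generator settings):

```
Cross-tabulation (rows: international, cols: Japanese)
        HIGHEST OTHER   NOINFO  Total
HIGHEST 18      83      50      151
OTHER   8       709     318     1035
NOINFO  22      608     0       630
Total   48      1400    368     1816
Cohen's kappa (Japanese vs international): -0.2285
International-Highest pairs missing from Japanese labels: 50
Japanese-Highest pairs missing internationally: 22
```

Reading: 1816 canonical ingredient pairs are known to at least one source;
only 18 + 709 pairs sit on the agreement diagonal of the two informative
levels, 50 internationally-serious pairs have no Japanese label entry, and
22 Japanese contraindications are unknown to the international sources.
The negative κ reflects that most pairs are covered by only one side, so
the *No information* rows/columns dominate the off-diagonal.  `results/`
also contains the crosswalk tables (`yj_rxcui.tsv`, `yj_rxcui_db.tsv`),
`conflicts.tsv`, the per-source harmonized pairs, the full pairwise kappa
matrix (`kappa.tsv`, `heatmap.svg`) and `summary.json` with every count.

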