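# Methods

## Overview

`ddiconcord` compares drug–drug interaction (DDI) severity across
terminologies.  The pipeline has three stages: (1) build an ingredient-level
crosswalk from Japanese YJ codes through RxNorm concepts (RxCUIs) to
DrugBank identifiers; (2) translate seven per-source DDI lists onto
canonical unordered RxCUI pairs and harmonize their native severity labels
onto a 3-level controlled scale; (3) integrate the sets and quantify
agreement by cross-tabulation, Cohen's kappa, and discordance gap reports.
All inputs are flat-file snapshots (TSV), and every stage is deterministic:
identical inputs produce byte-identical outputs.

## Code systems

* **YJ** — 12-character alphanumeric Japanese commercial product code.
  Characters 1–7 (YJ7) carry ingredient information comparable to RxNorm's
  IN/MIN classes; characters 1–9 (YJ9) add dose form and strength,
  comparable to the SCD class.  Validation accepts any 12-character
  alphanumeric string with letters upper-cased; no public check-digit
  specification exists, so none is enforced, and alphabetic characters are
  allowed at any position.
* **NDC** — canonicalized at product level: 5-digit labeler + 4-digit
  product, zero-padded, package segment stripped.  Product level is the
  granularity at which NDCs resolve to ingredient RxCUIs, so package
  distinctions carry no information for this analysis.  Bare 10-digit runs
  are rejected as ambiguous (4-4-2 / 5-3-2 / 5-4-1 cannot be told apart
  without hyphens).
* **RXCUI** (digit string), **DrugBank** (`DB` + 5 digits), **KEGG D**
  (`D` + 5 digits) — straightforward syntactic checks.

## Crosswalk construction

One YJ–RxCUI row exists per (YJ code, RxCUI) reachable via a KEGG-DRUG
entry and an **active** NDC→RxCUI link.  Three exclusion rules:

1. **NDC history.**  Inactivated links never contribute.  This is the fix
   for recycled NDCs that would otherwise emit two different ingredients;
   if more than one *active* RxCUI remains for an NDC, all are kept and the
   NDC is listed in the conflict report.
2. **Allergen extracts** are dropped before mapping.
3. **Notation verification.**  Real crosswalks of this kind are verified by
   a pharmacist; that step is irreproducible in software, so the package
   substitutes an automated detector: an edge whose KEGG-side and
   RxNorm-side ingredient names differ after normalization is reported, and
   a (YJ, RxCUI) row supported by *any* mismatched edge is marked
   `INACCURATE` and excluded from downstream joins (an optional review TSV
   can override statuses, keeping the human step explicit and auditable).

Name normalization is deliberately conservative: case-fold, trim, collapse
whitespace, and drop only exact tokens from a packaged, editable salt list
(`data/salts.txt`).  Identity-bearing suffixes such as *mononitrate* are
not on the list, so isosorbide mononitrate vs timolol stays a mismatch
while metoprolol tartrate vs metoprolol does not.

RxCUI→DrugBank candidates are collapsed to a functional 1:1 map: a unique
candidate wins directly; for 1:2 cases the candidate whose DrugBank name
equals the RxNorm name wins; if neither or both match, the
lexicographically smallest accession is kept and the RxCUI is flagged in
the conflict report, making the tie-break visible.  The final YJ–RxCUI–DB
table keeps oral and injectable ingredients (per the scope table) whose
status is not `INACCURATE`; rows without a resolved DrugBank identifier are
retained with a null identifier and reported.

Both IN and MIN concept-class links are kept: multi-ingredient products map
to both granularities, and no expansion of MIN concepts into constituent
ingredients is attempted.  The table is keyed by (YJ, RxCUI) — a YJ code
may legitimately map to several ingredient concepts.

## Severity harmonization

The controlled scale has three levels: *Highest class*, *Other class*,
*No information* (the last only arises at integration).  Native label →
level, per source: FrenchDB CI → Highest, AD/PE/PC → Other; NDF-RT
Critical → Highest, Significant → Other; OSCAR 3 → Highest, 2/1 → Other;
World Vista Contraindication → Highest, Not recommended / Precaution for
use / Take into account → Other; ONC High Priority → Highest (list
membership); ONC Noninterruptive → Other; KEGG (Japanese labels) CI →
Highest, P → Other.  Label matching is exact after trimming and
case-folding.

Interactions are keyed by canonical unordered RxCUI pairs (`low < high`
lexicographically); symmetric duplicates collapse.  Within one
(pair, source) group, raw labels are unioned and *any* label mapping to
Highest makes the record Highest.  Japanese labels demonstrably carry such
mixed annotations (a combination tagged contraindicated in one direction
and precaution in the other); the rule is applied uniformly to all sources
and logged whenever it fires elsewhere.  Rows whose endpoints resolve to
one ingredient (self pairs) are dropped with a counter — a pair-keyed
comparison cannot represent them.  Endpoints resolving to several
ingredient concepts fan out to every combination.

Japanese endpoints (KEGG D numbers) translate D → YJ → RxCUI through the
YJ–RxCUI–DB table; international endpoints (DrugBank accessions) translate
through the inverse of the resolved 1:1 map.  Rows with an untranslatable
endpoint are dropped and counted per stage in `summary.json`.

## Integration and agreement

Integration takes the union of pairs over all seven sources; each record
holds a level per source, with *No information* for absent sources.  The
single international axis of the headline cross-tabulation aggregates the
six international sources by **maximum severity** (Highest if any source
says Highest, else Other if any says Other, else No information).  This
rule is a design choice of this package — the safety-oriented reading, in
which a contraindication anywhere counts — registered as `max` and
overridable (`majority` is also provided).

Cohen's kappa is computed from contingency marginals:
p_o = Σᵢ nᵢᵢ / n, p_e = Σᵢ rᵢcᵢ / n², κ = (p_o − p_e)/(1 − p_e).  For a
table with all mass in one diagonal cell (p_o = p_e = 1) κ is defined as 1.
For pairwise source comparisons, pairs absent from **both** sources are
excluded — they are unobservable for that comparison, and keeping them
would presuppose a universe of all conceivable drug pairs; *No information*
participates only when the other source has the pair.  Interpretation uses
the McHugh bands (≤ 0.20 none, 0.21–0.39 minimal, 0.40–0.59 weak,
0.60–0.79 moderate, 0.80–0.90 strong, > 0.90 almost perfect).  The level
ordering everywhere is Highest, Other, No-information.

The discordance report bins every pair by (international level, Japanese
level) and surfaces the two headline cells: internationally-Highest pairs
missing from Japanese labels, and Japanese contraindications missing
internationally.

## Synthetic knowledge bases

The real upstream snapshots are licensed and cannot be redistributed, so
`synthkb` generates structurally faithful stand-ins with planted ground
truth.

**Generative model.**  An ingredient universe (default 200 ingredients)
gets synthetic names, RxCUIs, 7-digit YJ ingredient prefixes and DrugBank
accessions.  Each drug product (default 240; at least one per ingredient)
gets a KEGG D number, a YJ code built as ingredient-prefix + letter +
4-digit serial (so YJ-prefix semantics are exercised), an NDC and an
NDC→RxCUI link.  A planted pair universe (default 2000 distinct ingredient
pairs) carries a latent severity propensity `u ~ U(0,1)` per pair.  Each
source covers a pair with its coverage probability; a covering source
reports *Highest* when its comparison draw falls below its configured
Highest fraction, where the draw is the shared latent `u` with probability
`agreement` (default 0.7) and an independent uniform otherwise.  This
coupling leaves every source's marginal Highest fraction equal to its
configured value for *any* agreement, while cross-source agreement rises
monotonically with the parameter.  Default Highest fractions and relative
coverages are scaled from the published per-source volumes (e.g. FrenchDB
1820 Highest / 60 227 Other; Japanese labels 3230 / 112 589); the pair
universe itself is scaled down by roughly an order of magnitude to keep
test runtimes in seconds.  The single-level ONC lists clamp to the one
level they can express.  Japanese "group" precautions (one hub ingredient
fanning out to many partners with P) are emulated by a configurable number
of hub groups, reproducing the inflation of the Japanese *Other class*.

**Noise modes** (rates configurable, all active by default): a drug's only
link inactivated in the NDC history; an extra inactivated wrong-ingredient
link on a recycled NDC; 1:2 DrugBank candidates (half of them undecidable
ties); ingredient-notation mismatches; benign salt-suffix notation
differences; allergen-extract records; out-of-scope (non-oral/injectable)
products; symmetric duplicate DDI rows; Japanese CI rows duplicated with P.

**Truth oracle.**  `expected_truth` recomputes the integrated 3×3
cross-tabulation and the 7×7 pairwise kappa matrix by direct enumeration of
the planted assignments — plain dictionary walking and integer counting,
sharing no code with the pipeline — so recovery tests compare two
independent paths.  Both paths keep agreement counts integral until the
final divisions, so recovery is exact to the bit, not merely to a
tolerance.  The planted truth honours endpoint mappability: a pair whose
Japanese-side chain is broken by noise is absent from both the planted
Japanese truth and the pipeline output.

**What passing recovery tests does and does not show.**  Exact recovery
demonstrates that the pipeline implements the declared exclusion,
deduplication, harmonization, aggregation and kappa definitions correctly
under every planted noise mode.  It does not validate the crosswalk against
real pharmacology: synthetic names are tokens, each ingredient maps 1:1 to
a DrugBank accession, group DDIs arrive pre-expanded, and real-world
irregularities outside the documented noise modes (free-text label
variation, partially overlapping multi-ingredient products, clinical
context-dependent severity, route-of-administration effects) are out of
scope.

## Numerical and degenerate-input choices

* Empty integrated input yields an all-zero table with null p_o/p_e; kappa
  on an empty table raises.
* A pairwise comparison with no observable pairs, or a degenerate table,
  yields NaN in the kappa matrix with a warning (serialized as null).
* Kappa is reported unweighted; no confidence intervals or significance
  tests are attempted.
* Heatmap rendering pins the SVG hash salt and strips the date metadata so
  identical matrices produce identical bytes.
* Problem sizes in the test suite and acceptance script (bundles of 200
  ingredients / 2000 pairs; 100 random kappa tables; 1000-pair
  deduplication inputs) were chosen as the smallest scales at which every
  structural feature of the generator is exercised with comfortable
  statistical margins.

## Known limitations

* The pharmacist verification step is modelled, not reproduced; the
  automated mismatch detector only catches notation disagreements that
  survive salt-token normalization.
* The international aggregation rule and the pairwise-kappa universe
  (union of the two sources' pairs) are explicit design choices of this
  package; alternatives (majority aggregation) are provided but not the
  default.
* The published headline counts from the licensed snapshots cannot be
  regenerated from scratch; only their printed cross-tabulation arithmetic
  is reconstructed.
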