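"""Drug code systems: validation, canonicalization and structural semantics.

Five coding systems appear in the crosswalk pipeline:

* **YJ** — the Japanese individual drug code, a 12-character alphanumeric
  commercial product code.  Its first 7 characters identify the ingredient
  (analogous to RxNorm's IN/MIN granularity) and the first 9 the
  ingredient + dose form + strength (analogous to the SCD class).
* **NDC** — the U.S. National Drug Code.  Printed forms vary (hyphenated
  labeler-product, labeler-product-package, bare digit runs); the canonical
  form used here is the product level: 5-digit labeler + 4-digit product,
  zero padded, package segment stripped.
* **RXCUI** — an RxNorm Concept Unique Identifier, a nonempty digit string.
* **DRUGBANK** — a DrugBank accession number, ``DB`` + 5 digits.
* **KEGG_D** — a KEGG DRUG entry identifier, ``D`` + 5 digits.

All validation is pure, total and deterministic; canonical values round-trip
through :func:`validate_code` unchanged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "CodeSystem",
    "PrefixLevel",
    "ValidatedCode",
    "CodeValidationError",
    "WrongSystemError",
    "validate_code",
    "normalize_ndc",
    "yj_prefix",
]


class CodeSystem(str, Enum):
    """Closed enumeration of the drug coding systems the pipeline touches."""

    YJ = "YJ"
    NDC = "NDC"
    RXCUI = "RXCUI"
    DRUGBANK = "DRUGBANK"
    KEGG_D = "KEGG_D"


class PrefixLevel(str, Enum):
    """Granularity levels encoded in YJ code prefixes.

    ``INGREDIENT7`` (YJ7) approximates RxNorm ingredient (IN/MIN) granularity;
    ``SCD9`` (YJ9) approximates the Semantic Clinical Drug class.
    """

    INGREDIENT7 = "INGREDIENT7"
    SCD9 = "SCD9"


class CodeValidationError(ValueError):
    """A raw code string violates its system's syntax rule."""

    def __init__(self, system: CodeSystem, raw: str, rule: str):
        self.system = system
        self.raw = raw
        self.rule = rule
        super().__init__(f"{system.value} code {raw!r}: {rule}")


class WrongSystemError(TypeError):
    """An operation received a code from the wrong coding system."""


@dataclass(frozen=True, order=True)
class ValidatedCode:
    """A syntax-checked drug code in canonical form.

    ``value`` is the canonical string; ``raw`` preserves the input as read
    (e.g. a hyphenated NDC).  Equality and ordering consider only
    ``(system, value)`` so that differently-written inputs that normalize to
    the same canonical code compare equal.
    """

    system: CodeSystem
    value: str
    raw: str = field(default="", compare=False)

    def __post_init__(self):
        if not self.raw:
            object.__setattr__(self, "raw", self.value)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.value


_YJ_RE = re.compile(r"^[0-9A-Z]{12}$")
_KEGG_D_RE = re.compile(r"^D\d{5}$")
_DRUGBANK_RE = re.compile(r"^DB\d{5}$")
_RXCUI_RE = re.compile(r"^\d+$")


def validate_code(system: CodeSystem, raw: str) -> ValidatedCode:
    """Validate ``raw`` against ``system``'s syntax and return its canonical form.

    Parameters
    ----------
    system:
        The coding system the string claims to belong to.
    raw:
        The code as read from an input file; surrounding whitespace is
        ignored and letters are upper-cased before checking.

    Raises
    ------
    CodeValidationError
        If the string does not satisfy the system's rule.  The error names
        the system and the violated rule.
    """
    if not raw or not raw.strip():
        raise CodeValidationError(system, raw, "code must be nonempty")
    stripped = raw.strip()
    system = CodeSystem(system)
    if system is CodeSystem.NDC:
        return normalize_ndc(raw)
    canon = stripped.upper()
    if system is CodeSystem.YJ:
        if not _YJ_RE.match(canon):
            raise CodeValidationError(
                system, raw, "YJ codes are exactly 12 alphanumeric characters"
            )
    elif system is CodeSystem.KEGG_D:
        if not _KEGG_D_RE.match(canon):
            raise CodeValidationError(
                system, raw, "KEGG D numbers are 'D' followed by 5 digits"
            )
    elif system is CodeSystem.DRUGBANK:
        if not _DRUGBANK_RE.match(canon):
            raise CodeValidationError(
                system, raw, "DrugBank accessions are 'DB' followed by 5 digits"
            )
    elif system is CodeSystem.RXCUI:
        if not _RXCUI_RE.match(canon):
            raise CodeValidationError(
                system, raw, "RxCUIs are nonempty digit strings"
            )
    return ValidatedCode(system, canon, stripped)


# NDC dialects: hyphenated labeler-product or labeler-product-package, or
# bare digit runs of 9 (labeler5+product4) or 11 (5-4-2) digits.  Bare
# 10-digit runs are rejected: without hyphens the 4-4-2 / 5-3-2 / 5-4-1
# layouts cannot be told apart.
_NDC_HYPHEN_RE = re.compile(r"^(\d{1,5})-(\d{1,4})(?:-(\d{1,2}))?$")


def normalize_ndc(raw: str) -> ValidatedCode:
    """Normalize an NDC to canonical product-level form.

    The canonical value is the 9-digit string ``labeler(5) + product(4)``,
    zero padded; any package segment is stripped.  The hyphenated input is
    retained in ``raw``.  Idempotent: feeding a canonical value back in
    yields the same code.

    Raises
    ------
    CodeValidationError
        For strings matching no recognized NDC dialect.
    """
    if not raw or not raw.strip():
        raise CodeValidationError(CodeSystem.NDC, raw, "code must be nonempty")
    s = raw.strip()
    m = _NDC_HYPHEN_RE.match(s)
    if m:
        labeler, product = m.group(1), m.group(2)
    elif s.isdigit() and len(s) == 9:
        labeler, product = s[:5], s[5:]
    elif s.isdigit() and len(s) == 11:
        labeler, product = s[:5], s[5:9]
    else:
        raise CodeValidationError(
            CodeSystem.NDC,
            raw,
            "unrecognized NDC dialect (expect labeler-product[-package] or "
            "a bare 9- or 11-digit run)",
        )
    canon = labeler.zfill(5) + product.zfill(4)
    return ValidatedCode(CodeSystem.NDC, canon, s)


def yj_prefix(code: ValidatedCode, level: PrefixLevel) -> str:
    """Return the YJ7 (ingredient) or YJ9 (clinical-drug) prefix of a YJ code.

    The first 7 characters of a YJ code carry ingredient-level information
    and the first 9 add dose form and strength; these are the join keys that
    approximate RxNorm's IN/MIN and SCD classes respectively.

    Raises
    ------
    WrongSystemError
        If ``code`` is not a YJ code.
    """
    if code.system is not CodeSystem.YJ:
        raise WrongSystemError(
            f"yj_prefix requires a YJ code, got {code.system.value}"
        )
    n = 7 if PrefixLevel(level) is PrefixLevel.INGREDIENT7 else 9
    return code.value[:n]
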