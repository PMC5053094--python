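"""Pre-hashing normalization of identifier fields.

Hashed comparison is all-or-nothing: a single divergent character yields a
completely different fingerprint (avalanche effect), so common entry
variations — case, accents, minor spelling differences, date formats — must
be collapsed *before* fingerprinting. Each identifier field carries an
ordered plan of transforms; applying a plan is idempotent, so normalized
data can safely be re-normalized.

Available transforms:

``lowercase``
    Unicode case folding.
``strip-accents``
    Canonical (NFD) decomposition followed by removal of combining marks;
    deterministic and locale-independent.
``strip-nonalpha``
    Drop every character outside ``a-zA-Z``.
``phonetic-code``
    American Soundex (letter + 3 digits), collapsing common misspellings
    such as "Dupont"/"Dupond" onto one code.
``date-canonicalize``
    Parse under a declared dialect (default day/month/year) and emit ISO
    ``YYYY-MM-DD``.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from datetime import date

__all__ = [
    "NormalizationPlan",
    "NormalizationError",
    "UnencodableError",
    "DateError",
    "normalize_text",
    "strip_accents",
    "phonetic_code",
    "canonicalize_date",
    "TRANSFORMS",
]


class NormalizationError(ValueError):
    """Unknown transform name or invalid plan configuration."""


class UnencodableError(ValueError):
    """Input contains no alphabetic character to phonetically encode."""


class DateError(ValueError):
    """Unparseable or impossible calendar date."""

    def __init__(self, raw: str, reason: str = "unparseable") -> None:
        super().__init__(f"invalid date {raw!r}: {reason}")
        self.raw = raw


# --- elementary transforms ---------------------------------------------------

def strip_accents(text: str) -> str:
    """Remove diacritics via canonical decomposition ("Éléonore" → "Eleonore")."""
    decomposed = unicodedata.normalize("NFD", text)
    return "".join(c for c in decomposed if not unicodedata.combining(c))


_SOUNDEX_TABLE = str.maketrans(
    {
        **dict.fromkeys("bfpv", "1"),
        **dict.fromkeys("cgjkqsxz", "2"),
        **dict.fromkeys("dt", "3"),
        "l": "4",
        **dict.fromkeys("mn", "5"),
        "r": "6",
    }
)
_SOUNDEX_CODE_RE = re.compile(r"^[a-zA-Z][0-9]{3}$")


def phonetic_code(name: str) -> str:
    """American Soundex code of ``name``: first letter + 3 digits.

    Names differing in a trailing voiced/unvoiced consonant swap (the classic
    "Dupont"/"Dupond" typo) collapse onto the same code, which is the point:
    the code, not the raw name, is what gets hashed.

    An input that already *is* a Soundex code (letter + 3 digits) is returned
    unchanged (upper-cased), which makes the transform idempotent inside a
    normalization plan.

    Raises
    ------
    UnencodableError
        If ``name`` contains no alphabetic character.
    """
    if _SOUNDEX_CODE_RE.match(name):
        return name.upper()
    letters = [c for c in strip_accents(name).lower() if c.isalpha() and c.isascii()]
    if not letters:
        raise UnencodableError(f"no alphabetic character in {name!r}")
    first = letters[0]
    digits: list[str] = []
    prev = first.translate(_SOUNDEX_TABLE)
    prev = prev if prev.isdigit() else ""
    for c in letters[1:]:
        if c in "hw":  # h/w are transparent: they do not break a run
            continue
        code = c.translate(_SOUNDEX_TABLE)
        if not code.isdigit():  # vowels reset the run
            prev = ""
            continue
        if code != prev:
            digits.append(code)
            prev = code
        if len(digits) == 3:
            break
    return (first.upper() + "".join(digits) + "000")[:4]


_DIALECTS = {
    "dmy": ("%d", "%m", "%Y"),
    "mdy": ("%m", "%d", "%Y"),
    "ymd": ("%Y", "%m", "%d"),
}
_ISO_RE = re.compile(r"^(\d{4})-(\d{2})-(\d{2})$")


def canonicalize_date(raw: str, dialect: str = "dmy", sep: str = "/") -> str:
    """Canonicalize a date string to ISO ``YYYY-MM-DD``.

    ``dialect`` gives the component order of the input (default ``dmy``,
    i.e. "29/01/1940" → "1940-01-29"). Already-ISO input passes through
    unchanged after validation, so the transform is idempotent. Impossible
    calendar dates ("31/02/1990") raise :class:`DateError`.
    """
    raw = raw.strip()
    iso = _ISO_RE.match(raw)
    if iso:
        y, m, d = (int(g) for g in iso.groups())
    else:
        if dialect not in _DIALECTS:
            raise NormalizationError(f"unknown date dialect {dialect!r}")
        parts = raw.split(sep)
        if len(parts) != 3:
            raise DateError(raw)
        order = _DIALECTS[dialect]
        try:
            comp = {fmt: int(p) for fmt, p in zip(order, parts)}
        except ValueError:
            raise DateError(raw) from None
        y, m, d = comp["%Y"], comp["%m"], comp["%d"]
    try:
        date(y, m, d)
    except ValueError:
        raise DateError(raw, "impossible calendar date") from None
    return f"{y:04d}-{m:02d}-{d:02d}"


TRANSFORMS = {
    "lowercase": str.lower,
    "strip-accents": strip_accents,
    "strip-nonalpha": lambda s: "".join(c for c in s if c.isalpha() and c.isascii()),
    "phonetic-code": phonetic_code,
    "date-canonicalize": canonicalize_date,
}


# --- plans -------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationPlan:
    """Ordered list of transforms for one identifier field.

    ``date_dialect`` applies to the ``date-canonicalize`` step only.
    """

    transforms: tuple[str, ...] = ()
    date_dialect: str = "dmy"

    def __post_init__(self) -> None:
        unknown = [t for t in self.transforms if t not in TRANSFORMS]
        if unknown:
            raise NormalizationError(f"unknown transform(s): {unknown}")

    @classmethod
    def from_list(cls, names: list[str] | tuple[str, ...], date_dialect: str = "dmy") -> "NormalizationPlan":
        return cls(tuple(names), date_dialect)


def normalize_text(raw: str, plan: NormalizationPlan | list[str] | tuple[str, ...]) -> str:
    """Apply a normalization plan to ``raw``.

    Empty input maps to empty output regardless of the plan, and the result
    is a fixed point: applying the same plan again leaves it unchanged.
    """
    if not isinstance(plan, NormalizationPlan):
        plan = NormalizationPlan.from_list(plan)
    if raw == "":
        return ""
    out = raw
    for name in plan.transforms:
        if name == "date-canonicalize":
            out = canonicalize_date(out, plan.date_dialect)
        else:
            out = TRANSFORMS[name](out)
    return out
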