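"""Scientific-name parsing: authorship stripping and canonical forms.

Scientific names as written in occurrence spreadsheets frequently carry an
author citation ("Thelyphonellus amazonicus (Butler, 1872)") that reference
checklists may or may not include.  Comparison must therefore happen on the
*canonical* name — the Latin name alone.  The grammar here is intentionally
small and fully documented:

1. anything from the first ``(`` onward is authorship;
2. after the name tokens, a trailing run of tokens that start with an
   uppercase letter (author surnames), 4-digit years, and connecting
   punctuation (``&``, ``,``, ``et``, ``and``, ``ex``) is authorship;
3. infraspecific rank markers (``var.``, ``subsp.``, ``ssp.``, ``f.``,
   ``subvar.``) and the hybrid sign ``×`` are kept in the canonical string
   but excluded when counting tokens to classify the name structure.

This is deliberately far short of a full nomenclatural parser (no virus
names, no hybrid formulas); it covers the forms that occur in rank columns
of occurrence tables.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from typing import Literal

Structure = Literal["uninomial", "binomial", "trinomial", "unparseable"]

#: tokens that mark an infraspecific epithet; not counted toward structure
INFRASPECIFIC_MARKERS = frozenset(
    {"var.", "var", "subsp.", "subsp", "ssp.", "ssp", "f.", "subvar.", "subvar", "×", "x."}
)

#: connective tokens inside authorship strings
_AUTHORSHIP_CONNECTIVES = frozenset({"&", "et", "and", "ex", ","})

_YEAR_RE = re.compile(r"^\d{4}[a-z]?[,.]?$")
_WS_RE = re.compile(r"\s+")


@dataclass(frozen=True)
class ParsedName:
    """A raw name string split into canonical name and authorship."""

    raw: str
    canonical: str
    structure: Structure
    authorship: str
    normalized: str

    @property
    def is_parseable(self) -> bool:
        return self.structure != "unparseable"


def normalize(name: str) -> str:
    """Case-fold and collapse whitespace.  Idempotent.

    Unicode is NFC-normalized; diacritics are preserved.
    """
    name = unicodedata.normalize("NFC", name)
    return _WS_RE.sub(" ", name.strip()).casefold()


def _is_authorship_token(tok: str) -> bool:
    if _YEAR_RE.match(tok):
        return True
    if tok.lower() in _AUTHORSHIP_CONNECTIVES:
        return True
    # author surname: starts uppercase (possibly after "(" already stripped),
    # e.g. "Butler," "L." "Pocock"
    return bool(tok) and tok[0].isupper()


def parse_scientific_name(raw: str) -> ParsedName:
    """Split ``raw`` into canonical name + authorship and classify structure.

    Never raises: empty or unusable input yields ``structure="unparseable"``
    with an empty canonical.
    """
    text = unicodedata.normalize("NFC", raw or "").strip()
    if not text:
        return ParsedName(raw=raw or "", canonical="", structure="unparseable",
                          authorship="", normalized="")

    # rule (1): parenthesized authorship group and everything after it
    authorship = ""
    paren = text.find("(")
    if paren != -1:
        authorship = text[paren:].strip()
        text = text[:paren].strip()

    tokens = _WS_RE.split(text) if text else []

    # rule (2): trailing capitalized tokens / years after the leading name.
    # The first token is always part of the name (genus or uninomial); from
    # the second token on, the first authorship-looking token starts the
    # authorship tail.  Infraspecific markers never start authorship.
    cut = len(tokens)
    for i in range(1, len(tokens)):
        tok = tokens[i]
        if tok in INFRASPECIFIC_MARKERS:
            continue
        if _is_authorship_token(tok):
            cut = i
            break
    if cut < len(tokens):
        tail = " ".join(tokens[cut:])
        authorship = (tail + (" " + authorship if authorship else "")).strip()
        tokens = tokens[:cut]

    canonical = " ".join(tokens)
    counted = [t for t in tokens if t not in INFRASPECIFIC_MARKERS]
    n = len(counted)
    structure: Structure
    if n == 0:
        structure = "unparseable"
        canonical = ""
    elif n == 1:
        structure = "uninomial"
    elif n == 2:
        structure = "binomial"
    elif n == 3:
        structure = "trinomial"
    else:
        structure = "unparseable"

    return ParsedName(
        raw=raw,
        canonical=canonical,
        structure=structure,
        authorship=authorship,
        normalized=normalize(canonical),
    )
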