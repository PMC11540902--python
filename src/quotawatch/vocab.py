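"""Controlled vocabulary for quota-note parsing.

Quota notes are short free-text strings ("live", "all, wild-taken",
"skins and meat (Sabah)") whose tokens name the traded commodity (term),
the origin of the specimens (source) and the intended use (purpose).
The vocabulary maps surface forms to canonical codes and records which
terms are countable as whole animals.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["Vocabulary", "load_vocabulary", "default_vocabulary", "normalize_token"]

_WS = re.compile(r"\s+")


def normalize_token(text: str) -> str:
    """Case-fold, NFC-normalize and collapse internal whitespace."""
    text = unicodedata.normalize("NFC", text)
    return _WS.sub(" ", text.strip().casefold())


@dataclass(frozen=True)
class Vocabulary:
    """Token tables driving the note grammar.

    Each of ``terms``, ``sources`` and ``purposes`` maps a normalized
    surface form to its canonical code.  ``countable_terms`` lists term
    codes convertible to whole-animal counts; a scope whose term set
    leaves this list is flagged incomparable.
    """

    terms: dict[str, str]
    sources: dict[str, str]
    purposes: dict[str, str]
    all_tokens: frozenset[str]
    countable_terms: frozenset[str]
    regions: dict[str, str] = field(default_factory=dict)

    def classify(self, token: str) -> tuple[str, str] | None:
        """Return ``(dimension, code)`` for a normalized token, or None."""
        if token in self.all_tokens:
            return ("all", "all")
        for dim, table in (
            ("term", self.terms),
            ("source", self.sources),
            ("purpose", self.purposes),
            ("region", self.regions),
        ):
            if token in table:
                return (dim, table[token])
        return None

    def comparable(self, term_codes) -> bool:
        """True iff every term in the set is countable as individuals."""
        return all(t in self.countable_terms for t in term_codes)


def _invert(table: dict[str, list[str]]) -> dict[str, str]:
    out: dict[str, str] = {}
    for code, forms in table.items():
        for form in forms:
            out[normalize_token(form)] = code
        out.setdefault(normalize_token(code), code)
    return out


def load_vocabulary(path: str | Path) -> Vocabulary:
    """Load a vocabulary YAML file (same schema as the bundled default)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return Vocabulary(
        terms=_invert(raw["terms"]),
        sources=_invert(raw["sources"]),
        purposes=_invert(raw["purposes"]),
        all_tokens=frozenset(normalize_token(t) for t in raw.get("all_tokens", ["all"])),
        countable_terms=frozenset(raw.get("countable_terms", [])),
        regions=_invert(raw.get("regions", {})),
    )


_DEFAULT: Vocabulary | None = None


def default_vocabulary() -> Vocabulary:
    """The vocabulary bundled with the package (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        ref = resources.files("quotawatch.data") / "vocabulary.yaml"
        with resources.as_file(ref) as path:
            _DEFAULT = load_vocabulary(path)
    return _DEFAULT
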