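"""Sentiment lexicon container and a small synthetic default lexicon.

The lexicon follows the dual-scale convention of short-text sentiment
classifiers: every term carries either a positive strength in {2..5}
(one above the neutral floor of 1, up to 4 above neutral) or a negative
strength in {-5..-2}. A tweet's score is the strongest positive strength
found plus the strongest negative strength found, with neutral defaults
(1, -1), so scores live on the integer scale [-4, 4].

``DEFAULT_LEXICON`` is a synthetic stand-in written for this package: it
is *not* the lexicon of any licensed sentiment tool, just a vocabulary
large enough for simulation and testing.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, Mapping, Tuple

__all__ = ["Lexicon", "DEFAULT_LEXICON", "default_lexicon"]


class Lexicon:
    """Term -> signed integer strength map with validation.

    Positive strengths must lie in [2, 5], negative in [-5, -2]; zero and
    +/-1 are reserved for the neutral defaults and are rejected. Terms are
    lower-cased and must be unique after lower-casing.
    """

    def __init__(self, terms: Mapping[str, int]):
        table: Dict[str, int] = {}
        for term, strength in terms.items():
            key = term.lower()
            if key in table:
                raise ValueError(f"duplicate lexicon term after lower-casing: {key!r}")
            s = int(strength)
            if not (2 <= s <= 5 or -5 <= s <= -2):
                raise ValueError(
                    f"lexicon strength for {key!r} must be in [2,5] or [-5,-2], got {s}"
                )
            table[key] = s
        self._table = table

    def __contains__(self, term: str) -> bool:
        return term.lower() in self._table

    def __len__(self) -> int:
        return len(self._table)

    def __getitem__(self, term: str) -> int:
        return self._table[term.lower()]

    def get(self, term: str, default: int | None = None):
        return self._table.get(term.lower(), default)

    def items(self) -> Iterable[Tuple[str, int]]:
        return self._table.items()

    def positive_terms(self) -> Dict[str, int]:
        return {t: s for t, s in self._table.items() if s > 0}

    def negative_terms(self) -> Dict[str, int]:
        return {t: s for t, s in self._table.items() if s < 0}

    def term_of_strength(self, strength: int) -> str:
        """Return one term with exactly the given stored strength."""
        for t, s in sorted(self._table.items()):
            if s == strength:
                return t
        raise KeyError(f"no lexicon term with strength {strength}")

    # --- I/O -------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path: str | Path) -> "Lexicon":
        """Read a two-column (term, strength) tab-separated file."""
        terms: Dict[str, int] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            term, strength = line.split("\t")
            terms[term] = int(strength)
        return cls(terms)

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"{t}\t{s}" for t, s in sorted(self._table.items())]
        Path(path).write_text("\n".join(lines) + "\n")


# Synthetic vocabulary, several terms per strength level on both scales.
DEFAULT_LEXICON = Lexicon(
    {
        # positive, stored strength 2..5 (i.e. +1..+4 above neutral)
        "okay": 2, "fine": 2, "nice": 2, "decent": 2,
        "good": 3, "happy": 3, "glad": 3, "enjoy": 3,
        "love": 4, "wonderful": 4, "great": 4, "excited": 4,
        "amazing": 5, "ecstatic": 5, "fantastic": 5, "overjoyed": 5,
        # negative, stored strength -2..-5 (i.e. -1..-4 below neutral)
        "meh": -2, "tired": -2, "bored": -2, "annoyed": -2,
        "bad": -3, "sad": -3, "upset": -3, "worried": -3,
        "hate": -4, "awful": -4, "miserable": -4, "angry": -4,
        "devastated": -5, "hopeless": -5, "terrible": -5, "despair": -5,
    }
)


def default_lexicon() -> Lexicon:
    """Return the package's synthetic default lexicon."""
    return DEFAULT_LEXICON
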