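"""Tokenization and normalization for embedding corpora and mention text.

The normalization pipeline mirrors common clinical language-modeling
practice: lowercase everything, and replace numbers, URLs, dates and times
with the placeholders ``[NUMBER]``, ``[URL]``, ``[DATE]`` and ``[TIME]``.
Placeholder substitution happens before lowercasing, and placeholders are
emitted verbatim (uppercase).

The tokenizer is a deterministic rule-based tokenizer adequate for clinical
text; pass any callable ``text -> TokenizedText`` to downstream code to plug
in a different one.  Dates, times and URLs are kept as single tokens so the
normalizer can replace them; mixed alphanumerics like ``300'`` split into
the number and the measurement mark, so only pure-numeric tokens become
``[NUMBER]`` and clinically meaningful unit cues survive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

PLACEHOLDERS = ("[NUMBER]", "[URL]", "[DATE]", "[TIME]")

# Detection patterns, versioned: changing these changes corpora reproducibly.
URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
DATE_RE = re.compile(r"(?:\d{1,2}[/-]\d{1,2}[/-]\d{2,4}|\d{4}-\d{1,2}-\d{1,2})")
TIME_RE = re.compile(r"\d{1,2}:\d{2}(?::\d{2})?(?:[ap]m)?", re.IGNORECASE)
NUMBER_RE = re.compile(r"\d+(?:[.,]\d+)*")
_WORD_RE = r"[A-Za-z]+(?:'[A-Za-z]+)*"
_PLACEHOLDER_RE = r"\[(?:NUMBER|URL|DATE|TIME)\]"

_TOKEN_RE = re.compile(
    "|".join(
        [
            _PLACEHOLDER_RE,
            URL_RE.pattern,
            DATE_RE.pattern,
            TIME_RE.pattern,
            NUMBER_RE.pattern,
            _WORD_RE,
            r"\S",  # any other visible character, one token each
        ]
    ),
    re.IGNORECASE,
)


@dataclass
class TokenizedText:
    """Tokens plus per-token (start, end) character spans into the source."""

    tokens: list[str] = field(default_factory=list)
    char_spans: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert len(self.tokens) == len(self.char_spans)

    def __len__(self) -> int:
        return len(self.tokens)


def tokenize(text: str) -> TokenizedText:
    """Rule-based tokenization with exact source offsets.

    >>> tokenize("Pt ambulated 300'.").tokens
    ['Pt', 'ambulated', '300', "'", '.']
    """
    tokens, spans = [], []
    for m in _TOKEN_RE.finditer(text):
        tokens.append(m.group(0))
        spans.append((m.start(), m.end()))
    return TokenizedText(tokens=tokens, char_spans=spans)


def normalize_token(token: str) -> str:
    if token in PLACEHOLDERS:
        return token
    if URL_RE.fullmatch(token):
        return "[URL]"
    if DATE_RE.fullmatch(token):
        return "[DATE]"
    if TIME_RE.fullmatch(token):
        return "[TIME]"
    if NUMBER_RE.fullmatch(token):
        return "[NUMBER]"
    return token.lower()


def normalize(tokens: list[str]) -> list[str]:
    """Placeholder substitution then lowercasing; order preserved; idempotent."""
    return [normalize_token(t) for t in tokens]


def normalized_tokens(text: str) -> list[str]:
    """tokenize + normalize in one step."""
    return normalize(tokenize(text).tokens)


_SENT_BOUNDARY_RE = re.compile(r"(?<=[.!?])\s+|\n+")


def split_sentences(text: str) -> list[str]:
    """Crude sentence splitting on terminal punctuation and newlines."""
    parts = [p.strip() for p in _SENT_BOUNDARY_RE.split(text)]
    return [p for p in parts if p]


def write_embedding_corpus(texts, path) -> int:
    """Write one normalized sentence per line (UTF-8); returns line count.

    ``texts`` is an iterable of raw document strings.
    """
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for text in texts:
            for sent in split_sentences(text):
                toks = normalized_tokens(sent)
                if toks:
                    fh.write(" ".join(toks) + "\n")
                    n += 1
    return n
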