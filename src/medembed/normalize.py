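"""Concept normalization of clinical / biomedical text.

Raw text is lowercased, stripped of punctuation and tokenized; multi-word
medical concept mentions are then collapsed into single concept-identifier
tokens (CUIs, ``C`` followed by digits) by greedy left-to-right
longest-match against a surface-phrase dictionary.  The resulting token
stream is chunked into fixed-length, non-overlapping windows for
co-occurrence counting.

The dictionary linker is a deterministic stand-in for a full clinical NLP
normalizer: at every position the longest dictionary phrase starting there
wins and scanning resumes after it.  Concept IDs already present in the
input are passed through verbatim, so pre-normalized corpora can be
re-ingested.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CUI_PATTERN",
    "ConceptDictionary",
    "TokenStream",
    "Window",
    "tokenize",
    "normalize_text",
    "chunk_windows",
]

#: Concept unique identifiers: ``C`` followed by one or more digits.
CUI_PATTERN = re.compile(r"^C\d+$")

# Words are runs of alphanumerics; intra-token hyphens are kept
# (``x-ray`` is one token) but leading/trailing hyphens are not.
_TOKEN_RE = re.compile(r"[A-Za-z0-9](?:[A-Za-z0-9-]*[A-Za-z0-9])?")


def is_cui(token: str) -> bool:
    """True if *token* is a concept identifier (``C`` + digits)."""
    return CUI_PATTERN.match(token) is not None


@dataclass(frozen=True)
class ConceptDictionary:
    """Surface phrase -> concept ID lookup table.

    Parameters
    ----------
    entries
        Mapping from a tuple of lowercase, punctuation-free word tokens
        (the surface phrase) to a concept ID string.
    """

    entries: Mapping[tuple[str, ...], str]
    _max_len: int = field(init=False, repr=False, default=0)

    def __post_init__(self) -> None:
        for phrase, cui in self.entries.items():
            if len(phrase) == 0:
                raise ValueError("empty surface phrase in dictionary")
            for tok in phrase:
                if tok != tok.lower() or not tok:
                    raise ValueError(f"phrase token {tok!r} is not lowercase")
                if not all(c.isalnum() or c == "-" for c in tok):
                    raise ValueError(f"phrase token {tok!r} contains punctuation")
            if not is_cui(cui):
                raise ValueError(f"{cui!r} does not match the CUI pattern C<digits>")
        object.__setattr__(
            self, "_max_len", max((len(p) for p in self.entries), default=0)
        )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def max_phrase_length(self) -> int:
        return self._max_len

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "ConceptDictionary":
        """Build from (space-separated surface phrase, CUI) string pairs."""
        return cls({tuple(phrase.split()): cui for phrase, cui in pairs})


@dataclass(frozen=True)
class TokenStream:
    """An ordered sequence of tokens, each a concept ID or a lowercase word."""

    tokens: tuple[str, ...]
    doc_id: str = ""

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)


@dataclass(frozen=True)
class Window:
    """A contiguous slice of at most ``length`` tokens from one stream."""

    tokens: tuple[str, ...]
    length: int = 10

    def __post_init__(self) -> None:
        if not 1 <= len(self.tokens) <= self.length:
            raise ValueError(
                f"window holds {len(self.tokens)} tokens, allowed 1..{self.length}"
            )

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)


def tokenize(raw: str) -> list[str]:
    """Split *raw* into word tokens.

    All non-alphanumeric characters except intra-token hyphens act as
    separators; digits are kept.  Tokens matching the CUI pattern are
    preserved verbatim, everything else is lowercased.
    """
    out = []
    for match in _TOKEN_RE.finditer(raw):
        tok = match.group(0)
        out.append(tok if is_cui(tok) else tok.lower())
    return out


def normalize_text(
    raw: str, dictionary: ConceptDictionary, doc_id: str = ""
) -> TokenStream:
    """Normalize *raw* text into a concept-linked token stream.

    Every maximal dictionary phrase occurrence is replaced by its concept
    ID; remaining words are lowercased with punctuation stripped.  Matching
    is greedy left-to-right longest-match: at each position the longest
    phrase starting there wins, and the scan resumes after it.
    """
    if len(dictionary) == 0:
        raise ValueError("concept dictionary is empty")
    words = tokenize(raw)
    entries = dictionary.entries
    max_len = dictionary.max_phrase_length
    out: list[str] = []
    i = 0
    n = len(words)
    while i < n:
        matched = False
        for span in range(min(max_len, n - i), 0, -1):
            cui = entries.get(tuple(words[i : i + span]))
            if cui is not None:
                out.append(cui)
                i += span
                matched = True
                break
        if not matched:
            out.append(words[i])
            i += 1
    return TokenStream(tokens=tuple(out), doc_id=doc_id)


def chunk_windows(stream: TokenStream | Sequence[str], length: int = 10) -> list[Window]:
    """Chunk a token stream into consecutive non-overlapping windows.

    The final window may be shorter; concatenating the windows reproduces
    the stream exactly.  Windows are chunked, not sliding.
    """
    if length < 2:
        raise ValueError(f"window length must be >= 2, got {length}")
    tokens = tuple(stream.tokens if isinstance(stream, TokenStream) else stream)
    return [
        Window(tokens=tokens[i : i + length], length=length)
        for i in range(0, len(tokens), length)
    ]
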