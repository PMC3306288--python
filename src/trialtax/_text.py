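"""Shared string normalization for term matching.

Registry condition strings and thesaurus headings differ in case and
whitespace; all term matching in the package goes through one normal form.
Original strings are kept elsewhere for display.
"""

from __future__ import annotations

import re

_WS = re.compile(r"\s+")

#: trailing punctuation stripped when counting/matching free-text terms
_TRAILING_PUNCT = " .,;:"


def normalize_term(text: str) -> str:
    """Lowercase, collapse internal whitespace, strip trailing punctuation."""
    collapsed = _WS.sub(" ", text.strip())
    return collapsed.rstrip(_TRAILING_PUNCT).lower()
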