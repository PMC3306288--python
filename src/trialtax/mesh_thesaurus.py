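"""MeSH-style thesaurus: terms attached to dot-delimited tree numbers.

A tree number such as ``C19.700.355.528`` encodes a position in one MeSH
tree; its parent is the string with the last dot-segment removed, and its
descendants are exactly the loaded tree numbers extending it by at least one
segment. One term may hold several tree numbers (Acromegaly-style multi-tree
membership), which is what makes per-term tags ambiguous downstream.

Hierarchy exists only over loaded ids: a parent absent from the file is not
synthesized.
"""

from __future__ import annotations

import logging
import re
from bisect import bisect_left
from pathlib import Path
from typing import Iterable

from ._text import normalize_term

logger = logging.getLogger(__name__)

MAX_DEPTH = 12

#: letter + digits, then dot-delimited digit segments
TREE_NUMBER_RE = re.compile(r"^[A-Z][0-9]{1,3}(?:\.[0-9]{1,3})*$")


def is_valid_tree_number(value: str) -> bool:
    return bool(TREE_NUMBER_RE.match(value)) and depth_of(value) <= MAX_DEPTH


def depth_of(tree_number: str) -> int:
    """Number of dot-delimited segments; 1 for a top-of-tree id like ``C04``."""
    return tree_number.count(".") + 1


def parent_of(tree_number: str) -> str | None:
    """The tree number with its final segment removed; None at depth 1."""
    if not TREE_NUMBER_RE.match(tree_number):
        raise ValueError(f"invalid tree number: {tree_number!r}")
    if "." not in tree_number:
        return None
    return tree_number.rsplit(".", 1)[0]


class MeshThesaurus:
    """Bidirectional term <-> tree-number map with prefix hierarchy.

    Terms are matched case-insensitively (normalized); tree numbers are
    case-sensitive verbatim strings. ``id_to_term`` is a function: a tree
    number names exactly one term, while a term may own many tree numbers.
    """

    def __init__(self) -> None:
        self.term_to_ids: dict[str, set[str]] = {}
        self.id_to_term: dict[str, str] = {}
        self._display: dict[str, str] = {}  # normalized -> first-seen original
        self._sorted_ids: list[str] | None = None

    def __len__(self) -> int:
        return len(self.id_to_term)

    def __contains__(self, tree_number: str) -> bool:
        return tree_number in self.id_to_term

    def add(self, term: str, tree_number: str) -> None:
        if not is_valid_tree_number(tree_number):
            raise ValueError(f"invalid tree number: {tree_number!r}")
        key = normalize_term(term)
        if not key:
            raise ValueError("empty term")
        existing = self.id_to_term.get(tree_number)
        if existing is not None:
            if existing != key:
                raise ValueError(
                    f"tree number {tree_number} already mapped to "
                    f"{self._display[existing]!r}, cannot remap to {term!r}"
                )
            return  # duplicate pair, deduplicated
        self.id_to_term[tree_number] = key
        self.term_to_ids.setdefault(key, set()).add(tree_number)
        self._display.setdefault(key, " ".join(term.split()))
        self._sorted_ids = None

    def display_term(self, term: str) -> str:
        return self._display[normalize_term(term)]

    def ids_for_term(self, term: str) -> set[str]:
        return set(self.term_to_ids.get(normalize_term(term), set()))

    def term_for_id(self, tree_number: str) -> str:
        return self.id_to_term[tree_number]

    @property
    def terms(self) -> list[str]:
        """Normalized terms, sorted."""
        return sorted(self.term_to_ids)

    @property
    def categories(self) -> list[str]:
        """Distinct top-level (depth-1) subject-heading ids, sorted."""
        return sorted({tn.split(".", 1)[0] for tn in self.id_to_term})

    def _ids(self) -> list[str]:
        if self._sorted_ids is None:
            self._sorted_ids = sorted(self.id_to_term)
        return self._sorted_ids

    def descendants_of(self, tree_number: str) -> set[str]:
        """All loaded tree numbers strictly below ``tree_number``.

        Prefix semantics: ids starting with ``tree_number + "."``; the id
        itself is excluded. Sorted-order bisection keeps this O(log n + k).
        """
        if tree_number not in self.id_to_term:
            raise KeyError(f"tree number not in thesaurus: {tree_number!r}")
        prefix = tree_number + "."
        ids = self._ids()
        start = bisect_left(ids, prefix)
        out: set[str] = set()
        for i in range(start, len(ids)):
            if not ids[i].startswith(prefix):
                break
            out.add(ids[i])
        return out

    def children_of(self, tree_number: str) -> set[str]:
        want = depth_of(tree_number) + 1
        return {d for d in self.descendants_of(tree_number) if depth_of(d) == want}


def load_thesaurus(
    path: str | Path,
    category_whitelist: Iterable[str] | None = None,
) -> MeshThesaurus:
    """Load a two-column TSV of (term, tree number) pairs.

    Malformed tree numbers reject the line with a logged line number;
    a tree number mapped to two different terms is a hard error.
    ``category_whitelist`` restricts loading to tree numbers whose top
    segment starts with one of the given prefixes (e.g. ``{"C"}`` for
    Diseases, or ``{"C01", "C04"}``).
    """
    prefixes = tuple(category_whitelist) if category_whitelist else None
    thesaurus = MeshThesaurus()
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not is_valid_tree_number(parts[1].strip()):
                logger.warning("line %d rejected: %r", lineno, line)
                continue
            term, tree_number = parts[0].strip(), parts[1].strip()
            if prefixes is not None and not tree_number.split(".", 1)[0].startswith(
                prefixes
            ):
                continue
            thesaurus.add(term, tree_number)
    return thesaurus


def write_thesaurus(thesaurus: MeshThesaurus, path: str | Path) -> None:
    """Write the TSV form, sorted by tree number (deterministic bytes)."""
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        for tree_number in sorted(thesaurus.id_to_term):
            term = thesaurus._display[thesaurus.id_to_term[tree_number]]
            handle.write(f"{term}\t{tree_number}\n")
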