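"""Minimal tolerant BibTeX reader.

Only what the compiler needs: entry keys, a few common fields, and a
plain-text rendering for the reference list. Values may be brace- or
quote-delimited (nested braces allowed); ``@comment`` and ``@preamble``
blocks are ignored. Not a general BibTeX implementation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import ParseError


@dataclass
class BibEntry:
    key: str
    entry_type: str
    fields: dict[str, str] = field(default_factory=dict)

    def format_plain(self) -> str:
        """Unstyled one-line rendering: authors (year). title. venue."""
        parts: list[str] = []
        author = self.fields.get("author")
        if author:
            parts.append(" and ".join(a.strip() for a in author.split(" and ")))
        year = self.fields.get("year")
        if year:
            parts.append(f"({year})")
        title = self.fields.get("title")
        if title:
            parts.append(f"{title}.")
        venue = self.fields.get("journal") or self.fields.get("booktitle")
        if venue:
            parts.append(f"{venue}.")
        doi = self.fields.get("doi")
        if doi:
            parts.append(f"doi:{doi}")
        return " ".join(parts) if parts else self.key


_ENTRY_START = re.compile(r"@(\w+)\s*\{", re.IGNORECASE)
_STRIP_BRACES = re.compile(r"[{}]")


def parse_bibtex(text: str) -> dict[str, BibEntry]:
    """Parse BibTeX text into a key → entry mapping (keys case-sensitive)."""
    entries: dict[str, BibEntry] = {}
    pos = 0
    while True:
        match = _ENTRY_START.search(text, pos)
        if match is None:
            break
        entry_type = match.group(1).lower()
        body, pos = _read_braced(text, match.end() - 1)
        if entry_type in ("comment", "preamble", "string"):
            continue
        key, _, rest = body.partition(",")
        key = key.strip()
        if not key:
            raise ParseError(f"BibTeX entry of type @{entry_type} has no key")
        entry = BibEntry(key=key, entry_type=entry_type)
        for name, value in _parse_fields(rest):
            entry.fields[name.lower()] = value
        entries[key] = entry
    return entries


def _read_braced(text: str, open_pos: int) -> tuple[str, int]:
    """Return the contents of the brace group opening at ``open_pos`` and
    the index just past its closing brace."""
    depth = 0
    for i in range(open_pos, len(text)):
        c = text[i]
        if c == "{":
            depth += 1
        elif c == "}":
            depth -= 1
            if depth == 0:
                return text[open_pos + 1 : i], i + 1
    raise ParseError("unbalanced braces in BibTeX entry")


def _parse_fields(body: str):
    i, n = 0, len(body)
    while i < n:
        while i < n and body[i] in ", \t\r\n":
            i += 1
        start = i
        while i < n and body[i] not in "=,":
            i += 1
        name = body[start:i].strip()
        if i >= n or body[i] != "=":
            break
        i += 1
        while i < n and body[i] in " \t\r\n":
            i += 1
        if i < n and body[i] == "{":
            value, i = _read_braced(body, i)
        elif i < n and body[i] == '"':
            end = body.find('"', i + 1)
            if end == -1:
                raise ParseError(f"unterminated quoted value for field {name!r}")
            value, i = body[i + 1 : end], end + 1
        else:
            start = i
            while i < n and body[i] != ",":
                i += 1
            value = body[start:i].strip()
        if name:
            yield name, _STRIP_BRACES.sub("", " ".join(value.split()))
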