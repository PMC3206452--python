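"""Qualified names, namespace prefixes and the prefix-alias table.

Prefixes are treated as opaque strings: two references are the same term when
their (aliased) prefixes point at the same dictionary and their local names
agree.  No URI resolution is performed for equality; the URIs below exist only
so that serialized documents are well-formed XML.
"""

from __future__ import annotations

import logging

log = logging.getLogger("cclog")

CML_URI = "http://www.xml-cml.org/schema"
CMLX_URI = "http://www.xml-cml.org/schema/cmlx"

#: Prefix -> namespace URI used when *writing* documents.  The compchem
#: dictionary URI printed in source material is malformed; a syntactically
#: valid stand-in is used since equality never depends on it.
PREFIX_URIS = {
    None: CML_URI,
    "cmlx": CMLX_URI,
    "cml": "http://www.xml-cml.org/dictionary/cml/",
    "cc": "http://www.xml-cml.org/dictionary/compchem/",
    "compchem": "http://www.xml-cml.org/dictionary/compchem/",
    "g": "http://www.xml-cml.org/dictionary/gaussian/",
    "x": "http://www.xml-cml.org/dictionary/unassigned/",
    "nonsi": "http://www.xml-cml.org/unit/nonSi/",
    "si": "http://www.xml-cml.org/unit/si/",
    "u": "http://www.xml-cml.org/unit/units/",
    "xsd": "http://www.w3.org/2001/XMLSchema",
    "convention": "http://www.xml-cml.org/convention/",
    "unitType": "http://www.xml-cml.org/unit/unitType/",
    "conventions": "http://www.xml-cml.org/convention/",
    "h": "http://www.w3.org/1999/xhtml",
    "dc": "http://purl.org/dc/elements/1.1/",
}

#: Prefix alias table: maps a reference prefix to the dictionary it names.
#: ``cc`` and ``compchem`` both alias the compchem dictionary; ``x`` marks
#: unassigned temporary terms which are never dictionary errors.
PREFIX_ALIASES = {
    "cc": "compchem",
    "compchem": "compchem",
    "g": "gaussian",
    "x": None,
}

#: Canonical prefix to emit for each dictionary on output.
CANONICAL_PREFIX = {"compchem": "cc", "gaussian": "g"}

#: Code-specific prefixes that the paper's transform files use interchangeably
#: with the canonical one.  A dictRef predicate written with one of these
#: matches a node labelled with the other when the local names agree; the
#: match is logged because it papers over a source inconsistency.
_INTERCHANGEABLE = {"compchem", "gaussian"}


def split_ref(ref: str) -> tuple[str | None, str]:
    """Split ``prefix:local`` into its parts.  No prefix -> (None, ref)."""
    if ":" in ref:
        prefix, local = ref.split(":", 1)
        return prefix, local
    return None, ref


def is_valid_ref(ref: str) -> bool:
    prefix, local = split_ref(ref)
    return bool(prefix) and bool(local) and " " not in ref


def alias_of(prefix: str | None) -> str | None:
    """Dictionary name a prefix points at (None when unassigned/unknown)."""
    if prefix is None:
        return None
    return PREFIX_ALIASES.get(prefix, prefix)


def refs_equal(a: str, b: str) -> bool:
    """Term equality under the alias table."""
    pa, la = split_ref(a)
    pb, lb = split_ref(b)
    if la != lb:
        return False
    if pa == pb:
        return True
    return alias_of(pa) is not None and alias_of(pa) == alias_of(pb)


def refs_match_lenient(pattern_ref: str, node_ref: str) -> bool:
    """dictRef predicate match with code-specific/canonical prefix leniency.

    Transform files mix the code-specific ``g:`` prefix with the canonical
    ``cc:`` for the same concept.  When local names agree and both prefixes
    alias a known dictionary, the match succeeds and a warning is logged.
    """
    if refs_equal(pattern_ref, node_ref):
        return True
    pa, la = split_ref(pattern_ref)
    pb, lb = split_ref(node_ref)
    if la != lb:
        return False
    da, db = alias_of(pa), alias_of(pb)
    if da in _INTERCHANGEABLE and db in _INTERCHANGEABLE:
        log.info(
            "dictRef prefix mismatch tolerated: pattern %r matched node %r",
            pattern_ref, node_ref,
        )
        return True
    return False


def canonicalize(ref: str) -> str:
    """Rewrite a reference onto the canonical prefix for its dictionary."""
    prefix, local = split_ref(ref)
    dic = alias_of(prefix)
    if dic in CANONICAL_PREFIX:
        return f"{CANONICAL_PREFIX[dic]}:{local}"
    return ref
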