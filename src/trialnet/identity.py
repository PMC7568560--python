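"""Author-name canonicalization and gender assignment.

MEDLINE-style names (``Surname_Given``) are ambiguous in two directions: a
short form like ``Smith_J`` can denote several people, and several forms
(misspellings, alternate orderings, initials vs full given name) can denote
one person.  Canonicalization applies an explicit alias table first, then a
single conservative automatic rule: a short form (surname + initials) is
merged into a full form iff exactly one full-name form in the corpus shares
the surname and is consistent with the initials.

Gender is assigned from lookup tables only — a given-name frequency table
(counts by gender, e.g. derived from census data), a dictionary table of
categorical labels, and an override table — with no network access and no
probabilistic classifier.  Authors who only ever appear with initials cannot
be gendered and fall into their own category.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping

from .records_io import parse_author_name

__all__ = [
    "GENDER_CATEGORIES",
    "AliasCycleError",
    "canonicalize_authors",
    "assign_gender",
    "gender_census",
]

#: The four mutually exclusive gender categories used throughout the pipeline.
GENDER_CATEGORIES = ("woman", "man", "unknown_initials", "ambiguous")

#: Strict lower bound on the per-name gender frequency ratio: a name counts as
#: gendered only when more than 90% of its occurrences are of one gender.
FREQ_RATIO_THRESHOLD = 0.9


class AliasCycleError(ValueError):
    """Raised when the alias table contains a cycle (a -> b -> ... -> a)."""


def _resolve_alias(name: str, alias_table: Mapping[str, str]) -> str:
    seen = {name}
    cur = name
    while cur in alias_table:
        cur = alias_table[cur]
        if cur in seen:
            raise AliasCycleError(f"alias table cycle involving {name!r}")
        seen.add(cur)
    return cur


def canonicalize_authors(
    raw_names: Iterable[str],
    alias_table: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Map every raw author name form to a canonical key.

    The explicit ``alias_table`` (raw form -> preferred form) is applied first
    and closed transitively.  Then the automatic merge rule runs on the alias
    targets: an initials-only form ``Surname_AB`` merges into a full-name form
    ``Surname_Given`` iff exactly one full form with that surname has a given
    name starting with the short form's first initial.  With two or more
    candidates (``Smith_J`` vs ``Smith_Julian``/``Smith_Jane``) the short form
    stays its own key.

    The result is deterministic for a fixed input and idempotent: mapping the
    canonical keys again changes nothing.
    """
    alias_table = alias_table or {}
    raw_list = sorted(set(raw_names))
    resolved = {raw: _resolve_alias(raw, alias_table) for raw in raw_list}

    # Split resolved forms into full-name and initials-only, grouped by surname.
    parsed = {form: parse_author_name(form) for form in set(resolved.values())}
    full_by_surname: dict[str, list[str]] = defaultdict(list)
    for form, p in parsed.items():
        if not p.initials_only:
            full_by_surname[p.surname].append(form)

    merged: dict[str, str] = {}
    for form, p in parsed.items():
        if p.initials_only:
            candidates = [
                f
                for f in full_by_surname.get(p.surname, [])
                if parsed[f].given[:1].upper() == p.given[:1]
            ]
            merged[form] = candidates[0] if len(candidates) == 1 else form
        else:
            merged[form] = form
    return {raw: merged[resolved[raw]] for raw in raw_list}


def _freq_ratio_label(given: str, freq_table: Mapping[str, tuple[float, float]]) -> str | None:
    counts = freq_table.get(given)
    if counts is None:
        return None
    woman, man = counts
    total = woman + man
    if total <= 0:
        return None
    if woman / total > FREQ_RATIO_THRESHOLD:
        return "woman"
    if man / total > FREQ_RATIO_THRESHOLD:
        return "man"
    return None


def assign_gender(
    given_name: str,
    freq_table: Mapping[str, tuple[float, float]] | None = None,
    dictionary_table: Mapping[str, str] | None = None,
    override_table: Mapping[str, str] | None = None,
) -> str:
    """Assign one of the four gender categories to a given name.

    Precedence: initials-only names are always ``unknown_initials``; otherwise
    the override table wins, then the frequency table when one gender accounts
    for strictly more than 90% of the name's occurrences, then the dictionary
    table, and finally ``ambiguous``.  Total function — never raises.
    """
    if _initials_only(given_name):
        return "unknown_initials"
    if override_table and given_name in override_table:
        label = override_table[given_name]
        return label if label in GENDER_CATEGORIES else "ambiguous"
    if freq_table:
        label = _freq_ratio_label(given_name, freq_table)
        if label is not None:
            return label
    if dictionary_table and given_name in dictionary_table:
        label = dictionary_table[given_name]
        return label if label in GENDER_CATEGORIES else "ambiguous"
    return "ambiguous"


def _initials_only(given: str) -> bool:
    return 1 <= len(given) <= 3 and given.isalpha() and given.isupper()


def gender_census(
    canonical_map: Mapping[str, str],
    freq_table: Mapping[str, tuple[float, float]] | None = None,
    dictionary_table: Mapping[str, str] | None = None,
    override_table: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Assign a gender category to every canonical author key.

    A canonical key's gender comes from its own given block unless that block
    is initials-only and some merged raw form carries a full given name, in
    which case the full form is used.  Returns ``canonical_key -> category``;
    the category counts partition the distinct authors.
    """
    forms_by_key: dict[str, list[str]] = defaultdict(list)
    for raw, key in canonical_map.items():
        forms_by_key[key].append(raw)
    out: dict[str, str] = {}
    for key, forms in forms_by_key.items():
        given = parse_author_name(key).given
        if _initials_only(given):
            fulls = sorted(
                p.given for p in (parse_author_name(f) for f in forms) if not p.initials_only
            )
            if fulls:
                given = fulls[0]
        out[key] = assign_gender(given, freq_table, dictionary_table, override_table)
    return out
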