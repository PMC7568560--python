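"""Per-author career trajectories: primary subspecialty, longevity, change flag.

An author is *eligible* for a subspecialty in a given year if they have ever
been a first or last author on a manuscript mapping to it, or if their
cumulative impact there is no more than one standard deviation below the mean
cumulative impact of all authors active in that subspecialty.  Among eligible
subspecialties, the primary one is where the majority of the author's impact
lies; exact ties split the assignment equally, and authors eligible nowhere
carry the label ``"None"``.  The assignment is recomputed in every year the
author publishes, and an incumbent primary subspecialty is only displaced by
a newly eligible subspecialty holding strictly more impact.

Longevity is the interval in years between an author's first and final
publication; because trial results published shortly before the end of the
observation window may understate an ongoing career, final years falling in a
configurable truncation band (2016-2017 by default) are extended to the end
of the window (2018) when the career started earlier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .impact import ImpactLedger
from .records_io import PublicationRecord

__all__ = [
    "CareerState",
    "compute_careers",
    "primary_label_at",
    "longevity",
    "subspecialty_change_flag",
]

#: Assignment for a given year: a single label, "None", or a tuple of tied labels.
Assignment = str | tuple[str, ...]

NONE_LABEL = "None"
_TIE_RTOL = 1e-12


@dataclass
class CareerState:
    canonical_key: str
    #: year -> assignment, recorded only for years the author published in.
    primary_by_year: dict[int, Assignment]
    first_year: int
    last_year_raw: int
    last_year_adjusted: int
    changed_subspecialty: bool
    #: subspecialty -> first year with a first/last authorship there.
    ever_first_last_by_subspecialty: dict[str, int] = field(default_factory=dict)

    @property
    def longevity(self) -> int:
        return self.last_year_adjusted - self.first_year

    @property
    def final_primary(self) -> Assignment:
        return self.primary_by_year[max(self.primary_by_year)]


def longevity(
    author_years: Iterable[int],
    truncation_band: tuple[int, int] = (2016, 2017),
    horizon: int = 2018,
) -> int:
    """Career span in years, with right-truncation adjustment.

    The span is ``last - first`` publication year; a final year inside the
    truncation band is adjusted to ``horizon`` provided the career started
    before the band (a single recent publication is left unadjusted).
    """
    years = sorted(set(author_years))
    if not years:
        raise ValueError("author has no publication years")
    first, last = years[0], years[-1]
    if first < truncation_band[0] and truncation_band[0] <= last <= truncation_band[1]:
        last = horizon
    return last - first


def subspecialty_change_flag(primary_by_year: Mapping[int, Assignment]) -> bool:
    """True iff the single-label primary assignment took >= 2 distinct values.

    Years with an equal-split (tied) assignment and years labelled ``"None"``
    are ignored: moving into or out of either is not a subspecialty change.
    """
    labels = [
        a for _, a in sorted(primary_by_year.items()) if isinstance(a, str) and a != NONE_LABEL
    ]
    return len(set(labels)) >= 2


def _tied_argmax(impacts: Mapping[str, float]) -> tuple[str, ...]:
    best = max(impacts.values())
    tol = _TIE_RTOL * max(1.0, abs(best))
    return tuple(sorted(s for s, v in impacts.items() if best - v <= tol))


def compute_careers(
    records: Sequence[PublicationRecord],
    key_map: Mapping[str, str],
    ledger: ImpactLedger,
    truncation_band: tuple[int, int] = (2016, 2017),
    horizon: int = 2018,
) -> dict[str, CareerState]:
    """Run the yearly subspecialty-assignment sweep for every author.

    ``ledger`` must have been built from ``records`` with the same
    ``key_map``.  Returns one :class:`CareerState` per canonical author key.
    """
    # First/last authorship events: (author, subspecialty) -> first year.
    ever_fl: dict[tuple[str, str], int] = {}
    for rec in records:
        n = len(rec.authors)
        for slot in rec.authors:
            if slot.position == 1 or slot.position == n or slot.equal_contrib:
                key = key_map[slot.raw_name]
                for s, w in rec.subspecialty_weights.items():
                    if w > 0:
                        ev = (key, s)
                        if ev not in ever_fl or rec.year < ever_fl[ev]:
                            ever_fl[ev] = rec.year

    # Yearly non-cumulative contributions, author -> year -> subspec -> amount.
    by_year: dict[int, dict[str, dict[str, float]]] = {}
    for (a, y, s), v in ledger.entries.items():
        by_year.setdefault(y, {}).setdefault(a, {})[s] = by_year.get(y, {}).get(a, {}).get(s, 0.0) + v

    cum: dict[str, dict[str, float]] = {}
    current: dict[str, Assignment] = {}
    primary_by_year: dict[str, dict[int, Assignment]] = {}
    # subspecialty -> cumulative impact per author, maintained incrementally.
    per_subspec: dict[str, dict[str, float]] = {}

    for year in sorted(by_year):
        active = by_year[year]
        for a, contribs in active.items():
            acc = cum.setdefault(a, {})
            for s, v in contribs.items():
                acc[s] = acc.get(s, 0.0) + v
                if v > 0:
                    per_subspec.setdefault(s, {})[a] = acc[s]
        # Eligibility floor per subspecialty: mean - 1 SD (population) of the
        # cumulative impact of all authors with positive impact there.
        floors: dict[str, float] = {}
        for s, vals in per_subspec.items():
            arr = list(vals.values())
            mean = sum(arr) / len(arr)
            sd = math.sqrt(sum((x - mean) ** 2 for x in arr) / len(arr))
            floors[s] = mean - sd
        for a in active:
            impacts = cum[a]
            eligible = {
                s: v
                for s, v in impacts.items()
                if (a, s) in ever_fl and ever_fl[(a, s)] <= year or (v > 0 and v >= floors.get(s, math.inf))
            }
            incumbent = current.get(a)
            if not eligible:
                assignment: Assignment = incumbent if incumbent is not None else NONE_LABEL
            else:
                tied = _tied_argmax(eligible)
                candidate: Assignment = tied[0] if len(tied) == 1 else tied
                if incumbent is None or incumbent == NONE_LABEL:
                    assignment = candidate
                else:
                    inc_labels = (incumbent,) if isinstance(incumbent, str) else incumbent
                    inc_impact = max(impacts.get(l, 0.0) for l in inc_labels)
                    best = max(eligible.values())
                    if any(l in tied for l in inc_labels):
                        assignment = incumbent if set(inc_labels) <= set(tied) else candidate
                    elif best > inc_impact:
                        assignment = candidate
                    else:
                        assignment = incumbent
            current[a] = assignment
            primary_by_year.setdefault(a, {})[year] = assignment

    pub_years = ledger.publication_years()
    out: dict[str, CareerState] = {}
    for a, years in pub_years.items():
        first, last_raw = years[0], years[-1]
        last_adj = last_raw
        if first < truncation_band[0] and truncation_band[0] <= last_raw <= truncation_band[1]:
            last_adj = horizon
        pby = primary_by_year.get(a, {})
        out[a] = CareerState(
            canonical_key=a,
            primary_by_year=pby,
            first_year=first,
            last_year_raw=last_raw,
            last_year_adjusted=last_adj,
            changed_subspecialty=subspecialty_change_flag(pby),
            ever_first_last_by_subspecialty={
                s: y for (k, s), y in ever_fl.items() if k == a
            },
        )
    return out


def primary_label_at(career: CareerState, year: int) -> Assignment:
    """The author's primary-subspecialty assignment in force at ``year``.

    Assignments persist between publication years; before the first
    publication the label is ``"None"``.
    """
    best: Assignment = NONE_LABEL
    for y in sorted(career.primary_by_year):
        if y > year:
            break
        best = career.primary_by_year[y]
    return best


def assign_primary_subspecialty(
    author: str,
    records: Sequence[PublicationRecord],
    key_map: Mapping[str, str],
    ledger: ImpactLedger,
    year: int,
) -> Assignment:
    """Primary subspecialty of one author at one year (convenience wrapper).

    Runs the full yearly sweep through ``year`` and reports the assignment in
    force; prefer :func:`compute_careers` when querying many authors.
    """
    truncated = [r for r in records if r.year <= year]
    sub_ledger = ImpactLedger()
    for (a, y, s), v in ledger.entries.items():
        if y <= year:
            sub_ledger.add(a, y, s, v)
    careers = compute_careers(truncated, key_map, sub_ledger)
    if author not in careers:
        return NONE_LABEL
    return primary_label_at(careers[author], year)
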