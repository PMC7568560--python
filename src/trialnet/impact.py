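"""Author impact scoring.

Each author earns, per manuscript, the product of four coefficients:

* **role** — 3 for first or last authors (and authors flagged as equal
  contributors), 1 for middle authors;
* **trial design** — 2 if the manuscript reports any randomized trial, 1
  otherwise (mixed designs take the randomized value);
* **citation score** — the manuscript's citation count normalized to the
  corpus-wide maximum, with a blended score for recent manuscripts that are
  still accruing citations (a journal-tier median citation count is phased in
  linearly across the blend window);
* **update decay** — 0.5 per update generation, so a primary publication
  keeps weight 1, its first update 0.5, its second 0.25, and so forth; a
  manuscript pooling updates of several trials takes the generation giving
  the largest coefficient.

The per-manuscript score is split across disease subspecialties by the
record's subspecialty weights, and an author's total impact is the cumulative
sum over all of their manuscripts.  All coefficient values live in
:class:`ImpactConfig` so that the sensitivity analysis can perturb them.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .records_io import AuthorSlot, PublicationRecord

__all__ = [
    "ImpactConfig",
    "ImpactLedger",
    "role_coefficient",
    "trial_coefficient",
    "update_coefficient",
    "citation_score",
    "manuscript_impact",
    "cumulative_impact",
]


@dataclass(frozen=True)
class ImpactConfig:
    """All tunable coefficients of the impact algorithm.

    Defaults are the baseline values; the sensitivity analysis rescales
    ``role_first_last`` by ±67% and ``trial_randomized`` by ±50%.
    """

    role_first_last: float = 3.0
    role_middle: float = 1.0
    trial_randomized: float = 2.0
    trial_other: float = 1.0
    update_half_life: float = 0.5
    #: Last year scored by raw citations alone; the blend phases in after it.
    blend_start: int = 2008
    #: Final year of the blend window, where the tier median carries full weight.
    blend_end: int = 2018

    def scaled(self, role_factor: float = 1.0, trial_factor: float = 1.0) -> "ImpactConfig":
        """A copy with the first/last-role and randomized-trial coefficients rescaled."""
        return replace(
            self,
            role_first_last=self.role_first_last * role_factor,
            trial_randomized=self.trial_randomized * trial_factor,
        )


def role_coefficient(
    position: int,
    n_authors: int,
    equal_contrib: bool = False,
    config: ImpactConfig = ImpactConfig(),
) -> float:
    """Coefficient for the author's byline role.

    First and last positions — and any position marked as an equal
    contributor — take the first/last value (default 3); all other positions
    take the middle value (default 1).
    """
    if not 1 <= position <= n_authors:
        raise ValueError(f"position {position} out of range 1..{n_authors}")
    if position == 1 or position == n_authors or equal_contrib:
        return config.role_first_last
    return config.role_middle


def trial_coefficient(
    randomized_flags: Sequence[bool],
    config: ImpactConfig = ImpactConfig(),
) -> float:
    """Coefficient for trial design: randomized if *any* reported trial is."""
    if len(randomized_flags) == 0:
        raise ValueError("manuscript must report at least one trial")
    return config.trial_randomized if any(randomized_flags) else config.trial_other


def update_coefficient(
    update_index: int,
    pooled_indices: Sequence[int] | None = None,
    config: ImpactConfig = ImpactConfig(),
) -> float:
    """Half-life decay for updates: ``0.5 ** update_index``.

    The primary publication (index 0) keeps coefficient 1.  A pooled update of
    several trials uses the smallest pooled generation — the one yielding the
    maximum coefficient.
    """
    if update_index < 0:
        raise ValueError(f"negative update index {update_index}")
    if pooled_indices is not None:
        if len(pooled_indices) == 0:
            raise ValueError("pooled_indices must be non-empty when given")
        if any(i < 0 for i in pooled_indices):
            raise ValueError("negative pooled update index")
        return max(config.update_half_life**i for i in pooled_indices)
    return config.update_half_life**update_index


def citation_score(
    citations: int,
    max_citations: int,
    year: int,
    journal_tier: int | None = None,
    tier_median_table: Mapping[int, float] | None = None,
    config: ImpactConfig = ImpactConfig(),
) -> float:
    """Citation coefficient, normalized to the corpus-wide maximum count.

    Manuscripts up to ``blend_start`` score ``citations / max_citations``.
    Inside the blend window a journal-tier median citation count is phased in
    with weight ``w(year) = (year - blend_start) / (blend_end - blend_start)``
    ramping linearly from 0 to 1, compensating for citations that recent
    manuscripts have not yet accrued.  The normalization constant is always
    the corpus-wide maximum raw count, so blended scores may exceed 1.
    """
    if max_citations <= 0:
        raise ValueError("max_citations must be positive")
    if year <= config.blend_start:
        return citations / max_citations
    w = min(1.0, (year - config.blend_start) / (config.blend_end - config.blend_start))
    if tier_median_table is None or journal_tier not in tier_median_table:
        raise ValueError(
            f"tier median required for year {year} in blend window, journal tier {journal_tier!r}"
        )
    return (citations + w * tier_median_table[journal_tier]) / max_citations


class ImpactLedger:
    """Per-author, per-year, per-subspecialty cumulative impact contributions.

    ``entries[(author, year, subspecialty)]`` holds the impact earned by that
    author in that year within that subspecialty (not cumulative); the
    accessor methods aggregate cumulatively up to a year.
    """

    def __init__(self) -> None:
        self.entries: dict[tuple[str, int, str], float] = defaultdict(float)

    def add(self, author: str, year: int, subspecialty: str, amount: float) -> None:
        if amount < 0:
            raise ValueError("impact contributions must be non-negative")
        self.entries[(author, year, subspecialty)] += amount

    def authors(self) -> set[str]:
        return {a for a, _, _ in self.entries}

    def total_by_author(self, up_to_year: int | None = None) -> dict[str, float]:
        """Cumulative impact per author over all subspecialties through ``up_to_year``."""
        out: dict[str, float] = defaultdict(float)
        for (a, y, _), v in self.entries.items():
            if up_to_year is None or y <= up_to_year:
                out[a] += v
        return dict(out)

    def by_author_subspecialty(self, up_to_year: int | None = None) -> dict[str, dict[str, float]]:
        """Cumulative impact per author, split by subspecialty."""
        out: dict[str, dict[str, float]] = defaultdict(lambda: defaultdict(float))
        for (a, y, s), v in self.entries.items():
            if up_to_year is None or y <= up_to_year:
                out[a][s] += v
        return {a: dict(d) for a, d in out.items()}

    def publication_years(self) -> dict[str, list[int]]:
        """Sorted list of years with contributions, per author."""
        years: dict[str, set[int]] = defaultdict(set)
        for (a, y, _), v in self.entries.items():
            years[a].add(y)
        return {a: sorted(ys) for a, ys in years.items()}


def manuscript_impact(
    author_slot: AuthorSlot,
    record: PublicationRecord,
    max_citations: int,
    tier_median_table: Mapping[int, float] | None = None,
    config: ImpactConfig = ImpactConfig(),
) -> dict[str, float]:
    """Per-subspecialty impact contribution of one author slot on one record.

    The scalar score is the product role x trial x citation x update; the
    returned map splits it by the record's subspecialty weights, so its values
    sum to the scalar score.
    """
    role = role_coefficient(author_slot.position, len(record.authors), author_slot.equal_contrib, config)
    trial = trial_coefficient([record.randomized], config)
    cite = citation_score(
        record.citations, max_citations, record.year, record.journal_tier, tier_median_table, config
    )
    update = update_coefficient(record.update_index, record.pooled_update_indices, config)
    score = role * trial * cite * update
    return {s: score * w for s, w in record.subspecialty_weights.items()}


def manuscript_score(
    author_slot: AuthorSlot,
    record: PublicationRecord,
    max_citations: int,
    tier_median_table: Mapping[int, float] | None = None,
    config: ImpactConfig = ImpactConfig(),
) -> float:
    """Scalar (unsplit) manuscript-specific impact score for one author slot."""
    return sum(manuscript_impact(author_slot, record, max_citations, tier_median_table, config).values())


def corpus_max_citations(records: Iterable[PublicationRecord]) -> int:
    """The corpus-wide maximum raw citation count (the normalization constant)."""
    return max((r.citations for r in records), default=0)


def cumulative_impact(
    records: Sequence[PublicationRecord],
    key_map: Mapping[str, str],
    up_to_year: int | None = None,
    tier_median_table: Mapping[int, float] | None = None,
    config: ImpactConfig = ImpactConfig(),
    max_citations: int | None = None,
) -> ImpactLedger:
    """Build the impact ledger over all records with ``year <= up_to_year``.

    ``key_map`` maps raw author names to canonical keys (see
    :func:`trialnet.identity.canonicalize_authors`).  The citation
    normalization constant is the maximum over the *full* record set, not just
    the years included, unless ``max_citations`` overrides it.
    """
    if max_citations is None:
        max_citations = corpus_max_citations(records)
    ledger = ImpactLedger()
    for rec in records:
        if up_to_year is not None and rec.year > up_to_year:
            continue
        for slot in rec.authors:
            key = key_map[slot.raw_name]
            for subspec, amount in manuscript_impact(
                slot, rec, max_citations, tier_median_table, config
            ).items():
                ledger.add(key, rec.year, subspec, amount)
    return ledger
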