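"""Red List tabulation: category tallies, threatened-proportion bounds,
coverage fractions, threat/habitat profiles, and 2x2 chi-squared tests.

Data deficiency (DD) makes the proportion of species threatened with
extinction an interval rather than a point. Three estimators bracket it,
with T = EW + CR + EN + VU the threatened-plus-EW numerator:

    midpoint  T / (N - EX - DD)   DD species threatened at the same rate
                                  as data-sufficient ones (best estimate)
    lower     T / (N - EX)        no DD species threatened
    upper     (T + DD) / (N - EX) every DD species threatened

Extinct species are excluded from every denominator; possibly-extinct
tags on CR species can be toggled to count as extinctions (scenario
``pe_as_extinct``) to probe sensitivity of the bounds.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field

from scipy.stats import chi2_contingency

__all__ = [
    "CATEGORIES",
    "THREATENED",
    "AssessmentRecord",
    "CategoryTally",
    "ThreatProfile",
    "tally",
    "proportion_threatened",
    "coverage_fraction",
    "profile",
    "chisq_compare",
]

#: IUCN Red List categories, highest risk first.
CATEGORIES = ("EX", "EW", "CR", "EN", "VU", "NT", "LC", "DD")
#: categories counting as "threatened" (CR/EN/VU); EW joins them in the
#: numerator of the proportion estimators but is not itself "threatened".
THREATENED = frozenset({"CR", "EN", "VU"})

VALID_TAGS = frozenset({"possibly_extinct", "possibly_extinct_in_wild"})
_CODE_RE = re.compile(r"^\d+(\.\d+)*$")


@dataclass(frozen=True)
class AssessmentRecord:
    """One species' Red List assessment.

    ``threats`` and ``habitats`` are dotted hierarchical code strings from
    the IUCN classification schemes (e.g. threat "9.1.2" = domestic and
    urban waste water; habitat "5.1" = permanent rivers). PE/PEW tags are
    only legal on CR records.
    """

    species_id: str
    group: str
    category: str
    tags: frozenset[str] = frozenset()
    threats: frozenset[str] = frozenset()
    habitats: frozenset[str] = frozenset()
    assessment_year: int | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.species_id}: unknown category {self.category!r}")
        object.__setattr__(self, "tags", frozenset(self.tags))
        object.__setattr__(self, "threats", frozenset(self.threats))
        object.__setattr__(self, "habitats", frozenset(self.habitats))
        bad_tags = self.tags - VALID_TAGS
        if bad_tags:
            raise ValueError(f"{self.species_id}: unknown tags {sorted(bad_tags)}")
        if self.tags and self.category != "CR":
            raise ValueError(
                f"{self.species_id}: possibly-extinct tags only allowed on CR records"
            )
        for code in self.threats | self.habitats:
            if not _CODE_RE.match(code):
                raise ValueError(f"{self.species_id}: malformed code {code!r}")


@dataclass(frozen=True)
class CategoryTally:
    counts: dict[str, int]
    N: int = field(default=0)

    def __post_init__(self) -> None:
        counts = {c: int(self.counts.get(c, 0)) for c in CATEGORIES}
        if any(v < 0 for v in counts.values()):
            raise ValueError("negative category count")
        object.__setattr__(self, "counts", counts)
        total = sum(counts.values())
        if self.N == 0:
            object.__setattr__(self, "N", total)
        elif self.N != total:
            raise ValueError(f"counts sum to {total}, not N={self.N}")

    def __getitem__(self, category: str) -> int:
        return self.counts[category]


@dataclass(frozen=True)
class ThreatProfile:
    """Proportion of a species group affected per rolled-up code group.

    Codes are not mutually exclusive, so proportions do not sum to 1. The
    denominator is the number of species with at least one coded entry on
    the axis; species with no coded data are excluded (no known major
    threats, unknown threats, or older assessments without coding).
    """

    group: str
    axis: str
    proportions: dict[str, float]
    denominator: int
    multi_coded_fraction: float


def tally(records: list[AssessmentRecord], scenario: str = "baseline") -> CategoryTally:
    """Count records per category under a possibly-extinct scenario.

    ``baseline`` counts categories as assessed; ``pe_as_extinct`` moves CR
    records tagged possibly extinct / possibly extinct in the wild into EX.
    Total N is invariant under the toggle.
    """
    if scenario not in ("baseline", "pe_as_extinct"):
        raise ValueError(f"unknown scenario {scenario!r}")
    counts: Counter[str] = Counter()
    for r in records:
        cat = r.category
        if scenario == "pe_as_extinct" and cat == "CR" and r.tags:
            cat = "EX"
        counts[cat] += 1
    return CategoryTally(counts=dict(counts))


def proportion_threatened(t: CategoryTally, estimate: str = "midpoint") -> float:
    """One of the three threatened-proportion estimators on a tally.

    Raises ``ZeroDivisionError`` with an explicit message when the chosen
    denominator is empty (e.g. midpoint on an all-DD, all-EX tally).
    """
    numer = t["EW"] + t["CR"] + t["EN"] + t["VU"]
    if estimate == "midpoint":
        denom = t.N - t["EX"] - t["DD"]
        if denom <= 0:
            raise ZeroDivisionError(
                "midpoint undefined: no data-sufficient extant species (N - EX - DD = 0)"
            )
        return numer / denom
    if estimate == "lower":
        denom = t.N - t["EX"]
        if denom <= 0:
            raise ZeroDivisionError("lower estimate undefined: no extant species (N - EX = 0)")
        return numer / denom
    if estimate == "upper":
        denom = t.N - t["EX"]
        if denom <= 0:
            raise ZeroDivisionError("upper estimate undefined: no extant species (N - EX = 0)")
        return (numer + t["DD"]) / denom
    raise ValueError(f"estimate must be midpoint/lower/upper, got {estimate!r}")


def coverage_fraction(assessed: int, described: int) -> int:
    """Assessed-over-described coverage as an integer percentage, half-up."""
    if described <= 0:
        raise ValueError("described species count must be positive")
    if not (0 < assessed <= described):
        raise ValueError("need described >= assessed > 0")
    return int(math.floor(100 * assessed / described + 0.5))


def _matches(code: str, prefix: str) -> bool:
    """True when ``code`` equals or descends from the dotted ``prefix``."""
    return code == prefix or code.startswith(prefix + ".")


def profile(
    records: list[AssessmentRecord],
    axis: str,
    rollup: dict[str, list[str]],
    subset: frozenset[str] | None = None,
    group: str = "all",
) -> ThreatProfile:
    """Multi-label threat or habitat profile under a code roll-up.

    ``rollup`` maps a display group to the code prefixes it absorbs, e.g.
    ``{"pollution": ["9"], "agriculture": ["2.1", "2.2", "2.3"]}``; a
    species counts toward a group when any of its codes equals or descends
    from one of the group's prefixes. ``subset`` optionally filters by
    Red List category first.
    """
    if axis not in ("threats", "habitats"):
        raise ValueError("axis must be 'threats' or 'habitats'")
    pool = records if subset is None else [r for r in records if r.category in subset]
    coded = [(r, getattr(r, axis)) for r in pool]
    coded = [(r, codes) for r, codes in coded if codes]
    if not coded:
        raise ValueError(f"no species with coded {axis} after filtering")

    denominator = len(coded)
    hits = {g: 0 for g in rollup}
    multi = 0
    for _, codes in coded:
        groups_hit = {
            g for g, prefixes in rollup.items()
            if any(_matches(c, p) for c in codes for p in prefixes)
        }
        for g in groups_hit:
            hits[g] += 1
        if len(groups_hit) > 1:
            multi += 1
    return ThreatProfile(
        group=group,
        axis=axis,
        proportions={g: hits[g] / denominator for g in rollup},
        denominator=denominator,
        multi_coded_fraction=multi / denominator,
    )


def chisq_compare(
    k_a: int, n_a: int, k_b: int, n_b: int, correction: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-squared comparison of two proportions (2x2 table).

    Tests whether a trait is recorded at different rates in two species
    groups (e.g. a threat among extinct vs threatened species). No Yates
    continuity correction by default.
    """
    if not (0 <= k_a <= n_a and 0 <= k_b <= n_b) or n_a == 0 or n_b == 0:
        raise ValueError("need 0 <= k <= n and n > 0 in both groups")
    table = [[k_a, n_a - k_a], [k_b, n_b - k_b]]
    col_tot = (k_a + k_b, (n_a - k_a) + (n_b - k_b))
    if 0 in col_tot:
        raise ValueError("degenerate 2x2 table: a column total is zero")
    res = chi2_contingency(table, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)
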