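"""Half-diallel mating designs and plot-layout arithmetic.

A half-diallel crosses ``p`` parents in all unordered pairs, excluding selfs
and reciprocals, yielding ``p(p-1)/2`` F1 hybrids.  The design object is the
common currency passed between the simulator, the combining-ability stage and
the prediction stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

Cross = tuple[str, str]


def cross_id(a: str, b: str) -> Cross:
    """Canonical unordered cross identifier (lexicographically sorted pair)."""
    if a == b:
        raise ValueError(f"selfs are not part of a half-diallel: {a!r}")
    return (a, b) if a < b else (b, a)


def cross_label(cross: Cross) -> str:
    """Human-readable entry label for a cross, e.g. ``'P01/P07'``."""
    return f"{cross[0]}/{cross[1]}"


def parse_cross_label(label: str) -> Cross:
    a, _, b = label.partition("/")
    if not b:
        raise ValueError(f"not a cross label: {label!r}")
    return cross_id(a, b)


@dataclass(frozen=True)
class DiallelDesign:
    """Parent set, the enumerated unordered crosses, and optional check entries.

    Parameters
    ----------
    parents:
        Labels of the inbred parents.  Must be unique.
    checks:
        Labels of commercial check entries grown alongside the hybrids.
        Checks are carried through the trial-analysis stage but excluded
        from the diallel decomposition.
    """

    parents: tuple[str, ...]
    checks: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "parents", tuple(self.parents))
        object.__setattr__(self, "checks", tuple(self.checks))
        if len(set(self.parents)) != len(self.parents):
            raise ValueError("duplicate parent labels")
        if len(self.parents) < 2:
            raise ValueError("a diallel needs at least two parents")
        if set(self.checks) & set(self.parents):
            raise ValueError("check labels collide with parent labels")

    @classmethod
    def from_n_parents(cls, n_parents: int, prefix: str = "P",
                       checks: Sequence[str] = ()) -> "DiallelDesign":
        if n_parents < 2:
            raise ValueError("n_parents must be >= 2")
        width = max(2, len(str(n_parents)))
        parents = tuple(f"{prefix}{i + 1:0{width}d}" for i in range(n_parents))
        return cls(parents=parents, checks=tuple(checks))

    @property
    def n_parents(self) -> int:
        return len(self.parents)

    @property
    def crosses(self) -> tuple[Cross, ...]:
        return tuple(cross_id(a, b) for a, b in combinations(self.parents, 2))

    @property
    def n_crosses(self) -> int:
        p = self.n_parents
        return p * (p - 1) // 2

    @property
    def cross_labels(self) -> tuple[str, ...]:
        return tuple(cross_label(c) for c in self.crosses)

    @property
    def entries(self) -> tuple[str, ...]:
        """All entry labels grown in the trial: hybrids first, then checks."""
        return self.cross_labels + self.checks

    def parent_index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.parents)}

    def is_check(self, entry: str) -> bool:
        return entry in self.checks


def max_complete_subset(available_crosses: Iterable[Cross | str],
                        parents: Optional[Sequence[str]] = None) -> DiallelDesign:
    """Largest parent subset whose induced half-diallel is complete.

    When seed of some cross combinations is unavailable, the fixed-effects
    diallel decomposition is no longer estimable in closed form; the standard
    remedy is to restrict the analysis to the parents for which every
    pairwise combination was realized.  Parents are removed greedily, each
    round dropping the parent with the most missing cells (ties broken by
    taking the lexicographically smallest label), which is deterministic.
    """
    avail: set[Cross] = set()
    for c in available_crosses:
        avail.add(parse_cross_label(c) if isinstance(c, str) else cross_id(*c))
    if parents is None:
        pool = sorted({p for c in avail for p in c})
    else:
        pool = sorted(parents)
    current = list(pool)
    while len(current) >= 2:
        missing = {p: 0 for p in current}
        complete = True
        for a, b in combinations(current, 2):
            if cross_id(a, b) not in avail:
                missing[a] += 1
                missing[b] += 1
                complete = False
        if complete:
            break
        worst = max(missing.values())
        drop = min(p for p in current if missing[p] == worst)
        current.remove(drop)
    if len(current) < 4:
        warnings.warn(
            f"complete subset has only {len(current)} parents; the diallel "
            "decomposition needs at least 4", stacklevel=2)
    return DiallelDesign(parents=tuple(current))


def plants_per_hectare(row_spacing_m: float, plant_spacing_m: float,
                       plants_per_hill: int = 1) -> float:
    """Plant population density implied by a rectangular field layout.

    One hill every ``plant_spacing_m`` metres within rows that are
    ``row_spacing_m`` apart gives ``10_000 / (row * plant)`` hills per
    hectare, times the number of plants left per hill after thinning.
    """
    if row_spacing_m <= 0 or plant_spacing_m <= 0:
        raise ValueError("spacings must be positive")
    if plants_per_hill < 1:
        raise ValueError("plants_per_hill must be >= 1")
    return 10_000.0 / (row_spacing_m * plant_spacing_m) * plants_per_hill
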