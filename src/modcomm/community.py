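"""Community-level stepwise complementarity analysis.

For each culture (model community) we ask two questions of its member
genomes' KO sets:

* per module step, what proportion of members encode the step? (the
  stepwise "mosaic" view — partial contributions from different species);
* per module, what fraction of steps is satisfied by *some* member — the
  collective completeness, i.e. the binary completeness of the union KO
  set.  Collective completeness exceeding the best individual value is the
  signature of stepwise metabolic complementarity.

Genomes of any assembly quality participate here: even partial genomes
contribute evidence for individual steps.  Quality filtering belongs to the
per-genome comparisons, not this module.
"""

from __future__ import annotations

from functools import reduce

import pandas as pd

from .completeness import _as_definitions
from .module_grammar import ModuleDefinition, module_completeness, step_satisfied

__all__ = [
    "community_step_profile",
    "collective_completeness",
    "complementarity_gain",
    "community_step_matrix",
]


def _union(members: list[frozenset[str]]) -> frozenset[str]:
    return reduce(frozenset.union, members, frozenset())


def community_step_profile(members: list[frozenset[str]], library,
                           culture_id: str = "") -> pd.DataFrame:
    """Proportion of community members encoding each module step.

    Returns a DataFrame with columns ``culture_id``, ``step_id`` and
    ``proportion_encoding`` = (members satisfying the step expression) /
    (community size), one row per step of every module in the library.
    """
    if not members:
        raise ValueError("community has no members")
    modules = _as_definitions(library)
    rows = []
    for module in modules:
        for step, step_id in zip(module.steps, module.step_ids):
            n_hit = sum(step_satisfied(step, kos) for kos in members)
            rows.append((culture_id, step_id, n_hit / len(members)))
    return pd.DataFrame(rows, columns=["culture_id", "step_id",
                                       "proportion_encoding"])


def collective_completeness(members: list[frozenset[str]],
                            module: ModuleDefinition) -> float:
    """Fraction of module steps satisfied by at least one member.

    Equal, by definition, to the binary completeness of the union of all
    member KO sets; never below the best individual completeness.
    """
    if not members:
        raise ValueError("community has no members")
    return module_completeness(module, _union(members), mode="binary")


def complementarity_gain(members: list[frozenset[str]], library) -> pd.Series:
    """Per-module gain = collective − best individual binary completeness.

    Zero means no member benefits from the rest of the community for that
    module; values are always in [0, 1].
    """
    if not members:
        raise ValueError("community has no members")
    modules = _as_definitions(library)
    union = _union(members)
    gains = {}
    for module in modules:
        collective = module_completeness(module, union, mode="binary")
        best = max(module_completeness(module, kos, mode="binary")
                   for kos in members)
        gains[module.module_id] = collective - best
    return pd.Series(gains, name="complementarity_gain").sort_index()


def community_step_matrix(cultures: pd.DataFrame,
                          annotations: dict[str, frozenset[str]],
                          library,
                          min_size: int | None = None) -> pd.DataFrame:
    """Culture × step matrix of encoding proportions.

    ``cultures`` is a membership table (culture_id, species_id); members
    without annotations contribute empty KO sets.  ``min_size`` optionally
    restricts to communities of at least that many members (e.g. 4 for the
    more-than-three-species communities).
    """
    profiles = []
    for culture_id, grp in cultures.groupby("culture_id", sort=True):
        members = [annotations.get(s, frozenset())
                   for s in sorted(grp["species_id"])]
        if min_size is not None and len(members) < min_size:
            continue
        profiles.append(community_step_profile(members, library,
                                               culture_id=str(culture_id)))
    if not profiles:
        raise ValueError("no communities matched the size filter")
    long = pd.concat(profiles, ignore_index=True)
    wide = long.pivot(index="culture_id", columns="step_id",
                      values="proportion_encoding")
    return wide.sort_index(axis=0).sort_index(axis=1)
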