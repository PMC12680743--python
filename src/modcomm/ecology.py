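"""Abundance, prevalence, growth categories and species-accumulation curves.

Relative abundance of a genome in a sample is its q2q3 coverage (mean read
coverage over the inner quartiles of the per-position coverage distribution,
robust to outlier regions) divided by the overall sample mean coverage.
Prevalence is the proportion of samples where a species is detected at
relative abundance > 0 — a strict rule with no minimum-breadth screen.

Growth categories summarize the culture record of each species: ``Single``
(observed only in one-species cultures), ``Group`` (only with partners),
``Both``; Single ∪ Both = singleton-capable.

Accumulation (rarefaction) curves estimate how fast new species appear as
cultures are added: culture order is shuffled uniformly, the cumulative
count of distinct species is recorded after each culture, and the mean ±1
standard deviation over permutations is reported per k.  For small culture
sets the shuffle can be replaced by full enumeration of orderings, which
makes the mean exact.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CoverageTable

__all__ = [
    "relative_abundance",
    "complexity_class",
    "complexity_classes",
    "classify_growth",
    "accumulation_curve",
    "COMPLEXITY_LEVELS",
]

COMPLEXITY_LEVELS = ("1", "2", "3", "gt3")


def relative_abundance(coverage: CoverageTable) -> pd.DataFrame:
    """Per-species relative abundance, mean abundance and prevalence.

    Returns a DataFrame indexed by genome id with one ``ra_<sample>`` column
    per sample, plus ``mean_relative_abundance`` (over all samples,
    including zeros) and ``prevalence``.
    """
    ra = coverage.coverage.div(coverage.mean_coverage, axis=1)
    out = ra.add_prefix("ra_")
    out["mean_relative_abundance"] = ra.mean(axis=1)
    out["prevalence"] = (ra > 0).mean(axis=1)
    return out


def complexity_class(n_species: int) -> str:
    """Community complexity: ``"1"``, ``"2"``, ``"3"`` or ``"gt3"``."""
    if n_species < 1:
        raise ValueError("a culture needs at least one species")
    return str(n_species) if n_species <= 3 else "gt3"


def complexity_classes(cultures: pd.DataFrame) -> pd.Series:
    """Complexity class per culture from a membership table."""
    sizes = cultures.drop_duplicates(["culture_id", "species_id"]) \
                    .groupby("culture_id", sort=True)["species_id"].nunique()
    return sizes.map(complexity_class).rename("complexity")


def classify_growth(cultures: pd.DataFrame) -> pd.DataFrame:
    """Growth category per species from its culture record.

    ``Single`` if every culture containing the species has exactly one
    member, ``Group`` if every one has at least two, ``Both`` otherwise.
    ``singleton_capable`` is True for Single and Both.  Idempotent and
    invariant to duplicated membership rows.
    """
    dedup = cultures.drop_duplicates(["culture_id", "species_id"])
    sizes = dedup.groupby("culture_id")["species_id"].nunique()
    merged = dedup.assign(size=dedup["culture_id"].map(sizes))
    rows = {}
    for species, grp in merged.groupby("species_id", sort=True):
        alone = (grp["size"] == 1).any()
        grouped = (grp["size"] > 1).any()
        category = "Both" if alone and grouped else ("Single" if alone else "Group")
        rows[species] = (category, category in ("Single", "Both"))
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=["category", "singleton_capable"])
    out.index.name = "species_id"
    return out


@dataclass(frozen=True)
class AccumulationCurve:
    complexity: str
    k: np.ndarray             # 1..n_cultures
    mean: np.ndarray
    sd: np.ndarray
    n_permutations: int
    method: str               # "shuffle", "bootstrap" or "enumerate"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "complexity": self.complexity, "k": self.k,
            "mean_species": self.mean, "sd_species": self.sd,
            "n_permutations": self.n_permutations, "method": self.method,
        })


def accumulation_curve(cultures: pd.DataFrame,
                       complexity_filter: str | None = None,
                       n_permutations: int = 100,
                       seed: int | None = None,
                       method: str = "shuffle") -> AccumulationCurve:
    """Species-accumulation curve over random orderings of cultures.

    Parameters
    ----------
    cultures
        Membership table (culture_id, species_id).
    complexity_filter
        Restrict to one complexity class (``"1"``/``"2"``/``"3"``/``"gt3"``)
        or ``None`` for all cultures.
    method
        ``"shuffle"`` draws ``n_permutations`` uniform orderings without
        replacement (the default, matching ±1 SD ribbon usage);
        ``"bootstrap"`` resamples cultures with replacement;
        ``"enumerate"`` averages over all n! orderings exactly (small sets
        only) and ignores ``n_permutations``.
    """
    if complexity_filter is not None:
        cls = complexity_classes(cultures)
        keep = cls.index[cls == complexity_filter]
        cultures = cultures[cultures["culture_id"].isin(keep)]
    member_sets = [frozenset(grp["species_id"])
                   for _, grp in cultures.groupby("culture_id", sort=True)]
    n = len(member_sets)
    if n == 0:
        raise ValueError("no cultures in the requested complexity class")

    def curve(order) -> list[int]:
        seen: set[str] = set()
        counts = []
        for idx in order:
            seen |= member_sets[idx]
            counts.append(len(seen))
        return counts

    if method == "enumerate":
        if n > 9:
            raise ValueError("enumeration is limited to 9 cultures")
        all_curves = np.array([curve(p)
                               for p in itertools.permutations(range(n))],
                              dtype=float)
        n_used = math.factorial(n)
    elif method in ("shuffle", "bootstrap"):
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(n_permutations):
            if method == "shuffle":
                order = rng.permutation(n)
            else:
                order = rng.integers(0, n, size=n)
            draws.append(curve(order))
        all_curves = np.array(draws, dtype=float)
        n_used = n_permutations
    else:
        raise ValueError(f"unknown method {method!r}")

    return AccumulationCurve(
        complexity=complexity_filter or "all",
        k=np.arange(1, n + 1),
        mean=all_curves.mean(axis=0),
        sd=all_curves.std(axis=0, ddof=0),
        n_permutations=n_used,
        method=method,
    )
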