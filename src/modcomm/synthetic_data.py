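"""Seeded generator for fixtures with the structure the analysis assumes.

The generator emulates, at a statistical level, a collection of KO-annotated
genomes from dilution model communities and environmental metagenomes:

* a module library of amino-acid and B-vitamin biosynthesis definitions in
  the supported grammar (OR alternatives, ``+`` complexes, optional
  components), with globally disjoint KO ids so that satisfying one step
  never accidentally satisfies another;
* genomes built as KO sets that satisfy an exact, target fraction of each
  module's steps — so binary completeness is exact by construction;
* cultures of complexity 1/2/3/>3 whose larger communities hold
  lower-completeness genomes, and whose >3-species communities (when the
  complementarity flag is set) partition each module's steps across members
  so every pathway is collectively complete while no individual is;
* coverage tables in which relative abundance and prevalence are rank-coupled
  negatively (Gaussian copula on a shared latent score) with estimated
  genome size and biosynthetic completeness.

Everything is driven by one ``numpy`` Generator derived from the spec seed;
identical specs give byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io_formats import (CoverageTable, ModuleFlatFile, write_coverage_table,
                         write_culture_table, write_ko_annotations,
                         write_metadata, write_module_library)
from .module_grammar import (AndNode, KOLeaf, ModuleDefinition, Optional,
                             OrNode, StepExpression, render)

__all__ = ["SyntheticSpec", "Fixture", "make_module_library", "make_genome",
           "make_communities", "make_coverage", "simulate"]

_PHYLA = {
    0: ("Patescibacteria", "Firmicutes"),
    1: ("Bacteroidota", "Planctomycetota"),
    2: ("Proteobacteria", "Actinobacteria", "Verrucomicrobiota"),
}

_AA_NAMES = ("arginine", "cysteine", "glycine", "glutamate", "glutamine",
             "histidine", "isoleucine", "leucine", "lysine", "methionine",
             "phenylalanine", "proline", "serine", "threonine", "tryptophan",
             "tyrosine", "valine", "chorismate")
_VIT_NAMES = ("vitamin B1", "vitamin B2", "vitamin B3", "vitamin B5",
              "vitamin B6", "vitamin B7", "vitamin B9", "vitamin B12 aerobic",
              "vitamin B12 anaerobic")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study.

    Defaults mirror the study conditions the pipeline is meant to analyze:
    27 modules (18 amino-acid + 9 vitamin), pathway lengths of 2–10 steps,
    three completeness strata (0.15 / 0.45 / 0.80), cultures spanning
    complexities 1, 2, 3 and 4–13 species with the low stratum concentrated
    in the complex cultures, and 20 environmental samples with negative
    abundance couplings.
    """

    seed: int = 1
    n_aa_modules: int = 18
    n_vitamin_modules: int = 9
    steps_per_module: tuple[int, int] = (2, 10)
    strata: tuple[float, ...] = (0.15, 0.45, 0.80)
    # complexity class -> stratum index (low completeness in complex cultures)
    class_strata: dict = field(default_factory=lambda: {
        "1": 2, "2": 2, "3": 1, "gt3": 0})
    # one entry per culture: its member count
    community_sizes: tuple[int, ...] = tuple(
        [1] * 50 + [2] * 25 + [3] * 17 + [4, 4, 4, 5, 5, 6, 6, 8, 8])
    complementarity: bool = True
    # probability that a 1-species culture reuses a species already seen in
    # a group culture (creates the "Both" growth category)
    reuse_prob: float = 0.2
    hq_probability: float = 0.9
    n_samples: int = 20
    abundance_mu: float = -3.0
    abundance_sigma: float = 1.2
    sample_sigma: float = 0.3
    coupling: float = 0.7


@dataclass
class Fixture:
    spec: SyntheticSpec
    library: list[ModuleFlatFile]
    annotations: dict[str, frozenset[str]]
    metadata: pd.DataFrame
    cultures: pd.DataFrame
    coverage: CoverageTable
    targets: pd.Series  # per-species stratum target avg_all

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_module_library(self.library, outdir / "modules.tsv")
        write_ko_annotations(self.annotations, outdir / "annotations.tsv")
        write_metadata(self.metadata, outdir / "metadata.tsv")
        write_culture_table(self.cultures, outdir / "cultures.tsv")
        write_coverage_table(self.coverage, outdir / "coverage.tsv")


# --- module library --------------------------------------------------------

class _KOCounter:
    def __init__(self):
        self.next = 1

    def take(self) -> str:
        ko = f"K{self.next:05d}"
        self.next += 1
        if self.next > 99999:
            raise ValueError("KO id space exhausted")
        return ko


def _make_step(rng: np.random.Generator, kos: _KOCounter) -> StepExpression:
    """One step: an OR over 1–3 alternatives, each a single KO or a 2–3
    subunit complex, occasionally with an optional accessory subunit."""
    n_alt = int(rng.integers(1, 4))
    alts: list[StepExpression] = []
    for _ in range(n_alt):
        n_sub = int(rng.integers(1, 4))
        parts: list[StepExpression] = [KOLeaf(kos.take()) for _ in range(n_sub)]
        if n_sub > 1 and rng.random() < 0.2:
            parts.append(Optional(KOLeaf(kos.take())))
        alts.append(parts[0] if len(parts) == 1 else AndNode(tuple(parts)))
    return alts[0] if n_alt == 1 else OrNode(tuple(alts))


def make_module_library(spec: SyntheticSpec,
                        rng: np.random.Generator | None = None
                        ) -> list[ModuleFlatFile]:
    """Synthetic module library in the supported grammar dialect.

    Steps draw globally fresh KO ids, so modules and steps share no KOs.
    Consolidated modules carry the ``_00`` suffix and variants ``_01``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    kos = _KOCounter()
    lo, hi = spec.steps_per_module
    out: list[ModuleFlatFile] = []
    specs = ([("amino_acid", _AA_NAMES[i % len(_AA_NAMES)], i)
              for i in range(spec.n_aa_modules)]
             + [("vitamin", _VIT_NAMES[i % len(_VIT_NAMES)], i)
                for i in range(spec.n_vitamin_modules)])
    for idx, (category, name, _) in enumerate(specs):
        suffix = "_01" if "anaerobic" in name else "_00"
        module_id = f"MC{idx + 1:05d}{suffix}"
        n_steps = int(rng.integers(lo, hi + 1))
        steps = tuple(_make_step(rng, kos) for _ in range(n_steps))
        definition = render(ModuleDefinition(module_id=module_id, steps=steps))
        out.append(ModuleFlatFile(module_id=module_id,
                                  name=f"{name} biosynthesis",
                                  category=category, definition=definition))
    return out


# --- genomes ---------------------------------------------------------------

def _step_solution(step: StepExpression, rng: np.random.Generator) -> set[str]:
    """A KO set satisfying one step: random alternative per OR, all required
    components per AND, optional components skipped."""
    if isinstance(step, KOLeaf):
        return {step.ko}
    if isinstance(step, Optional):
        return set()
    if isinstance(step, OrNode):
        pick = step.children[rng.integers(0, len(step.children))]
        return _step_solution(pick, rng)
    if isinstance(step, AndNode):
        out: set[str] = set()
        for c in step.children:
            if not isinstance(c, Optional):
                out |= _step_solution(c, rng)
        return out
    return set()  # NoEnzyme needs nothing


def _satisfy_steps(module: ModuleDefinition, step_idx, rng) -> set[str]:
    out: set[str] = set()
    for i in step_idx:
        out |= _step_solution(module.steps[i], rng)
    return out


def _quota(target: float, n_steps: int) -> int:
    return int(round(target * n_steps))


def make_genome(target_completeness: float, library,
                rng: np.random.Generator,
                genome_id: str = "g1") -> tuple[frozenset[str], dict]:
    """A KO set with exact binary completeness ≈ target on every module.

    For each module, exactly ``round(target × n_steps)`` randomly chosen
    steps are satisfied.  Metadata draws estimated genome size increasing in
    the target (with noise) and quality numbers that pass the high-quality
    filter with the configured probability.
    """
    if not 0.0 <= target_completeness <= 1.0:
        raise ValueError("target completeness must be in [0, 1]")
    kos: set[str] = set()
    for m in library:
        module = m.parse() if isinstance(m, ModuleFlatFile) else m
        k = _quota(target_completeness, module.n_steps)
        chosen = rng.choice(module.n_steps, size=k, replace=False)
        kos |= _satisfy_steps(module, chosen, rng)
    meta = _draw_metadata(target_completeness, rng, hq_probability=0.9)
    meta["genome_id"] = genome_id
    return frozenset(kos), meta


def _draw_metadata(target: float, rng: np.random.Generator,
                   hq_probability: float, stratum: int | None = None,
                   source: str = "culture") -> dict:
    size = max(0.5, 1.0 + 4.0 * target + rng.normal(0.0, 0.3))
    if rng.random() < hq_probability:
        completeness = float(rng.uniform(92.0, 100.0))
        contamination = float(rng.uniform(0.0, 4.5))
    else:  # fail the high-quality gate on one of the two criteria
        if rng.random() < 0.5:
            completeness = float(rng.uniform(46.0, 90.0))
            contamination = float(rng.uniform(0.0, 4.5))
        else:
            completeness = float(rng.uniform(92.0, 100.0))
            contamination = float(rng.uniform(5.5, 9.5))
    if stratum is None:
        stratum = 0 if target < 0.3 else (1 if target < 0.625 else 2)
    phyla = _PHYLA[stratum]
    phylum = phyla[int(rng.integers(0, len(phyla)))]
    return {
        "completeness_pct": round(completeness, 2),
        "contamination_pct": round(contamination, 2),
        "est_genome_size_mbp": round(size, 3),
        "taxonomy": f"d__Bacteria;p__{phylum}",
        "source": source,
    }


# --- communities -----------------------------------------------------------

def _complementary_step_sets(n_steps: int, quotas: list[int],
                             rng: np.random.Generator) -> list[set[int]]:
    """Partition step indices across members so the union covers all steps
    and member i holds ``quotas[i]`` distinct steps (quotas already sum to
    at least ``n_steps``)."""
    order = list(rng.permutation(n_steps))
    held: list[set[int]] = [set() for _ in quotas]
    members = list(range(len(quotas)))
    # phase 1: deal each step once, cycling over members with room
    m = 0
    for step in order:
        for _ in range(len(members)):
            if len(held[members[m]]) < quotas[members[m]]:
                held[members[m]].add(step)
                m = (m + 1) % len(members)
                break
            m = (m + 1) % len(members)
    # phase 2: top up remaining quotas with steps not already held
    for i, quota in enumerate(quotas):
        if len(held[i]) < quota:
            pool = [s for s in order if s not in held[i]]
            extra = rng.choice(len(pool), size=quota - len(held[i]),
                               replace=False)
            held[i].update(pool[e] for e in extra)
    return held


def make_communities(spec: SyntheticSpec, library,
                     rng: np.random.Generator | None = None):
    """Build cultures and their member genomes.

    Returns ``(cultures, annotations, metadata, targets)``: a membership
    table, genome → KO set mapping, per-genome metadata and the per-genome
    stratum target.  Complexity classes follow ``spec.community_sizes``;
    each class draws its members from the stratum ``spec.class_strata``
    assigns it.  With ``spec.complementarity`` set, members of every
    ≥4-species culture receive disjoint satisfied-step patterns whose union
    covers every module completely (member quotas are minimally bumped when
    the stratum target alone could not cover a pathway).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    modules = [m.parse() if isinstance(m, ModuleFlatFile) else m
               for m in library]
    if not modules:
        raise ValueError("empty module library")
    n_genomes_needed = sum(spec.community_sizes)
    if n_genomes_needed == 0:
        raise ValueError("no communities requested")

    annotations: dict[str, frozenset[str]] = {}
    meta_rows: dict[str, dict] = {}
    targets: dict[str, float] = {}
    culture_rows: list[tuple[str, str]] = []
    group_species: list[str] = []  # species seen in multi-member cultures
    next_species = 1

    def new_species(target: float, kos: frozenset[str], source: str) -> str:
        nonlocal next_species
        sid = f"sp{next_species:04d}"
        next_species += 1
        annotations[sid] = kos
        meta_rows[sid] = _draw_metadata(target, rng, spec.hq_probability,
                                        source=source)
        targets[sid] = target
        return sid

    # multi-member cultures first so singles can reuse their species
    sizes = sorted(spec.community_sizes, reverse=True)
    for c_idx, size in enumerate(sizes):
        culture_id = f"cul{c_idx + 1:03d}"
        cls = str(size) if size <= 3 else "gt3"
        target = spec.strata[spec.class_strata[cls]]
        if size >= 4 and spec.complementarity:
            member_steps: dict[int, dict[int, set[int]]] = {
                i: {} for i in range(size)}
            for mi, module in enumerate(modules):
                quotas = [_quota(target, module.n_steps)] * size
                i = 0  # minimal round-robin bump so the union can cover
                while sum(quotas) < module.n_steps:
                    quotas[i % size] += 1
                    i += 1
                held = _complementary_step_sets(module.n_steps, quotas, rng)
                for member, steps in enumerate(held):
                    member_steps[member][mi] = steps
            for member in range(size):
                kos: set[str] = set()
                for mi, module in enumerate(modules):
                    kos |= _satisfy_steps(module, member_steps[member][mi], rng)
                sid = new_species(target, frozenset(kos), "culture")
                group_species.append(sid)
                culture_rows.append((culture_id, sid))
        else:
            for member in range(size):
                if size == 1 and group_species and rng.random() < spec.reuse_prob:
                    # singleton culture of a species also seen in groups
                    pool = sorted(set(group_species))
                    sid = pool[int(rng.integers(0, len(pool)))]
                else:
                    kos, _ = _make_kos_only(target, modules, rng)
                    sid = new_species(target, kos, "culture")
                    if size > 1:
                        group_species.append(sid)
                culture_rows.append((culture_id, sid))

    cultures = (pd.DataFrame(culture_rows, columns=["culture_id", "species_id"])
                .drop_duplicates()
                .sort_values(["culture_id", "species_id"])
                .reset_index(drop=True))
    metadata = pd.DataFrame.from_dict(meta_rows, orient="index").sort_index()
    metadata.index.name = "genome_id"
    return cultures, annotations, metadata, pd.Series(targets).sort_index()


def _make_kos_only(target: float, modules, rng) -> tuple[frozenset[str], None]:
    kos: set[str] = set()
    for module in modules:
        k = _quota(target, module.n_steps)
        chosen = rng.choice(module.n_steps, size=k, replace=False)
        kos |= _satisfy_steps(module, chosen, rng)
    return frozenset(kos), None


# --- coverage --------------------------------------------------------------

def make_coverage(spec: SyntheticSpec, metadata: pd.DataFrame,
                  targets: pd.Series,
                  rng: np.random.Generator | None = None) -> CoverageTable:
    """Coverage table with negative abundance couplings.

    A shared latent score blends the ranks of estimated genome size and
    biosynthetic completeness; species abundance is log-normal with a
    Gaussian-copula coupling of strength ``spec.coupling`` *against* that
    score, and per-species detection probability falls with the score, so
    small streamlined genomes come out more abundant *and* more prevalent.
    With coupling 0 the abundances are independent of genome traits.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    species = sorted(metadata.index)
    n = len(species)
    size_rank = pd.Series(metadata.loc[species, "est_genome_size_mbp"]
                          ).rank().to_numpy()
    compl_rank = targets.loc[species].rank().to_numpy()

    def standardize(v):
        return (v - v.mean()) / v.std() if v.std() > 0 else np.zeros_like(v)

    score = standardize(standardize(size_rank) + standardize(compl_rank))
    rho = spec.coupling
    latent = -rho * score + np.sqrt(max(0.0, 1 - rho ** 2)) * rng.normal(size=n)
    base = np.exp(spec.abundance_mu + spec.abundance_sigma * latent)
    # detection probability shrinks with the latent score
    detect_p = np.clip(1.0 - 0.6 * norm.cdf(rho * score), 0.05, 1.0)

    mean_cov = pd.Series(
        np.exp(np.log(50.0) + 0.3 * rng.normal(size=spec.n_samples)),
        index=[f"s{j + 1:03d}" for j in range(spec.n_samples)],
        name="mean_coverage")
    ra = (base[:, None]
          * np.exp(spec.sample_sigma * rng.normal(size=(n, spec.n_samples))))
    detected = rng.random((n, spec.n_samples)) < detect_p[:, None]
    ra = np.where(detected, ra, 0.0)
    coverage = pd.DataFrame(ra * mean_cov.to_numpy()[None, :],
                            index=pd.Index(species, name="genome_id"),
                            columns=mean_cov.index)
    return CoverageTable(coverage=coverage, mean_coverage=mean_cov)


# --- one-shot --------------------------------------------------------------

def simulate(spec: SyntheticSpec) -> Fixture:
    """Generate a complete fixture (library, genomes, cultures, coverage)
    from one seed."""
    rng = np.random.default_rng(spec.seed)
    library = make_module_library(spec, rng)
    cultures, annotations, metadata, targets = make_communities(
        spec, library, rng)
    coverage = make_coverage(spec, metadata, targets, rng)
    return Fixture(spec=spec, library=library, annotations=annotations,
                   metadata=metadata, cultures=cultures, coverage=coverage,
                   targets=targets)
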