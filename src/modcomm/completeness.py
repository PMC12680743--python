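"""Genome-level completeness scoring, quality filtering and QC regression.

The central object is the completeness matrix: genomes × modules with values
in [0, 1], where each cell is the pathway completeness of one biosynthesis
module in one genome.  Category averages condense it to one amino-acid, one
vitamin and one overall number per genome — the genome's "anabolic
independence".  A per-module ordinary-least-squares regression of module
completeness on genome (assembly) completeness screens for quality
artifacts: biosynthetic signal unrelated to assembly quality shows mean R²
near zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import ModuleFlatFile
from .module_grammar import ModuleDefinition, ScoringMode, module_completeness

__all__ = [
    "score_genomes",
    "filter_high_quality",
    "average_completeness",
    "exclude_modules",
    "qc_regress_module_vs_genome_completeness",
    "HQ_COMPLETENESS_PCT",
    "HQ_CONTAMINATION_PCT",
    "MAG_COMPLETENESS_PCT",
    "MAG_CONTAMINATION_PCT",
]

# Quality gates, strict inequalities: high-quality genomes for per-genome
# biosynthesis comparisons, and the looser gate for admitting a bin as a MAG.
HQ_COMPLETENESS_PCT = 90.0
HQ_CONTAMINATION_PCT = 5.0
MAG_COMPLETENESS_PCT = 45.0
MAG_CONTAMINATION_PCT = 10.0


def _as_definitions(library) -> list[ModuleDefinition]:
    out = []
    for m in library:
        out.append(m.parse() if isinstance(m, ModuleFlatFile) else m)
    return out


def score_genomes(annotations: dict[str, frozenset[str]],
                  library,
                  mode: ScoringMode = "binary") -> pd.DataFrame:
    """Score every genome against every module of a library.

    Parameters
    ----------
    annotations
        Mapping genome id → KO set.
    library
        Iterable of :class:`ModuleFlatFile` or parsed
        :class:`ModuleDefinition`.
    mode
        ``"binary"`` (fraction of satisfied steps, default) or
        ``"fractional"`` (continuous per-step credit).

    Returns a DataFrame (rows genomes, columns modules, sorted ids) with
    values in [0, 1] and ``attrs["mode"]`` recording the scoring mode.
    """
    modules = _as_definitions(library)
    if not modules:
        raise ValueError("empty module library")
    genome_ids = sorted(annotations)
    module_ids = [m.module_id for m in modules]
    values = np.empty((len(genome_ids), len(module_ids)))
    for i, g in enumerate(genome_ids):
        kos = annotations[g]
        for j, m in enumerate(modules):
            values[i, j] = module_completeness(m, kos, mode=mode)
    out = pd.DataFrame(values, index=pd.Index(genome_ids, name="genome_id"),
                       columns=module_ids).sort_index(axis=1)
    out.attrs["mode"] = mode
    return out


def filter_high_quality(metadata: pd.DataFrame,
                        min_completeness: float = HQ_COMPLETENESS_PCT,
                        max_contamination: float = HQ_CONTAMINATION_PCT) -> list[str]:
    """Genome ids passing completeness > threshold and contamination <
    threshold (both strict)."""
    keep = ((metadata["completeness_pct"] > min_completeness)
            & (metadata["contamination_pct"] < max_contamination))
    return sorted(metadata.index[keep])


def exclude_modules(library, excluded_names: set[str]):
    """Drop modules whose name or id matches an exclusion list.

    Used to remove metabolites (e.g. alanine, asparagine, aspartate) whose
    biosynthesis runs through generic transaminations that annotate poorly
    and would otherwise read as artificially incomplete.  Matching is
    case-insensitive against both the module name and id.
    """
    lows = {e.lower() for e in excluded_names}

    def hit(m) -> bool:
        name = (m.name or "").lower()
        return m.module_id.lower() in lows or any(e in name for e in lows)

    return [m for m in library if not hit(m)]


def average_completeness(matrix: pd.DataFrame,
                         category_map: dict[str, str]) -> pd.DataFrame:
    """Per-genome unweighted category means of the completeness matrix.

    ``category_map`` assigns each module column to ``amino_acid`` or
    ``vitamin``; every column must be covered.  ``avg_all`` is the mean over
    the union of all modules (so with 18 + 9 modules it is the 27-module
    mean, not the midpoint of the two category means).
    """
    missing = [m for m in matrix.columns if m not in category_map]
    if missing:
        raise ValueError(f"modules without category: {missing}")
    aa = [m for m in matrix.columns if category_map[m] == "amino_acid"]
    vit = [m for m in matrix.columns if category_map[m] == "vitamin"]
    out = pd.DataFrame(index=matrix.index)
    out["avg_aa"] = matrix[aa].mean(axis=1) if aa else np.nan
    out["avg_vit"] = matrix[vit].mean(axis=1) if vit else np.nan
    out["avg_all"] = matrix.mean(axis=1)
    return out


@dataclass(frozen=True)
class QCRegression:
    per_module: pd.DataFrame  # columns: slope, r_squared, p_value
    mean_r_squared: float


def qc_regress_module_vs_genome_completeness(
        matrix: pd.DataFrame, metadata: pd.DataFrame) -> QCRegression:
    """OLS of each module's completeness on genome completeness (%).

    Low mean R² across modules indicates the biosynthetic signal is not an
    artifact of varying assembly completeness.  With zero variance in genome
    completeness the slope is undefined and flagged as NaN.
    """
    common = matrix.index.intersection(metadata.index)
    if len(common) < 3:
        raise ValueError("need at least 3 genomes with metadata")
    x = metadata.loc[common, "completeness_pct"].to_numpy(float)
    rows = {}
    degenerate = np.ptp(x) == 0
    for module in matrix.columns:
        y = matrix.loc[common, module].to_numpy(float)
        if degenerate:
            rows[module] = (np.nan, np.nan, np.nan)
            continue
        fit = sps.linregress(x, y)
        # a constant response has R² = 0 by convention
        r2 = 0.0 if np.ptp(y) == 0 else fit.rvalue ** 2
        rows[module] = (fit.slope, r2, fit.pvalue)
    per_module = pd.DataFrame.from_dict(
        rows, orient="index", columns=["slope", "r_squared", "p_value"])
    per_module.index.name = "module_id"
    return QCRegression(per_module=per_module,
                        mean_r_squared=float(per_module["r_squared"].mean()))
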