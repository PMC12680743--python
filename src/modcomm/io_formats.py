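"""Readers and writers for the package's tabular formats and module flat files.

All tables are plain text, tab-delimited by default with comma fallback
detected from the header line.  Module libraries come in two dialects:

* KEGG-flat-file-style keyed blocks (``ENTRY`` / ``NAME`` / ``CLASS`` /
  ``DEFINITION`` lines, records separated by ``///``), the dialect used by
  published custom biosynthesis module collections;
* a simple 4-column TSV (``module_id``, ``name``, ``category``,
  ``definition``) convenient for fixtures.

Loaded tables are canonically sorted by id so input order never leaks into
downstream results, and every writer is deterministic byte-for-byte.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .module_grammar import KO_PATTERN, ModuleParseError, parse_definition

__all__ = [
    "GenomeMetadata",
    "CoverageTable",
    "ModuleFlatFile",
    "read_ko_annotations",
    "write_ko_annotations",
    "read_module_library",
    "write_module_library",
    "read_metadata",
    "write_metadata",
    "read_coverage_table",
    "write_coverage_table",
    "read_culture_table",
    "write_culture_table",
    "write_matrix",
    "read_matrix",
]

log = logging.getLogger(__name__)

SOURCES = ("culture", "environment", "both")
CATEGORIES = ("amino_acid", "vitamin")


@dataclass(frozen=True)
class ModuleFlatFile:
    """One raw (unparsed) module record from a library file."""

    module_id: str
    name: str
    category: str
    definition: str

    def parse(self):
        return parse_definition(self.definition, module_id=self.module_id,
                                category=self.category, name=self.name)


@dataclass
class CoverageTable:
    """Genome × sample q2q3 coverage plus per-sample mean coverage.

    ``coverage`` is a wide DataFrame (rows genomes, columns samples); pairs
    absent from the input file are zero — under competitive mapping every
    genome has a coverage in every sample, and absence simply means no reads
    mapped.  ``mean_coverage`` is a per-sample Series (> 0).
    """

    coverage: pd.DataFrame
    mean_coverage: pd.Series

    def __post_init__(self):
        self.coverage = self.coverage.sort_index(axis=0).sort_index(axis=1)
        self.coverage.index.name = "genome_id"
        self.coverage.columns.name = "sample_id"
        self.mean_coverage = self.mean_coverage.reindex(self.coverage.columns)
        self.mean_coverage.index.name = "sample_id"
        if (self.coverage.to_numpy() < 0).any():
            raise ValueError("negative coverage value")
        if (self.mean_coverage <= 0).any() or self.mean_coverage.isna().any():
            raise ValueError("every sample needs a mean coverage > 0")


GenomeMetadata = pd.DataFrame  # columns: completeness_pct, contamination_pct,
#                                est_genome_size_mbp, taxonomy, source


# --- helpers ---------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header or "," not in header else ","


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    return pd.read_csv(path, sep=_sniff_sep(path))


def _find_column(df: pd.DataFrame, *names: str) -> str:
    lower = {c.lower(): c for c in df.columns}
    for name in names:
        if name in lower:
            return lower[name]
    raise ValueError(f"no column named any of {names} in {list(df.columns)}")


# --- KO annotations --------------------------------------------------------

def read_ko_annotations(path) -> dict[str, frozenset[str]]:
    """Read a (genome_id, ko_id) table into a genome → KO-set mapping.

    KO ids must match ``K\\d{5}``; malformed rows are dropped with a warning.
    Duplicate (genome, KO) rows collapse under set semantics.  Genomes are
    returned in sorted order.
    """
    df = _read_table(path)
    if df.empty:
        raise ValueError(f"{path}: no annotations")
    gcol = _find_column(df, "genome_id", "genome", "bin_id", "mag_id")
    kcol = _find_column(df, "ko_id", "ko", "accession", "kofam")
    bad = ~df[kcol].astype(str).str.fullmatch(r"K\d{5}")
    if bad.any():
        warnings.warn(f"{path}: dropped {int(bad.sum())} rows with malformed KO ids")
        df = df[~bad]
    if df.empty:
        raise ValueError(f"{path}: no annotations")
    if (df[gcol].astype(str) == "").any():
        raise ValueError(f"{path}: empty genome id")
    out = {g: frozenset(sub[kcol]) for g, sub in df.groupby(gcol, sort=True)}
    log.info("read %d annotation rows for %d genomes from %s",
             len(df), len(out), path)
    return out


def write_ko_annotations(annotations: dict[str, frozenset[str]], path) -> None:
    rows = [(g, k) for g in sorted(annotations)
            for k in sorted(annotations[g])]
    pd.DataFrame(rows, columns=["genome_id", "ko_id"]).to_csv(
        path, sep="\t", index=False)


# --- module libraries ------------------------------------------------------

def read_module_library(path_or_dir) -> list[ModuleFlatFile]:
    """Read a module library from a directory of flat files, one keyed flat
    file with ``///`` record separators, or a 4-column TSV.

    Every definition is parsed on load, so an unbalanced or malformed
    definition raises a :class:`ModuleParseError` naming the module.
    Modules are returned in file order; ids must be unique.
    """
    path = Path(path_or_dir)
    if path.is_dir():
        modules: list[ModuleFlatFile] = []
        for child in sorted(path.iterdir()):
            if child.is_file():
                modules.extend(read_module_library(child))
    else:
        with open(path) as fh:
            text = fh.read()
        if "DEFINITION" in text:
            modules = _parse_keyed_blocks(text)
        else:
            df = pd.read_csv(path, sep=_sniff_sep(path))
            cols = {c.lower(): c for c in df.columns}
            modules = [
                ModuleFlatFile(
                    module_id=str(r[cols["module_id"]]),
                    name=str(r[cols.get("name", "name")]) if "name" in cols else "",
                    category=str(r[cols["category"]]),
                    definition=str(r[cols["definition"]]),
                )
                for _, r in df.iterrows()
            ]
    seen: set[str] = set()
    for m in modules:
        if m.module_id in seen:
            raise ValueError(f"duplicate module id {m.module_id}")
        seen.add(m.module_id)
        if m.category not in CATEGORIES:
            raise ValueError(f"module {m.module_id}: unknown category {m.category!r}")
        m.parse()  # raises ModuleParseError naming the module if malformed
    return modules


def _parse_keyed_blocks(text: str) -> list[ModuleFlatFile]:
    modules = []
    for block in text.split("///"):
        if not block.strip():
            continue
        fields: dict[str, str] = {}
        key = None
        for line in block.splitlines():
            if not line.strip():
                continue
            if line[:1] not in (" ", "\t"):
                key, _, value = line.partition(" ")
                fields[key] = value.strip()
            elif key:  # continuation line
                fields[key] += " " + line.strip()
        if "ENTRY" not in fields or "DEFINITION" not in fields:
            raise ValueError("keyed module block missing ENTRY or DEFINITION")
        module_id = fields["ENTRY"].split()[0]
        category = _infer_category(fields.get("CLASS", fields.get("CATEGORY", "")))
        modules.append(ModuleFlatFile(
            module_id=module_id,
            name=fields.get("NAME", ""),
            category=category,
            definition=fields["DEFINITION"],
        ))
    return modules


def _infer_category(class_field: str) -> str:
    low = class_field.lower()
    if "vitamin" in low or "cofactor" in low:
        return "vitamin"
    if "amino" in low:
        return "amino_acid"
    return class_field.strip()


def write_module_library(modules: list[ModuleFlatFile], path,
                         style: str = "tsv") -> None:
    """Write a library as 4-column TSV (default) or keyed flat file."""
    if style == "tsv":
        pd.DataFrame(
            [(m.module_id, m.name, m.category, m.definition) for m in modules],
            columns=["module_id", "name", "category", "definition"],
        ).to_csv(path, sep="\t", index=False)
    elif style == "keyed":
        with open(path, "w") as fh:
            for m in modules:
                fh.write(f"ENTRY       {m.module_id}\n")
                fh.write(f"NAME        {m.name}\n")
                fh.write(f"CLASS       {m.category}\n")
                fh.write(f"DEFINITION  {m.definition}\n")
                fh.write("///\n")
    else:
        raise ValueError(f"unknown style {style!r}")


# --- genome metadata -------------------------------------------------------

def read_metadata(path) -> pd.DataFrame:
    """Genome metadata: completeness/contamination %, size (Mbp), taxonomy,
    source ∈ {culture, environment, both}.  Indexed and sorted by genome id."""
    df = _read_table(path)
    gcol = _find_column(df, "genome_id", "genome", "mag_id")
    df = df.set_index(gcol).sort_index()
    for col, lo, hi in (("completeness_pct", 0, 100),
                        ("contamination_pct", 0, 100)):
        if ((df[col] < lo) | (df[col] > hi)).any():
            raise ValueError(f"{col} outside [{lo}, {hi}]")
    if (df["est_genome_size_mbp"] <= 0).any():
        raise ValueError("est_genome_size_mbp must be positive")
    bad = ~df["source"].isin(SOURCES)
    if bad.any():
        raise ValueError(f"unknown source labels: {sorted(df['source'][bad].unique())}")
    return df


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.sort_index().to_csv(path, sep="\t", index_label="genome_id")


# --- coverage --------------------------------------------------------------

def read_coverage_table(path, mean_coverage_path=None) -> CoverageTable:
    """Read coverage in long layout (genome_id, sample_id, q2q3_cov) or wide
    layout (genome rows, sample columns), auto-detected from the header.

    Per-sample mean coverage comes from a ``mean_coverage`` column of the
    long layout, a companion two-column table, or — if absent — the mean of
    the q2q3 values per sample.
    """
    df = _read_table(path)
    cols = [c.lower() for c in df.columns]
    if "sample_id" in cols and ("q2q3_cov" in cols or "coverage" in cols):
        gcol = _find_column(df, "genome_id", "genome")
        scol = _find_column(df, "sample_id", "sample")
        vcol = _find_column(df, "q2q3_cov", "coverage")
        if df.duplicated([gcol, scol]).any():
            raise ValueError("duplicate (genome, sample) coverage entries")
        wide = (df.pivot(index=gcol, columns=scol, values=vcol)
                  .fillna(0.0).astype(float))
        if "mean_coverage" in cols:
            mcol = _find_column(df, "mean_coverage")
            mean_cov = df.groupby(scol)[mcol].first().astype(float)
        else:
            mean_cov = None
    else:
        wide = df.set_index(df.columns[0]).astype(float)
        mean_cov = None
    if mean_coverage_path is not None:
        mtab = _read_table(mean_coverage_path)
        scol = _find_column(mtab, "sample_id", "sample")
        mcol = _find_column(mtab, "mean_coverage")
        mean_cov = mtab.set_index(scol)[mcol].astype(float)
    if mean_cov is None:
        mean_cov = wide.mean(axis=0)
    wide.index.name = "genome_id"
    wide.columns.name = "sample_id"
    return CoverageTable(coverage=wide, mean_coverage=mean_cov)


def write_coverage_table(table: CoverageTable, path,
                         mean_coverage_path=None) -> None:
    """Long-format writer (round-trips through :func:`read_coverage_table`)."""
    long = (table.coverage.stack().rename("q2q3_cov").reset_index())
    long["mean_coverage"] = long["sample_id"].map(table.mean_coverage)
    long.to_csv(path, sep="\t", index=False)
    if mean_coverage_path is not None:
        table.mean_coverage.rename("mean_coverage").to_csv(
            mean_coverage_path, sep="\t", index_label="sample_id")


# --- cultures --------------------------------------------------------------

def read_culture_table(path) -> pd.DataFrame:
    """Culture membership: rows (culture_id, species_id), optional
    inoculum_cells.  Duplicate membership rows collapse."""
    df = _read_table(path)
    ccol = _find_column(df, "culture_id", "culture")
    scol = _find_column(df, "species_id", "species", "genome_id")
    keep = [ccol, scol] + (["inoculum_cells"] if "inoculum_cells" in df.columns else [])
    df = (df[keep]
          .rename(columns={ccol: "culture_id", scol: "species_id"})
          .drop_duplicates(subset=["culture_id", "species_id"])
          .sort_values(["culture_id", "species_id"])
          .reset_index(drop=True))
    if df.empty:
        raise ValueError(f"{path}: no culture membership rows")
    return df


def write_culture_table(cultures: pd.DataFrame, path) -> None:
    (cultures.sort_values(["culture_id", "species_id"])
     .to_csv(path, sep="\t", index=False))


# --- generic matrices ------------------------------------------------------

def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Tab-delimited wide matrix, rows and columns in stable sorted order."""
    matrix.sort_index(axis=0).sort_index(axis=1).to_csv(
        path, sep="\t", index_label=matrix.index.name or "id")


def read_matrix(path) -> pd.DataFrame:
    df = _read_table(path)
    return df.set_index(df.columns[0])
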