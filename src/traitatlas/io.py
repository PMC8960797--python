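"""Readers and writers for every pipeline table, plus trait-matrix assembly.

All tabular files are UTF-8 TSV with a header row; nested structures
(module definitions, run summaries) are JSON and the run configuration is
YAML.  Readers validate on load and raise :class:`ValidationError` naming
the offending file/row/field; writers and readers round-trip exactly.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    HABITATS,
    TAX_RANKS,
    GenomeRecord,
    KOAnnotationTable,
    ModuleDefinition,
    TraitMatrix,
    ValidationError,
)
from .config import PipelineConfig, read_config, write_config  # noqa: F401  (re-export)

__all__ = [
    "read_genomes", "write_genomes",
    "read_ko_table", "write_ko_table",
    "read_trait_calls", "write_trait_calls",
    "read_trait_meta", "write_trait_meta",
    "read_trait_matrix", "write_trait_matrix",
    "read_module_definitions", "write_module_definitions",
    "read_config", "write_config",
    "assemble_trait_matrix",
]


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, **kw)
    except Exception as exc:  # pragma: no cover - passthrough context
        raise ValidationError(f"{path}: failed to parse TSV ({exc})") from exc


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------

def read_genomes(path: str | Path) -> list[GenomeRecord]:
    """Read ``genomes.tsv``: genome_id, habitat, genome_size, completeness,
    contamination plus one column per taxonomy rank present."""
    path = Path(path)
    df = _read_tsv(path)
    if "genome_id" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'genome_id'")
    dups = df["genome_id"][df["genome_id"].duplicated()].tolist()
    if dups:
        raise ValidationError(f"{path}: duplicate genome_id {sorted(set(dups))}")
    rank_cols = [r for r in TAX_RANKS if r in df.columns]
    records = []
    for lineno, row in enumerate(df.to_dict("records"), start=2):
        taxonomy = {r: row[r] for r in rank_cols if row[r]}
        try:
            records.append(
                GenomeRecord(
                    genome_id=row["genome_id"],
                    taxonomy=taxonomy,
                    habitat=row.get("habitat", "other") or "other",
                    genome_size=int(row.get("genome_size", 0) or 0),
                    completeness=float(row.get("completeness", 100) or 100),
                    contamination=float(row.get("contamination", 0) or 0),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    return records


def write_genomes(records: Sequence[GenomeRecord], path: str | Path) -> None:
    ranks = [r for r in TAX_RANKS if any(r in g.taxonomy for g in records)]
    rows = []
    for g in records:
        row = {"genome_id": g.genome_id}
        row.update({r: g.taxonomy.get(r, "") for r in ranks})
        row.update(
            habitat=g.habitat, genome_size=g.genome_size,
            completeness=g.completeness, contamination=g.contamination,
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# KO annotations (long format: genome_id, ko)
# ---------------------------------------------------------------------------

def read_ko_table(path: str | Path) -> KOAnnotationTable:
    path = Path(path)
    df = _read_tsv(path)
    for col in ("genome_id", "ko"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    try:
        return KOAnnotationTable(
            {g: set(sub["ko"]) for g, sub in df.groupby("genome_id", sort=False)}
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_ko_table(table: KOAnnotationTable, path: str | Path) -> None:
    rows = [
        {"genome_id": g, "ko": ko}
        for g in sorted(table.genomes)
        for ko in sorted(table[g])
    ]
    pd.DataFrame(rows, columns=["genome_id", "ko"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# trait calls (wide binary table per category) and trait metadata
# ---------------------------------------------------------------------------

def _validate_binary(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        vals = df[col]
        bad = ~vals.isin(["0", "1"])
        if bad.any():
            line = int(np.argmax(bad.to_numpy())) + 2
            raise ValidationError(
                f"{path}: line {line}, field {col!r}: "
                f"non-binary value {vals[bad].iloc[0]!r}"
            )
        out[col] = vals.astype(np.int8)
    return pd.DataFrame(out, index=df.index)


def read_trait_calls(path: str | Path, category: str) -> pd.DataFrame:
    """Read a per-category trait-call table: genome_id column + one binary
    column per trait.  Returns a genome x trait 0/1 DataFrame."""
    path = Path(path)
    df = _read_tsv(path)
    if "genome_id" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'genome_id'")
    dups = df["genome_id"][df["genome_id"].duplicated()].tolist()
    if dups:
        raise ValidationError(f"{path}: duplicate genome_id {sorted(set(dups))}")
    df = df.set_index("genome_id")
    out = _validate_binary(df, path)
    out.attrs["category"] = category
    return out


def write_trait_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.rename_axis("genome_id").reset_index().to_csv(path, sep="\t", index=False)


def read_trait_meta(path: str | Path) -> pd.DataFrame:
    """Read trait metadata: trait_id, category, interaction, substrate, role."""
    path = Path(path)
    df = _read_tsv(path)
    if "trait_id" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'trait_id'")
    df = df.set_index("trait_id")
    if "interaction" in df.columns:
        df["interaction"] = df["interaction"].isin(["1", "True", "true"])
    return df


def write_trait_meta(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    if "interaction" in out.columns:
        out["interaction"] = out["interaction"].astype(int)
    out.rename_axis("trait_id").reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# trait matrix
# ---------------------------------------------------------------------------

def write_trait_matrix(matrix: TraitMatrix, path: str | Path) -> None:
    """Write the wide binary matrix; trait metadata goes to a sibling
    ``<stem>_meta.tsv``."""
    path = Path(path)
    matrix.to_frame().reset_index().to_csv(path, sep="\t", index=False)
    write_trait_meta(matrix.trait_meta, path.with_name(path.stem + "_meta.tsv"))


def read_trait_matrix(path: str | Path, meta_path: str | Path | None = None) -> TraitMatrix:
    path = Path(path)
    df = _read_tsv(path)
    if "genome_id" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'genome_id'")
    df = df.set_index("genome_id")
    df = _validate_binary(df, path)
    if meta_path is None:
        candidate = path.with_name(path.stem + "_meta.tsv")
        meta_path = candidate if candidate.exists() else None
    meta = read_trait_meta(meta_path) if meta_path is not None else None
    return TraitMatrix(df, trait_meta=meta)


# ---------------------------------------------------------------------------
# module definitions (JSON)
# ---------------------------------------------------------------------------

def read_module_definitions(path: str | Path) -> list[ModuleDefinition]:
    raw = json.loads(Path(path).read_text())
    defs = [ModuleDefinition.from_dict(d) for d in raw]
    seen: set[str] = set()
    for d in defs:
        if d.module_id in seen:
            raise ValidationError(f"{path}: duplicate module_id {d.module_id!r}")
        seen.add(d.module_id)
    return defs


def write_module_definitions(defs: Sequence[ModuleDefinition], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([d.to_dict() for d in defs], indent=1, sort_keys=True)
    )


# ---------------------------------------------------------------------------
# trait matrix assembly
# ---------------------------------------------------------------------------

def assemble_trait_matrix(
    module_matrix: pd.DataFrame | None,
    call_tables: Mapping[str, pd.DataFrame] | None = None,
    interaction_traits: Iterable[str] = (),
    trait_meta: pd.DataFrame | None = None,
    genomes: Sequence[str] | None = None,
) -> TraitMatrix:
    """Combine module-completeness columns and per-category trait-call
    tables into one binary :class:`TraitMatrix`.

    Trait ids are prefixed with their category (``kegg_module:M0001``) to
    guarantee global uniqueness.  Genomes missing from any one table get 0s
    in that table's columns.  Interaction flags are set exactly for the ids
    in ``interaction_traits``; ids not found in the assembled matrix raise a
    :class:`UserWarning` and are recorded nowhere else.
    """
    call_tables = dict(call_tables or {})
    pieces: list[pd.DataFrame] = []
    categories: dict[str, str] = {}

    def _prefixed(df: pd.DataFrame, category: str) -> pd.DataFrame:
        ren = {
            c: c if str(c).startswith(category + ":") else f"{category}:{c}"
            for c in df.columns
        }
        df = df.rename(columns=ren)
        for c in df.columns:
            if c in categories:
                raise ValidationError(f"trait id collision across categories: {c!r}")
            categories[c] = category
        return df

    if module_matrix is not None:
        pieces.append(_prefixed(module_matrix.astype(np.int8), "kegg_module"))
    for category, table in call_tables.items():
        pieces.append(_prefixed(table.astype(np.int8), category))
    if not pieces:
        raise ValidationError("nothing to assemble: no module matrix, no call tables")

    if genomes is None:
        genomes = sorted({g for p in pieces for g in p.index})
    wide = pd.concat(
        [p.reindex(genomes).fillna(0).astype(np.int8) for p in pieces], axis=1
    )

    meta = pd.DataFrame(index=wide.columns)
    meta["category"] = [categories[c] for c in wide.columns]
    meta["interaction"] = False
    meta["substrate"] = ""
    meta["role"] = ""
    if trait_meta is not None:
        for col in ("substrate", "role"):
            if col in trait_meta.columns:
                meta[col] = trait_meta[col].reindex(wide.columns).fillna("")
    missing = [t for t in interaction_traits if t not in meta.index]
    if missing:
        warnings.warn(
            f"interaction-trait ids absent from matrix: {missing}", UserWarning
        )
    present = [t for t in interaction_traits if t in meta.index]
    meta.loc[present, "interaction"] = True
    return TraitMatrix(wide, trait_meta=meta)
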