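"""Module completeness calls from KO annotations.

A module definition is an ordered list of reactions; a reaction is
satisfied when the genome's KO set contains ALL members of at least one of
the reaction's alternatives (multi-subunit complexes are AND-sets).  A
module is called complete when every reaction is satisfied, or — to absorb
annotation gaps — when exactly one reaction is missing in a module with at
least three reactions.  The strict rule (no tolerance) is available via
``strict=True``.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    KOAnnotationTable,
    ModuleCall,
    ModuleDefinition,
    ValidationError,
)

__all__ = ["reaction_satisfied", "call_module", "call_all", "module_matrix"]


def reaction_satisfied(
    reaction: Sequence[frozenset[str]], ko_set: Iterable[str]
) -> bool:
    """True iff some alternative of the reaction has all its KOs in ``ko_set``."""
    kos = ko_set if isinstance(ko_set, (set, frozenset)) else set(ko_set)
    return any(alt <= kos for alt in reaction)


def _is_complete(n_reactions: int, n_annotated: int, strict: bool) -> bool:
    if n_annotated == n_reactions:
        return True
    if strict:
        return False
    return n_reactions >= 3 and n_reactions - n_annotated == 1


def call_module(
    defn: ModuleDefinition,
    ko_set: Iterable[str],
    genome_id: str = "",
    strict: bool = False,
) -> ModuleCall:
    """Assess one module in one genome.

    ``complete`` iff all reactions are satisfied, or all but one in a
    module with >= 3 reactions (unless ``strict``).
    """
    kos = frozenset(ko_set)
    n_annotated = sum(reaction_satisfied(r, kos) for r in defn.reactions)
    return ModuleCall(
        genome_id=genome_id,
        module_id=defn.module_id,
        n_reactions=defn.n_reactions,
        n_annotated=n_annotated,
        complete=_is_complete(defn.n_reactions, n_annotated, strict),
    )


def call_all(
    defs: Sequence[ModuleDefinition],
    ko_table: KOAnnotationTable,
    strict: bool = False,
) -> list[ModuleCall]:
    """One :class:`ModuleCall` per genome x module."""
    if not defs:
        raise ValidationError("no module definitions supplied")
    ids = [d.module_id for d in defs]
    if len(set(ids)) != len(ids):
        dupes = sorted({m for m in ids if ids.count(m) > 1})
        raise ValidationError(f"duplicate module_id {dupes}")
    return [
        call_module(d, ko_table[g], genome_id=g, strict=strict)
        for g in ko_table.genomes
        for d in defs
    ]


def module_matrix(calls: Iterable[ModuleCall]) -> pd.DataFrame:
    """Pivot calls into a binary genome x module completeness table."""
    df = pd.DataFrame(
        [(c.genome_id, c.module_id, int(c.complete)) for c in calls],
        columns=["genome_id", "module_id", "complete"],
    )
    wide = df.pivot(index="genome_id", columns="module_id", values="complete")
    return wide.fillna(0).astype(np.int8).rename_axis(columns=None)


def calls_table(calls: Iterable[ModuleCall]) -> pd.DataFrame:
    """Long-format calls table for export."""
    return pd.DataFrame(
        [
            {
                "genome_id": c.genome_id,
                "module_id": c.module_id,
                "n_reactions": c.n_reactions,
                "n_annotated": c.n_annotated,
                "complete": int(c.complete),
            }
            for c in calls
        ]
    )
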