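"""Per-genome trait summaries.

Covers the prevalence prefilter applied before trait clustering, B-vitamin
acquisition strategies (consumer / independent / flexible), enumeration of
the 4^3 = 64 three-vitamin configuration space, and interaction-trait
counts per genome.

A genome's strategy for one vitamin follows from two booleans — can it
synthesise the vitamin, can it transport it:

========== ========== ===========
synthesis  transport  strategy
========== ========== ===========
False      True       consumer
True       False      independent
True       True       flexible
False      False      none
========== ========== ===========
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import TraitMatrix, ValidationError

__all__ = [
    "VITAMINS",
    "STRATEGIES",
    "VitaminProfile",
    "InteractionProfile",
    "prevalence_filter",
    "classify_vitamins",
    "strategy_from_flags",
    "enumerate_configurations",
    "count_interaction_traits",
]

VITAMINS = ("B1", "B7", "B12")
STRATEGIES = ("none", "consumer", "independent", "flexible")


def strategy_from_flags(synthesis: bool, transport: bool) -> str:
    """Map the (synthesis, transport) booleans to an acquisition strategy."""
    if synthesis and transport:
        return "flexible"
    if synthesis:
        return "independent"
    if transport:
        return "consumer"
    return "none"


@dataclass(frozen=True)
class VitaminProfile:
    genome_id: str
    vitamin: str
    synthesis: bool
    transport: bool

    @property
    def strategy(self) -> str:
        return strategy_from_flags(self.synthesis, self.transport)


@dataclass
class InteractionProfile:
    genome_id: str
    n_interaction_traits: int
    genome_size: int = 0
    residual_from_size_expectation: float = float("nan")


def prevalence_filter(
    matrix: TraitMatrix,
    min_frac: float,
    min_count: int | None = None,
) -> tuple[TraitMatrix, list[str]]:
    """Drop traits below the prevalence threshold.

    A trait is kept when ``count / n_genomes >= min_frac`` evaluated
    exactly, or when ``count >= min_count`` if an absolute override is
    given.  Returns the filtered matrix and the removed trait ids.
    """
    if not 0.0 <= min_frac <= 1.0:
        raise ValidationError(f"min_frac={min_frac} not in [0, 1]")
    counts = matrix.trait_counts()
    n = len(matrix.genomes)
    if min_count is not None:
        keep_mask = counts >= min_count
    else:
        keep_mask = counts / n >= min_frac
    kept = [t for t in matrix.traits if keep_mask[t]]
    removed = [t for t in matrix.traits if not keep_mask[t]]
    if not kept:
        raise ValidationError("prevalence filter removed every trait")
    return matrix.subset_traits(kept), removed


def _vitamin_trait_map(matrix: TraitMatrix) -> dict[str, dict[str, list[str]]]:
    meta = matrix.trait_meta
    out: dict[str, dict[str, list[str]]] = {}
    for vit in VITAMINS:
        tagged = meta[meta["substrate"] == vit]
        out[vit] = {
            "biosynthesis": list(tagged.index[tagged["role"] == "biosynthesis"]),
            "transport": list(tagged.index[tagged["role"] == "transport"]),
        }
    return out


def classify_vitamins(matrix: TraitMatrix) -> pd.DataFrame:
    """Per-genome B-vitamin strategies.

    Synthesis (transport) for a vitamin is the OR over all traits tagged
    with that vitamin's substrate and the ``biosynthesis`` (``transport``)
    role.  Returns a DataFrame indexed by genome with, per vitamin,
    ``<vit>_synthesis``, ``<vit>_transport`` and ``<vit>_strategy`` columns.
    """
    frame = matrix.to_frame()
    trait_map = _vitamin_trait_map(matrix)
    out = pd.DataFrame(index=frame.index)
    for vit in VITAMINS:
        syn_traits = trait_map[vit]["biosynthesis"]
        trn_traits = trait_map[vit]["transport"]
        if not syn_traits and not trn_traits:
            raise ValidationError(
                f"no trait tagged for vitamin {vit}: cannot classify strategies"
            )
        syn = frame[syn_traits].any(axis=1) if syn_traits else pd.Series(False, index=frame.index)
        trn = frame[trn_traits].any(axis=1) if trn_traits else pd.Series(False, index=frame.index)
        out[f"{vit}_synthesis"] = syn
        out[f"{vit}_transport"] = trn
        out[f"{vit}_strategy"] = [
            strategy_from_flags(s, t) for s, t in zip(syn, trn)
        ]
    return out


def enumerate_configurations(profiles: pd.DataFrame) -> pd.DataFrame:
    """Count genomes over the 64-cell (B1, B7, B12) strategy space.

    Returns one row per cell of the full 4 x 4 x 4 configuration space,
    with zero counts for unobserved combinations; ``attrs['n_observed']``
    holds the number of occupied cells.
    """
    if profiles.empty:
        raise ValidationError("no vitamin profiles to enumerate")
    cols = [f"{v}_strategy" for v in VITAMINS]
    observed = profiles.groupby(cols).size()
    cells = list(product(STRATEGIES, repeat=len(VITAMINS)))
    table = pd.DataFrame(cells, columns=cols)
    table["n_genomes"] = [int(observed.get(c, 0)) for c in cells]
    table.attrs["n_possible"] = len(cells)
    table.attrs["n_observed"] = int((table["n_genomes"] > 0).sum())
    return table


def count_interaction_traits(
    matrix: TraitMatrix, genome_sizes: dict[str, int] | None = None
) -> list[InteractionProfile]:
    """Per-genome count of flagged interaction traits."""
    flagged = matrix.trait_meta.index[matrix.trait_meta["interaction"]]
    idx = [matrix.traits.index(t) for t in flagged]
    counts = matrix.values[:, idx].sum(axis=1) if idx else np.zeros(len(matrix.genomes), int)
    sizes = genome_sizes or {}
    return [
        InteractionProfile(
            genome_id=g,
            n_interaction_traits=int(c),
            genome_size=int(sizes.get(g, 0)),
        )
        for g, c in zip(matrix.genomes, counts)
    ]
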