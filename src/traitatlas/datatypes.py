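"""Shared data model for the trait atlas pipeline.

The central object is the :class:`TraitMatrix`, a binary genomes x traits
presence/absence matrix with per-trait metadata (category, interaction flag,
substrate tags).  Everything downstream — genome functional clusters (GFCs),
linked trait clusters (LTCs), vitamin strategies, environmental mapping —
is computed from it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TAX_RANKS",
    "HABITATS",
    "TRAIT_CATEGORIES",
    "GenomeRecord",
    "KOAnnotationTable",
    "TraitMatrix",
    "ModuleDefinition",
    "ModuleCall",
    "ClusteringResult",
    "ValidationError",
]

TAX_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

HABITATS = frozenset(
    {"marine_pelagic", "extreme", "sediment", "human", "plant", "other"}
)

TRAIT_CATEGORIES = frozenset(
    {
        "kegg_module",
        "secondary_metabolite",
        "phytohormone_pathway",
        "transporter",
        "sulfur_catabolism",
    }
)

_KO_RE = re.compile(r"^K\d{5}$")


class ValidationError(ValueError):
    """Raised when an input object violates a data-model invariant."""


@dataclass(frozen=True)
class GenomeRecord:
    """One genome: identifier, taxonomy path, habitat and assembly stats."""

    genome_id: str
    taxonomy: Mapping[str, str]
    habitat: str = "other"
    genome_size: int = 0
    completeness: float = 100.0
    contamination: float = 0.0

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ValidationError("genome_id must be non-empty")
        if self.habitat not in HABITATS:
            raise ValidationError(
                f"genome {self.genome_id}: unknown habitat {self.habitat!r}"
            )
        if not 0.0 <= self.completeness <= 100.0:
            raise ValidationError(
                f"genome {self.genome_id}: completeness {self.completeness} not in [0, 100]"
            )
        if self.contamination < 0:
            raise ValidationError(
                f"genome {self.genome_id}: negative contamination"
            )
        bad = [r for r in self.taxonomy if r not in TAX_RANKS]
        if bad:
            raise ValidationError(
                f"genome {self.genome_id}: unknown taxonomy ranks {bad}"
            )
        # normalise to rank order
        ordered = {r: self.taxonomy[r] for r in TAX_RANKS if r in self.taxonomy}
        object.__setattr__(self, "taxonomy", ordered)

    def taxon_at(self, rank: str) -> str | None:
        return self.taxonomy.get(rank)


class KOAnnotationTable:
    """Mapping genome_id -> set of KEGG Ortholog identifiers ("K#####")."""

    def __init__(self, annotations: Mapping[str, Iterable[str]]):
        table: dict[str, frozenset[str]] = {}
        for gid, kos in annotations.items():
            kos = frozenset(kos)
            for ko in kos:
                if not _KO_RE.match(ko):
                    raise ValidationError(
                        f"genome {gid}: invalid KO identifier {ko!r}"
                    )
            table[str(gid)] = kos
        self._table = table

    def __getitem__(self, genome_id: str) -> frozenset[str]:
        return self._table[genome_id]

    def get(self, genome_id: str) -> frozenset[str]:
        return self._table.get(genome_id, frozenset())

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self._table

    def __len__(self) -> int:
        return len(self._table)

    def __iter__(self):
        return iter(self._table)

    def __eq__(self, other) -> bool:
        return isinstance(other, KOAnnotationTable) and self._table == other._table

    @property
    def genomes(self) -> list[str]:
        return list(self._table)

    def items(self):
        return self._table.items()


#: trait metadata columns and their defaults
_META_DEFAULTS = {"category": "kegg_module", "interaction": False, "substrate": "", "role": ""}


class TraitMatrix:
    """Binary genomes x traits matrix with per-trait metadata.

    Parameters
    ----------
    values
        0/1 array of shape (n_genomes, n_traits), or a DataFrame whose
        index holds genome ids and columns hold trait ids.
    genomes, traits
        Ordered id lists (ignored when ``values`` is a DataFrame).
    trait_meta
        DataFrame indexed by trait id with columns ``category``
        (one of :data:`TRAIT_CATEGORIES`), ``interaction`` (bool),
        ``substrate`` (e.g. ``"B1"``, ``"B12"``, ``"siderophore"``) and
        ``role`` (``"biosynthesis"`` / ``"transport"`` where relevant).
        Missing traits/columns are filled with defaults.
    """

    def __init__(
        self,
        values,
        genomes: Sequence[str] | None = None,
        traits: Sequence[str] | None = None,
        trait_meta: pd.DataFrame | None = None,
    ):
        if isinstance(values, pd.DataFrame):
            genomes = [str(g) for g in values.index]
            traits = [str(t) for t in values.columns]
            values = values.to_numpy()
        if genomes is None or traits is None:
            raise ValidationError("genomes and traits id lists are required")
        arr = np.asarray(values)
        if arr.ndim != 2 or arr.shape != (len(genomes), len(traits)):
            raise ValidationError(
                f"values shape {arr.shape} does not match "
                f"{len(genomes)} genomes x {len(traits)} traits"
            )
        if np.isnan(arr.astype(float)).any():
            raise ValidationError("trait matrix contains NaN")
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError("trait matrix values must be binary 0/1")
        if len(set(genomes)) != len(genomes):
            raise ValidationError("duplicate genome ids")
        if len(set(traits)) != len(traits):
            raise ValidationError("duplicate trait ids")
        self.genomes = list(genomes)
        self.traits = list(traits)
        self.values = arr.astype(np.int8)
        self.trait_meta = self._normalise_meta(trait_meta)

    def _normalise_meta(self, meta: pd.DataFrame | None) -> pd.DataFrame:
        out = pd.DataFrame(index=pd.Index(self.traits, name="trait_id"))
        if meta is None:
            meta = pd.DataFrame()
        for col, default in _META_DEFAULTS.items():
            if col in meta.columns:
                out[col] = meta[col].reindex(self.traits).fillna(default)
            else:
                out[col] = default
        out["interaction"] = out["interaction"].astype(bool)
        bad = set(out["category"]) - TRAIT_CATEGORIES
        if bad:
            raise ValidationError(f"unknown trait categories {sorted(bad)}")
        return out

    # -- convenience -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.genomes, name="genome_id"),
            columns=self.traits,
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def prevalence(self) -> pd.Series:
        """Fraction of genomes carrying each trait."""
        return pd.Series(
            self.values.mean(axis=0), index=self.traits, name="prevalence"
        )

    def trait_counts(self) -> pd.Series:
        return pd.Series(self.values.sum(axis=0), index=self.traits)

    def subset_traits(self, trait_ids: Sequence[str]) -> "TraitMatrix":
        idx = [self.traits.index(t) for t in trait_ids]
        return TraitMatrix(
            self.values[:, idx], self.genomes, list(trait_ids),
            self.trait_meta.loc[list(trait_ids)],
        )

    def interaction_traits(self) -> list[str]:
        return list(self.trait_meta.index[self.trait_meta["interaction"]])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TraitMatrix)
            and self.genomes == other.genomes
            and self.traits == other.traits
            and np.array_equal(self.values, other.values)
            and self.trait_meta.equals(other.trait_meta)
        )


class ModuleDefinition:
    """A functional module: an ordered list of reactions.

    Each reaction is satisfied by any one of its *alternatives*; each
    alternative is a set of KOs that must ALL be annotated (multi-subunit
    complexes), a singleton for simple alternatives.
    """

    def __init__(self, module_id: str, reactions: Sequence[Sequence[Iterable[str]]]):
        if not module_id:
            raise ValidationError("module_id must be non-empty")
        if len(reactions) < 1:
            raise ValidationError(f"module {module_id}: needs >=1 reaction")
        parsed: list[tuple[frozenset[str], ...]] = []
        for i, reaction in enumerate(reactions):
            alts = tuple(frozenset(a) for a in reaction)
            if not alts:
                raise ValidationError(
                    f"module {module_id}: reaction {i} has no alternatives"
                )
            if any(not a for a in alts):
                raise ValidationError(
                    f"module {module_id}: reaction {i} has an empty alternative"
                )
            parsed.append(alts)
        self.module_id = module_id
        self.reactions = tuple(parsed)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def all_kos(self) -> frozenset[str]:
        return frozenset(k for r in self.reactions for a in r for k in a)

    def to_dict(self) -> dict:
        return {
            "module_id": self.module_id,
            "reactions": [[sorted(a) for a in r] for r in self.reactions],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModuleDefinition":
        return cls(d["module_id"], d["reactions"])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ModuleDefinition)
            and self.module_id == other.module_id
            and self.reactions == other.reactions
        )

    def __repr__(self) -> str:
        return f"ModuleDefinition({self.module_id!r}, {self.n_reactions} reactions)"


@dataclass(frozen=True)
class ModuleCall:
    """Completeness call for one module in one genome."""

    genome_id: str
    module_id: str
    n_reactions: int
    n_annotated: int
    complete: bool

    def __post_init__(self) -> None:
        if self.n_annotated > self.n_reactions:
            raise ValidationError(
                f"{self.genome_id}/{self.module_id}: "
                "n_annotated exceeds n_reactions"
            )


@dataclass
class ClusteringResult:
    """Exemplar clustering output: item -> cluster id, cluster -> exemplar."""

    labels: dict[str, int]
    exemplars: dict[int, str]
    n_iterations: int = 0
    converged: bool = True
    net_similarity: float = float("nan")

    def __post_init__(self) -> None:
        for cid, ex in self.exemplars.items():
            if self.labels.get(ex) != cid:
                raise ValidationError(
                    f"exemplar {ex!r} does not belong to its own cluster {cid}"
                )

    @property
    def n_clusters(self) -> int:
        return len(self.exemplars)

    def members(self, cluster_id: int) -> list[str]:
        return [i for i, c in self.labels.items() if c == cluster_id]

    def labels_for(self, items: Sequence[str]) -> np.ndarray:
        return np.array([self.labels[i] for i in items])
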