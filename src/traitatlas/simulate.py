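"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator plants the features downstream stages are designed to
recover, so every stage is testable without any external download:

* genomes fall into ``n_gfc_blocks`` planted functional blocks and traits
  into ``n_ltc_blocks`` linkage blocks; each linkage block is carried by
  one genome block, and a genome carries a trait of a block it hosts with
  probability ``block_trait_occupancy`` (``background_occupancy``
  otherwise);
* half of the traits are functional modules; their KO annotations are
  emitted from generated module definitions with independent per-KO
  Bernoulli dropout, emulating incomplete functional annotation;
* genus labels agree with the planted genome block with probability
  ``taxon_concordance``; higher ranks group genera deterministically;
* amplicon hit tables have per-OTU GFC agreement controlled by a
  specificity noise rate, and OTU-pair synchrony scores are Gaussian with
  the same-block mean shifted by a planted effect size.

All generators are deterministic given the spec seed, and the planted
truth is returned (and serialized) alongside the data for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    GenomeRecord,
    KOAnnotationTable,
    ModuleDefinition,
    TraitMatrix,
    ValidationError,
)
from .modules import call_module
from .profiles import VITAMINS

__all__ = [
    "SyntheticSpec",
    "PlantedTruth",
    "SyntheticDataset",
    "gen_trait_matrix",
    "make_module_definitions",
    "gen_ko_tables",
    "gen_taxonomy",
    "gen_env_tables",
    "gen_dataset",
    "write_dataset",
]

_CALL_CATEGORIES = (
    "secondary_metabolite",
    "transporter",
    "phytohormone_pathway",
    "sulfur_catabolism",
)
_PREFIX = {
    "secondary_metabolite": "S",
    "transporter": "T",
    "phytohormone_pathway": "P",
    "sulfur_catabolism": "U",
}


@dataclass
class SyntheticSpec:
    """Study conditions for a synthetic dataset.

    Defaults mirror the reference synthetic study: 150 genomes in 5 genome
    blocks, 300 traits in 6 linkage blocks, 95%/5% block/background trait
    occupancy, 10% per-KO annotation dropout and 90% genus/block
    concordance.
    """

    n_genomes: int = 150
    n_traits: int = 300
    n_gfc_blocks: int = 5
    n_ltc_blocks: int = 6
    block_trait_occupancy: float = 0.95
    background_occupancy: float = 0.05
    annotation_dropout: float = 0.1
    taxon_concordance: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genomes", "n_traits", "n_gfc_blocks", "n_ltc_blocks"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValidationError(f"{name} must be a count >= 1, got {v!r}")
        for name in (
            "block_trait_occupancy", "background_occupancy",
            "annotation_dropout", "taxon_concordance",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} not a probability in [0, 1]")
        if self.n_gfc_blocks > self.n_genomes:
            raise ValidationError("n_gfc_blocks cannot exceed n_genomes")
        if self.n_ltc_blocks > self.n_traits:
            raise ValidationError("n_ltc_blocks cannot exceed n_traits")


@dataclass
class PlantedTruth:
    """Ground truth stored alongside generated data for recovery tests."""

    genome_block: dict[str, int] = field(default_factory=dict)
    trait_block: dict[str, int] = field(default_factory=dict)
    #: genome -> vitamin -> {"synthesis": bool, "transport": bool}
    vitamin_state: dict[str, dict[str, dict[str, bool]]] = field(default_factory=dict)
    synchrony_effect: float = 0.0
    #: (genome, module trait) pairs whose module the dropout left
    #: unreconstructible
    annotation_gaps: list[list[str]] = field(default_factory=list)
    #: otu -> planted genome block
    otu_block: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        d = json.loads(Path(path).read_text())
        d["genome_block"] = {k: int(v) for k, v in d["genome_block"].items()}
        d["trait_block"] = {k: int(v) for k, v in d["trait_block"].items()}
        d["otu_block"] = {k: int(v) for k, v in d.get("otu_block", {}).items()}
        return cls(**d)


def _carriers(ltc_block: int, n_gfc_blocks: int) -> frozenset[int]:
    """Genome blocks carrying a given trait linkage block.

    The first ``n_gfc_blocks`` linkage blocks map one-to-one onto genome
    blocks; each further block is carried by a run of consecutive genome
    blocks one longer than the previous wrap.  Every linkage block thus has
    a distinct carrier set, so planted trait blocks remain statistically
    distinguishable even when there are more linkage blocks than genome
    blocks.
    """
    width = ltc_block // n_gfc_blocks + 1
    start = ltc_block % n_gfc_blocks
    return frozenset((start + k) % n_gfc_blocks for k in range(width))


def _trait_ids(spec: SyntheticSpec) -> tuple[list[str], pd.DataFrame]:
    """Deterministic trait ids and metadata.

    Even-indexed traits are functional modules (``kegg_module:M####``);
    odd-indexed traits cycle through the remaining categories.  Three
    module traits are tagged as B1/B7/B12 biosynthesis and three
    transporter traits as the matching vitamin transporters; vitamin traits
    plus the traits of the last linkage block carry the interaction flag.
    """
    ids, cats = [], []
    for j in range(spec.n_traits):
        if j % 2 == 0:
            cat = "kegg_module"
            ids.append(f"kegg_module:M{j:04d}")
        else:
            cat = _CALL_CATEGORIES[(j // 2) % len(_CALL_CATEGORIES)]
            ids.append(f"{cat}:{_PREFIX[cat]}{j:04d}")
        cats.append(cat)
    meta = pd.DataFrame(
        {"category": cats, "interaction": False, "substrate": "", "role": ""},
        index=pd.Index(ids, name="trait_id"),
    )
    module_ids = [t for t, c in zip(ids, cats) if c == "kegg_module"]
    transporter_ids = [t for t, c in zip(ids, cats) if c == "transporter"]
    for vit, syn, trn in zip(VITAMINS, module_ids, transporter_ids):
        meta.loc[syn, ["substrate", "role"]] = [vit, "biosynthesis"]
        meta.loc[trn, ["substrate", "role"]] = [vit, "transport"]
        meta.loc[[syn, trn], "interaction"] = True
    last_block = spec.n_ltc_blocks - 1
    for j, t in enumerate(ids):
        if j % spec.n_ltc_blocks == last_block:
            meta.loc[t, "interaction"] = True
    return ids, meta


def gen_trait_matrix(spec: SyntheticSpec) -> tuple[TraitMatrix, PlantedTruth]:
    """Generate the planted binary trait matrix and its truth.

    Genomes are assigned round-robin to genome blocks and traits to
    linkage blocks; presence is Bernoulli(``block_trait_occupancy``) when
    the genome's block carries the trait's linkage block, else
    Bernoulli(``background_occupancy``).
    """
    rng = np.random.default_rng(spec.seed)
    genomes = [f"G{i:04d}" for i in range(spec.n_genomes)]
    genome_block = {g: i % spec.n_gfc_blocks for i, g in enumerate(genomes)}
    trait_ids, meta = _trait_ids(spec)
    trait_block = {t: j % spec.n_ltc_blocks for j, t in enumerate(trait_ids)}

    gb = np.array([genome_block[g] for g in genomes])
    carrier_sets = [_carriers(trait_block[t], spec.n_gfc_blocks) for t in trait_ids]
    in_block = np.array(
        [[b in cs for cs in carrier_sets] for b in gb]
    )
    prob = np.where(in_block, spec.block_trait_occupancy, spec.background_occupancy)
    values = (rng.random(prob.shape) < prob).astype(np.int8)
    matrix = TraitMatrix(values, genomes, trait_ids, trait_meta=meta)

    vitamin_state: dict[str, dict[str, dict[str, bool]]] = {}
    frame = matrix.to_frame()
    for vit in VITAMINS:
        tagged = meta[meta["substrate"] == vit]
        syn_traits = list(tagged.index[tagged["role"] == "biosynthesis"])
        trn_traits = list(tagged.index[tagged["role"] == "transport"])
        for g in genomes:
            state = vitamin_state.setdefault(g, {})
            state[vit] = {
                "synthesis": bool(frame.loc[g, syn_traits].any()) if syn_traits else False,
                "transport": bool(frame.loc[g, trn_traits].any()) if trn_traits else False,
            }
    truth = PlantedTruth(
        genome_block=genome_block,
        trait_block=trait_block,
        vitamin_state=vitamin_state,
    )
    return matrix, truth


def make_module_definitions(
    trait_ids: Sequence[str],
    seed: int = 0,
    n_reactions_range: tuple[int, int] = (3, 8),
    complex_prob: float = 0.2,
) -> list[ModuleDefinition]:
    """Generate one module definition per module trait.

    Each module gets a random number of reactions in
    ``n_reactions_range``, each reaction two alternatives, each
    alternative one KO (or a two-KO complex with probability
    ``complex_prob``).  KO identifiers are globally unique across modules
    so an absent module can never be reconstructed from another module's
    annotations.
    """
    rng = np.random.default_rng(seed)
    defs = []
    ko_counter = 1
    lo, hi = n_reactions_range
    for t in trait_ids:
        module_id = t.split(":", 1)[1] if ":" in t else t
        n_reactions = int(rng.integers(lo, hi + 1))
        reactions = []
        for _ in range(n_reactions):
            alts = []
            for _ in range(2):
                size = 2 if rng.random() < complex_prob else 1
                alt = [f"K{ko_counter + k:05d}" for k in range(size)]
                ko_counter += size
                alts.append(alt)
            reactions.append(alts)
        defs.append(ModuleDefinition(module_id, reactions))
    if ko_counter > 99999:
        raise ValidationError("KO identifier space exhausted; fewer modules please")
    return defs


def gen_ko_tables(
    matrix: TraitMatrix,
    defs: Sequence[ModuleDefinition],
    dropout: float,
    seed: int = 0,
    truth: PlantedTruth | None = None,
) -> KOAnnotationTable:
    """Emit per-genome KO sets realizing the matrix's module traits.

    A genome carrying a module trait receives every KO of that module's
    definition, then each KO is independently deleted with probability
    ``dropout``.  Where deletion leaves a planted module unreconstructible
    (beyond the one-missing-reaction tolerance) the (genome, trait) pair is
    recorded in ``truth.annotation_gaps``.  Absent module traits emit no
    KOs, so they reconstruct as incomplete.
    """
    if not 0.0 <= dropout <= 1.0:
        raise ValidationError(f"dropout={dropout} not a probability")
    by_id = {d.module_id: d for d in defs}
    module_traits = [
        t for t in matrix.traits
        if matrix.trait_meta.loc[t, "category"] == "kegg_module"
    ]
    missing = [
        t for t in module_traits if t.split(":", 1)[1] not in by_id
    ]
    if missing:
        raise ValidationError(f"module traits without definition: {missing[:5]}")
    rng = np.random.default_rng(seed)
    frame = matrix.to_frame()
    table: dict[str, set[str]] = {}
    for g in matrix.genomes:
        kos: set[str] = set()
        present = [t for t in module_traits if frame.loc[g, t] == 1]
        for t in present:
            kos |= by_id[t.split(":", 1)[1]].all_kos()
        if dropout > 0 and kos:
            keep = rng.random(len(kos)) >= dropout
            ordered = sorted(kos)
            kos = {k for k, kp in zip(ordered, keep) if kp}
        if truth is not None and dropout > 0:
            for t in present:
                call = call_module(by_id[t.split(":", 1)[1]], kos, genome_id=g)
                if not call.complete:
                    truth.annotation_gaps.append([g, t])
        table[g] = kos
    return KOAnnotationTable(table)


_GENUS_FMT = "g_block{b}"


def gen_taxonomy(
    truth: PlantedTruth,
    concordance: float,
    seed: int = 0,
    genome_size_mean: float = 4.0e6,
    genome_size_sd: float = 6.0e5,
) -> list[GenomeRecord]:
    """Synthesize taxonomy (and assembly stats) for the planted genomes.

    The genus equals the planted-block genus with probability
    ``concordance``, otherwise a uniformly chosen other block's genus.
    Higher ranks group genera deterministically (two genera per family,
    two families per order, and so on).
    """
    if not truth.genome_block:
        raise ValidationError("truth has no genome-block assignment")
    if not 0.0 <= concordance <= 1.0:
        raise ValidationError(f"concordance={concordance} not a probability")
    rng = np.random.default_rng(seed)
    blocks = sorted(set(truth.genome_block.values()))
    records = []
    for g in sorted(truth.genome_block):
        b = truth.genome_block[g]
        if len(blocks) > 1 and rng.random() >= concordance:
            others = [x for x in blocks if x != b]
            b = int(others[rng.integers(len(others))])
        taxonomy = {
            "domain": "Bacteria",
            "phylum": f"p{b // 16}",
            "class": f"c{b // 8}",
            "order": f"o{b // 4}",
            "family": f"f{b // 2}",
            "genus": _GENUS_FMT.format(b=b),
        }
        size = int(max(1e6, rng.normal(genome_size_mean, genome_size_sd)))
        records.append(
            GenomeRecord(
                genome_id=g, taxonomy=taxonomy, habitat="marine_pelagic",
                genome_size=size, completeness=float(rng.uniform(95, 100)),
                contamination=float(rng.uniform(0, 5)),
            )
        )
    return records


def gen_env_tables(
    truth: PlantedTruth,
    n_otus: int = 100,
    specificity_noise: float = 0.0,
    effect_size: float = 0.0,
    seed: int = 0,
    n_pairs_per_group: int | None = None,
    max_hits: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate amplicon hit and OTU-pair synchrony tables.

    Each OTU belongs to a planted genome block; each of its hits points to
    a genome of that block with probability ``1 - specificity_noise``
    (otherwise a genome of another block), with percent identities in the
    high-identity range and bitscore-ranked rows.  Pair scores are standard
    Gaussian, with the same-block mean shifted by ``effect_size``;
    ``n_pairs_per_group`` caps the two groups at equal planted sizes.
    """
    if not truth.genome_block:
        raise ValidationError("truth has no genome-block assignment")
    if not 0.0 <= specificity_noise <= 1.0:
        raise ValidationError("specificity_noise must be a probability")
    rng = np.random.default_rng(seed)
    blocks: dict[int, list[str]] = {}
    for g, b in truth.genome_block.items():
        blocks.setdefault(b, []).append(g)
    block_ids = sorted(blocks)
    otus = [f"OTU{i:04d}" for i in range(n_otus)]
    truth.otu_block.update({o: i % len(block_ids) for i, o in enumerate(otus)})

    hit_rows = []
    for o in otus:
        own = block_ids[truth.otu_block[o]]
        n_hits = int(rng.integers(3, max_hits + 1))
        for rank in range(n_hits):
            if len(block_ids) > 1 and rng.random() < specificity_noise:
                other = [b for b in block_ids if b != own]
                b = int(other[rng.integers(len(other))])
            else:
                b = own
            members = blocks[b]
            genome = members[int(rng.integers(len(members)))]
            hit_rows.append(
                {
                    "otu_id": o,
                    "genome_id": genome,
                    "percent_identity": float(rng.uniform(97.5, 100.0)),
                    "bitscore": float(500 - rank),
                }
            )
    hits = pd.DataFrame(hit_rows)

    pair_rows = []
    same_pairs, diff_pairs = [], []
    for i in range(n_otus):
        for j in range(i + 1, n_otus):
            (same_pairs if truth.otu_block[otus[i]] == truth.otu_block[otus[j]]
             else diff_pairs).append((otus[i], otus[j]))
    rng.shuffle(same_pairs)
    rng.shuffle(diff_pairs)
    if n_pairs_per_group is not None:
        if len(same_pairs) < n_pairs_per_group or len(diff_pairs) < n_pairs_per_group:
            raise ValidationError(
                f"not enough OTU pairs for {n_pairs_per_group} per group"
            )
        same_pairs = same_pairs[:n_pairs_per_group]
        diff_pairs = diff_pairs[:n_pairs_per_group]
    for a, b in same_pairs:
        pair_rows.append(
            {"otu_a": a, "otu_b": b, "score": float(rng.normal(effect_size, 1.0)),
             "group": "same_gfc"}
        )
    for a, b in diff_pairs:
        pair_rows.append(
            {"otu_a": a, "otu_b": b, "score": float(rng.normal(0.0, 1.0)),
             "group": "different_gfc"}
        )
    truth.synchrony_effect = float(effect_size)
    return hits, pd.DataFrame(pair_rows)


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    truth: PlantedTruth
    genomes: list[GenomeRecord]
    matrix: TraitMatrix  # planted (pre-dropout) matrix
    module_defs: list[ModuleDefinition]
    ko_table: KOAnnotationTable
    call_tables: dict[str, pd.DataFrame]
    interaction_traits: list[str]


def gen_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate the full input bundle the pipeline consumes.

    Module traits travel through generated KO annotations (with dropout);
    the other categories travel as curated trait-call tables taken directly
    from the planted matrix.
    """
    matrix, truth = gen_trait_matrix(spec)
    module_traits = [
        t for t in matrix.traits
        if matrix.trait_meta.loc[t, "category"] == "kegg_module"
    ]
    defs = make_module_definitions(module_traits, seed=spec.seed + 1)
    ko_table = gen_ko_tables(
        matrix, defs, spec.annotation_dropout, seed=spec.seed + 2, truth=truth
    )
    genomes = gen_taxonomy(truth, spec.taxon_concordance, seed=spec.seed + 3)
    frame = matrix.to_frame()
    call_tables = {}
    for cat in _CALL_CATEGORIES:
        cols = [
            t for t in matrix.traits
            if matrix.trait_meta.loc[t, "category"] == cat
        ]
        if cols:
            call_tables[cat] = frame[cols].astype(np.int8)
    return SyntheticDataset(
        spec=spec,
        truth=truth,
        genomes=genomes,
        matrix=matrix,
        module_defs=defs,
        ko_table=ko_table,
        call_tables=call_tables,
        interaction_traits=matrix.interaction_traits(),
    )


def write_dataset(data: SyntheticDataset, out_dir: str | Path) -> None:
    """Write the bundle in the TSV/JSON formats the pipeline reads."""
    from . import io  # local import to avoid a cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_genomes(data.genomes, out / "genomes.tsv")
    io.write_ko_table(data.ko_table, out / "ko_annotations.tsv")
    io.write_module_definitions(data.module_defs, out / "module_definitions.json")
    for cat, table in data.call_tables.items():
        io.write_trait_calls(table, out / f"trait_calls_{cat}.tsv")
    io.write_trait_meta(data.matrix.trait_meta, out / "trait_meta.tsv")
    (out / "interaction_traits.txt").write_text(
        "\n".join(data.interaction_traits) + "\n"
    )
    data.truth.to_json(out / "truth.json")
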