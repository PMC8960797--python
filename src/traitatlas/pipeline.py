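"""End-to-end orchestration: inputs -> trait matrix -> similarities ->
GFC/LTC clustering -> interpretation -> optional environmental stage.

Every threshold comes from one :class:`PipelineConfig`; a bare run uses
the default analysis settings.  All outputs are TSV/JSON under the output
directory, traced by a run manifest (config snapshot, input digests, stage
timings, warnings).  Deterministic stages are bit-reproducible for a given
config and seed; ``summary.json`` carries no timestamps for that reason.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import envmap, io, modules
from .apcluster import APParams, affinity_propagation, set_preference
from .config import PipelineConfig
from .datatypes import ClusteringResult, TraitMatrix, ValidationError
from .interpret import (
    classify_coherence,
    enrichment_test,
    ltc_presence,
    sensitivity_analysis,
    size_expectation,
)
from .linkage import build_similarity
from .profiles import (
    classify_vitamins,
    count_interaction_traits,
    enumerate_configurations,
    prevalence_filter,
)

__all__ = ["RunManifest", "run_all", "report", "cluster_similarity"]


@dataclass
class RunManifest:
    config: dict
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.__dict__, indent=1, sort_keys=True, default=str)
        )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def cluster_similarity(sim, cfg: PipelineConfig, q: float | None = None) -> ClusteringResult:
    """Quantile preference + affinity propagation on a SimilarityMatrix."""
    q = cfg.q_preference if q is None else q
    pref = set_preference(sim.values, q)
    return affinity_propagation(
        pref,
        APParams(
            q_preference=q, damping=cfg.ap_damping, maxit=cfg.ap_maxit,
            convits=cfg.ap_convits, jitter_scale=cfg.ap_jitter_scale,
            seed=cfg.seed,
        ),
        ids=sim.ids,
    )


def _write_clusters(result: ClusteringResult, path: Path) -> None:
    rows = [
        {"item_id": item, "cluster_id": cid, "exemplar_id": result.exemplars[cid]}
        for item, cid in sorted(result.labels.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def run_all(
    config: PipelineConfig | str | Path,
    input_dir: str | Path,
    out_dir: str | Path,
    run_sensitivity: bool = False,
) -> RunManifest:
    """Execute the full pipeline on a directory of input tables.

    Expects in ``input_dir``: ``genomes.tsv``; ``ko_annotations.tsv`` plus
    ``module_definitions.json`` (module stage) and/or
    ``trait_calls_<category>.tsv`` tables; optional ``trait_meta.tsv``
    (substrate/role tags), ``interaction_traits.txt`` (one id per line),
    and for the environmental stage ``hits.tsv`` + ``pair_scores.tsv``
    (+ ``otu_abundances.tsv``).  Writes all result tables, the atlas
    matrix, ``summary.json`` and ``manifest.json`` to ``out_dir``.
    """
    cfg = config if isinstance(config, PipelineConfig) else io.read_config(config)
    inp = Path(input_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg.to_dict(), seed=cfg.seed)
    for f in sorted(inp.glob("*")):
        if f.is_file():
            manifest.input_digests[f.name] = _digest(f)

    summary: dict = {"config": cfg.to_dict()}
    t0 = time.perf_counter()
    stage = "read_inputs"
    caught: list[warnings.WarningMessage] = []
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")

            genomes = (
                io.read_genomes(inp / "genomes.tsv")
                if (inp / "genomes.tsv").exists() else []
            )
            genome_sizes = {g.genome_id: g.genome_size for g in genomes}
            taxonomy = {
                g.genome_id: g.taxon_at(cfg.coherence_rank) or "" for g in genomes
            }
            trait_meta = (
                io.read_trait_meta(inp / "trait_meta.tsv")
                if (inp / "trait_meta.tsv").exists() else None
            )
            interaction_traits: list[str] = []
            if (inp / "interaction_traits.txt").exists():
                interaction_traits = [
                    line.strip()
                    for line in (inp / "interaction_traits.txt").read_text().splitlines()
                    if line.strip()
                ]
            call_tables = {
                p.stem.replace("trait_calls_", ""): io.read_trait_calls(
                    p, p.stem.replace("trait_calls_", "")
                )
                for p in sorted(inp.glob("trait_calls_*.tsv"))
            }
            manifest.stage_seconds[stage] = time.perf_counter() - t0

            stage = "module_reconstruction"
            t0 = time.perf_counter()
            module_mat = None
            if (inp / "ko_annotations.tsv").exists() and (
                inp / "module_definitions.json"
            ).exists():
                ko = io.read_ko_table(inp / "ko_annotations.tsv")
                defs = io.read_module_definitions(inp / "module_definitions.json")
                calls = modules.call_all(defs, ko, strict=cfg.strict_modules)
                modules.calls_table(calls).to_csv(
                    out / "module_calls.tsv", sep="\t", index=False
                )
                module_mat = modules.module_matrix(calls)
                module_mat.reset_index().to_csv(
                    out / "module_matrix.tsv", sep="\t", index=False
                )
            manifest.stage_seconds[stage] = time.perf_counter() - t0

            stage = "assemble_matrix"
            t0 = time.perf_counter()
            matrix = io.assemble_trait_matrix(
                module_mat, call_tables, interaction_traits, trait_meta,
                genomes=[g.genome_id for g in genomes] or None,
            )
            io.write_trait_matrix(matrix, out / "trait_matrix.tsv")
            manifest.stage_seconds[stage] = time.perf_counter() - t0

            stage = "gfc_clustering"
            t0 = time.perf_counter()
            genome_sim = build_similarity(matrix, kind="genome")
            genome_sim.to_frame().to_csv(out / "similarity_genomes.tsv", sep="\t")
            gfc = cluster_similarity(genome_sim, cfg)
            _write_clusters(gfc, out / "clusters_gfc.tsv")
            manifest.stage_seconds[stage] = time.perf_counter() - t0

            stage = "ltc_clustering"
            t0 = time.perf_counter()
            filtered, removed = prevalence_filter(
                matrix, cfg.prevalence_min, cfg.prevalence_min_count
            )
            trait_sim = build_similarity(filtered, kind="trait", alpha=cfg.fdr_alpha)
            trait_sim.to_frame().to_csv(out / "similarity_traits.tsv", sep="\t")
            if trait_sim.pairs is not None:
                trait_sim.pairs.to_csv(out / "trait_pairs.tsv", sep="\t", index=False)
            ltc = cluster_similarity(trait_sim, cfg)
            _write_clusters(ltc, out / "clusters_ltc.tsv")
            manifest.stage_seconds[stage] = time.perf_counter() - t0

            stage = "interpretation"
            t0 = time.perf_counter()
            coherence = None
            if any(taxonomy.values()):
                coherence = classify_coherence(gfc, taxonomy, cfg.coherence_rank)
                coherence.to_csv(out / "coherence.tsv", sep="\t", index=False)
            filt_index = [matrix.traits.index(t) for t in trait_sim.ids]
            raw_phi = None
            if trait_sim.raw is not None:
                raw_phi_full = np.full((len(matrix.traits),) * 2, np.nan)
                raw_phi_full[np.ix_(filt_index, filt_index)] = trait_sim.raw
                raw_phi = raw_phi_full
            ltc_summary, ltc_by_genome, ltc_by_gfc = ltc_presence(
                matrix, ltc, gfc, cfg, raw_trait_phi=raw_phi
            )
            ltc_summary.to_csv(out / "ltc_summary.tsv", sep="\t", index=False)
            ltc_by_genome.rename_axis("genome_id").reset_index().to_csv(
                out / "ltc_by_genome.tsv", sep="\t", index=False
            )
            ltc_by_gfc.reset_index().to_csv(
                out / "ltc_by_gfc.tsv", sep="\t", index=False
            )

            vitamins = None
            configurations = None
            if (matrix.trait_meta["substrate"].isin(["B1", "B7", "B12"])).any():
                vitamins = classify_vitamins(matrix)
                vitamins.rename_axis("genome_id").reset_index().to_csv(
                    out / "vitamin_profiles.tsv", sep="\t", index=False
                )
                configurations = enumerate_configurations(vitamins)
                configurations.to_csv(out / "configurations.tsv", sep="\t", index=False)

            profiles = count_interaction_traits(matrix, genome_sizes)
            pd.DataFrame(
                [
                    {"genome_id": p.genome_id,
                     "n_interaction_traits": p.n_interaction_traits,
                     "genome_size": p.genome_size}
                    for p in profiles
                ]
            ).to_csv(out / "interaction_counts.tsv", sep="\t", index=False)

            enrichment = enrichment_test(
                matrix, gfc, n_permutations=cfg.n_permutations, seed=cfg.seed
            )
            enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)

            size_resid = None
            if sum(p.genome_size > 0 for p in profiles) >= 3:
                per_genome, per_taxon = size_expectation(
                    profiles, taxonomy,
                    n_permutations=cfg.n_permutations, seed=cfg.seed,
                )
                per_genome.to_csv(out / "size_residuals.tsv", sep="\t", index=False)
                per_taxon.to_csv(
                    out / "size_residuals_by_taxon.tsv", sep="\t", index=False
                )
                size_resid = per_genome
            manifest.stage_seconds[stage] = time.perf_counter() - t0

            if run_sensitivity:
                stage = "sensitivity"
                t0 = time.perf_counter()
                sens = sensitivity_analysis(matrix, taxonomy, cfg)
                (out / "sensitivity.json").write_text(
                    json.dumps(sens, indent=1, sort_keys=True)
                )
                manifest.stage_seconds[stage] = time.perf_counter() - t0

            env_report = None
            if (inp / "hits.tsv").exists() and (inp / "pair_scores.tsv").exists():
                stage = "environmental"
                t0 = time.perf_counter()
                hits = envmap.read_hits(inp / "hits.tsv")
                pairs_raw = envmap.read_pair_scores(inp / "pair_scores.tsv")
                threshold = (
                    cfg.identity_thresholds[1]
                    if len(cfg.identity_thresholds) > 1
                    else cfg.identity_thresholds[0]
                )
                mapping = envmap.map_otus(
                    hits, gfc.labels, threshold, max_hits=cfg.max_hits
                )
                mapping.to_csv(out / "otu_mapping.tsv", sep="\t", index=False)
                grouped = envmap.assign_pair_groups(pairs_raw, mapping)
                if (
                    grouped.empty
                    or grouped["group"].nunique() < 2
                ) and "group" in pairs_raw.columns:
                    grouped = pairs_raw
                env_report = envmap.synchrony_test(
                    grouped, n_randomizations=cfg.n_permutations, seed=cfg.seed
                )
                if (inp / "otu_abundances.tsv").exists():
                    ab = pd.read_csv(
                        inp / "otu_abundances.tsv", sep="\t", index_col=0
                    )
                    frac = envmap.community_fraction(ab, mapping)
                    frac.rename_axis("sample").reset_index().to_csv(
                        out / "community_fraction.tsv", sep="\t", index=False
                    )
                    env_report["community_fraction_mean"] = frac.attrs["mean_fraction"]
                    env_report["community_fraction_range"] = list(frac.attrs["range"])
                (out / "synchrony_report.json").write_text(
                    json.dumps(env_report, indent=1, sort_keys=True)
                )
                manifest.stage_seconds[stage] = time.perf_counter() - t0

            # atlas matrix: genomes ordered by GFC, traits by LTC
            stage = "atlas"
            t0 = time.perf_counter()
            g_order = sorted(matrix.genomes, key=lambda g: (gfc.labels[g], g))
            clustered_traits = [t for t in matrix.traits if t in ltc.labels]
            t_order = sorted(clustered_traits, key=lambda t: (ltc.labels[t], t))
            atlas = matrix.to_frame().loc[g_order, t_order]
            atlas.insert(0, "gfc_id", [gfc.labels[g] for g in g_order])
            atlas.rename_axis("genome_id").reset_index().to_csv(
                out / "atlas.tsv", sep="\t", index=False
            )
            pd.DataFrame(
                {"trait_id": t_order, "ltc_id": [ltc.labels[t] for t in t_order]}
            ).to_csv(out / "atlas_traits.tsv", sep="\t", index=False)
            manifest.stage_seconds[stage] = time.perf_counter() - t0

    except ValidationError as exc:
        raise ValidationError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        manifest.warnings = [str(w.message) for w in caught]

    summary.update(
        {
            "n_genomes": len(matrix.genomes),
            "n_traits": len(matrix.traits),
            "n_traits_clustered": len(trait_sim.ids),
            "n_traits_removed_by_prevalence": len(removed),
            "n_gfcs": gfc.n_clusters,
            "n_ltcs": ltc.n_clusters,
            "gfc_converged": bool(gfc.converged),
            "ltc_converged": bool(ltc.converged),
            "coherence_counts": (
                coherence["label"].value_counts().to_dict() if coherence is not None else {}
            ),
            "ltc_category_counts": ltc_summary["category"].value_counts().to_dict(),
            "n_unclustered_ltc_traits": int(
                ltc_summary.loc[ltc_summary["unclustered"], "n_traits"].sum()
            ),
            "mean_r_all_trait_pairs": ltc_summary.attrs.get("mean_r_all_pairs"),
            "vitamin_strategy_counts": (
                {
                    v: vitamins[f"{v}_strategy"].value_counts().to_dict()
                    for v in ("B1", "B7", "B12")
                }
                if vitamins is not None else {}
            ),
            "n_vitamin_configurations_observed": (
                configurations.attrs["n_observed"] if configurations is not None else None
            ),
            "n_enriched_gfcs": int((enrichment["p_adj"] < cfg.fdr_alpha).sum()),
            "size_regression_slope": (
                size_resid.attrs["slope"] if size_resid is not None else None
            ),
            "environment": env_report,
        }
    )
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    manifest.outputs = sorted(
        {p.name for p in out.glob("*") if p.is_file()} | {"manifest.json"}
    )
    manifest.to_json(out / "manifest.json")
    return manifest


def report(out_dir: str | Path) -> str:
    """Human-readable markdown summary sourced only from the result tables."""
    out = Path(out_dir)
    summary_path = out / "summary.json"
    if not summary_path.exists():
        raise ValidationError(f"missing table: {summary_path}")
    s = json.loads(summary_path.read_text())
    lines = [
        "# Trait atlas run summary",
        "",
        f"- genomes: {s['n_genomes']}",
        f"- traits: {s['n_traits']} ({s['n_traits_clustered']} clustered after the "
        f"prevalence filter, {s['n_traits_removed_by_prevalence']} removed)",
        f"- genome functional clusters (GFCs): {s['n_gfcs']}",
        f"- linked trait clusters (LTCs): {s['n_ltcs']}",
    ]
    if s.get("coherence_counts"):
        parts = ", ".join(f"{k}: {v}" for k, v in sorted(s["coherence_counts"].items()))
        lines.append(f"- GFC taxonomic coherence — {parts}")
    if s.get("ltc_category_counts"):
        parts = ", ".join(
            f"{k}: {v}" for k, v in sorted(s["ltc_category_counts"].items())
        )
        lines.append(f"- LTC categories — {parts}")
    if s.get("vitamin_strategy_counts"):
        lines.append("")
        lines.append("## B-vitamin strategies (genomes per strategy)")
        for vit, counts in s["vitamin_strategy_counts"].items():
            parts = ", ".join(f"{k}: {v}" for k, v in sorted(counts.items()))
            lines.append(f"- {vit}: {parts}")
        lines.append(
            f"- configurations observed: {s['n_vitamin_configurations_observed']} of 64"
        )
    lines.append(f"- GFCs enriched in interaction traits: {s['n_enriched_gfcs']}")
    if s.get("environment"):
        env = s["environment"]
        lines.extend(
            [
                "",
                "## Environmental mapping",
                f"- same-GFC pairs: {env['n_same_gfc']}, "
                f"different-GFC pairs: {env['n_different_gfc']}",
                f"- one-sided Welch p: {env['welch_p_one_sided']:.3g}",
            ]
        )
    return "\n".join(lines) + "\n"
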