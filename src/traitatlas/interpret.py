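"""Interpretation of genome and trait clusterings.

Turns raw exemplar clusterings into the atlas semantics:

* taxonomic coherence of genome functional clusters (GFCs) — a GFC is
  *monophyletic* when all grouped genomes belong to one taxon and all
  genomes of that taxon are grouped there; *paraphyletic* when it holds a
  proper subset of one taxon; *polyphyletic* when it mixes taxa;
* linked trait cluster (LTC) presence — an LTC is present in a genome when
  more than half of its traits are present, and present in a GFC when
  present in more than half of the grouped genomes; LTCs are categorized
  as core (> 90% of genomes), common or ancillary (<= 30%), and traits
  whose LTC is present in no GFC are flagged unclustered;
* permutation enrichment of interaction traits per GFC;
* the genome-size expectation for interaction-trait counts (least-squares
  line, residuals, per-taxon permutation test);
* sensitivity of the clustering to the preference quantile q and to
  down-sampling of overrepresented taxa.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .apcluster import APParams, affinity_propagation, set_preference
from .config import PipelineConfig
from .datatypes import ClusteringResult, TraitMatrix, ValidationError
from .linkage import bh_adjust, build_similarity, phi_matrix
from .profiles import InteractionProfile

__all__ = [
    "classify_coherence",
    "ltc_presence",
    "enrichment_test",
    "size_expectation",
    "sensitivity_analysis",
]


def _labels_of(assignment) -> dict[str, int]:
    if isinstance(assignment, ClusteringResult):
        return dict(assignment.labels)
    return dict(assignment)


# ---------------------------------------------------------------------------
# coherence
# ---------------------------------------------------------------------------

def classify_coherence(
    gfc_assignment,
    taxonomy: Mapping[str, str],
    rank: str = "genus",
) -> pd.DataFrame:
    """Label each GFC monophyletic / paraphyletic / polyphyletic at ``rank``.

    ``taxonomy`` maps genome_id to its taxon name at the evaluated rank;
    genomes without a label are excluded with a warning.
    """
    labels = _labels_of(gfc_assignment)
    missing = [g for g in labels if not taxonomy.get(g)]
    if missing:
        warnings.warn(
            f"{len(missing)} genome(s) lack a taxon at rank {rank!r} "
            "and are excluded from coherence labelling",
            UserWarning,
        )
    labels = {g: c for g, c in labels.items() if taxonomy.get(g)}
    taxon_members: dict[str, set[str]] = {}
    for g in labels:
        taxon_members.setdefault(taxonomy[g], set()).add(g)

    rows = []
    for gfc in sorted(set(labels.values())):
        members = {g for g, c in labels.items() if c == gfc}
        taxa = {taxonomy[g] for g in members}
        if len(taxa) > 1:
            label = "polyphyletic"
            split = sorted(
                t for t in taxa if not taxon_members[t] <= members
            )
        else:
            (taxon,) = taxa
            if taxon_members[taxon] <= members:
                label = "monophyletic"
                split = []
            else:
                label = "paraphyletic"
                split = [taxon]
        rows.append(
            {
                "gfc_id": gfc,
                "rank_evaluated": rank,
                "label": label,
                "n_genomes": len(members),
                "taxa_contained": ";".join(sorted(taxa)),
                "taxa_split_elsewhere": ";".join(split),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# LTC presence and categories
# ---------------------------------------------------------------------------

def ltc_presence(
    matrix: TraitMatrix,
    ltc_assignment,
    gfc_assignment,
    cfg: PipelineConfig | None = None,
    raw_trait_phi: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """LTC summaries plus LTC x genome and LTC x GFC boolean tables.

    Presence uses strict > rules: an LTC is present in a genome when more
    than ``ltc_genome_frac`` of its traits are carried, and in a GFC when
    present in more than ``ltc_gfc_frac`` of the grouped genomes.  Category
    cuts on the genome-presence fraction: core above ``core_frac``,
    ancillary at or below ``ancillary_frac``, common between.  The mean
    within-LTC phi is computed on raw (pre-thresholding) correlations.
    """
    cfg = cfg or PipelineConfig()
    trait_ltc = _labels_of(ltc_assignment)
    genome_gfc = _labels_of(gfc_assignment)
    if not trait_ltc:
        raise ValidationError("LTC assignment has no traits")
    frame = matrix.to_frame()

    if raw_trait_phi is None:
        raw_trait_phi = phi_matrix(matrix.values)
    trait_index = {t: i for i, t in enumerate(matrix.traits)}

    ltc_ids = sorted(set(trait_ltc.values()))
    gfc_ids = sorted(set(genome_gfc.values()))
    by_genome = pd.DataFrame(False, index=frame.index, columns=ltc_ids)
    for ltc in ltc_ids:
        traits = [t for t, c in trait_ltc.items() if c == ltc]
        if not traits:
            raise ValidationError(f"LTC {ltc} has no traits")
        frac = frame[traits].mean(axis=1)
        by_genome[ltc] = frac > cfg.ltc_genome_frac

    by_gfc = pd.DataFrame(False, index=pd.Index(gfc_ids, name="gfc_id"), columns=ltc_ids)
    for gfc in gfc_ids:
        members = [g for g, c in genome_gfc.items() if c == gfc]
        sub = by_genome.loc[members]
        by_gfc.loc[gfc] = sub.mean(axis=0) > cfg.ltc_gfc_frac

    all_pairs_mean = _offdiag_mean(raw_trait_phi)
    rows = []
    for ltc in ltc_ids:
        traits = sorted(t for t, c in trait_ltc.items() if c == ltc)
        idx = [trait_index[t] for t in traits if t in trait_index]
        if len(idx) >= 2:
            sub = raw_trait_phi[np.ix_(idx, idx)]
            mean_r = _offdiag_mean(sub)
        else:
            mean_r = float("nan")
        presence = float(by_genome[ltc].mean())
        if presence > cfg.core_frac:
            category = "core"
        elif presence <= cfg.ancillary_frac:
            category = "ancillary"
        else:
            category = "common"
        present_gfcs = [g for g in gfc_ids if bool(by_gfc.loc[g, ltc])]
        rows.append(
            {
                "ltc_id": ltc,
                "n_traits": len(traits),
                "traits": ";".join(traits),
                "mean_within_r": mean_r,
                "genome_presence": presence,
                "category": category,
                "gfc_presence": ";".join(str(g) for g in present_gfcs),
                "unclustered": len(present_gfcs) == 0,
            }
        )
    summary = pd.DataFrame(rows)
    summary.attrs["mean_r_all_pairs"] = all_pairs_mean
    return summary, by_genome, by_gfc


def _offdiag_mean(m: np.ndarray) -> float:
    mask = ~np.eye(m.shape[0], dtype=bool)
    vals = m[mask]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else float("nan")


# ---------------------------------------------------------------------------
# interaction-trait enrichment
# ---------------------------------------------------------------------------

def enrichment_test(
    matrix: TraitMatrix,
    gfc_assignment,
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation enrichment of interaction-trait load per GFC.

    Null: genome labels shuffled across GFCs keeping GFC sizes; statistic:
    mean interaction-trait count of the GFC's genomes.  Empirical p uses
    the +1 correction, then BH across GFCs.  Size-1 GFCs are flagged
    low-power.
    """
    if n_permutations < 100:
        raise ValidationError("n_permutations must be >= 100")
    labels = _labels_of(gfc_assignment)
    genomes = [g for g in matrix.genomes if g in labels]
    flagged = matrix.trait_meta.index[matrix.trait_meta["interaction"]]
    idx = [matrix.traits.index(t) for t in flagged]
    row_index = {g: i for i, g in enumerate(matrix.genomes)}
    counts = (
        matrix.values[:, idx].sum(axis=1)
        if idx else np.zeros(len(matrix.genomes))
    )
    counts = np.array([counts[row_index[g]] for g in genomes], dtype=float)
    gfc_of = np.array([labels[g] for g in genomes])
    gfc_ids = np.array(sorted(set(gfc_of)))

    obs = np.array([counts[gfc_of == g].mean() for g in gfc_ids])
    sizes = np.array([(gfc_of == g).sum() for g in gfc_ids])

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(gfc_ids))
    for _ in range(n_permutations):
        perm = rng.permutation(counts)
        null = np.array([perm[gfc_of == g].mean() for g in gfc_ids])
        exceed += null >= obs
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return pd.DataFrame(
        {
            "gfc_id": gfc_ids,
            "n_genomes": sizes,
            "mean_interaction_traits": obs,
            "p": p,
            "p_adj": bh_adjust(p),
            "low_power": sizes == 1,
        }
    )


# ---------------------------------------------------------------------------
# genome-size expectation
# ---------------------------------------------------------------------------

def size_expectation(
    profiles: Sequence[InteractionProfile],
    taxonomy: Mapping[str, str],
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Regression of interaction-trait count on genome size.

    Returns ``(per_genome, per_taxon)``: per-genome residuals from the
    least-squares line, and per-taxon mean residuals with a two-sided
    permutation p (residuals shuffled across genomes).  Positive mean
    residuals mark taxa carrying more interaction traits than their genome
    size predicts.
    """
    usable = [p for p in profiles if p.genome_size > 0]
    if len(usable) < 3:
        raise ValidationError("need >= 3 genomes with genome_size to regress")
    sizes = np.array([p.genome_size for p in usable], dtype=float)
    counts = np.array([p.n_interaction_traits for p in usable], dtype=float)
    if sizes.std() == 0:
        raise ValidationError("zero genome-size variance: line undefined")
    fit = stats.linregress(sizes, counts)
    resid = counts - (fit.intercept + fit.slope * sizes)
    per_genome = pd.DataFrame(
        {
            "genome_id": [p.genome_id for p in usable],
            "genome_size": sizes,
            "n_interaction_traits": counts,
            "residual": resid,
            "taxon": [taxonomy.get(p.genome_id, "") for p in usable],
        }
    )
    per_genome.attrs["slope"] = float(fit.slope)
    per_genome.attrs["intercept"] = float(fit.intercept)
    per_genome.attrs["stderr"] = float(fit.stderr)

    taxa = sorted({t for t in per_genome["taxon"] if t})
    obs = np.array(
        [per_genome.loc[per_genome["taxon"] == t, "residual"].mean() for t in taxa]
    )
    n_members = np.array([(per_genome["taxon"] == t).sum() for t in taxa])
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(taxa))
    tax_arr = per_genome["taxon"].to_numpy()
    for _ in range(n_permutations):
        perm = rng.permutation(resid)
        null = np.array([perm[tax_arr == t].mean() for t in taxa])
        exceed += np.abs(null) >= np.abs(obs)
    p = (1.0 + exceed) / (1.0 + n_permutations)
    per_taxon = pd.DataFrame(
        {
            "taxon": taxa,
            "n_genomes": n_members,
            "mean_residual": obs,
            "p": p,
            "p_adj": bh_adjust(p) if len(taxa) else p,
        }
    )
    return per_genome, per_taxon


# ---------------------------------------------------------------------------
# sensitivity analysis
# ---------------------------------------------------------------------------

def sensitivity_analysis(
    matrix: TraitMatrix,
    taxonomy: Mapping[str, str],
    cfg: PipelineConfig | None = None,
    q_grid: Sequence[float] = (0.1, 0.3, 0.5, 0.7, 0.9),
) -> dict:
    """Stability of the genome clustering.

    * q sweep: GFC clustering re-run for each preference quantile in
      ``q_grid``; reports the cluster count per q.
    * taxon down-sampling: taxa holding more than
      ``cfg.overrepresented_frac`` of the genomes are sub-sampled without
      replacement to each fraction in ``cfg.downsample_fracs``; clustering
      of the reduced dataset is compared to the full-data clustering
      restricted to the retained genomes (adjusted Rand index).
    """
    cfg = cfg or PipelineConfig()
    sim = build_similarity(matrix, kind="genome")

    def _run(values: np.ndarray, ids: Sequence[str], q: float) -> ClusteringResult:
        return affinity_propagation(
            set_preference(values, q),
            APParams(q_preference=q, damping=cfg.ap_damping, maxit=cfg.ap_maxit,
                     convits=cfg.ap_convits, jitter_scale=cfg.ap_jitter_scale,
                     seed=cfg.seed),
            ids=ids,
        )

    q_sweep = []
    full_res = None
    for q in q_grid:
        res = _run(sim.values, sim.ids, q)
        q_sweep.append({"q": float(q), "n_clusters": res.n_clusters,
                        "converged": bool(res.converged)})
        if abs(q - cfg.q_preference) < 1e-12:
            full_res = res

    if full_res is None:
        full_res = _run(sim.values, sim.ids, cfg.q_preference)
    full_labels = dict(full_res.labels)

    counts = pd.Series({g: taxonomy.get(g, "") for g in sim.ids}).value_counts()
    threshold = cfg.overrepresented_frac * len(sim.ids)
    overrep = {t for t, c in counts.items() if t and c > threshold}

    rng = np.random.default_rng(cfg.seed)
    downsampling = []
    for frac in cfg.downsample_fracs:
        if overrep:
            keep = []
            for taxon in sorted({taxonomy.get(g, "") for g in sim.ids}):
                members = [g for g in sim.ids if taxonomy.get(g, "") == taxon]
                if taxon in overrep:
                    k = max(1, int(np.ceil(frac * len(members))))
                    members = sorted(rng.choice(members, size=k, replace=False))
                keep.extend(members)
        else:
            keep = list(sim.ids)
        if len(keep) < 2:
            warnings.warn(
                f"down-sampling at {frac} leaves <2 genomes; replicate skipped",
                UserWarning,
            )
            continue
        pos = [sim.ids.index(g) for g in keep]
        sub = sim.values[np.ix_(pos, pos)]
        res = _run(sub, keep, cfg.q_preference)
        sub_labels = [res.labels[g] for g in keep]
        ref_labels = [full_labels[g] for g in keep]
        downsampling.append(
            {
                "fraction": float(frac),
                "n_genomes": len(keep),
                "n_clusters": res.n_clusters,
                "ari_vs_full": float(adjusted_rand_score(ref_labels, sub_labels)),
            }
        )
    return {
        "q_sweep": q_sweep,
        "downsampling": downsampling,
        "overrepresented_taxa": sorted(overrep),
        "n_genomes": len(sim.ids),
    }
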