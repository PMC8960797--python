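"""Mapping amplicon OTUs to genome functional clusters and testing
within-GFC temporal synchrony.

OTUs are mapped via tabular alignment hits (BLAST outfmt-6 dialect) of
their 16S sequence against the reference genomes' 16S genes.  For a given
percent-identity threshold, the retained top hits (capped, default 20)
define a *specificity index*: the fraction of hits falling in the modal
GFC.  An OTU is assigned to a GFC only when the index equals 1, i.e. every
retained hit agrees; anything else stays unmapped to avoid spurious
assignments.

The synchrony test asks whether OTU pairs mapped to the same GFC have
higher pairwise temporal synchrony ("frequency interaction score",
computed upstream) than pairs mapped to different GFCs: Shapiro normality
check per group, one-sided Welch t-test (primary) with a Mann-Whitney
rank test alongside, and two randomization controls that re-assign pairs
to groups (keeping the observed group sizes / using two equal halves).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ValidationError

__all__ = [
    "read_hits",
    "read_pair_scores",
    "map_otus",
    "community_fraction",
    "synchrony_test",
]

#: column names of the 12-column tabular alignment format (outfmt 6)
OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hits(path: str | Path) -> pd.DataFrame:
    """Read an alignment hit table.

    Accepts either a headered TSV with at least (otu_id, genome_id,
    percent_identity[, bitscore]) columns or a headerless 12-column
    outfmt-6 file (qseqid -> otu_id, sseqid -> genome_id, pident ->
    percent_identity).
    """
    path = Path(path)
    first = path.open().readline()
    if "otu_id" in first or "qseqid" in first:
        df = pd.read_csv(path, sep="\t")
        df = df.rename(
            columns={"qseqid": "otu_id", "sseqid": "genome_id",
                     "pident": "percent_identity"}
        )
    else:
        df = pd.read_csv(path, sep="\t", header=None, names=OUTFMT6_COLUMNS)
        df = df.rename(
            columns={"qseqid": "otu_id", "sseqid": "genome_id",
                     "pident": "percent_identity"}
        )
    need = {"otu_id", "genome_id", "percent_identity"}
    if not need <= set(df.columns):
        raise ValidationError(f"{path}: missing columns {need - set(df.columns)}")
    df["percent_identity"] = df["percent_identity"].astype(float)
    if ((df["percent_identity"] < 0) | (df["percent_identity"] > 100)).any():
        raise ValidationError(f"{path}: percent_identity outside [0, 100]")
    return df


def read_pair_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"otu_a", "otu_b", "score"}
    if not need <= set(df.columns):
        raise ValidationError(f"{path}: missing columns {need - set(df.columns)}")
    return df


def map_otus(
    hits: pd.DataFrame,
    gfc_assignment: Mapping[str, int],
    threshold: float,
    max_hits: int = 20,
) -> pd.DataFrame:
    """Map each OTU to a GFC at one identity threshold.

    Hits are filtered to ``percent_identity >= threshold``, ordered by
    bitscore (descending, when present) and capped at ``max_hits``; hits to
    genomes without a GFC assignment are ignored.  The specificity index is
    the fraction of retained hits in the modal GFC; the OTU is mapped to
    that GFC only when the index equals 1.  OTUs with no retained hits get
    a null index and stay unmapped.
    """
    if not 0.0 <= threshold <= 100.0:
        raise ValidationError(f"threshold {threshold} not in [0, 100]")
    rows = []
    for otu, sub in hits.groupby("otu_id", sort=True):
        sub = sub[sub["percent_identity"] >= threshold]
        if "bitscore" in sub.columns:
            sub = sub.sort_values("bitscore", ascending=False, kind="stable")
        sub = sub.head(max_hits)
        gfcs = [gfc_assignment[g] for g in sub["genome_id"] if g in gfc_assignment]
        if not gfcs:
            rows.append(
                {"otu_id": otu, "gfc_id": None, "specificity_index": np.nan,
                 "n_hits": 0, "mapped": False}
            )
            continue
        counts = pd.Series(gfcs).value_counts()
        modal = counts.index[0]
        index = counts.iloc[0] / len(gfcs)
        mapped = bool(index == 1.0)
        rows.append(
            {
                "otu_id": otu,
                "gfc_id": modal if mapped else None,
                "specificity_index": float(index),
                "n_hits": len(gfcs),
                "mapped": mapped,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["threshold"] = float(threshold)
    return out


def community_fraction(
    otu_abundances: pd.DataFrame, mapping: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample fraction of reads belonging to GFC-mapped OTUs.

    ``otu_abundances``: OTU x sample read counts (index = otu_id).
    Returns per-sample fractions with mean/min/max in ``attrs``; samples
    with zero total reads get a null fraction.
    """
    mapped_otus = set(mapping.loc[mapping["mapped"], "otu_id"])
    totals = otu_abundances.sum(axis=0).astype(float)
    mapped = otu_abundances.loc[
        otu_abundances.index.isin(mapped_otus)
    ].sum(axis=0).astype(float)
    frac = mapped / totals.where(totals > 0)
    out = pd.DataFrame({"total_reads": totals, "mapped_reads": mapped,
                        "fraction_mapped": frac})
    valid = frac.dropna()
    out.attrs["mean_fraction"] = float(valid.mean()) if len(valid) else float("nan")
    out.attrs["range"] = (
        (float(valid.min()), float(valid.max())) if len(valid) else (np.nan, np.nan)
    )
    return out


def assign_pair_groups(
    pairs: pd.DataFrame, mapping: pd.DataFrame
) -> pd.DataFrame:
    """Label OTU pairs same_gfc / different_gfc from an OTU mapping.

    Pairs where neither OTU is mapped are dropped (they could belong to the
    same unknown GFC); a pair is same_gfc only when both OTUs map to one
    GFC, different_gfc otherwise.
    """
    gfc_of = dict(
        zip(mapping.loc[mapping["mapped"], "otu_id"],
            mapping.loc[mapping["mapped"], "gfc_id"])
    )
    out = pairs.copy()
    a = out["otu_a"].map(gfc_of)
    b = out["otu_b"].map(gfc_of)
    out = out[a.notna() | b.notna()].copy()
    out["group"] = np.where(
        (a.reindex(out.index).notna())
        & (a.reindex(out.index) == b.reindex(out.index)),
        "same_gfc",
        "different_gfc",
    )
    return out


def _one_sided_welch(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    t, p = stats.ttest_ind(x, y, equal_var=False, alternative="greater")
    return float(t), float(p)


def synchrony_test(
    pairs: pd.DataFrame,
    n_randomizations: int = 999,
    seed: int = 0,
    alpha: float = 0.001,
) -> dict:
    """Compare synchrony scores of same-GFC vs different-GFC OTU pairs.

    ``pairs`` must hold columns ``score`` and ``group`` (``same_gfc`` /
    ``different_gfc``), typically from :func:`assign_pair_groups`.

    Returns a report with Shapiro normality p per group (skipped below 3
    observations), the one-sided Welch t-test (same-GFC mean greater), the
    Mann-Whitney rank test, and two randomization controls: pairs
    re-assigned at random (a) keeping the observed group sizes and (b) in
    two equal halves.  Each control reports the fraction of randomizations
    whose test clears ``alpha`` — near zero when the observed effect is not
    an artifact of the group structure — and the +1-corrected empirical p
    of the observed t statistic against the randomization null.
    """
    same = pairs.loc[pairs["group"] == "same_gfc", "score"].to_numpy(float)
    diff = pairs.loc[pairs["group"] == "different_gfc", "score"].to_numpy(float)
    if len(same) == 0 or len(diff) == 0:
        raise ValidationError("both pair groups must be non-empty")

    def _shapiro(v: np.ndarray) -> float | None:
        if len(v) < 3:
            return None
        return float(stats.shapiro(v).pvalue)

    t_obs, p_welch = _one_sided_welch(same, diff)
    u, p_rank = stats.mannwhitneyu(same, diff, alternative="greater")

    pooled = np.concatenate([same, diff])
    n_same = len(same)
    n_equal = len(pooled) // 2
    rng = np.random.default_rng(seed)

    def _control(n_a: int) -> dict:
        sig = 0
        t_null = np.empty(n_randomizations)
        for b in range(n_randomizations):
            perm = rng.permutation(pooled)
            t_b, p_b = _one_sided_welch(perm[:n_a], perm[n_a:])
            t_null[b] = t_b
            if p_b < alpha:
                sig += 1
        return {
            "n_randomizations": n_randomizations,
            "fraction_significant": sig / n_randomizations,
            "fraction_nonsignificant": 1.0 - sig / n_randomizations,
            "empirical_p_of_observed_t": float(
                (1 + np.sum(t_null >= t_obs)) / (1 + n_randomizations)
            ),
        }

    return {
        "n_same_gfc": int(n_same),
        "n_different_gfc": int(len(diff)),
        "mean_same_gfc": float(same.mean()),
        "mean_different_gfc": float(diff.mean()),
        "shapiro_p_same": _shapiro(same),
        "shapiro_p_diff": _shapiro(diff),
        "welch_t": t_obs,
        "welch_p_one_sided": p_welch,
        "welch_p_two_sided": float(min(1.0, 2 * min(p_welch, 1 - p_welch))),
        "mannwhitney_u": float(u),
        "mannwhitney_p_one_sided": float(p_rank),
        "alpha": alpha,
        "control_same_sizes": _control(n_same),
        "control_equal_sizes": _control(n_equal),
    }
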