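"""Strain and gene scoring for the column-selection screen.

Strain scores are log2 ratios of pseudocounted, depth-normalized
abundances versus the matching time-zero sample. Gene scores are
inverse-variance weighted means of eligible strain scores. The normalized
column score of a gene subtracts its precolumn score from its magnetic or
nonmagnetic score within each replicate, removing pure growth effects;
replicates are averaged after normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log
from pathlib import Path

import numpy as np
import pandas as pd

from magscreen.barseq import CountMatrix, SampleSheet

LN2_SQ = log(2) ** 2


@dataclass
class ScoreConfig:
    pseudo: float = 1.0
    t0_min_reads: int = 3
    min_strains_per_gene: int = 1
    median_center: bool = False  # per-sample median-centering of gene raw scores
    hit_threshold: float = 1.0
    require_consistent_sign: bool = True


def strain_score(n_cond, n_t0, total_cond, total_t0, pseudo: float = 1.0):
    """log2 of pseudocounted relative abundance in condition vs time zero.

    Accepts scalars or numpy arrays. With equal totals this reduces to
    log2((n_cond+pseudo)/(n_t0+pseudo)).
    """
    n_cond = np.asarray(n_cond, dtype=float)
    n_t0 = np.asarray(n_t0, dtype=float)
    if (n_cond < 0).any() or (n_t0 < 0).any():
        raise ValueError("negative counts")
    if total_cond <= 0 or total_t0 <= 0:
        raise ValueError("sample totals must be > 0")
    score = np.log2(((n_cond + pseudo) / total_cond) / ((n_t0 + pseudo) / total_t0))
    return float(score) if score.ndim == 0 else score


def strain_weight(n_cond, n_t0):
    """Inverse-variance weight with a Poisson-motivated variance
    V = (1/(1+n_cond) + 1/(1+n_t0)) / ln(2)^2; equal counts give equal
    weights, so balanced data reduce to a plain mean."""
    n_cond = np.asarray(n_cond, dtype=float)
    n_t0 = np.asarray(n_t0, dtype=float)
    v = (1.0 / (1.0 + n_cond) + 1.0 / (1.0 + n_t0)) / LN2_SQ
    w = 1.0 / v
    return float(w) if w.ndim == 0 else w


def gene_score(scores, weights=None) -> float:
    """Weighted mean of strain scores: sum(w*f)/sum(w); plain mean when
    weights are omitted or all equal."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no eligible strains")
    if weights is None:
        return float(scores.mean())
    weights = np.asarray(weights, dtype=float)
    if (weights <= 0).any() or not np.isfinite(weights).all():
        raise ValueError("weights must be finite and > 0")
    return float(np.sum(weights * scores) / np.sum(weights))


def score_samples(
    matrix: CountMatrix,
    pool: pd.DataFrame,
    sheet: SampleSheet,
    config: ScoreConfig | None = None,
) -> pd.DataFrame:
    """Per-(gene, sample) raw scores versus the matching time-zero sample.

    Eligible strains are central, uniquely mapped, gene-assigned, and have
    at least ``t0_min_reads`` reads in the matching t0 sample. Genes with
    fewer than ``min_strains_per_gene`` eligible strains are omitted for
    that sample. Returns a long DataFrame with columns gene_id, sample_id,
    condition, fraction, replicate, score, n_strains.
    """
    config = config or ScoreConfig()
    counts = matrix.counts
    totals = counts.sum(axis=0)
    strains = pool[pool["central"] & ~pool["multimapped"] & pool["gene_id"].notna()]
    strains = strains.set_index("barcode")
    gene_of = strains["gene_id"]

    out_rows = []
    for sample in sheet.samples:
        if sample.fraction == "t0":
            continue
        t0 = sheet.lookup(sample.condition, "t0", sample.replicate)
        if t0 is None:
            raise ValueError(
                f"no t0 sample for condition {sample.condition!r} "
                f"replicate {sample.replicate}"
            )
        n_cond = counts.loc[gene_of.index, sample.sample_id].to_numpy()
        n_t0 = counts.loc[gene_of.index, t0.sample_id].to_numpy()
        eligible = n_t0 >= config.t0_min_reads
        if not eligible.any():
            continue
        scores = strain_score(
            n_cond[eligible],
            n_t0[eligible],
            float(totals[sample.sample_id]),
            float(totals[t0.sample_id]),
            config.pseudo,
        )
        weights = strain_weight(n_cond[eligible], n_t0[eligible])
        df = pd.DataFrame(
            {
                "gene_id": gene_of.to_numpy()[eligible],
                "score": scores,
                "weight": weights,
            }
        )
        df["wf"] = df["score"] * df["weight"]
        grp = df.groupby("gene_id")
        agg = pd.DataFrame(
            {
                "score": grp["wf"].sum() / grp["weight"].sum(),
                "n_strains": grp.size(),
            }
        )
        agg = agg[agg["n_strains"] >= config.min_strains_per_gene]
        if config.median_center:
            agg["score"] = agg["score"] - agg["score"].median()
        agg = agg.reset_index()
        agg["sample_id"] = sample.sample_id
        agg["condition"] = sample.condition
        agg["fraction"] = sample.fraction
        agg["replicate"] = sample.replicate
        out_rows.append(agg)
    if not out_rows:
        raise ValueError("no scoreable samples")
    return pd.concat(out_rows, ignore_index=True)[
        ["gene_id", "sample_id", "condition", "fraction", "replicate", "score", "n_strains"]
    ]


def normalize_mcs(raw: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate normalized column score: fraction score minus the
    matching precolumn score.

    Returns columns gene_id, condition, fraction (magnetic/nonmagnetic),
    replicate, mcs. Genes missing the precolumn score in a replicate are
    dropped for that replicate.
    """
    pre = raw[raw["fraction"] == "precolumn"][
        ["gene_id", "condition", "replicate", "score"]
    ].rename(columns={"score": "pre_score"})
    conds_with_pre = set(zip(pre["condition"], pre["replicate"]))
    frac = raw[raw["fraction"].isin(["magnetic", "nonmagnetic"])]
    missing = set(zip(frac["condition"], frac["replicate"])) - conds_with_pre
    if missing:
        raise ValueError(
            f"missing precolumn scores for condition/replicate: {sorted(missing)}"
        )
    merged = frac.merge(pre, on=["gene_id", "condition", "replicate"], how="inner")
    merged["mcs"] = merged["score"] - merged["pre_score"]
    return merged[
        ["gene_id", "condition", "fraction", "replicate", "mcs", "n_strains"]
    ]


def replicate_mean(
    norm: pd.DataFrame, condition: str | None = None, fraction: str | None = None
) -> pd.DataFrame:
    """Arithmetic mean of normalized scores over available replicates.

    Returns columns gene_id, condition, fraction, mean_mcs, n_reps.
    """
    sub = norm
    if condition is not None:
        sub = sub[sub["condition"] == condition]
    if fraction is not None:
        sub = sub[sub["fraction"] == fraction]
    if sub.empty:
        raise ValueError("no replicates to average")
    grp = sub.groupby(["gene_id", "condition", "fraction"])
    out = pd.DataFrame(
        {"mean_mcs": grp["mcs"].mean(), "n_reps": grp.size()}
    ).reset_index()
    return out


def call_hits(
    norm: pd.DataFrame,
    threshold: float = 1.0,
    require_consistent_sign: bool = True,
) -> pd.DataFrame:
    """Genes with |replicate-mean score| >= threshold.

    Returns columns gene_id, condition, fraction, mean_mcs, n_reps,
    direction (depleted/enriched), consistent_sign. When
    *require_consistent_sign* is set, hits whose replicates disagree in
    sign are dropped (they remain visible with the flag when it is not).
    """
    means = replicate_mean(norm)
    sign_ok = (
        norm.assign(sgn=np.sign(norm["mcs"]))
        .groupby(["gene_id", "condition", "fraction"])["sgn"]
        .agg(lambda s: len(set(s)) == 1)
        .rename("consistent_sign")
        .reset_index()
    )
    means = means.merge(sign_ok, on=["gene_id", "condition", "fraction"])
    hits = means[means["mean_mcs"].abs() >= threshold].copy()
    hits["direction"] = np.where(hits["mean_mcs"] <= -threshold, "depleted", "enriched")
    if require_consistent_sign:
        hits = hits[hits["consistent_sign"]]
    return hits.reset_index(drop=True)[
        ["gene_id", "condition", "fraction", "mean_mcs", "n_reps", "direction", "consistent_sign"]
    ]


def write_score_tsv(norm: pd.DataFrame, path: str | Path) -> None:
    """Wide per-condition score table: one row per (gene, fraction) with
    replicate columns and the replicate mean."""
    wide = norm.pivot_table(
        index=["gene_id", "condition", "fraction"],
        columns="replicate",
        values="mcs",
    )
    wide.columns = [f"rep{int(c)}" for c in wide.columns]
    wide["meanMCS"] = wide.mean(axis=1)
    n_strains = norm.groupby(["gene_id", "condition", "fraction"])["n_strains"].min()
    wide["nStrains"] = n_strains
    wide.reset_index().rename(columns={"gene_id": "geneId"}).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def scatter_table(
    norm: pd.DataFrame, cond_x: str, cond_y: str, fraction: str = "magnetic"
) -> pd.DataFrame:
    """Per-gene replicate-mean scores for two conditions, for
    condition-vs-condition scatter plots."""
    mx = replicate_mean(norm, cond_x, fraction).rename(columns={"mean_mcs": "mcs_x"})
    my = replicate_mean(norm, cond_y, fraction).rename(columns={"mean_mcs": "mcs_y"})
    return mx[["gene_id", "mcs_x"]].merge(my[["gene_id", "mcs_y"]], on="gene_id")
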