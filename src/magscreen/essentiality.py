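"""Essential-gene calling from central insertion density.

A gene is called essential when it is not excluded, is at least as long as
the Poisson minimum-length threshold, and carries zero central insertions.
Short genes (<100 nt by default) and duplicate-like genes are excluded up
front; genes shorter than the threshold are reported but not called.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from magscreen.genome_io import GeneAnnotation, central_region

CLASSES = (
    "essential",
    "nonessential",
    "excluded_short",
    "excluded_duplicate",
    "not_called_below_threshold",
)


@dataclass
class EssentialityConfig:
    alpha: float = 0.02
    min_gene_len: int = 100
    duplicate_policy: str = "multimap_fraction"  # or "user_list"
    multimap_fraction_cutoff: float = 0.5
    duplicate_gene_ids: frozenset[str] = field(default_factory=frozenset)
    central_fracs: tuple[float, float] = (0.1, 0.9)
    low_density_factor: float = 0.2  # advisory flag only

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.duplicate_policy not in {"user_list", "multimap_fraction"}:
            raise ValueError(f"unknown duplicate_policy {self.duplicate_policy!r}")


def poisson_min_length(median_density: float, alpha: float) -> int:
    """Smallest gene length L at which zero insertions is improbable.

    Under a Poisson model with per-nucleotide insertion rate *d*, the
    probability of zero insertions in L nt is exp(-d*L); return the
    smallest integer L with exp(-d*L) < alpha.
    """
    if median_density <= 0:
        raise ValueError(f"density must be > 0, got {median_density}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    L = math.floor(-math.log(alpha) / median_density) + 1
    # guard against float edge cases near the boundary
    while L > 1 and math.exp(-median_density * (L - 1)) < alpha:
        L -= 1
    while math.exp(-median_density * L) >= alpha:
        L += 1
    return L


def compute_densities(
    pool: pd.DataFrame,
    genes: list[GeneAnnotation],
    config: EssentialityConfig | None = None,
) -> pd.DataFrame:
    """Per-gene central-strain counts, densities, and exclusion flags.

    Returns a DataFrame indexed by gene_id with columns gene_len,
    central_len, n_central_strains, density, excluded
    (None/'excluded_short'/'excluded_duplicate'), low_density. Multimapped
    barcodes are never counted.
    """
    config = config or EssentialityConfig()
    usable = pool[pool["central"] & ~pool["multimapped"]]
    central_counts = usable.groupby("gene_id").size()
    # per-gene multimap fraction among all gene-assigned barcodes
    genic = pool[pool["gene_id"].notna()]
    multi_frac = genic.groupby("gene_id")["multimapped"].mean()

    rows = []
    for g in genes:
        lo, hi = central_region(g, *config.central_fracs)
        central_len = hi - lo + 1
        n_central = int(central_counts.get(g.gene_id, 0))
        excluded = None
        if g.length < config.min_gene_len:
            excluded = "excluded_short"
        elif config.duplicate_policy == "user_list":
            if g.gene_id in config.duplicate_gene_ids:
                excluded = "excluded_duplicate"
        else:
            if float(multi_frac.get(g.gene_id, 0.0)) >= config.multimap_fraction_cutoff:
                excluded = "excluded_duplicate"
        rows.append(
            {
                "gene_id": g.gene_id,
                "gene_len": g.length,
                "central_len": central_len,
                "n_central_strains": n_central,
                "density": n_central / central_len,
                "excluded": excluded,
            }
        )
    df = pd.DataFrame(rows).set_index("gene_id")
    if df["excluded"].notna().all():
        raise ValueError("all genes excluded from essentiality analysis")
    med = float(df.loc[df["excluded"].isna(), "density"].median())
    df["low_density"] = df["excluded"].isna() & (
        df["density"] < config.low_density_factor * med
    )
    df.attrs["median_density"] = med
    return df


@dataclass
class EssentialitySummary:
    l_min: int
    alpha: float
    median_density: float
    class_counts: dict[str, int]

    def to_json(self) -> str:
        return json.dumps(
            {
                "L_min": self.l_min,
                "alpha": self.alpha,
                "median_density": self.median_density,
                "class_counts": self.class_counts,
            },
            indent=2,
        )


def call_essentials(
    pool: pd.DataFrame,
    genes: list[GeneAnnotation],
    config: EssentialityConfig | None = None,
) -> tuple[pd.DataFrame, EssentialitySummary]:
    """Classify every annotated gene.

    Classes partition the gene set: essential / nonessential /
    excluded_short / excluded_duplicate / not_called_below_threshold.
    """
    config = config or EssentialityConfig()
    dens = compute_densities(pool, genes, config)
    med = dens.attrs["median_density"]
    if med <= 0:
        raise ValueError("median insertion density is zero; cannot set threshold")
    l_min = poisson_min_length(med, config.alpha)

    def classify(row: pd.Series) -> str:
        if row["excluded"] is not None:
            return row["excluded"]
        if row["gene_len"] < l_min:
            return "not_called_below_threshold"
        if row["n_central_strains"] == 0:
            return "essential"
        return "nonessential"

    dens = dens.copy()
    dens["class"] = dens.apply(classify, axis=1)
    counts = {c: int((dens["class"] == c).sum()) for c in CLASSES}
    assert sum(counts.values()) == len(genes)
    summary = EssentialitySummary(
        l_min=l_min, alpha=config.alpha, median_density=med, class_counts=counts
    )
    return dens, summary


def write_calls_tsv(calls: pd.DataFrame, path: str | Path) -> None:
    out = calls.reset_index()[
        ["gene_id", "class", "n_central_strains", "central_len", "density"]
    ].rename(
        columns={
            "gene_id": "geneId",
            "class": "class",
            "n_central_strains": "nCentralStrains",
            "central_len": "centralLen",
        }
    )
    out.to_csv(path, sep="\t", index=False)
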