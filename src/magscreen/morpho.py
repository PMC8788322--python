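"""Particle-length summaries and normality-gated two-sample comparison.

Each sample is Shapiro–Wilk tested; if both pass at the gate alpha the
two-sided unpaired equal-variance Student's t test is used, otherwise the
two-sided Mann–Whitney U test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

RECOMMENDED_N = 200


@dataclass
class LengthSample:
    strain: str
    condition: str
    lengths: np.ndarray

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if (self.lengths <= 0).any():
            raise ValueError("lengths must be > 0")
        if self.n < RECOMMENDED_N:
            warnings.warn(
                f"{self.strain}/{self.condition}: only {self.n} measurements "
                f"(fewer than the recommended {RECOMMENDED_N})",
                stacklevel=2,
            )

    @property
    def n(self) -> int:
        return len(self.lengths)


def summarize(sample: LengthSample) -> tuple[float, float, int]:
    """(mean, sample standard deviation, n); n >= 2 required."""
    if sample.n < 2:
        raise ValueError("need at least 2 measurements")
    return (
        float(np.mean(sample.lengths)),
        float(np.std(sample.lengths, ddof=1)),
        sample.n,
    )


@dataclass(frozen=True)
class ComparisonResult:
    test_used: str  # "student_t" or "mann_whitney"
    p_value: float
    statistic: float
    shapiro_p_a: float
    shapiro_p_b: float
    significant: bool  # at p < 0.05


def normality_gated_compare(
    a: LengthSample,
    b: LengthSample,
    alpha: float = 0.05,
    welch: bool = False,
) -> ComparisonResult:
    """Shapiro-gated two-sample test.

    Both samples normal at *alpha* -> two-sided unpaired Student's t
    (equal variance unless *welch*); otherwise two-sided Mann-Whitney U.
    """
    if a.n < 3 or b.n < 3:
        raise ValueError("need n >= 3 per sample for the Shapiro-Wilk test")
    sw_a = stats.shapiro(a.lengths).pvalue
    sw_b = stats.shapiro(b.lengths).pvalue
    if sw_a >= alpha and sw_b >= alpha:
        res = stats.ttest_ind(a.lengths, b.lengths, equal_var=not welch)
        test = "student_t"
    else:
        res = stats.mannwhitneyu(a.lengths, b.lengths, alternative="two-sided")
        test = "mann_whitney"
    return ComparisonResult(
        test_used=test,
        p_value=float(res.pvalue),
        statistic=float(res.statistic),
        shapiro_p_a=float(sw_a),
        shapiro_p_b=float(sw_b),
        significant=bool(res.pvalue < 0.05),
    )


def read_lengths_csv(path: str | Path) -> list[LengthSample]:
    """Long-format CSV with columns strain,condition,length_nm."""
    df = pd.read_csv(path)
    required = {"strain", "condition", "length_nm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"lengths CSV missing columns: {sorted(missing)}")
    samples = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for (strain, condition), grp in df.groupby(["strain", "condition"]):
            samples.append(
                LengthSample(strain, condition, grp["length_nm"].to_numpy())
            )
    return samples


def pairwise_comparisons(
    samples: list[LengthSample], alpha: float = 0.05
) -> pd.DataFrame:
    """All pairwise normality-gated comparisons between samples."""
    rows = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            a, b = samples[i], samples[j]
            r = normality_gated_compare(a, b, alpha)
            mean_a, sd_a, _ = summarize(a)
            mean_b, sd_b, _ = summarize(b)
            rows.append(
                {
                    "a": f"{a.strain}/{a.condition}",
                    "b": f"{b.strain}/{b.condition}",
                    "mean_a": mean_a,
                    "sd_a": sd_a,
                    "n_a": a.n,
                    "mean_b": mean_b,
                    "sd_b": sd_b,
                    "n_b": b.n,
                    "test": r.test_used,
                    "p_value": r.p_value,
                    "significant": r.significant,
                }
            )
    return pd.DataFrame(rows)
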