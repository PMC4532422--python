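"""Sanger-vs-NGS method agreement: LOD substitution, Bland-Altman, bias test.

Heteroplasmy levels below the Sanger detection limit are substituted by
``LOD / sqrt(2)`` before summary statistics (the default; ``LOD / 2`` is the
alternative convention).  Agreement between the two quantification methods is
then summarised by a Bland-Altman analysis: differences ``b - a`` are plotted
against pair means, with 95% limits of agreement at ``mean +/- 1.96 * SD`` of
the differences, a one-sample t-test of the mean difference against zero
(fixed bias), and the Pearson product-moment correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, UndefinedCorrelationError

DEFAULT_SANGER_LOD_PCT = 10.0
LOA_Z = 1.96  # normal quantile used for the 95% limits of agreement


@dataclass(frozen=True)
class PairedMeasurement:
    """One position measured by two methods (a = e.g. Sanger, b = e.g. NGS)."""

    sample_id: str
    position: int
    value_a: float
    value_b: float
    a_below_lod: bool = False

    def __post_init__(self) -> None:
        for v in (self.value_a, self.value_b):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"percentage {v} outside [0, 100]")


@dataclass(frozen=True)
class BiasTest:
    t: float
    p: float
    degenerate: bool = False  # zero-variance differences: p undefined


@dataclass(frozen=True)
class AgreementStats:
    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pct_within: float
    bias_t: float
    bias_p: float
    bias_degenerate: bool
    pearson_r: float
    pearson_p: float


@dataclass(frozen=True)
class BlandAltmanData:
    """Plotting data: abscissa (pair means), ordinate (differences), lines."""

    mean: np.ndarray
    diff: np.ndarray
    line_mean: float
    line_low: float
    line_high: float


def lod_substitute(
    values: Sequence[float | None],
    lod: float = DEFAULT_SANGER_LOD_PCT,
    rule: str = "sqrt2",
) -> np.ndarray:
    """Replace below-LOD entries (None/NaN) by ``lod/sqrt(2)`` or ``lod/2``.

    Observed values pass through unchanged, so the substitution is idempotent.
    """
    if lod <= 0:
        raise ValueError("detection limit must be positive")
    if rule == "sqrt2":
        fill = lod / math.sqrt(2.0)
    elif rule == "half":
        fill = lod / 2.0
    else:
        raise ValueError(f"unknown substitution rule {rule!r}")
    out = np.array(
        [fill if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)
         for v in values],
        dtype=float,
    )
    return out


def fixed_bias_test(differences: Sequence[float]) -> BiasTest:
    """Two-sided one-sample t-test of the mean difference against zero."""
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise InsufficientDataError("bias test needs at least 2 differences")
    if d.std(ddof=1) == 0:
        return BiasTest(t=float("nan"), p=float("nan"), degenerate=True)
    t, p = stats.ttest_1samp(d, popmean=0.0)
    return BiasTest(t=float(t), p=float(p))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InsufficientDataError("correlation needs >=3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError("correlation undefined for constant vector")
    result = stats.pearsonr(x, y)
    return float(result.statistic), float(result.pvalue)


def bland_altman(
    pairs: Sequence[PairedMeasurement] | tuple[Sequence[float], Sequence[float]],
) -> tuple[AgreementStats, BlandAltmanData]:
    """Bland-Altman agreement analysis of two paired measurement series.

    Accepts a list of :class:`PairedMeasurement` or a ``(values_a, values_b)``
    pair of sequences.  Differences are ``b - a``.  With zero variance the
    limits collapse onto the mean difference and 100% of pairs lie within.
    """
    if isinstance(pairs, tuple) and len(pairs) == 2:
        a = np.asarray(pairs[0], dtype=float)
        b = np.asarray(pairs[1], dtype=float)
    else:
        a = np.array([p.value_a for p in pairs], dtype=float)
        b = np.array([p.value_b for p in pairs], dtype=float)
    if a.size != b.size:
        raise ValueError("paired series must have equal length")
    if a.size < 2:
        raise InsufficientDataError("Bland-Altman needs at least 2 pairs")
    diff = b - a
    mean = (a + b) / 2.0
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    loa_low = mean_diff - LOA_Z * sd_diff
    loa_high = mean_diff + LOA_Z * sd_diff
    within = (diff >= loa_low) & (diff <= loa_high)
    pct_within = 100.0 * float(within.mean())
    if sd_diff == 0:
        bias = BiasTest(t=float("nan"), p=float("nan"), degenerate=True)
    else:
        bias = fixed_bias_test(diff)
    try:
        r, r_p = pearson_r(a, b)
    except (InsufficientDataError, UndefinedCorrelationError):
        r, r_p = float("nan"), float("nan")
    statistics = AgreementStats(
        n=int(a.size),
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=loa_low,
        loa_high=loa_high,
        pct_within=pct_within,
        bias_t=bias.t,
        bias_p=bias.p,
        bias_degenerate=bias.degenerate,
        pearson_r=r,
        pearson_p=r_p,
    )
    data = BlandAltmanData(
        mean=mean, diff=diff,
        line_mean=mean_diff, line_low=loa_low, line_high=loa_high,
    )
    return statistics, data


def pairs_from_table(
    rows,
    lod: float = DEFAULT_SANGER_LOD_PCT,
    rule: str = "sqrt2",
) -> list[PairedMeasurement]:
    """Build measurement pairs from a table with columns
    ``sample``, ``pos``, ``sanger_pct`` ("NA" when below LOD) and ``ngs_pct``,
    applying the LOD substitution to the Sanger column.
    """
    import pandas as pd

    df = rows if isinstance(rows, pd.DataFrame) else pd.read_csv(rows, sep="\t")
    below = df["sanger_pct"].isna() | (df["sanger_pct"].astype(str).str.upper() == "NA")
    raw = [None if flag else float(v) for v, flag in zip(df["sanger_pct"], below)]
    substituted = lod_substitute(raw, lod=lod, rule=rule)
    return [
        PairedMeasurement(
            sample_id=str(row["sample"]),
            position=int(row["pos"]),
            value_a=float(sub),
            value_b=float(row["ngs_pct"]),
            a_below_lod=bool(flag),
        )
        for (_, row), sub, flag in zip(df.iterrows(), substituted, below)
    ]


def plot_bland_altman(data: BlandAltmanData, path, title: str = "Bland-Altman") -> None:
    """Write the standard Bland-Altman scatter with the three reference lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(data.mean, data.diff, s=12, alpha=0.7)
    ax.axhline(data.line_mean, color="green", label="mean difference")
    ax.axhline(data.line_low, color="red", linestyle=":", label="95% limits")
    ax.axhline(data.line_high, color="red", linestyle=":")
    ax.set_xlabel("mean of the two measurements (%)")
    ax.set_ylabel("difference (b - a) (%)")
    ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
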