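"""Pairwise genetic distances and intra/inter separation statistics.

Distances are Euclidean over per-locus genotype one-hot vectors, which
reduces to ``d(i, j) = sqrt(2 * m)`` where ``m`` is the number of loci at
which the two individuals carry different genotype states.  With complete
data on an L-locus panel, d therefore only takes the values
``{sqrt(2m): m = 0..L}``; with 12 loci the ceiling is sqrt(24) = 4.899.

Under pairwise-complete handling of missing data the mismatch count over the
jointly observed loci is rescaled by L / L_complete before the square root,
so distances remain on the full-panel scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GenotypeMatrix

__all__ = [
    "DistanceSummary",
    "SeparationReport",
    "pairwise_distance_matrix",
    "distance_summaries",
    "pair_values",
    "welch_t_test",
    "separation_gap",
    "separation_report",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class DistanceSummary:
    """Summary of one set of pairwise distances (e.g. intra-wolf)."""

    label: str
    n_pairs: int
    mean: float
    sd: float
    min: float
    max: float
    lower95: float
    upper95: float
    defined: bool = True

    @classmethod
    def undefined(cls, label: str) -> "DistanceSummary":
        nan = float("nan")
        return cls(label, 0, nan, nan, nan, nan, nan, nan, defined=False)


@dataclass
class SeparationReport:
    """Welch's t between intra and inter distance sets plus the 95% gap."""

    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    gap: float
    gap_method: str
    defined: bool = True


def pairwise_distance_matrix(
    matrix: GenotypeMatrix, missing: str = "error"
) -> pd.DataFrame:
    """Symmetric genotype-mismatch Euclidean distance matrix.

    ``missing='error'`` rejects matrices with MISSING calls (reference data
    are expected complete); ``missing='rescale'`` computes each pair over its
    jointly observed loci and rescales to the full panel length.
    """
    if missing not in ("error", "rescale"):
        raise ValueError("missing must be 'error' or 'rescale'")
    d = matrix.dosage.to_numpy(np.int8)
    valid = d >= 0
    if missing == "error" and not valid.all():
        raise ValueError("matrix contains MISSING calls; use missing='rescale'")
    n, n_loci = d.shape
    both = valid[:, None, :] & valid[None, :, :]
    mism = ((d[:, None, :] != d[None, :, :]) & both).sum(axis=2)
    n_complete = both.sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(n_complete > 0, mism * n_loci / n_complete, np.nan)
    dist = np.sqrt(2.0 * scaled)
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=matrix.individual_ids, columns=matrix.individual_ids)


def pair_values(
    distances: pd.DataFrame, labels: pd.Series
) -> dict[str, np.ndarray]:
    """Partition the unordered pairs of a two-population distance matrix.

    Returns arrays keyed ``intra_<pop1>``, ``intra_<pop2>``, ``intra_overall``
    and ``inter`` (pop order = sorted label order).
    """
    pops = sorted(labels.unique())
    if len(pops) != 2:
        raise ValueError(f"expected exactly two populations, found {pops}")
    lab = labels.loc[distances.index].to_numpy()
    dm = distances.to_numpy()
    iu = np.triu_indices(len(dm), k=1)
    vals = dm[iu]
    same = lab[iu[0]] == lab[iu[1]]
    out = {}
    for pop in pops:
        in_pop = (lab[iu[0]] == pop) & same
        out[f"intra_{pop}"] = vals[in_pop]
    out["intra_overall"] = vals[same]
    out["inter"] = vals[~same]
    return out


def _bounds(values: np.ndarray, method: str) -> tuple[float, float]:
    if method == "normal":
        m, s = float(np.mean(values)), float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        return m - Z95 * s, m + Z95 * s
    if method == "percentile":
        return tuple(np.quantile(values, [0.025, 0.975]))
    raise ValueError("method must be 'normal' or 'percentile'")


def _summarize(label: str, values: np.ndarray, bound_method: str) -> DistanceSummary:
    if len(values) == 0:
        return DistanceSummary.undefined(label)
    lo, hi = _bounds(values, bound_method)
    return DistanceSummary(
        label=label,
        n_pairs=len(values),
        mean=float(np.mean(values)),
        sd=float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
        min=float(np.min(values)),
        max=float(np.max(values)),
        lower95=lo,
        upper95=hi,
    )


def distance_summaries(
    distances: pd.DataFrame, labels: pd.Series, bound_method: str = "normal"
) -> dict[str, DistanceSummary]:
    """Intra/inter distance summaries for a labelled distance matrix.

    The 95% bounds describe the distance *distribution*: ``normal`` uses
    mean +/- 1.96 SD, ``percentile`` the empirical 2.5%/97.5% quantiles.
    A population with fewer than two individuals gets an undefined summary.
    """
    parts = pair_values(distances, labels)
    return {label: _summarize(label, vals, bound_method) for label, vals in parts.items()}


def welch_t_test(intra: np.ndarray, inter: np.ndarray) -> SeparationReport:
    """Welch's unequal-variance t-test of inter vs intra distances.

    Pairwise distances are treated as independent observations (the
    convention implied by the published degrees of freedom); t > 0 means
    inter distances exceed intra.  Returns a report without a gap (gap NaN);
    use :func:`separation_report` for the combined statistic.
    """
    intra = np.asarray(intra, float)
    inter = np.asarray(inter, float)
    if len(intra) == 0 or len(inter) == 0:
        raise ValueError("both distance sets must be non-empty")
    if np.var(intra) == 0.0 and np.var(inter) == 0.0:
        return SeparationReport(float("nan"), float("nan"), float("nan"),
                                float("nan"), "none", defined=False)
    res = stats.ttest_ind(inter, intra, equal_var=False)
    return SeparationReport(
        t_statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_value=float(res.pvalue),
        gap=float("nan"),
        gap_method="none",
    )


def separation_gap(
    intra: np.ndarray, inter: np.ndarray, method: str = "normal"
) -> float:
    """Gap between the inter 95% lower bound and the intra 95% upper bound.

    Positive values mean the two 95% intervals are disjoint — the safety
    margin against false assignment.
    """
    intra = np.asarray(intra, float)
    inter = np.asarray(inter, float)
    _, intra_hi = _bounds(intra, method)
    inter_lo, _ = _bounds(inter, method)
    return float(inter_lo - intra_hi)


def separation_report(
    intra: np.ndarray, inter: np.ndarray, gap_method: str = "normal"
) -> SeparationReport:
    """Welch's t plus the 95% separation gap in one report."""
    rep = welch_t_test(intra, inter)
    if rep.defined:
        rep.gap = separation_gap(intra, inter, gap_method)
        rep.gap_method = gap_method
    return rep


def distance_histogram(
    distances: pd.DataFrame, labels: pd.Series, bins: Optional[Sequence[float]] = None
) -> pd.DataFrame:
    """Bin counts of intra/inter distances, for plotting distributions."""
    parts = pair_values(distances, labels)
    all_vals = np.concatenate([parts["intra_overall"], parts["inter"]])
    if bins is None:
        bins = np.histogram_bin_edges(all_vals, bins=20)
    rows = []
    for label in sorted(parts):
        counts, edges = np.histogram(parts[label], bins=bins)
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            rows.append({"set": label, "bin_low": lo, "bin_high": hi, "count": int(c)})
    return pd.DataFrame(rows)
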