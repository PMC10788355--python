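"""Per-locus association and diversity statistics.

* Cochran–Armitage trend test (CATT): 1-df chi-square for a linear trend in
  genotype scores between the sexes, computed as N·r² with r the Pearson
  correlation between the score and the sex indicator.  Scores default to
  (0, 1, 2) for SNP genotype codes and (0, 1) for PA presence, making the PA
  case the 2×2 trend test.
* Pearson goodness-of-fit chi-square for observed vs expected genotype
  proportions.
* PIC in the biallelic DArT convention 2p(1−p), ranging 0 (one allele fixed)
  to 0.5 (both alleles equally frequent).
* Per-individual heterozygosity percentage over a candidate locus set.
* Kruskal–Wallis (tie-corrected, via scipy) and the Nemenyi post-hoc test on
  mean ranks (studentized-range reference distribution), used to compare
  the 90:10 / 80:20 / 70:30 threshold groups.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .panel import MISSING, GenotypePanel, MarkerType, SexRegistry


def catt(
    genotype_counts_by_sex: np.ndarray, weights: np.ndarray | None = None
) -> tuple[float, float]:
    """Cochran–Armitage trend chi-square and p-value from a 2×k count table.

    Rows are the two sexes, columns the genotype scores.  Degenerate tables
    (all mass in one score column, or an empty row) give (0.0, 1.0) with a
    warning rather than an exception.
    """
    t = np.asarray(genotype_counts_by_sex, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] not in (2, 3):
        raise ValueError("expected a 2×2 or 2×3 count table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    w = np.arange(t.shape[1], dtype=float) if weights is None else np.asarray(
        weights, dtype=float
    )
    if w.shape != (t.shape[1],):
        raise ValueError("weights length must match the number of columns")
    N = t.sum()
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if N == 0 or row.min() == 0 or np.count_nonzero(col) < 2:
        warnings.warn("degenerate CATT table; returning chi2=0, p=1", stacklevel=2)
        return 0.0, 1.0
    # N * r^2 with x = score, y = indicator of row 0
    sxy = w @ t[0] - (w @ col) * row[0] / N
    sxx = (w**2) @ col - (w @ col) ** 2 / N
    syy = row[0] * row[1] / N
    if sxx <= 0:
        warnings.warn("degenerate CATT table; returning chi2=0, p=1", stacklevel=2)
        return 0.0, 1.0
    chi2 = float(N * sxy**2 / (sxx * syy))
    return chi2, float(sps.chi2.sf(chi2, df=1))


def catt_table(
    panel: GenotypePanel, sexes: SexRegistry, locus: str
) -> np.ndarray:
    """2×k genotype count table (rows male, female) for one locus."""
    calls = panel.locus_calls(locus)
    males, females = sexes.indices(panel.individuals)
    k = 3 if panel.marker_type is MarkerType.SNP else 2
    out = np.zeros((2, k), dtype=float)
    for r, idx in enumerate((males, females)):
        sub = calls[idx]
        for code in range(k):
            out[r, code] = int((sub == code).sum())
    return out


def conformity_chi2(
    observed: np.ndarray, expected: np.ndarray, ddof: int = 0
) -> tuple[float, float]:
    """Pearson goodness-of-fit chi-square of observed vs expected counts.

    Degrees of freedom are ``n_cells − 1 − ddof`` (the expected table is
    treated as externally given, costing one constraint for the total).
    """
    obs = np.asarray(observed, dtype=float).ravel()
    exp = np.asarray(expected, dtype=float).ravel()
    if obs.shape != exp.shape:
        raise ValueError("observed and expected shapes differ")
    if (exp <= 0).any():
        raise ValueError("expected counts must be positive")
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = obs.size - 1 - ddof
    if df < 1:
        raise ValueError("non-positive degrees of freedom")
    return chi2, float(sps.chi2.sf(chi2, df=df))


def pic(allele_freq_p: float) -> float:
    """Biallelic polymorphic information content 2p(1−p) (max 0.5 at p=0.5)."""
    p = float(allele_freq_p)
    if not 0.0 <= p <= 1.0:
        raise ValueError("allele frequency must be in [0, 1]")
    return 2.0 * p * (1.0 - p)


def allele_frequency(panel: GenotypePanel, locus: str) -> float:
    """Alternate-allele frequency (SNP) or presence frequency (PA) from calls."""
    calls = panel.locus_calls(locus)
    called = calls[calls != MISSING]
    if called.size == 0:
        return float("nan")
    if panel.marker_type is MarkerType.SNP:
        return float((2 * (called == 2).sum() + (called == 1).sum()) / (2 * called.size))
    return float((called == 1).sum() / called.size)


def pic_table(panel: GenotypePanel) -> pd.Series:
    """Per-locus PIC over the whole panel (vectorised)."""
    calls = panel.calls
    called = calls != MISSING
    n_called = called.sum(axis=1).astype(float)
    if panel.marker_type is MarkerType.SNP:
        p = (2 * (calls == 2).sum(axis=1) + (calls == 1).sum(axis=1)) / np.where(
            n_called > 0, 2 * n_called, np.nan
        )
    else:
        p = (calls == 1).sum(axis=1) / np.where(n_called > 0, n_called, np.nan)
    return pd.Series(2 * p * (1 - p), index=pd.Index(panel.loci), name="pic")


def het_percent(
    panel: GenotypePanel, individual: str, locus_set: list[str]
) -> float:
    """Percentage of heterozygous calls for one individual over ``locus_set``.

    NaN when the individual has no calls in the set.
    """
    if panel.marker_type is not MarkerType.SNP:
        raise ValueError("heterozygosity percentage is defined for SNP panels")
    if not locus_set:
        raise ValueError("locus_set must be non-empty")
    j = panel.individuals.index(individual)
    pos = {l: i for i, l in enumerate(panel.loci)}
    idx = np.array([pos[l] for l in locus_set], dtype=int)
    col = panel.calls[idx, j]
    called = col != MISSING
    if not called.any():
        return float("nan")
    return float(100.0 * (col[called] == 1).sum() / called.sum())


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square p-value.

    The fully degenerate case (every value identical across all groups) is
    defined as (0.0, 1.0) — no rank variation means no evidence of a
    location difference.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrs)
    return float(h), float(p)


def nemenyi_posthoc(groups: list[np.ndarray]) -> pd.DataFrame:
    """Pairwise Nemenyi post-hoc p-values on Kruskal–Wallis mean ranks.

    The statistic for groups i, j is
    ``q = |R̄_i − R̄_j| / sqrt(N(N+1)/12 · (1/n_i + 1/n_j))`` compared to the
    studentized range distribution with k groups and infinite df (the Tukey
    variant used by R's PMCMR).  Returns a symmetric k×k DataFrame with unit
    diagonal.
    """
    k = len(groups)
    if k < 3:
        raise ValueError("Nemenyi post-hoc needs at least three groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrs):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(arrs)
    ranks = sps.rankdata(pooled)
    sizes = [a.size for a in arrs]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(k)]
    N = pooled.size
    out = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(N * (N + 1) / 12.0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
            q = abs(mean_ranks[i] - mean_ranks[j]) / se
            p = float(sps.studentized_range.sf(q * np.sqrt(2.0), k, np.inf))
            out[i, j] = out[j, i] = min(1.0, p)
    return pd.DataFrame(out)


def association_table(
    panel: GenotypePanel,
    sexes: SexRegistry,
    loci: list[str] | None = None,
    weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """CATT chi-square/p and PIC for each locus (default: all loci)."""
    loci = list(panel.loci) if loci is None else list(loci)
    pics = pic_table(panel)
    rows = []
    for locus in loci:
        chi2, p = catt(catt_table(panel, sexes, locus), weights=weights)
        rows.append((locus, chi2, p, pics[locus]))
    return pd.DataFrame(
        rows, columns=["locus", "catt_chi2", "catt_p", "pic"]
    ).set_index("locus")
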