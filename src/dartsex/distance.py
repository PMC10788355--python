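"""Hamming distances, sex-stratified summaries, PCoA and the genotype index
matrix used to visualise candidate loci.

The distance between two individuals is the fraction of *co-called* loci at
which their genotype codes differ (pairwise-complete handling of missing
data).  Principal coordinate analysis is classical metric scaling: double
centering of squared distances followed by an eigendecomposition; axes with
negative eigenvalues are reported but dropped from the coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel, SexRegistry


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # symmetric, zero diagonal, fractions in [0, 1]
    n_loci_used: np.ndarray  # per-pair co-called locus counts
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)


def hamming(panel: GenotypePanel, locus_set: list[str] | None = None) -> DistanceMatrix:
    """Pairwise Hamming distance over ``locus_set`` (default: all loci).

    Pairs with zero co-called loci get NaN and are flagged in
    ``undefined_pairs``.
    """
    sub = panel if locus_set is None else panel.subset_loci(locus_set)
    if sub.n_loci == 0:
        raise ValueError("locus_set must be non-empty")
    calls = sub.calls
    called = calls != MISSING
    n = sub.n_individuals
    d = np.zeros((n, n))
    used = np.zeros((n, n), dtype=int)
    undefined: list[tuple[str, str]] = []
    for i in range(n):
        both = called[:, i][:, None] & called[:, i + 1 :]
        diff = (calls[:, i][:, None] != calls[:, i + 1 :]) & both
        co = both.sum(axis=0)
        nd = diff.sum(axis=0)
        for off, j in enumerate(range(i + 1, n)):
            used[i, j] = used[j, i] = co[off]
            if co[off] == 0:
                d[i, j] = d[j, i] = np.nan
                undefined.append((sub.individuals[i], sub.individuals[j]))
            else:
                d[i, j] = d[j, i] = nd[off] / co[off]
    return DistanceMatrix(list(sub.individuals), d, used, undefined)


def sex_distance_summary(
    dm: DistanceMatrix, sexes: SexRegistry
) -> dict[str, dict[str, float]]:
    """Mean, SE and SD of distances within males, within females, between.

    The dispersion reported alongside the mean is the standard error over
    pairs; the SD over pairs is also returned.
    """
    males, females = sexes.indices(dm.ids)
    strata = {
        "within_male": [(i, j) for a, i in enumerate(males) for j in males[a + 1 :]],
        "within_female": [
            (i, j) for a, i in enumerate(females) for j in females[a + 1 :]
        ],
        "between": [(i, j) for i in males for j in females],
    }
    out: dict[str, dict[str, float]] = {}
    for name, pairs in strata.items():
        vals = np.array([dm.d[i, j] for i, j in pairs], dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            out[name] = {"mean": float("nan"), "se": float("nan"),
                         "sd": float("nan"), "n_pairs": 0}
            continue
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        out[name] = {
            "mean": float(vals.mean()),
            "se": sd / np.sqrt(vals.size),
            "sd": sd,
            "n_pairs": int(vals.size),
        }
    return out


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # ids × retained axes, descending eigenvalue
    eigenvalues: np.ndarray  # all eigenvalues, descending
    negative_eigenvalues: np.ndarray  # magnitudes of dropped negative axes


def pcoa(dm: DistanceMatrix, k: int = 2) -> PCoAResult:
    """Classical metric scaling of a complete distance matrix.

    Gower double centering ``B = −½·J·D²·J`` followed by ``eigh``;
    coordinates are eigenvectors scaled by the square root of their (positive)
    eigenvalues.  Negative eigenvalues (non-Euclidean input) are reported and
    their axes dropped; no Cailliez correction is applied.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    D = np.asarray(dm.d, dtype=float)
    if np.isnan(D).any():
        raise ValueError("PCoA requires a complete distance matrix")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, v = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    tol = 1e-10 * max(1.0, float(np.abs(w).max()))
    pos = w > tol
    neg = -w[w < -tol]
    m = min(k, int(pos.sum()))
    coords = v[:, :m] * np.sqrt(w[:m])
    frame = pd.DataFrame(
        coords, index=dm.ids, columns=[f"axis{i + 1}" for i in range(m)]
    )
    return PCoAResult(coordinates=frame, eigenvalues=w, negative_eigenvalues=neg)


def genotype_index_matrix(
    panel: GenotypePanel, candidate_loci: list[str], sexes: SexRegistry
) -> pd.DataFrame:
    """Individuals × candidate loci code matrix for heatmap plotting.

    Rows are ordered females first then males (panel order within sex); loci
    keep the given screen order.  Missing calls become pandas ``NA``.
    """
    if not candidate_loci:
        raise ValueError("candidate locus set must be non-empty")
    sub = panel.subset_loci(candidate_loci)
    males, females = sexes.indices(panel.individuals)
    order = np.concatenate([females, males])
    mat = sub.calls[:, order].T.astype(float)
    mat[mat == MISSING] = np.nan
    frame = pd.DataFrame(
        mat,
        index=[panel.individuals[j] for j in order],
        columns=candidate_loci,
    ).astype("Int64")
    return frame
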