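"""Core containers for reduced-representation genotype data.

A :class:`GenotypePanel` holds a locus-by-individual matrix of genotype codes
for one marker class:

* SNP (codominant): ``0`` homozygous reference, ``1`` heterozygous,
  ``2`` homozygous alternate;
* PA (dominant presence/absence, "silicoDArT"): ``0`` fragment absent,
  ``1`` fragment present.

Missing calls are stored as :data:`MISSING` (``-1``).  Per-locus quality
metadata (reproducibility, mean sequencing depth, allele-count balance, call
rate) travels with the panel in a :class:`pandas.DataFrame` indexed by locus.

A :class:`SexRegistry` maps sample IDs to phenotypic sex and exposes the
male/female column-index sets used throughout the screening code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

MISSING: int = -1

#: metadata columns every panel carries (``trimmed_sequence`` is optional)
META_COLUMNS = ("reproducibility", "avg_depth", "allele_balance", "call_rate")


class MarkerType(str, Enum):
    SNP = "SNP"
    PA = "PA"


class Sex(str, Enum):
    MALE = "MALE"
    FEMALE = "FEMALE"


class PanelError(ValueError):
    """Raised when a panel violates its structural invariants."""


@dataclass
class GenotypePanel:
    """Locus × individual genotype matrix with per-locus metadata.

    Parameters
    ----------
    marker_type
        SNP (codes 0/1/2) or PA (codes 0/1).
    loci
        Ordered, unique locus identifiers (file order is preserved).
    individuals
        Ordered, unique sample identifiers.
    calls
        ``int8`` array of shape ``(n_loci, n_individuals)``; ``-1`` = missing.
    locus_meta
        DataFrame indexed by locus with at least the columns in
        :data:`META_COLUMNS` (``allele_balance`` may be absent for PA panels).
    """

    marker_type: MarkerType
    loci: list[str]
    individuals: list[str]
    calls: np.ndarray
    locus_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.marker_type = MarkerType(self.marker_type)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.loci), len(self.individuals)):
            raise PanelError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.loci)} loci x {len(self.individuals)} individuals"
            )
        if len(set(self.loci)) != len(self.loci):
            dup = pd.Index(self.loci)
            raise PanelError(
                "duplicate locus IDs: "
                + ", ".join(sorted(dup[dup.duplicated()].unique()))
            )
        if len(set(self.individuals)) != len(self.individuals):
            raise PanelError("duplicate individual IDs")
        hi = 2 if self.marker_type is MarkerType.SNP else 1
        bad = (self.calls < MISSING) | (self.calls > hi)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise PanelError(
                f"illegal {self.marker_type.value} code {self.calls[i, j]} at "
                f"locus {self.loci[i]!r}, individual {self.individuals[j]!r}"
            )
        if not self.locus_meta.index.equals(pd.Index(self.loci)):
            raise PanelError("locus_meta index must equal the locus list, in order")

    # -- derived quantities -------------------------------------------------

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def observed_call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per locus."""
        return (self.calls != MISSING).mean(axis=1)

    def subset_loci(self, keep: np.ndarray | list) -> "GenotypePanel":
        """New panel restricted to ``keep`` (boolean mask or list of IDs)."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {l: i for i, l in enumerate(self.loci)}
            idx = np.array([pos[l] for l in keep], dtype=int)
        return GenotypePanel(
            marker_type=self.marker_type,
            loci=[self.loci[i] for i in idx],
            individuals=list(self.individuals),
            calls=self.calls[idx].copy(),
            locus_meta=self.locus_meta.iloc[idx].copy(),
        )

    def locus_calls(self, locus: str) -> np.ndarray:
        try:
            i = self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None
        return self.calls[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypePanel):
            return NotImplemented
        return (
            self.marker_type == other.marker_type
            and self.loci == other.loci
            and self.individuals == other.individuals
            and np.array_equal(self.calls, other.calls)
            and _meta_equal(self.locus_meta, other.locus_meta)
        )


def _meta_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    cols = sorted(set(a.columns) | set(b.columns))
    for c in cols:
        if c not in a.columns or c not in b.columns:
            return False
        va, vb = a[c], b[c]
        if va.dtype.kind == "f" and vb.dtype.kind == "f":
            if not np.allclose(va, vb, rtol=0, atol=1e-12, equal_nan=True):
                return False
        elif not va.fillna("").eq(vb.fillna("")).all():
            return False
    return True


@dataclass
class SexRegistry:
    """Phenotypic sex of every sample, with index sets relative to a panel order."""

    sex_of: dict[str, Sex]
    order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sex_of = {k: Sex(v) for k, v in self.sex_of.items()}
        if not self.order:
            self.order = list(self.sex_of)
        missing = [i for i in self.order if i not in self.sex_of]
        if missing:
            raise PanelError(f"individuals without a sex record: {missing}")
        if not self.male_ids or not self.female_ids:
            raise PanelError("both sexes must be non-empty")

    @property
    def male_ids(self) -> list[str]:
        return [i for i in self.order if self.sex_of[i] is Sex.MALE]

    @property
    def female_ids(self) -> list[str]:
        return [i for i in self.order if self.sex_of[i] is Sex.FEMALE]

    def indices(self, individuals: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """(male, female) column indices into ``individuals``.

        Raises if any panel individual lacks a sex record.
        """
        unknown = [i for i in individuals if i not in self.sex_of]
        if unknown:
            raise PanelError(f"individuals missing from sex table: {unknown}")
        males = np.array(
            [j for j, i in enumerate(individuals) if self.sex_of[i] is Sex.MALE],
            dtype=int,
        )
        females = np.array(
            [j for j, i in enumerate(individuals) if self.sex_of[i] is Sex.FEMALE],
            dtype=int,
        )
        return males, females

    def swapped(self) -> "SexRegistry":
        """Registry with every label flipped (used for symmetry checks)."""
        flip = {Sex.MALE: Sex.FEMALE, Sex.FEMALE: Sex.MALE}
        return SexRegistry({k: flip[v] for k, v in self.sex_of.items()}, list(self.order))
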