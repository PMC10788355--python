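"""Locus-level quality-control filtering of DArT-style panels.

Filters mirror the standard DArTsoft marker-quality screen: a locus is kept
only if it *strictly exceeds* every enabled threshold on reproducibility,
mean sequencing depth, SNP allele-count balance and call rate.  Rejections are
attributed to the first failing criterion in the fixed order
(reproducibility, depth, balance, call rate) so that the per-criterion counts
plus the kept count partition the input.

Reproducibility and call rate are fractions on [0, 1]; inputs scored on a
0–100 scale can be normalised with ``reproducibility_scale``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenotypePanel, MarkerType


class QCConfigError(ValueError):
    """A non-disabled threshold refers to a metadata field the panel lacks."""


#: attribution order for first-failure accounting
CRITERIA = ("reproducibility", "avg_depth", "allele_balance", "call_rate")


@dataclass
class QCThresholds:
    """Strict lower bounds on locus metadata; ``None`` disables a criterion.

    Defaults follow the conventional DArT screen: reproducibility > 0.95,
    depth > 5 reads, allele balance > 0.9, call rate > 0.8.
    """

    min_reproducibility: float | None = 0.95
    min_avg_depth: float | None = 5.0
    min_allele_balance: float | None = 0.9
    min_call_rate: float | None = 0.8
    #: divide the reproducibility column by this before comparing (e.g. 100)
    reproducibility_scale: float = 1.0

    def bound(self, criterion: str) -> float | None:
        return {
            "reproducibility": self.min_reproducibility,
            "avg_depth": self.min_avg_depth,
            "allele_balance": self.min_allele_balance,
            "call_rate": self.min_call_rate,
        }[criterion]


@dataclass
class QCReport:
    """Per-locus keep/reject table plus per-criterion first-failure counts."""

    table: pd.DataFrame  # columns: locus, kept, first_failed_criterion
    n_input: int
    n_kept: int
    rejected_by: dict[str, int]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def apply_qc(
    panel: GenotypePanel, thr: QCThresholds | None = None
) -> tuple[GenotypePanel, QCReport]:
    """Filter ``panel`` to loci strictly exceeding every enabled threshold.

    PA panels skip the allele-balance criterion when the metadata column is
    absent (balance is undefined for dominant markers).  The input panel is
    not modified.
    """
    thr = thr or QCThresholds()
    meta = panel.locus_meta
    n = panel.n_loci
    failed = np.full(n, "", dtype=object)
    keep = np.ones(n, dtype=bool)

    for crit in CRITERIA:
        bound = thr.bound(crit)
        if bound is None:
            continue
        if crit not in meta.columns:
            if crit == "allele_balance" and panel.marker_type is MarkerType.PA:
                continue
            raise QCConfigError(
                f"threshold on {crit!r} enabled but panel metadata has no such column"
            )
        values = meta[crit].to_numpy(dtype=float)
        if crit == "reproducibility" and thr.reproducibility_scale != 1.0:
            values = values / thr.reproducibility_scale
        fails = ~(values > bound)
        first = fails & keep
        failed[first] = crit
        keep &= ~fails

    table = pd.DataFrame(
        {
            "locus": panel.loci,
            "kept": keep,
            "first_failed_criterion": failed,
        }
    )
    rejected_by = {
        c: int(((failed == c)).sum()) for c in CRITERIA if (failed == c).any()
    }
    report = QCReport(
        table=table, n_input=n, n_kept=int(keep.sum()), rejected_by=rejected_by
    )
    return panel.subset_loci(keep), report
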