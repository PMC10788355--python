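"""Sex-conformity screening of SNP and presence/absence loci.

The screen asks, locus by locus, whether genotypes track phenotypic sex the
way a young sex chromosome would make them.  Under male heterogamety (XX/XY)
a Y-linked SNP keeps males heterozygous and females homozygous; a Y-borne
restriction fragment is present in males and absent in females (or the
mirror image for an X-borne fragment lost from the Y).  Female heterogamety
(ZZ/ZW) is the same picture with the sexes swapped.

For a threshold ``t`` (70, 80, 90 or 100 percent — the "30:70", "20:80",
"10:90", "0:100" female:male criteria under XY), a locus is a candidate when
at least ``t`` % of called heterogametic-sex individuals show the linked
state *and* at most ``100 − t`` % of called homogametic-sex individuals show
it.  Loci passing at 100 % are *sex-specific*; those passing only in the
70–90 % band are *sex-linked*.  Candidate sets therefore nest: the set at a
higher threshold is a subset of the set at any lower one.

``spurious_linkage`` gives the chance expectation used to judge the screen:
with n informative individuals the probability that every one of them
conforms by chance is :math:`P_i = 0.5^n`, and over L tested loci the
expected number of spuriously sex-specific loci is :math:`L \\cdot P_i`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel, MarkerType, SexRegistry

log = logging.getLogger(__name__)

THRESHOLDS = (70, 80, 90, 100)


class System(str, Enum):
    XY = "XY"  # male heterogamety (XX/XY)
    ZW = "ZW"  # female heterogamety (ZZ/ZW)


class Direction(str, Enum):
    HET_IN_HETEROGAMETIC = "HET_IN_HETEROGAMETIC"  # SNP
    PRESENT_IN_HETEROGAMETIC = "PRESENT_IN_HETEROGAMETIC"  # PA
    ABSENT_IN_HETEROGAMETIC = "ABSENT_IN_HETEROGAMETIC"  # PA


class Classification(str, Enum):
    SEX_SPECIFIC = "SEX_SPECIFIC"  # passed at 100 %
    SEX_LINKED = "SEX_LINKED"  # passed in the 70–90 % band


@dataclass(frozen=True)
class ScreenCriterion:
    system: System
    threshold_pct: int
    marker_type: MarkerType

    def __post_init__(self) -> None:
        if self.threshold_pct not in THRESHOLDS:
            raise ValueError(f"threshold_pct must be one of {THRESHOLDS}")


@dataclass
class Candidate:
    locus: str
    direction: Direction
    male_conformity: float
    female_conformity: float


@dataclass
class ScreenResult:
    criterion: ScreenCriterion
    candidates: list[Candidate]
    classification: Classification
    n_screened: int = 0
    skipped_loci: list[str] = field(default_factory=list)

    @property
    def locus_ids(self) -> set[str]:
        return {c.locus for c in self.candidates}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus": [c.locus for c in self.candidates],
                "system": self.criterion.system.value,
                "marker_type": self.criterion.marker_type.value,
                "threshold": self.criterion.threshold_pct,
                "direction": [c.direction.value for c in self.candidates],
                "male_conformity": [c.male_conformity for c in self.candidates],
                "female_conformity": [c.female_conformity for c in self.candidates],
                "classification": self.classification.value,
            }
        )


@dataclass
class SpuriousLinkage:
    """Chance expectation of fully sex-conforming loci."""

    n: int
    L: int
    P_i: float
    expected_count: float


def admissible_directions(
    marker_type: MarkerType, include_absent: bool = False
) -> tuple[Direction, ...]:
    """SNP loci are tested for heterogametic heterozygosity only.

    PA loci default to the presence direction: a dominant fragment specific
    to the heterogametic sex can only manifest as *present* there (the
    homogametic chromosome's copy keeps the fragment visible otherwise), and
    a fully sex-divided fragment is mirror-symmetric — it would pass the
    opposite system's screen in the ABSENT direction, making the two systems
    indistinguishable on PA markers.  ``include_absent=True`` adds the ABSENT
    direction for exploratory screens.
    """
    if MarkerType(marker_type) is MarkerType.SNP:
        return (Direction.HET_IN_HETEROGAMETIC,)
    if include_absent:
        return (Direction.PRESENT_IN_HETEROGAMETIC, Direction.ABSENT_IN_HETEROGAMETIC)
    return (Direction.PRESENT_IN_HETEROGAMETIC,)


def _conforming_masks(
    calls: np.ndarray, marker_type: MarkerType, direction: Direction
) -> tuple[np.ndarray, np.ndarray]:
    """(heterogametic-conforming, homogametic-conforming) boolean masks."""
    direction = Direction(direction)
    if MarkerType(marker_type) is MarkerType.SNP:
        if direction is not Direction.HET_IN_HETEROGAMETIC:
            raise ValueError(f"direction {direction} undefined for SNP loci")
        return calls == 1, (calls == 0) | (calls == 2)
    if direction is Direction.PRESENT_IN_HETEROGAMETIC:
        return calls == 1, calls == 0
    if direction is Direction.ABSENT_IN_HETEROGAMETIC:
        return calls == 0, calls == 1
    raise ValueError(direction)


def conformity(
    panel: GenotypePanel,
    sexes: SexRegistry,
    locus: str,
    system: System,
    direction: Direction | None = None,
) -> tuple[float, float]:
    """(male_conformity, female_conformity) for one locus.

    Conformity of a sex is the fraction of its *called* individuals in the
    state the hypothesised system predicts for that sex.  A sex with zero
    calls yields NaN for that side (the screen skips such loci).
    ``direction`` defaults to the SNP heterozygosity direction /
    PA presence direction.
    """
    system = System(system)
    if direction is None:
        direction = admissible_directions(panel.marker_type)[0]
    calls = panel.locus_calls(locus)
    males, females = sexes.indices(panel.individuals)
    het_conf, hom_conf = _conforming_masks(calls, panel.marker_type, direction)
    het_idx, hom_idx = (males, females) if system is System.XY else (females, males)
    called = calls != MISSING

    def frac(conf_mask: np.ndarray, idx: np.ndarray) -> float:
        n_called = int(called[idx].sum())
        if n_called == 0:
            log.warning("locus %s: no calls in one sex; conformity undefined", locus)
            return math.nan
        return float((conf_mask[idx] & called[idx]).sum() / n_called)

    het_c = frac(het_conf, het_idx)
    hom_c = frac(hom_conf, hom_idx)
    return (het_c, hom_c) if system is System.XY else (hom_c, het_c)


def screen(
    panel: GenotypePanel,
    sexes: SexRegistry,
    criterion: ScreenCriterion,
    min_calls_per_sex: int = 8,
    include_absent: bool = False,
) -> ScreenResult:
    """All candidate loci of ``panel`` under ``criterion``.

    A locus is a candidate iff for some admissible direction the
    heterogametic-sex conformity is ≥ ``threshold_pct``/100 and the
    homogametic-sex nonconformity is ≤ (100 − ``threshold_pct``)/100.
    Comparisons are done in integer arithmetic (counts × 100 vs threshold ×
    denominators), so boundary cases are exact.  Loci with fewer than
    ``min_calls_per_sex`` calls in either sex are skipped.
    """
    if panel.marker_type is not criterion.marker_type:
        raise ValueError(
            f"panel is {panel.marker_type.value}, criterion expects "
            f"{criterion.marker_type.value}"
        )
    t = criterion.threshold_pct
    males, females = sexes.indices(panel.individuals)
    het_idx, hom_idx = (
        (males, females) if criterion.system is System.XY else (females, males)
    )
    called = panel.calls != MISSING
    n_called_het = called[:, het_idx].sum(axis=1)
    n_called_hom = called[:, hom_idx].sum(axis=1)
    enough = (n_called_het >= min_calls_per_sex) & (n_called_hom >= min_calls_per_sex)
    skipped = [l for l, ok in zip(panel.loci, enough) if not ok]
    if skipped:
        log.info(
            "%d loci skipped (< %d calls in a sex)", len(skipped), min_calls_per_sex
        )

    candidates: list[Candidate] = []
    claimed = np.zeros(panel.n_loci, dtype=bool)
    for direction in admissible_directions(panel.marker_type, include_absent):
        het_conf, hom_conf = _conforming_masks(
            panel.calls, panel.marker_type, direction
        )
        c_het = (het_conf & called)[:, het_idx].sum(axis=1)
        c_hom = (hom_conf & called)[:, hom_idx].sum(axis=1)
        # het-sex conformity >= t/100  AND  hom-sex nonconformity <= (100-t)/100,
        # the latter being equivalent to hom-sex conformity >= t/100
        hit = (
            enough
            & ~claimed
            & (100 * c_het >= t * n_called_het)
            & (100 * c_hom >= t * n_called_hom)
        )
        for i in np.flatnonzero(hit):
            het_c = c_het[i] / n_called_het[i]
            hom_c = c_hom[i] / n_called_hom[i]
            male_c, female_c = (
                (het_c, hom_c) if criterion.system is System.XY else (hom_c, het_c)
            )
            candidates.append(
                Candidate(panel.loci[i], direction, float(male_c), float(female_c))
            )
        claimed |= hit

    classification = (
        Classification.SEX_SPECIFIC if t == 100 else Classification.SEX_LINKED
    )
    return ScreenResult(
        criterion=criterion,
        candidates=candidates,
        classification=classification,
        n_screened=int(enough.sum()),
        skipped_loci=skipped,
    )


def spurious_linkage(n: int, L: int) -> SpuriousLinkage:
    """Chance expectation of fully sex-conforming ("sex-specific") loci.

    ``n`` informative individuals each conform by chance with probability
    0.5, so P_i = 0.5**n exactly; over ``L`` loci the expected count is
    L * P_i.
    """
    if n < 1 or L < 1:
        raise ValueError("n and L must be positive")
    p = 0.5**n
    return SpuriousLinkage(n=n, L=L, P_i=p, expected_count=L * p)


@dataclass
class SystemCall:
    """Outcome of comparing XY- vs ZW-oriented candidate tallies."""

    system: str  # "XY", "ZW" or "inconclusive"
    counts: pd.DataFrame  # rows: system, columns: threshold, values: counts
    xy_linked_total: int
    zw_linked_total: int


def infer_system(results: list[ScreenResult]) -> SystemCall:
    """Call the sex-determination system from screens run for both systems.

    The sex-linked band (70–90 %) is compared: the system whose candidate
    locus union is larger wins; equal (including both-zero) unions are
    declared inconclusive rather than silently broken.
    """
    counts: dict[tuple[str, int], int] = {}
    union: dict[System, set[str]] = {System.XY: set(), System.ZW: set()}
    for res in results:
        key = (res.criterion.system.value, res.criterion.threshold_pct)
        counts[key] = counts.get(key, 0) + len(res.candidates)
        if res.criterion.threshold_pct < 100:
            union[res.criterion.system] |= res.locus_ids
    thresholds = sorted({k[1] for k in counts})
    table = pd.DataFrame(
        {t: [counts.get((s, t), 0) for s in ("XY", "ZW")] for t in thresholds},
        index=["XY", "ZW"],
    )
    nx, nz = len(union[System.XY]), len(union[System.ZW])
    if nx == nz:  # covers both-zero
        call = "inconclusive"
    else:
        call = "XY" if nx > nz else "ZW"
    return SystemCall(
        system=call, counts=table, xy_linked_total=nx, zw_linked_total=nz
    )
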