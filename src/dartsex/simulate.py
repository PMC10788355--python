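"""Full-sib family genotype simulator with known sex-linkage ground truth.

The generator emulates the study design this package is built for: a single
full-sib family of 32 balanced-sex offspring genotyped at tens of thousands
of DArT-style SNP and presence/absence loci, of which a small planted
minority tracks phenotypic sex.

Autosomal loci are Mendelian: per locus an alternate-allele (or fragment-
allele) frequency is drawn from Uniform(0.05, 0.95), two parents are sampled
from Hardy-Weinberg proportions at that frequency, and each offspring
receives one random allele from each parent.  PA loci are scored dominantly
(present iff at least one fragment allele).

Sex-linked loci are simulated marginally (no recombination map): an
individual of the heterogametic sex shows the linked state (SNP
heterozygosity / fragment presence or absence) with probability
``penetrance``; a homogametic individual shows it with probability
``leakage``.  Missing calls are applied i.i.d. at ``missing_rate``.  Locus
metadata are sampled within configured ranges except the call rate, which is
the realised non-missing fraction of the emitted matrix.

Everything is driven by one :class:`numpy.random.Generator` seeded from
``SimConfig.seed``, so a run is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel, MarkerType, Sex, SexRegistry
from .screen import Direction, System


@dataclass
class SimConfig:
    """Study-design and noise parameters of the simulated family."""

    n_males: int = 16
    n_females: int = 16
    n_snp_auto: int = 1000
    n_pa_auto: int = 1000
    n_snp_linked: int = 15
    n_pa_linked: int = 48
    system: System = System.XY
    #: P(heterogametic individual shows the linked state at a linked locus)
    penetrance: float = 0.9
    #: P(homogametic individual shows it)
    leakage: float = 0.05
    missing_rate: float = 0.05
    #: fraction of planted PA loci linked in the ABSENT direction (dominant
    #: heterogametic-specific fragments manifest as PRESENT, so 0 by default)
    pa_absent_fraction: float = 0.0
    reproducibility_range: tuple[float, float] = (0.96, 1.0)
    depth_range: tuple[float, float] = (6.0, 40.0)
    balance_range: tuple[float, float] = (0.92, 1.0)
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        self.system = System(self.system)
        if self.n_males < 1 or self.n_females < 1:
            raise ValueError("both sexes need at least one individual")
        for name in ("penetrance", "leakage", "missing_rate", "pa_absent_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if min(
            self.n_snp_auto, self.n_pa_auto, self.n_snp_linked, self.n_pa_linked
        ) < 0:
            raise ValueError("locus counts must be non-negative")


@dataclass
class SimTruth:
    """Ground truth of a simulated run, one row per locus.

    Columns: ``marker_type``, ``is_linked``, ``direction`` and the realised
    ``male_conformity`` / ``female_conformity`` (computed from the emitted
    panel under the locus's screening direction, missing calls excluded).
    """

    table: pd.DataFrame

    def linked_loci(self, marker_type: MarkerType | None = None) -> list[str]:
        t = self.table
        mask = t["is_linked"]
        if marker_type is not None:
            mask = mask & (t["marker_type"] == MarkerType(marker_type).value)
        return list(t.index[mask])


def _mendelian_codes(
    rng: np.random.Generator, n_loci: int, n_ind: int, freq_range: tuple[float, float]
) -> np.ndarray:
    """Offspring alt-allele counts (0/1/2) for autosomal loci of one family."""
    q = rng.uniform(*freq_range, size=n_loci)
    parent_alleles = rng.random((n_loci, 2, 2)) < q[:, None, None]  # (locus, parent, chrom)
    pick = rng.integers(0, 2, size=(n_loci, 2, n_ind))  # which parental chromosome
    sire = np.take_along_axis(parent_alleles[:, 0, :], pick[:, 0, :], axis=1)
    dam = np.take_along_axis(parent_alleles[:, 1, :], pick[:, 1, :], axis=1)
    return (sire.astype(np.int8) + dam.astype(np.int8))


def _linked_state(
    rng: np.random.Generator,
    n_loci: int,
    het_idx: np.ndarray,
    hom_idx: np.ndarray,
    n_ind: int,
    penetrance: float,
    leakage: float,
) -> np.ndarray:
    """Boolean matrix: individual shows the linked state at a linked locus."""
    show = np.zeros((n_loci, n_ind), dtype=bool)
    show[:, het_idx] = rng.random((n_loci, het_idx.size)) < penetrance
    show[:, hom_idx] = rng.random((n_loci, hom_idx.size)) < leakage
    return show


def _sample_meta(
    rng: np.random.Generator, cfg: SimConfig, loci: list[str], calls: np.ndarray,
    with_balance: bool,
) -> pd.DataFrame:
    n = len(loci)
    meta = {
        "reproducibility": rng.uniform(*cfg.reproducibility_range, size=n),
        "avg_depth": rng.uniform(*cfg.depth_range, size=n),
    }
    if with_balance:
        meta["allele_balance"] = rng.uniform(*cfg.balance_range, size=n)
    meta["call_rate"] = (calls != MISSING).mean(axis=1)
    return pd.DataFrame(meta, index=pd.Index(loci))


def _realized_conformity(
    calls: np.ndarray, het_idx: np.ndarray, hom_idx: np.ndarray,
    marker_type: MarkerType, direction: Direction,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus conformity fractions of the (het, hom) sexes, NaN if no calls."""
    if marker_type is MarkerType.SNP:
        het_state, hom_state = calls == 1, (calls == 0) | (calls == 2)
    elif direction is Direction.PRESENT_IN_HETEROGAMETIC:
        het_state, hom_state = calls == 1, calls == 0
    else:
        het_state, hom_state = calls == 0, calls == 1
    called = calls != MISSING
    with np.errstate(invalid="ignore"):
        het_c = (het_state & called)[:, het_idx].sum(1) / called[:, het_idx].sum(1)
        hom_c = (hom_state & called)[:, hom_idx].sum(1) / called[:, hom_idx].sum(1)
    return het_c, hom_c


def simulate_family(
    cfg: SimConfig,
) -> tuple[GenotypePanel, GenotypePanel, SexRegistry, SimTruth]:
    """Simulate one full-sib family; returns (snp_panel, pa_panel, sexes, truth)."""
    rng = np.random.default_rng(cfg.seed)
    males = [f"M{i + 1:02d}" for i in range(cfg.n_males)]
    females = [f"F{i + 1:02d}" for i in range(cfg.n_females)]
    individuals = males + females
    n_ind = len(individuals)
    sexes = SexRegistry(
        {**{m: Sex.MALE for m in males}, **{f: Sex.FEMALE for f in females}},
        individuals,
    )
    male_idx = np.arange(cfg.n_males)
    female_idx = np.arange(cfg.n_males, n_ind)
    het_idx, hom_idx = (
        (male_idx, female_idx) if cfg.system is System.XY else (female_idx, male_idx)
    )

    panels: dict[MarkerType, GenotypePanel] = {}
    truth_rows: list[pd.DataFrame] = []
    for mt, n_auto, n_linked in (
        (MarkerType.SNP, cfg.n_snp_auto, cfg.n_snp_linked),
        (MarkerType.PA, cfg.n_pa_auto, cfg.n_pa_linked),
    ):
        auto = _mendelian_codes(rng, n_auto, n_ind, cfg.allele_freq_range)
        if mt is MarkerType.PA:
            auto = (auto > 0).astype(np.int8)
        show = _linked_state(
            rng, n_linked, het_idx, hom_idx, n_ind, cfg.penetrance, cfg.leakage
        )
        if mt is MarkerType.SNP:
            linked = np.where(show, 1, 0).astype(np.int8)
            directions = [Direction.HET_IN_HETEROGAMETIC] * n_linked
        else:
            n_absent = int(round(cfg.pa_absent_fraction * n_linked))
            directions = [Direction.ABSENT_IN_HETEROGAMETIC] * n_absent + [
                Direction.PRESENT_IN_HETEROGAMETIC
            ] * (n_linked - n_absent)
            linked = np.empty((n_linked, n_ind), dtype=np.int8)
            for i, d in enumerate(directions):
                state = show[i]
                linked[i] = (
                    state if d is Direction.PRESENT_IN_HETEROGAMETIC else ~state
                ).astype(np.int8)

        calls = np.vstack([auto, linked]) if n_linked else auto
        n_loci = calls.shape[0]
        is_linked = np.zeros(n_loci, dtype=bool)
        is_linked[n_auto:] = True
        dir_col: list[str | None] = [None] * n_auto + [d.value for d in directions]

        # intersperse planted loci among autosomes, deterministically
        perm = rng.permutation(n_loci)
        calls = calls[perm]
        is_linked = is_linked[perm]
        dir_col = [dir_col[i] for i in perm]

        if cfg.missing_rate > 0:
            calls = np.where(
                rng.random(calls.shape) < cfg.missing_rate, MISSING, calls
            ).astype(np.int8)

        prefix = "SNP" if mt is MarkerType.SNP else "PA"
        loci = [f"{prefix}{i + 1:07d}" for i in range(n_loci)]
        meta = _sample_meta(rng, cfg, loci, calls, with_balance=mt is MarkerType.SNP)
        panels[mt] = GenotypePanel(
            marker_type=mt,
            loci=loci,
            individuals=individuals,
            calls=calls,
            locus_meta=meta,
        )

        screen_dir = [
            Direction(d) if d is not None
            else (Direction.HET_IN_HETEROGAMETIC if mt is MarkerType.SNP
                  else Direction.PRESENT_IN_HETEROGAMETIC)
            for d in dir_col
        ]
        het_c = np.empty(n_loci)
        hom_c = np.empty(n_loci)
        for d in set(screen_dir):
            rows = np.array([i for i, sd in enumerate(screen_dir) if sd is d])
            hc, oc = _realized_conformity(calls[rows], het_idx, hom_idx, mt, d)
            het_c[rows] = hc
            hom_c[rows] = oc
        male_c, female_c = (
            (het_c, hom_c) if cfg.system is System.XY else (hom_c, het_c)
        )
        truth_rows.append(
            pd.DataFrame(
                {
                    "marker_type": mt.value,
                    "is_linked": is_linked,
                    "direction": [d.value for d in screen_dir],
                    "male_conformity": male_c,
                    "female_conformity": female_c,
                },
                index=pd.Index(loci, name="locus"),
            )
        )

    truth = SimTruth(pd.concat(truth_rows))
    return panels[MarkerType.SNP], panels[MarkerType.PA], sexes, truth


#: study-scale dimensions: 20,129 SNP and 17,025 PA loci in 32 individuals,
#: with 15 SNP + 48 PA planted male-linked loci
STUDY_PRESET = SimConfig(
    n_males=16,
    n_females=16,
    n_snp_auto=20_129 - 15,
    n_pa_auto=17_025 - 48,
    n_snp_linked=15,
    n_pa_linked=48,
    system=System.XY,
    penetrance=0.9,
    leakage=0.05,
    missing_rate=0.05,
)


def emulate_study_scale(
    seed: int = 0, **overrides
) -> tuple[GenotypePanel, GenotypePanel, SexRegistry, SimTruth]:
    """Simulate panels at the full study scale (20,129 SNP + 17,025 PA × 32).

    Keyword overrides replace preset fields (e.g. ``penetrance=1.0``).
    """
    cfg = replace(STUDY_PRESET, seed=seed, **overrides)
    return simulate_family(cfg)


def write_simulation(outdir, snp, pa, sexes, truth) -> dict[str, str]:
    """Write simulated panels, sex table and truth as the CSVs the readers consume."""
    import os

    from .io import write_panel

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "snp": os.path.join(outdir, "snp_report.csv"),
        "pa": os.path.join(outdir, "pa_report.csv"),
        "sex": os.path.join(outdir, "sex_table.csv"),
        "truth": os.path.join(outdir, "sim_truth.csv"),
    }
    write_panel(snp, paths["snp"])
    write_panel(pa, paths["pa"])
    with open(paths["sex"], "w", encoding="utf-8") as fh:
        fh.write("id,sex\n")
        for ind in sexes.order:
            fh.write(f"{ind},{'M' if sexes.sex_of[ind] is Sex.MALE else 'F'}\n")
    truth.table.to_csv(paths["truth"])
    return paths
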