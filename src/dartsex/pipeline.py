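"""End-to-end orchestration: QC → dual-system screening → association
statistics → distances/PCoA → optional chromosome mapping.

A run is fully described by a :class:`RunConfig` (usually loaded from YAML)
and writes a deterministic bundle of CSV/JSON artefacts plus a plain-text
summary into the output directory.  Input panels are either read from DArT
reports or simulated in-process when a ``sim`` section is present.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version

import numpy as np
import pandas as pd
import yaml

from . import distance as dist
from . import io as gio
from . import screen as scr
from . import stats as st
from .chrommap import chromosome_tally, filter_hits, parse_blast_tab
from .panel import GenotypePanel, MarkerType, SexRegistry
from .qc import QCThresholds, apply_qc
from .simulate import SimConfig, simulate_family

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    outdir: str = "dartsex_out"
    seed: int = 0
    # inputs — either file paths ...
    snp_path: str | None = None
    pa_path: str | None = None
    sex_path: str | None = None
    snp_dialect: str = "one_row"
    male_token: str = "M"
    female_token: str = "F"
    # ... or an in-process simulation
    sim: SimConfig | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    systems: tuple[str, ...] = ("XY", "ZW")
    thresholds: tuple[int, ...] = scr.THRESHOLDS
    min_calls_per_sex: int = 8
    # optional chromosome mapping inputs
    blast_path: str | None = None
    assembly_map_path: str | None = None
    min_identity: float = 95.0
    min_len: int = 65

    def validate(self) -> None:
        if self.sim is None:
            for name in ("snp_path", "pa_path", "sex_path"):
                p = getattr(self, name)
                if p is None:
                    raise ConfigError(f"{name} required when no sim section is given")
                if not os.path.exists(p):
                    raise ConfigError(f"{name}: file not found: {p}")
        for p in (self.blast_path, self.assembly_map_path):
            if p is not None and not os.path.exists(p):
                raise ConfigError(f"file not found: {p}")
        bad = [t for t in self.thresholds if t not in scr.THRESHOLDS]
        if bad:
            raise ConfigError(f"unsupported thresholds: {bad}")


def load_config(path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    io_sec = raw.get("io", {})
    qc_sec = raw.get("qc", {})
    screen_sec = raw.get("screen", {})
    map_sec = raw.get("map", {})
    sim_sec = raw.get("sim")
    try:
        cfg = RunConfig(
            outdir=raw.get("out", "dartsex_out"),
            seed=int(raw.get("seed", 0)),
            snp_path=io_sec.get("snp"),
            pa_path=io_sec.get("pa"),
            sex_path=io_sec.get("sex"),
            snp_dialect=io_sec.get("snp_dialect", "one_row"),
            male_token=io_sec.get("male_token", "M"),
            female_token=io_sec.get("female_token", "F"),
            sim=SimConfig(**sim_sec) if sim_sec is not None else None,
            qc=QCThresholds(**qc_sec),
            systems=tuple(screen_sec.get("systems", ("XY", "ZW"))),
            thresholds=tuple(screen_sec.get("thresholds", scr.THRESHOLDS)),
            min_calls_per_sex=int(screen_sec.get("min_calls_per_sex", 8)),
            blast_path=map_sec.get("blast"),
            assembly_map_path=map_sec.get("assembly_map"),
            min_identity=float(map_sec.get("min_identity", 95.0)),
            min_len=int(map_sec.get("min_len", 65)),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return cfg


@dataclass
class RunBundle:
    """In-memory results of a run plus the paths of everything written."""

    config: RunConfig
    snp_panel: GenotypePanel
    pa_panel: GenotypePanel
    sexes: SexRegistry
    screens: list[scr.ScreenResult]
    system_call: scr.SystemCall
    spurious: scr.SpuriousLinkage
    association: pd.DataFrame
    distance_summary: pd.DataFrame
    files: dict[str, str] = field(default_factory=dict)


def _load_panels(
    cfg: RunConfig,
) -> tuple[GenotypePanel, GenotypePanel, SexRegistry]:
    if cfg.sim is not None:
        sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.sim.seed or cfg.seed)
        snp, pa, sexes, _truth = simulate_family(sim_cfg)
        return snp, pa, sexes
    snp = gio.read_snp_report(cfg.snp_path, dialect=cfg.snp_dialect)
    pa = gio.read_pa_report(cfg.pa_path)
    sexes = gio.read_sex_table(
        cfg.sex_path, male_token=cfg.male_token, female_token=cfg.female_token
    )
    return snp, pa, sexes


def run(cfg: RunConfig) -> RunBundle:
    """Execute the full pipeline and write the report bundle to ``cfg.outdir``."""
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    files: dict[str, str] = {}

    def out(name: str) -> str:
        p = os.path.join(cfg.outdir, name)
        files[name] = p
        return p

    snp_raw, pa_raw, sexes = _load_panels(cfg)

    # --- QC ---------------------------------------------------------------
    snp, snp_qc = apply_qc(snp_raw, cfg.qc)
    pa, pa_qc = apply_qc(pa_raw, cfg.qc)
    snp_qc.to_csv(out("qc_snp.csv"))
    pa_qc.to_csv(out("qc_pa.csv"))

    # --- screening, both systems, all thresholds --------------------------
    screens: list[scr.ScreenResult] = []
    for system in cfg.systems:
        for t in cfg.thresholds:
            for panel in (snp, pa):
                crit = scr.ScreenCriterion(
                    scr.System(system), t, panel.marker_type
                )
                screens.append(
                    scr.screen(panel, sexes, crit, cfg.min_calls_per_sex)
                )
    frames = [r.to_frame() for r in screens]
    screen_table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame()
    )
    screen_table.to_csv(out("screen_results.csv"), index=False)

    system_call = scr.infer_system(screens)
    spurious = scr.spurious_linkage(
        n=snp.n_individuals, L=snp.n_loci + pa.n_loci
    )

    # --- association statistics on the candidate union --------------------
    assoc_parts = []
    for panel in (snp, pa):
        loci = sorted(
            {
                c.locus
                for r in screens
                if r.criterion.marker_type is panel.marker_type
                for c in r.candidates
            },
            key=panel.loci.index if panel.loci else None,
        )
        if loci:
            part = st.association_table(panel, sexes, loci)
            part.insert(0, "marker_type", panel.marker_type.value)
            assoc_parts.append(part)
    association = (
        pd.concat(assoc_parts)
        if assoc_parts
        else pd.DataFrame(columns=["marker_type", "catt_chi2", "catt_p", "pic"])
    )
    association.to_csv(out("association.csv"))

    # --- distances / ordination / index matrices per criterion ------------
    dist_rows = []
    for r in screens:
        if not r.candidates:
            continue
        panel = snp if r.criterion.marker_type is MarkerType.SNP else pa
        loci = [c.locus for c in r.candidates]
        dm = dist.hamming(panel, loci)
        summary = dist.sex_distance_summary(dm, sexes)
        tag = (
            f"{r.criterion.system.value.lower()}"
            f"_{r.criterion.threshold_pct}_{r.criterion.marker_type.value.lower()}"
        )
        for stratum, s in summary.items():
            dist_rows.append(
                {
                    "system": r.criterion.system.value,
                    "threshold": r.criterion.threshold_pct,
                    "marker_type": r.criterion.marker_type.value,
                    "stratum": stratum,
                    **s,
                }
            )
        dist.genotype_index_matrix(panel, loci, sexes).to_csv(
            out(f"index_{tag}.csv"), na_rep="-"
        )
        if not np.isnan(dm.d).any():
            res = dist.pcoa(dm, k=2)
            res.coordinates.to_csv(out(f"pcoa_{tag}.csv"))
    distance_summary = pd.DataFrame(dist_rows)
    distance_summary.to_csv(out("distance_summary.csv"), index=False)

    # --- optional chromosome mapping ---------------------------------------
    if cfg.blast_path and cfg.assembly_map_path:
        hits = parse_blast_tab(cfg.blast_path)
        best, unmapped = filter_hits(hits, cfg.min_identity, cfg.min_len)
        amap = _read_assembly_map(cfg.assembly_map_path)
        tally = chromosome_tally(best, amap, unmapped)
        pd.Series(tally.per_chromosome, name="n_loci").rename_axis(
            "chromosome"
        ).to_csv(out("chromosome_tally.csv"))
        files["chromosome_tally_totals"] = out("chromosome_tally_totals.json")
        with open(files["chromosome_tally_totals"], "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "n_mapped": tally.n_mapped,
                    "n_unmapped": tally.n_unmapped,
                    "n_chromosomes_hit": tally.n_chromosomes_hit,
                },
                fh,
                indent=2,
            )

    bundle = RunBundle(
        config=cfg,
        snp_panel=snp,
        pa_panel=pa,
        sexes=sexes,
        screens=screens,
        system_call=system_call,
        spurious=spurious,
        association=association,
        distance_summary=distance_summary,
        files=files,
    )

    with open(out("summary.txt"), "w", encoding="utf-8") as fh:
        fh.write(summarize(bundle))
    _write_manifest(cfg, out("manifest.json"))
    return bundle


def _read_assembly_map(path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ConfigError(f"{path}: expected two columns (subject ID, chromosome)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def _write_manifest(cfg: RunConfig, path) -> None:
    def plain(obj):
        if hasattr(obj, "value"):  # enums
            return obj.value
        return str(obj)

    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=plain)
    manifest = {
        "package": "dartsex",
        "version": _pkg_version("dartsex"),
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "config": json.loads(blob),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)


def summarize(bundle: RunBundle) -> str:
    """One-page plain-text summary of a run."""
    lines = [
        "dartsex run summary",
        "===================",
        f"individuals: {bundle.snp_panel.n_individuals} "
        f"({len(bundle.sexes.male_ids)} M / {len(bundle.sexes.female_ids)} F)",
        f"loci after QC: {bundle.snp_panel.n_loci} SNP, {bundle.pa_panel.n_loci} PA",
        "",
        "candidate loci per criterion:",
    ]
    for r in bundle.screens:
        c = r.criterion
        lines.append(
            f"  {c.system.value} {c.threshold_pct:>3}% {c.marker_type.value:<3}: "
            f"{len(r.candidates)} ({r.classification.value})"
        )
    sp = bundle.spurious
    observed_specific = sum(
        len(r.candidates) for r in bundle.screens if r.criterion.threshold_pct == 100
    )
    lines += [
        "",
        f"sex-determination system call: {bundle.system_call.system}"
        f" (XY linked union {bundle.system_call.xy_linked_total},"
        f" ZW linked union {bundle.system_call.zw_linked_total})",
        f"spurious sex-specific expectation: P_i = {sp.P_i:.3g} over {sp.L} loci"
        f" -> {sp.expected_count:.3g} expected; observed sex-specific candidates:"
        f" {observed_specific}",
        "",
    ]
    return "\n".join(lines)
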