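"""Readers/writers for DArT-style genotype reports and the sex-phenotype table.

All files are plain comma-separated UTF-8 with a header row.  Two SNP report
dialects are supported:

* ``one_row`` — one row per locus, cells already coded 0/1/2;
* ``two_row`` — two consecutive rows per locus (reference-allele score then
  alternate-allele score, each 0/1), the format DArT commonly distributes.
  Pairs collapse as (1,0)→0, (1,1)→1, (0,1)→2; a double-missing pair is
  missing; any other pair is malformed.

PA (silicoDArT) reports are single-row 0/1.  Missing cells may be written as
``-``, ``NA`` or an empty string; ``-`` is emitted on write.  Column names
follow common DArT conventions and are overridable via :class:`ReportColumns`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel, MarkerType, PanelError, Sex, SexRegistry

MISSING_TOKENS = {"-", "NA", ""}
MISSING_OUT = "-"

#: legal two-row (ref_score, alt_score) pairs -> SNP code
TWO_ROW_COLLAPSE = {(1, 0): 0, (1, 1): 1, (0, 1): 2}
TWO_ROW_EXPAND = {v: k for k, v in TWO_ROW_COLLAPSE.items()}


class ReportFormatError(PanelError):
    """Malformed genotype report (bad symbol, odd pairing, missing column)."""


@dataclass
class ReportColumns:
    """Column-name conventions of the input reports (DArT defaults)."""

    locus_id: str = "CloneID"
    allele_id: str = "AlleleID"  # two_row dialect only
    reproducibility: str = "RepAvg"
    avg_depth: str = "AvgCountRef"
    allele_balance: str = "AlleleCountBalance"
    call_rate: str = "CallRate"
    trimmed_sequence: str = "TrimmedSequence"

    def meta_map(self, marker_type: MarkerType) -> dict[str, str]:
        m = {
            "reproducibility": self.reproducibility,
            "avg_depth": self.avg_depth,
            "call_rate": self.call_rate,
        }
        if marker_type is MarkerType.SNP:
            m["allele_balance"] = self.allele_balance
        return m


def _parse_cell(token: str, legal: tuple[int, ...], row: int, col: str) -> int:
    token = token.strip()
    if token in MISSING_TOKENS:
        return MISSING
    try:
        v = int(token)
    except ValueError:
        v = None
    if v not in legal:
        raise ReportFormatError(
            f"unknown call symbol {token!r} at row {row}, column {col!r}"
        )
    return v


def _split_columns(
    header: list[str], cols: ReportColumns, marker_type: MarkerType, two_row: bool
) -> tuple[dict[str, str], list[str]]:
    """Return (internal meta name -> file column, sample columns)."""
    if cols.locus_id not in header:
        raise ReportFormatError(f"locus ID column {cols.locus_id!r} not in header")
    known = {cols.locus_id}
    if two_row and cols.allele_id in header:
        known.add(cols.allele_id)
    meta = {}
    for internal, name in cols.meta_map(marker_type).items():
        if name in header:
            meta[internal] = name
            known.add(name)
    if cols.trimmed_sequence in header:
        meta["trimmed_sequence"] = cols.trimmed_sequence
        known.add(cols.trimmed_sequence)
    samples = [h for h in header if h not in known]
    if not samples:
        raise ReportFormatError("no sample columns found")
    return meta, samples


def _build_meta(
    rows: list[dict], loci: list[str], meta_cols: dict[str, str]
) -> pd.DataFrame:
    data: dict[str, list] = {}
    for internal, name in meta_cols.items():
        if internal == "trimmed_sequence":
            data[internal] = [r[name] for r in rows]
        else:
            data[internal] = [float(r[name]) for r in rows]
    return pd.DataFrame(data, index=pd.Index(loci))


def read_snp_report(
    path, dialect: str = "one_row", columns: ReportColumns | None = None
) -> GenotypePanel:
    """Read a SNP genotype report into a panel.

    ``dialect`` is ``"one_row"`` (cells 0/1/2) or ``"two_row"`` (consecutive
    reference/alternate score rows per locus, collapsed to 0/1/2).
    """
    if dialect not in ("one_row", "two_row"):
        raise ValueError(f"unknown dialect {dialect!r}")
    cols = columns or ReportColumns()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ReportFormatError(f"{path}: empty file")
        meta_cols, samples = _split_columns(
            list(reader.fieldnames), cols, MarkerType.SNP, dialect == "two_row"
        )
        rows = list(reader)

    loci: list[str] = []
    calls: list[list[int]] = []
    kept_rows: list[dict] = []
    seen: set[str] = set()

    if dialect == "one_row":
        for rnum, r in enumerate(rows, start=2):
            locus = r[cols.locus_id]
            if locus in seen:
                raise ReportFormatError(f"duplicate locus ID {locus!r}")
            seen.add(locus)
            loci.append(locus)
            kept_rows.append(r)
            calls.append([_parse_cell(r[s], (0, 1, 2), rnum, s) for s in samples])
    else:
        i = 0
        while i < len(rows):
            ref = rows[i]
            locus = ref[cols.locus_id]
            if i + 1 >= len(rows) or rows[i + 1][cols.locus_id] != locus:
                raise ReportFormatError(
                    f"locus {locus!r}: expected a reference/alternate row pair"
                )
            alt = rows[i + 1]
            if locus in seen:
                raise ReportFormatError(f"duplicate locus ID {locus!r}")
            seen.add(locus)
            loci.append(locus)
            kept_rows.append(ref)
            row_codes = []
            for s in samples:
                a = _parse_cell(ref[s], (0, 1), i + 2, s)
                b = _parse_cell(alt[s], (0, 1), i + 3, s)
                if a == MISSING and b == MISSING:
                    row_codes.append(MISSING)
                elif (a, b) in TWO_ROW_COLLAPSE:
                    row_codes.append(TWO_ROW_COLLAPSE[(a, b)])
                else:
                    raise ReportFormatError(
                        f"locus {locus!r}, sample {s!r}: illegal two-row score "
                        f"pair (ref={a}, alt={b})"
                    )
            calls.append(row_codes)
            i += 2

    return GenotypePanel(
        marker_type=MarkerType.SNP,
        loci=loci,
        individuals=samples,
        calls=np.array(calls, dtype=np.int8),
        locus_meta=_build_meta(kept_rows, loci, meta_cols),
    )


def read_pa_report(path, columns: ReportColumns | None = None) -> GenotypePanel:
    """Read a silicoDArT presence/absence report (single-row 0/1 cells)."""
    cols = columns or ReportColumns()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ReportFormatError(f"{path}: empty file")
        meta_cols, samples = _split_columns(
            list(reader.fieldnames), cols, MarkerType.PA, False
        )
        rows = list(reader)
    loci, calls, seen = [], [], set()
    for rnum, r in enumerate(rows, start=2):
        locus = r[cols.locus_id]
        if locus in seen:
            raise ReportFormatError(f"duplicate locus ID {locus!r}")
        seen.add(locus)
        loci.append(locus)
        calls.append([_parse_cell(r[s], (0, 1), rnum, s) for s in samples])
    return GenotypePanel(
        marker_type=MarkerType.PA,
        loci=loci,
        individuals=samples,
        calls=np.array(calls, dtype=np.int8),
        locus_meta=_build_meta(rows, loci, meta_cols),
    )


def read_sex_table(
    path, male_token: str = "M", female_token: str = "F"
) -> SexRegistry:
    """Read the two-column (id, sex) phenotype table."""
    sex_of: dict[str, Sex] = {}
    order: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or len(header) < 2:
            raise ReportFormatError(f"{path}: expected a two-column CSV with header")
        for rnum, row in enumerate(reader, start=2):
            if len(row) < 2:
                raise ReportFormatError(f"{path}: short row at line {rnum}")
            ind, tok = row[0].strip(), row[1].strip()
            if ind in sex_of:
                raise ReportFormatError(f"duplicated individual ID {ind!r}")
            if tok == male_token:
                sex_of[ind] = Sex.MALE
            elif tok == female_token:
                sex_of[ind] = Sex.FEMALE
            else:
                raise ReportFormatError(
                    f"unknown sex token {tok!r} for {ind!r} (line {rnum})"
                )
            order.append(ind)
    return SexRegistry(sex_of, order)


def write_panel(
    panel: GenotypePanel,
    path,
    dialect: str = "one_row",
    columns: ReportColumns | None = None,
) -> None:
    """Write a panel in a dialect :func:`read_snp_report`/:func:`read_pa_report`
    read back bit-exactly.  PA panels ignore ``dialect``."""
    cols = columns or ReportColumns()
    two_row = panel.marker_type is MarkerType.SNP and dialect == "two_row"
    meta_map = {
        k: v
        for k, v in cols.meta_map(panel.marker_type).items()
        if k in panel.locus_meta.columns
    }
    if "trimmed_sequence" in panel.locus_meta.columns:
        meta_map["trimmed_sequence"] = cols.trimmed_sequence
    header = [cols.locus_id]
    if two_row:
        header.append(cols.allele_id)
    header += list(meta_map.values()) + list(panel.individuals)

    def fmt(v) -> str:
        if isinstance(v, str):
            return v
        f = float(v)
        return repr(f)

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for i, locus in enumerate(panel.loci):
            meta_vals = [fmt(panel.locus_meta.iloc[i][k]) for k in meta_map]
            row_calls = panel.calls[i]
            if not two_row:
                cells = [MISSING_OUT if c == MISSING else str(c) for c in row_calls]
                w.writerow([locus] + meta_vals + cells)
            else:
                ref, alt = [], []
                for c in row_calls:
                    if c == MISSING:
                        ref.append(MISSING_OUT)
                        alt.append(MISSING_OUT)
                    else:
                        a, b = TWO_ROW_EXPAND[int(c)]
                        ref.append(str(a))
                        alt.append(str(b))
                w.writerow([locus, f"{locus}-Ref"] + meta_vals + ref)
                w.writerow([locus, f"{locus}-Alt"] + meta_vals + alt)
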