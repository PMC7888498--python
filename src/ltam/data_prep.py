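"""Editing rules and trait definitions for sow reproduction records.

Turns raw farrowing-event records into the analysis table the model
consumes: one row per sow with contemporary group (herd x year x season of
first farrowing), age at first farrowing (AFF) as a covariate, litter sizes
at parities 1-3 (NBA1-NBA3, missing after culling) and the binary
stayability trait STAY14 (1 if the sow reached a fourth farrowing, 0 if she
was removed before it, missing if she was still in the herd at the end of
data collection without a fourth-parity opportunity — right censoring).

Edits: sows missing a birth date, a farrowing date or a parity are dropped,
as are sows with AFF < 280 d or AFF > 460 d (strict inequalities: 280 and
460 are retained).  Every drop is counted in an :class:`EditLog`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

AFF_MIN = 280
AFF_MAX = 460

TRAIT_COLUMNS = ["nba1", "nba2", "nba3", "stay14"]


@dataclass(frozen=True)
class Farrowing:
    parity: int
    date: date
    nba: float | None


@dataclass
class SowRecord:
    """All reproduction events of one sow, as extracted from herd software."""

    sow: str
    herd: str
    birth_date: date | None
    farrowings: list[Farrowing]
    removal_date: date | None = None

    def farrowing_at(self, parity: int) -> Farrowing | None:
        for f in self.farrowings:
            if f.parity == parity:
                return f
        return None


@dataclass
class EditLog:
    """Per-rule drop counts plus per-sow reason codes."""

    n_input: int = 0
    n_kept: int = 0
    counts: dict[str, int] = field(default_factory=dict)
    reasons: dict[str, str] = field(default_factory=dict)

    def drop(self, sow: str, reason: str) -> None:
        self.counts[reason] = self.counts.get(reason, 0) + 1
        self.reasons[sow] = reason

    @property
    def n_dropped(self) -> int:
        return sum(self.counts.values())

    def __str__(self) -> str:
        lines = [f"records in: {self.n_input}, kept: {self.n_kept}, "
                 f"dropped: {self.n_dropped}"]
        for reason, cnt in sorted(self.counts.items()):
            lines.append(f"  {reason}: {cnt}")
        return "\n".join(lines)


def compute_aff(birth_date: date, first_farrowing_date: date) -> int:
    """Age at first farrowing in whole days."""
    if first_farrowing_date < birth_date:
        raise ValidationError(
            f"farrowing {first_farrowing_date} precedes birth {birth_date}"
        )
    return (first_farrowing_date - birth_date).days


def assign_season(month: int) -> str:
    """Season of a calendar month under the tropical three-season split:
    summer (Mar-Jun), rainy (Jul-Oct), winter (Nov-Feb)."""
    if not 1 <= int(month) <= 12:
        raise ValidationError(f"month {month} out of range 1..12")
    month = int(month)
    if 3 <= month <= 6:
        return "summer"
    if 7 <= month <= 10:
        return "rainy"
    return "winter"


def make_cg(herd: str, first_farrow_date: date) -> str:
    """Contemporary-group label: herd x year x season of first farrowing."""
    return f"{herd}-{first_farrow_date.year}-{assign_season(first_farrow_date.month)}"


def code_stay14(record: SowRecord, data_end_date: date | None = None) -> float:
    """Stayability from first to fourth farrowing.

    1 if a parity-4 farrowing exists (within the data window), 0 if the sow
    has a removal date and no fourth farrowing, NaN (right-censored) if she
    was still present at the end of data collection.
    """
    f4 = record.farrowing_at(4)
    if f4 is not None and (data_end_date is None or f4.date <= data_end_date):
        return 1.0
    if record.removal_date is not None and (
        data_end_date is None or record.removal_date <= data_end_date
    ):
        return 0.0
    return np.nan


def apply_edits(records: list[SowRecord]) -> tuple[list[SowRecord], EditLog]:
    """Apply the deletion rules, returning kept records and the edit log.

    Idempotent: running it again on its own output drops nothing.
    """
    log = EditLog(n_input=len(records))
    kept = []
    for rec in records:
        if rec.birth_date is None:
            log.drop(rec.sow, "missing_birth_date")
            continue
        if not rec.farrowings:
            log.drop(rec.sow, "no_farrowings")
            continue
        if any(f.parity is None or f.date is None for f in rec.farrowings):
            log.drop(rec.sow, "missing_farrow_field")
            continue
        parities = [f.parity for f in rec.farrowings]
        dates = [f.date for f in rec.farrowings]
        if sorted(set(parities)) != sorted(parities) or dates != sorted(dates):
            log.drop(rec.sow, "inconsistent_farrowings")
            continue
        f1 = rec.farrowing_at(1)
        if f1 is None:
            log.drop(rec.sow, "missing_first_parity")
            continue
        if f1.date < rec.birth_date:
            log.drop(rec.sow, "farrow_before_birth")
            continue
        aff = compute_aff(rec.birth_date, f1.date)
        if aff < AFF_MIN or aff > AFF_MAX:
            log.drop(rec.sow, "aff_out_of_range")
            continue
        kept.append(rec)
    log.n_kept = len(kept)
    return kept, log


def build_analysis_table(
    records: list[SowRecord], data_end_date: date | None = None,
) -> pd.DataFrame:
    """Analysis table for edited records: sow, cg, aff, nba1-3, stay14.

    NBA at parity k is present iff a parity-k farrowing (within the data
    window) carries a litter-size value; parity gaps leave the gap missing
    with a warning.  Missing values are NaN.
    """
    rows = []
    n_gaps = 0
    for rec in records:
        f1 = rec.farrowing_at(1)
        aff = compute_aff(rec.birth_date, f1.date)
        cg = make_cg(rec.herd, f1.date)
        nba = {}
        present = set()
        for k in (1, 2, 3):
            f = rec.farrowing_at(k)
            if (
                f is not None
                and f.nba is not None
                and (data_end_date is None or f.date <= data_end_date)
            ):
                nba[f"nba{k}"] = float(f.nba)
                present.add(k)
            else:
                nba[f"nba{k}"] = np.nan
        if present and (max(present) - len(present) + 1 != min(present)):
            n_gaps += 1
        rows.append(
            {"sow": rec.sow, "cg": cg, "aff": float(aff), **nba,
             "stay14": code_stay14(rec, data_end_date)}
        )
    if n_gaps:
        logger.warning("%d sows have parity gaps; gap litters left missing", n_gaps)
    return pd.DataFrame(
        rows, columns=["sow", "cg", "aff", "nba1", "nba2", "nba3", "stay14"]
    )


def edit_records(
    records: list[SowRecord], data_end_date: date | None = None,
) -> tuple[pd.DataFrame, EditLog]:
    """Full preparation: apply edits, then build the analysis table."""
    kept, log = apply_edits(records)
    return build_analysis_table(kept, data_end_date), log


def read_sow_records(path) -> list[SowRecord]:
    """Read long-format farrowing records.

    Columns: sow, herd, birth_date, parity, farrow_date, nba, removal_date;
    ISO-8601 dates, one row per farrowing, removal_date repeated or blank.
    """
    df = pd.read_csv(path, dtype={"sow": str, "herd": str}, comment="#")
    required = {"sow", "herd", "birth_date", "parity", "farrow_date", "nba"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"sow record file missing columns: {sorted(missing)}")
    if df.empty:
        raise FormatError(f"sow record file {path} has no rows")

    def _date(v):
        if pd.isna(v) or v == "":
            return None
        return pd.Timestamp(v).date()

    records = []
    for sow, grp in df.groupby("sow", sort=False):
        grp = grp.sort_values("parity", na_position="last")
        farrowings = [
            Farrowing(
                parity=None if pd.isna(r.parity) else int(r.parity),
                date=_date(r.farrow_date),
                nba=None if pd.isna(r.nba) else float(r.nba),
            )
            for r in grp.itertuples()
        ]
        removal = None
        if "removal_date" in grp.columns:
            vals = [_date(v) for v in grp["removal_date"] if not pd.isna(v)]
            removal = vals[0] if vals else None
        records.append(
            SowRecord(
                sow=str(sow),
                herd=str(grp["herd"].iloc[0]),
                birth_date=_date(grp["birth_date"].iloc[0]),
                farrowings=farrowings,
                removal_date=removal,
            )
        )
    return records


def write_analysis_table(df: pd.DataFrame, path, header_comment: str | None = None):
    """Write the analysis table as CSV with NA for missing."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False, na_rep="NA")


def read_analysis_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype={"sow": str, "cg": str},
                     na_values=["NA"])
    for c in ("aff", "nba1", "nba2", "nba3", "stay14"):
        if c in df.columns:
            df[c] = df[c].astype(float)
    return df
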