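"""Volatile-compound (VOC) tables and aroma-impact screening.

Works with GC-MS style tables (absolute concentrations, mg/L) and
GC-IMS style tables (relative signal intensities).  The aroma impact of
a quantified compound is its odor activity value

    OAV = concentration / odor threshold

(values above 1 are considered perceptible); for relative
quantification the relative OAV is used instead,

    rOAV_i = 100 * (I_i / T_i) / max_j (I_j / T_j)

so that the most potent compound in a sample scores exactly 100.  Key
aroma contributors are screened as compounds that are both
discriminating between samples (VIP > 1, taken as an input from an
OPLS-DA model) and perceptible (OAV > 1, maximum over samples).

"ND" (not detected) is a missing-value marker distinct from zero: ND
concentrations contribute 0 to category totals but are excluded from
detected-compound counts and produce no OAV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VOCRecord",
    "VOCTable",
    "CATEGORIES",
    "compute_oav",
    "compute_roav",
    "screen_key_compounds",
    "aggregate_by_category",
    "kovats_ri",
    "voc_table_from_csv",
    "voc_table_to_csv",
]

log = logging.getLogger(__name__)

CATEGORIES = (
    "aldehyde",
    "terpene",
    "ketone",
    "alcohol",
    "ester",
    "acid",
    "furan",
    "hydrocarbon",
    "other",
)

# plural/singular table headings normalized to the canonical category
_CATEGORY_ALIASES = {
    "aldehydes": "aldehyde",
    "terpenes": "terpene",
    "ketones": "ketone",
    "alcohols": "alcohol",
    "esters": "ester",
    "acids": "acid",
    "furans": "furan",
    "hydrocarbons": "hydrocarbon",
    "others": "other",
}

ND = "ND"


def _canon_category(raw: str) -> str:
    c = raw.strip().lower()
    c = _CATEGORY_ALIASES.get(c, c)
    if c not in CATEGORIES:
        raise ValueError(f"unknown VOC category {raw!r}")
    return c


@dataclass(frozen=True)
class VOCRecord:
    """One volatile compound: identity, retention indices, quantification.

    ``concentrations`` maps sample name to mg/L, with ``None`` standing
    for ND.  ``relative_intensity`` carries GC-IMS signal in arbitrary
    units.  ``threshold`` is the odor threshold in mg/L; ``vip`` the
    variable-importance-in-projection score from an external OPLS-DA.
    """

    name: str
    formula: str = ""
    category: str = "other"
    ri_observed: float | None = None
    ri_literature: float | None = None
    concentrations: Mapping[str, float | None] = field(default_factory=dict)
    threshold: float | None = None
    vip: float | None = None
    relative_intensity: Mapping[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "category", _canon_category(self.category))
        for s, c in self.concentrations.items():
            if c is not None and c < 0:
                raise ValueError(f"{self.name}: negative concentration in {s}")
        if self.threshold is not None and self.threshold <= 0:
            raise ValueError(f"{self.name}: odor threshold must be positive")


@dataclass(frozen=True)
class VOCTable:
    records: tuple[VOCRecord, ...]
    samples: tuple[str, ...]
    mode: Literal["gcms", "gcims"] = "gcms"

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate compound names: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def get(self, name: str) -> VOCRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)


def compute_oav(record: VOCRecord, sample: str) -> float | None:
    """OAV = concentration / threshold; None when ND or threshold missing."""
    if record.threshold is None:
        log.warning("%s: no odor threshold; OAV not computable", record.name)
        return None
    conc = record.concentrations.get(sample)
    if conc is None:
        return None
    return conc / record.threshold


def max_oav(record: VOCRecord, samples: Sequence[str]) -> float | None:
    vals = [v for v in (compute_oav(record, s) for s in samples) if v is not None]
    return max(vals) if vals else None


def compute_roav(table: VOCTable, sample: str) -> dict[str, float]:
    """Relative OAVs within one sample of a GC-IMS table.

    Each eligible compound (intensity and threshold present) gets
    100 * (I/T) / max(I/T); the most potent compound scores exactly 100.
    """
    if table.mode != "gcims":
        raise ValueError("rOAV applies to relative (GC-IMS) quantification")
    ratios: dict[str, float] = {}
    for r in table.records:
        inten = r.relative_intensity.get(sample)
        if inten is None or r.threshold is None:
            continue
        ratios[r.name] = inten / r.threshold
    if not ratios:
        raise ValueError(f"no compound in sample {sample!r} has both intensity and threshold")
    top = max(ratios.values())
    return {name: 100.0 * v / top for name, v in ratios.items()}


def screen_key_compounds(
    table: VOCTable, vip_cut: float = 1.0, oav_cut: float = 1.0
) -> list[VOCRecord]:
    """Select key aroma contributors: VIP > vip_cut AND OAV > oav_cut.

    Both inequalities are strict.  For GC-MS tables the OAV criterion
    uses the maximum OAV over samples; for GC-IMS tables the maximum
    rOAV over samples.  Records lacking a VIP score or a threshold are
    excluded (with a logged reason, not an error).  Output is ordered by
    descending aroma activity, ties broken by name.
    """
    if table.mode == "gcims":
        roav_by_sample = {}
        for s in table.samples:
            try:
                roav_by_sample[s] = compute_roav(table, s)
            except ValueError:
                roav_by_sample[s] = {}

        def activity(r: VOCRecord) -> float | None:
            vals = [
                roav_by_sample[s][r.name]
                for s in table.samples
                if r.name in roav_by_sample[s]
            ]
            return max(vals) if vals else None

    else:

        def activity(r: VOCRecord) -> float | None:
            return max_oav(r, table.samples)

    kept: list[tuple[float, str, VOCRecord]] = []
    for r in table.records:
        if r.vip is None:
            log.info("%s: excluded from screening (no VIP score)", r.name)
            continue
        act = activity(r)
        if act is None:
            log.info("%s: excluded from screening (no threshold/quantification)", r.name)
            continue
        if r.vip > vip_cut and act > oav_cut:
            kept.append((act, r.name, r))
    kept.sort(key=lambda t: (-t[0], t[1]))
    return [r for _, _, r in kept]


def aggregate_by_category(
    table: VOCTable, sample: str
) -> dict[str, tuple[int, float]]:
    """Per-category (detected count, total mg/L) for one sample.

    ND counts as 0 in the total and does not count as detected.
    Categories absent from the table appear with (0, 0.0).
    """
    if table.mode != "gcms":
        raise ValueError("category totals require absolute (GC-MS) quantification")
    out = {c: [0, 0.0] for c in CATEGORIES}
    for r in table.records:
        conc = r.concentrations.get(sample)
        if conc is not None:
            out[r.category][0] += 1
            out[r.category][1] += conc
    return {c: (n, total) for c, (n, total) in out.items()}


def category_census(table: VOCTable) -> dict[str, int]:
    """Number of table rows per category, regardless of detection."""
    out = {c: 0 for c in CATEGORIES}
    for r in table.records:
        out[r.category] += 1
    return out


def kovats_ri(rt: float, alkane_rts: Mapping[int, float]) -> float:
    """Linear (van den Dool) retention index against n-alkane standards.

    ``alkane_rts`` maps carbon number to retention time.  For a peak
    eluting between C_n and C_{n+1},

        RI = 100 * (n + (rt - rt_n) / (rt_{n+1} - rt_n)).

    The retention time must be bracketed by two consecutive alkanes.
    """
    carbons = sorted(alkane_rts)
    if len(carbons) < 2:
        raise ValueError("need at least two alkane standards")
    for n, n_next in zip(carbons, carbons[1:]):
        if n_next != n + 1:
            raise ValueError(f"alkane series has a gap between C{n} and C{n_next}")
        lo, hi = alkane_rts[n], alkane_rts[n_next]
        if lo <= rt <= hi:
            return 100.0 * (n + (rt - lo) / (hi - lo))
    raise ValueError(
        f"retention time {rt} outside alkane range "
        f"[{alkane_rts[carbons[0]]}, {alkane_rts[carbons[-1]]}]"
    )


# ---------------------------------------------------------------------------
# CSV dialect: category, ri_observed, ri_literature, name, formula,
# one concentration (or intensity) column per sample, optional threshold, vip

_META_COLS = ("category", "ri_observed", "ri_literature", "name", "formula")
_OPT_COLS = ("threshold", "vip")


def _parse_cell(v) -> float | None:
    if pd.isna(v):
        return None
    if isinstance(v, str):
        s = v.strip()
        if s.upper() == ND or s == "":
            return None
        return float(s)
    return float(v)


def voc_table_from_csv(
    path: str | Path, mode: Literal["gcms", "gcims"] = "gcms"
) -> VOCTable:
    df = pd.read_csv(path, encoding="utf-8", dtype=str, keep_default_na=False)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"VOC table missing columns {missing}")
    samples = tuple(
        c for c in df.columns if c not in _META_COLS and c not in _OPT_COLS
    )
    records = []
    for i, row in df.iterrows():
        try:
            quant = {s: _parse_cell(row[s]) for s in samples}
            rec = VOCRecord(
                name=row["name"],
                formula=row["formula"],
                category=row["category"],
                ri_observed=_parse_cell(row["ri_observed"]),
                ri_literature=_parse_cell(row["ri_literature"]),
                concentrations=quant if mode == "gcms" else {},
                relative_intensity=quant if mode == "gcims" else {},
                threshold=_parse_cell(row["threshold"]) if "threshold" in df.columns else None,
                vip=_parse_cell(row["vip"]) if "vip" in df.columns else None,
            )
        except (ValueError, KeyError) as err:
            raise ValueError(f"line {i + 2}: {err}") from err
        records.append(rec)
    return VOCTable(records=tuple(records), samples=samples, mode=mode)


def voc_table_to_csv(table: VOCTable, path: str | Path) -> None:
    quant_attr = "concentrations" if table.mode == "gcms" else "relative_intensity"

    def fmt(v: float | None) -> str:
        return ND if v is None else f"{v:.12g}"

    rows = []
    for r in table.records:
        quant = getattr(r, quant_attr)
        row = {
            "category": r.category,
            "ri_observed": "" if r.ri_observed is None else f"{r.ri_observed:.12g}",
            "ri_literature": "" if r.ri_literature is None else f"{r.ri_literature:.12g}",
            "name": r.name,
            "formula": r.formula,
            **{s: fmt(quant.get(s)) for s in table.samples},
            "threshold": "" if r.threshold is None else f"{r.threshold:.12g}",
            "vip": "" if r.vip is None else f"{r.vip:.12g}",
        }
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")
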