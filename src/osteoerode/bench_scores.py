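"""Scalar assay scores: IgG Fc glycan ratios and the transwell migration index.

Peak heights come from APTS-labeled N-glycan electropherograms. The seven
named peaks are, in canonical column order::

    G0F, G1F_1, G1F_2, G2F, G1FS1_1, G1FS1_2, G2FS1

Relative sialylation uses all seven; the undergalactosylation score (UGS)
uses only the four neutral peaks of a neuraminidase-digested profile. Both
are ratios and therefore invariant to any common rescaling of the peak
heights. The migration index normalizes migrated-cell counts by counting
beads spiked into each well as an internal acquisition control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical glycan peak column names.
PEAK_COLUMNS = ["G0F", "G1F_1", "G1F_2", "G2F", "G1FS1_1", "G1FS1_2", "G2FS1"]

#: Columns required in a migration-counts table.
MIGRATION_COLUMNS = [
    "migrated_cells_sample",
    "beads_sample",
    "migrated_cells_control",
    "beads_control",
]


@dataclass(frozen=True)
class GlycanPeaks:
    """Heights of the seven main IgG Fc N-glycan peaks (arbitrary fluorescence units)."""

    G0F: float
    G1F_1: float
    G1F_2: float
    G2F: float
    G1FS1_1: float = 0.0
    G1FS1_2: float = 0.0
    G2FS1: float = 0.0

    def __post_init__(self) -> None:
        for name in PEAK_COLUMNS:
            if getattr(self, name) < 0:
                raise ValueError(f"peak height {name} must be >= 0, got {getattr(self, name)}")

    @property
    def total(self) -> float:
        return sum(getattr(self, name) for name in PEAK_COLUMNS)


@dataclass(frozen=True)
class MigrationCounts:
    """Cell and internal-control bead counts for a sample well and a control well."""

    migrated_cells_sample: float
    beads_sample: float
    migrated_cells_control: float
    beads_control: float

    def __post_init__(self) -> None:
        if self.beads_sample <= 0 or self.beads_control <= 0:
            raise ValueError("bead counts must be strictly positive")
        if self.migrated_cells_sample < 0 or self.migrated_cells_control < 0:
            raise ValueError("cell counts must be >= 0")


def relative_sialylation(peaks: GlycanPeaks) -> float:
    """Sialylated fraction of total peak height:
    ``(G2FS1 + G1FS1_1 + G1FS1_2) / sum(all seven peaks)``.

    .. note::
       Electrokinetic injection preferentially loads analytes carrying
       extra negative charges, so sialylated peaks are overrepresented:
       these values are relative scores, not true sialylation percentages.
    """
    total = peaks.total
    if total <= 0:
        raise ValueError("relative_sialylation: all peak heights are zero")
    return (peaks.G2FS1 + peaks.G1FS1_1 + peaks.G1FS1_2) / total


def undergalactosylation_score(peaks: GlycanPeaks) -> float:
    """Weighted fraction of missing galactoses among the four neutral peaks:
    ``(G0F + 0.5*G1F_1 + 0.5*G1F_2) / (G0F + G1F_1 + G1F_2 + G2F)``.

    Computed on neuraminidase-digested (desialylated) profiles; only the
    four neutral peaks enter. 1 means fully agalactosylated, 0 fully
    digalactosylated.
    """
    denom = peaks.G0F + peaks.G1F_1 + peaks.G1F_2 + peaks.G2F
    if denom <= 0:
        raise ValueError("undergalactosylation_score: the four neutral peaks are all zero")
    return (peaks.G0F + 0.5 * peaks.G1F_1 + 0.5 * peaks.G1F_2) / denom


def migration_index(counts: MigrationCounts) -> float:
    """Bead-normalized migration ratio:
    ``(cells_sample / beads_sample) / (cells_control / beads_control)``.
    """
    if counts.migrated_cells_control <= 0:
        raise ValueError("migration_index: control well has no migrated cells; index undefined")
    sample_rate = counts.migrated_cells_sample / counts.beads_sample
    control_rate = counts.migrated_cells_control / counts.beads_control
    return sample_rate / control_rate


# ---------------------------------------------------------------------------
# table interfaces
# ---------------------------------------------------------------------------

def score_glycan_table(table: pd.DataFrame) -> pd.DataFrame:
    """Score a per-sample peak-height table.

    Requires a ``sample_id`` column plus the seven peak columns; unknown
    columns are ignored with a warning. Returns columns
    ``sample_id, sialylation, ugs``.
    """
    required = ["sample_id", *PEAK_COLUMNS]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"glycan table is missing required columns {missing}")
    unknown = [c for c in table.columns if c not in required]
    if unknown:
        logger.warning("glycan table: ignoring unknown columns %s", unknown)
    out = []
    for _, row in table.iterrows():
        peaks = GlycanPeaks(**{c: float(row[c]) for c in PEAK_COLUMNS})
        out.append(
            {
                "sample_id": row["sample_id"],
                "sialylation": relative_sialylation(peaks),
                "ugs": undergalactosylation_score(peaks),
            }
        )
    return pd.DataFrame(out, columns=["sample_id", "sialylation", "ugs"])


def score_migration_table(table: pd.DataFrame) -> pd.DataFrame:
    """Compute the migration index per row of a counts table.

    Requires ``sample_id`` plus the four count columns; returns
    ``sample_id, migration_index``.
    """
    required = ["sample_id", *MIGRATION_COLUMNS]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"migration table is missing required columns {missing}")
    unknown = [c for c in table.columns if c not in required]
    if unknown:
        logger.warning("migration table: ignoring unknown columns %s", unknown)
    out = []
    for _, row in table.iterrows():
        counts = MigrationCounts(**{c: float(row[c]) for c in MIGRATION_COLUMNS})
        out.append({"sample_id": row["sample_id"], "migration_index": migration_index(counts)})
    return pd.DataFrame(out, columns=["sample_id", "migration_index"])
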