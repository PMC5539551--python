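"""qPCR detection calls, background subtraction, and biomass conversion.

A panel bundles replicate gene-copy measurements for one sample/target with
the extraction- and PCR-negative replicates from its run.  A sample is above
detection only when every sample replicate exceeds every negative replicate
(of both kinds) by more than the detection factor.  Detected panels are
background-subtracted by the larger negative-control mean; below-detection
panels propagate as explicit below-detection records with their run's limit
of detection, never as zeros.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import BelowDetectionError, ConfigurationError, ValidationError
from .io_tables import QuantConfig, SampleMetadata

__all__ = [
    "Target",
    "MicrosphereFlag",
    "QpcrPanel",
    "QuantResult",
    "qpcr_above_detection",
    "qpcr_corrected_copies",
    "copies_per_gram",
    "cells_per_cm3",
    "microsphere_flag",
    "quantify_panel",
    "read_qpcr_table",
    "write_quant_results",
]


class Target(str, enum.Enum):
    BACTERIA_16S = "BACTERIA_16S"
    ARCHAEA_16S = "ARCHAEA_16S"


class MicrosphereFlag(str, enum.Enum):
    CLEAN = "CLEAN"
    FLAGGED = "FLAGGED"
    NOT_MEASURED = "NOT_MEASURED"


@dataclass(frozen=True)
class QpcrPanel:
    """Replicate copy numbers for one sample/target plus its negatives."""

    sample_id: str
    target: Target
    sample_reps: tuple[float, ...]  # copies per microlitre of extract
    extraction_negs: tuple[float, ...]
    pcr_negs: tuple[float, ...]
    config: QuantConfig = field(default_factory=QuantConfig)

    def __post_init__(self) -> None:
        for name in ("sample_reps", "extraction_negs", "pcr_negs"):
            reps = tuple(float(x) for x in getattr(self, name))
            if not reps:
                raise ValidationError(f"{self.sample_id}: {name} needs >= 1 replicate")
            if any(x < 0 for x in reps):
                raise ValidationError(f"{self.sample_id}: negative copy number in {name}")
            object.__setattr__(self, name, reps)
        object.__setattr__(self, "target", Target(self.target))

    @property
    def lod_copies_per_ul(self) -> float:
        """Run-specific limit of detection: factor x highest negative rep."""
        return self.config.detection_factor * max(
            max(self.extraction_negs), max(self.pcr_negs)
        )


@dataclass(frozen=True)
class QuantResult:
    sample_id: str
    target: Target
    above_detection: bool
    lod_copies_per_ul: float
    corrected_copies_per_ul: float | None = None
    copies_per_g: float | None = None
    cells_per_cm3: float | None = None


def qpcr_above_detection(panel: QpcrPanel) -> bool:
    """True iff every sample replicate exceeds every negative replicate
    (both extraction and PCR negatives) by more than the detection factor."""
    factor = panel.config.detection_factor
    worst_neg = max(max(panel.extraction_negs), max(panel.pcr_negs))
    return min(panel.sample_reps) > factor * worst_neg


def qpcr_corrected_copies(panel: QpcrPanel) -> float:
    """Background-subtracted copies per microlitre for a detected panel.

    The mean of the higher of the two negative-control types (extraction or
    PCR, whichever ran hotter) is subtracted from the mean of the sample
    replicates; the result is floored at zero.  Calling this on a
    below-detection panel is a contract error.
    """
    if not qpcr_above_detection(panel):
        raise BelowDetectionError(
            f"{panel.sample_id}/{panel.target.value}: panel is below detection"
        )
    mean = lambda xs: sum(xs) / len(xs)
    background = max(mean(panel.extraction_negs), mean(panel.pcr_negs))
    return max(0.0, mean(panel.sample_reps) - background)


def copies_per_gram(corrected: float, config: QuantConfig) -> float:
    """Scale extract concentration to sample mass: ``corrected * V_e / m``."""
    if config.elution_volume is None or config.extracted_mass is None:
        raise ConfigurationError(
            "copies_per_gram requires elution_volume and extracted_mass"
        )
    return corrected * config.elution_volume / config.extracted_mass


def cells_per_cm3(copies_per_g: float, config: QuantConfig) -> float:
    """Convert gene copies per gram to cell density:
    ``copies_per_g * density / operons_per_cell``."""
    return copies_per_g * config.sediment_density / config.operons_per_cell


def microsphere_flag(metadata: SampleMetadata) -> MicrosphereFlag:
    """Tracer-microsphere QC status of a sample."""
    if metadata.microsphere_count is None:
        return MicrosphereFlag.NOT_MEASURED
    return MicrosphereFlag.FLAGGED if metadata.microsphere_count > 0 else MicrosphereFlag.CLEAN


def quantify_panel(panel: QpcrPanel) -> QuantResult:
    """Full per-panel workflow: detection call, correction, conversions.

    Conversions to copies per gram (and onward to cells) are only attempted
    when the panel's config carries the extraction parameters.
    """
    lod = panel.lod_copies_per_ul
    if not qpcr_above_detection(panel):
        return QuantResult(panel.sample_id, panel.target, False, lod)
    corrected = qpcr_corrected_copies(panel)
    cpg = cells = None
    if panel.config.elution_volume is not None and panel.config.extracted_mass is not None:
        cpg = copies_per_gram(corrected, panel.config)
        cells = cells_per_cm3(cpg, panel.config)
    return QuantResult(panel.sample_id, panel.target, True, lod, corrected, cpg, cells)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_qpcr_table(path: str | Path, config: QuantConfig | None = None) -> list[QpcrPanel]:
    """Read a qPCR replicate table into panels.

    Expected columns: ``sample_id``, ``target``, ``replicate``,
    ``copies_per_ul``, ``is_extraction_negative``, ``is_pcr_negative``
    (comma- or tab-delimited, sniffed from the header).  Negative-control
    rows are shared by every sample panel of the same target.
    """
    config = config or QuantConfig()
    path = Path(path)
    sep = "\t" if "\t" in path.read_text().splitlines()[0] else ","
    df = pd.read_csv(path, sep=sep)
    required = {"sample_id", "target", "copies_per_ul",
                "is_extraction_negative", "is_pcr_negative"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")

    truthy = lambda v: str(v).strip().lower() in ("1", "true", "yes")
    panels: list[QpcrPanel] = []
    for target, group in df.groupby("target", sort=True):
        ext = tuple(float(v) for v, f in zip(group["copies_per_ul"],
                    group["is_extraction_negative"]) if truthy(f))
        pcr = tuple(float(v) for v, f in zip(group["copies_per_ul"],
                    group["is_pcr_negative"]) if truthy(f))
        is_neg = [truthy(a) or truthy(b) for a, b in
                  zip(group["is_extraction_negative"], group["is_pcr_negative"])]
        samples = group[[not n for n in is_neg]]
        for sid, sub in samples.groupby("sample_id", sort=True):
            panels.append(QpcrPanel(
                sample_id=str(sid),
                target=Target(str(target)),
                sample_reps=tuple(float(v) for v in sub["copies_per_ul"]),
                extraction_negs=ext,
                pcr_negs=pcr,
                config=config,
            ))
    return panels


def write_quant_results(results: Sequence[QuantResult], path: str | Path) -> None:
    """Write quantification results as a TSV; below-detection rows show 'ND'."""
    rows = []
    for r in sorted(results, key=lambda r: (r.sample_id, r.target.value)):
        nd = lambda v: "ND" if v is None else f"{v:.6g}"
        rows.append({
            "sample_id": r.sample_id,
            "target": r.target.value,
            "above_detection": int(r.above_detection),
            "lod_copies_per_ul": f"{r.lod_copies_per_ul:.6g}",
            "corrected_copies_per_ul": nd(r.corrected_copies_per_ul),
            "copies_per_g": nd(r.copies_per_g),
            "cells_per_cm3": nd(r.cells_per_cm3),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
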