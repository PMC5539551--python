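"""Four-bin provenance classification against a background control library.

Every OTU in a filtered table is compared against a single designated
background control library and assigned to exactly one of four bins:

* ``CONTROL_ONLY`` — present in the control, absent from every sample;
* ``SAMPLES_ONLY`` — present in at least one sample, absent from the control;
* ``TENFOLD_SAMPLE`` — present in both, and enriched in at least one sample
  relative to the control by at least the configured ratio threshold on
  per-library relative abundances;
* ``CONTROL_SAMPLE`` — present in both at below-threshold enrichment.

Only ``SAMPLES_ONLY`` OTUs survive the screen: shared OTUs are treated as
putative seawater/reagent/handling contamination and removed everywhere, and
the control library itself is dropped.  Samples that are both positive for
drilling-fluid tracer microspheres and dominated by control-overlapping
reads are excluded outright.

Presence is literal (count > 0, no pseudocounts) and enrichment ratios are
computed on relative abundances ``c / N_s``, so library-size differences do
not masquerade as enrichment.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateSampleError
from .io_tables import OtuTable, SampleMetadata, ScreenConfig

__all__ = [
    "Bin",
    "BinAssignment",
    "ScreenResult",
    "compute_relative_abundance",
    "assign_bins",
    "exclude_contaminated_samples",
    "apply_screen",
]


class Bin(str, enum.Enum):
    """Provenance bin of an OTU relative to the background control."""

    CONTROL_ONLY = "CONTROL_ONLY"
    SAMPLES_ONLY = "SAMPLES_ONLY"
    TENFOLD_SAMPLE = "TENFOLD_SAMPLE"
    CONTROL_SAMPLE = "CONTROL_SAMPLE"


#: Bins whose OTUs overlap the control from the samples' point of view.
OVERLAP_BINS = (Bin.TENFOLD_SAMPLE, Bin.CONTROL_SAMPLE)


@dataclass(frozen=True)
class BinAssignment:
    """Partition of a filtered OTU set into the four provenance bins.

    ``ratio`` holds, for each OTU present in both the control and at least
    one sample, the maximum over samples of ``r_sample / r_control``.
    """

    bins: Mapping[str, Bin]
    ratio: Mapping[str, float]
    control_id: str

    def otus_in(self, *bins: Bin) -> list[str]:
        wanted = set(bins)
        return [o for o, b in self.bins.items() if b in wanted]

    def bin_sizes(self) -> dict[Bin, int]:
        sizes = {b: 0 for b in Bin}
        for b in self.bins.values():
            sizes[b] += 1
        return sizes


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of applying the four-bin screen to an OTU table."""

    screened: OtuTable
    bins: BinAssignment | None
    overlap_fraction: pd.Series  # per non-control sample, on the input table
    group4_fraction: pd.Series
    pre_otu_counts: pd.Series
    post_otu_counts: pd.Series
    pre_read_counts: pd.Series
    post_read_counts: pd.Series
    excluded: Mapping[str, str] = field(default_factory=dict)
    unscreened: bool = False


def compute_relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Per-library relative abundances ``r = c / N_s`` (columns sum to 1)."""
    sizes = table.library_sizes
    empty = sizes[sizes == 0]
    if len(empty):
        raise DegenerateSampleError(
            f"samples with zero library size: {list(map(str, empty.index))}"
        )
    return table.counts / sizes


def assign_bins(
    abund: pd.DataFrame,
    control_id: str,
    config: ScreenConfig | None = None,
) -> BinAssignment:
    """Assign every OTU of a relative-abundance matrix to a provenance bin.

    Parameters
    ----------
    abund
        Relative-abundance matrix (OTU x sample), e.g. from
        :func:`compute_relative_abundance`.  Zero abundance must coincide
        with zero count.
    control_id
        Column holding the background control library.
    config
        Supplies the ratio threshold and its comparison mode (``GE``
        includes ties in the enriched bin; ``GT`` excludes them).
    """
    config = config or ScreenConfig()
    if control_id is None:
        raise ConfigurationError("a control sample id is required for binning")
    if control_id not in abund.columns:
        raise ConfigurationError(f"control sample {control_id!r} not in table")

    sample_cols = [c for c in abund.columns if c != control_id]
    r_ctrl = abund[control_id].to_numpy()
    r_smp = abund[sample_cols].to_numpy()
    in_ctrl = r_ctrl > 0
    in_smp = r_smp.max(axis=1) > 0 if sample_cols else np.zeros(len(abund), bool)

    bins: dict[str, Bin] = {}
    ratios: dict[str, float] = {}
    T = config.ratio_threshold
    enriched = (lambda R: R >= T) if config.ratio_comparison == "GE" else (lambda R: R > T)
    for i, otu in enumerate(abund.index):
        otu = str(otu)
        if in_ctrl[i] and not in_smp[i]:
            bins[otu] = Bin.CONTROL_ONLY
        elif in_smp[i] and not in_ctrl[i]:
            bins[otu] = Bin.SAMPLES_ONLY
        elif in_ctrl[i] and in_smp[i]:
            R = float(r_smp[i].max() / r_ctrl[i])
            ratios[otu] = R
            bins[otu] = Bin.TENFOLD_SAMPLE if enriched(R) else Bin.CONTROL_SAMPLE
        else:
            raise ValueError(
                f"OTU {otu!r} has zero abundance everywhere; filter before binning"
            )
    return BinAssignment(bins=bins, ratio=ratios, control_id=control_id)


def exclude_contaminated_samples(
    table: OtuTable,
    metadata: Mapping[str, SampleMetadata] | None,
    bins: BinAssignment,
    config: ScreenConfig | None = None,
) -> dict[str, str]:
    """Decide which samples are dropped outright, with reasons.

    A sample is excluded iff it tested positive for tracer microspheres
    (``microsphere_count > 0``) AND the fraction of its reads in
    control-overlapping OTUs reaches ``sample_exclusion_overlap_threshold``.
    Microsphere-positive samples below the overlap threshold are retained
    (they merely carry a QC flag); samples without a microsphere measurement
    are never excluded by this rule.
    """
    config = config or ScreenConfig()
    overlap = _overlap_fractions(table, bins, OVERLAP_BINS)
    excluded: dict[str, str] = {}
    if metadata is None:
        return excluded
    for sid in table.noncontrol_ids:
        meta = metadata.get(sid)
        if meta is None or meta.microsphere_count is None:
            continue
        frac = float(overlap.get(sid, 0.0))
        if meta.microsphere_count > 0 and frac >= config.sample_exclusion_overlap_threshold:
            excluded[sid] = (
                f"microspheres present ({meta.microsphere_count:g}) and "
                f"control-overlap read fraction {frac:.3f} >= "
                f"{config.sample_exclusion_overlap_threshold:g}"
            )
    return excluded


def apply_screen(
    table: OtuTable,
    bins: BinAssignment | None,
    metadata: Mapping[str, SampleMetadata] | None = None,
    config: ScreenConfig | None = None,
) -> ScreenResult:
    """Screen a filtered table down to its ``SAMPLES_ONLY`` fraction.

    Removes the control column and every control-overlapping OTU
    (``TENFOLD_SAMPLE`` and ``CONTROL_SAMPLE``) from all samples, drops
    samples failing :func:`exclude_contaminated_samples`, and reports
    per-sample pre/post OTU and read counts plus overlap fractions computed
    on the input table.

    With ``bins=None`` the call is a no-control pass-through: the table is
    returned unchanged and flagged ``unscreened`` (used for e.g. archaeal
    libraries that have no control library to screen against).
    """
    config = config or ScreenConfig()
    noncontrol = table.noncontrol_ids
    pre = table.counts[noncontrol] if noncontrol else table.counts
    pre_otu_counts = (pre > 0).sum(axis=0)
    pre_read_counts = pre.sum(axis=0)

    if bins is None:
        nan = pd.Series(np.nan, index=pre.columns)
        return ScreenResult(
            screened=table,
            bins=None,
            overlap_fraction=nan,
            group4_fraction=nan.copy(),
            pre_otu_counts=pre_otu_counts,
            post_otu_counts=pre_otu_counts.copy(),
            pre_read_counts=pre_read_counts,
            post_read_counts=pre_read_counts.copy(),
            excluded={},
            unscreened=True,
        )

    missing = set(map(str, table.otu_ids)) - set(bins.bins)
    if missing:
        raise ValueError(f"bins were not computed on this table; missing {sorted(missing)[:5]}")

    overlap = _overlap_fractions(table, bins, OVERLAP_BINS)
    group4 = _overlap_fractions(table, bins, (Bin.CONTROL_SAMPLE,))
    excluded = exclude_contaminated_samples(table, metadata, bins, config)

    keep_otus = [o for o in table.otu_ids if bins.bins[o] is Bin.SAMPLES_ONLY]
    keep_samples = [s for s in noncontrol if s not in excluded]
    screened_counts = table.counts.loc[keep_otus, keep_samples]
    # drop OTUs that only occurred in excluded samples
    screened_counts = screened_counts[screened_counts.sum(axis=1) > 0]
    screened = OtuTable(screened_counts)

    post_otu_counts = (screened.counts > 0).sum(axis=0)
    post_read_counts = screened.counts.sum(axis=0)
    return ScreenResult(
        screened=screened,
        bins=bins,
        overlap_fraction=overlap,
        group4_fraction=group4,
        pre_otu_counts=pre_otu_counts,
        post_otu_counts=post_otu_counts,
        pre_read_counts=pre_read_counts,
        post_read_counts=post_read_counts,
        excluded=excluded,
    )


def _overlap_fractions(table: OtuTable, bins: BinAssignment, which: tuple[Bin, ...]) -> pd.Series:
    """Per-sample fraction of reads in OTUs carrying one of ``which`` bins."""
    noncontrol = table.noncontrol_ids
    counts = table.counts[noncontrol]
    sizes = counts.sum(axis=0)
    otus = [o for o in table.otu_ids if bins.bins.get(o) in which]
    overlap_reads = counts.loc[otus].sum(axis=0) if otus else pd.Series(0, index=counts.columns)
    with np.errstate(invalid="ignore"):
        frac = overlap_reads / sizes
    return frac.fillna(0.0)
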