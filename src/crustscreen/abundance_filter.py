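"""Minimum-abundance filtering of rare OTUs.

Rare OTUs (clusters supported by only a handful of reads across the pooled
dataset) are disproportionately likely to be sequencing artifacts.  This
module removes them before provenance binning, using either a fixed minimum
total count or a fraction of the pooled read total.  Filtering deliberately
precludes singleton-based richness estimation downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .io_tables import OtuTable, ScreenConfig

__all__ = ["FilterReport", "filter_rare_otus"]


@dataclass(frozen=True)
class FilterReport:
    """Outcome of a rare-OTU filtering pass."""

    effective_threshold: int
    keep_at_threshold: bool
    n_input_otus: int
    n_retained_otus: int
    reads_input: int
    reads_retained: int
    per_otu: pd.DataFrame  # columns: total_count, retained

    @property
    def n_removed_otus(self) -> int:
        return self.n_input_otus - self.n_retained_otus

    @property
    def reads_removed(self) -> int:
        return self.reads_input - self.reads_retained

    def to_tsv(self, path) -> None:
        df = self.per_otu.copy()
        df["retained"] = df["retained"].astype(int)
        df.sort_index().to_csv(path, sep="\t")


def filter_rare_otus(table: OtuTable, config: ScreenConfig) -> tuple[OtuTable, FilterReport]:
    """Drop OTUs whose pooled count falls below the configured threshold.

    In ``FIXED_COUNT`` mode the threshold is ``rare_count_min``; in
    ``FRACTION_OF_TOTAL`` mode it is ``ceil(rare_fraction * grand_total)``.
    An OTU is retained when its total count across every sample (control
    included) compares favourably with the threshold: ``>=`` when
    ``rare_keep_at_threshold`` is set (default), ``>`` otherwise.  The sample
    set is never changed by filtering.
    """
    totals = table.counts.sum(axis=1)
    if config.rare_otu_mode == "FIXED_COUNT":
        threshold = int(config.rare_count_min)
    else:
        threshold = int(math.ceil(config.rare_fraction * int(totals.sum())))
    if config.rare_keep_at_threshold:
        retained_mask = totals >= threshold
    else:
        retained_mask = totals > threshold

    retained_ids = [o for o, keep in retained_mask.items() if keep]
    filtered = table.select_otus(retained_ids)

    report = FilterReport(
        effective_threshold=threshold,
        keep_at_threshold=config.rare_keep_at_threshold,
        n_input_otus=len(table.otu_ids),
        n_retained_otus=len(retained_ids),
        reads_input=int(totals.sum()),
        reads_retained=int(filtered.counts.to_numpy().sum()),
        per_otu=pd.DataFrame({"total_count": totals, "retained": retained_mask}),
    )
    if table.otu_ids and not retained_ids:
        warnings.warn(
            f"rare-OTU filter (threshold {threshold}) removed every OTU",
            stacklevel=2,
        )
    return filtered, report
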