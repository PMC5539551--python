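"""Post-screen community summaries.

Taxonomic aggregation at a chosen rank, a ranked view of OTUs shared between
samples, and presence/absence Jaccard similarity between sample pairs.
Composition tables always carry both raw read counts and per-sample read
fractions, since very small libraries are better displayed as counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tables import OtuTable, TaxonomyMap, UNCLASSIFIED

__all__ = [
    "CompositionTable",
    "aggregate_by_rank",
    "shared_otu_matrix",
    "jaccard_matrix",
]


@dataclass(frozen=True)
class CompositionTable:
    """Sample x taxon composition at one rank, as counts and fractions."""

    rank: str
    counts: pd.DataFrame  # sample x taxon, int reads
    fractions: pd.DataFrame  # sample x taxon, rows sum to 1 where N_s > 0

    @property
    def taxa(self) -> list[str]:
        return [str(t) for t in self.counts.columns]


def _taxon_label(taxonomy: TaxonomyMap, otu: str, rank: str) -> str:
    """Label at ``rank``; unclassified ranks pool under their nearest
    classified ancestor as ``unclassified_<ancestor>``."""
    label = taxonomy.label_at(otu, rank)
    if label != UNCLASSIFIED:
        return label
    lineage = taxonomy.lineage(otu)
    idx = taxonomy.ranks.index(rank)
    for parent in reversed(lineage[:idx]):
        if parent != UNCLASSIFIED:
            return f"{UNCLASSIFIED}_{parent}"
    return UNCLASSIFIED


def aggregate_by_rank(table: OtuTable, taxonomy: TaxonomyMap, rank: str) -> CompositionTable:
    """Sum reads per taxon per sample at the given rank.

    Every OTU in the table must have a taxonomy entry (an all-unclassified
    lineage is acceptable).  Read totals are conserved: for each sample the
    taxon counts sum to that sample's library size.
    """
    if rank not in taxonomy.ranks:
        raise ValueError(f"unknown rank {rank!r}; expected one of {taxonomy.ranks}")
    missing = [o for o in table.otu_ids if o not in taxonomy]
    if missing:
        raise KeyError(f"OTUs without taxonomy entries: {missing[:5]}")

    labels = pd.Series(
        {otu: _taxon_label(taxonomy, otu, rank) for otu in table.otu_ids},
        name="taxon",
    )
    counts = table.counts.groupby(labels).sum().T  # sample x taxon
    counts = counts[sorted(counts.columns)]
    sizes = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = counts.div(sizes, axis=0).fillna(0.0)
    return CompositionTable(rank=rank, counts=counts, fractions=fractions)


def shared_otu_matrix(screened: OtuTable) -> pd.DataFrame:
    """OTUs present in two or more samples, ranked by total abundance.

    Returns the count sub-matrix restricted to shared OTUs, rows ordered by
    descending total count with ties broken by ascending OTU id.
    """
    counts = screened.counts
    prevalence = (counts > 0).sum(axis=1)
    shared = counts[prevalence >= 2]
    totals = shared.sum(axis=1)
    order = sorted(shared.index, key=lambda o: (-int(totals[o]), str(o)))
    return shared.loc[order]


def jaccard_matrix(screened: OtuTable) -> pd.DataFrame:
    """Pairwise Jaccard similarity on OTU presence/absence.

    ``J(s, t) = |OTUs(s) & OTUs(t)| / |OTUs(s) | OTUs(t)|``; a pair of
    empty samples is defined as ``J = 0`` (with a warning), and the diagonal
    is 1 for any sample with at least one OTU.
    """
    presence = (screened.counts.to_numpy() > 0).astype(np.int64)
    inter = presence.T @ presence
    sizes = presence.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    if np.any(union == 0):
        warnings.warn("samples with empty OTU sets: their Jaccard entries are 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    samples = screened.sample_ids
    return pd.DataFrame(jac, index=samples, columns=samples)


# -- optional figures -------------------------------------------------------


def composition_barplot(composition: CompositionTable, path, as_counts: bool = False):
    """Stacked-bar composition figure (one bar per sample). Optional extra."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = composition.counts if as_counts else composition.fractions * 100
    ax = data.plot(kind="bar", stacked=True, figsize=(8, 5), width=0.8, colormap="tab20")
    ax.set_ylabel("reads" if as_counts else "% of reads")
    ax.set_xlabel("sample")
    ax.legend(bbox_to_anchor=(1.02, 1), loc="upper left", fontsize=7)
    plt.tight_layout()
    plt.savefig(path, dpi=150)
    plt.close()


def jaccard_heatmap(similarity: pd.DataFrame, path):
    """Heatmap of a Jaccard similarity matrix. Optional extra."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(similarity.to_numpy(), vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(similarity.columns)), similarity.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(similarity.index)), similarity.index, fontsize=7)
    fig.colorbar(im, label="Jaccard index")
    plt.tight_layout()
    plt.savefig(path, dpi=150)
    plt.close(fig)
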