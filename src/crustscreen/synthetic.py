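"""Synthetic low-biomass amplicon datasets with known provenance.

The generator emulates the contamination structure the screening pipeline
assumes: a small number of endemic source communities (clay, carbonate,
basalt), a seawater pool and a reagent pool, mixed per sample according to a
biomass-dependent contaminant fraction ``phi = kappa / (kappa + B)``; a
background control library drawn from the seawater+reagent pools with an
optional "leak" of endemic reads; and qPCR panels with replicate noise and a
realistic negative-control background range.  Every OTU carries a ground
truth source label so screening performance can be scored exactly.

All randomness flows through one ``numpy`` Generator seeded explicitly, so
identical seeds give identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binning import Bin, BinAssignment
from .errors import ValidationError
from .io_tables import (
    RANKS,
    OtuTable,
    QuantConfig,
    SampleMetadata,
    TaxonomyMap,
)
from .quant import QpcrPanel, Target

__all__ = [
    "SOURCE_LABELS",
    "CONTAMINANT_LABELS",
    "SourceProfile",
    "MixtureSpec",
    "SyntheticTruth",
    "RecoveryMetrics",
    "default_profiles",
    "generate_dataset",
    "generate_qpcr_panels",
    "evaluate_binning",
]

SOURCE_LABELS = (
    "ENDEMIC_CLAY",
    "ENDEMIC_CARBONATE",
    "ENDEMIC_BASALT",
    "SEAWATER",
    "REAGENT",
)
CONTAMINANT_LABELS = ("SEAWATER", "REAGENT")

# taxon pools: (weight, lineage) — lineages are labels for aggregation tests,
# no phylogenetic realism claimed
_TAXON_POOLS: dict[str, list[tuple[float, tuple[str, ...]]]] = {
    "ENDEMIC_CLAY": [
        (0.5, ("Bacteria", "Chloroflexi", "Dehalococcoidia", "unclassified", "unclassified", "unclassified")),
        (0.2, ("Bacteria", "Atribacteria", "unclassified", "unclassified", "unclassified", "unclassified")),
        (0.1, ("Bacteria", "Aerophobetes", "unclassified", "unclassified", "unclassified", "unclassified")),
        (0.1, ("Bacteria", "Planctomycetes", "Phycisphaerae", "MSBL9", "unclassified", "unclassified")),
        (0.1, ("Bacteria", "Nitrospirae", "Nitrospira", "Nitrospirales", "unclassified", "unclassified")),
    ],
    "ENDEMIC_CARBONATE": [
        (0.45, ("Bacteria", "Chloroflexi", "Dehalococcoidia", "unclassified", "unclassified", "unclassified")),
        (0.35, ("Bacteria", "Aerophobetes", "unclassified", "unclassified", "unclassified", "unclassified")),
        (0.1, ("Bacteria", "Chloroflexi", "Anaerolineae", "Anaerolineales", "unclassified", "unclassified")),
        (0.1, ("Bacteria", "Proteobacteria", "Deltaproteobacteria", "Desulfobacterales", "unclassified", "unclassified")),
    ],
    "ENDEMIC_BASALT": [
        (0.6, ("Bacteria", "Actinobacteria", "Actinobacteria", "Corynebacteriales", "Nocardiaceae", "Rhodococcus")),
        (0.2, ("Bacteria", "Firmicutes", "Bacilli", "Bacillales", "unclassified", "unclassified")),
        (0.2, ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rhizobiales", "unclassified", "unclassified")),
    ],
    "SEAWATER": [
        (0.4, ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "SAR86", "unclassified", "unclassified")),
        (0.3, ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "SAR11", "unclassified", "unclassified")),
        (0.2, ("Bacteria", "Bacteroidetes", "Flavobacteriia", "Flavobacteriales", "NS4", "unclassified")),
        (0.1, ("Bacteria", "Cyanobacteria", "unclassified", "unclassified", "unclassified", "unclassified")),
    ],
    "REAGENT": [
        (0.5, ("Bacteria", "Actinobacteria", "Actinobacteria", "Micrococcales", "Micrococcaceae", "Arthrobacter")),
        (0.3, ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "unclassified", "unclassified")),
        (0.2, ("Bacteria", "Proteobacteria", "Betaproteobacteria", "Burkholderiales", "unclassified", "unclassified")),
    ],
}


@dataclass(frozen=True)
class SourceProfile:
    """One source community: labelled OTUs with a fixed abundance profile."""

    label: str
    otu_ids: tuple[str, ...]
    abundances: np.ndarray  # sums to 1
    lineages: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if self.label not in SOURCE_LABELS:
            raise ValidationError(f"unknown source label {self.label!r}")
        ab = np.asarray(self.abundances, dtype=float)
        if len(ab) != len(self.otu_ids):
            raise ValidationError(f"{self.label}: abundances/otu_ids length mismatch")
        if np.any(ab < 0) or not np.isclose(ab.sum(), 1.0):
            raise ValidationError(f"{self.label}: abundances must be >= 0 and sum to 1")
        object.__setattr__(self, "abundances", ab / ab.sum())


@dataclass(frozen=True)
class MixtureSpec:
    """Per-sample mixing parameters for one synthetic dataset.

    ``biomass`` maps sample id to a positive biomass proxy ``B``; the
    contaminant read fraction of each sample is ``phi = kappa/(kappa + B)``,
    monotone decreasing in ``B``.  ``omega`` splits contaminant reads between
    the seawater (``omega``) and reagent (``1 - omega``) pools; ``epsilon``
    is the fraction of the control library leaked from endemic material.
    """

    biomass: Mapping[str, float]
    kappa: float = 100.0
    omega: float = 0.6
    epsilon: float = 0.0
    library_sizes: Mapping[str, int] | None = None  # None -> drawn U[3000, 16000]
    control_id: str = "CONTROL"
    control_library_size: int = 4000
    endemic_of_sample: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.biomass:
            raise ValidationError("at least one sample required")
        for sid, b in self.biomass.items():
            if not b > 0:
                raise ValidationError(f"{sid}: biomass must be > 0")
        if self.kappa < 0:
            raise ValidationError("kappa must be >= 0")  # 0 == contamination-free
        if not 0 <= self.omega <= 1:
            raise ValidationError("omega must be in [0, 1]")
        if not 0 <= self.epsilon < 1:
            raise ValidationError("epsilon must be in [0, 1)")
        if self.control_id in self.biomass:
            raise ValidationError("control_id collides with a sample id")

    def phi(self, sample_id: str) -> float:
        """Contaminant read fraction of a sample."""
        return self.kappa / (self.kappa + self.biomass[sample_id])


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic dataset."""

    source_of_otu: Mapping[str, str]
    mixture_weights: pd.DataFrame  # sample x source label
    expected_overlap: pd.Series  # per sample: phi (expected contaminant fraction)


@dataclass(frozen=True)
class RecoveryMetrics:
    """Screening performance against synthetic ground truth."""

    sensitivity: float  # contaminant-origin OTUs caught by the screen
    specificity: float  # endemic-origin OTUs kept as samples-only
    confusion: pd.DataFrame  # source label x bin counts


def default_profiles(
    rng: np.random.Generator,
    n_otus_per_source: int = 40,
    sigma: float = 1.5,
    shared_fraction: float = 0.0,
) -> list[SourceProfile]:
    """Build the five default source profiles with lognormal rank-abundance.

    ``shared_fraction`` > 0 makes that fraction of each endemic pool's OTUs
    reuse seawater-pool ids, emulating taxa genuinely present in both
    environments (the hard case for any control-based screen).
    """
    if not 0 <= shared_fraction <= 1:
        raise ValidationError("shared_fraction must be in [0, 1]")
    n_shared = int(round(shared_fraction * n_otus_per_source))
    seawater_ids = tuple(f"OtuSEAWATER{i:04d}" for i in range(n_otus_per_source))

    def make(label: str) -> SourceProfile:
        ids = tuple(f"Otu{label}{i:04d}" for i in range(n_otus_per_source))
        if label.startswith("ENDEMIC_") and n_shared:
            # endemic pools reuse the most prominent seawater ids
            ids = seawater_ids[:n_shared] + ids[n_shared:]
        ab = rng.lognormal(mean=0.0, sigma=sigma, size=n_otus_per_source)
        ab /= ab.sum()
        pool = _TAXON_POOLS[label]
        weights = np.array([w for w, _ in pool])
        choice = rng.choice(len(pool), size=n_otus_per_source, p=weights / weights.sum())
        lineages = {otu: pool[c][1] for otu, c in zip(ids, choice)}
        return SourceProfile(label, ids, ab, lineages)

    return [make(label) for label in SOURCE_LABELS]


def _universe(profiles: Sequence[SourceProfile]) -> tuple[list[str], dict[str, int]]:
    otus: list[str] = []
    index: dict[str, int] = {}
    for p in profiles:
        for otu in p.otu_ids:
            if otu not in index:
                index[otu] = len(otus)
                otus.append(otu)
    return otus, index


def _profile_vector(p: SourceProfile, index: dict[str, int], n: int) -> np.ndarray:
    v = np.zeros(n)
    for otu, a in zip(p.otu_ids, p.abundances):
        v[index[otu]] += a
    return v


def generate_dataset(
    spec: MixtureSpec,
    profiles: Sequence[SourceProfile] | None = None,
    seed: int = 0,
) -> tuple[OtuTable, TaxonomyMap, dict[str, SampleMetadata], SyntheticTruth]:
    """Draw one complete synthetic dataset.

    Per sample ``s`` reads are multinomial with ``N_s`` trials from the
    mixture ``(1 - phi_s) * endemic(s) + phi_s * (omega * seawater +
    (1 - omega) * reagent)``; the control library is drawn from the
    contaminant mixture with an ``epsilon`` leak of pooled endemic material.
    The returned table has the control designated via its role.
    """
    rng = np.random.default_rng(seed)
    if profiles is None:
        profiles = default_profiles(rng)
    by_label = {p.label: p for p in profiles}
    for needed in ("SEAWATER", "REAGENT"):
        if needed not in by_label:
            raise ValidationError(f"profiles must include a {needed} pool")
    endemic_labels = [l for l in by_label if l.startswith("ENDEMIC_")]
    if not endemic_labels:
        raise ValidationError("profiles must include at least one ENDEMIC_* pool")

    otus, index = _universe(profiles)
    n = len(otus)
    sw = _profile_vector(by_label["SEAWATER"], index, n)
    rg = _profile_vector(by_label["REAGENT"], index, n)
    contaminant_mix = spec.omega * sw + (1 - spec.omega) * rg

    # sample ids in a fixed order for determinism
    sample_ids = sorted(spec.biomass)
    sizes: dict[str, int] = {}
    for sid in sample_ids:
        if spec.library_sizes is not None and sid in spec.library_sizes:
            sizes[sid] = int(spec.library_sizes[sid])
        else:
            sizes[sid] = int(rng.integers(3000, 16001))

    endemic_vec: dict[str, np.ndarray] = {
        l: _profile_vector(by_label[l], index, n) for l in endemic_labels
    }
    pooled_endemic = np.mean(list(endemic_vec.values()), axis=0)

    counts = np.zeros((n, len(sample_ids) + 1), dtype=np.int64)
    weights_rows = []
    phis = []
    for j, sid in enumerate(sample_ids):
        endemic_label = spec.endemic_of_sample.get(sid) or endemic_labels[j % len(endemic_labels)]
        if endemic_label not in endemic_vec:
            raise ValidationError(f"{sid}: unknown endemic pool {endemic_label!r}")
        phi = spec.phi(sid)
        mix = (1 - phi) * endemic_vec[endemic_label] + phi * contaminant_mix
        mix = mix / mix.sum()
        counts[:, j] = rng.multinomial(sizes[sid], mix)
        phis.append(phi)
        row = {l: 0.0 for l in SOURCE_LABELS}
        row[endemic_label] = 1 - phi
        row["SEAWATER"] = phi * spec.omega
        row["REAGENT"] = phi * (1 - spec.omega)
        weights_rows.append(row)

    control_mix = (1 - spec.epsilon) * contaminant_mix + spec.epsilon * pooled_endemic
    control_mix = control_mix / control_mix.sum()
    counts[:, -1] = rng.multinomial(spec.control_library_size, control_mix)

    all_ids = sample_ids + [spec.control_id]
    table = OtuTable(
        pd.DataFrame(counts, index=pd.Index(otus, name="otu_id"), columns=all_ids)
    ).with_control(spec.control_id)

    lineages: dict[str, tuple[str, ...]] = {}
    source_of_otu: dict[str, str] = {}
    for p in profiles:  # first profile claiming an OTU id wins (shared ids)
        for otu in p.otu_ids:
            if otu not in source_of_otu:
                source_of_otu[otu] = p.label
                lineages[otu] = p.lineages[otu]
    taxonomy = TaxonomyMap(lineages, RANKS)

    metadata: dict[str, SampleMetadata] = {}
    for j, sid in enumerate(sample_ids):
        metadata[sid] = SampleMetadata(
            sample_id=sid,
            depth_mbsf=10.0 * (j + 1),
            lithology="synthetic",
            material="sediment",
            microsphere_count=0.0,
        )
    metadata[spec.control_id] = SampleMetadata(
        sample_id=spec.control_id,
        material="control_artifact",
        microsphere_count=None,
    )

    truth = SyntheticTruth(
        source_of_otu=source_of_otu,
        mixture_weights=pd.DataFrame(weights_rows, index=sample_ids)[list(SOURCE_LABELS)],
        expected_overlap=pd.Series(phis, index=sample_ids, name="phi"),
    )
    return table, taxonomy, metadata, truth


def generate_qpcr_panels(
    true_copies: Mapping[str, float],
    seed: int = 0,
    config: QuantConfig | None = None,
    target: Target = Target.BACTERIA_16S,
    n_reps: int = 2,
    noise_sigma: float = 0.2,
    background_range: tuple[float, float] = (35.0, 285.0),
) -> tuple[list[QpcrPanel], pd.DataFrame]:
    """Draw qPCR panels around known true copy concentrations.

    Each run draws one background level uniformly from ``background_range``
    (the default span mirrors typical bacterial negative-control levels);
    negatives scatter lognormally around it and sample replicates around
    ``true + background``.  ``noise_sigma=0`` collapses to the deterministic
    rule on true values.  Returns the panels plus a truth frame.
    """
    config = config or QuantConfig()
    rng = np.random.default_rng(seed)
    panels: list[QpcrPanel] = []
    rows = []
    noise = lambda k: (
        np.ones(k) if noise_sigma == 0
        else rng.lognormal(mean=-0.5 * noise_sigma**2, sigma=noise_sigma, size=k)
    )
    for sid in sorted(true_copies):
        true = float(true_copies[sid])
        if true < 0:
            raise ValidationError(f"{sid}: true copies must be >= 0")
        background = float(rng.uniform(*background_range))
        ext = tuple(background * noise(n_reps))
        pcr = tuple(background * noise(n_reps))
        reps = tuple((true + background) * noise(n_reps))
        panels.append(QpcrPanel(sid, target, reps, ext, pcr, config))
        rows.append({"sample_id": sid, "true_copies_per_ul": true,
                     "background_copies_per_ul": background})
    return panels, pd.DataFrame(rows).set_index("sample_id")


def evaluate_binning(truth: SyntheticTruth, bins: BinAssignment) -> RecoveryMetrics:
    """Score a bin assignment against ground-truth source labels.

    Sensitivity: fraction of contaminant-origin (seawater/reagent) OTUs
    placed in a control-associated bin (control-only, tenfold, or
    control:sample).  Specificity: fraction of endemic-origin OTUs placed in
    the samples-only bin.  Metrics are computed over the binned OTU set
    (rare-OTU filtering may have removed part of the generated universe).
    """
    unknown = set(bins.bins) - set(truth.source_of_otu)
    if unknown:
        raise ValidationError(f"binned OTUs missing from truth: {sorted(unknown)[:5]}")

    caught = (Bin.CONTROL_ONLY, Bin.TENFOLD_SAMPLE, Bin.CONTROL_SAMPLE)
    n_cont = n_cont_caught = n_end = n_end_kept = 0
    confusion = pd.DataFrame(
        0, index=list(SOURCE_LABELS), columns=[b.value for b in Bin], dtype=int
    )
    for otu, b in bins.bins.items():
        label = truth.source_of_otu[otu]
        confusion.loc[label, b.value] += 1
        if label in CONTAMINANT_LABELS:
            n_cont += 1
            n_cont_caught += b in caught
        else:
            n_end += 1
            n_end_kept += b is Bin.SAMPLES_ONLY
    sensitivity = n_cont_caught / n_cont if n_cont else float("nan")
    specificity = n_end_kept / n_end if n_end else float("nan")
    return RecoveryMetrics(sensitivity, specificity, confusion)
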