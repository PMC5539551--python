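"""Tabular I/O, domain containers, and run configuration.

This module owns the on-disk formats used throughout the pipeline:

* OTU count matrices, either as plain TSV (OTU rows x sample columns) or in
  the mothur ``.shared`` layout (``label``/``Group``/``numOtus`` columns
  followed by per-OTU counts, one row per sample);
* taxonomy assignments as two- or three-column files with semicolon-delimited
  lineages, tolerating bootstrap annotations in parentheses;
* sample metadata tables (depth, lithology, microsphere tracer counts, ...);
* run configuration (:class:`ScreenConfig`, :class:`QuantConfig`) as YAML.

All readers validate aggressively: counts must be non-negative integers,
identifiers must be unique, and library sizes are always recomputed from the
matrix rather than trusted from a file.
"""

from __future__ import annotations

import dataclasses
import enum
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, TableFormatError, ValidationError

__all__ = [
    "RANKS",
    "SampleRole",
    "OtuTable",
    "TaxonomyMap",
    "SampleMetadata",
    "ScreenConfig",
    "QuantConfig",
    "read_otu_table",
    "write_otu_table",
    "read_taxonomy",
    "read_metadata",
    "write_metadata",
    "load_config",
    "write_report",
]

#: Ordered taxonomic ranks used for aggregation.
RANKS: tuple[str, ...] = ("domain", "phylum", "class", "order", "family", "genus")

#: Canonical token for an unclassified rank.
UNCLASSIFIED = "unclassified"

_MOTHUR_COLUMNS = ("label", "Group", "numOtus")
_BOOTSTRAP_RE = re.compile(r"\(\d+(?:\.\d+)?\)")


class SampleRole(str, enum.Enum):
    """Role of a library in a screening run."""

    SAMPLE = "SAMPLE"
    CONTROL = "CONTROL"


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OtuTable:
    """An integer OTU-by-sample count matrix with per-sample roles.

    Parameters
    ----------
    counts
        Integer matrix with OTU ids as the index and sample ids as columns.
    roles
        Mapping ``sample_id -> SampleRole``; samples absent from the mapping
        default to :attr:`SampleRole.SAMPLE`.  At most one sample may carry
        the CONTROL role.

    Notes
    -----
    Library sizes are always derived from the column sums; they are never an
    input.  The container is immutable: derived tables are new objects.
    """

    counts: pd.DataFrame
    roles: Mapping[str, SampleRole] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate OTU ids: {dupes}")
        if counts.columns.has_duplicates:
            dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        arr = counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                raise ValidationError("counts must be integers")
            counts = counts.astype(np.int64)
            object.__setattr__(self, "counts", counts)
            arr = counts.to_numpy()
        if arr.size and arr.min() < 0:
            raise ValidationError("counts must be non-negative")
        roles = {str(s): SampleRole(r) for s, r in dict(self.roles).items()}
        unknown = set(roles) - set(map(str, counts.columns))
        if unknown:
            raise ValidationError(f"roles name unknown samples: {sorted(unknown)}")
        controls = [s for s, r in roles.items() if r is SampleRole.CONTROL]
        if len(controls) > 1:
            raise ValidationError(f"at most one CONTROL sample allowed, got {controls}")
        object.__setattr__(self, "roles", roles)

    # -- basic views --------------------------------------------------------

    @property
    def otu_ids(self) -> list[str]:
        return [str(i) for i in self.counts.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.counts.columns]

    @property
    def library_sizes(self) -> pd.Series:
        """Per-sample library size ``N_s`` (column sums, recomputed)."""
        return self.counts.sum(axis=0)

    @property
    def control_id(self) -> str | None:
        for s, r in self.roles.items():
            if r is SampleRole.CONTROL:
                return s
        return None

    @property
    def noncontrol_ids(self) -> list[str]:
        ctrl = self.control_id
        return [s for s in self.sample_ids if s != ctrl]

    @property
    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    # -- derivations --------------------------------------------------------

    def with_control(self, control_id: str) -> "OtuTable":
        """Return a copy with ``control_id`` designated as the CONTROL sample."""
        if control_id not in self.sample_ids:
            raise ValidationError(f"control sample {control_id!r} not in table")
        roles = {s: SampleRole.SAMPLE for s in self.sample_ids}
        roles[control_id] = SampleRole.CONTROL
        return OtuTable(self.counts, roles)

    def select_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        return OtuTable(self.counts.loc[list(otu_ids)], dict(self.roles))

    def select_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        keep = [s for s in self.sample_ids if s in set(sample_ids)]
        roles = {s: r for s, r in self.roles.items() if s in set(keep)}
        return OtuTable(self.counts[keep], roles)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return self.counts.equals(other.counts) and dict(self.roles) == dict(other.roles)


@dataclass(frozen=True)
class TaxonomyMap:
    """OTU id -> ordered lineage (domain ... genus).

    Lineages are stored with confidence annotations stripped and unclassified
    ranks normalised to the token ``"unclassified"``.
    """

    lineages: Mapping[str, tuple[str, ...]]
    ranks: tuple[str, ...] = RANKS

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, ...]] = {}
        for otu, lineage in dict(self.lineages).items():
            lineage = tuple(lineage)
            if len(lineage) > len(self.ranks):
                raise ValidationError(
                    f"{otu}: lineage longer than {len(self.ranks)} ranks: {lineage}"
                )
            clean[str(otu)] = lineage
        object.__setattr__(self, "lineages", clean)

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.lineages

    def __len__(self) -> int:
        return len(self.lineages)

    def lineage(self, otu_id: str) -> tuple[str, ...]:
        return self.lineages[otu_id]

    def label_at(self, otu_id: str, rank: str) -> str:
        """Label of ``otu_id`` at ``rank``, or ``"unclassified"`` if absent."""
        if rank not in self.ranks:
            raise ValueError(f"unknown rank {rank!r}; expected one of {self.ranks}")
        i = self.ranks.index(rank)
        lineage = self.lineages[otu_id]
        if i >= len(lineage):
            return UNCLASSIFIED
        return lineage[i]

    def covers(self, otu_ids: Iterable[str]) -> bool:
        return all(o in self.lineages for o in otu_ids)


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample contextual metadata (depth, lithology, tracer counts)."""

    sample_id: str
    hole: str = ""
    depth_mbsf: float | None = None
    lithology: str = ""
    material: str = "sediment"  # sediment | basalt | control_artifact
    microsphere_count: float | None = None  # None == not measured
    sulfate_mM: float | None = None

    def __post_init__(self) -> None:
        if self.depth_mbsf is not None and self.depth_mbsf < 0:
            raise ValidationError(f"{self.sample_id}: depth must be >= 0")
        if self.microsphere_count is not None and self.microsphere_count < 0:
            raise ValidationError(f"{self.sample_id}: microsphere count must be >= 0")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenConfig:
    """Parameters of the rare-OTU filter and the four-bin screen."""

    ratio_threshold: float = 10.0
    rare_otu_mode: str = "FIXED_COUNT"  # FIXED_COUNT | FRACTION_OF_TOTAL
    rare_count_min: int = 5
    rare_fraction: float = 5e-5
    rare_keep_at_threshold: bool = True
    ratio_comparison: str = "GE"  # GE | GT
    sample_exclusion_overlap_threshold: float = 0.99
    jaccard_input: str = "POST_SCREEN"  # POST_SCREEN | PRE_SCREEN

    def __post_init__(self) -> None:
        if not self.ratio_threshold > 1:
            raise ConfigurationError("ratio_threshold must be > 1")
        if self.rare_otu_mode not in ("FIXED_COUNT", "FRACTION_OF_TOTAL"):
            raise ConfigurationError(f"bad rare_otu_mode {self.rare_otu_mode!r}")
        if self.rare_count_min < 0:
            raise ConfigurationError("rare_count_min must be >= 0")
        if not 0 <= self.rare_fraction <= 1:
            raise ConfigurationError("rare_fraction must be in [0, 1]")
        if self.ratio_comparison not in ("GE", "GT"):
            raise ConfigurationError(f"bad ratio_comparison {self.ratio_comparison!r}")
        if not 0 <= self.sample_exclusion_overlap_threshold <= 1:
            raise ConfigurationError("sample_exclusion_overlap_threshold must be in [0, 1]")
        if self.jaccard_input not in ("POST_SCREEN", "PRE_SCREEN"):
            raise ConfigurationError(f"bad jaccard_input {self.jaccard_input!r}")


@dataclass(frozen=True)
class QuantConfig:
    """Parameters of qPCR detection calls and biomass conversion."""

    detection_factor: float = 2.0
    operons_per_cell: float = 4.0
    sediment_density: float = 2.5  # g cm^-3
    elution_volume: float | None = None  # microlitre
    extracted_mass: float | None = None  # gram

    def __post_init__(self) -> None:
        for name in ("detection_factor", "operons_per_cell", "sediment_density"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("elution_volume", "extracted_mass"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ConfigurationError(f"{name} must be > 0 when given")


def load_config(path: str | Path) -> tuple[ScreenConfig, QuantConfig, dict]:
    """Load a YAML config file into (ScreenConfig, QuantConfig, extras).

    The file may carry top-level ``screen:`` and ``quant:`` mappings whose
    keys mirror the dataclass field names; everything else is returned
    verbatim in ``extras`` (input paths, control id, output directory, seed).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(raw).__name__}")
    screen = _build_dataclass(ScreenConfig, raw.pop("screen", {}) or {})
    quant = _build_dataclass(QuantConfig, raw.pop("quant", {}) or {})
    return screen, quant, raw


def _build_dataclass(cls, mapping: Mapping):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ConfigurationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**mapping)


# ---------------------------------------------------------------------------
# OTU table I/O
# ---------------------------------------------------------------------------


def read_otu_table(path: str | Path, dialect: str = "auto") -> OtuTable:
    """Read an OTU count table.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"mothur"`` for the mothur ``.shared`` layout, ``"tsv"`` for a plain
        OTU x sample matrix, or ``"auto"`` to sniff (default).  Plain TSV
        orientation (OTU rows vs sample rows) is auto-detected from id
        prefixes; ambiguous tables are assumed to have OTU rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "auto":
        dialect = _sniff_dialect(path)
    if dialect == "mothur":
        return _read_mothur_shared(path)
    if dialect == "tsv":
        return _read_tsv_matrix(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _sniff_dialect(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if tuple(fields[:3]) == _MOTHUR_COLUMNS:
                return "mothur"
            return "tsv"
    raise TableFormatError(f"{path}: empty file")


def _read_mothur_shared(path: Path) -> OtuTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if tuple(df.columns[:3]) != _MOTHUR_COLUMNS:
        raise TableFormatError(
            f"{path}: mothur shared files must start with columns {_MOTHUR_COLUMNS}"
        )
    samples = df["Group"].astype(str).tolist()
    body = df.drop(columns=list(_MOTHUR_COLUMNS))
    counts = _coerce_counts(body, path).T
    counts.columns = samples
    counts.index.name = "otu_id"
    return OtuTable(counts)


def _read_tsv_matrix(path: Path) -> OtuTable:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    if df.empty and df.columns.empty:
        raise TableFormatError(f"{path}: no data rows")
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    counts = _coerce_counts(df, path)
    rows_look_like_otus = _looks_like_otu_ids(counts.index)
    cols_look_like_otus = _looks_like_otu_ids(counts.columns)
    if cols_look_like_otus and not rows_look_like_otus:
        counts = counts.T
    counts.index.name = "otu_id"
    return OtuTable(counts)


def _looks_like_otu_ids(ids: Iterable[str]) -> bool:
    ids = list(ids)
    if not ids:
        return False
    hits = sum(bool(re.match(r"(?i)^otu", str(i))) for i in ids)
    return hits >= max(1, len(ids) // 2)


def _coerce_counts(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    try:
        as_float = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-numeric count cell ({exc})") from None
    arr = as_float.to_numpy()
    if arr.size:
        if not np.all(np.isfinite(arr)):
            raise ValidationError(f"{path}: missing or non-finite count cells")
        if np.any(arr != np.floor(arr)):
            raise ValidationError(f"{path}: counts must be integers")
        if arr.min() < 0:
            raise ValidationError(f"{path}: counts must be non-negative")
    return as_float.astype(np.int64)


def write_otu_table(table: OtuTable, path: str | Path, dialect: str = "tsv") -> None:
    """Write an OTU table as plain TSV or mothur ``.shared``; rows sorted by id."""
    path = Path(path)
    counts = table.counts.sort_index()
    counts = counts[sorted(counts.columns)]
    if dialect == "tsv":
        counts.index.name = "otu_id"
        counts.to_csv(path, sep="\t")
    elif dialect == "mothur":
        shared = counts.T
        out = pd.DataFrame(
            {
                "label": "0.03",
                "Group": shared.index,
                "numOtus": shared.shape[1],
            }
        )
        out = pd.concat([out.reset_index(drop=True), shared.reset_index(drop=True)], axis=1)
        out.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Taxonomy I/O
# ---------------------------------------------------------------------------


def parse_lineage(text: str, ranks: tuple[str, ...] = RANKS) -> tuple[str, ...]:
    """Split a semicolon-delimited lineage, stripping bootstrap annotations.

    ``"Bacteria(100);Chloroflexi(98);"`` -> ``("Bacteria", "Chloroflexi")``.
    Tokens that are empty or carry an "unclassified"/"unknown" marker are
    normalised to ``"unclassified"``; trailing unclassified tokens beyond the
    configured rank depth are truncated.
    """
    text = _BOOTSTRAP_RE.sub("", text.strip()).strip()
    tokens = [t.strip().strip('"') for t in text.split(";")]
    tokens = [t for t in tokens if t != ""] if tokens else []
    out = []
    for t in tokens:
        low = t.lower()
        if low in ("", "unknown") or "unclassified" in low:
            out.append(UNCLASSIFIED)
        else:
            out.append(t)
    # mothur pads lineages with repeated *_unclassified entries past genus
    return tuple(out[: len(ranks)])


def read_taxonomy(path: str | Path, ranks: tuple[str, ...] = RANKS) -> TaxonomyMap:
    """Read a mothur-style taxonomy file (otu, [size,] lineage)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lineages: dict[str, tuple[str, ...]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split(None, 2)
            if len(fields) < 2:
                raise TableFormatError(f"{path}:{lineno}: expected >= 2 columns")
            if fields[0].strip().lower() in ("otu", "otu_id") and lineno == 1:
                continue  # header row
            otu = fields[0].strip()
            lineage_text = fields[-1]
            lineage = parse_lineage(lineage_text, ranks)
            if otu in lineages and lineages[otu] != lineage:
                raise ValidationError(
                    f"{path}:{lineno}: conflicting lineages for {otu!r}"
                )
            lineages[otu] = lineage
    return TaxonomyMap(lineages, ranks)


def write_taxonomy(taxonomy: TaxonomyMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("otu_id\ttaxonomy\n")
        for otu in sorted(taxonomy.lineages):
            fh.write(f"{otu}\t{';'.join(taxonomy.lineages[otu])};\n")


# ---------------------------------------------------------------------------
# Metadata I/O
# ---------------------------------------------------------------------------

_MISSING_TOKENS = {"", "na", "n.a.", "nan", "nm", "n.m.", "none", "not measured"}


def _parse_optional_float(token: str) -> float | None:
    if token.strip().lower() in _MISSING_TOKENS:
        return None
    return float(token)


def read_metadata(path: str | Path) -> dict[str, SampleMetadata]:
    """Read a sample metadata TSV keyed by ``sample_id``.

    Recognised columns: ``sample_id`` (required), ``hole``, ``depth_mbsf``,
    ``lithology``, ``material``, ``microsphere_count``, ``sulfate_mM``.
    Missing-value tokens (``n.a.``, ``n.m.``, empty) map to ``None``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    if "sample_id" not in df.columns:
        raise TableFormatError(f"{path}: missing required column 'sample_id'")
    out: dict[str, SampleMetadata] = {}
    for _, row in df.iterrows():
        sid = row["sample_id"].strip()
        if sid in out:
            raise ValidationError(f"{path}: duplicate sample_id {sid!r}")
        out[sid] = SampleMetadata(
            sample_id=sid,
            hole=row.get("hole", ""),
            depth_mbsf=_parse_optional_float(row.get("depth_mbsf", "")),
            lithology=row.get("lithology", ""),
            material=row.get("material", "sediment") or "sediment",
            microsphere_count=_parse_optional_float(row.get("microsphere_count", "")),
            sulfate_mM=_parse_optional_float(row.get("sulfate_mM", "")),
        )
    return out


def write_metadata(metadata: Mapping[str, SampleMetadata], path: str | Path) -> None:
    cols = ["sample_id", "hole", "depth_mbsf", "lithology", "material",
            "microsphere_count", "sulfate_mM"]
    rows = []
    for sid in sorted(metadata):
        m = metadata[sid]
        rows.append([
            m.sample_id, m.hole,
            "" if m.depth_mbsf is None else m.depth_mbsf,
            m.lithology, m.material,
            "n.m." if m.microsphere_count is None else m.microsphere_count,
            "n.a." if m.sulfate_mM is None else m.sulfate_mM,
        ])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------


def write_report(result, outdir: str | Path, composition=None) -> dict[str, Path]:
    """Write a screening result as a set of deterministic TSVs.

    Emits ``bins.tsv`` (per-OTU bin assignment and enrichment ratio),
    ``sample_summary.tsv`` (per-sample pre/post-screen OTU and read counts,
    overlap fractions, exclusion reasons) and, when a composition table is
    supplied, ``composition_<rank>.tsv``.  Rows are sorted by OTU id then
    sample id so repeated runs are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    bins_path = outdir / "bins.tsv"
    with open(bins_path, "w", encoding="utf-8") as fh:
        fh.write("otu_id\tbin\tratio\n")
        if result.bins is not None:
            for otu in sorted(result.bins.bins):
                ratio = result.bins.ratio.get(otu)
                ratio_s = "" if ratio is None else (
                    "inf" if math.isinf(ratio) else f"{ratio:.6g}")
                fh.write(f"{otu}\t{result.bins.bins[otu].value}\t{ratio_s}\n")
    written["bins"] = bins_path

    summary_path = outdir / "sample_summary.tsv"
    with open(summary_path, "w", encoding="utf-8") as fh:
        fh.write(
            "sample_id\tpre_otus\tpost_otus\tpre_reads\tpost_reads\t"
            "overlap_fraction\tgroup4_fraction\texcluded\treason\n"
        )
        for sid in sorted(result.pre_otu_counts.index):
            reason = result.excluded.get(sid, "")
            fh.write(
                f"{sid}\t{result.pre_otu_counts[sid]}\t"
                f"{result.post_otu_counts.get(sid, 0)}\t"
                f"{result.pre_read_counts[sid]}\t"
                f"{result.post_read_counts.get(sid, 0)}\t"
                f"{result.overlap_fraction.get(sid, float('nan')):.6g}\t"
                f"{result.group4_fraction.get(sid, float('nan')):.6g}\t"
                f"{int(sid in result.excluded)}\t{reason}\n"
            )
    written["sample_summary"] = summary_path

    if composition is not None:
        comp_path = outdir / f"composition_{composition.rank}.tsv"
        frac = composition.fractions.sort_index()
        frac = frac[sorted(frac.columns)]
        frac.index.name = "sample_id"
        frac.to_csv(comp_path, sep="\t", float_format="%.6g")
        written["composition"] = comp_path
    return written
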