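"""Data model and file I/O for segmented copy-number profiles and annotations.

All genomic coordinates held in memory are 1-based and inclusive, matching
array annotation tables; BED input/output converts at the boundary.  Probe
indices are 0-based *within* a chromosome.  Copy-number call states follow the
CGHcall convention (``-2`` double loss, ``-1`` loss, ``0`` neutral, ``1`` gain,
``2`` amplification); downstream code only distinguishes neutral (``0``) from
non-neutral, so any integer coding with 0 = neutral is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "ProbeMap",
    "Segment",
    "SegmentedProfile",
    "GeneModel",
    "ClinicalTable",
    "BinaryEventMatrix",
    "ParseError",
    "read_probes",
    "write_probes",
    "read_segments",
    "write_segments",
    "read_genes",
    "write_genes",
    "read_matrix",
    "write_matrix",
    "read_clinical",
    "write_clinical",
    "read_network",
    "write_network",
]

SEGMENT_COLUMNS = ["sample", "chromosome", "start_probe", "end_probe", "mean_log2", "call"]


class ParseError(ValueError):
    """A file violated the structural invariants of its format."""


class Segment(NamedTuple):
    """A run of probes sharing one copy-number level.

    ``start_probe``/``end_probe`` are 0-based within-chromosome probe indices,
    end inclusive.  ``call`` is the discretized state, 0 = neutral.
    """

    start_probe: int
    end_probe: int
    mean_log2: float
    call: int


class GeneModel(NamedTuple):
    """A gene span on the probe grid's genome build (1-based, inclusive)."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"


@dataclass(frozen=True)
class ProbeMap:
    """Ordered genomic probe positions, grouped by chromosome.

    Parameters
    ----------
    table
        DataFrame with columns ``probe_id``, ``chromosome``, ``position``
        (1-based bp).  Probes must be unique and sorted by position within
        each chromosome.
    """

    table: pd.DataFrame
    _positions: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        required = {"probe_id", "chromosome", "position"}
        missing = required - set(self.table.columns)
        if missing:
            raise ParseError(f"probe table missing columns: {sorted(missing)}")
        if self.table["probe_id"].duplicated().any():
            dup = self.table.loc[self.table["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ParseError(f"duplicate probe id: {dup}")
        pos = {}
        for chrom, sub in self.table.groupby("chromosome", sort=False):
            p = sub["position"].to_numpy(dtype=np.int64)
            if np.any(np.diff(p) <= 0):
                raise ParseError(f"probe positions not strictly increasing on {chrom}")
            pos[str(chrom)] = p
        object.__setattr__(self, "_positions", pos)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._positions)

    def positions(self, chromosome: str) -> np.ndarray:
        """Sorted probe positions (bp) of one chromosome."""
        return self._positions[chromosome]

    def n_probes(self, chromosome: str | None = None) -> int:
        if chromosome is None:
            return int(len(self.table))
        return int(len(self._positions[chromosome]))


@dataclass
class SegmentedProfile:
    """One sample's segmented, state-called copy-number profile.

    ``segments`` maps chromosome label to the ordered segment list; on each
    chromosome the segments tile the probe range contiguously.
    """

    sample_id: str
    segments: dict[str, list[Segment]]

    def validate(self, probe_map: ProbeMap | None = None) -> None:
        for chrom, segs in self.segments.items():
            if not segs:
                raise ParseError(f"{self.sample_id}/{chrom}: empty segment list")
            prev_end = None
            for seg in segs:
                if seg.start_probe > seg.end_probe:
                    raise ParseError(
                        f"{self.sample_id}/{chrom}: segment start {seg.start_probe} "
                        f"> end {seg.end_probe}"
                    )
                if prev_end is not None and seg.start_probe != prev_end + 1:
                    raise ParseError(
                        f"{self.sample_id}/{chrom}: gap or overlap between probe "
                        f"{prev_end} and {seg.start_probe}"
                    )
                prev_end = seg.end_probe
            if segs[0].start_probe != 0:
                raise ParseError(
                    f"{self.sample_id}/{chrom}: first segment starts at probe "
                    f"{segs[0].start_probe}, expected 0"
                )
            if probe_map is not None:
                n = probe_map.n_probes(chrom)
                if segs[-1].end_probe != n - 1:
                    raise ParseError(
                        f"{self.sample_id}/{chrom}: last segment ends at probe "
                        f"{segs[-1].end_probe}, expected {n - 1}"
                    )

    def n_breakpoint_candidates(self) -> int:
        """Number of within-chromosome segment boundaries, before filtering."""
        return sum(len(s) - 1 for s in self.segments.values())


@dataclass
class ClinicalTable:
    """Per-sample clinical follow-up: overall survival and MSI status.

    Columns: ``sample`` (index), ``os_days`` (non-negative), ``event``
    (1 = death observed, 0 = censored), ``msi_status`` (0/1, NaN if unknown).
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        if t.index.name != "sample":
            if "sample" in t.columns:
                t = t.set_index("sample")
            else:
                raise ParseError("clinical table needs a 'sample' column or index")
        for col in ("os_days", "event"):
            if col not in t.columns:
                raise ParseError(f"clinical table missing column {col!r}")
        if t.index.duplicated().any():
            raise ParseError("duplicate sample in clinical table")
        if (t["os_days"] < 0).any():
            raise ParseError("negative os_days in clinical table")
        if not t["event"].isin([0, 1]).all():
            raise ParseError("event indicator must be 0/1")
        self.table = t

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    def subset(self, samples: Iterable[str]) -> "ClinicalTable":
        return ClinicalTable(self.table.loc[list(samples)].copy())


@dataclass
class BinaryEventMatrix:
    """Binary incidence matrix, rows = genes or probes, columns = samples."""

    data: pd.DataFrame

    def __post_init__(self):
        if self.data.index.duplicated().any():
            raise ParseError("duplicate row labels in binary matrix")
        if self.data.columns.duplicated().any():
            raise ParseError("duplicate column labels in binary matrix")
        vals = self.data.to_numpy()
        if vals.size and not np.isin(vals, [0, 1]).all():
            bad = vals[~np.isin(vals, [0, 1])].flat[0]
            raise ParseError(f"non-binary entry in matrix: {bad!r}")
        self.data = self.data.astype(np.int8)

    @property
    def rows(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def values(self) -> np.ndarray:
        return self.data.to_numpy()


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_probes(path) -> ProbeMap:
    """Read a probe annotation TSV (columns probe_id, chromosome, position)."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chromosome": str})
    return ProbeMap(df)


def write_probes(probe_map: ProbeMap, path) -> None:
    probe_map.table.to_csv(path, sep="\t", index=False)


def read_segments(path, probe_map: ProbeMap | None = None) -> list[SegmentedProfile]:
    """Read a SEG-like TSV into validated :class:`SegmentedProfile` objects.

    Expected columns: sample, chromosome, start_probe, end_probe, mean_log2,
    call.  Per sample and chromosome, segments must tile the probe range
    contiguously; violations raise :class:`ParseError` naming the sample and
    chromosome.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chromosome": str})
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"segment file missing columns: {sorted(missing)}")
    profiles = []
    for sample, sub in df.groupby("sample", sort=False):
        segments: dict[str, list[Segment]] = {}
        for chrom, rows in sub.groupby("chromosome", sort=False):
            rows = rows.sort_values("start_probe")
            segments[str(chrom)] = [
                Segment(int(r.start_probe), int(r.end_probe), float(r.mean_log2), int(r.call))
                for r in rows.itertuples()
            ]
        prof = SegmentedProfile(str(sample), segments)
        prof.validate(probe_map)
        profiles.append(prof)
    return profiles


def write_segments(profiles: Iterable[SegmentedProfile], path) -> None:
    records = []
    for prof in profiles:
        for chrom, segs in prof.segments.items():
            for seg in segs:
                records.append((prof.sample_id, chrom, seg.start_probe, seg.end_probe,
                                seg.mean_log2, seg.call))
    pd.DataFrame(records, columns=SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_genes(path) -> list[GeneModel]:
    """Read gene annotation from BED4+ (0-based half-open) into 1-based inclusive spans."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         dtype={0: str, 3: str})
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    genes = []
    seen = set()
    for r in df.itertuples(index=False):
        chrom, bed_start, bed_end, gene_id = str(r[0]), int(r[1]), int(r[2]), str(r[3])
        strand = str(r[5]) if len(r) > 5 else "+"
        start, end = bed_start + 1, bed_end  # BED half-open -> 1-based inclusive
        if start > end:
            raise ParseError(f"gene {gene_id}: start {start} > end {end}")
        if gene_id in seen:
            raise ParseError(f"duplicate gene id: {gene_id}")
        seen.add(gene_id)
        genes.append(GeneModel(gene_id, chrom, start, end, strand))
    return genes


def write_genes(genes: Iterable[GeneModel], path) -> None:
    rows = [(g.chromosome, g.start - 1, g.end, g.gene_id, 0, g.strand) for g in genes]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_matrix(path) -> BinaryEventMatrix:
    """Read a genes-or-probes × samples binary matrix TSV (rows labelled)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return BinaryEventMatrix(df)


def write_matrix(matrix: BinaryEventMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t")


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path) -> None:
    clinical.table.to_csv(path, sep="\t")


def read_network(path) -> pd.DataFrame:
    """Read a two- or three-column (gene_a, gene_b[, weight]) edge list TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    if "weight" not in df.columns:
        df["weight"] = 1.0
    if (df["weight"] < 0).any():
        raise ParseError("negative edge weight in network")
    return df[["gene_a", "gene_b", "weight"]]


def write_network(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)
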