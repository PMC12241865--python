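"""Region catalog: HERV loci and host genes, with deterministic window partitions.

A *region* is a genomic interval (a HERV provirus or a neighbouring host gene)
carried with its reference sequence.  Every region is tiled by sequential,
non-overlapping windows of a fixed length ``L``; the final window may be
shorter so that the tiling covers the region exactly.  All downstream scoring
(per-window depth, usable-window counts, positive/negative calls) is defined
on this partition, so the partition must be deterministic and exact.

Coordinates are 0-based half-open throughout (BED convention); 1-based
coordinates appear only at the SAM boundary, which :mod:`pysam` handles.
Strand is stored but never used for coverage counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DEFAULT_WINDOW_LENGTH = 100

HERV_KIND = "herv"
HOST_GENE_KIND = "host_gene"


class CatalogError(ValueError):
    """Raised when a catalog violates a structural invariant."""


@dataclass(frozen=True)
class WindowScheme:
    """Sequential non-overlapping tiling of ``[0, region_length)``.

    ``windows`` are half-open ``(start, end)`` intervals in region-local
    coordinates.  All windows have length ``window_length`` except possibly
    the last, which is shorter when the region length is not a multiple of
    ``window_length``.
    """

    window_length: int
    windows: tuple[tuple[int, int], ...]

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def window_lengths(self) -> list[int]:
        return [end - start for start, end in self.windows]


def partition_windows(region_length: int, window_length: int) -> WindowScheme:
    """Tile ``[0, region_length)`` with windows of ``window_length``.

    The number of windows is ``ceil(region_length / window_length)``; the
    terminal partial window is retained (never dropped or merged) so that
    the window lengths sum exactly to the region length.

    Raises
    ------
    ValueError
        If either argument is not a positive integer.
    """
    if region_length < 1:
        raise ValueError(f"region_length must be >= 1, got {region_length}")
    if window_length < 1:
        raise ValueError(f"window_length must be >= 1, got {window_length}")
    starts = range(0, region_length, window_length)
    windows = tuple(
        (start, min(start + window_length, region_length)) for start in starts
    )
    return WindowScheme(window_length=window_length, windows=windows)


@dataclass(frozen=True)
class Region:
    """One catalog entry: a HERV locus or a host gene.

    ``start``/``end`` are 0-based half-open genome coordinates (kept for
    provenance); windowing and coverage work in region-local coordinates
    ``[0, length)``.  ``sequence`` is required when reads are to be checked
    base-by-base against the reference (identity / window perfection).
    """

    region_id: str
    kind: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise CatalogError(
                f"region {self.region_id!r}: end ({self.end}) must exceed "
                f"start ({self.start})"
            )
        if self.kind not in (HERV_KIND, HOST_GENE_KIND):
            raise CatalogError(
                f"region {self.region_id!r}: unknown kind {self.kind!r}"
            )
        if self.strand not in ("+", "-"):
            raise CatalogError(
                f"region {self.region_id!r}: strand must be '+' or '-'"
            )
        if self.sequence is not None and len(self.sequence) != self.length:
            raise CatalogError(
                f"region {self.region_id!r}: sequence length "
                f"{len(self.sequence)} != interval length {self.length}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class RegionCatalog:
    """Ordered collection of regions sharing one window length."""

    def __init__(self, regions: list[Region], window_length: int = DEFAULT_WINDOW_LENGTH):
        seen: set[str] = set()
        for region in regions:
            if region.region_id in seen:
                raise CatalogError(f"duplicate region_id {region.region_id!r}")
            seen.add(region.region_id)
        self.window_length = int(window_length)
        if self.window_length < 1:
            raise CatalogError("window_length must be >= 1")
        self._regions: dict[str, Region] = {r.region_id: r for r in regions}
        self._schemes: dict[str, WindowScheme] = {
            r.region_id: partition_windows(r.length, self.window_length)
            for r in regions
        }

    def __len__(self) -> int:
        return len(self._regions)

    def __iter__(self) -> Iterator[Region]:
        return iter(self._regions.values())

    def __contains__(self, region_id: str) -> bool:
        return region_id in self._regions

    @property
    def region_ids(self) -> list[str]:
        return list(self._regions)

    def region(self, region_id: str) -> Region:
        try:
            return self._regions[region_id]
        except KeyError:
            raise CatalogError(f"unknown region_id {region_id!r}") from None

    def scheme(self, region_id: str) -> WindowScheme:
        self.region(region_id)
        return self._schemes[region_id]

    def subset(self, kind: str) -> list[Region]:
        return [r for r in self if r.kind == kind]

    # -- persistence ---------------------------------------------------

    def write(self, fasta_path: str | Path, bed_path: str | Path) -> None:
        """Write sequences as FASTA and intervals as BED6 (name = region_id,
        score column carries the kind)."""
        records = []
        rows = []
        for region in self:
            if region.sequence is not None:
                records.append(
                    SeqRecord(Seq(region.sequence), id=region.region_id, description=region.kind)
                )
            rows.append(
                (region.chromosome, region.start, region.end,
                 region.region_id, region.kind, region.strand)
            )
        SeqIO.write(records, str(fasta_path), "fasta")
        pd.DataFrame(rows).to_csv(bed_path, sep="\t", header=False, index=False)

    def summary(self) -> pd.DataFrame:
        """Per-region summary table (id, kind, length, window count)."""
        return pd.DataFrame(
            {
                "region_id": self.region_ids,
                "kind": [self.region(r).kind for r in self.region_ids],
                "length": [self.region(r).length for r in self.region_ids],
                "n_windows": [self.scheme(r).n_windows for r in self.region_ids],
                "window_length": self.window_length,
            }
        )


def load_catalog(
    fasta_path: str | Path | None,
    bed_path: str | Path,
    window_length: int = DEFAULT_WINDOW_LENGTH,
) -> RegionCatalog:
    """Load a region catalog from a BED file plus (optionally) a FASTA.

    The BED file needs at least 4 columns (chrom, start, end, name); column 5,
    when present, is interpreted as the region kind (``herv``/``host_gene``,
    defaulting to ``herv``), column 6 as strand.  Sequences are attached by
    matching FASTA record ids to BED names.

    Raises
    ------
    CatalogError
        On duplicate names, zero-length intervals (with the offending BED line
        number), or BED names missing from the FASTA.
    """
    sequences: dict[str, str] = {}
    if fasta_path is not None:
        for record in SeqIO.parse(str(fasta_path), "fasta"):
            sequences[record.id] = str(record.seq).upper()

    regions: list[Region] = []
    seen: set[str] = set()
    with open(bed_path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise CatalogError(f"{bed_path}, line {lineno}: expected >= 4 BED columns")
            chrom, start_s, end_s, name = fields[:4]
            start, end = int(start_s), int(end_s)
            if end <= start:
                raise CatalogError(
                    f"{bed_path}, line {lineno}: zero- or negative-length "
                    f"interval for {name!r} ({start}, {end})"
                )
            if name in seen:
                raise CatalogError(f"{bed_path}, line {lineno}: duplicate region_id {name!r}")
            seen.add(name)
            kind = fields[4] if len(fields) > 4 and fields[4] in (HERV_KIND, HOST_GENE_KIND) else HERV_KIND
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "+"
            sequence = None
            if sequences:
                if name not in sequences:
                    raise CatalogError(
                        f"{bed_path}, line {lineno}: region {name!r} has no FASTA record"
                    )
                sequence = sequences[name]
            regions.append(
                Region(
                    region_id=name, kind=kind, chromosome=chrom,
                    start=start, end=end, strand=strand, sequence=sequence,
                )
            )
    return RegionCatalog(regions, window_length=window_length)
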