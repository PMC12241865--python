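"""Turn alignments into per-window depth profiles for the monocyte cell subset.

The ingest path applies two per-read predicates before any counting:

* **barcode filter** — keep only reads whose cell barcode is annotated with
  the target cell type (monocytes, label ``"Mono"``); reads with barcodes
  missing from the annotation table are dropped and tallied, not fatal;
* **identity filter** — keep a read iff its percent identity
  ``100 * n_matches / aligned_length`` is *strictly greater* than the cut
  (default 99.0%; a read at exactly 99.0% is rejected).

Depth is then computed per window as the mean per-base coverage: the total
number of aligned bases overlapping the window divided by the window length.
Reads spanning a window boundary contribute their overlapping bases to each
window.  Only primary alignments count; duplicates are not removed.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .catalog import RegionCatalog, Region, WindowScheme

logger = logging.getLogger(__name__)

MONOCYTE_LABEL = "Mono"
DEFAULT_IDENTITY_CUT = 99.0
BARCODE_TAG = "CB"


class IngestError(ValueError):
    pass


@dataclass(frozen=True)
class AlignedRead:
    """Minimal alignment record for windowed scoring.

    ``pos`` is the 0-based start on the region; ``mismatch_positions`` are
    0-based reference offsets of substituted bases (used for window
    perfection in the WSS score).  ``n_matches`` counts aligned columns that
    match the reference.
    """

    read_id: str
    region_id: str
    pos: int
    aligned_length: int
    n_matches: int
    barcode: str
    mismatch_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise IngestError(f"read {self.read_id!r}: negative position")
        if not 0 <= self.n_matches <= self.aligned_length:
            raise IngestError(
                f"read {self.read_id!r}: n_matches {self.n_matches} outside "
                f"[0, {self.aligned_length}]"
            )

    @property
    def end(self) -> int:
        return self.pos + self.aligned_length

    @property
    def identity_percent(self) -> float:
        if self.aligned_length == 0:
            return 0.0
        return 100.0 * self.n_matches / self.aligned_length


@dataclass
class WindowProfile:
    """Per-window mean depth vector for one region in one sample."""

    region_id: str
    sample_id: str
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if (self.depths < 0).any():
            raise IngestError(f"negative depth in profile for {self.region_id!r}")


def read_barcode_table(path: str | Path) -> dict[str, str]:
    """Read a (barcode, cell_type) TSV into a mapping."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"barcode", "cell_type"} <= set(table.columns):
        raise IngestError(f"{path}: expected columns 'barcode' and 'cell_type'")
    return dict(zip(table["barcode"], table["cell_type"]))


def filter_barcodes(
    reads: list[AlignedRead],
    barcode_table: dict[str, str],
    target_cell_type: str = MONOCYTE_LABEL,
) -> list[AlignedRead]:
    """Keep reads whose barcode maps to ``target_cell_type``.

    Reads with barcodes absent from the table are excluded and counted in a
    warning; they are never fatal (droplets outside the annotated set are
    expected in real data).
    """
    kept: list[AlignedRead] = []
    unknown = 0
    for read in reads:
        cell_type = barcode_table.get(read.barcode)
        if cell_type is None:
            unknown += 1
            continue
        if cell_type == target_cell_type:
            kept.append(read)
    if unknown:
        logger.warning("%d reads with barcodes absent from the annotation table", unknown)
    logger.info("barcode filter: %d -> %d reads", len(reads), len(kept))
    return kept


def identity_filter(
    reads: list[AlignedRead],
    min_identity_exclusive: float = DEFAULT_IDENTITY_CUT,
) -> list[AlignedRead]:
    """Keep reads with identity strictly above the cut (default >99%).

    Zero-length alignments are excluded and counted.
    """
    kept = []
    zero_length = 0
    for read in reads:
        if read.aligned_length == 0:
            zero_length += 1
            continue
        if read.identity_percent > min_identity_exclusive:
            kept.append(read)
    if zero_length:
        logger.warning("%d zero-length alignments excluded", zero_length)
    logger.info("identity filter (>%s%%): %d -> %d reads",
                min_identity_exclusive, len(reads), len(kept))
    return kept


def window_depth_profile(
    reads: list[AlignedRead],
    region: Region,
    scheme: WindowScheme,
    sample_id: str = "",
) -> WindowProfile:
    """Mean per-base coverage per window, by exact interval overlap.

    Coverage is accumulated on a difference array and cumulatively summed,
    which is exact for integer read intervals; the per-window depth is the
    window's total aligned bases divided by its length, so
    ``sum(depth_w * len_w)`` equals the total retained aligned bases.
    """
    length = region.length
    diff = np.zeros(length + 1, dtype=np.int64)
    for read in reads:
        if read.region_id != region.region_id:
            raise IngestError(
                f"read {read.read_id!r} maps to {read.region_id!r}, "
                f"not {region.region_id!r}"
            )
        if read.end > length:
            raise IngestError(
                f"read {read.read_id!r} extends past region end "
                f"({read.end} > {length})"
            )
        diff[read.pos] += 1
        diff[read.end] -= 1
    per_base = np.cumsum(diff[:-1])
    starts = np.fromiter((w[0] for w in scheme.windows), dtype=np.int64)
    lengths = np.fromiter((w[1] - w[0] for w in scheme.windows), dtype=np.int64)
    totals = np.add.reduceat(per_base, starts) if length else np.zeros(0)
    depths = totals / lengths
    return WindowProfile(region_id=region.region_id, sample_id=sample_id, depths=depths)


def _mismatch_offsets(query: str, reference: str, pos: int) -> tuple[int, ...]:
    """0-based reference offsets where the aligned read differs from the reference."""
    segment = reference[pos:pos + len(query)]
    return tuple(pos + i for i, (q, r) in enumerate(zip(query, segment)) if q != r)


def reads_from_sam(
    sam_path: str | Path,
    catalog: RegionCatalog,
) -> dict[str, list[AlignedRead]]:
    """Parse a SAM/BAM file into per-region :class:`AlignedRead` lists.

    Secondary, supplementary and unmapped records are skipped.  Mismatch
    positions and match counts are derived by comparing the read sequence to
    the catalog reference sequence; when the region carries no sequence the
    NM tag is used for the match count (mismatch positions then unavailable).
    """
    per_region: dict[str, list[AlignedRead]] = {rid: [] for rid in catalog.region_ids}
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as sam:
        for name in sam.references:
            if name not in catalog:
                raise IngestError(f"{sam_path}: unknown reference name {name!r}")
        for record in sam:
            if record.is_unmapped or record.is_secondary or record.is_supplementary:
                continue
            region_id = record.reference_name
            if region_id is None or region_id not in catalog:
                raise IngestError(
                    f"{sam_path}: record {record.query_name!r} maps to unknown "
                    f"reference {region_id!r}"
                )
            region = catalog.region(region_id)
            query = record.query_alignment_sequence or ""
            pos = record.reference_start
            aligned_length = len(query)
            if region.sequence is not None and query:
                mism = _mismatch_offsets(query.upper(), region.sequence, pos)
                n_matches = aligned_length - len(mism)
            else:
                nm = record.get_tag("NM") if record.has_tag("NM") else 0
                mism = ()
                n_matches = max(aligned_length - int(nm), 0)
            barcode = str(record.get_tag(BARCODE_TAG)) if record.has_tag(BARCODE_TAG) else ""
            per_region[region_id].append(
                AlignedRead(
                    read_id=record.query_name or "",
                    region_id=region_id,
                    pos=pos,
                    aligned_length=aligned_length,
                    n_matches=n_matches,
                    barcode=barcode,
                    mismatch_positions=mism,
                )
            )
    return per_region


def apply_read_filters(
    per_region: dict[str, list[AlignedRead]],
    barcode_table: dict[str, str],
    target_cell_type: str = MONOCYTE_LABEL,
    min_identity_exclusive: float = DEFAULT_IDENTITY_CUT,
) -> dict[str, list[AlignedRead]]:
    """Barcode then identity filter, per region.  The two predicates are
    independent per-read tests, so their order does not affect the result."""
    return {
        region_id: identity_filter(
            filter_barcodes(reads, barcode_table, target_cell_type),
            min_identity_exclusive,
        )
        for region_id, reads in per_region.items()
    }


def ingest_sam(
    sam_path: str | Path,
    catalog: RegionCatalog,
    barcode_table: dict[str, str],
    sample_id: str = "",
    target_cell_type: str = MONOCYTE_LABEL,
    min_identity_exclusive: float = DEFAULT_IDENTITY_CUT,
) -> tuple[dict[str, WindowProfile], dict[str, list[AlignedRead]]]:
    """Full ingest: SAM -> filtered reads -> window profiles, per region.

    Returns the profiles and the retained (filtered) reads, the latter being
    needed for the WSS window-perfection score.  Regions with no reads get
    all-zero profiles.
    """
    per_region = reads_from_sam(sam_path, catalog)
    filtered = apply_read_filters(
        per_region, barcode_table, target_cell_type, min_identity_exclusive
    )
    profiles = {
        region_id: window_depth_profile(
            reads, catalog.region(region_id), catalog.scheme(region_id), sample_id
        )
        for region_id, reads in filtered.items()
    }
    return profiles, filtered


def profiles_to_frame(profiles: dict[str, WindowProfile]) -> pd.DataFrame:
    """Long-format (region_id, window_index, depth) table for TSV export."""
    rows = [
        (region_id, idx, depth)
        for region_id, profile in profiles.items()
        for idx, depth in enumerate(profile.depths)
    ]
    return pd.DataFrame(rows, columns=["region_id", "window_index", "depth"])
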