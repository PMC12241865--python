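"""End-to-end drivers: simulate/ingest -> filter -> score -> presence matrix.

Two equivalent paths exist: the on-disk path consumes the SAM + barcode-TSV
artifacts a run directory contains (what users of real data do), and the
in-memory path short-circuits file round-tripping for large replicate
studies.  Both feed identical read records to the same filters and scorer.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .catalog import RegionCatalog, load_catalog
from .coverage import (
    MONOCYTE_LABEL,
    apply_read_filters,
    ingest_sam,
    read_barcode_table,
    window_depth_profile,
)
from .scoring import LocusCall, Thresholds, calls_to_frame, score_sample
from .simulate import CohortSpec, SimulatedRead, simulate_cohort_memory
from .cohort import PresenceMatrix


def score_sample_reads(
    reads_by_region: dict[str, list],
    catalog: RegionCatalog,
    barcode_table: dict[str, str],
    thresholds: Thresholds,
    sample_id: str,
) -> list[LocusCall]:
    """Filter + profile + score one sample's reads (in-memory path)."""
    as_aligned = {
        region_id: [
            r.to_aligned_read() if isinstance(r, SimulatedRead) else r
            for r in reads
        ]
        for region_id, reads in reads_by_region.items()
    }
    filtered = apply_read_filters(
        as_aligned, barcode_table, MONOCYTE_LABEL, thresholds.identity_min
    )
    profiles = {
        region_id: window_depth_profile(
            reads, catalog.region(region_id), catalog.scheme(region_id), sample_id
        )
        for region_id, reads in filtered.items()
    }
    return score_sample(profiles, filtered, catalog, thresholds, sample_id)


def score_cohort_memory(
    spec: CohortSpec,
    thresholds: Thresholds | None = None,
) -> tuple[PresenceMatrix, pd.DataFrame, RegionCatalog]:
    """Simulate and score a whole cohort without touching disk.

    Returns (presence matrix, ground-truth manifest, catalog).
    """
    thresholds = thresholds or Thresholds(window_length=spec.window_length)
    catalog, all_reads, barcode_tables, manifest = simulate_cohort_memory(spec)
    calls: list[LocusCall] = []
    for sample in spec.samples:
        table = dict(
            zip(
                barcode_tables[sample.sample_id]["barcode"],
                barcode_tables[sample.sample_id]["cell_type"],
            )
        )
        calls.extend(
            score_sample_reads(
                all_reads[sample.sample_id], catalog, table, thresholds,
                sample.sample_id,
            )
        )
    metadata = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in spec.samples],
            "cohort": [s.cohort for s in spec.samples],
        }
    )
    matrix = PresenceMatrix.from_calls(calls, metadata)
    return matrix, manifest, catalog


def score_run_dir(
    run_dir: str | Path,
    thresholds: Thresholds | None = None,
    window_length: int | None = None,
) -> pd.DataFrame:
    """Score every sample of a simulation run directory from its files.

    Expects ``catalog.fasta``/``catalog.bed``, ``samples.tsv`` and per-sample
    ``<id>.sam`` + ``<id>.barcodes.tsv``.  Returns the tidy calls table.
    """
    run_dir = Path(run_dir)
    thresholds = thresholds or Thresholds()
    catalog = load_catalog(
        run_dir / "catalog.fasta",
        run_dir / "catalog.bed",
        window_length=window_length or thresholds.window_length,
    )
    metadata = pd.read_csv(run_dir / "samples.tsv", sep="\t")
    frames = []
    for sample_id in metadata["sample_id"]:
        barcode_table = read_barcode_table(run_dir / f"{sample_id}.barcodes.tsv")
        profiles, reads = ingest_sam(
            run_dir / f"{sample_id}.sam", catalog, barcode_table,
            sample_id=sample_id,
            min_identity_exclusive=thresholds.identity_min,
        )
        frames.append(
            calls_to_frame(
                score_sample(profiles, reads, catalog, thresholds, sample_id)
            )
        )
    return pd.concat(frames, ignore_index=True)
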