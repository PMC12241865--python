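"""Synthetic cohort generator: reference catalog, reads, barcodes, ground truth.

The generator emulates the study design this pipeline targets: monocyte reads
from single-cell experiments aligned to a panel of autonomous HERV loci plus a
handful of neighbouring host genes, across a control cohort (all HERV loci
silent), an acute-infection cohort, and a PASC (long COVID) cohort in which a
designated subset of loci is *amplified* — expressed over more contiguous
windows (longer transcripts) and at greater depth.

Read model
----------
For each expressed (sample, region) pair a contiguous block of exactly
``n_covered_windows`` windows is chosen; within each window of the block the
read count is Poisson with mean ``depth * window_len / read_len`` and each
read lies wholly inside its window (start uniform over the admissible range),
so a covered window's expected mean per-base coverage equals ``depth`` and
uncovered windows receive no reads at all.  Substitution errors are i.i.d.
per base.  The ``"exact"`` coverage model replaces the Poisson draw with
``round(depth)`` window-spanning reads — a noiseless mode in which realized
coverage equals the intended depth exactly, used for classifier ground-truth
checks.

Decoy reads carrying non-monocyte barcodes are placed on expressed *and*
silent loci, so the cell-type barcode filter is consequential: without it,
silent loci would be called positive.

Everything is driven by one :class:`numpy.random.Generator` seeded from
``CohortSpec.seed``; identical seeds give byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .catalog import (
    HERV_KIND,
    HOST_GENE_KIND,
    Region,
    RegionCatalog,
)
from .coverage import AlignedRead, BARCODE_TAG, MONOCYTE_LABEL
from .scoring import NEGATIVE, POSITIVE, Thresholds

DECOY_CELL_TYPES = ("T", "B", "NK", "DC")
BASES = np.frombuffer(b"ACGT", dtype="S1")
ORIGIN_TAG = "XO"  # true read origin: "mono" or "decoy"

HOST_GENE_NAMES = ("JAKMIP2", "DPYSL3", "SPINK1", "STK32A", "SCGB3A2")


class SpecError(ValueError):
    """Raised when a cohort spec violates an invariant, before any file is written."""


@dataclass(frozen=True)
class SampleSpec:
    """Intended expression state of one sample.

    ``expressed`` maps region_id -> (n_covered_windows, mean_depth); regions
    absent from the map are silent in this sample's monocytes.
    """

    sample_id: str
    cohort: str
    expressed: dict[str, tuple[int, float]] = field(default_factory=dict)
    fraction_monocyte_barcodes: float = 0.4
    n_barcodes: int = 150

    VALID_COHORTS = ("control", "acute", "ERS", "LRS", "PASC", "vaccine", "other")

    def __post_init__(self) -> None:
        if self.cohort not in self.VALID_COHORTS:
            raise SpecError(f"sample {self.sample_id!r}: unknown cohort {self.cohort!r}")
        if not 0.0 <= self.fraction_monocyte_barcodes <= 1.0:
            raise SpecError(f"sample {self.sample_id!r}: monocyte fraction outside [0, 1]")
        if self.n_barcodes < 0:
            raise SpecError(f"sample {self.sample_id!r}: negative n_barcodes")
        for region_id, (n_win, depth) in self.expressed.items():
            if n_win < 0 or depth < 0:
                raise SpecError(
                    f"sample {self.sample_id!r}, region {region_id!r}: "
                    "negative windows or depth"
                )


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort."""

    n_loci: int = 50
    locus_length: int = 2500
    n_host_genes: int = 5
    host_gene_length: int = 3200
    samples: tuple[SampleSpec, ...] = ()
    window_length: int = 100
    read_length: int = 100
    substitution_rate: float = 0.001
    seed: int = 0
    coverage_model: str = "poisson"  # "poisson" | "exact"
    decoy_depth: float = 4.0
    decoy_windows: int = 10
    n_decoy_silent_regions: int = 5
    amplified_regions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if min(self.n_loci, self.n_host_genes) < 0:
            raise SpecError("region counts must be >= 0")
        if min(self.locus_length, self.window_length, self.read_length) < 1:
            raise SpecError("lengths must be >= 1")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise SpecError("substitution_rate must lie in [0, 1)")
        if self.coverage_model not in ("poisson", "exact"):
            raise SpecError(f"unknown coverage_model {self.coverage_model!r}")
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise SpecError("duplicate sample ids")


@dataclass(frozen=True)
class SimulatedRead:
    """A synthetic read with its true placement and origin retained."""

    read_id: str
    region_id: str
    pos: int
    sequence: str
    mismatch_positions: tuple[int, ...]
    barcode: str
    origin: str  # "mono" | "decoy"

    def to_aligned_read(self) -> AlignedRead:
        return AlignedRead(
            read_id=self.read_id,
            region_id=self.region_id,
            pos=self.pos,
            aligned_length=len(self.sequence),
            n_matches=len(self.sequence) - len(self.mismatch_positions),
            barcode=self.barcode,
            mismatch_positions=self.mismatch_positions,
        )


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------

def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def build_catalog(spec: CohortSpec, rng: np.random.Generator) -> RegionCatalog:
    """HERV loci named HERV001.. plus host genes, with random sequences."""
    regions: list[Region] = []
    offset = 10_000
    for i in range(spec.n_loci):
        regions.append(
            Region(
                region_id=f"HERV{i + 1:03d}",
                kind=HERV_KIND,
                chromosome="chr5",
                start=offset,
                end=offset + spec.locus_length,
                strand="+",
                sequence=_random_sequence(spec.locus_length, rng),
            )
        )
        offset += spec.locus_length + 1_000
    for i in range(spec.n_host_genes):
        name = HOST_GENE_NAMES[i] if i < len(HOST_GENE_NAMES) else f"GENE{i + 1:02d}"
        regions.append(
            Region(
                region_id=name,
                kind=HOST_GENE_KIND,
                chromosome="chr5",
                start=offset,
                end=offset + spec.host_gene_length,
                strand="+",
                sequence=_random_sequence(spec.host_gene_length, rng),
            )
        )
        offset += spec.host_gene_length + 1_000
    return RegionCatalog(regions, window_length=spec.window_length)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def _mutate(
    sequence: str,
    n_mut: int,
    rng: np.random.Generator,
) -> tuple[str, tuple[int, ...]]:
    """Apply ``n_mut`` substitutions at distinct positions; returns
    (sequence, offsets of changed bases)."""
    if n_mut == 0:
        return sequence, ()
    n = len(sequence)
    offsets = np.sort(rng.choice(n, size=n_mut, replace=False))
    arr = np.frombuffer(sequence.encode(), dtype="S1").copy()
    for off in offsets:
        current = arr[off]
        choices = BASES[BASES != current]
        arr[off] = rng.choice(choices)
    return arr.tobytes().decode(), tuple(int(o) for o in offsets)


def simulate_reads(
    region: Region,
    block_windows: list[tuple[int, int]],
    depth: float,
    read_length: int,
    substitution_rate: float,
    rng: np.random.Generator,
    coverage_model: str = "poisson",
    barcode_pool: list[str] | None = None,
    origin: str = "mono",
    id_prefix: str = "r",
) -> list[SimulatedRead]:
    """Simulate reads over a block of windows of one region.

    Each read lies wholly inside one window of the block; the per-window read
    count is Poisson with mean ``depth * window_len / read_len`` (or exactly
    ``round(depth)`` window-spanning reads under the exact model).

    Raises
    ------
    ValueError
        If ``read_length`` exceeds the region length or a block window falls
        outside the region.
    """
    if region.sequence is None:
        raise ValueError(f"region {region.region_id!r} carries no sequence")
    if read_length > region.length:
        raise ValueError(
            f"read_length {read_length} exceeds region length {region.length}"
        )
    if depth < 0:
        raise ValueError("depth must be >= 0")
    reads: list[SimulatedRead] = []
    serial = 0
    sequence = region.sequence
    for w_start, w_end in block_windows:
        if not (0 <= w_start < w_end <= region.length):
            raise ValueError(
                f"window ({w_start}, {w_end}) outside region {region.region_id!r}"
            )
        w_len = w_end - w_start
        r_len = min(read_length, w_len)
        if coverage_model == "exact":
            n_reads = max(0, round(depth))
            starts = [w_start] * n_reads
            r_len = w_len  # span the window exactly
        else:
            n_reads = int(rng.poisson(depth * w_len / r_len))
            starts = rng.integers(w_start, w_end - r_len + 1, size=n_reads).tolist()
        if n_reads == 0:
            continue
        # batched draws: substitution counts and barcode indices per read
        n_muts = (
            rng.binomial(r_len, substitution_rate, size=n_reads)
            if substitution_rate > 0 else np.zeros(n_reads, dtype=int)
        )
        bc_idx = (
            rng.integers(len(barcode_pool), size=n_reads)
            if barcode_pool else None
        )
        for i, start in enumerate(starts):
            template = sequence[start:start + r_len]
            n_mut = int(n_muts[i])
            if n_mut:
                seq, offsets = _mutate(template, n_mut, rng)
            else:
                seq, offsets = template, ()
            barcode = barcode_pool[int(bc_idx[i])] if barcode_pool else ""
            reads.append(
                SimulatedRead(
                    read_id=f"{id_prefix}:{region.region_id}:{serial}",
                    region_id=region.region_id,
                    pos=int(start),
                    sequence=seq,
                    mismatch_positions=tuple(int(start) + o for o in offsets),
                    barcode=barcode,
                    origin=origin,
                )
            )
            serial += 1
    return reads


# ---------------------------------------------------------------------------
# barcodes
# ---------------------------------------------------------------------------

def make_barcodes(
    n_barcodes: int,
    fraction_monocyte: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Barcode annotation table: 16-nt barcodes (10x convention), monocytes
    labelled ``Mono``, the rest drawn from a fixed decoy label set."""
    barcodes: list[str] = []
    seen: set[str] = set()
    while len(barcodes) < n_barcodes:
        bc = _random_sequence(16, rng)
        if bc not in seen:
            seen.add(bc)
            barcodes.append(bc)
    n_mono = int(round(fraction_monocyte * n_barcodes))
    labels = [MONOCYTE_LABEL] * n_mono + [
        DECOY_CELL_TYPES[int(rng.integers(len(DECOY_CELL_TYPES)))]
        for _ in range(n_barcodes - n_mono)
    ]
    return pd.DataFrame({"barcode": barcodes, "cell_type": labels})


def write_barcode_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# per-sample simulation
# ---------------------------------------------------------------------------

def _choose_block(
    n_windows_total: int, n_covered: int, rng: np.random.Generator
) -> tuple[int, int]:
    start = int(rng.integers(0, n_windows_total - n_covered + 1)) if n_covered < n_windows_total else 0
    return start, start + n_covered


def simulate_sample(
    spec: CohortSpec,
    sample: SampleSpec,
    catalog: RegionCatalog,
    rng: np.random.Generator,
) -> tuple[dict[str, list[SimulatedRead]], pd.DataFrame]:
    """Simulate one sample: monocyte reads on expressed regions plus decoy
    (non-monocyte) reads on expressed and silent regions.

    Returns (reads per region, barcode table).
    """
    for region_id, (n_win, _depth) in sample.expressed.items():
        if region_id not in catalog:
            raise SpecError(
                f"sample {sample.sample_id!r}: expressed region {region_id!r} "
                "not in catalog"
            )
        total = catalog.scheme(region_id).n_windows
        if n_win > total:
            raise SpecError(
                f"sample {sample.sample_id!r}, region {region_id!r}: "
                f"{n_win} covered windows exceed the {total} available"
            )

    barcode_table = make_barcodes(
        sample.n_barcodes, sample.fraction_monocyte_barcodes, rng
    )
    mono_pool = barcode_table.loc[
        barcode_table["cell_type"] == MONOCYTE_LABEL, "barcode"
    ].tolist()
    decoy_pool = barcode_table.loc[
        barcode_table["cell_type"] != MONOCYTE_LABEL, "barcode"
    ].tolist()

    reads: dict[str, list[SimulatedRead]] = {rid: [] for rid in catalog.region_ids}

    for region_id in sorted(sample.expressed):
        n_win, depth = sample.expressed[region_id]
        if n_win == 0 or depth == 0:
            continue
        if not mono_pool:
            raise SpecError(
                f"sample {sample.sample_id!r}: expressed regions but no "
                "monocyte barcodes"
            )
        scheme = catalog.scheme(region_id)
        lo, hi = _choose_block(scheme.n_windows, n_win, rng)
        reads[region_id].extend(
            simulate_reads(
                catalog.region(region_id),
                list(scheme.windows[lo:hi]),
                depth,
                spec.read_length,
                spec.substitution_rate,
                rng,
                coverage_model=spec.coverage_model,
                barcode_pool=mono_pool,
                origin="mono",
                id_prefix=f"{sample.sample_id}:m",
            )
        )

    # decoys on every expressed region plus a few silent ones
    if decoy_pool and spec.decoy_windows > 0 and spec.decoy_depth > 0:
        silent = [
            rid for rid in catalog.region_ids if rid not in sample.expressed
        ]
        n_silent = min(spec.n_decoy_silent_regions, len(silent))
        chosen_silent = (
            [silent[int(i)] for i in rng.choice(len(silent), size=n_silent, replace=False)]
            if n_silent else []
        )
        for region_id in sorted(set(sample.expressed) | set(chosen_silent)):
            scheme = catalog.scheme(region_id)
            n_win = min(spec.decoy_windows, scheme.n_windows)
            lo, hi = _choose_block(scheme.n_windows, n_win, rng)
            reads[region_id].extend(
                simulate_reads(
                    catalog.region(region_id),
                    list(scheme.windows[lo:hi]),
                    spec.decoy_depth,
                    spec.read_length,
                    spec.substitution_rate,
                    rng,
                    coverage_model=spec.coverage_model,
                    barcode_pool=decoy_pool,
                    origin="decoy",
                    id_prefix=f"{sample.sample_id}:d",
                )
            )
    return reads, barcode_table


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def build_manifest(
    spec: CohortSpec,
    catalog: RegionCatalog,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Ground-truth manifest: one row per (sample, region) with the intended
    expression state and the status it implies under the thresholds."""
    thresholds = thresholds or Thresholds(window_length=spec.window_length)
    rows = []
    for sample in spec.samples:
        for region_id in catalog.region_ids:
            n_win, depth = sample.expressed.get(region_id, (0, 0.0))
            status = (
                POSITIVE
                if n_win >= thresholds.windows_min and depth >= thresholds.depth_min
                else NEGATIVE
            )
            rows.append((sample.sample_id, region_id, status, n_win, depth))
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "region_id", "intended_status",
            "intended_windows", "intended_depth",
        ],
    )


def sample_metadata(spec: CohortSpec) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in spec.samples],
            "cohort": [s.cohort for s in spec.samples],
        }
    )


# ---------------------------------------------------------------------------
# cohort-level drivers
# ---------------------------------------------------------------------------

def simulate_cohort_memory(
    spec: CohortSpec,
) -> tuple[
    RegionCatalog,
    dict[str, dict[str, list[SimulatedRead]]],
    dict[str, pd.DataFrame],
    pd.DataFrame,
]:
    """Simulate the whole cohort in memory (no files).

    Returns (catalog, reads per sample per region, barcode tables, manifest).
    """
    rng = np.random.default_rng(spec.seed)
    catalog = build_catalog(spec, rng)
    all_reads: dict[str, dict[str, list[SimulatedRead]]] = {}
    barcode_tables: dict[str, pd.DataFrame] = {}
    for sample in spec.samples:
        reads, table = simulate_sample(spec, sample, catalog, rng)
        all_reads[sample.sample_id] = reads
        barcode_tables[sample.sample_id] = table
    manifest = build_manifest(spec, catalog)
    return catalog, all_reads, barcode_tables, manifest


def write_sam(
    reads_by_region: dict[str, list[SimulatedRead]],
    catalog: RegionCatalog,
    path: str | Path,
) -> None:
    """Write reads as a text SAM with the cell barcode in the CB tag and the
    true origin in the XO tag."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": rid, "LN": catalog.region(rid).length}
            for rid in catalog.region_ids
        ],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for tid, region_id in enumerate(catalog.region_ids):
            for read in reads_by_region.get(region_id, []):
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = read.read_id
                rec.query_sequence = read.sequence
                rec.flag = 0
                rec.reference_id = tid
                rec.reference_start = read.pos
                rec.mapping_quality = 60
                rec.cigarstring = f"{len(read.sequence)}M"
                rec.set_tag("NM", len(read.mismatch_positions))
                rec.set_tag(BARCODE_TAG, read.barcode)
                rec.set_tag(ORIGIN_TAG, read.origin)
                out.write(rec)


def simulate_cohort(spec: CohortSpec, out_dir: str | Path) -> Path:
    """Simulate the cohort and write all artifacts under ``out_dir/run_seed<N>``.

    Writes catalog FASTA + BED, one SAM and one barcode TSV per sample, the
    sample-metadata TSV and the ground-truth manifest TSV.  Spec validation
    happens before any file is created; the same seed gives byte-identical
    files.
    """
    catalog, all_reads, barcode_tables, manifest = simulate_cohort_memory(spec)
    run_dir = Path(out_dir) / f"run_seed{spec.seed}"
    run_dir.mkdir(parents=True, exist_ok=True)
    catalog.write(run_dir / "catalog.fasta", run_dir / "catalog.bed")
    for sample in spec.samples:
        write_sam(all_reads[sample.sample_id], catalog, run_dir / f"{sample.sample_id}.sam")
        write_barcode_table(
            barcode_tables[sample.sample_id],
            run_dir / f"{sample.sample_id}.barcodes.tsv",
        )
    sample_metadata(spec).to_csv(run_dir / "samples.tsv", sep="\t", index=False)
    manifest.to_csv(run_dir / "ground_truth.tsv", sep="\t", index=False)
    return run_dir


# ---------------------------------------------------------------------------
# the default cohort preset
# ---------------------------------------------------------------------------

BASELINE_WINDOWS = 12
BASELINE_DEPTH = 6.0
AMPLIFIED_WINDOWS = BASELINE_WINDOWS + 10  # longer transcript in PASC
AMPLIFIED_DEPTH = BASELINE_DEPTH + 3.0     # deeper coverage in PASC
HOST_BASELINE = (15, 5.0)
HOST_AMPLIFIED = (25, 8.0)
AMPLIFIED_HOST_GENES = ("JAKMIP2", "SPINK1", "DPYSL3")


def default_cohort_spec(seed: int = 0, coverage_model: str = "poisson") -> CohortSpec:
    """The desk-scale study preset: 31 controls, 11 acute, 12 PASC, 50 HERV
    loci, 5 host genes.

    Expression topology mirrors the target study at reduced scale:

    * HERV001–003 expressed in *all* 12 PASC samples and amplified there;
    * HERV004–006 amplified in most PASC samples;
    * HERV007–012 expressed at baseline in subsets of both patient groups
      (no amplification — the null loci for comparisons);
    * HERV013–017 PASC-only; HERV018–022 acute-only; the rest silent;
    * host genes expressed in every sample, with JAKMIP2/SPINK1/DPYSL3
      amplified in PASC;
    * controls carry no HERV expression (host genes at baseline only).

    Per-sample membership of the partially penetrant loci is drawn once here
    from the preset's own seeded stream, so a given seed fully determines the
    cohort.
    """
    rng = np.random.default_rng(seed + 1_000_003)
    control_ids = [f"C{i + 1:02d}" for i in range(31)]
    acute_ids = [f"A{i + 1:02d}" for i in range(11)]
    pasc_ids = [f"P{i + 1:02d}" for i in range(12)]

    amplified = tuple(f"HERV{i:03d}" for i in range(1, 7))
    shared_null = [f"HERV{i:03d}" for i in range(7, 13)]
    pasc_only = [f"HERV{i:03d}" for i in range(13, 18)]
    acute_only = [f"HERV{i:03d}" for i in range(18, 23)]

    host_expr_control = {g: HOST_BASELINE for g in HOST_GENE_NAMES}
    host_expr_pasc = {
        g: (HOST_AMPLIFIED if g in AMPLIFIED_HOST_GENES else HOST_BASELINE)
        for g in HOST_GENE_NAMES
    }

    def members(ids: list[str], k: int) -> set[str]:
        idx = rng.choice(len(ids), size=k, replace=False)
        return {ids[int(i)] for i in idx}

    # per-locus membership draws (deterministic order)
    acute_has = {locus: members(acute_ids, 6) for locus in amplified}
    pasc_has = {
        locus: (set(pasc_ids) if locus in amplified[:3] else members(pasc_ids, 10))
        for locus in amplified
    }
    acute_null_has = {locus: members(acute_ids, 8) for locus in shared_null}
    pasc_null_has = {locus: members(pasc_ids, 8) for locus in shared_null}
    pasc_only_has = {locus: members(pasc_ids, 6) for locus in pasc_only}
    acute_only_has = {locus: members(acute_ids, 6) for locus in acute_only}

    samples: list[SampleSpec] = []
    for sid in control_ids:
        samples.append(
            SampleSpec(sample_id=sid, cohort="control", expressed=dict(host_expr_control))
        )
    for sid in acute_ids:
        expressed: dict[str, tuple[int, float]] = dict(host_expr_control)
        for locus in amplified:
            if sid in acute_has[locus]:
                expressed[locus] = (BASELINE_WINDOWS, BASELINE_DEPTH)
        for locus in shared_null:
            if sid in acute_null_has[locus]:
                expressed[locus] = (BASELINE_WINDOWS, BASELINE_DEPTH)
        for locus in acute_only:
            if sid in acute_only_has[locus]:
                expressed[locus] = (BASELINE_WINDOWS, BASELINE_DEPTH)
        samples.append(SampleSpec(sample_id=sid, cohort="acute", expressed=expressed))
    for sid in pasc_ids:
        expressed = dict(host_expr_pasc)
        for locus in amplified:
            if sid in pasc_has[locus]:
                expressed[locus] = (AMPLIFIED_WINDOWS, AMPLIFIED_DEPTH)
        for locus in shared_null:
            if sid in pasc_null_has[locus]:
                expressed[locus] = (BASELINE_WINDOWS, BASELINE_DEPTH)
        for locus in pasc_only:
            if sid in pasc_only_has[locus]:
                expressed[locus] = (BASELINE_WINDOWS, BASELINE_DEPTH)
        samples.append(SampleSpec(sample_id=sid, cohort="PASC", expressed=expressed))

    return CohortSpec(
        samples=tuple(samples),
        seed=seed,
        coverage_model=coverage_model,
        amplified_regions=amplified,
    )
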