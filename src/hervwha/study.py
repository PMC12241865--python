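"""Replicate studies on the default synthetic cohort preset.

These drivers answer the calibration questions the pipeline is built for:
does the classifier recover the intended expression states, and do the
cohort comparisons find exactly the loci that were amplified by design?
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .catalog import HERV_KIND, HOST_GENE_KIND
from .cohort import compare_groups, compare_host_genes, pangenome_filter, set_summary, shared_loci
from .pipeline import score_cohort_memory
from .simulate import AMPLIFIED_HOST_GENES, default_cohort_spec


def noiseless_agreement(seed: int = 0) -> float:
    """Fraction of (sample, region) calls matching the ground-truth manifest
    under the exact (noiseless) coverage model with zero substitutions."""
    spec = dataclasses.replace(
        default_cohort_spec(seed=seed, coverage_model="exact"),
        substitution_rate=0.0,
    )
    matrix, manifest, _ = score_cohort_memory(spec)
    observed = matrix.to_long_frame().merge(manifest, on=["sample_id", "region_id"])
    return float((observed["status"] == observed["intended_status"]).mean())


def power_replicate(seed: int, metric: str = "n_usable_windows") -> dict:
    """One replicate of the acute-vs-PASC amplification comparison.

    Returns whether every ground-truth amplified locus that could be compared
    was flagged significant, and how many non-amplified loci were flagged
    (false positives).
    """
    spec = default_cohort_spec(seed=seed)
    matrix, _, catalog = score_cohort_memory(spec)
    herv_ids = [r.region_id for r in catalog.subset(HERV_KIND)]
    acute = matrix.samples_in_cohort("acute")
    pasc = matrix.samples_in_cohort("PASC")
    comparisons = compare_groups(
        matrix, acute, pasc, region_ids=herv_ids, metric=metric,
        group_a="acute", group_b="PASC",
    )
    significant = set(comparisons.loc[comparisons["significant"], "region_id"])
    amplified = set(spec.amplified_regions)
    compared = set(comparisons["region_id"])
    amplified_compared = amplified & compared
    return {
        "seed": seed,
        "n_amplified_compared": len(amplified_compared),
        "n_amplified_detected": len(significant & amplified_compared),
        "all_amplified_detected": bool(amplified_compared)
        and amplified_compared <= significant,
        "n_false_positives": len(significant - amplified),
    }


def amplification_power_study(
    n_replicates: int = 200, base_seed: int = 0
) -> pd.DataFrame:
    """Seeded replicates of :func:`power_replicate` (seeds base..base+n-1)."""
    return pd.DataFrame(
        [power_replicate(base_seed + i) for i in range(n_replicates)]
    )


def summarize_power(replicates: pd.DataFrame) -> dict:
    success = replicates["all_amplified_detected"] & (
        replicates["n_false_positives"] <= 1
    )
    return {
        "n_replicates": int(len(replicates)),
        "detection_rate": float(replicates["all_amplified_detected"].mean()),
        "replicates_with_at_most_one_false_positive": float(
            (replicates["n_false_positives"] <= 1).mean()
        ),
        "success_rate": float(success.mean()),
        "mean_false_positives": float(replicates["n_false_positives"].mean()),
    }


def cohort_set_analysis(seed: int = 0) -> dict:
    """One scored replicate of the default preset: pangenome filtering, the
    acute/PASC unique-and-shared arithmetic, PASC-universal loci, and the
    host-gene ANOVA + Tukey comparisons."""
    spec = default_cohort_spec(seed=seed)
    matrix, _, catalog = score_cohort_memory(spec)
    herv_ids = [r.region_id for r in catalog.subset(HERV_KIND)]
    gene_ids = [r.region_id for r in catalog.subset(HOST_GENE_KIND)]
    herv = matrix.subset_regions(herv_ids)
    controls = matrix.samples_in_cohort("control")
    acute = matrix.samples_in_cohort("acute")
    pasc = matrix.samples_in_cohort("PASC")

    retained = pangenome_filter(herv, controls, acute + pasc)
    sets = set_summary(herv, acute, pasc)
    universal_pasc = shared_loci(herv.subset_regions(retained), pasc)

    groups = {"control": controls, "acute": acute, "PASC": pasc}
    host_windows = compare_host_genes(matrix, gene_ids, groups, metric="n_usable_windows")
    host_depth = compare_host_genes(matrix, gene_ids, groups, metric="locus_depth")

    def significant_vs_control(frame: pd.DataFrame) -> list[str]:
        mask = (
            frame["significant"]
            & (
                ((frame["group1"] == "control") & (frame["group2"] == "PASC"))
                | ((frame["group1"] == "PASC") & (frame["group2"] == "control"))
            )
        )
        return sorted(frame.loc[mask, "region_id"].unique())

    return {
        "n_samples": len(matrix.sample_ids),
        "n_herv_loci": len(herv_ids),
        "pangenome_retained": retained,
        "n_unique_acute": sets["n_unique_a"],
        "n_unique_pasc": sets["n_unique_b"],
        "n_shared": sets["n_shared"],
        "universal_pasc_loci": universal_pasc,
        "host_genes_windows_significant": significant_vs_control(host_windows),
        "host_genes_depth_significant": significant_vs_control(host_depth),
        "intended_amplified_host_genes": sorted(AMPLIFIED_HOST_GENES),
    }
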