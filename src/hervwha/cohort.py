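"""Cohort-level analysis: presence matrices, pangenome-control filtering,
set arithmetic between patient groups, and comparative statistics.

The *pangenome control* is a panel of healthy individuals; a locus survives
filtering only when it is negative in every control sample and positive in at
least one patient sample.  Window-count and depth differences between patient
groups are assessed with Welch's two-sample t-test (two-sided); host genes
are compared across several groups with one-way ANOVA followed by Tukey's
HSD post-hoc test.  p < 0.05 is flagged significant throughout, with an
optional Benjamini–Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .scoring import LocusCall, POSITIVE, NEGATIVE, calls_to_frame

ALPHA = 0.05


class CohortError(ValueError):
    pass


@dataclass
class PresenceMatrix:
    """Samples x regions call matrices with cohort labels.

    ``status`` is boolean (True = positive); ``windows`` and ``depth`` are the
    parallel usable-window-count and locus-depth matrices.  Index = sample
    ids, columns = region ids, identical across the three frames.
    """

    status: pd.DataFrame
    windows: pd.DataFrame
    depth: pd.DataFrame
    cohorts: pd.Series

    def __post_init__(self) -> None:
        if not (
            self.status.shape == self.windows.shape == self.depth.shape
            and self.status.index.equals(self.windows.index)
            and self.status.columns.equals(self.windows.columns)
            and self.status.index.equals(self.depth.index)
            and self.status.columns.equals(self.depth.columns)
        ):
            raise CohortError("status/windows/depth matrices must share shape and labels")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.status.index)

    @property
    def region_ids(self) -> list[str]:
        return list(self.status.columns)

    def samples_in_cohort(self, cohort: str) -> list[str]:
        return list(self.cohorts.index[self.cohorts == cohort])

    def subset_regions(self, region_ids: list[str]) -> "PresenceMatrix":
        return PresenceMatrix(
            status=self.status[region_ids],
            windows=self.windows[region_ids],
            depth=self.depth[region_ids],
            cohorts=self.cohorts,
        )

    @classmethod
    def from_calls(
        cls,
        calls: list[LocusCall] | pd.DataFrame,
        metadata: pd.DataFrame,
    ) -> "PresenceMatrix":
        """Build from locus calls plus a (sample_id, cohort) metadata table."""
        frame = calls if isinstance(calls, pd.DataFrame) else calls_to_frame(calls)
        status = (
            frame.pivot(index="sample_id", columns="region_id", values="status")
            .eq(POSITIVE)
        )
        windows = frame.pivot(
            index="sample_id", columns="region_id", values="n_usable_windows"
        ).astype(int)
        depth = frame.pivot(index="sample_id", columns="region_id", values="locus_depth")
        meta = metadata.set_index("sample_id")["cohort"]
        missing = [s for s in status.index if s not in meta.index]
        if missing:
            raise CohortError(f"samples missing from metadata: {missing}")
        order = [s for s in meta.index if s in status.index]
        return cls(
            status=status.loc[order],
            windows=windows.loc[order],
            depth=depth.loc[order],
            cohorts=meta.loc[order],
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Heatmap-ready long format (sample_id, cohort, region_id, status,
        n_usable_windows, locus_depth)."""
        long = (
            self.status.stack().rename("positive").reset_index()
            .rename(columns={"level_0": "sample_id", "level_1": "region_id"})
        )
        long.columns = ["sample_id", "region_id", "positive"]
        long["status"] = np.where(long["positive"], POSITIVE, NEGATIVE)
        long = long.drop(columns="positive")
        long["n_usable_windows"] = self.windows.stack().to_numpy()
        long["locus_depth"] = self.depth.stack().to_numpy()
        long.insert(1, "cohort", self.cohorts.loc[long["sample_id"]].to_numpy())
        return long


def _check_ids(matrix: PresenceMatrix, ids: list[str], label: str) -> None:
    unknown = [s for s in ids if s not in matrix.status.index]
    if unknown:
        raise CohortError(f"{label}: unknown sample ids {unknown}")


def pangenome_filter(
    matrix: PresenceMatrix,
    control_ids: list[str],
    patient_ids: list[str],
) -> list[str]:
    """Regions negative in ALL controls and positive in at least one patient.

    This is the healthy-panel filter: any locus with even a single positive
    control is discarded; of the rest, only loci actually observed in a
    patient are kept.
    """
    if not control_ids or not patient_ids:
        raise CohortError("control and patient groups must both be non-empty")
    overlap = set(control_ids) & set(patient_ids)
    if overlap:
        raise CohortError(f"samples in both groups: {sorted(overlap)}")
    _check_ids(matrix, control_ids, "controls")
    _check_ids(matrix, patient_ids, "patients")
    neg_in_controls = ~matrix.status.loc[control_ids].any(axis=0)
    pos_in_patients = matrix.status.loc[patient_ids].any(axis=0)
    keep = neg_in_controls & pos_in_patients
    return [rid for rid in matrix.region_ids if keep[rid]]


def shared_loci(matrix: PresenceMatrix, group_ids: list[str]) -> list[str]:
    """Regions positive in every sample of the group."""
    if not group_ids:
        raise CohortError("group must be non-empty")
    _check_ids(matrix, group_ids, "group")
    keep = matrix.status.loc[group_ids].all(axis=0)
    return [rid for rid in matrix.region_ids if keep[rid]]


def set_summary(
    matrix: PresenceMatrix,
    group_a_ids: list[str],
    group_b_ids: list[str],
) -> dict:
    """Unique-vs-shared positive-locus arithmetic between two groups.

    A region is *unique to A* when positive in at least one A sample and in
    no B sample; *shared* when positive in at least one sample of each.
    """
    if set(group_a_ids) & set(group_b_ids):
        raise CohortError("groups must be disjoint")
    _check_ids(matrix, group_a_ids, "group A")
    _check_ids(matrix, group_b_ids, "group B")
    pos_a = matrix.status.loc[group_a_ids].any(axis=0)
    pos_b = matrix.status.loc[group_b_ids].any(axis=0)
    unique_a = [r for r in matrix.region_ids if pos_a[r] and not pos_b[r]]
    unique_b = [r for r in matrix.region_ids if pos_b[r] and not pos_a[r]]
    shared = [r for r in matrix.region_ids if pos_a[r] and pos_b[r]]
    return {
        "unique_a": unique_a,
        "unique_b": unique_b,
        "shared": shared,
        "n_unique_a": len(unique_a),
        "n_unique_b": len(unique_b),
        "n_shared": len(shared),
    }


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    """Result of one two-group or multi-group test on a region metric."""

    region_id: str
    metric: str  # "n_usable_windows" | "locus_depth"
    test: str    # "welch_t" | "anova_tukey"
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    significant: bool
    pairwise: tuple[tuple[str, str, float, bool], ...] = ()  # (g1, g2, p_adj, sig)


def compare_windows_ttest(
    values_a: list[float],
    values_b: list[float],
    region_id: str = "",
    metric: str = "n_usable_windows",
    group_a: str = "a",
    group_b: str = "b",
    alpha: float = ALPHA,
) -> GroupComparison:
    """Welch two-sample t-test (two-sided, unequal variances).

    When both groups have zero variance: equal means give (t=0, p=1); unequal
    means are reported as infinitely separated (p=0).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        small = group_a if a.size < 2 else group_b
        raise CohortError(f"group {small!r} has fewer than 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise CohortError("non-finite values in comparison input")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            statistic, p = 0.0, 1.0
        else:
            statistic, p = float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    else:
        # near-constant groups trip scipy's precision-loss warning; the
        # thresholded significance call is unaffected
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            result = sps.ttest_ind(a, b, equal_var=False)
        statistic, p = float(result.statistic), float(result.pvalue)
    return GroupComparison(
        region_id=region_id,
        metric=metric,
        test="welch_t",
        groups=(group_a, group_b),
        statistic=statistic,
        p_value=p,
        significant=p < alpha,
    )


def anova_tukey(
    values_by_group: dict[str, list[float]],
    region_id: str = "",
    metric: str = "n_usable_windows",
    alpha: float = ALPHA,
) -> GroupComparison:
    """One-way ANOVA F-test with Tukey HSD pairwise post-hoc comparisons.

    All-identical constant input (zero between- and within-group variance)
    is reported as no effect: F = 0, p = 1, all pairs non-significant.
    """
    if len(values_by_group) < 2:
        raise CohortError("ANOVA needs at least 2 groups")
    for label, values in values_by_group.items():
        if len(values) < 2:
            raise CohortError(f"group {label!r} has fewer than 2 values")
    labels = list(values_by_group)
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in labels]
    flat = np.concatenate(arrays)
    if not np.isfinite(flat).all():
        raise CohortError("non-finite values in ANOVA input")
    if np.ptp(flat) == 0.0:
        pairs = tuple(
            (labels[i], labels[j], 1.0, False)
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        )
        return GroupComparison(
            region_id=region_id, metric=metric, test="anova_tukey",
            groups=tuple(labels), statistic=0.0, p_value=1.0,
            significant=False, pairwise=pairs,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        f_stat, p = sps.f_oneway(*arrays)
    group_col = np.concatenate([[g] * len(values_by_group[g]) for g in labels])
    tukey = pairwise_tukeyhsd(flat, group_col, alpha=alpha)
    summary = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    pairs = tuple(
        (str(row["group1"]), str(row["group2"]), float(row["p-adj"]),
         bool(float(row["p-adj"]) < alpha))
        for _, row in summary.iterrows()
    )
    return GroupComparison(
        region_id=region_id, metric=metric, test="anova_tukey",
        groups=tuple(labels), statistic=float(f_stat), p_value=float(p),
        significant=float(p) < alpha, pairwise=pairs,
    )


def region_group_values(
    matrix: PresenceMatrix,
    region_id: str,
    group_ids: list[str],
    metric: str = "n_usable_windows",
    positive_only: bool = True,
) -> list[float]:
    """Metric values of one region over a sample group.

    By default only samples in which the region is *positive* contribute
    (comparisons are over expressing samples); set ``positive_only=False``
    to include zeros from negative samples.
    """
    _check_ids(matrix, group_ids, "group")
    source = matrix.windows if metric == "n_usable_windows" else matrix.depth
    values = []
    for sid in group_ids:
        if positive_only and not bool(matrix.status.loc[sid, region_id]):
            continue
        values.append(float(source.loc[sid, region_id]))
    return values


def compare_groups(
    matrix: PresenceMatrix,
    group_a_ids: list[str],
    group_b_ids: list[str],
    region_ids: list[str] | None = None,
    metric: str = "n_usable_windows",
    group_a: str = "a",
    group_b: str = "b",
    positive_only: bool = True,
    alpha: float = ALPHA,
    correction: str | None = None,
) -> pd.DataFrame:
    """Per-region Welch t-tests of a metric between two sample groups.

    Regions with fewer than 2 contributing samples in either group are
    skipped.  ``correction="bh"`` adds Benjamini–Hochberg adjusted p-values
    (significance then judged on the adjusted values).
    """
    region_ids = region_ids if region_ids is not None else matrix.region_ids
    rows = []
    for rid in region_ids:
        a = region_group_values(matrix, rid, group_a_ids, metric, positive_only)
        b = region_group_values(matrix, rid, group_b_ids, metric, positive_only)
        if len(a) < 2 or len(b) < 2:
            continue
        comp = compare_windows_ttest(
            a, b, region_id=rid, metric=metric,
            group_a=group_a, group_b=group_b, alpha=alpha,
        )
        rows.append(
            {
                "region_id": rid,
                "metric": metric,
                "test": "welch_t",
                "n_a": len(a),
                "n_b": len(b),
                "mean_a": float(np.mean(a)),
                "mean_b": float(np.mean(b)),
                "statistic": comp.statistic,
                "p_value": comp.p_value,
                "significant": comp.significant,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "region_id", "metric", "test", "n_a", "n_b",
            "mean_a", "mean_b", "statistic", "p_value", "significant",
        ],
    )
    if correction == "bh" and not frame.empty:
        finite_p = frame["p_value"].to_numpy(dtype=float)
        reject, p_adj, _, _ = multipletests(finite_p, alpha=alpha, method="fdr_bh")
        frame["p_adjusted"] = p_adj
        frame["significant"] = reject
    return frame


def compare_host_genes(
    matrix: PresenceMatrix,
    gene_ids: list[str],
    groups: dict[str, list[str]],
    metric: str = "n_usable_windows",
    positive_only: bool = True,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """ANOVA + Tukey HSD of a metric across several cohorts, per gene.

    Returns one row per (gene, group pair) carrying the gene-level F and p
    plus the pair's Tukey-adjusted p-value.
    """
    rows = []
    for gene in gene_ids:
        values_by_group = {
            label: region_group_values(matrix, gene, ids, metric, positive_only)
            for label, ids in groups.items()
        }
        values_by_group = {k: v for k, v in values_by_group.items() if len(v) >= 2}
        if len(values_by_group) < 2:
            continue
        comp = anova_tukey(values_by_group, region_id=gene, metric=metric, alpha=alpha)
        for g1, g2, p_adj, sig in comp.pairwise:
            rows.append(
                {
                    "region_id": gene,
                    "metric": metric,
                    "test": "anova_tukey",
                    "anova_F": comp.statistic,
                    "anova_p": comp.p_value,
                    "group1": g1,
                    "group2": g2,
                    "p_adjusted": p_adj,
                    "significant": sig,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "region_id", "metric", "test", "anova_F", "anova_p",
            "group1", "group2", "p_adjusted", "significant",
        ],
    )
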