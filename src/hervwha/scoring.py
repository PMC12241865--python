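"""The WHA classifier: usable windows, WSS, locus depth, positive/negative call.

Decision rule
-------------
A window is *good/usable* when its mean per-base depth is at least ``depth_min``
(default 3).  A locus in a sample is called **positive** when

* the number of usable windows is at least ``windows_min`` (default 9) — nine
  or more usable windows indicate an extended transcript; eight or fewer make
  the locus negative;
* the locus depth — the mean depth over its usable windows — is at least
  ``depth_min``;
* when the WSS gate is on (``wss_mode="strict"``), the window-similarity score
  is 100%.

The WSS here is defined operationally as the percentage of *covered* windows
(depth > 0) in which every retained read matches the reference base-for-base
within the window.  A region with no covered windows scores 100 (vacuous), so
the depth and window-count rules alone decide.  The gate is configurable
(``"strict"`` or ``"off"``) because with short reads the strict >99% identity
filter upstream already removes any read carrying a mismatch, making the gate
redundant for 100 nt reads but meaningful for longer ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .catalog import RegionCatalog
from .coverage import AlignedRead, WindowProfile

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class Thresholds:
    """All decision parameters of a WHA run, recorded in every output."""

    window_length: int = 100
    depth_min: float = 3.0
    windows_min: int = 9
    wss_min: float = 100.0
    identity_min: float = 99.0
    wss_mode: str = "strict"  # "strict" | "off"

    def __post_init__(self) -> None:
        if self.windows_min < 0 or self.depth_min < 0 or self.window_length < 1:
            raise ValueError("thresholds must be non-negative (window_length >= 1)")
        if self.wss_mode not in ("strict", "off"):
            raise ValueError(f"wss_mode must be 'strict' or 'off', got {self.wss_mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class LocusCall:
    """Per-(region, sample) WHA result."""

    region_id: str
    sample_id: str
    wss_percent: float
    n_usable_windows: int
    locus_depth: float
    status: str
    thresholds: Thresholds


def count_usable_windows(profile: WindowProfile, depth_min: float = 3.0) -> int:
    """Number of windows whose mean depth is ``depth_min`` or greater
    (a window at exactly the minimum counts)."""
    return int(np.count_nonzero(profile.depths >= depth_min))


def locus_depth(profile: WindowProfile, depth_min: float = 3.0) -> float:
    """Mean depth over usable windows; 0.0 when no window is usable."""
    usable = profile.depths[profile.depths >= depth_min]
    return float(usable.mean()) if usable.size else 0.0


def wss_score(
    profile: WindowProfile,
    reads_for_region: list[AlignedRead],
    scheme_windows: tuple[tuple[int, int], ...],
) -> float:
    """Percent of covered windows whose retained reads are all perfect matches.

    Covered = depth > 0.  A window is imperfect if any retained read has a
    mismatching base at a reference position inside the window.  100.0 when
    no window is covered (vacuous truth).
    """
    covered = [i for i, d in enumerate(profile.depths) if d > 0]
    if not covered:
        return 100.0
    mismatch_positions = sorted(
        p for read in reads_for_region for p in read.mismatch_positions
    )
    if not mismatch_positions:
        return 100.0
    mism = np.asarray(mismatch_positions)
    perfect = 0
    for i in covered:
        start, end = scheme_windows[i]
        lo = np.searchsorted(mism, start, side="left")
        hi = np.searchsorted(mism, end, side="left")
        if hi == lo:
            perfect += 1
    return 100.0 * perfect / len(covered)


def classify_locus(
    n_usable: int,
    depth: float,
    wss_percent: float,
    thresholds: Thresholds,
) -> str:
    """Positive iff (WSS gate passes) and n_usable >= windows_min and
    depth >= depth_min; negative otherwise."""
    if not (np.isfinite(depth) and np.isfinite(wss_percent)) or n_usable < 0 or depth < 0:
        raise ValueError("classify_locus requires finite, non-negative inputs")
    wss_ok = thresholds.wss_mode == "off" or wss_percent >= thresholds.wss_min
    positive = (
        wss_ok
        and n_usable >= thresholds.windows_min
        and depth >= thresholds.depth_min
    )
    return POSITIVE if positive else NEGATIVE


def score_sample(
    profiles: dict[str, WindowProfile],
    reads_by_region: dict[str, list[AlignedRead]],
    catalog: RegionCatalog,
    thresholds: Thresholds,
    sample_id: str = "",
) -> list[LocusCall]:
    """One :class:`LocusCall` per catalog region, deterministic given inputs.

    Regions missing from ``profiles`` are treated as all-zero (negative).
    """
    calls: list[LocusCall] = []
    for region_id in catalog.region_ids:
        profile = profiles.get(region_id)
        if profile is None:
            profile = WindowProfile(
                region_id=region_id,
                sample_id=sample_id,
                depths=np.zeros(catalog.scheme(region_id).n_windows),
            )
        n_usable = count_usable_windows(profile, thresholds.depth_min)
        depth = locus_depth(profile, thresholds.depth_min)
        wss = wss_score(
            profile,
            reads_by_region.get(region_id, []),
            catalog.scheme(region_id).windows,
        )
        calls.append(
            LocusCall(
                region_id=region_id,
                sample_id=profile.sample_id or sample_id,
                wss_percent=wss,
                n_usable_windows=n_usable,
                locus_depth=depth,
                status=classify_locus(n_usable, depth, wss, thresholds),
                thresholds=thresholds,
            )
        )
    return calls


def calls_to_frame(calls: list[LocusCall]) -> pd.DataFrame:
    """Calls as a tidy table (one row per sample x region)."""
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "region_id": [c.region_id for c in calls],
            "wss_percent": [c.wss_percent for c in calls],
            "n_usable_windows": [c.n_usable_windows for c in calls],
            "locus_depth": [c.locus_depth for c in calls],
            "status": [c.status for c in calls],
        }
    )
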