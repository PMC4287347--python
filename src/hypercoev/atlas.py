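"""Hybrid-atlas refinement from per-subject region-size tables.

Multi-scale parcellations do not yield equally sized regions once mapped
into functional-image space, and regions that are tiny or wildly variable
across subjects make poor network nodes.  This module implements an
iterative harmonization over a two-scale region-size table:

* a fine-scale region is *flagged* when its mean size falls below a
  percentile of the starting scale's mean sizes (default 25th) or its
  cross-subject coefficient of variation exceeds a threshold (default
  30%);
* a flagged region is tentatively merged with its siblings under the same
  coarse-scale parent; the merge is retained only if it strictly improves
  the flagged measure without worsening either the merged region's
  cross-subject variability or the within-subject spread of region sizes;
* otherwise the flagged region is excluded (reason ``rejected-merge``);
* regions with any subject of zero acquired size are excluded up front
  (``no-data``), and a top-level region flagged for variability with no
  parent to merge into is excluded as ``high-cv``.

Every input region ends up accounted for exactly once, either inside an
accepted (possibly merged) region or in the excluded list, so total voxel
counts are conserved per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

NO_DATA = "no-data"
HIGH_CV = "high-cv"
REJECTED_MERGE = "rejected-merge"


def coefficient_of_variation(sizes) -> float:
    """Sample (n-1) standard deviation divided by the mean."""
    x = np.asarray(sizes, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 subjects")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("mean size must be positive")
    return float(x.std(ddof=1) / mean)


@dataclass(eq=False)
class _Region:
    name: str
    parent: Optional[str]
    members: tuple[str, ...]
    sizes: np.ndarray  # per subject

    @property
    def mean(self) -> float:
        return float(self.sizes.mean())

    @property
    def cv(self) -> float:
        return coefficient_of_variation(self.sizes)


@dataclass
class HybridAtlas:
    """Refinement outcome: accepted regions with provenance, exclusions."""

    accepted: pd.DataFrame    # region, provenance, members, n_members
    excluded: pd.DataFrame    # region, reason
    accepted_sizes: dict[str, np.ndarray]
    excluded_sizes: dict[str, np.ndarray]
    subjects: list[str]
    cv_threshold: float
    size_percentile: float


def _within_subject_spread(regions: list[_Region]) -> float:
    """Mean over subjects of sd/mean of region sizes within the subject."""
    if len(regions) < 2:
        return 0.0
    mat = np.stack([r.sizes for r in regions])  # regions x subjects
    means = mat.mean(axis=0)
    means = np.where(means <= 0, 1.0, means)
    return float((mat.std(axis=0, ddof=1) / means).mean())


def refine(
    table: pd.DataFrame,
    cv_threshold: float = 0.30,
    size_percentile: float = 25.0,
) -> HybridAtlas:
    """Iteratively harmonize the fine scale of a region-size table.

    ``table`` needs columns region, scale, parent, subject, voxels; the
    fine scale is the one whose rows carry parent pointers.  The size
    percentile is frozen against the starting scale so the flag set
    shrinks monotonically and the iteration terminates.
    """
    required = {"region", "scale", "parent", "subject", "voxels"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table is missing columns {sorted(missing)}")
    fine = table[table["parent"].notna()]
    if fine.empty:
        raise ValueError("no fine-scale rows (parent pointers) found")
    subjects = sorted(table["subject"].unique())
    pivot = fine.pivot_table(index="region", columns="subject",
                             values="voxels", aggfunc="first")
    pivot = pivot[subjects]
    if pivot.isna().any().any():
        raise ValueError("missing (region, subject) size entries")
    parent_of = fine.drop_duplicates("region").set_index("region")["parent"]

    excluded: list[tuple[str, str]] = []
    excluded_sizes: dict[str, np.ndarray] = {}
    active: dict[str, _Region] = {}
    for region in pivot.index:
        sizes = pivot.loc[region].to_numpy(dtype=float)
        if (sizes == 0).any():
            excluded.append((region, NO_DATA))
            excluded_sizes[region] = sizes
        else:
            active[region] = _Region(
                name=region, parent=str(parent_of[region]),
                members=(region,), sizes=sizes,
            )
    if not active:
        raise ValueError("every region lacks data")

    size_floor = float(
        np.percentile([r.mean for r in active.values()], size_percentile)
    )

    def flag(r: _Region) -> Optional[str]:
        if r.cv > cv_threshold:
            return "cv"
        if r.mean < size_floor:
            return "size"
        return None

    merged_provenance: set[str] = set()
    while True:
        flagged = sorted(
            (name for name, r in active.items() if flag(r)),
        )
        if not flagged:
            break
        name = flagged[0]
        region = active[name]
        why = flag(region)
        siblings = [
            r for r in active.values()
            if r.parent is not None and r.parent == region.parent
            and r.name != name
        ]
        if region.parent is None or not siblings:
            reason = HIGH_CV if why == "cv" else REJECTED_MERGE
            excluded.append((name, reason))
            excluded_sizes[name] = region.sizes
            del active[name]
            continue
        candidates = [region] + siblings
        merged_sizes = np.sum([r.sizes for r in candidates], axis=0)
        merged = _Region(
            name=region.parent, parent=None,
            members=tuple(m for r in candidates for m in r.members),
            sizes=merged_sizes,
        )
        improves = (
            merged.cv < region.cv if why == "cv" else merged.mean > region.mean
        )
        others = [r for r in active.values() if r not in candidates]
        not_worse = (
            merged.cv <= max(r.cv for r in candidates)
            and _within_subject_spread(others + [merged])
            <= _within_subject_spread(list(active.values())) + 1e-12
        )
        if improves and not_worse:
            for r in candidates:
                del active[r.name]
            active[merged.name] = merged
            merged_provenance.add(merged.name)
        else:
            excluded.append((name, REJECTED_MERGE))
            excluded_sizes[name] = region.sizes
            del active[name]

    accepted_rows = [
        {
            "region": r.name,
            "provenance": "merged" if r.name in merged_provenance else "original",
            "members": ";".join(r.members),
            "n_members": len(r.members),
        }
        for r in sorted(active.values(), key=lambda r: r.name)
    ]
    return HybridAtlas(
        accepted=pd.DataFrame(
            accepted_rows, columns=["region", "provenance", "members", "n_members"]
        ),
        excluded=pd.DataFrame(excluded, columns=["region", "reason"]),
        accepted_sizes={r.name: r.sizes for r in active.values()},
        excluded_sizes=excluded_sizes,
        subjects=[str(s) for s in subjects],
        cv_threshold=cv_threshold,
        size_percentile=size_percentile,
    )
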