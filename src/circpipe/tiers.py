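"""Ordinal expression tiers per sample, the plotted matrix, clustering and
tissue-overlap counts.

Tier classes per sample: 0 = not_detected, 1 = detected (>= 2 unique
junction reads), 2 = high (detected and within the top fraction of the
sample's detected circRNAs by raw junction read count; fraction 0.10 by
default, 0.05 for platelet-style samples).  Only circRNAs that are high
in at least one compared sample enter the plotted matrix.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

log = logging.getLogger(__name__)

NOT_DETECTED, DETECTED, HIGH = 0, 1, 2
DEFAULT_TOP_FRACTION = 0.10
PLATELET_TOP_FRACTION = 0.05
DETECTION_MIN_READS = 2


def tier_sample(catalog: pd.DataFrame, top_fraction: float = DEFAULT_TOP_FRACTION,
                min_reads: int = DETECTION_MIN_READS,
                rounding: str = "ceil") -> pd.Series:
    """Ordinal tier label per circ_id for one sample's catalog.

    ``catalog`` needs circ_id and junction_reads columns (CLR used for
    tie-breaking when present).  Exactly ceil(top_fraction * n_detected)
    circRNAs are labeled high; ties at the cut are broken by higher CLR,
    then lexicographically by circ_id.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    if rounding not in ("ceil", "floor"):
        raise ValueError("rounding must be 'ceil' or 'floor'")
    df = catalog[["circ_id", "junction_reads"]].copy()
    df["clr"] = pd.to_numeric(catalog["CLR"], errors="coerce") if "CLR" in catalog else 0.0
    labels = pd.Series(NOT_DETECTED, index=df["circ_id"].to_numpy(), dtype=int)
    detected = df[df["junction_reads"] >= min_reads]
    labels.loc[detected["circ_id"]] = DETECTED
    n_det = len(detected)
    if n_det == 0:
        return labels
    k = (math.ceil if rounding == "ceil" else math.floor)(top_fraction * n_det)
    ranked = detected.sort_values(
        by=["junction_reads", "clr", "circ_id"],
        ascending=[False, False, True], kind="mergesort")
    labels.loc[ranked["circ_id"].head(k)] = HIGH
    return labels


def build_matrix(tiered_samples: Mapping[str, pd.Series]) -> pd.DataFrame:
    """circ_id x sample ordinal matrix, restricted to rows high somewhere.

    A circRNA absent from a sample's catalog scores 0 in that column.
    """
    if len(tiered_samples) < 2:
        raise ValueError("need at least two samples to build a tier matrix")
    samples = sorted(tiered_samples)
    all_ids = sorted(set().union(*(set(s.index) for s in tiered_samples.values())))
    mat = pd.DataFrame(NOT_DETECTED, index=all_ids, columns=samples, dtype=int)
    for name in samples:
        labels = tiered_samples[name]
        mat.loc[labels.index, name] = labels.to_numpy()
    keep = (mat == HIGH).any(axis=1)
    if not keep.any():
        log.warning("no circRNA is high in any sample; matrix is empty")
    return mat.loc[keep]


def cluster_matrix(matrix: pd.DataFrame, method: str = "complete",
                   metric: str = "cityblock") -> tuple[list[int], list[int]]:
    """Leaf orderings (row indices, column indices) from agglomerative
    clustering of the ordinal codes."""
    if matrix.empty:
        raise ValueError("cannot cluster an empty matrix")
    x = matrix.to_numpy(dtype=float)

    def order(arr):
        if arr.shape[0] < 2:
            return [0]
        return list(leaves_list(linkage(pdist(arr, metric=metric), method=method)))

    return order(x), order(x.T)


def overlap_counts(candidate_sets: Mapping[str, set[str]],
                   multiway: Sequence[Sequence[str]] = (),
                   ) -> tuple[pd.DataFrame, dict[tuple[str, ...], int]]:
    """Pairwise (and optional listed multi-way) intersection cardinalities."""
    names = sorted(candidate_sets)
    table = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for name in names:
        table.loc[name, name] = len(candidate_sets[name])
    for a, b in combinations(names, 2):
        n = len(candidate_sets[a] & candidate_sets[b])
        table.loc[a, b] = table.loc[b, a] = n
    multi = {}
    for group in multiway:
        key = tuple(sorted(group))
        common = set.intersection(*(candidate_sets[g] for g in key))
        multi[key] = len(common)
    return table, multi
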