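"""Dropout-gene calling and 2D/3D exclusivity partitioning.

A gene is called a dropout in a comparison when its control-normalized
gene effect falls below a threshold (u_gene < -0.1 by default) **and**
enough of its guides individually dropped out (>= 3 guides with
pZ <= -0.1 by default).  The four per-comparison call sets (2D/3D at
day 7/14) are then partitioned into condition-exclusive classes: a
3D-exclusive gene is called in 3D on both days but in neither 2D
comparison, and symmetrically for 2D; genes called in all four
comparisons are shared essentials.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .phenotype import ComparisonPhenotypes

__all__ = [
    "CallConfig",
    "Label",
    "COMPARISON_KEYS",
    "call_dropouts",
    "exclusivity_partition",
    "upset_membership",
]

#: Canonical comparison labels of the full two-condition design.
COMPARISON_KEYS = ("2D_D7_vs_D0", "2D_D14_vs_D0", "3D_D7_vs_D0", "3D_D14_vs_D0")


class Label(str, enum.Enum):
    """Condition-exclusivity class of a gene."""

    THREE_D_EXCLUSIVE = "3D_exclusive"
    TWO_D_EXCLUSIVE = "2D_exclusive"
    SHARED = "shared"
    OTHER = "other"
    NONE = "none"


@dataclass(frozen=True)
class CallConfig:
    """Dropout-call thresholds.

    gene_lfc_max
        Gene-level gate: called only if u_gene < gene_lfc_max (strict).
    min_guides_dropped
        Minimum number of guides that must individually drop out.
    guide_drop_max
        Per-guide gate: a guide is "dropped" iff pZ <= guide_drop_max
        (inclusive, so a guide exactly at threshold counts).
    """

    gene_lfc_max: float = -0.1
    min_guides_dropped: int = 3
    guide_drop_max: float = -0.1

    def __post_init__(self) -> None:
        if self.gene_lfc_max >= 0:
            raise ValueError("gene_lfc_max must be negative")
        if self.min_guides_dropped < 1:
            raise ValueError("min_guides_dropped must be >= 1")


def _n_dropped(phen: ComparisonPhenotypes, threshold: float) -> pd.Series:
    """Recount dropped guides per gene at an arbitrary pZ threshold."""
    lib = phen.library
    if lib is None:
        return phen.genes["n_dropped"]
    pz = phen.guide_frame["pZ"]
    gene_map = lib.gene_of()
    targeting = pz.index.intersection(lib.targeting_ids)
    mask = pz.loc[targeting] <= threshold
    counts = mask.groupby(gene_map.loc[targeting]).sum()
    return counts.reindex(phen.genes.index).fillna(0).astype(int)


def call_dropouts(
    phen: ComparisonPhenotypes, config: CallConfig | None = None
) -> set[str]:
    """Genes called as dropouts in one comparison under ``config``.

    Uses the precomputed ``n_dropped`` column when the config threshold
    matches the one the phenotype table was built with, otherwise
    recounts from the per-guide pZ values.
    """
    config = config or CallConfig()
    genes = phen.genes
    built_at = genes.attrs.get("drop_threshold")
    if built_at is not None and built_at != config.guide_drop_max:
        n_dropped = _n_dropped(phen, config.guide_drop_max)
    else:
        n_dropped = genes["n_dropped"]
    called = genes.index[
        (genes["u_gene"] < config.gene_lfc_max)
        & (n_dropped >= config.min_guides_dropped)
    ]
    return set(called)


def exclusivity_partition(
    sets: Mapping[str, set[str]],
    universe: set[str] | None = None,
    both_days: bool = True,
) -> pd.Series:
    """Partition genes into exclusivity classes from four dropout sets.

    ``sets`` maps the four canonical comparison labels to called-gene
    sets (missing comparisons are treated as empty).  With the default
    ``both_days=True`` exclusivity requires a call on both day 7 and
    day 14 of one condition and on neither day of the other; with
    ``both_days=False`` a call on either day suffices.  Genes called
    somewhere but fitting no class are OTHER; genes never called are
    NONE.  Returns a gene -> :class:`Label` Series over the universe
    (default: union of all sets).
    """
    s2d7 = set(sets.get("2D_D7_vs_D0", set()))
    s2d14 = set(sets.get("2D_D14_vs_D0", set()))
    s3d7 = set(sets.get("3D_D7_vs_D0", set()))
    s3d14 = set(sets.get("3D_D14_vs_D0", set()))
    any_called = s2d7 | s2d14 | s3d7 | s3d14
    if universe is None:
        universe = set(any_called)

    if both_days:
        in_3d, in_2d = s3d7 & s3d14, s2d7 & s2d14
    else:
        in_3d, in_2d = s3d7 | s3d14, s2d7 | s2d14
    three_excl = in_3d - (s2d7 | s2d14)
    two_excl = in_2d - (s3d7 | s3d14)
    shared = in_2d & in_3d

    labels = {}
    for g in universe:
        if g in three_excl:
            labels[g] = Label.THREE_D_EXCLUSIVE.value
        elif g in two_excl:
            labels[g] = Label.TWO_D_EXCLUSIVE.value
        elif g in shared:
            labels[g] = Label.SHARED.value
        elif g in any_called:
            labels[g] = Label.OTHER.value
        else:
            labels[g] = Label.NONE.value
    out = pd.Series(labels, name="label").sort_index()
    out.index.name = "gene"
    return out


def upset_membership(
    sets: Mapping[str, set[str]]
) -> tuple[pd.DataFrame, pd.Series]:
    """Membership table and exclusive-intersection counts for UpSet plots.

    Returns a boolean gene x comparison DataFrame over the union of the
    sets, plus counts per exclusive membership pattern (so the counts
    sum to the union size).
    """
    keys = [k for k in COMPARISON_KEYS if k in sets] or list(sets)
    union = sorted(set().union(*(sets[k] for k in keys)) if keys else set())
    membership = pd.DataFrame(
        {k: [g in sets[k] for g in union] for k in keys}, index=union, dtype=bool
    )
    membership.index.name = "gene"
    if union:
        counts = membership.groupby(keys).size()
    else:
        counts = pd.Series(dtype=int)
    counts.name = "n_genes"
    return membership, counts
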