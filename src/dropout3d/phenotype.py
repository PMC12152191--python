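"""Control-normalized effect sizes and gene phenotype (T) scores.

The effect size of a guide, pZ, is its log2 fold enrichment minus the
median log2 fold enrichment of the negative-control guides (safe and
non-targeting), so the control population is centred at zero in every
comparison.  A gene's effect size U_gene is the median pZ of its
guides.  The phenotype score standardizes U_gene against the control
distribution with a pooled variance:

    T = (U_gene - U_ctrl) / sqrt(S_var/N_exp + S_var/N_ctrl)

    S_var = Var_gene * (N_exp - 1) + Var_ctrl * (N_ctrl - 1)

where Var_gene is the sample variance of the gene's guide pZ values,
Var_ctrl the sample variance of control-guide pZ values, N_exp the
number of guides for the gene and N_ctrl the average number of guides
per gene in the screen.  Note that the pooled sum-of-squares S_var
itself (not a variance) enters both denominator terms; a conventional
Welch-style denominator sqrt(Var_gene/N_exp + Var_ctrl/N_ctrl) is
available behind ``welch=True`` for sensitivity analysis.  Sample
variances use divisor n-1 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import log2_fold_enrichment
from .screen import Comparison, CountMatrix, GuideLibrary, ScreenDesign, validate_design

__all__ = [
    "ControlSummary",
    "ComparisonPhenotypes",
    "PhenotypeError",
    "guide_pZ",
    "gene_u",
    "t_score",
    "gene_table",
    "screen_phenotypes",
]

#: Per-guide pZ at or below this value counts the guide as "dropped out".
DEFAULT_DROP_THRESHOLD = -0.1


class PhenotypeError(ValueError):
    """Raised when phenotype scores cannot be computed."""


@dataclass(frozen=True)
class ControlSummary:
    """Control-population statistics of one comparison.

    u_ctrl is the median control pZ (zero by construction, kept for
    transparency), var_ctrl the sample variance of control pZ values,
    n_ctrl the average number of guides per targeting gene.
    """

    comparison: str
    u_ctrl: float
    var_ctrl: float
    n_ctrl: float
    n_control_guides: int


def guide_pZ(enrichment: pd.DataFrame, library: GuideLibrary) -> pd.Series:
    """Control-median-normalized effect size per guide.

    ``enrichment`` must carry a ``log2fe`` column indexed by guide_id.
    """
    controls = [g for g in library.control_ids if g in enrichment.index]
    if not controls:
        raise PhenotypeError("no control guides present in enrichment table")
    ctrl_median = float(enrichment.loc[controls, "log2fe"].median())
    pz = enrichment["log2fe"] - ctrl_median
    pz.name = "pZ"
    return pz


def gene_u(pz: pd.Series, library: GuideLibrary) -> pd.Series:
    """Median pZ per targeting gene (midpoint for even guide counts)."""
    gene_map = library.gene_of()
    targeting = pz.index.intersection(library.targeting_ids)
    by_gene = pz.loc[targeting].groupby(gene_map.loc[targeting])
    u = by_gene.median()
    u.name = "u_gene"
    return u.loc[[g for g in library.genes if g in u.index]]


def t_score(
    u_gene: float,
    var_gene: float,
    n_exp: int,
    ctrl: ControlSummary,
    welch: bool = False,
) -> float:
    """Phenotype score of a single gene; NaN when undefined (n_exp < 2)."""
    if n_exp < 2 or not np.isfinite(var_gene):
        return float("nan")
    if welch:
        denom_sq = var_gene / n_exp + ctrl.var_ctrl / ctrl.n_ctrl
    else:
        s_var = var_gene * (n_exp - 1) + ctrl.var_ctrl * (ctrl.n_ctrl - 1)
        denom_sq = s_var / n_exp + s_var / ctrl.n_ctrl
    if denom_sq <= 0:
        return float("nan")
    return (u_gene - ctrl.u_ctrl) / float(np.sqrt(denom_sq))


def control_summary(
    pz: pd.Series, library: GuideLibrary, comparison_label: str
) -> ControlSummary:
    controls = [g for g in library.control_ids if g in pz.index]
    if not controls:
        raise PhenotypeError("no control guides present")
    ctrl_pz = pz.loc[controls]
    n_genes = len(library.genes)
    if n_genes == 0:
        raise PhenotypeError("library has no targeting genes")
    n_ctrl = len(library.targeting_ids) / n_genes
    return ControlSummary(
        comparison=comparison_label,
        u_ctrl=float(ctrl_pz.median()),
        var_ctrl=float(ctrl_pz.var(ddof=1)),
        n_ctrl=n_ctrl,
        n_control_guides=len(controls),
    )


def gene_table(
    pz: pd.Series,
    library: GuideLibrary,
    ctrl: ControlSummary,
    drop_threshold: float = DEFAULT_DROP_THRESHOLD,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-gene phenotype table: n_exp, u_gene, var_gene, n_dropped, t_score.

    ``n_dropped`` counts guides with pZ <= ``drop_threshold``.  Genes
    whose guides all lack a finite pZ are excluded (they are listed in
    ``.attrs["excluded_genes"]``); single-guide genes keep their u_gene
    but get an undefined (NaN) t_score.
    """
    gene_map = library.gene_of()
    targeting = pz.index.intersection(library.targeting_ids)
    pzt = pz.loc[targeting]
    finite = pzt[np.isfinite(pzt)]
    grouped = finite.groupby(gene_map.loc[finite.index])

    n_exp = grouped.size()
    u = grouped.median()
    var = grouped.var(ddof=1)
    dropped = finite[finite <= drop_threshold].groupby(
        gene_map.loc[finite.index][finite <= drop_threshold]
    ).size()

    order = [g for g in library.genes if g in u.index]
    table = pd.DataFrame(
        {
            "n_exp": n_exp.loc[order].astype(int),
            "u_gene": u.loc[order],
            "var_gene": var.loc[order],
            "n_dropped": dropped.reindex(order).fillna(0).astype(int),
        }
    )
    table["t_score"] = [
        t_score(row.u_gene, row.var_gene, row.n_exp, ctrl, welch=welch)
        for row in table.itertuples()
    ]
    table.index.name = "gene"
    table.attrs["excluded_genes"] = [g for g in library.genes if g not in u.index]
    table.attrs["comparison"] = ctrl.comparison
    table.attrs["drop_threshold"] = drop_threshold
    return table


@dataclass
class ComparisonPhenotypes:
    """All per-guide and per-gene scores of one comparison."""

    comparison: Comparison
    guide_frame: pd.DataFrame  # log2fe, log2fe_rep*, pZ; indexed by guide_id
    genes: pd.DataFrame  # n_exp, u_gene, var_gene, n_dropped, t_score
    control: ControlSummary
    library: GuideLibrary | None = None


def screen_phenotypes(
    counts: CountMatrix,
    library: GuideLibrary,
    design: ScreenDesign,
    pseudocount: float = 0.5,
    paired: bool = True,
    welch: bool = False,
    drop_threshold: float = DEFAULT_DROP_THRESHOLD,
    size_factor_method: str = "median_ratio",
    min_eligible: int = 100,
) -> dict[str, ComparisonPhenotypes]:
    """Score every computable comparison of the screen.

    Returns a mapping comparison label -> :class:`ComparisonPhenotypes`.
    Each comparison is normalized independently (its own size factors
    over the samples it uses).
    """
    report = validate_design(design, counts)
    if not report.computable:
        raise PhenotypeError("no computable comparisons in design")
    out: dict[str, ComparisonPhenotypes] = {}
    for comp in report.computable:
        enr = log2_fold_enrichment(
            counts,
            design,
            comp,
            pseudocount=pseudocount,
            paired=paired,
            size_factor_method=size_factor_method,
            min_eligible=min_eligible,
        )
        pz = guide_pZ(enr, library)
        ctrl = control_summary(pz, library, comp.label)
        genes = gene_table(
            pz, library, ctrl, drop_threshold=drop_threshold, welch=welch
        )
        frame = enr.copy()
        frame["pZ"] = pz
        out[comp.label] = ComparisonPhenotypes(comp, frame, genes, ctrl, library)
    return out
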