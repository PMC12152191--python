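"""Downstream triage of called dropout genes.

Screen hits are narrowed with user-supplied annotation tables rather
than recomputed enrichments: (1) a pathway-membership filter keeps genes
sitting in at least ``min_count`` of the ``top_n`` highest-ranked
pathways of a binary gene x pathway matrix (column order encodes the
significance ranking); (2) a survival filter keeps genes whose high
expression marks poor prognosis (hazard ratio > 1 at p < 0.05, both
strict); (3) an expression cohort can be scored against a proliferation
meta-gene signature (mean z-score) and correlated with any gene of
interest.  The cascade applies the filters in order, recording the
surviving set and per-gene elimination reasons after each stage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PROLIFERATION_SIGNATURE",
    "SignatureScore",
    "CascadeReport",
    "pathway_count_filter",
    "survival_filter",
    "signature_score",
    "correlate_with_signature",
    "cascade",
]

#: Proliferation meta-gene signature (cell-cycle / replication genes).
PROLIFERATION_SIGNATURE = [
    "MCM7", "PLK1", "MCM5", "BUB1", "MCM3", "MKI67", "MCM2", "CCND3",
    "MCM4", "MYBL2", "CCNB2", "E2F1", "MCM6", "CCNE2", "PCNA", "CCND2",
    "CCNB1", "CCNE1", "CCND1",
]


def pathway_count_filter(
    candidates: Iterable[str],
    membership: pd.DataFrame,
    top_n: int = 20,
    min_count: int = 9,
) -> set[str]:
    """Keep genes present in >= ``min_count`` of the top ``top_n`` pathways.

    ``membership`` is a binary gene x pathway DataFrame whose column
    order is the pathway significance ranking (most significant first).
    Candidates absent from the matrix count zero memberships and are
    reported with a warning.
    """
    candidates = set(candidates)
    if top_n > membership.shape[1]:
        raise ValueError(
            f"top_n={top_n} exceeds the {membership.shape[1]} pathways available"
        )
    vals = membership.iloc[:, :top_n]
    bad = vals.to_numpy()[~np.isin(vals.to_numpy(), [0, 1])]
    if bad.size:
        raise ValueError(f"membership matrix must be binary; found {bad[:3]}")
    uncovered = sorted(candidates - set(membership.index))
    if uncovered:
        warnings.warn(
            f"{len(uncovered)} candidate gene(s) absent from pathway matrix "
            f"(counted as 0): {uncovered[:5]}",
            stacklevel=2,
        )
    counts = vals.sum(axis=1)
    if min_count <= 0:
        return set(candidates)
    kept = {
        g for g in candidates if g in counts.index and counts[g] >= min_count
    }
    return kept


def survival_filter(
    candidates: Iterable[str],
    stats_table: pd.DataFrame,
    hr_min: float = 1.0,
    p_max: float = 0.05,
) -> set[str]:
    """Keep genes with hazard ratio > ``hr_min`` and p < ``p_max`` (strict).

    ``stats_table`` is indexed by gene with columns ``hr`` and ``p``.
    Candidates without statistics are excluded with a warning.
    """
    candidates = set(candidates)
    if (stats_table["hr"] <= 0).any():
        bad = stats_table.index[stats_table["hr"] <= 0][0]
        raise ValueError(f"hazard ratio must be positive (gene {bad!r})")
    missing = sorted(candidates - set(stats_table.index))
    if missing:
        warnings.warn(
            f"{len(missing)} candidate gene(s) without survival statistics "
            f"(excluded): {missing[:5]}",
            stacklevel=2,
        )
    sub = stats_table.loc[[g for g in candidates if g in stats_table.index]]
    kept = sub.index[(sub["hr"] > hr_min) & (sub["p"] < p_max)]
    return set(kept)


@dataclass
class SignatureScore:
    """Per-sample signature scores plus coverage diagnostics."""

    scores: pd.Series  # indexed by sample
    signature: list[str]
    used_genes: list[str]
    dropped_genes: list[str]

    @property
    def coverage(self) -> float:
        return len(self.used_genes) / len(self.signature) if self.signature else 0.0


def signature_score(
    expression: pd.DataFrame,
    signature: Sequence[str] = PROLIFERATION_SIGNATURE,
    method: str = "mean",
) -> SignatureScore:
    """Score samples against a gene signature.

    ``expression`` is a sample x gene table.  Each signature gene is
    z-scored across samples (ddof=1) and a sample's score is the mean
    (or, with ``method="median"``, the median) of the available
    z-scores.  Signature genes missing from the table or with zero
    variance are excluded and reported.
    """
    if expression.shape[0] < 2:
        raise ValueError("need at least 2 samples to z-score expression")
    present = [g for g in signature if g in expression.columns]
    if not present:
        raise ValueError("no signature genes present in expression table")
    sub = expression[present].astype(float)
    sd = sub.std(ddof=1)
    degenerate = sorted(sd.index[(sd == 0) | ~np.isfinite(sd)])
    if degenerate:
        warnings.warn(
            f"signature gene(s) with zero variance excluded: {degenerate}",
            stacklevel=2,
        )
    used = [g for g in present if g not in degenerate]
    if not used:
        raise ValueError("all signature genes have zero variance")
    z = (sub[used] - sub[used].mean()) / sd[used]
    scores = z.median(axis=1) if method == "median" else z.mean(axis=1)
    scores.name = "signature_score"
    dropped = sorted(set(signature) - set(used))
    return SignatureScore(scores, list(signature), used, dropped)


def correlate_with_signature(
    gene_expr: pd.Series, scores: SignatureScore | pd.Series
) -> tuple[float, float, float]:
    """Pearson correlation of one gene's expression with signature scores.

    Returns (correlation, least-squares slope, two-sided p-value for
    zero correlation), aligning on the common samples.
    """
    s = scores.scores if isinstance(scores, SignatureScore) else scores
    common = gene_expr.index.intersection(s.index)
    if len(common) < 3:
        raise ValueError("need at least 3 shared samples")
    x, y = s.loc[common].astype(float), gene_expr.loc[common].astype(float)
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValueError("zero variance in expression or signature scores")
    res = stats.linregress(x, y)
    return float(res.rvalue), float(res.slope), float(res.pvalue)


@dataclass
class CascadeReport:
    """Staged filtration record: surviving sets and elimination reasons."""

    stages: list[tuple[str, set[str]]]
    eliminated: dict[str, str] = field(default_factory=dict)
    notices: list[str] = field(default_factory=list)

    @property
    def stage_sizes(self) -> list[int]:
        return [len(s) for _, s in self.stages]

    @property
    def final(self) -> set[str]:
        return self.stages[-1][1] if self.stages else set()

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.stages[0][1]) if self.stages else []
        cols = {
            name: [g in kept for g in genes] for name, kept in self.stages
        }
        df = pd.DataFrame(cols, index=genes, dtype=bool)
        df.index.name = "gene"
        df["eliminated_at"] = [self.eliminated.get(g, "") for g in genes]
        return df

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "stages": [
                {"name": name, "n": len(kept), "genes": sorted(kept)}
                for name, kept in self.stages
            ],
            "eliminated": self.eliminated,
            "notices": self.notices,
        }
        text = json.dumps(payload, indent=2) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def cascade(
    candidates: Iterable[str],
    membership: pd.DataFrame | None = None,
    survival: pd.DataFrame | None = None,
    top_n: int = 20,
    min_count: int = 9,
    hr_min: float = 1.0,
    p_max: float = 0.05,
) -> CascadeReport:
    """Run the staged prioritization: pathway filter, then survival filter.

    A stage whose annotation table is missing is skipped with an
    explicit notice (never silently passed).  Each stage's output is a
    subset of its input, so the report is a filtration.
    """
    current = set(candidates)
    report = CascadeReport(stages=[("candidates", set(current))])
    if membership is not None:
        kept = pathway_count_filter(current, membership, top_n, min_count)
        for g in current - kept:
            report.eliminated[g] = "pathway_count"
        current = kept
        report.stages.append(("pathway_count", set(current)))
    else:
        report.notices.append("pathway stage skipped: no membership table")
    if survival is not None:
        kept = survival_filter(current, survival, hr_min, p_max)
        for g in current - kept:
            report.eliminated[g] = "survival"
        current = kept
        report.stages.append(("survival", set(current)))
    else:
        report.notices.append("survival stage skipped: no statistics table")
    return report
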