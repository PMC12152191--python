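"""Count normalization and per-sgRNA log2 fold enrichment.

Each endpoint sample (day 7 or 14) is compared against the day-0
baseline of the same growth condition.  Counts are first divided by
per-sample size factors (median-of-ratios by default, the DESeq/MAGeCK
family of normalization); a pseudocount then guards zero counts before
taking log2.  Per-replicate values are retained and averaged into the
reported log2 fold enrichment.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .screen import Comparison, CountMatrix, ScreenDesign

__all__ = ["size_factors", "log2_fold_enrichment", "EnrichmentError"]


class EnrichmentError(ValueError):
    """Raised when enrichment cannot be computed for a comparison."""


def size_factors(
    counts: pd.DataFrame,
    method: str = "median_ratio",
    min_eligible: int = 100,
) -> pd.Series:
    """Per-sample normalization factors, rescaled to geometric mean 1.

    ``median_ratio``: for every guide with a positive count in all
    samples, form count / geometric-mean-across-samples; the factor of a
    sample is the median of those ratios.  When fewer than
    ``min_eligible`` guides qualify the method degrades to total-count
    scaling with a warning (``method="total"`` selects it directly).

    Dividing counts by these factors makes samples comparable; the
    rescaling to geometric mean 1 keeps normalized counts on the raw
    count scale.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.frame
    vals = counts.to_numpy(dtype=float)
    col_sums = vals.sum(axis=0)
    if np.any(col_sums <= 0):
        bad = counts.columns[np.argmax(col_sums <= 0)]
        raise EnrichmentError(f"sample {bad!r} has all-zero counts")

    if method == "median_ratio":
        eligible = np.all(vals > 0, axis=1)
        if eligible.sum() >= min_eligible:
            logs = np.log(vals[eligible])
            log_geomean = logs.mean(axis=1, keepdims=True)
            factors = np.exp(np.median(logs - log_geomean, axis=0))
        else:
            warnings.warn(
                f"only {int(eligible.sum())} guides positive in every sample "
                f"(< {min_eligible}); falling back to total-count scaling",
                stacklevel=2,
            )
            factors = col_sums
    elif method == "total":
        factors = col_sums
    else:
        raise ValueError(f"unknown size-factor method {method!r}")

    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def log2_fold_enrichment(
    counts: CountMatrix,
    design: ScreenDesign,
    comparison: Comparison,
    pseudocount: float = 0.5,
    paired: bool = True,
    size_factor_method: str = "median_ratio",
    min_eligible: int = 100,
) -> pd.DataFrame:
    """Per-guide log2 fold enrichment for one comparison.

    Size factors are computed over the samples the comparison uses
    (baseline plus endpoint of its condition).  With ``paired=True``
    each endpoint replicate is compared to the baseline replicate with
    the same replicate number when one exists; otherwise (and always
    with ``paired=False``) each endpoint replicate is compared against
    the mean of the normalized baseline counts.  The reported ``log2fe``
    is the arithmetic mean over replicate values.

    Returns a DataFrame indexed by guide_id with columns ``log2fe`` and
    one ``log2fe_rep<r>`` per endpoint replicate; per-comparison size
    factors are attached as ``.attrs["size_factors"]``.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    base = design.samples_for(comparison.condition, design.baseline_day)
    end = design.samples_for(comparison.condition, comparison.day)
    base = [s for s in base if s.sample_id in counts.frame.columns]
    end = [s for s in end if s.sample_id in counts.frame.columns]
    if not base:
        raise EnrichmentError(
            f"{comparison.label}: no baseline sample for condition "
            f"{comparison.condition.value}"
        )
    if not end:
        raise EnrichmentError(f"{comparison.label}: no endpoint samples")

    sample_ids = [s.sample_id for s in base + end]
    sub = counts.frame[sample_ids]
    factors = size_factors(sub, method=size_factor_method, min_eligible=min_eligible)
    norm = sub / factors

    base_by_rep = {s.replicate: s.sample_id for s in base}
    base_mean = norm[[s.sample_id for s in base]].mean(axis=1)

    out = pd.DataFrame(index=counts.frame.index)
    rep_cols = []
    for s in sorted(end, key=lambda s: s.replicate):
        endpoint = norm[s.sample_id]
        if paired and s.replicate in base_by_rep:
            baseline = norm[base_by_rep[s.replicate]]
        else:
            baseline = base_mean
        col = f"log2fe_rep{s.replicate}"
        out[col] = np.log2((endpoint + pseudocount) / (baseline + pseudocount))
        rep_cols.append(col)
    out.insert(0, "log2fe", out[rep_cols].mean(axis=1))
    out.attrs["size_factors"] = factors
    out.attrs["comparison"] = comparison.label
    return out
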