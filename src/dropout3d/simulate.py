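"""Synthetic pooled-screen data with known ground truth.

The generator emulates a two-condition (2D monolayer vs 3D suspension)
dropout screen: a guide library with 10 guides per gene plus safe and
non-targeting controls, duplicate samples at days 0/7/14 in both
conditions, ~1000x cells-per-guide plating coverage, and negative
binomially overdispersed read counts.

Model, per guide i with per-day log2 fitness effect f_ic in condition c:

* baseline abundance a_i ~ log-normal(0, 0.25) (library skew);
* each (condition, replicate) lineage is plated once at day 0 through a
  multinomial bottleneck of ``coverage * n_guides`` cells, and all of
  that lineage's timepoints are sampled from the same plated
  population — mirroring a dish that is seeded once and harvested at
  day 0, 7 and 14;
* at day t the lineage's expected relative abundance is proportional to
  cells_i * 2**(f_ic * t), renormalized across the library (competitive
  growth: share lost by depleted guides is gained by the rest);
* read counts are Poisson around depth * n_guides * p_i * g_i where
  g_i ~ Gamma(1/dispersion, dispersion) is a guide-specific
  amplification propensity (mean 1).  Marginally each count is negative
  binomial with the configured dispersion; because amplification bias
  is a property of the spacer sequence it persists across samples, so
  it inflates count spread without corrupting fold changes — the noise
  structure exact-match screen quantification actually faces.

Essential-class effects are heterogeneous between guides,
f ~ Normal(effect, effect_sd) truncated above at 0; neutral genes and
control guides have f = 0 everywhere, 2D-/3D-exclusive classes have
f < 0 only in their condition.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .screen import (
    CONTROL_GENE,
    Category,
    Condition,
    CountMatrix,
    GuideLibrary,
    GuideRecord,
    SampleInfo,
    ScreenDesign,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_library",
    "simulate_screen",
    "write_fastq",
    "evaluate_recovery",
    "RecoveryMetrics",
    "simulate_annotations",
    "simulate_expression",
    "EXPECTED_LABEL",
]

_BASES = np.array(list("ACGT"))

#: Truth class -> the exclusivity label a perfect pipeline assigns it.
EXPECTED_LABEL = {
    "neutral": "none",
    "common_essential": "shared",
    "essential_2D": "2D_exclusive",
    "essential_3D": "3D_exclusive",
}


@dataclass(frozen=True)
class SimConfig:
    """Screen-generator settings.

    Counts of genes per fitness class, guides per gene and control-set
    sizes define the library; ``effect`` (log2 change per day, negative
    for depletion), ``effect_sd`` (between-guide potency spread),
    ``coverage`` (cells per guide at plating), ``depth`` (mean reads
    per guide per sample) and ``dispersion`` (negative-binomial
    overdispersion of counts) define the noise; all randomness flows
    from ``seed``.
    """

    n_neutral: int = 100
    n_common_essential: int = 20
    n_2d_essential: int = 20
    n_3d_essential: int = 20
    guides_per_gene: int = 10
    n_safe: int = 750
    n_nontargeting: int = 750
    effect: float = -0.4
    effect_sd: float = 0.15
    coverage: int = 1000
    depth: float = 500.0
    dispersion: float = 0.1
    days: tuple[int, ...] = (0, 7, 14)
    replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_neutral", "n_common_essential", "n_2d_essential",
            "n_3d_essential", "n_safe", "n_nontargeting",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.guides_per_gene < 1 or self.replicates < 1:
            raise ValueError("guides_per_gene and replicates must be >= 1")
        if self.dispersion < 0 or self.effect_sd < 0:
            raise ValueError("dispersion and effect_sd must be >= 0")
        if self.effect > 0:
            raise ValueError("effect must be <= 0 for depletion classes")


@dataclass
class SimTruth:
    """Ground-truth ledger of a simulated screen.

    gene_classes maps gene -> fitness class; effects holds the realized
    per-day log2 effect of every guide in each condition (controls and
    neutral guides are exactly 0).
    """

    gene_classes: pd.Series  # gene -> class
    effects: pd.DataFrame  # guide_id x {"2D", "3D"}

    def genes_of(self, cls: str) -> list[str]:
        return list(self.gene_classes.index[self.gene_classes == cls])

    def write_tsv(self, genes_path: str | Path, effects_path: str | Path) -> None:
        gf = self.gene_classes.rename("class").rename_axis("gene").reset_index()
        gf.to_csv(genes_path, sep="\t", index=False, lineterminator="\n")
        ef = self.effects.reset_index(names="guide_id")
        ef.to_csv(effects_path, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def read_tsv(cls, genes_path: str | Path, effects_path: str | Path) -> "SimTruth":
        gf = pd.read_csv(genes_path, sep="\t").set_index("gene")["class"]
        ef = pd.read_csv(effects_path, sep="\t").set_index("guide_id")
        return cls(gf, ef)


def _unique_spacers(rng: np.random.Generator, n: int, length: int = 18) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        block = rng.integers(0, 4, size=(n - len(out) + 16, length))
        for row in block:
            s = "".join(_BASES[row])
            if s not in seen:
                seen.add(s)
                out.append(s)
                if len(out) == n:
                    break
    return out


def simulate_library(config: SimConfig) -> tuple[GuideLibrary, SimTruth]:
    """Build a synthetic guide library and its ground-truth ledger."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    classes = (
        [("NEUT", "neutral")] * config.n_neutral
        + [("ESSC", "common_essential")] * config.n_common_essential
        + [("ESS2D", "essential_2D")] * config.n_2d_essential
        + [("ESS3D", "essential_3D")] * config.n_3d_essential
    )
    genes: list[tuple[str, str]] = []
    counters: dict[str, int] = {}
    for prefix, cls in classes:
        counters[prefix] = counters.get(prefix, 0) + 1
        genes.append((f"{prefix}{counters[prefix]:04d}", cls))

    n_targeting = len(genes) * config.guides_per_gene
    total = n_targeting + config.n_safe + config.n_nontargeting
    if total < 1:
        raise ValueError("library would contain no guides")
    spacers = iter(_unique_spacers(rng, total))

    records: list[GuideRecord] = []
    eff_rows: dict[str, dict[str, float]] = {}
    for gene, cls in genes:
        for j in range(1, config.guides_per_gene + 1):
            gid = f"{gene}_g{j:02d}"
            records.append(GuideRecord(gid, gene, next(spacers), Category.TARGETING))
            if cls == "neutral":
                f = 0.0
            else:
                f = min(0.0, rng.normal(config.effect, config.effect_sd))
            eff_rows[gid] = {
                "2D": f if cls in ("common_essential", "essential_2D") else 0.0,
                "3D": f if cls in ("common_essential", "essential_3D") else 0.0,
            }
    for i in range(1, config.n_safe + 1):
        gid = f"safe_{i:04d}"
        records.append(GuideRecord(gid, CONTROL_GENE, next(spacers), Category.SAFE))
        eff_rows[gid] = {"2D": 0.0, "3D": 0.0}
    for i in range(1, config.n_nontargeting + 1):
        gid = f"nt_{i:04d}"
        records.append(
            GuideRecord(gid, CONTROL_GENE, next(spacers), Category.NON_TARGETING)
        )
        eff_rows[gid] = {"2D": 0.0, "3D": 0.0}

    library = GuideLibrary(records)
    truth = SimTruth(
        gene_classes=pd.Series(dict(genes), name="class"),
        effects=pd.DataFrame.from_dict(eff_rows, orient="index").loc[
            library.guide_ids
        ],
    )
    return library, truth


def make_design(config: SimConfig) -> ScreenDesign:
    """Sample sheet implied by a simulator config."""
    samples = [
        SampleInfo(f"{cond.value}_D{day}_R{rep}", cond, day, rep)
        for cond in (Condition.TWO_D, Condition.THREE_D)
        for day in config.days
        for rep in range(1, config.replicates + 1)
    ]
    return ScreenDesign(samples)


def simulate_screen(
    library: GuideLibrary, truth: SimTruth, config: SimConfig
) -> tuple[CountMatrix, ScreenDesign]:
    """Draw read counts for every sample of the design.

    Deterministic given ``config.seed``.  Within each sample, expected
    relative abundances are renormalized to sum to 1 before sampling.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    design = make_design(config)
    n = len(library)
    guide_ids = library.guide_ids

    a = rng.lognormal(mean=0.0, sigma=0.25, size=n)
    p0 = a / a.sum()
    if config.dispersion > 0:
        amp = rng.gamma(1.0 / config.dispersion, config.dispersion, size=n)
    else:
        amp = np.ones(n)

    cols: dict[str, np.ndarray] = {}
    for cond in (Condition.TWO_D, Condition.THREE_D):
        f = truth.effects[cond.value].loc[guide_ids].to_numpy(dtype=float)
        for rep in range(1, config.replicates + 1):
            cells = rng.multinomial(config.coverage * n, p0).astype(float)
            for day in config.days:
                w = cells * np.exp2(f * day)
                p = w / w.sum()
                mu = config.depth * n * p * amp
                sample_id = f"{cond.value}_D{day}_R{rep}"
                cols[sample_id] = rng.poisson(mu)

    frame = pd.DataFrame(cols, index=guide_ids)
    return CountMatrix(frame, library=library, design=design), design


def write_fastq(
    counts: pd.Series,
    library: GuideLibrary,
    path: str | Path,
    offset: int = 10,
    read_length: int | None = None,
    jitter: int = 0,
    seed: int = 0,
) -> int:
    """Emit exactly ``counts[g]`` reads containing each guide's spacer.

    The spacer is embedded at ``offset`` (plus a per-read uniform shift
    in [-jitter, jitter] when ``jitter`` > 0) within random flanking
    sequence.  Gzipped when the path ends in ``.gz``.  Returns the
    number of reads written.
    """
    rng = np.random.default_rng(seed)
    if read_length is None:
        read_length = offset + jitter + 18 + 5
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    written = 0
    with opener(path, "wt") as fh:
        for rec in library.records:
            c = int(counts.get(rec.guide_id, 0))
            for k in range(c):
                shift = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
                start = max(0, offset + shift)
                flank = "".join(_BASES[rng.integers(0, 4, size=read_length)])
                seq = flank[:start] + rec.spacer + flank[start + len(rec.spacer):]
                seq = seq[:read_length]
                written += 1
                fh.write(f"@{rec.guide_id}_{k}\n{seq}\n+\n{'I' * len(seq)}\n")
    return written


@dataclass
class RecoveryMetrics:
    """Truth-vs-called confusion and per-class recovery rates."""

    confusion: pd.DataFrame  # truth class x assigned label
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    precision: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "confusion": {
                cls: self.confusion.loc[cls].to_dict()
                for cls in self.confusion.index
            },
        }


def evaluate_recovery(labels: pd.Series, truth: SimTruth) -> RecoveryMetrics:
    """Score an exclusivity partition against the simulator's ledger.

    ``labels`` maps gene -> partition label.  For each truth class the
    expected label is given by :data:`EXPECTED_LABEL`; sensitivity is
    the fraction of the class receiving it, specificity the fraction of
    out-of-class genes not receiving it, precision the fraction of
    genes with the label that belong to the class.
    """
    common = truth.gene_classes.index.intersection(labels.index)
    tc = truth.gene_classes.loc[common]
    lab = labels.loc[common].astype(str)

    label_values = sorted(set(lab) | set(EXPECTED_LABEL.values()))
    confusion = pd.DataFrame(
        0, index=sorted(set(tc)), columns=label_values, dtype=int
    )
    for cls, label in zip(tc, lab):
        confusion.loc[cls, label] += 1
    confusion.index.name = "truth_class"

    sens, spec, prec = {}, {}, {}
    for cls, expected in EXPECTED_LABEL.items():
        in_cls = tc == cls
        got = lab == expected
        sens[cls] = float((in_cls & got).sum() / in_cls.sum()) if in_cls.any() else float("nan")
        spec[cls] = (
            float((~in_cls & ~got).sum() / (~in_cls).sum())
            if (~in_cls).any()
            else float("nan")
        )
        prec[cls] = float((in_cls & got).sum() / got.sum()) if got.any() else float("nan")
    return RecoveryMetrics(confusion, sens, spec, prec)


# -- annotation fixtures for the prioritization cascade ------------------

def simulate_annotations(
    n_candidates: int = 85,
    n_pathway_pass: int = 24,
    n_survival_pass: int = 11,
    n_pathways: int = 20,
    min_count: int = 9,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame, pd.DataFrame]:
    """Construct annotation tables with an exact prioritization funnel.

    Returns (candidates, pathway membership matrix, survival table)
    built so that exactly ``n_pathway_pass`` candidates sit in at least
    ``min_count`` of the ``n_pathways`` ranked pathways and exactly
    ``n_survival_pass`` of those additionally have hazard ratio > 1 at
    p < 0.05.
    """
    if not n_survival_pass <= n_pathway_pass <= n_candidates:
        raise ValueError("need n_survival_pass <= n_pathway_pass <= n_candidates")
    rng = np.random.default_rng(seed)
    candidates = [f"CAND{i:03d}" for i in range(1, n_candidates + 1)]
    order = rng.permutation(n_candidates)
    pathway_pass = {candidates[i] for i in order[:n_pathway_pass]}
    survival_pass = {candidates[i] for i in order[:n_survival_pass]}

    pathways = [f"PW{j:02d}" for j in range(1, n_pathways + 1)]
    rows = np.zeros((n_candidates, n_pathways), dtype=int)
    for i, gene in enumerate(candidates):
        if gene in pathway_pass:
            k = int(rng.integers(min_count, n_pathways + 1))
        else:
            k = int(rng.integers(0, min_count))
        rows[i, rng.choice(n_pathways, size=k, replace=False)] = 1
    membership = pd.DataFrame(rows, index=candidates, columns=pathways)
    membership.index.name = "gene"

    hr = np.empty(n_candidates)
    p = np.empty(n_candidates)
    for i, gene in enumerate(candidates):
        if gene in survival_pass:
            hr[i] = rng.uniform(1.2, 3.0)
            p[i] = rng.uniform(0.001, 0.04)
        elif rng.random() < 0.5:
            hr[i] = rng.uniform(0.3, 0.95)  # protective
            p[i] = rng.uniform(0.001, 0.04)
        else:
            hr[i] = rng.uniform(1.05, 2.5)  # risk but not significant
            p[i] = rng.uniform(0.05, 0.9)
    survival = pd.DataFrame({"hr": hr, "p": p}, index=candidates)
    survival.index.name = "gene"
    return candidates, membership, survival


def simulate_expression(
    n_samples: int = 200,
    target_genes: Sequence[str] = ("GENE_X",),
    rho: float = 0.6,
    signature: Sequence[str] | None = None,
    signature_noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Expression cohort with a latent proliferation factor.

    Every signature gene tracks a per-sample latent factor z ~ N(0, 1)
    plus independent noise; each target gene is built to correlate with
    z at the requested ``rho``.  Returns a sample x gene DataFrame
    covering the signature plus the targets.
    """
    from .prioritize import PROLIFERATION_SIGNATURE

    if signature is None:
        signature = PROLIFERATION_SIGNATURE
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n_samples)
    data = {
        g: z + rng.normal(scale=signature_noise_sd, size=n_samples)
        for g in signature
    }
    for g in target_genes:
        data[g] = rho * z + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(
            size=n_samples
        )
    df = pd.DataFrame(data, index=[f"S{i:04d}" for i in range(1, n_samples + 1)])
    df.index.name = "sample"
    return df
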