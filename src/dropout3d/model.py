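"""Model/Results interface over the screen-scoring pipeline.

:class:`ScreenModel` bundles the three inputs of a screen (count
matrix, guide library, sample sheet) with the scoring options;
``fit()`` runs normalization, enrichment and phenotype scoring for
every computable comparison and returns a :class:`ScreenResults`
carrying the per-guide and per-gene tables, control summaries, a
``summary()`` text report, dropout calling and TSV export.

    model = ScreenModel.from_tables("counts.tsv", "library.tsv", "samples.tsv")
    res = model.fit()
    print(res.summary())
    calls = res.call_dropouts()
    calls.label_counts()
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .calling import CallConfig, Label, call_dropouts, exclusivity_partition, upset_membership
from .phenotype import ComparisonPhenotypes, screen_phenotypes
from .screen import (
    CountMatrix,
    GuideLibrary,
    ScreenDesign,
    read_counts,
    read_guide_library,
    read_sample_sheet,
    validate_design,
)

__all__ = ["ScreenModel", "ScreenResults", "DropoutCalls"]


class ScreenModel:
    """A 2D-vs-3D pooled dropout screen ready to be scored.

    Parameters mirror the scoring pipeline: ``pseudocount`` guards zero
    counts in the log2 ratio, ``paired`` matches endpoint and baseline
    replicates by replicate number, ``welch`` switches the phenotype
    score denominator to the conventional Welch form, and
    ``drop_threshold`` is the per-guide pZ value at or below which a
    guide counts as dropped out.
    """

    def __init__(
        self,
        counts: CountMatrix,
        library: GuideLibrary,
        design: ScreenDesign,
        pseudocount: float = 0.5,
        paired: bool = True,
        welch: bool = False,
        drop_threshold: float = -0.1,
        size_factor_method: str = "median_ratio",
        min_eligible: int = 100,
    ):
        self.counts = counts
        self.library = library
        self.design = design
        self.pseudocount = pseudocount
        self.paired = paired
        self.welch = welch
        self.drop_threshold = drop_threshold
        self.size_factor_method = size_factor_method
        self.min_eligible = min_eligible

    @classmethod
    def from_tables(
        cls,
        counts_path: str | Path,
        library_path: str | Path,
        samples_path: str | Path,
        **kwargs,
    ) -> "ScreenModel":
        """Build a model from the three standard TSV inputs."""
        library = read_guide_library(library_path)
        design = read_sample_sheet(samples_path)
        counts = read_counts(counts_path, library=library, design=design)
        return cls(counts, library, design, **kwargs)

    def validation_report(self):
        return validate_design(self.design, self.counts)

    def fit(self) -> "ScreenResults":
        """Score every computable comparison and return the results."""
        phenotypes = screen_phenotypes(
            self.counts,
            self.library,
            self.design,
            pseudocount=self.pseudocount,
            paired=self.paired,
            welch=self.welch,
            drop_threshold=self.drop_threshold,
            size_factor_method=self.size_factor_method,
            min_eligible=self.min_eligible,
        )
        return ScreenResults(self, phenotypes)


@dataclass
class DropoutCalls:
    """Called-gene sets per comparison plus the exclusivity partition."""

    config: CallConfig
    sets: dict[str, set[str]]
    partition: pd.Series  # gene -> label over the targeting-gene universe
    membership: pd.DataFrame
    intersection_counts: pd.Series

    def label_counts(self) -> dict[str, int]:
        counts = self.partition.value_counts()
        return {label.value: int(counts.get(label.value, 0)) for label in Label}

    def genes(self, label: Label | str) -> list[str]:
        value = Label(label).value if not isinstance(label, Label) else label.value
        return sorted(self.partition.index[self.partition == value])


class ScreenResults:
    """Fitted screen: per-comparison scores and downstream calling."""

    def __init__(
        self, model: ScreenModel, phenotypes: dict[str, ComparisonPhenotypes]
    ):
        self.model = model
        self.phenotypes = phenotypes

    @property
    def comparisons(self) -> list[str]:
        return list(self.phenotypes)

    def guide_effects(self, label: str) -> pd.DataFrame:
        """log2fe, per-replicate log2fe and pZ for one comparison."""
        return self.phenotypes[label].guide_frame

    def gene_table(self, label: str) -> pd.DataFrame:
        """n_exp, u_gene, var_gene, n_dropped and t_score per gene."""
        return self.phenotypes[label].genes

    def control_summary(self, label: str):
        return self.phenotypes[label].control

    def controls_frame(self) -> pd.DataFrame:
        rows = []
        for label, phen in self.phenotypes.items():
            c = phen.control
            rows.append(
                {
                    "comparison": label,
                    "u_ctrl": c.u_ctrl,
                    "var_ctrl": c.var_ctrl,
                    "n_ctrl": c.n_ctrl,
                    "n_control_guides": c.n_control_guides,
                }
            )
        return pd.DataFrame(rows)

    def call_dropouts(
        self, config: CallConfig | None = None, both_days: bool = True
    ) -> DropoutCalls:
        """Call dropout genes per comparison and partition by exclusivity."""
        config = config or CallConfig(guide_drop_max=self.model.drop_threshold)
        sets = {
            label: call_dropouts(phen, config)
            for label, phen in self.phenotypes.items()
        }
        universe = set(self.model.library.genes)
        partition = exclusivity_partition(sets, universe, both_days=both_days)
        membership, counts = upset_membership(sets)
        return DropoutCalls(config, sets, partition, membership, counts)

    def summary(self) -> str:
        """Human-readable overview, one block per comparison."""
        lines = [
            "Pooled CRISPR dropout screen — phenotype scoring",
            "=" * 52,
            f"guides: {len(self.model.library)}  "
            f"(targeting {len(self.model.library.targeting_ids)}, "
            f"controls {len(self.model.library.control_ids)})",
            f"genes: {len(self.model.library.genes)}   "
            f"samples: {len(self.model.design)}",
            f"pseudocount: {self.model.pseudocount}   paired: {self.model.paired}"
            f"   welch: {self.model.welch}",
            "",
        ]
        header = (
            f"{'comparison':<16}{'n_genes':>8}{'u_ctrl':>9}{'var_ctrl':>10}"
            f"{'n_ctrl':>8}{'med u':>9}{'med T':>9}"
        )
        lines += [header, "-" * len(header)]
        for label, phen in self.phenotypes.items():
            c = phen.control
            lines.append(
                f"{label:<16}{len(phen.genes):>8d}{c.u_ctrl:>9.3f}"
                f"{c.var_ctrl:>10.4f}{c.n_ctrl:>8.2f}"
                f"{phen.genes['u_gene'].median():>9.3f}"
                f"{phen.genes['t_score'].median():>9.3f}"
            )
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        """Write per-comparison guide/gene tables and the control summary."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for label, phen in self.phenotypes.items():
            phen.guide_frame.reset_index(names="guide_id").to_csv(
                outdir / f"guides_{label}.tsv",
                sep="\t",
                index=False,
                lineterminator="\n",
            )
            phen.genes.reset_index().to_csv(
                outdir / f"genes_{label}.tsv",
                sep="\t",
                index=False,
                lineterminator="\n",
            )
        self.controls_frame().to_csv(
            outdir / "controls.tsv", sep="\t", index=False, lineterminator="\n"
        )
        (outdir / "summary.txt").write_text(self.summary() + "\n")

    def run_report(self) -> dict:
        """Machine-readable per-stage summary for pipeline logs."""
        return {
            "n_guides": len(self.model.library),
            "n_genes": len(self.model.library.genes),
            "n_samples": len(self.model.design),
            "comparisons": {
                label: {
                    "n_genes_scored": int(len(phen.genes)),
                    "u_ctrl": phen.control.u_ctrl,
                    "var_ctrl": phen.control.var_ctrl,
                    "n_ctrl": phen.control.n_ctrl,
                }
                for label, phen in self.phenotypes.items()
            },
            "parameters": {
                "pseudocount": self.model.pseudocount,
                "paired": self.model.paired,
                "welch": self.model.welch,
                "drop_threshold": self.model.drop_threshold,
                "size_factor_method": self.model.size_factor_method,
            },
        }

    def save_run_report(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.run_report(), indent=2) + "\n")
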