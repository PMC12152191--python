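"""Domain types and TSV readers/writers for pooled-screen inputs.

A screen is described by three tables:

* a **guide library** mapping each sgRNA to its target gene, spacer
  sequence (17-18 nt) and category (``targeting`` or one of the two
  negative-control classes, ``safe`` / ``non_targeting``);
* a **sample sheet** assigning every sequenced sample a growth condition
  (2D monolayer vs 3D suspension), a collection day and a replicate
  number;
* a **count matrix** of integer read counts, one row per guide and one
  column per sample.

All tables are plain TSV: tab separated, mandatory header row, UTF-8,
no quoting, LF line endings.  Control guides carry the reserved gene
sentinel ``"CONTROL"`` so they can never be confused with a gene symbol.
"""

from __future__ import annotations

import enum
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONTROL_GENE",
    "Category",
    "Condition",
    "GuideRecord",
    "GuideLibrary",
    "SampleInfo",
    "ScreenDesign",
    "Comparison",
    "CountMatrix",
    "DesignReport",
    "LibraryError",
    "DesignError",
    "CountsError",
    "read_guide_library",
    "read_sample_sheet",
    "read_counts",
    "validate_design",
]

#: Reserved gene value carried by every control (safe / non-targeting) guide.
CONTROL_GENE = "CONTROL"

_SPACER_RE = re.compile(r"^[ACGT]{17,18}$")


class LibraryError(ValueError):
    """Raised when a guide library violates its invariants."""


class DesignError(ValueError):
    """Raised when a sample sheet violates its invariants."""


class CountsError(ValueError):
    """Raised when a count table is malformed or inconsistent."""


class Category(str, enum.Enum):
    """sgRNA category: gene-targeting or one of two negative-control classes."""

    TARGETING = "targeting"
    SAFE = "safe"
    NON_TARGETING = "non_targeting"

    @property
    def is_control(self) -> bool:
        return self is not Category.TARGETING


class Condition(str, enum.Enum):
    """Growth condition of a sample."""

    TWO_D = "2D"
    THREE_D = "3D"


@dataclass(frozen=True)
class GuideRecord:
    """A single sgRNA: identifier, target gene, spacer and category."""

    guide_id: str
    gene: str
    spacer: str
    category: Category

    def __post_init__(self) -> None:
        object.__setattr__(self, "spacer", self.spacer.upper())
        object.__setattr__(self, "category", Category(self.category))
        if not _SPACER_RE.match(self.spacer):
            raise LibraryError(
                f"guide {self.guide_id!r}: spacer {self.spacer!r} must be "
                "17-18 nt of A/C/G/T"
            )
        if self.category.is_control and self.gene != CONTROL_GENE:
            raise LibraryError(
                f"guide {self.guide_id!r}: category {self.category.value!r} "
                f"requires gene sentinel {CONTROL_GENE!r}, got {self.gene!r}"
            )
        if not self.category.is_control and self.gene == CONTROL_GENE:
            raise LibraryError(
                f"guide {self.guide_id!r}: targeting guides may not use the "
                f"{CONTROL_GENE!r} sentinel"
            )


class GuideLibrary:
    """An ordered, validated collection of :class:`GuideRecord`.

    Guide ids and spacers are unique across the whole library; the
    control set is the union of the ``safe`` and ``non_targeting``
    categories.  Load order is preserved and defines the canonical row
    order of every downstream table.
    """

    def __init__(self, records: Iterable[GuideRecord]):
        self.records: list[GuideRecord] = list(records)
        if not self.records:
            raise LibraryError("library has no records")
        self._check_unique()
        self._by_id = {r.guide_id: r for r in self.records}
        self.index: dict[str, list[str]] = {}
        for r in self.records:
            if not r.category.is_control:
                self.index.setdefault(r.gene, []).append(r.guide_id)

    def _check_unique(self) -> None:
        seen_id: dict[str, str] = {}
        seen_spacer: dict[str, str] = {}
        for r in self.records:
            if r.guide_id in seen_id:
                raise LibraryError(f"duplicate guide_id {r.guide_id!r}")
            seen_id[r.guide_id] = r.guide_id
            if r.spacer in seen_spacer:
                raise LibraryError(
                    f"duplicate spacer {r.spacer!r} shared by guides "
                    f"{seen_spacer[r.spacer]!r} and {r.guide_id!r}"
                )
            seen_spacer[r.spacer] = r.guide_id

    # -- queries ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, guide_id: str) -> bool:
        return guide_id in self._by_id

    def __getitem__(self, guide_id: str) -> GuideRecord:
        return self._by_id[guide_id]

    @property
    def guide_ids(self) -> list[str]:
        return [r.guide_id for r in self.records]

    @property
    def genes(self) -> list[str]:
        """Targeting genes, in first-appearance order."""
        return list(self.index)

    @property
    def targeting_ids(self) -> list[str]:
        return [r.guide_id for r in self.records if not r.category.is_control]

    @property
    def control_ids(self) -> list[str]:
        """Guide ids of the control set (safe ∪ non-targeting)."""
        return [r.guide_id for r in self.records if r.category.is_control]

    def guides_for(self, gene: str) -> list[str]:
        return list(self.index[gene])

    def category_counts(self) -> dict[str, int]:
        out = {c.value: 0 for c in Category}
        for r in self.records:
            out[r.category.value] += 1
        return out

    def gene_of(self) -> pd.Series:
        """guide_id -> gene mapping as a Series (controls map to the sentinel)."""
        return pd.Series(
            {r.guide_id: r.gene for r in self.records}, name="gene"
        )

    # -- IO --------------------------------------------------------------
    @classmethod
    def read_tsv(cls, path: str | Path) -> "GuideLibrary":
        df = _read_tsv(path)
        required = ["guide_id", "gene", "spacer", "category"]
        _require_columns(df, required, path, LibraryError)
        records = []
        for row in df.itertuples(index=False):
            try:
                cat = Category(row.category)
            except ValueError:
                raise LibraryError(
                    f"{path}: guide {row.guide_id!r} has unknown category "
                    f"{row.category!r}"
                ) from None
            records.append(
                GuideRecord(str(row.guide_id), str(row.gene), str(row.spacer), cat)
            )
        return cls(records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "guide_id": [r.guide_id for r in self.records],
                "gene": [r.gene for r in self.records],
                "spacer": [r.spacer for r in self.records],
                "category": [r.category.value for r in self.records],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        _write_tsv(self.to_frame(), path)


@dataclass(frozen=True)
class SampleInfo:
    """One sequenced sample of the screen."""

    sample_id: str
    condition: Condition
    day: int
    replicate: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition", Condition(self.condition))
        if self.day not in (0, 7, 14):
            raise DesignError(
                f"sample {self.sample_id!r}: day must be 0, 7 or 14, got {self.day}"
            )
        if self.replicate < 1:
            raise DesignError(
                f"sample {self.sample_id!r}: replicate must be >= 1"
            )


@dataclass(frozen=True)
class Comparison:
    """An endpoint-vs-baseline contrast within one growth condition."""

    condition: Condition
    day: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition", Condition(self.condition))
        if self.day not in (7, 14):
            raise DesignError(f"comparison day must be 7 or 14, got {self.day}")

    @property
    def label(self) -> str:
        return f"{self.condition.value}_D{self.day}_vs_D0"

    @classmethod
    def from_label(cls, label: str) -> "Comparison":
        m = re.match(r"^(2D|3D)_D(7|14)_vs_D0$", label)
        if not m:
            raise DesignError(f"unrecognized comparison label {label!r}")
        return cls(Condition(m.group(1)), int(m.group(2)))


class ScreenDesign:
    """The sample sheet: samples keyed by (condition, day, replicate)."""

    def __init__(self, samples: Iterable[SampleInfo], baseline_day: int = 0):
        self.samples: list[SampleInfo] = list(samples)
        self.baseline_day = baseline_day
        seen_key: set[tuple] = set()
        seen_id: set[str] = set()
        for s in self.samples:
            if s.sample_id in seen_id:
                raise DesignError(f"duplicate sample_id {s.sample_id!r}")
            seen_id.add(s.sample_id)
            key = (s.condition, s.day, s.replicate)
            if key in seen_key:
                raise DesignError(
                    f"duplicate (condition, day, replicate) = "
                    f"({s.condition.value}, {s.day}, {s.replicate})"
                )
            seen_key.add(key)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def samples_for(self, condition: Condition, day: int) -> list[SampleInfo]:
        condition = Condition(condition)
        return [
            s for s in self.samples if s.condition is condition and s.day == day
        ]

    def possible_comparisons(self) -> list[Comparison]:
        """All four endpoint-vs-baseline contrasts of the full design."""
        return [
            Comparison(cond, day)
            for cond in (Condition.TWO_D, Condition.THREE_D)
            for day in (7, 14)
        ]

    # -- IO --------------------------------------------------------------
    @classmethod
    def read_tsv(cls, path: str | Path) -> "ScreenDesign":
        df = _read_tsv(path)
        _require_columns(
            df, ["sample_id", "condition", "day", "replicate"], path, DesignError
        )
        samples = []
        for row in df.itertuples(index=False):
            try:
                cond = Condition(str(row.condition))
            except ValueError:
                raise DesignError(
                    f"{path}: sample {row.sample_id!r} has unknown condition "
                    f"{row.condition!r} (expected 2D or 3D)"
                ) from None
            samples.append(
                SampleInfo(str(row.sample_id), cond, int(row.day), int(row.replicate))
            )
        return cls(samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "condition": [s.condition.value for s in self.samples],
                "day": [s.day for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        _write_tsv(self.to_frame(), path)


class CountMatrix:
    """Integer read counts, guides x samples, aligned to a library order.

    Wraps a :class:`pandas.DataFrame` (``.frame``) whose index is
    guide_id in library order and whose columns are sample ids.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        library: GuideLibrary | None = None,
        design: ScreenDesign | None = None,
    ):
        frame = frame.copy()
        vals = frame.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise CountsError("count matrix must be numeric")
        if np.any(vals < 0):
            g, s = np.argwhere(vals < 0)[0]
            raise CountsError(
                f"negative count at guide {frame.index[g]!r}, "
                f"sample {frame.columns[s]!r}"
            )
        if np.any(vals != np.floor(vals)):
            g, s = np.argwhere(vals != np.floor(vals))[0]
            raise CountsError(
                f"non-integer count {vals[g, s]!r} at guide "
                f"{frame.index[g]!r}, sample {frame.columns[s]!r}"
            )
        frame = frame.astype(np.int64)
        if library is not None:
            extra = frame.index.difference(library.guide_ids)
            if len(extra):
                raise CountsError(
                    f"guides not in library: {sorted(extra)[:5]}"
                    + ("..." if len(extra) > 5 else "")
                )
            missing = pd.Index(library.guide_ids).difference(frame.index)
            if len(missing):
                raise CountsError(
                    f"{len(missing)} library guides missing from counts, "
                    f"e.g. {sorted(missing)[:5]}"
                )
            frame = frame.loc[library.guide_ids]
        if design is not None:
            unknown = frame.columns.difference(design.sample_ids)
            if len(unknown):
                raise CountsError(
                    f"sample columns absent from design: {sorted(unknown)}"
                )
        self.frame = frame
        self.library = library
        self.design = design

    @property
    def guide_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.columns)

    def column(self, sample_id: str) -> pd.Series:
        return self.frame[sample_id]

    def write_tsv(self, path: str | Path) -> None:
        _write_tsv(self.frame.reset_index(names="guide_id"), path)


def read_guide_library(path: str | Path) -> GuideLibrary:
    """Read and validate a guide-library TSV."""
    return GuideLibrary.read_tsv(path)


def read_sample_sheet(path: str | Path) -> ScreenDesign:
    """Read and validate a sample-sheet TSV."""
    return ScreenDesign.read_tsv(path)


def read_counts(
    path: str | Path,
    library: GuideLibrary | None = None,
    design: ScreenDesign | None = None,
    zero_fill_missing: bool = False,
) -> CountMatrix:
    """Read a guide x sample count TSV aligned against ``library``.

    Guides present in the library but absent from the file are an error
    unless ``zero_fill_missing`` is set; guides absent from the library
    are always an error.  Non-integer or negative cells are reported
    with their (guide, sample) location.
    """
    df = _read_tsv(path)
    if df.columns[0] != "guide_id":
        raise CountsError(f"{path}: first column must be 'guide_id'")
    df = df.set_index("guide_id")
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise CountsError(f"{path}: non-numeric value in column {col!r}: {exc}")
    if zero_fill_missing and library is not None:
        missing = pd.Index(library.guide_ids).difference(df.index)
        if len(missing):
            fill = pd.DataFrame(0, index=missing, columns=df.columns)
            df = pd.concat([df, fill])
    return CountMatrix(df, library=library, design=design)


@dataclass
class DesignReport:
    """Report-only summary of which comparisons a design supports."""

    computable: list[Comparison]
    replicate_counts: dict[tuple[str, int], int]
    warnings: list[str] = field(default_factory=list)

    @property
    def n_computable(self) -> int:
        return len(self.computable)


def validate_design(
    design: ScreenDesign, counts: CountMatrix | None = None
) -> DesignReport:
    """List the computable comparisons and replicate counts of a design.

    A comparison is computable when the design (and the count matrix, if
    given) contains at least one baseline sample and one endpoint sample
    for its condition.
    """
    have = set(counts.sample_ids) if counts is not None else None

    def present(samples: Sequence[SampleInfo]) -> list[SampleInfo]:
        if have is None:
            return list(samples)
        return [s for s in samples if s.sample_id in have]

    computable: list[Comparison] = []
    warnings: list[str] = []
    rep_counts: dict[tuple[str, int], int] = {}
    for cond in (Condition.TWO_D, Condition.THREE_D):
        for day in (0, 7, 14):
            n = len(present(design.samples_for(cond, day)))
            if n:
                rep_counts[(cond.value, day)] = n
    for comp in design.possible_comparisons():
        base = present(design.samples_for(comp.condition, design.baseline_day))
        end = present(design.samples_for(comp.condition, comp.day))
        if base and end:
            computable.append(comp)
        else:
            missing = "baseline" if not base else "endpoint"
            warnings.append(f"{comp.label}: no {missing} samples")
    return DesignReport(computable, rep_counts, warnings)


# -- TSV helpers (fixed dialect: tab, header, UTF-8, no quoting, LF) -----

def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, lineterminator="\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8", newline="\n")


def _require_columns(df: pd.DataFrame, cols, path, err) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise err(f"{path}: missing required column(s) {missing}")
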