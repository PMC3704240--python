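"""Data model and I/O for mutation-accumulation fitness-trait tables.

The universal currency between analysis stages is a long-format table of
replicate-level trait measurements with columns

    line_id, group, trait, block, replicate, value

where ``group`` is one of ``ancestor``, ``control``, ``MA``.  Values are on
the native measurement scale at ingestion (doublings, mm, counts, proportion,
index) and are converted to relative fitness — each value divided by the
ancestor mean for its trait — before any mutational inference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The eight fitness components scored in the experiment.
TRAITS = (
    "plate_growth",
    "liquid_growth",
    "slug_distance",
    "total_fbs",
    "spores_per_fb",
    "total_spores",
    "spore_germination",
    "competitive_ability",
)

GROUPS = ("ancestor", "control", "MA")

#: Native measurement units per trait.
DEFAULT_UNITS = {
    "plate_growth": "doublings/48h",
    "liquid_growth": "doublings/24h",
    "slug_distance": "mm",
    "total_fbs": "count",
    "spores_per_fb": "count",
    "total_spores": "count",
    "spore_germination": "proportion",
    "competitive_ability": "index",
}

REQUIRED_COLUMNS = ["line_id", "group", "trait", "block", "replicate", "value"]


class FitnessTableError(ValueError):
    """Raised for malformed or inconsistent fitness tables."""


@dataclass(frozen=True)
class FitnessRecord:
    """One replicate-level measurement of one trait on one line."""

    line_id: str
    group: str
    trait: str
    replicate: int
    value: float
    block: int | None = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise FitnessTableError(f"unknown group {self.group!r}")
        if self.trait not in TRAITS:
            raise FitnessTableError(f"unknown trait {self.trait!r}")
        if not math.isfinite(self.value):
            raise FitnessTableError(f"non-finite value for {self.line_id}/{self.trait}")
        if self.trait == "spore_germination" and not 0.0 <= self.value:
            raise FitnessTableError("spore_germination proportion must be >= 0")


@dataclass(frozen=True)
class GroupSummary:
    """Sample mean and variance (divisor n-1) of one group for one trait.

    MA and control groups are summarized over line means (replicates averaged
    within each line first); the ancestor is summarized over its replicates.
    ``variance`` is ``None`` when fewer than two values are available, never
    reported as zero by imputation.
    """

    trait: str
    group: str
    n: int
    mean: float
    variance: float | None

    @property
    def sd(self) -> float | None:
        return None if self.variance is None else math.sqrt(self.variance)


@dataclass
class FitnessTable:
    """Long-format replicate-level trait measurements with group labels.

    Parameters
    ----------
    df : pandas.DataFrame
        Columns ``line_id, group, trait, block, replicate, value``.
    units : dict
        trait -> unit string.
    G : int
        Cell generations elapsed during the MA phase (default 994).
    """

    df: pd.DataFrame
    units: dict = field(default_factory=lambda: dict(DEFAULT_UNITS))
    G: int = 994

    def __post_init__(self):
        df = self.df.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise FitnessTableError(f"missing columns: {missing}")
        df["line_id"] = df["line_id"].astype(str)
        df["value"] = pd.to_numeric(df["value"], errors="coerce")
        bad_traits = set(df["trait"]) - set(TRAITS)
        if bad_traits:
            raise FitnessTableError(f"unknown traits: {sorted(bad_traits)}")
        bad_groups = set(df["group"]) - set(GROUPS)
        if bad_groups:
            raise FitnessTableError(f"unknown groups: {sorted(bad_groups)}")
        if not np.isfinite(df["value"].to_numpy(float)).all():
            raise FitnessTableError("non-finite values present")
        dup = df.duplicated(subset=["line_id", "trait", "block", "replicate"])
        if dup.any():
            rows = df.index[dup].tolist()[:5]
            raise FitnessTableError(
                f"duplicate (line_id, trait, block, replicate) at rows {rows}"
            )
        self.df = df.reset_index(drop=True)

    # -- basic introspection ------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def traits(self) -> list[str]:
        return [t for t in TRAITS if t in set(self.df["trait"])]

    def lines(self, group: str = "MA") -> list[str]:
        sel = self.df[self.df["group"] == group]
        return sorted(set(sel["line_id"]))

    @property
    def n_ma(self) -> int:
        return len(self.lines("MA"))

    @property
    def n_control(self) -> int:
        return len(self.lines("control"))

    def subset(self, trait: str) -> pd.DataFrame:
        if trait not in TRAITS:
            raise FitnessTableError(f"unknown trait {trait!r}")
        return self.df[self.df["trait"] == trait]

    def line_means(self, trait: str, group: str = "MA") -> pd.Series:
        """Per-line mean across replicates for one trait ("averaged across
        replicates when present")."""
        sel = self.subset(trait)
        sel = sel[sel["group"] == group]
        return sel.groupby("line_id")["value"].mean().sort_index()

    def ancestor_values(self, trait: str) -> np.ndarray:
        sel = self.subset(trait)
        return sel.loc[sel["group"] == "ancestor", "value"].to_numpy(float)

    def validate_ancestry(self) -> None:
        """Every MA/control trait must have ancestor replicates."""
        anc_traits = set(self.df.loc[self.df["group"] == "ancestor", "trait"])
        other = set(self.df.loc[self.df["group"] != "ancestor", "trait"])
        orphans = other - anc_traits
        if orphans:
            raise FitnessTableError(f"traits without ancestor replicates: {sorted(orphans)}")


# -- I/O --------------------------------------------------------------------


def read_fitness_table(path, schema: dict | None = None) -> FitnessTable:
    """Read a CSV/TSV fitness table.

    Rows with a missing/NA value are dropped (the number of drops is logged).
    ``schema`` may carry ``units`` (trait -> unit) and ``G``.
    """
    schema = schema or {}
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as exc:
        raise FitnessTableError(f"malformed CSV {path}: {exc}") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FitnessTableError(f"{path}: header missing columns {missing}")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    n_na = int(df["value"].isna().sum())
    if n_na:
        logger.info("read_fitness_table: dropped %d rows with missing values", n_na)
        df = df[df["value"].notna()]
    return FitnessTable(
        df=df,
        units=schema.get("units", dict(DEFAULT_UNITS)),
        G=int(schema.get("G", 994)),
    )


def write_fitness_table(table: FitnessTable, path) -> None:
    """Write the table as CSV with a stable column order and full precision."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    out = table.df[REQUIRED_COLUMNS]
    out.to_csv(path, sep=sep, index=False, float_format="%.17g")


# -- transformations --------------------------------------------------------


def plate_growth_doublings(cell_counts) -> np.ndarray:
    """Convert plaque cell counts to doublings per growth period,
    log2(cell number), assuming a single founding amoeba."""
    counts = np.asarray(cell_counts, float)
    if (counts <= 0).any():
        raise FitnessTableError("cell counts must be positive")
    return np.log2(counts)


def relative_fitness(
    table: FitnessTable,
    trait: str | None = None,
    per_block: bool = False,
) -> FitnessTable:
    """Divide every value by the ancestor mean for its trait.

    By default ancestor replicates are pooled across blocks before taking the
    mean (block effects having been ruled out beforehand); ``per_block=True``
    normalizes within blocks instead.  After the transform the ancestor mean
    for each trait equals 1 exactly (per block, under ``per_block=True``).
    """
    traits = [trait] if trait is not None else table.traits
    df = table.df.copy()
    for t in traits:
        mask = df["trait"] == t
        anc = df[mask & (df["group"] == "ancestor")]
        if anc.empty:
            raise FitnessTableError(f"no ancestor replicates for {t!r}")
        if per_block:
            for blk, sub in anc.groupby("block", dropna=False):
                m = sub["value"].mean()
                if m <= 0:
                    raise FitnessTableError(f"ancestor mean <= 0 for {t!r} block {blk}")
                bmask = mask & (df["block"].isna() if pd.isna(blk) else df["block"] == blk)
                df.loc[bmask, "value"] = df.loc[bmask, "value"] / m
        else:
            m = anc["value"].mean()
            if m <= 0:
                raise FitnessTableError(f"ancestor mean <= 0 for {t!r}")
            df.loc[mask, "value"] = df.loc[mask, "value"] / m
    units = dict(table.units)
    for t in traits:
        units[t] = "relative fitness"
    return FitnessTable(df=df, units=units, G=table.G)


def summarize(
    table: FitnessTable, trait: str, level: str = "line_mean"
) -> dict[str, GroupSummary]:
    """Group summaries (mean, sample variance) for one trait.

    ``level='line_mean'`` (default): MA/control summarized over per-line
    means, ancestor over its replicates.  ``level='replicate'``: every group
    summarized over raw replicate values.
    """
    if level not in ("line_mean", "replicate"):
        raise ValueError(f"unknown level {level!r}")
    out: dict[str, GroupSummary] = {}
    for group in GROUPS:
        if group == "ancestor" or level == "replicate":
            sel = table.subset(trait)
            vals = sel.loc[sel["group"] == group, "value"].to_numpy(float)
        else:
            vals = table.line_means(trait, group).to_numpy(float)
        if len(vals) == 0:
            continue
        var = float(np.var(vals, ddof=1)) if len(vals) >= 2 else None
        out[group] = GroupSummary(
            trait=trait, group=group, n=len(vals), mean=float(np.mean(vals)), variance=var
        )
    return out


def summary_from_values(values, trait: str = "spore_germination", group: str = "ancestor") -> GroupSummary:
    """Summary of a plain value vector (convenience for printed-count checks)."""
    vals = np.asarray(values, float)
    var = float(np.var(vals, ddof=1)) if len(vals) >= 2 else None
    return GroupSummary(trait=trait, group=group, n=len(vals), mean=float(np.mean(vals)), variance=var)
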