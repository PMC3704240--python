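"""Competitive-ability index from labeled-spore chimera assays.

A line is mixed ~1:1 with the ancestor (one strain dye-labeled), the mix is
starved to form chimeric fruiting bodies, and labeled cells (before
starvation) and labeled spores (after fruiting) are scored.  The index is
the ratio of spore ratios to initial cell ratios,

    C_line = (S_line / S_anc) / (N_line / N_anc),

so C > 1 marks a line over-represented in spores relative to its starting
share (a good competitor/cheater) and C < 1 a poor one.  Each line is
assayed in two reciprocal mixes (line labeled; ancestor labeled) and the
line-level index is their average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CompetitionAssay:
    """Counts from one competition mix."""

    line_id: str
    labeled_strain: str  # "line" or "ancestor"
    N_line: int  # initial cells attributed to the line
    N_anc: int
    S_line: int  # spores attributed to the line
    S_anc: int
    retention: float = 0.992  # labeled-spore dye retention fraction

    def __post_init__(self):
        if self.labeled_strain not in ("line", "ancestor"):
            raise ValueError(f"labeled_strain must be 'line' or 'ancestor'")
        for name in ("N_line", "N_anc", "S_line", "S_anc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.retention <= 1:
            raise ValueError("retention must be in (0, 1]")


def competition_index(assay: CompetitionAssay, correct_retention: bool = False) -> float | None:
    """Eq.-style ratio-of-ratios index for one mix.

    Returns ``None`` (undefined, not infinity) when the ancestor spore count
    is zero.  ``correct_retention=True`` divides the labeled strain's spore
    count by the dye-retention fraction before forming the ratio (off by
    default: the index is conventionally computed from raw counts).
    """
    if assay.N_anc <= 0:
        raise ValueError("N_anc must be positive")
    if assay.N_line <= 0:
        raise ValueError("N_line must be positive")
    s_line, s_anc = float(assay.S_line), float(assay.S_anc)
    if correct_retention:
        if assay.labeled_strain == "line":
            s_line = s_line / assay.retention
        else:
            s_anc = s_anc / assay.retention
    if s_anc == 0:
        return None
    return (s_line / s_anc) / (assay.N_line / assay.N_anc)


def aggregate_reciprocal(c_line_labeled: float | None, c_anc_labeled: float | None):
    """Line-level index: mean of the two reciprocal-mix indices.

    If one index is undefined the other is returned with ``coverage='single'``.

    Returns
    -------
    (index, coverage) : (float | None, str)
        coverage is "both", "single", or "none".
    """
    a, b = c_line_labeled, c_anc_labeled
    if a is not None and b is not None:
        return 0.5 * (a + b), "both"
    if a is not None:
        return a, "single"
    if b is not None:
        return b, "single"
    return None, "none"


def read_competition_assays(path, retention: float = 0.992) -> list[CompetitionAssay]:
    """Read assays from CSV with columns line_id, labeled_strain,
    n_cells_labeled, n_cells_total, n_spores_labeled, n_spores_total.

    Strain attribution is explicit: when the line is labeled, its cell/spore
    counts are the labeled counts and the ancestor's the remainder, and
    conversely when the ancestor carries the label.
    """
    df = pd.read_csv(path)
    required = [
        "line_id", "labeled_strain",
        "n_cells_labeled", "n_cells_total",
        "n_spores_labeled", "n_spores_total",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    assays = []
    for _, row in df.iterrows():
        cl, ct = int(row.n_cells_labeled), int(row.n_cells_total)
        sl, st = int(row.n_spores_labeled), int(row.n_spores_total)
        if row.labeled_strain == "line":
            nl, na, s_l, s_a = cl, ct - cl, sl, st - sl
        else:
            nl, na, s_l, s_a = ct - cl, cl, st - sl, sl
        assays.append(
            CompetitionAssay(
                line_id=str(row.line_id), labeled_strain=str(row.labeled_strain),
                N_line=nl, N_anc=na, S_line=s_l, S_anc=s_a, retention=retention,
            )
        )
    return assays


def assays_to_fitness_rows(assays: list[CompetitionAssay], group: str = "MA") -> pd.DataFrame:
    """Aggregate reciprocal mixes per line and emit FitnessTable-compatible
    rows for the competitive_ability trait (one replicate per reciprocal pair)."""
    rows = []
    by_line: dict[str, dict[str, list[float]]] = {}
    for a in assays:
        c = competition_index(a)
        by_line.setdefault(a.line_id, {}).setdefault(a.labeled_strain, []).append(c)
    for line_id, sides in sorted(by_line.items()):
        line_side = [c for c in sides.get("line", []) if c is not None]
        anc_side = [c for c in sides.get("ancestor", []) if c is not None]
        n_pairs = max(len(line_side), len(anc_side))
        for i in range(n_pairs):
            a = line_side[i] if i < len(line_side) else None
            b = anc_side[i] if i < len(anc_side) else None
            idx, coverage = aggregate_reciprocal(a, b)
            if idx is None:
                continue
            rows.append(
                dict(line_id=line_id, group=group, trait="competitive_ability",
                     block=np.nan, replicate=i, value=idx)
            )
    return pd.DataFrame(rows)
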