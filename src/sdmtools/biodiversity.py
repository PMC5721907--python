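"""Richness and endemism grids, CANAPE categorization, significance reclassification.

Richness, weighted endemism (WE) and corrected weighted endemism (CWE) are
computed from stacks of binary range grids (typically thresholded SDMs).
WE sums, over the species present in a cell, the inverse of each species'
range size in cells, so each species contributes exactly 1 across the
landscape; CWE divides WE by richness, isolating range-restriction from
mere species number.

CANAPE (categorical analysis of neo- and paleo-endemism) consumes
randomization exports produced externally (Biodiverse): per-cell observed
phylogenetic endemism (PE) on the original tree, PE on a comparison tree,
and relative PE (RPE), each with a rank-based p field giving the
proportion of randomizations in which the observed value exceeded the
random one.  Cells significant for PE are split into neo-endemic (short
branches: low RPE rank), paleo-endemic (long branches: high RPE rank),
mixed, and super (extremely significant for both PE measures).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import Grid

__all__ = ["BinaryStack", "RandomizationTable", "CANAPE_CATEGORIES",
           "CanapeThresholds", "richness", "weighted_endemism",
           "corrected_weighted_endemism", "canape_classify",
           "reclassify_significance", "stack_from_occurrences"]

CANAPE_CATEGORIES = ("non-significant", "neo", "paleo", "mixed", "super")
#: integer codes used when rasterising categories
CANAPE_CODES = {name: i for i, name in enumerate(CANAPE_CATEGORIES)}


@dataclass
class BinaryStack:
    """Per-species binary range grids on a shared geometry."""

    grids: dict[str, Grid]

    def __post_init__(self):
        if not self.grids:
            raise ValueError("empty stack")
        gs = list(self.grids.values())
        for g in gs[1:]:
            if not g.same_geometry(gs[0]):
                raise ValueError("all stack grids must share geometry")
        for name, g in self.grids.items():
            data = g.values[g.data_mask()]
            if not np.isin(data, (0.0, 1.0)).all():
                raise ValueError(f"grid {name!r} is not binary")

    @property
    def template(self) -> Grid:
        return next(iter(self.grids.values()))

    @property
    def species(self) -> list[str]:
        return list(self.grids)

    def any_data_mask(self) -> np.ndarray:
        m = np.zeros(self.template.values.shape, dtype=bool)
        for g in self.grids.values():
            m |= g.data_mask()
        return m


def stack_from_occurrences(occ, template: Grid) -> BinaryStack:
    """Occurrence-based ranges: a species' range is the set of cells it
    occupies (parity mode for when no SDM stack is available)."""
    grids = {}
    for sp in occ.species:
        vals = np.full(template.values.shape, template.nodata)
        vals[template.data_mask()] = 0.0
        for rec in occ.for_species(sp):
            idx = template.index_of(rec.x, rec.y)
            if idx is not None:
                vals[idx] = 1.0
        grids[sp] = template.like(vals)
    return BinaryStack(grids)


def richness(stack: BinaryStack) -> Grid:
    """Cellwise species count; NoData only where every layer is NoData."""
    tpl = stack.template
    total = np.zeros(tpl.values.shape)
    anydata = stack.any_data_mask()
    for g in stack.grids.values():
        m = g.data_mask()
        total[m] += g.values[m]
    out = np.full(tpl.values.shape, tpl.nodata)
    out[anydata] = total[anydata]
    return tpl.like(out)


def weighted_endemism(stack: BinaryStack) -> Grid:
    """WE = sum over present species of 1 / (range size in cells).

    Each species contributes exactly 1 summed over the landscape, so the
    global WE sum equals the species count.
    """
    tpl = stack.template
    anydata = stack.any_data_mask()
    total = np.zeros(tpl.values.shape)
    for name, g in stack.grids.items():
        m = g.data_mask()
        range_size = int((g.values[m] == 1).sum())
        if range_size == 0:
            raise ValueError(f"species {name!r} occupies no cells")
        total[m] += g.values[m] / range_size
    out = np.full(tpl.values.shape, tpl.nodata)
    out[anydata] = total[anydata]
    return tpl.like(out)


def corrected_weighted_endemism(stack: BinaryStack) -> Grid:
    """CWE = WE / richness per cell; NoData where richness is 0."""
    we = weighted_endemism(stack)
    rich = richness(stack)
    out = np.full(we.values.shape, we.nodata)
    ok = we.data_mask() & rich.data_mask() & (rich.values > 0)
    out[ok] = we.values[ok] / rich.values[ok]
    return we.like(out)


# ---------------------------------------------------------------------------
# Randomization tables (Biodiverse exports)
# ---------------------------------------------------------------------------

#: default column names for randomization exports (editable per call)
DEFAULT_COLUMNS = {
    "x": "Axis_0",
    "y": "Axis_1",
    "p_pe_orig": "P_PE_WE_P",       # rank-p of PE on the original tree
    "p_pe_comp": "P_PHYLO_RPE_NULL2",  # rank-p of PE on the comparison tree
    "p_rpe": "P_PHYLO_RPE2",        # rank-p of relative PE
}


@dataclass
class RandomizationTable:
    """Per-cell observed metrics with rank-based p fields in [0, 1]."""

    frame: pd.DataFrame
    columns: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_COLUMNS))

    def col(self, key: str) -> pd.Series:
        name = self.columns[key]
        if name not in self.frame.columns:
            raise ValueError(f"table lacks required column {name!r} ({key})")
        return self.frame[name]

    @classmethod
    def from_csv(cls, csv_text: str,
                 columns: dict[str, str] | None = None) -> "RandomizationTable":
        colmap = dict(DEFAULT_COLUMNS)
        if columns:
            colmap.update(columns)
        return cls(pd.read_csv(io.StringIO(csv_text)), colmap)


@dataclass
class CanapeThresholds:
    """Significance thresholds of the CANAPE two-step test (configurable)."""

    significant: float = 0.95  # one-tailed PE significance
    super_: float = 0.99       # both-PE threshold for 'super' endemism
    neo: float = 0.025         # RPE rank at or below -> neo
    paleo: float = 0.975       # RPE rank at or above -> paleo


def canape_classify(table: RandomizationTable,
                    thresholds: CanapeThresholds | None = None,
                    template: Grid | None = None):
    """CANAPE categories per cell (and a coded category grid if a template
    is given).

    Two-step rule: a cell is significant iff its PE rank on the original
    or the comparison tree reaches ``significant``.  Among significant
    cells: ``super`` iff both PE ranks reach ``super_``; else ``neo`` iff
    the RPE rank is at most ``neo`` (branches significantly short);
    ``paleo`` iff it is at least ``paleo``; otherwise ``mixed``.
    """
    thr = thresholds or CanapeThresholds()
    p_orig = table.col("p_pe_orig").to_numpy(dtype=float)
    p_comp = table.col("p_pe_comp").to_numpy(dtype=float)
    p_rpe = table.col("p_rpe").to_numpy(dtype=float)
    for arr, name in ((p_orig, "p_pe_orig"), (p_comp, "p_pe_comp"),
                      (p_rpe, "p_rpe")):
        if ((arr < 0) | (arr > 1)).any():
            raise ValueError(f"{name} rank values must lie in [0, 1]")
    cats = np.full(len(p_orig), "non-significant", dtype=object)
    sig = (p_orig >= thr.significant) | (p_comp >= thr.significant)
    is_super = sig & (p_orig >= thr.super_) & (p_comp >= thr.super_)
    is_neo = sig & ~is_super & (p_rpe <= thr.neo)
    is_paleo = sig & ~is_super & (p_rpe >= thr.paleo)
    is_mixed = sig & ~is_super & ~is_neo & ~is_paleo
    cats[is_super] = "super"
    cats[is_neo] = "neo"
    cats[is_paleo] = "paleo"
    cats[is_mixed] = "mixed"
    result = table.frame.copy()
    result["canape"] = cats
    if template is None:
        return result
    vals = np.full(template.values.shape, template.nodata)
    xs = table.col("x").to_numpy(dtype=float)
    ys = table.col("y").to_numpy(dtype=float)
    for x, y, cat in zip(xs, ys, cats):
        idx = template.index_of(x, y)
        if idx is None:
            raise ValueError(f"table cell ({x}, {y}) falls outside the template")
        vals[idx] = CANAPE_CODES[cat]
    return result, template.like(vals)


def reclassify_significance(table: RandomizationTable, fieldname: str,
                            tails: str = "two", alpha: float = 0.05) -> pd.Series:
    """Classify rank-p values of any randomization field.

    Two-tailed: ``sig-high`` iff p >= 1 - alpha/2, ``sig-low`` iff
    p <= alpha/2.  ``one-high`` / ``one-low`` test a single tail at alpha.
    Everything else is ``ns``.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if fieldname not in table.frame.columns:
        raise ValueError(f"table lacks field {fieldname!r}")
    p = table.frame[fieldname].to_numpy(dtype=float)
    out = np.full(len(p), "ns", dtype=object)
    if tails == "two":
        out[p >= 1 - alpha / 2] = "sig-high"
        out[p <= alpha / 2] = "sig-low"
    elif tails == "one-high":
        out[p >= 1 - alpha] = "sig-high"
    elif tails == "one-low":
        out[p <= alpha] = "sig-low"
    else:
        raise ValueError(f"unknown tails {tails!r}")
    return pd.Series(out, index=table.frame.index, name=f"{fieldname}_sig")
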