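"""Occurrence ingestion and spatial rarefaction.

Spatial rarefaction ("spatial filtering") thins clustered occurrence
records so that no two retained points of the same species lie closer than
a filter distance, reducing spatial autocorrelation before model fitting.
A heterogeneity-stratified variant applies up to five different filter
distances keyed to classes of an integer raster (e.g. finer filtering in
climatically heterogeneous terrain, coarser in homogeneous terrain).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import Grid

__all__ = ["OccurrenceRecord", "OccurrenceSet", "load_occurrences",
           "rarefy", "rarefy_multiscale"]

MAX_FILTER_CLASSES = 5


@dataclass(frozen=True)
class OccurrenceRecord:
    species: str
    x: float
    y: float
    label: str | None = None  # clade / haplotype / group tag

    def __post_init__(self):
        if not self.species:
            raise ValueError("species id must be non-empty")
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("coordinates must be finite")


@dataclass
class OccurrenceSet:
    """Point records with species ids in projected map units."""

    records: list[OccurrenceRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.species, None)
        return list(seen)

    def coords(self) -> np.ndarray:
        """(n, 2) array of x, y."""
        return np.array([(r.x, r.y) for r in self.records], dtype=float).reshape(-1, 2)

    def subset(self, indices) -> "OccurrenceSet":
        return OccurrenceSet([self.records[i] for i in indices])

    def for_species(self, species: str) -> "OccurrenceSet":
        return OccurrenceSet([r for r in self.records if r.species == species])

    @classmethod
    def from_arrays(cls, species, x, y, label=None) -> "OccurrenceSet":
        labels = label if label is not None else [None] * len(x)
        return cls([OccurrenceRecord(s, float(xi), float(yi), l)
                    for s, xi, yi, l in zip(species, x, y, labels)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"species": [r.species for r in self.records],
             "x": [r.x for r in self.records],
             "y": [r.y for r in self.records],
             "label": [r.label for r in self.records]}
        )

    def to_csv(self) -> str:
        return self.to_dataframe().to_csv(index=False)


def load_occurrences(csv_text: str, column_map: dict[str, str] | None = None
                     ) -> tuple[OccurrenceSet, list[str]]:
    """Load occurrences from CSV text.

    ``column_map`` maps canonical names (``species``, ``x``, ``y``,
    ``label``) to the CSV's actual headers.  Rows with unparseable
    coordinates are skipped and reported (1-based data line numbers) in the
    second return value rather than raising.
    """
    colmap = {"species": "species", "x": "x", "y": "y", "label": "label"}
    if column_map:
        colmap.update(column_map)
    df = pd.read_csv(io.StringIO(csv_text), dtype=str)
    for req in ("species", "x", "y"):
        if colmap[req] not in df.columns:
            raise ValueError(f"missing required column {colmap[req]!r}")
    has_label = colmap["label"] in df.columns
    records, problems = [], []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            x = float(row[colmap["x"]])
            y = float(row[colmap["y"]])
            sp = str(row[colmap["species"]])
            if not sp or sp == "nan":
                raise ValueError("empty species")
            label = None
            if has_label and pd.notna(row[colmap["label"]]):
                label = str(row[colmap["label"]])
            records.append(OccurrenceRecord(sp, x, y, label))
        except (TypeError, ValueError) as exc:
            problems.append(f"line {line}: {exc}")
    return OccurrenceSet(records), problems


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------


def _greedy_thin(coords: np.ndarray, order: np.ndarray, min_dist) -> list[int]:
    """Keep-first greedy thinning.

    ``min_dist`` is either a scalar or a per-point array; a candidate is
    kept iff its distance to every already-kept point is >= the larger of
    the two points' distances.  The result is a maximal subset: no dropped
    point could be re-added without violating the rule.
    """
    scalar = np.isscalar(min_dist)
    kept: list[int] = []
    for i in order:
        ok = True
        for j in kept:
            d = float(np.hypot(*(coords[i] - coords[j])))
            thr = min_dist if scalar else max(min_dist[i], min_dist[j])
            if d < thr:
                ok = False
                break
        if ok:
            kept.append(int(i))
    return sorted(kept)


def rarefy(occ: OccurrenceSet, d: float, seed: int | None = None) -> OccurrenceSet:
    """Spatially rarefy occurrences to a minimum pairwise distance ``d``.

    Thinning is per species, greedy in input order (after an optional
    seeded shuffle when ``seed`` is given), and deterministic.  The
    retained subset has all within-species pairwise Euclidean distances
    >= ``d`` and is maximal.
    """
    if d < 0:
        raise ValueError("rarefaction distance must be >= 0")
    if d == 0 or len(occ) == 0:
        return OccurrenceSet(list(occ.records))
    keep: list[int] = []
    by_species: dict[str, list[int]] = {}
    for i, r in enumerate(occ.records):
        by_species.setdefault(r.species, []).append(i)
    rng = np.random.default_rng(seed) if seed is not None else None
    coords = occ.coords()
    for idxs in by_species.values():
        idxs = np.array(idxs)
        order = rng.permutation(len(idxs)) if rng is not None else np.arange(len(idxs))
        kept_local = _greedy_thin(coords[idxs], order, d)
        keep.extend(int(idxs[k]) for k in kept_local)
    return occ.subset(sorted(keep))


def rarefy_multiscale(occ: OccurrenceSet, class_grid: Grid,
                      d_by_class: dict[int, float],
                      seed: int | None = None) -> OccurrenceSet:
    """Heterogeneity-stratified rarefaction with up to five filter classes.

    Each occurrence takes the filter distance of the class raster cell it
    falls on.  A pair spanning two classes is governed by the larger of the
    two distances (conservative).  Occurrences on NoData / unclassified
    cells trigger a warning and are filtered at the largest supplied
    distance.
    """
    if len(d_by_class) > MAX_FILTER_CLASSES:
        raise ValueError(
            f"at most {MAX_FILTER_CLASSES} filter classes are supported, "
            f"got {len(d_by_class)}"
        )
    if not d_by_class:
        raise ValueError("d_by_class must be non-empty")
    if len(occ) == 0:
        return OccurrenceSet([])
    d_max = max(d_by_class.values())
    dists = np.empty(len(occ))
    n_unclassified = 0
    for i, rec in enumerate(occ.records):
        idx = class_grid.index_of(rec.x, rec.y)
        cls = None
        if idx is not None:
            v = class_grid.values[idx]
            if v != class_grid.nodata:
                cls = int(v)
        if cls is None or cls not in d_by_class:
            n_unclassified += 1
            dists[i] = d_max
        else:
            dists[i] = d_by_class[cls]
    if n_unclassified:
        warnings.warn(
            f"{n_unclassified} occurrence(s) fall on unclassified/NoData "
            f"cells; filtered at the largest distance {d_max}",
            stacklevel=2,
        )
    keep: list[int] = []
    by_species: dict[str, list[int]] = {}
    for i, r in enumerate(occ.records):
        by_species.setdefault(r.species, []).append(i)
    rng = np.random.default_rng(seed) if seed is not None else None
    coords = occ.coords()
    for idxs in by_species.values():
        idxs = np.array(idxs)
        order = rng.permutation(len(idxs)) if rng is not None else np.arange(len(idxs))
        kept_local = _greedy_thin(coords[idxs], order, dists[idxs])
        keep.extend(int(idxs[k]) for k in kept_local)
    return occ.subset(sorted(keep))
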