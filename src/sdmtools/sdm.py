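"""Spatial jackknifing, model tuning/evaluation/selection and SDM post-processing.

The tuning workflow mirrors the standard MaxEnt practice: candidate models
are the Cartesian product of a regularization-multiplier (RM) list with
five canonical feature-class combinations (L; L,Q; H; L,Q,H; L,Q,H,P,T —
the threshold class T can be dropped from the fifth combination to match
MaxEnt >= 3.4 recommendations).  Candidates are evaluated by spatial
jackknifing: occurrences are split into k (3-5) geographically segregated
groups, the landscape is carved into Voronoi regions dissolved by group,
and each fold trains on k-1 groups and tests on the withheld one.  The
best model has the lowest mean omission error rate (OER), then the highest
mean AUC, then the lowest feature-class complexity.

A percentile envelope scorer is built in as a universal stand-in model so
the whole pipeline runs and is testable without the external MaxEnt
program; for MaxEnt itself the module emits a java batch command file.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import rankdata

from .background import BiasSurface
from .grids import Grid
from .occurrences import OccurrenceSet

__all__ = [
    "FEATURE_COMBOS", "FEATURE_FLAGS", "Candidate", "TuningSpec",
    "SpatialPartition", "ModelEvaluation", "partition_occurrences",
    "voronoi_regions", "make_folds", "oer", "auc", "enumerate_candidates",
    "auto_features", "select_best", "write_maxent_batch", "envelope_model",
    "EnvelopeModel", "sample_at_points", "sample_background",
    "jackknife_evaluate", "tune_and_select", "binarize", "split_by_clades",
    "enforce_dispersal",
]

MIN_GROUPS, MAX_GROUPS = 3, 5
MIN_CLADES, MAX_CLADES = 2, 10

#: the five canonical feature-class combinations, in complexity order
FEATURE_COMBOS: tuple[tuple[str, ...], ...] = (
    ("L",),
    ("L", "Q"),
    ("H",),
    ("L", "Q", "H"),
    ("L", "Q", "H", "P", "T"),
)

#: MaxEnt 3.4 command-line flag spellings (the categorical class C is
#: applied automatically to categorical layers, not toggled here)
FEATURE_FLAGS = {"L": "linear", "Q": "quadratic", "P": "product",
                 "T": "threshold", "H": "hinge"}

OUTPUT_FORMATS = ("cloglog", "logistic", "raw")


# ---------------------------------------------------------------------------
# Tuning grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Candidate:
    rm: float
    combo: tuple[str, ...]
    complexity_rank: int  # 1-5, position in the canonical combo order


@dataclass
class TuningSpec:
    """RM x feature-class candidate grid."""

    rms: list[float] = field(default_factory=lambda: [1.0])
    combo_ids: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5])
    threshold_enabled: bool = True

    def __post_init__(self):
        if not self.rms:
            raise ValueError("rms must be non-empty")
        if any(r <= 0 for r in self.rms):
            raise ValueError("regularization multipliers must be positive")
        if any(c not in (1, 2, 3, 4, 5) for c in self.combo_ids):
            raise ValueError("combo ids must be drawn from 1-5")


def enumerate_candidates(spec: TuningSpec) -> list[Candidate]:
    """Cartesian product of RMs with the canonical combinations, in order.

    With ``threshold_enabled=False`` the fifth combination drops T
    (L,Q,H,P), per MaxEnt >= 3.4 recommendations.
    """
    out = []
    for rm in spec.rms:
        for cid in spec.combo_ids:
            combo = FEATURE_COMBOS[cid - 1]
            if cid == 5 and not spec.threshold_enabled:
                combo = tuple(f for f in combo if f != "T")
            out.append(Candidate(float(rm), combo, cid))
    return out


def auto_features(n: int) -> frozenset[str]:
    """MaxEnt's "auto features" sample-size mapping (optional emulation).

    All classes from 80 records; L, Q, H for 15-79; L, Q for 10-14; L only
    below 10.  The tuning workflow does not apply this silently — the five
    explicit combinations are always compared — but the mapping is exposed
    for parity with MaxEnt's default behaviour.
    """
    if n < 1:
        raise ValueError("occurrence count must be >= 1")
    if n >= 80:
        return frozenset("LQHPT")
    if n >= 15:
        return frozenset("LQH")
    if n >= 10:
        return frozenset("LQ")
    return frozenset("L")


# ---------------------------------------------------------------------------
# Spatial partitioning
# ---------------------------------------------------------------------------


@dataclass
class SpatialPartition:
    """k spatial groups of occurrences plus (optionally) their landscape
    regions as a Voronoi-dissolved group-id grid."""

    k: int
    assignment: np.ndarray  # occurrence index -> group id in [0, k)
    region_grid: Grid | None = None

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=int)
        if not (MIN_GROUPS <= self.k <= MAX_GROUPS):
            raise ValueError(f"k must be in [{MIN_GROUPS}, {MAX_GROUPS}]")
        if self.assignment.min() < 0 or self.assignment.max() >= self.k:
            raise ValueError("group ids must lie in [0, k)")

    def group_indices(self, group: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == group)


def partition_occurrences(occ: OccurrenceSet, k: int,
                          mode: str = "segregated",
                          seed: int = 0) -> SpatialPartition:
    """Assign occurrences to k in [3, 5] spatial groups.

    ``segregated`` clusters the coordinates with seeded multi-restart
    k-means (geographically coherent groups); ``random`` deals occurrences
    uniformly at random into groups balanced to within one record.
    """
    if not (MIN_GROUPS <= k <= MAX_GROUPS):
        raise ValueError(f"k must be in [{MIN_GROUPS}, {MAX_GROUPS}]")
    n = len(occ)
    if n < k:
        raise ValueError(f"need at least k={k} occurrences, got {n}")
    if mode == "segregated":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(occ.coords())
    elif mode == "random":
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        labels = np.empty(n, dtype=int)
        labels[order] = np.arange(n) % k  # round-robin deal: balanced to 1
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SpatialPartition(k, labels)


def voronoi_regions(partition: SpatialPartition, occ: OccurrenceSet,
                    template: Grid) -> Grid:
    """Group-id grid: each data cell takes the group of its nearest
    occurrence (Voronoi cells dissolved by group)."""
    tree = cKDTree(occ.coords())
    xs, ys = template.center_coords()
    mask = template.data_mask()
    _, nearest = tree.query(np.column_stack([xs[mask], ys[mask]]))
    vals = np.full(template.values.shape, template.nodata)
    vals[mask] = partition.assignment[nearest]
    return template.like(vals)


def make_folds(partition: SpatialPartition | int) -> list[tuple[tuple[int, ...], int]]:
    """Leave-one-group-out folds: fold i trains on all groups but i."""
    k = partition if isinstance(partition, int) else partition.k
    groups = tuple(range(k))
    return [(tuple(g for g in groups if g != i), i) for i in groups]


# ---------------------------------------------------------------------------
# Evaluation statistics
# ---------------------------------------------------------------------------


def oer(test_scores, threshold: float) -> float:
    """Omission error rate: fraction of test presences scoring strictly
    below the suitability threshold (false negatives)."""
    scores = np.asarray(test_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty test score set")
    return float(np.mean(scores < threshold))


def auc(presence_scores, background_scores) -> float:
    """Rank-based AUC (Mann-Whitney): probability that a random presence
    outscores a random background point, ties counting one half."""
    pres = np.asarray(presence_scores, dtype=float)
    back = np.asarray(background_scores, dtype=float)
    if pres.size == 0 or back.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([pres, back]))
    u = ranks[: pres.size].sum() - pres.size * (pres.size + 1) / 2.0
    return float(u / (pres.size * back.size))


@dataclass
class ModelEvaluation:
    """Per-fold and mean OER/AUC for one candidate."""

    candidate: Candidate
    fold_oer: list[float]
    fold_auc: list[float]

    def __post_init__(self):
        for v in [*self.fold_oer, *self.fold_auc]:
            if not (0.0 <= v <= 1.0):
                raise ValueError("OER and AUC must lie in [0, 1]")

    @property
    def mean_oer(self) -> float:
        return float(np.mean(self.fold_oer))

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))


def select_best(evaluations: list[ModelEvaluation]) -> ModelEvaluation:
    """Lexicographic model selection: lowest mean OER, then highest mean
    AUC, then lowest feature-class complexity; residual ties go to the
    lowest RM, then first in enumeration order.  A total order, so the
    winner is invariant to permuting the candidate list."""
    if not evaluations:
        raise ValueError("no evaluations to select from")
    return min(
        evaluations,
        key=lambda e: (e.mean_oer, -e.mean_auc,
                       e.candidate.complexity_rank, e.candidate.rm),
    )


# ---------------------------------------------------------------------------
# MaxEnt batch emission
# ---------------------------------------------------------------------------


def write_maxent_batch(candidates: list[Candidate],
                       folds: list[tuple[tuple[int, ...], int]],
                       paths: dict[str, str],
                       output_format: str = "cloglog",
                       memory_mb: int = 1024) -> str:
    """Emit a java command file running MaxEnt for every candidate x fold.

    ``paths`` supplies the file locations MaxEnt will see (no filesystem
    check is performed here): ``maxent_jar``, ``environmental_layers``,
    ``output_dir``, fold-templated ``train_samples`` / ``test_samples``
    (``{fold}`` is substituted), and optionally ``bias_file``.  Flags
    follow the MaxEnt 3.4 command-line dialect; one line per run,
    deterministic order (candidates outer, folds inner).
    """
    if output_format not in OUTPUT_FORMATS:
        raise ValueError(f"unknown output format {output_format!r}")
    lines = []
    for cand in candidates:
        feats = " ".join(
            f"{flag}={'true' if sym in cand.combo else 'false'}"
            for sym, flag in FEATURE_FLAGS.items()
        )
        for train_groups, test_group in folds:
            parts = [
                f"java -mx{memory_mb}m -jar {paths['maxent_jar']}",
                f"environmentallayers={paths['environmental_layers']}",
                f"samplesfile={paths['train_samples'].format(fold=test_group)}",
                f"testsamplesfile={paths['test_samples'].format(fold=test_group)}",
                f"outputdirectory={paths['output_dir']}",
            ]
            if paths.get("bias_file"):
                parts.append(f"biasfile={paths['bias_file']}")
            parts += [
                f"betamultiplier={cand.rm:g}",
                feats,
                "autofeature=false",
                f"outputformat={output_format}",
                "autorun redoifexists nowarnings",
            ]
            lines.append(" ".join(parts))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Built-in envelope scorer (universal stand-in model)
# ---------------------------------------------------------------------------


def sample_at_points(grid: Grid, coords: np.ndarray) -> np.ndarray:
    """Grid values at point locations; NaN outside the extent or on NoData."""
    out = np.full(len(coords), np.nan)
    for i, (x, y) in enumerate(np.asarray(coords, dtype=float)):
        idx = grid.index_of(x, y)
        if idx is not None and grid.values[idx] != grid.nodata:
            out[i] = grid.values[idx]
    return out


def envelope_model(presences: OccurrenceSet | np.ndarray,
                   env: dict[str, Grid],
                   percentile: float = 5.0) -> Grid:
    """Percentile envelope suitability surface.

    For each environmental layer the presence values define an envelope
    ``[p, 100 - p]`` (percentiles); a cell's suitability is the fraction of
    layers whose value falls inside its envelope.  Cells that are NoData in
    any layer are NoData.  This is a deterministic, training-data-only
    scorer used to exercise the jackknife pipeline end to end.
    """
    if not (0.0 <= percentile < 50.0):
        raise ValueError("percentile must lie in [0, 50)")
    coords = (presences.coords() if isinstance(presences, OccurrenceSet)
              else np.asarray(presences, dtype=float))
    if len(coords) < 2:
        raise ValueError("need at least 2 presences")
    layers = list(env.values())
    template = layers[0]
    mask = np.ones(template.values.shape, dtype=bool)
    for g in layers:
        mask &= g.data_mask()
    score = np.zeros(template.values.shape)
    for g in layers:
        vals = sample_at_points(g, coords)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ValueError("no presence falls on data cells of a layer")
        lo = np.percentile(vals, percentile)
        hi = np.percentile(vals, 100.0 - percentile)
        score += ((g.values >= lo) & (g.values <= hi)).astype(float)
    score /= len(layers)
    out = np.full(template.values.shape, template.nodata)
    out[mask] = score[mask]
    return template.like(out)


class EnvelopeModel:
    """Envelope scorer behind the generic train/score model interface.

    The regularization multiplier maps onto the envelope trim: the
    effective percentile is ``base_percentile / rm``, so larger RM trims
    less and yields a wider (less tightly fit) envelope — the analogue of
    stronger regularization.  Feature combinations do not alter the scorer
    (the envelope has no interaction terms); they still enter selection
    through the complexity rank.
    """

    def __init__(self, base_percentile: float = 5.0):
        self.base_percentile = base_percentile

    def train(self, presences, backgrounds, env: dict[str, Grid],
              rm: float = 1.0, combo: tuple[str, ...] = ("L",)):
        p = min(self.base_percentile / rm, np.nextafter(50.0, 0.0))
        surface = envelope_model(presences, env, percentile=p)
        return surface

    def score(self, surface: Grid, coords: np.ndarray) -> np.ndarray:
        return sample_at_points(surface, coords)


# ---------------------------------------------------------------------------
# Background sampling and the jackknife pipeline
# ---------------------------------------------------------------------------


def sample_background(bias: BiasSurface, n: int, seed: int,
                      region_grid: Grid | None = None,
                      allowed_groups=None) -> np.ndarray:
    """Draw ``n`` background cell centers from a bias surface (with
    replacement, probability proportional to the bias weight), optionally
    restricted to given group ids of a region grid."""
    grid = bias.grid
    mask = bias.region_mask()
    if region_grid is not None and allowed_groups is not None:
        mask = mask & np.isin(region_grid.values, list(allowed_groups))
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("no background cells available under the mask")
    w = grid.values[rows, cols]
    rng = np.random.default_rng(seed)
    pick = rng.choice(rows.size, size=n, replace=True, p=w / w.sum())
    xs = grid.xll + (cols[pick] + 0.5) * grid.cellsize
    ys = grid.yll + (grid.nrows - rows[pick] - 0.5) * grid.cellsize
    return np.column_stack([xs, ys])


@dataclass
class JackknifeResult:
    partition: SpatialPartition
    fold_oer: list[float]
    fold_auc: list[float]

    @property
    def mean_oer(self) -> float:
        return float(np.mean(self.fold_oer))

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))


def jackknife_evaluate(occ: OccurrenceSet, env: dict[str, Grid],
                       k: int = 3, mode: str = "segregated", seed: int = 0,
                       bias: BiasSurface | None = None,
                       n_background: int = 10_000,
                       model: EnvelopeModel | None = None,
                       rm: float = 1.0, combo: tuple[str, ...] = ("L",),
                       ) -> JackknifeResult:
    """Leave-one-spatial-group-out evaluation with the built-in scorer.

    Per fold: train the scorer on the k-1 training groups, threshold at
    the minimum training presence score (MTP), and measure the OER of the
    withheld group.  AUC is measured against background points drawn from
    the bias surface within the training groups' Voronoi regions only
    (so test regions contribute no background), seeded per fold.
    """
    model = model or EnvelopeModel()
    partition = partition_occurrences(occ, k, mode=mode, seed=seed)
    template = next(iter(env.values()))
    region = voronoi_regions(partition, occ, template)
    partition.region_grid = region
    coords = occ.coords()
    fold_oer, fold_auc = [], []
    for fold_i, (train_groups, test_group) in enumerate(make_folds(partition)):
        tr = np.isin(partition.assignment, train_groups)
        te = partition.assignment == test_group
        surface = model.train(coords[tr], None, env, rm=rm, combo=combo)
        train_scores = model.score(surface, coords[tr])
        test_scores = model.score(surface, coords[te])
        train_scores = train_scores[~np.isnan(train_scores)]
        test_scores = test_scores[~np.isnan(test_scores)]
        threshold = float(train_scores.min())
        fold_oer.append(oer(test_scores, threshold))
        if bias is not None:
            bg = sample_background(bias, n_background,
                                   seed=seed * 1000 + fold_i,
                                   region_grid=region,
                                   allowed_groups=train_groups)
            bg_scores = model.score(surface, bg)
            bg_scores = bg_scores[~np.isnan(bg_scores)]
            fold_auc.append(auc(test_scores, bg_scores))
        else:
            fold_auc.append(0.5)
    return JackknifeResult(partition, fold_oer, fold_auc)


def tune_and_select(occ: OccurrenceSet, env: dict[str, Grid],
                    spec: TuningSpec, k: int = 3, seed: int = 0,
                    bias: BiasSurface | None = None,
                    n_background: int = 10_000,
                    model: EnvelopeModel | None = None,
                    ) -> tuple[ModelEvaluation, list[ModelEvaluation]]:
    """Evaluate every candidate by spatial jackknife and pick the best."""
    evaluations = []
    for cand in enumerate_candidates(spec):
        res = jackknife_evaluate(occ, env, k=k, mode="segregated", seed=seed,
                                 bias=bias, n_background=n_background,
                                 model=model, rm=cand.rm, combo=cand.combo)
        evaluations.append(ModelEvaluation(cand, res.fold_oer, res.fold_auc))
    return select_best(evaluations), evaluations


# ---------------------------------------------------------------------------
# Post-processing
# ---------------------------------------------------------------------------


def binarize(suitability: Grid, rule: str = "mtp",
             training_scores=None, value: float | None = None) -> Grid:
    """Threshold a continuous suitability grid to presence/absence.

    Rules: ``fixed`` (threshold = ``value``), ``mtp`` (minimum training
    presence), ``percentile`` (the ``value``-th percentile of training
    scores, linear interpolation).  A cell is presence (1) iff its score
    >= threshold; NoData is preserved.
    """
    if rule == "fixed":
        if value is None:
            raise ValueError("fixed rule needs a threshold value")
        thr = float(value)
    elif rule in ("mtp", "percentile"):
        scores = np.asarray(training_scores if training_scores is not None else [],
                            dtype=float)
        if scores.size == 0:
            raise ValueError(f"{rule} rule needs training presence scores")
        if rule == "mtp":
            thr = float(scores.min())
        else:
            if value is None:
                raise ValueError("percentile rule needs a percentile value")
            thr = float(np.percentile(scores, value))
    else:
        raise ValueError(f"unknown binarization rule {rule!r}")
    mask = suitability.data_mask()
    out = np.full(suitability.values.shape, suitability.nodata)
    out[mask] = (suitability.values[mask] >= thr).astype(float)
    return suitability.like(out)


def split_by_clades(binary: Grid, occ: OccurrenceSet) -> dict[str, Grid]:
    """Split a binary SDM into per-clade grids by nearest-occurrence
    Voronoi assignment.

    Every presence cell goes to the clade of its nearest labelled
    occurrence; outputs are pairwise disjoint and their union is the input
    presence set.  Between 2 and 10 distinct clade labels are required.
    """
    labelled = [r for r in occ.records if r.label is not None]
    clades = sorted({r.label for r in labelled})
    if not (MIN_CLADES <= len(clades) <= MAX_CLADES):
        raise ValueError(
            f"need between {MIN_CLADES} and {MAX_CLADES} clade groups, "
            f"got {len(clades)}"
        )
    pts = np.array([(r.x, r.y) for r in labelled])
    labels = np.array([clades.index(r.label) for r in labelled])
    tree = cKDTree(pts)
    mask = binary.data_mask()
    presence = mask & (binary.values == 1)
    xs, ys = binary.center_coords()
    _, nearest = tree.query(np.column_stack([xs[presence], ys[presence]]))
    cell_clade = labels[nearest]
    out = {}
    for ci, clade in enumerate(clades):
        vals = np.full(binary.values.shape, binary.nodata)
        vals[mask] = 0.0
        sel = np.zeros(presence.sum(), dtype=bool)
        sel[cell_clade == ci] = True
        rr, cc = np.nonzero(presence)
        vals[rr[sel], cc[sel]] = 1.0
        out[clade] = binary.like(vals)
    return out


def enforce_dispersal(future: Grid, current_binary: Grid, dmax: float) -> Grid:
    """Clip a future-projection suitability grid by a dispersal limit.

    Future suitability survives only in cells whose center lies within
    ``dmax`` of some current presence cell center; everywhere else it is
    set to 0.  NoData is preserved.
    """
    if dmax < 0:
        raise ValueError("dmax must be >= 0")
    if not future.same_geometry(current_binary):
        raise ValueError("future and current grids must share geometry")
    cur = (current_binary.values == 1) & current_binary.data_mask()
    mask = future.data_mask()
    out = np.full(future.values.shape, future.nodata)
    out[mask] = 0.0
    if cur.any():
        xs, ys = future.center_coords()
        tree = cKDTree(np.column_stack([xs[cur], ys[cur]]))
        dist, _ = tree.query(np.column_stack([xs[mask], ys[mask]]))
        keep = dist <= dmax
        vals = future.values[mask]
        reach = np.zeros(vals.shape)
        reach[keep] = vals[keep]
        out[mask] = reach
    return future.like(out)
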