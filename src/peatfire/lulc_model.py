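"""Land-use/land-cover classification, multicollinearity screening,
Weights-of-Evidence calibration, and ranked-allocation projection.

The analysis uses an 8-class scheme: four cover classes (intact primary
forest, degraded primary forest, tree plantation / secondary forest,
nonforest) crossed with a peat / non-peat flag. Cover classes change over
time; the peat flag is a soil property and is immutable.

Future land use is projected with a Bayesian Weights-of-Evidence (WoE)
transition model: for each transition T (source class -> destination class)
and each binned spatial evidence layer, the positive weight

    W+(T, b) = ln[ P(b | T occurred) / P(b | T did not occur) ]

scores how strongly evidence bin b favours the transition. Cell-level
transition scores combine the log-odds of the calibration-period prior with
the sum of weights across layers (conditional independence of layers is
assumed after VIF screening). Each 5-year step converts exactly the demanded
number of cells per transition, picking the top-scoring eligible cells with
seeded uniform tie-breaking. Patch-geometry machinery (patcher/expander) is
deliberately omitted: patch shape does not affect emissions aggregated to
the coarse grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "INTACT",
    "DEGRADED",
    "PLANTATION",
    "NONFOREST",
    "CLASS_NAMES",
    "N_CLASSES",
    "LulcMap",
    "WoeModel",
    "merge_layers",
    "check_vif",
    "calibrate_woe",
    "project_lulc",
    "observed_demand",
    "distance_layers",
    "transition_labels",
    "decode_label",
    "class_areas",
]

INTACT = 0
DEGRADED = 1
PLANTATION = 2
NONFOREST = 3
N_CLASSES = 4
CLASS_NAMES = {
    INTACT: "intact_forest",
    DEGRADED: "degraded_forest",
    PLANTATION: "plantation_secondary",
    NONFOREST: "nonforest",
}


@dataclass
class LulcMap:
    """Categorical land-cover map on the fine grid.

    Attributes
    ----------
    classes : int array (rows, cols) with values in {0..3}
    peat : bool array, immutable across time
    year : calendar year the map represents
    cell_area_km2 : scalar, per-row vector, or full grid of cell areas
    """

    classes: np.ndarray
    peat: np.ndarray
    year: int
    cell_area_km2: object = 1.0

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.int8)
        self.peat = np.asarray(self.peat, dtype=bool)
        if self.classes.shape != self.peat.shape:
            raise ValueError("classes and peat grids have different shapes")
        if self.classes.min(initial=0) < 0 or self.classes.max(initial=0) >= N_CLASSES:
            raise ValueError("unknown class code in land-cover map")

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape

    def area_grid(self) -> np.ndarray:
        from .grids import row_areas

        return row_areas(self.cell_area_km2, self.shape)

    def copy(self, year: int | None = None) -> "LulcMap":
        return LulcMap(
            self.classes.copy(),
            self.peat.copy(),
            self.year if year is None else year,
            self.cell_area_km2,
        )


def merge_layers(forest_map: np.ndarray, treecover_map: np.ndarray,
                 peat_mask: np.ndarray, year: int = 0,
                 cell_area_km2: object = 1.0) -> LulcMap:
    """Merge a forest-status map, a tree-cover map and a peat mask.

    ``forest_map`` distinguishes intact primary forest, degraded primary
    forest and nonforest; it carries no information about what the nonforest
    is. Tree cover splits the nonforest into a combined tree-plantation /
    secondary-forest class (tree cover present) and residual nonforest
    (shrubland, agriculture, cleared). Forest classes pass through
    unchanged. The peat mask is attached as the soil flag.
    """
    forest_map = np.asarray(forest_map)
    treecover = np.asarray(treecover_map).astype(bool)
    peat = np.asarray(peat_mask).astype(bool)
    if not (forest_map.shape == treecover.shape == peat.shape):
        raise ValueError("input layers are on different grids")
    valid = {INTACT, DEGRADED, NONFOREST}
    codes = set(np.unique(forest_map).tolist())
    if not codes <= valid:
        raise ValueError(f"unknown forest-map class codes: {sorted(codes - valid)}")
    classes = forest_map.astype(np.int8).copy()
    nonforest = forest_map == NONFOREST
    classes[nonforest & treecover] = PLANTATION
    classes[nonforest & ~treecover] = NONFOREST
    return LulcMap(classes, peat, year, cell_area_km2)


def check_vif(evidence_layers: dict[str, np.ndarray], threshold: float = 5.0):
    """Variance inflation factors for candidate evidence layers.

    VIF_i = 1 / (1 - R^2_i) from regressing layer i on all the others
    (with intercept) over all cells. Layers with VIF >= threshold are
    flagged as collinear. A constant layer has undefined VIF and is an
    error, never a silent pass.
    """
    import pandas as pd
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    names = list(evidence_layers)
    if len(names) < 2:
        raise ValueError("VIF screening needs at least two layers")
    cols = []
    for name in names:
        flat = np.asarray(evidence_layers[name], dtype=float).ravel()
        if np.ptp(flat) == 0:
            raise ValueError(f"layer {name!r} is constant; VIF undefined")
        cols.append(flat)
    X = np.column_stack([np.ones(cols[0].size)] + cols)
    with np.errstate(divide="ignore"):
        vifs = [variance_inflation_factor(X, i + 1) for i in range(len(names))]
    return pd.DataFrame(
        {"layer": names, "vif": vifs, "collinear": [v >= threshold for v in vifs]}
    )


@dataclass
class WoeModel:
    """Calibrated Weights-of-Evidence transition model.

    ``weights[(src, dst)][layer]`` is the vector of W+ values per evidence
    bin (log-odds units, additively smoothed so every weight is finite);
    ``priors[(src, dst)]`` is the calibration-period transition fraction of
    eligible (source-class) cells; ``bin_edges[layer]`` are the interior
    edges partitioning that layer's range.
    """

    priors: dict = field(default_factory=dict)
    weights: dict = field(default_factory=dict)
    bin_edges: dict = field(default_factory=dict)
    smoothing: float = 0.5

    @property
    def transitions(self) -> list[tuple[int, int]]:
        return sorted(self.priors)

    def digitize(self, layer: str, values: np.ndarray) -> np.ndarray:
        return np.digitize(np.asarray(values, dtype=float), self.bin_edges[layer])

    def to_frame(self):
        import pandas as pd

        rows = []
        for (src, dst), per_layer in sorted(self.weights.items()):
            for layer, w in sorted(per_layer.items()):
                edges = np.concatenate(([-np.inf], self.bin_edges[layer], [np.inf]))
                for b, weight in enumerate(w):
                    rows.append(
                        {
                            "from_class": src,
                            "to_class": dst,
                            "layer": layer,
                            "bin": b,
                            "bin_lo": edges[b],
                            "bin_hi": edges[b + 1],
                            "weight": weight,
                            "prior": self.priors[(src, dst)],
                        }
                    )
        return pd.DataFrame(rows)


def _quantile_edges(values: np.ndarray, n_bins: int) -> np.ndarray:
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    edges = np.quantile(values, qs)
    return np.unique(edges)


def calibrate_woe(map_t0: LulcMap, map_t1: LulcMap,
                  evidence_layers: dict[str, np.ndarray],
                  bins: int = 10, smoothing: float = 0.5) -> WoeModel:
    """Calibrate WoE weights from an observed transition between two maps.

    Continuous evidence layers are binned by quantiles (deciles by default)
    over the whole domain. For each observed transition, counts of
    transitioned vs non-transitioned eligible cells per bin give the
    positive weights, with ``smoothing`` pseudo-counts added to every cell
    of the 2x2-per-bin table so weights stay finite.
    """
    if map_t0.shape != map_t1.shape:
        raise ValueError("calibration maps are on different grids")
    c0 = map_t0.classes.ravel()
    c1 = map_t1.classes.ravel()

    model = WoeModel(smoothing=smoothing)
    binned = {}
    for name, layer in evidence_layers.items():
        layer = np.asarray(layer, dtype=float).ravel()
        if layer.size != c0.size:
            raise ValueError(f"evidence layer {name!r} does not match the map grid")
        model.bin_edges[name] = _quantile_edges(layer, bins)
        binned[name] = np.digitize(layer, model.bin_edges[name])

    observed = {
        (int(s), int(d))
        for s, d in zip(*np.unique(np.stack([c0, c1]), axis=1))
        if s != d
    }
    for src, dst in sorted(observed):
        eligible = c0 == src
        n_elig = int(eligible.sum())
        if n_elig == 0:
            raise ValueError(f"no eligible source cells for transition {src}->{dst}")
        occurred = eligible & (c1 == dst)
        n_t = int(occurred.sum())
        model.priors[(src, dst)] = n_t / n_elig
        per_layer = {}
        for name, b in binned.items():
            n_bins_eff = model.bin_edges[name].size + 1
            cnt_t = np.bincount(b[occurred], minlength=n_bins_eff).astype(float)
            cnt_all = np.bincount(b[eligible], minlength=n_bins_eff).astype(float)
            cnt_not = cnt_all - cnt_t
            p_b_t = (cnt_t + smoothing) / (n_t + smoothing * n_bins_eff)
            p_b_not = (cnt_not + smoothing) / (
                (n_elig - n_t) + smoothing * n_bins_eff
            )
            per_layer[name] = np.log(p_b_t / p_b_not)
        model.weights[(src, dst)] = per_layer
    return model


def observed_demand(map_t0: LulcMap, map_t1: LulcMap) -> dict[tuple[int, int], int]:
    """Observed per-transition cell counts — the default BAU demand
    (calibration-period trends continue)."""
    c0 = map_t0.classes.ravel()
    c1 = map_t1.classes.ravel()
    demand: dict[tuple[int, int], int] = {}
    pairs, counts = np.unique(np.stack([c0, c1]), axis=1, return_counts=True)
    for (s, d), n in zip(pairs.T, counts):
        if s != d:
            demand[(int(s), int(d))] = int(n)
    return demand


def distance_layers(lulc: LulcMap, prefix: str = "dist_to_") -> dict[str, np.ndarray]:
    """Euclidean distance (in cells) to the nearest cell of each class.

    These are the dynamic evidence layers, recomputed at every projection
    step. A class absent from the map gets a large finite distance.
    """
    out = {}
    diag = math.hypot(*lulc.shape)
    for k, name in CLASS_NAMES.items():
        present = lulc.classes == k
        if present.any():
            out[prefix + name] = ndimage.distance_transform_edt(~present)
        else:
            out[prefix + name] = np.full(lulc.shape, diag)
    return out


def _logit(p: float, eps: float = 1e-9) -> float:
    p = min(max(p, eps), 1 - eps)
    return math.log(p / (1 - p))


def project_lulc(lulc: LulcMap, woe: WoeModel,
                 demand: dict[tuple[int, int], int], n_steps: int, seed: int,
                 static_evidence: dict[str, np.ndarray] | None = None,
                 dynamic_distance: bool = True,
                 step_years: int = 5) -> list[LulcMap]:
    """Project land cover forward in fixed steps under a transition demand.

    Per step and per transition the score surface is
    ``logit(prior) + sum_layers W+(bin)``; exactly ``demand[(src, dst)]``
    eligible cells convert, chosen as the top-scoring cells with seeded
    uniform tie-breaking. Within a step transitions are processed in sorted
    order and a cell converts at most once. Distance-to-class layers (if the
    model uses them) are recomputed from the current map at each step.

    Returns the ``n_steps`` projected maps (the input map is not repeated).
    The selection is nested in demand: under a fixed seed, raising the
    demand for a transition only adds cells to its converted set.
    """
    rng = np.random.default_rng(seed)
    static_evidence = static_evidence or {}
    maps: list[LulcMap] = []
    current = lulc
    for _ in range(n_steps):
        layers = dict(static_evidence)
        if dynamic_distance:
            layers.update(distance_layers(current))
        new_classes = current.classes.copy()
        taken = np.zeros(current.shape, dtype=bool).ravel()
        for (src, dst) in sorted(demand):
            k = int(demand[(src, dst)])
            tiebreak = rng.random(current.classes.size)
            if k == 0:
                continue
            if (src, dst) not in woe.priors:
                raise KeyError(f"transition {src}->{dst} not in calibrated model")
            eligible = (current.classes.ravel() == src) & ~taken
            n_elig = int(eligible.sum())
            if k > n_elig:
                raise ValueError(
                    f"infeasible demand {k} for transition {src}->{dst}: "
                    f"only {n_elig} eligible cells"
                )
            score = np.full(current.classes.size, _logit(woe.priors[(src, dst)]))
            for name, w in woe.weights[(src, dst)].items():
                if name not in layers:
                    raise KeyError(f"evidence layer {name!r} not supplied")
                score = score + w[woe.digitize(name, layers[name].ravel())]
            if not np.isfinite(score[eligible]).any():
                raise ValueError(
                    f"degenerate score surface for transition {src}->{dst}"
                )
            idx = np.flatnonzero(eligible)
            order = np.lexsort((tiebreak[idx], -score[idx]))
            chosen = idx[order[:k]]
            new_classes.ravel()[chosen] = dst
            taken[chosen] = True
        current = LulcMap(
            new_classes, current.peat, current.year + step_years,
            current.cell_area_km2,
        )
        maps.append(current)
    return maps


# ---------------------------------------------------------------------------
# Transition labels shared with the emissions module

def transition_labels(map_t0: LulcMap, map_t1: LulcMap) -> np.ndarray:
    """Encode per-cell transition/stable class over one map interval.

    Label = peat*16 + from*4 + to, in 0..31; from == to marks a stable
    class. Repeated burning at one location is characteristic of stable
    agricultural and degraded classes, which is why stable classes carry
    emission rates of their own.
    """
    if map_t0.shape != map_t1.shape:
        raise ValueError("maps are on different grids")
    if not np.array_equal(map_t0.peat, map_t1.peat):
        raise ValueError("peat mask must be constant across time")
    return (
        map_t0.peat.astype(np.int16) * 16
        + map_t0.classes.astype(np.int16) * 4
        + map_t1.classes.astype(np.int16)
    )


def decode_label(label: int) -> tuple[bool, int, int]:
    """Inverse of :func:`transition_labels` encoding: (peat, from, to)."""
    return bool(label // 16), (label % 16) // 4, label % 4


N_LABELS = 32


def class_areas(lulc: LulcMap) -> dict[int, float]:
    """Total area (km^2) per cover class."""
    area = lulc.area_grid()
    return {
        k: float(area[lulc.classes == k].sum()) for k in CLASS_NAMES
    }
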