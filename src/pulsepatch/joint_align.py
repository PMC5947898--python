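"""Joint face detection and alignment initialization.

A detection candidate is not a bare window but a (window, shape) pair: a
sliding window combined with one of a few representative facial shapes
(left-looking, frontal, right-looking, obtained by Hausdorff clustering of
training shapes).  Shape-indexed pixel-difference features are extracted
relative to the shape's landmarks, scored by a cascade of decision trees

    f^N = sum_i C^i(phi(x, S)),

and a candidate is rejected at the first stage where the running score
falls below that stage's bias threshold theta^i.  The surviving (window,
shape) pair with the greatest total score is returned as an
alignment-friendly bounding box together with a rough initial shape, which
a cascaded linear-regression refiner can then polish.

Shapes are stored in window-normalized [0, 1]^2 coordinates; feature
offsets are fractions of the window side, so the same model applies at any
scanning scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import directed_hausdorff
from skimage.transform import resize
from sklearn.linear_model import Ridge
from sklearn.tree import DecisionTreeRegressor

from .skin_map import rgb_luma

__all__ = [
    "Shape",
    "ShapeIndexedFeatureSpec",
    "CascadeModel",
    "CascadeConfig",
    "ScanConfig",
    "ShapeRefiner",
    "RefinerConfig",
    "TrainingError",
    "cluster_representative_shapes",
    "random_feature_spec",
    "extract_features",
    "train_cascade",
    "cascade_scores",
    "detect",
    "train_refiner",
    "refine_shape",
    "mean_shape",
    "normalized_error",
    "hausdorff_distance",
]


class TrainingError(RuntimeError):
    pass


@dataclass
class Shape:
    """K 2-D facial points; representative shapes carry a pose label."""

    points: np.ndarray
    pose_label: str | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (K, 2)")
        if not np.isfinite(self.points).all():
            raise ValueError("shape points must be finite")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class ShapeIndexedFeatureSpec:
    """Pixel-pair features indexed relative to facial landmarks.

    Each feature references two pixels, each given by (anchor landmark
    index, offset); the feature value is the intensity difference between
    the two referenced pixels.  Offsets are in window-side fractions and
    bounded by ``radius``; out-of-window references clamp to the border.
    """

    anchors: np.ndarray  # (F, 2) landmark indices
    offsets: np.ndarray  # (F, 2, 2) normalized (dx, dy)
    radius: float

    def __post_init__(self) -> None:
        self.anchors = np.asarray(self.anchors, dtype=int)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if len(self.anchors) == 0:
            raise ValueError("empty feature spec")
        if np.any(np.abs(self.offsets) > self.radius + 1e-12):
            raise ValueError("offsets exceed the configured radius")

    @property
    def n_features(self) -> int:
        return len(self.anchors)


def random_feature_spec(
    n_features: int, n_landmarks: int, radius: float = 0.25, seed: int = 0
) -> ShapeIndexedFeatureSpec:
    """Random pixel-pair spec with anchors stratified over the landmarks so
    every facial point contributes features regardless of the seed."""
    rng = np.random.default_rng(seed)
    first = np.arange(n_features) % n_landmarks
    anchors = np.stack([first, rng.integers(0, n_landmarks, n_features)], axis=1)
    perm = rng.permutation(n_features)
    anchors = anchors[perm]
    offsets = rng.uniform(-radius, radius, (n_features, 2, 2))
    return ShapeIndexedFeatureSpec(anchors, offsets, radius)


def _as_gray(window: np.ndarray) -> np.ndarray:
    window = np.asarray(window)
    if window.ndim == 3:
        return rgb_luma(window)
    return window.astype(float)


def extract_features(
    window: np.ndarray, shape: Shape | np.ndarray, spec: ShapeIndexedFeatureSpec
) -> np.ndarray:
    """Shape-indexed pixel-difference feature vector for one window.

    ``shape`` is in window-normalized coordinates; referenced pixels
    falling outside the window clamp to the nearest border pixel, so
    shapes near edges remain scoreable.
    """
    img = _as_gray(window)
    side_y, side_x = img.shape
    pts = shape.points if isinstance(shape, Shape) else np.asarray(shape, dtype=float)
    ref = pts[spec.anchors] + spec.offsets  # (F, 2, 2) normalized
    xs = np.clip(np.rint(ref[..., 0] * side_x).astype(int), 0, side_x - 1)
    ys = np.clip(np.rint(ref[..., 1] * side_y).astype(int), 0, side_y - 1)
    vals = img[ys, xs]  # (F, 2)
    return vals[:, 0] - vals[:, 1]


# ---------------------------------------------------------------------------
# representative shapes
# ---------------------------------------------------------------------------


def hausdorff_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two point sets."""
    return max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])


def _similarity_align(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Least-squares similarity transform (scale, rotation, translation)
    of ``src`` onto ``dst`` (Umeyama)."""
    mu_s, mu_d = src.mean(0), dst.mean(0)
    sc, dc = src - mu_s, dst - mu_d
    cov = dc.T @ sc / len(src)
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    diag = np.diag([1.0, d])
    var_s = (sc**2).sum() / len(src)
    scale = np.trace(np.diag(s) @ diag) / var_s if var_s > 0 else 1.0
    rot = u @ diag @ vt
    return (scale * (rot @ sc.T)).T + mu_d


def cluster_representative_shapes(
    training_shapes: list, n_clusters: int = 3
) -> list[Shape]:
    """Cluster shapes by Hausdorff distance and return per-cluster means.

    Complete-linkage agglomerative clustering on the symmetric Hausdorff
    distance; cluster members are similarity-aligned to a cluster anchor
    before coordinate-wise averaging.  With the default 3 clusters the
    representatives are pose-labelled left / frontal / right by their mean
    horizontal offset.
    """
    pts = [s.points if isinstance(s, Shape) else np.asarray(s, float) for s in training_shapes]
    n = len(pts)
    if n_clusters > n:
        raise ValueError("more clusters requested than shapes available")
    if any(p.shape != pts[0].shape for p in pts):
        raise ValueError("all shapes must share the same K")
    if n_clusters == n:
        labels = np.arange(n)
    elif n_clusters == 1:
        labels = np.zeros(n, dtype=int)
    else:
        cond = []
        for i in range(n):
            for j in range(i + 1, n):
                cond.append(hausdorff_distance(pts[i], pts[j]))
        z = linkage(np.array(cond), method="complete")
        labels = fcluster(z, t=n_clusters, criterion="maxclust") - 1
    reps = []
    for c in sorted(set(labels.tolist())):
        members = [pts[i] for i in range(n) if labels[i] == c]
        anchor = members[0]
        aligned = [anchor] + [_similarity_align(m, anchor) for m in members[1:]]
        reps.append(Shape(np.mean(aligned, axis=0)))
    if n_clusters == 3:
        xs = [r.points[:, 0].mean() for r in reps]
        order = np.argsort(xs)
        for lab, idx in zip(("left", "frontal", "right"), order):
            reps[idx].pose_label = lab
    return reps


def mean_shape(shapes: list) -> Shape:
    """Coordinate-wise mean of shapes (after similarity alignment)."""
    return cluster_representative_shapes(shapes, n_clusters=1)[0]


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------


@dataclass
class _Tree:
    """Array-form regression tree (extracted from a fitted sklearn tree)."""

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    value: np.ndarray

    @classmethod
    def from_sklearn(cls, tree: DecisionTreeRegressor) -> "_Tree":
        t = tree.tree_
        return cls(
            t.children_left.copy(),
            t.children_right.copy(),
            t.feature.copy(),
            t.threshold.copy(),
            np.clip(t.value.reshape(-1), 0.0, 1.0),
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        node = np.zeros(len(X), dtype=int)
        active = self.children_left[node] != -1
        while active.any():
            idx = np.flatnonzero(active)
            nd = node[idx]
            go_left = X[idx, self.feature[nd]] <= self.threshold[nd]
            node[idx] = np.where(go_left, self.children_left[nd], self.children_right[nd])
            active = self.children_left[node] != -1
        return self.value[node]

    def to_dict(self) -> dict:
        return {
            "children_left": self.children_left.tolist(),
            "children_right": self.children_right.tolist(),
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "value": self.value.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_Tree":
        return cls(
            np.array(d["children_left"]),
            np.array(d["children_right"]),
            np.array(d["feature"]),
            np.array(d["threshold"]),
            np.array(d["value"]),
        )


@dataclass
class CascadeConfig:
    n_stages: int = 8
    tree_depth: int = 4
    n_features: int = 128
    feature_radius: float = 0.25
    pass_rate: float = 0.99  # fraction of surviving positives each stage keeps
    max_features: str | float = "sqrt"  # per-node feature subsampling
    n_representative: int = 3
    seed: int = 0


@dataclass
class CascadeModel:
    trees: list
    thresholds: np.ndarray
    representative_shapes: list
    spec: ShapeIndexedFeatureSpec
    window_size: int
    config: CascadeConfig = field(default_factory=CascadeConfig)

    def __post_init__(self) -> None:
        if len(self.trees) != len(self.thresholds):
            raise ValueError("one threshold per cascade stage required")

    @property
    def n_stages(self) -> int:
        return len(self.trees)

    def to_json(self) -> str:
        return json.dumps(
            {
                "window_size": self.window_size,
                "thresholds": np.asarray(self.thresholds).tolist(),
                "trees": [t.to_dict() for t in self.trees],
                "shapes": [
                    {"points": s.points.tolist(), "pose_label": s.pose_label}
                    for s in self.representative_shapes
                ],
                "spec": {
                    "anchors": self.spec.anchors.tolist(),
                    "offsets": self.spec.offsets.tolist(),
                    "radius": self.spec.radius,
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CascadeModel":
        d = json.loads(text)
        return cls(
            trees=[_Tree.from_dict(t) for t in d["trees"]],
            thresholds=np.array(d["thresholds"]),
            representative_shapes=[
                Shape(np.array(s["points"]), s["pose_label"]) for s in d["shapes"]
            ],
            spec=ShapeIndexedFeatureSpec(
                np.array(d["spec"]["anchors"]),
                np.array(d["spec"]["offsets"]),
                d["spec"]["radius"],
            ),
            window_size=int(d["window_size"]),
        )


def _feature_matrix(samples: list, spec: ShapeIndexedFeatureSpec) -> np.ndarray:
    return np.array([extract_features(win, shape, spec) for win, shape in samples])


def train_cascade(
    positives: list, negatives: list, config: CascadeConfig | None = None
) -> CascadeModel:
    """Train the cascaded random forest on (window, shape) samples.

    Positives pair a face window with a roughly aligned shape; negatives
    pair noise windows with any shape or face windows with mismatched
    shapes.  Each stage fits one depth-limited decision tree
    (variance-reduction on the 0/1 labels, per-node feature subsampling),
    clips its leaf scores to [0, 1] so the running score is non-decreasing,
    and sets its bias threshold so ``pass_rate`` of surviving positives
    pass.  Later stages see only the survivors; training stops early once
    every negative is rejected.

    Raises
    ------
    TrainingError
        If a stage rejects all positives (reported with the stage index).
    """
    config = config or CascadeConfig()
    if not positives or not negatives:
        raise ValueError("need both positive and negative samples")
    n_landmarks = (
        positives[0][1].n_points
        if isinstance(positives[0][1], Shape)
        else len(positives[0][1])
    )
    window_size = np.asarray(positives[0][0]).shape[0]
    spec = random_feature_spec(
        config.n_features, n_landmarks, config.feature_radius, seed=config.seed
    )
    X_pos = _feature_matrix(positives, spec)
    X_neg = _feature_matrix(negatives, spec)
    X = np.vstack([X_pos, X_neg])
    y = np.concatenate([np.ones(len(X_pos)), np.zeros(len(X_neg))])
    is_pos = y == 1
    alive = np.ones(len(X), dtype=bool)
    cum = np.zeros(len(X))
    trees, thresholds = [], []
    for stage in range(config.n_stages):
        sk = DecisionTreeRegressor(
            max_depth=config.tree_depth,
            max_features=config.max_features,
            random_state=config.seed + stage,
        )
        sk.fit(X[alive], y[alive])
        tree = _Tree.from_sklearn(sk)
        cum[alive] += tree.predict(X[alive])
        pos_scores = cum[alive & is_pos]
        if len(pos_scores) == 0:
            raise TrainingError(f"stage {stage}: no surviving positives to threshold")
        theta = float(np.quantile(pos_scores, 1.0 - config.pass_rate)) - 1e-9
        alive &= cum >= theta
        if not (alive & is_pos).any():
            raise TrainingError(f"stage {stage}: rejected all positives")
        trees.append(tree)
        thresholds.append(theta)
        if not (alive & ~is_pos).any():
            break  # all negatives rejected: cascade is done
    shapes = [s for _, s in positives]
    reps = cluster_representative_shapes(
        shapes, n_clusters=min(config.n_representative, len(shapes))
    )
    return CascadeModel(
        trees, np.array(thresholds), reps, spec, window_size, config
    )


def cascade_scores(model: CascadeModel, window: np.ndarray):
    """Evaluate one window against every representative shape.

    Returns a list (per shape) of ``(survived, score, stages_passed)``
    where ``score`` is the running score at rejection time or the full
    cascade sum for survivors.
    """
    out = []
    for shape in model.representative_shapes:
        feats = extract_features(window, shape, model.spec)
        f = 0.0
        survived = True
        passed = 0
        for tree, theta in zip(model.trees, model.thresholds):
            f += float(tree.predict(feats[None])[0])
            if f < theta:
                survived = False
                break
            passed += 1
        out.append((survived, f, passed))
    return out


@dataclass
class ScanConfig:
    min_window: int = 24
    max_window: int | None = None
    scales_per_octave: int = 3
    stride_fraction: float = 0.25
    refine_locally: bool = True  # fine second pass around the coarse best


@dataclass
class DetectionResult:
    box: tuple[int, int, int, int]  # x, y, w, h
    shape: Shape  # landmarks in frame pixel coordinates
    shape_normalized: Shape
    score: float


def detect(
    frame: np.ndarray, model: CascadeModel, scan: ScanConfig | None = None
) -> DetectionResult | None:
    """Slide windows over a frame and return the best surviving
    (window, shape) combination, or None if everything is rejected.

    A coarse sweep locates the best candidate; a fine local pass (1-px
    stride around the winner, neighbouring scales) then polishes the box.
    Ties on the score are broken by smaller window area, then scan order.
    """
    scan = scan or ScanConfig()
    img = _as_gray(frame)
    h, w = img.shape
    min_side = min(h, w)
    if min_side < scan.min_window:
        raise ValueError("frame smaller than the minimum scan window")
    max_window = min(scan.max_window or min_side, min_side)
    sizes = []
    s = float(scan.min_window)
    factor = 2.0 ** (1.0 / scan.scales_per_octave)
    while round(s) <= max_window:
        if not sizes or round(s) != sizes[-1]:
            sizes.append(int(round(s)))
        s *= factor

    state = {"best": None, "order": 0}

    def consider(x0: int, y0: int, side: int) -> None:
        win = img[y0 : y0 + side, x0 : x0 + side]
        if side != model.window_size:
            win = resize(
                win,
                (model.window_size, model.window_size),
                preserve_range=True,
                anti_aliasing=side > model.window_size,
            )
        for shape, (survived, score, _) in zip(
            model.representative_shapes, cascade_scores(model, win)
        ):
            state["order"] += 1
            if not survived:
                continue
            key = (-score, side * side, state["order"])
            if state["best"] is None or key < state["best"][0]:
                pts_px = shape.points * side + np.array([x0, y0])
                state["best"] = (
                    key,
                    DetectionResult(
                        box=(x0, y0, side, side),
                        shape=Shape(pts_px, shape.pose_label),
                        shape_normalized=shape,
                        score=score,
                    ),
                )

    for side in sizes:
        stride = max(1, int(round(scan.stride_fraction * side)))
        for y0 in range(0, h - side + 1, stride):
            for x0 in range(0, w - side + 1, stride):
                consider(x0, y0, side)
    if state["best"] is not None and scan.refine_locally:
        bx, by, bside, _ = state["best"][1].box
        coarse_stride = max(1, int(round(scan.stride_fraction * bside)))
        for side in sorted({bside, max(scan.min_window, int(round(bside / factor))),
                            min(max_window, int(round(bside * factor)))}):
            for dy in range(-coarse_stride, coarse_stride + 1):
                for dx in range(-coarse_stride, coarse_stride + 1):
                    x0, y0 = bx + dx, by + dy
                    if 0 <= x0 <= w - side and 0 <= y0 <= h - side:
                        consider(x0, y0, side)
    return state["best"][1] if state["best"] else None


# ---------------------------------------------------------------------------
# shape refinement (cascaded linear regression on shape-indexed features)
# ---------------------------------------------------------------------------


@dataclass
class RefinerConfig:
    n_stages: int = 3
    n_features: int = 96
    feature_radius: float = 0.20
    perturbation: float = 0.06  # normalized units, training start-shape noise
    n_augment: int = 10
    ridge_alpha: float = 1.0
    seed: int = 0


@dataclass
class ShapeRefiner:
    """Cascaded linear shape regressor: each stage predicts a shape update
    from pixel-difference features indexed by the current estimate."""

    stages: list  # (spec, weights (2K, F), intercept (2K,))
    n_landmarks: int
    window_size: int

    def apply(self, window: np.ndarray, shape_norm: np.ndarray) -> np.ndarray:
        current = np.asarray(shape_norm, dtype=float).copy()
        img = _as_gray(window)
        for spec, weights, intercept in self.stages:
            feats = extract_features(img, current, spec)
            delta = weights @ feats + intercept
            current = current + delta.reshape(-1, 2)
        return current


def train_refiner(
    samples: list, config: RefinerConfig | None = None
) -> ShapeRefiner:
    """Train the cascaded linear refiner on (window, true shape) pairs.

    Training starts from randomly perturbed copies of each true shape and
    learns, stage by stage, a ridge-regression update from shape-indexed
    features toward the truth.
    """
    config = config or RefinerConfig()
    rng = np.random.default_rng(config.seed)
    windows = [_as_gray(w) for w, _ in samples]
    truths = [
        s.points if isinstance(s, Shape) else np.asarray(s, float) for _, s in samples
    ]
    k = truths[0].shape[0]
    window_size = windows[0].shape[0]
    cur, tru, win_idx = [], [], []
    for i, t in enumerate(truths):
        for _ in range(config.n_augment):
            cur.append(t + rng.normal(0, config.perturbation, t.shape))
            tru.append(t)
            win_idx.append(i)
    cur = np.array(cur)
    tru = np.array(tru)
    stages = []
    for s in range(config.n_stages):
        spec = random_feature_spec(
            config.n_features, k, config.feature_radius, seed=config.seed + 1000 + s
        )
        feats = np.array(
            [extract_features(windows[w], cur[i], spec) for i, w in enumerate(win_idx)]
        )
        target = (tru - cur).reshape(len(cur), -1)
        reg = Ridge(alpha=config.ridge_alpha).fit(feats, target)
        cur = cur + reg.predict(feats).reshape(cur.shape)
        stages.append((spec, reg.coef_.copy(), reg.intercept_.copy()))
    return ShapeRefiner(stages, k, window_size)


def refine_shape(
    frame: np.ndarray,
    box: tuple[int, int, int, int],
    initial_shape: Shape,
    refiner: ShapeRefiner | None = None,
) -> Shape:
    """Refine an initial shape inside its bounding box.

    Falls back to the identity (returns ``initial_shape``) when no refiner
    is loaded.  The refiner must have been trained with the same number of
    landmarks.
    """
    if refiner is None:
        return initial_shape
    if refiner.n_landmarks != initial_shape.n_points:
        raise ValueError("refiner was trained with a different number of landmarks")
    x0, y0, bw, bh = box
    img = _as_gray(frame)
    crop = img[y0 : y0 + bh, x0 : x0 + bw]
    if crop.shape[0] != refiner.window_size or crop.shape[1] != refiner.window_size:
        crop = resize(
            crop,
            (refiner.window_size, refiner.window_size),
            preserve_range=True,
            anti_aliasing=False,
        )
    norm = (initial_shape.points - np.array([x0, y0])) / np.array([bw, bh])
    refined = refiner.apply(crop, norm)
    pts = refined * np.array([bw, bh]) + np.array([x0, y0])
    return Shape(pts, initial_shape.pose_label)


def normalized_error(
    pred: Shape | np.ndarray,
    truth: Shape | np.ndarray,
    interocular_indices: tuple[int, int],
) -> float:
    """Mean point-to-point distance divided by the inter-ocular distance."""
    p = pred.points if isinstance(pred, Shape) else np.asarray(pred, float)
    t = truth.points if isinstance(truth, Shape) else np.asarray(truth, float)
    i, j = interocular_indices
    iod = float(np.linalg.norm(t[i] - t[j]))
    if iod == 0:
        raise ValueError("degenerate inter-ocular distance")
    return float(np.mean(np.linalg.norm(p - t, axis=1)) / iod)
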