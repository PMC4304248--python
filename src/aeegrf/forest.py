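"""Class-weighted random forest, written from first principles.

The ensemble follows the classic bagging + random-variable-selection recipe:
each tree is grown fully (no pruning, no depth cap) on a bootstrap sample of
the training set, and at every node a fresh random subset of ``m_try``
features is considered for the split. Class weights enter in exactly two
places: the Gini criterion used to pick splits, and the class-probability
vectors stored at the leaves (so the forest's vote is a weighted vote).
Out-of-bag (OOB) samples — the roughly e⁻¹ ≈ 37% of rows a tree's bootstrap
misses — provide an internal error estimate and drive permutation feature
significance: a feature's score is the mean per-tree drop in OOB
correct-vote rate when that feature's values are shuffled among the OOB
cases.

Determinism: every stochastic choice (bootstraps, feature subsets,
permutations) flows from per-tree streams derived from the master seed, so a
fitted forest and everything computed from it are reproducible bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

SCHEMA_VERSION = 1

#: Default class weights (abnormal-to-normal 3:1): missing the abnormal,
#: minority class is the costlier clinical error.
DEFAULT_CLASS_WEIGHTS = {"abnormal": 3.0, "normal": 1.0}

_GAIN_EPS = 1e-12


def default_m_try(p: int) -> int:
    """Default number of split candidates: round(sqrt(p)) (11 when p = 119)."""
    return max(1, int(round(np.sqrt(p))))


@dataclass
class ForestConfig:
    """Forest hyperparameters.

    ``m_try = None`` resolves to ``round(sqrt(p))`` at fit time.
    ``class_weights = None`` means an unweighted forest (all weights 1).
    ``vote`` selects how trees are aggregated: ``"soft"`` averages the leaf
    probability vectors; ``"hard"`` counts one weighted vote per tree. The two
    differ only on near-ties.
    """

    n_tree: int = 1000
    m_try: Optional[int] = None
    class_weights: Optional[Dict[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS)
    )
    seed: int = 0
    min_leaf: int = 1
    vote: str = "soft"

    def validate(self, p: Optional[int] = None) -> None:
        if self.n_tree < 1:
            raise ValueError("n_tree must be >= 1")
        if self.m_try is not None:
            if self.m_try < 1 or (p is not None and self.m_try > p):
                raise ValueError(f"m_try must be in [1, {p}]")
        if self.class_weights is not None and any(w <= 0 for w in self.class_weights.values()):
            raise ValueError("class weights must be > 0")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if self.vote not in ("soft", "hard"):
            raise ValueError("vote must be 'soft' or 'hard'")


# Tree nodes are plain dicts (JSON-serializable):
#   internal: {"feature": int, "threshold": float, "left": node, "right": node}
#   leaf:     {"probs": [float, ...]}   (weighted class probabilities, sum 1)
TreeNode = Dict[str, Union[int, float, list, dict]]


@dataclass
class Forest:
    """A fitted ensemble with per-tree bootstrap membership (for OOB)."""

    trees: List[TreeNode]
    bootstraps: List[np.ndarray]
    config: ForestConfig
    classes: Tuple[str, ...]
    n_samples: int
    feature_names: Optional[Tuple[str, ...]] = None

    @property
    def n_features(self) -> int:
        return self._p

    _p: int = 0


@dataclass
class ImportanceReport:
    """Raw permutation significance per feature (mean per-tree OOB drop)."""

    importances: np.ndarray
    feature_names: Optional[Tuple[str, ...]] = None

    def ranking(self) -> np.ndarray:
        """Feature indices sorted by decreasing significance."""
        return np.argsort(-self.importances, kind="stable")


# ---------------------------------------------------------------------------
# Split criterion
# ---------------------------------------------------------------------------

def weighted_gini(class_counts: Sequence[float], weights: Sequence[float]) -> float:
    """Gini impurity of weight-scaled class proportions.

    ``p_k = w_k n_k / Σ_j w_j n_j``; impurity is ``1 − Σ p_k²``. Up-weighting
    the minority class makes its misclassification costlier during split
    selection.
    """
    counts = np.asarray(class_counts, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be >= 0")
    mass = counts * w
    total = mass.sum()
    if total <= 0:
        raise ValueError("node has no samples")
    pk = mass / total
    return float(1.0 - np.sum(pk**2))


def best_split(
    X: np.ndarray,
    y: np.ndarray,
    candidates: Sequence[int],
    weights: np.ndarray,
    min_leaf: int = 1,
) -> Optional[Tuple[int, float, float]]:
    """Best (feature, threshold, gain) by weighted-Gini decrease.

    Thresholds are midpoints between consecutive distinct sorted values of a
    candidate feature. Gain is the decrease in weighted-mass-averaged
    impurity. Ties go to the lowest feature index, then the lowest threshold;
    returns ``None`` when no split reduces impurity (e.g. all candidates
    constant).

    ``y`` holds class indices (0-based); ``weights`` is the per-class weight
    vector aligned with those indices.
    """
    candidates = sorted(candidates)
    if not candidates:
        raise ValueError("candidate feature set is empty")
    n = y.size
    k = weights.size
    onehot = np.zeros((n, k))
    onehot[np.arange(n), y] = 1.0
    parent_counts = onehot.sum(axis=0)
    parent_mass = float((parent_counts * weights).sum())
    parent_imp = weighted_gini(parent_counts, weights)

    best = None  # (gain, feature, threshold)
    for f in candidates:
        col = X[:, f]
        order = np.argsort(col, kind="stable")
        sv = col[order]
        # cumulative weighted class mass left of each cut position
        cum = np.cumsum(onehot[order] * weights, axis=0)  # (n, k)
        total = cum[-1]
        # valid cut after position i (1-based left size i+1) where value changes
        diffs = np.nonzero(sv[1:] != sv[:-1])[0]  # left sizes = diffs + 1
        for i in diffs:
            left_n = i + 1
            if left_n < min_leaf or n - left_n < min_leaf:
                continue
            lm = cum[i]
            rm = total - lm
            lsum, rsum = lm.sum(), rm.sum()
            imp_l = 1.0 - np.sum((lm / lsum) ** 2)
            imp_r = 1.0 - np.sum((rm / rsum) ** 2)
            gain = parent_imp - (lsum * imp_l + rsum * imp_r) / parent_mass
            if gain > _GAIN_EPS and (best is None or gain > best[0] + _GAIN_EPS):
                thr = 0.5 * (sv[i] + sv[i + 1])
                best = (float(gain), int(f), float(thr))
    if best is None:
        return None
    gain, f, thr = best
    return f, thr, gain


# ---------------------------------------------------------------------------
# Tree growing
# ---------------------------------------------------------------------------

def _leaf(counts: np.ndarray, weights: np.ndarray) -> TreeNode:
    mass = counts * weights
    return {"probs": (mass / mass.sum()).tolist()}


def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    config: ForestConfig,
    rng: np.random.Generator,
    weights: np.ndarray,
    m_try: int,
) -> TreeNode:
    """Grow one unpruned tree; recursion stops only at purity, < 2 samples,
    or when no candidate split reduces the weighted impurity."""
    p = X.shape[1]
    k = weights.size

    def build(rows: np.ndarray) -> TreeNode:
        yr = y[rows]
        counts = np.bincount(yr, minlength=k).astype(float)
        if rows.size < 2 or np.count_nonzero(counts) <= 1:
            return _leaf(counts, weights)
        feats = rng.choice(p, size=m_try, replace=False)
        split = best_split(X[rows], yr, feats, weights, config.min_leaf)
        if split is None:
            return _leaf(counts, weights)
        f, thr, _ = split
        mask = X[rows, f] <= thr
        return {
            "feature": f,
            "threshold": thr,
            "left": build(rows[mask]),
            "right": build(rows[~mask]),
        }

    return build(np.arange(X.shape[0]))


def _tree_proba(root: TreeNode, X: np.ndarray) -> np.ndarray:
    """Leaf probability vector for every row of ``X``."""
    out = np.empty((X.shape[0], len(_first_leaf(root)["probs"])))
    for i, x in enumerate(X):
        node = root
        while "probs" not in node:
            node = node["left"] if x[node["feature"]] <= node["threshold"] else node["right"]
        out[i] = node["probs"]
    return out


def _first_leaf(node: TreeNode) -> TreeNode:
    while "probs" not in node:
        node = node["left"]
    return node


# ---------------------------------------------------------------------------
# Forest fit / predict
# ---------------------------------------------------------------------------

def _class_order(labels: Sequence[str]) -> Tuple[str, ...]:
    # "abnormal" (the clinical positive / tie-break class) first when present,
    # remaining classes alphabetical.
    uniq = sorted(set(labels))
    if "abnormal" in uniq:
        uniq.remove("abnormal")
        uniq.insert(0, "abnormal")
    return tuple(uniq)


def _weight_vector(classes: Tuple[str, ...], cw: Optional[Dict[str, float]]) -> np.ndarray:
    if cw is None:
        return np.ones(len(classes))
    return np.array([float(cw.get(c, 1.0)) for c in classes])


def _tree_rng(seed: int, b: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(b,)))


def fit(
    X: np.ndarray,
    labels: Sequence[str],
    config: Optional[ForestConfig] = None,
    feature_names: Optional[Sequence[str]] = None,
) -> Forest:
    """Fit a class-weighted random forest.

    Each of the ``n_tree`` trees is grown on an independent size-``n``
    bootstrap (sampling with replacement) drawn from its own seeded stream;
    the bootstrap index multisets are stored so OOB quantities can be
    computed later.
    """
    config = config or ForestConfig()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n, p = X.shape
    config.validate(p)
    if n < 2:
        raise ValueError("need at least 2 samples")
    classes = _class_order(labels)
    if len(classes) < 2:
        raise ValueError("training data must contain at least 2 classes")
    y = np.array([classes.index(l) for l in labels])
    weights = _weight_vector(classes, config.class_weights)
    m_try = config.m_try if config.m_try is not None else default_m_try(p)
    if m_try > p:
        raise ValueError(f"m_try={m_try} exceeds p={p}")

    trees, boots = [], []
    for b in range(config.n_tree):
        rng = _tree_rng(config.seed, b)
        boot = rng.integers(0, n, size=n)
        trees.append(grow_tree(X[boot], y[boot], config, rng, weights, m_try))
        boots.append(boot)
    forest = Forest(
        trees=trees,
        bootstraps=boots,
        config=config,
        classes=classes,
        n_samples=n,
        feature_names=tuple(feature_names) if feature_names is not None else None,
    )
    forest._p = p
    return forest


def predict_proba(forest: Forest, X: np.ndarray) -> np.ndarray:
    """Forest-averaged class probabilities (rows sum to 1)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != forest._p:
        raise ValueError(f"expected {forest._p} features, got {X.shape[1]}")
    k = len(forest.classes)
    if forest.config.vote == "hard":
        votes = np.zeros((X.shape[0], k))
        for tree in forest.trees:
            pr = _tree_proba(tree, X)
            votes[np.arange(X.shape[0]), np.argmax(pr, axis=1)] += 1.0
        return votes / len(forest.trees)
    acc = np.zeros((X.shape[0], k))
    for tree in forest.trees:
        acc += _tree_proba(tree, X)
    return acc / len(forest.trees)


def predict(forest: Forest, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Predicted class labels and averaged probabilities.

    Exact probability ties resolve to the first class in ``forest.classes``,
    i.e. ``"abnormal"`` when present (the costlier miss).
    """
    proba = predict_proba(forest, X)
    idx = np.argmax(proba, axis=1)  # argmax takes the first maximum: abnormal
    labels = np.array([forest.classes[i] for i in idx])
    return labels, proba


# ---------------------------------------------------------------------------
# Out-of-bag machinery
# ---------------------------------------------------------------------------

def _oob_masks(forest: Forest) -> List[np.ndarray]:
    masks = []
    for boot in forest.bootstraps:
        mask = np.ones(forest.n_samples, dtype=bool)
        mask[boot] = False
        masks.append(mask)
    return masks


def oob_proba(forest: Forest, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Per-sample class probabilities aggregated over out-of-bag trees only.

    Returns ``(proba, n_oob_trees)``; rows with ``n_oob_trees == 0`` are NaN.
    """
    X = np.asarray(X, dtype=float)
    n, k = forest.n_samples, len(forest.classes)
    if X.shape != (n, forest._p):
        raise ValueError("X must be the training matrix the forest was fitted on")
    acc = np.zeros((n, k))
    cnt = np.zeros(n)
    hard = forest.config.vote == "hard"
    for tree, mask in zip(forest.trees, _oob_masks(forest)):
        rows = np.nonzero(mask)[0]
        if rows.size == 0:
            continue
        pr = _tree_proba(tree, X[rows])
        if hard:
            v = np.zeros_like(pr)
            v[np.arange(rows.size), np.argmax(pr, axis=1)] = 1.0
            pr = v
        acc[rows] += pr
        cnt[rows] += 1
    proba = np.full((n, k), np.nan)
    has = cnt > 0
    proba[has] = acc[has] / cnt[has, None]
    return proba, cnt


def oob_predictions(forest: Forest, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """OOB-aggregated predicted labels plus the mask of evaluable samples."""
    proba, cnt = oob_proba(forest, X)
    has = cnt > 0
    idx = np.zeros(forest.n_samples, dtype=int)
    idx[has] = np.argmax(proba[has], axis=1)
    labels = np.array([forest.classes[i] for i in idx], dtype=object)
    labels[~has] = None
    return labels, has


def oob_error(forest: Forest, X: np.ndarray, labels: Sequence[str]) -> float:
    """OOB misclassification rate over samples with at least one OOB tree."""
    pred, has = oob_predictions(forest, X)
    if not np.any(has):
        raise ValueError("no sample is out-of-bag for any tree; cannot estimate OOB error")
    y = np.asarray(labels, dtype=object)
    return float(np.mean(pred[has] != y[has]))


def mean_oob_fraction(forest: Forest) -> float:
    """Average fraction of samples each tree leaves out of its bootstrap."""
    return float(np.mean([m.mean() for m in _oob_masks(forest)]))


# ---------------------------------------------------------------------------
# Permutation feature significance
# ---------------------------------------------------------------------------

def permutation_importance(
    forest: Forest, X: np.ndarray, labels: Sequence[str], seed: int = 0
) -> ImportanceReport:
    """Raw permutation significance of every feature.

    For each tree: classify its OOB cases, then re-classify them with feature
    ``i`` shuffled among those cases; the tree's score for ``i`` is the drop
    in correct-vote fraction. The reported significance is the mean over
    trees. Permutations come from one stream seeded by ``seed``.
    """
    if not forest.trees:
        raise ValueError("forest is not fitted")
    X = np.asarray(X, dtype=float)
    y = np.array([forest.classes.index(l) for l in labels])
    rng = np.random.default_rng(seed)
    p = forest._p
    fi = np.zeros((len(forest.trees), p))
    for t, (tree, mask) in enumerate(zip(forest.trees, _oob_masks(forest))):
        rows = np.nonzero(mask)[0]
        if rows.size == 0:
            continue
        Xo = X[rows]
        yo = y[rows]
        base = np.mean(np.argmax(_tree_proba(tree, Xo), axis=1) == yo)
        for i in range(p):
            perm = rng.permutation(rows.size)
            Xp = Xo.copy()
            Xp[:, i] = Xo[perm, i]
            acc = np.mean(np.argmax(_tree_proba(tree, Xp), axis=1) == yo)
            fi[t, i] = base - acc
    return ImportanceReport(importances=fi.mean(axis=0), feature_names=forest.feature_names)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def to_json(forest: Forest, path: Optional[str | Path] = None) -> str:
    """Serialize a fitted forest (config, trees, bootstraps) to JSON."""
    cfg = forest.config
    obj = {
        "schema_version": SCHEMA_VERSION,
        "config": {
            "n_tree": cfg.n_tree,
            "m_try": cfg.m_try,
            "class_weights": cfg.class_weights,
            "seed": cfg.seed,
            "min_leaf": cfg.min_leaf,
            "vote": cfg.vote,
        },
        "classes": list(forest.classes),
        "n_samples": forest.n_samples,
        "n_features": forest._p,
        "feature_names": list(forest.feature_names) if forest.feature_names else None,
        "trees": [
            {"root": tree, "bootstrap": boot.tolist()}
            for tree, boot in zip(forest.trees, forest.bootstraps)
        ],
    }
    text = json.dumps(obj)
    if path is not None:
        Path(path).write_text(text)
    return text


def from_json(source: str | Path) -> Forest:
    """Load a forest serialized by :func:`to_json`; predictions round-trip exactly."""
    if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
        text = Path(source).read_text()
    else:
        text = str(source)
    obj = json.loads(text)
    if obj.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {obj.get('schema_version')!r}")
    cfg = ForestConfig(**obj["config"])
    forest = Forest(
        trees=[t["root"] for t in obj["trees"]],
        bootstraps=[np.asarray(t["bootstrap"], dtype=int) for t in obj["trees"]],
        config=cfg,
        classes=tuple(obj["classes"]),
        n_samples=obj["n_samples"],
        feature_names=tuple(obj["feature_names"]) if obj["feature_names"] else None,
    )
    forest._p = obj["n_features"]
    return forest
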