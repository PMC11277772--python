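"""Binary chaotic crow search (CCSA) wrapper feature selection.

Crows carry continuous positions in [0, 1]^M. Each iteration, crow l picks
a random peer y and either follows that peer's memorised best position

    alpha_l <- alpha_l + varsigma * kappa * (Q_y - alpha_l)

(when the chaotic draw ``varsigma`` is at least the awareness probability
AP) or relocates uniformly at random. The chaotic value comes from a named
one-dimensional chaotic map rather than a PRNG — the same single draw
gates the branch and scales the step. Positions binarize through the
steep transfer

    v(alpha) = 1 / (1 + exp(10 (alpha - 0.5)))       bit = 1  iff  v >= u

with u uniform on [0, 1]; note v decreases in alpha, exactly as printed in
the source formulation (a flag flips the orientation for experimentation).

A mask's fitness is the mean stratified h-fold cross-validated accuracy of
a small random forest restricted to the masked features, plus a sparsity
bonus:

    F = Accuracy + lambda_F * (1 - L_F / L_tau)

Fold assignment is frozen per run so fitness differences reflect masks,
not fold noise; mask fitnesses are memoised. Per-crow memories keep the
best mask seen, so the reported best is monotone over iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from pulmotex.forest import _forest_votes_binned, quantile_bin
from pulmotex.types import FeatureTable

__all__ = [
    "CCSAConfig",
    "CHAOTIC_MAPS",
    "chaotic_sequence",
    "transfer_and_binarize",
    "subset_fitness",
    "ccsa_select",
]

_EPS = 1e-10


def _logistic(x: float) -> float:
    return 4.0 * x * (1.0 - x)


def _tent(x: float) -> float:
    return 2.0 * x if x < 0.5 else 2.0 * (1.0 - x)


def _sine(x: float) -> float:
    return np.sin(np.pi * x)


def _circle(x: float) -> float:
    # circle map with K=0.5, Omega=0.2, folded into (0,1)
    return (x + 0.2 - (0.5 / (2 * np.pi)) * np.sin(2 * np.pi * x)) % 1.0


def _chebyshev(x: float) -> float:
    # order-4 Chebyshev on [-1,1], affinely mapped into (0,1)
    t = 2.0 * x - 1.0
    return (np.cos(4.0 * np.arccos(np.clip(t, -1.0, 1.0))) + 1.0) / 2.0


def _gauss_mouse(x: float) -> float:
    if x == 0.0:
        return 0.0
    return (1.0 / x) % 1.0


def _iterative(x: float) -> float:
    return abs(np.sin(0.7 * np.pi / x)) if x != 0 else 0.0


def _piecewise(x: float, p: float = 0.4) -> float:
    if x < p:
        return x / p
    if x < 0.5:
        return (x - p) / (0.5 - p)
    if x < 1.0 - p:
        return (1.0 - p - x) / (0.5 - p)
    return (1.0 - x) / p


def _singer(x: float) -> float:
    return 1.07 * (7.86 * x - 23.31 * x**2 + 28.75 * x**3 - 13.302875 * x**4)


def _sinusoidal(x: float) -> float:
    return 2.3 * x**2 * np.sin(np.pi * x)


#: the ten standard metaheuristic chaotic maps, by name
CHAOTIC_MAPS = {
    "logistic": _logistic,
    "tent": _tent,
    "sine": _sine,
    "circle": _circle,
    "chebyshev": _chebyshev,
    "gauss": _gauss_mouse,
    "iterative": _iterative,
    "piecewise": _piecewise,
    "singer": _singer,
    "sinusoidal": _sinusoidal,
}


def chaotic_sequence(map_id: str, x0: float, length: int) -> np.ndarray:
    """Iterate the named chaotic map from ``x0``; values clipped to
    (eps, 1 - eps) to keep the sequence inside the open unit interval."""
    if not 0.0 < x0 < 1.0:
        raise ValueError("x0 must lie in (0, 1)")
    if map_id not in CHAOTIC_MAPS:
        raise ValueError(f"unknown chaotic map {map_id!r}")
    fn = CHAOTIC_MAPS[map_id]
    out = np.empty(length)
    x = x0
    for i in range(length):
        x = float(np.clip(fn(x), _EPS, 1.0 - _EPS))
        out[i] = x
    return out


def transfer_and_binarize(
    position: np.ndarray | float, u: np.ndarray | float, flip: bool = False
) -> np.ndarray:
    """Steep sigmoid transfer then stochastic thresholding.

    ``v = 1 / (1 + exp(10 (alpha - 0.5)))``; bit = 1 iff v >= u. The
    transfer is *decreasing* in alpha as printed; ``flip=True`` uses the
    increasing orientation instead.
    """
    position = np.asarray(position, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(u < 0) or np.any(u > 1):
        raise ValueError("u must lie in [0, 1]")
    v = transfer_value(position, flip)
    return (v >= u).astype(np.int8)


def transfer_value(position: np.ndarray | float, flip: bool = False) -> np.ndarray:
    """The sigmoid transfer value v(alpha) itself."""
    position = np.asarray(position, dtype=float)
    sign = -1.0 if flip else 1.0
    return 1.0 / (1.0 + np.exp(sign * 10.0 * (position - 0.5)))


def update_position(
    position: np.ndarray,
    peer_memory: np.ndarray,
    varsigma: float,
    config: "CCSAConfig",
    rng: np.random.Generator,
) -> np.ndarray:
    """One crow's position update.

    Follow branch (``varsigma >= AP``): step toward the peer's memory by
    ``varsigma * flight_length``; otherwise relocate uniformly inside the
    bounds. The single chaotic value gates the branch *and* scales the
    step. The result is clipped to [lower, upper].
    """
    position = np.asarray(position, dtype=float)
    if varsigma >= config.awareness:
        new = position + varsigma * config.flight_length * (peer_memory - position)
    else:
        new = rng.uniform(config.lower, config.upper, size=position.shape)
    return np.clip(new, config.lower, config.upper)


@dataclass
class CCSAConfig:
    """CCSA parameters (defaults follow the source's published table:
    H=30 crows, AP=0.1, flight length 2, bounds [0,1], 50 iterations,
    10-fold fitness CV)."""

    n_crows: int = 30
    awareness: float = 0.1
    flight_length: float = 2.0
    lower: float = 0.0
    upper: float = 1.0
    max_iter: int = 50
    lambda_f: float = 0.01
    chaotic_map: str = "logistic"
    cv_folds: int = 10
    flip_transfer: bool = False
    forest_trees: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.awareness <= 1.0:
            raise ValueError("awareness must lie in [0, 1]")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0.0 <= self.lambda_f <= 1.0:
            raise ValueError("lambda_f must lie in [0, 1]")
        if self.chaotic_map not in CHAOTIC_MAPS:
            raise ValueError(f"unknown chaotic map {self.chaotic_map!r}")


class _FitnessEvaluator:
    """Memoised h-fold CV accuracy of the forest on masked features.

    Features are quantile-binned once per run; the forest inside the
    wrapper grows histogram trees on the binned columns (exact CARTs live
    in :func:`pulmotex.forest.build_forest`; the binned search only coarsens
    candidate thresholds to the quantile grid)."""

    def __init__(self, table: FeatureTable, config: CCSAConfig, rng: np.random.Generator):
        self.table = table
        self.config = config
        self.binned = quantile_bin(table.features)
        self.y_codes = np.unique(table.labels, return_inverse=True)[1].astype(np.int64)
        self.n_classes = int(self.y_codes.max()) + 1
        # folds frozen once per run: every mask sees the same partition
        skf = StratifiedKFold(
            n_splits=config.cv_folds,
            shuffle=True,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        self.folds = list(skf.split(table.features, table.labels))
        self.forest_seed = int(rng.integers(0, 2**30 - 1))
        self.cache: dict[bytes, float] = {}
        self.n_evaluations = 0
        self.evaluation_log: list[tuple[np.ndarray, float]] = []

    def accuracy(self, mask: np.ndarray) -> float:
        key = np.packbits(mask).tobytes()
        if key in self.cache:
            return self.cache[key]
        self.n_evaluations += 1
        cols = np.flatnonzero(mask)
        Xb = np.ascontiguousarray(self.binned[:, cols])
        mtry = int(np.ceil(np.sqrt(cols.size)))
        correct = 0
        for fi, (train_idx, test_idx) in enumerate(self.folds):
            votes = _forest_votes_binned(
                Xb[train_idx],
                self.y_codes[train_idx],
                self.n_classes,
                Xb[test_idx],
                self.config.forest_trees,
                mtry,
                1,
                self.forest_seed + fi,
            )
            pred = np.argmax(votes, axis=1)
            correct += int(np.sum(pred == self.y_codes[test_idx]))
        acc = correct / self.table.n_samples
        self.cache[key] = acc
        return acc

    def fitness(self, mask: np.ndarray) -> float:
        acc = self.accuracy(mask)
        lf = int(mask.sum())
        fit = acc + self.config.lambda_f * (1.0 - lf / mask.size)
        self.evaluation_log.append((mask.copy(), fit))
        return fit


def subset_fitness(
    table: FeatureTable,
    mask: np.ndarray,
    config: CCSAConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Fitness of one feature mask: mean stratified h-fold CV accuracy of
    the forest on the masked features plus the sparsity bonus
    ``lambda_F * (1 - L_F / L_tau)``.

    An all-zero mask is repaired by setting one uniformly random bit.
    """
    config = config or CCSAConfig()
    rng = np.random.default_rng(config.seed if rng is None else rng)
    mask = np.asarray(mask, dtype=np.int8).copy()
    if mask.sum() == 0:
        mask[rng.integers(0, mask.size)] = 1
    evaluator = _FitnessEvaluator(table, config, rng)
    return evaluator.fitness(mask)


@dataclass
class CCSAResult:
    best_mask: np.ndarray
    best_fitness: float
    history: np.ndarray          # best-so-far fitness per iteration
    n_evaluations: int = 0
    evaluation_log: list = field(default_factory=list, repr=False)


def ccsa_select(
    table: FeatureTable,
    config: CCSAConfig | None = None,
) -> CCSAResult:
    """Run the binary CCSA wrapper and return the best mask found.

    The search runs exactly ``max_iter`` iterations; per-crow memories
    update only on fitness improvement, so the best-so-far trace is
    non-decreasing.
    """
    config = config or CCSAConfig()
    if table.classes.size < 2:
        raise ValueError("table must contain at least 2 classes")
    M = table.n_features
    if M < 2:
        raise ValueError("table must contain at least 2 features")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0FFEE]))
    evaluator = _FitnessEvaluator(table, config, rng)
    H = config.n_crows

    positions = rng.uniform(config.lower, config.upper, size=(H, M))
    chaos = rng.uniform(0.05, 0.95, size=H)  # per-crow chaotic state
    map_fn = CHAOTIC_MAPS[config.chaotic_map]

    def binarize(pos_row: np.ndarray) -> np.ndarray:
        mask = transfer_and_binarize(pos_row, rng.uniform(size=M), config.flip_transfer)
        if mask.sum() == 0:
            mask[rng.integers(0, M)] = 1  # repair: at least one feature
        return mask

    memory_masks = np.empty((H, M), dtype=np.int8)
    memory_fitness = np.full(H, -np.inf)
    memory_positions = positions.copy()
    for l in range(H):
        memory_masks[l] = binarize(positions[l])
        memory_fitness[l] = evaluator.fitness(memory_masks[l])

    history = np.empty(config.max_iter)
    for tau in range(config.max_iter):
        for l in range(H):
            chaos[l] = float(np.clip(map_fn(chaos[l]), _EPS, 1.0 - _EPS))
            varsigma = chaos[l]
            peer = int(rng.integers(0, H))
            positions[l] = update_position(
                positions[l], memory_positions[peer], varsigma, config, rng
            )

            mask = binarize(positions[l])
            fit = evaluator.fitness(mask)
            if fit > memory_fitness[l]:
                memory_fitness[l] = fit
                memory_masks[l] = mask
                memory_positions[l] = positions[l].copy()
        history[tau] = memory_fitness.max()

    best = int(np.argmax(memory_fitness))
    return CCSAResult(
        best_mask=memory_masks[best].copy(),
        best_fitness=float(memory_fitness[best]),
        history=history,
        n_evaluations=evaluator.n_evaluations,
        evaluation_log=evaluator.evaluation_log,
    )


def exhaustive_select(
    table: FeatureTable, config: CCSAConfig | None = None
) -> CCSAResult:
    """Evaluate every non-empty mask (feasible only for small M).

    Uses the same frozen folds and forest seed that :func:`ccsa_select`
    would derive from ``config.seed``, so its optimum is directly
    comparable with the wrapper's best fitness.
    """
    config = config or CCSAConfig()
    M = table.n_features
    if M > 16:
        raise ValueError("exhaustive search is limited to M <= 16 features")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0FFEE]))
    evaluator = _FitnessEvaluator(table, config, rng)
    best_fit = -np.inf
    best_mask = None
    for bits in range(1, 2**M):
        mask = np.array([(bits >> j) & 1 for j in range(M)], dtype=np.int8)
        fit = evaluator.fitness(mask)
        if fit > best_fit:
            best_fit = fit
            best_mask = mask
    return CCSAResult(
        best_mask=best_mask,
        best_fitness=float(best_fit),
        history=np.array([best_fit]),
        n_evaluations=evaluator.n_evaluations,
        evaluation_log=evaluator.evaluation_log,
    )
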