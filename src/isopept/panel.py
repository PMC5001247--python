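"""Marker-panel selection with a small feed-forward network and ROC AUC.

Samples are encoded as binary marker-presence vectors; outcomes use a
two-node scheme, cancer = (1, 0) and healthy = (0, 1).  The classifier is
a fixed N-7-2 fully connected network with sigmoid activations trained by
full-batch gradient descent with momentum on the cross-entropy loss.
Panels are chosen by training one network per marker combination on the
training cohort and ranking combinations by the AUC of the cancer-node
score on an independent test cohort.

Training is vectorized across many networks at once (a batch axis over
weight tensors), which makes exhaustive combination searches practical:
all C(26, 5) = 65 780 five-marker panels train in a few einsum-sized
matmuls per epoch.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import rankdata

__all__ = [
    "EncodedDataset", "PanelNetwork", "PanelSearchResult",
    "encode", "decode", "train", "predict", "roc_auc", "select_panel",
    "evaluate",
]

N_HIDDEN = 7
CANCER_CODE = (1, 0)
HEALTH_CODE = (0, 1)

_LABELS = {"cancer": CANCER_CODE, "health": HEALTH_CODE,
           "healthy": HEALTH_CODE}


@dataclass
class EncodedDataset:
    """Binary marker presences X (samples x N) with two-node outcomes Y."""

    X: np.ndarray
    Y: np.ndarray
    labels: list[str]
    markers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] < 1:
            raise ValueError("X must be samples x N with N >= 1")
        if self.Y.shape != (self.X.shape[0], 2):
            raise ValueError("Y must be samples x 2")
        if not self.markers:
            self.markers = [f"m{i}" for i in range(self.X.shape[1])]

    def subset(self, columns) -> "EncodedDataset":
        cols = list(columns)
        return EncodedDataset(self.X[:, cols], self.Y, list(self.labels),
                              [self.markers[c] for c in cols])


@dataclass
class PanelNetwork:
    """An N-7-2 sigmoid network: weights, biases and training metadata."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    seed: int
    loss: float

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[0]


@dataclass
class PanelSearchResult:
    best_combination: tuple[str, ...]
    best_auc: float
    network: PanelNetwork
    auc_table: list[tuple[tuple[str, ...], float]]
    n_evaluated: int
    objective: str


def encode(labels) -> np.ndarray:
    """Map outcome labels to the two-node codes cancer=(1,0), healthy=(0,1)."""
    rows = []
    for lab in labels:
        try:
            rows.append(_LABELS[str(lab).lower()])
        except KeyError:
            raise ValueError(f"unknown outcome label: {lab!r}") from None
    return np.array(rows, dtype=float)


def decode(codes) -> list[str]:
    """Inverse of :func:`encode` (exact codes only)."""
    out = []
    for row in np.asarray(codes):
        if tuple(int(v) for v in row) == CANCER_CODE:
            out.append("cancer")
        elif tuple(int(v) for v in row) == HEALTH_CODE:
            out.append("health")
        else:
            raise ValueError(f"not a valid outcome code: {row}")
    return out


def _init_params(rng, B: int, n_in: int, dtype):
    scale1 = 1.0 / math.sqrt(n_in)
    scale2 = 1.0 / math.sqrt(N_HIDDEN)
    W1 = rng.uniform(-scale1, scale1, size=(B, n_in, N_HIDDEN)).astype(dtype)
    b1 = np.zeros((B, N_HIDDEN), dtype=dtype)
    W2 = rng.uniform(-scale2, scale2, size=(B, N_HIDDEN, 2)).astype(dtype)
    b2 = np.zeros((B, 2), dtype=dtype)
    return W1, b1, W2, b2


def _forward(X, W1, b1, W2, b2):
    H = expit(X @ W1 + b1[:, None, :])
    O = expit(H @ W2 + b2[:, None, :])
    return H, O


def _batch_train(X, Y, B, rng, epochs, lr, momentum, dtype=np.float64):
    """Train B networks in parallel by full-batch gradient descent.

    ``X`` is (B, S, N) or (1, S, N) broadcast to every network; ``Y`` is
    (S, 2).  Returns weights and the final mean cross-entropy per network.
    """
    S = X.shape[1]
    n_in = X.shape[2]
    W1, b1, W2, b2 = _init_params(rng, B, n_in, dtype)
    vW1 = np.zeros_like(W1); vb1 = np.zeros_like(b1)
    vW2 = np.zeros_like(W2); vb2 = np.zeros_like(b2)
    Yb = Y[None, :, :].astype(dtype)
    Xt = X.transpose(0, 2, 1)
    for _ in range(epochs):
        H, O = _forward(X, W1, b1, W2, b2)
        dZ2 = (O - Yb) / S
        gW2 = H.transpose(0, 2, 1) @ dZ2
        gb2 = dZ2.sum(axis=1)
        dH = (dZ2 @ W2.transpose(0, 2, 1)) * H * (1.0 - H)
        if Xt.shape[0] == 1 and B > 1:
            gW1 = np.einsum("ns,bsh->bnh", Xt[0], dH)
        else:
            gW1 = Xt @ dH
        gb1 = dH.sum(axis=1)
        vW1 = momentum * vW1 - lr * gW1; W1 = W1 + vW1
        vb1 = momentum * vb1 - lr * gb1; b1 = b1 + vb1
        vW2 = momentum * vW2 - lr * gW2; W2 = W2 + vW2
        vb2 = momentum * vb2 - lr * gb2; b2 = b2 + vb2
    _, O = _forward(X, W1, b1, W2, b2)
    Oc = np.clip(O, 1e-9, 1.0 - 1e-9)
    loss = -(Yb * np.log(Oc) + (1 - Yb) * np.log(1 - Oc)).sum(axis=(1, 2)) / S
    return (W1, b1, W2, b2), np.asarray(loss, dtype=float)


def train(ds: EncodedDataset, seed: int = 0, restarts: int = 5,
          epochs: int = 500, lr: float = 0.5, momentum: float = 0.9
          ) -> PanelNetwork:
    """Train one N-7-2 network; best of ``restarts`` random inits by loss.

    Deterministic given ``seed``.  Raises on single-class data.
    """
    classes = {tuple(row) for row in ds.Y.astype(int)}
    if len(classes) < 2:
        raise ValueError("training data contains a single outcome class")
    rng = np.random.default_rng(seed)
    X = ds.X[None, :, :].repeat(restarts, axis=0)
    (W1, b1, W2, b2), losses = _batch_train(
        X, ds.Y, restarts, rng, epochs, lr, momentum)
    best = int(np.argmin(losses))
    return PanelNetwork(W1=W1[best], b1=b1[best], W2=W2[best], b2=b2[best],
                        seed=seed, loss=float(losses[best]))


def predict(net: PanelNetwork, X) -> tuple[np.ndarray, list[str]]:
    """Cancer-node scores and hard labels for samples ``X``.

    The label is the argmax of the two output nodes; an exact tie (the
    degenerate (1,1)/(0,0)-style outcome) resolves to healthy.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != net.n_inputs:
        raise ValueError(
            f"input width {X.shape} does not match network ({net.n_inputs})")
    _, O = _forward(X[None, :, :], net.W1[None], net.b1[None],
                    net.W2[None], net.b2[None])
    O = O[0]
    scores = O[:, 0]
    labels = ["cancer" if c > h else "health" for c, h in O]
    return scores, labels


def roc_auc(scores, truth) -> float:
    """Mann-Whitney AUC: P(score_cancer > score_health) + 0.5 P(equal)."""
    scores = np.asarray(scores, dtype=float)
    is_cancer = np.array([str(t).lower() == "cancer" for t in truth])
    n_c = int(is_cancer.sum())
    n_h = int(len(is_cancer) - n_c)
    if n_c == 0 or n_h == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)
    return float((ranks[is_cancer].sum() - n_c * (n_c + 1) / 2) / (n_c * n_h))


def _auc_batch(scores: np.ndarray, is_cancer: np.ndarray) -> np.ndarray:
    ranks = rankdata(scores, axis=1)
    n_c = int(is_cancer.sum())
    n_h = int(is_cancer.size - n_c)
    return (ranks[:, is_cancer].sum(axis=1) - n_c * (n_c + 1) / 2) / (n_c * n_h)


def select_panel(
    train_ds: EncodedDataset,
    test_ds: EncodedDataset,
    N: int,
    candidates: list[str] | None = None,
    mode: str = "exhaustive",
    budget: int = 100_000,
    seed: int = 0,
    objective: str = "max",
    epochs: int = 60,
    lr: float = 0.5,
    momentum: float = 0.9,
    restarts: int = 1,
    chunk_size: int = 4096,
) -> PanelSearchResult:
    """Search N-marker combinations by test-cohort AUC.

    ``mode="exhaustive"`` enumerates all C(|candidates|, N) combinations
    when that count fits the ``budget``, otherwise (or with
    ``mode="random"``) a seeded sample of ``budget`` combinations is
    drawn.  Each combination trains a fresh network on ``train_ds`` and
    is scored by the AUC of its cancer score on ``test_ds``; the
    AUC-maximizing combination is returned (``objective="min"`` flips the
    criterion).  Deterministic given ``seed`` and identical parameters.
    """
    if candidates is None:
        candidates = list(train_ds.markers)
    if N > len(candidates):
        raise ValueError(f"cannot choose {N} of {len(candidates)} candidates")
    if objective not in ("max", "min"):
        raise ValueError("objective must be 'max' or 'min'")
    name_to_col = {m: i for i, m in enumerate(train_ds.markers)}
    cand_cols = [name_to_col[c] for c in candidates]
    if [test_ds.markers[c] for c in cand_cols] != candidates:
        raise ValueError("train and test marker columns do not line up")

    n_total = math.comb(len(candidates), N)
    rng = np.random.default_rng(seed)
    if mode == "exhaustive" and n_total <= budget:
        combos = list(itertools.combinations(range(len(cand_cols)), N))
    else:
        seen = set()
        pool = np.arange(len(cand_cols))
        target = min(budget, n_total)
        while len(seen) < target:
            seen.add(tuple(sorted(rng.choice(pool, size=N, replace=False))))
        combos = sorted(seen)

    is_cancer = np.array([str(t).lower() == "cancer" for t in test_ds.labels])
    dtype = np.float32 if len(combos) > 64 else np.float64
    auc_table: list[tuple[tuple[str, ...], float]] = []
    best_idx, best_auc, best_net = -1, None, None

    for start in range(0, len(combos), chunk_size):
        chunk = combos[start:start + chunk_size]
        cols = np.array([[cand_cols[i] for i in combo] for combo in chunk])
        Xtr = np.ascontiguousarray(train_ds.X[:, cols].transpose(1, 0, 2),
                                   dtype=dtype)
        Xte = np.ascontiguousarray(test_ds.X[:, cols].transpose(1, 0, 2),
                                   dtype=dtype)
        B = len(chunk) * restarts
        if restarts > 1:
            Xtr = np.repeat(Xtr, restarts, axis=0)
        (W1, b1, W2, b2), losses = _batch_train(
            Xtr, train_ds.Y, B, rng, epochs, lr, momentum, dtype=dtype)
        if restarts > 1:
            pick = losses.reshape(len(chunk), restarts).argmin(axis=1)
            sel = np.arange(len(chunk)) * restarts + pick
            W1, b1, W2, b2 = W1[sel], b1[sel], W2[sel], b2[sel]
        _, O = _forward(Xte, W1, b1, W2, b2)
        aucs = _auc_batch(np.asarray(O[:, :, 0], dtype=float), is_cancer)
        for j, combo in enumerate(chunk):
            names = tuple(candidates[i] for i in combo)
            auc = float(aucs[j])
            auc_table.append((names, auc))
            better = (best_auc is None
                      or (objective == "max" and auc > best_auc)
                      or (objective == "min" and auc < best_auc))
            if better:
                best_idx, best_auc = start + j, auc
                best_net = PanelNetwork(
                    W1=np.asarray(W1[j], dtype=float),
                    b1=np.asarray(b1[j], dtype=float),
                    W2=np.asarray(W2[j], dtype=float),
                    b2=np.asarray(b2[j], dtype=float),
                    seed=seed, loss=float(losses[j] if restarts == 1
                                          else losses.reshape(-1, restarts)
                                          [j].min()))
    return PanelSearchResult(
        best_combination=tuple(candidates[i] for i in combos[best_idx]),
        best_auc=float(best_auc),
        network=best_net,
        auc_table=auc_table,
        n_evaluated=len(combos),
        objective=objective,
    )


def evaluate(pred_labels, truth) -> tuple[float, dict[str, float]]:
    """Overall and per-class prediction accuracy as fractions."""
    pred = [str(x).lower() for x in pred_labels]
    true = [str(x).lower() for x in truth]
    if not true or len(pred) != len(true):
        raise ValueError("prediction and truth lengths differ or are empty")
    overall = sum(p == t for p, t in zip(pred, true)) / len(true)
    per_class = {}
    for cls in sorted(set(true)):
        idx = [i for i, t in enumerate(true) if t == cls]
        per_class[cls] = sum(pred[i] == true[i] for i in idx) / len(idx)
    return overall, per_class
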