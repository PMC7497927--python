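"""The lesion-patch classifier ("Net-Pos") and its training loop.

A six-layer LeNet-style network maps a 28×28 normalized-intensity patch
to the probability that the patch is a lesion patch: two 5×5
convolutions (6 and 16 channels) each followed by ReLU and 2×2 max
pooling, then dense layers of 120 and 84 units onto a single sigmoid
output.  Feature-map sizes follow the usual convolution arithmetic
``(H + 2P − F)/S + 1`` and are exposed by :meth:`NetPosSpec.shape_chain`
so the architecture can be audited without running a forward pass.

Training minimizes the mean binary cross-entropy with stochastic
gradient descent with momentum (``lr=0.01``, ``ρ=0.9`` by default).  The
dataset-level entry point :func:`train` splits blocks 80/20 **by
patient** — no patient contributes to both sides — and stops when the
epoch cost plateaus.

The classifier is also exposed as a scikit-learn estimator,
:class:`NetPosClassifier`, so it composes with sklearn model selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn

__all__ = [
    "NetPosSpec",
    "TrainConfig",
    "NetPosModel",
    "build_model",
    "bce_loss",
    "sgdm_step",
    "train",
    "classify_block",
    "NetPosClassifier",
    "save_checkpoint",
    "load_checkpoint",
]

bce_loss = nn.bce_loss
sgdm_step = nn.sgdm_step


@dataclass(frozen=True)
class NetPosSpec:
    """Architecture hyperparameters of the patch classifier."""

    input_shape: tuple[int, int, int] = (1, 28, 28)
    conv1: dict = field(default_factory=lambda: dict(K=6, F=5, S=1, P=2))
    pool1: dict = field(default_factory=lambda: dict(F=2, S=2))
    conv2: dict = field(default_factory=lambda: dict(K=16, F=5, S=1, P=0))
    pool2: dict = field(default_factory=lambda: dict(F=2, S=2))
    fc1: int = 120
    fc2: int = 84
    n_out: int = 1

    def shape_chain(self) -> list[tuple[int, ...]]:
        """Feature-map shapes after each conv/pool stage plus the
        flattened length, from convolution arithmetic."""
        d, h, w = self.input_shape
        chain = []
        for conv, pool in ((self.conv1, self.pool1), (self.conv2, self.pool2)):
            h = (h + 2 * conv["P"] - conv["F"]) // conv["S"] + 1
            w = (w + 2 * conv["P"] - conv["F"]) // conv["S"] + 1
            d = conv["K"]
            chain.append((d, h, w))
            h //= pool["S"]
            w //= pool["S"]
            chain.append((d, h, w))
        chain.append((d * h * w,))
        return chain

    def parameter_count(self) -> int:
        """Trainable parameter total by layer-wise counting."""
        d_in = self.input_shape[0]
        c1 = self.conv1["K"] * (d_in * self.conv1["F"] ** 2 + 1)
        c2 = self.conv2["K"] * (self.conv1["K"] * self.conv2["F"] ** 2 + 1)
        flat = self.shape_chain()[-1][0]
        f1 = self.fc1 * (flat + 1)
        f2 = self.fc2 * (self.fc1 + 1)
        out = self.n_out * (self.fc2 + 1)
        return c1 + c2 + f1 + f2 + out


@dataclass
class TrainConfig:
    """Optimization settings: lr and momentum default to the method's
    stated values; schedule details (batch size, epochs, plateau rule)
    are package conventions."""

    lr: float = 0.01
    momentum: float = 0.9
    batch_size: int = 64
    max_epochs: int = 20
    tol: float = 1e-3            # relative epoch-cost improvement for plateau
    min_cost: float = 1e-3       # "loss tends to zero": stop below this cost
    split_fraction: float = 0.8  # train share of the by-patient split
    seed: int = 0
    literal_momentum: bool = False

    def __post_init__(self):
        if not self.lr > 0:
            raise ValueError("lr must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")


class NetPosModel:
    """A built network plus its bookkeeping (seed, iteration count,
    optimizer velocity).  Thin wrapper over :class:`amcl.nn.Sequential`
    that exposes exactly the derivatives the rest of the method needs."""

    # Grad-CAM reads the last conv layer's output (pre-ReLU, as a hook
    # on the conv module would see it); its backpropagated gradient
    # already carries the downstream ReLU mask
    GRADCAM_NODE = "conv2"

    def __init__(self, spec: NetPosSpec, seed: int):
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        c1, c2 = spec.conv1, spec.conv2
        flat = spec.shape_chain()[-1][0]
        self.net = nn.Sequential([
            ("conv1", nn.Conv2d(spec.input_shape[0], c1["K"], c1["F"],
                                c1["S"], c1["P"], rng=rng)),
            ("relu1", nn.ReLU()),
            ("pool1", nn.MaxPool2d(spec.pool1["F"])),
            ("conv2", nn.Conv2d(c1["K"], c2["K"], c2["F"], c2["S"], c2["P"],
                                rng=rng)),
            ("relu2", nn.ReLU()),
            ("pool2", nn.MaxPool2d(spec.pool2["F"])),
            ("flatten", nn.Flatten()),
            ("fc1", nn.Linear(flat, spec.fc1, rng=rng)),
            ("relu3", nn.ReLU()),
            ("fc2", nn.Linear(spec.fc1, spec.fc2, rng=rng)),
            ("relu4", nn.ReLU()),
            ("out", nn.Linear(spec.fc2, spec.n_out, rng=rng)),
        ])
        self.iteration = 0
        self.velocity = {k: np.zeros_like(v) for k, v in self.net.params().items()}
        self.prev_params = {k: v.copy() for k, v in self.net.params().items()}

    # ---- forward -----------------------------------------------------
    @staticmethod
    def _as_batch(blocks: np.ndarray) -> np.ndarray:
        x = np.asarray(blocks, dtype=float)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[1:] != (1, 28, 28):
            raise ValueError(f"expected 28×28 blocks, got array of shape {x.shape}")
        return x

    def logits(self, blocks: np.ndarray) -> np.ndarray:
        return self.net.forward(self._as_batch(blocks))[:, 0]

    def predict_proba(self, blocks: np.ndarray) -> np.ndarray:
        return nn.sigmoid(self.logits(blocks))

    # ---- derivatives -------------------------------------------------
    def input_gradient(self, block: np.ndarray) -> np.ndarray:
        """∂logit/∂pixels for one 28×28 block (same shape as the block)."""
        x = self._as_batch(block)
        self.net.forward(x)
        self.net.zero_grads()
        dx = self.net.backward(np.ones((x.shape[0], 1)))
        self.net.zero_grads()
        return dx[0, 0]

    def feature_maps_and_grads(self, block: np.ndarray):
        """(A, ∂logit/∂A, probability) at the last conv layer's ReLU
        output, for one block.  A has shape (K, H, W)."""
        x = self._as_batch(block)
        logit = self.net.forward(x)[:, 0]
        self.net.zero_grads()
        self.net.backward(np.ones((x.shape[0], 1)))
        fm = self.net.last_activations[self.GRADCAM_NODE][0]
        dfm = self.net.last_grads[self.GRADCAM_NODE][0]
        self.net.zero_grads()
        return fm.copy(), dfm.copy(), float(nn.sigmoid(logit[0]))

    # ---- misc --------------------------------------------------------
    @property
    def parameter_count(self) -> int:
        return int(sum(v.size for v in self.net.params().values()))


def build_model(spec: NetPosSpec | None = None, seed: int = 0) -> NetPosModel:
    """Build a freshly initialized patch classifier (seeded uniform
    fan-in initialization)."""
    return NetPosModel(spec or NetPosSpec(), seed)


def classify_block(model: NetPosModel, block: np.ndarray) -> float:
    """Lesion probability of one 28×28 block (>0.5 ⇒ lesion call)."""
    block = np.asarray(block, dtype=float)
    if block.shape != (28, 28):
        raise ValueError(f"block must be 28×28, got {block.shape}")
    return float(model.predict_proba(block)[0])


# ---------------------------------------------------------------------
# training
# ---------------------------------------------------------------------

def patient_split(patient_ids: np.ndarray, fraction: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (train, test) masks over blocks such that no patient
    appears on both sides and the train share is as close as possible to
    ``fraction`` while keeping both sides nonempty."""
    patients = np.unique(patient_ids)
    if patients.size < 2:
        raise ValueError("patient-wise split needs at least two patients")
    order = rng.permutation(patients)
    counts = {p: int(np.sum(patient_ids == p)) for p in patients}
    total = sum(counts.values())
    train_patients, acc = [], 0
    for p in order[:-1]:  # always leave at least one patient for test
        if acc / total >= fraction:
            break
        train_patients.append(p)
        acc += counts[p]
    if not train_patients:
        train_patients.append(order[0])
    train_mask = np.isin(patient_ids, train_patients)
    return train_mask, ~train_mask


def _run_epochs(model: NetPosModel, x: np.ndarray, y: np.ndarray,
                config: TrainConfig, rng: np.random.Generator) -> list[float]:
    history: list[float] = []
    n = x.shape[0]
    params = model.net.params()
    for _ in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_cost = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x[idx], y[idx]
            logit = model.net.forward(xb)[:, 0]
            prob = nn.sigmoid(logit)
            cost = nn.batch_cost(prob, yb)
            epoch_cost += cost * idx.size
            # d cost / d logit for sigmoid + BCE
            dlogit = (prob - yb)[:, None] / idx.size
            model.net.zero_grads()
            model.net.backward(dlogit)
            nn.sgdm_step(params, model.net.grads(), model.velocity,
                         config.lr, config.momentum,
                         literal=config.literal_momentum,
                         prev_params=model.prev_params)
            model.iteration += 1
        epoch_cost /= n
        history.append(epoch_cost)
        if epoch_cost < config.min_cost:
            break
        if len(history) >= 2:
            prev = history[-2]
            if prev > 0 and (prev - epoch_cost) / prev < config.tol:
                break
    return history


def train(model: NetPosModel, dataset, config: TrainConfig | None = None):
    """Train on a block dataset with a by-patient 80/20 split.

    ``dataset`` provides ``blocks`` (each with ``pixels``, ``label``,
    ``patient_id``) or is a plain list of such blocks.  Returns
    ``(model, loss_history, test_report)`` where the report holds
    held-out block accuracy and the patient assignment.
    """
    config = config or TrainConfig()
    blocks = getattr(dataset, "blocks", dataset)
    x = np.stack([np.asarray(b.pixels, dtype=float) for b in blocks])[:, None]
    y = np.array([b.label for b in blocks], dtype=float)
    pids = np.array([b.patient_id for b in blocks])
    rng = np.random.default_rng(config.seed)
    train_mask, test_mask = patient_split(pids, config.split_fraction, rng)

    history = _run_epochs(model, x[train_mask], y[train_mask], config, rng)

    prob_test = _batched_proba(model, x[test_mask])
    acc = float(np.mean((prob_test > 0.5) == (y[test_mask] > 0.5)))
    report = {
        "test_accuracy": acc,
        "n_train_blocks": int(train_mask.sum()),
        "n_test_blocks": int(test_mask.sum()),
        "train_patients": sorted(set(pids[train_mask])),
        "test_patients": sorted(set(pids[test_mask])),
        "final_cost": history[-1],
        "epochs": len(history),
    }
    return model, history, report


def fit_blocks(dataset, config: TrainConfig | None = None,
               spec: NetPosSpec | None = None) -> tuple[NetPosModel, list[float]]:
    """Train a fresh model on *all* blocks of a dataset (no held-out
    split) — the per-fold training used by the cross-validation
    harness, where the held-out unit is a whole patient."""
    config = config or TrainConfig()
    blocks = getattr(dataset, "blocks", dataset)
    if not len(blocks):
        raise ValueError("no blocks to train on")
    x = np.stack([np.asarray(b.pixels, dtype=float) for b in blocks])[:, None]
    y = np.array([b.label for b in blocks], dtype=float)
    model = build_model(spec, seed=config.seed)
    history = _run_epochs(model, x, y, config, np.random.default_rng(config.seed))
    return model, history


def _batched_proba(model: NetPosModel, x: np.ndarray,
                   batch: int = 512) -> np.ndarray:
    out = [model.predict_proba(x[i:i + batch, 0])
           for i in range(0, x.shape[0], batch)]
    return np.concatenate(out) if out else np.empty(0)


# ---------------------------------------------------------------------
# sklearn estimator facade
# ---------------------------------------------------------------------

class NetPosClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn wrapper around the patch classifier.

    ``fit(X, y)`` accepts blocks as ``(n, 28, 28)`` or flattened
    ``(n, 784)`` arrays with binary labels; it trains on everything it
    is given (patient-aware splitting is the responsibility of
    :func:`train` / the cross-validation harness, which operate on
    provenance-carrying block datasets).

    Parameters mirror :class:`TrainConfig`.
    """

    def __init__(self, lr: float = 0.01, momentum: float = 0.9,
                 batch_size: int = 64, max_epochs: int = 20,
                 tol: float = 1e-3, literal_momentum: bool = False,
                 random_state: int = 0):
        self.lr = lr
        self.momentum = momentum
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.tol = tol
        self.literal_momentum = literal_momentum
        self.random_state = random_state

    def _to_blocks(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 784:
            X = X.reshape(-1, 28, 28)
        if X.ndim != 3 or X.shape[1:] != (28, 28):
            raise ValueError("X must be (n, 28, 28) or (n, 784)")
        return X

    def fit(self, X, y):
        X = self._to_blocks(X)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.size:
            raise ValueError("X and y length mismatch")
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("labels must be binary {0, 1}")
        cfg = TrainConfig(lr=self.lr, momentum=self.momentum,
                          batch_size=self.batch_size,
                          max_epochs=self.max_epochs, tol=self.tol,
                          literal_momentum=self.literal_momentum,
                          seed=self.random_state)
        self.model_ = build_model(seed=self.random_state)
        rng = np.random.default_rng(self.random_state)
        self.loss_history_ = _run_epochs(self.model_, X[:, None], y, cfg, rng)
        self.n_iter_ = len(self.loss_history_)
        self.n_parameters_ = self.model_.parameter_count
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        p = _batched_proba(self.model_, self._to_blocks(X)[:, None])
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)


# ---------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------

def save_checkpoint(model: NetPosModel, path) -> None:
    """Save spec + weights + seed in one ``.npz`` file."""
    meta = json.dumps({"spec": asdict(model.spec), "seed": model.seed,
                       "iteration": model.iteration})
    arrays = {f"param/{k}": v for k, v in model.net.params().items()}
    np.savez(path, meta=np.array(meta), **arrays)


def load_checkpoint(path) -> NetPosModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        spec_d = meta["spec"]
        spec = NetPosSpec(
            input_shape=tuple(spec_d["input_shape"]),
            conv1=spec_d["conv1"], pool1=spec_d["pool1"],
            conv2=spec_d["conv2"], pool2=spec_d["pool2"],
            fc1=spec_d["fc1"], fc2=spec_d["fc2"], n_out=spec_d["n_out"])
        model = NetPosModel(spec, meta["seed"])
        model.iteration = meta["iteration"]
        params = model.net.params()
        for k in params:
            params[k][...] = data[f"param/{k}"]
    return model
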