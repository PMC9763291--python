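"""Convolutional sequence model for TCR-pMHC binding prediction.

Each input sequence (a CDR loop, plus the peptide in pan-specific mode) is
left-zero-padded to a fixed length (10 for CDR1/2, 20 for CDR3, 13 for the
peptide) and encoded residue-by-residue as its BLOSUM50 row divided by a
scale constant.  Every input is processed by its own convolution block: 1D
convolutions with 16 filters for each kernel size in {1, 3, 5, 7, 9} (80
filters per input in total), max-pooled over the length dimension.  The
pooled features are concatenated and passed through a 32-unit hidden layer
to a single output neuron; the sigmoid activation is used in all layers.

Training minimises binary cross-entropy with Adam (learning rate 0.001)
for up to 200 epochs with early stopping on a validation partition.  The
published evaluation protocol uses nested cross-validation: for k
partitions, one network per ordered (outer test fold, inner validation
fold) pair — k*(k-1) networks (20 for k=5) — whose predictions are averaged
at inference time.

The network is implemented directly on numpy (forward pass, analytic
backward pass, Adam updates); it is small enough that this runs comfortably
on a single CPU, and keeps training bitwise-reproducible from the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .kernel import load_substitution_matrix
from .repertoire import AMINO_ACIDS, Repertoire, TCRRecord

logger = logging.getLogger(__name__)

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    ``mode`` selects peptide-specific (one model per peptide; the peptide is
    constant and not an input) or pan-specific (the peptide sequence is an
    additional input block).  ``loops`` selects CDR3-only (2 loop blocks) or
    all-CDRs (6 loop blocks).
    """

    pad_cdr12: int = 10
    pad_cdr3: int = 20
    pad_peptide: int = 13
    encoding: str = "BLOSUM50"
    encoding_scale: float = 5.0
    n_filters: int = 16
    kernel_sizes: tuple[int, ...] = (1, 3, 5, 7, 9)
    hidden_units: int = 32
    activation: str = "sigmoid"  # conv + hidden layers; output is always sigmoid
    learning_rate: float = 0.001
    max_epochs: int = 200
    patience: int = 25
    batch_size: int = 64
    seed: int = 0
    mode: str = "peptide_specific"
    loops: str = "all_cdrs"

    def __post_init__(self):
        if self.pad_cdr3 < 20 or self.pad_peptide < 13:
            raise ValueError("pad lengths must cover the admissible input "
                             "(CDR3 <= 20, peptide <= 13)")
        shortest = min(self.pad_cdr12, self.pad_cdr3, self.pad_peptide)
        for k in self.kernel_sizes:
            if k % 2 == 0 or k > shortest:
                raise ValueError(f"kernel size {k} must be odd and <= the "
                                 f"shortest pad length ({shortest})")
        if self.mode not in ("peptide_specific", "pan_specific"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.loops not in ("cdr3_only", "all_cdrs"):
            raise ValueError(f"unknown loop set {self.loops!r}")
        if self.activation not in ("sigmoid", "relu"):
            raise ValueError(f"unknown activation {self.activation!r}")

    def input_specs(self) -> list[tuple[str, int]]:
        """Ordered (input name, pad length) pairs for this configuration."""
        if self.loops == "cdr3_only":
            specs = [("cdr3a", self.pad_cdr3), ("cdr3b", self.pad_cdr3)]
        else:
            specs = [("cdr1a", self.pad_cdr12), ("cdr2a", self.pad_cdr12),
                     ("cdr3a", self.pad_cdr3),
                     ("cdr1b", self.pad_cdr12), ("cdr2b", self.pad_cdr12),
                     ("cdr3b", self.pad_cdr3)]
        if self.mode == "pan_specific":
            specs.append(("peptide", self.pad_peptide))
        return specs


def encode_sequence(seq: str, pad_len: int,
                    config: ModelConfig = ModelConfig()) -> np.ndarray:
    """Encode one sequence as a (pad_len, 20) matrix, left-zero-padded.

    Row ``pad_len - len(seq) + i`` holds the BLOSUM50 row of residue ``i``
    divided by the scale constant; the leading rows are all zero.
    """
    if len(seq) > pad_len:
        raise ValueError(f"sequence of length {len(seq)} exceeds pad length "
                         f"{pad_len}: {seq!r}")
    B = load_substitution_matrix(config.encoding) / config.encoding_scale
    out = np.zeros((pad_len, 20), dtype=np.float32)
    offset = pad_len - len(seq)
    for i, a in enumerate(seq):
        try:
            out[offset + i] = B[_AA_INDEX[a]]
        except KeyError:
            raise ValueError(f"non-canonical amino acid {a!r} in {seq!r}")
    return out


def encode_repertoire(records: Repertoire | Sequence[TCRRecord],
                      config: ModelConfig) -> dict[str, np.ndarray]:
    """Stack per-input encodings: name -> (n, pad_len, 20) float32 array."""
    records = list(records)
    out = {}
    for name, pad in config.input_specs():
        arrs = np.zeros((len(records), pad, 20), dtype=np.float32)
        for i, rec in enumerate(records):
            seq = getattr(rec, name)
            if not seq:
                raise ValueError(f"record {i} has empty input {name!r}")
            arrs[i] = encode_sequence(seq, pad, config)
        out[name] = arrs
    return out


def labels_of(records: Repertoire | Sequence[TCRRecord]) -> np.ndarray:
    return np.array([r.label for r in records], dtype=np.float32)


# ---------------------------------------------------------------------------
# The network

def _act(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    return np.maximum(z, 0.0)


def _act_grad_from_output(a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "sigmoid":
        return a * (1.0 - a)
    return (a > 0.0).astype(a.dtype)


class ConvNet:
    """One CNN as described in the module docstring.

    Parameters are float64 for reproducible optimisation; inputs stay
    float32.  ``build_model`` is the conventional constructor entry point.
    """

    def __init__(self, config: ModelConfig, seed: Optional[int] = None):
        self.config = config
        self.specs = config.input_specs()
        rng = np.random.default_rng(config.seed if seed is None else seed)
        self.params: dict[str, np.ndarray] = {}
        n_feat = 0
        for name, _pad in self.specs:
            for k in config.kernel_sizes:
                fan_in = k * 20
                limit = np.sqrt(6.0 / (fan_in + config.n_filters))
                self.params[f"conv_{name}_{k}_W"] = rng.uniform(
                    -limit, limit, size=(fan_in, config.n_filters))
                self.params[f"conv_{name}_{k}_b"] = np.zeros(config.n_filters)
            n_feat += config.n_filters * len(config.kernel_sizes)
        self.n_features = n_feat
        limit = np.sqrt(6.0 / (n_feat + config.hidden_units))
        self.params["dense1_W"] = rng.uniform(
            -limit, limit, size=(n_feat, config.hidden_units))
        self.params["dense1_b"] = np.zeros(config.hidden_units)
        limit = np.sqrt(6.0 / (config.hidden_units + 1))
        self.params["dense2_W"] = rng.uniform(
            -limit, limit, size=(config.hidden_units, 1))
        self.params["dense2_b"] = np.zeros(1)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward / backward -------------------------------------------------

    def _forward(self, X: Mapping[str, np.ndarray], want_cache: bool = False):
        cfg = self.config
        n = next(iter(X.values())).shape[0]
        feats = []
        cache: dict[str, np.ndarray] = {}
        for name, pad in self.specs:
            x = X[name]
            for k in cfg.kernel_sizes:
                half = k // 2
                xp = np.pad(x, ((0, 0), (half, half), (0, 0)))
                col = sliding_window_view(xp, (k, 20), axis=(1, 2))
                col = col.reshape(n, pad, k * 20)
                z = col @ self.params[f"conv_{name}_{k}_W"] \
                    + self.params[f"conv_{name}_{k}_b"]
                a = _act(z, cfg.activation)
                arg = a.argmax(axis=1)                       # (n, filters)
                pooled = np.take_along_axis(a, arg[:, None, :], axis=1)[:, 0, :]
                feats.append(pooled)
                if want_cache:
                    cache[f"col_{name}_{k}"] = col
                    cache[f"a_{name}_{k}"] = a
                    cache[f"arg_{name}_{k}"] = arg
        F = np.concatenate(feats, axis=1)
        h_pre = F @ self.params["dense1_W"] + self.params["dense1_b"]
        h = _act(h_pre, cfg.activation)
        logit = (h @ self.params["dense2_W"] + self.params["dense2_b"]).ravel()
        p = 1.0 / (1.0 + np.exp(-logit))
        if want_cache:
            cache["F"] = F
            cache["h"] = h
            cache["p"] = p
        return p, cache

    def _backward(self, X, y, cache) -> dict[str, np.ndarray]:
        cfg = self.config
        n = y.shape[0]
        p, F, h = cache["p"], cache["F"], cache["h"]
        grads: dict[str, np.ndarray] = {}
        dlogit = (p - y) / n                                  # BCE + sigmoid
        grads["dense2_W"] = h.T @ dlogit[:, None]
        grads["dense2_b"] = np.array([dlogit.sum()])
        dh = dlogit[:, None] @ self.params["dense2_W"].T
        dh_pre = dh * _act_grad_from_output(h, cfg.activation)
        grads["dense1_W"] = F.T @ dh_pre
        grads["dense1_b"] = dh_pre.sum(axis=0)
        dF = dh_pre @ self.params["dense1_W"].T
        offset = 0
        nf = cfg.n_filters
        for name, pad in self.specs:
            for k in cfg.kernel_sizes:
                dpooled = dF[:, offset:offset + nf]
                offset += nf
                a = cache[f"a_{name}_{k}"]
                arg = cache[f"arg_{name}_{k}"]
                da = np.zeros_like(a)
                np.put_along_axis(da, arg[:, None, :], dpooled[:, None, :], axis=1)
                dz = da * _act_grad_from_output(a, cfg.activation)
                col = cache[f"col_{name}_{k}"]
                grads[f"conv_{name}_{k}_W"] = (
                    col.reshape(-1, col.shape[-1]).T @ dz.reshape(-1, nf))
                grads[f"conv_{name}_{k}_b"] = dz.sum(axis=(0, 1))
        return grads

    def _adam_step(self, grads: Mapping[str, np.ndarray],
                   beta1: float = 0.9, beta2: float = 0.999,
                   eps: float = 1e-8) -> None:
        self._adam_t += 1
        lr = self.config.learning_rate
        t = self._adam_t
        for key, g in grads.items():
            m = self._adam_m[key] = beta1 * self._adam_m[key] + (1 - beta1) * g
            v = self._adam_v[key] = beta2 * self._adam_v[key] + (1 - beta2) * g * g
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            self.params[key] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- training / inference ----------------------------------------------

    @staticmethod
    def _bce(p: np.ndarray, y: np.ndarray) -> float:
        eps = 1e-12
        return float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))

    def fit(self, X_train: Mapping[str, np.ndarray], y_train: np.ndarray,
            X_val: Mapping[str, np.ndarray], y_val: np.ndarray,
            rng: Optional[np.random.Generator] = None) -> dict[str, list[float]]:
        """Minibatch Adam with early stopping on the validation loss.

        Returns per-epoch ``train_loss``/``val_loss`` history; the weights
        of the best validation epoch are restored at the end.
        """
        cfg = self.config
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        n = y_train.shape[0]
        history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
        best_val = np.inf
        best_params = {k: v.copy() for k, v in self.params.items()}
        stale = 0
        for _epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                Xb = {k: v[idx] for k, v in X_train.items()}
                yb = y_train[idx]
                p, cache = self._forward(Xb, want_cache=True)
                losses.append(self._bce(p, yb))
                grads = self._backward(Xb, yb, cache)
                self._adam_step(grads)
            val_p, _ = self._forward(X_val)
            val_loss = self._bce(val_p, y_val)
            history["train_loss"].append(float(np.mean(losses)))
            history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_params = {k: v.copy() for k, v in self.params.items()}
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
        self.params = best_params
        self.history = history
        return history

    def predict(self, X: Mapping[str, np.ndarray],
                batch_size: int = 1024) -> np.ndarray:
        """Binding probabilities in (0, 1) for encoded inputs."""
        n = next(iter(X.values())).shape[0]
        out = np.empty(n)
        for start in range(0, n, batch_size):
            Xb = {k: v[start:start + batch_size] for k, v in X.items()}
            out[start:start + Xb[next(iter(Xb))].shape[0]], _ = self._forward(Xb)
        return out

    def predict_records(self, records: Repertoire | Sequence[TCRRecord]) -> np.ndarray:
        return self.predict(encode_repertoire(records, self.config))

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        np.savez(path, **self.params,
                 __config__=np.frombuffer(
                     json.dumps(asdict(self.config)).encode(), dtype=np.uint8))

    @classmethod
    def load(cls, path) -> "ConvNet":
        data = np.load(path)
        cfg_dict = json.loads(bytes(data["__config__"]).decode())
        cfg_dict["kernel_sizes"] = tuple(cfg_dict["kernel_sizes"])
        net = cls(ModelConfig(**cfg_dict))
        for key in net.params:
            net.params[key] = data[key]
        return net


def build_model(config: ModelConfig, seed: Optional[int] = None) -> ConvNet:
    """Construct an untrained network for the given configuration."""
    return ConvNet(config, seed=seed)


# ---------------------------------------------------------------------------
# Nested cross-validation and ensembling

@dataclass
class EnsembleModel:
    """Networks from nested CV, indexed by (outer test, inner val) folds."""

    members: list[tuple[int, int, ConvNet]]
    config: ModelConfig
    histories: dict[tuple[int, int], dict] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def predict(self, X: Mapping[str, np.ndarray]) -> np.ndarray:
        """Arithmetic mean of member predictions, in (0, 1)."""
        if not self.members:
            raise ValueError("empty ensemble")
        preds = [net.predict(X) for _, _, net in self.members]
        return np.mean(preds, axis=0)

    def predict_records(self, records: Repertoire | Sequence[TCRRecord]) -> np.ndarray:
        return self.predict(encode_repertoire(records, self.config))

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        index = []
        for t, v, net in self.members:
            fname = f"member_t{t}_v{v}.npz"
            net.save(directory / fname)
            index.append({"outer": t, "inner": v, "file": fname})
        (directory / "ensemble.json").write_text(json.dumps(
            {"config": asdict(self.config), "members": index}, indent=1))

    @classmethod
    def load(cls, directory) -> "EnsembleModel":
        directory = Path(directory)
        meta = json.loads((directory / "ensemble.json").read_text())
        cfg = meta["config"]
        cfg["kernel_sizes"] = tuple(cfg["kernel_sizes"])
        config = ModelConfig(**cfg)
        members = []
        for m in meta["members"]:
            members.append((m["outer"], m["inner"],
                            ConvNet.load(directory / m["file"])))
        return cls(members, config)


def train_nested_cv(data: Repertoire, config: ModelConfig) -> EnsembleModel:
    """Train one network per ordered (outer, inner) fold pair.

    ``data`` must carry partition ids 0..k-1 (the held-out evaluation
    partition is excluded upstream).  For every ordered pair of distinct
    folds (t, v), a network is trained on the remaining k-2 folds with early
    stopping monitored on fold v — k*(k-1) networks in total.  Each member's
    seed derives from the config seed and its fold pair, so the whole
    ensemble is reproducible.

    Raises
    ------
    ValueError
        If partitions are missing, or some fold lacks one of the classes.
    """
    parts = sorted({r.partition for r in data})
    if None in parts:
        raise ValueError("all records must carry a partition id")
    if len(parts) < 3:
        raise ValueError("nested CV needs at least 3 partitions")
    by_part: dict[int, list[int]] = {p: [] for p in parts}
    for i, r in enumerate(data):
        by_part[r.partition].append(i)
    for p in parts:
        labels = {data[i].label for i in by_part[p]}
        if labels != {0, 1}:
            raise ValueError(f"fold {p} contains a single class: {labels}")

    X_all = encode_repertoire(data, config)
    y_all = labels_of(data)
    members = []
    histories = {}
    for t in parts:
        for v in parts:
            if v == t:
                continue
            train_idx = np.array([i for p in parts if p not in (t, v)
                                  for i in by_part[p]], dtype=np.int64)
            val_idx = np.array(by_part[v], dtype=np.int64)
            seed = int(np.random.SeedSequence(
                [config.seed, t, v]).generate_state(1)[0] % (2 ** 31))
            net = ConvNet(config, seed=seed)
            hist = net.fit({k: arr[train_idx] for k, arr in X_all.items()},
                           y_all[train_idx],
                           {k: arr[val_idx] for k, arr in X_all.items()},
                           y_all[val_idx],
                           rng=np.random.default_rng(seed + 1))
            members.append((t, v, net))
            histories[(t, v)] = hist
            logger.info("trained member (outer=%d, inner=%d): %d epochs, "
                        "best val loss %.4f", t, v, len(hist["val_loss"]),
                        min(hist["val_loss"]))
    return EnsembleModel(members, config, histories)
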