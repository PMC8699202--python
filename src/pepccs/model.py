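"""The two-branch CCS regression network, training loop and ensembling.

Architecture (full variant): a convolutional branch of six valid 1D
convolutions (kernel 6, stride 1; 150 channels each, 50 in the last) with a
subsampling layer (kernel = stride = 2) between convolutions 3 and 4,
flattened; in parallel a dense branch of two 250-node layers on the global
feature vector.  Both are concatenated and fed through a 600-node hidden
layer to a single linear output.  All hidden activations are ReLU.  In the
reduced variant the dense-branch layers are dropped and the six global
scalars are concatenated directly to the flatten output.

Training: Adam (learning rate 3e-4), batch size 256, mean-absolute-error
loss on CCS divided by 1000; validation MAE is recorded every
``val_interval`` iterations and at every epoch end, and the parameters of
the best validation checkpoint are returned.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError, IncompatibleEncodingError, TrainingDivergedError
from .features import EncodedDataset, FeaturizationConfig, SPATIAL_CHANNELS, N_GLOBAL_SCALARS


@dataclass(frozen=True)
class NetworkConfig:
    """Layer layout of the two-branch network."""

    conv_channels: tuple[int, ...] = (150, 150, 150, 150, 150, 50)
    conv_kernel: int = 6
    pool_after: int = 3  # subsampling sits after this many conv layers
    pool_kind: str = "max"  # or "avg"
    dense_branch: tuple[int, ...] = (250, 250)
    head_hidden: int = 600
    variant: str = "full"  # or "reduced"

    def __post_init__(self) -> None:
        if self.variant not in ("full", "reduced"):
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if not 0 < self.pool_after < len(self.conv_channels):
            raise ConfigurationError("pool_after must fall between conv layers")

    @classmethod
    def desk_scale(cls, variant: str = "full") -> "NetworkConfig":
        """A narrow configuration for CPU-scale experiments and tests.

        Same topology as the default; channel counts are reduced so that a
        model trains in minutes on one core instead of hours on a GPU.
        """
        return cls(
            conv_channels=(16, 16, 16, 16, 16, 8),
            dense_branch=(32, 32),
            head_hidden=64,
            variant=variant,
        )


def flatten_length(cfg: NetworkConfig, L: int) -> int:
    """Length of the flattened conv-branch output for input length L."""
    length = L
    for i in range(len(cfg.conv_channels)):
        length -= cfg.conv_kernel - 1
        if i + 1 == cfg.pool_after:
            length //= 2
        if length < 1:
            raise ConfigurationError(f"encoding length {L} too short for the conv stack")
    return length * cfg.conv_channels[-1]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings (Adam + MAE on CCS/1000)."""

    learning_rate: float = 3e-4
    batch_size: int = 256
    target_scale: float = 1000.0
    max_epochs: int = 50
    max_iterations: int | None = None
    val_interval: int = 1000
    seed: int = 0
    stop_val_mae: float | None = None  # early stop once val MAE (A^2) drops below
    validate_each_epoch: bool = True  # epoch-end validations on top of the interval

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.target_scale <= 0:
            raise ConfigurationError("learning rate and target scale must be positive")


class TwoBranchNetwork:
    """Forward/backward implementation of the architecture above."""

    def __init__(self, cfg: NetworkConfig, L: int, global_dim: int):
        if cfg.variant == "reduced" and global_dim != N_GLOBAL_SCALARS:
            raise ConfigurationError(
                f"reduced variant expects {N_GLOBAL_SCALARS} global features, got {global_dim}"
            )
        self.cfg = cfg
        self.L = L
        self.global_dim = global_dim

        self.convs: list[nn.Conv1D] = []
        c_in = SPATIAL_CHANNELS
        for i, c_out in enumerate(cfg.conv_channels):
            self.convs.append(
                nn.Conv1D(c_in, c_out, cfg.conv_kernel, needs_input_grad=i > 0)
            )
            c_in = c_out
        self.pool = nn.Pool1D(cfg.pool_kind)
        self.conv_relus = [nn.ReLU() for _ in self.convs]
        self.flat_dim = flatten_length(cfg, L)

        self.dense_branch: list[nn.Dense] = []
        self.dense_relus: list[nn.ReLU] = []
        if cfg.variant == "full":
            d_in = global_dim
            for d_out in cfg.dense_branch:
                self.dense_branch.append(nn.Dense(d_in, d_out))
                self.dense_relus.append(nn.ReLU())
                d_in = d_out
            merged = self.flat_dim + d_in
        else:
            merged = self.flat_dim + global_dim

        self.head1 = nn.Dense(merged, cfg.head_hidden)
        self.head_relu = nn.ReLU()
        self.head2 = nn.Dense(cfg.head_hidden, 1)
        self._layers: list[nn.Layer] = (
            self.convs + self.dense_branch + [self.head1, self.head2]
        )

    def initialize(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        for layer in self._layers:
            layer.initialize(rng)

    def params(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self._layers:
            out.extend(layer.params())
        return out

    def grads(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self._layers:
            out.extend(layer.grads())
        return out

    def set_params(self, values: list[np.ndarray]) -> None:
        own = self.params()
        if len(own) != len(values):
            raise ConfigurationError("parameter list length mismatch")
        for p, v in zip(own, values):
            p[...] = v

    def forward(self, xs: np.ndarray, xg: np.ndarray, train: bool = False) -> np.ndarray:
        h = xs
        for i, (conv, relu) in enumerate(zip(self.convs, self.conv_relus)):
            h = relu.forward(conv.forward(h, train), train)
            if i + 1 == self.cfg.pool_after:
                h = self.pool.forward(h, train)
        flat = h.reshape(h.shape[0], -1)
        if self.cfg.variant == "full":
            g = xg
            for dense, relu in zip(self.dense_branch, self.dense_relus):
                g = relu.forward(dense.forward(g, train), train)
            merged = np.concatenate([flat, g], axis=1)
        else:
            merged = np.concatenate([flat, xg], axis=1)
        h2 = self.head_relu.forward(self.head1.forward(merged, train), train)
        return self.head2.forward(h2, train)[:, 0]

    def backward(self, dpred: np.ndarray) -> None:
        d = self.head2.backward(dpred[:, None])
        d = self.head1.backward(self.head_relu.backward(d))
        dflat = d[:, : self.flat_dim]
        if self.cfg.variant == "full":
            dg = d[:, self.flat_dim :]
            for dense, relu in zip(reversed(self.dense_branch), reversed(self.dense_relus)):
                dg = dense.backward(relu.backward(dg))
        B = dflat.shape[0]
        pooled_len = self.flat_dim // self.cfg.conv_channels[-1]
        dh = dflat.reshape(B, pooled_len, self.cfg.conv_channels[-1])
        for i in range(len(self.convs) - 1, -1, -1):
            if i + 1 == self.cfg.pool_after:
                dh = self.pool.backward(dh)
            dh = self.convs[i].backward(self.conv_relus[i].backward(dh))

    def train_step(self, xs: np.ndarray, xg: np.ndarray, y: np.ndarray) -> float:
        """One MAE forward/backward pass; returns the batch loss (scaled units)."""
        pred = self.forward(xs, xg, train=True)
        err = pred - y
        loss = float(np.mean(np.abs(err)))
        self.backward(np.sign(err).astype(nn.DTYPE) / len(y))
        return loss


def build_network(
    cfg: NetworkConfig, L: int, global_dim: int, seed: int = 0
) -> TwoBranchNetwork:
    """Construct and He-initialize an untrained network."""
    net = TwoBranchNetwork(cfg, L, global_dim)
    net.initialize(seed)
    return net


@dataclass
class TrainedModel:
    """A trained network bound to its featurization."""

    network: TwoBranchNetwork
    net_config: NetworkConfig
    train_config: TrainingConfig
    feature_config: FeaturizationConfig
    feature_hash: str
    history: list[tuple[int, float]]  # (iteration, validation MAE in A^2)
    best_iteration: int

    @property
    def best_val_mae(self) -> float:
        return min(mae for _, mae in self.history)

    def save(self, path: str) -> None:
        meta = {
            "net_config": _net_cfg_dict(self.net_config),
            "train_config": asdict(self.train_config),
            "feature_config": _feat_cfg_dict(self.feature_config),
            "feature_hash": self.feature_hash,
            "history": self.history,
            "best_iteration": self.best_iteration,
            "L": self.network.L,
            "global_dim": self.network.global_dim,
        }
        arrays = {f"p{i}": p for i, p in enumerate(self.network.params())}
        np.savez(path, meta=np.bytes_(json.dumps(meta).encode()), **arrays)

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            arrays = [data[f"p{i}"] for i in range(len(data.files) - 1)]
        net_cfg = _net_cfg_from_dict(meta["net_config"])
        feat_cfg = _feat_cfg_from_dict(meta["feature_config"])
        net = TwoBranchNetwork(net_cfg, meta["L"], meta["global_dim"])
        net.set_params(arrays)
        return cls(
            network=net,
            net_config=net_cfg,
            train_config=TrainingConfig(**meta["train_config"]),
            feature_config=feat_cfg,
            feature_hash=meta["feature_hash"],
            history=[tuple(h) for h in meta["history"]],
            best_iteration=meta["best_iteration"],
        )


def _net_cfg_dict(cfg: NetworkConfig) -> dict:
    d = asdict(cfg)
    d["conv_channels"] = list(cfg.conv_channels)
    d["dense_branch"] = list(cfg.dense_branch)
    return d


def _net_cfg_from_dict(d: dict) -> NetworkConfig:
    d = dict(d)
    d["conv_channels"] = tuple(d["conv_channels"])
    d["dense_branch"] = tuple(d["dense_branch"])
    return NetworkConfig(**d)


def _feat_cfg_dict(cfg: FeaturizationConfig) -> dict:
    return {
        "L": cfg.L,
        "fixed_lengths": list(cfg.layout.fixed_lengths),
        "fractional_levels": list(cfg.layout.fractional_levels),
        "reduced": cfg.reduced,
    }


def _feat_cfg_from_dict(d: dict) -> FeaturizationConfig:
    from .features import SubsequenceLayoutConfig

    return FeaturizationConfig(
        L=d["L"],
        layout=SubsequenceLayoutConfig(
            fixed_lengths=tuple(d["fixed_lengths"]),
            fractional_levels=tuple(d["fractional_levels"]),
        ),
        reduced=d["reduced"],
    )


def _dataset_mae(net: TwoBranchNetwork, ds: EncodedDataset, scale: float) -> float:
    pred = _forward_batched(net, ds) * scale
    return float(np.mean(np.abs(pred - ds.ccs)))


def _forward_batched(
    net: TwoBranchNetwork, ds: EncodedDataset, batch: int = 256
) -> np.ndarray:
    outs = []
    for start in range(0, len(ds), batch):
        outs.append(
            net.forward(ds.spatial[start : start + batch], ds.glob[start : start + batch])
        )
    return np.concatenate(outs).astype(np.float64)


def train(
    network: TwoBranchNetwork,
    train_set: EncodedDataset,
    val_set: EncodedDataset,
    tcfg: TrainingConfig | None = None,
) -> TrainedModel:
    """Train with Adam/MAE and return the best validation checkpoint.

    Weight initialization, shuffling and batch order are all driven by
    ``tcfg.seed``, so two runs with the same seed produce identical
    histories and parameters.
    """
    tcfg = tcfg or TrainingConfig()
    if len(train_set) == 0:
        raise ValueError("empty training set")
    if train_set.ccs is None or val_set.ccs is None:
        raise ValueError("train and validation sets must carry CCS labels")
    if train_set.feature_hash != val_set.feature_hash:
        raise IncompatibleEncodingError("train/validation featurization mismatch")

    network.initialize(tcfg.seed)
    rng = np.random.default_rng(tcfg.seed + 1)
    y_train = (train_set.ccs / tcfg.target_scale).astype(nn.DTYPE)

    opt = nn.Adam(network.params(), lr=tcfg.learning_rate)
    history: list[tuple[int, float]] = []
    best_mae = np.inf
    best_params: list[np.ndarray] | None = None
    best_iter = -1
    iteration = 0
    stop = False

    def validate() -> None:
        nonlocal best_mae, best_params, best_iter, stop
        if history and history[-1][0] == iteration:
            return  # epoch end coinciding with an interval validation
        mae = _dataset_mae(network, val_set, tcfg.target_scale)
        history.append((iteration, mae))
        if mae < best_mae:
            best_mae = mae
            best_params = [p.copy() for p in network.params()]
            best_iter = iteration
        if tcfg.stop_val_mae is not None and mae < tcfg.stop_val_mae:
            stop = True

    n = len(train_set)
    for _epoch in range(tcfg.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            loss = network.train_step(
                train_set.spatial[idx], train_set.glob[idx], y_train[idx]
            )
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"non-finite loss at iteration {iteration}")
            opt.step(network.grads())
            iteration += 1
            if iteration % tcfg.val_interval == 0:
                validate()
            if stop or (tcfg.max_iterations is not None and iteration >= tcfg.max_iterations):
                stop = True
                break
        if tcfg.validate_each_epoch:
            validate()
        if stop:
            break
    validate()  # guarantee a final checkpoint (deduped if one just ran)

    network.set_params(best_params)
    return TrainedModel(
        network=network,
        net_config=network.cfg,
        train_config=tcfg,
        feature_config=train_set.config,
        feature_hash=train_set.feature_hash,
        history=history,
        best_iteration=best_iter,
    )


def predict(model: TrainedModel, data: EncodedDataset) -> np.ndarray:
    """Predicted CCS in Angstrom^2 (network output times the target scale)."""
    if data.feature_hash != model.feature_hash:
        raise IncompatibleEncodingError(
            "encoded data was produced with a different featurization config"
        )
    return _forward_batched(model.network, data) * model.train_config.target_scale


def ensemble_predict(models: list[TrainedModel], data: EncodedDataset) -> np.ndarray:
    """Mean of member predictions; members must share one featurization."""
    if not models:
        raise ValueError("ensemble must contain at least one model")
    hashes = {m.feature_hash for m in models}
    if len(hashes) != 1:
        raise IncompatibleEncodingError("ensemble members use different featurizations")
    preds = np.stack([predict(m, data) for m in models])
    return preds.mean(axis=0)


def charge_mean_baseline(
    train_charges: np.ndarray,
    train_ccs: np.ndarray,
    test_charges: np.ndarray,
) -> np.ndarray:
    """Charge-stratified mean-CCS predictor, the reference for learning tests."""
    train_charges = np.asarray(train_charges)
    preds = np.empty(len(test_charges), dtype=np.float64)
    overall = float(np.mean(train_ccs))
    means = {
        z: float(np.mean(train_ccs[train_charges == z]))
        for z in np.unique(train_charges)
    }
    for i, z in enumerate(np.asarray(test_charges)):
        preds[i] = means.get(z, overall)
    return preds
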