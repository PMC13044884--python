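"""Graph attention network regressor for molecular property prediction.

A small graph attention (GAT) stack maps a heavy-atom molecular graph with a
16-column node-feature matrix to one scalar per node; a readout (average
pooling, or the node at the first/second/last SMILES position) reduces that
to one value per molecule. The default configuration is 4 attention layers of
28 channels with tanh activations for log signal-to-concentration ratios
(5 layers for ionization-efficiency targets), trained full-batch with
RMSprop on a mean-squared-error loss.

The network is implemented directly in NumPy with analytically derived
gradients. Undirected bonds are presented to the attention layers as both
directed edges plus a self-loop on every node; attention coefficients are a
softmax over each node's in-neighborhood of a LeakyReLU-transformed pair
score, as in the standard single-head GAT formulation. All training
molecules are packed into one disjoint-union batch so each epoch is a handful
of dense matrix products plus segment reductions; training is bitwise
deterministic for a fixed seed on a fixed platform.

Node features are standardized column-wise (z-score over the training
nodes); the statistics are stored on the fitted model and re-applied at
prediction time.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, TrainingError
from .featurize import MolGraph, N_NODE_FEATURES

READOUT_MODES = ("first_node", "second_node", "last_node", "average")

LEAKY_SLOPE = 0.2


@dataclass(frozen=True)
class GNNConfig:
    """Architecture and training configuration of the GAT regressor."""

    n_layers: int = 4  # 4 for β; 5 for logIE
    channels: int = 28
    activation: str = "tanh"
    readout: str = "average"
    optimizer: str = "rmsprop"
    learning_rate: float = 1e-3
    epochs: int = 1000
    loss: str = "mse"
    seed: int = 0
    rmsprop_decay: float = 0.9
    rmsprop_eps: float = 1e-8

    def __post_init__(self):
        if self.n_layers < 1 or self.channels < 1:
            raise ConfigurationError("n_layers and channels must be >= 1")
        if self.readout not in READOUT_MODES:
            raise ConfigurationError(f"readout must be one of {READOUT_MODES}")
        if self.activation != "tanh":
            raise ConfigurationError("only tanh activations are supported")
        if self.optimizer != "rmsprop":
            raise ConfigurationError("only the rmsprop optimizer is supported")
        if self.loss != "mse":
            raise ConfigurationError("only the mse loss is supported")
        if self.epochs < 1 or self.learning_rate <= 0:
            raise ConfigurationError("epochs must be >= 1 and learning_rate > 0")


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------


class _Batch:
    """Disjoint union of graphs with precomputed segment structure.

    Directed edges (both directions of every bond, plus one self-loop per
    node) are sorted by destination; because of the self-loops every node
    owns a non-empty contiguous segment, so per-node softmax and aggregation
    reduce to ``np.*.reduceat`` calls. A second permutation sorted by source
    node serves the scatter-adds of the backward pass.
    """

    def __init__(self, graphs: list[MolGraph], features: np.ndarray):
        sizes = np.array([g.n_nodes for g in graphs])
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        n_total = int(offsets[-1])
        if features.shape != (n_total, N_NODE_FEATURES):
            raise ConfigurationError(
                f"feature matrix has shape {features.shape}, expected ({n_total}, {N_NODE_FEATURES})"
            )
        src_list, dst_list = [], []
        for g, off in zip(graphs, offsets[:-1]):
            for i, j in g.edges:
                src_list += [off + i, off + j]
                dst_list += [off + j, off + i]
            for i in range(g.n_nodes):
                src_list.append(off + i)
                dst_list.append(off + i)
        src = np.asarray(src_list, dtype=np.intp)
        dst = np.asarray(dst_list, dtype=np.intp)
        order = np.lexsort((src, dst))
        self.edge_src = src[order]
        self.edge_dst = dst[order]
        self.seg_dst = np.searchsorted(self.edge_dst, np.arange(n_total))
        self.perm_src = np.lexsort((self.edge_dst, self.edge_src))
        self.seg_src = np.searchsorted(self.edge_src[self.perm_src], np.arange(n_total))

        self.X = np.ascontiguousarray(features, dtype=float)
        self.n_nodes = n_total
        self.n_graphs = len(graphs)
        self.sizes = sizes
        self.node_seg = offsets[:-1]
        self.graph_of_node = np.repeat(np.arange(self.n_graphs), sizes)

        self.readout_idx: dict[str, np.ndarray] = {}
        firsts, seconds, lasts = [], [], []
        self.second_fallbacks = 0
        for g, off in zip(graphs, offsets[:-1]):
            order_ = g.node_order
            firsts.append(off + order_[0])
            lasts.append(off + order_[-1])
            if g.n_nodes >= 2:
                seconds.append(off + order_[1])
            else:
                seconds.append(off + order_[0])
                self.second_fallbacks += 1
        self.readout_idx["first_node"] = np.asarray(firsts, dtype=np.intp)
        self.readout_idx["second_node"] = np.asarray(seconds, dtype=np.intp)
        self.readout_idx["last_node"] = np.asarray(lasts, dtype=np.intp)


def readout(node_outputs, mode: str, node_order: list[int] | None = None) -> float:
    """Reduce per-node outputs of one molecule to a single value."""
    values = np.asarray(node_outputs, dtype=float)
    if values.size == 0:
        raise ValueError("empty node output list")
    if mode not in READOUT_MODES:
        raise ConfigurationError(f"unknown readout mode {mode!r}")
    if mode == "average":
        return float(values.mean())
    order = list(node_order) if node_order is not None else list(range(values.size))
    if mode == "first_node":
        return float(values[order[0]])
    if mode == "last_node":
        return float(values[order[-1]])
    if values.size < 2:
        warnings.warn("second_node readout on a 1-atom molecule; using first node", stacklevel=2)
        return float(values[order[0]])
    return float(values[order[1]])


# ---------------------------------------------------------------------------
# parameters, forward, backward
# ---------------------------------------------------------------------------


def _init_params(config: GNNConfig, n_features: int, rng: np.random.Generator):
    layers = []
    fin = n_features
    for _ in range(config.n_layers):
        fout = config.channels
        lim_w = math.sqrt(6.0 / (fin + fout))
        lim_a = math.sqrt(6.0 / (fout + 1))
        layers.append(
            {
                "W": rng.uniform(-lim_w, lim_w, size=(fin, fout)),
                "a_src": rng.uniform(-lim_a, lim_a, size=fout),
                "a_dst": rng.uniform(-lim_a, lim_a, size=fout),
                "b": np.zeros(fout),
            }
        )
        fin = fout
    lim_o = math.sqrt(6.0 / (fin + 1))
    out = {"w": rng.uniform(-lim_o, lim_o, size=fin), "b": np.zeros(1)}
    return layers, out


def _forward(layers, out, batch: _Batch, want_cache: bool = False):
    """Per-node outputs for a batch; optionally keep the caches for backprop."""
    H = batch.X
    caches = []
    for p in layers:
        Z = H @ p["W"]
        s = Z @ p["a_dst"]  # center-node term
        d = Z @ p["a_src"]  # neighbor term
        pre = s[batch.edge_dst] + d[batch.edge_src]
        e = np.where(pre > 0, pre, LEAKY_SLOPE * pre)
        seg_max = np.maximum.reduceat(e, batch.seg_dst)
        ex = np.exp(e - seg_max[batch.edge_dst])
        denom = np.add.reduceat(ex, batch.seg_dst)
        alpha = ex / denom[batch.edge_dst]
        agg = np.add.reduceat(alpha[:, None] * Z[batch.edge_src], batch.seg_dst, axis=0)
        H_out = np.tanh(agg + p["b"])
        if want_cache:
            caches.append((H, Z, pre, alpha, H_out))
        H = H_out
    y_node = H @ out["w"] + out["b"][0]
    if want_cache:
        return y_node, H, caches
    return y_node


def _backward(layers, out, batch: _Batch, H_last, caches, dy_node):
    g_out = {"w": H_last.T @ dy_node, "b": np.array([dy_node.sum()])}
    dH = dy_node[:, None] * out["w"][None, :]
    g_layers = []
    for p, (H_in, Z, pre, alpha, H_out) in zip(reversed(layers), reversed(caches)):
        dAgg = dH * (1.0 - H_out**2)
        db = dAgg.sum(axis=0)
        dAgg_dst = dAgg[batch.edge_dst]
        Z_src = Z[batch.edge_src]
        dalpha = np.einsum("ef,ef->e", dAgg_dst, Z_src)
        # gradient of the weighted message into Z at the source nodes
        contrib = alpha[:, None] * dAgg_dst
        dZ = np.add.reduceat(contrib[batch.perm_src], batch.seg_src, axis=0)
        # softmax backward (per destination segment)
        sdot = np.add.reduceat(alpha * dalpha, batch.seg_dst)
        de = alpha * (dalpha - sdot[batch.edge_dst])
        dpre = de * np.where(pre > 0, 1.0, LEAKY_SLOPE)
        ds_node = np.add.reduceat(dpre, batch.seg_dst)
        dd_node = np.add.reduceat(dpre[batch.perm_src], batch.seg_src)
        g = {
            "a_dst": Z.T @ ds_node,
            "a_src": Z.T @ dd_node,
            "b": db,
        }
        dZ = dZ + ds_node[:, None] * p["a_dst"][None, :] + dd_node[:, None] * p["a_src"][None, :]
        g["W"] = H_in.T @ dZ
        dH = dZ @ p["W"].T
        g_layers.append(g)
    g_layers.reverse()
    return g_layers, g_out


def _readout_forward(y_node, batch: _Batch, mode: str):
    if mode == "average":
        return np.add.reduceat(y_node, batch.node_seg) / batch.sizes
    return y_node[batch.readout_idx[mode]]


def _readout_backward(dyhat, batch: _Batch, mode: str):
    dy_node = np.zeros(batch.n_nodes)
    if mode == "average":
        dy_node = dyhat[batch.graph_of_node] / batch.sizes[batch.graph_of_node]
    else:
        np.add.at(dy_node, batch.readout_idx[mode], dyhat)
    return dy_node


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


def _validate_graphs(graphs: list[MolGraph]):
    for g in graphs:
        if g.node_features is None or g.node_features.shape[1] != N_NODE_FEATURES:
            raise ConfigurationError(
                f"graph {g.molecule_id!r} lacks a {N_NODE_FEATURES}-column feature matrix"
            )
        if not np.all(np.isfinite(g.node_features)):
            raise ConfigurationError(f"graph {g.molecule_id!r} has non-finite node features")


def _stack_features(graphs: list[MolGraph]) -> np.ndarray:
    return np.concatenate([np.asarray(g.node_features, dtype=float) for g in graphs], axis=0)


class GraphAttentionRegressor:
    """Model object: featurized molecular graphs + targets + configuration.

    ``fit()`` trains the network and returns a :class:`GATResults` carrying
    the learned parameters, the loss trajectory, and prediction methods.
    """

    def __init__(self, graphs: list[MolGraph], targets, config: GNNConfig | None = None):
        if len(graphs) < 1:
            raise ConfigurationError("need at least one training molecule")
        _validate_graphs(graphs)
        y = np.asarray(targets, dtype=float)
        if y.shape != (len(graphs),):
            raise ConfigurationError("targets must align one-to-one with graphs")
        if not np.all(np.isfinite(y)):
            raise ConfigurationError("targets must be finite")
        self.graphs = list(graphs)
        self.endog = y
        self.config = config or GNNConfig()

    @classmethod
    def from_smiles(
        cls, smiles: list[str], targets, config: GNNConfig | None = None, conformer_seed: int = 17
    ) -> "GraphAttentionRegressor":
        from .featurize import featurize_smiles

        graphs = [featurize_smiles(s, molecule_id=s, conformer_seed=conformer_seed) for s in smiles]
        return cls(graphs, targets, config)

    def fit(self) -> "GATResults":
        cfg = self.config
        feats = _stack_features(self.graphs)
        mean = feats.mean(axis=0)
        std = feats.std(axis=0)
        std[std < 1e-12] = 1.0
        batch = _Batch(self.graphs, (feats - mean) / std)
        if cfg.readout == "second_node" and batch.second_fallbacks:
            warnings.warn(
                f"{batch.second_fallbacks} single-atom molecule(s): second_node readout "
                "falls back to the first node",
                stacklevel=2,
            )
        rng = np.random.default_rng(cfg.seed)
        layers, out = _init_params(cfg, N_NODE_FEATURES, rng)

        sq = [{k: np.zeros_like(v) for k, v in p.items()} for p in layers]
        sq_out = {k: np.zeros_like(v) for k, v in out.items()}
        rho, eps, lr = cfg.rmsprop_decay, cfg.rmsprop_eps, cfg.learning_rate

        y = self.endog
        training_log = []
        for epoch in range(cfg.epochs):
            y_node, H_last, caches = _forward(layers, out, batch, want_cache=True)
            yhat = _readout_forward(y_node, batch, cfg.readout)
            resid = yhat - y
            loss = float(np.mean(resid**2))
            if not math.isfinite(loss):
                raise TrainingError("training diverged to a non-finite loss", epoch=epoch)
            training_log.append(loss)
            dyhat = 2.0 * resid / len(y)
            dy_node = _readout_backward(dyhat, batch, cfg.readout)
            g_layers, g_out = _backward(layers, out, batch, H_last, caches, dy_node)
            for p, g, s in zip(layers, g_layers, sq):
                for k in p:
                    s[k] = rho * s[k] + (1 - rho) * g[k] ** 2
                    p[k] = p[k] - lr * g[k] / (np.sqrt(s[k]) + eps)
            for k in out:
                sq_out[k] = rho * sq_out[k] + (1 - rho) * g_out[k] ** 2
                out[k] = out[k] - lr * g_out[k] / (np.sqrt(sq_out[k]) + eps)

        fingerprint = hashlib.sha256()
        fingerprint.update(np.ascontiguousarray(feats).tobytes())
        fingerprint.update(np.ascontiguousarray(y).tobytes())
        fingerprint.update(repr(cfg).encode())
        return GATResults(
            model=self,
            config=cfg,
            layers=layers,
            out=out,
            feat_mean=mean,
            feat_std=std,
            training_log=training_log,
            data_fingerprint=fingerprint.hexdigest(),
        )


@dataclass
class GATResults:
    """Fitted GAT regressor: learned weights, loss trajectory, predictions."""

    model: GraphAttentionRegressor | None
    config: GNNConfig
    layers: list[dict]
    out: dict
    feat_mean: np.ndarray
    feat_std: np.ndarray
    training_log: list[float] = field(default_factory=list)
    data_fingerprint: str = ""

    @property
    def final_loss(self) -> float:
        return self.training_log[-1] if self.training_log else float("nan")

    def predict_nodes(self, graph: MolGraph) -> np.ndarray:
        """Per-node scalar outputs for one graph (inference, deterministic)."""
        _validate_graphs([graph])
        batch = _Batch([graph], (np.asarray(graph.node_features, float) - self.feat_mean) / self.feat_std)
        return _forward(self.layers, self.out, batch)

    def predict(self, graphs: list[MolGraph], readout_mode: str | None = None) -> np.ndarray:
        """One prediction per molecule, order-preserving."""
        if len(graphs) == 0:
            return np.array([])
        _validate_graphs(graphs)
        mode = readout_mode or self.config.readout
        feats = (_stack_features(graphs) - self.feat_mean) / self.feat_std
        batch = _Batch(graphs, feats)
        if mode == "second_node" and batch.second_fallbacks:
            warnings.warn(
                f"{batch.second_fallbacks} single-atom molecule(s): second_node readout "
                "falls back to the first node",
                stacklevel=2,
            )
        y_node = _forward(self.layers, self.out, batch)
        return np.asarray(_readout_forward(y_node, batch, mode), dtype=float)

    @property
    def fittedvalues(self) -> np.ndarray:
        if self.model is None:
            raise ValueError("fitted values unavailable for a deserialized checkpoint")
        return self.predict(self.model.graphs)

    def summary(self) -> str:
        cfg = self.config
        n = len(self.model.graphs) if self.model is not None else "?"
        lines = [
            "Graph Attention Network Regression Results",
            "=" * 46,
            f"No. molecules:        {n}",
            f"GAT layers:           {cfg.n_layers}  (channels={cfg.channels}, tanh)",
            f"Readout:              {cfg.readout}",
            f"Optimizer:            {cfg.optimizer} (lr={cfg.learning_rate:g})",
            f"Epochs:               {cfg.epochs}",
            f"Final training MSE:   {self.final_loss:.6g}",
            f"Data fingerprint:     {self.data_fingerprint[:16]}...",
            "=" * 46,
        ]
        return "\n".join(lines)

    # -- checkpointing ------------------------------------------------------

    def save(self, path) -> None:
        payload = {
            "config": {
                k: getattr(self.config, k)
                for k in (
                    "n_layers",
                    "channels",
                    "activation",
                    "readout",
                    "optimizer",
                    "learning_rate",
                    "epochs",
                    "loss",
                    "seed",
                    "rmsprop_decay",
                    "rmsprop_eps",
                )
            },
            "layers": [{k: v.tolist() for k, v in p.items()} for p in self.layers],
            "out": {k: v.tolist() for k, v in self.out.items()},
            "feat_mean": self.feat_mean.tolist(),
            "feat_std": self.feat_std.tolist(),
            "training_log": self.training_log,
            "data_fingerprint": self.data_fingerprint,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "GATResults":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            model=None,
            config=GNNConfig(**payload["config"]),
            layers=[{k: np.asarray(v) for k, v in p.items()} for p in payload["layers"]],
            out={k: np.asarray(v) for k, v in payload["out"].items()},
            feat_mean=np.asarray(payload["feat_mean"]),
            feat_std=np.asarray(payload["feat_std"]),
            training_log=list(payload["training_log"]),
            data_fingerprint=payload["data_fingerprint"],
        )


# functional aliases matching the operation-oriented surface


def train(dataset: list[tuple[MolGraph, float]], config: GNNConfig) -> GATResults:
    """Train a GAT regressor on (graph, target) pairs."""
    if len(dataset) < 2:
        raise ConfigurationError("need at least two training molecules")
    graphs = [g for g, _ in dataset]
    targets = [t for _, t in dataset]
    return GraphAttentionRegressor(graphs, targets, config).fit()


def forward(graph: MolGraph, model: GATResults) -> np.ndarray:
    """Per-node scalar outputs of a trained model for one graph."""
    return model.predict_nodes(graph)


def predict(model: GATResults, graphs: list[MolGraph]) -> np.ndarray:
    return model.predict(graphs)


def retrain_with_seed(results_or_model, seed: int) -> GATResults:
    """Refit the same data with a different initialization seed."""
    model = results_or_model.model if isinstance(results_or_model, GATResults) else results_or_model
    cfg = replace(model.config, seed=seed)
    return GraphAttentionRegressor(model.graphs, model.endog, cfg).fit()
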