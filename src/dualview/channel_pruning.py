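"""BatchNorm-γ structured channel pruning.

Channel importance is read off the BatchNorm scaling factors γ: during
training an L1 penalty λ·Σ|γ| drives unimportant channels' γ towards
zero, after which each prunable layer's channels are sorted by ascending
|γ| and the lowest fraction (the pruning rate) is removed, updating the
consumer layers' input-channel counts and the analytic parameter/FLOP
accounts.

Two representations are provided:

* :class:`PrunableNetSpec` — a purely structural description (per-layer
  channel counts, γ vectors, consumer links) on which ranking, pruning
  and parameter/FLOP accounting operate analytically.
* :class:`ToyConvNet` — a small executable Conv→BN→ReLU stack with a
  reference numpy forward pass, used to verify that pruning truly dead
  channels (γ = β = 0, zeroed downstream weights) preserves the network
  function exactly.

Conventions: a conv layer with kernel k, C_in inputs and C_out outputs
contributes k²·C_in·C_out weight parameters plus 2·C_out BN parameters;
FLOPs count a multiply–accumulate as 2, giving 2·k²·C_in·C_out·H·W per
layer (stride 1, same padding, so the spatial size is constant).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .errors import InvalidArgumentError

__all__ = [
    "LayerSpec", "PrunableNetSpec", "PruneConfig", "PruneReport",
    "sparsity_penalty", "rank_channels", "prune_network",
    "count_params", "count_flops",
    "ToyConvNet", "ConvLayer", "random_toy_net", "make_channels_dead",
    "prune_toy_net", "functional_equivalence_check", "sparsity_descent_demo",
]


# --- structural spec -------------------------------------------------------

@dataclass(frozen=True)
class LayerSpec:
    layer_id: str
    n_channels: int
    gammas: np.ndarray
    prunable: bool = True
    downstream_links: tuple[str, ...] = ()
    kernel_size: int = 3

    def __post_init__(self):
        g = np.asarray(self.gammas, dtype=float)
        object.__setattr__(self, "gammas", g)
        object.__setattr__(self, "downstream_links", tuple(self.downstream_links))
        if self.n_channels < 1:
            raise InvalidArgumentError("n_channels must be ≥ 1")
        if g.shape != (self.n_channels,):
            raise InvalidArgumentError(
                f"layer {self.layer_id}: {len(g)} gammas for "
                f"{self.n_channels} channels")
        if not np.all(np.isfinite(g)):
            raise InvalidArgumentError(f"layer {self.layer_id}: non-finite γ")
        if self.kernel_size < 1:
            raise InvalidArgumentError("kernel_size must be ≥ 1")


@dataclass(frozen=True)
class PrunableNetSpec:
    """Layer-wise structural description of a prunable conv network.

    ``in_channels`` is the network input depth; ``input_hw`` the spatial
    size used for FLOP accounting.  Links must form a DAG in which every
    layer has at most one producer (chains and trees of consumers).
    """

    layers: tuple[LayerSpec, ...]
    in_channels: int = 3
    input_hw: tuple[int, int] = (32, 32)

    def __post_init__(self):
        object.__setattr__(self, "layers", tuple(self.layers))
        ids = [l.layer_id for l in self.layers]
        if len(set(ids)) != len(ids):
            raise InvalidArgumentError("duplicate layer ids")
        known = set(ids)
        producers: dict[str, str] = {}
        for l in self.layers:
            for consumer in l.downstream_links:
                if consumer not in known:
                    raise InvalidArgumentError(
                        f"layer {l.layer_id} links to unknown layer {consumer}")
                if consumer in producers:
                    raise InvalidArgumentError(
                        f"layer {consumer} has multiple producers")
                producers[consumer] = l.layer_id
        self._assert_acyclic()
        object.__setattr__(self, "_producers", producers)

    def _assert_acyclic(self):
        adj = {l.layer_id: l.downstream_links for l in self.layers}
        seen: dict[str, int] = {}

        def visit(u):
            seen[u] = 1
            for v in adj[u]:
                state = seen.get(v, 0)
                if state == 1:
                    raise InvalidArgumentError("links must form a DAG")
                if state == 0:
                    visit(v)
            seen[u] = 2

        for u in adj:
            if seen.get(u, 0) == 0:
                visit(u)

    def layer(self, layer_id: str) -> LayerSpec:
        for l in self.layers:
            if l.layer_id == layer_id:
                return l
        raise InvalidArgumentError(f"no layer {layer_id}")

    def input_channels_of(self, layer_id: str) -> int:
        prod = self._producers.get(layer_id)
        if prod is None:
            return self.in_channels
        return self.layer(prod).n_channels


def count_params(spec: PrunableNetSpec) -> int:
    """Analytic learnable-parameter count: conv weights + 2 BN
    parameters per output channel."""
    total = 0
    for l in spec.layers:
        cin = spec.input_channels_of(l.layer_id)
        total += l.kernel_size ** 2 * cin * l.n_channels + 2 * l.n_channels
    return total


def count_flops(spec: PrunableNetSpec) -> int:
    """Analytic conv FLOPs (MAC = 2 FLOPs), stride 1, same padding."""
    H, W = spec.input_hw
    total = 0
    for l in spec.layers:
        cin = spec.input_channels_of(l.layer_id)
        total += 2 * l.kernel_size ** 2 * cin * l.n_channels * H * W
    return total


@dataclass(frozen=True)
class PruneConfig:
    sparsity_lambda: float = 0.005
    prune_rate: float = 0.5
    min_channels: int = 1

    def __post_init__(self):
        if self.sparsity_lambda < 0:
            raise InvalidArgumentError("sparsity_lambda must be ≥ 0")
        if not 0.0 <= self.prune_rate < 1.0:
            raise InvalidArgumentError("prune_rate must be in [0, 1)")
        if self.min_channels < 1:
            raise InvalidArgumentError("min_channels must be ≥ 1")


@dataclass
class PruneReport:
    kept: dict[str, list[int]]
    removed: dict[str, list[int]]
    params_before: int
    params_after: int
    flops_before: int
    flops_after: int

    def to_dict(self) -> dict:
        return {
            "kept": self.kept, "removed": self.removed,
            "params_before": self.params_before,
            "params_after": self.params_after,
            "flops_before": self.flops_before,
            "flops_after": self.flops_after,
            "param_reduction": 1.0 - self.params_after / self.params_before,
            "flop_reduction": 1.0 - self.flops_after / self.flops_before,
        }


def sparsity_penalty(spec: PrunableNetSpec, sparsity_lambda: float,
                     task_loss: float = 0.0) -> float:
    """λ·Σ_l Σ_c |γ| over prunable layers, plus the caller-supplied task
    loss (an opaque scalar)."""
    if sparsity_lambda < 0:
        raise InvalidArgumentError("sparsity_lambda must be ≥ 0")
    penalty = sum(float(np.abs(l.gammas).sum())
                  for l in spec.layers if l.prunable)
    return task_loss + sparsity_lambda * penalty


def rank_channels(spec: PrunableNetSpec) -> dict[str, list[int]]:
    """Per-layer channel indices sorted by ascending |γ|, ties broken by
    channel index (stable sort)."""
    return {l.layer_id: [int(i) for i in
                         np.argsort(np.abs(l.gammas), kind="stable")]
            for l in spec.layers}


def prune_network(spec: PrunableNetSpec, config: PruneConfig,
                  global_threshold: bool = False
                  ) -> tuple[PrunableNetSpec, PruneReport]:
    """Remove the floor(rate·C) lowest-|γ| channels of each prunable
    layer (never dropping below ``min_channels``); consumer layers'
    input-channel counts and the analytic parameter/FLOP accounts update
    automatically.

    With ``global_threshold`` the |γ| cutoff is instead computed over
    all prunable channels pooled together, removing floor(rate·ΣC)
    channels globally (each layer still keeps ≥ ``min_channels``).
    """
    ranking = rank_channels(spec)
    remove: dict[str, set[int]] = {l.layer_id: set() for l in spec.layers}

    if not global_threshold:
        for l in spec.layers:
            if not l.prunable:
                continue
            n_remove = min(math.floor(config.prune_rate * l.n_channels),
                           l.n_channels - config.min_channels)
            remove[l.layer_id] = set(ranking[l.layer_id][:max(n_remove, 0)])
    else:
        pool = [(float(abs(l.gammas[c])), l.layer_id, c)
                for l in spec.layers if l.prunable
                for c in range(l.n_channels)]
        pool.sort()
        budget = math.floor(config.prune_rate * len(pool))
        capacity = {l.layer_id: l.n_channels - config.min_channels
                    for l in spec.layers}
        for _, lid, c in pool:
            if budget <= 0:
                break
            if capacity[lid] > 0:
                remove[lid].add(c)
                capacity[lid] -= 1
                budget -= 1

    new_layers = []
    kept: dict[str, list[int]] = {}
    removed: dict[str, list[int]] = {}
    for l in spec.layers:
        rm = remove[l.layer_id]
        keep = [c for c in range(l.n_channels) if c not in rm]
        kept[l.layer_id] = keep
        removed[l.layer_id] = sorted(rm)
        new_layers.append(replace(l, n_channels=len(keep),
                                  gammas=l.gammas[keep]))
    new_spec = PrunableNetSpec(layers=tuple(new_layers),
                               in_channels=spec.in_channels,
                               input_hw=spec.input_hw)
    report = PruneReport(kept=kept, removed=removed,
                         params_before=count_params(spec),
                         params_after=count_params(new_spec),
                         flops_before=count_flops(spec),
                         flops_after=count_flops(new_spec))
    return new_spec, report


# --- spec YAML I/O ---------------------------------------------------------

def write_spec_yaml(spec: PrunableNetSpec, path) -> None:
    doc = {"in_channels": spec.in_channels,
           "input_hw": list(spec.input_hw),
           "layers": [{"layer_id": l.layer_id, "n_channels": l.n_channels,
                       "gammas": l.gammas.tolist(), "prunable": l.prunable,
                       "downstream_links": list(l.downstream_links),
                       "kernel_size": l.kernel_size} for l in spec.layers]}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def read_spec_yaml(path) -> PrunableNetSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    layers = [LayerSpec(layer_id=d["layer_id"], n_channels=d["n_channels"],
                        gammas=np.asarray(d["gammas"], float),
                        prunable=d.get("prunable", True),
                        downstream_links=tuple(d.get("downstream_links", ())),
                        kernel_size=d.get("kernel_size", 3))
              for d in doc["layers"]]
    return PrunableNetSpec(layers=tuple(layers),
                           in_channels=doc.get("in_channels", 3),
                           input_hw=tuple(doc.get("input_hw", (32, 32))))


# --- executable toy network ------------------------------------------------

_BN_EPS = 1e-5


@dataclass
class ConvLayer:
    """Conv(k×k, stride 1, same padding) → BatchNorm → ReLU with frozen
    statistics; weights (C_out, C_in, k, k)."""

    weight: np.ndarray
    gamma: np.ndarray
    beta: np.ndarray
    running_mean: np.ndarray
    running_var: np.ndarray
    prunable: bool = True

    @property
    def out_channels(self) -> int:
        return self.weight.shape[0]

    @property
    def in_channels(self) -> int:
        return self.weight.shape[1]

    @property
    def kernel_size(self) -> int:
        return self.weight.shape[2]


@dataclass
class ToyConvNet:
    layers: list[ConvLayer]
    in_channels: int
    input_hw: tuple[int, int]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Reference forward pass of the Conv–BN–ReLU stack."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 3 or x.shape[0] != self.in_channels:
            raise InvalidArgumentError(
                f"input must be ({self.in_channels}, H, W), got {x.shape}")
        for layer in self.layers:
            if x.shape[0] != layer.in_channels:
                raise InvalidArgumentError("channel mismatch between layers")
            x = _conv_same(x, layer.weight)
            x = (x - layer.running_mean[:, None, None]) \
                / np.sqrt(layer.running_var[:, None, None] + _BN_EPS)
            x = layer.gamma[:, None, None] * x + layer.beta[:, None, None]
            x = np.maximum(x, 0.0)
        return x

    def to_spec(self) -> PrunableNetSpec:
        layers = []
        ids = [f"conv{i}" for i in range(len(self.layers))]
        for i, layer in enumerate(self.layers):
            links = (ids[i + 1],) if i + 1 < len(self.layers) else ()
            layers.append(LayerSpec(
                layer_id=ids[i], n_channels=layer.out_channels,
                gammas=layer.gamma.copy(), prunable=layer.prunable,
                downstream_links=links, kernel_size=layer.kernel_size))
        return PrunableNetSpec(layers=tuple(layers),
                               in_channels=self.in_channels,
                               input_hw=self.input_hw)


def _conv_same(x: np.ndarray, weight: np.ndarray) -> np.ndarray:
    k = weight.shape[2]
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # windows: (C_in, H, W, k, k); weight: (C_out, C_in, k, k)
    return np.einsum("chwij,ocij->ohw", windows, weight)


def random_toy_net(channel_sizes, in_channels: int = 3,
                   input_hw: tuple[int, int] = (8, 8), kernel_size: int = 3,
                   seed: int = 0, last_prunable: bool = False) -> ToyConvNet:
    """Seeded random Conv–BN–ReLU stack; the last layer is kept
    non-prunable by default so pruned and dense nets stay output-shape
    compatible."""
    rng = np.random.default_rng(seed)
    layers = []
    cin = in_channels
    for i, cout in enumerate(channel_sizes):
        layers.append(ConvLayer(
            weight=rng.normal(0, 1 / np.sqrt(cin * kernel_size ** 2),
                              size=(cout, cin, kernel_size, kernel_size)),
            gamma=rng.uniform(0.2, 1.5, size=cout),
            beta=rng.normal(0, 0.1, size=cout),
            running_mean=rng.normal(0, 0.1, size=cout),
            running_var=rng.uniform(0.5, 1.5, size=cout),
            prunable=last_prunable or i + 1 < len(channel_sizes)))
        cin = cout
    return ToyConvNet(layers=layers, in_channels=in_channels,
                      input_hw=input_hw)


def make_channels_dead(net: ToyConvNet, dead: dict[int, list[int]]) -> ToyConvNet:
    """Return a copy with the given {layer_index: channels} made exactly
    dead: γ = β = 0 and the consuming layer's weights for those input
    channels zeroed."""
    import copy
    out = copy.deepcopy(net)
    for li, chans in dead.items():
        layer = out.layers[li]
        for c in chans:
            layer.gamma[c] = 0.0
            layer.beta[c] = 0.0
        if li + 1 < len(out.layers):
            out.layers[li + 1].weight[:, chans] = 0.0
    return out


def prune_toy_net(net: ToyConvNet, keep: dict[int, list[int]]) -> ToyConvNet:
    """Structurally remove channels: slice each layer's output side and
    the next layer's input side by the kept indices."""
    import copy
    out = copy.deepcopy(net)
    for li in sorted(keep):
        idx = list(keep[li])
        layer = out.layers[li]
        layer.weight = layer.weight[idx]
        layer.gamma = layer.gamma[idx]
        layer.beta = layer.beta[idx]
        layer.running_mean = layer.running_mean[idx]
        layer.running_var = layer.running_var[idx]
        if li + 1 < len(out.layers):
            out.layers[li + 1].weight = out.layers[li + 1].weight[:, idx]
    return out


def functional_equivalence_check(dense_net: ToyConvNet, pruned_net: ToyConvNet,
                                 inputs) -> float:
    """Run both nets on every input and return the maximum absolute
    output deviation — exactly 0 (to rounding) when the pruned channels
    were truly dead."""
    worst = 0.0
    for x in inputs:
        a = dense_net.forward(x)
        b = pruned_net.forward(x)
        if a.shape != b.shape:
            raise InvalidArgumentError(
                f"output shapes differ: {a.shape} vs {b.shape}")
        worst = max(worst, float(np.abs(a - b).max()))
    return worst


def sparsity_descent_demo(gammas: np.ndarray, sparsity_lambda: float,
                          steps: int = 100, lr: float = 0.1) -> np.ndarray:
    """Tiny demonstration of the L1 sparsity pressure: proximal descent
    on λ·Σ|γ| (soft-thresholding), returning the γ trajectory
    (steps + 1, n).  Stands in for the full sparsity training, which
    requires the task loss and its network."""
    g = np.asarray(gammas, dtype=float).copy()
    traj = [g.copy()]
    for _ in range(steps):
        g = np.sign(g) * np.maximum(np.abs(g) - lr * sparsity_lambda, 0.0)
        traj.append(g.copy())
    return np.array(traj)
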