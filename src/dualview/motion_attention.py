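"""Motion Attention: motion-biased scaled dot-product attention.

The computation highlights image regions that moved between consecutive
frames and biases self-attention towards them:

1. ``motion_residual``:  Dt = |Ft − Ft−1|, the element-wise residual of
   consecutive backbone feature maps (c, H, W).
2. ``embed_motion``:  a 1×1 convolution + ReLU compresses Dt to an
   embedded motion map Et (d, H, W), flattened row-major to
   Et_flat (N × d), N = H·W.
3. ``motion_guidance``:  Ms = row-softmax(Et_flat·Et_flatᵀ), an N × N
   row-stochastic pairwise position-similarity matrix.
4. ``motion_weighted_attention``:  with X = flatten(Ft), Q = X·Wq,
   K = X·Wk, V = X·Wv, the guidance enters as a score bias:
   As = row-softmax(Q·Kᵀ/√d_k + α·Ms),  Ys = As·V, reshaped back to a
   spatial map.  α ≥ 0 controls the strength of the motion bias; α = 0
   recovers plain scaled dot-product attention.
5. ``sequence_motion_weighting``: the same biased attention applied a
   second time in the sequence domain, to concatenated
   template/search feature sequences carrying positional encoding.

This module is a verified computational kernel, single-head by default,
with user-supplied or seeded-random weights; it contains no training
loop.  Softmaxes use max-subtraction for numerical stability.
Flattening is row-major (row index = h·W + w) throughout, so Ms
indexing always matches X flattening.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "FeatureMap", "MotionContext", "AttentionParams",
    "motion_residual", "embed_motion", "motion_guidance",
    "motion_weighted_attention", "sequence_motion_weighting",
    "softmax_rows", "positional_encoding", "random_params",
]


def _as_feature(a, name="feature map") -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 3 or a.shape[1] < 1 or a.shape[2] < 1:
        raise InvalidArgumentError(f"{name} must be (channels, H, W), got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise InvalidArgumentError(f"{name} has non-finite entries")
    return a


FeatureMap = np.ndarray  # (c, H, W)


@dataclass(frozen=True)
class AttentionParams:
    """Projection weights and bias strength of one attention head.

    Wq, Wk: (d_model × d_k); Wv: (d_model × d_v); ``alpha`` scales the
    motion-guidance bias; ``embed_weight`` (d × c) and ``embed_bias``
    (d,) are the 1×1-convolution parameters of the motion embedding,
    applied with ReLU unless ``embed_relu`` is False.
    """

    Wq: np.ndarray
    Wk: np.ndarray
    Wv: np.ndarray
    alpha: float = 1.0
    embed_weight: np.ndarray | None = None
    embed_bias: np.ndarray | None = None
    embed_relu: bool = True

    def __post_init__(self):
        for name in ("Wq", "Wk", "Wv"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if self.Wq.shape != self.Wk.shape:
            raise InvalidArgumentError("Wq and Wk must share shape (d_model × d_k)")
        if self.Wv.shape[0] != self.Wq.shape[0]:
            raise InvalidArgumentError("Wv must share d_model with Wq/Wk")
        if self.alpha < 0:
            raise InvalidArgumentError("alpha must be ≥ 0")

    @property
    def d_k(self) -> int:
        return self.Wq.shape[1]


@dataclass(frozen=True)
class MotionContext:
    """Intermediate products of the motion-guidance computation."""

    Dt: np.ndarray
    Et: np.ndarray
    Et_flat: np.ndarray
    Ms: np.ndarray
    shape: tuple[int, int] = field(default=(1, 1))


def random_params(d_model: int, d_k: int, d_v: int | None = None,
                  c_motion: int | None = None, d_embed: int | None = None,
                  alpha: float = 1.0, seed: int = 0) -> AttentionParams:
    """Seeded Gaussian weights at 1/√d scale — the standard way to build
    a reproducible random attention instance for verification."""
    rng = np.random.default_rng(seed)
    d_v = d_v if d_v is not None else d_model
    p = {}
    if c_motion is not None:
        d_embed = d_embed if d_embed is not None else max(c_motion // 2, 1)
        p["embed_weight"] = rng.normal(0, 1 / np.sqrt(c_motion),
                                       size=(d_embed, c_motion))
        p["embed_bias"] = rng.normal(0, 0.1, size=d_embed)
    return AttentionParams(
        Wq=rng.normal(0, 1 / np.sqrt(d_model), size=(d_model, d_k)),
        Wk=rng.normal(0, 1 / np.sqrt(d_model), size=(d_model, d_k)),
        Wv=rng.normal(0, 1 / np.sqrt(d_model), size=(d_model, d_v)),
        alpha=alpha, **p)


def softmax_rows(M: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-subtraction."""
    M = np.asarray(M, dtype=float)
    shifted = M - M.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def motion_residual(Ft, Ft_prev) -> np.ndarray:
    """Dt = |Ft − Ft−1| element-wise."""
    Ft = _as_feature(Ft, "Ft")
    Ft_prev = _as_feature(Ft_prev, "Ft_prev")
    if Ft.shape != Ft_prev.shape:
        raise InvalidArgumentError(
            f"shape mismatch {Ft.shape} vs {Ft_prev.shape}")
    return np.abs(Ft - Ft_prev)


def embed_motion(Dt, params: AttentionParams) -> tuple[np.ndarray, np.ndarray]:
    """1×1 convolution + ReLU channel compression of the residual map.

    Returns (Et (d, H, W), Et_flat (N × d)) with row index h·W + w.
    """
    Dt = _as_feature(Dt, "Dt")
    if params.embed_weight is None:
        raise InvalidArgumentError("params.embed_weight is not set")
    W = np.asarray(params.embed_weight, float)
    c, H, Wd = Dt.shape
    if W.shape[1] != c:
        raise InvalidArgumentError(
            f"embed weight expects {W.shape[1]} channels, Dt has {c}")
    b = np.zeros(W.shape[0]) if params.embed_bias is None \
        else np.asarray(params.embed_bias, float)
    Et = np.tensordot(W, Dt, axes=([1], [0])) + b[:, None, None]
    if params.embed_relu:
        Et = np.maximum(Et, 0.0)
    Et_flat = Et.reshape(W.shape[0], H * Wd).T
    return Et, Et_flat


def motion_guidance(Et_flat) -> np.ndarray:
    """Ms = row-softmax(Et_flat · Et_flatᵀ): the row-stochastic pairwise
    position-similarity matrix of the embedded motion."""
    Et_flat = np.asarray(Et_flat, dtype=float)
    if Et_flat.ndim != 2 or Et_flat.shape[0] < 1:
        raise InvalidArgumentError("Et_flat must be an (N, d) matrix with N ≥ 1")
    if not np.all(np.isfinite(Et_flat)):
        raise InvalidArgumentError("Et_flat has non-finite entries")
    return softmax_rows(Et_flat @ Et_flat.T)


def flatten_feature(Ft: np.ndarray) -> np.ndarray:
    """(c, H, W) → (N, c) with row index h·W + w (row-major)."""
    c, H, W = Ft.shape
    return Ft.reshape(c, H * W).T


def biased_attention(X: np.ndarray, Ms: np.ndarray | None,
                     params: AttentionParams,
                     return_weights: bool = False):
    """Core computation: As = row-softmax(Q·Kᵀ/√d_k + α·Ms), Ys = As·V."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InvalidArgumentError("X must be (N, d_model)")
    if X.shape[1] != params.Wq.shape[0]:
        raise InvalidArgumentError(
            f"X has d_model={X.shape[1]}, weights expect {params.Wq.shape[0]}")
    N = X.shape[0]
    scores = (X @ params.Wq) @ (X @ params.Wk).T / np.sqrt(params.d_k)
    if Ms is not None:
        Ms = np.asarray(Ms, dtype=float)
        if Ms.shape != (N, N):
            raise InvalidArgumentError(
                f"Ms must be ({N}, {N}), got {Ms.shape}")
        scores = scores + params.alpha * Ms
    As = softmax_rows(scores)
    Ys = As @ (X @ params.Wv)
    return (Ys, As) if return_weights else Ys


def motion_weighted_attention(Ft, Ms, params: AttentionParams,
                              return_weights: bool = False):
    """Motion-biased self-attention over the spatial positions of Ft.

    Returns Ft′ of shape (d_v, H, W); with ``return_weights`` also the
    row-stochastic attention matrix As.
    """
    Ft = _as_feature(Ft, "Ft")
    _, H, W = Ft.shape
    X = flatten_feature(Ft)
    out = biased_attention(X, Ms, params, return_weights=return_weights)
    Ys, As = out if return_weights else (out, None)
    Ft_prime = Ys.T.reshape(params.Wv.shape[1], H, W)
    return (Ft_prime, As) if return_weights else Ft_prime


def sequence_motion_weighting(sequence, Ms_seq, params: AttentionParams,
                              return_weights: bool = False):
    """Second round of motion weighting in the sequence domain: the same
    biased attention applied to an (L, d_model) concatenated
    template/search sequence (positional encoding already added).
    ``Ms_seq`` must be L × L (or None for plain attention)."""
    sequence = np.asarray(sequence, dtype=float)
    if sequence.ndim != 2:
        raise InvalidArgumentError("sequence must be (L, d_model)")
    if Ms_seq is not None and np.asarray(Ms_seq).shape != (len(sequence),) * 2:
        raise InvalidArgumentError("Ms_seq dimension must equal sequence length")
    return biased_attention(sequence, Ms_seq, params,
                            return_weights=return_weights)


def positional_encoding(length: int, d_model: int) -> np.ndarray:
    """Sinusoidal positional encoding (L, d_model)."""
    if length < 1 or d_model < 1:
        raise InvalidArgumentError("length and d_model must be ≥ 1")
    pos = np.arange(length)[:, None]
    i = np.arange(d_model)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe


def build_motion_context(Ft, Ft_prev, params: AttentionParams) -> MotionContext:
    """Run the full residual → embedding → guidance chain."""
    Dt = motion_residual(Ft, Ft_prev)
    Et, Et_flat = embed_motion(Dt, params)
    Ms = motion_guidance(Et_flat)
    return MotionContext(Dt=Dt, Et=Et, Et_flat=Et_flat, Ms=Ms,
                         shape=Ft.shape[1:])
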