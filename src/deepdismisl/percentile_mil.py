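"""Distribution-based multiple-instance survival model (DeepDisMISL).

Every instance (patch feature vector) in a bag is mapped to a scalar score
by a two-layer scorer shared across instances (equivalent to width-one 1-D
convolutions, d -> h -> 1 with a ReLU between).  The empirical distribution
of the n scores is then summarized by reading it at a fixed list of
percentiles; at each percentile a window of k consecutively ranked
instances (the "neighborhood") is selected, and the concatenated selected
scores feed a small MLP head that outputs the bag-level risk O_i.  Training
minimizes the Cox negative log partial likelihood, so the whole pipeline is
differentiable; gradients here are derived by hand (the percentile gather
back-propagates by scatter-adding into the selected score positions).

An attention variant combines the k scores within each percentile window
into one value by learned softmax weights, so every percentile location
contributes exactly one input to the head.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .bag_data import InstanceFeatureBag

__all__ = [
    "SCENARIO_PERCENTILES",
    "PercentileScheme",
    "scenario_scheme",
    "select_percentile_instances",
    "selection_ranks",
    "score_instances",
    "predict_risk",
    "predict_risk_attention",
    "PercentileAggregator",
    "MILSurvivalModel",
    "save_checkpoint",
    "load_checkpoint",
]

#: The seven percentile scenarios, from extremes-only to the (near-)complete
#: score distribution.
SCENARIO_PERCENTILES: dict[int, tuple[float, ...]] = {
    1: (0, 100),
    2: (0, 0.1, 99.9, 100),
    3: (0, 0.1, 1, 99, 99.9, 100),
    4: (0, 0.1, 1, 5, 95, 99, 99.9, 100),
    5: (0, 0.1, 1, 5, 10, 90, 95, 99, 99.9, 100),
    6: (0, 0.1, 1, 5, 10, 25, 75, 90, 95, 99, 99.9, 100),
    7: (0, 0.1, 1, 5, 10, 25, 50, 75, 90, 95, 99, 99.9, 100),
}


@dataclass(frozen=True)
class PercentileScheme:
    """Ordered percentile locations P plus the neighborhood width k."""

    percentiles: tuple[float, ...]
    neighborhood: int = 1

    def __post_init__(self) -> None:
        p = tuple(float(x) for x in self.percentiles)
        object.__setattr__(self, "percentiles", p)
        if len(p) == 0:
            raise ValueError("at least one percentile required")
        if any(not (0.0 <= x <= 100.0) for x in p):
            raise ValueError("percentiles must lie in [0, 100]")
        if any(b <= a for a, b in zip(p, p[1:])):
            raise ValueError("percentiles must be strictly increasing")
        k = self.neighborhood
        if not (isinstance(k, int) and k >= 1 and k % 2 == 1):
            raise ValueError(f"neighborhood must be an odd integer >= 1, got {k}")

    @property
    def width(self) -> int:
        """Number of selected instances |P| * k (the head input width)."""
        return len(self.percentiles) * self.neighborhood


def scenario_scheme(scenario_id: int, neighborhood: int = 1) -> PercentileScheme:
    """Return the percentile scheme for one of the seven study scenarios."""
    if scenario_id not in SCENARIO_PERCENTILES:
        raise ValueError(f"scenario_id must be in 1..7, got {scenario_id}")
    return PercentileScheme(SCENARIO_PERCENTILES[scenario_id], neighborhood)


def _nearest_rank(p: float, n: int) -> int:
    # round half away from zero; p and n-1 are non-negative here
    return int(np.floor(p / 100.0 * (n - 1) + 0.5))


def selection_ranks(n: int, scheme: PercentileScheme) -> np.ndarray:
    """Ascending-sort ranks selected by a scheme for a bag of n instances.

    Each percentile p maps to center rank c = round(p/100 * (n-1)) (half away
    from zero); its window is k consecutive ranks centered on c, shifted
    inward at the boundaries so the head input width stays constant.  When
    n < k the window is every rank, padded by repeating the boundary ranks.
    """
    if n < 1:
        raise ValueError("need at least one instance")
    k = scheme.neighborhood
    half = (k - 1) // 2
    out = np.empty(scheme.width, dtype=np.intp)
    for i, p in enumerate(scheme.percentiles):
        c = _nearest_rank(p, n)
        if n >= k:
            lo = min(max(c - half, 0), n - k)
            win = np.arange(lo, lo + k)
        else:
            win = np.clip(np.arange(c - half, c + half + 1), 0, n - 1)
        out[i * k : (i + 1) * k] = win
    return out


def select_percentile_instances(scores, scheme: PercentileScheme) -> np.ndarray:
    """Read the score distribution at the scheme's percentile windows.

    Scores are stably sorted ascending (original index breaks ties) and the
    windows are returned concatenated in scheme order, each ascending.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or scores.size == 0:
        raise ValueError("scores must be a non-empty 1-D vector")
    order = np.argsort(scores, kind="stable")
    return scores[order][selection_ranks(scores.size, scheme)]


# ---------------------------------------------------------------------------
# parameters and single-bag forward passes
# ---------------------------------------------------------------------------


def _fan_in_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


@dataclass
class ScorerParams:
    """Instance-shared scorer d -> h (ReLU) -> 1 (raw score)."""

    W1: np.ndarray  # (d, h)
    b1: np.ndarray  # (h,)
    w2: np.ndarray  # (h,)
    b2: float

    @classmethod
    def init(cls, feature_dim: int, hidden: int = 128, seed: int = 0) -> "ScorerParams":
        rng = np.random.default_rng(seed)
        return cls(
            W1=_fan_in_uniform(rng, (feature_dim, hidden), feature_dim),
            b1=np.zeros(hidden),
            w2=_fan_in_uniform(rng, (hidden,), hidden),
            b2=0.0,
        )


@dataclass
class HeadParams:
    """Risk head: ReLU MLP over the selected scores, final affine to O_i."""

    hidden: list  # list of (W, b) pairs
    w_out: np.ndarray
    b_out: float

    @classmethod
    def init(
        cls, input_width: int, hidden_sizes: tuple[int, ...] = (128, 64), seed: int = 0
    ) -> "HeadParams":
        rng = np.random.default_rng(seed)
        layers = []
        w = input_width
        for h in hidden_sizes:
            layers.append((_fan_in_uniform(rng, (w, h), w), np.zeros(h)))
            w = h
        return cls(hidden=layers, w_out=_fan_in_uniform(rng, (w,), w), b_out=0.0)

    @property
    def input_width(self) -> int:
        return self.hidden[0][0].shape[0] if self.hidden else self.w_out.shape[0]


@dataclass
class AttentionParams:
    """Per-instance attention scorer (scalar -> tanh hidden -> logit)."""

    wa1: np.ndarray  # (ha,)
    ba1: np.ndarray  # (ha,)
    wa2: np.ndarray  # (ha,)
    ba2: float

    @classmethod
    def init(cls, hidden: int = 8, seed: int = 0) -> "AttentionParams":
        rng = np.random.default_rng(seed)
        return cls(
            wa1=_fan_in_uniform(rng, (hidden,), 1),
            ba1=np.zeros(hidden),
            wa2=_fan_in_uniform(rng, (hidden,), hidden),
            ba2=0.0,
        )


def score_instances(bag: InstanceFeatureBag, params: ScorerParams) -> np.ndarray:
    """Score every instance with the shared scorer; returns a length-n vector."""
    X = np.asarray(bag.features, dtype=float)
    if X.shape[1] != params.W1.shape[0]:
        raise ValueError(
            f"feature width {X.shape[1]} != scorer input width {params.W1.shape[0]}"
        )
    A1 = np.maximum(X @ params.W1 + params.b1, 0.0)
    return A1 @ params.w2 + params.b2


def _head_forward(feats: np.ndarray, head: HeadParams) -> np.ndarray:
    h = feats
    for W, b in head.hidden:
        h = np.maximum(h @ W + b, 0.0)
    return h @ head.w_out + head.b_out


def predict_risk(
    bag: InstanceFeatureBag,
    scorer: ScorerParams,
    scheme: PercentileScheme,
    head: HeadParams,
) -> float:
    """Bag-level risk: score -> percentile selection -> MLP head."""
    if head.input_width != scheme.width:
        raise ValueError(
            f"head input width {head.input_width} != scheme width {scheme.width}"
        )
    scores = score_instances(bag, scorer)
    feats = select_percentile_instances(scores, scheme)
    return float(_head_forward(feats[None, :], head)[0])


def _attention_combine(v: np.ndarray, attn: AttentionParams):
    """Softmax-attention combine over the last (window) axis.

    v has shape (..., P, k); returns (y, cache) with y of shape (..., P) and
    attention weights summing to 1 within each window.
    """
    z = np.tanh(v[..., None] * attn.wa1 + attn.ba1)  # (..., P, k, ha)
    e = z @ attn.wa2 + attn.ba2  # (..., P, k)
    e_shift = e - e.max(axis=-1, keepdims=True)
    w = np.exp(e_shift)
    w /= w.sum(axis=-1, keepdims=True)
    y = np.sum(w * v, axis=-1)
    return y, (v, z, w, y)


def _attention_backward(dy: np.ndarray, cache, attn: AttentionParams):
    v, z, w, y = cache
    dv = dy[..., None] * w
    dw = dy[..., None] * v
    de = w * (dw - np.sum(dw * w, axis=-1, keepdims=True))
    dz = de[..., None] * attn.wa2
    dpre = dz * (1.0 - z**2)
    grads = {
        "wa1": np.sum(dpre * v[..., None], axis=tuple(range(dpre.ndim - 1))),
        "ba1": np.sum(dpre, axis=tuple(range(dpre.ndim - 1))),
        "wa2": np.sum(z * de[..., None], axis=tuple(range(z.ndim - 1))),
        "ba2": float(np.sum(de)),
    }
    dv += np.sum(dpre * attn.wa1, axis=-1)
    return dv, grads


def predict_risk_attention(
    bag: InstanceFeatureBag,
    scorer: ScorerParams,
    scheme: PercentileScheme,
    attn: AttentionParams,
    head: HeadParams,
) -> float:
    """Attention variant: each percentile window collapses to one weighted value.

    The head input width is |P| (one value per percentile location), so every
    location carries equal prior weight regardless of k.
    """
    if head.input_width != len(scheme.percentiles):
        raise ValueError(
            f"head input width {head.input_width} != number of percentiles "
            f"{len(scheme.percentiles)}"
        )
    scores = score_instances(bag, scorer)
    sel = select_percentile_instances(scores, scheme)
    v = sel.reshape(len(scheme.percentiles), scheme.neighborhood)
    y, _ = _attention_combine(v, attn)
    return float(_head_forward(y[None, :], head)[0])


# ---------------------------------------------------------------------------
# aggregation interface (shared with the baseline aggregators)
# ---------------------------------------------------------------------------


class Aggregator:
    """Maps per-instance scores (B, n) to fixed-width head features (B, m).

    Subclasses implement ``forward`` returning (features, context) and
    ``backward`` mapping d(features) back to d(scores); gather-style
    aggregators scatter-add, which is the exact adjoint.
    """

    name: str = "aggregator"

    def output_width(self, n_instances: int) -> int:
        raise NotImplementedError

    def forward(self, scores: np.ndarray):
        raise NotImplementedError

    def backward(self, dfeats: np.ndarray, ctx) -> np.ndarray:
        raise NotImplementedError


class PercentileAggregator(Aggregator):
    """Selects the scheme's percentile windows from each bag's sorted scores."""

    name = "dismisl"

    def __init__(self, scheme: PercentileScheme):
        self.scheme = scheme

    def output_width(self, n_instances: int) -> int:
        return self.scheme.width

    def forward(self, scores: np.ndarray):
        B, n = scores.shape
        order = np.argsort(scores, kind="stable", axis=1)
        idx = order[:, selection_ranks(n, self.scheme)]  # (B, m)
        feats = np.take_along_axis(scores, idx, axis=1)
        return feats, (idx, n)

    def backward(self, dfeats: np.ndarray, ctx) -> np.ndarray:
        idx, n = ctx
        dscores = np.zeros((dfeats.shape[0], n))
        np.add.at(dscores, (np.arange(dfeats.shape[0])[:, None], idx), dfeats)
        return dscores


# ---------------------------------------------------------------------------
# the trainable model
# ---------------------------------------------------------------------------


@dataclass
class MILSurvivalModel:
    """Scorer + aggregation + MLP head, with hand-derived batched gradients.

    ``attention`` may only be combined with a :class:`PercentileAggregator`;
    it collapses each percentile window to a single attention-weighted value
    before the head.
    """

    feature_dim: int
    aggregator: Aggregator
    scorer_hidden: int = 128
    head_hidden: tuple[int, ...] = (128, 64)
    attention: bool = False
    attention_hidden: int = 8
    seed: int = 0
    scorer: ScorerParams = field(init=False)
    head: HeadParams = field(init=False)
    attn: AttentionParams | None = field(init=False, default=None)

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed)
        s1, s2, s3 = rng.integers(0, 2**31 - 1, size=3)
        self.scorer = ScorerParams.init(self.feature_dim, self.scorer_hidden, int(s1))
        if self.attention:
            if not isinstance(self.aggregator, PercentileAggregator):
                raise ValueError("attention requires a percentile aggregator")
            self.attn = AttentionParams.init(self.attention_hidden, int(s3))
            width = len(self.aggregator.scheme.percentiles)
        else:
            # width must not depend on n; all provided aggregators are fixed-width
            width = self.aggregator.output_width(0)
        self.head = HeadParams.init(width, self.head_hidden, int(s2))

    # -- parameter flattening (used by the Adam optimizer and checkpoints) --

    def get_params(self) -> dict[str, np.ndarray]:
        p = {
            "scorer.W1": self.scorer.W1,
            "scorer.b1": self.scorer.b1,
            "scorer.w2": self.scorer.w2,
            "scorer.b2": np.array(self.scorer.b2, dtype=float),
            "head.w_out": self.head.w_out,
            "head.b_out": np.array(self.head.b_out, dtype=float),
        }
        for i, (W, b) in enumerate(self.head.hidden):
            p[f"head.W{i}"] = W
            p[f"head.b{i}"] = b
        if self.attn is not None:
            p.update(
                {
                    "attn.wa1": self.attn.wa1,
                    "attn.ba1": self.attn.ba1,
                    "attn.wa2": self.attn.wa2,
                    "attn.ba2": np.array(self.attn.ba2, dtype=float),
                }
            )
        return p

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.scorer.W1 = params["scorer.W1"]
        self.scorer.b1 = params["scorer.b1"]
        self.scorer.w2 = params["scorer.w2"]
        self.scorer.b2 = float(params["scorer.b2"])
        self.head.hidden = [
            (params[f"head.W{i}"], params[f"head.b{i}"])
            for i in range(len(self.head.hidden))
        ]
        self.head.w_out = params["head.w_out"]
        self.head.b_out = float(params["head.b_out"])
        if self.attn is not None:
            self.attn.wa1 = params["attn.wa1"]
            self.attn.ba1 = params["attn.ba1"]
            self.attn.wa2 = params["attn.wa2"]
            self.attn.ba2 = float(params["attn.ba2"])

    # -- batched forward / backward --

    def forward(self, X: np.ndarray):
        """Risks for a stacked batch of equal-size bags X of shape (B, n, d)."""
        if X.ndim != 3 or X.shape[2] != self.feature_dim:
            raise ValueError(f"expected (B, n, {self.feature_dim}) batch, got {X.shape}")
        Z1 = X @ self.scorer.W1 + self.scorer.b1
        A1 = np.maximum(Z1, 0.0)
        s = A1 @ self.scorer.w2 + self.scorer.b2  # (B, n)
        feats, agg_ctx = self.aggregator.forward(s)
        attn_cache = None
        if self.attn is not None:
            P = len(self.aggregator.scheme.percentiles)
            v = feats.reshape(feats.shape[0], P, self.aggregator.scheme.neighborhood)
            h, attn_cache = _attention_combine(v, self.attn)
        else:
            h = feats
        pre, post = [], []
        for W, b in self.head.hidden:
            z = h @ W + b
            pre.append(z)
            h = np.maximum(z, 0.0)
            post.append(h)
        O = h @ self.head.w_out + self.head.b_out
        cache = (X, Z1, A1, agg_ctx, attn_cache, feats, pre, post)
        return O, cache

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0]

    def backward(self, dO: np.ndarray, cache) -> dict[str, np.ndarray]:
        X, Z1, A1, agg_ctx, attn_cache, feats, pre, post = cache
        grads: dict[str, np.ndarray] = {}
        h_last = post[-1] if post else (
            attn_cache[3] if attn_cache is not None else feats
        )
        grads["head.w_out"] = h_last.T @ dO
        grads["head.b_out"] = np.array(dO.sum())
        dh = dO[:, None] * self.head.w_out
        for i in range(len(self.head.hidden) - 1, -1, -1):
            W, _ = self.head.hidden[i]
            dz = dh * (pre[i] > 0)
            if i > 0:
                h_prev = post[i - 1]
            elif attn_cache is not None:
                h_prev = attn_cache[3]
            else:
                h_prev = feats
            grads[f"head.W{i}"] = h_prev.T @ dz
            grads[f"head.b{i}"] = dz.sum(axis=0)
            dh = dz @ W.T
        if self.attn is not None:
            dv, agrads = _attention_backward(dh, attn_cache, self.attn)
            for k, v in agrads.items():
                grads[f"attn.{k}"] = np.asarray(v)
            dfeats = dv.reshape(feats.shape)
        else:
            dfeats = dh
        ds = self.aggregator.backward(dfeats, agg_ctx)  # (B, n)
        grads["scorer.w2"] = np.einsum("bnh,bn->h", A1, ds)
        grads["scorer.b2"] = np.array(ds.sum())
        dA1 = ds[:, :, None] * self.scorer.w2
        dZ1 = dA1 * (Z1 > 0)
        grads["scorer.W1"] = np.einsum("bnd,bnh->dh", X, dZ1)
        grads["scorer.b1"] = dZ1.sum(axis=(0, 1))
        return grads


def save_checkpoint(model: MILSurvivalModel, path: str) -> str:
    """Serialize parameters to ``path`` (.npz) with a JSON architecture sidecar.

    Returns the actual checkpoint path (an ``.npz`` suffix is appended when
    missing, matching NumPy's behavior).
    """
    if not path.endswith(".npz"):
        path += ".npz"
    np.savez(path, **model.get_params())
    meta = {
        "feature_dim": model.feature_dim,
        "scorer_hidden": model.scorer_hidden,
        "head_hidden": list(model.head_hidden),
        "attention": model.attention,
        "attention_hidden": model.attention_hidden,
        "seed": model.seed,
        "aggregator": model.aggregator.name,
    }
    if isinstance(model.aggregator, PercentileAggregator):
        meta["percentiles"] = list(model.aggregator.scheme.percentiles)
        meta["neighborhood"] = model.aggregator.scheme.neighborhood
    with open(path[:-4] + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return path


def load_checkpoint(path: str) -> MILSurvivalModel:
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    from . import baselines  # local import to avoid a cycle

    if not path.endswith(".npz"):
        path += ".npz"
    with open(path[:-4] + ".json") as fh:
        meta = json.load(fh)
    if meta["aggregator"] == "dismisl":
        scheme = PercentileScheme(tuple(meta["percentiles"]), meta["neighborhood"])
        agg: Aggregator = PercentileAggregator(scheme)
    else:
        agg = baselines.make_aggregator(meta["aggregator"])
    model = MILSurvivalModel(
        feature_dim=meta["feature_dim"],
        aggregator=agg,
        scorer_hidden=meta["scorer_hidden"],
        head_hidden=tuple(meta["head_hidden"]),
        attention=meta["attention"],
        attention_hidden=meta["attention_hidden"],
        seed=meta["seed"],
    )
    with np.load(path) as npz:
        model.set_params({k: npz[k].copy() for k in npz.files})
    return model
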