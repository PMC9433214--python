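"""Convolutional mask refinement: the FCM+CNN and K-means+CNN hybrids.

A clustering stage proposes a binary region-of-interest mask; a compact
convolutional encoder-decoder then predicts the true mask from the pair
(grayscale image, proposal mask) presented as a 2-channel tile.  Training
pairs come from images with known ground truth (here: synthetic phantoms),
so the network learns the systematic errors of the proposal — noise
speckles absorbed into the foreground, illumination-induced bias, eroded
boundaries — and corrects them.

The network is a small fully-numpy ConvNet (3 downsampling and 3
upsampling stages, ~21k parameters, 2-channel input tile -> per-pixel
foreground probability) trained with Adam on a 0.5*(1 - soft Dice) +
0.5*cross-entropy loss.  A skip connection feeds the raw 2-channel input
into the output head, so the identity mapping "copy the proposal" is
trivially representable and training can only improve on it.  Convolutions
run through im2col matrix multiplies; the input gradient is computed as a
convolution with the spatially flipped kernels, so no scatter-adds are
needed and training runs in seconds on one CPU.  Everything is seeded and
single-threaded-deterministic; a saved model reloads to bit-identical
forward outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize
from sklearn.base import BaseEstimator

from .clustering import EmptyROIWarning, fcm_segment, kmeans_segment, partition_to_mask
from .preprocess import EnhanceParams, prepare_image, to_grayscale

__all__ = [
    "TrainingError",
    "TrainReport",
    "CNNMaskRefiner",
    "train_refiner",
    "refine_mask",
    "fcm_cnn_segment",
    "kmeans_cnn_segment",
    "proposal_mask",
]


class TrainingError(RuntimeError):
    """Training could not proceed (e.g. every proposal mask was empty)."""


@dataclass
class TrainReport:
    loss_trace: list[float] = field(default_factory=list)
    val_dice_trace: list[float] = field(default_factory=list)
    checkpoint_path: str | None = None


# ---------------------------------------------------------------------------
# numpy conv-net plumbing
# ---------------------------------------------------------------------------


def _conv3(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """3x3 same-padding convolution. x: (B,C,H,W); W: (Cout, Cin*9)."""
    B, C, H, Wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (B,C,H,W,3,3)
    cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * Wd, C * 9)
    out = cols @ W.T + b
    out = out.reshape(B, H, Wd, -1).transpose(0, 3, 1, 2)
    return out, cols


def _conv3_input_grad(dout: np.ndarray, W: np.ndarray, c_in: int) -> np.ndarray:
    """Gradient w.r.t. the conv input, as a conv with flipped kernels."""
    c_out = dout.shape[1]
    Wk = W.reshape(c_out, c_in, 3, 3)
    Wflip = Wk[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(c_in, c_out * 9)
    dx, _ = _conv3(dout, Wflip, np.zeros(c_in))
    return dx


def _pool2(x: np.ndarray):
    B, C, H, W = x.shape
    r = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(B, C, H // 2, W // 2, 4)
    idx = np.argmax(r, axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _pool2_grad(dout: np.ndarray, idx: np.ndarray, shape) -> np.ndarray:
    B, C, H, W = shape
    dr = np.zeros((B, C, H // 2, W // 2, 4))
    np.put_along_axis(dr, idx[..., None], dout[..., None], axis=-1)
    dr = dr.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return dr.reshape(B, C, H, W)


def _up2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _up2_grad(dout: np.ndarray) -> np.ndarray:
    B, C, H, W = dout.shape
    return dout.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class _Net:
    """Parameter container + forward/backward for the encoder-decoder."""

    #: (name, c_in, c_out) for the seven 3x3 conv layers.
    def __init__(self, base_channels: int = 8):
        F = base_channels
        self.base_channels = F
        self.layer_spec = [
            ("enc1", 2, F),
            ("enc2", F, 2 * F),
            ("enc3", 2 * F, 4 * F),
            ("bott", 4 * F, 4 * F),
            ("dec3", 4 * F, 2 * F),
            ("dec2", 2 * F, F),
            ("dec1", F, F),
        ]
        self.params: dict[str, np.ndarray] = {}

    def init_params(self, rng: np.random.Generator) -> None:
        for name, c_in, c_out in self.layer_spec:
            fan_in = c_in * 9
            self.params[f"{name}_W"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in)
            )
            self.params[f"{name}_b"] = np.zeros(c_out)
        # The head starts as "copy the proposal channel" (the last input
        # channel reaches it through the skip connection), so the untrained
        # network already reproduces the clustering mask and training can
        # only move away from that identity where the loss rewards it.
        F = self.base_channels
        head_W = np.zeros((1, F + 2))
        head_W[0, F + 1] = 12.0
        self.params["head_W"] = head_W
        self.params["head_b"] = np.array([-6.0])

    def forward(self, x: np.ndarray, keep_cache: bool = False):
        """x: (B,2,T,T) -> per-pixel probability (B,1,T,T)."""
        p = self.params
        cache: dict = {"x": x}

        def conv_relu(name, inp):
            z, cols = _conv3(inp, p[f"{name}_W"], p[f"{name}_b"])
            a = np.maximum(z, 0.0)
            if keep_cache:
                cache[name] = (cols, z > 0, inp.shape[1])
            return a

        a1 = conv_relu("enc1", x)
        p1, i1 = _pool2(a1)
        a2 = conv_relu("enc2", p1)
        p2, i2 = _pool2(a2)
        a3 = conv_relu("enc3", p2)
        p3, i3 = _pool2(a3)
        ab = conv_relu("bott", p3)
        u3 = _up2(ab)
        d3 = conv_relu("dec3", u3)
        u2 = _up2(d3)
        d2 = conv_relu("dec2", u2)
        u1 = _up2(d2)
        d1 = conv_relu("dec1", u1)
        cat = np.concatenate([d1, x], axis=1)  # skip from the raw input
        B, C, H, W = cat.shape
        flat = cat.transpose(0, 2, 3, 1).reshape(-1, C)
        logits = (flat @ p["head_W"].T + p["head_b"]).reshape(B, H, W, 1)
        logits = logits.transpose(0, 3, 1, 2)
        prob = 1.0 / (1.0 + np.exp(-logits))
        if keep_cache:
            cache.update(
                pools=[(i1, a1.shape), (i2, a2.shape), (i3, a3.shape)],
                head_flat=flat,
                cat_channels=C,
            )
            return prob, cache
        return prob

    def backward(self, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        """dlogits: (B,1,T,T) gradient at the pre-sigmoid head output."""
        p = self.params
        grads: dict[str, np.ndarray] = {}
        B, _, H, W = dlogits.shape
        dflat = dlogits.transpose(0, 2, 3, 1).reshape(-1, 1)
        grads["head_W"] = dflat.T @ cache["head_flat"]
        grads["head_b"] = dflat.sum(axis=0)
        dcat = (dflat @ p["head_W"]).reshape(B, H, W, cache["cat_channels"])
        dcat = dcat.transpose(0, 3, 1, 2)
        F = self.base_channels
        dd1 = dcat[:, :F]
        # the skip-connection branch of the input gradient is discarded:
        # the input is data, not a parameter.

        def conv_back(name, dout):
            cols, relu_mask, c_in = cache[name]
            dz = dout * relu_mask
            dz_flat = dz.transpose(0, 2, 3, 1).reshape(-1, dz.shape[1])
            grads[f"{name}_W"] = dz_flat.T @ cols
            grads[f"{name}_b"] = dz_flat.sum(axis=0)
            return _conv3_input_grad(dz, p[f"{name}_W"], c_in)

        du1 = conv_back("dec1", dd1)
        dd2 = _up2_grad(du1)
        du2 = conv_back("dec2", dd2)
        dd3 = _up2_grad(du2)
        du3 = conv_back("dec3", dd3)
        dab = _up2_grad(du3)
        dp3 = conv_back("bott", dab)
        i3, s3 = cache["pools"][2]
        da3 = _pool2_grad(dp3, i3, s3)
        dp2 = conv_back("enc3", da3)
        i2, s2 = cache["pools"][1]
        da2 = _pool2_grad(dp2, i2, s2)
        dp1 = conv_back("enc2", da2)
        i1, s1 = cache["pools"][0]
        da1 = _pool2_grad(dp1, i1, s1)
        conv_back("enc1", da1)
        return grads


def _dice_bce_loss(prob: np.ndarray, target: np.ndarray, eps: float = 1.0):
    """0.5*(1 - soft Dice) + 0.5*BCE, with the gradient at the logits."""
    B = prob.shape[0]
    n_px = prob[0].size
    p = prob.reshape(B, -1)
    y = target.reshape(B, -1)

    inter = (p * y).sum(axis=1)
    sums = p.sum(axis=1) + y.sum(axis=1) + eps
    dice = (2 * inter + eps) / sums

    pc = np.clip(p, 1e-7, 1 - 1e-7)
    bce = -(y * np.log(pc) + (1 - y) * np.log(1 - pc)).mean()
    loss = 0.5 * (1 - dice).mean() + 0.5 * bce

    ddice_dp = (2 * y * sums[:, None] - (2 * inter + eps)[:, None]) / sums[:, None] ** 2
    dl_dp = -0.5 * ddice_dp / B
    dlogits = dl_dp * p * (1 - p) + 0.5 * (p - y) / (n_px * B)
    return float(loss), dlogits.reshape(prob.shape)


def _hard_dice(pred: np.ndarray, truth: np.ndarray) -> float:
    pred = pred.astype(bool)
    truth = truth.astype(bool)
    denom = pred.sum() + truth.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.sum(pred & truth) / denom


# ---------------------------------------------------------------------------
# proposal stage shared by training and inference
# ---------------------------------------------------------------------------


def proposal_mask(
    img: np.ndarray,
    method: str,
    n_clusters: int = 2,
    fuzziness: float = 2.0,
    seed: int = 0,
    apply_enhance: bool = True,
    enhance_params: EnhanceParams | None = None,
    **mask_kwargs,
) -> np.ndarray:
    """Preprocess and run the named clustering method to a binary mask."""
    gray = prepare_image(
        img, enhance_params=enhance_params, apply_enhance=apply_enhance
    )
    if method == "fcm":
        part = fcm_segment(gray, n_clusters=n_clusters, fuzziness=fuzziness, seed=seed)
    elif method == "kmeans":
        part = kmeans_segment(gray, n_clusters=n_clusters, seed=seed)
    else:
        raise ValueError(f"proposal method must be 'fcm' or 'kmeans', got {method!r}")
    return partition_to_mask(part, gray, **mask_kwargs)


def _to_tile(arr: np.ndarray, tile: int, is_mask: bool) -> np.ndarray:
    if arr.shape == (tile, tile):
        out = arr.astype(float)
    else:
        out = resize(
            arr.astype(float),
            (tile, tile),
            order=0 if is_mask else 1,
            preserve_range=True,
            anti_aliasing=False,
        )
    return out if is_mask else out / 255.0


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------


class CNNMaskRefiner(BaseEstimator):
    """Trainable ConvNet that refines clustering-proposed masks.

    Parameters
    ----------
    proposal_method : {"kmeans", "fcm"}
        Clustering stage whose output masks this model is trained to refine.
    tile_size : int, default 128
        Square side of the network input; images are resized to it (and
        predictions resized back).  Must be divisible by 8.
    base_channels : int, default 8
        Width of the first encoder stage; deeper stages double it.
    epochs, batch_size, learning_rate, val_fraction :
        Training schedule (Adam).
    threshold : float, default 0.5
        Probability cut for binarising predictions.
    random_state : int
        Seeds weight initialisation and batch shuffling; two fits with the
        same data, config and seed produce identical loss traces.

    Attributes
    ----------
    net_ : the fitted parameter container
    report_ : :class:`TrainReport` with loss and validation-Dice traces
    """

    def __init__(
        self,
        proposal_method: str = "kmeans",
        n_clusters: int = 2,
        fuzziness: float = 2.0,
        tile_size: int = 128,
        base_channels: int = 8,
        epochs: int = 10,
        batch_size: int = 4,
        learning_rate: float = 1e-3,
        val_fraction: float = 0.2,
        threshold: float = 0.5,
        apply_enhance: bool = True,
        random_state: int = 0,
    ):
        self.proposal_method = proposal_method
        self.n_clusters = n_clusters
        self.fuzziness = fuzziness
        self.tile_size = tile_size
        self.base_channels = base_channels
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.val_fraction = val_fraction
        self.threshold = threshold
        self.apply_enhance = apply_enhance
        self.random_state = random_state

    # -- training ----------------------------------------------------------

    def fit(self, samples: Sequence, proposals: Sequence[np.ndarray] | None = None):
        """Train on (image, truth-mask) samples.

        ``samples`` is a sequence of objects with ``image`` and
        ``truth_mask`` attributes (e.g. phantoms) or of ``(image, mask)``
        tuples.  ``proposals`` optionally overrides the clustering-computed
        proposal masks (useful for diagnostics).
        """
        if self.tile_size % 8 != 0:
            raise ValueError(f"tile_size must be divisible by 8, got {self.tile_size}")
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        pairs = [
            (s.image, s.truth_mask) if hasattr(s, "image") else (s[0], s[1])
            for s in samples
        ]
        pairs = [(to_grayscale(np.asarray(img)), m) for img, m in pairs]
        if len(pairs) < 20:
            raise ValueError(f"need >= 20 training samples, got {len(pairs)}")

        if proposals is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", EmptyROIWarning)
                proposals = [
                    proposal_mask(
                        img,
                        self.proposal_method,
                        n_clusters=self.n_clusters,
                        fuzziness=self.fuzziness,
                        seed=self.random_state,
                        apply_enhance=self.apply_enhance,
                    )
                    for img, _ in pairs
                ]
        if not any(np.asarray(p).any() for p in proposals):
            raise TrainingError(
                "every proposal mask is empty; the clustering stage found no ROI"
            )

        T = self.tile_size
        X = np.stack(
            [
                np.stack(
                    [
                        _to_tile(np.asarray(img, float), T, is_mask=False),
                        _to_tile(np.asarray(prop, float), T, is_mask=True),
                    ]
                )
                for (img, _), prop in zip(pairs, proposals)
            ]
        )
        Y = np.stack(
            [_to_tile(np.asarray(m, float), T, is_mask=True)[None] for _, m in pairs]
        )

        rng = np.random.default_rng(self.random_state)
        n = len(pairs)
        order = rng.permutation(n)
        n_val = max(1, int(round(self.val_fraction * n))) if n >= 5 else 0
        val_idx, train_idx = order[:n_val], order[n_val:]

        net = _Net(self.base_channels)
        net.init_params(rng)
        m_state = {k: np.zeros_like(v) for k, v in net.params.items()}
        v_state = {k: np.zeros_like(v) for k, v in net.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        report = TrainReport()

        for _epoch in range(self.epochs):
            perm = rng.permutation(train_idx)
            losses = []
            for start in range(0, len(perm), self.batch_size):
                batch = perm[start : start + self.batch_size]
                prob, cache = net.forward(X[batch], keep_cache=True)
                loss, dlogits = _dice_bce_loss(prob, Y[batch])
                grads = net.backward(dlogits, cache)
                step += 1
                for k in net.params:
                    g = grads[k]
                    m_state[k] = beta1 * m_state[k] + (1 - beta1) * g
                    v_state[k] = beta2 * v_state[k] + (1 - beta2) * g * g
                    mhat = m_state[k] / (1 - beta1**step)
                    vhat = v_state[k] / (1 - beta2**step)
                    net.params[k] -= (
                        self.learning_rate * mhat / (np.sqrt(vhat) + eps)
                    )
                losses.append(loss)
            report.loss_trace.append(float(np.mean(losses)))
            if len(val_idx):
                dices = [
                    _hard_dice(
                        net.forward(X[i : i + 1])[0, 0] >= self.threshold, Y[i, 0] > 0.5
                    )
                    for i in val_idx
                ]
                report.val_dice_trace.append(float(np.mean(dices)))

        self.net_ = net
        self.report_ = report
        return self

    # -- inference ---------------------------------------------------------

    def predict_proba(self, img: np.ndarray, proposal: np.ndarray) -> np.ndarray:
        """Foreground probability map at the input image's resolution."""
        if not hasattr(self, "net_"):
            raise RuntimeError("model is not fitted/loaded")
        img = np.asarray(img)
        proposal = np.asarray(proposal)
        if img.shape[:2] != proposal.shape[:2]:
            raise ValueError(
                f"image {img.shape} and proposal {proposal.shape} disagree"
            )
        T = self.tile_size
        x = np.stack(
            [
                _to_tile(img.astype(float), T, is_mask=False),
                _to_tile(proposal.astype(float), T, is_mask=True),
            ]
        )[None]
        prob = self.net_.forward(x)[0, 0]
        if prob.shape != img.shape[:2]:
            prob = resize(prob, img.shape[:2], order=1, preserve_range=True)
        return prob

    def refine(
        self, img: np.ndarray, proposal: np.ndarray, threshold: float | None = None
    ) -> np.ndarray:
        """Binary refined mask; warns if the result is empty."""
        thr = self.threshold if threshold is None else threshold
        mask = self.predict_proba(img, proposal) >= thr
        if not mask.any():
            warnings.warn("refined ROI is empty", EmptyROIWarning, stacklevel=2)
        return mask

    # -- persistence -------------------------------------------------------

    def save(self, path: Path | str) -> None:
        """Serialize config + weights; reload gives bit-identical forwards."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        meta = json.dumps(self.get_params())
        np.savez(
            path,
            __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
            **self.net_.params,
        )
        if hasattr(self, "report_"):
            self.report_.checkpoint_path = str(path)

    @classmethod
    def load(cls, path: Path | str) -> "CNNMaskRefiner":
        with np.load(Path(path) if str(path).endswith(".npz") else f"{path}.npz") as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            model = cls(**meta)
            net = _Net(model.base_channels)
            net.params = {k: z[k] for k in z.files if k != "__meta__"}
            model.net_ = net
        return model


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def train_refiner(
    samples: Sequence,
    proposal_method: str = "kmeans",
    config: dict | None = None,
    seed: int = 0,
    proposals: Sequence[np.ndarray] | None = None,
) -> tuple[CNNMaskRefiner, TrainReport]:
    """Train a refiner on phantom samples; returns (model, report)."""
    model = CNNMaskRefiner(
        proposal_method=proposal_method, random_state=seed, **(config or {})
    )
    model.fit(samples, proposals=proposals)
    return model, model.report_


def refine_mask(
    model: CNNMaskRefiner,
    img: np.ndarray,
    proposal: np.ndarray,
    threshold: float = 0.5,
) -> np.ndarray:
    return model.refine(img, proposal, threshold=threshold)


def _cnn_segment(img: np.ndarray, model: CNNMaskRefiner, method: str, **kwargs):
    if model.proposal_method != method:
        raise ValueError(
            f"model was trained on {model.proposal_method!r} proposals, "
            f"cannot drive a {method!r} pipeline"
        )
    proposal = proposal_mask(
        img,
        method,
        n_clusters=kwargs.pop("n_clusters", model.n_clusters),
        fuzziness=kwargs.pop("fuzziness", model.fuzziness),
        seed=kwargs.pop("seed", model.random_state),
        apply_enhance=model.apply_enhance,
        **kwargs,
    )
    return model.refine(to_grayscale(np.asarray(img)), proposal)


def fcm_cnn_segment(img: np.ndarray, model: CNNMaskRefiner, **kwargs) -> np.ndarray:
    """Preprocess -> FCM -> mask -> CNN refinement."""
    return _cnn_segment(img, model, "fcm", **kwargs)


def kmeans_cnn_segment(img: np.ndarray, model: CNNMaskRefiner, **kwargs) -> np.ndarray:
    """Preprocess -> K-means -> mask -> CNN refinement."""
    return _cnn_segment(img, model, "kmeans", **kwargs)
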