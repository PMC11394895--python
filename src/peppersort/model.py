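"""Assembly of the multi-domain classification and segmentation networks.

Both networks are YOLOv8-style: a staged backbone of conv/CSP blocks
with the dual-domain attention (MS-DFFM) inserted in the shallow
stages and the frequency-domain fusion layer (MSF3M) in the deep
stages.  The segmentation variant adds a neck that up-samples with
the Fourier operator and a prototype-mask instance head.  Training
defaults (SGD, lr0 0.01 → lrf 0.01, momentum 0.937, weight decay
5e-4, batch 16, patience 50, 300 epochs, no pretraining) follow the
standard from-scratch YOLO recipe; ``smoke`` configs scale the same
recipe down to desk size.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import autodiff as ad
from .autodiff import Tensor
from .blocks import ADown, C2f, C2fSE, ConvBNAct, RepNCSPELAN4, SPPELAN
from .fourier_up import FourierUpsample
from .msdffm import MSDFFM
from .msf3m import MSF3M
from .nn import SGD, Conv2d, Linear, Module, cross_entropy, global_avg_pool

__all__ = ["ModelConfig", "ClsDataset", "build_model", "param_count",
           "param_megabytes", "train_smoke", "save_checkpoint",
           "load_checkpoint", "smoke_config"]

_N_STAGES = 4


@dataclass
class ModelConfig:
    task: str = "classification"            # "classification" | "segmentation"
    num_classes: int = 2
    input_size: int = 640
    width_mult: float = 0.25
    depth_mult: float = 0.33
    base_channels: tuple[int, ...] = (64, 128, 256, 512, 1024)
    # custom-layer insertion (1-based backbone stage indices)
    msdffm_stages: tuple[int, ...] = (1, 2)
    msf3m_stages: tuple[int, ...] = (4,)
    # block toggles
    use_repncspelan4: bool = True
    use_adown: bool = True
    use_c2f_se: bool = True
    use_sppelan: bool = True
    use_fourier_upsample: bool = True
    use_msdffm: bool = True
    use_msf3m: bool = True
    # segmentation head
    num_prototypes: int = 8
    conf_threshold: float = 0.25
    mask_threshold: float = 0.5
    # training hyperparameters
    epochs: int = 300
    batch_size: int = 16
    optimizer: str = "SGD"
    patience: int = 50
    pretrained: bool = False
    weight_decay: float = 0.0005
    workers: int = 4
    lr0: float = 0.01
    lrf: float = 0.01
    momentum: float = 0.937
    seed: int = 0

    def __post_init__(self):
        if self.task not in ("classification", "segmentation"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.num_classes < 1:
            raise ValueError("need at least one class")
        if self.width_mult <= 0 or self.depth_mult <= 0:
            raise ValueError("multipliers must be positive")
        if self.pretrained:
            raise ValueError("pretrained weights are not supported; "
                             "models are trained from scratch")
        for name, stages in (("msdffm", self.msdffm_stages),
                             ("msf3m", self.msf3m_stages)):
            for s in stages:
                if not 1 <= s <= _N_STAGES:
                    raise ValueError(
                        f"invalid {name} insertion stage {s}: backbone has "
                        f"stages 1..{_N_STAGES}")

    # -- derived sizes --------------------------------------------------
    def widths(self) -> list[int]:
        return [max(4, int(round(c * self.width_mult))) for c in self.base_channels]

    def depth(self, n: int = 3) -> int:
        return max(1, int(round(n * self.depth_mult)))


def smoke_config(**overrides) -> ModelConfig:
    """A desk-scale config: 64×64 inputs, narrow widths, few epochs."""
    defaults = dict(input_size=64, width_mult=0.125, depth_mult=0.33,
                    epochs=12, patience=50, num_prototypes=4)
    defaults.update(overrides)
    return ModelConfig(**defaults)


# ----------------------------------------------------------------------
# backbone
# ----------------------------------------------------------------------

class _Backbone(Module):
    """Stem + four downsampling stages; returns the last three stage maps."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        w = cfg.widths()
        n = cfg.depth()
        self.stages: list[list[Module]] = []
        self.stem = ConvBNAct(3, w[0], 3, stride=2, rng=rng)

        def down(cin, cout):
            if cfg.use_adown:
                return ADown(cin, cout, rng=rng)
            return ConvBNAct(cin, cout, 3, stride=2, rng=rng)

        def shallow_block(c):
            if cfg.use_repncspelan4:
                return RepNCSPELAN4(c, c, n=n, rng=rng)
            return C2f(c, c, n=n, rng=rng)

        def deep_block(c):
            if cfg.use_c2f_se:
                return C2fSE(c, c, n=n, rng=rng)
            return C2f(c, c, n=n, rng=rng)

        idx = 0
        for stage in range(1, _N_STAGES + 1):
            cin, cout = w[stage - 1], w[stage]
            layers: list[Module] = [down(cin, cout)]
            layers.append(shallow_block(cout) if stage <= 2 else deep_block(cout))
            if cfg.use_msdffm and stage in cfg.msdffm_stages:
                layers.append(MSDFFM(cout, rng=rng))
            if cfg.use_msf3m and stage in cfg.msf3m_stages:
                layers.append(MSF3M(cout, rng=rng))
            if stage == _N_STAGES and cfg.use_sppelan:
                layers.append(SPPELAN(cout, cout, rng=rng))
            self.stages.append(layers)
            for layer in layers:
                setattr(self, f"s{stage}_{idx}", layer)
                idx += 1

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_features(x)[-1]

    def forward_features(self, x: Tensor) -> list[Tensor]:
        x = self.stem(x)
        feats = []
        for layers in self.stages:
            for layer in layers:
                x = layer(x)
            feats.append(x)
        return feats[1:]                      # P3 (s/8), P4 (s/16), P5 (s/32)


# ----------------------------------------------------------------------
# classification
# ----------------------------------------------------------------------

class ClassificationModel(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.backbone = _Backbone(cfg, rng)
        c5 = cfg.widths()[-1]
        hidden = max(c5, 64)
        self.neck = ConvBNAct(c5, hidden, 1, rng=rng)
        self.fc = Linear(hidden, cfg.num_classes, rng=rng)

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        t = x if isinstance(x, Tensor) else Tensor(x)
        return self.fc(global_avg_pool(self.neck(self.backbone(t))))

    def predict_proba(self, x) -> np.ndarray:
        self.eval()
        logits = self.forward(x)
        return np.exp(ad.log_softmax(logits, axis=-1).data)

    def predict(self, x) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=-1)


# ----------------------------------------------------------------------
# segmentation
# ----------------------------------------------------------------------

class SegmentationModel(Module):
    """Prototype-mask instance head over a Fourier-up-sampled neck."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.backbone = _Backbone(cfg, rng)
        w = cfg.widths()
        c3, c4, c5 = w[2], w[3], w[4]
        n = cfg.depth()

        def up(c):
            if cfg.use_fourier_upsample:
                return FourierUpsample(c, rng=rng)
            return _NearestUp()

        self.up1 = up(c5)
        self.n4 = C2fSE(c5 + c4, c4, n=n, rng=rng) if cfg.use_c2f_se else \
            C2f(c5 + c4, c4, n=n, rng=rng)
        self.att4 = MSDFFM(c4, rng=rng) if cfg.use_msdffm else None
        self.up2 = up(c4)
        self.n3 = C2f(c4 + c3, c3, n=n, rng=rng)
        self.att3 = MSDFFM(c3, rng=rng) if cfg.use_msdffm else None

        nm = cfg.num_prototypes
        self.proto = ConvBNAct(c3, nm, 3, rng=rng)
        self.head = Conv2d(c3, 1 + cfg.num_classes + nm, 1, rng=rng)
        # objectness prior: start pessimistic so an untrained model is silent
        self.head.bias.data[0] = -5.0

    def forward(self, x: Tensor | np.ndarray):
        t = x if isinstance(x, Tensor) else Tensor(x)
        p3, p4, p5 = self.backbone.forward_features(t)
        y = ad.concat([self.up1(p5), p4], axis=1)
        y = self.n4(y)
        if self.att4 is not None:
            y = self.att4(y)
        y = ad.concat([self.up2(y), p3], axis=1)
        y = self.n3(y)
        if self.att3 is not None:
            y = self.att3(y)
        return self.head(y), self.proto(y)

    def predict(self, image: np.ndarray) -> list[dict]:
        """Decode per-instance (class, confidence, mask, polygon) predictions.

        ``image`` is a single (3, H, W) array in [0, 1].  Instances are
        grid cells whose objectness·class score clears
        ``conf_threshold``; masks come from the prototype/coefficient
        product at ``mask_threshold``, greedily de-duplicated by mask
        overlap.
        """
        self.eval()
        head, proto = self.forward(image[None])
        h = head.data[0]
        pr = proto.data[0]                            # (nm, Hf, Wf)
        nc = self.cfg.num_classes
        obj = _sigmoid(h[0])
        cls = _sigmoid(h[1:1 + nc])
        coef = h[1 + nc:]
        conf_map = obj * cls.max(axis=0)
        ys, xs = np.where(conf_map >= self.cfg.conf_threshold)
        order = np.argsort(-conf_map[ys, xs])
        H, W = image.shape[-2:]
        scale = H // pr.shape[-2] if pr.shape[-2] else 1
        out: list[dict] = []
        taken: list[np.ndarray] = []
        for idx in order:
            y, x = ys[idx], xs[idx]
            mask_small = _sigmoid(np.einsum("m,mhw->hw", coef[:, y, x], pr))
            mask = np.kron(mask_small, np.ones((scale, scale)))[:H, :W]
            binmask = mask >= self.cfg.mask_threshold
            if not binmask.any():
                continue
            if any(_mask_iou(binmask, t) > 0.5 for t in taken):
                continue
            taken.append(binmask)
            out.append({
                "class_id": int(cls[:, y, x].argmax()),
                "confidence": float(conf_map[y, x]),
                "mask": binmask,
                "polygon": _mask_to_polygon(binmask),
            })
        return out


class _NearestUp(Module):
    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        y = x.reshape(b, c, h, 1, w, 1)
        y = ad.concat([y, y], axis=3)
        y = ad.concat([y, y], axis=5)
        return y.reshape(b, c, 2 * h, 2 * w)


def _sigmoid(a: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(a, -500, 500)))


def _mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    return float(np.logical_and(a, b).sum() / union) if union else 0.0


def _mask_to_polygon(mask: np.ndarray) -> np.ndarray | None:
    """Longest 0.5-level contour as normalized (x, y) vertices."""
    from skimage import measure
    contours = measure.find_contours(np.pad(mask.astype(float), 1), 0.5)
    if not contours:
        return None
    c = max(contours, key=len) - 1.0
    h, w = mask.shape
    poly = np.stack([np.clip(c[:, 1] / w, 0, 1), np.clip(c[:, 0] / h, 0, 1)],
                    axis=1)
    return poly if len(poly) >= 3 else None


# ----------------------------------------------------------------------
# assembly API
# ----------------------------------------------------------------------

def build_model(config: ModelConfig):
    """Construct the configured network; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    if config.task == "classification":
        return ClassificationModel(config, rng)
    return SegmentationModel(config, rng)


def param_count(model: Module) -> int:
    """Exact number of learnable scalars."""
    return int(sum(p.data.size for p in model.parameters()))


def param_megabytes(model: Module, bytes_per_param: int = 4) -> float:
    return param_count(model) * bytes_per_param / 1e6


# ----------------------------------------------------------------------
# training
# ----------------------------------------------------------------------

@dataclass
class ClsDataset:
    """In-memory classification dataset: (N, 3, H, W) float images in [0, 1]."""

    train_images: np.ndarray
    train_labels: np.ndarray
    val_images: np.ndarray
    val_labels: np.ndarray
    class_names: tuple[str, ...] = ("mature", "semi_mature")

    def __post_init__(self):
        if len(self.train_images) == 0:
            raise ValueError("empty training set")


def _accuracy(model: ClassificationModel, images, labels, batch: int) -> float:
    correct = 0
    for i in range(0, len(images), batch):
        correct += int((model.predict(images[i:i + batch]) ==
                        labels[i:i + batch]).sum())
    return correct / len(images)


def train_smoke(model: ClassificationModel, dataset: ClsDataset,
                config: ModelConfig, verbose: bool = False) -> dict:
    """SGD training loop with linear lr decay and patience early stopping.

    Returns a history dict with per-epoch train loss, validation
    accuracy and learning rate.  Training is single-process, so a
    fixed ``config.seed`` reproduces the history exactly.
    """
    if len(dataset.train_images) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed + 1)
    opt = SGD(model.parameters(), lr=config.lr0, momentum=config.momentum,
              weight_decay=config.weight_decay)
    history = {"train_loss": [], "val_accuracy": [], "lr": []}
    best, stale, best_state = -np.inf, 0, None
    n = len(dataset.train_images)
    for epoch in range(config.epochs):
        frac = epoch / max(config.epochs - 1, 1)
        lr = config.lr0 * (1.0 - frac * (1.0 - config.lrf))
        opt.lr = lr
        model.train()
        perm = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = perm[i:i + config.batch_size]
            logits = model(dataset.train_images[idx])
            loss = cross_entropy(logits, dataset.train_labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        acc = _accuracy(model, dataset.val_images, dataset.val_labels,
                        config.batch_size)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_accuracy"].append(acc)
        history["lr"].append(lr)
        if verbose:
            print(f"epoch {epoch + 1:3d}  loss {history['train_loss'][-1]:.4f}"
                  f"  val_acc {acc:.4f}")
        if acc > best:
            best, stale = acc, 0
            best_state = model.state_dict()
        else:
            stale += 1
            if stale >= config.patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    history["epochs_run"] = len(history["train_loss"])
    history["best_val_accuracy"] = float(best)
    return history


# ----------------------------------------------------------------------
# checkpoints: one weights file + a plain-text config sidecar
# ----------------------------------------------------------------------

def save_checkpoint(model: Module, config: ModelConfig, path: str) -> None:
    np.savez(path if path.endswith(".npz") else path + ".npz",
             **model.state_dict())
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh)


def load_checkpoint(path: str):
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".yaml") as fh:
        raw = yaml.safe_load(fh)
    for key in ("base_channels", "msdffm_stages", "msf3m_stages"):
        raw[key] = tuple(raw[key])
    config = ModelConfig(**raw)
    model = build_model(config)
    state = dict(np.load(base + ".npz"))
    model.load_state_dict(state)
    return model, config
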