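"""2D U-Net lung segmentation, majority-vote ensembling and Dice concordance.

One network is trained per human rater on that rater's annotations; their
binarised predictions are fused pixelwise by strict majority vote, the
same rule used to form the physician consensus.  Concordance between
masks is measured with the volumetric Dice coefficient (VDC), computed
over the whole 3D stack rather than slice-averaged.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._nn import Adam, UNet2D, dice_bce_loss, sigmoid
from .core import MaskStack, MriVolume
from .image_io import normalize_for_model


@dataclass
class SegModelConfig:
    """Hyperparameters of one per-rater segmentation network."""

    depth: int = 3
    base_channels: int = 8
    loss: str = "dice_bce"
    learning_rate: float = 1e-3
    epochs: int = 20
    batch_size: int = 8
    augment_flip_lr: bool = False
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss != "dice_bce":
            raise ValueError(f"unknown loss {self.loss!r}")


class UNetSegmenter:
    """Slice-wise 2D U-Net segmenter with an sklearn-style interface.

    ``fit`` consumes whole volumes and congruent binary masks, trains on
    the individual axial slices, and records the per-epoch training loss
    in ``loss_history_``; ``predict_proba``/``predict`` run slice-by-slice
    inference on a volume.
    """

    def __init__(
        self,
        depth: int = 3,
        base_channels: int = 8,
        loss: str = "dice_bce",
        learning_rate: float = 1e-3,
        epochs: int = 20,
        batch_size: int = 8,
        augment_flip_lr: bool = False,
        threshold: float = 0.5,
        seed: int = 0,
    ):
        self.depth = depth
        self.base_channels = base_channels
        self.loss = loss
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.augment_flip_lr = augment_flip_lr
        self.threshold = threshold
        self.seed = seed

    _param_names = (
        "depth",
        "base_channels",
        "loss",
        "learning_rate",
        "epochs",
        "batch_size",
        "augment_flip_lr",
        "threshold",
        "seed",
    )

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "UNetSegmenter":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    @classmethod
    def from_config(cls, config: SegModelConfig) -> "UNetSegmenter":
        return cls(**dataclasses.asdict(config))

    # -- training -----------------------------------------------------

    def _stack_slices(self, volumes, masks):
        xs, ys = [], []
        for vol, msk in zip(volumes, masks):
            if msk.shape != vol.shape:
                raise ValueError(
                    f"mask shape {msk.shape} does not match volume shape {vol.shape}"
                )
            arr = normalize_for_model(vol).intensities
            for k in range(arr.shape[2]):
                xs.append(arr[:, :, k])
                ys.append(msk.values[:, :, k].astype(np.float64))
        return np.stack(xs)[:, None], np.stack(ys)[:, None]

    def fit(self, volumes: list[MriVolume], masks: list[MaskStack]) -> "UNetSegmenter":
        SegModelConfig(**self.get_params())  # validate hyperparameters
        if len(volumes) == 0 or len(volumes) != len(masks):
            raise ValueError("need equal, non-zero numbers of volumes and masks")
        x, y = self._stack_slices(volumes, masks)
        self.net_ = UNet2D(self.depth, self.base_channels, in_channels=1, seed=self.seed)
        opt = Adam(self.net_.params(), lr=self.learning_rate)
        rng = np.random.default_rng(self.seed + 1)
        n = x.shape[0]
        self.loss_history_ = []
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = x[idx], y[idx]
                if self.augment_flip_lr and rng.random() < 0.5:
                    xb, yb = xb[:, :, :, ::-1], yb[:, :, :, ::-1]
                logits = self.net_.forward(xb)
                loss, dlogits = dice_bce_loss(logits, yb)
                self.net_.zero_grad()
                self.net_.backward(dlogits)
                opt.step()
                losses.append(loss)
            self.loss_history_.append(float(np.mean(losses)))
        self.n_training_slices_ = n
        return self

    # -- inference ----------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "net_"):
            raise RuntimeError("model is not fitted; call fit() first")

    def predict_proba(self, volume: MriVolume, batch_size: int = 16) -> MaskStack:
        """Per-pixel lung probability for every axial slice."""
        self._check_fitted()
        arr = normalize_for_model(volume).intensities
        div = 2**self.depth
        if arr.shape[0] % div or arr.shape[1] % div:
            raise ValueError(
                f"in-plane shape {arr.shape[:2]} not divisible by 2^depth={div}; "
                "crop/pad the volume as was done for training"
            )
        probs = np.empty_like(arr)
        ks = range(arr.shape[2])
        for start in range(0, arr.shape[2], batch_size):
            batch = [arr[:, :, k] for k in ks[start : start + batch_size]]
            logits = self.net_.forward(np.stack(batch)[:, None])
            p = sigmoid(logits)[:, 0]
            for i, k in enumerate(ks[start : start + batch_size]):
                probs[:, :, k] = p[i]
        return MaskStack(probs, volume.spacing, rater_id="proba", binary=False)

    def predict(self, volume: MriVolume, threshold: float | None = None) -> MaskStack:
        """Binary lung mask at ``threshold`` (default: the configured cutoff)."""
        thr = self.threshold if threshold is None else threshold
        proba = self.predict_proba(volume)
        return MaskStack(
            (proba.values >= thr).astype(np.uint8), volume.spacing, rater_id="model"
        )

    # -- persistence ---------------------------------------------------

    def save(self, path) -> None:
        self._check_fitted()
        path = Path(path)
        arrays = {f"p{i}": p for i, (p, _) in enumerate(self.net_.params())}
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {"params": self.get_params(), "loss_history": self.loss_history_}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "UNetSegmenter":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(**meta["params"])
        model.net_ = UNet2D(model.depth, model.base_channels, in_channels=1, seed=model.seed)
        with np.load(path.with_suffix(".npz")) as data:
            for i, (p, _) in enumerate(model.net_.params()):
                p[...] = data[f"p{i}"]
        model.loss_history_ = meta["loss_history"]
        return model


def train_segmenter(
    volumes: list[MriVolume], masks: list[MaskStack], config: SegModelConfig
) -> UNetSegmenter:
    """Train one per-rater network on that rater's annotations."""
    return UNetSegmenter.from_config(config).fit(volumes, masks)


def predict_mask(
    model: UNetSegmenter, volume: MriVolume, threshold: float | None = 0.5
) -> MaskStack:
    """Slice-wise inference; binary at ``threshold``, probabilistic if None."""
    if threshold is None:
        return model.predict_proba(volume)
    if threshold >= 1.0:
        proba = model.predict_proba(volume)
        return MaskStack(
            (proba.values >= threshold).astype(np.uint8), volume.spacing, rater_id="model"
        )
    return model.predict(volume, threshold=threshold)


# -- ensembling and concordance ---------------------------------------


def majority_vote(masks: list[MaskStack], tie_value: int = 0) -> MaskStack:
    """Pixelwise strict majority vote over binary masks.

    A pixel is foreground iff strictly more than half the members vote 1.
    With an even member count, exactly-half ties take ``tie_value``
    (default 0, the conservative choice) and the tie count is recorded on
    the result as ``n_tied_pixels``.
    """
    if len(masks) < 1:
        raise ValueError("majority vote needs at least one mask")
    first = masks[0]
    for m in masks[1:]:
        first.check_congruent(m)
    for m in masks:
        if not m.binary:
            raise ValueError("majority vote requires binary masks")
    votes = np.sum([m.values for m in masks], axis=0)
    n = len(masks)
    fused_arr = (votes * 2 > n).astype(np.uint8)
    n_tied = 0
    if n % 2 == 0:
        tied = votes * 2 == n
        n_tied = int(tied.sum())
        if tie_value:
            fused_arr[tied] = 1
    fused = MaskStack(fused_arr, first.spacing, rater_id="ensemble")
    fused.n_tied_pixels = n_tied
    return fused


def volumetric_dice(a: MaskStack, b: MaskStack) -> float:
    """Volumetric Dice coefficient 2|A∩B| / (|A| + |B|) over the whole stack."""
    a.check_congruent(b)
    if not (a.binary and b.binary):
        raise ValueError("VDC requires binary masks")
    va, vb = a.values.astype(bool), b.values.astype(bool)
    denom = int(va.sum()) + int(vb.sum())
    if denom == 0:
        raise ValueError("VDC undefined: both masks are empty")
    return 2.0 * int((va & vb).sum()) / denom


@dataclass
class ConcordanceReport:
    """Ensemble-vs-rater, interrater and ensemble-vs-consensus VDCs."""

    ensemble_vs_rater: dict[str, float]
    interrater: np.ndarray  # symmetric matrix, 1 on the diagonal
    rater_ids: list[str]
    ensemble_vs_consensus: float
    consensus_tie_pixels: int = 0
    notes: list[str] = field(default_factory=list)

    @property
    def mean_interrater_vdc(self) -> float:
        n = self.interrater.shape[0]
        iu = np.triu_indices(n, k=1)
        return float(self.interrater[iu].mean())

    def to_json(self) -> str:
        return json.dumps(
            {
                "ensemble_vs_rater": self.ensemble_vs_rater,
                "interrater": self.interrater.tolist(),
                "rater_ids": self.rater_ids,
                "ensemble_vs_consensus": self.ensemble_vs_consensus,
                "mean_interrater_vdc": self.mean_interrater_vdc,
                "consensus_tie_pixels": self.consensus_tie_pixels,
                "notes": self.notes,
            },
            indent=2,
        )


def evaluate_concordance(raters: list[MaskStack], ensemble: MaskStack) -> ConcordanceReport:
    """Compare an ensemble mask against every rater and the rater consensus."""
    if len(raters) < 2:
        raise ValueError("concordance evaluation needs at least 2 raters")
    ids = [m.rater_id or f"rater-{i + 1}" for i, m in enumerate(raters)]
    n = len(raters)
    inter = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            inter[i, j] = inter[j, i] = volumetric_dice(raters[i], raters[j])
    consensus = majority_vote(raters)
    notes = []
    if n % 2 == 0:
        notes.append(
            f"even rater count ({n}): consensus ties set to background "
            f"({consensus.n_tied_pixels} tied pixels)"
        )
    return ConcordanceReport(
        ensemble_vs_rater={rid: volumetric_dice(ensemble, m) for rid, m in zip(ids, raters)},
        interrater=inter,
        rater_ids=ids,
        ensemble_vs_consensus=volumetric_dice(ensemble, consensus),
        consensus_tie_pixels=getattr(consensus, "n_tied_pixels", 0),
        notes=notes,
    )
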