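"""Training, evaluation, ablation and baseline harness.

The desk-scale profile trains the dual-branch classifier with plain SGD
(learning rate 0.01) on synthetic campaigns: micrographs are reduced to
32 px inputs, texture and morphology features are standardized on the
training split, and grades are the five strength classes.  The full-scale
profile (500 epochs, batch 128) is the same code at different settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import train_test_split

from tracheidnet import glcm, morphology
from tracheidnet.grading import GRADE_LABELS, classify_grade, compressive_strength
from tracheidnet.network import AttentionConfig, DualFCN, DualFCNConfig, cross_entropy
from tracheidnet.selection import SELECTED_FEATURES
from tracheidnet.synth import SynthConfig, generate_dataset


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.  ``desk()`` gives the reduced-scale profile."""

    lr: float = 0.01
    epochs: int = 500
    batch_size: int = 128
    split: float = 0.8
    seed: int = 0
    augment: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.split < 1:
            raise ValueError("split fraction must lie in (0, 1)")
        if self.lr < 0:
            raise ValueError("learning rate must be non-negative")

    @classmethod
    def desk(cls, seed: int = 0, **kw) -> "TrainConfig":
        return cls(epochs=30, batch_size=32, seed=seed, **kw)


@dataclass
class TracheidDataset:
    """Arrays consumed by the network.

    ``features`` are raw (unstandardized) selected features; ``images``
    are float images in [0, 1]; ``labels`` index :data:`GRADE_LABELS`;
    ``sigma`` is the strength in MPa.
    """

    features: np.ndarray
    images: np.ndarray
    labels: np.ndarray
    sigma: np.ndarray
    feature_names: tuple[str, ...] = SELECTED_FEATURES

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class EvalReport:
    """Evaluation summary: the grade-wise accuracy decomposition."""

    accuracy: float
    per_grade_correct: dict[str, int]
    confusion: np.ndarray              # rows true, cols predicted
    loss: float
    margin_mean: float | None = None
    margin_sd: float | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# dataset assembly


def _block_mean(img: np.ndarray, out_px: int) -> np.ndarray:
    h, w = img.shape
    if h % out_px or w % out_px:
        raise ValueError(f"image {img.shape} not divisible into {out_px} blocks")
    fh, fw = h // out_px, w // out_px
    return img.reshape(out_px, fh, out_px, fw).mean(axis=(1, 3))


def make_desk_dataset(
    n_images: int = 500,
    seed: int = 1,
    net_image_px: int = 32,
    gen_image_px: int = 256,
    positions: int = 4,
) -> TracheidDataset:
    """The default synthetic benchmark: balanced grades, one magnification.

    ``n_images`` must be a multiple of ``positions``; specimens cycle
    through the five grades so the campaign is balanced by design.
    Features are the selected five (CON, CORR, AREA, PERIMETER, ASM):
    texture from the co-occurrence pipeline, morphology from the
    ground-truth masks.
    """
    if n_images % positions:
        raise ValueError("n_images must be a multiple of positions")
    config = SynthConfig(
        n_specimens=n_images // positions,
        positions_per_specimen=positions,
        magnifications=(200,),
        image_size=(gen_image_px, gen_image_px),
        seed=seed,
    )
    micros, masks, records = generate_dataset(config)
    by_id = {r.specimen_id: r for r in records}
    feats, imgs, labels, sigmas = [], [], [], []
    for mic, mask in zip(micros, masks):
        tex = glcm.image_texture(mic.pixels)
        morph = morphology.image_morphology(mask, mic.magnification,
                                            config.scale_um_per_px)
        row = {**tex.to_dict(), "AREA": morph.area_um2,
               "PERIMETER": morph.perimeter_um}
        feats.append([row[name] for name in SELECTED_FEATURES])
        imgs.append(_block_mean(mic.pixels.astype(float), net_image_px) / 255.0)
        rec = by_id[mic.specimen_id]
        sw = compressive_strength(rec.failure_load_Pmax, rec.width_b, rec.thickness_t)
        sigmas.append(sw)
        labels.append(GRADE_LABELS.index(classify_grade(sw)))
    return TracheidDataset(
        features=np.asarray(feats, dtype=float),
        images=np.asarray(imgs, dtype=float),
        labels=np.asarray(labels, dtype=int),
        sigma=np.asarray(sigmas, dtype=float),
    )


def split_dataset(
    labels: np.ndarray | pd.Series,
    split: float = 0.8,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test index split, stratified by grade.

    Stratification applies when every class has at least two members;
    otherwise the split is simple random.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < 5:
        raise ValueError("need at least 5 rows to split")
    classes, counts = np.unique(labels, return_counts=True)
    n_test = int(np.ceil(n * (1.0 - split)))
    # stratify only when sklearn can honour it: every class twice and
    # both partitions at least one row per class
    can_stratify = counts.min() >= 2 and min(n_test, n - n_test) >= len(classes)
    strat = labels if can_stratify else None
    idx = np.arange(n)
    train_idx, test_idx = train_test_split(
        idx, test_size=1.0 - split, random_state=seed, stratify=strat
    )
    return np.sort(train_idx), np.sort(test_idx)


# ---------------------------------------------------------------------------
# metrics


def accuracy(pred: np.ndarray, true: np.ndarray) -> float:
    """Fraction of correct grade predictions (sum of per-grade correct
    counts over the total — identical to plain proportion correct)."""
    pred, true = np.asarray(pred), np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError("prediction/label shapes differ")
    return float(np.mean(pred == true))


def margin_stats(true_sigma: np.ndarray, pred_sigma: np.ndarray) -> tuple[float, float]:
    """Mean and population SD of the residuals true - predicted (MPa)."""
    true_sigma, pred_sigma = np.asarray(true_sigma), np.asarray(pred_sigma)
    if true_sigma.size == 0:
        raise ValueError("empty residual input")
    resid = true_sigma - pred_sigma
    return float(resid.mean()), float(resid.std(ddof=0))


# ---------------------------------------------------------------------------
# training


def _standardize(x: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (x - mean) / sd


def _augment_batch(images: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Label-preserving dihedral augmentation: flips and 90-degree turns."""
    out = images.copy()
    flips_h = rng.random(len(out)) < 0.5
    flips_v = rng.random(len(out)) < 0.5
    turns = rng.integers(0, 4, size=len(out))
    for i in range(len(out)):
        img = out[i]
        if flips_h[i]:
            img = img[:, ::-1]
        if flips_v[i]:
            img = img[::-1, :]
        out[i] = np.rot90(img, turns[i])
    return out


def train(
    model: DualFCN,
    dataset: TracheidDataset,
    config: TrainConfig,
    train_idx: np.ndarray | None = None,
) -> dict:
    """SGD on cross-entropy (plus MSE in regression mode).

    Standardizes features and centers images on the training rows and
    stores the scaler on the model, so later evaluation reuses it.
    Returns the history dict with per-epoch loss and accuracy.
    """
    if train_idx is None:
        train_idx = np.arange(len(dataset))
    feats = dataset.features[train_idx]
    model.feature_mean = feats.mean(axis=0)
    model.feature_sd = np.where(feats.std(axis=0) > 0, feats.std(axis=0), 1.0)
    x = _standardize(feats, model.feature_mean, model.feature_sd)
    imgs = dataset.images[train_idx] - 0.5
    y = dataset.labels[train_idx]
    sg = dataset.sigma[train_idx]
    rng = np.random.default_rng(config.seed)
    history = {"loss": [], "accuracy": []}
    n = len(train_idx)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            xb, ib, yb, sb = x[sel], imgs[sel], y[sel], sg[sel]
            if config.augment:
                ib = _augment_batch(ib, rng)
            probs, sigma_hat = model.forward(xb, ib)
            loss = cross_entropy(probs, yb, model.config.n_classes)
            if model.config.regression_head:
                loss += float(np.mean((sigma_hat - sb) ** 2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {_epoch}, batch {start // config.batch_size}: "
                    f"loss={loss}, lr={config.lr}"
                )
            model.zero_grad()
            model.backward(yb, sb if model.config.regression_head else None)
            for p, g in zip(model.parameters, model.gradients):
                p -= config.lr * g
            ep_loss += loss * len(sel)
            ep_correct += int((probs.argmax(axis=1) == yb).sum())
        history["loss"].append(ep_loss / n)
        history["accuracy"].append(ep_correct / n)
    return history


def evaluate(
    model: DualFCN,
    dataset: TracheidDataset,
    idx: np.ndarray | None = None,
    batch_size: int = 128,
) -> EvalReport:
    """Grade accuracy, per-grade correct counts, confusion and margins."""
    if idx is None:
        idx = np.arange(len(dataset))
    mean = getattr(model, "feature_mean", np.zeros(dataset.features.shape[1]))
    sd = getattr(model, "feature_sd", np.ones(dataset.features.shape[1]))
    x = _standardize(dataset.features[idx], mean, sd)
    imgs = dataset.images[idx] - 0.5
    y = dataset.labels[idx]
    preds, sigmas = [], []
    loss_sum = 0.0
    for start in range(0, len(idx), batch_size):
        sl = slice(start, start + batch_size)
        probs, sigma_hat = model.forward(x[sl], imgs[sl])
        loss_sum += cross_entropy(probs, y[sl], model.config.n_classes) * len(y[sl])
        preds.append(probs.argmax(axis=1))
        if sigma_hat is not None:
            sigmas.append(sigma_hat)
    pred = np.concatenate(preds)
    n_cls = model.config.n_classes
    confusion = np.zeros((n_cls, n_cls), dtype=int)
    for t, p in zip(y, pred):
        confusion[t, p] += 1
    per_grade = {
        g: int(confusion[i, i]) for i, g in enumerate(GRADE_LABELS[:n_cls])
    }
    report = EvalReport(
        accuracy=accuracy(pred, y),
        per_grade_correct=per_grade,
        confusion=confusion,
        loss=loss_sum / len(idx),
    )
    if sigmas:
        mu, sdv = margin_stats(dataset.sigma[idx], np.concatenate(sigmas))
        report.margin_mean, report.margin_sd = mu, sdv
    return report


# ---------------------------------------------------------------------------
# ablations and baselines


def _model_config(
    dataset: TracheidDataset,
    channel: str = "double",
    attention: str = "sparse",
    image_px: int | None = None,
) -> DualFCNConfig:
    fam = {"none": "none", "spatial": "dense"}.get(attention, attention)
    return DualFCNConfig(
        feature_dim=dataset.features.shape[1],
        image_size=image_px or dataset.images.shape[-1],
        attention=AttentionConfig(family=fam),
        use_feature_branch=channel == "double",
    )


def run_ablation(
    dataset: TracheidDataset,
    axes: dict[str, list[str]] | None = None,
    config: TrainConfig = TrainConfig.desk(),
) -> pd.DataFrame:
    """Train one model per switch combination on an identical split.

    ``axes`` maps axis name to levels; supported axes are ``channel``
    (single | double), ``attention`` (none | spatial | atrous | local |
    sparse) and ``augment`` (off | on).  The "spatial" level is ungrouped
    dense attention over the spatial tokens.
    """
    axes = axes or {
        "channel": ["single", "double"],
        "attention": ["none", "sparse"],
        "augment": ["off", "on"],
    }
    channels = axes.get("channel", ["double"])
    attentions = axes.get("attention", ["sparse"])
    augments = axes.get("augment", ["off"])
    train_idx, test_idx = split_dataset(dataset.labels, config.split, config.seed)
    rows = []
    for ch in channels:
        for at in attentions:
            for aug in augments:
                model = DualFCN(_model_config(dataset, ch, at),
                                init_seed=config.seed)
                cfg = replace(config, augment=aug == "on")
                train(model, dataset, cfg, train_idx)
                rep = evaluate(model, dataset, test_idx)
                rows.append({"channel": ch, "attention": at,
                             "augment": aug, "accuracy": rep.accuracy})
    return pd.DataFrame(rows)


BASELINES = ("random_forest", "cnn", "single_fcn", "double_fcn", "dual_sa_fcn")

# forest hyperparameters shared with the feature-selection stage
RF_N_TREES = 900
RF_MAX_DEPTH = 35


def baseline_models(
    dataset: TracheidDataset,
    which: tuple[str, ...] = BASELINES,
    config: TrainConfig = TrainConfig.desk(),
) -> pd.DataFrame:
    """Accuracy table of the reference models on one shared split.

    The random forest regresses strength from the features and grades the
    predictions; the neural baselines are reduced variants of the dual
    model (image-only with and without attention, dual without attention).
    """
    unknown = set(which) - set(BASELINES)
    if unknown:
        raise ValueError(f"unknown baseline(s): {sorted(unknown)}")
    train_idx, test_idx = split_dataset(dataset.labels, config.split, config.seed)
    rows = []
    for name in which:
        if name == "random_forest":
            forest = RandomForestRegressor(
                n_estimators=RF_N_TREES, max_depth=RF_MAX_DEPTH,
                random_state=config.seed, n_jobs=1,
            )
            forest.fit(dataset.features[train_idx], dataset.sigma[train_idx])
            pred_sigma = forest.predict(dataset.features[test_idx])
            pred = np.array([
                GRADE_LABELS.index(classify_grade(max(0.0, s))) for s in pred_sigma
            ])
            acc = accuracy(pred, dataset.labels[test_idx])
        else:
            spec = {
                "cnn": dict(channel="single", attention="none"),
                "single_fcn": dict(channel="single", attention="none"),
                "double_fcn": dict(channel="double", attention="none"),
                "dual_sa_fcn": dict(channel="double", attention="sparse"),
            }[name]
            mc = _model_config(dataset, **spec)
            if name == "cnn":
                mc = replace(mc, head=(128, 5))
            model = DualFCN(mc, init_seed=config.seed)
            train(model, dataset, config, train_idx)
            acc = evaluate(model, dataset, test_idx).accuracy
        rows.append({"model": name, "accuracy": acc})
    return pd.DataFrame(rows)
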