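"""Patient-level cross-validation, training loop, metrics and ablations.

Five-fold splits are made at the patient level with class-balanced
stratification so that no patient leaks between train and validation and
the metastatic/non-metastatic ratio stays consistent across folds.
Training minimises the bidirectional KL contrastive objective with AdamW
(batch size 4 by default), runs a minimum number of epochs, and early-stops
on validation loss.  Reported scores are the metastatic-class probabilities
from the prompt-ensemble classifier; metrics are
sensitivity/specificity/accuracy/precision/F1, trapezoidal ROC AUC and
decision-curve net benefit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve as sk_roc_curve

from .autodiff import no_grad
from .model import AftoConfig, DualBranchModel, ModelConfig
from .nn import AdamW
from .preprocess import preprocess_clip
from .prompts import PromptPool, default_pool, fixed_prompt, render, sample_prompt
from .synthetic import CeusSample

MODULE_ABLATIONS = (
    "Baseline",
    "Baseline + RP",
    "Baseline + AFTO (video)",
    "Baseline + AFTO (text)",
    "Baseline + AFTO (both)",
    "Baseline + RP + AFTO",
)
FRAME_ABLATIONS = (2, 4, 8, 10, 12, 16, 32)


# ---------------------------------------------------------------------------
# fold construction
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class FoldAssignment:
    k: int
    assignment: dict[str, int]

    def fold_patients(self, fold: int) -> list[str]:
        return [p for p, f in self.assignment.items() if f == fold]

    def folds(self) -> list[list[str]]:
        return [self.fold_patients(f) for f in range(self.k)]


def make_folds(patient_ids, labels, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Stratified patient-level fold assignment.

    Patients of each class are shuffled and dealt round-robin, always into
    the currently least-loaded fold, so per-fold class counts stay within
    one patient of the stratified ideal and the folds partition the cohort.
    """
    ids = list(patient_ids)
    labels = np.asarray(list(labels))
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate patient ids")
    if len(ids) < k:
        raise ValueError("fewer patients than folds")
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    load = [0] * k
    for cls in classes:
        members = [ids[i] for i in range(len(ids)) if labels[i] == cls]
        if len(members) < k:
            warnings.warn(
                f"class {cls} has fewer members ({len(members)}) than folds ({k}); "
                "stratification is best-effort", stacklevel=2,
            )
        members = [members[i] for i in rng.permutation(len(members))]
        i = 0
        while i < len(members):
            for f in sorted(range(k), key=lambda f: (load[f], f)):
                if i >= len(members):
                    break
                assignment[members[i]] = f
                load[f] += 1
                i += 1
    return FoldAssignment(k=k, assignment=assignment)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adamw"
    batch_size: int = 4
    min_epochs: int = 50
    max_epochs: int = 100
    patience: int = 10
    lr: float = 1e-4
    weight_decay: float = 0.01
    cosine_decay: bool = True
    augment: bool = True
    seed: int = 0
    random_prompt: bool = True
    use_clinical_text: bool = True
    n_frames: int = 10
    half_window: int = 5
    binarize_threshold: float = 50.0

    def __post_init__(self):
        if self.min_epochs < 1:
            raise ValueError("min_epochs must be >= 1")
        if self.batch_size < 2:
            raise ValueError("the contrastive loss needs batches of >= 2")


@dataclass
class FoldHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)


def _prepare_clips(samples: list[CeusSample], tc: TrainConfig,
                   frame_size: tuple[int, int]) -> np.ndarray:
    clips = [
        preprocess_clip(
            s.frames, s.keyframe_index, tc.binarize_threshold,
            tc.half_window, tc.n_frames, frame_size,
        )[0]
        for s in samples
    ]
    return np.stack(clips)


def _instance_text(sample: CeusSample, pool: PromptPool, tc: TrainConfig,
                   rng: np.random.Generator | None) -> str:
    template = sample_prompt(pool, rng) if (tc.random_prompt and rng is not None) \
        else fixed_prompt(pool)
    text = render(template, pool.class_labels[sample.class_label])
    if tc.use_clinical_text:
        text = text + ". " + ", ".join(sample.clinical_attributes.values())
    return text


def train_fold(train_samples: list[CeusSample], val_samples: list[CeusSample],
               model_config: ModelConfig, tc: TrainConfig,
               pool: PromptPool | None = None,
               init_state: dict | None = None) -> tuple[DualBranchModel, FoldHistory]:
    """Train one fold; returns the model and per-epoch loss history.

    Runs at least ``min_epochs`` epochs and stops once validation loss has
    not improved for ``patience`` consecutive epochs (or at ``max_epochs``).
    ``init_state`` warm-starts the backbone from pretrained weights (see
    :func:`pretrain_backbone`); with adapters attached and
    ``afto.freeze_backbone`` set, only the adapters and the temperature then
    train, which is the parameter-efficient fine-tuning regime.
    """
    if not train_samples or not val_samples:
        raise ValueError("empty train or validation split")
    train_pids = {s.patient_id for s in train_samples}
    if train_pids & {s.patient_id for s in val_samples}:
        raise ValueError("patient overlap between train and validation")
    if pool is None:
        pool = default_pool()

    rng = np.random.default_rng(tc.seed)
    model = DualBranchModel(model_config, seed=tc.seed)
    if init_state is not None:
        model.import_backbone_weights(init_state)
    clips = _prepare_clips(train_samples, tc, model_config.frame_size)
    val_clips = _prepare_clips(val_samples, tc, model_config.frame_size)
    labels = np.array([s.class_label for s in train_samples])
    val_labels = np.array([s.class_label for s in val_samples])
    val_texts = [_instance_text(s, pool, tc, None) for s in val_samples]

    opt = AdamW(model.trainable_parameters(), lr=tc.lr, weight_decay=tc.weight_decay)
    history = FoldHistory()
    best_val = math.inf
    since_best = 0
    for epoch in range(tc.max_epochs):
        if tc.cosine_decay:
            opt.lr = tc.lr * 0.5 * (1.0 + math.cos(math.pi * epoch / tc.max_epochs))
        order = rng.permutation(len(train_samples))
        epoch_losses = []
        for start in range(0, len(order), tc.batch_size):
            idx = order[start : start + tc.batch_size]
            if len(idx) < 2:
                continue
            batch = clips[idx]
            if tc.augment:
                batch = batch.copy()
                for b in range(len(idx)):
                    if rng.random() < 0.5:
                        batch[b] = batch[b, :, :, ::-1]  # horizontal flip, whole clip
                    batch[b] = np.clip(batch[b] * rng.uniform(0.85, 1.15), 0.0, 1.0)
            texts = [_instance_text(train_samples[i], pool, tc, rng) for i in idx]
            loss = model.contrastive_loss(batch, texts, labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        history.train_loss.append(float(np.mean(epoch_losses)))

        with no_grad():
            vloss = model.contrastive_loss(val_clips, val_texts, val_labels).item()
        history.val_loss.append(vloss)
        if vloss < best_val - 1e-6:
            best_val = vloss
            best_state = model.state_dict()
            since_best = 0
        else:
            since_best += 1
        if epoch + 1 >= tc.min_epochs and since_best > tc.patience:
            break
    model.load_state_dict(best_state)  # early stopping keeps the best-val model
    return model, history


def score_samples(model: DualBranchModel, samples: list[CeusSample],
                  tc: TrainConfig, pool: PromptPool) -> tuple[np.ndarray, np.ndarray]:
    """Metastatic-class probability per sample -> (y_true, y_score).

    When training texts carried the clinical-attribute suffix, the same
    suffix (a known input, unlike the class label) is appended to every
    rendered prompt of the sample's ensemble so that train and inference
    texts come from the same distribution.
    """
    clips = _prepare_clips(samples, tc, model.config.frame_size)
    if tc.use_clinical_text:
        from .prompts import class_prompt_texts

        scores = []
        for sample, clip in zip(samples, clips):
            suffix = ". " + ", ".join(sample.clinical_attributes.values())
            with no_grad():
                embs = [
                    model.encode_texts(
                        [t + suffix for t in class_prompt_texts(pool, c, mode="all")]
                    ).data
                    for c in range(len(pool.class_labels))
                ]
            scores.append(model.predict_proba(clip[None], pool, prompt_embs=embs)[0])
        probs = np.stack(scores)
    else:
        probs = model.predict_proba(clips, pool)
    return np.array([s.class_label for s in samples]), probs[:, 1]


def pretrain_backbone(samples: list[CeusSample], model_config: ModelConfig,
                      tc: TrainConfig, pool: PromptPool | None = None) -> dict:
    """Contrastively pretrain a backbone on a source cohort.

    Stands in for large-scale pretrained weights: the returned state dict
    warm-starts fine-tuning on a *disjoint* target cohort (full fine-tuning,
    or frozen-backbone adapter tuning with AFTO attached).  An internal
    stratified 80/20 split provides the validation loss for early stopping.
    """
    from dataclasses import replace as _replace

    mc = _replace(model_config, afto=AftoConfig(where="none"))
    folds = make_folds([s.patient_id for s in samples],
                       [s.class_label for s in samples], k=5, seed=tc.seed)
    val_ids = set(folds.fold_patients(0))
    train = [s for s in samples if s.patient_id not in val_ids]
    val = [s for s in samples if s.patient_id in val_ids]
    model, _ = train_fold(train, val, mc, tc, pool)
    return model.state_dict()


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    f1: float
    auc: float
    zero_division: bool = False

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy, "precision": self.precision,
            "f1": self.f1, "auc": self.auc,
        }


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    return (num / den, False) if den else (0.0, True)


def compute_metrics(y_true, y_score, threshold: float = 0.5) -> MetricsReport:
    """Confusion-matrix metrics at ``score >= threshold`` plus ROC AUC."""
    y_true = np.asarray(y_true).astype(int)
    y_score = np.asarray(y_score, dtype=float)
    if len(set(y_true.tolist())) < 2:
        raise ValueError("both classes must be present in y_true")
    y_pred = (y_score >= threshold).astype(int)
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    sen, z1 = _safe_div(tp, tp + fn)
    spe, z2 = _safe_div(tn, tn + fp)
    acc = (tp + tn) / len(y_true)
    pre, z3 = _safe_div(tp, tp + fp)
    f1, z4 = _safe_div(2 * pre * sen, pre + sen)
    area, _, _ = roc_auc(y_true, y_score)
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=sen,
                         specificity=spe, accuracy=acc, precision=pre, f1=f1,
                         auc=area, zero_division=z1 or z2 or z3 or z4)


def roc_auc(y_true, y_score) -> tuple[float, np.ndarray, np.ndarray]:
    """Trapezoidal ROC AUC with the curve points (ties averaged).

    Constant scores carry no ranking information and give AUC 0.5 (the
    random-guess diagonal).
    """
    y_true = np.asarray(y_true).astype(int)
    y_score = np.asarray(y_score, dtype=float)
    if len(set(y_true.tolist())) < 2:
        raise ValueError("both classes must be present")
    if np.unique(y_score).size == 1:
        return 0.5, np.array([0.0, 1.0]), np.array([0.0, 1.0])
    fpr, tpr, _ = sk_roc_curve(y_true, y_score)
    return float(sk_auc(fpr, tpr)), fpr, tpr


@dataclass(frozen=True)
class NetBenefitCurve:
    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray


def decision_curve(y_true, y_score, thresholds=None) -> NetBenefitCurve:
    """Decision-curve analysis: NB(p_t) = TP/N - (FP/N) * p_t / (1 - p_t)
    under the classification rule score >= p_t, with treat-all and
    treat-none (identically zero) reference strategies."""
    y_true = np.asarray(y_true).astype(int)
    y_score = np.asarray(y_score, dtype=float)
    if thresholds is None:
        thresholds = np.linspace(0.01, 0.99, 99)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds <= 0.0) or np.any(thresholds >= 1.0):
        raise ValueError("threshold probabilities must lie strictly in (0, 1)")
    n = len(y_true)
    prevalence = y_true.mean()
    odds = thresholds / (1.0 - thresholds)
    nb = np.empty_like(thresholds)
    for i, pt in enumerate(thresholds):
        pred = y_score >= pt
        tp = np.sum(pred & (y_true == 1))
        fp = np.sum(pred & (y_true == 0))
        nb[i] = tp / n - (fp / n) * odds[i]
    treat_all = prevalence - (1.0 - prevalence) * odds
    return NetBenefitCurve(thresholds=thresholds, net_benefit=nb,
                           treat_all=treat_all, treat_none=np.zeros_like(thresholds))


# ---------------------------------------------------------------------------
# cross-validation and ablation drivers
# ---------------------------------------------------------------------------
@dataclass
class CVResult:
    fold_metrics: list[MetricsReport]
    histories: list[FoldHistory]
    y_true: np.ndarray  # pooled over folds
    y_score: np.ndarray
    patient_ids: list[str]

    def pooled_metrics(self, threshold: float = 0.5) -> MetricsReport:
        return compute_metrics(self.y_true, self.y_score, threshold)

    def summary(self) -> dict[str, tuple[float, float]]:
        """Fold-wise mean +/- sd for each metric."""
        out = {}
        for key in ("sensitivity", "specificity", "accuracy", "precision", "f1", "auc"):
            vals = np.array([getattr(m, key) for m in self.fold_metrics])
            out[key] = (float(vals.mean()), float(vals.std(ddof=1) if len(vals) > 1 else 0.0))
        return out


def cross_validate(samples: list[CeusSample], model_config: ModelConfig,
                   tc: TrainConfig, k: int = 5,
                   pool: PromptPool | None = None,
                   folds: FoldAssignment | None = None,
                   init_state: dict | None = None) -> CVResult:
    """Patient-level stratified k-fold CV of the full pipeline."""
    if pool is None:
        pool = default_pool()
    ids = [s.patient_id for s in samples]
    labels = [s.class_label for s in samples]
    if folds is None:
        folds = make_folds(ids, labels, k=k, seed=tc.seed)
    by_id = {s.patient_id: s for s in samples}
    fold_metrics, histories = [], []
    all_true, all_score, all_pids = [], [], []
    for f in range(folds.k):
        val_ids = set(folds.fold_patients(f))
        train = [by_id[p] for p in ids if p not in val_ids]
        val = [by_id[p] for p in ids if p in val_ids]
        assert not ({s.patient_id for s in train} & {s.patient_id for s in val})
        model, hist = train_fold(train, val, model_config, tc, pool, init_state=init_state)
        y_true, y_score = score_samples(model, val, tc, pool)
        fold_metrics.append(compute_metrics(y_true, y_score))
        histories.append(hist)
        all_true.append(y_true)
        all_score.append(y_score)
        all_pids.extend(s.patient_id for s in val)
    return CVResult(
        fold_metrics=fold_metrics, histories=histories,
        y_true=np.concatenate(all_true), y_score=np.concatenate(all_score),
        patient_ids=all_pids,
    )


def _module_configs(model_config: ModelConfig, tc: TrainConfig, pretrained: bool):
    """The six module-ablation configurations.

    With pretrained weights (the intended setting) AFTO rows freeze the
    backbone and train only adapters + temperature, while the Baseline
    fine-tunes the whole backbone; without pretraining everything trains
    from scratch in every row.
    """
    for name in MODULE_ABLATIONS:
        rp = "RP" in name
        if "AFTO (video)" in name:
            where = "video"
        elif "AFTO (text)" in name:
            where = "text"
        elif "AFTO" in name:
            where = "both"
        else:
            where = "none"
        mc = replace(model_config, afto=AftoConfig(where=where, freeze_backbone=pretrained))
        yield name, mc, replace(tc, random_prompt=rp)


def run_ablation(samples: list[CeusSample], model_config: ModelConfig,
                 tc: TrainConfig, suite: str = "modules",
                 seeds: tuple[int, ...] = (0, 1, 2), k: int = 5,
                 pool: PromptPool | None = None,
                 configs: tuple[str, ...] | None = None,
                 pretrain_samples: list[CeusSample] | None = None) -> pd.DataFrame:
    """Run the module or frame-count ablation suite under identical folds.

    Returns one row per (configuration, seed) with fold-mean metrics; rows
    that fail (e.g. a frame count exceeding the clip's window capacity)
    record the error and the suite continues.  ``configs`` restricts the
    module suite to a named subset (e.g. a single pairwise comparison).
    ``pretrain_samples`` (a cohort disjoint from ``samples``) enables the
    pretrain-then-fine-tune regime the module comparisons are about; see
    :func:`pretrain_backbone`.
    """
    if pretrain_samples is not None:
        overlap = {s.patient_id for s in pretrain_samples} & {s.patient_id for s in samples}
        if overlap:
            raise ValueError("pretraining cohort overlaps the evaluation cohort")
    if suite == "modules":
        runs = [(name, mc, t)
                for name, mc, t in _module_configs(model_config, tc,
                                                   pretrain_samples is not None)
                if configs is None or name in configs]
    elif suite == "frames":
        runs = []
        for n in FRAME_ABLATIONS:
            hw = max(tc.half_window, (n + 1) // 2)
            runs.append((f"{n} frames", model_config,
                         replace(tc, n_frames=n, half_window=hw)))
    else:
        raise ValueError("suite must be 'modules' or 'frames'")

    rows = []
    for seed in seeds:
        ids = [s.patient_id for s in samples]
        labels = [s.class_label for s in samples]
        folds = make_folds(ids, labels, k=k, seed=seed)
        init_state = None
        if pretrain_samples is not None:
            init_state = pretrain_backbone(
                pretrain_samples, model_config, replace(tc, seed=seed), pool
            )
        for name, mc, t in runs:
            t = replace(t, seed=seed)
            row: dict[str, object] = {"config": name, "seed": seed}
            try:
                result = cross_validate(samples, mc, t, k=k, pool=pool, folds=folds,
                                        init_state=init_state)
                for key, (mean, sd) in result.summary().items():
                    row[key] = mean
                    row[key + "_sd"] = sd
                row["error"] = ""
            except Exception as exc:  # recorded, suite continues
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_ablation(table: pd.DataFrame) -> pd.DataFrame:
    """Mean over seeds per configuration (successful runs only)."""
    ok = table[table["error"] == ""]
    metrics = [c for c in ok.columns if c not in ("config", "seed", "error")
               and not c.endswith("_sd")]
    out = ok.groupby("config", sort=False)[metrics].mean().reset_index()
    return out
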