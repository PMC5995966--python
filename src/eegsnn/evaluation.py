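"""End-to-end evaluation: leave-one-out cross-validation, exhaustive grid
search over (STDP rate, firing threshold, mod), and confusion metrics.

Every LOOCV fold starts from a freshly initialised reservoir (the
initialisation seed is fixed across folds so folds differ only in data),
STDP-trains it on the n-1 training samples, evolves one deSNN output neuron
per training sample, and classifies the held-out sample. Metrics come from
the pooled confusion matrix over all folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd

from .brain_space import SmallWorldConfig, build_atlas, init_small_world
from .containers import EpochedRecording
from .desnn_classifier import DesnnConfig, classify, ro_train_output
from .reservoir_learning import (LifConfig, ReservoirModel, StdpConfig,
                                 run_epoch, train_unsupervised)
from .spike_encoding import TbrConfig, encode_recording


@dataclass
class PipelineConfig:
    """Bundle of all stage configurations for an end-to-end run.

    ``resolution`` sets the reservoir lattice spacing (2.0 gives a ~220
    neuron model, the package's standard analysis scale; 1.0 gives ~1,700).
    The small-world seed is the single reservoir-initialisation seed, held
    fixed across CV folds.
    """

    resolution: float = 2.0
    tbr: TbrConfig = field(default_factory=TbrConfig)
    small_world: SmallWorldConfig = field(default_factory=SmallWorldConfig)
    lif: LifConfig = field(default_factory=LifConfig)
    stdp: StdpConfig = field(default_factory=StdpConfig)
    desnn: DesnnConfig = field(default_factory=DesnnConfig)
    passes: int = 1
    input_mode: str = "signed_input"


@dataclass
class CvReport:
    """Pooled LOOCV outcome."""

    confusion: pd.DataFrame               # rows = real, cols = predicted
    metrics: dict[str, float]             # percentages
    predictions: pd.DataFrame             # per-fold real/predicted (+ alt mode)
    alt_mode_metrics: dict[str, float]    # same folds, other decision rule
    params: dict[str, float] = field(default_factory=dict)


def metrics(confusion: np.ndarray | pd.DataFrame) -> dict[str, float]:
    """Accuracy, F-score, sensitivity and specificity (in %) of a 2x2
    confusion matrix with rows = real, cols = predicted and the positive
    class in the first row. Undefined ratios (zero denominators) are NaN.
    """
    c = np.asarray(confusion, dtype=float)
    if c.shape != (2, 2) or np.any(c < 0):
        raise ValueError("confusion must be non-negative 2x2")
    tp, fn = c[0, 0], c[0, 1]
    fp, tn = c[1, 0], c[1, 1]
    n = c.sum()

    def ratio(num: float, den: float) -> float:
        return float(num / den) if den > 0 else float("nan")

    acc = ratio(tp + tn, n)
    sens = ratio(tp, tp + fn)               # recall of the positive class
    spec = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    if np.isnan(prec) or np.isnan(sens) or (prec + sens) == 0:
        f1 = float("nan")
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return {"accuracy": 100 * acc, "f_score": 100 * f1,
            "sensitivity": 100 * sens, "specificity": 100 * spec}


def confusion_from_predictions(real: list[str], predicted: list[str],
                               class_order: list[str]) -> pd.DataFrame:
    """Tally a confusion matrix (rows real, cols predicted)."""
    mat = pd.DataFrame(0, index=class_order, columns=class_order, dtype=int)
    for r, p in zip(real, predicted):
        mat.loc[r, p] += 1
    return mat


class _Pipeline:
    """Cached encodings + initial reservoir shared across folds/combos."""

    def __init__(self, rec: EpochedRecording, cfg: PipelineConfig):
        if rec.n_epochs < 2:
            raise ValueError("need at least two samples")
        if len(set(rec.labels)) < 2:
            raise ValueError("need both classes present")
        self.rec = rec
        self.cfg = cfg
        self.fs = rec.fs
        self.n_steps = rec.n_samples
        self.spikes = encode_recording(rec, cfg.tbr)
        self.atlas = build_atlas(resolution=cfg.resolution)
        self.synapses = init_small_world(self.atlas, cfg.small_world)
        self.base_model = ReservoirModel(self.atlas, self.synapses,
                                         input_mode=cfg.input_mode)

    def run_fold(self, holdout: int, cfg: PipelineConfig
                 ) -> tuple[str, str, str]:
        """Train on all samples but ``holdout``; return (real, predicted,
        predicted_under_the_alternative_decision_mode)."""
        train_idx = [i for i in range(self.rec.n_epochs) if i != holdout]
        model = self.base_model.copy()
        train_unsupervised(model, [self.spikes[i] for i in train_idx],
                           self.n_steps, lif=cfg.lif, stdp=cfg.stdp,
                           passes=cfg.passes, fs=self.fs)
        outputs = []
        for i in train_idx:
            recd = run_epoch(model, self.spikes[i], self.n_steps,
                             lif=cfg.lif, stdp=cfg.stdp, learn=False, fs=self.fs)
            outputs.append(ro_train_output(recd, cfg.desnn,
                                           label=self.rec.labels[i]))
        test = run_epoch(model, self.spikes[holdout], self.n_steps,
                         lif=cfg.lif, stdp=cfg.stdp, learn=False, fs=self.fs)
        pred, _ = classify(outputs, test, cfg.desnn)
        alt = "psp_spiking" if cfg.desnn.mode == "weight_similarity" \
            else "weight_similarity"
        pred_alt, _ = classify(outputs, test, replace(cfg.desnn, mode=alt))
        return self.rec.labels[holdout], pred, pred_alt


def _class_order(labels: list[str], positive_class: str) -> list[str]:
    classes = sorted(set(labels))
    if positive_class in classes:
        classes.remove(positive_class)
        classes.insert(0, positive_class)
    return classes


def loocv(rec: EpochedRecording, cfg: PipelineConfig | None = None,
          positive_class: str = "familiar") -> CvReport:
    """Leave-one-out cross-validation of the full pipeline.

    One fold per sample; each fold re-initialises the reservoir from the
    fixed seed, trains on the remaining samples and tests on the holdout.
    The report carries the pooled confusion matrix and metrics for the
    configured decision mode, plus the same-fold metrics under the
    alternative deSNN decision rule.
    """
    cfg = cfg or PipelineConfig()
    pipe = _Pipeline(rec, cfg)
    rows = [pipe.run_fold(i, cfg) for i in range(rec.n_epochs)]
    real = [r[0] for r in rows]
    pred = [r[1] for r in rows]
    alt = [r[2] for r in rows]
    order = _class_order(rec.labels, positive_class)
    conf = confusion_from_predictions(real, pred, order)
    conf_alt = confusion_from_predictions(real, alt, order)
    preds = pd.DataFrame({"fold": range(len(real)), "real": real,
                          "predicted": pred, "predicted_alt_mode": alt})
    return CvReport(confusion=conf, metrics=metrics(conf.to_numpy()),
                    predictions=preds,
                    alt_mode_metrics=metrics(conf_alt.to_numpy()),
                    params={"stdp_rate": cfg.stdp.rate,
                            "theta_fire": cfg.lif.theta_fire,
                            "mod": cfg.desnn.mod})


@dataclass
class ParamGrid:
    """Evenly spaced search grid over the three optimised parameters."""

    stdp_rate: tuple[float, float, int] = (0.001, 0.1, 10)
    theta_fire: tuple[float, float, int] = (0.1, 1.0, 10)
    mod: tuple[float, float, int] = (0.1, 0.9, 10)

    def __post_init__(self) -> None:
        for name in ("stdp_rate", "theta_fire", "mod"):
            lo, hi, k = getattr(self, name)
            if lo > hi or k < 1:
                raise ValueError(f"{name}: need min <= max and n_steps >= 1")

    @staticmethod
    def _values(lo: float, hi: float, k: int) -> np.ndarray:
        return np.array([lo]) if k == 1 else np.linspace(lo, hi, k)

    def combinations(self) -> list[tuple[float, float, float]]:
        return list(product(self._values(*self.stdp_rate),
                            self._values(*self.theta_fire),
                            self._values(*self.mod)))


@dataclass
class GridSearchResult:
    best: dict[str, float]
    table: pd.DataFrame          # one row per combination with accuracy
    fold_correct: np.ndarray     # (n_combos, n_folds) 0/1


def select_best_combination(correct: np.ndarray,
                            combos: list[tuple[float, ...]]) -> int:
    """Pick the winning grid combination from a per-fold correctness matrix.

    A combination earns a vote on every fold where no other combination beat
    it; the most-voted combination wins ("best in most iterations"). Ties
    break by highest mean accuracy, then lexicographic parameter order.
    """
    correct = np.asarray(correct)
    per_fold_best = correct.max(axis=0)
    votes = (correct == per_fold_best[None, :]).sum(axis=1)
    mean_acc = correct.mean(axis=1)
    order = sorted(range(len(combos)),
                   key=lambda i: (-votes[i], -mean_acc[i], combos[i]))
    return order[0]


def grid_search(rec: EpochedRecording, grid: ParamGrid | None = None,
                cfg: PipelineConfig | None = None,
                positive_class: str = "familiar") -> GridSearchResult:
    """Exhaustive grid search over (STDP rate, firing threshold, mod).

    Every combination is evaluated by LOOCV over all samples. The winning
    combination is the one that is among the best on the largest number of
    folds ("best in most iterations"); ties break by highest mean accuracy,
    then lexicographic parameter order. A nested (per-outer-fold selection)
    variant is the statistically safer protocol for new studies and can be
    built on this routine; the flat variant implemented here mirrors the
    historical protocol.
    """
    grid = grid or ParamGrid()
    cfg = cfg or PipelineConfig()
    combos = grid.combinations()
    if not combos:
        raise ValueError("empty grid")
    pipe = _Pipeline(rec, cfg)
    n_folds = rec.n_epochs
    correct = np.zeros((len(combos), n_folds), dtype=int)
    rows = []
    for ci, (rate, theta, mod) in enumerate(combos):
        cfg_c = replace(cfg, stdp=replace(cfg.stdp, rate=float(rate)),
                        lif=replace(cfg.lif, theta_fire=float(theta)),
                        desnn=replace(cfg.desnn, mod=float(mod)))
        for f in range(n_folds):
            real, pred, _ = pipe.run_fold(f, cfg_c)
            correct[ci, f] = int(pred == real)
        rows.append((float(rate), float(theta), float(mod),
                     100.0 * correct[ci].mean()))
    table = pd.DataFrame(rows, columns=["stdp_rate", "theta_fire", "mod",
                                        "accuracy"])

    best_i = select_best_combination(correct, combos)
    votes = (correct == correct.max(axis=0)[None, :]).sum(axis=1)
    best = {"stdp_rate": combos[best_i][0], "theta_fire": combos[best_i][1],
            "mod": combos[best_i][2], "accuracy": float(table["accuracy"][best_i]),
            "votes": int(votes[best_i])}
    return GridSearchResult(best=best, table=table, fold_correct=correct)
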