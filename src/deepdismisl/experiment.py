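"""Training loop, cross-validation, sweeps and interpretation.

Training minimizes the event-normalized Cox partial likelihood with Adam;
risk sets are formed within each training batch (the default batch is the
whole training cohort, which desk-scale cohorts allow).  Early stopping is
patience-based on the validation Cox loss and the parameters from the best
validation epoch are restored.  Cross-validation follows the 5-fold 80/20
protocol: each fold serves once as the 20% validation split on which the
loss is monitored and the concordance index reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import baselines
from .percentile_mil import MILSurvivalModel, scenario_scheme
from .survival_stats import (
    concordance_index,
    cox_loss,
    cox_loss_gradient,
    kaplan_meier,
    logrank_test,
    stratify_by_median,
)

__all__ = [
    "TrainConfig",
    "FoldSplit",
    "TrainedModel",
    "EarlyStopper",
    "kfold_split",
    "cohort_arrays",
    "train_model",
    "run_scenario_sweep",
    "interpret_percentile_risk",
    "evaluate_stratification",
]


@dataclass
class TrainConfig:
    """Hyperparameters for one training run.

    When ``lr_grid``/``wd_grid`` hold more than one value, every (learning
    rate, weight decay) combination is trained and the run with the best
    validation loss is kept.
    """

    scenario: int = 7
    neighborhood: int = 1
    aggregator: str = "dismisl"
    attention: bool = False
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    lr_grid: tuple[float, ...] = (1e-3, 1e-4)
    wd_grid: tuple[float, ...] = (0.0, 1e-4)
    batch_size: int | None = None  # bags per step; None = full training cohort
    max_epochs: int = 200
    patience: int = 10
    scorer_hidden: int = 128
    head_hidden: tuple[int, ...] = (128, 64)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def desk_train_config(**overrides) -> TrainConfig:
    """Desk-scale training configuration for synthetic cohorts.

    Narrow widths (32-unit scorer, 32/16 head), a single-point learning-rate
    grid and a 120-epoch cap keep one training run in seconds on one CPU
    while still recovering the generator's quantile signal; the full-width
    defaults in :class:`TrainConfig` match the original slide-cohort setup.
    """
    cfg = dict(
        lr_grid=(1e-3,),
        wd_grid=(0.0,),
        scorer_hidden=32,
        head_hidden=(32, 16),
        max_epochs=120,
        patience=10,
    )
    cfg.update(overrides)
    return TrainConfig(**cfg)


@dataclass
class FoldSplit:
    """Partition of a cohort's bag ids into k folds (sizes differ by <= 1)."""

    assignments: dict[str, int]
    k: int

    def fold_of(self, bag_id: str) -> int:
        return self.assignments[bag_id]


def kfold_split(cohort, k: int, seed: int = 0) -> FoldSplit:
    """Seeded random partition into k near-equal folds."""
    n = len(cohort)
    if k < 2 or k > n:
        raise ValueError(f"need 2 <= k <= n_bags, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignments: dict[str, int] = {}
    for f, chunk in enumerate(np.array_split(perm, k)):
        for i in chunk:
            assignments[cohort[i][0].bag_id] = f
    return FoldSplit(assignments, k)


def cohort_arrays(cohort):
    """Stack a cohort into (X, times, events, bag_ids); bags must share n."""
    sizes = {bag.n_instances for bag, _ in cohort}
    if len(sizes) != 1:
        raise ValueError(
            "bags have unequal instance counts; resample_bag to a common size first"
        )
    X = np.stack([bag.features.astype(float) for bag, _ in cohort])
    times = np.array([rec.time for _, rec in cohort])
    events = np.array([rec.event for _, rec in cohort])
    ids = [bag.bag_id for bag, _ in cohort]
    return X, times, events, ids


class EarlyStopper:
    """Patience-based early stopping on the validation loss.

    ``update`` returns True when training should stop; the best epoch's
    snapshot is kept in ``best_state``.
    """

    def __init__(self, patience: int):
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch = -1
        self.best_state = None
        self._since_best = 0

    def update(self, epoch: int, val_loss: float, state=None) -> bool:
        if val_loss < self.best_loss - 1e-12:
            self.best_loss = val_loss
            self.best_epoch = epoch
            self.best_state = state
            self._since_best = 0
        else:
            self._since_best += 1
        return self._since_best >= self.patience


class _Adam:
    def __init__(self, params, lr, weight_decay=0.0):
        self.lr = lr
        self.wd = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        out = {}
        for k, p in params.items():
            g = grads[k] + self.wd * p
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            out[k] = p - self.lr * mhat / (np.sqrt(vhat) + eps)
        return out


@dataclass
class TrainedModel:
    """A fitted risk model plus its training log."""

    model: object  # MILSurvivalModel or PenalizedCoxModel
    config: TrainConfig
    log: pd.DataFrame
    best_epoch: int
    best_val_loss: float

    def predict_cohort(self, cohort) -> np.ndarray:
        """One finite risk per bag, in cohort order."""
        if isinstance(self.model, baselines.PenalizedCoxModel):
            design = np.stack(
                [baselines.mean_feature_vector(bag) for bag, _ in cohort]
            )
            return self.model.predict_risk(design)
        X, _, _, _ = cohort_arrays(cohort)
        return self.model.predict(X)


def _build_model(config: TrainConfig, feature_dim: int, seed: int) -> MILSurvivalModel:
    scheme = scenario_scheme(config.scenario, config.neighborhood)
    agg = baselines.make_aggregator(config.aggregator, scheme)
    return MILSurvivalModel(
        feature_dim=feature_dim,
        aggregator=agg,
        scorer_hidden=config.scorer_hidden,
        head_hidden=config.head_hidden,
        attention=config.attention,
        seed=seed,
    )


def _fit_lassocox(train_cohort, val_cohort, config: TrainConfig) -> TrainedModel:
    design = np.stack([baselines.mean_feature_vector(bag) for bag, _ in train_cohort])
    times = np.array([rec.time for _, rec in train_cohort])
    events = np.array([rec.event for _, rec in train_cohort])
    model = baselines.fit_penalized_cox(design, times, events, seed=config.seed)
    vX = np.stack([baselines.mean_feature_vector(bag) for bag, _ in val_cohort])
    vt = np.array([rec.time for _, rec in val_cohort])
    ve = np.array([rec.event for _, rec in val_cohort])
    val_loss = cox_loss(model.predict_risk(vX), vt, ve, normalize=True)
    log = pd.DataFrame([{"epoch": 0, "train_loss": np.nan, "val_loss": val_loss}])
    return TrainedModel(model, config, log, 0, val_loss)


def _train_one(train_arrays, val_arrays, config, lr, wd) -> TrainedModel:
    X, t, e, _ = train_arrays
    Xv, tv, ev, _ = val_arrays
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    model = _build_model(config, X.shape[2], config.seed)
    params = model.get_params()
    opt = _Adam(params, lr, wd)
    stopper = EarlyStopper(config.patience)
    rows = []
    B = X.shape[0]
    for epoch in range(1, config.max_epochs + 1):
        if config.batch_size is None or config.batch_size >= B:
            batches = [np.arange(B)]
        else:
            perm = rng.permutation(B)
            batches = np.array_split(perm, int(np.ceil(B / config.batch_size)))
        epoch_loss = 0.0
        n_terms = 0
        for idx in batches:
            if e[idx].sum() == 0:
                continue  # all-censored batch carries no likelihood terms
            O, cache = model.forward(X[idx])
            loss = cox_loss(O, t[idx], e[idx], normalize=True)
            dO = cox_loss_gradient(O, t[idx], e[idx], normalize=True)
            grads = model.backward(dO, cache)
            params = opt.step(params, grads)
            model.set_params(params)
            epoch_loss += loss * len(idx)
            n_terms += len(idx)
        train_loss = epoch_loss / max(n_terms, 1)
        val_loss = cox_loss(model.predict(Xv), tv, ev, normalize=True)
        rows.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        snapshot = {k: v.copy() for k, v in params.items()}
        if stopper.update(epoch, val_loss, snapshot):
            break
    if stopper.best_state is not None:
        model.set_params(stopper.best_state)
    return TrainedModel(
        model, config, pd.DataFrame(rows), stopper.best_epoch, stopper.best_loss
    )


def train_model(train_cohort, val_cohort, config: TrainConfig) -> TrainedModel:
    """Fit a risk model on the training cohort, monitored on the validation one.

    Neural aggregators are trained with Adam on the Cox loss; the
    ``meanfeature_lassocox`` aggregator is fitted in closed form via the
    penalized Cox baseline.  Deterministic given ``config.seed``.
    """
    if not any(rec.event for _, rec in train_cohort) or not any(
        rec.event for _, rec in val_cohort
    ):
        raise ValueError("training and validation cohorts each need >= 1 event")
    if config.aggregator == "meanfeature_lassocox":
        return _fit_lassocox(train_cohort, val_cohort, config)
    train_arrays = cohort_arrays(train_cohort)
    val_arrays = cohort_arrays(val_cohort)
    lrs = config.lr_grid or (config.learning_rate,)
    wds = config.wd_grid or (config.weight_decay,)
    best: TrainedModel | None = None
    for lr in lrs:
        for wd in wds:
            run_cfg = replace(config, learning_rate=lr, weight_decay=wd,
                              lr_grid=(lr,), wd_grid=(wd,))
            fitted = _train_one(train_arrays, val_arrays, run_cfg, lr, wd)
            if best is None or fitted.best_val_loss < best.best_val_loss:
                best = fitted
    assert best is not None
    return best


def run_scenario_sweep(
    cohort,
    scenarios,
    neighborhoods,
    k_folds: int = 5,
    seed: int = 0,
    base_config: TrainConfig | None = None,
) -> pd.DataFrame:
    """Cross-validated C-index for every (scenario, neighborhood) pair.

    Returns a tidy table with one row per (scenario, neighborhood, fold)
    plus ``mean``/``sd`` aggregate rows (fold = -1) per pair.
    """
    base = base_config or TrainConfig()
    split = kfold_split(cohort, k_folds, seed)
    rows = []
    for scenario in scenarios:
        for k in neighborhoods:
            cis = []
            for fold in range(k_folds):
                train = [cs for cs in cohort if split.fold_of(cs[0].bag_id) != fold]
                val = [cs for cs in cohort if split.fold_of(cs[0].bag_id) == fold]
                cfg = replace(base, scenario=scenario, neighborhood=k, seed=seed)
                fitted = train_model(train, val, cfg)
                risks = fitted.predict_cohort(val)
                times = np.array([rec.time for _, rec in val])
                events = np.array([rec.event for _, rec in val])
                ci = concordance_index(risks, times, events)
                cis.append(ci)
                rows.append(
                    {"scenario": scenario, "neighborhood": k, "fold": fold,
                     "cindex": ci}
                )
            rows.append(
                {"scenario": scenario, "neighborhood": k, "fold": -1,
                 "cindex": float(np.mean(cis)), "sd": float(np.std(cis, ddof=1))}
            )
    return pd.DataFrame(rows)


def interpret_percentile_risk(
    trained: TrainedModel, cohort, n_risk_groups: int = 10
) -> pd.DataFrame:
    """Mean selected score per percentile within predicted-risk groups.

    Bags are ranked by predicted risk (stable order on ties) and split into
    ``n_risk_groups`` near-equal groups (group 0 = lowest risk); for each
    group and each percentile of the model's scheme, the mean of the selected
    window scores is reported.
    """
    from .percentile_mil import PercentileAggregator, score_instances, selection_ranks

    if n_risk_groups > len(cohort):
        raise ValueError("n_risk_groups cannot exceed the number of bags")
    model = trained.model
    if not isinstance(model, MILSurvivalModel) or not isinstance(
        model.aggregator, PercentileAggregator
    ):
        raise ValueError("interpretation requires a percentile-scheme model")
    scheme = model.aggregator.scheme
    risks = trained.predict_cohort(cohort)
    order = np.argsort(risks, kind="stable")
    groups = np.empty(len(cohort), dtype=int)
    for g, chunk in enumerate(np.array_split(order, n_risk_groups)):
        groups[chunk] = g
    ranks = None
    sel = np.empty((len(cohort), len(scheme.percentiles)))
    for i, (bag, _) in enumerate(cohort):
        s = score_instances(bag, model.scorer)
        if ranks is None:
            ranks = selection_ranks(s.size, scheme)
        windows = np.sort(s)[ranks].reshape(
            len(scheme.percentiles), scheme.neighborhood
        )
        sel[i] = windows.mean(axis=1)
    rows = []
    for g in range(n_risk_groups):
        mask = groups == g
        for j, p in enumerate(scheme.percentiles):
            rows.append(
                {"risk_group": g, "percentile": p,
                 "mean_score": float(sel[mask, j].mean()),
                 "mean_risk": float(risks[mask].mean())}
            )
    return pd.DataFrame(rows)


def evaluate_stratification(trained: TrainedModel, train_cohort, eval_cohort) -> dict:
    """Median-split risk stratification with KM curves and a log-rank test.

    The threshold is the median predicted risk on the *training* cohort;
    evaluation bags at or above it are high-risk.  Raises ``ValueError``
    when either risk group is empty (e.g. constant risks).
    """
    train_risks = trained.predict_cohort(train_cohort)
    eval_risks = trained.predict_cohort(eval_cohort)
    labels = stratify_by_median(train_risks, eval_risks)
    times = np.array([rec.time for _, rec in eval_cohort])
    events = np.array([rec.event for _, rec in eval_cohort])
    if labels.all() or not labels.any():
        raise ValueError(
            "median split produced an empty risk group (constant risks?)"
        )
    hi, lo = labels == 1, labels == 0
    chi2, p = logrank_test(times[hi], events[hi], times[lo], events[lo])
    return {
        "cindex": concordance_index(eval_risks, times, events),
        "labels": labels,
        "risks": eval_risks,
        "km_high": kaplan_meier(times[hi], events[hi]),
        "km_low": kaplan_meier(times[lo], events[lo]),
        "logrank_chi2": chi2,
        "logrank_p": p,
    }
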