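"""Penalized proportional-hazards risk model: LASSO path, cross-validated
partial-likelihood deviance for the penalty choice, the linear KRD risk
score, median stratification and survival evaluation.

The model is fit on per-gene standardized expression (penalized paths are
scale-sensitive); coefficients are reported on the standardized scale and
the training means/SDs travel with the model so new cohorts can be placed
on the same scale. The penalty is chosen at the minimum mean cross-validated
partial-likelihood deviance, each fold's deviance computed as
``-2 * (loglik(all) - loglik(train))`` under the Breslow tie convention
(the "subtraction" form, which is stable when folds are small).

The risk score itself is the exact linear combination
``score_j = sum_i Exp_ij * Coef_i``; cohorts are split at the median score
into high and low risk groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ExpressionMatrix, SurvivalTable
from .stratify import assign_groups

DEFAULT_CV_FOLDS = 10


@dataclass
class RiskModel:
    """A sparse linear proportional-hazards signature model.

    ``genes``/``coefs`` hold only the nonzero-coefficient genes, on the
    standardized-expression scale; ``means``/``sds`` are the training
    per-gene statistics needed to standardize a new cohort.
    """

    genes: list[str]
    coefs: np.ndarray
    penalty: float
    cv_folds: int
    seed: int
    means: pd.Series
    sds: pd.Series
    selection_rule: str = "min_deviance"
    standardized: bool = True
    cv_path: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coefs = np.asarray(self.coefs, dtype=float)
        if len(self.genes) != self.coefs.size:
            raise ValidationError("genes and coefs length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("model genes must be unique")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def standardize(self, matrix: ExpressionMatrix) -> ExpressionMatrix:
        """Apply the training per-gene standardization to a cohort."""
        sub = matrix.subset_genes(self.genes)
        mu = self.means.loc[self.genes].to_numpy()[:, None]
        sd = self.sds.loc[self.genes].to_numpy()[:, None]
        return ExpressionMatrix(
            sub.genes, sub.samples, (sub.values - mu) / sd, sub.modality, sub.scale
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "coef": self.coefs})


@dataclass
class ModelEvaluation:
    logrank_p: float
    hazard_ratio: float
    hr_ci: tuple[float, float]
    hr_p: float
    auc: dict[float, float]
    n_high: int
    n_low: int
    degenerate: bool = False


def breslow_loglik(eta: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Cox partial log-likelihood of linear predictors, Breslow ties."""
    order = np.argsort(time, kind="stable")
    t, d, e = time[order], event[order], eta[order]
    # log cumulative sum of exp(eta) over the risk set {j : t_j >= t_i}
    m = e.max()
    rev = np.exp(e[::-1] - m).cumsum()[::-1]
    log_risk = np.log(rev) + m
    # all tied times share the risk set of the first index of the tie group
    first = np.zeros(t.size, dtype=int)
    for i in range(1, t.size):
        first[i] = first[i - 1] if t[i] == t[i - 1] else i
    mask = d == 1
    return float(np.sum(e[mask] - log_risk[first[mask]]))


def _coxnet_path(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                 alphas: np.ndarray | None, n_alphas: int):
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    y = Surv.from_arrays(event=event.astype(bool), time=time)
    model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0,
        n_alphas=n_alphas,
        alphas=None if alphas is None else list(alphas),
        fit_baseline_model=False,
        max_iter=100000,
    )
    model.fit(X, y)
    return model


def fit_penalized_cox(
    matrix: ExpressionMatrix,
    survival: SurvivalTable,
    cv_folds: int = DEFAULT_CV_FOLDS,
    seed: int = 0,
    n_alphas: int = 50,
) -> RiskModel:
    """Fit the L1-penalized proportional-hazards model over a penalty path
    and select the penalty at minimum cross-validated deviance.

    The matrix should already be restricted to the candidate genes (e.g. a
    screened signature). Constant genes are dropped with a warning. The CV
    fold assignment is drawn from ``seed``; genes with zero coefficients at
    the selected penalty are excluded from the returned model.
    """
    from sklearn.model_selection import KFold

    surv = survival.subset(matrix.samples)
    if matrix.n_genes < 2:
        raise ValidationError("need >= 2 candidate genes")
    if surv.n_events < 10:
        raise ValidationError("need >= 10 events to fit the penalized model")

    values = matrix.values
    sds_all = values.std(axis=1, ddof=1)
    keep = sds_all > 0
    if not keep.all():
        dropped = [g for g, k in zip(matrix.genes, keep) if not k]
        warnings.warn(f"dropping {len(dropped)} constant gene(s): {dropped[:5]}")
    genes = [g for g, k in zip(matrix.genes, keep) if k]
    means = pd.Series(values[keep].mean(axis=1), index=genes)
    sds = pd.Series(sds_all[keep], index=genes)
    X = ((values[keep] - means.to_numpy()[:, None]) / sds.to_numpy()[:, None]).T
    time, event = surv.time, surv.event

    full = _coxnet_path(X, time, event, None, n_alphas)
    alphas = np.asarray(full.alphas_)

    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=int(seed) % (2**31))
    dev = np.zeros((cv_folds, alphas.size))
    for f, (tr, _te) in enumerate(kf.split(X)):
        sub = _coxnet_path(X[tr], time[tr], event[tr], alphas, n_alphas)
        coefs = sub.coef_  # (n_features, n_alphas_fit)
        fitted = np.asarray(sub.alphas_)
        for a, alpha in enumerate(alphas):
            k = int(np.argmin(np.abs(fitted - alpha)))
            beta = coefs[:, k]
            ll_all = breslow_loglik(X @ beta, time, event)
            ll_tr = breslow_loglik(X[tr] @ beta, time[tr], event[tr])
            dev[f, a] = -2.0 * (ll_all - ll_tr)
    mean_dev = dev.mean(axis=0)
    best = int(np.argmin(mean_dev))
    best_alpha = float(alphas[best])

    beta = full.coef_[:, best]
    nz = np.flatnonzero(beta)
    model = RiskModel(
        genes=[genes[i] for i in nz],
        coefs=beta[nz],
        penalty=best_alpha,
        cv_folds=cv_folds,
        seed=int(seed),
        means=means,
        sds=sds,
        cv_path=pd.DataFrame({"alpha": alphas, "mean_deviance": mean_dev}),
    )
    return model


def krd_score(matrix: ExpressionMatrix, model: RiskModel) -> pd.DataFrame:
    """Per-sample risk score ``sum_i Exp_i * Coef_i`` with median groups.

    The linear combination is applied to the matrix values as given (pass
    the output of :meth:`RiskModel.standardize` to score on the model's
    training scale). All model genes must be present; there is no
    imputation. Returns columns ``sample``, ``krd_score``, ``group``.
    """
    if model.n_genes == 0:
        scores = np.zeros(matrix.n_samples)
    else:
        idx = matrix.gene_index(model.genes)
        scores = model.coefs @ matrix.values[idx]
    groups = assign_groups(scores, rule="median", samples=matrix.samples)
    out = pd.DataFrame(
        {"sample": matrix.samples, "krd_score": scores, "group": groups["label"]}
    )
    out.attrs.update({"rule": "median", "n_model_genes": model.n_genes})
    return out


def evaluate_model(
    scores: pd.DataFrame,
    survival: SurvivalTable,
    horizons: tuple[float, ...] = (),
) -> ModelEvaluation:
    """Evaluate a scored cohort: high-vs-low log-rank test, hazard ratio of
    the high group, and time-dependent AUC at the requested horizons.

    The AUC is the cumulative/dynamic estimator with inverse-probability-
    of-censoring weights; horizons at or beyond the last observed time are
    dropped with a warning. A cohort where every sample landed in one group
    (all scores identical) is reported as degenerate.
    """
    from lifelines import CoxPHFitter
    from lifelines.statistics import logrank_test

    surv = survival.subset(scores["sample"].tolist())
    high = (scores["group"] == "high").to_numpy()
    n_high, n_low = int(high.sum()), int((~high).sum())
    if n_high == 0 or n_low == 0:
        warnings.warn("degenerate stratification: one risk group is empty")
        return ModelEvaluation(
            np.nan, np.nan, (np.nan, np.nan), np.nan, {}, n_high, n_low, True
        )
    time, event = surv.time, surv.event
    lr = logrank_test(time[high], time[~high], event[high], event[~high])

    df = pd.DataFrame({"time": time, "event": event, "high": high.astype(float)})
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["high"]))
    ci = cph.confidence_intervals_
    hr_ci = (
        float(np.exp(ci.loc["high"].iloc[0])),
        float(np.exp(ci.loc["high"].iloc[1])),
    )
    hr_p = float(cph.summary.loc["high", "p"])

    auc: dict[float, float] = {}
    if horizons:
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        t_max = time[event == 1].max() if event.any() else time.max()
        usable = [h for h in horizons if time.min() < h < t_max]
        skipped = [h for h in horizons if h not in usable]
        if skipped:
            warnings.warn(f"horizons outside follow-up range dropped: {skipped}")
        if usable:
            y = Surv.from_arrays(event=event.astype(bool), time=time)
            aucs, _ = cumulative_dynamic_auc(
                y, y, scores["krd_score"].to_numpy(), np.asarray(usable)
            )
            auc = {float(h): float(a) for h, a in zip(usable, aucs)}
    return ModelEvaluation(
        float(lr.p_value), hr, hr_ci, hr_p, auc, n_high, n_low, False
    )


def train_validation_split(
    survival: SurvivalTable, train_frac: float = 0.6, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Seeded train/validation split of a cohort, stratified by event status."""
    from sklearn.model_selection import train_test_split

    if not 0 < train_frac < 1:
        raise ValidationError("train_frac must be in (0, 1)")
    train, val = train_test_split(
        survival.samples,
        train_size=train_frac,
        random_state=int(seed) % (2**31),
        stratify=survival.event,
    )
    return list(train), list(val)
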