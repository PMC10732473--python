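"""Bootstrap prediction, null-model comparison, and confound auditing.

The workhorse is :func:`bootstrap_predict`: repeated random 80/20
train/test splits (Monte-Carlo cross-validation) of a regularized linear
model — ridge regression scored by test RMSE, or logistic regression scored
by test accuracy — against a null predictor evaluated on the *same* test
split (training-mean for regression, training-majority-class for
classification).  Significance against the null is a one-sided Wilcoxon
signed-rank test across repetitions.

The composite :func:`confound_audit` operationalizes a demographic-confound
check: if whole-cohort prediction of a target beats the null but prediction
*within* each level of a suspected confound does not, the apparent signal
is attributable to the confound.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import (
    LogisticRegression,
    LogisticRegressionCV,
    Ridge,
    RidgeCV,
)

from .association import AssociationMap, containment_fraction, correlate_features
from .cohort import Cohort, GroupMask
from .exceptions import (
    DataError,
    IncompatibleMapsError,
    RequestError,
)

__all__ = [
    "SplitSpec",
    "NullComparison",
    "PredictionResult",
    "bootstrap_predict",
    "compare_to_null",
    "within_group_predict",
    "transfer_evaluate",
    "ConfoundAuditReport",
    "confound_audit",
]

MIN_GROUP_SIZE = 20


@dataclass(frozen=True)
class SplitSpec:
    """Monte-Carlo split schedule: test fraction, repetitions, seed."""

    test_fraction: float = 0.2
    repetitions: int = 20
    seed: int = 0
    stratify: bool = True  # applies to classification only

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise RequestError(
                f"test fraction must be in (0, 1), got {self.test_fraction}"
            )
        if self.repetitions < 1:
            raise RequestError("need at least 1 repetition")


@dataclass
class NullComparison:
    """Outcome of the model-vs-null significance procedure."""

    significant: bool
    p_value: float
    procedure: str = "wilcoxon_signed_rank_one_sided"
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "significant": bool(self.significant),
            "p_value": float(self.p_value),
            "procedure": self.procedure,
            "alpha": self.alpha,
        }


@dataclass
class PredictionResult:
    """Per-repetition test metrics of a model and its null baseline.

    ``metrics`` is RMSE for regression (lower is better) and accuracy for
    classification (higher is better); ``null_metrics`` is the matched null
    on the same test split.
    """

    task_kind: str  # "regression" | "classification"
    metric_name: str  # "rmse" | "accuracy"
    metrics: np.ndarray
    null_metrics: np.ndarray
    model_desc: dict = field(default_factory=dict)
    coefs: np.ndarray | None = None  # repetitions x m, for weight maps
    verdict: NullComparison | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.metrics = np.asarray(self.metrics, dtype=float)
        self.null_metrics = np.asarray(self.null_metrics, dtype=float)
        if self.metrics.shape != self.null_metrics.shape:
            raise DataError("model and null repetition counts differ")

    @property
    def mean(self) -> float:
        return float(self.metrics.mean())

    @property
    def sd(self) -> float:
        return float(self.metrics.std(ddof=1)) if len(self.metrics) > 1 else 0.0

    @property
    def null_mean(self) -> float:
        return float(self.null_metrics.mean())

    @property
    def null_sd(self) -> float:
        return float(self.null_metrics.std(ddof=1)) if len(self.null_metrics) > 1 else 0.0

    @property
    def best(self) -> float:
        """Best single repetition (lowest RMSE / highest accuracy)."""
        if self.task_kind == "regression":
            return float(self.metrics.min())
        return float(self.metrics.max())

    def improvements(self) -> np.ndarray:
        """Per-repetition margin of the model over the null (positive = better)."""
        if self.task_kind == "regression":
            return self.null_metrics - self.metrics
        return self.metrics - self.null_metrics

    def to_dict(self) -> dict:
        return {
            "task_kind": self.task_kind,
            "metric": self.metric_name,
            "mean": self.mean,
            "sd": self.sd,
            "best": self.best,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "per_repetition": self.metrics.tolist(),
            "null_per_repetition": self.null_metrics.tolist(),
            "model": self.model_desc,
            "verdict": self.verdict.to_dict() if self.verdict else None,
            "warnings": self.warnings,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _split_indices(
    rng: np.random.Generator,
    y: np.ndarray,
    test_fraction: float,
    stratify: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """One train/test index split; stratified keeps class shares within ±1."""
    n = len(y)
    if stratify:
        test_parts, train_parts = [], []
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            idx = rng.permutation(idx)
            n_test = int(round(test_fraction * len(idx)))
            n_test = min(max(n_test, 1), len(idx) - 1)
            test_parts.append(idx[:n_test])
            train_parts.append(idx[n_test:])
        return np.sort(np.concatenate(train_parts)), np.sort(
            np.concatenate(test_parts)
        )
    perm = rng.permutation(n)
    n_test = max(1, int(round(test_fraction * n)))
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def _standardize(train: np.ndarray, other: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """z-score both arrays using training statistics only (leakage-free)."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (other - mu) / sd


def _train_abs_corr(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.linalg.norm(Xc, axis=0) * np.linalg.norm(yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Xc.T @ yc / np.where(denom > 0, denom, 1.0), 0.0)
    return np.abs(r)


def _majority_class(y_train: np.ndarray) -> float:
    vals, counts = np.unique(y_train, return_counts=True)
    # deterministic tie-break: lower label wins
    return float(vals[np.argmax(counts)])


RIDGE_ALPHA_GRID = np.logspace(0, 5, 11)
LOGISTIC_C_GRID = np.logspace(-3, 2, 6)


def _make_model(kind: str, tune: bool = False):
    if kind == "ridge":
        if tune:
            return RidgeCV(alphas=RIDGE_ALPHA_GRID, cv=5)
        return Ridge(alpha=1.0)
    if kind == "logistic":
        if tune:
            return LogisticRegressionCV(Cs=LOGISTIC_C_GRID, cv=5, max_iter=2000)
        return LogisticRegression(C=1.0, max_iter=2000)
    raise RequestError(f"unknown model kind {kind!r}; use 'ridge' or 'logistic'")


def bootstrap_predict(
    X: np.ndarray,
    y: np.ndarray | pd.Series,
    kind: str,
    spec: SplitSpec = SplitSpec(),
    top_k: int | None = None,
    tune: bool = False,
) -> PredictionResult:
    """Monte-Carlo cross-validated prediction with a matched null baseline.

    Parameters
    ----------
    X, y
        Feature matrix (subjects x features) and target.  For
        ``kind='logistic'`` the target must be 0/1 coded.
    kind
        ``'ridge'`` (regression, RMSE) or ``'logistic'`` (classification,
        accuracy).
    top_k
        If set, features are ranked on each training split by absolute
        correlation with the target and only the top ``k`` are refit —
        selection happens inside the split, so the test set never informs it.
    tune
        Select the regularization strength by an inner 5-fold grid on each
        training split instead of the fixed default (alpha = 1, C = 1).
        High-dimensional regression targets typically need this: a weak
        fixed penalty overfits and loses to the null even when signal is
        present.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise DataError("X must be subjects x features, aligned with y")
    ok = np.isfinite(X).all(axis=1) & np.isfinite(y)
    X, y = X[ok], y[ok]
    n, m = X.shape
    if n < MIN_GROUP_SIZE:
        raise DataError(f"need at least {MIN_GROUP_SIZE} complete subjects, got {n}")
    if top_k is not None and top_k > m:
        raise RequestError(f"top_k={top_k} exceeds {m} features")
    classification = kind == "logistic"
    if classification:
        classes = np.unique(y)
        if len(classes) != 2:
            raise DataError(f"logistic target must have 2 classes, got {len(classes)}")
    _make_model(kind)  # validates kind early

    rng = np.random.default_rng(spec.seed)
    metrics = np.empty(spec.repetitions)
    nulls = np.empty(spec.repetitions)
    coefs = np.zeros((spec.repetitions, m))
    for rep in range(spec.repetitions):
        tr, te = _split_indices(
            rng, y, spec.test_fraction, stratify=classification and spec.stratify
        )
        Xtr, Xte = _standardize(X[tr], X[te])
        ytr, yte = y[tr], y[te]
        sel = slice(None)
        if top_k is not None:
            score = _train_abs_corr(Xtr, ytr)
            order = np.lexsort((np.arange(m), -score))
            sel = np.sort(order[:top_k])
        model = _make_model(kind, tune=tune)
        model.fit(Xtr[:, sel], ytr)
        if classification:
            pred = model.predict(Xte[:, sel])
            metrics[rep] = float(np.mean(pred == yte))
            nulls[rep] = float(np.mean(_majority_class(ytr) == yte))
            w = np.asarray(model.coef_).ravel()
        else:
            pred = model.predict(Xte[:, sel])
            metrics[rep] = float(np.sqrt(np.mean((pred - yte) ** 2)))
            nulls[rep] = float(np.sqrt(np.mean((ytr.mean() - yte) ** 2)))
            w = np.asarray(model.coef_).ravel()
        coefs[rep, sel] = w
    result = PredictionResult(
        task_kind="classification" if classification else "regression",
        metric_name="accuracy" if classification else "rmse",
        metrics=metrics,
        null_metrics=nulls,
        model_desc={
            "kind": kind,
            "regularization": "inner_5fold_grid" if tune else 1.0,
            "features": int(top_k) if top_k is not None else "full",
            "n_subjects": int(n),
            "n_features": int(m),
            "test_fraction": spec.test_fraction,
            "repetitions": spec.repetitions,
            "seed": spec.seed,
        },
        coefs=coefs,
    )
    result.verdict = compare_to_null(result)
    return result


def compare_to_null(result: PredictionResult, alpha: float = 0.05) -> NullComparison:
    """One-sided paired Wilcoxon signed-rank of model vs null across repetitions.

    Tests whether the per-repetition improvement margins are symmetric about
    zero against the alternative that the model is better.  With all margins
    exactly zero (model indistinguishable from null) the verdict is not
    significant.
    """
    d = result.improvements()
    if len(d) < 2:
        raise DataError("need at least 2 repetitions to compare against null")
    if np.all(d == 0):
        return NullComparison(False, 1.0, alpha=alpha)
    res = stats.wilcoxon(d, alternative="greater", zero_method="wilcox")
    p = float(res.pvalue)
    return NullComparison(p < alpha, p, alpha=alpha)


def within_group_predict(
    X: np.ndarray,
    y: np.ndarray | pd.Series,
    groups: dict[str, GroupMask],
    kind: str,
    spec: SplitSpec = SplitSpec(),
    top_k: int | None = None,
    tune: bool = False,
) -> dict[str, PredictionResult | None]:
    """Run :func:`bootstrap_predict` independently inside each group mask.

    Nulls are computed within-group, so each group's verdict asks whether
    the features carry information *beyond* group membership.  Groups below
    the minimum size are skipped with a warning record (value ``None``).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    out: dict[str, PredictionResult | None] = {}
    for name, mask in groups.items():
        if len(mask) != X.shape[0]:
            raise DataError(f"group {name!r} mask length mismatch")
        if mask.n_selected < MIN_GROUP_SIZE:
            out[name] = None
            continue
        out[name] = bootstrap_predict(
            X[mask.values], y[mask.values], kind, spec=spec, top_k=top_k, tune=tune
        )
    return out


def transfer_evaluate(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    spec: SplitSpec = SplitSpec(),
    subgroups: dict[str, GroupMask] | None = None,
    refit_per_repetition: bool = True,
) -> dict[str, PredictionResult]:
    """Cross-cohort transfer of a binary classifier.

    Per repetition a logistic model is fit on a bootstrap draw (sampling
    with replacement) of the training cohort, standardized by that draw's
    statistics, and evaluated on the *full* test cohort and on any named
    test subgroups.  The null is the training draw's majority class.  Both
    cohorts must share the parcellation/edge ordering (same feature count)
    and the same 0/1 target coding.

    ``refit_per_repetition=False`` fits one model on the whole training
    cohort and bootstrap-resamples only the test set, the alternative
    reading of "bootstrapped transfer"; the default refits.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    if X_train.shape[1] != X_test.shape[1]:
        raise IncompatibleMapsError(
            f"feature spaces differ: {X_train.shape[1]} vs {X_test.shape[1]} "
            "(parcellation/edge-ordering mismatch)"
        )
    groups: dict[str, np.ndarray] = {"all": np.ones(len(y_test), dtype=bool)}
    for name, mask in (subgroups or {}).items():
        if len(mask) != len(y_test):
            raise DataError(f"subgroup {name!r} mask length mismatch")
        groups[name] = mask.values
    rng = np.random.default_rng(spec.seed)
    n_tr = len(y_train)
    accs = {g: np.empty(spec.repetitions) for g in groups}
    nulls = {g: np.empty(spec.repetitions) for g in groups}
    single_model = None
    if not refit_per_repetition:
        Xs, _ = _standardize(X_train, X_train)
        single_model = _make_model("logistic").fit(Xs, y_train)
    for rep in range(spec.repetitions):
        if refit_per_repetition:
            draw = rng.integers(0, n_tr, size=n_tr)
            while len(np.unique(y_train[draw])) < 2:  # degenerate bootstrap draw
                draw = rng.integers(0, n_tr, size=n_tr)
            Xd, yd = X_train[draw], y_train[draw]
            Xds, Xts = _standardize(Xd, X_test)
            model = _make_model("logistic").fit(Xds, yd)
            majority = _majority_class(yd)
            pred = model.predict(Xts)
        else:
            draw_te = rng.integers(0, len(y_test), size=len(y_test))
            _, Xts = _standardize(X_train, X_test[draw_te])
            pred_full = single_model.predict(Xts)
            majority = _majority_class(y_train)
            for g, sel in groups.items():
                sel_b = sel[draw_te]
                accs[g][rep] = float(np.mean(pred_full[sel_b] == y_test[draw_te][sel_b]))
                nulls[g][rep] = float(np.mean(majority == y_test[draw_te][sel_b]))
            continue
        for g, sel in groups.items():
            accs[g][rep] = float(np.mean(pred[sel] == y_test[sel]))
            nulls[g][rep] = float(np.mean(majority == y_test[sel]))
    out = {}
    for g in groups:
        res = PredictionResult(
            task_kind="classification",
            metric_name="accuracy",
            metrics=accs[g],
            null_metrics=nulls[g],
            model_desc={
                "kind": "logistic",
                "transfer": True,
                "refit_per_repetition": refit_per_repetition,
                "evaluation_group": g,
                "n_train": int(n_tr),
                "n_test": int(groups[g].sum()),
                "seed": spec.seed,
            },
        )
        res.verdict = compare_to_null(res)
        out[g] = res
    return out


@dataclass
class ConfoundAuditReport:
    """Everything needed to judge whether a confound explains a prediction.

    The verdict is derivable from the stored components alone:
    ``confounded`` iff whole-cohort prediction significantly beats its null
    while no within-group prediction does; ``not-confounded`` if any
    within-group prediction stays significant; ``inconclusive`` if the
    whole-cohort prediction is itself not significant.
    """

    target: str
    confound: str
    group_summary: pd.DataFrame
    target_map: AssociationMap
    confound_map: AssociationMap
    containment: float
    whole_cohort: PredictionResult
    per_group: dict[str, PredictionResult | None]
    verdict: str = ""
    criteria: str = (
        "confounded iff whole-cohort significant vs null AND no within-group "
        "significant; inconclusive if whole-cohort not significant"
    )

    def derive_verdict(self) -> str:
        whole_sig = self.whole_cohort.verdict.significant
        group_sigs = [
            r.verdict.significant for r in self.per_group.values() if r is not None
        ]
        if not whole_sig:
            return "inconclusive"
        if any(group_sigs):
            return "not-confounded"
        return "confounded"

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "confound": self.confound,
            "verdict": self.verdict,
            "criteria": self.criteria,
            "group_summary": self.group_summary.to_dict(orient="records"),
            "containment_fraction": float(self.containment),
            "whole_cohort": self.whole_cohort.to_dict(),
            "per_group": {
                name: (res.to_dict() if res is not None else None)
                for name, res in self.per_group.items()
            },
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _binary_codes(series: pd.Series) -> tuple[np.ndarray, list]:
    """0/1-code a two-level column; levels sorted, lower level -> 0."""
    levels = sorted(series.dropna().unique(), key=str)
    if len(levels) != 2:
        raise DataError(
            f"confound column must have exactly 2 observed levels, got {levels}"
        )
    codes = np.full(len(series), np.nan)
    codes[(series == levels[0]).to_numpy()] = 0.0
    codes[(series == levels[1]).to_numpy()] = 1.0
    return codes, levels


def confound_audit(
    cohort: Cohort,
    target: str,
    confound: str,
    features: str | np.ndarray,
    spec: SplitSpec = SplitSpec(),
    top_k_target: int = 20,
    top_k_confound: int = 50,
    tune: bool = True,
) -> ConfoundAuditReport:
    """Full demographic-confound audit of a continuous target.

    Assembles (1) the target's distribution per confound group, (2) the
    feature-target and feature-confound association maps with the fraction
    of the target map's hotspots contained in the confound map's, and
    (3) whole-cohort vs within-group bootstrap ridge prediction, then
    derives the verdict.

    ``features`` names a connectivity task of the cohort, or is an explicit
    subjects x features matrix (e.g. zero-filled SNP dosages).
    """
    pheno = cohort.phenotypes
    y = pd.to_numeric(pheno.column(target), errors="coerce").to_numpy(dtype=float)
    c, levels = _binary_codes(pheno.column(confound))
    if isinstance(features, str):
        X = cohort.connectivity[features].values
    else:
        X = np.asarray(features, dtype=float)
    if X.shape[0] != cohort.n_subjects:
        raise DataError("feature matrix is not subject-aligned with the cohort")

    rows = []
    groups: dict[str, GroupMask] = {}
    for code, level in enumerate(levels):
        sel = c == code
        groups[str(level)] = GroupMask(sel, provenance=f"{confound} == {level!r}")
        yy = y[sel & np.isfinite(y)]
        rows.append(
            {
                "group": str(level),
                "n": int(sel.sum()),
                "target_mean": float(yy.mean()) if yy.size else np.nan,
                "target_sd": float(yy.std(ddof=1)) if yy.size > 1 else np.nan,
            }
        )
    group_summary = pd.DataFrame(rows)

    target_map = correlate_features(X, y, phenotype=target)
    confound_map = correlate_features(X, c, phenotype=confound)
    k_t = min(top_k_target, X.shape[1])
    k_c = min(top_k_confound, X.shape[1])
    containment = containment_fraction(target_map, k_t, confound_map, k_c)

    whole = bootstrap_predict(X, y, "ridge", spec=spec, tune=tune)
    per_group = within_group_predict(X, y, groups, "ridge", spec=spec, tune=tune)

    report = ConfoundAuditReport(
        target=target,
        confound=confound,
        group_summary=group_summary,
        target_map=target_map,
        confound_map=confound_map,
        containment=containment,
        whole_cohort=whole,
        per_group=per_group,
    )
    report.verdict = report.derive_verdict()
    return report
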