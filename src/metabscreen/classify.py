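"""Three-class metabolite-signature construction under nested cross-validation.

Outer loop: 10-fold CV on the large (MOLTEST-like) cohort, each fold holding
out ten samples per screening group.  Inner loop on the remainder: 100
repetitions of a stratified 70/30 split with greedy forward selection for a
multinomial logistic regression (MLR), stopping when the best candidate
improves BIC by no more than 2.  The 100 selection traces are pooled into a
consensus ranking (selection frequency, ties broken by mean addition order)
cut at the elbow of the score curve; the final per-fold MLR is refit on all
non-test samples and evaluated on the fold's test set and on the entire
small (SMAC-like) validation cohort.  Classification is maximum a
posteriori; overall AUC is the macro average of one-vs-rest AUCs.

The MLR fit is an exact maximum-likelihood Newton iteration written for the
call volume forward selection needs (~1e5 fits per run), with a small ridge
fallback when the likelihood degenerates under perfect separation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .core import GROUPS, MeasurementMatrix
from .stats import kruskal_wallis

CLASSES = tuple(GROUPS)  # fixed order; first class is the MLR reference

_logger = logging.getLogger(__name__)

_MAX_ITER = 200
_TOL = 1e-8
_RIDGE_FALLBACK = 1e-6
_COEF_BLOWUP = 30.0


# ---------------------------------------------------------------------------
# Multinomial logistic regression


@dataclass
class MLRModel:
    """Fitted multinomial logit: reference class first, coef rows per other class."""

    feature_ids: tuple[str, ...]
    coef: np.ndarray          # (k-1, n_features + 1); column 0 = intercept
    classes: tuple[str, ...]
    loglik: float
    n_train: int
    converged: bool
    ridge: float = 0.0

    @property
    def n_params(self) -> int:
        return self.coef.size

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X1 = np.column_stack([np.ones(len(X)), X])
        eta = X1 @ self.coef.T
        logits = np.column_stack([np.zeros(len(X)), eta])
        logits -= logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        return expl / expl.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        # ties (within tolerance) resolve to the earliest class in the order
        proba = self.predict_proba(X)
        tied = proba >= proba.max(axis=1, keepdims=True) - 1e-12
        n_tied = int((tied.sum(axis=1) > 1).sum())
        if n_tied:
            _logger.debug("MAP ties on %d samples; fixed class order applied", n_tied)
        idx = tied.argmax(axis=1)
        return np.array(self.classes)[idx]


def _onehot(y: np.ndarray, classes: tuple[str, ...]) -> np.ndarray:
    Y = np.zeros((len(y), len(classes)))
    for a, c in enumerate(classes):
        Y[y == c, a] = 1.0
    return Y


def _loglik_eta(eta: np.ndarray, Y1: np.ndarray) -> float:
    """Log-likelihood from the non-reference linear predictors (n, k-1)."""
    shift = np.maximum(eta.max(axis=1), 0.0)
    denom = np.exp(-shift) + np.exp(eta - shift[:, None]).sum(axis=1)
    return float((Y1 * eta).sum() - (shift + np.log(denom)).sum())


def fit_mlr(
    X: np.ndarray,
    y: np.ndarray,
    classes: tuple[str, ...] = CLASSES,
    feature_ids: tuple[str, ...] | None = None,
    warm_start: np.ndarray | None = None,
    ridge: float = 0.0,
    tol: float = _TOL,
) -> MLRModel:
    """Exact-ML multinomial logit via Newton iteration.

    Converges when the relative log-likelihood change drops below ``tol``
    (default 1e-8; forward selection scans candidates at a looser 1e-6 and
    refits the winner at full tolerance) or after 200 iterations; on
    degeneracy (perfect separation) the fit is repeated with a tiny ridge
    penalty and flagged via ``model.ridge``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    n, p = X.shape
    k = len(classes)
    X1 = np.empty((n, p + 1))
    X1[:, 0] = 1.0
    X1[:, 1:] = X
    Y = _onehot(y, classes)
    counts = Y.sum(axis=0)
    if counts.sum() != n:
        bad = set(y) - set(classes)
        raise ValueError(f"labels {bad} not in {classes}")
    if (counts > 0).sum() < 2:
        raise ValueError("need at least 2 classes present")
    Y1 = Y[:, 1:]

    B = np.zeros((k - 1, p + 1)) if warm_start is None else warm_start.copy()
    eta = X1 @ B.T
    ll = _loglik_eta(eta, Y1) - 0.5 * ridge * (B**2).sum()
    converged = False
    m = p + 1
    diag = np.arange((k - 1) * m)
    for _ in range(_MAX_ITER):
        # class probabilities for the non-reference classes
        shift = np.maximum(eta.max(axis=1), 0.0)[:, None]
        Pm = np.exp(eta - shift)
        Pm /= np.exp(-shift) + Pm.sum(axis=1, keepdims=True)
        G = X1.T @ (Y1 - Pm) - ridge * B.T  # (p+1, k-1)
        # Hessian blocks H[a,b] = X1' diag(P_a (delta_ab - P_b)) X1, via BLAS
        H = np.empty(((k - 1) * m, (k - 1) * m))
        for a in range(k - 1):
            for b in range(a, k - 1):
                w = Pm[:, a] * ((a == b) - Pm[:, b])
                block = X1.T @ (w[:, None] * X1)
                H[a * m:(a + 1) * m, b * m:(b + 1) * m] = block
                if b != a:
                    H[b * m:(b + 1) * m, a * m:(a + 1) * m] = block
        H[diag, diag] += ridge + 1e-12
        try:
            step = np.linalg.solve(H, G.T.reshape(-1)).reshape(k - 1, p + 1)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _half in range(30):
            B_new = B + scale * step
            eta_new = X1 @ B_new.T
            ll_new = _loglik_eta(eta_new, Y1) - 0.5 * ridge * (B_new**2).sum()
            if ll_new >= ll - 1e-13:
                break
            scale *= 0.5
        else:
            break
        rel = abs(ll_new - ll) / max(abs(ll), 1.0)
        B, ll, eta = B_new, ll_new, eta_new
        if rel < tol:
            converged = True
            break

    # a log-likelihood at (numerically) zero means the classes are perfectly
    # separated and the MLE does not exist
    separated = ll > -1e-6 and p > 0
    blown = np.abs(B).max() > _COEF_BLOWUP
    if ridge == 0.0 and (not converged or blown or separated or not np.isfinite(ll)):
        return fit_mlr(X, y, classes, feature_ids, None, ridge=_RIDGE_FALLBACK,
                       tol=tol)
    ids = feature_ids if feature_ids is not None else tuple(f"x{j}" for j in range(p))
    return MLRModel(
        feature_ids=tuple(ids),
        coef=B,
        classes=tuple(classes),
        loglik=_loglik_eta(X1 @ B.T, Y1),  # unpenalized, for BIC
        n_train=n,
        converged=converged,
        ridge=ridge,
    )


def bic(model: MLRModel) -> float:
    """BIC = -2 logL + q ln(n), q = (k-1) * (features + 1) free parameters."""
    return -2.0 * model.loglik + model.n_params * np.log(model.n_train)


# ---------------------------------------------------------------------------
# Forward selection


@dataclass
class SelectionTrace:
    """Ordered record of one greedy forward-selection run."""

    features: list[str]
    bics: list[float]         # BIC after each accepted addition
    bic_null: float           # intercept-only BIC
    stop_reason: str
    model: MLRModel | None = None


def forward_select(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: list[str],
    delta: float = 2.0,
    max_features: int | None = None,
) -> SelectionTrace:
    """Greedy forward BIC selection for the multinomial logit.

    At each step the candidate with the lowest BIC is added; selection stops
    when the best achievable improvement over the current BIC is <= ``delta``
    (a BIC difference of 2 being the conventional evidence grade).
    """
    if len(feature_ids) == 0:
        raise ValueError("zero candidate features")
    X = np.asarray(X, dtype=float)
    null_model = fit_mlr(np.empty((len(y), 0)), y, feature_ids=())
    current_bic = bic(null_model)
    current_model = null_model
    chosen: list[int] = []
    bics: list[float] = []
    remaining = list(range(len(feature_ids)))
    stop = "no_improvement"
    cap = max_features if max_features is not None else len(feature_ids)
    while remaining and len(chosen) < cap:
        warm = np.column_stack(
            [current_model.coef, np.zeros(current_model.coef.shape[0])]
        )
        best_bic, best_j, best_model = np.inf, None, None
        for j in remaining:
            cols = chosen + [j]
            # candidate scan at loosened tolerance; the winner is refit below
            m = fit_mlr(
                X[:, cols], y,
                feature_ids=tuple(feature_ids[c] for c in cols),
                warm_start=warm,
                tol=1e-6,
            )
            b = bic(m)
            if b < best_bic:
                best_bic, best_j, best_model = b, j, m
        if current_bic - best_bic <= delta:
            stop = "no_improvement"
            break
        chosen.append(best_j)
        remaining.remove(best_j)
        cols = list(chosen)
        best_model = fit_mlr(
            X[:, cols], y,
            feature_ids=tuple(feature_ids[c] for c in cols),
            warm_start=best_model.coef,
        )
        best_bic = bic(best_model)
        bics.append(best_bic)
        current_bic, current_model = best_bic, best_model
    else:
        stop = "exhausted" if not remaining else "max_features"
    return SelectionTrace(
        features=[feature_ids[j] for j in chosen],
        bics=bics,
        bic_null=bic(null_model),
        stop_reason=stop,
        model=current_model,
    )


# ---------------------------------------------------------------------------
# Inner multiple random cross-validation


def stratified_split(
    y: np.ndarray, train_frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One stratified train/test split preserving class shares within 1 sample."""
    train_idx, test_idx = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if len(idx) < 2:
            raise ValueError(f"stratum {c!r} too small to split")
        rng.shuffle(idx)
        n_train = int(round(train_frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


@dataclass
class MrcvRep:
    trace: SelectionTrace
    acc_train: float
    acc_test: float


def mrcv(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: list[str],
    reps: int = 100,
    train_frac: float = 0.70,
    delta: float = 2.0,
    rng: np.random.Generator | None = None,
) -> list[MrcvRep]:
    """Repeated stratified 70/30 splits with forward-BIC selection on each."""
    rng = rng if rng is not None else np.random.default_rng(0)
    out = []
    for _ in range(reps):
        tr, te = stratified_split(y, train_frac, rng)
        trace = forward_select(X[tr], y[tr], feature_ids, delta=delta)
        model = trace.model
        cols = [feature_ids.index(f) for f in trace.features]
        acc_tr = float((model.predict(X[tr][:, cols]) == y[tr]).mean())
        acc_te = float((model.predict(X[te][:, cols]) == y[te]).mean())
        out.append(MrcvRep(trace=trace, acc_train=acc_tr, acc_test=acc_te))
    return out


def rank_and_cut(traces: list[SelectionTrace]) -> list[str]:
    """Consensus feature list: frequency-ranked, cut at the score-curve elbow.

    Features are scored by how often they were selected across traces, ties
    broken by mean addition position; the sorted frequency curve is cut at
    the point of maximum perpendicular deviation from the chord joining its
    endpoints (earliest point on ties).
    """
    if not traces:
        raise ValueError("no traces")
    freq: dict[str, int] = {}
    pos_sum: dict[str, float] = {}
    for tr in traces:
        for pos, f in enumerate(tr.features, start=1):
            freq[f] = freq.get(f, 0) + 1
            pos_sum[f] = pos_sum.get(f, 0.0) + pos
    if not freq:
        raise ValueError("all traces empty")
    feats = sorted(freq, key=lambda f: (-freq[f], pos_sum[f] / freq[f], f))
    scores = np.array([freq[f] for f in feats], dtype=float)
    if len(feats) <= 2:
        return feats
    x = np.arange(len(scores), dtype=float)
    x1, y1, x2, y2 = x[0], scores[0], x[-1], scores[-1]
    denom = np.hypot(y2 - y1, x2 - x1)
    dist = np.abs((y2 - y1) * x - (x2 - x1) * scores + x2 * y1 - y2 * x1) / denom
    elbow = int(np.argmax(dist))
    return feats[: elbow + 1]


# ---------------------------------------------------------------------------
# Evaluation


def evaluate(model: MLRModel, X: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """MAP accuracy, macro one-vs-rest AUC, per-class sensitivity/specificity,
    and balanced accuracy (mean per-class sensitivity)."""
    y = np.asarray(y)
    missing = set(model.classes) - set(np.unique(y))
    if missing:
        raise ValueError(f"classes absent from y: {sorted(missing)}")
    proba = model.predict_proba(X)
    pred = model.predict(X)
    metrics: dict[str, float] = {"accuracy": float((pred == y).mean())}
    aucs = [
        roc_auc_score((y == c).astype(int), proba[:, a])
        for a, c in enumerate(model.classes)
    ]
    metrics["auc_macro"] = float(np.mean(aucs))
    sens = []
    for a, c in enumerate(model.classes):
        is_c = y == c
        tp = float(((pred == c) & is_c).sum())
        fn = float(((pred != c) & is_c).sum())
        tn = float(((pred != c) & ~is_c).sum())
        fp = float(((pred == c) & ~is_c).sum())
        se = tp / (tp + fn)
        sp = tn / (tn + fp) if (tn + fp) > 0 else np.nan
        metrics[f"sensitivity_{c}"] = se
        metrics[f"specificity_{c}"] = sp
        sens.append(se)
    metrics["balanced_accuracy"] = float(np.mean(sens))
    return metrics


METRIC_KEYS = (
    "accuracy",
    "auc_macro",
    "balanced_accuracy",
    "sensitivity_Ctr",
    "sensitivity_LN",
    "sensitivity_LC",
    "specificity_Ctr",
    "specificity_LN",
    "specificity_LC",
)
SETS = ("train", "test", "validation")


@dataclass
class FoldResult:
    fold: int
    consensus: list[str]
    metrics: dict[str, dict[str, float]]   # set -> metric -> value


@dataclass
class ClassifierReport:
    folds: list[FoldResult]
    aggregate: pd.DataFrame                # (set, metric) -> mean, ci_lo, ci_hi
    selection_counts: pd.Series            # feature -> folds containing it
    signature_sizes: list[int]
    mode: str = "paper"

    def to_table2(self) -> pd.DataFrame:
        """Table shaped like the study's classification-indices table."""
        rows = []
        label = {"train": "Training", "test": "Test", "validation": "Validation"}
        for s in SETS:
            agg = self.aggregate.loc[s]
            def cell(metric, scale=100.0, digits=0):
                m, lo, hi = agg.loc[metric]
                if scale == 100.0:
                    return f"{m*scale:.0f} ({lo*scale:.0f}-{hi*scale:.0f})"
                return f"{m:.2f} ({lo:.2f}-{hi:.2f})"
            rows.append(
                {
                    "Set": label[s],
                    "Overall Accuracy% (95% CI)": cell("accuracy"),
                    "Overall AUC (95% CI)": cell("auc_macro", scale=1.0),
                    "Specificity% Ctr": cell("specificity_Ctr"),
                    "Specificity% LN": cell("specificity_LN"),
                    "Specificity% LC": cell("specificity_LC"),
                    "Sensitivity% Ctr": cell("sensitivity_Ctr"),
                    "Sensitivity% LN": cell("sensitivity_LN"),
                    "Sensitivity% LC": cell("sensitivity_LC"),
                    "Balanced Accuracy%": cell("balanced_accuracy"),
                }
            )
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "mode": self.mode,
            "signature_sizes": self.signature_sizes,
            "selection_counts": self.selection_counts.to_dict(),
            "aggregate": {
                s: {
                    m: dict(zip(("mean", "ci_lo", "ci_hi"),
                                map(float, self.aggregate.loc[(s, m)])))
                    for m in METRIC_KEYS
                }
                for s in SETS
            },
            "folds": [
                {
                    "fold": fr.fold,
                    "consensus": fr.consensus,
                    "metrics": fr.metrics,
                }
                for fr in self.folds
            ],
        }


def _aggregate(folds: list[FoldResult]) -> pd.DataFrame:
    rows = []
    for s in SETS:
        for m in METRIC_KEYS:
            vals = np.array([f.metrics[s][m] for f in folds], dtype=float)
            mean = float(np.nanmean(vals))
            se = float(np.nanstd(vals, ddof=1) / np.sqrt(len(vals)))
            rows.append((s, m, mean, mean - 1.96 * se, mean + 1.96 * se))
    df = pd.DataFrame(rows, columns=["set", "metric", "mean", "ci_lo", "ci_hi"])
    return df.set_index(["set", "metric"])


# ---------------------------------------------------------------------------
# Outer cross-validation


def _screen_candidates(
    X: np.ndarray, y: np.ndarray, feature_ids: list[str], cap: int | None
) -> list[str]:
    """Pre-screen: keep the ``cap`` features with smallest Kruskal-Wallis p."""
    if cap is None or len(feature_ids) <= cap:
        return list(feature_ids)
    pvals = np.empty(len(feature_ids))
    for j in range(len(feature_ids)):
        _, pvals[j] = kruskal_wallis([X[y == g, j] for g in CLASSES])
    order = np.argsort(pvals, kind="stable")[:cap]
    order = np.sort(order)  # keep original feature order
    return [feature_ids[j] for j in order]


def _fold_test_indices(
    y: np.ndarray, folds: int, per_group_test: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Disjoint outer test sets: ``per_group_test`` samples per group per fold."""
    picks: dict[str, np.ndarray] = {}
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if len(idx) < folds * per_group_test:
            raise ValueError(
                f"group {c!r} has {len(idx)} samples; needs >= "
                f"{folds * per_group_test} for {folds} disjoint test sets"
            )
        rng.shuffle(idx)
        picks[c] = idx
    return [
        np.concatenate(
            [picks[c][f * per_group_test : (f + 1) * per_group_test]
             for c in np.unique(y)]
        )
        for f in range(folds)
    ]


def _run_fold(
    fold: int,
    X_pool: np.ndarray,
    y_pool: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    feature_ids: list[str],
    mrcv_reps: int,
    train_frac: float,
    delta: float,
    candidate_cap: int | None,
    rng: np.random.Generator,
) -> FoldResult:
    candidates = _screen_candidates(X_pool, y_pool, feature_ids, candidate_cap)
    cand_cols = [feature_ids.index(f) for f in candidates]
    reps = mrcv(X_pool[:, cand_cols], y_pool, candidates, reps=mrcv_reps,
                train_frac=train_frac, delta=delta, rng=rng)
    traces = [r.trace for r in reps]
    if all(len(t.features) == 0 for t in traces):
        consensus: list[str] = []
    else:
        consensus = rank_and_cut(traces)
    cols = [feature_ids.index(f) for f in consensus]
    final = fit_mlr(X_pool[:, cols], y_pool, feature_ids=tuple(consensus))
    metrics = {
        "train": evaluate(final, X_pool[:, cols], y_pool),
        "test": evaluate(final, X_test[:, cols], y_test),
        "validation": evaluate(final, X_val[:, cols], y_val),
    }
    return FoldResult(fold=fold, consensus=consensus, metrics=metrics)


def _report(folds_out: list[FoldResult], mode: str) -> ClassifierReport:
    counts: dict[str, int] = {}
    for fr in folds_out:
        for f in fr.consensus:
            counts[f] = counts.get(f, 0) + 1
    return ClassifierReport(
        folds=folds_out,
        aggregate=_aggregate(folds_out),
        selection_counts=pd.Series(counts, dtype=int).sort_values(ascending=False),
        signature_sizes=[len(fr.consensus) for fr in folds_out],
        mode=mode,
    )


def _matrix_xy(
    matrix: MeasurementMatrix, features: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    X = matrix.values[features].to_numpy(dtype=float)
    y = matrix.samples["group"].to_numpy()
    return X, y


def outer_cv(
    moltest: MeasurementMatrix,
    smac: MeasurementMatrix,
    features: list[str],
    folds: int = 10,
    per_group_test: int = 10,
    mrcv_reps: int = 100,
    train_frac: float = 0.70,
    delta: float = 2.0,
    candidate_cap: int | None = 60,
    seed: int = 0,
) -> ClassifierReport:
    """Paper-faithful nested CV on preprocessed (log2, corrected) matrices.

    The two cohorts must share the ``features`` columns.  Fully
    deterministic given ``seed``.
    """
    for f in features:
        if f not in moltest.values.columns or f not in smac.values.columns:
            raise ValueError(f"cohorts lack shared analyte {f!r}")
    X_mol, y_mol = _matrix_xy(moltest, features)
    X_val, y_val = _matrix_xy(smac, features)
    ss = np.random.SeedSequence(seed)
    rng_split = np.random.default_rng(ss.spawn(1)[0])
    test_sets = _fold_test_indices(y_mol, folds, per_group_test, rng_split)
    fold_rngs = [np.random.default_rng(c) for c in ss.spawn(folds)]
    folds_out = []
    for f, test_idx in enumerate(test_sets):
        pool_idx = np.setdiff1d(np.arange(len(y_mol)), test_idx)
        folds_out.append(
            _run_fold(
                f, X_mol[pool_idx], y_mol[pool_idx],
                X_mol[test_idx], y_mol[test_idx], X_val, y_val,
                list(features), mrcv_reps, train_frac, delta, candidate_cap,
                fold_rngs[f],
            )
        )
    return _report(folds_out, mode="paper")


def outer_cv_strict(
    raw: MeasurementMatrix,
    limits,
    folds: int = 10,
    per_group_test: int = 10,
    mrcv_reps: int = 100,
    train_frac: float = 0.70,
    delta: float = 2.0,
    candidate_cap: int | None = 60,
    seed: int = 0,
    preprocess_kwargs: dict | None = None,
) -> ClassifierReport:
    """Leakage-guarded nested CV: per-fold preprocessing excludes test samples.

    ``raw`` holds both cohorts on the linear scale.  For every outer fold the
    whole normalization chain (partition, imputation donors, LOD draws,
    batch parameters) is fitted on all samples except that fold's test set;
    the held-out samples are then mapped through the fitted parameters.
    """
    from .preprocess import preprocess

    pp_kwargs = dict(preprocess_kwargs or {})
    samples = raw.samples
    mol_ids = np.array(raw.sample_ids)[(samples["cohort"] == "MOLTEST").to_numpy()]
    y_mol_all = samples.loc[mol_ids, "group"].to_numpy()
    ss = np.random.SeedSequence(seed)
    rng_split = np.random.default_rng(ss.spawn(1)[0])
    test_sets = _fold_test_indices(y_mol_all, folds, per_group_test, rng_split)
    fold_seeds = ss.spawn(folds)
    folds_out = []
    for f, test_pos in enumerate(test_sets):
        test_ids = mol_ids[test_pos]
        fit_ids = [s for s in raw.sample_ids if s not in set(test_ids)]
        sub_seeds = fold_seeds[f].generate_state(3) % (2**31)
        res = preprocess(raw.subset_samples(fit_ids), limits,
                         seed=int(sub_seeds[0]), **pp_kwargs)
        features = [a for a in res.partition.quantitative]
        fit_mat = res.matrix
        test_mat = res.transform(raw.subset_samples(list(test_ids)),
                                 seed=int(sub_seeds[1]))
        pool_mask = (fit_mat.samples["cohort"] == "MOLTEST").to_numpy()
        pool_ids = np.array(fit_mat.sample_ids)[pool_mask]
        val_ids = np.array(fit_mat.sample_ids)[~pool_mask]
        X_pool, y_pool = _matrix_xy(fit_mat.subset_samples(list(pool_ids)), features)
        X_val, y_val = _matrix_xy(fit_mat.subset_samples(list(val_ids)), features)
        X_test, y_test = _matrix_xy(test_mat, features)
        folds_out.append(
            _run_fold(
                f, X_pool, y_pool, X_test, y_test, X_val, y_val,
                features, mrcv_reps, train_frac, delta, candidate_cap,
                np.random.default_rng(int(sub_seeds[2])),
            )
        )
    return _report(folds_out, mode="strict")
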