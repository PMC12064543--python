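"""Distant-metastasis classifiers and clinical logistic screening.

All four model flavours (clinical, conventional radiomics, ITH, combined)
share one training recipe: minority-class SMOTE balancing applied inside
each training fold only, a random forest classifier, and sequential
model-based (Bayesian) hyperparameter search scored by stratified
cross-validated AUC.  Clinical covariates are screened by univariate
logistic regression with an entry rule (p < 0.1 by default) feeding one
multivariate model, reported as odds ratios with Wald 95% intervals.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "ModelBundle",
    "LogisticReport",
    "smote_oversample",
    "fit_rf_classifier",
    "fit_logistic_screen",
    "assemble_combined_features",
    "predict_risk",
]


# ---------------------------------------------------------------------------
# SMOTE


def smote_oversample(
    X: np.ndarray | pd.DataFrame,
    y: Sequence[int],
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by synthetic minority oversampling.

    Each synthetic sample is ``x_i + u * (x_nn - x_i)`` with ``u ~ U[0,1]``,
    ``x_nn`` one of the ``k_neighbors`` minority nearest neighbors of the
    minority sample ``x_i``.  Originals are preserved; classes come back at
    equal counts.
    """
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y).astype(int)
    classes, counts = np.unique(ya, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE expects binary labels with both classes present")
    if counts[0] == counts[1]:
        return Xa.copy(), ya.copy()
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min < 2:
        raise ValueError("minority class needs at least 2 samples for SMOTE")
    if k_neighbors >= n_min:
        raise ValueError(
            f"k_neighbors={k_neighbors} must be < minority count {n_min}; "
            f"lower k_neighbors or collect more minority samples"
        )
    rng = np.random.default_rng(seed)
    Xmin = Xa[ya == minority]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xmin)
    _, idx = nn.kneighbors(Xmin)  # first column is the sample itself
    n_new = n_maj - n_min
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(1, k_neighbors + 1, size=n_new)
    u = rng.random(size=n_new)[:, None]
    neigh = Xmin[idx[base, pick]]
    synth = Xmin[base] + u * (neigh - Xmin[base])
    X_out = np.vstack([Xa, synth])
    y_out = np.concatenate([ya, np.full(n_new, minority)])
    return X_out, y_out


# ---------------------------------------------------------------------------
# RF with sequential model-based hyperparameter search


_SPACE = {
    "n_estimators": (50, 300),
    "max_depth": (2, 16),
    "min_samples_leaf": (1, 10),
    "max_features": (0.1, 1.0),
}


def _sample_config(rng: np.random.Generator) -> dict:
    return {
        "n_estimators": int(rng.integers(*_SPACE["n_estimators"])),
        "max_depth": int(rng.integers(*_SPACE["max_depth"])),
        "min_samples_leaf": int(rng.integers(*_SPACE["min_samples_leaf"])),
        "max_features": float(rng.uniform(*_SPACE["max_features"])),
    }


def _config_vector(cfg: dict) -> list[float]:
    return [cfg[k] for k in ("n_estimators", "max_depth", "min_samples_leaf",
                             "max_features")]


@dataclasses.dataclass
class ModelBundle:
    """A fitted DM classifier plus everything needed to reapply it."""

    kind: str
    feature_names: list[str]
    model: RandomForestClassifier
    best_params: dict
    cv_auc: float
    search_record: list[tuple[dict, float]]
    folds: int
    seed: int

    def to_dict(self) -> dict:
        """JSON-serializable description (hyperparameters + features)."""
        return {
            "kind": self.kind,
            "feature_names": self.feature_names,
            "best_params": self.best_params,
            "cv_auc": self.cv_auc,
            "folds": self.folds,
            "seed": self.seed,
        }


def _cv_auc(X, y, cfg, folds, seed, smote_k) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for fi, (tr, va) in enumerate(skf.split(X, y)):
        Xtr, ytr = X[tr], y[tr]
        counts = np.bincount(ytr)
        n_min = counts[counts > 0].min()
        if len(np.unique(ytr)) == 2 and counts.min() != counts.max() and n_min >= 2:
            k = min(smote_k, n_min - 1)
            Xtr, ytr = smote_oversample(Xtr, ytr, k_neighbors=k, seed=seed + fi)
        clf = RandomForestClassifier(random_state=seed, n_jobs=1, **cfg)
        clf.fit(Xtr, ytr)
        p = clf.predict_proba(X[va])[:, 1]
        if len(np.unique(y[va])) == 2:
            aucs.append(roc_auc_score(y[va], p))
    return float(np.mean(aucs)) if aucs else 0.5


def fit_rf_classifier(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[int],
    folds: int = 10,
    search_budget: int = 50,
    seed: int = 0,
    smote_k: int = 5,
    kind: str = "rf",
) -> ModelBundle:
    """Random forest with SMOTE-in-fold CV and sequential model-based tuning.

    The search spends ``search_budget`` evaluations on the space (trees,
    depth, min leaf size, feature fraction): a random initial design, then
    expected-improvement proposals from a random-forest surrogate over the
    observed (configuration, CV-AUC) pairs.  SMOTE is applied inside each
    training fold only, never to validation folds.  The final model refits
    the full (SMOTE-balanced) training data at the best settings.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        feature_names = [f"f{i}" for i in range(Xa.shape[1])]
    ya = np.asarray(y).astype(int)
    classes, counts = np.unique(ya, return_counts=True)
    if len(classes) != 2:
        raise ValueError("training labels must contain both classes")
    folds = int(min(folds, counts.min()))
    if folds < 2:
        raise ValueError("too few subjects in the minority class for CV")
    rng = np.random.default_rng(seed)
    n_init = min(max(5, search_budget // 5), search_budget)
    record: list[tuple[dict, float]] = []
    for _ in range(n_init):
        cfg = _sample_config(rng)
        record.append((cfg, _cv_auc(Xa, ya, cfg, folds, seed, smote_k)))
    while len(record) < search_budget:
        Xs = np.array([_config_vector(c) for c, _ in record])
        ys = np.array([a for _, a in record])
        surrogate = RandomForestRegressor(
            n_estimators=50, random_state=seed, n_jobs=1
        ).fit(Xs, ys)
        cands = [_sample_config(rng) for _ in range(256)]
        Xc = np.array([_config_vector(c) for c in cands])
        preds = np.stack([t.predict(Xc) for t in surrogate.estimators_])
        mu, sd = preds.mean(axis=0), preds.std(axis=0)
        best = ys.max()
        z = (mu - best) / np.maximum(sd, 1e-9)
        from scipy.stats import norm

        ei = (mu - best) * norm.cdf(z) + sd * norm.pdf(z)
        cfg = cands[int(np.argmax(ei))]
        record.append((cfg, _cv_auc(Xa, ya, cfg, folds, seed, smote_k)))
    best_cfg, best_auc = max(record, key=lambda t: t[1])
    n_min = counts.min()
    Xf, yf = Xa, ya
    if counts.min() != counts.max() and n_min >= 2:
        Xf, yf = smote_oversample(
            Xa, ya, k_neighbors=min(smote_k, n_min - 1), seed=seed
        )
    final = RandomForestClassifier(random_state=seed, n_jobs=1, **best_cfg)
    final.fit(Xf, yf)
    return ModelBundle(
        kind=kind,
        feature_names=feature_names,
        model=final,
        best_params=best_cfg,
        cv_auc=best_auc,
        search_record=record,
        folds=folds,
        seed=seed,
    )


def predict_risk(bundle: ModelBundle, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Per-subject event probability from a fitted bundle."""
    if isinstance(X, pd.DataFrame):
        missing = [f for f in bundle.feature_names if f not in X.columns]
        if missing:
            raise ValueError(f"missing features: {missing}")
        Xa = X[bundle.feature_names].to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        if Xa.shape[1] != len(bundle.feature_names):
            raise ValueError(
                f"expected {len(bundle.feature_names)} features, got {Xa.shape[1]}"
            )
    return bundle.model.predict_proba(Xa)[:, 1]


# ---------------------------------------------------------------------------
# logistic screening (clinical covariates)


@dataclasses.dataclass
class LogisticReport:
    """Odds ratios from the univariate screen and the multivariate model."""

    univariate: pd.DataFrame   # variable, or, ci_low, ci_high, p, unstable
    multivariate: pd.DataFrame
    entry_p: float

    def advanced_variables(self) -> list[str]:
        return list(self.multivariate["variable"])


def _fit_logit(y: np.ndarray, X: pd.DataFrame) -> tuple[pd.DataFrame, bool]:
    Xc = sm.add_constant(X, has_constant="add")
    unstable = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            if not res.mle_retvals.get("converged", True):
                unstable = True
        except Exception:
            res = None
            unstable = True
    rows = []
    for var in X.columns:
        if res is not None and var in res.params.index:
            beta = res.params[var]
            se = res.bse[var]
            bad = unstable or not np.isfinite(se) or se > 1e3
            rows.append({
                "variable": var,
                "or": float(np.exp(beta)),
                "ci_low": float(np.exp(beta - 1.959963984540054 * se)),
                "ci_high": float(np.exp(beta + 1.959963984540054 * se)),
                "p": float(res.pvalues[var]),
                "unstable": bool(bad),
            })
        else:
            rows.append({
                "variable": var, "or": np.nan, "ci_low": np.nan,
                "ci_high": np.nan, "p": np.nan, "unstable": True,
            })
    return pd.DataFrame(rows), unstable


def fit_logistic_screen(
    table: pd.DataFrame,
    outcome: Sequence[int] | str,
    entry_p: float = 0.1,
) -> LogisticReport:
    """Univariate logistic screen feeding one multivariate model.

    Every covariate is fit against the binary outcome on its own; those
    with univariate Wald p below ``entry_p`` advance together to the
    multivariate model.  Perfect separation or non-convergence flags the
    estimate as unstable rather than failing.  Collinear covariates in the
    multivariate stage (rank-deficient design) are flagged likewise.
    """
    if isinstance(outcome, str):
        y = table[outcome].to_numpy().astype(int)
        covars = table.drop(columns=[outcome])
    else:
        y = np.asarray(outcome).astype(int)
        covars = table
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("outcome must be binary 0/1")
    uni_rows = []
    for var in covars.columns:
        df, _ = _fit_logit(y, covars[[var]])
        uni_rows.append(df.iloc[0])
    uni = pd.DataFrame(uni_rows).reset_index(drop=True)
    advance = uni.loc[(uni["p"] < entry_p) & ~uni["unstable"], "variable"].tolist()
    if advance:
        Xm = covars[advance]
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(Xm)), Xm]))
        multi, unstable = _fit_logit(y, Xm)
        if rank < Xm.shape[1] + 1:
            multi["unstable"] = True
    else:
        multi = uni.iloc[0:0].copy()
    return LogisticReport(univariate=uni, multivariate=multi, entry_p=entry_p)


# ---------------------------------------------------------------------------
# combined model assembly


def assemble_combined_features(
    clinical: pd.DataFrame,
    ith_vector: pd.DataFrame,
    aux_score: pd.Series | None = None,
) -> pd.DataFrame:
    """Column-bind clinical covariates, the ITH vector, and an optional
    auxiliary score, aligned on subject id.

    The auxiliary column stands in for an externally supplied per-subject
    score (for example from a separately trained image model); omitting it
    yields the clinical+ITH feature set.
    """
    for name, df in (("clinical", clinical), ("ith_vector", ith_vector)):
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].tolist()
            raise ValueError(f"duplicate subject ids in {name}: {dups}")
    only_a = set(clinical.index) - set(ith_vector.index)
    only_b = set(ith_vector.index) - set(clinical.index)
    if only_a or only_b:
        raise ValueError(
            "subject id mismatch; clinical-only="
            f"{sorted(map(str, only_a))}, ith-only={sorted(map(str, only_b))}"
        )
    out = clinical.join(ith_vector.loc[clinical.index])
    if aux_score is not None:
        if aux_score.index.duplicated().any():
            raise ValueError("duplicate subject ids in aux_score")
        extra = set(out.index) - set(aux_score.index)
        if extra:
            raise ValueError(f"aux_score missing subjects: {sorted(map(str, extra))}")
        out = out.join(aux_score.rename(aux_score.name or "aux_score"))
    return out
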