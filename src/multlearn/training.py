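"""Supervised model training: log-loss objective, Gaussian-process Bayesian
hyperparameter optimization, the three-fold boosted-tree ensemble (TSPT), the
training-data decision-threshold rule, the SMLA baseline, and the end-to-end
MuLT trainer that wires marker selection and feature extraction together.

The Bayesian optimizer evaluates ``n_init`` random points in the search
space, then fits a Gaussian-process surrogate (Matérn-5/2 kernel) to the
observed losses and sequentially proposes the candidate maximizing expected
improvement, for ``n_iter`` further evaluations.  It returns the point with
the global-minimum observed loss and the full trace.  An objective that
raises is recorded as a failed evaluation with infinite loss and skipped when
fitting the surrogate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import lightgbm as lgb
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .core import Cohort, ContractError, DataError, Normalizer, fit_normalizer, one_hot_treatment
from .extraction import (DenoiserModel, GeneClusterer, PatientProfiler,
                         denoise, gene_clustering, genetic_profiling,
                         select_num_clusters, train_denoiser)
from .selection import SelectionReport, select_markers

EPS_LOG_LOSS = 1e-15


# ---------------------------------------------------------------------------
# Hyperparameter spaces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Real:
    name: str
    low: float
    high: float
    log: bool = False


@dataclass(frozen=True)
class Integer:
    name: str
    low: int
    high: int
    log: bool = False


@dataclass(frozen=True)
class Categorical:
    name: str
    choices: tuple


#: Boosted-tree (LightGBM) search space: tree complexity, class weighting,
#: leaf constraints, histogram binning and row/feature subsampling.
LIGHTGBM_SPACE = [
    Integer("num_leaves", 2, 64, log=True),
    Real("scale_pos_weight", 0.5, 10.0, log=True),
    Integer("min_child_samples", 2, 50, log=True),
    Integer("bin_construct_sample_cnt", 1000, 100000, log=True),
    Integer("max_bin", 16, 255, log=True),
    Real("min_sum_hessian_in_leaf", 1e-3, 10.0, log=True),
    Real("bagging_fraction", 0.5, 1.0),
    Real("feature_fraction", 0.3, 1.0),
    Real("feature_fraction_bynode", 0.3, 1.0),
]

#: Multilayer-perceptron search space.
MLP_SPACE = [
    Integer("hidden_layer_sizes", 8, 256, log=True),
    Categorical("learning_rate", ("constant", "invscaling", "adaptive")),
    Real("learning_rate_init", 1e-4, 1e-1, log=True),
    Integer("max_iter", 50, 500, log=True),
    Real("tol", 1e-5, 1e-2, log=True),
]

#: Support-vector-machine search space.
SVM_SPACE = [
    Real("C", 1e-2, 1e3, log=True),
    Real("gamma", 1e-4, 10.0, log=True),
    Integer("degree", 2, 5),
    Categorical("kernel", ("linear", "poly", "rbf")),
]

SPACES = {"gbt": LIGHTGBM_SPACE, "mlp": MLP_SPACE, "svm": SVM_SPACE}


# ---------------------------------------------------------------------------
# Log loss
# ---------------------------------------------------------------------------

def log_loss(y, y_hat, eps: float = EPS_LOG_LOSS) -> float:
    """Binary cross-entropy, -(1/N) sum[y log p + (1-y) log(1-p)]."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(y_hat, dtype=float)
    if y.shape != p.shape:
        raise ContractError(
            f"label/probability length mismatch: {y.shape} vs {p.shape}")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


# ---------------------------------------------------------------------------
# Bayesian optimization
# ---------------------------------------------------------------------------

def _sample_params(space, rng) -> dict:
    out = {}
    for dim in space:
        if isinstance(dim, Real):
            if dim.log:
                out[dim.name] = float(np.exp(rng.uniform(
                    np.log(dim.low), np.log(dim.high))))
            else:
                out[dim.name] = float(rng.uniform(dim.low, dim.high))
        elif isinstance(dim, Integer):
            if dim.log:
                v = np.exp(rng.uniform(np.log(dim.low), np.log(dim.high + 1)))
            else:
                v = rng.uniform(dim.low, dim.high + 1)
            out[dim.name] = int(min(dim.high, max(dim.low, math.floor(v))))
        else:
            out[dim.name] = dim.choices[rng.integers(len(dim.choices))]
    return out


def _encode(space, params: dict) -> np.ndarray:
    """Map a parameter dict to a unit-cube vector for the GP surrogate."""
    enc: list[float] = []
    for dim in space:
        v = params[dim.name]
        if isinstance(dim, (Real, Integer)):
            lo, hi = dim.low, dim.high
            if dim.log:
                enc.append((np.log(v) - np.log(lo)) / (np.log(hi) - np.log(lo)))
            else:
                enc.append((v - lo) / (hi - lo) if hi > lo else 0.0)
        else:
            onehot = [0.0] * len(dim.choices)
            onehot[dim.choices.index(v)] = 1.0
            enc.extend(onehot)
    return np.array(enc)


@dataclass
class BOResult:
    best_params: dict
    best_loss: float
    trace: list  # list of (params, loss) in evaluation order


def bayesian_optimize(space, objective, n_init: int = 10, n_iter: int = 50,
                      seed: int = 0, n_candidates: int = 512) -> BOResult:
    """Minimize ``objective`` over ``space`` with GP-guided search."""
    rng = np.random.default_rng(seed)
    trace: list[tuple[dict, float]] = []

    def evaluate(params):
        try:
            loss = float(objective(params))
        except Exception:
            loss = np.inf
        if not np.isfinite(loss):
            loss = np.inf
        trace.append((params, loss))

    for _ in range(n_init):
        evaluate(_sample_params(space, rng))

    for _ in range(n_iter):
        finite = [(p, l) for p, l in trace if np.isfinite(l)]
        if len(finite) < 2:
            evaluate(_sample_params(space, rng))
            continue
        X = np.vstack([_encode(space, p) for p, _ in finite])
        y = np.array([l for _, l in finite])
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5, length_scale=np.full(X.shape[1], 0.5),
                          length_scale_bounds=(1e-2, 1e2)),
            alpha=1e-6, normalize_y=True, random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(X, y)
        cand_params = [_sample_params(space, rng) for _ in range(n_candidates)]
        C = np.vstack([_encode(space, p) for p in cand_params])
        mu, sigma = gp.predict(C, return_std=True)
        sigma = np.maximum(sigma, 1e-12)
        best_f = y.min()
        z = (best_f - mu) / sigma
        ei = (best_f - mu) * stats.norm.cdf(z) + sigma * stats.norm.pdf(z)
        evaluate(cand_params[int(np.argmax(ei))])

    losses = [l for _, l in trace]
    best_idx = int(np.argmin(losses))
    return BOResult(best_params=dict(trace[best_idx][0]),
                    best_loss=losses[best_idx], trace=trace)


# ---------------------------------------------------------------------------
# Decision threshold
# ---------------------------------------------------------------------------

def select_threshold(scores, labels) -> tuple[float, float]:
    """Training-data decision threshold maximizing Youden's J.

    Scans the midpoints between adjacent sorted unique scores; classification
    is ``score >= threshold``.  Ties go to the lower threshold.  Returns
    ``(threshold, J)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ContractError("threshold selection needs both classes present")
    pos = labels == labels.max()
    uniq = np.unique(scores)
    if len(uniq) == 1:
        return float(uniq[0]), 0.0
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best_thr, best_j = candidates[0], -np.inf
    for thr in candidates:
        pred = scores >= thr
        sens = (pred & pos).sum() / pos.sum()
        spec = (~pred & ~pos).sum() / (~pos).sum()
        j = sens + spec - 1.0
        if j > best_j:
            best_thr, best_j = thr, j
    return float(best_thr), float(best_j)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def _make_lgbm(params: dict, seed: int, n_estimators: int = 100):
    return lgb.LGBMClassifier(
        objective="binary", n_estimators=n_estimators, bagging_freq=1,
        random_state=seed, n_jobs=1, verbose=-1, **params)


def make_estimator(model: str, params: dict, seed: int,
                   n_estimators: int = 100):
    """Instantiate a classifier for one of the supported methods."""
    if model == "gbt":
        return _make_lgbm(params, seed, n_estimators)
    if model == "mlp":
        p = dict(params)
        p["hidden_layer_sizes"] = (int(p["hidden_layer_sizes"]),)
        return MLPClassifier(random_state=seed, **p)
    if model == "svm":
        return SVC(probability=True, random_state=seed, **params)
    raise ContractError(f"unknown model {model!r} (expected gbt|mlp|svm)")


# ---------------------------------------------------------------------------
# Settings
# ---------------------------------------------------------------------------

@dataclass
class MultSettings:
    """Tunable knobs for the full training pipeline.

    Defaults follow the method's stated procedure (10 random + 50 GP-guided
    BO evaluations, 1000-epoch denoiser patience, 10-step NCS stall).  The
    ``fast`` preset trades optimization depth for wall time and is the size
    used by the bundled demonstrations.
    """

    alpha: float = 0.05
    beta: float = 0.75
    bo_n_init: int = 10
    bo_n_iter: int = 50
    n_estimators: int = 100
    early_stopping_rounds: int = 1
    ncs_max_stall: int = 10
    ncs_c_max: int | None = None
    kmeans_n_init: int = 10
    denoiser_patience: int = 1000
    denoiser_max_iter: int = 5000

    @classmethod
    def fast(cls) -> "MultSettings":
        return cls(bo_n_init=5, bo_n_iter=8, ncs_max_stall=5, ncs_c_max=8,
                   kmeans_n_init=5, denoiser_patience=100,
                   denoiser_max_iter=600)


# ---------------------------------------------------------------------------
# TSPT: three-fold boosted-tree ensemble
# ---------------------------------------------------------------------------

@dataclass
class TSPredictor:
    """A fitted treatment-sensitivity predictor.

    Holds the three boosted-tree members (scores are averaged), the
    Bayesian-optimized hyperparameters, the training-derived decision
    threshold, and — when trained through :func:`train_mult` — the full
    featurization bundle (normalizer, selected markers, clustering models,
    denoiser, treatment vocabulary) needed to score raw cohort patients.
    """

    boosters: list
    params: dict
    threshold: float
    youden_j: float
    feature_columns: list
    bo_result: BOResult | None = None
    # featurization bundle (set by train_mult)
    normalizer: Normalizer | None = None
    clinical_columns: list = field(default_factory=list)
    gene_columns: list = field(default_factory=list)
    selected_clinical: list = field(default_factory=list)
    selected_genes: list = field(default_factory=list)
    profiler: PatientProfiler | None = None
    gene_clusterer: GeneClusterer | None = None
    denoiser: DenoiserModel | None = None
    treatment_vocab: list = field(default_factory=list)
    reports: dict = field(default_factory=dict)

    def predict_scores(self, X: pd.DataFrame) -> np.ndarray:
        """Mean TS score of the ensemble members, in [0, 1]."""
        X = X[self.feature_columns]
        probs = [m.predict_proba(X)[:, 1] for m in self.boosters]
        return np.mean(probs, axis=0)

    def featurize(self, cohort: Cohort, treatment_override=None,
                  clip: bool = True) -> pd.DataFrame:
        """Build the G'|C'|L|E|G^d|T feature row block for cohort patients."""
        if self.normalizer is None:
            raise ContractError("predictor has no featurization bundle")
        raw = pd.concat([cohort.clinical[self.clinical_columns],
                         cohort.expression[self.gene_columns]], axis=1)
        Fn = self.normalizer.transform(raw, clip=clip)
        G = Fn[self.selected_genes]
        blocks = [G, Fn[self.selected_clinical]]
        if self.profiler is not None:
            blocks.append(self.profiler.transform(G))
        if self.gene_clusterer is not None:
            blocks.append(self.gene_clusterer.transform(G))
        if self.denoiser is not None:
            blocks.append(denoise(self.denoiser, G))
        if treatment_override is None:
            treatment = cohort.treatment
        elif isinstance(treatment_override, str):
            treatment = pd.Series(treatment_override,
                                  index=cohort.clinical.index)
        else:
            treatment = treatment_override
        blocks.append(one_hot_treatment(treatment, self.treatment_vocab))
        X = pd.concat(blocks, axis=1)
        return X[self.feature_columns]

    def score(self, cohort: Cohort, treatment_override=None) -> pd.Series:
        X = self.featurize(cohort, treatment_override=treatment_override)
        return pd.Series(self.predict_scores(X), index=X.index)

    def classify(self, cohort: Cohort) -> pd.Series:
        return (self.score(cohort) >= self.threshold).astype(int)


def _stratified_three_folds(y: np.ndarray, seed: int):
    """Three folds, each with both classes; re-splits up to 5 times."""
    for attempt in range(5):
        skf = StratifiedKFold(n_splits=3, shuffle=True,
                              random_state=seed + attempt)
        folds = [test for _, test in skf.split(np.zeros(len(y)), y)]
        if all(len(np.unique(y[f])) == 2 for f in folds):
            return folds
    raise DataError("could not build 3 stratified folds with both classes "
                    "after 5 attempts")


def train_tspt(X: pd.DataFrame, c, seed: int = 0,
               settings: MultSettings | None = None) -> TSPredictor:
    """Train the three-member boosted-tree ensemble on extracted features.

    Phase 1 optimizes the boosted-tree hyperparameters with BO on a
    stratified half-split of the training data (half trains, half scores the
    log loss).  Phase 2 splits the training data into three stratified folds
    and fits one member per pairwise fold union, early-stopped on log loss of
    the held-out third (1 round patience, 100 iterations max).  The decision
    threshold is then learned from the ensemble's training scores.
    """
    settings = settings or MultSettings()
    y = np.asarray(c).astype(int)
    if len(np.unique(y)) != 2:
        raise ContractError("training requires both outcome classes")

    idx = np.arange(len(y))
    half_a, half_b = train_test_split(idx, test_size=0.5, stratify=y,
                                      random_state=seed)

    def objective(params):
        m = _make_lgbm(params, seed, settings.n_estimators)
        m.fit(X.iloc[half_a], y[half_a])
        return log_loss(y[half_b], m.predict_proba(X.iloc[half_b])[:, 1])

    bo = bayesian_optimize(SPACES["gbt"], objective,
                           n_init=settings.bo_n_init,
                           n_iter=settings.bo_n_iter, seed=seed)

    folds = _stratified_three_folds(y, seed)
    boosters = []
    for k in range(3):
        val = folds[k]
        train = np.concatenate([folds[j] for j in range(3) if j != k])
        m = _make_lgbm(bo.best_params, seed, settings.n_estimators)
        m.fit(X.iloc[train], y[train],
              eval_set=[(X.iloc[val], y[val])], eval_metric="binary_logloss",
              callbacks=[lgb.early_stopping(settings.early_stopping_rounds,
                                            verbose=False)])
        boosters.append(m)

    pred = TSPredictor(boosters=boosters, params=bo.best_params,
                       threshold=0.5, youden_j=0.0,
                       feature_columns=list(X.columns), bo_result=bo)
    scores = pred.predict_scores(X)
    pred.threshold, pred.youden_j = select_threshold(scores, y)
    return pred


# ---------------------------------------------------------------------------
# Full MuLT trainer
# ---------------------------------------------------------------------------

def train_mult(cohort: Cohort, seed: int = 0,
               settings: MultSettings | None = None) -> TSPredictor:
    """Fit the complete pipeline on a training cohort with a TS outcome.

    Runs min-max normalization, clinical-marker and gene selection, the
    three extraction branches on the selected genes, and the TSPT ensemble on
    the concatenated G'|C'|L|E|G^d|T block.  Branches that need more selected
    genes than available (fewer than 2 for profiling, 3 for gene clustering,
    4 for the denoiser) are skipped.
    """
    settings = settings or MultSettings()
    if cohort.ts is None:
        raise ContractError("cohort has no TS outcome; derive it first")
    ts = cohort.ts.to_numpy().astype(int)

    raw = pd.concat([cohort.clinical, cohort.expression], axis=1)
    norm = fit_normalizer(raw)
    Fn = norm.transform(raw, clip=False)
    Cn = Fn[cohort.clinical.columns]
    Gn = Fn[cohort.expression.columns]

    cms = select_markers(Cn, ts, settings.alpha, settings.beta)
    gs = select_markers(Gn, ts, settings.alpha, settings.beta)
    G = Gn[gs.selected]

    blocks = [G, Cn[cms.selected]]
    profiler = clusterer = denoiser_model = None
    if len(gs.selected) >= 2:
        o, _ = select_num_clusters(
            G.to_numpy(), max_stall=settings.ncs_max_stall,
            c_max=settings.ncs_c_max, seed=seed, n_init=settings.kmeans_n_init)
        L, profiler = genetic_profiling(G, o, seed)
        blocks.append(L)
    if len(gs.selected) >= 3:
        k, _ = select_num_clusters(
            G.to_numpy().T, max_stall=settings.ncs_max_stall,
            c_max=settings.ncs_c_max, seed=seed, n_init=settings.kmeans_n_init)
        E, clusterer = gene_clustering(G, k, seed)
        blocks.append(E)
    if len(gs.selected) >= 4:
        denoiser_model = train_denoiser(
            G, patience=settings.denoiser_patience, seed=seed,
            max_iter=settings.denoiser_max_iter)
        blocks.append(denoise(denoiser_model, G))

    vocab = sorted(cohort.treatment.unique())
    blocks.append(one_hot_treatment(cohort.treatment, vocab))
    X = pd.concat(blocks, axis=1)

    pred = train_tspt(X, ts, seed=seed, settings=settings)
    pred.normalizer = norm
    pred.clinical_columns = list(cohort.clinical.columns)
    pred.gene_columns = list(cohort.expression.columns)
    pred.selected_clinical = cms.selected
    pred.selected_genes = gs.selected
    pred.profiler = profiler
    pred.gene_clusterer = clusterer
    pred.denoiser = denoiser_model
    pred.treatment_vocab = vocab
    pred.reports = {"clinical": cms, "gene": gs}
    return pred


# ---------------------------------------------------------------------------
# SMLA baseline
# ---------------------------------------------------------------------------

@dataclass
class SMLAPredictor:
    """Marker selection + BO + a single classifier, with the threshold rule."""

    model_name: str
    estimator: object
    report: SelectionReport
    params: dict
    threshold: float
    youden_j: float
    feature_columns: list
    bo_result: BOResult | None = None

    def predict_scores(self, F: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict_proba(F[self.feature_columns])[:, 1]

    def classify(self, F: pd.DataFrame) -> np.ndarray:
        return (self.predict_scores(F) >= self.threshold).astype(int)


def train_smla(F: pd.DataFrame, labels, model: str = "gbt",
               alpha: float = 0.05, beta: float = 0.75, seed: int = 0,
               settings: MultSettings | None = None,
               passthrough: pd.DataFrame | None = None) -> SMLAPredictor:
    """Train the simplified baseline on a normalized feature matrix.

    Steps: marker selection, Bayesian hyperparameter optimization of the
    chosen classifier on a stratified half-split, then a final fit on all
    training data.  ``passthrough`` columns (e.g. the treatment one-hot
    block) bypass selection and are always included.
    """
    settings = settings or MultSettings()
    y = np.asarray(labels).astype(int)
    report = select_markers(F, y, alpha, beta)
    if not report.selected:
        raise DataError(
            "no markers passed selection; consider a larger alpha")
    Xs = F[report.selected]
    if passthrough is not None:
        Xs = pd.concat([Xs, passthrough], axis=1)

    idx = np.arange(len(y))
    half_a, half_b = train_test_split(idx, test_size=0.5, stratify=y,
                                      random_state=seed)

    def objective(params):
        m = make_estimator(model, params, seed, settings.n_estimators)
        m.fit(Xs.iloc[half_a], y[half_a])
        return log_loss(y[half_b], m.predict_proba(Xs.iloc[half_b])[:, 1])

    bo = bayesian_optimize(SPACES[model], objective,
                           n_init=settings.bo_n_init,
                           n_iter=settings.bo_n_iter, seed=seed)
    est = make_estimator(model, bo.best_params, seed, settings.n_estimators)
    est.fit(Xs, y)
    scores = est.predict_proba(Xs)[:, 1]
    thr, j = select_threshold(scores, y)
    return SMLAPredictor(model_name=model, estimator=est, report=report,
                         params=bo.best_params, threshold=thr, youden_j=j,
                         feature_columns=list(Xs.columns), bo_result=bo)
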