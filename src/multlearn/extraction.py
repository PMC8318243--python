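"""Unsupervised and self-supervised feature extraction from selected genes.

Three branches turn the selected-gene matrix G' into extra feature blocks:

* genetic profiling (GP): k-means over patients; features are each patient's
  Euclidean distances to the cluster centroids (matrix L, patients x o);
* gene clustering (GC): k-means over genes (the transposed matrix); features
  are each patient's mean expression per gene cluster (matrix E, patients x k);
* gene denoising (GD): a deep denoising autoencoder reconstructs expression
  from noise-corrupted input; features are the reconstruction G^d.

Cluster counts o and k are chosen by the incremental NCS procedure, which
maximizes a silhouette-based metric SCM(c) = (mean(SC) - sd(SC)) / (sd(cluster
sizes) + 1) and stops after ``max_stall`` candidate counts without a new
maximum.  Both standard deviations are population (divide-by-n) deviations.
All k-means fits use k-means++ with restarts and a fixed seed so traces are
reproducible; trained centroids, gene assignments and autoencoder weights are
persisted so validation patients are projected without refitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .core import ContractError, DataError


# ---------------------------------------------------------------------------
# SCM / NCS
# ---------------------------------------------------------------------------

def scm(cluster_labels, silhouette_values) -> float:
    """Silhouette-coefficient-based metric for one clustering.

    ``(mean(SC) - sd(SC)) / (sd(cluster sizes) + 1)`` with population
    standard deviations; penalizes both silhouette spread and cluster-size
    imbalance.
    """
    labels = np.asarray(cluster_labels)
    sil = np.asarray(silhouette_values, dtype=float)
    if labels.shape != sil.shape:
        raise ContractError("one silhouette value per sample required")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ContractError("silhouette is undefined for a single cluster")
    return float((sil.mean() - sil.std()) / (counts.std() + 1.0))


def _fit_kmeans(X: np.ndarray, c: int, seed: int, n_init: int = 10) -> KMeans:
    return KMeans(n_clusters=c, init="k-means++", n_init=n_init,
                  random_state=seed).fit(X)


def select_num_clusters(X, max_stall: int = 10, c_start: int = 2,
                        c_max: int | None = None, seed: int = 0,
                        n_init: int = 10) -> tuple[int, dict[int, float]]:
    """Choose a cluster count by maximizing SCM over c = c_start, c_start+1, ...

    Stops after ``max_stall`` consecutive counts without a new SCM maximum
    (or at ``c_max`` / the sample-count ceiling).  Returns the argmax count
    and the full SCM trace; ties go to the smallest count.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < c_start + 1:
        raise ContractError(
            f"need at least {c_start + 1} samples, got {n}")
    ceiling = n - 1 if c_max is None else min(c_max, n - 1)

    trace: dict[int, float] = {}
    best_c, best_val, stall = None, -np.inf, 0
    c = c_start
    while c <= ceiling and stall < max_stall:
        km = _fit_kmeans(X, c, seed, n_init)
        labels = km.labels_
        if len(np.unique(labels)) < 2:
            break
        val = scm(labels, silhouette_samples(X, labels, metric="euclidean"))
        trace[c] = val
        if val > best_val:
            best_c, best_val, stall = c, val, 0
        else:
            stall += 1
        c += 1
    if best_c is None:
        raise DataError("no feasible cluster count (degenerate data)")
    return best_c, trace


# ---------------------------------------------------------------------------
# Genetic profiling (patient clusters -> centroid distances L)
# ---------------------------------------------------------------------------

@dataclass
class PatientProfiler:
    """Persisted patient-cluster centroids; projects any patient set to L."""

    centroids: pd.DataFrame = field(default_factory=pd.DataFrame)

    def fit(self, G: pd.DataFrame, o: int, seed: int = 0) -> "PatientProfiler":
        km = _fit_kmeans(G.to_numpy(dtype=float), o, seed)
        self.centroids = pd.DataFrame(km.cluster_centers_, columns=G.columns)
        return self

    def transform(self, G: pd.DataFrame) -> pd.DataFrame:
        if list(G.columns) != list(self.centroids.columns):
            raise ContractError("gene set differs from the profiling fit")
        d = cdist(G.to_numpy(dtype=float), self.centroids.to_numpy())
        return pd.DataFrame(
            d, index=G.index,
            columns=[f"gp_dist_{j}" for j in range(d.shape[1])])


def genetic_profiling(G_prime: pd.DataFrame, o: int,
                      seed: int = 0) -> tuple[pd.DataFrame, PatientProfiler]:
    """Fit patient clusters and return (L, fitted profiler)."""
    model = PatientProfiler().fit(G_prime, o, seed)
    return model.transform(G_prime), model


# ---------------------------------------------------------------------------
# Gene clustering (gene clusters -> per-cluster mean expression E)
# ---------------------------------------------------------------------------

@dataclass
class GeneClusterer:
    """Persisted gene-to-cluster assignment; maps patients to cluster means."""

    assignment: pd.Series = field(default_factory=pd.Series)  # gene -> cluster

    def fit(self, G: pd.DataFrame, k: int, seed: int = 0) -> "GeneClusterer":
        km = _fit_kmeans(G.to_numpy(dtype=float).T, k, seed)
        self.assignment = pd.Series(km.labels_, index=G.columns)
        return self

    def transform(self, G: pd.DataFrame) -> pd.DataFrame:
        if set(G.columns) != set(self.assignment.index):
            raise ContractError("gene set differs from the clustering fit")
        cols = {}
        for j in sorted(self.assignment.unique()):
            genes = self.assignment.index[self.assignment == j]
            if len(genes) == 0:
                warnings.warn(f"gene cluster {j} is empty; column dropped")
                continue
            cols[f"gc_mean_{j}"] = G[list(genes)].mean(axis=1)
        return pd.DataFrame(cols, index=G.index)


def gene_clustering(G_prime: pd.DataFrame, k: int,
                    seed: int = 0) -> tuple[pd.DataFrame, GeneClusterer]:
    """Cluster genes (samples = genes) and return (E, fitted clusterer)."""
    model = GeneClusterer().fit(G_prime, k, seed)
    return model.transform(G_prime), model


# ---------------------------------------------------------------------------
# Gene denoising (deep denoising autoencoder)
# ---------------------------------------------------------------------------

def denoiser_widths(i: int) -> list[int]:
    """Layer widths [i, |0.5i|, |0.4i|, |0.3i|, |0.4i|, |0.5i|, i] (floors)."""
    return [i, int(0.5 * i), int(0.4 * i), int(0.3 * i),
            int(0.4 * i), int(0.5 * i), i]


@dataclass
class DenoiserModel:
    """A trained denoising autoencoder over the selected genes.

    Hidden layers use ReLU, the output layer is linear; training corrupts the
    input with fresh additive N(0, 1) noise every epoch and minimizes the MSE
    between the raw input and the reconstruction, plus an L2 weight penalty,
    using AdaDelta.  ``mse_trace`` records the reconstruction MSE per epoch.
    """

    genes: list[str]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    mse_trace: list[float]
    noise_spec: str = "additive standard normal, resampled each epoch"

    @property
    def widths(self) -> list[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]

    def forward(self, X: np.ndarray) -> np.ndarray:
        h = X
        last = len(self.weights) - 1
        for layer, (W, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ W + b
            if layer < last:
                h = np.maximum(h, 0.0)
        return h


class _AdaDelta:
    """Per-parameter AdaDelta accumulator (Zeiler's rho/eps defaults)."""

    def __init__(self, shapes, rho=0.95, eps=1e-6):
        self.rho, self.eps = rho, eps
        self.eg = [np.zeros(s) for s in shapes]
        self.ed = [np.zeros(s) for s in shapes]

    def step(self, grads):
        deltas = []
        for i, g in enumerate(grads):
            self.eg[i] = self.rho * self.eg[i] + (1 - self.rho) * g * g
            d = -np.sqrt(self.ed[i] + self.eps) / np.sqrt(self.eg[i] + self.eps) * g
            self.ed[i] = self.rho * self.ed[i] + (1 - self.rho) * d * d
            deltas.append(d)
        return deltas


def train_denoiser(G_prime: pd.DataFrame, patience: int = 1000,
                   l2_scale: float = 0.01, seed: int = 0,
                   max_iter: int = 5000) -> DenoiserModel:
    """Train the denoising autoencoder on the selected-gene matrix.

    Stops once ``patience`` consecutive epochs fail to reduce the minimum
    reconstruction MSE, or at ``max_iter`` epochs.  Training is full-batch;
    the same seed reproduces the exact weight trajectory.
    """
    X = G_prime.to_numpy(dtype=float)
    n, i = X.shape
    if n < 2:
        raise ContractError("denoiser training needs at least 2 patients")
    if i < 4:
        raise ContractError(
            f"need at least 4 selected genes for positive layer widths, got {i}")

    widths = denoiser_widths(i)
    rng = np.random.default_rng(seed)
    weights = [rng.normal(0.0, np.sqrt(2.0 / widths[l]),
                          size=(widths[l], widths[l + 1]))
               for l in range(len(widths) - 1)]
    biases = [np.zeros(widths[l + 1]) for l in range(len(widths) - 1)]
    opt = _AdaDelta([w.shape for w in weights] + [b.shape for b in biases])
    n_layers = len(weights)

    best = np.inf
    stall = 0
    trace: list[float] = []
    best_state = None
    for _epoch in range(max_iter):
        noisy = X + rng.standard_normal(X.shape)
        # forward
        acts = [noisy]
        h = noisy
        for layer in range(n_layers):
            z = h @ weights[layer] + biases[layer]
            h = np.maximum(z, 0.0) if layer < n_layers - 1 else z
            acts.append(h)
        out = acts[-1]
        err = out - X
        mse = float(np.mean(err * err))
        if not np.isfinite(mse):
            raise DataError(
                f"denoiser training diverged (non-finite loss); trace={trace[-5:]}")
        trace.append(mse)
        if mse < best:
            best = mse
            stall = 0
            best_state = ([w.copy() for w in weights], [b.copy() for b in biases])
        else:
            stall += 1
            if stall >= patience:
                break
        # backward
        grad = 2.0 * err / err.size
        gw = [None] * n_layers
        gb = [None] * n_layers
        for layer in range(n_layers - 1, -1, -1):
            gw[layer] = acts[layer].T @ grad + 2.0 * l2_scale * weights[layer]
            gb[layer] = grad.sum(axis=0)
            if layer > 0:
                grad = (grad @ weights[layer].T) * (acts[layer] > 0.0)
        deltas = opt.step(gw + gb)
        for layer in range(n_layers):
            weights[layer] += deltas[layer]
            biases[layer] += deltas[n_layers + layer]

    weights, biases = best_state
    return DenoiserModel(genes=list(G_prime.columns), weights=weights,
                         biases=biases, mse_trace=trace)


def denoise(model: DenoiserModel, G_prime: pd.DataFrame) -> pd.DataFrame:
    """Deterministic forward pass on clean inputs; returns G^d."""
    if list(G_prime.columns) != list(model.genes):
        raise ContractError("gene set differs from the denoiser's training set")
    out = model.forward(G_prime.to_numpy(dtype=float))
    return pd.DataFrame(out, index=G_prime.index,
                        columns=[f"gd_{g}" for g in model.genes])
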