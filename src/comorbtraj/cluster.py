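"""PCA and Ward clustering of comorbidities on four model-derived metrics.

Each converged comorbidity contributes a 4-vector: the centered case-vs-
control effect (alpha at the mean follow-up time), its signed -log10
p-value, the trajectory-divergence slope gamma, and its signed -log10
p-value.  The metric matrix is (optionally) z-standardized, rotated by PCA,
and the comorbidities are grouped by agglomerative Ward clustering on
Euclidean distances over all retained principal components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .gee import GeeFit

METRIC_NAMES = ("alpha_centered", "log10p_alpha", "gamma", "log10p_gamma")
P_FLOOR = 1e-300


@dataclass
class MetricMatrix:
    """Comorbidity x 4 metric matrix feeding the multivariate analysis."""

    labels: list[str]
    values: np.ndarray           # (n, 4), columns = METRIC_NAMES
    signed: bool = True
    scaling: pd.DataFrame | None = None   # per-column mean/sd if standardized

    def frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.values, columns=list(METRIC_NAMES))
        out.insert(0, "comorbidity", self.labels)
        return out


@dataclass
class ClusterResult:
    """PC coordinates, Ward tree and cluster labels for the comorbidities."""

    labels: np.ndarray                  # cluster id (1..k) per comorbidity
    comorbidities: list[str]
    k: int
    linkage: np.ndarray                 # scipy linkage matrix (Ward / Euclidean)
    pc_scores: np.ndarray               # (n, n_pcs)
    loadings: np.ndarray                # (n_metrics_kept, n_pcs), orthonormal columns
    variance_explained: np.ndarray      # fractions, descending, sum 1
    metric_matrix: MetricMatrix | None = None
    method: str = "ward (Lance-Williams, squared Euclidean merge cost)"

    def label_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"comorbidity": self.comorbidities, "cluster": self.labels})


def build_metric_matrix(fits: Sequence[GeeFit], signed: bool = True) -> MetricMatrix:
    """Four metrics per converged comorbidity.

    The evidence columns are -log10(p); with ``signed=True`` (default) they
    are multiplied by the sign of the corresponding effect so protective and
    adverse associations separate.  Zero p-values (underflow) are floored at
    1e-300 with a warning.
    """
    labels, rows = [], []
    floored = 0
    for f in fits:
        if not f.converged:
            raise ValueError(f"non-converged fit {f.label!r} must be excluded upstream")
        pa, pg = f.p_alpha_centered, f.p_gamma
        if pa == 0 or pg == 0:
            floored += 1
        pa, pg = max(pa, P_FLOOR), max(pg, P_FLOOR)
        sa = np.sign(f.params[1]) if signed else 1.0
        sg = np.sign(f.params[3]) if signed else 1.0
        labels.append(f.label)
        rows.append([f.params[1], -np.log10(pa) * sa, f.params[3], -np.log10(pg) * sg])
    if floored:
        warnings.warn(f"{floored} comorbidities had p-values of 0; floored at {P_FLOOR}")
    values = np.asarray(rows, float)
    if not np.isfinite(values).all():
        raise ValueError("metric matrix contains non-finite values")
    return MetricMatrix(labels=labels, values=values, signed=signed)


def run_pca(
    matrix: MetricMatrix | np.ndarray, standardize: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[int]]:
    """PCA of the metric matrix.

    Returns ``(scores, loadings, variance_explained, kept_columns)``.  With
    ``standardize=True`` columns are z-scored first (correlation PCA); a
    zero-variance column cannot be z-scored and is dropped with a warning.
    All components are retained, so the variance fractions sum to 1.
    """
    values = matrix.values if isinstance(matrix, MetricMatrix) else np.asarray(matrix, float)
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("PCA needs at least 2 rows and 2 columns")
    kept = list(range(values.shape[1]))
    data = values.astype(float).copy()
    if standardize:
        sd = data.std(axis=0, ddof=1)
        zero = sd == 0
        if zero.any():
            warnings.warn(f"dropping zero-variance columns {np.where(zero)[0].tolist()}")
            kept = [i for i in kept if not zero[i]]
            data = data[:, kept]
            sd = sd[kept]
        data = (data - data.mean(axis=0)) / sd
        if isinstance(matrix, MetricMatrix):
            matrix.scaling = pd.DataFrame(
                {"column": [METRIC_NAMES[i] for i in kept],
                 "mean": values[:, kept].mean(axis=0), "sd": sd}
            )
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(data)
    return scores, pca.components_.T, pca.explained_variance_ratio_, kept


def ward_cluster(pc_scores: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Ward-linkage agglomeration on Euclidean distances; cut at k clusters."""
    n = pc_scores.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must be between 1 and the number of rows ({n})")
    Z = linkage(pc_scores, method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return Z, labels


def _relabel_by_evidence(labels: np.ndarray, evidence: np.ndarray) -> np.ndarray:
    """Renumber clusters by descending median evidence (1 = most divergent)."""
    order = sorted(
        np.unique(labels), key=lambda c: -np.median(evidence[labels == c])
    )
    mapping = {old: new for new, old in enumerate(order, start=1)}
    return np.array([mapping[l] for l in labels])


def cluster_comorbidities(
    fits: Sequence[GeeFit],
    k: int = 5,
    standardize: bool = True,
    signed_logp: bool = True,
) -> ClusterResult:
    """Metric matrix -> PCA -> Ward clustering, with evidence-ordered cluster ids.

    Cluster ids are renumbered so cluster 1 has the largest median
    -log10 p of the trajectory-divergence term gamma.
    """
    matrix = build_metric_matrix(fits, signed=signed_logp)
    scores, loadings, var_ratio, kept = run_pca(matrix, standardize=standardize)
    Z, raw_labels = ward_cluster(scores, k)
    evidence = np.abs(matrix.values[:, 3])   # -log10 p of gamma, magnitude
    labels = _relabel_by_evidence(raw_labels, evidence)
    return ClusterResult(
        labels=labels,
        comorbidities=list(matrix.labels),
        k=k,
        linkage=Z,
        pc_scores=scores,
        loadings=loadings,
        variance_explained=var_ratio,
        metric_matrix=matrix,
    )


def cluster_summary(
    result: ClusterResult,
    fits: Sequence[GeeFit],
    prevalence: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-cluster quantitative summary (counts, metric quartiles, ORs, prevalence)."""
    fit_by_label = {f.label: f for f in fits}
    matrix = result.metric_matrix
    prev_map = {}
    if prevalence is not None:
        prev_map = dict(zip(prevalence["category"], prevalence["overall_frac"]))
    rows = []
    for cid in np.unique(result.labels):
        mask = result.labels == cid
        members = [c for c, m in zip(result.comorbidities, mask) if m]
        sub = matrix.values[mask]
        row = {"cluster": int(cid), "n_comorbidities": int(mask.sum())}
        for j, name in enumerate(METRIC_NAMES):
            row[f"{name}_median"] = float(np.median(sub[:, j]))
            row[f"{name}_q1"] = float(np.percentile(sub[:, j], 25))
            row[f"{name}_q3"] = float(np.percentile(sub[:, j], 75))
        alphas = np.array([fit_by_label[c].params[1] for c in members])
        gammas = np.array([fit_by_label[c].params[3] for c in members])
        row["or_alpha_median"] = float(np.exp(np.median(alphas)))
        row["or_gamma_median"] = float(np.exp(np.median(gammas)))
        if prev_map:
            prevs = [prev_map[c] for c in members if c in prev_map]
            row["mean_prevalence"] = float(np.mean(prevs)) if prevs else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
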