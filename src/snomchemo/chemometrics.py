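"""Latent-variable and discriminant chemometrics.

Implements the multivariate toolbox used on both measurement arms:

* PCA by mean-centred singular value decomposition, with Hotelling T² /
  Q-residual diagnostics and their 95% confidence limits (F-distribution and
  Jackson–Mudholkar limits respectively);
* the classic Kennard–Stone maximin-distance ordering for deterministic
  train / validation / prediction splits;
* nearest-class-mean LDA under the pooled within-class Mahalanobis metric;
* the G cost function (mean ratio of a validation sample's squared Mahalanobis
  distance to its own class mean over the distance to the nearest rival mean);
* PCA-LDA with a validation-chosen number of components, and SPA-LDA variable
  selection by successive orthogonal projections with the G cost.

All estimators are deterministic functions of their inputs; randomness is
confined to the synthetic-data generators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg, stats
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralDataset",
    "PCAModel",
    "DiagnosticResult",
    "SplitAssignment",
    "LDAModel",
    "SPAResult",
    "PCALDAResult",
    "fit_pca",
    "diagnostics",
    "kennard_stone_split",
    "fit_lda",
    "discriminant_scores",
    "predict",
    "g_cost",
    "pca_lda_train",
    "spa_chains",
    "spa_lda_select",
    "confusion_matrix",
]


@dataclass
class SpectralDataset:
    """n samples × p variables with class labels.

    ``variables_axis`` is strictly increasing: wavenumbers in cm⁻¹ for the
    ATR-FTIR arm, spatial positions in μm for stacked image-derived signals.
    """

    variables_axis: np.ndarray
    intensities: np.ndarray
    class_labels: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.variables_axis = np.asarray(self.variables_axis, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        n, p = self.intensities.shape
        if n < 2 or p < 2:
            raise ValueError(f"dataset needs n >= 2 and p >= 2, got {n}x{p}")
        if self.variables_axis.shape != (p,):
            raise ValueError("variables_axis length must equal the number of columns")
        if not (np.diff(self.variables_axis) > 0).all():
            raise ValueError("variables_axis must be strictly increasing")
        if not np.isfinite(self.intensities).all():
            raise ValueError("intensities must be finite")
        if len(self.class_labels) != n or len(self.sample_ids) != n:
            raise ValueError("labels and sample ids must have one entry per sample")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_variables(self) -> int:
        return self.intensities.shape[1]

    @property
    def classes(self) -> list[str]:
        return list(dict.fromkeys(self.class_labels))

    def subset(self, idx: Sequence[int]) -> "SpectralDataset":
        idx = np.asarray(idx, dtype=int)
        return SpectralDataset(
            variables_axis=self.variables_axis,
            intensities=self.intensities[idx],
            class_labels=[self.class_labels[i] for i in idx],
            sample_ids=[self.sample_ids[i] for i in idx],
        )


@dataclass
class PCAModel:
    mean_vector: np.ndarray
    loadings: np.ndarray            # p × A, orthonormal columns
    scores: np.ndarray              # n × A training scores
    explained_variance_pct: np.ndarray
    n_components: int
    n_samples: int
    eigenvalues_all: np.ndarray     # all sample-covariance eigenvalues, descending

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean_vector) @ self.loadings


@dataclass
class DiagnosticResult:
    t2_values: np.ndarray
    q_values: np.ndarray
    t2_limit_95: float
    q_limit_95: float

    def outliers(self) -> np.ndarray:
        """Boolean mask of samples beyond either 95% limit."""
        return (self.t2_values > self.t2_limit_95) | (self.q_values > self.q_limit_95)


@dataclass
class SplitAssignment:
    """Disjoint train / validation / prediction indices, in selection order."""

    train_idx: np.ndarray
    validation_idx: np.ndarray
    prediction_idx: np.ndarray
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)

    def __post_init__(self) -> None:
        parts = [np.asarray(p, dtype=int) for p in
                 (self.train_idx, self.validation_idx, self.prediction_idx)]
        self.train_idx, self.validation_idx, self.prediction_idx = parts
        combined = np.concatenate(parts)
        if len(np.unique(combined)) != len(combined):
            raise ValueError("split index sets overlap")


@dataclass
class LDAModel:
    feature_idx: np.ndarray
    class_means: np.ndarray          # K × d
    pooled_covariance: np.ndarray    # d × d, SPD after regularization
    class_order: list[str]
    _cho: tuple = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self._cho is None:
            self._cho = linalg.cho_factor(self.pooled_covariance, lower=True)


@dataclass
class SPAResult:
    chains: dict[int, list[int]]
    cost_curve: dict[tuple[int, int], float]   # (start variable, subset size) -> G
    selected_variables: tuple[int, ...]
    model: LDAModel
    best_cost: float


@dataclass
class PCALDAResult:
    pca: PCAModel
    lda: LDAModel
    chosen_a: int
    cost_curve: dict[int, float]               # A -> validation cost


# ---------------------------------------------------------------------------
# PCA and diagnostics


def fit_pca(X: np.ndarray, n_components: int) -> PCAModel:
    """Principal component analysis by SVD of the mean-centred data.

    Explained variance percentages are ``100·σ_a²/Σσ²`` over all components.
    Sign convention: each loading column's largest-magnitude element is made
    positive, so outputs are bit-reproducible across runs and platforms.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    rank_bound = min(n - 1, p)
    if not (1 <= n_components <= rank_bound):
        raise ValueError(
            f"n_components must be in [1, {rank_bound}] for a {n}x{p} matrix, "
            f"got {n_components}"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    s = s[:rank_bound]
    Vt = Vt[:rank_bound]
    loadings = Vt[:n_components].T.copy()
    for a in range(n_components):
        j = np.argmax(np.abs(loadings[:, a]))
        if loadings[j, a] < 0:
            loadings[:, a] = -loadings[:, a]
    scores = Xc @ loadings
    total = float((s ** 2).sum())
    if total <= 0:
        raise ValueError("data matrix has zero variance")
    evp = 100.0 * s[:n_components] ** 2 / total
    return PCAModel(
        mean_vector=mean,
        loadings=loadings,
        scores=scores,
        explained_variance_pct=evp,
        n_components=n_components,
        n_samples=n,
        eigenvalues_all=s ** 2 / (n - 1),
    )


def diagnostics(model: PCAModel, X: np.ndarray) -> DiagnosticResult:
    """Hotelling T² and Q residuals with 95% confidence limits.

    T² for sample i is ``Σ_a t_ia²/λ_a`` with λ_a the variance of the training
    scores on component a; Q is the squared norm of the off-model residual.
    The T² limit is ``A(n−1)/(n−A)·F₀.₉₅(A, n−A)``; the Q limit follows the
    Jackson–Mudholkar approximation from the residual eigenvalues.
    """
    X = np.asarray(X, dtype=float)
    n, A = model.n_samples, model.n_components
    if n <= A:
        raise ValueError(f"T2 limit undefined: n={n} <= A={A}")
    if n < 10:
        logger.warning(
            "diagnostics on a small training set (n=%d): 95%% limits are "
            "poorly determined in this regime", n,
        )
    lam = model.scores.var(axis=0, ddof=1)
    T = model.transform(X)
    t2 = (T ** 2 / lam).sum(axis=1)
    resid = (X - model.mean_vector) - T @ model.loadings.T
    q = (resid ** 2).sum(axis=1)

    t2_limit = A * (n - 1) / (n - A) * stats.f.ppf(0.95, A, n - A)

    resid_eig = model.eigenvalues_all[A:]
    resid_eig = resid_eig[resid_eig > 1e-12 * max(model.eigenvalues_all[0], 1e-300)]
    if resid_eig.size == 0:
        # full-rank model: no residual space, limit degenerates to ~0
        q_limit = float(np.finfo(float).eps)
    else:
        th1 = float(resid_eig.sum())
        th2 = float((resid_eig ** 2).sum())
        th3 = float((resid_eig ** 3).sum())
        h0 = 1.0 - 2.0 * th1 * th3 / (3.0 * th2 ** 2)
        if h0 <= 0:
            h0 = 1e-3
            logger.warning("Jackson-Mudholkar h0 <= 0; clamped for limit computation")
        z = stats.norm.ppf(0.95)
        q_limit = th1 * (
            z * np.sqrt(2.0 * th2 * h0 ** 2) / th1
            + 1.0
            + th2 * h0 * (h0 - 1.0) / th1 ** 2
        ) ** (1.0 / h0)
        q_limit = float(max(q_limit, np.finfo(float).eps))
    return DiagnosticResult(
        t2_values=t2, q_values=q, t2_limit_95=float(t2_limit), q_limit_95=q_limit
    )


# ---------------------------------------------------------------------------
# Kennard–Stone


def kennard_stone_split(
    X: np.ndarray, fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
) -> SplitAssignment:
    """Classic Kennard–Stone maximin ordering → train/validation/prediction.

    The first two samples are the pair at maximal Euclidean distance; each
    subsequent sample maximizes its minimum distance to the already-selected
    set.  Ties break to the lowest sample index.  The first ``round(f_tr·n)``
    samples in KS order form the training set, the next ``round(f_val·n)`` the
    validation set, and the remainder the prediction set (train rounded first,
    then validation; prediction absorbs the remainder).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("Kennard-Stone needs at least 3 samples")
    f = np.asarray(fractions, dtype=float)
    if (f <= 0).any() or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")

    D = cdist(X, X, metric="sqeuclidean")
    np.fill_diagonal(D, -1.0)  # a sample never pairs with itself
    start = int(np.argmax(D))  # row-major argmax → lowest (i, j) among ties
    i, j = divmod(start, n)
    if D[i, j] <= 0.0:
        logger.warning("all pairwise distances are zero; ties broken by index")
    order = [i, j]
    selected = np.zeros(n, dtype=bool)
    selected[[i, j]] = True
    min_d = np.minimum(D[i], D[j])
    for _ in range(n - 2):
        cand = np.where(selected, -1.0, min_d)
        nxt = int(np.argmax(cand))  # first occurrence → lowest index on ties
        order.append(nxt)
        selected[nxt] = True
        min_d = np.minimum(min_d, D[nxt])

    n_train = int(np.floor(f[0] * n + 0.5))
    n_val = int(np.floor(f[1] * n + 0.5))
    n_val = min(n_val, n - n_train)
    order_arr = np.asarray(order, dtype=int)
    return SplitAssignment(
        train_idx=order_arr[:n_train],
        validation_idx=order_arr[n_train : n_train + n_val],
        prediction_idx=order_arr[n_train + n_val :],
        fractions=tuple(f),
    )


# ---------------------------------------------------------------------------
# LDA with the pooled Mahalanobis metric


def fit_lda(
    X: np.ndarray,
    labels: Sequence[str],
    *,
    class_order: Sequence[str] | None = None,
    feature_idx: Sequence[int] | None = None,
) -> LDAModel:
    """Nearest-class-mean LDA under the pooled within-class covariance.

    The pooled covariance uses divisor ``n − K``.  When its smallest
    eigenvalue falls below ``1e-10·trace/d`` a ridge of ``1e-8·trace/d`` is
    added to the diagonal (logged), keeping the metric positive definite in
    the nearly singular regimes that full-spectrum data produce.
    """
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    n, d = X.shape
    if class_order is None:
        class_order = list(dict.fromkeys(labels))
    else:
        class_order = list(class_order)
    K = len(class_order)
    if K < 2:
        raise ValueError("LDA needs at least two classes")
    means = np.empty((K, d))
    scatter = np.zeros((d, d))
    for k, cls in enumerate(class_order):
        rows = X[[i for i, lab in enumerate(labels) if lab == cls]]
        if rows.shape[0] < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 training samples")
        means[k] = rows.mean(axis=0)
        dev = rows - means[k]
        scatter += dev.T @ dev
    cov = scatter / (n - K)
    cov = 0.5 * (cov + cov.T)
    tr_d = np.trace(cov) / d
    if tr_d <= 0:
        tr_d = 1.0
    if np.linalg.eigvalsh(cov).min() < 1e-10 * tr_d:
        logger.info("pooled covariance near-singular; ridge %.3e added", 1e-8 * tr_d)
        cov = cov + 1e-8 * tr_d * np.eye(d)
    return LDAModel(
        feature_idx=np.asarray(
            feature_idx if feature_idx is not None else np.arange(d), dtype=int
        ),
        class_means=means,
        pooled_covariance=cov,
        class_order=class_order,
    )


def discriminant_scores(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Squared Mahalanobis distance of each sample to each class mean (n × K)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.class_means.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: model has {model.class_means.shape[1]}, "
            f"data has {X.shape[1]}"
        )
    out = np.empty((X.shape[0], model.class_means.shape[0]))
    for k in range(model.class_means.shape[0]):
        diff = (X - model.class_means[k]).T          # d × n
        sol = linalg.cho_solve(model._cho, diff)
        out[:, k] = (diff * sol).sum(axis=0)
    return out


def predict(model: LDAModel, X: np.ndarray) -> list[str]:
    """Assign each sample to the nearest class mean; ties go to the lowest
    class index and are logged."""
    D = discriminant_scores(model, X)
    idx = np.argmin(D, axis=1)
    ties = (D == D[np.arange(len(idx)), idx][:, None]).sum(axis=1) > 1
    if ties.any():
        logger.info("%d tied discriminant scores resolved to the lowest class index",
                    int(ties.sum()))
    return [model.class_order[k] for k in idx]


def g_cost(model: LDAModel, X_val: np.ndarray, val_labels: Sequence[str]) -> float:
    """Validation cost G: mean over samples of
    ``r²(x, m_own) / min_{rival} r²(x, m_rival)`` under the pooled metric.

    A sample exactly at its own class mean contributes 0; a sample at a rival
    mean (but not its own) contributes +inf.
    """
    val_labels = list(val_labels)
    missing = set(val_labels) - set(model.class_order)
    if missing:
        raise ValueError(f"validation classes absent from training: {sorted(missing)}")
    D = discriminant_scores(model, X_val)
    own_idx = np.array([model.class_order.index(lab) for lab in val_labels])
    own = D[np.arange(len(val_labels)), own_idx]
    rival_d = D.copy()
    rival_d[np.arange(len(val_labels)), own_idx] = np.inf
    rival = rival_d.min(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(own == 0.0, 0.0, own / rival)
    return float(g.mean())


# ---------------------------------------------------------------------------
# PCA-LDA


def pca_lda_train(
    dataset: SpectralDataset,
    split: SplitAssignment,
    max_a: int,
    *,
    criterion: str = "g",
) -> PCALDAResult:
    """PCA compression + LDA, with the component count chosen on validation.

    For each candidate A in 1..max_a the PCA is fit on the training block, an
    LDA on the training scores, and the validation cost evaluated — the G
    function by default, or ``1 − accuracy`` with ``criterion='accuracy'``.
    Ties prefer the smallest A; the returned models are refit at the choice.
    """
    if max_a < 1:
        raise ValueError("max_a must be >= 1")
    if criterion not in ("g", "accuracy"):
        raise ValueError("criterion must be 'g' or 'accuracy'")
    Xtr = dataset.intensities[split.train_idx]
    ytr = [dataset.class_labels[i] for i in split.train_idx]
    Xval = dataset.intensities[split.validation_idx]
    yval = [dataset.class_labels[i] for i in split.validation_idx]
    cap = min(Xtr.shape[0] - 1, dataset.n_variables)
    if max_a > cap:
        raise ValueError(f"max_a={max_a} exceeds the rank bound {cap}")

    curve: dict[int, float] = {}
    best_a, best_cost = None, np.inf
    for a in range(1, max_a + 1):
        pca = fit_pca(Xtr, a)
        lda = fit_lda(pca.transform(Xtr), ytr, class_order=dataset.classes)
        if criterion == "g":
            cost = g_cost(lda, pca.transform(Xval), yval)
        else:
            pred = predict(lda, pca.transform(Xval))
            cost = 1.0 - float(np.mean([p == t for p, t in zip(pred, yval)]))
        curve[a] = cost
        if cost < best_cost:  # strict < keeps the smallest A on ties
            best_a, best_cost = a, cost
    pca = fit_pca(Xtr, best_a)
    lda = fit_lda(pca.transform(Xtr), ytr, class_order=dataset.classes)
    logger.info("PCA-LDA: chose A=%d (validation %s cost %.4g)",
                best_a, criterion, best_cost)
    return PCALDAResult(pca=pca, lda=lda, chosen_a=best_a, cost_curve=curve)


# ---------------------------------------------------------------------------
# SPA-LDA


def spa_chains(
    X_train: np.ndarray, max_len: int, *, rel_tol: float = 1e-10
) -> dict[int, list[int]]:
    """Successive-projections chains from every viable starting variable.

    Columns are taken from the mean-centred training matrix.  From start k the
    next variable is always the one whose column has maximal norm after
    orthogonal projection onto the complement of the span of the selected
    columns; columns whose residual norm falls below ``rel_tol`` of the
    largest original norm are treated as dependent and never appended.
    Zero-variance starting columns are skipped (logged).
    """
    X = np.asarray(X_train, dtype=float)
    n, p = X.shape
    if not (1 <= max_len <= min(p, n - 1)):
        raise ValueError(f"max_len must be in [1, {min(p, n - 1)}]")
    Xc = X - X.mean(axis=0)
    norms0 = np.linalg.norm(Xc, axis=0)
    tol = rel_tol * max(norms0.max(), 1e-300)
    chains: dict[int, list[int]] = {}
    for start in range(p):
        if norms0[start] <= tol:
            logger.info("SPA: start variable %d has zero variance; chain skipped", start)
            continue
        R = Xc.copy()
        chain = [start]
        in_chain = np.zeros(p, dtype=bool)
        in_chain[start] = True
        current = start
        while len(chain) < max_len:
            q = R[:, current] / np.linalg.norm(R[:, current])
            R = R - np.outer(q, q @ R)
            res_norms = np.linalg.norm(R, axis=0)
            res_norms[in_chain] = -1.0
            res_norms[res_norms <= tol] = -1.0
            nxt = int(np.argmax(res_norms))
            if res_norms[nxt] < 0:
                break
            chain.append(nxt)
            in_chain[nxt] = True
            current = nxt
        chains[start] = chain
    if not chains:
        raise ValueError("all starting variables are degenerate")
    return chains


def spa_lda_select(
    dataset: SpectralDataset,
    split: SplitAssignment,
    max_len: int | None = None,
) -> SPAResult:
    """SPA-LDA variable selection: minimize the validation G over every prefix
    of every successive-projections chain.

    Ties prefer fewer variables, then the lexicographically smallest sorted
    index tuple.  The returned LDA is refit on the training block at the
    selected variables.
    """
    Xtr = dataset.intensities[split.train_idx]
    ytr = [dataset.class_labels[i] for i in split.train_idx]
    Xval = dataset.intensities[split.validation_idx]
    yval = [dataset.class_labels[i] for i in split.validation_idx]
    n_tr = Xtr.shape[0]
    K = len(set(ytr))
    cap = min(dataset.n_variables, n_tr - K - 1)
    if cap < 1:
        raise ValueError("training set too small for SPA-LDA")
    max_len = cap if max_len is None else min(max_len, cap)

    chains = spa_chains(Xtr, max_len)
    cost_curve: dict[tuple[int, int], float] = {}
    best: tuple[float, int, tuple[int, ...]] | None = None
    for start, chain in chains.items():
        for size in range(1, len(chain) + 1):
            vars_ = tuple(chain[:size])
            lda = fit_lda(Xtr[:, vars_], ytr, class_order=dataset.classes,
                          feature_idx=vars_)
            g = g_cost(lda, Xval[:, vars_], yval)
            cost_curve[(start, size)] = g
            key = (g, size, tuple(sorted(vars_)))
            if best is None or key < best:
                best = key
    best_g, _, selected = best
    model = fit_lda(Xtr[:, selected], ytr, class_order=dataset.classes,
                    feature_idx=selected)
    logger.info("SPA-LDA: selected %d variables (validation G=%.4g)",
                len(selected), best_g)
    return SPAResult(
        chains=chains,
        cost_curve=cost_curve,
        selected_variables=selected,
        model=model,
        best_cost=best_g,
    )


def confusion_matrix(
    true_labels: Sequence[str], pred_labels: Sequence[str], class_order: Sequence[str]
) -> np.ndarray:
    """K × K count matrix, rows = true class, columns = predicted class."""
    idx = {c: k for k, c in enumerate(class_order)}
    M = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(true_labels, pred_labels):
        M[idx[t], idx[p]] += 1
    return M
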