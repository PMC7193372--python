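"""O-PLS metabolite association with cross-validated Q2Y and permutation p.

Orthogonal projection to latent structures (O-PLS) regresses a single
response y (here: the relative abundance of a gene function) on a
metabolite matrix X while separating y-predictive variation from
y-orthogonal variation.  The fitter follows the standard single-y
construction: w is proportional to X'y (normalised); for each
orthogonal component, w_o is proportional to p - (w'p) w, t_o = X w_o,
and X is deflated by t_o p_o'; because t_o'y = 0 by construction, the
predictive weight vector is unchanged by deflation and stays orthogonal
to every w_o.

Model quality is summarised by the training R2Y, a k-fold
cross-validated Q2Y = 1 - PRESS/TSS (scaling and centering re-estimated
inside each training fold), and a permutation p-value for Q2Y with the
add-one convention p = (1 + #{Q2_perm >= Q2_obs}) / (n_perm + 1).

Preprocessing helpers: probabilistic quotient normalization (PQN) for
dilution correction of fecal spectra, and unit-variance (UV) scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import bh_adjust

Matrix = Union[np.ndarray, pd.DataFrame]


@dataclass(frozen=True)
class CorrelationRecord:
    """Feature-level association with the model driver."""

    feature: str
    r: float
    p: float
    q: float


@dataclass
class Scaler:
    """Column means/SDs of a training matrix (SD with denominator n-1)."""

    means: np.ndarray
    sds: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.means) / self.sds

    def inverse(self, X: np.ndarray) -> np.ndarray:
        return X * self.sds + self.means


@dataclass
class OplsModel:
    """Fitted O-PLS model with one predictive component.

    ``w`` is the unit-norm predictive weight vector, ``t = X w`` the
    predictive scores and ``b`` the inner regression coefficient of y on
    t.  ``W_o`` / ``P_o`` / ``T_o`` hold the orthogonal components
    column-wise (possibly zero columns).  ``w' W_o = 0`` and the columns
    of ``T_o`` are pairwise orthogonal by construction.
    """

    w: np.ndarray
    p: np.ndarray
    t: np.ndarray
    W_o: np.ndarray
    P_o: np.ndarray
    T_o: np.ndarray
    b: float
    r2y: float
    q2y: Optional[float] = None
    permutation_p: Optional[float] = None

    @property
    def n_ortho(self) -> int:
        return self.W_o.shape[1]

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Predictive scores of new (already scaled) rows.

        Orthogonal variation is filtered out of the new data exactly as
        during fitting before projecting onto ``w``.
        """
        Xf = np.asarray(X, dtype=float).copy()
        for k in range(self.n_ortho):
            t_o = Xf @ self.W_o[:, k]
            Xf -= np.outer(t_o, self.P_o[:, k])
        return Xf @ self.w

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted (centered) response for new scaled rows."""
        return self.b * self.predict_scores(X)


def _values(X: Matrix) -> np.ndarray:
    return X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)


def pqn_normalize(X: Matrix) -> Tuple[Matrix, np.ndarray]:
    """Probabilistic quotient normalization across samples (rows).

    The reference spectrum is the feature-wise median over samples; each
    sample is divided by the median of its feature-wise quotients
    against the reference.  Non-positive values (and features whose
    reference is non-positive) are excluded from the quotient
    computation but still rescaled by the sample's factor.  Returns the
    normalised matrix and the per-sample dilution factors.
    """
    values = _values(X)
    if values.ndim != 2 or values.size == 0:
        raise ValueError("X must be a non-empty 2-D matrix")
    if np.isnan(values).any():
        raise ValueError("X contains missing values")
    reference = np.median(values, axis=0)
    factors = np.empty(values.shape[0])
    sample_ids = list(X.index) if isinstance(X, pd.DataFrame) else list(range(values.shape[0]))
    for i, row in enumerate(values):
        eligible = (row > 0) & (reference > 0)
        if not eligible.any():
            raise ValueError(
                f"sample {sample_ids[i]!r} has no positive features usable for PQN quotients"
            )
        factors[i] = np.median(row[eligible] / reference[eligible])
    out = values / factors[:, None]
    if isinstance(X, pd.DataFrame):
        out = pd.DataFrame(out, index=X.index, columns=X.columns)
    return out, factors


def uv_scale(X: Matrix) -> Tuple[Matrix, Scaler]:
    """Unit-variance scale columns to mean 0, SD 1 (denominator n-1)."""
    values = _values(X)
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        names = (
            [X.columns[i] for i in zero] if isinstance(X, pd.DataFrame) else list(map(int, zero))
        )
        raise ValueError(f"zero-variance features cannot be UV-scaled: {names}")
    out = (values - means) / sds
    if isinstance(X, pd.DataFrame):
        out = pd.DataFrame(out, index=X.index, columns=X.columns)
    return out, Scaler(means=means, sds=sds)


def fit_opls(X: Matrix, y: Sequence[float], n_ortho: int = 1) -> OplsModel:
    """Fit an O-PLS model with one predictive and ``n_ortho`` orthogonal parts.

    ``X`` should already be scaled and ``y`` centered; ``y`` is centered
    defensively if its mean is nonzero.
    """
    Xd = _values(X).copy()
    y = np.asarray(y, dtype=float)
    y = y - y.mean()
    n, m = Xd.shape
    if n <= n_ortho + 1:
        raise ValueError("need n_samples > n_ortho + 1")
    if not y.any():
        raise ValueError("y has zero variance")
    if not Xd.any():
        raise ValueError("X is degenerate (all zero)")

    W_o, P_o, T_o = [], [], []
    for _ in range(n_ortho):
        w = Xd.T @ y
        w /= np.linalg.norm(w)
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:  # no y-orthogonal variation left
            break
        w_o /= norm
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd -= np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)

    w = Xd.T @ y
    w /= np.linalg.norm(w)
    t = Xd @ w
    p = Xd.T @ t / (t @ t)
    b = float(t @ y / (t @ t))
    residual = y - b * t
    r2y = 1.0 - float(residual @ residual) / float(y @ y)

    stack = lambda vs: np.column_stack(vs) if vs else np.empty((m, 0))
    return OplsModel(
        w=w,
        p=p,
        t=t,
        W_o=stack(W_o),
        P_o=stack(P_o),
        T_o=np.column_stack(T_o) if T_o else np.empty((n, 0)),
        b=b,
        r2y=r2y,
    )


def q2_cross_validate(
    X: Matrix,
    y: Sequence[float],
    k: int = 7,
    n_ortho: int = 1,
    seed: int = 0,
) -> float:
    """k-fold cross-validated Q2Y = 1 - PRESS/TSS on raw (unscaled) inputs.

    Folds are a deterministic seeded shuffle of the samples.  UV scaling
    of X and centering of y are re-estimated inside each training fold;
    test predictions are brought back to the original y scale with the
    training-fold mean.
    """
    values = _values(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k < 2:
        raise ValueError("need at least 2 folds")
    if n < 2 * k:
        raise ValueError(f"need n_samples >= 2k (= {2 * k}) for {k}-fold CV")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    for fold in folds:
        if len(fold) < 2:
            raise ValueError("every fold must contain at least 2 samples")

    press = 0.0
    for fold in folds:
        train = np.setdiff1d(order, fold)
        X_train, scaler = uv_scale(values[train])
        y_mean = y[train].mean()
        model = fit_opls(X_train, y[train] - y_mean, n_ortho=n_ortho)
        pred = model.predict(scaler.transform(values[fold])) + y_mean
        press += float(np.sum((y[fold] - pred) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / tss


def permutation_validate(
    X: Matrix,
    y: Sequence[float],
    n_perm: int = 1000,
    seed: int = 0,
    *,
    k: int = 7,
    n_ortho: int = 1,
) -> Tuple[float, float, np.ndarray]:
    """Permutation test of the cross-validated Q2Y.

    Returns ``(permutation_p, observed_q2, null_q2s)`` with
    ``p = (1 + #{null >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y, dtype=float)
    observed = q2_cross_validate(X, y, k=k, n_ortho=n_ortho, seed=seed)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = q2_cross_validate(X, rng.permutation(y), k=k, n_ortho=n_ortho, seed=seed)
    p = (1.0 + float(np.sum(null >= observed))) / (n_perm + 1.0)
    return p, observed, null


def feature_correlations(
    X: Matrix,
    driver: Sequence[float],
    feature_names: Optional[Sequence[str]] = None,
) -> List[CorrelationRecord]:
    """Pearson correlation of every feature with the driver, BH-adjusted.

    The driver is typically the model's predictive scores t (or the raw
    response y).  Constant features are reported as r = 0, p = 1 with a
    warning.  p-values come from the exact t-distribution with n - 2
    degrees of freedom.
    """
    values = _values(X)
    driver = np.asarray(driver, dtype=float)
    n = values.shape[0]
    if len(driver) != n:
        raise ValueError("driver length must equal the number of samples")
    if feature_names is None:
        feature_names = (
            list(X.columns) if isinstance(X, pd.DataFrame) else [f"f{j}" for j in range(values.shape[1])]
        )

    xc = values - values.mean(axis=0)
    dc = driver - driver.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sd = np.sqrt((dc**2).sum())
    if sd == 0:
        raise ValueError("driver is constant")
    constant = sx == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) reported as r=0, p=1", stacklevel=2
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc.T @ dc) / (sx * sd)
    r = np.clip(np.where(constant, 0.0, r), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(constant, 1.0, p)
    q = bh_adjust(p)
    return [
        CorrelationRecord(feature=str(f), r=float(ri), p=float(pi), q=float(qi))
        for f, ri, pi, qi in zip(feature_names, r, p, q)
    ]


def correlation_frame(records: Sequence[CorrelationRecord]) -> pd.DataFrame:
    """Tabular view of correlation records (feature, r, p, q)."""
    return pd.DataFrame(
        [(c.feature, c.r, c.p, c.q) for c in records], columns=["feature", "r", "p", "q"]
    )
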