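"""State-space Granger causality on pooled multi-session VAR models.

A VAR(p) fitted jointly to all of a subject's sessions is rewritten in
innovations state-space form; for each source node the "reduced" model
that no longer observes the source is obtained by solving a discrete
algebraic Riccati equation (DARE) for the reduced innovations covariance,
and the Granger strength toward every remaining node i is

    F(source -> i | rest) = ln( V^R_ii / V_ii ),

the log-ratio of reduced to full innovations variances. One DARE per
source therefore serves all targets, and no model is ever refitted.
Conditioning on all remaining nodes is the default; an unconditional
bivariate mode is available.

Matrix orientation throughout: entry ``[source, target]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla

_NEG_CLIP = 1e-10


@dataclass
class VARModel:
    """Vector autoregression of order p with pooled-session residual cov."""

    order: int
    coefs: np.ndarray          # (p, N, N); coefs[k] multiplies lag k+1
    sigma: np.ndarray          # (N, N) residual covariance (dof-corrected)
    nobs: int                  # stacked regression rows used
    stable: bool = True

    @property
    def n_nodes(self) -> int:
        return self.coefs.shape[1]

    def companion(self) -> np.ndarray:
        p, N, _ = self.coefs.shape
        A = np.zeros((N * p, N * p))
        A[:N, :] = np.hstack(list(self.coefs))
        if p > 1:
            A[N:, : N * (p - 1)] = np.eye(N * (p - 1))
        return A

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion()))))


@dataclass
class StateSpaceModel:
    """Innovations-form state space of a VAR: x+ = A x + K e, y = C x + e."""

    A: np.ndarray              # (m, m) state transition (companion)
    C: np.ndarray              # (N, m) observation
    K: np.ndarray              # (m, N) Kalman gain
    V: np.ndarray              # (N, N) innovations covariance

    @property
    def n_nodes(self) -> int:
        return self.C.shape[0]

    def autocovariance(self, max_lag: int) -> np.ndarray:
        """Process autocovariances Gamma_0..Gamma_max_lag via the state recursion."""
        P = sla.solve_discrete_lyapunov(self.A, self.K @ self.V @ self.K.T)
        out = np.empty((max_lag + 1, self.n_nodes, self.n_nodes))
        out[0] = self.C @ P @ self.C.T + self.V
        M = self.A @ P @ self.C.T + self.K @ self.V
        Ah = np.eye(self.A.shape[0])
        for h in range(1, max_lag + 1):
            out[h] = self.C @ Ah @ M
            Ah = self.A @ Ah
        return out


@dataclass
class GCMatrix:
    """Directed connection strengths; entry [source, target] = F(s -> t)."""

    values: np.ndarray
    labels: list[str]
    n_failures: int = 0
    n_clipped: int = 0

    def dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path, comment: str | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("# rows = source, columns = target\n")
            if comment:
                fh.write(f"# {comment}\n")
            self.dataframe().to_csv(fh)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GCMatrix":
        df = pd.read_csv(path, comment="#", index_col=0)
        return cls(df.to_numpy(float), [str(c) for c in df.columns])


# ---------------------------------------------------------------------------
# Pooled VAR estimation
# ---------------------------------------------------------------------------


def _pooled_design(sessions: Sequence[np.ndarray], p: int):
    """Lag-stacked (X, Y) with no row spanning a session boundary."""
    Xs, Ys = [], []
    for arr in sessions:
        arr = np.asarray(arr, dtype=float)
        arr = arr - arr.mean(axis=0, keepdims=True)
        T, N = arr.shape
        if T <= p:
            continue
        Y = arr[p:]
        X = np.hstack([arr[p - k : T - k] for k in range(1, p + 1)])
        Xs.append(X)
        Ys.append(Y)
    if not Xs:
        raise ValueError("no session long enough for the requested order")
    return np.vstack(Xs), np.vstack(Ys)


def _fit_at_order(sessions, p: int):
    X, Y = _pooled_design(sessions, p)
    B, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ B
    return B, resid, X.shape[0]


def _select_order(sessions, criterion: str, p_max: int) -> int:
    """AIC/BIC over 1..p_max on a common sample (first p_max rows dropped)."""
    N = np.asarray(sessions[0]).shape[1]
    X, Y = _pooled_design(sessions, p_max)
    rows = X.shape[0]
    best_p, best_val = 1, np.inf
    for p in range(1, p_max + 1):
        Xp = X[:, : N * p]
        B, _, _, _ = np.linalg.lstsq(Xp, Y, rcond=None)
        resid = Y - Xp @ B
        sigma_ml = resid.T @ resid / rows
        sign, logdet = np.linalg.slogdet(sigma_ml)
        if sign <= 0:
            continue
        k = p * N * N
        if criterion == "aic":
            val = logdet + 2.0 * k / rows
        elif criterion == "bic":
            val = logdet + np.log(rows) * k / rows
        else:
            raise ValueError(f"unknown order criterion {criterion!r}")
        if val < best_val:
            best_p, best_val = p, val
    return best_p


def fit_var_pooled(
    sessions: Sequence[np.ndarray],
    order: int | str = "aic",
    p_max: int = 20,
) -> VARModel:
    """Least-squares VAR fit pooling several sessions of one subject.

    Predictor/target rows from all sessions are stacked into one normal-
    equation system with no row spanning a session boundary; each session
    is de-meaned first. ``order`` is an integer, or ``"aic"``/``"bic"``
    to select p in 1..p_max on a common sample. The residual covariance
    carries a degrees-of-freedom correction. An unstable fitted model
    triggers a warning but is still returned.
    """
    if len(sessions) == 0:
        raise ValueError("at least one session is required")
    N = np.asarray(sessions[0]).shape[1]
    if isinstance(order, str):
        p = _select_order(sessions, order.lower(), p_max)
    else:
        p = int(order)
        if p < 1:
            raise ValueError("order must be >= 1")
    B, resid, rows = _fit_at_order(sessions, p)
    if rows < 5 * N * p:
        raise ValueError(
            f"insufficient data: {rows} stacked rows < {5 * N * p} "
            f"(5 x N x p) for N={N}, p={p}"
        )
    dof = rows - N * p
    sigma = resid.T @ resid / dof
    coefs = np.stack([B[k * N : (k + 1) * N, :].T for k in range(p)])
    model = VARModel(order=p, coefs=coefs, sigma=sigma, nobs=rows)
    if model.spectral_radius() >= 1.0:
        model.stable = False
        warnings.warn("fitted VAR is unstable (spectral radius >= 1)",
                      RuntimeWarning, stacklevel=2)
    return model


# ---------------------------------------------------------------------------
# State-space conversion and GC
# ---------------------------------------------------------------------------


def var_to_state_space(var: VARModel) -> StateSpaceModel:
    """Companion-form innovations representation of a stable VAR.

    State ``x_t = [y_{t-1}; ...; y_{t-p}]`` gives ``y_t = C x_t + e_t`` with
    ``C = [A_1 ... A_p]``, transition equal to the companion matrix,
    ``K = [I; 0]`` and innovations covariance ``V = Sigma`` exactly.
    """
    if var.spectral_radius() >= 1.0:
        raise ValueError("cannot build state space from an unstable VAR")
    p, N, _ = var.coefs.shape
    A = var.companion()
    C = np.hstack(list(var.coefs))
    K = np.zeros((N * p, N))
    K[:N, :] = np.eye(N)
    return StateSpaceModel(A=A, C=C, K=K, V=var.sigma.copy())


def _reduced_innovations(ss: StateSpaceModel, keep: Sequence[int]) -> np.ndarray:
    """Innovations covariance of the sub-process observing only ``keep``.

    Solves the filtering DARE of the reduced observation model (state noise
    K V K', observation noise V[keep, keep], cross-covariance K V[:, keep]).
    Falls back to the Riccati fixed-point iteration if the Schur solver
    fails on the rank-deficient state-noise structure.
    """
    keep = list(keep)
    C = ss.C[keep]
    R = ss.V[np.ix_(keep, keep)]
    Q = ss.K @ ss.V @ ss.K.T
    S = ss.K @ ss.V[:, keep]
    A = ss.A
    try:
        P = sla.solve_discrete_are(A.T, C.T, Q, R, s=S)
    except (np.linalg.LinAlgError, ValueError):
        P = _riccati_iteration(A, C, Q, R, S)
    return C @ P @ C.T + R


def _riccati_iteration(A, C, Q, R, S, tol: float = 1e-12, max_iter: int = 500):
    P = Q.copy()
    for _ in range(max_iter):
        G = A @ P @ C.T + S
        Pn = A @ P @ A.T + Q - G @ np.linalg.solve(C @ P @ C.T + R, G.T)
        Pn = (Pn + Pn.T) / 2
        if np.max(np.abs(Pn - P)) < tol * max(1.0, np.max(np.abs(P))):
            return Pn
        P = Pn
    raise np.linalg.LinAlgError("Riccati iteration did not converge")


def gc_from_source(ss: StateSpaceModel, source: int) -> np.ndarray:
    """``F(source -> i | all others)`` for every other node i.

    Returns a length-(N-1) vector ordered by remaining node index. Raises
    ``numpy.linalg.LinAlgError`` on DARE failure (callers record NaN).
    """
    N = ss.n_nodes
    keep = [i for i in range(N) if i != source]
    Vr = _reduced_innovations(ss, keep)
    F = np.log(np.diag(Vr) / np.diag(ss.V)[keep])
    return F


def gc_matrix(
    sessions: Sequence[np.ndarray],
    order: int | str = "aic",
    p_max: int = 20,
    mode: str = "conditional",
    labels: list[str] | None = None,
) -> GCMatrix:
    """Full directed-connectivity matrix for one subject.

    Pipeline: pooled VAR fit -> innovations state space -> one reduced-model
    DARE per source (``mode="conditional"``, conditioning on all remaining
    nodes) or per pair (``mode="bivariate"``, unconditional). Entry
    ``[source, target]``; diagonal fixed at 0; per-source DARE failures
    yield NaN rows and are counted, tiny negative values are clipped to 0.
    """
    N = np.asarray(sessions[0]).shape[1]
    if labels is None:
        labels = [f"n{i:03d}" for i in range(N)]
    if N == 1:
        return GCMatrix(np.zeros((1, 1)), labels)
    var = fit_var_pooled(sessions, order=order, p_max=p_max)
    ss = var_to_state_space(var)
    return gc_matrix_from_model(ss, mode=mode, labels=labels)


def gc_matrix_from_model(
    ss: StateSpaceModel, mode: str = "conditional", labels: list[str] | None = None
) -> GCMatrix:
    """GC matrix from an already-built state-space model (true or estimated)."""
    N = ss.n_nodes
    if labels is None:
        labels = [f"n{i:03d}" for i in range(N)]
    F = np.zeros((N, N))
    failures = 0
    if mode == "conditional":
        for src in range(N):
            keep = [i for i in range(N) if i != src]
            try:
                F[src, keep] = gc_from_source(ss, src)
            except np.linalg.LinAlgError:
                F[src, keep] = np.nan
                failures += 1
    elif mode == "bivariate":
        own = np.empty(N)
        for i in range(N):
            try:
                own[i] = _reduced_innovations(ss, [i])[0, 0]
            except np.linalg.LinAlgError:
                own[i] = np.nan
                failures += 1
        for i in range(N):
            for j in range(i + 1, N):
                try:
                    Vp = _reduced_innovations(ss, [i, j])
                    F[j, i] = np.log(own[i] / Vp[0, 0])
                    F[i, j] = np.log(own[j] / Vp[1, 1])
                except np.linalg.LinAlgError:
                    F[j, i] = F[i, j] = np.nan
                    failures += 1
    else:
        raise ValueError(f"unknown GC mode {mode!r}")
    np.fill_diagonal(F, 0.0)
    neg = F < 0
    n_clipped = int(np.sum(neg & np.isfinite(F)))
    F[neg & (F > -_NEG_CLIP)] = 0.0
    F[neg & (F <= -_NEG_CLIP)] = 0.0  # clipped too, but counted above
    return GCMatrix(F, labels, n_failures=failures, n_clipped=n_clipped)


# ---------------------------------------------------------------------------
# Brute-force cross-check for bivariate systems
# ---------------------------------------------------------------------------


def bivariate_gc_yule_walker(
    A: np.ndarray,
    sigma: np.ndarray,
    source: int,
    target: int,
    ar_order: int = 50,
) -> float:
    """Brute-force GC for a bivariate VAR(1), bypassing the Riccati route.

    Derives the target's exact autocovariance sequence from the discrete
    Lyapunov solution of the full model, fits a long univariate AR to it by
    Yule-Walker, and returns ``ln(reduced residual variance / Sigma_tt)``.
    Serves as an independent oracle for the DARE-based computation.
    """
    if A.shape != (2, 2):
        raise ValueError("oracle is defined for bivariate VAR(1) systems")
    P = sla.solve_discrete_lyapunov(A, sigma)
    gammas = np.empty(ar_order + 1)
    Ah = np.eye(2)
    for h in range(ar_order + 1):
        gammas[h] = (Ah @ P)[target, target]
        Ah = A @ Ah
    a = sla.solve_toeplitz(gammas[:ar_order], gammas[1 : ar_order + 1])
    sigma_red = gammas[0] - a @ gammas[1 : ar_order + 1]
    return float(np.log(sigma_red / sigma[target, target]))


# ---------------------------------------------------------------------------
# Group aggregation
# ---------------------------------------------------------------------------


def aggregate_connectome(
    matrices: Sequence[GCMatrix],
) -> tuple[GCMatrix, pd.DataFrame]:
    """Entrywise median across subjects and the upper-quartile report.

    The report lists the directed connections whose median strength reaches
    the 75th percentile across all N(N-1) connections, sorted descending —
    the group-level "strongest directed connections" summary.
    """
    if not matrices:
        raise ValueError("aggregate_connectome requires at least one matrix")
    labels = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != labels or m.values.shape != matrices[0].values.shape:
            raise ValueError("all GC matrices must share shape and labels")
    stack = np.stack([m.values for m in matrices])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN entries
        med = np.nanmedian(stack, axis=0)
    np.fill_diagonal(med, 0.0)
    N = med.shape[0]
    off = ~np.eye(N, dtype=bool)
    vals = med[off]
    rows: list[dict] = []
    if vals.size:
        thr = np.nanpercentile(vals, 75)
        for s in range(N):
            for t in range(N):
                if s != t and np.isfinite(med[s, t]) and med[s, t] >= thr:
                    rows.append(dict(source=labels[s], target=labels[t],
                                     median_gc=med[s, t]))
    report = pd.DataFrame(rows, columns=["source", "target", "median_gc"])
    report = report.sort_values("median_gc", ascending=False,
                                kind="mergesort").reset_index(drop=True)
    return GCMatrix(med, list(labels)), report
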