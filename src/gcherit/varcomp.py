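"""Polygenic variance-component heritability of directed-connection traits.

Each directed connection is treated as an endophenotypic trait y over the
cohort, modelled as zero-mean multivariate normal with covariance

    Omega = sigma_g^2 (2*Phi) + sigma_c^2 H + sigma_e^2 I

where 2*Phi is the expected-relatedness (kinship) matrix, H the shared-
household indicator and I the identity (AE model: sigma_c^2 = 0). Narrow-
sense heritability is h^2 = sigma_g^2 / sigma_p^2 with sigma_p^2 the
component sum. Maximum likelihood is computed blockwise per family (the
covariance is block-diagonal across families) by profiling the total
variance out analytically and scanning the (h^2, c^2) variance-share
simplex on a grid with local refinement — a bounded 2-D problem where the
grid immunizes against boundary-local optima.

Significance of sigma_g^2 > 0 uses the boundary-corrected likelihood-ratio
test (null distribution a 50:50 mixture of a point mass at zero and
chi-square with 1 df), and Benjamini-Hochberg FDR across all connections
of a cohort. Preprocessing residualizes traits on age, sex, handedness and
education, then applies a rank-based inverse normal transform (Blom
constants).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components
from scipy.special import ndtri
from statsmodels.stats.multitest import multipletests

from .pedigree import HouseholdMatrix, KinshipMatrix

SHARE_CAP = 0.99          # h2 + c2 ceiling; family blocks go singular at 1
COARSE_STEP = 0.01
REFINE_STEP = 0.001

FLAG_UNIDENTIFIABLE = "unidentifiable"
FLAG_OPTIMIZER = "optimizer_failure"


# ---------------------------------------------------------------------------
# Trait container
# ---------------------------------------------------------------------------


@dataclass
class TraitTable:
    """Subjects x directed-connections trait matrix keyed by (source, target)."""

    values: np.ndarray
    columns: list[tuple]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.columns)):
            raise ValueError("trait shape does not match ids/columns")

    @classmethod
    def from_gc_stack(cls, matrices: dict) -> "TraitTable":
        """Build from {subject_id: GCMatrix}; columns are all ordered pairs."""
        sids = list(matrices)
        first = matrices[sids[0]]
        labels = first.labels
        N = len(labels)
        cols = [(labels[s], labels[t]) for s in range(N) for t in range(N) if s != t]
        vals = np.empty((len(sids), len(cols)))
        for i, sid in enumerate(sids):
            M = matrices[sid].values
            vals[i] = [M[s, t] for s in range(N) for t in range(N) if s != t]
        return cls(vals, cols, sids)

    def subset(self, ids: Sequence[str]) -> "TraitTable":
        pos = {sid: i for i, sid in enumerate(self.subject_ids)}
        rows = [pos[i] for i in ids]
        return TraitTable(self.values[rows], list(self.columns), list(ids))

    def to_frame(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_tuples(self.columns, names=["source", "target"])
        return pd.DataFrame(self.values, index=self.subject_ids, columns=cols)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def adjust_covariates(traits: TraitTable, cov: pd.DataFrame) -> TraitTable:
    """Residualize every trait on [1, age, sex, handedness, education].

    Returns a TraitTable of least-squares residuals; the design must be
    full rank (collinear columns are named in the error).
    """
    cov = cov.copy()
    cov["id"] = cov["id"].astype(str)
    cov = cov.set_index("id").loc[traits.subject_ids]
    cols = ["age", "sex", "handedness", "education"]
    X = np.column_stack([np.ones(len(cov))] + [cov[c].to_numpy(float) for c in cols])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns by leave-one-out rank probing
        bad = [c for i, c in enumerate(["intercept"] + cols)
               if np.linalg.matrix_rank(np.delete(X, i, axis=1)) == rank]
        raise ValueError(f"collinear covariate design; involved columns: {bad}")
    beta, _, _, _ = np.linalg.lstsq(X, traits.values, rcond=None)
    resid = traits.values - X @ beta
    return TraitTable(resid, list(traits.columns), list(traits.subject_ids))


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform with Blom constants.

    Maps value of rank r (mean ranks for ties) to
    ``Phi^{-1}((r - 3/8) / (n + 1/4))``; order-preserving by construction.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("inverse normal transform requires n >= 3")
    if np.all(x == x[0]):
        raise ValueError("all values identical: ranks undefined")
    r = stats.rankdata(x, method="average")
    return ndtri((r - 0.375) / (n + 0.25))


# ---------------------------------------------------------------------------
# Blockwise likelihood machinery
# ---------------------------------------------------------------------------


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_c2: float
    sigma_e2: float
    loglik: float
    model: str = "AE"
    flag: str = ""

    @property
    def sigma_p2(self) -> float:
        return self.sigma_g2 + self.sigma_c2 + self.sigma_e2

    @property
    def h2(self) -> float:
        return self.sigma_g2 / self.sigma_p2

    @property
    def c2(self) -> float:
        return self.sigma_c2 / self.sigma_p2


def _family_blocks(K: np.ndarray, H: np.ndarray | None) -> list[np.ndarray]:
    """Connected components of the joint kinship/household sparsity pattern."""
    M = np.abs(K) > 0
    if H is not None:
        M |= np.abs(H) > 0
    _, labels = connected_components(sparse.csr_matrix(M), directed=False)
    return [np.flatnonzero(labels == c) for c in range(labels.max() + 1)]


class _BlockStructures:
    """Families grouped by identical (kinship, household) block pattern.

    Precomputes, for a grid of variance shares, the batched inverse and
    log-determinant of the unit-variance family covariance
    ``R(theta) = h2 K_b + c2 H_b + (1 - h2 - c2) I`` so that the profile
    log-likelihood of any trait reduces to a few small matrix
    contractions.
    """

    def __init__(self, K: np.ndarray, H: np.ndarray | None):
        self.n = K.shape[0]
        blocks = _family_blocks(K, H)
        groups: dict[tuple, dict] = {}
        for idx in blocks:
            Kb = K[np.ix_(idx, idx)]
            Hb = H[np.ix_(idx, idx)] if H is not None else None
            key = (len(idx), Kb.round(10).tobytes(),
                   Hb.round(10).tobytes() if Hb is not None else b"")
            g = groups.setdefault(key, dict(K=Kb, H=Hb, members=[]))
            g["members"].append(idx)
        self.groups = list(groups.values())
        self.has_relatedness = any(
            np.any(np.abs(g["K"] - np.eye(g["K"].shape[0])) > 0) for g in self.groups
        )
        self._cache: dict[bytes, tuple] = {}

    def scatter(self, y: np.ndarray) -> list[np.ndarray]:
        """Per-structure scatter matrix sum_f y_f y_f'."""
        out = []
        for g in self.groups:
            Y = np.stack([y[idx] for idx in g["members"]])  # (F, k)
            out.append(Y.T @ Y)
        return out

    def _grid_factors(self, h2v: np.ndarray, c2v: np.ndarray):
        key = np.stack([h2v, c2v]).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        e2v = 1.0 - h2v - c2v
        factors = []
        for g in self.groups:
            k = g["K"].shape[0]
            I = np.eye(k)
            Hb = g["H"] if g["H"] is not None else np.zeros((k, k))
            R = (h2v[:, None, None] * g["K"] + c2v[:, None, None] * Hb
                 + e2v[:, None, None] * I)
            L = np.linalg.cholesky(R)
            logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)), axis=1)
            invR = np.linalg.inv(R)
            factors.append((invR, logdet, len(g["members"])))
        self._cache[key] = factors
        return factors

    def profile_loglik(self, scatters, h2v: np.ndarray, c2v: np.ndarray):
        """Profile (over total variance) log-likelihood on a share grid.

        Returns ``(loglik, sigma_p2)`` arrays over the grid.
        """
        n = self.n
        factors = self._grid_factors(h2v, c2v)
        q = np.zeros(len(h2v))
        D = np.zeros(len(h2v))
        for (invR, logdet, nf), S in zip(factors, scatters):
            q += np.einsum("gij,ij->g", invR, S)
            D += nf * logdet
        sigma_p2 = q / n
        ll = -0.5 * (n * np.log(2 * np.pi * sigma_p2) + D + n)
        return ll, sigma_p2


def loglik_components(
    y: np.ndarray,
    kin: KinshipMatrix,
    house: HouseholdMatrix | None,
    sigma_g2: float,
    sigma_c2: float,
    sigma_e2: float,
) -> float:
    """Blockwise zero-mean Gaussian log-likelihood at given components."""
    K = kin.values
    H = house.values if house is not None else None
    y = np.asarray(y, dtype=float)
    ll = 0.0
    for idx in _family_blocks(K, H):
        Hb = H[np.ix_(idx, idx)] if H is not None else 0.0
        R = sigma_g2 * K[np.ix_(idx, idx)] + sigma_c2 * Hb + sigma_e2 * np.eye(len(idx))
        L = np.linalg.cholesky(R)
        z = np.linalg.solve(L, y[idx])
        ll += -0.5 * (len(idx) * np.log(2 * np.pi)
                      + 2 * np.sum(np.log(np.diag(L))) + z @ z)
    return float(ll)


def _share_grid(model: str, step: float, h_lo=0.0, h_hi=SHARE_CAP,
                c_lo=0.0, c_hi=SHARE_CAP):
    hs = np.arange(h_lo, h_hi + step / 2, step)
    if model == "AE":
        return hs, np.zeros_like(hs)
    h_list, c_list = [], []
    cs = np.arange(c_lo, c_hi + step / 2, step)
    for h in hs:
        for c in cs:
            if h + c <= SHARE_CAP + 1e-12:
                h_list.append(h)
                c_list.append(c)
    return np.array(h_list), np.array(c_list)


def fit_variance_components(
    trait: np.ndarray,
    kin: KinshipMatrix,
    house: HouseholdMatrix | None = None,
    model: str = "AE",
    _structures: "_BlockStructures | None" = None,
) -> VarianceComponents:
    """Maximum-likelihood AE/ACE fit of one trait on a kinship structure.

    Profiles the total variance analytically and scans variance shares on
    a 0.01 grid followed by 0.001 local refinement; boundary solutions
    (sigma_g^2 = 0, sigma_c^2 = 0) are admissible. A pedigree with no
    related pairs leaves h^2 unidentifiable: the fit is returned at the
    boundary with an ``unidentifiable`` flag.
    """
    model = model.upper()
    if model not in ("AE", "ACE"):
        raise ValueError("model must be 'AE' or 'ACE'")
    if model == "ACE" and house is None:
        raise ValueError("ACE model requires a household matrix")
    y = np.asarray(trait, dtype=float)
    if y.ndim != 1 or len(y) != kin.values.shape[0]:
        raise ValueError("trait must be a vector aligned to the kinship matrix")
    if np.var(y) == 0:
        raise ValueError("trait has zero variance")

    H = house.values if (house is not None and model == "ACE") else None
    st = _structures if _structures is not None else _BlockStructures(
        kin.values, H)
    scat = st.scatter(y)

    if not st.has_relatedness:
        # 2*Phi = I: sigma_g2 and sigma_e2 enter only through their sum
        sp2 = float(np.sum(y**2) / len(y))
        ll, _ = st.profile_loglik(scat, np.array([0.0]), np.array([0.0]))
        return VarianceComponents(0.0, 0.0, sp2, float(ll[0]), model,
                                  flag=FLAG_UNIDENTIFIABLE)

    h2v, c2v = _share_grid(model, COARSE_STEP)
    ll, sp2 = st.profile_loglik(scat, h2v, c2v)
    best = int(np.argmax(ll))
    h_best, c_best = h2v[best], c2v[best]

    # local refinement at 1e-3 resolution around the coarse optimum
    span = COARSE_STEP + REFINE_STEP
    h2f, c2f = _share_grid(
        model, REFINE_STEP,
        h_lo=max(0.0, h_best - span), h_hi=min(SHARE_CAP, h_best + span),
        c_lo=max(0.0, c_best - span), c_hi=min(SHARE_CAP, c_best + span),
    )
    llf, sp2f = st.profile_loglik(scat, h2f, c2f)
    bf = int(np.argmax(llf))
    h_hat, c_hat = float(h2f[bf]), float(c2f[bf])
    sp_hat, ll_hat = float(sp2f[bf]), float(llf[bf])

    flag = "" if np.isfinite(ll_hat) else FLAG_OPTIMIZER
    return VarianceComponents(
        sigma_g2=h_hat * sp_hat,
        sigma_c2=c_hat * sp_hat,
        sigma_e2=(1.0 - h_hat - c_hat) * sp_hat,
        loglik=ll_hat,
        model=model,
        flag=flag,
    )


def fit_null(
    trait: np.ndarray,
    kin: KinshipMatrix,
    house: HouseholdMatrix | None = None,
    model: str = "AE",
    _structures: "_BlockStructures | None" = None,
) -> VarianceComponents:
    """Same-likelihood fit with sigma_g^2 constrained to zero (E or CE)."""
    model = model.upper()
    y = np.asarray(trait, dtype=float)
    H = house.values if (house is not None and model == "ACE") else None
    st = _structures if _structures is not None else _BlockStructures(
        kin.values, H)
    scat = st.scatter(y)
    if model == "AE":
        c2v = np.array([0.0])
    else:
        c2v = np.arange(0.0, SHARE_CAP + COARSE_STEP / 2, COARSE_STEP)
    h2v = np.zeros_like(c2v)
    ll, sp2 = st.profile_loglik(scat, h2v, c2v)
    b = int(np.argmax(ll))
    if model == "ACE":
        c2f = np.arange(max(0.0, c2v[b] - COARSE_STEP),
                        min(SHARE_CAP, c2v[b] + COARSE_STEP) + REFINE_STEP / 2,
                        REFINE_STEP)
        llf, sp2f = st.profile_loglik(scat, np.zeros_like(c2f), c2f)
        bf = int(np.argmax(llf))
        c_hat, sp_hat, ll_hat = float(c2f[bf]), float(sp2f[bf]), float(llf[bf])
    else:
        c_hat, sp_hat, ll_hat = 0.0, float(sp2[b]), float(ll[b])
    return VarianceComponents(0.0, c_hat * sp_hat, (1 - c_hat) * sp_hat,
                              ll_hat, model)


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------


def lrt_heritability(full: VarianceComponents, null_loglik: float):
    """Boundary-corrected likelihood-ratio test of sigma_g^2 = 0.

    ``Lambda = 2 (LL_full - LL_null)`` clipped at zero; because sigma_g^2
    sits on the boundary under the null, p = 0.5 * P(chi2_1 >= Lambda)
    (the 50:50 point-mass/chi-square mixture), so Lambda = 0 gives p = 0.5.
    Returns ``(statistic, p, flag)``.
    """
    lam = 2.0 * (full.loglik - null_loglik)
    flag = ""
    if lam < -1e-6:
        flag = FLAG_OPTIMIZER
    lam = max(lam, 0.0)
    p = 0.5 * float(stats.chi2.sf(lam, df=1))
    if lam == 0.0:
        p = 0.5
    return lam, p, flag


def fdr_bh(pvals: np.ndarray, alpha: float = 0.05):
    """Benjamini-Hochberg step-up: returns (q-values, significance flags)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


# ---------------------------------------------------------------------------
# Per-cohort scan and replication
# ---------------------------------------------------------------------------


def heritability_scan(
    traits: TraitTable,
    ped,
    cov: pd.DataFrame | None = None,
    model: str = "AE",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full per-connection heritability analysis for one cohort.

    Covariate residualization (if ``cov`` given) -> rank-based inverse
    normal transform -> AE/ACE maximum likelihood (full and sigma_g^2 = 0
    null) -> boundary-corrected LRT -> Benjamini-Hochberg FDR pooled across
    all connections. Connections whose fit fails are flagged and excluded
    from the FDR family.
    """
    from .pedigree import build_household, build_kinship  # late: cycle-free

    kin = build_kinship(ped)
    house = build_household(ped)
    if list(kin.ids) != list(traits.subject_ids):
        traits = traits.subset(list(kin.ids))
    X = traits
    if cov is not None:
        X = adjust_covariates(X, cov)

    model = model.upper()
    H = house.values if model == "ACE" else None
    st = _BlockStructures(kin.values, H)

    rows = []
    for j, conn in enumerate(X.columns):
        y = X.values[:, j]
        flag = ""
        try:
            y = inverse_normal_transform(y)
            full = fit_variance_components(y, kin, house, model, _structures=st)
            null = fit_null(y, kin, house, model, _structures=st)
            lam, p, lflag = lrt_heritability(full, null.loglik)
            flag = full.flag or lflag
        except (ValueError, np.linalg.LinAlgError) as exc:
            rows.append(dict(source=conn[0], target=conn[1], model=model,
                             sigma_g2=np.nan, sigma_c2=np.nan, sigma_e2=np.nan,
                             h2=np.nan, c2=np.nan, loglik=np.nan,
                             null_loglik=np.nan, lrt=np.nan, p=np.nan,
                             flag=f"failed:{exc}"))
            continue
        rows.append(dict(source=conn[0], target=conn[1], model=model,
                         sigma_g2=full.sigma_g2, sigma_c2=full.sigma_c2,
                         sigma_e2=full.sigma_e2, h2=full.h2, c2=full.c2,
                         loglik=full.loglik, null_loglik=null.loglik,
                         lrt=lam, p=p, flag=flag))
    cols = ["source", "target", "model", "sigma_g2", "sigma_c2", "sigma_e2",
            "h2", "c2", "loglik", "null_loglik", "lrt", "p", "flag"]
    out = pd.DataFrame(rows, columns=cols)
    out["q"] = np.nan
    out["significant"] = False
    valid = out["p"].notna() & ~out["flag"].str.startswith("failed")
    if valid.any():
        q, rej = fdr_bh(out.loc[valid, "p"].to_numpy(), alpha=alpha)
        out.loc[valid, "q"] = q
        out.loc[valid, "significant"] = rej
    return out


@dataclass
class ReplicationSummary:
    n_discovery: int
    n_replication: int
    n_both: int
    pct_of_discovery: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dict(
            n_discovery=self.n_discovery, n_replication=self.n_replication,
            n_both=self.n_both, pct_of_discovery=self.pct_of_discovery)])


def replication_overlap(
    scan_discovery: pd.DataFrame, scan_replication: pd.DataFrame
) -> ReplicationSummary:
    """Overlap of FDR-significant connections between two cohorts.

    The replication percentage is ``100 * n_both / n_discovery`` rounded
    to the nearest integer (0 when the discovery set is empty).
    """
    ka = set(zip(scan_discovery["source"], scan_discovery["target"]))
    kb = set(zip(scan_replication["source"], scan_replication["target"]))
    if ka != kb:
        raise ValueError("discovery and replication scans cover different connections")
    sig_a = {k for k, s in zip(
        zip(scan_discovery["source"], scan_discovery["target"]),
        scan_discovery["significant"]) if bool(s)}
    sig_b = {k for k, s in zip(
        zip(scan_replication["source"], scan_replication["target"]),
        scan_replication["significant"]) if bool(s)}
    both = sig_a & sig_b
    pct = int(round(100.0 * len(both) / len(sig_a))) if sig_a else 0
    return ReplicationSummary(len(sig_a), len(sig_b), len(both), pct)


def write_results_csv(df: pd.DataFrame, path: str | Path,
                      comment: str | None = None) -> None:
    cols = ["source", "target", "model", "h2", "c2", "loglik", "lrt", "p", "q",
            "significant"]
    extra = [c for c in df.columns if c not in cols]
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df[cols + extra].to_csv(fh, index=False)
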