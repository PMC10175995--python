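"""Validation experiments with planted ground truth.

These are small simulation studies the package runs on itself: oracle
agreement for the Riccati-based Granger computation, estimation
consistency in T, the hemodynamic-lag directional-confound rescue, and
variance-component parameter recovery. They are used by the test suite
and the reproduction script, and are handy when porting the method to new
data regimes.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .containers import standardize
from .hrf import deconvolve_series, double_gamma_hrf
from .simulate import SimConfig, simulate_ace_traits, simulate_pedigree, synthesize_session
from .ssgc import (
    StateSpaceModel,
    VARModel,
    bivariate_gc_yule_walker,
    fit_var_pooled,
    gc_from_source,
    var_to_state_space,
)
from .varcomp import _BlockStructures, fit_null, fit_variance_components, lrt_heritability


def random_stable_var1(rng: np.random.Generator, n: int = 2,
                       rho_max: float = 0.9) -> tuple[np.ndarray, np.ndarray]:
    """Random stable VAR(1) coefficients and a random SPD residual cov."""
    A = rng.uniform(-0.8, 0.8, size=(n, n))
    rho = np.max(np.abs(np.linalg.eigvals(A)))
    if rho >= rho_max:
        A *= rho_max * rng.uniform(0.5, 1.0) / rho
    W = rng.standard_normal((n, n)) * 0.3
    sigma = np.eye(n) + W @ W.T
    return A, sigma


def true_model_gc(A: np.ndarray, sigma: np.ndarray, source: int) -> np.ndarray:
    """Model-based GC from known VAR(1) parameters (no estimation)."""
    var = VARModel(order=1, coefs=A[None, :, :], sigma=sigma, nobs=0)
    return gc_from_source(var_to_state_space(var), source)


def gc_oracle_agreement(n_systems: int = 20, seed: int = 0) -> dict:
    """DARE-based GC vs the reduced-AR Yule-Walker oracle on random systems.

    Also evaluates triangular (single-edge) systems where the absent
    direction must give F = 0.
    """
    rng = np.random.default_rng(seed)
    errs, absent = [], []
    for _ in range(n_systems):
        A, sigma = random_stable_var1(rng)
        for src in (0, 1):
            tgt = 1 - src
            f_model = true_model_gc(A, sigma, src)[0]
            f_oracle = bivariate_gc_yule_walker(A, sigma, src, tgt, ar_order=50)
            errs.append(abs(f_model - f_oracle))
        # single-edge system: 1 -> 2 only, diagonal noise
        b = rng.uniform(0.2, 0.6)
        A1 = np.array([[0.5, 0.0], [b, 0.5]])
        absent.append(abs(true_model_gc(A1, np.eye(2), 1)[0]))
    return dict(max_abs_err=float(np.max(errs)),
                absent_edge_max=float(np.max(absent)))


def gc_consistency(
    t_small: int = 1000,
    t_large: int = 4000,
    n_seeds: int = 20,
    n_replicates: int = 4,
    seed: int = 0,
) -> dict:
    """Median |estimated - true| GC at two record lengths.

    Uses a fixed single-edge bivariate VAR(1). The GC estimate's sampling
    error shrinks like 1/sqrt(T), so quadrupling T halves the error. To
    measure that ratio rather than median-of-20 sampling noise, each seed
    simulates ``n_replicates`` independent records of length ``t_large``
    and its error at each T is the mean absolute error over all disjoint
    segments of that length; the reported medians are across seeds.
    """
    A = np.array([[0.5, 0.0], [0.4, 0.5]])
    f_true = true_model_gc(A, np.eye(2), 0)[0]
    n_blocks = t_large // t_small

    def _est(y: np.ndarray) -> float:
        var = fit_var_pooled([y], order=1)
        return float(gc_from_source(var_to_state_space(var), 0)[0])

    err_small, err_large = [], []
    for s in range(n_seeds):
        rng = np.random.default_rng((seed << 8) + s)
        e1, e4 = [], []
        for _ in range(n_replicates):
            y = _simulate_var1(A, t_large + 500, rng)[500:]
            e4.append(abs(_est(y) - f_true))
            for b in range(n_blocks):
                e1.append(abs(_est(y[b * t_small : (b + 1) * t_small]) - f_true))
        err_small.append(np.mean(e1))
        err_large.append(np.mean(e4))
    med_small = float(np.median(err_small))
    med_large = float(np.median(err_large))
    return dict(median_err_small=med_small, median_err_large=med_large,
                ratio=med_large / med_small)


def _simulate_var1(A: np.ndarray, T: int, rng: np.random.Generator) -> np.ndarray:
    n = A.shape[0]
    y = np.zeros((T, n))
    eps = rng.standard_normal((T, n))
    for t in range(1, T):
        y[t] = A @ y[t - 1] + eps[t]
    return y


def deconvolution_rescue(
    n_seeds: int = 50,
    seed: int = 0,
    T: int = 1200,
    n_sessions: int = 4,
    tr: float = 0.72,
    coupling: float = 0.4,
    noise_sd: float = 0.2,
    source_peak: float = 7.0,
    target_peak: float = 5.0,
) -> dict:
    """Directional-confound experiment: source HRF slower than target's.

    A 2-node system with true coupling 1 -> 2 is observed through HRFs
    whose peak latency differs by ``source_peak - target_peak`` seconds
    (the slow-source case that reverses apparent lag). Each seed simulates
    ``n_sessions`` sessions (the per-subject session structure of the
    pipeline); one HRF per node is estimated blindly from all sessions
    pooled, each session is deconvolved, and GC is fitted on the pooled
    sessions. The direction is called correct when F(1->2) > F(2->1);
    rates are returned for raw-BOLD GC and deconvolved GC.
    """
    from .hrf import HRFModel, estimate_hrf_pooled, wiener_deconvolve

    A = np.array([[0.5, 0.0], [coupling, 0.5]])
    kernels = [double_gamma_hrf(tr, peak=source_peak),
               double_gamma_hrf(tr, peak=target_peak)]
    raw_hits, dec_hits = 0, 0
    for s in range(n_seeds):
        rng = np.random.default_rng((seed << 8) + s)
        sessions = [synthesize_session(A, kernels, T, noise_sd, rng)[0]
                    for _ in range(n_sessions)]
        raw_hits += _direction_correct(sessions)
        models = [estimate_hrf_pooled([b[:, i] for b in sessions], tr)
                  for i in range(2)]
        dec = [np.column_stack([wiener_deconvolve(b[:, i], models[i]).values
                                for i in range(2)]) for b in sessions]
        dec_hits += _direction_correct(dec)
    return dict(raw_rate=raw_hits / n_seeds, deconv_rate=dec_hits / n_seeds)


def _direction_correct(sessions) -> bool:
    var = fit_var_pooled([standardize(y) for y in sessions],
                         order="aic", p_max=10)
    ss = var_to_state_space(var)
    f12 = gc_from_source(ss, 0)[0]
    f21 = gc_from_source(ss, 1)[0]
    return bool(f12 > f21)


def heritability_recovery(
    n_traits: int = 50,
    h2: float = 0.40,
    c2: float = 0.0,
    model: str = "AE",
    seed: int = 0,
) -> dict:
    """Parameter recovery on a full-composition synthetic cohort.

    Simulates ``n_traits`` independent traits with the given true variance
    shares on the default 449-individual cohort and refits them; returns
    the mean and RMSE of the estimates.
    """
    cfg = SimConfig(n_networks=_traits_to_networks(n_traits), h2=h2, c2=c2,
                    seed=seed)
    ped, _ = simulate_pedigree(cfg)
    traits = simulate_ace_traits(ped, cfg)
    from .pedigree import build_household, build_kinship

    kin = build_kinship(ped)
    house = build_household(ped)
    H = house.values if model.upper() == "ACE" else None
    st = _BlockStructures(kin.values, H)
    h_hats, c_hats = [], []
    for j in range(n_traits):
        fit = fit_variance_components(traits.values[:, j], kin, house,
                                      model=model, _structures=st)
        h_hats.append(fit.h2)
        c_hats.append(fit.c2)
    h_hats = np.array(h_hats)
    c_hats = np.array(c_hats)
    return dict(
        h2_mean=float(h_hats.mean()),
        h2_rmse=float(np.sqrt(np.mean((h_hats - h2) ** 2))),
        c2_mean=float(c_hats.mean()),
        c2_rmse=float(np.sqrt(np.mean((c_hats - c2) ** 2))),
    )


def _traits_to_networks(n_traits: int) -> int:
    """Smallest N with N(N-1) >= n_traits."""
    n = 2
    while n * (n - 1) < n_traits:
        n += 1
    return n


def lrt_type1_rate(
    n_traits: int = 1000, alpha: float = 0.05, seed: int = 0, model: str = "AE"
) -> dict:
    """Rejection rate of the boundary-corrected LRT under the null.

    Null traits are iid standard normal over the default synthetic cohort
    (h^2 = 0); the pre-FDR rejection rate at ``alpha`` should sit near the
    nominal level.
    """
    cfg = SimConfig(seed=seed)
    ped, _ = simulate_pedigree(cfg)
    from .pedigree import build_household, build_kinship

    kin = build_kinship(ped)
    house = build_household(ped)
    H = house.values if model.upper() == "ACE" else None
    st = _BlockStructures(kin.values, H)
    rng = np.random.default_rng(seed + 1)
    rejections = 0
    for _ in range(n_traits):
        y = rng.standard_normal(ped.n)
        full = fit_variance_components(y, kin, house, model=model, _structures=st)
        null = fit_null(y, kin, house, model=model, _structures=st)
        _, p, _ = lrt_heritability(full, null.loglik)
        rejections += p < alpha
    return dict(rate=rejections / n_traits, n=n_traits)
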