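"""Synthetic twin-cohort generator with known directed-coupling heritability.

Every downstream stage (deconvolution, state-space Granger causality,
variance-component heritability) is testable against ground truth because
the generator plants it: per-connection coupling strengths are drawn from
a zero-mean multivariate normal over the cohort with covariance
``sigma_g^2 (2*Phi) + sigma_c^2 H + sigma_e^2 I`` (the ACE decomposition on
the kinship and household structure), the couplings parameterize each
subject's VAR(1) neural dynamics on a designated sparse edge set, and the
neural series are convolved with node- and subject-specific double-gamma
HRFs before observation noise is added — emulating the lag confound the
deconvolution stage must remove.

The default cohort composition mirrors a large young-adult family imaging
sample: 62 MZ twin pairs, 25 DZ twin pairs, sibling sets totalling 197
individuals, and 78 singletons (449 individuals per cohort), scanned in
4 sessions of 1200 timepoints at TR = 0.72 s. The network count defaults
to a desk-scale 10 nodes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .containers import NetworkTimeseriesSet, standardize
from .hrf import DEFAULT_KERNEL_DURATION, delta_kernel, double_gamma_hrf
from .pedigree import Pedigree, build_household, build_kinship


def table1_sibling_sets(total: int = 197) -> tuple[int, ...]:
    """Partition a sibling headcount into full-sib sets of size 2 and 3."""
    if total < 0:
        raise ValueError("total must be >= 0")
    threes = total % 2
    twos = (total - 3 * threes) // 2
    return tuple([2] * twos + [3] * threes)


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort and its BOLD-like observations."""

    n_mz_pairs: int = 62
    n_dz_pairs: int = 25
    sibling_set_sizes: tuple[int, ...] = field(default_factory=table1_sibling_sets)
    n_singletons: int = 78

    n_networks: int = 10
    n_sessions: int = 4
    n_timepoints: int = 1200
    tr: float = 0.72

    #: variance shares of the latent coupling traits (scalar applies to all
    #: connections; a mapping keyed by (source, target) overrides per edge)
    h2: float | Mapping = 0.4
    c2: float | Mapping = 0.0

    base_coupling: float = 0.25
    ar_coeff: float = 0.5
    n_edges: int | None = None          # default: ~15% of directed pairs
    spectral_radius_cap: float = 0.95

    hrf_kind: str = "double-gamma"      # or "delta" (no hemodynamic blur)
    hrf_peak_range: tuple[float, float] = (4.0, 7.0)
    hrf_peaks: Sequence[float] | None = None   # explicit per-node peaks
    #: sparse positive neural "burst" innovations on top of a weaker
    #: Gaussian background; spontaneous activity is heavy-tailed, and these
    #: supra-threshold events are what blind deconvolution locks onto (a
    #: purely Gaussian process has no recoverable HRF phase)
    background_sd: float = 0.5
    spike_prob: float = 0.02
    spike_amp: float = 5.0
    noise_sd: float = 0.3
    burn_in: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mz_pairs", "n_dz_pairs", "n_singletons", "n_networks",
                     "n_sessions", "n_timepoints"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(s < 1 for s in self.sibling_set_sizes):
            raise ValueError("sibling set sizes must be >= 1")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if not 0 < self.spectral_radius_cap < 1:
            raise ValueError("spectral_radius_cap must lie in (0, 1)")
        for h, c in self.share_pairs():
            if not (0 <= h <= 1 and 0 <= c <= 1 and h + c <= 1):
                raise ValueError("need 0 <= h2, c2 and h2 + c2 <= 1")

    # -- helpers -----------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return (2 * self.n_mz_pairs + 2 * self.n_dz_pairs
                + sum(self.sibling_set_sizes) + self.n_singletons)

    def connections(self) -> list[tuple[int, int]]:
        N = self.n_networks
        return [(s, t) for s in range(N) for t in range(N) if s != t]

    def shares_for(self, conn: tuple[int, int]) -> tuple[float, float]:
        h = self.h2[conn] if isinstance(self.h2, Mapping) else self.h2
        c = self.c2[conn] if isinstance(self.c2, Mapping) else self.c2
        return float(h), float(c)

    def share_pairs(self):
        if isinstance(self.h2, Mapping) or isinstance(self.c2, Mapping):
            return [self.shares_for(cn) for cn in self.connections()]
        return [(float(self.h2), float(self.c2))]


def _child_rng(seed: int, tag: str, *extra: int) -> np.random.Generator:
    key = [int(seed) & 0x7FFFFFFF, zlib.crc32(tag.encode()) & 0x7FFFFFFF]
    key += [int(e) & 0x7FFFFFFF for e in extra]
    return np.random.default_rng(np.random.SeedSequence(key))


def twin_study_config(n_cohorts: int = 1, **overrides) -> SimConfig:
    """Cohort with the default family composition, optionally doubled so a
    matched half-split can recover one full cohort per side."""
    base = SimConfig()
    cfg = replace(
        base,
        n_mz_pairs=base.n_mz_pairs * n_cohorts,
        n_dz_pairs=base.n_dz_pairs * n_cohorts,
        sibling_set_sizes=base.sibling_set_sizes * n_cohorts,
        n_singletons=base.n_singletons * n_cohorts,
        **overrides,
    )
    return cfg


# ---------------------------------------------------------------------------
# Pedigree and covariates
# ---------------------------------------------------------------------------


def simulate_pedigree(cfg: SimConfig) -> tuple[Pedigree, pd.DataFrame]:
    """Generate a pedigree and covariate table with the configured composition.

    Ages are family-anchored around 29 +- 3.5 y (twins share age), education
    ~ 15 +- 1.8 y, sex is balanced (MZ co-twins share sex), handedness is
    ~90% right. Fully deterministic for a fixed ``cfg.seed``.
    """
    rng = _child_rng(cfg.seed, "pedigree")
    rows: list[dict] = []
    cov: list[dict] = []
    fam_counter = 0
    pair_counter = 0

    def new_fam() -> str:
        nonlocal fam_counter
        fam_counter += 1
        return f"F{fam_counter:04d}"

    def draw_age(base: float | None = None) -> int:
        if base is None:
            base = rng.normal(29.0, 3.5)
        return int(np.clip(round(base + 0.0), 22, 36))

    def draw_person(fid: str, group: str, twinpair, sex, age) -> None:
        pid = f"S{len(rows) + 1:05d}"
        rows.append(dict(id=pid, famid=fid, sex=sex, group=group,
                         twinpair=twinpair, hhid=fid))
        cov.append(dict(
            id=pid,
            age=age,
            sex=1.0 if sex == "M" else 0.0,
            handedness=float(rng.random() < 0.9),
            education=int(np.clip(round(rng.normal(15.0, 1.8)), 11, 17)),
        ))

    for _ in range(cfg.n_mz_pairs):
        fid = new_fam()
        pair_counter += 1
        sex = "M" if rng.random() < 0.5 else "F"
        age = draw_age()
        for _ in range(2):
            draw_person(fid, "MZ", f"T{pair_counter:04d}", sex, age)
    for _ in range(cfg.n_dz_pairs):
        fid = new_fam()
        pair_counter += 1
        age = draw_age()
        for _ in range(2):
            sex = "M" if rng.random() < 0.5 else "F"
            draw_person(fid, "DZ", f"T{pair_counter:04d}", sex, age)
    for size in cfg.sibling_set_sizes:
        fid = new_fam()
        base = rng.normal(29.0, 3.0)
        for _ in range(size):
            sex = "M" if rng.random() < 0.5 else "F"
            draw_person(fid, "SIB", None, sex, draw_age(base + rng.uniform(-2, 2)))
    for _ in range(cfg.n_singletons):
        fid = new_fam()
        sex = "M" if rng.random() < 0.5 else "F"
        draw_person(fid, "SINGLETON", None, sex, draw_age())

    ped_df = pd.DataFrame(rows, columns=["id", "famid", "sex", "group",
                                         "twinpair", "hhid"])
    cov_df = pd.DataFrame(cov, columns=["id", "age", "sex", "handedness",
                                        "education"])
    return Pedigree(ped_df), cov_df


# ---------------------------------------------------------------------------
# Latent ACE traits
# ---------------------------------------------------------------------------


@dataclass
class LatentTraitTable:
    """True per-subject coupling strengths and their variance decomposition."""

    values: np.ndarray                      # (n_subjects, n_connections)
    columns: list[tuple[int, int]]          # (source, target) per column
    subject_ids: list[str]
    components: pd.DataFrame                # per connection: sigma_g2/c2/e2

    def to_frame(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_tuples(self.columns, names=["source", "target"])
        return pd.DataFrame(self.values, index=self.subject_ids, columns=cols)


def simulate_ace_traits(ped: Pedigree, cfg: SimConfig) -> LatentTraitTable:
    """Draw per-connection traits from N(0, sg2*2Phi + sc2*H + se2*I).

    Total variance is 1 (sg2 = h2, sc2 = c2, se2 = 1 - h2 - c2); draws are
    independent across connections and performed blockwise per family.
    """
    K = build_kinship(ped).values
    H = build_household(ped).values
    n = ped.n
    conns = cfg.connections()
    rng = _child_rng(cfg.seed, "traits")

    # family blocks (kinship and household share the family partition here)
    fam_codes = ped.table["famid"].to_numpy()
    blocks = [np.flatnonzero(fam_codes == f) for f in pd.unique(fam_codes)]

    chol_cache: dict[tuple, np.ndarray] = {}
    values = np.empty((n, len(conns)))
    comp_rows = []
    for j, conn in enumerate(conns):
        h2, c2 = cfg.shares_for(conn)
        e2 = 1.0 - h2 - c2
        y = np.empty(n)
        for idx in blocks:
            key = (K[np.ix_(idx, idx)].tobytes(), H[np.ix_(idx, idx)].tobytes(),
                   round(h2, 12), round(c2, 12))
            L = chol_cache.get(key)
            if L is None:
                R = (h2 * K[np.ix_(idx, idx)] + c2 * H[np.ix_(idx, idx)]
                     + e2 * np.eye(len(idx)))
                # jitter keeps the h2 + c2 = 1 boundary factorizable
                L = np.linalg.cholesky(R + 1e-12 * np.eye(len(idx)))
                chol_cache[key] = L
            y[idx] = L @ rng.standard_normal(len(idx))
        values[:, j] = y
        comp_rows.append(dict(source=conn[0], target=conn[1],
                              sigma_g2=h2, sigma_c2=c2, sigma_e2=e2))
    return LatentTraitTable(values, conns, ped.ids, pd.DataFrame(comp_rows))


# ---------------------------------------------------------------------------
# Subject-level VAR ground truth and BOLD observations
# ---------------------------------------------------------------------------


def default_edge_set(cfg: SimConfig) -> list[tuple[int, int]]:
    """Deterministic sparse directed edge set (about 15% of ordered pairs)."""
    conns = cfg.connections()
    n_edges = cfg.n_edges
    if n_edges is None:
        n_edges = max(1, int(round(0.15 * len(conns)))) if conns else 0
    if n_edges > len(conns):
        raise ValueError("n_edges exceeds the number of directed pairs")
    rng = _child_rng(cfg.seed, "edges")
    pick = rng.choice(len(conns), size=n_edges, replace=False)
    return [conns[i] for i in sorted(pick)]


def build_subject_var(
    trait_row: np.ndarray,
    cfg: SimConfig,
    edges: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """VAR(1) coefficient matrix for one subject.

    Diagonal autoregression ``cfg.ar_coeff``; each designated edge
    (source -> target) gets coefficient ``base_coupling * (1 + trait)``
    with the trait clipped at -0.9 so the edge sign is preserved. The
    matrix is rescaled to spectral radius <= ``spectral_radius_cap``.
    Row/column convention: ``A[target, source]`` multiplies the source's
    past in the target's equation.
    """
    trait_row = np.asarray(trait_row, dtype=float)
    if not np.all(np.isfinite(trait_row)):
        raise ValueError("trait row must be finite")
    N = cfg.n_networks
    if edges is None:
        edges = default_edge_set(cfg)
    col_index = {conn: j for j, conn in enumerate(cfg.connections())}
    A = np.eye(N) * cfg.ar_coeff
    for (s, t) in edges:
        tr_val = max(trait_row[col_index[(s, t)]], -0.9)
        A[t, s] = cfg.base_coupling * (1.0 + tr_val)
    rho = np.max(np.abs(np.linalg.eigvals(A)))
    if rho > cfg.spectral_radius_cap:
        A *= cfg.spectral_radius_cap / rho
    return A


def stationary_autocovariance(A: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Lag-0 autocovariance of a stable VAR(1): solves A X A' - X + Sigma = 0."""
    return sla.solve_discrete_lyapunov(A, sigma)


def _simulate_var(A: np.ndarray, T: int, rng: np.random.Generator,
                  burn_in: int, spike_prob: float = 0.0,
                  spike_amp: float = 0.0,
                  background_sd: float = 1.0) -> np.ndarray:
    N = A.shape[0]
    total = T + burn_in
    eps = background_sd * rng.standard_normal((total, N))
    if spike_prob > 0 and spike_amp > 0:
        mask = rng.random((total, N)) < spike_prob
        amp = spike_amp * np.abs(1.0 + 0.25 * rng.standard_normal((total, N)))
        eps = eps + mask * amp
    y = np.zeros((total, N))
    for t in range(1, total):
        y[t] = A @ y[t - 1] + eps[t]
    return y[burn_in:]


def _node_kernels(cfg: SimConfig, rng: np.random.Generator) -> list[np.ndarray]:
    N = cfg.n_networks
    if cfg.hrf_kind == "delta":
        return [delta_kernel(cfg.tr) for _ in range(N)]
    if cfg.hrf_kind != "double-gamma":
        raise ValueError(f"unknown hrf_kind {cfg.hrf_kind!r}")
    if cfg.hrf_peaks is not None:
        peaks = list(cfg.hrf_peaks)
        if len(peaks) != N:
            raise ValueError("hrf_peaks must list one peak per network")
    else:
        lo, hi = cfg.hrf_peak_range
        peaks = list(rng.uniform(lo, hi, size=N))
    return [double_gamma_hrf(cfg.tr, peak=p) for p in peaks]


def synthesize_session(
    A: np.ndarray,
    kernels: list[np.ndarray],
    T: int,
    noise_sd: float,
    rng: np.random.Generator,
    burn_in: int = 200,
    spike_prob: float = 0.02,
    spike_amp: float = 5.0,
    background_sd: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """One session: neural VAR -> per-node HRF convolution -> noise.

    Returns ``(bold, neural)`` where ``bold`` is the standardized noisy
    observation and ``neural`` the standardized latent series. Extra neural
    samples are simulated so the convolution has reached steady state at
    the first output sample.
    """
    Lk = max(len(k) for k in kernels)
    neural = _simulate_var(A, T + Lk, rng, burn_in, spike_prob, spike_amp,
                           background_sd)
    bold = np.empty((T, A.shape[0]))
    for i, k in enumerate(kernels):
        conv = np.convolve(neural[:, i], k)
        bold[:, i] = conv[Lk - 1 : Lk - 1 + T]
    bold = standardize(bold)
    if noise_sd > 0:
        bold = bold + noise_sd * rng.standard_normal(bold.shape)
    return standardize(bold), standardize(neural[Lk - 1 : Lk - 1 + T])


def generate_bold(
    ped: Pedigree,
    traits: LatentTraitTable,
    cfg: SimConfig,
    edges: list[tuple[int, int]] | None = None,
) -> NetworkTimeseriesSet:
    """BOLD-like sessions for every subject in the pedigree.

    HRF peak latencies are jittered per node and subject (shared across a
    subject's sessions, as a hemodynamic property of the subject's anatomy);
    sessions differ only in innovation noise. The neural simulation step
    equals TR.
    """
    if edges is None:
        edges = default_edge_set(cfg)
    subjects: dict[str, list[np.ndarray]] = {}
    id_to_row = {sid: i for i, sid in enumerate(traits.subject_ids)}
    for sid in ped.ids:
        srow = id_to_row[sid]
        A = build_subject_var(traits.values[srow], cfg, edges)
        hrf_rng = _child_rng(cfg.seed, "hrf", srow)
        kernels = _node_kernels(cfg, hrf_rng)
        sessions = []
        for sess in range(cfg.n_sessions):
            rng = _child_rng(cfg.seed, "bold", srow, sess)
            bold, _ = synthesize_session(A, kernels, cfg.n_timepoints,
                                         cfg.noise_sd, rng, cfg.burn_in,
                                         cfg.spike_prob, cfg.spike_amp,
                                         cfg.background_sd)
            sessions.append(bold)
        subjects[sid] = sessions
    return NetworkTimeseriesSet(subjects, tr=cfg.tr)
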