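"""End-to-end orchestration: configuration, I/O, logging, reproducible runs.

A run executes: simulate (or load) network time-series -> optional blind
HRF deconvolution -> per-subject state-space GC -> group aggregation ->
kinship-aware discovery/replication split -> per-cohort variance-component
heritability -> replication overlap. Every tabular output carries the
configuration hash in a leading comment line, and the master seed is split
into per-stage child seeds (stage name CRC mixed with the master) so each
stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import hrf as hrfmod
from .containers import NetworkTimeseriesSet, standardize
from .pedigree import Pedigree, balance_report, split_cohort
from .simulate import SimConfig, generate_bold, simulate_ace_traits, simulate_pedigree
from .ssgc import GCMatrix, aggregate_connectome, gc_matrix
from .varcomp import TraitTable, heritability_scan, replication_overlap

log = logging.getLogger("gcherit")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    mode: str = "synthetic"                  # or "real"
    sim: SimConfig = field(default_factory=SimConfig)
    manifest: str | None = None              # real mode inputs
    pedigree: str | None = None
    covariates: str | None = None
    out_dir: str = "runs/gcherit"

    deconvolve: bool = True
    #: event-to-response lag grid 0..max; None uses the default 2.5-10 s
    #: peak-latency grid of the adaptive-gamma basis
    hrf_lag_max: int | None = None

    gc_order: int | str = "aic"
    gc_p_max: int = 5
    gc_mode: str = "conditional"

    model: str = "AE"
    alpha: float = 0.05
    split_max_std_diff: float = 0.05
    split_max_restarts: int = 20

    seed: int = 0
    threads: int = 1
    save_timeseries: bool = False
    save_hdf5: bool = False                  # single HDF5 container for GC stack

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.mode not in ("synthetic", "real"):
            raise ValueError("mode must be 'synthetic' or 'real'")
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["sibling_set_sizes"] = list(d["sim"]["sibling_set_sizes"])
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "sim" in d and isinstance(d["sim"], dict):
            if "sibling_set_sizes" in d["sim"]:
                d["sim"]["sibling_set_sizes"] = tuple(d["sim"]["sibling_set_sizes"])
            if "hrf_peak_range" in d["sim"]:
                d["sim"]["hrf_peak_range"] = tuple(d["sim"]["hrf_peak_range"])
            d["sim"] = SimConfig(**d["sim"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # where outputs land does not change them
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def stage_seed(master: int, stage: str, *extra: int) -> int:
    """Deterministic per-stage child seed (< 2^31)."""
    h = zlib.crc32(stage.encode()) & 0x7FFFFFFF
    mix = np.random.SeedSequence(
        [int(master) & 0x7FFFFFFF, h] + [int(e) & 0x7FFFFFFF for e in extra]
    )
    return int(mix.generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# Time-series I/O
# ---------------------------------------------------------------------------


def write_timeseries(ts: NetworkTimeseriesSet, out_dir: str | Path) -> Path:
    """Write per-subject/session delimited text files plus a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid, sessions in ts.subjects.items():
        for k, arr in enumerate(sessions):
            fname = f"{sid}_sess{k}.tsv"
            np.savetxt(out_dir / fname, arr, delimiter="\t", fmt="%.8g")
            rows.append(dict(subject_id=sid, session_id=k,
                             timeseries_path=fname, tr=ts.tr))
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_timeseries(manifest_path: str | Path) -> NetworkTimeseriesSet:
    """Load a manifest of per-subject/session delimited text series.

    Every file must be numeric and rectangular with a consistent network
    count; violations are reported with the file (and line) involved.
    Series are standardized per column on load.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    man = pd.read_csv(manifest_path)
    needed = {"subject_id", "session_id", "timeseries_path", "tr"}
    if not needed <= set(man.columns):
        raise ValueError(f"manifest missing columns: {sorted(needed - set(man.columns))}")
    base = manifest_path.parent
    trs = set(man["tr"].astype(float))
    if len(trs) != 1:
        raise ValueError("all sessions must share one TR")
    subjects: dict[str, list[np.ndarray]] = {}
    n_nodes = None
    for _, row in man.sort_values(["subject_id", "session_id"]).iterrows():
        path = base / str(row["timeseries_path"])
        if not path.exists():
            raise FileNotFoundError(f"time-series file not found: {path}")
        arrs = []
        width = None
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                parts = line.replace(",", "\t").split()
                if width is None:
                    width = len(parts)
                elif len(parts) != width:
                    raise ValueError(f"{path}: ragged row at line {ln}")
                try:
                    arrs.append([float(v) for v in parts])
                except ValueError:
                    bad = next(i for i, v in enumerate(parts)
                               if not _is_float(v))
                    raise ValueError(
                        f"{path}: non-numeric cell at line {ln}, column {bad + 1}"
                    ) from None
        arr = np.asarray(arrs, dtype=float)
        if n_nodes is None:
            n_nodes = arr.shape[1]
        elif arr.shape[1] != n_nodes:
            raise ValueError(
                f"{path}: {arr.shape[1]} networks, expected {n_nodes}"
            )
        subjects.setdefault(str(row["subject_id"]), []).append(standardize(arr))
    return NetworkTimeseriesSet(subjects, tr=float(trs.pop()))


def _is_float(v: str) -> bool:
    try:
        float(v)
        return True
    except ValueError:
        return False


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config={cfg_hash}\n")
        df.to_csv(fh, index=index)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def deconvolve_set(
    ts: NetworkTimeseriesSet,
    lag_max: int | None = None,
    threads: int = 1,
) -> tuple[NetworkTimeseriesSet, pd.DataFrame]:
    """Blind HRF deconvolution of every node/session series.

    Returns the deconvolved set plus the per-node HRF report table.
    """
    lag_grid = range(0, lag_max + 1) if lag_max is not None else None

    def one_subject(sid: str, sessions):
        # one HRF per node, pooling the subject's sessions (the kernel is a
        # hemodynamic property of the subject's anatomy, not of a session)
        models = []
        for node in range(sessions[0].shape[1]):
            models.append(hrfmod.estimate_hrf_pooled(
                [arr[:, node] for arr in sessions], ts.tr, lag_grid=lag_grid))
        new_sessions, report = [], []
        for k, arr in enumerate(sessions):
            out = np.empty_like(arr)
            for node in range(arr.shape[1]):
                out[:, node] = hrfmod.wiener_deconvolve(
                    arr[:, node], models[node]).values
            new_sessions.append(out)
            report.extend(hrfmod.hrf_report_rows(sid, k, models))
        return sid, new_sessions, report

    items = list(ts.subjects.items())
    if threads > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=threads)(
            delayed(one_subject)(sid, sess) for sid, sess in items
        )
    else:
        results = [one_subject(sid, sess) for sid, sess in items]
    subjects = {sid: sess for sid, sess, _ in results}
    report = pd.DataFrame([r for _, _, rep in results for r in rep])
    return NetworkTimeseriesSet(subjects, tr=ts.tr, node_labels=list(ts.node_labels)), report


def gc_stage(
    ts: NetworkTimeseriesSet,
    order: int | str = "aic",
    p_max: int = 5,
    mode: str = "conditional",
    threads: int = 1,
) -> dict[str, GCMatrix]:
    def one(sid, sessions):
        return sid, gc_matrix(sessions, order=order, p_max=p_max, mode=mode,
                              labels=list(ts.node_labels))

    items = list(ts.subjects.items())
    if threads > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=threads)(delayed(one)(s, x) for s, x in items)
    else:
        results = [one(s, x) for s, x in items]
    return dict(results)


def save_gc_hdf5(matrices: dict[str, GCMatrix], path: str | Path) -> None:
    """Optional single-container storage: one dataset per subject."""
    with h5py.File(path, "w") as fh:
        for sid, m in matrices.items():
            d = fh.create_dataset(sid, data=m.values)
            d.attrs["labels"] = np.array(m.labels, dtype="S")
            d.attrs["orientation"] = "rows=source, cols=target"


# ---------------------------------------------------------------------------
# run_all
# ---------------------------------------------------------------------------


@dataclass
class RunResult:
    out_dir: Path
    replication: "pd.DataFrame"
    paths: dict


def run_all(cfg: RunConfig) -> RunResult:
    """Execute the full pipeline and write all outputs under ``cfg.out_dir``.

    Rerunning with the same configuration and seed reproduces every result
    file bit-for-bit. Stage failures leave earlier outputs in place; the
    log records the failing stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()
    cfg.to_yaml(out / "run_config.yaml")

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    paths: dict[str, Path] = {}
    t_all = time.time()
    try:
        # ---- inputs -----------------------------------------------------
        t0 = time.time()
        if cfg.mode == "real":
            for name in ("manifest", "pedigree", "covariates"):
                p = getattr(cfg, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"real mode requires existing {name} file, got {p!r}")
            ped = Pedigree.from_csv(cfg.pedigree)
            cov = pd.read_csv(cfg.covariates, dtype={"id": str}, comment="#")
            ts = load_timeseries(cfg.manifest)
        else:
            sim = dataclasses.replace(cfg.sim, seed=stage_seed(cfg.seed, "simulate"))
            ped, cov = simulate_pedigree(sim)
            traits_true = simulate_ace_traits(ped, sim)
            ts = generate_bold(ped, traits_true, sim)
            ped.to_csv(out / "pedigree.csv")
            cov.to_csv(out / "covariates.csv", index=False)
            paths["pedigree"] = out / "pedigree.csv"
        if cfg.save_timeseries:
            paths["manifest"] = write_timeseries(ts, out / "timeseries")
        log.info("stage=input mode=%s subjects=%d elapsed=%.2fs",
                 cfg.mode, len(ts.subjects), time.time() - t0)

        # ---- deconvolution ----------------------------------------------
        if cfg.deconvolve:
            t0 = time.time()
            ts, hrf_report = deconvolve_set(ts, lag_max=cfg.hrf_lag_max,
                                            threads=cfg.threads)
            _write_csv(hrf_report, out / "hrf_report.csv", cfg_hash)
            paths["hrf_report"] = out / "hrf_report.csv"
            n_flag = int((hrf_report["flag"] != "").sum())
            log.info("stage=deconvolve flagged=%d elapsed=%.2fs",
                     n_flag, time.time() - t0)

        # ---- Granger causality ------------------------------------------
        t0 = time.time()
        matrices = gc_stage(ts, order=cfg.gc_order, p_max=cfg.gc_p_max,
                            mode=cfg.gc_mode, threads=cfg.threads)
        gc_dir = out / "gc"
        gc_dir.mkdir(exist_ok=True)
        for sid, m in matrices.items():
            m.to_csv(gc_dir / f"{sid}.csv", comment=f"config={cfg_hash}")
        if cfg.save_hdf5:
            save_gc_hdf5(matrices, out / "gc_stack.h5")
        median, uq = aggregate_connectome(list(matrices.values()))
        median.to_csv(out / "gc_median.csv", comment=f"config={cfg_hash}")
        _write_csv(uq, out / "gc_upper_quartile.csv", cfg_hash)
        paths["gc_dir"] = gc_dir
        n_fail = sum(m.n_failures for m in matrices.values())
        n_clip = sum(m.n_clipped for m in matrices.values())
        log.info("stage=gc subjects=%d dare_failures=%d clipped=%d elapsed=%.2fs",
                 len(matrices), n_fail, n_clip, time.time() - t0)

        # ---- split -------------------------------------------------------
        t0 = time.time()
        ids_a, ids_b, excluded = split_cohort(
            ped, cov, seed=stage_seed(cfg.seed, "split"),
            max_std_diff=cfg.split_max_std_diff,
            max_restarts=cfg.split_max_restarts,
        )
        (out / "discovery_ids.txt").write_text("\n".join(ids_a) + "\n")
        (out / "replication_ids.txt").write_text("\n".join(ids_b) + "\n")
        (out / "excluded_ids.txt").write_text(
            ("\n".join(excluded) + "\n") if excluded else "")
        _write_csv(balance_report(ids_a, ids_b, ped, cov),
                   out / "balance_report.csv", cfg_hash)
        log.info("stage=split a=%d b=%d excluded=%d elapsed=%.2fs",
                 len(ids_a), len(ids_b), len(excluded), time.time() - t0)

        # ---- heritability ------------------------------------------------
        t0 = time.time()
        traits = TraitTable.from_gc_stack(matrices)
        scans = {}
        for name, ids in (("discovery", ids_a), ("replication", ids_b)):
            sub_ped = ped.subset(ids)
            scan = heritability_scan(traits.subset(ids), sub_ped, cov,
                                     model=cfg.model, alpha=cfg.alpha)
            scans[name] = scan
            from .varcomp import write_results_csv

            write_results_csv(scan, out / f"heritability_{name}.csv",
                              comment=f"config={cfg_hash}")
            n_failed = int(scan["flag"].str.startswith("failed").sum())
            log.info("stage=heritability cohort=%s model=%s significant=%d "
                     "failed=%d", name, cfg.model, int(scan["significant"].sum()),
                     n_failed)
        log.info("stage=heritability elapsed=%.2fs", time.time() - t0)

        # ---- replication -------------------------------------------------
        summary = replication_overlap(scans["discovery"], scans["replication"])
        _write_csv(summary.to_frame(), out / "replication_summary.csv", cfg_hash)
        log.info("stage=replicate both=%d pct=%d total_elapsed=%.2fs",
                 summary.n_both, summary.pct_of_discovery, time.time() - t_all)
        paths.update({
            "heritability_discovery": out / "heritability_discovery.csv",
            "heritability_replication": out / "heritability_replication.csv",
            "replication_summary": out / "replication_summary.csv",
        })
        return RunResult(out, summary.to_frame(), paths)
    except Exception:
        log.exception("run failed")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
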