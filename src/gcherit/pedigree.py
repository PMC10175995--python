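"""Family structure: pedigree validation, kinship and household matrices,
and the kinship-aware discovery/replication split.

The cohorts handled here consist of monozygotic (MZ) and dizygotic (DZ)
twin pairs, full-sibling sets and singletons, as in large young-adult
family imaging samples. Under that structure the expected-relatedness
matrix ``2*Phi`` takes only the values 1 (self, MZ co-twins), 0.5 (DZ
co-twins and full siblings within a family) and 0 (across families), so
kinship is derived from group labels rather than from parental genealogy.
Household sharing defaults to family membership (a ``hhid`` column is
exposed so users can override it).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("MZ", "DZ", "SIB", "SINGLETON")

PEDIGREE_COLUMNS = ["id", "famid", "sex", "group", "twinpair", "hhid"]
COVARIATE_COLUMNS = ["id", "age", "sex", "handedness", "education"]

#: covariates entering the balance cost of the cohort split
_BALANCE_COLS = ["age", "education", "sex", "handedness"]


class PedigreeError(ValueError):
    pass


class SplitError(RuntimeError):
    """Raised when no admissible discovery/replication split exists."""


@dataclass(frozen=True)
class Pedigree:
    """Validated family-structure table.

    Columns: ``id, famid, sex, group, twinpair, hhid``. ``group`` is one of
    MZ, DZ, SIB, SINGLETON; ``twinpair`` identifies co-twins (exactly two
    rows per value) and is empty for non-twins; ``hhid`` defaults to
    ``famid``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = [c for c in ("id", "famid", "group") if c not in df.columns]
        if missing:
            raise PedigreeError(f"missing pedigree columns: {missing}")
        df["id"] = df["id"].astype(str)
        df["famid"] = df["famid"].astype(str)
        if "sex" not in df.columns:
            df["sex"] = "F"
        if "twinpair" not in df.columns:
            df["twinpair"] = None
        if "hhid" not in df.columns or df["hhid"].isna().all():
            df["hhid"] = df["famid"]
        df["hhid"] = df["hhid"].where(~pd.isna(df["hhid"]), df["famid"]).astype(str)

        dup = df["id"][df["id"].duplicated()]
        if len(dup):
            raise PedigreeError(f"duplicate individual id(s): {sorted(set(dup))}")
        bad = set(df["group"]) - set(GROUPS)
        if bad:
            raise PedigreeError(f"unknown group label(s): {sorted(bad)}")

        tp = df.loc[~pd.isna(df["twinpair"]) & (df["twinpair"] != ""), "twinpair"]
        for pair_id, sub in df[df["twinpair"].isin(tp)].groupby("twinpair"):
            if len(sub) != 2:
                raise PedigreeError(f"twin pair {pair_id!r} has {len(sub)} members, expected 2")
            if sub["famid"].nunique() != 1 or sub["group"].nunique() != 1:
                raise PedigreeError(f"twin pair {pair_id!r} spans families or groups")
            if sub["group"].iloc[0] not in ("MZ", "DZ"):
                raise PedigreeError(f"twin pair {pair_id!r} carries non-twin group label")
        singleton_with_pair = df[(df["group"] == "SINGLETON") & df["twinpair"].isin(tp)]
        if len(singleton_with_pair):
            raise PedigreeError("SINGLETON records must not carry a twin_pair id")

        object.__setattr__(self, "table", df.reset_index(drop=True))

    # -- accessors ---------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    def families(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for fid, sub in self.table.groupby("famid", sort=True):
            out[fid] = list(sub["id"])
        return out

    def subset(self, ids: list[str]) -> "Pedigree":
        keep = self.table[self.table["id"].isin(set(ids))]
        return Pedigree(keep.reset_index(drop=True))

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path) -> "Pedigree":
        return cls(pd.read_csv(path, dtype={"id": str, "famid": str}, comment="#"))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


@dataclass(frozen=True)
class KinshipMatrix:
    """Expected-relatedness matrix holding 2*Phi values (n x n)."""

    values: np.ndarray
    ids: tuple[str, ...]

    def dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


@dataclass(frozen=True)
class HouseholdMatrix:
    """Binary shared-household indicator matrix (n x n, diagonal 1)."""

    values: np.ndarray
    ids: tuple[str, ...]

    def dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


def build_kinship(ped: Pedigree) -> KinshipMatrix:
    """Build the ``2*Phi`` matrix from group labels.

    MZ co-twins get 1, DZ co-twins and full siblings within a family 0.5,
    unrelated (cross-family) pairs 0; the diagonal is 1.
    """
    df = ped.table
    n = ped.n
    K = np.zeros((n, n))
    idx = {sid: i for i, sid in enumerate(df["id"])}
    for _, sub in df.groupby("famid"):
        members = [idx[s] for s in sub["id"]]
        for a in members:
            for b in members:
                if a != b:
                    K[a, b] = 0.5
        # co-twins of an MZ pair share their full genome
        for pair_id, twins in sub[sub["group"] == "MZ"].groupby("twinpair"):
            if pd.isna(pair_id) or pair_id == "":
                continue
            i, j = (idx[s] for s in twins["id"])
            K[i, j] = K[j, i] = 1.0
    np.fill_diagonal(K, 1.0)
    return KinshipMatrix(K, tuple(df["id"]))


def build_household(ped: Pedigree) -> HouseholdMatrix:
    """Binary matrix with entry 1 iff two individuals share ``hhid``."""
    hh = ped.table["hhid"].to_numpy()
    H = (hh[:, None] == hh[None, :]).astype(float)
    return HouseholdMatrix(H, tuple(ped.table["id"]))


# ---------------------------------------------------------------------------
# Discovery/replication split
# ---------------------------------------------------------------------------


def _validate_covariates(ped: Pedigree, cov: pd.DataFrame) -> pd.DataFrame:
    cov = cov.copy()
    cov["id"] = cov["id"].astype(str)
    missing = [c for c in COVARIATE_COLUMNS if c not in cov.columns]
    if missing:
        raise PedigreeError(f"missing covariate columns: {missing}")
    cov = cov.set_index("id")
    absent = [i for i in ped.ids if i not in cov.index]
    if absent:
        raise PedigreeError(f"covariates missing for ids: {absent[:5]}")
    sub = cov.loc[ped.ids, ["age", "sex", "handedness", "education"]]
    if sub.isna().any().any():
        raise PedigreeError("covariate table contains missing values")
    return sub.astype(float)


def _family_stats(ped: Pedigree, cov: pd.DataFrame):
    """Per-family member count, covariate sums/sum-of-squares, signature."""
    df = ped.table.merge(cov, left_on="id", right_index=True, suffixes=("_ped", ""))
    fams, sigs, s1, s2, counts, members = [], [], [], [], [], []
    for fid, sub in df.groupby("famid", sort=True):
        fams.append(fid)
        grp = sub["group"].value_counts().sort_index()
        sigs.append(tuple(grp.items()))
        x = sub[_BALANCE_COLS].to_numpy(float)
        s1.append(x.sum(axis=0))
        s2.append((x**2).sum(axis=0))
        counts.append(len(sub))
        members.append(list(sub["id"]))
    return fams, sigs, np.array(s1), np.array(s2), np.array(counts), members


def _std_diffs(aggA, aggB) -> np.ndarray:
    """Absolute standardized mean differences from side aggregates."""
    nA, s1A, s2A = aggA
    nB, s1B, s2B = aggB
    mA, mB = s1A / nA, s1B / nB
    vA = np.maximum(s2A / nA - mA**2, 0.0) * nA / max(nA - 1, 1)
    vB = np.maximum(s2B / nB - mB**2, 0.0) * nB / max(nB - 1, 1)
    pooled = np.sqrt((vA + vB) / 2)
    diff = np.abs(mA - mB)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(pooled > 0, diff / np.where(pooled > 0, pooled, 1.0),
                       np.where(diff > 0, np.inf, 0.0))
    return out


def split_cohort(
    ped: Pedigree,
    cov: pd.DataFrame,
    seed: int = 0,
    max_std_diff: float = 0.05,
    max_restarts: int = 20,
) -> tuple[list[str], list[str], list[str]]:
    """Split a cohort into matched halves without breaking families.

    Families are grouped by composition signature (their multiset of group
    labels); within each signature class families are shuffled and dealt
    alternately to the two sides, which guarantees identical MZ/DZ/SIB/
    SINGLETON counts on both sides. A greedy same-class swap pass then
    reduces the worst absolute standardized covariate difference (age,
    education, sex, handedness). If after ``max_restarts`` random restarts
    the balance target is still unmet, matched same-class family pairs are
    excluded (one from each side) until it is, mirroring the exclusion step
    of interactive cohort-matching tools. One family per odd-sized signature
    class is excluded up front since it cannot be mirrored.

    Returns ``(side_a_ids, side_b_ids, excluded_ids)``; deterministic for a
    fixed ``seed``.
    """
    covt = _validate_covariates(ped, cov)
    fams, sigs, s1, s2, counts, members = _family_stats(ped, covt)
    nfam = len(fams)
    if nfam == 0:
        raise SplitError("empty pedigree")
    classes: dict[tuple, list[int]] = {}
    for i, sig in enumerate(sigs):
        classes.setdefault(sig, []).append(i)

    rng = np.random.default_rng(seed)
    base_excluded: list[int] = []
    even_classes: dict[tuple, list[int]] = {}
    for sig in sorted(classes):
        lst = sorted(classes[sig])
        if len(lst) % 2 == 1:
            drop = lst[int(rng.integers(len(lst)))]
            base_excluded.append(drop)
            lst = [f for f in lst if f != drop]
        if lst:
            even_classes[sig] = lst
    if not even_classes:
        blocking = ", ".join(str(s) for s in sorted(classes))
        raise SplitError(f"no splittable families; blocking signatures: {blocking}")

    def agg(side: list[int]):
        idx = np.array(side, dtype=int)
        return counts[idx].sum(), s1[idx].sum(axis=0), s2[idx].sum(axis=0)

    def cost(A: list[int], B: list[int]) -> float:
        return float(_std_diffs(agg(A), agg(B)).max())

    best_assign, best_cost = None, np.inf
    for _ in range(max(1, max_restarts)):
        A: list[int] = []
        B: list[int] = []
        for sig in sorted(even_classes):
            lst = list(even_classes[sig])
            perm = rng.permutation(len(lst))
            half = len(lst) // 2
            A += [lst[k] for k in perm[:half]]
            B += [lst[k] for k in perm[half:]]
        A, B = _improve_by_swaps(A, B, sigs, counts, s1, s2)
        c = cost(A, B)
        if c < best_cost:
            best_assign, best_cost = (list(A), list(B)), c
        if c <= max_std_diff:
            break

    A, B = best_assign
    excluded = list(base_excluded)
    # exclusion phase: drop matched same-class pairs until balance is reached
    while best_cost > max_std_diff:
        improved = False
        best_pair, pair_cost = None, best_cost
        by_sig_A: dict[tuple, list[int]] = {}
        by_sig_B: dict[tuple, list[int]] = {}
        for f in A:
            by_sig_A.setdefault(sigs[f], []).append(f)
        for f in B:
            by_sig_B.setdefault(sigs[f], []).append(f)
        for sig in by_sig_A:
            for fa in by_sig_A[sig]:
                for fb in by_sig_B.get(sig, []):
                    trialA = [f for f in A if f != fa]
                    trialB = [f for f in B if f != fb]
                    if not trialA or not trialB:
                        continue
                    c = cost(trialA, trialB)
                    if c < pair_cost - 1e-12:
                        pair_cost, best_pair = c, (fa, fb)
        if best_pair is None:
            break
        fa, fb = best_pair
        A = [f for f in A if f != fa]
        B = [f for f in B if f != fb]
        excluded += [fa, fb]
        A, B = _improve_by_swaps(A, B, sigs, counts, s1, s2)
        best_cost = cost(A, B)
        improved = True
        if not improved:
            break
    if best_cost > max_std_diff:
        raise SplitError(
            f"covariate balance unreachable: best max std diff {best_cost:.3f} "
            f"> {max_std_diff}"
        )

    ids_a = [sid for f in sorted(A) for sid in members[f]]
    ids_b = [sid for f in sorted(B) for sid in members[f]]
    ids_ex = [sid for f in sorted(excluded) for sid in members[f]]
    return ids_a, ids_b, ids_ex


def _improve_by_swaps(A, B, sigs, counts, s1, s2, max_passes: int = 10):
    """Greedy hill-climbing on same-signature A<->B family swaps."""
    A, B = list(A), list(B)

    def agg(side):
        idx = np.array(side, dtype=int)
        return counts[idx].sum(), s1[idx].sum(axis=0), s2[idx].sum(axis=0)

    for _ in range(max_passes):
        nA, s1A, s2A = agg(A)
        nB, s1B, s2B = agg(B)
        cur = float(_std_diffs((nA, s1A, s2A), (nB, s1B, s2B)).max())
        best_swap, best_val = None, cur
        by_sig_A: dict[tuple, list[int]] = {}
        by_sig_B: dict[tuple, list[int]] = {}
        for f in A:
            by_sig_A.setdefault(sigs[f], []).append(f)
        for f in B:
            by_sig_B.setdefault(sigs[f], []).append(f)
        for sig, fa_list in by_sig_A.items():
            fb_list = by_sig_B.get(sig, [])
            for fa in fa_list:
                for fb in fb_list:
                    dn = counts[fb] - counts[fa]
                    d1 = s1[fb] - s1[fa]
                    d2 = s2[fb] - s2[fa]
                    val = float(
                        _std_diffs(
                            (nA + dn, s1A + d1, s2A + d2),
                            (nB - dn, s1B - d1, s2B - d2),
                        ).max()
                    )
                    if val < best_val - 1e-12:
                        best_val, best_swap = val, (fa, fb)
        if best_swap is None:
            break
        fa, fb = best_swap
        A[A.index(fa)] = fb
        B[B.index(fb)] = fa
    return A, B


def balance_report(
    side_a: list[str], side_b: list[str], ped: Pedigree, cov: pd.DataFrame
) -> pd.DataFrame:
    """Per-covariate standardized differences and two-sample tests.

    Welch's t-test for continuous covariates (age, education), chi-square
    for categorical ones (sex, handedness); group-composition counts are
    appended as extra rows. The standardized difference uses the pooled SD
    sqrt((var_a + var_b)/2).
    """
    if not side_a or not side_b:
        raise PedigreeError("balance_report requires two non-empty sides")
    if set(side_a) & set(side_b):
        raise PedigreeError("sides must be disjoint")
    covt = _validate_covariates(ped, cov)
    xa = covt.loc[[i for i in side_a]]
    xb = covt.loc[[i for i in side_b]]
    rows = []
    for col, kind in [("age", "welch_t"), ("education", "welch_t"),
                      ("sex", "chi2"), ("handedness", "chi2")]:
        a, b = xa[col].to_numpy(), xb[col].to_numpy()
        va, vb = a.var(ddof=1), b.var(ddof=1)
        pooled = np.sqrt((va + vb) / 2)
        diff = abs(a.mean() - b.mean())
        sd = diff / pooled if pooled > 0 else (0.0 if diff == 0 else np.inf)
        if kind == "welch_t":
            if pooled > 0:
                p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            else:
                p = 1.0
        else:
            tab = pd.crosstab(
                np.concatenate([np.zeros(len(a)), np.ones(len(b))]),
                np.concatenate([a, b]),
            ).to_numpy()
            if tab.shape[1] < 2:
                p = 1.0
            else:
                p = float(stats.chi2_contingency(tab, correction=False)[1])
        rows.append(dict(metric=col, mean_a=a.mean(), mean_b=b.mean(),
                         std_diff=sd, test=kind, p=p))
    ga = ped.table.set_index("id").loc[side_a, "group"].value_counts()
    gb = ped.table.set_index("id").loc[side_b, "group"].value_counts()
    for g in GROUPS:
        rows.append(dict(metric=f"n_{g}", mean_a=float(ga.get(g, 0)),
                         mean_b=float(gb.get(g, 0)), std_diff=np.nan,
                         test="count", p=np.nan))
    return pd.DataFrame(rows)
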