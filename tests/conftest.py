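import numpy as np
import pandas as pd
import pytest

from gcherit.pedigree import Pedigree
from gcherit.simulate import SimConfig, simulate_pedigree


@pytest.fixture(scope="session")
def table1_cohort():
    """Default-composition cohort (449 individuals) with covariates."""
    cfg = SimConfig(seed=11)
    ped, cov = simulate_pedigree(cfg)
    return cfg, ped, cov


@pytest.fixture
def tiny_pedigree():
    """One MZ pair, one DZ pair, a 3-sib family, and a singleton."""
    rows = [
        ("m1", "F1", "F", "MZ", "T1", "F1"),
        ("m2", "F1", "F", "MZ", "T1", "F1"),
        ("d1", "F2", "M", "DZ", "T2", "F2"),
        ("d2", "F2", "F", "DZ", "T2", "F2"),
        ("s1", "F3", "M", "SIB", None, "F3"),
        ("s2", "F3", "F", "SIB", None, "F3"),
        ("s3", "F3", "M", "SIB", None, "F3"),
        ("x1", "F4", "F", "SINGLETON", None, "F4"),
    ]
    return Pedigree(pd.DataFrame(
        rows, columns=["id", "famid", "sex", "group", "twinpair", "hhid"]))


def random_pedigree(rng: np.random.Generator, max_families: int = 30) -> Pedigree:
    """Random mix of MZ/DZ pairs, sibling sets and singletons."""
    rows = []
    pair = 0
    n_fam = int(rng.integers(1, max_families + 1))
    for f in range(n_fam):
        fid = f"F{f:03d}"
        kind = rng.choice(["MZ", "DZ", "SIB", "SINGLETON"])
        if kind in ("MZ", "DZ"):
            pair += 1
            sex = rng.choice(["M", "F"])
            for j in range(2):
                s = sex if kind == "MZ" else rng.choice(["M", "F"])
                rows.append((f"I{len(rows)}", fid, s, kind, f"T{pair}", fid))
        elif kind == "SIB":
            for j in range(int(rng.integers(2, 5))):
                rows.append((f"I{len(rows)}", fid, rng.choice(["M", "F"]),
                             "SIB", None, fid))
        else:
            rows.append((f"I{len(rows)}", fid, rng.choice(["M", "F"]),
                         "SINGLETON", None, fid))
    return Pedigree(pd.DataFrame(
        rows, columns=["id", "famid", "sex", "group", "twinpair", "hhid"]))
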