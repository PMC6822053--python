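"""Permutation Mantel test between two aligned distance matrices.

The statistic is the Pearson correlation of the strictly-lower-triangle
entries of the two matrices.  The null distribution is built by jointly
permuting the rows and columns of the second matrix; under permutation
the correlation form is a strictly increasing function of the classical
cross-product (sum-of-products) form, so the two give identical
permutation rankings and p-values.  Confidence limits come from a
species-level percentile bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

__all__ = [
    "MantelResult",
    "mantel_statistic",
    "cross_product_sum",
    "mantel_test",
    "mantel_report",
]


@dataclass
class MantelResult:
    """One Mantel-test row: observed r, permutation p, bootstrap limits."""

    r_obs: float
    p: float
    ci_low: float
    ci_high: float
    n_perm: int
    n_boot: int
    n_species: int
    seed: int | None
    tail: str = "greater"
    exact: bool = False


def _as_array(m) -> np.ndarray:
    a = m.to_numpy(float) if isinstance(m, pd.DataFrame) else np.asarray(m, float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(a, a.T, equal_nan=True):
        raise ValueError("matrix must be symmetric")
    return a


def _check_pair(m1, m2) -> tuple[np.ndarray, np.ndarray]:
    a1, a2 = _as_array(m1), _as_array(m2)
    if a1.shape != a2.shape:
        raise ValueError(f"matrix shapes differ: {a1.shape} vs {a2.shape}")
    if isinstance(m1, pd.DataFrame) and isinstance(m2, pd.DataFrame):
        if list(m1.index) != list(m2.index):
            raise ValueError("matrices are not aligned to the same species order")
    if a1.shape[0] < 4:
        raise ValueError("need at least 4 species")
    return a1, a2


def _tri(a: np.ndarray) -> np.ndarray:
    iu = np.tril_indices(a.shape[0], k=-1)
    return a[iu]


def mantel_statistic(m1, m2) -> float:
    """Pearson correlation of the strictly-lower triangles of m1, m2."""
    a1, a2 = _check_pair(m1, m2)
    v1, v2 = _tri(a1), _tri(a2)
    if v1.std() == 0 or v2.std() == 0:
        raise ValueError("zero variance in a matrix's lower triangle")
    return float(np.corrcoef(v1, v2)[0, 1])


def cross_product_sum(m1, m2) -> float:
    """Classical Mantel Z: sum over pairs of m1[i,j]*m2[i,j].

    Monotone-equivalent to the correlation form under permutation (the
    permutation only reorders m2's entries, leaving both triangles'
    means and variances fixed).
    """
    a1, a2 = _check_pair(m1, m2)
    return float(_tri(a1) @ _tri(a2))


def _perm_stats(
    a1: np.ndarray, a2: np.ndarray, perms: np.ndarray
) -> np.ndarray:
    """Correlation statistic for each row of ``perms`` applied to m2."""
    n = a1.shape[0]
    iu, ju = np.tril_indices(n, k=-1)
    v1 = a1[iu, ju]
    v1c = v1 - v1.mean()
    denom1 = np.sqrt((v1c**2).sum())
    out = np.empty(len(perms))
    for k, p in enumerate(perms):
        v2 = a2[p[iu], p[ju]]
        v2c = v2 - v2.mean()
        denom2 = np.sqrt((v2c**2).sum())
        out[k] = (v1c @ v2c) / (denom1 * denom2)
    return out


def mantel_test(
    m1,
    m2,
    n_perm: int = 9999,
    seed: int | None = None,
    tail: str = "greater",
    n_boot: int = 500,
) -> MantelResult:
    """Permutation Mantel test with bootstrap confidence limits.

    ``tail="greater"`` (default) tests for positive matrix association:
    p = (#{permuted r >= observed r} + 1) / (n_perm + 1).  When n! <=
    n_perm the test enumerates all n! relabelings exactly instead of
    sampling (p = #{r_perm >= r_obs} / n!, identity included).
    Confidence limits are the 2.5/97.5 percentiles of the statistic over
    ``n_boot`` resamples of species with replacement.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if tail not in ("greater", "less", "two"):
        raise ValueError(f"unknown tail {tail!r}")
    a1, a2 = _check_pair(m1, m2)
    n = a1.shape[0]
    r_obs = mantel_statistic(a1, a2)
    rng = np.random.default_rng(seed)

    exact = math.factorial(n) <= n_perm
    if exact:
        perms = np.array(list(permutations(range(n))))
    else:
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    stats = _perm_stats(a1, a2, perms)

    eps = 1e-12
    if tail == "greater":
        hits = int((stats >= r_obs - eps).sum())
    elif tail == "less":
        hits = int((stats <= r_obs + eps).sum())
    else:
        hits = int((np.abs(stats) >= abs(r_obs) - eps).sum())
    if exact:
        p = hits / len(perms)
    else:
        p = (hits + 1) / (n_perm + 1)

    if n_boot == 0:
        return MantelResult(
            r_obs=r_obs, p=float(p), ci_low=float("nan"),
            ci_high=float("nan"), n_perm=len(perms) if exact else n_perm,
            n_boot=0, n_species=n, seed=seed, tail=tail, exact=exact,
        )
    boot = np.empty(n_boot)
    iu, ju = np.tril_indices(n, k=-1)
    k = 0
    attempts = 0
    while k < n_boot and attempts < 20 * n_boot:
        attempts += 1
        idx = rng.integers(0, n, size=n)
        # pairs of two copies of the same species are zero in both
        # matrices by construction; including them would bias r upward
        keep = idx[iu] != idx[ju]
        if keep.sum() < 3:
            continue
        v1 = a1[idx[iu[keep]], idx[ju[keep]]]
        v2 = a2[idx[iu[keep]], idx[ju[keep]]]
        if v1.std() == 0 or v2.std() == 0:
            continue  # degenerate resample (e.g. one species repeated)
        boot[k] = np.corrcoef(v1, v2)[0, 1]
        k += 1
    if k < n_boot:
        raise ValueError("bootstrap resamples are persistently degenerate")
    ci_low, ci_high = np.percentile(boot, [2.5, 97.5])

    return MantelResult(
        r_obs=r_obs,
        p=float(p),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_perm=len(perms) if exact else n_perm,
        n_boot=n_boot,
        n_species=n,
        seed=seed,
        tail=tail,
        exact=exact,
    )


def mantel_report(
    pairs: list[tuple[str, str, pd.DataFrame, pd.DataFrame]],
    n_perm: int = 9999,
    seed: int | None = None,
    n_boot: int = 500,
    tail: str = "greater",
) -> pd.DataFrame:
    """Run one Mantel test per named matrix pair and tabulate the results.

    Output columns mirror a published matrix-association summary:
    matrix1, matrix2, mantel_r, p_value, ci_lower, ci_upper (plus
    bookkeeping columns n_species, n_perm, n_boot, seed).  Rows keep the
    input order; each test draws its own substream of the seed so the
    table is reproducible row by row.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(pairs)) if pairs else []
    rows = []
    for (name1, name2, m1, m2), child in zip(pairs, children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        res = mantel_test(
            m1, m2, n_perm=n_perm, seed=sub_seed, tail=tail, n_boot=n_boot
        )
        rows.append(
            {
                "matrix1": name1,
                "matrix2": name2,
                "mantel_r": res.r_obs,
                "p_value": res.p,
                "ci_lower": res.ci_low,
                "ci_upper": res.ci_high,
                "n_species": res.n_species,
                "n_perm": res.n_perm,
                "n_boot": res.n_boot,
                "seed": sub_seed,
            }
        )
    columns = [
        "matrix1", "matrix2", "mantel_r", "p_value", "ci_lower", "ci_upper",
        "n_species", "n_perm", "n_boot", "seed",
    ]
    return pd.DataFrame(rows, columns=columns)
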