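"""Permutation and rank-correlation inference for dyadic matrices.

The Mantel test asks whether two square matrices indexed by the same
individuals covary: the statistic is the Pearson correlation over
off-diagonal dyadic cells, and its null distribution is obtained by jointly
permuting the rows and columns of one matrix with the same random
permutation of individuals, which preserves each matrix's internal
dependence structure. Missing dyads (NaN cells, e.g. never-observed
associations) are pairwise-deleted, both in the observed statistic and in
every permutation.

Rank correlations among node-level metric vectors (Spearman for
indegree/outdegree relationships, Kendall's tau-b for betweenness against
degree) delegate to scipy.stats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .matrices import LabeledMatrix, symmetrize
from .metrics import density as _density
from .metrics import random_network

TAILS = ("two_sided", "greater", "less")


@dataclass(frozen=True)
class MantelResult:
    matrix_a_name: str
    matrix_b_name: str
    r: float
    p_value: float
    n_permutations: int
    seed: int | None
    tail: str
    n: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class CorrelationResult:
    metric_x: str
    metric_y: str
    coefficient: float
    p_value: float
    method: str
    n: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _as_matrix(m, name: str = "") -> tuple[np.ndarray, tuple[str, ...], str]:
    if isinstance(m, LabeledMatrix):
        return np.asarray(m.values, dtype=float), m.ids, m.name or name
    if isinstance(m, pd.DataFrame):
        return m.to_numpy(dtype=float), tuple(map(str, m.columns)), name
    a = np.asarray(m, dtype=float)
    return a, tuple(f"N{k}" for k in range(a.shape[0])), name


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x @ x) * (y @ y))
    if denom == 0:
        return float("nan")
    return float(np.clip((x @ y) / denom, -1.0, 1.0))


def mantel_test(
    a,
    b,
    n_permutations: int = 10_000,
    tail: str = "two_sided",
    seed: int | np.random.Generator | None = None,
    names: tuple[str, str] = ("A", "B"),
) -> MantelResult:
    """Mantel matrix-permutation test between two symmetric matrices.

    ``r`` is the Pearson correlation over upper-triangle dyadic cells
    (pairwise-deleting missing cells); the null distribution permutes the
    individuals of ``b`` (rows and columns together) ``n_permutations``
    times, and the p-value carries the add-one correction
    ``(1 + #{|r*| >= |r|}) / (n_permutations + 1)`` for the two-sided tail
    (signed comparisons for ``greater`` / ``less``), so the smallest
    attainable p is ``1 / (n_permutations + 1)``.
    """
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}, got {tail!r}")
    va, ids_a, name_a = _as_matrix(a, names[0])
    vb, ids_b, name_b = _as_matrix(b, names[1])
    if ids_a != ids_b:
        raise ValueError("matrices must share the same individuals in the same order")
    n = va.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs at least 4 individuals")
    if not np.allclose(va, va.T, equal_nan=True) or not np.allclose(vb, vb.T, equal_nan=True):
        raise ValueError(
            "Mantel test expects symmetric matrices; symmetrize directed matrices first"
        )
    iu, ju = np.triu_indices(n, 1)
    xa = va[iu, ju]
    xb = vb[iu, ju]
    valid = np.isfinite(xa) & np.isfinite(xb)
    if valid.sum() < 3:
        raise ValueError("too few defined dyads for a Mantel correlation")
    if np.nanstd(xa[valid]) == 0 or np.nanstd(xb[valid]) == 0:
        raise ValueError("constant matrix: Mantel correlation undefined")
    r_obs = _pearson(xa[valid], xb[valid])

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_int = seed if isinstance(seed, (int, np.integer)) else None

    has_missing = bool(np.isnan(va[iu, ju]).any() or np.isnan(vb[iu, ju]).any())
    perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
    if not has_missing:
        # vectorized: gather all permuted b's upper-triangle cells at once
        pb = vb[perms[:, :, None], perms[:, None, :]]          # (P, n, n)
        yb = pb[:, iu, ju]                                     # (P, m)
        yb_c = yb - yb.mean(axis=1, keepdims=True)
        xa_c = xa - xa.mean()
        denom = np.sqrt((xa_c @ xa_c) * (yb_c * yb_c).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r_perm = (yb_c @ xa_c) / denom
    else:
        r_perm = np.empty(n_permutations)
        for k in range(n_permutations):
            p = perms[k]
            yb = vb[p[:, None], p[None, :]][iu, ju]
            m = np.isfinite(xa) & np.isfinite(yb)
            r_perm[k] = _pearson(xa[m], yb[m]) if m.sum() >= 3 else np.nan

    eps = 1e-12
    if tail == "two_sided":
        exceed = np.abs(r_perm) >= np.abs(r_obs) - eps
    elif tail == "greater":
        exceed = r_perm >= r_obs - eps
    else:
        exceed = r_perm <= r_obs + eps
    p = (1 + int(np.nansum(exceed))) / (n_permutations + 1)
    return MantelResult(
        matrix_a_name=name_a,
        matrix_b_name=name_b,
        r=r_obs,
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed_int,
        tail=tail,
        n=n,
    )


def mantel_panel(
    networks: Mapping[str, LabeledMatrix | pd.DataFrame],
    attributes: Mapping[str, LabeledMatrix | pd.DataFrame],
    n_permutations: int = 10_000,
    seed: int | None = None,
    include_random: bool = True,
    symmetrization: str = "sum",
    tail: str = "two_sided",
) -> pd.DataFrame:
    """All network×network and attribute×network Mantel tests as a tidy table.

    Directed network matrices are symmetrized (default i↔j sum) before
    testing. When ``include_random`` is set, each network is additionally
    tested against one fresh density-matched binary random network (the
    draw's seed is recorded in the output). Columns:
    ``matrix_a, matrix_b, r, p_value, n_permutations, seed, tail``.
    """
    rng = np.random.default_rng(seed)

    def prep(m, name):
        v, ids, _ = _as_matrix(m, name)
        if not np.allclose(v, v.T, equal_nan=True):
            v = symmetrize(v, symmetrization)
        return pd.DataFrame(v, index=list(ids), columns=list(ids))

    nets = {k: prep(v, k) for k, v in networks.items()}
    attrs = {k: prep(v, k) for k, v in attributes.items()}
    rows = []

    def run(name_a, ma, name_b, mb):
        sub = int(rng.integers(0, 2**31 - 1))
        try:
            res = mantel_test(
                ma, mb, n_permutations=n_permutations, tail=tail, seed=sub, names=(name_a, name_b)
            )
        except ValueError:
            # constant matrix (e.g. a complete association network with all
            # indices equal) has no defined Mantel correlation
            res = MantelResult(name_a, name_b, float("nan"), float("nan"),
                               n_permutations, sub, tail, ma.shape[0])
        rows.append(res.to_dict())

    net_names = list(nets)
    for i, na in enumerate(net_names):
        for nb in net_names[i + 1:]:
            run(na, nets[na], nb, nets[nb])
    for nb in net_names:
        for na, ma in attrs.items():
            run(na, ma, nb, nets[nb])
        if include_random:
            ids = tuple(nets[nb].columns)
            d = _density(nets[nb].to_numpy(), directed=False)
            rnd = random_network(len(ids), d, directed=False, seed=rng, ids=ids)
            run("random", rnd.to_dataframe(), nb, nets[nb])
    return pd.DataFrame(rows)


def panel_blocks(panel: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pivot a tidy Mantel panel into p-value and coefficient blocks.

    Rows are the 'a' matrices (networks in the upper-triangular block, then
    attributes), columns the 'b' networks — the conventional layout of a
    network-by-attribute Mantel table.
    """
    p_block = panel.pivot(index="matrix_a_name", columns="matrix_b_name", values="p_value")
    r_block = panel.pivot(index="matrix_a_name", columns="matrix_b_name", values="r")
    return p_block, r_block


def rank_correlation(
    x: pd.Series | Sequence[float],
    y: pd.Series | Sequence[float],
    method: str = "spearman",
    names: tuple[str, str] = ("x", "y"),
) -> CorrelationResult:
    """Spearman (midranks) or Kendall tau-b correlation with asymptotic p."""
    xs = pd.Series(x, dtype=float)
    ys = pd.Series(y, dtype=float)
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        if list(xs.index) != list(ys.index):
            raise ValueError("metric vectors must share the same individuals")
        names = (str(xs.name) if xs.name is not None else names[0],
                 str(ys.name) if ys.name is not None else names[1])
    if len(xs) != len(ys):
        raise ValueError("vectors must have equal length")
    if len(xs) < 3:
        raise ValueError("need at least 3 individuals")
    if xs.nunique() < 2 or ys.nunique() < 2:
        raise ValueError("constant vector: rank correlation undefined")
    if method == "spearman":
        coef, p = sps.spearmanr(xs, ys)
    elif method == "kendall_tau":
        coef, p = sps.kendalltau(xs, ys)  # tau-b, handles ties
    else:
        raise ValueError(f"unknown method {method!r}; expected spearman|kendall_tau")
    return CorrelationResult(names[0], names[1], float(coef), float(p), method, len(xs))


def leave_one_out(
    x: pd.Series,
    y: pd.Series,
    drop: str,
    method: str = "spearman",
) -> tuple[CorrelationResult, CorrelationResult]:
    """Rank correlation with and without one individual, side by side.

    Used to check whether a single extreme individual (e.g. a male who
    initiates almost nothing) drives an otherwise significant correlation.
    """
    if drop not in x.index or drop not in y.index:
        raise KeyError(f"id {drop!r} not present in the metric vectors")
    full = rank_correlation(x, y, method=method)
    reduced = rank_correlation(x.drop(drop), y.drop(drop), method=method)
    return full, reduced
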