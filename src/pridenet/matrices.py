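"""Dyadic matrices: association indices, interaction counts, attributes.

Three matrix families feed the network analysis:

* **Association matrix** — symmetric, built from group-composition scans
  under the gambit of the group with a modified simple ratio index
  ``X / (X + Y_A + Y_B)`` where, for a dyad {A, B}, ``X`` counts scans with
  both present, ``Y_A`` scans with A present and B absent, and ``Y_B`` the
  converse. The classical SRI's ``Y_AB`` term (seen simultaneously in
  *different* groups) is excluded: with a single observation platform it
  cannot be determined with confidence. Index 1 = always together,
  0 = never together; a dyad never observed at all is *missing* (NaN),
  not zero.
* **Interaction matrices** — directed bout counts per behaviour
  (play, greeting, social licking) plus their elementwise sum
  (``all_social``); entry (i, j) counts bouts initiated by i toward j.
* **Attribute matrices** — symmetric similarity matrices on individual
  traits (kinship, same-sex, age similarity, half/full sibling indicators)
  used as Mantel-test predictors.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .observations import ALL_SOCIAL, BEHAVIORS, GroupScan, Individual, InteractionEvent

logger = logging.getLogger(__name__)

ATTRIBUTE_KINDS = ("kinship", "gender_similarity", "age_similarity", "half_sibling", "full_sibling")


@dataclass
class LabeledMatrix:
    """A square matrix labelled by individual ids (roster order)."""

    ids: tuple[str, ...]
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index_label="id")

    def to_edgelist(self, directed: bool = False) -> pd.DataFrame:
        """Weighted edge list of the nonzero, non-missing off-diagonal cells."""
        rows = []
        for i, a in enumerate(self.ids):
            for j, b in enumerate(self.ids):
                if i == j or (not directed and j <= i):
                    continue
                w = self.values[i, j]
                if np.isnan(w) or w == 0:
                    continue
                rows.append((a, b, w))
        return pd.DataFrame(rows, columns=["source", "target", "weight"])

    @classmethod
    def from_csv(cls, path: str | Path, **kw) -> "LabeledMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(ids=tuple(str(c) for c in df.columns), values=df.to_numpy(dtype=float), **kw)


@dataclass
class AssociationMatrix(LabeledMatrix):
    """Symmetric simple-ratio-index matrix; NaN marks never-observed dyads."""

    name: str = "composition"

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("association matrix must be symmetric")
        with np.errstate(invalid="ignore"):
            off = self.values[~np.eye(self.n, dtype=bool)]
            bad = off[np.isfinite(off)]
            if bad.size and (bad.min() < 0 or bad.max() > 1):
                raise ValueError("association indices must lie in [0, 1]")
        np.fill_diagonal(self.values, 0.0)


@dataclass
class InteractionMatrix(LabeledMatrix):
    """Directed bout-count matrix for one behaviour (or the all-social sum)."""

    behavior: str = ALL_SOCIAL

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.behavior not in BEHAVIORS + (ALL_SOCIAL,):
            raise ValueError(f"unknown behavior {self.behavior!r}")
        if np.any(self.values < 0) or not np.allclose(self.values, np.round(self.values)):
            raise ValueError("interaction counts must be non-negative integers")
        np.fill_diagonal(self.values, 0.0)
        if not self.name:
            self.name = self.behavior


@dataclass
class AttributeMatrix(LabeledMatrix):
    """Symmetric trait-similarity matrix used as a Mantel predictor."""

    kind: str = "kinship"

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.kind not in ATTRIBUTE_KINDS:
            raise ValueError(f"unknown attribute kind {self.kind!r}")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("attribute matrix must be symmetric")
        if not self.name:
            self.name = self.kind


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def simple_ratio_index(x: float, y_a: float, y_b: float) -> float:
    """Modified simple ratio index ``X / (X + Y_A + Y_B)``.

    Returns NaN when the dyad was never observed (all three counts zero):
    an unobserved dyad carries no information and must not masquerade as
    "never together" (index 0).
    """
    if min(x, y_a, y_b) < 0:
        raise ValueError("counts must be non-negative")
    denom = x + y_a + y_b
    if denom == 0:
        return float("nan")
    return x / denom


def build_association_matrix(
    scans: Sequence[GroupScan], ids: Sequence[str], name: str = "composition"
) -> AssociationMatrix:
    """Per-dyad simple ratio indices tallied over group-composition scans.

    For each unordered dyad {A, B}: X counts scans where both are present,
    Y_A scans with A present and B absent, Y_B the converse. Scans that
    record neither member of a dyad contribute nothing to it. Dyads with no
    joint observability yield NaN and a warning.
    """
    ids = tuple(ids)
    idx = {a: k for k, a in enumerate(ids)}
    n = len(ids)
    present = np.zeros((len(scans), n), dtype=bool)
    absent = np.zeros((len(scans), n), dtype=bool)
    for s_i, scan in enumerate(scans):
        for a in scan.present:
            if a in idx:
                present[s_i, idx[a]] = True
        for a in scan.absent:
            if a in idx:
                absent[s_i, idx[a]] = True

    pf = present.astype(np.int64)
    af = absent.astype(np.int64)
    x = pf.T @ pf          # both present
    y_a = pf.T @ af        # row id present, column id absent (Y for the row)
    denom = x + y_a + y_a.T
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(denom > 0, x / np.maximum(denom, 1), np.nan)
    np.fill_diagonal(vals, 0.0)

    iu = np.triu_indices(n, 1)
    n_missing = int(np.isnan(vals[iu]).sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} dyad(s) never jointly observable; association left missing",
            stacklevel=2,
        )
    return AssociationMatrix(ids=ids, values=vals, name=name)


def build_interaction_matrix(
    events: Iterable[InteractionEvent], behavior: str, ids: Sequence[str]
) -> InteractionMatrix:
    """Directed bout-count matrix; ``behavior='all_social'`` sums all three."""
    if behavior not in BEHAVIORS + (ALL_SOCIAL,):
        raise ValueError(f"unknown behavior {behavior!r}")
    ids = tuple(ids)
    idx = {a: k for k, a in enumerate(ids)}
    counts = np.zeros((len(ids), len(ids)), dtype=float)
    wanted = BEHAVIORS if behavior == ALL_SOCIAL else (behavior,)
    for ev in events:
        if ev.behavior in wanted and ev.initiator in idx and ev.recipient in idx:
            counts[idx[ev.initiator], idx[ev.recipient]] += 1
    return InteractionMatrix(ids=ids, values=counts, behavior=behavior)


def build_interaction_matrices(
    events: Iterable[InteractionEvent], ids: Sequence[str]
) -> dict[str, InteractionMatrix]:
    """All three behaviour matrices plus their all-social sum."""
    events = tuple(events)
    out = {b: build_interaction_matrix(events, b, ids) for b in BEHAVIORS}
    out[ALL_SOCIAL] = build_interaction_matrix(events, ALL_SOCIAL, ids)
    return out


def build_attribute_matrix(
    roster: Sequence[Individual],
    kinship: pd.DataFrame | None,
    kind: str,
    *,
    reference_date: dt.date | None = None,
    half_sibling_band: tuple[float, float] = (0.25, 0.5),
    sibling_pairs: set[frozenset[str]] | None = None,
) -> AttributeMatrix:
    """Build one similarity-oriented attribute matrix.

    kinds:

    * ``kinship`` — the relatedness coefficients themselves;
    * ``gender_similarity`` — 1 iff same sex;
    * ``age_similarity`` — ``1 - |Δage| / max|Δage|`` over birth dates
      (all 1 when every age is equal), so that, like the other attributes,
      larger means more similar and Mantel signs are comparable;
    * ``half_sibling`` — 1 iff relatedness falls in ``half_sibling_band``
      (default [0.25, 0.5), which also captures inbred-litter values such
      as 0.313);
    * ``full_sibling`` — 1 iff relatedness >= 0.5 **and** the dyad is a
      sibling rather than parent-offspring pair. Parent-offspring dyads
      share r = 0.5 too, so a pedigree flag is needed; absent explicit
      ``sibling_pairs``, same age class (adult/adult or cub/cub) is used
      as the generation proxy.
    """
    if kind not in ATTRIBUTE_KINDS:
        raise ValueError(f"unknown attribute kind {kind!r}; expected one of {ATTRIBUTE_KINDS}")
    ids = tuple(ind.id for ind in roster)
    n = len(ids)
    vals = np.zeros((n, n), dtype=float)

    if kind == "gender_similarity":
        sexes = [ind.sex for ind in roster]
        for i in range(n):
            for j in range(n):
                vals[i, j] = 1.0 if i != j and sexes[i] == sexes[j] else 0.0
    elif kind == "age_similarity":
        ref = reference_date or dt.date.today()
        ages = np.array(
            [ind.age_years(ref) if ind.age_years(ref) is not None else np.nan for ind in roster]
        )
        if np.isnan(ages).any():
            # fall back to the coarse adult/cub classes when birth dates are partial
            ages = np.array([0.0 if ind.is_cub() else 1.0 for ind in roster])
        diff = np.abs(ages[:, None] - ages[None, :])
        top = diff.max()
        vals = np.ones((n, n)) if top == 0 else 1.0 - diff / top
    else:
        if kinship is None:
            raise ValueError(f"attribute kind {kind!r} requires a kinship matrix")
        k = kinship.reindex(index=list(ids), columns=list(ids)).fillna(0.0).to_numpy(dtype=float)
        if kind == "kinship":
            vals = k.copy()
        elif kind == "half_sibling":
            lo, hi = half_sibling_band
            vals = ((k >= lo) & (k < hi)).astype(float)
        else:  # full_sibling
            age_class = [("cub" if ind.is_cub() else "adult") for ind in roster]
            for i in range(n):
                for j in range(n):
                    if i == j or k[i, j] < 0.5:
                        continue
                    if sibling_pairs is not None:
                        sib = frozenset((ids[i], ids[j])) in sibling_pairs
                    else:
                        sib = age_class[i] == age_class[j]
                    vals[i, j] = 1.0 if sib else 0.0
    np.fill_diagonal(vals, 0.0)
    return AttributeMatrix(ids=ids, values=vals, kind=kind)


def build_attribute_matrices(
    roster: Sequence[Individual],
    kinship: pd.DataFrame | None,
    kinds: Sequence[str] = ("gender_similarity", "half_sibling", "full_sibling", "age_similarity"),
    **kw,
) -> dict[str, AttributeMatrix]:
    return {kind: build_attribute_matrix(roster, kinship, kind, **kw) for kind in kinds}


# ---------------------------------------------------------------------------
# matrix transforms shared by metrics and stats
# ---------------------------------------------------------------------------

def symmetrize(values: np.ndarray, how: str = "sum") -> np.ndarray:
    """Collapse a directed matrix to a symmetric dyadic one."""
    v = np.asarray(values, dtype=float)
    if how == "sum":
        return v + v.T
    if how == "max":
        return np.maximum(v, v.T)
    if how == "min":
        return np.minimum(v, v.T)
    raise ValueError(f"unknown symmetrization {how!r}; expected sum|max|min")


def binarize(values: np.ndarray) -> np.ndarray:
    """Edge iff weight > 0; NaN (missing dyad) maps to no edge."""
    v = np.asarray(values, dtype=float)
    out = np.where(np.isnan(v), 0.0, v) > 0
    return out.astype(float)
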