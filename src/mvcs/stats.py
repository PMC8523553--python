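"""Repeated-measures models for similarity indices and behavior.

Fixed effects use sum-to-zero (effects) coding throughout, so the
block-of-coefficients F test for each term is the Type-III test, and the
omnibus F tables mirror the conventional mixed-model output: effect, F,
numerator df, Satterthwaite denominator df, p.

The similarity-index model has fixed effects visit (1-4) + stimulation
(cTBS/iTBS) + task (SEQ/RND) + stimulation:task with an unstructured
4x4 covariance over the condition cells within subject.  The block-level
behavior model adds block (16) and all its two- and three-way
interactions with stimulation and task, with an ``unstructured(4) (x)
compound-symmetry(16)`` Kronecker covariance.  Subjects with missing
cells contribute their available cells (no imputation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .mixedlm import (
    FTestResult,
    KroneckerCS,
    RemlFit,
    Unstructured,
    reml_fit,
    wald_f_test,
)

__all__ = [
    "LmmResult",
    "ContrastResult",
    "FdrResult",
    "fit_repeated",
    "fit_lmm_si",
    "fit_lmm_behavior",
    "followup_contrast",
    "fdr_bh",
    "SI_FACTORS",
    "CONDITION_CELLS",
]

#: Factor levels of the similarity-index design.  The first level codes
#: +1 under effects coding, so positive task/stimulation estimates mean
#: "higher for SEQ" / "higher for cTBS".
SI_FACTORS: dict[str, tuple] = {
    "visit": (1, 2, 3, 4),
    "stimulation": ("cTBS", "iTBS"),
    "task": ("SEQ", "RND"),
}

SI_TERMS: tuple[tuple[str, ...], ...] = (
    ("visit",),
    ("stimulation",),
    ("task",),
    ("stimulation", "task"),
)

#: The four within-subject condition cells (stimulation x task crossing).
CONDITION_CELLS: tuple[tuple[str, str], ...] = (
    ("cTBS", "SEQ"),
    ("cTBS", "RND"),
    ("iTBS", "SEQ"),
    ("iTBS", "RND"),
)

_CELL_LABEL = {
    ("cTBS", "SEQ"): "cSEQ",
    ("cTBS", "RND"): "cRND",
    ("iTBS", "SEQ"): "iSEQ",
    ("iTBS", "RND"): "iRND",
}


def _effects_codes(levels: Sequence) -> dict:
    """Sum-to-zero coding: level -> vector of len(levels)-1 codes."""
    k = len(levels)
    codes = {}
    for i, lev in enumerate(levels):
        row = np.zeros(k - 1)
        if i < k - 1:
            row[i] = 1.0
        else:
            row[:] = -1.0
        codes[lev] = row
    return codes


def _build_design(
    df: pd.DataFrame,
    factors: Mapping[str, Sequence],
    terms: Sequence[tuple[str, ...]],
) -> tuple[np.ndarray, dict[str, slice], list[str]]:
    """Effects-coded design matrix with intercept and term column slices."""
    codes = {f: _effects_codes(levels) for f, levels in factors.items()}
    n = len(df)
    columns = [np.ones((n, 1))]
    names = ["(Intercept)"]
    slices: dict[str, slice] = {}
    col = 1
    for term in terms:
        for f in term:
            if f not in factors:
                raise ConfigError(f"unknown factor {f!r} in model term")
        mats = []
        for f in term:
            lev_codes = codes[f]
            try:
                m = np.stack([lev_codes[v] for v in df[f]])
            except KeyError as exc:
                raise ConfigError(
                    f"factor {f!r} contains unknown level {exc.args[0]!r}"
                ) from None
            mats.append(m)
        block = mats[0]
        for m in mats[1:]:
            block = np.einsum("ni,nj->nij", block, m).reshape(n, -1)
        columns.append(block)
        width = block.shape[1]
        term_name = ":".join(term)
        slices[term_name] = slice(col, col + width)
        names.extend(f"{term_name}[{j}]" for j in range(width))
        col += width
    X = np.hstack(columns)
    return X, slices, names


@dataclass
class LmmResult:
    """Fixed-effect F table plus the underlying REML fit.

    ``anova`` has one row per fixed effect: F, numerator df,
    Satterthwaite denominator df, p.  ``theta`` and ``V`` hold the
    covariance estimate; ``cell_rows`` maps condition-cell labels to
    design rows (marginal over the other factors) for follow-up
    contrasts.
    """

    anova: pd.DataFrame
    fit: RemlFit
    terms: dict[str, slice]
    cell_rows: dict[str, np.ndarray] = field(default_factory=dict)
    response: str = ""

    @property
    def converged(self) -> bool:
        return self.fit.converged

    @property
    def theta(self) -> np.ndarray:
        return self.fit.theta

    @property
    def V(self) -> np.ndarray:
        return self.fit.V

    @property
    def loglik(self) -> float:
        return self.fit.loglik

    def effect(self, name: str) -> pd.Series:
        return self.anova.set_index("effect").loc[name]


def _selector(n_cols: int, sl: slice) -> np.ndarray:
    L = np.zeros((sl.stop - sl.start, n_cols))
    for i, j in enumerate(range(sl.start, sl.stop)):
        L[i, j] = 1.0
    return L


def fit_repeated(
    df: pd.DataFrame,
    *,
    response: str,
    subject: str = "subject",
    factors: Mapping[str, Sequence],
    terms: Sequence[tuple[str, ...]],
    repeated: Sequence[str],
    block: str | None = None,
    theta0: np.ndarray | None = None,
) -> LmmResult:
    """General repeated-measures GLS/REML fit with Type-III F tests.

    ``repeated`` names the factors whose level crossing defines the
    within-subject covariance cells (unstructured).  If ``block`` is
    given and has more than one level, the covariance becomes
    ``unstructured(cells) (x) compound-symmetry(blocks)``.
    """
    df = df.dropna(subset=[response]).reset_index(drop=True)
    if len(df) == 0:
        raise ConfigError("no observations after dropping missing responses")
    cell_factors = list(repeated)
    cell_levels = [tuple(factors[f]) for f in cell_factors]
    cells = [()]
    for levs in cell_levels:
        cells = [c + (l,) for c in cells for l in levs]
    cell_index = {c: i for i, c in enumerate(cells)}
    cell_of_row = [
        cell_index[tuple(row)] for row in df[cell_factors].itertuples(
            index=False, name=None
        )
    ]
    n_cells = len(cells)
    if block is not None:
        block_levels = list(factors[block])
        n_blocks = len(block_levels)
        block_idx = {b: i for i, b in enumerate(block_levels)}
        if n_blocks > 1:
            unit_idx = np.array(
                [
                    c * n_blocks + block_idx[b]
                    for c, b in zip(cell_of_row, df[block])
                ]
            )
            cov = KroneckerCS(n_cells, n_blocks)
        else:
            unit_idx = np.asarray(cell_of_row)
            cov = Unstructured(n_cells)
    else:
        unit_idx = np.asarray(cell_of_row)
        cov = Unstructured(n_cells)

    # subjects x cells must not duplicate
    dup = df.assign(_u=unit_idx).duplicated(subset=[subject, "_u"])
    if dup.any():
        raise ConfigError("duplicated subject x cell observations in design")

    X, slices, names = _build_design(df, factors, terms)
    fit = reml_fit(
        df[response].to_numpy(dtype=float), X,
        df[subject].to_numpy(), unit_idx, cov,
        theta0=theta0, column_names=names,
    )
    rows = []
    for term_name, sl in slices.items():
        res: FTestResult = wald_f_test(
            fit, _selector(X.shape[1], sl), term_name
        )
        rows.append((term_name, res.f, res.df_num, res.df_den, res.p))
    anova = pd.DataFrame(
        rows, columns=["effect", "F", "df_num", "df_den", "p"]
    )
    cell_rows = _condition_cell_rows(factors, terms, X.shape[1], slices)
    return LmmResult(anova, fit, slices, cell_rows, response)


def _condition_cell_rows(factors, terms, n_cols, slices) -> dict[str, np.ndarray]:
    """Design rows of the stimulation x task cell means (visit/block at 0).

    Under effects coding, marginalizing a factor zeroes its columns, so a
    cell-mean row has the intercept, plus the coded values of the terms
    built solely from stimulation and task.
    """
    if "stimulation" not in factors or "task" not in factors:
        return {}
    codes = {f: _effects_codes(list(factors[f])) for f in factors}
    out: dict[str, np.ndarray] = {}
    for stim, task in CONDITION_CELLS:
        if stim not in codes["stimulation"] or task not in codes["task"]:
            continue
        row = np.zeros(n_cols)
        row[0] = 1.0
        values = {"stimulation": stim, "task": task}
        for term in terms:
            if not set(term) <= {"stimulation", "task"}:
                continue
            vecs = [codes[f][values[f]] for f in term]
            block = vecs[0]
            for v in vecs[1:]:
                block = np.outer(block, v).ravel()
            sl = slices[":".join(term)]
            row[sl] = block
        out[_CELL_LABEL[(stim, task)]] = row
    return out


def fit_lmm_si(
    df: pd.DataFrame, response: str = "si", include_visit: bool = True
) -> LmmResult:
    """Similarity-index mixed model for one ROI and pairing.

    Expects long-format rows with subject, visit, stimulation, task and
    the response; fits visit + stimulation + task + stimulation:task
    fixed effects over an unstructured 4x4 within-subject covariance,
    with Type-III F tests and Satterthwaite denominator df.
    """
    factors = dict(SI_FACTORS)
    terms: tuple = SI_TERMS
    if not include_visit:
        factors.pop("visit")
        terms = tuple(t for t in SI_TERMS if t != ("visit",))
    needed = set(sum(terms, ())) | {"subject", response}
    missing = needed - set(df.columns)
    if missing:
        raise ConfigError(f"SI design is missing columns {sorted(missing)}")
    if df.groupby("subject")[response].count().max() < 2:
        raise ConfigError("SI model needs >= 2 condition cells per subject")
    return fit_repeated(
        df, response=response, factors=factors, terms=terms,
        repeated=("stimulation", "task"),
    )


BEHAVIOR_TERMS: tuple[tuple[str, ...], ...] = (
    ("visit",),
    ("stimulation",),
    ("task",),
    ("block",),
    ("stimulation", "task"),
    ("stimulation", "block"),
    ("task", "block"),
    ("stimulation", "task", "block"),
)


def fit_lmm_behavior(
    df: pd.DataFrame, response: str = "mean_rt_correct", n_blocks: int = 16
) -> LmmResult:
    """Block-level behavior mixed model (speed or accuracy).

    Fixed effects: visit, stimulation, task, block and the stimulation by
    task, stimulation by block, task by block and stimulation by task by
    block interactions.  Within-subject covariance: unstructured over the
    four condition cells, Kronecker compound symmetry (correlation form)
    over blocks.
    """
    factors = dict(SI_FACTORS)
    factors["block"] = tuple(range(1, n_blocks + 1))
    needed = {"subject", "visit", "stimulation", "task", "block", response}
    missing = needed - set(df.columns)
    if missing:
        raise ConfigError(
            f"behavior design is missing columns {sorted(missing)}"
        )
    present_blocks = sorted(df["block"].unique())
    if len(present_blocks) == 1:
        # single-block sub-design: no block terms, plain unstructured cells
        factors.pop("block")
        return fit_repeated(
            df, response=response, factors=factors, terms=SI_TERMS,
            repeated=("stimulation", "task"),
        )
    return fit_repeated(
        df, response=response, factors=factors, terms=BEHAVIOR_TERMS,
        repeated=("stimulation", "task"), block="block",
    )


@dataclass
class ContrastResult:
    """Single-df follow-up contrast between two condition cells."""

    cells: tuple[str, str]
    estimate: float
    f: float
    df_num: int
    df_den: float
    p: float


def followup_contrast(
    result: LmmResult, cell_a: str, cell_b: str
) -> ContrastResult:
    """F test of the difference between two condition-cell means.

    Cells are named cSEQ, cRND, iSEQ, iRND; the estimate is
    ``mean(cell_a) - mean(cell_b)`` under the fitted model, with
    Satterthwaite denominator df.
    """
    if cell_a not in result.cell_rows or cell_b not in result.cell_rows:
        raise ConfigError(
            f"cells {cell_a!r}/{cell_b!r} not available in this fit"
        )
    c = result.cell_rows[cell_a] - result.cell_rows[cell_b]
    if not np.any(c):
        return ContrastResult((cell_a, cell_b), 0.0, 0.0, 1,
                              float(max(result.fit.n_obs - 1, 1)), 1.0)
    res = wald_f_test(result.fit, c[None, :], f"{cell_a}-{cell_b}")
    return ContrastResult(
        (cell_a, cell_b), float(res.estimate), res.f, res.df_num,
        res.df_den, res.p,
    )


@dataclass
class FdrResult:
    """Benjamini-Hochberg step-up FDR over a keyed family of p-values."""

    raw: dict
    adjusted: dict
    reject: dict
    q: float


def fdr_bh(pvals, q: float = 0.05) -> FdrResult:
    """Benjamini-Hochberg step-up procedure.

    ``pvals`` may be a mapping (key -> p) or a sequence (keys become
    indices).  Adjusted values are the standard monotone BH q-values;
    ``reject[k]`` is True when the step-up rule rejects at level ``q``.
    """
    if isinstance(pvals, Mapping):
        keys = list(pvals.keys())
        p = np.array([pvals[k] for k in keys], dtype=float)
    else:
        p = np.asarray(list(pvals), dtype=float)
        keys = list(range(p.size))
    if p.size == 0:
        return FdrResult({}, {}, {}, q)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ConfigError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = ranked * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    passing = np.flatnonzero(ranked <= np.arange(1, m + 1) * q / m)
    k_star = passing.max() + 1 if passing.size else 0
    reject_sorted = np.arange(m) < k_star
    adjusted = np.empty(m)
    reject = np.empty(m, dtype=bool)
    adjusted[order] = adj
    reject[order] = reject_sorted
    return FdrResult(
        raw={k: float(v) for k, v in zip(keys, p)},
        adjusted={k: float(v) for k, v in zip(keys, adjusted)},
        reject={k: bool(v) for k, v in zip(keys, reject)},
        q=q,
    )
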