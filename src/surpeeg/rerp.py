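"""Per-subject mass-univariate single-trial regression (rERP).

Single-trial epoch amplitudes are regressed on stimulus predictors
independently at every (electrode, sample).  The coefficient time-courses
play the role of ERP components: the intercept waveform is the estimated ERP
at the predictor means, and each beta waveform is the amplitude change per
unit of its (mean-centered) predictor.

A matched "null" fit repeats the regression after randomly permuting the
rows of the design matrix, destroying the predictor-epoch pairing while
preserving everything else; the group-level cluster test compares target
against null coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import EpochSet

__all__ = [
    "DesignMatrix",
    "BetaArray",
    "build_design",
    "fit_single_trial",
    "fit_null",
    "reconstruct_erp",
    "average_betas",
]

_CENTER_TOL = 1e-9


@dataclass(frozen=True)
class DesignMatrix:
    """Centered, rank-checked design over retained trials of one word class.

    ``X`` has an intercept first column; all other columns are mean-centered
    over the retained rows.  ``rows`` maps design rows back to corpus word
    indices.  ``column_means`` stores pre-centering means for reconstruction.
    """

    X: np.ndarray  # (n, p)
    columns: tuple[str, ...]  # including "intercept"
    column_means: np.ndarray  # (p,), 0.0 for the intercept
    rows: np.ndarray  # (n,) word indices
    word_class: str  # {"content", "function", "all"}

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]


def build_design(
    table: pd.DataFrame,
    word_class: str,
    predictors: list[str],
    mask: np.ndarray | None = None,
) -> DesignMatrix:
    """Filter by word class and retained-trial mask, center, check rank."""
    if word_class not in ("content", "function", "all"):
        raise ValueError("word_class must be 'content', 'function' or 'all'")
    missing = [p for p in predictors if p not in table.columns]
    if missing:
        raise ValueError(f"predictors not in table: {missing}")
    keep = np.ones(len(table), dtype=bool)
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)
    if word_class != "all":
        keep &= (table["word_class"] == word_class).to_numpy()
    rows = np.flatnonzero(keep)
    if len(rows) < len(predictors) + 2:
        raise ValueError(
            f"only {len(rows)} retained trials for {len(predictors)} predictors"
        )
    raw = table.iloc[rows][predictors].to_numpy(float)
    means = raw.mean(axis=0)
    centered = raw - means
    X = np.column_stack([np.ones(len(rows)), centered])
    columns = ("intercept",) + tuple(predictors)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify the offending columns: those whose residual after
        # projecting on the preceding columns is numerically zero
        bad = []
        for j in range(1, X.shape[1]):
            sub = X[:, : j + 1]
            if np.linalg.matrix_rank(sub) < sub.shape[1]:
                bad.append(columns[j])
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    return DesignMatrix(
        X=X,
        columns=columns,
        column_means=np.concatenate(([0.0], means)),
        rows=rows,
        word_class=word_class,
    )


@dataclass(frozen=True)
class BetaArray:
    """OLS coefficients per (predictor, electrode, sample) for one subject."""

    beta: np.ndarray  # (p, E, T)
    residual_variance: np.ndarray  # (E, T)
    columns: tuple[str, ...]
    column_means: np.ndarray  # (p,)

    def coef(self, name: str) -> np.ndarray:
        return self.beta[self.columns.index(name)]


def _ols(epochs: EpochSet, design: DesignMatrix, subject: int, X: np.ndarray) -> BetaArray:
    y = epochs.data[subject][design.rows]  # (n, E, T)
    if not np.all(np.isfinite(y)):
        raise ValueError(f"non-finite amplitudes for subject {subject}")
    n, E, T = y.shape
    yf = y.reshape(n, E * T)
    # numerically stable OLS via QR (lstsq uses SVD; either satisfies the
    # 1e-9 normal-equation contract on well-conditioned designs)
    beta, _, _, _ = np.linalg.lstsq(X, yf, rcond=None)
    resid = yf - X @ beta
    dof = max(n - X.shape[1], 1)
    rvar = (resid**2).sum(axis=0) / dof
    return BetaArray(
        beta=beta.reshape(X.shape[1], E, T),
        residual_variance=rvar.reshape(E, T),
        columns=design.columns,
        column_means=design.column_means,
    )


def fit_single_trial(epochs: EpochSet, design: DesignMatrix, subject: int) -> BetaArray:
    """OLS independently at every (electrode, sample) for one subject."""
    return _ols(epochs, design, subject, design.X)


def fit_null(
    epochs: EpochSet, design: DesignMatrix, subject: int, seed: int
) -> BetaArray:
    """Target fit's matched null: one seeded row permutation of the design.

    The intercept column is constant and therefore unchanged by the
    permutation; only the predictor-epoch pairing is destroyed.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(design.n_trials)
    return _ols(epochs, design, subject, design.X[perm])


def reconstruct_erp(
    mean_beta: BetaArray, values: dict[str, float], electrode: int
) -> np.ndarray:
    """Model-reconstructed ERP waveform at given predictor settings.

    ``values`` are on the original (pre-centering) scale; unspecified
    predictors sit at their training means, so an empty dict returns the
    intercept waveform exactly.
    """
    unknown = [k for k in values if k not in mean_beta.columns]
    if unknown:
        raise ValueError(f"unknown predictors: {unknown}")
    wave = mean_beta.beta[0, electrode].copy()
    for name, val in values.items():
        j = mean_beta.columns.index(name)
        wave += mean_beta.beta[j, electrode] * (val - mean_beta.column_means[j])
    return wave


def average_betas(fits: list[BetaArray]) -> BetaArray:
    """Group-mean coefficients (for ERP reconstruction and reporting)."""
    if not fits:
        raise ValueError("no fits to average")
    cols = fits[0].columns
    if any(f.columns != cols for f in fits):
        raise ValueError("fits have mismatched designs")
    return BetaArray(
        beta=np.mean([f.beta for f in fits], axis=0),
        residual_variance=np.mean([f.residual_variance for f in fits], axis=0),
        columns=cols,
        column_means=np.mean([f.column_means for f in fits], axis=0),
    )
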