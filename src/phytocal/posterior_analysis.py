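"""Marginals, conditional marginals, PCA/EOF and effective dimension.

Operates on posterior sample matrices (n draws x M parameters).  Five
of the six diatom parameters have heavy right tails, so the standard
transform takes natural logs of every column except the silica content
f_si before correlation-based analysis; the flags are recorded so the
transform is invertible.

The effective number of independent directions in parameter space
("statistical degrees of freedom") is the spread-of-spectrum ratio

    dof = (sum_k lambda_k)^2 / sum_k lambda_k^2  =  M^2 / sum lambda_k^2

for the eigenvalues of the correlation matrix, which ranges from 1
(one dominant direction) to M (isotropic posterior).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleSet",
    "MarginalHist",
    "EOFResult",
    "transform_params",
    "marginal",
    "conditional_marginal",
    "pca_eof",
    "dof",
]

DEFAULT_NAMES = ("mu0", "lambda_s", "k_light", "f_si", "sigma0", "a")


@dataclass
class SampleSet:
    """Posterior draws with column names and per-column transform flags."""

    values: np.ndarray                       # (n, M)
    names: Sequence[str] = DEFAULT_NAMES
    log_applied: Sequence[bool] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] < 1:
            raise ValueError("need at least one draw")
        m = self.values.shape[1]
        self.names = tuple(self.names)[:m] if len(self.names) >= m else tuple(
            f"p{k}" for k in range(m)
        )
        if self.log_applied is None:
            self.log_applied = tuple(False for _ in range(m))
        self.log_applied = tuple(self.log_applied)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def column(self, key) -> int:
        if isinstance(key, str):
            return self.names.index(key)
        return int(key)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.names))

    @classmethod
    def from_csv(cls, path, names=None) -> "SampleSet":
        df = pd.read_csv(path)
        cols = list(names) if names is not None else [
            c for c in df.columns if c not in ("log_post",)
        ]
        return cls(values=df[cols].to_numpy(float), names=tuple(cols))


def transform_params(samples: SampleSet, skip: Sequence[str] = ("f_si",)) -> SampleSet:
    """Natural log of every column except those named in ``skip``.

    Errors on non-positive entries in a logged column; the inverse is
    exp on the flagged columns.
    """
    vals = samples.values.copy()
    flags = []
    for j, name in enumerate(samples.names):
        if name in skip:
            flags.append(False)
            continue
        col = vals[:, j]
        if np.any(col <= 0):
            raise ValueError(f"non-positive entry in log-transformed column {name!r}")
        vals[:, j] = np.log(col)
        flags.append(True)
    return SampleSet(values=vals, names=samples.names, log_applied=tuple(flags))


def inverse_transform(samples: SampleSet) -> SampleSet:
    """Undo :func:`transform_params` using the recorded flags."""
    vals = samples.values.copy()
    for j, flag in enumerate(samples.log_applied):
        if flag:
            vals[:, j] = np.exp(vals[:, j])
    return SampleSet(values=vals, names=samples.names)


@dataclass
class MarginalHist:
    """Normalized histogram over fixed bin edges (probabilities sum to 1)."""

    edges: np.ndarray
    probs: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.probs) != len(self.edges) - 1:
            raise ValueError("edges must bracket the probabilities")
        if np.any(self.probs < 0) or not np.isclose(self.probs.sum(), 1.0):
            raise ValueError("probabilities must be non-negative and sum to 1")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def _bin_edges(col: np.ndarray, nbins: int) -> np.ndarray:
    lo, hi = float(col.min()), float(col.max())
    if hi <= lo:
        raise ValueError("degenerate (constant) column has no histogram range")
    return np.linspace(lo, hi, nbins + 1)


def _hist(col: np.ndarray, edges: np.ndarray) -> np.ndarray:
    # half-open bins (A, B]; the lowest edge is inclusive so all mass is kept
    idx = np.searchsorted(edges, col, side="left") - 1
    idx = np.clip(idx, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1).astype(float)
    return counts / counts.sum()


def marginal(samples: SampleSet, k, nbins: int = 10) -> MarginalHist:
    """Marginal posterior of column k as a normalized histogram over the
    column's [min, max] range."""
    j = samples.column(k)
    col = samples.values[:, j]
    if samples.n < nbins:
        raise ValueError("fewer draws than bins")
    edges = _bin_edges(col, nbins)
    return MarginalHist(edges=edges, probs=_hist(col, edges), name=samples.names[j])


def conditional_marginal(
    samples: SampleSet,
    k,
    conditions: Mapping,
    nbins: int = 10,
) -> MarginalHist:
    """Marginal of column k restricted to draws with theta_l in (A, B].

    ``conditions`` maps column name/index -> (A, B) interval.  The
    histogram range is the *unconditioned* range of column k so that
    conditional and unconditional shapes are directly comparable.
    Equivalent to the ratio of integrals defining the conditional
    density, evaluated by sub-sampling the posterior draws.
    """
    j = samples.column(k)
    col = samples.values[:, j]
    edges = _bin_edges(col, nbins)
    mask = np.ones(samples.n, dtype=bool)
    for key, (a, b) in conditions.items():
        l = samples.column(key)
        mask &= (samples.values[:, l] > a) & (samples.values[:, l] <= b)
    if not mask.any():
        raise ValueError(
            f"no posterior draws satisfy condition on column {key!r} in ({a}, {b}]"
        )
    return MarginalHist(
        edges=edges, probs=_hist(col[mask], edges), name=samples.names[j]
    )


@dataclass
class EOFResult:
    """Eigen-decomposition of the parameter correlation matrix."""

    eigenvalues: np.ndarray          # descending, sum to M
    eofs: np.ndarray                 # (M, M), columns are unit loading vectors
    explained: np.ndarray            # lambda_k / M
    dof: float
    names: Sequence[str] = ()
    correlation: np.ndarray = field(default=None)  # type: ignore[assignment]


def pca_eof(samples: SampleSet) -> EOFResult:
    """PCA/EOF of the sample correlation matrix of the (transformed) draws.

    Correlation (not covariance) removes the parameters' physical
    dimensions; explained-variance fractions are lambda_k / M.
    """
    if samples.n <= samples.dim:
        raise ValueError("need more draws than parameters")
    x = samples.values
    if np.any(x.std(axis=0) == 0):
        raise ValueError("degenerate column: zero variance")
    corr = np.corrcoef(x, rowvar=False)
    lam, vec = np.linalg.eigh(corr)
    lam = np.maximum(lam[::-1], 0.0)
    vec = vec[:, ::-1]
    return EOFResult(
        eigenvalues=lam,
        eofs=vec,
        explained=lam / samples.dim,
        dof=dof(lam),
        names=samples.names,
        correlation=corr,
    )


def dof(eigenvalues) -> float:
    """Effective dimension (sum lambda)^2 / sum lambda^2 of a spectrum.

    For a correlation-matrix spectrum (sum = M) this is M^2 / sum
    lambda_k^2, in [1, M]; permutation invariant, equal to M iff the
    spectrum is flat.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam < 0):
        raise ValueError("eigenvalues must be non-negative")
    s2 = float(np.sum(lam**2))
    if s2 == 0:
        raise ValueError("all-zero spectrum")
    return float(np.sum(lam)) ** 2 / s2
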