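"""Single-batch multiple-testing procedures.

Implements the classical step-up procedures applied to one gene-p-value
matrix (one family of experiments): uncorrected thresholding, the
Benjamini-Hochberg (BH) step-up procedure, Storey's null-proportion
estimator and the adaptive Storey-BH procedure, plus the ``R+`` statistic
(maximum rejection count when one p-value is set to zero) that the online
batch algorithms spend against.

Conventions
-----------
* BH: with ordered p-values p_(1) <= ... <= p_(N), let i* be the maximal
  index with p_(i*) <= i* * alpha / N (i* = 0 if none); reject every
  hypothesis with p_j <= p_(i*).  Ties are therefore rejected or retained
  together.
* Storey's estimator pi0_hat = (1 + #{p_i > lambda}) / (N * (1 - lambda)),
  clamped to (0, 1].  Storey-BH is BH run at the effective level
  alpha / pi0_hat.
* p-values exactly 0 or 1 are legal; NaN or out-of-range values raise —
  silently dropping them would change N and every threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PValueVector",
    "RejectionResult",
    "uncorrected_reject",
    "bh_reject",
    "storey_pi0",
    "storey_bh_reject",
    "r_plus",
]


@dataclass(frozen=True)
class PValueVector:
    """One batch of p-values P_t = {P_{t,1}, ..., P_{t,N_t}}.

    Parameters
    ----------
    values : array-like of float
        The p-values, each finite and in [0, 1]; length N_t >= 1.
    batch_index : int
        1-based position t of this batch in the online stream.
    gene_ids : sequence of str, optional
        Unique identifiers parallel to ``values``.
    """

    values: np.ndarray
    batch_index: int = 1
    gene_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("p-value vector must be one-dimensional with N >= 1")
        if not np.all(np.isfinite(vals)):
            bad = np.flatnonzero(~np.isfinite(vals))
            raise ValueError(f"non-finite p-values at positions {bad.tolist()[:5]}")
        if vals.min() < 0.0 or vals.max() > 1.0:
            bad = np.flatnonzero((vals < 0) | (vals > 1))
            raise ValueError(f"p-values outside [0, 1] at positions {bad.tolist()[:5]}")
        if int(self.batch_index) < 1:
            raise ValueError("batch_index must be a positive integer")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "batch_index", int(self.batch_index))
        if self.gene_ids is not None:
            ids = tuple(str(g) for g in self.gene_ids)
            if len(ids) != vals.size:
                raise ValueError("gene_ids length must match values length")
            if len(set(ids)) != len(ids):
                raise ValueError("gene_ids contains duplicates")
            object.__setattr__(self, "gene_ids", ids)

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class RejectionResult:
    """Decision set of one offline procedure run on one batch."""

    level_used: float
    rejected_indices: frozenset[int]
    num_rejections: int
    crossing_index: int
    crossing_pvalue: float
    pi0_estimate: float = 1.0
    lambda_used: float | None = None

    def rejected_mask(self, n: int) -> np.ndarray:
        mask = np.zeros(n, dtype=bool)
        if self.rejected_indices:
            mask[np.fromiter(self.rejected_indices, dtype=int)] = True
        return mask


def _check_alpha(alpha: float) -> float:
    alpha = float(alpha)
    if not (0.0 <= alpha <= 1.0) or not np.isfinite(alpha):
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return alpha


def _as_pvector(p: "PValueVector | Sequence[float] | np.ndarray") -> PValueVector:
    return p if isinstance(p, PValueVector) else PValueVector(np.asarray(p, dtype=float))


def uncorrected_reject(p, alpha: float) -> RejectionResult:
    """Reject every hypothesis with p < alpha (no multiplicity adjustment)."""
    p = _as_pvector(p)
    alpha = _check_alpha(alpha)
    rej = np.flatnonzero(p.values < alpha)
    return RejectionResult(
        level_used=alpha,
        rejected_indices=frozenset(int(i) for i in rej),
        num_rejections=int(rej.size),
        crossing_index=int(rej.size),
        crossing_pvalue=float(p.values[rej].max()) if rej.size else 0.0,
    )


def _bh_core(values: np.ndarray, alpha: float, pi0: float) -> tuple[int, float, np.ndarray]:
    """Step-up scan at effective level alpha/pi0; returns (i*, p_(i*), rejected)."""
    n = values.size
    order = np.sort(values)
    thresholds = alpha * np.arange(1, n + 1) / (n * pi0)
    passing = np.flatnonzero(order <= thresholds)
    if passing.size == 0:
        return 0, 0.0, np.array([], dtype=int)
    i_star = int(passing[-1]) + 1  # 1-based maximal index
    p_star = float(order[i_star - 1])
    rejected = np.flatnonzero(values <= p_star)
    return i_star, p_star, rejected


def bh_reject(p, alpha: float) -> RejectionResult:
    """Benjamini-Hochberg step-up procedure at level alpha."""
    p = _as_pvector(p)
    alpha = _check_alpha(alpha)
    i_star, p_star, rej = _bh_core(p.values, alpha, 1.0)
    return RejectionResult(
        level_used=alpha,
        rejected_indices=frozenset(int(i) for i in rej),
        num_rejections=i_star,
        crossing_index=i_star,
        crossing_pvalue=p_star,
    )


def storey_pi0(p, lam: float = 0.5) -> float:
    """Storey's null-proportion estimate (1 + #{p_i > lambda}) / (N (1 - lambda)).

    The raw estimator can exceed 1; it is clamped to (0, 1] because an
    estimated null proportion above one is meaningless and would only make
    the adaptive procedure more conservative than plain BH.
    """
    p = _as_pvector(p)
    lam = float(lam)
    if not (0.0 < lam < 1.0):
        raise ValueError(f"lambda must be in (0, 1), got {lam}")
    n = len(p)
    raw = (1.0 + np.count_nonzero(p.values > lam)) / (n * (1.0 - lam))
    return float(min(1.0, raw))


def storey_bh_reject(p, alpha: float, lam: float = 0.5) -> RejectionResult:
    """Adaptive Storey-BH: BH with per-rank thresholds i*alpha/(N*pi0_hat)."""
    p = _as_pvector(p)
    alpha = _check_alpha(alpha)
    pi0 = storey_pi0(p, lam)
    i_star, p_star, rej = _bh_core(p.values, alpha, pi0)
    return RejectionResult(
        level_used=alpha,
        rejected_indices=frozenset(int(i) for i in rej),
        num_rejections=i_star,
        crossing_index=i_star,
        crossing_pvalue=p_star,
        pi0_estimate=pi0,
        lambda_used=lam,
    )


def _run_procedure(values: np.ndarray, alpha: float, procedure: str, lam: float) -> int:
    vec = PValueVector(values)
    if procedure == "bh":
        return bh_reject(vec, alpha).num_rejections
    if procedure == "storey_bh":
        return storey_bh_reject(vec, alpha, lam).num_rejections
    raise ValueError(f"unknown procedure {procedure!r}")


def r_plus(
    p,
    alpha: float,
    procedure: str = "bh",
    lam: float = 0.5,
    exhaustive: bool = False,
) -> int:
    """Maximum rejections when one p-value is replaced by zero.

    ``R+`` is max over j of the rejection count after setting p_j = 0 and
    rerunning the procedure, all other p-values held fixed.  Always
    >= max(R, 1) for alpha > 0.

    The default path replaces the single largest p-value: the post-
    replacement multiset {0} ∪ P \\ {p_j} is element-wise smallest (every
    order statistic weakly smallest) when p_j is the maximum, which weakly
    maximises the step-up rejection count; for Storey-BH it also maximally
    reduces #{p > lambda} and hence pi0_hat.  ``exhaustive=True`` runs the
    literal N-rerun definition; tests assert both paths agree.
    """
    p = _as_pvector(p)
    alpha = _check_alpha(alpha)
    values = p.values
    if exhaustive:
        best = 0
        for j in range(values.size):
            mod = values.copy()
            mod[j] = 0.0
            best = max(best, _run_procedure(mod, alpha, procedure, lam))
        return best
    mod = values.copy()
    mod[int(np.argmax(mod))] = 0.0
    return _run_procedure(mod, alpha, procedure, lam)
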