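"""Online batch FDR control: alpha-wealth accounting across families.

Batches of p-values (one gene-p-value matrix per family of experiments)
arrive over time.  Each batch t is tested with an offline procedure (BH or
Storey-BH) at an adaptively chosen level alpha_t that depends only on the
history of past batches, guaranteeing control of the global FDR

    FDR(t) = E[ sum_{s<=t} V_s / max(sum_{s<=t} R_s, 1) ]

at the nominal level alpha for every t.  Three procedures are provided:

onlineBH
    alpha_{t+1} = [ sum_{s<=t+1} gamma_s alpha
                    - sum_{s<=t} alpha_s R_s^+ / (R_s^+ + sum_{r<=t, r!=s} R_r) ]
                  * (N_{t+1} + sum_{s<=t} R_s) / N_{t+1}

onlineStBH
    as onlineBH with each spent term scaled by an adaptive constant k_s
    (default: the batch-s Storey pi0 estimate) and Storey-BH run per batch.

onlinePRDS
    alpha_{t+1} = alpha * gamma_{t+1} * (N_{t+1} + sum_{s<=t} R_s) / N_{t+1},
    valid under positive dependence (PRDS) within a batch.

All levels are clamped to [0, 1]; a depleted (negative) wealth yields
alpha_t = 0, meaning the batch is still tested but nothing can be rejected.
With zero rejections everywhere the spend telescopes so that
alpha_t = gamma_t * alpha exactly, for every method.

{gamma_s} is a non-negative sequence summing to 1 that schedules how the
alpha-wealth is spread over (a possibly unbounded number of) future
batches; the built-in default is gamma(s) = (6/pi^2) s^-2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Callable, Sequence

from scipy.special import zeta

from .offline import (
    PValueVector,
    RejectionResult,
    bh_reject,
    r_plus,
    storey_bh_reject,
    storey_pi0,
)

__all__ = [
    "GammaSequence",
    "BatchRecord",
    "OnlineState",
    "make_gamma",
    "init_state",
    "next_alpha",
    "process_batch",
    "state_to_json",
    "state_from_json",
]

STATE_SCHEMA_VERSION = "1"

METHODS = ("online_bh", "online_stbh", "online_prds")


@dataclass(frozen=True)
class GammaSequence:
    """Evaluator for the wealth-spreading sequence {gamma_s}, s >= 1."""

    kind: str  # "power_law" | "custom"
    exponent: float | None = None
    weights: tuple[float, ...] | None = None

    def __call__(self, s: int) -> float:
        if s < 1:
            raise ValueError("gamma sequence is indexed from s = 1")
        if self.kind == "power_law":
            return float(s ** (-self.exponent) / zeta(self.exponent))
        if s > len(self.weights):
            return 0.0
        return float(self.weights[s - 1])

    def cumulative(self, t: int) -> float:
        """sum_{s=1..t} gamma_s."""
        return float(sum(self(s) for s in range(1, t + 1)))

    def params(self) -> dict:
        if self.kind == "power_law":
            return {"exponent": self.exponent}
        return {"weights": list(self.weights)}


def make_gamma(kind: str = "power_law", **params) -> GammaSequence:
    """Construct a gamma sequence.

    ``power_law``: gamma(s) = s^-exponent / zeta(exponent), exponent > 1
    (default 2, giving the closed-form normalizer pi^2/6).
    ``custom``: an explicit non-negative weight list summing to <= 1.
    """
    if kind == "power_law":
        exponent = float(params.get("exponent", 2.0))
        if not exponent > 1.0:
            raise ValueError("power_law exponent must be > 1 for a summable sequence")
        return GammaSequence(kind="power_law", exponent=exponent)
    if kind == "custom":
        weights = tuple(float(w) for w in params["weights"])
        if any(w < 0 for w in weights):
            raise ValueError("custom gamma weights must be non-negative")
        if sum(weights) > 1.0 + 1e-12:
            raise ValueError("custom gamma weights must sum to at most 1")
        return GammaSequence(kind="custom", weights=weights)
    raise ValueError(f"unknown gamma kind {kind!r}")


@dataclass(frozen=True)
class BatchRecord:
    """Immutable per-batch ledger entry."""

    s: int
    N_s: int
    alpha_s: float
    R_s: int
    R_plus_s: int
    k_s: float = 1.0
    pi0_s: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha_s <= 1.0):
            raise ValueError("alpha_s must be in [0, 1]")
        if not (0 <= self.R_s <= self.N_s):
            raise ValueError("need 0 <= R_s <= N_s")
        if self.R_plus_s < max(self.R_s, 1):
            raise ValueError("R_plus_s must be >= max(R_s, 1)")
        if not (0.0 < self.k_s <= 1.0):
            raise ValueError("k_s must be in (0, 1]")


@dataclass(frozen=True)
class OnlineState:
    """Append-only alpha-wealth ledger for one online testing stream."""

    method: str
    alpha: float
    gamma: GammaSequence
    lam: float = 0.5
    history: tuple[BatchRecord, ...] = ()
    schema_version: str = STATE_SCHEMA_VERSION

    @property
    def t(self) -> int:
        return len(self.history)

    def total_rejections(self) -> int:
        return sum(rec.R_s for rec in self.history)


def init_state(
    method: str,
    alpha: float,
    gamma: GammaSequence | None = None,
    lam: float = 0.5,
) -> OnlineState:
    """Fresh state with empty history; the first test level is gamma(1)*alpha."""
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    alpha = float(alpha)
    if not (0.0 < alpha <= 1.0):
        raise ValueError("global alpha must be in (0, 1]")
    lam = float(lam)
    if not (0.0 < lam < 1.0):
        raise ValueError("lambda must be in (0, 1)")
    return OnlineState(method=method, alpha=alpha, gamma=gamma or make_gamma(), lam=lam)


def _wealth_spend(history: Sequence[BatchRecord]) -> float:
    """sum_s k_s alpha_s R_s^+ / (R_s^+ + sum_{r!=s} R_r), denominators at time t."""
    total_r = sum(rec.R_s for rec in history)
    spend = 0.0
    for rec in history:
        denom = rec.R_plus_s + (total_r - rec.R_s)
        spend += rec.k_s * rec.alpha_s * rec.R_plus_s / denom
    return spend


def next_alpha(state: OnlineState, n_next: int) -> float:
    """Test level alpha_{t+1} for the next batch of ``n_next`` p-values."""
    n_next = int(n_next)
    if n_next < 1:
        raise ValueError("next batch must contain at least one p-value")
    t = state.t
    if state.method == "online_prds":
        level = state.alpha * state.gamma(t + 1) * (n_next + state.total_rejections()) / n_next
    else:
        if t == 0:
            level = state.gamma(1) * state.alpha
        else:
            wealth = state.alpha * state.gamma.cumulative(t + 1) - _wealth_spend(state.history)
            level = wealth * (n_next + state.total_rejections()) / n_next
    return float(min(1.0, max(0.0, level)))


def process_batch(
    state: OnlineState,
    p: PValueVector,
    k_fn: Callable[[PValueVector, float], float] | None = None,
) -> tuple[RejectionResult, OnlineState]:
    """Test one incoming batch and append its record to the ledger.

    ``p.batch_index`` must equal t+1 for the current state.  For
    onlineStBH, ``k_fn(p, lam)`` supplies the adaptive constant k_s
    (default: Storey's pi0 estimate for the batch).  Past records are
    never modified; the returned state shares them.
    """
    if p.batch_index != state.t + 1:
        raise ValueError(
            f"batch_index {p.batch_index} does not follow history of length {state.t}"
        )
    alpha_t = next_alpha(state, len(p))
    if state.method == "online_stbh":
        result = storey_bh_reject(p, alpha_t, state.lam)
        rp = r_plus(p, alpha_t, procedure="storey_bh", lam=state.lam)
        k_t = float(k_fn(p, state.lam)) if k_fn is not None else storey_pi0(p, state.lam)
        pi0_t = result.pi0_estimate
    else:
        result = bh_reject(p, alpha_t)
        rp = r_plus(p, alpha_t, procedure="bh")
        k_t, pi0_t = 1.0, 1.0
    record = BatchRecord(
        s=state.t + 1,
        N_s=len(p),
        alpha_s=alpha_t,
        R_s=result.num_rejections,
        R_plus_s=rp,
        k_s=k_t,
        pi0_s=pi0_t,
    )
    new_state = replace(state, history=state.history + (record,))
    return result, new_state


# ---------------------------------------------------------------------------
# serialization — versioned JSON, bit-exact float round-trip


def state_to_json(state: OnlineState) -> str:
    doc = {
        "schema_version": state.schema_version,
        "method": state.method,
        "alpha": state.alpha,
        "gamma": {"kind": state.gamma.kind, "params": state.gamma.params()},
        "lambda": state.lam,
        "history": [
            {
                "s": rec.s,
                "N_s": rec.N_s,
                "alpha_s": rec.alpha_s,
                "R_s": rec.R_s,
                "R_plus_s": rec.R_plus_s,
                "k_s": rec.k_s,
                "pi0_s": rec.pi0_s,
            }
            for rec in state.history
        ],
    }
    return json.dumps(doc, indent=1)


def state_from_json(text: str) -> OnlineState:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt state file: {exc}") from exc
    if doc.get("schema_version") != STATE_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported state schema version {doc.get('schema_version')!r}"
        )
    gamma = make_gamma(doc["gamma"]["kind"], **doc["gamma"]["params"])
    history = []
    for i, rec in enumerate(doc["history"], start=1):
        if rec["s"] != i:
            raise ValueError("history batch indices must be contiguous 1..t")
        history.append(
            BatchRecord(
                s=rec["s"],
                N_s=rec["N_s"],
                alpha_s=rec["alpha_s"],
                R_s=rec["R_s"],
                R_plus_s=rec["R_plus_s"],
                k_s=rec["k_s"],
                pi0_s=rec["pi0_s"],
            )
        )
    state = OnlineState(
        method=doc["method"],
        alpha=doc["alpha"],
        gamma=gamma,
        lam=doc["lambda"],
        history=tuple(history),
    )
    if state.method not in METHODS:
        raise ValueError(f"unknown method {state.method!r} in state file")
    return state
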