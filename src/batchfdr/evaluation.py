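"""Simulation-study harness: cumulative FDP/power metrics and orchestration.

Runs repeated simulation studies comparing repeated-offline corrections
(uncorrected, BH, Storey-BH applied per batch at the nominal level) with
the online batch procedures (onlineBH, onlineStBH, onlinePRDS), in either
the unordered setting (constant proportion pi of DE genes per batch) or
the ordered setting, where a block of high-pi "super" matrices is tested
before lower-pi "regular" matrices.

The headline study output is the empirical global FDR: the mean over
replicate runs of the final cumulative false discovery proportion

    FDP = sum_s V_s / max(sum_s R_s, 1)

across all batches of a run.  Power is reported under two definitions:
``standard`` (true positives over truly DE genes) and ``as_printed``
(true positives over declared-DE genes, i.e. the true-discovery
proportion).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .de import de_test
from .offline import PValueVector, bh_reject, storey_bh_reject, uncorrected_reject
from .online import init_state, make_gamma, process_batch
from .simulate import SimulationConfig, simulate_batch

__all__ = [
    "STUDY_METHODS",
    "RunMetrics",
    "StudySummary",
    "OrderedSchedule",
    "compute_fdp",
    "compute_power",
    "make_ordered_schedule",
    "ordered_design_rows",
    "run_simulation_study",
]

STUDY_METHODS = (
    "uncorrected",
    "offline_bh",
    "offline_stbh",
    "online_bh",
    "online_stbh",
    "online_prds",
)

# Ordered-setting design: 10 super matrices then 40 regular matrices whose
# within-block DE proportions combine to the stated overall pi.
_ORDERED_DESIGN = (
    (10, 0.3, 40, 0.050, 0.1),
    (10, 0.3, 40, 0.175, 0.2),
    (10, 0.5, 40, 0.250, 0.3),
    (10, 0.5, 40, 0.375, 0.4),
    (10, 0.5, 40, 0.500, 0.5),
)


def compute_fdp(V: Sequence[int], R: Sequence[int], t: int | None = None) -> float:
    """Cumulative FDP up to batch t: sum V_s / max(sum R_s, 1)."""
    V = np.asarray(V, dtype=float)
    R = np.asarray(R, dtype=float)
    if t is None:
        t = len(V)
    V, R = V[:t], R[:t]
    if np.any(V > R) or np.any(V < 0):
        raise ValueError("need 0 <= V_s <= R_s for every batch")
    return float(V.sum() / max(R.sum(), 1.0))


def compute_power(
    truly_de: np.ndarray, rejected: np.ndarray, definition: str = "standard"
) -> float:
    """Power over aligned truth/rejection flags.

    ``standard``: TP / #truly-DE (0 when nothing is truly DE).
    ``as_printed``: TP / max(#declared-DE, 1) — the true-discovery
    proportion, reported alongside because some studies print this
    quantity under the name power.
    """
    truly_de = np.asarray(truly_de, dtype=bool)
    rejected = np.asarray(rejected, dtype=bool)
    if truly_de.shape != rejected.shape:
        raise ValueError("truth and rejection flags must be aligned")
    tp = int((truly_de & rejected).sum())
    if definition == "standard":
        n_de = int(truly_de.sum())
        return tp / n_de if n_de else 0.0
    if definition == "as_printed":
        return tp / max(int(rejected.sum()), 1)
    raise ValueError(f"unknown power definition {definition!r}")


@dataclass(frozen=True)
class OrderedSchedule:
    """Blocks of (batch count, within-block pi) tested in order."""

    blocks: tuple[tuple[int, float], ...]

    @property
    def total_batches(self) -> int:
        return sum(c for c, _ in self.blocks)

    @property
    def overall_pi(self) -> float:
        return sum(c * p for c, p in self.blocks) / self.total_batches

    def pi_for_batch(self, t: int) -> float:
        """pi for 1-based batch index t."""
        upto = 0
        for count, pi in self.blocks:
            upto += count
            if t <= upto:
                return pi
        raise ValueError(f"batch index {t} beyond schedule of {self.total_batches}")


def make_ordered_schedule(
    super_count: int,
    super_pi: float,
    regular_count: int,
    regular_pi: float,
    overall_pi: float | None = None,
    n_batches: int | None = None,
) -> OrderedSchedule:
    """Two-block super-then-regular schedule, validating the overall pi."""
    if super_count < 1 or regular_count < 1:
        raise ValueError("block counts must be positive")
    for pi in (super_pi, regular_pi):
        if not (0.0 <= pi <= 1.0):
            raise ValueError("block pi values must be in [0, 1]")
    sched = OrderedSchedule(blocks=((super_count, super_pi), (regular_count, regular_pi)))
    if n_batches is not None and sched.total_batches != n_batches:
        raise ValueError(
            f"schedule covers {sched.total_batches} batches, expected {n_batches}"
        )
    if overall_pi is not None and abs(sched.overall_pi - overall_pi) > 1e-12:
        raise ValueError(
            f"stated overall pi {overall_pi} != implied {sched.overall_pi}"
        )
    return sched


def ordered_design_rows() -> list[OrderedSchedule]:
    """The five built-in 50-batch ordered designs (overall pi 0.1 .. 0.5)."""
    return [
        make_ordered_schedule(sc, sp, rc, rp, overall_pi=op, n_batches=50)
        for sc, sp, rc, rp, op in _ORDERED_DESIGN
    ]


@dataclass(frozen=True)
class RunMetrics:
    """Per-run bookkeeping for one method on one simulated stream."""

    method: str
    V: np.ndarray
    R: np.ndarray
    N: np.ndarray
    n_truly_de: int
    true_positives: int

    @property
    def fdp_trajectory(self) -> np.ndarray:
        cv, cr = np.cumsum(self.V), np.cumsum(self.R)
        return cv / np.maximum(cr, 1.0)

    @property
    def final_fdp(self) -> float:
        return compute_fdp(self.V, self.R)

    @property
    def power_standard(self) -> float:
        return self.true_positives / self.n_truly_de if self.n_truly_de else 0.0

    @property
    def power_as_printed(self) -> float:
        return self.true_positives / max(int(self.R.sum()), 1)


@dataclass(frozen=True)
class StudySummary:
    """Aggregated study results; ``table`` has one row per (method, pi)."""

    table: pd.DataFrame
    runs: dict  # (method, pi) -> per-run final FDP array

    def get(self, method: str, pi: float) -> pd.Series:
        mask = (self.table["method"] == method) & np.isclose(self.table["pi"], pi)
        rows = self.table[mask]
        if len(rows) != 1:
            raise KeyError(f"no unique row for ({method}, {pi})")
        return rows.iloc[0]


def _reject_offline(method: str, pvec: PValueVector, alpha: float, lam: float):
    if method == "uncorrected":
        return uncorrected_reject(pvec, alpha)
    if method == "offline_bh":
        return bh_reject(pvec, alpha)
    if method == "offline_stbh":
        return storey_bh_reject(pvec, alpha, lam)
    raise ValueError(f"unknown offline method {method!r}")


def _one_run(
    config: SimulationConfig,
    methods: Sequence[str],
    pi_setting,
    rep_code: int,
    alpha: float,
    lam: float,
    engine: str,
    gamma_kwargs: dict,
) -> dict[str, RunMetrics]:
    n_batches = config.n_batches
    states = {
        m: init_state(m, alpha, make_gamma(**gamma_kwargs), lam)
        for m in methods
        if m.startswith("online_")
    }
    acc = {
        m: {"V": [], "R": [], "N": [], "tp": 0, "nde": 0} for m in methods
    }
    for t in range(1, n_batches + 1):
        pi_t = pi_setting.pi_for_batch(t) if isinstance(pi_setting, OrderedSchedule) else pi_setting
        sim = simulate_batch(replace(config, pi_de=pi_t), t, replicate=rep_code)
        de = de_test(sim.counts, sim.group_labels, engine=engine)
        pvec = PValueVector(de.p_value, batch_index=t)
        n_t = len(pvec)
        for m in methods:
            if m.startswith("online_"):
                pv = PValueVector(de.p_value, batch_index=states[m].t + 1)
                result, states[m] = process_batch(states[m], pv)
            else:
                result = _reject_offline(m, pvec, alpha, lam)
            rej = result.rejected_mask(n_t)
            a = acc[m]
            a["V"].append(int((rej & ~sim.is_de).sum()))
            a["R"].append(result.num_rejections)
            a["N"].append(n_t)
            a["tp"] += int((rej & sim.is_de).sum())
            a["nde"] += int(sim.is_de.sum())
    return {
        m: RunMetrics(
            method=m,
            V=np.array(acc[m]["V"]),
            R=np.array(acc[m]["R"]),
            N=np.array(acc[m]["N"]),
            n_truly_de=acc[m]["nde"],
            true_positives=acc[m]["tp"],
        )
        for m in methods
    }


def run_simulation_study(
    config: SimulationConfig,
    methods: Sequence[str] = STUDY_METHODS,
    pi_grid: Sequence[float] = (0.1,),
    n_reps: int = 100,
    alpha: float = 0.05,
    lam: float = 0.5,
    engine: str = "welch",
    schedule: OrderedSchedule | None = None,
    gamma_kwargs: dict | None = None,
) -> StudySummary:
    """Replicate the simulation study over a pi grid (or an ordered schedule).

    Every method sees the identical per-rep p-value stream; offline
    methods are applied independently per batch at level ``alpha`` while
    online methods update their alpha-wealth across batches.  Fully
    reproducible from ``config.master_seed``; per-(rep, pi, batch) RNG
    streams are derived seeds, so results do not depend on execution
    order.
    """
    unknown = set(methods) - set(STUDY_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if n_reps < 2:
        raise ValueError("need at least 2 replicates to estimate Monte-Carlo error")
    gamma_kwargs = gamma_kwargs or {}
    if schedule is not None:
        if schedule.total_batches != config.n_batches:
            raise ValueError("schedule must cover exactly n_batches batches")
        settings = [(schedule.overall_pi, schedule)]
    else:
        settings = [(pi, pi) for pi in pi_grid]

    rows, runs = [], {}
    for i_setting, (pi_label, pi_setting) in enumerate(settings):
        per_method = {m: {"fdp": [], "pow_std": [], "pow_pr": []} for m in methods}
        for rep in range(n_reps):
            rep_code = rep * len(settings) + i_setting
            metrics = _one_run(
                config, methods, pi_setting, rep_code, alpha, lam, engine, gamma_kwargs
            )
            for m, rm in metrics.items():
                per_method[m]["fdp"].append(rm.final_fdp)
                per_method[m]["pow_std"].append(rm.power_standard)
                per_method[m]["pow_pr"].append(rm.power_as_printed)
        for m in methods:
            fdp = np.array(per_method[m]["fdp"])
            runs[(m, pi_label)] = fdp
            rows.append(
                {
                    "method": m,
                    "pi": pi_label,
                    "n_reps": n_reps,
                    "fdr": fdp.mean(),
                    "fdr_sd": fdp.std(ddof=1),
                    "fdr_se": fdp.std(ddof=1) / np.sqrt(n_reps),
                    "power_standard": float(np.mean(per_method[m]["pow_std"])),
                    "power_as_printed": float(np.mean(per_method[m]["pow_pr"])),
                    "fdp_q025": float(np.quantile(fdp, 0.025)),
                    "fdp_q975": float(np.quantile(fdp, 0.975)),
                }
            )
    return StudySummary(table=pd.DataFrame(rows), runs=runs)
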