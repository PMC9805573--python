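"""File formats and state persistence.

Gene-p-value tables are TSV (or CSV) files with at least ``gene_id`` and
``p_value`` columns; extra columns are passed through untouched.  Online
state is a versioned JSON document replaced atomically (write-temp-then-
rename), so a killed process never leaves a half-written ledger.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .offline import PValueVector, RejectionResult
from .online import (
    OnlineState,
    init_state,
    make_gamma,
    process_batch,
    state_from_json,
    state_to_json,
)

__all__ = [
    "read_pvalue_table",
    "write_decisions",
    "filter_unique_genes",
    "load_state",
    "save_state",
    "online_step",
]


def _sep(dialect: str) -> str:
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def read_pvalue_table(
    path: str | Path, dialect: str = "tsv", batch_index: int = 1
) -> PValueVector:
    """Read a gene-p-value table, preserving file row order.

    Raises on missing columns, duplicate gene ids (never silently
    deduplicated) and unparseable or out-of-range p-values, naming the
    offending rows (1-based, excluding the header).
    """
    df = pd.read_csv(path, sep=_sep(dialect))
    missing = {"gene_id", "p_value"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    genes = df["gene_id"].astype(str)
    if genes.str.len().eq(0).any() or genes.isna().any():
        raise ValueError(f"{path}: empty gene_id values")
    dupes = genes[genes.duplicated()].unique()
    if len(dupes):
        raise ValueError(f"{path}: duplicate gene ids {list(dupes)[:5]}")
    pvals = pd.to_numeric(df["p_value"], errors="coerce").to_numpy()
    bad = np.flatnonzero(~np.isfinite(pvals) | (pvals < 0) | (pvals > 1))
    if bad.size:
        raise ValueError(
            f"{path}: invalid p-values at row(s) {[int(b) + 1 for b in bad[:5]]}"
        )
    return PValueVector(pvals, batch_index=batch_index, gene_ids=tuple(genes))


def write_decisions(
    result: RejectionResult,
    p: PValueVector,
    path: str | Path,
    method: str,
    dialect: str = "tsv",
) -> None:
    """Write per-gene decisions for one batch, in input order."""
    n = len(p)
    rejected = result.rejected_mask(n)
    df = pd.DataFrame(
        {
            "gene_id": list(p.gene_ids) if p.gene_ids else [f"g{i+1}" for i in range(n)],
            "p_value": p.values,
            "alpha_used": result.level_used,
            "rejected": rejected,
            "method": method,
            "batch_index": p.batch_index,
        }
    )
    df.to_csv(path, sep=_sep(dialect), index=False)


def filter_unique_genes(gene_sets: list[set[str]]) -> list[set[str]]:
    """Keep, per input set, only the ids appearing in exactly one set.

    This is the sensitivity-analysis filter for applying online FDR
    control across families with overlapping gene panels: shared genes
    are removed post-DE so each family tests distinct hypotheses.
    """
    if len(gene_sets) < 2:
        raise ValueError("need at least two gene sets to filter overlaps")
    counts: dict[str, int] = {}
    for s in gene_sets:
        for g in s:
            counts[g] = counts.get(g, 0) + 1
    return [{g for g in s if counts[g] == 1} for s in gene_sets]


def load_state(path: str | Path) -> OnlineState:
    return state_from_json(Path(path).read_text())


def save_state(state: OnlineState, path: str | Path) -> None:
    """Atomic replace: write to a temp file in the same directory, rename."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(state_to_json(state))
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def online_step(
    state_path: str | Path,
    pvalue_path: str | Path,
    out_path: str | Path,
    method: str | None = None,
    alpha: float | None = None,
    gamma_exponent: float = 2.0,
    lam: float = 0.5,
    batch_index: int | None = None,
    dialect: str = "tsv",
) -> tuple[RejectionResult, OnlineState]:
    """Process one batch of an online stream persisted in a state file.

    First invocation (state file absent) requires ``method`` and
    ``alpha`` and initializes the ledger; later invocations must either
    omit the configuration flags or repeat the stored values exactly —
    a mismatch is an error, never a silent reconfiguration.  A
    ``batch_index`` at or below the last processed batch is refused
    (idempotence guard); past decisions files are never rewritten.
    """
    state_path = Path(state_path)
    if state_path.exists():
        state = load_state(state_path)
        if method is not None and method != state.method:
            raise ValueError(
                f"method {method!r} conflicts with stored state ({state.method!r})"
            )
        if alpha is not None and alpha != state.alpha:
            raise ValueError(
                f"alpha {alpha} conflicts with stored state ({state.alpha})"
            )
    else:
        if method is None or alpha is None:
            raise ValueError("first invocation requires --method and --alpha")
        state = init_state(method, alpha, make_gamma(exponent=gamma_exponent), lam)
    expected = state.t + 1
    if batch_index is None:
        batch_index = expected
    elif batch_index != expected:
        raise ValueError(
            f"batch index {batch_index} already processed or out of order "
            f"(next expected: {expected}); state unchanged"
        )
    p = read_pvalue_table(pvalue_path, dialect=dialect, batch_index=batch_index)
    result, new_state = process_batch(state, p)
    write_decisions(result, p, out_path, method=new_state.method, dialect=dialect)
    save_state(new_state, state_path)
    return result, new_state
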