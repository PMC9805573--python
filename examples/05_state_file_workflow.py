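"""Online testing across separate invocations via a persistent state file.

Mimics the shell workflow (`batchfdr online-step ...`): each incoming
gene-p-value table is processed against a JSON alpha-wealth ledger on
disk, decisions are written per batch, and past decisions never change.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from batchfdr import load_state, online_step

workdir = Path(tempfile.mkdtemp())
rng = np.random.default_rng(5)

for t in (1, 2, 3):
    p = np.clip(np.concatenate([rng.beta(0.1, 9, 60), rng.random(240)]), 0, 1)
    table = workdir / f"family{t}.tsv"
    pd.DataFrame(
        {"gene_id": [f"fam{t}_g{i}" for i in range(p.size)], "p_value": p}
    ).to_csv(table, sep="\t", index=False)
    result, state = online_step(
        workdir / "stream.json", table, workdir / f"decisions{t}.tsv",
        method="online_stbh", alpha=0.05,
    )
    print(f"batch {t}: level {result.level_used:.5f}, "
          f"{result.num_rejections} genes declared DE")

state = load_state(workdir / "stream.json")
print(f"\nledger holds {state.t} batches; total rejections so far: "
      f"{state.total_rejections()}")
print("re-running batch 3 now would be refused — past decisions are final.")
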