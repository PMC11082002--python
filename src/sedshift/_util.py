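"""Shared helpers: provenance headers, seed splitting, TSV writing."""

from __future__ import annotations

import sys
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from . import __version__

MAX_SEED = 2**31 - 1


def split_seed(master: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(int(master))
    return [int(s) % MAX_SEED for s in ss.generate_state(n, dtype=np.uint64)]


def provenance_header(command: str, seed: int | None = None) -> str:
    parts = [f"sedshift {__version__}", f"command: {command}"]
    if seed is not None:
        parts.append(f"seed: {seed}")
    parts.append(datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ"))
    return "# " + " | ".join(parts)


def write_tsv(df: pd.DataFrame, path, command: str, seed: int | None = None,
              index: bool = True, extra_header: list[str] | None = None) -> None:
    """Write a DataFrame as UTF-8 TSV with a commented provenance header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(provenance_header(command, seed) + "\n")
        for line in extra_header or []:
            fh.write(f"# {line}\n")
        # %.17g keeps doubles bit-exact across a write/read cycle
        df.to_csv(fh, sep="\t", index=index, float_format="%.17g")


def log(msg: str, *, quiet: bool = False) -> None:
    if not quiet:
        print(msg, file=sys.stderr)
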