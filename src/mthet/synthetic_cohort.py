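"""Synthetic stand-in cohort call tables.

These tables are NOT real data. They are constructed call sets whose
cohort-level marginal counts match the reported headline numbers of the
source study's multi-species screen — 107 heteroplasmic positions across
45 of 79 screened individuals, with 85 transitions and 22 transversions
among the major->minor substitutions — so that the cohort summary and
mutation-spectrum machinery can be exercised end to end without the
(unavailable) per-call supplementary table. Only the marginals are
faithful; positions, species labels and per-call details are arbitrary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import CALL_COLUMNS, CallTable
from .stats import SUBSTITUTIONS, TRANSITIONS

#: Directional substitution counts summing to 85 transitions / 22
#: transversions over 107 calls (transitions spread evenly; transversions
#: thinly across all 8 classes, C>G / T>G rarest).
SPECTRUM_COUNTS = {
    "A>G": 21, "G>A": 21, "C>T": 22, "T>C": 21,
    "A>C": 3, "A>T": 3, "C>A": 3, "C>G": 2,
    "G>C": 3, "G>T": 3, "T>A": 3, "T>G": 2,
}

#: Calls per positive individual: 24 individuals carry a single position,
#: the rest carry several; totals 107 positions over 45 individuals.
CALLS_PER_POSITIVE = [1] * 24 + [4] * 20 + [3]

N_INDIVIDUALS_SCREENED = 79


def _rows(seed: int = 0):
    assert sum(CALLS_PER_POSITIVE) == sum(SPECTRUM_COUNTS.values()) == 107
    rng = np.random.default_rng(seed)
    subs = [s for s, c in SPECTRUM_COUNTS.items() for _ in range(c)]
    rng.shuffle(subs)
    rows = []
    k = 0
    for i, n_calls in enumerate(CALLS_PER_POSITIVE):
        positions = rng.choice(np.arange(100, 16500), size=n_calls, replace=False)
        for pos in positions:
            major, minor = subs[k].split(">")
            depth = int(rng.integers(21, 120))
            minor_count = max(4, int(round(depth * rng.uniform(0.15, 0.45))))
            rows.append(
                {
                    "individual": f"ind{i:02d}",
                    "species": f"sp{i % 14}",
                    "position": int(pos),
                    "ref": major,
                    "major": major,
                    "minor": minor,
                    "depth": depth,
                    "minor_fraction": minor_count / depth,
                    "minor_fwd": minor_count // 2,
                    "minor_rev": minor_count - minor_count // 2,
                    "context": "",
                }
            )
            k += 1
    return rows


def cohort_calltable(seed: int = 0) -> CallTable:
    """A 107-call, 45-individual synthetic stand-in table (see module docs)."""
    return CallTable(pd.DataFrame(_rows(seed), columns=CALL_COLUMNS))
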