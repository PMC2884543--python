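"""Worked-example checks: recompute every printed percentage or
approximation of the study's headline count pairs from its printed counts
and compare at the printed precision.

Most entries are integer percentages (tolerance: rounds to the printed
value); fractions printed with one decimal carry a 0.05 tolerance; the
"about" entries allow one percentage point; the repertoire-scale pair
approximation n^2/2 is compared after rounding to the nearest 500.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import pandas as pd


@dataclass
class WorkedExample:
    label: str
    computed: float
    expected: float
    tolerance: float

    @property
    def passed(self) -> bool:
        return abs(self.computed - self.expected) <= self.tolerance


def _pct(num: int, den: int) -> float:
    return 100.0 * num / den


_EXAMPLES: list[tuple[str, Callable[[], float], float, float]] = [
    # (label, computation, printed value, tolerance)
    ("TFs with active transcription, 694/731 (%)",
     lambda: round(_pct(694, 731)), 95, 0),
    ("TFs average-or-high in time course, 667/679 (%)",
     lambda: round(_pct(667, 679)), 98, 0),
    ("TFs detected in situ, 351/373 (%)",
     lambda: round(_pct(351, 373)), 94, 0),
    ("TFs expressed in adult tissues, 687/724 (about %)",
     lambda: round(_pct(687, 724)), 94, 1),
    ("maternal TFs in situ, 219/373 (%)",
     lambda: round(_pct(219, 373), 1), 58.7, 0.05),
    ("TFs high at 1-2 h in time course, 327/679 (%)",
     lambda: round(_pct(327, 679), 1), 48.2, 0.05),
    ("TFs at 0-30 min on early chips, 337/715 (%)",
     lambda: round(_pct(337, 715), 1), 47.1, 0.05),
    ("TFs transcribed at 0-2 h in tiling map, 429/731 (%)",
     lambda: round(_pct(429, 731), 1), 58.7, 0.05),
    ("in situ coverage of the TF repertoire, 373/731 (%)",
     lambda: round(_pct(373, 731)), 51, 0),
    ("exclusively ubiquitous among ever-ubiquitous TFs, 28/146 (%)",
     lambda: round(_pct(28, 146)), 19, 0),
    ("potential TF pairs, 373^2/2 rounded to nearest 500",
     lambda: round(373**2 / 2 / 500) * 500, 69500, 0),
    ("potential TF pairs, exact C(373, 2)",
     lambda: math.comb(373, 2), 69378, 0),
    ("adult head/crop/gut cluster members annotated midgut, 8/23 (%)",
     lambda: round(_pct(8, 23)), 35, 0),
]


def worked_examples() -> list[WorkedExample]:
    return [
        WorkedExample(label, float(fn()), float(expected), float(tol))
        for label, fn, expected, tol in _EXAMPLES
    ]


def worked_examples_table() -> pd.DataFrame:
    rows = [
        (ex.label, ex.computed, ex.expected, ex.tolerance, ex.passed)
        for ex in worked_examples()
    ]
    return pd.DataFrame(
        rows, columns=["label", "computed", "expected", "tolerance", "passed"]
    )
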