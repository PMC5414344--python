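"""Bundled reference datasets: published CheckM quality estimates.

Two case-study tables ship with the package so that summary utilities
(:func:`binref.quality.method_averages`, :func:`binref.quality.categorize`)
can be exercised against real refinement campaigns without sequence data:

* ``anaerobic_digester_checkm()`` — 31 manually refined genome bins from
  an anaerobic-digester metagenome co-assembled over seven time-point
  samples, with the CheckM completeness/contamination of each refined bin
  and of the corresponding bins from the automated binners that seeded
  the refinement (MyCC, MetaBAT in sensitive/specific and superspecific
  modes, CONCOCT).  ``NaN`` marks "NB" — the binner assigned no
  corresponding bin — and is excluded from per-method averages.

* ``infant_gut_checkm()`` — nine manually refined genome bins from a
  benchmark human infant-gut metagenome (18 samples, 2329 contigs over
  1000 nt).

Values are externally estimated (CheckM) percentages transcribed from the
published campaign reports; they are *inputs* here, not quantities this
package recomputes from sequence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

NB = np.nan

# bin, refined, mycc, metabat_1 (sensitive/specific), metabat_2
# (superspecific), concoct — each as (completeness %, contamination %)
_AD_ROWS = [
    (1, 98.9, 0.0, 98.9, 0.0, 98.9, 0.0, 98.9, 0.0, 100.0, 18.8),
    (2, 96.6, 0.4, 98.9, 39.2, 96.6, 0.4, 96.6, 2.2, 100.0, 82.3),
    (3, 95.3, 1.3, 96.6, 1.8, 95.0, 0.7, 74.8, 0.7, 98.0, 1.7),
    (4, 94.9, 2.0, 94.9, 2.2, 90.3, 2.0, 90.3, 2.0, 98.3, 6.0),
    (5, 94.8, 1.7, 94.8, 3.7, 90.8, 0.0, 90.8, 0.0, 94.8, 2.0),
    (6, 92.2, 0.2, 94.7, 4.7, 85.8, 0.1, 85.8, 0.1, 94.6, 42.8),
    (7, 66.7, 0.0, 94.7, 51.0, 66.7, 0.0, 66.7, 0.0, 100.0, 101.7),
    (8, 82.9, 2.5, 93.4, 23.8, 75.6, 7.7, 75.7, 9.8, 100.0, 99.4),
    (9, 92.8, 3.2, 92.8, 1.5, 80.0, 0.6, 80.0, 0.6, 92.7, 3.2),
    (10, 92.2, 0.0, 91.4, 1.7, 93.6, 6.8, 93.6, 6.8, 98.2, 19.1),
    (11, 85.9, 3.8, 90.4, 22.0, 58.2, 2.2, 67.1, 6.1, 88.0, 3.8),
    (12, 89.8, 2.7, 90.1, 6.8, 85.2, 3.2, 85.2, 3.2, 100.0, 72.2),
    (13, 87.3, 2.2, 87.3, 3.8, 76.3, 0.0, 76.8, 0.0, 96.5, 92.0),
    (14, 83.8, 0.6, 84.9, 7.6, 66.4, 0.4, 66.3, 0.4, 94.6, 42.8),
    (15, 81.6, 2.5, 84.3, 5.3, 73.7, 0.5, 74.8, 1.1, 100.0, 99.4),
    (16, 63.9, 2.0, 83.4, 17.2, 48.0, 0.2, 43.8, 0.2, 100.0, 72.2),
    (17, 91.2, 0.6, 82.0, 14.1, 91.0, 1.1, 91.2, 1.6, 96.5, 54.0),
    (18, 76.3, 3.8, 78.5, 7.2, 48.6, 0.0, 48.6, 0.0, 100.0, 82.3),
    (19, 77.3, 5.3, 77.7, 5.3, 56.2, 1.4, 56.2, 1.4, 77.7, 2.6),
    (20, 60.4, 2.1, 77.6, 8.7, 62.9, 9.8, 63.4, 18.5, 99.8, 110.8),
    (21, 65.5, 1.1, 66.6, 1.7, 25.5, 1.1, 25.5, 1.1, 67.6, 12.2),
    (22, 62.0, 2.4, 63.7, 4.0, NB, NB, NB, NB, 63.0, 5.1),
    (23, 51.8, 3.2, 63.7, 7.3, 28.9, 0.1, 29.0, 0.0, 51.8, 3.2),
    (24, 66.8, 3.6, 63.3, 3.6, 14.9, 0.0, 16.7, 0.0, 72.7, 24.2),
    (25, 59.0, 1.0, 60.0, 5.0, 46.2, 0.7, 46.2, 0.7, 75.5, 3.0),
    (26, 51.3, 3.3, 56.8, 10.2, NB, NB, NB, NB, 96.6, 54.0),
    (27, 49.5, 1.0, 56.8, 6.0, 12.8, 0.0, NB, NB, 47.0, 1.1),
    (28, 54.5, 2.1, 54.5, 2.1, 11.2, 0.0, NB, NB, 62.4, 15.3),
    (29, 14.6, 0.7, 53.7, 8.1, NB, NB, NB, NB, 45.2, 3.8),
    (30, 99.5, 0.5, 52.4, 0.7, 98.6, 0.5, 93.3, 0.5, 100.0, 101.7),
    (31, 95.6, 0.1, 49.4, 0.0, 78.0, 0.1, 93.4, 0.1, 96.6, 91.9),
]

# bin, refined (completeness %, contamination %)
_INFANT_GUT_ROWS = [
    (1, 99.2, 0.0),
    (2, 98.9, 0.0),
    (3, 97.9, 0.0),
    (4, 99.5, 0.1),
    (5, 95.9, 0.0),
    (6, 97.9, 2.8),
    (7, 95.4, 0.6),
    (8, 84.1, 0.0),
    (9, 45.1, 0.2),
]


def anaerobic_digester_checkm() -> pd.DataFrame:
    """31 refined anaerobic-digester bins, indexed by bin number.

    Columns ``{method}_completeness`` / ``{method}_contamination`` for
    methods ``refined``, ``mycc``, ``metabat_1``, ``metabat_2``,
    ``concoct``; NaN means the binner produced no corresponding bin.
    """
    cols = ["bin"]
    for m in ("refined", "mycc", "metabat_1", "metabat_2", "concoct"):
        cols += [f"{m}_completeness", f"{m}_contamination"]
    df = pd.DataFrame(_AD_ROWS, columns=cols).set_index("bin")
    return df


def infant_gut_checkm() -> pd.DataFrame:
    """Nine refined infant-gut benchmark bins, indexed by bin number."""
    cols = ["bin", "refined_completeness", "refined_contamination"]
    return pd.DataFrame(_INFANT_GUT_ROWS, columns=cols).set_index("bin")
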