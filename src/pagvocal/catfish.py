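"""catFISH two-period activation quantification.

Input is a per-cell table already scored for nuclear (intronic) and
cytoplasmic (coding) c-fos label — nuclear signal marks transcription
during the recent second behavioural period, cytoplasmic signal marks the
earlier first period. This module counts label combinations per
anatomical zone, computes the reactivation index (percent of
nuclear-labelled cells that also carry cytoplasmic label, i.e. cells
active in both periods), and estimates the underlying conditional
activation probability with an exact binomial confidence interval.

Cells from multiple sections of one animal are summed within the animal
before the index is computed; group summaries average per-animal indices
(mean ± SEM), never pooled cells. An undefined index (no nuclear cells)
propagates as NaN and is excluded from group means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest

__all__ = [
    "ZONES",
    "ReactivationSummary",
    "zone_counts",
    "reactivation_index",
    "recover_overlap",
    "per_animal_summary",
]

ZONES = ("PAGrs", "PAGcs", "PAGcd", "VPP", "other")


@dataclass(frozen=True)
class ReactivationSummary:
    """Counts and reactivation index for one zone (or animal x zone)."""

    n_nuclear: int
    n_both: int
    index: float  # percent in [0, 100]; NaN when n_nuclear == 0


def _zone_slice(cells: pd.DataFrame, zone: str) -> pd.DataFrame:
    if zone not in ZONES:
        raise ValueError(f"unknown zone {zone!r}; expected one of {ZONES}")
    return cells[cells["zone"] == zone]


def zone_counts(cells: pd.DataFrame, zone: str) -> tuple[int, int, int]:
    """(n_nuclear, n_cytoplasmic, n_both) within a zone."""
    sub = _zone_slice(cells, zone)
    nuc = sub["nuclear"].astype(bool)
    cyt = sub["cytoplasmic"].astype(bool)
    return int(nuc.sum()), int(cyt.sum()), int((nuc & cyt).sum())


def reactivation_index(cells: pd.DataFrame, zone: str) -> ReactivationSummary:
    """Reactivation index: 100 x n_both / n_nuclear.

    The percentage of cells activated in the second behavioural period
    (nuclear intron signal) that were also activated in the first
    (cytoplasmic coding signal). Undefined (NaN, not 0) when the zone has
    no nuclear-labelled cells.
    """
    n_nuc, _, n_both = zone_counts(cells, zone)
    index = 100.0 * n_both / n_nuc if n_nuc > 0 else float("nan")
    return ReactivationSummary(n_nuclear=n_nuc, n_both=n_both, index=index)


def recover_overlap(
    cells: pd.DataFrame, zone: str, confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Estimate P(active in period 1 | active in period 2) with an exact CI.

    Point estimate is the reactivation index / 100; the interval is the
    Clopper-Pearson binomial CI on n_both successes out of n_nuclear
    trials. This is the recovery harness for the synthetic two-period
    generator, whose implied conditional is known.
    """
    summary = reactivation_index(cells, zone)
    if summary.n_nuclear == 0:
        return float("nan"), (float("nan"), float("nan"))
    test = binomtest(summary.n_both, summary.n_nuclear)
    ci = test.proportion_ci(confidence_level=confidence, method="exact")
    return summary.n_both / summary.n_nuclear, (float(ci.low), float(ci.high))


def per_animal_summary(
    cells: pd.DataFrame, zone: str, animal_col: str = "animal_id"
) -> pd.DataFrame:
    """Per-animal reactivation indices plus the group mean ± SEM.

    Counts are summed within animal (across sections) before each index
    is computed. Returns a table with one row per animal and attrs
    ``group_mean`` / ``group_sem`` computed over animals with a defined
    index; the number of excluded (undefined) animals is in attrs too.
    """
    sub = _zone_slice(cells, zone)
    rows = []
    for animal, grp in sub.groupby(animal_col):
        nuc = grp["nuclear"].astype(bool)
        cyt = grp["cytoplasmic"].astype(bool)
        n_nuc = int(nuc.sum())
        n_both = int((nuc & cyt).sum())
        rows.append(
            {
                "animal_id": animal,
                "zone": zone,
                "n_nuclear": n_nuc,
                "n_both": n_both,
                "index": 100.0 * n_both / n_nuc if n_nuc else float("nan"),
            }
        )
    out = pd.DataFrame(rows)
    defined = out["index"].dropna()
    out.attrs["group_mean"] = float(defined.mean()) if len(defined) else float("nan")
    out.attrs["group_sem"] = (
        float(defined.std(ddof=1) / np.sqrt(len(defined)))
        if len(defined) > 1
        else float("nan")
    )
    out.attrs["n_undefined"] = int(out["index"].isna().sum())
    return out
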