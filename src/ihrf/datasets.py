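"""Bundled worked-example data.

The worked example mirrors a published two-visit intermediate-AMD cohort:
120 eyes screened, of which 52 (43.3%) carried IHRF at baseline and entered
quantification; per-slab lesion totals were counted at baseline and at the
2-year follow-up.  These totals serve as the input of the report-stage
arithmetic (totals, per-eye means, subgroup fraction) in the README example
and the acceptance checks.
"""

from __future__ import annotations

import pandas as pd

from ._util import round_half_up

__all__ = [
    "EXAMPLE_EYES_ANALYZED",
    "EXAMPLE_EYES_SCREENED",
    "load_example_slab_counts",
    "cohort_summary",
]

EXAMPLE_EYES_ANALYZED = 52
EXAMPLE_EYES_SCREENED = 120

_EXAMPLE_BASELINE = (58, 132, 49, 4, 0)
_EXAMPLE_FOLLOWUP = (194, 287, 100, 23, 0)


def load_example_slab_counts() -> pd.DataFrame:
    """Per-slab IHRF totals of the worked-example cohort (slabs 1..5)."""
    return pd.DataFrame(
        {
            "slab": [1, 2, 3, 4, 5],
            "baseline_count": _EXAMPLE_BASELINE,
            "followup_count": _EXAMPLE_FOLLOWUP,
        }
    )


def cohort_summary(
    counts: pd.DataFrame,
    n_analyzed: int = EXAMPLE_EYES_ANALYZED,
    n_screened: int = EXAMPLE_EYES_SCREENED,
) -> dict:
    """Report-stage arithmetic on a per-slab totals table.

    Returns overall totals per visit, per-eye means (half-up, 1 decimal,
    over the analyzed eyes), and the analyzed-subgroup percentage of the
    screened cohort.
    """
    baseline_total = int(counts["baseline_count"].sum())
    followup_total = int(counts["followup_count"].sum())
    return {
        "baseline_total": baseline_total,
        "followup_total": followup_total,
        "baseline_mean_per_eye": round_half_up(baseline_total / n_analyzed, 1),
        "followup_mean_per_eye": round_half_up(followup_total / n_analyzed, 1),
        "fold_increase": round_half_up(followup_total / baseline_total, 2),
        "subgroup_pct": round_half_up(100.0 * n_analyzed / n_screened, 1),
    }
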