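"""Decision curve analysis: net benefit across risk thresholds.

Net benefit at threshold probability Pt weighs true positives against false
positives:

    NB = TP/n - FP/n * Pt/(1 - Pt)

where a subject is classified positive when their predicted probability
reaches Pt (ties treated as positive by default). The model curve is
compared with the extreme strategies "treat all" (everyone positive) and
"treat none" (NB = 0 by definition) over a 5%-50% threshold grid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["net_benefit", "treat_all_net_benefit", "dca_table", "DEFAULT_THRESHOLDS"]

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))


def _classify(p, pt, ties_positive=True):
    return p >= pt if ties_positive else p > pt


def net_benefit(probabilities, labels, pt, ties_positive: bool = True) -> float:
    """Net benefit of the model's classification at threshold ``pt``."""
    if not 0.0 < pt < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    n = len(y)
    pos = _classify(p, pt, ties_positive)
    tp = int((pos & (y == 1)).sum())
    fp = int((pos & (y == 0)).sum())
    return tp / n - (fp / n) * pt / (1 - pt)


def treat_all_net_benefit(prevalence: float, pt: float) -> float:
    """Closed-form net benefit of treating everyone: pi - (1-pi)*Pt/(1-Pt)."""
    if not 0.0 < pt < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    return prevalence - (1 - prevalence) * pt / (1 - pt)


def dca_table(
    probabilities,
    labels,
    thresholds=DEFAULT_THRESHOLDS,
    ties_positive: bool = True,
) -> pd.DataFrame:
    """One row per threshold: model NB, treat-all NB, treat-none NB (0),
    the model-minus-treat-all difference, and the intervention/avoided
    proportions implied by the model's classification rule."""
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("threshold grid is empty")
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("net benefit comparison needs both outcome classes")
    prev = float(y.mean())
    rows = []
    for pt in thresholds:
        nb = net_benefit(p, y, pt, ties_positive)
        nb_all = treat_all_net_benefit(prev, pt)
        frac_pos = float(_classify(p, pt, ties_positive).mean())
        rows.append(
            dict(
                threshold=pt,
                nb_model=nb,
                nb_treat_all=nb_all,
                nb_treat_none=0.0,
                nb_difference=nb - nb_all,
                intervention_proportion=frac_pos,
                avoided_proportion=1.0 - frac_pos,
            )
        )
    return pd.DataFrame(rows)
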