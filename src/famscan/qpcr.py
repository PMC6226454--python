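"""Relative qRT-PCR quantification by the 2^-ddCT method with replicate
statistics.

dCT = CT_target - CT_reference (technical replicates averaged first);
ddCT = mean dCT(treated) - mean dCT(control); fold change = 2^-ddCT.
A gene is called up (down) under a treatment when the fold change clears
the fold threshold and a two-sample Student's t-test on the biological-
replicate dCT values against the control is significant.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd
from scipy import stats

from .models import CtRecord, CtTable, RegulationCall

ALPHA = 0.05
FOLD_MIN = 2.0


def delta_ct(records: list[CtRecord]) -> float:
    """dCT of one biological replicate: technical replicates averaged
    before subtraction."""
    if not records:
        raise ValueError("no CT records")
    targets = [r.ct_target for r in records]
    references = [r.ct_reference for r in records]
    if any(r is None or not np.isfinite(r) for r in references):
        raise ValueError("missing reference CT")
    return float(np.mean(targets) - np.mean(references))


def fold_change(dct_treated_mean: float, dct_control_mean: float) -> float:
    """2^-(ddCT) with ddCT = treated - control."""
    return float(2.0 ** -(dct_treated_mean - dct_control_mean))


def _replicate_dcts(table: CtTable) -> dict[tuple[str, str], list[float]]:
    """Per (gene, treatment): one dCT per biological replicate."""
    grouped: dict[tuple[str, str, int], list[CtRecord]] = defaultdict(list)
    for r in table.records:
        grouped[(r.gene_id, r.treatment, r.biological_replicate)].append(r)
    out: dict[tuple[str, str], list[float]] = defaultdict(list)
    for (gene, treatment, _rep), recs in sorted(grouped.items()):
        out[(gene, treatment)].append(delta_ct(recs))
    return out


def regulation_calls(
    table: CtTable,
    alpha: float = ALPHA,
    fold_min: float = FOLD_MIN,
    welch: bool = False,
) -> list[RegulationCall]:
    """Up/down/unchanged calls for every (gene, non-control treatment).

    ``fold_min=1.0`` reproduces significance-only calling; ``welch``
    switches the equal-variance Student's t-test to Welch's.
    """
    if fold_min < 1.0:
        raise ValueError("fold_min must be >= 1")
    dcts = _replicate_dcts(table)
    control = table.control_label
    calls = []
    for gene in table.genes():
        if (gene, control) not in dcts:
            raise ValueError(f"gene {gene}: no control measurements")
        ref = dcts[(gene, control)]
        if len(ref) < 2:
            raise ValueError(f"gene {gene}: need >= 2 control replicates")
        for treatment in table.treatments():
            if treatment == control:
                continue
            obs = dcts[(gene, treatment)]
            if len(obs) < 2:
                raise ValueError(f"gene {gene}/{treatment}: need >= 2 replicates")
            fold = fold_change(float(np.mean(obs)), float(np.mean(ref)))
            t_res = stats.ttest_ind(obs, ref, equal_var=not welch)
            p = float(t_res.pvalue)
            if p < alpha and fold >= fold_min:
                call = "up"
            elif p < alpha and fold <= 1.0 / fold_min:
                call = "down"
            else:
                call = "unchanged"
            calls.append(RegulationCall(gene, treatment, fold, p, call))
    return calls


def calls_table(calls: list[RegulationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [c.gene_id for c in calls],
            "treatment": [c.treatment for c in calls],
            "fold_change": [c.fold_change for c in calls],
            "p_value": [c.p_value for c in calls],
            "call": [c.call for c in calls],
        }
    )


def changed_counts(calls: list[RegulationCall]) -> pd.Series:
    """Number of genes called up or down per treatment."""
    frame = calls_table(calls)
    changed = frame[frame["call"] != "unchanged"]
    return changed.groupby("treatment")["gene"].nunique()
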