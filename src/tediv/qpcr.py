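"""Relative expression by the comparative-threshold (ΔΔCt) method.

For each subject, ΔCt = Ct(target) − Ct(reference) is computed within each
treatment; ΔΔCt = ΔCt(drug) − ΔCt(control); the fold change is 2^(−ΔΔCt),
i.e. expression relative to the control condition after normalising to a
reference gene.  Replicate Ct values within one (subject, treatment, gene)
cell are averaged before the differences are taken.  Subjects missing any
required Ct are excluded with a warning rather than failing the run.

Fold changes are averaged on the linear scale to match the usual bar-plot
presentation; a log2-scale (geometric) summary is available as an option.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError

CT_COLUMNS = ["subject_id", "species", "treatment", "gene", "ct"]
TREATMENTS = ("drug", "control")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise ParameterError(f"Ct table missing columns: {sorted(missing)}")
    return validate_ct_table(table)


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    if (table["ct"] <= 0).any():
        raise ParameterError("Ct values must be positive cycle numbers")
    bad = set(table["treatment"]) - set(TREATMENTS)
    if bad:
        raise ParameterError(f"unknown treatments {sorted(bad)}; use drug/control")
    return table


def delta_delta_ct(
    table: pd.DataFrame, target_gene: str, reference_gene: str
) -> pd.DataFrame:
    """Per-subject ΔΔCt fold change of *target_gene* vs *reference_gene*.

    Returns a frame with columns subject_id, species, delta_ct_drug,
    delta_ct_control, delta_delta_ct, fold_change.  Subjects with any
    missing Ct are dropped with a warning.
    """
    validate_ct_table(table)
    cells = (
        table.groupby(["subject_id", "species", "treatment", "gene"])["ct"]
        .mean()
        .reset_index()
    )
    rows = []
    for (subject, species), sub in cells.groupby(["subject_id", "species"]):
        lookup = {
            (t.treatment, t.gene): t.ct for t in sub.itertuples()
        }
        needed = [
            (trt, gene) for trt in TREATMENTS for gene in (target_gene, reference_gene)
        ]
        if any(key not in lookup for key in needed):
            warnings.warn(
                f"subject {subject!r}: incomplete Ct data for "
                f"{target_gene}/{reference_gene}; excluded",
                stacklevel=2,
            )
            continue
        d_drug = lookup[("drug", target_gene)] - lookup[("drug", reference_gene)]
        d_ctrl = lookup[("control", target_gene)] - lookup[("control", reference_gene)]
        ddct = d_drug - d_ctrl
        rows.append(
            {
                "subject_id": subject,
                "species": species,
                "delta_ct_drug": d_drug,
                "delta_ct_control": d_ctrl,
                "delta_delta_ct": ddct,
                "fold_change": 2.0 ** (-ddct),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "species", "delta_ct_drug", "delta_ct_control",
            "delta_delta_ct", "fold_change",
        ],
    )


def summarize_fold(folds, log_scale: bool = False) -> tuple[float, float]:
    """(mean, SEM) of per-subject fold changes.

    With ``log_scale=True`` the summary is geometric: the mean is
    2^(mean log2 fold) and the SEM is that of the log2 folds.
    """
    folds = np.asarray(list(folds), dtype=float)
    n = folds.size
    if n < 1:
        raise ParameterError("need at least one fold change")
    if log_scale:
        logs = np.log2(folds)
        center = float(2.0 ** logs.mean())
        spread = logs
    else:
        center = float(folds.mean())
        spread = folds
    if n == 1:
        warnings.warn("single observation: SEM reported as 0", stacklevel=2)
        return center, 0.0
    sem = float(spread.std(ddof=1) / math.sqrt(n))
    return center, sem
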