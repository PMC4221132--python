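"""Relative-expression analysis of qRT-PCR Ct tables by the 2^-ddCt method.

Each replicate's cycle threshold for a target gene is normalized to a
reference gene measured in the same tissue and replicate (dCt), then to the
mean dCt of a calibrator tissue (ddCt); relative expression is 2^-ddCt.
Replicate folds are summarized as mean +- sd, and tissues are grouped with a
compact letter display from pairwise Welch t-tests on the replicate dCt
values (tissues sharing a letter are not significantly different).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CT_COLUMNS = ["gene", "tissue", "replicate", "ct", "is_reference"]


@dataclass
class RelativeExpression:
    gene: str
    tissue: str
    fold: float        # mean of replicate 2^-ddCt values
    sd: float
    group: str = ""    # compact letter display


def delta_delta_ct(ct_target: float, ct_reference: float,
                   calibrator_delta: float) -> float:
    """2^-(dCt - calibrator_delta) with dCt = ct_target - ct_reference."""
    ddct = (ct_target - ct_reference) - calibrator_delta
    return 2.0 ** (-ddct)


def _welch_p(x: np.ndarray, y: np.ndarray) -> float:
    if np.allclose(x.var(ddof=1) + y.var(ddof=1), 0.0):
        return 0.0 if not np.isclose(x.mean(), y.mean()) else 1.0
    return stats.ttest_ind(x, y, equal_var=False).pvalue


def compact_letter_display(labels: Sequence[str],
                           significant: dict) -> dict[str, str]:
    """Greedy letter grouping: labels sharing a letter are not sig. different.

    ``significant`` maps frozenset({a, b}) -> bool.  Labels are processed in
    the given order; each joins every existing letter group it does not
    conflict with, or opens a new one.
    """
    groups: list[list[str]] = []
    done: list[str] = []
    for lab in labels:
        placed = False
        for g in groups:
            if all(not significant.get(frozenset((lab, other)), False)
                   for other in g):
                g.append(lab)
                placed = True
        if not placed:
            # absorb step: earlier labels compatible with the new group join it
            group = [lab]
            for other in done:
                if all(not significant.get(frozenset((other, member)), False)
                       for member in group):
                    group.append(other)
            groups.append(group)
        done.append(lab)
    letters = {}
    for idx, g in enumerate(groups):
        letter = chr(ord("a") + idx)
        for lab in g:
            letters[lab] = letters.get(lab, "") + letter
    return letters


def summarize(table: pd.DataFrame, calibrator_tissue: str,
              reference_gene: str, alpha: float = 0.05,
              ) -> list[RelativeExpression]:
    """Per gene x tissue relative expression with letter groups.

    ``table`` columns: gene, tissue, replicate, ct, is_reference.  Folds are
    computed per replicate and then averaged, which propagates replicate
    variance into the reported sd.  Tissues missing the reference gene are
    skipped with a warning.
    """
    ref = table[(table["gene"] == reference_gene) & table["is_reference"]]
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} not in table")
    ref_ct = ref.set_index(["tissue", "replicate"])["ct"]

    results: list[RelativeExpression] = []
    for gene, sub in table[~table["is_reference"]].groupby("gene"):
        dct = {}
        for tissue, tsub in sub.groupby("tissue"):
            if tissue not in ref_ct.index.get_level_values(0):
                logger.warning("tissue %s lacks reference gene; skipped", tissue)
                continue
            values = []
            for _, row in tsub.iterrows():
                key = (tissue, row["replicate"])
                if key in ref_ct.index:
                    values.append(row["ct"] - ref_ct.loc[key])
            if len(values) >= 2:
                dct[tissue] = np.asarray(values, dtype=float)
        if calibrator_tissue not in dct:
            logger.warning("gene %s lacks calibrator tissue; skipped", gene)
            continue
        calib = dct[calibrator_tissue].mean()
        sig = {}
        tissues = sorted(dct)
        for i, a in enumerate(tissues):
            for b in tissues[i + 1:]:
                sig[frozenset((a, b))] = _welch_p(dct[a], dct[b]) < alpha
        order = sorted(tissues, key=lambda t: dct[t].mean())  # most expressed first
        letters = compact_letter_display(order, sig)
        for tissue in tissues:
            folds = 2.0 ** (-(dct[tissue] - calib))
            results.append(RelativeExpression(
                gene=gene, tissue=tissue, fold=float(folds.mean()),
                sd=float(folds.std(ddof=1)), group=letters[tissue]))
    return results


def results_to_frame(results: Sequence[RelativeExpression]) -> pd.DataFrame:
    rows = [(r.gene, r.tissue, r.fold, r.sd, r.group) for r in results]
    return pd.DataFrame(rows, columns=["gene", "tissue", "fold", "sd", "group"])


def read_ct_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    df["is_reference"] = df["is_reference"].astype(bool)
    return df
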