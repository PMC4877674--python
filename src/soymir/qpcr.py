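"""Relative qPCR quantitation by the 2^-ddCt method.

Ct tables hold one row per (gene, condition, replicate). Expression of a
gene is normalised to a reference gene within each replicate
(dCt = Ct_gene − Ct_reference), the calibrator condition's mean dCt is
subtracted (ddCt), and relative expression reported as 2^−ddCt. U6 is the
conventional reference for miRNAs and an actin gene for mRNA targets.
Group comparisons use Welch's t-test on the per-replicate dCt values — for
two groups this is the two-sample special case of the ANOVA customarily
quoted for such designs — with significance stars at p < 0.05 (*) and
p < 0.01 (**).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ["gene", "condition", "replicate", "ct"]


def load_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return df


@dataclass
class RelativeExpression:
    gene: str
    condition: str
    calibrator: str
    fold_change: float            # 2^-ddCt
    replicate_folds: list[float]  # per-replicate 2^-ddCt values
    delta_ct: list[float]
    delta_ct_calibrator: list[float]


def _delta_ct(table: pd.DataFrame, gene: str, reference: str, condition: str) -> np.ndarray:
    sub = table[table["condition"] == condition]
    g = sub[sub["gene"] == gene].sort_values("replicate")["ct"].to_numpy(float)
    r = sub[sub["gene"] == reference].sort_values("replicate")["ct"].to_numpy(float)
    if len(g) == 0:
        raise ValueError(f"gene {gene!r} absent in condition {condition!r}")
    if len(r) == 0:
        raise ValueError(f"reference gene {reference!r} absent in condition {condition!r}")
    if len(g) == len(r):
        return g - r  # replicate-paired normalisation
    return g - r.mean()


def delta_delta_ct(table: pd.DataFrame, gene: str, reference: str,
                   condition: str, calibrator: str) -> RelativeExpression:
    """Relative expression of ``gene`` in ``condition`` vs ``calibrator``.

    ddCt = mean dCt(condition) − mean dCt(calibrator); per-replicate fold
    changes (2^−(dCt_rep − mean dCt calibrator)) are retained for
    dispersion summaries.
    """
    dct = _delta_ct(table, gene, reference, condition)
    dct_cal = _delta_ct(table, gene, reference, calibrator)
    ddct = dct.mean() - dct_cal.mean()
    rep_folds = 2.0 ** (-(dct - dct_cal.mean()))
    return RelativeExpression(gene, condition, calibrator,
                              float(2.0 ** (-ddct)), list(rep_folds),
                              list(dct), list(dct_cal))


def summarize_replicates(rel: RelativeExpression) -> dict:
    """Mean ± SD of replicate fold changes and a two-group Welch test.

    The test compares dCt replicates between condition and calibrator
    (approximately normal scale); stars: ** for p < 0.01, * for p < 0.05.
    With fewer than 2 replicates in either group only the summaries are
    returned (no test).
    """
    folds = np.asarray(rel.replicate_folds, float)
    out = {
        "gene": rel.gene,
        "condition": rel.condition,
        "fold_change": rel.fold_change,
        "mean": float(folds.mean()),
        "sd": float(folds.std(ddof=1)) if len(folds) > 1 else float("nan"),
        "p_value": float("nan"),
        "stars": "",
    }
    if len(rel.delta_ct) >= 2 and len(rel.delta_ct_calibrator) >= 2:
        if np.allclose(rel.delta_ct, rel.delta_ct_calibrator):
            p = 1.0
        else:
            p = float(stats.ttest_ind(rel.delta_ct, rel.delta_ct_calibrator,
                                      equal_var=False).pvalue)
            if np.isnan(p):
                p = 1.0
        out["p_value"] = p
        out["stars"] = "**" if p < 0.01 else ("*" if p < 0.05 else "")
    return out


def analyze_ct_table(table: pd.DataFrame, reference: str,
                     calibrator: str = "control",
                     condition: str = "chilling") -> pd.DataFrame:
    """Per-gene relative expression with replicate summaries."""
    genes = [g for g in table["gene"].unique() if g != reference]
    rows = []
    for gene in genes:
        rel = delta_delta_ct(table, gene, reference, condition, calibrator)
        rows.append(summarize_replicates(rel))
    return pd.DataFrame(rows)
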