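"""Two-library differential expression of miRNAs.

Counts are normalised to reads-per-million of total miRNA reads (RPM),
ratios reported as log2(chilling/control), and significance assessed with a
two-library count comparison in the Audic–Claverie conditional-binomial
form: conditional on the summed count n = x + y, y follows
Binomial(n, N2/(N1+N2)) under the null of equal relative abundance, and the
two-sided p-value sums all outcomes no more likely than the observed one
(minlike convention). The summation is done directly in log space. No
multiple-testing correction is applied by default (raw p ≤ 0.001 with
|log2 ratio| ≥ 1 defines the calls); a Benjamini–Hochberg flag and a
Fisher-exact alternative test are provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

DEFAULT_P = 0.001
DEFAULT_LFC = 1.0


@dataclass
class ExpressionRecord:
    mirna_id: str
    raw_control: int
    raw_chilling: int
    rpm_control: float = 0.0
    rpm_chilling: float = 0.0
    log2_ratio: float | None = None
    p_value: float = 1.0
    call: str = "ns"


def rpm_normalize(count: int, library_total: int) -> float:
    """count / total miRNA reads × 1e6 (no pseudocount at this stage)."""
    if library_total <= 0:
        raise ValueError("library miRNA total must be positive")
    return count / library_total * 1e6


def log2_ratio(norm_control: float, norm_chilling: float,
               pseudocount: float = 0.0) -> float | None:
    """log2((chilling + pc) / (control + pc)); None when undefined.

    With the default pseudocount of 0 a ratio is only defined when both
    values are positive; records with one zero get ±inf only if a positive
    pseudocount is configured, and double zeros are always undefined.
    """
    if norm_control < 0 or norm_chilling < 0:
        raise ValueError("normalized values must be non-negative")
    a, b = norm_control + pseudocount, norm_chilling + pseudocount
    if a == 0 and b == 0:
        return None
    if a == 0:
        return float("inf")
    if b == 0:
        return float("-inf")
    return float(np.log2(b / a))


def count_test(raw_control: int, raw_chilling: int,
               total_control: int, total_chilling: int) -> float:
    """Two-sided conditional-binomial p-value for a two-library comparison.

    Direct summation of the conditional distribution in log space: given
    n = x + y, P(Y = k) = C(n, k) p^k (1-p)^(n-k) with
    p = N2/(N1+N2); the p-value is Σ P(k) over all k with
    P(k) ≤ P(y_obs)·(1+1e-7) (minlike two-sided convention).
    """
    x, y = int(raw_control), int(raw_chilling)
    if x < 0 or y < 0 or total_control < x or total_chilling < y:
        raise ValueError("counts must be non-negative and within library totals")
    n = x + y
    if n == 0:
        return 1.0
    p = total_chilling / (total_control + total_chilling)
    k = np.arange(n + 1)
    logpmf = (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
              + k * np.log(p) + (n - k) * np.log1p(-p))
    cutoff = logpmf[y] + np.log1p(1e-7)
    keep = logpmf <= cutoff
    return float(min(1.0, np.exp(logsumexp(logpmf[keep]))))


def fisher_test(raw_control: int, raw_chilling: int,
                total_control: int, total_chilling: int) -> float:
    """Pluggable alternative: Fisher's exact test on the 2×2 count table."""
    table = [[raw_control, total_control - raw_control],
             [raw_chilling, total_chilling - raw_chilling]]
    return float(stats.fisher_exact(table)[1])


def call_differential(counts: pd.DataFrame,
                      p_threshold: float = DEFAULT_P,
                      lfc_threshold: float = DEFAULT_LFC,
                      pseudocount: float = 0.0,
                      test=count_test,
                      fdr: bool = False) -> pd.DataFrame:
    """Full DE table from a count matrix with columns control / chilling.

    Normalisation uses each library's total miRNA reads. Calls: ``up`` when
    log2 ≥ lfc_threshold and p ≤ p_threshold, ``down`` for the mirrored
    bound, otherwise ``ns``. Rows are sorted by log2 ratio ascending;
    undefined ratios (both counts zero at zero pseudocount) sort last and
    are flagged ``undefined``.
    """
    total_c = int(counts["control"].sum())
    total_t = int(counts["chilling"].sum())
    rows = []
    for mirna_id, row in counts.iterrows():
        x, y = int(row["control"]), int(row["chilling"])
        rec = ExpressionRecord(str(mirna_id), x, y,
                               rpm_normalize(x, total_c), rpm_normalize(y, total_t))
        rec.log2_ratio = log2_ratio(rec.rpm_control, rec.rpm_chilling, pseudocount)
        rec.p_value = test(x, y, total_c, total_t)
        rows.append(rec)

    pvals = np.array([r.p_value for r in rows])
    padj = _bh_adjust(pvals) if fdr else pvals
    for rec, q in zip(rows, padj):
        lr = rec.log2_ratio
        if lr is None:
            rec.call = "undefined"
        elif q <= p_threshold and lr >= lfc_threshold:
            rec.call = "up"
        elif q <= p_threshold and lr <= -lfc_threshold:
            rec.call = "down"
        else:
            rec.call = "ns"

    df = pd.DataFrame(
        {
            "mirna_id": [r.mirna_id for r in rows],
            "raw_control": [r.raw_control for r in rows],
            "raw_chilling": [r.raw_chilling for r in rows],
            "rpm_control": [r.rpm_control for r in rows],
            "rpm_chilling": [r.rpm_chilling for r in rows],
            "log2_ratio": [np.nan if r.log2_ratio is None else r.log2_ratio for r in rows],
            "p_value": [r.p_value for r in rows],
            "p_adjusted": padj,
            "call": [r.call for r in rows],
        }
    )
    return df.sort_values("log2_ratio", na_position="last").reset_index(drop=True)


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, pvals[i] * m / (rank + 1))
        adj[i] = running
    return adj


def format_de_table(df: pd.DataFrame, sequences: dict[str, str] | None = None) -> pd.DataFrame:
    """Report-time table with two-decimal rounding of RPM and log2 columns."""
    out = pd.DataFrame(
        {
            "miRNA": df["mirna_id"],
            "sequence": [
                (sequences or {}).get(mid, "") for mid in df["mirna_id"]
            ],
            "norm_control": df["rpm_control"].round(2),
            "norm_chilling": df["rpm_chilling"].round(2),
            "log2": df["log2_ratio"].round(2),
            "p_value": df["p_value"],
            "call": df["call"],
        }
    )
    return out
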