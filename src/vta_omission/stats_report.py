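"""Statistics layer: exact 2x2 tests, rank correlation, paired t, summary tables.

The headline inferential claims of the analysis are (i) comparisons of
response *proportions* between trial epochs (Fisher's exact test on 2x2
responder tables), (ii) the across-animal rank correlation between the
omission-evoked calcium signal and the behavioral extinction magnitude
(Spearman), and (iii) within-population paired t-tests.  This module owns
those statistics plus the bookkeeping that turns per-unit response labels
into contingency tables.

Two-sided Fisher convention: the p-value is the sum of hypergeometric point
probabilities, over all tables with the observed margins, that do not exceed
the observed table's point probability (with a 1e-7 relative tolerance for
floating-point ties).  This is the convention used by R's ``fisher.test``
and ``scipy.stats.fisher_exact`` and reproduces the published p-values from
the published counts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import StatisticsError

__all__ = [
    "TestResult",
    "ContingencyTable",
    "fisher_exact_2x2",
    "spearman_corr",
    "paired_t",
    "build_proportion_tables",
    "omission_learning_correlation",
]

#: Relative tolerance when comparing hypergeometric point probabilities.
FISHER_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class TestResult:
    """Outcome of one statistical test.

    ``degenerate`` flags results where the test's assumptions collapsed
    (zero margins, constant inputs, zero-variance differences); the p-value
    then follows the documented degenerate contract rather than a sampling
    distribution.
    """

    statistic: float
    p_two_sided: float
    method: str
    df: Optional[float] = None
    n: Optional[int] = None
    degenerate: bool = False
    note: str = ""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 count table: rows are epochs, columns responder / non-responder."""

    a: int
    b: int
    c: int
    d: int
    row_labels: Tuple[str, str] = ("epoch_1", "epoch_2")
    col_labels: Tuple[str, str] = ("responder", "nonresponder")

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise StatisticsError(f"contingency counts must be non-negative integers, got {v}")

    @property
    def counts(self) -> Tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_exact_2x2(table: ContingencyTable) -> TestResult:
    """Two-sided Fisher's exact test by hypergeometric enumeration.

    Enumerates every table compatible with the observed margins and sums the
    point probabilities that are at most the observed one.  A zero margin
    makes every statistic conditionally constant; the test is then degenerate
    with p = 1.
    """
    a, b, c, d = table.counts
    n_total = table.total
    row1, col1 = a + b, a + c
    if n_total == 0 or row1 == 0 or row1 == n_total or col1 == 0 or col1 == n_total:
        return TestResult(
            statistic=float("nan"), p_two_sided=1.0, method="fisher_exact",
            n=n_total, degenerate=True, note="zero margin",
        )
    k_min = max(0, row1 + col1 - n_total)
    k_max = min(row1, col1)
    support = np.arange(k_min, k_max + 1)
    pmf = stats.hypergeom.pmf(support, n_total, row1, col1)
    p_obs = pmf[a - k_min]
    p = float(pmf[pmf <= p_obs * (1.0 + FISHER_TIE_RTOL)].sum())
    odds = float("inf") if b * c == 0 else (a * d) / (b * c)
    if a * d == 0 and b * c == 0:
        odds = float("nan")
    return TestResult(
        statistic=odds, p_two_sided=min(p, 1.0), method="fisher_exact", n=n_total,
    )


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, chunk: int = 100_000) -> float:
    """Exact two-sided permutation p for Spearman's rho.

    Enumerates all n! pairings of the (tie-averaged) ranks.  Because the rank
    marginals are fixed under permutation, comparing |rho| is equivalent to
    comparing the absolute centred cross-product, which vectorises cleanly.
    """
    n = rx.size
    rx_c = rx - rx.mean()
    obs = abs(float(rx_c @ (ry - ry.mean())))
    count = 0
    total = 0
    perm_iter = itertools.permutations(ry)
    while True:
        block = list(itertools.islice(perm_iter, chunk))
        if not block:
            break
        mat = np.asarray(block)
        dots = np.abs(mat @ rx_c)
        count += int((dots >= obs - 1e-9 * max(obs, 1.0)).sum())
        total += mat.shape[0]
    return count / total


def spearman_corr(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "auto",
    exact_max_n: int = 10,
) -> TestResult:
    """Spearman rank correlation with exact or t-approximate p-value.

    Ranks are tie-averaged.  With ``method="auto"`` the two-sided p-value is
    an exact permutation enumeration for n <= ``exact_max_n`` and the usual
    t-distribution approximation for larger samples; either convention can be
    forced with ``method="exact"`` / ``method="approx"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatisticsError("x and y must be 1-d sequences of equal length")
    n = x.size
    if n < 3:
        raise StatisticsError("spearman_corr needs at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(
            statistic=float("nan"), p_two_sided=float("nan"),
            method="spearman", n=n, degenerate=True, note="constant input",
        )
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    use_exact = method == "exact" or (method == "auto" and n <= exact_max_n)
    if use_exact:
        p = _exact_spearman_p(rx, ry)
        tag = "spearman_exact_permutation"
    else:
        p = float(stats.spearmanr(x, y).pvalue)
        tag = "spearman_t_approx"
    return TestResult(statistic=rho, p_two_sided=p, method=tag, n=n)


def paired_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Paired two-sided t-test on element-wise differences, df = n - 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise StatisticsError("paired_t needs two equal-length 1-d samples with n >= 2")
    d = x - y
    n = d.size
    if np.all(d == 0):
        return TestResult(statistic=0.0, p_two_sided=1.0, method="paired_t", df=n - 1, n=n)
    if d.std(ddof=1) == 0:
        # all differences identical and nonzero: t diverges
        t = math.copysign(float("inf"), d.mean())
        return TestResult(
            statistic=t, p_two_sided=0.0, method="paired_t", df=n - 1, n=n,
            degenerate=True, note="zero-variance nonzero differences",
        )
    res = stats.ttest_rel(x, y)
    return TestResult(
        statistic=float(res.statistic), p_two_sided=float(res.pvalue),
        method="paired_t", df=float(n - 1), n=n,
    )


def build_proportion_tables(
    unit_labels: pd.DataFrame,
    epoch_pairs: Iterable[Tuple[str, str]] = (("e_ext", "hab"), ("l_ext", "hab")),
    criteria: Iterable[str] = ("omission", "cs"),
    responses: Iterable[str] = ("excited", "inhibited"),
) -> list[dict]:
    """Assemble responder/non-responder 2x2 tables and their exact tests.

    ``unit_labels`` must carry one row per unit per epoch with columns
    ``unit_id``, ``cell_class``, ``epoch``, ``omission_label``, ``cs_label``.
    Units labelled ``unclassifiable`` for a criterion are excluded from that
    criterion's denominators.  Pairs where neither epoch has any responder
    are returned with a degenerate test (nothing to compare).
    """
    if unit_labels.empty:
        raise StatisticsError("no unit labels to tabulate")
    out: list[dict] = []
    for cell_class in sorted(unit_labels["cell_class"].unique()):
        sub = unit_labels[unit_labels["cell_class"] == cell_class]
        for criterion in criteria:
            col = f"{criterion}_label"
            for epoch_a, epoch_b in epoch_pairs:
                rows = {}
                for ep in (epoch_a, epoch_b):
                    lab = sub.loc[sub["epoch"] == ep, col]
                    lab = lab[lab != "unclassifiable"]
                    rows[ep] = lab
                for response in responses:
                    n_a, n_b = len(rows[epoch_a]), len(rows[epoch_b])
                    k_a = int((rows[epoch_a] == response).sum())
                    k_b = int((rows[epoch_b] == response).sum())
                    tab = ContingencyTable(
                        k_a, n_a - k_a, k_b, n_b - k_b,
                        row_labels=(epoch_a, epoch_b),
                        col_labels=(response, f"not_{response}"),
                    )
                    if k_a == 0 and k_b == 0:
                        test = TestResult(
                            statistic=float("nan"), p_two_sided=1.0,
                            method="fisher_exact", n=tab.total,
                            degenerate=True, note="no responders in either epoch",
                        )
                    else:
                        test = fisher_exact_2x2(tab)
                    out.append(
                        {
                            "cell_class": cell_class,
                            "criterion": criterion,
                            "response": response,
                            "epoch_pair": (epoch_a, epoch_b),
                            "table": tab,
                            "test": test,
                        }
                    )
    return out


def omission_learning_correlation(
    omission_dff: Sequence[float],
    freezing_change: Sequence[float],
    reward_dff: Optional[Sequence[float]] = None,
    method: str = "auto",
) -> dict:
    """Correlate the omission calcium signal with extinction magnitude.

    Returns the Spearman test between per-animal early-extinction omission
    dF/F and the E-Ext minus L-Ext freezing change, plus — when reward
    responses are supplied — the control correlation between the reward dF/F
    and the same freezing change (a recording-placement control: reward
    responses index fiber placement quality but not extinction learning).
    """
    result = {"omission": spearman_corr(omission_dff, freezing_change, method=method)}
    if reward_dff is not None:
        result["reward_control"] = spearman_corr(reward_dff, freezing_change, method=method)
    return result
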