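"""Concordance and association statistics for the adjudication review and
the demographic comparisons: Fleiss' Kappa, chi-squared with adjusted
standardized residuals, exact Fisher tests (RxC enumeration with a
Monte-Carlo fallback), and the stratified adjudication sampler.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sp_stats

log = logging.getLogger(__name__)

ENUMERATION_GUARD = 10_000_000


class UndefinedKappaError(ValueError):
    """All rating mass in one category: chance agreement is 1, kappa undefined."""


class CapacityError(RuntimeError):
    """Exact enumeration would exceed the table-count guard."""


@dataclass(frozen=True)
class RatingMatrix:
    """n items x k categories counts with a constant number of raters."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", arr)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 2:
            raise ValueError("rating matrix must be n x k with k >= 2")
        if (arr < 0).any():
            raise ValueError("rating counts must be nonnegative")
        row_sums = arr.sum(axis=1)
        if (row_sums != row_sums[0]).any():
            raise ValueError("every item must have the same number of ratings")
        if row_sums[0] < 2:
            raise ValueError("need at least 2 raters per item")

    @property
    def n_items(self) -> int:
        return self.counts.shape[0]

    @property
    def n_raters(self) -> int:
        return int(self.counts.sum(axis=1)[0])


def fleiss_kappa(matrix: RatingMatrix) -> float:
    """Fleiss' chance-corrected multi-rater agreement.

    kappa = (P_bar - Pe_bar) / (1 - Pe_bar), with per-item agreement
    P_i = sum_j n_ij (n_ij - 1) / (r (r - 1)) and chance agreement
    Pe_bar = sum_j p_j^2 over marginal category proportions.
    """
    counts = matrix.counts.astype(float)
    r = matrix.n_raters
    p_items = (counts * (counts - 1)).sum(axis=1) / (r * (r - 1))
    p_bar = p_items.mean()
    p_j = counts.sum(axis=0) / counts.sum()
    pe_bar = float((p_j**2).sum())
    if pe_bar >= 1.0 - 1e-12:
        raise UndefinedKappaError("all ratings fall in a single category")
    return float((p_bar - pe_bar) / (1.0 - pe_bar))


def unanimity_rate(matrix: RatingMatrix) -> float:
    """Fraction of items where one category holds every rating."""
    return float((matrix.counts.max(axis=1) == matrix.n_raters).mean())


@dataclass(frozen=True)
class ChiSquaredResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    adjusted_residuals: np.ndarray


def chi_squared(table: np.ndarray) -> ChiSquaredResult:
    """Pearson chi-squared with adjusted standardized residuals.

    Residuals are (O - E) / sqrt(E (1 - row/N) (1 - col/N)), which localize
    which cells drive a significant statistic.
    """
    observed = np.asarray(table, dtype=float)
    if observed.ndim != 2 or observed.size == 0:
        raise ValueError("contingency table must be 2-dimensional")
    if (observed < 0).any():
        raise ValueError("counts must be nonnegative")
    total = observed.sum()
    if total <= 0:
        raise ValueError("contingency table is empty")
    rows = observed.sum(axis=1)
    cols = observed.sum(axis=0)
    expected = np.outer(rows, cols) / total
    if (expected <= 0).any():
        raise ValueError("degenerate table: zero expected count")
    statistic = float(((observed - expected) ** 2 / expected).sum())
    df = (observed.shape[0] - 1) * (observed.shape[1] - 1)
    p_value = float(sp_stats.chi2.sf(statistic, df)) if df > 0 else 1.0
    denom = np.sqrt(
        expected
        * (1.0 - rows[:, None] / total)
        * (1.0 - cols[None, :] / total)
    )
    adjusted = np.where(denom > 0, (observed - expected) / np.where(denom > 0, denom, 1.0), 0.0)
    return ChiSquaredResult(statistic, df, p_value, expected, adjusted)


def _log_table_prob(table: np.ndarray, log_const: float) -> float:
    return log_const - special.gammaln(table + 1).sum()


def _enumerate_tables(rows: np.ndarray, cols: np.ndarray, guard: int):
    """Yield every nonnegative integer table with the given margins.

    Recursive row-by-row fill; raises CapacityError past ``guard`` tables.
    """
    n_rows, n_cols = len(rows), len(cols)
    count = 0

    def fill(row_idx: int, remaining_cols: np.ndarray, acc: list[np.ndarray]):
        nonlocal count
        if row_idx == n_rows - 1:
            if (remaining_cols < 0).any():
                return
            count += 1
            if count > guard:
                raise CapacityError(
                    f"exact enumeration exceeds {guard} tables; enable Monte-Carlo"
                )
            yield np.vstack(acc + [remaining_cols])
            return
        target = rows[row_idx]

        def fill_row(col_idx: int, left: int, row_acc: list[int]):
            if col_idx == n_cols - 1:
                if 0 <= left <= remaining_cols[col_idx]:
                    yield row_acc + [left]
                return
            for v in range(min(left, remaining_cols[col_idx]) + 1):
                yield from fill_row(col_idx + 1, left - v, row_acc + [v])

        for row in fill_row(0, int(target), []):
            row_arr = np.array(row)
            yield from fill(row_idx + 1, remaining_cols - row_arr, acc + [row_arr])

    yield from fill(0, cols.copy(), [])


def fisher_exact(
    table: np.ndarray,
    *,
    monte_carlo: bool = False,
    n_replicates: int = 20_000,
    seed: int | None = None,
    guard: int = ENUMERATION_GUARD,
) -> float:
    """Two-sided exact test for an RxC table, point-probability rule.

    The p-value sums the probabilities (under the fixed-margin
    multivariate hypergeometric) of all tables whose point probability does
    not exceed the observed table's.  When enumeration would exceed
    ``guard`` tables, a seeded Monte-Carlo estimate is used instead if
    ``monte_carlo`` is set; otherwise a CapacityError is raised.
    """
    observed = np.asarray(table, dtype=int)
    if observed.ndim != 2 or (observed < 0).any() or observed.sum() == 0:
        raise ValueError("need a nonnegative, nonempty 2-d table")
    rows = observed.sum(axis=1)
    cols = observed.sum(axis=0)
    log_const = (
        special.gammaln(rows + 1).sum()
        + special.gammaln(cols + 1).sum()
        - special.gammaln(observed.sum() + 1)
    )
    log_p_obs = _log_table_prob(observed, log_const)
    tol = 1e-9
    if not monte_carlo:
        try:
            total = 0.0
            for cand in _enumerate_tables(rows, cols, guard):
                log_p = _log_table_prob(cand, log_const)
                if log_p <= log_p_obs + tol:
                    total += float(np.exp(log_p))
            return min(total, 1.0)
        except CapacityError:
            raise
    rng = np.random.default_rng(seed)
    row_labels = np.repeat(np.arange(len(rows)), rows)
    col_labels = np.repeat(np.arange(len(cols)), cols)
    hits = 0
    for _ in range(n_replicates):
        permuted = rng.permutation(col_labels)
        cand = np.zeros_like(observed)
        np.add.at(cand, (row_labels, permuted), 1)
        if _log_table_prob(cand, log_const) <= log_p_obs + tol:
            hits += 1
    log.info("fisher_exact Monte-Carlo: %d replicates, seed=%s", n_replicates, seed)
    return (hits + 1) / (n_replicates + 1)


def sample_adjudication(
    mentions: pd.DataFrame,
    notes: dict[str, str],
    per_method_n: int,
    seed: int,
    n_raters: int = 3,
) -> pd.DataFrame:
    """Stratified, seeded, without-replacement note-level review sample.

    One stratum per detection method; ``per_method_n`` distinct notes drawn
    from each.  Strata smaller than the quota are sampled exhaustively with
    a warning; empty strata are skipped with a warning.  The sheet carries
    the note text, the highlighted span, and blank rating columns.
    """
    rng = np.random.default_rng(seed)
    sheets = []
    for method in sorted(mentions["method"].unique()):
        stratum = mentions[mentions["method"] == method]
        note_ids = sorted(stratum["note_id"].unique())
        if not note_ids:
            log.warning("adjudication stratum %r is empty; skipped", method)
            continue
        n_take = per_method_n
        if len(note_ids) < per_method_n:
            log.warning(
                "stratum %r has %d notes < quota %d; sampling all",
                method,
                len(note_ids),
                per_method_n,
            )
            n_take = len(note_ids)
        chosen = rng.choice(note_ids, size=n_take, replace=False)
        for note_id in chosen:
            first = stratum[stratum["note_id"] == note_id].iloc[0]
            row = {
                "note_id": note_id,
                "method": method,
                "surface": first["surface"],
                "start": int(first["start"]),
                "end": int(first["end"]),
                "note_text": notes.get(note_id, ""),
            }
            for r in range(1, n_raters + 1):
                row[f"rater_{r}"] = ""
            sheets.append(row)
    columns = ["note_id", "method", "surface", "start", "end", "note_text"] + [
        f"rater_{r}" for r in range(1, n_raters + 1)
    ]
    return pd.DataFrame(sheets, columns=columns)
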