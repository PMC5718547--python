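"""Observer-score aggregation, agreement summary, and exact Wilcoxon tests.

Two observers each scored ten patients by picking, for five views per
patient, which of two 4D CT sortings showed fewer or smaller artifacts
(+1 recalculated-phase set, 0 neither, -1 original-phase set); the patient
score is the mean of the five view scores, so it lies in [-1, +1] in steps
of 0.2.  The study's published per-patient score table and observer
selection cross-tabulation ship as packaged CSV fixtures.

The signed-rank test here follows Wilcoxon's original convention: zero
differences are discarded, tied absolute differences get mid-ranks, and the
two-sided p-value is the exact probability, under random sign assignment
over the observed rank multiset, of a rank sum at least as far from its
mean n(n+1)/4 as observed.  For n_effective <= 20 the full 2^n sign
distribution is computed (via its generating function, which enumerates it
exactly); beyond that a tie-corrected normal approximation is used and
flagged in ``method``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import NoEffectiveObservationsError

__all__ = [
    "CHOICES",
    "PatientScoreTable",
    "SelectionRecord",
    "AgreementTable",
    "WilcoxonResult",
    "load_patient_scores",
    "load_selection_records",
    "view_scores_to_patient_score",
    "agreement_summary",
    "wilcoxon_exact",
    "wilcoxon_paired",
]

CHOICES = ("recalculated", "neither", "original")
_ZERO_TOL = 1e-12


@dataclass
class PatientScoreTable:
    """Per-patient observer and automated scores, all in [-1, +1]."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"patient", "observer1", "observer2", "average", "automated"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"score table missing columns: {sorted(missing)}")
        cols = ["observer1", "observer2", "average", "automated"]
        vals = self.table[cols].to_numpy(dtype=float)
        if np.any(np.abs(vals) > 1 + _ZERO_TOL):
            raise ValueError("scores must lie in [-1, +1]")
        avg = (self.table["observer1"] + self.table["observer2"]) / 2.0
        if np.max(np.abs(avg - self.table["average"])) > _ZERO_TOL:
            raise ValueError("average column must equal the mean of the two observers")


@dataclass(frozen=True)
class SelectionRecord:
    """One pairwise image-set selection by both observers for one view."""

    patient_id: int
    view_id: int
    observer1_choice: str
    observer2_choice: str

    def __post_init__(self) -> None:
        for c in (self.observer1_choice, self.observer2_choice):
            if c not in CHOICES:
                raise ValueError(f"choice must be one of {CHOICES}, got {c!r}")


@dataclass
class AgreementTable:
    """3x3 observer-choice cross-tabulation and its agreement categories.

    Rows are observer 1's choice, columns observer 2's, both ordered
    (recalculated, neither, original).  Complete agreement: the diagonal;
    partial agreement: exactly one observer chose "neither"; complete
    disagreement: opposite picks.
    """

    counts: np.ndarray
    complete_agreement: int
    partial_agreement: int
    complete_disagreement: int

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class WilcoxonResult:
    """Outcome of a two-sided signed-rank test."""

    w_plus: float
    n_effective: int
    p_two_sided: float
    method: str


def load_patient_scores() -> PatientScoreTable:
    """The packaged per-patient score table (observer and automated scores)."""
    with importlib.resources.files("cinecompare.data").joinpath("table1.csv").open() as fh:
        return PatientScoreTable(pd.read_csv(fh))


def load_selection_records() -> list[SelectionRecord]:
    """Expand the packaged observer selection cross-tabulation into records.

    The published cross-tabulation records only the 3x3 counts, not which
    patient/view produced each cell, so the patient and view ids here are
    synthetic running indices over the 50 selections.
    """
    with importlib.resources.files("cinecompare.data").joinpath("table2.csv").open() as fh:
        counts = pd.read_csv(fh)
    records = []
    k = 0
    for _, row in counts.iterrows():
        for _ in range(int(row["count"])):
            records.append(
                SelectionRecord(
                    patient_id=k // 5 + 1,
                    view_id=k % 5 + 1,
                    observer1_choice=str(row["observer1"]),
                    observer2_choice=str(row["observer2"]),
                )
            )
            k += 1
    return records


def view_scores_to_patient_score(view_scores) -> float:
    """Mean of exactly five per-view scores, each in {+1, 0, -1}."""
    scores = list(view_scores)
    if len(scores) != 5:
        raise ValueError(f"exactly 5 view scores required, got {len(scores)}")
    if any(s not in (-1, 0, 1) for s in scores):
        raise ValueError("view scores must be +1, 0 or -1")
    return float(sum(scores)) / 5.0


def agreement_summary(records) -> AgreementTable:
    """Cross-tabulate both observers' choices and classify the agreement."""
    records = list(records)
    if not records:
        raise ValueError("no selection records supplied")
    idx = {c: i for i, c in enumerate(CHOICES)}
    counts = np.zeros((3, 3), dtype=int)
    for r in records:
        counts[idx[r.observer1_choice], idx[r.observer2_choice]] += 1
    complete = int(np.trace(counts))
    neither = idx["neither"]
    partial = int(
        counts[neither].sum() + counts[:, neither].sum() - 2 * counts[neither, neither]
    )
    disagreement = int(
        counts[idx["recalculated"], idx["original"]]
        + counts[idx["original"], idx["recalculated"]]
    )
    return AgreementTable(counts, complete, partial, disagreement)


def _exact_sign_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Counts of each doubled rank-sum value over all 2^n sign assignments.

    Generating-function convolution: the returned array ``c`` satisfies
    ``c[w] = #{sign vectors with 2*W+ == w}`` and sums to 2^n.  Ranks are
    doubled so mid-ranks (halves) become integers and the count is exact.
    """
    counts = np.zeros(int(ranks2.sum()) + 1, dtype=np.int64)
    counts[0] = 1
    top = 0
    for r in ranks2:
        r = int(r)
        new = counts.copy()
        new[r : top + r + 1] += counts[: top + 1]
        counts = new
        top += r
    return counts


def wilcoxon_exact(values, null_location: float = 0.0) -> WilcoxonResult:
    """Two-sided one-sample Wilcoxon signed-rank test against a location.

    Zero differences are dropped; tied |differences| get mid-ranks; the
    p-value is exact over all sign assignments for n_effective <= 20,
    otherwise a tie-corrected normal approximation.
    """
    d = np.asarray(values, dtype=np.float64) - null_location
    d = d[np.abs(d) > _ZERO_TOL]
    n = len(d)
    if n == 0:
        raise NoEffectiveObservationsError(
            "no effective observations: all values equal the null location"
        )
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    if n <= 20:
        ranks2 = np.rint(2 * ranks).astype(np.int64)
        counts = _exact_sign_distribution(ranks2)
        w2 = np.arange(len(counts), dtype=np.float64)
        dev = abs(2 * w_plus - 2 * mu)
        extreme = np.abs(w2 - 2 * mu) >= dev - 1e-9
        p = float(counts[extreme].sum() / counts.sum())
        method = "exact-enumeration"
    else:
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
            tie_counts**3 - tie_counts
        ) / 48.0
        z = (w_plus - mu) / np.sqrt(var)
        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
        method = "normal-approximation"
    return WilcoxonResult(w_plus=w_plus, n_effective=n, p_two_sided=p, method=method)


def wilcoxon_paired(x, y) -> WilcoxonResult:
    """Two-sided signed-rank test on paired differences x - y."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be equal-length 1D sequences")
    return wilcoxon_exact(x - y, 0.0)
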