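"""Censoring-aware descriptive statistics, relative-to-muscle distribution,
rank-correlation matrices, and the body condition index.

Censoring policy: statistics are computed on detected values only
(complete-case); censored rows are counted, never substituted, unless the
``half_lod`` policy is requested, in which case each censored threshold enters
at half its value. With tissue n of 5-10 any substitution rule dominates the
tail statistics, so the conservative drop policy is the default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CohortDataset, ValidationError

__all__ = [
    "SummaryRow",
    "RelativeDistribution",
    "summarize",
    "summary_table",
    "relative_to_muscle",
    "spearman_matrix",
    "compute_bci",
    "attach_bci",
]

logger = logging.getLogger(__name__)


class EmptySummaryError(ValidationError):
    """No detected values to summarize."""


@dataclass(frozen=True)
class SummaryRow:
    """AM +/- SD, GM, median and range of the detected values of one cell."""

    analyte: str
    tissue: str
    n_detected: int
    n_censored: int
    am: float
    sd: float
    gm: float
    median: float
    min: float
    max: float


def _apply_policy(
    values: np.ndarray, censored: np.ndarray, policy: str
) -> tuple[np.ndarray, int]:
    if policy == "drop":
        return values[~censored], int(censored.sum())
    if policy == "half_lod":
        out = values.copy()
        out[censored] = out[censored] / 2.0
        return out, int(censored.sum())
    raise ValidationError(f"unknown censoring policy {policy!r}")


def summarize(
    values,
    censored=None,
    analyte: str = "",
    tissue: str = "",
    policy: str = "drop",
) -> SummaryRow:
    """Summarize one analyte x tissue cell.

    SD uses the n-1 denominator; GM is exp(mean of logs) and requires strictly
    positive values; the median uses the midpoint rule for even n. Raises
    :class:`EmptySummaryError` when nothing is detected.
    """
    values = np.asarray(values, dtype=float)
    if censored is None:
        censored = np.zeros(values.shape, dtype=bool)
    censored = np.asarray(censored, dtype=bool)
    used, n_censored = _apply_policy(values, censored, policy)
    if used.size == 0:
        raise EmptySummaryError(f"no detected values for {analyte}/{tissue}")
    if np.any(used <= 0):
        raise ValidationError("geometric mean requires strictly positive values")
    sd = float(np.std(used, ddof=1)) if used.size > 1 else 0.0
    return SummaryRow(
        analyte=analyte,
        tissue=tissue,
        n_detected=int(used.size) if policy == "drop" else int((~censored).sum()),
        n_censored=n_censored,
        am=float(np.mean(used)),
        sd=sd,
        gm=float(np.exp(np.mean(np.log(used)))),
        median=float(np.median(used)),
        min=float(np.min(used)),
        max=float(np.max(used)),
    )


def summary_table(dataset: CohortDataset, policy: str = "drop") -> pd.DataFrame:
    """One summary row per analyte x tissue cell present in the dataset."""
    df = dataset.measurements_frame()
    rows = []
    for (analyte, tissue), g in df.groupby(["analyte", "tissue"], sort=True):
        try:
            s = summarize(
                g["value"].to_numpy(),
                g["censored"].to_numpy(),
                analyte=analyte,
                tissue=tissue,
                policy=policy,
            )
        except EmptySummaryError:
            logger.warning("all values censored for %s/%s; cell skipped", analyte, tissue)
            continue
        rows.append(s.__dict__)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RelativeDistribution:
    """Per-animal tissue levels as percent of the same animal's muscle level."""

    analyte: str
    tissue: str
    animal_ids: tuple[str, ...]
    per_animal_percent: tuple[float, ...]
    mean_percent: float


def relative_to_muscle(
    dataset: CohortDataset, analyte: str
) -> dict[str, RelativeDistribution]:
    """Relative tissue distribution: 100 * value(tissue) / value(muscle),
    paired within animal, then averaged across animals.

    Aggregating per-animal ratios (mean of ratios, not ratio of means) keeps
    the values paired, which is what the paired sign-flip comparison between
    two analytes' relative distributions requires. Animals without a detected
    muscle value are dropped with a warning; censored tissue values are
    skipped for that tissue only.
    """
    df = dataset.measurements_frame()
    df = df[df["analyte"] == analyte]
    muscle = {
        r.animal_id: r.value
        for r in df[(df["tissue"] == "muscle") & (~df["censored"])].itertuples()
    }
    if not muscle:
        raise ValidationError(f"no animal with a detected muscle value for {analyte}")
    dropped = sorted(set(df["animal_id"]) - set(muscle))
    if dropped:
        logger.warning(
            "animals without detected muscle %s dropped from relative distribution: %s",
            analyte,
            ", ".join(dropped),
        )
    out: dict[str, RelativeDistribution] = {}
    for tissue, g in df.groupby("tissue", sort=True):
        ids, pct = [], []
        for r in g.itertuples():
            if r.censored or r.animal_id not in muscle:
                continue
            ids.append(r.animal_id)
            pct.append(100.0 * r.value / muscle[r.animal_id])
        if not pct:
            continue
        out[tissue] = RelativeDistribution(
            analyte=analyte,
            tissue=tissue,
            animal_ids=tuple(ids),
            per_animal_percent=tuple(pct),
            mean_percent=float(np.mean(pct)),
        )
    return out


def spearman_matrix(
    dataset: CohortDataset, analyte: str, tissues=None, min_pairs: int = 3
) -> pd.DataFrame:
    """Tie-aware Spearman rank correlation between tissues for one analyte.

    Pairwise-complete over animals with detected values in both tissues;
    entries with fewer than ``min_pairs`` complete pairs are NaN (missing,
    never 0). The matrix is symmetric with unit diagonal.
    """
    df = dataset.measurements_frame()
    df = df[(df["analyte"] == analyte) & (~df["censored"])]
    if tissues is None:
        tissues = sorted(df["tissue"].unique())
    wide = df.pivot_table(index="animal_id", columns="tissue", values="value")
    k = len(tissues)
    mat = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            if tissues[i] not in wide.columns or tissues[j] not in wide.columns:
                continue
            pair = wide[[tissues[i], tissues[j]]].dropna() if i != j else wide[[tissues[i]]].dropna()
            if i == j:
                if len(pair) >= min_pairs:
                    mat[i, j] = 1.0
                continue
            if len(pair) < min_pairs:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1]).statistic
            mat[i, j] = mat[j, i] = float(r)
    return pd.DataFrame(mat, index=list(tissues), columns=list(tissues))


def compute_bci(mass_kg, length_cm, reference_pairs) -> np.ndarray:
    """Body condition index: residual of mass from an OLS fit of mass on
    length over a reference population.

    ``reference_pairs`` is an (m, 2) array-like of (length_cm, mass_kg) with
    m >= 3 and nonzero length variance. Animals with a missing biometric get
    NaN. Mass is the response: condition is mass relative to that predicted
    for the animal's length.
    """
    ref = np.asarray(reference_pairs, dtype=float)
    if ref.ndim != 2 or ref.shape[1] != 2 or ref.shape[0] < 3:
        raise ValidationError("reference_pairs must be (m>=3, 2) of (length, mass)")
    if np.ptp(ref[:, 0]) == 0:
        raise ValidationError("reference lengths are constant; OLS fit is degenerate")
    slope, intercept = np.polyfit(ref[:, 0], ref[:, 1], 1)
    mass = np.asarray(mass_kg, dtype=float)
    length = np.asarray(length_cm, dtype=float)
    return mass - (intercept + slope * length)


def attach_bci(dataset: CohortDataset, reference_pairs) -> CohortDataset:
    """Return a dataset whose animals carry BCI derived from the reference fit."""
    from dataclasses import replace

    mass = np.array(
        [a.body_mass_kg if a.body_mass_kg is not None else np.nan for a in dataset.animals]
    )
    length = np.array(
        [a.body_length_cm if a.body_length_cm is not None else np.nan for a in dataset.animals]
    )
    bci = compute_bci(mass, length, reference_pairs)
    animals = [
        replace(a, bci=float(b) if np.isfinite(b) else None)
        for a, b in zip(dataset.animals, bci)
    ]
    return CohortDataset(animals, list(dataset.measurements), dict(dataset.tissue_moisture))
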