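"""qPCR standard-curve quantification and fold-enrichment accounting.

Host DNA in a fecal extract is quantified by amplifying a single-copy host
locus and reading the quantification cycle Ct off a standard curve fit to
a dilution series of known host DNA amounts::

    Ct = a + b * log10(quantity),   b < 0

Amplification efficiency is ``10^(-1/b) - 1`` (1.0 for perfect doubling,
i.e. slope -3.3219). Pre-enrichment host proportion is host concentration
(qPCR) over total DNA concentration (fluorometry); fold enrichment is the
post-enrichment mapped-read host proportion divided by that pre-enrichment
proportion. Samples whose host signal falls below the lowest standard (the
limit of quantification, LOQ) are flagged and excluded from cohort
summaries rather than guessed at.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class CurveError(ValueError):
    """Raised when a standard-curve fit is rejected."""


@dataclass(frozen=True)
class StandardCurve:
    """Fitted qPCR standard curve: Ct = intercept + slope * log10(quantity)."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    limit_of_quantification: float

    def ct_for(self, quantity: float) -> float:
        return self.intercept + self.slope * np.log10(quantity)


@dataclass
class EnrichmentRecord:
    """Per-sample pre/post host proportions and derived fold enrichment."""

    sample_id: str
    pre_host_prop: float | None
    post_host_prop: float
    fold: float | None
    below_loq: bool = False


def fit_standard_curve(standards: Iterable[tuple[float, float]]) -> StandardCurve:
    """Least-squares fit of Ct on log10(known quantity).

    Requires >= 3 distinct positive quantities. A non-negative slope means
    signal did not increase with template and the curve is rejected.
    The LOQ is the smallest standard quantity.
    """
    pts = [(float(q), float(ct)) for q, ct in standards]
    if any(q <= 0 for q, _ in pts):
        raise ValueError("standard quantities must be positive")
    distinct = {q for q, _ in pts}
    if len(distinct) < 3:
        raise ValueError("need at least 3 distinct standard quantities")
    x = np.log10([q for q, _ in pts])
    y = np.array([ct for _, ct in pts])
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise CurveError(
            f"standard curve rejected: slope {fit.slope:.4g} >= 0 "
            "(Ct must decrease with template quantity)"
        )
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        efficiency=float(efficiency),
        limit_of_quantification=min(distinct),
    )


def quantify(ct: float, curve: StandardCurve) -> float:
    """Invert the standard curve: quantity = 10^((Ct - a) / b)."""
    return float(10.0 ** ((ct - curve.intercept) / curve.slope))


def is_below_loq(quantity: float, curve: StandardCurve) -> bool:
    return quantity < curve.limit_of_quantification


def host_proportion(host_conc: float, total_conc: float) -> float:
    """Host over total DNA concentration, clamped into [0, 1].

    qPCR and fluorometric quantification have independent errors, so the
    ratio can exceed 1 for nearly-pure samples; it is clamped with a
    warning rather than rejected.
    """
    if total_conc <= 0:
        raise ValueError("total concentration must be positive")
    ratio = host_conc / total_conc
    if ratio > 1.0:
        warnings.warn(
            f"host/total ratio {ratio:.3f} > 1; clamping to 1.0 (measurement noise)"
        )
        return 1.0
    return max(0.0, ratio)


def fold_enrichment(
    sample_id: str,
    pre_host_prop: float | None,
    post_host_prop: float,
    below_loq: bool = False,
) -> EnrichmentRecord:
    """Fold = post / pre; undefined (and excluded) when pre is unquantifiable."""
    if not 0.0 <= post_host_prop <= 1.0:
        raise ValueError("post-enrichment proportion must lie in [0, 1]")
    if below_loq or pre_host_prop is None or pre_host_prop == 0.0:
        return EnrichmentRecord(sample_id, pre_host_prop, post_host_prop, None,
                                below_loq=True)
    return EnrichmentRecord(
        sample_id, pre_host_prop, post_host_prop, post_host_prop / pre_host_prop
    )


def summarize_folds(records: Sequence[EnrichmentRecord]) -> dict:
    """Cohort summary: mean of per-sample folds over quantifiable samples.

    The mean of per-sample folds (not the ratio of mean proportions) is the
    cohort statistic; unquantifiable samples are counted as excluded.
    """
    folds = [r.fold for r in records if r.fold is not None]
    return {
        "n_total": len(records),
        "n_excluded_below_loq": sum(1 for r in records if r.fold is None),
        "mean_fold": float(np.mean(folds)) if folds else float("nan"),
        "min_fold": float(np.min(folds)) if folds else float("nan"),
        "max_fold": float(np.max(folds)) if folds else float("nan"),
    }


DUPLICATE_SPREAD_CYCLES = 0.5


def process_qpcr_sheet(
    sheet: pd.DataFrame,
    post_props: dict[str, float] | None = None,
    duplicate_spread_threshold: float = DUPLICATE_SPREAD_CYCLES,
) -> tuple[StandardCurve, pd.DataFrame, list[EnrichmentRecord]]:
    """Process a plate sheet: fit standards, quantify unknowns, compute folds.

    ``sheet`` columns: well, sample, role (standard/unknown/NTC),
    known_quantity, Ct, total_conc. Replicate wells of one unknown are
    averaged; a Ct spread above ``duplicate_spread_threshold`` cycles flags
    the sample as unreliable (it is still quantified). ``post_props`` maps
    sample id to post-enrichment mapped host proportion; samples without an
    entry get no fold.
    """
    required = {"sample", "role", "known_quantity", "Ct", "total_conc"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"qPCR sheet missing columns: {sorted(missing)}")
    std = sheet[sheet["role"] == "standard"]
    curve = fit_standard_curve(zip(std["known_quantity"], std["Ct"]))

    rows = []
    records = []
    for sample, grp in sheet[sheet["role"] == "unknown"].groupby("sample", sort=True):
        cts = grp["Ct"].astype(float)
        spread = float(cts.max() - cts.min())
        flagged = spread > duplicate_spread_threshold
        ct_mean = float(cts.mean())
        qty = quantify(ct_mean, curve)
        below = is_below_loq(qty, curve)
        total = float(grp["total_conc"].iloc[0])
        prop = None if below else host_proportion(qty, total)
        rows.append(
            {
                "sample": sample, "ct_mean": ct_mean, "ct_spread": spread,
                "unreliable_duplicates": flagged, "host_quantity": qty,
                "below_loq": below, "total_conc": total,
                "pre_host_prop": np.nan if prop is None else prop,
            }
        )
        if post_props is not None and sample in post_props:
            records.append(
                fold_enrichment(str(sample), prop, post_props[sample], below_loq=below)
            )
    return curve, pd.DataFrame(rows), records
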