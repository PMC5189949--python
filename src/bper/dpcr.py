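"""Droplet digital PCR: limit of blank, positivity, Poisson-corrected mutant fraction.

Each assay (one mutation-specific probe pair) gets its own limit of blank
(LOB) from wild-type-only runs: mutant-droplet counts are normalized per 1e6
droplets and the LOB is mean + 1.645 SD (parametric, CLSI EP17 style) or the
nonparametric 95th percentile when >= 20 blanks are available.  A sample is
positive only when its normalized mutant count strictly exceeds the LOB.

Mutant fractions use Poisson occupancy correction: with a fraction f of
positive droplets, the mean copies per droplet is lambda = -ln(1 - f), and
MAF = lambda_mut / (lambda_mut + lambda_wt).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import CalibrationError, ConsistencyError, SaturationError

PER_DROPLETS = 1e6  # normalization basis for blank counts and LOB
Z_95 = 1.645  # one-sided 95% normal quantile (parametric LOB)
NONPARAMETRIC_MIN_BLANKS = 20


@dataclass(frozen=True)
class DropletAssayResult:
    """Droplet counts of one dPCR assay on one sample.

    Double-positive droplets are assumed merged into ``n_mut`` upstream, so
    ``n_mut + n_wt <= n_total``.
    """

    assay_id: str
    sample_id: str
    n_total: int
    n_mut: int
    n_wt: int
    input_volume_ul: float = 5.0

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if min(self.n_mut, self.n_wt) < 0 or self.n_mut + self.n_wt > self.n_total:
            raise ValueError("droplet counts must be >= 0 with n_mut + n_wt <= n_total")

    @property
    def mut_per_million(self) -> float:
        return self.n_mut / self.n_total * PER_DROPLETS


@dataclass(frozen=True)
class AssayLOB:
    """Per-assay limit of blank, in mutant droplets per 1e6 droplets."""

    assay_id: str
    blanks: tuple[float, ...]  # normalized blank counts, per 1e6 droplets
    lob: float

    def __post_init__(self) -> None:
        if self.lob < 0:
            raise ValueError("lob must be >= 0")


def compute_lob(blank_runs: list[DropletAssayResult]) -> AssayLOB:
    """Estimate the limit of blank of an assay from wild-type-only runs.

    Requires >= 3 blanks.  Parametric (mean + 1.645 SD) below 20 blanks,
    nonparametric 95th percentile at 20 or more.
    """
    if len(blank_runs) < 3:
        raise CalibrationError(f"need >= 3 blank runs, got {len(blank_runs)}")
    assay_ids = {b.assay_id for b in blank_runs}
    if len(assay_ids) != 1:
        raise ConsistencyError(f"blank runs span multiple assays: {sorted(assay_ids)}")
    norm = np.array([b.mut_per_million for b in blank_runs], dtype=float)
    if len(norm) >= NONPARAMETRIC_MIN_BLANKS:
        lob = float(np.percentile(norm, 95))
    else:
        lob = float(norm.mean() + Z_95 * norm.std(ddof=1))
    return AssayLOB(assay_ids.pop(), tuple(norm), max(lob, 0.0))


def assay_positive(assay: DropletAssayResult, lob: AssayLOB) -> bool:
    """Mutant detected iff the normalized mutant count strictly exceeds the LOB."""
    if assay.assay_id != lob.assay_id:
        raise ConsistencyError(f"assay {assay.assay_id!r} vs LOB for {lob.assay_id!r}")
    return assay.mut_per_million > lob.lob


def poisson_lambda(positives: int, total: int) -> float:
    """Mean target copies per droplet from the positive-droplet fraction."""
    if total <= 0 or positives < 0 or positives > total:
        raise ValueError(f"invalid droplet counts {positives}/{total}")
    if positives == total:
        raise SaturationError(
            "all droplets positive: occupancy is saturated, dilute the sample"
        )
    return -math.log1p(-positives / total)


def mutant_fraction(assay: DropletAssayResult, lob: AssayLOB, raw_ratio: bool = False) -> float:
    """Poisson-corrected mutant allele fraction; 0.0 for assays below the LOB.

    With ``raw_ratio`` the uncorrected droplet ratio n_mut / (n_mut + n_wt)
    is returned instead (adequate at low occupancy).
    """
    if not assay_positive(assay, lob):
        return 0.0
    if raw_ratio:
        return assay.n_mut / (assay.n_mut + assay.n_wt)
    lam_mut = poisson_lambda(assay.n_mut, assay.n_total)
    lam_wt = poisson_lambda(assay.n_wt, assay.n_total)
    denom = lam_mut + lam_wt
    return lam_mut / denom if denom > 0 else 0.0
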