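"""Longitudinal cohort layer: combined positivity, trajectories, turnover, rates.

Samples are drawn at baseline (T0, before treatment), first evaluation
(E1, 6 +/- 2 weeks) and time of radiological progression (ToP).  A time point
is ctDNA-positive when either modality detects a mutation (NGS screening /
marker tracking, or any dPCR assay above its limit of blank).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .exceptions import UndefinedRateError

POSITIVE = "positive"
NEGATIVE = "negative"
NOT_CONTRIBUTIVE = "not_contributive"

TRAJECTORY_LABELS = ("increase", "decrease", "normalized", "negative", "na")


@dataclass
class TimepointSample:
    """Everything known about one patient at one sampling time point.

    ``ngs_positive`` / ``dpcr_positive`` are None when the modality was not
    run; ``mutations`` holds variant-id strings of passing calls.
    """

    date: _dt.date | None = None
    ngs_positive: bool | None = None
    dpcr_positive: bool | None = None
    conc_ng_per_ml: float | None = None
    mutations: frozenset[str] = frozenset()

    @property
    def status(self) -> str:
        return combined_status(self.ngs_positive, self.dpcr_positive)


@dataclass
class PatientTimeline:
    patient_id: str
    tumor_mutations: frozenset[str] = frozenset()
    samples: dict[str, TimepointSample] = field(default_factory=dict)
    treatment_start_date: _dt.date | None = None
    progression_date: _dt.date | None = None
    death_or_censor_date: _dt.date | None = None

    @property
    def marker_mutations(self) -> frozenset[str]:
        """Trackable markers: tumor-tissue mutations union baseline-plasma mutations."""
        t0 = self.samples.get("T0")
        return self.tumor_mutations | (t0.mutations if t0 else frozenset())


def combined_status(ngs, dpcr) -> str:
    """Combined positivity: positive if detected by NGS or by dPCR.

    ``ngs`` may be a bool, None, or any object with a ``positive`` attribute
    (e.g. a :class:`~bper.caller.SampleCallResult`); ``dpcr`` may be a bool,
    None, or an iterable of per-assay positivity booleans.
    """
    if ngs is not None and hasattr(ngs, "positive"):
        ngs = bool(ngs.positive)
    if dpcr is not None and not isinstance(dpcr, bool):
        items = list(dpcr)
        dpcr = any(bool(x) for x in items) if items else None
    if ngs is None and dpcr is None:
        return NOT_CONTRIBUTIVE
    return POSITIVE if bool(ngs) or bool(dpcr) else NEGATIVE


@dataclass(frozen=True)
class TrajectoryClass:
    label: str
    reason: str = ""

    def __post_init__(self):
        if self.label not in TRAJECTORY_LABELS:
            raise ValueError(f"unknown trajectory label {self.label!r}")


def classify_trajectory(
    t0_status: str, t0_conc: float | None, e1_status: str, e1_conc: float | None
) -> TrajectoryClass:
    """Classify the T0 -> E1 ctDNA trajectory.

    increase / decrease for E1-positive patients (ties count as increase,
    conservatively), normalized for T0-positive patients turning negative,
    negative when both time points are negative.
    """
    if t0_status == NOT_CONTRIBUTIVE or e1_status == NOT_CONTRIBUTIVE:
        return TrajectoryClass("na", "missing or non-contributive time point")
    c0 = t0_conc or 0.0
    c1 = e1_conc or 0.0
    if e1_status == POSITIVE:
        return TrajectoryClass("increase" if c1 >= c0 else "decrease")
    if t0_status == POSITIVE:
        return TrajectoryClass("normalized")
    return TrajectoryClass("negative")


@dataclass(frozen=True)
class DetectionRate:
    k: int
    n: int
    percent: float  # 100*k/n, one decimal, half-up
    ci_low: float
    ci_high: float


def detection_rate_from_counts(k: int, n: int) -> DetectionRate:
    """Positivity rate with a Wilson-score 95% CI; percent rounded half-up to 1 dp."""
    if n <= 0:
        raise UndefinedRateError("detection rate undefined for n = 0")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    percent = float(Decimal(100 * k / n).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return DetectionRate(k, n, percent, float(lo), float(hi))


def detection_rate(cohort: list[PatientTimeline], time_point: str) -> DetectionRate:
    """Cohort positivity rate at a time point; only contributive samples enter n."""
    k = n = 0
    for tl in cohort:
        s = tl.samples.get(time_point)
        if s is None or s.status == NOT_CONTRIBUTIVE:
            continue
        n += 1
        k += s.status == POSITIVE
    return detection_rate_from_counts(k, n)


@dataclass(frozen=True)
class TurnoverResult:
    acquired: frozenset[str]
    lost: frozenset[str]
    persistent: frozenset[str]
    na: bool = False


def mutation_turnover(timeline: PatientTimeline) -> TurnoverResult:
    """Mutations acquired / lost / persistent at progression (ToP) vs markers."""
    top = timeline.samples.get("ToP")
    if top is None:
        return TurnoverResult(frozenset(), frozenset(), frozenset(), na=True)
    markers = timeline.marker_mutations
    return TurnoverResult(
        acquired=top.mutations - markers,
        lost=markers - top.mutations,
        persistent=markers & top.mutations,
    )


@dataclass(frozen=True)
class ProgressionTime:
    days: int
    event: bool
    rule: str


def time_to_ctdna_progression(
    timeline: PatientTimeline, rule: str = "nadir_exceeded"
) -> ProgressionTime:
    """Days from treatment start to biological (ctDNA) progression, or censoring.

    Rules (the operational definition is configurable):

    * ``nadir_exceeded`` (default): first sample at/after E1 that is positive
      with a concentration above the running nadir of all earlier samples;
    * ``reappearance``: first positive sample after any negative one;
    * ``increase``: first positive sample with a concentration above the
      immediately preceding sample's.
    """
    if rule not in ("nadir_exceeded", "reappearance", "increase"):
        raise ValueError(f"unknown progression rule {rule!r}")
    start = timeline.treatment_start_date
    if start is None:
        raise ValueError(f"patient {timeline.patient_id}: no treatment start date")
    ordered = [tp for tp in ("T0", "E1", "ToP") if tp in timeline.samples]
    undated = [tp for tp in ordered if timeline.samples[tp].date is None]
    if undated:
        raise ValueError(f"patient {timeline.patient_id}: undated samples at {undated}")
    samples = sorted((timeline.samples[tp] for tp in ordered), key=lambda s: s.date)

    nadir = float("inf")
    seen_negative = False
    prev_conc = None
    last_date = start
    for j, s in enumerate(samples):
        last_date = s.date
        conc = s.conc_ng_per_ml or 0.0
        is_t0 = j == 0
        if not is_t0 and s.status == POSITIVE:
            hit = (
                (rule == "nadir_exceeded" and conc > min(nadir, float("inf")))
                or (rule == "reappearance" and seen_negative)
                or (rule == "increase" and prev_conc is not None and conc > prev_conc)
            )
            if hit:
                return ProgressionTime((s.date - start).days, True, rule)
        nadir = min(nadir, conc)
        seen_negative = seen_negative or s.status == NEGATIVE
        prev_conc = conc
    return ProgressionTime((last_date - start).days, False, rule)


def cohort_table(cohort: list[PatientTimeline]):
    """Analysis-ready per-patient table (one row per patient-time point)."""
    import pandas as pd

    rows = []
    for tl in cohort:
        t0 = tl.samples.get("T0")
        e1 = tl.samples.get("E1")
        traj = (
            classify_trajectory(
                t0.status, t0.conc_ng_per_ml, e1.status, e1.conc_ng_per_ml
            ).label
            if t0 and e1
            else "na"
        )
        for tp, s in sorted(tl.samples.items()):
            rows.append(
                {
                    "patient_id": tl.patient_id,
                    "time_point": tp,
                    "date": s.date,
                    "status": s.status,
                    "conc_ng_per_ml": s.conc_ng_per_ml,
                    "n_mutations": len(s.mutations),
                    "trajectory_t0_e1": traj,
                }
            )
    return pd.DataFrame(rows)
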