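"""Synthetic data generators for every input the pipeline consumes.

Count-level simulation of ultra-deep amplicon sequencing (controls and plasma
samples with spiked variants), droplet digital PCR runs, dated longitudinal
cohorts, and a minimal planted-read SAM writer for alignment-extraction
tests.  All generators are deterministic under a fixed seed.

Study-condition defaults: 1,000 panel positions sequenced at ~10,000x,
per-position substitution error rates log-uniform in [1e-5, 1e-3] and indel
error rates log-uniform in [1e-6, 1e-4], 20 control samples, baseline cohort
positivity 71.4% with a baseline concentration distribution whose median
(0.12 ng/mL) and tertile cut-offs (0.027 / 0.50 ng/mL) match the clinical
series this package models.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass

import numpy as np

from .dpcr import DropletAssayResult, PER_DROPLETS
from .monitor import PatientTimeline, TimepointSample
from .panel import Alteration, PanelPosition, PileupMatrix

BASES = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; the defaults ARE the study conditions."""

    seed: int
    n_positions: int = 1000
    depth_mean: float = 10_000.0
    sub_rate_bounds: tuple[float, float] = (1e-5, 1e-3)
    indel_rate_bounds: tuple[float, float] = (1e-6, 1e-4)
    indel_span: int = 3
    n_controls: int = 20
    depth_overdispersion: float | None = None  # negative-binomial shape, None = Poisson


@dataclass(frozen=True)
class ErrorProfile:
    """Ground-truth per-position error rates of a simulated panel."""

    panel: tuple[PanelPosition, ...]
    sub_key: tuple[str, ...]  # the one error-prone substitution per position
    sub_rate: np.ndarray
    indel_key: tuple[str, ...]
    indel_rate: np.ndarray


def make_panel(n_positions: int, seed: int | np.random.Generator = 0, contig: str = "panel1") -> list[PanelPosition]:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    refs = rng.choice(list(BASES), size=n_positions)
    return [PanelPosition(contig, i + 1, str(refs[i]), gene="SIM") for i in range(n_positions)]


def _loguniform(rng, lo, hi, size):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def draw_error_profile(panel, rng: np.random.Generator, config: SimulationConfig) -> ErrorProfile:
    """One error-prone substitution (random non-reference base) and one
    ``del:<span>`` error channel per position, rates drawn log-uniformly."""
    n = len(panel)
    sub_keys = []
    for p in panel:
        alts = [b for b in BASES if b != p.ref_base]
        sub_keys.append(f"sub:{str(rng.choice(alts))}")
    return ErrorProfile(
        panel=tuple(panel),
        sub_key=tuple(sub_keys),
        sub_rate=_loguniform(rng, *config.sub_rate_bounds, n),
        indel_key=tuple(f"del:{config.indel_span}" for _ in panel),
        indel_rate=_loguniform(rng, *config.indel_rate_bounds, n),
    )


def _draw_depth(rng, config: SimulationConfig, n: int) -> np.ndarray:
    if config.depth_overdispersion is None:
        return rng.poisson(config.depth_mean, size=n)
    shape = config.depth_overdispersion
    lam = rng.gamma(shape, config.depth_mean / shape, size=n)
    return rng.poisson(lam)


def simulate_control(
    profile: ErrorProfile, config: SimulationConfig, rng: np.random.Generator, sample_id: str = "control"
) -> PileupMatrix:
    """Mutation-free control sample: background errors only."""
    n = len(profile.panel)
    depth = _draw_depth(rng, config, n)
    sub_counts = rng.binomial(depth, profile.sub_rate)
    indel_counts = rng.binomial(depth, profile.indel_rate)
    counts: list[dict[str, int]] = []
    for i in range(n):
        d: dict[str, int] = {}
        if sub_counts[i] > 0:
            d[profile.sub_key[i]] = int(sub_counts[i])
        if indel_counts[i] > 0:
            d[profile.indel_key[i]] = int(indel_counts[i])
        counts.append(d)
    return PileupMatrix(sample_id, list(profile.panel), depth, counts)


def simulate_plasma(
    profile: ErrorProfile,
    config: SimulationConfig,
    rng: np.random.Generator,
    spikes: list[tuple[int, Alteration, float]] = (),
    sample_id: str = "plasma",
    masked_positions=(),
) -> PileupMatrix:
    """Plasma sample: background errors plus variants spiked at true allele
    fractions (binomial mutant reads on top of background, capped at depth).

    ``spikes`` entries are (position index, alteration, true AF).
    """
    mat = simulate_control(profile, config, rng, sample_id)
    masked = set(masked_positions)
    for i, alt, af in spikes:
        if not 0.0 <= af <= 1.0:
            raise ValueError(f"spike AF must be in [0, 1], got {af}")
        if i in masked:
            warnings.warn(f"spiking at masked position index {i}")
        extra = int(rng.binomial(mat.depth[i], af))
        key = alt.key
        total = min(mat.counts[i].get(key, 0) + extra, int(mat.depth[i]))
        if total > 0:
            mat.counts[i][key] = total
    return mat


# ---------------------------------------------------------------------------
# droplet digital PCR
# ---------------------------------------------------------------------------

def simulate_droplets(
    rng: np.random.Generator,
    n_droplets: int = 1_000_000,
    copies_in_reaction: float = 300_000.0,
    maf: float = 0.0,
    assay_id: str = "assay",
    sample_id: str = "sample",
    input_volume_ul: float = 5.0,
) -> DropletAssayResult:
    """One dPCR run: molecules ~ Poisson, dispersed independently over droplets.

    A droplet containing any mutant copy reads mutant (double positives merged
    upstream); wild-type-only droplets read wild type.
    """
    lam_mut = copies_in_reaction * maf / n_droplets
    lam_wt = copies_in_reaction * (1.0 - maf) / n_droplets
    p_mut = -np.expm1(-lam_mut)
    p_wt_only = np.exp(-lam_mut) * -np.expm1(-lam_wt)
    n_mut, n_wt, _ = rng.multinomial(n_droplets, [p_mut, p_wt_only, 1.0 - p_mut - p_wt_only])
    return DropletAssayResult(assay_id, sample_id, n_droplets, int(n_mut), int(n_wt), input_volume_ul)


def simulate_blanks(
    rng: np.random.Generator,
    n_blanks: int = 3,
    n_droplets: int = 1_000_000,
    blank_rate_per_million: float = 2.0,
    wt_copies: float = 100_000.0,
    assay_id: str = "assay",
) -> list[DropletAssayResult]:
    """Wild-type-only runs with rare false-positive mutant droplets."""
    out = []
    p_fp = blank_rate_per_million / PER_DROPLETS
    for b in range(n_blanks):
        n_mut = int(rng.binomial(n_droplets, p_fp))
        lam_wt = wt_copies / n_droplets
        n_wt = int(rng.binomial(n_droplets - n_mut, -np.expm1(-lam_wt)))
        out.append(DropletAssayResult(assay_id, f"blank{b}", n_droplets, n_mut, n_wt))
    return out


# ---------------------------------------------------------------------------
# longitudinal cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Treatment-response dynamics of a synthetic monitoring cohort."""

    n_patients: int = 60
    baseline_positive: float = 0.714
    conc_median: float = 0.12  # ng/mL at baseline among positives
    conc_log_sd: float = 3.4  # matches tertile cut-offs 0.027 / 0.50 around 0.12
    detection_limit: float = 0.01  # ng/mL below which a sample reads negative
    responder_fraction: float = 0.65
    decay_rate: float = 0.12  # per day, exponential clearance under response
    growth_rate: float = 0.015  # per day, regrowth under progression
    e1_day: int = 42
    top_day_median: int = 139
    top_day_log_sd: float = 0.45
    acquired_mutation_fraction: float = 0.25
    start_date: _dt.date = _dt.date(2020, 1, 1)


def simulate_cohort(
    config: CohortConfig, rng: np.random.Generator, out_dir=None
) -> list[PatientTimeline]:
    """Dated T0/E1/ToP timelines with exponential decay under response,
    regrowth at resistance, and acquired mutations injected at progression.

    Returns in-memory timelines; with ``out_dir`` also writes the cohort
    analysis table as ``cohort.csv``.
    """
    timelines = []
    for j in range(config.n_patients):
        pid = f"P{j:04d}"
        marker = f"panel1:{int(rng.integers(1, 1001))}:sub:{str(rng.choice(list(BASES)))}"
        positive_t0 = rng.random() < config.baseline_positive
        if positive_t0:
            # lognormal truncated above the detection limit, so that
            # baseline_positive IS the detected T0 positivity rate
            from scipy import stats as _st

            f_lo = _st.norm.cdf(
                (np.log(config.detection_limit) - np.log(config.conc_median)) / config.conc_log_sd
            )
            u = rng.uniform(f_lo, 1.0)
            c0 = float(np.exp(np.log(config.conc_median) + config.conc_log_sd * _st.norm.ppf(u)))
        else:
            c0 = 0.0
        responder = rng.random() < config.responder_fraction
        if responder:
            c1 = c0 * np.exp(-config.decay_rate * config.e1_day)
        else:
            c1 = max(c0, config.detection_limit) * np.exp(config.growth_rate * config.e1_day)
        top_day = max(
            config.e1_day + 7,
            int(round(rng.lognormal(np.log(config.top_day_median), config.top_day_log_sd))),
        )
        c2 = max(c0, c1, config.detection_limit) * np.exp(config.growth_rate * (top_day - config.e1_day))

        def _tp(day, conc, muts):
            detected = conc > config.detection_limit
            return TimepointSample(
                date=config.start_date + _dt.timedelta(days=day),
                ngs_positive=detected,
                dpcr_positive=None,
                conc_ng_per_ml=conc if detected else 0.0,
                mutations=frozenset(muts) if detected else frozenset(),
            )

        top_muts = {marker}
        if rng.random() < config.acquired_mutation_fraction:
            top_muts.add(f"panel1:{int(rng.integers(1, 1001))}:sub:{str(rng.choice(list(BASES)))}")
        timelines.append(
            PatientTimeline(
                patient_id=pid,
                tumor_mutations=frozenset({marker}),
                samples={
                    "T0": _tp(0, c0, {marker}),
                    "E1": _tp(config.e1_day, c1, {marker}),
                    "ToP": _tp(top_day, c2, top_muts),
                },
                treatment_start_date=config.start_date,
            )
        )
    if out_dir is not None:
        from pathlib import Path

        from .monitor import cohort_table

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cohort_table(timelines).to_csv(out / "cohort.csv", index=False)
    return timelines


# ---------------------------------------------------------------------------
# planted-read SAM writer (for alignment-extraction tests)
# ---------------------------------------------------------------------------

def write_planted_sam(
    path,
    contig: str = "panel1",
    ref_length: int = 400,
    ref_seq: str | None = None,
    n_reads: int = 100,
    read_length: int = 100,
    read_start: int = 51,
    deletion: tuple[int, int, int] | None = None,
    substitution: tuple[int, str, int] | None = None,
    seed: int = 0,
) -> str:
    """Write a coordinate-sorted SAM with reads planted over one region.

    ``deletion`` = (first deleted 1-based pos, length, carrier reads);
    ``substitution`` = (1-based pos, alt base, carrier reads).  Returns the
    reference sequence used, so callers can build a matching panel.
    """
    import pysam

    rng = np.random.default_rng(seed)
    if ref_seq is None:
        ref_seq = "".join(str(b) for b in rng.choice(list(BASES), size=ref_length))
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": contig, "LN": len(ref_seq)}],
    }
    start0 = read_start - 1
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in range(n_reads):
            a = pysam.AlignedSegment()
            a.query_name = f"read{r:05d}"
            a.reference_id = 0
            a.reference_start = start0
            a.mapping_quality = 60
            seq = list(ref_seq[start0 : start0 + read_length])
            if substitution is not None and r < substitution[2]:
                pos, base, _ = substitution
                seq[pos - read_start] = base
            if deletion is not None and r < deletion[2]:
                dpos, dlen, _ = deletion
                off = dpos - read_start
                del seq[off : off + dlen]
                a.cigarstring = f"{off}M{dlen}D{len(seq) - off}M"
            else:
                a.cigarstring = f"{len(seq)}M"
            a.query_sequence = "".join(seq)
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            a.flag = 0
            out.write(a)
    return ref_seq
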