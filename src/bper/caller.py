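"""Variant calling against the background error model.

Two modes share one decision rule and differ only in the multiple-testing
burden M:

* whole-panel screening (:func:`call_sample`): every testable (position,
  alteration) hypothesis on the panel is counted in M;
* marker tracking (:func:`track_markers`): only the patient's known marker
  mutations are tested (M = number of markers), which is what makes
  follow-up samples far more sensitive than a de novo screen.

Decision rule — a candidate with ``alt_reads`` supporting reads at depth
``d`` (af = alt_reads / d) passes iff all of:

1. ``alt_reads >= min_alt_reads``            (single-molecule artifact guard);
2. ``af > mu + k sigma``                     (position-specific noise bound);
3. ``upper95(af) > tau``                     (detection-floor check): the
   one-sided 95% Clopper-Pearson upper bound of the measured fraction must
   exceed tau = max(mu + k sigma, floor).  Comparing the upper bound rather
   than the point estimate makes a variant truly present at the assay's
   validated floor (0.003 SNV / 0.001 long indel) detectable with high
   probability instead of ~50%;
4. ``p_binom * M <= alpha``                  (Bonferroni-adjusted binomial
   tail P[X >= alt_reads | Binomial(d, mu)]).

Short indels (<= 2 bp) are outside the validated scope of the assay and are
refused by default (config override available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import ConsistencyError
from .panel import Alteration, PanelPosition, PileupMatrix, variant_id

SUBSTITUTION_ALTS = {
    "A": ("C", "G", "T"),
    "C": ("A", "G", "T"),
    "G": ("A", "C", "T"),
    "T": ("A", "C", "G"),
    "N": ("A", "C", "G", "T"),
}


@dataclass(frozen=True)
class CallerConfig:
    min_depth: int = 1000
    min_alt_reads: int = 5
    alpha: float = 0.05
    multiplicity: str = "bonferroni"  # bonferroni | none
    sigma_min: float = 1e-6
    allow_short_indels: bool = False
    floor_confidence: float = 0.95  # one-sided level of the AF upper bound vs the floor


@dataclass(frozen=True)
class VariantCall:
    position: PanelPosition
    alteration: Alteration
    depth: int
    alt_reads: int
    af: float
    mu: float
    sigma: float
    tau: float
    z: float
    p_binom: float
    passed: bool
    filter_reason: str = ""

    @property
    def id(self) -> str:
        return variant_id(self.position, self.alteration)


@dataclass
class SampleCallResult:
    """Outcome of calling one plasma sample (screening or marker tracking)."""

    sample_id: str
    calls: list[VariantCall]
    mode: str  # "panel" | "markers"
    n_tested: int  # multiple-testing burden M
    warnings: list[str] = field(default_factory=list)

    @property
    def passing(self) -> list[VariantCall]:
        return [c for c in self.calls if c.passed]

    @property
    def n_mutations(self) -> int:
        return len(self.passing)

    @property
    def positive(self) -> bool:
        return self.n_mutations >= 1

    def detected_markers(self) -> list[str]:
        return [c.id for c in self.passing]

    def marker_af(self, position: PanelPosition, alteration: Alteration) -> float:
        vid = variant_id(position, alteration)
        for c in self.calls:
            if c.id == vid:
                return c.af
        return 0.0


def classify_alteration(alteration: Alteration) -> str:
    """snv / short_indel (<= 2 bp) / long_indel (> 2 bp)."""
    return alteration.classify()


def ngs_maf(result: SampleCallResult) -> float:
    """Mutant allele fraction used for quantification: highest passing AF, else 0."""
    return max((c.af for c in result.passing), default=0.0)


def af_upper_bound(alt_reads: int, depth: int, confidence: float = 0.95) -> float:
    """One-sided Clopper-Pearson upper bound on the allele fraction."""
    if depth <= 0:
        return 0.0
    if alt_reads >= depth:
        return 1.0
    return float(stats.beta.ppf(confidence, alt_reads + 1, depth - alt_reads))


def _evaluate(pileup, model, i, alteration, cfg, m_tests) -> VariantCall:
    p = model.panel[i]
    depth = int(pileup.depth[i])
    alt_reads = pileup.count(i, alteration)
    af = alt_reads / depth if depth > 0 else 0.0
    st = model.noise(i, alteration)
    k = model.config.k_for(p)
    noise_bound = st.mu + k * st.sigma
    tau = max(noise_bound, model.config.floor_for(alteration))
    z = (af - st.mu) / max(st.sigma, cfg.sigma_min)
    p_binom = float(stats.binom.sf(alt_reads - 1, depth, min(st.mu, 1.0))) if alt_reads > 0 else 1.0

    reason = ""
    if alteration.classify() == "short_indel" and not cfg.allow_short_indels:
        reason = "short_indel_not_supported"
    elif depth < cfg.min_depth:
        reason = "low_depth"
    elif alt_reads < cfg.min_alt_reads:
        reason = "min_alt_reads"
    elif af <= noise_bound:
        reason = "below_threshold"
    elif af_upper_bound(alt_reads, depth, cfg.floor_confidence) <= tau:
        reason = "below_threshold"
    else:
        p_adj = p_binom * m_tests if cfg.multiplicity == "bonferroni" else p_binom
        if p_adj > cfg.alpha:
            reason = "not_significant"

    return VariantCall(
        position=p,
        alteration=alteration,
        depth=depth,
        alt_reads=alt_reads,
        af=af,
        mu=st.mu,
        sigma=st.sigma,
        tau=tau,
        z=z,
        p_binom=p_binom,
        passed=reason == "",
        filter_reason=reason,
    )


def _check_same_panel(pileup: PileupMatrix, model) -> None:
    if [(p.contig, p.pos) for p in pileup.positions] != [(p.contig, p.pos) for p in model.panel]:
        raise ConsistencyError("pileup and background model are on different panels")


def _testable(pileup, model, cfg) -> np.ndarray:
    return (np.asarray(pileup.depth) >= cfg.min_depth) & ~model.masked


def call_sample(pileup: PileupMatrix, model, config: CallerConfig | None = None) -> SampleCallResult:
    """Whole-panel screening of one plasma sample against the background model.

    Every candidate with at least one supporting read at a testable position
    is retained in the result with its pass/fail status; M counts all tested
    hypotheses (3 substitutions per testable position plus indel keys known
    to the model or carrying reads in this sample).
    """
    cfg = config or CallerConfig()
    _check_same_panel(pileup, model)
    testable = _testable(pileup, model, cfg)
    warnings_: list[str] = []
    if not testable.any():
        warnings_.append("no testable positions (all masked or below min_depth)")

    def _is_del_continuation(i: int, key: str) -> bool:
        # deletions are counted at every deleted base but called once per
        # event, anchored at the first deleted base of a contiguous run
        if not key.startswith("del:") or i == 0:
            return False
        prev, cur = model.panel[i - 1], model.panel[i]
        return prev.contig == cur.contig and prev.pos == cur.pos - 1 and pileup.counts[i - 1].get(key, 0) > 0

    # multiple-testing burden: every hypothesis that could be rejected
    m_tests = 0
    candidates: list[tuple[int, Alteration]] = []
    for i in np.flatnonzero(testable):
        p = model.panel[i]
        keys = {f"sub:{b}" for b in SUBSTITUTION_ALTS[p.ref_base]}
        keys.update(k for k in model.observed_keys(i) if not k.startswith("sub:"))
        keys.update(k for k, v in pileup.counts[i].items() if v > 0 and not k.startswith("sub:"))
        tested_keys = {
            k for k in keys
            if (cfg.allow_short_indels or Alteration.from_key(k).classify() != "short_indel")
            and not _is_del_continuation(int(i), k)
        }
        m_tests += len(tested_keys)
        for k, v in pileup.counts[i].items():
            if v > 0 and not _is_del_continuation(int(i), k):
                candidates.append((int(i), Alteration.from_key(k)))

    m_tests = max(m_tests, 1)
    calls = [_evaluate(pileup, model, i, a, cfg, m_tests) for i, a in candidates]
    calls.sort(key=lambda c: (c.position.contig, c.position.pos, c.alteration.key))
    return SampleCallResult(pileup.sample_id, calls, "panel", m_tests, warnings_)


def track_markers(
    pileup: PileupMatrix,
    model,
    markers: list[tuple[PanelPosition, Alteration]],
    config: CallerConfig | None = None,
) -> SampleCallResult:
    """Marker-restricted calling at follow-up: M = number of marker pairs.

    Every marker is reported, including undetected ones (af = 0, failed).
    """
    cfg = config or CallerConfig()
    _check_same_panel(pileup, model)
    offenders = [
        (p.contig, p.pos) for p, _ in markers if (p.contig, p.pos) not in model._index
    ]
    if offenders:
        raise ConsistencyError(f"markers not on panel: {offenders}")

    m_tests = max(len(markers), 1)
    calls = []
    warnings_: list[str] = []
    for p, a in markers:
        i = model.index_of(p)
        if model.masked[i]:
            warnings_.append(f"marker at masked position {p.contig}:{p.pos} not testable")
            continue
        calls.append(_evaluate(pileup, model, i, a, cfg, m_tests))
    return SampleCallResult(pileup.sample_id, calls, "markers", m_tests, warnings_)
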