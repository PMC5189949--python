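"""Absolute ctDNA quantification per mL plasma, genome equivalents, LOD, tertiles.

Total cell-free DNA copies in the dPCR reaction are recovered from droplet
counts by Poisson correction, scaled from the loaded aliquot to the full
extract (default 50 uL) and normalized to 1 mL plasma (default draw 2 mL).
Mass uses m_g = 3.3 pg per haploid genome, so that

    ctDNA (ng/mL) = copies/mL * MAF * 0.0033 ng.

Concentration categories use the fixed cohort tertile cut-offs 0.027 and
0.50 ng/mL; ``tertile_cutoffs`` re-estimates them for a new cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dpcr import DropletAssayResult, poisson_lambda
from .exceptions import UndefinedRateError
from .panel import SampleMeta

#: mass of one haploid human genome in ng (3.3 pg)
HAPLOID_GENOME_NG = 3.3e-3

#: fixed concentration tertile cut-offs, ng ctDNA per mL plasma
CUT_LOW = 0.027
CUT_HIGH = 0.50


@dataclass(frozen=True)
class Quantification:
    sample_id: str
    total_cfdna_copies_per_ml: float
    maf: float
    ctdna_ng_per_ml: float
    genome_equivalents: int  # countable haploid genomes loaded in the reaction
    source: str  # "dpcr" | "ngs"


@dataclass(frozen=True)
class ConcentrationCategory:
    label: str  # low | intermediate | high
    cut_low: float = CUT_LOW
    cut_high: float = CUT_HIGH


def ctdna_concentration(
    assay: DropletAssayResult,
    maf: float,
    meta: SampleMeta,
    source: str = "dpcr",
    wt_only: bool = False,
) -> Quantification:
    """Absolute ctDNA concentration from droplet counts, a MAF and sample metadata.

    ``maf`` may come from the same dPCR assay (:func:`bper.dpcr.mutant_fraction`)
    or from an NGS marker allele fraction.  ``wt_only`` restricts the total
    cfDNA estimate to wild-type droplets (literal workflow); the default uses
    wild-type + mutant droplets, indistinguishable at MAF << 1.
    """
    if not 0.0 <= maf <= 1.0:
        raise ValueError(f"maf must be in [0, 1], got {maf}")
    vol_in = assay.input_volume_ul
    if vol_in <= 0 or vol_in > meta.extract_volume_ul:
        raise ValueError(
            f"input volume {vol_in} uL must be in (0, extract volume {meta.extract_volume_ul} uL]"
        )
    positives = assay.n_wt if wt_only else assay.n_mut + assay.n_wt
    lam = poisson_lambda(positives, assay.n_total)
    copies_in_reaction = lam * assay.n_total
    copies_per_ml = copies_in_reaction * (meta.extract_volume_ul / vol_in) / meta.plasma_volume_ml
    return Quantification(
        sample_id=assay.sample_id,
        total_cfdna_copies_per_ml=copies_per_ml,
        maf=maf,
        ctdna_ng_per_ml=copies_per_ml * maf * HAPLOID_GENOME_NG,
        genome_equivalents=int(math.floor(copies_in_reaction)),
        source=source,
    )


def genome_equivalents(mass_ng: float) -> int:
    """Countable haploid genomes in a DNA mass: floor(mass / 3.3 pg)."""
    if mass_ng < 0:
        raise ValueError(f"mass must be >= 0, got {mass_ng}")
    # epsilon keeps exact multiples of m_g from flooring one unit low
    return int(math.floor(mass_ng / HAPLOID_GENOME_NG + 1e-9))


def theoretical_lod(genome_equiv: int, min_molecules: int = 3) -> float:
    """Lowest allele fraction countable from a finite input.

    With ``genome_equiv`` haploid genomes loaded, at least ``min_molecules``
    mutant molecules must be present to call a variant, so the LOD is
    ``min_molecules / genome_equiv`` (capped at 1).
    """
    if genome_equiv <= 0:
        raise UndefinedRateError("LOD undefined for zero genome equivalents")
    if min_molecules < 1:
        raise ValueError("min_molecules must be >= 1")
    return min(min_molecules / genome_equiv, 1.0)


def categorize(conc_ng_per_ml: float, cut_low: float = CUT_LOW, cut_high: float = CUT_HIGH) -> ConcentrationCategory:
    """Fixed-cutoff concentration category: low < cut_low <= intermediate <= cut_high < high."""
    if conc_ng_per_ml < 0:
        raise ValueError("concentration must be >= 0")
    if conc_ng_per_ml < cut_low:
        label = "low"
    elif conc_ng_per_ml > cut_high:
        label = "high"
    else:
        label = "intermediate"
    return ConcentrationCategory(label, cut_low, cut_high)


def tertile_cutoffs(concentrations) -> tuple[float, float]:
    """Empirical tertile cut-offs (33.3 / 66.7 percentiles) for a new cohort."""
    vals = np.asarray(list(concentrations), dtype=float)
    if vals.size < 3:
        raise ValueError(f"need >= 3 concentrations, got {vals.size}")
    lo, hi = np.percentile(vals, [100.0 / 3.0, 200.0 / 3.0])
    return float(lo), float(hi)
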