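"""Core domain types: panel positions, alterations, pileup matrices, sample metadata.

Coordinate convention: all positions are 1-based inclusive internally.  BED input
is converted from 0-based half-open on read; VCF output is 1-based (standard).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from .exceptions import PileupValidationError

VALID_BASES = frozenset("ACGT")

#: closed set of longitudinal sampling points: baseline, first evaluation
#: (6 +/- 2 weeks), time of radiological progression, plus technical controls
TIME_POINTS = ("T0", "E1", "ToP", "control")


@dataclass(frozen=True, order=True)
class PanelPosition:
    """One targeted reference base of an amplicon panel (1-based)."""

    contig: str
    pos: int
    ref_base: str = field(compare=False, default="N")
    gene: str = field(compare=False, default="")
    hotspot: bool = field(compare=False, default=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"panel position must be >= 1, got {self.pos}")
        if self.ref_base not in VALID_BASES and self.ref_base != "N":
            raise ValueError(f"invalid reference base {self.ref_base!r}")


@dataclass(frozen=True)
class Alteration:
    """A substitution, insertion or deletion relative to the panel reference.

    ``alt_seq`` holds the substituted base (substitutions) or the inserted
    sequence (insertions); deletions are described by ``span`` alone, the
    number of reference bases removed.  ``span`` is the number of reference
    bases affected: 1 for substitutions, 0 for insertions (anchored to the
    base preceding the event), the deleted length for deletions.
    """

    kind: str  # "sub" | "ins" | "del"
    alt_seq: str = ""
    span: int = 1

    def __post_init__(self) -> None:
        if self.kind == "sub":
            if self.span != 1 or len(self.alt_seq) != 1 or self.alt_seq not in VALID_BASES:
                raise ValueError(f"invalid substitution {self.alt_seq!r}/{self.span}")
        elif self.kind == "ins":
            if self.span != 0 or len(self.alt_seq) < 1 or set(self.alt_seq) - VALID_BASES:
                raise ValueError(f"invalid insertion {self.alt_seq!r}/{self.span}")
        elif self.kind == "del":
            if self.span < 1 or self.alt_seq:
                raise ValueError(f"invalid deletion span {self.span}")
        else:
            raise ValueError(f"unknown alteration kind {self.kind!r}")

    @property
    def length(self) -> int:
        """Event length in bases: 1 for substitutions, inserted/deleted length otherwise."""
        if self.kind == "ins":
            return len(self.alt_seq)
        return self.span

    @property
    def key(self) -> str:
        """Canonical text key, e.g. ``sub:T``, ``ins:ACG``, ``del:3``."""
        if self.kind == "del":
            return f"del:{self.span}"
        return f"{self.kind}:{self.alt_seq}"

    @classmethod
    def from_key(cls, key: str) -> "Alteration":
        try:
            kind, payload = key.split(":", 1)
        except ValueError:
            raise ValueError(f"malformed alteration key {key!r}") from None
        if kind == "sub":
            return cls("sub", payload, 1)
        if kind == "ins":
            return cls("ins", payload, 0)
        if kind == "del":
            return cls("del", "", int(payload))
        raise ValueError(f"unknown alteration kind in key {key!r}")

    def classify(self) -> str:
        """Class used for detection floors: snv, short_indel (<=2 bp) or long_indel (>2 bp)."""
        if self.kind == "sub":
            return "snv"
        return "short_indel" if self.length <= 2 else "long_indel"


def variant_id(position: PanelPosition, alteration: Alteration) -> str:
    """Stable text identity of a mutation, e.g. ``chr7:55242465:sub:T``."""
    return f"{position.contig}:{position.pos}:{alteration.key}"


class PileupMatrix:
    """Per-position allele counts for one ultra-deep sequencing sample.

    ``depth[i]`` is the number of filter-passing reads aligned across position
    ``i`` (as match/mismatch/deletion); ``counts[i]`` maps alteration keys to
    the number of reads supporting that alteration.  Insertions are anchored
    to the base preceding the inserted sequence and therefore do not
    contribute to the substitution/deletion depth bound.
    """

    def __init__(
        self,
        sample_id: str,
        positions: list[PanelPosition],
        depth: np.ndarray | list[int],
        counts: list[dict[str, int]] | None = None,
    ) -> None:
        self.sample_id = sample_id
        self.positions = list(positions)
        self.depth = np.asarray(depth, dtype=np.int64)
        self.counts: list[dict[str, int]] = (
            [dict(c) for c in counts] if counts is not None else [{} for _ in self.positions]
        )
        if len(self.positions) != len(self.depth) or len(self.positions) != len(self.counts):
            raise PileupValidationError("positions, depth and counts lengths differ")
        self._index = {(p.contig, p.pos): i for i, p in enumerate(self.positions)}
        if len(self._index) != len(self.positions):
            raise PileupValidationError("duplicate (contig, pos) in panel")

    # -- lookups ---------------------------------------------------------
    def index_of(self, contig: str, pos: int) -> int:
        return self._index[(contig, pos)]

    def count(self, i: int, alteration: Alteration | str) -> int:
        key = alteration if isinstance(alteration, str) else alteration.key
        return self.counts[i].get(key, 0)

    def af(self, i: int, alteration: Alteration | str) -> float:
        d = int(self.depth[i])
        return self.count(i, alteration) / d if d > 0 else 0.0

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def uncallable_positions(self) -> list[PanelPosition]:
        """Positions with zero depth — present in the panel but untestable."""
        return [p for p, d in zip(self.positions, self.depth) if d == 0]

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Check invariants: non-negative counts/depth, counts bounded by depth.

        Insertion counts are excluded from the depth bound (anchored events).
        """
        if (self.depth < 0).any():
            raise PileupValidationError("negative depth")
        for i, cdict in enumerate(self.counts):
            aligned = 0
            for key, c in cdict.items():
                if c < 0:
                    raise PileupValidationError(f"negative count at index {i} ({key})")
                if not key.startswith("ins:"):
                    aligned += c
            if aligned > self.depth[i]:
                p = self.positions[i]
                raise PileupValidationError(
                    f"counts ({aligned}) exceed depth ({self.depth[i]}) at {p.contig}:{p.pos}"
                )

    def same_panel(self, other: "PileupMatrix") -> bool:
        return [(p.contig, p.pos, p.ref_base) for p in self.positions] == [
            (p.contig, p.pos, p.ref_base) for p in other.positions
        ]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"PileupMatrix(sample_id={self.sample_id!r}, n_positions={self.n_positions}, "
            f"median_depth={int(np.median(self.depth)) if self.n_positions else 0})"
        )


@dataclass
class SampleMeta:
    """Per-sample processing metadata used for absolute quantification.

    Defaults mirror the clinical workflow this package models: cell-free DNA
    extracted from 2 mL plasma into a 50 uL eluate.
    """

    patient_id: str
    sample_id: str
    time_point: str = "T0"
    plasma_volume_ml: float = 2.0
    extract_volume_ul: float = 50.0
    input_mass_ng: float | None = None
    collection_date: _dt.date | None = None

    def __post_init__(self) -> None:
        if self.time_point not in TIME_POINTS:
            raise ValueError(f"time_point must be one of {TIME_POINTS}, got {self.time_point!r}")
        if self.plasma_volume_ml <= 0 or self.extract_volume_ul <= 0:
            raise ValueError("plasma and extract volumes must be positive")
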