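"""On-disk formats: BED panels, pileup TSV tables, SAM/BAM extraction, VCF output.

Pileup TSV dialect
------------------
Tab-separated, UTF-8, ``#`` comments, one header line, then one row per
(position, alteration) observed plus one depth-only row (alteration ``.``,
count 0) for positions without any observed alteration::

    sample_id  contig  pos  ref  depth  alteration  count

``pos`` is 1-based; ``alteration`` uses the canonical keys ``sub:<base>``,
``ins:<seq>``, ``del:<len>``.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pysam

from .exceptions import ConsistencyError, PanelParseError, PileupValidationError
from .panel import Alteration, PanelPosition, PileupMatrix

log = logging.getLogger(__name__)

PILEUP_COLUMNS = ("sample_id", "contig", "pos", "ref", "depth", "alteration", "count")
_TRUTHY = {"1", "true", "yes", "y"}


# ---------------------------------------------------------------------------
# panel (BED)
# ---------------------------------------------------------------------------

def read_panel(path, reference: str | None = None) -> list[PanelPosition]:
    """Read a panel BED file into per-base :class:`PanelPosition` records.

    BED intervals are 0-based half-open; the returned positions are 1-based
    per covered base, sorted by (contig, pos).  Optional columns: 4th = gene
    symbol, 5th = hotspot flag, 6th = reference sequence of the interval.
    ``reference`` may name a FASTA file supplying the reference bases instead
    of the 6th column; one of the two must provide them.
    """
    fasta = None
    if reference is not None:
        import pyfaidx

        fasta = pyfaidx.Fasta(str(reference))

    out: dict[tuple[str, int], PanelPosition] = {}
    n_lines = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise PanelParseError(f"line {lineno}: expected >=3 BED columns")
            contig = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise PanelParseError(f"line {lineno}: non-integer interval bounds") from None
            if start < 0 or start >= end:
                raise PanelParseError(f"line {lineno}: invalid interval [{start}, {end})")
            gene = fields[3] if len(fields) > 3 and fields[3] != "." else ""
            hotspot = len(fields) > 4 and fields[4].strip().lower() in _TRUTHY
            seq = fields[5].strip().upper() if len(fields) > 5 else None

            if seq is not None and len(seq) != end - start:
                raise PanelParseError(
                    f"line {lineno}: reference column length {len(seq)} != interval length {end - start}"
                )
            if seq is None and fasta is not None:
                seq = str(fasta[contig][start:end]).upper()
            if seq is None:
                raise PanelParseError(
                    f"line {lineno}: no reference base available (supply a FASTA or a 6th column)"
                )
            for k in range(end - start):
                pos = start + k + 1  # 1-based
                if (contig, pos) in out:
                    raise ConsistencyError(f"duplicate panel position {contig}:{pos}")
                out[(contig, pos)] = PanelPosition(contig, pos, seq[k], gene, hotspot)
    if n_lines == 0:
        log.warning("panel file %s contains no intervals", path)
    return sorted(out.values(), key=lambda p: (p.contig, p.pos))


# ---------------------------------------------------------------------------
# pileup TSV
# ---------------------------------------------------------------------------

def write_pileup_tsv(pileup: PileupMatrix, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(PILEUP_COLUMNS) + "\n")
        for i, p in enumerate(pileup.positions):
            base = (pileup.sample_id, p.contig, str(p.pos), p.ref_base, str(int(pileup.depth[i])))
            rows = sorted((k, c) for k, c in pileup.counts[i].items() if c > 0)
            if not rows:
                rows = [(".", 0)]
            for key, c in rows:
                fh.write("\t".join(base + (key, str(c))) + "\n")


def read_pileup_tsv(path) -> PileupMatrix:
    """Read the native pileup dialect into a validated :class:`PileupMatrix`."""
    sample_id = None
    order: list[tuple[str, int]] = []
    meta: dict[tuple[str, int], tuple[str, int]] = {}  # (contig,pos) -> (ref, depth)
    counts: dict[tuple[str, int], dict[str, int]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        header = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if tuple(header) != PILEUP_COLUMNS:
                    raise PanelParseError(f"line {lineno}: unexpected header {header}")
                continue
            if len(fields) != len(PILEUP_COLUMNS):
                raise PanelParseError(f"line {lineno}: expected {len(PILEUP_COLUMNS)} columns")
            sid, contig, pos_s, ref, depth_s, alt_key, count_s = fields
            if sample_id is None:
                sample_id = sid
            elif sid != sample_id:
                raise PanelParseError(f"line {lineno}: multiple sample_ids in one pileup file")
            try:
                pos, depth, count = int(pos_s), int(depth_s), int(count_s)
            except ValueError:
                raise PanelParseError(f"line {lineno}: non-integer pos/depth/count") from None
            key = (contig, pos)
            if key not in meta:
                order.append(key)
                meta[key] = (ref, depth)
                counts[key] = {}
            elif meta[key] != (ref, depth):
                raise PileupValidationError(f"line {lineno}: conflicting ref/depth at {contig}:{pos}")
            if alt_key == ".":
                if count != 0:
                    raise PileupValidationError(f"line {lineno}: depth-only row with count != 0")
                continue
            try:
                Alteration.from_key(alt_key)
            except ValueError as exc:
                raise PanelParseError(f"line {lineno}: {exc}") from None
            if alt_key in counts[key]:
                raise PileupValidationError(
                    f"line {lineno}: duplicate (position, alteration) row {contig}:{pos} {alt_key}"
                )
            counts[key][alt_key] = count
    positions = [PanelPosition(c, p, meta[(c, p)][0]) for c, p in order]
    depth = [meta[k][1] for k in order]
    mat = PileupMatrix(sample_id or "", positions, depth, [counts[k] for k in order])
    mat.validate()
    if mat.uncallable_positions():
        log.warning(
            "%d position(s) with zero depth in %s are uncallable", len(mat.uncallable_positions()), path
        )
    return mat


# ---------------------------------------------------------------------------
# alignment extraction
# ---------------------------------------------------------------------------

def pileup_from_alignments(
    alignment_path,
    panel: Sequence[PanelPosition],
    sample_id: str | None = None,
    min_mapq: int = 20,
    min_baseq: int = 20,
) -> PileupMatrix:
    """Count substitutions, insertions and deletions over the panel from SAM/BAM.

    Reads below ``min_mapq`` are skipped entirely; bases below ``min_baseq``
    contribute neither depth nor counts.  Insertions are anchored to the base
    preceding the inserted sequence; deletions add one depth unit and one
    ``del:<len>`` count at every deleted reference base.  Depth counts reads
    aligned as match/mismatch/deletion only.
    """
    panel = sorted(panel, key=lambda p: (p.contig, p.pos))
    idx = {(p.contig, p.pos): i for i, p in enumerate(panel)}
    ref_base = [p.ref_base for p in panel]
    depth = np.zeros(len(panel), dtype=np.int64)
    counts: list[dict[str, int]] = [{} for _ in panel]

    path = str(alignment_path)
    mode = "r" if path.endswith(".sam") else "rb"
    with pysam.AlignmentFile(path, mode) as af:
        contigs = sorted({p.contig for p in panel})
        if mode == "rb" and not af.has_index():
            raise OSError(f"alignment file {path} has no index")
        if af.has_index():
            reads: Iterable[pysam.AlignedSegment] = []
            read_iters = []
            for contig in contigs:
                if contig not in af.references:
                    warnings.warn(f"contig {contig!r} absent from alignments; zero depth")
                    continue
                lo = min(p.pos for p in panel if p.contig == contig)
                hi = max(p.pos for p in panel if p.contig == contig)
                read_iters.append(af.fetch(contig, lo - 1, hi))
            reads = (r for it in read_iters for r in it)
        else:
            reads = af.fetch(until_eof=True)
        for read in reads:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            _accumulate_read(read, idx, ref_base, depth, counts, min_baseq)

    mat = PileupMatrix(sample_id or "sample", panel, depth, counts)
    return mat


def _accumulate_read(read, idx, ref_base, depth, counts, min_baseq) -> None:
    contig = read.reference_name
    rpos = read.reference_start  # 0-based
    qpos = 0
    seq = read.query_sequence or ""
    quals = read.query_qualities
    for op, ln in read.cigartuples or ():
        if op in (0, 7, 8):  # M, =, X
            for k in range(ln):
                i = idx.get((contig, rpos + k + 1))
                if i is not None and (quals is None or quals[qpos + k] >= min_baseq):
                    depth[i] += 1
                    base = seq[qpos + k]
                    if base != ref_base[i] and base != "N":
                        key = f"sub:{base}"
                        counts[i][key] = counts[i].get(key, 0) + 1
            rpos += ln
            qpos += ln
        elif op == 1:  # I: anchored to the preceding reference base (1-based rpos)
            i = idx.get((contig, rpos))
            if i is not None and (quals is None or min(quals[qpos : qpos + ln]) >= min_baseq):
                key = f"ins:{seq[qpos:qpos + ln]}"
                counts[i][key] = counts[i].get(key, 0) + 1
            qpos += ln
        elif op == 2:  # D: counted at every deleted reference base
            key = f"del:{ln}"
            for k in range(ln):
                i = idx.get((contig, rpos + k + 1))
                if i is not None:
                    depth[i] += 1
                    counts[i][key] = counts[i].get(key, 0) + 1
            rpos += ln
        elif op == 3:  # N
            rpos += ln
        elif op == 4:  # S
            qpos += ln
        # H, P consume nothing


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

def write_vcf(calls, sample_id: str, panel: Sequence[PanelPosition], path) -> None:
    """Write variant calls as VCF 4.2 (indels left-anchored with a leading ref base)."""
    ref_at = {(p.contig, p.pos): p.ref_base for p in panel}
    contigs = sorted({p.contig for p in panel})
    filters = sorted({c.filter_reason for c in calls if not c.passed and c.filter_reason})
    lines = [
        "##fileformat=VCFv4.2",
        "##source=bper",
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Allele fraction">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Filtered depth">',
        '##INFO=<ID=ALTREADS,Number=1,Type=Integer,Description="Reads supporting the alteration">',
        '##INFO=<ID=TAU,Number=1,Type=Float,Description="Position-specific BPER calling threshold">',
        '##INFO=<ID=PBINOM,Number=1,Type=Float,Description="Binomial tail probability under background">',
        '##INFO=<ID=Z,Number=1,Type=Float,Description="Standardized excess over background mean">',
    ]
    lines += [f'##FILTER=<ID={f},Description="Failed: {f}">' for f in filters]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")

    for call in calls:
        p, a = call.position, call.alteration
        if (p.contig, p.pos) not in ref_at:
            raise ConsistencyError(f"call at {p.contig}:{p.pos} is not a panel position")
        if a.kind == "sub":
            pos, ref, alt = p.pos, p.ref_base, a.alt_seq
        elif a.kind == "ins":
            pos, ref = p.pos, p.ref_base
            alt = p.ref_base + a.alt_seq
        else:  # deletion: anchor at the base before the first deleted base
            pos = p.pos - 1
            anchor = ref_at.get((p.contig, pos), "N")
            deleted = "".join(ref_at.get((p.contig, p.pos + k), "N") for k in range(a.span))
            ref, alt = anchor + deleted, anchor
        info = (
            f"AF={call.af:.6g};DP={call.depth};ALTREADS={call.alt_reads};"
            f"TAU={call.tau:.6g};PBINOM={call.p_binom:.6g};Z={call.z:.6g}"
        )
        status = "PASS" if call.passed else (call.filter_reason or "FAIL")
        lines.append(f"{p.contig}\t{pos}\t.\t{ref}\t{alt}\t.\t{status}\t{info}")

    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
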