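"""From raw pairwise hits to lineage CNS sets.

The calling chain per lineage: discard hits whose reference interval is
completely contained in another hit's; extract conserved cores from each
remaining alignment by sliding identity windows; merge cores per partner
species; intersect across all lineage members (group-common); subtract
exclusion tracks (coding/RNA/pseudogene/masked bases) and outgroup
conserved cores (group-unique); flag multi-copy CNSs by self-search of the
reference genome.

Core windows are measured in alignment columns and the output is trimmed
so both ends are match columns; interval arithmetic then happens in
reference coordinates mapped through the column string.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .align import AlignmentHit, ScoringScheme, local_align, percent_identity
from .intervals import (
    GenomicInterval,
    intersect_coverage,
    merge_intervals,
    subtract_intervals,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_LENGTH = 100


@dataclass
class CNSRecord:
    """One conserved noncoding sequence on the reference genome."""

    cns_id: str
    interval: GenomicInterval
    homologs: dict[str, tuple[GenomicInterval, float]] = field(default_factory=dict)
    single_copy: bool | None = None
    labels: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.interval)


def filter_contained_hits(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Drop every hit whose reference interval is contained in another's.

    Partial overlaps are retained. For exactly equal reference intervals one
    hit survives (higher score, then lower subject start). Output is sorted
    by (chrom, start, end).
    """
    by_chrom: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.query.chrom, []).append(h)
    kept: list[AlignmentHit] = []
    for chrom in sorted(by_chrom):
        hs = sorted(by_chrom[chrom],
                    key=lambda h: (h.query.start, -h.query.end, -h.score,
                                   h.subject.start))
        # dedupe equal intervals first (keep best)
        uniq: list[AlignmentHit] = []
        for h in hs:
            if uniq and (uniq[-1].query.start, uniq[-1].query.end) == \
                    (h.query.start, h.query.end):
                continue
            uniq.append(h)
        max_end = -1
        for h in uniq:
            if h.query.end <= max_end:
                continue  # contained in an earlier (longer) hit
            kept.append(h)
            max_end = h.query.end
    kept.sort(key=lambda h: (h.query.chrom, h.query.start, h.query.end))
    return kept


def _column_arrays(hit: AlignmentHit) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(is_match, query position per column, subject offset per column).

    Query positions are absolute reference coordinates; columns that do not
    consume the reference carry the next reference position. Subject offsets
    count subject-consuming columns from the subject interval start.
    """
    cols = np.frombuffer(hit.columns.encode(), dtype=np.uint8)
    is_match = cols == ord("M")
    consumes_q = (cols == ord("M")) | (cols == ord("X")) | (cols == ord("S"))
    consumes_s = (cols == ord("M")) | (cols == ord("X")) | (cols == ord("Q"))
    qpos = hit.query.start + np.concatenate([[0], np.cumsum(consumes_q)[:-1]])
    soff = np.concatenate([[0], np.cumsum(consumes_s)[:-1]])
    return is_match, qpos, soff


def extract_cores(
    hit: AlignmentHit,
    threshold_divergence: float,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> list[GenomicInterval]:
    """Conserved cores of one alignment, as reference intervals.

    If the whole alignment passes (identity >= 100 - threshold and the
    reference span is at least ``min_length``), it is returned whole.
    Otherwise every ``min_length``-column window meeting the identity
    threshold is kept, passing windows are unioned (in columns), and each
    resulting run is trimmed so that its first and last columns are
    matches before mapping to reference coordinates; trimmed cores whose
    reference span falls below ``min_length`` are dropped.
    """
    n = len(hit.columns)
    min_identity = 100.0 - threshold_divergence
    if n >= 1 and percent_identity(hit) >= min_identity \
            and len(hit.query) >= min_length:
        return [GenomicInterval(hit.query.chrom, hit.query.start, hit.query.end)]
    if n < min_length:
        return []
    is_match, qpos, _ = _column_arrays(hit)
    m = np.cumsum(np.concatenate([[0], is_match]))
    window_matches = m[min_length:] - m[:-min_length]  # per window start
    passing = window_matches >= min_identity / 100.0 * min_length
    if not passing.any():
        return []
    # union of passing windows, as column runs
    covered = np.zeros(n, dtype=bool)
    starts = np.nonzero(passing)[0]
    # mark via diff trick
    delta = np.zeros(n + 1, dtype=np.int64)
    delta[starts] += 1
    delta[starts + min_length] -= 1
    covered = np.cumsum(delta[:-1]) > 0
    out: list[GenomicInterval] = []
    boundaries = np.nonzero(np.diff(covered.astype(np.int8)))[0] + 1
    runs = np.split(np.arange(n), boundaries)
    for run in runs:
        if len(run) == 0 or not covered[run[0]]:
            continue
        a, b = run[0], run[-1]
        # trim so both ends are match columns
        while a <= b and not is_match[a]:
            a += 1
        while b >= a and not is_match[b]:
            b -= 1
        if b < a:
            continue
        ref_s = int(qpos[a])
        ref_e = int(qpos[b]) + 1  # match column consumes the reference
        if ref_e - ref_s >= min_length:
            out.append(GenomicInterval(hit.query.chrom, ref_s, ref_e))
    return out


def map_to_subject(hit: AlignmentHit, ref_iv: GenomicInterval
                   ) -> GenomicInterval | None:
    """Project a reference sub-interval of a hit onto the subject genome."""
    if ref_iv.chrom != hit.query.chrom:
        return None
    s = max(ref_iv.start, hit.query.start)
    e = min(ref_iv.end, hit.query.end)
    if e <= s:
        return None
    is_match, qpos, soff = _column_arrays(hit)
    cols = np.frombuffer(hit.columns.encode(), dtype=np.uint8)
    consumes_q = (cols == ord("M")) | (cols == ord("X")) | (cols == ord("S"))
    sel = consumes_q & (qpos >= s) & (qpos < e)
    offs = soff[sel]
    if len(offs) == 0:
        return None
    lo, hi = int(offs.min()), int(offs.max()) + 1
    if hit.subject.strand == "-":
        return GenomicInterval(hit.subject.chrom, hit.subject.end - hi,
                               hit.subject.end - lo, "-")
    return GenomicInterval(hit.subject.chrom, hit.subject.start + lo,
                           hit.subject.start + hi, "+")


def conserved_track(
    hits: list[AlignmentHit],
    threshold_divergence: float,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> list[GenomicInterval]:
    """Merged reference track of conserved cores from filtered hits."""
    cores: list[GenomicInterval] = []
    for h in filter_contained_hits(hits):
        cores.extend(extract_cores(h, threshold_divergence, min_length))
    return merge_intervals(cores) if cores else []


def group_common(
    per_partner_core_tracks: dict[str, list[GenomicInterval]],
    exclusion_tracks: list[GenomicInterval],
    min_length: int = DEFAULT_MIN_LENGTH,
    per_partner_hits: dict[str, list[AlignmentHit]] | None = None,
) -> list[CNSRecord]:
    """Reference regions conserved in every lineage member.

    Intersection is base-level across the partner core tracks; exclusion
    bases (coding/RNA/pseudogene/masked) are subtracted; fragments shorter
    than ``min_length`` are dropped. When the supporting hits are supplied,
    each CNS carries back-mapped per-partner homolog intervals and
    identities.
    """
    if not per_partner_core_tracks:
        raise ValueError("need at least one partner track")
    for sp, track in per_partner_core_tracks.items():
        if track is None:
            raise ValueError(f"missing core track for partner {sp!r}")
    common: list[GenomicInterval] | None = None
    for sp in sorted(per_partner_core_tracks):
        track = merge_intervals(per_partner_core_tracks[sp]) \
            if per_partner_core_tracks[sp] else []
        common = track if common is None else intersect_coverage(common, track)
    if exclusion_tracks:
        common = subtract_intervals(common, exclusion_tracks)
    records = []
    for i, iv in enumerate(iv for iv in common if len(iv) >= min_length):
        rec = CNSRecord(cns_id=f"cns{i:06d}", interval=iv,
                        labels={"group-common"})
        if per_partner_hits:
            for sp, hits in per_partner_hits.items():
                best = None
                for h in hits:
                    ov = h.query.overlap_length(iv)
                    if ov > 0 and (best is None or ov > best[0]):
                        best = (ov, h)
                if best:
                    sub = map_to_subject(best[1], iv)
                    if sub is not None:
                        rec.homologs[sp] = (sub, percent_identity(best[1]))
        records.append(rec)
    return records


def group_unique(
    common: list[CNSRecord],
    outgroup_core_tracks: dict[str, list[GenomicInterval]],
    min_length: int = DEFAULT_MIN_LENGTH,
) -> list[CNSRecord]:
    """Residual parts of group-common CNSs conserved in no outgroup species.

    Outgroup tracks must already be conserved cores at each outgroup's own
    threshold. Fragments of at least ``min_length`` survive, labeled
    group-unique.
    """
    outgroup_all: list[GenomicInterval] = []
    for track in outgroup_core_tracks.values():
        outgroup_all.extend(track)
    outgroup_all = merge_intervals(outgroup_all) if outgroup_all else []
    out = []
    n = 0
    for rec in common:
        residual = subtract_intervals([rec.interval], outgroup_all)
        for iv in residual:
            if len(iv) >= min_length:
                out.append(CNSRecord(
                    cns_id=f"{rec.cns_id}.u{n}", interval=iv,
                    homologs=dict(rec.homologs),
                    single_copy=rec.single_copy,
                    labels=rec.labels | {"group-unique"},
                ))
                n += 1
    return out


def flag_duplicates(
    cns: list[CNSRecord],
    genome: dict[str, str],
    scheme: ScoringScheme | None = None,
    threshold_divergence: float = 10.0,
    min_length: int = DEFAULT_MIN_LENGTH,
    engine: str = "auto",
) -> list[CNSRecord]:
    """Set the single-copy flag by searching each CNS against its own genome.

    A CNS is multi-copy when a second conserved core of at least
    ``min_length`` exists at the lineage threshold outside its own locus.
    """
    scheme = scheme or ScoringScheme()
    queries = {
        rec.cns_id: genome[rec.interval.chrom][rec.interval.start:rec.interval.end]
        for rec in cns
    }
    if not queries:
        return cns
    hits = local_align(queries, genome, scheme, evalue_max=1e-5, engine=engine)
    by_id: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_id.setdefault(h.query.chrom, []).append(h)
    for rec in cns:
        rec.single_copy = True
        for h in by_id.get(rec.cns_id, []):
            cores = extract_cores(h, threshold_divergence, min_length)
            if not cores:
                continue
            for core in cores:
                sub = map_to_subject(h, core)
                if sub is None:
                    continue
                self_iv = GenomicInterval(rec.interval.chrom, rec.interval.start,
                                          rec.interval.end)
                if sub.chrom == self_iv.chrom and sub.overlap_length(self_iv) \
                        >= 0.5 * len(sub):
                    continue  # the CNS finding itself
                rec.single_copy = False
                break
            if not rec.single_copy:
                break
    return cns


def assign_age_classes(
    presence_by_set: dict[str, bool],
) -> set[str]:
    """Age-class label from a presence pattern over nested outgroup sets.

    ``presence_by_set`` maps progressively older set names (e.g. 'eutherian',
    'mammalian', 'tetrapod') to whether the CNS is conserved in that set;
    the oldest set with presence names the class, else 'lineage-unique'.
    """
    label = "lineage-unique"
    for name, present in presence_by_set.items():
        if present:
            label = f"{name}-common"
    return {label}
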