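"""Positional signatures in and around CNSs.

Flank profiles slide fixed windows outward from just inside the CNS edges
through 1,500-bp flanks: 50-bp windows at 20-bp steps starting 30 bp
inside the CNS for conservation, 200-bp windows at 10-bp steps starting
50 bp inside for GC content. Point 0 of either curve is the central 100 bp
of the CNS. Conservation is measured on a per-reference-position projection
of the pairwise alignment (match / mismatch / gap / unaligned); gap
positions count against identity and unaligned windows are excluded from
that window's mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .align import AlignmentHit
from .intervals import GenomicInterval, coverage_fraction, merge_intervals
from .detect import _column_arrays

logger = logging.getLogger(__name__)


@dataclass
class ProfileSpec:
    flank_bp: int = 1500
    cons_window: int = 50
    cons_step: int = 20
    cons_inset: int = 30
    gc_window: int = 200
    gc_step: int = 10
    gc_inset: int = 50
    center_span: int = 100


# ---------------------------------------------------------------------------
# Alignment projection


MATCH, MISMATCH, GAP, UNALIGNED = 3, 2, 1, 0


def project_alignment(
    hits: list[AlignmentHit], region: GenomicInterval
) -> np.ndarray:
    """Per-reference-position alignment status over ``region``.

    Positions covered by no hit are UNALIGNED; where hits overlap the best
    status wins (match > mismatch > gap)."""
    status = np.zeros(len(region), dtype=np.uint8)
    for h in hits:
        if h.query.chrom != region.chrom:
            continue
        is_match, qpos, _ = _column_arrays(h)
        cols = np.frombuffer(h.columns.encode(), dtype=np.uint8)
        consumes_q = (cols == ord("M")) | (cols == ord("X")) | (cols == ord("S"))
        val = np.where(cols == ord("M"), MATCH,
                       np.where(cols == ord("X"), MISMATCH, GAP)).astype(np.uint8)
        sel = consumes_q & (qpos >= region.start) & (qpos < region.end)
        pos = qpos[sel] - region.start
        np.maximum.at(status, pos, val[sel])
    return status


def _window_layout(cns: GenomicInterval, spec: ProfileSpec, window: int,
                   step: int, inset: int) -> list[tuple[int, int, int]]:
    """(offset index, start, end) for center and both flank window ladders.

    Negative offsets are upstream of the CNS start, positive downstream of
    the end; offset 0 is the CNS-central ``center_span`` window.
    """
    mid = (cns.start + cns.end) // 2
    half = spec.center_span // 2
    out = [(0, mid - half, mid + half)]
    k_max = (spec.flank_bp - window + inset) // step + 1
    for k in range(1, k_max + 1):
        s = cns.end - inset + (k - 1) * step
        out.append((k, s, s + window))
        e = cns.start + inset - (k - 1) * step
        out.append((-k, e - window, e))
    return out


def conservation_profile(
    cns_list: list[GenomicInterval],
    per_cns_hits: list[list[AlignmentHit]],
    spec: ProfileSpec | None = None,
    region_bound: int | None = None,
) -> pd.DataFrame:
    """Mean percent identity (+/- SEM) per window offset across CNSs.

    Identity in a window = matches / (match+mismatch+gap positions); windows
    with no aligned position are excluded from that offset's mean. CNSs
    shorter than the center span are excluded entirely (logged). SEM is 0
    with an ``n=1`` count when a single CNS contributes.
    """
    spec = spec or ProfileSpec()
    per_offset: dict[int, list[float]] = {}
    for cns, hits in zip(cns_list, per_cns_hits):
        if len(cns) < spec.center_span:
            logger.info("CNS %s shorter than center span; excluded", cns.name)
            continue
        region = GenomicInterval(
            cns.chrom, max(0, cns.start - spec.flank_bp - spec.cons_window),
            cns.end + spec.flank_bp + spec.cons_window)
        status = project_alignment(hits, region)
        for off, s, e in _window_layout(cns, spec, spec.cons_window,
                                        spec.cons_step, spec.cons_inset):
            s -= region.start
            e -= region.start
            if s < 0 or e > len(status):
                continue
            win = status[s:e]
            aligned = win > UNALIGNED
            if not aligned.any():
                continue
            ident = 100.0 * float((win == MATCH).sum()) / float(aligned.sum())
            per_offset.setdefault(off, []).append(ident)
    rows = []
    for off in sorted(per_offset):
        vals = np.array(per_offset[off])
        sem = float(stats.sem(vals)) if len(vals) > 1 else 0.0
        rows.append({"offset": off, "mean_identity": float(vals.mean()),
                     "sem": sem, "n": len(vals)})
    return pd.DataFrame(rows)


def gc_profile(
    cns_list: list[GenomicInterval],
    genome: dict[str, str],
    spec: ProfileSpec | None = None,
) -> pd.DataFrame:
    """Mean GC fraction per window offset; ambiguous bases are excluded from
    numerator and denominator, fully ambiguous windows from the mean."""
    spec = spec or ProfileSpec()
    per_offset: dict[int, list[float]] = {}
    for cns in cns_list:
        if len(cns) < spec.center_span:
            continue
        seq = genome[cns.chrom]
        for off, s, e in _window_layout(cns, spec, spec.gc_window,
                                        spec.gc_step, spec.gc_inset):
            if s < 0 or e > len(seq):
                continue
            win = seq[s:e].upper()
            gc = sum(win.count(b) for b in "GC")
            at = sum(win.count(b) for b in "AT")
            if gc + at == 0:
                continue
            per_offset.setdefault(off, []).append(gc / (gc + at))
    rows = [
        {"offset": off, "mean_gc": float(np.mean(vals)), "n": len(vals)}
        for off, vals in sorted(per_offset.items())
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SNP coverage and DAF


def sample_control_intervals(
    like: list[GenomicInterval],
    chrom_sizes: dict[str, int],
    exclusion: list[GenomicInterval],
    seed: int = 0,
    max_tries: int = 1000,
) -> list[GenomicInterval]:
    """Length- and chromosome-matched random intervals avoiding exclusion
    bases (masked/genic), rejection-sampled with a fixed seed."""
    rng = np.random.default_rng(seed)
    excl = merge_intervals(exclusion) if exclusion else []
    out = []
    for iv in like:
        size = chrom_sizes[iv.chrom]
        for _ in range(max_tries):
            s = int(rng.integers(0, max(1, size - len(iv))))
            cand = GenomicInterval(iv.chrom, s, s + len(iv))
            if coverage_fraction(cand, excl) == 0.0:
                out.append(cand)
                break
        else:
            logger.warning("no control placement found for %s", iv)
    return out


def snp_coverage(
    class_tracks: dict[str, list[GenomicInterval]],
    variants: pd.DataFrame,
) -> pd.DataFrame:
    """Single-nucleotide variants per 100 bp for each interval class."""
    rows = []
    for cls, track in class_tracks.items():
        track = merge_intervals(track) if track else []
        total_bp = sum(len(iv) for iv in track)
        if total_bp == 0:
            rows.append({"class": cls, "n_snps": 0, "bp": 0,
                         "per_100bp": np.nan})
            continue
        count = 0
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in track:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            starts = np.array([iv.start for iv in ivs])
            ends = np.array([iv.end for iv in ivs])
            pos = variants.loc[variants["chrom"] == chrom, "pos0"].to_numpy()
            idx = np.searchsorted(starts, pos, side="right") - 1
            ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
            count += int(ok.sum())
        rows.append({"class": cls, "n_snps": count, "bp": total_bp,
                     "per_100bp": 100.0 * count / total_bp})
    return pd.DataFrame(rows)


@dataclass
class DAFSpectrum:
    bin_edges: np.ndarray
    counts_cns: np.ndarray
    counts_control: np.ndarray
    n_excluded: int
    lowest_bin_p: float | None = None
    lowest_bin_cns_prop: float | None = None
    lowest_bin_control_prop: float | None = None


def polarize_variants(variants: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Derived-allele frequencies from the outgroup allele.

    The ancestral allele is whichever of ref/alt matches the outgroup;
    records whose outgroup allele matches neither are excluded (counted).
    """
    bad = ~((variants["alt_freq"] >= 0) & (variants["alt_freq"] <= 1))
    if bad.any():
        raise ValueError("allele frequency outside [0, 1]")
    match_ref = variants["outgroup_allele"] == variants["ref"]
    match_alt = variants["outgroup_allele"] == variants["alt"]
    usable = variants[match_ref | match_alt].copy()
    usable["daf"] = np.where(
        usable["outgroup_allele"] == usable["ref"],
        usable["alt_freq"], 1.0 - usable["alt_freq"])
    return usable, int(len(variants) - len(usable))


def daf_spectrum(
    variants: pd.DataFrame,
    cns_track: list[GenomicInterval],
    control_track: list[GenomicInterval],
    bin_width: float = 0.1,
) -> DAFSpectrum:
    """Outgroup-polarized DAF spectra for CNS and control variants, plus a
    binomial test of excess in the lowest-frequency bin (purifying-selection
    signature: constrained sites skew toward rare derived alleles)."""
    polarized, n_excluded = polarize_variants(variants)
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)

    def in_track(track):
        track = merge_intervals(track) if track else []
        flags = np.zeros(len(polarized), dtype=bool)
        for chrom in polarized["chrom"].unique():
            ivs = [iv for iv in track if iv.chrom == chrom]
            if not ivs:
                continue
            starts = np.array([iv.start for iv in ivs])
            ends = np.array([iv.end for iv in ivs])
            sel = (polarized["chrom"] == chrom).to_numpy()
            pos = polarized.loc[sel, "pos0"].to_numpy()
            idx = np.searchsorted(starts, pos, side="right") - 1
            ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
            flags[np.nonzero(sel)[0][ok]] = True
        return flags

    cns_daf = polarized.loc[in_track(cns_track), "daf"].to_numpy()
    ctl_daf = polarized.loc[in_track(control_track), "daf"].to_numpy()
    counts_cns, _ = np.histogram(np.clip(cns_daf, 0, 1 - 1e-12), bins=edges)
    counts_ctl, _ = np.histogram(np.clip(ctl_daf, 0, 1 - 1e-12), bins=edges)
    spectrum = DAFSpectrum(edges, counts_cns, counts_ctl, n_excluded)
    if len(cns_daf) and len(ctl_daf):
        p0 = counts_ctl[0] / counts_ctl.sum()
        x, n = int(counts_cns[0]), int(counts_cns.sum())
        if 0 < p0 < 1:
            spectrum.lowest_bin_p = float(stats.binom.sf(x - 1, n, p0))
        spectrum.lowest_bin_cns_prop = x / n
        spectrum.lowest_bin_control_prop = float(p0)
    return spectrum


# ---------------------------------------------------------------------------
# Outgroup-polarized substitution polarity


def substitution_polarity(
    ref_seq: str, partner_seq: str, outgroup_seq: str
) -> dict[str, int]:
    """GC->AT vs AT->GC substitution counts on the reference lineage.

    A site counts when the ingroup partner and the outgroup agree and the
    reference differs (so the change happened on the reference lineage, with
    ancestral state = partner base). Gap or ambiguous sites are skipped.
    """
    if not (len(ref_seq) == len(partner_seq) == len(outgroup_seq)):
        raise ValueError("aligned sequences must have equal length")
    strong = set("GC")
    weak = set("AT")
    counts = {"gc_to_at": 0, "at_to_gc": 0, "other": 0, "sites": 0}
    for r, p, o in zip(ref_seq.upper(), partner_seq.upper(), outgroup_seq.upper()):
        if r not in "ACGT" or p not in "ACGT" or o not in "ACGT":
            continue
        counts["sites"] += 1
        if p != o or r == p:
            continue
        if p in strong and r in weak:
            counts["gc_to_at"] += 1
        elif p in weak and r in strong:
            counts["at_to_gc"] += 1
        else:
            counts["other"] += 1
    return counts
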