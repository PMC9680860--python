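"""Chromosome ancestry painting: graphical genotypes and smoothed segments.

The ordered per-site genotype classes along a chromosome form its
"graphical genotype".  In a backcross hybrid these classes cluster into
long tracts reflecting the recombination history, so a simple smoothing
— majority vote in a centered window of sites, followed by merging runs
and absorbing tiny segments — recovers the underlying ancestry segments.

Windows are indexed in sites, not base pairs, which makes the smoothing
robust to variation in diagnostic-marker density.  Ties in the majority
vote are broken toward the unsmoothed class at the focal site, keeping
the procedure deterministic and conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from hybridtrace.errors import ArgumentError, DataError

_CLASS_ORDER = ("AA", "Aa", "aa")


@dataclass(frozen=True)
class Segment:
    """A run of constant smoothed class; start/end are 1-based site positions."""

    start: int
    end: int
    cls: str
    n_sites: int


@dataclass(frozen=True)
class AncestryTrack:
    """Per-site genotype classes along one chromosome, optionally smoothed."""

    chrom: str
    pos: np.ndarray
    classes: np.ndarray  # per-site labels from _CLASS_ORDER
    segments: "tuple[Segment, ...] | None" = None  # populated by smooth_track

    def __post_init__(self) -> None:
        if len(self.pos) != len(self.classes):
            raise ArgumentError("pos and classes must have equal length")
        if len(self.pos) and np.any(np.diff(self.pos) <= 0):
            raise ArgumentError("positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return len(self.pos)


def paint_chromosomes(
    classes: pd.DataFrame, drop_other: bool = True
) -> list[AncestryTrack]:
    """Build one unsmoothed :class:`AncestryTrack` per chromosome.

    ``classes`` is the per-site frame from the diagnostic stage
    (columns ``chrom, pos, class``, sorted by chromosome and position).
    Sites classified ``other`` (third-allele genotypes) are dropped by
    default; they carry no ancestry information.
    """
    if drop_other:
        classes = classes[classes["class"].isin(_CLASS_ORDER)]
    tracks = []
    for chrom, sub in classes.groupby("chrom", sort=False):
        tracks.append(
            AncestryTrack(
                chrom=chrom,
                pos=sub["pos"].to_numpy(dtype=np.int64),
                classes=sub["class"].to_numpy(dtype=object),
            )
        )
    return tracks


def _majority_smooth(codes: np.ndarray, window: int) -> np.ndarray:
    """Centered majority vote over ``window`` sites, clipped at the ends.

    Ties are broken toward the site's own unsmoothed class when it is
    among the tied classes, otherwise toward the class listed first in
    AA < Aa < aa order.
    """
    n = len(codes)
    h = window // 2
    onehot = np.zeros((n + 1, 3), dtype=np.int64)
    onehot[1:][np.arange(n), codes] = 1
    csum = np.cumsum(onehot, axis=0)
    lo = np.clip(np.arange(n) - h, 0, n)
    hi = np.clip(np.arange(n) + h + 1, 0, n)
    counts = csum[hi] - csum[lo]
    maxc = counts.max(axis=1, keepdims=True)
    is_max = counts == maxc
    out = np.argmax(is_max, axis=1)  # first class in order among the tied
    own_tied = is_max[np.arange(n), codes]
    out[own_tied] = codes[own_tied]
    return out


def _runs_to_segments(pos: np.ndarray, codes: np.ndarray) -> list[list]:
    segs: list[list] = []  # [start_i, end_i, code] as site indices
    start = 0
    for i in range(1, len(codes) + 1):
        if i == len(codes) or codes[i] != codes[start]:
            segs.append([start, i - 1, codes[start]])
            start = i
    return segs


def _absorb_small(segs: list[list], min_sites: int) -> list[list]:
    """Merge segments spanning fewer than ``min_sites`` into the longer neighbor."""

    def n_sites(s: list) -> int:
        return s[1] - s[0] + 1

    changed = True
    while changed and len(segs) > 1:
        changed = False
        sizes = [n_sites(s) for s in segs]
        order = sorted(range(len(segs)), key=lambda i: (sizes[i], i))
        for i in order:
            if sizes[i] >= min_sites:
                continue
            left = segs[i - 1] if i > 0 else None
            right = segs[i + 1] if i < len(segs) - 1 else None
            if left is None and right is None:
                continue
            if right is None or (left is not None and n_sites(left) >= n_sites(right)):
                target = left
            else:
                target = right
            segs[i][2] = target[2]
            # merge adjacent equal-class runs
            merged: list[list] = []
            for s in segs:
                if merged and merged[-1][2] == s[2]:
                    merged[-1][1] = s[1]
                else:
                    merged.append(s)
            segs = merged
            changed = True
            break
    return segs


def smooth_track(track: AncestryTrack, window: int = 101, min_sites: int = 10) -> AncestryTrack:
    """Smooth a graphical genotype into ancestry segments.

    Each site's class is replaced by the majority class in a centered
    window of ``window`` sites (clipped at chromosome ends); runs of
    identical smoothed class are merged into segments, and segments with
    fewer than ``min_sites`` sites are absorbed into the longer
    neighbor.  Smoothing a track whose segments are all longer than the
    window is a no-op (idempotence).
    """
    if window < 1 or window % 2 == 0:
        raise ArgumentError("window must be an odd integer >= 1")
    if min_sites < 1:
        raise ArgumentError("min_sites must be >= 1")
    if track.n_sites == 0:
        return replace(track, segments=())
    code_of = {c: k for k, c in enumerate(_CLASS_ORDER)}
    try:
        codes = np.array([code_of[c] for c in track.classes], dtype=np.int64)
    except KeyError as exc:
        raise ArgumentError(f"unknown class label {exc.args[0]!r}") from None
    smoothed = _majority_smooth(codes, window) if window > 1 else codes
    segs = _absorb_small(_runs_to_segments(track.pos, smoothed), min_sites)
    segments = tuple(
        Segment(
            start=int(track.pos[s0]),
            end=int(track.pos[s1]),
            cls=_CLASS_ORDER[code],
            n_sites=s1 - s0 + 1,
        )
        for s0, s1, code in segs
    )
    return replace(track, segments=segments)


def count_segments(tracks: "list[AncestryTrack]") -> pd.DataFrame:
    """Per-chromosome segment counts with a min/median/max summary.

    Returns a frame with one row per chromosome (columns ``chrom``,
    ``n_segments``) whose ``attrs['summary']`` holds the genome summary.
    """
    for t in tracks:
        if t.segments is None:
            raise DataError(f"track {t.chrom} is unsmoothed; call smooth_track first")
    df = pd.DataFrame(
        {"chrom": [t.chrom for t in tracks], "n_segments": [len(t.segments) for t in tracks]}
    )
    counts = df["n_segments"].to_numpy()
    df.attrs["summary"] = {
        "min": int(counts.min()) if len(counts) else 0,
        "median": float(np.median(counts)) if len(counts) else 0.0,
        "max": int(counts.max()) if len(counts) else 0,
    }
    return df


def segments_to_bed(tracks: "list[AncestryTrack]") -> str:
    """Smoothed segments as BED (0-based half-open), class in col 4, n_sites in col 5."""
    lines = []
    for t in tracks:
        if t.segments is None:
            raise DataError(f"track {t.chrom} is unsmoothed; call smooth_track first")
        for s in t.segments:
            lines.append(f"{t.chrom}\t{s.start - 1}\t{s.end}\t{s.cls}\t{s.n_sites}")
    return "\n".join(lines) + ("\n" if lines else "")


def classes_to_bedgraph(tracks: "list[AncestryTrack]") -> str:
    """Per-site classes as a bedGraph-style 4-column text (0-based half-open)."""
    lines = []
    for t in tracks:
        for p, c in zip(t.pos, t.classes):
            lines.append(f"{t.chrom}\t{p - 1}\t{p}\t{c}")
    return "\n".join(lines) + ("\n" if lines else "")
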