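"""Cryptic transcript-end calling from per-base RNA coverage.

Coverage is normalised by the mean of the per-gene counts (x a fixed
scale), tumour-specific expression peaks are flagged by comparing mean
coverage across samples, the polyadenylation signal motif is located on
the transcribed strand, and the cleavage site is placed 10-30 bp downstream
of a motif at the candidate with the greatest coverage drop, measured as a
two-sided mean difference over a surrounding window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .io_formats import CoverageTrack, GenomicInterval, Parameters


@dataclass(frozen=True)
class PolyACall:
    """A called cleavage/polyadenylation site.

    ``cleavage_site`` is the first genomic position past the transcript end
    (0-based half-open convention: transcribed bases end just before it).
    """

    motif_site: int
    cleavage_site: int
    offset: int  # bp downstream of the motif end
    drop_magnitude: float
    segment_means: tuple[float, float, float] | None = None


def normalise_coverage(
    raw: CoverageTrack,
    gene_counts: Mapping[str, float] | pd.Series,
    norm_scale: float = 1e3,
) -> CoverageTrack:
    """Divide coverage by the mean per-gene count and rescale.

    values' = values / mean(counts) * norm_scale; the applied factor is
    recorded in ``norm_factor`` so the transform is invertible.
    """
    counts = pd.Series(dict(gene_counts)) if not isinstance(gene_counts, pd.Series) else gene_counts
    if len(counts) == 0:
        raise AnalysisError("empty gene-count table")
    mean = float(counts.mean())
    if mean <= 0:
        raise AnalysisError("mean gene count is zero; sample unusable")
    factor = norm_scale / mean
    return CoverageTrack(raw.region, raw.values * factor, norm_factor=factor)


def detect_peak(
    tracks: Mapping[str, CoverageTrack],
    region: GenomicInterval,
    fold_threshold: float = 5.0,
    background_floor: float = 1.0,
) -> list[str]:
    """Samples whose mean coverage over ``region`` stands out.

    A sample is flagged iff its mean normalised coverage is at least
    ``fold_threshold`` times the background, taken as the *median* of the
    other samples' means (robust to a second carrier in the cohort) and
    floored at ``background_floor`` normalised units.
    """
    if len(tracks) < 2:
        raise AnalysisError("peak detection needs at least 2 samples")
    means = {
        s: float(np.mean(t.slice_values(region.start, region.end)))
        for s, t in tracks.items()
    }
    flagged = []
    for s, m in means.items():
        others = [v for k, v in means.items() if k != s]
        background = max(background_floor, float(np.median(others)))
        if m >= fold_threshold * background:
            flagged.append(s)
    return sorted(flagged)


def scan_polya_motifs(seq: str, motif: str = "AATAAA") -> list[int]:
    """All (possibly overlapping) exact motif start offsets in ``seq``.

    ``seq`` must already be the transcribed strand of the fusion.
    """
    out = []
    i = seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)
    return out


def _drop(values: np.ndarray, idx: int, half_window: int) -> float:
    """Mean coverage upstream minus downstream of an array index, windows
    clipped to the track."""
    up = values[max(0, idx - half_window):idx]
    down = values[idx:idx + half_window]
    if len(up) == 0 or len(down) == 0:
        return float("-inf")
    return float(np.mean(up) - np.mean(down))


def call_cleavage_site(
    track: CoverageTrack,
    motifs: Sequence[int],
    params: Parameters | None = None,
) -> PolyACall | None:
    """Place the transcript end at the greatest coverage drop.

    For every motif (genomic start positions) and every candidate end
    ``c`` in [motif_end + offset_min, motif_end + offset_max], the drop is
    the mean coverage over the ``drop_window``/2 bases before ``c`` minus
    the mean over the ``drop_window``/2 bases from ``c`` on. The maximising
    (motif, candidate) wins; ties break toward the smallest offset, then
    the most 5' motif. Returns None when there is no motif or no positive
    drop.
    """
    params = params or Parameters()
    if not motifs:
        return None
    w = params.drop_window // 2
    motif_len = len(params.polya_motif)
    best: tuple[float, int, int] | None = None  # (drop, offset, motif)
    for m in sorted(motifs):
        motif_end = m + motif_len
        for offset in range(params.cleavage_offset_min, params.cleavage_offset_max + 1):
            c = motif_end + offset
            if not track.region.contains(c):
                continue
            d = _drop(track.values, c - track.region.start, w)
            if best is None or d > best[0]:
                best = (d, offset, m)
    if best is None or best[0] <= 0:
        return None
    drop, offset, m = best
    return PolyACall(
        motif_site=m,
        cleavage_site=m + motif_len + offset,
        offset=offset,
        drop_magnitude=drop,
    )


def segment_means(
    track: CoverageTrack, break_position: int, cleavage_site: int
) -> tuple[float, float, float]:
    """(5' flank, transcript segment, 3' flank) mean coverages.

    The middle segment spans [break, cleavage); the flanks are adjacent
    ranges of equal length, clipped at the track edges.
    """
    if cleavage_site <= break_position:
        raise AnalysisError("cleavage site must lie 3' of the break position")
    length = cleavage_site - break_position
    middle = track.slice_values(break_position, cleavage_site)
    flank5 = track.slice_values(break_position - length, break_position)
    flank3 = track.slice_values(cleavage_site, cleavage_site + length)
    if len(middle) == 0:
        raise AnalysisError("transcript segment outside coverage track")

    def mean(a: np.ndarray) -> float:
        return float(np.mean(a)) if len(a) else float("nan")

    return (mean(flank5), mean(middle), mean(flank3))


__all__ = [
    "PolyACall",
    "normalise_coverage",
    "detect_peak",
    "scan_polya_motifs",
    "call_cleavage_site",
    "segment_means",
]
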