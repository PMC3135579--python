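"""Center-aligned metagene profiles of coverage and sequence content.

Every pre-miRNA contributes one 2,000-nt window centred on the midpoint of
its genomic sequence; position zero is the centre, downstream positions are
plus and upstream minus (minus-strand features are flipped into transcript
orientation). Coverage windows are smoothed by assigning each 10-nt sliding
window the mean of the per-base scores in the 140 nt surrounding it.

Sequence content at position i is the fraction N/T over the 100-nt window
around i, where N counts the matching nucleotides (G or C for GC content)
and T the total counted nucleotides; dinucleotide variants count
overlapping 2-mers ({GC, CG} or {AT, TA}) instead. Ambiguous bases (N) are
excluded from both N and T; a window with no countable positions yields a
missing value (NaN).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .genomic_io import CoverageTrack, GenomicInterval, GenomeSequence

CONTENT_PATTERNS = ("gc", "at", "gc_dinucleotide", "at_dinucleotide")


@dataclass(frozen=True)
class ProfileParams:
    """Window geometry and smoothing parameters, in nucleotides."""

    window_width: int = 2000
    core_width: int = 400
    slide_step: int = 10
    smooth_span: int = 140
    content_window: int = 100
    strand_flip: bool = True

    def __post_init__(self) -> None:
        for name in ("window_width", "core_width", "slide_step",
                     "smooth_span", "content_window"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.smooth_span < self.slide_step:
            raise ValidationError("smooth_span must be >= slide_step")
        if self.window_width % 2 != 0:
            raise ValidationError("window_width must be even")
        if self.window_width % self.slide_step != 0:
            raise ValidationError("window_width must be divisible by slide_step")


@dataclass
class MetaProfile:
    """Per-feature smoothed windows and their column-mean profile."""

    offsets: np.ndarray
    matrix: np.ndarray  # one row per feature
    n_features: int = field(init=False)
    mean: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[1] != self.offsets.size:
            raise ValidationError("matrix width must match offsets length")
        self.n_features = self.matrix.shape[0]
        # content profiles carry NaN at undefined positions; ignore them
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self.mean = np.nanmean(self.matrix, axis=0)


def center_of(interval: GenomicInterval) -> int:
    """Midpoint of the interval, floor of (start+end)/2."""
    return (interval.start + interval.end) // 2


def extract_window(
    track: CoverageTrack,
    chrom: str,
    center: int,
    strand: str = "+",
    params: ProfileParams = ProfileParams(),
) -> np.ndarray:
    """Per-base scores over the window_width window around ``center``.

    Positions outside the covered chromosome are zero-filled. Minus-strand
    features return the reversed vector so that downstream = plus in
    transcript orientation (disable via ``params.strand_flip``).
    """
    if chrom not in track:
        raise ValidationError(f"chromosome {chrom!r} not present in track")
    half = params.window_width // 2
    values = track.get(chrom, center - half, center + half)
    if strand == "-" and params.strand_flip:
        values = values[::-1]
    return values


def window_offsets(params: ProfileParams = ProfileParams()) -> np.ndarray:
    """Offsets (relative to the feature centre) of each sliding window.

    Each 10-nt sliding window is represented by its own centre, so the
    offsets run symmetrically from -(w/2 - step/2) to +(w/2 - step/2).
    """
    half = params.window_width // 2
    centers = np.arange(0, params.window_width, params.slide_step) + params.slide_step / 2
    return centers - half


def smooth_profile(
    vector: np.ndarray, params: ProfileParams = ProfileParams()
) -> np.ndarray:
    """Boxcar-smooth a per-base window into per-sliding-window values.

    The value of the sliding window centred at c is the mean of the
    per-base scores in [c - span/2, c + span/2), truncated at the vector
    bounds (the mean is taken over the available positions only).
    """
    vector = np.asarray(vector, dtype=float)
    if vector.size == 0:
        raise ValidationError("cannot smooth an empty vector")
    if vector.size % params.slide_step != 0:
        raise ValidationError("vector length must be divisible by slide_step")
    half_span = params.smooth_span / 2
    centers = np.arange(0, vector.size, params.slide_step) + params.slide_step / 2
    los = np.maximum(np.ceil(centers - half_span).astype(int), 0)
    his = np.minimum(np.ceil(centers + half_span).astype(int), vector.size)
    csum = np.concatenate(([0.0], np.cumsum(vector)))
    return (csum[his] - csum[los]) / (his - los)


def mean_profile(
    features: list[tuple[str, int, str]],
    track: CoverageTrack,
    params: ProfileParams = ProfileParams(),
) -> MetaProfile:
    """Smoothed metaprofile over (chrom, center, strand) feature tuples."""
    if not features:
        raise ValidationError("mean_profile requires at least one feature")
    rows = [
        smooth_profile(extract_window(track, chrom, center, strand, params), params)
        for chrom, center, strand in features
    ]
    return MetaProfile(offsets=window_offsets(params), matrix=np.vstack(rows))


def annotation_profile(annotations, track, params: ProfileParams = ProfileParams()):
    """mean_profile over MiRNAAnnotation objects (convenience wrapper)."""
    features = [
        (a.locus.chrom, center_of(a.locus), a.locus.strand) for a in annotations
    ]
    return mean_profile(features, track, params)


def sequence_content(seq: str, pattern: str) -> float:
    """Fractional content N/T of a sequence for one of the four patterns.

    Mononucleotide patterns count matching bases over all unambiguous
    bases; dinucleotide patterns count matching overlapping 2-mers over
    all fully unambiguous 2-mers. Returns NaN when T = 0.
    """
    seq = seq.upper()
    if pattern == "gc":
        t = sum(seq.count(b) for b in "ACGT")
        n = seq.count("G") + seq.count("C")
    elif pattern == "at":
        t = sum(seq.count(b) for b in "ACGT")
        n = seq.count("A") + seq.count("T")
    elif pattern in ("gc_dinucleotide", "at_dinucleotide"):
        targets = ("GC", "CG") if pattern == "gc_dinucleotide" else ("AT", "TA")
        n = t = 0
        for i in range(len(seq) - 1):
            pair = seq[i : i + 2]
            if pair[0] in "ACGT" and pair[1] in "ACGT":
                t += 1
                if pair in targets:
                    n += 1
    else:
        raise ValidationError(
            f"unknown content pattern {pattern!r}; expected one of {CONTENT_PATTERNS}"
        )
    return n / t if t > 0 else float("nan")


def _base_indicators(seq: str, pattern: str) -> tuple[np.ndarray, np.ndarray]:
    """(match, countable) indicator arrays used for rolling content."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    is_base = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    if pattern in ("gc", "at"):
        letters = b"GC" if pattern == "gc" else b"AT"
        match = np.isin(arr, np.frombuffer(letters, dtype=np.uint8))
        return match.astype(float), is_base.astype(float)
    first, second = (b"GC", b"CG") if pattern == "gc_dinucleotide" else (b"AT", b"TA")
    a, b = arr[:-1], arr[1:]
    countable = is_base[:-1] & is_base[1:]
    match = ((a == first[0]) & (b == first[1])) | ((a == second[0]) & (b == second[1]))
    return match.astype(float), countable.astype(float)


def rolling_content(seq: str, pattern: str, window: int) -> np.ndarray:
    """Content score at every position i of ``seq``: N/T over [i-w/2, i+w/2).

    Windows are truncated at the sequence bounds; positions whose window
    holds no countable nucleotides are NaN. Dinucleotide 2-mers are
    attributed to the position of their first base.
    """
    if window <= 0:
        raise ValidationError("content window must be positive")
    match, countable = _base_indicators(seq, pattern)
    half = window // 2
    n_pos = len(seq)
    m_csum = np.concatenate(([0.0], np.cumsum(match)))
    c_csum = np.concatenate(([0.0], np.cumsum(countable)))
    idx = np.arange(n_pos)
    los = np.clip(idx - half, 0, match.size)
    his = np.clip(idx + window - half, 0, match.size)
    n = m_csum[his] - m_csum[los]
    t = c_csum[his] - c_csum[los]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(t > 0, n / np.where(t > 0, t, 1), np.nan)
    return out


def content_profile(
    sequences: GenomeSequence,
    chrom: str,
    center: int,
    strand: str = "+",
    pattern: str = "gc",
    params: ProfileParams = ProfileParams(),
) -> np.ndarray:
    """Per-position content over the window_width window around ``center``.

    Content is always computed on the + genome strand (GC/AT content is
    strand-symmetric and both dinucleotide sets are reverse-complement
    closed); minus-strand features only reverse the positional axis.
    Positions whose content window falls entirely outside the chromosome
    are NaN.
    """
    if pattern not in CONTENT_PATTERNS:
        raise ValidationError(f"unknown content pattern {pattern!r}")
    half = params.window_width // 2
    pad = params.content_window  # enough flank for every rolling window
    lo = center - half - pad
    hi = center + half + pad
    seq = sequences.fetch_padded(chrom, lo, hi)
    scores = rolling_content(seq, pattern, params.content_window)
    values = scores[pad : pad + params.window_width]
    if strand == "-" and params.strand_flip:
        values = values[::-1]
    return values


def content_metaprofile(
    annotations,
    sequences: GenomeSequence,
    pattern: str,
    params: ProfileParams = ProfileParams(),
) -> MetaProfile:
    """Per-base content metaprofile over annotated loci (NaN-aware mean)."""
    if not annotations:
        raise ValidationError("content_metaprofile requires at least one feature")
    rows = []
    for ann in annotations:
        locus = ann.locus
        rows.append(
            content_profile(
                sequences, locus.chrom, center_of(locus), locus.strand, pattern, params
            )
        )
    half = params.window_width // 2
    return MetaProfile(offsets=np.arange(-half, half), matrix=np.vstack(rows))
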