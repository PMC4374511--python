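"""Punctum calling and synaptic-enrichment quantification on line scans.

Two per-animal statistics are computed from a 1D cord profile:

* **PN (puncta number)** — the count of called puncta in the analysis
  window. A candidate peak is a punctum when its peak punctal fluorescence
  (PF) divided by the average inter-punctal fluorescence (IPF) is at least
  the ratio threshold (default 2, inclusive).
* **SE (synaptic enrichment)** — total PF / total IPF inside a centered
  analysis window (default 100 µm), i.e. the summed intensity inside
  punctum extents over the summed intensity between them.

PF and IPF regions are mutually defining: the IPF baseline is the mean of
samples *outside* punctum extents, but which candidates count as puncta
depends on that baseline. ``call_puncta`` resolves this with a fixed-point
iteration that starts from all candidates and discards sub-threshold ones;
removals move bright samples into the IPF pool, which can only raise the
baseline, so the punctal set shrinks monotonically and the loop terminates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .profiles import IntensityProfile

__all__ = [
    "QuantParams",
    "Candidate",
    "Punctum",
    "ProfileQuant",
    "FullyMaskedError",
    "detect_candidates",
    "punctum_extent",
    "call_puncta",
    "synaptic_enrichment",
    "quantify_animal",
]


class FullyMaskedError(ValueError):
    """Raised when every sample of a profile is excluded."""


@dataclass(frozen=True)
class QuantParams:
    """Tunable parameters of the punctum-calling procedure.

    ratio_threshold
        Minimum peak-PF / average-IPF ratio for a punctum (inclusive).
    window_length_um
        Length of the centered analysis window for PN and SE.
    min_separation_um
        Candidate peaks closer than this keep only the higher one
        (suppresses sampling-noise duplicates on one physical punctum).
    min_prominence
        Minimum topographic prominence of a candidate peak (AU); 0 leaves
        the ratio rule as the only filter.
    extent_rule
        How punctum boundaries are drawn; only ``"half_max"`` is defined:
        the maximal contiguous run around the peak strictly above the
        midpoint between peak intensity and the IPF baseline.
    max_iterations
        Cap on fixed-point sweeps in :func:`call_puncta`.
    window_offset_um
        Shift of the analysis window from the profile midpoint.
    smooth_window_um
        Optional moving-average width applied before detection; 0 = off.
    subtract_offset
        Constant camera offset subtracted before ratio computation; 0 = off
        (ratios are computed on raw intensities by default).
    """

    ratio_threshold: float = 2.0
    window_length_um: float = 100.0
    min_separation_um: float = 1.0
    min_prominence: float = 0.0
    extent_rule: str = "half_max"
    max_iterations: int = 50
    window_offset_um: float = 0.0
    smooth_window_um: float = 0.0
    subtract_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.ratio_threshold <= 1:
            raise ValueError("ratio_threshold must exceed 1")
        if self.window_length_um <= 0:
            raise ValueError("window_length_um must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.extent_rule != "half_max":
            raise ValueError(f"unknown extent_rule {self.extent_rule!r}")


@dataclass(frozen=True)
class Candidate:
    """A local-maximum candidate peak (pre-ratio-rule)."""

    index: int
    position_um: float
    intensity: float
    prominence: float


@dataclass(frozen=True)
class Punctum:
    """One called synaptic punctum.

    ``extent_idx`` is the half-open sample-index interval of the punctum;
    ``extent_um`` reports the µm coordinates of its first and last samples.
    ``ratio`` is peak intensity over the converged IPF baseline.
    """

    peak_position_um: float
    peak_intensity: float
    extent_um: tuple[float, float]
    extent_idx: tuple[int, int]
    ratio: float


@dataclass
class ProfileQuant:
    """Per-animal quantification result."""

    pn: int
    se: float
    total_pf: float
    total_ipf: float
    avg_ipf: float
    window_um: tuple[float, float]
    flags: set[str] = field(default_factory=set)
    puncta: list[Punctum] = field(default_factory=list)


def _working_intensities(profile: IntensityProfile, params: QuantParams) -> np.ndarray:
    y = profile.intensities.astype(float)
    if params.subtract_offset:
        y = np.clip(y - params.subtract_offset, 0.0, None)
    if params.smooth_window_um > 0:
        w = max(1, int(round(params.smooth_window_um / profile.spacing_um)))
        if w > 1:
            kernel = np.ones(w) / w
            y = np.convolve(y, kernel, mode="same")
    return y


def _unmasked_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of unmasked samples."""
    runs = []
    n = mask.size
    i = 0
    while i < n:
        if not mask[i]:
            j = i
            while j < n and not mask[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def detect_candidates(profile: IntensityProfile, params: QuantParams) -> list[Candidate]:
    """All unmasked local maxima surviving prominence and separation filters.

    Local maxima are interior samples strictly above their nearest differing
    neighbours; a flat plateau reports its center sample. Masked stretches
    act as profile boundaries. Of any pair of candidates closer than
    ``min_separation_um`` only the higher survives (ties keep the leftmost).
    """
    mask = profile.exclude_mask
    if mask.all():
        raise FullyMaskedError("every sample of the profile is masked")
    y = _working_intensities(profile, params)

    raw: list[Candidate] = []
    for start, stop in _unmasked_runs(mask):
        seg = y[start:stop]
        if seg.size < 3:
            continue
        peaks, props = find_peaks(seg, prominence=0.0)
        for p, prom in zip(peaks, props["prominences"]):
            if prom >= params.min_prominence:
                idx = start + int(p)
                raw.append(
                    Candidate(
                        index=idx,
                        position_um=float(profile.positions_um[idx]),
                        intensity=float(seg[p]),
                        prominence=float(prom),
                    )
                )

    # minimum separation: of any pair closer than min_separation_um only the
    # higher survives (ties keep the leftmost); a peak with any dominating
    # neighbour is removed even if that neighbour is itself removed, which
    # suppresses chains of noise maxima on the shoulders of a tall punctum
    def dominated(c: Candidate) -> bool:
        for o in raw:
            if o is c or abs(o.position_um - c.position_um) >= params.min_separation_um:
                continue
            if o.intensity > c.intensity or (
                o.intensity == c.intensity and o.position_um < c.position_um
            ):
                return True
        return False

    kept = [c for c in raw if not dominated(c)]
    kept.sort(key=lambda c: c.index)
    return kept


def _extent_indices(
    y: np.ndarray, mask: np.ndarray, peak_idx: int, avg_ipf: float
) -> tuple[int, int]:
    """Half-open index extent of the punctum at ``peak_idx``.

    Half-max rule: extend from the peak over neighbours strictly above the
    level midway between the IPF baseline and the peak intensity, stopping
    at masked samples. A peak not above the baseline gets the minimum
    one-sample extent.
    """
    level = avg_ipf + (y[peak_idx] - avg_ipf) / 2.0
    i0 = peak_idx
    while i0 > 0 and not mask[i0 - 1] and y[i0 - 1] > level:
        i0 -= 1
    i1 = peak_idx + 1
    n = y.size
    while i1 < n and not mask[i1] and y[i1] > level:
        i1 += 1
    return i0, i1


def punctum_extent(
    profile: IntensityProfile, peak_index: int, avg_ipf: float, params: QuantParams | None = None
) -> tuple[float, float]:
    """µm extent of a single punctum around ``peak_index`` (half-max rule)."""
    params = params or QuantParams()
    y = _working_intensities(profile, params)
    i0, i1 = _extent_indices(y, profile.exclude_mask, peak_index, avg_ipf)
    return float(profile.positions_um[i0]), float(profile.positions_um[i1 - 1])


def _extents_for_set(
    y: np.ndarray, mask: np.ndarray, peak_indices: list[int], avg_ipf: float
) -> list[tuple[int, int]]:
    """Disjoint half-open extents for an ordered set of peaks.

    Raw half-max extents of neighbouring peaks may overlap; overlaps are
    split at the lowest sample between the two peaks (leftmost on ties),
    which is assigned to the right-hand punctum.
    """
    extents = [_extent_indices(y, mask, p, avg_ipf) for p in peak_indices]
    for k in range(1, len(extents)):
        (a0, a1), (b0, b1) = extents[k - 1], extents[k]
        if b0 < a1:
            lo, hi = peak_indices[k - 1], peak_indices[k]
            m = lo + 1 + int(np.argmin(y[lo + 1 : hi])) if hi > lo + 1 else hi
            extents[k - 1] = (a0, m)
            extents[k] = (m, b1)
    return extents


def _punctal_mask(n: int, extents: list[tuple[int, int]]) -> np.ndarray:
    punctal = np.zeros(n, dtype=bool)
    for i0, i1 in extents:
        punctal[i0:i1] = True
    return punctal


def _converged_ipf(
    y: np.ndarray,
    mask: np.ndarray,
    peak_indices: list[int],
    rel_tol: float = 1e-12,
    max_iter: int = 100,
) -> tuple[float, list[tuple[int, int]]]:
    """Average IPF implied by a fixed punctum membership.

    Extents depend on the baseline and vice versa; at fixed membership the
    baseline sequence started from the global unmasked mean decreases
    monotonically (a lower baseline widens extents, which removes bright
    shoulder samples from the pool) and is bounded below, so this inner
    fixed point converges. Returns NaN if no inter-punctal sample remains.
    """
    avg = float(y[~mask].mean())
    extents = _extents_for_set(y, mask, peak_indices, avg)
    for _ in range(max_iter):
        outside = ~mask & ~_punctal_mask(y.size, extents)
        if not outside.any():
            return float("nan"), extents
        new = float(y[outside].mean())
        if abs(new - avg) <= rel_tol * max(1.0, abs(avg)):
            return new, extents
        avg = new
        extents = _extents_for_set(y, mask, peak_indices, avg)
    return avg, extents


def call_puncta(
    profile: IntensityProfile, params: QuantParams | None = None
) -> tuple[list[Punctum], float, set[str]]:
    """Call puncta by the peak-PF / average-IPF ratio rule.

    Fixed-point procedure: start with every candidate punctal; each sweep
    first converges the extent/baseline coupling for the current membership
    (see :func:`_converged_ipf`), then drops candidates whose peak/IPF
    ratio falls below the threshold (inclusive ``>=`` keeps a ratio exactly
    at threshold). Removals return bright extent samples to the
    inter-punctal pool and can only raise the baseline, so membership
    shrinks monotonically and the loop stops when it is unchanged — at the
    maximal set whose members all satisfy the ratio rule against the
    baseline that set itself implies.

    Returns the converged puncta, the final average IPF, and any flags
    (``zero_ipf`` when no inter-punctal sample remains, ``not_converged``
    when the iteration cap was hit).
    """
    params = params or QuantParams()
    candidates = detect_candidates(profile, params)
    mask = profile.exclude_mask
    y = _working_intensities(profile, params)
    flags: set[str] = set()
    unmasked = ~mask

    if not candidates:
        avg_ipf = float(y[unmasked].mean())
        return [], avg_ipf, flags

    active = list(range(len(candidates)))
    extents: list[tuple[int, int]] = []
    avg_ipf = float(y[unmasked].mean())
    for _ in range(params.max_iterations):
        avg_ipf, extents = _converged_ipf(y, mask, [candidates[i].index for i in active])
        if not np.isfinite(avg_ipf):
            flags.add("zero_ipf")
            break
        new_active = [
            i for i in active if candidates[i].intensity / avg_ipf >= params.ratio_threshold
        ]
        if new_active == active:
            break
        active = new_active
    else:
        flags.add("not_converged")
    if len(extents) != len(active):
        extents = _extents_for_set(
            y, mask, [candidates[i].index for i in active], avg_ipf if np.isfinite(avg_ipf) else 0.0
        )

    puncta = []
    for i, (i0, i1) in zip(active, extents):
        c = candidates[i]
        ratio = c.intensity / avg_ipf if np.isfinite(avg_ipf) and avg_ipf > 0 else float("inf")
        puncta.append(
            Punctum(
                peak_position_um=c.position_um,
                peak_intensity=c.intensity,
                extent_um=(
                    float(profile.positions_um[i0]),
                    float(profile.positions_um[i1 - 1]),
                ),
                extent_idx=(i0, i1),
                ratio=float(ratio),
            )
        )
    return puncta, avg_ipf, flags


def synaptic_enrichment(
    profile: IntensityProfile,
    puncta: list[Punctum],
    params: QuantParams | None = None,
    extra_flags: set[str] | None = None,
) -> ProfileQuant:
    """Compute PN and SE = total PF / total IPF in the analysis window.

    The window is centered on the profile midpoint (plus any configured
    offset); a profile shorter than the window is used whole and flagged
    ``window_truncated``. Total PF sums unmasked intensities inside punctum
    extents within the window, total IPF those outside; PN counts puncta
    whose peak lies in the window. With zero puncta SE is reported as 0 with
    the ``no_puncta`` flag; with zero IPF it is undefined (NaN, ``zero_ipf``).
    """
    params = params or QuantParams()
    flags = set(extra_flags or ())
    pos = profile.positions_um
    mask = profile.exclude_mask
    y = _working_intensities(profile, params)

    center = (pos[0] + pos[-1]) / 2.0 + params.window_offset_um
    half = params.window_length_um / 2.0
    lo, hi = center - half, center + half
    if profile.span_um < params.window_length_um - profile.spacing_um / 2.0:
        flags.add("window_truncated")
        lo, hi = pos[0], pos[-1]
    in_window = (pos >= lo) & (pos <= hi)
    if not in_window.any():
        raise ValueError("analysis window contains no samples")

    punctal = _punctal_mask(len(profile), [p.extent_idx for p in puncta])
    usable = in_window & ~mask
    if not usable.any():
        flags.add("all_masked")
    total_pf = float(y[usable & punctal].sum())
    total_ipf = float(y[usable & ~punctal].sum())
    pn = sum(1 for p in puncta if lo <= p.peak_position_um <= hi)

    if pn == 0:
        se = 0.0
        flags.add("no_puncta")
    elif total_ipf == 0:
        se = float("nan")
        flags.add("zero_ipf")
    else:
        se = total_pf / total_ipf

    out_full = ~mask & ~punctal
    avg_ipf = float(y[out_full].mean()) if out_full.any() else float("nan")

    return ProfileQuant(
        pn=pn,
        se=se,
        total_pf=total_pf,
        total_ipf=total_ipf,
        avg_ipf=avg_ipf,
        window_um=(float(lo), float(hi)),
        flags=flags,
        puncta=[p for p in puncta if lo <= p.peak_position_um <= hi],
    )


def quantify_animal(
    profile: IntensityProfile, params: QuantParams | None = None
) -> ProfileQuant:
    """Full per-animal quantification: detect, call, and score one profile."""
    params = params or QuantParams()
    if profile.exclude_mask.all():
        return ProfileQuant(
            pn=0,
            se=float("nan"),
            total_pf=0.0,
            total_ipf=0.0,
            avg_ipf=float("nan"),
            window_um=(float(profile.positions_um[0]), float(profile.positions_um[-1])),
            flags={"all_masked"},
        )
    puncta, _, call_flags = call_puncta(profile, params)
    return synaptic_enrichment(profile, puncta, params, extra_flags=call_flags)
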