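"""Normalized read-depth deconvolution of a two-strain endosymbiont mixture.

A host doubly infected by two closely related *Wolbachia* strains yields a
single pooled read set.  Aligned to the assembly of one strain (the
"reference" strain), genomic intervals private to that strain are sequenced
only from its cells, so their depth relative to the shared backbone
estimates the strain's titer fraction *f* — the proportion of all symbiont
cells that belong to it.  True copy-number changes leave a different
signature: a k -> k-1 loss produces *k* paired intervals at depth (k-1)/k.

The pipeline is: per-base depth -> normalized sliding windows
(:func:`windowed_normalized_depth`) -> run-based segmentation of depressed /
elevated windows (:func:`segment_regions`) -> rule-based hypothesis labels
(:func:`classify_regions`) -> titer estimate with a bootstrap interval
(:func:`estimate_titer`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DepthTrack",
    "WindowTrack",
    "RegionCall",
    "TiterEstimate",
    "expected_depth_cnv",
    "expected_depth_private",
    "windowed_normalized_depth",
    "segment_regions",
    "classify_regions",
    "estimate_titer",
]

#: small-integer copy-number losses considered by the classifier: k -> k-1
_CNV_LOSS_KS = (2, 3, 4)


def expected_depth_cnv(copies_reference: int, copies_sample: int) -> float:
    """Expected normalized depth of a region whose copy number changed.

    Under uniform coverage a region present in ``copies_sample`` copies,
    against a baseline of ``copies_reference`` copies in the reference,
    sequences at depth ``copies_sample / copies_reference`` relative to
    single-copy backbone.  A 2 -> 1 loss therefore sits at 0.5, a 3 -> 2
    loss at 2/3.
    """
    if copies_reference <= 0:
        raise ValueError("reference copy number must be positive")
    if copies_sample < 0:
        raise ValueError("sample copy number must be non-negative")
    return copies_sample / copies_reference


def expected_depth_private(titer: float) -> float:
    """Expected normalized depth of a strain-private region.

    If the strain carrying the region makes up a fraction ``titer`` of all
    symbiont cells, its private intervals are covered at ``titer`` times the
    depth of the shared backbone.
    """
    if not 0.0 <= titer <= 1.0:
        raise ValueError("titer must lie in [0, 1]")
    return float(titer)


@dataclass
class DepthTrack:
    """Per-base read depth over one symbiont genome."""

    genome_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 1 or self.depth.size == 0:
            raise ValueError("depth must be a non-empty 1-D array")
        if np.any(self.depth < 0):
            raise ValueError("depth values must be non-negative")

    def __len__(self) -> int:
        return int(self.depth.size)


@dataclass
class WindowTrack:
    """Sliding-window normalized depth.

    ``windows`` has columns ``start`` (1-based), ``end`` (inclusive),
    ``raw_norm_depth`` and ``capped_norm_depth``.  The genome mean is
    computed from raw per-base depth over *all* bases (including any
    trailing bases not covered by a full window), before capping.
    """

    windows: pd.DataFrame
    window_size: int
    step: int
    cap: float
    genome_mean_depth: float
    genome_id: str = ""

    def __len__(self) -> int:
        return len(self.windows)


@dataclass
class RegionCall:
    """A contiguous run of depressed or elevated windows."""

    start: int
    end: int
    mean_norm_depth: float
    n_windows: int
    direction: str  # "low" | "high"
    label: str | None = None  # cnv_loss | cnv_gain | strain_private | ambiguous
    rationale: str = ""
    member_windows: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TiterEstimate:
    """Inferred titer fraction of the strain carrying the private regions.

    ``f_hat`` estimates the fraction of symbiont cells belonging to the
    region-carrying strain; ``1 - f_hat`` is the co-infecting strain's share.
    """

    f_hat: float
    ci_low: float
    ci_high: float
    n_windows_used: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.f_hat <= self.ci_high <= 1.0):
            raise ValueError("bootstrap interval must bracket f_hat within [0, 1]")


def windowed_normalized_depth(
    track: DepthTrack,
    window_size: int = 1000,
    step: int = 500,
    cap: float = 5.0,
) -> WindowTrack:
    """Compute half-overlapping normalized depth windows.

    Windows start at 1, 1+step, 1+2*step, ... while the full window fits on
    the genome; each window's mean depth is divided by the genome-wide mean
    per-base depth.  Values are additionally capped at ``cap`` (the capped
    track is what segmentation consumes; raw values are kept for
    estimation).
    """
    if window_size < 1 or step < 1 or step > window_size:
        raise ValueError("require window_size >= step >= 1")
    depth = track.depth.astype(float)
    L = depth.size
    if L < window_size:
        raise ValueError("genome shorter than window")
    genome_mean = float(depth.mean())
    if genome_mean <= 0:
        raise ValueError("genome mean depth is zero; nothing to normalize")

    starts = np.arange(1, L - window_size + 2, step, dtype=int)
    csum = np.concatenate(([0.0], np.cumsum(depth)))
    window_means = (csum[starts - 1 + window_size] - csum[starts - 1]) / window_size
    raw = window_means / genome_mean
    windows = pd.DataFrame(
        {
            "start": starts,
            "end": starts + window_size - 1,
            "raw_norm_depth": raw,
            "capped_norm_depth": np.minimum(raw, cap),
        }
    )
    return WindowTrack(
        windows=windows,
        window_size=window_size,
        step=step,
        cap=cap,
        genome_mean_depth=genome_mean,
        genome_id=track.genome_id,
    )


def _runs_with_gaps(inband: np.ndarray, max_gap: int) -> list[np.ndarray]:
    """Indices of maximal in-band runs, bridging gaps of <= max_gap windows."""
    idx = np.flatnonzero(inband)
    if idx.size == 0:
        return []
    runs: list[list[int]] = [[int(idx[0])]]
    for i in idx[1:]:
        if int(i) - runs[-1][-1] - 1 <= max_gap:
            runs[-1].append(int(i))
        else:
            runs.append([int(i)])
    return [np.asarray(r, dtype=int) for r in runs]


def segment_regions(
    wt: WindowTrack,
    low_band: tuple[float, float] = (0.35, 0.90),
    high_band: tuple[float, float] = (1.15, math.inf),
    min_windows: int = 10,
    max_gap_windows: int = 2,
) -> list[RegionCall]:
    """Call maximal runs of windows whose capped depth falls in a band.

    Runs may be interrupted by at most ``max_gap_windows`` consecutive
    out-of-band windows and must contain at least ``min_windows`` in-band
    members.  The region interval spans the first member window's start to
    the last member window's end; its mean depth is the mean of member raw
    values (bridged gap windows are not members).
    """
    if len(wt) == 0:
        raise ValueError("window track is empty")
    capped = wt.windows["capped_norm_depth"].to_numpy()
    raw = wt.windows["raw_norm_depth"].to_numpy()
    starts = wt.windows["start"].to_numpy()
    ends = wt.windows["end"].to_numpy()

    regions: list[RegionCall] = []
    for (lo, hi), direction in ((low_band, "low"), (high_band, "high")):
        inband = (capped > lo) & (capped < hi)
        for members in _runs_with_gaps(inband, max_gap_windows):
            if members.size < min_windows:
                continue
            regions.append(
                RegionCall(
                    start=int(starts[members[0]]),
                    end=int(ends[members[-1]]),
                    mean_norm_depth=float(raw[members].mean()),
                    n_windows=int(members.size),
                    direction=direction,
                    member_windows=members,
                )
            )
    regions.sort(key=lambda r: r.start)
    return regions


def _cluster_by_level(regions: list[RegionCall], tol: float) -> list[list[RegionCall]]:
    """Group regions whose mean depths agree pairwise within tol."""
    ordered = sorted(regions, key=lambda r: r.mean_norm_depth)
    clusters: list[list[RegionCall]] = []
    for reg in ordered:
        if clusters and reg.mean_norm_depth - clusters[-1][0].mean_norm_depth <= tol:
            clusters[-1].append(reg)
        else:
            clusters.append([reg])
    return clusters


def classify_regions(
    regions: list[RegionCall],
    duplication_evidence: int = 0,
    tol: float = 0.06,
    low_band: tuple[float, float] = (0.35, 0.90),
) -> list[RegionCall]:
    """Label segmented regions under copy-number vs. strain-private hypotheses.

    Decision rules for depressed regions, applied per depth-level cluster
    (regions whose means agree pairwise within ``tol``):

    a. the cluster mean is within ``tol`` of a small-integer loss ratio
       (k-1)/k AND the cluster contains the k same-depth partner regions a
       k -> k-1 loss requires AND there is no independent duplicated-gene
       evidence of a second strain -> ``cnv_loss``;
    b. otherwise, a shared depth level inside ``low_band`` -> ``strain_private``
       (a positive ``duplication_evidence`` count — duplicated single-copy
       genes in the mixed assembly — independently supports a co-resident
       strain and overrides the copy-number reading);
    c. otherwise -> ``ambiguous``.

    Elevated regions are labelled ``cnv_gain``.  Rationale strings record
    which clause fired.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if duplication_evidence < 0:
        raise ValueError("duplication_evidence must be non-negative")

    out: list[RegionCall] = []
    lows = [r for r in regions if r.direction == "low"]
    highs = [r for r in regions if r.direction == "high"]

    for cluster in _cluster_by_level(lows, tol):
        d = float(np.mean([r.mean_norm_depth for r in cluster]))
        m = len(cluster)
        matched_k = next(
            (k for k in _CNV_LOSS_KS if abs(d - (k - 1) / k) <= tol), None
        )
        if matched_k is not None and m >= matched_k and duplication_evidence == 0:
            label = "cnv_loss"
            rationale = (
                f"mean depth {d:.3f} ~ {matched_k - 1}/{matched_k} with "
                f"{m} matching regions (clause a: {matched_k}->{matched_k - 1} loss)"
            )
        elif low_band[0] < d < low_band[1]:
            label = "strain_private"
            bits = [f"{m} region(s) share depth level {d:.3f} inside {low_band}"]
            if matched_k is not None and m < matched_k:
                bits.append(
                    f"~{matched_k - 1}/{matched_k} ratio lacks the {matched_k} "
                    f"partner regions a copy-number loss requires"
                )
            if matched_k is not None and duplication_evidence > 0:
                bits.append(
                    f"{duplication_evidence} duplicated single-copy genes "
                    "independently indicate a co-resident strain"
                )
            elif duplication_evidence > 0:
                bits.append(
                    f"strengthened by {duplication_evidence} duplicated genes"
                )
            rationale = "clause b: " + "; ".join(bits)
        else:
            label = "ambiguous"
            rationale = f"clause c: depth level {d:.3f} fits no hypothesis"
        for reg in cluster:
            out.append(replace(reg, label=label, rationale=rationale))

    for reg in highs:
        out.append(
            replace(
                reg,
                label="cnv_gain",
                rationale=f"elevated depth {reg.mean_norm_depth:.3f}",
            )
        )
    out.sort(key=lambda r: r.start)
    return out


def estimate_titer(
    regions: list[RegionCall],
    wt: WindowTrack,
    n_boot: int = 1000,
    seed: int = 42,
    ci: float = 0.95,
) -> TiterEstimate:
    """Estimate the titer fraction of the strain carrying the private regions.

    The estimate is the mean raw normalized depth over member windows of
    ``strain_private`` regions, rescaled by the mean over background windows
    (windows outside every called region) so that the depressed intervals
    are measured against "the rest of the genome" rather than the global
    mean, which they themselves depress.  The confidence interval is a
    seeded percentile bootstrap resampling private and background windows
    independently.
    """
    private = [r for r in regions if r.label == "strain_private"]
    if not private:
        raise ValueError("nothing to estimate: no strain_private regions")
    raw = wt.windows["raw_norm_depth"].to_numpy()
    members = np.unique(np.concatenate([r.member_windows for r in private]))

    in_any_region = np.zeros(len(wt), dtype=bool)
    starts = wt.windows["start"].to_numpy()
    ends = wt.windows["end"].to_numpy()
    for r in regions:
        in_any_region |= (starts >= r.start) & (ends <= r.end)
    background = np.flatnonzero(~in_any_region)
    bg_mean = float(raw[background].mean()) if background.size else 1.0

    f_hat = float(np.clip(raw[members].mean() / bg_mean, 0.0, 1.0))

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    priv_vals = raw[members]
    bg_vals = raw[background] if background.size else np.ones(1)
    for b in range(n_boot):
        p = rng.choice(priv_vals, size=priv_vals.size, replace=True).mean()
        g = rng.choice(bg_vals, size=bg_vals.size, replace=True).mean()
        boots[b] = p / g
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    lo = float(np.clip(min(lo, f_hat), 0.0, 1.0))
    hi = float(np.clip(max(hi, f_hat), 0.0, 1.0))
    return TiterEstimate(f_hat=f_hat, ci_low=lo, ci_high=hi, n_windows_used=int(members.size))
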