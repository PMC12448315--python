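"""Bulk-segregant genome scan over pooled allele-frequency tracks.

The scan converts per-marker pooled read counts into parent-2 (wild-type
donor) allele-frequency tracks, smooths them, and scores sliding windows
with a binomial log-likelihood ratio: the linked alternative puts the
control pool at the segregation model's expected frequency (1 at the
suppressor locus) and the mutant pool at its expectation (1/3), against
the unlinked null of 0.5 / 0.5.  Windows exceeding a permutation-calibrated
genome-wide threshold are merged into candidate regions.

The statistic is depth-weighted by construction: a marker sequenced deeper
contributes more log-likelihood, which is exactly how much evidence it
carries about the pool frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .segregation import PhenotypeModel, expected_pool_allele_frequency

__all__ = [
    "RegionCall",
    "SelectionLocusDiagnostic",
    "ScanResult",
    "select_informative_markers",
    "compute_frequency_track",
    "smooth_track",
    "window_score",
    "permutation_threshold",
    "call_regions",
    "check_selection_locus",
    "scan_genome",
]


@dataclass(frozen=True)
class RegionCall:
    """A maximal run of above-threshold windows, half-open 0-based."""

    chromosome: str
    start_bp: int
    end_bp: int
    peak_score: float
    mean_control_freq: float
    mean_mutant_freq: float

    def __post_init__(self) -> None:
        if not self.start_bp < self.end_bp:
            raise ValueError("region start must precede end")

    def contains(self, chromosome: str, pos: int) -> bool:
        return self.chromosome == chromosome and self.start_bp <= pos < self.end_bp


@dataclass(frozen=True)
class SelectionLocusDiagnostic:
    """Local pool frequencies around the selection locus vs expectation."""

    chromosome: str
    position_bp: int
    n_markers: int
    control_freq: float
    mutant_freq: float
    expected_control: float
    expected_mutant: float
    tolerance: float
    ok: bool


@dataclass
class ScanResult:
    track: pd.DataFrame
    threshold: float
    regions: list[RegionCall]
    expected_control: float
    expected_mutant: float
    exclusions: dict
    selection_diagnostic: SelectionLocusDiagnostic | None = None


def select_informative_markers(
    variant_table: pd.DataFrame, min_parent_depth: int = 10
) -> tuple[pd.DataFrame, dict]:
    """Keep biallelic sites where the parental haploid calls differ.

    Sites with a missing parental call or a parent below the depth floor
    are excluded and tallied in the returned exclusion log.  The parent-2
    read count per pool is derived from which allele parent 2 carries.
    """
    vt = variant_table
    missing = (vt["p1_gt"] < 0) | (vt["p2_gt"] < 0)
    low_depth = (vt["p1_dp"] < min_parent_depth) | (vt["p2_dp"] < min_parent_depth)
    same = vt["p1_gt"] == vt["p2_gt"]
    keep = ~missing & ~low_depth & ~same
    log = {
        "missing_parent_call": int((missing & ~low_depth).sum()),
        "low_parent_depth": int(low_depth.sum()),
        "parents_identical": int((same & ~missing & ~low_depth).sum()),
        "kept": int(keep.sum()),
    }
    if log["kept"] == 0:
        raise ValueError("no informative markers: parental genomes are not distinguishable")
    markers = vt.loc[keep].copy()
    p2_has_alt = markers["p2_gt"] == 1
    for pool in ("ctrl", "mut"):
        alt = markers[f"{pool}_alt"]
        depth = markers[f"{pool}_depth"]
        markers[f"{pool}_p2"] = np.where(p2_has_alt, alt, depth - alt)
    return markers.reset_index(drop=True), log


def compute_frequency_track(markers: pd.DataFrame, min_depth: int = 10) -> pd.DataFrame:
    """Raw parent-2 allele frequency per marker per pool.

    Markers whose depth falls below ``min_depth`` in either pool are
    flagged ``included == False`` rather than dropped.
    """
    track = markers.copy()
    for pool in ("ctrl", "mut"):
        depth = track[f"{pool}_depth"].to_numpy().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            track[f"{pool}_freq"] = np.where(
                depth > 0, track[f"{pool}_p2"] / np.maximum(depth, 1), np.nan
            )
    track["included"] = (track["ctrl_depth"] >= min_depth) & (
        track["mut_depth"] >= min_depth
    )
    track = track.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return track


def smooth_track(track: pd.DataFrame, window_markers: int = 51) -> pd.DataFrame:
    """Centered rolling median over included markers, per chromosome.

    Edge windows are truncated; excluded markers get no smoothed value.
    """
    if window_markers < 1 or window_markers % 2 == 0:
        raise ValueError("window must be an odd number of markers >= 1")
    out = track.copy()
    for pool in ("ctrl", "mut"):
        out[f"{pool}_smooth"] = np.nan
    for _, grp in out.groupby("chrom", sort=False):
        inc = grp[grp["included"]]
        if len(inc) == 0:
            continue
        if window_markers > len(inc):
            warnings.warn(
                f"smoothing window {window_markers} exceeds the {len(inc)} included "
                f"markers on {grp['chrom'].iloc[0]}; windows are truncated",
                stacklevel=2,
            )
        for pool in ("ctrl", "mut"):
            sm = (
                inc[f"{pool}_freq"]
                .rolling(window_markers, center=True, min_periods=1)
                .median()
            )
            out.loc[inc.index, f"{pool}_smooth"] = sm
    return out


def _marker_llr(
    counts: np.ndarray, depths: np.ndarray, f_expected: float, clip: float
) -> np.ndarray:
    f = float(np.clip(f_expected, clip, 1 - clip))
    return stats.binom.logpmf(counts, depths, f) - stats.binom.logpmf(counts, depths, 0.5)


def window_score(
    ctrl_counts,
    ctrl_depths,
    mut_counts,
    mut_depths,
    expected: tuple[float, float],
    clip: float = 0.01,
) -> float:
    """Binomial log-likelihood ratio of linkage vs the unlinked null.

    Sums, over the window's markers and both pools, the log-likelihood of
    the parent-2 read counts under the expected linked frequencies
    (clipped into ``[clip, 1-clip]``) minus the log-likelihood under 0.5.
    Positive values favour linkage.
    """
    ctrl_counts = np.atleast_1d(np.asarray(ctrl_counts))
    mut_counts = np.atleast_1d(np.asarray(mut_counts))
    if ctrl_counts.size == 0 or mut_counts.size == 0:
        raise ValueError("window is empty")
    ctrl_depths = np.atleast_1d(np.asarray(ctrl_depths))
    mut_depths = np.atleast_1d(np.asarray(mut_depths))
    f_ctrl, f_mut = expected
    return float(
        _marker_llr(ctrl_counts, ctrl_depths, f_ctrl, clip).sum()
        + _marker_llr(mut_counts, mut_depths, f_mut, clip).sum()
    )


def _centered_rolling_sum(x: np.ndarray, w: int) -> np.ndarray:
    """Truncated centered rolling sum along the last axis."""
    n = x.shape[-1]
    h = w // 2
    zeros = np.zeros(x.shape[:-1] + (1,))
    cs = np.concatenate([zeros, np.cumsum(x, axis=-1)], axis=-1)
    hi = np.minimum(np.arange(n) + h + 1, n)
    lo = np.maximum(np.arange(n) - h, 0)
    return cs[..., hi] - cs[..., lo]


def _marker_scores(
    track: pd.DataFrame, expected: tuple[float, float], clip: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker LLR for the observed pool orientation and the swap."""
    f_ctrl, f_mut = expected
    c_cnt = track["ctrl_p2"].to_numpy()
    c_dep = track["ctrl_depth"].to_numpy()
    m_cnt = track["mut_p2"].to_numpy()
    m_dep = track["mut_depth"].to_numpy()
    obs = _marker_llr(c_cnt, c_dep, f_ctrl, clip) + _marker_llr(m_cnt, m_dep, f_mut, clip)
    swap = _marker_llr(m_cnt, m_dep, f_ctrl, clip) + _marker_llr(c_cnt, c_dep, f_mut, clip)
    return obs, swap


def _window_scores_by_chrom(
    scores: np.ndarray, chrom_codes: np.ndarray, w: int
) -> np.ndarray:
    out = np.empty_like(scores, dtype=float)
    for code in np.unique(chrom_codes):
        sel = chrom_codes == code
        out[..., sel] = _centered_rolling_sum(scores[..., sel], w)
    return out


def permutation_threshold(
    track: pd.DataFrame,
    expected: tuple[float, float],
    window_markers: int,
    n_permutations: int = 200,
    quantile: float = 0.95,
    clip: float = 0.01,
    rng: np.random.Generator | None = None,
) -> float:
    """Genome-wide significance threshold by pool-label permutation.

    For each permutation the control/mutant read counts of every marker are
    independently swapped with probability 1/2, window scores are
    recomputed, and the genome-wide maximum recorded; the threshold is the
    requested quantile (conservative ``higher`` interpolation) of those
    maxima.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    inc = track[track["included"]]
    obs, swap = _marker_scores(inc, expected, clip)
    codes = pd.factorize(inc["chrom"])[0]
    masks = rng.random(size=(n_permutations, len(inc))) < 0.5
    perm = np.where(masks, swap, obs)
    win = _window_scores_by_chrom(perm, codes, window_markers)
    maxima = win.max(axis=-1)
    return float(np.quantile(maxima, quantile, method="higher"))


def call_regions(track: pd.DataFrame, threshold: float) -> list[RegionCall]:
    """Merge maximal runs of contiguous above-threshold windows.

    Requires a ``window_score`` column (see :func:`scan_genome`).  Regions
    are reported best-first: by peak score, then longer span, then lower
    genomic coordinate.  An empty list is a valid outcome.
    """
    regions: list[RegionCall] = []
    inc = track[track["included"]]
    for chrom, grp in inc.groupby("chrom", sort=False):
        scores = grp["window_score"].to_numpy()
        pos = grp["pos"].to_numpy()
        above = scores > threshold
        if not above.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
        for s, e in zip(edges[::2], edges[1::2]):
            run = slice(s, e)
            regions.append(
                RegionCall(
                    chromosome=str(chrom),
                    start_bp=int(pos[s]),
                    end_bp=int(pos[e - 1]) + 1,
                    peak_score=float(scores[run].max()),
                    mean_control_freq=float(np.nanmean(grp["ctrl_freq"].to_numpy()[run])),
                    mean_mutant_freq=float(np.nanmean(grp["mut_freq"].to_numpy()[run])),
                )
            )
    regions.sort(
        key=lambda r: (-r.peak_score, -(r.end_bp - r.start_bp), r.chromosome, r.start_bp)
    )
    return regions


def check_selection_locus(
    track: pd.DataFrame,
    model: PhenotypeModel,
    halfwidth_bp: int = 50_000,
    tolerance: float = 0.15,
) -> SelectionLocusDiagnostic:
    """Verify the selection locus segregated as the model expects.

    Compares the mean raw parent-2 frequency of the included markers within
    ``halfwidth_bp`` of the selection locus against the model's fully
    linked expectations (control ~0, mutant ~2/3 at full viability).
    """
    locus = model.locus("selection")
    if locus.chromosome not in set(track["chrom"]):
        raise ValueError(f"selection locus chromosome {locus.chromosome} not in track")
    near = track[
        (track["chrom"] == locus.chromosome)
        & (track["pos"] >= locus.position_bp - halfwidth_bp)
        & (track["pos"] < locus.position_bp + halfwidth_bp)
        & track["included"]
    ]
    exp_c = expected_pool_allele_frequency(model, "control", locus, 0.0).frequency
    exp_m = expected_pool_allele_frequency(model, "mutant", locus, 0.0).frequency
    if len(near) == 0:
        return SelectionLocusDiagnostic(
            locus.chromosome, locus.position_bp, 0, np.nan, np.nan, exp_c, exp_m,
            tolerance, False,
        )
    f_c = float(near["ctrl_freq"].mean())
    f_m = float(near["mut_freq"].mean())
    ok = abs(f_c - exp_c) <= tolerance and abs(f_m - exp_m) <= tolerance
    return SelectionLocusDiagnostic(
        locus.chromosome, locus.position_bp, len(near), f_c, f_m, exp_c, exp_m,
        tolerance, ok,
    )


def scan_genome(
    variant_table: pd.DataFrame,
    model: PhenotypeModel,
    window_markers: int = 51,
    min_depth: int = 10,
    min_parent_depth: int = 10,
    n_permutations: int = 200,
    quantile: float = 0.95,
    clip: float = 0.01,
    seed: int = 0,
    smooth_window: int | None = None,
) -> ScanResult:
    """Full scan: markers -> tracks -> window LLR -> threshold -> regions.

    The expected linked frequencies are taken from the segregation model at
    zero recombination from the suppressor locus (control pool 1, mutant
    pool 1/3 at full viability).  The scan is invariant to the order of the
    input rows: markers are sorted canonically before scoring, and the
    permutation stream is tied to the sorted order.
    """
    markers, exclusions = select_informative_markers(variant_table, min_parent_depth)
    track = compute_frequency_track(markers, min_depth)
    track = smooth_track(track, smooth_window or window_markers)
    suppressor = model.locus("suppressor")
    exp_c = expected_pool_allele_frequency(model, "control", suppressor, 0.0).frequency
    exp_m = expected_pool_allele_frequency(model, "mutant", suppressor, 0.0).frequency
    expected = (exp_c, exp_m)

    inc = track[track["included"]]
    obs, _ = _marker_scores(inc, expected, clip)
    codes = pd.factorize(inc["chrom"])[0]
    track["window_score"] = np.nan
    track.loc[inc.index, "window_score"] = _window_scores_by_chrom(
        obs, codes, window_markers
    )
    rng = np.random.default_rng(seed)
    # calling requires positive evidence for the linked model on top of the
    # permutation control: per-marker label swapping breaks the linkage
    # autocorrelation of neighbouring markers, so its null maxima can sit
    # below zero while the LLR of a truly unlinked window never favours the
    # alternative on average — the floor at 0 keeps calls meaningful
    threshold = max(
        permutation_threshold(
            track, expected, window_markers, n_permutations, quantile, clip, rng
        ),
        0.0,
    )
    regions = call_regions(track, threshold)
    diagnostic = None
    try:
        model.locus("selection")
    except KeyError:
        pass
    else:
        diagnostic = check_selection_locus(track, model)
    return ScanResult(
        track=track,
        threshold=threshold,
        regions=regions,
        expected_control=exp_c,
        expected_mutant=exp_m,
        exclusions=exclusions,
        selection_diagnostic=diagnostic,
    )
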