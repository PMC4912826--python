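"""Post-Gibbs sliding-window QTL-region detection.

Each chromosome is covered by sliding windows of equal bp length, one
window anchored at every marker position (maximal resolution). A
window's ``PP_int`` is the fraction of saved MCMC cycles in which at
least one SNP inside the window is in the large-effect mixture
component. Above-threshold windows (default 0.8) are chained into
candidate peaks wherever consecutive windows overlap or touch; the
window with the highest ``PP_int`` in each peak (ties to the smaller
start) is reported as the QTL region, together with the posterior mean
and SD of the genetic variance the region explains per cycle,
``var(X_region g_region^(t))``, and its share of the total additive
genetic variance.

Coordinates are 1-based marker positions with half-open
``[start, start + length)`` windows; variances over individuals use the
population (denominator n) convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mixture import PosteriorSamples

DEFAULT_WINDOW_LENGTHS = (1_000_000, 2_500_000, 5_000_000)
DEFAULT_THRESHOLD = 0.8


def build_windows(marker_map: pd.DataFrame, length_bp: int) -> pd.DataFrame:
    """One window [p, p + length_bp) anchored at each marker position p.

    The map must be sorted by chromosome and position. Returned columns:
    chromosome, start_bp, end_bp, marker_lo, marker_hi (half-open row
    range into the map), n_markers. Every window contains at least its
    anchor marker.
    """
    chrom = marker_map["chromosome"].to_numpy()
    pos = marker_map["position_bp"].to_numpy()
    m = len(marker_map)
    order_ok = True
    for j in range(1, m):
        if chrom[j] < chrom[j - 1] or (chrom[j] == chrom[j - 1] and pos[j] <= pos[j - 1]):
            order_ok = False
            break
    if not order_ok:
        raise ValueError(
            f"marker map not sorted by chromosome/position at row {j} "
            f"({marker_map['marker_id'].iloc[j]})"
        )
    rows = []
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        cpos = pos[idx]
        lo = idx[0]
        for k, p in enumerate(cpos):
            end = p + length_bp
            hi_local = int(np.searchsorted(cpos, end, side="left"))
            rows.append(
                (
                    int(c),
                    int(p),
                    int(end),
                    int(lo + k),
                    int(lo + hi_local),
                    int(hi_local - k),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["chromosome", "start_bp", "end_bp", "marker_lo", "marker_hi", "n_markers"],
    )


def compute_pp_int(windows: pd.DataFrame, samples) -> pd.DataFrame:
    """Fill the pp_int column: fraction of cycles with >=1 large-effect SNP.

    ``samples`` is a :class:`PosteriorSamples` or a (T, m) binary
    indicator array. Vectorised via a per-cycle cumulative count of
    indicators along the marker axis.
    """
    delta = samples.delta if isinstance(samples, PosteriorSamples) else np.asarray(samples)
    if delta.ndim != 2 or delta.shape[0] == 0:
        raise ValueError("need a non-empty (cycles x markers) indicator matrix")
    T = delta.shape[0]
    csum = np.zeros((T, delta.shape[1] + 1), dtype=np.int64)
    np.cumsum(delta, axis=1, out=csum[:, 1:])
    lo = windows["marker_lo"].to_numpy()
    hi = windows["marker_hi"].to_numpy()
    counts = csum[:, hi] - csum[:, lo]  # (T, n_windows)
    out = windows.copy()
    out["pp_int"] = (counts > 0).mean(axis=0)
    return out


def find_candidate_peaks(
    windows: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
) -> list[np.ndarray]:
    """Chain above-threshold windows into maximal candidate peaks.

    Windows on the same chromosome whose bp spans overlap or touch are
    merged into one peak; an empty list means no region was detected.
    Returns row indices into ``windows`` per peak.
    """
    above = windows[windows["pp_int"] > threshold]
    peaks: list[np.ndarray] = []
    for c in above["chromosome"].unique():
        sub = above[above["chromosome"] == c].sort_values("start_bp")
        current: list[int] = []
        max_end = -1
        for row_idx, start, end in zip(
            sub.index, sub["start_bp"].to_numpy(), sub["end_bp"].to_numpy()
        ):
            if current and start > max_end:
                peaks.append(np.array(current, dtype=np.int64))
                current = []
                max_end = -1
            current.append(int(row_idx))
            max_end = max(max_end, int(end))
        if current:
            peaks.append(np.array(current, dtype=np.int64))
    return peaks


def select_regions(windows: pd.DataFrame, peaks: list[np.ndarray]) -> pd.DataFrame:
    """Pick the maximal-pp_int window per peak (ties: smallest start_bp)."""
    rows = []
    for peak in peaks:
        sub = windows.loc[peak]
        best = sub.sort_values(
            ["pp_int", "start_bp"], ascending=[False, True], kind="mergesort"
        ).iloc[0]
        rows.append(best)
    if not rows:
        return windows.iloc[0:0].copy()
    return pd.DataFrame(rows).reset_index(drop=True)


def region_variance(
    genotypes: np.ndarray,
    samples: PosteriorSamples,
    marker_lo: int,
    marker_hi: int,
    denominator: str = "genomic_plus_polygenic",
    total_values: np.ndarray | None = None,
):
    """Posterior mean/SD of the variance explained by a marker window.

    Per saved cycle t, ``v_region = var_n(X[:, lo:hi] @ g_t[lo:hi])``
    (population variance across individuals). The proportion averages
    ``v_region / v_total`` over cycles, where the total is the per-cycle
    variance of the full genomic value plus the polygenic effect
    (``denominator='genomic_plus_polygenic'``) or of the genomic value
    alone (``'markers_only'``). Cycles with zero total variance are
    skipped and counted.
    """
    X = np.asarray(genotypes, dtype=float)
    vals = X[:, marker_lo:marker_hi] @ samples.g[:, marker_lo:marker_hi].T  # (n, T)
    v_region = vals.var(axis=0)
    if total_values is None:
        total_values = total_genetic_values(X, samples, denominator)
    v_total = total_values.var(axis=0)
    ok = v_total > 0
    n_skipped = int((~ok).sum())
    proportion = float((v_region[ok] / v_total[ok]).mean()) if ok.any() else np.nan
    return {
        "variance_mean": float(v_region.mean()),
        "variance_sd": float(v_region.std()),
        "variance_proportion": proportion,
        "n_cycles_skipped": n_skipped,
    }


def total_genetic_values(
    genotypes: np.ndarray,
    samples: PosteriorSamples,
    denominator: str = "genomic_plus_polygenic",
) -> np.ndarray:
    """Per-cycle total additive genetic value of each individual, (n, T)."""
    if denominator not in ("genomic_plus_polygenic", "markers_only"):
        raise ValueError(f"unknown denominator {denominator!r}")
    total = np.asarray(genotypes, dtype=float) @ samples.g.T
    if denominator == "genomic_plus_polygenic":
        total = total + samples.u.T
    return total


class QTLRegionScan:
    """Scikit-learn-style wrapper running the full region analysis.

    ``fit(samples, marker_map, genotypes)`` computes, for each window
    length, the PP_int track, candidate peaks and selected QTL regions
    with variance summaries. Fitted attributes: ``windows_`` (dict
    length -> PP_int track) and ``regions_`` (one DataFrame over all
    lengths; empty when nothing exceeds the threshold).
    """

    def __init__(
        self,
        window_lengths: tuple[int, ...] = DEFAULT_WINDOW_LENGTHS,
        threshold: float = DEFAULT_THRESHOLD,
        denominator: str = "genomic_plus_polygenic",
    ) -> None:
        self.window_lengths = window_lengths
        self.threshold = threshold
        self.denominator = denominator

    def get_params(self, deep: bool = True) -> dict:
        return {
            "window_lengths": self.window_lengths,
            "threshold": self.threshold,
            "denominator": self.denominator,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(
        self,
        samples: PosteriorSamples,
        marker_map: pd.DataFrame,
        genotypes: np.ndarray | None = None,
    ) -> "QTLRegionScan":
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must lie in (0, 1]")
        self.windows_ = {}
        region_frames = []
        totals = (
            total_genetic_values(genotypes, samples, self.denominator)
            if genotypes is not None
            else None
        )
        for L in self.window_lengths:
            win = compute_pp_int(build_windows(marker_map, int(L)), samples)
            self.windows_[int(L)] = win
            peaks = find_candidate_peaks(win, self.threshold)
            reg = select_regions(win, peaks)
            reg.insert(0, "window_length_bp", int(L))
            if genotypes is not None and len(reg):
                stats = [
                    region_variance(
                        genotypes,
                        samples,
                        int(r.marker_lo),
                        int(r.marker_hi),
                        self.denominator,
                        total_values=totals,
                    )
                    for r in reg.itertuples()
                ]
                for key in (
                    "variance_mean",
                    "variance_sd",
                    "variance_proportion",
                    "n_cycles_skipped",
                ):
                    reg[key] = [s[key] for s in stats]
            region_frames.append(reg)
        self.regions_ = (
            pd.concat(region_frames, ignore_index=True)
            if region_frames
            else pd.DataFrame()
        )
        return self
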