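"""Read-depth copy-number variant detection against a control alignment.

Depth profiles are normalized per genome (window mean depth divided by the
genome-wide mean), so profiles are invariant to sequencing effort.  Calls
come from the per-window ratio of sample to control normalized depth:
copy estimate = round(ratio x ploidy), where the ploidy of a window is the
copy count of that region in the reference (2 for regions the reference
carries in duplicate, 1 elsewhere).  Runs of at least ``min_windows``
consecutive windows with the same non-reference copy estimate are merged
into one call, and each call spanning >= 2 windows gets a two-sample
Kolmogorov–Smirnov p-value comparing its ratio values against the
genome-wide background.

Inputs are depth tables (per-base or fixed-window means); read mapping is
upstream.  Windows are non-overlapping tiles.  Positions in reports are
1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

__all__ = [
    "DepthProfile",
    "CNVCall",
    "normalize_depth",
    "call_cnv",
    "cnv_significance",
    "call_and_test",
    "read_depth_table",
    "read_ploidy_bed",
    "write_calls",
]


@dataclass
class DepthProfile:
    """Windowed depth for one contig, raw and genome-mean-normalized."""

    contig: str
    window_size: int
    depth: np.ndarray          # per-window mean raw depth
    genome_mean: float
    genome_length: int

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if (self.depth < 0).any():
            raise ValueError("depths must be non-negative")

    @property
    def n_windows(self) -> int:
        return len(self.depth)

    @property
    def normalized(self) -> np.ndarray:
        return self.depth / self.genome_mean

    def window_starts(self) -> np.ndarray:
        """0-based start coordinate of each window."""
        return np.arange(self.n_windows) * self.window_size


@dataclass
class CNVCall:
    """One merged copy-number call; coordinates 1-based inclusive."""

    contig: str
    start: int
    end: int
    from_copy: int
    to_copy: int
    n_windows: int
    p_value: float | None = None
    mean_ratio: float = 0.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if self.from_copy == self.to_copy:
            raise ValueError("call must change copy number")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def normalize_depth(
    raw: np.ndarray,
    window: int = 1000,
    input_window: int | None = None,
    contig: str = "genome",
) -> DepthProfile:
    """Windowed, genome-mean-normalized depth profile.

    ``raw`` is per-base depth when ``input_window`` is None, otherwise
    fixed-step window means at step ``input_window`` (which must divide
    ``window``).  The genome mean is the average depth over the whole
    genome.  A trailing partial window is averaged over its actual length.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("empty depth vector")
    if (raw < 0).any():
        raise ValueError("depths must be non-negative")
    if not raw.any():
        raise ValueError("all-zero depth: nothing to normalize")
    if input_window is None:
        per_base = raw
        genome_length = raw.size
    else:
        if window % input_window != 0:
            raise ValueError("window must be a multiple of input_window")
        per_base = np.repeat(raw, input_window)
        genome_length = per_base.size
    genome_mean = float(per_base.mean())
    n_win = int(np.ceil(genome_length / window))
    padded = np.full(n_win * window, np.nan)
    padded[:genome_length] = per_base
    means = np.nanmean(padded.reshape(n_win, window), axis=1)
    return DepthProfile(
        contig=contig,
        window_size=window,
        depth=means,
        genome_mean=genome_mean,
        genome_length=genome_length,
    )


def _window_ploidy(
    n_windows: int, window: int, ploidy_regions: list[tuple[int, int, int]] | None
) -> np.ndarray:
    """Per-window reference copy count; a window takes the ploidy of any
    region covering its midpoint (default 1)."""
    ploidy = np.ones(n_windows, dtype=int)
    if ploidy_regions:
        mid = np.arange(n_windows) * window + window // 2
        for start, end, p in ploidy_regions:
            ploidy[(mid >= start) & (mid < end)] = p
    return ploidy


def call_cnv(
    sample: DepthProfile,
    control: DepthProfile,
    ploidy_regions: list[tuple[int, int, int]] | None = None,
    min_windows: int = 4,
    min_control_norm: float = 0.05,
) -> list[CNVCall]:
    """Copy-number calls from the sample/control normalized-depth ratio.

    ``ploidy_regions`` is a list of (start, end, ploidy) intervals, 0-based
    half-open, giving the reference copy count where it is not 1.  Windows
    whose control normalized depth falls below ``min_control_norm`` are
    masked (unmappable in the control, ratio undefined).  Runs shorter than
    ``min_windows`` are suppressed as single-window noise.
    """
    if sample.contig != control.contig or sample.window_size != control.window_size:
        raise ValueError("sample and control profiles are on different grids")
    if sample.n_windows != control.n_windows:
        raise ValueError("sample and control have different window counts")
    w = sample.window_size
    ratio = np.full(sample.n_windows, np.nan)
    ok = control.normalized >= min_control_norm
    ratio[ok] = sample.normalized[ok] / control.normalized[ok]
    ploidy = _window_ploidy(sample.n_windows, w, ploidy_regions)
    estimate = np.where(ok, np.round(ratio * ploidy), ploidy).astype(int)

    calls: list[CNVCall] = []
    i = 0
    n = sample.n_windows
    while i < n:
        if estimate[i] == ploidy[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and estimate[j + 1] == estimate[i]
            and ploidy[j + 1] == ploidy[i]
        ):
            j += 1
        if j - i + 1 >= min_windows:
            sel = slice(i, j + 1)
            calls.append(
                CNVCall(
                    contig=sample.contig,
                    start=i * w + 1,
                    end=min((j + 1) * w, sample.genome_length),
                    from_copy=int(ploidy[i]),
                    to_copy=int(estimate[i]),
                    n_windows=j - i + 1,
                    mean_ratio=float(np.nanmean(ratio[sel])),
                )
            )
        i = j + 1
    return calls


def cnv_significance(
    call: CNVCall, sample: DepthProfile, control: DepthProfile
) -> float | None:
    """Two-sample KS p-value of the call's ratio windows vs the background.

    The background is every other window with usable control depth.  Calls
    spanning a single window have no distribution to test; their p-value is
    undefined (None).
    """
    if call.n_windows < 2:
        return None
    w = sample.window_size
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = sample.normalized / control.normalized
    usable = np.isfinite(ratio)
    idx = np.arange(sample.n_windows)
    inside = (idx * w + 1 >= call.start) & (idx * w < call.end)
    fg = ratio[inside & usable]
    bg = ratio[~inside & usable]
    if fg.size < 2 or bg.size < 2:
        return None
    return float(ks_2samp(fg, bg).pvalue)


def call_and_test(
    sample: DepthProfile,
    control: DepthProfile,
    ploidy_regions: list[tuple[int, int, int]] | None = None,
    min_windows: int = 4,
) -> list[CNVCall]:
    """Run call_cnv and attach KS p-values to every call."""
    calls = call_cnv(sample, control, ploidy_regions, min_windows=min_windows)
    for c in calls:
        c.p_value = cnv_significance(c, sample, control)
    return calls


def read_depth_table(path: str | Path) -> tuple[str, np.ndarray, int | None]:
    """Read a depth TSV; returns (contig, depths, input_window).

    Accepts (contig, pos, depth) per-base rows (1-based positions) or
    (contig, win_start, win_end, mean_depth) fixed-window rows;
    input_window is None for per-base input.
    """
    df = pd.read_csv(path, sep="\t")
    if df["contig"].nunique() != 1:
        raise ValueError("expected a single contig per depth table")
    contig = str(df["contig"].iloc[0])
    if {"pos", "depth"}.issubset(df.columns):
        depths = np.zeros(int(df["pos"].max()))
        depths[df["pos"].to_numpy() - 1] = df["depth"].to_numpy()
        return contig, depths, None
    if {"win_start", "win_end", "mean_depth"}.issubset(df.columns):
        widths = (df["win_end"] - df["win_start"] + 1).to_numpy()
        step = int(widths[0])
        if not (widths[:-1] == step).all():
            raise ValueError("window rows must share a fixed step")
        return contig, df["mean_depth"].to_numpy(dtype=float), step
    raise ValueError("unrecognized depth table columns")


def read_ploidy_bed(path: str | Path, ploidy: int = 2) -> list[tuple[int, int, int]]:
    """BED intervals of reference-duplicated regions -> (start, end, ploidy)."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        p = int(parts[3]) if len(parts) > 3 and parts[3].isdigit() else ploidy
        out.append((int(parts[1]), int(parts[2]), p))
    return out


def write_calls(calls: list[CNVCall], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "contig": c.contig,
                "start": c.start,
                "end": c.end,
                "from_copy": c.from_copy,
                "to_copy": c.to_copy,
                "n_windows": c.n_windows,
                "p_value": c.p_value,
                "mean_ratio": c.mean_ratio,
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)
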