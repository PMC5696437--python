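"""Inferring the mode of endosymbiont acquisition from relative divergences.

The logic: a maternally inherited symbiont can arrive in a host lineage
cladogenically (inherited through the host speciation, so symbiont and host
divergence times coincide), by introgression (co-transferred with the
mitochondrion through hybridization, so symbiont and mito divergences agree
and are younger than the nuclear genome's), or horizontally (symbiont
younger than both).  Because symbionts and hosts evolve at very different
rates, observed symbiont/host synonymous-divergence ratios are compared
against ratios measured in documented cladogenic systems (Nasonia wasps,
Nomada bees); a bundled calibration table ships with the package.

Calendar-time conversion supports two rate conventions that both occur in
the literature and are NOT interchangeable: ``per_lineage`` rates (per site
per generation or year along one lineage, t = d / (2 r g)) and
``pairwise_divergence`` rates (per site per year of pairwise separation,
t = d / r).  The convention is always an explicit input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from statistics import median
from typing import Iterable, Literal, Sequence

import pandas as pd

from ._util import round_sig

__all__ = [
    "CalibrationEntry",
    "RateCalibration",
    "TransmissionCall",
    "CalibrationComparison",
    "TimeEstimate",
    "load_calibrations",
    "ks_ratio",
    "compare_to_calibrations",
    "classify_mode",
    "calibrate_time",
]

Mode = Literal[
    "cladogenic_plausible",
    "noncladogenic_transfer",
    "introgression",
    "horizontal",
    "indeterminate",
]


@dataclass
class CalibrationEntry:
    """One documented host pair with host and symbiont k_s / k_a values."""

    source: str
    host_a: str
    host_b: str
    host_ks: float
    host_ka: float
    symb_ks: float
    symb_ka: float
    ratio: float          # symbiont k_s / host k_s as published
    cladogenic: bool = True

    def recomputed_ratio(self, sig: int = 2) -> float:
        return ks_ratio(self.symb_ks, self.host_ks, sig=sig)


@dataclass
class RateCalibration:
    """A substitution-rate calibration with units and convention."""

    rate: float
    interval: tuple[float, float]
    units: Literal["per-site-per-generation", "per-site-per-year"]
    convention: Literal["per_lineage", "pairwise_divergence"]
    generations_per_year: float | None = None

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if not (0 < lo <= hi):
            raise ValueError("rate interval bounds must be positive and ordered")
        if self.units == "per-site-per-generation" and not self.generations_per_year:
            raise ValueError(
                "per-generation rates need generations_per_year to reach calendar time"
            )
        if self.units == "per-site-per-year" and self.generations_per_year not in (
            None,
            1,
            1.0,
        ):
            raise ValueError("per-year rates must not carry a generations_per_year")


@dataclass
class TimeEstimate:
    years: float
    interval: tuple[float, float]

    def rounded(self, sig: int = 2) -> float:
        return round_sig(self.years, sig)

    def rounded_interval(self, sig: int = 2) -> tuple[float, float]:
        return tuple(round_sig(v, sig) for v in self.interval)


@dataclass
class CalibrationComparison:
    observed_ratio: float
    folds: dict[str, float]  # "source: host_a vs host_b" -> fold difference
    min_fold: float
    max_fold: float
    orders_of_magnitude: tuple[float, float]


@dataclass
class TransmissionCall:
    mode: Mode
    observed_ratio: float
    fold_differences: dict[str, float]
    rationale: str
    scaled_symbiont_divergence: float | None = None


def load_calibrations(path: str | Path | None = None) -> list[CalibrationEntry]:
    """Load the bundled (or a user-supplied) calibration table."""
    if path is None:
        source = resources.files("codiverge.data") / "wolbachia_host_calibrations.tsv"
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    entries = []
    for row in df.itertuples():
        entries.append(
            CalibrationEntry(
                source=str(row.source),
                host_a=str(row.host_a),
                host_b=str(row.host_b),
                host_ks=float(row.host_ks),
                host_ka=float(row.host_ka),
                symb_ks=float(row.symb_ks),
                symb_ka=float(row.symb_ka),
                ratio=float(row.ratio),
                cladogenic=bool(getattr(row, "cladogenic", True)),
            )
        )
    return entries


def ks_ratio(symbiont_ks: float, host_ks: float, sig: int = 2) -> float:
    """Symbiont/host synonymous-divergence ratio at ``sig`` significant figures."""
    if host_ks <= 0:
        raise ValueError("host k_s must be positive")
    if symbiont_ks < 0:
        raise ValueError("symbiont k_s must be non-negative")
    return round_sig(symbiont_ks / host_ks, sig)


def _label(e: CalibrationEntry) -> str:
    return f"{e.source}: {e.host_a} vs {e.host_b}"


def compare_to_calibrations(
    observed_ratio: float, calibrations: Sequence[CalibrationEntry]
) -> CalibrationComparison:
    """Fold difference of each calibration ratio over the observed ratio."""
    if observed_ratio <= 0:
        raise ValueError("observed ratio must be positive")
    if not calibrations:
        raise ValueError("need at least one calibration entry")
    import math

    folds = {_label(e): e.ratio / observed_ratio for e in calibrations}
    vals = list(folds.values())
    return CalibrationComparison(
        observed_ratio=observed_ratio,
        folds=folds,
        min_fold=min(vals),
        max_fold=max(vals),
        orders_of_magnitude=(math.log10(min(vals)), math.log10(max(vals))),
    )


def _within_factor(x: float, y: float, factor: float) -> bool:
    return y / factor <= x <= y * factor


def classify_mode(
    nuclear_div: float,
    symbiont_div: float,
    calibrations: Sequence[CalibrationEntry],
    mito_div: float | None = None,
    t1: float = 2.0,
    t2: float = 10.0,
) -> TransmissionCall:
    """Classify the symbiont acquisition mode from relative divergences.

    Inputs must be on a common relative scale: ``nuclear_div`` and
    ``mito_div`` directly comparable (e.g. synonymous divergences, or
    relative chronogram ages), the symbiont divergence being rescaled
    internally by the median cladogenic calibration ratio.

    Rules (factor ``t1`` is the concordance tolerance, ``t2`` the rejection
    margin): cladogenic transmission is plausible when the observed
    symbiont/host ratio falls within factor ``t1`` of the span of cladogenic
    calibration ratios -- the span rather than a single summary because
    documented cladogenic systems themselves vary ~20-fold -- and, when a
    mitochondrial divergence is supplied, the mitochondrion is concordant
    with the nuclear genome.  Otherwise, with mito data, concordant
    symbiont/mito divergences both younger than nuclear indicate
    introgression, and a symbiont younger than the mitochondrion indicates
    horizontal transfer.  Without mito data the two lateral modes cannot be
    separated: a ratio below min(calibrations)/``t2`` is called
    noncladogenic transfer, anything else indeterminate.
    """
    if nuclear_div <= 0 or symbiont_div <= 0:
        raise ValueError("divergences must be positive")
    if mito_div is not None and mito_div <= 0:
        raise ValueError("mito divergence must be positive")
    clado = [e for e in calibrations if e.cladogenic]
    if not clado:
        raise ValueError("no cladogenic calibration entries supplied")

    observed = symbiont_div / nuclear_div
    comparison = compare_to_calibrations(observed, clado)
    ratios = [e.ratio for e in clado]
    med = median(ratios)
    scaled_symb = symbiont_div / med  # symbiont divergence on the nuclear scale
    in_range = min(ratios) / t1 <= observed <= max(ratios) * t1

    def call(mode: Mode, why: str) -> TransmissionCall:
        return TransmissionCall(
            mode=mode,
            observed_ratio=observed,
            fold_differences=comparison.folds,
            rationale=why,
            scaled_symbiont_divergence=scaled_symb,
        )

    if mito_div is None:
        if in_range:
            return call(
                "cladogenic_plausible",
                f"symbiont/host ratio {observed:.3g} lies within factor {t1} of the "
                f"cladogenic calibration range [{min(ratios):.3g}, {max(ratios):.3g}]",
            )
        if observed < min(ratios) / t2:
            return call(
                "noncladogenic_transfer",
                f"ratio {observed:.3g} is {comparison.min_fold:.0f}- to "
                f"{comparison.max_fold:.0f}-fold below cladogenic calibrations; "
                "without mitochondrial data introgression and horizontal transfer "
                "cannot be separated",
            )
        return call(
            "indeterminate",
            f"ratio {observed:.3g} falls between the calibration range and the "
            f"rejection margin (min/{t2})",
        )

    mito_concordant = _within_factor(mito_div, nuclear_div, t1)
    if in_range and mito_concordant:
        return call(
            "cladogenic_plausible",
            "symbiont/host ratio within the cladogenic calibration range and the "
            "mitochondrial divergence concordant with the nuclear genome",
        )
    if _within_factor(scaled_symb, mito_div, t1) and nuclear_div > t1 * mito_div:
        return call(
            "introgression",
            "mitochondrial and (rescaled) symbiont divergences concordant and both "
            "more recent than the nuclear divergence",
        )
    if t1 * scaled_symb < mito_div:
        return call(
            "horizontal",
            "(rescaled) symbiont divergence more recent than the mitochondrial "
            "divergence",
        )
    return call("indeterminate", "divergence pattern matches no mode cleanly")


def calibrate_time(divergence: float, cal: RateCalibration) -> TimeEstimate:
    """Convert a divergence into calendar years under the stated convention.

    ``per_lineage``: t = d / (2 r g), with g = generations per year (1 for
    per-year rates); ``pairwise_divergence``: t = d / r.  The interval is
    the rate interval mapped through the same formula (slow rate -> old
    age).
    """
    if divergence < 0:
        raise ValueError("divergence must be non-negative")
    g = cal.generations_per_year or 1.0

    def to_years(rate: float) -> float:
        if cal.convention == "per_lineage":
            return divergence / (2.0 * rate * g)
        return divergence / rate

    lo_rate, hi_rate = cal.interval
    return TimeEstimate(
        years=to_years(cal.rate),
        interval=(to_years(hi_rate), to_years(lo_rate)),
    )
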