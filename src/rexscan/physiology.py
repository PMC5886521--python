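"""Fermentation, growth, enzyme-activity and qPCR calculators.

The quantitative wet-lab bookkeeping of an ethanol-fermentation study:

* percent-of-theoretical ethanol yield from substrate consumed, using
  stoichiometric maxima (one glucose equivalent -> at most two ethanol,
  so cellobiose -> four; pentoses -> 5/3);
* maximal specific growth rate (mu_max, 1/h) from an OD600 time series
  by sliding-window log-linear regression, plus the smoothed maximal OD;
* alcohol-dehydrogenase specific activity (U/mg; 1 U = 1 umol product
  per minute) from the A340 slope of NAD(P)H oxidation;
* absolute qPCR quantification against a standard curve of Cq versus
  log10 copy number, expressed as a ratio to a reference gene (recA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "FermentationRecord",
    "YieldResult",
    "ODSeries",
    "GrowthFit",
    "AdhAssay",
    "StandardCurve",
    "QpcrSample",
    "ETHANOL_MW",
    "SUBSTRATE_TABLE",
    "theoretical_yield_coeff",
    "percent_theoretical_yield",
    "fit_growth",
    "adh_specific_activity",
    "fit_standard_curve",
    "quantify_and_normalize",
]

#: Molar mass of ethanol, g/mol (standard atomic weights).
ETHANOL_MW = 46.069

#: substrate -> (formula mass g/mol, max mol ethanol per mol substrate).
SUBSTRATE_TABLE: dict[str, tuple[float, float]] = {
    "cellobiose": (342.297, 4.0),  # two glucose units, two ethanol each
    "glucose": (180.156, 2.0),
    "xylose": (150.130, 5.0 / 3.0),  # pentose phosphate route, 5 C -> 5/3 EtOH
}

#: NAD(P)H molar extinction coefficient at 340 nm, mM^-1 cm^-1.
NADH_EXTINCTION_MM = 6.22


@dataclass(frozen=True)
class FermentationRecord:
    """End-point fermentation measurements for one strain (g/L)."""

    strain: str
    substrate: str
    substrate_initial: float
    substrate_final: float
    ethanol: float
    acetate: float = 0.0
    lactate: float = 0.0

    def __post_init__(self) -> None:
        if self.substrate_final > self.substrate_initial:
            raise ValueError("substrate_final cannot exceed substrate_initial")
        for name in ("substrate_initial", "substrate_final", "ethanol", "acetate", "lactate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def consumed(self) -> float:
        return self.substrate_initial - self.substrate_final


@dataclass(frozen=True)
class YieldResult:
    percent_theoretical: float
    coeff_g_per_g: float
    flag_over_100: bool


@dataclass(frozen=True)
class ODSeries:
    """An OD600 growth curve; times in hours, strictly increasing."""

    times: tuple[float, ...]
    od600: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        if t.shape != od.shape or t.ndim != 1:
            raise ValueError("times and od600 must be 1-D and equal length")
        if len(t) and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(od < 0):
            raise ValueError("od600 must be non-negative")


@dataclass(frozen=True)
class GrowthFit:
    mu_max: float  # 1/h
    max_od: float
    window_start: float  # h, start of the steepest window
    r_squared: float


@dataclass(frozen=True)
class AdhAssay:
    """One spectrophotometric ADH assay (cofactor oxidation at 340 nm).

    ``slope`` is the magnitude of the A340 change per minute;
    extinction coefficient in mM^-1 cm^-1, reaction volume in mL,
    protein mass in mg.
    """

    slope: float  # |dA340/dt|, 1/min
    protein_mass: float  # mg in the cuvette
    extinction_coeff: float = NADH_EXTINCTION_MM
    path_length: float = 1.0  # cm
    reaction_volume: float = 1.0  # mL
    cofactor: str = "NADH"

    def __post_init__(self) -> None:
        if self.cofactor not in {"NADH", "NADPH"}:
            raise ValueError("cofactor must be NADH or NADPH")
        if self.slope < 0:
            raise ValueError("slope enters as a positive magnitude")
        for name in ("extinction_coeff", "path_length", "reaction_volume", "protein_mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class StandardCurve:
    """qPCR calibration line Cq = intercept + slope * log10(copies)."""

    slope: float  # Cq per log10(copies); negative
    intercept: float
    efficiency: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("standard-curve slope must be negative")
        object.__setattr__(self, "efficiency", 10 ** (-1.0 / self.slope) - 1.0)

    def copies(self, cq: float) -> float:
        return 10 ** ((cq - self.intercept) / self.slope)


@dataclass(frozen=True)
class QpcrSample:
    sample: str
    target: str
    cq: float


def theoretical_yield_coeff(substrate: str) -> float:
    """Maximal g ethanol per g substrate (e.g. cellobiose -> ~0.54)."""
    key = substrate.strip().lower()
    if key not in SUBSTRATE_TABLE:
        raise ValueError(
            f"unknown substrate {substrate!r}; supported: {sorted(SUBSTRATE_TABLE)}"
        )
    mass, mol_ethanol = SUBSTRATE_TABLE[key]
    return mol_ethanol * ETHANOL_MW / mass


def percent_theoretical_yield(rec: FermentationRecord) -> YieldResult:
    """Ethanol yield as percent of the stoichiometric maximum for the
    substrate actually consumed."""
    consumed = rec.consumed
    if consumed <= 0:
        raise ValueError("substrate consumed must be positive")
    coeff = theoretical_yield_coeff(rec.substrate)
    percent = 100.0 * rec.ethanol / (consumed * coeff)
    return YieldResult(percent, coeff, percent > 100.0)


def _window_regression(t: np.ndarray, ln_od: np.ndarray) -> tuple[float, float]:
    """Slope and r^2 of a least-squares line; a perfectly flat window
    (zero variance in ln OD) counts as r^2 = 1 with slope 0."""
    slope, intercept = np.polyfit(t, ln_od, 1)
    pred = slope * t + intercept
    ss_tot = float(np.sum((ln_od - ln_od.mean()) ** 2))
    ss_res = float(np.sum((ln_od - pred) ** 2))
    if ss_tot == 0.0:
        return float(slope), 1.0
    return float(slope), 1.0 - ss_res / ss_tot


def fit_growth(series: ODSeries, window: int = 5, min_r_squared: float = 0.98) -> GrowthFit:
    """Maximal specific growth rate from an OD600 curve.

    A two-stage fit. Sliding ``window``-point log-linear regressions
    give a first estimate: the largest slope of ln(OD600) among windows
    whose fit reaches ``min_r_squared`` (windows containing a zero OD
    are excluded from the log transform; if no window meets the guard
    the best-r^2 window's slope is used). That estimate then seeds a
    parametric logistic least-squares refinement on the log scale,
    which corrects the downward bias the window slopes acquire once the
    culture starts saturating (at a typical inoculation density the
    curve is never purely exponential). If the refinement fails to
    converge, the window estimate is reported as-is.

    The maximal OD is read from a 3-point running-median smoothed
    series. A culture that never grows reports mu_max 0.
    """
    t = np.asarray(series.times, dtype=float)
    od = np.asarray(series.od600, dtype=float)
    if len(t) < window:
        raise ValueError(f"need at least {window} points, got {len(t)}")
    if window < 3:
        raise ValueError("window must be at least 3 points")
    if np.all(od == 0):
        raise ValueError("all-zero OD series cannot be fitted")
    smoothed = np.copy(od)
    if len(od) >= 3:
        smoothed[1:-1] = np.median(
            np.column_stack([od[:-2], od[1:-1], od[2:]]), axis=1
        )
    max_od = float(np.max(smoothed))
    best: tuple[float, float, float] | None = None  # (slope, r2, t0)
    fallback: tuple[float, float, float] | None = None
    for i in range(len(t) - window + 1):
        tw = t[i : i + window]
        odw = od[i : i + window]
        if np.any(odw <= 0):
            continue
        slope, r2 = _window_regression(tw, np.log(odw))
        if fallback is None or r2 > fallback[1]:
            fallback = (slope, r2, tw[0])
        if r2 >= min_r_squared and (best is None or slope > best[0]):
            best = (slope, r2, tw[0])
    chosen = best if best is not None else fallback
    if chosen is None:
        raise ValueError("no window with positive OD values to fit")
    slope, r2, t0 = chosen
    # whole-series log slope rescues the seed when short noisy windows
    # leave the window stage without a usable positive slope
    pos = od > 0
    global_slope = float(np.polyfit(t[pos], np.log(od[pos]), 1)[0]) if pos.sum() >= 2 else 0.0
    mu = max(slope, global_slope, 0.0)
    if mu < 1e-8:  # flat curve: no growth to refine
        mu = 0.0
    else:
        refined = _refine_logistic(t, od, mu, max_od)
        if refined is not None:
            mu, r2 = refined
        else:
            mu = max(slope, 0.0)
    return GrowthFit(mu_max=mu, max_od=max_od, window_start=float(t0), r_squared=r2)


def _refine_logistic(
    t: np.ndarray, od: np.ndarray, mu0: float, max_od: float
) -> tuple[float, float] | None:
    """Least-squares logistic fit of ln(OD) on time.

    Free parameters: rate mu, carrying capacity K and inoculum od0. K
    is bounded well above the observed maximum so a curve that never
    saturates degenerates gracefully to an exponential. Returns
    (mu, r^2 of ln OD) or None if the optimiser fails.
    """
    from scipy.optimize import curve_fit

    mask = od > 0
    if mask.sum() < 4:
        return None
    tt, oo = t[mask], od[mask]

    def model(x, mu, k, od0):
        return np.log(logistic_od(x, mu, k, od0))

    od0_guess = float(oo[0])
    try:
        popt, _ = curve_fit(
            model,
            tt,
            np.log(oo),
            p0=[mu0, max(max_od * 1.05, od0_guess * 2), od0_guess],
            bounds=(
                [0.0, max_od * 0.99, 1e-12],
                [10.0, max_od * 1e6, max_od * 10],
            ),
            maxfev=10_000,
        )
    except (RuntimeError, ValueError):
        return None
    pred = model(tt, *popt)
    ln_oo = np.log(oo)
    ss_tot = float(np.sum((ln_oo - ln_oo.mean()) ** 2))
    ss_res = float(np.sum((ln_oo - pred) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(popt[0]), r2


def adh_specific_activity(assay: AdhAssay) -> float:
    """Specific activity in U/mg from Beer-Lambert conversion of the
    A340 slope: umol/min = slope * volume / (epsilon * path)."""
    rate_umol_min = assay.slope * assay.reaction_volume / (
        assay.extinction_coeff * assay.path_length
    )
    return rate_umol_min / assay.protein_mass


def fit_standard_curve(points: list[tuple[float, float]]) -> StandardCurve:
    """Least-squares line of Cq on log10(copies) from a dilution series."""
    if any(c <= 0 for c, _ in points):
        raise ValueError("copy numbers must be positive")
    levels = {c for c, _ in points}
    if len(levels) < 2:
        raise ValueError("need at least two distinct copy levels")
    x = np.log10([c for c, _ in points])
    y = np.asarray([q for _, q in points], dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite Cq value in standards")
    res = stats.linregress(x, y)
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept))


def quantify_and_normalize(
    samples: list[QpcrSample],
    curves: dict[str, StandardCurve],
    reference_target: str = "recA",
) -> dict[str, float]:
    """Absolute copies per target via its standard curve, averaged over
    replicate wells on the copy scale, expressed as a ratio to the
    reference target. Returns target -> ratio (reference maps to 1)."""
    by_target: dict[str, list[float]] = {}
    for s in samples:
        if s.target not in curves:
            raise ValueError(f"no standard curve for target {s.target!r}")
        by_target.setdefault(s.target, []).append(curves[s.target].copies(s.cq))
    if reference_target not in by_target:
        raise ValueError(f"reference target {reference_target!r} missing from samples")
    mean_copies = {t: float(np.mean(v)) for t, v in by_target.items()}
    ref = mean_copies[reference_target]
    return {t: c / ref for t, c in mean_copies.items()}


def logistic_od(t: float | np.ndarray, mu: float, k: float, od0: float):
    """Logistic growth OD(t) = K*od0*e^(mu t) / (K + od0*(e^(mu t)-1)).

    Reduces to exponential growth while OD << K and plateaus at K; a
    zero rate gives a flat curve at od0.
    """
    if k <= 0:
        raise ValueError("carrying capacity K must be positive")
    e = np.exp(np.asarray(mu, dtype=float) * np.asarray(t, dtype=float))
    return k * od0 * e / (k + od0 * (e - 1.0))
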