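"""Relative plaque-age scores and the group-level contrasts built on them.

Age is always reported as a *relative* score — the Da shift of the envelope
centroid from the natural (unlabeled) reference — never as calendar time.
The sign convention depends on the feeding scheme:

* ``pulse_chase``: label was available early, so more label (higher
  centroid) means earlier deposition -> higher score = older plaque.
* ``pulse_only``: label accumulated over the experiment, so material
  deposited before the pulse carries less label -> the sign flips.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from . import isotope_model as im
from . import peakfit

log = logging.getLogger(__name__)

SCHEMES = ("pulse_only", "pulse_chase")


@dataclass
class AgeEstimate:
    plaque_id: str
    animal: str
    region: str  # cortex | hippocampus
    subregion: str  # center | periphery | whole
    centroid: float
    age_score: float
    scheme: str
    ratio43: float | None = None


@dataclass
class GroupComparison:
    contrast: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str  # mixed-model | paired-t
    n: int
    note: str = ""


@lru_cache(maxsize=8)
def natural_reference_centroid(
    resolving_power: float = 1000.0, charge: int = 1
) -> float:
    """Centroid of the noiseless natural Abeta1-42 envelope, measured with the
    same spectral pipeline that measures the data."""
    species = im.PeptideSpecies(im.ABETA42_SEQUENCE, charge=charge)
    comp = im.composition_from_sequence(species)
    nat = im.natural_distribution(comp, charge=charge)
    spec = im.render_spectrum(nat, resolving_power)
    cfg = peakfit.FitConfig()
    return peakfit.fit_roi_spectrum(spec, cfg).centroid


def age_from_centroid(
    centroid: float,
    scheme: str,
    reference_centroid: float | None = None,
    resolving_power: float = 1000.0,
) -> float:
    """Signed relative age score (Da) from an envelope centroid."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if reference_centroid is None:
        reference_centroid = natural_reference_centroid(resolving_power)
    shift = centroid - reference_centroid
    return shift if scheme == "pulse_chase" else -shift


def centroid_calibration(
    rho: float,
    resolving_power: float = 1000.0,
    f_grid: np.ndarray | None = None,
    charge: int = 1,
    config: peakfit.FitConfig | None = None,
) -> tuple[float, float]:
    """Calibration line centroid = slope * f + intercept.

    Built by rendering noiseless mixture envelopes from the isotope model at
    a grid of label fractions and measuring each with the same centroid
    pipeline used on data. Inverting the line turns a measured centroid into
    an estimated label fraction f.
    """
    if f_grid is None:
        f_grid = np.linspace(0.0, 1.0, 5)
    config = config or peakfit.FitConfig()
    species = im.PeptideSpecies(im.ABETA42_SEQUENCE, charge=charge)
    comp = im.composition_from_sequence(species)
    nat = im.natural_distribution(comp, charge=charge)
    lab = im.labeled_distribution(comp, rho=rho, charge=charge)
    cents = []
    for f in f_grid:
        mix = im.mixture_envelope(im.LabelingModel(float(f), rho), nat, lab)
        spec = im.render_spectrum(mix, resolving_power)
        cents.append(peakfit.fit_roi_spectrum(spec, config).centroid)
    slope, intercept = np.polyfit(f_grid, cents, 1)
    return float(slope), float(intercept)


def invert_calibration(centroid: float, slope: float, intercept: float) -> float:
    """Estimated label fraction f from a measured centroid (unclamped)."""
    return (centroid - intercept) / slope


@dataclass
class CentroidCalibration:
    """Monotone centroid-vs-f calibration built from the isotope model.

    The mixture *mean mass* is exactly affine in f, but the measured
    centroid (baseline-bounded, window-truncated) deviates slightly from a
    straight line, with the deviation concentrated at the ends of the f
    range; inverting by monotone interpolation of the measured noiseless
    curve removes that bias. The fitted line is kept for reporting.
    """

    f_grid: np.ndarray
    centroids: np.ndarray
    slope: float
    intercept: float

    def invert(self, centroid: float | np.ndarray) -> np.ndarray:
        """Label fraction estimate; extrapolates linearly beyond the grid."""
        c = np.atleast_1d(np.asarray(centroid, dtype=float))
        f = np.interp(c, self.centroids, self.f_grid)
        below = c < self.centroids[0]
        above = c > self.centroids[-1]
        f[below] = (c[below] - self.intercept) / self.slope
        f[above] = (c[above] - self.intercept) / self.slope
        return f if f.size > 1 else float(f[0])

    @classmethod
    def build(
        cls,
        rho: float,
        resolving_power: float = 1000.0,
        n_points: int = 21,
        charge: int = 1,
        config: peakfit.FitConfig | None = None,
    ) -> "CentroidCalibration":
        f_grid = np.linspace(0.0, 1.0, n_points)
        config = config or peakfit.FitConfig()
        species = im.PeptideSpecies(im.ABETA42_SEQUENCE, charge=charge)
        comp = im.composition_from_sequence(species)
        nat = im.natural_distribution(comp, charge=charge)
        lab = im.labeled_distribution(comp, rho=rho, charge=charge)
        cents = []
        for f in f_grid:
            mix = im.mixture_envelope(im.LabelingModel(float(f), rho), nat, lab)
            spec = im.render_spectrum(mix, resolving_power)
            cents.append(peakfit.fit_roi_spectrum(spec, config).centroid)
        cents = np.asarray(cents)
        if np.any(np.diff(cents) <= 0):
            raise ValueError("calibration centroids are not strictly monotone in f")
        slope, intercept = np.polyfit(f_grid, cents, 1)
        return cls(f_grid, cents, float(slope), float(intercept))


def _paired_t(diff: np.ndarray, contrast: str) -> GroupComparison:
    n = len(diff)
    est = float(np.mean(diff))
    if n < 2 or float(np.std(diff, ddof=1)) == 0.0:
        p = 1.0 if est == 0.0 else 0.0
        return GroupComparison(contrast, est, est, est, p, "paired-t", n,
                               "degenerate: zero variance")
    se = float(np.std(diff, ddof=1) / np.sqrt(n))
    t = est / se
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    half = float(stats.t.ppf(0.975, n - 1)) * se
    return GroupComparison(contrast, est, est - half, est + half, p, "paired-t", n)


def compare_center_periphery(estimates: pd.DataFrame) -> GroupComparison:
    """Center-vs-periphery contrast of the age signal within plaques.

    Expects columns ``plaque_id, animal, subregion, value`` with paired
    center/periphery rows per plaque (unpaired plaques are excluded and
    logged). Pairing is handled exactly by differencing within plaques; the
    per-plaque differences are then modelled with a random intercept per
    animal (REML), so the subregion fixed effect equals the one from the
    long-format mixed model with the same random structure. Falls back to a
    paired t-test when fewer than 3 animals are present.
    """
    wide = estimates.pivot_table(
        index=["plaque_id", "animal"], columns="subregion", values="value"
    )
    if "center" not in wide.columns or "periphery" not in wide.columns:
        raise ValueError("need both 'center' and 'periphery' subregions")
    unpaired = wide[wide[["center", "periphery"]].isna().any(axis=1)]
    for pid, _ in unpaired.index:
        log.info("plaque %s excluded: unpaired center/periphery", pid)
    wide = wide.dropna(subset=["center", "periphery"])
    diff = (wide["center"] - wide["periphery"]).to_numpy(dtype=float)
    animals = wide.index.get_level_values("animal").to_numpy()
    n_animals = len(np.unique(animals))
    contrast = "center - periphery"
    if n_animals < 3:
        log.warning("only %d animal(s): degrading to paired t-test", n_animals)
        return _paired_t(diff, contrast)
    if float(np.std(diff)) == 0.0:
        est = float(np.mean(diff))
        return GroupComparison(contrast, est, est, est,
                               1.0 if est == 0.0 else 0.0,
                               "mixed-model", len(diff), "degenerate: zero variance")
    import statsmodels.api as sm

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(diff, np.ones((len(diff), 1)), groups=animals)
            try:
                fit = model.fit(reml=True)
            except np.linalg.LinAlgError:
                # gradient-free retry: the REML score is singular when the
                # animal variance estimate sits on the zero boundary
                fit = model.fit(reml=True, method="powell")
        est = float(fit.params[0])
        se = float(fit.bse[0])
        if not np.isfinite(se) or se <= 0:
            raise RuntimeError("mixed model produced a non-finite standard error")
        z = est / se
        p = float(2.0 * stats.norm.sf(abs(z)))
        half = 1.959963984540054 * se
        return GroupComparison(contrast, est, est - half, est + half, p,
                               "mixed-model", len(diff))
    except Exception as exc:  # singular fits on tiny data
        log.warning("mixed model failed (%s); using paired t-test", exc)
        return _paired_t(diff, contrast)


def compare_regions(estimates: pd.DataFrame) -> GroupComparison:
    """Cortex-vs-hippocampus contrast: paired t-test on per-animal region means.

    Expects columns ``animal, region, value``.
    """
    means = estimates.groupby(["animal", "region"])["value"].mean().unstack()
    for col in ("cortex", "hippocampus"):
        if col not in means.columns:
            raise ValueError(f"missing region {col!r}")
    means = means.dropna(subset=["cortex", "hippocampus"])
    if len(means) < 2:
        raise ValueError("paired region test needs at least 2 animals")
    diff = (means["cortex"] - means["hippocampus"]).to_numpy(dtype=float)
    return _paired_t(diff, "cortex - hippocampus")


def correlate_age_lco(per_plaque: pd.DataFrame) -> pd.DataFrame:
    """Per-animal Pearson correlation of label score vs LCO 500/580 ratio.

    Expects columns ``animal, ratio43, lco_ratio``; animals with < 3 complete
    plaques are skipped, zero-variance inputs are flagged. A pooled row
    (animal = "pooled") is appended.
    """
    rows = []

    def _one(name: str, sub: pd.DataFrame) -> None:
        sub = sub.dropna(subset=["ratio43", "lco_ratio"])
        n = len(sub)
        if n < 3:
            log.info("animal %s skipped: %d complete plaques < 3", name, n)
            return
        x = sub["ratio43"].to_numpy(float)
        y = sub["lco_ratio"].to_numpy(float)
        if np.std(x) == 0.0 or np.std(y) == 0.0:
            rows.append({"animal": name, "n": n, "r": np.nan, "p": np.nan,
                         "flag": "zero variance"})
            return
        r, p = stats.pearsonr(x, y)
        rows.append({"animal": name, "n": n, "r": float(r), "p": float(p), "flag": ""})

    for animal, sub in per_plaque.groupby("animal"):
        _one(str(animal), sub)
    _one("pooled", per_plaque)
    return pd.DataFrame(rows, columns=["animal", "n", "r", "p", "flag"])
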