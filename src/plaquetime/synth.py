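"""Synthetic datasets with the statistical structure the analysis assumes.

Every generator is a pure function of (config, seed) and returns a
GroundTruth record sufficient to score recovery by the downstream stages:

* ``simulate_msi_dataset`` — per-plaque center/periphery ROI spectra in
  linear and reflector mode, built from the isotope-model mixture envelopes
  plus additive Gaussian noise;
* ``simulate_counts`` — negative-binomial gene counts with designated gene
  sets planted to correlate with plaque age;
* ``simulate_hyperspectral`` — 32-channel LCO emission stacks as
  non-negative q-FTAA / h-FTAA mixtures with a core-ward maturity gradient,
  plus Abeta / HOMER1 / LAMP1 marker images with ring-structured profiles.

Default parameter values mirror the study conditions: 3 animals, ~8 plaques
per region (the correlation analyses used 7-10 plaques per animal from 3
animals), a 15N pulse followed by an unlabeled chase, linear-mode
acquisition at R = 1000 and reflector mode at R = 15000 around m/z 4512,
and 10-um rings out to 30 um.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import isotope_model as im
from .spectra import Spectrum


@dataclass
class SimulationConfig:
    """Study conditions for the generators.

    ``rho`` is the per-nitrogen 15N probability in molecules made during the
    pulse. The feed is highly enriched but tissue relative isotope abundance
    is substantially diluted by pre-existing unlabeled amino-acid pools, so
    the default is a modest 0.15 — which also keeps the linear-mode envelope
    unimodal, the regime in which the centroid is a meaningful mean-shift
    estimator. ``periphery_f_offset`` is f(periphery) - f(center); under a
    pulse-chase scheme the plaque center is the oldest, most-labeled part,
    so the default offset is negative, and plaques present after the chase
    nucleated during or near the pulse, so center label fractions default
    high (0.7) with substantial plaque-to-plaque spread. Linear-mode ROI
    spectra carry single-ROI noise (``snr``); reflector ROI spectra are
    TIC-normalized averages over a whole plaque raster and carry
    correspondingly lower noise (``snr_reflector``).
    """

    n_animals: int = 3
    n_plaques_cortex: int = 8
    n_plaques_hippocampus: int = 8
    scheme: str = "pulse_chase"  # pulse_only | pulse_chase
    rho: float = 0.15
    f_center_mean: float = 0.7
    periphery_f_offset: float = -0.2
    region_f_shift: float = 0.1  # cortex minus hippocampus, added to f
    f_animal_sd: float = 0.0
    f_plaque_sd: float = 0.10
    snr: float = 20.0  # linear-mode per-ROI spectra
    snr_reflector: float = 150.0  # reflector ROI spectra are raster averages
    resolving_power_linear: float = 1000.0
    resolving_power_reflector: float = 15000.0
    mz_range: tuple[float, float] = (4455.0, 4590.0)
    grid_step_linear: float = 0.2
    grid_step_reflector: float = 0.02
    # counts
    n_genes: int = 1000
    planted_sets: dict = field(
        default_factory=lambda: {"synaptic": (-0.8, 25), "immune": (0.8, 25)}
    )
    baseline_log_mean: float = 6.0
    baseline_log_sd: float = 1.0
    effect_scale: float = 0.6
    dispersion: float = 0.02  # NB alpha; 0 switches off all count noise
    libsize_sd: float = 0.2
    # imaging
    pixel_size_um: float = 1.0
    image_shape: tuple[int, int] = (256, 256)
    n_channels: int = 32
    wavelength_range: tuple[float, float] = (480.0, 690.0)
    plaque_radius_um: float = 12.0
    plaques_per_type: tuple[int, int, int] = (4, 2, 4)  # h+q+, h+q-, LCO-
    image_noise_sd: float = 0.02
    homer1_deficit: dict = field(
        default_factory=lambda: {
            "Ab+h+q+": (0.60, 0.80, 0.95),
            "Ab+h+q-": (0.75, 0.90, 1.00),
            "Ab+h-q-": (0.90, 0.97, 1.00),
        }
    )
    lamp1_elevation: dict = field(
        default_factory=lambda: {
            "Ab+h+q+": (1.80, 1.40, 1.10),
            "Ab+h+q-": (1.50, 1.25, 1.05),
            "Ab+h-q-": (1.20, 1.10, 1.00),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_animals, self.n_plaques_cortex, self.n_plaques_hippocampus) < 1:
            raise ValueError("all counts must be >= 1")
        if self.snr < 0 or self.image_noise_sd < 0:
            raise ValueError("noise levels must be non-negative")
        if self.scheme not in ("pulse_only", "pulse_chase"):
            raise ValueError("scheme must be pulse_only or pulse_chase")


@dataclass
class GroundTruth:
    """Planted truth written alongside every simulated dataset."""

    config: dict
    plaques: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config,
            "plaques": None if self.plaques is None
            else self.plaques.to_dict(orient="list"),
            "extras": {
                k: (v.to_dict(orient="list") if isinstance(v, pd.DataFrame) else v)
                for k, v in self.extras.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["seed"] = config.seed
    return d


# ---------------------------------------------------------------------------
# MSI spectra


def _plaque_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for a in range(config.n_animals):
        animal = f"animal{a + 1}"
        f_animal = rng.normal(0.0, config.f_animal_sd)
        for region, n in (
            ("cortex", config.n_plaques_cortex),
            ("hippocampus", config.n_plaques_hippocampus),
        ):
            shift = config.region_f_shift / 2 if region == "cortex" else -config.region_f_shift / 2
            for i in range(n):
                f_center = np.clip(
                    config.f_center_mean + shift + f_animal
                    + rng.normal(0.0, config.f_plaque_sd),
                    0.02, 0.98,
                )
                f_periph = float(np.clip(f_center + config.periphery_f_offset, 0.0, 1.0))
                rows.append(
                    {"plaque_id": f"{animal}_{region}_{i + 1}",
                     "animal": animal, "region": region,
                     "f_center": float(f_center), "f_periphery": f_periph,
                     "f_whole": float(0.5 * (f_center + f_periph))}
                )
    df = pd.DataFrame(rows)
    # maturity score: older (higher f under pulse-chase) = more mature
    order = df["f_center"] if config.scheme == "pulse_chase" else -df["f_center"]
    df["maturity"] = order.rank(pct=True)
    return df


def simulate_msi_dataset(
    config: SimulationConfig,
) -> tuple[list[Spectrum], GroundTruth]:
    """Per-plaque center/periphery ROI spectra in both instrument modes.

    Each ROI spectrum is a rendered mixture envelope plus additive Gaussian
    noise of sd = apex / SNR. Center and periphery ROIs come in linear mode
    (the centroid pipeline's input); a whole-plaque ROI comes in reflector
    mode (the ratio43 pipeline's input). Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    plaques = _plaque_table(config, rng)

    species = im.PeptideSpecies(im.ABETA42_SEQUENCE)
    comp = im.composition_from_sequence(species)
    nat = im.natural_distribution(comp)
    lab = im.labeled_distribution(comp, rho=config.rho)
    lo, hi = config.mz_range
    grid_lin = np.arange(lo, hi, config.grid_step_linear)
    grid_ref = np.arange(lo, hi, config.grid_step_reflector)

    spectra: list[Spectrum] = []
    for _, row in plaques.iterrows():
        base_meta = {"plaque_id": row["plaque_id"], "animal": row["animal"],
                     "region": row["region"]}
        for subregion, f, mode, grid, rp, snr in (
            ("center", row["f_center"], "linear", grid_lin,
             config.resolving_power_linear, config.snr),
            ("periphery", row["f_periphery"], "linear", grid_lin,
             config.resolving_power_linear, config.snr),
            ("whole", row["f_whole"], "reflector", grid_ref,
             config.resolving_power_reflector, config.snr_reflector),
        ):
            mix = im.mixture_envelope(im.LabelingModel(float(f), config.rho), nat, lab)
            spec = im.render_spectrum(mix, rp, mz_grid=grid, mode=mode)
            if snr > 0:
                sd = float(spec.intensity.max()) / snr
                noisy = spec.intensity + rng.normal(0.0, sd, size=spec.intensity.shape)
            else:
                noisy = spec.intensity
            meta = dict(base_meta, subregion=subregion)
            spectra.append(Spectrum(spec.mz, noisy, mode, meta))

    truth = GroundTruth(config=_config_dict(config), plaques=plaques,
                        extras={"rho": config.rho, "scheme": config.scheme})
    return spectra, truth


# ---------------------------------------------------------------------------
# Counts


def simulate_counts(
    config: SimulationConfig, age: np.ndarray, roi_ids: list[str] | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Negative-binomial gene x ROI counts with age-correlated planted sets.

    Planted sets (name -> (target Pearson r, n genes)) get a latent
    expression profile with the stated correlation to ``age`` on the log
    scale; remaining genes are null. Per-ROI library-size factors are
    log-normal. ``dispersion`` is the NB alpha (variance mu + alpha mu^2);
    dispersion 0 switches off both biological and counting noise, making
    null genes exactly constant.
    """
    rng = np.random.default_rng(config.seed + 1)
    age = np.asarray(age, dtype=float)
    n_roi = len(age)
    z = (age - age.mean()) / (age.std() if age.std() > 0 else 1.0)

    names: list[str] = []
    planted_r: list[float] = []
    set_map: dict[str, list[str]] = {}
    for set_name, (r, k) in config.planted_sets.items():
        ids = [f"{set_name}_{j + 1}" for j in range(k)]
        if any(i in names for i in ids):
            raise ValueError(f"gene-set name collision for {set_name}")
        set_map[set_name] = ids
        names.extend(ids)
        planted_r.extend([r] * k)
    n_null = config.n_genes - len(names)
    if n_null < 0:
        raise ValueError("planted sets exceed n_genes")
    names.extend(f"null_{j + 1}" for j in range(n_null))
    planted_r.extend([0.0] * n_null)
    rvec = np.asarray(planted_r)

    log_mu = rng.normal(config.baseline_log_mean, config.baseline_log_sd, len(names))
    if config.dispersion > 0:
        eps = rng.normal(size=(len(names), n_roi))
    else:
        eps = np.zeros((len(names), n_roi))
    x = rvec[:, None] * z[None, :] + np.sqrt(1.0 - rvec[:, None] ** 2) * eps
    mu = np.exp(log_mu[:, None] + config.effect_scale * x)
    lib = np.exp(rng.normal(0.0, config.libsize_sd, n_roi)) if config.libsize_sd > 0 \
        else np.ones(n_roi)
    mu = mu * lib[None, :]
    if config.dispersion > 0:
        size = 1.0 / config.dispersion
        counts = rng.negative_binomial(size, size / (size + mu))
    else:
        counts = np.rint(mu).astype(int)
    if roi_ids is None:
        roi_ids = [f"roi{j + 1}" for j in range(n_roi)]
    table = pd.DataFrame(counts, index=pd.Index(names, name="gene"), columns=roi_ids)
    truth = GroundTruth(
        config=_config_dict(config),
        extras={"age": age.tolist(), "planted_sets": set_map,
                "planted_r": {k: config.planted_sets[k][0] for k in set_map}},
    )
    return table, truth


# ---------------------------------------------------------------------------
# Hyperspectral imaging


def reference_emission_spectra(
    n_channels: int = 32, wavelength_range: tuple[float, float] = (480.0, 690.0)
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Parametric q-FTAA / h-FTAA emission curves on the channel grid.

    Two-Gaussian shapes with maxima at 500 nm (q-FTAA) and 580 nm (h-FTAA),
    unit peak normalisation. Returns (wavelengths, q_curve, h_curve).
    """
    wl = np.linspace(wavelength_range[0], wavelength_range[1], n_channels)
    # secondary shoulders give realistic red tails but are kept weak enough
    # that each composite maximum stays at its stated peak wavelength
    q = np.exp(-0.5 * ((wl - 500.0) / 30.0) ** 2) + 0.12 * np.exp(
        -0.5 * ((wl - 560.0) / 45.0) ** 2
    )
    h = np.exp(-0.5 * ((wl - 580.0) / 35.0) ** 2) + 0.12 * np.exp(
        -0.5 * ((wl - 640.0) / 45.0) ** 2
    )
    return wl, q / q.max(), h / h.max()


@dataclass
class HyperspectralSim:
    wavelengths: np.ndarray
    stack: np.ndarray  # (C, H, W)
    ab_image: np.ndarray
    homer1: np.ndarray
    lamp1: np.ndarray
    plaque_labels: np.ndarray
    plaque_meta: pd.DataFrame
    truth: GroundTruth


def simulate_hyperspectral(
    config: SimulationConfig, maturity: np.ndarray | None = None
) -> HyperspectralSim:
    """LCO stack + marker images around planted plaques.

    Plaques are discs placed on a non-overlapping lattice (so no contested
    ring pixels by default). Each LCO-positive plaque pixel mixes the q and
    h reference spectra with a q-fraction that rises toward the core in
    proportion to the plaque's maturity score; marker images get
    piecewise-constant 10-um ring profiles (HOMER1 deficit recovering
    outward, LAMP1 elevation decaying outward) with type-ordered amplitude.
    ``maturity`` optionally supplies per-plaque maturity scores in [0, 1]
    (e.g. from the MSI ground truth) for the h+q+ plaques.
    """
    rng = np.random.default_rng(config.seed + 2)
    h_img, w_img = config.image_shape
    px = config.pixel_size_um
    wl, q_ref, h_ref = reference_emission_spectra(
        config.n_channels, config.wavelength_range
    )
    r_px = config.plaque_radius_um / px
    margin = r_px + 30.0 / px + 2
    types = (
        ["Ab+h+q+"] * config.plaques_per_type[0]
        + ["Ab+h+q-"] * config.plaques_per_type[1]
        + ["Ab+h-q-"] * config.plaques_per_type[2]
    )
    n_plaques = len(types)
    # lattice placement with ring-wide separation
    cols = int(np.ceil(np.sqrt(n_plaques)))
    rows_n = int(np.ceil(n_plaques / cols))
    xs = np.linspace(margin, w_img - margin, cols)
    ys = np.linspace(margin, h_img - margin, rows_n)
    centers = [(ys[i // cols], xs[i % cols]) for i in range(n_plaques)]

    yy, xx = np.mgrid[:h_img, :w_img]
    labels = np.zeros((h_img, w_img), dtype=int)
    ab = np.full((h_img, w_img), 0.05)
    homer1 = np.ones((h_img, w_img))
    lamp1 = np.ones((h_img, w_img))
    stack = np.full((config.n_channels, h_img, w_img), 0.01)

    ab_level = {"Ab+h+q+": 1.0, "Ab+h+q-": 0.8, "Ab+h-q-": 0.6}
    meta_rows = []
    hq_count = 0
    for pid, ((cy, cx), tlab) in enumerate(zip(centers, types), start=1):
        dist_px = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        disc = dist_px <= r_px
        labels[disc] = pid
        ab[disc] = ab_level[tlab]
        if tlab == "Ab+h+q+":
            if maturity is not None and hq_count < len(maturity):
                mat = float(maturity[hq_count])
            else:
                mat = float(rng.uniform(0.6, 1.0))
            hq_count += 1
        elif tlab == "Ab+h+q-":
            mat = float(rng.uniform(0.05, 0.15))
        else:
            mat = 0.0
        # q-fraction rises toward the core
        qfrac = np.clip(mat * (1.0 - dist_px / r_px), 0.0, 1.0)
        lco_amp = 1.0 if tlab != "Ab+h-q-" else 0.02
        mix = qfrac[None, disc] * q_ref[:, None] + (1.0 - qfrac[None, disc]) * h_ref[:, None]
        stack[:, disc] += lco_amp * mix
        # ring profiles, piecewise constant per 10-um annulus from the edge
        dist_um = (dist_px - r_px) * px
        for k, (lo_d, hi_d) in enumerate(((0.0, 10.0), (10.0, 20.0), (20.0, 30.0))):
            ring = (dist_um > lo_d) & (dist_um <= hi_d)
            homer1[ring] *= config.homer1_deficit[tlab][k]
            lamp1[ring] *= config.lamp1_elevation[tlab][k]
        meta_rows.append(
            {"plaque_id": pid, "type": tlab, "maturity": mat,
             "center_y": float(cy), "center_x": float(cx),
             "radius_um": config.plaque_radius_um,
             "image": "img1", "animal": "animal1"}
        )
    if config.image_noise_sd > 0:
        stack = stack + rng.normal(0.0, config.image_noise_sd, stack.shape)
        ab = ab + rng.normal(0.0, config.image_noise_sd, ab.shape)
        homer1 = homer1 + rng.normal(0.0, config.image_noise_sd, homer1.shape)
        lamp1 = lamp1 + rng.normal(0.0, config.image_noise_sd, lamp1.shape)
    meta = pd.DataFrame(meta_rows)
    truth = GroundTruth(
        config=_config_dict(config),
        plaques=meta,
        extras={"homer1_deficit": config.homer1_deficit,
                "lamp1_elevation": config.lamp1_elevation},
    )
    return HyperspectralSim(wl, stack, ab, homer1, lamp1, labels, meta, truth)
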