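"""Peptide isotopologue modelling at arbitrary 15N enrichment.

This module is the analytic backbone of the package: it computes elemental
compositions of peptides, convolves per-atom isotope distributions into
nominal-mass-binned isotopologue envelopes, mixes labeled and unlabeled
populations, and renders the result as a resolution-limited mass spectrum.

The metabolic-labeling picture is a two-parameter model:

* ``rho`` — the probability that any one nitrogen atom in a molecule
  synthesised *during* the labeling period is 15N (the tissue relative
  isotope abundance, which is below the dietary enrichment);
* ``f``  — the fraction of deposited molecules synthesised during the
  labeling period.

The observed envelope is the mixture ``(1 - f) * natural + f * labeled`` and
its mean mass is exactly affine in ``f`` — that linearity is what makes the
envelope centroid a usable relative-age coordinate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ABETA42_SEQUENCE",
    "PROTON_MASS",
    "PeptideSpecies",
    "ElementalComposition",
    "IsotopeTable",
    "IsotopologueDistribution",
    "LabelingModel",
    "composition_from_sequence",
    "natural_distribution",
    "labeled_distribution",
    "mixture_envelope",
    "render_spectrum",
    "monoisotopic_mz",
]

log = logging.getLogger(__name__)

#: Human amyloid-beta 1-42, the species the pipeline tracks.
ABETA42_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"

PROTON_MASS = 1.007276466621  # Da

# Residue (= amino acid minus water) elemental compositions, (C, H, N, O, S).
_RESIDUES: dict[str, tuple[int, int, int, int, int]] = {
    "G": (2, 3, 1, 1, 0),
    "A": (3, 5, 1, 1, 0),
    "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0),
    "V": (5, 9, 1, 1, 0),
    "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1),
    "L": (6, 11, 1, 1, 0),
    "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0),
    "D": (4, 5, 1, 3, 0),
    "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0),
    "E": (5, 7, 1, 3, 0),
    "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0),
    "F": (9, 9, 1, 1, 0),
    "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0),
    "W": (11, 10, 2, 1, 0),
}

_ELEMENTS = ("C", "H", "N", "O", "S")


@dataclass(frozen=True)
class PeptideSpecies:
    """A peptide ion: sequence, charge state and adduct mass (proton default)."""

    sequence: str
    charge: int = 1
    adduct_mass: float = PROTON_MASS

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = sorted(set(self.sequence) - set(_RESIDUES))
        if bad:
            raise ValueError(f"unknown residue letter(s): {', '.join(bad)}")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")


@dataclass(frozen=True)
class ElementalComposition:
    """Atom counts for C, H, N, O, S."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        for el, n in self.counts.items():
            if el not in _ELEMENTS:
                raise ValueError(f"unsupported element {el!r}")
            if n < 0:
                raise ValueError(f"negative count for {el}")

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())

    def formula(self) -> str:
        return "".join(
            f"{el}{self.counts[el]}" for el in _ELEMENTS if self.counts.get(el, 0)
        )


@dataclass(frozen=True)
class LabelingModel:
    """Pulse labeling parameters: molecule label fraction f, per-N 15N prob rho."""

    f: float
    rho: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("f must be in [0, 1]")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")


class IsotopeTable:
    """Per-element isotope masses and abundances.

    Loaded from the packaged CSV of standard natural abundances by default;
    :meth:`with_nitrogen_enrichment` returns a copy whose nitrogen channel is
    a two-point (14N, 15N) distribution at the given 15N probability.
    """

    def __init__(self, entries: dict[str, tuple[np.ndarray, np.ndarray]]):
        self._entries = {}
        for el, (masses, abund) in entries.items():
            masses = np.asarray(masses, dtype=float)
            abund = np.asarray(abund, dtype=float)
            if np.any(np.diff(masses) <= 0):
                raise ValueError(f"{el}: isotope masses must be strictly increasing")
            if abs(abund.sum() - 1.0) > 1e-9:
                raise ValueError(f"{el}: abundances must sum to 1")
            self._entries[el] = (masses, abund)

    @classmethod
    def natural(cls, path: str | Path | None = None) -> "IsotopeTable":
        if path is None:
            with resources.as_file(
                resources.files("plaquetime.data").joinpath("isotopes.csv")
            ) as p:
                df = pd.read_csv(p)
        else:
            df = pd.read_csv(path)
        entries = {
            el: (grp["mass"].to_numpy(), grp["abundance"].to_numpy())
            for el, grp in df.groupby("element", sort=False)
        }
        return cls(entries)

    def __getitem__(self, element: str) -> tuple[np.ndarray, np.ndarray]:
        return self._entries[element]

    def __contains__(self, element: str) -> bool:
        return element in self._entries

    @property
    def n15_mass_shift(self) -> float:
        """Mass difference m(15N) - m(14N), taken from the table."""
        masses, _ = self._entries["N"]
        return float(masses[1] - masses[0])

    def with_nitrogen_enrichment(self, rho: float) -> "IsotopeTable":
        if not 0.0 <= rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        entries = dict(self._entries)
        masses, _ = self._entries["N"]
        entries["N"] = (masses[:2], np.array([1.0 - rho, rho]))
        return IsotopeTable(entries)


@dataclass
class IsotopologueDistribution:
    """Nominal-mass-binned isotopologue envelope of one peptide ion.

    ``offsets`` are integer nominal-mass offsets from the all-light
    (monoisotopic) species; ``mz`` are abundance-weighted mean m/z per bin.
    """

    offsets: np.ndarray
    mz: np.ndarray
    probabilities: np.ndarray
    charge: int = 1

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=int)
        self.mz = np.asarray(self.mz, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if np.any(np.diff(self.offsets) <= 0):
            raise ValueError("offsets must be strictly increasing")
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    @property
    def mean_mz(self) -> float:
        return float(np.sum(self.mz * self.probabilities))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"offset": self.offsets, "mz": self.mz, "probability": self.probabilities}
        ).to_csv(path, sep="\t", index=False)


def composition_from_sequence(species: PeptideSpecies) -> ElementalComposition:
    """Sum residue compositions over the sequence and add one water."""
    totals = np.zeros(5, dtype=int)
    for aa in species.sequence:
        totals += np.asarray(_RESIDUES[aa])
    totals += np.array([0, 2, 0, 1, 0])  # H2O
    return ElementalComposition(dict(zip(_ELEMENTS, (int(x) for x in totals))))


def monoisotopic_mz(species: PeptideSpecies, table: IsotopeTable | None = None) -> float:
    """m/z of the all-lightest-isotope species, with charge and adduct."""
    table = table if table is not None else IsotopeTable.natural()
    comp = composition_from_sequence(species)
    mass = sum(comp[el] * table[el][0][0] for el in _ELEMENTS)
    return (mass + species.charge * species.adduct_mass) / species.charge


# --- nominal-mass convolution machinery -------------------------------------


def _atom_pmf(masses: np.ndarray, abund: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom (probability, conditional-mean-mass) arrays on nominal offsets."""
    offsets = np.rint(masses - masses[0]).astype(int)
    n = int(offsets[-1]) + 1
    p = np.zeros(n)
    pm = np.zeros(n)
    for off, m, a in zip(offsets, masses, abund):
        p[off] += a
        pm[off] += a * m
    return p, pm


def _convolve(a: tuple[np.ndarray, np.ndarray], b: tuple[np.ndarray, np.ndarray],
              floor: float) -> tuple[np.ndarray, np.ndarray]:
    pa, pma = a
    pb, pmb = b
    p = np.convolve(pa, pb)
    pm = np.convolve(pma, pb) + np.convolve(pa, pmb)
    keep = p >= floor
    if not keep.any():
        raise ValueError("distribution vanished under pruning floor")
    last = np.nonzero(keep)[0][-1]
    p, pm = p[: last + 1], pm[: last + 1]
    # zero out (don't drop) interior sub-floor bins so offsets stay aligned
    tiny = p < floor
    p[tiny] = 0.0
    pm[tiny] = 0.0
    s = p.sum()
    return p / s, pm / s


def _power(base: tuple[np.ndarray, np.ndarray], n: int,
           floor: float) -> tuple[np.ndarray, np.ndarray] | None:
    """Distribution of the sum over n iid atoms, by squaring."""
    result = None
    sq = base
    while n:
        if n & 1:
            result = sq if result is None else _convolve(result, sq, floor)
        n >>= 1
        if n:
            sq = _convolve(sq, sq, floor)
    return result


def _distribution(comp: ElementalComposition, table: IsotopeTable, charge: int,
                  adduct_mass: float, floor: float) -> IsotopologueDistribution:
    if comp.n_atoms == 0:
        raise ValueError("empty composition")
    acc: tuple[np.ndarray, np.ndarray] | None = None
    for el in _ELEMENTS:
        n = comp[el]
        if n == 0:
            continue
        part = _power(_atom_pmf(*table[el]), n, floor)
        acc = part if acc is None else _convolve(acc, part, floor)
    assert acc is not None
    p, pm = acc
    nz = p > 0
    offsets = np.nonzero(nz)[0]
    probs = p[nz]
    mean_mass = pm[nz] / probs
    probs = probs / probs.sum()
    mz = (mean_mass + charge * adduct_mass) / charge
    return IsotopologueDistribution(offsets, mz, probs, charge=charge)


def natural_distribution(
    comp: ElementalComposition,
    table: IsotopeTable | None = None,
    charge: int = 1,
    adduct_mass: float = PROTON_MASS,
    prune_floor: float = 1e-10,
) -> IsotopologueDistribution:
    """Isotopologue envelope at natural isotope abundances.

    Per-atom distributions are convolved iteratively on nominal-mass bins
    (bins below ``prune_floor`` are dropped and the rest renormalised after
    every convolution step); bin masses are abundance-weighted means.
    """
    table = table if table is not None else IsotopeTable.natural()
    return _distribution(comp, table, charge, adduct_mass, prune_floor)


def labeled_distribution(
    comp: ElementalComposition,
    table: IsotopeTable | None = None,
    rho: float = 0.98,
    charge: int = 1,
    adduct_mass: float = PROTON_MASS,
    prune_floor: float = 1e-10,
) -> IsotopologueDistribution:
    """Envelope with the nitrogen channel replaced by (1-rho, rho) on (14N, 15N)."""
    table = table if table is not None else IsotopeTable.natural()
    return _distribution(
        comp, table.with_nitrogen_enrichment(rho), charge, adduct_mass, prune_floor
    )


def mixture_envelope(
    model: LabelingModel,
    nat: IsotopologueDistribution,
    lab: IsotopologueDistribution,
) -> IsotopologueDistribution:
    """Pointwise mixture (1-f)*nat + f*lab, re-binned by nominal offset.

    The mean m/z of the result is exactly affine in ``f``.
    """
    if nat.charge != lab.charge:
        raise ValueError("mixture components must share a charge state")
    f = model.f
    lo = min(nat.offsets[0], lab.offsets[0])
    hi = max(nat.offsets[-1], lab.offsets[-1])
    n = hi - lo + 1
    p = np.zeros(n)
    pm = np.zeros(n)
    for w, d in ((1.0 - f, nat), (f, lab)):
        if w == 0.0:
            continue
        idx = d.offsets - lo
        p[idx] += w * d.probabilities
        pm[idx] += w * d.probabilities * d.mz
    nz = p > 0
    offsets = np.arange(lo, hi + 1)[nz]
    probs = p[nz]
    mz = pm[nz] / probs
    return IsotopologueDistribution(offsets, mz, probs / probs.sum(), charge=nat.charge)


def render_spectrum(
    dist: IsotopologueDistribution,
    resolving_power: float,
    mz_grid: np.ndarray | None = None,
    mode: str = "linear",
    meta: dict | None = None,
):
    """Convolve the stick envelope with instrument-resolution Gaussians.

    Each stick at m/z ``m`` becomes a Gaussian of FWHM ``m / resolving_power``
    and area equal to its probability, so the integrated intensity is
    independent of resolving power. Returns a :class:`plaquetime.spectra.Spectrum`.
    """
    from .spectra import Spectrum  # local import: spectra is a leaf module

    if resolving_power <= 0:
        raise ValueError("resolving_power must be positive")
    fwhm = dist.mz / resolving_power
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    if mz_grid is None:
        # generous padding: downstream fit-range selection may extend several
        # provisional FWHMs beyond the envelope before its stop rule triggers
        pad = 6.0 * float(sigma.max()) + 30.0
        step = float(fwhm.min()) / 8.0
        mz_grid = np.arange(dist.mz[0] - pad, dist.mz[-1] + pad + step, step)
    else:
        mz_grid = np.asarray(mz_grid, dtype=float)
        if len(mz_grid) > 1:
            spacing = float(np.max(np.diff(mz_grid)))
            if spacing > float(fwhm.min()) / 4.0:
                log.warning(
                    "m/z grid spacing %.3g coarser than FWHM/4 = %.3g; "
                    "rendered peaks may be under-sampled",
                    spacing,
                    float(fwhm.min()) / 4.0,
                )
    intensity = np.zeros_like(mz_grid)
    for m, s, p in zip(dist.mz, sigma, dist.probabilities):
        if p == 0.0:
            continue
        amp = p / (s * np.sqrt(2.0 * np.pi))
        lo = np.searchsorted(mz_grid, m - 8.0 * s)
        hi = np.searchsorted(mz_grid, m + 8.0 * s)
        x = mz_grid[lo:hi]
        intensity[lo:hi] += amp * np.exp(-0.5 * ((x - m) / s) ** 2)
    return Spectrum(mz=mz_grid, intensity=intensity, mode=mode, meta=meta or {})
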